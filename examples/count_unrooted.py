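"""Count unrooted trees via the centroid decomposition.

Every tree is rooted canonically at its Jordan centroid: odd orders have
a single centroid vertex; even orders may instead have a centroid edge
whose removal splits the tree into two equal halves.  The script prints
both contributions for a small even instance and the reference counts
for the larger instances.
"""

from treeloops import bicentroid_count, build_table, t_unrooted, unicentroid_count

n, delta = 10, 5
table = build_table(n, delta)
uni = unicentroid_count(n, delta, table)
bi = bicentroid_count(n, delta, table)
print(f"trees with {n} vertices, {delta} loops: {uni + bi}")
print(f"  with a centroid vertex: {uni}")
print(f"  with a centroid edge:   {bi}")

print("reference instances:")
for m, d in [(10, 0), (20, 0), (10, 5), (10, 30), (20, 10), (30, 10)]:
    print(f"  t({m},{d}) = {t_unrooted(m, d)}")
# Counts are exact integers; the last one exceeds 2.5 * 10^18, well past
# what the naive enumerate-and-deduplicate route could ever reach.
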