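"""Count rooted trees with self-loops and peek inside the DP table.

Builds the count table for 6 vertices and 2 self-loops, prints the total
number of rooted isomorphism classes, and shows how the total splits by
(Maxv, Maxs) — the size of the root's largest child subtree and the loop
count of the largest such subtree.
"""

from treeloops import build_table, h_rooted

n, delta = 6, 2
table = build_table(n, delta)

print(f"rooted trees with {n} vertices and {delta} self-loops: {h_rooted(n, delta)}")
print("breakdown by (largest child subtree size, its loop count):")
for m in range(n):
    for d in range(delta + 1):
        count = table.eq_eq_at(n, delta, m, d)
        if count:
            print(f"  Maxv={m} Maxs={d}: {count}")
# The cells above partition the total: each rooted class has exactly one
# (Maxv, Maxs) profile, which is what drives the recurrence.
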