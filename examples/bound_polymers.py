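"""Bracket the number of tree-like polymer topologies by cycle rank.

A tree-like polymer topology is a loop tree in which every vertex has
degree at least three (a self-loop adds two).  Exact counts are open;
the package computes exact integer lower and upper bounds from tree
counts.  Rank 1 is the known degenerate case where the printed lower
bound counts a non-polymer and the bounds cross — it is flagged, not
patched.
"""

from treeloops import polymer_bounds

print("rank  lower  upper  valid")
for r in range(1, 9):
    b = polymer_bounds(r)
    print(f"{b.rank:>4}  {b.lower:>5}  {b.upper:>5}  {b.valid}")
# Each row says: of all polymer topologies with self-loops and no
# multi-edges whose cycle rank is r, at least `lower` and at most `upper`
# exist up to isomorphism.
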