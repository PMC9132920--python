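"""Dated-tree utilities: grafting a missing tip and patristic distances.

Newly described or elevated species are often absent from published dated
trees; grafting them onto their sister's terminal edge (preserving
ultrametricity) lets the reconciliation cascade compute divergence times for
them too.
"""
from enmpipe import graft_tip, patristic_distance, read_newick
from enmpipe.taxa import is_ultrametric, tip_labels

tree = read_newick("((A:2,B:2):3,(C:4,D:4):1);")
print("tips:", tip_labels(tree))
print(f"d(A,B) = {patristic_distance(tree, 'A', 'B')} My, "
      f"d(A,C) = {patristic_distance(tree, 'A', 'C')} My")

grafted = graft_tip(tree, sister="A", new_tip="A2", stem_fraction=0.5)
print("after grafting A2 onto A's terminal edge at its midpoint:")
print(f"  d(A,A2) = {patristic_distance(grafted, 'A', 'A2')} My  "
      f"(attachment 1 My above A, so 1 + 1)")
print(f"  d(B,A2) = {patristic_distance(grafted, 'B', 'A2')} My  (unchanged via B's path)")
print(f"  d(A,B) still {patristic_distance(grafted, 'A', 'B')} My; "
      f"ultrametric: {is_ultrametric(grafted)}")
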