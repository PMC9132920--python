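"""Synonym-aware name harmonization and dated-tree utilities.

Occurrence records frequently carry outdated binomials or trinomials whose
subspecies was since elevated to species rank. :func:`update_name` resolves a
(genus, species[, subspecies]) triple against a synonym table; exact matches
of the most specific name win, and a per-component Levenshtein fallback
handles misspelled names. Tree utilities operate on rooted, dated phylogenies
(branch lengths in millions of years): grafting a tip onto a terminal edge
while preserving ultrametricity, and patristic distance between tips.
"""
from __future__ import annotations

import io
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import dendropy
import pandas as pd

_WS = re.compile(r"\s+")


def normalize_name(*components: Optional[str]) -> tuple[str, ...]:
    """Trim, collapse whitespace and lowercase non-empty name components."""
    out = []
    for c in components:
        if c is None:
            continue
        c = _WS.sub(" ", str(c).strip()).lower()
        if c:
            out.append(c)
    return tuple(out)


def canonical(name: str) -> str:
    """Render a name in canonical 'Genus epithet...' capitalization."""
    parts = normalize_name(*name.split())
    if not parts:
        return ""
    return " ".join([parts[0].capitalize(), *parts[1:]])


def levenshtein(a: str, b: str) -> int:
    """Edit distance between two short strings (insert/delete/substitute = 1)."""
    if a == b:
        return 0
    if len(a) < len(b):
        a, b = b, a
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


class SynonymTable:
    """Historical name -> current accepted binomial lookup.

    Keys are normalized lowercase names (binomial or trinomial); values are
    accepted binomials in canonical capitalization. Every accepted value is
    also entered as a key resolving to itself, so resolution is idempotent.
    """

    def __init__(self, entries: dict[str, str]):
        self._map: dict[tuple[str, ...], str] = {}
        for syn, acc in entries.items():
            key = normalize_name(*str(syn).split())
            val = canonical(acc)
            if not key or not val:
                raise ValueError(f"empty name in synonym entry {syn!r} -> {acc!r}")
            if key in self._map and self._map[key] != val:
                raise ValueError(f"synonym {syn!r} maps to both {self._map[key]!r} and {val!r}")
            self._map[key] = val
        # accepted names resolve to themselves
        for val in list(self._map.values()):
            key = normalize_name(*val.split())
            existing = self._map.setdefault(key, val)
            if existing != val:
                raise ValueError(f"accepted name {val!r} is also a synonym of {existing!r}")

    def __len__(self) -> int:
        return len(self._map)

    def __contains__(self, name: str) -> bool:
        return normalize_name(*str(name).split()) in self._map

    def get(self, *components: Optional[str]) -> Optional[str]:
        return self._map.get(normalize_name(*components))

    def items(self):
        return self._map.items()

    @property
    def accepted_names(self) -> set[str]:
        return set(self._map.values())

    @classmethod
    def from_csv(cls, path: str | Path | io.TextIOBase) -> "SynonymTable":
        df = pd.read_csv(path)
        missing = {"synonym", "accepted"} - set(df.columns)
        if missing:
            raise ValueError(f"synonym CSV missing columns: {sorted(missing)}")
        return cls(dict(zip(df["synonym"].astype(str), df["accepted"].astype(str))))

    def to_csv(self, path: str | Path) -> None:
        rows = sorted((" ".join(k), v) for k, v in self._map.items())
        pd.DataFrame(rows, columns=["synonym", "accepted"]).to_csv(path, index=False)


@dataclass(frozen=True)
class NameUpdate:
    """Outcome of resolving one record's name fields."""

    name: str
    changed: bool
    ambiguous: bool = False
    not_in_table: bool = False


def update_name(
    genus: str,
    species: str,
    subspecies: Optional[str],
    table: SynonymTable,
) -> NameUpdate:
    """Resolve a (genus, species[, subspecies]) name against a synonym table.

    Resolution order:

    1. exact trinomial key (the authoritative entry for a subspecies elevated
       to species rank);
    2. resolve the species (genus+species key) and, when a subspecies is
       present, the subspecies (genus+subspecies key) separately: agreement
       (or a single resolution) wins; two different accepted names trigger a
       per-component edit-distance contest, with ``ambiguous`` reported on a
       tie (broken by fewer changed components, then lexicographically);
    3. fallback: the accepted name reachable with the minimum summed
       per-component Levenshtein distance over all table keys, with the same
       tie handling.

    A name with no plausible match (minimum distance above a quarter of the
    name's length, and at least 2) is returned unchanged with
    ``not_in_table`` set.
    """
    g, s = normalize_name(genus), normalize_name(species)
    if not g or not s:
        raise ValueError("genus and species must be non-empty")
    comps = (*g, *s, *normalize_name(subspecies))
    input_binomial = canonical(f"{g[0]} {s[0]}")

    if len(comps) == 3:
        hit = table.get(*comps)
        if hit is not None:
            return NameUpdate(hit, changed=hit != input_binomial)
        x = table.get(comps[0], comps[1])       # species resolution
        y = table.get(comps[0], comps[2])       # subspecies resolution
        if x is not None and (y is None or y == x):
            return NameUpdate(x, changed=x != input_binomial)
        if y is not None and x is None:
            return NameUpdate(y, changed=y != input_binomial)
        if x is not None and y is not None:     # disagreement: edit-distance contest
            scored = sorted(_component_distance(comps, normalize_name(*c.split())) + (c,)
                            for c in (x, y))
            winner = scored[0][2]
            ambiguous = scored[1][0] == scored[0][0]
            return NameUpdate(winner, changed=winner != input_binomial,
                              ambiguous=ambiguous)
    else:
        hit = table.get(comps[0], comps[1])
        if hit is not None:
            return NameUpdate(hit, changed=hit != input_binomial)

    # fuzzy fallback over all keys
    best: list[tuple[int, int, str]] = []  # (distance, n_changed_components, accepted)
    best_d = None
    for key, accepted in table.items():
        d, changed_comps = _component_distance(comps, key)
        if best_d is None or d < best_d:
            best_d = d
            best = [(d, changed_comps, accepted)]
        elif d == best_d:
            best.append((d, changed_comps, accepted))
    # no plausible match: repair budget of a quarter of the name's length
    max_reasonable = max(2, sum(len(c) for c in comps) // 4)
    if best_d is None or best_d > max_reasonable:
        return NameUpdate(input_binomial, changed=False, not_in_table=True)

    candidates = sorted({(nc, acc) for _, nc, acc in best})
    distinct = sorted({acc for _, acc in candidates})
    ambiguous = len(distinct) > 1
    min_changed = candidates[0][0]
    winner = sorted(acc for nc, acc in candidates if nc == min_changed)[0]
    return NameUpdate(winner, changed=winner != input_binomial, ambiguous=ambiguous)


def _component_distance(comps: tuple[str, ...], key: tuple[str, ...]) -> tuple[int, int]:
    """Summed per-component Levenshtein between an input name and a table key.

    When the input is a trinomial and the key a binomial, the key's epithet is
    matched against whichever of species/subspecies is closer (the other
    component is treated as dropped at no cost: the elevation case). The
    symmetric rule applies for binomial input vs trinomial key.
    """
    d = levenshtein(comps[0], key[0])
    changed = int(d > 0)
    ci, ki = comps[1:], key[1:]
    if len(ci) == len(ki):
        for a, b in zip(ci, ki):
            dd = levenshtein(a, b)
            d += dd
            changed += int(dd > 0)
    elif len(ci) > len(ki):  # trinomial input vs binomial key
        dd = min(levenshtein(c, ki[0]) for c in ci)
        d += dd
        changed += int(dd > 0)
    else:  # binomial input vs trinomial key
        dd = min(levenshtein(ci[0], k) for k in ki)
        d += dd
        changed += int(dd > 0)
    return d, changed


# ---------------------------------------------------------------------------
# Dated-tree utilities
# ---------------------------------------------------------------------------

def read_newick(source: str | Path) -> dendropy.Tree:
    """Read a rooted Newick tree with branch lengths (millions of years)."""
    src = Path(source)
    if src.exists():
        tree = dendropy.Tree.get(path=str(src), schema="newick")
    else:
        tree = dendropy.Tree.get(data=str(source), schema="newick")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise ValueError("negative branch length in tree")
    return tree


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True,
               real_value_format_specifier=".9g")


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


def _leaf(tree: dendropy.Tree, label: str):
    for lf in tree.leaf_node_iter():
        if lf.taxon is not None and lf.taxon.label == label:
            return lf
    raise KeyError(f"tip {label!r} not found in tree")


def patristic_distance(tree: dendropy.Tree, a: str, b: str) -> float:
    """Sum of branch lengths along the unique path between tips ``a`` and ``b``."""
    if a == b:
        _leaf(tree, a)  # existence check
        return 0.0
    na, nb = _leaf(tree, a), _leaf(tree, b)
    depth: dict[int, float] = {}
    anc_a = {}
    node, d = na, 0.0
    while node is not None:
        anc_a[id(node)] = d
        d += node.edge.length or 0.0
        node = node.parent_node
    node, d = nb, 0.0
    while node is not None:
        if id(node) in anc_a:
            return anc_a[id(node)] + d
        d += node.edge.length or 0.0
        node = node.parent_node
    raise ValueError("tips are not connected (malformed tree)")


def patristic_matrix(tree: dendropy.Tree) -> pd.DataFrame:
    labels = sorted(tip_labels(tree))
    out = pd.DataFrame(0.0, index=labels, columns=labels)
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            d = patristic_distance(tree, a, b)
            out.loc[a, b] = out.loc[b, a] = d
    return out


def graft_tip(
    tree: dendropy.Tree,
    sister: str,
    new_tip: str,
    stem_fraction: float = 0.5,
) -> dendropy.Tree:
    """Attach ``new_tip`` on the terminal edge of ``sister``.

    The attachment point sits at ``stem_fraction`` of the sister's terminal
    edge measured from the tip; the new tip's branch length equals the
    sister's remaining depth below the attachment, so an ultrametric tree
    stays ultrametric and all pre-existing pairwise patristic distances are
    unchanged. Returns a new tree; the input is not modified.
    """
    if not (0.0 < stem_fraction <= 1.0):
        raise ValueError("stem_fraction must be in (0, 1]")
    if new_tip in tip_labels(tree):
        raise ValueError(f"tip {new_tip!r} already present")
    tree = tree.clone(depth=1)
    sis = _leaf(tree, sister)
    edge_len = sis.edge.length
    if edge_len is None:
        raise ValueError(f"sister tip {sister!r} has no branch length")
    parent = sis.parent_node
    if parent is None:
        raise ValueError("cannot graft onto the root tip of a single-tip tree")
    below = stem_fraction * edge_len

    attach = dendropy.Node()
    attach.edge.length = edge_len - below
    parent.remove_child(sis)
    parent.add_child(attach)
    sis.edge.length = below
    attach.add_child(sis)
    taxon = tree.taxon_namespace.require_taxon(label=new_tip)
    child = dendropy.Node(taxon=taxon)
    child.edge.length = below
    attach.add_child(child)
    return tree


def remove_tip(tree: dendropy.Tree, label: str) -> dendropy.Tree:
    """Prune a tip (merging its orphaned parent edge); returns a new tree."""
    tree = tree.clone(depth=1)
    lf = _leaf(tree, label)
    tree.prune_subtree(lf, suppress_unifurcations=True)
    return tree


def is_ultrametric(tree: dendropy.Tree, tol: float = 1e-9) -> bool:
    depths = []
    for lf in tree.leaf_node_iter():
        d, node = 0.0, lf
        while node.parent_node is not None:
            d += node.edge.length or 0.0
            node = node.parent_node
        depths.append(d)
    return max(depths) - min(depths) < tol
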