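"""Occurrence-record reconciliation against range polygons.

A record that falls outside the range of its recorded species is often a
victim of taxonomic churn: the population it belongs to has since been
assigned to another species whose range *does* cover the point. The
reconciliation cascade therefore joins each record with nearby species
ranges, and resolves mismatches by minimizing phylogenetic distance first and
geographic distance second, flagging records it cannot resolve:

1. the recorded species' own range is among the nearby candidates ->
   unchanged (with an ``outside_range`` flag when the point is near but not
   inside it);
2. otherwise restrict the candidates to minimal patristic distance from the
   recorded species; a unique minimizer -> reassigned;
3. a phylogenetic tie -> restrict to minimal geodesic distance; unique ->
   reassigned;
4. still tied -> flagged for manual checking, name retained.

Any reassignment across more than ``dubious_my`` million years of divergence
is additionally flagged as dubious. Records with manual/dubious/outside-range
flags are excluded from downstream distribution modeling.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import dendropy
import pandas as pd
from shapely.geometry.base import BaseGeometry

from .geodesy import point_geometry_distance_m
from .taxa import SynonymTable, canonical, patristic_distance, tip_labels, update_name

PHYLO_TIE_TOL_MY = 1e-9
EXCLUSION_FLAGS = {"manual_check", "dubious", "outside_range"}


@dataclass
class Candidate:
    species: str
    geodesic_m: float
    phylo_my: Optional[float] = None


@dataclass
class ReconciliationOutcome:
    record_id: str
    original_name: str
    final_name: str
    action: str  # unchanged | reassigned | flagged_manual | flagged_dubious
    flags: set[str] = field(default_factory=set)
    candidates: list[Candidate] = field(default_factory=list)

    @property
    def excluded_for_modeling(self) -> bool:
        return bool(self.flags & EXCLUSION_FLAGS)


def nearest_distributions(
    lon: float,
    lat: float,
    ranges: dict[str, BaseGeometry],
    k: int = 20,
    radius_km: float = 50.0,
) -> list[tuple[str, float]]:
    """The up-to-``k`` nearest species ranges within ``radius_km`` (inclusive).

    Returns (species, geodesic distance in meters) sorted ascending; a point
    inside a polygon has distance 0. Empty ranges yield an empty list.
    """
    out = []
    limit = radius_km * 1000.0
    for species in sorted(ranges):
        d = point_geometry_distance_m(lon, lat, ranges[species])
        if d <= limit:
            out.append((species, d))
    out.sort(key=lambda t: (t[1], t[0]))
    return out[:k]


def reconcile_record(
    record: pd.Series,
    ranges: dict[str, BaseGeometry],
    tree: dendropy.Tree,
    dubious_my: float = 5.0,
    k: int = 20,
    radius_km: float = 50.0,
    _tips: Optional[set[str]] = None,
) -> ReconciliationOutcome:
    """Apply the reconciliation cascade to one record.

    ``record`` needs fields id, name (current binomial), lon, lat. A name
    absent from the tree cannot be placed phylogenetically and is flagged for
    manual checking.
    """
    rid = str(record["id"])
    name = canonical(record["name"])
    lon, lat = float(record["lon"]), float(record["lat"])
    tips = _tips if _tips is not None else set(tip_labels(tree))

    near = nearest_distributions(lon, lat, ranges, k=k, radius_km=radius_km)
    if name not in tips:
        cands = [Candidate(s, d) for s, d in near]
        return ReconciliationOutcome(rid, name, name, "flagged_manual",
                                     {"manual_check"}, cands)
    if not near:
        return ReconciliationOutcome(rid, name, name, "flagged_manual",
                                     {"manual_check", "outside_range"}, [])

    cands = []
    for species, d in near:
        phylo = patristic_distance(tree, name, species) if species in tips else None
        cands.append(Candidate(species, d, phylo))

    expected = next((c for c in cands if c.species == name), None)
    if expected is not None:
        flags = {"outside_range"} if expected.geodesic_m > 0 else set()
        cands.sort(key=_candidate_key)
        return ReconciliationOutcome(rid, name, name, "unchanged", flags, cands)

    placeable = [c for c in cands if c.phylo_my is not None]
    cands.sort(key=_candidate_key)
    if not placeable:
        return ReconciliationOutcome(rid, name, name, "flagged_manual",
                                     {"manual_check"}, cands)

    min_phylo = min(c.phylo_my for c in placeable)
    closest = [c for c in placeable if c.phylo_my - min_phylo <= PHYLO_TIE_TOL_MY]
    if len(closest) > 1:
        min_geo = min(c.geodesic_m for c in closest)
        closest = [c for c in closest if c.geodesic_m == min_geo]
    if len(closest) > 1:
        return ReconciliationOutcome(rid, name, name, "flagged_manual",
                                     {"manual_check"}, cands)

    winner = closest[0]
    flags = {"taxonomy_changed"}
    action = "reassigned"
    if winner.phylo_my > dubious_my:
        flags.add("dubious")
        action = "flagged_dubious"
    return ReconciliationOutcome(rid, name, winner.species, action, flags, cands)


def _candidate_key(c: Candidate):
    return (c.phylo_my if c.phylo_my is not None else float("inf"),
            c.geodesic_m, c.species)


def reconcile_all(
    records: pd.DataFrame,
    ranges: dict[str, BaseGeometry],
    tree: dendropy.Tree,
    synonyms: Optional[SynonymTable] = None,
    dubious_my: float = 5.0,
    k: int = 20,
    radius_km: float = 50.0,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Reconcile a full occurrence table.

    When a synonym table is given, names are first harmonized with
    :func:`enmpipe.taxa.update_name` (adding a ``taxonomy_changed`` flag), then
    each record passes through the spatial/phylogenetic cascade. Returns the
    outcome table and a summary of counts per action; per-record failures
    become ``flagged_manual`` rather than raising.
    """
    tips = set(tip_labels(tree))
    rows = []
    summary = {"unchanged": 0, "reassigned": 0, "flagged_manual": 0, "flagged_dubious": 0}
    for _, rec in records.iterrows():
        pre_flags: set[str] = set()
        genus, species = str(rec["genus"]), str(rec["species"])
        subsp = rec.get("subspecies")
        if pd.isna(subsp) or subsp == "":
            subsp = None
        original = canonical(f"{genus} {species}")
        name = original
        if synonyms is not None:
            upd = update_name(genus, species, subsp, synonyms)
            name = upd.name
            if upd.changed:
                pre_flags.add("taxonomy_changed")
            if upd.ambiguous:
                pre_flags.add("manual_check")

        try:
            rec2 = pd.Series({"id": rec["id"], "name": name,
                              "lon": rec["lon"], "lat": rec["lat"]})
            outcome = reconcile_record(rec2, ranges, tree, dubious_my=dubious_my,
                                       k=k, radius_km=radius_km, _tips=tips)
        except Exception:
            outcome = ReconciliationOutcome(str(rec["id"]), name, name,
                                            "flagged_manual", {"manual_check"}, [])
        outcome.original_name = original
        outcome.flags |= pre_flags
        if "manual_check" in outcome.flags and outcome.action in ("unchanged", "reassigned"):
            outcome.action = "flagged_manual"
        summary[outcome.action] += 1
        rows.append({
            "id": outcome.record_id,
            "original_name": outcome.original_name,
            "final_name": outcome.final_name,
            "action": outcome.action,
            "flags": ";".join(sorted(outcome.flags)),
            "excluded_for_modeling": outcome.excluded_for_modeling,
            "n_candidates": len(outcome.candidates),
        })
    table = pd.DataFrame(rows, columns=["id", "original_name", "final_name", "action",
                                        "flags", "excluded_for_modeling", "n_candidates"])
    return table, summary
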