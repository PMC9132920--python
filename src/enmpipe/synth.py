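"""Seeded synthetic world: environment, true suitability, phylogeny, ranges
and contaminated occurrence records.

The generator builds a self-consistent toy study system so that every
pipeline stage has a known ground truth: six predictor layers (two
informative, two shadows correlated at ~0.95 with them, two noise), a true
suitability surface that is a logistic function of the two informative
layers, an ultrametric dated phylogeny, range polygons around suitability
peaks, a synonym table with outdated names, and occurrence records
contaminated with planted outdated names and cross-range mislabels whose
truth is kept in a ledger.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import dendropy
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from shapely.geometry import Polygon, box

from . import io as eio
from .geometry import EcoregionSet, chaikin_smooth
from .grid import EnvStack, GridSpec, write_ascii
from .reconcile import reconcile_all
from .taxa import SynonymTable, patristic_distance, write_newick

_EPITHETS = ["arida", "borealis", "cinerea", "dorsata",
             "elegans", "fulva", "gracilis", "humilis"]
_OLD_EPITHETS = ["antiqua", "vetusta", "prisca", "obsoleta",
                 "relicta", "archaea", "caduca", "decessa"]
_GENUS = "Ophiora"


@dataclass
class WorldConfig:
    """Study conditions of the synthetic world."""

    nrows: int = 100
    ncols: int = 100
    xll: float = -105.0
    yll: float = 20.0
    cellsize: float = 0.1          # degrees; 10 x 10 degree extent
    n_species: int = 8
    root_depth_my: float = 20.0
    records_per_species: int = 150
    outdated_rate: float = 0.10    # fraction of records given an outdated name
    mislabel_rate: float = 0.05    # fraction relabeled as the phylo-nearest species
    smooth_sigma: float = 8.0      # cells; spatial autocorrelation of layers
    shadow_corr: float = 0.95
    suit_intercept: float = -0.5
    suit_coef: tuple[float, float] = (2.5, 2.0)   # informative-layer coefficients
    range_radius_deg: float = 1.0
    ecoregion_tiles: int = 5       # per axis

    @property
    def spec(self) -> GridSpec:
        return GridSpec(self.nrows, self.ncols, self.xll, self.yll, self.cellsize)


PREDICTOR_SETS = {
    "bioclimatic": ["bio1", "bio2", "bio3"],
    "topographic": ["topo1", "topo2", "topo3"],
    "combination": ["bio1", "bio2", "bio3", "topo1", "topo2", "topo3"],
}


@dataclass
class SyntheticWorld:
    config: WorldConfig
    seed: int
    world_id: str
    env: EnvStack
    suitability: np.ndarray
    tree: dendropy.Tree
    ranges: dict[str, Polygon]
    ecoregions: EcoregionSet
    records: pd.DataFrame
    synonyms: SynonymTable
    ledger: pd.DataFrame = field(repr=False, default=None)

    @property
    def species(self) -> list[str]:
        return sorted(self.ranges)

    def write(self, outdir: str | Path) -> None:
        """Emit the full fixture as CSV/GeoJSON/ASCII-grid/Newick files."""
        outdir = Path(outdir)
        (outdir / "env").mkdir(parents=True, exist_ok=True)
        self.env.to_ascii_dir(outdir / "env")
        write_ascii(outdir / "true_suitability.asc", self.env.spec, self.suitability)
        eio.write_ranges_geojson(self.ranges, outdir / "ranges.geojson")
        eio.write_ecoregions_geojson(self.ecoregions, outdir / "ecoregions.geojson")
        eio.write_occurrences_csv(self.records, outdir / "occurrences.csv")
        self.synonyms.to_csv(outdir / "synonyms.csv")
        write_newick(self.tree, outdir / "tree.nwk")
        self.ledger.to_csv(outdir / "contamination_ledger.csv", index=False)
        (outdir / "world.json").write_text(json.dumps(
            {"world_id": self.world_id, "seed": self.seed, "config": asdict(self.config)},
            indent=1))


def _smooth_field(rng: np.ndarray, shape: tuple[int, int], sigma: float,
                  generator: np.random.Generator) -> np.ndarray:
    f = gaussian_filter(generator.standard_normal(shape), sigma, mode="nearest")
    return (f - f.mean()) / f.std()


def _random_ultrametric_tree(names: list[str], root_depth: float,
                             rng: np.random.Generator) -> dendropy.Tree:
    """Random coalescent-style ultrametric tree scaled to a fixed root depth."""
    taxa = dendropy.TaxonNamespace(names)
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes = [(dendropy.Node(taxon=taxa.get_taxon(n)), 0.0) for n in names]
    times = np.sort(rng.uniform(0.05, 1.0, size=len(names) - 1))
    times = times / times[-1] * root_depth
    for t in times:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        (na, ha), (nb, hb) = nodes[i], nodes[j]
        parent = dendropy.Node()
        parent.add_child(na)
        na.edge.length = t - ha
        parent.add_child(nb)
        nb.edge.length = t - hb
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)]
        nodes.append((parent, float(t)))
    tree.seed_node = nodes[0][0]
    return tree


def _pick_peaks(suit: np.ndarray, n: int, min_sep: int,
                margin: int) -> list[tuple[int, int]]:
    order = np.argsort(suit, axis=None)[::-1]
    nrows, ncols = suit.shape
    sep = min_sep
    while sep >= 2:
        peaks: list[tuple[int, int]] = []
        for flat in order:
            r, c = divmod(int(flat), ncols)
            if not (margin <= r < nrows - margin and margin <= c < ncols - margin):
                continue
            if all((r - pr) ** 2 + (c - pc) ** 2 >= sep**2 for pr, pc in peaks):
                peaks.append((r, c))
            if len(peaks) == n:
                return peaks
        sep -= 2
    raise ValueError(f"could not place {n} separated range centers")


def _blob(center: tuple[float, float], radius: float, rng: np.random.Generator,
          bounds: tuple[float, float, float, float]) -> Polygon:
    angles = np.linspace(0, 2 * np.pi, 24, endpoint=False)
    wobble = 1.0 + 0.25 * np.sin(angles * rng.integers(2, 5) + rng.uniform(0, 2 * np.pi))
    xs = center[0] + radius * wobble * np.cos(angles)
    ys = center[1] + radius * wobble * np.sin(angles)
    poly = chaikin_smooth(Polygon(np.column_stack([xs, ys])), iterations=2)
    return poly.intersection(box(*bounds))


def make_world(seed: int, config: Optional[WorldConfig] = None) -> SyntheticWorld:
    """Generate the seeded synthetic world; identical seed gives identical output."""
    config = config or WorldConfig()
    if config.n_species > config.nrows * config.ncols:
        raise ValueError("more species than grid cells")
    if config.n_species > len(_EPITHETS):
        raise ValueError(f"at most {len(_EPITHETS)} species supported")
    rng = np.random.default_rng(seed)
    spec = config.spec
    shape = (config.nrows, config.ncols)

    # --- environment: informative z1/z2, shadows, noise -------------------
    z1 = _smooth_field(rng, shape, config.smooth_sigma, rng)
    z2 = _smooth_field(rng, shape, config.smooth_sigma, rng)
    r = config.shadow_corr
    sh1 = r * z1 + np.sqrt(1 - r**2) * _smooth_field(rng, shape, config.smooth_sigma, rng)
    sh2 = r * z2 + np.sqrt(1 - r**2) * _smooth_field(rng, shape, config.smooth_sigma, rng)
    n1 = _smooth_field(rng, shape, config.smooth_sigma, rng)
    n2 = _smooth_field(rng, shape, config.smooth_sigma, rng)
    env = EnvStack(spec, {
        "bio1": 15.0 + 8.0 * z1,       # informative (temperature-like)
        "bio2": 15.0 + 8.0 * sh1,      # shadow of bio1, r ~ 0.95
        "bio3": 1200.0 + 300.0 * n1,   # noise (precipitation-like)
        "topo1": 1000.0 + 500.0 * z2,  # informative (elevation-like)
        "topo2": 1000.0 + 500.0 * sh2, # shadow of topo1
        "topo3": 5.0 + 2.0 * n2,       # noise (slope-like)
    })
    b1, b2 = config.suit_coef
    logit = config.suit_intercept + b1 * z1 + b2 * z2
    suitability = 1.0 / (1.0 + np.exp(-logit))

    # --- species, tree, synonyms -----------------------------------------
    names = [f"{_GENUS} {e}" for e in _EPITHETS[: config.n_species]]
    tree = _random_ultrametric_tree(names, config.root_depth_my, rng)
    entries: dict[str, str] = {}
    old_binomials: dict[str, str] = {}
    for i, name in enumerate(names):
        old = f"{_GENUS} {_OLD_EPITHETS[i]}"
        entries[old] = name
        old_binomials[name] = old
    # a few trinomial elevation entries: "G a b" -> "G b"
    for i in range(0, config.n_species - 1, 2):
        tri = f"{_GENUS} {_EPITHETS[i]} {_EPITHETS[i + 1]}"
        entries[tri] = names[i + 1]
    synonyms = SynonymTable(entries)

    # --- ranges around suitability peaks ----------------------------------
    margin = max(3, int(config.range_radius_deg / config.cellsize) + 2)
    peaks = _pick_peaks(suitability, config.n_species,
                        min_sep=int(2.6 * config.range_radius_deg / config.cellsize),
                        margin=margin)
    bounds = (spec.xll, spec.yll, spec.xur, spec.yur)
    ranges: dict[str, Polygon] = {}
    for name, (pr, pc) in zip(names, peaks):
        center = spec.cell_center(pr, pc)
        ranges[name] = _blob(center, config.range_radius_deg, rng, bounds)

    # --- ecoregion tiles ---------------------------------------------------
    tiles = {}
    tx = (spec.xur - spec.xll) / config.ecoregion_tiles
    ty = (spec.yur - spec.yll) / config.ecoregion_tiles
    for i in range(config.ecoregion_tiles):
        for j in range(config.ecoregion_tiles):
            tiles[f"eco_{i}{j}"] = box(spec.xll + i * tx, spec.yll + j * ty,
                                       spec.xll + (i + 1) * tx, spec.yll + (j + 1) * ty)
    ecoregions = EcoregionSet.from_polygons(tiles)

    # --- records sampled inside ranges proportional to suitability --------
    lon_c, lat_c = spec.cell_centers()
    from shapely import contains_xy
    rows = []
    rid = 0
    true_name = []
    for name in names:
        inside = contains_xy(ranges[name], lon_c.ravel(), lat_c.ravel()).reshape(shape)
        cells = np.flatnonzero(inside)
        if cells.size == 0:
            raise ValueError(f"range of {name} contains no cell centers")
        w = suitability.ravel()[cells]
        w = w / w.sum()
        draws = rng.choice(cells, size=config.records_per_species, replace=True, p=w)
        jitter = rng.uniform(-0.49, 0.49, size=(config.records_per_species, 2))
        for d, (jx, jy) in zip(draws, jitter):
            rr, cc = divmod(int(d), config.ncols)
            lon, lat = spec.cell_center(rr, cc)
            genus, epithet = name.split()
            rows.append({"id": f"r{rid:05d}", "genus": genus, "species": epithet,
                         "subspecies": "", "lon": lon + jx * config.cellsize,
                         "lat": lat + jy * config.cellsize, "source": "synthetic"})
            true_name.append(name)
            rid += 1
    records = pd.DataFrame(rows)
    n = len(records)

    # --- planted contamination --------------------------------------------
    n_out = round(config.outdated_rate * n)
    n_mis = round(config.mislabel_rate * n)
    perm = rng.permutation(n)
    out_idx, mis_idx = perm[:n_out], perm[n_out:n_out + n_mis]
    world_id = "world-" + hashlib.blake2b(
        json.dumps({"seed": seed, "config": asdict(config)}, sort_keys=True).encode(),
        digest_size=4).hexdigest()

    ledger_rows = []
    for i in out_idx:
        truth = true_name[i]
        old = old_binomials[truth]
        records.loc[i, ["genus", "species"]] = old.split()
        ledger_rows.append({"record_id": records.loc[i, "id"], "kind": "outdated_name",
                            "true_name": truth, "planted_name": old,
                            "world_id": world_id})
    nearest = {a: min((b for b in names if b != a),
                      key=lambda b: (patristic_distance(tree, a, b), b))
               for a in names}
    for i in mis_idx:
        truth = true_name[i]
        wrong = nearest[truth]
        records.loc[i, ["genus", "species"]] = wrong.split()
        ledger_rows.append({"record_id": records.loc[i, "id"], "kind": "mislabel",
                            "true_name": truth, "planted_name": wrong,
                            "world_id": world_id})
    ledger = pd.DataFrame(ledger_rows, columns=["record_id", "kind", "true_name",
                                                "planted_name", "world_id"])

    return SyntheticWorld(config=config, seed=seed, world_id=world_id, env=env,
                          suitability=suitability, tree=tree, ranges=ranges,
                          ecoregions=ecoregions, records=records,
                          synonyms=synonyms, ledger=ledger)


def sample_presences(world: SyntheticWorld, n: int, seed: int,
                     within: Optional[str] = None) -> np.ndarray:
    """Sample (lon, lat) presences with cell probability proportional to true
    suitability, optionally restricted to one species' range polygon."""
    rng = np.random.default_rng(seed)
    spec = world.env.spec
    suit = world.suitability.ravel().copy()
    if within is not None:
        from shapely import contains_xy
        lon_c, lat_c = spec.cell_centers()
        inside = contains_xy(world.ranges[within], lon_c.ravel(), lat_c.ravel())
        suit = np.where(inside, suit, 0.0)
    p = suit / suit.sum()
    draws = rng.choice(suit.size, size=n, replace=True, p=p)
    out = np.empty((n, 2))
    jitter = rng.uniform(-0.49, 0.49, size=(n, 2))
    for i, d in enumerate(draws):
        r, c = divmod(int(d), spec.ncols)
        lon, lat = spec.cell_center(r, c)
        out[i] = (lon + jitter[i, 0] * spec.cellsize, lat + jitter[i, 1] * spec.cellsize)
    return out


def clean_world(world: SyntheticWorld, **kwargs) -> tuple[pd.DataFrame, dict]:
    """Run name harmonization plus the reconciliation cascade on the world's
    records; the outcome table carries the world id for recovery scoring."""
    outcomes, summary = reconcile_all(world.records, world.ranges, world.tree,
                                      synonyms=world.synonyms, **kwargs)
    outcomes.attrs["world_id"] = world.world_id
    return outcomes, summary


def score_recovery(outcomes: pd.DataFrame, ledger: pd.DataFrame) -> dict[str, float]:
    """Precision/recall of planted cross-range mislabel correction.

    A planted error (outdated name or mislabel) counts as recovered when the
    pipeline's final name equals the ledger's true name. Recall is the
    recovered fraction of planted errors; precision is the fraction of all
    name-changing outcomes that restored a planted truth (spurious changes to
    uncontaminated records count against it).
    """
    if "world_id" in ledger.columns and "world_id" in outcomes.attrs:
        ids = set(ledger["world_id"].unique())
        if ids and outcomes.attrs["world_id"] not in ids:
            raise ValueError("outcomes and ledger come from different worlds")
    planted = ledger.set_index("record_id")
    merged = outcomes.set_index("id")
    recovered = 0
    for rid, row in planted.iterrows():
        if rid in merged.index and merged.loc[rid, "final_name"] == row["true_name"]:
            recovered += 1
    changed = merged[merged["final_name"] != merged["original_name"]]
    good_changes = sum(
        rid in planted.index and row["final_name"] == planted.loc[rid, "true_name"]
        for rid, row in changed.iterrows())
    n_changed = len(changed)
    precision = (good_changes / n_changed) if n_changed else (1.0 if len(planted) == 0 else 0.0)
    recall = recovered / len(planted) if len(planted) else 1.0
    return {"precision": precision, "recall": recall,
            "n_planted": int(len(planted)), "n_recovered": recovered,
            "n_changed": int(n_changed)}
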