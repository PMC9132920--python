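"""Pipeline orchestration: clean -> marea -> bias -> select_vars -> calibrate
-> finalize -> threshold, driven by one YAML config.

Each stage reads and writes files under the run directory, so any stage can
be reproduced in isolation. A JSON manifest records the config hash, per-stage
seeds, input/output checksums and status; re-running with ``resume=True``
skips stages whose recorded inputs and outputs are unchanged. The master seed
fans out to per-stage seeds through a keyed blake2b hash, so every stage is
independently reproducible.
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path
from typing import Callable, Optional

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import mapping

from . import io as eio
from .calibrate import (
    EvalConfig,
    InsufficientRecordsError,
    bootstrap_final,
    CandidateSpec,
    enumerate_candidates,
    evaluate_candidates,
    jackknife_importance,
    make_partitions,
    pick_final,
    select_candidates,
    threshold_map,
)
from .geometry import bias_raster, buffered_points, build_m_area, concave_hull
from .grid import EnvStack, read_ascii, write_ascii
from .reconcile import reconcile_all
from .synth import PREDICTOR_SETS, WorldConfig, make_world
from .taxa import SynonymTable, read_newick

log = logging.getLogger("enmpipe")

STAGES = ["simulate", "clean", "marea", "bias", "select_vars",
          "calibrate", "finalize", "threshold"]


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31 from the master seed."""
    digest = hashlib.blake2b(f"{master_seed}:{stage}".encode(), digest_size=4).digest()
    return int.from_bytes(digest, "big") % (2**31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _checksum_paths(paths: list[Path]) -> dict[str, str]:
    out = {}
    for p in sorted(set(paths)):
        p = Path(p)
        if p.is_dir():
            for f in sorted(p.rglob("*")):
                if f.is_file():
                    out[str(f)] = _sha256(f)
        elif p.exists():
            out[str(p)] = _sha256(p)
        else:
            out[str(p)] = "MISSING"
    return out


class Pipeline:
    """One configured run over one species."""

    def __init__(self, config_path: str | Path):
        self.config_path = Path(config_path)
        with open(self.config_path) as fh:
            self.cfg = yaml.safe_load(fh) or {}
        self.base = self.config_path.parent
        self.outdir = Path(self.cfg.get("outdir", self.base / "run"))
        if not self.outdir.is_absolute():
            self.outdir = self.base / self.outdir
        self.seed = int(self.cfg.get("seed", 0))
        self.eval_config = EvalConfig(**self.cfg.get("eval", {}))
        self.config_hash = hashlib.sha256(
            json.dumps(self.cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]

    # -- input resolution ---------------------------------------------------

    def has_fixture(self) -> bool:
        return "world" in self.cfg

    def input_path(self, key: str) -> Path:
        inputs = self.cfg.get("inputs", {})
        fixture_defaults = {
            "occurrences": "fixture/occurrences.csv",
            "ranges": "fixture/ranges.geojson",
            "ecoregions": "fixture/ecoregions.geojson",
            "synonyms": "fixture/synonyms.csv",
            "tree": "fixture/tree.nwk",
            "env": "fixture/env",
        }
        if key in inputs:
            p = Path(inputs[key])
            return p if p.is_absolute() else self.base / p
        if self.has_fixture():
            return self.outdir / fixture_defaults[key]
        raise FileNotFoundError(f"no input configured for {key!r} and no fixture world")

    def predictor_sets(self, env: EnvStack) -> dict[str, list[str]]:
        sets = self.cfg.get("candidates", {}).get("predictor_sets")
        if sets is None:
            sets = {k: [v for v in vs if v in env.layers]
                    for k, vs in PREDICTOR_SETS.items()}
            sets = {k: vs for k, vs in sets.items() if vs}
        return sets

    def candidate_grid(self) -> tuple[list[float], list[str]]:
        c = self.cfg.get("candidates", {})
        rms = [float(x) for x in c.get("rms", [0.5, 1, 2])]
        combos = list(c.get("class_combos", ["lq", "lqp", "h", "lqh"]))
        return rms, combos

    def target_species(self) -> Optional[str]:
        return self.cfg.get("species")

    # -- stage bodies -------------------------------------------------------

    def stage_simulate(self, seed: int) -> tuple[list[Path], list[Path]]:
        wc = WorldConfig(**{k: v for k, v in self.cfg.get("world", {}).items()
                            if k in WorldConfig.__dataclass_fields__})
        world = make_world(seed, wc)
        world.write(self.outdir / "fixture")
        return [self.config_path], [self.outdir / "fixture"]

    def stage_clean(self, seed: int) -> tuple[list[Path], list[Path]]:
        occ = self.input_path("occurrences")
        rng_path = self.input_path("ranges")
        tree_path = self.input_path("tree")
        syn_path = self.input_path("synonyms")
        records = eio.read_occurrences_csv(occ)
        ranges = eio.read_ranges_geojson(rng_path)
        tree = read_newick(tree_path)
        synonyms = SynonymTable.from_csv(syn_path)
        outcomes, summary = reconcile_all(records, ranges, tree, synonyms=synonyms)
        outdir = self.outdir / "clean"
        outdir.mkdir(parents=True, exist_ok=True)
        outcomes.to_csv(outdir / "outcomes.csv", index=False)
        kept = outcomes[~outcomes["excluded_for_modeling"]]
        merged = records.merge(kept[["id", "final_name"]], on="id")
        parts = merged["final_name"].str.split(" ", n=1, expand=True)
        merged["genus"], merged["species"] = parts[0], parts[1]
        merged["subspecies"] = ""
        merged.drop(columns=["final_name"]).to_csv(outdir / "cleaned.csv", index=False)
        (outdir / "summary.json").write_text(json.dumps(summary, indent=1))
        return [occ, rng_path, tree_path, syn_path], [outdir]

    def _cleaned(self) -> pd.DataFrame:
        return eio.read_occurrences_csv(self.outdir / "clean" / "cleaned.csv")

    def _species(self, cleaned: pd.DataFrame) -> str:
        sp = self.target_species()
        if sp is None:
            names = cleaned["genus"] + " " + cleaned["species"]
            sp = names.value_counts().idxmax()
        return sp

    def stage_marea(self, seed: int) -> tuple[list[Path], list[Path]]:
        cleaned = self._cleaned()
        species = self._species(cleaned)
        eco = eio.read_ecoregions_geojson(self.input_path("ecoregions"))
        env = EnvStack.from_ascii_dir(self.input_path("env"))
        sub = cleaned[(cleaned["genus"] + " " + cleaned["species"]) == species]
        if len(sub) < 10:
            raise InsufficientRecordsError(
                f"{species}: {len(sub)} usable records (<10)")
        pts = list(zip(sub["lon"], sub["lat"]))
        try:
            hull = concave_hull(pts)
        except ValueError:
            hull = buffered_points(pts)
        m_area = build_m_area(hull, eco, min_coverage=self.cfg.get("min_coverage", 0.20))
        if m_area.is_empty:
            log.warning("no ecoregion reached the coverage threshold; using the hull as M")
            m_area = hull
        outdir = self.outdir / "marea"
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "marea.geojson", "w") as fh:
            json.dump({"type": "Feature", "properties": {"species": species},
                       "geometry": mapping(m_area)}, fh)
        xmin, ymin, xmax, ymax = m_area.bounds
        pad = env.spec.cellsize
        cropped = env.crop(xmin - pad, ymin - pad, xmax + pad, ymax + pad)
        cropped.mask_outside(m_area).to_ascii_dir(outdir / "env")
        (outdir / "marea.json").write_text(json.dumps(
            {"species": species, "n_records": int(len(sub))}, indent=1))
        return [self.outdir / "clean", self.input_path("ecoregions"),
                self.input_path("env")], [outdir]

    def stage_bias(self, seed: int) -> tuple[list[Path], list[Path]]:
        cleaned = self._cleaned()
        env = EnvStack.from_ascii_dir(self.outdir / "marea" / "env")
        surface = bias_raster(cleaned["lon"].to_numpy(), cleaned["lat"].to_numpy(),
                              env.spec)
        outdir = self.outdir / "bias"
        outdir.mkdir(parents=True, exist_ok=True)
        write_ascii(outdir / "bias.asc", env.spec, surface, fmt="%.3f")
        return [self.outdir / "clean", self.outdir / "marea"], [outdir]

    def _modeling_inputs(self):
        env = EnvStack.from_ascii_dir(self.outdir / "marea" / "env")
        cleaned = self._cleaned()
        species = self._species(cleaned)
        sub = cleaned[(cleaned["genus"] + " " + cleaned["species"]) == species]
        inside = np.array([env.spec.contains(lo, la) and
                           env.mask[env.spec.index_of(lo, la)]
                           for lo, la in zip(sub["lon"], sub["lat"])])
        pres_xy = sub[["lon", "lat"]].to_numpy()[inside]
        _, bias = read_ascii(self.outdir / "bias" / "bias.asc")
        weights = bias[env.mask]
        weights = np.where(np.isnan(weights), 0.0, weights)
        if weights.sum() > 0:
            weights = weights / weights.mean()
        else:
            weights = None
        return env, species, pres_xy, weights

    def stage_select_vars(self, seed: int) -> tuple[list[Path], list[Path]]:
        from .maxent import select_variables

        env, species, pres_xy, weights = self._modeling_inputs()
        sets = self.predictor_sets(env)
        if len(pres_xy) < 10:
            raise InsufficientRecordsError(
                f"{species}: {len(pres_xy)} usable records (<10)")
        selected = {}
        for name, variables in sets.items():
            Xp = env.values_at(pres_xy[:, 0], pres_xy[:, 1], variables)
            Xb = env.table(variables)
            selected[name] = select_variables(Xp, Xb, variables, seed=seed,
                                              weights=weights)
        outdir = self.outdir / "vars"
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "variables.json").write_text(json.dumps(selected, indent=1))
        return [self.outdir / "marea", self.outdir / "bias",
                self.outdir / "clean"], [outdir]

    def stage_calibrate(self, seed: int) -> tuple[list[Path], list[Path]]:
        env, species, pres_xy, weights = self._modeling_inputs()
        sets = json.loads((self.outdir / "vars" / "variables.json").read_text())
        parts = make_partitions(pres_xy[:, 0], pres_xy[:, 1], env, seed,
                                self.eval_config)
        rms, combos = self.candidate_grid()
        candidates = enumerate_candidates(rms, combos, sorted(sets))
        metrics = evaluate_candidates(candidates, env, sets, pres_xy, parts,
                                      self.eval_config, weights, seed=seed)
        outdir = self.outdir / "calib"
        outdir.mkdir(parents=True, exist_ok=True)
        selection = {}
        retained_frames = []
        for set_name in sorted(sets):
            subm = metrics[metrics["predictor_set"] == set_name]
            retained, info = select_candidates(subm, self.eval_config)
            selection[set_name] = info
            if not retained.empty:
                retained_frames.append(retained)
        metrics.to_csv(outdir / "metrics.csv", index=False)
        retained_all = (pd.concat(retained_frames) if retained_frames
                        else metrics.iloc[0:0])
        retained_all.to_csv(outdir / "selected.csv", index=False)
        (outdir / "selection.json").write_text(json.dumps(selection, indent=1))
        return [self.outdir / "marea", self.outdir / "bias",
                self.outdir / "vars"], [outdir]

    def stage_finalize(self, seed: int) -> tuple[list[Path], list[Path]]:
        from .calibrate import average_models

        env, species, pres_xy, weights = self._modeling_inputs()
        sets = json.loads((self.outdir / "vars" / "variables.json").read_text())
        calib_seed = stage_seed(self.seed, "calibrate")
        parts = make_partitions(pres_xy[:, 0], pres_xy[:, 1], env, calib_seed,
                                self.eval_config)
        selected = pd.read_csv(self.outdir / "calib" / "selected.csv")
        if selected.empty:
            raise RuntimeError("no significant candidate model; nothing to finalize")
        outdir = self.outdir / "final"
        outdir.mkdir(parents=True, exist_ok=True)
        per_set = {}
        surfaces = {}
        specs = {}
        for set_name, group in selected.groupby("predictor_set"):
            best = group.sort_values(["omission_rate", "auc_ratio", "n_nonzero"],
                                     ascending=[True, False, True]).iloc[0]
            spec = CandidateSpec(float(best["rm"]), str(best["classes"]), set_name)
            models, fmetrics = bootstrap_final(spec, env, sets, pres_xy, parts,
                                               self.eval_config, weights, seed=seed)
            fmetrics["n_nonzero"] = int(np.mean([m.n_nonzero for m in models]))
            per_set[set_name] = fmetrics
            surfaces[set_name] = average_models(models, env.subset(sets[set_name]))
            specs[set_name] = spec
            for i, m in enumerate(models):
                m.to_json(outdir / f"model_{set_name}_{i}.json")
        winner = pick_final(per_set)
        write_ascii(outdir / "cloglog.asc", env.spec, surfaces[winner], fmt="%.6f")
        jk = None
        if len(sets[winner]) >= 2:
            fit_idx = parts.train_idx if parts.fallback else parts.non_independent_idx
            jk = jackknife_importance(env, sets, specs[winner], pres_xy, fit_idx, weights)
            jk.to_csv(outdir / "jackknife.csv", index=False)
        (outdir / "final.json").write_text(json.dumps(
            {"species": species, "winner": winner,
             "spec": asdict(specs[winner]),
             "per_set": {k: {kk: (None if isinstance(vv, float) and np.isnan(vv) else vv)
                             for kk, vv in v.items()} for k, v in per_set.items()}},
            indent=1, default=float))
        return [self.outdir / "calib", self.outdir / "vars",
                self.outdir / "marea"], [outdir]

    def stage_threshold(self, seed: int) -> tuple[list[Path], list[Path]]:
        env, species, pres_xy, weights = self._modeling_inputs()
        spec_grid, cloglog = read_ascii(self.outdir / "final" / "cloglog.asc")
        calib_seed = stage_seed(self.seed, "calibrate")
        parts = make_partitions(pres_xy[:, 0], pres_xy[:, 1], env, calib_seed,
                                self.eval_config)
        fit_idx = parts.train_idx if parts.fallback else parts.non_independent_idx
        rc = np.array([env.spec.index_of(lo, la) for lo, la in pres_xy[fit_idx]])
        suits = cloglog[rc[:, 0], rc[:, 1]]
        suits = suits[~np.isnan(suits)]
        binary, T = threshold_map(cloglog, suits,
                                  self.eval_config.threshold_percentile)
        outdir = self.outdir / "threshold"
        outdir.mkdir(parents=True, exist_ok=True)
        write_ascii(outdir / "binary.asc", spec_grid, binary, fmt="%.0f")
        (outdir / "threshold.json").write_text(json.dumps(
            {"species": species, "threshold": T,
             "percentile": self.eval_config.threshold_percentile}, indent=1))
        return [self.outdir / "final", self.outdir / "marea"], [outdir]

    # -- driver -------------------------------------------------------------

    def _stage_fn(self, name: str) -> Callable:
        return getattr(self, f"stage_{name}")

    def run(self, stages: Optional[list[str]] = None, resume: bool = False) -> dict:
        """Execute stages in dependency order; returns (and writes) the manifest."""
        manifest_path = self.outdir / "manifest.json"
        manifest = {"config_hash": self.config_hash, "master_seed": self.seed,
                    "stages": {}}
        if resume and manifest_path.exists():
            old = json.loads(manifest_path.read_text())
            if old.get("config_hash") == self.config_hash:
                manifest["stages"] = old.get("stages", {})
        wanted = stages or STAGES
        todo = [s for s in STAGES if s in wanted]
        if "simulate" in todo and not self.has_fixture():
            todo.remove("simulate")
        self.outdir.mkdir(parents=True, exist_ok=True)

        skip_downstream = False
        for name in todo:
            seed = stage_seed(self.seed, name)
            entry = manifest["stages"].get(name)
            if skip_downstream:
                manifest["stages"][name] = {
                    "status": "skipped: insufficient records", "seed": seed}
                continue
            if resume and entry and entry.get("status") == "done":
                in_ok = all(Path(p).exists() and _sha256(Path(p)) == h
                            for p, h in entry.get("inputs", {}).items())
                out_ok = all(Path(p).exists() and _sha256(Path(p)) == h
                             for p, h in entry.get("outputs", {}).items())
                if in_ok and out_ok:
                    log.info("stage %s: up to date, skipping", name)
                    entry["cached"] = True
                    continue
            t0 = time.time()
            log.info("stage %s: running (seed=%d)", name, seed)
            try:
                inputs, outputs = self._stage_fn(name)(seed)
            except InsufficientRecordsError as exc:
                log.warning("stage %s skipped: insufficient records (%s)", name, exc)
                manifest["stages"][name] = {
                    "status": "skipped: insufficient records", "seed": seed,
                    "error": str(exc)}
                skip_downstream = True
                continue
            manifest["stages"][name] = {
                "status": "done",
                "seed": seed,
                "cached": False,
                "wall_s": round(time.time() - t0, 3),
                "inputs": _checksum_paths(inputs),
                "outputs": _checksum_paths(outputs),
            }
            manifest_path.write_text(json.dumps(manifest, indent=1))
        manifest_path.write_text(json.dumps(manifest, indent=1))
        return manifest


def run_pipeline(config_path: str | Path, stages: Optional[list[str]] = None,
                 resume: bool = False) -> dict:
    return Pipeline(config_path).run(stages=stages, resume=resume)


def validate_inputs(config_path: str | Path) -> dict:
    """Report-only consistency checks of a run's inputs.

    Checks file existence, grid co-registration of the environmental layers,
    coordinate ranges, and whether record names resolve (via the synonym
    table) to tree tips and range polygons. Returns
    ``{"failures": [...], "n_checked": ...}``; an empty failure list means
    the inputs are consistent.
    """
    pipe = Pipeline(config_path)
    failures: list[str] = []
    if pipe.has_fixture() and not (pipe.outdir / "fixture").exists():
        pipe.stage_simulate(stage_seed(pipe.seed, "simulate"))
    paths = {}
    for key in ["occurrences", "ranges", "ecoregions", "synonyms", "tree", "env"]:
        try:
            paths[key] = pipe.input_path(key)
            if not paths[key].exists():
                failures.append(f"{key}: missing file {paths[key]}")
        except FileNotFoundError as exc:
            failures.append(f"{key}: {exc}")
    if failures:
        return {"failures": failures, "n_checked": 0}

    specs = {}
    for layer in sorted(Path(paths["env"]).glob("*.asc")):
        spec, _ = read_ascii(layer)
        specs[layer.stem] = spec
    ref_name, ref = next(iter(specs.items()))
    for name, spec in specs.items():
        if spec != ref:
            failures.append(
                f"env: layer {name} not co-registered with {ref_name}: "
                f"d_xll={spec.xll - ref.xll:g} d_yll={spec.yll - ref.yll:g} "
                f"d_cell={spec.cellsize - ref.cellsize:g} "
                f"d_shape=({spec.nrows - ref.nrows},{spec.ncols - ref.ncols})")

    records = eio.read_occurrences_csv(paths["occurrences"])
    ranges = eio.read_ranges_geojson(paths["ranges"])
    tree = read_newick(paths["tree"])
    synonyms = SynonymTable.from_csv(paths["synonyms"])
    from .taxa import tip_labels, update_name
    tips = set(tip_labels(tree))
    seen = set()
    for _, rec in records.iterrows():
        sub = rec.get("subspecies")
        sub = None if pd.isna(sub) or sub == "" else sub
        key = (rec["genus"], rec["species"], sub)
        if key in seen:
            continue
        seen.add(key)
        upd = update_name(rec["genus"], rec["species"], sub, synonyms)
        if upd.not_in_table:
            failures.append(f"name: {' '.join(str(k) for k in key if k)} "
                            "not resolvable via the synonym table")
        if upd.name not in tips:
            failures.append(f"name: {upd.name} absent from the tree")
        if upd.name not in ranges:
            failures.append(f"name: {upd.name} has no range polygon")
    return {"failures": sorted(set(failures)), "n_checked": int(len(records))}
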