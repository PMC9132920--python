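"""Calibrate a candidate-model grid, select, finalize and threshold.

Evaluates a reduced grid (3 regularization multipliers x 4 feature-class
combinations) with partial ROC, omission rates and AICc, applies the
selection cascade, refits the winner on bootstrap replicates and binarizes
the averaged cloglog surface at the 10th-percentile training presence.
"""
import numpy as np

from enmpipe import (
    EvalConfig,
    PREDICTOR_SETS,
    bootstrap_final,
    average_models,
    enumerate_candidates,
    evaluate_candidates,
    make_partitions,
    make_world,
    sample_presences,
    select_candidates,
    threshold_map,
)
from enmpipe.calibrate import CandidateSpec

world = make_world(seed=1)
pres = sample_presences(world, 400, seed=1)
config = EvalConfig(proc_replicates=300)
parts = make_partitions(pres[:, 0], pres[:, 1], world.env, seed=1, config=config)
print(f"partitions: {parts.train_idx.size} train / {parts.test_idx.size} test "
      f"/ {parts.independent_idx.size} independent (fallback={parts.fallback})")

cands = enumerate_candidates([0.5, 1.0, 2.0], ["lq", "lqp", "h", "lqh"], ["combination"])
metrics = evaluate_candidates(cands, world.env, PREDICTOR_SETS, pres, parts,
                              config, seed=2)
retained, info = select_candidates(metrics, config)
print(f"{len(cands)} candidates -> {len(retained)} retained "
      f"(fallback={info['or_fallback']})")
print(retained[["rm", "classes", "auc_ratio", "p", "omission_rate", "aicc"]]
      .round(3).to_string(index=False))

best = retained.sort_values(["omission_rate", "auc_ratio"],
                            ascending=[True, False]).iloc[0]
spec = CandidateSpec(float(best.rm), str(best.classes), "combination")
models, final = bootstrap_final(spec, world.env, PREDICTOR_SETS, pres, parts,
                                config, seed=3)
print(f"final ({spec.label()}): AUC ratio {final['auc_ratio']:.2f}, "
      f"p={final['p']:.3f}, OR={final['omission_rate']:.2f} "
      f"on {parts.final_eval_idx.size} independent records")

surface = average_models(models, world.env.subset(PREDICTOR_SETS["combination"]))
rc = np.array([world.env.spec.index_of(lo, la)
               for lo, la in pres[parts.non_independent_idx]])
binary, T = threshold_map(surface, surface[rc[:, 0], rc[:, 1]], percentile=10)
print(f"10th-percentile threshold {T:.3f}: "
      f"{np.nansum(binary):.0f}/{binary.size} cells predicted present")
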