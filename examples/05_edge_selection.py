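"""Edge-level brain-behavior stability selection on a planted cohort.

Plants a +0.3 correlation offset (incompatible dual task) with a 0.6
subject-level brain-behavior coupling on two edges, runs the full
screening pipeline (Bayes-factor filter, task-cluster filter, partial
Spearman screen, leave-one-out stability against a permutation null), and
prints the selection report.
"""

from fcx.edge_selection import report_selection
from fcx.io_config import PipelineConfig
from fcx.pipeline import run_dual_task_selection
from fcx.synthetic import SimulationConfig, make_parcel_table

parcels = make_parcel_table(50)
planted = [(0, 9), (3, 12)]
cfg = SimulationConfig(
    n_subjects=47, n_regions=50, n_timepoints=300,
    runs_per_condition={"dual-compatible": 1, "dual-incompatible": 1},
    effect_edges=tuple((i, j, "dual-incompatible", 0.3) for i, j in planted),
    coupling_edges=tuple((i, j, 0.6) for i, j in planted),
    network_assignment=parcels, seed=1,
)
res = run_dual_task_selection(cfg, PipelineConfig(n_permutations=1000, rng_seed=1))
report = report_selection(res, parcels)

print(f"candidates after BF>3 + cluster filters: {res.n_candidates_prescreen}")
print(f"candidates after p<0.05 screen:          {len(report)}")
print(f"selected after leave-one-out stability:  {int(res.selected.sum())}")
print()
cols = ["region_i", "region_j", "bf10", "partial_rho", "null_lower",
        "null_upper", "selected"]
print(report[cols].to_string(index=False, float_format=lambda x: f"{x:.3f}"))
print()
print(f"planted edges were {sorted((i + 1, j + 1) for i, j in planted)} "
      "(1-based region ids).")
print("A selected edge had a credibly nonzero FC difference between the two")
print("dual-task pairings on every leave-one-out fold, and its covariate-")
print("adjusted rank correlation with the behavioral modality-compatibility")
print("effect stayed outside the permutation-null 5%/95% band on every fold.")
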