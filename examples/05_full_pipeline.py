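"""End-to-end run: simulate -> scan -> regions -> JN -> PLSC -> report.

Writes every stage's tables plus a JSON report and manifest into ./run_demo,
and prints the headline findings.
"""
import json

from callothick import SyntheticCohortConfig, run_pipeline

report = run_pipeline(
    "run_demo",
    config=SyntheticCohortConfig(n_patients=150, n_controls=150, seed=3),
    n_perm=1000, n_boot=500, seed=3,
)
print("significant nodes:", report["significant_nodes"])
for row in report["region_jn"]:
    print(f"region {row['region']}: crossover {row['crossover_age']:.1f} y, "
          f"JN boundaries [{row['boundaries']}]")
for reg, res in report["plsc"].items():
    print(f"PLSC region {reg}: LV1 p = {res['perm_p'][0]:.4f}, "
          f"q across regions = {res['lv1_q_across_regions']:.4f}")
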