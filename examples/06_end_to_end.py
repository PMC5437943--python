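"""Full chain on a planted cohort: simulate → vote → tabulate → layouts.

50 patients, three callers at 90% sensitivity, 2-of-3 voting.  The expected
per-variant recovery is the binomial closed form
P(≥2 of 3) = 3·0.9²·0.1 + 0.9³ = 0.972.
"""

import math

from oncocohort import CohortDesign, generate_cohort, run_pipeline
from oncocohort.simulate import emit_caller_vcfs

design = CohortDesign(seed=1)
truth = generate_cohort(design)
vcfs = emit_caller_vcfs(truth)
print(f"planted: {len(truth.variants)} variants across "
      f"{len(truth.patients)} patients, "
      f"{len(design.caller_sensitivity)} callers at sensitivity 0.9")

result = run_pipeline(truth, vcfs, k=2, min_patients=5)

truth_keys = {(v.patient, v.key()) for v in truth.variants}
recovered = {
    (p, c.key)
    for p, cons in result.consensus.items()
    for c in cons
    if (p, c.key) in truth_keys
}
n = len(truth_keys)
expected = 3 * 0.9**2 * 0.1 + 0.9**3
sd = math.sqrt(n * expected * (1 - expected))
print(f"\nrecovered {len(recovered)}/{n} planted variants "
      f"({len(recovered) / n:.4f}; expected {expected:.3f} "
      f"± {3 * sd / n:.4f} at 3 SDs)")

drivers = {g for g, _ in design.driver_genes}
print(f"planted drivers retained above threshold: "
      f"{len(drivers & set(result.retained_genes))}/{len(drivers)}")

acc = sum(result.subgroup_labels[p] == truth.labels[p] for p in truth.patients)
print(f"subgroup labels correct after lossy calling: {acc}/{len(truth.patients)}")
print(f"circos bundle tracks: {sorted(result.circos.tracks)}")
print(f"oncoprint: {len(result.oncoprint.genes)} genes × "
      f"{len(result.oncoprint.patients)} patients")
print("\nRecovery sits within sampling error of the closed form; every")
print("planted driver survives filtering. Subgroup accuracy can dip below")
print("100% here only because voting occasionally drops a marker mutation.")
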