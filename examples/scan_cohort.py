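"""Min-p cutoff screening of a simulated survival cohort.

Simulates a 349-patient cohort in which 5 genes carry a planted hazard
ratio of 3 for their high-expression half and 200 genes are unrelated to
survival, then scans every gene for its best prognostic FPKM cutoff.
"""

import numpy as np

from survscan import CohortSimConfig, ScanConfig, scan_cohort, simulate_cohort

cfg = CohortSimConfig(
    n_samples=349, n_null_genes=200, n_prognostic_genes=5,
    log_hr=np.log(3.0), censoring_fraction_target=0.30, seed=42,
)
expr, clin, truth = simulate_cohort(cfg)
results = scan_cohort(expr, clin, ScanConfig())

print(f"cohort: {expr.n_samples} samples, {expr.n_genes} genes, "
      f"{clin.event.sum()} deaths ({1 - clin.event.mean():.0%} censored)")
prognostic = [r for r in results if r.prognostic]
print(f"prognostic genes at best-cutoff log-rank p < 0.001: {len(prognostic)}")
print()
print(f"{'gene':>9} {'best cutoff':>11} {'best p':>9} {'n high/low':>10} "
      f"{'O/E high':>11} direction")
for r in sorted(prognostic, key=lambda r: r.best_p)[:8]:
    print(f"{r.gene_id:>9} {r.best_cutoff:11.3f} {r.best_p:9.2e} "
          f"{r.n_high:>4}/{r.n_low:<4} {r.observed_high:5.1f}/{r.expected_high:<5.1f} "
          f"{r.direction}")
print()
print("A gene is 'unfavorable' when its high-expression group accumulates "
      "more observed than expected deaths at the selected cutoff.")
planted_found = sum(r.gene_id.startswith("PROG") for r in prognostic)
print(f"planted hazard-ratio-3 genes recovered: {planted_found}/5; "
      f"null genes slipping below 0.001: {len(prognostic) - planted_found}/200")
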