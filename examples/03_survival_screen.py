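"""Median-split survival screen on a simulated patient cohort.

One gene carries a planted hazard ratio of 1.78 (high- vs low-expression
group); the screen estimates Kaplan-Meier log-rank p-values and Cox
hazard ratios for overall and progression-free survival and selects genes
significant on either endpoint.
"""

from datcascade import screen_genes
from datcascade.simulate import SimConfig, generate_survival_cohort, make_truth

config = SimConfig(seed=1, n_genes=60, n_patients=800,
                   class_counts={"concordant_up": 16},
                   n_offtarget=0, n_specific=0)
truth = make_truth(config)
cohort = generate_survival_cohort(truth, config)

results = screen_genes(cohort, truth["gene_id"].tolist(), alpha=0.05)
driver = results.set_index("gene_id").loc["G000001"]

print(f"genes screened: {len(results)}, selected: {int(results['selected'].sum())}")
print(f"driver gene OS:  HR = {driver['hr_os']:.2f} "
      f"[{driver['ci_os_low']:.2f}, {driver['ci_os_high']:.2f}], "
      f"p = {driver['p_os']:.2e}")
print(f"driver gene PFS: HR = {driver['hr_pfs']:.2f}, p = {driver['p_pfs']:.2e}")
print("The planted HR of 1.78 should sit inside the driver's confidence "
      "interval; null genes are selected at roughly the 1-0.95^2 ~ 10% "
      "rate implied by testing two endpoints without correction.")
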