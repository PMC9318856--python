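"""siRNA screen hit calling and knockdown downstream-effector analysis.

First: colony counts per gene siRNA relative to control siRNA; a hit
loses strictly more than half its colonies.  Second: a three-arm
knockdown experiment (untreated / control siRNA / target siRNA) in which
off-target transcripts (perturbed by any transfection) are excluded by a
Venn difference and the remaining exclusive transcripts are shortlisted
with a stricter cutoff (|log2FC| > 1.2, padj <= 0.01).
"""

from datcascade import call_screen_hits, knockdown_analysis
from datcascade.simulate import (
    SimConfig,
    generate_knockdown_experiment,
    generate_screen_table,
    make_knockdown_truth,
    make_truth,
)

config = SimConfig(seed=1, n_genes=400, class_counts={"concordant_up": 64},
                   n_offtarget=12, n_specific=48, dispersion=0.02,
                   n_reps_per_condition=4)

# colony-formation screen over the planted up-regulated candidates
truth = make_truth(config)
screened = truth.loc[truth["class"] == "concordant_up", "gene_id"].tolist()[:27]
table = generate_screen_table(truth, config, genes=screened)
hits = call_screen_hits(table, reduction_cut=50.0)
print(f"screened {len(hits)} genes, hits: {int(hits['hit'].sum())}")
print(hits[hits["hit"]].to_string(index=False))

# knockdown effector analysis
kd_truth = make_knockdown_truth(config)
experiment = generate_knockdown_experiment(kd_truth, config)
result = knockdown_analysis(experiment)
print(f"\nknockdown DATs vs control siRNA:  {len(result.dats_kd_vs_nc)}")
print(f"off-target (control vs untreated): {len(result.dats_nc_vs_nt)}")
print(f"exclusive to the knockdown:        {len(result.exclusive)}")
print(f"shortlisted effectors:             {len(result.shortlist)} "
      f"({(result.shortlist['direction'] == 'up').sum()} up, "
      f"{(result.shortlist['direction'] == 'down').sum()} down)")
print("Exclusive = knockdown-regulated minus off-target; the shortlist "
      "is the high-effect, high-confidence subset of those effectors.")
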