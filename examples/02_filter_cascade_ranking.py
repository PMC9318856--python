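"""Reduce two DE tables to a ranked candidate list.

Runs the three-stage cascade: keep transcripts differentially abundant in
both pairs, drop direction-discordant ones, then score each survivor by
the sum of its base-mean and |log2FC| quartiles (2-8) and keep ranks >= 7.
"""

from datcascade import build_cascade, nb_wald_test, select_by_rank
from datcascade.simulate import SimConfig, generate_pair_experiment, make_truth, split_pair

config = SimConfig(seed=1)
truth = make_truth(config)
experiment = generate_pair_experiment(config, truth)
de1 = nb_wald_test(split_pair(experiment, "pair1"))
de2 = nb_wald_test(split_pair(experiment, "pair2"))

records = build_cascade(de1, de2, padj_cut=0.05, lfc_cut=1.0)
candidates = select_by_rank(records, min_rank=7)

print(f"DATs shared by both pairs: {int(records['shared'].sum())}")
print(f"sign-concordant:           {int(records['concordant'].sum())}")
print(f"rank >= 7 candidates:      {len(candidates)} "
      f"({(candidates['direction'] > 0).sum()} up, "
      f"{(candidates['direction'] < 0).sum()} down)")
print(candidates.head(10).to_string(index=False))
print("rank_final sums the quartile (1-4) of expression level and of "
      "effect size, taken over the concordant survivors, per pair, "
      "combined by minimum: 8 means top quartile of both in both pairs.")
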