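"""Downstream-effector analysis after target knockdown.

Two DE contrasts are run on a three-arm experiment (untreated, control
siRNA, target siRNA): target-siRNA vs control-siRNA identifies transcripts
responding to the knockdown, and control-siRNA vs untreated identifies
transcripts perturbed by the transfection itself (off-target effects).
Off-target transcripts are excluded by set difference, and the remaining
exclusive set is shortlisted with a stricter fold-change/p cutoff to yield
the candidate downstream effectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .de import call_dats, nb_wald_test
from .experiment import CountExperiment

__all__ = ["offtarget_exclusion", "shortlist_effectors", "knockdown_analysis", "KnockdownResult"]


def offtarget_exclusion(dats_kd: set[str], dats_offtarget: set[str]) -> set[str]:
    """Transcripts regulated by the target siRNA but not by the control
    siRNA alone: plain set difference by gene id."""
    return set(dats_kd) - set(dats_offtarget)


def shortlist_effectors(
    de: pd.DataFrame,
    exclusive: set[str],
    lfc_cut: float = 1.2,
    p_cut: float = 0.01,
) -> pd.DataFrame:
    """Most relevant effectors among the exclusive set.

    Kept iff log2fc > lfc_cut or log2fc < -lfc_cut (strict) and adjusted
    p <= p_cut (inclusive).  Returned ranked by adjusted p ascending, with
    a direction column.
    """
    sub = de[de["gene_id"].isin(exclusive)]
    keep = (sub["log2fc"].abs() > lfc_cut) & (sub["padj"] <= p_cut)
    out = sub.loc[keep, ["gene_id", "log2fc", "padj"]].copy()
    out["direction"] = out["log2fc"].apply(lambda x: "up" if x > 0 else "down")
    return out.sort_values(["padj", "gene_id"]).reset_index(drop=True)


@dataclass
class KnockdownResult:
    de_kd_vs_nc: pd.DataFrame
    de_nc_vs_nt: pd.DataFrame
    dats_kd_vs_nc: set[str] = field(default_factory=set)
    dats_nc_vs_nt: set[str] = field(default_factory=set)
    exclusive: set[str] = field(default_factory=set)
    shortlist: pd.DataFrame | None = None


def knockdown_analysis(
    experiment: CountExperiment,
    kd_condition: str = "target_sirna",
    nc_condition: str = "nc_sirna",
    nt_condition: str = "untreated",
    padj_cut: float = 0.01,
    lfc_cut: float = 1.2,
    p_cut: float = 0.01,
    batch_covariate: bool = True,
) -> KnockdownResult:
    """Full effector analysis on a three-arm knockdown experiment.

    DAT calling for both contrasts uses the adjusted-p cutoff alone (no
    fold-change gate); the fold-change gate belongs to the later
    shortlisting step.
    """
    cond = experiment.samples["condition"]
    exp_kd = experiment.subset_samples(cond.isin([kd_condition, nc_condition]))
    exp_ot = experiment.subset_samples(cond.isin([nc_condition, nt_condition]))
    de_kd = nb_wald_test(exp_kd, contrast=(kd_condition, nc_condition),
                         batch_covariate=batch_covariate)
    de_ot = nb_wald_test(exp_ot, contrast=(nc_condition, nt_condition),
                         batch_covariate=batch_covariate)
    dats_kd = set(call_dats(de_kd, padj_cut=padj_cut, lfc_cut=0.0)["gene_id"])
    dats_ot = set(call_dats(de_ot, padj_cut=padj_cut, lfc_cut=0.0)["gene_id"])
    exclusive = offtarget_exclusion(dats_kd, dats_ot)
    shortlist = shortlist_effectors(de_kd, exclusive, lfc_cut=lfc_cut, p_cut=p_cut)
    return KnockdownResult(
        de_kd_vs_nc=de_kd,
        de_nc_vs_nt=de_ot,
        dats_kd_vs_nc=dats_kd,
        dats_nc_vs_nt=dats_ot,
        exclusive=exclusive,
        shortlist=shortlist,
    )
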