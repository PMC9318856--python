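"""Three-stage filter cascade reducing two DE tables to ranked candidates.

Stage 1 keeps genes called differentially abundant in both cell-line
pairs; stage 2 keeps those whose fold change has the same sign in both
pairs; stage 3 scores each survivor by summing the quartile index (1-4) of
its base mean and of its absolute log2 fold change within the survivor
distribution, per pair, and keeps genes whose combined rank (minimum over
the two pairs by default) reaches a threshold.  The rank therefore lives
in {2, ..., 8}: a gene in the top quartile of both expression level and
effect size scores 8.
"""

from __future__ import annotations

from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "intersect_pairs",
    "filter_concordant",
    "quartile_index",
    "build_cascade",
    "select_by_rank",
]


def intersect_pairs(dats1: pd.DataFrame, dats2: pd.DataFrame) -> set[str]:
    """Genes called DATs in both pairs, regardless of direction."""
    return set(dats1["gene_id"]) & set(dats2["gene_id"])


def filter_concordant(
    shared: Iterable[str], de1: pd.DataFrame, de2: pd.DataFrame
) -> set[str]:
    """Drop genes whose fold changes disagree in sign between the pairs."""
    lfc1 = de1.set_index("gene_id")["log2fc"]
    lfc2 = de2.set_index("gene_id")["log2fc"]
    shared = set(shared)
    for gene in shared:
        if gene not in lfc1.index or gene not in lfc2.index:
            raise KeyError(f"gene '{gene}' missing from a DE table")
    s1 = np.sign(lfc1[list(shared)])
    s2 = np.sign(lfc2[list(shared)])
    keep = (s1 == s2) & (s1 != 0)
    return set(keep.index[keep])


def quartile_index(value: float, reference: Sequence[float]) -> int:
    """Quartile (1-4) of ``value`` within the empirical distribution of
    ``reference``.

    Boundaries are the 25th/50th/75th percentiles with linear
    interpolation; a value equal to a boundary falls in the lower quartile
    (the index counts boundaries strictly below the value).
    """
    ref = np.asarray(reference, dtype=float)
    if ref.size == 0:
        raise ValueError("empty reference distribution")
    bounds = np.percentile(ref, [25, 50, 75])
    return 1 + int(np.sum(bounds < value))


def _quartile_indices(values: np.ndarray, reference: np.ndarray) -> np.ndarray:
    bounds = np.percentile(reference, [25, 50, 75])
    return 1 + (bounds[None, :] < values[:, None]).sum(axis=1)


def build_cascade(
    de1: pd.DataFrame,
    de2: pd.DataFrame,
    padj_cut: float = 0.05,
    lfc_cut: float = 1.0,
    combine: Literal["min", "mean"] = "min",
    min_rank: int = 7,
) -> pd.DataFrame:
    """Run all three filters and return one record per gene seen in either
    DE table, with per-filter pass flags and the quartile-sum rank for the
    concordant survivors.

    ``combine='min'`` ranks each pair separately against the survivor
    distribution of that pair and takes the minimum (a candidate must be
    strong in both pairs); ``combine='mean'`` averages base mean and
    |log2fc| across pairs first and ranks the averaged statistics once.
    """
    from .de import call_dats

    dats1 = call_dats(de1, padj_cut, lfc_cut)
    dats2 = call_dats(de2, padj_cut, lfc_cut)
    dir1 = dats1.set_index("gene_id")["direction"]
    dir2 = dats2.set_index("gene_id")["direction"]
    shared = intersect_pairs(dats1, dats2)
    concordant = filter_concordant(shared, de1, de2)

    t1 = de1.set_index("gene_id")
    t2 = de2.set_index("gene_id")
    all_genes = sorted(set(t1.index) | set(t2.index))
    records = pd.DataFrame({"gene_id": all_genes}).set_index("gene_id")
    records["dat_pair1"] = records.index.isin(dir1.index)
    records["dat_pair2"] = records.index.isin(dir2.index)
    records["direction_pair1"] = dir1.reindex(records.index).fillna(0).astype(int)
    records["direction_pair2"] = dir2.reindex(records.index).fillna(0).astype(int)
    records["shared"] = records.index.isin(shared)
    records["concordant"] = records.index.isin(concordant)

    for col in (
        "base_mean_quartile_pair1",
        "lfc_quartile_pair1",
        "base_mean_quartile_pair2",
        "lfc_quartile_pair2",
        "rank_pair1",
        "rank_pair2",
        "rank_final",
    ):
        records[col] = 0

    surv = sorted(concordant)
    if surv:
        bm1 = t1.loc[surv, "base_mean"].to_numpy(dtype=float)
        bm2 = t2.loc[surv, "base_mean"].to_numpy(dtype=float)
        fc1 = t1.loc[surv, "log2fc"].abs().to_numpy(dtype=float)
        fc2 = t2.loc[surv, "log2fc"].abs().to_numpy(dtype=float)
        if combine == "min":
            q_bm1 = _quartile_indices(bm1, bm1)
            q_fc1 = _quartile_indices(fc1, fc1)
            q_bm2 = _quartile_indices(bm2, bm2)
            q_fc2 = _quartile_indices(fc2, fc2)
            rank1 = q_bm1 + q_fc1
            rank2 = q_bm2 + q_fc2
            rank_final = np.minimum(rank1, rank2)
        elif combine == "mean":
            bm = (bm1 + bm2) / 2.0
            fc = (fc1 + fc2) / 2.0
            q_bm1 = q_bm2 = _quartile_indices(bm, bm)
            q_fc1 = q_fc2 = _quartile_indices(fc, fc)
            rank1 = rank2 = rank_final = q_bm1 + q_fc1
        else:
            raise ValueError(f"unknown combine rule '{combine}'")
        records.loc[surv, "base_mean_quartile_pair1"] = q_bm1
        records.loc[surv, "lfc_quartile_pair1"] = q_fc1
        records.loc[surv, "base_mean_quartile_pair2"] = q_bm2
        records.loc[surv, "lfc_quartile_pair2"] = q_fc2
        records.loc[surv, "rank_pair1"] = rank1
        records.loc[surv, "rank_pair2"] = rank2
        records.loc[surv, "rank_final"] = rank_final

    # highest filter index passed: 1 = shared, 2 = concordant, 3 = rank
    records["passed_filter"] = (
        records["shared"].astype(int)
        + records["concordant"].astype(int)
        + (records["concordant"] & (records["rank_final"] >= min_rank)).astype(int)
    )
    return records.reset_index()


def select_by_rank(records: pd.DataFrame, min_rank: int = 7) -> pd.DataFrame:
    """Concordant genes with rank_final >= min_rank, with direction."""
    keep = records["concordant"] & (records["rank_final"] >= min_rank)
    out = records.loc[keep, ["gene_id", "rank_final", "direction_pair1"]].copy()
    out = out.rename(columns={"direction_pair1": "direction"})
    return out.sort_values(
        ["rank_final", "gene_id"], ascending=[False, True]
    ).reset_index(drop=True)
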