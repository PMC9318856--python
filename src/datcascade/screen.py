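"""Clonogenic siRNA-screen quantification and hit calling.

Colony counts per gene-targeting siRNA are expressed as a percentage of
the negative-control siRNA wells (ratio of replicate means); a gene is a
hit when its knockdown removes strictly more than ``reduction_cut``
percent of colonies.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["percent_clonogenicity", "call_screen_hits"]


def percent_clonogenicity(table: pd.DataFrame, gene: str) -> float:
    """100 * mean(colonies with gene siRNA) / mean(colonies with NC siRNA)."""
    sub = table[table["gene_id"] == gene]
    if sub.empty:
        raise KeyError(f"gene '{gene}' not in screen table")
    nc = float(sub["colonies_nc"].mean())
    if nc <= 0:
        raise ValueError(f"gene '{gene}': NC colony mean is zero")
    return 100.0 * float(sub["colonies_sirna"].mean()) / nc


def call_screen_hits(
    table: pd.DataFrame, reduction_cut: float = 50.0
) -> pd.DataFrame:
    """Per-gene clonogenicity and hit flag.

    hit iff percent clonogenicity < 100 - reduction_cut (strict, so the
    default calls genes with more than a 50% colony reduction).
    """
    rows = []
    for gene in pd.unique(table["gene_id"]):
        pct = percent_clonogenicity(table, gene)
        rows.append(
            {
                "gene_id": gene,
                "percent_clonogenicity": pct,
                "hit": pct < 100.0 - reduction_cut,
            }
        )
    return pd.DataFrame(rows)
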