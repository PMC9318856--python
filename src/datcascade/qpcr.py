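"""Relative quantification (2^-ddCt) and qPCR-vs-RNA-seq concordance.

The comparative Ct method: per condition, dCt = Ct(target) -
Ct(reference gene); ddCt = dCt(test) - dCt(control); relative expression
= 2^-ddCt, so log2 fold change = -ddCt.  A DE call is "validated" when
the qPCR fold change agrees in sign with the RNA-seq estimate and its
magnitude clears a configurable floor.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "delta_delta_ct",
    "qpcr_log2fc",
    "validate_concordance",
    "load_qpcr_panel",
]


def delta_delta_ct(
    table: pd.DataFrame,
    gene: str,
    reference_condition: str = "sensitive",
    test_condition: str = "resistant",
    per_replicate: bool = False,
) -> tuple[float, float]:
    """ddCt and relative expression (2^-ddCt) for one gene.

    By default replicate Ct values are averaged within condition before
    taking dCt; ``per_replicate=True`` instead forms dCt per replicate
    and averages those (identical in expectation, different variance
    weighting).
    """
    sub = table[table["gene_id"] == gene]
    dct = {}
    for condition in (reference_condition, test_condition):
        wells = sub[sub["condition"] == condition]
        if wells.empty:
            raise ValueError(f"gene {gene}: condition '{condition}' missing")
        if per_replicate:
            dct[condition] = float(
                (wells["ct_target"] - wells["ct_reference"]).mean()
            )
        else:
            dct[condition] = float(
                wells["ct_target"].mean() - wells["ct_reference"].mean()
            )
    ddct = dct[test_condition] - dct[reference_condition]
    return ddct, float(2.0 ** (-ddct))


def qpcr_log2fc(relative_expression: float) -> float:
    """log2 of relative expression; equals -ddCt."""
    if relative_expression <= 0:
        raise ValueError("relative expression must be positive")
    return float(np.log2(relative_expression))


def validate_concordance(
    qpcr: pd.Series,
    rnaseq: pd.Series,
    min_abs_lfc: float = 0.5,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Per-gene qPCR/RNA-seq concordance records plus summary counts.

    A gene is validated when sign(qpcr) == sign(rnaseq), both nonzero,
    and |qpcr log2FC| >= min_abs_lfc.  Only genes present in both inputs
    are scored.  The summary reports the total and the up/down split of
    validated genes by qPCR sign.
    """
    genes = [g for g in qpcr.index if g in rnaseq.index]
    q = qpcr[genes].to_numpy(dtype=float)
    r = rnaseq[genes].to_numpy(dtype=float)
    concordant = (np.sign(q) == np.sign(r)) & (np.sign(q) != 0)
    validated = concordant & (np.abs(q) >= min_abs_lfc)
    records = pd.DataFrame(
        {
            "gene_id": genes,
            "qpcr_log2fc": q,
            "rnaseq_log2fc": r,
            "concordant": concordant,
            "validated": validated,
        }
    )
    summary = {
        "validated": int(validated.sum()),
        "up": int((validated & (q > 0)).sum()),
        "down": int((validated & (q < 0)).sum()),
    }
    return records, summary


def load_qpcr_panel() -> pd.DataFrame:
    """Bundled reference panel: qPCR and RNA-seq log2 fold changes for the
    45 transcripts validated in cisplatin-resistant vs -sensitive OVCAR3
    cells (columns gene_id, qpcr_log2fc, rnaseq_log2fc)."""
    with resources.files("datcascade.data").joinpath(
        "ovcar3_qpcr_panel.tsv"
    ).open("r") as fh:
        return pd.read_csv(fh, sep="\t")
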