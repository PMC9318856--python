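"""Validate DE calls against the bundled qPCR panel.

The panel holds qPCR (2^-ddCt derived) and RNA-seq log2 fold changes for
45 transcripts measured in cisplatin-resistant vs -sensitive OVCAR3
cells.  A transcript is validated when both platforms agree in sign and
the qPCR magnitude clears the floor.
"""

from datcascade import load_qpcr_panel, validate_concordance

panel = load_qpcr_panel().set_index("gene_id")
records, summary = validate_concordance(
    panel["qpcr_log2fc"], panel["rnaseq_log2fc"], min_abs_lfc=0.5
)

print(f"validated: {summary['validated']} of {len(panel)} "
      f"({summary['up']} up, {summary['down']} down)")
print(records.head(5).to_string(index=False))
print("Sign concordance between an orthogonal assay and the sequencing "
      "estimate is the validation criterion; the up/down split follows "
      "the qPCR sign.")
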