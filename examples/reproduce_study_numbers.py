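"""Re-derive the published analysis from the packaged study tables.

Prints the full fixture-based report: the Rockall intervention AUC (0.564)
and reconstructed mortality AUC (0.929), recomputed threshold tables,
Youden-optimal cutoffs (9 / 9 / 4), both endoscopy-timing odds-ratio
analyses, and an explicit list of published numbers the printed tables
cannot support, with reasons.
"""

from ugib_triage import reproduce_study

print(reproduce_study().format_text())
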