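"""Bundled reference data.

``reference_run_stats`` returns the published per-sample sequencing
statistics of the S. meliloti antimicrobial-peptide Tn-seq screen (input,
nontreated, NCR247-treated and polymyxin-B-treated cultures in two
biological replicates).  The normalization factor (NF) column is printed at
three decimals, as reported; the normalized-read column in the source
equals round(total_reads x NF), which `tnseq_ci.pipeline.table1_report`
reproduces for any run.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["reference_run_stats"]

_ROWS = [
    # replicate, sample, total_reads, pct_no_tn, reads_too_short,
    # reads_used, alignment_rate, nf, normalized_reads, reads_per_site
    (1, "Input", 21_652_251, 5.20, 36_631, 20_489_022, 80.40, 0.844, 18_274_500, 129),
    (1, "Nontreated", 20_304_098, 6.94, 29_769, 18_865_247, 80.09, 0.920, 18_679_770, 119),
    (1, "NCR247 treated", 20_121_669, 8.14, 34_245, 18_450_409, 80.80, 0.921, 18_532_057, 116),
    (1, "PMB treated", 18_401_067, 7.18, 30_931, 17_049_767, 80.66, 0.998, 18_364_265, 107),
    (2, "Input", 20_153_000, 12.72, 30_042, 17_560_139, 81.50, 0.943, 19_004_279, 111),
    (2, "Nontreated", 22_731_094, 7.97, 33_510, 20_885_738, 80.66, 0.811, 18_434_917, 132),
    (2, "NCR247 treated", 18_798_923, 7.77, 30_051, 17_307_732, 80.11, 1.000, 18_798_923, 109),
    (2, "PMB treated", 18_906_038, 8.75, 28_138, 17_224_367, 79.88, 0.994, 18_792_602, 109),
]

_COLUMNS = [
    "replicate",
    "sample",
    "total_reads",
    "pct_no_tn",
    "reads_too_short",
    "reads_used",
    "alignment_rate",
    "nf",
    "normalized_reads",
    "reads_per_site",
]


def reference_run_stats() -> pd.DataFrame:
    """Published per-sample statistics of the reference Tn-seq screen."""
    return pd.DataFrame(_ROWS, columns=_COLUMNS)
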