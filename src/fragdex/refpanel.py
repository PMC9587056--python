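"""Published candidate reference-gene panel for toad (Rhinella arenarum) larvae.

Summary statistics (TMM units, over 10 samples: 5 treatment groups in
duplicate) of 12 transcripts proposed as housekeeping candidates for the
stage-25 larval transcriptome, as printed in the source study's
stability table.  Used as a worked-example input: the CV% column must be
recoverable from the mean and SD columns, and the CV% < 20 rule must
retain exactly the nine accepted reference transcripts.
"""

from __future__ import annotations

import io

import pandas as pd

_PANEL_TSV = """\
transcript	mean	minimum	maximum	sd	median	cv_percent
ef1a0	7329.9	6610.7	8457.7	586.4	7265.4	8.00
ef1b	583.4	498.6	676.9	64.3	589.4	11.03
ef1d	922.1	800.7	1074.7	98.3	910.4	10.66
ef1g-a	2993.7	2611.2	3344.1	252.9	2968.2	8.45
g3pdh	1822.0	1289.5	2425.1	411.3	1768.3	22.58
rl8	1108.0	883.6	1309.3	134.8	1131.6	12.16
tuba	1829.9	1589.5	2014.7	142.9	1826.3	7.81
tuba1	146.1	98.1	195.5	31.8	142.1	21.74
tubb	518.4	350.2	586.8	70.4	526.8	13.58
tubb4b	219.0	137.1	253.7	33.3	224.5	15.19
actb	363.6	301.7	394.4	37.2	380.3	10.22
acta4	90.1	15.1	259.4	73.3	61.9	81.27
"""

# Rows whose printed CV% is exactly 100*sd/mean at the printed precision;
# the remaining rows carry more rounding in the printed summary columns.
SELF_CONSISTENT_ROWS = ("ef1a0", "ef1d", "tubb", "tuba", "ef1g-a")

# The nine transcripts that satisfy CV% < 20.
ACCEPTED_REFERENCES = (
    "ef1a0", "ef1b", "ef1d", "ef1g-a", "rl8", "tuba", "tubb", "tubb4b", "actb",
)


def candidate_panel() -> pd.DataFrame:
    """The 12-row candidate panel, indexed by transcript."""
    return pd.read_csv(io.StringIO(_PANEL_TSV), sep="\t", index_col="transcript")
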