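"""Cross-approach concordance and heat-map-style summaries.

Per gene x treated-vs-control pair, the nonparametric (fragments as
replicates) and collapsed negative-binomial calls either agree on a
significant change in the same direction, agree that nothing is called,
or disagree.  The summary reports the overall percent agreement, the
per-pair agreement, and a histogram of genes by how many of their pairs
agree.  The heat-map table lays out the nonparametric classification
codes per gene x treatment, counts up vs down calls (significant and
tendency tiers) and their down:up ratio, and tallies fold-change
magnitude bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._frames import DataError

AGREE_SIG = "agree_sig_same_dir"
AGREE_NS = "agree_ns"
DISAGREE = "disagree"


@dataclass
class ConcordanceSummary:
    cells: pd.DataFrame           # gene x pair agreement categories
    percent_overall: float        # agreeing cells / all cells, in percent
    percent_by_pair: pd.Series    # per comparison
    histogram: pd.Series          # #agreeing pairs (0..n_pairs) -> gene count


def _np_call(p: float, r: float, alpha: float, tendency_as_sig: bool,
             tendency: float) -> str:
    """Direction of the nonparametric call, or 'none'."""
    cut = tendency if tendency_as_sig else alpha
    if p <= cut and r > 0 and r != 1.0:
        return "up" if r > 1.0 else "down"
    return "none"


def compare_calls(
    np_results: pd.DataFrame,
    nb_results: pd.DataFrame,
    pairs: list[str] | None = None,
    alpha: float = 0.05,
    tendency: float = 0.10,
    tendency_as_sig: bool = False,
    direction_must_match: bool = True,
) -> ConcordanceSummary:
    """Agreement of the two statistical approaches per gene x pair.

    ``np_results`` is the per-gene table from the nonparametric driver
    (columns p_<pair>, R_<pair>); ``nb_results`` the called NB table
    (gene_id, comparison, call).  Agreement means both significant with
    the same direction, or both not called; tendencies count as not
    called unless ``tendency_as_sig``.
    """
    if pairs is None:
        pairs = sorted(nb_results["comparison"].unique())
    nb_calls = nb_results.pivot(index="gene_id", columns="comparison", values="call")
    shared = [g for g in np_results.index if g in nb_calls.index]
    if not shared:
        raise DataError("no genes shared between the two result sets")

    cells = {}
    for t in pairs:
        col = []
        for g in shared:
            a = _np_call(float(np_results.loc[g, f"p_{t}"]),
                         float(np_results.loc[g, f"R_{t}"]),
                         alpha, tendency_as_sig, tendency)
            b = str(nb_calls.loc[g, t])
            if a == "none" and b == "none":
                col.append(AGREE_NS)
            elif a != "none" and b != "none" and (a == b or not direction_must_match):
                col.append(AGREE_SIG)
            else:
                col.append(DISAGREE)
        cells[t] = col
    table = pd.DataFrame(cells, index=pd.Index(shared, name="gene_id"))

    agree = table.isin([AGREE_SIG, AGREE_NS])
    percent_overall = 100.0 * agree.to_numpy().mean()
    percent_by_pair = 100.0 * agree.mean(axis=0)
    percent_by_pair.name = "percent_agreement"
    n_agree = agree.sum(axis=1)
    histogram = (
        n_agree.value_counts().reindex(range(len(pairs) + 1), fill_value=0).sort_index()
    )
    histogram.name = "n_genes"
    return ConcordanceSummary(table, float(percent_overall), percent_by_pair, histogram)


@dataclass
class HeatmapSummary:
    matrix: pd.DataFrame          # gene x treatment classification codes
    n_up: int
    n_down: int
    down_up_ratio: float          # NaN when no up-regulated cells ("NA" on export)
    magnitude_counts: pd.Series   # fold-change bin -> #called cells


def heatmap_table(
    np_results: pd.DataFrame, genes: list[str] | None = None
) -> HeatmapSummary:
    """Classification-code matrix with down:up and magnitude-bin counts.

    Counts consider cells called at either tier (significant or
    tendency); the ratio is reported as NaN when undefined.
    """
    class_cols = [c for c in np_results.columns if c.startswith("class_")]
    if not class_cols:
        raise DataError("result table has no classification columns")
    matrix = np_results[class_cols].copy()
    matrix.columns = [c.removeprefix("class_") for c in class_cols]
    if genes is not None:
        matrix = matrix.loc[[g for g in genes if g in matrix.index]]

    codes = matrix.to_numpy().ravel()
    called = [c for c in codes if c != "ns"]
    n_up = sum(c.startswith("up/") for c in called)
    n_down = sum(c.startswith("down/") for c in called)
    ratio = n_down / n_up if n_up > 0 else float("nan")
    bins = pd.Series([c.rsplit("/", 1)[-1] for c in called], dtype=object)
    magnitude_counts = (
        bins.value_counts().reindex(["<2-fold", "2-4-fold", ">4-fold"], fill_value=0)
    )
    magnitude_counts.name = "n_cells"
    return HeatmapSummary(matrix, int(n_up), int(n_down), float(ratio), magnitude_counts)


def heatmap_export(summary: HeatmapSummary) -> dict:
    """JSON-ready heat-map counts; the undefined ratio becomes "NA"."""
    ratio = summary.down_up_ratio
    return {
        "n_up": summary.n_up,
        "n_down": summary.n_down,
        "down_up_ratio": "NA" if np.isnan(ratio) else round(ratio, 4),
        "magnitude_counts": {k: int(v) for k, v in summary.magnitude_counts.items()},
    }
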