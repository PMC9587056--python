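"""Fragment curation funnel: annotation confirmation, then expression filtering.

Stage 1 keeps a fragment only if its best alignment hit (highest bit
score; ties broken by lowest e-value, then lexicographic subject id)
points at the annotated gene with a percent match above threshold.
Stage 2 rejects fragments whose normalized expression is zero in any
sample, or whose overall mean is below a low floor while some
within-group coefficient of variation exceeds an erratic-variation
limit.  Statuses partition the fragment set; acceptance is monotone in
the thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._frames import DataError, split_meta

STATUS_CONFIRMED = "confirmed"
STATUS_REJECTED_ANNOTATION = "rejected_annotation"
STATUS_REJECTED_EXPRESSION = "rejected_expression"
STATUS_ACCEPTED = "accepted"

HIT_COLUMNS = ["qseqid", "sseqid", "pident", "length", "evalue", "bitscore"]


@dataclass
class CurationReport:
    """Per-fragment statuses plus funnel counts and per-group percentages."""

    statuses: pd.Series           # fragment_id -> status
    funnel: dict                  # stage -> count
    per_group: pd.DataFrame       # group_tag -> pass counts / percentages

    def passing(self) -> list[str]:
        ok = self.statuses.isin([STATUS_CONFIRMED, STATUS_ACCEPTED])
        return list(self.statuses.index[ok])

    @property
    def pass_percent(self) -> float:
        n = len(self.statuses)
        return 100.0 * len(self.passing()) / n if n else float("nan")


def read_hits(path) -> pd.DataFrame:
    """Read a BLAST tabular (outfmt-6-like) hit file."""
    try:
        hits = pd.read_csv(path, sep="\t", header=None, names=HIT_COLUMNS)
    except pd.errors.ParserError as exc:  # pragma: no cover - message passthrough
        raise DataError(f"malformed alignment hit file {path}: {exc}") from exc
    return hits


def _validate_hits(hits: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in HIT_COLUMNS if c not in hits.columns]
    if missing:
        raise DataError(f"alignment hit table lacks columns: {missing}")
    bad = hits.index[~hits["pident"].between(0.0, 100.0) | hits["pident"].isna()]
    if len(bad):
        raise DataError(f"percent match outside [0, 100] at row(s) {list(bad[:5])}")
    return hits


def best_hits(hits: pd.DataFrame) -> pd.DataFrame:
    """One row per query: highest bit score, ties by e-value then subject id."""
    ordered = hits.sort_values(
        ["qseqid", "bitscore", "evalue", "sseqid"],
        ascending=[True, False, True, True],
        kind="mergesort",
    )
    return ordered.drop_duplicates("qseqid", keep="first").set_index("qseqid")


def _group_rates(passed: pd.Series, groups: pd.Series) -> pd.DataFrame:
    tbl = pd.DataFrame({"passed": passed, "group_tag": groups})
    agg = tbl.groupby("group_tag", sort=True)["passed"].agg(["sum", "count"])
    agg.columns = ["n_passed", "n_total"]
    agg["percent"] = 100.0 * agg["n_passed"] / agg["n_total"]
    return agg


def confirm_annotation(
    hits: pd.DataFrame, fragments: pd.DataFrame, threshold_percent: float = 50.0
) -> CurationReport:
    """Annotation stage of the funnel.

    ``fragments`` is the annotated table (index fragment_id, columns
    gene_id and group_tag); a fragment with no hit row is rejected.
    """
    if fragments.empty:
        raise DataError("no fragments to confirm")
    _validate_hits(hits)
    best = best_hits(hits)
    frag_ids = fragments.index
    expected = fragments["gene_id"]

    sub = best["sseqid"].reindex(frag_ids)
    pid = best["pident"].reindex(frag_ids)
    ok = (sub == expected) & (pid > threshold_percent)
    statuses = pd.Series(
        np.where(ok, STATUS_CONFIRMED, STATUS_REJECTED_ANNOTATION),
        index=frag_ids, name="status",
    )
    funnel = {
        "total": int(len(frag_ids)),
        "confirmed": int(ok.sum()),
        "rejected_annotation": int((~ok).sum()),
    }
    return CurationReport(statuses, funnel, _group_rates(ok, fragments["group_tag"]))


def within_group_cv_percent(values: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Per-row CV% (sample SD / mean) within each treatment group."""
    out = {}
    for t, sub in design.groupby("treatment", sort=True):
        cols = [s for s in sub.index if s in values.columns]
        v = values[cols]
        m = v.mean(axis=1)
        sd = v.std(axis=1, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[t] = 100.0 * sd / m
    return pd.DataFrame(out)


def filter_expression(
    expr: pd.DataFrame,
    design: pd.DataFrame,
    low_floor: float = 5.0,
    erratic_cv_percent: float = 50.0,
) -> CurationReport:
    """Expression stage of the funnel, on a normalized abundance table.

    Rejects a fragment if (a) any sample value is exactly zero, or
    (b) its overall mean is below ``low_floor`` while some within-group
    CV% exceeds ``erratic_cv_percent``.
    """
    meta, values = split_meta(expr)
    if (values.to_numpy() < 0).any():
        raise DataError("expression matrix contains negative values")
    counts_per_group = design.groupby("treatment").size()
    if (counts_per_group < 2).any():
        raise DataError("each treatment group needs at least 2 samples")

    has_zero = (values == 0).any(axis=1)
    mean_all = values.mean(axis=1)
    cv = within_group_cv_percent(values, design)
    erratic = (mean_all < low_floor) & (cv > erratic_cv_percent).any(axis=1)
    rejected = has_zero | erratic
    statuses = pd.Series(
        np.where(rejected, STATUS_REJECTED_EXPRESSION, STATUS_ACCEPTED),
        index=values.index, name="status",
    )
    funnel = {
        "total": int(len(values)),
        "accepted": int((~rejected).sum()),
        "rejected_expression": int(rejected.sum()),
    }
    groups = meta["group_tag"] if "group_tag" in meta else pd.Series("none", index=values.index)
    return CurationReport(statuses, funnel, _group_rates(~rejected, groups))


def curate(
    hits: pd.DataFrame,
    expr: pd.DataFrame,
    design: pd.DataFrame,
    threshold_percent: float = 50.0,
    low_floor: float = 5.0,
    erratic_cv_percent: float = 50.0,
) -> CurationReport:
    """Full funnel: annotation confirmation, then expression filtering.

    The accepted set is a subset of the confirmed set, which is a subset
    of all fragments.
    """
    meta, _ = split_meta(expr)
    ann = confirm_annotation(hits, meta, threshold_percent)
    confirmed_ids = ann.statuses.index[ann.statuses == STATUS_CONFIRMED]
    expression = filter_expression(
        expr.loc[confirmed_ids], design, low_floor, erratic_cv_percent
    )
    statuses = ann.statuses.copy()
    statuses.loc[expression.statuses.index] = expression.statuses
    accepted = statuses == STATUS_ACCEPTED
    funnel = {
        "total": int(len(statuses)),
        "confirmed": ann.funnel["confirmed"],
        "rejected_annotation": ann.funnel["rejected_annotation"],
        "rejected_expression": expression.funnel["rejected_expression"],
        "accepted": int(accepted.sum()),
    }
    groups = meta["group_tag"]
    return CurationReport(statuses, funnel, _group_rates(accepted, groups))
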