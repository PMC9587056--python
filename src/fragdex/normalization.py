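"""Between-sample TMM normalization and housekeeping-referenced standardization.

TMM (trimmed mean of M-values) computes one scale factor per sample from
doubly-trimmed, precision-weighted log count ratios against a reference
sample, then rescales so the factors have geometric mean 1.  Normalized
abundance is counts per million of the effective (factor-adjusted)
library.

Housekeeping (HK) candidates are ranked by their percent coefficient of
variation over all samples; transcripts under the CV% ceiling (default
20) form the reference set.  Standardization divides every sample by the
mean HK ratio-to-control of that sample, removing residual between-
sample drift, and expresses each row relative to its control mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._frames import DataError, split_meta


# --------------------------------------------------------------------------
# TMM scale factors
# --------------------------------------------------------------------------

def _pick_reference(values: np.ndarray) -> int:
    """Sample whose 75th-percentile count fraction is closest to the mean."""
    lib = values.sum(axis=0)
    q75 = np.quantile(values / lib, 0.75, axis=0)
    return int(np.argmin(np.abs(q75 - q75.mean())))


def _tmm_one(
    y_k: np.ndarray, y_r: np.ndarray, n_k: float, n_r: float,
    trim_m: float, trim_a: float,
) -> float:
    both = (y_k > 0) & (y_r > 0)
    if not both.any():
        raise DataError("sample shares no positive rows with the reference")
    yk, yr = y_k[both].astype(float), y_r[both].astype(float)
    pk, pr = yk / n_k, yr / n_r
    m = np.log2(pk / pr)
    a = 0.5 * np.log2(pk * pr)
    n = m.size
    # double trim: drop trim_m of each M tail and trim_a of each A tail
    m_rank = pd.Series(m).rank().to_numpy()
    a_rank = pd.Series(a).rank().to_numpy()
    lo_m, hi_m = np.floor(n * trim_m) + 1, n + 1 - (np.floor(n * trim_m) + 1)
    lo_a, hi_a = np.floor(n * trim_a) + 1, n + 1 - (np.floor(n * trim_a) + 1)
    keep = (m_rank >= lo_m) & (m_rank <= hi_m) & (a_rank >= lo_a) & (a_rank <= hi_a)
    if not keep.any():
        return 1.0
    var = (n_k - yk[keep]) / (n_k * yk[keep]) + (n_r - yr[keep]) / (n_r * yr[keep])
    w = 1.0 / var
    return float(2.0 ** (np.sum(w * m[keep]) / np.sum(w)))


def tmm_factors(
    counts: pd.DataFrame, trim_m: float = 0.30, trim_a: float = 0.05
) -> pd.Series:
    """Per-sample TMM scale factors, geometric mean 1."""
    _, values = split_meta(counts)
    if values.shape[1] < 2:
        raise DataError("TMM needs at least 2 samples")
    arr = values.to_numpy(dtype=float)
    lib = arr.sum(axis=0)
    if (lib <= 0).any():
        bad = values.columns[lib <= 0].tolist()
        raise DataError(f"zero library size in sample(s) {bad}")
    ref = _pick_reference(arr)
    factors = np.ones(arr.shape[1])
    for j in range(arr.shape[1]):
        if j == ref:
            continue
        try:
            factors[j] = _tmm_one(arr[:, j], arr[:, ref], lib[j], lib[ref], trim_m, trim_a)
        except DataError as exc:
            raise DataError(f"sample {values.columns[j]}: {exc}") from exc
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=values.columns, name="tmm_factor")


def tmm_normalize(
    counts: pd.DataFrame, trim_m: float = 0.30, trim_a: float = 0.05
) -> tuple[pd.DataFrame, pd.Series]:
    """Counts per million of the TMM-adjusted library, metadata preserved."""
    meta, values = split_meta(counts)
    factors = tmm_factors(counts, trim_m, trim_a)
    lib = values.sum(axis=0)
    norm = values / (lib * factors) * 1.0e6
    return pd.concat([meta, norm], axis=1), factors


# --------------------------------------------------------------------------
# Housekeeping stability statistics and selection
# --------------------------------------------------------------------------

def cv_percent(sd, mean):
    """Percent coefficient of variation, 100 * SD / mean."""
    return 100.0 * np.asarray(sd, dtype=float) / np.asarray(mean, dtype=float)


def hk_stats(expr: pd.DataFrame, candidates: list[str] | None = None) -> pd.DataFrame:
    """Distribution statistics per transcript over all samples.

    Columns: mean, minimum, maximum, sd (n-1 denominator), median,
    cv_percent.  ``candidates`` restricts (and orders) the rows.
    """
    _, values = split_meta(expr)
    if candidates is not None:
        missing = [c for c in candidates if c not in values.index]
        if missing:
            raise DataError(f"candidate transcript(s) absent from matrix: {missing}")
        values = values.loc[candidates]
    if values.shape[1] < 2:
        raise DataError("stability statistics need at least 2 samples")
    stats = pd.DataFrame(
        {
            "mean": values.mean(axis=1),
            "minimum": values.min(axis=1),
            "maximum": values.max(axis=1),
            "sd": values.std(axis=1, ddof=1),
            "median": values.median(axis=1),
        }
    )
    stats["cv_percent"] = cv_percent(stats["sd"], stats["mean"])
    return stats


def select_hk(stats: pd.DataFrame, cv_max: float = 20.0) -> list[str]:
    """Transcripts with CV% strictly below ``cv_max``, most stable first."""
    if stats.empty:
        raise DataError("empty stability table")
    kept = stats[stats["cv_percent"] < cv_max].sort_values("cv_percent")
    if kept.empty:
        import warnings

        warnings.warn("no transcript satisfies the CV% ceiling", stacklevel=2)
    return list(kept.index)


# --------------------------------------------------------------------------
# HK-referenced standardization
# --------------------------------------------------------------------------

@dataclass
class StandardizationFactors:
    per_sample: pd.Series          # F_s, dimensionless
    hk_transcripts: list[str]
    control_means: pd.Series       # HK transcript -> mean control abundance
    per_treatment_mode: bool = False


def standardize(
    expr: pd.DataFrame,
    hk: list[str],
    design: pd.DataFrame,
    control: str = "control",
    per_treatment: bool = False,
) -> tuple[StandardizationFactors, pd.DataFrame, pd.DataFrame]:
    """HK-referenced standardization and relative-to-control expression.

    For each HK transcript h: r_{h,s} = E_{h,s} / mean_control(E_h); the
    per-sample factor F_s is the arithmetic mean of r_{h,s} over h (with
    ``per_treatment`` the factors are additionally averaged over the
    replicates of each treatment).  Standardized values are E / F_s, and
    the relative table gives mean_t / mean_control per row.
    """
    if not hk:
        raise DataError("standardization needs a non-empty HK set")
    meta, values = split_meta(expr)
    if control not in set(design["treatment"]):
        raise DataError(f"control group {control!r} missing from design")
    control_samples = [
        s for s in design.index[design["treatment"] == control] if s in values.columns
    ]
    if len(control_samples) < 2:
        raise DataError("control group needs at least 2 replicates")
    missing = [h for h in hk if h not in values.index]
    if missing:
        raise DataError(f"HK transcript(s) absent from matrix: {missing}")

    hk_vals = values.loc[hk]
    control_means = hk_vals[control_samples].mean(axis=1)
    if (control_means <= 0).any():
        bad = list(control_means.index[control_means <= 0])
        raise DataError(f"HK transcript(s) with nonpositive control mean: {bad}")

    ratios = hk_vals.div(control_means, axis=0)
    factors = ratios.mean(axis=0)
    if per_treatment:
        by_t = design.loc[factors.index, "treatment"]
        factors = factors.groupby(by_t).transform("mean")
    factors.name = "standardization_factor"

    standardized = values.div(factors, axis=1)
    rel = {}
    for t, sub in design.groupby("treatment", sort=True):
        cols = [s for s in sub.index if s in standardized.columns]
        rel[t] = standardized[cols].mean(axis=1)
    relative = pd.DataFrame(rel)
    ctrl = relative[control].copy()
    relative = relative.div(ctrl, axis=0)

    info = StandardizationFactors(factors, list(hk), control_means, per_treatment)
    std_frame = pd.concat([meta, standardized], axis=1) if len(meta.columns) else standardized
    return info, std_frame, relative
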