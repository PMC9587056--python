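"""Collapsed-gene negative-binomial exact tests (classic count-based DE).

Fragments are summed into one count row per gene; a single common
dispersion phi (NB variance = mu + phi*mu^2) is estimated by a
method-of-moments/median pool over genes; each treated-vs-control pair
is tested with a two-sided exact test that conditions on the pooled
group total and sums the conditional probabilities of all splits as or
less likely than the observed one.  Calls follow the classic screening
rule: fold change >= 2 (or <= 1/2) with p <= 0.05, ranked by |log2 fold
change|.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import nbinom, poisson

from ._frames import DataError, split_meta

_POISSON_PHI = 1e-12

RANK_BINS = (
    (10, "top-10"),
    (50, "10-50"),
    (100, "50-100"),
    (500, "100-500"),
    (1500, "500-1500"),
)


def collapse_fragments(counts: pd.DataFrame) -> pd.DataFrame:
    """Column-preserving sum of fragment counts per gene, genes sorted."""
    meta, values = split_meta(counts)
    if "gene_id" not in meta:
        raise DataError("fragment matrix lacks a gene_id column")
    gc = values.groupby(meta["gene_id"], sort=True).sum()
    gc.index.name = "gene_id"
    return gc


def effective_library_sizes(
    counts_values: pd.DataFrame, factors: pd.Series | None = None
) -> pd.Series:
    lib = counts_values.sum(axis=0).astype(float)
    if factors is not None:
        lib = lib * factors.reindex(lib.index).fillna(1.0)
    lib.name = "effective_library"
    return lib


def estimate_common_dispersion(
    gene_counts: pd.DataFrame,
    design: pd.DataFrame,
    factors: pd.Series | None = None,
    min_mean: float = 5.0,
) -> float:
    """Method-of-moments common dispersion, pooled by the median.

    Counts are first rescaled to a common effective library; per gene the
    within-group mean and variance are averaged over replicated groups
    and phi_g = max(0, (s^2 - m)/m^2); the estimate is the median of
    phi_g over genes whose mean exceeds ``min_mean``.
    """
    values = gene_counts[[c for c in gene_counts.columns if c in design.index]]
    lib = effective_library_sizes(values, factors)
    scale = np.exp(np.mean(np.log(lib))) / lib
    scaled = values * scale

    groups = [
        [s for s in sub.index if s in scaled.columns]
        for _, sub in design.groupby("treatment", sort=True)
    ]
    groups = [g for g in groups if len(g) >= 2]
    if not groups:
        raise DataError("no treatment group has replication")
    means = np.stack([scaled[g].mean(axis=1).to_numpy() for g in groups])
    variances = np.stack([scaled[g].var(axis=1, ddof=1).to_numpy() for g in groups])
    m = means.mean(axis=0)
    s2 = variances.mean(axis=0)
    keep = m > min_mean
    if not keep.any():
        return 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        phi_g = np.maximum(0.0, (s2[keep] - m[keep]) / m[keep] ** 2)
    return float(np.median(phi_g))


def _log_pmf(x: np.ndarray, mean: float, size: float, phi: float) -> np.ndarray:
    if phi <= _POISSON_PHI:
        return poisson.logpmf(x, mean)
    return nbinom.logpmf(x, size, size / (size + mean))


def nb_exact_test(
    treated: np.ndarray,
    control: np.ndarray,
    lib_treated: np.ndarray,
    lib_control: np.ndarray,
    phi: float,
    prior_count: float = 0.5,
) -> tuple[float, float]:
    """Two-sided conditional exact test for one gene; returns (p, log2FC).

    Sample counts are first rescaled to the pair's geometric-mean
    effective library (deterministic rounding) so the group sums are
    exchangeable under the null; the two-sided p-value sums conditional
    probabilities of every split of the pooled total that is as or less
    likely than the observed one.  log2FC uses a library-size-
    proportional prior count for stabilization.
    """
    treated = np.asarray(treated, dtype=float)
    control = np.asarray(control, dtype=float)
    lib_t = np.asarray(lib_treated, dtype=float)
    lib_c = np.asarray(lib_control, dtype=float)
    if treated.size == 0 or control.size == 0:
        raise DataError("both groups need at least one sample")

    # log2 fold change on raw rates with a prior proportional to library size
    lt, lc = lib_t.sum(), lib_c.sum()
    lbar = 0.5 * (lt + lc)
    rate_t = (treated.sum() + prior_count * lt / lbar) / lt
    rate_c = (control.sum() + prior_count * lc / lbar) / lc
    log2fc = float(np.log2(rate_t / rate_c))

    # equalize libraries, then condition on the pooled total
    all_lib = np.concatenate([lib_t, lib_c])
    geo = float(np.exp(np.mean(np.log(all_lib))))
    s1 = int(np.floor(np.sum(treated * geo / lib_t) + 0.5))
    s2 = int(np.floor(np.sum(control * geo / lib_c) + 0.5))
    total = s1 + s2
    if total == 0:
        return 1.0, 0.0

    n1, n2 = treated.size, control.size
    mu = total / (n1 + n2)
    x = np.arange(total + 1)
    with np.errstate(divide="ignore"):
        lp = (
            _log_pmf(x, n1 * mu, n1 / phi if phi > _POISSON_PHI else np.inf, phi)
            + _log_pmf(total - x, n2 * mu, n2 / phi if phi > _POISSON_PHI else np.inf, phi)
        )
    lp -= lp.max()
    probs = np.exp(lp)
    obs = probs[s1]
    p = float(probs[probs <= obs * (1.0 + 1e-10)].sum() / probs.sum())
    return min(p, 1.0), log2fc


def nb_analyze(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    factors: pd.Series | None = None,
    control: str = "control",
    phi: float | None = None,
    prior_count: float = 0.5,
    pairs: list[str] | None = None,
) -> pd.DataFrame:
    """Collapse, estimate dispersion, and exact-test every treated pair.

    Returns one row per gene x comparison with p, log2FC and the
    dispersion used.
    """
    gc = collapse_fragments(counts)
    samples = [c for c in gc.columns if c in design.index]
    gc = gc[samples]
    lib = effective_library_sizes(gc, factors)
    if phi is None:
        phi = estimate_common_dispersion(gc, design.loc[samples], factors)
    treatments = design.loc[samples, "treatment"]
    if pairs is None:
        pairs = [t for t in dict.fromkeys(treatments) if t != control]
    ctrl_cols = [s for s in samples if treatments[s] == control]
    if not ctrl_cols:
        raise DataError(f"control group {control!r} missing from design")
    lib_c = lib[ctrl_cols].to_numpy()
    ctrl = gc[ctrl_cols].to_numpy()

    rows = []
    for t in pairs:
        t_cols = [s for s in samples if treatments[s] == t]
        if not t_cols:
            raise DataError(f"treatment group {t!r} missing from design")
        lib_t = lib[t_cols].to_numpy()
        tr = gc[t_cols].to_numpy()
        for i, gene in enumerate(gc.index):
            p, lfc = nb_exact_test(tr[i], ctrl[i], lib_t, lib_c, phi, prior_count)
            rows.append({"gene_id": gene, "comparison": t, "p": p,
                         "log2FC": lfc, "dispersion": phi})
    return pd.DataFrame(rows)


def call_degs(
    results: pd.DataFrame, fc_threshold: float = 2.0, p_max: float = 0.05
) -> pd.DataFrame:
    """Classic screening call: |FC| bound and p-value bound jointly."""
    if results.empty:
        raise DataError("empty result table")
    out = results.copy()
    log2_thr = np.log2(fc_threshold)
    up = (out["log2FC"] >= log2_thr) & (out["p"] <= p_max)
    down = (out["log2FC"] <= -log2_thr) & (out["p"] <= p_max)
    out["call"] = np.where(up, "up", np.where(down, "down", "none"))
    return out


def rank_bin(rank: int) -> str:
    for ceiling, label in RANK_BINS:
        if rank <= ceiling:
            return label
    return ">1500"


def rank_degs(called: pd.DataFrame) -> pd.DataFrame:
    """Rank significant DEGs per comparison by descending |log2FC|.

    Ties break by smaller p, then gene id.  Non-called genes keep rank
    NaN and bin "NS".
    """
    out = called.copy()
    out["rank"] = np.nan
    out["bin"] = "NS"
    for _, idx in out.groupby("comparison").groups.items():
        sub = out.loc[idx]
        sig = sub[sub["call"] != "none"].copy()
        if sig.empty:
            continue
        sig["_abs"] = sig["log2FC"].abs()
        sig = sig.sort_values(["_abs", "p", "gene_id"], ascending=[False, True, True],
                              kind="mergesort")
        ranks = np.arange(1, len(sig) + 1)
        out.loc[sig.index, "rank"] = ranks
        out.loc[sig.index, "bin"] = [rank_bin(r) for r in ranks]
    return out
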