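"""Exact nonparametric tests on fragments-as-replicates gene observations.

Each curated gene contributes its accepted fragments x replicates as
exchangeable observations per treatment group.  Across all groups a
tie-corrected Kruskal-Wallis H and Mood's median test are computed with
exact (enumeration) p-values at small sample sizes, seeded Monte-Carlo
permutation p-values otherwise, and a flagged chi-square approximation
as a last resort.  Treated-vs-control pairs use the two-group exact rank
test.  Responses are classified into a two-tier calling scheme:
significant (p <= 0.05) or tendency (p <= 0.10), with fold-change
magnitude bins matching a heat-map summary (< 2-fold, 2-4-fold,
> 4-fold).
"""

from __future__ import annotations

import itertools
import math
from collections import OrderedDict
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2, chi2_contingency, rankdata

from ._frames import DataError, split_meta

P_EPS = 1e-9  # absolute slack when comparing permuted statistics to the observed one


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str  # "exact" | "permutation" | "chi2"


@dataclass
class GeneObservations:
    gene_id: str
    groups: dict[str, np.ndarray]  # treatment -> standardized values


@dataclass
class Classification:
    direction: str      # up | down | none
    tier: str           # significant | tendency | ns
    magnitude_bin: str  # <2-fold | 2-4-fold | >4-fold

    @property
    def code(self) -> str:
        if self.tier == "ns":
            return "ns"
        return f"{self.direction}/{self.tier}/{self.magnitude_bin}"


def _check_groups(groups: list[np.ndarray]) -> list[np.ndarray]:
    groups = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(groups) < 2:
        raise DataError("need at least 2 groups")
    if any(g.size == 0 for g in groups):
        raise DataError("every group must be non-empty")
    return groups


def _tie_factor(pooled: np.ndarray) -> float:
    n = pooled.size
    _, t = np.unique(pooled, return_counts=True)
    return 1.0 - float(np.sum(t**3 - t)) / (n**3 - n)


def _h_from_ranksums(ranksums, sizes, n, tie_c):
    raw = 12.0 / (n * (n + 1)) * np.sum(
        np.asarray(ranksums, dtype=float) ** 2 / np.asarray(sizes, dtype=float),
        axis=-1,
    ) - 3.0 * (n + 1)
    return raw / tie_c


def _partitions(indices: tuple, sizes: tuple):
    """All ordered partitions of ``indices`` into blocks of the given sizes."""
    if len(sizes) == 1:
        yield (indices,)
        return
    for head in itertools.combinations(indices, sizes[0]):
        taken = set(head)
        rest = tuple(i for i in indices if i not in taken)
        for tail in _partitions(rest, sizes[1:]):
            yield (head,) + tail


# The enumeration null depends only on the rank multiset and group sizes,
# so it is cached (LRU) across genes sharing the same design and tie pattern.
_NULL_CACHE: OrderedDict[tuple, np.ndarray] = OrderedDict()
_NULL_CACHE_SIZE = 256


def _null_h_distribution(ranks: np.ndarray, sizes: tuple, tie_c: float) -> np.ndarray:
    ranks = np.sort(ranks)  # the null depends only on the multiset
    key = (sizes, tuple(ranks))
    cached = _NULL_CACHE.get(key)
    if cached is not None:
        _NULL_CACHE.move_to_end(key)
        return cached
    n = ranks.size
    sums = np.array(
        [[ranks[list(block)].sum() for block in part]
         for part in _partitions(tuple(range(n)), sizes)]
    )
    h = _h_from_ranksums(sums, sizes, n, tie_c)
    _NULL_CACHE[key] = h
    while len(_NULL_CACHE) > _NULL_CACHE_SIZE:
        _NULL_CACHE.popitem(last=False)
    return h


def kruskal_wallis_exact(
    groups,
    exact_limit: int = 10,
    n_perm: int = 100_000,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> TestResult:
    """Tie-corrected Kruskal-Wallis H with an exact/permutation p-value.

    Full enumeration of all N!/prod(n_i!) rank assignments when the total
    N is at most ``exact_limit``; otherwise a seeded Monte-Carlo
    permutation null of size ``n_perm``; with ``n_perm <= 0`` the
    chi-square approximation is used and flagged in ``method``.
    """
    groups = _check_groups(groups)
    sizes = tuple(g.size for g in groups)
    pooled = np.concatenate(groups)
    n = pooled.size
    if n < 3:
        raise DataError("need at least 3 observations in total")
    if np.ptp(pooled) == 0:
        return TestResult(0.0, 1.0, "exact")

    ranks = rankdata(pooled)
    tie_c = _tie_factor(pooled)
    bounds = np.cumsum((0,) + sizes)
    obs_sums = [ranks[bounds[i]:bounds[i + 1]].sum() for i in range(len(sizes))]
    h_obs = float(_h_from_ranksums(obs_sums, sizes, n, tie_c))
    h_obs = max(h_obs, 0.0)

    if n <= exact_limit:
        null = _null_h_distribution(ranks, sizes, tie_c)
        p = float(np.mean(null >= h_obs - P_EPS))
        return TestResult(h_obs, p, "exact")

    if n_perm > 0:
        if rng is None:
            rng = np.random.default_rng(seed)
        perm = np.argsort(rng.random((n_perm, n)), axis=1)
        perm_ranks = ranks[perm]
        sums = np.add.reduceat(perm_ranks, bounds[:-1], axis=1)
        h = _h_from_ranksums(sums, sizes, n, tie_c)
        hits = int(np.sum(h >= h_obs - P_EPS))
        return TestResult(h_obs, (hits + 1) / (n_perm + 1), "permutation")

    return TestResult(h_obs, float(chi2.sf(h_obs, len(sizes) - 1)), "chi2")


def median_test(groups, exact_limit: int = 10) -> TestResult:
    """Mood's median test: 2 x k table of counts above vs at-or-below the
    grand median, with an exact conditional p-value at small N."""
    groups = _check_groups(groups)
    pooled = np.concatenate(groups)
    n = pooled.size
    if n < 3:
        raise DataError("need at least 3 observations in total")
    grand = float(np.median(pooled))
    above = np.array([int(np.sum(g > grand)) for g in groups])
    sizes = np.array([g.size for g in groups])
    below = sizes - above
    a_total = int(above.sum())
    if a_total == 0 or a_total == n:
        return TestResult(0.0, 1.0, "exact")

    table = np.vstack([above, below])
    stat = float(chi2_contingency(table, correction=False)[0])

    if n <= exact_limit:
        # conditional null: multivariate hypergeometric over tables with fixed margins
        def prob(vec):
            num = math.prod(math.comb(int(s), int(a)) for s, a in zip(sizes, vec))
            return num / math.comb(n, a_total)

        p_obs = prob(above)
        p = 0.0
        ranges = [range(max(0, a_total - (n - int(sizes[j]))), min(sizes[j], a_total) + 1)
                  for j in range(len(sizes))]
        for vec in itertools.product(*ranges):
            if sum(vec) != a_total:
                continue
            pr = prob(vec)
            if pr <= p_obs * (1.0 + 1e-12):
                p += pr
        return TestResult(stat, min(p, 1.0), "exact")

    correction = len(groups) == 2
    p = float(chi2_contingency(table, correction=correction)[1])
    return TestResult(stat, p, "chi2")


def pairwise_vs_control(
    obs: GeneObservations,
    control: str = "control",
    exact_limit: int = 14,
    n_perm: int = 10_000,
    rng: np.random.Generator | None = None,
) -> dict[str, TestResult]:
    """Two-group exact rank test (Kruskal-Wallis at k=2) of each treatment
    against the control group."""
    if control not in obs.groups:
        raise DataError(f"control group {control!r} absent for gene {obs.gene_id}")
    out = {}
    for t, values in obs.groups.items():
        if t == control:
            continue
        out[t] = kruskal_wallis_exact(
            [values, obs.groups[control]],
            exact_limit=exact_limit, n_perm=n_perm, rng=rng,
        )
    return out


def classify_response(
    r: float, p: float, alpha: float = 0.05, tendency: float = 0.10
) -> Classification:
    """Two-tier call (significant / tendency / NS) with a fold-change bin."""
    if not (r > 0):
        raise DataError("relative expression must be positive")
    fold = max(r, 1.0 / r)
    if fold < 2.0:
        magnitude = "<2-fold"
    elif fold < 4.0:
        magnitude = "2-4-fold"
    else:
        magnitude = ">4-fold"
    if p <= alpha:
        tier = "significant"
    elif p <= tendency:
        tier = "tendency"
    else:
        return Classification("none", "ns", magnitude)
    return Classification("up" if r > 1 else "down", tier, magnitude)


# --------------------------------------------------------------------------
# Matrix-level driver
# --------------------------------------------------------------------------

def build_observations(
    std_expr: pd.DataFrame,
    design: pd.DataFrame,
    accepted: list[str] | None = None,
    genes: list[str] | None = None,
) -> list[GeneObservations]:
    """Pool accepted fragments x replicates per gene and treatment group."""
    meta, values = split_meta(std_expr)
    if accepted is not None:
        keep = [f for f in accepted if f in values.index]
        values, meta = values.loc[keep], meta.loc[keep]
    sample_groups = {
        t: [s for s in sub.index if s in values.columns]
        for t, sub in design.groupby("treatment", sort=True)
    }
    out = []
    for gene, sub in values.groupby(meta["gene_id"], sort=True):
        if genes is not None and gene not in genes:
            continue
        grp = {t: sub[cols].to_numpy().ravel() for t, cols in sample_groups.items()}
        if all(v.size > 0 for v in grp.values()):
            out.append(GeneObservations(str(gene), grp))
    return out


def analyze_genes(
    std_expr: pd.DataFrame,
    design: pd.DataFrame,
    accepted: list[str] | None = None,
    control: str = "control",
    alpha: float = 0.05,
    tendency: float = 0.10,
    exact_limit: int = 10,
    n_perm: int = 10_000,
    seed: int = 0,
    genes: list[str] | None = None,
) -> pd.DataFrame:
    """Per-gene omnibus + pairwise exact tests on standardized expression.

    Returns one row per gene: H and its p-value, the median-test p-value,
    and per non-control treatment the pairwise p, relative expression R
    (pooled mean over fragments and replicates, relative to control) and
    the classification code.
    """
    observations = build_observations(std_expr, design, accepted, genes)
    non_control = [t for t in dict.fromkeys(design["treatment"]) if t != control]
    rng = np.random.default_rng(seed)
    rows = []
    for obs in observations:
        ordered = [obs.groups[t] for t in sorted(obs.groups)]
        kw = kruskal_wallis_exact(ordered, exact_limit=exact_limit, n_perm=n_perm, rng=rng)
        med = median_test(ordered, exact_limit=exact_limit)
        pairs = pairwise_vs_control(
            obs, control=control, exact_limit=max(exact_limit, 14), n_perm=n_perm, rng=rng
        )
        ctrl_mean = float(obs.groups[control].mean())
        row = {"gene_id": obs.gene_id, "H": kw.statistic, "p_kw": kw.p_value,
               "p_median": med.p_value}
        for t in non_control:
            res = pairs[t]
            r = float(obs.groups[t].mean()) / ctrl_mean if ctrl_mean > 0 else float("nan")
            row[f"p_{t}"] = res.p_value
            row[f"R_{t}"] = r
            if r > 0:
                row[f"class_{t}"] = classify_response(r, res.p_value, alpha, tendency).code
            else:
                row[f"class_{t}"] = "ns"
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene_id") if rows else pd.DataFrame()
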