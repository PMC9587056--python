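"""Synthetic fragment-level transcriptome datasets with known ground truth.

Emulates a 5-treatment (solvent control plus two organophosphorus
pesticides at two exposure times) x 2-replicate bulk RNA-seq design in
which each annotated gene is represented by several assembled transcript
fragments.  Counts are negative-binomially distributed around
library-size x gene-abundance x treatment-effect x fragment-share means;
a designated set of housekeeping (HK) genes receives zero treatment
effect and tightened biological dispersion so that their coefficient of
variation stays below a target; a fraction of fragments is corrupted
(zeros or low/erratic values) to exercise the curation filters.

Every generator draws from an independent, labelled substream of one
top-level seed, so adding or re-running one generator never perturbs the
others.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._frames import ConfigurationError, DataError

# Fixed substream labels: adding a stream must never renumber others.
_STREAMS = {"structure": 0, "counts": 1, "corruption": 2, "hits": 3, "qpcr": 4}

DEFAULT_TREATMENTS = ("control", "AZM6", "AZM24", "CPF6", "CPF24")


def _substream(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(_STREAMS[name],))
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study design.

    Defaults mirror the emulated study: 5 treatment groups in duplicate,
    1-5 fragments per gene (~2-3 on average), mostly sub-2-fold effects
    with down-regulation dominating up-regulation 3:1, NB-distributed
    counts, and a panel of low-variability housekeeping genes.
    """

    n_genes: int = 2000
    fragments_per_gene: tuple[int, int] = (1, 5)
    treatments: tuple[str, ...] = DEFAULT_TREATMENTS
    control: str = "control"
    n_replicates: int = 2
    baseline_log_mean: float = 5.5   # natural-log counts: median gene ~245 counts
    baseline_log_sd: float = 1.5
    nb_dispersion: float = 0.05      # NB variance = mu + phi * mu^2
    library_size_cv: float = 0.2
    frac_affected: float = 0.3
    down_up_ratio: float = 3.0
    effect_log2_range: tuple[float, float] = (0.3, 2.0)
    n_hk_genes: int = 50
    hk_cv_target: float = 15.0       # percent
    frac_bad_fragments: float = 0.25
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be a positive integer")
        lo, hi = self.fragments_per_gene
        if lo < 1 or hi < lo:
            raise ConfigurationError("fragments_per_gene bounds must satisfy 1 <= lo <= hi")
        if self.n_replicates < 2:
            raise ConfigurationError("n_replicates must be >= 2")
        if self.treatments.count(self.control) != 1 or len(set(self.treatments)) != len(self.treatments):
            raise ConfigurationError("treatments must be unique and contain exactly one control group")
        if self.baseline_log_sd < 0:
            raise ConfigurationError("baseline_log_sd must be nonnegative")
        if not math.isfinite(self.baseline_log_mean):
            raise ConfigurationError("baseline_log_mean must be finite")
        if self.nb_dispersion < 0:
            raise ConfigurationError("nb_dispersion must be nonnegative")
        if self.library_size_cv < 0:
            raise ConfigurationError("library_size_cv must be nonnegative")
        for name in ("frac_affected", "frac_bad_fragments"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if self.down_up_ratio <= 0:
            raise ConfigurationError("down_up_ratio must be positive")
        e_lo, e_hi = self.effect_log2_range
        if e_lo < 0 or e_hi < e_lo:
            raise ConfigurationError("effect_log2_range must satisfy 0 <= lo <= hi")
        if self.n_hk_genes < 0:
            raise ConfigurationError("n_hk_genes must be nonnegative")
        if self.n_hk_genes > self.n_genes:
            raise ConfigurationError("n_hk_genes cannot exceed n_genes")
        if self.hk_cv_target <= 0:
            raise ConfigurationError("hk_cv_target must be positive")

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class TruthTable:
    """Ground truth of a simulated dataset.

    ``genes`` has one row per gene: ``group_tag``, ``is_hk`` and one
    ``log2_effect_<treatment>`` column per non-control treatment.
    ``bad_fragment_ids`` lists the deliberately corrupted fragments.
    """

    genes: pd.DataFrame
    bad_fragment_ids: list[str] = field(default_factory=list)
    fragment_means: pd.DataFrame | None = None  # expected NB means, pre-corruption

    @property
    def hk_gene_ids(self) -> list[str]:
        return list(self.genes.index[self.genes["is_hk"]])

    def effect_columns(self) -> list[str]:
        return [c for c in self.genes.columns if c.startswith("log2_effect_")]

    def affected_gene_ids(self, min_abs_log2: float = 0.0) -> list[str]:
        eff = self.genes[self.effect_columns()].abs().max(axis=1)
        return list(self.genes.index[(eff > 0) & (eff >= min_abs_log2)])


def generate_design(config: SimulationConfig) -> pd.DataFrame:
    """One sample per (treatment, replicate); ids stable under the seed."""
    config.validate()
    rows = [
        {"sample_id": f"{t}_r{r}", "treatment": t, "replicate": r}
        for t in config.treatments
        for r in range(1, config.n_replicates + 1)
    ]
    return pd.DataFrame(rows).set_index("sample_id")


def _lognormal_unit_mean(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Log-normal multipliers with mean 1 and the requested CV."""
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log1p(cv * cv))
    return rng.lognormal(mean=-sigma * sigma / 2.0, sigma=sigma, size=size)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """NB(mean, dispersion phi) with variance mu + phi*mu^2; Poisson at phi=0."""
    mean = np.asarray(mean, dtype=float)
    phi = np.broadcast_to(np.asarray(phi, dtype=float), mean.shape)
    out = np.empty(mean.shape, dtype=np.int64)
    pois = phi <= 1e-12
    if pois.any():
        out[pois] = rng.poisson(mean[pois])
    if (~pois).any():
        size = 1.0 / phi[~pois]
        p = size / (size + mean[~pois])
        out[~pois] = rng.negative_binomial(size, p)
    return out


def generate_counts(
    design: pd.DataFrame, config: SimulationConfig
) -> tuple[pd.DataFrame, TruthTable]:
    """Simulate the fragment x sample count matrix and its ground truth.

    The housekeeping panel (group tag ``A``) contains the ``n_hk_genes``
    true HK genes plus an equal number of treatment-responsive decoy
    genes, emulating an a-priori proposed reference panel of which some
    members turn out to be unstable.
    """
    config.validate()
    if config.baseline_log_mean != 0 and math.exp(config.baseline_log_mean) <= 0:
        raise ConfigurationError("baseline_log_mean yields nonpositive abundance")
    rng_s = _substream(config.seed, "structure")
    rng_c = _substream(config.seed, "counts")
    rng_x = _substream(config.seed, "corruption")

    n = config.n_genes
    gene_ids = np.array([f"g{i:05d}" for i in range(1, n + 1)])
    non_control = [t for t in config.treatments if t != config.control]

    # --- gene-level structure -------------------------------------------------
    hk_idx = rng_s.choice(n, size=config.n_hk_genes, replace=False)
    is_hk = np.zeros(n, dtype=bool)
    is_hk[hk_idx] = True

    affected = np.zeros(n, dtype=bool)
    cand = ~is_hk
    affected[cand] = rng_s.random(cand.sum()) < config.frac_affected

    p_down = config.down_up_ratio / (1.0 + config.down_up_ratio)
    sign = np.where(rng_s.random(n) < p_down, -1.0, 1.0)
    e_lo, e_hi = config.effect_log2_range
    magnitude = rng_s.uniform(e_lo, e_hi, size=n)
    log2_effect = np.where(affected, sign * magnitude, 0.0)

    # decoy panel members: affected genes posing as reference candidates
    n_decoys = min(config.n_hk_genes, int(affected.sum()))
    decoy_pool = np.flatnonzero(affected)
    decoy_idx = (
        rng_s.choice(decoy_pool, size=n_decoys, replace=False)
        if n_decoys
        else np.array([], dtype=int)
    )
    group = np.full(n, "none", dtype=object)
    other = np.flatnonzero(~is_hk)
    pathway = rng_s.random(n) < 0.4
    group[other] = np.where(
        pathway[other], rng_s.choice(list("BCDE"), size=other.size), "none"
    )
    group[hk_idx] = "A"
    group[decoy_idx] = "A"

    abundance = rng_s.lognormal(config.baseline_log_mean, config.baseline_log_sd, size=n)
    # HK genes are highly expressed, like real reference transcripts
    abundance[hk_idx] = math.exp(config.baseline_log_mean + 1.0) * rng_s.lognormal(
        0.0, 0.4, size=config.n_hk_genes
    )

    phi = np.full(n, config.nb_dispersion)
    phi_hk = min(config.nb_dispersion, (0.45 * config.hk_cv_target / 100.0) ** 2)
    phi[hk_idx] = phi_hk

    # --- fragment-level structure --------------------------------------------
    f_lo, f_hi = config.fragments_per_gene
    n_frags = rng_s.integers(f_lo, f_hi + 1, size=n)
    frag_gene = np.repeat(np.arange(n), n_frags)
    frag_ids, shares = [], []
    for gi in range(n):
        k = n_frags[gi]
        frag_ids.extend(f"{gene_ids[gi]}_f{j}" for j in range(1, k + 1))
        shares.append(rng_s.dirichlet(np.full(k, 5.0)))
    frag_ids = np.array(frag_ids)
    shares = np.concatenate(shares)

    # --- count sampling -------------------------------------------------------
    samples = design.index.to_numpy()
    treatments = design["treatment"].to_numpy()
    lib = _lognormal_unit_mean(rng_c, config.library_size_cv, len(samples))

    eff_by_treatment = {config.control: np.zeros(n)}
    for t in non_control:
        eff_by_treatment[t] = log2_effect
    mu = np.empty((len(frag_ids), len(samples)))
    base = abundance[frag_gene] * shares
    for j, (s, t) in enumerate(zip(samples, treatments)):
        mu[:, j] = lib[j] * base * np.exp2(eff_by_treatment[t][frag_gene])
    counts = _nb_draw(rng_c, mu, phi[frag_gene][:, None])

    # --- corruption -----------------------------------------------------------
    eligible = np.flatnonzero(~is_hk[frag_gene])  # keep the HK panel clean
    n_bad = int(round(config.frac_bad_fragments * len(frag_ids)))
    n_bad = min(n_bad, eligible.size)
    bad = rng_x.choice(eligible, size=n_bad, replace=False) if n_bad else np.array([], int)
    modes = rng_x.random(n_bad)
    median_count = max(float(np.median(counts.sum(axis=0))), 1.0)
    low_target = 5.0 * median_count / 1.0e6  # just under a 5-per-million floor
    for fi, m in zip(bad, modes):
        if m < 0.5:  # dropout: one sample forced to zero
            counts[fi, rng_x.integers(len(samples))] = 0
        else:  # erratic: scale the whole fragment below the low floor, crush one replicate
            row_mean = max(counts[fi].mean(), 1.0)
            scaled = counts[fi] * (rng_x.uniform(0.2, 0.8) * low_target / row_mean)
            j = rng_x.integers(len(samples))
            scaled[j] *= rng_x.uniform(0.05, 0.3)
            counts[fi] = np.maximum(np.rint(scaled), 0)
            if counts[fi].max() == 0:
                counts[fi, rng_x.integers(len(samples))] = 1

    frame = pd.DataFrame(counts, index=pd.Index(frag_ids, name="fragment_id"), columns=samples)
    frame.insert(0, "group_tag", group[frag_gene])
    frame.insert(0, "gene_id", gene_ids[frag_gene])

    truth_genes = pd.DataFrame(
        {"group_tag": group, "is_hk": is_hk},
        index=pd.Index(gene_ids, name="gene_id"),
    )
    for t in non_control:
        truth_genes[f"log2_effect_{t}"] = eff_by_treatment[t]
    truth = TruthTable(
        genes=truth_genes,
        bad_fragment_ids=sorted(frag_ids[bad]),
        fragment_means=pd.DataFrame(mu, index=frame.index, columns=samples),
    )
    return frame, truth


def generate_alignment_hits(
    fragments: pd.DataFrame, confirm_rate: float, config: SimulationConfig
) -> pd.DataFrame:
    """Best-hit alignment rows in BLAST tabular (outfmt-6-like) dialect.

    Exactly ``round(confirm_rate * n_fragments)`` fragments receive a best
    hit to their annotated gene with percent identity above 50; the rest
    get a sub-threshold hit or no row at all.  Subject ids are the
    annotated gene ids.  Some confirmed fragments also get a weaker decoy
    hit to a different gene, exercising best-hit selection downstream.
    """
    if not 0.0 <= confirm_rate <= 1.0:
        raise ConfigurationError("confirm_rate must lie in [0, 1]")
    rng = _substream(config.seed, "hits")
    frag_ids = fragments.index.to_numpy()
    genes = fragments["gene_id"].to_numpy()
    n = len(frag_ids)
    k = int(round(confirm_rate * n))
    confirmed = np.zeros(n, dtype=bool)
    confirmed[rng.choice(n, size=k, replace=False)] = True

    all_genes = np.unique(genes)
    rows = []
    for i in range(n):
        if confirmed[i]:
            bits = rng.uniform(200.0, 1000.0)
            rows.append(
                (frag_ids[i], genes[i], rng.uniform(55.0, 100.0),
                 int(rng.integers(150, 900)), 10.0 ** -rng.uniform(20, 100), bits)
            )
            if rng.random() < 0.3 and all_genes.size > 1:  # weaker off-target hit
                wrong = rng.choice(all_genes)
                if wrong != genes[i]:
                    rows.append(
                        (frag_ids[i], wrong, rng.uniform(55.0, 100.0),
                         int(rng.integers(150, 900)), 10.0 ** -rng.uniform(5, 20),
                         bits * rng.uniform(0.3, 0.9))
                    )
        elif rng.random() < 0.5:  # sub-threshold match to the expected gene
            rows.append(
                (frag_ids[i], genes[i], rng.uniform(20.0, 50.0),
                 int(rng.integers(60, 300)), 10.0 ** -rng.uniform(1, 5),
                 rng.uniform(30.0, 80.0))
            )
        # else: no hit at all
    return pd.DataFrame(
        rows, columns=["qseqid", "sseqid", "pident", "length", "evalue", "bitscore"]
    )


def generate_qpcr(
    design: pd.DataFrame,
    truth: TruthTable,
    efficiency: float = 2.0,
    ct_noise_sd: float = 0.2,
    config: SimulationConfig | None = None,
    target_genes: list[str] | None = None,
    hk_genes: list[str] | None = None,
) -> pd.DataFrame:
    """Simulated qPCR quantification-cycle (Ct) table.

    Ct_{g,s} = Ct0_g - log_E(relative quantity implied by the truth
    table) + N(0, ct_noise_sd); HK genes have treatment-independent
    expected Ct.  Rows: (sample_id, gene_id, role, ct).
    """
    if not 1.0 < efficiency <= 2.0:
        raise ConfigurationError("efficiency must lie in (1, 2]")
    if ct_noise_sd < 0:
        raise ConfigurationError("ct_noise_sd must be nonnegative")
    seed = config.seed if config is not None else 0
    rng = _substream(seed, "qpcr")

    hk_all = truth.hk_gene_ids
    if hk_genes is None:
        hk_genes = hk_all[:2]
    if not hk_genes:
        raise DataError("qPCR simulation needs at least one HK gene in the truth table")
    if target_genes is None:
        aff = [g for g in truth.affected_gene_ids() if g not in hk_genes]
        target_genes = aff[:8]

    eff_cols = truth.effect_columns()
    log_e = math.log(efficiency)
    rows = []
    for role, genes in (("hk", hk_genes), ("target", target_genes)):
        for g in genes:
            ct0 = rng.uniform(18.0, 28.0)
            for s, t in design["treatment"].items():
                if role == "hk" or t not in {c.removeprefix("log2_effect_") for c in eff_cols}:
                    delta = 0.0
                else:
                    delta = float(truth.genes.loc[g, f"log2_effect_{t}"])
                ct = ct0 - (delta * math.log(2.0)) / log_e
                if ct_noise_sd > 0:
                    ct += rng.normal(0.0, ct_noise_sd)
                rows.append((s, g, role, ct))
    return pd.DataFrame(rows, columns=["sample_id", "gene_id", "role", "ct"])
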