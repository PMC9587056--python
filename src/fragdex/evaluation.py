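"""Synthetic-data validation studies for the complete workflow.

Each study generates a dataset under the emulated study design, runs the
relevant pipeline stages, and measures how well the known ground truth
is recovered: reference-gene selection specificity, differential-
expression power and direction, the down:up call balance, and qPCR
fold-change recovery.  These functions back both the test suite and the
reproduction script; all randomness flows from one integer seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import compare, curation, de_collapsed, de_nonparametric, normalization
from .refpanel import SELF_CONSISTENT_ROWS, candidate_panel
from .simulate import (
    SimulationConfig,
    generate_alignment_hits,
    generate_counts,
    generate_design,
    generate_qpcr,
)


def reference_panel_checks(cv_max: float = 20.0) -> dict:
    """Recompute CV% from the panel's printed mean/SD and apply the
    selection rule."""
    panel = candidate_panel()
    out = {}
    for name in SELF_CONSISTENT_ROWS:
        cv = normalization.cv_percent(panel.loc[name, "sd"], panel.loc[name, "mean"])
        out[f"cv_{name}"] = round(float(cv), 2)
    selected = normalization.select_hk(panel, cv_max)
    out["n_selected"] = len(selected)
    out["excluded"] = sorted(set(panel.index) - set(selected))
    out["n_candidates"] = len(panel)
    return out


def annotation_confirmation_study(seed: int, n_fragments: int = 225,
                                  confirm_rate: float = 0.938) -> dict:
    """Best-hit confirmation rate on a synthetic single-fragment panel."""
    cfg = SimulationConfig(n_genes=n_fragments, fragments_per_gene=(1, 1), seed=seed)
    counts, _ = generate_counts(generate_design(cfg), cfg)
    hits = generate_alignment_hits(counts, confirm_rate, cfg)
    report = curation.confirm_annotation(hits, counts[["gene_id", "group_tag"]])
    return {
        "confirmed_pct": round(100.0 * report.funnel["confirmed"]
                               / report.funnel["total"], 1),
        "n_fragments": report.funnel["total"],
    }


def _generate_and_curate(cfg: SimulationConfig, confirm_rate: float = 0.938):
    design = generate_design(cfg)
    counts, truth = generate_counts(design, cfg)
    tmm, factors = normalization.tmm_normalize(counts)
    hits = generate_alignment_hits(counts, confirm_rate, cfg)
    report = curation.curate(hits, tmm, design)
    accepted = list(report.statuses.index[report.statuses == curation.STATUS_ACCEPTED])
    return design, counts, truth, tmm, factors, accepted


def _panel_min_cv(tmm: pd.DataFrame, accepted: list[str]) -> pd.Series:
    """Minimum fragment CV% per candidate-panel gene (best representative
    transcript), over accepted fragments of genes tagged 'A'."""
    meta = tmm[["gene_id", "group_tag"]]
    panel_frags = [f for f in accepted if meta.loc[f, "group_tag"] == "A"]
    stats = normalization.hk_stats(tmm, panel_frags)
    return stats["cv_percent"].groupby(meta.loc[panel_frags, "gene_id"]).min()


def hk_selection_study(seed: int, n_genes: int = 2000, cv_max: float = 20.0) -> dict:
    """Recovery of designated HK genes vs admission of responsive decoys.

    The candidate panel (group tag 'A') holds the true HK genes plus an
    equal number of treatment-responsive decoys; a gene is selected when
    its most stable accepted fragment passes CV% < ``cv_max``.
    """
    cfg = SimulationConfig(n_genes=n_genes, seed=seed)
    _, _, truth, tmm, _, accepted = _generate_and_curate(cfg)
    min_cv = _panel_min_cv(tmm, accepted)
    hk = set(truth.hk_gene_ids)
    panel_genes = set(truth.genes.index[truth.genes["group_tag"] == "A"])
    decoys = panel_genes - hk
    selected = set(min_cv.index[min_cv < cv_max])
    return {
        "recovery_pct": round(100.0 * len(selected & hk) / len(hk), 1),
        "false_admission_pct": round(100.0 * len(selected & decoys) / len(decoys), 1),
        "n_hk": len(hk),
        "n_decoys": len(decoys),
    }


def _standardized(tmm, design, accepted, cv_max=20.0):
    min_cv = _panel_min_cv(tmm, accepted)
    meta = tmm[["gene_id", "group_tag"]]
    panel_frags = [f for f in accepted if meta.loc[f, "group_tag"] == "A"]
    stats = normalization.hk_stats(tmm, panel_frags)
    hk_frags = normalization.select_hk(stats, cv_max)
    _, std, _ = normalization.standardize(tmm, hk_frags, design)
    return std


def effect_recovery_study(seed: int, n_genes: int = 2000,
                          effect_log2: float = 2.0, n_perm: int = 5000) -> dict:
    """Detection of planted 4-fold effects with correct direction.

    Effects are pinned at |log2FC| = ``effect_log2`` under the otherwise
    default design; a gene x pair cell counts as recovered when the
    collapsed-NB path calls it in the right direction, or (failing that)
    the nonparametric pairwise test reaches p <= 0.10 with the right
    sign of R - 1.
    """
    cfg = SimulationConfig(n_genes=n_genes, seed=seed,
                           effect_log2_range=(effect_log2, effect_log2))
    design, counts, truth, tmm, factors, accepted = _generate_and_curate(cfg)
    nb = de_collapsed.call_degs(de_collapsed.nb_analyze(counts, design, factors))
    nb_call = nb.set_index(["gene_id", "comparison"])["call"]

    treatments = [t for t in cfg.treatments if t != cfg.control]
    affected = truth.affected_gene_ids()
    eff = truth.genes.loc[affected]

    pending: dict[str, list[str]] = {}
    correct = 0
    total = len(affected) * len(treatments)
    for g in affected:
        for t in treatments:
            want = "up" if eff.loc[g, f"log2_effect_{t}"] > 0 else "down"
            if nb_call.get((g, t), "none") == want:
                correct += 1
            else:
                pending.setdefault(g, []).append(t)

    if pending:
        std = _standardized(tmm, design, accepted)
        np_res = de_nonparametric.analyze_genes(
            std, design, accepted, n_perm=n_perm, seed=seed,
            genes=sorted(pending))
        for g, ts in pending.items():
            if g not in np_res.index:
                continue
            for t in ts:
                p = float(np_res.loc[g, f"p_{t}"])
                r = float(np_res.loc[g, f"R_{t}"])
                want_up = eff.loc[g, f"log2_effect_{t}"] > 0
                if p <= 0.10 and ((r > 1.0) == want_up):
                    correct += 1
    return {
        "detection_pct": round(100.0 * correct / total, 1),
        "n_cells": total,
        "n_genes_affected": len(affected),
    }


def down_up_ratio_study(seed: int, n_genes: int = 2000, n_perm: int = 5000) -> dict:
    """Observed down:up call balance among genes with planted effects
    under the default 3:1 simulation, plus direction agreement."""
    cfg = SimulationConfig(n_genes=n_genes, seed=seed)
    design, _, truth, tmm, _, accepted = _generate_and_curate(cfg)
    std = _standardized(tmm, design, accepted)
    affected = truth.affected_gene_ids()
    np_res = de_nonparametric.analyze_genes(
        std, design, accepted, n_perm=n_perm, seed=seed, genes=affected)
    heat = compare.heatmap_table(np_res)

    # direction agreement among tendency-or-better pairwise calls
    treatments = [t for t in cfg.treatments if t != cfg.control]
    match = called = 0
    for g in np_res.index:
        for t in treatments:
            if float(np_res.loc[g, f"p_{t}"]) <= 0.10:
                called += 1
                r = float(np_res.loc[g, f"R_{t}"])
                want_up = truth.genes.loc[g, f"log2_effect_{t}"] > 0
                match += int((r > 1.0) == want_up)
    return {
        "down_up_ratio": round(heat.down_up_ratio, 2),
        "n_down": heat.n_down,
        "n_up": heat.n_up,
        "direction_agreement_pct": round(100.0 * match / called, 1) if called else None,
        "n_called": called,
    }


def qpcr_recovery_study(seed: int, n_sims: int = 100, ct_noise_sd: float = 0.2) -> dict:
    """Fold-change recovery from simulated Ct tables.

    Noise-free tables must invert exactly; under Ct noise the median
    estimate over ``n_sims`` replicate assays is compared to the planted
    fold change per gene x treatment.
    """
    planted = {"amd1_like": np.log2(3.0), "sodc_like": -0.5, "weak_like": 0.3}
    hk = ("hk_actb_like", "hk_rl8_like")
    cfg0 = SimulationConfig(seed=seed)
    treatments = [t for t in cfg0.treatments if t != cfg0.control]
    genes = list(planted) + list(hk)
    frame = pd.DataFrame(
        {"group_tag": ["B"] * len(planted) + ["A"] * len(hk),
         "is_hk": [False] * len(planted) + [True] * len(hk)},
        index=pd.Index(genes, name="gene_id"),
    )
    for t in treatments:
        frame[f"log2_effect_{t}"] = [planted[g] for g in planted] + [0.0] * len(hk)
    from .simulate import TruthTable
    truth = TruthTable(genes=frame)
    from .qpcr import relative_expression

    design = generate_design(cfg0)
    ct0 = generate_qpcr(design, truth, ct_noise_sd=0.0, config=cfg0,
                        target_genes=list(planted), hk_genes=list(hk))
    fc0 = relative_expression(ct0, design).fold_change
    err0 = max(
        abs(fc0.loc[g, t] - 2.0 ** planted[g]) for g in planted for t in treatments
    )

    ratios = {g: [] for g in planted}
    for i in range(n_sims):
        cfg = SimulationConfig(seed=(seed * 100_003 + i) % 2**31)
        ct = generate_qpcr(design, truth, ct_noise_sd=ct_noise_sd, config=cfg,
                           target_genes=list(planted), hk_genes=list(hk))
        fc = relative_expression(ct, design).fold_change
        for g in planted:
            for t in treatments:
                ratios[g].append(fc.loc[g, t] / 2.0 ** planted[g])
    median_err_pct = max(
        100.0 * abs(float(np.median(r)) - 1.0) for r in ratios.values()
    )
    return {
        "noise_free_max_abs_error": float(err0),
        "noisy_median_error_pct": round(median_err_pct, 2),
        "n_sims": n_sims,
    }
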