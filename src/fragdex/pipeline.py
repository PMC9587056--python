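"""End-to-end workflow orchestration with a reproducibility manifest.

Runs the stages in dependency order -- simulate (optional), curate,
normalize, housekeeping selection, standardization, nonparametric and
collapsed-NB differential expression, concordance/heat-map summaries,
and qPCR -- from one flat configuration, writing every artifact as TSV
or JSON plus a manifest holding parameter values and SHA-256 checksums
of all outputs.  Identical configuration and seed yield identical
checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import compare, curation, de_collapsed, de_nonparametric, normalization, qpcr
from ._frames import ConfigurationError, DataError, read_tsv, split_meta
from .simulate import (
    SimulationConfig,
    generate_alignment_hits,
    generate_counts,
    generate_design,
    generate_qpcr,
)

log = logging.getLogger("fragdex.pipeline")

MODES = ("simulate+analyze", "analyze-only")


@dataclass
class PipelineConfig:
    """Flat configuration covering all stages; CLI flags mirror these keys."""

    outdir: str = "fragdex_run"
    mode: str = "simulate+analyze"
    seed: int = 0
    # analyze-only inputs
    counts_path: str | None = None
    design_path: str | None = None
    hits_path: str | None = None
    ct_path: str | None = None
    # simulation
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    confirm_rate: float = 0.938
    qpcr_efficiency: float = 2.0
    qpcr_ct_noise_sd: float = 0.2
    # curation
    min_match: float = 50.0
    low_floor: float = 5.0
    erratic_cv: float = 50.0
    # normalization / HK
    trim_m: float = 0.30
    trim_a: float = 0.05
    cv_max: float = 20.0
    hk_group_tag: str = "A"
    per_treatment_factors: bool = False
    # testing
    control: str = "control"
    alpha: float = 0.05
    tendency: float = 0.10
    exact_limit: int = 10
    n_perm: int = 10_000
    fc_threshold: float = 2.0
    p_max: float = 0.05
    prior_count: float = 0.5

    def validate(self) -> None:
        if self.mode not in MODES:
            raise ConfigurationError(f"mode must be one of {MODES}")
        self.simulation.validate()
        if self.mode == "analyze-only":
            for name in ("counts_path", "design_path", "hits_path"):
                path = getattr(self, name)
                if path is None:
                    raise ConfigurationError(f"{name} is required in analyze-only mode")
                if not Path(path).is_file():
                    raise ConfigurationError(f"{name} does not exist: {path}")
            if self.ct_path is not None and not Path(self.ct_path).is_file():
                raise ConfigurationError(f"ct_path does not exist: {self.ct_path}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim_fields = {f.name for f in dataclasses.fields(SimulationConfig)}
        own_fields = {f.name for f in dataclasses.fields(cls)} - {"simulation"}
        sim_kw, own_kw = {}, {}
        for key, value in raw.items():
            if key in own_fields:
                own_kw[key] = value
            elif key in sim_fields:
                if isinstance(value, list):
                    value = tuple(value)
                sim_kw[key] = value
            else:
                raise ConfigurationError(f"unknown configuration key: {key}")
        seed = own_kw.get("seed", 0)
        sim_kw.setdefault("seed", seed)
        return cls(simulation=SimulationConfig(**sim_kw), **own_kw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _Run:
    def __init__(self, outdir: Path):
        self.outdir = outdir
        self.stages: dict[str, dict[str, str]] = {}

    def emit(self, stage: str, name: str, obj) -> Path:
        path = self.outdir / name
        if isinstance(obj, pd.DataFrame):
            obj.to_csv(path, sep="\t")
        elif isinstance(obj, pd.Series):
            obj.to_frame().to_csv(path, sep="\t")
        elif isinstance(obj, (dict, list)):
            path.write_text(json.dumps(obj, indent=2, default=str) + "\n")
        else:
            path.write_text(str(obj))
        self.stages.setdefault(stage, {})[name] = _sha256(path)
        log.info("[%s] wrote %s", stage, path.name)
        return path


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; return (and write) the run manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    run = _Run(outdir)
    sim = config.simulation

    # --- inputs ---------------------------------------------------------
    if config.mode == "simulate+analyze":
        design = generate_design(sim)
        counts, truth = generate_counts(design, sim)
        hits = generate_alignment_hits(counts, config.confirm_rate, sim)
        ct = generate_qpcr(design, truth, config.qpcr_efficiency,
                           config.qpcr_ct_noise_sd, sim)
        run.emit("simulate", "design.tsv", design)
        run.emit("simulate", "counts.tsv", counts)
        run.emit("simulate", "truth.tsv", truth.genes)
        run.emit("simulate", "bad_fragments.txt", "\n".join(truth.bad_fragment_ids) + "\n")
        hits.to_csv(outdir / "hits.tsv", sep="\t", index=False, header=False)
        run.stages["simulate"]["hits.tsv"] = _sha256(outdir / "hits.tsv")
        run.emit("simulate", "qpcr_ct.tsv", ct.set_index("sample_id"))
    else:
        design = read_tsv(config.design_path)
        counts = read_tsv(config.counts_path)
        hits = curation.read_hits(config.hits_path)
        ct = read_tsv(config.ct_path).reset_index() if config.ct_path else None

    # --- normalization (needed by the curation expression stage) --------
    tmm, factors = normalization.tmm_normalize(counts, config.trim_m, config.trim_a)
    run.emit("normalize", "tmm_factors.tsv", factors)
    run.emit("normalize", "tmm.tsv", tmm)

    # --- curation funnel ------------------------------------------------
    report = curation.curate(hits, tmm, design, config.min_match,
                             config.low_floor, config.erratic_cv)
    run.emit("curate", "curation_report.tsv", report.statuses.to_frame())
    run.emit("curate", "curation_summary.json",
             {"funnel": report.funnel,
              "per_group": report.per_group.round(4).to_dict(orient="index")})
    accepted = list(report.statuses.index[report.statuses == curation.STATUS_ACCEPTED])
    if not accepted:
        raise DataError("curation accepted no fragments; cannot continue")

    # --- housekeeping selection -----------------------------------------
    meta, _ = split_meta(tmm)
    candidates = [f for f in accepted if meta.loc[f, "group_tag"] == config.hk_group_tag]
    if not candidates:
        raise DataError(f"no accepted fragments in HK panel group "
                        f"{config.hk_group_tag!r}")
    stats = normalization.hk_stats(tmm, candidates)
    hk = normalization.select_hk(stats, config.cv_max)
    run.emit("hk", "hk_stats.tsv", stats)
    run.emit("hk", "hk_selected.txt", "\n".join(hk) + "\n")
    if not hk:
        raise DataError("no transcript passed the CV% ceiling; "
                        "standardization refuses to run")

    # --- standardization -------------------------------------------------
    info, standardized, relative = normalization.standardize(
        tmm, hk, design, config.control, config.per_treatment_factors)
    run.emit("standardize", "standardization_factors.tsv", info.per_sample)
    run.emit("standardize", "standardized.tsv", standardized)
    run.emit("standardize", "relative.tsv", relative)

    # --- nonparametric DE on the hypothesis-selected pathway genes ------
    pathway_genes = sorted(
        meta.loc[accepted].query("group_tag in ('B', 'C', 'D', 'E')")["gene_id"].unique()
    )
    np_results = de_nonparametric.analyze_genes(
        standardized, design, accepted, config.control, config.alpha,
        config.tendency, config.exact_limit, config.n_perm, config.seed,
        genes=pathway_genes or None,
    )
    run.emit("detest_np", "de_nonparametric.tsv", np_results)

    # --- collapsed NB DE on the raw, unfiltered matrix -------------------
    nb_raw = de_collapsed.nb_analyze(
        counts, design, factors, config.control,
        prior_count=config.prior_count)
    nb_results = de_collapsed.rank_degs(
        de_collapsed.call_degs(nb_raw, config.fc_threshold, config.p_max))
    run.emit("detest_nb", "de_collapsed.tsv", nb_results.set_index("gene_id"))

    # --- concordance and heat map ---------------------------------------
    if not np_results.empty:
        conc = compare.compare_calls(np_results, nb_results,
                                     alpha=config.alpha, tendency=config.tendency)
        run.emit("compare", "concordance.tsv", conc.cells)
        run.emit("compare", "concordance_summary.json",
                 {"percent_overall": round(conc.percent_overall, 4),
                  "percent_by_pair": conc.percent_by_pair.round(4).to_dict(),
                  "histogram": {str(k): int(v) for k, v in conc.histogram.items()}})
        heat = compare.heatmap_table(np_results)
        run.emit("compare", "heatmap.tsv", heat.matrix)
        run.emit("compare", "heatmap_summary.json", compare.heatmap_export(heat))

    # --- qPCR ------------------------------------------------------------
    if ct is not None:
        qres = qpcr.relative_expression(ct, design, efficiency=config.qpcr_efficiency,
                                        control=config.control)
        run.emit("qpcr", "qpcr_fold_change.tsv", qres.fold_change)

    manifest = {
        "mode": config.mode,
        "seed": config.seed,
        "parameters": {
            **{k: v for k, v in dataclasses.asdict(config).items()
               if k != "simulation"},
            "simulation": dataclasses.asdict(sim),
        },
        "stages": run.stages,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    log.info("[pipeline] manifest written with %d stages", len(run.stages))
    return manifest
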