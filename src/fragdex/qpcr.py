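"""Geometric-mean housekeeping normalization of qPCR Ct data.

Quantities are reconstructed from quantification cycles as
Q_{g,s} = E_g^(-Ct_{g,s}) with per-gene amplification efficiency E
(default 2.0, i.e. perfect doubling); each sample is divided by the
geometric mean of its housekeeping quantities, and fold changes per
treatment are ratios of geometric means of the normalized quantities
against the control group.  With a single housekeeping gene and E = 2
this reduces to the classic 2^-ddCt method.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._frames import DataError


@dataclass
class QpcrResult:
    rq: pd.DataFrame           # gene x sample normalized relative quantity
    fold_change: pd.DataFrame  # gene x treatment FC vs control


def _geometric_mean(values: np.ndarray) -> float:
    return float(np.exp(np.mean(np.log(values))))


def relative_expression(
    ct: pd.DataFrame,
    design: pd.DataFrame,
    hk_genes: list[str] | None = None,
    efficiency: float | dict[str, float] = 2.0,
    control: str = "control",
    replicate_geometric: bool = True,
) -> QpcrResult:
    """Per-sample normalized quantities and per-treatment fold changes.

    ``ct`` rows: (sample_id, gene_id, role, ct); technical replicates of
    one (sample, gene) are averaged on the Ct scale first.  ``efficiency``
    may be a scalar or a per-gene mapping; values must exceed 1.
    ``replicate_geometric`` selects geometric (default) or arithmetic
    pooling of replicates within a treatment.
    """
    required = {"sample_id", "gene_id", "ct"}
    if not required.issubset(ct.columns):
        raise DataError(f"Ct table needs columns {sorted(required)}")
    if (ct["ct"] <= 0).any():
        raise DataError("Ct values must be positive")
    if hk_genes is None:
        if "role" not in ct.columns:
            raise DataError("no HK genes given and no role column present")
        hk_genes = sorted(ct.loc[ct["role"] == "hk", "gene_id"].unique())
    if not hk_genes:
        raise DataError("need at least one HK gene")

    # average technical replicates on the Ct scale
    wide = ct.groupby(["gene_id", "sample_id"])["ct"].mean().unstack("sample_id")

    def eff_of(gene: str) -> float:
        e = efficiency.get(gene, 2.0) if isinstance(efficiency, dict) else efficiency
        if e <= 1.0:
            raise DataError(f"amplification efficiency for {gene} must exceed 1")
        return float(e)

    samples = list(wide.columns)
    for h in hk_genes:
        if h not in wide.index:
            raise DataError(f"HK gene {h} absent from the Ct table")
        missing = wide.loc[h].index[wide.loc[h].isna()]
        if len(missing):
            raise DataError(f"HK gene {h} lacks a Ct in sample(s) {list(missing)}")

    eff = pd.Series({g: eff_of(g) for g in wide.index})
    quantity = pd.DataFrame(
        np.power(eff.to_numpy()[:, None], -wide.to_numpy()),
        index=wide.index, columns=samples,
    )
    nf = quantity.loc[hk_genes].apply(lambda col: _geometric_mean(col.to_numpy()), axis=0)
    rq = quantity.div(nf, axis=1)

    if control not in set(design["treatment"]):
        raise DataError(f"control group {control!r} missing from design")
    pooled = {}
    for t, sub in design.groupby("treatment", sort=True):
        cols = [s for s in sub.index if s in rq.columns]
        if not cols:
            continue
        block = rq[cols]
        if replicate_geometric:
            pooled[t] = np.exp(np.log(block).mean(axis=1))
        else:
            pooled[t] = block.mean(axis=1)
    pooled = pd.DataFrame(pooled)
    fc = pooled.div(pooled[control], axis=0)
    return QpcrResult(rq=rq, fold_change=fc)
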