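"""Weighted Expression (WE) scoring: expression matrix -> per-pathway scores.

The WE score summarizes transcriptional regulation of a DDR pathway in one
number per sample.  For pathway *P* and sample *s*:

    raw_WE(P, s) = sum_{g in P} esf_g * z(g, s) / n_P

where ``z(g, s)`` is the gene's expression z-score across samples and
``esf_g`` its essentiality scaling factor.  Raw scores are then scaled
(row-standardized) across samples so pathways share a common scale.

Z-scoring uses the sample standard deviation (ddof=1).  TPM input is
log2(TPM+1)-transformed by default before z-scoring; matrices already in
z-score units pass through unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import DDRPanel

__all__ = [
    "ExpressionMatrix",
    "ZMatrix",
    "WEScoreMatrix",
    "SignatureDefinition",
    "to_log_scale",
    "zscore_genes",
    "raw_we_scores",
    "scale_we_scores",
    "we_score_pipeline",
    "signature_score",
]

_UNITS = ("TPM", "log2TPM", "zscore")


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with declared units.

    ``units`` is one of ``TPM`` (non-negative), ``log2TPM``, or ``zscore``
    (pre-standardized rows, passed through the z-step untouched).
    """

    values: pd.DataFrame
    units: str = "TPM"

    def __post_init__(self) -> None:
        if self.units not in _UNITS:
            raise ValueError(f"units must be one of {_UNITS}, got {self.units!r}")
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene labels: {dup[:5]}")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample labels: {dup[:5]}")
        if self.units == "TPM" and (self.values.to_numpy() < 0).any():
            raise ValueError("TPM matrix contains negative values")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class ZMatrix:
    """Per-gene z-scores across samples, plus transform provenance."""

    values: pd.DataFrame
    provenance: dict = field(default_factory=dict)
    degenerate_genes: tuple[str, ...] = ()


@dataclass
class WEScoreMatrix:
    """Pathways x samples WE scores, raw and (optionally) scaled."""

    raw: pd.DataFrame
    scaled: pd.DataFrame | None = None
    n_genes_used: pd.Series | None = None
    unmatched_genes: tuple[str, ...] = ()


@dataclass(frozen=True)
class SignatureDefinition:
    """A named weighted gene signature; weight sign encodes direction."""

    name: str
    weights: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.weights:
            raise ValueError(f"signature {self.name!r}: needs at least one gene")
        w = np.asarray(list(self.weights.values()), dtype=float)
        if not np.isfinite(w).all():
            raise ValueError(f"signature {self.name!r}: non-finite weight")
        if np.all(w == 0):
            raise ValueError(f"signature {self.name!r}: weights are all zero")


def to_log_scale(expr: ExpressionMatrix) -> ExpressionMatrix:
    """log2(TPM + 1) transform; no-op (with a warning) on log2TPM input."""
    if expr.units == "log2TPM":
        warnings.warn("input already log2TPM; to_log_scale is a no-op", stacklevel=2)
        return expr
    if expr.units != "TPM":
        raise ValueError(f"cannot log-transform units={expr.units!r}")
    return ExpressionMatrix(values=np.log2(expr.values + 1.0), units="log2TPM")


def zscore_genes(expr: ExpressionMatrix, log_transform: bool = True) -> ZMatrix:
    """Row-wise (per-gene) standardization across samples, ddof=1.

    TPM input is log2(TPM+1)-transformed first unless ``log_transform`` is
    False.  Constant genes become all-zero rows and are listed in
    ``degenerate_genes``.  Input declared as ``zscore`` passes through.
    """
    if expr.n_samples < 2:
        raise ValueError("z-scoring requires at least 2 samples")
    vals = expr.values
    if vals.isna().any().any():
        gi, sj = np.argwhere(vals.isna().to_numpy())[0]
        raise ValueError(
            f"NaN in expression matrix at gene={vals.index[gi]}, "
            f"sample={vals.columns[sj]}"
        )
    if expr.units == "zscore":
        return ZMatrix(values=vals.copy(), provenance={"transform": "passthrough"})

    transform = "none"
    if expr.units == "TPM" and log_transform:
        vals = np.log2(vals + 1.0)
        transform = "log2(TPM+1)"
    x = vals.to_numpy(dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    degenerate = sd[:, 0] == 0
    sd[degenerate] = 1.0
    z = (x - mu) / sd
    z[degenerate] = 0.0
    return ZMatrix(
        values=pd.DataFrame(z, index=vals.index, columns=vals.columns),
        provenance={"transform": transform, "ddof": 1},
        degenerate_genes=tuple(vals.index[degenerate]),
    )


def raw_we_scores(
    z: ZMatrix, panel: DDRPanel, strict_denominator: bool = False
) -> WEScoreMatrix:
    """ESF-weighted per-pathway mean of gene z-scores.

    For each retained pathway: sum of esf*z over panel genes found in the
    data, divided by the number of matched genes (or by the full pathway
    size when ``strict_denominator`` is True).  Pathways with no matched
    genes are dropped with a warning.
    """
    data_genes = set(z.values.index)
    rows: dict[str, np.ndarray] = {}
    n_used: dict[str, int] = {}
    unmatched: list[str] = []
    for pathway in panel.pathways:
        genes = panel.genes_in(pathway)
        present = [g for g in genes if g in data_genes]
        unmatched.extend(g for g in genes if g not in data_genes)
        if not present:
            warnings.warn(
                f"pathway {pathway}: no panel genes found in the data; dropped",
                stacklevel=2,
            )
            continue
        esf = np.array([panel.esf_map()[g] for g in present])
        sub = z.values.loc[present].to_numpy(dtype=float)
        denom = len(genes) if strict_denominator else len(present)
        rows[pathway] = esf @ sub / denom
        n_used[pathway] = len(present)
    if not rows:
        raise ValueError("no panel genes found in the expression data for any pathway")
    raw = pd.DataFrame(rows, index=z.values.columns).T
    raw.index.name = "pathway"
    return WEScoreMatrix(
        raw=raw,
        n_genes_used=pd.Series(n_used, name="n_genes_used"),
        unmatched_genes=tuple(unmatched),
    )


def scale_we_scores(we: WEScoreMatrix) -> WEScoreMatrix:
    """Standardize each pathway row across samples (mean 0, sample SD 1)."""
    if we.raw.shape[1] < 2:
        raise ValueError("scaling requires at least 2 samples")
    x = we.raw.to_numpy(dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    constant = sd[:, 0] == 0
    if constant.any():
        warnings.warn(
            f"constant WE score row(s) scaled to zeros: "
            f"{list(we.raw.index[constant])}",
            stacklevel=2,
        )
    sd[constant] = 1.0
    scaled = (x - mu) / sd
    scaled[constant] = 0.0
    return WEScoreMatrix(
        raw=we.raw,
        scaled=pd.DataFrame(scaled, index=we.raw.index, columns=we.raw.columns),
        n_genes_used=we.n_genes_used,
        unmatched_genes=we.unmatched_genes,
    )


def we_score_pipeline(
    expr: ExpressionMatrix,
    panel: DDRPanel,
    log_transform: bool = True,
    strict_denominator: bool = False,
) -> tuple[ZMatrix, WEScoreMatrix]:
    """Convenience composition: z-score -> raw WE -> scaled WE."""
    z = zscore_genes(expr, log_transform=log_transform)
    we = raw_we_scores(z, panel, strict_denominator=strict_denominator)
    return z, scale_we_scores(we)


def signature_score(z: ZMatrix, signature: SignatureDefinition) -> pd.Series:
    """Generic weighted-mean signature score per sample.

    score(s) = sum_g w_g * z[g, s] / sum_g |w_g| over signature genes found
    in the data.  This is a generic stand-in for published weighted
    signatures (e.g. replication-stress or neuroendocrine scores); it does
    not reproduce correlation-based scoring schemes.
    """
    present = [g for g in signature.weights if g in z.values.index]
    if not present:
        raise ValueError(
            f"signature {signature.name!r}: no genes overlap the expression data"
        )
    missing = [g for g in signature.weights if g not in z.values.index]
    if missing:
        warnings.warn(
            f"signature {signature.name!r}: {len(missing)} gene(s) missing from "
            f"the data: {missing[:5]}",
            stacklevel=2,
        )
    w = np.array([signature.weights[g] for g in present])
    sub = z.values.loc[present].to_numpy(dtype=float)
    scores = w @ sub / np.abs(w).sum()
    return pd.Series(scores, index=z.values.columns, name=signature.name)
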