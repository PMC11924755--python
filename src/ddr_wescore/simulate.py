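"""Synthetic SCLC-like expression cohorts with planted DDR cluster structure.

The generator produces the statistical structure the scoring and
clustering pipeline assumes, without any real data:

* three (by default) planted clusters realized as per-pathway mean shifts
  of panel-gene expression in log2 space — the Low cluster is shifted down
  on all pathways, High up on all, and Intermediate up on a deterministic
  half of the pathways (a hybrid signature);
* cluster-dependent SCLC subtype label frequencies (SCLC-N enriched in
  High, SCLC-A in Intermediate, SCLC-P/SCLC-I in Low);
* a monotone neuroendocrine-like continuous covariate increasing with
  cluster rank;
* background genes with no cluster effect, and i.i.d. Gaussian noise on
  every latent log2 value, mapped to TPM via 2^x - 1 floored at zero.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .associations import ContingencyTable, contingency
from .panel import DDRPanel, load_default_panel
from .scoring import ExpressionMatrix

__all__ = ["CohortSpec", "SyntheticCohort", "generate_cohort", "truth_tables",
           "SUBTYPES", "default_subtype_probs", "default_pathway_effects"]

SUBTYPES = ("SCLC-A", "SCLC-N", "SCLC-P", "SCLC-I")


def default_pathway_effects(pathways: tuple[str, ...], delta: float = 1.5) -> pd.DataFrame:
    """Cluster x pathway mean shifts (z-units, log2 space).

    Low = -delta everywhere; Intermediate = +delta on the first half of the
    pathways (deterministic, panel order); High = +delta everywhere.
    """
    n = len(pathways)
    eff = pd.DataFrame(0.0, index=["Low", "Intermediate", "High"], columns=list(pathways))
    eff.loc["Low"] = -delta
    eff.loc["High"] = delta
    eff.loc["Intermediate", list(pathways[: n // 2])] = delta
    return eff


def default_subtype_probs() -> pd.DataFrame:
    """Cluster-conditional subtype frequencies encoding the enrichment pattern
    SCLC-N high in High, SCLC-A high in Intermediate, SCLC-P/I high in Low."""
    return pd.DataFrame(
        [
            [0.20, 0.10, 0.35, 0.35],  # Low
            [0.60, 0.15, 0.125, 0.125],  # Intermediate
            [0.20, 0.60, 0.10, 0.10],  # High
        ],
        index=["Low", "Intermediate", "High"],
        columns=list(SUBTYPES),
    )


@dataclass
class CohortSpec:
    """Parameters of a synthetic cohort.

    Defaults give a 120-sample cohort with three equiprobable planted
    clusters separated by delta = 1.5 z-units per affected pathway on top
    of unit Gaussian noise, 500 background genes, subtype frequencies
    encoding the canonical enrichment pattern, and a covariate rising one
    unit per cluster rank.
    """

    n_samples: int = 120
    planted_clusters: int = 3
    cluster_proportions: np.ndarray | None = None
    pathway_effects: pd.DataFrame | None = None
    delta: float = 1.5
    n_background_genes: int = 500
    noise_sd: float = 1.0
    subtype_probs: pd.DataFrame | None = None
    covariate_slope: float = 1.0
    seed: int = 0
    panel: DDRPanel | None = None

    def __post_init__(self) -> None:
        if self.panel is None:
            self.panel = load_default_panel(warn=False)
        if self.cluster_proportions is None:
            self.cluster_proportions = np.full(
                self.planted_clusters, 1.0 / self.planted_clusters
            )
        self.cluster_proportions = np.asarray(self.cluster_proportions, dtype=float)
        if len(self.cluster_proportions) != self.planted_clusters:
            raise ValueError("cluster_proportions length != planted_clusters")
        if abs(self.cluster_proportions.sum() - 1.0) > 1e-12:
            raise ValueError("cluster_proportions must sum to 1")
        if self.pathway_effects is None:
            if self.planted_clusters != 3:
                raise ValueError(
                    "default pathway_effects assume 3 clusters; supply a "
                    "planted_clusters x pathways effects matrix"
                )
            self.pathway_effects = default_pathway_effects(
                self.panel.pathways, self.delta
            )
        if self.pathway_effects.shape[0] != self.planted_clusters:
            raise ValueError("pathway_effects rows != planted_clusters")
        if self.subtype_probs is None:
            if self.planted_clusters == 3:
                self.subtype_probs = default_subtype_probs()
            else:
                self.subtype_probs = pd.DataFrame(
                    np.full((self.planted_clusters, len(SUBTYPES)), 1 / len(SUBTYPES)),
                    index=self.pathway_effects.index,
                    columns=list(SUBTYPES),
                )
        if not np.allclose(self.subtype_probs.sum(axis=1), 1.0):
            raise ValueError("each subtype_probs row must sum to 1")
        if not (self.noise_sd > 0):
            raise ValueError("noise_sd must be positive")
        if self.n_samples < 3 * self.planted_clusters:
            raise ValueError("n_samples must be >= 3 x planted_clusters")


@dataclass
class SyntheticCohort:
    """A generated cohort plus its ground truth."""

    expression: ExpressionMatrix
    truth_clusters: pd.Series
    truth_subtypes: pd.Series
    truth_covariate: pd.Series
    spec: CohortSpec


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Draw one cohort from the spec; bit-identical under a fixed seed."""
    rng = np.random.default_rng(spec.seed)
    panel = spec.panel
    cluster_names = list(spec.pathway_effects.index)

    members = rng.choice(
        spec.planted_clusters, size=spec.n_samples, p=spec.cluster_proportions
    )
    if len(np.unique(members)) < spec.planted_clusters:
        raise ValueError(
            "a planted cluster received no samples; increase n_samples or "
            "rebalance cluster_proportions"
        )
    sample_ids = [f"S{i:03d}" for i in range(spec.n_samples)]

    panel_genes = list(panel.genes)
    bg_genes = [f"BG{i:04d}" for i in range(spec.n_background_genes)]
    all_genes = panel_genes + bg_genes
    n_genes = len(all_genes)

    # per-gene baseline in log2 space, typical RNA-seq dynamic range
    baseline = rng.normal(5.0, 2.0, size=n_genes)

    effect = np.zeros((n_genes, spec.n_samples))
    pw_map = panel.pathway_map()
    eff_mat = spec.pathway_effects.to_numpy()
    pw_index = {p: j for j, p in enumerate(spec.pathway_effects.columns)}
    for gi, g in enumerate(panel_genes):
        j = pw_index[pw_map[g]]
        effect[gi] = eff_mat[members, j]

    latent = baseline[:, None] + effect + rng.normal(
        0.0, spec.noise_sd, size=(n_genes, spec.n_samples)
    )
    tpm = np.maximum(np.exp2(latent) - 1.0, 0.0)
    expr = ExpressionMatrix(
        values=pd.DataFrame(tpm, index=all_genes, columns=sample_ids), units="TPM"
    )

    probs = spec.subtype_probs.to_numpy()
    subtype_idx = np.array(
        [rng.choice(len(SUBTYPES), p=probs[c]) for c in members]
    )
    covariate = spec.covariate_slope * members + rng.normal(0.0, 1.0, spec.n_samples)

    idx = pd.Index(sample_ids, name="sample")
    return SyntheticCohort(
        expression=expr,
        truth_clusters=pd.Series(
            [cluster_names[c] for c in members], index=idx, name="truth_cluster"
        ),
        truth_subtypes=pd.Series(
            [SUBTYPES[i] for i in subtype_idx], index=idx, name="truth_subtype"
        ),
        truth_covariate=pd.Series(covariate, index=idx, name="truth_covariate"),
        spec=spec,
    )


def truth_tables(cohort: SyntheticCohort) -> tuple[ContingencyTable, pd.DataFrame]:
    """Ground-truth cluster x subtype table and covariate-by-cluster medians."""
    tab = contingency(cohort.truth_clusters, cohort.truth_subtypes)
    med = (
        pd.DataFrame(
            {
                "cluster": cohort.truth_clusters,
                "covariate": cohort.truth_covariate,
            }
        )
        .groupby("cluster", sort=False)["covariate"]
        .agg(n="size", median="median", q1=lambda s: s.quantile(0.25),
             q3=lambda s: s.quantile(0.75))
        .reset_index()
    )
    return tab, med
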