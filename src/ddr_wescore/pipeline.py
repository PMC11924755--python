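"""End-to-end pipeline driver and file-format plumbing.

Stages: load panel -> z-score -> raw WE -> scaled WE -> WSS curve ->
elbow k selection -> k-means labels -> optional association statistics.
All tabular output is TSV, all statistics JSON; a ``manifest.json``
records seeds, input checksums, warnings, and the chosen k so a run can
be audited and reproduced byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .associations import chisq_test, contingency, score_by_cluster
from .clustering import cluster, cluster_summary, select_k, wss_curve
from .panel import DDRPanel, load_default_panel, load_panel
from .scoring import ExpressionMatrix, we_score_pipeline

logger = logging.getLogger("ddr_wescore")

__all__ = ["RunConfig", "run_pipeline", "read_expression", "read_labels",
            "write_cohort"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run (YAML-serializable)."""

    expression_path: str
    out_dir: str
    panel_path: str | None = None
    units: str = "TPM"
    log_transform: bool = True
    strict_denominator: bool = False
    k_max: int = 10
    k: int | None = None  # fixed k overrides elbow selection
    restarts: int = 25
    n_sim: int = 2000
    seed: int = 0
    labels_path: str | None = None  # sample -> category (e.g. SCLC subtype)
    scores_path: str | None = None  # sample -> continuous score

    def __post_init__(self) -> None:
        if self.k_max < 3:
            raise ValueError("k_max must be >= 3")
        if self.n_sim < 1:
            raise ValueError("n_sim must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def validate_paths(self) -> None:
        for name in ("expression_path", "panel_path", "labels_path", "scores_path"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p}")


def read_expression(path: str | Path, units: str = "TPM") -> ExpressionMatrix:
    """Read a genes x samples matrix: first column gene symbols, rest samples."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.shape[1] < 1:
        raise ValueError(f"{path}: no sample columns")
    df.index = df.index.astype(str).str.upper()
    return ExpressionMatrix(values=df, units=units)


def read_labels(path: str | Path) -> pd.Series:
    """Read a two-column sample->category file with header."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep)
    if df.empty or df.shape[1] < 2:
        raise ValueError(f"{path}: expected a non-empty two-column table with header")
    samples = df.iloc[:, 0].astype(str)
    if samples.duplicated().any():
        dup = samples[samples.duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicate sample id {dup!r}")
    return pd.Series(df.iloc[:, 1].values, index=pd.Index(samples, name="sample"),
                     name=df.columns[1])


def write_cohort(cohort, out_dir: str | Path) -> dict[str, str]:
    """Serialize a synthetic cohort (expression + truth labels + spec)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    p = out / "expression.tsv"
    cohort.expression.values.rename_axis("gene").to_csv(p, sep="\t")
    paths["expression"] = str(p)
    for name, series in (
        ("truth_clusters", cohort.truth_clusters),
        ("truth_subtypes", cohort.truth_subtypes),
        ("truth_covariate", cohort.truth_covariate),
    ):
        p = out / f"{name}.tsv"
        series.rename_axis("sample").to_csv(p, sep="\t")
        paths[name] = str(p)
    spec_payload = {
        "n_samples": cohort.spec.n_samples,
        "planted_clusters": cohort.spec.planted_clusters,
        "delta": cohort.spec.delta,
        "noise_sd": cohort.spec.noise_sd,
        "n_background_genes": cohort.spec.n_background_genes,
        "covariate_slope": cohort.spec.covariate_slope,
        "seed": cohort.spec.seed,
    }
    p = out / "spec.yaml"
    with open(p, "w") as fh:
        yaml.safe_dump(spec_payload, fh)
    paths["spec"] = str(p)
    return paths


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index_label: str | None = None) -> None:
    df.to_csv(path, sep="\t", index=index_label is not None,
              index_label=index_label, float_format="%.10g")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline and write all artifacts plus a manifest."""
    config.validate_paths()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "inputs": {},
        "stages": {},
        "warnings": [],
    }
    caught: list[str] = []

    def _stage(name: str):
        t0 = time.perf_counter()

        def done(**extra):
            # timings go to the log only, so manifests are byte-reproducible
            manifest["stages"][name] = dict(extra)
            logger.info("stage %s done in %.2fs", name,
                        time.perf_counter() - t0)

        return done

    with warnings.catch_warnings(record=True) as wrec:
        warnings.simplefilter("always")

        done = _stage("load_panel")
        if config.panel_path:
            panel = load_panel(config.panel_path)
            manifest["inputs"]["panel"] = {
                "path": config.panel_path, "sha256": _sha256(config.panel_path)
            }
        else:
            panel = load_default_panel()
            manifest["inputs"]["panel"] = {"path": "<packaged synthetic default>"}
        done(n_genes=len(panel), n_pathways=len(panel.pathways))

        done = _stage("load_expression")
        expr = read_expression(config.expression_path, units=config.units)
        manifest["inputs"]["expression"] = {
            "path": config.expression_path,
            "sha256": _sha256(config.expression_path),
            "n_genes": expr.values.shape[0],
            "n_samples": expr.values.shape[1],
        }
        done()

        done = _stage("we_scoring")
        z, we = we_score_pipeline(
            expr, panel, log_transform=config.log_transform,
            strict_denominator=config.strict_denominator,
        )
        _write_tsv(we.raw, out / "we_scores_raw.tsv", index_label="pathway")
        _write_tsv(we.scaled, out / "we_scores_scaled.tsv", index_label="pathway")
        with open(out / "zscore_provenance.json", "w") as fh:
            json.dump(
                {
                    "transform": z.provenance,
                    "degenerate_genes": list(z.degenerate_genes),
                    "unmatched_panel_genes": list(we.unmatched_genes),
                    "n_genes_used": we.n_genes_used.to_dict(),
                },
                fh, indent=2, sort_keys=True,
            )
        done(n_pathways_scored=we.raw.shape[0])

        done = _stage("cluster")
        curve = wss_curve(we, k_max=config.k_max, restarts=config.restarts,
                          seed=config.seed)
        _write_tsv(curve.to_frame(), out / "wss_curve.tsv")
        k = config.k if config.k is not None else select_k(curve)
        sol = cluster(we, k, restarts=config.restarts, seed=config.seed, wss=curve)
        clusters_df = pd.DataFrame(
            {"cluster_index": sol.assignments, "label": sol.label_series}
        )
        _write_tsv(clusters_df, out / "clusters.tsv", index_label="sample")
        _write_tsv(cluster_summary(sol, we), out / "cluster_summary.tsv")
        label_counts = sol.label_series.value_counts().to_dict()
        done(chosen_k=k, label_counts=label_counts)
        manifest["chosen_k"] = k
        manifest["label_counts"] = label_counts

        if config.labels_path:
            done = _stage("associate_labels")
            labels = read_labels(config.labels_path)
            tab = contingency(sol.label_series, labels)
            res = chisq_test(tab, n_sim=config.n_sim, seed=config.seed)
            with open(out / "chisq_result.json", "w") as fh:
                payload = res.to_dict()
                payload["observed"] = tab.counts.to_dict()
                json.dump(payload, fh, indent=2, sort_keys=True)
            done(statistic=res.statistic, p_simulated=res.p_simulated)

        if config.scores_path:
            done = _stage("associate_scores")
            scores = read_labels(config.scores_path).astype(float)
            results, summary = score_by_cluster(scores, sol)
            rows = [
                {
                    "group_a": r.group_a, "group_b": r.group_b,
                    "statistic": r.statistic, "p_value": r.p_value,
                    "significant": r.significant,
                }
                for r in results
            ]
            _write_tsv(pd.DataFrame(rows), out / "pairwise_wilcoxon.tsv")
            _write_tsv(summary, out / "score_summary.tsv")
            done(n_comparisons=len(rows))

        caught = sorted({str(w.message) for w in wrec})

    manifest["warnings"] = caught
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
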