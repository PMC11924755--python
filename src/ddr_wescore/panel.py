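"""DDR gene panel registry: gene symbol -> (pathway, ESF weight).

The panel is explicit data, not code: a delimited table with columns
``gene``, ``pathway``, ``esf``.  The essentiality scaling factor (ESF) is a
positive, dimensionless per-gene weight expressing how important a gene is
to its pathway's function; it multiplies the gene's expression z-score
before per-pathway averaging.

The canonical pathway vocabulary covers ten DDR pathways: NHEJ, TLS, NER,
MMEJ, HR, FA, Checkpoint (damage sensing and signaling), MMR, BER and DR
(direct reversal).  User panels may extend this vocabulary; unknown pathway
names only raise a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "PATHWAY_VOCABULARY",
    "PanelEntry",
    "DDRPanel",
    "PanelFormatError",
    "PanelValidationError",
    "load_panel",
    "load_default_panel",
    "write_panel",
    "panel_summary",
]

#: Canonical ten-pathway DDR vocabulary, in conventional display order.
PATHWAY_VOCABULARY: tuple[str, ...] = (
    "NHEJ",
    "TLS",
    "NER",
    "MMEJ",
    "HR",
    "FA",
    "Checkpoint",
    "MMR",
    "BER",
    "DR",
)

_DEFAULT_PANEL_RESOURCE = "default_panel_synthetic.tsv"


class PanelFormatError(ValueError):
    """The panel file is structurally malformed (missing columns, not a table)."""


class PanelValidationError(ValueError):
    """The panel table parsed but violates a panel invariant."""


@dataclass(frozen=True)
class PanelEntry:
    """One gene's membership: symbol, pathway, and positive ESF weight."""

    gene: str
    pathway: str
    esf: float

    def __post_init__(self) -> None:
        if not self.gene:
            raise PanelValidationError("panel entry with empty gene symbol")
        if not (self.esf > 0):
            raise PanelValidationError(
                f"gene {self.gene}: esf must be positive, got {self.esf!r}"
            )


@dataclass
class DDRPanel:
    """A validated DDR gene panel.

    Each gene belongs to exactly one pathway (disjoint counting is what the
    per-pathway denominators of the WE score assume); every pathway listed
    in :attr:`pathways` has at least one gene.  ``pathways`` preserves the
    order of first appearance in the source table.
    """

    entries: tuple[PanelEntry, ...]
    pathways: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for e in self.entries:
            if e.gene in seen:
                raise PanelValidationError(f"duplicate gene in panel: {e.gene}")
            seen[e.gene] = e.pathway
        if not self.pathways:
            order: list[str] = []
            for e in self.entries:
                if e.pathway not in order:
                    order.append(e.pathway)
            self.pathways = tuple(order)
        present = {e.pathway for e in self.entries}
        empty = [p for p in self.pathways if p not in present]
        if empty:
            raise PanelValidationError(f"pathways with no genes: {empty}")

    def __len__(self) -> int:
        return len(self.entries)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DDRPanel):
            return NotImplemented
        return set(self.entries) == set(other.entries) and self.pathways == other.pathways

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(e.gene for e in self.entries)

    def genes_in(self, pathway: str) -> tuple[str, ...]:
        return tuple(e.gene for e in self.entries if e.pathway == pathway)

    def esf_map(self) -> dict[str, float]:
        return {e.gene: e.esf for e in self.entries}

    def pathway_map(self) -> dict[str, str]:
        return {e.gene: e.pathway for e in self.entries}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": [e.gene for e in self.entries],
                "pathway": [e.pathway for e in self.entries],
                "esf": [e.esf for e in self.entries],
            }
        )


def _panel_from_frame(df: pd.DataFrame, source: str) -> DDRPanel:
    required = {"gene", "pathway", "esf"}
    missing = required - set(df.columns)
    if missing:
        raise PanelFormatError(
            f"{source}: missing required column(s) {sorted(missing)}; "
            "expected gene, pathway, esf"
        )
    entries: list[PanelEntry] = []
    for _, row in df.iterrows():
        gene = str(row["gene"]).strip().upper()
        pathway = str(row["pathway"]).strip()
        try:
            esf = float(row["esf"])
        except (TypeError, ValueError) as exc:
            raise PanelValidationError(
                f"{source}: gene {gene}: non-numeric esf {row['esf']!r}"
            ) from exc
        entries.append(PanelEntry(gene=gene, pathway=pathway, esf=esf))
    unknown = sorted({e.pathway for e in entries} - set(PATHWAY_VOCABULARY))
    if unknown:
        warnings.warn(
            f"{source}: pathway name(s) outside the canonical DDR vocabulary: "
            f"{unknown}",
            stacklevel=3,
        )
    return DDRPanel(entries=tuple(entries))


def load_panel(path: str | Path) -> DDRPanel:
    """Load and validate a DDR panel from a TSV/CSV/YAML file.

    Gene symbols are uppercased; pathway order is order of first appearance.
    Duplicate genes and non-positive ESF values raise
    :class:`PanelValidationError`; missing columns raise
    :class:`PanelFormatError`.
    """
    path = Path(path)
    if path.suffix.lower() in {".yaml", ".yml"}:
        import yaml

        with open(path) as fh:
            payload = yaml.safe_load(fh)
        if not isinstance(payload, list):
            raise PanelFormatError(f"{path}: YAML panel must be a list of mappings")
        df = pd.DataFrame(payload)
    else:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
        df = pd.read_csv(path, sep=sep)
    return _panel_from_frame(df, str(path))


def load_default_panel(warn: bool = True) -> DDRPanel:
    """Load the packaged 130-gene / 10-pathway default panel.

    .. warning::
        The packaged panel is a synthetic stand-in: the gene-to-pathway
        assignments follow standard DDR pathway curation, but every ESF is
        set to 1.0 (unweighted).  Study-specific ESF weights should be
        supplied as a user panel file.
    """
    if warn:
        warnings.warn(
            "Loading the packaged synthetic default panel: 130 DDR genes across "
            "10 pathways with ALL ESF WEIGHTS SET TO 1.0. Supply your own panel "
            "file to use curated essentiality weights.",
            stacklevel=2,
        )
    ref = resources.files("ddr_wescore.data").joinpath(_DEFAULT_PANEL_RESOURCE)
    with resources.as_file(ref) as p:
        return load_panel(p)


def write_panel(panel: DDRPanel, path: str | Path) -> None:
    """Write a panel as TSV (columns gene, pathway, esf), grouped by pathway order."""
    df = panel.to_frame()
    df["__order"] = df["pathway"].map({p: i for i, p in enumerate(panel.pathways)})
    df = df.sort_values(["__order"], kind="stable").drop(columns="__order")
    df.to_csv(path, sep="\t", index=False)


def panel_summary(panel: DDRPanel) -> pd.DataFrame:
    """Per-pathway gene counts and mean ESF, one row per pathway."""
    df = panel.to_frame()
    out = (
        df.groupby("pathway", sort=False)
        .agg(n_genes=("gene", "size"), mean_esf=("esf", "mean"))
        .reindex(list(panel.pathways))
        .reset_index()
    )
    return out
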