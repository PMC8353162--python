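"""Trinary marker knowledge matrix: cell types defined by required/forbidden genes.

Each row is a cell type; each marker gene is *required* (1), *forbidden* (-1)
or *irrelevant* (0) for that type.  Progenitor rows additionally carry a
dorsoventral rank so that composition tables can be ordered along the axis.

The default matrix is shipped as TSV data (``data/knowledge_matrix.tsv``) so
it can be replaced wholesale by a user-supplied table with the same layout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

REQUIRED = 1
FORBIDDEN = -1
IRRELEVANT = 0

#: valid values of the per-row ``class`` column
TYPE_CLASSES = (
    "progenitor",
    "neuron",
    "pns_progenitor",
    "pns_precursor",
    "pns_neuron",
    "glia",
)

#: pan-lineage gate genes used before row competition
PROGENITOR_PAN = "SOX2"
NEURON_PAN = "ELAVL3"

#: genes whose positivity routes a neural cell into the PNS branch
PNS_PROGENITOR_GATE = "SOX10"
PNS_PRECURSOR_GATE = ("NEUROG1", "NEUROG2", "NEUROD1")
PNS_NEURON_GATE = ("SIX1", "PRPH")
#: positivity for this gene vetoes PNS routing (oligodendrocyte precursors)
GLIA_VETO_GATE = "PDGFRA"

#: tissue-module names that count as neural in broad typing
NEURAL_MODULE_NAMES = frozenset({"neural_progenitor", "neuron", "neural_crest"})
NEURAL_TISSUE = "neural"

_META_COLUMNS = ("class", "dv_rank")


class KnowledgeMatrixError(ValueError):
    """Raised when a knowledge matrix violates its schema."""


@dataclass
class KnowledgeMatrix:
    """Cell types x marker genes trinary requirement table.

    Parameters
    ----------
    markers
        DataFrame indexed by cell-type name, columns are marker genes,
        values in {1, -1, 0}.
    classes
        Series mapping cell type -> class (one of :data:`TYPE_CLASSES`).
    dv_rank
        Series mapping cell type -> integer dorsoventral rank; NaN for
        types without a DV position (PNS rows).
    """

    markers: pd.DataFrame
    classes: pd.Series
    dv_rank: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.dv_rank is None:
            self.dv_rank = pd.Series(np.nan, index=self.markers.index)
        self.markers = self.markers.astype(np.int8)
        self.validate()

    # -- schema ---------------------------------------------------------
    def validate(self) -> None:
        idx = self.markers.index
        if idx.duplicated().any():
            dupes = idx[idx.duplicated()].tolist()
            raise KnowledgeMatrixError(f"duplicate type names: {dupes}")
        if self.markers.columns.duplicated().any():
            raise KnowledgeMatrixError("duplicate marker gene columns")
        bad = set(np.unique(self.markers.to_numpy())) - {REQUIRED, FORBIDDEN, IRRELEVANT}
        if bad:
            raise KnowledgeMatrixError(f"marker values outside {{1,-1,0}}: {bad}")
        unknown = set(self.classes) - set(TYPE_CLASSES)
        if unknown:
            raise KnowledgeMatrixError(f"unknown type classes: {unknown}")
        if not self.classes.index.equals(idx) or not self.dv_rank.index.equals(idx):
            raise KnowledgeMatrixError("classes/dv_rank index must match marker rows")
        no_req = idx[(self.markers.to_numpy() == REQUIRED).sum(axis=1) == 0]
        if len(no_req):
            raise KnowledgeMatrixError(
                f"every row needs >=1 required marker; offending: {list(no_req)}"
            )
        prog_ranks = self.dv_rank[self.classes == "progenitor"].dropna()
        if prog_ranks.duplicated().any():
            raise KnowledgeMatrixError("dv_rank must be unique within progenitors")

    # -- accessors ------------------------------------------------------
    @property
    def types(self) -> pd.Index:
        return self.markers.index

    @property
    def marker_genes(self) -> list[str]:
        return list(self.markers.columns)

    def required(self, cell_type: str) -> list[str]:
        row = self.markers.loc[cell_type]
        return list(row.index[row == REQUIRED])

    def forbidden(self, cell_type: str) -> list[str]:
        row = self.markers.loc[cell_type]
        return list(row.index[row == FORBIDDEN])

    def types_of_class(self, *classes: str) -> list[str]:
        return list(self.types[self.classes.isin(classes)])

    def subset(self, types) -> "KnowledgeMatrix":
        types = list(types)
        return KnowledgeMatrix(
            markers=self.markers.loc[types].copy(),
            classes=self.classes.loc[types].copy(),
            dv_rank=self.dv_rank.loc[types].copy(),
        )

    def rename_type(self, old: str, new: str) -> "KnowledgeMatrix":
        mapper = {old: new}
        return KnowledgeMatrix(
            markers=self.markers.rename(index=mapper),
            classes=self.classes.rename(index=mapper),
            dv_rank=self.dv_rank.rename(index=mapper),
        )

    def drop_type(self, name: str) -> "KnowledgeMatrix":
        keep = [t for t in self.types if t != name]
        return self.subset(keep)

    def dv_ordered_progenitors(self) -> list[str]:
        prog = self.dv_rank[self.classes == "progenitor"].dropna().sort_values()
        return list(prog.index)

    # -- I/O ------------------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        out = pd.DataFrame(index=self.types)
        out.index.name = "type"
        out["class"] = self.classes
        out["dv_rank"] = self.dv_rank.astype("Int64")
        out = pd.concat([out, self.markers], axis=1)
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "KnowledgeMatrix":
        df = pd.read_csv(path, sep="\t", index_col="type")
        missing = [c for c in _META_COLUMNS if c not in df.columns]
        if missing:
            raise KnowledgeMatrixError(f"knowledge matrix TSV missing columns: {missing}")
        gene_cols = [c for c in df.columns if c not in _META_COLUMNS]
        return cls(
            markers=df[gene_cols].fillna(0).astype(np.int8),
            classes=df["class"].astype(str),
            dv_rank=pd.to_numeric(df["dv_rank"], errors="coerce"),
        )

    def __eq__(self, other: object) -> bool:  # noqa: D105
        if not isinstance(other, KnowledgeMatrix):
            return NotImplemented
        return (
            self.markers.equals(other.markers)
            and self.classes.equals(other.classes)
            and self.dv_rank.fillna(-1).equals(other.dv_rank.fillna(-1))
        )


def _data_path(name: str):
    return resources.files("sctube").joinpath("data", name)


def default_knowledge_matrix() -> KnowledgeMatrix:
    """Load the shipped default knowledge matrix.

    The default covers 13 progenitor rows (RP, dp1-dp6, p0-p3, pMN, FP),
    12 neuronal rows (dI1-dI6, V0-V3, MN and the visceral motor neuron row
    ``vMN``), the PNS lineage rows and an oligodendrocyte-precursor row.
    ``vMN`` is the documented "extra" neuronal row: the canonical inventory
    names 11 neuronal classes, and the visceral motor neuron split brings
    the total to 12; rename or drop it via :meth:`KnowledgeMatrix.rename_type`
    / :meth:`KnowledgeMatrix.drop_type` to change that convention.
    """
    with resources.as_file(_data_path("knowledge_matrix.tsv")) as p:
        return KnowledgeMatrix.from_tsv(p)


def default_tissue_modules() -> dict[str, list[str]]:
    """Shipped broad-tissue gene modules.

    Three neural sub-modules (neural_progenitor, neuron, neural_crest — all
    mapped to the ``neural`` tissue by the classifier) plus the contaminant
    modules mesoderm, blood and skin.
    """
    with resources.as_file(_data_path("tissue_modules.tsv")) as p:
        df = pd.read_csv(p, sep="\t")
    return {m: list(g["gene"]) for m, g in df.groupby("module", sort=False)}


def load_modules_tsv(path: str | Path) -> dict[str, list[str]]:
    """Read a two-column (module, gene) TSV into named gene lists."""
    df = pd.read_csv(path, sep="\t")
    if not {"module", "gene"} <= set(df.columns):
        raise ValueError("module TSV needs 'module' and 'gene' columns")
    return {m: list(g["gene"]) for m, g in df.groupby("module", sort=False)}


def default_cell_cycle_modules() -> tuple[list[str], list[str]]:
    """Return the shipped (S-phase, G2M-phase) marker gene lists."""
    with resources.as_file(_data_path("cell_cycle_genes.tsv")) as p:
        df = pd.read_csv(p, sep="\t")
    return (
        list(df.loc[df["phase"] == "S", "gene"]),
        list(df.loc[df["phase"] == "G2M", "gene"]),
    )
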