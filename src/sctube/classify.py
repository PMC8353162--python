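"""Two-step marker-driven classification.

Step one assigns a broad tissue label from gene-module scores; step two
binarises marker expression in neural cells and matches each cell against
the knowledge matrix by counting mismatches (required markers absent plus
forbidden markers present).  Peripheral cells take a dedicated staged
route (progenitor -> precursor -> postmitotic sensory subtype).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .counts_io import CountMatrix
from .knowledge import (
    GLIA_VETO_GATE,
    NEURAL_MODULE_NAMES,
    NEURAL_TISSUE,
    NEURON_PAN,
    PNS_NEURON_GATE,
    PNS_PRECURSOR_GATE,
    PNS_PROGENITOR_GATE,
    PROGENITOR_PAN,
    KnowledgeMatrix,
    default_tissue_modules,
)
from .scoring import NormalizedMatrix, normalize_log, score_modules

UNASSIGNED = "Unassigned"
OTHER = "other"

#: gate-group eligibility by pan-marker state
_PROGENITOR_CLASSES = ("progenitor", "glia", "pns_progenitor")
_NEURON_CLASSES = ("neuron", "pns_neuron")


@dataclass
class BinaryMatrix:
    """Marker genes x cells 0/1 calls plus the per-gene threshold used."""

    values: np.ndarray
    genes: pd.Index
    cells: pd.Index
    thresholds: pd.Series

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.uint8)
        self.genes = pd.Index(self.genes, name="gene")
        self.cells = pd.Index(self.cells, name="barcode")
        if self.values.shape != (len(self.genes), len(self.cells)):
            raise ValueError("binary matrix shape mismatch")
        if not set(np.unique(self.values)) <= {0, 1}:
            raise ValueError("binary matrix must contain only 0/1")

    def row(self, gene: str) -> np.ndarray:
        """0/1 vector for one gene; absent genes are all-zero."""
        if gene in self.genes:
            return self.values[self.genes.get_loc(gene)].astype(bool)
        return np.zeros(len(self.cells), dtype=bool)

    def aligned(self, genes) -> np.ndarray:
        """Genes x cells matrix aligned to ``genes``; absent genes -> zero rows."""
        out = np.zeros((len(genes), len(self.cells)), dtype=np.uint8)
        idx = self.genes.get_indexer(pd.Index(genes))
        present = np.flatnonzero(idx >= 0)
        out[present] = self.values[idx[present]]
        return out

    def subset_cells(self, barcodes) -> "BinaryMatrix":
        idx = self.cells.get_indexer(pd.Index(barcodes))
        if (idx < 0).any():
            raise KeyError("unknown barcodes")
        return BinaryMatrix(self.values[:, idx], self.genes, self.cells[idx], self.thresholds)


def _otsu_or_midpoint(values: np.ndarray) -> float:
    """Threshold for one gene: Otsu on the positive-expression histogram,
    midpoint of min/max when Otsu is degenerate.

    Degenerate means fewer than two distinct positive values, or a
    positive-value distribution confined to the upper half of the gene's
    range (a single "on" mode with no ambient mode below it).
    """
    lo, hi = float(values.min()), float(values.max())
    midpoint = (lo + hi) / 2.0
    pos = values[values > 0]
    if len(np.unique(pos)) < 2 or pos.min() > midpoint:
        return midpoint
    from skimage.filters import threshold_otsu

    try:
        return float(threshold_otsu(pos))
    except ValueError:
        return midpoint


def binarize_expression(
    nm: NormalizedMatrix,
    marker_genes: list[str],
    method: str = "otsu",
    min_positive_frac: float = 0.01,
) -> BinaryMatrix:
    """Per-gene thresholding of marker expression into 0/1 calls.

    Genes positive (expression > 0) in fewer than ``min_positive_frac`` of
    cells are called all-zero; genes absent from the dataset are dropped
    with a warning and treated as all-zero downstream.
    """
    if not marker_genes:
        raise ValueError("empty marker gene list")
    if method not in ("otsu", "midpoint"):
        raise ValueError(f"unknown binarisation method {method!r}")
    present = [g for g in marker_genes if g in nm.genes]
    missing = [g for g in marker_genes if g not in nm.genes]
    if missing:
        warnings.warn(f"{len(missing)} marker genes absent from dataset: {missing[:5]}...")
    n_cells = len(nm.cells)
    values = np.zeros((len(present), n_cells), dtype=np.uint8)
    thresholds = pd.Series(np.nan, index=pd.Index(present, name="gene"))
    for i, g in enumerate(present):
        expr = nm.expr(g)
        if (expr > 0).sum() < min_positive_frac * n_cells:
            thresholds[g] = np.inf  # effectively all-zero
            continue
        if expr.max() == expr.min():
            thresholds[g] = np.inf
            continue
        t = (
            _otsu_or_midpoint(expr)
            if method == "otsu"
            else (float(expr.min()) + float(expr.max())) / 2.0
        )
        thresholds[g] = t
        values[i] = expr > t
    return BinaryMatrix(values, pd.Index(present), nm.cells, thresholds)


def assign_broad_type(score_table: pd.DataFrame, min_score: float = 0.0) -> pd.Series:
    """Tissue label per cell: argmax module score, or ``other`` on ties /
    sub-threshold maxima."""
    if score_table.shape[1] < 1:
        raise ValueError("need at least one scored tissue module")
    arr = score_table.to_numpy(dtype=float)
    best = arr.max(axis=1)
    n_best = (arr == best[:, None]).sum(axis=1)
    labels = np.array(score_table.columns)[arr.argmax(axis=1)]
    labels = np.where((best < min_score) | (n_best > 1), OTHER, labels)
    return pd.Series(labels, index=score_table.index, name="tissue")


def _mismatch_table(bm: BinaryMatrix, km: KnowledgeMatrix) -> np.ndarray:
    """types x cells mismatch counts: required absent + forbidden present."""
    B = bm.aligned(km.marker_genes)
    M = km.markers.to_numpy()
    R = (M == 1).astype(np.int32)
    F = (M == -1).astype(np.int32)
    return R @ (1 - B.astype(np.int32)) + F @ B.astype(np.int32)


def _competition(
    mism: np.ndarray, eligible: np.ndarray, types: pd.Index, max_mismatch: int
) -> tuple[np.ndarray, np.ndarray]:
    """Resolve row competition; ties or minima above tolerance -> Unassigned."""
    BIG = 1 << 30
    masked = np.where(eligible, mism, BIG)
    best = masked.min(axis=0)
    n_best = (masked == best[None, :]).sum(axis=0)
    winner = np.asarray(types)[masked.argmin(axis=0)]
    labels = np.where((best > max_mismatch) | (n_best > 1), UNASSIGNED, winner)
    return labels, np.where(best >= BIG, -1, best)


def assign_subtype(
    bm: BinaryMatrix, km: KnowledgeMatrix, max_mismatch: int = 0
) -> pd.DataFrame:
    """Assign each cell the unique minimal-mismatch knowledge-matrix row.

    Pan-marker gating restricts the candidate rows: SOX2+/ELAVL3- cells
    compete among progenitor-side rows, ELAVL3+/SOX2- cells among neuronal
    rows, and cells positive for both or neither compete across all rows.
    Returns a frame with subtype, n_mismatches and a match score in [0, 1]
    (1 = perfect match of the assigned row; NaN when unassigned).
    """
    if len(km.types) == 0:
        raise ValueError("empty knowledge matrix")
    mism = _mismatch_table(bm, km)
    sox2 = bm.row(PROGENITOR_PAN)
    elavl3 = bm.row(NEURON_PAN)
    is_prog_row = km.classes.isin(_PROGENITOR_CLASSES).to_numpy()
    is_neu_row = km.classes.isin(_NEURON_CLASSES).to_numpy()

    eligible = np.ones(mism.shape, dtype=bool)
    prog_gate = sox2 & ~elavl3
    neu_gate = elavl3 & ~sox2
    eligible[:, prog_gate] = is_prog_row[:, None]
    eligible[:, neu_gate] = is_neu_row[:, None]

    labels, best = _competition(mism, eligible, km.types, max_mismatch)
    weight = ((km.markers.to_numpy() != 0).sum(axis=1)).astype(float)
    assigned_idx = km.types.get_indexer(pd.Index(labels))  # -1 for Unassigned
    score = np.where(
        assigned_idx >= 0,
        1.0 - best / weight[np.maximum(assigned_idx, 0)],
        np.nan,
    )
    return pd.DataFrame(
        {"subtype": labels, "n_mismatches": best, "score": score}, index=bm.cells
    )


def classify_pns(
    bm: BinaryMatrix, km: KnowledgeMatrix, max_mismatch: int = 0
) -> pd.DataFrame:
    """Three-way PNS staging, then sensory-subtype refinement.

    Staging: postmitotic sensory neurons are ELAVL3+; sensory neuron
    precursors express any of NEUROG1/NEUROG2/NEUROD1; progenitors express
    SOX10 (alone or with SOX2).  Postmitotic cells are then refined into
    the pns_neuron rows of the knowledge matrix by the mismatch rule;
    unrefined postmitotic cells keep the generic ``pns_neuron`` label.
    """
    pns_rows = km.types_of_class("pns_progenitor", "pns_precursor", "pns_neuron")
    if not pns_rows:
        raise ValueError("knowledge matrix has no PNS rows")
    elavl3 = bm.row(NEURON_PAN)
    precursor = np.zeros(len(bm.cells), dtype=bool)
    for g in PNS_PRECURSOR_GATE:
        precursor |= bm.row(g)
    progenitor = bm.row(PNS_PROGENITOR_GATE)

    stage = np.full(len(bm.cells), UNASSIGNED, dtype=object)
    stage[progenitor] = "pns_progenitor"
    stage[precursor & ~elavl3] = "pns_precursor"
    stage[elavl3] = "pns_neuron"

    labels = stage.copy()
    n_mism = np.full(len(bm.cells), -1)
    score = np.full(len(bm.cells), np.nan)
    neuron_rows = km.types_of_class("pns_neuron")
    post = np.flatnonzero(elavl3)
    if len(post) and neuron_rows:
        sub_km = km.subset(neuron_rows)
        sub = assign_subtype(bm.subset_cells(bm.cells[post]), sub_km, max_mismatch)
        refined = sub["subtype"].to_numpy()
        keep = refined != UNASSIGNED
        labels[post[keep]] = refined[keep]
        n_mism[post] = sub["n_mismatches"].to_numpy()
        score[post] = sub["score"].to_numpy()
    return pd.DataFrame(
        {"subtype": labels, "stage": stage, "n_mismatches": n_mism, "score": score},
        index=bm.cells,
    )


def pns_routing_mask(bm: BinaryMatrix) -> np.ndarray:
    """Cells routed to the PNS branch: SOX10+ (unless PDGFRA+, which marks
    oligodendrocyte precursors), NEUROG/NEUROD+ without SOX2, or ELAVL3+
    peripheral neurons (SIX1/PRPH positive)."""
    sox10 = bm.row(PNS_PROGENITOR_GATE)
    pdgfra = bm.row(GLIA_VETO_GATE)
    sox2 = bm.row(PROGENITOR_PAN)
    elavl3 = bm.row(NEURON_PAN)
    precursor = np.zeros(len(bm.cells), dtype=bool)
    for g in PNS_PRECURSOR_GATE:
        precursor |= bm.row(g)
    peripheral_neuron = np.zeros(len(bm.cells), dtype=bool)
    for g in PNS_NEURON_GATE:
        peripheral_neuron |= bm.row(g)
    return (sox10 & ~pdgfra) | (precursor & ~sox2) | (elavl3 & peripheral_neuron)


def two_step_classify(
    cm: CountMatrix,
    km: KnowledgeMatrix,
    modules: dict[str, list[str]] | None = None,
    *,
    neural_modules: frozenset[str] | set[str] = NEURAL_MODULE_NAMES,
    min_score: float = 0.0,
    max_mismatch: int = 0,
    binarize_method: str = "otsu",
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
    target_depth: float = 1e4,
) -> tuple[pd.DataFrame, dict]:
    """Full two-step classification: broad tissue label, then CNS/PNS subtype.

    Returns (assignment, log).  The assignment frame has one row per cell
    with columns tissue, subtype, n_mismatches, score; non-neural cells
    carry an empty subtype.  Modules named in ``neural_modules`` are
    collapsed to the single ``neural`` tissue label before subtype
    assignment.  The log records per-step cell counts.
    """
    modules = modules if modules is not None else default_tissue_modules()
    if not (set(neural_modules) & set(modules)):
        raise ValueError(f"tissue modules must include one of {sorted(neural_modules)}")
    nm = normalize_log(cm, target_depth=target_depth)
    scores = score_modules(nm, modules, n_bins=n_bins, n_ctrl=n_ctrl, seed=seed)
    tissue = assign_broad_type(scores, min_score=min_score)
    tissue = tissue.where(~tissue.isin(neural_modules), NEURAL_TISSUE)

    out = pd.DataFrame(
        {"tissue": tissue, "subtype": "", "n_mismatches": -1, "score": np.nan},
        index=cm.cells,
    )
    log = {
        "n_cells": len(cm.cells),
        "tissue_counts": tissue.value_counts().to_dict(),
    }
    neural_cells = cm.cells[(tissue == NEURAL_TISSUE).to_numpy()]
    log["n_neural"] = len(neural_cells)
    if len(neural_cells) == 0:
        return out, log

    nm_neural = nm.subset_cells(neural_cells)
    marker_genes = list(km.marker_genes)
    for g in PNS_NEURON_GATE:
        if g not in marker_genes and g in nm.genes:
            marker_genes.append(g)
    bm = binarize_expression(nm_neural, marker_genes, method=binarize_method)

    pns_mask = pns_routing_mask(bm)
    log["n_pns_routed"] = int(pns_mask.sum())
    cns_cells = neural_cells[~pns_mask]
    pns_cells = neural_cells[pns_mask]

    if len(cns_cells):
        cns = assign_subtype(bm.subset_cells(cns_cells), km, max_mismatch)
        out.loc[cns_cells, ["subtype", "n_mismatches", "score"]] = cns[
            ["subtype", "n_mismatches", "score"]
        ].to_numpy()
    if len(pns_cells):
        pns = classify_pns(bm.subset_cells(pns_cells), km, max_mismatch)
        out.loc[pns_cells, ["subtype", "n_mismatches", "score"]] = pns[
            ["subtype", "n_mismatches", "score"]
        ].to_numpy()
    assigned = out.loc[neural_cells, "subtype"]
    log["n_assigned"] = int((assigned != UNASSIGNED).sum())
    log["subtype_counts"] = assigned.value_counts().to_dict()
    return out, log


def write_assignment_tsv(assignment: pd.DataFrame, path) -> None:
    out = assignment.copy()
    out.index.name = "barcode"
    out.to_csv(path, sep="\t")
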