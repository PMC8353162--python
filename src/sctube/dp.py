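"""OLIG2/NKX2-2 double-positive progenitor analysis.

Gates SOX2-positive progenitors into double-positive, OLIG2-only and
NKX2-2-only groups from binarised marker calls, tracks their per-stage
ratio, and quantifies how close double-positive cells sit to the pMN and
p3 reference populations in expression space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import BinaryMatrix
from .knowledge import NEURON_PAN, PROGENITOR_PAN, KnowledgeMatrix
from .scoring import GLIOGENIC_GENES, NormalizedMatrix

GATE_A = "OLIG2"
GATE_B = "NKX2-2"
DEFAULT_MIN_CELLS = 10


@dataclass
class GateGroups:
    """Disjoint barcode sets of SOX2+ cells expressing the two gate markers."""

    dp: pd.Index
    pmn_like: pd.Index
    p3_like: pd.Index

    def __post_init__(self) -> None:
        sets = [set(self.dp), set(self.pmn_like), set(self.p3_like)]
        for i in range(3):
            for j in range(i + 1, 3):
                if sets[i] & sets[j]:
                    raise ValueError("gate groups must be pairwise disjoint")

    @property
    def gated(self) -> pd.Index:
        return self.dp.append(self.pmn_like).append(self.p3_like)


def gate_cells(bm: BinaryMatrix) -> GateGroups:
    """Partition SOX2+ cells by OLIG2/NKX2-2 positivity.

    SOX2-negative cells are excluded entirely; cells positive for neither
    gate gene belong to no group.
    """
    for g in (PROGENITOR_PAN, GATE_A, GATE_B):
        if g not in bm.genes:
            raise KeyError(f"gate gene {g!r} missing from binary matrix")
    sox2 = bm.row(PROGENITOR_PAN)
    olig2 = bm.row(GATE_A) & sox2
    nkx22 = bm.row(GATE_B) & sox2
    return GateGroups(
        dp=bm.cells[olig2 & nkx22],
        pmn_like=bm.cells[olig2 & ~nkx22],
        p3_like=bm.cells[~olig2 & nkx22],
    )


def dp_ratio(groups: GateGroups, stages: pd.Series | None = None) -> pd.Series | float:
    """|dp| / (|dp| + |pmn_like| + |p3_like|), optionally per stage.

    Stages with no gated cells are reported as NaN.
    """
    if stages is None:
        denom = len(groups.dp) + len(groups.pmn_like) + len(groups.p3_like)
        return len(groups.dp) / denom if denom else np.nan
    per_stage = {}
    for stage in pd.unique(stages):
        in_stage = set(stages.index[stages == stage])
        n_dp = len(set(groups.dp) & in_stage)
        n_all = n_dp + len(set(groups.pmn_like) & in_stage) + len(set(groups.p3_like) & in_stage)
        per_stage[stage] = n_dp / n_all if n_all else np.nan
    return pd.Series(per_stage, name="dp_ratio")


def default_gene_space(km: KnowledgeMatrix, nm: NormalizedMatrix) -> list[str]:
    """Marker genes of the knowledge matrix plus the gliogenic panel,
    excluding the gate/pan genes themselves, intersected with the dataset."""
    genes = list(dict.fromkeys(list(km.marker_genes) + list(GLIOGENIC_GENES)))
    drop = {GATE_A, GATE_B, PROGENITOR_PAN, NEURON_PAN}
    return [g for g in genes if g in nm.genes and g not in drop]


def _profile(nm: NormalizedMatrix, barcodes: pd.Index, gene_idx: np.ndarray) -> np.ndarray:
    idx = nm.cells.get_indexer(barcodes)
    return nm.values[np.ix_(gene_idx, idx)].mean(axis=1)


def _similarity(x: np.ndarray, y: np.ndarray, metric: str) -> float:
    if metric == "pearson":
        if np.std(x) == 0 or np.std(y) == 0:
            return np.nan
        r = float(np.corrcoef(x, y)[0, 1])
        return (r + 1.0) / 2.0
    if metric == "euclidean":
        return 1.0 / (1.0 + float(np.linalg.norm(x - y)))
    raise ValueError(f"unknown similarity metric {metric!r}")


def dp_similarity(
    nm: NormalizedMatrix,
    groups: GateGroups,
    assignment: pd.DataFrame,
    gene_space: list[str],
    min_cells: int = DEFAULT_MIN_CELLS,
    metric: str = "pearson",
    stage_col: str = "stage",
    type_col: str = "subtype",
) -> pd.DataFrame:
    """Per-stage similarity of the double-positive profile to pMN and p3.

    Profiles are mean expression over ``gene_space``; similarity is
    (Pearson r + 1)/2 by default (``metric='euclidean'`` gives 1/(1+d)),
    so values lie in [0, 1] with 1 = identical profile.  Entries with
    fewer than ``min_cells`` cells in either group are NaN.
    """
    gene_idx = nm.genes.get_indexer([g for g in gene_space if g in nm.genes])
    if len(gene_idx) < 2:
        raise ValueError("gene space too small for a similarity profile")
    assignment = assignment.loc[assignment.index.intersection(nm.cells)]
    stages = pd.unique(assignment[stage_col])
    out = pd.DataFrame(index=pd.Index(stages, name="stage"), columns=["pMN", "p3"], dtype=float)
    dp_set = set(groups.dp)
    for stage in stages:
        stage_cells = assignment.index[assignment[stage_col] == stage]
        dp_cells = pd.Index([c for c in stage_cells if c in dp_set])
        if len(dp_cells) < min_cells:
            continue
        dp_prof = _profile(nm, dp_cells, gene_idx)
        for ref in ("pMN", "p3"):
            ref_cells = stage_cells[
                (assignment.loc[stage_cells, type_col] == ref).to_numpy()
            ]
            if len(ref_cells) < min_cells:
                continue
            out.loc[stage, ref] = _similarity(
                dp_prof, _profile(nm, ref_cells, gene_idx), metric
            )
    return out
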