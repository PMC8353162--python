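"""Depth-scaled log normalisation and gene-module scoring.

Module scores follow the matched-control convention: genes are ranked by
dataset-wide mean expression, cut into equal-frequency bins, and each
module gene contributes control genes drawn from its own bin; the score is
the per-cell mean expression of the module minus that of the control pool.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .counts_io import CountMatrix

#: gliogenic marker panel used for the gliogenic programme score
GLIOGENIC_GENES = (
    "FABP7", "SOX9", "SOX10", "PDGFRA", "CSPG4", "FGFR3",
    "FGFBP3", "DBI", "SLC1A3", "HOPX", "ALDH1L1",
)

DEFAULT_N_BINS = 24
DEFAULT_N_CTRL = 100


@dataclass
class NormalizedMatrix:
    """Dense genes x cells real-valued expression with its normalisation descriptor."""

    values: np.ndarray
    genes: pd.Index
    cells: pd.Index
    target_depth: float = 1e4
    pseudo_count: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.genes = pd.Index(self.genes, name="gene")
        self.cells = pd.Index(self.cells, name="barcode")
        if self.values.shape != (len(self.genes), len(self.cells)):
            raise ValueError("values shape does not match gene/cell identifiers")
        if not np.isfinite(self.values).all():
            raise ValueError("normalised expression must be finite")

    def expr(self, gene: str) -> np.ndarray:
        return self.values[self.genes.get_loc(gene)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.cells)

    def subset_cells(self, barcodes) -> "NormalizedMatrix":
        idx = self.cells.get_indexer(pd.Index(barcodes))
        if (idx < 0).any():
            raise KeyError("unknown barcodes")
        return NormalizedMatrix(
            self.values[:, idx], self.genes, self.cells[idx],
            self.target_depth, self.pseudo_count,
        )


@dataclass
class GeneModule:
    """A named, de-duplicated marker gene list."""

    name: str
    genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: list[str] = []
        for g in self.genes:
            if g not in seen:
                seen.append(g)
        self.genes = seen
        if not self.genes:
            raise ValueError(f"module {self.name!r} has no genes")


def normalize_log(
    cm: CountMatrix, target_depth: float = 1e4, pseudo_count: float = 1.0
) -> NormalizedMatrix:
    """expression = log(pseudo_count + count * target_depth / cell_total).

    Cells with zero total counts are mapped to all-zero columns.
    """
    if target_depth <= 0:
        raise ValueError("target_depth must be positive")
    counts = cm.counts.tocsc().astype(float)
    totals = np.asarray(counts.sum(axis=0)).ravel()
    scale = np.where(totals > 0, target_depth / np.maximum(totals, 1e-300), 0.0)
    scaled = counts.multiply(scale[None, :]).toarray()
    values = np.log(pseudo_count + scaled)
    values[:, totals == 0] = 0.0
    return NormalizedMatrix(
        values=values,
        genes=cm.genes,
        cells=cm.cells,
        target_depth=target_depth,
        pseudo_count=pseudo_count,
    )


def _expression_bins(nm: NormalizedMatrix, n_bins: int) -> np.ndarray:
    """Equal-frequency bin id per gene, by dataset-wide mean expression."""
    means = nm.values.mean(axis=1)
    order = np.argsort(means, kind="stable")
    ranks = np.empty_like(order)
    ranks[order] = np.arange(len(order))
    return (ranks * n_bins) // len(order)


def module_score(
    nm: NormalizedMatrix,
    module: GeneModule,
    n_bins: int = DEFAULT_N_BINS,
    n_ctrl: int = DEFAULT_N_CTRL,
    seed: int = 0,
) -> pd.Series:
    """Per-cell module score against expression-bin-matched control genes.

    Control genes are sampled with replacement from each module gene's
    expression bin; when ``n_ctrl`` meets or exceeds the bin size the whole
    bin is used exactly once instead (exhaustive controls).
    """
    present = [g for g in module.genes if g in nm.genes]
    missing = [g for g in module.genes if g not in nm.genes]
    if not present:
        raise ValueError(f"no genes of module {module.name!r} found in the dataset")
    if missing:
        warnings.warn(f"module {module.name!r}: {len(missing)} genes absent, ignored")
    n_bins = min(n_bins, len(nm.genes))
    bins = _expression_bins(nm, n_bins)
    rng = np.random.default_rng(seed)

    gene_pos = nm.genes.get_indexer(present)
    ctrl_counts = np.zeros(len(nm.genes), dtype=np.int64)  # control multiset
    for gp in gene_pos:
        pool = np.flatnonzero(bins == bins[gp])
        if n_ctrl >= len(pool):
            # requested pool covers the bin: use it exhaustively (deterministic)
            np.add.at(ctrl_counts, pool, 1)
        else:
            draws = rng.choice(pool, size=n_ctrl, replace=True)
            np.add.at(ctrl_counts, draws, 1)

    module_mean = nm.values[gene_pos].mean(axis=0)
    ctrl_mean = (ctrl_counts @ nm.values) / ctrl_counts.sum()
    return pd.Series(module_mean - ctrl_mean, index=nm.cells, name=module.name)


def score_modules(
    nm: NormalizedMatrix,
    modules: dict[str, list[str]] | list[GeneModule],
    n_bins: int = DEFAULT_N_BINS,
    n_ctrl: int = DEFAULT_N_CTRL,
    seed: int = 0,
) -> pd.DataFrame:
    """Score several modules; one column per module, cells as rows."""
    if isinstance(modules, dict):
        modules = [GeneModule(name, genes) for name, genes in modules.items()]
    cols = {m.name: module_score(nm, m, n_bins, n_ctrl, seed) for m in modules}
    return pd.DataFrame(cols, index=nm.cells)


def cell_cycle_scores(
    nm: NormalizedMatrix,
    s_genes: GeneModule,
    g2m_genes: GeneModule,
    n_bins: int = DEFAULT_N_BINS,
    n_ctrl: int = DEFAULT_N_CTRL,
    seed: int = 0,
) -> pd.DataFrame:
    """S/G2M scores, phase call and their difference (S - G2M).

    Phase is G1 when both scores are <= 0, otherwise the phase of the
    larger score; exact ties go to G2M.
    """
    s = module_score(nm, s_genes, n_bins, n_ctrl, seed)
    g2m = module_score(nm, g2m_genes, n_bins, n_ctrl, seed)
    phase = np.where(
        (s <= 0) & (g2m <= 0), "G1", np.where(s > g2m, "S", "G2M")
    )
    return pd.DataFrame(
        {"s_score": s, "g2m_score": g2m, "phase": phase, "difference": s - g2m},
        index=nm.cells,
    )


def regress_covariate(nm: NormalizedMatrix, covariate: pd.Series | np.ndarray) -> NormalizedMatrix:
    """Mean-preserving residualisation of every gene on a per-cell covariate."""
    cov = (
        covariate.loc[nm.cells].to_numpy()
        if isinstance(covariate, pd.Series)
        else np.asarray(covariate, dtype=float)
    )
    if cov.shape != (len(nm.cells),):
        raise ValueError("covariate must provide one value per cell")
    if not np.isfinite(cov).all():
        raise ValueError("covariate must be finite for all cells")
    centered = cov - cov.mean()
    denom = centered @ centered
    if denom == 0:
        warnings.warn("constant covariate: regression skipped, returning input unchanged")
        return NormalizedMatrix(
            nm.values.copy(), nm.genes, nm.cells, nm.target_depth, nm.pseudo_count
        )
    slopes = (nm.values @ centered) / denom  # per-gene OLS slope
    residual = nm.values - slopes[:, None] * centered[None, :]
    return NormalizedMatrix(residual, nm.genes, nm.cells, nm.target_depth, nm.pseudo_count)


def gliogenic_score(
    nm: NormalizedMatrix,
    n_bins: int = DEFAULT_N_BINS,
    n_ctrl: int = DEFAULT_N_CTRL,
    seed: int = 0,
) -> pd.Series:
    """Module score of the fixed gliogenic marker panel."""
    return module_score(
        nm, GeneModule("gliogenic", list(GLIOGENIC_GENES)), n_bins, n_ctrl, seed
    ).rename("gliogenic")


def default_cell_cycle_modules_safe(
    nm: NormalizedMatrix,
    seed: int = 0,
    n_bins: int = DEFAULT_N_BINS,
    n_ctrl: int = DEFAULT_N_CTRL,
) -> pd.DataFrame | None:
    """Cell-cycle scores with the shipped gene lists, or None when the
    dataset contains none of the S or G2M genes."""
    from .knowledge import default_cell_cycle_modules

    s_genes, g2m_genes = default_cell_cycle_modules()
    if not any(g in nm.genes for g in s_genes) or not any(g in nm.genes for g in g2m_genes):
        return None
    return cell_cycle_scores(
        nm, GeneModule("S", s_genes), GeneModule("G2M", g2m_genes),
        n_bins=n_bins, n_ctrl=n_ctrl, seed=seed,
    )


def write_scores_tsv(scores: pd.DataFrame, path) -> None:
    out = scores.copy()
    out.index.name = "barcode"
    out.to_csv(path, sep="\t")
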