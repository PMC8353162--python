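"""Cross-species and time-course comparison utilities.

Mean per-type expression profiles are compared across species over strict
1:1 orthologs (Pearson), pseudo-bulk stage profiles against bulk in vitro
days after 0-1 scaling (Spearman), and single genes against all others
within a cell subset (targeted correlate discovery).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .scoring import NormalizedMatrix

logger = logging.getLogger(__name__)

DEFAULT_MIN_CELLS = 10
DEFAULT_TOP_K = 30  # default size of the ranked correlate list


def map_orthologs(raw_pairs: pd.DataFrame) -> pd.DataFrame:
    """Strict 1:1 filtering of an ortholog pair table.

    Keeps only pairs whose genes each occur exactly once across the whole
    input (columns ``gene_a``, ``gene_b``).
    """
    if raw_pairs is None or len(raw_pairs) == 0:
        raise ValueError("empty ortholog pair table")
    pairs = raw_pairs[["gene_a", "gene_b"]].copy()
    count_a = pairs["gene_a"].value_counts()
    count_b = pairs["gene_b"].value_counts()
    keep = pairs["gene_a"].map(count_a).eq(1) & pairs["gene_b"].map(count_b).eq(1)
    return pairs.loc[keep].reset_index(drop=True)


def restrict_gene_set(genes: list[str], tf_table: pd.DataFrame) -> list[str]:
    """Order-stable intersection of ``genes`` with the annotated gene column
    of a (gene, term) table."""
    annotated = set(tf_table["gene"]) if len(tf_table) else set()
    seen: set[str] = set()
    out = []
    for g in genes:
        if g in annotated and g not in seen:
            out.append(g)
            seen.add(g)
    return out


def mean_profiles(
    nm: NormalizedMatrix,
    assignment: pd.Series,
    gene_set: list[str] | None = None,
    min_cells: int = DEFAULT_MIN_CELLS,
    type_order: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-type mean expression profiles.

    Returns (profiles, n_cells): profiles is types x genes; types with
    fewer than ``min_cells`` assigned cells are excluded and logged.
    """
    assignment = assignment.loc[nm.cells]
    genes = list(gene_set) if gene_set is not None else list(nm.genes)
    present = [g for g in genes if g in nm.genes]
    sub = nm.values[nm.genes.get_indexer(present)]
    rows, sizes = {}, {}
    for t, grp in pd.Series(np.arange(len(nm.cells)), index=nm.cells).groupby(assignment):
        idx = grp.to_numpy()
        if len(idx) < min_cells:
            logger.info("mean_profiles: excluding %r (%d < %d cells)", t, len(idx), min_cells)
            continue
        rows[t] = sub[:, idx].mean(axis=1)
        sizes[t] = len(idx)
    if not rows:
        raise ValueError(f"no cell type reaches min_cells={min_cells}")
    profiles = pd.DataFrame(rows, index=pd.Index(present, name="gene")).T
    if type_order is not None:
        order = [t for t in type_order if t in profiles.index]
        order += [t for t in profiles.index if t not in order]
        profiles = profiles.loc[order]
    return profiles, pd.Series(sizes, name="n_cells").loc[profiles.index]


def _safe_corr(x: np.ndarray, y: np.ndarray, method: str) -> float:
    if np.std(x) == 0 or np.std(y) == 0:
        return np.nan  # undefined for constant profiles; reported missing
    if method == "pearson":
        return float(stats.pearsonr(x, y)[0])
    if method == "spearman":
        return float(stats.spearmanr(x, y)[0])
    raise ValueError(f"unknown correlation method {method!r}")


def cross_correlate(
    profiles_a: pd.DataFrame,
    profiles_b: pd.DataFrame,
    ortholog_map: pd.DataFrame | None = None,
    method: str = "pearson",
) -> pd.DataFrame:
    """Type x type correlation matrix over (mapped) shared genes.

    ``ortholog_map`` translates species-B gene names (``gene_b``) into the
    species-A namespace (``gene_a``) before intersecting; ``None`` means
    the two profile matrices already share a namespace.
    """
    b = profiles_b.copy()
    if ortholog_map is not None:
        translate = dict(zip(ortholog_map["gene_b"], ortholog_map["gene_a"]))
        b = b.loc[:, b.columns.isin(translate)].rename(columns=translate)
    shared = [g for g in profiles_a.columns if g in set(b.columns)]
    if len(shared) < 2:
        raise ValueError("need >=2 shared genes after ortholog mapping")
    A = profiles_a[shared].to_numpy(dtype=float)
    B = b[shared].to_numpy(dtype=float)
    out = np.empty((A.shape[0], B.shape[0]))
    for i in range(A.shape[0]):
        for j in range(B.shape[0]):
            out[i, j] = _safe_corr(A[i], B[j], method)
    return pd.DataFrame(out, index=profiles_a.index, columns=b.index)


def minmax_scale_columns(df: pd.DataFrame) -> pd.DataFrame:
    """Scale each column (time point) to [0, 1]; constant columns -> NaN."""
    lo, hi = df.min(axis=0), df.max(axis=0)
    span = hi - lo
    scaled = (df - lo) / span.replace(0, np.nan)
    return scaled


def staging_correlation(
    pseudobulk: pd.DataFrame,
    bulk: pd.DataFrame,
    gene_subset: list[str] | None = None,
) -> pd.DataFrame:
    """Spearman matrix between in vivo stages and in vitro days.

    Both matrices are genes x time-point tables; each time point is min-max
    scaled to [0, 1] over the shared gene subset before correlating.  (The
    scaling is monotone so Spearman is unchanged; it is applied for
    comparability of the stored intermediate tables.)
    """
    genes = gene_subset if gene_subset is not None else list(pseudobulk.index)
    shared = [g for g in genes if g in pseudobulk.index and g in bulk.index]
    if not shared:
        raise ValueError("empty shared gene subset")
    vivo = minmax_scale_columns(pseudobulk.loc[shared])
    vitro = minmax_scale_columns(bulk.loc[shared])
    out = np.empty((vivo.shape[1], vitro.shape[1]))
    for i, ci in enumerate(vivo.columns):
        for j, cj in enumerate(vitro.columns):
            x, y = vivo[ci].to_numpy(), vitro[cj].to_numpy()
            if np.isnan(x).all() or np.isnan(y).all():
                out[i, j] = np.nan
                continue
            out[i, j] = _safe_corr(x, y, "spearman")
    return pd.DataFrame(out, index=vivo.columns, columns=vitro.columns)


def correlated_genes(
    nm: NormalizedMatrix,
    target_gene: str,
    cell_subset: list[str] | np.ndarray | None = None,
    k: int = DEFAULT_TOP_K,
) -> pd.DataFrame:
    """Top-k genes most positively Spearman-correlated with a target gene.

    Computed within ``cell_subset`` (default: all cells).  Only positive
    correlates are returned, sorted by descending coefficient with ties
    broken alphabetically; the list is shorter than k when fewer positive
    correlates exist.
    """
    sub = nm if cell_subset is None else nm.subset_cells(cell_subset)
    if target_gene not in sub.genes:
        raise KeyError(f"target gene {target_gene!r} not in dataset")
    target = sub.expr(target_gene)
    if (target > 0).sum() < 3:
        raise ValueError(f"target gene {target_gene!r} expressed in <3 cells of the subset")
    rows = []
    for g in sub.genes:
        if g == target_gene:
            continue
        rho = _safe_corr(target, sub.expr(g), "spearman")
        if not np.isnan(rho) and rho > 0:
            rows.append((g, rho))
    rows.sort(key=lambda r: (-r[1], r[0]))
    return pd.DataFrame(rows[:k], columns=["gene", "rho"])
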