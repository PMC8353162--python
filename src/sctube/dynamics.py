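"""Stage-resolved composition, territory grouping and expression summaries."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import UNASSIGNED
from .counts_io import CountMatrix
from .knowledge import KnowledgeMatrix
from .scoring import NormalizedMatrix

#: progenitor territory grouping along the DV axis; FP/RP stay separate
TERRITORY_OF = {
    "dp1": "pD", "dp2": "pD", "dp3": "pD", "dp4": "pD", "dp5": "pD", "dp6": "pD",
    "p0": "pI", "p1": "pI", "p2": "pI",
    "pMN": "pMN",
    "p3": "p3",
    "FP": "FP", "RP": "RP",
}

#: neuronal class -> progenitor domain of origin (neurogenesis-rate proxy)
DEFAULT_DOMAIN_PAIRING = {
    "dI1": "dp1", "dI2": "dp2", "dI3": "dp3", "dI4": "dp4", "dI5": "dp5", "dI6": "dp6",
    "V0": "p0", "V1": "p1", "V2": "p2", "MN": "pMN", "V3": "p3",
}


@dataclass
class CompositionTable:
    """Stage x cell-type counts and per-stage proportions."""

    counts: pd.DataFrame
    proportions: pd.DataFrame
    denominator: str

    def __post_init__(self) -> None:
        sums = self.proportions.sum(axis=1)
        nonzero = sums[self.counts.sum(axis=1) > 0]
        if len(nonzero) and not np.allclose(nonzero, 1.0, atol=1e-9):
            raise ValueError("proportions must sum to 1 per stage")


def composition_table(
    assignment: pd.DataFrame,
    denominator: str = "assigned",
    km: KnowledgeMatrix | None = None,
    stage_col: str = "stage",
    type_col: str = "subtype",
) -> CompositionTable:
    """Counts and proportions of cell types per stage.

    ``denominator`` selects which columns the proportions are relative to:
    ``assigned`` (every labelled type; Unassigned tracked but excluded),
    ``all`` (including Unassigned), or ``progenitors_neurons`` (CNS
    progenitor + neuron classes only; requires ``km``).
    """
    if len(assignment) == 0:
        raise ValueError("empty assignment")
    counts = (
        assignment.groupby([stage_col, type_col], sort=False, observed=True)
        .size()
        .unstack(fill_value=0)
    )
    counts = counts.loc[:, sorted(counts.columns)]
    if denominator == "assigned":
        denom_cols = [c for c in counts.columns if c not in (UNASSIGNED, "")]
    elif denominator == "all":
        denom_cols = list(counts.columns)
    elif denominator == "progenitors_neurons":
        if km is None:
            raise ValueError("denominator='progenitors_neurons' needs a knowledge matrix")
        keep = set(km.types_of_class("progenitor", "neuron"))
        denom_cols = [c for c in counts.columns if c in keep]
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    if not denom_cols:
        raise ValueError("denominator selects no cell-type columns")
    totals = counts[denom_cols].sum(axis=1)
    proportions = counts[denom_cols].div(totals.replace(0, np.nan), axis=0).fillna(0.0)
    return CompositionTable(counts=counts, proportions=proportions, denominator=denominator)


def group_territories(
    assignment: pd.DataFrame,
    km: KnowledgeMatrix,
    stage_col: str = "stage",
    type_col: str = "subtype",
) -> CompositionTable:
    """Group progenitor subtypes into pD / pI / pMN / p3 territories.

    FP and RP are reported as separate categories; proportions are over the
    four territories (FP/RP excluded from the denominator).
    """
    progenitors = set(km.types_of_class("progenitor"))
    sub = assignment[assignment[type_col].isin(progenitors)].copy()
    unknown = sorted(set(sub[type_col]) - set(TERRITORY_OF))
    if unknown:
        raise ValueError(f"progenitor subtype(s) without a territory: {unknown}")
    sub["territory"] = sub[type_col].map(TERRITORY_OF)
    counts = (
        sub.groupby([stage_col, "territory"], sort=False, observed=True)
        .size()
        .unstack(fill_value=0)
    )
    for terr in ("pD", "pI", "pMN", "p3", "FP", "RP"):
        if terr not in counts.columns:
            counts[terr] = 0
    counts = counts[["pD", "pI", "pMN", "p3", "FP", "RP"]]
    denom_cols = ["pD", "pI", "pMN", "p3"]
    totals = counts[denom_cols].sum(axis=1)
    proportions = counts[denom_cols].div(totals.replace(0, np.nan), axis=0).fillna(0.0)
    return CompositionTable(counts=counts, proportions=proportions, denominator="territories")


def neurogenesis_rate(
    assignment: pd.DataFrame,
    domain_pairing: dict[str, str] | None = None,
    stage_col: str = "stage",
    type_col: str = "subtype",
) -> pd.DataFrame:
    """Neurons-over-progenitors ratio per domain per stage.

    Zero progenitors with neurons present -> ``inf``; both zero -> NaN.
    """
    pairing = domain_pairing if domain_pairing is not None else DEFAULT_DOMAIN_PAIRING
    counts = (
        assignment.groupby([stage_col, type_col], sort=False, observed=True)
        .size()
        .unstack(fill_value=0)
    )
    stages = counts.index
    out = pd.DataFrame(index=stages, columns=sorted(set(pairing.values())), dtype=float)
    for neuron, domain in pairing.items():
        n_neu = counts[neuron] if neuron in counts.columns else pd.Series(0, index=stages)
        n_pro = counts[domain] if domain in counts.columns else pd.Series(0, index=stages)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = n_neu.to_numpy(float) / n_pro.to_numpy(float)
        ratio[(n_neu.to_numpy() == 0) & (n_pro.to_numpy() == 0)] = np.nan
        out[domain] = ratio
    return out


def expression_summary(
    nm: NormalizedMatrix,
    cm: CountMatrix,
    assignment: pd.DataFrame,
    genes: list[str],
    detect_threshold: float = 0.0,
    highlight_threshold: float = 0.10,
    stage_col: str = "stage",
    group_col: str = "subtype",
) -> pd.DataFrame:
    """Long-format dot-plot summary per (stage, group, gene).

    fraction_expressing counts raw counts > ``detect_threshold``;
    mean_expression averages normalised expression; mean_counts_per_cell
    averages raw counts.  A gene is ``highlighted`` when its
    mean_counts_per_cell reaches ``highlight_threshold`` in any group.
    Genes absent from the dataset are reported as all-zero (and warned).
    """
    missing = [g for g in genes if g not in cm.genes]
    if missing:
        warnings.warn(f"expression_summary: {len(missing)} genes absent: {missing[:5]}")
    assignment = assignment.loc[cm.cells]
    groups = assignment.groupby([stage_col, group_col], sort=True, observed=True).groups
    rows = []
    for (stage, group), barcodes in groups.items():
        idx = cm.cells.get_indexer(barcodes)
        for g in genes:
            if g in cm.genes:
                raw = np.asarray(cm.counts[cm.genes.get_loc(g)].todense()).ravel()[idx]
                norm = nm.expr(g)[nm.cells.get_indexer(cm.cells[idx])]
                frac = float((raw > detect_threshold).mean())
                rows.append((stage, group, g, frac, float(norm.mean()), float(raw.mean())))
            else:
                rows.append((stage, group, g, 0.0, 0.0, 0.0))
    out = pd.DataFrame(
        rows,
        columns=[
            "stage", "group", "gene",
            "fraction_expressing", "mean_expression", "mean_counts_per_cell",
        ],
    )
    peak = out.groupby("gene")["mean_counts_per_cell"].transform("max")
    out["highlighted"] = peak >= highlight_threshold
    return out


def plot_dotplot(summary: pd.DataFrame, path, stage: str | None = None) -> None:
    """Convenience dot-plot rendering (size=fraction, colour=mean expression)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = summary if stage is None else summary[summary["stage"] == stage]
    groups = sorted(sub["group"].unique())
    genes = list(dict.fromkeys(sub["gene"]))
    fig, ax = plt.subplots(figsize=(1 + 0.4 * len(groups), 1 + 0.3 * len(genes)))
    x = sub["group"].map({g: i for i, g in enumerate(groups)})
    y = sub["gene"].map({g: i for i, g in enumerate(genes)})
    sc = ax.scatter(x, y, s=200 * sub["fraction_expressing"], c=sub["mean_expression"],
                    cmap="viridis")
    ax.set_xticks(range(len(groups)), groups, rotation=90)
    ax.set_yticks(range(len(genes)), genes)
    fig.colorbar(sc, ax=ax, label="mean expression")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
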