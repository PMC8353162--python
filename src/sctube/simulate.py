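"""Ground-truthed negative-binomial count simulation.

Cells draw NB counts with mean ``mu_on * depth`` for the required markers
of their type (plus a small per-class structural gene programme) and
``mu_off * depth`` for every other marker.  Housekeeping genes are always
on at gene-specific levels, mitochondrial genes form a dedicated ``MT-``
block tuned to a target UMI fraction, and a male-specific gene (``SRY``)
is expressed only in samples designated male.  Everything is deterministic
under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .counts_io import CountMatrix
from .knowledge import KnowledgeMatrix, default_tissue_modules

SEX_GENE = "SRY"
MITO_PREFIX = "MT-"

#: structural genes switched on per type class, on top of required markers
CLASS_PROGRAMS: dict[str, list[str]] = {
    "progenitor": ["TUBB2B", "NES", "SOX21", "VIM"],
    "neuron": ["STMN2", "MAP2", "TUBB2B"],
    "pns_progenitor": ["VIM", "NES"],
    "pns_precursor": ["TUBB2B"],
    "pns_neuron": ["STMN2", "MAP2", "PRPH"],
    "glia": ["FABP7", "SOX9", "DBI", "SLC1A3", "VIM"],
}


def default_contaminant_programs() -> dict[str, list[str]]:
    """Gene programmes for non-neural contaminant tissues (mesoderm, blood, skin)."""
    from .knowledge import NEURAL_MODULE_NAMES

    modules = default_tissue_modules()
    return {name: genes for name, genes in modules.items() if name not in NEURAL_MODULE_NAMES}


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the count generator.

    ``dispersion`` is the NB inverse-dispersion (size) parameter theta, so
    Var = mu + mu^2/theta; ``math.inf`` gives the Poisson limit.
    ``depth_sigma`` is the sigma of the log-normal per-cell library-size
    multiplier, normalised to mean 1.
    """

    mu_on: float = 20.0
    mu_off: float = 0.05
    dispersion: float = 8.0
    n_housekeeping: int = 200
    mito_frac_mean: float = 0.05
    n_mito_genes: int = 10
    depth_sigma: float = 0.3
    n_type_markers: int = 0
    hk_mu_range: tuple[float, float] = (0.5, 20.0)
    sry_mu: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.mu_on > self.mu_off >= 0:
            raise ValueError("need mu_on > mu_off >= 0")
        if not self.dispersion > 0:
            raise ValueError("dispersion must be positive")
        if not 0 <= self.mito_frac_mean < 1:
            raise ValueError("mito_frac_mean must lie in [0, 1)")
        if self.n_housekeeping < 0 or self.n_mito_genes < 0 or self.n_type_markers < 0:
            raise ValueError("gene counts must be non-negative")
        if self.depth_sigma < 0:
            raise ValueError("depth_sigma must be non-negative")


@dataclass(frozen=True)
class StageComposition:
    """One sample: a stage label, its cell-type mixture and size."""

    stage_label: str
    type_proportions: dict[str, float]
    n_cells: int
    sex: str = "female"

    def __post_init__(self) -> None:
        if self.n_cells <= 0:
            raise ValueError("n_cells must be positive")
        props = np.array(list(self.type_proportions.values()), dtype=float)
        if (props < 0).any():
            raise ValueError("proportions must be non-negative")
        if abs(props.sum() - 1.0) > 1e-9:
            raise ValueError(f"proportions must sum to 1 (got {props.sum():.12f})")
        if self.sex not in ("male", "female"):
            raise ValueError("sex must be 'male' or 'female'")


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, theta: float) -> np.ndarray:
    if math.isinf(theta):
        return rng.poisson(mean)
    p = theta / (theta + mean)
    return rng.negative_binomial(theta, p)


def _type_marker_genes(km: KnowledgeMatrix, params: SimulationParams) -> dict[str, list[str]]:
    """Private TF-like marker genes per knowledge-matrix type (optional).

    These model the many type-specific genes of a real transcriptome; they
    are not part of the knowledge matrix, so classification ignores them,
    but cross-species profiles gain realistic per-type signal.
    """
    if params.n_type_markers == 0:
        return {}
    return {
        t: [f"TF-{t}-{j:02d}" for j in range(params.n_type_markers)] for t in km.types
    }


def _gene_universe(
    km: KnowledgeMatrix, programs: dict[str, list[str]], params: SimulationParams
) -> tuple[list[str], list[str], list[str]]:
    signal: list[str] = []
    for g in km.marker_genes:
        if g not in signal:
            signal.append(g)
    for prog in list(CLASS_PROGRAMS.values()) + list(programs.values()):
        for g in prog:
            if g not in signal:
                signal.append(g)
    for extras in _type_marker_genes(km, params).values():
        signal.extend(extras)
    hk = [f"HK{i:04d}" for i in range(params.n_housekeeping)]
    mito = [f"{MITO_PREFIX}G{i:02d}" for i in range(params.n_mito_genes)]
    return signal, hk, mito


def _on_genes(km: KnowledgeMatrix, programs: dict[str, list[str]], cell_type: str) -> list[str]:
    if cell_type in km.types:
        return km.required(cell_type) + CLASS_PROGRAMS.get(km.classes[cell_type], [])
    if cell_type in programs:
        return list(programs[cell_type])
    raise KeyError(f"unknown type label {cell_type!r}")


def simulate_counts(
    km: KnowledgeMatrix,
    comp: StageComposition,
    params: SimulationParams,
    contaminant_programs: dict[str, list[str]] | None = None,
    exact_proportions: bool = False,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Draw one ground-truthed sample.

    Returns the count matrix and a per-cell annotation frame with columns
    sample, stage, sex, truth_type, truth_tissue.  By default cell types
    are drawn multinomially from the composition; ``exact_proportions``
    instead apportions cell counts deterministically (largest remainder)
    and shuffles their order — use it when every type must be present with
    its nominal cell count.
    """
    programs = (
        contaminant_programs if contaminant_programs is not None else default_contaminant_programs()
    )
    for t in comp.type_proportions:
        _on_genes(km, programs, t)  # raises on unknown labels

    rng = np.random.default_rng(params.seed)
    signal, hk, mito = _gene_universe(km, programs, params)
    genes = signal + hk + mito + [SEX_GENE]
    gene_index = pd.Index(genes, name="gene")
    n_signal, n_hk, n_mito = len(signal), len(hk), len(mito)

    types = list(comp.type_proportions)
    props = np.array([comp.type_proportions[t] for t in types], dtype=float)
    props = props / props.sum()
    if exact_proportions:
        quota = props * comp.n_cells
        counts_per_type = np.floor(quota).astype(int)
        remainder = comp.n_cells - counts_per_type.sum()
        for i in np.argsort(-(quota - np.floor(quota)), kind="stable")[:remainder]:
            counts_per_type[i] += 1
        type_idx = rng.permutation(np.repeat(np.arange(len(types)), counts_per_type))
    else:
        type_idx = rng.choice(len(types), size=comp.n_cells, p=props)

    # per-type base means over the signal block
    base = np.full((n_signal, len(types)), params.mu_off)
    sig_pos = {g: i for i, g in enumerate(signal)}
    extras = _type_marker_genes(km, params)
    for j, t in enumerate(types):
        for g in _on_genes(km, programs, t) + extras.get(t, []):
            base[sig_pos[g], j] = params.mu_on
    hk_mu = np.exp(
        rng.uniform(
            np.log(params.hk_mu_range[0]), np.log(params.hk_mu_range[1]), size=n_hk
        )
    )

    if params.depth_sigma > 0:
        depth = rng.lognormal(0.0, params.depth_sigma, comp.n_cells)
        depth /= math.exp(params.depth_sigma**2 / 2)  # mean-1 multiplier
    else:
        depth = np.ones(comp.n_cells)

    mean = np.empty((len(genes), comp.n_cells))
    mean[:n_signal] = base[:, type_idx] * depth
    mean[n_signal : n_signal + n_hk] = hk_mu[:, None] * depth
    # mito block targets E[mito / total] = mito_frac_mean
    nonmito_total = mean[: n_signal + n_hk].sum(axis=0)
    if n_mito and params.mito_frac_mean > 0:
        ratio = params.mito_frac_mean / (1 - params.mito_frac_mean)
        mean[n_signal + n_hk : n_signal + n_hk + n_mito] = (
            ratio * nonmito_total / n_mito
        )
    else:
        mean[n_signal + n_hk : n_signal + n_hk + n_mito] = 0.0
    mean[-1] = params.sry_mu * depth if comp.sex == "male" else 0.0

    counts = _nb_sample(rng, mean, params.dispersion).astype(np.int64)

    barcodes = pd.Index(
        [f"{comp.stage_label}:BC{i:06d}" for i in range(comp.n_cells)], name="barcode"
    )
    truth_type = [types[j] for j in type_idx]
    truth_tissue = ["neural" if t in km.types else t for t in truth_type]
    annotation = pd.DataFrame(
        {
            "sample": comp.stage_label,
            "stage": comp.stage_label,
            "sex": comp.sex,
            "truth_type": truth_type,
            "truth_tissue": truth_tissue,
        },
        index=barcodes,
    )
    cm = CountMatrix(
        counts=sp.csr_matrix(counts),
        genes=gene_index,
        cells=barcodes,
        cell_meta=annotation[["sample", "stage"]].copy(),
    )
    return cm, annotation


def simulate_timecourse(
    stages: list[StageComposition],
    params: SimulationParams,
    km: KnowledgeMatrix | None = None,
    contaminant_programs: dict[str, list[str]] | None = None,
) -> list[tuple[CountMatrix, pd.DataFrame]]:
    """One dataset per stage, with per-stage sub-seeds derived from ``params.seed``."""
    if not stages:
        raise ValueError("empty stage list")
    from .knowledge import default_knowledge_matrix

    km = km if km is not None else default_knowledge_matrix()
    child_seeds = np.random.SeedSequence(params.seed).generate_state(len(stages))
    out = []
    for comp, seed in zip(stages, child_seeds):
        stage_params = replace(params, seed=int(seed))
        out.append(simulate_counts(km, comp, stage_params, contaminant_programs))
    return out


def concat_datasets(
    datasets: list[tuple[CountMatrix, pd.DataFrame]]
) -> tuple[CountMatrix, pd.DataFrame]:
    """Stack per-stage datasets that share a gene universe into one matrix."""
    genes = datasets[0][0].genes
    for cm, _ in datasets[1:]:
        if not cm.genes.equals(genes):
            raise ValueError("datasets must share an identical gene list")
    counts = sp.hstack([cm.counts for cm, _ in datasets], format="csr")
    cells = pd.Index(np.concatenate([cm.cells for cm, _ in datasets]), name="barcode")
    meta = pd.concat([cm.cell_meta for cm, _ in datasets])
    anno = pd.concat([a for _, a in datasets])
    return CountMatrix(counts=counts, genes=genes, cells=cells, cell_meta=meta), anno


def default_timecourse_preset(
    km: KnowledgeMatrix | None = None,
    n_cells: int = 3000,
    stage_labels: tuple[str, ...] = ("CS12", "CS14", "CS17", "CS19"),
    contaminant_frac: tuple[float, ...] = (0.25, 0.2, 0.1, 0.05),
    progenitor_frac: tuple[float, ...] = (0.62, 0.5, 0.34, 0.2),
    pns_frac: float = 0.1,
) -> list[StageComposition]:
    """Four-stage preset: progenitor-rich/ventral-biased early, neuron-rich/
    dorsal-biased late, with contaminant tissue enriched at early stages.

    Neuron share of the truth table strictly increases across stages.
    """
    from .knowledge import default_knowledge_matrix

    km = km if km is not None else default_knowledge_matrix()
    progs = km.dv_ordered_progenitors()
    neurons = km.types_of_class("neuron")
    pns = km.types_of_class("pns_progenitor", "pns_precursor", "pns_neuron")
    n_stage = len(stage_labels)
    males = {stage_labels[0], stage_labels[2]} & set(stage_labels)

    comps = []
    for i, label in enumerate(stage_labels):
        c_frac, p_frac = contaminant_frac[i], progenitor_frac[i]
        n_frac = 1.0 - c_frac - p_frac - pns_frac
        # ventral bias early -> dorsal bias late, linear in DV order
        tilt = 1.0 - 2.0 * i / max(n_stage - 1, 1)  # +1 .. -1
        prog_w = np.array(
            [1.0 + 0.6 * tilt * (r / (len(progs) - 1) - 0.5) * 2 for r in range(len(progs))]
        )
        neu_w = np.array(
            [1.0 + 0.6 * tilt * (r / (len(neurons) - 1) - 0.5) * 2 for r in range(len(neurons))]
        )
        props: dict[str, float] = {}
        for t, w in zip(progs, prog_w / prog_w.sum()):
            props[t] = p_frac * w
        for t, w in zip(neurons, neu_w / neu_w.sum()):
            props[t] = n_frac * w
        pns_weights = {t: (2.0 if km.classes[t] == "pns_progenitor" else 1.0) for t in pns}
        wsum = sum(pns_weights.values())
        for t in pns:
            props[t] = pns_frac * pns_weights[t] / wsum
        props["mesoderm"] = c_frac * 0.6
        props["blood"] = c_frac * 0.25
        props["skin"] = c_frac * 0.15
        total = sum(props.values())
        props = {t: v / total for t, v in props.items()}
        comps.append(
            StageComposition(
                stage_label=label,
                type_proportions=props,
                n_cells=n_cells,
                sex="male" if label in males else "female",
            )
        )
    return comps


# ---------------------------------------------------------------------------
# cross-species pair
# ---------------------------------------------------------------------------


def _speciesb_name(gene: str) -> str:
    """Map a species-A gene symbol to a disjoint species-B namespace."""
    return gene[0].upper() + gene[1:].lower() + "-b" if gene else gene


@dataclass
class OrthologPairSim:
    """Paired two-species simulation with ortholog-map bookkeeping."""

    counts_a: CountMatrix
    anno_a: pd.DataFrame
    counts_b: CountMatrix
    anno_b: pd.DataFrame
    pairs: pd.DataFrame  # raw map (gene_a, gene_b), possibly corrupted
    true_one_to_one: pd.DataFrame  # the clean 1:1 subset, by construction


def simulate_ortholog_pair(
    km: KnowledgeMatrix,
    comp_a: StageComposition,
    comp_b: StageComposition,
    ortholog_noise: float,
    params: SimulationParams,
    contaminant_programs: dict[str, list[str]] | None = None,
) -> OrthologPairSim:
    """Two datasets over disjoint gene namespaces linked by an ortholog map.

    ``ortholog_noise`` is the fraction of genes whose mapping is corrupted:
    half of those are dropped from the map, the other half get a duplicate
    (many-to-one) entry, so strict 1:1 filtering must discard them.
    """
    if not 0 <= ortholog_noise <= 1:
        raise ValueError("ortholog_noise must lie in [0, 1]")
    seeds = np.random.SeedSequence(params.seed).generate_state(3)
    cm_a, anno_a = simulate_counts(
        km, comp_a, replace(params, seed=int(seeds[0])), contaminant_programs
    )
    cm_b, anno_b = simulate_counts(
        km, comp_b, replace(params, seed=int(seeds[1])), contaminant_programs
    )
    b_names = pd.Index([_speciesb_name(g) for g in cm_b.genes], name="gene")
    cm_b = CountMatrix(
        counts=cm_b.counts, genes=b_names, cells=cm_b.cells, cell_meta=cm_b.cell_meta
    )

    rng = np.random.default_rng(int(seeds[2]))
    genes_a = list(cm_a.genes)
    pairs = [(g, _speciesb_name(g)) for g in genes_a]
    n_corrupt = int(round(ortholog_noise * len(pairs)))
    corrupt_idx = rng.choice(len(pairs), size=n_corrupt, replace=False)
    dropped = set(corrupt_idx[: n_corrupt // 2].tolist())
    duplicated = [i for i in corrupt_idx.tolist() if i not in dropped]

    raw = [p for i, p in enumerate(pairs) if i not in dropped]
    for i in duplicated:
        raw.append((f"{pairs[i][0]}_ALT", pairs[i][1]))  # makes gene_b non-unique
    clean = [p for i, p in enumerate(pairs) if i not in dropped and i not in set(duplicated)]
    return OrthologPairSim(
        counts_a=cm_a,
        anno_a=anno_a,
        counts_b=cm_b,
        anno_b=anno_b,
        pairs=pd.DataFrame(raw, columns=["gene_a", "gene_b"]),
        true_one_to_one=pd.DataFrame(clean, columns=["gene_a", "gene_b"]),
    )


# ---------------------------------------------------------------------------
# bulk time course
# ---------------------------------------------------------------------------


def expected_profile(
    km: KnowledgeMatrix,
    cell_type: str,
    params: SimulationParams,
    contaminant_programs: dict[str, list[str]] | None = None,
) -> pd.Series:
    """Expected (depth-1) mean expression of the signal genes for one type."""
    programs = (
        contaminant_programs if contaminant_programs is not None else default_contaminant_programs()
    )
    signal, _, _ = _gene_universe(km, programs, params)
    prof = pd.Series(params.mu_off, index=pd.Index(signal, name="gene"))
    on = _on_genes(km, programs, cell_type) + _type_marker_genes(km, params).get(cell_type, [])
    prof[on] = params.mu_on
    return prof


def simulate_bulk_timecourse(
    km: KnowledgeMatrix,
    trajectory_types: dict[str, list[str]] | None,
    n_days: int,
    params: SimulationParams,
) -> pd.DataFrame:
    """Genes x days bulk matrix interpolating progenitor -> neuron pseudo-bulk.

    Day 0 equals the pure-progenitor pseudo-bulk; the final day the pure
    neuronal pseudo-bulk; intermediate days mix the two linearly, so the
    designed alignment with an in vivo series is the matching
    progenitor:neuron balance.  The output is the deterministic expectation
    (no sampling noise).
    """
    if n_days < 2:
        raise ValueError("n_days must be >= 2")
    if trajectory_types is None:
        trajectory_types = {
            "progenitor": ["p0", "p1", "p2", "pMN", "p3"],
            "neuron": ["V0", "V1", "V2", "MN", "V3"],
        }
    prog = pd.concat(
        [expected_profile(km, t, params) for t in trajectory_types["progenitor"]], axis=1
    ).mean(axis=1)
    neu = pd.concat(
        [expected_profile(km, t, params) for t in trajectory_types["neuron"]], axis=1
    ).mean(axis=1)
    cols = {}
    for d in range(n_days):
        w = d / (n_days - 1)
        cols[f"day_{d}"] = (1 - w) * prog + w * neu
    return pd.DataFrame(cols)


def varying_genes(
    km: KnowledgeMatrix, contaminant_programs: dict[str, list[str]] | None = None
) -> list[str]:
    """The generator's signal genes (markers + class programmes), i.e. the
    genes that vary across cell types — the natural comparison subset."""
    programs = (
        contaminant_programs if contaminant_programs is not None else default_contaminant_programs()
    )
    signal, _, _ = _gene_universe(km, programs, SimulationParams())
    return signal
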