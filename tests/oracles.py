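"""Independent brute-force reference implementations used only by tests.

Deliberately written with plain loops / explicit formulas, not the vectorised
code paths of the package, so agreement is a meaningful check.
"""

import numpy as np


def pearson(x, y):
    """Closed-form Pearson coefficient, no library call."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xm, ym = x - x.mean(), y - y.mean()
    denom = np.sqrt((xm**2).sum() * (ym**2).sum())
    if denom == 0:
        return np.nan
    return float((xm * ym).sum() / denom)


def average_ranks(x):
    """Average ranks (1-based) with tie handling, by explicit grouping."""
    x = np.asarray(x, dtype=float)
    order = np.argsort(x, kind="stable")
    ranks = np.empty(len(x), dtype=float)
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and x[order[j + 1]] == x[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def spearman(x, y):
    return pearson(average_ranks(x), average_ranks(y))


def module_score_exhaustive(frame, module_genes, n_bins):
    """Module score with whole-bin control pools, recomputed from scratch.

    ``frame`` is a genes x cells DataFrame.  Mirrors the documented scoring
    convention (equal-frequency bins on dataset-wide mean, bin multiset
    controls) with independent pandas/loop code.
    """
    means = frame.mean(axis=1)
    order = means.sort_values(kind="stable").index
    bin_of = {}
    n = len(order)
    for rank, gene in enumerate(order):
        bin_of[gene] = (rank * n_bins) // n
    control_pool = []  # multiset of gene names
    for g in module_genes:
        control_pool.extend([h for h in frame.index if bin_of[h] == bin_of[g]])
    module_mean = frame.loc[module_genes].mean(axis=0)
    ctrl_mean = sum(frame.loc[h] for h in control_pool) / len(control_pool)
    return module_mean - ctrl_mean


def assign_bruteforce(binary, km, max_mismatch=0):
    """Cell-by-cell, row-by-row knowledge-matrix assignment.

    ``binary`` is a genes x cells DataFrame of 0/1; returns a list of labels.
    Replicates the gating contract with explicit set logic.
    """
    prog_classes = {"progenitor", "glia", "pns_progenitor"}
    neu_classes = {"neuron", "pns_neuron"}
    labels = []
    for cell in binary.columns:
        positive = set(binary.index[binary[cell] > 0])
        sox2 = "SOX2" in positive
        elavl3 = "ELAVL3" in positive
        if sox2 and not elavl3:
            candidates = [t for t in km.types if km.classes[t] in prog_classes]
        elif elavl3 and not sox2:
            candidates = [t for t in km.types if km.classes[t] in neu_classes]
        else:
            candidates = list(km.types)
        scored = []
        for t in candidates:
            required = set(km.required(t))
            forbidden = set(km.forbidden(t))
            mism = len(required - positive) + len(forbidden & positive)
            scored.append((mism, t))
        if not scored:
            labels.append("Unassigned")
            continue
        best = min(m for m, _ in scored)
        winners = [t for m, t in scored if m == best]
        if best <= max_mismatch and len(winners) == 1:
            labels.append(winners[0])
        else:
            labels.append("Unassigned")
    return labels


def one_to_one_pairs(pairs):
    """Set-arithmetic 1:1 filter over (gene_a, gene_b) tuples."""
    from collections import Counter

    ca = Counter(a for a, _ in pairs)
    cb = Counter(b for _, b in pairs)
    return [(a, b) for a, b in pairs if ca[a] == 1 and cb[b] == 1]
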