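"""Pairwise F_st (Weir-Cockerham theta) with permutation p-values, and
principal coordinates analysis of distance matrices.

Theta follows Weir & Cockerham (1984) for diploid loci, combined across
alleles and loci as the ratio of summed variance components.  X loci are
handled by pooling allele copies (one per male, two per female) through the
haploid ANOVA form of the same estimator, whose between/within components
are added into the same sums.  Negative estimates are retained: they are
the estimator's honest answer near zero differentiation.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .io import GenotypeTable, StrpopError, sort_alleles


@dataclass
class FstMatrix:
    populations: list[str]
    fst: pd.DataFrame  # symmetric, zero diagonal
    p_values: pd.DataFrame  # NaN when no permutations were run
    n_permutations: int
    seed: int


@dataclass
class PCoAResult:
    coordinates: pd.DataFrame  # populations x axes
    eigenvalues: np.ndarray  # all, descending
    proportion_explained: np.ndarray  # over positive eigenvalues only


# -- Weir-Cockerham components ---------------------------------------------


def _diploid_components(C1, C2):
    """Per-allele (a, a+b+c) sums for a pair of populations.

    C1, C2: individuals x alleles integer copy-count matrices (rows sum
    to 2)."""
    r = 2.0
    n1, n2 = len(C1), len(C2)
    nbar = (n1 + n2) / r
    nsum = n1 + n2
    nc = (nsum - (n1 * n1 + n2 * n2) / nsum) / (r - 1.0)
    p1 = C1.sum(axis=0) / (2.0 * n1)
    p2 = C2.sum(axis=0) / (2.0 * n2)
    pbar = (n1 * p1 + n2 * p2) / nsum
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
    h1 = (C1 == 1).sum(axis=0) / n1
    h2 = (C2 == 1).sum(axis=0) / n2
    hbar = (n1 * h1 + n2 * h2) / nsum
    pq = pbar * (1.0 - pbar)
    inner = pq - (r - 1.0) / r * s2 - hbar / 4.0
    a = nbar / nc * (s2 - inner / (nbar - 1.0))
    b = nbar / (nbar - 1.0) * (pq - (r - 1.0) / r * s2 - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar)
    c = hbar / 2.0
    return float(a.sum()), float((a + b + c).sum())


def _haploid_components(counts1, counts2, n1, n2):
    """Per-allele (between, between+within) sums for haploid allele-copy
    counts (ANOVA form: MSP/MSG)."""
    r = 2.0
    nsum = n1 + n2
    nc = (nsum - (n1 * n1 + n2 * n2) / nsum) / (r - 1.0)
    p1 = counts1 / n1
    p2 = counts2 / n2
    pbar = (counts1 + counts2) / nsum
    msp = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / (r - 1.0)
    msg = (n1 * p1 * (1.0 - p1) + n2 * p2 * (1.0 - p2)) / (nsum - r)
    a = (msp - msg) / nc
    return float(a.sum()), float((a + msg).sum())


def _locus_arrays(table: GenotypeTable, locus: str):
    """Per-individual copy-count matrix at a locus plus bookkeeping.

    Returns (sample_ids, C, ploidies) where C[i, j] counts copies of
    allele j carried by individual i (2 for diploid calls, 1 for
    hemizygous male X)."""
    ld = table.locus(locus)
    rows = []
    for s in table.samples:
        g = table.calls.get((s.sample_id, locus))
        if g is not None:
            rows.append((s.sample_id, g))
    alleles = sort_alleles(a for _, g in rows for a in g)
    idx = {a: i for i, a in enumerate(alleles)}
    C = np.zeros((len(rows), len(alleles)), dtype=np.int8)
    ploidy = np.zeros(len(rows), dtype=np.int8)
    ids = []
    for i, (sid, g) in enumerate(rows):
        ids.append(sid)
        ploidy[i] = len(g)
        for a in g:
            C[i, idx[a]] += 1
    return ids, C, ploidy, ld.is_x


def _pair_theta(locus_data, in_pop1: dict[str, bool]) -> float:
    """Multi-locus Weir-Cockerham theta for one population pair given an
    individual -> bool assignment."""
    num = 0.0
    den = 0.0
    for ids, C, ploidy, is_x in locus_data:
        mask = np.array([in_pop1[i] for i in ids])
        if is_x:
            n1 = float(ploidy[mask].sum())
            n2 = float(ploidy[~mask].sum())
            if n1 < 2 or n2 < 2:
                continue
            a, t = _haploid_components(
                C[mask].sum(axis=0).astype(float),
                C[~mask].sum(axis=0).astype(float),
                n1,
                n2,
            )
        else:
            C1, C2 = C[mask], C[~mask]
            if len(C1) < 2 or len(C2) < 2:
                continue
            a, t = _diploid_components(C1.astype(float), C2.astype(float))
        num += a
        den += t
    if den == 0.0:
        return float("nan")
    return num / den


def pairwise_fst(
    table: GenotypeTable,
    loci: Sequence[str] | None = None,
    n_permutations: int = 0,
    seed: int = 0,
) -> FstMatrix:
    """Pairwise Weir-Cockerham theta between every population in the table.

    Permutation p-values (when ``n_permutations`` > 0) reassign individuals
    to the two populations at random and count permuted theta >= observed.
    Negative estimates are retained.
    """
    pops = table.populations
    if len(pops) < 2:
        raise StrpopError("need at least 2 populations")
    for pop in pops:
        if sum(1 for s in table.samples if s.population == pop) < 2:
            raise StrpopError(f"population {pop!r} has fewer than 2 individuals")
    loci = list(loci) if loci is not None else table.locus_names
    rng = np.random.default_rng(seed)

    fst = pd.DataFrame(0.0, index=pops, columns=pops)
    pvals = pd.DataFrame(np.nan, index=pops, columns=pops)
    pop_of = {s.sample_id: s.population for s in table.samples}

    for pa, pb in combinations(pops, 2):
        sub = table.subset(populations=[pa, pb])
        locus_data = [_locus_arrays(sub, l) for l in loci]
        locus_data = [d for d in locus_data if d[1].shape[1] >= 1]
        in_pop1 = {sid: pop_of[sid] == pa for s in sub.samples for sid in [s.sample_id]}
        theta = _pair_theta(locus_data, in_pop1)
        fst.loc[pa, pb] = fst.loc[pb, pa] = theta
        if n_permutations > 0 and np.isfinite(theta):
            ids = [s.sample_id for s in sub.samples]
            labels = np.array([in_pop1[i] for i in ids])
            worse = 0
            for _ in range(n_permutations):
                perm = rng.permutation(labels)
                assign = dict(zip(ids, perm.tolist()))
                if _pair_theta(locus_data, assign) >= theta - 1e-12:
                    worse += 1
            p = (worse + 1) / (n_permutations + 1)
            pvals.loc[pa, pb] = pvals.loc[pb, pa] = p
    return FstMatrix(pops, fst, pvals, n_permutations, seed)


# -- PCoA -------------------------------------------------------------------


def pcoa(distance_matrix: pd.DataFrame | np.ndarray, n_axes: int | None = None) -> PCoAResult:
    """Principal coordinates analysis (classical MDS).

    Gower-centers -D^2/2, eigendecomposes, and scales eigenvectors by the
    square root of their (positive) eigenvalues.  Negative eigenvalues are
    reported but excluded from both the coordinates and the variance
    denominator.
    """
    if isinstance(distance_matrix, pd.DataFrame):
        names = list(distance_matrix.index)
        D = distance_matrix.to_numpy(dtype=float)
    else:
        D = np.asarray(distance_matrix, dtype=float)
        names = [f"item{i}" for i in range(len(D))]
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise StrpopError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise StrpopError("distance matrix must be symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-10):
        raise StrpopError("distance matrix must have a zero diagonal")
    n = len(D)
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval = eigval[order]
    eigvec = eigvec[:, order]
    tol = max(abs(eigval[0]), 1.0) * 1e-12
    pos = eigval > tol
    coords = eigvec[:, pos] * np.sqrt(eigval[pos])
    if n_axes is not None:
        coords = coords[:, :n_axes]
    total_pos = eigval[pos].sum()
    prop = eigval[pos] / total_pos if total_pos > 0 else eigval[pos]
    cols = [f"PCo{i+1}" for i in range(coords.shape[1])]
    return PCoAResult(
        coordinates=pd.DataFrame(coords, index=names, columns=cols),
        eigenvalues=eigval,
        proportion_explained=prop,
    )


def ordered_distance_matrix(distance_matrix: pd.DataFrame) -> pd.DataFrame:
    """Reorder a distance matrix by average-linkage hierarchical clustering
    leaf order (the ordering a heatmap would use)."""
    from scipy.cluster.hierarchy import average, leaves_list
    from scipy.spatial.distance import squareform

    D = distance_matrix.to_numpy(dtype=float)
    # clip tiny negatives (Fst estimates may dip below zero)
    cond = squareform(np.maximum(D, 0.0), checks=False)
    order = leaves_list(average(cond))
    names = [distance_matrix.index[i] for i in order]
    return distance_matrix.loc[names, names]
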