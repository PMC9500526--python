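"""Between-group differentiation: distance matrices, AMOVA/PhiST, MDS.

"FST" throughout this package is the molecular, distance-based PhiST
of a one-level analysis of molecular variance computed from raw
pairwise difference counts, with significance from permutation of
individual group labels.  Kimura two-parameter distances are provided
for tree-oriented comparisons; classical (metric) multidimensional
scaling embeds a PhiST matrix for visualisation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diversity import MISSING, encode_sequences
from .seq_io import Alignment, GroupedAlignment

logger = logging.getLogger(__name__)

TRANSITIONS = {(0, 2), (2, 0), (1, 3), (3, 1)}  # A<->G, C<->T


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric individual-level distance matrix with a metric tag."""

    ids: tuple[str, ...]
    values: np.ndarray
    metric: str  # "raw_differences" | "K2P"

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape mismatch")
        finite = np.isfinite(v)
        if not np.allclose(v[finite], v.T[finite.T], atol=1e-12):
            raise ValueError("distance matrix not symmetric")
        if np.nanmax(np.abs(np.diag(v))) > 1e-12:
            raise ValueError("distance matrix diagonal not zero")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


@dataclass(frozen=True)
class AmovaResult:
    """One-level AMOVA: variance components, PhiST, permutation p."""

    sigma2_among: float
    sigma2_within: float
    phi_st: float
    p_value: float | None
    p_se: float | None
    n_perm: int
    df_among: int
    df_within: int
    ssd_among: float
    ssd_within: float
    ssd_total: float


@dataclass(frozen=True)
class FstMatrix:
    """Groups x groups pairwise PhiST (negative estimates retained)."""

    groups: tuple[str, ...]
    values: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.groups, columns=self.groups)


# ---------------------------------------------------------------------------
# distances


def difference_matrix_from_codes(
    mat: np.ndarray, ids: tuple[str, ...], allow_null: bool = False
) -> DistanceMatrix:
    n = mat.shape[0]
    out = np.zeros((n, n), dtype=float)
    miss = mat == MISSING
    for i in range(n - 1):
        both = ~miss[i] & ~miss[i + 1:]
        if not allow_null and (both.sum(axis=1) == 0).any():
            raise ValueError(
                "a sequence pair shares no complete site; "
                "pass allow_null=True to keep null distances"
            )
        counts = ((mat[i] != mat[i + 1:]) & both).sum(axis=1).astype(float)
        counts[both.sum(axis=1) == 0] = np.nan
        out[i, i + 1:] = counts
        out[i + 1:, i] = counts
    return DistanceMatrix(ids=ids, values=out, metric="raw_differences")


def difference_matrix(aln: Alignment, allow_null: bool = False) -> DistanceMatrix:
    """Pairwise difference counts under pairwise deletion of missing sites."""
    if aln.n < 2:
        raise ValueError("need at least 2 sequences")
    return difference_matrix_from_codes(
        encode_sequences(aln.sequences), aln.ids, allow_null
    )


def k2p_distance(P: float, Q: float) -> float:
    """Kimura 2-parameter distance from transition/transversion proportions."""
    arg = (1.0 - 2.0 * P - Q) * np.sqrt(1.0 - 2.0 * Q)
    if arg <= 0:
        return np.nan
    return float(-0.5 * np.log(arg))


def k2p_matrix(aln: Alignment) -> DistanceMatrix:
    """Kimura 2-parameter distances over jointly complete sites per pair.

    Saturated pairs (log argument <= 0) yield NaN entries with a warning.
    """
    if aln.n < 2:
        raise ValueError("need at least 2 sequences")
    mat = encode_sequences(aln.sequences)
    n = mat.shape[0]
    miss = mat == MISSING
    is_purine = (mat == 0) | (mat == 2)
    out = np.zeros((n, n), dtype=float)
    n_saturated = 0
    for i in range(n):
        for j in range(i + 1, n):
            both = ~miss[i] & ~miss[j]
            m = int(both.sum())
            if m == 0:
                out[i, j] = out[j, i] = np.nan
                continue
            diff = (mat[i] != mat[j]) & both
            ts = diff & (is_purine[i] == is_purine[j])
            P = ts.sum() / m
            Q = (diff.sum() - ts.sum()) / m
            d = k2p_distance(P, Q)
            if np.isnan(d):
                n_saturated += 1
            out[i, j] = out[j, i] = d
    if n_saturated:
        warnings.warn(
            f"{n_saturated} saturated pair(s): K2P log argument <= 0, set NaN"
        )
    return DistanceMatrix(ids=aln.ids, values=out, metric="K2P")


# ---------------------------------------------------------------------------
# AMOVA / PhiST


def _group_indices(
    ids: tuple[str, ...], partition: dict[str, tuple[str, ...]]
) -> list[np.ndarray]:
    pos = {sid: i for i, sid in enumerate(ids)}
    return [
        np.array([pos[sid] for sid in members], dtype=int)
        for members in partition.values()
    ]


def _phi_components(
    d: np.ndarray, labels: np.ndarray, n_groups: int
) -> tuple[float, float, float, float, float, float]:
    """Variance decomposition of a squared-distance matrix by labels.

    Returns (ssd_total, ssd_within, ssd_among, sigma2_among,
    sigma2_within, phi_st).  Distances enter as their own squares, the
    convention for raw difference counts.
    """
    N = d.shape[0]
    P = n_groups
    iu = np.triu_indices(N, k=1)
    ssd_total = d[iu].sum() / N
    ssd_within = 0.0
    sizes = np.empty(P, dtype=float)
    for g in range(P):
        idx = np.flatnonzero(labels == g)
        sizes[g] = idx.size
        sub = d[np.ix_(idx, idx)]
        ssd_within += sub.sum() / 2.0 / idx.size
    ssd_among = ssd_total - ssd_within
    df_among = P - 1
    df_within = N - P
    sigma2_within = ssd_within / df_within
    n_prime = (N - (sizes**2).sum() / N) / df_among
    sigma2_among = (ssd_among / df_among - sigma2_within) / n_prime
    denom = sigma2_among + sigma2_within
    phi = sigma2_among / denom if denom > 0 else 0.0
    return ssd_total, ssd_within, ssd_among, sigma2_among, sigma2_within, phi


def amova(
    dist: DistanceMatrix,
    partition: dict[str, tuple[str, ...]],
    n_perm: int = 10_000,
    seed: int | None = None,
) -> AmovaResult:
    """One-level AMOVA with a permutation test on PhiST.

    The p-value is the +1-smoothed proportion of label permutations
    with PhiST >= observed (ties count, a conservative choice); its
    standard error is the binomial sqrt(p(1-p)/n_perm).  Set
    ``n_perm=0`` to skip the test.
    """
    groups_idx = _group_indices(dist.ids, partition)
    if len(groups_idx) < 2:
        raise ValueError("AMOVA needs at least 2 groups")
    for label, idx in zip(partition, groups_idx):
        if idx.size < 2:
            raise ValueError(f"group {label!r} has fewer than 2 members")
    if 0 < n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is small; p-value will be coarse")
    used = np.concatenate(groups_idx)
    labels = np.empty(used.size, dtype=int)
    offset = 0
    for g, idx in enumerate(groups_idx):
        labels[offset:offset + idx.size] = g
        offset += idx.size
    d = dist.values[np.ix_(used, used)]
    if np.isnan(d).any():
        raise ValueError("null distances present; AMOVA undefined")
    (ssd_total, ssd_within, ssd_among,
     s2_among, s2_within, phi) = _phi_components(d, labels, len(groups_idx))

    p_value = p_se = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        hits = 0
        perm = labels.copy()
        for _ in range(n_perm):
            rng.shuffle(perm)
            phi_perm = _phi_components(d, perm, len(groups_idx))[5]
            if phi_perm >= phi - 1e-12:
                hits += 1
        p_value = (hits + 1) / (n_perm + 1)
        p_se = float(np.sqrt(p_value * (1 - p_value) / n_perm))
    return AmovaResult(
        sigma2_among=s2_among,
        sigma2_within=s2_within,
        phi_st=phi,
        p_value=p_value,
        p_se=p_se,
        n_perm=n_perm,
        df_among=len(groups_idx) - 1,
        df_within=used.size - len(groups_idx),
        ssd_among=ssd_among,
        ssd_within=ssd_within,
        ssd_total=ssd_total,
    )


def pairwise_fst(
    dist: DistanceMatrix, partition: dict[str, tuple[str, ...]]
) -> FstMatrix:
    """Pairwise PhiST between all group pairs (2-group AMOVA each).

    Negative estimates are retained; they are sampling noise around
    zero, informative in the full table.
    """
    groups = tuple(partition)
    idx_by_group = dict(zip(groups, _group_indices(dist.ids, partition)))
    for g, idx in idx_by_group.items():
        if idx.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 members")
    n = len(groups)
    out = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            ia, ib = idx_by_group[groups[i]], idx_by_group[groups[j]]
            used = np.concatenate([ia, ib])
            labels = np.r_[np.zeros(ia.size, int), np.ones(ib.size, int)]
            d = dist.values[np.ix_(used, used)]
            phi = _phi_components(d, labels, 2)[5]
            out[i, j] = out[j, i] = phi
    return FstMatrix(groups=groups, values=out)


def grouped_difference_matrix(ga: GroupedAlignment) -> DistanceMatrix:
    """Raw difference matrix restricted to the partitioned samples."""
    ids = tuple(sid for members in ga.partition.values() for sid in members)
    return difference_matrix(ga.alignment.subset(ids))


# ---------------------------------------------------------------------------
# classical MDS


def classical_mds(fst: FstMatrix | np.ndarray, k: int = 2):
    """Classical (Torgerson) MDS of a dissimilarity matrix.

    Negative entries are clamped to zero (logged) before
    double-centering B = -1/2 J D^2 J; coordinates are the top-k
    eigenpairs with positive eigenvalues, V Lambda^(1/2).  When fewer
    than k eigenvalues are positive, fewer columns are returned with a
    warning.
    """
    if isinstance(fst, FstMatrix):
        labels: tuple[str, ...] | None = fst.groups
        D = fst.values.astype(float).copy()
    else:
        labels = None
        D = np.asarray(fst, dtype=float).copy()
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T, atol=1e-9):
        raise ValueError("MDS input must be a square symmetric matrix")
    if (D < 0).any():
        logger.info("clamping %d negative dissimilarities to 0", int((D < 0).sum()))
        D = np.maximum(D, 0.0)
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    positive = eigval > max(1e-12, 1e-12 * abs(eigval[0]))
    n_pos = int(positive.sum())
    if n_pos < k:
        warnings.warn(
            f"only {n_pos} positive eigenvalue(s); returning {n_pos} axes"
        )
    k_eff = min(k, n_pos)
    coords = eigvec[:, :k_eff] * np.sqrt(eigval[:k_eff])
    cols = [f"MDS{i + 1}" for i in range(k_eff)]
    if labels is not None:
        return pd.DataFrame(coords, index=labels, columns=cols)
    return pd.DataFrame(coords, columns=cols)
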