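"""Within-group molecular diversity: K, H, S, pi and Tajima's D.

Statistics operate on equal-length sequences; ``N`` and ``-`` count as
missing.  Under the default policy, haplotype count (K), gene
diversity (H) and segregating sites (S) use complete deletion (any
column containing a missing character is removed first) while the mean
number of pairwise differences (pi) uses pairwise deletion (each pair
is compared over the sites complete in that pair).  Pi is reported as
a count of differences, not a per-site rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import sqrt
from typing import Sequence

import numpy as np

MISSING = np.uint8(255)
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 255, "-": 255}
_DECODE = np.array(list("ACGT"))


def encode_sequences(seqs: Sequence[str]) -> np.ndarray:
    """Encode sequences to a (n, L) uint8 matrix; N/- become 255."""
    lut = np.full(256, 254, dtype=np.uint8)
    for ch, code in _CODE.items():
        lut[ord(ch)] = code
    mat = np.vstack([
        lut[np.frombuffer(s.encode("ascii"), dtype=np.uint8)] for s in seqs
    ])
    if (mat == 254).any():
        raise ValueError("sequence contains characters outside {A,C,G,T,N,-}")
    return mat


@dataclass(frozen=True)
class DiversityVector:
    """Per-group summary: n, K, H, S, Pi and (optionally) Tajima's D."""

    n: int
    K: int
    H: float
    S: int
    Pi: float
    D: float | None = None


def _pairwise_diff_counts(mat: np.ndarray) -> np.ndarray:
    """Per-pair difference counts over jointly non-missing sites."""
    n = mat.shape[0]
    out = np.zeros((n, n), dtype=float)
    miss = mat == MISSING
    for i in range(n - 1):
        both = ~miss[i] & ~miss[i + 1:]
        diff = (mat[i] != mat[i + 1:]) & both
        counts = diff.sum(axis=1).astype(float)
        out[i, i + 1:] = counts
        out[i + 1:, i] = counts
    return out


def stats_from_codes(
    mat: np.ndarray, missing_policy: str = "complete"
) -> DiversityVector:
    """Diversity statistics from an encoded (n, L) matrix (no D)."""
    if missing_policy not in {"complete", "pairwise"}:
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    n = mat.shape[0]
    if n < 2:
        raise ValueError("need at least 2 sequences")
    if mat.shape[1] == 0:
        # vacuous input (e.g. a monomorphic simulation's empty variant
        # matrix): every statistic sits at its floor
        return DiversityVector(n=n, K=1, H=0.0, S=0, Pi=0.0)
    complete_cols = ~(mat == MISSING).any(axis=0)
    kept = mat[:, complete_cols]
    if kept.shape[1] == 0:
        warnings.warn("no site is complete across the group; floors returned")
        return DiversityVector(n=n, K=1, H=0.0, S=0, Pi=0.0)
    _, inverse = np.unique(kept, axis=0, return_inverse=True)
    k = int(inverse.max()) + 1
    freqs = np.bincount(inverse) / n
    h = (n / (n - 1)) * (1.0 - float((freqs**2).sum()))
    s = int((kept != kept[0]).any(axis=0).sum())
    if missing_policy == "complete":
        diffs = _pairwise_diff_counts(kept)
    else:
        diffs = _pairwise_diff_counts(mat)
    iu = np.triu_indices(n, k=1)
    pi = float(diffs[iu].mean())
    return DiversityVector(n=n, K=k, H=h, S=s, Pi=pi)


def within_group_stats(
    seqs: Sequence[str], missing_policy: str = "complete"
) -> DiversityVector:
    """K, H, S and pi for one group of aligned sequences.

    ``missing_policy`` governs pi only ("complete" recomputes pair
    differences on the complete-deletion matrix, "pairwise" compares
    each pair over its jointly complete sites); K, H and S always use
    complete deletion.
    """
    lengths = {len(s) for s in seqs}
    if len(lengths) > 1:
        raise ValueError("sequences of unequal length")
    return stats_from_codes(encode_sequences(seqs), missing_policy)


def tajimas_d(S: int, Pi: float, n: int) -> float | None:
    """Tajima's D from segregating sites, mean pairwise differences, n.

    Standardised difference between pi and S/a1 using the constant-size
    neutral variance; returns None when S == 0 (the statistic is
    undefined), and requires n >= 4 for stable variance terms.
    """
    if n < 4:
        raise ValueError("Tajima's D requires n >= 4")
    if S < 0:
        raise ValueError("negative segregating-site count")
    if S == 0:
        return None
    i = np.arange(1, n)
    a1 = float((1.0 / i).sum())
    a2 = float((1.0 / i**2).sum())
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (Pi - S / a1) / sqrt(e1 * S + e2 * S * (S - 1))


def group_diversity(
    grouped, missing_policy: str = "complete", impute_d: bool = False
):
    """DiversityVector (with D where computable) for every group.

    Returns a dict group label -> DiversityVector.  D is None for
    monomorphic groups or n < 4 unless ``impute_d`` substitutes 0 (the
    convention used when the vector feeds a classifier that cannot
    accept missing features).
    """
    out = {}
    for label in grouped.group_labels:
        sub = grouped.group_alignment(label)
        vec = within_group_stats(sub.sequences, missing_policy)
        d: float | None = None
        if vec.n >= 4:
            d = tajimas_d(vec.S, vec.Pi, vec.n)
        if d is None and impute_d:
            d = 0.0
        out[label] = DiversityVector(
            n=vec.n, K=vec.K, H=vec.H, S=vec.S, Pi=vec.Pi, D=d
        )
    return out
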