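"""Classical diversity and neutrality statistics: pi, Watterson's theta,
Tajima's D.

Inputs are alignment-like matrices (rows = sequences/haplotypes, columns =
sites): either single-character arrays where ``N``/``-``/ambiguity codes
mark missing data, or integer allele matrices with ``-1`` for missing.

Missing-data policy: pairwise deletion for pi (each pair is compared over
its jointly called sites); for S and Tajima's D only columns with at least
``min(4, n)`` called states are used, and D combines S with the mean
pairwise difference count over those same columns, so the two ingredients
of the statistic always refer to the same sites.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DiversitySummary",
    "segregating_sites",
    "nucleotide_diversity",
    "pairwise_differences",
    "watterson_theta",
    "tajimas_d",
    "tajima_constants",
    "diversity_summary",
]


def _encode(matrix: np.ndarray) -> np.ndarray:
    """Normalise an alignment to an integer matrix with -1 = missing."""
    mat = np.asarray(matrix)
    if mat.ndim != 2:
        raise ValueError("alignment matrix must be 2-D (sequences x sites)")
    if mat.dtype.kind in "US":
        up = np.char.upper(mat.astype("U1"))
        out = np.full(mat.shape, -1, dtype=np.int8)
        for code, sym in enumerate("ACGT"):
            out[up == sym] = code
        return out
    out = mat.astype(np.int64)
    out[out < 0] = -1
    return out


def _complete_columns(enc: np.ndarray, min_called: int | None = None) -> np.ndarray:
    n = enc.shape[0]
    need = min(4, n) if min_called is None else min_called
    return (enc >= 0).sum(axis=0) >= need


def segregating_sites(matrix: np.ndarray) -> int:
    """Number of columns with >= 2 distinct called states (columns with
    fewer than ``min(4, n)`` called states are ignored)."""
    enc = _encode(matrix)
    if enc.shape[0] < 2:
        raise ValueError("need at least two sequences")
    keep = _complete_columns(enc)
    s = 0
    for j in np.flatnonzero(keep):
        col = enc[:, j]
        if np.unique(col[col >= 0]).size >= 2:
            s += 1
    return s


def pairwise_differences(matrix: np.ndarray,
                         columns: np.ndarray | None = None) -> float:
    """Mean number of differences over all unordered sequence pairs
    (pairwise deletion; optionally restricted to a column mask)."""
    enc = _encode(matrix)
    n = enc.shape[0]
    if n < 2:
        raise ValueError("need at least two sequences")
    if columns is not None:
        enc = enc[:, columns]
    total = 0.0
    pairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            both = (enc[i] >= 0) & (enc[j] >= 0)
            total += float(np.sum((enc[i] != enc[j]) & both))
            pairs += 1
    return total / pairs


def nucleotide_diversity(matrix: np.ndarray) -> float:
    """Per-site pi: mean over pairs of (differences / jointly called sites)."""
    enc = _encode(matrix)
    n = enc.shape[0]
    if n < 2:
        raise ValueError("need at least two sequences")
    vals = []
    for i in range(n):
        for j in range(i + 1, n):
            both = (enc[i] >= 0) & (enc[j] >= 0)
            m = int(both.sum())
            if m:
                vals.append(float(np.sum((enc[i] != enc[j]) & both)) / m)
    if not vals:
        raise ValueError("no pairwise-complete sites")
    return float(np.mean(vals))


def _a1(n: int) -> float:
    return sum(1.0 / i for i in range(1, n))


def watterson_theta(s: int, n: int) -> float:
    """Watterson estimator (total over the surveyed region): S / a1."""
    if n < 2:
        raise ValueError("need at least two sequences")
    if s < 0:
        raise ValueError("S must be non-negative")
    return s / _a1(n)


def tajima_constants(n: int) -> dict[str, float]:
    """The a1, a2, b1, b2, c1, c2, e1, e2 coefficients used by Tajima's D."""
    a1 = _a1(n)
    a2 = sum(1.0 / i ** 2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n ** 2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2,
            "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajimas_d(matrix: np.ndarray) -> float | None:
    """Tajima's D, or ``None`` when undefined (no segregating sites).

    ``D = (pi_total - S/a1) / sqrt(e1 S + e2 S (S - 1))`` with the usual
    coefficients as functions of the number of sequences.
    """
    enc = _encode(matrix)
    n = enc.shape[0]
    if n < 2:
        raise ValueError("need at least two sequences")
    keep = _complete_columns(enc)
    sub = enc[:, keep]
    s = 0
    for j in range(sub.shape[1]):
        col = sub[:, j]
        if np.unique(col[col >= 0]).size >= 2:
            s += 1
    if s == 0:
        return None
    pi_total = pairwise_differences(sub)
    k = tajima_constants(n)
    var = k["e1"] * s + k["e2"] * s * (s - 1)
    if var <= 0:
        return None
    return (pi_total - s / k["a1"]) / math.sqrt(var)


@dataclass
class DiversitySummary:
    """Per-alignment molecular-variation summary."""

    n: int
    valid_sites: int
    S: int
    pi_per_site: float
    pi_total: float
    theta_w_total: float
    theta_w_per_site: float
    tajima_d: float | None


def diversity_summary(matrix: np.ndarray) -> DiversitySummary:
    enc = _encode(matrix)
    n = enc.shape[0]
    keep = _complete_columns(enc)
    s = segregating_sites(enc)
    pi_site = nucleotide_diversity(enc)
    pi_total = pairwise_differences(enc[:, keep]) if keep.any() else 0.0
    theta = watterson_theta(s, n)
    valid = int(keep.sum())
    return DiversitySummary(
        n=n,
        valid_sites=valid,
        S=s,
        pi_per_site=pi_site,
        pi_total=pi_total,
        theta_w_total=theta,
        theta_w_per_site=theta / valid if valid else float("nan"),
        tajima_d=tajimas_d(enc),
    )
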