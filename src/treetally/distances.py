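"""Pairwise protein distances and distance matrices.

Three models are provided:

``p``
    Raw mismatch fraction over columns where both rows have a residue.
``kimura``
    Kimura's closed-form correction for proteins,
    ``d = -ln(1 - p - 0.2 p^2)``, a matrix-free approximation to
    empirical-matrix distances that is the package default.
``empirical``
    Maximum-likelihood distance under a supplied reversible 20-state
    exchangeability matrix and stationary frequencies (one-dimensional
    likelihood optimisation per pair).

Distances saturate at deep divergences; when the correction's domain edge is
reached (``1 - p - 0.2 p^2 <= 0``) the distance is capped at a configurable
maximum and a :class:`~treetally.errors.SaturationWarning` is raised instead
of failing, because deep multi-kingdom datasets always contain such pairs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import minimize_scalar

from .alignment import GAP, MISSING, SegmentAlignment
from .errors import DataError, SaturationWarning
from .seqio import AMINO_ACIDS

DEFAULT_MAX_DISTANCE = 10.0

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


@dataclass
class DistanceMatrix:
    """Symmetric distances (expected substitutions/site) over ordered labels."""

    labels: list[str]
    d: np.ndarray
    saturated: np.ndarray | None = None  # boolean mask of capped pairs

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise DataError("distance matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T):
            raise DataError("distance matrix is not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise DataError("distance matrix diagonal must be zero")
        if not np.all(np.isfinite(self.d)):
            raise DataError("distance matrix contains non-finite entries")

    def index(self, label: str) -> int:
        return self.labels.index(label)


def _shared_mismatch(rowA: str, rowB: str) -> tuple[int, int]:
    shared = mism = 0
    for a, b in zip(rowA, rowB):
        if a in MISSING or b in MISSING:
            continue
        shared += 1
        if a != b:
            mism += 1
    return shared, mism


def kimura_correct(p: float, max_distance: float = DEFAULT_MAX_DISTANCE) -> tuple[float, bool]:
    """Apply ``d = -ln(1 - p - 0.2 p^2)``; returns (distance, was_capped)."""
    arg = 1.0 - p - 0.2 * p * p
    if arg <= 0:
        return max_distance, True
    d = -math.log(arg)
    if d > max_distance:
        return max_distance, True
    return d, False


class EmpiricalModel:
    """Reversible 20-state model from an exchangeability matrix + frequencies.

    The rate matrix is normalised to one expected substitution per site per
    unit time, so ML distances are on the same scale as the corrected
    p-distances.
    """

    def __init__(self, exchangeabilities: np.ndarray, frequencies: np.ndarray):
        S = np.asarray(exchangeabilities, dtype=float)
        pi = np.asarray(frequencies, dtype=float)
        if S.shape != (20, 20) or not np.allclose(S, S.T):
            raise DataError("exchangeability matrix must be symmetric 20x20")
        if pi.shape != (20,) or not np.isclose(pi.sum(), 1.0):
            raise DataError("frequencies must be length-20 and sum to 1")
        Q = S * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        scale = -np.sum(pi * np.diag(Q))
        Q /= scale
        self.pi = pi
        # symmetrize for a stable eigendecomposition: B = D^1/2 Q D^-1/2
        sqrt_pi = np.sqrt(pi)
        B = (Q * sqrt_pi[None, :]) / sqrt_pi[:, None]
        B = (B + B.T) / 2
        self.eigval, eigvec = np.linalg.eigh(B)
        self.left = eigvec / sqrt_pi[:, None]
        self.right = eigvec * sqrt_pi[:, None]

    @classmethod
    def uniform(cls) -> "EmpiricalModel":
        """All exchangeabilities equal, uniform frequencies (protein JC)."""
        S = np.ones((20, 20))
        np.fill_diagonal(S, 0.0)
        return cls(S, np.full(20, 0.05))

    def transition_matrix(self, t: float) -> np.ndarray:
        P = (self.left * np.exp(self.eigval * t)) @ self.right.T
        return np.clip(P, 1e-300, None)

    def ml_distance(
        self, counts: np.ndarray, max_distance: float = DEFAULT_MAX_DISTANCE
    ) -> tuple[float, bool]:
        """Maximise the pair likelihood over t given a 20x20 count table."""
        ij = np.nonzero(counts)

        def nll(t: float) -> float:
            P = self.transition_matrix(t)
            return -np.sum(counts[ij] * np.log(self.pi[ij[0]] * P[ij]))

        res = minimize_scalar(nll, bounds=(1e-9, max_distance), method="bounded")
        t = float(res.x)
        capped = t >= max_distance * (1 - 1e-6)
        return (max_distance, True) if capped else (t, False)

    @classmethod
    def from_paml_file(cls, path: str | Path) -> "EmpiricalModel":
        """Read a PAML-format .dat matrix (lower triangle then frequencies)."""
        nums: list[float] = []
        with open(path) as fh:
            for line in fh:
                nums.extend(float(x) for x in line.split())
        if len(nums) < 190 + 20:
            raise DataError(f"{path}: expected 190 exchangeabilities + 20 frequencies")
        S = np.zeros((20, 20))
        k = 0
        for i in range(1, 20):
            for j in range(i):
                S[i, j] = S[j, i] = nums[k]
                k += 1
        pi = np.array(nums[k : k + 20])
        pi = pi / pi.sum()
        return cls(S, pi)


def pairwise_distance(
    rowA: str,
    rowB: str,
    model: str = "kimura",
    empirical: EmpiricalModel | None = None,
    max_distance: float = DEFAULT_MAX_DISTANCE,
) -> float:
    """Distance between two gapped rows of equal length.

    Columns where either row is missing (gap or X) are excluded.  Raises
    :class:`DataError` when the rows share no columns; warns and caps when
    the model saturates.
    """
    if len(rowA) != len(rowB):
        raise DataError("rows must have equal length")
    shared, mism = _shared_mismatch(rowA, rowB)
    if shared == 0:
        raise DataError("rows share no non-gap columns")
    p = mism / shared
    if model == "p":
        return p
    if model == "kimura":
        d, capped = kimura_correct(p, max_distance)
        if capped:
            warnings.warn(
                f"kimura distance saturated (p={p:.3f}); capped at {max_distance}",
                SaturationWarning,
                stacklevel=2,
            )
        return d
    if model == "empirical":
        if empirical is None:
            raise ValueError("model='empirical' requires an EmpiricalModel")
        counts = np.zeros((20, 20))
        for a, b in zip(rowA, rowB):
            if a in MISSING or b in MISSING:
                continue
            counts[_AA_INDEX[a], _AA_INDEX[b]] += 1
        d, capped = empirical.ml_distance(counts, max_distance)
        if capped:
            warnings.warn(
                f"empirical ML distance saturated; capped at {max_distance}",
                SaturationWarning,
                stacklevel=2,
            )
        return d
    raise ValueError(f"unknown distance model {model!r}")


def pair_mismatch_tables(aln: SegmentAlignment) -> tuple[np.ndarray, np.ndarray, list[tuple[int, int]]]:
    """Per-column shared/mismatch masks for every row pair (bootstrap fast path).

    Returns boolean arrays ``shared`` and ``mismatch`` of shape
    (n_pairs, n_cols) plus the pair index list, so a bootstrap replicate's
    p-distances are two fancy-indexed sums instead of a re-scan.
    """
    arr = aln.to_array()
    missing = (arr == b"-") | (arr == b"X")
    n = len(aln)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    shared = np.empty((len(pairs), aln.n_cols), dtype=bool)
    mismatch = np.empty_like(shared)
    for k, (i, j) in enumerate(pairs):
        ok = ~missing[i] & ~missing[j]
        shared[k] = ok
        mismatch[k] = ok & (arr[i] != arr[j])
    return shared, mismatch, pairs


def p_distances_from_tables(
    shared: np.ndarray,
    mismatch: np.ndarray,
    pairs: list[tuple[int, int]],
    n_rows: int,
    col_idx: np.ndarray | None = None,
    labels: list[str] | None = None,
) -> np.ndarray:
    """p-distance matrix from precomputed tables, optionally over resampled columns."""
    if col_idx is not None:
        sh = shared[:, col_idx].sum(axis=1)
        mm = mismatch[:, col_idx].sum(axis=1)
    else:
        sh = shared.sum(axis=1)
        mm = mismatch.sum(axis=1)
    if np.any(sh == 0):
        k = int(np.argmax(sh == 0))
        i, j = pairs[k]
        a = labels[i] if labels else str(i)
        b = labels[j] if labels else str(j)
        raise DataError(f"rows {a!r} and {b!r} share no non-gap columns")
    p = mm / sh
    D = np.zeros((n_rows, n_rows))
    for k, (i, j) in enumerate(pairs):
        D[i, j] = D[j, i] = p[k]
    return D


def distance_matrix(
    aln: SegmentAlignment,
    model: str = "kimura",
    empirical: EmpiricalModel | None = None,
    max_distance: float = DEFAULT_MAX_DISTANCE,
) -> DistanceMatrix:
    """All-pairs distance matrix for an alignment (>= 3 rows)."""
    if len(aln) < 3:
        raise DataError("distance matrix needs at least 3 rows")
    labels = aln.codes
    n = len(labels)
    if model in ("p", "kimura"):
        shared, mismatch, pairs = pair_mismatch_tables(aln)
        P = p_distances_from_tables(shared, mismatch, pairs, n, labels=labels)
        if model == "p":
            return DistanceMatrix(labels, P, saturated=np.zeros((n, n), dtype=bool))
        D = np.zeros((n, n))
        sat = np.zeros((n, n), dtype=bool)
        capped_pairs = []
        for i in range(n):
            for j in range(i + 1, n):
                d, capped = kimura_correct(P[i, j], max_distance)
                D[i, j] = D[j, i] = d
                sat[i, j] = sat[j, i] = capped
                if capped:
                    capped_pairs.append((labels[i], labels[j]))
        if capped_pairs:
            warnings.warn(
                f"{len(capped_pairs)} saturated pair(s) capped at {max_distance}, "
                f"first: {capped_pairs[0]}",
                SaturationWarning,
                stacklevel=2,
            )
        return DistanceMatrix(labels, D, saturated=sat)
    if model == "empirical":
        D = np.zeros((n, n))
        sat = np.zeros((n, n), dtype=bool)
        rows = list(aln.rows.values())
        with warnings.catch_warnings():
            warnings.simplefilter("always", SaturationWarning)
            for i in range(n):
                for j in range(i + 1, n):
                    try:
                        d = pairwise_distance(
                            rows[i], rows[j], "empirical", empirical, max_distance
                        )
                    except DataError as exc:
                        raise DataError(
                            f"pair ({labels[i]}, {labels[j]}): {exc}"
                        ) from None
                    D[i, j] = D[j, i] = d
                    sat[i, j] = sat[j, i] = d >= max_distance
        return DistanceMatrix(labels, D, saturated=sat)
    raise ValueError(f"unknown distance model {model!r}")


def kimura_matrix_from_p(P: np.ndarray, max_distance: float = DEFAULT_MAX_DISTANCE) -> np.ndarray:
    """Vectorised Kimura correction of a p-distance matrix (bootstrap fast path)."""
    arg = 1.0 - P - 0.2 * P * P
    with np.errstate(invalid="ignore", divide="ignore"):
        D = np.where(arg > 0, -np.log(np.clip(arg, 1e-300, None)), max_distance)
    D = np.minimum(D, max_distance)
    np.fill_diagonal(D, 0.0)
    return D


def write_phylip(dm: DistanceMatrix, path: str | Path) -> None:
    """Write a square PHYLIP distance matrix."""
    with open(path, "w") as fh:
        fh.write(f"{len(dm.labels)}\n")
        for i, lab in enumerate(dm.labels):
            vals = " ".join(f"{x:.6f}" for x in dm.d[i])
            fh.write(f"{lab:<12s}{vals}\n")


def read_phylip(path: str | Path) -> DistanceMatrix:
    """Read a square PHYLIP distance matrix."""
    with open(path) as fh:
        lines = [ln.rstrip() for ln in fh if ln.strip()]
    try:
        n = int(lines[0].split()[0])
    except (IndexError, ValueError):
        raise DataError(f"{path}: bad PHYLIP header") from None
    if len(lines) != n + 1:
        raise DataError(f"{path}: expected {n} matrix rows")
    labels, rows = [], []
    for ln in lines[1:]:
        parts = ln.split()
        labels.append(parts[0])
        rows.append([float(x) for x in parts[1:]])
    d = np.array(rows)
    if d.shape != (n, n):
        raise DataError(f"{path}: matrix is not {n}x{n}")
    return DistanceMatrix(labels, d)
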