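"""Spatial autocorrelation diagnostics and Moran eigenvector maps.

Species are reduced to the centroid of their sequence localities; a relative
neighbourhood (RN) graph over the centroids (great-circle distances) defines
a binary spatial weighting matrix.  Moran's I of model residuals over that
matrix tests for residual spatial autocorrelation, and eigenvectors of the
doubly-centred weighting matrix (Moran eigenvector maps, MEM) supply
synthetic spatial predictors that can absorb it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .predictors import haversine_km

__all__ = [
    "SpatialWeights",
    "MoranResult",
    "EigenvectorSet",
    "rn_graph",
    "moran_i",
    "mem_eigenvectors",
    "select_mems",
]


@dataclass
class SpatialWeights:
    """Symmetric binary neighbour matrix over species centroids."""

    adjacency: np.ndarray
    centroids: np.ndarray  # (n, 2) lat, lon
    style: str = "binary"

    def __post_init__(self):
        A = np.asarray(self.adjacency, float)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.allclose(A, A.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(A) != 0):
            raise ValueError("adjacency diagonal must be zero")
        self.adjacency = A

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]

    @property
    def isolates(self) -> np.ndarray:
        return np.flatnonzero(self.adjacency.sum(axis=1) == 0)

    def edge_list(self) -> list[tuple[int, int]]:
        i, j = np.nonzero(np.triu(self.adjacency))
        return list(zip(i.tolist(), j.tolist()))


@dataclass
class MoranResult:
    """Moran's I with moments and p-value under the normality assumption."""

    observed_i: float
    expected_i: float
    variance: float
    p_value: float


@dataclass
class EigenvectorSet:
    """Moran eigenvector maps: orthonormal, centred columns MEM1..MEMm in
    decreasing-eigenvalue order."""

    vectors: np.ndarray  # (n, m)
    eigenvalues: np.ndarray  # (m,)

    @property
    def names(self) -> list[str]:
        return [f"MEM{i+1}" for i in range(self.vectors.shape[1])]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.vectors, columns=self.names)

    def positive(self) -> "EigenvectorSet":
        keep = self.eigenvalues > 0
        return EigenvectorSet(self.vectors[:, keep], self.eigenvalues[keep])


def rn_graph(centroids: Sequence[Sequence[float]], jitter: float = 1e-6, seed: int = 0) -> SpatialWeights:
    """Relative neighbourhood graph over centroids with great-circle distances.

    Edge (a,b) exists iff no third point c satisfies
    max(d(a,c), d(b,c)) < d(a,b) — i.e. the lune between a and b is empty.
    Duplicated centroids are jittered by a tiny offset (with a warning) so
    distances are all positive.
    """
    pts = np.asarray(centroids, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need >= 3 (lat, lon) centroids")
    n = pts.shape[0]
    # resolve exact duplicates
    _, inverse, counts = np.unique(pts, axis=0, return_inverse=True, return_counts=True)
    if np.any(counts > 1):
        warnings.warn("duplicated centroids jittered by a tiny offset")
        rng = np.random.default_rng(seed)
        dup = counts[inverse] > 1
        pts = pts.copy()
        pts[dup] += rng.normal(0, jitter, size=(dup.sum(), 2))
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = haversine_km(pts[i], pts[j])
    A = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dij = D[i, j]
            blocked = False
            for k in range(n):
                if k != i and k != j and max(D[i, k], D[j, k]) < dij:
                    blocked = True
                    break
            if not blocked:
                A[i, j] = A[j, i] = 1.0
    return SpatialWeights(A, pts)


def moran_i(
    values: Sequence[float],
    W: SpatialWeights | np.ndarray,
    row_normalize: bool = True,
    assumption: str = "randomization",
) -> MoranResult:
    """Moran's I with expectation -1/(n-1) and a two-sided normal p-value.

    With ``row_normalize`` (default) each row of the symmetric input matrix
    is divided by its sum before the statistic is evaluated, and the default
    variance is the randomization (kurtosis-corrected) formula — both
    matching the standard tree/stats implementation this mirrors
    (``assumption='normality'`` gives the plain normal-theory variance).
    Rows with no neighbours keep zero weight (a warning is raised).
    """
    x = np.asarray(values, float)
    A = W.adjacency if isinstance(W, SpatialWeights) else np.asarray(W, float)
    n = x.size
    if n < 5:
        raise ValueError("Moran's I needs n >= 5")
    if A.shape != (n, n):
        raise ValueError("weight matrix shape mismatch")
    if not np.allclose(A, A.T):
        raise ValueError("weight matrix must be symmetric")
    if A.sum() == 0:
        raise ValueError("zero total weight")
    if row_normalize:
        rs = A.sum(axis=1, keepdims=True)
        if np.any(rs == 0):
            warnings.warn("isolated nodes keep zero weight under row normalization")
        A = np.divide(A, rs, out=np.zeros_like(A, dtype=float), where=rs > 0)
    s0 = A.sum()
    z = x - x.mean()
    denom = float(z @ z)
    if denom == 0:
        raise ValueError("constant values: Moran's I undefined")
    obs = float(n / s0 * (z @ A @ z) / denom)
    e_i = -1.0 / (n - 1)
    s1 = 0.5 * ((A + A.T) ** 2).sum()
    s2 = ((A.sum(axis=0) + A.sum(axis=1)) ** 2).sum()
    if assumption == "normality":
        var = (n**2 * s1 - n * s2 + 3 * s0**2) / ((n**2 - 1) * s0**2) - e_i**2
    elif assumption == "randomization":
        k = (np.sum(z**4) / n) / (denom / n) ** 2
        var = (
            n * ((n**2 - 3 * n + 3) * s1 - n * s2 + 3 * s0**2)
            - k * (n * (n - 1) * s1 - 2 * n * s2 + 6 * s0**2)
        ) / ((n - 1) * (n - 2) * (n - 3) * s0**2) - 1.0 / (n - 1) ** 2
    else:
        raise ValueError("assumption must be randomization|normality")
    sd = np.sqrt(var)
    p = float(2 * stats.norm.sf(abs(obs - e_i) / sd)) if sd > 0 else np.nan
    return MoranResult(obs, e_i, float(var), min(p, 1.0))


def mem_eigenvectors(W: SpatialWeights | np.ndarray, tol: float = 1e-10) -> EigenvectorSet:
    """Moran eigenvector maps of a spatial weighting matrix.

    Eigenvectors of (I - 11'/n) W (I - 11'/n) with |eigenvalue| > ``tol``,
    sorted by descending eigenvalue.  Positive eigenvalues correspond to
    broad positively-autocorrelated spatial patterns, negative eigenvalues
    to fine-scale alternation.
    """
    A = W.adjacency if isinstance(W, SpatialWeights) else np.asarray(W, float)
    n = A.shape[0]
    if n < 4:
        raise ValueError("MEM construction needs n >= 4")
    H = np.eye(n) - np.ones((n, n)) / n
    omega = H @ A @ H
    omega = (omega + omega.T) / 2
    vals, vecs = np.linalg.eigh(omega)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    keep = np.abs(vals) > tol
    return EigenvectorSet(vecs[:, keep], vals[keep])


def select_mems(
    residual_provider: Callable[[np.ndarray | None, list[str]], np.ndarray],
    E: EigenvectorSet,
    W: SpatialWeights,
    alpha: float = 0.05,
    max_select: int | None = None,
    positive_only: bool = False,
) -> tuple[list[str], pd.DataFrame]:
    """Forward selection of spatial eigenvectors to absorb residual
    autocorrelation.

    ``residual_provider(mem_matrix, mem_names)`` must refit the model with
    the given MEM columns added and return its residuals (``None`` columns
    mean the base model).  At each step the candidate whose inclusion most
    reduces |I - E[I]| of the refit residuals is added; selection stops when
    the residual Moran p-value reaches ``alpha`` or candidates are
    exhausted.  Returns the selected names and a trace table
    (step, MEM, moran_i, p).
    """
    if E.vectors.shape[1] == 0:
        raise ValueError("empty eigenvector set")
    cand = E.positive() if positive_only else E
    names = cand.names if not positive_only else [
        n for n, keep in zip(E.names, E.eigenvalues > 0) if keep
    ]
    vectors = {nm: cand.vectors[:, k] for k, nm in enumerate(names)}
    selected: list[str] = []
    trace_rows = []
    base_res = residual_provider(None, [])
    mr = moran_i(base_res, W)
    trace_rows.append({"step": 0, "MEM": "<none>", "moran_i": mr.observed_i, "p": mr.p_value})
    if max_select is None:
        max_select = len(names)
    while mr.p_value < alpha and len(selected) < max_select:
        best = None
        for nm in names:
            if nm in selected:
                continue
            trial = selected + [nm]
            M = np.column_stack([vectors[t] for t in trial])
            res = residual_provider(M, trial)
            m_trial = moran_i(res, W)
            score = abs(m_trial.observed_i - m_trial.expected_i)
            if best is None or score < best[0]:
                best = (score, nm, m_trial)
        if best is None:
            break
        score, nm, m_best = best
        prev = abs(mr.observed_i - mr.expected_i)
        if score >= prev:  # no candidate reduces autocorrelation
            break
        selected.append(nm)
        mr = m_best
        trace_rows.append(
            {"step": len(selected), "MEM": nm, "moran_i": mr.observed_i, "p": mr.p_value}
        )
    return selected, pd.DataFrame(trace_rows)
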