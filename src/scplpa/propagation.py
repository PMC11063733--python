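"""Network normalization and label propagation to the estimated score matrix.

Each heterogeneous similarity network W is normalized so that the iteration
F_{t+1} = (1 - a) W* F_t + a Y contracts, then iterated from F_0 = Y until
the max-abs elementwise change drops below tolerance.  The disease-network
run diffuses the transposed association matrix, the miRNA-network run the
association matrix itself; a convex combination of the two fixed points is
the estimated score matrix Fe.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from scplpa.core_io import SimilarityMatrix

__all__ = [
    "NormalizedNetwork",
    "PropagationResult",
    "normalize_network",
    "label_propagate",
    "estimate_scores",
]


@dataclass
class NormalizedNetwork:
    values: np.ndarray
    provenance: str = "disease"  # or "mirna"
    normalization_mode: str = "degree_sum"


@dataclass
class PropagationResult:
    fixed_point: np.ndarray
    iterations: int
    residual: float
    converged: bool


def normalize_network(
    network: SimilarityMatrix | np.ndarray,
    mode: str = "degree_sum",
    provenance: str = "disease",
) -> NormalizedNetwork:
    """Normalize a nonnegative similarity network.

    ``degree_sum`` (default) divides each entry by the sum of its row and
    column totals, W*(i,j) = W(i,j) / (rowsum_i + colsum_j); every row of the
    result sums to at most 1, so (1 - a) W* is a contraction for a > 0.
    ``symmetric`` applies the usual D^{-1/2} W D^{-1/2} with D the row-sum
    diagonal.  Zero denominators yield zero entries.
    """
    w = network.values if isinstance(network, SimilarityMatrix) else np.asarray(network, float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("network must be square")
    if w.min(initial=0.0) < 0:
        raise ValueError("network entries must be nonnegative")
    if mode == "degree_sum":
        row = w.sum(axis=1)
        col = w.sum(axis=0)
        denom = row[:, None] + col[None, :]
        out = np.divide(w, denom, out=np.zeros_like(w), where=denom > 0)
    elif mode == "symmetric":
        deg = w.sum(axis=1)
        inv_sqrt = np.divide(1.0, np.sqrt(deg), out=np.zeros_like(deg), where=deg > 0)
        out = inv_sqrt[:, None] * w * inv_sqrt[None, :]
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    return NormalizedNetwork(values=out, provenance=provenance, normalization_mode=mode)


def label_propagate(
    wstar: NormalizedNetwork | np.ndarray,
    y: np.ndarray,
    weight: float,
    tolerance: float = 1e-6,
    max_iterations: int = 1000,
) -> PropagationResult:
    """Iterate F_{t+1} = (1 - weight) W* F_t + weight Y from F_0 = Y.

    Stops when the max-abs elementwise change is below ``tolerance``; a run
    that exhausts ``max_iterations`` is returned with ``converged=False``
    rather than raising, so callers can flag it.
    """
    w = wstar.values if isinstance(wstar, NormalizedNetwork) else np.asarray(wstar, float)
    y = np.asarray(y, dtype=float)
    if w.shape[0] != w.shape[1] or w.shape[1] != y.shape[0]:
        raise ValueError(f"shape mismatch: W* {w.shape} vs Y {y.shape}")
    if not 0 < weight <= 1:
        raise ValueError(f"propagation weight must be in (0, 1], got {weight}")
    f = y.copy()
    residual = np.inf
    for t in range(1, max_iterations + 1):
        f_next = (1.0 - weight) * (w @ f) + weight * y
        residual = float(np.abs(f_next - f).max(initial=0.0))
        f = f_next
        if residual < tolerance:
            return PropagationResult(f, iterations=t, residual=residual, converged=True)
    return PropagationResult(f, iterations=max_iterations, residual=residual, converged=False)


def estimate_scores(
    fd: PropagationResult | np.ndarray,
    fm: PropagationResult | np.ndarray,
    delta: float,
) -> np.ndarray:
    """Mix the two propagation fixed points into the estimated score matrix.

    The disease-network fixed point is disease x miRNA and is transposed;
    Fe = (1 - delta) FD^T + delta FM, oriented miRNA x disease.
    """
    fd_mat = fd.fixed_point if isinstance(fd, PropagationResult) else np.asarray(fd, float)
    fm_mat = fm.fixed_point if isinstance(fm, PropagationResult) else np.asarray(fm, float)
    if not 0 <= delta <= 1:
        raise ValueError(f"delta must be in [0, 1], got {delta}")
    if fd_mat.T.shape != fm_mat.shape:
        raise ValueError(
            f"incompatible shapes: FD^T {fd_mat.T.shape} vs FM {fm_mat.shape}"
        )
    return (1.0 - delta) * fd_mat.T + delta * fm_mat
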