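"""Principal coordinates analysis (classical metric MDS) of genetic distances.

The Gower double-centred matrix B = -1/2 J D^2 J (J the centering projector)
is eigendecomposed; coordinates are eigenvectors scaled by the square root of
their (positive) eigenvalues. Shared-band distances need not be Euclidean, so
negative eigenvalues can occur; they are reported but excluded both from the
coordinates and from the variance-explained denominator (standard Gower
treatment, keeping cumulative percentages at 100 over the positive part).
Each axis's sign is fixed by making its largest-magnitude loading positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg


@dataclass
class PcoaResult:
    labels: list[str]
    coordinates: np.ndarray        # n x n_pos axis scores
    eigenvalues: np.ndarray        # all eigenvalues, descending
    percent_variance: np.ndarray   # per positive axis, %
    cumulative_percent: np.ndarray

    @property
    def n_axes(self) -> int:
        return self.coordinates.shape[1]


_EIG_TOL = 1e-10


def pcoa(D: np.ndarray, labels: list[str] | None = None) -> PcoaResult:
    """Classical PCoA of a symmetric distance matrix with zero diagonal."""
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n):
        raise ValueError("distance matrix is not square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("distance matrix is not symmetric")
    if np.abs(np.diag(D)).max() > 1e-10:
        raise ValueError("distance matrix diagonal is not zero")
    if labels is None:
        labels = [f"item{i}" for i in range(n)]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D * D) @ J
    B = (B + B.T) / 2.0
    eigvals, eigvecs = linalg.eigh(B)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    scale = max(abs(eigvals[0]), 1.0)
    pos = eigvals > _EIG_TOL * scale
    lam = eigvals[pos]
    vec = eigvecs[:, pos]
    # deterministic sign: largest-magnitude loading positive per axis
    for a in range(vec.shape[1]):
        idx = np.argmax(np.abs(vec[:, a]))
        if vec[idx, a] < 0:
            vec[:, a] = -vec[:, a]
    coords = vec * np.sqrt(lam)
    total_pos = lam.sum()
    if total_pos > 0:
        percent = 100.0 * lam / total_pos
    else:
        percent = np.zeros(0)
    return PcoaResult(
        labels=list(labels),
        coordinates=coords,
        eigenvalues=eigvals,
        percent_variance=percent,
        cumulative_percent=np.cumsum(percent),
    )
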