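"""Natural-abundance correction of 13C isotopologue distributions.

A metabolite with ``n`` carbons measured as isotopologues M+0..M+n carries,
besides tracer-derived 13C, naturally occurring 13C at abundance ``p``
(~1.07% per carbon).  Given a true labeling state M+j, the ``n - j``
remaining carbons are each 13C with probability ``p``, so the observed
distribution is a binomial smear towards heavier isotopologues:

    A[i, j] = C(n-j, i-j) * p**(i-j) * (1-p)**(n-i)   for i >= j, else 0.

Correction inverts this convolution by non-negative least squares, which
keeps corrected intensities non-negative under measurement noise.  Only the
metabolite's own carbon atoms are corrected (no 2H/15N/18O terms, no tracer
impurity), matching uniformly labeled tracers of >= 98% purity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_triangular
from scipy.optimize import nnls
from scipy.special import comb

from .constants import P_C13
from .errors import ValidationError

__all__ = [
    "CorrectionMatrix",
    "correction_matrix",
    "forward_convolve",
    "correct_distribution",
    "correct_matrix",
]


@dataclass(frozen=True)
class CorrectionMatrix:
    """Column j = observed isotopologue distribution given true M+j."""

    n_carbons: int
    p: float
    matrix: np.ndarray  # (n+1, n+1), columns sum to 1


def correction_matrix(n_carbons: int, p: float = P_C13) -> CorrectionMatrix:
    """Build the natural-abundance convolution matrix for ``n_carbons``."""
    if not 0 <= p < 1:
        raise ValidationError("p must satisfy 0 <= p < 1")
    if n_carbons < 1:
        raise ValidationError("n_carbons must be >= 1")
    n = n_carbons
    i = np.arange(n + 1)[:, None]
    j = np.arange(n + 1)[None, :]
    with np.errstate(invalid="ignore"):
        m = comb(n - j, i - j) * p ** np.maximum(i - j, 0) * (1 - p) ** np.maximum(n - i, 0)
    m = np.where(i >= j, m, 0.0)
    return CorrectionMatrix(n_carbons=n, p=p, matrix=m)


def forward_convolve(x: np.ndarray, cm: CorrectionMatrix) -> np.ndarray:
    """Apply natural abundance to a true distribution: ``A @ x``.

    Works on a single (n+1)-vector or on rows of an (N, n+1) matrix.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        return cm.matrix @ x
    return x @ cm.matrix.T


def correct_distribution(measured: np.ndarray, cm: CorrectionMatrix) -> np.ndarray:
    """Solve ``measured ~= A @ x`` for ``x >= 0`` (NNLS).

    An all-zero measurement returns an all-zero correction.
    """
    measured = np.asarray(measured, dtype=float)
    if measured.ndim != 1 or measured.size != cm.n_carbons + 1:
        raise ValidationError(
            f"measured must be a vector of length {cm.n_carbons + 1}"
        )
    if np.any(measured < 0):
        raise ValidationError("measured intensities must be non-negative")
    if not measured.any():
        return np.zeros_like(measured)
    x, _ = nnls(cm.matrix, measured)
    return x


def correct_matrix(measured: np.ndarray, cm: CorrectionMatrix) -> np.ndarray:
    """Correct many pixels at once (rows of ``measured``).

    The convolution matrix is lower-triangular with positive diagonal, so an
    exact triangular solve is used as a vectorized fast path; rows whose
    exact solution dips negative (possible under noise) are re-solved with
    NNLS.
    """
    measured = np.asarray(measured, dtype=float)
    if measured.ndim != 2 or measured.shape[1] != cm.n_carbons + 1:
        raise ValidationError(
            f"measured must be (n_pixels, {cm.n_carbons + 1})"
        )
    if np.any(measured < 0):
        raise ValidationError("measured intensities must be non-negative")
    x = solve_triangular(cm.matrix, measured.T, lower=True).T
    bad = np.any(x < 0, axis=1)
    for i in np.where(bad)[0]:
        x[i] = correct_distribution(measured[i], cm)
    zero = ~measured.any(axis=1)
    x[zero] = 0.0
    return x
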