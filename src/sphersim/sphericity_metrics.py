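"""Sphericity indices of a covariance matrix.

Sphericity — equal variances of all pairwise difference scores among the k
repeated measures — is the condition under which the one-way within-subject
F-test is exact.  Departure from it is indexed by Box's epsilon, which ranges
from 1/(k-1) (maximal violation) to 1 (sphericity holds) and multiplies the
numerator and denominator degrees of freedom of the F-test.

Two classical sample estimators are provided: the Greenhouse-Geisser moment
estimator ``epsilon_hat`` (the plug-in of Box's epsilon at the sample
covariance) and the Huynh-Feldt bias-adjusted transformation ``epsilon_tilde``
(which may exceed 1 and is capped when used for degree-of-freedom adjustment).
An eigenvalue-based formulation of Box's epsilon is exposed separately as an
independent cross-check: both compute the same functional, through different
arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CovarianceMatrix",
    "EpsilonEstimates",
    "epsilon_hat",
    "epsilon_eigen_oracle",
    "epsilon_tilde",
    "epsilon_lower_bound",
    "estimate_epsilons",
    "validate_covariance",
]

#: relative tolerance for the symmetry check
SYMMETRY_RTOL = 1e-10
#: smallest eigenvalue must exceed this fraction of the largest
PD_RTOL = 1e-12


@dataclass(frozen=True)
class CovarianceMatrix:
    """A validated k x k covariance matrix of repeated measures.

    Parameters
    ----------
    entries
        Symmetric positive-definite matrix; ``entries[j, j']`` is the
        covariance between measures j and j'.
    """

    entries: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", validate_covariance(self.entries))

    @property
    def k(self) -> int:
        return self.entries.shape[0]


@dataclass(frozen=True)
class EpsilonEstimates:
    """Greenhouse-Geisser and Huynh-Feldt epsilon estimates for one matrix.

    ``eps_tilde`` is the raw Huynh-Feldt value, which may exceed 1;
    ``eps_tilde_capped`` is ``min(eps_tilde, 1)``, the value used for
    degree-of-freedom adjustment.  ``n`` is the subject count entering the
    Huynh-Feldt formula.
    """

    eps_hat: float
    eps_tilde: float
    eps_tilde_capped: float
    lower_bound: float
    n: int


def validate_covariance(entries: np.ndarray) -> np.ndarray:
    """Validate a covariance matrix and return it as a float array.

    Checks: square with k >= 2, symmetric to ``SYMMETRY_RTOL`` (relative),
    strictly positive diagonal, and positive definite in the sense that the
    smallest eigenvalue exceeds ``PD_RTOL`` times the largest.
    """
    S = np.asarray(entries, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError(f"covariance matrix must be square, got shape {S.shape}")
    k = S.shape[0]
    if k < 2:
        raise ValueError(f"need at least 2 repeated measures, got k={k}")
    scale = np.abs(S).max()
    if scale == 0.0:
        raise ValueError("covariance matrix is identically zero")
    if np.abs(S - S.T).max() > SYMMETRY_RTOL * scale:
        raise ValueError("covariance matrix is not symmetric")
    if np.any(np.diag(S) <= 0.0):
        raise ValueError("covariance matrix has non-positive diagonal entries")
    eigvals = np.linalg.eigvalsh(S)
    if eigvals[0] <= PD_RTOL * eigvals[-1]:
        raise ValueError(
            "covariance matrix is not positive definite "
            f"(smallest eigenvalue {eigvals[0]:.3e} vs largest {eigvals[-1]:.3e})"
        )
    return S


def _as_entries(S, validate: bool = True) -> np.ndarray:
    if isinstance(S, CovarianceMatrix):
        return S.entries
    if validate:
        return validate_covariance(S)
    A = np.asarray(S, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1] or A.shape[0] < 2:
        raise ValueError(f"covariance matrix must be square with k >= 2, got {A.shape}")
    return A


def epsilon_hat(S, validate: bool = True) -> float:
    """Greenhouse-Geisser epsilon of a covariance matrix (moment formula).

    With s_jj' the matrix elements, s̄_jj the mean diagonal element, s̄_..
    the grand mean, and s̄_j. the row means::

        eps = k^2 (s̄_jj - s̄_..)^2
              / [ (k-1) ( ΣΣ s_jj'^2 - 2k Σ_j s̄_j.^2 + k^2 s̄_..^2 ) ]

    The value lies in [1/(k-1), 1]; 1 means the matrix is spherical.

    ``validate=False`` skips the positive-definiteness check, which is needed
    for sample covariances of rank < k (small n); the estimator remains
    well defined as long as the double-centered matrix is nonzero.
    """
    A = _as_entries(S, validate=validate)
    k = A.shape[0]
    mean_diag = float(np.mean(np.diag(A)))
    grand = float(np.mean(A))
    row_means = A.mean(axis=1)
    denom = (k - 1) * (
        float(np.sum(A**2)) - 2.0 * k * float(np.sum(row_means**2)) + k**2 * grand**2
    )
    if denom <= 0.0 or not np.isfinite(denom):
        raise ValueError(
            "degenerate covariance (double-centered matrix vanishes, e.g. all "
            "entries equal): epsilon is undefined"
        )
    return k**2 * (mean_diag - grand) ** 2 / denom


def epsilon_eigen_oracle(S) -> float:
    """Box's epsilon via the spectrum of the double-centered matrix.

    Computes (Σλ_i)^2 / [(k-1) Σλ_i^2] over the nonzero eigenvalues λ_i of
    C·S·C with C = I - J/k the centering projector.  Algebraically identical
    to :func:`epsilon_hat`; implemented independently as a cross-check.
    """
    A = _as_entries(S)
    k = A.shape[0]
    C = np.eye(k) - np.ones((k, k)) / k
    lam = np.linalg.eigvalsh(C @ A @ C)
    total = float(lam.sum())
    total_sq = float(np.sum(lam**2))
    if total_sq <= 0.0:
        raise ValueError(
            "degenerate covariance (double-centered matrix vanishes): "
            "epsilon is undefined"
        )
    return total**2 / ((k - 1) * total_sq)


def epsilon_tilde(eps_hat: float, n: int, k: int) -> float:
    """Huynh-Feldt epsilon for a single-group within-subject design.

    ``[n(k-1)·eps_hat - 2] / [(k-1)(n - 1 - (k-1)·eps_hat)]`` with n subjects
    and k measures.  Always >= ``eps_hat``, with equality exactly at the lower
    bound 1/(k-1); may exceed 1 (cap at 1 before adjusting degrees of
    freedom).
    """
    if k < 2:
        raise ValueError(f"need k >= 2, got {k}")
    if n < 2:
        raise ValueError(f"need n >= 2 subjects, got {n}")
    denom = (k - 1) * (n - 1 - (k - 1) * eps_hat)
    if denom <= 0.0:
        raise ValueError(
            f"Huynh-Feldt denominator non-positive for n={n}, k={k}, "
            f"eps_hat={eps_hat}: sample too small for this design"
        )
    return (n * (k - 1) * eps_hat - 2.0) / denom


def epsilon_lower_bound(k: int) -> float:
    """Theoretical minimum of epsilon for k repeated measures: 1/(k-1)."""
    if k < 2:
        raise ValueError(f"need k >= 2, got {k}")
    return 1.0 / (k - 1)


def estimate_epsilons(S, n: int) -> EpsilonEstimates:
    """Bundle epsilon-hat, epsilon-tilde (raw and capped) and the lower bound."""
    A = _as_entries(S)
    k = A.shape[0]
    eh = epsilon_hat(A)
    et = epsilon_tilde(eh, n, k)
    return EpsilonEstimates(
        eps_hat=eh,
        eps_tilde=et,
        eps_tilde_capped=min(et, 1.0),
        lower_bound=epsilon_lower_bound(k),
        n=n,
    )
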