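"""Synthetic inputs for the simulation: covariance matrices with a prescribed
Greenhouse-Geisser epsilon, multivariate-normal sample blocks, and mean
patterns scaled to a target Cohen's f.

Covariance construction
-----------------------
Box's epsilon depends on a covariance matrix only through the spectrum of its
double-centered form C·S·C (C = I - J/k).  We therefore build matrices in a
fixed orthonormal basis {q_1 = 1/sqrt(k), q_2, ..., q_k} (normalized Helmert
contrasts) as

    S = q_1 q_1' + sum_i lambda_i q_{i+1} q_{i+1}',   lambda_i = r**(i-1),

so the centered spectrum is the geometric sequence lambda_1..lambda_{k-1}.
r = 1 gives equal eigenvalues (epsilon = 1, S = identity); r -> 0 drives
epsilon toward its minimum 1/(k-1).  Epsilon is strictly increasing in r, so a
scalar root-find on r reaches any interior target deterministically.  Targets
at (or numerically indistinguishable from) the lower bound use a near-rank-1
centered spectrum (1, delta, ..., delta) with a small flat tail so the matrix
stays positive definite; the same flat-tail family, solved in closed form,
serves targets so close to the bound that the geometric family would go
numerically singular.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Optional, Sequence

import numpy as np
from scipy import optimize

from .sphericity_metrics import (
    CovarianceMatrix,
    epsilon_hat,
    epsilon_lower_bound,
)

__all__ = [
    "CovarianceSpec",
    "MeanPattern",
    "SampleBlock",
    "build_covariance",
    "sample_mvn",
    "mean_patterns",
    "scale_pattern_to_f",
    "cohens_f",
    "helmert_basis",
]

#: flat-tail eigenvalue used when the target epsilon equals the lower bound
_LOWER_BOUND_TAIL = 1e-9
#: smallest geometric-family eigenvalue tolerated before switching families
_MIN_GEOMETRIC_EIGVAL = 1e-10


@dataclass(frozen=True)
class CovarianceSpec:
    """A constructed covariance matrix together with its epsilon bookkeeping."""

    k: int
    target_eps: float
    realized_eps: float
    matrix: CovarianceMatrix
    family_param: float
    family: Literal["geometric", "flat_tail", "identity"]
    tol: float


@dataclass(frozen=True)
class MeanPattern:
    """A mean-vector shape and (optionally) its effect-size-scaled version.

    ``kind`` describes the shape family; ``label`` disambiguates the two
    one-different variants used when k is odd.  ``scaled_vector`` is filled by
    :func:`scale_pattern_to_f` and holds mean deviations (centered) in
    response units.
    """

    kind: Literal["one_different", "half_different", "linear", "flat"]
    label: str
    base_vector: tuple[float, ...]
    scaled_vector: Optional[tuple[float, ...]] = None

    @property
    def k(self) -> int:
        return len(self.base_vector)


@dataclass(frozen=True)
class SampleBlock:
    """An n x k block of simulated responses (subjects by repeated measures)."""

    n: int
    k: int
    values: np.ndarray
    seed: int
    mean_vector: tuple[float, ...]


def helmert_basis(k: int) -> np.ndarray:
    """Orthonormal k x k basis whose first column is the equal-weights vector.

    Columns 2..k are normalized Helmert contrasts; they span the
    between-measure contrast space on which epsilon is defined.
    """
    Q = np.zeros((k, k))
    Q[:, 0] = 1.0 / np.sqrt(k)
    for i in range(1, k):
        Q[:i, i] = 1.0
        Q[i, i] = -float(i)
        Q[:, i] /= np.sqrt(i * (i + 1))
    return Q


def _box_epsilon_of_spectrum(lam: np.ndarray, k: int) -> float:
    return float(lam.sum() ** 2 / ((k - 1) * np.sum(lam**2)))


def _geometric_spectrum(r: float, k: int) -> np.ndarray:
    return r ** np.arange(k - 1)


def _flat_tail_delta(target: float, k: int) -> float:
    """Solve for the flat tail (1, d, ..., d) whose Box epsilon equals target.

    With m = k - 2 tail entries the condition (1 + m d)^2 =
    target (k-1) (1 + m d^2) is quadratic in d; the root in (0, 1) is taken.
    """
    m = k - 2
    t = target * (k - 1)
    a = m * (m - t)
    b = 2.0 * m
    c = 1.0 - t
    if m == 0 or a == 0.0:
        # k = 3 (single tail entry) reduces to the geometric family
        raise ValueError("flat-tail family degenerate for this k/target")
    disc = b * b - 4.0 * a * c
    d = (-b + np.sqrt(disc)) / (2.0 * a)
    return float(d)


def _assemble(spectrum: np.ndarray, k: int) -> np.ndarray:
    Q = helmert_basis(k)
    eigs = np.concatenate(([1.0], spectrum))
    return (Q * eigs) @ Q.T


def build_covariance(k: int, target_eps: float, tol: float = 1e-8) -> CovarianceSpec:
    """Construct a positive-definite k x k covariance matrix whose
    Greenhouse-Geisser epsilon equals ``target_eps`` to within ``tol``.

    Deterministic given (k, target_eps).  ``target_eps`` must lie in
    [1/(k-1), 1]; a target exactly at the lower bound is realized to within
    ~1e-9 above it (a matrix exactly at the bound would be singular).
    """
    if k < 3:
        raise ValueError(f"need k >= 3 to span an epsilon range, got k={k}")
    if tol <= 0:
        raise ValueError("tol must be positive")
    lb = epsilon_lower_bound(k)
    if not (lb - 1e-12 <= target_eps <= 1.0 + 1e-12):
        raise ValueError(
            f"target epsilon {target_eps} outside [{lb:.6g}, 1] for k={k}"
        )

    if target_eps >= 1.0 - 1e-12:
        spectrum = np.ones(k - 1)
        family, param = "identity", 1.0
    elif target_eps <= lb + 1e-12:
        # near-rank-1 centered spectrum; small flat tail keeps the matrix PD
        spectrum = np.concatenate(([1.0], np.full(k - 2, _LOWER_BOUND_TAIL)))
        family, param = "flat_tail", _LOWER_BOUND_TAIL
    else:
        def gap(r: float) -> float:
            return _box_epsilon_of_spectrum(_geometric_spectrum(r, k), k) - target_eps

        r_lo = 1e-8
        if gap(r_lo) > 0.0:
            # target below the geometric family's numerically reachable range
            d = _flat_tail_delta(target_eps, k)
            spectrum = np.concatenate(([1.0], np.full(k - 2, d)))
            family, param = "flat_tail", d
        else:
            r = optimize.brentq(gap, r_lo, 1.0, xtol=1e-15, rtol=1e-15, maxiter=200)
            if r ** (k - 2) < _MIN_GEOMETRIC_EIGVAL:
                d = _flat_tail_delta(target_eps, k)
                spectrum = np.concatenate(([1.0], np.full(k - 2, d)))
                family, param = "flat_tail", d
            else:
                spectrum = _geometric_spectrum(r, k)
                family, param = "geometric", r

    matrix = CovarianceMatrix(_assemble(spectrum, k))
    realized = epsilon_hat(matrix)
    if abs(realized - target_eps) > tol and not (
        target_eps <= lb + 1e-12 and realized - target_eps <= tol
    ):
        raise RuntimeError(
            f"covariance construction missed target epsilon {target_eps} "
            f"(realized {realized}, k={k}, family={family}, param={param})"
        )
    return CovarianceSpec(
        k=k,
        target_eps=float(target_eps),
        realized_eps=realized,
        matrix=matrix,
        family_param=float(param),
        family=family,
        tol=tol,
    )


def sample_mvn(
    spec: CovarianceSpec,
    mean_vector: Sequence[float],
    n: int,
    seed: int | np.random.Generator,
) -> SampleBlock:
    """Draw n independent subjects from N(mean_vector, spec.matrix).

    Data are generated as L·z + mean with L the lower Cholesky factor of the
    covariance matrix and z standard normal, so the same seed reproduces the
    block bit-identically.
    """
    if n < 2:
        raise ValueError(f"need n >= 2 subjects, got {n}")
    mean = np.asarray(mean_vector, dtype=float)
    if mean.shape != (spec.k,):
        raise ValueError(f"mean vector must have length k={spec.k}")
    L = np.linalg.cholesky(spec.matrix.entries)
    if isinstance(seed, np.random.Generator):
        rng, seed_val = seed, -1
    else:
        rng, seed_val = np.random.default_rng(seed), int(seed)
    z = rng.standard_normal((n, spec.k))
    values = z @ L.T + mean
    return SampleBlock(
        n=n, k=spec.k, values=values, seed=seed_val, mean_vector=tuple(mean)
    )


def mean_patterns(k: int) -> list[MeanPattern]:
    """The three mean-vector shapes studied for each design size.

    For every k: a one-different pattern (last mean raised), a second
    non-linear pattern — half the means raised when k is even, the middle mean
    raised when k is odd — and a linear trend with equal increments.
    """
    if k < 3:
        raise ValueError(f"need k >= 3, got {k}")
    one = tuple([1.0] * (k - 1) + [2.0])
    patterns = [MeanPattern("one_different", "one_high_last", one)]
    if k % 2 == 0:
        half = tuple([1.0] * (k // 2) + [2.0] * (k // 2))
        patterns.append(MeanPattern("half_different", "half_high", half))
    else:
        mid = [1.0] * k
        mid[k // 2] = 2.0
        patterns.append(MeanPattern("one_different", "one_high_middle", tuple(mid)))
    linear = tuple(1.0 + 0.75 * np.arange(k))
    patterns.append(MeanPattern("linear", "linear", linear))
    return patterns


def cohens_f(mean_vector: Sequence[float], S) -> float:
    """Cohen's f of a mean vector against a covariance matrix.

    f = sd(mu) / sigma-bar with sd(mu) the population (divide-by-k) standard
    deviation of the level means and sigma-bar = sqrt(trace(S)/k) the root
    mean within-level variance.
    """
    mu = np.asarray(mean_vector, dtype=float)
    entries = S.entries if isinstance(S, CovarianceMatrix) else np.asarray(S, float)
    sigma_bar = np.sqrt(np.trace(entries) / entries.shape[0])
    return float(np.sqrt(np.mean((mu - mu.mean()) ** 2)) / sigma_bar)


def scale_pattern_to_f(
    pattern: MeanPattern, S, f_target: float
) -> MeanPattern:
    """Scale a pattern's mean deviations so its population Cohen's f equals
    ``f_target`` against covariance ``S``, preserving the shape.

    The scaled vector is centered (zero grand mean); only deviations matter
    for the within-subject F-test.
    """
    entries = S.entries if isinstance(S, CovarianceMatrix) else np.asarray(S, float)
    k = entries.shape[0]
    base = np.asarray(pattern.base_vector, dtype=float)
    if base.shape != (k,):
        raise ValueError(f"pattern has k={base.size} but covariance has k={k}")
    dev = base - base.mean()
    sd = np.sqrt(np.mean(dev**2))
    if sd == 0.0:
        if f_target != 0.0:
            raise ValueError("flat pattern cannot achieve a nonzero effect size")
        return replace(pattern, scaled_vector=tuple(np.zeros(k)))
    sigma_bar = np.sqrt(np.trace(entries) / k)
    scaled = dev * (f_target * sigma_bar / sd)
    return replace(pattern, scaled_vector=tuple(scaled))
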