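"""Condition grids and seeded Monte Carlo execution.

The Type I error design crosses the number of repeated measures K in
{3, 4, 6} with a K-specific grid of target Greenhouse-Geisser epsilon values
(from the lower bound 1/(K-1) up to 1) and 19 sample sizes from 10 to 300,
giving 437 null conditions.  The power design replaces the null mean vector
with one of three mean patterns per K, scaled to Cohen's f = 0.25, over the
same grid minus each K's lower-bound epsilon level: 1,140 conditions.

Each condition is simulated with its own random stream derived from the
master seed and the condition index, so any condition is reproducible in
isolation and results do not depend on execution order or worker count.
Replications are processed in vectorized batches: all replications of a
condition share one covariance Cholesky factor, and the ANOVA decomposition,
epsilon estimates, and F-tail probabilities are evaluated on whole batches at
once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic_data import (
    CovarianceSpec,
    MeanPattern,
    build_covariance,
    mean_patterns,
    scale_pattern_to_f,
)

__all__ = [
    "Condition",
    "ConditionResult",
    "EPSILON_GRIDS",
    "SAMPLE_SIZES",
    "EFFECT_SIZE_F",
    "type1_grid",
    "power_grid",
    "run_condition",
    "run_grid",
    "results_to_frame",
]

logger = logging.getLogger(__name__)

#: target epsilon-hat grids per design size; the first entry of each list is
#: the exact lower bound 1/(K-1)
EPSILON_GRIDS: dict[int, tuple[float, ...]] = {
    3: (0.5, 0.6, 0.7, 0.8, 0.9, 1.0),
    4: (1.0 / 3.0, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0),
    6: (0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0),
}

SAMPLE_SIZES: tuple[int, ...] = (
    10, 15, 20, 25, 30, 40, 50, 60, 70, 80, 90, 100,
    120, 150, 180, 210, 240, 270, 300,
)

#: medium effect size used for all power conditions
EFFECT_SIZE_F = 0.25

DEFAULT_ALPHA = 0.05

#: cap on batch memory: replications per batch chosen so a batch holds at most
#: this many doubles
_BATCH_ELEMENTS = 4_000_000


@dataclass(frozen=True)
class Condition:
    """One cell of the simulation design."""

    design: Literal["type1", "power"]
    k: int
    eps_target: float
    eps_label: float
    is_lower_bound: bool
    n: int
    pattern: Optional[MeanPattern]
    alpha: float
    condition_index: int


@dataclass(frozen=True)
class ConditionResult:
    """Empirical rejection percentages for one condition."""

    condition: Condition
    nreps: int
    seed: int
    realized_eps: float
    rej_f: float
    rej_gg: float
    rej_hf: float
    mean_eps_hat: float
    mean_sample_f: float


def type1_grid(alpha: float = DEFAULT_ALPHA) -> list[Condition]:
    """All null-mean conditions: K crossed with its epsilon grid and the 19
    sample sizes (437 conditions)."""
    conditions: list[Condition] = []
    idx = 0
    for k in sorted(EPSILON_GRIDS):
        grid = EPSILON_GRIDS[k]
        for j, eps in enumerate(grid):
            for n in SAMPLE_SIZES:
                conditions.append(
                    Condition(
                        design="type1",
                        k=k,
                        eps_target=eps,
                        eps_label=round(eps, 2),
                        is_lower_bound=(j == 0),
                        n=n,
                        pattern=None,
                        alpha=alpha,
                        condition_index=idx,
                    )
                )
                idx += 1
    return conditions


def power_grid(alpha: float = DEFAULT_ALPHA) -> list[Condition]:
    """All power conditions: three mean patterns per K crossed with each K's
    epsilon grid excluding its lower-bound level, and the 19 sample sizes
    (1,140 conditions).

    Lower-bound levels are excluded because there the Greenhouse-Geisser and
    Huynh-Feldt estimates coincide and the two adjusted tests are identical.
    """
    conditions: list[Condition] = []
    idx = 0
    for k in sorted(EPSILON_GRIDS):
        grid = EPSILON_GRIDS[k][1:]  # drop the lower bound
        for pattern in mean_patterns(k):
            for eps in grid:
                for n in SAMPLE_SIZES:
                    conditions.append(
                        Condition(
                            design="power",
                            k=k,
                            eps_target=eps,
                            eps_label=round(eps, 2),
                            is_lower_bound=False,
                            n=n,
                            pattern=pattern,
                            alpha=alpha,
                            condition_index=idx,
                        )
                    )
                    idx += 1
    return conditions


def _batch_rm_anova(X: np.ndarray) -> dict[str, np.ndarray]:
    """Vectorized one-way RM-ANOVA over a batch of blocks.

    ``X`` has shape (reps, n, k).  Returns per-replication arrays of the
    three p-values, the epsilon estimates, and the sample Cohen's f.  The
    arithmetic mirrors :func:`sphersim.rm_anova.fit_rm_anova` exactly (same
    estimators, same divisors); the two paths are cross-checked in the test
    suite.
    """
    reps, n, k = X.shape
    grand = X.mean(axis=(1, 2))
    col_means = X.mean(axis=1)
    row_means = X.mean(axis=2)
    ss_t = n * np.sum((col_means - grand[:, None]) ** 2, axis=1)
    ss_s = k * np.sum((row_means - grand[:, None]) ** 2, axis=1)
    ss_tot = np.sum((X - grand[:, None, None]) ** 2, axis=(1, 2))
    ss_r = np.maximum(ss_tot - ss_t - ss_s, 0.0)
    df1 = k - 1
    df2 = (k - 1) * (n - 1)
    if np.any(ss_r <= 0.0):
        raise RuntimeError("degenerate replication: zero residual sum of squares")
    f_val = (ss_t / df1) / (ss_r / df2)

    Xc = X - col_means[:, None, :]
    S = Xc.transpose(0, 2, 1) @ Xc / (n - 1)

    diag = S[:, np.arange(k), np.arange(k)]
    mean_diag = diag.mean(axis=1)
    grand_s = S.mean(axis=(1, 2))
    row_s = S.mean(axis=2)
    den = (k - 1) * (
        np.sum(S**2, axis=(1, 2))
        - 2.0 * k * np.sum(row_s**2, axis=1)
        + k**2 * grand_s**2
    )
    eps_hat = np.minimum(k**2 * (mean_diag - grand_s) ** 2 / den, 1.0)
    eps_tilde = (n * (k - 1) * eps_hat - 2.0) / (
        (k - 1) * (n - 1 - (k - 1) * eps_hat)
    )
    eps_hf = np.minimum(eps_tilde, 1.0)

    p_un = stats.f.sf(f_val, df1, df2)
    p_gg = stats.f.sf(f_val, eps_hat * df1, eps_hat * df2)
    p_hf = stats.f.sf(f_val, eps_hf * df1, eps_hf * df2)

    sample_f = np.sqrt(np.mean((col_means - grand[:, None]) ** 2, axis=1)) / np.sqrt(
        mean_diag
    )
    return {
        "p_un": p_un,
        "p_gg": p_gg,
        "p_hf": p_hf,
        "eps_hat": eps_hat,
        "sample_f": sample_f,
    }


def run_condition(
    condition: Condition,
    nreps: int,
    seed: int,
    spec: Optional[CovarianceSpec] = None,
) -> ConditionResult:
    """Simulate one condition: ``nreps`` multivariate-normal blocks, each fit
    with the RM-ANOVA, returning percentage rejections of the three tests.

    ``spec`` may carry a pre-built covariance (must match the condition's k
    and epsilon target); otherwise it is constructed here.  Reproducible
    given (condition, nreps, seed) and independent of batch partitioning.
    """
    if nreps < 1:
        raise ValueError("nreps must be >= 1")
    if spec is None:
        spec = build_covariance(condition.k, condition.eps_target)
    elif spec.k != condition.k or abs(spec.target_eps - condition.eps_target) > spec.tol:
        raise ValueError("provided covariance spec does not match the condition")

    if condition.pattern is not None:
        scaled = scale_pattern_to_f(condition.pattern, spec.matrix, EFFECT_SIZE_F)
        mean = np.asarray(scaled.scaled_vector)
    else:
        mean = np.zeros(condition.k)

    L = np.linalg.cholesky(spec.matrix.entries)
    rng = np.random.default_rng(seed)
    n, k = condition.n, condition.k
    batch = max(1, _BATCH_ELEMENTS // (n * k))

    n_rej = np.zeros(3, dtype=np.int64)
    sum_eps = 0.0
    sum_f = 0.0
    done = 0
    while done < nreps:
        m = min(batch, nreps - done)
        z = rng.standard_normal((m, n, k))
        X = z @ L.T + mean
        try:
            out = _batch_rm_anova(X)
        except RuntimeError as exc:  # pragma: no cover - a.s. impossible under PD Gaussian
            raise RuntimeError(
                f"condition {condition.condition_index} "
                f"(k={k}, eps={condition.eps_target}, n={n}): {exc}"
            ) from exc
        alpha = condition.alpha
        n_rej += [
            int(np.count_nonzero(out["p_un"] <= alpha)),
            int(np.count_nonzero(out["p_gg"] <= alpha)),
            int(np.count_nonzero(out["p_hf"] <= alpha)),
        ]
        sum_eps += float(out["eps_hat"].sum())
        sum_f += float(out["sample_f"].sum())
        done += m

    pct = 100.0 * n_rej / nreps
    return ConditionResult(
        condition=condition,
        nreps=nreps,
        seed=int(seed),
        realized_eps=spec.realized_eps,
        rej_f=float(pct[0]),
        rej_gg=float(pct[1]),
        rej_hf=float(pct[2]),
        mean_eps_hat=sum_eps / nreps,
        mean_sample_f=(sum_f / nreps) if condition.pattern is not None else float("nan"),
    )


def derive_condition_seed(master_seed: int, condition_index: int) -> int:
    """Deterministic per-condition seed from the master seed."""
    ss = np.random.SeedSequence([int(master_seed), int(condition_index)])
    return int(ss.generate_state(1, dtype=np.uint32)[0])


def run_grid(
    design: Literal["type1", "power"] | Sequence[Condition],
    nreps: int,
    master_seed: int,
    workers: int = 1,
    out_csv: Optional[str] = None,
    alpha: float = DEFAULT_ALPHA,
) -> list[ConditionResult]:
    """Run every condition of a design with independent per-condition seeds.

    Results are identical for any ``workers`` value (each condition's random
    stream depends only on the master seed and its index).  If ``out_csv`` is
    given, rows are appended as conditions complete.
    """
    if isinstance(design, str):
        if design == "type1":
            conditions = type1_grid(alpha=alpha)
        elif design == "power":
            conditions = power_grid(alpha=alpha)
        else:
            raise ValueError(f"unknown design {design!r}")
    else:
        conditions = list(design)

    # one covariance per (k, eps): shared across sample sizes
    specs: dict[tuple[int, float], CovarianceSpec] = {}
    for c in conditions:
        key = (c.k, c.eps_target)
        if key not in specs:
            specs[key] = build_covariance(c.k, c.eps_target)

    def _one(c: Condition) -> ConditionResult:
        return run_condition(
            c, nreps, derive_condition_seed(master_seed, c.condition_index),
            spec=specs[(c.k, c.eps_target)],
        )

    writer = _CsvStreamWriter(out_csv) if out_csv else None
    results: list[ConditionResult] = []
    if workers == 1:
        iterator: Iterable[ConditionResult] = (_one(c) for c in conditions)
    else:
        from joblib import Parallel, delayed

        iterator = Parallel(n_jobs=workers, return_as="generator")(
            delayed(_one)(c) for c in conditions
        )
    for res in iterator:
        results.append(res)
        c = res.condition
        logger.info(
            "condition %d/%d done: k=%d eps=%.3f n=%d rej_f=%.2f rej_gg=%.2f rej_hf=%.2f",
            c.condition_index + 1, len(conditions), c.k, c.eps_target, c.n,
            res.rej_f, res.rej_gg, res.rej_hf,
        )
        if writer is not None:
            writer.write(res)
    if writer is not None:
        writer.close()
    return results


def results_to_frame(results: Sequence[ConditionResult]) -> pd.DataFrame:
    """Flatten condition results into the canonical results table."""
    rows = [_result_row(r) for r in results]
    return pd.DataFrame(rows, columns=_RESULT_COLUMNS)


_RESULT_COLUMNS = [
    "design", "k", "eps_target", "eps_label", "is_lower_bound", "realized_eps",
    "n", "pattern_kind", "pattern_label", "nreps", "seed",
    "rej_f", "rej_gg", "rej_hf", "mean_eps_hat", "mean_sample_f",
]


def _result_row(r: ConditionResult) -> dict:
    c = r.condition
    return {
        "design": c.design,
        "k": c.k,
        "eps_target": c.eps_target,
        "eps_label": c.eps_label,
        "is_lower_bound": c.is_lower_bound,
        "realized_eps": r.realized_eps,
        "n": c.n,
        "pattern_kind": c.pattern.kind if c.pattern else "null",
        "pattern_label": c.pattern.label if c.pattern else "null",
        "nreps": r.nreps,
        "seed": r.seed,
        "rej_f": r.rej_f,
        "rej_gg": r.rej_gg,
        "rej_hf": r.rej_hf,
        "mean_eps_hat": r.mean_eps_hat,
        "mean_sample_f": r.mean_sample_f,
    }


class _CsvStreamWriter:
    """Append condition results to a CSV file as they complete."""

    def __init__(self, path: str):
        self._fh = open(path, "w", newline="")
        self._fh.write(",".join(_RESULT_COLUMNS) + "\n")

    def write(self, r: ConditionResult) -> None:
        row = _result_row(r)
        self._fh.write(",".join(_fmt(row[c]) for c in _RESULT_COLUMNS) + "\n")
        self._fh.flush()

    def close(self) -> None:
        self._fh.close()


def _fmt(v) -> str:
    if isinstance(v, float):
        return repr(v)
    return str(v)
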