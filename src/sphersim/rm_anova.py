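"""One-way repeated-measures ANOVA with sphericity-corrected p-values.

The n x k data block (subjects by repeated measures) is decomposed additively
as a two-way table with one observation per cell:

    SS_total = SS_treatment + SS_subject + SS_residual

and F = MS_treatment / MS_residual is referred to the F distribution with
(k-1) and (k-1)(n-1) degrees of freedom.  When the covariance of the k
measures is not spherical this reference distribution is too liberal; the
Greenhouse-Geisser and Huynh-Feldt procedures multiply both degrees of
freedom by an epsilon estimate (eps-hat, and min(eps-tilde, 1) respectively)
computed from the sample covariance.  All three p-values are always computed;
non-integer degrees of freedom are handled exactly through the continuous F
distribution (regularized incomplete beta function).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .sphericity_metrics import epsilon_hat, epsilon_tilde

__all__ = ["RMAnovaFit", "fit_rm_anova", "adjusted_p"]


@dataclass(frozen=True)
class RMAnovaFit:
    """Result of a one-way within-subject ANOVA on an n x k block."""

    n: int
    k: int
    f_value: float
    df_num: int
    df_den: int
    ss_treatment: float
    ss_subject: float
    ss_residual: float
    eps_hat: float
    eps_tilde: float
    eps_tilde_capped: float
    p_unadjusted: float
    p_gg: float
    p_hf: float


def adjusted_p(f_value: float, df_num: float, df_den: float, eps: float) -> float:
    """Upper-tail F probability with both degrees of freedom scaled by eps.

    ``eps`` must lie in (0, 1]; eps = 1 reproduces the unadjusted p-value.
    """
    if not (0.0 < eps <= 1.0):
        raise ValueError(f"epsilon must be in (0, 1], got {eps}")
    if df_num <= 0 or df_den <= 0:
        raise ValueError("degrees of freedom must be positive")
    return float(stats.f.sf(f_value, eps * df_num, eps * df_den))


def fit_rm_anova(data: np.ndarray) -> RMAnovaFit:
    """Fit the one-way repeated-measures ANOVA on an n x k data block.

    Returns the F statistic, the additive sum-of-squares decomposition, the
    sample epsilon estimates (divisor n-1 covariance), and the unadjusted,
    Greenhouse-Geisser, and Huynh-Feldt p-values.
    """
    X = np.asarray(data, dtype=float)
    if X.ndim != 2:
        raise ValueError(f"data must be a 2-D subjects-by-measures block, got {X.ndim}-D")
    n, k = X.shape
    if n < 2 or k < 2:
        raise ValueError(f"need at least 2 subjects and 2 measures, got n={n}, k={k}")

    grand = X.mean()
    col_means = X.mean(axis=0)
    row_means = X.mean(axis=1)
    ss_treatment = n * float(np.sum((col_means - grand) ** 2))
    ss_subject = k * float(np.sum((row_means - grand) ** 2))
    ss_total = float(np.sum((X - grand) ** 2))
    ss_residual = ss_total - ss_treatment - ss_subject
    # exact decomposition; guard against tiny negative round-off
    ss_residual = max(ss_residual, 0.0)

    df_num = k - 1
    df_den = (k - 1) * (n - 1)
    ms_residual = ss_residual / df_den
    if ms_residual <= 0.0:
        raise ValueError(
            "degenerate fit: residual mean square is zero (columns differ by "
            "exact per-subject constants)"
        )
    f_value = (ss_treatment / df_num) / ms_residual

    S = np.cov(X, rowvar=False, ddof=1)
    # round-off can push the estimate a few ulp past 1 for spherical samples
    eh = min(epsilon_hat(S, validate=False), 1.0)
    et = epsilon_tilde(eh, n, k)
    et_capped = min(et, 1.0)

    return RMAnovaFit(
        n=n,
        k=k,
        f_value=float(f_value),
        df_num=df_num,
        df_den=df_den,
        ss_treatment=ss_treatment,
        ss_subject=ss_subject,
        ss_residual=ss_residual,
        eps_hat=eh,
        eps_tilde=et,
        eps_tilde_capped=et_capped,
        p_unadjusted=float(stats.f.sf(f_value, df_num, df_den)),
        p_gg=adjusted_p(f_value, df_num, df_den, eh),
        p_hf=adjusted_p(f_value, df_num, df_den, et_capped),
    )
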