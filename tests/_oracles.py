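"""Independent brute-force oracles for cross-checking the implementation.

Everything here is written with explicit loops and elementary formulas,
deliberately sharing no code with the package.
"""

import numpy as np
from scipy import integrate, stats


def brute_force_rm_anova(X: np.ndarray) -> dict:
    """Two-way (subjects x treatments) decomposition via explicit loops,
    epsilon estimates from first principles, and quadrature p-values."""
    n, k = X.shape
    grand = sum(X[i][j] for i in range(n) for j in range(k)) / (n * k)
    col = [sum(X[i][j] for i in range(n)) / n for j in range(k)]
    row = [sum(X[i][j] for j in range(k)) / k for i in range(n)]

    ss_t = n * sum((c - grand) ** 2 for c in col)
    ss_s = k * sum((r - grand) ** 2 for r in row)
    ss_tot = sum((X[i][j] - grand) ** 2 for i in range(n) for j in range(k))
    ss_r = ss_tot - ss_t - ss_s

    df1, df2 = k - 1, (k - 1) * (n - 1)
    f_val = (ss_t / df1) / (ss_r / df2)

    # sample covariance, divisor n - 1
    S = [
        [
            sum((X[i][a] - col[a]) * (X[i][b] - col[b]) for i in range(n)) / (n - 1)
            for b in range(k)
        ]
        for a in range(k)
    ]
    mean_diag = sum(S[j][j] for j in range(k)) / k
    mean_all = sum(S[a][b] for a in range(k) for b in range(k)) / k**2
    row_means = [sum(S[a][b] for b in range(k)) / k for a in range(k)]
    num = k**2 * (mean_diag - mean_all) ** 2
    den = (k - 1) * (
        sum(S[a][b] ** 2 for a in range(k) for b in range(k))
        - 2 * k * sum(m**2 for m in row_means)
        + k**2 * mean_all**2
    )
    eps_hat = num / den
    eps_tilde = (n * (k - 1) * eps_hat - 2) / ((k - 1) * (n - 1 - (k - 1) * eps_hat))
    eps_hf = min(eps_tilde, 1.0)

    return {
        "ss_treatment": ss_t,
        "ss_subject": ss_s,
        "ss_residual": ss_r,
        "f_value": f_val,
        "eps_hat": eps_hat,
        "eps_tilde": eps_tilde,
        "p_unadjusted": quadrature_f_tail(f_val, df1, df2),
        "p_gg": quadrature_f_tail(f_val, eps_hat * df1, eps_hat * df2),
        "p_hf": quadrature_f_tail(f_val, eps_hf * df1, eps_hf * df2),
    }


def quadrature_f_tail(x: float, d1: float, d2: float) -> float:
    """Upper-tail F probability by numerical integration of the density."""
    val, _ = integrate.quad(
        lambda t: stats.f.pdf(t, d1, d2), x, np.inf, epsabs=1e-13, epsrel=1e-13
    )
    return val
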