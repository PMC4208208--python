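"""Identification-quality diagnostics for the stacked linear system.

Treating the identification as an ordinary linear model
``y = D x + noise`` (rows r = 2m, columns c = 7), the quality measures
are: the condition number of the regressor (numerical sensitivity of the
solution), the residual standard deviation, per-parameter standard
deviations from the parameter covariance ``sigma_rho^2 (D^T D)^-1``,
relative standard deviations in percent, their ratio to the smallest one
(the k-ratio; k > 10 flags a poorly identified parameter) and a
two-sided Student-t significance test per parameter (p > 0.01 flags a
parameter that does not contribute to the model).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .sesc_core import (
    PARAMETER_LABELS,
    SVD_RCOND,
    IdentificationSystem,
    RankDeficiencyError,
    SESCParameters,
)

#: k-ratio above which a parameter is considered poorly identified
K_RATIO_THRESHOLD = 10.0
#: two-sided p-value above which a parameter is considered not significant
P_VALUE_THRESHOLD = 0.01
#: default acceptable regressor condition number for a well-excited protocol
DEFAULT_COND_THRESHOLD = 20.0

# residuals below this (meters) are treated as an exact fit
_EXACT_FIT_TOL = 1e-12


@dataclass
class IdentificationDiagnostics:
    """Per-identification quality summary; vectors ordered like
    :data:`~sesc.sesc_core.PARAMETER_LABELS`."""

    cond: float
    sigma_rho: float
    param_sigma: np.ndarray
    rel_std_pct: np.ndarray
    k_ratio: np.ndarray
    t_stats: np.ndarray
    t_pvalues: np.ndarray
    dof: int
    poorly_identified: np.ndarray  # bool, k > 10
    not_significant: np.ndarray  # bool, p > 0.01

    def to_dict(self) -> dict:
        return {
            "cond": float(self.cond),
            "sigma_rho_m": float(self.sigma_rho),
            "dof": int(self.dof),
            "parameters": {
                label: {
                    "sigma_m": float(self.param_sigma[j]),
                    "rel_std_pct": float(self.rel_std_pct[j]),
                    "k_ratio": float(self.k_ratio[j]),
                    "t": float(self.t_stats[j]),
                    "p": float(self.t_pvalues[j]),
                    "poorly_identified": bool(self.poorly_identified[j]),
                    "not_significant": bool(self.not_significant[j]),
                }
                for j, label in enumerate(PARAMETER_LABELS)
            },
        }


def condition_number(D: np.ndarray) -> float:
    """Ratio of extreme singular values; +inf for a rank-deficient matrix."""
    D = np.asarray(D, dtype=float)
    if D.size == 0:
        raise ValueError("empty matrix has no condition number")
    s = np.linalg.svd(D, compute_uv=False)
    if s[-1] <= s[0] * SVD_RCOND:  # numerically rank deficient
        return float("inf")
    return float(s[0] / s[-1])


def compute_diagnostics(
    system: IdentificationSystem, params: SESCParameters
) -> IdentificationDiagnostics:
    """Quality metrics for an identified parameter set on its own system.

    Requires more rows than parameters (dof = r - c > 0) and a full-rank
    regressor.  For an exact fit (zero residual) all standard deviations
    and relative standard deviations are zero and every k-ratio is 1.
    """
    D, y = system.D, system.y
    r, c = D.shape
    if r <= c:
        raise ValueError(
            f"diagnostics need more rows than parameters (r={r} <= c={c}); "
            "record more static postures"
        )
    x = params.as_vector()

    u, s, vt = np.linalg.svd(D, full_matrices=False)
    if s[-1] <= s[0] * SVD_RCOND:
        raise RankDeficiencyError(rank=int((s > s[0] * SVD_RCOND).sum()), cond=float("inf"))
    cond = float(s[0] / s[-1])

    resid = y - D @ x
    dof = r - c
    sigma_rho2 = float(resid @ resid) / dof
    sigma_rho = float(np.sqrt(sigma_rho2))

    # (D^T D)^-1 through the SVD for stability
    dtd_inv = (vt.T * (1.0 / s**2)) @ vt
    param_sigma = np.sqrt(sigma_rho2 * np.diag(dtd_inv))

    exact = sigma_rho <= _EXACT_FIT_TOL
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = 100.0 * param_sigma / np.abs(x)
    if exact:
        rel = np.zeros(c)
        k = np.ones(c)
        t = np.where(x == 0.0, 0.0, np.inf * np.sign(x))
    else:
        rel = np.where(np.abs(x) > 0.0, rel, np.inf)
        k = rel / rel.min()
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(param_sigma > 0.0, x / param_sigma, np.inf * np.sign(x))
        t = np.where((x == 0.0) & (param_sigma == 0.0), 0.0, t)
    pvals = 2.0 * stats.t.sf(np.abs(t), df=dof)
    pvals = np.where(np.isinf(t), 0.0, pvals)
    pvals = np.where(t == 0.0, 1.0, pvals)

    return IdentificationDiagnostics(
        cond=cond,
        sigma_rho=sigma_rho,
        param_sigma=param_sigma,
        rel_std_pct=rel,
        k_ratio=k,
        t_stats=t,
        t_pvalues=pvals,
        dof=dof,
        poorly_identified=k > K_RATIO_THRESHOLD,
        not_significant=pvals > P_VALUE_THRESHOLD,
    )


def grade_identification(
    diag: IdentificationDiagnostics, cond_threshold: float = DEFAULT_COND_THRESHOLD
) -> dict:
    """Structured pass/warn report on conditioning and per-parameter quality."""
    flagged_k = [PARAMETER_LABELS[j] for j in range(7) if diag.poorly_identified[j]]
    flagged_p = [PARAMETER_LABELS[j] for j in range(7) if diag.not_significant[j]]
    cond_ok = diag.cond < cond_threshold
    return {
        "cond": float(diag.cond),
        "cond_threshold": float(cond_threshold),
        "cond_ok": bool(cond_ok),
        "poorly_identified": flagged_k,
        "not_significant": flagged_p,
        "passed": bool(cond_ok and not flagged_k and not flagged_p),
    }


def render_diagnostics_table(params: SESCParameters, diag: IdentificationDiagnostics) -> str:
    """Plain-text table: parameter value (optionally height-normalized),
    k-ratio and significance, followed by the condition number."""
    vec = params.as_vector()
    norm = params.height is not None
    values = vec / params.height if norm else vec
    unit = "/height" if norm else "m"
    lines = [
        f"{'param':>6} {'value [' + unit + ']':>16} {'k':>10} {'p':>10}  flags",
        "-" * 56,
    ]
    for j, label in enumerate(PARAMETER_LABELS):
        flags = []
        if diag.poorly_identified[j]:
            flags.append("k>10")
        if diag.not_significant[j]:
            flags.append("p>0.01")
        lines.append(
            f"{label:>6} {values[j]:>16.4f} {diag.k_ratio[j]:>10.2f} "
            f"{diag.t_pvalues[j]:>10.3g}  {','.join(flags)}"
        )
    lines.append("-" * 56)
    lines.append(f"cond(D) = {diag.cond:.2f}   sigma_rho = {diag.sigma_rho * 1e3:.3f} mm"
                 f"   dof = {diag.dof}")
    return "\n".join(lines)
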