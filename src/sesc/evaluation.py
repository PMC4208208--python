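"""Cross-validation protocol and accuracy metrics.

Estimated CoM ground projections are compared to the measured CoP over a
validation posture set disjoint from the identification set.  Metrics
(reported in millimeters): rmse of the planar residual norms, per-axis
anterior-posterior (AP, x) and medio-lateral (ML, y) rmse, and the
coefficient of determination R^2 computed per axis against the CoP
series and aggregated across the two axes (mean by default).  R^2 may be
negative (an estimator worse than the CoP mean) and is never clamped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .anthropometry import AnthropometricTable, literature_sesc
from .quality import IdentificationDiagnostics, compute_diagnostics
from .sesc_core import (
    SESCParameters,
    assemble_identification_system,
    estimate_com,
    identify,
)
from .synthetic import VirtualSession, windows_from_session


@dataclass
class EvaluationReport:
    rmse_mm: float
    ap_rmse_mm: float
    ml_rmse_mm: float
    r_squared: float
    n_postures: int
    residuals_mm: np.ndarray  # (n, 2) signed per-axis residuals

    def to_dict(self) -> dict:
        return {
            "rmse_mm": float(self.rmse_mm),
            "ap_rmse_mm": float(self.ap_rmse_mm),
            "ml_rmse_mm": float(self.ml_rmse_mm),
            "r_squared": float(self.r_squared),
            "n_postures": int(self.n_postures),
        }


def split_identification_validation(
    windows: Sequence, n_identify: int = 40, seed: int = 0
) -> tuple[list, list]:
    """Seeded disjoint split into identification and validation sets."""
    windows = list(windows)
    if len(windows) < n_identify + 1:
        raise ValueError(
            f"need at least {n_identify + 1} windows for a {n_identify}/validation "
            f"split, got {len(windows)}"
        )
    order = np.random.default_rng(seed).permutation(len(windows))
    ident = [windows[i] for i in sorted(order[:n_identify])]
    valid = [windows[i] for i in sorted(order[n_identify:])]
    return ident, valid


def evaluate(
    estimates: np.ndarray,
    cop: np.ndarray,
    r2_aggregation: str = "mean",
) -> EvaluationReport:
    """Accuracy of planar CoM estimates against measured CoP (both meters).

    ``r2_aggregation`` is ``"mean"`` (average the per-axis R^2) or
    ``"min"`` (worst axis).
    """
    est = np.asarray(estimates, dtype=float).reshape(-1, 2)
    ref = np.asarray(cop, dtype=float).reshape(-1, 2)
    if est.shape != ref.shape:
        raise ValueError(f"length mismatch: {est.shape} vs {ref.shape}")
    n = len(est)
    if n < 2:
        raise ValueError("at least 2 postures are required (R^2 needs variance)")
    res = est - ref
    rmse = float(np.sqrt(np.mean(np.sum(res**2, axis=1))))
    ax_rmse = np.sqrt(np.mean(res**2, axis=0))
    ss_res = np.sum(res**2, axis=0)
    ss_tot = np.sum((ref - ref.mean(axis=0)) ** 2, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2_axes = 1.0 - ss_res / ss_tot
    if r2_aggregation == "mean":
        r2 = float(np.mean(r2_axes))
    elif r2_aggregation == "min":
        r2 = float(np.min(r2_axes))
    else:
        raise ValueError("r2_aggregation must be 'mean' or 'min'")
    return EvaluationReport(
        rmse_mm=rmse * 1000.0,
        ap_rmse_mm=float(ax_rmse[0] * 1000.0),
        ml_rmse_mm=float(ax_rmse[1] * 1000.0),
        r_squared=r2,
        n_postures=n,
        residuals_mm=res * 1000.0,
    )


@dataclass
class MethodComparison:
    reports: dict[str, EvaluationReport]
    ordering: list[str]  # method names sorted best (lowest rmse) first
    params: SESCParameters
    diagnostics: IdentificationDiagnostics | None

    def to_dict(self) -> dict:
        return {
            "reports": {k: v.to_dict() for k, v in self.reports.items()},
            "ordering": self.ordering,
        }


def compare_methods(
    session: VirtualSession,
    n_identify: int = 40,
    split_seed: int = 0,
    table: AnthropometricTable | None = None,
    windows: Sequence | None = None,
    with_diagnostics: bool = False,
) -> MethodComparison:
    """Identified-SESC vs literature estimator on one virtual session.

    Identification runs on ``n_identify`` windows; both methods are then
    evaluated on the disjoint validation windows against the measured
    CoP.  ``windows`` defaults to label-averaged holds of the session.
    """
    if windows is None:
        windows = windows_from_session(session)
    ident, valid = split_identification_validation(windows, n_identify, seed=split_seed)
    system = assemble_identification_system(ident)
    params = identify(system)
    if params.height is None:
        params.height = session.model.height

    lit = literature_sesc(session.model.height, table=table)
    cop = np.array([w.mean_cop for w in valid])
    est_sesc = np.array([estimate_com(params, w.mean_posture)[:2] for w in valid])
    est_lit = np.array([estimate_com(lit, w.mean_posture)[:2] for w in valid])
    reports = {
        "sesc_identified": evaluate(est_sesc, cop),
        "literature": evaluate(est_lit, cop),
    }
    ordering = sorted(reports, key=lambda k: reports[k].rmse_mm)
    diag = compute_diagnostics(system, params) if with_diagnostics else None
    return MethodComparison(reports=reports, ordering=ordering, params=params, diagnostics=diag)
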