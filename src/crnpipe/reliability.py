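"""Generalizability-theory reliability from the extended-model posterior.

Two coefficients are computed from the random-RT-slope (extended) model fit:

* subject-level internal consistency
  ``phi_j = sigma_m^2 / (sigma_m^2 + sigma_e_j^2 / n_j)``, where for each
  posterior draw ``sigma_m^2`` is the variance of the model-predicted trial
  values over subject j's trials, ``sigma_e_j^2`` the variance of that
  subject's residuals, and ``n_j`` the subject's trial count; and

* group-level fixed-effects dependability
  ``phi_G(S) = sigma_G^2 / (sigma_G^2 + (sigma_s^2 + sigma_e^2 / n_hat) / S)``
  per condition, where ``sigma_G^2`` is the variance of the fixed-effect
  predictions, ``sigma_s^2`` the variance of the subject-specific parts
  (random slope and intercept contributions), ``sigma_e^2`` the residual
  variance, ``n_hat`` the harmonic mean trial count per subject, and ``S``
  the number of subjects.

Both are evaluated per posterior draw and summarized (mean and central 95%
interval).  Variances are population-style (divide by n), matching a
draw-wise deterministic transform of the posterior sample.  Subjects whose
posterior-mean ``phi_j`` falls below the retention threshold (.8) are
excluded from final fixed-effects modeling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import DesignMatrix, PosteriorFit

__all__ = [
    "ReliabilityReport",
    "phi_subject",
    "phi_group",
    "subject_internal_consistency",
    "fixed_effects_dependability",
    "retain_subjects",
]


def phi_subject(sigma_m2: float, sigma_e2: float, n: int) -> float:
    """Closed-form internal consistency for known variance components."""
    if n < 1:
        raise ValueError("n must be at least 1")
    return sigma_m2 / (sigma_m2 + sigma_e2 / n)


def phi_group(sigma_G2: float, sigma_s2: float, sigma_e2: float, n_hat: float, S: float) -> float:
    """Closed-form fixed-effects dependability for known variance components."""
    if S <= 0 or n_hat <= 0:
        raise ValueError("S and n_hat must be positive")
    return sigma_G2 / (sigma_G2 + (sigma_s2 + sigma_e2 / n_hat) / S)


@dataclass
class ReliabilityReport:
    """Subject-level phi_j table, per-condition dependability curves, and the
    retention decision at the configured threshold."""

    subject_table: pd.DataFrame
    group_table: pd.DataFrame
    n_hat: dict[str, float]
    threshold: float = 0.8
    meta: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "n_hat": self.n_hat,
            "subjects": self.subject_table.to_dict(orient="records"),
            "groups": self.group_table.to_dict(orient="records"),
            **self.meta,
        }


def _draw_components(
    fit: PosteriorFit, design: DesignMatrix, y: np.ndarray, chunk: int = 250
) -> dict[str, np.ndarray]:
    """One pass over posterior draws, chunked for flat memory.

    Returns per-draw subject variance components (``var_m``, ``var_e``:
    draws x subjects) and per-draw condition components (``sigma_G2``,
    ``sigma_s2``, ``sigma_e2``: draws x conditions).
    """
    if not fit.extended:
        raise ValueError("reliability analysis requires the extended (random RT slope) model fit")
    B = fit.stacked("B")  # (D, C, P)
    I = fit.stacked("I")  # (D, S)
    b = fit.stacked("b")  # (D, S)
    X = design.X
    cond, subj = design.condition_index, design.subject_index
    rt = X[:, design.rt_column]
    D, S, C = B.shape[0], design.n_subjects, design.n_conditions

    onehot_s = np.zeros((design.n_trials, S))
    onehot_s[np.arange(design.n_trials), subj] = 1.0
    onehot_c = np.zeros((design.n_trials, C))
    onehot_c[np.arange(design.n_trials), cond] = 1.0
    n_j = onehot_s.sum(axis=0)
    n_c = onehot_c.sum(axis=0)

    out = {
        "var_m": np.empty((D, S)),
        "var_e": np.empty((D, S)),
        "sigma_G2": np.empty((D, C)),
        "sigma_s2": np.empty((D, C)),
        "sigma_e2": np.empty((D, C)),
        "n_j": n_j,
    }

    def _var_by(group_onehot: np.ndarray, counts: np.ndarray, v: np.ndarray) -> np.ndarray:
        m1 = (v @ group_onehot) / counts
        m2 = (v**2 @ group_onehot) / counts
        return m2 - m1**2

    for lo_ in range(0, D, chunk):
        sl = slice(lo_, min(lo_ + chunk, D))
        Bc = B[sl]
        fixed = np.einsum("kp,dkp->dk", X, Bc[:, cond, :])
        subject_part = b[sl][:, subj] * rt[None, :] + I[sl][:, subj]
        resid = y[None, :] - fixed - subject_part
        yhat = fixed + subject_part
        out["var_m"][sl] = _var_by(onehot_s, np.maximum(n_j, 1), yhat)
        out["var_e"][sl] = _var_by(onehot_s, np.maximum(n_j, 1), resid)
        out["sigma_G2"][sl] = _var_by(onehot_c, np.maximum(n_c, 1), fixed)
        out["sigma_s2"][sl] = _var_by(onehot_c, np.maximum(n_c, 1), subject_part)
        out["sigma_e2"][sl] = _var_by(onehot_c, np.maximum(n_c, 1), resid)
    return out


def subject_internal_consistency(
    fit: PosteriorFit,
    design: DesignMatrix,
    y: np.ndarray | None = None,
    ci: float = 0.95,
) -> pd.DataFrame:
    """Draw-wise phi_j per subject with posterior mean and central interval.

    Subjects with fewer than two trials have undefined variance components and
    are returned flagged with NaN phi.
    """
    y = design.y if y is None else np.asarray(y, float)
    comp = _draw_components(fit, design, y)
    var_m, var_e, n_j = comp["var_m"], comp["var_e"], comp["n_j"]

    with np.errstate(divide="ignore", invalid="ignore"):
        phi = var_m / (var_m + var_e / np.maximum(n_j, 1)[None, :])
    lo, hi = (1 - ci) / 2, 1 - (1 - ci) / 2
    table = pd.DataFrame(
        {
            "subject": design.subjects,
            "n_trials": n_j.astype(int),
            "sigma_m2": var_m.mean(axis=0),
            "sigma_e2": var_e.mean(axis=0),
            "phi": phi.mean(axis=0),
            "phi_lo": np.quantile(phi, lo, axis=0),
            "phi_hi": np.quantile(phi, hi, axis=0),
        }
    )
    table.loc[table.n_trials < 2, ["sigma_m2", "sigma_e2", "phi", "phi_lo", "phi_hi"]] = np.nan
    table["defined"] = table.n_trials >= 2
    return table


def fixed_effects_dependability(
    fit: PosteriorFit,
    design: DesignMatrix,
    y: np.ndarray | None = None,
    s_grid: tuple[int, ...] = (5, 10, 15, 20, 25, 30, 40, 50),
    ci: float = 0.95,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Draw-wise phi_G(S) per condition on a grid of subject counts.

    Returns the tidy curve table (condition, S, mean, interval) and the
    harmonic-mean trial counts per condition.
    """
    y = design.y if y is None else np.asarray(y, float)
    comp = _draw_components(fit, design, y)
    lo, hi = (1 - ci) / 2, 1 - (1 - ci) / 2

    rows = []
    n_hat: dict[str, float] = {}
    for i, cond in enumerate(design.conditions):
        sel = design.condition_index == i
        if not sel.any():
            import warnings

            warnings.warn(f"condition {cond!r} has no trials; skipped", stacklevel=2)
            continue
        counts = np.bincount(design.subject_index[sel])
        counts = counts[counts > 0]
        nh = counts.size / np.sum(1.0 / counts)
        n_hat[cond] = float(nh)
        sigma_G2 = comp["sigma_G2"][:, i]
        sigma_s2 = comp["sigma_s2"][:, i]
        sigma_e2 = comp["sigma_e2"][:, i]
        for S in s_grid:
            phi = sigma_G2 / (sigma_G2 + (sigma_s2 + sigma_e2 / nh) / S)
            rows.append(
                {
                    "condition": cond,
                    "S": S,
                    "phi_G": phi.mean(),
                    "phi_G_lo": np.quantile(phi, lo),
                    "phi_G_hi": np.quantile(phi, hi),
                    "sigma_G2": sigma_G2.mean(),
                    "sigma_s2": sigma_s2.mean(),
                    "sigma_e2": sigma_e2.mean(),
                }
            )
    return pd.DataFrame(rows), n_hat


def retain_subjects(report: ReliabilityReport | pd.DataFrame, threshold: float = 0.8) -> tuple[list, list[dict]]:
    """Retention rule: keep subjects with posterior-mean phi_j at or above the
    threshold; return (retained subject ids, exclusion records)."""
    table = report.subject_table if isinstance(report, ReliabilityReport) else report
    retained, excluded = [], []
    for row in table.itertuples():
        if bool(getattr(row, "defined", True)) and np.isfinite(row.phi) and row.phi >= threshold:
            retained.append(row.subject)
        else:
            reason = "undefined phi" if not np.isfinite(row.phi) else f"phi {row.phi:.3f} below {threshold}"
            excluded.append({"subject": row.subject, "reason": reason, "phi": None if not np.isfinite(row.phi) else float(row.phi)})
    return retained, excluded


def reliability_report(
    fit: PosteriorFit,
    design: DesignMatrix,
    y: np.ndarray | None = None,
    s_grid: tuple[int, ...] = (5, 10, 15, 20, 25, 30, 40, 50),
    threshold: float = 0.8,
) -> ReliabilityReport:
    """Full reliability analysis: phi_j table, phi_G(S) curves, retention."""
    subject_table = subject_internal_consistency(fit, design, y)
    group_table, n_hat = fixed_effects_dependability(fit, design, y, s_grid)
    report = ReliabilityReport(subject_table=subject_table, group_table=group_table, n_hat=n_hat, threshold=threshold)
    retained, excluded = retain_subjects(report, threshold)
    report.meta["retained"] = [int(s) for s in retained]
    report.meta["excluded"] = excluded
    return report
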