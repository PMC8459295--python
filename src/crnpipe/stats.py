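"""Descriptive and psychometric helpers.

Cronbach's alpha with a percentile bootstrap over respondents, per-subject
RT/CRN Pearson correlations with per-condition quartile summaries, and
block-binned behavioral summaries with subject-level bootstrap confidence
intervals.  The bootstrap resampling unit is always the respondent/subject,
matching subject-level confidence regions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "cronbach_alpha",
    "cronbach_alpha_bootstrap",
    "bootstrap_ci",
    "rt_crn_correlations",
    "binned_behavior_summary",
]


def cronbach_alpha(items: np.ndarray) -> float:
    """Cronbach's alpha of a respondents x items matrix.

    ``alpha = k/(k-1) * (1 - sum of item variances / variance of total score)``
    with sample (n-1) variances.
    """
    items = np.asarray(items, float)
    if items.ndim != 2 or items.shape[1] < 2:
        raise ValueError("need a 2D matrix with at least two items")
    if np.isnan(items).all(axis=1).any():
        raise ValueError("matrix contains all-missing rows")
    k = items.shape[1]
    item_var = items.var(axis=0, ddof=1).sum()
    total_var = items.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("zero total-score variance; alpha undefined")
    return float(k / (k - 1) * (1.0 - item_var / total_var))


def cronbach_alpha_bootstrap(
    items: np.ndarray,
    reps: int = 5000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, tuple[float, float]]:
    """Alpha with a percentile-bootstrap confidence interval over respondents."""
    items = np.asarray(items, float)
    if items.shape[0] < 3:
        raise ValueError("need at least three respondents")
    alpha = cronbach_alpha(items)
    rng = np.random.default_rng(seed)
    n = items.shape[0]
    boot = np.empty(reps)
    for r in range(reps):
        idx = rng.integers(0, n, n)
        resampled = items[idx]
        if resampled.sum(axis=1).var(ddof=1) == 0:
            boot[r] = np.nan
            continue
        boot[r] = cronbach_alpha(resampled)
    lo, hi = (1 - level) / 2, 1 - (1 - level) / 2
    ci = (float(np.nanquantile(boot, lo)), float(np.nanquantile(boot, hi)))
    return alpha, ci


def bootstrap_ci(
    values: np.ndarray,
    reps: int = 10000,
    level: float = 0.95,
    seed: int = 0,
    stat=np.mean,
) -> tuple[np.ndarray, np.ndarray]:
    """Percentile bootstrap CI for ``stat`` over axis 0 (subjects).

    Works for vectors (one value per subject) and for subjects x timepoints
    arrays (applied timepoint-wise, as for waveform confidence bands).
    """
    values = np.asarray(values, float)
    rng = np.random.default_rng(seed)
    n = values.shape[0]
    boot = np.empty((reps,) + values.shape[1:])
    for r in range(reps):
        boot[r] = stat(values[rng.integers(0, n, n)], axis=0)
    lo, hi = (1 - level) / 2, 1 - (1 - level) / 2
    return np.quantile(boot, lo, axis=0), np.quantile(boot, hi, axis=0)


def rt_crn_correlations(amps: pd.DataFrame, min_trials: int = 3) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-subject Pearson correlation between raw RT and amplitude.

    Other predictors are ignored.  Subjects with fewer than ``min_trials``
    trials or zero RT variance get NaN and are flagged.  Returns the
    per-subject table and a per-condition summary (median, 25th and 75th
    percentiles).
    """
    rows = []
    for subject, sub in amps.groupby("subject"):
        rt = sub.rt_s.to_numpy(float)
        amp = sub.amplitude.to_numpy(float)

        def _varies(v: np.ndarray) -> bool:
            return v.std() > 1e-12 * max(1.0, float(np.abs(v).max()))

        ok = len(sub) >= min_trials and _varies(rt) and _varies(amp)
        r = float(sps.pearsonr(rt, amp).statistic) if ok else np.nan
        rows.append({"subject": subject, "condition": sub.condition.iloc[0], "n": len(sub), "r": r, "defined": ok})
    table = pd.DataFrame(rows)
    summary = (
        table[table.defined]
        .groupby("condition")
        .r.agg(median="median", q25=lambda v: v.quantile(0.25), q75=lambda v: v.quantile(0.75), n="count")
        .reset_index()
    )
    return table, summary


def binned_behavior_summary(
    trials: pd.DataFrame,
    bin_blocks: int = 3,
    reps: int = 10000,
    level: float = 0.95,
    seed: int = 0,
    drop_remainder: bool = False,
) -> pd.DataFrame:
    """Hit rate, correct-rejection rate, and mean RT per condition x block bin.

    Blocks are pooled into bins of ``bin_blocks``; a trailing partial bin is
    kept and flagged (or dropped with ``drop_remainder``).  Group means are
    means of subject-level values; confidence intervals are percentile
    bootstrap over subjects.
    """
    trials = trials.copy()
    trials["bin"] = (trials.block - 1) // bin_blocks
    n_blocks = int(trials.block.max())
    n_bins = -(-n_blocks // bin_blocks)
    partial = set()
    if n_blocks % bin_blocks:
        if drop_remainder:
            trials = trials[trials.bin < n_blocks // bin_blocks]
            n_bins = n_blocks // bin_blocks
        else:
            partial.add(n_bins - 1)

    go = trials[trials.trial_type == "go"]
    nogo = trials[trials.trial_type == "nogo"]
    per_subject = pd.DataFrame(
        {
            "hit_rate": go.groupby(["condition", "bin", "subject"]).correct.mean(),
            "cr_rate": nogo.groupby(["condition", "bin", "subject"]).correct.mean(),
            "mean_rt": go[go.correct == 1].groupby(["condition", "bin", "subject"]).rt_s.mean(),
        }
    ).reset_index()

    rows = []
    rng_seed = seed
    for (cond, bin_), grp in per_subject.groupby(["condition", "bin"]):
        if grp.empty:
            import warnings

            warnings.warn(f"empty bin {bin_} in condition {cond!r}; omitted", stacklevel=2)
            continue
        row = {"condition": cond, "bin": int(bin_), "n_subjects": len(grp), "partial_bin": bin_ in partial}
        for measure in ("hit_rate", "cr_rate", "mean_rt"):
            v = grp[measure].to_numpy(float)
            v = v[np.isfinite(v)]
            row[measure] = float(v.mean())
            lo, hi = bootstrap_ci(v, reps=reps, level=level, seed=rng_seed)
            row[f"{measure}_lo"], row[f"{measure}_hi"] = float(lo), float(hi)
            rng_seed += 1
        rows.append(row)
    return pd.DataFrame(rows)
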