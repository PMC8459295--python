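"""Bayesian reduced-rank multivariate regression of behavioral outcomes.

Four subject-level outcomes — initial log-odds correct rejection (CR), change
in log-odds CR, change in mean response time, and the intrinsic-motivation
effort/enjoyment score — are regressed on eight standardized predictors
(promotion, prevention, gain and loss condition indicators, and the
promotion/prevention x condition interactions) through a low-rank coefficient
matrix: ``Y ~ (X a) w' + E`` with one latent dimension by default.  Priors are
standard normal on the projection ``a`` and loadings ``w``; per-outcome noise
SDs have half-normal priors.  For identifiability the coefficient projecting
prevention strength onto the latent dimension is constrained positive (a sign
flip of ``(a, w)`` leaves the likelihood unchanged).  Rank comparison uses
Pareto-smoothed importance-sampling leave-one-out cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

__all__ = [
    "RRR_PREDICTORS",
    "OUTCOME_COLUMNS",
    "RRRFit",
    "derive_outcomes",
    "build_rrr_predictors",
    "fit_reduced_rank",
    "compare_ranks",
]

RRR_PREDICTORS = ("prom", "prev", "gain", "loss", "prom_gain", "prom_loss", "prev_gain", "prev_loss")
OUTCOME_COLUMNS = ("initial_logodds_cr", "change_logodds_cr", "change_rt_s", "imi")

_PREV_IDX = RRR_PREDICTORS.index("prev")


# --------------------------------------------------------------------------
# outcome derivation
# --------------------------------------------------------------------------


def _block_logodds_cr(block_rows: pd.DataFrame) -> float:
    """Continuity-corrected log-odds of correct rejection within one block."""
    nogo = block_rows[block_rows.trial_type == "nogo"]
    cr = float((nogo.correct == 1).sum())
    fa = float(len(nogo) - cr)
    return float(np.log((cr + 0.5) / (fa + 0.5)))


def derive_outcomes(trials: pd.DataFrame, imi: pd.DataFrame, bin_blocks: int = 3) -> pd.DataFrame:
    """Subject-level behavioral outcomes from the trial table.

    Blocks are grouped into bins of ``bin_blocks`` successive blocks.  The
    log-odds CR outcome is the continuity-corrected per-block log-odds (0.5
    added to both counts) averaged within a bin; "initial" is the first bin
    and "change" is the last full bin minus the first.  Change in RT is the
    corresponding difference of mean correct-go response times.  ``imi`` maps
    subjects to effort/enjoyment scores (columns ``subject``,
    ``imi_effort_enjoyment``); subjects with a missing score are dropped.
    """
    imi_map = imi.set_index("subject")["imi_effort_enjoyment"]
    n_blocks = int(trials.block.max())
    n_full = n_blocks // bin_blocks
    if n_full < 2:
        raise ValueError("need at least two full bins of blocks")
    first_bin = range(1, bin_blocks + 1)
    last_bin = range((n_full - 1) * bin_blocks + 1, n_full * bin_blocks + 1)

    rows = []
    for subject, sub in trials.groupby("subject"):
        if subject not in imi_map.index or not np.isfinite(imi_map.loc[subject]):
            continue

        def bin_logodds(blocks) -> float:
            return float(np.mean([_block_logodds_cr(sub[sub.block == blk]) for blk in blocks]))

        def bin_rt(blocks) -> float:
            rows_ = sub[sub.block.isin(list(blocks)) & (sub.trial_type == "go") & (sub.correct == 1)]
            return float(rows_.rt_s.mean())

        lo_first, lo_last = bin_logodds(first_bin), bin_logodds(last_bin)
        rows.append(
            {
                "subject": subject,
                "condition": sub.condition.iloc[0],
                "initial_logodds_cr": lo_first,
                "change_logodds_cr": lo_last - lo_first,
                "change_rt_s": bin_rt(last_bin) - bin_rt(first_bin),
                "imi": float(imi_map.loc[subject]),
            }
        )
    return pd.DataFrame(rows)


def build_rrr_predictors(outcomes: pd.DataFrame, traits: pd.DataFrame) -> np.ndarray:
    """Standardized subject-level predictor matrix (subjects x 8).

    Trait scores are z-scored before the trait x condition products are
    formed (otherwise the interaction columns are nearly collinear with the
    condition indicators); all columns are standardized afterwards.
    """
    tr = traits.set_index("subject")
    prom = tr.promotion.loc[outcomes.subject].to_numpy(float)
    prev = tr.prevention.loc[outcomes.subject].to_numpy(float)
    for name, v in (("prom", prom), ("prev", prev)):
        if v.std() == 0:
            raise ValueError(f"zero variance in predictor {name!r}")
    prom = (prom - prom.mean()) / prom.std()
    prev = (prev - prev.mean()) / prev.std()
    gain = (outcomes.condition == "gain").to_numpy(float)
    loss = (outcomes.condition == "loss").to_numpy(float)
    cols = [prom, prev, gain, loss, prom * gain, prom * loss, prev * gain, prev * loss]
    X = np.column_stack(cols)
    sd = X.std(axis=0)
    if np.any(sd == 0):
        bad = [RRR_PREDICTORS[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"zero variance in predictors {bad}")
    return (X - X.mean(axis=0)) / sd


# --------------------------------------------------------------------------
# reduced-rank fit (ensemble MCMC)
# --------------------------------------------------------------------------


@dataclass
class RRRFit:
    """Posterior draws of the rank-``r`` regression.

    ``a``: draws x predictors x rank, ``w``: draws x outcomes x rank,
    ``sigma``: draws x outcomes, ``log_lik``: draws x subjects (pointwise,
    summed over outcomes) for cross-validation.
    """

    a: np.ndarray
    w: np.ndarray
    sigma: np.ndarray
    log_lik: np.ndarray
    rank: int
    predictor_names: tuple[str, ...] = RRR_PREDICTORS
    outcome_names: tuple[str, ...] = OUTCOME_COLUMNS
    meta: dict = field(default_factory=dict)

    @property
    def coefficient_draws(self) -> np.ndarray:
        """Full coefficient matrix a w' per draw (draws x predictors x outcomes);
        invariant to the scale split between ``a`` and ``w``."""
        return np.einsum("dpr,dqr->dpq", self.a, self.w)

    def summary(self) -> pd.DataFrame:
        rows = []
        for r in range(self.rank):
            for i, name in enumerate(self.predictor_names):
                v = self.a[:, i, r]
                rows.append({"block": "projection", "rank": r + 1, "name": name, **_qsum(v)})
            for i, name in enumerate(self.outcome_names):
                v = self.w[:, i, r]
                rows.append({"block": "loading", "rank": r + 1, "name": name, **_qsum(v)})
        return pd.DataFrame(rows)


def _qsum(v: np.ndarray) -> dict:
    q = np.quantile(v, [0.025, 0.25, 0.5, 0.75, 0.975])
    return {"mean": v.mean(), "q2.5": q[0], "q25": q[1], "median": q[2], "q75": q[3], "q97.5": q[4]}


def _unpack(theta: np.ndarray, P: int, Q: int, r: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    a = theta[: P * r].reshape(P, r)
    w = theta[P * r : P * r + Q * r].reshape(Q, r)
    log_sigma = theta[P * r + Q * r :]
    return a, w, log_sigma


def _pointwise_loglik(theta: np.ndarray, X: np.ndarray, Y: np.ndarray, r: int) -> np.ndarray:
    P, Q = X.shape[1], Y.shape[1]
    a, w, log_sigma = _unpack(theta, P, Q, r)
    mu = (X @ a) @ w.T
    sigma = np.exp(log_sigma)
    z = (Y - mu) / sigma
    return np.sum(-0.5 * z**2 - log_sigma - 0.5 * np.log(2 * np.pi), axis=1)


def _log_prob(theta: np.ndarray, X: np.ndarray, Y: np.ndarray, r: int) -> float:
    P, Q = X.shape[1], Y.shape[1]
    a, w, log_sigma = _unpack(theta, P, Q, r)
    if np.any(a[_PREV_IDX] <= 0):  # identifiability constraint
        return -np.inf
    sigma = np.exp(log_sigma)
    logp = float(np.sum(_pointwise_loglik(theta, X, Y, r)))
    logp += float(-0.5 * np.sum(a**2) - 0.5 * np.sum(w**2))
    logp += float(np.sum(-0.5 * sigma**2 + log_sigma))  # half-normal prior on sigma, log-scale Jacobian
    return logp


def fit_reduced_rank(
    outcomes: pd.DataFrame,
    traits: pd.DataFrame,
    rank: int = 1,
    seed: int = 0,
    n_steps: int = 3000,
    n_burn: int = 1000,
    thin: int = 5,
    standardize_outcomes: bool = True,
) -> RRRFit:
    """Fit the rank-``rank`` multivariate regression by ensemble MCMC.

    Outcomes are standardized by default (predictors always are).  Warns if
    there are fewer subjects than predictors.
    """
    import emcee
    import warnings

    X = build_rrr_predictors(outcomes, traits)
    Y = outcomes[list(OUTCOME_COLUMNS)].to_numpy(float)
    if standardize_outcomes:
        Y = (Y - Y.mean(axis=0)) / Y.std(axis=0)
    n, P = X.shape
    Q = Y.shape[1]
    if n < P:
        warnings.warn(f"fewer subjects ({n}) than predictors ({P}); fit is weakly identified", stacklevel=2)

    ndim = P * rank + Q * rank + Q
    nwalkers = max(2 * ndim + 2, 40)
    rng = np.random.default_rng(seed)

    # initialize walkers around the rank-r SVD of the least-squares solution,
    # signs flipped so the constrained prevention coefficients are positive
    ols, *_ = np.linalg.lstsq(X, Y, rcond=None)
    U, s, Vt = np.linalg.svd(ols, full_matrices=False)
    a0 = U[:, :rank] * np.sqrt(s[:rank])
    w0 = Vt[:rank].T * np.sqrt(s[:rank])
    for r in range(rank):
        if a0[_PREV_IDX, r] < 0:
            a0[:, r] *= -1.0
            w0[:, r] *= -1.0
    resid_sd = np.maximum((Y - (X @ a0) @ w0.T).std(axis=0), 1e-3)
    center = np.concatenate([a0.ravel(), w0.ravel(), np.log(resid_sd)])
    p0 = center[None, :] + 0.05 * rng.standard_normal((nwalkers, ndim))
    # a is stored predictor-major (flat index p*rank + r); keep the constrained
    # prevention coefficients strictly positive
    a_prev_cols = [_PREV_IDX * rank + r for r in range(rank)]
    p0[:, a_prev_cols] = np.maximum(np.abs(p0[:, a_prev_cols]), 1e-3)

    sampler = emcee.EnsembleSampler(nwalkers, ndim, _log_prob, args=(X, Y, rank))
    sampler.random_state = np.random.RandomState(seed).get_state()
    sampler.run_mcmc(p0, n_steps, progress=False)
    chain = sampler.get_chain(discard=n_burn, thin=thin)  # (steps, walkers, ndim)
    flat = chain.reshape(-1, ndim)

    D = flat.shape[0]
    a = np.empty((D, P, rank))
    w = np.empty((D, Q, rank))
    sigma = np.empty((D, Q))
    log_lik = np.empty((D, n))
    for d in range(D):
        a_d, w_d, ls_d = _unpack(flat[d], P, Q, rank)
        a[d], w[d], sigma[d] = a_d, w_d, np.exp(ls_d)
        log_lik[d] = _pointwise_loglik(flat[d], X, Y, rank)
    return RRRFit(
        a=a,
        w=w,
        sigma=sigma,
        log_lik=log_lik,
        rank=rank,
        meta={"seed": seed, "n_steps": n_steps, "n_burn": n_burn, "thin": thin, "acceptance": float(sampler.acceptance_fraction.mean())},
    )


# --------------------------------------------------------------------------
# rank comparison via PSIS-LOO
# --------------------------------------------------------------------------


def _psis_elpd(log_lik: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise PSIS-LOO expected log predictive density and Pareto k-hats."""
    import arviz as az

    # importance ratios 1/p(y_i | theta): log weights are -log_lik;
    # psislw smooths along the last (sample) axis, so pass observations x draws
    lw, khat = az.psislw(-log_lik.T)
    elpd_i = logsumexp(lw + log_lik.T, axis=1)
    return elpd_i, np.asarray(khat)


def compare_ranks(fits: dict[int, RRRFit]) -> dict:
    """Prefer the lowest rank unless a higher rank improves LOO by > 2 SE.

    Returns the preferred rank, pairwise elpd differences with standard
    errors, and a flag when any Pareto k-hat exceeds 0.7 (unstable
    importance weights).
    """
    if len(fits) < 2:
        raise ValueError("need at least two fitted ranks to compare")
    ranks = sorted(fits)
    elpd: dict[int, np.ndarray] = {}
    unstable = False
    for r in ranks:
        elpd_i, khat = _psis_elpd(fits[r].log_lik)
        elpd[r] = elpd_i
        unstable = unstable or bool(np.any(khat > 0.7))

    preferred = ranks[0]
    comparisons = []
    for r in ranks[1:]:
        d_i = elpd[r] - elpd[preferred]
        diff = float(d_i.sum())
        se = float(np.sqrt(len(d_i)) * d_i.std(ddof=1))
        comparisons.append({"rank_a": preferred, "rank_b": r, "elpd_diff": diff, "se": se})
        if diff > 2 * se:
            preferred = r
    return {
        "preferred_rank": preferred,
        "comparisons": comparisons,
        "elpd": {r: float(v.sum()) for r, v in elpd.items()},
        "unstable_weights": unstable,
    }
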