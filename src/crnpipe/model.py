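"""Hierarchical regularized-horseshoe regression of single-trial amplitudes.

The outcome (z-scored single-trial CRN or ERN amplitude) is regressed, per
feedback condition, on eleven standardized predictors: response time (RT),
promotion strength, prevention strength, miss-error count (ErrN), and all
two- and three-way interactions not involving both promotion and prevention.
The model is

    Y_k ~ Student-t(nu, B_i' X_k + I_j, sigma_g)             (basic variant)
    Y_k ~ Student-t(nu, B_i' X_k + b_j rt_k + I_j, sigma_g)  (extended variant)

with a regularized horseshoe prior on each coefficient B_ip (and on the
mean-zero per-subject RT slopes b_j in the extended variant):

    B_ip ~ N(0, tau^2 * lambda_tilde_ip^2)
    lambda_tilde^2 = c^2 lambda^2 / (c^2 + tau^2 lambda^2)
    lambda_ip ~ HalfCauchy(1),  tau ~ HalfCauchy(tau0),
    c^2 ~ InvGamma(nu0/2, nu0 s^2 / 2),
    tau0 = p0 / (P*C - p0) * sigma_g / sqrt(N)

and weakly informative priors elsewhere: I_j ~ N(I0, sigma_I), I0 ~ N(0,1),
sigma_I ~ HalfNormal(1), sigma_g ~ HalfNormal(1), nu ~ Gamma(2, rate 1/10).

Sampling uses a data-augmentation Gibbs scheme: the Student-t likelihood is
represented as a normal scale mixture (per-trial inverse-gamma mixing weights),
making B, I, I0 and b conjugate Gaussian blocks; the scale and shape
parameters (lambda, tau, c^2, sigma_g, sigma_I, nu) are updated by univariate
slice sampling on the log scale.  The sampler targets exactly the joint
density implemented in :func:`log_joint_density`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .config import MCMCSettings, ModelConfig

__all__ = [
    "PREDICTOR_COLUMNS",
    "DesignMatrix",
    "HorseshoeSpec",
    "PosteriorFit",
    "build_design_matrix",
    "compute_tau0",
    "log_joint_density",
    "fit_mcmc",
    "diagnose_and_summarize",
]

PREDICTOR_COLUMNS = (
    "rt",
    "prom",
    "prev",
    "errn",
    "rt_prom",
    "rt_prev",
    "rt_errn",
    "prom_errn",
    "prev_errn",
    "rt_prom_errn",
    "rt_prev_errn",
)

_BASE = ("rt", "prom", "prev", "errn")


# --------------------------------------------------------------------------
# design matrix
# --------------------------------------------------------------------------


@dataclass
class DesignMatrix:
    """Trials x predictors matrix with condition/subject bookkeeping.

    ``X`` has exactly 11 columns (``column_names``); base columns are z-scored
    over the analysis set and interaction columns are elementwise products of
    the z-scored bases.  ``subjects`` maps the dense subject index used in
    ``subject_index`` back to original subject ids.
    """

    X: np.ndarray
    column_names: tuple[str, ...]
    condition_index: np.ndarray
    subject_index: np.ndarray
    conditions: tuple[str, ...]
    subjects: np.ndarray
    y: np.ndarray | None = None
    y_mean: float = 0.0
    y_sd: float = 1.0

    @property
    def n_trials(self) -> int:
        return self.X.shape[0]

    @property
    def n_predictors(self) -> int:
        return self.X.shape[1]

    @property
    def n_conditions(self) -> int:
        return len(self.conditions)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def rt_column(self) -> int:
        return self.column_names.index("rt")


def _zscore(v: np.ndarray, name: str) -> np.ndarray:
    sd = v.std()
    if sd == 0 or not np.isfinite(sd):
        raise ValueError(f"zero or undefined variance in base predictor {name!r}")
    return (v - v.mean()) / sd


def build_design_matrix(
    amps: pd.DataFrame,
    traits: pd.DataFrame,
    conditions: tuple[str, ...] | None = None,
    restandardize_interactions: bool = False,
) -> DesignMatrix:
    """Build the 11-column standardized design matrix from an amplitude table.

    ``amps`` needs columns ``subject, condition, rt_s`` (and optionally
    ``amplitude``, which is z-scored into ``y``); ``traits`` needs ``subject,
    promotion, prevention, n_miss``.  Base predictors are z-scored over all
    trials in the analysis set; interactions are products of z-scores (by
    default not re-standardized after multiplication).
    """
    required = {"subject", "condition", "rt_s"}
    if missing := required - set(amps.columns):
        raise KeyError(f"amplitude table missing columns {sorted(missing)}")
    for col in ("promotion", "prevention", "n_miss"):
        if col not in traits.columns:
            raise KeyError(f"trait table missing column {col!r}")
    tr = traits.set_index("subject")
    unknown = set(amps.subject) - set(tr.index)
    if unknown:
        raise KeyError(f"subjects missing from trait table: {sorted(unknown)[:5]}")

    if conditions is None:
        conditions = tuple(pd.unique(amps.condition))
    cond_map = {c: i for i, c in enumerate(conditions)}
    try:
        cond_idx = amps.condition.map(cond_map).to_numpy(dtype=int)
    except (TypeError, ValueError):
        raise KeyError("amplitude table contains conditions not in the condition list") from None

    subjects = np.array(sorted(amps.subject.unique()))
    subj_map = {s: i for i, s in enumerate(subjects)}
    subj_idx = amps.subject.map(subj_map).to_numpy(dtype=int)

    base = {
        "rt": _zscore(amps.rt_s.to_numpy(float), "rt"),
        "prom": _zscore(tr.promotion.loc[amps.subject].to_numpy(float), "prom"),
        "prev": _zscore(tr.prevention.loc[amps.subject].to_numpy(float), "prev"),
        "errn": _zscore(tr.n_miss.loc[amps.subject].to_numpy(float), "errn"),
    }
    cols = []
    for name in PREDICTOR_COLUMNS:
        parts = name.split("_")
        col = np.prod([base[p] for p in parts], axis=0)
        if restandardize_interactions and len(parts) > 1:
            col = _zscore(col, name)
        cols.append(col)
    X = np.column_stack(cols)

    y = y_mean = y_sd = None
    if "amplitude" in amps.columns:
        raw = amps.amplitude.to_numpy(float)
        y_mean, y_sd = float(raw.mean()), float(raw.std())
        if y_sd == 0:
            raise ValueError("zero variance in outcome")
        y = (raw - y_mean) / y_sd

    return DesignMatrix(
        X=X,
        column_names=PREDICTOR_COLUMNS,
        condition_index=cond_idx,
        subject_index=subj_idx,
        conditions=tuple(conditions),
        subjects=subjects,
        y=y,
        y_mean=y_mean or 0.0,
        y_sd=y_sd or 1.0,
    )


# --------------------------------------------------------------------------
# horseshoe specification and elementary densities
# --------------------------------------------------------------------------


@dataclass
class HorseshoeSpec:
    """Hyperparameters of the regularized-horseshoe hierarchical model."""

    p0: int = 9
    nu0: float = 20.0
    s: float = 1.0
    nu_prior_shape: float = 2.0
    nu_prior_rate: float = 0.1

    @classmethod
    def from_config(cls, cfg: ModelConfig) -> "HorseshoeSpec":
        return cls(p0=cfg.p0, nu0=cfg.nu0, s=cfg.s, nu_prior_shape=cfg.nu_prior_shape, nu_prior_rate=cfg.nu_prior_rate)


def compute_tau0(spec: HorseshoeSpec, sigma_g: float, N: int, P: int = 11, C: int = 3) -> float:
    """Global-scale prior location: ``tau0 = p0/(P*C - p0) * sigma_g / sqrt(N)``."""
    if N <= 0:
        raise ValueError("N must be positive")
    if spec.p0 >= P * C:
        raise ValueError("p0 must be smaller than the total coefficient count P*C")
    return spec.p0 / (P * C - spec.p0) * sigma_g / math.sqrt(N)


_LOG_2_PI = math.log(2.0 / math.pi)


def _log_half_cauchy(x, scale):
    return _LOG_2_PI - np.log(scale) - np.log1p((x / scale) ** 2)


def _log_half_normal(x):
    return 0.5 * _LOG_2_PI - 0.5 * x**2


def _log_normal(x, mu, sd):
    return -0.5 * math.log(2 * math.pi) - np.log(sd) - 0.5 * ((x - mu) / sd) ** 2


def _log_inv_gamma(x, a, b):
    return a * math.log(b) - gammaln(a) - (a + 1) * np.log(x) - b / x


def _log_gamma(x, shape, rate):
    return shape * math.log(rate) - gammaln(shape) + (shape - 1) * np.log(x) - rate * x


def _log_student_t(z, nu):
    return gammaln((nu + 1) / 2) - gammaln(nu / 2) - 0.5 * np.log(nu * math.pi) - (nu + 1) / 2 * np.log1p(z**2 / nu)


def _lambda_tilde_sq(lam_sq, tau_sq, c_sq):
    return c_sq * lam_sq / (c_sq + tau_sq * lam_sq)


# --------------------------------------------------------------------------
# exact joint density
# --------------------------------------------------------------------------


def log_joint_density(
    params: dict,
    design: DesignMatrix,
    spec: HorseshoeSpec,
    y: np.ndarray,
    extended: bool = False,
) -> float:
    """Log joint density of data and parameters under the model.

    ``params`` holds ``B`` (C x P), ``I0``, ``I`` (per subject), ``sigma_g``,
    ``sigma_I``, ``nu``, ``tau``, ``lam`` (C x P), ``c2``, and in the extended
    variant also ``b`` (per subject) and ``lam_b``.  Out-of-support parameter
    values return ``-inf`` (by contract, not an exception).
    """
    B = np.asarray(params["B"], float)
    I = np.asarray(params["I"], float)
    lam = np.asarray(params["lam"], float)
    I0, sigma_g, sigma_I = params["I0"], params["sigma_g"], params["sigma_I"]
    nu, tau, c2 = params["nu"], params["tau"], params["c2"]

    pos = [sigma_g, sigma_I, nu, tau, c2]
    if extended:
        pos.append(params["lam_b"])
    if np.any(lam <= 0) or any(v <= 0 for v in pos):
        return -np.inf

    N = design.n_trials
    mu = np.einsum("kp,kp->k", design.X, B[design.condition_index]) + I[design.subject_index]
    if extended:
        b = np.asarray(params["b"], float)
        mu = mu + b[design.subject_index] * design.X[:, design.rt_column]
    logp = float(np.sum(_log_student_t((y - mu) / sigma_g, nu)) - N * math.log(sigma_g))

    tau0 = compute_tau0(spec, sigma_g, N, P=design.n_predictors, C=design.n_conditions)
    lt_sq = _lambda_tilde_sq(lam**2, tau**2, c2)
    logp += float(np.sum(_log_normal(B, 0.0, np.sqrt(tau**2 * lt_sq))))
    logp += float(np.sum(_log_half_cauchy(lam, 1.0)))
    logp += float(_log_half_cauchy(tau, tau0))
    logp += float(_log_inv_gamma(c2, spec.nu0 / 2.0, spec.nu0 * spec.s**2 / 2.0))

    logp += float(np.sum(_log_normal(I, I0, sigma_I)))
    logp += float(_log_normal(I0, 0.0, 1.0))
    logp += float(_log_half_normal(sigma_I))
    logp += float(_log_half_normal(sigma_g))
    logp += float(_log_gamma(nu, spec.nu_prior_shape, spec.nu_prior_rate))

    if extended:
        lam_b = params["lam_b"]
        ltb_sq = _lambda_tilde_sq(lam_b**2, tau**2, c2)
        logp += float(np.sum(_log_normal(b, 0.0, math.sqrt(tau**2 * ltb_sq))))
        logp += float(_log_half_cauchy(lam_b, 1.0))
    return logp


# --------------------------------------------------------------------------
# slice samplers
# --------------------------------------------------------------------------


def _slice_scalar(logf, x0: float, rng: np.random.Generator, width: float = 1.0, max_steps: int = 50) -> float:
    """Univariate slice sampler with stepping-out (Neal 2003)."""
    f0 = logf(x0)
    if not np.isfinite(f0):
        raise FloatingPointError("slice sampler started outside support")
    logy = f0 - rng.exponential()
    L = x0 - width * rng.random()
    R = L + width
    j = max_steps
    while j > 0 and logf(L) > logy:
        L -= width
        j -= 1
    j = max_steps
    while j > 0 and logf(R) > logy:
        R += width
        j -= 1
    while True:
        x1 = rng.uniform(L, R)
        if logf(x1) >= logy:
            return x1
        if x1 < x0:
            L = x1
        else:
            R = x1


def _slice_batch(logf, x0: np.ndarray, rng: np.random.Generator, width: float = 1.0, max_steps: int = 50) -> np.ndarray:
    """Slice sampling for a vector of conditionally independent scalars."""
    f0 = logf(x0)
    logy = f0 - rng.exponential(size=x0.shape)
    L = x0 - width * rng.random(size=x0.shape)
    R = L + width
    for _ in range(max_steps):
        grow = logf(L) > logy
        if not grow.any():
            break
        L = np.where(grow, L - width, L)
    for _ in range(max_steps):
        grow = logf(R) > logy
        if not grow.any():
            break
        R = np.where(grow, R + width, R)
    out = x0.copy()
    done = np.zeros(x0.shape, dtype=bool)
    for _ in range(200):
        prop = rng.uniform(L, R)
        ok = (logf(prop) >= logy) & ~done
        out = np.where(ok, prop, out)
        done |= ok
        if done.all():
            break
        shrink_left = ~done & (prop < x0)
        shrink_right = ~done & ~(prop < x0)
        L = np.where(shrink_left, prop, L)
        R = np.where(shrink_right, prop, R)
    return out


# --------------------------------------------------------------------------
# posterior container
# --------------------------------------------------------------------------


@dataclass
class PosteriorFit:
    """MCMC draws (chains x draws x ...) plus model bookkeeping."""

    draws: dict[str, np.ndarray]
    column_names: tuple[str, ...]
    conditions: tuple[str, ...]
    subjects: np.ndarray
    extended: bool
    settings: MCMCSettings
    spec: HorseshoeSpec
    seeds: tuple[int, ...] = ()
    meta: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return next(iter(self.draws.values())).shape[0]

    @property
    def n_draws(self) -> int:
        return next(iter(self.draws.values())).shape[1]

    def stacked(self, name: str) -> np.ndarray:
        """All chains pooled: (chains*draws, ...)."""
        v = self.draws[name]
        return v.reshape(v.shape[0] * v.shape[1], *v.shape[2:])

    def coefficient_summary(self, quantiles=(0.025, 0.25, 0.5, 0.75, 0.975)) -> pd.DataFrame:
        """Per-coefficient posterior quantiles of B, tidy one row per (condition, predictor)."""
        B = self.stacked("B")
        qs = np.quantile(B, quantiles, axis=0)
        rows = []
        for i, cond in enumerate(self.conditions):
            for p, name in enumerate(self.column_names):
                row = {"condition": cond, "predictor": name}
                for q, qv in zip(quantiles, qs[:, i, p]):
                    row[f"q{q:g}"] = qv
                rows.append(row)
        return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Gibbs sampler
# --------------------------------------------------------------------------


def fit_mcmc(
    design: DesignMatrix,
    y: np.ndarray | None = None,
    spec: HorseshoeSpec | None = None,
    settings: MCMCSettings | None = None,
    extended: bool = False,
) -> PosteriorFit:
    """Fit the hierarchical horseshoe model by data-augmentation Gibbs sampling.

    Deterministic given ``settings.seed``; each chain uses an independent
    seeded generator.  The extended variant adds mean-zero per-subject RT
    slopes sharing one horseshoe local scale (``lam_b``).
    """
    spec = spec or HorseshoeSpec()
    settings = settings or MCMCSettings()
    if y is None:
        y = design.y
    if y is None:
        raise ValueError("no outcome: pass y or build the design with an amplitude column")
    y = np.asarray(y, float)
    if y.shape[0] != design.n_trials:
        raise ValueError("outcome and design are not conformable")

    X = design.X
    N, P = X.shape
    C, S = design.n_conditions, design.n_subjects
    cond_idx, subj_idx = design.condition_index, design.subject_index
    rt = X[:, design.rt_column]
    cond_rows = [np.flatnonzero(cond_idx == i) for i in range(C)]
    Xc = [X[rows] for rows in cond_rows]
    k0 = spec.p0 / (P * C - spec.p0) / math.sqrt(N)  # tau0 = k0 * sigma_g

    names = ["B", "I", "I0", "sigma_g", "sigma_I", "nu", "tau", "lam", "c2"]
    if extended:
        names += ["b", "lam_b"]
    shapes = {"B": (C, P), "I": (S,), "I0": (), "sigma_g": (), "sigma_I": (), "nu": (), "tau": (), "lam": (C, P), "c2": (), "b": (S,), "lam_b": ()}
    store = {n: np.empty((settings.chains, settings.samples) + shapes[n]) for n in names}
    seeds = tuple(int(settings.seed) * 10_000 + c for c in range(settings.chains))

    ln_hc = _log_half_cauchy  # local aliases
    for chain, chain_seed in enumerate(seeds):
        rng = np.random.default_rng(chain_seed)
        B = np.zeros((C, P))
        I = np.zeros(S)
        b = np.zeros(S)
        I0 = 0.0
        sigma_g = max(float(y.std()), 0.1)
        sigma_I = 0.5
        nu = 20.0
        lam = np.ones((C, P))
        lam_b = 1.0
        c2 = spec.s**2
        tau = k0 * sigma_g
        w = np.ones(N)

        fixed = np.einsum("kp,kp->k", X, B[cond_idx])
        for it in range(settings.warmup + settings.samples):
            mu = fixed + I[subj_idx] + (b[subj_idx] * rt if extended else 0.0)
            r = y - mu

            # -- mixing weights: t as normal scale mixture ----------------
            shape = (nu + 1.0) / 2.0
            rate = (nu + (r / sigma_g) ** 2) / 2.0
            w = rate / rng.gamma(shape, 1.0, size=N)
            u = 1.0 / (w * sigma_g**2)

            # -- coefficient blocks (conjugate Gaussian) -------------------
            lt_sq = _lambda_tilde_sq(lam**2, tau**2, c2)
            prior_prec = 1.0 / (tau**2 * lt_sq)
            resid_coef = y - I[subj_idx] - (b[subj_idx] * rt if extended else 0.0)
            for i in range(C):
                rows = cond_rows[i]
                Xi = Xc[i]
                ui = u[rows]
                A = (Xi * ui[:, None]).T @ Xi
                A[np.diag_indices(P)] += prior_prec[i]
                rhs = Xi.T @ (ui * resid_coef[rows])
                L = np.linalg.cholesky(A)
                mean = np.linalg.solve(L.T, np.linalg.solve(L, rhs))
                B[i] = mean + np.linalg.solve(L.T, rng.standard_normal(P))
            fixed = np.einsum("kp,kp->k", X, B[cond_idx])

            # -- random intercepts ----------------------------------------
            e = y - fixed - (b[subj_idx] * rt if extended else 0.0)
            su = np.bincount(subj_idx, weights=u, minlength=S)
            se = np.bincount(subj_idx, weights=u * e, minlength=S)
            prec_I = su + 1.0 / sigma_I**2
            I = (se + I0 / sigma_I**2) / prec_I + rng.standard_normal(S) / np.sqrt(prec_I)

            prec_I0 = S / sigma_I**2 + 1.0
            I0 = I.sum() / sigma_I**2 / prec_I0 + rng.standard_normal() / math.sqrt(prec_I0)

            # -- random RT slopes (extended) -------------------------------
            if extended:
                ltb_sq = _lambda_tilde_sq(lam_b**2, tau**2, c2)
                e2 = y - fixed - I[subj_idx]
                srt2 = np.bincount(subj_idx, weights=u * rt * rt, minlength=S)
                srte = np.bincount(subj_idx, weights=u * rt * e2, minlength=S)
                prec_b = srt2 + 1.0 / (tau**2 * ltb_sq)
                b = srte / prec_b + rng.standard_normal(S) / np.sqrt(prec_b)

            # -- sigma_I (slice on log scale) ------------------------------
            ss_I = float(np.sum((I - I0) ** 2))

            def logf_sigma_I(ls):
                s_ = math.exp(ls)
                return float(_log_half_normal(s_)) + ls - S * ls - ss_I / (2 * s_**2)

            sigma_I = math.exp(_slice_scalar(logf_sigma_I, math.log(sigma_I), rng))

            # -- local scales lambda (batched slice) -----------------------
            bsq = B**2
            m_cnt = np.ones(C * P)
            ssq = bsq.ravel().copy()
            lam_flat = lam.ravel().copy()
            if extended:
                m_cnt = np.append(m_cnt, S)
                ssq = np.append(ssq, float(np.sum(b**2)))
                lam_flat = np.append(lam_flat, lam_b)

            tau_sq, c2_cur = tau**2, c2

            def logf_lam(ll):
                lam_ = np.exp(ll)
                var = tau_sq * _lambda_tilde_sq(lam_**2, tau_sq, c2_cur)
                return ln_hc(lam_, 1.0) + ll - 0.5 * m_cnt * np.log(var) - ssq / (2 * var)

            lam_flat = np.exp(_slice_batch(logf_lam, np.log(lam_flat), rng))
            lam = lam_flat[: C * P].reshape(C, P)
            if extended:
                lam_b = float(lam_flat[-1])

            # -- global scale tau ------------------------------------------
            lam_sq_all = lam.ravel() ** 2
            m_all = np.ones(C * P)
            ssq_all = bsq.ravel()
            if extended:
                lam_sq_all = np.append(lam_sq_all, lam_b**2)
                m_all = np.append(m_all, S)
                ssq_all = np.append(ssq_all, float(np.sum(b**2)))
            tau0 = k0 * sigma_g

            def logf_tau(lt):
                t_ = math.exp(lt)
                var = t_**2 * _lambda_tilde_sq(lam_sq_all, t_**2, c2_cur)
                return float(ln_hc(t_, tau0)) + lt + float(np.sum(-0.5 * m_all * np.log(var) - ssq_all / (2 * var)))

            tau = math.exp(_slice_scalar(logf_tau, math.log(tau), rng))

            # -- slab width c^2 --------------------------------------------
            tau_sq = tau**2
            a_c, b_c = spec.nu0 / 2.0, spec.nu0 * spec.s**2 / 2.0

            def logf_c2(lc):
                c2_ = math.exp(lc)
                var = tau_sq * _lambda_tilde_sq(lam_sq_all, tau_sq, c2_)
                return float(_log_inv_gamma(c2_, a_c, b_c)) + lc + float(np.sum(-0.5 * m_all * np.log(var) - ssq_all / (2 * var)))

            c2 = math.exp(_slice_scalar(logf_c2, math.log(c2), rng))

            # -- residual scale sigma_g ------------------------------------
            mu = fixed + I[subj_idx] + (b[subj_idx] * rt if extended else 0.0)
            r = y - mu
            ssr_w = float(np.sum(r * r / w))

            def logf_sigma_g(ls):
                s_ = math.exp(ls)
                return (
                    float(_log_half_normal(s_)) + ls - N * ls - ssr_w / (2 * s_**2) + float(ln_hc(tau, k0 * s_))
                )

            sigma_g = math.exp(_slice_scalar(logf_sigma_g, math.log(sigma_g), rng, width=0.5))

            # -- degrees of freedom nu -------------------------------------
            slw = float(np.sum(np.log(w)))
            siw = float(np.sum(1.0 / w))

            def logf_nu(ln_):
                nu_ = math.exp(ln_)
                h = nu_ / 2.0
                return (
                    float(_log_gamma(nu_, spec.nu_prior_shape, spec.nu_prior_rate))
                    + ln_
                    + N * (h * math.log(h) - gammaln(h))
                    - h * (slw + siw)
                )

            nu = math.exp(_slice_scalar(logf_nu, math.log(nu), rng, width=0.5))

            if it >= settings.warmup:
                k = it - settings.warmup
                store["B"][chain, k] = B
                store["I"][chain, k] = I
                store["I0"][chain, k] = I0
                store["sigma_g"][chain, k] = sigma_g
                store["sigma_I"][chain, k] = sigma_I
                store["nu"][chain, k] = nu
                store["tau"][chain, k] = tau
                store["lam"][chain, k] = lam
                store["c2"][chain, k] = c2
                if extended:
                    store["b"][chain, k] = b
                    store["lam_b"][chain, k] = lam_b

    return PosteriorFit(
        draws=store,
        column_names=design.column_names,
        conditions=design.conditions,
        subjects=design.subjects,
        extended=extended,
        settings=settings,
        spec=spec,
        seeds=seeds,
    )


# --------------------------------------------------------------------------
# diagnostics
# --------------------------------------------------------------------------


def diagnose_and_summarize(fit: PosteriorFit, rhat_limit: float = 1.05, ess_ratio_limit: float = 0.1) -> pd.DataFrame:
    """Per-parameter posterior summary with split-R-hat and ESS ratio.

    Returns one row per scalar parameter element with the posterior median,
    central 50% and 95% intervals, split-R-hat, bulk-ESS ratio, and pass
    flags at the stated limits.  With a single chain R-hat is undefined and
    flagged as failing.
    """
    import arviz as az

    total = fit.n_chains * fit.n_draws
    single_chain = fit.n_chains < 2
    rows = []
    for name, v in fit.draws.items():
        idata = az.from_dict({name: v})
        rhat = az.rhat(idata) if not single_chain else None
        ess = az.ess(idata)
        flat = v.reshape(total, -1)
        qs = np.quantile(flat, [0.025, 0.25, 0.5, 0.75, 0.975], axis=0)
        rhat_vals = np.atleast_1d(rhat[name].values).ravel() if rhat is not None else np.full(flat.shape[1], np.nan)
        ess_vals = np.atleast_1d(ess[name].values).ravel()
        for j in range(flat.shape[1]):
            label = name if flat.shape[1] == 1 else f"{name}[{_element_label(fit, name, j)}]"
            rows.append(
                {
                    "parameter": label,
                    "median": qs[2, j],
                    "q25": qs[1, j],
                    "q75": qs[3, j],
                    "q2.5": qs[0, j],
                    "q97.5": qs[4, j],
                    "rhat": rhat_vals[j],
                    "ess_ratio": ess_vals[j] / total,
                }
            )
    out = pd.DataFrame(rows)
    out["rhat_ok"] = np.where(np.isnan(out.rhat), False, out.rhat < rhat_limit)
    out["ess_ok"] = out.ess_ratio > ess_ratio_limit
    out.attrs["all_rhat_ok"] = bool(out.rhat_ok.all())
    out.attrs["all_ess_ok"] = bool(out.ess_ok.all())
    return out


def _element_label(fit: PosteriorFit, name: str, j: int) -> str:
    shape = fit.draws[name].shape[2:]
    if name in ("B", "lam") and len(shape) == 2:
        i, p = divmod(j, shape[1])
        return f"{fit.conditions[i]},{fit.column_names[p]}"
    if name in ("I", "b"):
        return str(fit.subjects[j])
    return str(j)
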