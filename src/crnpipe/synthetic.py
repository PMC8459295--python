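"""Synthetic go/no-go cohorts with known ground truth.

Generates (a) trial tables for a speeded go/no-go task with point-based
feedback, (b) participant trait tables (regulatory-focus scale scores plus
item-level responses), (c) trial-level component amplitudes from the
hierarchical Student-t regression model, and (d) continuous raw EEG in which
those amplitudes are embedded as a response-locked fronto-central negativity.
Every generator is deterministic given its seed, so each downstream stage can
be tested against known truth without any external data.

The default cohort emulates the study conditions: 91 participants split
26/35/30 across gain-framed, loss-framed, and control feedback groups; 20
blocks of 30 trials (24 go, 6 no-go); a 1 s response deadline; group mean
response times near 0.40-0.46 s; and trait distributions matching the
published group means and SDs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .preprocessing import Recording

__all__ = [
    "CONDITIONS",
    "PREDICTOR_COLUMNS",
    "SimConfig",
    "GroundTruth",
    "EEGSimParams",
    "simulate_cohort",
    "simulate_trial_amplitudes",
    "simulate_raw_eeg",
    "make_crn_template",
    "make_evoked_template",
    "template_window_mean",
    "effective_fcz_gain",
    "expected_extracted_amplitude",
    "go_trial_points",
]

CONDITIONS = ("gain", "loss", "control")

#: Predictor columns of the trial-level design matrix: four base predictors and
#: all two- and three-way interactions not involving both promotion and
#: prevention strength (11 columns total).
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

# event codes used in simulated recordings
EVENT_GO, EVENT_NOGO, EVENT_RESPONSE = 1, 2, 10


# --------------------------------------------------------------------------
# configuration and ground truth
# --------------------------------------------------------------------------


@dataclass
class SimConfig:
    """Study-design parameters for the simulated cohort.

    Defaults reproduce the reference study's conditions.  Response times are
    truncated normal on (0.1 s, 1.0 s] (1 s was the response deadline), with
    between-subject spread of subject mean RT (``rt_sd_between_s``) and
    within-subject trial-to-trial spread (``rt_sd_within_s``) exposed
    separately.  Trait scores are normals truncated to the 1-5 RFQ scale.
    """

    group_sizes: tuple[int, int, int] = (26, 35, 30)
    conditions: tuple[str, ...] = CONDITIONS
    n_blocks: int = 20
    go_per_block: int = 24
    nogo_per_block: int = 6
    rt_mean_s: tuple[float, float, float] = (0.40, 0.43, 0.46)
    rt_sd_within_s: float = 0.09
    rt_sd_between_s: float = 0.05
    rt_bounds_s: tuple[float, float] = (0.1, 1.0)
    fa_rt_shift_s: float = -0.05  # false alarms are faster than hits
    miss_rate: float = 0.03
    false_alarm_rate: float = 0.27
    prom_mean: tuple[float, float, float] = (4.0, 3.8, 3.8)
    prom_sd: tuple[float, float, float] = (0.6, 0.5, 0.6)
    prev_mean: tuple[float, float, float] = (3.3, 3.5, 3.2)
    prev_sd: tuple[float, float, float] = (0.9, 0.9, 0.8)
    trait_bounds: tuple[float, float] = (1.0, 5.0)
    n_prom_items: int = 6
    n_prev_items: int = 5
    # item noise SDs calibrated (accounting for trait truncation and item
    # clipping) so the expected Cronbach's alpha of the promotion and
    # prevention scales matches the published .62 and .79
    prom_item_noise_sd: float = 1.03
    prev_item_noise_sd: float = 0.94
    imi_mean: float = 5.0
    imi_sd: float = 1.0
    seed: int = 0

    @property
    def n_subjects(self) -> int:
        return int(sum(self.group_sizes))

    @property
    def trials_per_block(self) -> int:
        return self.go_per_block + self.nogo_per_block

    def validate(self) -> None:
        if len(self.group_sizes) != len(self.conditions):
            raise ValueError("group_sizes must match number of conditions")
        if any(g <= 0 for g in self.group_sizes):
            raise ValueError("group sizes must be positive")
        for name, rate in (("miss_rate", self.miss_rate), ("false_alarm_rate", self.false_alarm_rate)):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.rt_bounds_s[0] >= self.rt_bounds_s[1]:
            raise ValueError("rt bounds must be increasing")


@dataclass
class GroundTruth:
    """Generating parameters of the trial-level amplitude model.

    ``B`` is conditions x 11 predictors (same column order as
    ``PREDICTOR_COLUMNS``); ``I`` are per-subject intercepts around ``I0``;
    ``b`` are mean-zero per-subject slopes on (standardized) response time;
    noise is Student-t with ``nu`` degrees of freedom and scale ``sigma_g``.
    """

    B: np.ndarray
    I0: float
    I: np.ndarray
    b: np.ndarray
    sigma_g: float
    nu: float
    sigma_I: float
    slope_sd: float
    conditions: tuple[str, ...] = CONDITIONS

    def __post_init__(self) -> None:
        self.B = np.asarray(self.B, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.B.shape != (len(self.conditions), len(PREDICTOR_COLUMNS)):
            raise ValueError(f"B must be {len(self.conditions)} x {len(PREDICTOR_COLUMNS)}")
        if self.sigma_g <= 0 or self.nu <= 0:
            raise ValueError("sigma_g and nu must be positive")

    @classmethod
    def default(
        cls,
        n_subjects: int,
        rng: np.random.Generator,
        conditions: tuple[str, ...] = CONDITIONS,
        sigma_g: float = 0.9,
        nu: float = 8.0,
        sigma_I: float = 0.3,
        slope_sd: float = 0.05,
        I0: float = 0.0,
        scale: float = 1.0,
    ) -> "GroundTruth":
        """Truth on the standardized scale with the published RT effects.

        The per-condition RT coefficients are -0.15 (gain), -0.17 (loss) and
        -0.08 (control), and the gain-condition RT x promotion interaction is
        -0.05; all other coefficients are zero.  ``scale`` multiplies every
        amplitude-scale parameter (use e.g. 0.76 uV with ``I0=-1.17`` for a
        microvolt-scale CRN cohort).
        """
        B = np.zeros((len(conditions), len(PREDICTOR_COLUMNS)))
        rt_col = PREDICTOR_COLUMNS.index("rt")
        rtprom_col = PREDICTOR_COLUMNS.index("rt_prom")
        rt_coefs = {"gain": -0.15, "loss": -0.17, "control": -0.08}
        for i, cond in enumerate(conditions):
            B[i, rt_col] = rt_coefs.get(cond, -0.10) * scale
        if "gain" in conditions:
            B[conditions.index("gain"), rtprom_col] = -0.05 * scale
        return cls(
            B=B,
            I0=I0,
            I=I0 + sigma_I * scale * rng.standard_normal(n_subjects),
            b=slope_sd * scale * rng.standard_normal(n_subjects),
            sigma_g=sigma_g * scale,
            nu=nu,
            sigma_I=sigma_I * scale,
            slope_sd=slope_sd * scale,
            conditions=conditions,
        )

    @classmethod
    def microvolts(cls, n_subjects: int, rng: np.random.Generator, **kwargs) -> "GroundTruth":
        """Truth on the microvolt scale, matching the published grand-mean CRN
        of about -1.17 uV with between-subject SD 0.76 uV."""
        kwargs.setdefault("I0", -1.17)
        kwargs.setdefault("sigma_I", 0.76)
        kwargs.setdefault("sigma_g", 2.0)
        kwargs.setdefault("scale", 1.0)
        kwargs.setdefault("slope_sd", 0.1)
        gt = cls.default(n_subjects, rng, **kwargs)
        # on this scale sigma_I is absolute, not a multiple of `scale`
        return gt


def _truncnorm(rng: np.random.Generator, mean, sd, lo, hi, size) -> np.ndarray:
    a, b = (lo - np.asarray(mean)) / sd, (hi - np.asarray(mean)) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def go_trial_points(rt_s: np.ndarray | float, deadline_s: float = 1.0, full_speed_s: float = 0.452) -> np.ndarray:
    """Points earned on a correct go trial: 30 for beating the deadline plus up
    to 30 speed points, full for responses faster than 452 ms and decaying
    linearly to 0 at the deadline."""
    rt = np.asarray(rt_s, dtype=float)
    speed = np.clip((deadline_s - rt) / (deadline_s - full_speed_s), 0.0, 1.0) * 30.0
    return np.where(rt <= deadline_s, 30.0 + speed, 0.0)


# --------------------------------------------------------------------------
# cohort simulation
# --------------------------------------------------------------------------


def simulate_cohort(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate a full cohort: trial table, trait table, and ground truth.

    Returns
    -------
    trials
        One row per trial: ``subject, condition, block, trial, trial_type,
        onset_s, rt_s, responded, correct, points``.  ``rt_s`` is NaN for
        trials without a response; false alarms on no-go trials carry an RT.
    traits
        One row per subject: scale scores, item responses, IMI
        effort/enjoyment, and the subject's miss count (``n_miss``).
    truth
        The amplitude-model generating parameters (standardized scale).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    cond_of_subject = np.repeat(np.arange(len(config.conditions)), config.group_sizes)
    n_sub = config.n_subjects

    # --- traits ---------------------------------------------------------
    lo, hi = config.trait_bounds
    prom = _truncnorm(rng, np.take(config.prom_mean, cond_of_subject), np.take(config.prom_sd, cond_of_subject), lo, hi, n_sub)
    prev = _truncnorm(rng, np.take(config.prev_mean, cond_of_subject), np.take(config.prev_sd, cond_of_subject), lo, hi, n_sub)
    prom_items = np.clip(prom[:, None] + config.prom_item_noise_sd * rng.standard_normal((n_sub, config.n_prom_items)), lo, hi)
    prev_items = np.clip(prev[:, None] + config.prev_item_noise_sd * rng.standard_normal((n_sub, config.n_prev_items)), lo, hi)
    imi = np.clip(rng.normal(config.imi_mean, config.imi_sd, n_sub), 1.0, 7.0)

    traits = pd.DataFrame(
        {
            "subject": np.arange(n_sub),
            "condition": [config.conditions[c] for c in cond_of_subject],
            "promotion": prom,
            "prevention": prev,
            "imi_effort_enjoyment": imi,
        }
    )
    for i in range(config.n_prom_items):
        traits[f"prom_item_{i + 1}"] = prom_items[:, i]
    for i in range(config.n_prev_items):
        traits[f"prev_item_{i + 1}"] = prev_items[:, i]

    # --- trials ---------------------------------------------------------
    n_trials = config.n_blocks * config.trials_per_block
    subj_rt_mean = _truncnorm(
        rng,
        np.take(config.rt_mean_s, cond_of_subject),
        config.rt_sd_between_s,
        config.rt_bounds_s[0] + 0.05,
        config.rt_bounds_s[1] - 0.1,
        n_sub,
    )

    rows: list[pd.DataFrame] = []
    rt_lo, rt_hi = config.rt_bounds_s
    for j in range(n_sub):
        # randomized go/no-go order within each block
        types = np.empty((config.n_blocks, config.trials_per_block), dtype="U4")
        for blk in range(config.n_blocks):
            order = np.concatenate([np.zeros(config.go_per_block, int), np.ones(config.nogo_per_block, int)])
            rng.shuffle(order)
            types[blk] = np.where(order == 0, "go", "nogo")
        types = types.ravel()
        is_go = types == "go"

        # trial onsets: 0.4 s stimulus, feedback at 1 s for 0.5 s, then 1-2 s fixation
        gaps = 1.5 + rng.uniform(1.0, 2.0, n_trials)
        onsets = 2.0 + np.concatenate([[0.0], np.cumsum(gaps[:-1])])

        rt = _truncnorm(rng, subj_rt_mean[j], config.rt_sd_within_s, rt_lo, rt_hi, n_trials)
        miss = is_go & (rng.random(n_trials) < config.miss_rate)
        fa = ~is_go & (rng.random(n_trials) < config.false_alarm_rate)
        responded = (is_go & ~miss) | fa
        rt = np.where(responded, np.clip(rt + np.where(fa, config.fa_rt_shift_s, 0.0), rt_lo, rt_hi), np.nan)
        correct = (is_go & ~miss) | (~is_go & ~fa)
        points = np.where(is_go & correct, go_trial_points(np.nan_to_num(rt, nan=2.0)), 0.0)
        points = np.where(~is_go & correct, 180.0, points)

        rows.append(
            pd.DataFrame(
                {
                    "subject": j,
                    "condition": config.conditions[cond_of_subject[j]],
                    "block": np.repeat(np.arange(1, config.n_blocks + 1), config.trials_per_block),
                    "trial": np.tile(np.arange(1, config.trials_per_block + 1), config.n_blocks),
                    "trial_type": types,
                    "onset_s": onsets,
                    "rt_s": rt,
                    "responded": responded.astype(int),
                    "correct": correct.astype(int),
                    "points": points,
                }
            )
        )
    trials = pd.concat(rows, ignore_index=True)

    miss_counts = (
        trials[(trials.trial_type == "go") & (trials.correct == 0)].groupby("subject").size().reindex(range(n_sub), fill_value=0)
    )
    traits["n_miss"] = miss_counts.values

    truth = GroundTruth.default(n_sub, rng, conditions=config.conditions)
    return trials, traits, truth


# --------------------------------------------------------------------------
# trial-level amplitudes
# --------------------------------------------------------------------------


def simulate_trial_amplitudes(
    trials: pd.DataFrame,
    traits: pd.DataFrame,
    truth: GroundTruth,
    seed: int = 0,
    kind: str = "CRN",
) -> pd.DataFrame:
    """Generate single-trial amplitudes from the hierarchical model.

    For each usable trial ``Y_k = B_i' X_k + b_j rt_k + I_j + eps`` with
    ``eps ~ sigma_g * t(nu)``.  ``X_k`` is built by the same design-matrix
    rules used at fit time (base predictors z-scored over the trial set,
    interactions as products of z-scores); ``rt_k`` in the random-slope term
    is the z-scored response time.  CRN amplitudes attach to correct go
    trials, ERN amplitudes to false-alarm no-go trials.
    """
    from .model import build_design_matrix

    if kind == "CRN":
        sel = (trials.trial_type == "go") & (trials.correct == 1) & (trials.responded == 1)
    elif kind == "ERN":
        sel = (trials.trial_type == "nogo") & (trials.correct == 0) & (trials.responded == 1)
    else:
        raise ValueError(f"kind must be CRN or ERN, got {kind!r}")
    sub = trials[sel].reset_index(drop=True)
    if sub.empty:
        raise ValueError(f"no usable trials for kind {kind!r}")

    unknown = set(sub.subject) - set(traits.subject)
    if unknown:
        raise KeyError(f"trials reference subjects missing from traits: {sorted(unknown)[:5]}")
    cond_names = list(truth.conditions)
    bad_cond = set(sub.condition) - set(cond_names)
    if bad_cond:
        raise KeyError(f"conditions missing from ground truth: {sorted(bad_cond)}")

    amps = sub[["subject", "condition", "block", "trial", "rt_s"]].copy()
    design = build_design_matrix(amps, traits, conditions=tuple(cond_names))

    rng = np.random.default_rng(seed)
    fixed = np.einsum("kp,kp->k", design.X, truth.B[design.condition_index])
    rt_z = design.X[:, design.column_names.index("rt")]
    y = (
        fixed
        + truth.b[sub.subject.to_numpy()] * rt_z
        + truth.I[sub.subject.to_numpy()]
        + truth.sigma_g * rng.standard_t(truth.nu, len(sub))
    )
    amps["amplitude"] = y
    amps["kind"] = kind
    amps["usable"] = True
    return amps


# --------------------------------------------------------------------------
# raw EEG
# --------------------------------------------------------------------------

# default montage spans the head so that average referencing (which subtracts
# the montage-mean signal) behaves like a dense whole-head layout would
DEFAULT_LABELS = ("Fpz", "F3", "F4", "FCz", "C3", "C4", "Pz", "O1", "O2")
# response-locked component topography: focal, maximal at FCz
DEFAULT_CRN_GAINS = (0.2, 0.3, 0.3, 1.0, 0.3, 0.3, 0.15, 0.05, 0.05)
# stimulus-evoked topography: posterior visual maximum
DEFAULT_EVOKED_GAINS = (0.4, 0.5, 0.5, 0.6, 0.6, 0.6, 0.8, 1.0, 1.0)


def make_crn_template(
    rate_hz: float = 512.0,
    peak_s: float = 0.020,
    sigma_s: float = 0.025,
    span_s: tuple[float, float] = (-0.12, 0.2),
) -> tuple[np.ndarray, np.ndarray]:
    """Unit-amplitude response-locked negativity template.

    Gaussian bump peaking at ``peak_s`` after the response (20 ms for the CRN;
    use 59 ms for an ERN-like morphology).  Returns ``(times_s, values)`` with
    peak value 1; multiply by a (negative) trial amplitude to embed it.
    """
    t = np.arange(round(span_s[0] * rate_hz), round(span_s[1] * rate_hz) + 1) / rate_hz
    return t, np.exp(-0.5 * ((t - peak_s) / sigma_s) ** 2)


def make_evoked_template(rate_hz: float = 512.0, span_s: tuple[float, float] = (0.0, 0.8)) -> tuple[np.ndarray, np.ndarray]:
    """Stimulus-locked evoked waveform (P1-N1-P3-like morphology), in uV."""
    t = np.arange(round(span_s[0] * rate_hz), round(span_s[1] * rate_hz) + 1) / rate_hz
    v = (
        2.0 * np.exp(-0.5 * ((t - 0.100) / 0.020) ** 2)
        - 3.0 * np.exp(-0.5 * ((t - 0.170) / 0.025) ** 2)
        + 4.0 * np.exp(-0.5 * ((t - 0.350) / 0.060) ** 2)
    )
    return t, v


def template_window_mean(
    window_ms: tuple[float, float],
    rate_hz: float = 512.0,
    peak_s: float = 0.020,
    sigma_s: float = 0.025,
) -> float:
    """Mean of the unit CRN template over a response-locked window.

    The expected extracted amplitude of an embedded component is the trial's
    generating amplitude times this factor (window means, not peaks, are the
    amplitude measure).
    """
    t, v = make_crn_template(rate_hz, peak_s, sigma_s)
    lo, hi = window_ms[0] / 1000.0, window_ms[1] / 1000.0
    if lo < t[0] or hi > t[-1]:
        raise ValueError("window extends beyond the template span")
    keep = (t >= lo - 1e-9) & (t <= hi + 1e-9)
    return float(v[keep].mean())


def effective_fcz_gain(params: "EEGSimParams") -> float:
    """FCz gain of the response-locked component under average reference.

    Average referencing subtracts the montage-mean signal, so the component
    seen at FCz is the embedded amplitude times ``g_FCz - mean(g)``.
    """
    g = np.asarray(params.crn_gains, float)
    return float(g[params.channel_labels.index("FCz")] - g.mean())


def expected_extracted_amplitude(
    amps: pd.DataFrame,
    params: "EEGSimParams",
    window_ms: tuple[float, float],
    baseline_ms: tuple[float, float] = (-500.0, -400.0),
    exact: bool = True,
) -> np.ndarray:
    """Analytic oracle for the pipeline's extracted window-mean amplitudes.

    For an embedded trial amplitude ``a`` the average-referenced FCz epoch
    contains ``a * (g_FCz - mean(g))`` times the unit template, whose mean
    over the measurement window is :func:`template_window_mean`.  With
    ``exact=True`` the oracle additionally accounts for the response-locked
    content of the subtracted stimulus-locked average (the per-subject mean
    component, smeared by the response-time distribution, which evoked
    subtraction removes from each trial) and for the baseline correction —
    i.e. it is the exact noise-free output of the extraction procedure.
    """
    g_eff = effective_fcz_gain(params)
    rate = params.rate_hz

    def tmpl(t: np.ndarray) -> np.ndarray:
        return np.exp(-0.5 * ((t - params.crn_peak_s) / params.crn_sigma_s) ** 2)

    m_win = template_window_mean(window_ms, rate, params.crn_peak_s, params.crn_sigma_s)
    direct = amps.amplitude.to_numpy(float) * g_eff * m_win
    if not exact:
        return direct

    t_win = np.arange(round(window_ms[0] / 1000 * rate), round(window_ms[1] / 1000 * rate) + 1) / rate
    t_base = np.arange(round(baseline_ms[0] / 1000 * rate), round(baseline_ms[1] / 1000 * rate) + 1) / rate
    amps = amps.reset_index(drop=True)
    out = np.empty(len(amps))
    for _, sub in amps.groupby("subject", sort=False):
        rts = sub.rt_s.to_numpy(float)
        a = sub.amplitude.to_numpy(float)
        # smear(k, t) = subject-mean component at response-locked time t of trial k
        def smear(tgrid: np.ndarray) -> np.ndarray:
            dt = tgrid[None, :, None] + rts[:, None, None] - rts[None, None, :]  # k x t x m
            return (tmpl(dt) * a[None, None, :]).mean(axis=2) * g_eff

        win_term = smear(t_win).mean(axis=1)
        base_term = smear(t_base).mean(axis=1)
        base_direct = a * g_eff * tmpl(t_base).mean()
        out[sub.index.to_numpy()] = a * g_eff * m_win - win_term - (base_direct - base_term)
    return out


@dataclass
class EEGSimParams:
    """Raw-EEG generator settings."""

    rate_hz: float = 512.0
    channel_labels: tuple[str, ...] = DEFAULT_LABELS
    crn_gains: tuple[float, ...] = DEFAULT_CRN_GAINS
    evoked_gains: tuple[float, ...] = DEFAULT_EVOKED_GAINS
    crn_peak_s: float = 0.020
    crn_sigma_s: float = 0.025
    noise_rms_uv: float = 0.5
    noise_spectrum_exponent: float = 1.0
    line_noise_amp_uv: float = 1.0
    artifact_segment_rate: float = 0.0
    artifact_amp_uv: float = 40.0
    seg_len_s: float = 0.5
    pad_s: float = 2.0

    def __post_init__(self) -> None:
        if "FCz" not in self.channel_labels:
            raise ValueError("montage must include FCz")
        if len(self.crn_gains) != len(self.channel_labels) or len(self.evoked_gains) != len(self.channel_labels):
            raise ValueError("gain vectors must match channel count")


def _pink_noise(rng: np.random.Generator, n_ch: int, n_samp: int, rate: float, exponent: float, rms: float) -> np.ndarray:
    """Gaussian noise with a 1/f**exponent power spectrum, scaled to target RMS."""
    freqs = np.fft.rfftfreq(n_samp, d=1.0 / rate)
    shape = np.ones_like(freqs)
    nz = freqs > 0
    shape[nz] = freqs[nz] ** (-exponent / 2.0)
    shape[0] = 0.0
    spec = (rng.standard_normal((n_ch, freqs.size)) + 1j * rng.standard_normal((n_ch, freqs.size))) * shape
    x = np.fft.irfft(spec, n=n_samp, axis=1)
    x *= rms / x.std(axis=1, keepdims=True)
    return x


def simulate_raw_eeg(
    trials: pd.DataFrame,
    amps: pd.DataFrame,
    params: EEGSimParams | None = None,
    seed: int = 0,
) -> Recording:
    """Continuous EEG for one subject with embedded known components.

    Every trial contributes the stimulus-evoked template at its onset; each
    trial with a row in ``amps`` additionally contributes the response-locked
    template scaled by that trial's amplitude, centered on the response
    sample.  The background is 1/f noise plus 60 Hz line noise.  Common-mode
    broadband artifact segments are injected at ``artifact_segment_rate`` per
    0.5 s segment; injected positions are recorded in
    ``recording.meta["injected_artifacts"]``.
    """
    params = params or EEGSimParams()
    if trials.subject.nunique() != 1:
        raise ValueError("simulate_raw_eeg expects a single subject's trials")
    trials = trials.sort_values("onset_s").reset_index(drop=True)
    onsets = trials.onset_s.to_numpy()
    if onsets[0] < 1.0:
        raise ValueError("first trial onset must leave at least 1 s of padding")
    if np.any(np.diff(onsets) <= 0):
        raise ValueError("trial onsets overlap")

    rate = params.rate_hz
    n_ch = len(params.channel_labels)
    duration = float(np.ceil(onsets[-1] + params.pad_s))
    n_samp = int(round(duration * rate))

    rng = np.random.default_rng(seed)
    if params.noise_rms_uv > 0:
        data = _pink_noise(rng, n_ch, n_samp, rate, params.noise_spectrum_exponent, params.noise_rms_uv)
    else:
        data = np.zeros((n_ch, n_samp))
    if params.line_noise_amp_uv > 0:
        t = np.arange(n_samp) / rate
        data += params.line_noise_amp_uv * np.sin(2 * np.pi * 60.0 * t + rng.uniform(0, 2 * np.pi))

    ev_t, ev_v = make_evoked_template(rate)
    crn_t, crn_v = make_crn_template(rate, params.crn_peak_s, params.crn_sigma_s)
    ev_gain = np.asarray(params.evoked_gains)[:, None]
    crn_gain = np.asarray(params.crn_gains)[:, None]

    def _add(template: np.ndarray, t0: np.ndarray, center_sample: int, gains: np.ndarray, scale: float) -> None:
        start = center_sample + int(round(t0[0] * rate))
        stop = start + template.size
        if start < 0 or stop > n_samp:
            return
        data[:, start:stop] += scale * gains * template

    events: list[tuple[int, int]] = []
    amp_by_key = {(r.block, r.trial): r.amplitude for r in amps.itertuples()}
    for r in trials.itertuples():
        onset_sample = int(round(r.onset_s * rate))
        events.append((onset_sample, EVENT_GO if r.trial_type == "go" else EVENT_NOGO))
        _add(ev_v, ev_t, onset_sample, ev_gain, 1.0)
        if r.responded and np.isfinite(r.rt_s):
            resp_sample = int(round((r.onset_s + r.rt_s) * rate))
            events.append((resp_sample, EVENT_RESPONSE))
            amp = amp_by_key.get((r.block, r.trial))
            if amp is not None:
                _add(crn_v, crn_t, resp_sample, crn_gain, amp)

    injected: list[tuple[int, int]] = []
    if params.artifact_segment_rate > 0:
        seg_len = int(round(params.seg_len_s * rate))
        for k in range(n_samp // seg_len):
            if rng.random() < params.artifact_segment_rate:
                burst = params.artifact_amp_uv * rng.standard_normal(seg_len)
                data[:, k * seg_len : (k + 1) * seg_len] += burst  # common-mode
                injected.append((k * seg_len, (k + 1) * seg_len))

    return Recording(
        data=data,
        rate=rate,
        labels=list(params.channel_labels),
        events=events,
        meta={"injected_artifacts": injected, "subject": int(trials.subject.iloc[0])},
    )
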