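"""Single-trial CRN/ERN waveform extraction.

The response-locked components are isolated by evoked subtraction: the
participant's stimulus-locked average (correct go trials for the CRN; all
no-go trials for the ERN, because false alarms are too rare to average) is
subtracted from each trial in stimulus-locked alignment, leaving
response-related activity plus noise.  A -500..+500 ms epoch is then cut
around the button press and baseline-corrected over -500..-400 ms.  Component
amplitude is the time-window mean at FCz over the grand-mean negative peak
+-50 ms — a window mean rather than a peak, because the time average is an
unbiased amplitude estimate while peaks are biased by noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import EpochConfig
from .preprocessing import Recording

__all__ = [
    "EpochSet",
    "ComponentWindow",
    "evoked_average",
    "extract_response_epochs",
    "grand_mean_waveform",
    "find_component_window",
    "mean_amplitude",
    "apply_trial_criteria",
    "single_trial_amplitudes",
]


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------


@dataclass
class EpochSet:
    """Response-locked epochs for one subject: trials x channels x time."""

    waveforms: np.ndarray
    times_ms: np.ndarray
    labels: list[str]
    trials: pd.DataFrame  # one row per kept epoch (subject, condition, block, trial, rt_s)
    kind: str
    subject: int

    @property
    def n_trials(self) -> int:
        return self.waveforms.shape[0]

    def channel(self, label: str) -> np.ndarray:
        try:
            return self.waveforms[:, self.labels.index(label), :]
        except ValueError:
            raise KeyError(f"channel {label!r} not in epoch set") from None


@dataclass
class ComponentWindow:
    """Measurement window: the grand-mean negative peak +-50 ms."""

    peak_ms: float
    half_width_ms: float = 50.0

    @property
    def start_ms(self) -> float:
        return self.peak_ms - self.half_width_ms

    @property
    def end_ms(self) -> float:
        return self.peak_ms + self.half_width_ms


def _qualifying(trials: pd.DataFrame, kind: str, for_average: bool = False) -> pd.DataFrame:
    """Trial rows entering the evoked average / the epoch set for a component."""
    if kind == "CRN":
        return trials[(trials.trial_type == "go") & (trials.correct == 1) & (trials.responded == 1)]
    if kind == "ERN":
        if for_average:
            # the stimulus-evoked average uses ALL no-go trials, not only false alarms
            return trials[trials.trial_type == "nogo"]
        return trials[(trials.trial_type == "nogo") & (trials.responded == 1)]
    raise ValueError(f"kind must be CRN or ERN, got {kind!r}")


# --------------------------------------------------------------------------
# evoked subtraction and epoching
# --------------------------------------------------------------------------


def evoked_average(rec: Recording, trials: pd.DataFrame, kind: str, cfg: EpochConfig | None = None) -> np.ndarray:
    """Per-participant stimulus-locked average over the evoked span.

    Returns channels x samples covering ``cfg.evoked_span_s`` relative to
    stimulus onset, averaged over the component's averaging set.
    """
    cfg = cfg or EpochConfig()
    rows = _qualifying(trials, kind, for_average=True)
    if rows.empty:
        raise ValueError(f"no qualifying trials for {kind} evoked average")
    n0 = int(round(cfg.evoked_span_s[0] * rec.rate))
    n1 = int(round(cfg.evoked_span_s[1] * rec.rate))
    acc = np.zeros((rec.n_channels, n1 - n0))
    count = 0
    for onset_s in rows.onset_s:
        start = int(round(onset_s * rec.rate)) + n0
        stop = start + (n1 - n0)
        if start < 0 or stop > rec.n_samples:
            continue
        acc += rec.data[:, start:stop]
        count += 1
    if count == 0:
        raise ValueError(f"no {kind} trials fully inside the recording")
    return acc / count


def _overlaps_bad(start: int, stop: int, bad: list[tuple[int, int]]) -> bool:
    return any(start < b_stop and b_start < stop for b_start, b_stop in bad)


def extract_response_epochs(
    rec: Recording,
    trials: pd.DataFrame,
    evoked: np.ndarray,
    kind: str,
    cfg: EpochConfig | None = None,
) -> tuple[EpochSet, list[dict]]:
    """Cut evoked-subtracted, baseline-corrected response-locked epochs.

    The evoked average is subtracted in stimulus-locked alignment before the
    -pre..+post epoch is cut around the button press; the per-channel mean
    over the baseline window is then removed.  Epochs overlapping flagged bad
    segments or extending past the recording are dropped and logged.
    """
    cfg = cfg or EpochConfig()
    rows = _qualifying(trials, kind).reset_index(drop=True)
    rate = rec.rate
    n_pre = int(round(cfg.epoch_pre_ms / 1000.0 * rate))
    n_post = int(round(cfg.epoch_post_ms / 1000.0 * rate))
    times_ms = np.arange(-n_pre, n_post + 1) / rate * 1000.0
    ev_offset = int(round(cfg.evoked_span_s[0] * rate))
    ev_len = evoked.shape[1]
    base = (times_ms >= cfg.baseline_ms[0]) & (times_ms <= cfg.baseline_ms[1])

    kept, kept_rows, log = [], [], []
    for r in rows.itertuples():
        resp = int(round((r.onset_s + r.rt_s) * rate))
        onset = int(round(r.onset_s * rate))
        start, stop = resp - n_pre, resp + n_post + 1
        if start < 0 or stop > rec.n_samples:
            log.append({"subject": r.subject, "block": r.block, "trial": r.trial, "reason": "epoch outside recording"})
            continue
        if _overlaps_bad(start, stop, rec.bad_segments):
            log.append({"subject": r.subject, "block": r.block, "trial": r.trial, "reason": "overlaps bad segment"})
            continue
        epoch = rec.data[:, start:stop].copy()
        # subtract the stimulus-locked average where the spans overlap
        ev_lo = max(start - onset - ev_offset, 0)
        ev_hi = min(stop - onset - ev_offset, ev_len)
        if ev_hi > ev_lo:
            ep_lo = ev_lo + ev_offset + onset - start
            epoch[:, ep_lo : ep_lo + (ev_hi - ev_lo)] -= evoked[:, ev_lo:ev_hi]
        epoch -= epoch[:, base].mean(axis=1, keepdims=True)
        kept.append(epoch)
        kept_rows.append(r.Index)

    waveforms = np.stack(kept) if kept else np.empty((0, rec.n_channels, times_ms.size))
    return (
        EpochSet(
            waveforms=waveforms,
            times_ms=times_ms,
            labels=list(rec.labels),
            trials=rows.loc[kept_rows].reset_index(drop=True),
            kind=kind,
            subject=int(rows.subject.iloc[0]) if len(rows) else -1,
        ),
        log,
    )


# --------------------------------------------------------------------------
# component window and amplitude
# --------------------------------------------------------------------------


def grand_mean_waveform(epoch_sets: list[EpochSet], channel: str = "FCz") -> tuple[np.ndarray, np.ndarray]:
    """Grand mean at one channel: average of per-subject mean epochs."""
    if not epoch_sets:
        raise ValueError("no epoch sets")
    times = epoch_sets[0].times_ms
    means = [es.channel(channel).mean(axis=0) for es in epoch_sets if es.n_trials > 0]
    if not means:
        raise ValueError("all epoch sets are empty")
    return times, np.mean(means, axis=0)


def find_component_window(
    grand: np.ndarray,
    times_ms: np.ndarray,
    cfg: EpochConfig | None = None,
) -> ComponentWindow:
    """Window around the grand-mean negative peak within the search range.

    The peak is the minimum of the grand-mean waveform in the post-response
    search range (ties broken by the earliest sample), refined to sub-sample
    resolution by parabolic interpolation through the minimum and its two
    neighbors, and reported at 1 ms resolution; the window is peak +- half
    width.
    """
    cfg = cfg or EpochConfig()
    if not np.all(np.isfinite(grand)):
        raise ValueError("grand mean contains non-finite values")
    lo, hi = cfg.peak_search_ms
    sel = np.flatnonzero((times_ms >= lo) & (times_ms <= hi))
    if sel.size == 0:
        raise ValueError("empty peak search range")
    peak_idx = sel[np.argmin(grand[sel])]
    peak_ms = float(times_ms[peak_idx])
    # refine by a least-squares parabola over the +-10 ms neighborhood
    near = np.flatnonzero(np.abs(times_ms - peak_ms) <= 10.0)
    if near.size >= 3:
        t = times_ms[near] - peak_ms
        coef = np.polynomial.polynomial.polyfit(t, grand[near], 2)
        if coef[2] > 0:  # convex: vertex is a minimum
            vertex = -coef[1] / (2 * coef[2])
            peak_ms = peak_ms + float(np.clip(vertex, -10.0, 10.0))
    return ComponentWindow(peak_ms=float(round(peak_ms)), half_width_ms=cfg.window_half_ms)


def mean_amplitude(epochs: EpochSet, window: ComponentWindow, channel: str = "FCz") -> pd.DataFrame:
    """One amplitude per trial: the time-window mean at the given channel."""
    t = epochs.times_ms
    if window.start_ms < t[0] or window.end_ms > t[-1]:
        raise ValueError("component window extends beyond the epoch span")
    sel = (t >= window.start_ms - 1e-9) & (t <= window.end_ms + 1e-9)
    amp = epochs.channel(channel)[:, sel].mean(axis=1)
    out = epochs.trials.copy()
    out["amplitude"] = amp
    out["kind"] = epochs.kind
    out["usable"] = True
    return out


# --------------------------------------------------------------------------
# retention rules
# --------------------------------------------------------------------------


def apply_trial_criteria(
    amps: pd.DataFrame,
    trials: pd.DataFrame,
    kind: str,
    cfg: EpochConfig | None = None,
) -> tuple[pd.DataFrame, list[dict]]:
    """Apply subject-retention rules; return the filtered table and a report.

    Two rules: (1) subjects with a false-alarm rate of 83% or higher on 10 or
    more blocks are excluded entirely (inattention criterion); (2) for the
    ERN only, subjects with fewer than six usable error trials are excluded
    from the ERN set (they remain usable for the CRN).
    """
    cfg = cfg or EpochConfig()
    report: list[dict] = []

    nogo = trials[trials.trial_type == "nogo"]
    fa_rate = nogo.assign(fa=(nogo.responded == 1).astype(int)).groupby(["subject", "block"]).fa.mean()
    high_fa_blocks = (fa_rate >= cfg.fa_rate_exclude).groupby("subject").sum()
    inattentive = set(high_fa_blocks[high_fa_blocks >= cfg.fa_blocks_exclude].index)
    for s in sorted(inattentive):
        report.append({"subject": s, "rule": "false-alarm rate >= 83% on >= 10 blocks", "kind": "all"})

    keep = ~amps.subject.isin(inattentive)
    if kind == "ERN":
        counts = amps[keep & amps.usable].groupby("subject").size()
        too_few = set(counts[counts < cfg.min_error_trials].index)
        # subjects with no usable trials at all also fail the minimum
        too_few |= set(amps.subject.unique()) - set(counts.index) - inattentive
        for s in sorted(too_few):
            report.append({"subject": s, "rule": f"fewer than {cfg.min_error_trials} usable error trials", "kind": "ERN"})
        keep &= ~amps.subject.isin(too_few)

    return amps[keep].reset_index(drop=True), report


# --------------------------------------------------------------------------
# end-to-end convenience
# --------------------------------------------------------------------------


def single_trial_amplitudes(
    recordings: dict[int, Recording],
    trials: pd.DataFrame,
    kind: str = "CRN",
    cfg: EpochConfig | None = None,
    window: ComponentWindow | None = None,
) -> tuple[pd.DataFrame, ComponentWindow, list[dict]]:
    """Full extraction across subjects: evoked subtraction, epoching, one
    dataset-level component window from the grand mean, and window-mean
    amplitudes.  Returns (amplitude table, window, rejection log)."""
    cfg = cfg or EpochConfig()
    epoch_sets: list[EpochSet] = []
    log: list[dict] = []
    for subject, rec in sorted(recordings.items()):
        sub_trials = trials[trials.subject == subject]
        evoked = evoked_average(rec, sub_trials, kind, cfg)
        epochs, rejected = extract_response_epochs(rec, sub_trials, evoked, kind, cfg)
        epoch_sets.append(epochs)
        log.extend(rejected)
    if window is None:
        times, grand = grand_mean_waveform(epoch_sets, cfg.channel)
        window = find_component_window(grand, times, cfg)
    tables = [mean_amplitude(es, window, cfg.channel) for es in epoch_sets if es.n_trials > 0]
    amps = pd.concat(tables, ignore_index=True)
    return amps, window, log
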