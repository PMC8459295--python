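"""Continuous-EEG cleaning.

Implements the fixed preprocessing chain used before single-trial component
extraction: Butterworth high-pass and line-noise band-stop filters, bad-channel
interpolation from montage neighbors, average re-referencing, automated bad
segment detection via cross-channel spectral correlation, and a final zero-phase
low-pass.  The intended order is::

    highpass -> bandstop -> interpolation -> average reference
             -> (pluggable ocular cleaning) -> segment scoring -> lowpass

Epochs overlapping flagged segments are rejected downstream (see
:mod:`crnpipe.erp`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import signal

from .config import FilterConfig, SegmentConfig

__all__ = [
    "Recording",
    "SegmentScore",
    "filter_continuous",
    "interpolate_channels",
    "rereference_average",
    "detect_bad_segments",
    "montage_adjacency",
    "noisy_channel_candidates",
]


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------


@dataclass
class Recording:
    """Continuous multichannel EEG.

    Parameters
    ----------
    data
        Channels x samples voltages in microvolts.
    rate
        Sampling rate in Hz.
    labels
        10-10 channel names, unique, same length as ``data``.
    events
        ``(sample_index, event_code)`` pairs, sorted by sample.
    bad_segments
        Half-open ``[start, stop)`` sample intervals flagged as unusable.
    """

    data: np.ndarray
    rate: float
    labels: list[str]
    events: list[tuple[int, int]] = field(default_factory=list)
    bad_segments: list[tuple[int, int]] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("labels must match number of data rows")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")
        self.events = sorted(self.events)
        for start, stop in self.bad_segments:
            if not (0 <= start < stop <= self.n_samples):
                raise ValueError(f"bad segment ({start}, {stop}) out of bounds")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate

    def copy(self, data: np.ndarray | None = None) -> "Recording":
        return Recording(
            data=self.data.copy() if data is None else data,
            rate=self.rate,
            labels=list(self.labels),
            events=list(self.events),
            bad_segments=list(self.bad_segments),
            meta=dict(self.meta),
        )

    def channel(self, label: str) -> np.ndarray:
        try:
            return self.data[self.labels.index(label)]
        except ValueError:
            raise KeyError(f"channel {label!r} not in recording") from None


@dataclass
class SegmentScore:
    """Mean channel-pair spectral correlation for one 0.5 s segment."""

    segment_index: int
    interval: tuple[int, int]
    score: float
    flagged: bool = False


# --------------------------------------------------------------------------
# filtering
# --------------------------------------------------------------------------


def _design(stage: str, rate: float, cfg: FilterConfig) -> tuple[np.ndarray, bool]:
    nyq = rate / 2.0
    if stage == "highpass":
        spec = (cfg.highpass_order, cfg.highpass_hz, "highpass", cfg.highpass_two_pass)
    elif stage == "bandstop":
        spec = (cfg.bandstop_order, cfg.bandstop_hz, "bandstop", cfg.bandstop_two_pass)
    elif stage == "lowpass":
        spec = (cfg.lowpass_order, cfg.lowpass_hz, "lowpass", cfg.lowpass_two_pass)
    else:
        raise ValueError(f"unknown filter stage {stage!r}")
    order, freq, btype, two_pass = spec
    if np.max(freq) >= nyq:
        raise ValueError(f"{stage} cutoff at or above Nyquist")
    # a two-pass filter applies half the stated order forward and backward
    if two_pass:
        order = max(order // 2, 1)
    sos = signal.butter(order, freq, btype, fs=rate, output="sos")
    return sos, two_pass


def filter_continuous(rec: Recording, stage: str, cfg: FilterConfig | None = None) -> Recording:
    """Apply one filter stage and return a filtered copy.

    All stages are two-pass (forward-backward, zero net phase) by default;
    set the per-stage ``*_two_pass`` config flags for causal filtering.
    """
    cfg = cfg or FilterConfig()
    sos, two_pass = _design(stage, rec.rate, cfg)
    if two_pass:
        out = signal.sosfiltfilt(sos, rec.data, axis=1)
    else:
        out = signal.sosfilt(sos, rec.data, axis=1)
    return rec.copy(data=np.ascontiguousarray(out))


# --------------------------------------------------------------------------
# channel interpolation
# --------------------------------------------------------------------------

_MONTAGE_POS: dict[str, np.ndarray] | None = None


def _standard_positions() -> dict[str, np.ndarray]:
    """3D positions (meters) of standard 10-05 electrode sites, via mne."""
    global _MONTAGE_POS
    if _MONTAGE_POS is None:
        import mne

        montage = mne.channels.make_standard_montage("colin27_1005")
        pos = montage.get_positions()["ch_pos"]
        _MONTAGE_POS = {name: np.asarray(p) for name, p in pos.items()}
    return _MONTAGE_POS


def montage_adjacency(labels: Sequence[str], neighbor_radius_m: float = 0.06) -> dict[str, list[str]]:
    """Neighbor lists from inter-electrode distance on the standard montage.

    Channels without a standard-montage position get an empty neighbor list.
    """
    pos = _standard_positions()
    known = [lab for lab in labels if lab in pos]
    adj: dict[str, list[str]] = {lab: [] for lab in labels}
    for a in known:
        for b in known:
            if a == b:
                continue
            if np.linalg.norm(pos[a] - pos[b]) <= neighbor_radius_m:
                adj[a].append(b)
    return adj


def interpolate_channels(
    rec: Recording,
    bad: Iterable[str],
    adjacency: dict[str, list[str]] | None = None,
) -> Recording:
    """Replace each bad channel by the unweighted mean of its montage neighbors.

    Bad neighbors are excluded from each other's averaging set.  A bad channel
    with fewer than two good neighbors is a montage error.
    """
    bad = list(bad)
    unknown = set(bad) - set(rec.labels)
    if unknown:
        raise ValueError(f"bad channels not in recording: {sorted(unknown)}")
    if not bad:
        return rec.copy()
    adjacency = adjacency if adjacency is not None else montage_adjacency(rec.labels)
    out = rec.data.copy()
    idx = {lab: i for i, lab in enumerate(rec.labels)}
    for lab in bad:
        neighbors = [n for n in adjacency.get(lab, []) if n in idx and n not in bad]
        if len(neighbors) < 2:
            raise ValueError(f"channel {lab!r} has fewer than two good montage neighbors")
        out[idx[lab]] = rec.data[[idx[n] for n in neighbors]].mean(axis=0)
    return rec.copy(data=out)


def noisy_channel_candidates(rec: Recording, k: float = 5.0) -> list[str]:
    """Automated noisy-channel criterion: robust SD > ``k`` x median channel SD.

    Robust SD is 1.4826 x median absolute deviation, per channel.
    """
    mad = np.median(np.abs(rec.data - np.median(rec.data, axis=1, keepdims=True)), axis=1)
    robust_sd = 1.4826 * mad
    ref = np.median(robust_sd)
    if ref == 0:
        return []
    return [lab for lab, sd in zip(rec.labels, robust_sd) if sd > k * ref]


# --------------------------------------------------------------------------
# referencing
# --------------------------------------------------------------------------


def rereference_average(rec: Recording, exclude: Sequence[str] = ()) -> Recording:
    """Re-reference to the average of scalp channels.

    After this, the mean over included channels is zero at every sample.
    """
    include = [i for i, lab in enumerate(rec.labels) if lab not in set(exclude)]
    if len(include) < 2:
        raise ValueError("average reference requires at least two scalp channels")
    out = rec.data.copy()
    ref = out[include].mean(axis=0)
    out[include] -= ref
    return rec.copy(data=out)


# --------------------------------------------------------------------------
# bad-segment detection
# --------------------------------------------------------------------------


def _segment_spectra(block: np.ndarray, rate: float, cfg: SegmentConfig) -> np.ndarray:
    """Per-channel spectra of one segment, restricted to the configured band."""
    spec = np.abs(np.fft.rfft(block, axis=1))
    freqs = np.fft.rfftfreq(block.shape[1], d=1.0 / rate)
    lo, hi = cfg.spectrum_band_hz
    keep = (freqs >= lo) & (freqs <= hi)
    spec = spec[:, keep]
    if cfg.spectrum_kind == "power":
        spec = spec**2
    elif cfg.spectrum_kind == "log":
        spec = np.log(spec + 1e-12)
    elif cfg.spectrum_kind != "amplitude":
        raise ValueError(f"unknown spectrum kind {cfg.spectrum_kind!r}")
    return spec


def detect_bad_segments(rec: Recording, cfg: SegmentConfig | None = None) -> list[SegmentScore]:
    """Flag segments whose cross-channel spectral correlation is atypical.

    The recording is divided into non-overlapping ``seg_len_s`` segments.  For
    each segment the per-channel amplitude spectrum is computed, all channel
    pairs are Pearson-correlated, and the pair average is the segment score.
    Segments scoring more than ``z_thresh`` standard deviations from the mean
    score (two-sided) are flagged and appended to ``rec.bad_segments``.
    """
    cfg = cfg or SegmentConfig()
    if rec.n_channels < 2:
        raise ValueError("segment detector requires at least two channels")
    seg_len = int(round(cfg.seg_len_s * rec.rate))
    n_segments = rec.n_samples // seg_len
    if n_segments < 2:
        raise ValueError("recording shorter than two segments")

    scores: list[SegmentScore] = []
    iu = np.triu_indices(rec.n_channels, k=1)
    for k in range(n_segments):
        start, stop = k * seg_len, (k + 1) * seg_len
        spec = _segment_spectra(rec.data[:, start:stop], rec.rate, cfg)
        corr = np.corrcoef(spec)
        scores.append(SegmentScore(k, (start, stop), float(corr[iu].mean())))

    vals = np.array([s.score for s in scores])
    mean, sd = vals.mean(), vals.std()
    if sd > 0 and np.isfinite(cfg.z_thresh):
        for s in scores:
            if abs(s.score - mean) > cfg.z_thresh * sd:
                s.flagged = True
                rec.bad_segments.append(s.interval)
    rec.bad_segments = sorted(set(rec.bad_segments))
    return scores


def preprocess(
    rec: Recording,
    filters: FilterConfig | None = None,
    segments: SegmentConfig | None = None,
    bad_channels: Iterable[str] = (),
) -> tuple[Recording, list[SegmentScore]]:
    """Run the full cleaning chain in the canonical order."""
    filters = filters or FilterConfig()
    segments = segments or SegmentConfig()
    rec = filter_continuous(rec, "highpass", filters)
    rec = filter_continuous(rec, "bandstop", filters)
    rec = interpolate_channels(rec, bad_channels)
    rec = rereference_average(rec)
    scores = detect_bad_segments(rec, segments)
    rec = filter_continuous(rec, "lowpass", filters)
    return rec, scores
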