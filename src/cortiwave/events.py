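"""Threshold-based extraction of epileptic-spike windows.

"Spikes" here are the millivolt-scale ictal / inter-ictal field-potential
transients of a drug-induced seizure, not single-unit action potentials.
Detection runs on the low-pass-filtered (120 Hz) recording: the across-
channel maximum of the absolute voltage is scanned for excursions above a
fixed threshold (500 uV by default), each excursion seeds one event
centred on its peak, and a refractory distance keeps one event per spike
complex even when the wave sweeps the array over tens of milliseconds.

Window length depends on context: 100 ms for ictal spikes, 500 ms for
inter-ictal ones, so each window holds exactly one spike.  Context is
assigned from a sliding spike-rate estimate (the recordings themselves do
not label seizure stages).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .core import GridGeometry, MultichannelRecording

__all__ = ["DetectionConfig", "SpikeEvent", "detect_events", "slice_window"]


@dataclass(frozen=True)
class DetectionConfig:
    """Spike-detection parameters (times in ms, threshold in uV).

    ``refractory`` must exceed the cross-array sweep time of one wave so a
    single propagating spike never yields two events; the default 200 ms
    covers a ~70 ms sweep plus a 40 ms waveform.  ``ictal_rate_cutoff`` is
    the spike rate (spikes/s, estimated over ``rate_window_s``) above which
    context is called ictal and the short window used.  ``absolute``
    selects |v| (default) versus positive-polarity-only thresholding.
    """

    threshold: float = 500.0
    window_ictal: float = 100.0
    window_interictal: float = 500.0
    ictal_rate_cutoff: float = 1.0
    refractory: float = 200.0
    rate_window_s: float = 10.0
    absolute: bool = True

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be > 0 uV")
        if self.window_ictal <= 0 or self.window_interictal <= 0:
            raise ValueError("windows must be > 0 ms")
        if self.window_ictal > self.window_interictal:
            raise ValueError("ictal window must not exceed the inter-ictal window")
        if self.refractory <= 0:
            raise ValueError("refractory must be > 0 ms")


@dataclass
class SpikeEvent:
    """One extracted spike window across all channels."""

    event_id: int
    window: tuple[float, float]  # (start s, end s) in recording time
    segment: np.ndarray          # (n_channels, n_window_samples) uV
    context: str                 # "ictal" | "interictal"
    peak_channel: int
    peak_time: float             # s
    fs: float
    geometry: GridGeometry

    @property
    def n_samples(self) -> int:
        return self.segment.shape[1]


def detect_events(rec: MultichannelRecording, cfg: DetectionConfig | None = None
                  ) -> list[SpikeEvent]:
    """Extract one :class:`SpikeEvent` per supra-threshold spike complex.

    The input should already be low-pass filtered (``epileptic_lowpass``
    preset); detection itself is filter-agnostic.  Returned events are
    sorted by time and their windows never overlap (when two candidate
    windows collide, the larger-peak event wins).
    """
    cfg = cfg or DetectionConfig()
    fs = rec.fs
    min_win = int(round(cfg.window_ictal * fs / 1e3))
    if rec.n_samples < min_win:
        raise ValueError(
            f"recording ({rec.n_samples} samples) shorter than one "
            f"{cfg.window_ictal} ms window")

    good = rec.geometry.good_channels()
    traces = rec.data[good]
    detection = np.abs(traces).max(axis=0) if cfg.absolute else traces.max(axis=0)

    distance = max(1, int(round(cfg.refractory * fs / 1e3)))
    peaks, _ = signal.find_peaks(detection, height=cfg.threshold, distance=distance)
    if peaks.size == 0:
        return []

    # Context from the local spike rate in a centred sliding window.
    peak_t = rec.t0 + peaks / fs
    half = cfg.rate_window_s / 2
    rates = np.array([
        np.sum((peak_t >= t - half) & (peak_t <= t + half)) / cfg.rate_window_s
        for t in peak_t
    ])
    contexts = np.where(rates >= cfg.ictal_rate_cutoff, "ictal", "interictal")

    events: list[SpikeEvent] = []
    for idx, ctx in zip(peaks, contexts):
        win_ms = cfg.window_ictal if ctx == "ictal" else cfg.window_interictal
        n_win = int(round(win_ms * fs / 1e3))
        start = idx - n_win // 2
        start = min(max(start, 0), rec.n_samples - n_win)  # keep fully inside
        seg = rec.data[:, start:start + n_win]
        pk_ch = good[int(np.argmax(np.abs(rec.data[good, idx])))]
        events.append(SpikeEvent(
            event_id=-1,
            window=(rec.t0 + start / fs, rec.t0 + (start + n_win) / fs),
            segment=seg.copy(),
            context=str(ctx),
            peak_channel=int(pk_ch),
            peak_time=rec.t0 + idx / fs,
            fs=fs,
            geometry=rec.geometry,
        ))

    # Resolve window overlaps in favour of the larger peak.
    events.sort(key=lambda e: e.peak_time)
    kept: list[SpikeEvent] = []
    for ev in events:
        if kept and ev.window[0] < kept[-1].window[1]:
            prev = kept[-1]
            pv = np.abs(rec.data[good, int(round((prev.peak_time - rec.t0) * fs))]).max()
            cv = np.abs(rec.data[good, int(round((ev.peak_time - rec.t0) * fs))]).max()
            if cv > pv:
                kept[-1] = ev
            continue
        kept.append(ev)
    for i, ev in enumerate(kept):
        ev.event_id = i
    return kept


def slice_window(rec: MultichannelRecording, start_s: float, end_s: float
                 ) -> np.ndarray:
    """Raw segment of the recording over an absolute time window.

    Used to re-cut a detected event's window from a differently filtered
    copy of the same recording (e.g. the high-gamma band for connectivity).
    """
    i0 = int(round((start_s - rec.t0) * rec.fs))
    i1 = int(round((end_s - rec.t0) * rec.fs))
    if i0 < 0 or i1 > rec.n_samples or i1 <= i0:
        raise ValueError(f"window ({start_s}, {end_s}) s outside the recording")
    return rec.data[:, i0:i1].copy()
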