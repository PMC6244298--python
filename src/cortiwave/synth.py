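"""Synthetic micro-ECoG generator with known ground truth.

Every analysis stage in this package is validated against recordings whose
propagation structure is planted by construction.  The generator is
phenomenological (no biophysics): it emulates the statistical features the
analysis relies on —

* globally phase-locked low-amplitude theta oscillations (stationary waves);
* high-amplitude biphasic spike events sweeping the array as plane waves
  (arrival delay linear in position along a direction) or as rotating
  spirals (arrival delay proportional to polar angle about a centre);
* a volume-conduction surrogate: a shared band-limited (1-10 Hz by default)
  random process added identically to all channels;
* per-event high-gamma (80-120 Hz) noise whose cross-channel correlation
  follows a planted community structure that depends on the event label,
  so functional network states co-vary with wave types by construction.

All randomness flows from a single seed through named substreams
(background / events / high-gamma), so each component is independently
reproducible.

Defaults mirror realistic drug-induced-seizure recordings on an 8x8,
500 um pitch array: 2 mV spikes over ~50 uV background, cross-array
delays of tens of milliseconds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .core import GridGeometry, MultichannelRecording

__all__ = [
    "WaveSpec",
    "NoiseSpec",
    "EventSchedule",
    "spike_template",
    "gen_stationary",
    "gen_plane_wave_event",
    "gen_spiral_wave_event",
    "gen_seizure",
    "event_window_ms",
]

#: Arrival-time margin (ms) kept between the window edge and the first/last
#: spike so cross-correlation never sees a truncated template.
EVENT_MARGIN_MS = 30.0


@dataclass(frozen=True)
class WaveSpec:
    """Parameters of one wave pattern.

    ``kind`` selects which fields matter: ``stationary`` uses ``frequency``;
    ``plane`` uses ``speed`` (um/ms) and the unit ``direction`` the wave
    travels along; ``spiral`` uses ``center`` (um), ``angular_speed``
    (rad/ms) and ``chirality``.  ``amplitude`` is the peak voltage in uV and
    ``template_duration`` (ms) the width of the biphasic spike waveform used
    for plane/spiral events.
    """

    kind: str
    amplitude: float = 2000.0
    frequency: float = 7.0
    speed: float = 50.0
    direction: tuple[float, float] = (-1.0, 0.0)
    center: tuple[float, float] = (1750.0, 1750.0)
    angular_speed: float = 0.1
    chirality: str = "cw"
    template_duration: float = 40.0

    def __post_init__(self) -> None:
        if self.kind not in ("stationary", "plane", "spiral"):
            raise ValueError(f"unknown wave kind {self.kind!r}")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be > 0 uV")
        if self.kind == "plane":
            if self.speed <= 0:
                raise ValueError("plane-wave speed must be > 0 um/ms")
            norm = float(np.hypot(*self.direction))
            if not np.isclose(norm, 1.0, atol=1e-6):
                raise ValueError(f"direction must be a unit vector, |d| = {norm:.4g}")
        if self.kind == "spiral":
            if self.angular_speed <= 0:
                raise ValueError("angular_speed must be > 0 rad/ms")
            if self.chirality not in ("cw", "ccw"):
                raise ValueError("chirality must be 'cw' or 'ccw'")

    @classmethod
    def stationary(cls, frequency: float = 7.0, amplitude: float = 100.0) -> "WaveSpec":
        """Globally synchronous oscillation (theta by default, low amplitude)."""
        return cls(kind="stationary", frequency=frequency, amplitude=amplitude)

    @classmethod
    def plane(cls, direction: tuple[float, float] = (-1.0, 0.0), speed: float = 50.0,
              amplitude: float = 2000.0, template_duration: float = 40.0) -> "WaveSpec":
        d = np.asarray(direction, dtype=float)
        d = d / np.hypot(*d)
        return cls(kind="plane", direction=(float(d[0]), float(d[1])), speed=speed,
                   amplitude=amplitude, template_duration=template_duration)

    @classmethod
    def spiral(cls, center: tuple[float, float] = (1750.0, 1750.0),
               angular_speed: float = 0.1, chirality: str = "cw",
               amplitude: float = 2000.0, template_duration: float = 40.0) -> "WaveSpec":
        return cls(kind="spiral", center=center, angular_speed=angular_speed,
                   chirality=chirality, amplitude=amplitude,
                   template_duration=template_duration)


@dataclass(frozen=True)
class NoiseSpec:
    """Additive noise model: per-channel white noise plus a shared
    band-limited common-mode process (the volume-conduction surrogate)."""

    white_sd: float = 50.0
    common_mode_amplitude: float = 50.0
    common_mode_band: tuple[float, float] = (1.0, 10.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.white_sd < 0 or self.common_mode_amplitude < 0:
            raise ValueError("noise amplitudes must be >= 0")

    @classmethod
    def silent(cls, seed: int = 0) -> "NoiseSpec":
        return cls(white_sd=0.0, common_mode_amplitude=0.0, seed=seed)


@dataclass
class EventSchedule:
    """Timed sequence of labelled wave events for :func:`gen_seizure`.

    ``events`` is a list of ``(onset_s, WaveSpec, label)``.  When
    ``hg_block_assignment`` maps a label to a partition of channel indices,
    events with that label additionally receive high-gamma activity whose
    *power* co-fluctuates within each block: every channel carries an
    independent band-limited carrier, and all channels of a block share one
    slow bounded amplitude modulation ``1 + hg_depth * tanh(s(t))``
    (``hg_depth`` in [0, 1); bounded so the burst can never cross the
    spike-detection threshold).  Power
    co-modulation (rather than a shared waveform) is what survives both
    common-average referencing and envelope-based connectivity, so the
    planted community structure is visible to exactly the estimator the
    analysis uses.  ``hg_amplitude`` is the overall RMS in uV,
    ``hg_band`` the carrier band in Hz.
    """

    events: list[tuple[float, WaveSpec, str]]
    hg_block_assignment: dict[str, list[list[int]]] | None = None
    hg_amplitude: float = 50.0
    hg_depth: float = 0.9
    hg_band: tuple[float, float] = (80.0, 120.0)
    hg_mod_cutoff: float = 8.0
    hg_pad_s: float = 0.3
    tail_s: float = 0.5

    def labels(self) -> list[str]:
        return [lab for _, _, lab in self.events]

    @classmethod
    def regular(cls, specs: list[tuple[WaveSpec, str]], start_s: float = 1.0,
                spacing_s: float = 1.2, **kwargs) -> "EventSchedule":
        """Events at ``start_s``, ``start_s + spacing_s``, ... in list order."""
        events = [(start_s + i * spacing_s, spec, lab)
                  for i, (spec, lab) in enumerate(specs)]
        return cls(events=events, **kwargs)


def _substreams(seed: int) -> dict[str, np.random.Generator]:
    """Named, independent random substreams derived from one seed."""
    root = np.random.SeedSequence(seed)
    bg, ev, hg = root.spawn(3)
    return {
        "background": np.random.default_rng(bg),
        "events": np.random.default_rng(ev),
        "hg": np.random.default_rng(hg),
    }


def spike_template(t_ms: np.ndarray, duration_ms: float = 40.0) -> np.ndarray:
    """Unit-amplitude biphasic spike waveform evaluated at times ``t_ms``.

    A half-sine depolarisation over the first 60% of the window followed by
    a rebound of 30% amplitude and opposite sign; zero outside [0, duration].
    The peak sits at 30% of the duration.
    """
    t = np.asarray(t_ms, dtype=float)
    t1 = 0.6 * duration_ms
    out = np.zeros_like(t)
    m1 = (t >= 0) & (t < t1)
    out[m1] = np.sin(np.pi * t[m1] / t1)
    m2 = (t >= t1) & (t <= duration_ms)
    out[m2] = -0.3 * np.sin(np.pi * (t[m2] - t1) / (duration_ms - t1))
    return out


def _common_mode(n_samples: int, fs: float, noise: NoiseSpec,
                 rng: np.random.Generator) -> np.ndarray:
    """Shared band-limited random trace, std scaled to the requested amplitude."""
    if noise.common_mode_amplitude == 0:
        return np.zeros(n_samples)
    lo, hi = noise.common_mode_band
    # pad generously and trim so forward-backward filter edge transients
    # (large for a band reaching down to ~1 Hz) never enter the recording
    pad = int(round(2.0 / lo * fs))
    white = rng.standard_normal(n_samples + 2 * pad)
    sos = signal.butter(4, (lo, hi), btype="bandpass", fs=fs, output="sos")
    cm = signal.sosfiltfilt(sos, white)[pad:pad + n_samples]
    sd = cm.std()
    if sd > 0:
        cm = cm * (noise.common_mode_amplitude / sd)
    return cm


def _background(n_channels: int, n_samples: int, fs: float, noise: NoiseSpec,
                rng: np.random.Generator) -> np.ndarray:
    bg = rng.standard_normal((n_channels, n_samples)) * noise.white_sd \
        if noise.white_sd > 0 else np.zeros((n_channels, n_samples))
    bg += _common_mode(n_samples, fs, noise, rng)[None, :]
    return bg


def gen_stationary(geometry: GridGeometry, fs: float, duration: float,
                   spec: WaveSpec, noise: NoiseSpec) -> MultichannelRecording:
    """Globally synchronous oscillation: every channel carries
    ``amplitude * cos(2 pi f t)`` (identical phase) plus noise."""
    if spec.kind != "stationary":
        raise ValueError("gen_stationary requires a stationary WaveSpec")
    if duration * spec.frequency < 10:
        warnings.warn(
            f"only {duration * spec.frequency:.1f} oscillation periods; "
            "phase estimation may be unreliable", UserWarning)
    rng = _substreams(noise.seed)["background"]
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    osc = spec.amplitude * np.cos(2 * np.pi * spec.frequency * t)
    data = np.broadcast_to(osc, (geometry.n_channels, n)).copy()
    data += _background(geometry.n_channels, n, fs, noise, rng)
    return MultichannelRecording(data=data, fs=fs, geometry=geometry)


def plane_delay_field(geometry: GridGeometry, spec: WaveSpec) -> np.ndarray:
    """True plane-wave arrival delays (ms) per channel: (p . direction)/speed."""
    pos = geometry.positions()
    d = np.asarray(spec.direction, dtype=float)
    return pos @ d / spec.speed


def spiral_fields(geometry: GridGeometry, spec: WaveSpec) -> tuple[np.ndarray, np.ndarray]:
    """True spiral phase (rad, in (-pi, pi]) and arrival offsets (ms).

    The spiral is a pure rotating-phase field: arrival time depends only on
    the polar angle about the centre, with sign set by chirality (cw
    positive in the array frame where y points down).
    """
    pos = geometry.positions()
    rel = pos - np.asarray(spec.center, dtype=float)
    r = np.hypot(rel[:, 0], rel[:, 1])
    if np.any(r < 1e-9):
        ch = int(np.argmin(r))
        raise ValueError(
            f"spiral center coincides with channel {ch}; its angle is undefined")
    theta = np.arctan2(rel[:, 1], rel[:, 0])
    sign = 1.0 if spec.chirality == "cw" else -1.0
    offsets = sign * theta / spec.angular_speed
    return theta, offsets


def event_window_ms(geometry: GridGeometry, spec: WaveSpec) -> float:
    """Window length (ms) for one event: arrival spread + template + margins."""
    if spec.kind == "plane":
        d = plane_delay_field(geometry, spec)
    elif spec.kind == "spiral":
        _, d = spiral_fields(geometry, spec)
    else:
        raise ValueError("event windows are defined for plane/spiral specs")
    return float(d.max() - d.min()) + spec.template_duration + 2 * EVENT_MARGIN_MS


def _render_event(geometry: GridGeometry, fs: float, spec: WaveSpec,
                  arrivals_ms: np.ndarray, n_samples: int) -> np.ndarray:
    """Per-channel template traces with the given arrival times (ms)."""
    t_ms = np.arange(n_samples) / fs * 1e3
    return spec.amplitude * spike_template(
        t_ms[None, :] - arrivals_ms[:, None], spec.template_duration)


def gen_plane_wave_event(geometry: GridGeometry, fs: float, spec: WaveSpec,
                         noise: NoiseSpec) -> tuple[MultichannelRecording, np.ndarray]:
    """One plane-wave spike event plus its true delay field (ms).

    The channel at position ``p`` receives the spike template delayed by
    ``(p . direction) / speed``; the window is sized so the template fully
    crosses the array with a margin on both sides.
    """
    if spec.kind != "plane":
        raise ValueError("gen_plane_wave_event requires a plane WaveSpec")
    delays = plane_delay_field(geometry, spec)
    win_ms = event_window_ms(geometry, spec)
    n = int(round(win_ms * fs / 1e3))
    if n * 1e3 / fs < np.ptp(delays) + spec.template_duration:
        raise ValueError("window too short for the template to cross the array")
    arrivals = EVENT_MARGIN_MS + delays - delays.min()
    data = _render_event(geometry, fs, spec, arrivals, n)
    rng = _substreams(noise.seed)["events"]
    data += _background(geometry.n_channels, n, fs, noise, rng)
    return MultichannelRecording(data=data, fs=fs, geometry=geometry), delays


def gen_spiral_wave_event(geometry: GridGeometry, fs: float, spec: WaveSpec,
                          noise: NoiseSpec) -> tuple[MultichannelRecording, np.ndarray]:
    """One rotating spiral event plus its true phase field (rad).

    Arrival offset is ``+/- theta / angular_speed`` (sign by chirality) where
    ``theta`` is the channel's polar angle about the spiral centre, so the
    arrival-time field winds by one full turn around the centre.
    """
    if spec.kind != "spiral":
        raise ValueError("gen_spiral_wave_event requires a spiral WaveSpec")
    theta, offsets = spiral_fields(geometry, spec)
    win_ms = event_window_ms(geometry, spec)
    n = int(round(win_ms * fs / 1e3))
    arrivals = EVENT_MARGIN_MS + offsets - offsets.min()
    data = _render_event(geometry, fs, spec, arrivals, n)
    rng = _substreams(noise.seed)["events"]
    data += _background(geometry.n_channels, n, fs, noise, rng)
    return MultichannelRecording(data=data, fs=fs, geometry=geometry), theta


def _hg_noise(geometry: GridGeometry, fs: float, n_samples: int,
              blocks: list[list[int]], schedule: EventSchedule,
              rng: np.random.Generator) -> np.ndarray:
    """High-gamma activity whose power co-modulates inside each block.

    Each channel gets an independent carrier (white noise band-passed to
    ``hg_band``); the channels of one block are multiplied by a shared
    slow bounded envelope ``1 + hg_depth * tanh(s(t))`` with ``s`` a
    standardized low-pass (``hg_mod_cutoff`` Hz) process.  Blocks are
    normalized to equal power so the planted structure lives purely in the
    power co-fluctuations.
    """
    if not 0 <= schedule.hg_depth < 1:
        raise ValueError("hg_depth must lie in [0, 1)")
    lo, hi = schedule.hg_band
    if hi >= fs / 2:
        raise ValueError(
            f"sampling rate {fs} Hz too low for the {lo}-{hi} Hz high-gamma band")
    sos = signal.butter(4, (lo, hi), btype="bandpass", fs=fs, output="sos")
    sos_slow = signal.butter(4, schedule.hg_mod_cutoff, btype="lowpass", fs=fs,
                             output="sos")
    out = signal.sosfiltfilt(
        sos, rng.standard_normal((geometry.n_channels, n_samples)), axis=-1)
    for block in blocks:
        s = signal.sosfiltfilt(sos_slow, rng.standard_normal(n_samples))
        sd = s.std()
        if sd > 0:
            s = s / sd
        mod = 1.0 + schedule.hg_depth * np.tanh(s)
        mod /= np.sqrt((mod ** 2).mean())
        out[np.asarray(block, dtype=int)] *= mod
    sd = out.std()
    if sd > 0:
        out *= schedule.hg_amplitude / sd
    return out


def gen_seizure(geometry: GridGeometry, fs: float, schedule: EventSchedule,
                noise: NoiseSpec) -> tuple[MultichannelRecording, list[dict]]:
    """Full seizure recording: background plus scheduled labelled events.

    Returns the recording and a ground-truth list with one dict per event:
    ``event_id``, ``onset_s``, ``true_peak_s`` (time of the earliest channel
    peak), ``window_s`` (event extent), ``label``, ``spec`` and the planted
    high-gamma ``blocks`` (or None).

    Raises if any two event windows overlap.
    """
    events = sorted(schedule.events, key=lambda e: e[0])
    windows = []
    for onset, spec, label in events:
        win_s = event_window_ms(geometry, spec) / 1e3
        windows.append((onset, onset + win_s, spec, label))
    for (s0, e0, *_), (s1, _e1, _sp, lab) in zip(windows, windows[1:]):
        if s1 < e0:
            raise ValueError(
                f"event at {s1:.3f}s (label {lab!r}) overlaps the previous "
                f"event window ending at {e0:.3f}s")

    total_s = (windows[-1][1] if windows else 0.0) + schedule.tail_s
    n = int(round(total_s * fs))
    streams = _substreams(noise.seed)
    data = _background(geometry.n_channels, n, fs, noise, streams["background"])

    truth: list[dict] = []
    for eid, (start, end, spec, label) in enumerate(windows):
        i0 = int(round(start * fs))
        i1 = min(int(round(end * fs)), n)
        n_ev = i1 - i0
        if spec.kind == "plane":
            field = plane_delay_field(geometry, spec)
        else:
            _, field = spiral_fields(geometry, spec)
        arrivals = EVENT_MARGIN_MS + field - field.min()
        data[:, i0:i1] += _render_event(geometry, fs, spec, arrivals, n_ev)
        blocks = None
        if schedule.hg_block_assignment and label in schedule.hg_block_assignment:
            # The network state persists around the spike, not only during
            # the template sweep, so the planted burst is padded to cover
            # the analysis window cut around the event.
            blocks = schedule.hg_block_assignment[label]
            j0 = max(0, i0 - int(round(schedule.hg_pad_s * fs)))
            j1 = min(n, i1 + int(round(schedule.hg_pad_s * fs)))
            data[:, j0:j1] += _hg_noise(geometry, fs, j1 - j0, blocks, schedule,
                                        streams["hg"])
        truth.append({
            "event_id": eid,
            "onset_s": start,
            "true_peak_s": start + (EVENT_MARGIN_MS + 0.3 * spec.template_duration) / 1e3,
            "window_s": (start, end),
            "label": label,
            "spec": spec,
            "true_field": field,
            "blocks": blocks,
        })
    rec = MultichannelRecording(data=data, fs=fs, geometry=geometry)
    return rec, truth
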