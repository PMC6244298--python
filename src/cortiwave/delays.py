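"""Pairwise time-delay estimation by normalized cross-correlation.

For each spike event the lag between two channels is the integer-sample
shift that maximizes their Pearson-normalized cross-correlation (computed
over the overlapping samples at each candidate lag).  Collecting all pairs
gives an antisymmetric delay matrix; one row of it arranged on the grid is
a delay map (the propagation portrait of the event); the column against a
fixed reference channel is the feature vector used for clustering.

Conventions:

* ``d[i][j]`` is the lag of channel j **relative to** channel i in ms —
  positive when j activates later than i — so ``d`` is antisymmetric with a
  zero diagonal by construction (each unordered pair is computed once).
* Ties at the correlation maximum break toward the smallest ``|lag|``,
  then toward the negative lag: deterministic and documented.
* Normalization is Pearson-style so per-channel amplitude differences do
  not bias the lag choice.
* Lags are integer-sample by default (parabolic sub-sample refinement is
  available via ``refine=True``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .core import GridGeometry, GridMap, map_to_grid
from .events import SpikeEvent

__all__ = [
    "DelayMatrix",
    "normalized_xcorr",
    "xcorr_delay",
    "delay_matrix",
    "peak_time_delay",
    "delay_map",
    "delay_features",
]


def normalized_xcorr(a: np.ndarray, b: np.ndarray, max_lag: int
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Pearson correlation of ``a[t]`` with ``b[t + lag]`` at every integer
    lag in ``[-max_lag, max_lag]``.

    At each lag the correlation is computed over the overlapping samples
    only.  Lags whose overlap has (numerically) zero variance get ``-inf``
    so they can never win the argmax.

    Returns ``(lags, r)``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("signals must be 1-D and of equal length")
    n = a.size
    if max_lag < 0 or max_lag >= n:
        raise ValueError(f"max_lag {max_lag} out of range for length {n}")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero-variance input: correlation undefined")

    lags = np.arange(-max_lag, max_lag + 1)
    full = signal.correlate(b, a, mode="full")  # index n-1+lag holds dot(lag)
    dots = full[n - 1 + lags]

    ca = np.concatenate(([0.0], np.cumsum(a)))
    ca2 = np.concatenate(([0.0], np.cumsum(a * a)))
    cb = np.concatenate(([0.0], np.cumsum(b)))
    cb2 = np.concatenate(([0.0], np.cumsum(b * b)))

    n_ov = (n - np.abs(lags)).astype(float)
    pos = lags >= 0
    tau = np.abs(lags)
    # a-side overlap: a[:n-lag] for lag>=0, a[lag:] for lag<0 (and mirrored for b)
    sa = np.where(pos, ca[n - tau], ca[n] - ca[tau])
    sa2 = np.where(pos, ca2[n - tau], ca2[n] - ca2[tau])
    sb = np.where(pos, cb[n] - cb[tau], cb[n - tau])
    sb2 = np.where(pos, cb2[n] - cb2[tau], cb2[n - tau])

    cov = dots - sa * sb / n_ov
    var_a = np.maximum(sa2 - sa * sa / n_ov, 0.0)
    var_b = np.maximum(sb2 - sb * sb / n_ov, 0.0)
    denom = np.sqrt(var_a * var_b)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, cov / np.maximum(denom, 1e-300), -np.inf)
    np.clip(r, -1.0, 1.0, out=r)
    r[denom == 0] = -np.inf
    return lags, r


def _argmax_tiebreak(lags: np.ndarray, r: np.ndarray) -> int:
    """Index of the max of ``r``; ties -> smallest |lag|, then negative."""
    order = np.lexsort((lags, np.abs(lags)))
    best = order[int(np.argmax(r[order]))]
    return int(best)


def xcorr_delay(a: np.ndarray, b: np.ndarray, max_lag_ms: float, fs: float,
                refine: bool = False) -> tuple[float, float]:
    """Delay of ``b`` relative to ``a`` (ms) and the peak correlation.

    Positive when ``b`` lags ``a``.  With ``refine=True`` the integer-sample
    argmax is polished by parabolic interpolation of the correlation peak.
    """
    max_lag = int(round(max_lag_ms * fs / 1e3))
    n = np.asarray(a).size
    if max_lag >= n / 2:
        raise ValueError(
            f"max_lag {max_lag_ms} ms is not below half the window "
            f"({n / fs * 500:.1f} ms)")
    lags, r = normalized_xcorr(a, b, max_lag)
    i = _argmax_tiebreak(lags, r)
    lag = float(lags[i])
    if refine and 0 < i < lags.size - 1 and np.isfinite(r[i - 1]) and np.isfinite(r[i + 1]):
        y0, y1, y2 = r[i - 1], r[i], r[i + 1]
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            lag += 0.5 * (y0 - y2) / denom
    return lag * 1e3 / fs, float(r[i])


@dataclass
class DelayMatrix:
    """Antisymmetric pairwise lag matrix (ms) for one event.

    ``d[i][j]`` = lag of j relative to i; ``quality[i][j]`` = the peak
    correlation.  Rows/columns of bad channels are NaN (diagonal stays 0).
    """

    d: np.ndarray
    quality: np.ndarray
    max_lag: float
    geometry: GridGeometry
    event_id: int = -1


def _default_max_lag_ms(ev: SpikeEvent) -> float:
    """Half the event window, just under the estimator's validity bound."""
    return (int(np.ceil(ev.n_samples / 2)) - 1) / ev.fs * 1e3


def delay_matrix(ev: SpikeEvent, max_lag_ms: float | None = None,
                 refine: bool = False) -> DelayMatrix:
    """All-pairs cross-correlation delays for one spike event.

    Antisymmetry is exact because each unordered pair is estimated once.
    A zero-variance channel aborts with the offending pair named.
    """
    if max_lag_ms is None:
        max_lag_ms = _default_max_lag_ms(ev)
    good = ev.geometry.good_channels()
    n_ch = ev.geometry.n_channels
    d = np.full((n_ch, n_ch), np.nan)
    q = np.full((n_ch, n_ch), np.nan)
    np.fill_diagonal(d, 0.0)
    np.fill_diagonal(q, 1.0)
    for ii, i in enumerate(good):
        for j in good[ii + 1:]:
            try:
                lag, corr = xcorr_delay(ev.segment[i], ev.segment[j],
                                        max_lag_ms, ev.fs, refine=refine)
            except ValueError as exc:
                raise ValueError(f"channel pair ({i}, {j}): {exc}") from exc
            d[i, j], d[j, i] = lag, -lag
            q[i, j] = q[j, i] = corr
    return DelayMatrix(d=d, quality=q, max_lag=max_lag_ms,
                       geometry=ev.geometry, event_id=ev.event_id)


def peak_time_delay(ev: SpikeEvent) -> DelayMatrix:
    """Delay matrix from per-channel global peak times (|v| argmax).

    A cheap cross-check for the cross-correlation estimator:
    ``d[i][j] = peak_time_j - peak_time_i``, exactly antisymmetric.
    """
    good = ev.geometry.good_channels()
    n_ch = ev.geometry.n_channels
    seg = ev.segment
    flat = [int(k) for k in good if seg[k].std() == 0]
    if flat:
        raise ValueError(f"flat channel(s) {flat}: peak time undefined")
    peaks_ms = np.full(n_ch, np.nan)
    peaks_ms[good] = np.argmax(np.abs(seg[good]), axis=1) * 1e3 / ev.fs
    d = peaks_ms[None, :] - peaks_ms[:, None]
    d[np.isnan(d)] = np.nan
    np.fill_diagonal(d, 0.0)
    q = np.full((n_ch, n_ch), np.nan)
    q[np.ix_(good, good)] = 1.0
    return DelayMatrix(d=d, quality=q, max_lag=ev.n_samples / ev.fs * 1e3,
                       geometry=ev.geometry, event_id=ev.event_id)


def delay_map(dm: DelayMatrix, reference: int) -> GridMap:
    """Row ``reference`` of the delay matrix arranged on the electrode grid.

    The map shows, per channel, how much later (positive, ms) it activates
    than the reference; the reference cell is exactly 0.
    """
    if reference in dm.geometry.bad_channels:
        raise ValueError(f"reference channel {reference} is flagged bad")
    return map_to_grid(dm.d[reference], dm.geometry, kind="delay",
                       label=f"event {dm.event_id} ref {reference}")


def delay_features(events: list[SpikeEvent], reference: int | None = None,
                   max_lag_ms: float | None = None, refine: bool = False
                   ) -> tuple[np.ndarray, np.ndarray, int]:
    """Per-event delay feature vectors: delays of every good channel
    relative to one reference channel (default: the first good channel).

    Only the reference column of the delay matrix is computed — it already
    separates the propagation types, and the full matrix is redundant by
    antisymmetry.  Returns ``(features [n_events x n_good], good_channels,
    reference)``; the reference entry of every row is 0.
    """
    if not events:
        raise ValueError("need at least one event")
    geometry = events[0].geometry
    good = geometry.good_channels()
    if reference is None:
        reference = int(good[0])
    if reference in geometry.bad_channels:
        raise ValueError(f"reference channel {reference} is flagged bad")
    feats = np.zeros((len(events), good.size))
    for e, ev in enumerate(events):
        ml = max_lag_ms if max_lag_ms is not None else _default_max_lag_ms(ev)
        ref_sig = ev.segment[reference]
        for c, j in enumerate(good):
            if j == reference:
                continue
            try:
                lag, _ = xcorr_delay(ref_sig, ev.segment[j], ml, ev.fs, refine=refine)
            except ValueError as exc:
                raise ValueError(
                    f"event {ev.event_id}, channel pair ({reference}, {j}): {exc}"
                ) from exc
            feats[e, c] = lag
    return feats, good, reference
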