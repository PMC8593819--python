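"""Respiratory-signal extraction and the baseline hand-crafted features.

The predominant coherent motion in a sleeping-subject video is breathing.
The baseline approach recovers it by principal component analysis of the
tracked-point trajectories over 30-second sliding windows with a 1-second
stride: within each window the first principal component of the centered
(time x 2K coordinates) matrix is the breathing displacement, up to sign.
Window scores are sign-aligned on their overlap and stitched into one
1 Hz :class:`RespiratorySignal`.

From that signal, three features are computed per 10-second analysis
window for the baseline event classifier:

* ``respiratory_rate`` -- the frequency of maximum FFT energy within the
  physiological band (default 0.1-1.0 Hz, capped at Nyquist);
* ``movement_power`` -- mean of squared respiratory displacement, which
  collapses during apneas and hypopneas;
* ``total_displacement`` -- summed raw tracked-point motion (before PCA),
  which spikes during arousals and gross movements.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .events import EventInterval
from .motion import PointTrajectories, total_displacement

#: Default PCA window and stride, seconds.
PCA_WINDOW_S = 30.0
PCA_STRIDE_S = 1.0
#: Default feature analysis window, seconds.
FEATURE_WINDOW_S = 10.0
#: Physiological breathing band searched for the spectral peak, Hz.
RESPIRATORY_BAND_HZ = (0.1, 1.0)


@dataclass
class RespiratorySignal:
    """Stitched 1 Hz breathing-displacement series.

    Sample ``i`` is the displacement at second ``i``, taken from the
    30-second PCA window whose center lies nearest to ``i``.  Length is
    ``max(0, floor(T_seconds) - window_s + 1)``.
    """

    values: np.ndarray
    window_s: float = PCA_WINDOW_S
    stride_s: float = PCA_STRIDE_S
    sample_rate: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise ValueError("respiratory signal must be finite")

    def __len__(self) -> int:
        return self.values.shape[0]


def _window_values(signal, window_s: Optional[float], sample_rate: float):
    values = signal.values if isinstance(signal, RespiratorySignal) else np.asarray(signal, dtype=float)
    rate = signal.sample_rate if isinstance(signal, RespiratorySignal) else sample_rate
    if window_s is not None:
        n = int(round(window_s * rate))
        values = values[:n]
    return values, rate


def extract_respiratory(
    traj: PointTrajectories,
    window_s: float = PCA_WINDOW_S,
    stride_s: float = PCA_STRIDE_S,
) -> RespiratorySignal:
    """First-principal-component breathing signal from point trajectories.

    Per window the PC1 score series is obtained from the eigendecomposition
    of the (time x time) Gram matrix of the centered trajectory matrix --
    algebraically the same PC1 as an SVD of the (time x 2K) matrix but far
    cheaper for K = 768 points.  The PCA sign is undefined, so each
    window's scores are flipped to correlate positively with the previous
    window on their overlap; the first window's sign is arbitrary.
    """
    t_count = traj.n_samples
    rate = traj.rate
    w_samp = int(round(window_s * rate))
    s_samp = max(1, int(round(stride_s * rate)))
    if t_count < w_samp:
        warnings.warn("trajectory shorter than one PCA window; empty signal")
        return RespiratorySignal(np.empty(0), window_s, stride_s)
    n_windows = (t_count - w_samp) // s_samp + 1
    x_full = np.ascontiguousarray(
        traj.positions.transpose(1, 0, 2).reshape(t_count, -1), dtype=np.float64
    )
    half = int(round(window_s / 2.0))  # seconds from window start to center

    def pc1_scores(xw: np.ndarray) -> np.ndarray:
        xc = xw - xw.mean(axis=0)
        gram = xc @ xc.T
        evals, evecs = np.linalg.eigh(gram)
        return evecs[:, -1] * np.sqrt(max(evals[-1], 0.0))

    # Stitching rule: the value at second i comes from the window centered
    # nearest i (window w = clip(i - half, 0, n_windows - 1)), evaluated at
    # second i.  Walk windows once; each window's scores are sign-aligned
    # against the predecessor on the (w_samp - s_samp)-sample overlap and
    # offset-chained to it (per-window PCA centering subtracts the window's
    # own breathing mean, which would otherwise leak a spurious DC level
    # into low-motion sections such as apneas).  The chained series equals
    # the true displacement up to one global constant, removed at the end.
    stitched = np.empty(n_windows)
    prev = None
    first_scores = None
    for w in range(n_windows):
        sc = pc1_scores(x_full[w * s_samp : w * s_samp + w_samp])
        if prev is not None:
            if prev[s_samp:] @ sc[:-s_samp] < 0:
                sc = -sc
            rel = prev[s_samp:] - sc[:-s_samp]
            # When consecutive windows track the same motion mode their
            # overlap differs by a constant; a large spread means the mode
            # changed (e.g. a gross body movement entered the window), in
            # which case the chain re-anchors at the window's own mean
            # instead of propagating a corrupted level.
            if rel.std() <= 0.5 * np.sqrt(np.mean(sc ** 2)) + 1e-12:
                sc = sc + rel.mean()
        prev = sc
        if w == 0:
            first_scores = sc
        i = w + half  # the second this window's center sample represents
        if i < n_windows:
            stitched[i] = sc[int(round(half * rate))]
    for i in range(min(half, n_windows)):
        stitched[i] = first_scores[int(round(i * rate))]
    stitched -= stitched.mean()
    return RespiratorySignal(stitched, window_s, stride_s)


def respiratory_rate(
    signal,
    window_s: Optional[float] = FEATURE_WINDOW_S,
    band=RESPIRATORY_BAND_HZ,
    sample_rate: float = 1.0,
) -> float:
    """Frequency of maximum spectral energy within the breathing band, Hz.

    Computed by FFT of the (de-meaned) window.  An all-zero window has no
    defined rate and returns NaN, which downstream consumers treat as
    missing rather than as 0 Hz.
    """
    values, rate = _window_values(signal, window_s, sample_rate)
    if values.size < 4:
        raise ValueError("rate estimation needs at least 4 samples")
    values = values - values.mean()
    if float(np.max(np.abs(values))) < 1e-12:
        return float("nan")
    spectrum = np.abs(np.fft.rfft(values)) ** 2
    freqs = np.fft.rfftfreq(values.size, d=1.0 / rate)
    lo, hi = band
    hi = min(hi, rate / 2.0)
    sel = np.flatnonzero((freqs >= lo - 1e-12) & (freqs <= hi + 1e-12))
    if sel.size == 0:
        return float("nan")
    return float(freqs[sel[np.argmax(spectrum[sel])]])


def movement_power(signal, window_s: Optional[float] = FEATURE_WINDOW_S,
                   sample_rate: float = 1.0) -> float:
    """Mean of squared respiratory displacement over the window, pixels^2."""
    values, _ = _window_values(signal, window_s, sample_rate)
    if values.size == 0:
        raise ValueError("empty window")
    return float(np.mean(values ** 2))


def compute_baseline_features(
    traj: PointTrajectories,
    signal: Optional[RespiratorySignal] = None,
    annotations: Sequence[EventInterval] = (),
    window_s: float = FEATURE_WINDOW_S,
    stride_s: float = 1.0,
    band=RESPIRATORY_BAND_HZ,
) -> pd.DataFrame:
    """Per-window baseline feature table.

    One row per ``window_s``-second analysis window at ``stride_s`` stride:
    ``window_start_s, respiratory_rate, movement_power, total_displacement``
    and, when annotations are given, a binary ``label`` that is 1 when at
    least half of the window overlaps an annotated event.
    """
    if signal is None:
        signal = extract_respiratory(traj)
    values = signal.values
    w = int(round(window_s * signal.sample_rate))
    stride = max(1, int(round(stride_s * signal.sample_rate)))
    if values.size < w:
        return pd.DataFrame(
            columns=["window_start_s", "respiratory_rate", "movement_power",
                     "total_displacement", "label"]
        )
    windows = np.lib.stride_tricks.sliding_window_view(values, w)[::stride]
    starts = np.arange(windows.shape[0]) * stride / signal.sample_rate

    demeaned = windows - windows.mean(axis=1, keepdims=True)
    spectra = np.abs(np.fft.rfft(demeaned, axis=1)) ** 2
    freqs = np.fft.rfftfreq(w, d=1.0 / signal.sample_rate)
    lo, hi = band[0], min(band[1], signal.sample_rate / 2.0)
    sel = np.flatnonzero((freqs >= lo - 1e-12) & (freqs <= hi + 1e-12))
    rates = freqs[sel[np.argmax(spectra[:, sel], axis=1)]]
    undefined = np.max(np.abs(demeaned), axis=1) < 1e-12
    rates = np.where(undefined, np.nan, rates)

    power = (windows ** 2).mean(axis=1)

    disp_1s = total_displacement(traj, window_s=1.0)
    n_disp = disp_1s.shape[0]
    disp = np.array(
        [
            disp_1s[int(s) : min(int(s) + int(window_s), n_disp)].sum()
            for s in starts
        ]
    )

    df = pd.DataFrame(
        {
            "window_start_s": starts,
            "respiratory_rate": rates,
            "movement_power": power,
            "total_displacement": disp,
        }
    )
    if annotations:
        overlap = np.zeros(len(starts))
        for ev in annotations:
            overlap += np.maximum(
                0.0,
                np.minimum(ev.end_s, starts + window_s) - np.maximum(ev.start_s, starts),
            )
        df["label"] = (overlap >= window_s / 2.0).astype(int)
    return df
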