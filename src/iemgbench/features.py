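"""Sliding-window segmentation and time-domain EMG features.

Six features per channel — mean absolute value (MAV), waveform length (WL),
zero crossings (ZC), slope sign changes (SSC), Willison amplitude (WAMP) and
cardinality (CARD) — computed on overlapping 200 ms windows with a 50 ms
increment over the central steady-state 4 s of each 6 s contraction, giving
an 18-element vector (6 features x 3 channels, channel-major) per window.

The four threshold features take a threshold ``epsilon``; by default it is
resolved per window and channel as a fraction of the window RMS
(``epsilon_mode="relative"``), which keeps behaviour stable under the
simulator's arbitrary amplitude units.  An absolute mode is available for
reproducibility tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

try:  # compiled kernel for the per-window hot path (closed-loop decoding)
    import numba

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional accelerator
    _HAVE_NUMBA = False

FEATURE_NAMES = ("mav", "wl", "zc", "ssc", "wamp", "card")


def feature_column_names(n_channels: int = 3) -> list[str]:
    """Channel-major feature column names, e.g. ``ch1_mav ... ch3_card``."""
    return [f"ch{c + 1}_{f}" for c in range(n_channels) for f in FEATURE_NAMES]


@dataclass
class WindowingConfig:
    window_len: float = 0.200
    increment: float = 0.050
    steady_state_len: float = 4.0
    epsilon_mode: str = "relative"  # or "absolute"
    epsilon_value: float = 0.01

    def __post_init__(self):
        if not 0 < self.increment <= self.window_len:
            raise ValueError("require 0 < increment <= window_len")
        if self.steady_state_len < self.window_len:
            raise ValueError("steady_state_len must be >= window_len")
        if self.epsilon_mode not in ("relative", "absolute"):
            raise ValueError("epsilon_mode must be 'relative' or 'absolute'")
        if self.epsilon_value < 0:
            raise ValueError("epsilon_value must be >= 0")


@dataclass
class FeatureVector:
    """18-element feature vector for one window, with provenance metadata."""

    values: np.ndarray
    label: str | None = None
    day: int | None = None
    session: object = None
    repetition: int | None = None
    window_index: int | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be 1-D")


# ---------------------------------------------------------------------------
# Single-channel features
# ---------------------------------------------------------------------------


def _check_window(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("feature input must be a nonempty 1-D window")
    return x


def mav(x) -> float:
    """Mean absolute value: (1/N) * sum |x_n|."""
    return float(np.mean(np.abs(_check_window(x))))


def wl(x) -> float:
    """Waveform length: sum |x_n - x_{n+1}|."""
    return float(np.sum(np.abs(np.diff(_check_window(x)))))


def zc(x, epsilon: float) -> int:
    """Zero crossings: sign changes whose step also exceeds ``epsilon``."""
    x = _check_window(x)
    d = np.diff(x)
    return int(np.count_nonzero((x[:-1] * x[1:] < 0) & (np.abs(d) > epsilon)))


def ssc(x, epsilon: float) -> int:
    """Slope sign changes: (x_n - x_{n-1}) * (x_n - x_{n+1}) > epsilon."""
    x = _check_window(x)
    left = x[1:-1] - x[:-2]
    right = x[1:-1] - x[2:]
    return int(np.count_nonzero(left * right > epsilon))


def wamp(x, epsilon: float) -> int:
    """Willison amplitude: steps with |x_n - x_{n+1}| > epsilon."""
    x = _check_window(x)
    return int(np.count_nonzero(np.abs(np.diff(x)) > epsilon))


def card(x, epsilon: float) -> int:
    """Cardinality: adjacent differences of the sorted window above epsilon."""
    x = np.sort(_check_window(x))
    return int(np.count_nonzero(np.diff(x) > epsilon))


def resolve_epsilon(x: np.ndarray, cfg: WindowingConfig) -> float:
    """Threshold for one single-channel window under ``cfg``'s epsilon mode."""
    if cfg.epsilon_mode == "absolute":
        return cfg.epsilon_value
    return cfg.epsilon_value * float(np.sqrt(np.mean(np.asarray(x, dtype=float) ** 2)))


def channel_features(x, cfg: WindowingConfig) -> np.ndarray:
    """The six features of one single-channel window, in canonical order."""
    eps = resolve_epsilon(x, cfg)
    return np.array(
        [mav(x), wl(x), zc(x, eps), ssc(x, eps), wamp(x, eps), card(x, eps)],
        dtype=float,
    )


if _HAVE_NUMBA:

    @numba.njit(cache=False, fastmath=False)
    def _features_kernel(w, relative, eps_value):  # pragma: no cover
        n, c = w.shape
        out = np.empty(c * 6)
        for ch in range(c):
            if relative:
                s2 = 0.0
                for i in range(n):
                    s2 += w[i, ch] * w[i, ch]
                e = eps_value * np.sqrt(s2 / n)
            else:
                e = eps_value
            sabs = abs(w[0, ch])
            wl_ = 0.0
            zc_ = 0
            wamp_ = 0
            for i in range(n - 1):
                xi = w[i, ch]
                xj = w[i + 1, ch]
                sabs += abs(xj)
                ad = abs(xj - xi)
                wl_ += ad
                if ad > e:
                    wamp_ += 1
                    if xi * xj < 0:
                        zc_ += 1
            ssc_ = 0
            for i in range(1, n - 1):
                if (w[i, ch] - w[i - 1, ch]) * (w[i, ch] - w[i + 1, ch]) > e:
                    ssc_ += 1
            y = np.sort(w[:, ch].copy())
            card_ = 0
            for i in range(n - 1):
                if y[i + 1] - y[i] > e:
                    card_ += 1
            base = ch * 6
            out[base] = sabs / n
            out[base + 1] = wl_
            out[base + 2] = zc_
            out[base + 3] = ssc_
            out[base + 4] = wamp_
            out[base + 5] = card_
        return out


def window_features(window: np.ndarray, cfg: WindowingConfig) -> np.ndarray:
    """Channel-major feature vector (6 * n_channels) for one window.

    Per-feature semantics are identical to the single-channel functions
    above (which serve as the reference path); a compiled kernel is used
    when numba is available since this runs at every closed-loop tick.
    """
    w = np.asarray(window, dtype=float)
    if w.ndim != 2 or w.shape[0] < 2:
        raise ValueError("window must be 2-D (time x channel) with >= 2 samples")
    if _HAVE_NUMBA:
        return _features_kernel(
            np.ascontiguousarray(w), cfg.epsilon_mode == "relative", cfg.epsilon_value
        )
    if cfg.epsilon_mode == "absolute":
        eps = np.full(w.shape[1], float(cfg.epsilon_value))
    else:
        eps = cfg.epsilon_value * np.sqrt(np.mean(w * w, axis=0))
    d = np.diff(w, axis=0)
    absd = np.abs(d)
    out = np.empty((w.shape[1], len(FEATURE_NAMES)))
    out[:, 0] = np.mean(np.abs(w), axis=0)  # MAV
    out[:, 1] = absd.sum(axis=0)  # WL
    out[:, 2] = ((w[:-1] * w[1:] < 0) & (absd > eps)).sum(axis=0)  # ZC
    out[:, 3] = ((w[1:-1] - w[:-2]) * (w[1:-1] - w[2:]) > eps).sum(axis=0)  # SSC
    out[:, 4] = (absd > eps).sum(axis=0)  # WAMP
    out[:, 5] = (np.diff(np.sort(w, axis=0), axis=0) > eps).sum(axis=0)  # CARD
    return out.ravel()


# ---------------------------------------------------------------------------
# Segmentation and extraction
# ---------------------------------------------------------------------------


def segment_windows(rec, cfg: WindowingConfig) -> list[np.ndarray]:
    """Overlapping windows covering the central steady-state segment.

    All lengths are converted to integer sample counts before indexing, so
    the window count is exactly ``(ss - w) // inc + 1``.
    """
    w = int(round(cfg.window_len * rec.fs))
    inc = int(round(cfg.increment * rec.fs))
    ss = int(round(cfg.steady_state_len * rec.fs))
    n = rec.samples.shape[0]
    if ss > n:
        raise ValueError(
            f"recording of {n} samples is shorter than steady_state_len ({ss} samples)"
        )
    start = (n - ss) // 2
    count = (ss - w) // inc + 1
    return [
        rec.samples[start + i * inc : start + i * inc + w] for i in range(count)
    ]


def extract_features(rec, cfg: WindowingConfig) -> list[FeatureVector]:
    """One channel-major feature vector per window of the recording."""
    return [
        FeatureVector(
            values=window_features(win, cfg),
            label=rec.label,
            day=rec.day,
            session=rec.session,
            repetition=rec.repetition,
            window_index=i,
        )
        for i, win in enumerate(segment_windows(rec, cfg))
    ]


def feature_table(recordings: Iterable, cfg: WindowingConfig) -> pd.DataFrame:
    """Tidy feature table for a set of recordings.

    Columns: the 18 feature names plus label/day/session/repetition/
    window_index.
    """
    rows = []
    meta = []
    n_channels = None
    for rec in recordings:
        n_channels = rec.samples.shape[1]
        for fv in extract_features(rec, cfg):
            rows.append(fv.values)
            meta.append((fv.label, fv.day, fv.session, fv.repetition, fv.window_index))
    if not rows:
        raise ValueError("no recordings supplied")
    df = pd.DataFrame(np.vstack(rows), columns=feature_column_names(n_channels))
    df[["label", "day", "session", "repetition", "window_index"]] = pd.DataFrame(
        meta, index=df.index
    )
    return df


def feature_matrix(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Split a feature table into ``(X, labels)`` arrays."""
    cols = [c for c in table.columns if c.startswith("ch")]
    return table[cols].to_numpy(dtype=float), table["label"].to_numpy()
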