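"""Multiday intramuscular EMG simulator.

Generates class-labelled, band-limited (100–900 Hz) three-channel iEMG at
2 kHz with controllable day-to-day and session-to-session nonstationarity,
and provides a streaming "simulated user" that emits EMG windows during
closed-loop target-acquisition testing.

Signal model
------------
Each channel of a contraction is zero-mean Gaussian noise, recoloured by a
small class-specific first-order autoregressive "tilt" (different motions
recruit different motor-unit pools, whose spectra differ slightly), shaped
by a Butterworth band-pass filter to the 100–900 Hz acquisition passband,
and scaled so that its RMS equals ``gain * sqrt(a**2 + noise_floor**2)``,
where ``a`` is the activation of that channel for the motion class and
``gain`` is the drift state's channel gain.  Amplitude pattern across the
three channels plus the spectral tilt are the only class-identifying
structure — which is exactly what the downstream time-domain features
consume; motor-unit microstructure is deliberately not modelled.

Nonstationarity
---------------
Fine-wire electrodes migrate and tissue state changes between sessions and
days.  This is emulated by multiplicative drift on channel gains and on the
activation pattern, each with an independent per-day (or per-session)
fluctuation component and a cumulative random-walk component — see
:class:`DriftConfig` — plus i.i.d. log-normal per-repetition jitter
emulating contraction-level variability between repeated 6 s contractions.

Every generated artifact is a pure function of ``(config.seed, metadata)``;
regenerating any recording is bit-identical.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

#: Motion class vocabulary, in canonical order.  Four active motions plus rest.
MOTION_CLASSES: tuple[str, ...] = (
    "wrist_extension",
    "wrist_flexion",
    "hand_open",
    "hand_close",
    "rest",
)
REST = "rest"
ACTIVE_CLASSES: tuple[str, ...] = MOTION_CLASSES[:4]

#: Session label used for the calibration (training-data) recordings of a day.
CALIBRATION = "calibration"

# Default class x channel activation pattern (arbitrary units).  Channels map
# to extensor digitorum, extensor carpi radialis longus and flexor digitorum
# superficialis; each motion preferentially recruits its agonist with partial
# co-activation, so classes are separable but not trivially so.
DEFAULT_ACTIVATION = np.array(
    [
        [0.60, 1.00, 0.10],  # wrist extension: ECRL dominant
        [0.10, 0.20, 1.00],  # wrist flexion: FDS dominant
        [0.95, 0.60, 0.12],  # hand open: ED dominant
        [0.22, 0.15, 0.88],  # hand close: FDS + finger extensor coactivation
        [0.00, 0.00, 0.00],  # rest
    ]
)


def stream_rng(seed: int, *parts) -> np.random.Generator:
    """Deterministic random generator for one artifact.

    The entropy pool is ``[seed, hash(part), ...]`` where string parts are
    hashed with CRC-32, so any subset of the simulated data set can be
    regenerated independently of generation order.
    """
    entropy = [int(seed) & 0x7FFFFFFF]
    for part in parts:
        if isinstance(part, str):
            entropy.append(zlib.crc32(part.encode("utf-8")))
        else:
            entropy.append(int(part) & 0xFFFFFFFF)
    return np.random.default_rng(np.random.SeedSequence(entropy))


def _session_code(session) -> int:
    return 0 if session == CALIBRATION else int(session)


@dataclass(frozen=True)
class DriftConfig:
    """Stds of the drift components on log-amplitude and channel mixing.

    Two temporal structures, each with three spatial components:

    * fluctuation (``*_std``): an independent offset drawn per day (or per
      session) around the subject baseline — tissue state, bandaging,
      contraction posture;
    * random walk (``walk_*_std``): steps that accumulate over days (or over
      the sessions of a day) — electrode migration — so the signal
      distribution also moves systematically further away as the time gap
      grows.

    Spatially, ``common_amplitude_std`` scales all channels together
    (interface impedance / gain; preserves the between-channel pattern that
    identifies a motion), ``amplitude_std`` is per-channel, and
    ``mixing_std`` perturbs the class x channel activation matrix with
    cross-channel terms (pick-up volume shifts toward neighbouring muscles).
    """

    amplitude_std: float = 0.0
    common_amplitude_std: float = 0.0
    mixing_std: float = 0.0
    walk_amplitude_std: float = 0.0
    walk_common_amplitude_std: float = 0.0
    walk_mixing_std: float = 0.0

    def __post_init__(self):
        if min(
            self.amplitude_std,
            self.common_amplitude_std,
            self.mixing_std,
            self.walk_amplitude_std,
            self.walk_common_amplitude_std,
            self.walk_mixing_std,
        ) < 0:
            raise ValueError("drift standard deviations must be >= 0")

    @property
    def any_drift(self) -> bool:
        return (
            max(
                self.amplitude_std,
                self.common_amplitude_std,
                self.mixing_std,
                self.walk_amplitude_std,
                self.walk_common_amplitude_std,
                self.walk_mixing_std,
            )
            > 0
        )


@dataclass
class SimConfig:
    """Parameters of the synthetic recording setup and its nonstationarity.

    Defaults encode the recording constants of the emulated protocol (three
    channels, 2 kHz sampling, 100–900 Hz passband, five motion classes) and a
    drift level at which a previous-day classifier degrades appreciably while
    a same-day classifier stays accurate.
    """

    n_channels: int = 3
    fs: float = 2000.0
    band: tuple[float, float] = (100.0, 900.0)
    classes: tuple[str, ...] = MOTION_CLASSES
    activation: np.ndarray = field(default_factory=lambda: DEFAULT_ACTIVATION.copy())
    day_drift: DriftConfig = field(
        default_factory=lambda: DriftConfig(
            amplitude_std=0.08,
            common_amplitude_std=0.45,
            mixing_std=0.03,
            walk_amplitude_std=0.05,
            walk_common_amplitude_std=0.05,
            walk_mixing_std=0.02,
        )
    )
    session_drift: DriftConfig = field(
        default_factory=lambda: DriftConfig(
            walk_amplitude_std=0.05,
            walk_common_amplitude_std=0.15,
            walk_mixing_std=0.01,
        )
    )
    repetition_jitter_std: float = 0.15
    session_gain_trend: float = -0.12
    noise_floor: float = 0.10
    spectral_tilt: tuple[float, ...] = (0.08, -0.15, -0.08, 0.15, 0.0)
    seed: int = 0

    def __post_init__(self):
        self.activation = np.asarray(self.activation, dtype=float)
        self.classes = tuple(self.classes)
        if self.activation.shape != (len(self.classes), self.n_channels):
            raise ValueError(
                f"activation must have shape {(len(self.classes), self.n_channels)}, "
                f"got {self.activation.shape}"
            )
        if np.any(self.activation < 0):
            raise ValueError("activation matrix must be nonnegative")
        if not 0 < self.band[0] < self.band[1]:
            raise ValueError("band must satisfy 0 < low < high")
        if self.band[1] >= self.fs / 2:
            raise ValueError("band upper edge must be below the Nyquist frequency")
        if self.noise_floor < 0 or self.repetition_jitter_std < 0:
            raise ValueError("noise_floor and repetition_jitter_std must be >= 0")
        self.spectral_tilt = tuple(float(t) for t in self.spectral_tilt)
        if len(self.spectral_tilt) != len(self.classes):
            raise ValueError("spectral_tilt needs one coefficient per class")
        if any(abs(t) >= 1 for t in self.spectral_tilt):
            raise ValueError("spectral_tilt coefficients must lie in (-1, 1)")
        if REST in self.classes:
            rest_row = self.activation[self.classes.index(REST)]
            if np.any(rest_row > self.noise_floor + 1e-9):
                raise ValueError("rest activation must not exceed the noise floor")

    def class_index(self, label: str) -> int:
        try:
            return self.classes.index(label)
        except ValueError:
            raise ValueError(f"unknown class label {label!r}; known: {self.classes}") from None


@dataclass
class EmgRecording:
    """One labelled multichannel contraction (time x channel at ``fs``)."""

    samples: np.ndarray
    fs: float
    label: str
    day: int
    session: object  # int test session or "calibration"
    repetition: int
    seed_used: int

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be 2-D (time x channel)")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


# ---------------------------------------------------------------------------
# Spectral shaping
# ---------------------------------------------------------------------------
#
# Each class's signal is white noise passed through a first-order
# autoregressive "tilt" (emulating class-specific differences in the active
# motor-unit pools' spectra: a positive coefficient shifts power downward in
# frequency, a negative one upward) and then through the acquisition chain's
# Butterworth band-pass.  The cascade is normalised so unit-variance white
# input yields unit output RMS, making activation values direct RMS targets.

_SHAPING_CACHE: dict[tuple, tuple[np.ndarray, float]] = {}


def _shaping(fs: float, band: tuple[float, float], tilt: float = 0.0):
    """Cached band-pass SOS and RMS gain of the tilt + band-pass cascade."""
    key = (float(fs), float(band[0]), float(band[1]), float(tilt))
    if key not in _SHAPING_CACHE:
        sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
        impulse = np.zeros(4096)
        impulse[0] = 1.0
        h = signal.sosfilt(sos, _ar_tilt(impulse, tilt))
        _SHAPING_CACHE[key] = (sos, float(np.sqrt(np.sum(h**2))))
    return _SHAPING_CACHE[key]


def _ar_tilt(x: np.ndarray, tilt: float, zi=None):
    """First-order AR recolouring y_n = tilt * y_{n-1} + x_n along axis 0."""
    if tilt == 0.0:
        return x if zi is None else (x, zi)
    if zi is None:
        return signal.lfilter([1.0], [1.0, -tilt], x, axis=0)
    return signal.lfilter([1.0], [1.0, -tilt], x, axis=0, zi=zi)


# ---------------------------------------------------------------------------
# Drift state
# ---------------------------------------------------------------------------


def drift_state(config: SimConfig, day: int, session) -> tuple[np.ndarray, np.ndarray]:
    """Return ``(amplitude_factors, activation_matrix)`` for a day/session.

    Each day draws an independent fluctuation offset (``amplitude_std`` /
    ``mixing_std``) around the subject baseline and, from day 2 on,
    accumulates random-walk steps (``walk_*_std``).  Test sessions within a
    day add session-drift steps on top of that day's calibration state, so
    later sessions sit further from the data the decoder was trained on.
    Everything is a deterministic function of ``config.seed``.
    """
    if day < 1:
        raise ValueError("day must be >= 1")
    nc = config.n_channels

    def _draw(rng, drift: DriftConfig, log_amp, mix):
        log_amp += rng.normal(0.0, drift.amplitude_std, nc)
        log_amp += rng.normal(0.0, drift.common_amplitude_std)
        mix += rng.normal(0.0, drift.mixing_std, (nc, nc))

    def _draw_walk(rng, drift: DriftConfig, log_amp, mix):
        log_amp += rng.normal(0.0, drift.walk_amplitude_std, nc)
        log_amp += rng.normal(0.0, drift.walk_common_amplitude_std)
        mix += rng.normal(0.0, drift.walk_mixing_std, (nc, nc))

    log_amp = np.zeros(nc)
    mix = np.zeros((nc, nc))
    _draw(stream_rng(config.seed, "day-fluct", int(day)), config.day_drift, log_amp, mix)
    for d in range(2, int(day) + 1):
        _draw_walk(stream_rng(config.seed, "day-walk", d), config.day_drift, log_amp, mix)
    if session != CALIBRATION:
        sd = config.session_drift
        # deterministic effort decline over a day's sessions (fatigue): the
        # first test session is always closest to the calibration state
        log_amp += config.session_gain_trend * _session_code(session)
        _draw(
            stream_rng(config.seed, "session-fluct", day, _session_code(session)),
            sd, log_amp, mix,
        )
        for s in range(1, _session_code(session) + 1):
            _draw_walk(stream_rng(config.seed, "session-walk", day, s), sd, log_amp, mix)
    activation = np.clip(config.activation @ (np.eye(nc) + mix), 0.0, None)
    return np.exp(log_amp), activation


def _channel_stds(
    config: SimConfig,
    label: str,
    day: int,
    session,
    jitter: np.ndarray | None = None,
) -> np.ndarray:
    """Per-channel RMS targets for one contraction of ``label``.

    The amplitude drift factors act as per-channel gains (electrode contact /
    pick-up volume), so they scale the baseline noise floor as well as the
    class activation; contraction-level ``jitter`` scales the activation
    only.
    """
    idx = config.class_index(label)
    amp, activation = drift_state(config, day, session)
    base = activation[idx]
    if jitter is not None:
        base = base * jitter
    return amp * np.sqrt(base**2 + config.noise_floor**2)


# ---------------------------------------------------------------------------
# Recording generation
# ---------------------------------------------------------------------------


def generate_recording(
    config: SimConfig,
    label: str,
    day: int = 1,
    session=CALIBRATION,
    repetition: int = 1,
    duration: float = 6.0,
) -> EmgRecording:
    """Generate one labelled contraction recording.

    Deterministic given ``(config.seed, label, day, session, repetition)``.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if day < 1:
        raise ValueError("day must be >= 1")
    config.class_index(label)  # raises on unknown label
    rng = stream_rng(
        config.seed, "recording", day, _session_code(session), repetition, label
    )
    jitter = np.exp(rng.normal(0.0, config.repetition_jitter_std, config.n_channels))
    stds = _channel_stds(config, label, day, session, jitter)
    n = int(round(duration * config.fs))
    tilt = config.spectral_tilt[config.class_index(label)]
    sos, gain = _shaping(config.fs, config.band, tilt)
    white = rng.standard_normal((n, config.n_channels))
    shaped = signal.sosfilt(sos, _ar_tilt(white, tilt), axis=0) / gain
    return EmgRecording(
        samples=shaped * stds[None, :],
        fs=config.fs,
        label=label,
        day=int(day),
        session=session,
        repetition=int(repetition),
        seed_used=int(config.seed),
    )


def generate_calibration_day(config: SimConfig, day: int) -> list[EmgRecording]:
    """One calibration session: 4 repetitions x 6 s for each of the 5 classes."""
    if day < 1:
        raise ValueError("day must be >= 1")
    return [
        generate_recording(config, label, day=day, session=CALIBRATION, repetition=rep)
        for label in config.classes
        for rep in (1, 2, 3, 4)
    ]


# ---------------------------------------------------------------------------
# Closed-loop simulated user
# ---------------------------------------------------------------------------


class SimulatedUser:
    """Streaming EMG source standing in for the human subject.

    Emits successive samples of a single band-limited unit-variance noise
    stream, amplitude-modulated at emission time by the intended class's
    channel activations, so consecutive windows overlap exactly as they would
    when segmenting a live signal and class transitions pass through the
    usual window-mixing transient.  Each trial's underlying white-noise draw
    is generated once and shaped per spectral tilt in large filter passes;
    ``reset(trial_seed)`` re-seeds it and redraws the contraction-level
    jitter, making each trial independently reproducible.
    """

    def __init__(
        self,
        config: SimConfig,
        day: int,
        session,
        seed: int | None = None,
        buffer_len: float = 0.2,
        horizon: float = 8.0,
    ):
        self.config = config
        self.day = int(day)
        self.session = session
        self._base_seed = config.seed if seed is None else int(seed)
        self._buffer_n = int(round(buffer_len * config.fs))
        self._horizon_n = int(round(horizon * config.fs))
        self._tilts = dict(zip(config.classes, config.spectral_tilt))
        self._amp, self._activation = drift_state(config, day, session)
        self._stds_cache: dict[str, np.ndarray] = {}
        self.reset(0)

    def reset(self, trial_seed: int) -> None:
        """Start a fresh, reproducible noise stream for one trial."""
        self._rng = stream_rng(
            self._base_seed, "user", self.day, _session_code(self.session), trial_seed
        )
        cfg = self.config
        nc = cfg.n_channels
        jitter = np.exp(
            self._rng.normal(0.0, cfg.repetition_jitter_std, (len(cfg.classes), nc))
        )
        self._stds_cache = {
            label: self._amp
            * np.sqrt((self._activation[i] * jitter[i]) ** 2 + cfg.noise_floor**2)
            for i, label in enumerate(cfg.classes)
        }
        # one white-noise draw for the whole trial; per-tilt shaped streams
        # are filtered lazily on first use (most trials touch 2-3 tilts)
        self._white = self._rng.standard_normal((self._buffer_n + self._horizon_n, nc))
        self._unit: dict[float, np.ndarray] = {}
        self._zi: dict[float, tuple] = {}
        self._scaled = np.empty_like(self._white)
        self.intended: str = REST
        self._pos = 0  # samples emitted so far
        self._append_scaled(REST, self._buffer_n)  # prefill with pre-cue rest

    def _unit_for(self, tilt: float) -> np.ndarray:
        """Shaped unit-variance stream for one tilt, filtered up to the
        current white-noise length (incrementally on later extensions)."""
        sos, gain = _shaping(self.config.fs, self.config.band, tilt)
        if tilt not in self._unit:
            self._unit[tilt] = np.empty((0, self.config.n_channels))
            self._zi[tilt] = (
                np.zeros((1, self.config.n_channels)),  # AR(1) state
                np.zeros((sos.shape[0], 2, self.config.n_channels)),
            )
        done = self._unit[tilt].shape[0]
        if done < self._white.shape[0]:
            ar_zi, sos_zi = self._zi[tilt]
            fresh = self._white[done:]
            if tilt != 0.0:
                fresh, ar_zi = signal.lfilter([1.0], [1.0, -tilt], fresh, axis=0, zi=ar_zi)
            shaped, sos_zi = signal.sosfilt(sos, fresh, axis=0, zi=sos_zi)
            self._zi[tilt] = (ar_zi, sos_zi)
            self._unit[tilt] = np.concatenate([self._unit[tilt], shaped / gain])
        return self._unit[tilt]

    def _append_scaled(self, intended: str, n_new: int) -> None:
        end = self._pos + n_new
        if end > self._white.shape[0]:
            grow = self._rng.standard_normal(
                (max(n_new, self._horizon_n), self.config.n_channels)
            )
            self._white = np.concatenate([self._white, grow])
            pad = np.empty_like(grow)
            self._scaled = np.concatenate([self._scaled, pad])
        unit = self._unit_for(self._tilts[intended])
        self._scaled[self._pos : end] = (
            unit[self._pos : end] * self._stds_cache[intended][None, :]
        )
        self._pos = end

    def emit(self, intended: str, advance: float) -> np.ndarray:
        """Advance the stream by ``advance`` seconds of ``intended``-class EMG
        and return the latest ``buffer_len`` window (time x channel)."""
        if intended not in self._stds_cache:
            raise ValueError(f"unknown class label {intended!r}")
        self.intended = intended
        self._append_scaled(intended, int(round(advance * self.config.fs)))
        # a view is returned; it stays valid but callers must not mutate it
        return self._scaled[self._pos - self._buffer_n : self._pos]


def simulated_user_window(
    config: SimConfig,
    intended: str,
    day: int,
    t: float,
    window_len: float = 0.2,
    session=1,
    seed: int | None = None,
) -> np.ndarray:
    """One stateless EMG window for class ``intended`` at time ``t``.

    Convenience for open-loop sampling of the user model: each call draws an
    independent window (with fresh contraction-level jitter) from the
    generative distribution at the given day/session drift state, keyed by the
    tick index ``round(t * fs)``.
    """
    if window_len <= 0:
        raise ValueError("window_len must be positive")
    rng = stream_rng(
        config.seed if seed is None else seed,
        "user-window",
        day,
        _session_code(session),
        int(round(t * config.fs)),
    )
    jitter = np.exp(rng.normal(0.0, config.repetition_jitter_std, config.n_channels))
    stds = _channel_stds(config, intended, day, session, jitter)
    n = int(round(window_len * config.fs))
    tilt = config.spectral_tilt[config.class_index(intended)]
    sos, gain = _shaping(config.fs, config.band, tilt)
    white = rng.standard_normal((n + 200, config.n_channels))  # warm-up pad
    shaped = signal.sosfilt(sos, _ar_tilt(white, tilt), axis=0)[200:] / gain
    return shaped * stds[None, :]
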