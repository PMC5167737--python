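"""External input currents applied to STN cells.

Three input classes: a pure beta-band sine, a sine with Gaussian phase
jitter, and a phase-derived current built from the beta-band Hilbert phase
of a recorded (or surrogate) cortical signal.  A synthetic broadband
beta-peaked "cortical surrogate" generator stands in for recorded EEG.

Time ``t`` is in ms throughout; input frequencies ``omega0`` are in Hz, so
the sine argument carries the 2*pi*omega0*t/1000 normalization.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import scipy.signal

__all__ = [
    "InputSpec",
    "SampledSignal",
    "sine_input",
    "noisy_sine_input",
    "draw_phase_jitter",
    "phase_derived_input",
    "synthetic_cortical_signal",
    "realize_input",
]

MODES = ("none", "sine", "noisy_sine", "phase_derived")


@dataclass
class SampledSignal:
    """A uniformly sampled single-channel signal."""

    values: np.ndarray
    sample_rate: float  # Hz
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be > 0")

    @property
    def duration_s(self) -> float:
        return self.values.size / self.sample_rate

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.values.size) / self.sample_rate

    def write_text(self, path: str | Path, two_column: bool = True) -> None:
        """Write as two-column (time_s, value) text, or single-column with
        a ``# sample_rate_hz:`` header line."""
        path = Path(path)
        if two_column:
            np.savetxt(path, np.column_stack([self.time_s, self.values]),
                       header="time_s value")
        else:
            np.savetxt(path, self.values,
                       header=f"sample_rate_hz: {self.sample_rate}")

    @classmethod
    def read_text(cls, path: str | Path, label: str = "") -> "SampledSignal":
        """Read either of the two text layouts written by :meth:`write_text`.

        Two numeric columns are interpreted as (time_s, value) with the
        sample rate inferred from the time column; a single column
        requires a ``sample_rate_hz:`` header comment.
        """
        path = Path(path)
        data = np.loadtxt(path)
        if data.ndim == 2 and data.shape[1] >= 2:
            tt, vv = data[:, 0], data[:, 1]
            dts = np.diff(tt)
            if dts.size < 1 or np.any(dts <= 0):
                raise ValueError("time column must be strictly increasing")
            return cls(values=vv, sample_rate=1.0 / float(np.median(dts)),
                       label=label or path.name)
        rate = None
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") and "sample_rate_hz:" in line:
                    rate = float(line.split("sample_rate_hz:")[1])
                    break
        if rate is None:
            raise ValueError(
                "single-column signal file needs a '# sample_rate_hz: <Hz>' header"
            )
        return cls(values=np.atleast_1d(data), sample_rate=rate,
                   label=label or path.name)


@dataclass
class InputSpec:
    """Parametric description of the external current I_ext(t).

    A is the amplitude (model current units), omega0 the frequency in Hz,
    noise_variance the variance of the Gaussian phase jitter (radians^2).
    """

    mode: str = "none"
    A: float = 0.0
    omega0: float = 20.0
    noise_variance: float = 0.08
    seed: Optional[int] = None
    source_signal: Optional[SampledSignal] = None

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.A < 0:
            raise ValueError("A must be >= 0")
        if self.noise_variance < 0:
            raise ValueError("noise_variance must be >= 0")
        if self.mode != "none" and self.mode != "phase_derived" and self.omega0 <= 0:
            raise ValueError("omega0 must be > 0")


def sine_input(t, spec: InputSpec):
    """A sin(2 pi omega0 t / 1000) with t in ms."""
    t = np.asarray(t, dtype=float)
    return spec.A * np.sin(2.0 * np.pi * spec.omega0 * t / 1000.0)


def draw_phase_jitter(spec: InputSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """n i.i.d. Gaussian phase-jitter draws xi ~ N(0, noise_variance)."""
    return rng.normal(0.0, np.sqrt(spec.noise_variance), size=n)


def noisy_sine_input(t, spec: InputSpec, rng: np.random.Generator):
    """A sin(2 pi omega0 t / 1000 + xi_t), xi_t i.i.d. per evaluation point."""
    t = np.asarray(t, dtype=float)
    xi = draw_phase_jitter(spec, t.size, rng).reshape(t.shape)
    return spec.A * np.sin(2.0 * np.pi * spec.omega0 * t / 1000.0 + xi)


def _beta_phase(signal: SampledSignal, band: tuple[float, float]):
    """Unwrapped beta-band Hilbert phase of a sampled signal."""
    # shared implementation with the analysis chain
    from .phase_analysis import bandpass_beta, min_signal_length

    nmin = min_signal_length(signal.sample_rate, band)
    if signal.values.size < nmin:
        raise ValueError(
            f"signal too short for stable band-pass phase: need >= {nmin} samples "
            f"at {signal.sample_rate} Hz, got {signal.values.size}"
        )
    filt = bandpass_beta(signal.values, signal.sample_rate, band)
    return np.unwrap(np.angle(scipy.signal.hilbert(filt)))


def phase_derived_input(
    signal: SampledSignal,
    A: float,
    band: tuple[float, float] = (10.0, 30.0),
    t_ms: np.ndarray | None = None,
) -> np.ndarray:
    """I(t) = A sin(phi(t)) where phi is the signal's beta-band Hilbert phase.

    The phase is extracted at the signal's own sample rate and linearly
    interpolated (unwrapped) onto the integrator grid ``t_ms``; amplitude
    information of the source signal is discarded by construction.
    """
    phi = _beta_phase(signal, band)
    if t_ms is None:
        return A * np.sin(phi)
    t_ms = np.asarray(t_ms, dtype=float)
    t_sig_ms = signal.time_s * 1000.0
    if t_ms[-1] > t_sig_ms[-1] + 1e-9:
        raise ValueError(
            f"source signal ({t_sig_ms[-1]:.1f} ms) shorter than requested grid "
            f"({t_ms[-1]:.1f} ms)"
        )
    phi_on_grid = np.interp(t_ms, t_sig_ms, phi)
    return A * np.sin(phi_on_grid)


def synthetic_cortical_signal(
    peak_freq: float = 13.0,
    bandwidth: float = 6.0,
    duration: float = 60.0,
    sample_rate: float = 1000.0,
    seed: Optional[int] = None,
) -> SampledSignal:
    """Broadband surrogate of a motor-cortex EEG with a beta-band peak.

    Gaussian white noise is shaped by a resonant peak filter centered at
    ``peak_freq`` (quality factor peak_freq/bandwidth), a small white
    floor is added to keep the spectrum broad, and the result is
    normalized to zero mean and unit variance.  Reproducible given seed.
    """
    if not 0 < peak_freq < sample_rate / 2:
        raise ValueError("peak_freq must lie in (0, sample_rate/2)")
    if bandwidth <= 0:
        raise ValueError("bandwidth must be > 0")
    rng = np.random.default_rng(seed)
    n = int(round(duration * sample_rate))
    white = rng.standard_normal(n)
    b, a = scipy.signal.iirpeak(peak_freq, Q=peak_freq / bandwidth, fs=sample_rate)
    shaped = scipy.signal.lfilter(b, a, white)
    shaped = shaped / np.std(shaped)
    x = shaped + 0.3 * rng.standard_normal(n)
    x = (x - np.mean(x)) / np.std(x)
    return SampledSignal(values=x, sample_rate=sample_rate,
                         label=f"surrogate-{peak_freq:g}Hz")


def realize_input(
    spec: InputSpec,
    dt: float,
    n_steps: int,
    rng: np.random.Generator,
    band: tuple[float, float] = (10.0, 30.0),
) -> np.ndarray:
    """External current on the RK4 half-step grid (2 n_steps + 1 values).

    For the noisy sine the phase jitter is drawn once per integrator step
    and held constant across the step's sub-stage evaluations, so the
    stated jitter variance is per grid point.
    """
    t_half = 0.5 * dt * np.arange(2 * n_steps + 1)
    if spec.mode == "none" or spec.A == 0.0:
        return np.zeros(2 * n_steps + 1)
    if spec.mode == "sine":
        return sine_input(t_half, spec)
    if spec.mode == "noisy_sine":
        xi_step = draw_phase_jitter(spec, n_steps + 1, rng)
        xi_half = xi_step[np.minimum(np.arange(2 * n_steps + 1) // 2, n_steps)]
        return spec.A * np.sin(2.0 * np.pi * spec.omega0 * t_half / 1000.0 + xi_half)
    if spec.mode == "phase_derived":
        if spec.source_signal is None:
            raise ValueError("phase_derived mode requires spec.source_signal")
        return phase_derived_input(spec.source_signal, spec.A, band, t_ms=t_half)
    raise ValueError(f"unknown input mode {spec.mode!r}")
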