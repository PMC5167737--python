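"""Temporal patterns of beta-band synchrony between spiking and LFP.

The chain: zero-phase band-pass in the beta band (10-30 Hz), instantaneous
phase via the analytic signal, a first-return map of the spike-train phase
sampled once per LFP cycle at a fixed LFP-phase checkpoint, a partition of
the phase circle into four equal arcs with the phase-locked state at the
center of the synchronization arc, and per-region transition rates
(fraction of visits that leave the region on the next map step).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.signal

__all__ = [
    "PhaseSeries",
    "ReturnMapSeries",
    "TransitionRates",
    "MatchCriterion",
    "bandpass_beta",
    "instantaneous_phase",
    "spike_train_phase",
    "build_return_map",
    "partition_regions",
    "transition_rates",
    "matches_experiment",
    "min_signal_length",
]

logger = logging.getLogger(__name__)

N_REGIONS = 4


def wrap_phase(phi):
    """Wrap angles to the interval (-pi, pi]."""
    return np.pi - np.mod(np.pi - np.asarray(phi, dtype=float), 2.0 * np.pi)


def circular_distance(a, b):
    """Absolute circular distance between angles, in [0, pi]."""
    return np.abs(wrap_phase(np.asarray(a) - np.asarray(b)))


def min_signal_length(sample_rate: float, band=(10.0, 30.0)) -> int:
    """Minimum sample count for a stable zero-phase band-pass.

    Ten cycles of the lowest band frequency, and never less than the
    forward-backward filter's own edge-transient requirement.
    """
    return int(np.ceil(10.0 * sample_rate / band[0]))


def _beta_sos(sample_rate: float, band=(10.0, 30.0), order: int = 4):
    lo, hi = band
    nyq = sample_rate / 2.0
    if not 0 < lo < hi < nyq:
        raise ValueError(f"band {band} invalid for sample rate {sample_rate}")
    return scipy.signal.butter(order, [lo, hi], btype="bandpass", fs=sample_rate,
                               output="sos")


def bandpass_beta(x, sample_rate: float, band=(10.0, 30.0), order: int = 4):
    """Zero-phase Butterworth band-pass (forward-backward), mean removed first."""
    x = np.asarray(x, dtype=float)
    nmin = min_signal_length(sample_rate, band)
    if x.size < nmin:
        raise ValueError(
            f"signal too short for band-pass: need >= {nmin} samples at "
            f"{sample_rate} Hz, got {x.size}"
        )
    sos = _beta_sos(sample_rate, band, order)
    return scipy.signal.sosfiltfilt(sos, x - np.mean(x))


@dataclass
class PhaseSeries:
    """Instantaneous phase of a band-limited signal, wrapped to (-pi, pi]."""

    time: np.ndarray  # ms
    phase: np.ndarray  # radians, wrapped
    label: str = ""

    def unwrapped(self) -> np.ndarray:
        return np.unwrap(self.phase)


def instantaneous_phase(filtered, time=None, label: str = "") -> PhaseSeries:
    """Analytic-signal (Hilbert) phase of an already band-passed signal."""
    filtered = np.asarray(filtered, dtype=float)
    phi = np.angle(scipy.signal.hilbert(filtered))
    if time is None:
        time = np.arange(filtered.size, dtype=float)
    return PhaseSeries(time=np.asarray(time, dtype=float), phase=wrap_phase(phi),
                       label=label)


def spike_train_phase(binary_train, sample_rate: float, time=None,
                      band=(10.0, 30.0), order: int = 4) -> PhaseSeries:
    """Beta-band phase of a binary spike train (mean removed, filtered, Hilbert)."""
    filt = bandpass_beta(np.asarray(binary_train, dtype=float), sample_rate, band,
                         order)
    return instantaneous_phase(filt, time=time, label="spikes")


@dataclass
class ReturnMapSeries:
    """Spike phases recorded once per LFP cycle at an LFP-phase checkpoint."""

    checkpoint: float
    values: np.ndarray  # wrapped spike phases, one per upward checkpoint crossing
    crossing_times: np.ndarray  # ms

    @property
    def n(self) -> int:
        return self.values.size

    def to_text(self, path) -> None:
        """Columnar export: crossing time (ms) and recorded spike phase."""
        np.savetxt(path, np.column_stack([self.crossing_times, self.values]),
                   header="crossing_time_ms phi_spikes_rad")


def build_return_map(phi_lfp: PhaseSeries, phi_spikes: PhaseSeries,
                     checkpoint: float = 0.0) -> ReturnMapSeries:
    """Record the spike phase at every upward checkpoint crossing of the LFP phase.

    Crossing instants are located by linear interpolation between the
    bracketing samples; the spike phase is interpolated (unwrapped) to the
    crossing instant.  Wrap-around jumps of the LFP phase are not
    crossings.
    """
    if phi_lfp.time.shape != phi_spikes.time.shape or not np.allclose(
        phi_lfp.time, phi_spikes.time
    ):
        raise ValueError("phase series must share one time grid")
    d = wrap_phase(phi_lfp.phase - checkpoint)
    up = np.nonzero((d[:-1] < 0.0) & (d[1:] >= 0.0) & (d[1:] - d[:-1] < np.pi))[0]
    if up.size < 2:
        raise ValueError(
            f"only {up.size} checkpoint crossings found; window too short"
        )
    frac = -d[up] / (d[up + 1] - d[up])
    t_cross = phi_lfp.time[up] + frac * (phi_lfp.time[up + 1] - phi_lfp.time[up])
    spk_u = phi_spikes.unwrapped()
    vals = wrap_phase(spk_u[up] + frac * (spk_u[up + 1] - spk_u[up]))
    return ReturnMapSeries(checkpoint=float(checkpoint), values=vals,
                           crossing_times=t_cross)


def locked_state_center(values: np.ndarray) -> float:
    """Circular mean of the recorded spike phases (the phase-locked state).

    Falls back to the center of the densest quarter-circle when the
    circular mean is undefined (resultant length ~ 0).
    """
    z = np.exp(1j * np.asarray(values, dtype=float)).mean()
    if np.abs(z) < 1e-8:
        logger.warning(
            "circular mean undefined (resultant ~ 0); falling back to densest "
            "quartile center"
        )
        edges = np.linspace(-np.pi, np.pi, 73)
        counts, _ = np.histogram(wrap_phase(values), bins=edges)
        # occupancy of a pi/2 window starting at each bin edge
        k = 18  # 90 degrees of 5-degree bins
        window = np.array([np.roll(counts, -i)[:k].sum() for i in range(counts.size)])
        i0 = int(np.argmax(window))
        return float(wrap_phase(edges[i0] + np.pi / 4.0))
    return float(np.angle(z))


def partition_regions(rm: ReturnMapSeries) -> tuple[np.ndarray, float]:
    """Label each map point with one of four equal pi/2 arcs of the phase circle.

    Region 1 (the synchronization region) is centered on the phase-locked
    state; regions 2-4 are the remaining arcs in order of increasing
    phase difference (the direction of traversal during desynchronization
    events).  Returns (labels in 1..4, center).
    """
    if rm.n < 2:
        raise ValueError("need at least 2 map points")
    center = locked_state_center(rm.values)
    delta = wrap_phase(rm.values - center)
    labels = (np.floor((delta + np.pi / 4.0) / (np.pi / 2.0)).astype(int) % N_REGIONS) + 1
    return labels, center


@dataclass
class TransitionRates:
    """Per-region occupancy, leave counts and transition rates.

    rate_k is the number of points leaving region k on the next map step
    divided by the total number of points in region k; a region never
    visited has an undefined (NaN) rate.  Region 1 is the synchronization
    region.
    """

    occupancy: np.ndarray  # (4,) ints, all points in the region
    leaves: np.ndarray  # (4,) ints, counted over consecutive pairs
    rates: np.ndarray  # (4,) floats in [0,1] or NaN
    sync_region: int = 1

    def defined(self) -> np.ndarray:
        return ~np.isnan(self.rates)

    def summary(self, matched: bool | None = None) -> dict:
        """JSON-ready summary: occupancy, leaves and rate per region."""
        out = {
            f"region{k + 1}": {
                "occupancy": int(self.occupancy[k]),
                "leaves": int(self.leaves[k]),
                "rate": None if np.isnan(self.rates[k]) else float(self.rates[k]),
            }
            for k in range(N_REGIONS)
        }
        if matched is not None:
            out["matched"] = bool(matched)
        return out


def transition_rates(labels: np.ndarray) -> TransitionRates:
    """Transition rates of the four-region symbolic dynamics.

    Occupancy counts every point in a region (the final point cannot
    leave but still counts); leaves are counted over consecutive pairs.
    """
    labels = np.asarray(labels, dtype=int)
    if labels.size < 2:
        raise ValueError("need at least 2 labeled points")
    cur, nxt = labels[:-1], labels[1:]
    occ = np.zeros(N_REGIONS, dtype=int)
    lea = np.zeros(N_REGIONS, dtype=int)
    for k in range(1, N_REGIONS + 1):
        occ[k - 1] = int((labels == k).sum())
        lea[k - 1] = int(((cur == k) & (nxt != k)).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rates = np.where(occ > 0, lea / np.maximum(occ, 1), np.nan)
    return TransitionRates(occupancy=occ, leaves=lea, rates=rates)


@dataclass
class MatchCriterion:
    """Reference transition rates and SDs from experimental recordings.

    The model matches the experiment when every model rate lies within
    ``k`` reference SDs of the corresponding reference rate (boundary
    inclusive).  The shipped default is a documented placeholder: the
    actual patient-derived reference values are an external input and
    must be supplied in config for any quantitative matching claim.
    """

    reference_rates: np.ndarray = field(
        default_factory=lambda: np.array([0.3, 0.7, 0.6, 0.7])
    )
    reference_sds: np.ndarray = field(
        default_factory=lambda: np.array([0.1, 0.15, 0.2, 0.15])
    )
    k: float = 0.7

    def __post_init__(self) -> None:
        self.reference_rates = np.asarray(self.reference_rates, dtype=float)
        self.reference_sds = np.asarray(self.reference_sds, dtype=float)
        if self.reference_rates.shape != (N_REGIONS,) or self.reference_sds.shape != (
            N_REGIONS,
        ):
            raise ValueError("reference rates/SDs must have 4 entries")
        if np.any(self.reference_sds <= 0):
            raise ValueError("reference SDs must be > 0")
        if self.k <= 0:
            raise ValueError("tolerance multiplier k must be > 0")


def matches_experiment(rates: TransitionRates, criterion: MatchCriterion) -> bool:
    """True iff every model rate is within k SD of its reference (inclusive)."""
    if not np.all(rates.defined()):
        logger.info("match criterion false: %d region(s) never visited",
                    int((~rates.defined()).sum()))
        return False
    dev = np.abs(rates.rates - criterion.reference_rates)
    return bool(np.all(dev <= criterion.k * criterion.reference_sds + 1e-12))
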