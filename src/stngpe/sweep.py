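"""Amplitude x frequency sweeps and minimal-amplitude (Arnold-tongue) curves.

A sweep runs one simulation plus the full synchrony analysis per
(A, omega0) cell at a fixed (g_syn, I_app) parameter pair, optionally
averaged over replicate seeds.  From the per-cell PCA component counts it
derives, per frequency, the minimal input amplitude that reaches a target
synchrony level, and from that curve the tongue-tip (resonance) frequency.

Cell seeds are derived deterministically from the base seed and the cell's
(A, omega0, replicate) identity, so interrupted sweeps resume exactly and
an early-stopping amplitude scan reproduces the full grid cell-by-cell.
"""

from __future__ import annotations

import logging
import time as _time
import traceback
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .inputs import InputSpec, SampledSignal
from .network_synchrony import classify_synchrony, pca_component_count
from .params import ModelConfig
from .phase_analysis import (
    MatchCriterion,
    build_return_map,
    instantaneous_phase,
    bandpass_beta,
    matches_experiment,
    partition_regions,
    spike_train_phase,
    transition_rates,
)
from .simulate import integrate_network

logger = logging.getLogger(__name__)

__all__ = [
    "PRESETS",
    "SweepGrid",
    "MinimalAmplitudeCurve",
    "run_cell",
    "run_sweep",
    "minimal_amplitude",
    "minimal_amplitude_search",
    "tongue_tip",
]

#: The five (g_syn, I_app) parameter pairs studied.
PRESETS: dict[str, tuple[float, float]] = {
    "0.5-5": (0.5, 5.0),
    "0.5-7": (0.5, 7.0),
    "0.5-9": (0.5, 9.0),
    "0.7-5": (0.7, 5.0),
    "0.9-5": (0.9, 5.0),
}

_RATE_COLS = ["rate1", "rate2", "rate3", "rate4"]


def cell_seed(base_seed: int, amplitude: float, omega0: float, replicate: int) -> int:
    """Deterministic per-cell seed, independent of grid shape (< 2**31)."""
    ss = np.random.SeedSequence(
        [int(base_seed), int(round(amplitude * 1000)),
         int(round(omega0 * 1000)), int(replicate)]
    )
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass
class MinimalAmplitudeCurve:
    """Per-frequency minimal amplitude reaching <= target components.

    NaN marks frequencies where no amplitude on the grid achieves the
    target.
    """

    frequencies: np.ndarray
    amplitudes: np.ndarray
    target_count: int

    def defined(self) -> np.ndarray:
        return ~np.isnan(self.amplitudes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"omega0": self.frequencies, "min_amplitude": self.amplitudes,
             "target_count": self.target_count}
        )


@dataclass
class SweepGrid:
    """Results of one amplitude x frequency sweep at a (g_syn, I_app) pair."""

    g_syn: float
    i_app: float
    mode: str
    amplitudes: np.ndarray
    frequencies: np.ndarray
    replicates: int
    base_seed: int
    table: pd.DataFrame = field(default_factory=pd.DataFrame)  # per replicate rows

    def aggregated(self) -> pd.DataFrame:
        """One row per (A, omega0): median component count, mean rates,
        majority match flag, over replicates."""
        ok = self.table[self.table["ok"]]
        if ok.empty:
            return pd.DataFrame()
        agg = ok.groupby(["A", "omega0"], as_index=False).agg(
            count=("count", "median"),
            matched=("matched", lambda s: bool(np.mean(s.astype(float)) > 0.5)),
            n_rep=("count", "size"),
            **{c: (c, "mean") for c in _RATE_COLS},
        )
        agg["count"] = np.rint(agg["count"]).astype(int)
        agg["category"] = [classify_synchrony(c) for c in agg["count"]]
        return agg

    def save(self, out_dir: str | Path) -> Path:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        path = out_dir / self._csv_name()
        self.table.to_csv(path, index=False)
        return path

    def _csv_name(self) -> str:
        return f"sweep_g{self.g_syn:g}_i{self.i_app:g}_{self.mode}_s{self.base_seed}.csv"


def run_cell(
    config: ModelConfig,
    amplitude: float,
    omega0: float,
    mode: str = "sine",
    seed: int = 0,
    duration: Optional[float] = None,
    transient: Optional[float] = None,
    source_signal: Optional[SampledSignal] = None,
    criterion: Optional[MatchCriterion] = None,
    with_rates: bool = True,
    site: int = 0,
) -> dict:
    """Simulate one sweep cell and run the synchrony analyses.

    Returns a flat record with the PCA component count, the four
    transition rates of the site's spike-vs-LFP return map, and the
    experiment-match flag.
    """
    spec = InputSpec(mode=mode if amplitude > 0 else "none", A=amplitude,
                     omega0=omega0, seed=seed, source_signal=source_signal)
    res = integrate_network(config, spec, duration=duration, transient=transient,
                            seed=seed)
    mask = res.analysis_mask
    score = pca_component_count(res.slow_variable()[mask],
                                config.analysis.pca_threshold)
    rec: dict = {
        "count": score.component_count,
        "category": score.category,
        "matched": False,
        **{c: np.nan for c in _RATE_COLS},
    }
    if with_rates:
        try:
            fs = res.sample_rate
            band = config.analysis.beta_band
            order = config.analysis.filter_order
            lfp_f = bandpass_beta(res.lfp[mask, site], fs, band, order)
            phi_lfp = instantaneous_phase(lfp_f, time=res.time[mask], label="lfp")
            phi_spk = spike_train_phase(res.spike_trains[mask, site], fs,
                                        time=res.time[mask], band=band, order=order)
            rm = build_return_map(phi_lfp, phi_spk)
            labels, _ = partition_regions(rm)
            rates = transition_rates(labels)
            rec.update({c: rates.rates[i] for i, c in enumerate(_RATE_COLS)})
            rec["matched"] = matches_experiment(rates, criterion or MatchCriterion())
        except ValueError as exc:  # too few spikes / crossings in the window
            logger.debug("rates unavailable for A=%g omega0=%g: %s",
                         amplitude, omega0, exc)
    return rec


def _aggregate_counts(counts: Sequence[int]) -> int:
    return int(np.rint(np.median(counts)))


def run_sweep(
    config: ModelConfig,
    g_syn: float,
    i_app: float,
    mode: str = "sine",
    amplitudes: Sequence[float] = tuple(range(0, 17)),
    frequencies: Sequence[float] = tuple(range(10, 31)),
    base_seed: int = 0,
    replicates: int = 1,
    duration: Optional[float] = None,
    transient: Optional[float] = None,
    source_signal: Optional[SampledSignal] = None,
    criterion: Optional[MatchCriterion] = None,
    out_dir: Optional[str | Path] = None,
    with_rates: bool = True,
) -> SweepGrid:
    """Run (or resume) a full amplitude x frequency sweep.

    When ``out_dir`` is given the per-replicate table is persisted
    incrementally after every cell, and previously completed cells are
    skipped on re-run.  A failing cell is recorded as failed and the
    sweep continues.
    """
    cfg = config.with_pair(g_syn, i_app)
    amplitudes = np.asarray(sorted(set(float(a) for a in amplitudes)))
    frequencies = np.asarray(sorted(set(float(f) for f in frequencies)))
    grid = SweepGrid(g_syn=g_syn, i_app=i_app, mode=mode,
                     amplitudes=amplitudes, frequencies=frequencies,
                     replicates=replicates, base_seed=base_seed)

    done: set[tuple[float, float, int]] = set()
    rows: list[dict] = []
    csv_path = None
    if out_dir is not None:
        csv_path = Path(out_dir) / grid._csv_name()
        if csv_path.exists():
            prev = pd.read_csv(csv_path)
            rows = prev.to_dict("records")
            done = {(r["A"], r["omega0"], r["replicate"]) for r in rows}
            logger.info("resuming sweep: %d cells already done", len(done))

    for w0 in frequencies:
        for a in amplitudes:
            for rep in range(replicates):
                key = (float(a), float(w0), rep)
                if key in done:
                    continue
                seed = cell_seed(base_seed, a, w0, rep)
                t0 = _time.perf_counter()
                row: dict = {"g_syn": g_syn, "I_app": i_app, "mode": mode,
                             "A": float(a), "omega0": float(w0),
                             "replicate": rep, "seed": seed}
                try:
                    row.update(run_cell(cfg, a, w0, mode, seed, duration, transient,
                                        source_signal, criterion, with_rates))
                    row["ok"] = True
                    row["error"] = ""
                except Exception as exc:  # noqa: BLE001 - cell failures must not kill the sweep
                    row.update({"count": -1, "category": "", "matched": False,
                                **{c: np.nan for c in _RATE_COLS},
                                "ok": False, "error": repr(exc)})
                    logger.error("cell A=%g omega0=%g rep=%d failed:\n%s",
                                 a, w0, rep, traceback.format_exc())
                row["wall_s"] = round(_time.perf_counter() - t0, 3)
                rows.append(row)
                logger.info("cell A=%g omega0=%g rep=%d seed=%d count=%s (%.2fs)",
                            a, w0, rep, seed, row.get("count"), row["wall_s"])
                if csv_path is not None:
                    csv_path.parent.mkdir(parents=True, exist_ok=True)
                    pd.DataFrame(rows).to_csv(csv_path, index=False)
    grid.table = pd.DataFrame(rows)
    return grid


def minimal_amplitude(grid: SweepGrid, target_count: int) -> MinimalAmplitudeCurve:
    """Per frequency, the smallest grid amplitude with count <= target."""
    agg = grid.aggregated()
    out = np.full(grid.frequencies.size, np.nan)
    for i, w0 in enumerate(grid.frequencies):
        col = agg[(agg["omega0"] == w0) & (agg["count"] <= target_count)]
        if not col.empty:
            out[i] = col["A"].min()
    return MinimalAmplitudeCurve(frequencies=grid.frequencies.copy(),
                                 amplitudes=out, target_count=target_count)


def minimal_amplitude_search(
    config: ModelConfig,
    g_syn: float,
    i_app: float,
    mode: str = "sine",
    amplitudes: Sequence[float] = tuple(range(0, 11)),
    frequencies: Sequence[float] = tuple(range(14, 25)),
    target_count: int = 3,
    base_seed: int = 0,
    replicates: int = 3,
    duration: Optional[float] = None,
    transient: Optional[float] = None,
    source_signal: Optional[SampledSignal] = None,
    progress: bool = False,
) -> MinimalAmplitudeCurve:
    """Minimal-amplitude curve via an ascending early-stopping amplitude scan.

    For each frequency the amplitude grid is scanned upward and the scan
    stops at the first amplitude whose replicate-median component count
    reaches the target.  Because cell seeds depend only on the cell
    identity, the result equals running the full grid and then taking
    :func:`minimal_amplitude`, at a fraction of the cost.
    """
    cfg = config.with_pair(g_syn, i_app)
    amplitudes = np.asarray(sorted(set(float(a) for a in amplitudes)))
    frequencies = np.asarray(sorted(set(float(f) for f in frequencies)))
    out = np.full(frequencies.size, np.nan)
    for i, w0 in enumerate(frequencies):
        for a in amplitudes:
            counts = []
            for rep in range(replicates):
                if replicates == 3 and rep == 2:
                    # the median-of-3 decision is already settled when the
                    # first two replicates agree about reaching the target
                    hits = sum(c <= target_count for c in counts)
                    if hits in (0, 2):
                        counts.append(counts[0] if hits == 2 else counts[-1])
                        break
                seed = cell_seed(base_seed, a, w0, rep)
                rec = run_cell(cfg, a, w0, mode, seed, duration, transient,
                               source_signal, with_rates=False)
                counts.append(rec["count"])
            hit = sum(c <= target_count for c in counts) * 2 > len(counts)
            if hit:
                out[i] = a
                break
        if progress:
            logger.info("omega0=%g Hz: minimal A = %s", w0, out[i])
    return MinimalAmplitudeCurve(frequencies=frequencies, amplitudes=out,
                                 target_count=target_count)


def tongue_tip(curve: MinimalAmplitudeCurve, neighborhood: int = 1) -> float:
    """Frequency of the tongue tip (argmin of the minimal-amplitude curve).

    Ties on the minimum are broken toward the frequency whose local
    neighborhood average (radius ``neighborhood`` grid points, defined
    values only) is deepest, then toward the lower frequency.
    """
    defined = curve.defined()
    if defined.sum() < 3:
        raise ValueError("tongue tip needs >= 3 defined frequencies")
    amin = np.nanmin(curve.amplitudes)
    candidates = np.nonzero(defined & (curve.amplitudes == amin))[0]
    if candidates.size == 1:
        return float(curve.frequencies[candidates[0]])

    def neigh_avg(idx: int) -> float:
        lo, hi = max(0, idx - neighborhood), min(curve.amplitudes.size, idx + neighborhood + 1)
        vals = curve.amplitudes[lo:hi]
        vals = vals[~np.isnan(vals)]
        return float(vals.mean())

    avgs = np.array([neigh_avg(i) for i in candidates])
    best = candidates[avgs == avgs.min()]
    return float(curve.frequencies[best.min()])
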