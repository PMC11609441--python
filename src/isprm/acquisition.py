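"""Discrete-event simulator of internal-standard-triggered PRM acquisition.

The instrument loops over a fixed duty cycle. Each cycle starts with a
survey MS1 scan; every heavy (internal standard) precursor observed in the
MS1 centroids within the precursor tolerance and above an intensity
threshold receives a fast, low-resolution "watch" MS2 scan on the heavy
m/z. If at least ``trigger_threshold`` of the expected heavy transitions
are matched in the watch spectrum, a high-resolution, long-injection
quantitative MS2 scan is fired in the same cycle at the offset precursor
m/z (heavy m/z minus label delta over charge) — i.e. on the endogenous
light peptide. A scheduled-PRM comparator fires quantitative scans on
every light precursor whose predefined retention-time window contains the
current clock, regardless of signal.

Cycle budget policy: a watch scan is only started if its matched
quantitative scan could still begin inside the current cycle, so the total
scan time between consecutive MS1 scans never exceeds the duty-cycle
period plus one maximal scan duration. Targets that do not fit are simply
picked up on a later cycle (the internal standard is still eluting); when
a cycle overruns, the next MS1 starts as soon as the overflowing scan
finishes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .lc import GradientMethod
from .panel import Panel, PeptideSpec
from .samples import (
    NO_BACKGROUND,
    NOISELESS,
    BackgroundModel,
    NoiseModel,
    SignalSet,
    sample_background,
)

#: Orbitrap transient durations (ms) by resolution setting.
TRANSIENT_MS: dict[int, float] = {
    7500: 16.0,
    15000: 32.0,
    30000: 64.0,
    60000: 128.0,
    120000: 256.0,
}

MS1 = "MS1"
WATCH_MS2 = "WATCH_MS2"
QUANT_MS2 = "QUANT_MS2"


@dataclass(frozen=True)
class AcquisitionParams:
    """Instrument method parameters for the triggered-acquisition cycle."""

    ms1_resolution: int = 120_000
    ms1_injection_ms: float = 50.0
    cycle_s: float = 2.0
    watch_resolution: int = 7_500
    watch_injection_ms: float = 10.0
    quant_resolution: int = 60_000
    quant_injection_ms: float = 250.0
    precursor_tol_ppm: float = 10.0
    fragment_tol_ppm: float = 20.0
    trigger_threshold: int = 3  # matched product ions needed for an offset scan
    is_detect_fraction: float = 0.01  # MS1 threshold as fraction of IS apex
    isolation_width: float = 1.0  # Th
    overhead_ms: float = 5.0
    # recorded for provenance only; ion-population control is not simulated
    agc_targets: tuple[tuple[str, str], ...] = (
        ("MS1", "300%"),
        ("WATCH_MS2", "1000%"),
        ("QUANT_MS2", "1000%"),
    )

    def __post_init__(self):
        if min(self.ms1_injection_ms, self.watch_injection_ms,
               self.quant_injection_ms, self.cycle_s, self.overhead_ms) <= 0:
            raise ValueError("all times must be positive")
        if self.trigger_threshold < 1:
            raise ValueError("trigger threshold must be >= 1")
        if min(self.precursor_tol_ppm, self.fragment_tol_ppm) <= 0:
            raise ValueError("tolerances must be positive")


def scan_duration(
    resolution: int, injection_ms: float, overhead_ms: float = 5.0
) -> float:
    """Scan wall time (s): max(injection, transient) + fixed overhead.

    The orbitrap transient length is looked up from :data:`TRANSIENT_MS`;
    an unlisted resolution falls back to the nearest documented one with a
    warning.
    """
    if resolution not in TRANSIENT_MS:
        nearest = min(TRANSIENT_MS, key=lambda r: abs(r - resolution))
        warnings.warn(
            f"resolution {resolution} not in transient table; using {nearest}",
            stacklevel=2,
        )
        resolution = nearest
    transient = TRANSIENT_MS[resolution]
    return (max(injection_ms, transient) + overhead_ms) / 1000.0


@dataclass
class ScanEvent:
    """One simulated instrument scan."""

    time: float
    kind: str  # MS1 | WATCH_MS2 | QUANT_MS2
    target: str | None  # spec_id; None for MS1
    isolation_center: float | None
    resolution: int
    injection_ms: float
    mz: np.ndarray
    intensity: np.ndarray
    matched_count: int | None = None  # watch scans only

    @property
    def tic(self) -> float:
        return float(self.intensity.sum())


@dataclass
class RunRecord:
    """Ordered scan events of one simulated LC-MS run."""

    run_index: int
    gradient: GradientMethod
    params: AcquisitionParams
    mode: str
    seed: int | None = None
    events: list[ScanEvent] = field(default_factory=list)

    def scans(self, kind: str | None = None, target: str | None = None):
        out = self.events
        if kind is not None:
            out = [e for e in out if e.kind == kind]
        if target is not None:
            out = [e for e in out if e.target == target]
        return out

    def ms1_tic(self) -> tuple[np.ndarray, np.ndarray]:
        """(times, summed intensity) over the MS1 scans."""
        ms1 = self.scans(MS1)
        return (
            np.array([e.time for e in ms1]),
            np.array([e.tic for e in ms1]),
        )

    def tic_area(self) -> float:
        t, y = self.ms1_tic()
        if len(t) < 2:
            return 0.0
        return float(np.trapezoid(y, t))


def offset_mz(heavy_precursor_mz: float, label_delta: float, charge: int) -> float:
    """Light-precursor m/z from its heavy partner: heavy − delta/charge."""
    if charge < 1:
        raise ValueError("charge must be >= 1")
    return heavy_precursor_mz - label_delta / charge


def match_fragments(
    centroid_mz: np.ndarray,
    expected_mz: np.ndarray,
    tol_ppm: float,
) -> int:
    """Count expected transitions matched by the centroids within ±tol.

    Greedy nearest assignment: candidate (expectation, centroid) pairs are
    taken in order of increasing m/z error (ties broken by expectation
    index, then centroid index) and each centroid satisfies at most one
    expectation.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    centroid_mz = np.asarray(centroid_mz, dtype=float)
    expected_mz = np.asarray(expected_mz, dtype=float)
    if centroid_mz.size == 0 or expected_mz.size == 0:
        return 0
    tol = expected_mz * tol_ppm * 1e-6
    err = np.abs(centroid_mz[None, :] - expected_mz[:, None])  # (exp, cent)
    ei, ci = np.nonzero(err <= tol[:, None])
    if ei.size == 0:
        return 0
    order = np.lexsort((ci, ei, err[ei, ci]))
    used_exp: set[int] = set()
    used_cent: set[int] = set()
    count = 0
    for k in order:
        e, c = int(ei[k]), int(ci[k])
        if e in used_exp or c in used_cent:
            continue
        used_exp.add(e)
        used_cent.add(c)
        count += 1
    return count


def acquire_spectrum(
    signals: SignalSet,
    time: float,
    isolation_center: float,
    isolation_width: float,
    noise: NoiseModel = NOISELESS,
    background: BackgroundModel = NO_BACKGROUND,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate one MS2 spectrum: true transitions of every co-isolated
    precursor, plus noise and matrix background."""
    half = isolation_width / 2.0
    mzs: list[np.ndarray] = []
    ints: list[np.ndarray] = []
    sel = np.nonzero(np.abs(signals.precursor_mz - isolation_center) <= half)[0]
    for i in sel:
        inten = signals.transition_intensity(int(i), time)
        nz = inten > 0
        if nz.any():
            mzs.append(signals.transition_mz[int(i)][nz])
            ints.append(inten[nz])
    if background.mean_ions_per_scan > 0 and rng is not None:
        true_mz = (
            np.concatenate(mzs) if mzs else np.empty(0)
        )
        bmz, bint = sample_background(background, rng, true_mz)
        mzs.append(bmz)
        ints.append(bint)
    if mzs:
        mz = np.concatenate(mzs)
        intensity = np.concatenate(ints)
    else:
        mz = np.empty(0)
        intensity = np.empty(0)
    mz, intensity = _apply_noise(mz, intensity, noise, rng)
    order = np.argsort(mz)
    return mz[order], intensity[order]


def _apply_noise(mz, intensity, noise, rng):
    if rng is not None:
        return noise.apply(mz, intensity, rng)
    if noise.floor > 0:
        keep = intensity >= noise.floor
        return mz[keep], intensity[keep]
    return mz, intensity


def _ms1_spectrum(signals, t, noise, rng):
    intensity = signals.precursor_intensity(t)
    nz = intensity > 0
    mz, intensity = signals.precursor_mz[nz], intensity[nz]
    mz, intensity = _apply_noise(mz, intensity, noise, rng)
    order = np.argsort(mz)
    return mz[order], intensity[order]


def _detected_in_ms1(mz, intensity, target_mz, tol_ppm, threshold):
    tol = target_mz * tol_ppm * 1e-6
    sel = np.abs(mz - target_mz) <= tol
    return bool(sel.any()) and float(intensity[sel].max()) >= threshold


def run_surequant(
    signals: SignalSet,
    panel: Panel,
    params: AcquisitionParams = AcquisitionParams(),
    gradient: GradientMethod | None = None,
    noise: NoiseModel = NOISELESS,
    background: BackgroundModel = NO_BACKGROUND,
    rng: np.random.Generator | None = None,
    run_index: int = 0,
) -> RunRecord:
    """Simulate one IS-triggered run over the active gradient."""
    from .lc import GRADIENT_100SPD

    gradient = gradient or GRADIENT_100SPD
    record = RunRecord(run_index, gradient, params, mode="surequant")
    ms1_dur = scan_duration(params.ms1_resolution, params.ms1_injection_ms,
                            params.overhead_ms)
    watch_dur = scan_duration(params.watch_resolution, params.watch_injection_ms,
                              params.overhead_ms)
    quant_dur = scan_duration(params.quant_resolution, params.quant_injection_ms,
                              params.overhead_ms)
    threshold = params.is_detect_fraction * _is_apex_amplitude(signals)
    pairs = panel.pairs()
    heavy_info = [
        (h, l, offset_mz(h.precursor_mz, h.label_delta, h.charge))
        for h, l in pairs
    ]
    end = gradient.active_gradient_length
    clock = 0.0
    cycle_start = 0.0
    cycle_index = 0
    while cycle_start < end:
        cycle_end = cycle_start + params.cycle_s
        clock = cycle_start
        mz, inten = _ms1_spectrum(signals, clock, noise, rng)
        record.events.append(
            ScanEvent(clock, MS1, None, None, params.ms1_resolution,
                      params.ms1_injection_ms, mz, inten)
        )
        clock += ms1_dur
        # round-robin over the currently detected standards: under budget
        # contention no co-eluting target is systematically starved
        active = [
            info for info in heavy_info
            if _detected_in_ms1(mz, inten, info[0].precursor_mz,
                                params.precursor_tol_ppm, threshold)
        ]
        for heavy, light, off_mz in _rotated(active, cycle_index):
            # require room for the watch AND a potential same-cycle offset scan
            if clock + watch_dur >= cycle_end:
                break
            wmz, wint = acquire_spectrum(
                signals, clock, heavy.precursor_mz, params.isolation_width,
                noise, background, rng,
            )
            matched = match_fragments(
                wmz, np.array(heavy.transition_mzs()), params.fragment_tol_ppm
            )
            record.events.append(
                ScanEvent(clock, WATCH_MS2, heavy.spec_id, heavy.precursor_mz,
                          params.watch_resolution, params.watch_injection_ms,
                          wmz, wint, matched_count=matched)
            )
            clock += watch_dur
            if matched >= params.trigger_threshold:
                qmz, qint = acquire_spectrum(
                    signals, clock, off_mz, params.isolation_width,
                    noise, background, rng,
                )
                record.events.append(
                    ScanEvent(clock, QUANT_MS2, light.spec_id, off_mz,
                              params.quant_resolution, params.quant_injection_ms,
                              qmz, qint)
                )
                clock += quant_dur
        cycle_start = max(cycle_start + params.cycle_s, clock)
        cycle_index += 1
    return record


def _rotated(items: list, k: int) -> list:
    if not items:
        return items
    k %= len(items)
    return items[k:] + items[:k]


def run_scheduled_prm(
    signals: SignalSet,
    panel: Panel,
    rt_windows: dict[str, tuple[float, float]],
    params: AcquisitionParams = AcquisitionParams(),
    gradient: GradientMethod | None = None,
    noise: NoiseModel = NOISELESS,
    background: BackgroundModel = NO_BACKGROUND,
    rng: np.random.Generator | None = None,
    run_index: int = 0,
) -> RunRecord:
    """Scheduled-PRM comparator: quantitative scans on every precursor whose
    predefined retention-time window contains the cycle clock, signal or no
    signal. The internal standard is spiked in this mode too, so each
    in-window cycle schedules the heavy precursor alongside its light
    partner (keyed by the light spec_id's window) — integration stays
    anchored to the heavy trace exactly as in triggered mode. The same
    scan-time budget rules apply; windows that do not fit a cycle are
    revisited on the next one."""
    from .lc import GRADIENT_100SPD

    gradient = gradient or GRADIENT_100SPD
    record = RunRecord(run_index, gradient, params, mode="prm")
    ms1_dur = scan_duration(params.ms1_resolution, params.ms1_injection_ms,
                            params.overhead_ms)
    quant_dur = scan_duration(params.quant_resolution, params.quant_injection_ms,
                              params.overhead_ms)
    pairs = panel.pairs()
    end = gradient.active_gradient_length
    cycle_start = 0.0
    cycle_index = 0
    while cycle_start < end:
        cycle_end = cycle_start + params.cycle_s
        clock = cycle_start
        mz, inten = _ms1_spectrum(signals, clock, noise, rng)
        record.events.append(
            ScanEvent(clock, MS1, None, None, params.ms1_resolution,
                      params.ms1_injection_ms, mz, inten)
        )
        clock += ms1_dur
        active = []
        for heavy, light in pairs:
            window = rt_windows.get(light.spec_id)
            if window is not None and window[0] <= cycle_start <= window[1]:
                active.append((heavy, light))
        # round-robin over the open windows so contention is shared fairly
        for heavy, light in _rotated(active, cycle_index):
            # the pair is scheduled atomically: both heavy and light scans
            # or neither, so neither species is starved under contention;
            # the second scan may overflow the cycle by at most one scan
            if clock + quant_dur >= cycle_end:
                break  # window is revisited next cycle
            for spec in (heavy, light):
                qmz, qint = acquire_spectrum(
                    signals, clock, spec.precursor_mz, params.isolation_width,
                    noise, background, rng,
                )
                record.events.append(
                    ScanEvent(clock, QUANT_MS2, spec.spec_id, spec.precursor_mz,
                              params.quant_resolution, params.quant_injection_ms,
                              qmz, qint)
                )
                clock += quant_dur
        cycle_start = max(cycle_start + params.cycle_s, clock)
        cycle_index += 1
    return record


def _is_apex_amplitude(signals: SignalSet) -> float:
    if signals.is_heavy.any():
        return float(signals.amplitude[signals.is_heavy].max())
    return float(signals.amplitude.max()) if len(signals.amplitude) else 0.0


# ---------------------------------------------------------------------------
# Scan-table I/O: one CSV row per scan, centroids in a long-format sidecar.
# ---------------------------------------------------------------------------

SCAN_COLUMNS = [
    "scan_id", "run_index", "time", "kind", "target", "isolation_center",
    "resolution", "injection_ms", "matched_count",
]
CENTROID_COLUMNS = ["scan_id", "mz", "intensity"]


def write_scan_tables(
    runs: list[RunRecord], scans_path: str | Path, centroids_path: str | Path
) -> None:
    scan_rows, cent_rows = [], []
    scan_id = 0
    for run in runs:
        for e in run.events:
            scan_rows.append(
                {
                    "scan_id": scan_id,
                    "run_index": run.run_index,
                    "time": e.time,
                    "kind": e.kind,
                    "target": e.target if e.target is not None else "",
                    "isolation_center": e.isolation_center,
                    "resolution": e.resolution,
                    "injection_ms": e.injection_ms,
                    "matched_count": e.matched_count,
                }
            )
            for m, i in zip(e.mz, e.intensity):
                cent_rows.append({"scan_id": scan_id, "mz": m, "intensity": i})
            scan_id += 1
    pd.DataFrame(scan_rows, columns=SCAN_COLUMNS).to_csv(scans_path, index=False)
    pd.DataFrame(cent_rows, columns=CENTROID_COLUMNS).to_csv(
        centroids_path, index=False
    )


def read_scan_tables(
    scans_path: str | Path,
    centroids_path: str | Path,
    gradient: GradientMethod,
    params: AcquisitionParams = AcquisitionParams(),
) -> list[RunRecord]:
    scans = pd.read_csv(scans_path, keep_default_na=False, na_values=[],
                        float_precision="round_trip")
    cents = pd.read_csv(centroids_path, float_precision="round_trip")
    by_scan = dict(tuple(cents.groupby("scan_id"))) if not cents.empty else {}
    runs: dict[int, RunRecord] = {}
    for _, row in scans.iterrows():
        ri = int(row["run_index"])
        run = runs.get(ri)
        if run is None:
            run = runs[ri] = RunRecord(ri, gradient, params, mode="loaded")
        grp = by_scan.get(row["scan_id"])
        if grp is None:
            mz = np.empty(0)
            inten = np.empty(0)
        else:
            mz = grp["mz"].to_numpy()
            inten = grp["intensity"].to_numpy()
        matched = row["matched_count"]
        iso = row["isolation_center"]
        run.events.append(
            ScanEvent(
                float(row["time"]),
                str(row["kind"]),
                str(row["target"]) or None,
                float(iso) if iso not in ("", None) else None,
                int(row["resolution"]),
                float(row["injection_ms"]),
                mz,
                inten,
                matched_count=(
                    int(float(matched)) if matched not in ("", None) else None
                ),
            )
        )
    return [runs[k] for k in sorted(runs)]


def export_mzml(runs: list[RunRecord], path: str | Path) -> None:
    """Placeholder mzML export hook; raw vendor-style output is out of scope."""
    raise NotImplementedError(
        "mzML export is a stub; use write_scan_tables for CSV scan tables"
    )
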