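"""Transition-chromatogram quantification.

Mirrors the standard targeted-proteomics report chain: extract per-transition
traces from the targeted MS2 scans at a fragment tolerance (default 20 ppm),
set integration boundaries from the heavy internal-standard trace (the
automated analogue of curating boundaries against heavy retention times),
integrate light transitions over those boundaries, sum them into a total
fragment area per precursor, normalize run-to-run by the total-ion-current
chromatogram area, average peptide values into protein values, and finally
min-max rescale each protein to 0-100 across samples.

Missing-data policy: an undetected peptide is *missing*, never zero; zeros
arise only from genuinely empty integration regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .acquisition import QUANT_MS2, WATCH_MS2, RunRecord
from .panel import Panel, PeptideSpec


@dataclass
class TransitionTrace:
    """Per-transition chromatogram points for one targeted species."""

    spec_id: str
    times: np.ndarray  # (n_scans,), strictly increasing
    intensities: np.ndarray  # (n_scans, n_transitions), >= 0

    def summed(self) -> np.ndarray:
        return self.intensities.sum(axis=1)

    @property
    def n_points(self) -> int:
        return len(self.times)


def extract_traces(
    run: RunRecord, panel: Panel, tol_ppm: float = 20.0
) -> dict[str, TransitionTrace]:
    """Harvest transition traces from targeted scans.

    Light traces come from QUANT_MS2 scans, heavy traces from WATCH_MS2
    scans. For every expected transition, the intensities of all centroids
    within ±tol_ppm are summed; a transition with no centroid contributes an
    explicit zero at that scan time. Interfering ions inside the tolerance
    are, by construction, added to the trace.
    """
    specs = {p.spec_id: p for p in panel.peptides}
    rows: dict[str, list[tuple[float, np.ndarray]]] = {s: [] for s in specs}
    for e in run.events:
        if e.kind not in (QUANT_MS2, WATCH_MS2) or e.target not in specs:
            continue
        spec = specs[e.target]
        expected = np.array(spec.transition_mzs())
        tol = expected * tol_ppm * 1e-6
        vals = np.empty(len(expected))
        for j, (m, w) in enumerate(zip(expected, tol)):
            sel = np.abs(e.mz - m) <= w
            vals[j] = e.intensity[sel].sum() if sel.any() else 0.0
        rows[e.target].append((e.time, vals))
    out: dict[str, TransitionTrace] = {}
    for sid, points in rows.items():
        n_tr = len(specs[sid].transitions)
        if points:
            times = np.array([t for t, _ in points])
            mat = np.vstack([v for _, v in points])
        else:
            times = np.empty(0)
            mat = np.empty((0, n_tr))
        out[sid] = TransitionTrace(sid, times, mat)
    return out


def detect_boundaries(
    heavy_trace: TransitionTrace, threshold_frac: float = 0.05
) -> tuple[float, float] | None:
    """Integration boundaries from the heavy internal-standard trace.

    The contiguous region around the apex of the summed heavy trace where
    the intensity stays at or above ``threshold_frac`` of the apex. Returns
    None when the heavy peptide was never observed (all-zero or empty
    trace), in which case the peptide is flagged as not detected.
    """
    if heavy_trace.n_points == 0:
        return None
    y = heavy_trace.summed()
    apex = int(np.argmax(y))
    if y[apex] <= 0:
        return None
    cut = threshold_frac * y[apex]
    lo = apex
    while lo > 0 and y[lo - 1] >= cut:
        lo -= 1
    hi = apex
    while hi < len(y) - 1 and y[hi + 1] >= cut:
        hi += 1
    return float(heavy_trace.times[lo]), float(heavy_trace.times[hi])


def integrate(
    times: np.ndarray, intensities: np.ndarray, boundaries: tuple[float, float]
) -> float:
    """Trapezoidal area of a trace within [start, end]; <2 points → 0."""
    start, end = boundaries
    if start >= end:
        raise ValueError("boundary start must precede end")
    sel = (times >= start) & (times <= end)
    if sel.sum() < 2:
        return 0.0
    return float(np.trapezoid(intensities[sel], times[sel]))


def tic_normalize(areas: pd.DataFrame, run_tic_areas: pd.Series) -> pd.DataFrame:
    """Scale-preserving TIC normalization across runs.

    ``areas`` is indexed by sample/run (rows) with arbitrary value columns;
    each row is divided by its run's TIC chromatogram area and multiplied by
    the median TIC area across runs, so a uniform intensity scaling of one
    run cancels while the overall magnitude stays on the raw scale.
    """
    tics = run_tic_areas.reindex(areas.index)
    if tics.isna().any():
        missing = list(areas.index[tics.isna()])
        raise ValueError(f"no TIC area for runs {missing}")
    if (tics <= 0).any():
        bad = list(areas.index[tics <= 0])
        raise ValueError(f"zero or negative TIC area for runs {bad}")
    anchor = float(np.median(run_tic_areas.to_numpy()))
    return areas.div(tics, axis=0) * anchor


def protein_rollup(peptide_values: pd.DataFrame, peptide_to_protein: pd.Series
                   ) -> pd.DataFrame:
    """Average available peptide values into protein values per sample.

    ``peptide_values``: samples x peptides (NaN = missing). A protein with
    no quantified peptide in a sample stays missing, never zero.
    """
    groups = peptide_to_protein.reindex(peptide_values.columns)
    if groups.isna().any():
        unknown = list(peptide_values.columns[groups.isna()])
        raise ValueError(f"peptides with no protein mapping: {unknown}")
    return peptide_values.T.groupby(groups).mean().T


def rescale_0_100(protein_values: pd.DataFrame) -> pd.DataFrame:
    """Min-max rescale each protein to [0, 100] across samples.

    Columns are proteins, rows samples. NaN entries stay NaN. A protein with
    fewer than 2 non-missing values is passed through unchanged; a constant
    series maps to all zeros with a warning.
    """
    out = protein_values.copy().astype(float)
    for col in out.columns:
        v = out[col]
        n = v.notna().sum()
        if n < 2:
            continue
        lo, hi = v.min(), v.max()
        if hi == lo:
            warnings.warn(f"protein {col}: constant values, rescaled to 0",
                          stacklevel=2)
            out[col] = v.where(v.isna(), 0.0)
        else:
            out[col] = (v - lo) / (hi - lo) * 100.0
    return out


def completeness_matrix(
    quant: pd.DataFrame,
    value_col: str = "normalized_area",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """log2 peptide x sample and protein x sample matrices.

    ``quant`` is the long-format quantification table with columns
    sample, protein, pair_id and ``value_col``. Missing (NaN or undetected)
    cells remain NaN — never -inf.
    """
    pep = quant.pivot_table(
        index="pair_id", columns="sample", values=value_col, aggfunc="first",
        dropna=False,
    )
    pep_log = np.log2(pep.where(pep > 0))
    wide = quant.pivot_table(
        index="sample", columns="pair_id", values=value_col, aggfunc="first",
        dropna=False,
    )
    mapping = quant.drop_duplicates("pair_id").set_index("pair_id")["protein"]
    prot = protein_rollup(wide, mapping)
    prot_log = np.log2(prot.where(prot > 0)).T
    return pep_log, prot_log


def quantify_run(
    run: RunRecord,
    panel: Panel,
    tol_ppm: float = 20.0,
    boundary_frac: float = 0.05,
) -> pd.DataFrame:
    """Full per-run quantification report (one row per heavy/light pair).

    Columns: sample (run index), protein, pair_id, detected, boundary_start,
    boundary_end, apex_rt (heavy summed-trace argmax time), per-pair light
    total fragment area (sum of transition areas), heavy total area,
    n_nonzero_transitions (light transitions with positive area),
    points_per_peak (QUANT_MS2 scans inside the boundaries) and window_s
    (last minus first quant-scan time inside the boundaries).
    """
    traces = extract_traces(run, panel, tol_ppm)
    rows = []
    for heavy, light in panel.pairs():
        htr = traces[heavy.spec_id]
        ltr = traces[light.spec_id]
        bounds = detect_boundaries(htr, boundary_frac)
        row = {
            "sample": run.run_index,
            "protein": heavy.protein_id,
            "pair_id": heavy.pair_id,
            "detected": bounds is not None,
            "boundary_start": np.nan,
            "boundary_end": np.nan,
            "apex_rt": np.nan,
            "total_area": np.nan,
            "heavy_total_area": np.nan,
            "n_nonzero_transitions": 0,
            "points_per_peak": 0,
            "window_s": np.nan,
        }
        if bounds is not None:
            start, end = bounds
            hy = htr.summed()
            row["apex_rt"] = float(htr.times[int(np.argmax(hy))])
            # degenerate single-scan boundary: widen by half a point spacing
            if start == end:
                start -= 1e-9
                end += 1e-9
            row["boundary_start"], row["boundary_end"] = start, end
            areas = [
                integrate(ltr.times, ltr.intensities[:, j], (start, end))
                for j in range(ltr.intensities.shape[1])
            ] if ltr.n_points else []
            row["total_area"] = float(np.sum(areas)) if areas else 0.0
            row["n_nonzero_transitions"] = int(np.sum(np.array(areas) > 0))
            hareas = [
                integrate(htr.times, htr.intensities[:, j], (start, end))
                for j in range(htr.intensities.shape[1])
            ]
            row["heavy_total_area"] = float(np.sum(hareas))
            qt = np.array([t for t in ltr.times if start <= t <= end])
            row["points_per_peak"] = int(len(qt))
            row["window_s"] = float(qt[-1] - qt[0]) if len(qt) else np.nan
        # quantification relies on >= 3 transitions with signal
        row["quantifiable"] = bool(row["detected"]) and row[
            "n_nonzero_transitions"] >= 3
        rows.append(row)
    return pd.DataFrame(rows)
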