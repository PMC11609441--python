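"""Multiplex bead-immunoassay calibration math used for orthogonal validation.

Implements the five-parameter logistic (5PL) standard curve

    MFI(x) = d + (a - d) / (1 + (x / c)^b)^g

with a/d the asymptotes at zero/infinite concentration, c the inflection
concentration, b the slope and g the asymmetry, together with the
plate-validation rules applied to 7-point triplicate standard series:

* replication — a standard whose replicate %CV exceeds 10% is removed;
* flattening — if the highest (lowest) standard's net MFI is within 10% of
  its neighbor, it is removed as saturated;
* recovery — a standard whose back-calculated concentration falls outside
  80-120% of nominal after fitting is removed for poor model fit.

Rules are applied in the order CV → flattening → fit → recovery → refit,
refitting after any removal; at least 5 valid standards are required for a
usable curve. Sample wells are back-calculated through the analytic 5PL
inverse times the dilution factor; wells whose net MFI falls outside the
MFI range covered by the surviving standards are censored with a side
indicator rather than extrapolated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

MIN_VALID_STANDARDS = 5
CV_LIMIT_PCT = 10.0
FLATTENING_PCT = 10.0
RECOVERY_RANGE_PCT = (80.0, 120.0)


@dataclass(frozen=True)
class FivePL:
    a: float  # asymptote at zero concentration
    d: float  # asymptote at infinite concentration
    c: float  # inflection concentration
    b: float  # slope
    g: float  # asymmetry

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        out = self.d + (self.a - self.d) / (1.0 + (x / self.c) ** self.b) ** self.g
        return out if out.ndim else float(out)

    def inverse(self, y: float) -> float:
        """Analytic inverse on the curve's monotone range."""
        lo, hi = sorted((self.a, self.d))
        if not lo < y < hi:
            raise ValueError(f"MFI {y} outside the asymptote range ({lo}, {hi})")
        ratio = (self.a - self.d) / (y - self.d)
        return self.c * (ratio ** (1.0 / self.g) - 1.0) ** (1.0 / self.b)


@dataclass
class StandardPoint:
    concentration: float  # nominal, pg/ml
    mfis: list[float]  # replicate net-zero raw MFIs (background included)
    background: float = 0.0

    @property
    def net_mfi(self) -> float:
        return float(np.mean(self.mfis)) - self.background

    @property
    def cv_pct(self) -> float:
        m = float(np.mean(self.mfis))
        if m == 0:
            return 0.0
        return float(np.std(self.mfis, ddof=1) / m * 100.0)


@dataclass
class StandardVerdict:
    concentration: float
    kept: bool
    reason: str = ""  # 'cv' | 'flattening' | 'recovery' when removed
    recovery_pct: float | None = None


def fit_5pl(standards: list[StandardPoint]) -> FivePL:
    """Least-squares 5PL fit of net MFI against concentration.

    Fitted on a log-concentration axis internally for conditioning, with the
    documented deterministic initializer (a = min net MFI, d = max, c =
    geometric mid of the concentrations, b = 1, g = 1); orientation-agnostic
    (decreasing curves fit with b*g < 0).
    """
    if len(standards) < MIN_VALID_STANDARDS:
        raise ValueError(
            f"need >= {MIN_VALID_STANDARDS} standards, got {len(standards)}"
        )
    x = np.array([s.concentration for s in standards], dtype=float)
    y = np.array([s.net_mfi for s in standards], dtype=float)
    if x.min() <= 0:
        raise ValueError("standard concentrations must be positive")
    if x.max() / x.min() <= 10.0:
        raise ValueError("standards must span more than one decade")
    lx = np.log(x)
    scale = max(abs(y).max(), 1.0)

    def model(p, lxv):
        a, d, lc, b, g = p
        with np.errstate(over="ignore"):  # exp overflow -> asymptote, fine
            return d + (a - d) / (1.0 + np.exp(b * (lxv - lc))) ** np.exp(g)

    def resid(p):
        return (model(p, lx) - y) / scale

    # orientation lives in (a, d): a is the level approached at x -> 0,
    # so a decreasing curve simply has a > d; b stays positive initially
    increasing = y[np.argmax(x)] >= y[np.argmin(x)]
    a0, d0 = (y.min(), y.max()) if increasing else (y.max(), y.min())
    p0 = np.array([a0, d0, float(np.mean(lx)), 1.0, 0.0])
    sol = least_squares(resid, p0, method="lm", xtol=1e-12, ftol=1e-12,
                        max_nfev=20000)
    rms = float(np.sqrt(np.mean(sol.fun**2)))
    if not sol.success or not np.all(np.isfinite(sol.x)):
        raise RuntimeError(
            f"5PL fit did not converge (status {sol.status}, "
            f"relative residual RMS {rms:.3g})"
        )
    a, d, lc, b, g = sol.x
    return FivePL(float(a), float(d), float(np.exp(lc)), float(b),
                  float(np.exp(g)))


@dataclass
class CurveResult:
    fit: FivePL | None
    surviving: list[StandardPoint]
    verdicts: list[StandardVerdict]
    valid: bool


def validate_standards(standards: list[StandardPoint]) -> CurveResult:
    """Apply the exclusion rules and return the surviving calibration.

    Order: replicate-CV removals first, then end-point flattening, then an
    initial fit whose per-standard recoveries drive the poor-fit rule, then
    a final refit on the survivors. A curve with fewer than
    5 surviving standards is flagged invalid (fit = None).
    """
    verdicts: dict[float, StandardVerdict] = {
        s.concentration: StandardVerdict(s.concentration, True)
        for s in standards
    }

    def drop(s: StandardPoint, reason: str, recovery: float | None = None):
        v = verdicts[s.concentration]
        v.kept = False
        v.reason = reason
        v.recovery_pct = recovery

    pool = sorted(standards, key=lambda s: s.concentration)
    # 1) replication
    keep = []
    for s in pool:
        if len(s.mfis) > 1 and s.cv_pct > CV_LIMIT_PCT:
            drop(s, "cv")
        else:
            keep.append(s)
    pool = keep
    # 2) flattening at the curve ends
    for end, neighbor in ((-1, -2), (0, 1)):
        if len(pool) >= 2:
            rel = abs(pool[end].net_mfi - pool[neighbor].net_mfi)
            base = abs(pool[neighbor].net_mfi)
            if base > 0 and rel / base * 100.0 < FLATTENING_PCT:
                drop(pool[end], "flattening")
                pool.pop(end if end == -1 else 0)
    # 3) fit and recovery
    fit = None
    if len(pool) >= MIN_VALID_STANDARDS:
        fit = fit_5pl(pool)
        lo, hi = RECOVERY_RANGE_PCT
        keep = []
        for s in pool:
            try:
                back = fit.inverse(s.net_mfi)
                rec = back / s.concentration * 100.0
            except ValueError:
                rec = float("nan")
            if not np.isfinite(rec) or not lo <= rec <= hi:
                drop(s, "recovery", rec)
            else:
                verdicts[s.concentration].recovery_pct = rec
                keep.append(s)
        pool = keep
        # 4) refit on survivors
        fit = fit_5pl(pool) if len(pool) >= MIN_VALID_STANDARDS else None
    valid = fit is not None and len(pool) >= MIN_VALID_STANDARDS
    return CurveResult(fit if valid else None, pool,
                       [verdicts[s.concentration]
                        for s in sorted(standards, key=lambda x: x.concentration)],
                       valid)


def in_working_range(
    net_mfi: float, fit: FivePL, low: float = 0.10, high: float = 0.90
) -> bool:
    """Whether a response sits in the curve's working range.

    The working range is where the net MFI lies between ``low`` and ``high``
    of the span between the asymptotes — outside it, the curve flattens and
    back-calculation becomes ill-conditioned.
    """
    lo, hi = sorted((fit.a, fit.d))
    frac = (net_mfi - lo) / (hi - lo)
    return low <= frac <= high


@dataclass
class BackCalcResult:
    concentration: float | None  # pg/ml, dilution-corrected
    censored: str = ""  # '', 'high' or 'low'


def back_calculate(
    net_mfi: float, fit: FivePL, dilution_factor: float = 1.0,
    mfi_range: tuple[float, float] | None = None,
) -> BackCalcResult:
    """Concentration from net MFI via the 5PL inverse, times the dilution.

    ``mfi_range`` (typically the net-MFI range covered by the surviving
    standards) censors out-of-range wells with a side indicator instead of
    extrapolating beyond the calibrated range.
    """
    lo, hi = mfi_range if mfi_range is not None else sorted((fit.a, fit.d))
    upward = fit(fit.c * 4) > fit(fit.c / 4)
    if net_mfi >= hi:
        return BackCalcResult(None, "high" if upward else "low")
    if net_mfi <= lo:
        return BackCalcResult(None, "low" if upward else "high")
    return BackCalcResult(fit.inverse(net_mfi) * dilution_factor, "")


@dataclass
class SampleWell:
    sample_id: str
    analyte: str
    dilution: float
    mfis: list[float]
    background: float = 0.0

    @property
    def net_mfi(self) -> float:
        return float(np.mean(self.mfis)) - self.background

    @property
    def cv_pct(self) -> float:
        m = float(np.mean(self.mfis))
        if m == 0:
            return 0.0
        return float(np.std(self.mfis, ddof=1) / m * 100.0)


@dataclass
class SampleMeasurement:
    well: SampleWell
    kept: bool
    reason: str
    result: BackCalcResult | None
    flag: str = ""


def validate_samples(
    wells: list[SampleWell], curve: CurveResult
) -> list[SampleMeasurement]:
    """Back-calculate sample wells, dropping poor replicates and censoring
    out-of-range MFIs. A well with a single surviving replicate is kept but
    flagged 'singleton'."""
    out = []
    if not curve.valid or curve.fit is None:
        return [
            SampleMeasurement(w, False, "no valid standard curve", None)
            for w in wells
        ]
    mfis = [s.net_mfi for s in curve.surviving]
    mfi_range = (min(mfis), max(mfis))
    for w in wells:
        if len(w.mfis) > 1 and w.cv_pct > CV_LIMIT_PCT:
            out.append(SampleMeasurement(w, False, "replicate CV > 10%", None))
            continue
        res = back_calculate(w.net_mfi, curve.fit, w.dilution, mfi_range)
        if res.censored:
            out.append(
                SampleMeasurement(w, False, f"net MFI censored {res.censored}",
                                  res)
            )
            continue
        flag = "singleton" if len(w.mfis) == 1 else ""
        out.append(SampleMeasurement(w, True, "", res, flag))
    return out


@dataclass
class SimulatedPlate:
    standards: dict[str, list[StandardPoint]]  # analyte -> 7-point series
    samples: dict[str, list[SampleWell]]  # analyte -> duplicate wells
    truth: dict[str, FivePL]
    true_concentrations: dict[str, float]
    background: float
    no_standard_analytes: tuple[str, ...]


def simulate_plate(
    true_concentrations: dict[str, float],
    fivepl_truth: dict[str, FivePL],
    noise_cv: float = 0.02,
    seed: int = 0,
    dilutions: tuple[float, ...] = (50.0, 500.0, 10_000.0),
    top_standard: dict[str, float] | None = None,
    n_standards: int = 7,
    standard_step: float = 4.0,
    background: float = 20.0,
    no_standard_analytes: tuple[str, ...] = (),
) -> SimulatedPlate:
    """Simulate a calibration plate: triplicate 7-point standards (serial
    ``standard_step``-fold dilutions from the top standard) and duplicate
    sample wells at the given dilution factors. MFIs are
    truth(concentration) x lognormal(noise_cv) + background. Analytes in
    ``no_standard_analytes`` get sample wells but no standard series,
    mirroring panels where a reference standard is unavailable.
    """
    rng = np.random.default_rng(seed & 0x7FFFFFFF)
    sigma = np.sqrt(np.log1p(noise_cv**2)) if noise_cv > 0 else 0.0

    def mfi(curve: FivePL, conc: float) -> float:
        base = curve(conc)
        if sigma > 0:
            base = base * rng.lognormal(-0.5 * sigma**2, sigma)
        return float(base + background)

    standards: dict[str, list[StandardPoint]] = {}
    sample_wells: dict[str, list[SampleWell]] = {}
    for analyte, conc in true_concentrations.items():
        curve = fivepl_truth[analyte]
        if analyte not in no_standard_analytes:
            top = (top_standard or {}).get(analyte, conc * standard_step**3)
            series = []
            for i in range(n_standards):
                std_conc = top / standard_step**i
                reps = [mfi(curve, std_conc) for _ in range(3)]
                series.append(StandardPoint(std_conc, reps, background))
            standards[analyte] = series
        wells = []
        for dil in dilutions:
            reps = [mfi(curve, conc / dil) for _ in range(2)]
            wells.append(SampleWell("S1", analyte, dil, reps, background))
        sample_wells[analyte] = wells
    return SimulatedPlate(standards, sample_wells, dict(fivepl_truth),
                          dict(true_concentrations), background,
                          no_standard_analytes)


#: Specificity-test target concentrations (pg/ml) for the recombinant
#: biomarker mix, usable as a test fixture.
SPECIFICITY_TEST_CONCENTRATIONS: dict[str, float] = {
    "COL1A1": 260.0,
    "FN1": 59_100.0,
    "IL1B": 316.0,
    "MMP2": 5416.0,
    "MMP9": 2108.0,
    "S100A8": 1205.0,
    "S100A9": 426.0,
    "TNFA": 143.0,
}
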