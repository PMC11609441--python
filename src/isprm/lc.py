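"""Chromatography model: gradients, elution peaks, retention-time drift.

The standardized high-throughput LC methods are modeled by their active
gradient length and injection-to-injection cycle time: 100 samples/day uses
an 11.5 min gradient (14.4 min cycle), 60 samples/day a 22 min gradient.
Retention times are predicted by a deterministic affine map of the
Kyte-Doolittle hydropathy onto the central part of the gradient — a
reproducible stand-in for observed elution, not a physical model. Heavy and
light partners always share the same elution profile shape and apex, which
is what makes internal-standard anchoring work.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from . import chem

#: Peaks are treated as zero beyond this many sigma from the apex; the
#: neglected area is below 1e-5 of the total.
TRUNCATION_SIGMAS = 5.0


@dataclass(frozen=True)
class GradientMethod:
    name: str
    active_gradient_length: float  # s
    cycle_time: float  # s, injection to injection
    flow_rate_ul_min: float | None = None  # informational

    def __post_init__(self):
        if self.cycle_time < self.active_gradient_length:
            raise ValueError("cycle_time must be >= active_gradient_length")


#: 100 samples/day: 11.5 min active gradient, 14.4 min cycle.
GRADIENT_100SPD = GradientMethod("100SPD", 690.0, 864.0, 1.5)
#: 60 samples/day: 22 min active gradient, 24 min cycle.
GRADIENT_60SPD = GradientMethod("60SPD", 1320.0, 1440.0, None)

GRADIENTS = {"100spd": GRADIENT_100SPD, "60spd": GRADIENT_60SPD}

#: Default Gaussian peak sigma on the 100SPD gradient (s). Gives ~14.7 s
#: peak width at 5% height and ~7 quantitative scans per peak at a 2 s
#: duty cycle; scaled by gradient-length ratio for other methods.
DEFAULT_SIGMA_100SPD = 3.0


@dataclass(frozen=True)
class ElutionProfile:
    """Gaussian elution peak of one peptide species in one run."""

    peptide_id: str
    apex_rt: float  # s
    sigma: float  # s
    amplitude: float  # arbitrary intensity units
    tail: float = 1.0  # right-side sigma multiplier; 1 = symmetric

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be nonnegative")


@dataclass(frozen=True)
class DriftModel:
    """Run-to-run retention-time instability over a long sample sequence."""

    jitter_sd: float = 0.0  # per-run random apex shift SD (s)
    linear_per_run: float = 0.0  # slow systematic drift (s per run)
    seed: int = 0

    def __post_init__(self):
        if self.jitter_sd < 0:
            raise ValueError("jitter SD must be nonnegative")


def predict_rt(sequence: str, gradient: GradientMethod) -> float:
    """Deterministic apex retention time (s) for a peptide sequence.

    Affine map of the GRAVY score (clamped to [-4.5, 4.5]) onto
    [0.1, 0.9] x active gradient length, plus a tiny mass-derived term that
    separates peptides with identical hydropathy. Depends on the sequence
    only, so heavy/light partners co-elute exactly.
    """
    g = max(-4.5, min(4.5, chem.gravy(sequence)))
    mean_mass = chem.peptide_mass(sequence) / len(sequence)
    tiebreak = 1e-4 * (mean_mass - 110.0)
    frac = 0.1 + 0.8 * (g + 4.5) / 9.0 + tiebreak
    frac = max(0.02, min(0.98, frac))
    return frac * gradient.active_gradient_length


def peak_intensity(profile: ElutionProfile, t: float | np.ndarray):
    """Peak height at time t: truncated (optionally asymmetric) Gaussian."""
    t = np.asarray(t, dtype=float)
    dt = t - profile.apex_rt
    sigma = np.where(dt > 0, profile.sigma * profile.tail, profile.sigma)
    z = dt / sigma
    out = profile.amplitude * np.exp(-0.5 * z * z)
    out = np.where(np.abs(z) > TRUNCATION_SIGMAS, 0.0, out)
    return out if out.ndim else float(out)


def peak_area(profile: ElutionProfile) -> float:
    """Closed-form area of the (untruncated) peak."""
    return (
        profile.amplitude
        * profile.sigma
        * (1.0 + profile.tail)
        / 2.0
        * math.sqrt(2.0 * math.pi)
    )


def default_sigma(gradient: GradientMethod) -> float:
    """Default peak sigma, scaled by gradient length relative to 100SPD."""
    return DEFAULT_SIGMA_100SPD * (
        gradient.active_gradient_length / GRADIENT_100SPD.active_gradient_length
    )


def apply_drift(
    profiles: list[ElutionProfile],
    run_index: int,
    drift: DriftModel,
    gradient: GradientMethod,
) -> list[ElutionProfile]:
    """Shift profile apexes for one run of a long sequence.

    apex' = apex + linear_per_run * run_index + N(0, jitter_sd), clipped to
    the active gradient. The random shift is drawn once per heavy/light pair
    (keyed on the pair identity, 'protein|sequence|charge'), so partners move
    together; the draw is a pure function of (seed, run_index), making whole
    sequences reproducible and individual runs independently addressable.
    """
    pair_ids = sorted({_pair_of(p.peptide_id) for p in profiles})
    rng = np.random.default_rng([drift.seed & 0x7FFFFFFF, run_index])
    jitter = {
        pid: rng.normal(0.0, drift.jitter_sd) if drift.jitter_sd > 0 else 0.0
        for pid in pair_ids
    }
    out = []
    for p in profiles:
        shift = drift.linear_per_run * run_index + jitter[_pair_of(p.peptide_id)]
        apex = min(max(p.apex_rt + shift, 0.0), gradient.active_gradient_length)
        out.append(replace(p, apex_rt=apex))
    return out


def _pair_of(spec_id: str) -> str:
    # 'protein|sequence|charge|H' -> 'protein|sequence|charge'
    return spec_id.rsplit("|", 1)[0] if spec_id.count("|") >= 3 else spec_id
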