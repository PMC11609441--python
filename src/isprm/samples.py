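"""Synthetic-sample ground truth and signal rendering.

Emulates the measurement situation the assay is built for: a small protein
panel whose concentrations span many orders of magnitude in a complex
matrix, a constant heavy internal-standard spike per run, and matrix
background ions in MS2 spectra. Per-protein median concentrations are
placed on an even log-spaced grid across the requested span; each sample
draws lognormal biological variation around the medians. Each light peptide
carries a fixed lognormal response factor (its ionization/digestion
efficiency surrogate), so that light signal = concentration x response,
while heavy signal is the same constant spike in every run.

Separate named RNG streams are derived for ground truth, shot noise and
background so toggling one concern leaves the others bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lc import ElutionProfile, peak_intensity
from .panel import Panel

#: Named substreams spawned from the experiment seed.
STREAMS = ("ground_truth", "noise", "background", "drift")


def spawn_streams(seed: int) -> dict[str, np.random.SeedSequence]:
    """One independent SeedSequence per simulation concern."""
    children = np.random.SeedSequence(seed & 0x7FFFFFFF).spawn(len(STREAMS))
    return dict(zip(STREAMS, children))


@dataclass
class GroundTruth:
    """Per-sample protein concentrations and per-peptide response factors."""

    proteins: list[str]
    medians: pd.Series  # protein -> median concentration (relative units)
    concentrations: pd.DataFrame  # samples x proteins, realized values
    response: pd.Series  # pair_id -> response factor
    is_amplitude: float  # heavy spike apex intensity, identical everywhere
    amplitude_scale: float  # intensity units per concentration unit
    seed: int

    def light_amplitude(self, sample: int, pair_id: str, protein: str) -> float:
        return (
            float(self.concentrations.loc[sample, protein])
            * float(self.response[pair_id])
            * self.amplitude_scale
        )


def generate_ground_truth(
    panel: Panel,
    log10_span: float = 7.0,
    n_samples: int = 42,
    seed: int = 0,
    bio_sigma_ln: float = 0.3,
    response_sigma_ln: float = 0.2,
    is_amplitude: float = 1.0e6,
    amplitude_scale: float = 100.0,
) -> GroundTruth:
    """Draw the ground truth for a cohort of synthetic samples.

    Protein medians are 10**linspace(0, log10_span, n_proteins) — an even
    log grid whose extremes realize the requested span exactly. Per-sample
    concentrations multiply the median by lognormal(0, bio_sigma_ln)
    biological variation; per-peptide response factors are
    lognormal(0, response_sigma_ln), fixed across samples.
    """
    if log10_span < 0:
        raise ValueError("log10_span must be >= 0")
    proteins = panel.proteins()
    if not proteins:
        raise ValueError("empty panel")
    n_prot = len(proteins)
    if n_prot == 1:
        medians = np.array([10.0 ** (log10_span / 2.0)])
    else:
        medians = 10.0 ** np.linspace(0.0, log10_span, n_prot)
    rng = np.random.default_rng(spawn_streams(seed)["ground_truth"])
    conc = medians[None, :] * rng.lognormal(
        0.0, bio_sigma_ln, size=(n_samples, n_prot)
    )
    pair_ids = [h.pair_id for h, _ in panel.pairs()]
    resp = rng.lognormal(0.0, response_sigma_ln, size=len(pair_ids))
    return GroundTruth(
        proteins=proteins,
        medians=pd.Series(medians, index=proteins),
        concentrations=pd.DataFrame(conc, columns=proteins),
        response=pd.Series(resp, index=pair_ids),
        is_amplitude=is_amplitude,
        amplitude_scale=amplitude_scale,
        seed=seed,
    )


def fragment_weights(n: int, decay: float = 0.85) -> np.ndarray:
    """Fixed per-peptide relative transition abundances (sum to 1)."""
    w = decay ** np.arange(n)
    return w / w.sum()


@dataclass
class SignalSet:
    """Vectorized per-run ground-truth signal: every species' peak + transitions.

    One entry per PeptideSpec (heavy and light). Transition intensity at
    time t is amplitude x Gaussian(t) x fragment weight; precursor (MS1)
    intensity is amplitude x Gaussian(t).
    """

    spec_ids: list[str]
    precursor_mz: np.ndarray  # (n,)
    apex: np.ndarray  # (n,)
    sigma: np.ndarray  # (n,)
    amplitude: np.ndarray  # (n,)
    transition_mz: list[np.ndarray]  # per spec, (n_transitions,)
    weights: list[np.ndarray]  # per spec, sums to 1
    is_heavy: np.ndarray = field(default_factory=lambda: np.array([], bool))
    index: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if not self.index:
            self.index = {sid: i for i, sid in enumerate(self.spec_ids)}

    def precursor_intensity(self, t: float) -> np.ndarray:
        z = (t - self.apex) / self.sigma
        out = self.amplitude * np.exp(-0.5 * z * z)
        out[np.abs(z) > 5.0] = 0.0
        return out

    def transition_intensity(self, i: int, t: float) -> np.ndarray:
        z = (t - self.apex[i]) / self.sigma[i]
        if abs(z) > 5.0:
            return np.zeros_like(self.weights[i])
        return self.amplitude[i] * np.exp(-0.5 * z * z) * self.weights[i]


def render_signals(
    truth: GroundTruth,
    panel: Panel,
    profiles: dict[str, ElutionProfile],
    sample: int,
) -> SignalSet:
    """Assemble the noiseless signal model for one sample/run.

    ``profiles`` maps spec_id to that run's (possibly drifted) elution
    profile; profile amplitudes are ignored in favor of the ground truth
    (IS spike for heavy species, concentration x response for light).
    """
    spec_ids, pmz, apex, sigma, amp, tmz, wts, heavy = [], [], [], [], [], [], [], []
    for p in panel.peptides:
        prof = profiles.get(p.spec_id)
        if prof is None:
            raise KeyError(f"no elution profile for {p.spec_id}")
        spec_ids.append(p.spec_id)
        pmz.append(p.precursor_mz)
        apex.append(prof.apex_rt)
        sigma.append(prof.sigma)
        if p.is_heavy:
            amp.append(truth.is_amplitude)
        else:
            amp.append(truth.light_amplitude(sample, p.pair_id, p.protein_id))
        tmz.append(np.array(p.transition_mzs()))
        wts.append(fragment_weights(len(p.transitions)))
        heavy.append(p.is_heavy)
    return SignalSet(
        spec_ids=spec_ids,
        precursor_mz=np.array(pmz),
        apex=np.array(apex),
        sigma=np.array(sigma),
        amplitude=np.array(amp),
        transition_mz=tmz,
        weights=wts,
        is_heavy=np.array(heavy, dtype=bool),
    )


@dataclass(frozen=True)
class NoiseModel:
    """Detector noise: multiplicative lognormal shot noise + detection floor.

    ``cv`` is the coefficient of variation of centroid intensities;
    ``baseline`` is an additive offset; centroids below ``floor`` are
    dropped, giving the simulator a genuine sensitivity limit.
    """

    cv: float = 0.05
    baseline: float = 0.0
    floor: float = 50.0

    def apply(
        self, mz: np.ndarray, intensity: np.ndarray, rng: np.random.Generator
    ) -> tuple[np.ndarray, np.ndarray]:
        if len(intensity) == 0:
            return mz, intensity
        out = intensity.astype(float).copy()
        if self.cv > 0:
            sigma = np.sqrt(np.log1p(self.cv**2))
            out = out * rng.lognormal(-0.5 * sigma**2, sigma, size=out.shape)
        out = out + self.baseline
        keep = out >= self.floor
        return mz[keep], out[keep]


NOISELESS = NoiseModel(cv=0.0, baseline=0.0, floor=0.0)


@dataclass(frozen=True)
class BackgroundModel:
    """Matrix background ions added to MS2 spectra.

    A Poisson number of centroids per scan; a configurable fraction are
    'interferents' placed within the fragment tolerance of randomly chosen
    true transitions, the rest uniform over the MS2 m/z range. Intensities
    are lognormal.
    """

    mean_ions_per_scan: float = 20.0
    mz_range: tuple[float, float] = (200.0, 1500.0)
    intensity_median: float = 30.0
    intensity_sigma_ln: float = 1.0
    interferent_fraction: float = 0.05
    interferent_tol_ppm: float = 20.0

    def __post_init__(self):
        if self.mean_ions_per_scan < 0:
            raise ValueError("ion count must be >= 0")
        if not 0.0 <= self.interferent_fraction <= 1.0:
            raise ValueError("interferent fraction must be in [0, 1]")


NO_BACKGROUND = BackgroundModel(mean_ions_per_scan=0.0)


def sample_background(
    model: BackgroundModel,
    rng: np.random.Generator,
    true_transition_mz: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw one scan's background centroids: (mz, intensity) arrays."""
    n = int(rng.poisson(model.mean_ions_per_scan))
    if n == 0:
        return np.empty(0), np.empty(0)
    lo, hi = model.mz_range
    mz = rng.uniform(lo, hi, size=n)
    if (
        true_transition_mz is not None
        and len(true_transition_mz)
        and model.interferent_fraction > 0
    ):
        is_interf = rng.random(n) < model.interferent_fraction
        k = int(is_interf.sum())
        if k:
            targets = rng.choice(true_transition_mz, size=k)
            tol = targets * model.interferent_tol_ppm * 1e-6
            mz[is_interf] = targets + rng.uniform(-1.0, 1.0, size=k) * tol
    intensity = model.intensity_median * rng.lognormal(
        0.0, model.intensity_sigma_ln, size=n
    )
    return mz, intensity
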