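"""End-to-end orchestration: panel → signals → acquisition → quantification.

Ties the modules together for multi-sample experiments: per-run elution
profiles (with drift), ground-truth rendering, triggered or scheduled
acquisition, per-run quantification, TIC normalization, protein rollup and
0-100 rescaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import acquisition, lc, quant, samples
from .acquisition import AcquisitionParams, RunRecord
from .lc import DriftModel, ElutionProfile, GradientMethod, GRADIENT_100SPD
from .panel import Panel, default_panel
from .samples import BackgroundModel, GroundTruth, NoiseModel, SignalSet


def base_profiles(
    panel: Panel, gradient: GradientMethod, sigma: float | None = None
) -> list[ElutionProfile]:
    """Nominal (undrifted) elution profiles for every panel species.

    Amplitudes are placeholders (1.0); the ground truth supplies them at
    rendering time. Heavy/light partners share apex and sigma by
    construction since the predictor sees only the sequence.
    """
    sigma = lc.default_sigma(gradient) if sigma is None else sigma
    return [
        ElutionProfile(p.spec_id, lc.predict_rt(p.sequence, gradient), sigma, 1.0)
        for p in panel.peptides
    ]


def profiles_for_run(
    panel: Panel,
    gradient: GradientMethod,
    run_index: int,
    drift: DriftModel | None = None,
    sigma: float | None = None,
) -> dict[str, ElutionProfile]:
    profs = base_profiles(panel, gradient, sigma)
    if drift is not None:
        profs = lc.apply_drift(profs, run_index, drift, gradient)
    return {p.peptide_id: p for p in profs}


def scheduled_windows(
    panel: Panel, gradient: GradientMethod, half_width_s: float = 15.0
) -> dict[str, tuple[float, float]]:
    """Static scheduled-PRM windows: nominal apex ± half_width per light."""
    out = {}
    for p in panel.lights():
        apex = lc.predict_rt(p.sequence, gradient)
        out[p.spec_id] = (apex - half_width_s, apex + half_width_s)
    return out


@dataclass
class ExperimentResult:
    panel: Panel
    truth: GroundTruth
    quant_table: pd.DataFrame  # long format, one row per pair per sample
    protein_values: pd.DataFrame  # samples x proteins, TIC-normalized means
    rescaled: pd.DataFrame  # samples x proteins on the 0-100 scale
    runs: list[RunRecord] = field(default_factory=list)  # kept on request


def simulate_experiment(
    n_samples: int = 42,
    seed: int = 0,
    panel: Panel | None = None,
    gradient: GradientMethod = GRADIENT_100SPD,
    params: AcquisitionParams | None = None,
    drift: DriftModel | None = None,
    noise: NoiseModel | None = None,
    background: BackgroundModel | None = None,
    log10_span: float = 7.0,
    mode: str = "surequant",
    window_half_width_s: float = 15.0,
    keep_runs: bool = False,
    truth: GroundTruth | None = None,
) -> ExperimentResult:
    """Simulate and quantify a cohort of samples under one acquisition mode."""
    panel = panel or default_panel()
    params = params or AcquisitionParams()
    noise = NoiseModel() if noise is None else noise
    background = BackgroundModel() if background is None else background
    if truth is None:
        truth = samples.generate_ground_truth(
            panel, log10_span=log10_span, n_samples=n_samples, seed=seed
        )
    streams = samples.spawn_streams(seed)
    noise_rng = np.random.default_rng(streams["noise"])
    drift = drift or DriftModel(seed=seed)
    windows = scheduled_windows(panel, gradient, window_half_width_s)
    tables = []
    runs: list[RunRecord] = []
    tic_areas = {}
    for i in range(n_samples):
        profiles = profiles_for_run(panel, gradient, i, drift)
        sig = samples.render_signals(truth, panel, profiles, i)
        if mode == "surequant":
            run = acquisition.run_surequant(
                sig, panel, params, gradient, noise, background, noise_rng, i
            )
        elif mode == "prm":
            run = acquisition.run_scheduled_prm(
                sig, panel, windows, params, gradient, noise, background,
                noise_rng, i,
            )
        else:
            raise ValueError(f"unknown mode {mode!r}")
        tables.append(quant.quantify_run(run, panel, params.fragment_tol_ppm))
        tic_areas[i] = run.tic_area()
        if keep_runs:
            runs.append(run)
    table = pd.concat(tables, ignore_index=True)
    table = _normalize_and_rollup(table, pd.Series(tic_areas), panel)
    prot = table.pivot_table(
        index="sample", columns="protein", values="protein_value",
        aggfunc="first", dropna=False,
    )
    rescaled = quant.rescale_0_100(prot)
    return ExperimentResult(panel, truth, table, prot, rescaled, runs)


def _normalize_and_rollup(
    table: pd.DataFrame, tic_areas: pd.Series, panel: Panel
) -> pd.DataFrame:
    """Attach TIC-normalized areas, protein rollups and detection flags."""
    table = table.copy()
    # undetected / unquantifiable pairs are missing, never zero
    values = table["total_area"].where(table["quantifiable"])
    wide = (
        table.assign(value=values)
        .pivot_table(index="sample", columns="pair_id", values="value",
                     aggfunc="first", dropna=False)
    )
    wide_norm = quant.tic_normalize(wide, tic_areas)
    mapping = table.drop_duplicates("pair_id").set_index("pair_id")["protein"]
    prot = quant.protein_rollup(wide_norm, mapping)
    long_norm = wide_norm.stack(future_stack=True).rename("normalized_area")
    table = table.merge(
        long_norm.reset_index().rename(columns={"level_1": "pair_id"}),
        on=["sample", "pair_id"],
        how="left",
    )
    long_prot = prot.stack(future_stack=True).rename("protein_value")
    table = table.merge(
        long_prot.reset_index().rename(columns={"level_1": "protein"}),
        on=["sample", "protein"],
        how="left",
    )
    return table
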