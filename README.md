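# isprm — internal-standard-triggered PRM simulator and quantification toolkit

`isprm` is a desk-scale model of a triggered targeted-proteomics workflow
(IS-PRM, often called SureQuant-style acquisition) on a fast-LC
quadrupole-orbitrap platform. It is written for assay developers and
computational proteomics researchers who want to reason about — and test —
the *acquisition logic* and the *quantification chain* of such assays
without an instrument: how duty-cycle budgets, trigger thresholds,
retention-time drift and sensitivity floors shape data completeness, points
per peak and dynamic range.

## What it models

**Acquisition.** A stable-isotope-labeled (heavy) internal standard is
spiked into every sample at a constant amount. The instrument cycles every
2 s: a survey MS1 scan; for each heavy precursor detected in the MS1
centroids (10 ppm, above an intensity threshold) a fast low-resolution
*watch* MS2 scan on the heavy m/z; and, if at least 3 of the expected heavy
product ions match within 20 ppm, a high-resolution, 250 ms-injection
*quantitative* MS2 scan in the same cycle at the offset precursor m/z

    m/z(light) = m/z(heavy) − Δ/z,   Δ = +8.014 Da (heavy Lys) or +10.008 Da (heavy Arg),

i.e. on the endogenous (light) peptide. A scheduled-PRM comparator fires
quantitative scans inside fixed retention-time windows instead, which is
exactly what breaks under run-to-run RT drift.

**Quantification.** Per-transition chromatograms are extracted from the
targeted scans at 20 ppm; integration boundaries are set where the summed
heavy trace stays above 5% of its apex (the automated analogue of curating
boundaries against the internal standard's retention time); light
transition areas are summed into a total fragment area per precursor,
normalized by the run's total-ion-current (TIC) chromatogram area, averaged
across a protein's peptides, and min-max rescaled to 0–100 per protein
across samples.

**Synthetic samples.** A 9-protein wound-biomarker panel (two tryptic
peptides each, heavy/light pairs, five y-ion transitions per precursor)
with per-protein median concentrations on an even log grid spanning 7
orders of magnitude, lognormal biological variation, Gaussian elution peaks
(σ = 3 s on the 11.5 min / 100 samples-per-day gradient), run-to-run RT
jitter and drift, lognormal shot noise, a detection floor, and Poisson
matrix background ions with configurable interferent placement.

**Immunoassay validation math.** The orthogonal-validation side: 5PL
standard curves `y = d + (a−d)/(1+(x/c)^b)^g`, the plate-validation rules
(replicate CV > 10%, end-standard flattening < 10%, recovery outside
80–120%), dilution-corrected back-calculation, and a plate simulator.

## Worked example

```bash
isprm demo --samples 42 --seed 7 --outdir demo_out
```

runs the full pipeline — panel design, 42 synthetic samples spanning 7
orders of magnitude, triggered acquisition on the 11.5 min gradient,
quantification, rollup — and prints:

```json
{
  "mean_points_per_peak": 6.361111111111111,
  "max_window_s": 12.0,
  "detected_log10_span": 6.125
}
```

Reading: each detected peptide's peak is covered by ~6–7 quantitative scans
(the 2 s duty cycle against ~15 s-wide peaks); every measurement window —
the time between the first and last triggered quantitative scan — stays
within 12 s, because scans are only fired while the internal standard is
actually eluting; and although the ground truth spans 7 orders of
magnitude, the lowest-abundance protein (the TNFA stand-in) falls below the
detection floor, so the *reliably quantified* panel spans 6.1 orders.
`demo_out/` also receives the panel transition list, the long-format
quantification table, protein values (raw and 0–100 rescaled), and log2
peptide/protein completeness matrices as CSV.

The library surface mirrors the pipeline: `build_panel` / `default_panel`
(panel design), `generate_ground_truth` + `render_signals` (synthetic
samples), `run_surequant` / `run_scheduled_prm` (acquisition),
`quantify_run`, `tic_normalize`, `protein_rollup`, `rescale_0_100`
(quantification), `points_per_peak`, `rt_stability`, `dynamic_range`,
`compare_modes` (metrics), and `fit_5pl`, `validate_standards`,
`back_calculate`, `simulate_plate` (immunoassay). CLI subcommands `panel`,
`simulate`, `acquire`, `quantify`, `immuno`, `metrics`, `demo` wrap the
same functions; scan tables are written as a scans CSV plus a long-format
centroid CSV, and the panel CSV is a Skyline-flavored transition list
(`protein, sequence, charge, is_heavy, precursor_mz, ion_type,
fragment_index, fragment_charge, fragment_mz`).

## Known limitations

The retention-time predictor is a hydropathy-based stand-in, not a physical
model; ion-population control (AGC) is recorded as metadata but not
simulated; FAIMS is not modeled; and raw vendor formats are out of scope
(the mzML export hook is a stub). See `docs/methods.md` for the full model
description, parameter defaults and design rationale.
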