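# Methods

## Scope and model overview

`isprm` simulates one acquisition strategy — internal-standard-triggered
parallel reaction monitoring on a quadrupole-orbitrap with short,
standardized LC gradients — end to end: from panel design over synthetic
signal generation and the discrete-event acquisition loop to the
quantification chain and the immunoassay calibration math used for
orthogonal validation. Everything is deterministic given a seed; all
randomness flows through named, independent RNG streams (`ground_truth`,
`noise`, `background`, `drift`) so toggling one concern leaves the others
bit-identical.

## Peptide chemistry

Monoisotopic residue masses come from pyteomics' NIST-derived tables.
Heavy-label deltas are computed, not stored: 6×(¹³C−¹²C) + 2×(¹⁵N−¹⁴N) =
8.0142 Da for C-terminal lysine and 6×(¹³C−¹²C) + 4×(¹⁵N−¹⁴N) = 10.0083 Da
for arginine, matching the conventional +8.014/+10.008 printed values to
three decimals. Carbamidomethyl-Cys (+57.021 Da) is a fixed modification on
every cysteine; oxidation (+15.995 Da) is defined but not applied by
default. Mass constants are stored at full float precision; tests compare
at three decimals, the printed precision of such values.

Tryptic digestion is an ordered partition (cleave after K/R), with the
proline rule (no cleavage before P) on by default and switchable — common
practice, and the candidate filter applies "no missed cleavages" afterwards
anyway. Candidate peptides for a panel must be 8–21 residues, methionine
free (oxidation would split the signal), fully tryptic at the C-terminus,
and free of missed cleavages; every violated rule is reported per peptide.

## Panel design

Real assay panels rank candidates by observed DDA intensity. To stay
reproducible without external spectral libraries, candidates are ranked by
a deterministic surrogate — `|len − 12| + 2·|GRAVY|`, preferring mid-length,
mid-hydropathy peptides, ties broken lexicographically — and the top two
per protein become heavy/light pairs. This surrogate is a design stand-in,
not a claim about ionization efficiency. Transitions are singly charged
y-ions, longest first, minimum fragment index 3 (avoids the low-mass /
immonium-range ambiguity), five per precursor by default and never fewer
than three. A peptide occurring in more than one protein is excluded
entirely (not quantotypic). The default panel covers nine wound biomarkers
with two peptides each; three sequences are published assay peptides
(VNLLSAIK, IPVALGLK, AFQVWSDVTPLR) and the other fifteen are synthetic
stand-ins satisfying the same rules, chosen to spread across the hydropathy
range. The default protein "sequences" are simply the concatenations of
their two target peptides — synthetic fixtures, labeled as such in the
code.

## Chromatography

Two gradient methods are built in: 100 samples/day (11.5 min = 690 s active
gradient, 864 s cycle) and 60 samples/day (22 min gradient). Peaks are
truncated Gaussians (support ±5σ; the neglected tail is <1e-5 of the area),
with an optional right-side tail factor. The default width is σ = 3 s on
the 100SPD gradient (≈14.7 s at 5% height), scaled by gradient-length ratio
for other methods; under a 2 s duty cycle this yields the ~6–7 quantitative
scans per peak and sub-30 s measurement windows the workflow is built
around. Apex retention times are an affine map of the Kyte–Doolittle GRAVY
score (clamped to [−4.5, 4.5]) onto [0.1, 0.9] of the active gradient, plus
a tiny mean-residue-mass term that separates peptides of identical
hydropathy. This predictor is deliberately non-physical: it exists to give
every peptide a stable, distinct apex that scales with gradient length and
is identical for heavy/light partners (the predictor sees only the
sequence). Run-to-run instability is modeled as apex' = apex +
linear·run_index + N(0, jitter_SD), drawn once per heavy/light pair per run
(partners co-elute under every realization), clipped to the gradient.

## Synthetic samples

Per-protein median concentrations sit on an even log₁₀ grid across the
requested span (default 7 orders over 9 proteins, so adjacent proteins are
7/8 ≈ 0.875 orders apart), assigned in panel order so the first protein is
the rarest. Per-sample concentrations multiply the median by lognormal
biological variation (σ_ln = 0.3, ≈30% CV — moderate for a simulator whose
job is rank/recovery testing, not clinical realism). Each light peptide
carries a fixed lognormal response factor (σ_ln = 0.2; quantotypic peptides
are selected for consistent response, so the spread is modest); light
amplitude = concentration × response × scale (100 intensity units per
concentration unit). Heavy amplitude is one constant (10⁶) everywhere —
the fixed spike per injection. Transition intensities split a precursor's
amplitude by a fixed per-peptide weight vector (geometric with ratio 0.85,
normalized to sum to 1, shared by heavy and light).

Detector noise is multiplicative lognormal on centroid intensities (CV 5%,
mean-one so quantification stays unbiased), plus an optional additive
baseline (default 0), plus a detection floor (50 intensity units) below
which centroids are dropped. The floor is what makes the dynamic-range
claim falsifiable: with the default scale the rarest protein's transitions
sit below it, so a 7-order truth yields ≈6.1 quantified orders rather than
a tautological 7. MS2 matrix background is Poisson (mean 20 ions/scan),
lognormal intensities (median 30, σ_ln = 1), uniform over 200–1500 Th
except for a configurable interferent fraction (default 5%) placed within
the fragment tolerance of randomly chosen true transitions. MS1 spectra
carry noise and the floor but no background ions; false triggering is
already bounded by the watch-scan fragment match.

What the generator does **not** emulate — and hence what green tests do not
show about real data: isotope envelopes, charge-state distributions,
co-eluting near-isobaric peptides, ion suppression, AGC-driven injection
time variation, detector saturation, peak-shape degradation over a column's
lifetime, or digestion variability. Results here are statements about the
acquisition/quantification logic, not about matrix chemistry.

## Acquisition engine

Scan wall time is max(injection time, orbitrap transient) + 5 ms overhead,
with transients 16/32/64/128/256 ms at resolutions 7.5k/15k/30k/60k/120k
(unlisted resolutions fall back to the nearest with a warning). Defaults:
MS1 at 120k resolution / 50 ms injection every 2 s cycle; watch scans at
7.5k / 10 ms; quantitative scans at 60k / 250 ms; 10 ppm precursor and
20 ppm fragment tolerances; trigger threshold 3 product ions; isolation
width 1.0 Th (unstated for this scan type in practice; a config knob).

The internal standard is "detected" when an MS1 centroid within the
precursor tolerance of the heavy m/z exceeds 1% of the IS apex amplitude —
the simplest faithful reading of watch-mode MS1 surveillance; the threshold
is configurable. Detected standards are serviced in round-robin order
(start index rotates each cycle) so that, under budget contention, no
co-eluting target is systematically starved by its position in the panel. A
watch scan is only started if its potential same-cycle offset scan could
still begin inside the cycle, so the time between consecutive MS1 scans
never exceeds the duty-cycle period plus one maximal scan; targets that do
not fit are simply picked up on a later cycle, and when a cycle overruns,
the next MS1 starts as soon as the overflowing scan ends. At most one
quantitative scan per peptide per cycle. Fragment matching is greedy
nearest-assignment in ppm space; each centroid satisfies at most one
expected transition, ties broken by expectation index.

The scheduled-PRM comparator fires quantitative scans on every precursor
whose fixed retention-time window (default nominal apex ± 15 s) contains
the cycle clock, signal or no signal. Since the internal standard is spiked
in this mode too, each in-window cycle schedules the heavy precursor
alongside its light partner — atomically, both scans or neither, so
neither species is starved — and integration stays IS-anchored in both
modes. AGC targets are recorded as run metadata only; emulating ion
population control is not attempted because it would be unverifiable here.

## Quantification

Traces are extracted per expected transition as the summed intensity of
centroids within ±20 ppm, with explicit zeros where nothing matched
(interferents inside the tolerance are, by construction, added to the
trace). Light traces come from quantitative scans, heavy traces from watch
scans. Integration boundaries are the contiguous region around the summed
heavy-trace apex where intensity stays ≥5% of the apex — a reproducible
proxy for manual boundary curation against the internal standard, and by
construction invariant to light-peptide abundance. Areas are trapezoidal;
fewer than two points integrate to zero. The run normalizer is the TIC
chromatogram area computed from MS1 scans only (the natural reading of
"TIC chromatogram" here); normalized area = area / run TIC × median TIC
across runs, a scale-preserving ratio (pure ratios would satisfy the math
equally; the median anchor keeps values interpretable on the raw scale).
Protein values are arithmetic means of available peptide values — missing
peptides are skipped, a protein with no quantified peptide stays missing,
never zero — and the 0–100 rescaling is per-protein min–max across samples
(constant series map to 0 with a warning; fewer than two values pass
through as missing). A precursor is "quantifiable" only with ≥3 transitions
showing nonzero area, echoing the panel's minimum-transition rule.

## Performance metrics

Points per peak counts quantitative scans inside a peptide's integration
boundaries; the measurement window is last-minus-first quantitative scan
time. Apex RT per run is the argmax of the summed heavy trace — no
interpolation, so reported RT SDs include a quantization component of about
cycle/√12 ≈ 0.6 s on top of injected jitter; with 5 s jitter the expected
observed SD is √(25 + 0.33) ≈ 5.03 s. Peptides missing in more than half
the runs are excluded from stability summaries with a note. The dynamic
range is the log₁₀ span of ground-truth medians over proteins quantifiable
(≥3 nonzero transitions in ≥1 peptide) in at least 90% of samples. The mode
comparison runs both engines on identical ground truth, drift realizations
and noise seeds across a ladder of jitter magnitudes, reporting completeness
(% quantifiable peptide-sample pairs) and mean points per peak; its ground
truth uses a high amplitude scale so the comparison isolates scheduling
robustness rather than sensitivity.

## Immunoassay calibration

The 5PL curve y = d + (a−d)/(1+(x/c)^b)^g is fitted by least squares on a
log-concentration axis (better conditioning; parameters are reported on the
natural scale) with the deterministic initializer a = min y, d = max y,
c = geometric mid, b = 1, g = 1. Orientation lives in (a, d): a is the
level approached at zero concentration, so decreasing (competitive-format)
curves fit without sign gymnastics; g is kept positive via an exp
reparametrization. At least 5 standards spanning more than one decade are
required. Validation rules run in the order CV → flattening → fit →
recovery → refit (the order is not prescribed anywhere authoritative; this
one removes clearly-bad replicates before any shape judgment, and refits
after removals): standards with replicate CV > 10% are dropped; an end
standard within 10% (net MFI) of its neighbor is dropped as flattened; after
an initial fit, standards back-calculating outside 80–120% of nominal are
dropped and the curve is refitted. Fewer than 5 survivors invalidate the
curve. Note that a single biased standard is partially absorbed by the
flexible 5PL, so the recovery rule may implicate neighbors rather than the
culprit — tests therefore assert the rule's contract (a recovery removal
fires and all survivors back-calculate in-band), not which point is blamed.

Sample wells are censored (with a side indicator) when their net MFI falls
outside the range covered by the surviving standards — the range-based
reading of an ambiguous bound; the alternative (distance from the mean
standard MFI) was rejected as discarding half of every plate. Wells with
duplicate CV > 10% are dropped; a singleton whose partner was censored is
kept but flagged. Back-calculation is the analytic 5PL inverse times the
dilution factor. A working-range helper (net MFI within 10–90% of the
asymptote span) marks where back-calculation is well-conditioned; round-trip
recovery is only claimed there. The plate simulator renders triplicate
7-point standards (4-fold serial dilutions from a top standard placed so
the target concentration sits mid-curve) and duplicate sample wells at
1:50 / 1:500 / 1:10,000 dilutions, MFI = curve(conc) × lognormal(CV) +
background; one analyte can be marked standard-less to mirror panels where
no reference standard exists.

## Problem sizes and numerical choices

The shipped checks use: one 690 s run per sample at a 2 s duty cycle (~345
cycles, ~900 scans); 42-sample cohorts for recovery/dynamic-range checks;
and a 365-run sequence for RT stability (≈25 s wall time) — sizes chosen so
the whole suite runs on a laptop in well under a minute per scenario.
Trapezoidal integration is used throughout (peak areas, TIC); boundaries
degenerate to a single scan are widened by ±1 ns to stay valid; peptide CSV
I/O uses pandas' round-trip float parser so written m/z values reload
bit-identically. Seeds are masked to 31 bits before reaching numpy.

## Known limitations

RT prediction is a stand-in (no mobile-phase, temperature or column-aging
physics); no isotope envelopes or charge-state competition; AGC and
dynamic injection-time control are not modeled (injection times are fixed
maxima); FAIMS is out of scope; the mzML export hook is a stub — scan
tables are CSV. The immunoassay simulator models noise and censoring, not
cross-reactivity or matrix effects.
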