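"""Trace extraction, IS-anchored boundaries, integration and normalization."""

import math

import numpy as np
import pandas as pd
import pytest

from isprm import lc, pipeline, quant, samples
from isprm.acquisition import run_surequant
from isprm.panel import build_panel
from isprm.quant import TransitionTrace


def _single_pair(light_conc=100.0, seed=0):
    pnl = build_panel({"P1": "VNLLSAIK"}, peptides_per_protein=1)
    truth = samples.generate_ground_truth(pnl, 0, 1, seed=seed)
    truth.concentrations.iloc[0, 0] = light_conc
    truth.response.iloc[0] = 1.0
    profiles = pipeline.profiles_for_run(pnl, lc.GRADIENT_100SPD, 0)
    sig = samples.render_signals(truth, pnl, profiles, 0)
    return pnl, sig, profiles


class TestExtractTraces:
    def test_noiseless_traces_equal_rendered_signal(self):
        pnl, sig, _ = _single_pair()
        run = run_surequant(sig, pnl)
        traces = quant.extract_traces(run, pnl)
        light = pnl.lights()[0]
        tr = traces[light.spec_id]
        i = sig.index[light.spec_id]
        for k, t in enumerate(tr.times):
            np.testing.assert_allclose(
                tr.intensities[k], sig.transition_intensity(i, t), rtol=1e-12
            )

    def test_vanishing_tolerance_zeroes_jittered_traces(self):
        pnl, sig, _ = _single_pair()
        # shift every rendered transition m/z by ~5 ppm
        sig.transition_mz = [m * (1 + 5e-6) for m in sig.transition_mz]
        run = run_surequant(sig, pnl)
        traces = quant.extract_traces(run, pnl, tol_ppm=1e-3)
        light = pnl.lights()[0]
        assert np.all(traces[light.spec_id].intensities == 0.0)

    def test_interferent_inside_tolerance_adds_to_trace(self):
        pnl, sig, _ = _single_pair()
        run = run_surequant(sig, pnl)
        light = pnl.lights()[0]
        # inject an interfering centroid 10 ppm from transition 0 into a scan
        scan = run.scans("QUANT_MS2", target=light.spec_id)[0]
        target_mz = light.transitions[0].mz
        scan.mz = np.append(scan.mz, target_mz * (1 + 10e-6))
        scan.intensity = np.append(scan.intensity, 1234.0)
        traces = quant.extract_traces(run, pnl, tol_ppm=20.0)
        tr = traces[light.spec_id]
        k = list(tr.times).index(scan.time)
        i = sig.index[light.spec_id]
        clean = sig.transition_intensity(i, scan.time)[0]
        assert tr.intensities[k, 0] == pytest.approx(clean + 1234.0)

    def test_peptide_without_scans_has_empty_trace(self, panel9):
        pnl, sig, _ = _single_pair()
        run = run_surequant(sig, pnl)
        traces = quant.extract_traces(run, pnl)
        assert all(t.times.ndim == 1 for t in traces.values())


class TestDetectBoundaries:
    def _gaussian_trace(self, sigma=3.0, spacing=2.0, apex=300.0, amp=1e5):
        times = np.arange(apex - 30.0, apex + 30.0 + spacing, spacing)
        y = amp * np.exp(-0.5 * ((times - apex) / sigma) ** 2)
        return TransitionTrace("x", times, y[:, None])

    def test_five_percent_cut_width_matches_closed_form(self):
        spacing = 2.0
        tr = self._gaussian_trace(spacing=spacing)
        start, end = quant.detect_boundaries(tr)
        expected = 2.0 * 3.0 * math.sqrt(2.0 * math.log(20.0))  # 14.69 s
        # sampling can only shrink the 5% region, by < spacing per side
        assert expected - 2 * spacing < (end - start) <= expected

    def test_region_contains_apex(self):
        tr = self._gaussian_trace()
        start, end = quant.detect_boundaries(tr)
        apex_t = tr.times[np.argmax(tr.summed())]
        assert start <= apex_t <= end

    def test_apex_at_run_edge_clips_boundaries(self):
        times = np.arange(0.0, 20.0, 2.0)
        y = 1e5 * np.exp(-0.5 * (times / 3.0) ** 2)
        tr = TransitionTrace("x", times, y[:, None])
        start, end = quant.detect_boundaries(tr)
        assert start == 0.0

    def test_all_zero_trace_flags_not_detected(self):
        tr = TransitionTrace("x", np.arange(5.0), np.zeros((5, 2)))
        assert quant.detect_boundaries(tr) is None
        empty = TransitionTrace("x", np.empty(0), np.empty((0, 2)))
        assert quant.detect_boundaries(empty) is None

    def test_boundaries_invariant_to_light_abundance(self):
        runs = {}
        for conc in (10.0, 1e6):
            pnl, sig, _ = _single_pair(light_conc=conc)
            run = run_surequant(sig, pnl)
            traces = quant.extract_traces(run, pnl)
            heavy = pnl.heavies()[0]
            runs[conc] = quant.detect_boundaries(traces[heavy.spec_id])
        assert runs[10.0] == runs[1e6]


class TestIntegrate:
    def test_constant_trace(self):
        t = np.linspace(10.0, 20.0, 11)
        y = np.full(11, 7.0)
        assert quant.integrate(t, y, (10.0, 20.0)) == pytest.approx(70.0)

    def test_empty_region_is_zero(self):
        t = np.array([0.0, 1.0, 2.0])
        assert quant.integrate(t, t, (5.0, 6.0)) == 0.0

    def test_linear_in_amplitude(self):
        t = np.linspace(0, 10, 21)
        y = np.sin(t / 3) + 1.1
        a1 = quant.integrate(t, y, (0.0, 10.0))
        a3 = quant.integrate(t, 3 * y, (0.0, 10.0))
        assert a3 == pytest.approx(3 * a1)

    def test_invalid_boundaries(self):
        with pytest.raises(ValueError):
            quant.integrate(np.arange(3.0), np.arange(3.0), (2.0, 1.0))


class TestTicNormalize:
    def test_identical_tics_are_identity(self):
        areas = pd.DataFrame({"p": [10.0, 20.0]}, index=[0, 1])
        tics = pd.Series([100.0, 100.0], index=[0, 1])
        out = quant.tic_normalize(areas, tics)
        pd.testing.assert_frame_equal(out, areas)

    def test_toy_two_run_example(self):
        # TICs {100, 200}, raw areas {10, 20} -> both normalize to 15
        areas = pd.DataFrame({"p": [10.0, 20.0]}, index=[0, 1])
        tics = pd.Series([100.0, 200.0], index=[0, 1])
        out = quant.tic_normalize(areas, tics)
        assert list(out["p"]) == [15.0, 15.0]

    def test_scale_invariance(self, panel9):
        # multiplying every intensity of one run by k scales both its areas
        # and its TIC by k, so the normalized value is unchanged
        areas = pd.DataFrame({"p": [10.0, 20.0, 30.0]}, index=[0, 1, 2])
        tics = pd.Series([100.0, 200.0, 150.0], index=[0, 1, 2])
        base = quant.tic_normalize(areas, tics)
        k = 7.3
        areas2 = areas.copy()
        areas2.loc[1] *= k
        tics2 = tics.copy()
        tics2.loc[1] *= k
        scaled = quant.tic_normalize(areas2, tics2)
        assert scaled.loc[1, "p"] == pytest.approx(base.loc[1, "p"], rel=1e-6)

    def test_zero_tic_names_run(self):
        areas = pd.DataFrame({"p": [1.0, 2.0]}, index=["r1", "r2"])
        tics = pd.Series([10.0, 0.0], index=["r1", "r2"])
        with pytest.raises(ValueError, match="r2"):
            quant.tic_normalize(areas, tics)


class TestRollupAndRescale:
    def test_mean_of_peptides(self):
        vals = pd.DataFrame({"pepA": [10.0], "pepB": [20.0]})
        mapping = pd.Series({"pepA": "P", "pepB": "P"})
        out = quant.protein_rollup(vals, mapping)
        assert out.loc[0, "P"] == 15.0

    def test_missing_peptide_uses_remaining(self):
        vals = pd.DataFrame({"pepA": [np.nan], "pepB": [20.0]})
        mapping = pd.Series({"pepA": "P", "pepB": "P"})
        assert quant.protein_rollup(vals, mapping).loc[0, "P"] == 20.0

    def test_all_missing_stays_missing(self):
        vals = pd.DataFrame({"pepA": [np.nan], "pepB": [np.nan]})
        mapping = pd.Series({"pepA": "P", "pepB": "P"})
        assert np.isnan(quant.protein_rollup(vals, mapping).loc[0, "P"])

    def test_rollup_bounded_by_peptides(self, cohort42):
        q = cohort42.quant_table.dropna(subset=["protein_value"])
        for (s, prot), grp in q.groupby(["sample", "protein"]):
            vals = grp["normalized_area"].dropna()
            if len(vals):
                assert vals.min() - 1e-9 <= grp["protein_value"].iloc[0]
                assert grp["protein_value"].iloc[0] <= vals.max() + 1e-9

    def test_rescale_simple(self):
        df = pd.DataFrame({"P": [5.0, 10.0, 15.0]})
        out = quant.rescale_0_100(df)
        assert list(out["P"]) == [0.0, 50.0, 100.0]

    def test_rescale_keeps_missing(self):
        df = pd.DataFrame({"P": [5.0, np.nan, 15.0]})
        out = quant.rescale_0_100(df)
        assert np.isnan(out["P"].iloc[1])
        assert out["P"].iloc[2] == 100.0

    def test_rescale_constant_warns_and_zeroes(self):
        df = pd.DataFrame({"P": [5.0, 5.0, 5.0]})
        with pytest.warns(UserWarning, match="constant"):
            out = quant.rescale_0_100(df)
        assert list(out["P"]) == [0.0, 0.0, 0.0]

    def test_rescale_range(self, cohort42):
        r = cohort42.rescaled
        assert np.nanmin(r.to_numpy()) >= 0.0
        assert np.nanmax(r.to_numpy()) <= 100.0
        assert all(
            np.nanmax(r[c]) == pytest.approx(100.0)
            for c in r.columns
            if r[c].notna().sum() >= 2 and r[c].nunique() > 1
        )


class TestCompletenessMatrix:
    def test_shapes_and_missing_encoding(self, cohort42):
        pep, prot = quant.completeness_matrix(cohort42.quant_table)
        n_samples = cohort42.quant_table["sample"].nunique()
        assert pep.shape == (18, n_samples)
        assert prot.shape == (9, n_samples)
        assert not np.isinf(pep.to_numpy()).any()
        # lowest-abundance protein is mostly below the sensitivity floor:
        # explicit missing cells, never -inf or 0
        assert pep.isna().to_numpy().any()
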