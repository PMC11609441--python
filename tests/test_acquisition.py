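"""The triggered-acquisition state machine and its scheduled comparator."""

import numpy as np
import pytest

from isprm import acquisition as acq
from isprm import lc, pipeline, samples
from isprm.acquisition import MS1, QUANT_MS2, WATCH_MS2, AcquisitionParams
from isprm.panel import build_panel


class TestScanDuration:
    @pytest.mark.parametrize(
        "resolution,injection,expected",
        [
            (60000, 250.0, 0.255),  # injection-bound
            (7500, 10.0, 0.021),  # transient-bound
            (120000, 50.0, 0.261),
        ],
    )
    def test_documented_values(self, resolution, injection, expected):
        assert acq.scan_duration(resolution, injection) == pytest.approx(expected)

    def test_monotone_in_both_arguments(self):
        resolutions = sorted(acq.TRANSIENT_MS)
        for lo, hi in zip(resolutions, resolutions[1:]):
            assert acq.scan_duration(lo, 10.0) <= acq.scan_duration(hi, 10.0)
        assert acq.scan_duration(60000, 100.0) <= acq.scan_duration(60000, 300.0)

    def test_unknown_resolution_warns_and_uses_nearest(self):
        with pytest.warns(UserWarning, match="transient table"):
            d = acq.scan_duration(8000, 10.0)
        assert d == acq.scan_duration(7500, 10.0)


class TestOffsetMz:
    def test_lysine_label_z2(self):
        assert acq.offset_mz(500.0, 8.0142, 2) == pytest.approx(495.993, abs=1e-3)

    def test_arginine_label_z1(self):
        assert acq.offset_mz(800.0, 10.0083, 1) == pytest.approx(
            800.0 - 10.008, abs=1e-3
        )

    def test_inverse(self):
        off = acq.offset_mz(512.345, 8.0142, 3)
        assert off + 8.0142 / 3 == pytest.approx(512.345, abs=1e-9)


class TestMatchFragments:
    expected = np.array([300.0, 500.0, 700.0, 900.0, 1100.0])

    def test_empty_centroids(self):
        assert acq.match_fragments(np.array([]), self.expected, 20.0) == 0

    def test_exact_match_counts_all(self):
        assert acq.match_fragments(self.expected, self.expected, 20.0) == 5

    def test_partial_match(self):
        cents = np.array([300.0, 700.000001, 1500.0])
        assert acq.match_fragments(cents, self.expected, 20.0) == 2

    def test_one_centroid_satisfies_one_expectation(self):
        # centroid exactly between two close expectations: counted once
        expected = np.array([500.000, 500.004])
        cent = np.array([500.002])
        assert acq.match_fragments(cent, expected, 20.0) == 1

    def test_tolerance_is_ppm(self):
        cents = np.array([500.0 * (1 + 25e-6)])
        assert acq.match_fragments(cents, np.array([500.0]), 20.0) == 0
        assert acq.match_fragments(cents, np.array([500.0]), 30.0) == 1


def _single_pair_setup(seed=0, heavy_amp=1.0e6, light_conc=100.0):
    pnl = build_panel({"P1": "VNLLSAIK"}, peptides_per_protein=1)
    truth = samples.generate_ground_truth(pnl, 0, 1, seed=seed)
    truth.is_amplitude = heavy_amp
    truth.concentrations.iloc[0, 0] = light_conc
    truth.response.iloc[0] = 1.0
    profiles = pipeline.profiles_for_run(pnl, lc.GRADIENT_100SPD, 0)
    sig = samples.render_signals(truth, pnl, profiles, 0)
    return pnl, sig, profiles


class TestRunSureQuant:
    def test_trigger_needs_three_matched_ions(self):
        # watch spectra with k = 1..6 matched product ions: the smallest k
        # that fires an offset scan is the trigger threshold of 3
        params = AcquisitionParams()
        expected = np.array([300.0, 450.0, 600.0, 750.0, 900.0])
        fired = []
        for k in range(1, 7):
            cents = expected[: min(k, 5)]
            if k == 6:
                cents = np.append(expected, 1200.0)
            matched = acq.match_fragments(cents, expected, params.fragment_tol_ppm)
            if matched >= params.trigger_threshold:
                fired.append(k)
        assert min(fired) == 3

    def test_two_matching_fragments_do_not_trigger(self):
        pnl, sig, _ = _single_pair_setup()
        heavy = pnl.heavies()[0]
        # keep only 2 of the 5 heavy transitions in the rendered signal
        i = sig.index[heavy.spec_id]
        sig.weights[i][2:] = 0.0
        run = acq.run_surequant(sig, pnl)
        assert len(run.scans(WATCH_MS2)) > 0
        assert len(run.scans(QUANT_MS2)) == 0

    def test_zero_heavy_amplitude_never_watched(self):
        pnl, sig, _ = _single_pair_setup(heavy_amp=0.0)
        run = acq.run_surequant(sig, pnl)
        assert len(run.scans(WATCH_MS2)) == 0
        assert len(run.scans(QUANT_MS2)) == 0
        assert len(run.scans(MS1)) > 300  # MS1-only record

    def test_quant_scans_confined_to_elution_support(self):
        pnl, sig, profiles = _single_pair_setup()
        apex = profiles[pnl.heavies()[0].spec_id].apex_rt
        run = acq.run_surequant(sig, pnl)
        qt = [e.time for e in run.scans(QUANT_MS2)]
        assert qt, "expected triggered quantitative scans"
        assert all(apex - 15.0 <= t <= apex + 15.0 for t in qt)

    def test_quant_isolation_center_is_offset_mz(self):
        pnl, sig, _ = _single_pair_setup()
        heavy, light = pnl.pairs()[0]
        run = acq.run_surequant(sig, pnl)
        for e in run.scans(QUANT_MS2):
            assert e.isolation_center == pytest.approx(
                heavy.precursor_mz - heavy.label_delta / heavy.charge, abs=1e-9
            )
            assert e.target == light.spec_id

    def test_no_quant_without_triggering_watch_in_same_cycle(self, one_run):
        run = one_run.runs[0]
        params = run.params
        cycle_watches: dict[str, int] = {}
        last_ms1 = None
        for e in run.events:
            if e.kind == MS1:
                cycle_watches = {}
                last_ms1 = e.time
            elif e.kind == WATCH_MS2:
                cycle_watches[e.target] = e.matched_count
            elif e.kind == QUANT_MS2:
                heavy_id = e.target[:-1] + "H"
                assert heavy_id in cycle_watches
                assert cycle_watches[heavy_id] >= params.trigger_threshold
                assert last_ms1 is not None and e.time > last_ms1

    def test_events_strictly_time_ordered(self, one_run):
        times = [e.time for e in one_run.runs[0].events]
        assert all(b > a for a, b in zip(times, times[1:]))

    def test_cycle_budget_never_exceeded(self, one_run):
        run = one_run.runs[0]
        params = run.params
        max_scan = acq.scan_duration(params.quant_resolution,
                                     params.quant_injection_ms)
        ms1_times = [e.time for e in run.scans(MS1)]
        for a, b in zip(ms1_times, ms1_times[1:]):
            assert b - a <= params.cycle_s + max_scan + 1e-9


class TestAcquireSpectrum:
    def test_noiseless_centroids_at_exact_transition_mz(self):
        pnl, sig, profiles = _single_pair_setup()
        heavy = pnl.heavies()[0]
        t = profiles[heavy.spec_id].apex_rt
        mz, inten = acq.acquire_spectrum(sig, t, heavy.precursor_mz, 1.0)
        np.testing.assert_allclose(mz, sorted(heavy.transition_mzs()))
        i = sig.index[heavy.spec_id]
        np.testing.assert_allclose(inten.sum(), sig.amplitude[i])

    def test_isolation_window_excludes_other_precursors(self):
        pnl, sig, profiles = _single_pair_setup()
        heavy, light = pnl.pairs()[0]
        t = profiles[heavy.spec_id].apex_rt
        # isolation on the light precursor: heavy transitions must not appear
        mz, _ = acq.acquire_spectrum(sig, t, light.precursor_mz, 1.0)
        assert set(np.round(mz, 4)) == set(
            np.round(sorted(light.transition_mzs()), 4)
        )

    def test_seeds_change_noise_not_positions(self):
        pnl, sig, profiles = _single_pair_setup()
        heavy = pnl.heavies()[0]
        t = profiles[heavy.spec_id].apex_rt
        noise = samples.NoiseModel(cv=0.05, floor=0.0)
        mz1, i1 = acq.acquire_spectrum(sig, t, heavy.precursor_mz, 1.0,
                                       noise, rng=np.random.default_rng(1))
        mz2, i2 = acq.acquire_spectrum(sig, t, heavy.precursor_mz, 1.0,
                                       noise, rng=np.random.default_rng(2))
        np.testing.assert_array_equal(mz1, mz2)
        assert not np.allclose(i1, i2)


class TestScheduledPrm:
    def test_whole_gradient_window_scans_every_cycle(self):
        pnl, sig, _ = _single_pair_setup()
        light = pnl.lights()[0]
        windows = {light.spec_id: (0.0, 690.0)}
        run = acq.run_scheduled_prm(sig, pnl, windows)
        n_cycles = len(run.scans(MS1))
        assert len(run.scans(QUANT_MS2, target=light.spec_id)) == n_cycles

    def test_window_missing_peak_yields_no_signal(self):
        from isprm import quant

        pnl, sig, profiles = _single_pair_setup()
        light = pnl.lights()[0]
        apex = profiles[light.spec_id].apex_rt
        windows = {light.spec_id: (apex + 100.0, apex + 130.0)}
        run = acq.run_scheduled_prm(sig, pnl, windows)
        table = quant.quantify_run(run, pnl)
        assert not table["detected"].iloc[0]
        assert table["total_area"].isna().iloc[0]

    def test_contention_reduces_per_peptide_scan_rate(self, panel9):
        truth = samples.generate_ground_truth(panel9, 0, 1, seed=0,
                                              amplitude_scale=1e5)
        profiles = pipeline.profiles_for_run(panel9, lc.GRADIENT_100SPD, 0)
        sig = samples.render_signals(truth, panel9, profiles, 0)
        lights = panel9.lights()
        full = {p.spec_id: (0.0, 690.0) for p in lights}
        solo = {lights[0].spec_id: (0.0, 690.0)}
        contended = acq.run_scheduled_prm(sig, panel9, full)
        alone = acq.run_scheduled_prm(sig, panel9, solo)
        n_contended = len(contended.scans(QUANT_MS2, target=lights[0].spec_id))
        n_alone = len(alone.scans(QUANT_MS2, target=lights[0].spec_id))
        assert n_contended < n_alone


class TestScanTables:
    def test_round_trip(self, one_run, tmp_path):
        run = one_run.runs[0]
        scans, cents = tmp_path / "scans.csv", tmp_path / "centroids.csv"
        acq.write_scan_tables([run], scans, cents)
        loaded = acq.read_scan_tables(scans, cents, run.gradient)[0]
        assert len(loaded.events) == len(run.events)
        for a, b in zip(run.events, loaded.events):
            assert a.kind == b.kind and a.target == b.target
            assert a.time == pytest.approx(b.time)
            np.testing.assert_allclose(a.mz, b.mz)
            np.testing.assert_allclose(a.intensity, b.intensity)

    def test_mzml_export_is_stub(self):
        with pytest.raises(NotImplementedError):
            acq.export_mzml([], "x.mzML")
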