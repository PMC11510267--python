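"""Peak filtering, candidate search, isotope fit, fragment matching,
isomer discrimination and whole-run identification."""

import dataclasses

import numpy as np
import pytest

from dbaffinity import (FeatureObservation, MatchParams, Peak,
                        discriminate_isomers, filter_peaks,
                        fragment_match_score, identify_run, isotope_envelope,
                        isotopic_fit, ppm_error, precursor_candidates,
                        RunSpec, simulate_run)
from dbaffinity.matcher import AmbiguousMatch

ISOMER_IDS = {1, 2, 3, 4, 5, 6, 7, 8, 23, 24}


def _feature(mz, rt=1.0, polarity="-", msms=(), envelope=(1.0, 0.1, 0.01)):
    return FeatureObservation(rt=rt, precursor_mz=mz, area=1e5,
                              envelope=envelope, msms=tuple(msms),
                              polarity=polarity)


class TestFilterPeaks:
    def test_equal_intensities_all_removed(self):
        peaks = [Peak(100 + i, 50.0) for i in range(8)]
        assert filter_peaks(peaks, 5.0) == []

    def test_strong_peak_over_unit_noise_survives(self):
        peaks = [Peak(100 + i, 1.0) for i in range(9)] + [Peak(500.0, 100.0)]
        kept = filter_peaks(peaks, 5.0)
        assert [p.mz for p in kept] == [500.0]

    def test_empty_in_empty_out(self):
        assert filter_peaks([], 5.0) == []

    def test_order_preserved(self):
        peaks = [Peak(300.0, 90.0), Peak(200.0, 80.0)] + \
            [Peak(100 + i, 1.0) for i in range(8)]
        assert [p.mz for p in filter_peaks(peaks, 5.0)] == [300.0, 200.0]


class TestPrecursorCandidates:
    def test_mz_255_negative_hits_isomer_group_i(self, ref_lib):
        ids = {r.id for r in precursor_candidates(_feature(255.0661), ref_lib)}
        assert ids == {1, 2, 3}

    def test_mz_283_negative_hits_isomer_group_ii(self, ref_lib):
        ids = {r.id for r in precursor_candidates(_feature(283.0612), ref_lib)}
        assert ids == {4, 5, 6}

    def test_far_mass_has_no_candidates(self, ref_lib):
        assert precursor_candidates(_feature(500.0), ref_lib) == []
        assert precursor_candidates(_feature(500.0, polarity="+"), ref_lib) == []

    def test_polarity_is_respected(self, ref_lib):
        # proline's [M+H]+ m/z finds nothing in negative mode
        assert precursor_candidates(_feature(116.0706, polarity="-"), ref_lib) == []
        ids = {r.id for r in precursor_candidates(
            _feature(116.0706, polarity="+"), ref_lib)}
        assert ids == {41}

    def test_agrees_with_brute_force_scan(self, ref_lib):
        rng = np.random.default_rng(7)
        params = MatchParams()
        for _ in range(1000):
            mz = rng.uniform(100.0, 1500.0)
            pol = "-" if rng.random() < 0.5 else "+"
            got = {r.id for r in precursor_candidates(
                _feature(mz, polarity=pol), ref_lib, params)}
            want = {r.id for r in ref_lib
                    if r.polarity == pol and
                    abs(mz - r.theoretical_mz) / r.theoretical_mz * 1e6
                    <= params.precursor_tol}
            assert got == want

    def test_sorted_by_ppm(self, ref_lib):
        cands = precursor_candidates(_feature(255.0661), ref_lib)
        errs = [ppm_error(255.0661, r.theoretical_mz) for r in cands]
        assert errs == sorted(errs)


def test_tolerance_monotonicity(ref_lib):
    rng = np.random.default_rng(11)
    for _ in range(200):
        mz = rng.uniform(100.0, 1500.0)
        f = _feature(mz)
        narrow = {r.id for r in precursor_candidates(
            f, ref_lib, MatchParams(precursor_tol=5.0))}
        wide = {r.id for r in precursor_candidates(
            f, ref_lib, MatchParams(precursor_tol=20.0))}
        assert narrow <= wide


class TestIsotopicFit:
    def test_proportional_envelopes_fit_perfectly(self):
        theo = [0.9, 0.09, 0.01]
        assert isotopic_fit([x * 7.3 for x in theo], theo) == pytest.approx(1.0)

    def test_reversed_envelope_fits_badly(self):
        assert isotopic_fit([0, 0, 1], [0.98, 0.02, 0.0002]) < 0.05

    def test_small_relative_noise_keeps_fit_high(self):
        theo = np.array([a for _, a in isotope_envelope("C15H11O4", 3)])
        rng = np.random.default_rng(3)
        fits = [isotopic_fit(theo * (1 + rng.normal(0, 0.05, 3)), theo)
                for _ in range(1000)]
        assert min(fits) >= 0.99

    def test_all_zero_observed_rejected(self):
        with pytest.raises(ValueError):
            isotopic_fit([0, 0, 0], [0.9, 0.1])


class TestFragmentMatchScore:
    def test_full_match_scores_one(self, ref_lib):
        msms = [Peak(m, 100.0) for m in (463.0874, 300.0273, 271.0247, 255.0298)]
        score, matched, _ = fragment_match_score(msms, ref_lib[7])
        assert score == 1.0
        assert len(matched) == 4

    def test_diagnostic_hit_for_alpha_fragmentation_pair(self, ref_lib):
        msms = [Peak(135.0441, 900.0), Peak(119.0492, 800.0), Peak(255.0661, 100.0)]
        _, _, diag = fragment_match_score(msms, ref_lib[2])
        assert diag is True

    def test_empty_spectrum_scores_zero(self, ref_lib):
        score, matched, diag = fragment_match_score([], ref_lib[2])
        assert (score, matched, diag) == (0.0, (), False)
        # vacuous diagnostic set: empty spectrum still "hits"
        _, _, diag7 = fragment_match_score([], ref_lib[7])
        assert diag7 is True

    def test_tolerance_window(self, ref_lib):
        rec = ref_lib[29]
        near = [Peak(169.0133 + 0.009, 10.0)]
        far = [Peak(169.0133 + 0.011, 10.0)]
        assert fragment_match_score(near, rec)[0] > 0
        assert fragment_match_score(far, rec)[0] == 0


class TestDiscriminateIsomers:
    def test_alpha_fragmentation_selects_isoliquiritigenin(self, ref_lib):
        group = [ref_lib[i] for i in (1, 2, 3)]
        msms = [Peak(135.0441, 900.0), Peak(119.0492, 800.0),
                Peak(255.0661, 200.0), Peak(91.0178, 150.0)]
        f = _feature(255.0661, rt=11.52, msms=msms)
        assert discriminate_isomers(group, f).id == 2

    def test_rt_resolves_shared_fragment_isomers(self, ref_lib):
        group = [ref_lib[i] for i in (23, 24)]
        msms = [Peak(153.0186, 500.0), Peak(109.0285, 300.0), Peak(108.0206, 200.0)]
        f = _feature(153.0186, rt=1.62, msms=msms)
        assert discriminate_isomers(group, f).id == 23

    def test_single_candidate_returned(self, ref_lib):
        f = _feature(169.0142, rt=0.9)
        assert discriminate_isomers([ref_lib[29]], f).id == 29

    def test_exact_rt_tie_is_ambiguous(self, ref_lib):
        group = [ref_lib[i] for i in (23, 24)]
        f = _feature(153.0186, rt=1.8, msms=())  # equidistant from 1.6 and 2.0
        with pytest.raises(AmbiguousMatch):
            discriminate_isomers(group, f, MatchParams(rt_tol=0.5))

    def test_empty_candidates_rejected(self, ref_lib):
        with pytest.raises(ValueError):
            discriminate_isomers([], _feature(100.0))


class TestIdentifyRun:
    def test_default_synthetic_run_recovered_exactly(self, ref_lib, default_run):
        run, truth = default_run
        results = identify_run(run, ref_lib)
        for res, true_id in zip(results, truth.feature_ids):
            if true_id is None:
                assert res.decision != "identified"
            else:
                assert res.decision == "identified"
                assert res.standard_id == true_id

    def test_identified_results_pass_all_gates(self, ref_lib, default_run):
        run, _ = default_run
        params = MatchParams()
        for res in identify_run(run, ref_lib, params):
            if res.decision == "identified":
                assert res.ppm_error <= params.precursor_tol
                assert abs(res.rt_delta) <= params.rt_tol
                assert res.isotopic_fit >= params.isotopic_fit_threshold

    def test_determinism(self, ref_lib, default_run):
        run, _ = default_run
        assert identify_run(run, ref_lib) == identify_run(run, ref_lib)

    def test_emptied_msms_falls_back_to_rt(self, ref_lib):
        run, truth = simulate_run(ref_lib, RunSpec(
            seed=5, ppm_jitter_sd=0.0, rt_jitter_sd=0.0, n_noise_features=0,
            envelope_noise_rel=0.0, area_noise_rel=0.0, msms_noise_peaks=0))
        run = [dataclasses.replace(f, msms=()) for f in run]
        results = identify_run(run, ref_lib)
        for res, true_id in zip(results, truth.feature_ids):
            assert res.decision == "identified" and res.standard_id == true_id

    def test_empty_run(self, ref_lib):
        assert identify_run([], ref_lib) == []

    def test_one_to_one_assignment_demotes_duplicates(self, ref_lib):
        rec = ref_lib[29]
        f_good = _feature(rec.theoretical_mz, rt=rec.rt,
                          envelope=[a for _, a in isotope_envelope(rec.ion)])
        f_off = dataclasses.replace(f_good,
                                    precursor_mz=rec.theoretical_mz * (1 + 4e-6))
        results = identify_run([f_off, f_good], ref_lib)
        decisions = {r.decision for r in results}
        assert decisions == {"identified", "ambiguous"}
        winner = next(r for r in results if r.decision == "identified")
        assert winner.feature.precursor_mz == f_good.precursor_mz
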