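"""Psychometric fitting, reliability statistics, and the WER(SNR, RT) grid."""

import numpy as np
import pytest

from asr_audiobench import (
    PsychometricCurve,
    SpeechAudiogram,
    TranscriberModel,
    bland_altman,
    fit_psychometric,
    make_cnc_list,
    make_dialogue,
    rmsd,
    run_fixed_levels,
    semantic_distance_default,
    srt_from_curve,
    wer_grid,
)
from asr_audiobench.analysis import FitFailure, SemanticDistanceHook


class TestPsychometricFit:
    def test_noiseless_recovery_to_1e6(self):
        truth = PsychometricCurve(midpoint=55.0, slope=5.0)
        x = np.arange(35.0, 80.0, 2.5)
        curve = fit_psychometric(list(zip(x, truth.predict(x))))
        assert curve.midpoint == pytest.approx(55.0, abs=1e-6)
        assert curve.slope == pytest.approx(5.0, abs=1e-6)

    def test_two_symmetric_points_give_midpoint_55(self):
        curve = fit_psychometric([(50.0, 25.0), (60.0, 75.0)])
        assert curve.midpoint == pytest.approx(55.0, abs=1e-6)

    def test_identical_percents_is_fit_failure(self):
        with pytest.raises(FitFailure):
            fit_psychometric([(45.0, 60.0), (55.0, 60.0), (65.0, 60.0)])

    def test_results_object_reports_uncertainty_and_summary(self):
        rng = np.random.default_rng(1)
        truth = PsychometricCurve(midpoint=55.0, slope=5.0)
        x = np.repeat(np.arange(40.0, 75.0, 5.0), 3)
        y = np.clip(truth.predict(x) + rng.normal(0, 3, size=x.size), 0, 100)
        res = SpeechAudiogram(x, y).fit()
        assert res.params["midpoint"] == pytest.approx(55.0, abs=3.0)
        assert np.isfinite(res.bse["midpoint"]) and res.bse["midpoint"] > 0
        text = res.summary()
        assert "midpoint" in text and "slope" in text
        assert f"{res.curve.midpoint:.3f}" in text

    def test_from_dataframe_constructor(self):
        import pandas as pd

        truth = PsychometricCurve(midpoint=0.0, slope=10.0)
        x = np.array([-10.0, -5.0, 0.0, 5.0, 10.0])
        df = pd.DataFrame({"level": x, "percent": truth.predict(x)})
        res = SpeechAudiogram.from_dataframe(df).fit()
        assert res.curve.midpoint == pytest.approx(0.0, abs=1e-6)

    def test_simulated_transcriber_midpoint_in_app_range(self):
        # a transcriber with its quiet SRT inside 50-60 dB SPL must yield a
        # fitted speech-audiogram midpoint inside the same range
        model = TranscriberModel(srt_quiet=57.0, slope_quiet=5.0,
                                 insertion_rate=0.0, seed=12)
        lists = [make_cnc_list(s) for s in range(5)]
        points = run_fixed_levels(model, lists, (45.0, 55.0, 65.0, 75.0, 85.0))
        curve = fit_psychometric([(p.level, p.percent) for p in points])
        assert 50.0 <= curve.midpoint <= 60.0


class TestSrtFromCurve:
    def test_criterion_50_is_the_midpoint(self):
        curve = PsychometricCurve(midpoint=-1.8, slope=12.0)
        assert srt_from_curve(curve, 50.0) == pytest.approx(-1.8)

    def test_antisymmetric_criteria(self):
        curve = PsychometricCurve(midpoint=0.0, slope=8.0)
        up = srt_from_curve(curve, 75.0)
        down = srt_from_curve(curve, 25.0)
        assert up > 0
        assert up == pytest.approx(-down, abs=1e-12)

    def test_round_trip_through_sampling_and_fit(self):
        for midpoint, slope in [(55.0, 5.0), (8.0, 12.0), (-1.8, 15.0)]:
            truth = PsychometricCurve(midpoint=midpoint, slope=slope)
            x = np.linspace(midpoint - 12, midpoint + 12, 15)
            fitted = fit_psychometric(list(zip(x, truth.predict(x))))
            for crit in (20.0, 50.0, 80.0):
                assert srt_from_curve(fitted, crit) == pytest.approx(
                    truth.inverse(crit), abs=1e-6
                )

    def test_criterion_outside_asymptotes_rejected(self):
        curve = PsychometricCurve(midpoint=0.0, slope=8.0, floor=10.0, ceiling=90.0)
        with pytest.raises(ValueError):
            srt_from_curve(curve, 95.0)


class TestReliability:
    def test_identical_pairs(self):
        r = bland_altman([(10.0, 10.0), (12.0, 12.0), (14.0, 14.0)])
        assert (r.bias, r.loa_low, r.loa_high, r.rmsd) == (0.0, 0.0, 0.0, 0.0)

    def test_constant_offset_pairs(self):
        r = bland_altman([(x + 2.0, x) for x in (10.0, 20.0, 30.0)])
        assert r.bias == pytest.approx(2.0)
        assert r.sd_diff == 0.0
        assert r.rmsd == pytest.approx(2.0)

    def test_hand_computed_five_pairs(self):
        # differences: 1, -1, 2, 0, 3 -> mean 1.0; sd (ddof=1) = sqrt(10/4)
        pairs = [(5.0, 4.0), (3.0, 4.0), (6.0, 4.0), (4.0, 4.0), (7.0, 4.0)]
        r = bland_altman(pairs)
        sd = np.sqrt(2.5)
        assert r.bias == pytest.approx(1.0)
        assert r.loa_low == pytest.approx(1.0 - 1.96 * sd)
        assert r.loa_high == pytest.approx(1.0 + 1.96 * sd)
        assert r.rmsd == pytest.approx(np.sqrt((1 + 1 + 4 + 0 + 9) / 5))
        assert r.means == tuple(np.mean(p) for p in pairs)

    def test_invariants_on_random_pairs(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            pairs = rng.normal(0, 5, size=(rng.integers(2, 40), 2))
            r = bland_altman([tuple(p) for p in pairs])
            assert r.loa_low <= r.bias <= r.loa_high
            assert r.rmsd >= abs(r.bias) - 1e-12

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            bland_altman([(1.0, 2.0)])
        with pytest.raises(ValueError):
            rmsd([])

    def test_rmsd_trivial_cases(self):
        assert rmsd([(4.0, 4.0), (9.0, 9.0)]) == 0.0
        assert rmsd([(7.0, 4.0)]) == 3.0

    def test_rmsd_of_independent_runs_matches_sampling_theory(self):
        # RMSD of test-retest pairs of independent, identically distributed
        # staircase runs is sqrt(2) x the single-run SD of the SRT estimate
        from asr_audiobench import (
            LogisticItemResponder,
            StaircaseConfig,
            make_triplet_series,
            run_din,
        )

        cfg = StaircaseConfig(initial_snr=-1.8)
        srts = np.array([
            run_din(
                LogisticItemResponder(srt=-1.8, slope=15.0, seed=[77, i]),
                make_triplet_series(i, 24),
                cfg,
            ).srt
            for i in range(400)
        ])
        pairs = list(zip(srts[::2], srts[1::2]))  # 200 independent pairs
        expected = np.sqrt(2.0) * srts.std(ddof=1)
        assert rmsd(pairs) == pytest.approx(expected, rel=0.2)


class TestSemanticDistance:
    def test_identical_transcripts(self):
        assert semantic_distance_default(("a", "b"), ("a", "b")) == 0.0

    def test_disjoint_vocabularies(self):
        assert semantic_distance_default(("a", "b"), ("x", "y")) == 1.0

    def test_half_overlap(self):
        ref = ("a", "b", "c", "d")
        hyp = ("a", "b", "x", "y")
        assert semantic_distance_default(ref, hyp) == pytest.approx(0.5)

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            semantic_distance_default((), ("a",))

    def test_hook_contract(self):
        hook = SemanticDistanceHook(name="dice", distance=semantic_distance_default)
        assert hook.distance(("x",), ("x",)) == 0.0


class TestWerGrid:
    def test_perfect_model_gives_zero_grid(self):
        model = TranscriberModel(srt_noise=-1000.0, insertion_rate=0.0, seed=1)
        grid = wer_grid(model, make_dialogue(1, 40), n_reps=5, seed=2)
        assert grid.wer.shape == (3, 3)
        assert np.all(grid.wer == 0.0)

    def test_default_grids_are_3_by_3(self):
        model = TranscriberModel(seed=1)
        grid = wer_grid(model, make_dialogue(1, 30), n_reps=2, seed=0)
        assert grid.snr_values == (-5.0, 10.0, 30.0)
        assert grid.rt_values == (0.0, 0.5, 2.5)
        df = grid.to_dataframe()
        assert df.shape == (3, 3)
        assert df.index.name == "snr_db"

    def test_monotone_in_snr_and_rt(self):
        model = TranscriberModel(srt_noise=8.0, slope_noise=5.0,
                                 rt_penalty=2.0, insertion_rate=0.02, seed=3)
        grid = wer_grid(model, make_dialogue(2, 80), n_reps=40, seed=4)
        assert np.all(np.diff(grid.wer, axis=0) <= 0), "WER must not rise with SNR"
        assert np.all(np.diff(grid.wer, axis=1) >= 0), "WER must not fall with RT"

    def test_semantic_metric_pluggable(self):
        model = TranscriberModel(srt_noise=-1000.0, insertion_rate=0.0, seed=1)
        grid = wer_grid(model, make_dialogue(1, 20), n_reps=2, seed=0,
                        metric=semantic_distance_default)
        assert grid.metric_name == "semantic_distance_default"
        assert np.all(grid.wer == 0.0)
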