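"""EM mixture deconvolution: closed-form fixed points, null behavior and
parameter recovery on planted screens."""

import numpy as np
import pytest

from tcrscreen import (
    BackgroundFreqs,
    classify_binders,
    deconvolve_cores,
    estimate_background,
    fit_mixture,
    position_information_content,
)
from tcrscreen.alphabet import AA_INDEX
from tcrscreen.processing import CoreSet


def core_set(cores_by_length):
    cs = CoreSet()
    for length, cores in cores_by_length.items():
        cs.cores[length] = list(cores)
    return cs


UNIFORM_BG = BackgroundFreqs(freqs=np.full(20, 0.05), pseudocount=0.0)


class TestBackground:
    def test_single_letter_library(self):
        bg = estimate_background(core_set({5: ["GGGGG"] * 3}), pseudocount=0.0)
        assert bg.freqs[AA_INDEX["G"]] == pytest.approx(1.0)

    def test_two_letter_split(self):
        bg = estimate_background(core_set({5: ["AAAAA", "CCCCC"]}), pseudocount=0.0)
        assert bg.freqs[AA_INDEX["A"]] == pytest.approx(0.5)
        assert bg.freqs[AA_INDEX["C"]] == pytest.approx(0.5)

    def test_matches_hand_count(self, screen_cores):
        input_cores, _, background = screen_cores
        counts = np.zeros(20)
        total = 0
        for core in input_cores.all_cores():
            for aa in core:
                counts[AA_INDEX[aa]] += 1
                total += 1
        expected = (counts + background.pseudocount) / (
            total + 20 * background.pseudocount
        )
        np.testing.assert_allclose(background.freqs, expected, atol=1e-12)

    def test_empty_input_named_error(self):
        with pytest.raises(ValueError, match="empty"):
            estimate_background(core_set({}))


class TestInformationContent:
    def test_background_motif_has_zero_ic(self):
        pwm = np.tile(UNIFORM_BG.freqs, (5, 1))
        ic = position_information_content(pwm, UNIFORM_BG)
        np.testing.assert_allclose(ic, 0.0, atol=1e-12)

    def test_point_mass_on_uniform_background(self):
        pwm = np.zeros((1, 20))
        pwm[0, AA_INDEX["W"]] = 1.0
        ic = position_information_content(pwm, UNIFORM_BG)
        assert ic[0] == pytest.approx(np.log2(20))

    def test_point_mass_on_half_background_is_one_bit(self):
        bg = np.full(20, 0.5 / 19)
        bg[AA_INDEX["L"]] = 0.5
        pwm = np.zeros((1, 20))
        pwm[0, AA_INDEX["L"]] = 1.0
        ic = position_information_content(
            pwm, BackgroundFreqs(freqs=bg, pseudocount=0.0)
        )
        assert ic[0] == pytest.approx(1.0)

    def test_zero_background_entry_named_error(self):
        bg = BackgroundFreqs.__new__(BackgroundFreqs)  # bypass smoothing validation
        bg.freqs = np.r_[1.0, np.zeros(19)]
        bg.pseudocount = 0.0
        with pytest.raises(ValueError, match="zero"):
            position_information_content(np.full((2, 20), 0.05), bg)


class TestEMFixedPoints:
    def test_identical_sequences_concentrate_the_motif(self):
        """100 copies of one core: motif weight -> ~1, PWM -> point mass."""
        model = fit_mixture(["NLGGL"] * 100, 1, UNIFORM_BG, seed=0)
        assert model.weights[0] > 0.95
        pwm = model.pwms[0]
        for p, aa in enumerate("NLGGL"):
            # pseudocount 0.1 over 100 responsibilities: ~100.1/102
            assert pwm[p, AA_INDEX[aa]] > 0.97

    def test_restart_stability_on_identical_sequences(self):
        lls = [
            fit_mixture(["NLGGL"] * 100, 1, UNIFORM_BG, seed=s,
                        n_restarts=5).log_likelihood
            for s in (0, 1)
        ]
        assert abs(lls[0] - lls[1]) <= 1e-6 * abs(lls[0])

    def test_too_few_sequences_named_error(self):
        with pytest.raises(ValueError, match="k\\+1"):
            fit_mixture(["NLGGL"], 1, UNIFORM_BG)

    def test_mixed_length_cores_rejected(self):
        with pytest.raises(ValueError, match="length"):
            fit_mixture(["NLGGL", "NLGG"], 1, UNIFORM_BG)


class TestEMInvariants:
    def test_loglik_monotone_and_simplex(self, screen_cores):
        _, output_cores, background = screen_cores
        model = fit_mixture(output_cores.cores[5], 1, background, seed=1)
        trace = np.array(model.trace)
        assert np.all(np.diff(trace) >= -1e-8 * np.abs(trace[:-1]))
        np.testing.assert_allclose(model.weights.sum(), 1.0, atol=1e-9)
        assert np.all(model.weights >= 0)
        np.testing.assert_allclose(
            model.responsibilities.sum(axis=1), 1.0, atol=1e-9
        )


class TestNullScreens:
    def test_background_only_cores_fail_ic_gate(self):
        """Cores sampled from the background yield a flat motif (< 1 bit)."""
        rng = np.random.default_rng(2)
        aa = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        cores = ["".join(rng.choice(aa, 5, p=UNIFORM_BG.freqs)) for _ in range(2_000)]
        model = fit_mixture(cores, 1, UNIFORM_BG, seed=2)
        ic = position_information_content(model.pwms[0], UNIFORM_BG)
        assert ic.max() < 1.0
        result = classify_binders(model, cores)
        assert not result.binders
        assert len(result.contaminants) == 2_000


class TestPlantedRecovery:
    def test_pwm_recovery_and_binder_f1(self, planted_screen, screen_cores,
                                        truth_binder_cores):
        """Recovered PWM within TV 0.1 per position; binder F1 >= 0.9."""
        _, output_cores, background = screen_cores
        results = deconvolve_cores(output_cores, background, seed=3)
        res = results[5]
        planted = planted_screen.motif.pwms[5]
        tv = 0.5 * np.abs(res.pwm - planted).sum(axis=1)
        assert tv.max() < 0.1

        truth5 = truth_binder_cores & set(output_cores.cores[5])
        predicted = set(res.binders)
        tp = len(predicted & truth5)
        precision = tp / len(predicted)
        recall = tp / len(truth5)
        f1 = 2 * precision * recall / (precision + recall)
        assert f1 >= 0.9
        assert precision >= 0.9 and recall >= 0.9
        # partition invariant
        assert set(res.binders) | set(res.contaminants) == set(output_cores.cores[5])
        assert not set(res.binders) & set(res.contaminants)

    def test_pure_screen_classifies_nearly_all_as_binders(self, design):
        """phi=0: >= 99% of cores join the (IC-passing) motif component."""
        from tcrscreen import ScreenSimConfig, sample_input_library, simulate_panning
        from tcrscreen import extract_cores
        from tcrscreen.pipeline import default_planted_motif

        cfg = ScreenSimConfig(
            n_input_clonotypes=2_000, n_output_clonotypes=2_000,
            contamination=0.0, seed=4,
        )
        inp = sample_input_library(design, cfg)
        screen = simulate_panning(inp, default_planted_motif((5,), seed=4), cfg, design)
        out_cores = extract_cores(screen.output_table, design)
        background = estimate_background(extract_cores(inp, design))
        model = fit_mixture(out_cores.cores[5], 1, background, seed=4)
        result = classify_binders(model, out_cores.cores[5])
        frac = len(result.binders) / len(out_cores.cores[5])
        assert result.ic_pass
        assert frac >= 0.99


def test_degenerate_model_with_no_flat_weight_keeps_all_binders():
    """A point-mass motif with negligible flat weight claims every matching core."""
    model = fit_mixture(["NLGGL"] * 50, 1, UNIFORM_BG, seed=5)
    result = classify_binders(model, ["NLGGL"] * 50)
    assert result.ic_pass
    assert len(result.binders) == 50
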