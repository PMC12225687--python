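"""Statistical and bookkeeping properties of the screen/repertoire simulators."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chisquare

from tcrscreen import (
    LibraryDesign,
    PlantedMotif,
    RepertoireSimConfig,
    ScreenSimConfig,
    generate_repertoire,
    sample_input_library,
    simulate_panning,
)
from tcrscreen.alphabet import AMINO_ACIDS, AA_INDEX
from tcrscreen.synthetic import write_airr_tsv, write_mixcr_tsv, write_truth_tsv


def core_of(seq: str) -> str:
    return seq[4:-5]


def position_freqs(cores: list[str], length: int) -> np.ndarray:
    counts = np.zeros((length, 20))
    for c in cores:
        for p, aa in enumerate(c):
            counts[p, AA_INDEX[aa]] += 1
    return counts / counts.sum(axis=1, keepdims=True)


class TestInputLibrary:
    def test_empty_request_gives_empty_table(self, design):
        table = sample_input_library(design, ScreenSimConfig(n_input_clonotypes=0))
        assert table.empty

    def test_degenerate_composition_collapses_to_one_clonotype(self):
        design = LibraryDesign(aa_composition={"G": 1.0}, core_lengths=(5,))
        cfg = ScreenSimConfig(n_input_clonotypes=3, seed=1)
        table = sample_input_library(design, cfg)
        assert list(table["cdr3_aa"]) == ["CASSGGGGGGELFF"]
        assert table["count"].iloc[0] >= 3  # summed over the three draws

    def test_invalid_composition_rejected_with_diagnostic(self):
        with pytest.raises(ValueError, match="sum"):
            LibraryDesign(aa_composition={"G": 0.7, "A": 0.4})
        with pytest.raises(ValueError, match="negative.*'A'"):
            LibraryDesign(aa_composition={"G": 1.2, "A": -0.2})
        with pytest.raises(ValueError, match="'B'"):
            LibraryDesign(aa_composition={"B": 1.0})

    def test_composition_goodness_of_fit(self, design):
        """Sampled per-letter frequencies match the design at alpha=0.01."""
        cfg = ScreenSimConfig(n_input_clonotypes=10_000, seed=3)
        table = sample_input_library(design, cfg)
        cores = [core_of(s) for s in table["cdr3_aa"]]
        expected = design.composition_vector()
        observed = np.zeros(20)
        for c in cores:
            for aa in c:
                observed[AA_INDEX[aa]] += 1
        keep = expected > 0
        assert observed[~keep].sum() == 0  # zero-probability letters never drawn
        stat, p = chisquare(observed[keep],
                            observed.sum() * expected[keep] / expected[keep].sum())
        assert p > 0.01

    def test_deterministic_given_seed(self, design):
        cfg = ScreenSimConfig(n_input_clonotypes=500, seed=5)
        a = sample_input_library(design, cfg)
        b = sample_input_library(design, cfg)
        pd.testing.assert_frame_equal(a, b)


class TestPanning:
    def test_pure_contamination_matches_input_composition(self):
        design = LibraryDesign(core_lengths=(5,))
        cfg = ScreenSimConfig(
            n_input_clonotypes=100, n_output_clonotypes=5_000,
            contamination=1.0, seed=2,
        )
        inp = sample_input_library(design, cfg)
        motif = PlantedMotif({5: np.full((5, 20), 0.05)}, beta=1.0)
        screen = simulate_panning(inp, motif, cfg, design)
        assert (screen.truth == "contaminant").all()
        cores5 = [core_of(s) for s in screen.output_table["cdr3_aa"]
                  if len(s) == 14]
        freqs = position_freqs(cores5, 5)
        tv = 0.5 * np.abs(freqs - design.composition_vector()).sum(axis=1)
        assert tv.max() < 0.05

    def test_degenerate_motif_dominates_at_high_beta(self, design):
        pwm = np.zeros((5, 20))
        for p, aa in enumerate("NLGGL"):
            pwm[p, AA_INDEX[aa]] = 1.0
        motif = PlantedMotif({5: pwm}, beta=50.0)
        cfg = ScreenSimConfig(
            n_input_clonotypes=100, n_output_clonotypes=200,
            contamination=0.0, seed=4,
        )
        inp = sample_input_library(design, cfg)
        screen = simulate_panning(inp, motif, cfg, design)
        assert all(core_of(s) == "NLGGL" for s in screen.output_table["cdr3_aa"])

    def test_binder_frequencies_match_planted_pwm(self, planted_screen):
        """Truth-binder per-position frequencies within TV 0.05 of the PWM."""
        binder_rows = planted_screen.truth.eq("binder").to_numpy()
        cores = [core_of(s) for s in
                 planted_screen.output_table.loc[binder_rows, "cdr3_aa"]]
        freqs = position_freqs(cores, 5)
        tilt = planted_screen.motif.pwms[5]  # beta=1 tilt IS the pwm
        tv = 0.5 * np.abs(freqs - tilt).sum(axis=1)
        assert tv.max() < 0.05

    def test_label_conservation(self, planted_screen):
        counts = planted_screen.truth.value_counts()
        assert counts.sum() == len(planted_screen.output_table) == 5_000

    def test_beta_zero_reduces_to_background(self, design):
        """With no selection the binder channel equals the background draw."""
        rng_pwm = np.random.default_rng(6).dirichlet(np.ones(20), size=5)
        motif = PlantedMotif({5: rng_pwm}, beta=0.0)
        cfg = ScreenSimConfig(
            n_input_clonotypes=100, n_output_clonotypes=2_000,
            contamination=0.0, seed=6,
        )
        inp = sample_input_library(design, cfg)
        screen = simulate_panning(inp, motif, cfg, design)
        cores = [core_of(s) for s in screen.output_table["cdr3_aa"]
                 if len(s) == 14]
        observed = np.zeros(20)
        for c in cores:
            for aa in c:
                observed[AA_INDEX[aa]] += 1
        expected = design.composition_vector()
        keep = expected > 0
        _, p = chisquare(observed[keep],
                         observed.sum() * expected[keep] / expected[keep].sum())
        assert p > 0.01

    def test_motif_length_absent_from_design_rejected(self, design):
        cfg = ScreenSimConfig(n_input_clonotypes=50, n_output_clonotypes=10)
        inp = sample_input_library(design, cfg)
        motif = PlantedMotif({6: np.full((6, 20), 0.05)})
        with pytest.raises(ValueError, match="absent"):
            simulate_panning(inp, motif, cfg, design)


class TestRepertoire:
    def test_spike_in_bookkeeping(self, design):
        spikes = ("CASSNTGGVGELFF", "CASSYVGNNGELFF", "CASSNLGGLGELFF")
        cfg = RepertoireSimConfig(n_records=1_000, spike_in=spikes, seed=8)
        rep = generate_repertoire(cfg, design)
        assert rep["spiked"].sum() == 3
        assert set(rep.loc[rep["spiked"], "junction_aa"]) == set(spikes)

    def test_flank_convention(self, design):
        rep = generate_repertoire(RepertoireSimConfig(n_records=500, seed=9), design)
        assert rep["junction_aa"].str.startswith("CASS").all()
        assert rep["junction_aa"].str.endswith("GELFF").all()

    def test_spike_violating_flanks_rejected(self, design):
        cfg = RepertoireSimConfig(n_records=10, spike_in=("CASAYVGNTGELFF",))
        with pytest.raises(ValueError, match="flank"):
            generate_repertoire(cfg, design)

    def test_length_histogram_goodness_of_fit(self, design):
        cfg = RepertoireSimConfig(n_records=50_000, seed=10)
        rep = generate_repertoire(cfg, design)
        lengths = rep["junction_aa"].str.len() - 9
        support = sorted(cfg.core_length_distribution)
        observed = np.array([(lengths == k).sum() for k in support])
        expected = len(rep) * np.array(
            [cfg.core_length_distribution[k] for k in support]
        )
        _, p = chisquare(observed, expected)
        assert p > 0.01

    def test_deterministic_given_seed(self, design):
        cfg = RepertoireSimConfig(n_records=300, seed=12)
        pd.testing.assert_frame_equal(
            generate_repertoire(cfg, design), generate_repertoire(cfg, design)
        )


def test_writers_round_trip(tmp_path, design, planted_screen):
    """MiXCR/AIRR writers emit files the readers parse back losslessly."""
    from tcrscreen import read_clonotype_table

    write_mixcr_tsv(planted_screen.input_table.head(50), tmp_path / "m.tsv")
    back = read_clonotype_table(tmp_path / "m.tsv", "mixcr")
    assert list(back["cdr3_aa"]) == list(planted_screen.input_table["cdr3_aa"].head(50))
    assert back["v_gene"].eq("TRBV6-5").all()

    rep = generate_repertoire(RepertoireSimConfig(n_records=20, seed=1), design)
    write_airr_tsv(rep, tmp_path / "a.tsv")
    back = read_clonotype_table(tmp_path / "a.tsv", "airr")
    assert list(back["cdr3_aa"]) == list(rep["junction_aa"])

    write_truth_tsv(planted_screen, tmp_path / "t.tsv")
    truth = pd.read_csv(tmp_path / "t.tsv", sep="\t")
    assert set(truth["truth"]) <= {"binder", "contaminant"}
    assert len(truth) == planted_screen.output_table["cdr3_aa"].nunique()
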