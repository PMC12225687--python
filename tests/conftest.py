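"""Shared fixtures: one planted screen reused by the deconvolution and
classifier tests (session-scoped; regenerating it per test would dominate
runtime without changing what is checked)."""

from __future__ import annotations

import numpy as np
import pytest

from tcrscreen import (
    ClassifierConfig,
    LibraryDesign,
    ScreenSimConfig,
    estimate_background,
    extract_cores,
    sample_input_library,
    simulate_panning,
)
from tcrscreen.pipeline import default_planted_motif


@pytest.fixture(scope="session")
def design() -> LibraryDesign:
    return LibraryDesign()


@pytest.fixture(scope="session")
def planted_screen(design):
    """Screen at the reference study conditions: phi=0.5, beta=1, n=5,000."""
    cfg = ScreenSimConfig(
        n_input_clonotypes=8_000,
        n_output_clonotypes=5_000,
        contamination=0.5,
        singleton_rate=0.2,
        seed=11,
    )
    motif = default_planted_motif((5,), beta=1.0, seed=11)
    input_table = sample_input_library(design, cfg)
    screen = simulate_panning(input_table, motif, cfg, design)
    return screen


@pytest.fixture(scope="session")
def screen_cores(planted_screen, design):
    """Input/output core sets plus the estimated background of the screen."""
    input_cores = extract_cores(planted_screen.input_table, design)
    output_cores = extract_cores(planted_screen.output_table, design)
    background = estimate_background(input_cores)
    return input_cores, output_cores, background


@pytest.fixture(scope="session")
def truth_binder_cores(planted_screen):
    """Ground-truth binder cores (unique), for recovery checks."""
    binder_rows = planted_screen.truth.eq("binder").to_numpy()
    seqs = planted_screen.output_table.loc[binder_rows, "cdr3_aa"]
    return set(seqs.str[4:-5])


@pytest.fixture(scope="session")
def small_clf_config() -> ClassifierConfig:
    """Compact encoder for fast tests; architecture unchanged in kind."""
    return ClassifierConfig(
        d_model=32,
        n_heads=4,
        n_layers=1,
        d_ff=64,
        dropout=0.1,
        max_epochs=40,
        patience=6,
        batch_size=32,
        max_len=20,
        seed=7,
    )


@pytest.fixture(scope="session")
def multilength_screen(design):
    """Screen with the motif planted at all three library core lengths,
    as the affinity-enhanced templates yield; used for classifier fixtures."""
    cfg = ScreenSimConfig(
        n_input_clonotypes=8_000,
        n_output_clonotypes=6_000,
        contamination=0.5,
        singleton_rate=0.2,
        seed=17,
    )
    motif = default_planted_motif((5, 7, 9), beta=2.0, seed=17)
    input_table = sample_input_library(design, cfg)
    return simulate_panning(input_table, motif, cfg, design)


@pytest.fixture(scope="session")
def screen_model(multilength_screen, small_clf_config, design):
    """Classifier trained on deconvolved screen binders vs library negatives,
    with 40 binder sequences held out for spike-in tests."""
    from tcrscreen import deconvolve_cores, train_classifier

    screen = multilength_screen
    output_cores = extract_cores(screen.output_table, design)
    background = estimate_background(extract_cores(screen.input_table, design))
    results = deconvolve_cores(output_cores, background, seed=13)
    binders = sorted(
        design.embed(core) for res in results.values() for core in res.binders
    )
    output_seqs = set(screen.output_table["cdr3_aa"])
    negatives = sorted(set(screen.input_table["cdr3_aa"]) - output_seqs)
    rng = np.random.default_rng(31)
    rng.shuffle(binders)
    rng.shuffle(negatives)
    held_out, train_pos = binders[:60], binders[60:1260]
    cfg = ClassifierConfig(
        **{**small_clf_config.__dict__, "batch_size": 64, "max_epochs": 25}
    )
    model = train_classifier(train_pos, negatives[:1200], cfg)
    return model, tuple(held_out)


def make_separable_sets(n_per_class: int, seed: int = 0):
    """Toy planted rule: positives always carry G at core position 3."""
    rng = np.random.default_rng(seed)
    letters = np.array(list("ARNDEQHKFYWLIVST"))
    pos, neg = set(), set()
    while len(pos) < n_per_class:
        core = "".join(rng.choice(letters, 5))
        pos.add("CASS" + core[:2] + "G" + core[3:] + "GELFF")
    while len(neg) < n_per_class:
        core = "".join(rng.choice(letters, 5))
        seq = "CASS" + core + "GELFF"
        if seq not in pos:
            neg.add(seq)
    return sorted(pos), sorted(neg)
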