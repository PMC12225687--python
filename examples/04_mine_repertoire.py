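"""Mine a bulk TCR repertoire for epitope-specific candidates.

Generates a TRBV6-5/TRBJ2-2 repertoire with a handful of known binders
spiked in, scores every record with a screen-trained model, and selects a
validation panel spanning the score range.
"""

import numpy as np

from tcrscreen import (
    ClassifierConfig,
    LibraryDesign,
    RepertoireSimConfig,
    ScreenSimConfig,
    deconvolve_cores,
    estimate_background,
    extract_cores,
    filter_repertoire,
    generate_repertoire,
    rank_repertoire,
    sample_input_library,
    select_candidates,
    simulate_panning,
    train_classifier,
)
from tcrscreen.pipeline import default_planted_motif

design = LibraryDesign()
cfg = ScreenSimConfig(n_input_clonotypes=8_000, n_output_clonotypes=6_000,
                      contamination=0.5, singleton_rate=0.2, seed=3)
motif = default_planted_motif((5, 7, 9), beta=2.0, seed=3)
input_table = sample_input_library(design, cfg)
screen = simulate_panning(input_table, motif, cfg, design)
background = estimate_background(extract_cores(input_table, design))
results = deconvolve_cores(extract_cores(screen.output_table, design),
                           background, seed=3)
binders = sorted(design.embed(c) for r in results.values() for c in r.binders)
negatives = sorted(set(input_table["cdr3_aa"]) - set(screen.output_table["cdr3_aa"]))
rng = np.random.default_rng(3)
rng.shuffle(binders)
rng.shuffle(negatives)

clf = ClassifierConfig(d_model=32, n_heads=4, n_layers=1, d_ff=64,
                       max_epochs=25, patience=4, batch_size=64,
                       max_len=20, seed=3)
model = train_classifier(binders[20:1020], negatives[:1000], clf)

spikes = tuple(binders[:20])  # known binders planted into the repertoire
rep = generate_repertoire(
    RepertoireSimConfig(n_records=20_000, spike_in=spikes, seed=3), design
)
filtered = filter_repertoire(rep, design)
scored = rank_repertoire(model, filtered, design)
panel = select_candidates(scored, 30, "broad_range", seed=3)

table = scored.table
spike_ranks = sorted(table.loc[table["junction_aa"].isin(spikes), "rank"])
cutoff = int(np.ceil(0.01 * len(table)))
print(f"repertoire: {len(table)} template-compatible records")
print(f"spiked binder ranks: {spike_ranks}")
print(f"spikes in top 1% (rank <= {cutoff}): "
      f"{np.mean([r <= cutoff for r in spike_ranks]):.0%}")
print()
print("selected validation panel (first 8 of 30, broad score range):")
print(panel.head(8)[["junction_aa", "score", "rank", "core_length"]]
      .to_string(index=False))
print()
print(
    "Known binders concentrate at the very top of the ranking; the selected "
    "panel deliberately spans high and low scores and several core lengths, "
    "the way an experimental validation set should."
)
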