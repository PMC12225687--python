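"""Separate the binding motif from background contamination with mixture EM.

Fits a one-motif + fixed-flat-background mixture to the panned cores and
gates the motif on information content (> 1 bit at some position), then
compares the recovered binder calls with the simulation's ground truth.
"""

import numpy as np

from tcrscreen import (
    LibraryDesign,
    ScreenSimConfig,
    deconvolve_cores,
    estimate_background,
    extract_cores,
    sample_input_library,
    simulate_panning,
)
from tcrscreen.pipeline import default_planted_motif

design = LibraryDesign()
cfg = ScreenSimConfig(
    n_input_clonotypes=8_000, n_output_clonotypes=5_000,
    contamination=0.5, singleton_rate=0.2, seed=1,
)
motif = default_planted_motif((5,), beta=1.0, seed=1)
input_table = sample_input_library(design, cfg)
screen = simulate_panning(input_table, motif, cfg, design)

background = estimate_background(extract_cores(input_table, design))
output_cores = extract_cores(screen.output_table, design)
result = deconvolve_cores(output_cores, background, seed=1)[5]

print(f"length-5 cores: {len(output_cores.cores[5])} unique")
print(f"binders called: {len(result.binders)}; contaminants: {len(result.contaminants)}")
print(f"motif weight: {result.model.weights[0]:.3f}  (flat: {result.model.weights[-1]:.3f})")
print("per-position information content (bits):",
      np.round(result.information_content, 2))
print(f"IC gate (> 1 bit at some position): {'PASS' if result.ic_pass else 'FAIL'}")

truth = set(
    screen.output_table.loc[screen.truth.eq('binder').to_numpy(), "cdr3_aa"].str[4:-5]
) & set(output_cores.cores[5])
tp = len(set(result.binders) & truth)
f1 = 2 * tp / (len(result.binders) + len(truth))
print(f"binder F1 against simulation truth: {f1:.3f}")
print()
print(
    "High IC at the anchor positions marks a genuine binding motif; an F1 "
    "near 1 means the mixture cleanly separated binders from carryover."
)
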