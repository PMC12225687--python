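# tcrscreen

Analysis toolkit for phage-display screens of T-cell receptors (TCRs) with
randomized CDR3β loops, and for mining bulk TCR repertoires with the
models trained on such screens.

The workflow it implements: a TCR library is built on a template receptor
(here the NY-ESO-1–specific 1G4, `CASSYVGNTGELFF` on TRBV6-5/TRBJ2-2) with
the central CDR3β *core* randomized at lengths 5/7/9 between constant
flanks `CASS…GELFF`. After one round of panning against the peptide–MHC
target, the sequenced output is a mixture of epitope-binding clones and
background carryover. `tcrscreen` takes it from there:

1. **Simulation** (`tcrscreen.synthetic`) — generate input libraries, panned
   outputs with planted ground truth, and AIRR-style repertoires with
   spiked-in binders, so every downstream stage is testable without data
   downloads.
2. **Processing** (`tcrscreen.processing`) — read MiXCR/AIRR clonotype
   tables, drop singletons, template escapees (`YVGNT` cores) and
   non-standard sequences, deduplicate, and extract per-length cores.
3. **Motif deconvolution** (`tcrscreen.deconvolution`) — per core length, an
   EM-fitted mixture of `k` position-weight-matrix (PWM) motifs plus one
   *flat* component pinned to the input-library composition `b`:

   `p(s) = w_flat · Π_p b(s_p) + Σ_m w_m · Π_p f_{m,p}(s_p)`

   Sequences in the flat component, or in motifs with no position whose
   information content `IC_p = Σ_a f_{p,a} log2(f_{p,a}/b_a)` exceeds 1 bit,
   are flagged as contaminants; the rest are binders.
4. **Classification** (`tcrscreen.classifier`) — a transformer-encoder
   binding classifier (token embedding + positional encoding + self-attention
   encoder + linear head) trained on deconvolved binders vs input-library
   non-binders, emitting a log-odds binding score per CDR3β. Implemented in
   NumPy on an in-package reverse-mode autodiff core; training and scoring
   are fully seed-deterministic.
5. **Repertoire mining** (`tcrscreen.mining`) — filter a repertoire to the
   template-compatible space (V/J match, `CASS…GELFF` flanks, standard
   alphabet), rank by model score, and select validation panels spanning the
   score range.
6. **Baselines & benchmark** (`tcrscreen.baselines`) — exact match, BLOSUM62
   similarity to the reference CDR3β, a tcrdist-style capped substitution
   distance, and a Mann–Whitney AUC harness; a published 30-TCR validation
   panel is bundled (`tcrscreen.datasets`).
7. **Cross-reactivity scan** (`tcrscreen.crossreactivity`) — enumerate
   proteome 9-mers, filter by pMHC %rank (external file or a labeled
   heuristic stand-in), require anchor residues (W5/Q8 for SLLMWITQC), rank
   by BLOSUM62 similarity.

A thin `tcrscreen` CLI (`run-all`, `process`, `deconvolve`, `train`, `cv`,
`score`, `mine`, `xreact`) wraps the same API; `tcrscreen.pipeline` runs the
full workflow from one YAML config and writes a reproducibility manifest.

## Worked example

`python examples/02_deconvolve_motif.py` simulates a screen at 50%
contamination and deconvolves it:

```
length-5 cores: 2793 unique
binders called: 1950; contaminants: 843
motif weight: 0.697  (flat: 0.303)
per-position information content (bits): [1.31 2.18 2.19 1.18 1.  ]
IC gate (> 1 bit at some position): PASS
binder F1 against simulation truth: 0.967
```

The mixture recovers the planted motif (anchor positions above 2 bits) and
calls binders with F1 0.97 against the simulation's hidden labels.

`python examples/05_benchmark_baselines.py` scores the bundled 30-TCR
validation panel (6 multimer-positive, 24 negative):

```
                        method      auc  n_pos  n_neg
        published_model_scores 0.930556      6     24
blosum_similarity_to_reference 0.829861      6     24
    cdr3_distance_to_reference 0.715278      6     24
 exact_match_vs_reference_only 0.500000      6     24
```

The screen-trained model's published scores separate validated binders from
non-binders best (AUC = 134/144 ≈ 0.93); similarity to the single reference
CDR3β is weaker. The other examples cover simulation, training/CV,
repertoire mining and the proteome scan.

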