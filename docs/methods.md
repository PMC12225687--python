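# Methods

This note documents the models behind `tcrscreen`, the choices made where
the design was genuinely open, and what the synthetic-data results do and do
not establish.

## The screen simulator

The generator emulates a one-round phage-display selection of a TCR library
whose CDR3β core is randomized between constant flanks (`CASS` … `GELFF`)
at lengths 5/7/9 on a single V/J pair (TRBV6-5 / TRBJ2-2).

**Input library.** Cores are i.i.d. draws from a designed amino-acid
composition; lengths uniform over the design lengths. The default
composition is a *stand-in*: mild Gly/Ser enrichment and no Cys, reproducing
the qualitative features of trimer-codon mixes designed to mimic natural
CDR3β cores. It is fully overridable (`LibraryDesign.aa_composition`);
nothing downstream assumes its exact values. Clone read counts follow a
geometric distribution (support ≥ 1, default mean 5) — a deliberately
heavy-ish tail so that the singleton filter downstream has real work.

**Panning.** Selection is a likelihood-ratio tilt: a binder core is drawn
with probability ∝ `b(core) · [PWM(core)/b(core)]^β`, which factorizes
per position into `b^(1−β) f^β` (normalized). β = 0 reduces exactly to the
background; β = 1 draws straight from the PWM; β > 1 sharpens selection the
way higher panning stringency does. With probability φ (the contamination
fraction) an output clone is instead re-drawn from the input composition.
Output rows model nucleotide-level clonotypes, so duplicate amino-acid
sequences can occur and are collapsed only by the downstream dedup filter.
A configurable fraction of output rows is forced to read count 1 as a
sequencing-noise stand-in; there is no PCR/error model beyond that, no
multi-round kinetics, and wash-stringency arms are modeled as one pooled
output.

**Planted motif.** The default test motif mirrors the structure of motifs
such screens recover for the NY-ESO-1 system: Asn/Tyr/Ser-enriched position
1, aliphatic (Leu/Ile/Val) position 2, Gly at position 3, weak preferences
elsewhere. Validated binder cores in the published panel are
near-deterministic at those anchors (position 3 is always Gly), so the
screens used for classifier studies are simulated at β = 2; the motif-
recovery studies use the more adversarial φ = 0.5, β = 1 setting.

**Repertoires.** AIRR-convention records on the same V/J pair with core
lengths 4–9 (including lengths absent from the phage design, as real
repertoires have), plus spike-in sequences placed exactly once at recorded
indices. The generator does not model V/J diversity, clonal expansion
structure, or sequencing chemistry — synthetic results therefore speak to
the statistical machinery, not to artifacts of real repertoire sequencing.

## Quality filters

Filter order is fixed: standard-alphabet → singleton (count = 1) → template
core (cores equal to the un-randomized template, default `YVGNT`) →
amino-acid-level deduplication with summed counts. Dedup runs last so that
summing counts can never ambiguously resurrect a removed singleton. Gene
matching strips allele suffixes (`*01`), alignment scores (`(1200)`) and
whitespace, case-insensitively, while the original strings are preserved.
Every filter logs its removal tally; kept + removed = input is asserted in
tests.

## Motif deconvolution

Per core length L, sequences are modeled as a mixture of k PWM motifs and
one flat component fixed to the input-library composition (position-pooled,
additive smoothing 0.5 so every frequency is strictly positive):

    p(s) = w_flat · Π_p b(s_p) + Σ_m w_m · Π_p f_{m,p}(s_p)

EM updates the motif PWMs (pseudocount α = 0.1 per cell) and all mixture
weights; the flat component's frequencies are never updated. Convergence is
a relative log-likelihood change below 1e-6 (cap 500 iterations); 5 random
restarts keep the best likelihood. Restarts initialize PWMs as an even blend
of the empirical position frequencies and Dirichlet noise. Deconvolution is
run independently per length — fixed-length PWMs, no offset/alignment
handling — and k defaults to 1, matching how such screens are analyzed.

Information content is the KL divergence of a motif column to the
background, in bits: `IC_p = Σ_a f_{p,a} log2(f_{p,a}/b_a)`. A motif with no
position strictly above 1 bit fails the gate and its members are reported as
putative contaminants, as are all members of the flat component. Assignment
is by maximum responsibility; exact ties go to the flat component
(conservative). This module follows the published mixture structure (flat
background + PWM motifs) but does not claim bit-compatibility with the MoDec
tool, whose priors and offset handling are parameterized differently.

## The binding classifier

Architecture: token embedding (20 residues + padding + begin/end markers),
sinusoidal positional encoding, a pre-LayerNorm transformer encoder
(default: embedding 64, 2 layers, 4 heads, feed-forward 128, dropout 0.1),
masked mean pooling, and a linear head giving one pre-sigmoid score — a
log-odds of binding, matching the signed-real score scale of published
panels. The input unit is the full CDR3β including flanks, so a trained
model scores repertoire sequences of core lengths never seen in training.

The implementation is NumPy throughout, on an in-package reverse-mode
autodiff engine whose gradients are finite-difference-checked in the test
suite. Everything is seeded: parameter init, batch order, dropout masks and
fold assignment derive from the config seed, so identical config + data
reproduce identical weights. Padding width cannot change a score: padded
positions receive exactly zero attention weight and are excluded from
pooling, so scores are invariant to batch composition (up to BLAS rounding
of order 1e-16).

Training: Adam (lr 1e-3), binary cross-entropy via a stable softplus form,
negatives subsampled to a 1:1 ratio by default, a stratified 10% validation
split for early stopping (patience 10 by default), best-validation weights
restored. Positives and negatives must be disjoint — the negative
construction (input-library sequences absent from the panned output)
guarantees it for real screens, and the trainer enforces it. Stated test and
acceptance runs use a scaled-down encoder (embedding 32, 1 layer,
feed-forward 64, batch 32–64, ≤ 25–40 epochs) — the same architecture
family at sizes suited to a single CPU; the library defaults above remain
the recommended configuration.

AUC is computed by the Mann–Whitney rank formulation with ties counted ½
(equal to trapezoidal ROC area); tests pin it to an exhaustive pairwise
oracle at 1e-12 and to scikit-learn's implementation. Cross-validation uses
stratified folds with per-fold seeds.

## Mining and selection

Repertoire filtering keeps records matching the design V/J
(allele-insensitive), the flank convention and the standard alphabet, then
collapses duplicate junctions. Ranking is by model score, descending, with
score ties broken lexicographically by sequence so rankings are
deterministic and stable under record shuffling. The `broad_range` selection
strategy stratifies the score range into 6 quantile bands (a documented
stand-in — published panels mix high and low scores without a stated rule)
and prefers distinct core lengths within a band; `top` takes the best n.

## Baselines

BLOSUM62 comes from Biopython's substitution matrices; tests cross-check a
hand-entered subset of published entries. For unequal lengths both the
similarity and the distance anchor the constant flanks and slide the shorter
core gaplessly along the longer, taking the best offset; unmatched positions
cost the matrix minimum (similarity) or 4 per gap (distance). The distance
uses capped substitution penalties `min(4, 4 − BLOSUM62)` scaled by the
conventional CDR3 weight 3. This length handling is a simplification of
tcrdist — deliberately documented as such, not a bit-compatible clone — so
its absolute AUCs are not comparable against published tcrdist numbers.

## Cross-reactivity scan

All 9-mer windows of a proteome FASTA are enumerated with provenance
(0-based internally, 1-based in reports); windows with non-standard residues
are skipped. The pMHC binding filter is pluggable: an external
peptide→%rank TSV (strictly `rank < 1.5` kept, matching "below 1.5"
semantics — 1.5 exactly is dropped), or a built-in HLA-A\*02:01 anchor
heuristic (position 2 ∈ {L,M,I,V}, C-terminus ∈ {V,L,I,A}) that is
explicitly labeled *not* equivalent to a trained predictor, or pass-through.
Anchor requirements (default W at 5 and Q at 8, the residues critical for
TCR contact on SLLMWITQC) reject peptides before ranking regardless of
score; ranking is by BLOSUM62 similarity with lexicographic tie-break. The
final manual choice among top candidates is not algorithmic; the module
stops at the ranked report.

## Problem sizes

Synthetic studies run at: screens of 8,000 input / 5,000–6,000 output
clonotypes; motif recovery at φ = 0.5, β = 1, single length; classifier
studies on 400–1,200 sequences per class with fivefold CV; spike-in recovery
with 50 planted binders in a 50,000-record repertoire. These sizes give
stable statistics (motif TV ≈ 0.06, binder F1 ≈ 0.97, CV AUC ≈ 0.99,
spike recovery ≥ 0.9 across seeds) while keeping a full run in minutes on
one CPU.

## Known limitations

- The simulator's composition, count model and motif are stand-ins; passing
  tests establish correctness of the estimators under the stated generative
  model, not performance on any particular real screen.
- Spiked "known binders" are deconvolution-validated sequences; since the
  deconvolution has ~4% false-positive binder calls, spike-recovery near
  0.95 is the practical ceiling, not 1.0.
- Deconvolution handles one motif per length by default and no cross-length
  alignment; k > 1 is supported but no model-selection criterion is
  provided.
- The classifier is a single-epitope CDR3β model: no α chain, CDR1/2 or
  V/J covariates, and predictions do not transfer across V genes.
- The built-in pMHC anchor heuristic is intentionally crude; real scans
  should supply an external %rank file.
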