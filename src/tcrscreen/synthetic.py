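"""Synthetic phage-screen and repertoire generators.

The simulators emulate a single-round phage-display selection of TCRs with a
randomized CDR3β core: an *input* library of cores drawn i.i.d. from a
designed amino-acid composition between fixed flanks (CASS ... GELFF), and a
panned *output* library that mixes motif-selected binders with background
contaminants carried over from the input. A repertoire generator emulates a
bulk TCRβ extract restricted to one V/J pair, with known binder sequences
spiked in at recorded positions.

All generators are deterministic given their seed; tables are returned as
pandas DataFrames with columns ``cdr3_aa``, ``count``, ``v_call``, ``j_call``
and can be written as MiXCR-style or AIRR rearrangement TSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alphabet import AMINO_ACIDS, AA_INDEX, freq_vector

#: Canonical clonotype-table columns used across the package.
CLONOTYPE_COLUMNS = ["cdr3_aa", "count", "v_call", "j_call"]

# Stand-in core composition: mild Gly/Ser enrichment, no Cys. The real screen
# used a trimer-codon mixture approximating natural CDR3β cores; that exact
# composition is configurable, this default only reproduces its qualitative
# features (Gly enrichment, cysteine excluded).
_default_weights = {aa: 1.0 for aa in AMINO_ACIDS}
_default_weights["C"] = 0.0
_default_weights["G"] = 2.5
_default_weights["S"] = 2.0
_total = sum(_default_weights.values())
DEFAULT_CORE_COMPOSITION: dict[str, float] = {
    aa: w / _total for aa, w in _default_weights.items() if w > 0
}


@dataclass(frozen=True)
class LibraryDesign:
    """Design of the randomized-core CDR3β library.

    Cores of the given lengths are drawn i.i.d. from ``aa_composition`` and
    embedded between the constant N-/C-terminal flanks; every clonotype
    carries the single V/J pair of the template TCR.
    """

    flank_n: str = "CASS"
    flank_c: str = "GELFF"
    core_lengths: tuple[int, ...] = (5, 7, 9)
    aa_composition: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CORE_COMPOSITION)
    )
    v_gene: str = "TRBV6-5"
    j_gene: str = "TRBJ2-2"

    def __post_init__(self) -> None:
        if not self.core_lengths or min(self.core_lengths) <= 0:
            raise ValueError("core_lengths must be positive integers")
        # validates alphabet, non-negativity and normalization
        freq_vector(self.aa_composition)

    def composition_vector(self) -> np.ndarray:
        return freq_vector(self.aa_composition)

    def embed(self, core: str) -> str:
        return self.flank_n + core + self.flank_c


@dataclass(frozen=True)
class PlantedMotif:
    """Ground-truth binding preference planted in a simulated screen.

    ``pwms`` maps core length L to an (L, 20) row-stochastic position
    frequency matrix; ``beta`` is the selection-strength exponent of the
    likelihood-ratio tilt used during panning (0 = no selection).
    """

    pwms: dict[int, np.ndarray]
    beta: float = 1.0

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError("enrichment strength beta must be >= 0")
        for length, pwm in self.pwms.items():
            pwm = np.asarray(pwm, dtype=float)
            if pwm.shape != (length, 20):
                raise ValueError(
                    f"PWM for length {length} has shape {pwm.shape}, expected ({length}, 20)"
                )
            if np.any(pwm < 0) or not np.allclose(pwm.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError(f"PWM rows for length {length} must sum to 1")
            self.pwms[length] = pwm


@dataclass(frozen=True)
class ScreenSimConfig:
    """Sizes, noise and count model of a simulated screen."""

    n_input_clonotypes: int = 10_000
    n_output_clonotypes: int = 5_000
    contamination: float = 0.5
    count_mean: float = 5.0
    singleton_rate: float = 0.2
    allele_suffix: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.contamination <= 1.0:
            raise ValueError("contamination fraction must be in [0, 1]")
        if self.count_mean < 1.0:
            raise ValueError("count_mean must be >= 1 (counts are >= 1)")
        if not 0.0 <= self.singleton_rate <= 1.0:
            raise ValueError("singleton_rate must be in [0, 1]")


@dataclass(frozen=True)
class RepertoireSimConfig:
    """Configuration of the bulk-repertoire generator."""

    n_records: int = 10_000
    core_length_distribution: dict[int, float] = field(
        default_factory=lambda: {4: 0.1, 5: 0.4, 6: 0.2, 7: 0.2, 8: 0.05, 9: 0.05}
    )
    spike_in: tuple[str, ...] = ()
    spike_positions: tuple[int, ...] | None = None
    allele_suffix: bool = True
    count_mean: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        probs = np.array(list(self.core_length_distribution.values()), dtype=float)
        if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("core length distribution must be a probability vector")
        if self.spike_positions is not None and len(self.spike_positions) != len(
            self.spike_in
        ):
            raise ValueError("spike_positions must match spike_in in length")


@dataclass
class SimulatedScreen:
    """Paired input/output tables with per-output-row ground truth.

    ``truth`` is aligned with ``output_table`` rows and takes values
    ``"binder"`` / ``"contaminant"``. Output rows are nucleotide-level
    clonotype draws, so identical amino-acid sequences may appear in several
    rows; the downstream deduplication filter collapses them.
    """

    input_table: pd.DataFrame
    output_table: pd.DataFrame
    truth: pd.Series
    motif: PlantedMotif


def _gene_name(gene: str, allele_suffix: bool) -> str:
    return f"{gene}*01" if allele_suffix else gene


def _draw_counts(rng: np.random.Generator, n: int, mean: float) -> np.ndarray:
    # geometric on {1, 2, ...}: heavy-ish tail, exercises the singleton filter
    return rng.geometric(1.0 / mean, size=n)


def _sample_cores(
    rng: np.random.Generator,
    n: int,
    lengths: np.ndarray,
    comp: np.ndarray,
) -> list[str]:
    aa = np.array(list(AMINO_ACIDS))
    cores = []
    for length in lengths:
        idx = rng.choice(20, size=int(length), p=comp)
        cores.append("".join(aa[idx]))
    return cores


def sample_input_library(
    design: LibraryDesign, cfg: ScreenSimConfig
) -> pd.DataFrame:
    """Draw an unselected input library of unique clonotypes.

    Cores are i.i.d. from the design composition with lengths uniform over
    the design lengths; identical amino-acid sequences are collapsed with
    summed counts, so the returned table has unique ``cdr3_aa``.
    """
    rng = np.random.default_rng(cfg.seed)
    comp = design.composition_vector()
    n = cfg.n_input_clonotypes
    lengths = rng.choice(
        np.array(sorted(design.core_lengths)), size=n
    )
    cores = _sample_cores(rng, n, lengths, comp)
    counts = _draw_counts(rng, n, cfg.count_mean)
    table = pd.DataFrame(
        {
            "cdr3_aa": [design.embed(c) for c in cores],
            "count": counts,
            "v_call": _gene_name(design.v_gene, cfg.allele_suffix),
            "j_call": _gene_name(design.j_gene, cfg.allele_suffix),
        }
    )
    table = (
        table.groupby(["cdr3_aa", "v_call", "j_call"], as_index=False, sort=True)
        .agg(count=("count", "sum"))
        .loc[:, CLONOTYPE_COLUMNS]
    )
    return table.reset_index(drop=True)


def _tilted_pwm(pwm: np.ndarray, background: np.ndarray, beta: float) -> np.ndarray:
    """Per-position selection distribution b^(1-beta) * f^beta, normalized.

    The panning model reweights a core by [PWM(core)/background(core)]^beta on
    top of the background, which factorizes position-wise into this tilt.
    """
    b = np.broadcast_to(np.asarray(background, dtype=float), pwm.shape)
    if beta == 0.0:
        tilt = b.copy()
    elif beta == 1.0:
        tilt = pwm.copy()
    else:
        tilt = np.zeros_like(pwm)
        ok = (b > 0) & (pwm > 0)
        tilt[ok] = np.exp((1.0 - beta) * np.log(b[ok]) + beta * np.log(pwm[ok]))
    norms = tilt.sum(axis=1, keepdims=True)
    if np.any(norms <= 0):
        raise ValueError("selection tilt degenerate: a position has zero total mass")
    return tilt / norms


def simulate_panning(
    input_table: pd.DataFrame,
    motif: PlantedMotif,
    cfg: ScreenSimConfig,
    design: LibraryDesign | None = None,
) -> SimulatedScreen:
    """Simulate one pooled round of panning against the planted motif.

    Each output clonotype is, with probability ``1 - contamination``, a binder
    whose core is drawn from the motif-tilted composition, and otherwise a
    contaminant re-drawn from the input composition. Counts are re-drawn from
    the count model; a ``singleton_rate`` fraction of rows is forced to count
    1 as a stand-in for sequencing noise.
    """
    if input_table.empty:
        raise ValueError("input_table is empty; nothing to pan")
    design = design or LibraryDesign()
    missing = set(motif.pwms) - set(design.core_lengths)
    if missing:
        raise ValueError(
            f"motif lengths {sorted(missing)} absent from the library design"
        )
    rng = np.random.default_rng(cfg.seed + 1)
    comp = design.composition_vector()
    n = cfg.n_output_clonotypes

    is_binder = rng.random(n) < (1.0 - cfg.contamination)
    motif_lengths = np.array(sorted(motif.pwms))
    tilts = {
        length: _tilted_pwm(motif.pwms[length], comp, motif.beta)
        for length in motif.pwms
    }
    aa = np.array(list(AMINO_ACIDS))

    cores: list[str] = []
    for binder in is_binder:
        if binder:
            length = int(rng.choice(motif_lengths))
            tilt = tilts[length]
            idx = [rng.choice(20, p=tilt[p]) for p in range(length)]
        else:
            length = int(rng.choice(np.array(sorted(design.core_lengths))))
            idx = rng.choice(20, size=length, p=comp)
        cores.append("".join(aa[idx]))

    counts = _draw_counts(rng, n, cfg.count_mean)
    force_single = rng.random(n) < cfg.singleton_rate
    counts = np.where(force_single, 1, counts)

    output = pd.DataFrame(
        {
            "cdr3_aa": [design.embed(c) for c in cores],
            "count": counts,
            "v_call": _gene_name(design.v_gene, cfg.allele_suffix),
            "j_call": _gene_name(design.j_gene, cfg.allele_suffix),
        }
    )
    truth = pd.Series(
        np.where(is_binder, "binder", "contaminant"), name="truth"
    )
    return SimulatedScreen(
        input_table=input_table, output_table=output, truth=truth, motif=motif
    )


def generate_repertoire(
    cfg: RepertoireSimConfig, design: LibraryDesign | None = None
) -> pd.DataFrame:
    """Generate an AIRR-convention bulk repertoire restricted to one V/J pair.

    Core lengths follow ``core_length_distribution`` (which may include
    lengths outside the phage-library design, as real repertoires do); all
    spike-in sequences are placed exactly once at their recorded indices. The
    returned frame carries AIRR column names plus a boolean ``spiked`` flag.
    """
    design = design or LibraryDesign()
    rng = np.random.default_rng(cfg.seed + 2)
    for seq in cfg.spike_in:
        if not (seq.startswith(design.flank_n) and seq.endswith(design.flank_c)):
            raise ValueError(
                f"spike-in {seq!r} violates the {design.flank_n}...{design.flank_c} "
                "flank convention"
            )
    comp = design.composition_vector()
    lengths_support = np.array(sorted(cfg.core_length_distribution))
    probs = np.array(
        [cfg.core_length_distribution[k] for k in lengths_support], dtype=float
    )
    lengths = rng.choice(lengths_support, size=cfg.n_records, p=probs)
    cores = _sample_cores(rng, cfg.n_records, lengths, comp)
    seqs = [design.embed(c) for c in cores]
    counts = _draw_counts(rng, cfg.n_records, cfg.count_mean)
    spiked = np.zeros(cfg.n_records, dtype=bool)

    if cfg.spike_in:
        if cfg.spike_positions is not None:
            positions = np.asarray(cfg.spike_positions)
        else:
            positions = rng.choice(cfg.n_records, size=len(cfg.spike_in), replace=False)
        for pos, seq in zip(positions, cfg.spike_in):
            seqs[int(pos)] = seq
            spiked[int(pos)] = True

    return pd.DataFrame(
        {
            "junction_aa": seqs,
            "v_call": _gene_name(design.v_gene, cfg.allele_suffix),
            "j_call": _gene_name(design.j_gene, cfg.allele_suffix),
            "duplicate_count": counts,
            "spiked": spiked,
        }
    )


# ---------------------------------------------------------------------------
# Writers


def write_mixcr_tsv(table: pd.DataFrame, path) -> None:
    """Write a clonotype table as MiXCR-style TSV (hit strings with scores)."""
    out = pd.DataFrame(
        {
            "cloneCount": table["count"],
            "aaSeqCDR3": table["cdr3_aa"],
            "allVHitsWithScore": table["v_call"].map(lambda g: f"{g}(1200)"),
            "allJHitsWithScore": table["j_call"].map(lambda g: f"{g}(800)"),
        }
    )
    out.to_csv(path, sep="\t", index=False)


def write_airr_tsv(table: pd.DataFrame, path) -> None:
    """Write a table as AIRR rearrangement TSV (junction_aa, v_call, j_call, duplicate_count)."""
    if "junction_aa" in table.columns:
        out = table[["junction_aa", "v_call", "j_call", "duplicate_count"]]
    else:
        out = pd.DataFrame(
            {
                "junction_aa": table["cdr3_aa"],
                "v_call": table["v_call"],
                "j_call": table["j_call"],
                "duplicate_count": table["count"],
            }
        )
    out.to_csv(path, sep="\t", index=False)


def write_truth_tsv(screen: SimulatedScreen, path) -> None:
    """Write ground-truth labels keyed by sequence (any binder draw -> binder)."""
    df = pd.DataFrame(
        {"cdr3_aa": screen.output_table["cdr3_aa"], "truth": screen.truth}
    )
    agg = (
        df.assign(is_binder=df["truth"].eq("binder"))
        .groupby("cdr3_aa", as_index=False)["is_binder"]
        .any()
    )
    agg["truth"] = np.where(agg["is_binder"], "binder", "contaminant")
    agg[["cdr3_aa", "truth"]].to_csv(path, sep="\t", index=False)
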