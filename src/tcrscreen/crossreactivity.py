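"""Proteome-wide scan for self-peptides resembling a query epitope.

Cross-reactivity risk assessment for an epitope-specific TCR: enumerate all
9-mer windows of a proteome, keep predicted MHC binders (from an external
%rank file, or a clearly-labeled built-in anchor heuristic), require the
residues known to be critical for TCR contact (W5 and Q8 for the NY-ESO-1
epitope SLLMWITQC), score the rest by BLOSUM62 similarity to the epitope and
report a ranked candidate table with provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO

from .alphabet import AA_SET
from .baselines import blosum62


@dataclass(frozen=True)
class PeptideCandidate:
    """One proteome window: peptide, source protein, 0-based offset."""

    peptide: str
    protein: str
    offset: int  # 0-based, half-open window start
    binding_rank: float | None = None
    similarity: float | None = None
    anchors_ok: bool | None = None


@dataclass(frozen=True)
class ScanConfig:
    """Epitope, binding filter and anchor requirements of the scan."""

    epitope: str = "SLLMWITQC"
    rank_threshold: float = 1.5
    required_positions: dict[int, str] = field(default_factory=lambda: {5: "W", 8: "Q"})
    rank_source: str | None = None  # path to a TSV, "heuristic", or None
    missing_rank: str = "drop"  # external mode: "drop" or "error"

    def __post_init__(self) -> None:
        for pos in self.required_positions:
            if not 1 <= pos <= len(self.epitope):
                raise ValueError(
                    f"required position {pos} outside 1..{len(self.epitope)}"
                )


def enumerate_peptides(
    proteome_fasta, length: int = 9, *, skip: str = "window"
) -> list[PeptideCandidate]:
    """All length-``length`` windows of every protein, with provenance.

    Sequences are uppercased. Windows containing non-standard residues are
    skipped (``skip="window"``); ``skip="protein"`` drops the whole record
    instead.
    """
    candidates: list[PeptideCandidate] = []
    n_records = 0
    for record in SeqIO.parse(str(proteome_fasta), "fasta"):
        n_records += 1
        seq = str(record.seq).upper()
        if skip == "protein" and not set(seq) <= AA_SET:
            continue
        for start in range(0, len(seq) - length + 1):
            window = seq[start : start + length]
            if not set(window) <= AA_SET:
                continue
            candidates.append(
                PeptideCandidate(peptide=window, protein=record.id, offset=start)
            )
    if n_records == 0:
        raise ValueError(f"no FASTA records found in {proteome_fasta}")
    return candidates


def _heuristic_binder(peptide: str) -> bool:
    # HLA-A*02:01 anchor stand-in (position 2 aliphatic, C-terminal aliphatic).
    # NOT equivalent to a trained pMHC predictor; use an external %rank file
    # for real scans.
    return peptide[1] in "LMIV" and peptide[-1] in "VLIA"


def filter_binders(
    candidates: list[PeptideCandidate], cfg: ScanConfig
) -> list[PeptideCandidate]:
    """Keep candidates predicted to bind the MHC allele.

    External mode joins a TSV of ``peptide<TAB>%rank`` and keeps strictly
    ``%rank < rank_threshold`` (rank 1.5 exactly is dropped at the default
    threshold); peptides missing from the file are dropped (or raise, per
    ``cfg.missing_rank``). Heuristic mode applies the built-in anchor
    stand-in; ``rank_source=None`` passes everything through.
    """
    if cfg.rank_source is None:
        return list(candidates)
    if cfg.rank_source == "heuristic":
        return [
            c for c in candidates if _heuristic_binder(c.peptide)
        ]
    ranks_df = pd.read_csv(cfg.rank_source, sep="\t")
    cols = list(ranks_df.columns[:2])
    ranks = dict(zip(ranks_df[cols[0]], ranks_df[cols[1]].astype(float)))
    kept: list[PeptideCandidate] = []
    n_missing = 0
    for c in candidates:
        rank = ranks.get(c.peptide)
        if rank is None:
            if cfg.missing_rank == "error":
                raise ValueError(f"no %rank entry for peptide {c.peptide}")
            n_missing += 1
            continue
        if rank < cfg.rank_threshold:
            kept.append(
                PeptideCandidate(
                    peptide=c.peptide,
                    protein=c.protein,
                    offset=c.offset,
                    binding_rank=rank,
                )
            )
    return kept


def similarity_to_epitope(peptide: str, cfg: ScanConfig) -> float | None:
    """BLOSUM62 similarity of ``peptide`` to the epitope, or None if rejected.

    Rejection happens when any required anchor residue (1-based positions,
    e.g. W at 5 and Q at 8) is absent, regardless of the similarity score.
    Length mismatch raises.
    """
    if len(peptide) != len(cfg.epitope):
        raise ValueError(
            f"peptide {peptide!r} has length {len(peptide)}, "
            f"epitope has {len(cfg.epitope)}"
        )
    for pos, residue in cfg.required_positions.items():
        if peptide[pos - 1] != residue:
            return None
    return float(sum(blosum62(a, b) for a, b in zip(peptide, cfg.epitope)))


def rank_candidates(
    candidates: list[PeptideCandidate], top_n: int | None = None
) -> pd.DataFrame:
    """Ranked report: descending similarity, ties broken lexicographically.

    Candidates must already carry a similarity (rejected ones are excluded
    upstream). Offsets are reported 1-based in the ``position`` column.
    """
    rows = [
        {
            "peptide": c.peptide,
            "protein": c.protein,
            "position": c.offset + 1,
            "binding_rank": c.binding_rank,
            "similarity": c.similarity,
        }
        for c in candidates
        if c.similarity is not None
    ]
    report = pd.DataFrame(
        rows, columns=["peptide", "protein", "position", "binding_rank", "similarity"]
    )
    report = report.sort_values(
        ["similarity", "peptide"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    if top_n is not None:
        report = report.head(top_n)
    return report


def scan_proteome(
    proteome_fasta, cfg: ScanConfig | None = None, top_n: int | None = None
) -> pd.DataFrame:
    """End-to-end scan: enumerate, binding-filter, anchor+similarity, rank."""
    cfg = cfg or ScanConfig()
    candidates = enumerate_peptides(proteome_fasta, length=len(cfg.epitope))
    candidates = filter_binders(candidates, cfg)
    scored = []
    for c in candidates:
        sim = similarity_to_epitope(c.peptide, cfg)
        if sim is not None:
            scored.append(
                PeptideCandidate(
                    peptide=c.peptide,
                    protein=c.protein,
                    offset=c.offset,
                    binding_rank=c.binding_rank,
                    similarity=sim,
                    anchors_ok=True,
                )
            )
    return rank_candidates(scored, top_n=top_n)
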