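"""Clonotype-table ingestion and quality filters for phage-screen output.

Reads MiXCR-style and AIRR rearrangement TSVs into a unified clonotype table
(``cdr3_aa``, ``count``, ``v_call``, ``j_call``), applies the screen quality
filters (non-standard alphabet, singletons, template core, deduplication) and
extracts the randomized core between the constant flanks, partitioned by
length.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field

import pandas as pd

from .alphabet import is_standard
from .synthetic import CLONOTYPE_COLUMNS, LibraryDesign

logger = logging.getLogger(__name__)

_MIXCR_COLUMNS = {
    "cloneCount": "count",
    "aaSeqCDR3": "cdr3_aa",
    "allVHitsWithScore": "v_call",
    "allJHitsWithScore": "j_call",
}
_AIRR_COLUMNS = {
    "junction_aa": "cdr3_aa",
    "duplicate_count": "count",
    "v_call": "v_call",
    "j_call": "j_call",
}

_HIT_SCORE_RE = re.compile(r"\(.*?\)")


def normalize_gene(name: str) -> str:
    """Strip allele suffix, alignment scores and whitespace from a gene call.

    ``"TRBV6-5*01(1200)"`` and ``" trbv6-5 "`` both normalize to
    ``"TRBV6-5"``; used for allele-insensitive matching while the original
    string is preserved in the table.
    """
    name = _HIT_SCORE_RE.sub("", str(name))
    name = name.split(",")[0].split("*")[0]
    return name.strip().upper()


def read_clonotype_table(path, dialect: str) -> pd.DataFrame:
    """Read a clonotype TSV in the given dialect into the unified table.

    Parameters
    ----------
    path : path-like
        TSV file with a header row.
    dialect : {"mixcr", "airr"}
        Column convention of the file.

    The returned frame has columns ``cdr3_aa``, ``count``, ``v_call``,
    ``j_call`` plus normalized gene columns ``v_gene`` / ``j_gene`` (allele
    suffixes and hit scores stripped). Rows with an unparseable count or an
    empty sequence are skipped and counted in the log.
    """
    if dialect == "mixcr":
        colmap = _MIXCR_COLUMNS
    elif dialect == "airr":
        colmap = _AIRR_COLUMNS
    else:
        raise ValueError(f"unknown dialect {dialect!r}; expected 'mixcr' or 'airr'")
    raw = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(colmap) - set(raw.columns)
    if missing:
        raise ValueError(
            f"{path}: missing required {dialect} column(s) {sorted(missing)}"
        )
    table = raw[list(colmap)].rename(columns=colmap)
    counts = pd.to_numeric(table["count"], errors="coerce")
    bad = counts.isna() | (counts < 1) | table["cdr3_aa"].isna()
    if bad.any():
        logger.warning("%s: skipped %d unparseable row(s)", path, int(bad.sum()))
    table = table.loc[~bad].copy()
    # counts may be written as floats (MiXCR does); they are read-level integers
    table["count"] = counts.loc[~bad].astype(float).round().astype(int)
    table["v_gene"] = table["v_call"].map(normalize_gene)
    table["j_gene"] = table["j_call"].map(normalize_gene)
    return table.reset_index(drop=True)[CLONOTYPE_COLUMNS + ["v_gene", "j_gene"]]


@dataclass
class FilterAudit:
    """Per-filter removal tallies; ``kept + sum(removed) == n_input`` rows."""

    n_input: int = 0
    removed_nonstandard: int = 0
    removed_singleton: int = 0
    removed_template: int = 0
    collapsed_duplicates: int = 0
    n_kept: int = 0

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2)


def filter_clonotypes(
    table: pd.DataFrame,
    template_core: str,
    design: LibraryDesign | None = None,
    audit: FilterAudit | None = None,
) -> pd.DataFrame:
    """Apply the screen quality filters, in fixed order.

    1. drop sequences with non-standard amino acids;
    2. drop singletons (count == 1, likely sequencing errors);
    3. drop sequences whose core equals ``template_core`` (template TCRs that
       escaped randomization);
    4. collapse duplicate amino-acid sequences, summing counts.

    Deduplication runs last so that summed counts cannot ambiguously
    resurrect singletons. The optional ``audit`` records per-filter tallies.
    """
    if not template_core:
        raise ValueError("template_core must be non-empty")
    design = design or LibraryDesign()
    audit = audit if audit is not None else FilterAudit()
    audit.n_input = len(table)

    ok_alpha = table["cdr3_aa"].map(is_standard)
    audit.removed_nonstandard = int((~ok_alpha).sum())
    table = table.loc[ok_alpha]

    ok_count = table["count"] >= 2
    audit.removed_singleton = int((~ok_count).sum())
    table = table.loc[ok_count]

    template_full = design.embed(template_core)
    ok_template = table["cdr3_aa"] != template_full
    audit.removed_template = int((~ok_template).sum())
    table = table.loc[ok_template]

    before = len(table)
    group_cols = ["cdr3_aa"] + [
        c for c in ("v_call", "j_call", "v_gene", "j_gene") if c in table.columns
    ]
    table = (
        table.groupby(group_cols, as_index=False, sort=True)
        .agg(count=("count", "sum"))
    )
    cols = [c for c in CLONOTYPE_COLUMNS + ["v_gene", "j_gene"] if c in table.columns]
    table = table[cols]
    audit.collapsed_duplicates = before - len(table)
    audit.n_kept = len(table)
    return table.reset_index(drop=True)


@dataclass
class CoreSet:
    """Unique randomized cores partitioned by length, with provenance."""

    cores: dict[int, list[str]] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)  # core -> source CDR3
    n_excluded: int = 0

    def all_cores(self) -> list[str]:
        return [c for length in sorted(self.cores) for c in self.cores[length]]

    def to_frame(self, counts: dict[str, int] | None = None) -> pd.DataFrame:
        rows = [
            {
                "length": length,
                "core": core,
                "source_cdr3": self.provenance.get(core, ""),
                "count": (counts or {}).get(core, 1),
            }
            for length in sorted(self.cores)
            for core in self.cores[length]
        ]
        return pd.DataFrame(rows, columns=["length", "core", "source_cdr3", "count"])


def extract_cores(table: pd.DataFrame, design: LibraryDesign | None = None) -> CoreSet:
    """Strip the constant flanks and partition cores by length.

    Sequences not matching ``flank_n + core + flank_c`` with a non-empty core
    (flank mismatch, or too short for both flanks) are excluded and tallied
    in ``n_excluded``.
    """
    design = design or LibraryDesign()
    n, c = design.flank_n, design.flank_c
    min_len = len(n) + len(c) + 1
    result = CoreSet()
    seen: set[str] = set()
    for seq in table["cdr3_aa"]:
        if len(seq) < min_len or not (seq.startswith(n) and seq.endswith(c)):
            result.n_excluded += 1
            continue
        core = seq[len(n) : len(seq) - len(c)]
        if core in seen:
            continue
        seen.add(core)
        result.cores.setdefault(len(core), []).append(core)
        result.provenance[core] = seq
    if result.n_excluded:
        logger.info("extract_cores: excluded %d flank-mismatched sequence(s)",
                    result.n_excluded)
    return result
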