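"""Mining bulk TCR repertoires for epitope-specific candidates.

Restricts an AIRR-convention repertoire to the sequence space the screen and
classifier cover (one V/J pair, fixed CDR3β flanks, standard alphabet),
scores every record with a trained model, ranks them, and selects
experiment-ready candidates either from the top of the ranking or spread
across the score range with enforced core-length diversity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alphabet import is_standard
from .classifier import TrainedModel
from .processing import normalize_gene
from .synthetic import LibraryDesign


def filter_repertoire(
    table: pd.DataFrame, design: LibraryDesign | None = None
) -> pd.DataFrame:
    """Restrict a repertoire to template-compatible records.

    Keeps records whose V/J calls match the design genes (allele-
    insensitive), whose junction carries the design flanks with a non-empty
    core, and whose junction uses only standard amino acids. Duplicate
    junctions are collapsed (summed ``duplicate_count``). Per-filter tallies
    are attached as ``frame.attrs["filter_tallies"]``.
    """
    design = design or LibraryDesign()
    n, c = design.flank_n, design.flank_c
    tallies = {"n_input": len(table)}

    v_ok = table["v_call"].map(normalize_gene) == design.v_gene.upper()
    j_ok = table["j_call"].map(normalize_gene) == design.j_gene.upper()
    gene_ok = v_ok & j_ok
    tallies["removed_gene"] = int((~gene_ok).sum())
    table = table.loc[gene_ok]

    alpha_ok = table["junction_aa"].map(is_standard)
    tallies["removed_nonstandard"] = int((~alpha_ok).sum())
    table = table.loc[alpha_ok]

    min_len = len(n) + len(c) + 1
    flank_ok = (
        table["junction_aa"].str.startswith(n)
        & table["junction_aa"].str.endswith(c)
        & (table["junction_aa"].str.len() >= min_len)
    )
    tallies["removed_flank"] = int((~flank_ok).sum())
    table = table.loc[flank_ok]

    before = len(table)
    agg_cols = {"duplicate_count": ("duplicate_count", "sum")}
    if "spiked" in table.columns:
        agg_cols["spiked"] = ("spiked", "any")
    table = table.groupby(
        ["junction_aa", "v_call", "j_call"], as_index=False, sort=True
    ).agg(**agg_cols)
    tallies["collapsed_duplicates"] = before - len(table)
    tallies["n_kept"] = len(table)

    table = table.reset_index(drop=True)
    table.attrs["filter_tallies"] = tallies
    return table


@dataclass
class ScoredRepertoire:
    """Repertoire records with model scores, descending ranks and core lengths."""

    table: pd.DataFrame  # junction_aa, v_call, j_call, score, rank, core_length

    def score_histogram(self, bins: int = 50) -> pd.DataFrame:
        counts, edges = np.histogram(self.table["score"], bins=bins)
        return pd.DataFrame(
            {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
        )


def rank_repertoire(
    model: TrainedModel, table: pd.DataFrame, design: LibraryDesign | None = None
) -> ScoredRepertoire:
    """Score every record and rank descending (1 = best).

    Score ties are broken lexicographically by sequence so the ranking is
    deterministic and stable under record shuffling.
    """
    design = design or LibraryDesign()
    out = table.copy()
    out["score"] = model.score(list(out["junction_aa"]))
    out["core_length"] = out["junction_aa"].str.len() - len(design.flank_n) - len(
        design.flank_c
    )
    out = out.sort_values(
        ["score", "junction_aa"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return ScoredRepertoire(table=out)


def select_candidates(
    scored: ScoredRepertoire,
    n: int,
    strategy: str = "broad_range",
    *,
    n_strata: int = 6,
    seed: int = 0,
) -> pd.DataFrame:
    """Pick ``n`` experiment-ready candidates from a ranked repertoire.

    ``"top"`` takes the best ``n`` ranks. ``"broad_range"`` stratifies the
    score range into ``n_strata`` quantile bands and samples each band,
    preferring core-length diversity inside a band, so the selection spans
    high and low scores the way a validation panel should.
    """
    table = scored.table
    if n > len(table):
        raise ValueError(f"requested {n} candidates from {len(table)} records")
    if strategy == "top":
        return table.head(n).reset_index(drop=True)
    if strategy != "broad_range":
        raise ValueError(f"unknown selection strategy {strategy!r}")

    rng = np.random.default_rng(seed)
    quantiles = pd.qcut(table["score"], q=n_strata, labels=False, duplicates="drop")
    picked: list[int] = []
    per_stratum = max(1, n // n_strata)
    for stratum in sorted(pd.unique(quantiles), reverse=True):
        pool = table.index[quantiles == stratum].to_numpy()
        take = min(per_stratum, len(pool), n - len(picked))
        if take <= 0:
            continue
        # prefer one candidate per core length before repeating lengths
        chosen: list[int] = []
        lengths_seen: set[int] = set()
        for idx in pool:  # pool is rank-ordered (best first)
            length = int(table.at[idx, "core_length"])
            if length not in lengths_seen:
                chosen.append(idx)
                lengths_seen.add(length)
            if len(chosen) == take:
                break
        while len(chosen) < take:
            extra = [i for i in pool if i not in chosen]
            chosen.append(int(rng.choice(extra)))
        picked.extend(chosen)
    # top up from the best remaining ranks
    if len(picked) < n:
        remaining = [i for i in table.index if i not in set(picked)]
        picked.extend(remaining[: n - len(picked)])
    out = table.loc[sorted(picked[:n])].reset_index(drop=True)
    return out
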