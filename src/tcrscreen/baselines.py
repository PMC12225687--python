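"""Reference scorers and the AUC benchmark harness.

Three non-learned baselines for identifying epitope-specific CDR3β
sequences, evaluated against a labeled set by ROC AUC:

* exact match against the set of sequences observed in the screen;
* BLOSUM62 similarity to a reference CDR3β (TCRbase-style);
* a tcrdist-style CDR3 substitution distance.

Sequences of unequal length are compared with the constant flanks anchored
and the cores aligned at the best gapless offset; the distance charges 4 per
gap position, the similarity charges the BLOSUM62 minimum per unmatched
position. This length handling is a documented simplification of tcrdist,
not a bit-compatible clone of it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices

from .classifier import compute_auc

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
BLOSUM62_MIN = float(min(_BLOSUM62.values()))  # -4


def blosum62(a: str, b: str) -> float:
    """BLOSUM62 substitution score for one residue pair."""
    return float(_BLOSUM62[a, b])


def exact_match_score(query: str, reference_set) -> int:
    """1 iff ``query`` has an exact amino-acid match in ``reference_set``."""
    return int(query in set(reference_set))


def _split_flanked(seq: str, flank_n: str, flank_c: str) -> tuple[str, str, str] | None:
    if (
        len(seq) > len(flank_n) + len(flank_c)
        and seq.startswith(flank_n)
        and seq.endswith(flank_c)
    ):
        return flank_n, seq[len(flank_n) : len(seq) - len(flank_c)], flank_c
    return None


def _core_offset_pairs(short: str, long: str):
    """Best gapless offset of the shorter core inside the longer one.

    Yields, for each offset, the list of aligned residue pairs plus the
    number of unmatched positions of the longer core.
    """
    n_gap = len(long) - len(short)
    for offset in range(n_gap + 1):
        pairs = list(zip(short, long[offset : offset + len(short)]))
        yield pairs, n_gap


def blosum_similarity(
    query: str,
    reference_cdr3: str,
    weights: np.ndarray | None = None,
    *,
    flank_n: str = "CASS",
    flank_c: str = "GELFF",
) -> float:
    """Position-wise BLOSUM62 similarity of ``query`` to a reference CDR3β.

    Equal lengths: ``sum_p w_p * BLOSUM62(query_p, ref_p)`` (uniform weights
    by default). Unequal lengths: the flanks are anchored and the shorter
    core is slid gaplessly along the longer; the best offset sum is returned
    with every unmatched core position contributing the matrix minimum.
    """
    if len(query) == len(reference_cdr3):
        if weights is None:
            weights = np.ones(len(query))
        return float(
            sum(
                w * blosum62(a, b)
                for w, a, b in zip(weights, query, reference_cdr3)
            )
        )
    qs = _split_flanked(query, flank_n, flank_c)
    rs = _split_flanked(reference_cdr3, flank_n, flank_c)
    if qs is None or rs is None:
        # no shared flank convention: gapless offset over the whole strings
        core_q, core_r = query, reference_cdr3
        flank_score = 0.0
    else:
        core_q, core_r = qs[1], rs[1]
        flank_score = sum(blosum62(a, a) for a in flank_n + flank_c)
    short, long_ = sorted((core_q, core_r), key=len)
    best = -np.inf
    for pairs, n_gap in _core_offset_pairs(short, long_):
        s = sum(blosum62(a, b) for a, b in pairs) + n_gap * BLOSUM62_MIN
        best = max(best, s)
    return float(flank_score + best)


def cdr3_distance(
    a: str,
    b: str,
    *,
    flank_n: str = "CASS",
    flank_c: str = "GELFF",
    cdr3_weight: float = 3.0,
) -> float:
    """tcrdist-style CDR3 distance: capped substitution penalties + gap costs.

    Aligned positions cost ``0`` when identical, else
    ``min(4, 4 - BLOSUM62(x, y))``; positions left unmatched by the
    flank-anchored gapless core alignment cost 4 each; the total is scaled by
    the CDR3 weight (default 3). Symmetric, and zero iff the sequences are
    identical.
    """
    if a == b:
        return 0.0

    def pair_cost(x: str, y: str) -> float:
        return 0.0 if x == y else min(4.0, 4.0 - blosum62(x, y))

    if len(a) == len(b):
        return cdr3_weight * sum(pair_cost(x, y) for x, y in zip(a, b))
    sa = _split_flanked(a, flank_n, flank_c)
    sb = _split_flanked(b, flank_n, flank_c)
    if sa is not None and sb is not None:
        core_a, core_b = sa[1], sb[1]
    else:
        core_a, core_b = a, b
    short, long_ = sorted((core_a, core_b), key=len)
    best = np.inf
    for pairs, n_gap in _core_offset_pairs(short, long_):
        d = sum(pair_cost(x, y) for x, y in pairs) + 4.0 * n_gap
        best = min(best, d)
    return float(cdr3_weight * best)


def blosum_similarity_scorer(reference_cdr3: str):
    """Scorer: BLOSUM62 similarity to the reference (higher = more binder-like)."""
    return lambda seq: blosum_similarity(seq, reference_cdr3)


def cdr3_distance_scorer(reference_cdr3: str):
    """Scorer: negated CDR3 distance to the reference (higher = more binder-like)."""
    return lambda seq: -cdr3_distance(seq, reference_cdr3)


def exact_match_scorer(reference_set):
    """Scorer: 1 if the sequence was observed in the screen output, else 0."""
    ref = set(reference_set)
    return lambda seq: float(seq in ref)


def benchmark_methods(labeled: pd.DataFrame, methods: dict) -> pd.DataFrame:
    """AUC of each method on a labeled set of CDR3β sequences.

    ``labeled`` needs columns ``cdr3_aa`` and ``label`` (1 = binder).
    ``methods`` maps a method name to either a callable ``seq -> score``
    (higher = more binder-like; negate distances before passing them) or a
    precomputed score vector aligned with the rows.
    """
    if labeled["label"].nunique() != 2:
        raise ValueError("labeled set must contain both classes")
    seqs = list(labeled["cdr3_aa"])
    labels = labeled["label"].to_numpy()
    rows = []
    for name, method in methods.items():
        scores = (
            np.asarray(method, dtype=float)
            if not callable(method)
            else np.array([method(s) for s in seqs], dtype=float)
        )
        rows.append(
            {
                "method": name,
                "auc": compute_auc(scores, labels),
                "n_pos": int(labels.sum()),
                "n_neg": int(len(labels) - labels.sum()),
            }
        )
    return pd.DataFrame(rows, columns=["method", "auc", "n_pos", "n_neg"])
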