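"""The 20-letter amino-acid alphabet and small helpers shared across modules."""

from __future__ import annotations

import numpy as np

#: Standard amino acids in the conventional alphabetical one-letter order.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

AA_SET = frozenset(AMINO_ACIDS)


def is_standard(seq: str) -> bool:
    """True iff every character of ``seq`` is one of the 20 standard amino acids."""
    return bool(seq) and all(c in AA_SET for c in seq)


def seq_to_indices(seq: str) -> np.ndarray:
    """Map an amino-acid string to integer indices into :data:`AMINO_ACIDS`.

    Raises
    ------
    ValueError
        If the sequence contains a non-standard character.
    """
    try:
        return np.array([AA_INDEX[c] for c in seq], dtype=np.int64)
    except KeyError as exc:  # pragma: no cover - message formatting
        raise ValueError(
            f"non-standard amino acid {exc.args[0]!r} in sequence {seq!r}"
        ) from None


def freq_vector(freqs: dict[str, float]) -> np.ndarray:
    """Dense length-20 frequency vector from a mapping, validated.

    Frequencies must be non-negative, cover only standard amino acids and sum
    to 1 within 1e-9 (missing amino acids count as zero).
    """
    vec = np.zeros(20)
    for aa, f in freqs.items():
        if aa not in AA_INDEX:
            raise ValueError(f"unknown amino acid {aa!r} in composition")
        if f < 0:
            raise ValueError(f"negative frequency {f} for amino acid {aa!r}")
        vec[AA_INDEX[aa]] = f
    total = vec.sum()
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"composition frequencies sum to {total}, expected 1")
    return vec
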