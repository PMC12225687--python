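"""Proteome 9-mer enumeration, binding filter, anchor rule and ranking."""

import numpy as np
import pytest

from tcrscreen import (
    PeptideCandidate,
    ScanConfig,
    enumerate_peptides,
    filter_binders,
    rank_candidates,
    scan_proteome,
    similarity_to_epitope,
)
from tcrscreen.datasets import NYESO_EPITOPE


def write_fasta(path, records):
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")
    return path


@pytest.fixture
def toy_proteome(tmp_path):
    rng = np.random.default_rng(5)
    aa = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    random_prot = "".join(rng.choice(aa, 120))
    return write_fasta(
        tmp_path / "toy.fasta",
        [
            ("KI67_LIKE", "MAGT" + "FLTLWLTQV" + "KDER"),
            ("RANDOM1", random_prot),
            ("SHORTY", "MKVLAW"),
        ],
    )


class TestEnumeration:
    def test_window_counts(self, tmp_path):
        path = write_fasta(tmp_path / "p.fasta", [("A", "ACDEFGHIKL")])  # length 10
        assert len(enumerate_peptides(path)) == 2

    def test_short_protein_yields_nothing(self, tmp_path):
        path = write_fasta(tmp_path / "p.fasta", [("A", "ACDEFGHI")])
        assert enumerate_peptides(path) == []

    def test_counts_match_arithmetic_oracle(self, tmp_path):
        rng = np.random.default_rng(2)
        aa = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        lengths = [3, 9, 15, 40, 100]
        records = [
            (f"P{i}", "".join(rng.choice(aa, n))) for i, n in enumerate(lengths)
        ]
        path = write_fasta(tmp_path / "p.fasta", records)
        expected = sum(max(0, n - 8) for n in lengths)
        assert len(enumerate_peptides(path)) == expected

    def test_nonstandard_residue_skips_window_only(self, tmp_path):
        path = write_fasta(tmp_path / "p.fasta", [("A", "ACDEFGHIKX" + "ACDEFGHIKL")])
        peptides = {c.peptide for c in enumerate_peptides(path)}
        assert not any("X" in p for p in peptides)
        assert "ACDEFGHIK" in peptides  # windows on both sides of the X survive

    def test_empty_fasta_named_error(self, tmp_path):
        path = tmp_path / "empty.fasta"
        path.write_text("")
        with pytest.raises(ValueError, match="no FASTA records"):
            enumerate_peptides(path)

    def test_provenance_offsets(self, toy_proteome):
        hits = [
            c for c in enumerate_peptides(toy_proteome) if c.peptide == "FLTLWLTQV"
        ]
        assert len(hits) == 1
        assert hits[0].protein == "KI67_LIKE"
        assert hits[0].offset == 4  # 0-based


class TestBindingFilter:
    def make_candidates(self, *peptides):
        return [PeptideCandidate(p, "P", 0) for p in peptides]

    def test_external_rank_strictly_below_threshold(self, tmp_path):
        ranks = tmp_path / "r.tsv"
        ranks.write_text("peptide\trank\nAAAAAAAAA\t0.4\nCCCCCCCCC\t1.5\n")
        cfg = ScanConfig(rank_source=str(ranks))
        kept = filter_binders(
            self.make_candidates("AAAAAAAAA", "CCCCCCCCC"), cfg
        )
        assert [c.peptide for c in kept] == ["AAAAAAAAA"]
        assert kept[0].binding_rank == 0.4

    def test_missing_rank_dropped_or_error(self, tmp_path):
        ranks = tmp_path / "r.tsv"
        ranks.write_text("peptide\trank\nAAAAAAAAA\t0.4\n")
        cands = self.make_candidates("AAAAAAAAA", "DDDDDDDDD")
        kept = filter_binders(cands, ScanConfig(rank_source=str(ranks)))
        assert len(kept) == 1
        with pytest.raises(ValueError, match="DDDDDDDDD"):
            filter_binders(
                cands, ScanConfig(rank_source=str(ranks), missing_rank="error")
            )

    def test_heuristic_keeps_anchor_compatible_peptide(self):
        kept = filter_binders(
            self.make_candidates("FLTLWLTQV", "FRTLWLTQR"),
            ScanConfig(rank_source="heuristic"),
        )
        assert [c.peptide for c in kept] == ["FLTLWLTQV"]

    def test_none_passes_through(self):
        cands = self.make_candidates("AAAAAAAAA")
        assert filter_binders(cands, ScanConfig(rank_source=None)) == cands


class TestSimilarity:
    def test_epitope_self_similarity(self):
        cfg = ScanConfig(required_positions={})
        assert similarity_to_epitope(NYESO_EPITOPE, cfg) == 51

    def test_published_crossreactive_peptide(self):
        """FLTLWLTQV carries W5/Q8 and scores 25 against SLLMWITQC."""
        assert similarity_to_epitope("FLTLWLTQV", ScanConfig()) == 25

    def test_anchor_violation_rejected_regardless_of_score(self):
        near_epitope = NYESO_EPITOPE[:4] + "A" + NYESO_EPITOPE[5:]  # W5 -> A
        assert similarity_to_epitope(near_epitope, ScanConfig()) is None

    def test_length_mismatch_named_error(self):
        with pytest.raises(ValueError, match="length"):
            similarity_to_epitope("SLLM", ScanConfig())

    def test_epitope_maximizes_similarity(self):
        """BLOSUM62 diagonal dominance: no 9-mer beats the epitope itself."""
        rng = np.random.default_rng(3)
        aa = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        cfg = ScanConfig(required_positions={})
        best = similarity_to_epitope(NYESO_EPITOPE, cfg)
        for _ in range(10_000):
            peptide = "".join(rng.choice(aa, 9))
            assert similarity_to_epitope(peptide, cfg) <= best


class TestRanking:
    def test_anchored_peptide_outranks_everything_without_anchors(self, toy_proteome):
        report = scan_proteome(toy_proteome, ScanConfig())
        assert report["peptide"].iloc[0] == "FLTLWLTQV"
        assert (report["peptide"].str[4] == "W").all()
        assert (report["peptide"].str[7] == "Q").all()

    def test_top_n_larger_than_candidates_returns_all(self):
        cands = [
            PeptideCandidate("FLTLWLTQV", "P", 0, similarity=25.0),
            PeptideCandidate("GLRMWIKQV", "Q", 3, similarity=24.0),
        ]
        report = rank_candidates(cands, top_n=10)
        assert len(report) == 2
        assert list(report["position"]) == [1, 4]  # reported 1-based

    def test_deterministic_and_tie_broken_lexicographically(self):
        cands = [
            PeptideCandidate("ZZZZWZZQZ", "P", 0, similarity=10.0),
            PeptideCandidate("AAAAWAAQA", "Q", 0, similarity=10.0),
        ]
        a = rank_candidates(cands)
        b = rank_candidates(cands)
        assert list(a["peptide"]) == ["AAAAWAAQA", "ZZZZWZZQZ"]
        assert a.equals(b)


def test_filter_order_does_not_change_final_set(toy_proteome, tmp_path):
    """Binding filter before or after the anchor/similarity step: same set."""
    cfg = ScanConfig(rank_source="heuristic")
    candidates = enumerate_peptides(toy_proteome)

    # binding -> anchors -> similarity (the implemented order)
    a = scan_proteome(toy_proteome, cfg)

    # anchors/similarity first, binding filter last
    scored = []
    for c in candidates:
        sim = similarity_to_epitope(c.peptide, cfg)
        if sim is not None:
            scored.append(PeptideCandidate(c.peptide, c.protein, c.offset,
                                           similarity=sim))
    late = filter_binders(scored, cfg)
    late = [
        PeptideCandidate(c.peptide, c.protein, c.offset,
                         binding_rank=c.binding_rank,
                         similarity=similarity_to_epitope(c.peptide, cfg))
        for c in late
    ]
    b = rank_candidates(late)
    assert list(a["peptide"]) == list(b["peptide"])
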