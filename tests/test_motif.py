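import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cladescan import (
    InputError,
    Motif,
    SyntheticSpec,
    canonical_kmer,
    classify_conservation,
    count_repeats,
    discover_conserved_kmers,
    generate_ortholog_group,
    generate_promoter,
    plant_motif,
    reverse_complement,
    scan,
)
from cladescan.motif import scan_sequence
from helpers import max_nonoverlapping, naive_scan

IUPAC_ALPHABET = "ACGTRYSWKMBDHVN"


class TestReverseComplement:
    @pytest.mark.parametrize(
        "seq,expected",
        [("CGGAT", "ATCCG"), ("CGGCTT", "AAGCCG"), ("ATGCA", "TGCAT"), ("N", "N")],
    )
    def test_printed_pairs(self, seq, expected):
        """The motif/reverse pairs used in the clade analysis reproduce exactly."""
        assert reverse_complement(seq) == expected
        assert reverse_complement(expected) == seq

    def test_rejects_non_iupac(self):
        with pytest.raises(InputError):
            reverse_complement("ACXGT")

    @settings(max_examples=200, derandomize=True)
    @given(st.text(alphabet=IUPAC_ALPHABET, min_size=1, max_size=40))
    def test_involution_and_biopython_agreement(self, seq):
        from Bio.Seq import reverse_complement as bio_rc

        assert reverse_complement(reverse_complement(seq)) == seq
        assert reverse_complement(seq) == str(bio_rc(seq))


class TestMotifType:
    def test_validation(self):
        for bad in ("", "AC", "ACGTACGTACGTA", "AXGCA"):
            with pytest.raises(InputError):
                Motif(bad)
        assert Motif("atgca").pattern == "ATGCA"
        assert Motif("ATGCA").reverse == "TGCAT"
        assert not Motif("ATGCA").is_palindromic
        assert Motif("ACGT").is_palindromic

    def test_canonical_kmer_folds_orientations(self):
        assert canonical_kmer("ATGCA") == canonical_kmer("TGCAT") == "ATGCA"
        assert canonical_kmer("CGGAT") == "ATCCG"


class TestScan:
    def test_single_plus_hit_anchored_offset(self, make_promoter):
        hits = scan(make_promoter("GGATGCAGG"), "ATGCA")
        assert [(h.offset, h.strand, h.matched) for h in hits] == [(-7, "+", "ATGCA")]

    def test_reverse_orientation_reported_on_minus_strand(self, make_promoter):
        hits = scan(make_promoter("GGTGCATGG"), "ATGCA", both_strands=True)
        assert [(h.offset, h.strand) for h in hits] == [(-7, "-")]
        assert scan(make_promoter("GGTGCATGG"), "ATGCA", both_strands=False) == []

    def test_no_match(self, make_promoter):
        assert scan(make_promoter("AAAAA"), "ATGCA") == []

    def test_motif_longer_than_promoter(self, make_promoter):
        with pytest.raises(InputError):
            scan(make_promoter("ACG"), "ATGCA")

    def test_n_in_sequence_matches_nothing(self, make_promoter):
        assert scan(make_promoter("GGATGNAGG"), "ATGNA") == []
        # but N in the pattern matches any plain base
        assert len(scan(make_promoter("GGATGCAGG"), "ATGNA")) == 1

    def test_overlapping_hits_all_reported(self, make_promoter):
        hits = scan(make_promoter("AAAAAA"), "AAA", both_strands=True)
        assert [h.offset for h in hits] == [-6, -5, -4, -3]

    def test_palindrome_counts_each_window_once(self, make_promoter):
        hits = scan(make_promoter("TACGTA"), "ACGT", both_strands=True)
        assert [(h.offset, h.strand) for h in hits] == [(-5, "+")]

    def test_matches_naive_oracle_random(self, rng):
        """Scan output equals the every-window both-strand oracle exactly."""
        bases = np.array(list("ACGT"))
        for _ in range(100):
            L = int(rng.integers(20, 200))
            gc = rng.choice([0.3, 0.5, 0.7])
            seq = generate_promoter(L, gc, rng)
            k = int(rng.integers(5, 7))
            pattern = "".join(rng.choice(bases, size=k))
            got = scan_sequence(seq, pattern, both_strands=True)
            assert got == naive_scan(seq, pattern, both_strands=True)

    def test_strand_fold_symmetry(self, rng):
        """Both-strand scan = plus scans of motif and its reverse, relabeled."""
        for _ in range(50):
            seq = generate_promoter(150, 0.5, rng)
            pattern = "".join(rng.choice(np.array(list("ACGT")), size=5))
            rc = reverse_complement(pattern)
            both = scan_sequence(seq, pattern, both_strands=True)
            plus = scan_sequence(seq, pattern, both_strands=False)
            minus = [] if rc == pattern else [
                (o, "-", m) for o, _, m in scan_sequence(seq, rc, both_strands=False)
            ]
            assert both == sorted(plus + minus, key=lambda t: (t[0], t[1]))

    def test_offset_convention_invariant(self, rng, make_promoter):
        """The promoter substring at L+offset equals the matched sequence."""
        for _ in range(25):
            seq = generate_promoter(120, 0.5, rng)
            for h in scan(make_promoter(seq), "ATGCA"):
                L = len(seq)
                assert seq[L + h.offset : L + h.offset + 5] == h.matched


class TestCountRepeats:
    def _hits(self, make_promoter, seq, motif="ATGCA"):
        return scan(make_promoter(seq), motif)

    def test_disjoint_offsets(self, make_promoter):
        seq = plant_motif(plant_motif("A" * 30, "ATGCA", -20), "ATGCA", -10)
        rc = count_repeats(self._hits(make_promoter, seq), "ATGCA")
        assert rc.count == 2

    def test_overlap_collapses(self, make_promoter):
        # ATGCATGCA: hits at -9 and -5 overlap -> one repeat
        rc = count_repeats(self._hits(make_promoter, "ATGCATGCA"), "ATGCA")
        assert rc.count == 1

    def test_mixed_genes_rejected(self, make_promoter):
        h1 = scan(make_promoter("GGATGCAGG", gene_id="a"), "ATGCA")
        h2 = scan(make_promoter("GGATGCAGG", gene_id="b"), "ATGCA")
        with pytest.raises(InputError):
            count_repeats(h1 + h2)

    def test_empty(self):
        assert count_repeats([], "ATGCA").count == 0

    def test_equals_interval_scheduling_oracle(self, rng, make_promoter):
        """Greedy count equals exhaustive maximum non-overlapping selection."""
        for _ in range(100):
            seq = generate_promoter(60, 0.5, rng)
            # densify with a few planted copies to force overlaps
            for _ in range(int(rng.integers(1, 5))):
                off = int(rng.integers(-60, -4))
                seq = plant_motif(seq, "ATGCA", max(off, -60), "+")
            hits = scan(make_promoter(seq), "ATGCA")
            if not hits:
                continue
            got = count_repeats(hits, "ATGCA").count
            assert got == max_nonoverlapping([h.offset for h in hits], 5)


class TestDiscovery:
    def _cluster(self, motif, n_genes=5, planted_genes=None, seed=0, **kw):
        groups = []
        planted = set(planted_genes if planted_genes is not None else range(n_genes))
        for j in range(n_genes):
            spec = SyntheticSpec(
                n_species=12, promoter_length=300, gc_content=0.0,
                motif=motif, presence_prob=1.0 if j in planted else 0.0,
                anchor_offset=-150, jitter_sd=0.0, seed=seed + j, **kw,
            )
            group, _ = generate_ortholog_group(spec, group_id=f"c{j}")
            groups.append(group)
        return groups

    def test_planted_motif_recovered_with_perfect_score(self):
        """A motif planted in every species of every cluster gene scores 1.0."""
        groups = self._cluster("CGGAT")
        found = discover_conserved_kmers(groups, kmin=5, kmax=5)
        key = canonical_kmer("CGGAT")
        scores = {d.kmer: d.score for d in found}
        assert scores[key] == 1.0
        # G/C-containing words cannot arise in the A/T background, so the
        # planted key has by far the fewest occurrences among perfect scores
        assert found[0].kmer == key

    def test_sub_threshold_candidate_absent(self):
        """A motif carried by 2 of 5 cluster genes fails min_cluster_fraction=0.8."""
        groups = self._cluster("CGGAT", planted_genes={0, 1})
        found = discover_conserved_kmers(groups, kmin=5, kmax=5, min_cluster_fraction=0.8)
        assert canonical_kmer("CGGAT") not in {d.kmer for d in found}

    def test_every_returned_motif_repasses_classifier(self):
        """Discovery soundness: results re-pass the conservation rule per gene."""
        groups = self._cluster("CGGAT")
        found = discover_conserved_kmers(groups, kmin=5, kmax=5, min_cluster_fraction=0.8)
        for d in found[:10]:
            recheck = [
                classify_conservation(g, Motif(d.kmer)).conserved for g in groups
            ]
            assert sum(recheck) / len(groups) >= 0.8

    def test_empty_cluster_rejected(self):
        with pytest.raises(InputError):
            discover_conserved_kmers([])
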