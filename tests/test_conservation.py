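import numpy as np
import pytest

from cladescan import (
    GeneSet,
    InputError,
    OrthologGroup,
    PromoterRecord,
    SyntheticSpec,
    classify_conservation,
    generate_ortholog_group,
    generate_promoter,
    plant_motif,
    summarize_motifs,
)
from cladescan.conservation import percent
from helpers import brute_force_conserved

SPECIES = [f"sp{i:02d}" for i in range(1, 13)]


def build_group(n_in_window, n_extra_anywhere=0, motif="CGGCTT", L=400,
                anchor=-200, far_offset=None, gene="gX"):
    """A 12-species group over A/T-only backgrounds: hits exist only where planted.

    The focal species is always among the in-window carriers (the classifier
    needs a focal reference hit); ``n_extra_anywhere`` species carry the
    motif far from the anchor instead (out of a +-200 bp window when
    ``far_offset`` is provided accordingly).
    """
    group = OrthologGroup(focal_gene_id=f"{gene}_{SPECIES[0]}", focal_species=SPECIES[0])
    extras_start = n_in_window if n_in_window > 0 else 1  # focal stays empty when 0
    for i, sp in enumerate(SPECIES):
        seq = generate_promoter(L, 0.0, 1000 + i)  # A/T only: no spurious hits
        if i < n_in_window:
            seq = plant_motif(seq, motif, anchor, "+")
        elif extras_start <= i < extras_start + n_extra_anywhere:
            seq = plant_motif(seq, motif, far_offset if far_offset is not None else -10, "+")
        group.gene_ids[sp] = f"{gene}_{sp}"
        group.promoters[sp] = PromoterRecord(f"{gene}_{sp}", sp, seq, L)
    return group


class TestClassifyConservation:
    def test_inclusive_75_percent_boundary(self):
        """9 of 12 in-window carriers is exactly 75% and counts as conserved."""
        call = classify_conservation(build_group(9), "CGGCTT")
        assert call.presence_fraction == pytest.approx(0.75)
        assert call.conserved and call.evaluable

    def test_below_boundary_not_conserved(self):
        call = classify_conservation(build_group(8), "CGGCTT")
        assert call.presence_fraction == pytest.approx(8 / 12)
        assert not call.conserved
        assert call.majority  # 8 of 12 anywhere is still a majority

    def test_positional_rule_separates_anywhere_from_in_window(self):
        # 6 at the anchor, 4 more at -10: |(-10) - (-200)| > 150-bp window
        group = build_group(6, n_extra_anywhere=4, L=400, anchor=-350, far_offset=-10)
        call = classify_conservation(group, "CGGCTT", position_window=150)
        assert call.n_with_hit_anywhere == 10
        assert call.n_with_hit_in_window == 6
        assert not call.conserved and call.majority

    def test_reference_is_focal_hit_nearest_start_codon(self):
        group = build_group(1, L=400, anchor=-300)
        seq = group.promoters[SPECIES[0]].sequence
        seq = plant_motif(seq, "CGGCTT", -50, "+")  # nearer the start codon
        group.promoters[SPECIES[0]] = PromoterRecord(
            group.focal_gene_id, SPECIES[0], seq, 400
        )
        call = classify_conservation(group, "CGGCTT")
        assert call.reference_offset == -50

    def test_focal_without_hit_not_conserved_majority_still_computed(self):
        group = build_group(0, n_extra_anywhere=8, far_offset=-100)
        call = classify_conservation(group, "CGGCTT")
        assert not call.evaluable and not call.conserved
        assert call.reference_offset is None
        assert call.majority  # 8 of 12 anywhere

    def test_min_orthologs_gate(self):
        group = build_group(12)
        for sp in SPECIES[5:]:  # drop to 5 collected promoters
            del group.promoters[sp]
        call = classify_conservation(group, "CGGCTT", min_orthologs=8)
        assert not call.evaluable and not call.conserved

    def test_missing_focal_promoter_rejected(self):
        group = build_group(9)
        del group.promoters[SPECIES[0]]
        with pytest.raises(InputError, match="focal"):
            classify_conservation(group, "CGGCTT")

    def test_monotone_in_threshold_and_window(self):
        """Loosening the rule never revokes a conserved call."""
        rng = np.random.default_rng(42)
        for trial in range(25):
            spec = SyntheticSpec(
                promoter_length=400, anchor_offset=-200, presence_prob=0.7,
                jitter_sd=60.0, motif="CGGCTTAT", gc_content=0.4,
                focal_presence_prob=1.0, seed=int(rng.integers(1 << 30)),
            )
            group, _ = generate_ortholog_group(spec)
            for window in (50, 100, 200):
                for thr in (0.9, 0.75, 0.5):
                    call = classify_conservation(
                        group, spec.motif, presence_threshold=thr, position_window=window
                    )
                    looser = classify_conservation(
                        group, spec.motif, presence_threshold=thr - 0.2,
                        position_window=window + 150,
                    )
                    if call.conserved:
                        assert looser.conserved

    def test_adding_in_window_ortholog_never_decreases_numerator(self):
        base = build_group(9)
        call9 = classify_conservation(base, "CGGCTT")
        grown = build_group(10)
        call10 = classify_conservation(grown, "CGGCTT")
        assert call10.n_with_hit_in_window >= call9.n_with_hit_in_window

    def test_background_conserved_rate_shrinks_with_window(self):
        """On background-only clades the conserved rate falls as the window narrows."""
        groups = []
        for seed in range(250):
            spec = SyntheticSpec(
                promoter_length=1000, gc_content=0.5, presence_prob=0.0,
                motif="ATGCA", seed=seed,
            )
            groups.append(generate_ortholog_group(spec)[0])
        rates = {}
        for window in (50, 100, 200):
            conserved = [
                classify_conservation(g, "ATGCA", position_window=window).conserved
                for g in groups
            ]
            rates[window] = np.mean(conserved)
        assert rates[50] <= rates[100] <= rates[200]
        assert rates[200] < 0.35  # background alone rarely passes the rule


class TestSummarizeMotifs:
    def _fixture(self, n_genes=10, plant_in_orthologs=True, motif="CGGCTT"):
        groups, focal_promoters = [], {}
        genes = []
        for j in range(n_genes):
            spec = SyntheticSpec(
                promoter_length=400, gc_content=0.0, motif=motif,
                presence_prob=1.0 if plant_in_orthologs else 0.0,
                focal_presence_prob=1.0, anchor_offset=-200, jitter_sd=0.0,
                seed=j,
            )
            group, _ = generate_ortholog_group(spec, group_id=f"q{j}")
            groups.append(group)
            focal_promoters[group.focal_gene_id] = group.focal_promoter
            genes.append(group.focal_gene_id)
        regulated = GeneSet(comparison="c1", direction="up", genes=tuple(genes))
        return regulated, focal_promoters, groups

    def test_all_planted_gives_100_percent_rows(self):
        regulated, proms, groups = self._fixture()
        (row,), calls, missing = summarize_motifs(regulated, proms, groups, ["CGGCTT"])
        assert missing == []
        assert (row.n_present_focal, row.n_with_promoter) == (10, 10)
        assert (row.n_conserved, row.n_majority, row.n_evaluable) == (10, 10, 10)
        assert (row.pct_present_focal, row.pct_conserved, row.pct_majority) == (
            100, 100, 100,
        )

    def test_focal_only_planting_zeroes_clade_columns(self):
        regulated, proms, groups = self._fixture(plant_in_orthologs=False)
        (row,), _, _ = summarize_motifs(regulated, proms, groups, ["CGGCTT"])
        assert row.pct_present_focal == 100
        assert row.n_conserved == 0 and row.n_majority == 0

    def test_missing_promoters_reported_not_dropped(self):
        regulated, proms, groups = self._fixture()
        regulated = GeneSet("c1", "up", regulated.genes + ("ghost",))
        (row,), _, missing = summarize_motifs(regulated, proms, groups, ["CGGCTT"])
        assert missing == ["ghost"]
        assert row.n_with_promoter == 10

    def test_empty_motif_list_rejected(self):
        regulated, proms, groups = self._fixture(2)
        with pytest.raises(InputError):
            summarize_motifs(regulated, proms, groups, [])

    def test_counts_equal_brute_force_recount(self):
        """Randomized fixture: summary counts equal an independent recount."""
        rng = np.random.default_rng(7)
        groups, focal_promoters, genes = [], {}, []
        motif = "CGGCTT"
        for j in range(30):
            spec = SyntheticSpec(
                promoter_length=600, gc_content=0.5, motif=motif,
                presence_prob=float(rng.uniform(0.2, 1.0)),
                focal_presence_prob=float(rng.uniform(0.5, 1.0)),
                anchor_offset=-250, jitter_sd=40.0, seed=int(rng.integers(1 << 30)),
            )
            group, _ = generate_ortholog_group(spec, group_id=f"r{j}")
            # random ortholog availability, incl. some below the minimum
            keep = sorted(
                rng.choice(SPECIES[1:], size=int(rng.integers(4, 12)), replace=False)
            )
            group.promoters = {
                sp: rec for sp, rec in group.promoters.items()
                if sp == SPECIES[0] or sp in keep
            }
            groups.append(group)
            focal_promoters[group.focal_gene_id] = group.focal_promoter
            genes.append(group.focal_gene_id)
        regulated = GeneSet("c1", "up", tuple(genes))
        (row,), calls, _ = summarize_motifs(regulated, focal_promoters, groups, [motif])

        from helpers import both_strand_offsets

        n_present = sum(
            1 for g in genes if both_strand_offsets(focal_promoters[g].sequence, motif)
        )
        evaluable = [g for g in groups if g.n_collected >= 8]
        n_conserved = sum(brute_force_conserved(g, motif) for g in evaluable)
        assert row.n_present_focal == n_present
        assert row.n_evaluable == len(evaluable)
        assert row.n_conserved == n_conserved

    def test_percent_rounds_half_up(self):
        assert percent(1, 8) == 13  # 12.5 -> 13, not banker's 12
        assert percent(135, 146) == 92
        assert percent(0, 0) == 0
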