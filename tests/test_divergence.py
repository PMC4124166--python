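"""Parsimony branch counting, ancestral reconstruction and quality filters."""

import pytest

from lineagemk import (
    AnalysisConfig,
    BRANCHES,
    BranchCounts,
    GeneFamily,
    SimConfig,
    apply_quality_filters,
    count_branch_substitutions,
    fitch_ancestral_codons,
    misalignment_fraction,
    simulate_dataset,
)

from _oracles import brute_force_single_change_column

SP = ("human", "chimp", "macaque", "mouse")


def family_from_columns(columns, gene_id="g"):
    """Build a GeneFamily from a list of 4-codon tuples (human, chimp,
    macaque, mouse)."""
    seqs = {sp: "".join(col[i] for col in columns) for i, sp in enumerate(SP)}
    return GeneFamily(gene_id=gene_id, sequences=seqs)


class TestFitchAncestors:
    def test_identical_column_has_zero_changes(self):
        fam = family_from_columns([("AAA",) * 4])
        (col,) = fitch_ancestral_codons(fam)
        assert col.min_changes == 0
        assert col.hominoid_codons == col.root_codons == frozenset({"AAA"})

    def test_three_vs_one_majority(self):
        # only human differs: unique reconstruction, change on human branch
        fam = family_from_columns([("AAA", "AAG", "AAG", "AAG")])
        (col,) = fitch_ancestral_codons(fam)
        assert col.min_changes == 1
        assert col.hominoid_codons == frozenset({"AAG"})
        counts = count_branch_substitutions(fam).by_branch()
        assert counts["human"].Ds == pytest.approx(1.0)  # AAA/AAG both Lys
        assert counts["human"].Dn == pytest.approx(0.0)
        for br in ("chimp", "hominoid_ancestor", "macaque", "mouse"):
            assert counts[br].Dn + counts[br].Ds == pytest.approx(0.0)

    def test_sister_pattern_maps_to_internal_branch(self):
        # human=chimp vs macaque=mouse: one change on the hominoid-ancestor
        # edge is strictly more parsimonious than any two-change scenario
        fam = family_from_columns([("AAA", "AAA", "AAG", "AAG")])
        (col,) = fitch_ancestral_codons(fam)
        assert col.min_changes == 1
        counts = count_branch_substitutions(fam).by_branch()
        assert counts["hominoid_ancestor"].Ds == pytest.approx(1.0)

    def test_genuinely_ambiguous_column_is_tie_averaged(self):
        # human=macaque=AAA, chimp=mouse=AAG: two equally parsimonious
        # reconstructions (cost 2), changes averaged half-and-half
        fam = family_from_columns([("AAA", "AAG", "AAA", "AAG")])
        (col,) = fitch_ancestral_codons(fam)
        assert col.min_changes == 2
        assert col.hominoid_codons == frozenset({"AAA", "AAG"})
        counts = count_branch_substitutions(fam).by_branch()
        for br in ("human", "chimp", "macaque", "mouse"):
            assert counts[br].Ds == pytest.approx(0.5)
        assert counts["hominoid_ancestor"].Dn + counts["hominoid_ancestor"].Ds == pytest.approx(0.0)


class TestBranchCounting:
    def test_identical_family_counts_zero_everywhere(self):
        fam = family_from_columns([("ATG",) * 4, ("CCC",) * 4])
        counts = count_branch_substitutions(fam).by_branch()
        for br in BRANCHES:
            assert counts[br].Dn == counts[br].Ds == 0.0

    def test_single_human_nonsynonymous_change(self):
        fam = family_from_columns(
            [("ATG",) * 4, ("GTT", "ATT", "ATT", "ATT"), ("CCC",) * 4]
        )
        counts = count_branch_substitutions(fam).by_branch()
        assert counts["human"].Dn == pytest.approx(1.0)  # Ile -> Val
        assert counts["human"].Ds == pytest.approx(0.0)
        assert sum(counts[b].Dn + counts[b].Ds for b in BRANCHES) == pytest.approx(1.0)

    def test_site_counts_conserve_and_use_human_sequence(self):
        fam = family_from_columns([("ATG",) * 4, ("TTT", "TTC", "TTT", "TTT")])
        counts = count_branch_substitutions(fam).by_branch()
        assert counts["human"].N + counts["human"].S == pytest.approx(6.0)

    def test_gap_columns_excluded(self):
        fam = family_from_columns(
            [("ATG",) * 4, ("---", "AAA", "AAA", "AAA"), ("CCC",) * 4]
        )
        counts = count_branch_substitutions(fam).by_branch()
        assert counts["human"].N + counts["human"].S == pytest.approx(6.0)
        assert all(counts[b].Dn + counts[b].Ds == 0 for b in BRANCHES)

    def test_all_gap_family_raises(self):
        fam = family_from_columns([("---", "AAA", "AAA", "AAA")])
        with pytest.raises(ValueError, match="gap-free"):
            count_branch_substitutions(fam)

    def test_conservation_total_changes_equal_parsimony_minimum(self):
        cfg = SimConfig(
            n_genes=20,
            codons_per_gene=60,
            branch_lengths={b: 0.05 for b in BRANCHES},
            branch_omega={b: 0.6 for b in BRANCHES},
            seed=11,
        )
        fams, _, _ = simulate_dataset(cfg)
        for fam in fams:
            res = count_branch_substitutions(fam)
            total = sum(bc.Dn + bc.Ds for bc in res.branch_counts)
            skipped = set(res.skipped_columns)
            minimum = sum(
                col.min_changes
                for col in fitch_ancestral_codons(fam)
                if col.column not in skipped
            )
            assert total == pytest.approx(minimum, abs=1e-9)

    def test_branch_assignment_matches_exhaustive_enumeration(self):
        """Single-change columns: tie-averaged branch attribution equals a
        brute-force search over all 61x61 sense ancestor assignments."""
        cfg = SimConfig(
            n_genes=30,
            codons_per_gene=40,
            branch_lengths={b: 0.004 for b in BRANCHES},
            branch_omega={b: 1.0 for b in BRANCHES},
            seed=5,
        )
        fams, _, _ = simulate_dataset(cfg)
        checked = 0
        for fam in fams:
            for col in fitch_ancestral_codons(fam):
                if col.min_changes != 1:
                    continue
                h, c, m, o = fam.codon_column(col.column)
                oracle = brute_force_single_change_column(h, c, m, o)
                one = family_from_columns([(h, c, m, o)])
                counts = count_branch_substitutions(one).by_branch()
                for br in BRANCHES:
                    assert counts[br].Dn == pytest.approx(oracle[br][0], abs=1e-9)
                    assert counts[br].Ds == pytest.approx(oracle[br][1], abs=1e-9)
                checked += 1
        assert checked >= 20

    def test_low_divergence_recovery_of_true_counts(self):
        """At low divergence the parsimony counts equal the generator's true
        per-branch (Dn, Ds) in at least 90% of families."""
        cfg = SimConfig(
            n_genes=200,
            codons_per_gene=100,
            branch_lengths={b: 0.003 for b in BRANCHES},
            branch_omega={b: 0.5 for b in BRANCHES},
            seed=1,
        )
        fams, _, truth = simulate_dataset(cfg)
        exact = 0
        for fam, gt in zip(fams, truth.genes):
            counts = count_branch_substitutions(fam).by_branch()
            exact += all(
                counts[b].Dn == pytest.approx(gt.branch_dn[b], abs=1e-9)
                and counts[b].Ds == pytest.approx(gt.branch_ds[b], abs=1e-9)
                for b in BRANCHES
            )
        assert exact / len(fams) >= 0.90


class TestQualityFilters:
    def _counts(self, gene, human=(1, 2), chimp=(1, 2), anc=(1, 2)):
        return [
            BranchCounts(gene, "human", *human),
            BranchCounts(gene, "chimp", *chimp),
            BranchCounts(gene, "hominoid_ancestor", *anc),
        ]

    def test_protein_length_boundary_is_strict(self):
        # rule is "longer than 100 aa": exactly 100 codons fails
        fam100 = GeneFamily("a", {sp: "AAA" * 100 for sp in SP})
        fam101 = GeneFamily("b", {sp: "AAA" * 101 for sp in SP})
        qc = {q.gene_id: q for q in apply_quality_filters(
            [fam100, fam101], self._counts("a") + self._counts("b"))}
        assert not qc["a"].passed and "short_protein" in qc["a"].reasons
        assert qc["b"].passed

    def test_high_dn_flag_is_not_excluding(self):
        qc = apply_quality_filters([], self._counts("g", human=(11, 3)))
        assert qc[0].passed and qc[0].reasons == ["high_dn_flag"]

    def test_dn_without_ds_counts_as_unbounded_omega(self):
        qc = apply_quality_filters([], self._counts("g", human=(5, 0)))
        assert not qc[0].passed and "dnds_gt_max" in qc[0].reasons

    def test_zero_zero_branch_passes(self):
        qc = apply_quality_filters([], self._counts("g", anc=(0, 0)))
        assert qc[0].passed

    def test_count_ratio_cap(self):
        qc = apply_quality_filters([], self._counts("g", chimp=(44, 4)))
        assert not qc[0].passed and "dnds_gt_max" in qc[0].reasons


def test_misalignment_fraction_near_gaps():
    cols = [("ATG",) * 4] * 20
    cols[10] = ("---", "AAA", "AAA", "AAA")
    fam = family_from_columns(cols)
    assert misalignment_fraction(fam, [12, 13]) == pytest.approx(1.0)
    assert misalignment_fraction(fam, [1, 12]) == pytest.approx(0.5)
    assert misalignment_fraction(fam, []) == 0.0
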