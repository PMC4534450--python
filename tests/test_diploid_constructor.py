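"""Personalized-reference construction: classification, clustering,
haplotype enumeration, window arithmetic and assembly."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from refeditor.diploid_constructor import (
    BuildParameters,
    VariantCluster,
    apply_backbone_edits,
    assemble,
    build_mini,
    build_reference,
    classify_variants,
    cluster_mini_variants,
    enumerate_combos,
)
from refeditor.io_formats import ReferenceGenome, VariantRecord
from refeditor.synthetic_data import generate_genome

from conftest import het_snp, hom_snp


def mkparams(**kw):
    defaults = dict(k=36, m=2)
    defaults.update(kw)
    return BuildParameters(**defaults)


class TestBuildParameters:
    def test_default_width_is_2k_minus_1_plus_2m(self):
        assert mkparams().w == 75
        assert BuildParameters(k=100, m=5).w == 209

    def test_width_floor_enforced(self):
        with pytest.raises(ValueError, match="floor"):
            BuildParameters(k=36, m=0, w=70)

    def test_flank_splits_width_symmetrically(self):
        assert mkparams().flank == 37  # (75-1)/2 = k-1+m

    @pytest.mark.parametrize("kw", [dict(k=0), dict(k=36, m=-1),
                                    dict(k=36, sex="robot")])
    def test_invalid_rejected(self, kw):
        with pytest.raises(ValueError):
            BuildParameters(**kw)


class TestClassify:
    def test_routing(self):
        variants = [
            VariantRecord("c1", 10, "A", ("G",), (0, 0)),   # hom-ref
            VariantRecord("c1", 20, "A", ("G",), (1, 1)),   # hom-alt SNP
            VariantRecord("c1", 30, "A", ("G",), (0, 1)),   # het SNP
            VariantRecord("c1", 40, "ACC", ("A",), (1, 1)),  # hom-alt del
            VariantRecord("c1", 50, "A", ("AGG",), (0, 1)),  # het ins
        ]
        skips, backbone, minis = classify_variants(variants, mkparams())
        assert [v.pos for v in skips] == [10]
        assert [v.pos for v in backbone] == [20]
        # indels never edit the backbone: that would shift coordinates
        assert [v.pos for v in minis] == [30, 40, 50]

    def test_conflicting_duplicates_rejected(self):
        variants = [het_snp("c1", 10, "A", "G"), het_snp("c1", 10, "A", "T")]
        with pytest.raises(ValueError, match="conflicting"):
            classify_variants(variants, mkparams())


class TestBackboneEdits:
    def test_single_edit_changes_one_base(self):
        g = ReferenceGenome([("c1", "A" * 20)])
        out = apply_backbone_edits(g, [hom_snp("c1", 10, "A", "G")])
        assert out.sequence("c1") == "A" * 10 + "G" + "A" * 9
        assert out.length("c1") == 20

    def test_empty_edit_list_is_identity(self):
        g = ReferenceGenome([("c1", "ACGT" * 5)])
        assert apply_backbone_edits(g, []) == g

    def test_edits_on_two_chromosomes(self):
        g = ReferenceGenome([("c1", "AAAA"), ("c2", "CCCC"), ("c3", "GGGG")])
        out = apply_backbone_edits(
            g, [hom_snp("c1", 0, "A", "T"), hom_snp("c2", 3, "C", "T")])
        assert out.sequence("c1") == "TAAA"
        assert out.sequence("c2") == "CCCT"
        assert out.sequence("c3") == "GGGG"

    def test_ref_mismatch_names_locus(self):
        g = ReferenceGenome([("c1", "AAAA")])
        with pytest.raises(ValueError, match="c1:2"):
            apply_backbone_edits(g, [hom_snp("c1", 2, "C", "T")])


class TestClustering:
    def test_distance_under_k_plus_m_joins(self):
        # k=36, m=2: positions 100 and 137 are 37 < 38 apart
        clusters = cluster_mini_variants(
            [het_snp("c1", 100, "A", "G"), het_snp("c1", 137, "C", "T")],
            mkparams())
        assert len(clusters) == 1

    def test_distance_k_plus_m_splits(self):
        clusters = cluster_mini_variants(
            [het_snp("c1", 100, "A", "G"), het_snp("c1", 138, "C", "T")],
            mkparams())
        assert len(clusters) == 2

    def test_chaining_is_transitive(self):
        # 100-130 and 130-160 each < 38 although 100-160 is not
        clusters = cluster_mini_variants(
            [het_snp("c1", p, "A", "G") for p in (100, 130, 160)],
            mkparams())
        assert len(clusters) == 1
        assert len(clusters[0].variants) == 3

    def test_chromosome_boundary_always_splits(self):
        clusters = cluster_mini_variants(
            [het_snp("c1", 100, "A", "G"), het_snp("c2", 101, "C", "T")],
            mkparams())
        assert len(clusters) == 2

    @given(st.lists(st.integers(min_value=0, max_value=2000),
                    min_size=1, max_size=15, unique=True))
    @settings(max_examples=100, deadline=None)
    def test_maximality_matches_all_pairs_check(self, positions):
        """Brute force: within a cluster consecutive gaps < k+m; across
        a cluster boundary the gap is >= k+m."""
        params = mkparams()
        variants = [het_snp("c1", p, "A", "G") for p in sorted(positions)]
        clusters = cluster_mini_variants(variants, params)
        flat = [v for c in clusters for v in c.variants]
        assert flat == variants
        for cluster in clusters:
            for a, b in itertools.pairwise(cluster.variants):
                assert b.pos - a.pos < params.cluster_distance
        for a, b in itertools.pairwise(clusters):
            assert b.variants[0].pos - a.variants[-1].pos \
                >= params.cluster_distance


class TestEnumerate:
    def test_single_het_snp_one_combo(self):
        cluster = VariantCluster("c1", (het_snp("c1", 100, "A", "G"),))
        assert enumerate_combos(cluster, mkparams()) == [(1,)]

    @pytest.mark.parametrize("h", [1, 2, 3, 4, 5])
    def test_h_hets_give_2h_minus_1(self, h):
        cluster = VariantCluster("c1", tuple(
            het_snp("c1", 100 + 10 * i, "A", "G") for i in range(h)))
        combos = enumerate_combos(cluster, mkparams())
        # independent enumeration: {ref,alt}^h minus the all-ref point
        expected = set(itertools.product((0, 1), repeat=h)) - {(0,) * h}
        assert set(combos) == expected
        assert len(combos) == 2 ** h - 1

    def test_triallelic_het_yields_both_alts_never_ref(self):
        v = VariantRecord("c1", 100, "A", ("G", "T"), (1, 2))
        combos = enumerate_combos(VariantCluster("c1", (v,)), mkparams())
        assert set(combos) == {(1,), (2,)}

    def test_hom_alt_indel_forced_into_every_combo(self):
        indel = VariantRecord("c1", 100, "AC", ("A",), (1, 1))
        snp = het_snp("c1", 110, "A", "G")
        combos = enumerate_combos(
            VariantCluster("c1", (indel, snp)), mkparams())
        assert all(c[0] == 1 for c in combos)
        assert set(combos) == {(1, 0), (1, 1)}

    def test_cap_falls_back_to_single_variant_minis(self):
        hets = tuple(het_snp("c1", 100 + i, "A", "G") for i in range(10))
        combos = enumerate_combos(
            VariantCluster("c1", hets), mkparams(max_cluster_hets=4))
        assert len(combos) == 10
        for i, combo in enumerate(combos):
            assert combo[i] == 1
            assert all(a == 0 for j, a in enumerate(combo) if j != i)


class TestBuildMini:
    def test_single_snp_mini_width_and_center(self, toy_genome):
        cluster = VariantCluster(
            "chr1", (het_snp("chr1", 500, toy_genome.sequence("chr1")[500],
                             "G" if toy_genome.sequence("chr1")[500] != "G"
                             else "T"),))
        mini = build_mini(toy_genome, cluster, (1,), mkparams())
        assert len(mini.sequence) == 75
        assert mini.univ_start == 500 - 37
        alt = cluster.variants[0].alt_alleles[0]
        assert mini.sequence[37] == alt
        # everything except the middle equals the reference window
        ref_win = toy_genome.fetch("chr1", 463, 538)
        assert [i for i in range(75) if mini.sequence[i] != ref_win[i]] \
            == [37]

    def test_window_clipped_at_chromosome_start(self, toy_genome):
        ref = toy_genome.sequence("chr1")[10]
        alt = "G" if ref != "G" else "T"
        cluster = VariantCluster("chr1", (het_snp("chr1", 10, ref, alt),))
        mini = build_mini(toy_genome, cluster, (1,), mkparams())
        assert mini.univ_start == 0
        assert len(mini.sequence) == 10 + 1 + 37  # clipped left flank
        assert mini.sequence[10] == alt
        # recompute via direct substring splice
        expected = toy_genome.fetch("chr1", 0, 10) + alt \
            + toy_genome.fetch("chr1", 11, 48)
        assert mini.sequence == expected

    def test_deletion_mini_shrinks_by_deleted_bases(self, toy_genome):
        # window spans flank + 3-bp REF footprint + flank = 77; splicing
        # the 2-bp deletion leaves 75
        ref = toy_genome.fetch("chr1", 500, 503)
        v = VariantRecord("chr1", 500, ref, (ref[0],), (0, 1))
        mini = build_mini(toy_genome, VariantCluster("chr1", (v,)), (1,),
                          mkparams())
        assert len(mini.sequence) == 77 - 2
        # sequence-diff oracle: splice by hand
        expected = toy_genome.fetch("chr1", 463, 500) + ref[0] \
            + toy_genome.fetch("chr1", 503, 540)
        assert mini.sequence == expected

    def test_insertion_mini_grows_by_inserted_bases(self, toy_genome):
        ref = toy_genome.sequence("chr1")[500]
        v = VariantRecord("chr1", 500, ref, (ref + "GG",), (0, 1))
        mini = build_mini(toy_genome, VariantCluster("chr1", (v,)), (1,),
                          mkparams())
        assert len(mini.sequence) == 77

    def test_liftback_inverts_combo_edits(self, toy_genome):
        """Reversing the combo's edits on the mini reproduces the
        universal substring exactly."""
        ref = toy_genome.fetch("chr1", 300, 302)
        variants = (
            VariantRecord("chr1", 300, ref, (ref[0],), (0, 1)),  # 1-bp del
            het_snp("chr1", 320, toy_genome.sequence("chr1")[320], "N"
                    if False else
                    ("A" if toy_genome.sequence("chr1")[320] != "A"
                     else "C")),
        )
        cluster = VariantCluster("chr1", variants)
        mini = build_mini(toy_genome, cluster, (1, 1), mkparams())
        seq = mini.sequence
        for pos, ref_a, alt_a in sorted(mini.variant_edits, reverse=True):
            off = pos - mini.univ_start
            # locate alt in mini coordinates by replaying earlier edits
            shift = sum(len(a) - len(r) for p, r, a in mini.variant_edits
                        if p < pos)
            seq = seq[:off + shift] + ref_a \
                + seq[off + shift + len(alt_a):]
        assert seq == toy_genome.fetch("chr1", mini.univ_start,
                                       mini.univ_end)


class TestAssemble:
    def test_augmented_length_arithmetic(self, toy_genome):
        params = mkparams()
        ref = toy_genome.sequence("chr1")[500]
        cluster = VariantCluster("chr1", (het_snp(
            "chr1", 500, ref, "G" if ref != "G" else "T"),))
        mini = build_mini(toy_genome, cluster, (1,), params)
        augmented, aux = assemble(toy_genome, [mini], params)
        assert augmented.length("chr1") == 1000 + 3 + 75
        assert augmented.names == ["chr1"]  # name preserved for pairing
        assert aux.minis[0].aug_start == 1003
        assert aux.minis[0].aug_end == 1078

    def test_two_minis_cumulative_offsets(self):
        g = generate_genome(1, [1000], seed=5)
        params = mkparams()
        ref1 = g.sequence("chr1")[200]
        ref3 = g.fetch("chr1", 600, 603)
        m1 = build_mini(g, VariantCluster("chr1", (het_snp(
            "chr1", 200, ref1, "G" if ref1 != "G" else "T"),)), (1,), params)
        m2 = build_mini(g, VariantCluster("chr1", (VariantRecord(
            "chr1", 600, ref3, (ref3[0],), (0, 1)),)), (1,), params)
        augmented, aux = assemble(g, [m1, m2], params)
        assert augmented.length("chr1") == 1000 + 3 + 75 + 3 + 75
        assert aux.minis[1].aug_start == 1081
        assert aux.minis[1].aug_end == 1156

    def test_zero_minis_identity(self, toy_genome):
        augmented, aux = assemble(toy_genome, [], mkparams(),
                                  edits=[("chr1", 3, "A", "G")])
        assert augmented == toy_genome
        assert aux.minis == [] and len(aux.edits) == 1

    def test_separator_is_m_plus_1_ns(self, toy_genome):
        params = mkparams()
        ref = toy_genome.sequence("chr1")[500]
        mini = build_mini(toy_genome, VariantCluster("chr1", (het_snp(
            "chr1", 500, ref, "G" if ref != "G" else "T"),)), (1,), params)
        augmented, _ = assemble(toy_genome, [mini], params)
        assert augmented.fetch("chr1", 1000, 1003) == "NNN"


class TestBuildReference:
    def test_female_drops_chry(self):
        g = ReferenceGenome([("chr1", "ACGT" * 100), ("chrY", "ACGT" * 50)])
        augmented, aux = build_reference(
            g, [], BuildParameters(k=36, m=2, sex="female"))
        assert augmented.names == ["chr1"]
        assert "chrY" not in aux.universal_lengths

    def test_all_hom_ref_is_identity(self, toy_genome):
        variants = [VariantRecord(
            "chr1", p, toy_genome.sequence("chr1")[p],
            ("A" if toy_genome.sequence("chr1")[p] != "A" else "C",), (0, 0))
            for p in (10, 200, 500)]
        augmented, aux = build_reference(toy_genome, variants, mkparams())
        assert augmented == toy_genome
        assert aux.minis == [] and aux.edits == []

    def test_mini_count_equals_cluster_enumeration(self, small_genome,
                                                   small_individual):
        params = mkparams()
        augmented, aux = build_reference(
            small_genome, small_individual.variants, params)
        _, _, mini_vars = classify_variants(
            sorted(small_individual.variants, key=lambda v: (v.chrom, v.pos)),
            params)
        expected = sum(
            len(enumerate_combos(c, params))
            for c in cluster_mini_variants(mini_vars, params)
        )
        assert len(aux.minis) == expected

    def test_backbone_differs_exactly_at_hom_alt_snps(self, small_genome,
                                                      small_individual):
        params = mkparams()
        augmented, aux = build_reference(
            small_genome, small_individual.variants, params)
        backbone = augmented.sequence("chr1")[:small_genome.length("chr1")]
        universal = small_genome.sequence("chr1")
        diff = {i for i in range(len(universal))
                if backbone[i] != universal[i]}
        assert diff == {pos for _, pos, _, _ in aux.edits}

    def test_determinism_byte_identical_outputs(self, small_genome,
                                                small_individual, tmp_path):
        from refeditor.io_formats import write_aux_map, write_fasta
        paths = []
        for run in (1, 2):
            augmented, aux = build_reference(
                small_genome, small_individual.variants, mkparams())
            fa = tmp_path / f"run{run}.fa"
            tsv = tmp_path / f"run{run}.tsv"
            write_fasta(augmented, fa)
            write_aux_map(aux, tsv)
            paths.append((fa.read_bytes(), tsv.read_bytes()))
        assert paths[0] == paths[1]

    def test_inter_cluster_gaps_protect_reads(self, small_genome,
                                              small_individual):
        """No read can span variants of two different clusters."""
        params = mkparams()
        _, _, mini_vars = classify_variants(
            sorted(small_individual.variants, key=lambda v: (v.chrom, v.pos)),
            params)
        clusters = cluster_mini_variants(mini_vars, params)
        for a, b in itertools.pairwise(clusters):
            gap = b.variants[0].pos - a.variants[-1].pos
            assert gap >= params.k + params.m
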