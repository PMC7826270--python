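import numpy as np
import pytest

from meioscan._encode import decode
from meioscan.synthgenome import (
    MeiosisParams,
    ParentalGenomes,
    ReadSimParams,
    build_reference,
    make_male_genome,
    place_snps,
    simulate_meiosis,
    simulate_reads,
    spike_deletions,
)


class TestBuildReference:
    def test_construction_and_determinism(self):
        spec = [("chr2L", 50_000, "A")]
        g1 = build_reference(spec, seed=1)
        g2 = build_reference(spec, seed=1)
        assert g1.length("chr2L") == 50_000
        assert g1.seqs["chr2L"].max() <= 3  # only ACGT
        assert np.array_equal(g1.seqs["chr2L"], g2.seqs["chr2L"])
        assert not np.array_equal(
            g1.seqs["chr2L"], build_reference(spec, seed=2).seqs["chr2L"]
        )

    def test_sex_flags_retrievable(self):
        g = build_reference([("X", 5000, "X"), ("Y", 2000, "Y"), ("2", 3000, "A")], 0)
        assert g.x_name() == "X" and g.y_name() == "Y"
        assert g.female_chroms() == ["X", "2"]
        assert g.autosomes() == ["2"]

    @pytest.mark.parametrize(
        "spec", [[("a", 0, "A")], [("a", 1000, "A"), ("a", 1000, "A")]]
    )
    def test_invalid_specs_rejected(self, spec):
        with pytest.raises(ValueError):
            build_reference(spec, 0)


class TestPlaceSnps:
    def test_count_matches_geometric_expectation(self):
        ref = build_reference([("c", 1_000_000, "A")], 3)
        snps = place_snps(ref, 500.0, seed=5)
        n = len(snps)
        assert abs(n - 2000) < 3 * np.sqrt(2000)
        pos = snps.positions("c")
        assert np.all(np.diff(pos) > 0)

    def test_alleles_differ_and_allele_a_is_reference(self):
        ref = build_reference([("c", 20_000, "A")], 3)
        snps = place_snps(ref, 250.0, seed=5)
        assert (snps.df["allele_a"] != snps.df["allele_b"]).all()
        assert np.array_equal(snps.codes_a("c"), ref.seqs["c"][snps.positions("c")])

    def test_degenerate_spacing_yields_few_snps(self):
        ref = build_reference([("c", 5_000, "A")], 3)
        snps = place_snps(ref, 5_000.0, seed=5)
        assert len(snps) <= 5

    def test_minimum_spacing_enforced(self):
        ref = build_reference([("c", 1_000, "A")], 3)
        with pytest.raises(ValueError):
            place_snps(ref, 1.0)

    def test_exclusion_masks_positions(self, ref, snps, male):
        for chrom in male.snps.chroms():
            banned = set(snps.positions(chrom).tolist()) if chrom in snps.chroms() else set()
            assert not banned & set(male.snps.positions(chrom).tolist())


class TestSpikeDeletions:
    def test_counts_sizes_and_offspring_within_bounds(self, ref, snps):
        for seed in range(5):
            sp = spike_deletions(ref, (5, 25), (1, 20), seed=seed, snps=snps)
            assert 5 <= len(sp.truth) <= 25
            assert sp.truth["size"].between(1, 20).all()
            assert (sp.truth["end"] - sp.truth["start"]).equals(sp.truth["size"])
            assert 0 <= sp.offspring <= 3
            assert "Y" not in set(sp.truth["chrom"])

    def test_no_overlap_on_same_haplotype(self, ref, snps):
        sp = spike_deletions(ref, (25, 25), (500, 1000), seed=9, snps=snps)
        for hap in sp.haplotypes:
            by_chrom = {}
            for c, s, e in hap.deletions:
                by_chrom.setdefault(c, []).append((s, e))
            for spans in by_chrom.values():
                spans.sort()
                assert all(a[1] <= b[0] for a, b in zip(spans, spans[1:]))

    def test_empty_range_leaves_reference_intact(self, ref):
        sp = spike_deletions(ref, (0, 0), (1, 20), seed=1)
        assert len(sp.truth) == 0
        for hap in sp.haplotypes:
            for chrom in ref.female_chroms():
                assert np.array_equal(hap.materialize()[chrom], ref.seqs[chrom])

    def test_materialized_length_shrinks_by_deleted_bases(self, ref, snps):
        sp = spike_deletions(ref, (10, 10), (100, 200), seed=3, snps=snps)
        hap = sp.haplotypes[0]
        removed = sum(e - s for _, s, e in hap.deletions)
        assert sum(v.size for v in hap.materialize().values()) == (
            ref.total_length(ref.female_chroms()) - removed
        )


class TestMaleGenome:
    def test_chromosome_set_is_autosomes_plus_y(self, ref, male):
        assert set(male.genome) == set(ref.autosomes()) | {ref.y_name()}

    def test_karyotype_set_arithmetic(self, ref, male):
        female_chromatid = set(ref.female_chroms())
        offspring = female_chromatid | set(male.genome)
        assert "X" in offspring and "Y" in offspring  # XY
        nullo_x = (female_chromatid - {"X"}) | set(male.genome)
        assert "X" not in nullo_x  # X0 product

    def test_requires_declared_sex_chromosomes(self):
        no_y = build_reference([("X", 5000, "X"), ("2", 5000, "A")], 0)
        with pytest.raises(ValueError):
            make_male_genome(no_y)


class TestSimulateMeiosis:
    def test_no_dsbs_yields_parental_duplicates(self, parents):
        m = simulate_meiosis(parents, MeiosisParams(dsb_count_range=(0, 0)), seed=0)
        assert not m.truth.co and not m.truth.nco and not m.truth.nhej
        for chrom in parents.chroms:
            paint = m.paintings[chrom]
            assert np.array_equal(paint[0], paint[1])
            assert (paint[0] == 0).all() and (paint[2] == 1).all()

    def test_marker_segregation_two_two_outside_three_one_inside_tracts(self, parents):
        # crossovers exchange whole suffixes and keep 2:2 segregation at
        # every marker; conversion flips one chromatid, so a marker covered
        # by exactly one tract (no crossover to re-shuffle the donor) is 3:1
        for seed in range(8):
            m = simulate_meiosis(parents, MeiosisParams(co_fraction=0.0), seed=seed)
            for chrom in parents.chroms:
                pos = parents.snps.positions(chrom)
                hits = np.zeros(pos.size, dtype=int)
                for c, s, e, _ in m.truth.nco:
                    if c == chrom:
                        hits += ((pos >= s) & (pos < e)).astype(int)
                sums = m.paintings[chrom].sum(axis=0)
                assert (sums[hits == 0] == 2).all()
                assert np.isin(sums[hits == 1], (1, 3)).all()
        # with crossovers enabled, markers outside tracts still segregate 2:2
        m = simulate_meiosis(parents, MeiosisParams(), seed=99)
        for chrom in parents.chroms:
            pos = parents.snps.positions(chrom)
            in_tract = np.zeros(pos.size, dtype=bool)
            for c, s, e, _ in m.truth.nco:
                if c == chrom:
                    in_tract |= (pos >= s) & (pos < e)
            assert (m.paintings[chrom].sum(axis=0)[~in_tract] == 2).all()

    def test_crossover_reciprocality(self, parents):
        # the two recombinants are complementary mosaics: across the exchanged
        # pair every marker still carries one copy of each parental allele
        m = simulate_meiosis(
            parents, MeiosisParams(dsb_count_range=(1, 1), co_fraction=1.0), seed=11
        )
        assert len(m.truth.co) == 1
        chrom, _, (i, j) = m.truth.co[0]
        paint = m.paintings[chrom]
        assert ((paint[i] + paint[j]) == 1).all()

    def test_chromatid_sampling_fractions(self, parents):
        co_hit = co_tot = nco_hit = nco_tot = 0
        for seed in range(2000):
            m = simulate_meiosis(parents, None, seed=seed)
            co_tot += len(m.truth.co)
            co_hit += m.truth.co_on_offspring()
            nco_tot += len(m.truth.nco)
            nco_hit += m.truth.nco_on_offspring()
        assert abs(co_hit / co_tot - 0.5) < 3 * np.sqrt(0.25 / co_tot)
        assert abs(nco_hit / nco_tot - 0.25) < 3 * np.sqrt(0.1875 / nco_tot)

    def test_nhej_scar_preset_records_deletions(self, parents):
        params = MeiosisParams(hr_fail_prob=1.0, nhej_deletion_range="clip-2bp")
        m = simulate_meiosis(parents, params, seed=3)
        assert m.truth.nhej and not m.truth.co and not m.truth.nco
        sizes = [s for _, _, s, _ in m.truth.nhej]
        assert all(2 <= s <= 10 for s in sizes)
        # scars shorten the materialized chromatid
        k = m.truth.nhej[0][3]
        removed = sum(e - s for _, s, e in m.deletions[k])
        assert sum(v.size for v in m.chromatid_genome(k).values()) == (
            parents.ref.total_length(parents.chroms) - removed
        )

    def test_determinism(self, parents):
        a = simulate_meiosis(parents, None, seed=42)
        b = simulate_meiosis(parents, None, seed=42)
        assert a.truth == b.truth
        for chrom in parents.chroms:
            assert np.array_equal(a.paintings[chrom], b.paintings[chrom])


class TestSimulateReads:
    def test_pair_count_follows_coverage_convention(self):
        ref = build_reference([("c", 100_000, "A")], 3)
        reads = simulate_reads(
            {"c": ref.seqs["c"]}, ReadSimParams(coverage=10.0, error_rate=0.0), seed=0
        )
        assert len(reads) == int(np.ceil(10.0 * 100_000 / 200))

    def test_error_free_reads_are_exact_substrings(self):
        ref = build_reference([("c", 30_000, "A")], 3)
        hap = {"c": ref.seqs["c"]}
        reads = simulate_reads(hap, ReadSimParams(coverage=2.0, error_rate=0.0), seed=1)
        genome = decode(ref.seqs["c"])
        for i in range(0, len(reads), 37):
            assert decode(reads.r1[i]) in genome
            assert decode((3 - reads.r2[i][::-1]).astype(np.uint8)) in genome

    def test_insert_mean_and_mate_orientation(self):
        ref = build_reference([("c", 200_000, "A")], 3)
        p = ReadSimParams(coverage=5.0, error_rate=0.0, insert_mean=400, insert_sd=40)
        reads = simulate_reads({"c": ref.seqs["c"]}, p, seed=2)
        se = 40 / np.sqrt(len(reads))
        assert abs(reads.insert.mean() - 400) < 2 * se
        i = 0  # mate 2 reverse-complements the fragment end
        s, ins = int(reads.start[i]), int(reads.insert[i])
        frag = ref.seqs["c"][s : s + ins]
        assert np.array_equal(reads.r1[i], frag[:100])
        assert np.array_equal(reads.r2[i], (3 - frag[-100:][::-1]).astype(np.uint8))

    def test_substitution_error_rate(self):
        ref = build_reference([("c", 100_000, "A")], 3)
        hap = {"c": ref.seqs["c"]}
        clean = simulate_reads(hap, ReadSimParams(coverage=4.0, error_rate=0.0), seed=9)
        noisy = simulate_reads(hap, ReadSimParams(coverage=4.0, error_rate=0.01), seed=9)
        frac = (clean.r1 != noisy.r1).mean()
        assert abs(frac - 0.01) < 0.002

    def test_rejects_insert_longer_than_sequences(self):
        ref = build_reference([("c", 300, "A")], 3)
        with pytest.raises(ValueError):
            simulate_reads({"c": ref.seqs["c"]}, ReadSimParams(insert_mean=400), seed=0)

    def test_determinism(self):
        ref = build_reference([("c", 20_000, "A")], 3)
        a = simulate_reads({"c": ref.seqs["c"]}, None, seed=5)
        b = simulate_reads({"c": ref.seqs["c"]}, None, seed=5)
        assert np.array_equal(a.r1, b.r1) and np.array_equal(a.r2, b.r2)
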