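import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from meioscan.delscan import (
    KmerIndex,
    SensitivityConfig,
    UNGAPPED,
    call_deletions,
    call_large_deletions,
    call_small_deletions,
    estimate_sensitivity,
    expected_deletions,
    map_reads,
    match_deletion_calls,
)
from meioscan.synthgenome import (
    Haplotype,
    ReadSimParams,
    build_reference,
    simulate_reads,
)

from conftest import MINI_CHROM_SPEC


def reads_from(hap, coverage=10.0, error_rate=0.0, seed=0):
    return simulate_reads([hap], ReadSimParams(coverage=coverage, error_rate=error_rate), seed)


class TestMapper:
    def test_exact_reads_place_at_true_locus(self, mini_ref, mini_index):
        hap = {"2": mini_ref.seqs["2"]}
        reads = reads_from(hap, coverage=1.0, seed=1)
        alns = map_reads(reads, mini_index)
        assert (alns.status == UNGAPPED).all()
        n = len(reads)
        base = mini_index.global_pos("2", 0)
        # mate 1 is the fragment start on the forward strand
        assert np.array_equal(alns.gpos[:n], base + reads.start)
        assert (alns.mm == 0).all()

    def test_read_straddling_small_deletion_gets_gap_at_truth(self, mini_ref, mini_index):
        hap = Haplotype({"2": mini_ref.seqs["2"]}, [("2", 20_000, 20_010)]).materialize()
        alns = map_reads(reads_from(hap, coverage=12.0, seed=2), mini_index)
        gaps = {(mini_index.to_local(g.gap_gpos), g.gap_size) for g in alns.gapped}
        assert (("2", 20_000), 10) in gaps

    def test_pair_spanning_large_deletion_shows_inflated_insert(self, mini_ref, mini_index):
        hap = Haplotype({"2": mini_ref.seqs["2"]}, [("2", 20_000, 20_800)]).materialize()
        reads = reads_from(hap, coverage=10.0, seed=3)
        alns = map_reads(reads, mini_index)
        inserts = alns.pair_inserts()
        spanning = inserts[~np.isnan(inserts) & (inserts > 600)]
        assert spanning.size >= 3
        assert abs(np.median(spanning) - (400 + 800)) < 120

    def test_determinism(self, mini_ref, mini_index):
        reads = reads_from({"2": mini_ref.seqs["2"]}, coverage=2.0, error_rate=0.001, seed=4)
        a = map_reads(reads, mini_index)
        b = map_reads(reads, mini_index)
        assert np.array_equal(a.status, b.status) and np.array_equal(a.gpos, b.gpos)

    def test_empty_reference_rejected(self):
        from meioscan.synthgenome import ReferenceGenome

        with pytest.raises(ValueError):
            KmerIndex(ReferenceGenome([], {}, {}))


class TestSmallDeletionCalls:
    def test_heterozygous_deletion_called_at_exact_coordinates(self, mini_ref, mini_index):
        alt = Haplotype({"2": mini_ref.seqs["2"]}, [("2", 20_000, 20_010)]).materialize()
        wt = {"2": mini_ref.seqs["2"]}
        reads = simulate_reads([alt, wt], ReadSimParams(coverage=10.0, error_rate=0.0), 5)
        calls = call_small_deletions(map_reads(reads, mini_index), min_support=3)
        assert len(calls) == 1
        c = calls[0]
        assert (c.chrom, c.start, c.end, c.size) == ("2", 20_000, 20_010, 10)
        assert c.genotype == "het" and c.n_support >= 3

    def test_reference_only_reads_give_zero_calls(self, mini_ref, mini_index):
        alns = map_reads(reads_from({"2": mini_ref.seqs["2"]}, seed=6), mini_index)
        assert call_small_deletions(alns) == []
        assert call_large_deletions(alns) == []


class TestLargeDeletionCalls:
    def test_800bp_heterozygous_deletion_breakpoints(self, mini_ref, mini_index):
        alt = Haplotype({"2": mini_ref.seqs["2"]}, [("2", 20_000, 20_800)]).materialize()
        wt = {"2": mini_ref.seqs["2"]}
        reads = simulate_reads([alt, wt], ReadSimParams(coverage=10.0, error_rate=0.0), 7)
        calls = call_large_deletions(map_reads(reads, mini_index), min_support=3)
        assert len(calls) == 1
        c = calls[0]
        assert c.chrom == "2" and abs(c.start - 20_000) <= 5 and abs(c.end - 20_800) <= 5

    def test_known_3067bp_deletion_sized_exactly(self, mini_ref, mini_index):
        # fixture mirroring a multi-kb deficiency sized by split reads
        alt = Haplotype({"2": mini_ref.seqs["2"]}, [("2", 10_000, 13_067)]).materialize()
        wt = {"2": mini_ref.seqs["2"]}
        reads = simulate_reads([alt, wt], ReadSimParams(coverage=10.0, error_rate=0.001), 8)
        calls = call_large_deletions(map_reads(reads, mini_index), min_support=3)
        assert any(c.size == 3067 and abs(c.start - 10_000) <= 5 for c in calls)


class TestSensitivity:
    def test_monotonic_in_coverage(self, mini_ref, mini_index):
        overall = []
        for cov in (3.0, 6.0, 20.0):
            cfg = SensitivityConfig(
                chrom_spec=list(MINI_CHROM_SPEC),
                read=ReadSimParams(coverage=cov, error_rate=0.001),
            )
            rep = estimate_sensitivity(
                4, (1, 20), seed=9, config=cfg, ref=mini_ref, index=mini_index
            )
            overall.append(rep.overall)
        assert overall[0] <= overall[1] + 0.1 and overall[1] <= overall[2] + 0.05
        assert overall[2] > overall[0]

    def test_saturation_at_high_coverage_error_free(self, mini_ref, mini_index):
        cfg = SensitivityConfig(
            chrom_spec=list(MINI_CHROM_SPEC), read=ReadSimParams(coverage=30.0, error_rate=0.0)
        )
        rep = estimate_sensitivity(4, (10, 20), seed=10, config=cfg, ref=mini_ref, index=mini_index)
        assert rep.overall == 1.0

    def test_size_conservation_of_gapped_calls(self, mini_ref, mini_index):
        cfg = SensitivityConfig(
            chrom_spec=list(MINI_CHROM_SPEC), read=ReadSimParams(coverage=12.0, error_rate=0.0)
        )
        rep = estimate_sensitivity(3, (5, 20), seed=11, config=cfg, ref=mini_ref, index=mini_index)
        assert rep.overall == 1.0  # every matched gapped call is exact at error 0

    def test_report_table_consistency(self, mini_ref, mini_index):
        cfg = SensitivityConfig(chrom_spec=list(MINI_CHROM_SPEC))
        rep = estimate_sensitivity(3, (1, 200), seed=12, config=cfg, ref=mini_ref, index=mini_index)
        assert rep.table["n_detected"].le(rep.table["n_truth"]).all()
        assert rep.table["n_truth"].sum() == rep.n_truth
        assert rep.table["n_detected"].sum() == rep.n_detected
        assert 0.0 <= rep.overall <= 1.0
        assert rep.ci[0] <= rep.overall <= rep.ci[1]

    def test_requires_genomes_and_truth(self, mini_ref, mini_index):
        with pytest.raises(ValueError):
            estimate_sensitivity(0, (1, 20))
        cfg = SensitivityConfig(chrom_spec=list(MINI_CHROM_SPEC), n_deletions=(0, 0))
        with pytest.raises(ValueError):
            estimate_sensitivity(1, (1, 20), seed=1, config=cfg, ref=mini_ref, index=mini_index)


class TestMatching:
    def test_breakpoint_and_overlap_rules(self):
        import pandas as pd
        from meioscan.delscan import DeletionCall

        truth = pd.DataFrame(
            {"chrom": ["2", "2"], "start": [100, 5000], "end": [110, 6000], "size": [10, 1000]}
        )
        calls = [
            DeletionCall("2", 105, 115, 10, "gapped", 5),  # within 10 bp
            DeletionCall("2", 5400, 6100, 700, "split", 4),  # reciprocal overlap 0.6
        ]
        assert match_deletion_calls(calls, truth).all()
        far = [DeletionCall("2", 200, 210, 10, "gapped", 5)]
        assert not match_deletion_calls(far, truth).any()


class TestExpectedDeletions:
    def test_conservative_cohort_arithmetic(self):
        e = expected_deletions(15, 0.8, 28, sens_small=0.85)
        assert e.per_progeny_mean == 3
        assert e.nhej_per_meiosis == 12
        assert e.cohort_total == 84
        assert e.expected_detected_small == 71

    def test_degenerate_inputs(self):
        assert expected_deletions(15, 0.0, 28).cohort_total == 0
        e = expected_deletions(20, 0.5, 10, 1.0, 1.0)
        assert e.per_progeny_mean == 2.5
        assert e.cohort_total == 25
        assert e.expected_detected_small == 25 and e.expected_detected_large == 25

    @given(
        st.floats(0, 30), st.floats(0, 1), st.integers(0, 200), st.floats(0, 1)
    )
    @settings(max_examples=100, deadline=None)
    def test_against_reordered_derivation(self, dsbs, hr, n, sens):
        e = expected_deletions(dsbs, hr, n, sens_small=sens)
        # independent re-derivation, multiplied in a different order
        alt_cohort = (n / 4.0) * (hr * dsbs)
        assert e.cohort_total == pytest.approx(alt_cohort, rel=1e-12, abs=1e-9)
        assert e.expected_detected_small == int(np.floor(sens * alt_cohort))

    def test_input_validation(self):
        with pytest.raises(ValueError):
            expected_deletions(-1, 0.5, 10)
        with pytest.raises(ValueError):
            expected_deletions(10, 1.5, 10)
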