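"""Junction loading/classification, skip profiling, PSI and SE event calls."""

import math

import numpy as np
import pytest
from scipy import stats

from ejcsplice.junctions import (
    JunctionRecord,
    SkipEvent,
    assign_and_classify,
    call_se_events,
    classify_junction,
    compute_psi,
    load_junctions,
    skip_read_ratio_profile,
    tabulate_skip_events,
)
from .conftest import make_chain


def jr(donor, acceptor, count=1, strand=".", chrom="chr1", sample="s1", cond="control"):
    return JunctionRecord(
        chrom=chrom, donor_end=donor, acceptor_start=acceptor, strand=strand,
        sample_id=sample, condition=cond, read_count=count,
    )


SJ_FIXTURE = (
    "chr1\t201\t300\t1\t1\t1\t12\t0\t30\n"   # exon1->exon2 junction, 12 uniq
    "chr1\t201\t500\t1\t1\t0\t5\t0\t25\n"    # exon1->exon3 skip, 5 uniq
    "chr1\t401\t500\t0\t0\t1\t7\t2\t30\n"    # strand unknown, 7 uniq
)
BED_FIXTURE = (
    "chr1\t200\t300\t12\t+\n"
    "chr1\t200\t500\t5\t+\n"
    "chr1\t400\t500\t7\t.\n"
)


class TestLoadJunctions:
    def test_sj_fixture(self, tmp_path):
        p = tmp_path / "a.sj.tab"
        p.write_text(SJ_FIXTURE)
        recs = load_junctions(str(p), "sj_tab", "s1", "control")
        assert [(r.donor_end, r.acceptor_start, r.read_count) for r in recs] == [
            (200, 300, 12), (200, 500, 5), (400, 500, 7),
        ]
        assert recs[0].strand == "+" and recs[2].strand == "."

    def test_zero_count_dropped(self, tmp_path):
        p = tmp_path / "z.sj.tab"
        p.write_text("chr1\t201\t300\t1\t1\t1\t0\t9\t30\n")
        assert load_junctions(str(p), "sj_tab", "s", "kd") == []

    def test_bed_dialect_equivalent(self, tmp_path):
        a = tmp_path / "a.sj.tab"
        a.write_text(SJ_FIXTURE)
        b = tmp_path / "b.bed"
        b.write_text(BED_FIXTURE)
        sj = load_junctions(str(a), "sj_tab", "s1", "control")
        bed = load_junctions(str(b), "bed", "s1", "control")
        assert [(r.donor_end, r.acceptor_start, r.read_count) for r in sj] == [
            (r.donor_end, r.acceptor_start, r.read_count) for r in bed
        ]

    def test_acceptor_before_donor_rejected(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t500\t400\t3\n")
        with pytest.raises(ValueError, match="acceptor"):
            load_junctions(str(p), "bed", "s", "control")

    def test_unknown_chrom_warns_but_kept(self, tmp_path):
        p = tmp_path / "c.bed"
        p.write_text("chrUn\t10\t20\t3\n")
        with pytest.warns(UserWarning, match="unknown chromosome"):
            recs = load_junctions(str(p), "bed", "s", "control", known_chroms={"chr1"})
        assert len(recs) == 1


class TestClassifyJunction:
    def test_canonical_adjacent(self, six_exon_chain):
        cls = classify_junction(jr(400, 500), six_exon_chain)
        assert cls.kind == "canonical" and cls.k_skipped == 0
        assert (cls.upstream_exon, cls.downstream_exon) == (2, 3)

    def test_skip_two_exons(self, six_exon_chain):
        cls = classify_junction(jr(400, 900), six_exon_chain)
        assert cls.kind == "skip" and cls.k_skipped == 2
        assert (cls.upstream_exon, cls.downstream_exon) == (2, 5)

    def test_donor_inside_exon_body_unannotated(self, six_exon_chain):
        assert classify_junction(jr(350, 500), six_exon_chain).kind == "unannotated"

    def test_minus_strand_skip(self, six_exon_chain_minus):
        # transcript exon 5 = genomic (300,400); exon 2 = genomic (900,1000)
        cls = classify_junction(jr(400, 900, strand="-"), six_exon_chain_minus)
        assert cls.kind == "skip" and cls.k_skipped == 2
        assert (cls.upstream_exon, cls.downstream_exon) == (2, 5)

    def test_chrom_mismatch_errors(self, six_exon_chain):
        with pytest.raises(ValueError, match="chr2"):
            classify_junction(jr(400, 500, chrom="chr2"), six_exon_chain)

    def test_strand_mismatch_errors(self, six_exon_chain):
        with pytest.raises(ValueError, match="strand"):
            classify_junction(jr(400, 500, strand="-"), six_exon_chain)

    def test_first_to_last_exon_is_valid_skip(self, six_exon_chain):
        cls = classify_junction(jr(200, 1100), six_exon_chain)
        assert cls.kind == "skip" and cls.k_skipped == 4


def brute_force_classify(j, chain):
    """Oracle: try every ordered exon pair's transcript-orientation boundaries."""
    for u in range(1, chain.n_exons + 1):
        for v in range(1, chain.n_exons + 1):
            eu, ev = chain.exon(u), chain.exon(v)
            if chain.strand == "+":
                hit = j.donor_end == eu.end and j.acceptor_start == ev.start
            else:
                hit = j.acceptor_start == eu.start and j.donor_end == ev.end
            if hit and v > u:
                return ("canonical" if v == u + 1 else "skip", u, v)
    return ("unannotated", None, None)


def test_classification_agrees_with_brute_force_oracle():
    rng = np.random.default_rng(42)
    for trial in range(300):
        n = int(rng.integers(3, 9))
        pos, coords = 0, []
        for _ in range(n):
            pos += int(rng.integers(50, 400))
            end = pos + int(rng.integers(50, 300))
            coords.append((pos, end))
            pos = end
        strand = "+" if rng.random() < 0.5 else "-"
        chain = make_chain(exon_coords=coords, strand=strand)
        bounds = sorted({c for se in coords for c in se})
        for _ in range(5):
            if rng.random() < 0.7:  # boundary-derived junction
                d, a = sorted(rng.choice(bounds, size=2, replace=False))
            else:  # arbitrary coordinates
                d, a = sorted(rng.integers(0, pos, size=2))
                if d == a:
                    a += 1
            j = jr(int(d), int(a), strand=strand)
            got = classify_junction(j, chain)
            kind, u, v = brute_force_classify(j, chain)
            assert got.kind == kind
            if kind != "unannotated":
                assert (got.upstream_exon, got.downstream_exon) == (u, v)


class TestTabulateSkipEvents:
    def test_aggregation_across_samples(self, six_exon_chain):
        recs = [
            jr(400, 900, 5, sample="s1"),
            jr(400, 900, 5, sample="s2", cond="kd"),
        ]
        (ev,) = tabulate_skip_events(recs, [six_exon_chain])
        assert ev.reads_by_sample == {"s1": 5, "s2": 5}
        assert ev.k_skipped == 2 and ev.skipped_exons == [3, 4]

    def test_missing_sample_recorded_zero(self, six_exon_chain):
        recs = [jr(400, 900, 3, sample="kd1", cond="kd")]
        (ev,) = tabulate_skip_events(recs, [six_exon_chain], sample_ids=["c1", "kd1"])
        assert ev.reads_by_sample == {"c1": 0, "kd1": 3}

    def test_two_distinct_junctions_two_events(self, six_exon_chain):
        recs = [jr(400, 900, 3), jr(200, 700, 2)]
        events = tabulate_skip_events(recs, [six_exon_chain])
        assert len(events) == 2

    def test_canonical_not_tabulated(self, six_exon_chain):
        assert tabulate_skip_events([jr(400, 500, 9)], [six_exon_chain]) == []


def _event(reads):
    return SkipEvent(gene_id="G1", upstream_exon=2, downstream_exon=5,
                     reads_by_sample=reads)


class TestSkipReadRatioProfile:
    def test_single_event_arithmetic_no_pseudocount(self):
        ev = _event({"c1": 2, "k1": 4})
        prof = skip_read_ratio_profile(
            [ev], {"c1": 10**6, "k1": 10**6}, {"c1": "control", "k1": "kd"},
            pseudocount=0.0,
        )
        row = prof[prof.k == 2].iloc[0]
        assert row.median_ratio == pytest.approx(2.0)

    def test_identical_tables_give_unit_ratio(self):
        evs = [
            SkipEvent("G1", 2, 4, {"c1": 7, "k1": 7}),
            SkipEvent("G2", 2, 5, {"c1": 3, "k1": 3}),
        ]
        prof = skip_read_ratio_profile(
            evs, {"c1": 10**6, "k1": 10**6}, {"c1": "control", "k1": "kd"}
        )
        assert (prof.median_ratio == 1.0).all()

    def test_pseudocount_with_zero_control(self):
        ev = _event({"c1": 0, "k1": 3})
        prof = skip_read_ratio_profile(
            [ev], {"c1": 10**6, "k1": 10**6}, {"c1": "control", "k1": "kd"},
            pseudocount=0.5,
        )
        assert prof[prof.k == 2].iloc[0].median_ratio == pytest.approx(7.0)

    def test_empty_events_error(self):
        with pytest.raises(ValueError):
            skip_read_ratio_profile([], {}, {})


class TestComputePsi:
    @pytest.mark.parametrize(
        "inc_up,inc_down,exc,expected",
        [(30, 30, 10, 0.75), (10, 10, 0, 1.0), (0, 0, 5, 0.0), (20, 10, 15, 0.5)],
    )
    def test_values(self, inc_up, inc_down, exc, expected):
        assert compute_psi(inc_up, inc_down, exc) == pytest.approx(expected)

    def test_no_evidence_is_nan(self):
        assert math.isnan(compute_psi(0, 0, 0))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            compute_psi(-1, 0, 0)


def se_records(chain, cond, inc, exc, sample):
    """Canonical junctions around exon 3 at `inc` reads, the skip over it at `exc`."""
    e = chain.exon
    return [
        jr(e(2).end, e(3).start, inc, sample=sample, cond=cond),
        jr(e(3).end, e(4).start, inc, sample=sample, cond=cond),
        jr(e(2).end, e(4).start, exc, sample=sample, cond=cond),
    ]


class TestCallSeEvents:
    def test_strong_shift_called_significant(self, six_exon_chain):
        recs = (
            se_records(six_exon_chain, "control", 90, 10, "c1")
            + se_records(six_exon_chain, "kd", 30, 70, "k1")
        )
        calls = call_se_events(recs, [six_exon_chain])
        call = next(c for c in calls if c.exon_index == 3)
        assert call.psi_control == pytest.approx(0.9)
        assert call.psi_kd == pytest.approx(0.3)
        assert call.delta_psi == pytest.approx(-0.6)
        # independent oracle for the exact test on the pooled 2x2
        _, p_expected = stats.fisher_exact([[90, 10], [30, 70]])
        assert call.p_value == pytest.approx(p_expected)
        assert call.significant

    def test_identical_conditions_yield_no_calls(self, six_exon_chain):
        recs = (
            se_records(six_exon_chain, "control", 50, 50, "c1")
            + se_records(six_exon_chain, "kd", 50, 50, "k1")
        )
        calls = call_se_events(recs, [six_exon_chain])
        assert not any(c.significant for c in calls)

    def test_small_dpsi_never_called_despite_tiny_p(self, six_exon_chain):
        recs = (
            se_records(six_exon_chain, "control", 5000, 5000, "c1")
            + se_records(six_exon_chain, "kd", 3500, 6500, "k1")
        )
        calls = call_se_events(recs, [six_exon_chain])
        call = next(c for c in calls if c.exon_index == 3)
        assert abs(call.delta_psi) == pytest.approx(0.15, abs=0.01)
        assert call.p_value < 1e-10 and not call.significant

    def test_no_evidence_warns_empty(self, six_exon_chain):
        with pytest.warns(UserWarning, match="no testable"):
            assert call_se_events([], [six_exon_chain]) == []


def test_read_count_conservation(six_exon_chain):
    """Canonical + skip + unannotated counts account for every junction read."""
    rng = np.random.default_rng(3)
    recs = []
    for _ in range(50):
        d, a = sorted(rng.integers(100, 1200, size=2))
        if d == a:
            continue
        recs.append(jr(int(d), int(a), int(rng.integers(1, 20))))
    classified = assign_and_classify(recs, [six_exon_chain])
    total_in_span = sum(j.read_count for j, _, _ in classified)
    by_kind = {}
    for j, _, cls in classified:
        by_kind[cls.kind] = by_kind.get(cls.kind, 0) + j.read_count
    assert sum(by_kind.values()) == total_in_span
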