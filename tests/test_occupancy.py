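"""Occupancy ratios, bootstrap null and the empirical two-tailed p-value."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ejcsplice.junctions import SkipEvent
from ejcsplice.occupancy import (
    EJCOccupancyTest,
    GeneOccupancy,
    bootstrap_null,
    build_ratio_pool,
    empirical_two_tailed_p,
    internal_mean,
    load_occupancy,
    observed_mean_ratio,
    occupancy_from_frame,
    upstream_ratio,
)
from .conftest import make_chain

WORKED_COUNTS = [10, 4, 8, 6, 2]


def occ(counts, gene="G1"):
    return GeneOccupancy(
        gene_id=gene,
        crosslink=np.asarray(counts, dtype=float),
        rnaseq=np.ones(len(counts)),
    )


def ev(upstream, gene="G1"):
    return SkipEvent(gene_id=gene, upstream_exon=upstream, downstream_exon=upstream + 2)


class TestInternalMean:
    @pytest.mark.parametrize(
        "counts,expected",
        [(WORKED_COUNTS, 6.0), ([5, 9, 1], 9.0), ([7, 0, 0, 7], 0.0)],
    )
    def test_values(self, counts, expected):
        assert internal_mean(counts) == pytest.approx(expected)

    def test_too_few_exons_is_nan(self):
        assert math.isnan(internal_mean([3, 4]))


class TestUpstreamRatio:
    def test_offset_one_worked_fixture(self):
        assert upstream_ratio(ev(3), occ(WORKED_COUNTS), 1) == pytest.approx(8 / 6)

    def test_offset_two_worked_fixture(self):
        assert upstream_ratio(ev(3), occ(WORKED_COUNTS), 2) == pytest.approx(4 / 6)

    def test_first_exon_excluded(self):
        assert math.isnan(upstream_ratio(ev(1), occ(WORKED_COUNTS), 1))

    def test_offset_off_chain_is_nan(self):
        assert math.isnan(upstream_ratio(ev(2), occ(WORKED_COUNTS), 2))

    def test_zero_internal_mean_is_nan(self):
        assert math.isnan(upstream_ratio(ev(3), occ([7, 0, 0, 0, 7]), 1))

    def test_invalid_offset(self):
        with pytest.raises(ValueError):
            upstream_ratio(ev(3), occ(WORKED_COUNTS), 0)


class TestObservedMeanRatio:
    def test_mean_of_two(self):
        occupancy = {
            "A": occ([1, 9, 6, 1], gene="A"),   # event upstream 3 -> 6/7.5 = 0.8
            "B": occ([1, 2, 8, 1], gene="B"),   # 8/5 = 1.6
        }
        mean, m = observed_mean_ratio(
            [ev(3, "A"), ev(3, "B")], occupancy, offset=1
        )
        assert m == 2 and mean == pytest.approx((6 / 7.5 + 8 / 5) / 2)

    def test_nan_ratios_excluded(self):
        occupancy = {"A": occ(WORKED_COUNTS, "A")}
        mean, m = observed_mean_ratio([ev(1, "A"), ev(3, "A")], occupancy, 1)
        assert m == 1 and mean == pytest.approx(8 / 6)

    def test_all_nan_errors(self):
        with pytest.raises(ValueError):
            observed_mean_ratio([ev(1, "A")], {"A": occ(WORKED_COUNTS, "A")}, 1)


class TestEmpiricalP:
    def test_enumerated_four_value_case(self):
        p = empirical_two_tailed_p(1.15, np.array([0.8, 0.9, 1.1, 1.2]))
        assert p == pytest.approx(0.8)

    def test_floor_when_observed_beyond_all(self):
        null = np.linspace(0, 1, 999)
        assert empirical_two_tailed_p(2.0, null) == pytest.approx(2 / 1000)

    def test_center_of_symmetric_null_capped_at_one(self):
        null = np.concatenate([np.full(500, 0.9), np.full(500, 1.1)])
        assert empirical_two_tailed_p(1.0, null) == 1.0

    @settings(max_examples=50, deadline=None)
    @given(
        obs=st.floats(min_value=-5, max_value=5),
        seed=st.integers(min_value=0, max_value=10**6),
        B=st.integers(min_value=1, max_value=500),
    )
    def test_bounds_always_hold(self, obs, seed, B):
        null = np.random.default_rng(seed).normal(size=B)
        p = empirical_two_tailed_p(obs, null)
        assert 2 / (B + 1) <= p <= 1.0


class TestBootstrapNull:
    def test_deterministic_given_seed(self):
        pool = np.array([0.5, 1.0, 1.5, 2.0])
        a = bootstrap_null(pool, m=3, B=500, rng=np.random.default_rng(7))
        b = bootstrap_null(pool, m=3, B=500, rng=np.random.default_rng(7))
        assert np.array_equal(a, b)

    def test_constant_pool_degenerate(self):
        pool = np.ones(10)
        null = bootstrap_null(pool, m=4, B=100, rng=np.random.default_rng(0))
        assert np.all(null == 1.0)

    def test_single_gene_three_point_distribution(self):
        """Pool [10,4,8,6,2] -> internal ratios {4/6, 8/6, 1}; replicate means
        for m=1 average to 1.0 (exact enumeration of the 3-point law)."""
        pool = build_ratio_pool({"G": occ(WORKED_COUNTS, "G")})
        assert sorted(pool) == pytest.approx([4 / 6, 1.0, 8 / 6])
        null = bootstrap_null(pool, m=1, B=60_000, rng=np.random.default_rng(5))
        assert set(np.round(null, 6)) <= set(np.round(pool, 6))
        exact_sd = math.sqrt(np.mean((pool - 1.0) ** 2))
        assert null.mean() == pytest.approx(1.0, abs=3 * exact_sd / math.sqrt(60_000))

    def test_empty_pool_errors(self):
        with pytest.raises(ValueError):
            bootstrap_null(np.array([]), m=1, B=10)


@settings(max_examples=30, deadline=None)
@given(c=st.floats(min_value=0.01, max_value=100.0))
def test_scale_invariance_of_ratios(c):
    """Multiplying a gene's crosslink counts by c > 0 leaves its ratios unchanged."""
    base = occ(WORKED_COUNTS)
    scaled = occ([c * x for x in WORKED_COUNTS])
    assert upstream_ratio(ev(3), base, 1) == pytest.approx(
        upstream_ratio(ev(3), scaled, 1)
    )
    assert build_ratio_pool({"G1": base}) == pytest.approx(
        build_ratio_pool({"G1": scaled})
    )


OCC_TSV_HEADER = "gene_id\texon_index\tcrosslink_1\tcrosslink_2\trnaseq_1\trnaseq_2\n"


class TestLoadOccupancy:
    def chains(self):
        return [
            make_chain(gene_id="G1", exon_coords=((0, 10), (20, 30), (40, 50), (60, 70))),
            make_chain(gene_id="G2", exon_coords=((0, 10), (20, 30), (40, 50))),
        ]

    def test_crosslink_columns_summed(self, tmp_path):
        p = tmp_path / "occ.tsv"
        rows = [f"G1\t{i}\t3\t4\t1\t0\n" for i in range(1, 5)]
        p.write_text(OCC_TSV_HEADER + "".join(rows))
        occd = load_occupancy(str(p), self.chains())
        assert occd["G1"].crosslink.tolist() == [7.0] * 4

    def test_silent_gene_dropped(self, tmp_path):
        p = tmp_path / "occ.tsv"
        rows = [f"G1\t{i}\t3\t4\t0\t0\n" for i in range(1, 5)]
        rows += [f"G2\t{i}\t1\t1\t2\t2\n" for i in range(1, 4)]
        p.write_text(OCC_TSV_HEADER + "".join(rows))
        occd = load_occupancy(str(p), self.chains())
        assert set(occd) == {"G2"}

    def test_gene_absent_from_chains_warns(self, tmp_path):
        p = tmp_path / "occ.tsv"
        p.write_text(OCC_TSV_HEADER + "GX\t1\t1\t1\t1\t1\n")
        with pytest.warns(UserWarning, match="GX"):
            assert load_occupancy(str(p), self.chains()) == {}

    def test_duplicate_row_errors(self, tmp_path):
        p = tmp_path / "occ.tsv"
        p.write_text(OCC_TSV_HEADER + "G1\t2\t1\t1\t1\t1\nG1\t2\t1\t1\t1\t1\n")
        with pytest.raises(ValueError, match="duplicate"):
            load_occupancy(str(p), self.chains())

    def test_exon_index_out_of_range_errors(self, tmp_path):
        p = tmp_path / "occ.tsv"
        p.write_text(OCC_TSV_HEADER + "G2\t9\t1\t1\t1\t1\n")
        with pytest.raises(ValueError, match="outside"):
            load_occupancy(str(p), self.chains())

    def test_missing_exon_rows_fill_zero(self):
        df = pd.DataFrame(
            [{"gene_id": "G1", "exon_index": 2, "crosslink_1": 5, "rnaseq_1": 1}]
        )
        occd = occupancy_from_frame(df, self.chains())
        assert occd["G1"].crosslink.tolist() == [0.0, 5.0, 0.0, 0.0]


class TestModelInterface:
    def occupancy(self):
        rng = np.random.default_rng(11)
        return {
            f"G{i}": GeneOccupancy(
                gene_id=f"G{i}",
                crosslink=rng.poisson(30, size=8).astype(float),
                rnaseq=np.ones(8),
            )
            for i in range(20)
        }

    def events(self):
        return [ev(4, f"G{i}") for i in range(20)]

    def test_fit_is_deterministic(self):
        occd = self.occupancy()
        r1 = EJCOccupancyTest(self.events(), occd).fit(B=1000, seed=3)
        r2 = EJCOccupancyTest(self.events(), occd).fit(B=1000, seed=3)
        assert r1.to_json() == r2.to_json()

    def test_summary_and_frame(self):
        res = EJCOccupancyTest(self.events(), self.occupancy()).fit(B=500, seed=1)
        txt = res.summary()
        assert "offset" in txt and "p" in txt
        df = res.to_frame()
        assert set(df.offset) == {1, 2}
        assert ((df.p >= 2 / 501) & (df.p <= 1)).all()

    def test_events_deduplicated_on_gene_and_upstream(self):
        events = self.events() + self.events()  # every event twice
        model = EJCOccupancyTest(events, self.occupancy())
        assert len(model.events) == 20

    def test_empty_events_error(self):
        with pytest.raises(ValueError):
            EJCOccupancyTest([], self.occupancy()).fit(B=10, seed=0)
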