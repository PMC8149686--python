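"""Conversion filter, per-cytosine aggregation, region and genome-wide levels."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hcgkit.calling import (
    CytosineTable,
    ReadMethCalls,
    ReadSet,
    aggregate_cytosines,
    filter_nonconverted_reads,
    genome_wide_difference,
    max_mchh_run,
    region_methylation,
)

from .conftest import make_table


def read_from_pattern(read_id, pattern, chrom="chr1", start=1, step=2):
    """Pattern items like 'chh:M', 'cg:U' -> a ReadMethCalls at spaced positions."""
    ctx = {"cg": "CG", "chg": "CHG", "chh": "CHH"}
    calls = [
        (start + i * step, ctx[p.split(":")[0]], p.split(":")[1] == "M")
        for i, p in enumerate(pattern)
    ]
    return ReadMethCalls(read_id, chrom, start, "+", calls)


class TestConversionFilter:
    def test_four_consecutive_methylated_chh_removed(self):
        read = read_from_pattern("x", ["chh:M"] * 4)
        kept, removed = filter_nonconverted_reads([read])
        assert removed == 1 and len(kept) == 0

    def test_exactly_three_retained(self):
        read = read_from_pattern("x", ["chh:M", "chh:M", "chh:M", "chh:U", "chh:M"])
        kept, removed = filter_nonconverted_reads([read])
        assert removed == 0 and len(kept) == 1

    def test_run_spans_other_contexts_by_default(self):
        # 4 methylated CHH with a CG call in between: still one run of 4
        pattern = ["chh:M", "chh:M", "cg:U", "chh:M", "chh:M"]
        read = read_from_pattern("x", pattern)
        kept, removed = filter_nonconverted_reads([read])
        assert removed == 1
        # alternate interpretation: intervening CG breaks the run
        kept, removed = filter_nonconverted_reads([read], span_other_contexts=False)
        assert removed == 0

    def test_empty_collection(self):
        kept, removed = filter_nonconverted_reads([])
        assert removed == 0 and len(kept) == 0

    def test_methylated_cg_runs_do_not_count(self):
        read = read_from_pattern("x", ["cg:M"] * 6 + ["chh:M"])
        kept, removed = filter_nonconverted_reads([read])
        assert removed == 0

    def test_unordered_calls_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            ReadMethCalls("x", "chr1", 5, "+", [(5, "CG", True), (5, "CHH", False)])

    @given(
        st.lists(
            st.lists(
                st.tuples(st.sampled_from(["CG", "CHG", "CHH"]), st.booleans()),
                min_size=0,
                max_size=12,
            ),
            min_size=0,
            max_size=8,
        )
    )
    def test_max_run_matches_naive_scan(self, payloads):
        reads = [
            ReadMethCalls(
                f"r{i}", "chr1", 1, "+",
                [(j * 3 + 1, ctx, m) for j, (ctx, m) in enumerate(calls)],
            )
            for i, calls in enumerate(payloads)
        ]

        def naive(calls):
            best = run = 0
            for _, ctx, m in calls:
                if ctx != "CHH":
                    continue
                run = run + 1 if m else 0
                best = max(best, run)
            return best

        got = max_mchh_run(ReadSet.from_reads(reads)) if reads else []
        assert list(got) == [naive(r.calls) for r in reads]

    def test_filter_never_increases_counts(self, small_world):
        """aggregate(filter(R)) <= aggregate(R), sitewise."""
        from hcgkit.simulate import sample_reads, true_cytosine_table

        cfg = dataclasses.replace(small_world["config"], nonconversion_read_fraction=0.05)
        reads = sample_reads(small_world["baseline"], cfg, seed=13)
        cmap = true_cytosine_table(small_world["baseline"])
        cols = ["meth", "total"]
        before = aggregate_cytosines(reads, cmap).df.set_index(["chrom", "pos", "strand"])[cols]
        kept, removed = filter_nonconverted_reads(reads)
        assert removed > 0
        after = aggregate_cytosines(kept, cmap).df.set_index(["chrom", "pos", "strand"])[cols]
        joined = before.join(after, rsuffix="_f", how="left").fillna(0)
        assert (joined["meth_f"] <= joined["meth"]).all()
        assert (joined["total_f"] <= joined["total"]).all()

    def test_filter_efficacy_on_unmethylated_truth(self):
        """With true level 0 and long reads, post-filter CHH level << the
        nonconversion fraction."""
        from hcgkit.simulate import SimConfig, TrueMethylome, sample_reads, true_cytosine_table

        rng = np.random.default_rng(0)
        n = 4000
        sites = pd.DataFrame(
            {
                "chrom": "chr1",
                "pos": np.arange(1, n + 1),
                "strand": "+",
                "context": rng.choice(["CG", "CHG", "CHH"], size=n, p=[0.25, 0.2, 0.55]),
                "trinucleotide": ".",
                "p_base": 0.0,
                "p": 0.0,
            }
        )
        m = TrueMethylome(sites)
        f = 0.04
        cfg = SimConfig(coverage_mean=30.0, read_length_cytosines=10,
                        nonconversion_read_fraction=f)
        reads = sample_reads(m, cfg, seed=3)
        kept, _ = filter_nonconverted_reads(reads)
        table = aggregate_cytosines(kept, true_cytosine_table(m))
        chh = table.by_context("CHH")
        level = chh["meth"].sum() / chh["total"].sum()
        assert level < f / 10


class TestAggregation:
    def test_counts_and_level(self):
        reads = [
            ReadMethCalls("a", "chr1", 7, "+", [(7, "CG", True)]),
            ReadMethCalls("b", "chr1", 7, "+", [(7, "CG", False)]),
        ]
        cmap = pd.DataFrame(
            {"chrom": ["chr1"], "pos": [7], "strand": ["+"], "context": ["CG"]}
        )
        table = aggregate_cytosines(reads, cmap)
        row = table.df.iloc[0]
        assert row["meth"] == 1 and row["total"] == 2

    def test_unknown_position_names_site(self):
        reads = [ReadMethCalls("a", "chr1", 9, "+", [(9, "CG", True)])]
        cmap = pd.DataFrame(
            {"chrom": ["chr1"], "pos": [7], "strand": ["+"], "context": ["CG"]}
        )
        with pytest.raises(KeyError, match="chr1:9"):
            aggregate_cytosines(reads, cmap)

    def test_uncovered_sites_absent(self):
        reads = [ReadMethCalls("a", "chr1", 7, "+", [(7, "CG", True)])]
        cmap = pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "pos": [7, 8], "strand": ["+", "+"],
             "context": ["CG", "CHH"]}
        )
        table = aggregate_cytosines(reads, cmap)
        assert len(table) == 1

    def test_levels_always_in_unit_interval(self, small_world):
        from hcgkit.simulate import sample_reads, true_cytosine_table

        reads = sample_reads(small_world["gained"], small_world["config"], seed=5)
        table = aggregate_cytosines(reads, true_cytosine_table(small_world["gained"]))
        lv = table.levels.dropna()
        assert ((lv >= 0) & (lv <= 1)).all()


class TestRegionMethylation:
    def test_amplicon_coverage_rule(self):
        table = make_table(
            [
                ("chr1", 10, "+", "CG", 10, 19),   # below 20 reads: excluded
                ("chr1", 12, "+", "CG", 10, 20),
            ]
        )
        r = region_methylation(table, "chr1", 0, 100, "CG", min_coverage=20)
        assert r.n_cytosines == 1
        assert r.pooled == 0.5

    def test_count_pooling(self):
        table = make_table(
            [("chr1", 10, "+", "CG", 2, 10), ("chr1", 12, "+", "CG", 8, 10)]
        )
        r = region_methylation(table, "chr1", 0, 100, "CG", min_coverage=4)
        assert r.pooled == pytest.approx(0.5)
        assert r.pooled_unweighted == pytest.approx(0.5)

    def test_fully_methylated_identity(self):
        table = make_table(
            [("chr1", 10, "+", "CG", 6, 6), ("chr1", 12, "+", "CG", 9, 9)]
        )
        r = region_methylation(table, "chr1", 0, 100, "CG")
        assert r.pooled == 1.0

    def test_no_data_result(self):
        table = make_table([("chr1", 10, "+", "CG", 1, 2)])
        r = region_methylation(table, "chr1", 0, 100, "CG", min_coverage=20)
        assert r.pooled is None and r.n_cytosines == 0


class TestGenomeWideDifference:
    def test_identity_and_antisymmetry(self):
        a = make_table(
            [("chr1", 10, "+", "CG", 2, 10), ("chr1", 12, "+", "CG", 4, 10)]
        )
        b = make_table(
            [("chr1", 10, "+", "CG", 1, 10), ("chr1", 12, "+", "CG", 4, 10)]
        )
        assert genome_wide_difference(a, a, "CG").mean == 0.0
        assert genome_wide_difference(a, b, "CG").mean == pytest.approx(
            -genome_wide_difference(b, a, "CG").mean
        )

    def test_hand_computed_mean(self):
        a = make_table(
            [
                ("chr1", 10, "+", "CG", 2, 10),
                ("chr1", 12, "+", "CG", 4, 10),
                ("chr1", 14, "+", "CG", 6, 10),
            ]
        )
        b = make_table(
            [
                ("chr1", 10, "+", "CG", 1, 10),
                ("chr1", 12, "+", "CG", 4, 10),
                ("chr1", 14, "+", "CG", 3, 10),
            ]
        )
        d = genome_wide_difference(a, b, "CG")
        assert d.mean == pytest.approx((0.1 + 0.0 + 0.3) / 3)
        assert d.n_sites == 3

    def test_coverage_rule_and_no_overlap_error(self):
        a = make_table([("chr1", 10, "+", "CG", 2, 3)])  # below min coverage 4
        with pytest.raises(ValueError, match="no shared"):
            genome_wide_difference(a, a, "CG")
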