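import numpy as np
import pandas as pd
import pytest
from scipy.special import betainc

from isomirseq import (
    AlignmentCandidate,
    CollapsedRead,
    IsomiRCall,
    TailKind,
    arm_usage,
    build_count_table,
    group_ttest,
    isoform_diversity,
    isomir_composition,
    make_reference,
    normalize_cpm,
    rank_cumulative,
)
from isomirseq.isomir import classify_candidate
from isomirseq.quantify import CountTable, KEY_FIELDS


def call(mature="m1", off5=0, off3=0, subs=(), tail="", count=1, sample="s1", fraction=1.0):
    c = AlignmentCandidate(mature, off5, off3, tuple(subs), max(off3, 0) - len(tail), tail)
    return IsomiRCall(
        read=CollapsedRead("A" * 22, count, sample),
        candidate=c,
        category=classify_candidate(c),
        tail=TailKind.NONE,
        seed="A" * 7,
        assigned_fraction=fraction,
    )


def table_from_counts(counts: dict[str, dict[str, float]]) -> CountTable:
    """counts: {mature: {sample: n}} for canonical variants only."""
    calls = [
        call(mature=m, count=int(n), sample=s)
        for m, per in counts.items()
        for s, n in per.items()
    ]
    return build_count_table(calls)


class TestBuildCountTable:
    def test_same_key_aggregates(self):
        t = build_count_table([call(count=3), call(count=2)])
        assert t.counts.shape == (1, 1)
        assert t.counts.iloc[0, 0] == 5

    def test_fractional_multimapping(self):
        calls = [
            call(mature="mA", count=4, fraction=0.5),
            call(mature="mB", count=4, fraction=0.5),
        ]
        t = build_count_table(calls)
        assert sorted(t.counts["s1"]) == [2.0, 2.0]
        assert t.counts["s1"].sum() == 4.0

    def test_empty(self):
        t = build_count_table([])
        assert t.counts.empty

    def test_count_conservation(self):
        rng = np.random.default_rng(5)
        calls = [
            call(mature=f"m{rng.integers(5)}", off3=int(rng.integers(-2, 3)), count=int(rng.integers(1, 50)))
            for _ in range(200)
        ]
        t = build_count_table(calls)
        assert t.counts.to_numpy().sum() == pytest.approx(
            sum(c.read.count * c.assigned_fraction for c in calls)
        )

    def test_tsv_roundtrip(self, tmp_path):
        t = build_count_table([call(count=3), call(off3=2, tail="AA", count=2)])
        t.to_tsv(tmp_path / "c.tsv")
        back = CountTable.from_tsv(tmp_path / "c.tsv")
        pd.testing.assert_frame_equal(back.counts, t.counts)


class TestNormalizeCpm:
    def test_even_split(self):
        t = table_from_counts({"a": {"s1": 5}, "b": {"s1": 5}})
        cpm = normalize_cpm(t).cpm
        assert sorted(cpm["s1"]) == [500000.0, 500000.0]

    def test_single_row_is_million(self):
        t = table_from_counts({"a": {"s1": 7}})
        assert normalize_cpm(t).cpm.iloc[0, 0] == pytest.approx(1e6)

    def test_quarter_split(self):
        t = table_from_counts({"a": {"s1": 1}, "b": {"s1": 3}})
        assert sorted(normalize_cpm(t).cpm["s1"]) == [250000.0, 750000.0]

    def test_zero_total_sample_named(self):
        t = table_from_counts({"a": {"s1": 5}})
        t.counts["s2"] = 0.0
        with pytest.raises(ValueError, match="s2"):
            normalize_cpm(t)

    def test_cpm_sums_to_million(self):
        rng = np.random.default_rng(0)
        t = table_from_counts(
            {f"m{i}": {f"s{j}": int(rng.integers(1, 1000)) for j in range(3)} for i in range(20)}
        )
        sums = normalize_cpm(t).cpm.sum(axis=0)
        assert np.allclose(sums, 1e6, rtol=1e-6)


class TestRankCumulative:
    def test_hand_example(self):
        t = normalize_cpm(table_from_counts({"a": {"s1": 800}, "b": {"s1": 150}, "c": {"s1": 50}}))
        out = rank_cumulative(t)
        assert list(out["name"]) == ["a", "b", "c"]
        assert list(out["pct"]) == pytest.approx([80, 15, 5])
        assert list(out["cumulative_pct"]) == pytest.approx([80, 95, 100])

    def test_single(self):
        out = rank_cumulative(normalize_cpm(table_from_counts({"a": {"s1": 9}})))
        assert out.loc[0, "pct"] == pytest.approx(100)
        assert out.loc[0, "cumulative_pct"] == pytest.approx(100)

    def test_matches_prefix_sum_oracle(self):
        rng = np.random.default_rng(1)
        counts = {f"m{i:02d}": {"s1": float(1000 * 0.8**i + rng.integers(1, 5))} for i in range(50)}
        out = rank_cumulative(normalize_cpm(table_from_counts(counts)))
        pct = out["pct"].to_numpy()
        assert np.allclose(out["cumulative_pct"], np.cumsum(pct))
        assert np.all(np.diff(out["cumulative_pct"]) >= -1e-12)
        assert out["cumulative_pct"].iloc[-1] == pytest.approx(100, rel=1e-6)


class TestArmUsage:
    @pytest.fixture
    def ref(self):
        return make_reference(3, 2)

    def _table(self, ref, cpm5, cpm3):
        m5, m3 = ref.matures[0], ref.matures[1]
        calls = [call(mature="pad", count=1000000, sample="s1")]
        for name, v in ((m5.name, cpm5), (m3.name, cpm3)):
            if v >= 1:
                calls.append(call(mature=name, count=int(v), sample="s1"))
            elif v > 0:
                # sub-read values enter via the multimapping fraction
                calls.append(call(mature=name, count=1, sample="s1", fraction=v))
        return normalize_cpm(build_count_table(calls))

    @pytest.mark.parametrize(
        "c5,c3,expected",
        [(120, 0, "5p-only"), (50, 50, "both"), (0, 80, "3p-only"), (0.5, 0.5, "none")],
    )
    def test_usage_rules(self, ref, c5, c3, expected):
        t = self._table(ref, c5, c3)
        out = arm_usage(t, ref, min_cpm=1.0)
        hid = ref.matures[0].hairpin_id
        assert out.set_index("precursor_id").loc[hid, "usage"] == expected


class TestComposition:
    def test_canonical_fraction_by_construction(self):
        calls = [call(count=48), call(off3=-1, count=32), call(off3=2, tail="AA", count=20)]
        _, global_frac, summary = isomir_composition(build_count_table(calls))
        assert global_frac["canonical"] == pytest.approx(0.48)
        assert summary["pct_canonical"] == pytest.approx(48)
        assert summary["pct_variant"] == pytest.approx(52)
        assert summary["pct_isomir_with_3p_change"] == pytest.approx(100)

    def test_pure_add3p_mature(self):
        calls = [call(mature="mZ", off3=1, tail="A", count=10)]
        per_mature, _, _ = isomir_composition(build_count_table(calls))
        assert per_mature.loc["mZ", "add3p"] == pytest.approx(1.0)

    def test_global_equals_weighted_mean_of_per_mature(self):
        rng = np.random.default_rng(3)
        calls = []
        for i in range(10):
            for off3 in (-1, 0, 2):
                calls.append(
                    call(
                        mature=f"m{i}",
                        off3=off3,
                        tail="AA" if off3 == 2 else "",
                        count=int(rng.integers(1, 100)),
                    )
                )
        t = build_count_table(calls)
        per_mature, global_frac, _ = isomir_composition(t)
        weights = t.counts.sum(axis=1).groupby(level="mature").sum()
        weights = weights / weights.sum()
        recombined = per_mature.mul(weights, axis=0).sum(axis=0)
        assert np.allclose(recombined, global_frac, atol=1e-12)

    def test_fractions_sum_to_one(self):
        calls = [call(count=3), call(off5=1, count=2), call(off3=-1, count=5)]
        per_mature, global_frac, _ = isomir_composition(build_count_table(calls))
        assert global_frac.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(per_mature.sum(axis=1), 1.0, atol=1e-9)


class TestIsoformDiversity:
    def test_seventeen_isoforms(self):
        calls = [call(mature="mir140", off3=-d, count=100) for d in range(1, 6)]
        calls += [call(mature="mir140", off5=d, count=100) for d in range(1, 4)]
        calls += [call(mature="mir140", off3=d, tail="A" * d, count=100) for d in range(1, 4)]
        calls += [call(mature="mir140", off5=-d, count=100) for d in range(1, 4)]
        calls += [call(mature="mir140", subs=[(p, "A", "G")], count=100) for p in range(3)]
        from isomirseq.quantify import key_of_call

        assert len({key_of_call(c) for c in calls}) == 17
        t = build_count_table(calls)
        assert isoform_diversity(t, min_reads=100)["mir140"] == 17

    def test_threshold_excludes(self):
        t = build_count_table([call(count=99), call(off3=-1, count=100)])
        div = isoform_diversity(t, min_reads=100)
        assert div["m1"] == 1

    def test_zero_threshold_counts_all(self):
        t = build_count_table([call(count=99), call(off3=-1, count=100)])
        assert isoform_diversity(t, min_reads=0)["m1"] == 2

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(9)
        calls = [
            call(mature="mX", off3=int(o), count=int(rng.integers(1, 300)))
            for o in range(-5, 4)
        ]
        t = build_count_table(calls)
        values = [
            isoform_diversity(t, r).get("mX", 0) for r in (0, 50, 100, 200, 400)
        ]
        assert values == sorted(values, reverse=True)


class TestGroupTtest:
    def _table(self, a_vals, b_vals):
        rows = {}
        for i, v in enumerate(a_vals):
            rows.setdefault(f"sa{i}", v)
        calls = []
        for i, v in enumerate(a_vals):
            calls.append(call(count=int(v), sample=f"a{i}"))
            calls.append(call(mature="pad", count=int(1000 - v), sample=f"a{i}"))
        for i, v in enumerate(b_vals):
            calls.append(call(count=int(v), sample=f"b{i}"))
            calls.append(call(mature="pad", count=int(1000 - v), sample=f"b{i}"))
        t = normalize_cpm(build_count_table(calls))
        return t, [f"a{i}" for i in range(len(a_vals))], [f"b{i}" for i in range(len(b_vals))]

    def test_symmetric_groups(self):
        t, ga, gb = self._table([10, 12], [10, 12])
        row = group_ttest(t, ga, gb).loc[("m1", 0, 0, "", "")]
        assert row["t"] == pytest.approx(0.0)
        assert row["p"] == pytest.approx(1.0)

    def test_degenerate_zero_variance(self):
        t, ga, gb = self._table([10, 10], [20, 20])
        row = group_ttest(t, ga, gb).loc[("m1", 0, 0, "", "")]
        assert row["degenerate"]
        assert row["p"] == 0.0

    def test_small_group_rejected(self):
        t, ga, gb = self._table([10, 12], [10, 12])
        with pytest.raises(ValueError):
            group_ttest(t, ga[:1], gb)

    def test_p_matches_independent_cdf(self):
        """p equals the regularized-incomplete-beta closed form to 1e-9."""
        rng = np.random.default_rng(7)
        a = rng.normal(100, 10, size=(30, 4))
        b = rng.normal(105, 10, size=(30, 4))
        calls = []
        for i in range(30):
            for j in range(4):
                calls.append(call(mature=f"m{i:02d}", count=1, sample=f"a{j}"))
                calls.append(call(mature=f"m{i:02d}", count=1, sample=f"b{j}"))
        t = build_count_table(calls)
        t.counts.loc[:, [f"a{j}" for j in range(4)]] = a
        t.counts.loc[:, [f"b{j}" for j in range(4)]] = b
        t = CountTable(counts=t.counts, cpm=t.counts)  # treat values as CPM directly
        out = group_ttest(t, [f"a{j}" for j in range(4)], [f"b{j}" for j in range(4)])
        df = 4 + 4 - 2
        p_oracle = betainc(df / 2, 0.5, df / (df + out["t"].to_numpy() ** 2))
        assert np.allclose(out["p"], p_oracle, atol=1e-9)
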