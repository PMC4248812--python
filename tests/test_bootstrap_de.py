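"""The bootstrap DE test: pairing, support, binomial calibration, calls."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isode import (
    BootstrapFolder,
    DEConfig,
    FoldChangePairs,
    binomial_min_support,
    bootstrap_support,
    classify_gene,
    fold_change,
    load_bootstrap_folder,
    merge_replicates,
    min_supported_fold,
    pair_all,
    pair_matching,
    run_isode,
)

from conftest import gaussian_folder


def exact_binomial_b(n, alpha):
    """Oracle: exhaustive pmf tail summation in exact rational arithmetic."""
    a = Fraction(alpha).limit_denominator(10**6)
    tail = 0
    x_min = n + 1
    for x in range(n, -1, -1):
        tail += math.comb(n, x)
        if Fraction(tail, 2**n) <= a:
            x_min = x
        else:
            break
    return Fraction(x_min, n)


class TestMergeReplicates:
    def test_single_folder_identity(self):
        f = BootstrapFolder([{"g": 1.0}, {"g": 2.0}])
        merged = merge_replicates([f])
        assert merged.estimates == f.estimates

    def test_sizes_add_in_folder_order(self):
        f1 = BootstrapFolder([{"g": float(i)} for i in range(3)])
        f2 = BootstrapFolder([{"g": float(10 + i)} for i in range(4)])
        merged = merge_replicates([f1, f2])
        assert merged.m == 7
        assert [e["g"] for e in merged.estimates] == [0, 1, 2, 10, 11, 12, 13]

    def test_seven_replicates_totalling_twenty(self):
        sizes = [3, 3, 3, 3, 3, 3, 2]
        folders = [
            BootstrapFolder([{"g": 1.0}] * s) for s in sizes
        ]
        assert merge_replicates(folders).m == 20

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            merge_replicates([])


class TestPairing:
    def test_matching_n_equals_m(self):
        rng = np.random.default_rng(0)
        a = gaussian_folder(rng, {"g1": 5.0}, 200)
        b = gaussian_folder(rng, {"g1": 5.0}, 200)
        pairs = pair_matching(a, b, seed=1)
        assert pairs["g1"].n == 200

    def test_matching_single_pair(self):
        a = BootstrapFolder([{"g": 4.0}])
        b = BootstrapFolder([{"g": 2.0}])
        pairs = pair_matching(a, b, seed=0)
        assert pairs["g"].ratios.tolist() == [2.0]

    def test_matching_deterministic(self):
        rng = np.random.default_rng(1)
        a = gaussian_folder(rng, {"g": 3.0}, 10)
        b = gaussian_folder(rng, {"g": 3.0}, 10)
        r1 = pair_matching(a, b, seed=7)["g"].ratios
        r2 = pair_matching(a, b, seed=7)["g"].ratios
        assert np.array_equal(r1, r2)

    def test_matching_unequal_m_rejected(self):
        a = BootstrapFolder([{"g": 1.0}] * 3)
        b = BootstrapFolder([{"g": 1.0}] * 4)
        with pytest.raises(ValueError, match="all-pairs"):
            pair_matching(a, b, seed=0)

    def test_all_pairs_cartesian(self):
        a = BootstrapFolder([{"g": float(x)} for x in (1, 2, 3)])
        b = BootstrapFolder([{"g": float(x)} for x in (1, 2, 3, 4, 5)])
        pairs = pair_all(a, b)
        assert pairs["g"].n == 15
        expected = sorted(x / y for x in (1, 2, 3) for y in (1, 2, 3, 4, 5))
        assert sorted(pairs["g"].ratios) == pytest.approx(expected)

    def test_all_pairs_m20_gives_400(self):
        rng = np.random.default_rng(2)
        a = gaussian_folder(rng, {"g": 5.0}, 20)
        b = gaussian_folder(rng, {"g": 5.0}, 20)
        assert pair_all(a, b)["g"].n == 400


class TestFoldChange:
    @pytest.mark.parametrize(
        "a,b,expected", [(10, 5, 2.0), (0, 0, 1.0), (7, 0, math.inf), (0, 3, 0.0)]
    )
    def test_conventions(self, a, b, expected):
        assert fold_change(a, b) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            fold_change(-1, 2)

    def test_infinite_ratio_supports_any_fold(self):
        pairs = FoldChangePairs("g", np.array([math.inf] * 4))
        s_over, _ = bootstrap_support(pairs, 1e9)
        assert s_over == 1.0


class TestBootstrapSupport:
    def test_counting(self):
        pairs = FoldChangePairs("g", np.array([2.0, 2.0, 2.0, 0.5]))
        assert bootstrap_support(pairs, 2.0) == (0.75, 0.25)

    def test_inclusive_at_f_equal_1(self):
        pairs = FoldChangePairs("g", np.ones(5))
        assert bootstrap_support(pairs, 1.0) == (1.0, 1.0)

    def test_matches_naive_count(self):
        rng = np.random.default_rng(3)
        r = rng.lognormal(0, 1, 400)
        pairs = FoldChangePairs("g", r)
        for f in (1.0, 1.5, 2.0, 4.0):
            s_over, s_under = bootstrap_support(pairs, f)
            assert s_over == sum(1 for x in r if x >= f) / 400
            assert s_under == sum(1 for x in r if x <= 1 / f) / 400

    @given(st.floats(min_value=1.0, max_value=50.0), st.floats(min_value=1.0, max_value=50.0))
    @settings(max_examples=50, derandomize=True)
    def test_support_non_increasing_in_f(self, f1, f2):
        rng = np.random.default_rng(4)
        pairs = FoldChangePairs("g", rng.lognormal(0, 1, 100))
        lo, hi = sorted((f1, f2))
        assert bootstrap_support(pairs, lo)[0] >= bootstrap_support(pairs, hi)[0]
        assert bootstrap_support(pairs, lo)[1] >= bootstrap_support(pairs, hi)[1]


class TestBinomialMinSupport:
    def test_n20_alpha05_is_three_quarters(self):
        # tail sums: P(X>=15) ~ 0.0207 <= 0.05 < P(X>=14) ~ 0.0577
        assert binomial_min_support(20, 0.05) == pytest.approx(0.75)

    def test_degenerate_n1_unreachable(self):
        assert binomial_min_support(1, 0.05) == pytest.approx(2.0)

    @pytest.mark.parametrize("alpha", [0.10, 0.05, 0.01])
    def test_matches_exact_tail_oracle_sampled(self, alpha):
        for n in (1, 2, 5, 17, 20, 100, 400, 999):
            assert binomial_min_support(n, alpha) == pytest.approx(
                float(exact_binomial_b(n, alpha))
            )


class TestMinSupportedFold:
    def test_order_statistic_example(self):
        pairs = FoldChangePairs("g", np.array([1.0, 2.0, 3.0, 4.0]))
        assert min_supported_fold(pairs, 0.5) == 3.0

    def test_b_one_requires_all(self):
        pairs = FoldChangePairs("g", np.array([1.5, 2.0, 8.0]))
        assert min_supported_fold(pairs, 1.0) == 1.5

    def test_constant_ratios(self):
        pairs = FoldChangePairs("g", np.full(10, 3.0))
        for b in (0.1, 0.5, 1.0):
            assert min_supported_fold(pairs, b) == 3.0

    def test_matches_enumeration_oracle(self):
        """The largest threshold with support >= b, found by enumerating
        every candidate threshold (each ratio and each reciprocal)."""
        rng = np.random.default_rng(5)
        r = rng.lognormal(0.5, 1, 50)
        pairs = FoldChangePairs("g", r)
        candidates = np.concatenate([r, 1.0 / r])
        for b in (0.2, 0.5, 0.9):
            feasible = [
                f
                for f in candidates
                if max(np.mean(r >= f), np.mean(r <= 1.0 / f)) >= b
            ]
            assert min_supported_fold(pairs, b) == pytest.approx(max(feasible))


class TestClassifyGene:
    def test_over_when_support_exceeds_b(self):
        pairs = FoldChangePairs("g", np.array([3.0] * 8 + [1.0] * 2))
        cfg = DEConfig(min_fold=2.0, alpha=None, min_support=0.75)
        assert classify_gene(pairs, cfg).status == "over"

    def test_non_de_when_support_low(self):
        pairs = FoldChangePairs("g", np.array([3.0] * 6 + [0.4] * 2 + [1.0] * 2))
        cfg = DEConfig(min_fold=2.0, alpha=None, min_support=0.75)
        assert classify_gene(pairs, cfg).status == "non-DE"

    def test_inclusive_exactly_at_binomial_threshold(self):
        """Support exactly x_min/N counts as DE (inclusive comparison)."""
        n = 400
        b = binomial_min_support(n, 0.05)
        k = round(b * n)  # = x_min
        ratios = np.array([3.0] * k + [1.0] * (n - k))
        pairs = FoldChangePairs("g", ratios)
        cfg = DEConfig(min_fold=2.0, alpha=0.05)
        call = classify_gene(pairs, cfg)
        assert call.support_over == pytest.approx(b)
        assert call.status == "over"


class TestRunIsode:
    def test_identical_folders_yield_no_de(self):
        rng = np.random.default_rng(6)
        f = gaussian_folder(rng, {f"g{i}": 10.0 for i in range(20)}, 20)
        calls = run_isode([f], [f], DEConfig(min_fold=1.5, alpha=0.05), seed=0)
        assert all(c.status == "non-DE" for c in calls)
        assert len(calls) == 20

    def test_constructed_de_gene_called_over(self):
        rng = np.random.default_rng(7)
        means_a = {"G": 10.0, "x": 5.0}
        means_b = {"G": 2.0, "x": 5.0}
        a = gaussian_folder(rng, means_a, 20, sd=0.02)
        b = gaussian_folder(rng, means_b, 20, sd=0.02)
        calls = {
            c.gene_id: c
            for c in run_isode([a], [b], DEConfig(min_fold=2.0, alpha=0.05), seed=0)
        }
        assert calls["G"].status == "over"
        assert calls["G"].support_over == 1.0
        assert calls["G"].min_supported_fold == pytest.approx(5.0, rel=0.15)

    def test_direction_antisymmetry(self):
        """Swapping conditions maps over<->under and inverts the minimum
        supported fold."""
        rng = np.random.default_rng(8)
        means_a = {"up": 20.0, "null": 5.0, "down": 1.0}
        means_b = {"up": 5.0, "null": 5.0, "down": 4.0}
        a = gaussian_folder(rng, means_a, 15, sd=0.03)
        b = gaussian_folder(rng, means_b, 15, sd=0.03)
        cfg = DEConfig(min_fold=2.0, alpha=0.05)
        fwd = {c.gene_id: c for c in run_isode([a], [b], cfg, seed=1)}
        rev = {c.gene_id: c for c in run_isode([b], [a], cfg, seed=1)}
        flip = {"over": "under", "under": "over", "non-DE": "non-DE"}
        for g in fwd:
            assert rev[g].status == flip[fwd[g].status]
            assert rev[g].support_over == pytest.approx(fwd[g].support_under)
        assert rev["up"].min_supported_fold == pytest.approx(
            fwd["up"].min_supported_fold
        )

    def test_gene_universe_zero_filled(self):
        a = BootstrapFolder([{"g1": 5.0}] * 4)
        b = BootstrapFolder([{"g2": 5.0}] * 4)
        calls = run_isode([a], [b], DEConfig(min_fold=2.0, alpha=None, min_support=0.9), seed=0)
        assert {c.gene_id for c in calls} == {"g1", "g2"}


class TestFolderIO:
    def test_round_trip_and_malformed(self, tmp_path):
        import pandas as pd

        d = tmp_path / "boot"
        d.mkdir()
        for i in range(3):
            pd.DataFrame({"gene_id": ["g1", "g2"], "fpkm": [1.0 * i, 2.0]}).to_csv(
                d / f"b{i}.tsv", sep="\t", index=False
            )
        folder = load_bootstrap_folder(d)
        assert folder.m == 3
        assert folder.estimates[2]["g1"] == 2.0
        (d / "bad.tsv").write_text("not\ta\tvalid\theader\n1\t2\t3\t4\n")
        with pytest.raises(ValueError, match="bad.tsv"):
            load_bootstrap_folder(d)


class TestNullCalibrationMatching:
    def test_matching_type_i_error_controlled(self):
        """Under the null, matching pairing with the binomial threshold
        keeps the DE-call rate near alpha: the M indicators a_i >= b_i are
        genuinely independent Bernoulli(1/2) there."""
        rng = np.random.default_rng(9)
        n_genes, m, reps = 100, 20, 10
        called = total = 0
        cfg = DEConfig(min_fold=1.0, alpha=0.05, pairing="matching")
        for _ in range(reps):
            means = {f"g{i}": 10.0 for i in range(n_genes)}
            a = gaussian_folder(rng, means, m, sd=0.1)
            b = gaussian_folder(rng, means, m, sd=0.1)
            calls = run_isode([a], [b], cfg, seed=int(rng.integers(2**31)))
            called += sum(c.status != "non-DE" for c in calls)
            total += len(calls)
        rate = called / total
        mc_se = math.sqrt(0.05 * 0.95 / total)
        assert rate <= 0.05 + 3 * mc_se
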