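import math

import numpy as np
import pytest

from acetylstoich import dynamics as dyn
from acetylstoich.io import ProteinQuant, TmtRecord
from oracles import hypergeom_tail, permutation_t_p, rank_sum_p_exact


class TestCorrectedRatios:
    @pytest.mark.parametrize("site, prot, expected", [(6, 2, 3), (5, 1, 5), (2, 2, 1)])
    def test_division_in_linear_space(self, site, prot, expected):
        assert dyn.correct_site_ratio(site, prot) == pytest.approx(expected)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            dyn.correct_site_ratio(1.0, 0.0)


class TestExclusiveLocalization:
    @pytest.mark.parametrize(
        "locs, expected",
        [
            ({"mitochondrion"}, "mitochondrion"),
            ({"mitochondrion", "nucleus"}, None),
            (set(), None),
            ({"other"}, None),
        ],
    )
    def test_definition(self, locs, expected):
        prot = ProteinQuant("P1", 1.0, localizations=frozenset(locs))
        assert dyn.exclusive_localization(prot) == expected


class TestWilcoxon:
    def test_identical_samples_give_p_one(self):
        assert dyn.wilcoxon_rank_sum([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_fully_separated_small_samples(self):
        assert dyn.wilcoxon_rank_sum([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_symmetry_in_arguments(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=12).tolist(), rng.normal(1.0, size=9).tolist()
        assert dyn.wilcoxon_rank_sum(a, b) == pytest.approx(dyn.wilcoxon_rank_sum(b, a))

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            dyn.wilcoxon_rank_sum([], [1.0])

    @pytest.mark.parametrize("n_a, n_b, seed", [(3, 5, 0), (4, 4, 1), (6, 2, 2), (8, 8, 3)])
    def test_exact_path_matches_enumeration_oracle(self, n_a, n_b, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=n_a).tolist()
        b = rng.normal(0.8, size=n_b).tolist()
        assert dyn.wilcoxon_rank_sum(a, b) == pytest.approx(rank_sum_p_exact(a, b))

    def test_approximation_close_to_enumeration_for_ties(self):
        # integer data forces midranks and the asymptotic path
        rng = np.random.default_rng(5)
        a = rng.integers(0, 4, size=8).tolist()
        b = rng.integers(1, 5, size=8).tolist()
        assert dyn.wilcoxon_rank_sum(a, b) == pytest.approx(rank_sum_p_exact(a, b), abs=0.02)


class TestFisher:
    def test_certain_event(self):
        assert dyn.fisher_enrichment(3, 3, 10, 10) == pytest.approx(1.0)

    def test_all_selected_carry_rare_term(self):
        assert dyn.fisher_enrichment(3, 3, 3, 10) == pytest.approx(1 / 120)

    def test_zero_overlap_gives_one(self):
        assert dyn.fisher_enrichment(0, 5, 3, 20) == pytest.approx(1.0)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            dyn.fisher_enrichment(4, 3, 5, 10)

    def test_matches_brute_force_on_small_universe(self):
        for N in (5, 12, 30):
            for n in (1, N // 2, N - 1):
                for K in (1, N // 3 + 1, N):
                    for k in range(max(0, n + K - N), min(n, K) + 1):
                        assert dyn.fisher_enrichment(k, n, K, N) == pytest.approx(
                            hypergeom_tail(k, n, K, N), rel=1e-9, abs=1e-12
                        )

    def test_term_enrichment_table(self):
        annotations = {f"P{i}": frozenset({"T1"} if i < 4 else {"T2"}) for i in range(10)}
        table = dyn.term_enrichment({"P0", "P1", "P2"}, {f"P{i}" for i in range(10)}, annotations)
        row = table.set_index("term").loc["T1"]
        assert (row["k"], row["n"], row["K"], row["N"]) == (3, 3, 4, 10)
        assert set(table.columns) >= {"p", "p_bh"}


class TestSimpleSummaries:
    def test_fraction_above(self):
        assert dyn.fraction_above([5, 15, 25], 10) == pytest.approx(2 / 3)
        assert dyn.fraction_above([5, 15, 25], 0) == 1.0
        assert dyn.fraction_above([5, 15, 25], math.inf) == 0.0

    def test_cp_abundance_check(self):
        out = dyn.cp_abundance_check([0.9, 1.0, 1.1, 0.3])
        assert out["median"] == pytest.approx(0.95)
        assert out["fraction_within_2fold"] == pytest.approx(0.75)
        assert dyn.cp_abundance_check([1.0, 1.0]) == {
            "median": 1.0,
            "fraction_within_2fold": 1.0,
        }
        with pytest.raises(ValueError):
            dyn.cp_abundance_check([])


class TestTmt:
    def make(self, purity):
        return TmtRecord("PEP", True, (1.0, 2.0), purity)

    def test_purity_filter_inclusive_at_threshold(self):
        records = [self.make(0.95), self.make(0.90), self.make(0.85)]
        kept = dyn.tmt_purity_filter(records)
        assert [r.parent_purity for r in kept] == [0.95, 0.90]
        assert kept[0] is records[0]  # membership changes, contents never do

    def test_identical_groups(self):
        out = dyn.tmt_relative_abundance([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert out.ratio == pytest.approx(1.0)
        assert out.p_value == pytest.approx(1.0)

    def test_zero_variance_groups_flagged(self):
        out = dyn.tmt_relative_abundance([2.0, 2.0, 2.0], [1.0, 1.0, 1.0])
        assert out.ratio == pytest.approx(2.0)
        assert out.degenerate and out.p_value == 0.0

    def test_single_replicate_has_no_p_value(self):
        out = dyn.tmt_relative_abundance([2.0], [1.0, 1.5])
        assert out.p_value is None

    def test_t_test_close_to_permutation_oracle(self):
        rng = np.random.default_rng(11)
        a = rng.normal(1.0, 0.3, size=4).tolist()
        b = rng.normal(2.0, 0.3, size=4).tolist()
        out = dyn.tmt_relative_abundance(a, b)
        assert out.p_value == pytest.approx(permutation_t_p(a, b), abs=0.05)


class TestPools:
    def test_cit1_fold_change(self):
        pools = dyn.AcetylCoAPools(total_wt=3.0, total_pda1=2.0, total_cit1=3.9)
        assert dyn.mito_pool_fold_change(pools) == pytest.approx(1.9)

    def test_unchanged_total_gives_unity(self):
        pools = dyn.AcetylCoAPools(total_wt=3.0, total_pda1=2.0, total_cit1=3.0)
        assert dyn.mito_pool_fold_change(pools) == pytest.approx(1.0)

    def test_pda1_above_wt_rejected(self):
        pools = dyn.AcetylCoAPools(total_wt=2.0, total_pda1=2.5, total_cit1=3.0)
        with pytest.raises(ValueError):
            dyn.mito_pool_fold_change(pools)

    @pytest.mark.parametrize(
        "pool, volume, expected",
        [(1 / 3, 0.02, 24.5), (1 / 3, 0.015, 32.83), (0.25, 0.25, 1.0)],
    )
    def test_concentration_fold(self, pool, volume, expected):
        assert dyn.compartment_concentration_fold(pool, volume) == pytest.approx(
            expected, rel=1e-3
        )

    def test_concentration_fold_increasing_in_pool_fraction(self):
        folds = [dyn.compartment_concentration_fold(p, 0.02) for p in (0.1, 0.3, 0.5, 0.9)]
        assert folds == sorted(folds)


class TestCompartmentSummaries:
    def proteins(self):
        return [
            ProteinQuant("M1", 1.0, localizations=frozenset({"mitochondrion"})),
            ProteinQuant("C1", 1.0, localizations=frozenset({"cytoplasm"})),
            ProteinQuant("D1", 1.0, localizations=frozenset({"cytoplasm", "nucleus"})),
        ]

    def test_single_compartment_medians(self):
        ratios = [("M1", 2.0), ("M1", 4.0), ("M1", 8.0)]
        (summary,) = dyn.compartment_summaries(ratios, self.proteins())
        assert summary.median_linear_ratio == pytest.approx(4.0)
        assert summary.median_log2_ratio == pytest.approx(2.0)
        assert summary.p_vs_reference is None  # no reference sites

    def test_identical_compartments_give_p_one(self):
        ratios = [("M1", r) for r in (2.0, 4.0)] + [("C1", r) for r in (2.0, 4.0)]
        summaries = {s.compartment: s for s in dyn.compartment_summaries(ratios, self.proteins())}
        assert summaries["mitochondrion"].p_vs_reference == pytest.approx(1.0)

    def test_multi_localized_proteins_excluded(self):
        ratios = [("D1", 2.0), ("C1", 3.0)]
        summaries = dyn.compartment_summaries(ratios, self.proteins())
        assert [s.compartment for s in summaries] == ["cytoplasm"]
        assert summaries[0].n_sites == 1

    def test_simulated_shift_recovered(self):
        rng = np.random.default_rng(4)
        ratios = [("C1", float(r)) for r in 2 ** rng.normal(1.0, 0.5, size=120)]
        ratios += [("M1", float(r)) for r in 2 ** rng.normal(3.0, 0.5, size=120)]
        summaries = {s.compartment: s for s in dyn.compartment_summaries(ratios, self.proteins())}
        shift = (
            summaries["mitochondrion"].median_log2_ratio
            - summaries["cytoplasm"].median_log2_ratio
        )
        assert shift == pytest.approx(2.0, abs=0.3)
        assert summaries["mitochondrion"].p_vs_reference < 1e-6

    def test_linear_median_is_two_to_the_log2_median(self, dataset):
        corrected = [
            (s.protein_id, s.silac_ratio) for s in dataset.sites if s.silac_ratio is not None
        ]
        for summary in dyn.compartment_summaries(corrected, dataset.proteins):
            assert 2 ** summary.median_log2_ratio == pytest.approx(summary.median_linear_ratio)
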