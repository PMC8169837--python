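"""ssGSEA scoring against an independent oracle, empirical null, subtype calls,
meta-module scores."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from gliotraj.iokit import ModuleLibrary
from gliotraj.preprocess import NormalizedMatrix
from gliotraj.scoring import (
    SubtypeClassifier,
    build_empirical_null,
    classify_subtype,
    dominant_module_test,
    empirical_pvalue,
    meta_module_score,
    module_score_table,
    scaled_module_heatmap_scores,
    ssgsea_score,
)
from gliotraj.synthdata import (
    SimulationDesign,
    make_subtype_fixture,
    make_subtype_library,
    simulate_timeseries_counts,
)


def oracle_ssgsea(profile: pd.Series, gene_set, tau: float) -> float:
    """Literal double-loop direct summation of the running-sum definition.

    Independent of the package implementation: positions from an explicit
    sort, P_hit/P_miss accumulated per position in pure Python.
    """
    items = sorted(profile.items(), key=lambda kv: (-kv[1], kv[0]))
    genes = [g for g, _ in items]
    n = len(genes)
    in_set = set(gene_set) & set(genes)
    m = len(in_set)
    weights = {g: (n - pos) ** tau for pos, g in enumerate(genes) if g in in_set}
    w_total = sum(weights.values())
    es = 0.0
    hit = 0.0
    miss = 0
    for pos, g in enumerate(genes):
        if g in in_set:
            hit += weights[g]
        else:
            miss += 1
        es += hit / w_total - miss / (n - m)
    return es


def random_instance(rng):
    n = int(rng.integers(5, 51))
    values = rng.normal(size=n)
    genes = [f"g{i}" for i in range(n)]
    profile = pd.Series(values, index=genes)
    m = int(rng.integers(1, n))
    gene_set = list(rng.choice(genes, size=m, replace=False))
    return profile, gene_set


class TestSsgseaScore:
    def test_single_top_gene_hand_value(self):
        """N=4, S = top gene: ES = 1 + 2/3 + 1/3 + 0 = 2 for any tau."""
        profile = pd.Series([4.0, 3.0, 2.0, 1.0], index=list("ABCD"))
        for tau in (0.0, 0.25, 1.0):
            assert ssgsea_score(profile, ["A"], tau) == pytest.approx(2.0, abs=1e-12)

    def test_positions_one_and_three_hand_value(self):
        """N=5, S at ranked positions {1,3}, tau=0: ES = 5/3 by direct summation."""
        profile = pd.Series([5.0, 4.0, 3.0, 2.0, 1.0], index=list("ABCDE"))
        assert ssgsea_score(profile, ["A", "C"], 0.0) == pytest.approx(5 / 3, abs=1e-12)

    def test_matches_direct_summation_oracle(self):
        rng = np.random.default_rng(2024)
        worst = 0.0
        for _ in range(200):
            profile, gene_set = random_instance(rng)
            tau = float(rng.choice([0.0, 0.25, 1.0]))
            diff = abs(ssgsea_score(profile, gene_set, tau) - oracle_ssgsea(profile, gene_set, tau))
            worst = max(worst, diff)
        assert worst < 1e-9

    def test_promoting_in_set_gene_never_decreases_score(self):
        """Swapping an in-set gene above an adjacent out-of-set gene raises ES."""
        rng = np.random.default_rng(7)
        checked = 0
        while checked < 100:
            profile, gene_set = random_instance(rng)
            ordered = profile.sort_index(kind="stable").sort_values(ascending=False, kind="stable")
            in_set = set(gene_set)
            pos = next(
                (p for p in range(1, len(ordered))
                 if ordered.index[p] in in_set and ordered.index[p - 1] not in in_set),
                None,
            )
            if pos is None:
                continue
            tau = float(rng.choice([0.0, 0.25, 1.0]))
            before = ssgsea_score(profile, gene_set, tau)
            swapped = profile.copy()
            up, down = ordered.index[pos], ordered.index[pos - 1]
            swapped[up], swapped[down] = ordered.iloc[pos - 1] + 1e-9, ordered.iloc[pos]
            after = ssgsea_score(swapped, gene_set, tau)
            assert after >= before - 1e-12
            checked += 1

    def test_degenerate_sets_rejected(self):
        profile = pd.Series([2.0, 1.0], index=["a", "b"])
        with pytest.raises(ValueError):
            ssgsea_score(profile, ["absent"], 0.25)
        with pytest.raises(ValueError):
            ssgsea_score(profile, ["a", "b"], 0.25)


class TestEmpiricalNull:
    def test_deterministic_given_seed(self):
        profile = pd.Series(np.random.default_rng(0).normal(size=40),
                            index=[f"g{i}" for i in range(40)])
        a = build_empirical_null(profile, 5, n_draws=3, seed=9)
        b = build_empirical_null(profile, 5, n_draws=3, seed=9)
        np.testing.assert_array_equal(a, b)

    def test_null_values_are_genuine_scores(self):
        """Closed-form null draws live inside the range of explicit random-set scores."""
        rng = np.random.default_rng(3)
        profile = pd.Series(rng.normal(size=30), index=[f"g{i}" for i in range(30)])
        null = build_empirical_null(profile, 6, n_draws=500, seed=1)
        direct = [
            oracle_ssgsea(profile, list(rng.choice(profile.index, 6, replace=False)), 0.25)
            for _ in range(300)
        ]
        # same distribution: two-sample KS should not reject wildly
        assert stats.ks_2samp(null, direct).pvalue > 1e-3

    def test_set_size_bounds(self):
        profile = pd.Series([3.0, 2.0, 1.0], index=list("abc"))
        with pytest.raises(ValueError):
            build_empirical_null(profile, 3, n_draws=5)
        with pytest.raises(ValueError):
            build_empirical_null(profile, 0, n_draws=5)

    def test_null_pvalues_uniform(self):
        """p of a random true set is uniform on (0,1): the calibration property."""
        rng = np.random.default_rng(12)
        profile = pd.Series(rng.normal(size=300), index=[f"g{i}" for i in range(300)])
        ps = []
        for rep in range(200):
            genes = list(rng.choice(profile.index, 20, replace=False))
            es = ssgsea_score(profile, genes, 0.25)
            null = build_empirical_null(profile, 20, n_draws=500, tau=0.25, seed=rep)
            ps.append(empirical_pvalue(es, null))
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestEmpiricalPvalue:
    def test_boundaries_and_median(self):
        null = np.arange(999, dtype=float)
        assert empirical_pvalue(1e9, null) == pytest.approx(1 / 1000)
        assert empirical_pvalue(-1e9, null) == 1.0
        assert empirical_pvalue(499.0, null) == pytest.approx(0.5, abs=0.01)

    def test_empty_null_rejected(self):
        with pytest.raises(ValueError):
            empirical_pvalue(0.0, np.array([]))


class TestClassifySubtype:
    def test_recovers_programmed_subtypes(self):
        lib = make_subtype_library()
        expr, truth = make_subtype_fixture(lib, 8, effect=2.0, seed=5)
        clf = SubtypeClassifier(signatures=lib, n_draws=2_000, random_state=5).fit()
        pred = clf.predict(expr.T)
        assert (pred == np.array(truth)).mean() >= 0.95

    def test_identical_signatures_tie_break_and_flag(self):
        lib = ModuleLibrary(sets={"B_sig": ["g0", "g1"], "A_sig": ["g0", "g1"]})
        profile = pd.Series(np.linspace(5, 1, 20), index=[f"g{i}" for i in range(20)])
        call = classify_subtype(profile, lib, n_draws=200, seed=0)
        assert call.subtype == "A_sig"  # lexicographic among identical evidence
        assert call.ambiguous

    def test_deterministic_including_margin(self):
        lib = make_subtype_library()
        expr, _ = make_subtype_fixture(lib, 2, effect=1.0, seed=6)
        a = classify_subtype(expr.iloc[:, 0], lib, n_draws=500, seed=3)
        b = classify_subtype(expr.iloc[:, 0], lib, n_draws=500, seed=3)
        assert a.subtype == b.subtype and a.margin == b.margin
        assert a.results[0].p_emp == b.results[0].p_emp


class TestMetaModuleScore:
    def test_singleton_and_pair_means(self):
        norm = NormalizedMatrix(
            values=np.array([[1.0, 2.0], [3.0, 4.0]]),
            gene_ids=["a", "b"], unit_ids=["u", "v"], scale=1.0,
        )
        np.testing.assert_allclose(meta_module_score(norm, ["a"]), [1.0, 2.0])
        np.testing.assert_allclose(meta_module_score(norm, ["a", "b"]), [2.0, 3.0])

    def test_empty_intersection_rejected(self):
        norm = NormalizedMatrix(values=np.ones((1, 1)), gene_ids=["a"],
                                unit_ids=["u"], scale=1.0)
        with pytest.raises(ValueError):
            meta_module_score(norm, ["zz"])

    def test_programmed_population_ranks_top_every_seed(self):
        from gliotraj.preprocess import normalize
        for seed in range(5):
            design = SimulationDesign(n_cells_per_stage=150, seed=seed)
            counts, meta, lib = simulate_timeseries_counts(design)
            norm = normalize(counts)
            score = meta_module_score(norm, lib["AC"])
            by_pop = pd.Series(score).groupby(meta["population"].to_numpy()).mean()
            assert by_pop.idxmax() == "AC"


class TestScaledHeatmapScores:
    def test_two_group_z_values(self):
        table = pd.DataFrame({"mod": [1.0, 1.0, 3.0, 3.0]}, index=list("abcd"))
        scaled = scaled_module_heatmap_scores(table, ["g1", "g1", "g2", "g2"])
        np.testing.assert_allclose(
            scaled["mod"].to_numpy(), [-1 / np.sqrt(2), 1 / np.sqrt(2)], rtol=1e-12
        )

    def test_identical_means_scale_to_zero(self):
        table = pd.DataFrame({"mod": [2.0, 2.0]}, index=list("ab"))
        scaled = scaled_module_heatmap_scores(table, ["g1", "g2"])
        np.testing.assert_array_equal(scaled["mod"].to_numpy(), [0.0, 0.0])

    def test_shift_invariance(self):
        rng = np.random.default_rng(0)
        table = pd.DataFrame({"m1": rng.normal(size=30), "m2": rng.normal(size=30)})
        labels = ["g1"] * 10 + ["g2"] * 10 + ["g3"] * 10
        shifted = table.copy()
        shifted["m1"] = shifted["m1"] + 100.0
        pd.testing.assert_frame_equal(
            scaled_module_heatmap_scores(table, labels),
            scaled_module_heatmap_scores(shifted, labels),
        )

    def test_single_group_rejected(self):
        table = pd.DataFrame({"m": [1.0, 2.0]})
        with pytest.raises(ValueError):
            scaled_module_heatmap_scores(table, ["g1", "g1"])


class TestDominantModule:
    def test_constant_margin_gives_minimal_p(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=30)
        table = pd.DataFrame({"top": base + 1.0, "second": base})
        res = dominant_module_test(table)
        assert res.top_module == "top"
        # fully concordant pairs: p at the floor of the signed-rank test for n=30
        assert res.p_value < 1e-5

    def test_null_type_i_error_calibrated(self):
        rng = np.random.default_rng(99)
        hits = 0
        n_runs = 1_000
        for _ in range(n_runs):
            table = pd.DataFrame(rng.normal(size=(40, 2)), columns=["m1", "m2"])
            if dominant_module_test(table).significant:
                hits += 1
        # expect ~1% at alpha 0.01; allow generous binomial slack
        assert hits / n_runs < 0.03

    def test_programmed_fate_switch_sequence(self, small_timeseries):
        from gliotraj.preprocess import normalize
        counts, meta, lib = small_timeseries
        norm = normalize(counts)
        modules = [m for m in lib.names() if m not in ("G1S", "G2M")]
        table = module_score_table(norm, lib, modules)
        expected = {"T0": "NSC_cc", "T1": "NB_Neuron", "T2": "AC", "End": "OPC"}
        nsc = (meta["population"] == "NSC_cc").to_numpy()
        for stage, want in expected.items():
            sel = np.flatnonzero(nsc & (meta["stage"] == stage).to_numpy())
            res = dominant_module_test(table.iloc[sel])
            assert res.top_module == want and res.significant

    def test_too_few_cells_rejected(self):
        table = pd.DataFrame({"m1": [1.0] * 5, "m2": [0.0] * 5})
        with pytest.raises(ValueError, match="6"):
            dominant_module_test(table)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_ssgsea_oracle_property(seed):
    """Implementation equals the direct-summation oracle on arbitrary instances."""
    rng = np.random.default_rng(seed)
    profile, gene_set = random_instance(rng)
    tau = float(rng.choice([0.0, 0.25, 1.0]))
    assert ssgsea_score(profile, gene_set, tau) == pytest.approx(
        oracle_ssgsea(profile, gene_set, tau), abs=1e-9
    )
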