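"""Fleiss' kappa: examples, oracle equivalence and invariances."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from jemforge import (
    DegenerateMarginError,
    UnequalRaterCountError,
    bootstrap_kappa_ci,
    count_disagreements_by_group,
    fleiss_kappa,
    make_panel,
)
from jemforge.synthetic import SimulationConfig, simulate_raters, simulate_truth

from oracles import fleiss_kappa_pairwise


def panel_of(rows, items=None):
    df = pd.DataFrame(rows, columns=[f"r{j}" for j in range(1, len(rows[0]) + 1)])
    df.index = items if items is not None else [f"{1000 + i}" for i in range(len(rows))]
    return df


@st.composite
def random_panels(draw):
    n_items = draw(st.integers(2, 12))
    n_raters = draw(st.integers(2, 4))
    n_cats = draw(st.integers(2, 4))
    rows = draw(
        st.lists(
            st.lists(st.integers(0, n_cats - 1), min_size=n_raters, max_size=n_raters),
            min_size=n_items, max_size=n_items,
        )
    )
    return panel_of(rows)


class TestFleissKappaExamples:
    def test_perfect_agreement_gives_kappa_one(self):
        panel = panel_of([[0, 0, 0], [1, 1, 1], [0, 0, 0], [1, 1, 1]])
        res = fleiss_kappa(panel)
        assert res.kappa == 1.0
        assert res.observed_agreement == 1.0
        assert res.disagreement_codes == frozenset()

    def test_balanced_two_rater_example_gives_kappa_zero(self):
        # (0,0),(0,1),(1,0),(1,1): observed = expected = 0.5 by hand
        panel = panel_of([[0, 0], [0, 1], [1, 0], [1, 1]])
        res = fleiss_kappa(panel)
        assert res.observed_agreement == pytest.approx(0.5)
        assert res.expected_agreement == pytest.approx(0.5)
        assert res.kappa == pytest.approx(0.0)

    def test_disagreement_codes_are_items_with_two_levels(self):
        panel = panel_of([[0, 0, 0], [0, 1, 0], [1, 1, 0]], items=["2211", "2212", "5111"])
        res = fleiss_kappa(panel)
        assert res.disagreement_codes == {"2212", "5111"}

    def test_degenerate_margin_with_perfect_agreement_is_kappa_one(self):
        # all assignments in one category forces observed agreement 1 as
        # well, so the only reachable degenerate case is kappa = 1
        panel = panel_of([[1, 1], [1, 1]])
        assert fleiss_kappa(panel).kappa == 1.0

    def test_missing_items_dropped_and_counted(self):
        panel = panel_of([[0, 0], [0, None], [1, 1]]).astype("Float64")
        res = fleiss_kappa(panel)
        assert res.n_excluded == 1
        assert res.n_items == 2

    def test_missing_items_raise_when_asked(self):
        panel = panel_of([[0, 0], [0, None]]).astype("Float64")
        with pytest.raises(UnequalRaterCountError):
            fleiss_kappa(panel, on_missing="raise")

    def test_categories_must_cover_observed_levels(self):
        panel = panel_of([[0, 2], [1, 1]])
        with pytest.raises(ValueError, match="cover"):
            fleiss_kappa(panel, categories=(0, 1))


class TestOracleEquivalence:
    @settings(max_examples=300, derandomize=True, deadline=None)
    @given(random_panels())
    def test_matches_pairwise_enumeration_oracle(self, panel):
        flat = panel.to_numpy().ravel()
        if len(set(flat)) == 1:
            return  # degenerate-by-construction: perfect one-category panel
        res = fleiss_kappa(panel)
        kappa, p_bar, p_e = fleiss_kappa_pairwise(panel)
        assert res.kappa == pytest.approx(kappa, abs=1e-12)
        assert res.observed_agreement == pytest.approx(p_bar, abs=1e-12)
        assert res.expected_agreement == pytest.approx(p_e, abs=1e-12)

    def test_matches_statsmodels_on_a_random_panel(self):
        from statsmodels.stats.inter_rater import aggregate_raters
        from statsmodels.stats.inter_rater import fleiss_kappa as sm_fleiss

        rng = np.random.default_rng(5)
        panel = panel_of(rng.integers(0, 3, size=(30, 4)).tolist())
        counts, _ = aggregate_raters(panel.to_numpy())
        assert fleiss_kappa(panel).kappa == pytest.approx(sm_fleiss(counts), abs=1e-12)


class TestInvariances:
    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(random_panels(), st.randoms(use_true_random=False))
    def test_permutation_of_items_raters_and_labels(self, panel, rnd):
        flat = panel.to_numpy().ravel()
        if len(set(flat)) == 1:
            return
        base = fleiss_kappa(panel).kappa

        items = list(panel.index)
        rnd.shuffle(items)
        assert fleiss_kappa(panel.loc[items]).kappa == pytest.approx(base, abs=1e-12)

        raters = list(panel.columns)
        rnd.shuffle(raters)
        assert fleiss_kappa(panel[raters]).kappa == pytest.approx(base, abs=1e-12)

        labels = sorted(set(int(v) for v in flat))
        shuffled = labels[:]
        rnd.shuffle(shuffled)
        relabel = dict(zip(labels, shuffled))
        relabelled = panel.map(lambda v: relabel[int(v)])
        assert fleiss_kappa(relabelled).kappa == pytest.approx(base, abs=1e-12)

    def test_kappa_is_one_iff_all_raters_agree(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            panel = panel_of(rng.integers(0, 2, size=(8, 3)).tolist())
            res = fleiss_kappa(panel)
            all_agree = (panel.nunique(axis=1) == 1).all()
            assert (res.kappa == 1.0) == bool(all_agree)


class TestMonotoneDegradation:
    def test_mean_kappa_decreases_with_rater_error(self):
        """More rater noise -> lower chance-corrected agreement on average."""
        error_rates = [0.0, 0.1, 0.3, 0.5]
        means = []
        for eps in error_rates:
            kappas = []
            for rep in range(200):
                cfg = SimulationConfig(
                    n_codes=30, n_groups=3, rater_error=eps, seed=1000 + rep
                )
                _, truth = simulate_truth(cfg)
                ratings = simulate_raters(truth, cfg)
                try:
                    kappas.append(fleiss_kappa(make_panel(ratings)).kappa)
                except DegenerateMarginError:
                    continue
            means.append(np.mean(kappas))
        assert means[0] == pytest.approx(1.0)
        assert means[0] > means[1] > means[2] > means[3]


class TestDisagreementLocalization:
    def make_universe(self):
        codes = [f"51{k:02d}" for k in range(1, 6)] + [f"22{k:02d}" for k in range(1, 5)]
        return pd.DataFrame({"code4": codes})

    def test_no_disagreement_gives_all_zero(self):
        res = fleiss_kappa(panel_of([[0, 0]] * 3 + [[1, 1]], items=["5101", "5102", "5103", "2201"]))
        out = count_disagreements_by_group(res, self.make_universe())
        assert (out["n_disagreeing"] == 0).all()

    def test_whole_group_disagreeing_maps_to_full_fraction(self):
        # all 5 codes of the agricultural group disagree -> 5/5
        items = [f"51{k:02d}" for k in range(1, 6)]
        res = fleiss_kappa(panel_of([[0, 1, 0]] * 5, items=items))
        out = count_disagreements_by_group(res, self.make_universe()).set_index("code2")
        assert out.loc["51", "n_disagreeing"] == 5
        assert out.loc["51", "n_total"] == 5
        assert out.loc["51", "fraction"] == 1.0
        assert out.loc["22", "n_disagreeing"] == 0

    def test_numerators_sum_to_total_disagreements(self):
        items = ["5101", "5102", "2201"]
        res = fleiss_kappa(panel_of([[0, 1], [0, 1], [1, 0]], items=items))
        out = count_disagreements_by_group(res, self.make_universe())
        assert out["n_disagreeing"].sum() == len(res.disagreement_codes) == 3

    def test_unknown_code_is_an_error_naming_it(self):
        res = fleiss_kappa(panel_of([[0, 1]], items=["9999"]))
        with pytest.raises(KeyError, match="9999"):
            count_disagreements_by_group(res, self.make_universe())


class TestPanelConstruction:
    def test_conditional_axes_need_explicit_opt_in(self, ratings_factory):
        table = ratings_factory([("r1", "1101", 2, 1, 2, 2)])
        with pytest.raises(ValueError, match="allow_conditional_axes"):
            make_panel(table, axis="frequency")

    def test_conditional_panel_restricted_to_complete_items(self, ratings_factory):
        table = ratings_factory([
            ("r1", "1101", 2, 1, 2, 2),
            ("r2", "1101", 2, 1, 3, 2),
            ("r1", "1102", 2, 1, 4, 3),
            ("r2", "1102", 2, 0, None, None),
        ])
        panel = make_panel(table, axis="frequency", allow_conditional_axes=True)
        assert list(panel.index) == ["1101"]


class TestBootstrapCI:
    def test_ci_brackets_kappa_and_is_seed_deterministic(self):
        rng = np.random.default_rng(3)
        panel = panel_of(rng.integers(0, 2, size=(40, 3)).tolist())
        kappa = fleiss_kappa(panel).kappa
        lo1, hi1 = bootstrap_kappa_ci(panel, n_boot=200, seed=9)
        lo2, hi2 = bootstrap_kappa_ci(panel, n_boot=200, seed=9)
        assert (lo1, hi1) == (lo2, hi2)
        assert lo1 <= kappa <= hi1
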