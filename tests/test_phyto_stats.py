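"""ANOVA, Duncan letter display and Pearson matrix against oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from phytodiv.phyto_stats import (
    TraitTable,
    anova_oneway,
    duncan,
    pearson_matrix,
)


class TestAnova:
    def test_identical_groups_give_zero_f(self):
        res = anova_oneway({"a": [1, 1, 1], "b": [1, 1, 1]})
        assert res.F == 0.0 and res.p == 1.0

    def test_separated_groups_with_jitter(self):
        eps = 1e-4
        res = anova_oneway({"a": [0, eps, -eps], "b": [10, 10 + eps, 10 - eps]})
        assert res.p < 1e-6

    def test_matches_sum_of_squares_oracle(self):
        groups = {"a": [1.0, 2.0, 3.0], "b": [2.0, 4.0, 6.0], "c": [5.0, 5.5, 6.5]}
        res = anova_oneway(groups)
        f_ref, p_ref = stats.f_oneway(*groups.values())
        assert res.F == pytest.approx(f_ref, abs=1e-9)
        assert res.p == pytest.approx(p_ref, abs=1e-12)

    def test_single_value_group_rejected(self):
        with pytest.raises(ValueError):
            anova_oneway({"a": [1.0], "b": [1.0, 2.0]})

    @given(
        shift=st.floats(-100, 100, allow_nan=False),
        scale=st.floats(0.01, 50, allow_nan=False),
    )
    def test_f_invariant_to_shift_and_scale(self, shift, scale):
        groups = {"a": [1.0, 2.0, 2.5], "b": [3.0, 3.5, 5.0]}
        base = anova_oneway(groups).F
        moved = anova_oneway(
            {k: [scale * x + shift for x in v] for k, v in groups.items()}
        ).F
        assert moved == pytest.approx(base, rel=1e-8)


class TestDuncan:
    def test_identical_groups_share_one_letter(self):
        d = duncan({"a": [1, 1, 1.0], "b": [1, 1, 1.0]})
        assert set(d.letters.values()) == {"a"}

    def test_widely_separated_means_get_distinct_letters(self):
        d = duncan(
            {"lo": [-0.1, 0.0, 0.1], "mid": [49.9, 50.0, 50.1],
             "hi": [99.9, 100.0, 100.1]}
        )
        assert d.letters["hi"] == "a"
        assert d.letters["mid"] == "b"
        assert d.letters["lo"] == "c"

    def test_overlap_case_gives_a_ab_b(self):
        """Adjacent pairs n.s. but extremes differ: letters a / ab / b.

        With n=3, MSE=1 (df=6): R2 = q(.05,2,6)·sqrt(1/3) ≈ 1.998 and
        R3 ≈ 2.071; gaps of 1.6 are below R2 while the extreme gap 3.2
        exceeds R3.
        """
        d = duncan(
            {"low": [-1.0, 0.0, 1.0], "mid": [0.6, 1.6, 2.6],
             "high": [2.2, 3.2, 4.2]}
        )
        assert d.letters == {"high": "a", "mid": "ab", "low": "b"}

    def test_letter_ranges_match_studentized_range_quantiles(self):
        groups = {"g1": [10.0, 11.0, 12.0], "g2": [12.5, 13.5, 14.5],
                  "g3": [15.5, 16.5, 17.5]}
        res = anova_oneway(groups)
        se = np.sqrt(res.ms_error / 3)
        r2 = stats.studentized_range.ppf(0.95, 2, res.df_within) * se
        r3 = stats.studentized_range.ppf((1 - 0.05) ** 2, 3, res.df_within) * se
        means = sorted((np.mean(v) for v in groups.values()), reverse=True)
        d = duncan(groups)
        # oracle: apply the range tests directly
        extremes_sig = means[0] - means[2] > r3
        adj_sig = [means[0] - means[1] > r2, means[1] - means[2] > r2]
        shared_01 = set(d.letters["g3"]) & set(d.letters["g2"])
        shared_12 = set(d.letters["g2"]) & set(d.letters["g1"])
        assert bool(shared_01) == (not adj_sig[0])
        assert bool(shared_12) == (not adj_sig[1])
        assert (set(d.letters["g3"]) & set(d.letters["g1"]) == set()) == extremes_sig

    def test_alpha_validation(self):
        with pytest.raises(ValueError):
            duncan({"a": [1, 2.0], "b": [2, 3.0]}, alpha=1.5)

    def test_unequal_replicates_warn_and_use_harmonic_n(self):
        with pytest.warns(UserWarning, match="harmonic"):
            duncan({"a": [1.0, 2.0], "b": [2.0, 3.0, 4.0]})

    def test_shared_letters_are_transitively_consistent(self, rng):
        for _ in range(20):
            groups = {
                f"g{i}": rng.normal(loc=rng.uniform(0, 6), scale=1.0, size=4)
                for i in range(5)
            }
            d = duncan(groups)
            res = anova_oneway(groups)
            se = np.sqrt(res.ms_error / 4)
            order = sorted(d.means, key=lambda k: -d.means[k])
            for letter in set("".join(d.letters.values())):
                members = [i for i, acc in enumerate(order)
                           if letter in d.letters[acc]]
                i, j = min(members), max(members)
                k = j - i + 1
                if k < 2:
                    continue
                alpha_k = 1 - 0.95 ** (k - 1)
                rk = stats.studentized_range.ppf(
                    1 - alpha_k, k, res.df_within) * se
                assert d.means[order[i]] - d.means[order[j]] <= rk + 1e-9


class TestPearson:
    @staticmethod
    def _table(values: dict[str, dict[str, list[float]]]) -> TraitTable:
        rows = []
        for trait, per_acc in values.items():
            for acc, reps in per_acc.items():
                for r, v in enumerate(reps, 1):
                    rows.append({"accession": acc, "trait": trait,
                                 "replicate": r, "value": v})
        return TraitTable(data=pd.DataFrame(rows))

    def test_perfectly_linear_traits(self):
        x = {"C1": [1.0], "C2": [2.0], "C3": [3.0], "C4": [4.0]}
        t = self._table({"x": x, "y2": {k: [2 * v[0]] for k, v in x.items()},
                         "neg": {k: [-v[0]] for k, v in x.items()}})
        corr = pearson_matrix(t, "mean_level")
        assert corr.loc["x", "y2"] == pytest.approx(1.0)
        assert corr.loc["x", "neg"] == pytest.approx(-1.0)

    def test_matches_textbook_formula_oracle(self):
        xs = [1.0, 2.0, 4.0, 5.5, 9.0]
        ys = [2.0, 1.0, 5.0, 4.0, 8.5]
        t = self._table(
            {"x": {f"A{i}": [v] for i, v in enumerate(xs)},
             "y": {f"A{i}": [v] for i, v in enumerate(ys)}}
        )
        corr = pearson_matrix(t, "mean_level")
        r_ref = stats.pearsonr(xs, ys).statistic
        assert corr.loc["x", "y"] == pytest.approx(r_ref, abs=1e-12)

    def test_zero_variance_trait_flagged_not_zeroed(self):
        t = self._table(
            {"x": {"C1": [1.0], "C2": [2.0], "C3": [3.0]},
             "flat": {"C1": [5.0], "C2": [5.0], "C3": [5.0]}}
        )
        with pytest.warns(UserWarning):
            corr = pearson_matrix(t, "mean_level")
        assert np.isnan(corr.loc["x", "flat"])

    def test_matrix_symmetric_positive_semidefinite(self, rng):
        data = rng.normal(size=(6, 4))
        t = self._table(
            {f"t{j}": {f"A{i}": [data[i, j]] for i in range(6)} for j in range(4)}
        )
        corr = pearson_matrix(t, "mean_level").to_numpy()
        assert np.allclose(corr, corr.T)
        assert np.linalg.eigvalsh(corr).min() > -1e-10

    def test_replicate_level_uses_paired_replicates(self, rng):
        rows = []
        base = {"C1": 1.0, "C2": 5.0, "C3": 9.0}
        for acc, mu in base.items():
            for r in range(1, 4):
                noise = rng.normal()
                rows.append({"accession": acc, "trait": "x", "replicate": r,
                             "value": mu + noise})
                rows.append({"accession": acc, "trait": "y", "replicate": r,
                             "value": 2 * mu + noise})
        t = TraitTable(data=pd.DataFrame(rows))
        corr = pearson_matrix(t, "replicate_level")
        assert corr.loc["x", "y"] > 0.9
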