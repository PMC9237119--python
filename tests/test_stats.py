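"""Group summaries, Tukey compact letter displays, two-way ANOVA, and the
Pearson/Bonferroni correlation screen."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from droughtmark import (anova_tukey, classify_strength, dual_letter_summary,
                         generate_measurements, pearson_bonferroni,
                         stage_accuracy_screen, summarize_groups,
                         two_way_anova)


def _frame(groups: dict) -> pd.DataFrame:
    rows = [(g, v) for g, vals in groups.items() for v in vals]
    return pd.DataFrame(rows, columns=["group", "value"])


class TestSummarizeGroups:
    def test_constant_group(self):
        out = summarize_groups(_frame({"a": [5.0] * 4}), ["group"])
        assert out.loc[0, "mean"] == 5.0 and out.loc[0, "se"] == 0.0

    def test_two_values_hand_computed(self):
        out = summarize_groups(_frame({"a": [1.0, 3.0]}), ["group"])
        assert out.loc[0, "mean"] == 2.0
        assert out.loc[0, "se"] == pytest.approx(1.0)  # sd=sqrt(2), /sqrt(2)

    def test_zero_noise_cell_recovers_printed_mean(self, design,
                                                   zero_noise_params):
        tab = generate_measurements(design, zero_noise_params)
        out = summarize_groups(
            tab[tab["marker"] == "SOD"],
            ["genotype", "treatment", "stage", "das"])
        row = out[(out["genotype"] == "MUNASQA") & (out["treatment"] == "stress")
                  & (out["stage"] == "V3") & (out["das"] == 4)]
        assert row["mean"].iloc[0] == pytest.approx(183.55)


def _letters_consistent(result, alpha=0.05):
    """Exhaustive pairwise oracle: sharing a letter <=> Tukey p > alpha."""
    names = list(result.letters)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            share = set(result.letters[a]) & set(result.letters[b])
            p = result.pairwise_p.loc[a, b]
            if share:
                assert p > alpha, (a, b, p, result.letters)
            else:
                assert p <= alpha, (a, b, p, result.letters)


class TestTukeyLetters:
    def test_identical_groups_share_letter_a(self):
        rng = np.random.default_rng(0)
        base = rng.normal(10, 1, 12)
        res = anova_tukey(_frame({g: base for g in "abcd"}), "group")
        assert set(res.letters.values()) == {"A"}

    def test_two_well_separated_groups(self):
        rng = np.random.default_rng(1)
        res = anova_tukey(_frame({"lo": rng.normal(0, 1, 10),
                                  "hi": rng.normal(10, 1, 10)}), "group")
        assert res.letters == {"lo": "A", "hi": "B"}
        _letters_consistent(res)

    def test_two_clusters_of_two(self):
        rng = np.random.default_rng(2)
        res = anova_tukey(_frame({
            "a": rng.normal(0, 0.2, 10), "b": rng.normal(0, 0.2, 10),
            "c": rng.normal(5, 0.2, 10), "d": rng.normal(5, 0.2, 10)}),
            "group")
        assert res.letters["a"] == res.letters["b"] == "A"
        assert res.letters["c"] == res.letters["d"] == "B"
        _letters_consistent(res)

    def test_lowercase_family(self):
        rng = np.random.default_rng(3)
        res = anova_tukey(_frame({"x": rng.normal(0, 1, 8),
                                  "y": rng.normal(8, 1, 8)}),
                          "group", uppercase=False)
        assert res.letters == {"x": "a", "y": "b"}

    def test_degenerate_zero_variance_warns(self):
        with pytest.warns(RuntimeWarning, match="zero within-group"):
            res = anova_tukey(_frame({"a": [1.0, 1.0], "b": [2.0, 2.0]}),
                              "group")
        assert res.letters["a"] != res.letters["b"]

    @pytest.mark.parametrize("seed", range(12))
    def test_letters_agree_with_pairwise_oracle(self, seed):
        """Random configurations of up to 6 groups: the compact display is
        checked against the exhaustive all-pairs Tukey oracle."""
        rng = np.random.default_rng(seed)
        k = rng.integers(3, 7)
        means = rng.uniform(0, 6, k)
        groups = {f"g{i}": rng.normal(means[i], 1.0, 8) for i in range(k)}
        res = anova_tukey(_frame(groups), "group")
        _letters_consistent(res)

    def test_letters_start_contiguous(self):
        rng = np.random.default_rng(5)
        groups = {f"g{i}": rng.normal(3 * i, 0.3, 8) for i in range(4)}
        res = anova_tukey(_frame(groups), "group")
        used = sorted(set("".join(res.letters.values())))
        assert used == list("ABCD"[: len(used)])


class TestDualLetterSummary:
    def test_families_are_cased_correctly(self, design, params):
        tab = generate_measurements(design, params)
        out = dual_letter_summary(tab[tab["marker"] == "SOD"])
        assert out["letter_col"].str.isupper().all()
        assert out["letter_row"].str.islower().all()
        # 4 groups x 2 stages x 3 DAS summary cells
        assert len(out) == 24


class TestTwoWayAnova:
    @staticmethod
    def _cells(rng, effect_g=0.0, effect_t=0.0, interaction=0.0, n=10):
        rows = []
        for gi, g in enumerate(("G1", "G2")):
            for ti, t in enumerate(("c", "s")):
                mu = gi * effect_g + ti * effect_t + gi * ti * interaction
                for v in rng.normal(mu, 1.0, n):
                    rows.append((g, t, v))
        return pd.DataFrame(rows, columns=["genotype", "treatment", "value"])

    def test_strong_genotype_effect_detected(self):
        hits = 0
        for seed in range(40):
            df = self._cells(np.random.default_rng(seed), effect_g=10.0)
            tab = two_way_anova(df).set_index("effect")
            if tab.loc["genotype", "p"] < 0.001:
                hits += 1
        assert hits == 40  # 10-SD effect: power is essentially 1

    def test_identical_cells_give_null_f(self):
        df = self._cells(np.random.default_rng(0))
        tab = two_way_anova(df).set_index("effect")
        assert (tab.loc[["genotype", "treatment", "genotype:treatment"], "p"]
                > 0.05).all()

    def test_interaction_type_one_error_calibrated(self):
        """Purely additive effects: the interaction test rejects at ~alpha
        (Monte-Carlo calibration, scaled to 200 seeds)."""
        rejections = 0
        n_seeds = 200
        for seed in range(n_seeds):
            df = self._cells(np.random.default_rng(1000 + seed),
                             effect_g=1.0, effect_t=1.0, n=5)
            tab = two_way_anova(df).set_index("effect")
            rejections += tab.loc["genotype:treatment", "p"] < 0.05
        rate = rejections / n_seeds
        se = np.sqrt(0.05 * 0.95 / n_seeds)
        assert abs(rate - 0.05) < 3 * se

    def test_missing_cell_rejected(self):
        df = self._cells(np.random.default_rng(0))
        df = df[~((df["genotype"] == "G2") & (df["treatment"] == "s"))]
        with pytest.raises(ValueError, match="missing cell"):
            two_way_anova(df)


class TestPearsonBonferroni:
    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        res = pearson_bonferroni(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)
        assert res.strength == "Strong"

    def test_orthogonalized_residuals_are_weak(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        y = rng.normal(size=50)
        y = y - np.polyval(np.polyfit(x, y, 1), x)  # residualize on x
        res = pearson_bonferroni(x, y)
        assert abs(res.r) < 1e-10
        assert res.strength == "Weak"

    def test_matches_from_scratch_formula(self):
        """Small worked vectors against a covariance/SD oracle."""
        x = np.array([1.0, 2.0, 4.0, 4.5, 7.0])
        y = np.array([2.0, 2.5, 3.0, 5.0, 6.0])
        r_oracle = (np.mean(x * y) - x.mean() * y.mean()) / (
            x.std() * y.std())
        res = pearson_bonferroni(x, y)
        assert res.r == pytest.approx(r_oracle, rel=1e-12)
        # two-sided t-test p from first principles
        t = r_oracle * np.sqrt(3 / (1 - r_oracle ** 2))
        assert res.p_raw == pytest.approx(2 * sps.t.sf(abs(t), 3), rel=1e-9)

    def test_constant_stream_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_bonferroni([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_bonferroni_monotone_in_family_size(self):
        x = np.arange(20.0)
        y = x + np.random.default_rng(0).normal(0, 5, 20)
        padj = [pearson_bonferroni(x, y, family_size=m).p_adj
                for m in (1, 2, 5, 20, 1000)]
        assert all(a <= b for a, b in zip(padj, padj[1:]))
        assert padj[-1] <= 1.0

    @settings(derandomize=True, max_examples=30)
    @given(a=st.floats(0.1, 50), b=st.floats(-100, 100),
           sign=st.sampled_from([-1.0, 1.0]))
    def test_affine_invariance(self, a, b, sign):
        rng = np.random.default_rng(4)
        x = rng.normal(size=25)
        y = x + rng.normal(0, 1, 25)
        base = pearson_bonferroni(x, y).r
        scaled = pearson_bonferroni(x, sign * a * y + b).r
        assert scaled == pytest.approx(sign * base, rel=1e-9)


class TestStrengthClassification:
    @pytest.mark.parametrize("r,expected", [
        (0.62, "Strong"), (0.29, "Weak"), (-0.66, "Strong"),
        (0.60, "Strong"), (0.59, "Weak"), (-0.60, "Strong"), (0.0, "Weak"),
    ])
    def test_threshold_rule(self, r, expected):
        assert classify_strength(r) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_strength(1.5)


class TestStageAccuracyScreen:
    @staticmethod
    def _records(rng, markers=("m1", "m2"), r5=None):
        rows = []
        for m in markers:
            for g in ("A", "B"):
                for t in ("control", "stress"):
                    for das in (0, 4, 8):
                        v3 = rng.normal(10, 2, 5)
                        vals_r5 = v3 if r5 is None else r5(v3, rng)
                        for i in range(5):
                            rows.append((m, g, t, "V3", das, v3[i]))
                            rows.append((m, g, t, "R5", das, vals_r5[i]))
        return pd.DataFrame(rows, columns=["marker", "genotype", "treatment",
                                           "stage", "das", "value"])

    def test_copied_stream_gives_unit_correlation(self):
        rec = self._records(np.random.default_rng(0))
        for res in stage_accuracy_screen(rec):
            assert res.r == pytest.approx(1.0)
            assert res.strength == "Strong"

    def test_family_size_is_marker_count(self):
        rec = self._records(np.random.default_rng(0), markers=("a", "b", "c"))
        out = stage_accuracy_screen(rec)
        assert len(out) == 3 and all(r.family_size == 3 for r in out)

    def test_shuffled_stream_mostly_weak(self):
        """Breaking the V3/R5 pairing destroys the association in >= 95% of
        seeds (permutation oracle)."""
        weak = 0
        n_seeds = 40
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            rec = self._records(
                rng, markers=("m1",),
                r5=lambda v, rr: rr.permutation(rr.normal(10, 2, len(v))))
            res = stage_accuracy_screen(rec)[0]
            weak += res.strength == "Weak"
        assert weak >= 0.95 * n_seeds

    def test_synthetic_sod_stress_strong(self, design, params):
        """Regenerated stress-response data keeps the published pattern:
        the SOD stress-group V3-vs-R5 correlation is Strong."""
        tab = generate_measurements(design, params[params["marker"] == "SOD"])
        out = stage_accuracy_screen(tab, by_group=True)
        by_key = {r.pair[:3]: r for r in out}
        res = by_key[("SOD", "MUNASQA", "stress")]
        assert res.strength == "Strong" and res.r > 0.6

    def test_cell_mean_pairing_mode(self, design, params):
        tab = generate_measurements(design, params[params["marker"] == "CTD"])
        out = stage_accuracy_screen(tab, pairing="cell-mean")
        assert out[0].n == 12  # 4 groups x 3 DAS cell-mean pairs

    def test_missing_stage_rejected(self):
        rec = self._records(np.random.default_rng(0))
        with pytest.raises(ValueError, match="V3 and R5"):
            stage_accuracy_screen(rec[rec["stage"] == "V3"])
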