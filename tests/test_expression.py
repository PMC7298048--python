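"""Expression scoring: centering, outliers, signatures, ssGSEA, correlations."""

import numpy as np
import pandas as pd
import pytest

from pdxtrial.expression import (
    ExpressionMatrix,
    GeneSet,
    SignatureDef,
    call_outliers,
    filter_by_correction_factor,
    median_center_log2,
    outlier_score,
    rna_protein_correlation,
    signature_score,
    ssgsea_score,
)


def matrix(values, samples=None, **kwargs):
    df = pd.DataFrame(values).T if isinstance(values, dict) else pd.DataFrame(values)
    if samples is not None:
        df.columns = samples
    return ExpressionMatrix(df, **kwargs)


class TestMedianCenterLog2:
    def test_linear_hand_example(self):
        m = matrix({"f": [1.0, 2.0, 4.0]}, is_log2=False)
        out = median_center_log2(m)
        assert list(out.values.loc["f"]) == pytest.approx([-1.0, 0.0, 1.0])

    def test_constant_feature_goes_to_zero(self):
        m = matrix({"f": [3.0, 3.0, 3.0]})
        assert (median_center_log2(m).values == 0).all().all()

    def test_idempotent_on_centered_input(self):
        m = matrix({"f": [-1.0, 0.0, 2.0], "g": [5.0, 0.0, -5.0]})
        once = median_center_log2(m)
        twice = median_center_log2(once)
        pd.testing.assert_frame_equal(once.values, twice.values)

    def test_rejects_nonpositive_linear(self):
        m = matrix({"f": [1.0, 0.0, 2.0]}, is_log2=False)
        with pytest.raises(ValueError):
            median_center_log2(m)


class TestOutlierScore:
    # [2, 2, 6, 6] has Q3 = 6, Q1 = 2, IQR = 4 under linear interpolation
    VALUES = [2.0, 2.0, 6.0, 6.0]

    def test_at_q3_scores_zero(self):
        assert outlier_score(self.VALUES, 6.0) == pytest.approx(0.0)

    def test_boundary_is_strict(self):
        assert outlier_score(self.VALUES, 12.0) == pytest.approx(1.5)
        # exactly 1.5 is NOT an outlier; just above is
        assert outlier_score(self.VALUES, 12.1) > 1.5

    def test_translation_equivariance(self):
        base = outlier_score(self.VALUES, 12.0)
        shifted = outlier_score([v + 7 for v in self.VALUES], 19.0)
        assert shifted == pytest.approx(base)

    def test_zero_iqr_is_undefined(self):
        with pytest.raises(ValueError):
            outlier_score([5.0, 5.0, 5.0, 5.0], 9.0)

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            outlier_score([1.0, 2.0], 3.0)


class TestCallOutliers:
    def test_single_spike_is_the_only_flag(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            rng.normal(size=(5, 20)),
            index=[f"f{i}" for i in range(5)],
            columns=[f"s{j}" for j in range(20)],
        )
        q3 = df.loc["f2"].quantile(0.75)
        iqr = q3 - df.loc["f2"].quantile(0.25)
        df.loc["f2", "s7"] = q3 + 10 * iqr
        calls = call_outliers(ExpressionMatrix(df))
        flagged = calls[calls["outlier"]]
        assert len(flagged) == 1
        assert (flagged.iloc[0]["feature"], flagged.iloc[0]["sample"]) == ("f2", "s7")

    def test_constant_matrix_yields_no_flags(self):
        df = pd.DataFrame(np.ones((4, 10)))
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        calls = call_outliers(ExpressionMatrix(df))
        assert not calls["outlier"].any()
        assert calls["score"].isna().all()  # IQR = 0 -> undefined, never flagged

    def test_planted_cohort_spikes_recovered(self, small_cohort):
        calls = call_outliers(small_cohort.rna)
        flagged = set(
            map(tuple, calls.loc[calls["outlier"], ["feature", "sample"]].values)
        )
        planted = set(
            map(
                tuple,
                small_cohort.spikes.query("platform == 'RNA'")[
                    ["feature", "sample"]
                ].values,
            )
        )
        sensitivity = len(planted & flagged) / len(planted)
        assert sensitivity >= 0.95


class TestSignatureScore:
    def test_single_positive_component(self):
        m = matrix({"A": [1.0, -2.0, 0.5]})
        sig = SignatureDef("s", ("A",))
        assert list(signature_score(m, sig)) == pytest.approx([1.0, -2.0, 0.5])

    def test_positive_minus_negative(self):
        m = matrix({"A": [1.0], "B": [2.0], "C": [0.5]})
        sig = SignatureDef("s", ("A", "B"), ("C",))
        assert signature_score(m, sig).iloc[0] == pytest.approx(2.5)

    def test_flipping_component_sign_negates_contribution(self):
        m = matrix({"A": [1.0], "B": [2.0], "C": [0.5]})
        as_pos = signature_score(m, SignatureDef("s", ("A", "B", "C"))).iloc[0]
        as_neg = signature_score(m, SignatureDef("s", ("A", "B"), ("C",))).iloc[0]
        assert as_pos - as_neg == pytest.approx(2 * 0.5)

    def test_linear_in_matrix_values(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(
            rng.normal(size=(4, 6)), index=list("ABCD"),
            columns=[f"s{j}" for j in range(6)],
        )
        sig = SignatureDef("s", ("A", "C"), ("B",))
        one = signature_score(ExpressionMatrix(df), sig)
        three = signature_score(ExpressionMatrix(3 * df), sig)
        assert np.allclose(three, 3 * one)

    def test_all_components_missing_is_an_error(self):
        m = matrix({"A": [1.0]})
        with pytest.raises(ValueError):
            signature_score(m, SignatureDef("s", ("Z",)))

    def test_overlapping_components_rejected(self):
        with pytest.raises(ValueError):
            SignatureDef("s", ("A",), ("A",))


def ssgsea_oracle(values: pd.Series, members: set, alpha: float) -> float:
    """Brute-force cumulative-sum enrichment score for tiny universes."""
    order = sorted(
        range(len(values)),
        key=lambda i: (-values.iloc[i], i),
    )
    n = len(values)
    ranks = {idx: n - pos for pos, idx in enumerate(order)}
    in_flags = [values.index[i] in members for i in order]
    weights = [abs(ranks[i]) ** alpha for i in order]
    sum_in = sum(w for w, f in zip(weights, in_flags) if f)
    n_out = sum(1 for f in in_flags if not f)
    score, cin, cout = 0.0, 0.0, 0.0
    for w, f in zip(weights, in_flags):
        if f:
            cin += w / sum_in
        else:
            cout += 1.0 / n_out
        score += cin - cout
    return score


class TestSsgsea:
    VALUES = pd.Series([4.0, 3.0, 2.0, 1.0], index=list("ABCD"))

    def test_top_feature_set_is_positive(self):
        score = ssgsea_score(self.VALUES, GeneSet("top", ("A",)), alpha=0)
        assert score == pytest.approx(ssgsea_oracle(self.VALUES, {"A"}, 0))
        assert score > 0

    def test_bottom_feature_set_is_negative(self):
        score = ssgsea_score(self.VALUES, GeneSet("bot", ("D",)), alpha=0)
        assert score == pytest.approx(ssgsea_oracle(self.VALUES, {"D"}, 0))
        assert score < 0

    @pytest.mark.parametrize("alpha", [0.0, 0.25, 1.0])
    def test_matches_oracle_on_random_small_universes(self, alpha):
        rng = np.random.default_rng(8)
        for _ in range(25):
            n = int(rng.integers(4, 11))
            values = pd.Series(
                rng.normal(size=n), index=[f"g{i}" for i in range(n)]
            )
            k = int(rng.integers(1, n))
            members = tuple(rng.choice(values.index, size=k, replace=False))
            got = ssgsea_score(values, GeneSet("s", members), alpha=alpha)
            want = ssgsea_oracle(values, set(members), alpha)
            assert got == pytest.approx(want, abs=1e-10)

    def test_complement_antisymmetry_at_alpha_zero(self):
        values = pd.Series([5.0, 4.0, 2.0, 1.0, 0.5], index=list("ABCDE"))
        s = ssgsea_score(values, GeneSet("s", ("A", "C")), alpha=0)
        c = ssgsea_score(values, GeneSet("c", ("B", "D", "E")), alpha=0)
        assert s == pytest.approx(-c)

    def test_rank_invariance_across_samples(self):
        a = pd.Series([10.0, 5.0, 1.0], index=list("ABC"))
        b = pd.Series([100.0, 50.0, 2.0], index=list("ABC"))  # same ordering
        gs = GeneSet("s", ("A",))
        assert ssgsea_score(a, gs, 0.25) == pytest.approx(ssgsea_score(b, gs, 0.25))

    def test_full_universe_set_rejected(self):
        with pytest.raises(ValueError):
            ssgsea_score(self.VALUES, GeneSet("all", tuple("ABCD")), alpha=0)


def bh_oracle(pvals):
    """Brute-force Benjamini–Hochberg step-up adjusted p-values."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank_from_end, i in enumerate(reversed(order)):
        rank = m - rank_from_end
        running_min = min(running_min, pvals[i] * m / rank)
        adjusted[i] = running_min
    return adjusted


class TestRnaProteinCorrelation:
    def test_identical_probe_and_transcript(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(size=(1, 10))
        rna = ExpressionMatrix(
            pd.DataFrame(vals, index=["G"], columns=[f"s{i}" for i in range(10)])
        )
        rppa = ExpressionMatrix(
            pd.DataFrame(vals, index=["P_G"], columns=[f"s{i}" for i in range(10)]),
            platform="RPPA",
        )
        table, frac = rna_protein_correlation(rna, rppa, {"P_G": "G"})
        assert table.iloc[0]["r"] == pytest.approx(1.0)
        assert frac == 100.0

    def test_independent_nulls_rarely_significant(self):
        rng = np.random.default_rng(6)
        samples = [f"s{i}" for i in range(30)]
        genes = [f"G{i}" for i in range(80)]
        rna = ExpressionMatrix(
            pd.DataFrame(rng.normal(size=(80, 30)), index=genes, columns=samples)
        )
        rppa = ExpressionMatrix(
            pd.DataFrame(
                rng.normal(size=(80, 30)),
                index=[f"P_{g}" for g in genes], columns=samples,
            ),
            platform="RPPA",
        )
        _, frac = rna_protein_correlation(rna, rppa, {f"P_{g}": g for g in genes})
        assert frac <= 10.0  # BH controls the null fraction near zero

    def test_bh_hand_example(self):
        from statsmodels.stats.multitest import multipletests

        adjusted = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")[1]
        assert list(adjusted) == pytest.approx([0.04, 0.04, 0.04, 0.04])
        assert bh_oracle([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_too_few_shared_samples(self):
        rna = matrix({"G": [1.0, 2.0]}, samples=["a", "b"])
        rppa = matrix({"P": [1.0, 2.0]}, samples=["a", "b"], platform="RPPA")
        with pytest.raises(ValueError):
            rna_protein_correlation(rna, rppa, {"P": "G"})


def test_correction_factor_filter_drops_low_samples():
    df = pd.DataFrame(
        np.ones((3, 3)), index=list("ABC"), columns=["s1", "s2", "s3"]
    )
    out = filter_by_correction_factor(
        ExpressionMatrix(df, platform="RPPA"), {"s2": 0.33}, threshold=0.5
    )
    assert out.sample_ids == ["s1", "s3"]
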