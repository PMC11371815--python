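"""Moderated t, BH, fusion scoring and MDS, against closed-form and
enumeration oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fibretmt.diffexpr import (
    bh_adjust,
    classify_de,
    de_table,
    eb_moderate,
    fibre_contrast_samples,
    fit_linear_models,
    fusion_scheme,
    mds_coordinates,
    paired_design,
    paired_differences,
    training_contrast_samples,
)
from fibretmt.io import LOG2, QuantMatrix, ValidationError
from fibretmt.normalise import log2_transform
from fibretmt.simulate import generate_cohort, null_params


def _log2_matrix(values, samples=None):
    values = np.asarray(values, float)
    return QuantMatrix(
        pd.DataFrame(
            values,
            index=[f"P{i + 1}" for i in range(values.shape[0])],
            columns=samples or [f"S{j + 1}" for j in range(values.shape[1])],
        ),
        LOG2,
    )


def _paired_annot(n_pairs):
    rows = []
    for i in range(n_pairs):
        for fibre in ("I", "II"):
            rows.append({
                "sample_id": f"P{i + 1:02d}_{fibre}",
                "participant_id": f"P{i + 1:02d}",
                "fibre_type": fibre,
                "timepoint": "PRE",
                "training": "MICT",
                "plex_id": "plex1",
                "channel_label": "126",
            })
    return pd.DataFrame(rows)


class TestLinearModels:
    def test_exact_shift_recovers_beta_and_zero_variance(self):
        annot = _paired_annot(4)
        base = np.array([[10.0, 11.0, 9.0, 10.5]])
        data = np.empty((1, 8))
        data[0, ::2] = base  # type I
        data[0, 1::2] = base + 0.5  # type II
        m = _log2_matrix(data, samples=list(annot["sample_id"]))
        design = paired_design(annot, annot.set_index("sample_id")["fibre_type"], "II")
        fit = fit_linear_models(m, design)
        assert fit.coef[0] == pytest.approx(0.5, abs=1e-12)
        assert fit.zero_variance[0]

    def test_matches_closed_form_paired_statistics(self):
        # single protein, 4 pairs, worked by the textbook paired formulas
        pre = np.array([10.0, 11.0, 9.5, 10.2])
        post = np.array([10.4, 11.9, 9.6, 10.9])
        annot = _paired_annot(4)
        data = np.empty((1, 8))
        data[0, ::2] = pre
        data[0, 1::2] = post
        m = _log2_matrix(data, samples=list(annot["sample_id"]))
        design = paired_design(annot, annot.set_index("sample_id")["fibre_type"], "II")
        fit = fit_linear_models(m, design)
        d = post - pre
        assert fit.coef[0] == pytest.approx(d.mean(), abs=1e-12)
        # residual variance of the blocked model is half the paired-diff
        # variance (each of the n pairs contributes its within-pair spread)
        assert fit.s2[0] * fit.v == pytest.approx(d.var(ddof=1) / len(d), abs=1e-12)
        assert fit.df_residual == 3
        t_ref, p_ref = stats.ttest_rel(post, pre)
        fit = eb_moderate(fit, d0=0.0, s02=1.0)
        assert fit.t[0] == pytest.approx(t_ref, abs=1e-10)
        assert fit.p[0] == pytest.approx(p_ref, abs=1e-10)

    def test_null_data_betas_centred_on_zero(self):
        matrix, samples, *_ = generate_cohort(
            null_params(n_participants_per_group=4, n_proteins=500), seed=2
        )
        logged = log2_transform(matrix)
        pre = fibre_contrast_samples(samples, "PRE")
        sub = logged.subset_samples(list(pre["sample_id"]))
        fit = fit_linear_models(
            sub, paired_design(pre, pre.set_index("sample_id")["fibre_type"], "II")
        )
        assert abs(fit.coef.mean()) < 3 * fit.coef.std() / np.sqrt(len(fit.coef))

    def test_rank_deficient_design_rejected(self):
        annot = _paired_annot(3)
        m = _log2_matrix(np.random.default_rng(0).normal(10, 1, (5, 6)),
                         samples=list(annot["sample_id"]))
        design = paired_design(annot, annot.set_index("sample_id")["fibre_type"], "II")
        design["dup"] = design["__contrast__"]
        with pytest.raises(ValidationError, match="rank"):
            fit_linear_models(m, design)


class TestEbModerate:
    @pytest.fixture()
    def fit(self):
        matrix, samples, *_ = generate_cohort(
            null_params(n_participants_per_group=4, n_proteins=400), seed=3
        )
        logged = log2_transform(matrix)
        pre = fibre_contrast_samples(samples, "PRE")
        sub = logged.subset_samples(list(pre["sample_id"]))
        return fit_linear_models(
            sub, paired_design(pre, pre.set_index("sample_id")["fibre_type"], "II")
        )

    def test_d0_zero_is_ordinary_t(self, fit):
        out = eb_moderate(fit, d0=0.0, s02=1.0)
        ordinary = fit.coef / np.sqrt(fit.s2 * fit.v)
        assert np.allclose(out.t, ordinary)

    def test_d0_infinite_pools_all_variances(self, fit):
        out = eb_moderate(fit, d0=np.inf)
        assert np.allclose(out.s2_post, out.s02)

    def test_posterior_variance_between_prior_and_sample(self, fit):
        out = eb_moderate(fit)
        lo = np.minimum(out.s02, fit.s2)
        hi = np.maximum(out.s02, fit.s2)
        assert np.all(out.s2_post >= lo - 1e-12)
        assert np.all(out.s2_post <= hi + 1e-12)
        assert out.d0 > 0

    def test_null_p_values_uniform(self):
        # simulated null cohort, 2000 proteins, 8 pairs
        matrix, samples, *_ = generate_cohort(
            null_params(n_participants_per_group=4, n_proteins=2000), seed=4
        )
        logged = log2_transform(matrix)
        pre = fibre_contrast_samples(samples, "PRE")
        sub = logged.subset_samples(list(pre["sample_id"]))
        fit = eb_moderate(fit_linear_models(
            sub, paired_design(pre, pre.set_index("sample_id")["fibre_type"], "II")
        ))
        assert stats.kstest(fit.p, "uniform").pvalue > 0.01


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust(np.array([0.037]))[0] == pytest.approx(0.037)

    def test_matches_direct_step_up_formula(self):
        p = np.array([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(bh_adjust(p), [0.04, 0.04, 0.04, 0.04])
        # general oracle: direct step-up evaluation on a scrambled vector
        p = np.array([0.30, 0.001, 0.048, 0.9, 0.052, 0.02])
        order = np.argsort(p)
        m = len(p)
        stepped = p[order] * m / (np.arange(m) + 1)
        expected_sorted = np.minimum.accumulate(stepped[::-1])[::-1].clip(max=1)
        expected = np.empty(m)
        expected[order] = expected_sorted
        assert np.allclose(bh_adjust(p), expected)

    def test_permutation_equivariant(self):
        rng = np.random.default_rng(8)
        p = rng.random(50)
        perm = rng.permutation(50)
        assert np.allclose(bh_adjust(p)[perm], bh_adjust(p[perm]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust(np.array([0.5, 1.2]))


class TestClassifyDe:
    @pytest.mark.parametrize(
        "p_adj, lfc, significant, direction",
        [
            (0.05, -0.5, False, ""),       # boundary: strict <
            (0.01, 0.1, True, ""),          # significant but below display bound
            (0.01, -0.3, True, "higher_in_type_I"),
            (0.01, 0.3, True, "higher_in_type_II"),
        ],
    )
    def test_rule(self, p_adj, lfc, significant, direction):
        table = pd.DataFrame({
            "protein_id": ["P1"], "log2FC": [lfc], "p_adj": [p_adj],
        })
        out = classify_de(table, alpha=0.05, lfc_display=0.2,
                          label_up="higher_in_type_II",
                          label_down="higher_in_type_I")
        assert bool(out["significant"][0]) is significant
        assert out["direction"][0] == direction


class TestFusion:
    def test_zero_fold_change_zero_pi(self):
        diffs = pd.DataFrame(
            [[0.3, -0.3, 0.2, -0.2, 0.1, -0.1]], index=["P1"]
        )
        out = fusion_scheme(diffs)
        assert out["log2FC"][0] == 0.0
        assert out["pi"][0] == 0.0

    def test_p_one_zero_pi(self):
        # symmetric differences: t = 0, p = 1, pi = 0
        diffs = pd.DataFrame([[1.0, -1.0, 1.0, -1.0]], index=["P1"])
        out = fusion_scheme(diffs)
        assert out["p_raw"][0] == pytest.approx(1.0)
        assert out["pi"][0] == 0.0

    def test_matches_exhaustive_enumeration_oracle(self):
        rng = np.random.default_rng(9)
        diffs = pd.DataFrame(
            rng.normal(0.2, 0.5, (5, 6)),
            index=[f"P{i + 1}" for i in range(5)],
        )
        out = fusion_scheme(diffs)
        assert bool(out["exhaustive"][0])

        def pi_of(d):
            n = len(d)
            t, p = stats.ttest_1samp(d, 0.0)
            return abs(np.mean(d)) * (-np.log10(max(p, 5e-324)))

        for g, pid in enumerate(diffs.index):
            d = diffs.loc[pid].to_numpy()
            observed = pi_of(d)
            null = [
                pi_of(d * np.array(signs))
                for signs in itertools.product((1, -1), repeat=6)
            ]
            expected = np.mean([x >= observed for x in null])
            assert out.loc[g, "fusion_p"] == expected  # exact

    def test_flags_more_than_bh_on_moderate_effects(self):
        # moderate training effects, 8 pairs: the fusion scheme calls more
        # proteins than BH-adjusted moderated t on the same contrast
        from fibretmt.simulate import CohortParams

        params = CohortParams(
            n_participants_per_group=8, n_proteins=800,
            frac_fibre_de=0.0, frac_train_de=0.15, train_effect_sd=0.35,
            batch_location_sd=0.0, batch_scale_log_sd=0.0,
            loading_log2_sd=0.0, missing_intercept=-50.0,
            missing_random_rate=0.0,
        )
        matrix, samples, *_ = generate_cohort(params, seed=10)
        logged = log2_transform(matrix)
        cell = training_contrast_samples(samples, "MICT", "I")
        sub = logged.subset_samples(list(cell["sample_id"]))
        cond = cell.set_index("sample_id")["timepoint"]
        diffs = paired_differences(sub, cell, cond, "POST")
        fusion_n = int((fusion_scheme(diffs)["fusion_p"] < 0.05).sum())
        fit = eb_moderate(fit_linear_models(sub, paired_design(cell, cond, "POST")))
        bh_n = int((bh_adjust(fit.p) < 0.05).sum())
        assert fusion_n > bh_n

    def test_unpaired_input_rejected(self):
        annot = _paired_annot(3).iloc[:-1]  # break the last pair
        m = _log2_matrix(np.ones((2, 5)), samples=list(annot["sample_id"]))
        with pytest.raises(ValidationError, match="pair"):
            paired_differences(
                m, annot, annot.set_index("sample_id")["fibre_type"], "II"
            )


class TestMds:
    def test_duplicated_sample_coincident(self):
        rng = np.random.default_rng(11)
        X = rng.normal(10, 1, (50, 3))
        X = np.column_stack([X, X[:, 0]])
        m = _log2_matrix(X)
        coords = mds_coordinates(m, top_n=50)
        assert np.allclose(coords.loc["S1"], coords.loc["S4"], atol=1e-8)

    def test_equilateral_distances_preserved(self):
        # three samples pairwise-equidistant by construction
        X = np.array([
            [1.0, 0.0, 0.0],
            [0.0, 1.0, 0.0],
            [0.0, 0.0, 1.0],
        ])
        m = _log2_matrix(X)
        coords = mds_coordinates(m, top_n=3).to_numpy()
        d01 = np.linalg.norm(coords[0] - coords[1])
        d02 = np.linalg.norm(coords[0] - coords[2])
        d12 = np.linalg.norm(coords[1] - coords[2])
        assert d01 == pytest.approx(d02, abs=1e-6)
        assert d01 == pytest.approx(d12, abs=1e-6)

    def test_fibre_types_separate_with_strong_effect(self, clean_cohort):
        matrix, samples, *_ = clean_cohort
        logged = log2_transform(matrix)
        pre = fibre_contrast_samples(samples, "PRE")
        sub = logged.subset_samples(list(pre["sample_id"]))
        coords = mds_coordinates(sub, top_n=200)
        labels = pre.set_index("sample_id").loc[coords.index, "fibre_type"]
        from sklearn.metrics import silhouette_score

        assert silhouette_score(coords.to_numpy(), labels.to_numpy()) > 0

    def test_too_few_samples_rejected(self):
        m = _log2_matrix(np.ones((5, 2)))
        with pytest.raises(ValidationError):
            mds_coordinates(m)


class TestDeTable:
    def test_table_invariants(self, clean_cohort):
        matrix, samples, *_ = clean_cohort
        logged = log2_transform(matrix)
        pre = fibre_contrast_samples(samples, "PRE")
        sub = logged.subset_samples(list(pre["sample_id"]))
        fit = eb_moderate(fit_linear_models(
            sub, paired_design(pre, pre.set_index("sample_id")["fibre_type"], "II")
        ))
        table = de_table(fit)
        assert ((table["p_adj"] >= table["p_raw"] - 1e-15)
                & (table["p_adj"] <= 1.0)).all()
        # BH preserves the p-value ranking
        order = table.sort_values("p_raw")["p_adj"].to_numpy()
        assert (np.diff(order) >= -1e-15).all()
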