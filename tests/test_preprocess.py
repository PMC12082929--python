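"""Missingness filter, TAMPOR median polish, MDS QC, and outlier screen."""

import numpy as np
import pandas as pd
import pytest

import csfnet as cn
from csfnet import synthetic as syn
from csfnet.exceptions import ConfigurationError, EmptyResultError
from csfnet.preprocess import (
    ALL_SAMPLE_DENOMINATOR,
    PreprocessParams,
    detect_outliers,
    filter_by_missingness,
    mds_qc,
    tampor_normalize,
)


def two_sample_traits(columns, batch="b1", refs=()):
    return pd.DataFrame({
        "sample_id": list(columns),
        "group": ["control"] * len(columns),
        "batch": [batch] * len(columns),
        "center": [None] * len(columns),
        "is_reference": [c in refs for c in columns],
    })


class TestMissingnessFilter:
    def make(self, missing_per_row):
        data = np.full((len(missing_per_row), 4), 20.0)
        for i, k in enumerate(missing_per_row):
            data[i, :k] = np.nan
        return pd.DataFrame(data, index=[f"P{i}|G{i}" for i in range(len(missing_per_row))],
                            columns=list("abcd"))

    def test_exactly_half_missing_is_removed(self):
        m = self.make([2, 1, 0])
        out = filter_by_missingness(m)
        assert "P0|G0" not in out.index  # 2/4 = 50% -> removed
        assert list(out.index) == ["P1|G1", "P2|G2"]  # 25% retained, order kept

    def test_fully_observed_unchanged(self):
        m = self.make([0, 0])
        assert filter_by_missingness(m).equals(m)

    def test_all_removed_raises(self):
        m = self.make([4, 3])
        with pytest.raises(EmptyResultError):
            filter_by_missingness(m)

    def test_reference_channels_excluded_from_denominator(self):
        # protein missing in 2/4 subjects but observed in the reference:
        # the reference column must not rescue it
        m = self.make([2])
        m["gis"] = 20.0
        traits = two_sample_traits(m.columns, refs=("gis",))
        with pytest.raises(EmptyResultError):
            filter_by_missingness(m, traits=traits)

    def test_relaxing_threshold_is_monotone(self):
        rng = np.random.default_rng(0)
        data = rng.normal(20, 2, (50, 8))
        data[rng.random((50, 8)) < 0.4] = np.nan
        m = pd.DataFrame(data, index=[f"P{i}|G{i}" for i in range(50)],
                         columns=[f"s{j}" for j in range(8)])
        kept = None
        for frac in (0.3, 0.5, 0.8, 1.0):
            try:
                now = set(filter_by_missingness(m, PreprocessParams(max_missing_frac=frac)).index)
            except EmptyResultError:
                now = set()
            if kept is not None:
                assert kept <= now
            kept = now


class TestTampor:
    def test_two_by_two_toy_hand_computed(self):
        # log2 values {{1,3},{2,6}}, single batch, all-sample denominator:
        # row medians 2 and 4 -> ratios {{-1,1},{-2,2}}; one polish pass
        # leaves {{0.5,-0.5},{-0.5,0.5}}; re-centering adds back 2 and 4
        m = pd.DataFrame([[1.0, 3.0], [2.0, 6.0]], index=["A|a", "B|b"],
                         columns=["s1", "s2"])
        traits = two_sample_traits(m.columns)
        out, report = tampor_normalize(
            m, traits, PreprocessParams(tampor_mode=ALL_SAMPLE_DENOMINATOR))
        expected = pd.DataFrame([[2.5, 1.5], [3.5, 4.5]], index=m.index,
                                columns=m.columns)
        pd.testing.assert_frame_equal(out, expected)
        assert report.converged

    def test_residual_medians_within_tol(self, small_cohort):
        matrix, traits, _ = small_cohort
        params = PreprocessParams()
        out, report = tampor_normalize(matrix, traits, params)
        assert report.converged
        assert report.max_abs_row_median <= params.tol
        assert report.max_abs_col_median <= params.tol
        col_medians = (out - out.median(axis=1).to_numpy()[:, None]).median(axis=0)
        assert np.nanmax(np.abs(col_medians.to_numpy())) <= 10 * params.tol

    def test_idempotent_on_own_output(self):
        rng = np.random.default_rng(1)
        m = pd.DataFrame(rng.normal(20, 2, (30, 10)),
                         index=[f"P{i}|G{i}" for i in range(30)],
                         columns=[f"s{j}" for j in range(10)])
        traits = two_sample_traits(m.columns)
        params = PreprocessParams(tampor_mode=ALL_SAMPLE_DENOMINATOR)
        once, _ = tampor_normalize(m, traits, params)
        twice, report = tampor_normalize(once, traits, params)
        assert report.iterations == 1
        assert np.nanmax(np.abs((twice - once).to_numpy())) <= 2 * params.tol

    def test_gis_mode_requires_reference_channel(self):
        m = pd.DataFrame(np.ones((3, 4)) * 20, index=[f"P{i}|G{i}" for i in range(3)],
                         columns=list("abcd"))
        traits = two_sample_traits(m.columns)
        with pytest.raises(ConfigurationError):
            tampor_normalize(m, traits, PreprocessParams())

    def test_removes_planted_batch_offsets(self):
        params = syn.TruthParams(n_proteins=150, n_modules=2, max_module_size=40,
                                 min_module_size=20, subthreshold_module_size=0,
                                 group_effects={}, batch_sd=1.0,
                                 mcar_rate=0.0, mnar_strength=0.0)
        matrix, traits, _ = cn.generate_cohort(cn.single_center_design(), params, seed=5)
        out, _ = tampor_normalize(matrix, traits, PreprocessParams())
        batch = traits.set_index("sample_id")["batch"]

        def batch_spread(df):
            b = batch.reindex(df.columns)
            return df.T.groupby(b.to_numpy()).mean().std().mean()

        subj = [c for c in out.columns]
        assert batch_spread(out[subj]) < 0.25 * batch_spread(matrix[subj])


class TestMdsQc:
    def test_duplicated_sample_identical_coordinates(self):
        rng = np.random.default_rng(2)
        m = pd.DataFrame(rng.standard_normal((40, 5)), columns=list("abcde"))
        m["e"] = m["d"]
        coords = mds_qc(m).set_index("sample_id")
        assert coords.loc["d", ["MDS1", "MDS2"]].to_numpy() == pytest.approx(
            coords.loc["e", ["MDS1", "MDS2"]].to_numpy(), abs=1e-8)

    def test_rank2_distances_preserved(self):
        # samples on a 2-D plane embedded in protein space: classical MDS
        # reproduces the pairwise distances exactly
        rng = np.random.default_rng(3)
        basis = rng.standard_normal((30, 2))
        plane = rng.standard_normal((2, 8))
        m = pd.DataFrame(basis @ plane, columns=[f"s{j}" for j in range(8)])
        coords = mds_qc(m).set_index("sample_id")[["MDS1", "MDS2"]].to_numpy()
        orig = m.to_numpy()
        d_in, d_out = [], []
        for i in range(8):
            for j in range(i):
                d_in.append(np.linalg.norm(orig[:, i] - orig[:, j]))
                d_out.append(np.linalg.norm(coords[i] - coords[j]))
        assert np.corrcoef(d_in, d_out)[0, 1] > 0.99

    def test_needs_three_samples(self):
        m = pd.DataFrame(np.ones((5, 2)))
        with pytest.raises(ValueError):
            mds_qc(m)

    def test_batch_structure_removed_by_tampor(self):
        from sklearn.metrics import silhouette_score

        params = syn.TruthParams(n_proteins=120, n_modules=2, max_module_size=40,
                                 min_module_size=20, subthreshold_module_size=0,
                                 group_effects={}, batch_sd=1.0,
                                 mcar_rate=0.0, mnar_strength=0.0)
        matrix, traits, _ = cn.generate_cohort(cn.single_center_design(), params, seed=8)
        batch = traits.set_index("sample_id")["batch"]
        pre = mds_qc(matrix, traits).set_index("sample_id")
        pre = pre[~pre.index.str.contains("GIS")]
        s_pre = silhouette_score(pre[["MDS1", "MDS2"]], batch.reindex(pre.index))
        post_m, _ = tampor_normalize(matrix, traits, PreprocessParams())
        post = mds_qc(post_m, traits).set_index("sample_id")
        s_post = silhouette_score(post[["MDS1", "MDS2"]], batch.reindex(post.index))
        assert s_pre > 0.2
        assert s_post < 0.05


class TestOutlierScreen:
    def test_homogeneous_samples_not_flagged(self):
        rng = np.random.default_rng(4)
        m = pd.DataFrame(rng.normal(20, 2, (200, 40)),
                         columns=[f"s{j}" for j in range(40)])
        assert detect_outliers(m) == []

    def test_noise_sample_flagged(self, small_cohort):
        matrix, _, _ = small_cohort
        m = matrix.copy()
        m.iloc[:, 3] = np.random.default_rng(5).normal(20, 2, len(m))
        flagged = detect_outliers(m)
        assert m.columns[3] in flagged

    def test_infinite_threshold_flags_nothing(self, small_cohort):
        matrix, _, _ = small_cohort
        assert detect_outliers(matrix, PreprocessParams(outlier_z=-np.inf)) == []
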