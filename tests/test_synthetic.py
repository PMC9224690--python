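"""Synthetic cohorts: class balance, determinism, nesting, planted signal."""

import numpy as np
import pytest
from scipy import stats

from camrad.features.names import all_column_names
from camrad.synthetic import (
    SyntheticSpec,
    generate_feature_cohort,
    generate_phantom,
    generate_phantom_cohort,
    informative_rows,
)


class TestSpecValidation:
    def test_label_balance_emulates_study_cohort(self):
        spec = SyntheticSpec()
        assert spec.n_patients == 111
        assert spec.labels.sum() == 56
        assert (spec.labels == 0).sum() == 55

    def test_invalid_prevalence_rejected(self):
        with pytest.raises(ValueError):
            SyntheticSpec(n_patients=10, n_positive=0)
        with pytest.raises(ValueError):
            SyntheticSpec(n_patients=10, n_positive=10)

    def test_oversized_lesion_rejected(self):
        with pytest.raises(ValueError, match="does not fit"):
            SyntheticSpec(volume_shape=(20, 20, 16), lesion_radius_range=(8, 14))

    def test_noise_and_effect_bounds(self):
        with pytest.raises(ValueError):
            SyntheticSpec(noise_sd=0.0)
        with pytest.raises(ValueError):
            SyntheticSpec(effect_size=-1.0)


class TestPhantoms:
    def test_cohort_structure_and_nesting(self):
        spec = SyntheticSpec(n_patients=6, n_positive=3, seed=5)
        cohort = generate_phantom_cohort(spec)
        assert len(cohort) == 6
        assert sum(lbl for _, lbl in cohort) == 3
        for patient, _ in cohort:
            assert set(patient.volumes) == set(spec.modalities)
            for vol in patient.volumes.values():
                assert vol.shape == spec.volume_shape
            tc, wt = patient.masks["TC"], patient.masks["WT"]
            assert not (tc & ~wt).any()  # core nested in whole tumor
            assert tc.sum() >= 27

    def test_deterministic_given_seed(self):
        spec = SyntheticSpec(n_patients=3, n_positive=1, seed=9)
        a = generate_phantom_cohort(spec)
        b = generate_phantom_cohort(spec)
        for (pa, la), (pb, lb) in zip(a, b):
            assert la == lb
            for mod in pa.volumes:
                np.testing.assert_array_equal(pa.volumes[mod], pb.volumes[mod])
            np.testing.assert_array_equal(pa.masks["WT"], pb.masks["WT"])

    def test_patient_stream_independent_of_order(self):
        spec = SyntheticSpec(n_patients=5, n_positive=2, seed=4)
        direct = generate_phantom(spec, 3, 0)
        in_cohort = generate_phantom_cohort(spec)[3][0]
        np.testing.assert_array_equal(
            direct.volumes["T1CE"], in_cohort.volumes["T1CE"]
        )

    def test_class_texture_differs(self):
        spec = SyntheticSpec(n_patients=4, n_positive=2, seed=8)
        p1 = generate_phantom(spec, 0, 1)
        p0 = generate_phantom(spec, 0, 0)
        wt = p1.masks["WT"]
        assert p1.volumes["T1CE"][wt].var() > p0.volumes["T1CE"][wt].var()


class TestFeatureCohorts:
    def test_688_columns_and_shapes(self):
        spec = SyntheticSpec(n_patients=20, n_positive=10, seed=0,
                             informative_features=informative_rows([1, 2]))
        table, labels = generate_feature_cohort(spec)
        assert table.data.shape == (20, 688)
        assert table.columns == all_column_names()
        assert labels.sum() == 10
        assert table.normalization_state == "raw"

    def test_null_effect_mean_differences_small(self):
        spec = SyntheticSpec(n_patients=400, n_positive=200, effect_size=0.0,
                             seed=1)
        table, labels = generate_feature_cohort(spec)
        x = table.data.to_numpy()
        diff = x[labels == 1].mean(axis=0) - x[labels == 0].mean(axis=0)
        assert np.abs(diff).max() < 0.5  # ~N(0, 0.1) per column, 688 draws

    def test_null_ks_rejection_near_nominal(self):
        spec = SyntheticSpec(n_patients=300, n_positive=150, effect_size=0.0,
                             seed=2)
        table, labels = generate_feature_cohort(spec)
        x = table.data.to_numpy()
        pvals = np.array([
            stats.ks_2samp(x[labels == 1, j], x[labels == 0, j]).pvalue
            for j in range(0, 688, 4)
        ])
        rate = (pvals < 0.05).mean()
        assert 0.0 <= rate < 0.15  # ~5% nominal

    def test_planted_cells_dominate_t_statistics(self):
        rng = np.random.default_rng(6)
        cells = frozenset(
            (int(f), int(p))
            for f, p in zip(rng.choice(86, 20), rng.choice(8, 20))
        )
        spec = SyntheticSpec(n_patients=200, n_positive=100, effect_size=2.0,
                             informative_features=cells, seed=3)
        table, labels = generate_feature_cohort(spec)
        x = table.data.to_numpy()
        t = stats.ttest_ind(x[labels == 1], x[labels == 0], axis=0).statistic
        informative_cols = sorted(p * 86 + f for f, p in cells)
        other = np.setdiff1d(np.arange(688), informative_cols)
        thresh = np.percentile(np.abs(t[other]), 95)
        assert (np.abs(t[informative_cols]) > thresh).all()

    def test_empty_informative_set_warns(self):
        spec = SyntheticSpec(n_patients=10, n_positive=5, effect_size=1.0, seed=0)
        with pytest.warns(UserWarning, match="no signal"):
            generate_feature_cohort(spec)

    def test_out_of_grid_cell_rejected(self):
        spec = SyntheticSpec(n_patients=10, n_positive=5, seed=0,
                             informative_features=frozenset({(86, 0)}))
        with pytest.raises(ValueError, match="outside"):
            generate_feature_cohort(spec)


def test_phantom_io_round_trip(tmp_path):
    from camrad.synthetic import load_phantom_cohort, save_phantom_cohort

    spec = SyntheticSpec(n_patients=2, n_positive=1, seed=0,
                         volume_shape=(32, 32, 24),
                         lesion_radius_range=(6.0, 9.0))
    cohort = generate_phantom_cohort(spec)
    save_phantom_cohort(cohort, tmp_path)
    back = load_phantom_cohort(tmp_path)
    assert len(back) == 2
    for (pa, la), (pb, lb) in zip(cohort, back):
        assert la == lb and pa.patient_id == pb.patient_id
        np.testing.assert_allclose(pa.volumes["ADC"], pb.volumes["ADC"],
                                   atol=1e-6)
        np.testing.assert_array_equal(pa.masks["TC"], pb.masks["TC"])
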