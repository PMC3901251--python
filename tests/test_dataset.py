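import numpy as np
import pytest

from specnet import (
    SpectralDataset,
    add_noise,
    bin_spectrum,
    load_spectra,
    mask_bins,
    write_spectra,
)


def tiny_dataset():
    return SpectralDataset(
        intensities=np.array([[1.0, 2.0, 3.0, 4.0], [2.0, 3.0, 4.0, 5.0], [0.5, 1.5, 2.5, 3.5]]),
        subject_ids=["a", "b", "c"],
        labels=np.array(["control", "disease", "unlabeled"], dtype=object),
        bin_axis=np.array([0.02, 0.06, 0.10, 0.14]),
    )


class TestLoadWrite:
    def test_loader_reads_shape_and_labels(self, tmp_path):
        p = tmp_path / "cohort.csv"
        p.write_text(
            "subject_id,label,0.02,0.06,0.10,0.14\n"
            "a,control,1.0,2.0,3.0,4.0\n"
            "b,disease,2.0,3.0,4.0,5.0\n"
            "c,unlabeled,0.5,1.5,2.5,3.5\n"
        )
        data = load_spectra(p)
        assert data.m == 3 and data.n_bins == 4
        assert data.m_control == 1 and data.m_disease == 1
        np.testing.assert_allclose(data.bin_axis, [0.02, 0.06, 0.10, 0.14])

    def test_unknown_label_rejected_listing_allowed(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("subject_id,label,1.0\na,patient,1.0\n")
        with pytest.raises(ValueError, match="control"):
            load_spectra(p)

    def test_label_alias_mapping(self, tmp_path):
        p = tmp_path / "alias.csv"
        p.write_text("subject_id,label,1.0\na,patient,1.0\nb,healthy,2.0\nc,GN,3.0\n")
        data = load_spectra(
            p, label_aliases={"patient": "disease", "healthy": "control", "GN": "disease"}
        )
        assert data.m_control == 1 and data.m_disease == 2

    def test_non_numeric_cell_names_row_and_column(self, tmp_path):
        p = tmp_path / "nonnum.csv"
        p.write_text("subject_id,label,1.0,2.0\na,control,1.0,oops\n")
        with pytest.raises(ValueError, match="'a'.*'2.0'"):
            load_spectra(p)

    def test_missing_label_column(self, tmp_path):
        p = tmp_path / "nolabel.csv"
        p.write_text("subject_id,1.0\na,1.0\n")
        with pytest.raises(ValueError, match="label"):
            load_spectra(p)

    def test_round_trip_is_exact(self, tmp_path, small_cohort):
        p = tmp_path / "rt.csv"
        write_spectra(small_cohort, p)
        back = load_spectra(p, axis_unit=small_cohort.axis_unit)
        np.testing.assert_array_equal(back.intensities, small_cohort.intensities)
        np.testing.assert_array_equal(back.bin_axis, small_cohort.bin_axis)
        assert back.subject_ids == small_cohort.subject_ids
        assert list(back.labels) == list(small_cohort.labels)


class TestValidation:
    def test_non_finite_intensity_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            SpectralDataset(
                np.array([[1.0, np.nan]]),
                ["a"],
                np.array(["control"], dtype=object),
                np.array([1.0, 2.0]),
            )

    def test_non_monotone_axis_rejected(self):
        with pytest.raises(ValueError, match="monotone"):
            SpectralDataset(
                np.ones((1, 3)),
                ["a"],
                np.array(["control"], dtype=object),
                np.array([1.0, 3.0, 2.0]),
            )

    def test_duplicate_subject_ids_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            SpectralDataset(
                np.ones((2, 2)),
                ["a", "a"],
                np.array(["control", "disease"], dtype=object),
                np.array([1.0, 2.0]),
            )


class TestBinning:
    def test_group_means_of_consecutive_columns(self, rng):
        values = rng.normal(size=(5, 200))
        data = SpectralDataset(
            values, [f"s{i}" for i in range(5)],
            np.array(["unlabeled"] * 5, dtype=object), np.arange(200.0),
        )
        out = bin_spectrum(data, bin_size=10)
        assert out.n_bins == 20
        np.testing.assert_allclose(
            out.intensities, values.reshape(5, 20, 10).mean(axis=2)
        )
        np.testing.assert_allclose(out.bin_axis, np.arange(200.0).reshape(20, 10).mean(axis=1))

    def test_bin_size_one_is_identity(self, small_cohort):
        out = bin_spectrum(small_cohort, bin_size=1)
        np.testing.assert_array_equal(out.intensities, small_cohort.intensities)
        np.testing.assert_array_equal(out.bin_axis, small_cohort.bin_axis)

    def test_constant_spectrum_stays_constant(self):
        data = SpectralDataset(
            np.full((2, 7), 5.0), ["a", "b"],
            np.array(["control", "disease"], dtype=object), np.arange(7.0),
        )
        out = bin_spectrum(data, bin_size=3)
        np.testing.assert_array_equal(out.intensities, np.full((2, 3), 5.0))

    def test_trailing_partial_bin_kept_and_logged(self):
        data = SpectralDataset(
            np.arange(7.0)[None, :], ["a"],
            np.array(["control"], dtype=object), np.arange(7.0),
        )
        out = bin_spectrum(data, bin_size=3)
        assert out.n_bins == 3
        np.testing.assert_allclose(out.intensities[0], [1.0, 4.0, 6.0])
        assert any("partial" in entry for entry in out.provenance)

    def test_sum_aggregation_flag(self):
        data = SpectralDataset(
            np.ones((1, 4)), ["a"], np.array(["control"], dtype=object), np.arange(4.0)
        )
        out = bin_spectrum(data, bin_size=2, aggregate="sum")
        np.testing.assert_array_equal(out.intensities[0], [2.0, 2.0])

    def test_bin_width_grouping(self):
        data = SpectralDataset(
            np.arange(6.0)[None, :], ["a"],
            np.array(["control"], dtype=object),
            np.array([0.0, 0.1, 0.2, 0.3, 0.4, 0.5]),
        )
        out = bin_spectrum(data, bin_width=0.25)
        assert out.n_bins == 3  # [0,0.25), [0.25,0.5), [0.5,...)
        np.testing.assert_allclose(out.intensities[0], [1.0, 3.5, 5.0])

    def test_oversized_bin_rejected(self, small_cohort):
        with pytest.raises(ValueError, match="exceeds"):
            bin_spectrum(small_cohort, bin_size=small_cohort.n_bins + 1)


class TestMasking:
    def test_mask_removes_covered_centers(self):
        axis = 0.02 + 0.04 * np.arange(200)  # 0.04-wide grid spanning 0-8
        data = SpectralDataset(
            np.ones((1, 200)), ["a"], np.array(["control"], dtype=object), axis
        )
        out = mask_bins(data, [(4.5, 5.0)])
        expected_removed = int(np.sum((axis >= 4.5) & (axis <= 5.0)))
        assert expected_removed == 13
        assert out.n_bins == 200 - expected_removed
        assert not np.any((out.bin_axis >= 4.5) & (out.bin_axis <= 5.0))

    def test_empty_region_list_is_identity(self, small_cohort):
        out = mask_bins(small_cohort, [])
        np.testing.assert_array_equal(out.intensities, small_cohort.intensities)

    def test_overlapping_regions_behave_as_union(self, small_cohort):
        a = mask_bins(small_cohort, [(5.0, 15.0), (10.0, 20.0)])
        b = mask_bins(small_cohort, [(5.0, 20.0)])
        np.testing.assert_array_equal(a.intensities, b.intensities)

    def test_masking_everything_rejected(self, small_cohort):
        lo, hi = small_cohort.bin_axis.min(), small_cohort.bin_axis.max()
        with pytest.raises(ValueError, match="every bin"):
            mask_bins(small_cohort, [(lo, hi)])

    def test_bin_then_mask_commutes_when_bins_nest_in_region(self):
        # region [20, 40) covers whole output bins of width 10 exactly
        values = np.random.default_rng(1).normal(size=(3, 60))
        data = SpectralDataset(
            values, ["a", "b", "c"],
            np.array(["control", "disease", "unlabeled"], dtype=object),
            np.arange(60.0),
        )
        binned_then_masked = mask_bins(bin_spectrum(data, bin_size=10), [(20.0, 39.0)])
        masked_then_binned = bin_spectrum(mask_bins(data, [(20.0, 39.0)]), bin_size=10)
        np.testing.assert_allclose(
            binned_then_masked.intensities, masked_then_binned.intensities
        )


class TestNoise:
    def test_zero_sigma_is_exact_identity(self, small_cohort):
        out = add_noise(small_cohort, 0.0, seed=1)
        np.testing.assert_array_equal(out.intensities, small_cohort.intensities)

    def test_same_seed_reproduces(self, small_cohort):
        a = add_noise(small_cohort, 0.5, seed=7)
        b = add_noise(small_cohort, 0.5, seed=7)
        np.testing.assert_array_equal(a.intensities, b.intensities)

    def test_negative_sigma_rejected(self, small_cohort):
        with pytest.raises(ValueError):
            add_noise(small_cohort, -0.1, seed=1)

    def test_noise_moments(self):
        data = SpectralDataset(
            np.zeros((100, 500)), [f"s{i}" for i in range(100)],
            np.array(["unlabeled"] * 100, dtype=object), np.arange(500.0),
        )
        diff = add_noise(data, 1.0, seed=2).intensities
        n = diff.size
        assert abs(diff.mean()) < 3.0 / np.sqrt(n)
        assert abs(diff.std() - 1.0) < 3.0 / np.sqrt(2 * n)

    def test_noise_variances_add(self):
        data = SpectralDataset(
            np.zeros((100, 500)), [f"s{i}" for i in range(100)],
            np.array(["unlabeled"] * 100, dtype=object), np.arange(500.0),
        )
        out = add_noise(add_noise(data, 0.6, seed=3), 0.8, seed=4)
        n = out.intensities.size
        observed = out.intensities.std()
        expected = np.sqrt(0.6**2 + 0.8**2)
        assert abs(observed - expected) < 3.0 * expected / np.sqrt(2 * n)
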