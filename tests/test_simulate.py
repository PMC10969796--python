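"""Generator contracts: determinism, planted truth, placement and noise structure."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage

from replikit.simulate import (
    NucleusSimSpec,
    SpotPlacementError,
    generate_nucleus_volume,
    generate_origin_bed,
    generate_population,
    render_spot_field,
    sample_potts_labels,
)

SMALL = dict(shape=(16, 64, 64), semi_axes_um=(1.8, 3.0, 3.0))


class TestNucleusGenerator:
    def test_same_seed_bit_identical(self):
        a, _ = generate_nucleus_volume(NucleusSimSpec(seed=5, n_spots={"pcna": 10}, **SMALL))
        b, _ = generate_nucleus_volume(NucleusSimSpec(seed=5, n_spots={"pcna": 10}, **SMALL))
        for name in a:
            np.testing.assert_array_equal(a[name].data, b[name].data)

    def test_different_seed_differs(self):
        a, _ = generate_nucleus_volume(NucleusSimSpec(seed=5, n_spots={"pcna": 10}, **SMALL))
        b, _ = generate_nucleus_volume(NucleusSimSpec(seed=6, n_spots={"pcna": 10}, **SMALL))
        assert not np.array_equal(a["pcna"].data, b["pcna"].data)

    def test_zero_spots_blank_channel(self):
        channels, truth = generate_nucleus_volume(
            NucleusSimSpec(seed=1, n_spots={"pcna": 0}, noise_sd=0.0, poisson=False, **SMALL)
        )
        assert len(truth.spots) == 0
        spec = NucleusSimSpec(seed=1, n_spots={"pcna": 0}, noise_sd=0.0, poisson=False, **SMALL)
        assert np.allclose(channels["pcna"].data, spec.background)

    def test_planted_centroids_inside_mask(self, nucleus50):
        spec, _, truth = nucleus50
        assert len(truth.spots) == 50
        vox = np.asarray(spec.voxel_size)
        for _, row in truth.spots.iterrows():
            idx = tuple(np.round(np.array([row.z_um, row.y_um, row.x_um]) / vox).astype(int))
            assert truth.mask[idx]

    def test_min_separation_honored(self, nucleus50):
        spec, _, truth = nucleus50
        pts = truth.spots[["z_um", "y_um", "x_um"]].to_numpy()
        from scipy.spatial.distance import pdist

        assert pdist(pts).min() >= spec.min_separation - 1e-9

    def test_full_colocalization_shares_centroids(self):
        spec = NucleusSimSpec(
            seed=3, n_spots={"fish": 5, "pcna": 8}, coloc_pair=("fish", "pcna"), coloc_fraction=1.0, **SMALL
        )
        _, truth = generate_nucleus_volume(spec)
        fish = truth.spots.query("channel == 'fish'")[["z_um", "y_um", "x_um"]].to_numpy()
        pcna = truth.spots.query("channel == 'pcna'")[["z_um", "y_um", "x_um"]].to_numpy()
        for p in fish:
            assert np.min(np.linalg.norm(pcna - p, axis=1)) < 1e-12
        assert truth.n_colocalizing == 5

    def test_edu_pcna_ratio_exact_before_noise(self):
        spec = NucleusSimSpec(
            seed=4, n_spots={"edu": 8, "pcna": 8}, edu_pcna_ratio=0.5, noise_sd=0.0, poisson=False, **SMALL
        )
        channels, _ = generate_nucleus_volume(spec)
        e = (channels["edu"].data - spec.background).sum()
        p = (channels["pcna"].data - spec.background).sum()
        assert e / p == pytest.approx(0.5, rel=1e-9)

    def test_placement_failure_reports_count(self):
        spec = NucleusSimSpec(
            shape=(8, 24, 24), semi_axes_um=(0.8, 1.2, 1.2), n_spots={"pcna": 500}, seed=1
        )
        with pytest.raises(SpotPlacementError) as exc:
            generate_nucleus_volume(spec)
        assert exc.value.n_failed > 0

    def test_peripheral_placement_radius(self):
        spec = NucleusSimSpec(seed=8, n_spots={"pcna": 15}, placement="peripheral", **SMALL)
        _, truth = generate_nucleus_volume(spec)
        center = (np.array(spec.shape) - 1) / 2 * np.array(spec.voxel_size)
        axes = np.array(spec.semi_axes_um) - 2 * spec.spot_sigma_um
        pts = truth.spots[["z_um", "y_um", "x_um"]].to_numpy()
        r = np.sqrt((((pts - center) / axes) ** 2).sum(axis=1))
        assert np.all((r >= 0.70) & (r <= 1.0))

    def test_truth_count_equals_noiseless_maxima(self):
        """Planted count == local maxima of the noiseless field at >= 4 sigma separation."""
        spec = NucleusSimSpec(seed=9, n_spots={"pcna": 20}, noise_sd=0.0, poisson=False, **SMALL)
        channels, truth = generate_nucleus_volume(spec)
        data = channels["pcna"].data
        mx = ndimage.maximum_filter(data, size=3)
        n_max = int(((data == mx) & (data > spec.background + 1e-6)).sum())
        assert n_max == len(truth.spots)

    def test_dapi_class_means_strictly_increasing(self, small_noiseless_nucleus):
        spec, channels, truth = small_noiseless_nucleus
        dapi = channels["dapi"].data
        means = [dapi[truth.compaction == c].mean() for c in range(1, spec.n_classes + 1)]
        assert np.all(np.diff(means) > 0)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            NucleusSimSpec(coloc_fraction=1.5)
        with pytest.raises(ValueError):
            NucleusSimSpec(spot_sigma_um=0.0)
        with pytest.raises(ValueError):
            NucleusSimSpec(placement="ring")
        with pytest.raises(ValueError):
            NucleusSimSpec(edu_pcna_ratio=-1.0)


class TestPottsField:
    def test_beta_increases_neighbor_agreement(self):
        mask = np.ones((12, 24, 24), dtype=bool)
        rng0 = np.random.default_rng(0)
        rng1 = np.random.default_rng(0)
        free = sample_potts_labels(mask, 7, 0.0, rng0, sweeps=10)
        coupled = sample_potts_labels(mask, 7, 1.5, rng1, sweeps=20)

        def agreement(lab):
            return np.mean(lab[:, :, 1:] == lab[:, :, :-1])

        assert agreement(coupled) > agreement(free) + 0.1

    def test_labels_in_range_and_masked(self):
        mask = np.zeros((8, 16, 16), dtype=bool)
        mask[2:6, 4:12, 4:12] = True
        lab = sample_potts_labels(mask, 7, 1.0, np.random.default_rng(1), sweeps=5)
        assert lab[~mask].max() == 0
        assert set(np.unique(lab[mask])) <= set(range(1, 8))


class TestRenderSpotField:
    def test_peak_amplitude_and_isotropy_in_um(self):
        vs = (0.29, 0.125, 0.125)
        c = np.array([[8 * 0.29, 32 * 0.125, 32 * 0.125]])
        f = render_spot_field((16, 64, 64), vs, c, 0.25, 100.0)
        assert f.max() == pytest.approx(100.0, rel=1e-6)
        # half-width measured along y and z agrees in µm (anisotropic grid)
        peak = np.unravel_index(np.argmax(f), f.shape)
        prof_y = f[peak[0], :, peak[2]]
        sigma_y = np.sqrt(np.sum(prof_y * (np.arange(64) * 0.125 - c[0, 1]) ** 2) / prof_y.sum())
        assert sigma_y == pytest.approx(0.25, rel=0.05)


class TestPopulation:
    def test_exact_class_counts(self):
        _, truth = generate_population(500, (0.4, 0.4, 0.2), seed=7)
        counts = truth.cells["true_phase"].value_counts()
        assert counts["G1"] == 200 and counts["S"] == 200 and counts["G2"] == 100

    def test_all_g1_edu_negative(self):
        df, truth = generate_population(50, (1.0, 0.0, 0.0), seed=1)
        assert (truth.cells["true_phase"] == "G1").all()
        assert df["edu"].max() < 100  # negative-level noise only

    def test_g2_dapi_twice_g1(self):
        df, truth = generate_population(400, (0.5, 0.0, 0.5), seed=2)
        m = truth.cells.groupby("true_phase")["dapi_sum"].mean()
        assert m["G2"] / m["G1"] == pytest.approx(2.0, rel=0.05)

    def test_bad_fractions_raise(self):
        with pytest.raises(ValueError):
            generate_population(10, (-0.1, 0.6, 0.5))
        with pytest.raises(ValueError):
            generate_population(10, (0.5, 0.2, 0.2))

    def test_seed_determinism(self):
        a, _ = generate_population(100, seed=3)
        b, _ = generate_population(100, seed=3)
        pd.testing.assert_frame_equal(a, b)


class TestOriginGenerator:
    def test_single_peak_no_gaps(self):
        os_, truth = generate_origin_bed({"chr1": 1}, seed=0)
        assert len(os_) == 1 and len(truth.gaps) == 0

    def test_fixed_gaps_mean(self):
        os_, truth = generate_origin_bed({"chr1": 3}, gap_sampler=[300, 600], peak_width=200, seed=0)
        assert truth.gaps["gap"].tolist() == [300, 600]
        assert truth.gaps["gap"].mean() == 450

    def test_sorted_non_overlapping(self):
        os_, _ = generate_origin_bed({"chr1": 50, "chr2": 30}, seed=4)
        for _, grp in os_.intervals.groupby("chrom"):
            assert (grp["start"].diff().dropna() > 0).all()
            assert (grp["start"].to_numpy()[1:] >= grp["end"].to_numpy()[:-1]).all()

    def test_seed_contract(self):
        a, _ = generate_origin_bed({"chr1": 20}, seed=1)
        b, _ = generate_origin_bed({"chr1": 20}, seed=1)
        c, _ = generate_origin_bed({"chr1": 20}, seed=2)
        pd.testing.assert_frame_equal(a.intervals, b.intervals)
        assert not a.intervals.equals(c.intervals)

    def test_nonpositive_gaps_rejected(self):
        with pytest.raises(ValueError):
            generate_origin_bed({"chr1": 3}, gap_sampler=[-10, 500], peak_width=100)
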