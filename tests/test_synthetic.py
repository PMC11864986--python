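"""Planted-structure guarantees of the synthetic generators."""

import numpy as np
import pandas as pd
import pytest

from tectomap.synthetic import (
    SyntheticConfig,
    coupling_position_only,
    coupling_type_only,
    generate_multimodal,
    generate_point_cloud,
    generate_roi_masks,
    generate_traces,
)


def _plugin_mi(a, b):
    """Plug-in mutual information (nats) from the empirical contingency."""
    tab = pd.crosstab(pd.Series(a), pd.Series(b)).to_numpy().astype(float)
    p = tab / tab.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float(np.sum(p[nz] * np.log(p[nz] / (px @ py)[nz])))


class TestPointCloud:
    def test_deterministic_under_seed(self):
        cfg = SyntheticConfig(
            n_types=1, layer_assignment=(0,), mosaic_exclusion_radius=0.0,
            n_cells_per_type=100, seed=11,
        )
        c1, l1 = generate_point_cloud(cfg)
        c2, l2 = generate_point_cloud(cfg)
        assert len(c1) == 100
        assert c1.coords.tobytes() == c2.coords.tobytes()
        assert np.array_equal(l1, l2)

    def test_cells_confined_to_their_layer_slab(self):
        cfg = SyntheticConfig(
            n_types=2, layer_assignment=(0, 1),
            layer_depths=((0.0, 20.0), (40.0, 60.0)),
            mosaic_exclusion_radius=0.0, n_cells_per_type=80, seed=0,
        )
        cloud, layers = generate_point_cloud(cfg)
        z = cloud.coords[:, 2]
        assert np.all(z[cloud.labels == "t0"] < 20.0)
        assert np.all(z[cloud.labels == "t1"] > 40.0)
        assert np.array_equal(layers, np.repeat([0, 1], 80))

    def test_mosaic_hard_core_bruteforce(self):
        """No same-type pair closer than the exclusion radius (all-pairs scan)."""
        cfg = SyntheticConfig(
            n_types=2, layer_assignment=(0, 1), mosaic_exclusion_radius=5.0,
            n_cells_per_type=150, seed=3,
        )
        cloud, _ = generate_point_cloud(cfg)
        for t in ("t0", "t1"):
            pts = cloud.coords[cloud.labels == t]
            d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
            np.fill_diagonal(d2, np.inf)
            assert np.sqrt(d2.min()) >= 5.0

    def test_infeasible_packing_names_type(self):
        cfg = SyntheticConfig(
            n_types=1, layer_assignment=(0,), layer_depths=((0.0, 5.0),),
            extent_um=(30.0, 30.0), mosaic_exclusion_radius=20.0,
            n_cells_per_type=100, seed=0,
        )
        with pytest.raises(RuntimeError, match="t0"):
            generate_point_cloud(cfg)

    def test_ap_gradient_shifts_mass_posteriorly(self):
        cfg = SyntheticConfig(
            n_types=1, layer_assignment=(0,), mosaic_exclusion_radius=0.0,
            ap_gradient=(1.5,), n_cells_per_type=2000, seed=5,
        )
        cloud, _ = generate_point_cloud(cfg)
        x = cloud.coords[:, 0] / cfg.extent_um[0]
        # E[x] for density 1 + 1.5 (x - 1/2) is 1/2 + 1.5/12
        assert np.mean(x) == pytest.approx(0.5 + 1.5 / 12.0, abs=0.02)


class TestTraces:
    def test_noiseless_trace_is_baseline_plus_regressor(self, protocol, regressors):
        amps = np.zeros((1, 8))
        amps[0, 4] = 1.0
        cfg = SyntheticConfig(f_archetypes=amps, noise_sd=0.0, drift_sd=0.0, seed=0)
        traces, signal = generate_traces(protocol, cfg, [0])
        expect = cfg.baseline + regressors.values[:, 4]
        assert np.allclose(traces.values[0], expect, atol=1e-12)
        assert np.allclose(signal[0], expect, atol=1e-12)

    def test_identical_archetypes_perfectly_correlated(self, protocol):
        cfg = SyntheticConfig(noise_sd=0.0, drift_sd=0.0, seed=0)
        traces, _ = generate_traces(protocol, cfg, [2, 2])
        r = np.corrcoef(traces.values)[0, 1]
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_residual_noise_sd(self, protocol):
        cfg = SyntheticConfig(noise_sd=0.1, drift_sd=0.0, seed=7)
        ftypes = np.zeros(500, dtype=int)
        traces, signal = generate_traces(protocol, cfg, ftypes)
        resid = traces.values - signal
        assert resid.std() == pytest.approx(0.1, rel=0.05)

    def test_archetype_out_of_range_rejected(self, protocol):
        cfg = SyntheticConfig(seed=0)
        with pytest.raises(ValueError, match="out of range"):
            generate_traces(protocol, cfg, [cfg.n_archetypes])


class TestCoupling:
    def test_position_only_coupling_gives_zero_type_mi(self):
        """Type and archetype independent when coupling ignores type."""
        cfg = SyntheticConfig(
            n_types=4, layer_assignment=(0, 0, 1, 1),
            mosaic_exclusion_radius=0.0, n_cells_per_type=2500,
            coupling=coupling_position_only(4, 2, 5, strength=0.8), seed=9,
        )
        data = generate_multimodal(cfg, with_traces=False)
        t = data.provenance["t_type"].to_numpy()
        a = data.provenance["archetype"].to_numpy()
        mi = _plugin_mi(t, a)
        rng = np.random.default_rng(1)
        null = np.array([_plugin_mi(t, rng.permutation(a)) for _ in range(200)])
        assert mi <= np.percentile(null, 99)

    def test_deterministic_type_coupling_zero_conditional_entropy(self):
        cfg = SyntheticConfig(
            n_types=4, layer_assignment=(0, 0, 1, 1),
            mosaic_exclusion_radius=0.0, n_cells_per_type=200,
            coupling=coupling_type_only(4, 2, 5, strength=1.0), seed=2,
        )
        data = generate_multimodal(cfg, with_traces=False)
        grp = data.provenance.groupby("t_type")["archetype"].nunique()
        assert (grp == 1).all()  # H(archetype | type) = 0

    def test_swapped_bin_preferences_reproduce_contrast(self):
        """Anterior/posterior archetype frequencies differ by the planted contrast."""
        strength = 0.6
        K = 2
        cfg = SyntheticConfig(
            n_types=2, layer_assignment=(0, 1), mosaic_exclusion_radius=0.0,
            n_cells_per_type=2500, n_archetypes=K,
            f_archetypes=np.eye(2, 8),
            coupling=coupling_position_only(2, 2, K, strength=strength), seed=4,
        )
        data = generate_multimodal(cfg, with_traces=False)
        prov = data.provenance
        p0 = (prov.loc[prov.pos_bin == 0, "archetype"] == 0).mean()
        p1 = (prov.loc[prov.pos_bin == 1, "archetype"] == 0).mean()
        n = min((prov.pos_bin == 0).sum(), (prov.pos_bin == 1).sum())
        se = np.sqrt(2 * 0.5 * 0.5 / n)
        assert (p0 - p1) == pytest.approx(strength, abs=4 * se)

    def test_archetype_marginals_match_configuration(self):
        """Uniform coupling: archetype frequencies inside a multinomial band."""
        from scipy.stats import binomtest

        K = 5
        cfg = SyntheticConfig(
            n_types=2, layer_assignment=(0, 1), mosaic_exclusion_radius=0.0,
            n_cells_per_type=2000,
            coupling=np.full((2, 2, K), 1.0 / K), seed=6,
        )
        data = generate_multimodal(cfg, with_traces=False)
        counts = data.provenance["archetype"].value_counts()
        n = len(data.provenance)
        for k in range(K):
            p = binomtest(int(counts.get(k, 0)), n, 1.0 / K).pvalue
            assert p > 0.001


class TestRoiMasks:
    def test_zero_jitter_centroid_inside_own_mask(self):
        cfg = SyntheticConfig(
            n_types=1, layer_assignment=(0,), mosaic_exclusion_radius=6.0,
            n_cells_per_type=60, seed=1,
        )
        cloud, _ = generate_point_cloud(cfg)
        masks, truth = generate_roi_masks(cloud, jitter_sd=0.0, mask_radius=2)
        for rec in truth.itertuples():
            px = masks.masks[rec.true_roi_id]
            assert any(
                (p == rec.plane and r == rec.row and c == rec.col)
                for p, r, c in px
            )

    def test_overlapping_masks_both_recorded(self):
        from tectomap.layering import LabeledPointCloud

        cloud = LabeledPointCloud(
            coords=np.array([[10.0, 10.0, 5.0], [11.0, 10.0, 5.0]]),
            labels=np.array(["a", "a"]),
        )
        masks, _ = generate_roi_masks(cloud, jitter_sd=0.0, mask_radius=2)
        assert len(masks.masks) == 2
        pix0 = set(map(tuple, masks.masks[0]))
        pix1 = set(map(tuple, masks.masks[1]))
        assert pix0 & pix1  # shared pixels allowed

    def test_large_jitter_breaks_containment(self):
        cfg = SyntheticConfig(
            n_types=1, layer_assignment=(0,), mosaic_exclusion_radius=8.0,
            n_cells_per_type=100, seed=2,
        )
        cloud, _ = generate_point_cloud(cfg)
        masks, truth = generate_roi_masks(cloud, jitter_sd=10.0, mask_radius=2, seed=0)
        inside = 0
        for rec in truth.itertuples():
            px = set(map(tuple, masks.masks[rec.true_roi_id]))
            inside += (rec.plane, rec.row, rec.col) in px
        assert inside / len(truth) < 0.5

    def test_negative_jitter_rejected(self):
        from tectomap.layering import LabeledPointCloud

        cloud = LabeledPointCloud(np.zeros((1, 3)) + 5, np.array(["a"]))
        with pytest.raises(ValueError):
            generate_roi_masks(cloud, jitter_sd=-1.0)


class TestMultimodalDeterminism:
    def test_full_dataset_reproducible(self):
        cfg = SyntheticConfig(n_cells_per_type=20, seed=42)
        d1 = generate_multimodal(cfg)
        d2 = generate_multimodal(cfg)
        assert d1.cloud.coords.tobytes() == d2.cloud.coords.tobytes()
        assert d1.traces.values.tobytes() == d2.traces.values.tobytes()
        assert d1.provenance.equals(d2.provenance)
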