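"""Phenotype sampling and constrained plug growth."""

import warnings

import numpy as np
import pytest
from scipy import stats

from plugforge.errors import ConfigError, DataError, NoEligibleSite
from plugforge.geometry import LumenMap, per_section_occlusion
from plugforge.phantom import generate_phantom
from plugforge.plug_synthesis import (
    PlugPhenotype,
    PlugSamplingConfig,
    grow_plug,
    populate_scan,
    sample_phenotype,
    select_seed,
)

from conftest import small_spec


class TestSamplePhenotype:
    def test_defaults_follow_protocol_ranges(self, rng):
        cfg = PlugSamplingConfig()
        for _ in range(100):
            ph = sample_phenotype(cfg, rng)
            assert 2.0 <= ph.target_length_mm <= 20.0
            assert 0.35 <= ph.target_occlusion_ratio <= 1.0
            assert ph.eligible_diameter_mm == (1.0, 20.0)

    def test_degenerate_range_is_point_mass(self, rng):
        cfg = PlugSamplingConfig(length_range_mm=(5.0, 5.0))
        assert all(sample_phenotype(cfg, rng).target_length_mm == 5.0 for _ in range(10))

    def test_draws_are_uniform(self, rng):
        cfg = PlugSamplingConfig()
        lengths = np.array([sample_phenotype(cfg, rng).target_length_mm for _ in range(10_000)])
        assert lengths.min() >= 2.0 and lengths.max() <= 20.0
        _, p = stats.kstest(lengths, stats.uniform(loc=2.0, scale=18.0).cdf)
        assert p > 0.01

    def test_empty_range_rejected(self):
        with pytest.raises(ConfigError, match="empty"):
            PlugSamplingConfig(length_range_mm=(10.0, 5.0))


class TestSelectSeed:
    def test_seed_diameter_within_eligible_range(self, anatomy, lumen_map, rng):
        cfg = PlugSamplingConfig()
        ph = sample_phenotype(cfg, rng)
        seed = select_seed(anatomy, ph, None, rng, lumen_map, cfg)
        row = lumen_map.row_of_voxel(seed)
        assert 1.0 <= 2.0 * lumen_map.radius[row] <= 20.0

    def test_impossible_caliber_raises(self, anatomy, lumen_map, rng):
        cfg = PlugSamplingConfig(eligible_diameter_mm=(30.0, 40.0))
        ph = sample_phenotype(cfg, rng)
        with pytest.raises(NoEligibleSite):
            select_seed(anatomy, ph, None, rng, lumen_map, cfg)

    def test_uniform_sampling_covers_all_branches(self, rng):
        model = generate_phantom(small_spec(tree_depth=1))
        lm = LumenMap(model)
        cfg = PlugSamplingConfig()
        ph = sample_phenotype(cfg, rng)
        hit = set()
        for _ in range(500):
            seed = select_seed(model, ph, None, rng, lm, cfg)
            hit.add(int(lm.branch_id[lm.row_of_voxel(seed)]))
        assert hit == {b.id for b in model.centerlines.branches}


class TestGrowPlug:
    def test_full_occlusion_fills_every_covered_section(self, anatomy, lumen_map, rng):
        cfg = PlugSamplingConfig(occlusion_range=(1.0, 1.0))
        ph = sample_phenotype(cfg, rng)
        seed = select_seed(anatomy, ph, None, rng, lumen_map, cfg)
        plug = grow_plug(anatomy, seed, ph, lumen_map, config=cfg)
        assert np.all(plug.section_occlusion == pytest.approx(1.0))

    def test_target_length_approached_within_one_voxel(self, anatomy, lumen_map, rng):
        ph = PlugPhenotype(10.0, 0.8, (1.0, 20.0))
        # place in the root branch which is far longer than 10 mm
        root = anatomy.centerlines.branches[0]
        rows = np.nonzero(lumen_map.branch_id == root.id)[0]
        mid = rows[np.argsort(np.abs(lumen_map.s[rows] - root.length_mm / 2))[0]]
        seed = tuple(int(v) for v in lumen_map.voxels[mid])
        plug = grow_plug(anatomy, seed, ph, lumen_map)
        assert plug.achieved_length_mm == pytest.approx(10.0, abs=1.0)
        assert not plug.truncated

    def test_plug_confined_to_lumen(self, anatomy, lumen_map, rng):
        cfg = PlugSamplingConfig()
        ph = sample_phenotype(cfg, rng)
        seed = select_seed(anatomy, ph, None, rng, lumen_map, cfg)
        plug = grow_plug(anatomy, seed, ph, lumen_map, config=cfg)
        lumen = anatomy.airway_lumen_mask.data.astype(bool)
        assert lumen[plug.voxels[:, 0], plug.voxels[:, 1], plug.voxels[:, 2]].all()

    def test_occlusion_floor_at_every_section(self, anatomy, lumen_map, rng):
        cfg = PlugSamplingConfig()
        for _ in range(20):
            ph = sample_phenotype(cfg, rng)
            seed = select_seed(anatomy, ph, None, rng, lumen_map, cfg)
            plug = grow_plug(anatomy, seed, ph, lumen_map, config=cfg)
            measured = per_section_occlusion(plug.voxels, lumen_map)
            assert min(measured.values()) >= ph.target_occlusion_ratio - 1e-9

    def test_growth_is_deterministic(self, anatomy, lumen_map, rng):
        cfg = PlugSamplingConfig()
        ph = sample_phenotype(cfg, rng)
        seed = select_seed(anatomy, ph, None, rng, lumen_map, cfg)
        p1 = grow_plug(anatomy, seed, ph, lumen_map, config=cfg)
        p2 = grow_plug(anatomy, seed, ph, lumen_map, config=cfg)
        assert np.array_equal(p1.voxels, p2.voxels)

    def test_plug_is_26_connected(self, anatomy, lumen_map, rng):
        from skimage import measure

        cfg = PlugSamplingConfig()
        ph = sample_phenotype(cfg, rng)
        seed = select_seed(anatomy, ph, None, rng, lumen_map, cfg)
        plug = grow_plug(anatomy, seed, ph, lumen_map, config=cfg)
        lo = plug.voxels.min(axis=0)
        sub = np.zeros(plug.voxels.max(axis=0) - lo + 1, dtype=bool)
        sub[tuple((plug.voxels - lo).T)] = True
        assert measure.label(sub, connectivity=3).max() == 1


class TestPopulateScan:
    def test_zero_plugs(self, anatomy, lumen_map, rng):
        plugs, labels = populate_scan(anatomy, 0, rng=rng, lumen_map=lumen_map)
        assert plugs == []
        assert labels.data.max() == 0

    def test_negative_count_rejected(self, anatomy, rng):
        with pytest.raises(ConfigError):
            populate_scan(anatomy, -1, rng=rng)

    def test_fifty_disjoint_labelled_plugs_on_default_phantom(
        self, default_anatomy, default_lumen_map, rng
    ):
        plugs, labels = populate_scan(default_anatomy, 50, rng=rng, lumen_map=default_lumen_map)
        assert len(plugs) == 50
        assert sorted(p.label_id for p in plugs) == list(range(1, 51))
        all_vox = np.concatenate([p.voxels for p in plugs])
        flat = np.ravel_multi_index(tuple(all_vox.T), labels.shape)
        assert len(flat) == len(np.unique(flat))  # pairwise disjoint
        assert set(np.unique(labels.data)) == set(range(51))

    def test_reproducible_under_fixed_seed(self, anatomy, lumen_map):
        out = []
        for _ in range(2):
            plugs, labels = populate_scan(
                anatomy, 10, rng=np.random.default_rng(99), lumen_map=lumen_map
            )
            out.append((plugs, labels))
        assert np.array_equal(out[0][1].data, out[1][1].data)
        for a, b in zip(out[0][0], out[1][0]):
            assert np.array_equal(a.voxels, b.voxels)

    def test_request_monotonicity(self, anatomy, lumen_map):
        small, _ = populate_scan(anatomy, 5, rng=np.random.default_rng(7), lumen_map=lumen_map)
        large, _ = populate_scan(anatomy, 15, rng=np.random.default_rng(7), lumen_map=lumen_map)
        assert len(large) >= len(small)
        for a, b in zip(small, large):  # shared prefix of the plug stream
            assert np.array_equal(a.voxels, b.voxels)

    def test_saturation_warns_and_returns_fewer(self):
        model = generate_phantom(small_spec(tree_depth=0, seed=13))
        with pytest.warns(UserWarning, match="saturated"):
            plugs, _ = populate_scan(model, 400, rng=np.random.default_rng(1))
        assert 0 < len(plugs) < 400

    def test_no_airway_rejected(self, anatomy, rng):
        from dataclasses import replace

        broken = replace(
            anatomy,
            airway_lumen_mask=anatomy.airway_lumen_mask.with_data(
                np.zeros_like(anatomy.airway_lumen_mask.data)
            ),
        )
        with pytest.raises(DataError, match="airway"):
            populate_scan(broken, 5, rng=rng)
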