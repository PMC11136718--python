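"""Synthetic-cohort generator: atlas construction, images, cognition, study."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import cortexdiff as cd
from cortexdiff.config import DOMAINS, MS_PHENOTYPES
from cortexdiff.errors import AtlasError, ConfigError
from cortexdiff.simulate import draw_lesions, make_toy_atlas, partial_volume_map


class TestToyAtlas:
    def test_default_atlas_has_212_regions_each_in_one_network(self):
        atlas = make_toy_atlas(cd.SimulationConfig())
        assert atlas.n_regions == 212
        nets = atlas.lookup_table().groupby("network").size()
        assert nets.sum() == 212
        assert set(nets.index) == set(cd.NETWORKS)

    def test_one_region_per_network_is_a_bijection(self):
        cfg = cd.SimulationConfig(n_regions=7, grid_shape=(9, 9, 3))
        atlas = make_toy_atlas(cfg)
        nets = [atlas.region_networks[r] for r in range(1, 8)]
        assert sorted(nets) == sorted(cd.NETWORKS)

    def test_region_voxel_tally_matches_label_volume(self, tiny_atlas):
        assert (
            tiny_atlas.region_sizes().sum()
            == np.count_nonzero(tiny_atlas.labels)
        )

    def test_every_region_has_at_least_8_voxels(self, tiny_atlas):
        assert (tiny_atlas.region_sizes() >= 8).all()

    def test_every_region_has_a_hemisphere(self, tiny_atlas):
        assert set(tiny_atlas.region_hemispheres.values()) <= {"L", "R"}

    def test_grid_too_small_raises(self):
        with pytest.raises(AtlasError):
            make_toy_atlas(cd.SimulationConfig(grid_shape=(6, 6, 6)))


class TestSubjectImages:
    def test_hc_subject_has_empty_lesion_mask(self, tiny_config, tiny_atlas, rng):
        img = cd.simulate_subject_images(tiny_atlas, "HC", tiny_config, rng)
        assert img.cl_mask.sum() == 0

    def test_zero_noise_zero_effect_md_equals_baseline(self, tiny_config, tiny_atlas, rng):
        cfg = cd.SimulationConfig(
            grid_shape=tiny_config.grid_shape,
            n_regions=tiny_config.n_regions,
            hc_region_sds={"fa": 0.0, "md": 0.0},
            voxel_noise={"fa": 0.0, "md": 0.0},
        )
        img = cd.simulate_subject_images(tiny_atlas, "HC", cfg, rng)
        base = cfg.region_baselines()
        for rid in tiny_atlas.region_ids:
            vals = img.md[tiny_atlas.labels == rid]
            assert np.allclose(vals, base.loc[rid, "md"], atol=1e-6)

    def test_unknown_phenotype_rejected(self, tiny_config, tiny_atlas, rng):
        with pytest.raises(ConfigError):
            cd.simulate_subject_images(tiny_atlas, "XX", tiny_config, rng)

    def test_lesion_voxels_lie_inside_cortex(self, tiny_config, tiny_atlas, rng):
        for _ in range(20):
            img = cd.simulate_subject_images(tiny_atlas, "CI", tiny_config, rng)
            assert not np.any((img.cl_mask > 0) & (tiny_atlas.labels == 0))

    def test_pv_map_in_unit_interval_and_zero_outside(self, tiny_atlas):
        pv = partial_volume_map(tiny_atlas)
        assert pv.min() >= 0 and pv.max() <= 1
        assert np.all(pv[tiny_atlas.labels == 0] == 0)
        assert np.all(pv[tiny_atlas.labels > 0] > 0)

    def test_ci_dmn_shift_recovered_over_many_subjects(self):
        """Mean non-lesional DMN MD exceeds baseline by the configured shift."""
        cfg = cd.SimulationConfig(seed=5)
        atlas = cd.make_toy_atlas(cfg)
        rng = np.random.default_rng(5)
        shift = cfg.nonlesional_md_effect["CI"]["DMN"]
        dmn = [r for r, n in atlas.region_networks.items() if n == "DMN"]
        base = cfg.region_baselines().loc[dmn, "md"].to_numpy()
        n_sub = 200
        devs = []
        for _ in range(n_sub):
            img = cd.simulate_subject_images(atlas, "CI", cfg, rng)
            topo = cd.intersect_lesions(atlas, img.cl_mask)
            lesional, _ = cd.lesional_region_split(topo)
            tab = cd.region_metric_table(atlas, img.fa, img.md, img.pv, lesional)
            keep = [r for r in dmn if r not in lesional]
            if keep:
                devs.append(
                    (tab.loc[keep, "md_raw"].to_numpy()
                     - cfg.region_baselines().loc[keep, "md"].to_numpy()).mean()
                )
        devs = np.asarray(devs)
        se = devs.std(ddof=1) / np.sqrt(len(devs))
        assert abs(devs.mean() - shift) < 3 * se + 1e-4


class TestCognition:
    def _mean_covs(self, cfg, ph):
        cov = cfg.covariate_model
        return {
            "age": cov["age"][ph][0],
            "sex_female": cov["sex_female"][ph],
            "educ_high": cov["educ_high"][ph],
        }

    def test_hc_zero_noise_scores_are_zero(self, rng):
        cfg = cd.SimulationConfig(
            domain_effects={
                g: {d: (m, 0.0) for d, (m, s) in v.items()}
                for g, v in cd.SimulationConfig().domain_effects.items()
            }
        )
        scores = cd.simulate_cognition("HC", self._mean_covs(cfg, "HC"), cfg, rng)
        assert np.allclose(scores.to_numpy(), 0.0)

    def test_ci_processing_speed_mean_matches_configured_value(self, rng):
        cfg = cd.SimulationConfig()
        target, sd = cfg.domain_effects["CI"]["information_processing_speed"]
        draws = np.array([
            cd.simulate_cognition("CI", self._mean_covs(cfg, "CI"), cfg, rng)[
                "information_processing_speed"
            ]
            for _ in range(500)
        ])
        assert abs(draws.mean() - target) < 3 * sd / np.sqrt(500)

    def test_seven_finite_domains(self, rng):
        cfg = cd.SimulationConfig()
        s = cd.simulate_cognition("CP", self._mean_covs(cfg, "CP"), cfg, rng)
        assert len(s) == 7 and np.isfinite(s.to_numpy()).all()


class TestStudy:
    def test_default_cohort_sizes_match_margins(self, default_study):
        cohort = default_study.cohort
        assert (cohort["group"] == "HC").sum() == 48
        assert (cohort["group"] == "MS").sum() == 176
        counts = cohort["phenotype_true"].value_counts()
        assert counts["CP"] == 95 and counts["mildly_CI"] == 37 and counts["CI"] == 44

    def test_same_seed_gives_identical_cohorts_and_images(self, small_config):
        a = cd.simulate_study(small_config)
        b = cd.simulate_study(small_config)
        pd.testing.assert_frame_equal(a.cohort, b.cohort)
        s = a.ms_subjects[0]
        assert np.array_equal(a.images[s].md, b.images[s].md)
        assert np.array_equal(a.images[s].cl_mask, b.images[s].cl_mask)

    def test_hc_images_have_no_lesions(self, default_study):
        for s in default_study.hc_subjects:
            assert default_study.images[s].cl_mask.sum() == 0

    def test_cl_prevalence_within_binomial_ci_of_target(self, default_study):
        ms = default_study.ms_subjects
        has_cl = np.array(
            [default_study.images[s].cl_mask.sum() > 0 for s in ms]
        )
        p0 = default_study.config.target_cl_prevalence
        se = np.sqrt(p0 * (1 - p0) / len(ms))
        assert abs(has_cl.mean() - p0) < 3 * se

    def test_lesional_nonlesional_sets_partition_regions(self, default_study):
        atlas = default_study.atlas
        s = default_study.ms_subjects[0]
        topo = cd.intersect_lesions(atlas, default_study.images[s].cl_mask)
        les, non = cd.lesional_region_split(topo)
        assert les | non == set(int(r) for r in atlas.region_ids)
        assert les & non == set()

    def test_network_lesion_counts_proportional_to_rates(self):
        """Chi-square goodness of fit of drawn counts against the rates."""
        cfg = cd.SimulationConfig(seed=2)
        atlas = cd.make_toy_atlas(cfg)
        rng = np.random.default_rng(2)
        nets = list(cfg.lesion_rate_by_network)
        totals = dict.fromkeys(nets, 0)
        for _ in range(500):
            _, counts = draw_lesions(atlas, "CP", cfg, rng)
            for n in nets:
                totals[n] += counts[n]
        obs = np.array([totals[n] for n in nets], dtype=float)
        rates = np.array([cfg.lesion_rate_by_network[n] for n in nets])
        exp = rates / rates.sum() * obs.sum()
        p = sps.chisquare(obs, exp).pvalue
        assert p > 0.01

    def test_domain_missingness_never_leaves_fewer_than_two(self, default_study):
        score_cols = [f"score_{d}" for d in DOMAINS]
        ms = default_study.cohort[default_study.cohort["group"] == "MS"]
        assert (ms[score_cols].notna().sum(axis=1) >= 2).all()

    def test_invalid_group_mix_rejected(self):
        with pytest.raises(ConfigError):
            cd.SimulationConfig(group_mix=(0.5, 0.5, 0.5)).validate()

    def test_config_yaml_roundtrip(self, tmp_path, small_config):
        path = tmp_path / "cfg.yaml"
        small_config.to_yaml(path)
        loaded = cd.SimulationConfig.from_yaml(path)
        assert loaded.n_hc == small_config.n_hc
        assert loaded.lesion_rate_by_network == small_config.lesion_rate_by_network
        pd.testing.assert_frame_equal(
            cd.simulate_study(loaded).cohort, cd.simulate_study(small_config).cohort
        )
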