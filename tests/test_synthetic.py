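"""Tests of the synthetic hose-biofilm generator: thickness field, TCC,
community table, B-scan rendering, and full determinism."""

import numpy as np
import pandas as pd
import pytest

import hosebiofilm as hb
from hosebiofilm.synthetic import base_proportions, render_bscan, section_ids


def _flat_cfg(**kw):
    params = dict(
        baseline_thickness_um=300.0,
        trend_slope_um_per_cm=0.0,
        smallscale_cv=0.0,
        seed=0,
    )
    params.update(kw)
    return hb.SimulationConfig(**params)


class TestThicknessField:
    def test_degenerate_no_noise_field_is_constant(self):
        field = hb.generate_thickness_field(_flat_cfg())
        for half in hb.HALVES:
            assert np.allclose(field.thickness_um[half], 300.0)
            assert np.allclose(field.section_means(half), 300.0)

    def test_field_spans_hose_and_is_nonnegative(self, control_field, control_cfg):
        assert control_field.positions_cm[0] == 0.0
        assert control_field.positions_cm[-1] == control_cfg.hose_length_cm
        for half in hb.HALVES:
            assert np.all(control_field.thickness_um[half] >= 0)

    def test_trend_slope_recovered_across_seeds(self):
        """OLS on per-section means recovers the configured 0.83 um/cm slope."""
        slopes = []
        covered = 0
        for seed in range(20):
            cfg = hb.control_hose_config(seed=seed)
            field = hb.generate_thickness_field(cfg)
            tr = hb.longitudinal_trend(
                field.section_means("top"), cfg.section_positions_cm()
            )
            slopes.append(tr.slope)
            covered += tr.ci95_slope[0] <= 0.83 <= tr.ci95_slope[1]
        se = np.std(slopes, ddof=1) / np.sqrt(len(slopes))
        assert abs(np.mean(slopes) - 0.83) < 4 * se
        assert covered >= 16  # ~95% nominal coverage

    def test_higher_smallscale_cv_gives_larger_adjacent_variation(self):
        """Paired over seeds: cv=0.24 produces strictly more small-scale
        variation than cv=0.12."""
        wins = 0
        for seed in range(15):
            avs = []
            for cv in (0.12, 0.24):
                cfg = hb.control_hose_config(smallscale_cv=cv, seed=seed)
                field = hb.generate_thickness_field(cfg)
                avs.append(hb.adjacent_variation(field.section_means("top")).mean)
            wins += avs[1] > avs[0]
        assert wins == 15

    def test_adjacent_variation_targets_configured_level(self):
        """smallscale_cv is the target adjacent-variation level (in %/100)."""
        means = {h: [] for h in hb.HALVES}
        for seed in range(15):
            field = hb.generate_thickness_field(hb.control_hose_config(seed=seed))
            for h in hb.HALVES:
                means[h].append(hb.adjacent_variation(field.section_means(h)).mean)
        assert np.mean(means["top"]) == pytest.approx(12.0, abs=1.5)
        assert np.mean(means["bottom"]) == pytest.approx(24.0, abs=3.0)

    def test_excessive_clipping_rejected(self):
        with pytest.raises(ValueError, match="clips"):
            hb.generate_thickness_field(_flat_cfg(baseline_thickness_um=-50.0))


class TestTCC:
    def test_perfect_correlation_is_affine_in_thickness(self, control_field):
        cfg = hb.control_hose_config(tcc_thickness_corr=1.0)
        tcc = hb.generate_tcc(control_field, cfg)
        t = control_field.section_mean_series()
        r, _ = hb.abundance_covariate_correlation(t, tcc)
        assert r == pytest.approx(1.0, abs=1e-12)
        coeffs = np.polyfit(t, tcc, 1)
        assert np.allclose(np.polyval(coeffs, t), tcc, rtol=1e-9)

    def test_zero_correlation_null(self, control_field):
        rs = []
        for seed in range(30):
            cfg = hb.control_hose_config(tcc_thickness_corr=0.0, seed=seed)
            field = hb.generate_thickness_field(cfg)
            tcc = hb.generate_tcc(field, cfg)
            r, _ = hb.abundance_covariate_correlation(
                field.section_mean_series(), tcc
            )
            rs.append(r)
        assert abs(np.mean(rs)) < 0.15

    def test_default_control_levels(self, control_field, control_cfg):
        """Defaults emulate the control hose: mean ~2.4e7, ~1-3.5e7 span."""
        tcc = hb.generate_tcc(control_field, control_cfg)
        assert tcc.mean() == pytest.approx(2.4e7, rel=0.1)
        assert tcc.min() > 0.5e7
        assert tcc.max() < 5e7
        assert 2.0 < hb.fold_range(tcc) < 6.0

    def test_invalid_inputs_rejected(self, control_field):
        with pytest.raises(ValueError):
            hb.control_hose_config(tcc_mean=-1.0)
        short = hb.SimulationConfig(hose_length_cm=12.0)
        with pytest.raises(ValueError, match="section count"):
            hb.generate_tcc(control_field, short)


class TestCommunity:
    def test_single_taxon_table(self):
        cfg = hb.SimulationConfig(
            hose_length_cm=12.0,
            n_taxa=1,
            dominant_profile=[("only", 0.999)],
            dominant_anticorr_pair=None,
            step_changes=[],
            missing_section_prob=0.0,
            reads_per_section=1000,
            seed=3,
        )
        table = hb.generate_community(cfg)
        assert (table.loc["only"] == 1000).all()
        assert table.shape == (1, 20)

    def test_column_sums_equal_read_depth(self, small_cfg):
        table = hb.generate_community(small_cfg)
        assert (table.sum(axis=0) == small_cfg.reads_per_section).all()
        assert table.dtypes.map(pd.api.types.is_integer_dtype).all()

    def test_taxon_labels_stable_and_complete(self, small_cfg):
        table = hb.generate_community(small_cfg)
        assert list(table.index[:3]) == [t for t, _ in small_cfg.dominant_profile]
        assert len(table.index) == small_cfg.n_taxa
        assert not table.index.duplicated().any()

    def test_missing_sections_are_dropped(self):
        cfg = hb.control_hose_config(missing_section_prob=0.2, seed=11)
        table = hb.generate_community(cfg)
        assert table.shape[1] < cfg.n_sections
        assert set(table.columns) <= set(section_ids(cfg))

    def test_base_proportions_sum_to_one(self, control_cfg):
        p = base_proportions(control_cfg)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)
        assert (p > 0).all()

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError, match="n_taxa"):
            hb.SimulationConfig(n_taxa=2)

    def test_dominant_share_matches_multinomial_expectation(self):
        """With spatial wobble off, the pooled top-3 share converges on the
        configured dominant mass (pure multinomial oracle)."""
        shares = []
        for seed in range(20):
            cfg = hb.SimulationConfig(
                dominant_profile=[("A", 0.25), ("B", 0.23), ("C", 0.10)],
                dominant_anticorr_pair=None,
                step_changes=[],
                taxon_wobble_sd=0.0,
                missing_section_prob=0.0,
                seed=seed,
            )
            table = hb.generate_community(cfg)
            dom = hb.dominant_taxa(table)
            shares.append(dom.cumulative_top_pct[2] / 100.0)
        assert np.mean(shares) == pytest.approx(0.58, abs=0.02)

    def test_step_change_recovered_by_window_contrast(self):
        """A +0.081 step on top sections 81-91 is recovered as a mean
        difference of ~0.081 against the preceding 11 sections."""
        diffs = []
        for seed in range(10):
            cfg = hb.control_hose_config(seed=seed, missing_section_prob=0.0)
            table = hb.generate_community(cfg)
            rel = hb.relative_abundance(table)
            top_ids = [f"top_{i:03d}" for i in range(1, 101)]
            series = rel.loc["TM6_Dependentiae"].reindex(top_ids).to_numpy(float)
            wc = hb.window_contrast(series, (69, 80), (80, 91))
            diffs.append(wc.difference)
        assert np.mean(diffs) == pytest.approx(0.081, abs=0.03)

    def test_pooled_abundance_converges_with_read_depth(self):
        """Known-truth convergence: deeper sequencing pulls the pooled
        dominant shares toward the configured proportions."""
        errs = {}
        for reads in (500, 50_000):
            per_seed = []
            for seed in range(10):
                cfg = hb.SimulationConfig(
                    hose_length_cm=12.0,
                    taxon_wobble_sd=0.0,
                    dominant_anticorr_pair=None,
                    step_changes=[],
                    missing_section_prob=0.0,
                    reads_per_section=reads,
                    seed=seed,
                )
                table = hb.generate_community(cfg)
                pooled = table.sum(axis=1) / table.to_numpy().sum()
                expected = base_proportions(cfg)
                per_seed.append(
                    float(np.abs(pooled[:3] - expected[:3]).max())
                )
            errs[reads] = np.mean(per_seed)
        assert errs[50_000] < errs[500]
        assert errs[50_000] < 0.01


class TestRendering:
    def test_flat_segment_truth_rows(self, clean_img_cfg):
        img = render_bscan(np.full(500, 100.0), clean_img_cfg, seed=0)
        gap = img.truth_substratum_rows - img.truth_surface_rows
        assert (gap == 50).all()  # 100 um / 2 um per px

    def test_zero_thickness_interfaces_coincide(self, clean_img_cfg):
        img = render_bscan(np.zeros(500), clean_img_cfg, seed=0)
        assert (img.truth_surface_rows == img.truth_substratum_rows).all()
        assert not (img.data == clean_img_cfg.biofilm_level).any()

    def test_thickness_beyond_depth_rejected(self, clean_img_cfg):
        with pytest.raises(ValueError, match="imageable depth"):
            render_bscan(np.full(500, 990.0), clean_img_cfg, seed=0)

    def test_wrong_segment_length_rejected(self, clean_img_cfg):
        with pytest.raises(ValueError, match="column thicknesses"):
            render_bscan(np.full(100, 50.0), clean_img_cfg, seed=0)

    def test_artifacts_bias_then_masking_repairs(self, control_field):
        """Floating-debris artifacts inflate the unmasked thickness; masking
        their boxes restores agreement with ground truth within 1 axial px."""
        img_cfg = hb.ImagingConfig(noise_sd=0.0, artifact_rate=2.0)
        n_with = 0
        for half, piece, im, image in hb.render_hose(control_field, img_cfg, seed=5):
            if not image.artifact_boxes:
                continue
            truth = (
                image.truth_substratum_rows - image.truth_surface_rows
            ).mean() * img_cfg.axial_pixel_um
            unmasked = hb.measure_image(image, img_cfg).mean_um
            masked = hb.measure_image(
                image, img_cfg, boxes=image.artifact_boxes
            ).mean_um
            assert unmasked > truth
            assert abs(masked - truth) <= img_cfg.axial_pixel_um
            n_with += 1
            if n_with >= 5:
                break
        assert n_with >= 5


class TestDeterminism:
    def test_identical_seed_bitwise_identical_outputs(self, control_cfg):
        st1, c1, f1 = hb.simulate_hose(control_cfg)
        st2, c2, f2 = hb.simulate_hose(hb.control_hose_config())
        pd.testing.assert_frame_equal(st1, st2)
        pd.testing.assert_frame_equal(c1, c2)
        for h in hb.HALVES:
            assert np.array_equal(f1.thickness_um[h], f2.thickness_um[h])

    def test_image_rendering_deterministic(self, control_field):
        img_cfg = hb.ImagingConfig(noise_sd=8.0, artifact_rate=1.0)
        a = next(iter(hb.render_hose(control_field, img_cfg, seed=9)))[3]
        b = next(iter(hb.render_hose(control_field, img_cfg, seed=9)))[3]
        assert np.array_equal(a.data, b.data)

    def test_streams_are_independent(self, control_cfg):
        """Changing community parameters must not shift the thickness field."""
        f1 = hb.generate_thickness_field(control_cfg)
        f2 = hb.generate_thickness_field(
            hb.control_hose_config(n_taxa=350, reads_per_section=1000)
        )
        for h in hb.HALVES:
            assert np.array_equal(f1.thickness_um[h], f2.thickness_um[h])

    def test_field_vs_image_section_means_agree(self, control_field, clean_img_cfg):
        """Section means computed from the field directly and via rendered
        images + extraction (noise off) agree within 1 axial pixel."""
        layout = hb.HoseLayout()
        means = []
        for half, piece, im, image in hb.render_hose(
            control_field, clean_img_cfg, layout, seed=0
        ):
            means.append(hb.measure_image(image, clean_img_cfg).mean_um)
            if len(means) == layout.images_per_piece:  # first piece, top half
                break
        sections = hb.aggregate_sections(means, layout.images_per_section)
        truth = control_field.section_means("top")[: len(sections)]
        assert np.abs(sections - truth).max() <= clean_img_cfg.axial_pixel_um
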