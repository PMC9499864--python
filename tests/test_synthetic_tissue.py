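"""Simulator: kinetics, determinism, noiseless exactness, oracle tables."""

import dataclasses

import numpy as np
import pytest

from spacetrace import synthetic_tissue as st
from spacetrace.errors import ValidationError
from spacetrace.isotope_correction import correction_matrix, correct_matrix
from spacetrace.dynamics import fraction_enrichment


class TestKineticModel:
    def test_zero_at_t0(self):
        assert st.kinetic_model(0.0, 0.4, 0.02) == 0.0

    def test_saturates_at_plateau(self):
        assert st.kinetic_model(1e9, 0.4, 0.02) == pytest.approx(0.4)

    def test_worked_value(self):
        # 0.4 * (1 - exp(-0.02 * 60)) = 0.4 * (1 - e^-1.2)
        assert st.kinetic_model(60.0, 0.4, 0.02) == pytest.approx(
            0.4 * (1 - np.exp(-1.2))
        )

    def test_plateau_outside_unit_interval_errors(self):
        with pytest.raises(ValidationError):
            st.kinetic_model(10.0, 1.5, 0.02)


class TestGenerate:
    def test_deterministic_per_seed(self, small_config):
        c1, l1, _ = st.generate(small_config, seed=5)
        c2, l2, _ = st.generate(small_config, seed=5)
        np.testing.assert_array_equal(c1.intensities, c2.intensities)
        np.testing.assert_array_equal(
            l1[0].intensities, l2[0].intensities
        )

    def test_sections_have_independent_noise(self, small_config):
        _, labeled, _ = st.generate(small_config, seed=5)
        assert not np.array_equal(
            labeled[0].intensities[:, :5], labeled[1].intensities[:, :5]
        )

    def test_noiseless_pixels_copy_archetypes(self, small_config):
        cfg = dataclasses.replace(small_config, noise_cv=0.0, tic_cv=0.0)
        control, _, truth = st.generate(cfg, seed=1)
        types = truth.type_maps["control"]
        lipids = control.intensities[:, : cfg.n_lipids]
        for t in range(cfg.n_types):
            rows = lipids[types == t]
            np.testing.assert_allclose(
                rows,
                np.broadcast_to(truth.lipid_archetypes[t], rows.shape),
                rtol=1e-12,
            )

    def test_t0_control_shows_natural_abundance_pattern(self, small_config):
        cfg = dataclasses.replace(small_config, noise_cv=0.0, tic_cv=0.0)
        control, _, truth = st.generate(cfg, seed=1)
        name, cc, _mz = cfg.metabolites[0]
        fids = [name] + [f"{name}_M+{n}" for n in range(1, cc + 1)]
        M = control.subset_features(fids).intensities
        frac = M / M.sum(axis=1, keepdims=True)
        cm = correction_matrix(cc, cfg.p_c13)
        np.testing.assert_allclose(frac[0], cm.matrix[:, 0], atol=1e-12)

    def test_correction_recovers_configured_labeling_exactly(
        self, small_config
    ):
        # correct_distribution then fraction_enrichment undoes the
        # generator's convolution: fractions equal (1-f, f*split) exactly
        cfg = dataclasses.replace(small_config, noise_cv=0.0, tic_cv=0.0)
        _, labeled, truth = st.generate(cfg, seed=1)
        sec = labeled[-1]
        types = truth.type_maps[sec.section_id]
        name, cc, _mz = cfg.metabolites[0]
        fids = [name] + [f"{name}_M+{n}" for n in range(1, cc + 1)]
        M = sec.subset_features(fids).intensities
        fr = fraction_enrichment(correct_matrix(M, correction_matrix(cc, cfg.p_c13)))
        kin = truth.kinetics[(types[0], name, "glc13")]
        f = st.kinetic_model(sec.timepoint_min, kin.plateau, kin.rate)
        expected = np.zeros(cc + 1)
        expected[0] = 1 - f
        for n, w in kin.split.items():
            expected[n] = f * w
        np.testing.assert_allclose(fr[0], expected, atol=1e-6)

    def test_grid_too_small_rejected(self):
        with pytest.raises(ValidationError):
            st.SimConfig(shape=(10, 10))

    def test_replicate_shares_truth_but_not_noise(self, small_config):
        _, _, truth = st.generate(small_config, seed=5)
        r1 = st.generate_replicate(truth, 100, "rep1", "glc13", 120.0)
        r2 = st.generate_replicate(truth, 101, "rep2", "glc13", 120.0)
        assert r1.n_pixels == r2.n_pixels
        assert not np.array_equal(r1.intensities, r2.intensities)
        assert "rep1" in truth.type_maps and "rep2" in truth.type_maps


class TestTruthEnrichment:
    def test_zero_plateau_gives_zero(self, small_config):
        _, _, truth = st.generate(small_config, seed=3)
        key = next(iter(truth.kinetics))
        truth.kinetics[key] = st.Kinetics(
            plateau=0.0, rate=0.02, split=truth.kinetics[key].split
        )
        df = st.truth_enrichment(
            truth, "glc13", timepoints=np.array([0.0, 60.0, 120.0])
        )
        t, name, _ = key
        rows = df.query(
            f"type == {t} and metabolite == '{name}' and isotopologue > 0"
        )
        assert (rows["auc_enrichment"] == 0).all()

    def test_fast_kinetics_approach_plateau(self, small_config):
        _, _, truth = st.generate(small_config, seed=3)
        key = next(iter(truth.kinetics))
        truth.kinetics[key] = st.Kinetics(
            plateau=0.5, rate=1e3, split={truth.config.metabolites[0][1]: 1.0}
        )
        df = st.truth_enrichment(truth, "glc13", fine=20001,
                                 timepoints=np.array([0.0, 120.0]))
        t, name, _ = key
        cc = truth.config.metabolites[0][1]
        row = df.query(
            f"type == {t} and metabolite == '{name}' and isotopologue == {cc}"
        )
        assert row["auc_enrichment"].iloc[0] == pytest.approx(0.5, rel=1e-3)

    def test_fine_grid_matches_closed_form(self, small_config):
        _, _, truth = st.generate(small_config, seed=3)
        (t, name, tracer), kin = next(iter(truth.kinetics.items()))
        T = 120.0
        df = st.truth_enrichment(
            truth, tracer, timepoints=np.array([0.0, T]), fine=200001
        )
        # closed form: P * (1 - (1 - exp(-kT)) / (kT))
        P, k = kin.plateau, kin.rate
        expected = P * (1 - (1 - np.exp(-k * T)) / (k * T))
        n_max = max(kin.split)
        got = df.query(
            f"type == {t} and metabolite == '{name}' "
            f"and isotopologue == {n_max}"
        )["auc_enrichment"].iloc[0]
        assert got == pytest.approx(expected * kin.split[n_max], rel=1e-6)
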