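"""Ground-truth generator: uptake physics, rendering, cohort structure."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qdect.synthetic import (
    BathState,
    MU_BISMUTH,
    TRUE_COEFFICIENTS,
    VolumeGeometry,
    default_tissue_model,
    generate_cohort,
    generate_phantom_table,
    generate_sample_volume,
    generate_uptake_profiles,
)

Z = np.linspace(0.0, 1.0, 101)


class TestUptakeProfiles:
    def test_interior_empty_at_time_zero(self):
        model = default_tissue_model()
        ci, cgd = generate_uptake_profiles(model, BathState(), time_h=0.0, z=Z)
        assert np.all(ci[1:] == 0) and np.all(cgd[1:] == 0)
        assert ci[0] > 0 and cgd[0] > 0

    def test_surface_equals_equilibrium_partition(self):
        model = default_tissue_model()
        bath = BathState()
        ci, cgd = generate_uptake_profiles(model, bath, time_h=2.0, z=np.array([0.0]))
        k_i = 2.4 * model.fcd_profile(0.0) * model.water_profile(0.0)
        k_gd = 0.5 * model.water_profile(0.0) / model.steric_profile(0.0)
        assert ci[0] == pytest.approx(k_i * bath.c_iodine)
        assert cgd[0] == pytest.approx(k_gd * bath.c_gadolinium)

    def test_fcd_loss_lowers_ca4_only(self):
        """Scaling FCD down suppresses cationic-agent uptake but leaves the
        neutral agent untouched (the uptake mechanism's directionality)."""
        bath = BathState()
        full = default_tissue_model(fcd_scale=1.0)
        low = default_tissue_model(fcd_scale=0.2)
        sup = Z <= 0.1
        ci_f, cgd_f = generate_uptake_profiles(full, bath, 2.0, z=Z)
        ci_l, cgd_l = generate_uptake_profiles(low, bath, 2.0, z=Z)
        assert ci_l[sup].mean() < ci_f[sup].mean()
        assert np.allclose(cgd_l, cgd_f)

    @settings(deadline=None, derandomize=True)
    @given(t=st.floats(0.1, 6.0), dt=st.floats(0.01, 2.0))
    def test_front_monotonicity(self, t, dt):
        model = default_tissue_model()
        bath = BathState()
        ci, cgd = generate_uptake_profiles(model, bath, t, z=Z)
        ci2, _ = generate_uptake_profiles(model, bath, t + dt, z=Z)
        # non-increasing in depth for monotone partition-factor-free front:
        front_now = ci / np.maximum(2.4 * model.fcd_profile(Z) * model.water_profile(Z), 1e-12)
        assert np.all(np.diff(front_now) <= 1e-12)
        # non-decreasing in time at fixed depth
        assert np.all(ci2 >= ci - 1e-12)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            generate_uptake_profiles(default_tissue_model(), BathState(), -1.0)
        with pytest.raises(ValueError):
            generate_uptake_profiles(default_tissue_model(), BathState(), 1.0, d_iodine=-5)


class TestTissueModels:
    def test_injured_requires_cracks(self):
        from qdect.synthetic import TissueModel

        with pytest.raises(ValueError, match="crack"):
            TissueModel(group="injured", crack_spec=None)

    def test_depleted_fcd_integral_below_intact(self):
        intact = default_tissue_model("intact")
        depleted = default_tissue_model("pg_depleted")
        assert np.trapezoid(depleted.fcd_profile(Z), Z) < np.trapezoid(
            intact.fcd_profile(Z), Z
        )
        # residual deep fraction survives
        assert depleted.fcd_profile(np.array([1.0]))[0] > 0.5 * intact.fcd_profile(
            np.array([1.0])
        )[0]


class TestPhantomTable:
    def test_noiseless_table_lies_on_generating_lines(self):
        table = generate_phantom_table(noise_sigma=0.0)
        ca4_32 = table[(table.agent == "CA4+") & (table.energy_keV == 32)]
        expected = 2.1 + 0.38 * ca4_32.concentration_mg_per_mL
        assert np.allclose(ca4_32.mean_attenuation, expected)
        assert set(table.agent) == {"CA4+", "gadoteridol"}


class TestSampleVolume:
    def test_zero_agent_bath_matches_baseline(self):
        """With no agents and no noise, the contrast acquisition is the baseline."""
        model = default_tissue_model()
        empty = BathState(c_iodine=0.0, c_gadolinium=0.0, c_bismuth=0.0)
        acq, _ = generate_sample_volume(model, empty, noise_sigma=0.0, seed=11)
        assert np.array_equal(acq.vol_32, acq.baseline_32)
        assert np.array_equal(acq.vol_34_first, acq.baseline_34)

    def test_bismuth_brightens_bath_at_both_energies(self):
        model = default_tissue_model()
        kw = dict(noise_sigma=0.0, seed=11)
        acq_d, gt_d = generate_sample_volume(model, BathState.for_mixture("dual"), **kw)
        acq_t, gt_t = generate_sample_volume(model, BathState.for_mixture("triple"), **kw)
        bath = gt_d.labels == 0
        for vd, vt in ((acq_d.vol_32, acq_t.vol_32), (acq_d.vol_34_first, acq_t.vol_34_first)):
            assert vt[bath].mean() > vd[bath].mean()

    def test_triple_mixture_boosts_interface_contrast(self):
        """Bath-minus-cartilage contrast at 2 h is larger with the
        nanoparticle-supplemented bath — the rationale for the triple mixture."""
        model = default_tissue_model()
        kw = dict(noise_sigma=0.0, seed=11)
        acq_d, gt = generate_sample_volume(model, BathState.for_mixture("dual"), **kw)
        acq_t, _ = generate_sample_volume(model, BathState.for_mixture("triple"), **kw)
        bath, cart = gt.labels == 0, gt.labels == 1
        for vd, vt in ((acq_d.vol_32, acq_t.vol_32), (acq_d.vol_34_first, acq_t.vol_34_first)):
            contrast_dual = abs(vd[bath].mean() - vd[cart].mean())
            contrast_triple = abs(vt[bath].mean() - vt[cart].mean())
            assert contrast_triple > contrast_dual

    def test_mass_conservation_across_acquisitions(self):
        model = default_tissue_model("injured")
        bath = BathState.for_mixture("triple")
        geom = VolumeGeometry()
        acq, gt = generate_sample_volume(model, bath, geometry=geom, noise_sigma=0.0, seed=2)
        voxvol = geom.voxel_um**3
        n_cart = int((gt.labels == 1).sum() + gt.crack_mask.sum())
        v_bath = bath.volume_ratio * n_cart * voxvol
        # truth fields are stored at the middle acquisition
        state = gt.bath_states[1]
        tissue_mass = gt.c_iodine_field[gt.labels == 1].sum() * voxvol
        total = state.c_iodine * v_bath + tissue_mass
        assert total == pytest.approx(bath.c_iodine * v_bath, rel=1e-3)
        # the bath strictly depletes over the sequential scans
        ci = [s.c_iodine for s in gt.bath_states]
        assert ci[0] > ci[1] > ci[2]
        assert ci[0] < bath.c_iodine

    def test_crack_voxels_carry_exact_bath_concentrations(self):
        model = default_tissue_model("injured")
        bath = BathState.for_mixture("triple")
        acq, gt = generate_sample_volume(model, bath, noise_sigma=0.0, seed=3)
        assert gt.crack_mask.any()
        state = gt.bath_states[1]
        assert np.allclose(gt.c_iodine_field[gt.crack_mask], state.c_iodine)
        assert np.allclose(gt.c_bismuth_field[gt.crack_mask], bath.c_bismuth)
        # bismuth never enters tissue; masks are disjoint
        assert np.all(gt.c_bismuth_field[gt.labels == 1] == 0)
        assert not np.any(gt.crack_mask & (gt.labels == 1))

    def test_seeded_rendering_is_byte_identical(self):
        model = default_tissue_model()
        a1, _ = generate_sample_volume(model, BathState(), seed=99)
        a2, _ = generate_sample_volume(model, BathState(), seed=99)
        for v1, v2 in zip(a1.volumes + [a1.baseline_32], a2.volumes + [a2.baseline_32]):
            assert np.array_equal(v1, v2)

    def test_bad_geometry_rejected(self):
        with pytest.raises(ValueError):
            VolumeGeometry(voxel_um=0.0)


class TestCohort:
    def test_nine_patellae_give_27_dual_and_27_triple(self):
        cohort = generate_cohort(n_patellae=9, seed=0)
        assert len(cohort) == 54
        assert sum(s.mixture == "dual" for s in cohort) == 27
        assert sum(s.mixture == "triple" for s in cohort) == 27
        assert len({s.sample_id for s in cohort}) == 54

    def test_halves_share_tissue_model_up_to_thickness_jitter(self):
        cohort = generate_cohort(n_patellae=2, seed=1)
        by_id = {s.sample_id: s for s in cohort}
        a = by_id["P01_intact_dual"]
        b = by_id["P01_intact_triple"]
        z = np.linspace(0, 1, 11)
        assert np.allclose(a.model.fcd_profile(z), b.model.fcd_profile(z))
        assert abs(a.model.thickness_um / b.model.thickness_um - 1) < 0.15

    def test_cohort_is_deterministic(self):
        c1 = generate_cohort(n_patellae=3, seed=5)
        c2 = generate_cohort(n_patellae=3, seed=5)
        assert [s.seed for s in c1] == [s.seed for s in c2]
        assert all(
            np.allclose(
                a.model.fcd_profile(np.linspace(0, 1, 7)),
                b.model.fcd_profile(np.linspace(0, 1, 7)),
            )
            for a, b in zip(c1, c2)
        )

    def test_depleted_group_has_lower_mean_fcd(self):
        cohort = generate_cohort(n_patellae=5, seed=2)
        z = np.linspace(0, 1, 101)
        mean_fcd = lambda g: np.mean(
            [np.trapezoid(s.model.fcd_profile(z), z) for s in cohort if s.group == g]
        )
        assert mean_fcd("pg_depleted") < mean_fcd("intact")
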