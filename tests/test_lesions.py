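"""Lesion metrics, aggregation identities, and the adaptive delineator."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import petsurv as ps
from petsurv.errors import ConfigError, NoLesionAtSeedError


def _volume(values, voxel=2.0):
    return ps.PETVolume(values=values, voxel_size=(voxel,) * 3)


class TestLesionMetrics:
    def test_single_voxel(self):
        values = np.ones((4, 4, 4))
        values[1, 1, 1] = 5.0
        mask = np.zeros((4, 4, 4), bool)
        mask[1, 1, 1] = True
        # 4 mm isotropic voxels: 64 mm^3 = 0.064 ml each
        vol = ps.PETVolume(values=values, voxel_size=(4.0, 4.0, 4.0))
        m = ps.compute_lesion_metrics(vol, mask)
        assert m.suv_max == 5.0 and m.suv_mean == 5.0
        assert m.mtv == pytest.approx(0.064)
        assert m.tlg == pytest.approx(0.32)

    def test_hundred_voxel_brute_force(self):
        """Explicit sums over a 100-voxel mask with values 1..100."""
        values = np.zeros((5, 5, 5))
        flat = values.reshape(-1)
        flat[:100] = np.arange(1, 101)
        mask = np.zeros(125, bool)
        mask[:100] = True
        vol = ps.PETVolume(values=values,
                           voxel_size=(np.cbrt(100.0),) * 3)  # 0.1 ml voxels
        m = ps.compute_lesion_metrics(vol, mask.reshape(5, 5, 5))
        assert m.mtv == pytest.approx(10.0)
        assert m.suv_mean == pytest.approx(50.5)
        assert m.tlg == pytest.approx(505.0)

    def test_tlg_definitional_identity(self, sphere_phantom):
        vol, lesions, _ = sphere_phantom
        m = ps.compute_lesion_metrics(vol, lesions.lesions[0].mask)
        assert m.tlg / m.mtv == pytest.approx(m.suv_mean, rel=1e-12)

    def test_empty_mask_rejected(self):
        vol = _volume(np.ones((4, 4, 4)))
        with pytest.raises(ConfigError, match="empty"):
            ps.compute_lesion_metrics(vol, np.zeros((4, 4, 4), bool))


class TestAggregation:
    def test_no_nodes_identity(self):
        prim = ps.LesionMetrics(suv_max=7, suv_mean=4, mtv=10, tlg=40)
        p = ps.aggregate_patient(prim, [])
        assert (p.suv_all, p.mtv_all, p.tlg_all) == (
            p.suv_prim, p.mtv_prim, p.tlg_prim)

    def test_two_lesion_worked_example(self):
        prim = ps.LesionMetrics(suv_max=7, suv_mean=4, mtv=10, tlg=40)
        node = ps.LesionMetrics(suv_max=9, suv_mean=2, mtv=5, tlg=10)
        p = ps.aggregate_patient(prim, [node])
        assert p.mtv_all == pytest.approx(15)
        assert p.tlg_all == pytest.approx(50)            # = 40 + 10
        assert p.tlg_all / p.mtv_all == pytest.approx(50 / 15)  # overall mean
        assert p.suv_all == 9                            # max rule

    def test_two_lesion_voxelwise_union_oracle(self):
        """Aggregation equals brute-force voxelwise sums on the union mask."""
        cfg = ps.PhantomConfig(
            grid_shape=(48, 48, 48), voxel_size_mm=(2, 2, 2),
            lesions=[
                ps.LesionSpec(center_mm=(30, 30, 30), radii_mm=(8, 8, 8),
                              peak_suv=8.0, role="primary"),
                ps.LesionSpec(center_mm=(66, 66, 66), radii_mm=(5, 5, 5),
                              peak_suv=5.0, role="node"),
            ],
        )
        vol, lesions, _ = ps.generate_phantom(cfg)
        p = ps.patient_params_from_lesions(vol, lesions)
        union = lesions.lesions[0].mask | lesions.lesions[1].mask
        vals = vol.values[union]
        mtv_union = union.sum() * vol.voxel_volume_ml
        assert p.mtv_all == pytest.approx(mtv_union, rel=1e-12)
        assert p.tlg_all == pytest.approx(mtv_union * vals.mean(), rel=1e-12)
        assert p.suv_all == vals.max()

    def test_missing_primary_rejected(self):
        with pytest.raises(ConfigError, match="primary"):
            ps.aggregate_patient(None, [])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(
            st.tuples(
                st.floats(0.5, 20.0),   # suv_mean
                st.floats(0.1, 200.0),  # mtv
            ),
            min_size=1,
            max_size=6,
        )
    )
    def test_tlg_additivity_property(self, lesion_params):
        """TLG_all via the volume-weighted overall mean equals the sum of

        per-lesion TLG for any disjoint lesion configuration."""
        metrics = [
            ps.LesionMetrics(suv_max=sm * 1.7, suv_mean=sm, mtv=mtv,
                             tlg=mtv * sm)
            for sm, mtv in lesion_params
        ]
        p = ps.aggregate_patient(metrics[0], metrics[1:])
        assert p.tlg_all == pytest.approx(sum(m.tlg for m in metrics),
                                          rel=1e-9)


class TestDelineation:
    def test_noiseless_uniform_lesion_recovered_exactly(self, sphere_phantom):
        """Binary image with threshold between levels: MTV error is zero."""
        vol, lesions, truth = sphere_phantom
        out = ps.delineate_adaptive(vol, [ps.Seed((48, 48, 48))])
        assert len(out) == 1
        m = ps.compute_lesion_metrics(vol, out.lesions[0].mask)
        assert m.mtv == pytest.approx(truth.lesions[0].volume_ml, abs=0)
        assert np.array_equal(out.lesions[0].mask, lesions.lesions[0].mask)

    def test_blurred_sphere_recovery_vs_threshold_oracle(self):
        """PSF-blurred sphere: recovered MTV within 15% of 4.19 ml and

        consistent with an independent fixed-threshold sweep using the true
        background region."""
        cfg = ps.PhantomConfig(
            grid_shape=(48, 48, 48), voxel_size_mm=(2, 2, 2),
            background_suv=1.0, psf_fwhm_mm=6.0,
            lesions=[ps.LesionSpec(center_mm=(48, 48, 48),
                                   radii_mm=(10, 10, 10), peak_suv=8.0)],
        )
        vol, lesions, truth = ps.generate_phantom(cfg)
        out = ps.delineate_adaptive(vol, [ps.Seed((48, 48, 48))])
        mtv = ps.compute_lesion_metrics(vol, out.lesions[0].mask).mtv
        analytic = 4.0 / 3.0 * np.pi
        assert abs(mtv - analytic) / analytic < 0.15
        # oracle: T = BG + 0.39 (max - BG), BG measured on the known
        # background (far from the pre-blur lesion mask)
        from scipy import ndimage
        far = ~ndimage.binary_dilation(lesions.lesions[0].mask,
                                       iterations=6)
        bg = vol.values[far].mean()
        t_oracle = bg + 0.39 * (vol.values.max() - bg)
        oracle_mtv = (vol.values >= t_oracle).sum() * vol.voxel_volume_ml
        assert mtv == pytest.approx(oracle_mtv, rel=0.10)

    def test_seed_in_background_raises(self, sphere_phantom):
        vol, _, _ = sphere_phantom
        with pytest.raises(NoLesionAtSeedError):
            ps.delineate_adaptive(vol, [ps.Seed((4, 4, 4))])

    def test_beta_monotonicity(self):
        """A larger threshold fraction never increases the recovered MTV."""
        cfg = ps.PhantomConfig(
            grid_shape=(48, 48, 48), voxel_size_mm=(2, 2, 2),
            background_suv=1.0, psf_fwhm_mm=8.0,
            lesions=[ps.LesionSpec(center_mm=(48, 48, 48),
                                   radii_mm=(12, 10, 10), peak_suv=9.0)],
        )
        vol, _, _ = ps.generate_phantom(cfg)
        mtvs = []
        for beta in (0.25, 0.39, 0.5, 0.65):
            out = ps.delineate_adaptive(
                vol, [ps.Seed((48, 48, 48))],
                ps.DelineationConfig(threshold_fraction=beta))
            mtvs.append(ps.compute_lesion_metrics(
                vol, out.lesions[0].mask).mtv)
        assert all(a >= b for a, b in zip(mtvs, mtvs[1:]))

    def test_two_seeds_in_one_lesion_merge(self, sphere_phantom):
        vol, _, _ = sphere_phantom
        out = ps.delineate_adaptive(
            vol, [ps.Seed((48, 48, 48), role="primary"),
                  ps.Seed((50, 48, 48), role="node")])
        assert len(out) == 1
        assert out.lesions[0].role == "primary"  # first seed's role wins

    def test_voxel_size_consistency(self):
        """MTV on a 1 mm grid vs its 2 mm counterpart agree within one

        voxel shell of the sphere surface."""
        mtvs = {}
        for voxel in (1.0, 2.0):
            n = int(64 / voxel)
            cfg = ps.PhantomConfig(
                grid_shape=(n, n, n), voxel_size_mm=(voxel,) * 3,
                lesions=[ps.LesionSpec(center_mm=(32, 32, 32),
                                       radii_mm=(10, 10, 10), peak_suv=8.0)],
            )
            vol, _, truth = ps.generate_phantom(cfg)
            out = ps.delineate_adaptive(vol, [ps.Seed((32, 32, 32))])
            mtvs[voxel] = ps.compute_lesion_metrics(
                vol, out.lesions[0].mask).mtv
        shell_ml = 4 * np.pi * 10.0**2 * 2.0 / 1000.0  # surface x coarse voxel
        assert abs(mtvs[1.0] - mtvs[2.0]) < shell_ml
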