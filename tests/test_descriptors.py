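"""Statistical descriptors, bins and ensemble medians."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dtdmri import (
    DEFAULT_BINS,
    DiscreteDTD,
    bin_resolve,
    build_protocol,
    dtd_moments,
    ensemble_medians,
    make_preset_voxel,
    orientation_rgb,
    quality_maps,
)
from dtdmri.inversion import DTDEnsemble


def make_dtd(rows):
    """rows: (w, d_par, d_perp, theta, phi)."""
    arr = np.array(rows, dtype=float)
    return DiscreteDTD(arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3], arr[:, 4])


class TestMoments:
    def test_two_point_mix(self):
        """Equal-weight pair at (3.1e-9, 0) and (0.7e-9, 0.2)."""
        m = dtd_moments(make_preset_voxel("MIX").dtd)
        assert m.e_diso == pytest.approx(1.9e-9, rel=1e-12)
        assert m.e_ddelta2 == pytest.approx(0.1, rel=1e-12)
        assert m.var_diso == pytest.approx(1.44e-18, rel=1e-12)
        assert m.cov_diso_ddelta2 == pytest.approx(-0.12e-9, rel=1e-12)

    def test_single_component_has_zero_spread(self):
        m = dtd_moments(make_dtd([(2.0, 1.5e-9, 0.5e-9, 0.3, 0.4)]))
        assert m.var_diso == pytest.approx(0.0, abs=1e-30)
        assert m.var_ddelta2 == pytest.approx(0.0, abs=1e-16)
        assert m.cov_diso_ddelta2 == pytest.approx(0.0, abs=1e-24)

    def test_weight_rescaling_only_scales_s0(self):
        base = make_dtd([(1.0, 2e-9, 1e-9, 0.1, 0.2), (2.0, 1e-9, 0.5e-9, 1.0, 2.0)])
        scaled = DiscreteDTD(base.w * 7, base.d_par, base.d_perp, base.theta, base.phi)
        m1, m2 = dtd_moments(base), dtd_moments(scaled)
        assert m2.s0 == pytest.approx(7 * m1.s0)
        assert m2.e_diso == pytest.approx(m1.e_diso, rel=1e-12)
        assert m2.var_diso == pytest.approx(m1.var_diso, rel=1e-12)

    def test_empty_dtd_is_flagged(self):
        m = dtd_moments(DiscreteDTD.empty())
        assert not m.defined
        assert np.isnan(m.e_diso)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), n=st.integers(1, 8))
    def test_against_brute_force_oracle(self, seed, n):
        """Weighted moments match an explicit per-component summation."""
        rng = np.random.default_rng(seed)
        dtd = DiscreteDTD(
            rng.uniform(0.1, 1, n),
            10 ** rng.uniform(-11, -8.5, n),
            10 ** rng.uniform(-11, -8.5, n),
            rng.uniform(0, np.pi, n),
            rng.uniform(0, 2 * np.pi, n),
        )
        m = dtd_moments(dtd)
        wsum = sum(c.w for c in dtd.components)
        ex = sum(c.w * c.d_iso for c in dtd.components) / wsum
        ey = sum(c.w * c.d_delta**2 for c in dtd.components) / wsum
        var_x = sum(c.w * (c.d_iso - ex) ** 2 for c in dtd.components) / wsum
        cov = (
            sum(c.w * (c.d_iso - ex) * (c.d_delta**2 - ey) for c in dtd.components)
            / wsum
        )
        assert m.e_diso == pytest.approx(ex, rel=1e-12)
        assert m.e_ddelta2 == pytest.approx(ey, rel=1e-12)
        assert m.var_diso == pytest.approx(var_x, rel=1e-9, abs=1e-30)
        assert m.cov_diso_ddelta2 == pytest.approx(cov, rel=1e-9, abs=1e-24)


class TestBins:
    def test_default_bins_are_disjoint(self):
        """Interval arithmetic: no (D_iso, D_delta2) rectangle overlap."""
        for i, a in enumerate(DEFAULT_BINS):
            for b in DEFAULT_BINS[i + 1:]:
                iso_overlap = min(a.d_iso[1], b.d_iso[1]) > max(a.d_iso[0], b.d_iso[0])
                d2_overlap = min(a.d_delta2[1], b.d_delta2[1]) > max(
                    a.d_delta2[0], b.d_delta2[0]
                )
                assert not (iso_overlap and d2_overlap)

    def test_csf_preset_is_pure_big(self):
        res = bin_resolve(make_preset_voxel("CSF").dtd)
        assert res["big"].fraction == 1.0
        assert res["thin"].fraction == 0.0
        assert res["thick"].fraction == 0.0
        assert not res["thin"].defined

    def test_component_in_thin_bin(self):
        # D_iso = 1e-9, D_delta^2 = 0.5: d_par/d_perp from (1e-9, sqrt(0.5))
        dd = np.sqrt(0.5)
        dtd = make_dtd([(1.0, 1e-9 * (1 + 2 * dd), 1e-9 * (1 - dd), 0, 0)])
        res = bin_resolve(dtd)
        assert res["thin"].fraction == 1.0

    def test_mix_splits_between_big_and_thick(self):
        res = bin_resolve(make_preset_voxel("MIX").dtd)
        assert res["big"].fraction == pytest.approx(0.5)
        assert res["thick"].fraction == pytest.approx(0.5)
        assert res["thin"].fraction == 0.0

    def test_boundary_membership_lower_inclusive(self):
        iso = make_dtd([(1.0, 1e-9, 1e-9, 0, 0)])  # d_delta2 = 0 exactly
        res = bin_resolve(iso)
        assert res["thick"].fraction == 1.0
        stick = make_dtd([(1.0, 1e-9, 0.0, 0, 0)])  # d_delta2 = 1 exactly
        assert bin_resolve(stick)["thin"].fraction == 1.0

    def test_fractions_invariant_to_order_and_scale(self):
        rows = [(1.0, 2.5e-9, 2.5e-9, 0, 0), (3.0, 1e-9, 0.2e-9, 1, 2)]
        a = bin_resolve(make_dtd(rows))
        b = bin_resolve(make_dtd([(7 * w, dp, dr, th, ph) for w, dp, dr, th, ph in rows[::-1]]))
        for name in ("thin", "thick", "big"):
            assert a[name].fraction == pytest.approx(b[name].fraction, rel=1e-12)

    def test_mean_orientation_respects_axial_symmetry(self):
        rows = [(1.0, 2e-9, 0.2e-9, np.pi / 2, 0.0), (1.0, 2e-9, 0.2e-9, np.pi / 2, np.pi)]
        res = bin_resolve(make_dtd(rows))
        # both components lie along +/- x: dyadic mean axis is x
        assert abs(res["thin"].mean_axis[0]) == pytest.approx(1.0, abs=1e-9)


class TestEnsembleMedians:
    def test_identical_replicates_collapse_to_single_values(self):
        dtd = make_preset_voxel("MIX").dtd
        ens = DTDEnsemble(replicates=[dtd] * 5, rss=np.zeros(5))
        ds = ensemble_medians(ens)
        assert ds.medians["e_diso"] == pytest.approx(1.9e-9, rel=1e-12)
        assert ds.medians["big_fraction"] == pytest.approx(0.5)
        assert len(ds.per_replicate) == 5

    def test_median_convention_matches_sorted_middle(self):
        dtds = [
            make_dtd([(1.0, d, d, 0, 0)])
            for d in (1e-9, 2e-9, 3e-9, 4e-9, 5e-9)
        ]
        for k in (3, 4, 5):  # odd and even replicate counts
            ens = DTDEnsemble(replicates=dtds[:k], rss=np.zeros(k))
            ds = ensemble_medians(ens)
            expected = float(np.median([1e-9 * (i + 1) for i in range(k)]))
            assert ds.medians["e_diso"] == pytest.approx(expected, rel=1e-12)

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ensemble_medians(DTDEnsemble(replicates=[], rss=np.zeros(0)))


class TestQualityMaps:
    def test_rss_bookkeeping_and_highb_map(self):
        scheme = build_protocol(directions=3)
        dtd = make_preset_voxel("GM").dtd
        from dtdmri import predict_signal

        signal = predict_signal(dtd, scheme)
        stack = signal[None, None, None, :]
        ens = DTDEnsemble(replicates=[dtd] * 3, rss=np.full(3, 0.25))
        m1, m2 = quality_maps({(0, 0, 0): ens}, stack, scheme)
        assert m1[0, 0, 0] == pytest.approx(dtd.s0 / np.sqrt(0.25))
        sel = (scheme.b_delta == 0) & (scheme.b == scheme.b.max())
        expected = signal[sel].mean() / signal[sel].std(ddof=1)
        assert m2[0, 0, 0] == pytest.approx(expected)

    def test_missing_spherical_shell_warns(self):
        scheme = build_protocol(directions=2, shapes=[1.0], n_b0=1)
        ens = DTDEnsemble(
            replicates=[make_preset_voxel("CSF").dtd], rss=np.zeros(1)
        )
        with pytest.warns(UserWarning, match="spherical"):
            _, m2 = quality_maps(
                {(0, 0, 0): ens}, np.ones((1, 1, 1, len(scheme))), scheme
            )
        assert np.isnan(m2).all()


class TestOrientationRgb:
    def test_isotropic_tensor_is_white(self):
        np.testing.assert_allclose(
            orientation_rgb(2e-9 * np.eye(3), mode="tensor"), [1, 1, 1]
        )

    def test_stick_along_z_is_blue_in_tensor_mode(self):
        rgb = orientation_rgb(np.diag([1e-11, 1e-11, 2e-9]), mode="tensor")
        assert rgb[2] == 1.0
        assert rgb[0] < 0.01

    def test_x_axis_is_red_in_axis_mode(self):
        np.testing.assert_allclose(
            orientation_rgb(np.array([1.0, 0, 0]), mode="axis"), [1, 0, 0]
        )

    def test_zero_tensor_rejected(self):
        with pytest.raises(ValueError):
            orientation_rgb(np.zeros((3, 3)), mode="tensor")
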