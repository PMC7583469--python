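"""Discrete DTD representation and the forward signal model."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dtdmri import (
    DiscreteDTD,
    DTDComponent,
    bd_contraction,
    btensor_from_shape,
    build_protocol,
    predict_signal,
    tensor_from_component,
)
from dtdmri.scheme import AcquisitionScheme


def random_dtd(rng, n):
    return DiscreteDTD(
        w=rng.uniform(0.1, 1.0, n),
        d_par=10 ** rng.uniform(-11, -8.5, n),
        d_perp=10 ** rng.uniform(-11, -8.5, n),
        theta=np.arccos(rng.uniform(-1, 1, n)),
        phi=rng.uniform(0, 2 * np.pi, n),
    )


def random_scheme(rng, n):
    return AcquisitionScheme(
        entries=[
            btensor_from_shape(
                rng.uniform(0, 4e9),
                rng.uniform(-0.5, 1),
                np.arccos(rng.uniform(-1, 1)),
                rng.uniform(0, 2 * np.pi),
            )
            for _ in range(n)
        ]
    )


def brute_force_signal(dtd, scheme):
    """Independent oracle: explicit double loop with elementwise 3x3 sums."""
    out = np.zeros(len(scheme))
    for i, bt in enumerate(scheme):
        bmat = bt.matrix
        for c in dtd.components:
            dmat = tensor_from_component(c)
            expo = sum(
                bmat[a, b] * dmat[a, b] for a in range(3) for b in range(3)
            )
            out[i] += c.w * np.exp(-expo)
    return out


class TestComponent:
    def test_isotropic_component(self):
        c = DTDComponent(1.0, 2e-9, 2e-9)
        np.testing.assert_allclose(tensor_from_component(c), 2e-9 * np.eye(3))
        assert c.d_delta == 0.0

    def test_prolate_component_parameters(self):
        c = DTDComponent(1.0, 2e-9, 0.5e-9)
        assert c.d_iso == pytest.approx(1e-9)
        assert c.d_delta == pytest.approx(0.5)

    def test_stick_limit(self):
        c = DTDComponent(1.0, 2e-9, 0.0, theta=0.0)
        np.testing.assert_allclose(
            tensor_from_component(c), np.diag([0.0, 0.0, 2e-9])
        )
        assert c.d_delta == pytest.approx(1.0)

    def test_eigen_roundtrip(self):
        c = DTDComponent(1.0, 1.7e-9, 0.3e-9, theta=1.0, phi=2.0)
        vals = np.linalg.eigvalsh(tensor_from_component(c))
        d_iso = vals.sum() / 3
        assert d_iso == pytest.approx(c.d_iso, rel=1e-9)

    def test_negative_diffusivity_rejected(self):
        with pytest.raises(ValueError):
            DTDComponent(1.0, -1e-9, 1e-9)


class TestContraction:
    def test_spherical_times_any(self):
        b = btensor_from_shape(1e9, 0.0)
        d = tensor_from_component(DTDComponent(1.0, 3.1e-9, 3.1e-9))
        assert bd_contraction(b, d) == pytest.approx(3.1, rel=1e-12)

    def test_linear_parallel_stick(self):
        b = btensor_from_shape(1e9, 1.0, 0.0, 0.0)
        d = tensor_from_component(DTDComponent(1.0, 2e-9, 0.0, theta=0.0))
        assert bd_contraction(b, d) == pytest.approx(2.0, rel=1e-12)

    def test_planar_orthogonal_stick(self):
        b = btensor_from_shape(1e9, -0.5, 0.0, 0.0)  # xy-plane encoding
        d = tensor_from_component(DTDComponent(1.0, 2e-9, 0.0, theta=0.0))
        assert bd_contraction(b, d) == pytest.approx(0.0, abs=1e-15)


class TestPredictSignal:
    def test_monoexponential(self):
        dtd = DiscreteDTD([1.0], [3.1e-9], [3.1e-9], [0.0], [0.0])
        scheme = AcquisitionScheme(
            entries=[btensor_from_shape(1e9, bd) for bd in (-0.5, 0.0, 1.0)]
        )
        np.testing.assert_allclose(
            predict_signal(dtd, scheme), np.exp(-3.1), rtol=1e-12
        )

    def test_b0_returns_s0(self, protocol):
        rng = np.random.default_rng(0)
        dtd = random_dtd(rng, 5)
        s = predict_signal(dtd, protocol)
        np.testing.assert_allclose(s[protocol.b0_mask()], dtd.s0, rtol=1e-12)
        assert (s > 0).all() and (s <= dtd.s0 * (1 + 1e-12)).all()

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            dtd = random_dtd(rng, rng.integers(1, 6))
            scheme = random_scheme(rng, 15)
            np.testing.assert_allclose(
                predict_signal(dtd, scheme),
                brute_force_signal(dtd, scheme),
                rtol=1e-12,
            )

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_rotational_invariance(self, seed):
        """Jointly rotating components and b-tensors leaves signals unchanged."""
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(seed)
        dtd = random_dtd(rng, 3)
        scheme = random_scheme(rng, 10)
        s = predict_signal(dtd, scheme)
        rot = Rotation.random(random_state=int(seed)).as_matrix()

        def rotate_angles(theta, phi):
            st_ = np.sin(theta)
            u = np.column_stack(
                [st_ * np.cos(phi), st_ * np.sin(phi), np.cos(theta)]
            ) @ rot.T
            return np.arccos(np.clip(u[:, 2], -1, 1)), np.arctan2(u[:, 1], u[:, 0])

        th, ph = rotate_angles(dtd.theta, dtd.phi)
        dtd_r = DiscreteDTD(dtd.w, dtd.d_par, dtd.d_perp, th, ph)
        entries = []
        for e in scheme:
            th_e, ph_e = rotate_angles(
                np.array([e.theta_lab]), np.array([e.phi_lab])
            )
            entries.append(
                btensor_from_shape(e.b, e.b_delta, th_e[0], ph_e[0])
            )
        s_rot = predict_signal(dtd_r, AcquisitionScheme(entries=entries))
        np.testing.assert_allclose(s_rot, s, rtol=1e-9)

    def test_monotone_decay_with_b(self):
        rng = np.random.default_rng(3)
        dtd = random_dtd(rng, 4)
        bs = np.linspace(0.1e9, 4e9, 10)
        scheme = AcquisitionScheme(
            entries=[btensor_from_shape(b, 0.7, 0.4, 1.0) for b in bs]
        )
        s = predict_signal(dtd, scheme)
        assert (np.diff(s) < 0).all()

    def test_spherical_shells_ignore_orientations(self):
        """At b_delta = 0 the signal depends only on the D_iso spectrum."""
        rng = np.random.default_rng(5)
        dtd = random_dtd(rng, 4)
        scrambled = DiscreteDTD(
            dtd.w, dtd.d_par, dtd.d_perp,
            np.arccos(rng.uniform(-1, 1, 4)), rng.uniform(0, 2 * np.pi, 4),
        )
        scheme = AcquisitionScheme(
            entries=[btensor_from_shape(b, 0.0, 0.2, 0.3) for b in (1e9, 3e9)]
        )
        np.testing.assert_allclose(
            predict_signal(dtd, scheme), predict_signal(scrambled, scheme),
            rtol=1e-12,
        )


def test_json_roundtrip(tmp_path):
    rng = np.random.default_rng(1)
    dtd = random_dtd(rng, 3)
    path = tmp_path / "dtd.json"
    dtd.to_json(path)
    back = DiscreteDTD.from_json(path)
    np.testing.assert_allclose(back.w, dtd.w)
    np.testing.assert_allclose(back.d_par, dtd.d_par)
    assert back.s0 == pytest.approx(dtd.s0)
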