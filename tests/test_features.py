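"""Map features against brute-force oracles, symmetry and linearity checks."""

import numpy as np
import pytest
from scipy.special import erfc
from scipy.stats import ortho_group

from specmap import synthetic
from specmap.features import (
    compute_features,
    dsf_field,
    projected_field_derivatives,
    repulsive_lj,
)
from specmap.frames import (
    ROLE_CH,
    ROLE_CR,
    ROLE_DONOR,
    ROLE_H,
    ROLE_SOLVENT,
    SnapshotFrame,
)
from specmap.units import ANGSTROM_TO_BOHR, KJMOL_TO_HARTREE


def _probe_frame(solvent_coords, charges, sigma=None, eps=None, roles=None, box=40.0):
    """Probe on the z axis at the box center plus explicit solvent atoms."""
    n = len(solvent_coords)
    center = box / 2.0
    probe = np.array(
        [[center, center, center], [center, center, center + 1.215],
         [center, center, center + 2.276]]
    )
    return SnapshotFrame(
        coordinates=np.vstack([probe, np.asarray(solvent_coords, dtype=float)]),
        charges=np.concatenate([np.zeros(3), charges]),
        lj_sigma=np.concatenate([np.full(3, 3.0), sigma if sigma is not None else np.full(n, 3.0)]),
        lj_epsilon=np.concatenate([np.zeros(3), eps if eps is not None else np.full(n, 0.3)]),
        roles=np.array(
            ["C_R", "C_H", "H_terminal"] + list(roles if roles is not None else [ROLE_SOLVENT] * n),
            dtype=object,
        ),
        box=np.full(3, box),
    )


def _dsf_kernel_scalar(r_b, alpha_b, rc_b):
    k = lambda r: erfc(alpha_b * r) / r**2 + 2 * alpha_b * np.exp(-((alpha_b * r) ** 2)) / (
        np.sqrt(np.pi) * r
    )
    return k(r_b) - k(rc_b)


class TestDsfField:
    def test_single_charge_matches_kernel_formula(self):
        """One charge on +x: field is q * f_DSF(r) x_hat, near-Coulomb at small alpha."""
        box, center = 40.0, 20.0
        r = 3.0
        q = 0.4
        frame = _probe_frame([[center + r, center, center]], np.array([q]))
        eval_point = np.array([center, center, center])
        for alpha in (0.01, 0.2):
            field = dsf_field(frame, eval_point, cutoff=14.0, damping=alpha)
            expected = -q * _dsf_kernel_scalar(
                r * ANGSTROM_TO_BOHR, alpha / ANGSTROM_TO_BOHR, 14.0 * ANGSTROM_TO_BOHR
            )
            assert field[0] == pytest.approx(expected, rel=1e-12)
            assert field[1] == pytest.approx(0.0, abs=1e-15)
        # alpha -> 0 approaches the shifted Coulomb field
        field = dsf_field(frame, eval_point, cutoff=14.0, damping=1e-6)
        coulomb = q / (r * ANGSTROM_TO_BOHR) ** 2
        assert abs(abs(field[0]) - coulomb) / coulomb < 0.05

    def test_symmetric_pair_cancels(self):
        box, c = 40.0, 20.0
        frame = _probe_frame(
            [[c + 4.0, c, c], [c - 4.0, c, c]], np.array([0.3, 0.3])
        )
        field = dsf_field(frame, np.array([c, c, c]))
        assert np.max(np.abs(field)) < 1e-12

    def test_beyond_cutoff_contributes_zero(self):
        box, c = 60.0, 30.0
        near = _probe_frame([[c + 5.0, c, c]], np.array([0.3]), box=box)
        both = _probe_frame(
            [[c + 5.0, c, c], [c, c + 20.0, c]], np.array([0.3, -0.8]), box=box
        )
        p = np.array([c, c, c])
        assert np.allclose(
            dsf_field(near, p, cutoff=14.0), dsf_field(both, p, cutoff=14.0), atol=1e-16
        )

    def test_brute_force_random_frame(self, random_frame):
        """Vectorized field equals a naive double loop to 1e-10 relative."""
        pt = random_frame.position_of(ROLE_H) + np.array([0.3, -0.2, 0.1])
        fast = dsf_field(random_frame, pt)
        slow = np.zeros(3)
        rc_b = 14.0 * ANGSTROM_TO_BOHR
        al_b = 0.2 / ANGSTROM_TO_BOHR
        for i in range(random_frame.n_atoms):
            if random_frame.roles[i] not in (ROLE_SOLVENT, ROLE_DONOR):
                continue
            d = pt - random_frame.coordinates[i]
            d -= random_frame.box * np.round(d / random_frame.box)
            r = np.linalg.norm(d)
            if r >= 14.0:
                continue
            k = _dsf_kernel_scalar(r * ANGSTROM_TO_BOHR, al_b, rc_b)
            slow += random_frame.charges[i] * k * d / r
        assert np.max(np.abs(fast - slow)) <= 1e-10 * np.max(np.abs(slow))

    def test_cutoff_must_fit_box(self, random_frame):
        with pytest.raises(ValueError, match="half the minimum box edge"):
            dsf_field(random_frame, np.zeros(3), cutoff=15.0)

    def test_coincident_atom_named(self):
        frame = _probe_frame([[20.0, 20.0, 25.0]], np.array([0.3]))
        with pytest.raises(ValueError, match="atom index 3"):
            dsf_field(frame, np.array([20.0, 20.0, 25.0]))


class TestProjectedDerivatives:
    def test_uniform_field_limit(self):
        """A distant symmetric charge pair: f0 near the Coulomb pair value, f1, f2 ~ 0."""
        c, d = 22.0, 12.0
        frame = _probe_frame(
            [[c, c, c + 2.276 + d], [c, c, c + 2.276 - d]],
            np.array([-0.5, 0.5]),
            box=44.0,
        )
        # weak damping so the kernel is near-Coulomb and the pair field near-uniform;
        # the force shift subtracts the kernel value at the cutoff
        f0, f1, f2 = projected_field_derivatives(frame, cutoff=20.0, damping=0.02)
        shifted_pair = -2.0 * 0.5 * (
            1.0 / (d * ANGSTROM_TO_BOHR) ** 2 - 1.0 / (20.0 * ANGSTROM_TO_BOHR) ** 2
        )
        assert f0 == pytest.approx(shifted_pair, rel=0.05)
        assert abs(f1) < 1e-6 * abs(f0)  # exact by symmetry
        assert abs(f2) < 0.05 * abs(f0)  # residual curvature O(6/d^2) per bohr^2

    def test_on_axis_charge_matches_analytic_derivatives(self):
        """Point charge on the C-H axis: derivatives of q f(d) to O(spacing^2)."""
        c, d = 20.0, 2.5
        q = -0.63
        frame = _probe_frame([[c, c, c + 2.276 + d]], np.array([q]))
        f0, f1, f2 = projected_field_derivatives(frame, spacing=0.05)
        rc_b = 14.0 * ANGSTROM_TO_BOHR
        al_b = 0.2 / ANGSTROM_TO_BOHR
        d_b = d * ANGSTROM_TO_BOHR
        eps = 1e-6
        f = lambda r: _dsf_kernel_scalar(r, al_b, rc_b)
        fp = (f(d_b + eps) - f(d_b - eps)) / (2 * eps)
        fpp = (f(d_b + eps) - 2 * f(d_b) + f(d_b - eps)) / eps**2
        # H -> C projection: p(delta) = q * f(d - delta)
        assert f0 == pytest.approx(q * f(d_b), rel=1e-10)
        assert f1 == pytest.approx(-q * fp, rel=1e-3)
        assert f2 == pytest.approx(q * fpp, rel=1e-2)

    def test_negative_charge_facing_h_gives_negative_features(self):
        """Electron-rich site toward H: f0, f1, f2 all negative (red-shift signs)."""
        c = 20.0
        frame = _probe_frame([[c, c, c + 2.276 + 2.1]], np.array([-0.63]))
        f0, f1, f2 = projected_field_derivatives(frame)
        assert f0 < 0 and f1 < 0 and f2 < 0

    def test_linear_in_charges(self, random_frame):
        base = np.array(projected_field_derivatives(random_frame))
        flipped = SnapshotFrame(
            coordinates=random_frame.coordinates,
            charges=-random_frame.charges,
            lj_sigma=random_frame.lj_sigma,
            lj_epsilon=random_frame.lj_epsilon,
            roles=random_frame.roles,
            box=random_frame.box,
        )
        assert np.allclose(np.array(projected_field_derivatives(flipped)), -base, rtol=1e-12)

    def test_halving_spacing_converges_quadratically(self):
        c = 20.0
        frame = _probe_frame([[c + 1.5, c, c + 2.276 + 2.5]], np.array([-0.4]))
        ref = np.array(projected_field_derivatives(frame, spacing=0.003125))
        err = []
        for spacing in (0.2, 0.1, 0.05):
            vals = np.array(projected_field_derivatives(frame, spacing=spacing))
            err.append(np.abs(vals - ref)[1:])  # f1, f2
        err = np.array(err)
        ratio = err[0] / err[1]
        assert np.all(ratio > 3.0)  # O(spacing^2) => factor ~4


class TestRepulsiveLJ:
    def test_no_solvent_gives_zero(self):
        frame = _probe_frame(np.empty((0, 3)), np.empty(0), np.empty(0), np.empty(0), [])
        assert repulsive_lj(frame, ROLE_H) == 0.0

    def test_contact_distance_closed_form(self):
        """One atom at r = sigma contributes exactly 4 epsilon."""
        c, sigma, eps = 20.0, 3.3, 0.5
        frame = _probe_frame(
            [[c, c, c + 2.276 + sigma]], np.array([0.0]),
            sigma=np.array([sigma]), eps=np.array([eps]),
        )
        assert repulsive_lj(frame, ROLE_H) == pytest.approx(
            4.0 * eps * KJMOL_TO_HARTREE, rel=1e-12
        )

    def test_brute_force_random_frame(self, random_frame):
        for role in (ROLE_H, ROLE_CH, ROLE_CR):
            fast = repulsive_lj(random_frame, role)
            site = random_frame.position_of(role)
            slow = 0.0
            for i in range(random_frame.n_atoms):
                if random_frame.roles[i] != ROLE_SOLVENT:
                    continue
                d = site - random_frame.coordinates[i]
                d -= random_frame.box * np.round(d / random_frame.box)
                r = np.linalg.norm(d)
                if r >= 14.0:
                    continue
                slow += 4 * random_frame.lj_epsilon[i] * (random_frame.lj_sigma[i] / r) ** 12
            slow *= KJMOL_TO_HARTREE
            assert fast == pytest.approx(slow, rel=1e-10)

    def test_donor_atoms_excluded(self, random_frame):
        """Flagging every solvent atom as donor empties the repulsive sums."""
        all_donor = SnapshotFrame(
            coordinates=random_frame.coordinates,
            charges=random_frame.charges,
            lj_sigma=random_frame.lj_sigma,
            lj_epsilon=random_frame.lj_epsilon,
            roles=np.array(
                [r if r in ("H_terminal", "C_H", "C_R") else ROLE_DONOR
                 for r in random_frame.roles],
                dtype=object,
            ),
            box=random_frame.box,
        )
        assert repulsive_lj(all_donor, ROLE_H) == 0.0
        # but the donor atoms still contribute to the field
        h = random_frame.position_of(ROLE_H)
        assert np.allclose(
            dsf_field(all_donor, h + np.array([0.3, 0.0, 0.0])),
            dsf_field(random_frame, h + np.array([0.3, 0.0, 0.0])),
        )

    def test_charges_do_not_matter(self, random_frame):
        flipped = SnapshotFrame(
            coordinates=random_frame.coordinates,
            charges=-2.0 * random_frame.charges,
            lj_sigma=random_frame.lj_sigma,
            lj_epsilon=random_frame.lj_epsilon,
            roles=random_frame.roles,
            box=random_frame.box,
        )
        assert repulsive_lj(flipped, ROLE_CH) == repulsive_lj(random_frame, ROLE_CH)


def test_rigid_motion_invariance(cluster_frame):
    """Rotating + translating a cluster frame leaves all six features unchanged."""
    base = compute_features(cluster_frame).as_array()
    rot = ortho_group.rvs(3, random_state=5)
    center = cluster_frame.box / 2.0
    shift = np.array([1.3, -2.1, 0.7])
    moved = SnapshotFrame(
        coordinates=(cluster_frame.coordinates - center) @ rot.T + center + shift,
        charges=cluster_frame.charges,
        lj_sigma=cluster_frame.lj_sigma,
        lj_epsilon=cluster_frame.lj_epsilon,
        roles=cluster_frame.roles,
        box=cluster_frame.box,
    )
    assert np.allclose(compute_features(moved).as_array(), base, rtol=1e-9, atol=1e-12)


def test_feature_vector_rejects_negative_lj():
    with pytest.raises(ValueError, match="non-negative"):
        from specmap.features import FeatureVector

        FeatureVector(f0=0.0, f1=0.0, f2=0.0, u_H=-1e-3, u_CH=0.0, u_CR=0.0)
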