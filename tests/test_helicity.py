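"""Cluster axis, ribbon assignment, and the helicity order parameter."""

import numpy as np
import pytest

from fibriltwist import (
    assign_ribbons,
    cluster_helicity,
    decomposition_from_membership,
    fit_cluster_axis,
    helicity_of_centers,
    pair_twist,
    peptide_mass_centers,
    reference_spacing,
    ribbon_cutoffs,
)
from fibriltwist.helicity import ClusterAxis
from fibriltwist import synthetic as syn

from conftest import random_rotation


def helix_centers(n, twist_deg, rise=0.5, radius=1.0, phase=0.0):
    k = np.arange(n)
    phi = phase + k * np.radians(twist_deg)
    return np.column_stack(
        [radius * np.cos(phi), radius * np.sin(phi), k * rise]
    )


# ---------------------------------------------------------------------------
# axis fitting


def test_axis_recovers_exact_line():
    pts = np.outer(np.arange(5, dtype=float), [1.0, 2.0, 2.0]) / 3.0
    axis = fit_cluster_axis(pts)
    np.testing.assert_allclose(np.abs(axis.direction), [1 / 3, 2 / 3, 2 / 3],
                               atol=1e-12)
    # oriented from first toward last input point
    assert axis.project(pts)[-1] > axis.project(pts)[0]


def test_axis_through_two_points():
    pts = np.array([[0.0, 0.0, 0.0], [1.0, 1.0, 0.0]])
    axis = fit_cluster_axis(pts)
    np.testing.assert_allclose(axis.direction, [1, 1, 0] / np.sqrt(2), atol=1e-12)


def test_axis_of_ideal_helix_is_near_z():
    """A single off-axis helix tilts the principal direction slightly
    (the layer centroids are not on the axis), so the tolerance is loose."""
    pts = helix_centers(30, twist_deg=12.0)
    axis = fit_cluster_axis(pts)
    assert abs(axis.direction @ [0, 0, 1]) > 0.98


def test_axis_exact_for_symmetric_multi_ribbon_fibril(fibril_three_ribbon):
    """Azimuthally symmetric layers put every layer centroid on the axis, so
    the principal direction is exactly the fibril axis."""
    frame, truth = fibril_three_ribbon
    centers = peptide_mass_centers(frame, "all")
    axis = fit_cluster_axis(centers)
    np.testing.assert_allclose(axis.direction, truth.axis_direction, atol=1e-9)


def test_axis_degenerate_inputs():
    with pytest.raises(ValueError):
        fit_cluster_axis(np.ones((4, 3)))
    iso = np.array([[1.0, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0],
                    [0, 0, 1], [0, 0, -1]])
    assert fit_cluster_axis(iso).ill_defined


# ---------------------------------------------------------------------------
# cutoff arithmetic


def test_reference_spacing_values():
    assert reference_spacing(72) == pytest.approx(0.13270, abs=5e-6)
    assert reference_spacing(25) == pytest.approx(0.38387, abs=5e-6)


def test_reference_spacing_invalid_for_huge_clusters():
    with pytest.raises(ValueError):
        reference_spacing(20000)  # a/M < |b|


def test_ribbon_cutoffs_values():
    d_par, d_perp = ribbon_cutoffs(reference_spacing(72))
    assert d_par == pytest.approx(0.11678, abs=5e-6)
    assert d_perp == pytest.approx(0.06237, abs=5e-6)
    assert ribbon_cutoffs(1.0, 1.0, 1.0) == (1.0, 1.0)
    d_par2, d_perp2 = ribbon_cutoffs(reference_spacing(25))
    assert d_par2 == pytest.approx(0.33780, abs=1e-5)
    assert d_perp2 == pytest.approx(0.18042, abs=1e-5)


def test_ribbon_cutoffs_reject_nonpositive():
    with pytest.raises(ValueError):
        ribbon_cutoffs(0.5, s_par=-1.0)


# ---------------------------------------------------------------------------
# ribbon assignment


def _z_axis(anchor=(0.0, 0.0, 0.0)):
    return ClusterAxis(np.asarray(anchor, float), np.array([0.0, 0.0, 1.0]))


def test_collinear_stack_single_ribbon():
    centers = np.column_stack([np.ones(6), np.zeros(6), 0.1 * np.arange(6)])
    d = assign_ribbons(centers, _z_axis(), cutoffs=(0.15, 0.05))
    assert d.n_ribbons == 1
    assert len(d.ribbons[0]) == 6


def test_gap_splits_into_two_ribbons():
    z = np.array([0.0, 0.1, 0.2, 0.5, 0.6, 0.7])  # gap 0.3 > 0.15
    centers = np.column_stack([np.ones(6), np.zeros(6), z])
    d = assign_ribbons(centers, _z_axis(), cutoffs=(0.15, 0.05))
    assert d.n_ribbons == 2
    assert [len(r) for r in d.ribbons] == [3, 3]


def test_interleaved_stacks_fragment():
    """Two laterally offset stacks interleaved in projection fragment under
    consecutive-run chaining (documented behaviour)."""
    za = np.arange(5) * 0.2
    zb = za + 0.1
    a = np.column_stack([np.full(5, 1.0), np.zeros(5), za])
    b = np.column_stack([np.full(5, -1.0), np.zeros(5), zb])
    centers = np.concatenate([a, b])
    d = assign_ribbons(centers, _z_axis(), cutoffs=(0.25, 2.5))
    assert d.n_ribbons == 1  # d_perp above the 2.0 nm offset: chains everything
    d2 = assign_ribbons(centers, _z_axis(), cutoffs=(0.25, 0.05))
    assert d2.n_ribbons == 10  # tight d_perp: every pair breaks


# ---------------------------------------------------------------------------
# pair twist


def test_untwisted_pair_has_zero_twist():
    axis = _z_axis()
    g = np.array([1.0, 0.0, 0.0])
    assert pair_twist(g, g, axis) == pytest.approx(0.0, abs=1e-15)


@pytest.mark.parametrize("dphi", [5.0, -5.0, 30.0, 120.0])
def test_twist_is_minus_sine_of_azimuthal_step(dphi):
    axis = _z_axis()
    r1 = np.array([1.0, 0.0, 0.0])
    a = np.radians(dphi)
    r2 = np.array([np.cos(a), np.sin(a), 0.0])
    assert pair_twist(r1, r2, axis) == pytest.approx(-np.sin(a), abs=1e-12)


def test_aligned_radial_and_tangential_gives_one():
    axis = _z_axis()
    r_next = np.array([1.0, 0.0, 0.0])
    e_next = np.cross(axis.direction, r_next)
    assert pair_twist(e_next, r_next, axis) == pytest.approx(1.0)


def test_twist_undefined_on_axis():
    axis = _z_axis()
    with pytest.raises(ValueError):
        pair_twist(np.zeros(3), np.array([1.0, 0, 0]), axis)
    with pytest.raises(ValueError):
        pair_twist(np.array([1.0, 0, 0]), np.array([0.0, 0, 1.0]), axis)


# ---------------------------------------------------------------------------
# cluster helicity


def test_helicity_averages_constant_twists():
    centers = helix_centers(5, twist_deg=30.0)
    axis = _z_axis(anchor=(0, 0, centers[:, 2].mean()))
    d = decomposition_from_membership(centers, axis, [[0, 1, 2, 3, 4]])
    res = cluster_helicity(d)
    assert res.h == pytest.approx(-np.sin(np.radians(30.0)), abs=1e-12)
    assert res.ribbon_helicities == pytest.approx((res.h,))


def test_helicity_averages_over_ribbons():
    """Two ribbons with different twists: H is the mean of the two."""
    r1 = helix_centers(4, twist_deg=10.0, phase=0.0)
    r2 = helix_centers(4, twist_deg=20.0, phase=np.pi)
    centers = np.concatenate([r1, r2])
    axis = _z_axis(anchor=(0, 0, centers[:, 2].mean()))
    d = decomposition_from_membership(
        centers, axis, [[0, 1, 2, 3], [4, 5, 6, 7]]
    )
    res = cluster_helicity(d)
    expected = -(np.sin(np.radians(10.0)) + np.sin(np.radians(20.0))) / 2
    assert res.h == pytest.approx(expected, abs=1e-12)
    assert res.n_ribbons == 2


def test_singleton_ribbons_excluded():
    centers = helix_centers(4, twist_deg=15.0)
    axis = _z_axis()
    d = decomposition_from_membership(centers, axis, [[0, 1, 2], [3]])
    res = cluster_helicity(d)
    assert res.n_ribbons == 1
    d_all_single = decomposition_from_membership(centers, axis, [[0], [1], [2], [3]])
    with pytest.raises(ValueError):
        cluster_helicity(d_all_single)


def test_three_ribbon_fibril_closed_form(fibril_three_ribbon):
    """Full pipeline on an ideal fibril reproduces H = -sin(twist)."""
    frame, truth = fibril_three_ribbon
    centers = peptide_mass_centers(frame, "all")
    res = helicity_of_centers(centers, membership=truth.ribbons)
    assert res.h == pytest.approx(truth.helicity, abs=1e-9)
    assert res.n_ribbons == 3


def test_helicity_rigid_motion_invariance(fibril_three_ribbon):
    frame, truth = fibril_three_ribbon
    centers = peptide_mass_centers(frame, "all")
    h0 = helicity_of_centers(centers, membership=truth.ribbons).h
    moved = centers @ random_rotation(2).T + np.array([5.0, -3.0, 1.0])
    h1 = helicity_of_centers(moved, membership=truth.ribbons).h
    assert h1 == pytest.approx(h0, abs=1e-10)


def test_mirroring_flips_sign(fibril_three_ribbon):
    frame, truth = fibril_three_ribbon
    centers = peptide_mass_centers(frame, "all")
    h0 = helicity_of_centers(centers, membership=truth.ribbons).h
    mirrored = centers * np.array([-1.0, 1.0, 1.0])
    h1 = helicity_of_centers(mirrored, membership=truth.ribbons).h
    assert h1 == pytest.approx(-h0, abs=1e-10)


def test_axis_reversal_antisymmetry_of_pair_twist():
    """Flipping the axis orientation flips the sign of a single pair twist
    (the tangential direction reverses while the radial ones do not)."""
    anchor = np.zeros(3)
    up = ClusterAxis(anchor, np.array([0.0, 0.0, 1.0]))
    down = ClusterAxis(anchor, np.array([0.0, 0.0, -1.0]))
    a = np.radians(12.0)
    r1 = np.array([1.0, 0.0, 0.0])
    r2 = np.array([np.cos(a), np.sin(a), 0.0])
    assert pair_twist(r1, r2, down) == pytest.approx(-pair_twist(r1, r2, up),
                                                     abs=1e-12)


def test_helicity_invariant_under_axis_reversal():
    """The cluster value H does not depend on the axis orientation: reversing
    the axis also reverses the projection-sorted traversal order, and the two
    sign flips cancel."""
    centers = helix_centers(6, twist_deg=12.0)
    anchor = np.array([0.0, 0.0, centers[:, 2].mean()])
    up = ClusterAxis(anchor, np.array([0.0, 0.0, 1.0]))
    down = ClusterAxis(anchor, np.array([0.0, 0.0, -1.0]))
    membership = [[0, 1, 2, 3, 4, 5]]
    h_up = cluster_helicity(
        decomposition_from_membership(centers, up, membership)
    ).h
    h_down = cluster_helicity(
        decomposition_from_membership(centers, down, membership)
    ).h
    assert h_down == pytest.approx(h_up, abs=1e-12)


def test_noise_shrinks_helicity_magnitude():
    """Isotropic coordinate noise pulls |H| toward zero on average."""
    h_by_eps = []
    for eps in (0.0, 0.05, 0.15):
        hs = []
        for seed in range(8):
            frame, truth = syn.build_helical_fibril(syn.FibrilSpec(
                n_ribbons=3, peptides_per_ribbon=10, twist_deg=20.0,
                noise=eps, seed=seed))
            centers = peptide_mass_centers(frame, "all")
            hs.append(helicity_of_centers(centers, membership=truth.ribbons).h)
        h_by_eps.append(abs(np.mean(hs)))
    assert h_by_eps[0] > h_by_eps[1] > h_by_eps[2]
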