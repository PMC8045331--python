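"""Expansion-vector casting, directional margins and margin deviation."""

import numpy as np
import pytest

from ctvmargins import (
    BinaryVolume,
    CastParams,
    DirectionSpec,
    FewVectorsWarning,
    GeometryMismatchError,
    InsufficientExpertsError,
    NoVectorError,
    PhantomSpec,
    cast_expansion_vector,
    directional_margin,
    expected_sphere_margin,
    extract_surface,
    make_phantom,
    margin_deviation,
)
from oracles import dense_cast

L = DirectionSpec.from_label("L")
R = DirectionSpec.from_label("R")


def slab_pair(plus=7.0, minus=2.0):
    ph = make_phantom(
        PhantomSpec(
            gtv_shape="slab",
            size_mm=(10.0,),
            expansion={"per_face": {"+x": plus, "-x": minus}},
            spacing_mm=(1.0, 1.0, 1.0),
        )
    )
    return ph.gtv, ph.ctv


def expert_slab(gtv, plus, minus=2.0, half=5.0):
    """An expert CTV slab on the *same grid* as ``gtv`` (x in [-half-minus, half+plus])."""
    xc = gtv.origin[0] + gtv.spacing[0] * np.arange(gtv.shape[0])
    keep = (xc >= -half - minus) & (xc <= half + plus)
    occ = np.zeros(gtv.shape, dtype=bool)
    occ[keep, :, :] = True
    return gtv.with_occupancy(occ)


class TestCastExpansionVector:
    def test_slab_lengths_both_directions(self):
        gtv, ctv = slab_pair()
        start = extract_surface(gtv).points[0]
        right = cast_expansion_vector(start, L, gtv, ctv)
        left = cast_expansion_vector(start, R, gtv, ctv)
        assert right.status == "accepted" and left.status == "accepted"
        assert right.length_mm == pytest.approx(7.0, abs=1e-9)
        assert left.length_mm == pytest.approx(2.0, abs=1e-9)
        # endpoints are consistent with the reported length and direction
        assert np.allclose(right.end - right.start, right.length_mm * L.vector)

    def test_coincident_masks_give_zero_length(self):
        gtv, _ = slab_pair()
        start = extract_surface(gtv).points[0]
        out = cast_expansion_vector(start, L, gtv, gtv)
        assert out.length_mm == pytest.approx(0.0, abs=1e-9)

    def test_interior_crossing_is_rejected(self, u_phantom):
        gtv, ctv = u_phantom.gtv, u_phantom.ctv
        # a voxel on the inner face of the -x prong, inside the slot's y-range
        surf = extract_surface(gtv)
        inner = surf.points[
            (surf.points[:, 0] < -2.0)
            & (surf.points[:, 1] > 3.0)
            & (np.abs(surf.points[:, 2]) < 1.0)
        ]
        assert len(inner) > 0
        out = cast_expansion_vector(inner[0], L, gtv, ctv)
        assert out.status == "rejected_interior"

    def test_incompatible_grids_raise(self):
        gtv, ctv = slab_pair()
        shifted = BinaryVolume(ctv.occupancy, ctv.spacing, ctv.origin + 0.5)
        start = extract_surface(gtv).points[0]
        with pytest.raises(GeometryMismatchError):
            cast_expansion_vector(start, L, gtv, shifted)

    def test_point_not_on_gtv_raises(self):
        gtv, ctv = slab_pair()
        with pytest.raises(ValueError):
            cast_expansion_vector(gtv.origin - 1.0, L, gtv, ctv)


class TestDirectionalMargin:
    def test_slab_margins_exact(self, slab_phantom):
        gtv, ctv = slab_phantom.gtv, slab_phantom.ctv
        res_l = directional_margin(gtv, ctv, L)
        res_r = directional_margin(gtv, ctv, R)
        assert res_l.margin_mm == pytest.approx(7.0, abs=1e-9)
        assert res_r.margin_mm == pytest.approx(2.0, abs=1e-9)
        # all accepted vectors identical by construction
        assert np.ptp(res_l.vector_set.lengths) < 1e-9

    def test_identity_ctv_margin_zero(self, sphere_phantom):
        gtv = sphere_phantom.gtv
        res = directional_margin(gtv, gtv, DirectionSpec.from_label("SA"))
        assert res.margin_mm == pytest.approx(0.0, abs=0.02)

    def test_sphere_margin_matches_continuum_oracle(self, sphere_phantom):
        # for an isotropic 5 mm expansion of a 10 mm sphere the ensemble
        # median is inflated above 5 mm by surface obliquity; the continuum
        # prediction is sqrt((r+m)^2 - 0.75 r^2) - r/2 ~ 7.25 mm, and the
        # voxel ensemble sits within a voxel diagonal of it
        gtv, ctv = sphere_phantom.gtv, sphere_phantom.ctv
        truth = expected_sphere_margin(10.0, 5.0)
        tol = float(np.linalg.norm(gtv.spacing))
        rng = np.random.default_rng(42)
        for i in range(5):
            d = DirectionSpec.from_vector(rng.normal(size=3), label=f"d{i}")
            res = directional_margin(gtv, ctv, d)
            assert abs(res.margin_mm - truth) < tol
            # per-ray analytic bounds: pole m up to equator sqrt(m^2 + 2 r m)
            assert res.vector_set.lengths.min() > 5.0 - tol
            assert res.vector_set.lengths.max() < np.sqrt(25.0 + 100.0) + tol

    def test_margin_between_min_and_max_lengths(self, sphere_phantom):
        res = directional_margin(sphere_phantom.gtv, sphere_phantom.ctv, L)
        lengths = res.vector_set.lengths
        assert 0.0 <= lengths.min() <= res.margin_mm <= lengths.max()
        assert res.margin_mm == pytest.approx(float(np.median(lengths)))

    def test_vector_set_invariants(self, sphere_phantom):
        res = directional_margin(sphere_phantom.gtv, sphere_phantom.ctv, L)
        vs = res.vector_set
        gaps = vs.ends - vs.starts
        lengths = np.linalg.norm(gaps, axis=1)
        assert np.allclose(lengths, vs.lengths, atol=1e-6)
        nonzero = vs.lengths > 1e-9
        cross = np.linalg.norm(np.cross(gaps[nonzero], L.vector), axis=1)
        angles = np.arcsin(np.clip(cross / lengths[nonzero], -1, 1))
        assert np.all(angles < 1e-6)
        assert vs.n_candidates >= len(vs.lengths) + vs.n_rejected_interior + vs.n_rejected_barrier

    def test_few_vectors_warning(self):
        # a 2-voxel GTV produces fewer than 10 rays
        occ = np.zeros((9, 9, 9), dtype=bool)
        occ[4, 4, 4] = occ[5, 4, 4] = True
        gtv = BinaryVolume(occ, (1, 1, 1), (0, 0, 0))
        ctv_occ = np.zeros_like(occ)
        ctv_occ[3:7, 3:6, 3:6] = True
        ctv = gtv.with_occupancy(ctv_occ)
        with pytest.warns(FewVectorsWarning):
            directional_margin(gtv, ctv, L)

    def test_no_vector_error_when_barrier_blocks_everything(self, sphere_phantom):
        gtv, ctv = sphere_phantom.gtv, sphere_phantom.ctv
        barrier = gtv.with_occupancy(~gtv.occupancy)  # everything outside the GTV
        with pytest.raises(NoVectorError):
            directional_margin(gtv, ctv, L, barrier=barrier)

    def test_barrier_never_increases_accepted_vectors(self, sphere_phantom):
        gtv, ctv = sphere_phantom.gtv, sphere_phantom.ctv
        saw_rejection = False
        for z0 in [12.0, 13.0, 14.0]:
            # half-space barrier z >= z0 (inside the CTV cap, above the GTV)
            zc = gtv.origin[2] + gtv.spacing[2] * np.arange(gtv.shape[2])
            occ = np.zeros(gtv.shape, dtype=bool)
            occ[:, :, zc >= z0] = True
            barrier = gtv.with_occupancy(occ)
            for d in [DirectionSpec.from_label("S"), DirectionSpec.from_label("SA")]:
                free = directional_margin(gtv, ctv, d)
                try:
                    blocked = directional_margin(gtv, ctv, d, barrier=barrier)
                    n_blocked = len(blocked.vector_set.lengths)
                    saw_rejection |= blocked.vector_set.n_rejected_barrier > 0
                except NoVectorError:
                    n_blocked = 0
                    saw_rejection = True
                assert n_blocked <= len(free.vector_set.lengths)
        assert saw_rejection  # the barrier actually intersected some rays

    def test_caster_agrees_with_dense_marcher(self, u_phantom, sphere_phantom):
        # 200 random rays across a concave and a curved phantom, checked
        # against a fixed-step (0.005 * spacing) marcher with no bisection
        rng = np.random.default_rng(2024)
        budget = 200
        for ph in (u_phantom, sphere_phantom):
            gtv, ctv = ph.gtv, ph.ctv
            surf = extract_surface(gtv)
            n = budget // 2
            rows = rng.choice(len(surf), size=n, replace=False)
            dirs = rng.normal(size=(n, 3))
            for row, dvec in zip(rows, dirs):
                d = DirectionSpec.from_vector(dvec, label="rnd")
                fast = cast_expansion_vector(surf.points[row], d, gtv, ctv)
                slow_status, slow_len = dense_cast(gtv, ctv, d, surf.points[row])
                assert fast.status == slow_status
                if slow_len is not None:
                    assert fast.length_mm == pytest.approx(slow_len, abs=0.05)

    def test_u_shape_rejects_rays_across_slot(self, u_phantom):
        res = directional_margin(u_phantom.gtv, u_phantom.ctv, L)
        assert res.vector_set.n_rejected_interior > 0
        # the accepted rays pass through the solid base: all equal the face offset
        assert res.margin_mm == pytest.approx(4.0, abs=1e-9)


@pytest.fixture(scope="module")
def aniso():
    return make_phantom(
        PhantomSpec(
            gtv_shape="sphere",
            size_mm=(8.0,),
            expansion={"per_axis": (3.0, 5.0, 4.0)},
            spacing_mm=(1.0, 1.0, 1.0),
        )
    )


class TestRigidMotionAndScale:

    def test_translation_by_whole_voxels_is_exact(self, aniso):
        d = DirectionSpec.from_vector([0.3, -0.5, 0.81], label="d")
        m0 = directional_margin(aniso.gtv, aniso.ctv, d).margin_mm
        shift = np.array([3.0, -2.0, 5.0])
        gtv = BinaryVolume(aniso.gtv.occupancy, aniso.gtv.spacing, aniso.gtv.origin + shift)
        ctv = BinaryVolume(aniso.ctv.occupancy, aniso.ctv.spacing, aniso.ctv.origin + shift)
        assert directional_margin(gtv, ctv, d).margin_mm == m0

    def test_rotation_about_grid_axis(self, aniso):
        # 90 deg about z: (x, y) -> (-y, x); exact up to float round-off in
        # the reflected coordinate arithmetic
        d = DirectionSpec.from_vector([0.3, -0.5, 0.81], label="d")
        m0 = directional_margin(aniso.gtv, aniso.ctv, d).margin_mm

        def rot(v):
            return BinaryVolume(
                np.rot90(v.occupancy, k=1, axes=(0, 1)),
                v.spacing[[1, 0, 2]],
                v.origin,
                v.axis_directions,
            )

        dr = DirectionSpec.from_vector(
            [-d.vector[1], d.vector[0], d.vector[2]], label="dr"
        )
        m1 = directional_margin(rot(aniso.gtv), rot(aniso.ctv), dr).margin_mm
        assert m1 == pytest.approx(m0, abs=1e-12)

    def test_spacing_scale_equivariance_power_of_two(self, aniso):
        d = DirectionSpec.from_vector([0.3, -0.5, 0.81], label="d")
        params = CastParams()
        m0 = directional_margin(aniso.gtv, aniso.ctv, d, params=params).margin_mm
        s = 2.0

        def scale(v):
            return BinaryVolume(v.occupancy, v.spacing * s, v.origin * s)

        m1 = directional_margin(
            scale(aniso.gtv), scale(aniso.ctv), d, params=params.scaled(s)
        ).margin_mm
        assert m1 == s * m0


class TestMarginDeviation:
    def test_identical_experts_cv_zero(self, slab_phantom):
        gtv, ctv = slab_phantom.gtv, slab_phantom.ctv
        res = margin_deviation(gtv, [ctv, ctv, ctv], L)
        assert res.cv == 0.0

    def test_three_slab_experts_cv_half(self):
        # experts at +1, +2, +3 mm: sample SD 1.0, mean 2.0 -> cv = 0.5
        gtv, _ = slab_pair()
        experts = [expert_slab(gtv, plus=m) for m in (1.0, 2.0, 3.0)]
        res = margin_deviation(gtv, experts, L)
        assert res.per_expert_margins_mm == pytest.approx([1.0, 2.0, 3.0], abs=1e-9)
        assert res.cv == pytest.approx(0.5, abs=1e-9)

    def test_two_experts_cv(self):
        # margins {4, 6}: sample SD sqrt(2), mean 5 -> cv = 0.28284
        gtv, _ = slab_pair()
        experts = [expert_slab(gtv, plus=m) for m in (4.0, 6.0)]
        res = margin_deviation(gtv, experts, L)
        assert res.cv == pytest.approx(np.sqrt(2.0) / 5.0, abs=1e-9)

    def test_all_zero_margins_cv_zero_by_convention(self, slab_phantom):
        gtv = slab_phantom.gtv
        res = margin_deviation(gtv, [gtv, gtv], L)
        assert res.cv == 0.0

    def test_fewer_than_two_experts_raises(self, slab_phantom):
        with pytest.raises(InsufficientExpertsError):
            margin_deviation(slab_phantom.gtv, [slab_phantom.ctv], L)

    def test_tighter_expert_contributes_zero_not_failure(self):
        # one expert's CTV equals the GTV: clamped to margin 0, K preserved
        gtv, ctv = slab_pair()
        res = margin_deviation(gtv, [ctv, gtv], L)
        assert res.per_expert_margins_mm == pytest.approx([7.0, 0.0], abs=1e-9)

    def test_expert_permutation_leaves_cv_unchanged(self):
        gtv, _ = slab_pair()
        experts = [expert_slab(gtv, plus=m) for m in (1.0, 3.0, 6.0)]
        a = margin_deviation(gtv, experts, L).cv
        b = margin_deviation(gtv, experts[::-1], L).cv
        assert a == b
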