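"""Line-trajectory geometry, profile sampling, centre detection, radial
fans, and signature classification."""

import math

import numpy as np
import pytest

from sinudens import densitogram as dg
from sinudens import phantom
from sinudens.densitogram import (Signature, Thresholds, aggregate_signatures,
                                  classify_profile, line_trajectory, radial_fan,
                                  sample_profile, sinus_center)
from sinudens.volume import LabelVolume, Tissue, Volume


def brute_force_samples(ts, te):
    """Independent evaluation of the parametric line at steps 1/d."""
    xs, ys = ts
    xe, ye = te
    d = math.sqrt((xe - xs) ** 2 + (ye - ys) ** 2)
    dt = 1.0 / d
    t, ts_list = 0.0, []
    while t < 1.0 - 1e-12:
        ts_list.append(t)
        t += dt
    ts_list.append(1.0)
    coords = [(xs + (xe - xs) * t, ys + (ye - ys) * t) for t in ts_list]
    return d, ts_list, coords


class TestLineTrajectory:
    def test_3_4_5_triangle(self):
        tr = line_trajectory((0, 0), (3, 4))
        assert tr.d == 5.0
        assert tr.dt == pytest.approx(0.2)
        assert np.allclose(tr.t_samples, [0, 0.2, 0.4, 0.6, 0.8, 1.0])

    def test_axis_aligned_coordinates(self):
        tr = line_trajectory((0, 0), (10, 0))
        x, y = tr.coordinates()
        assert np.allclose(x, np.arange(11))
        assert np.allclose(y, 0)

    def test_matches_brute_force_on_stated_example(self):
        tr = line_trajectory((2, 3), (7, 15))
        d, ts_list, coords = brute_force_samples((2, 3), (7, 15))
        assert tr.d == pytest.approx(13.0)
        assert len(tr.t_samples) == len(ts_list) == 14
        x, y = tr.coordinates()
        assert np.allclose(np.c_[x, y], coords)

    def test_matches_brute_force_on_random_endpoints(self, rng):
        for _ in range(100):
            ts = tuple(rng.uniform(0, 50, 2))
            te = tuple(rng.uniform(0, 50, 2))
            if ts == te:
                continue
            tr = line_trajectory(ts, te)
            d, ts_list, coords = brute_force_samples(ts, te)
            assert tr.d == pytest.approx(d)
            assert len(tr.t_samples) == len(ts_list)
            x, y = tr.coordinates()
            assert np.allclose(np.c_[x, y], coords)
            # sample count within one of ceil(d) + 1
            assert abs(len(tr.t_samples) - (math.ceil(d) + 1)) <= 1

    def test_coincident_endpoints_rejected(self):
        with pytest.raises(ValueError):
            line_trajectory((1, 1), (1, 1))

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError, match="end"):
            line_trajectory((0, 0), (100, 0), slice_shape=(32, 32))


class TestSampleProfile:
    def _vol(self, sl):
        return Volume(np.asarray(sl, float)[None], (1, 1, 1), unit="hu")

    def test_constant_slice_both_interpolators(self):
        vol = self._vol(np.full((16, 16), 100.0))
        tr = line_trajectory((1, 1), (14, 12))
        for interp in ("nearest", "linear"):
            prof = sample_profile(vol, tr, interp)
            assert np.allclose(prof.values, 100.0)
            assert len(prof.values) == len(tr.t_samples)

    def test_step_edge_nearest(self):
        sl = np.zeros((8, 16))
        sl[:, 8:] = 50.0
        prof = sample_profile(self._vol(sl), line_trajectory((0, 4), (15, 4)))
        assert np.array_equal(np.unique(prof.values), [0.0, 50.0])
        assert np.all(np.diff(prof.values) >= 0)

    def test_reversed_trajectory_reverses_profile(self, serous_phantom):
        vol = serous_phantom[0]
        k = vol.n_slices // 2
        tr = line_trajectory((10, 10), (50, 40), k)
        fwd = sample_profile(vol, tr)
        bwd = sample_profile(vol, tr.reversed())
        assert np.array_equal(fwd.values, bwd.values[::-1])

    def test_ray_through_bone_shows_plateau_then_peak(self, norm_phantom):
        vol, labels, _ = norm_phantom
        k = vol.n_slices // 2
        cx, cy = sinus_center(labels, k)
        prof = sample_profile(vol, line_trajectory((cx, cy), (cx, 62), k))
        r_vox = 12.0 / vol.spacing_mm[1]  # cavity radius in voxels
        first_bone = np.nonzero(prof.values >= 700)[0][0]
        assert abs(prof.positions_px[first_bone] - r_vox) <= 1.5
        assert np.all(prof.values[: first_bone - 1][1:-1] <= -500)

    def test_trajectory_outside_volume_rejected(self):
        vol = self._vol(np.zeros((8, 8)))
        tr = line_trajectory((0, 0), (3, 4), slice_index=5)
        with pytest.raises(ValueError):
            sample_profile(vol, tr)


class TestSinusCenter:
    def test_full_sphere_centroid(self, norm_phantom):
        labels = norm_phantom[1]
        k = labels.shape[0] // 2
        cx, cy = sinus_center(labels, k)
        # grid centre of a 64-cube lies between voxels 31 and 32
        assert abs(cx - 31.5) <= 1 and abs(cy - 31.5) <= 1

    def test_center_unmoved_by_filling(self, norm_phantom, serous_phantom):
        k = norm_phantom[1].shape[0] // 2
        assert sinus_center(norm_phantom[1], k) == sinus_center(serous_phantom[1], k)

    def test_crescent_matches_coordinate_average(self):
        lab = np.zeros((1, 32, 32), np.uint8)
        yy, xx = np.mgrid[0:32, 0:32]
        crescent = ((yy - 16) ** 2 + (xx - 16) ** 2 <= 100) & (xx > 18)
        lab[0][crescent] = int(Tissue.AIR)
        labels = LabelVolume(lab, (1, 1, 1))
        ys, xs = np.nonzero(crescent)
        assert sinus_center(labels, 0) == (round(xs.mean()), round(ys.mean()))

    def test_no_interior_voxels(self):
        labels = LabelVolume(np.ones((1, 8, 8), np.uint8), (1, 1, 1))  # all bone
        with pytest.raises(ValueError, match="center undeterminable"):
            sinus_center(labels, 0)


class TestRadialFan:
    def test_three_rays_hit_cardinal_angles(self):
        rays = radial_fan((20, 20), 10, n_rays=3)
        ends = [r.end for r in rays]
        assert ends[0] == pytest.approx((10, 20))  # horizontal left
        assert ends[1] == pytest.approx((20, 30))  # straight down
        assert ends[2] == pytest.approx((30, 20))  # horizontal right

    def test_angular_gap(self):
        rays = radial_fan((20, 20), 10, n_rays=5)
        angles = [math.degrees(math.atan2(r.end[1] - 20, r.end[0] - 20)) for r in rays]
        gaps = np.diff(sorted(angles))
        assert np.allclose(np.abs(gaps), 45, atol=1e-9)

    def test_clipping_near_edge(self):
        rays = radial_fan((3, 28), 20, n_rays=13, slice_shape=(32, 32))
        for r in rays:
            assert r.d <= 20 + 1e-9
            x, y = r.coordinates()
            assert x.min() >= 0 and x.max() <= 31
            assert y.min() >= 0 and y.max() <= 31

    def test_validation(self):
        with pytest.raises(ValueError):
            radial_fan((5, 5), 10, n_rays=2)
        with pytest.raises(ValueError, match="center"):
            radial_fan((50, 5), 10, slice_shape=(32, 32))


def toy_profile(values):
    v = np.asarray(values, float)
    return dg.Densitogram(positions_px=np.arange(v.size, dtype=float),
                          positions_mm=np.arange(v.size, dtype=float),
                          values=v, unit="hu",
                          trajectory=line_trajectory((0, 0), (v.size - 1.0, 0)))


class TestClassifyProfile:
    def test_normal_signature(self):
        sig = classify_profile(toy_profile([-1000] * 20 + [700, 700]))
        assert sig.label == Signature.NORMAL

    def test_tissue_content(self):
        sig = classify_profile(toy_profile([-1000] * 5 + [19] * 15 + [700, 700]))
        assert sig.label == Signature.TISSUE_CONTENT

    def test_perforation_no_bone_peak(self):
        sig = classify_profile(toy_profile([40] * 20))
        assert sig.label == Signature.PERFORATION

    def test_cyst_extra_border(self):
        profile = [-1000] * 5 + [45] * 6 + [-1000] * 5 + [700, 700]
        sig = classify_profile(toy_profile(profile))
        assert sig.label == Signature.CYST
        assert sig.evidence["tissue_upward_crossings"] >= 2

    def test_foreign_body_overrides_everything(self):
        profile = [-1000] * 5 + [2000] * 2 + [19] * 10 + [700]
        sig = classify_profile(toy_profile(profile))
        assert sig.label == Signature.FOREIGN_BODY

    def test_rule_order_on_enumerated_toy_profiles(self):
        # any profile containing a metal-level sample is FOREIGN_BODY no
        # matter what other evidence it carries
        bases = [
            [-1000] * 10 + [700],
            [19] * 10 + [700],
            [45] * 5 + [-1000] * 5 + [700],
            [40] * 11,
        ]
        for base in bases:
            spiked = list(base)
            spiked[4] = 2000
            assert classify_profile(toy_profile(spiked)).label == Signature.FOREIGN_BODY

    def test_padding_beyond_bone_peak_is_ignored(self):
        base = [-1000] * 15 + [700, 700]
        padded = base + [40] * 10
        assert (classify_profile(toy_profile(base)).label
                == classify_profile(toy_profile(padded)).label
                == Signature.NORMAL)

    def test_too_short_profile(self):
        with pytest.raises(ValueError):
            classify_profile(toy_profile([0, 1, 2]))

    def test_threshold_ordering_enforced(self):
        with pytest.raises(ValueError):
            Thresholds(t_air=0, t_tissue=-10, t_bone=300)


class TestAggregate:
    def _sigs(self, labels):
        return [dg.ProfileSignature(label=l) for l in labels]

    def test_all_normal(self):
        label, support, _ = aggregate_signatures(self._sigs([Signature.NORMAL] * 5))
        assert label == Signature.NORMAL and support == 5

    def test_priority_with_min_support(self):
        sigs = self._sigs([Signature.NORMAL] * 11 + [Signature.PERFORATION] * 2)
        label, support, _ = aggregate_signatures(sigs, min_support=2)
        assert label == Signature.PERFORATION and support == 2

    def test_min_support_guards_single_ray(self):
        sigs = self._sigs([Signature.NORMAL] * 11 + [Signature.PERFORATION])
        label, _, _ = aggregate_signatures(sigs, min_support=2)
        assert label == Signature.NORMAL

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate_signatures([])


class TestPhantomFans:
    """Lesion presets produce their designated signature on every ray
    that geometrically intersects the lesion."""

    def _fan_signatures(self, name, n_rays=13):
        vol, labels, gt = phantom.make_sinus_phantom(phantom.preset_config(name))
        k = vol.n_slices // 2
        center = sinus_center(labels, k)
        radius = (12.0 + 2.5) / vol.spacing_mm[1] + 3  # through the bone wall
        fan = radial_fan(center, radius, n_rays, slice_index=k,
                         slice_shape=labels.shape[1:])
        sigs = [classify_profile(sample_profile(vol, t)) for t in fan]
        return fan, sigs, center, vol

    def test_normal_phantom_all_rays_normal(self):
        _, sigs, _, _ = self._fan_signatures("conditional_norm")
        assert all(s.label == Signature.NORMAL for s in sigs)

    @staticmethod
    def _ray_hits_sphere(ray, center_px, sphere_px, r_px, margin=1.0):
        """Chord test: perpendicular distance of the ray line to the
        sphere centre, restricted to the ray's parameter range."""
        p0 = np.array(ray.start)
        p1 = np.array(ray.end)
        c = np.array(sphere_px)
        d = p1 - p0
        t = np.clip(np.dot(c - p0, d) / np.dot(d, d), 0, 1)
        closest = p0 + t * d
        return np.linalg.norm(closest - c) <= r_px - margin

    def test_cyst_rays_designated(self):
        cfg = phantom.preset_config("cyst")
        fan, sigs, center, vol = self._fan_signatures("cyst")
        sy = vol.spacing_mm[1]
        cyst_px = (center[0] + cfg.cyst.offset_mm[2] / sy,
                   center[1] + cfg.cyst.offset_mm[1] / sy)
        r_px = cfg.cyst.radius_mm / sy
        hits = [self._ray_hits_sphere(ray, center, cyst_px, r_px) for ray in fan]
        assert any(hits)
        for ray, sig, hit in zip(fan, sigs, hits):
            if hit:
                assert sig.label == Signature.CYST

    def test_foreign_body_rays_designated(self):
        cfg = phantom.preset_config("foreign_body")
        fan, sigs, center, vol = self._fan_signatures("foreign_body")
        sy = vol.spacing_mm[1]
        fb_px = (center[0] + cfg.foreign_body.offset_mm[2] / sy,
                 center[1] + cfg.foreign_body.offset_mm[1] / sy)
        r_px = cfg.foreign_body.radius_mm / sy
        hits = [self._ray_hits_sphere(ray, center, fb_px, r_px) for ray in fan]
        assert any(hits)
        for ray, sig, hit in zip(fan, sigs, hits):
            if hit:
                assert sig.label == Signature.FOREIGN_BODY

    def test_perforation_rays_designated(self):
        cfg = phantom.preset_config("perforation")
        fan, sigs, center, vol = self._fan_signatures("perforation")
        half = math.radians(cfg.perforation.half_angle_deg)
        found = 0
        for ray, sig in zip(fan, sigs):
            dx = ray.end[0] - ray.start[0]
            dy = ray.end[1] - ray.start[1]
            angle_from_down = math.atan2(abs(dx), dy) if dy > 0 else math.pi
            if angle_from_down <= half - math.radians(5):  # clear of the rim
                assert sig.label == Signature.PERFORATION
                found += 1
        assert found >= 1

    def test_cyst_support_matches_geometry(self):
        cfg = phantom.preset_config("cyst")
        fan, sigs, center, vol = self._fan_signatures("cyst")
        label, support, _ = aggregate_signatures(sigs)
        assert label == Signature.CYST
        sy = vol.spacing_mm[1]
        cyst_px = (center[0] + cfg.cyst.offset_mm[2] / sy,
                   center[1] + cfg.cyst.offset_mm[1] / sy)
        r_px = cfg.cyst.radius_mm / sy
        n_hits = sum(self._ray_hits_sphere(ray, center, cyst_px, r_px) for ray in fan)
        assert support >= n_hits
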