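"""Lesion planners, phase mapping, singularity detection, success labels."""

import math
import warnings

import numpy as np
import pytest
from scipy import ndimage

from afablate import ablation, epsim, tissue
from afablate.ablation import (
    LabelConfig,
    LesionMask,
    Strategy,
    StrategyLabels,
    compute_phase,
    detect_ps,
    plan_fibro,
    plan_pvi,
    plan_rotor,
    success_rule,
)


# ---------------------------------------------------------------------------
# planners


def test_pvi_rings_encircle_each_pv(small_disk):
    lm = plan_pvi(small_disk, ring_width=2)
    assert lm.strategy is Strategy.PVI
    H, W = small_disk.label_grid.shape
    rr, cc = np.mgrid[0:H, 0:W]
    for r0, c0, rad in small_disk.geometry.pv_list:
        d = np.hypot(rr - r0, cc - c0)
        ring_px = lm.mask & (d <= rad + 3)
        assert ring_px.sum() > 0
        # every mask pixel near this PV sits within ring_width+1 of its rim
        assert np.all(d[ring_px] <= rad + 3)
    # and no lesion pixel is far from every PV rim
    near_any = np.zeros((H, W), bool)
    for r0, c0, rad in small_disk.geometry.pv_list:
        d = np.hypot(rr - r0, cc - c0)
        near_any |= d <= rad + 3
    assert np.all(near_any[lm.mask])


def test_pvi_rejects_degenerate_width(small_disk):
    with pytest.raises(ValueError):
        plan_pvi(small_disk, ring_width=0)


def _disk_with_square_fibrosis(geom, r0=40, c0=40, size=10):
    label = np.full(geom.grid_shape, tissue.Label.OUTSIDE, np.uint8)
    label[geom.disk_mask] = tissue.Label.HEALTHY
    label[r0:r0 + size, c0:c0 + size] = tissue.Label.FIBROTIC
    d = tissue.TissueDisk(geometry=geom, label_grid=label, fibrotic_fraction=0.0)
    d.fibrotic_fraction = d.recompute_fibrotic_fraction()
    return d


def test_fibro_square_outline(geometry128):
    d = _disk_with_square_fibrosis(geometry128)
    lm = plan_fibro(d, min_region_px=9)
    assert 0 < lm.mask.sum() <= 44
    # perimeter only: no overlap with the fibrotic interior
    assert not (lm.mask & d.fibrosis_mask).any()
    # equals the one-pixel outer boundary
    comp = d.fibrosis_mask
    expected = ndimage.binary_dilation(comp) & ~comp & d.tissue_mask
    assert np.array_equal(lm.mask, expected)


def test_fibro_no_fibrosis_empty(geometry128):
    label = np.full(geometry128.grid_shape, tissue.Label.OUTSIDE, np.uint8)
    label[geometry128.disk_mask] = tissue.Label.HEALTHY
    d = tissue.TissueDisk(geometry=geometry128, label_grid=label, fibrotic_fraction=0.0)
    lm = plan_fibro(d)
    assert lm.mask.sum() == 0
    assert lm.ablated_fraction == 0.0


def test_fibro_ignores_speckle(geometry128):
    d = _disk_with_square_fibrosis(geometry128, size=2)  # 4 px < min_region
    lm = plan_fibro(d, min_region_px=9)
    assert lm.mask.sum() == 0


def test_fibro_mask_within_boundary_zone(small_disk):
    lm = plan_fibro(small_disk)
    fib = small_disk.fibrosis_mask
    zone = ndimage.binary_dilation(fib) & ~ndimage.binary_erosion(fib)
    assert np.all(zone[lm.mask])


# ---------------------------------------------------------------------------
# phase


def test_phase_of_sinusoid_advances_uniformly():
    f = 0.02  # cycles per ms
    t = np.arange(0, 400, 2.0)
    u = np.sin(2 * np.pi * f * t)[:, None, None] * np.ones((1, 4, 4))
    phase = compute_phase(u)
    mid = phase[:, 2, 2]
    slope = np.diff(np.unwrap(mid)).mean() / 2.0  # rad per ms
    assert slope == pytest.approx(2 * np.pi * f, rel=0.01)


def test_phase_flags_quiescent_pixels():
    t = np.arange(0, 200, 2.0)
    u = np.zeros((len(t), 3, 3))
    u[:, 0, 0] = np.sin(0.1 * t)
    phase = compute_phase(u)
    assert np.all(np.isnan(phase[:, 1, 1]))
    assert not np.any(np.isnan(phase[:, 0, 0]))


def test_phase_quarter_cycle_offset():
    t = np.arange(0, 400, 2.0)
    u = np.zeros((len(t), 1, 2))
    u[:, 0, 0] = np.sin(0.05 * t)
    u[:, 0, 1] = np.sin(0.05 * t + np.pi / 2)
    phase = compute_phase(u)
    d = np.angle(np.exp(1j * (phase[:, 0, 1] - phase[:, 0, 0])))
    assert d[20:-20].mean() == pytest.approx(np.pi / 2, abs=0.03)
    assert np.allclose(d[20:-20], np.pi / 2, atol=0.2)


def test_phase_requires_window():
    with pytest.raises(ValueError):
        compute_phase(np.zeros((4, 3, 3)))


# ---------------------------------------------------------------------------
# phase singularities vs brute-force oracle


def oracle_ps(phase):
    """Independent plaquette winding-number scan (scalar loops)."""
    H, W = phase.shape
    out = []
    for i in range(H - 1):
        for j in range(W - 1):
            corners = [phase[i, j], phase[i, j + 1], phase[i + 1, j + 1], phase[i + 1, j]]
            if any(math.isnan(c) for c in corners):
                continue
            s = 0.0
            for k in range(4):
                d = corners[(k + 1) % 4] - corners[k]
                while d > math.pi:
                    d -= 2 * math.pi
                while d <= -math.pi:
                    d += 2 * math.pi
                s += d
            q = round(s / (2 * math.pi))
            if q != 0:
                out.append((i, j, q))
    return out


def defect_field(shape, defects, smooth_seed=None):
    H, W = shape
    y, x = np.mgrid[0:H, 0:W]
    phase = np.zeros(shape)
    for (r0, c0, q) in defects:
        phase = phase + q * np.arctan2(y - r0, x - c0)
    if smooth_seed is not None:
        rng = np.random.default_rng(smooth_seed)
        noise = ndimage.gaussian_filter(rng.standard_normal(shape), 4.0)
        phase = phase + 2.0 * noise
    return np.angle(np.exp(1j * phase))


def test_single_defect_detected_at_core():
    phase = defect_field((40, 40), [(20.3, 19.6, 1)])
    found = detect_ps(phase)
    assert len(found) == 1
    ps = found[0]
    assert ps.charge == 1
    assert abs(ps.row - 20.3) <= 1.5 and abs(ps.col - 19.6) <= 1.5


def test_mirror_pair_has_zero_total_charge():
    # off-node cores: a defect exactly on a grid node splits its winding
    # over the four surrounding plaquettes
    phase = defect_field((40, 40), [(20.4, 12.3, 1), (19.7, 28.4, -1)])
    found = detect_ps(phase)
    assert len(found) == 2
    assert sum(p.charge for p in found) == 0


def test_uniform_phase_has_no_singularity():
    assert detect_ps(np.full((20, 20), 0.7)) == []


def test_detector_agrees_with_oracle_on_random_fields():
    rng = np.random.default_rng(99)
    for trial in range(50):
        n_def = int(rng.integers(0, 4))
        defects = [
            (float(rng.uniform(6, 34)), float(rng.uniform(6, 34)), int(rng.choice([-1, 1])))
            for _ in range(n_def)
        ]
        phase = defect_field((40, 40), defects, smooth_seed=trial)
        got = {(int(p.row - 0.5), int(p.col - 0.5), p.charge) for p in detect_ps(phase)}
        want = {(i, j, q) for i, j, q in oracle_ps(phase)}
        assert got == want


def test_total_charge_conserved_with_constant_boundary():
    # smooth interior deformation with constant boundary phase: net charge 0
    phase = defect_field((40, 40), [(16.4, 16.2, 1), (24.6, 23.8, -1)], smooth_seed=5)
    found = detect_ps(phase)
    assert sum(p.charge for p in found) == 0


# ---------------------------------------------------------------------------
# rotor planning on synthetic rotating fields


def synthetic_rotor_result(centres, shape=(64, 64), n_frames=120, period=40.0):
    # each rotor carries a Gaussian envelope so far-apart cores do not
    # interfere; quiescent pixels are amplitude-masked by the phase step
    H, W = shape
    y, x = np.mgrid[0:H, 0:W]
    times = np.arange(n_frames) * 2.0
    snaps = np.zeros((n_frames, H, W), np.float32)
    for k, t in enumerate(times):
        u = np.zeros((H, W))
        for (r0, c0) in centres:
            theta = np.arctan2(y - r0, x - c0)
            env = np.exp(-((y - r0) ** 2 + (x - c0) ** 2) / (2 * 8.0**2))
            u = u + env * np.cos(theta - 2 * np.pi * t / period)
        snaps[k] = 0.5 + 0.4 * u / max(1, len(centres))
    return epsim.SimulationResult(
        snapshots=snaps, snapshot_times=times,
        max_u_trace=np.ones(n_frames), trace_times=times,
        terminated=False, termination_time=None, t_end=times[-1],
    )


def _plain_disk(shape=(64, 64)):
    return tissue.make_sheet(shape)


def test_plan_rotor_single_stationary_core():
    res = synthetic_rotor_result([(32, 30)])
    disk = _plain_disk()
    lm = plan_rotor(res, disk, lesion_radius=3, mapping_window=200.0)
    lab, n = ndimage.label(lm.mask)
    assert n == 1
    com = ndimage.center_of_mass(lm.mask)
    assert np.hypot(com[0] - 32, com[1] - 30) <= 3.0


def test_plan_rotor_two_separated_cores():
    res = synthetic_rotor_result([(20, 16), (44, 48)])
    disk = _plain_disk()
    lm = plan_rotor(res, disk, lesion_radius=3, mapping_window=200.0)
    lab, n = ndimage.label(lm.mask)
    assert n == 2


def test_plan_rotor_quiescent_gives_empty_mask():
    n_frames = 120
    times = np.arange(n_frames) * 2.0
    res = epsim.SimulationResult(
        snapshots=np.zeros((n_frames, 64, 64), np.float32),
        snapshot_times=times, max_u_trace=np.zeros(n_frames),
        trace_times=times, terminated=True, termination_time=0.0, t_end=times[-1],
    )
    with pytest.warns(UserWarning, match="no phase singularities"):
        lm = plan_rotor(res, _plain_disk(), lesion_radius=3)
    assert lm.mask.sum() == 0


# ---------------------------------------------------------------------------
# success rule and labels


@pytest.mark.parametrize(
    "terminated,t_term,frac,expected",
    [
        (True, 1500.0, 0.30, True),
        (True, 1500.0, 0.45, False),
        (False, None, 0.10, False),
    ],
)
def test_success_rule_cases(terminated, t_term, frac, expected):
    assert success_rule(terminated, t_term, frac, t_end=2000.0) is expected


def test_success_rule_matches_independent_rederivation(rng):
    for _ in range(100):
        terminated = bool(rng.random() < 0.5)
        t_term = float(rng.uniform(0, 2500)) if terminated else None
        frac = float(rng.uniform(0, 0.8))
        expect = terminated and (t_term is not None and t_term <= 2000.0) and frac < 0.40
        assert success_rule(terminated, t_term, frac) == expect


def test_labels_vector_ordering():
    lab = StrategyLabels(pvi=False, fibro=True, rotor=True)
    assert np.array_equal(lab.y, [0.0, 1.0, 1.0])


def test_lesion_mask_fraction_recomputable(small_disk):
    lm = plan_pvi(small_disk)
    n_t = small_disk.tissue_mask.sum()
    assert lm.ablated_fraction == pytest.approx(lm.mask.sum() / n_t)
    # masks never cover non-tissue
    assert not (lm.mask & ~small_disk.tissue_mask).any()
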