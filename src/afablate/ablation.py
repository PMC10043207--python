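"""Ablation strategy planning, phase-singularity mapping and outcome labels.

Three catheter-ablation strategies are modelled as binary lesion masks on a
tissue disk:

* ``PVI``   - rings of ablated tissue encircling each pulmonary-vein opening;
* ``FIBRO`` - the perimeter of every sufficiently large fibrotic patch;
* ``ROTOR`` - discs at the organising centres (phase singularities) of the
  re-entrant activity observed in a baseline simulation.

A strategy succeeds for a disk when the simulated fibrillation terminates
within the episode limit (2000 ms at full scale) and less than 40% of the
tissue has been ablated.  The three success booleans, ordered
(PVI, FIBRO, ROTOR), are the multi-label training target for the outcome
classifier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy import ndimage
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.signal import hilbert

from . import epsim
from .tissue import Label, TissueDisk


class Strategy(str, Enum):
    PVI = "pvi"
    FIBRO = "fibro"
    ROTOR = "rotor"


@dataclass
class LesionMask:
    """Binary set of ablated pixels for one strategy."""

    mask: np.ndarray
    strategy: Strategy
    ablated_fraction: float = 0.0

    @staticmethod
    def from_mask(mask: np.ndarray, strategy: Strategy, disk: TissueDisk) -> "LesionMask":
        tissue = disk.tissue_mask
        mask = mask & tissue
        n_t = int(tissue.sum())
        frac = float(mask.sum()) / n_t if n_t else 0.0
        return LesionMask(mask=mask, strategy=strategy, ablated_fraction=frac)


@dataclass(frozen=True)
class PhaseSingularity:
    """Spiral-wave organising centre with topological charge +-1."""

    row: float
    col: float
    time: float
    charge: int


@dataclass
class StrategyOutcome:
    strategy: Strategy
    lesions: LesionMask
    terminated: bool
    termination_time: float | None
    success: bool


@dataclass
class StrategyLabels:
    """Success booleans ordered (PVI, FIBRO, ROTOR)."""

    pvi: bool
    fibro: bool
    rotor: bool

    @property
    def y(self) -> np.ndarray:
        return np.array([self.pvi, self.fibro, self.rotor], dtype=float)


class NonInducibleError(RuntimeError):
    """Baseline simulation failed to sustain fibrillation on this disk."""


# ---------------------------------------------------------------------------
# lesion planners


def plan_pvi(disk: TissueDisk, ring_width: int = 2) -> LesionMask:
    """Annulus of ``ring_width`` tissue pixels around each PV opening."""
    if ring_width < 1:
        raise ValueError("ring_width must be >= 1")
    H, W = disk.label_grid.shape
    rr, cc = np.mgrid[0:H, 0:W]
    mask = np.zeros((H, W), dtype=bool)
    for r0, c0, rad in disk.geometry.pv_list:
        d2 = (rr - r0) ** 2 + (cc - c0) ** 2
        ring = (d2 > rad**2) & (d2 <= (rad + ring_width) ** 2)
        mask |= ring
    lm = LesionMask.from_mask(mask, Strategy.PVI, disk)
    # a ring clipped by the disk edge stays partial; flag it
    lab, n = ndimage.label(lm.mask)
    if n < len(disk.geometry.pv_list):
        warnings.warn("PVI rings broken or merged; partial isolation", stacklevel=2)
    return lm


def plan_fibro(disk: TissueDisk, min_region_px: int = 9) -> LesionMask:
    """One-pixel outer perimeter of every fibrotic patch of at least
    ``min_region_px`` pixels (smaller speckle is ignored)."""
    fib = disk.fibrosis_mask
    lab, n = ndimage.label(fib)
    mask = np.zeros_like(fib)
    for i in range(1, n + 1):
        comp = lab == i
        if comp.sum() < min_region_px:
            continue
        ring = ndimage.binary_dilation(comp) & ~comp
        mask |= ring
    return LesionMask.from_mask(mask, Strategy.FIBRO, disk)


# ---------------------------------------------------------------------------
# phase and phase singularities


def compute_phase(u_history: np.ndarray, min_amplitude: float = 1e-3) -> np.ndarray:
    """Instantaneous phase of each pixel's u time series.

    Analytic-signal (Hilbert transform) construction on the mean-subtracted
    series; returns phase in (-pi, pi] with NaN where the oscillation
    amplitude is negligible (quiescent or non-tissue pixels).

    Parameters
    ----------
    u_history : (T, H, W) snapshot stack covering at least one rotation.
    """
    if u_history.ndim != 3 or u_history.shape[0] < 8:
        raise ValueError("need a (T, H, W) stack with T >= 8 samples")
    series = u_history.astype(float)
    centred = series - series.mean(axis=0, keepdims=True)
    analytic = hilbert(centred, axis=0)
    phase = np.angle(analytic)
    amp = np.abs(analytic).max(axis=0)
    phase[:, amp < min_amplitude] = np.nan
    return phase


def _wrap(a: np.ndarray) -> np.ndarray:
    return (a + np.pi) % (2 * np.pi) - np.pi


def detect_ps(phase: np.ndarray, time: float = 0.0) -> list[PhaseSingularity]:
    """Phase singularities of one phase frame by plaquette winding number.

    The wrapped phase differences are summed around every 2x2 plaquette;
    a total of +-2pi marks a singularity of charge +-1 at the plaquette
    centre.  Plaquettes touching undefined (NaN) phase are skipped.
    """
    p = phase
    a, b, c, d = p[:-1, :-1], p[:-1, 1:], p[1:, 1:], p[1:, :-1]
    total = _wrap(b - a) + _wrap(c - b) + _wrap(d - c) + _wrap(a - d)
    valid = ~(np.isnan(a) | np.isnan(b) | np.isnan(c) | np.isnan(d))
    hits = valid & (np.abs(total) > np.pi)
    out = []
    for r, cidx in zip(*np.nonzero(hits)):
        charge = 1 if total[r, cidx] > 0 else -1
        out.append(PhaseSingularity(row=r + 0.5, col=cidx + 0.5, time=time, charge=charge))
    return out


def track_ps(u_history: np.ndarray, times: np.ndarray) -> list[PhaseSingularity]:
    """All phase singularities over a snapshot window (one phase pass)."""
    phase = compute_phase(u_history)
    found: list[PhaseSingularity] = []
    for k in range(phase.shape[0]):
        found.extend(detect_ps(phase[k], time=float(times[k])))
    return found


def plan_rotor(
    baseline: epsim.SimulationResult,
    disk: TissueDisk,
    lesion_radius: int = 3,
    mapping_window: float = 200.0,
) -> LesionMask:
    """Discs of ``lesion_radius`` at the clustered phase-singularity sites
    detected over the last ``mapping_window`` ms of the baseline run."""
    times = baseline.snapshot_times
    if len(times) < 2:
        raise ValueError("baseline run has no snapshots to map")
    t_hi = times[-1]
    sel = times >= t_hi - mapping_window
    if sel.sum() < 8:
        raise ValueError("baseline snapshots do not cover the mapping window")
    ps = track_ps(baseline.snapshots[sel], times[sel])
    H, W = disk.label_grid.shape
    if not ps:
        warnings.warn("no phase singularities found; empty ROTOR lesion set", stacklevel=2)
        return LesionMask.from_mask(np.zeros((H, W), bool), Strategy.ROTOR, disk)

    pts = np.array([[p.row, p.col] for p in ps])
    if len(pts) == 1:
        centroids = pts
    else:
        Z = linkage(pts, method="single")
        labels = fcluster(Z, t=float(lesion_radius), criterion="distance")
        centroids = np.array([pts[labels == k].mean(axis=0) for k in np.unique(labels)])

    rr, cc = np.mgrid[0:H, 0:W]
    mask = np.zeros((H, W), dtype=bool)
    for r0, c0 in centroids:
        mask |= (rr - r0) ** 2 + (cc - c0) ** 2 <= lesion_radius**2
    return LesionMask.from_mask(mask, Strategy.ROTOR, disk)


# ---------------------------------------------------------------------------
# outcome evaluation


@dataclass
class LabelConfig:
    """Study settings for labelling one disk.

    ``t_end`` is the episode limit the success rule is judged against
    (2000 ms in the full-scale protocol; scaled studies may shorten it) and
    ``lesion_time`` the moment the planned lesions are applied to the
    ongoing episode.
    """

    params: epsim.FKParams = field(default_factory=epsim.FKParams)
    protocol: epsim.StimulusProtocol = field(default_factory=epsim.StimulusProtocol)
    dt: float = 0.01
    t_end: float = 2000.0
    lesion_time: float = 500.0
    snapshot_stride: float = 2.0
    max_ablated_fraction: float = 0.40
    u_act: float = 0.1
    quiescence_window: float = 50.0
    pvi_ring_width: int = 2
    fibro_min_region_px: int = 9
    rotor_lesion_radius: int = 3
    rotor_mapping_window: float = 200.0


def success_rule(terminated: bool, termination_time: float | None,
                 ablated_fraction: float, t_end: float = 2000.0,
                 max_ablated_fraction: float = 0.40) -> bool:
    """Termination within the episode limit with less than 40% ablated."""
    return bool(
        terminated
        and termination_time is not None
        and termination_time <= t_end
        and ablated_fraction < max_ablated_fraction
    )


def evaluate_strategy(
    disk: TissueDisk,
    lesions: LesionMask,
    config: LabelConfig,
    baseline_state: epsim.FKState | None = None,
) -> StrategyOutcome:
    """Apply one lesion set to the fibrillation episode and judge success.

    With ``baseline_state`` (the saved state at ``lesion_time`` of a
    baseline run) the pre-ablation portion is not re-simulated; the result
    is identical because lesions only act from ``lesion_time`` on.
    """
    if lesions.mask.shape != disk.label_grid.shape:
        raise ValueError("lesion mask grid does not match the disk")
    if baseline_state is not None:
        res = epsim.run_crossfield(
            disk, lesions=lesions, lesion_time=config.lesion_time,
            params=config.params, t_end=config.t_end, dt=config.dt,
            protocol=config.protocol, snapshot_stride=config.snapshot_stride,
            record_snapshots=False, u_act=config.u_act,
            quiescence_window=config.quiescence_window,
            initial_state=baseline_state, apply_stimuli=False,
        )
    else:
        res = epsim.run_crossfield(
            disk, lesions=lesions, lesion_time=config.lesion_time,
            params=config.params, t_end=config.t_end, dt=config.dt,
            protocol=config.protocol, snapshot_stride=config.snapshot_stride,
            record_snapshots=False, u_act=config.u_act,
            quiescence_window=config.quiescence_window,
        )
    ok = success_rule(res.terminated, res.termination_time,
                      lesions.ablated_fraction, config.t_end,
                      config.max_ablated_fraction)
    return StrategyOutcome(
        strategy=lesions.strategy, lesions=lesions,
        terminated=res.terminated, termination_time=res.termination_time,
        success=ok,
    )


def label_disk(
    disk: TissueDisk, config: LabelConfig | None = None
) -> tuple[StrategyLabels, dict[Strategy, StrategyOutcome]]:
    """Baseline episode plus the three strategy evaluations for one disk.

    Runs the cross-field induction once up to ``lesion_time`` (recording
    the rotor-mapping snapshots), verifies fibrillation is still ongoing,
    then continues the episode three times from the saved state under each
    strategy's lesions.  Raises :class:`NonInducibleError` when the baseline
    is quiescent at ``lesion_time`` - such disks are excluded from cohorts.
    """
    cfg = config or LabelConfig()
    base = epsim.run_crossfield(
        disk, lesions=None, params=cfg.params, t_end=cfg.lesion_time,
        dt=cfg.dt, protocol=cfg.protocol, snapshot_stride=cfg.snapshot_stride,
        record_snapshots=True, u_act=cfg.u_act,
        quiescence_window=cfg.quiescence_window, stop_on_termination=False,
    )
    recent = base.trace_times >= cfg.lesion_time - cfg.quiescence_window
    if not (base.max_u_trace[recent] >= cfg.u_act).any():
        raise NonInducibleError("no sustained fibrillation at lesion time")

    plans = {
        Strategy.PVI: plan_pvi(disk, cfg.pvi_ring_width),
        Strategy.FIBRO: plan_fibro(disk, cfg.fibro_min_region_px),
        Strategy.ROTOR: plan_rotor(
            baseline=base, disk=disk,
            lesion_radius=cfg.rotor_lesion_radius,
            mapping_window=cfg.rotor_mapping_window,
        ),
    }
    outcomes = {
        s: evaluate_strategy(disk, lm, cfg, baseline_state=base.final_state)
        for s, lm in plans.items()
    }
    labels = StrategyLabels(
        pvi=outcomes[Strategy.PVI].success,
        fibro=outcomes[Strategy.FIBRO].success,
        rotor=outcomes[Strategy.ROTOR].success,
    )
    return labels, outcomes
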