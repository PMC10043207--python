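"""Fenton-Karma monodomain solver on 2D tissue disks.

Three-variable phenomenological atrial action-potential model (membrane
variable u plus gates v, w; fast-inward, slow-outward and slow-inward
currents) coupled to tissue-level diffusion:

    du/dt = div(D grad u) - (Ifi + Iso + Isi)

with membrane capacitance normalised to 1 so u is dimensionless.  The PDE is
integrated with forward Euler and a 5-point finite-difference Laplacian with
face-averaged (harmonic-mean) conductances, which makes zero-flux boundaries
at non-conducting pixels (outside the disk, PV openings, ablated lesions)
automatic.  Fibrillation-like re-entry is induced with the standard
cross-field S1-S2 protocol; ablation lesions can be applied mid-run by
zeroing the diffusivity of lesion pixels.

Diffusivities follow the convention D_healthy = 0.1 mm^2/ms and
D_fibrotic = 0.015 mm^2/ms (ratio 0.15), which puts the planar conduction
velocity in the physiological range for atrial myocardium.  Values quoted
in mm^2/s can be converted with :func:`diffusivity_to_mm2_per_ms`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit
from scipy.optimize import brentq

from .tissue import Label, TissueDisk


class ConfigurationError(ValueError):
    """Raised before a run when numerical settings are unstable or invalid."""


class NoPropagationError(RuntimeError):
    """Raised when a calibration wave fails to reach its sensing points."""


@dataclass(frozen=True)
class FKParams:
    """Fenton-Karma model constants plus tissue diffusivities.

    The defaults are an aggressively remodelled variant of parameter set 4
    of the three-variable model catalogue (Fenton, Cherry, Hastings &
    Evans, Chaos 2002), calibrated for desk-scale atrial-fibrillation
    studies on ~40 mm tissue disks at 0.3 mm resolution: the action
    potential is compressed (fast v-gate collapse, weak plateau current) so
    that the re-entry wavelength fits the disk, the S1-S2 cross-field
    protocol at 28 ms induces re-entry, and slow conduction survives in
    fibrotic tissue at the reduced diffusivity.  Planar conduction velocity
    in healthy tissue is ~0.39 m/s.  Time constants in ms, diffusivities in
    mm^2/ms.  :data:`FK_SET_4` and :data:`FK_SET_8` carry the unmodified
    published sets.
    """

    tau_d: float = 0.2
    tau_o: float = 5.0
    tau_r: float = 20.0
    tau_si: float = 200.0
    tau_v_plus: float = 2.4
    tau_v1_minus: float = 4.0
    tau_v2_minus: float = 2.0
    tau_w_plus: float = 350.0
    tau_w_minus: float = 80.0
    u_c: float = 0.15
    u_v: float = 0.10
    u_c_si: float = 0.45
    k_si: float = 15.0
    D_healthy: float = 0.1
    D_fibrotic: float = 0.015
    D_ablated: float = 0.0

    def __post_init__(self):
        taus = (
            self.tau_d, self.tau_o, self.tau_r, self.tau_si, self.tau_v_plus,
            self.tau_v1_minus, self.tau_v2_minus, self.tau_w_plus, self.tau_w_minus,
        )
        if any(t <= 0 for t in taus):
            raise ConfigurationError("all time constants must be positive")
        if not 0.0 < self.u_c < 1.0:
            raise ConfigurationError("u_c must lie in (0, 1)")
        if self.D_ablated != 0.0:
            raise ConfigurationError("ablated tissue must be non-conducting")
        if self.D_fibrotic >= self.D_healthy:
            raise ConfigurationError("fibrotic diffusivity must be below healthy")

    def min_tau(self) -> float:
        return min(
            self.tau_d, self.tau_o, self.tau_r, self.tau_si, self.tau_v_plus,
            self.tau_v1_minus, self.tau_v2_minus, self.tau_w_plus, self.tau_w_minus,
        )

    def rest_u(self) -> float:
        """Quiescent equilibrium of u (slightly above 0: the residual
        slow-inward current at u=0 is balanced by the outward current)."""

        def f(u):
            iso = u / self.tau_o
            isi = -(1.0 / (2 * self.tau_si)) * (1 + math.tanh(self.k_si * (u - self.u_c_si)))
            return iso + isi

        return brentq(f, 0.0, self.u_c * 0.99, xtol=1e-16)


#: Published set 4 of the three-variable catalogue (spiral breakup regime;
#: action potential far too long for desk-scale disks, kept for reference).
FK_SET_4 = FKParams(
    tau_d=0.407, tau_o=9.0, tau_r=34.0, tau_si=26.5,
    tau_v_plus=3.33, tau_v1_minus=15.6, tau_v2_minus=5.0,
    tau_w_plus=350.0, tau_w_minus=80.0,
    u_c=0.15, u_v=0.04, u_c_si=0.45, k_si=15.0,
)

#: Published set 8 of the same catalogue (stable spiral, long action
#: potential).
FK_SET_8 = FKParams(
    tau_d=0.45, tau_o=12.5, tau_r=33.33, tau_si=29.0,
    tau_v_plus=13.03, tau_v1_minus=19.6, tau_v2_minus=1250.0,
    tau_w_plus=800.0, tau_w_minus=40.0,
    u_c=0.13, u_v=0.04, u_c_si=0.85, k_si=10.0,
)

PARAMETER_SETS = {"default": FKParams(), "set4": FK_SET_4, "set8": FK_SET_8}


def diffusivity_to_mm2_per_ms(value: float, units: str = "mm2/ms") -> float:
    """Convert a diffusivity to the solver's mm^2/ms convention."""
    if units == "mm2/ms":
        return value
    if units == "mm2/s":
        return value / 1000.0
    raise ValueError(f"unknown diffusivity units {units!r}")


@dataclass
class FKState:
    """Membrane variable and gates on the grid at simulation time t (ms)."""

    u: np.ndarray
    v: np.ndarray
    w: np.ndarray
    t: float = 0.0

    def copy(self) -> "FKState":
        return FKState(self.u.copy(), self.v.copy(), self.w.copy(), self.t)


def resting_state(shape: tuple[int, int], params: FKParams) -> FKState:
    u = np.full(shape, params.rest_u())
    v = np.ones(shape)
    w = np.ones(shape)
    return FKState(u, v, w, 0.0)


# ---------------------------------------------------------------------------
# currents and stepping


def fk_currents(state: FKState, params: FKParams):
    """Vectorised three-variable currents (Ifi, Iso, Isi) per pixel."""
    u, v, w = state.u, state.v, state.w
    p = (u >= params.u_c).astype(float)  # Heaviside H(u - u_c)
    ifi = -(v / params.tau_d) * p * (1.0 - u) * (u - params.u_c)
    iso = (u / params.tau_o) * (1.0 - p) + p / params.tau_r
    isi = -(w / (2.0 * params.tau_si)) * (1.0 + np.tanh(params.k_si * (u - params.u_c_si)))
    return ifi, iso, isi


def diffusion_map(disk: TissueDisk, params: FKParams, lesions=None) -> np.ndarray:
    """Per-pixel diffusivity: healthy / fibrotic values, zero elsewhere."""
    D = np.zeros(disk.label_grid.shape)
    D[disk.label_grid == Label.HEALTHY] = params.D_healthy
    D[disk.label_grid == Label.FIBROTIC] = params.D_fibrotic
    if lesions is not None:
        mask = lesions.mask if hasattr(lesions, "mask") else lesions
        D[mask] = params.D_ablated
    return D


def face_conductances(D: np.ndarray, dx: float):
    """Harmonic-mean conductances on the four faces of each pixel, per dx^2.

    A zero diffusivity on either side closes the face, which implements
    zero-flux boundaries into outside/PV/ablated pixels.
    """
    H, W = D.shape

    def harm(a, b):
        s = a + b
        out = np.zeros_like(a)
        nz = s > 0
        out[nz] = 2.0 * a[nz] * b[nz] / s[nz]
        return out

    Ge = np.zeros((H, W)); Gw = np.zeros((H, W))
    Gs = np.zeros((H, W)); Gn = np.zeros((H, W))
    Ge[:, :-1] = harm(D[:, :-1], D[:, 1:])
    Gw[:, 1:] = Ge[:, :-1]
    Gs[:-1, :] = harm(D[:-1, :], D[1:, :])
    Gn[1:, :] = Gs[:-1, :]
    return Ge / dx**2, Gw / dx**2, Gs / dx**2, Gn / dx**2


def check_stability(params: FKParams, dt: float, dx: float) -> None:
    """Explicit-Euler stability bounds, enforced before any run."""
    d_max = max(params.D_healthy, params.D_fibrotic)
    if dt > dx**2 / (4.0 * d_max):
        raise ConfigurationError(
            f"dt={dt} violates the diffusion bound dx^2/(4 D) = {dx**2 / (4 * d_max):.4g}"
        )
    if dt > params.min_tau() / 2.0:
        raise ConfigurationError(
            f"dt={dt} exceeds half the fastest time constant {params.min_tau():.4g}"
        )


def step(state: FKState, D: np.ndarray, params: FKParams, dt: float, dx: float = 0.3,
         tissue: np.ndarray | None = None) -> FKState:
    """One forward-Euler step of the monodomain system (vectorised numpy).

    Reference path used by tests and single-step analyses; production runs
    use the compiled kernel in :func:`run_crossfield`, which performs the
    identical arithmetic.
    """
    if tissue is None:
        tissue = D > 0
    u, v, w = state.u, state.v, state.w
    Ge, Gw, Gs, Gn = face_conductances(D, dx)
    lap = np.zeros_like(u)
    lap[:, :-1] += Ge[:, :-1] * (u[:, 1:] - u[:, :-1])
    lap[:, 1:] += Gw[:, 1:] * (u[:, :-1] - u[:, 1:])
    lap[:-1, :] += Gs[:-1, :] * (u[1:, :] - u[:-1, :])
    lap[1:, :] += Gn[1:, :] * (u[:-1, :] - u[1:, :])

    ifi, iso, isi = fk_currents(state, params)
    p = (u >= params.u_c)
    q = (u >= params.u_v)
    tau_vm = np.where(q, params.tau_v1_minus, params.tau_v2_minus)

    du = lap - (ifi + iso + isi)
    dv = np.where(p, -v / params.tau_v_plus, (1.0 - v) / tau_vm)
    dw = np.where(p, -w / params.tau_w_plus, (1.0 - w) / params.tau_w_minus)

    u2 = np.where(tissue, u + dt * du, u)
    v2 = np.where(tissue, np.clip(v + dt * dv, 0.0, 1.0), v)
    w2 = np.where(tissue, np.clip(w + dt * dw, 0.0, 1.0), w)
    return FKState(u2, v2, w2, state.t + dt)


@njit(cache=False, fastmath=True)
def _advance(u, v, w, unew, Ge, Gw, Gs, Gn, tissue,
             tau_d, tau_o, tau_r, tau_si, tau_vp, tau_v1m, tau_v2m,
             tau_wp, tau_wm, u_c, u_v_thr, u_c_si, k_si, dt, n_steps):
    """Advance n_steps in place; arithmetic identical to :func:`step`."""
    H, W = u.shape
    for _ in range(n_steps):
        for i in range(1, H - 1):
            for j in range(1, W - 1):
                if not tissue[i, j]:
                    continue
                uu = u[i, j]
                lap = (Ge[i, j] * (u[i, j + 1] - uu)
                       + Gw[i, j] * (u[i, j - 1] - uu)
                       + Gs[i, j] * (u[i + 1, j] - uu)
                       + Gn[i, j] * (u[i - 1, j] - uu))
                p = 1.0 if uu >= u_c else 0.0
                ifi = -(v[i, j] / tau_d) * p * (1.0 - uu) * (uu - u_c)
                iso = (uu / tau_o) * (1.0 - p) + p / tau_r
                isi = -(w[i, j] / (2.0 * tau_si)) * (1.0 + math.tanh(k_si * (uu - u_c_si)))
                unew[i, j] = uu + dt * (lap - (ifi + iso + isi))
                if p == 1.0:
                    dv = -v[i, j] / tau_vp
                    dw = -w[i, j] / tau_wp
                else:
                    tau_vm = tau_v1m if uu >= u_v_thr else tau_v2m
                    dv = (1.0 - v[i, j]) / tau_vm
                    dw = (1.0 - w[i, j]) / tau_wm
                vv = v[i, j] + dt * dv
                ww = w[i, j] + dt * dw
                v[i, j] = 0.0 if vv < 0.0 else (1.0 if vv > 1.0 else vv)
                w[i, j] = 0.0 if ww < 0.0 else (1.0 if ww > 1.0 else ww)
        for i in range(1, H - 1):
            for j in range(1, W - 1):
                if tissue[i, j]:
                    u[i, j] = unew[i, j]


def _params_tuple(p: FKParams):
    return (p.tau_d, p.tau_o, p.tau_r, p.tau_si, p.tau_v_plus, p.tau_v1_minus,
            p.tau_v2_minus, p.tau_w_plus, p.tau_w_minus, p.u_c, p.u_v, p.u_c_si, p.k_si)


# ---------------------------------------------------------------------------
# protocols and runs


@dataclass
class StimulusProtocol:
    """Cross-field S1-S2 protocol: S1 plane wave from the left edge at t=0,
    S2 half-plane stimulus at ``s2_time`` (ms) covering the bottom half."""

    s1_width: int = 24
    s2_time: float = 28.0
    amplitude: float = 1.0

    def __post_init__(self):
        if self.s2_time <= 0:
            raise ConfigurationError("s2_time must be positive")


@dataclass
class SimulationResult:
    """Recorded output of one monodomain run."""

    snapshots: np.ndarray          # (T, H, W) float32 u-fields
    snapshot_times: np.ndarray     # ms
    max_u_trace: np.ndarray        # max over tissue pixels, one entry per sample
    trace_times: np.ndarray        # ms
    terminated: bool
    termination_time: float | None
    t_end: float
    final_state: FKState | None = None

    @property
    def activation_trace(self) -> np.ndarray:
        return self.max_u_trace >= 0.1


def is_af_terminated(max_u_trace: np.ndarray, sample_dt: float,
                     u_act: float = 0.1, quiescence_window: float = 50.0):
    """First time after which activity stays below ``u_act`` for a full
    quiescence window.  Returns (terminated, termination_time)."""
    if not 0.0 < u_act < 1.0:
        raise ValueError("u_act must lie in (0, 1)")
    quiet = max_u_trace < u_act
    need = max(1, int(round(quiescence_window / sample_dt)))
    n = len(quiet)
    # find first index t* with quiet[t*:] all True and at least `need` samples
    run = 0
    first_quiet = None
    for i in range(n):
        if quiet[i]:
            if run == 0:
                first_quiet = i
            run += 1
        else:
            run = 0
            first_quiet = None
    if first_quiet is not None and run >= need:
        return True, first_quiet * sample_dt
    return False, None


def run_crossfield(
    disk: TissueDisk,
    lesions=None,
    lesion_time: float = 500.0,
    params: FKParams | None = None,
    t_end: float = 2000.0,
    dt: float = 0.01,
    protocol: StimulusProtocol | None = None,
    snapshot_stride: float = 1.0,
    record_snapshots: bool = True,
    u_act: float = 0.1,
    quiescence_window: float = 50.0,
    stop_on_termination: bool = True,
    initial_state: FKState | None = None,
    apply_stimuli: bool = True,
) -> SimulationResult:
    """Cross-field AF induction with optional mid-run lesion application.

    S1 excites a band at the left edge at t=0 and S2 the bottom half-plane
    at ``protocol.s2_time``; if ``lesions`` is given, those pixels become
    non-conducting at ``lesion_time``.  The run may be warm-started from
    ``initial_state`` (with ``apply_stimuli=False``) to continue a baseline
    episode under different lesion sets.
    """
    params = params or FKParams()
    protocol = protocol or StimulusProtocol()
    dx = disk.geometry.pixel_spacing
    check_stability(params, dt, dx)
    if lesions is not None and lesion_time >= t_end:
        raise ConfigurationError("lesion_time must precede t_end")

    tissue = disk.tissue_mask
    state = (initial_state.copy() if initial_state is not None
             else resting_state(disk.label_grid.shape, params))
    u, v, w = state.u, state.v, state.w
    unew = u.copy()
    t0 = state.t

    D0 = diffusion_map(disk, params)
    G0 = face_conductances(D0, dx)
    if lesions is not None:
        D1 = diffusion_map(disk, params, lesions)
        G1 = face_conductances(D1, dx)
        lesion_mask = lesions.mask if hasattr(lesions, "mask") else lesions
    else:
        G1 = G0
        lesion_mask = None

    pt = _params_tuple(params)
    steps_per_sample = max(1, int(round(snapshot_stride / dt)))
    n_samples = int(round((t_end - t0) / (steps_per_sample * dt)))

    s1 = np.zeros_like(tissue)
    s1[:, : protocol.s1_width] = True
    s2 = np.zeros_like(tissue)
    s2[u.shape[0] // 2:, :] = True

    # stimuli depolarise only excitable (sub-threshold) tissue; forcing u on
    # refractory pixels would artificially extend their refractoriness
    if apply_stimuli:
        u[s1 & tissue & (u < params.u_c)] = protocol.amplitude
    s2_done = not apply_stimuli
    lesioned = lesions is None
    if not lesioned and t0 >= lesion_time - dt / 2:
        # warm start at/after the ablation moment: apply lesions up front
        lesioned = True
        u[lesion_mask] = 0.0

    snaps, snap_times, trace, trace_times = [], [], [], []
    terminated = False
    termination_time = None
    quiet_run = 0
    need_quiet = max(1, int(round(quiescence_window / snapshot_stride)))
    quiet_start = None

    t = t0
    for _ in range(n_samples):
        # event boundaries inside this sample block
        block_end = t + steps_per_sample * dt
        while t < block_end - dt / 2:
            next_event = block_end
            if not s2_done and t < protocol.s2_time <= block_end:
                next_event = min(next_event, protocol.s2_time)
            if not lesioned and t < lesion_time <= block_end:
                next_event = min(next_event, lesion_time)
            n_sub = max(1, int(round((next_event - t) / dt)))
            G = G1 if lesioned else G0
            _advance(u, v, w, unew, *G, tissue, *pt, dt, n_sub)
            t += n_sub * dt
            if not s2_done and t >= protocol.s2_time - dt / 2:
                u[s2 & tissue & (u < params.u_c)] = protocol.amplitude
                s2_done = True
            if not lesioned and t >= lesion_time - dt / 2:
                lesioned = True
                if lesion_mask is not None:
                    u[lesion_mask] = 0.0

        m = float(u[tissue].max()) if tissue.any() else 0.0
        trace.append(m)
        trace_times.append(t)
        if record_snapshots:
            snaps.append(u.astype(np.float32).copy())
            snap_times.append(t)

        if m < u_act:
            if quiet_run == 0:
                quiet_start = t - steps_per_sample * dt
            quiet_run += 1
        else:
            quiet_run = 0
            quiet_start = None
        if lesioned and quiet_run >= need_quiet:
            terminated = True
            termination_time = max(t0, quiet_start)
            if stop_on_termination:
                break

    state = FKState(u, v, w, t)
    return SimulationResult(
        snapshots=np.array(snaps) if snaps else np.zeros((0, *u.shape), np.float32),
        snapshot_times=np.array(snap_times),
        max_u_trace=np.array(trace),
        trace_times=np.array(trace_times),
        terminated=terminated,
        termination_time=termination_time,
        t_end=t_end,
        final_state=state,
    )


def save_result(result: SimulationResult, path) -> None:
    """Persist a run as a compressed archive plus a JSON summary."""
    import json
    from pathlib import Path

    path = Path(path)
    np.savez_compressed(
        path.with_suffix(".npz"),
        snapshots=result.snapshots, snapshot_times=result.snapshot_times,
        max_u_trace=result.max_u_trace, trace_times=result.trace_times,
    )
    summary = {
        "terminated": result.terminated,
        "termination_time": result.termination_time,
        "t_end": result.t_end,
        "n_snapshots": int(len(result.snapshot_times)),
    }
    path.with_suffix(".json").write_text(json.dumps(summary, indent=1))


def load_result(path) -> SimulationResult:
    import json
    from pathlib import Path

    path = Path(path)
    arrays = np.load(path.with_suffix(".npz"))
    meta = json.loads(path.with_suffix(".json").read_text())
    return SimulationResult(
        snapshots=arrays["snapshots"], snapshot_times=arrays["snapshot_times"],
        max_u_trace=arrays["max_u_trace"], trace_times=arrays["trace_times"],
        terminated=meta["terminated"], termination_time=meta["termination_time"],
        t_end=meta["t_end"],
    )


# ---------------------------------------------------------------------------
# conduction-velocity calibration


def measure_cv(params: FKParams | None = None, D: float | None = None,
               strip_length: float = 40.0, dx: float = 0.3, dt: float = 0.05,
               u_thr: float = 0.5, t_max: float = 400.0) -> float:
    """Planar conduction velocity (m/s) on a thin strip.

    A plane wave is launched from one end of a 1D-like strip and timed
    between two distal sensing points; CV = distance / transit time.
    mm/ms equals m/s numerically.
    """
    params = params or FKParams()
    if D is None:
        D = params.D_healthy
    n_cols = int(round(strip_length / dx))
    if n_cols * dx < 20.0:
        raise ValueError("strip must allow >= 20 mm of planar propagation")
    H, W = 5, n_cols + 2
    Dmap = np.zeros((H, W))
    Dmap[1:-1, 1:-1] = D
    tissue = Dmap > 0
    # reuse the stepping kernel directly on the strip
    p_loc = replace(params, D_healthy=max(D, params.D_healthy))
    check_stability(p_loc, dt, dx)
    G = face_conductances(Dmap, dx)
    rest = params.rest_u()
    u = np.full((H, W), rest); u[~tissue] = 0.0
    v = np.ones((H, W)); w = np.ones((H, W))
    unew = u.copy()
    u[:, :4][tissue[:, :4]] = 1.0

    c1, c2 = int(0.35 * n_cols), int(0.85 * n_cols)
    row = H // 2
    t1 = t2 = None
    pt = _params_tuple(params)
    t = 0.0
    while t < t_max:
        _advance(u, v, w, unew, *G, tissue, *pt, dt, 10)
        t += 10 * dt
        if t1 is None and u[row, c1] >= u_thr:
            t1 = t
        if t2 is None and u[row, c2] >= u_thr:
            t2 = t
        if t2 is not None:
            break
    if t1 is None or t2 is None:
        raise NoPropagationError("wavefront did not reach both sensing points")
    return (c2 - c1) * dx / (t2 - t1)
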