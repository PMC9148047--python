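"""Transient heat conduction on the axisymmetric grid.

Solves rho*cp dT/dt = div(k grad T) + P_loss with the temperature pinned to
the ambient value on the outer domain boundary (Dirichlet) and an initial
state equal to ambient everywhere.  The spatial operator is a conservative
finite-volume discretization in cylindrical (r, z) with harmonic-mean face
conductivities; time stepping is implicit Euler (unconditionally stable), so
the default 1 s step is a cost/accuracy choice, not a stability limit.

The thin brass walls are excluded from the thermal problem: by default they
behave as thermally transparent sheets (conduction passes through them with
the surrounding dielectric's properties).  The EM loss field enters linearly,
rescaled so that its volume integral equals the effectively supplied power of
each schedule segment.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu, spsolve

from .em import LossField
from .geometry import MaterialMap

__all__ = [
    "PowerSchedule",
    "Controller",
    "ThermalSeries",
    "ThermalModel",
    "scale_loss",
    "run_transient",
    "run_controlled",
    "cooling_phase",
    "maintenance_schedule",
]


@dataclass(frozen=True)
class PowerSchedule:
    """Piecewise-constant effective power vs time.

    ``segments`` is a list of ``(start_s, end_s, power_W)``; times outside all
    segments mean zero power.
    """

    segments: tuple[tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        prev_end = -np.inf
        for start, end, power in self.segments:
            if end <= start:
                raise ValueError(f"segment ({start}, {end}) has no duration")
            if start < prev_end - 1e-9:
                raise ValueError("schedule segments overlap or are unordered")
            if power < 0:
                raise ValueError("power must be non-negative")
            prev_end = end

    @classmethod
    def constant(cls, power: float, duration: float, start: float = 0.0) -> "PowerSchedule":
        return cls(((start, start + duration, power),))

    def power_at(self, t: float) -> float:
        for start, end, power in self.segments:
            if start <= t < end:
                return power
        return 0.0

    @property
    def end_time(self) -> float:
        return max(end for _, end, _ in self.segments) if self.segments else 0.0


def maintenance_schedule(
    duration: float,
    preheat_power: float = 18.0,
    preheat_time: float = 120.0,
    hold_power: float = 3.2,
) -> PowerSchedule:
    """Scripted target-maintenance waveform: a high-power preheat burst
    followed by a low held power for the rest of ``duration``."""
    return PowerSchedule(
        (
            (0.0, preheat_time, preheat_power),
            (preheat_time, duration, hold_power),
        )
    )


@dataclass(frozen=True)
class Controller:
    """Proportional-integral feedback on one probe-point temperature.

    Output power is ``kp * e + (kp / ti) * integral(e)`` clipped to
    ``power_bounds``, with conditional integration as anti-windup.  Gains were
    chosen to reproduce the characteristic maintenance waveform: the clipped
    high-power burst at switch-on followed by a ~3 W hold.
    """

    target_C: float = 43.0
    probe_r_cm: float = 0.0
    probe_z_cm: float = 0.0
    kp: float = 5.0            # W per degree C
    ti: float = 60.0           # integral time, s
    power_bounds: tuple[float, float] = (0.0, 20.0)
    overshoot_limit_C: float = 3.0

    def __post_init__(self) -> None:
        lo, hi = self.power_bounds
        if not (np.isfinite(lo) and np.isfinite(hi) and 0 <= lo < hi):
            raise ValueError("power bounds must be finite with 0 <= lo < hi")


@dataclass
class ThermalSeries:
    """Time-stamped temperature fields, probe traces and the power trace."""

    times: np.ndarray                  # snapshot times, s
    fields: np.ndarray                 # (n_snap, Nr, Nz) degrees C
    probe_times: np.ndarray            # s (one per step)
    probe_traces: dict[int, np.ndarray]
    probe_points: dict[int, tuple[float, float]]  # id -> (r_cm, z_cm)
    power_times: np.ndarray
    power_trace: np.ndarray            # W
    t_ext: float
    map: MaterialMap = field(repr=False)
    loss: LossField | None = field(repr=False, default=None)
    dt: float = 1.0
    t_power_off: float | None = None
    controller_flagged: bool = False

    def temperature_at(self, t: float) -> np.ndarray:
        """Field at time ``t`` (linear interpolation between snapshots)."""
        times = self.times
        if t <= times[0]:
            return self.fields[0]
        if t >= times[-1]:
            return self.fields[-1]
        j = int(np.searchsorted(times, t))
        w = (t - times[j - 1]) / (times[j] - times[j - 1])
        return (1 - w) * self.fields[j - 1] + w * self.fields[j]

    @property
    def final_field(self) -> np.ndarray:
        return self.fields[-1]


class ThermalModel:
    """Finite-volume conduction operator with Dirichlet outer boundary.

    Assembled once per (map, ambient, metal handling); the implicit-Euler
    factorization is cached per time step so repeated transients on the same
    geometry reuse it.
    """

    def __init__(
        self,
        mmap: MaterialMap,
        t_ext: float = 21.5,
        metal_mode: str = "transparent",
    ):
        self.map = mmap
        self.t_ext = float(t_ext)
        nr, nz = mmap.shape
        self.shape = (nr, nz)
        n = nr * nz

        mat = mmap.thermal_material(metal_mode)
        k = mmap.materials.property_vector("k")[mat]
        rho = mmap.materials.property_vector("rho")[mat]
        cp = mmap.materials.property_vector("cp")[mat]
        vol = mmap.cell_volumes
        self.heat_capacity = (rho * cp * vol).ravel()  # J/K per cell

        dr, dz = mmap.dr, mmap.dz
        r_edges = mmap.r_edges
        ring = np.pi * (r_edges[1:] ** 2 - r_edges[:-1] ** 2)

        idx = np.arange(n).reshape(nr, nz)
        rows, cols, vals = [], [], []
        diag = np.zeros(n)

        def add_face(ia, ib, g):
            rows.append(ia); cols.append(ib); vals.append(-g)
            rows.append(ib); cols.append(ia); vals.append(-g)
            np.add.at(diag, ia, g)
            np.add.at(diag, ib, g)

        # radial faces
        area_r = 2 * np.pi * r_edges[1:-1, None] * dz[None, :]
        g_r = area_r / (dr[:-1, None] / (2 * k[:-1, :]) + dr[1:, None] / (2 * k[1:, :]))
        add_face(idx[:-1, :].ravel(), idx[1:, :].ravel(), g_r.ravel())
        # axial faces
        area_z = ring[:, None] * np.ones((1, nz - 1))
        g_z = area_z / (dz[:-1] / (2 * k[:, :-1]) + dz[1:] / (2 * k[:, 1:]))
        add_face(idx[:, :-1].ravel(), idx[:, 1:].ravel(), g_z.ravel())

        # Dirichlet boundary: half-cell conductances to the ambient ghost
        self.boundary_g = np.zeros(n)
        g_out = (2 * np.pi * r_edges[-1] * dz) / (dr[-1] / (2 * k[-1, :]))
        np.add.at(diag, idx[-1, :], g_out)
        np.add.at(self.boundary_g, idx[-1, :], g_out)
        for j_bound, dz_b in ((0, dz[0]), (nz - 1, dz[-1])):
            g_b = ring / (dz_b / (2 * k[:, j_bound]))
            np.add.at(diag, idx[:, j_bound], g_b)
            np.add.at(self.boundary_g, idx[:, j_bound], g_b)

        rows.append(np.arange(n)); cols.append(np.arange(n)); vals.append(diag)
        self.K = sp.csc_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n, n),
        )
        self.b_dirichlet = self.boundary_g * self.t_ext
        self._factors: dict[float, object] = {}

    def factor(self, dt: float):
        lu = self._factors.get(dt)
        if lu is None:
            A = sp.diags(self.heat_capacity / dt) + self.K
            lu = splu(A.tocsc())
            self._factors[dt] = lu
        return lu

    def step(self, T_flat: np.ndarray, q_flat: np.ndarray, dt: float) -> np.ndarray:
        lu = self.factor(dt)
        rhs = self.heat_capacity / dt * T_flat + q_flat + self.b_dirichlet
        return lu.solve(rhs)

    def steady_state(self, q_flat: np.ndarray) -> np.ndarray:
        """Temperature field solving K T = q + boundary (the t -> inf limit)."""
        return spsolve(self.K, q_flat + self.b_dirichlet).reshape(self.shape)

    def boundary_flux(self, T_flat: np.ndarray) -> float:
        """Heat flow out through the Dirichlet boundary, W."""
        return float(np.dot(self.boundary_g, T_flat - self.t_ext))

    def probe_weights(self, r_cm: float, z_cm: float) -> tuple[np.ndarray, np.ndarray]:
        """Flat indices and bilinear weights for sampling at one point."""
        rc, zc = self.map.r_centers, self.map.z_centers
        r, z = r_cm * 1e-2, z_cm * 1e-2
        i = int(np.clip(np.searchsorted(rc, r) - 1, 0, len(rc) - 2))
        j = int(np.clip(np.searchsorted(zc, z) - 1, 0, len(zc) - 2))
        fr = np.clip((r - rc[i]) / (rc[i + 1] - rc[i]), 0.0, 1.0)
        fz = np.clip((z - zc[j]) / (zc[j + 1] - zc[j]), 0.0, 1.0)
        nz = self.shape[1]
        flat = np.array([i * nz + j, i * nz + j + 1, (i + 1) * nz + j, (i + 1) * nz + j + 1])
        w = np.array([(1 - fr) * (1 - fz), (1 - fr) * fz, fr * (1 - fz), fr * fz])
        return flat, w


def scale_loss(loss: LossField, effective_power: float) -> LossField:
    """Rescale the loss field so the total absorbed power is ``effective_power``."""
    if effective_power < 0:
        raise ValueError("effective power must be non-negative")
    if loss.total_absorbed <= 0:
        raise ValueError("cannot rescale a zero loss field")
    return loss.scaled(effective_power / loss.total_absorbed)


def _integrate(
    model: ThermalModel,
    q_unit: np.ndarray,
    power_of_t,
    T0: np.ndarray,
    t0: float,
    duration: float,
    dt: float,
    snapshot_every: float,
    probe_points: dict[int, tuple[float, float]] | None,
    controller: Controller | None = None,
):
    """Shared implicit-Euler loop; ``power_of_t`` maps time to watts, or the
    controller closes the loop on its probe point."""
    n_steps = int(round(duration / dt))
    probe_points = probe_points or {}
    weights = {pid: model.probe_weights(r, z) for pid, (r, z) in probe_points.items()}
    traces = {pid: np.empty(n_steps) for pid in probe_points}
    powers = np.empty(n_steps)
    ptimes = np.empty(n_steps)

    snaps = [T0.reshape(model.shape).copy()]
    snap_times = [t0]
    T = T0.ravel().copy()

    ctrl_flat = ctrl_w = None
    integral = 0.0
    flagged = False
    if controller is not None:
        ctrl_flat, ctrl_w = model.probe_weights(controller.probe_r_cm, controller.probe_z_cm)

    next_snap = t0 + snapshot_every
    for n in range(n_steps):
        t_mid = t0 + (n + 0.5) * dt
        if controller is not None:
            t_probe = float(np.dot(T[ctrl_flat], ctrl_w))
            err = controller.target_C - t_probe
            lo, hi = controller.power_bounds
            p_unclipped = controller.kp * (err + integral / controller.ti)
            power = float(np.clip(p_unclipped, lo, hi))
            if lo < p_unclipped < hi:
                integral += err * dt   # conditional integration anti-windup
            if t_probe > controller.target_C + controller.overshoot_limit_C:
                flagged = True
        else:
            power = float(power_of_t(t_mid))
        T = model.step(T, power * q_unit, dt)
        if not np.all(np.isfinite(T)):
            raise FloatingPointError(
                f"thermal solver produced non-finite temperatures at t={t0 + (n + 1) * dt:.1f} s"
            )
        t_now = t0 + (n + 1) * dt
        ptimes[n] = t_now
        powers[n] = power
        for pid, (flat, w) in weights.items():
            traces[pid][n] = float(np.dot(T[flat], w))
        if t_now >= next_snap - 1e-9 or n == n_steps - 1:
            snaps.append(T.reshape(model.shape).copy())
            snap_times.append(t_now)
            next_snap += snapshot_every

    return np.array(snap_times), np.array(snaps), ptimes, traces, powers, flagged


def _q_unit(model: ThermalModel, loss: LossField | None) -> np.ndarray:
    """Per-cell heat (W) for 1 W of total absorbed power."""
    if loss is None:
        return np.zeros(model.shape[0] * model.shape[1])
    q = (loss.p_loss * loss.map.cell_volumes).ravel()
    total = q.sum()
    if total <= 0:
        raise ValueError("loss field deposits no power")
    return q / total


def run_transient(
    mmap: MaterialMap,
    loss: LossField | None,
    schedule: PowerSchedule,
    t_ext: float = 21.5,
    dt: float = 1.0,
    duration: float | None = None,
    snapshot_every: float = 10.0,
    probe_points: dict[int, tuple[float, float]] | None = None,
    model: ThermalModel | None = None,
    metal_mode: str = "transparent",
) -> ThermalSeries:
    """Integrate a heating/cooling transient under a power schedule.

    ``probe_points`` maps point ids to (r_cm, z_cm) positions sampled every
    step.  Passing a prebuilt ``model`` reuses its operator factorization.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    model = model or ThermalModel(mmap, t_ext, metal_mode)
    duration = duration if duration is not None else schedule.end_time
    q_unit = _q_unit(model, loss)
    T0 = np.full(model.shape, float(t_ext))
    snap_times, snaps, ptimes, traces, powers, _ = _integrate(
        model, q_unit, schedule.power_at, T0, 0.0, duration, dt,
        snapshot_every, probe_points,
    )
    return ThermalSeries(
        times=snap_times, fields=snaps,
        probe_times=ptimes, probe_traces=traces,
        probe_points=dict(probe_points or {}),
        power_times=ptimes, power_trace=powers,
        t_ext=t_ext, map=mmap, loss=loss, dt=dt,
        t_power_off=min(schedule.end_time, duration),
    )


def run_controlled(
    mmap: MaterialMap,
    loss: LossField,
    controller: Controller,
    t_ext: float = 21.5,
    dt: float = 1.0,
    duration: float = 720.0,
    snapshot_every: float = 10.0,
    probe_points: dict[int, tuple[float, float]] | None = None,
    model: ThermalModel | None = None,
) -> ThermalSeries:
    """Closed-loop maintenance of a target temperature at a probe point."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    model = model or ThermalModel(mmap, t_ext)
    q_unit = _q_unit(model, loss)
    T0 = np.full(model.shape, float(t_ext))
    snap_times, snaps, ptimes, traces, powers, flagged = _integrate(
        model, q_unit, None, T0, 0.0, duration, dt,
        snapshot_every, probe_points, controller=controller,
    )
    return ThermalSeries(
        times=snap_times, fields=snaps,
        probe_times=ptimes, probe_traces=traces,
        probe_points=dict(probe_points or {}),
        power_times=ptimes, power_trace=powers,
        t_ext=t_ext, map=mmap, loss=loss, dt=dt,
        t_power_off=duration, controller_flagged=flagged,
    )


def cooling_phase(
    series: ThermalSeries,
    extra_duration: float,
    model: ThermalModel | None = None,
) -> ThermalSeries:
    """Continue a completed run with the power off, appending to the series."""
    if extra_duration <= 0:
        raise ValueError("extra_duration must be positive")
    model = model or ThermalModel(series.map, series.t_ext)
    t0 = float(series.probe_times[-1]) if len(series.probe_times) else float(series.times[-1])
    q_unit = np.zeros(model.shape[0] * model.shape[1])
    snap_times, snaps, ptimes, traces, powers, _ = _integrate(
        model, q_unit, lambda t: 0.0, series.final_field, t0,
        extra_duration, series.dt, 10.0, series.probe_points,
    )
    return ThermalSeries(
        times=np.concatenate([series.times, snap_times[1:]]),
        fields=np.concatenate([series.fields, snaps[1:]]),
        probe_times=np.concatenate([series.probe_times, ptimes]),
        probe_traces={
            pid: np.concatenate([series.probe_traces[pid], traces[pid]])
            for pid in series.probe_traces
        },
        probe_points=series.probe_points,
        power_times=np.concatenate([series.power_times, ptimes]),
        power_trace=np.concatenate([series.power_trace, powers]),
        t_ext=series.t_ext, map=series.map, loss=series.loss, dt=series.dt,
        t_power_off=series.t_power_off if series.t_power_off is not None else t0,
        controller_flagged=series.controller_flagged,
    )
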