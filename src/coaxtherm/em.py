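"""Axisymmetric FDTD solution of the driven coaxial applicator.

The applicator is a body of revolution excited in the rotationally symmetric
TEM-like mode, so Maxwell's curl equations reduce to three coupled field
components on the (r, z) half-plane:

    dHphi/dt = (1/mu) (dEz/dr - dEr/dz)
    dEr/dt   = -(1/eps) dHphi/dz - (sigma/eps) Er
    dEz/dt   =  (1/eps) (1/r) d(r Hphi)/dr - (sigma/eps) Ez

integrated leap-frog on a staggered Yee grid.  The axis r = 0 uses the Ampere
contour update; the open boundaries carry a first-order absorbing condition;
conductors are perfect electric conductors (tangential E forced to zero).  The
harmonic drive is a lumped voltage source with internal resistance across the
feed gap in the bottom plate.  After the cycle-to-cycle feed-current amplitude
settles, complex phasors are extracted by single-frequency projection over one
full period.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .geometry import MaterialMap

__all__ = [
    "SourceSpec",
    "RunControl",
    "PhasorSolution",
    "LossField",
    "ConvergenceError",
    "run_fdtd",
    "compute_sar",
    "compute_s11",
    "delivered_power",
    "boundary_outflow",
]

EPS0 = 8.8541878128e-12
MU0 = 4e-7 * np.pi
C0 = 1.0 / np.sqrt(EPS0 * MU0)


class ConvergenceError(RuntimeError):
    """Raised when an operation requires a converged field solution."""


@dataclass(frozen=True)
class SourceSpec:
    """Harmonic feed: 434 MHz, 1 V amplitude, 50 ohm internal resistance."""

    frequency: float = 434e6
    amplitude: float = 1.0
    internal_load: float = 50.0

    def __post_init__(self) -> None:
        if self.frequency <= 0:
            raise ValueError("frequency must be positive")
        if self.internal_load <= 0:
            raise ValueError("internal_load must be positive")


@dataclass(frozen=True)
class RunControl:
    """Time-stepping control.

    ``courant`` is the safety factor on the 2D stability limit of the smallest
    cell; the run stops once the relative cycle-to-cycle change of the feed
    current amplitude drops below ``tolerance`` (or after ``max_periods``).
    The source amplitude is ramped up smoothly over ``ramp_periods`` cycles to
    limit the switch-on transient.
    """

    max_periods: int = 60
    tolerance: float = 1e-4
    courant: float = 0.95
    ramp_periods: float = 3.0
    port_offset_cells: int = 3
    min_periods: int = 6

    def __post_init__(self) -> None:
        if not (0 < self.courant <= 1):
            raise ValueError("courant factor must lie in (0, 1]")
        if self.max_periods < self.min_periods:
            raise ValueError("max_periods must be >= min_periods")


@dataclass
class PhasorSolution:
    """Steady-state phasors at the drive frequency.

    Fields follow the convention ``F(t) = Re(F_hat * exp(i omega t))``.  The
    feed voltage/current are measured at a reference port plane inside the
    coax a few cells above the feed plate.
    """

    Er: np.ndarray            # (Nr, Nz+1) complex, V/m
    Ez: np.ndarray            # (Nr+1, Nz) complex, V/m
    Hphi: np.ndarray          # (Nr, Nz) complex, A/m
    feed_voltage: complex
    feed_current: complex
    frequency: float
    converged: bool
    periods_run: int
    residual: float
    map: MaterialMap = field(repr=False)

    @property
    def delivered_power(self) -> float:
        return delivered_power(self)


@dataclass
class LossField:
    """Time-averaged volumetric power loss and SAR on the cell grid."""

    p_loss: np.ndarray        # (Nr, Nz) W/m^3
    sar: np.ndarray           # (Nr, Nz) W/kg
    total_absorbed: float     # W
    map: MaterialMap = field(repr=False)

    def scaled(self, factor: float) -> "LossField":
        return LossField(
            p_loss=self.p_loss * factor,
            sar=self.sar * factor,
            total_absorbed=self.total_absorbed * factor,
            map=self.map,
        )


def _edge_average(cell_values: np.ndarray, widths: np.ndarray, axis: int) -> np.ndarray:
    """Width-weighted average of a cell quantity onto the edges along ``axis``.

    Boundary edges copy the adjacent cell.
    """
    v = np.moveaxis(cell_values, axis, 0)
    w = widths
    out = np.empty((v.shape[0] + 1,) + v.shape[1:], dtype=v.dtype)
    wl = w[:-1, None] if v.ndim > 1 else w[:-1]
    wr = w[1:, None] if v.ndim > 1 else w[1:]
    out[1:-1] = (wl * v[:-1] + wr * v[1:]) / (wl + wr)
    out[0] = v[0]
    out[-1] = v[-1]
    return np.moveaxis(out, 0, axis)


def run_fdtd(
    mmap: MaterialMap,
    src: SourceSpec | None = None,
    ctrl: RunControl | None = None,
) -> PhasorSolution:
    """Drive the applicator to harmonic steady state and extract phasors."""
    src = src or SourceSpec()
    ctrl = ctrl or RunControl()
    if mmap.source_index is None:
        raise ValueError("material map carries no feed location")

    r_edges, z_edges = mmap.r_edges, mmap.z_edges
    rc, zc = mmap.r_centers, mmap.z_centers
    dr, dz = mmap.dr, mmap.dz
    nr, nz = mmap.shape

    eps_c = EPS0 * mmap.cell_property("eps_r")
    sig_c = mmap.cell_property("sigma")

    # edge-collocated material parameters
    eps_er = _edge_average(eps_c, dz, axis=1)
    sig_er = _edge_average(sig_c, dz, axis=1)
    eps_ez = _edge_average(eps_c, dr, axis=0)
    sig_ez = _edge_average(sig_c, dr, axis=0)

    # time step from the 2D stability limit of the smallest cell
    omega = 2 * np.pi * src.frequency
    period = 1.0 / src.frequency
    dt_max = ctrl.courant / (C0 * np.sqrt(1.0 / dr.min() ** 2 + 1.0 / dz.min() ** 2))
    n_steps = int(np.ceil(period / dt_max))
    dt = period / n_steps

    loss_er = sig_er * dt / (2 * eps_er)
    loss_ez = sig_ez * dt / (2 * eps_ez)
    ca_er = (1 - loss_er) / (1 + loss_er)
    cb_er = (dt / eps_er) / (1 + loss_er)
    ca_ez = (1 - loss_ez) / (1 + loss_ez)
    cb_ez = (dt / eps_ez) / (1 + loss_ez)

    pec_er = mmap.pec_er
    pec_ez = mmap.pec_ez
    i_s, j_s = mmap.source_index
    pec_er[i_s, j_s] = False  # the feed edge is driven, never shorted
    ca_er[pec_er] = 0.0
    cb_er[pec_er] = 0.0
    ca_ez[pec_ez] = 0.0
    cb_ez[pec_ez] = 0.0

    dz_node = zc[1:] - zc[:-1]            # (nz-1,) spans interior Er planes
    dr_node = rc[1:] - rc[:-1]            # (nr-1,) spans interior Ez radii
    cb_er_i = cb_er[:, 1:-1] / dz_node[None, :]
    w_out = rc[1:] / (r_edges[1:-1] * dr_node)
    w_in = rc[:-1] / (r_edges[1:-1] * dr_node)
    cb_ez_i = cb_ez[1:-1, :]
    cb_ez_axis = cb_ez[0, :] * 2.0 / rc[0]

    # first-order absorbing boundaries (local wave speed from boundary cells)
    def _mur_coef(eps_cells_line, delta):
        c_loc = 1.0 / np.sqrt(MU0 * eps_cells_line)
        return (c_loc * dt - delta) / (c_loc * dt + delta)

    mur_er_lo = _mur_coef(eps_c[:, 0], z_edges[1] - z_edges[0])
    mur_er_hi = _mur_coef(eps_c[:, -1], z_edges[-1] - z_edges[-2])
    mur_ez = _mur_coef(eps_c[-1, :], r_edges[-1] - r_edges[-2])

    # lumped source bookkeeping: series 50-ohm element across the gap edge,
    # conductance folded semi-implicitly into the update like a loss term
    dr_s = dr[i_s]
    area_s = 2 * np.pi * rc[i_s] * (zc[j_s] - zc[j_s - 1])
    beta = dt * (sig_er[i_s, j_s] / 2 + dr_s / (2 * src.internal_load * area_s)) / eps_er[i_s, j_s]
    denom_s = 1 + beta
    numer_keep = 1 - beta

    # port plane for feed voltage/current: the contiguous run of free radial
    # edges between the conductors, a few cells above the feed plate
    j_port = j_s + ctrl.port_offset_cells
    keep = [i_s]
    while keep[-1] + 1 < nr and not pec_er[keep[-1] + 1, j_port]:
        keep.append(keep[-1] + 1)
    slots = np.array(keep)
    slot_dr = dr[slots]
    slot_r = rc[slots]

    Er = np.zeros((nr, nz + 1))
    Ez = np.zeros((nr + 1, nz))
    Hphi = np.zeros((nr, nz))

    v_trace = np.empty(n_steps)
    i_trace = np.empty(n_steps)
    ph = np.arange(1, n_steps + 1) * (omega * dt)
    cos_e, sin_e = np.cos(ph), np.sin(ph)
    ph_h = (np.arange(n_steps) + 0.5) * (omega * dt)
    cos_h, sin_h = np.cos(ph_h), np.sin(ph_h)

    def project(trace, c, s):
        return (2.0 / n_steps) * (np.dot(trace, c) - 1j * np.dot(trace, s))

    inv_mu_dt = dt / MU0
    amp_prev = None
    residual = np.inf
    converged = False
    periods = 0
    t = 0.0
    ramp_T = ctrl.ramp_periods * period

    def run_period(accumulate=False):
        nonlocal t
        if accumulate:
            acc = {
                "Er": np.zeros((nr, nz + 1), dtype=complex),
                "Ez": np.zeros((nr + 1, nz), dtype=complex),
                "Hphi": np.zeros((nr, nz), dtype=complex),
            }
        for n in range(n_steps):
            # H at t + dt/2
            Hphi[:, :] += inv_mu_dt * (
                (Ez[1:, :] - Ez[:-1, :]) / dr[:, None]
                - (Er[:, 1:] - Er[:, :-1]) / dz[None, :]
            )
            t_half = t + 0.5 * dt
            # E at t + dt
            er_old_lo = Er[:, 0].copy()
            er_old_hi = Er[:, -1].copy()
            ez_old = Ez[-1, :].copy()
            er_nb_lo = Er[:, 1].copy()
            er_nb_hi = Er[:, -2].copy()
            ez_nb = Ez[-2, :].copy()
            e_src_old = Er[i_s, j_s]

            Er[:, 1:-1] = ca_er[:, 1:-1] * Er[:, 1:-1] - cb_er_i * (Hphi[:, 1:] - Hphi[:, :-1])
            Ez[0, :] = ca_ez[0, :] * Ez[0, :] + cb_ez_axis * Hphi[0, :]
            Ez[1:-1, :] = ca_ez[1:-1, :] * Ez[1:-1, :] + cb_ez_i * (
                w_out[:, None] * Hphi[1:, :] - w_in[:, None] * Hphi[:-1, :]
            )
            # lumped resistive voltage source across the feed gap
            ramp = 1.0 if t_half >= ramp_T else np.sin(0.5 * np.pi * t_half / ramp_T) ** 2
            vs = src.amplitude * ramp * np.sin(omega * t_half)
            curl_s = -(Hphi[i_s, j_s] - Hphi[i_s, j_s - 1]) / (zc[j_s] - zc[j_s - 1])
            Er[i_s, j_s] = (
                numer_keep * e_src_old
                + (dt / eps_er[i_s, j_s]) * (curl_s + vs / (src.internal_load * area_s))
            ) / denom_s
            # absorbing boundaries (skip edges pinned by PEC)
            Er[:, 0] = np.where(pec_er[:, 0], 0.0, er_nb_lo + mur_er_lo * (Er[:, 1] - er_old_lo))
            Er[:, -1] = np.where(pec_er[:, -1], 0.0, er_nb_hi + mur_er_hi * (Er[:, -2] - er_old_hi))
            Ez[-1, :] = np.where(pec_ez[-1, :], 0.0, ez_nb + mur_ez * (Ez[-2, :] - ez_old))
            t += dt
            v_trace[n] = np.dot(Er[slots, j_port], slot_dr)
            i_trace[n] = 2 * np.pi * np.mean(slot_r * Hphi[slots, j_port])
            if accumulate:
                w = cos_e[n] - 1j * sin_e[n]
                acc["Er"] += Er * w
                acc["Ez"] += Ez * w
                acc["Hphi"] += Hphi * (cos_h[n] - 1j * sin_h[n])
        if accumulate:
            for k in acc:
                acc[k] *= 2.0 / n_steps
            return acc
        return None

    for p in range(ctrl.max_periods - 1):
        run_period()
        periods += 1
        amp = abs(project(i_trace, cos_h, sin_h))
        if amp_prev is not None and amp > 0:
            residual = abs(amp - amp_prev) / amp
            if periods >= ctrl.min_periods and residual < ctrl.tolerance:
                converged = True
        amp_prev = amp
        if converged:
            break
    acc = run_period(accumulate=True)
    periods += 1
    if not converged:
        # one extra check over the projection period before flagging
        amp = abs(project(i_trace, cos_h, sin_h))
        residual = abs(amp - amp_prev) / amp if amp > 0 else np.inf
        converged = residual < ctrl.tolerance
        if not converged:
            warnings.warn(
                f"FDTD feed current not settled after {periods} periods "
                f"(residual {residual:.2e})",
                RuntimeWarning,
                stacklevel=2,
            )

    v_hat = project(v_trace, cos_e, sin_e)
    i_hat = project(i_trace, cos_h, sin_h) * np.exp(-0.5j * omega * dt)
    return PhasorSolution(
        Er=acc["Er"],
        Ez=acc["Ez"],
        Hphi=acc["Hphi"] * np.exp(-0.5j * omega * dt),
        feed_voltage=v_hat,
        feed_current=i_hat,
        frequency=src.frequency,
        converged=converged,
        periods_run=periods,
        residual=float(residual),
        map=mmap,
    )


def compute_sar(sol: PhasorSolution, mmap: MaterialMap | None = None) -> LossField:
    """Time-averaged loss density p = sigma <|E|^2>/2 and SAR = p/rho per cell."""
    if not sol.converged:
        raise ConvergenceError("refusing to compute SAR from an unconverged solution")
    mmap = mmap or sol.map
    sig = mmap.cell_property("sigma")
    sig[mmap.pec_cells] = 0.0
    rho = mmap.cell_property("rho")
    er2 = 0.5 * (np.abs(sol.Er[:, :-1]) ** 2 + np.abs(sol.Er[:, 1:]) ** 2)
    ez2 = 0.5 * (np.abs(sol.Ez[:-1, :]) ** 2 + np.abs(sol.Ez[1:, :]) ** 2)
    p_loss = 0.5 * sig * (er2 + ez2)
    sar = p_loss / rho
    total = float(np.sum(p_loss * mmap.cell_volumes))
    return LossField(p_loss=p_loss, sar=sar, total_absorbed=total, map=mmap)


def delivered_power(sol: PhasorSolution) -> float:
    """Cycle-averaged power into the applicator at the feed port, W."""
    return 0.5 * float(np.real(sol.feed_voltage * np.conj(sol.feed_current)))


def compute_s11(
    sol: PhasorSolution,
    reference_impedance: float = 50.0,
    floor_db: float = -120.0,
) -> float:
    """Reflection coefficient 20 log10 |(Z_in - Z0)/(Z_in + Z0)| in dB."""
    if abs(sol.feed_current) == 0:
        raise ConvergenceError("degenerate solution: zero feed current")
    z_in = sol.feed_voltage / sol.feed_current
    gamma = (z_in - reference_impedance) / (z_in + reference_impedance)
    mag = abs(gamma)
    if mag <= 10 ** (floor_db / 20):
        return floor_db
    return float(20 * np.log10(mag))


def input_impedance(sol: PhasorSolution) -> complex:
    """Feed-plane impedance V/I (ohm)."""
    if abs(sol.feed_current) == 0:
        raise ConvergenceError("degenerate solution: zero feed current")
    return sol.feed_voltage / sol.feed_current


def boundary_outflow(sol: PhasorSolution) -> float:
    """Cycle-averaged Poynting power leaving through the open boundaries, W."""
    mmap = sol.map
    r_edges, z_edges = mmap.r_edges, mmap.z_edges
    rc = mmap.r_centers
    dz = mmap.dz
    # side wall r = r_max: S_r = -Re(Ez Hphi*)/2
    ez_side = sol.Ez[-1, :]
    h_side = sol.Hphi[-1, :]
    s_r = -0.5 * np.real(ez_side * np.conj(h_side))
    p_side = float(np.sum(s_r * 2 * np.pi * r_edges[-1] * dz))
    # top/bottom z = z_max / z_min: S_z = +/- Re(Er Hphi*)/2
    ring = np.pi * (r_edges[1:] ** 2 - r_edges[:-1] ** 2)
    s_top = 0.5 * np.real(sol.Er[:, -1] * np.conj(sol.Hphi[:, -1]))
    s_bot = -0.5 * np.real(sol.Er[:, 0] * np.conj(sol.Hphi[:, 0]))
    return p_side + float(np.sum(s_top * ring)) + float(np.sum(s_bot * ring))
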