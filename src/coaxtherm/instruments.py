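"""Virtual counterparts of the thermometry instrumentation.

Emulates the measurement chain used to characterize the applicator: three
fiber-optic temperature probes with measuring points every 2 cm along their
length (fibers at 0, 0.5 and 1 cm from the axis, +-0.1 degC accuracy), an IR
camera image of the opened split-phantom mid-plane (+-0.2 degC, acquired
within 3 min of power-off), a climate-controlled ambient of 21.5 +- 1 degC,
and idealized power-meter readings of the effectively supplied power.

Every generator is a pure function of its inputs and an integer seed: the
noise-free mode reproduces the solver output exactly, and a fixed seed gives
bit-identical readings.  Stated +-x accuracies are modelled as zero-mean
Gaussian noise with standard deviation x/2.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

from .geometry import MaterialProperties, MaterialTable, default_materials
from .thermal import PowerSchedule, ThermalSeries

__all__ = [
    "ProbeLayout",
    "NoiseModel",
    "sample_probes",
    "ir_snapshot",
    "IRImage",
    "sample_phantom_properties",
    "power_trace",
]


@dataclass(frozen=True)
class NoiseModel:
    """Instrument noise levels and the random seed that drives them."""

    fiber_sd: float = 0.05       # degC, half the +-0.1 degC probe accuracy
    ir_sd: float = 0.2           # degC, IR camera accuracy under lab conditions
    ambient_mean: float = 21.5   # degC
    ambient_halfwidth: float = 1.0
    power_rel_sd: float = 0.01   # relative sd of power-meter readings
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.fiber_sd, self.ir_sd, self.ambient_halfwidth, self.power_rel_sd) < 0:
            raise ValueError("noise levels must be non-negative")

    def rng(self, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng((self.seed, stream))

    def draw_ambient(self, stream: int = 17) -> float:
        """One ambient-temperature realization, uniform in mean +- halfwidth."""
        return float(
            self.rng(stream).uniform(
                self.ambient_mean - self.ambient_halfwidth,
                self.ambient_mean + self.ambient_halfwidth,
            )
        )


def _default_points() -> tuple[tuple[int, float, float], ...]:
    # fiber A on the axis, B at 0.5 cm, C at 1.0 cm; 2 cm pitch along each
    # fiber; ids chosen so that #3 sits at the VOI center, #9 and #12 on the
    # VOI boundary and at 1 cm (the radial line of the transient experiments)
    a = [(i + 1, 0.0, z) for i, z in enumerate((4.0, 2.0, 0.0, -2.0, -4.0))]
    b = [(i + 6, 0.5, z) for i, z in enumerate((6.0, 4.0, 2.0, 0.0, -2.0))]
    c = [(i + 11, 1.0, z) for i, z in enumerate((2.0, 0.0, -2.0, -4.0))]
    return tuple(a + b + c)


@dataclass(frozen=True)
class ProbeLayout:
    """The 14 fiber-optic measuring points, as (id, r_cm, z_cm).

    Fibers run vertically at radial offsets 0, 0.5 and 1 cm with measuring
    points spaced 2 cm.  Point #3 is the VOI center (0, 0), #2/#4 sit 2 cm
    above/below it, #9 is on the VOI boundary (0.5, 0) and #12 at (1, 0).
    The fibers' insertion depths differ so that all points stay in the gel
    (the phantom column extends 1 cm higher above the aperture than below).
    """

    points: tuple[tuple[int, float, float], ...] = field(default_factory=_default_points)
    spacing_cm: float = 2.0

    def __post_init__(self) -> None:
        ids = [p[0] for p in self.points]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate probe point ids")

    def as_dict(self) -> dict[int, tuple[float, float]]:
        return {pid: (r, z) for pid, r, z in self.points}

    def validate_inside(self, phantom_radius_cm: float, z_range_cm: tuple[float, float]) -> None:
        z0, z1 = z_range_cm
        for pid, r, z in self.points:
            if r > phantom_radius_cm + 1e-9 or not (z0 - 1e-9 <= z <= z1 + 1e-9):
                raise ValueError(f"probe point #{pid} at (r={r}, z={z}) cm lies outside the phantom")


def sample_probes(
    series: ThermalSeries,
    layout: ProbeLayout | None = None,
    noise: NoiseModel | None = None,
) -> pd.DataFrame:
    """Noisy fiber-optic readings of a thermal run.

    Returns a long DataFrame with columns ``time_s, point_id, temperature_C``.
    The exact probe traces are taken from the solver when the run recorded
    them; otherwise the saved fields are interpolated bilinearly at each point.
    """
    layout = layout or ProbeLayout()
    noise = noise or NoiseModel()
    geom = series.map.geometry
    if geom is not None:
        layout.validate_inside(geom.phantom_radius, geom.phantom_z_range)
    rng = noise.rng(stream=1)

    frames = []
    for pid, r, z in layout.points:
        if pid in series.probe_traces:
            t = series.probe_times
            vals = series.probe_traces[pid]
        else:
            t = series.times
            interp_pts = np.array([[r * 1e-2, z * 1e-2]])
            vals = np.array(
                [
                    RegularGridInterpolator(
                        (series.map.r_centers, series.map.z_centers), f,
                        bounds_error=False, fill_value=None,
                    )(interp_pts)[0]
                    for f in series.fields
                ]
            )
        readings = vals + rng.normal(0.0, noise.fiber_sd, size=len(vals)) if noise.fiber_sd > 0 else vals
        frames.append(pd.DataFrame({"time_s": t, "point_id": pid, "temperature_C": readings}))
    return pd.concat(frames, ignore_index=True)


@dataclass
class IRImage:
    """Mid-plane temperature image of the opened split phantom."""

    x_cm: np.ndarray          # transverse coordinate, mirrored about the axis
    z_cm: np.ndarray
    temperature_C: np.ndarray  # (nx, nz)
    time_s: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.temperature_C, index=self.x_cm, columns=self.z_cm)


def ir_snapshot(
    series: ThermalSeries,
    delay: float = 180.0,
    noise: NoiseModel | None = None,
    pixel_cm: float = 0.05,
) -> IRImage:
    """IR-camera image of the phantom mid-plane ``delay`` seconds after power-off.

    The (r, z) half-plane is mirrored into a full longitudinal section; camera
    noise is independent Gaussian per pixel.  The series must contain a cooling
    phase at least ``delay`` long.
    """
    noise = noise or NoiseModel()
    if series.t_power_off is None:
        raise ValueError("series has no power-off time")
    t_acq = series.t_power_off + delay
    if t_acq > series.times[-1] + 1e-9:
        raise ValueError(
            f"series ends at {series.times[-1]:.0f} s; cannot image at {t_acq:.0f} s "
            f"(power off + {delay:.0f} s)"
        )
    field_ = series.temperature_at(t_acq)
    geom = series.map.geometry
    if geom is None:
        raise ValueError("series map carries no phantom geometry")
    r_ph = geom.phantom_radius
    z0, z1 = geom.phantom_z_range
    x = np.arange(-r_ph + pixel_cm / 2, r_ph, pixel_cm)
    z = np.arange(z0 + pixel_cm / 2, z1, pixel_cm)
    interp = RegularGridInterpolator(
        (series.map.r_centers, series.map.z_centers), field_,
        bounds_error=False, fill_value=None,
    )
    X, Z = np.meshgrid(np.abs(x) * 1e-2, z * 1e-2, indexing="ij")
    img = interp(np.column_stack([X.ravel(), Z.ravel()])).reshape(X.shape)
    if noise.ir_sd > 0:
        img = img + noise.rng(stream=2).normal(0.0, noise.ir_sd, size=img.shape)
    return IRImage(x_cm=x, z_cm=z, temperature_C=img, time_s=t_acq)


def sample_phantom_properties(
    noise: NoiseModel | None = None,
    relative_sd: float = 0.02,
    materials: MaterialTable | None = None,
) -> MaterialProperties:
    """One realization of the measured agar-gel properties.

    Electrical conductivity and permittivity are drawn lognormally around
    their measured means (0.755 S/m, 74) with the given relative spread, so
    draws are strictly positive; ``relative_sd = 0`` returns the table values.
    """
    if relative_sd < 0:
        raise ValueError("relative_sd must be non-negative")
    noise = noise or NoiseModel()
    materials = materials or default_materials()
    agar = materials.lookup("agar gel")
    if relative_sd == 0:
        return agar
    rng = noise.rng(stream=3)
    s = np.sqrt(np.log1p(relative_sd**2))
    mu_correction = -0.5 * s * s  # lognormal mean equals the table value
    sigma = agar.sigma * np.exp(rng.normal(mu_correction, s))
    eps_r = agar.eps_r * np.exp(rng.normal(mu_correction, s))
    return replace(agar, sigma=float(sigma), eps_r=float(max(eps_r, 1.0)))


def power_trace(
    schedule: PowerSchedule,
    noise: NoiseModel | None = None,
    duration: float | None = None,
    interval: float = 1.0,
) -> pd.DataFrame:
    """Power-meter readings of the effectively supplied power.

    The schedule is sampled every ``interval`` seconds with multiplicative
    Gaussian noise of relative sd ``noise.power_rel_sd``.
    """
    noise = noise or NoiseModel()
    duration = duration if duration is not None else schedule.end_time
    t = np.arange(0.0, duration, interval) + interval / 2
    p = np.array([schedule.power_at(ti) for ti in t])
    if noise.power_rel_sd > 0:
        p = p * (1 + noise.rng(stream=4).normal(0.0, noise.power_rel_sd, size=len(p)))
    return pd.DataFrame({"time_s": t, "power_W": p})
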