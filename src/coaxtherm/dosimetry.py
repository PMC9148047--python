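"""Volume-of-interest dosimetry: exceedance percentiles, heterogeneity
coefficients, deposited-power fraction and axis profiles.

The target region is a 1 cm^3 cube centered on the axis at the aperture
center.  Because the cube is not a body of revolution while the fields are,
VOI statistics are computed by sampling the axisymmetric field on a regular
3D lattice inside the cube (equal-volume samples), mapping each lattice point
to its (r, z) coordinate.

Percentile convention (the hyperthermia T_q convention): ``P5`` is the value
exceeded in at least 5% of the volume (a high value), ``P95`` the value
exceeded in at least 95% (a low value).  The heterogeneity coefficients are

    eta_P = (P5 - P95) / P5        for the power-loss density,
    eta_T = (T5 - T95) / T5        for the temperature in degrees C,

and ``alpha`` is the percentage of the effectively supplied power deposited
inside the VOI.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

from .em import LossField
from .geometry import MaterialMap

__all__ = [
    "VOISpec",
    "MetricsResult",
    "volume_percentile",
    "voi_samples",
    "eta_P",
    "eta_T",
    "alpha",
    "extract_profiles",
]


@dataclass(frozen=True)
class VOISpec:
    """Cubic volume of interest centered on the axis at the aperture center.

    ``edge`` is the cube edge in cm (default 1 cm -> 1 cm^3); ``center_z`` the
    axial position of the cube center in cm; ``n`` the lattice points per axis
    used when sampling axisymmetric fields.
    """

    edge: float = 1.0
    center_z: float = 0.0
    n: int = 40

    def __post_init__(self) -> None:
        if self.edge <= 0:
            raise ValueError("VOI edge must be positive")
        if self.n < 2:
            raise ValueError("need at least 2 lattice points per axis")

    @property
    def volume_m3(self) -> float:
        return (self.edge * 1e-2) ** 3

    def lattice_rz(self) -> tuple[np.ndarray, np.ndarray]:
        """(r, z) coordinates (m) of the equal-volume cube lattice, flattened."""
        half = self.edge / 2 * 1e-2
        x = (np.arange(self.n) + 0.5) / self.n * 2 * half - half
        X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
        r = np.hypot(X, Y).ravel()
        z = (Z + self.center_z * 1e-2).ravel()
        return r, z


@dataclass
class MetricsResult:
    """Dosimetry summary over the VOI."""

    P5: float | None = None
    P95: float | None = None
    T5: float | None = None
    T95: float | None = None
    eta_P: float | None = None
    eta_T: float | None = None
    alpha: float | None = None
    profiles: dict[str, pd.DataFrame] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        scalars = {
            k: getattr(self, k)
            for k in ("P5", "P95", "T5", "T95", "eta_P", "eta_T", "alpha")
            if getattr(self, k) is not None
        }
        return pd.DataFrame([scalars])


def volume_percentile(values, q: float, weights=None) -> float:
    """Largest value exceeded in at least ``q`` percent of the region volume.

    ``values`` are field samples; ``weights`` their volumes (equal volumes if
    omitted).  ``q=5`` returns a high value (exceeded in only 5% of the
    volume); ``q=95`` a low one.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("empty region")
    if not (0 < q < 100):
        raise ValueError("percentile must lie strictly between 0 and 100")
    if weights is None:
        weights = np.ones_like(values)
    else:
        weights = np.asarray(weights, dtype=float).ravel()
        if weights.shape != values.shape:
            raise ValueError("weights must match values")
        if weights.sum() <= 0:
            raise ValueError("region has no volume")
    order = np.argsort(values)[::-1]
    frac = np.cumsum(weights[order]) / weights.sum()
    idx = np.searchsorted(frac, q / 100.0 - 1e-12, side="left")
    idx = min(idx, len(values) - 1)
    return float(values[order][idx])


def _interpolator(mmap: MaterialMap, cell_field: np.ndarray) -> RegularGridInterpolator:
    return RegularGridInterpolator(
        (mmap.r_centers, mmap.z_centers),
        cell_field,
        bounds_error=False,
        fill_value=None,
        method="linear",
    )


def voi_samples(mmap: MaterialMap, cell_field: np.ndarray, voi: VOISpec) -> np.ndarray:
    """Field sampled on the VOI cube lattice (equal-volume samples)."""
    r, z = voi.lattice_rz()
    if mmap.geometry is not None:
        r_ph = mmap.geometry.phantom_radius * 1e-2
        z0, z1 = (v * 1e-2 for v in mmap.geometry.phantom_z_range)
        if r.max() > r_ph + 1e-9 or z.min() < z0 - 1e-9 or z.max() > z1 + 1e-9:
            raise ValueError("VOI extends outside the phantom")
    return _interpolator(mmap, cell_field)(np.column_stack([r, z]))


def eta_P(loss: LossField, voi: VOISpec | None = None) -> float:
    """Coefficient of power heterogeneity (P5 - P95)/P5 over the VOI."""
    voi = voi or VOISpec()
    samples = voi_samples(loss.map, loss.p_loss, voi)
    p5 = volume_percentile(samples, 5)
    p95 = volume_percentile(samples, 95)
    if p5 <= 0:
        raise ValueError("undefined metric: P5 is not positive")
    return (p5 - p95) / p5


def eta_T(
    temperature: np.ndarray,
    mmap: MaterialMap,
    voi: VOISpec | None = None,
) -> float:
    """Coefficient of temperature heterogeneity (T5 - T95)/T5, temperatures
    in degrees C on the cell grid."""
    voi = voi or VOISpec()
    samples = voi_samples(mmap, temperature, voi)
    t5 = volume_percentile(samples, 5)
    t95 = volume_percentile(samples, 95)
    if t5 == 0:
        raise ValueError("undefined metric: T5 is zero")
    return (t5 - t95) / t5


def alpha(loss: LossField, supplied_power: float, voi: VOISpec | None = None) -> float:
    """Percentage of the supplied power deposited inside the VOI."""
    if supplied_power <= 0:
        raise ValueError("supplied power must be positive")
    voi = voi or VOISpec()
    samples = voi_samples(loss.map, loss.p_loss, voi)
    deposited = float(np.mean(samples)) * voi.volume_m3
    return 100.0 * deposited / supplied_power


def extract_profiles(
    mmap: MaterialMap,
    cell_field: np.ndarray,
    axis: str = "radial",
    normalize: bool = False,
    extent_cm: float | None = None,
    step_cm: float = 0.025,
    center_z_cm: float = 0.0,
) -> pd.DataFrame:
    """Field profile through the VOI center along the radial or longitudinal axis.

    Returns a DataFrame with columns ``distance_cm`` and ``value`` (value
    normalized to the profile value at the center when ``normalize``).
    """
    interp = _interpolator(mmap, cell_field)
    geom = mmap.geometry
    if axis == "radial":
        if extent_cm is None:
            extent_cm = geom.phantom_radius if geom else mmap.r_edges[-1] * 100
        s = np.arange(0.0, extent_cm + step_cm / 2, step_cm)
        pts = np.column_stack([s * 1e-2, np.full_like(s, center_z_cm * 1e-2)])
    elif axis == "longitudinal":
        if extent_cm is None:
            if geom:
                z0, z1 = geom.phantom_z_range
                extent_cm = min(abs(z0), z1)
            else:
                extent_cm = mmap.z_edges[-1] * 100
        s = np.arange(-extent_cm, extent_cm + step_cm / 2, step_cm)
        pts = np.column_stack([np.full_like(s, 0.0), s * 1e-2 + center_z_cm * 1e-2])
    else:
        raise ValueError("axis must be 'radial' or 'longitudinal'")
    vals = interp(pts)
    if normalize:
        ref = interp([[0.0, center_z_cm * 1e-2]])[0]
        vals = vals / ref
    return pd.DataFrame({"distance_cm": s, "value": vals})
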