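"""Applicator geometry, material table and axisymmetric rasterization.

The device is an open-ended coaxial TEM applicator: a hollow inner conductor
(outer diameter ``d``) with a circumferential aperture of width ``w``, an outer
conductor (inner diameter ``D``), HDPE dielectric in between, and a cylindrical
agar-gel phantom held in a PVC tube inside the inner-conductor bore.  The whole
assembly is a body of revolution, so fields and temperatures are computed on an
``(r, z)`` half-plane with the aperture center at ``z = 0``.

Interface lengths are centimeters (the unit the applicator is specified in);
everything stored on grids is SI (meters).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GeometryError",
    "ResolutionError",
    "MaterialProperties",
    "MaterialTable",
    "default_materials",
    "coax_impedance",
    "solve_outer_diameter",
    "ApplicatorGeometry",
    "GridSpec",
    "MaterialMap",
    "build_material_map",
    "build_coax_line_map",
]

CM = 1e-2  # interface unit -> SI


class GeometryError(ValueError):
    """Raised for non-physical or inconsistent applicator dimensions."""


class ResolutionError(ValueError):
    """Raised when a grid cannot resolve every material layer."""


# ---------------------------------------------------------------------------
# materials
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MaterialProperties:
    """Electrical and thermal bulk properties of one medium.

    Parameters
    ----------
    rho : mass density, kg/m^3
    sigma : electrical conductivity, S/m
    eps_r : relative permittivity (dimensionless)
    cp : specific heat capacity, J/(kg K)
    k : thermal conductivity, W/(m K)
    is_pec : if True the medium is a perfect electric conductor and its
        electrical properties are ignored by the field solver.
    """

    name: str
    rho: float
    sigma: float
    eps_r: float
    cp: float
    k: float
    is_pec: bool = False

    def __post_init__(self) -> None:
        if self.rho <= 0 or self.cp <= 0 or self.k <= 0:
            raise ValueError(f"{self.name}: rho, cp, k must be positive")
        if self.sigma < 0:
            raise ValueError(f"{self.name}: sigma must be non-negative")
        if self.eps_r < 1:
            raise ValueError(f"{self.name}: eps_r must be >= 1")


_CSV_COLUMNS = ["rho", "sigma", "eps_r", "cp", "k", "is_pec"]


class MaterialTable:
    """Ordered collection of :class:`MaterialProperties` with name lookup."""

    def __init__(self, materials: Sequence[MaterialProperties]):
        self._materials = list(materials)
        self._by_name = {m.name: i for i, m in enumerate(self._materials)}
        if len(self._by_name) != len(self._materials):
            raise ValueError("duplicate material names")

    def __len__(self) -> int:
        return len(self._materials)

    def __iter__(self) -> Iterator[MaterialProperties]:
        return iter(self._materials)

    def __getitem__(self, index: int) -> MaterialProperties:
        return self._materials[index]

    def index(self, name: str) -> int:
        return self._by_name[name]

    def lookup(self, name: str) -> MaterialProperties:
        return self._materials[self._by_name[name]]

    def property_vector(self, prop: str) -> np.ndarray:
        return np.array([getattr(m, prop) for m in self._materials], dtype=float)

    def to_csv(self, path_or_buf) -> None:
        df = pd.DataFrame(
            [[m.name] + [getattr(m, c) for c in _CSV_COLUMNS] for m in self],
            columns=["material"] + _CSV_COLUMNS,
        )
        df.to_csv(path_or_buf, index=False)

    @classmethod
    def from_csv(cls, path_or_buf) -> "MaterialTable":
        df = pd.read_csv(path_or_buf)
        mats = [
            MaterialProperties(
                name=row["material"],
                rho=float(row["rho"]),
                sigma=float(row["sigma"]),
                eps_r=float(row["eps_r"]),
                cp=float(row["cp"]),
                k=float(row["k"]),
                is_pec=bool(row["is_pec"]),
            )
            for _, row in df.iterrows()
        ]
        return cls(mats)


def default_materials() -> MaterialTable:
    """Material table of the applicator study.

    HDPE, PVC and the muscle-mimicking agar gel carry their measured/handbook
    properties; brass parts are perfect electric conductors; air (padding only)
    uses textbook values.  Brass thermal entries are placeholders -- metal is
    excluded from the thermal stage.
    """
    return MaterialTable(
        [
            MaterialProperties("air", rho=1.2, sigma=0.0, eps_r=1.0, cp=1005.0, k=0.026),
            MaterialProperties("agar gel", rho=1000.0, sigma=0.755, eps_r=74.0, cp=4181.0, k=0.563),
            MaterialProperties("PVC", rho=1380.0, sigma=0.0001, eps_r=3.0, cp=1250.0, k=0.2),
            MaterialProperties("HDPE", rho=950.0, sigma=0.00001, eps_r=2.1, cp=1900.0, k=0.5),
            MaterialProperties("brass", rho=8500.0, sigma=0.0, eps_r=1.0, cp=380.0, k=120.0, is_pec=True),
        ]
    )


# ---------------------------------------------------------------------------
# coax line sizing
# ---------------------------------------------------------------------------

def coax_impedance(D: float, d: float, eps_r_dielectric: float) -> float:
    """Characteristic impedance (ohm) of a coaxial line.

    ``Z = 138 log10(D/d) / sqrt(eps_r)`` with ``D`` the outer-conductor inner
    diameter and ``d`` the inner-conductor outer diameter (any common length
    unit).
    """
    if d <= 0 or D <= 0 or D < d:
        raise GeometryError(f"need D >= d > 0, got D={D}, d={d}")
    if eps_r_dielectric < 1:
        raise GeometryError("eps_r_dielectric must be >= 1")
    return 138.0 * np.log10(D / d) / np.sqrt(eps_r_dielectric)


def solve_outer_diameter(Z: float, d: float, eps_r_dielectric: float) -> float:
    """Invert the coax impedance relation for the outer-conductor diameter."""
    if Z < 0:
        raise GeometryError("impedance must be non-negative")
    if d <= 0:
        raise GeometryError("inner diameter must be positive")
    if eps_r_dielectric < 1:
        raise GeometryError("eps_r_dielectric must be >= 1")
    return d * 10.0 ** (Z * np.sqrt(eps_r_dielectric) / 138.0)


# ---------------------------------------------------------------------------
# parametric geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ApplicatorGeometry:
    """Parametric description of applicator, phantom, tube and domain (cm).

    ``z = 0`` is the aperture center; ``phantom_z_offset`` shifts the phantom
    column upward so that the uppermost fiber-optic measuring point still sits
    in the gel.  The PVC tube fits tightly in the inner-conductor bore, so
    ``tube_outer_diameter = d - 2*conductor_wall`` for a consistent build.
    """

    d: float = 3.5                 # inner-conductor outer diameter
    D: float = 11.7                # outer-conductor inner diameter
    w: float = 1.7                 # aperture width
    h: float = 8.0                 # outer-conductor height
    phantom_diameter: float = 3.0
    phantom_height: float = 10.0
    tube_outer_diameter: float = 3.3
    tube_wall: float = 0.15
    conductor_wall: float = 0.1
    domain_padding: float = 17.3
    phantom_z_offset: float = 1.0

    def __post_init__(self) -> None:
        lengths = {
            "d": self.d, "D": self.D, "w": self.w, "h": self.h,
            "phantom_diameter": self.phantom_diameter,
            "phantom_height": self.phantom_height,
            "tube_outer_diameter": self.tube_outer_diameter,
            "tube_wall": self.tube_wall,
            "conductor_wall": self.conductor_wall,
            "domain_padding": self.domain_padding,
        }
        for name, val in lengths.items():
            if val <= 0:
                raise GeometryError(f"{name} must be positive, got {val}")
        if not (self.D > self.d > self.tube_outer_diameter >= self.phantom_diameter):
            raise GeometryError(
                "need D > d > tube_outer_diameter >= phantom_diameter, got "
                f"D={self.D}, d={self.d}, tube={self.tube_outer_diameter}, "
                f"phantom={self.phantom_diameter}"
            )
        if not (0 < self.w < self.h):
            raise GeometryError(f"need 0 < w < h, got w={self.w}, h={self.h}")
        if self.tube_outer_diameter - 2 * self.tube_wall < self.phantom_diameter - 1e-9:
            raise GeometryError("tube bore smaller than phantom diameter")

    @classmethod
    def prototype(cls, **overrides) -> "ApplicatorGeometry":
        """The built device: d=3.5 cm, D=11.7 cm, w=1.7 cm, h=8 cm."""
        return cls(**overrides)

    @classmethod
    def for_sweep(
        cls,
        d: float,
        w: float,
        h: float = 8.0,
        impedance: float = 50.0,
        eps_r_dielectric: float = 2.1,
        **overrides,
    ) -> "ApplicatorGeometry":
        """Geometry for one point of the (d, w) design sweep.

        ``D`` follows from the 50-ohm impedance constraint; the PVC tube and
        phantom are resized to fill the bore of the chosen inner conductor,
        mirroring how the physical tubes were adapted per diameter.
        """
        D = solve_outer_diameter(impedance, d, eps_r_dielectric)
        base = cls()
        tube_out = d - 2 * base.conductor_wall
        phantom = tube_out - 2 * base.tube_wall
        return cls(
            d=d, D=D, w=w, h=h,
            tube_outer_diameter=tube_out,
            phantom_diameter=phantom,
            **overrides,
        )

    # convenient radii in cm
    @property
    def phantom_radius(self) -> float:
        return self.phantom_diameter / 2

    @property
    def phantom_z_range(self) -> tuple[float, float]:
        z0 = -self.phantom_height / 2 + self.phantom_z_offset
        return (z0, z0 + self.phantom_height)


@dataclass(frozen=True)
class GridSpec:
    """Non-uniform grid resolution specification (mm).

    ``fine_mm`` applies in the phantom and around the aperture, ``device_mm``
    in the rest of the applicator volume, and spacings grow geometrically to
    ``coarse_mm`` through the padding toward the absorbing boundary.  Every
    material layer is guaranteed at least ``min_layer_cells`` cells across by
    snapping grid lines to layer boundaries and subdividing thin layers.
    """

    fine_mm: float = 0.5
    device_mm: float = 2.0
    coarse_mm: float = 5.0
    growth: float = 1.3
    min_layer_cells: int = 2
    fine_margin_cm: float = 0.5

    def __post_init__(self) -> None:
        if not (0 < self.fine_mm <= self.device_mm <= self.coarse_mm):
            raise ResolutionError("need 0 < fine_mm <= device_mm <= coarse_mm")
        if self.growth <= 1:
            raise ResolutionError("growth must exceed 1")
        if self.min_layer_cells < 1:
            raise ResolutionError("min_layer_cells must be >= 1")


def _uniform_seg(x0: float, x1: float, h: float, min_cells: int = 1) -> np.ndarray:
    """Edges of a uniform segment with spacing <= h and >= min_cells cells."""
    length = x1 - x0
    if length <= 0:
        raise ResolutionError(f"degenerate segment [{x0}, {x1}]")
    n = max(min_cells, int(np.ceil(length / h - 1e-9)))
    return x0 + length * np.arange(n + 1) / n


def _graded_seg(x0: float, x1: float, h0: float, h1: float, growth: float) -> np.ndarray:
    """Edges of a segment whose spacing grows geometrically from h0 to h1.

    The spacing sequence starts at ``h0`` at ``x0`` and is rescaled so that the
    segment length is matched exactly.
    """
    length = x1 - x0
    if length <= 0:
        raise ResolutionError(f"degenerate segment [{x0}, {x1}]")
    steps = []
    h = h0
    total = 0.0
    while total < length:
        steps.append(h)
        total += h
        h = min(h * growth, h1)
    steps = np.array(steps) * (length / total)
    return x0 + np.concatenate([[0.0], np.cumsum(steps)])


def _merge(segments: Sequence[np.ndarray]) -> np.ndarray:
    edges = np.concatenate([segments[0]] + [s[1:] for s in segments[1:]])
    return edges


# ---------------------------------------------------------------------------
# material map
# ---------------------------------------------------------------------------

@dataclass
class MaterialMap:
    """Axisymmetric (r, z) grid with per-cell material assignment.

    ``cell_material`` holds indices into ``materials`` for each of the
    ``(Nr, Nz)`` cells.  ``pec_cells`` marks perfect-conductor cells; the face
    masks used by the field solver derive from it.  ``source_index`` is the
    ``(i, j)`` index of the radial E edge in the feed gap of the bottom plate
    (None for maps without a feed).
    """

    r_edges: np.ndarray          # (Nr+1,), m, r_edges[0] == 0
    z_edges: np.ndarray          # (Nz+1,), m
    cell_material: np.ndarray    # (Nr, Nz) int
    materials: MaterialTable
    pec_cells: np.ndarray        # (Nr, Nz) bool
    source_index: tuple[int, int] | None = None
    geometry: ApplicatorGeometry | None = None

    def __post_init__(self) -> None:
        if abs(self.r_edges[0]) > 1e-15:
            raise GeometryError("r_edges must start at the axis (r = 0)")
        if np.any(np.diff(self.r_edges) <= 0) or np.any(np.diff(self.z_edges) <= 0):
            raise GeometryError("grid edges must be strictly increasing")

    # --- grid helpers -----------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.r_edges) - 1, len(self.z_edges) - 1)

    @property
    def r_centers(self) -> np.ndarray:
        return 0.5 * (self.r_edges[:-1] + self.r_edges[1:])

    @property
    def z_centers(self) -> np.ndarray:
        return 0.5 * (self.z_edges[:-1] + self.z_edges[1:])

    @property
    def dr(self) -> np.ndarray:
        return np.diff(self.r_edges)

    @property
    def dz(self) -> np.ndarray:
        return np.diff(self.z_edges)

    @property
    def cell_volumes(self) -> np.ndarray:
        """Cell ring volumes 2*pi*r*dA = pi*(r_out^2 - r_in^2)*dz, m^3."""
        ring = np.pi * (self.r_edges[1:] ** 2 - self.r_edges[:-1] ** 2)
        return ring[:, None] * self.dz[None, :]

    def cell_property(self, prop: str) -> np.ndarray:
        """Per-cell array of one material property."""
        return self.materials.property_vector(prop)[self.cell_material]

    def material_volume(self, name: str) -> float:
        """Total rasterized volume (m^3) of one material."""
        mask = self.cell_material == self.materials.index(name)
        return float(self.cell_volumes[mask].sum())

    # --- PEC face masks ---------------------------------------------------
    @property
    def pec_er(self) -> np.ndarray:
        """Radial-E edges forced to zero: (Nr, Nz+1)."""
        nr, nz = self.shape
        mask = np.zeros((nr, nz + 1), dtype=bool)
        mask[:, 1:] |= self.pec_cells
        mask[:, :-1] |= self.pec_cells
        return mask

    @property
    def pec_ez(self) -> np.ndarray:
        """Axial-E edges forced to zero: (Nr+1, Nz)."""
        nr, nz = self.shape
        mask = np.zeros((nr + 1, nz), dtype=bool)
        mask[1:, :] |= self.pec_cells
        mask[:-1, :] |= self.pec_cells
        return mask

    def thermal_material(self, metal_mode: str = "transparent") -> np.ndarray:
        """Per-cell material indices for the thermal stage.

        The thin brass walls are excluded from thermal simulation.  In the
        default ``"transparent"`` mode they conduct like the HDPE dielectric
        that surrounds them (heat passes through); ``"metal"`` keeps the brass
        entry, which approximates isothermal sheets through its high k.
        """
        mat = self.cell_material.copy()
        if metal_mode == "transparent":
            mat[self.pec_cells] = self.materials.index("HDPE")
        elif metal_mode != "metal":
            raise ValueError(f"unknown metal_mode {metal_mode!r}")
        return mat


def _segments_with_breaks(
    breaks: Sequence[tuple[float, float, int]],
    growth: float,
) -> np.ndarray:
    """Assemble edges from (x_end, target_spacing, min_cells) segments.

    ``breaks[0]`` gives the start coordinate (its spacing/min_cells unused).
    A negative target spacing requests geometric grading from the previous
    segment's spacing to ``-target``.
    """
    segs = []
    x_prev = breaks[0][0]
    h_prev = None
    for x, h, mc in breaks[1:]:
        if x <= x_prev + 1e-12:
            continue
        if h < 0:
            seg = _graded_seg(x_prev, x, h_prev if h_prev else -h, -h, growth)
            h_prev = -h
        else:
            seg = _uniform_seg(x_prev, x, h, mc)
            h_prev = h
        segs.append(seg)
        x_prev = x
    return _merge(segs)


def build_material_map(
    geom: ApplicatorGeometry,
    grid: GridSpec | None = None,
) -> MaterialMap:
    """Rasterize the applicator onto a non-uniform axisymmetric grid.

    Regions, inside-out: agar phantom, PVC tube, inner-conductor shell (PEC,
    broken by the aperture of width ``w`` centered at z=0), HDPE annulus,
    outer-conductor shell (PEC), air padding.  The outer conductor is closed at
    the bottom by a PEC plate carrying a one-cell feed gap next to the inner
    conductor, and open at the top.
    """
    grid = grid or GridSpec()
    mats = default_materials()
    fine = grid.fine_mm * 1e-3
    dev = grid.device_mm * 1e-3
    coarse = grid.coarse_mm * 1e-3
    mc = grid.min_layer_cells
    margin = grid.fine_margin_cm * CM

    # radii (m), inside out
    r_ph = geom.phantom_radius * CM
    r_tube = geom.tube_outer_diameter / 2 * CM
    a = geom.d / 2 * CM                      # inner conductor outer radius
    a_in = a - geom.conductor_wall * CM      # inner conductor inner radius
    b = geom.D / 2 * CM                      # outer conductor inner radius
    b_out = b + geom.conductor_wall * CM
    r_max = b_out + geom.domain_padding * CM
    if r_tube > a_in + 1e-12:
        raise GeometryError("PVC tube does not fit inside the inner-conductor bore")
    for lo, hi, label in [(r_ph, r_tube, "tube wall"), (a_in, a, "inner conductor wall"),
                          (b, b_out, "outer conductor wall")]:
        if hi - lo <= 1e-9:
            raise ResolutionError(f"{label} has no thickness; cannot be resolved by {mc} cells")

    r_breaks = [(0.0, 0.0, 0), (r_ph, fine, mc), (r_tube, fine, mc)]
    if a_in - r_tube > 1e-12:
        r_breaks.append((a_in, fine, 1))
    r_breaks += [(a, fine, mc), (b, dev, 1), (b_out, fine, mc), (r_max, -coarse, 1)]
    r_edges = _segments_with_breaks(r_breaks, grid.growth)

    # axial coordinates (m)
    hw = geom.w / 2 * CM
    hh = geom.h / 2 * CM
    tc = geom.conductor_wall * CM
    z_ph0, z_ph1 = (v * CM for v in geom.phantom_z_range)
    z_lo = min(-hh, z_ph0)
    z_hi = max(hh, z_ph1)
    z_min = z_lo - geom.domain_padding * CM
    z_max = z_hi + geom.domain_padding * CM
    if hw + margin >= hh:
        raise GeometryError("aperture too close to conductor height for the fine band")

    interior: list[tuple[float, float, int]] = [(z_lo, 0.0, 0)]
    pts = sorted({-hh, -hh + tc, z_ph0, -hw - margin, -hw, hw, hw + margin, hh, z_ph1, z_hi})
    for z in pts:
        if z <= z_lo + 1e-12:
            continue
        if -hw - margin - 1e-12 <= z <= hw + margin + 1e-12:
            h_target, n_min = fine, 1
        elif abs(z - (-hh + tc)) < 1e-12:
            h_target, n_min = fine, mc      # bottom plate layer
        else:
            h_target, n_min = dev, 1
        interior.append((z, h_target, n_min))
    z_core = _segments_with_breaks(interior, grid.growth)
    # grade away from the device on both sides: build outward then flip for below
    below = z_lo - (_graded_seg(0.0, z_lo - z_min, dev, coarse, grid.growth))[::-1]
    above = _graded_seg(z_hi, z_max, dev, coarse, grid.growth)
    z_edges = _merge([below, z_core, above])

    nr, nz = len(r_edges) - 1, len(z_edges) - 1
    rc = 0.5 * (r_edges[:-1] + r_edges[1:])
    zc = 0.5 * (z_edges[:-1] + z_edges[1:])
    R, Z = np.meshgrid(rc, zc, indexing="ij")

    i_air = mats.index("air")
    i_agar = mats.index("agar gel")
    i_pvc = mats.index("PVC")
    i_hdpe = mats.index("HDPE")
    i_brass = mats.index("brass")

    mat = np.full((nr, nz), i_air, dtype=np.int16)
    in_phantom_z = (Z > z_ph0) & (Z < z_ph1)
    mat[(R < r_ph) & in_phantom_z] = i_agar
    mat[(R > r_ph) & (R < r_tube) & in_phantom_z] = i_pvc
    mat[(R > a) & (R < b) & (Z > -hh + tc) & (Z < hh)] = i_hdpe
    # conductors; the inner-conductor bore is closed at the bottom where the
    # feed-line core attaches (the phantom tube is inserted from the top)
    inner_shell = (R > a_in) & (R < a) & (Z > -hh) & (Z < hh) & (np.abs(Z) > hw)
    outer_shell = (R > b) & (R < b_out) & (Z > -hh) & (Z < hh)
    plate = (R < b) & (Z > -hh) & (Z < -hh + tc)
    mat[inner_shell | outer_shell | plate] = i_brass

    # feed gap: one radial cell column cut out of the bottom plate, adjacent
    # to the inner conductor; the lumped source drives the radial E edge on
    # the plate's upper surface across this gap (a delta-gap feed; a small
    # fraction of the source power radiates backward through the slot)
    i_gap = int(np.searchsorted(r_edges, a + 1e-12)) - 1  # cell whose inner edge is r = a
    j_plate = np.where((zc > -hh) & (zc < -hh + tc))[0]
    if len(j_plate) == 0:
        raise ResolutionError("bottom plate not resolved by the grid")
    mat[i_gap, j_plate] = i_hdpe
    j_src = int(j_plate[-1] + 1)  # z-edge index of the plate top surface
    pec = mats.property_vector("is_pec").astype(bool)[mat]

    return MaterialMap(
        r_edges=r_edges,
        z_edges=z_edges,
        cell_material=mat,
        materials=mats,
        pec_cells=pec,
        source_index=(i_gap, j_src),
        geometry=geom,
    )


def build_coax_line_map(
    d: float = 3.5,
    D: float = 11.7,
    length: float = 30.0,
    conductor_wall: float = 0.1,
    padding: float = 5.0,
    grid: GridSpec | None = None,
    dielectric: str = "HDPE",
) -> MaterialMap:
    """Uniform coaxial line section for solver validation (lengths in cm).

    A straight coax (no aperture, no phantom) fed through the usual bottom
    plate and running to the top of the computational domain, where the
    absorbing boundary acts as a matched termination.  The ratio of feed
    voltage to feed current then measures the line's characteristic impedance.
    """
    grid = grid or GridSpec()
    mats = default_materials()
    fine = grid.fine_mm * 1e-3
    dev = grid.device_mm * 1e-3
    coarse = grid.coarse_mm * 1e-3
    mc = grid.min_layer_cells

    a = d / 2 * CM
    a_in = a - conductor_wall * CM
    b = D / 2 * CM
    b_out = b + conductor_wall * CM
    tc = conductor_wall * CM
    r_max = b_out + padding * CM
    r_edges = _segments_with_breaks(
        [(0.0, 0.0, 0), (a_in, dev, 1), (a, fine, mc), (b, dev, 1),
         (b_out, fine, mc), (r_max, -coarse, 1)],
        grid.growth,
    )
    z0 = 0.0
    z_top = length * CM
    z_min = -padding * CM
    below = z0 - (_graded_seg(0.0, z0 - z_min, dev, coarse, grid.growth))[::-1]
    core = _segments_with_breaks(
        [(z0, 0.0, 0), (tc, fine, mc), (z_top, dev, 1)], grid.growth
    )
    z_edges = _merge([below, core])

    rc = 0.5 * (r_edges[:-1] + r_edges[1:])
    zc = 0.5 * (z_edges[:-1] + z_edges[1:])
    R, Z = np.meshgrid(rc, zc, indexing="ij")
    mat = np.full(R.shape, mats.index("air"), dtype=np.int16)
    mat[(R > a) & (R < b) & (Z > tc)] = mats.index(dielectric)
    shells = ((R > a_in) & (R < a) & (Z > z0)) | ((R > b) & (R < b_out) & (Z > z0))
    plate = (R > a_in) & (R < b) & (Z > z0) & (Z < tc)
    mat[shells | plate] = mats.index("brass")

    i_gap = int(np.searchsorted(r_edges, a + 1e-12)) - 1
    j_plate = np.where((zc > z0) & (zc < tc))[0]
    mat[i_gap, j_plate] = mats.index(dielectric)
    j_src = int(j_plate[-1] + 1)
    pec = mats.property_vector("is_pec").astype(bool)[mat]
    return MaterialMap(
        r_edges=r_edges, z_edges=z_edges, cell_material=mat,
        materials=mats, pec_cells=pec, source_index=(i_gap, j_src),
    )
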