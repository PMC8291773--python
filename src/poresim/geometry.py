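"""Axisymmetric pore geometries: presets, geometric queries, and meshing.

The coordinate convention is cylindrical (r, z) with z = 0 at the upper (cis)
channel entry and z increasing upward.  The channel occupies z in [-L, 0].
All lengths at this interface are in nanometres; SI conversion happens inside
the continuum solver.
"""
from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import yaml

from .constants import CONSTANTS, Q_PER_NM2

__all__ = [
    "PoreSpec",
    "WallRegion",
    "Membrane",
    "Reservoir",
    "Mesh",
    "MeshOptions",
    "build_preset",
    "mesh",
    "wall_distance",
    "graded_edges",
]

# region ids used in Mesh.region
FLUID, WALL, MEMBRANE, PROTEIN = 0, 1, 2, 3
REGION_NAMES = {FLUID: "fluid", WALL: "wall", MEMBRANE: "membrane", PROTEIN: "protein"}


@dataclass(frozen=True)
class WallRegion:
    """A z-range of the channel wall with a surface charge density.

    ``sigma`` is in q/nm^2 (multiply by :data:`poresim.constants.Q_PER_NM2`
    for C/m^2).
    """

    z_lo: float
    z_hi: float
    sigma: float
    material: str = "dna"


@dataclass(frozen=True)
class Membrane:
    """Planar membrane slab attached to the channel wall."""

    center_z: float
    thickness: float
    sigma: float = 0.0
    material: str = "lipid"

    @property
    def z_top(self) -> float:
        return self.center_z + self.thickness / 2.0

    @property
    def z_bot(self) -> float:
        return self.center_z - self.thickness / 2.0


@dataclass(frozen=True)
class Reservoir:
    """Cylindrical electrolyte reservoir surrounding the pore."""

    radius: float
    height_above: float
    height_below: float


@dataclass(frozen=True)
class PoreSpec:
    """Parameterized axisymmetric pore geometry.

    ``profile`` lists (z, wall radius) breakpoints in nm, ordered from the
    upper entry (z = 0) downward; the wall radius is piecewise linear in
    between.  ``wall_thickness`` is the radial extent of the channel wall
    (None means the wall fills the domain laterally, as for a channel drilled
    through a thick membrane).
    """

    name: str
    profile: tuple[tuple[float, float], ...]
    channel_length: float
    wall_thickness: float | None
    wall_material: str
    wall_regions: tuple[WallRegion, ...]
    membrane: Membrane | None
    reservoir: Reservoir
    cross_section: str = "circular"
    nominal_width: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        zs = [p[0] for p in self.profile]
        rads = [p[1] for p in self.profile]
        if any(r <= 0 for r in rads):
            raise ValueError("profile radius must be > 0 everywhere")
        if not all(a > b for a, b in zip(zs, zs[1:])):
            raise ValueError("profile breakpoints must be ordered from z=0 downward")
        if abs(zs[0]) > 1e-9 or abs(zs[-1] + self.channel_length) > 1e-6:
            raise ValueError("profile must span [-channel_length, 0]")
        if self.membrane is not None:
            if self.membrane.z_top > 1e-9 + self.reservoir.height_above:
                raise ValueError("membrane overlaps the reservoir top")
            if self.membrane.z_bot < -(self.channel_length + self.reservoir.height_below) - 1e-9:
                raise ValueError("membrane overlaps the reservoir bottom")
        lo, hi = -self.channel_length, 0.0
        covered = sorted((max(w.z_lo, lo), min(w.z_hi, hi)) for w in self.wall_regions)
        pos = lo
        for a, b in covered:
            if a > pos + 1e-6:
                break
            pos = max(pos, b)
        # gaps are allowed and mean "uncharged"; nothing to enforce beyond ordering

    # -- geometric queries -------------------------------------------------

    def channel_radius(self, z):
        """Piecewise-linear wall radius at axial position(s) z (nm)."""
        zs = np.array([p[0] for p in self.profile])[::-1]
        rs = np.array([p[1] for p in self.profile])[::-1]
        return np.interp(np.asarray(z, dtype=float), zs, rs)

    @property
    def z_top(self) -> float:
        return self.reservoir.height_above

    @property
    def z_bot(self) -> float:
        return -(self.channel_length + self.reservoir.height_below)

    def wall_outer_radius(self, z) -> np.ndarray:
        if self.wall_thickness is None:
            return np.full_like(np.asarray(z, dtype=float), self.reservoir.radius)
        return self.channel_radius(z) + self.wall_thickness

    def wall_sigma(self, z) -> np.ndarray:
        """Surface charge density (C/m^2) of the channel wall at height z."""
        z = np.asarray(z, dtype=float)
        out = np.zeros_like(z)
        for w in self.wall_regions:
            m = (z >= w.z_lo - 1e-9) & (z <= w.z_hi + 1e-9)
            out = np.where(m, w.sigma * Q_PER_NM2, out)
        return out

    def solid_at(self, r, z, protein: tuple[float, float] | None = None):
        """Region id (FLUID/WALL/MEMBRANE/PROTEIN) at points (r, z) in nm."""
        r = np.asarray(r, dtype=float)
        z = np.asarray(z, dtype=float)
        out = np.zeros(np.broadcast(r, z).shape, dtype=np.int8)
        in_chan = (z <= 0.0) & (z >= -self.channel_length)
        rw = self.channel_radius(z)
        ro = self.wall_outer_radius(z)
        wall = in_chan & (r >= rw) & (r <= ro)
        out[wall] = WALL
        if self.membrane is not None:
            mb = self.membrane
            zc = np.clip(z, -self.channel_length, 0.0)
            inner = self.wall_outer_radius(zc)
            inner = np.where(in_chan, inner, self.channel_radius(zc))
            memb = (z <= mb.z_top) & (z >= mb.z_bot) & (r >= inner) & ~wall
            out[memb] = MEMBRANE
        if protein is not None:
            zp, a = protein
            out[(r**2 + (z - zp) ** 2) <= a**2] = PROTEIN
        return out

    # -- serialization -----------------------------------------------------

    def to_yaml(self) -> str:
        d = {
            "name": self.name,
            "profile_nm": [[float(z), float(r)] for z, r in self.profile],
            "channel_length_nm": self.channel_length,
            "wall_thickness_nm": self.wall_thickness,
            "wall_material": self.wall_material,
            "wall_regions": [
                {"z_lo_nm": w.z_lo, "z_hi_nm": w.z_hi, "sigma_q_per_nm2": w.sigma,
                 "material": w.material}
                for w in self.wall_regions
            ],
            "membrane": None if self.membrane is None else {
                "center_z_nm": self.membrane.center_z,
                "thickness_nm": self.membrane.thickness,
                "sigma_q_per_nm2": self.membrane.sigma / 1.0,
                "material": self.membrane.material,
            },
            "reservoir": {
                "radius_nm": self.reservoir.radius,
                "height_above_nm": self.reservoir.height_above,
                "height_below_nm": self.reservoir.height_below,
            },
            "cross_section": self.cross_section,
            "nominal_width_nm": self.nominal_width,
            "metadata": self.metadata,
        }

        def _plain(obj):
            if isinstance(obj, dict):
                return {k: _plain(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [_plain(v) for v in obj]
            if isinstance(obj, np.generic):
                return obj.item()
            return obj

        return yaml.safe_dump(_plain(d), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "PoreSpec":
        d = yaml.safe_load(text)
        memb = d.get("membrane")
        return cls(
            name=d["name"],
            profile=tuple(tuple(p) for p in d["profile_nm"]),
            channel_length=d["channel_length_nm"],
            wall_thickness=d["wall_thickness_nm"],
            wall_material=d["wall_material"],
            wall_regions=tuple(
                WallRegion(w["z_lo_nm"], w["z_hi_nm"], w["sigma_q_per_nm2"], w["material"])
                for w in d.get("wall_regions", [])
            ),
            membrane=None if memb is None else Membrane(
                memb["center_z_nm"], memb["thickness_nm"], memb["sigma_q_per_nm2"],
                memb["material"],
            ),
            reservoir=Reservoir(
                d["reservoir"]["radius_nm"],
                d["reservoir"]["height_above_nm"],
                d["reservoir"]["height_below_nm"],
            ),
            cross_section=d.get("cross_section", "circular"),
            nominal_width=d.get("nominal_width_nm"),
            metadata=d.get("metadata", {}),
        )


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

_PRESET_OVERRIDES = {
    "width", "voltage_mV", "bulk_concentration_M", "cross_section",
    "reservoir_radius", "reservoir_height_above", "reservoir_height_below",
    "wall_sigma", "channel_length",
}


def _dna_origami(width: float = 6.0, cross_section: str = "square-equivalent",
                 wall_sigma: float = -0.74, channel_length: float = 46.0,
                 **res) -> PoreSpec:
    # Square w x w lumen mapped to the equal-area circle in the axisymmetric
    # reference mode; "circular" takes the width literally as a diameter.
    if cross_section == "square-equivalent":
        radius = width / np.sqrt(np.pi)
    elif cross_section == "circular":
        radius = width / 2.0
    else:
        raise ValueError(f"unknown cross_section {cross_section!r}")
    L = channel_length
    memb_th = 2.2
    return PoreSpec(
        name="dna_origami",
        profile=((0.0, radius), (-L, radius)),
        channel_length=L,
        wall_thickness=6.0,
        wall_material="dna",
        wall_regions=(WallRegion(-L, 0.0, wall_sigma, "dna"),),
        membrane=Membrane(center_z=-L + memb_th / 2.0, thickness=memb_th,
                          sigma=0.0, material="lipid"),
        reservoir=Reservoir(
            radius=res.get("reservoir_radius", 20.0 / np.sqrt(np.pi)),
            height_above=res.get("reservoir_height_above", 12.0),
            height_below=res.get("reservoir_height_below", 12.0),
        ),
        cross_section=cross_section,
        nominal_width=width,
        metadata={
            "voltage_mV": res.get("voltage_mV", -80.0),
            "bulk_concentration_M": res.get("bulk_concentration_M", 1.0),
            "protein_radius_nm": 2.078,
            "protein_charge_q": 5.0,
            "dt_ns": 0.2,
            "binding_radius_nm": 0.2,
        },
    )


def _solid_state(width: float = 20.0, **res) -> PoreSpec:
    # Conical channel through a 50 nm SiN membrane, SAM-coated; the tip
    # (smallest diameter, `width`) is the upper entry, the aperture opens at
    # 40 degrees (full angle) toward the lower entry where proteins start.
    L = 50.0
    tip_r = width / 2.0
    slope = np.tan(np.deg2rad(20.0))
    base_r = tip_r + L * slope
    sam_sigma = -0.078 / Q_PER_NM2  # -0.078 C/m^2 expressed in q/nm^2
    return PoreSpec(
        name="solid_state",
        profile=((0.0, tip_r), (-L, base_r)),
        channel_length=L,
        wall_thickness=None,
        wall_material="silicon_nitride",
        wall_regions=(WallRegion(-L, 0.0, sam_sigma, "sam"),),
        membrane=None,
        reservoir=Reservoir(
            radius=res.get("reservoir_radius", 120.0),
            height_above=res.get("reservoir_height_above", 95.0),
            height_below=res.get("reservoir_height_below", 95.0),
        ),
        cross_section="circular",
        nominal_width=width,
        metadata={
            "voltage_mV": res.get("voltage_mV", -200.0),
            "bulk_concentration_M": res.get("bulk_concentration_M", 1.0),
            "protein_radius_nm": 3.0,
            "protein_charge_q": -50.0,
            "dt_ns": 1.0,
            "binding_radius_nm": 5.75,
            "receptor_height_fraction": 0.95,
            "receptor_wall_distance_nm": 2.75,
            "k_a_solution_per_M_s": 1.5e5,
            "k_d_solution_per_s": 25e-3,
            "k_a_inferred_per_M_s": 5.2e6,
            "k_d_inferred_per_s": 4.5e-3,
            "bond_rupture_length_nm": 0.55,
            "sin_sigma_C_per_m2": -0.022,
        },
    )


def _alpha_hemolysin(**res) -> PoreSpec:
    # Parameterized axisymmetric stand-in profile built from the headline
    # numbers only (10 nm channel, radii spanning 0.5-2.8 nm, vestibule above
    # the membrane, constriction at the vestibule-barrel junction, ~1 nm
    # beta-barrel through the membrane centred at z = -7.6 nm).
    profile = (
        (0.0, 2.4), (-2.0, 2.8), (-4.4, 1.3), (-5.0, 0.5),
        (-5.6, 1.0), (-9.2, 1.0), (-10.0, 1.15),
    )
    return PoreSpec(
        name="alpha_hemolysin",
        profile=profile,
        channel_length=10.0,
        wall_thickness=2.0,
        wall_material="protein",
        wall_regions=(WallRegion(-10.0, 0.0, 0.0, "protein"),),
        membrane=Membrane(center_z=-7.6, thickness=2.2, sigma=0.0, material="lipid"),
        reservoir=Reservoir(
            radius=res.get("reservoir_radius", 10.0),
            height_above=res.get("reservoir_height_above", 6.0),
            height_below=res.get("reservoir_height_below", 6.0),
        ),
        cross_section="circular",
        nominal_width=None,
        metadata={
            "voltage_mV": res.get("voltage_mV", 40.0),
            "bulk_concentration_M": res.get("bulk_concentration_M", 1.0),
        },
    )


_PRESETS = {
    "dna_origami": _dna_origami,
    "solid_state": _solid_state,
    "alpha_hemolysin": _alpha_hemolysin,
}


def make_fixture(name: str, **kw) -> PoreSpec:
    """Small analytic geometries used by the validation suite.

    ``toy_cylinder``: straight bore of radius ``radius`` (default 5 nm) and
    length ``length`` (20 nm) through an uncharged thick wall, with an
    analytic Ohmic + access-resistance conductance oracle.
    ``plane_wall``: a flat solid floor at z = 0 under a wide open reservoir,
    for plane-wall hindered-diffusion validation (``radius``/``height`` of
    the fluid region, defaults 150/300 nm).
    ``open_box``: like plane_wall but intended for far-from-wall (bulk)
    hydrodynamics.
    """
    if name == "toy_cylinder":
        Rch = kw.get("radius", 5.0)
        L = kw.get("length", 20.0)
        return PoreSpec(
            name="toy_cylinder", profile=((0.0, Rch), (-L, Rch)),
            channel_length=L, wall_thickness=None,
            wall_material="silicon_nitride",
            wall_regions=(WallRegion(-L, 0.0, kw.get("wall_sigma", 0.0),
                                     "silicon_nitride"),),
            membrane=None,
            reservoir=Reservoir(radius=kw.get("reservoir_radius", 6 * Rch),
                                height_above=kw.get("reservoir_height", 5 * Rch),
                                height_below=kw.get("reservoir_height", 5 * Rch)),
        )
    if name == "harmonic_box":
        # closed cylindrical cavity (all boundaries reflecting); pair with a
        # harmonic restoring force to test Boltzmann-distribution sampling
        R = kw.get("radius", 10.0)
        L = kw.get("length", 20.0)
        return PoreSpec(
            name="harmonic_box", profile=((0.0, R), (-L, R)),
            channel_length=L, wall_thickness=None,
            wall_material="silicon_nitride", wall_regions=(), membrane=None,
            reservoir=Reservoir(radius=R, height_above=0.0, height_below=0.0),
        )
    if name in ("plane_wall", "open_box"):
        R = kw.get("radius", 150.0)
        H = kw.get("height", 300.0)
        return PoreSpec(
            name=name, profile=((0.0, 1e-3), (-1e-2, 1e-3)),
            channel_length=1e-2, wall_thickness=None,
            wall_material="silicon_nitride", wall_regions=(), membrane=None,
            reservoir=Reservoir(radius=R, height_above=H, height_below=0.0),
        )
    raise KeyError(f"unknown fixture {name!r}")


def build_preset(name: str, overrides: dict | None = None) -> PoreSpec:
    """Build one of the three built-in pores, optionally overriding declared
    parameters (width, voltage_mV, bulk_concentration_M, cross_section,
    reservoir dimensions, wall_sigma, channel_length)."""
    if name not in _PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(_PRESETS)}")
    overrides = dict(overrides or {})
    unknown = set(overrides) - _PRESET_OVERRIDES
    if unknown:
        raise KeyError(f"unknown preset override(s): {sorted(unknown)}")
    return _PRESETS[name](**overrides)


# ---------------------------------------------------------------------------
# wall distance
# ---------------------------------------------------------------------------

def _surface_segments(spec: PoreSpec, include_boundaries: bool = False) -> np.ndarray:
    """Polyline segments ((r1,z1),(r2,z2)) describing the solid surfaces in
    the (r, z) half-plane (nm).  Segments lying inside solids are harmless
    for distance queries from the fluid side."""
    segs: list[tuple[tuple[float, float], tuple[float, float]]] = []
    prof = list(spec.profile)
    for (z1, r1), (z2, r2) in zip(prof, prof[1:]):
        segs.append(((r1, z1), (r2, z2)))
    R_res = spec.reservoir.radius
    r_top = spec.channel_radius(0.0)
    r_bot = spec.channel_radius(-spec.channel_length)
    if spec.wall_thickness is None:
        segs.append(((r_top, 0.0), (R_res, 0.0)))
        segs.append(((r_bot, -spec.channel_length), (R_res, -spec.channel_length)))
    else:
        r_out = float(np.max([p[1] for p in spec.profile])) + spec.wall_thickness
        segs.append(((r_top, 0.0), (r_out, 0.0)))  # top cap annulus
        z_low = -spec.channel_length
        if spec.membrane is not None:
            z_low = spec.membrane.z_top
        segs.append(((r_out, 0.0), (r_out, z_low)))  # outer wall
        segs.append(((r_bot, -spec.channel_length),
                     (r_out, -spec.channel_length)))  # bottom cap annulus
    if spec.membrane is not None:
        mb = spec.membrane
        r_in_top = float(spec.wall_outer_radius(np.clip(mb.z_top, -spec.channel_length, 0.0)))
        r_in_bot = float(spec.wall_outer_radius(np.clip(mb.z_bot, -spec.channel_length, 0.0)))
        segs.append(((r_in_top, mb.z_top), (R_res, mb.z_top)))
        segs.append(((r_in_bot, mb.z_bot), (R_res, mb.z_bot)))
    if include_boundaries:
        zt, zb = spec.z_top, spec.z_bot
        segs.append(((R_res, zt), (R_res, zb)))
        segs.append(((0.0, zt), (R_res, zt)))
        segs.append(((0.0, zb), (R_res, zb)))
    return np.asarray(segs, dtype=float)  # (n, 2, 2) as ((r1,z1),(r2,z2))


def _point_segment_distance(pr, pz, segs):
    """Vectorized distance from points to each segment; returns (dist, nr, nz)
    of the minimum over segments."""
    pr = np.atleast_1d(np.asarray(pr, dtype=float))
    pz = np.atleast_1d(np.asarray(pz, dtype=float))
    a = segs[:, 0, :]  # (n, 2) r,z
    b = segs[:, 1, :]
    ab = b - a
    denom = np.maximum((ab**2).sum(axis=1), 1e-30)
    # points (m, 1, 2) minus a (n, 2)
    p = np.stack([pr, pz], axis=-1)[:, None, :]
    t = ((p - a[None]) * ab[None]).sum(axis=-1) / denom[None]
    t = np.clip(t, 0.0, 1.0)
    proj = a[None] + t[..., None] * ab[None]
    d2 = ((p - proj) ** 2).sum(axis=-1)
    idx = np.argmin(d2, axis=1)
    m = np.arange(len(pr))
    dmin = np.sqrt(d2[m, idx])
    nearest = proj[m, idx]
    vec = p[:, 0, :] - nearest
    norm = np.maximum(np.sqrt((vec**2).sum(axis=-1)), 1e-30)
    n = vec / norm[:, None]
    return dmin, n[:, 0], n[:, 1]


def wall_distance(spec: PoreSpec, points, protein: tuple[float, float] | None = None,
                  include_boundaries: bool = False):
    """Distance (nm) to the nearest solid surface and the outward unit normal.

    ``points`` is (r, z) or an array of shape (n, 2) in nm.  If ``protein``
    (center z on the axis, radius) is given, its sphere surface counts as a
    wall (used for position-dependent ion diffusivity around an explicit
    protein).  Returns (distance, normal_r, normal_z); scalars for a single
    point.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    segs = _surface_segments(spec, include_boundaries)
    d, nr, nz = _point_segment_distance(pts[:, 0], pts[:, 1], segs)
    if protein is not None:
        zp, a = protein
        dc = np.sqrt(pts[:, 0] ** 2 + (pts[:, 1] - zp) ** 2)
        dp = dc - a
        closer = dp < d
        with np.errstate(invalid="ignore"):
            pn_r = np.where(dc > 1e-30, pts[:, 0] / np.maximum(dc, 1e-30), 0.0)
            pn_z = np.where(dc > 1e-30, (pts[:, 1] - zp) / np.maximum(dc, 1e-30), 1.0)
        d = np.where(closer, dp, d)
        nr = np.where(closer, pn_r, nr)
        nz = np.where(closer, pn_z, nz)
    if np.asarray(points).ndim == 1:
        return float(d[0]), float(nr[0]), float(nz[0])
    return d, nr, nz


# ---------------------------------------------------------------------------
# meshing
# ---------------------------------------------------------------------------

def graded_edges(required: Sequence[float], anchors: Iterable[tuple],
                 coarse: float, growth: float = 0.3) -> np.ndarray:
    """1-D graded grid edges.

    ``required`` coordinates are guaranteed to be edges.  Anchors are either
    points (x_i, h_i) or bands (x_lo, x_hi, h_i): the local spacing is h_i at
    the anchor, growing linearly with slope ``growth`` away from it, capped
    at ``coarse``.
    """
    req = np.unique(np.asarray(required, dtype=float))
    anchors = list(anchors)

    def h_of(x):
        h = np.full_like(x, coarse)
        for anc in anchors:
            if len(anc) == 2:
                xi, hi = anc
                dist = np.abs(x - xi)
            else:
                x_lo, x_hi, hi = anc
                dist = np.maximum.reduce([x_lo - x, x - x_hi, np.zeros_like(x)])
            h = np.minimum(h, hi + growth * dist)
        return np.maximum(h, 1e-6)

    edges = [req[0]]
    for a, b in zip(req, req[1:]):
        xs = np.linspace(a, b, max(int((b - a) / 0.005), 64))
        dens = 1.0 / h_of(xs)
        s = np.concatenate([[0.0], np.cumsum((dens[1:] + dens[:-1]) / 2 * np.diff(xs))])
        n = max(int(np.ceil(s[-1])), 1)
        targets = np.linspace(0.0, s[-1], n + 1)[1:]
        edges.extend(np.interp(targets, s, xs).tolist())
        edges[-1] = b  # exact
    return np.asarray(edges)


@dataclass(frozen=True)
class MeshOptions:
    """Mesh sizing.  Defaults: 0.25 nm near walls/protein, 2 nm in the
    reservoir; ``edl`` refines the first ~1 nm off charged walls and
    ``protein`` the protein surface (defaults to ``fine`` when unset)."""

    fine: float = 0.25
    coarse: float = 2.0
    edl: float | None = None
    protein: float | None = None
    growth: float = 0.3


@dataclass
class Mesh:
    """Structured axisymmetric grid with cell region tags.

    ``region`` has shape (n_r, n_z); ``sigma_rface``/(n_r+1, n_z) and
    ``sigma_zface``/(n_r, n_z+1) carry surface charge (C/m^2) on fluid-solid
    faces.  Lengths in nm.
    """

    spec: PoreSpec
    protein: tuple[float, float] | None
    r_edges: np.ndarray
    z_edges: np.ndarray
    region: np.ndarray
    sigma_rface: np.ndarray
    sigma_zface: np.ndarray

    @property
    def r_centers(self) -> np.ndarray:
        return 0.5 * (self.r_edges[1:] + self.r_edges[:-1])

    @property
    def z_centers(self) -> np.ndarray:
        return 0.5 * (self.z_edges[1:] + self.z_edges[:-1])

    @property
    def shape(self) -> tuple[int, int]:
        return self.region.shape

    @property
    def fluid(self) -> np.ndarray:
        return self.region == FLUID

    def fluid_volume(self) -> float:
        """Total fluid volume in nm^3 (exact for the staircase mesh)."""
        re = self.r_edges
        ring = np.pi * (re[1:] ** 2 - re[:-1] ** 2)
        vol = ring[:, None] * np.diff(self.z_edges)[None, :]
        return float(vol[self.fluid].sum())

    def export_vtk(self, path: str) -> None:
        """Write the grid and region tags as legacy ASCII VTK (rectilinear)."""
        nr, nz = self.shape
        with open(path, "w") as f:
            f.write("# vtk DataFile Version 3.0\nporesim mesh\nASCII\n")
            f.write("DATASET RECTILINEAR_GRID\n")
            f.write(f"DIMENSIONS {nr + 1} {nz + 1} 1\n")
            f.write(f"X_COORDINATES {nr + 1} float\n")
            f.write(" ".join(f"{v:.6g}" for v in self.r_edges) + "\n")
            f.write(f"Y_COORDINATES {nz + 1} float\n")
            f.write(" ".join(f"{v:.6g}" for v in self.z_edges) + "\n")
            f.write("Z_COORDINATES 1 float\n0\n")
            f.write(f"CELL_DATA {nr * nz}\nSCALARS region int 1\nLOOKUP_TABLE default\n")
            f.write("\n".join(str(int(v)) for v in self.region.T.ravel()) + "\n")


def mesh(spec: PoreSpec, resolution: MeshOptions | float = MeshOptions(),
         protein: tuple[float, float] | None = None) -> Mesh:
    """Build a structured axisymmetric mesh for a pore.

    ``protein`` is (center z on the axis, radius) in nm; the protein is
    rejected if its sphere intersects walls or membrane.
    """
    if isinstance(resolution, (int, float)):
        resolution = MeshOptions(fine=float(resolution))
    opt = resolution
    if opt.fine <= 0 or opt.coarse <= 0:
        raise ValueError("mesh resolution must be positive")
    if protein is not None:
        zp, a = protein
        d, _, _ = wall_distance(spec, (0.0, zp))
        if d < a - 1e-9:
            raise ValueError(
                f"protein (z={zp}, a={a}) overlaps the solid region (wall distance {d:.3f} nm)")
    h_p = opt.protein if opt.protein is not None else opt.fine
    charged = any(abs(w.sigma) > 0 for w in spec.wall_regions)
    h_edl = opt.edl if opt.edl is not None else (opt.fine if not charged else opt.fine)

    # radial edges: axis, channel radii breakpoints, wall outer radius, reservoir
    radii = sorted({p[1] for p in spec.profile})
    req_r = [0.0, spec.reservoir.radius]
    anchors_r: list[tuple[float, float]] = []
    for rr in radii:
        req_r.append(rr)
        anchors_r.append((rr, h_edl))
    if spec.wall_thickness is not None:
        r_out = max(radii) + spec.wall_thickness
        if r_out < spec.reservoir.radius:
            req_r.append(r_out)
            anchors_r.append((r_out, opt.fine))
    if len(radii) > 1:  # tapered bore: keep the whole channel radial band fine
        anchors_r.append((min(radii), max(radii), opt.fine))
    if protein is not None:
        a_p = protein[1]
        anchors_r.append((0.0, a_p + 2 * h_p, h_p))
        # align an edge with the equator so the staircase sphere has the
        # exact radial extent
        if a_p < spec.reservoir.radius:
            req_r.append(a_p)
    r_edges = graded_edges(req_r, anchors_r, opt.coarse, opt.growth)

    # axial edges
    req_z = [spec.z_bot, -spec.channel_length, 0.0, spec.z_top]
    anchors_z: list[tuple[float, float]] = [(0.0, opt.fine), (-spec.channel_length, opt.fine)]
    for z, _r in spec.profile:
        anchors_z.append((z, opt.fine))
    if spec.membrane is not None:
        req_z += [spec.membrane.z_top, spec.membrane.z_bot]
        anchors_z.append((spec.membrane.z_top, opt.fine))
        anchors_z.append((spec.membrane.z_bot, opt.fine))
    in_channel_h = max(opt.fine, min(opt.coarse, 1.0))
    anchors_z.append((-spec.channel_length / 2, in_channel_h))
    if protein is not None:
        zp, a = protein
        anchors_z.append((zp - a - 2 * h_p, zp + a + 2 * h_p, h_p))
        req_z += [zp - a, zp + a]  # pole-aligned edges
    z_edges = graded_edges(req_z, anchors_z, opt.coarse, opt.growth)

    rc = 0.5 * (r_edges[1:] + r_edges[:-1])
    zc = 0.5 * (z_edges[1:] + z_edges[:-1])
    R, Z = np.meshgrid(rc, zc, indexing="ij")
    region = spec.solid_at(R, Z, protein)

    nr, nz = region.shape
    sigma_rface = np.zeros((nr + 1, nz))
    sigma_zface = np.zeros((nr, nz + 1))
    memb_sigma = 0.0 if spec.membrane is None else spec.membrane.sigma * Q_PER_NM2

    fluid = region == FLUID
    # r-faces between fluid and solid
    left, right = region[:-1, :], region[1:, :]
    zq = zc[None, :]
    face_sig = np.zeros((nr - 1, nz))
    wall_pair = ((left == FLUID) & (right == WALL)) | ((left == WALL) & (right == FLUID))
    memb_pair = ((left == FLUID) & (right == MEMBRANE)) | ((left == MEMBRANE) & (right == FLUID))
    sig_w = np.broadcast_to(spec.wall_sigma(np.clip(zc, -spec.channel_length, 0.0))[None, :],
                            face_sig.shape)
    face_sig = np.where(wall_pair, sig_w, face_sig)
    face_sig = np.where(memb_pair, memb_sigma, face_sig)
    sigma_rface[1:-1, :] = face_sig
    # z-faces
    lo, hi = region[:, :-1], region[:, 1:]
    face_sig = np.zeros((nr, nz - 1))
    wall_pair = ((lo == FLUID) & (hi == WALL)) | ((lo == WALL) & (hi == FLUID))
    memb_pair = ((lo == FLUID) & (hi == MEMBRANE)) | ((lo == MEMBRANE) & (hi == FLUID))
    zf = z_edges[1:-1]
    sig_w = np.broadcast_to(spec.wall_sigma(np.clip(zf, -spec.channel_length, 0.0))[None, :],
                            face_sig.shape)
    face_sig = np.where(wall_pair, sig_w, face_sig)
    face_sig = np.where(memb_pair, memb_sigma, face_sig)
    sigma_zface[:, 1:-1] = face_sig

    return Mesh(spec=spec, protein=protein, r_edges=r_edges, z_edges=z_edges,
                region=region, sigma_rface=sigma_rface, sigma_zface=sigma_zface)
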