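"""Source and phantom geometry: nested cylinders and ray tracing.

The GammaMed Plus style source is modelled as three coaxial right
cylinders: the active iridium core, the 316L steel capsule envelope (with
a flat distal tip), and the 304 steel drive cable on the proximal side.
The coordinate frame has its origin at the geometric centre of the core,
the +z axis pointing to the distal capsule tip (polar angle theta = 0) and
the cable occupying theta near 180 deg.

Only the core length and diameter, the capsule diameter and the cable
length/diameter are published in running text; the tip and proximal
thicknesses are drawing-derived defaults and can be overridden in the
model constructor.

Boundary convention: points on a region boundary belong to the inner
region (core over capsule over cable over phantom medium); intervals along
rays are half-open accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SourceModel", "Phantom", "PathSegments",
           "sample_core_position", "trace_path", "locate_material",
           "R0_CM", "THETA0_DEG", "GeometryError"]

#: TG-43 reference point: 1 cm on the transverse plane.
R0_CM = 1.0
THETA0_DEG = 90.0

_EPS = 1e-12


class GeometryError(ValueError):
    pass


@dataclass(frozen=True)
class SourceModel:
    """Nested-cylinder model of the encapsulated source.

    All lengths in cm.  Defaults: 0.6 mm diameter x 3.5 mm long Ir core in
    a 0.9 mm diameter 316L capsule with a 0.62 mm flat distal tip and a
    0.65 mm proximal wall, attached to a 6 cm long, 0.9 mm diameter 304
    steel cable.
    """

    core_radius: float = 0.03
    core_length: float = 0.35
    capsule_radius: float = 0.045
    tip_thickness: float = 0.062
    proximal_thickness: float = 0.065
    cable_radius: float = 0.045
    cable_length: float = 6.0
    core_material: str = "iridium"
    capsule_material: str = "steel316l"
    cable_material: str = "steel304"

    def __post_init__(self):
        if not (0 < self.core_radius < self.capsule_radius):
            raise GeometryError("need 0 < core radius < capsule radius")
        if self.core_length <= 0 or self.cable_length <= 0:
            raise GeometryError("lengths must be positive")
        if self.tip_thickness < 0 or self.proximal_thickness < 0:
            raise GeometryError("capsule thicknesses must be >= 0")
        if self.cable_radius > self.capsule_radius + _EPS:
            raise GeometryError("cable radius must not exceed capsule radius")

    @property
    def half_length(self):
        return 0.5 * self.core_length

    @property
    def z_cap_max(self):
        """Distal end of the capsule (outer tip surface)."""
        return self.half_length + self.tip_thickness

    @property
    def z_cap_min(self):
        """Proximal end of the capsule / start of the cable."""
        return -(self.half_length + self.proximal_thickness)

    @property
    def z_cable_min(self):
        return self.z_cap_min - self.cable_length


@dataclass(frozen=True)
class Phantom:
    """The surrounding medium: a cube or sphere of one material.

    kinds: ``water_cube`` (side ``size``), ``air_sphere`` / ``vacuum``
    (radius ``size``).
    """

    kind: str = "water_cube"
    size: float = 80.0
    material: str = "water"

    def __post_init__(self):
        if self.kind not in ("water_cube", "air_sphere", "vacuum"):
            raise GeometryError(f"unknown phantom kind {self.kind!r}")
        if self.size <= 0:
            raise GeometryError("phantom size must be positive")

    @property
    def medium(self):
        if self.kind == "vacuum":
            return "vacuum"
        return self.material

    def boundary_distance(self, origin, direction):
        """Distance along the ray to the phantom boundary (vectorized)."""
        p = np.atleast_2d(origin)
        d = np.atleast_2d(direction)
        if self.kind == "water_cube":
            half = 0.5 * self.size
            with np.errstate(divide="ignore", invalid="ignore"):
                t_hi = (half - p) / d
                t_lo = (-half - p) / d
            t = np.where(d > 0, t_hi, np.where(d < 0, t_lo, np.inf))
            out = np.min(t, axis=1)
        else:
            # sphere of radius size centred at origin
            b = np.einsum("ij,ij->i", p, d)
            c = np.einsum("ij,ij->i", p, p) - self.size**2
            disc = np.maximum(b * b - c, 0.0)
            out = -b + np.sqrt(disc)
        out = np.maximum(out, 0.0)
        return out if np.ndim(origin) == 2 else float(out[0])


@dataclass(frozen=True)
class PathSegments:
    """Ordered (material, length) segments along a ray."""

    segments: tuple  # of (material, length_cm)

    @property
    def total_length(self):
        return float(sum(s[1] for s in self.segments))

    def length_in(self, material):
        return float(sum(s[1] for s in self.segments if s[0] == material))


def sample_core_position(rng, model=None, n=None):
    """Uniform points inside the active core cylinder.

    Inverse-CDF in (rho^2, phi, z).  Returns shape (3,) for ``n=None``,
    else (n, 3).
    """
    model = model or SourceModel()
    m = 1 if n is None else int(n)
    rho = model.core_radius * np.sqrt(rng.random(m))
    phi = 2.0 * np.pi * rng.random(m)
    z = model.half_length * (2.0 * rng.random(m) - 1.0)
    pts = np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])
    return pts[0] if n is None else pts


# ---------------------------------------------------------------------------
# Ray/region intersections (vectorized kernels shared with the transport
# engine).  Each region is a convex finite cylinder -> one interval per ray.
# ---------------------------------------------------------------------------
def _cylinder_interval(p, d, radius, z_min, z_max):
    """Entry/exit distances (t0, t1) of rays with a finite z-cylinder.

    Arrays p, d of shape (n, 3); returns (t0, t1) with t0 >= 0 clipping at
    the ray start; empty intersections give t0 > t1.
    """
    px, py, pz = p[:, 0], p[:, 1], p[:, 2]
    dx, dy, dz = d[:, 0], d[:, 1], d[:, 2]
    a = dx * dx + dy * dy
    b = px * dx + py * dy
    c = px * px + py * py - radius * radius
    t_in = np.full(len(p), np.inf)
    t_out = np.full(len(p), -np.inf)
    with np.errstate(divide="ignore", invalid="ignore"):
        disc = b * b - a * c
        hit = (a > _EPS) & (disc > 0.0)
        sq = np.sqrt(np.where(hit, disc, 0.0))
        r0 = np.where(hit, (-b - sq) / np.where(a > _EPS, a, 1.0), np.inf)
        r1 = np.where(hit, (-b + sq) / np.where(a > _EPS, a, 1.0), -np.inf)
        # rays parallel to the axis: inside or outside for all t
        par_in = (a <= _EPS) & (c <= 0.0)
        r0 = np.where(par_in, -np.inf, r0)
        r1 = np.where(par_in, np.inf, r1)
        # z-slab interval
        z0 = np.where(dz > _EPS, (z_min - pz) / np.where(np.abs(dz) > _EPS, dz, 1.0),
                      np.where(dz < -_EPS, (z_max - pz) / np.where(np.abs(dz) > _EPS, dz, 1.0),
                               np.where((pz >= z_min) & (pz <= z_max), -np.inf, np.inf)))
        z1 = np.where(dz > _EPS, (z_max - pz) / np.where(np.abs(dz) > _EPS, dz, 1.0),
                      np.where(dz < -_EPS, (z_min - pz) / np.where(np.abs(dz) > _EPS, dz, 1.0),
                               np.where((pz >= z_min) & (pz <= z_max), np.inf, -np.inf)))
    t_in = np.maximum(r0, z0)
    t_out = np.minimum(r1, z1)
    return np.maximum(t_in, 0.0), t_out


def region_intervals(p, d, model):
    """Per-ray [t0, t1] intervals for core, capsule envelope and cable.

    The 'envelope' is the union cylinder (capsule + cable z-span) at the
    capsule radius; the capsule metal is envelope minus core minus cable.
    Returns dict of (t0, t1) arrays.
    """
    hl = model.half_length
    core = _cylinder_interval(p, d, model.core_radius, -hl, hl)
    env = _cylinder_interval(p, d, model.capsule_radius,
                             model.z_cable_min, model.z_cap_max)
    cable = _cylinder_interval(p, d, model.cable_radius,
                               model.z_cable_min, model.z_cap_min)
    return {"core": core, "envelope": env, "cable": cable}


def _locate_many(pts, model, phantom):
    """Region name per point, vectorized; boundary points -> inner region."""
    x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
    rho2 = x * x + y * y
    out = np.full(len(pts), phantom.medium, dtype=object)
    hl = model.half_length
    in_core = (rho2 <= model.core_radius**2 + _EPS) & (np.abs(z) <= hl + _EPS)
    in_env = (rho2 <= model.capsule_radius**2 + _EPS) & \
             (z >= model.z_cable_min - _EPS) & (z <= model.z_cap_max + _EPS)
    in_cable = in_env & (z < model.z_cap_min - _EPS) & \
               (rho2 <= model.cable_radius**2 + _EPS)
    out[in_env] = model.capsule_material
    out[in_cable] = model.cable_material
    out[in_core] = model.core_material
    return out


def locate_material(point, model=None, phantom=None):
    """Material name at a point (inner region wins on boundaries)."""
    model = model or SourceModel()
    phantom = phantom or Phantom()
    return str(_locate_many(np.atleast_2d(np.asarray(point, float)),
                            model, phantom)[0])


def trace_path(origin, direction, model=None, phantom=None, t_max=None):
    """Ordered material segments along a ray.

    Traces from ``origin`` along unit vector ``direction`` to the phantom
    boundary (or ``t_max`` if given).  Exact cylinder/plane intersections;
    adjacent same-material segments are merged.
    """
    model = model or SourceModel()
    phantom = phantom or Phantom()
    p = np.atleast_2d(np.asarray(origin, dtype=float))
    d = np.atleast_2d(np.asarray(direction, dtype=float))
    norm = np.linalg.norm(d[0])
    if norm < 1e-9:
        raise GeometryError("degenerate (zero) direction vector")
    if abs(norm - 1.0) > 1e-9:
        raise GeometryError("direction must be a unit vector")
    t_end = phantom.boundary_distance(p, d)[0] if t_max is None else float(t_max)
    iv = region_intervals(p, d, model)
    cuts = [0.0, t_end]
    for t0, t1 in iv.values():
        for t in (float(t0[0]), float(t1[0])):
            if 0.0 < t < t_end and np.isfinite(t):
                cuts.append(t)
    # capsule/cable plane inside the envelope
    if abs(d[0, 2]) > _EPS:
        t = (model.z_cap_min - p[0, 2]) / d[0, 2]
        if 0.0 < t < t_end:
            cuts.append(float(t))
    cuts = np.unique(np.array(cuts))
    mids = p + np.outer(0.5 * (cuts[:-1] + cuts[1:]), d[0])
    mats = _locate_many(mids, model, phantom)
    segs = []
    for mat, ln in zip(mats, np.diff(cuts)):
        if ln <= _EPS:
            continue
        if segs and segs[-1][0] == mat:
            segs[-1] = (mat, segs[-1][1] + float(ln))
        else:
            segs.append((str(mat), float(ln)))
    return PathSegments(segments=tuple(segs))
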