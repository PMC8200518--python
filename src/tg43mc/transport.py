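"""Analog Monte Carlo photon transport with track-length tallies.

The engine transports photons emitted from the encapsulated source through
the phantom, alternating sampled free flights (piecewise-exponential
across the heterogeneous material segments returned by the ray tracer)
with sampled interactions:

* photoelectric absorption terminates the history;
* incoherent scattering samples the free-electron Klein-Nishina angular
  distribution by rejection, with the Compton energy shift;
* coherent scattering (optional) redirects the photon with the Thomson
  angular distribution at unchanged energy.

Fluence is scored with a track-length estimator on ring (annular) voxels
bounded by spheres and cones around the source centre -- the azimuthal
symmetry of the problem makes one ring equivalent to the conventional
Cartesian voxel it contains, at orders of magnitude lower variance.  Dose
in water is the collision-kerma fold of the track-length fluence with the
water mass energy-absorption coefficient (valid beyond 2 mm from the
capsule where charged-particle equilibrium holds).

For air-kerma runs, the photon fluence in the 10 x 10 x 0.05 cm^3 region
at 1 m on the transverse plane is estimated three ways: an analog
track-length box tally, a next-event (expected-value) estimate of the
uncollided fluence from every emission point, and a point-detector
next-event estimate of the collided fluence from every interaction.

Everything is vectorized over photons; a run is reproducible bit for bit
from its root seed (per-batch and per-chunk generators are derived with
numpy's SeedSequence spawning).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .attenuation import load_attenuation
from .elements import kn_total_cross_section
from .geometry import (Phantom, SourceModel, region_intervals,
                       sample_core_position)
from .materials import STANDARD_MATERIALS
from .spectra import load_spectrum, sample_emission_energy
from .tg43 import FluenceSpectrum
from .verify import kn_differential

__all__ = ["RunConfig", "PhysicsData", "TallyGrid", "AirTally",
           "RunResult", "run_histories", "sample_free_flight",
           "sample_interaction_type", "sample_compton",
           "sample_rayleigh_angle", "score_track_length",
           "next_event_air_estimate", "estimate_uncertainty",
           "ConfigError"]

ELECTRON_REST_MEV = 0.51099895
ENERGY_BIN_MEV = 0.005
N_ENERGY_BINS = 300  # covers (0, 1.5] MeV in 5 keV bins
AIR_TALLY_CENTRE = np.array([100.0, 0.0, 0.0])
AIR_TALLY_HALF = np.array([0.025, 5.0, 5.0])  # 0.05 x 10 x 10 cm^3
_EPS = 1e-12


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class RunConfig:
    """Transport run configuration.

    ``histories`` is per batch; ``batches`` independent repeats provide
    the statistical uncertainty (>= 2 unless histories == 0).
    """

    histories: int
    batches: int = 10
    seed: int = 1
    phantom_kind: str = "water_cube"   # water_cube | air_sphere | vacuum
    phantom_size: float = 80.0         # cube side or sphere radius, cm
    spectrum: object = "NNDC"          # label or ("mono", E_MeV)
    source_type: str = "volumetric"    # volumetric | point (bare)
    cutoff_mev: float = 0.010
    r_edges_cm: np.ndarray = None
    theta_edges_deg: np.ndarray = None
    air_tally: bool = False
    coherent_enabled: bool = True
    chunk_size: int = 250_000

    def __post_init__(self):
        if self.histories < 0:
            raise ConfigError("histories must be >= 0")
        if self.batches < 1 or (self.histories > 0 and self.batches < 2):
            raise ConfigError("need >= 2 batches for uncertainty estimation")
        if self.cutoff_mev < 0.010:
            raise ConfigError("energy cutoff below the 10 keV threshold")
        if self.phantom_kind not in ("water_cube", "air_sphere", "vacuum"):
            raise ConfigError(f"invalid phantom {self.phantom_kind!r}")
        if self.source_type not in ("volumetric", "point"):
            raise ConfigError(f"invalid source type {self.source_type!r}")

    def make_phantom(self):
        if self.phantom_kind == "water_cube":
            return Phantom("water_cube", self.phantom_size, "water")
        if self.phantom_kind == "air_sphere":
            return Phantom("air_sphere", self.phantom_size, "air")
        return Phantom("vacuum", self.phantom_size, "vacuum")


_HBARC_MEV_CM = 1.973269804e-11


class PhysicsData:
    """Pre-multiplied linear attenuation tables for fast vector lookup,
    plus per-material coherent-scattering form-factor samplers.

    ``rayleigh_model``: ``"form_factor"`` (default; samples the Thomson
    law modulated by the squared Thomas-Fermi form factor, matching the
    tabulated coherent cross sections) or ``"thomson"`` (bare Thomson
    angles, the simplest documented approximation).
    """

    def __init__(self, coherent_enabled=True, rayleigh_model="form_factor"):
        if rayleigh_model not in ("form_factor", "thomson"):
            raise ValueError(f"unknown rayleigh model {rayleigh_model!r}")
        self.coherent_enabled = coherent_enabled
        self.rayleigh_model = rayleigh_model
        self._tab = {}
        self._log = {}
        self._ff = {}
        for name in ("iridium", "steel316l", "steel304", "water", "air"):
            tab = load_attenuation(name)
            rho = STANDARD_MATERIALS[name].density
            total = tab.mu["total"]
            if not coherent_enabled:
                total = total - tab.mu["coherent"]
            self._tab[name] = tab
            self._log[name] = {
                "loge": np.log(tab.energy_mev),
                "total": np.log(total * rho),
                "photoelectric": np.log(tab.mu["photoelectric"] * rho),
                "incoherent": np.log(tab.mu["incoherent"] * rho),
                "coherent": np.log(tab.mu["coherent"] * rho),
            }
            self._ff[name] = self._build_ff_cdf(name)
        self._water_muen = self._tab["water"]
        self._air_muen = self._tab["air"]

    @staticmethod
    def _build_ff_cdf(name):
        """Cumulative integral of the squared atomic form factor over q^2
        (atoms-per-gram weighted mixture), for coherent angle sampling."""
        from .elements import ELEMENTS, _form_factor
        mat = STANDARD_MATERIALS[name]
        q2 = np.concatenate([[0.0], np.geomspace(1e14, 4e21, 384)])
        q = np.sqrt(q2)
        f2 = np.zeros_like(q)
        for sym, pct in mat.fractions.items():
            z, a = ELEMENTS[sym]
            n_per_g = pct / 100.0 / a
            f2 = f2 + n_per_g * _form_factor(q, z) ** 2
        cdf = np.concatenate([[0.0], np.cumsum(
            0.5 * (f2[1:] + f2[:-1]) * np.diff(q2))])
        return {"q2": q2, "cdf": cdf}

    def sample_rayleigh_ff(self, name, energy, rng):
        """Coherent scattering cosines from the form-factor-modulated
        Thomson distribution for the given material (vectorized)."""
        data = self._ff[name]
        e = np.atleast_1d(np.asarray(energy, float))
        k = e / _HBARC_MEV_CM
        q2max = 4.0 * k * k
        amax = np.interp(q2max, data["q2"], data["cdf"])
        mu = np.empty(len(e))
        todo = np.ones(len(e), dtype=bool)
        while todo.any():
            n = int(todo.sum())
            u = rng.random(n) * amax[todo]
            q2 = np.interp(u, data["cdf"], data["q2"])
            prop = 1.0 - q2 / (2.0 * k[todo] * k[todo])
            prop = np.clip(prop, -1.0, 1.0)
            acc = rng.random(n) <= 0.5 * (1.0 + prop * prop)
            idx = np.flatnonzero(todo)[acc]
            mu[idx] = prop[acc]
            todo[idx] = False
        return mu

    def rayleigh_pdf_sr(self, name, energy, cos_d):
        """Per-steradian probability density of coherent scattering into
        the direction with cosine ``cos_d``, for the chosen angular
        model."""
        e = np.asarray(energy, float)
        mu = np.asarray(cos_d, float)
        if self.rayleigh_model == "thomson":
            return 3.0 / (16.0 * np.pi) * (1.0 + mu * mu)
        from .elements import CLASSICAL_ELECTRON_RADIUS_CM
        k = e / _HBARC_MEV_CM
        q = k * np.sqrt(np.clip(2.0 * (1.0 - mu), 0.0, None))
        sigma_mass = np.exp(np.interp(
            np.log(np.clip(e, 0.010, 1.5)), self._log[name]["loge"],
            self._log[name]["coherent"])) / STANDARD_MATERIALS[name].density
        re2 = CLASSICAL_ELECTRON_RADIUS_CM ** 2
        return 0.5 * re2 * (1.0 + mu * mu) * self._f2_mix(name, q) \
            / sigma_mass

    def _f2_mix(self, name, q):
        """Atoms-per-gram weighted squared form factor, 1/g."""
        from .elements import AVOGADRO, ELEMENTS, _form_factor
        mat = STANDARD_MATERIALS[name]
        out = np.zeros_like(np.asarray(q, float))
        for sym, pct in mat.fractions.items():
            z, a = ELEMENTS[sym]
            out = out + (AVOGADRO * pct / 100.0 / a) \
                * _form_factor(q, z) ** 2
        return out

    def table(self, name):
        return self._tab[name]

    def mu_linear(self, name, energy, process="total"):
        """Linear attenuation coefficient (1/cm), vectorized."""
        if name == "vacuum":
            return np.zeros_like(np.asarray(energy, float))
        d = self._log[name]
        e = np.clip(np.asarray(energy, float), 0.010, 1.5)
        return np.exp(np.interp(np.log(e), d["loge"], d[process]))

    def mu_en_water(self, energy):
        return self._water_muen.mu_en_at(np.clip(energy, 0.010, 1.5))

    def mu_en_air(self, energy):
        return self._air_muen.mu_en_at(np.clip(energy, 0.010, 1.5))


# ---------------------------------------------------------------------------
# Tallies
# ---------------------------------------------------------------------------
def ring_volumes(r_edges, theta_edges_deg):
    """Exact shell-integral volumes of the (r, theta) ring voxels:
    (2 pi / 3)(r1^3 - r0^3)(cos t0 - cos t1), shape (n_r, n_theta)."""
    r = np.asarray(r_edges, float)
    ct = np.cos(np.radians(np.asarray(theta_edges_deg, float)))
    dr3 = (r[1:] ** 3 - r[:-1] ** 3)[:, None]
    dct = (ct[:-1] - ct[1:])[None, :]
    return (2.0 * np.pi / 3.0) * dr3 * dct


@dataclass
class TallyGrid:
    """Track-length fluence and kerma accumulators on ring voxels."""

    r_edges_cm: np.ndarray
    theta_edges_deg: np.ndarray
    n_batches: int

    def __post_init__(self):
        nr = len(self.r_edges_cm) - 1
        nt = len(self.theta_edges_deg) - 1
        self.volumes = ring_volumes(self.r_edges_cm, self.theta_edges_deg)
        # kerma-fold accumulator per batch and azimuthal half (MeV/g units)
        self.dose = np.zeros((self.n_batches, nr, nt, 2))
        # energy-binned track length, summed over batches
        self.track_length = np.zeros((nr, nt, N_ENERGY_BINS))

    @property
    def shape(self):
        return self.volumes.shape


@dataclass
class AirTally:
    """Fluence estimators for the 10 x 10 x 0.05 cm^3 region at 1 m."""

    n_batches: int

    def __post_init__(self):
        nb = self.n_batches
        self.analog_spectrum = np.zeros(N_ENERGY_BINS)  # track length, cm
        self.analog_kerma = np.zeros(nb)                # MeV/g fold
        self.ne_uncollided_spectrum = np.zeros(N_ENERGY_BINS)  # cm^-2
        self.ne_collided_spectrum = np.zeros(N_ENERGY_BINS)
        self.ne_kerma = np.zeros(nb)                    # MeV/g fold, u + c
        self.ne_uncollided_kerma = np.zeros(nb)

    @property
    def volume(self):
        return float(np.prod(2.0 * AIR_TALLY_HALF))


@dataclass
class RunResult:
    config: RunConfig
    histories_per_batch: int
    grid: TallyGrid = None
    air: AirTally = None
    interactions: int = 0
    escapes: int = 0

    def fluence_spectrum(self, kind="ne"):
        """Air-region fluence per initial photon, 5 keV bins."""
        n = self.histories_per_batch * self.config.batches
        mid = (np.arange(N_ENERGY_BINS) + 0.5) * ENERGY_BIN_MEV
        if kind == "analog":
            phi = self.air.analog_spectrum / self.air.volume / max(n, 1)
        elif kind == "ne":
            phi = (self.air.ne_uncollided_spectrum
                   + self.air.ne_collided_spectrum) / max(n, 1)
        elif kind == "ne_uncollided":
            phi = self.air.ne_uncollided_spectrum / max(n, 1)
        else:
            raise ValueError(kind)
        return FluenceSpectrum(energy_mid_mev=mid, fluence=phi)


# ---------------------------------------------------------------------------
# Elementary sampling operations
# ---------------------------------------------------------------------------
def sample_free_flight(tau, seg_lengths, seg_mu):
    """Invert the piecewise-exponential flight law.

    ``tau``: sampled optical depths, shape (n,); ``seg_lengths`` and
    ``seg_mu``: (n, k) per-segment lengths and linear attenuation
    coefficients.  Returns (distance, segment_index, escaped): photons
    whose optical depth exceeds the path total escape at the path end.
    """
    depths = seg_lengths * seg_mu
    cum = np.cumsum(depths, axis=1)
    total = cum[:, -1]
    escaped = tau >= total - _EPS
    k = np.argmax(cum >= tau[:, None], axis=1)
    prev = np.where(k > 0, np.take_along_axis(cum, np.maximum(k - 1, 0)[:, None],
                                              axis=1)[:, 0], 0.0)
    start = np.cumsum(seg_lengths, axis=1) - seg_lengths
    mu_k = np.take_along_axis(seg_mu, k[:, None], axis=1)[:, 0]
    t_k = np.take_along_axis(start, k[:, None], axis=1)[:, 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        dist = t_k + (tau - prev) / np.where(mu_k > 0, mu_k, np.inf)
    dist = np.where(escaped, np.sum(seg_lengths, axis=1), dist)
    return dist, k, escaped


def sample_interaction_type(physics, material_names, energy, u):
    """Choose photoelectric / incoherent / coherent with probability
    mu_process/mu_total per photon.  Returns an int array: 0 pe, 1 inc,
    2 coh."""
    e = np.asarray(energy, float)
    out = np.zeros(len(e), dtype=np.int8)
    for name in np.unique(material_names):
        m = material_names == name
        if name == "vacuum":
            continue
        pe = physics.mu_linear(name, e[m], "photoelectric")
        inc = physics.mu_linear(name, e[m], "incoherent")
        coh = physics.mu_linear(name, e[m], "coherent") \
            if physics.coherent_enabled else np.zeros_like(pe)
        tot = pe + inc + coh
        um = u[m] * tot
        out[m] = np.where(um < pe, 0, np.where(um < pe + inc, 1, 2))
    return out


def sample_compton(energy, rng):
    """Sample the Klein-Nishina distribution by rejection.

    Returns (scattered energy MeV, scattering cosine).  The scattered
    energy obeys E' = E / (1 + (E/m)(1 - cos)).
    """
    e = np.atleast_1d(np.asarray(energy, float))
    a = e / ELECTRON_REST_MEV
    mu = np.empty_like(e)
    todo = np.ones(len(e), dtype=bool)
    while todo.any():
        n = int(todo.sum())
        prop = 2.0 * rng.random(n) - 1.0
        t = 1.0 / (1.0 + a[todo] * (1.0 - prop))
        f = t * t * (t + 1.0 / t - (1.0 - prop * prop))
        acc = rng.random(n) * 2.0 <= f
        idx = np.flatnonzero(todo)[acc]
        mu[idx] = prop[acc]
        todo[idx] = False
    eprime = e / (1.0 + a * (1.0 - mu))
    if np.ndim(energy) == 0:
        return float(eprime[0]), float(mu[0])
    return eprime, mu


def sample_rayleigh_angle(n_or_energy, rng):
    """Thomson-distribution scattering cosine(s), energy unchanged.

    Accepts a count or an energy array (only its length is used: the
    Thomson angular law is energy-independent).
    """
    n = int(n_or_energy) if np.ndim(n_or_energy) == 0 else len(n_or_energy)
    mu = np.empty(n)
    todo = np.ones(n, dtype=bool)
    while todo.any():
        m = int(todo.sum())
        prop = 2.0 * rng.random(m) - 1.0
        acc = rng.random(m) * 2.0 <= 1.0 + prop * prop
        idx = np.flatnonzero(todo)[acc]
        mu[idx] = prop[acc]
        todo[idx] = False
    return mu if n > 1 else float(mu[0])


def rotate_direction(d, cos_theta, phi):
    """Rotate unit vectors ``d`` by polar angle arccos(cos_theta) about
    themselves with azimuth ``phi``; vectorized, renormalised."""
    u, v, w = d[:, 0], d[:, 1], d[:, 2]
    sin_t = np.sqrt(np.clip(1.0 - cos_theta**2, 0.0, None))
    sq = np.sqrt(np.clip(1.0 - w * w, 0.0, None))
    cp, sp = np.cos(phi), np.sin(phi)
    safe = sq > 1e-10
    sq_ = np.where(safe, sq, 1.0)
    nu = np.where(safe, u * cos_theta + sin_t * (u * w * cp - v * sp) / sq_,
                  sin_t * cp)
    nv = np.where(safe, v * cos_theta + sin_t * (v * w * cp + u * sp) / sq_,
                  sin_t * sp)
    nw = np.where(safe, w * cos_theta - sin_t * sq * cp,
                  np.sign(w) * cos_theta)
    out = np.column_stack([nu, nv, nw])
    out /= np.linalg.norm(out, axis=1, keepdims=True)
    return out


# ---------------------------------------------------------------------------
# Ring-voxel track-length scoring
# ---------------------------------------------------------------------------
try:  # optional acceleration; the numpy path below is the reference
    from numba import njit as _njit
    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is normally present
    _HAVE_NUMBA = False

    def _njit(*a, **k):
        def deco(f):
            return f
        return deco


@_njit(cache=True)
def _score_kernel(p, d, s, b, c0, fold, wgt, iE, r_edges, cth,
                  track_length, dose):  # pragma: no cover - jitted
    nr = len(r_edges) - 1
    ncone = len(cth)
    nt = ncone + 1
    buf = np.empty(2 * (len(r_edges) + ncone) + 2)
    for i in range(len(p)):
        si = s[i]
        bi = b[i]
        ci = c0[i]
        n = 0
        buf[n] = 0.0
        n += 1
        buf[n] = si
        n += 1
        for k in range(len(r_edges)):
            disc = bi * bi - (ci - r_edges[k] * r_edges[k])
            if disc > 0.0:
                sq = np.sqrt(disc)
                t = -bi - sq
                if 0.0 < t < si:
                    buf[n] = t
                    n += 1
                t = -bi + sq
                if 0.0 < t < si:
                    buf[n] = t
                    n += 1
        pz = p[i, 2]
        dz = d[i, 2]
        for k in range(ncone):
            c = cth[k]
            a2 = dz * dz - c * c
            b2 = pz * dz - c * c * bi
            c2 = pz * pz - c * c * ci
            if abs(c) < 1e-12:
                if abs(dz) > 1e-12:
                    t = -pz / dz
                    if 0.0 < t < si:
                        buf[n] = t
                        n += 1
            elif abs(a2) > 1e-12:
                disc = b2 * b2 - a2 * c2
                if disc > 0.0:
                    sq = np.sqrt(disc)
                    for sgn in (-1.0, 1.0):
                        t = (-b2 + sgn * sq) / a2
                        if 0.0 < t < si:
                            z = pz + t * dz
                            if (z > 0.0) == (c > 0.0):
                                buf[n] = t
                                n += 1
            elif abs(b2) > 1e-12:
                t = -c2 / (2.0 * b2)
                if 0.0 < t < si:
                    z = pz + t * dz
                    if (z > 0.0) == (c > 0.0):
                        buf[n] = t
                        n += 1
        # insertion sort of the n cut points
        for a_ in range(1, n):
            key = buf[a_]
            j = a_ - 1
            while j >= 0 and buf[j] > key:
                buf[j + 1] = buf[j]
                j -= 1
            buf[j + 1] = key
        for a_ in range(n - 1):
            t0 = buf[a_]
            t1 = buf[a_ + 1]
            dt = t1 - t0
            if dt <= 1e-12:
                continue
            tm = 0.5 * (t0 + t1)
            x = p[i, 0] + tm * d[i, 0]
            y = p[i, 1] + tm * d[i, 1]
            z = p[i, 2] + tm * d[i, 2]
            r = np.sqrt(x * x + y * y + z * z)
            if r < r_edges[0] or r >= r_edges[nr]:
                continue
            ir = np.searchsorted(r_edges, r) - 1
            if ir < 0 or ir >= nr:
                continue
            cz = z / r
            # theta bins: cth is descending in cos (ascending theta)
            it = 0
            while it < ncone and cz < cth[it]:
                it += 1
            ih = 0 if y >= 0.0 else 1
            track_length[ir, it, iE[i]] += wgt[i] * dt
            dose[ir, it, ih] += fold[i] * dt
    return


def score_track_length(grid, batch, p, d, s, energy, weight,
                       physics=None, gy_fold=True):
    """Score flight segments into the ring-voxel grid.

    For each segment (origin ``p``, unit direction ``d``, length ``s``)
    every chord across a sphere/cone cell boundary is found exactly; the
    chord length times weight accumulates as track length in the cell's
    energy bin, and (optionally) folded with the water mu_en/rho as
    collision kerma.
    """
    if grid is None or len(p) == 0:
        return
    r_edges = np.asarray(grid.r_edges_cm, float)
    th_edges = np.asarray(grid.theta_edges_deg, float)
    r_max = r_edges[-1]
    w = np.asarray(weight, float)
    live = w > 0
    # closest-approach filter against the outer tally sphere
    b = np.einsum("ij,ij->i", p, d)
    c0 = np.einsum("ij,ij->i", p, p)
    t_star = np.clip(-b, 0.0, s)
    dmin2 = c0 + 2.0 * b * t_star + t_star**2
    sel = live & (dmin2 <= r_max**2)
    if not sel.any():
        return
    p, d, s, e, w = p[sel], d[sel], s[sel], np.asarray(energy)[sel], w[sel]
    b, c0 = b[sel], c0[sel]
    m = len(p)

    if _HAVE_NUMBA:
        iE = np.clip((e / ENERGY_BIN_MEV).astype(np.int64), 0,
                     N_ENERGY_BINS - 1)
        if gy_fold and physics is not None:
            fold = w * e * physics.mu_en_water(e)
        else:
            fold = np.zeros(m)
        inner = th_edges[(th_edges > 0.0) & (th_edges < 180.0)]
        cth = np.cos(np.radians(inner))
        _score_kernel(np.ascontiguousarray(p), np.ascontiguousarray(d),
                      np.ascontiguousarray(s, dtype=float),
                      b, c0, fold, w, iE, r_edges, cth,
                      grid.track_length, grid.dose[batch])
        return

    # sphere crossings, vectorized over all radial edges at once
    disc_s = b[:, None] ** 2 - (c0[:, None] - r_edges[None, :] ** 2)
    ok_s = disc_s > 0
    sq_s = np.sqrt(np.where(ok_s, disc_s, 0.0))
    t_sph = np.concatenate([-b[:, None] - sq_s, -b[:, None] + sq_s], axis=1)
    t_sph = np.where(np.tile(ok_s, (1, 2)), t_sph, np.inf)
    # cone / plane crossings
    pz, dz = p[:, 2], d[:, 2]
    inner = th_edges[(th_edges > 0.0) & (th_edges < 180.0)]
    cth = np.cos(np.radians(inner))[None, :]
    a2 = dz[:, None] ** 2 - cth**2
    b2 = pz[:, None] * dz[:, None] - cth**2 * b[:, None]
    c2 = pz[:, None] ** 2 - cth**2 * c0[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        disc_c = b2 * b2 - a2 * c2
        ok_c = disc_c > 0
        sq_c = np.sqrt(np.where(ok_c, disc_c, 0.0))
        quad = np.abs(a2) > _EPS
        a2s = np.where(quad, a2, 1.0)
        tc0 = np.where(ok_c & quad, (-b2 - sq_c) / a2s, np.inf)
        tc1 = np.where(ok_c & quad, (-b2 + sq_c) / a2s, np.inf)
        # degenerate (|dz| ~ |cos|): linear equation; plane z=0 handled too
        lin = ~quad & (np.abs(b2) > _EPS)
        tc1 = np.where(lin, -c2 / (2.0 * b2), tc1)
    t_con = np.concatenate([tc0, tc1], axis=1)
    cth2 = np.tile(cth, (1, 2))
    zq = pz[:, None] + t_con * dz[:, None]
    # keep only the nappe matching the polar angle (plane: both sides)
    wrong = (np.abs(cth2) > 1e-12) & (np.sign(zq) != np.sign(cth2))
    t_con = np.where(wrong, np.inf, t_con)
    ts = np.concatenate([np.zeros((m, 1)), s[:, None], t_sph, t_con], axis=1)
    ts = np.where((ts > 0) & (ts < s[:, None]) | (ts == 0.0)
                  | (ts == s[:, None]), ts, np.inf)
    ts.sort(axis=1)
    t0 = ts[:, :-1]
    t1 = ts[:, 1:]
    with np.errstate(invalid="ignore"):
        seg = t1 - t0
    valid = np.isfinite(seg) & (seg > 1e-12)
    tm = 0.5 * (t0 + t1)
    mx = p[:, 0:1] + tm * d[:, 0:1]
    my = p[:, 1:2] + tm * d[:, 1:2]
    mz = p[:, 2:3] + tm * d[:, 2:3]
    rm = np.sqrt(mx * mx + my * my + mz * mz)
    with np.errstate(invalid="ignore"):
        thm = np.degrees(np.arccos(np.clip(mz / np.where(rm > 0, rm, 1.0),
                                           -1.0, 1.0)))
    ir = np.searchsorted(r_edges, rm, side="right") - 1
    it = np.searchsorted(th_edges, thm, side="right") - 1
    it = np.clip(it, 0, len(th_edges) - 2)
    inside = valid & (ir >= 0) & (ir < len(r_edges) - 1)
    if not inside.any():
        return
    half = (my >= 0).astype(np.int8)
    iE = np.clip((np.asarray(e) / ENERGY_BIN_MEV).astype(int), 0,
                 N_ENERGY_BINS - 1)
    iE2 = np.broadcast_to(iE[:, None], seg.shape)
    wseg = np.broadcast_to(w[:, None], seg.shape)
    e2 = np.broadcast_to(np.asarray(e)[:, None], seg.shape)
    contrib = wseg * seg
    flat_idx = (ir * (len(th_edges) - 1) + it)
    np.add.at(grid.track_length.reshape(-1, N_ENERGY_BINS),
              (flat_idx[inside], iE2[inside]), contrib[inside])
    if gy_fold and physics is not None:
        muen = physics.mu_en_water(e2[inside])
        fold = contrib[inside] * e2[inside] * muen
        flat2 = flat_idx[inside] * 2 + half[inside]
        np.add.at(grid.dose[batch].reshape(-1), flat2, fold)


# ---------------------------------------------------------------------------
# Air-region estimators
# ---------------------------------------------------------------------------
def _attenuation_to_point(physics, model, phantom, p, target):
    """Optical-depth attenuation from points ``p`` to the fixed target,
    and the distances; vectorized over p."""
    delta = target[None, :] - p
    dist = np.linalg.norm(delta, axis=1)
    dirs = delta / np.where(dist[:, None] > 0, dist[:, None], 1.0)
    return dirs, dist


def _optical_depth(physics, model, phantom, p, dirs, dist, energy):
    tau = np.zeros(len(p))
    medium = phantom.medium
    if model is not None:
        iv = region_intervals(p, dirs, model)
        c0, c1 = iv["core"]
        e0, e1 = iv["envelope"]
        k0, k1 = iv["cable"]
        lc = np.clip(np.minimum(c1, dist) - np.minimum(c0, dist), 0, None)
        le = np.clip(np.minimum(e1, dist) - np.minimum(e0, dist), 0, None)
        lk = np.clip(np.minimum(k1, dist) - np.minimum(k0, dist), 0, None)
        lcap = np.clip(le - lc - lk, 0.0, None)
        tau += lc * physics.mu_linear(model.core_material, energy)
        tau += lcap * physics.mu_linear(model.capsule_material, energy)
        tau += lk * physics.mu_linear(model.cable_material, energy)
        lmetal = np.clip(le, 0, None)
    else:
        lmetal = 0.0
    if medium != "vacuum":
        tau += np.clip(dist - lmetal, 0.0, None) * \
            physics.mu_linear(medium, energy)
    return tau


def next_event_air_estimate(air, batch, physics, model, phantom,
                            p, energy, weight, pdf_per_sr=None,
                            collided=False):
    """Expected fluence contribution at the 1 m point per history.

    For emission points (``pdf_per_sr`` None) the uncollided estimate is
    weight * exp(-optical depth) / (4 pi d'^2); for interaction points a
    caller-supplied per-steradian emission density replaces 1/(4 pi).
    Accumulates fluence spectra and the air-kerma fold into ``air``.
    """
    if air is None or len(p) == 0:
        return
    target = AIR_TALLY_CENTRE
    dirs, dist = _attenuation_to_point(physics, model, phantom, p, target)
    tau = _optical_depth(physics, model, phantom, p, dirs, dist, energy)
    geom = 1.0 / (4.0 * np.pi * dist**2) if pdf_per_sr is None \
        else pdf_per_sr / dist**2
    contrib = np.asarray(weight, float) * np.exp(-tau) * geom
    iE = np.clip((np.asarray(energy) / ENERGY_BIN_MEV).astype(int), 0,
                 N_ENERGY_BINS - 1)
    spec = air.ne_collided_spectrum if collided else \
        air.ne_uncollided_spectrum
    np.add.at(spec, iE, contrib)
    fold = contrib * np.asarray(energy) * physics.mu_en_air(energy)
    air.ne_kerma[batch] += fold.sum()
    if not collided:
        air.ne_uncollided_kerma[batch] += fold.sum()


def _score_air_box(air, batch, physics, p, d, s, energy, weight):
    """Analog track-length chords through the 1 m scoring box."""
    if air is None or len(p) == 0:
        return
    lo = AIR_TALLY_CENTRE - AIR_TALLY_HALF
    hi = AIR_TALLY_CENTRE + AIR_TALLY_HALF
    t0 = np.zeros(len(p))
    t1 = np.asarray(s, float).copy()
    for ax in range(3):
        da = d[:, ax]
        pa = p[:, ax]
        with np.errstate(divide="ignore", invalid="ignore"):
            ta = np.where(np.abs(da) > _EPS, (lo[ax] - pa) / da, -np.inf)
            tb = np.where(np.abs(da) > _EPS, (hi[ax] - pa) / da, np.inf)
        tlo = np.minimum(ta, tb)
        thi = np.maximum(ta, tb)
        inside = (np.abs(da) <= _EPS) & (pa >= lo[ax]) & (pa <= hi[ax])
        tlo = np.where(np.abs(da) <= _EPS, np.where(inside, -np.inf, np.inf),
                       tlo)
        thi = np.where(np.abs(da) <= _EPS, np.where(inside, np.inf, -np.inf),
                       thi)
        t0 = np.maximum(t0, tlo)
        t1 = np.minimum(t1, thi)
    chord = np.clip(t1 - t0, 0.0, None)
    hit = chord > 0
    if not hit.any():
        return
    e = np.asarray(energy)[hit]
    wl = np.asarray(weight, float)[hit] * chord[hit]
    iE = np.clip((e / ENERGY_BIN_MEV).astype(int), 0, N_ENERGY_BINS - 1)
    np.add.at(air.analog_spectrum, iE, wl)
    air.analog_kerma[batch] += float(
        np.sum(wl * e * physics.mu_en_air(e)) / air.volume)


# ---------------------------------------------------------------------------
# The history loop
# ---------------------------------------------------------------------------
def _emit(config, model, spectrum, rng, n):
    if config.source_type == "point" or model is None:
        pos = np.zeros((n, 3))
    else:
        pos = sample_core_position(rng, model, n)
    mu = 2.0 * rng.random(n) - 1.0
    phi = 2.0 * np.pi * rng.random(n)
    st = np.sqrt(1.0 - mu * mu)
    d = np.column_stack([st * np.cos(phi), st * np.sin(phi), mu])
    if isinstance(spectrum, tuple):
        e = np.full(n, float(spectrum[1]))
    else:
        e = np.asarray(sample_emission_energy(spectrum, rng.random(n)), float)
    return pos, d, e


def _segments_for(physics, model, phantom, p, d, energy):
    """Ordered material segments per ray as fixed-width arrays.

    Returns (lengths, mu) of shape (n, 6).  The decomposition uses the
    convexity of the three source cylinders; rays missing all metal get a
    single medium segment.
    """
    n = len(p)
    t_b = phantom.boundary_distance(p, d)
    K = 8
    lengths = np.zeros((n, K))
    mu = np.zeros((n, K))
    mu_med = physics.mu_linear(phantom.medium, energy) \
        if phantom.medium != "vacuum" else np.zeros(n)
    if model is None:
        lengths[:, 0] = t_b
        mu[:, 0] = mu_med
        return lengths, mu, t_b
    # quick reject: 2D distance of ray to the z axis
    b2d = p[:, 0] * d[:, 0] + p[:, 1] * d[:, 1]
    a2d = d[:, 0] ** 2 + d[:, 1] ** 2
    c2d = p[:, 0] ** 2 + p[:, 1] ** 2
    tstar = np.where(a2d > _EPS, np.clip(-b2d / np.where(a2d > _EPS, a2d, 1.0),
                                         0.0, t_b), 0.0)
    dmin2 = c2d + 2.0 * b2d * tstar + a2d * tstar**2
    cand = dmin2 <= model.capsule_radius**2 + 1e-9
    lengths[:, 0] = t_b
    mu[:, 0] = mu_med
    if not cand.any():
        return lengths, mu, t_b
    idx = np.flatnonzero(cand)
    pc, dc, ec = p[idx], d[idx], energy[idx]
    tb_c = t_b[idx]
    iv = region_intervals(pc, dc, model)
    cuts = np.full((len(idx), 9), np.inf)
    cuts[:, 0] = 0.0
    cuts[:, 1] = tb_c
    col = 2
    for t0, t1 in iv.values():
        for t in (t0, t1):
            cuts[:, col] = np.where((t > 0) & (t < tb_c), t, np.inf)
            col += 1
    # capsule/cable boundary plane (different steels and densities)
    dz = dc[:, 2]
    with np.errstate(divide="ignore", invalid="ignore"):
        tz = np.where(np.abs(dz) > _EPS,
                      (model.z_cap_min - pc[:, 2]) / np.where(
                          np.abs(dz) > _EPS, dz, 1.0), np.inf)
    cuts[:, 8] = np.where((tz > 0) & (tz < tb_c), tz, np.inf)
    cuts.sort(axis=1)
    ncol = cuts.shape[1]
    seg_t0 = cuts[:, :-1]
    seg_t1 = np.minimum(cuts[:, 1:], tb_c[:, None])
    seg_len = np.clip(seg_t1 - seg_t0, 0.0, None)
    seg_len[~np.isfinite(seg_len)] = 0.0
    tm = seg_t0 + 0.5 * np.clip(seg_t1 - seg_t0, 0, None)
    # material at segment midpoints
    seg_mu = np.zeros_like(seg_len)
    hl = model.half_length
    for j in range(ncol - 1):
        good = seg_len[:, j] > _EPS
        if not good.any():
            continue
        mp = pc[good] + tm[good, j][:, None] * dc[good]
        x, y, z = mp[:, 0], mp[:, 1], mp[:, 2]
        r2 = x * x + y * y
        in_core = (r2 <= model.core_radius**2) & (np.abs(z) <= hl)
        in_env = (r2 <= model.capsule_radius**2) & \
                 (z >= model.z_cable_min) & (z <= model.z_cap_max)
        in_cable = in_env & (z < model.z_cap_min)
        mloc = np.zeros(int(good.sum()))
        eg = ec[good]
        mloc = physics.mu_linear(phantom.medium, eg) \
            if phantom.medium != "vacuum" else np.zeros(len(eg))
        mloc = np.where(in_env & ~in_core & ~in_cable,
                        physics.mu_linear(model.capsule_material, eg), mloc)
        mloc = np.where(in_cable,
                        physics.mu_linear(model.cable_material, eg), mloc)
        mloc = np.where(in_core,
                        physics.mu_linear(model.core_material, eg), mloc)
        seg_mu[good, j] = mloc
    # fold back into the fixed-width output (8 intervals between 9 sorted
    # cuts; degenerate ones have zero length)
    take = min(K, ncol - 1)
    lengths[idx, :take] = seg_len[:, :take]
    mu[idx, :take] = seg_mu[:, :take]
    # any residual length beyond the kept columns is medium
    resid = tb_c - seg_len[:, :take].sum(axis=1)
    lengths[idx, take - 1] += np.clip(resid, 0.0, None)
    return lengths, mu, t_b


def _locate_codes(model, phantom, pts):
    """Material codes at points: 0 medium, 1 core, 2 capsule, 3 cable."""
    codes = np.zeros(len(pts), dtype=np.int8)
    if model is None:
        return codes
    x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
    r2 = x * x + y * y
    hl = model.half_length
    in_core = (r2 <= model.core_radius**2) & (np.abs(z) <= hl)
    in_env = (r2 <= model.capsule_radius**2) & \
             (z >= model.z_cable_min) & (z <= model.z_cap_max)
    in_cable = in_env & (z < model.z_cap_min)
    codes[in_env] = 2
    codes[in_cable] = 3
    codes[in_core] = 1
    return codes


def _code_names(model, phantom):
    return {0: phantom.medium,
            1: model.core_material if model else phantom.medium,
            2: model.capsule_material if model else phantom.medium,
            3: model.cable_material if model else phantom.medium}


def run_histories(config, model=None, physics=None):
    """Run the configured number of histories; returns :class:`RunResult`.

    Deterministic for a given (config, seed): per-batch generators are
    spawned from the root SeedSequence, per-chunk generators from each
    batch, with a fixed chunk size.
    """
    if config.source_type == "volumetric" and model is None:
        model = SourceModel()
    if config.source_type == "point":
        model = None
    physics = physics or PhysicsData(config.coherent_enabled)
    phantom = config.make_phantom()
    spectrum = config.spectrum if isinstance(config.spectrum, tuple) \
        else load_spectrum(config.spectrum)

    grid = None
    if config.r_edges_cm is not None:
        th = config.theta_edges_deg if config.theta_edges_deg is not None \
            else np.linspace(0.0, 180.0, 19)
        grid = TallyGrid(np.asarray(config.r_edges_cm, float),
                         np.asarray(th, float), config.batches)
    air = AirTally(config.batches) if config.air_tally else None
    result = RunResult(config=config, histories_per_batch=config.histories,
                       grid=grid, air=air)
    if config.histories == 0:
        return result

    root = np.random.SeedSequence(config.seed)
    batch_seeds = root.spawn(config.batches)
    for b in range(config.batches):
        remaining = config.histories
        chunk_seqs = iter(batch_seeds[b].spawn(
            max(1, -(-config.histories // config.chunk_size))))
        while remaining > 0:
            n = min(config.chunk_size, remaining)
            remaining -= n
            rng = np.random.default_rng(next(chunk_seqs))
            _run_chunk(config, model, phantom, physics, spectrum, rng,
                       n, b, grid, air, result)
    return result


def _run_chunk(config, model, phantom, physics, spectrum, rng, n, batch,
               grid, air, result):
    p, d, e = _emit(config, model, spectrum, rng, n)
    w = np.ones(n)
    # next-event uncollided estimate from every emission point
    if air is not None:
        alive0 = e >= config.cutoff_mev
        next_event_air_estimate(air, batch, physics, model, phantom,
                                p[alive0], e[alive0], w[alive0])
    alive = e >= config.cutoff_mev  # sub-cutoff lines terminate at birth
    p, d, e, w = p[alive], d[alive], e[alive], w[alive]
    for _gen in range(10000):
        if len(p) == 0:
            break
        lengths, mus, t_b = _segments_for(physics, model, phantom, p, d, e)
        tau = -np.log1p(-rng.random(len(p)))
        dist, _k, escaped = sample_free_flight(tau, lengths, mus)
        dist = np.minimum(dist, t_b)
        score_track_length(grid, batch, p, d, dist, e, w, physics)
        _score_air_box(air, batch, physics, p, d, dist, e, w)
        result.escapes += int(escaped.sum())
        # advance survivors to their interaction points
        keep = ~escaped
        if not keep.any():
            break
        p = p[keep] + dist[keep, None] * d[keep]
        d = d[keep]
        e = e[keep]
        w = w[keep]
        codes = _locate_codes(model, phantom, p)
        names = _code_names(model, phantom)
        result.interactions += len(p)
        itype = np.zeros(len(p), dtype=np.int8)
        u_int = rng.random(len(p))
        for code in np.unique(codes):
            msk = codes == code
            name = names[int(code)]
            if name == "vacuum":
                continue
            pe = physics.mu_linear(name, e[msk], "photoelectric")
            inc_mu = physics.mu_linear(name, e[msk], "incoherent")
            coh_mu = physics.mu_linear(name, e[msk], "coherent") \
                if physics.coherent_enabled else np.zeros_like(pe)
            um = u_int[msk] * (pe + inc_mu + coh_mu)
            itype[msk] = np.where(um < pe, 0,
                                  np.where(um < pe + inc_mu, 1, 2))
        # photoelectric: terminate
        surv = itype != 0
        # incoherent
        inc = itype == 1
        if inc.any():
            ep, mu_s = sample_compton(e[inc], rng)
            if air is not None:
                # point-detector estimate of the collided fluence
                dirs, distt = _attenuation_to_point(
                    physics, model, phantom, p[inc], AIR_TALLY_CENTRE)
                mu_d = np.einsum("ij,ij->i", d[inc], dirs)
                a = e[inc] / ELECTRON_REST_MEV
                e_d = e[inc] / (1.0 + a * (1.0 - mu_d))
                # per-steradian density: dsigma/dOmega over the KN total
                pdf = kn_differential(e[inc], mu_d) / \
                    kn_total_cross_section(e[inc])
                good = e_d >= config.cutoff_mev
                next_event_air_estimate(air, batch, physics, model, phantom,
                                        p[inc][good], e_d[good],
                                        w[inc][good],
                                        pdf_per_sr=pdf[good], collided=True)
            phi = 2.0 * np.pi * rng.random(int(inc.sum()))
            d[inc] = rotate_direction(d[inc], mu_s, phi)
            e[inc] = ep
        # coherent: angle from the configured model, per material
        coh = itype == 2
        if coh.any():
            ncoh = int(coh.sum())
            mu_s = np.empty(ncoh)
            sub_codes = codes[coh]
            for code in np.unique(sub_codes):
                smask = sub_codes == code
                name = names[int(code)]
                if physics.rayleigh_model == "form_factor":
                    mu_s[smask] = physics.sample_rayleigh_ff(
                        name, e[coh][smask], rng)
                else:
                    mu_s[smask] = np.atleast_1d(
                        sample_rayleigh_angle(int(smask.sum()), rng))
            if air is not None:
                dirs, distt = _attenuation_to_point(
                    physics, model, phantom, p[coh], AIR_TALLY_CENTRE)
                mu_d = np.einsum("ij,ij->i", d[coh], dirs)
                pdf = np.empty(ncoh)
                for code in np.unique(sub_codes):
                    smask = sub_codes == code
                    pdf[smask] = physics.rayleigh_pdf_sr(
                        names[int(code)], e[coh][smask], mu_d[smask])
                next_event_air_estimate(air, batch, physics, model, phantom,
                                        p[coh], e[coh], w[coh],
                                        pdf_per_sr=pdf, collided=True)
            phi = 2.0 * np.pi * rng.random(ncoh)
            d[coh] = rotate_direction(d[coh], mu_s, phi)
        surv &= e >= config.cutoff_mev
        p, d, e, w = p[surv], d[surv], e[surv], w[surv]


# ---------------------------------------------------------------------------
# Batch statistics
# ---------------------------------------------------------------------------
def estimate_uncertainty(batch_means, axis=0):
    """(mean, standard error of the mean) across batches."""
    arr = np.asarray(batch_means, float)
    nb = arr.shape[axis]
    if nb < 2:
        raise ConfigError("need >= 2 batches to estimate uncertainty")
    mean = arr.mean(axis=axis)
    se = arr.std(axis=axis, ddof=1) / np.sqrt(nb)
    return mean, se
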