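"""TG-43 dosimetry-parameter extraction for a line source.

Implements the 2D line-source formalism: the geometry function G_L(r,theta),
air-kerma strength S_K from a fluence spectrum at 1 m, the dose-rate
constant Lambda, the radial dose function g_L(r) with its fifth-order
polynomial fit, the 2D anisotropy function F(r,theta), and the dose-rate
reconstruction

    D(r,theta) = S_K * Lambda * [G_L(r,theta)/G_L(r0,theta0)]
                 * g_L(r) * F(r,theta)

with reference point (r0, theta0) = (1 cm, 90 deg).

Units: internal dose/kerma are per initial photon; conversion to U/Bq and
cGy/h/U happens only at this reporting boundary through
:class:`AirKermaConstants`.  The product k*d^2 is carried in Gy*m^2 per
initial photon, the convention under which the 3.6e9 hour/centigray/area
factor yields U/Bq directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import R0_CM, THETA0_DEG, SourceModel

__all__ = ["AirKermaConstants", "FluenceSpectrum", "DoseRateTable",
           "TG43Parameters", "geometry_function_line",
           "air_kerma_per_photon", "sk_per_activity", "dose_rate_constant",
           "radial_dose_function", "fit_radial_polynomial",
           "anisotropy_function", "reconstruct_dose_rate",
           "voxel_correction_factor", "TG43Error"]


class TG43Error(ValueError):
    pass


@dataclass(frozen=True)
class AirKermaConstants:
    """Bookkeeping constants for the air-kerma strength chain."""

    cutoff_mev: float = 0.010          # delta
    distance_cm: float = 100.0         # d
    gy_per_mev_per_g: float = 1.602e-10
    per_hour_factor: float = 3.6e9     # s/h x cGy/Gy x cm^2/m^2
    photons_per_decay: float = 2.363
    voxel_correction: float = 1.0      # finite-scoring-region factor

    def __post_init__(self):
        if not (0.995 <= self.voxel_correction <= 1.005):
            raise TG43Error("voxel correction factor outside [0.995, 1.005]")
        for name in ("cutoff_mev", "distance_cm", "gy_per_mev_per_g",
                     "per_hour_factor", "photons_per_decay"):
            if getattr(self, name) <= 0:
                raise TG43Error(f"{name} must be positive")


@dataclass(frozen=True)
class FluenceSpectrum:
    """Energy-binned photon fluence per initial photon at the 1 m point."""

    energy_mid_mev: np.ndarray   # bin midpoints, contiguous, constant width
    fluence: np.ndarray          # cm^-2 per initial photon, per bin
    uncertainty: np.ndarray = None

    def __post_init__(self):
        e = np.asarray(self.energy_mid_mev, float)
        f = np.asarray(self.fluence, float)
        if len(e) != len(f):
            raise TG43Error("fluence/energy length mismatch")
        widths = np.diff(e)
        if len(e) > 1 and not np.allclose(widths, widths[0], rtol=1e-6):
            raise TG43Error("energy bins must be contiguous, constant width")
        if np.any(f < 0):
            raise TG43Error("fluence must be non-negative")

    @property
    def bin_width_mev(self):
        e = np.asarray(self.energy_mid_mev, float)
        return float(e[1] - e[0]) if len(e) > 1 else 0.005


@dataclass(frozen=True)
class DoseRateTable:
    """Dose rate per initial photon on an (r, theta) grid.

    ``dose`` has shape (n_theta, n_r); ``available`` marks cells outside
    the source and its 2 mm exclusion shell.
    """

    r_cm: np.ndarray
    theta_deg: np.ndarray
    dose: np.ndarray
    uncertainty: np.ndarray = None
    available: np.ndarray = None

    def __post_init__(self):
        d = np.asarray(self.dose, float)
        if d.shape != (len(self.theta_deg), len(self.r_cm)):
            raise TG43Error("dose table shape must be (n_theta, n_r)")
        if self.available is None:
            object.__setattr__(self, "available",
                               np.ones_like(d, dtype=bool))
        avail = np.asarray(self.available, bool)
        if np.any(d[avail] < 0):
            raise TG43Error("negative dose in available cells")

    def _index_of(self, grid, value, what):
        idx = np.argmin(np.abs(np.asarray(grid, float) - value))
        if abs(grid[idx] - value) > 1e-6:
            raise TG43Error(f"table does not cover {what} = {value}")
        return int(idx)

    @property
    def i_r0(self):
        return self._index_of(self.r_cm, R0_CM, "r0")

    @property
    def i_theta0(self):
        return self._index_of(self.theta_deg, THETA0_DEG, "theta0")


@dataclass(frozen=True)
class TG43Parameters:
    """The extracted parameter set with uncertainties."""

    sk_per_a_u_per_bq: float = None
    dose_rate_constant: float = None          # cGy/h/U
    active_length_cm: float = 0.35
    gl_r_cm: np.ndarray = None
    gl: np.ndarray = None
    gl_fit_coefficients: np.ndarray = None    # a0..a5
    anisotropy: DoseRateTable = None          # F(r,theta) stored as table
    uncertainties: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Geometry function
# ---------------------------------------------------------------------------
_SIN_FLOOR = 1e-9


def geometry_function_line(r_cm, theta_deg, active_length_cm=0.35):
    """TG-43 line-source geometry function G_L(r, theta), cm^-2.

    beta/(L r sin theta) away from the axis, (r^2 - L^2/4)^-1 on it;
    continuous in theta and -> 1/r^2 as L -> 0.  Raises if the field point
    lies on the active line segment.
    """
    r = np.asarray(r_cm, dtype=float)
    th = np.radians(np.asarray(theta_deg, dtype=float))
    L = float(active_length_cm)
    if L <= 0:
        raise TG43Error("active length must be positive")
    x = r * np.sin(th)
    z = r * np.cos(th)
    on_axis = np.abs(x) < _SIN_FLOOR * np.maximum(r, 1.0)
    if np.any(on_axis & (np.abs(z) <= 0.5 * L + 1e-12)):
        raise TG43Error("field point lies on the active line segment")
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.arctan2(0.5 * L - z, x) - np.arctan2(-0.5 * L - z, x)
        g_off = beta / (L * np.where(np.abs(x) > 0, np.abs(x), 1.0))
        g_on = 1.0 / (r * r - 0.25 * L * L)
    out = np.where(on_axis, g_on, g_off)
    return float(out) if np.ndim(out) == 0 else out


# ---------------------------------------------------------------------------
# Air-kerma strength chain
# ---------------------------------------------------------------------------
def air_kerma_per_photon(fluence, air_table, constants=None):
    """Air-kerma rate at d per initial photon, Gy.

    Folds the binned fluence with the air mass energy-absorption
    coefficient: k = c * sum_i phi_i E_i (mu_en/rho)(E_i) over bins with
    E_i >= delta.  ``phi_i`` is the fluence accumulated in bin i (cm^-2);
    equivalently a fluence density times the bin width.
    """
    constants = constants or AirKermaConstants()
    e = np.asarray(fluence.energy_mid_mev, float)
    phi = np.asarray(fluence.fluence, float)
    keep = e >= constants.cutoff_mev
    e, phi = e[keep], phi[keep]
    if len(e) == 0:
        return 0.0
    try:
        muen = air_table.mu_en_at(e)
    except Exception as exc:
        raise TG43Error(f"fluence bins incompatible with mu_en table: {exc}")
    return float(constants.gy_per_mev_per_g * np.sum(phi * e * muen))


def sk_per_activity(k_gy_per_photon, constants=None, correction=None):
    """Air-kerma strength per unit activity, U/Bq.

    S_K/A = 3.6e9 * (k * d^2 [Gy m^2] * correction) * photons_per_decay.
    ``correction`` defaults to the constants' voxel correction (use 1 for
    a point estimate of k, the numeric factor for a finite scoring
    region).
    """
    constants = constants or AirKermaConstants()
    if k_gy_per_photon < 0:
        raise TG43Error("kerma per photon must be >= 0")
    corr = constants.voxel_correction if correction is None else correction
    d_m = constants.distance_cm / 100.0
    kd2 = k_gy_per_photon * d_m * d_m * corr
    return constants.per_hour_factor * kd2 * constants.photons_per_decay


def dose_rate_constant(dose_ref_gy_per_photon, k_d2_gy_m2_per_photon):
    """Dose-rate constant Lambda, cGy/h/U.

    Ratio of the water dose rate at (1 cm, 90 deg) to the air-kerma
    strength, both per initial photon, so every activity/time conversion
    cancels: numerically Lambda = D / (k d^2 * 1e4 cm^2/m^2).
    """
    if k_d2_gy_m2_per_photon <= 0:
        raise TG43Error("air-kerma strength must be positive")
    return float(dose_ref_gy_per_photon / (k_d2_gy_m2_per_photon * 1.0e4))


# ---------------------------------------------------------------------------
# Radial dose function and anisotropy function
# ---------------------------------------------------------------------------
def radial_dose_function(table, active_length_cm=0.35):
    """g_L(r) from the transverse-plane row of a dose-rate table.

    g_L(r) = [D(r,theta0) G_L(r0,theta0)] / [D(r0,theta0) G_L(r,theta0)];
    exactly 1 at r0 by construction.  Returns (r, gL, rel_unc).
    """
    it = table.i_theta0
    ir0 = table.i_r0
    d_row = np.asarray(table.dose, float)[it]
    d0 = d_row[ir0]
    if d0 <= 0:
        raise TG43Error("non-positive reference dose at (r0, theta0)")
    gl_geo = geometry_function_line(table.r_cm, THETA0_DEG, active_length_cm)
    g0 = geometry_function_line(R0_CM, THETA0_DEG, active_length_cm)
    gl = (d_row / d0) * (g0 / gl_geo)
    gl[ir0] = 1.0
    rel = None
    if table.uncertainty is not None:
        u = np.asarray(table.uncertainty, float)[it]
        with np.errstate(divide="ignore", invalid="ignore"):
            rel = np.sqrt((u / d_row) ** 2 + (u[ir0] / d0) ** 2)
        rel[ir0] = 0.0
    return np.asarray(table.r_cm, float).copy(), gl, rel


def fit_radial_polynomial(r_cm, gl, order=5):
    """Unweighted least-squares polynomial fit g_L(r) = a0 + ... + a5 r^5.

    Returns (coefficients a0..a5, rms residual).  No constraint is placed
    on g_L(1); a well-sampled input reproduces 1 there on its own.
    """
    r = np.asarray(r_cm, float)
    y = np.asarray(gl, float)
    if len(r) < order + 1:
        raise TG43Error(f"need at least {order + 1} samples for the fit")
    design = np.vander(r, order + 1, increasing=True)
    if np.linalg.matrix_rank(design) < order + 1:
        raise TG43Error("rank-deficient design matrix (duplicate radii?)")
    coeffs, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coeffs
    return coeffs, float(np.sqrt(np.mean(resid**2)))


def evaluate_radial_polynomial(coeffs, r_cm):
    return np.polynomial.polynomial.polyval(np.asarray(r_cm, float),
                                            np.asarray(coeffs, float))


def source_proximity_mask(r_cm, theta_deg, model=None, margin_cm=0.2):
    """True where a field point is farther than ``margin_cm`` from the
    capsule surface (the usability rule for reported F cells)."""
    model = model or SourceModel()
    r = np.asarray(r_cm, float)[None, :]
    th = np.radians(np.asarray(theta_deg, float))[:, None]
    x = r * np.sin(th)
    z = r * np.cos(th)
    # distance to the finite capsule cylinder (axis z in [zmin, zmax])
    dz = np.maximum(np.maximum(model.z_cap_min - z, z - model.z_cap_max), 0.0)
    dx = x - model.capsule_radius
    inside = (dx <= 0) & (dz <= 0)
    dist = np.where(dx > 0,
                    np.hypot(np.maximum(dx, 0.0), dz),
                    dz)
    return ~inside & (dist > margin_cm)


def anisotropy_function(table, active_length_cm=0.35, model=None):
    """2D anisotropy function F(r,theta) from a dose-rate table.

    F(r,theta) = [D(r,theta)/D(r,theta0)] * [G_L(r,theta0)/G_L(r,theta)];
    exactly 1 on the transverse plane.  Cells inside or within 2 mm of the
    capsule surface (or unavailable in the input) are masked.
    Returns a :class:`DoseRateTable` whose ``dose`` field holds F.
    """
    it = table.i_theta0
    d = np.asarray(table.dose, float)
    d0 = d[it][None, :]
    if np.any(d0 <= 0):
        raise TG43Error("non-positive transverse-plane dose")
    r = np.asarray(table.r_cm, float)
    th = np.asarray(table.theta_deg, float)
    g_ref = geometry_function_line(r, THETA0_DEG, active_length_cm)[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.empty((len(th), len(r)))
        for j, t in enumerate(th):
            if t in (0.0, 180.0):
                g[j] = [geometry_function_line(ri, t, active_length_cm)
                        if ri > 0.5 * active_length_cm else np.nan
                        for ri in r]
            else:
                g[j] = geometry_function_line(r, t, active_length_cm)
    f = (d / d0) * (g_ref / g)
    f[it] = 1.0
    avail = source_proximity_mask(r, th, model=model) & \
        np.asarray(table.available, bool) & np.isfinite(f)
    unc = None
    if table.uncertainty is not None:
        u = np.asarray(table.uncertainty, float)
        with np.errstate(divide="ignore", invalid="ignore"):
            unc = np.abs(f) * np.sqrt((u / d) ** 2 + (u[it][None, :] / d0) ** 2)
        unc[it] = 0.0
    return DoseRateTable(r_cm=r.copy(), theta_deg=th.copy(),
                         dose=np.where(avail, f, np.nan),
                         uncertainty=unc, available=avail)


# ---------------------------------------------------------------------------
# Dose-rate reconstruction (Eq. 1 direction)
# ---------------------------------------------------------------------------
def reconstruct_dose_rate(params, sk_u, r_cm, theta_deg, use_fit=False):
    """Dose rate in cGy/h at (r, theta) from an extracted parameter set.

    g_L is interpolated linearly in r (or evaluated from the polynomial
    fit if ``use_fit``); F bilinearly in (r, theta).  Queries outside the
    parameter coverage raise.
    """
    lam = params.dose_rate_constant
    L = params.active_length_cm
    r = float(r_cm)
    th = float(theta_deg)
    gl_r = np.asarray(params.gl_r_cm, float)
    if not (gl_r[0] - 1e-9 <= r <= gl_r[-1] + 1e-9):
        raise TG43Error(f"r = {r} cm outside g_L coverage")
    if use_fit and params.gl_fit_coefficients is not None:
        gl = float(evaluate_radial_polynomial(params.gl_fit_coefficients, r))
    else:
        gl = float(np.interp(r, gl_r, np.asarray(params.gl, float)))
    ftab = params.anisotropy
    fth = np.asarray(ftab.theta_deg, float)
    fr = np.asarray(ftab.r_cm, float)
    if not (fth[0] - 1e-9 <= th <= fth[-1] + 1e-9):
        raise TG43Error(f"theta = {th} outside F coverage")
    if not (fr[0] - 1e-9 <= r <= fr[-1] + 1e-9):
        raise TG43Error(f"r = {r} outside F coverage")
    fgrid = np.asarray(ftab.dose, float)
    # bilinear with nan-avoidance: nearest available along theta first
    j = np.searchsorted(fth, th)
    j0, j1 = max(j - 1, 0), min(j, len(fth) - 1)
    wj = 0.0 if j1 == j0 else (th - fth[j0]) / (fth[j1] - fth[j0])
    i = np.searchsorted(fr, r)
    i0, i1 = max(i - 1, 0), min(i, len(fr) - 1)
    wi = 0.0 if i1 == i0 else (r - fr[i0]) / (fr[i1] - fr[i0])
    corners = fgrid[np.ix_([j0, j1], [i0, i1])]
    if np.any(~np.isfinite(corners)):
        raise TG43Error("query touches unavailable anisotropy cells")
    fval = ((1 - wj) * ((1 - wi) * corners[0, 0] + wi * corners[0, 1])
            + wj * ((1 - wi) * corners[1, 0] + wi * corners[1, 1]))
    g = geometry_function_line(r, th, L)
    g0 = geometry_function_line(R0_CM, THETA0_DEG, L)
    return float(sk_u * lam * (g / g0) * gl * fval)


# ---------------------------------------------------------------------------
# Result serialisation
# ---------------------------------------------------------------------------
def gl_to_csv(r_cm, gl, rel_unc=None):
    """Radial-dose-function samples as CSV text (r_cm, gL, rel_unc)."""
    lines = ["r_cm,gL,rel_unc"]
    u = rel_unc if rel_unc is not None else np.zeros_like(np.asarray(gl))
    for r, g, e in zip(r_cm, gl, u):
        lines.append(f"{r:g},{g:.6f},{e:.2e}")
    return "\n".join(lines) + "\n"


def fit_to_json(coefficients, residual_rms):
    """Fifth-order fit coefficients as a JSON string {a0..a5, rms}."""
    import json
    out = {f"a{i}": float(c) for i, c in enumerate(coefficients)}
    out["residual_rms"] = float(residual_rms)
    return json.dumps(out, indent=1)


def scalars_to_json(params):
    """Headline scalars of a TG43Parameters set as a JSON string."""
    import json
    meta = dict(params.metadata)
    return json.dumps({
        "Sk_per_A_U_per_Bq": params.sk_per_a_u_per_bq,
        "Lambda_cGy_per_h_per_U": params.dose_rate_constant,
        "spectrum_label": meta.get("spectrum"),
        "air_mode": meta.get("air_mode"),
        "uncertainties": {k: float(v)
                          for k, v in params.uncertainties.items()},
    }, indent=1)


# ---------------------------------------------------------------------------
# Finite scoring-region correction
# ---------------------------------------------------------------------------
def voxel_correction_factor(region_cm=(0.05, 10.0, 10.0), d_cm=100.0,
                            n_nodes=(16, 301, 301)):
    """Inverse-square correction for the finite 1 m scoring region.

    The scoring region (dx along the source-detector axis, dy, dz) centred
    at distance d samples <1/r^2> rather than 1/d^2; the returned factor
    is (1/d^2) / <1/r^2>, computed by trapezoid quadrature with at least
    ~1e6 nodes by default.  Shrinking the region gives exactly 1.
    """
    dx, dy, dz = region_cm
    if dx == 0 and dy == 0 and dz == 0:
        return 1.0
    xs = np.linspace(d_cm - dx / 2, d_cm + dx / 2, n_nodes[0])
    ys = np.linspace(-dy / 2, dy / 2, n_nodes[1])
    zs = np.linspace(-dz / 2, dz / 2, n_nodes[2])
    x2 = xs[:, None, None] ** 2
    y2 = ys[None, :, None] ** 2
    z2 = zs[None, None, :] ** 2
    inv_r2 = 1.0 / (x2 + y2 + z2)
    # trapezoid weights per axis
    def w(n):
        v = np.ones(n)
        if n > 1:
            v[0] = v[-1] = 0.5
        return v
    wgt = w(n_nodes[0])[:, None, None] * w(n_nodes[1])[None, :, None] \
        * w(n_nodes[2])[None, None, :]
    mean_inv_r2 = float((inv_r2 * wgt).sum() / wgt.sum())
    return (1.0 / d_cm**2) / mean_inv_r2
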