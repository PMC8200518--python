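"""Independent oracles and synthetic-input generators.

Everything here is implemented independently of the production code paths
it checks (numeric quadrature instead of closed forms, direct line
integrals instead of the arctangent geometry function, forward evaluation
of the dose-rate equation instead of the extraction routines), so each
pipeline stage can be validated in isolation with no external data.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import quad

from .geometry import R0_CM, THETA0_DEG
from .tg43 import DoseRateTable, geometry_function_line

__all__ = ["gl_line_integral_oracle", "kn_quadrature_oracle",
           "make_synthetic_dose_table", "make_vacuum_config",
           "mc_voxel_correction_oracle"]

_ELECTRON_REST_MEV = 0.51099895
_RE2 = 2.8179403262e-13 ** 2


def gl_line_integral_oracle(r_cm, theta_deg, active_length_cm=0.35):
    """Line-source geometry function by direct numeric integration.

    (1/L) * integral over the active length of 1/(distance to field
    point)^2 -- the defining integral, evaluated with adaptive quadrature.
    """
    L = float(active_length_cm)
    th = np.radians(theta_deg)
    x = r_cm * np.sin(th)
    z = r_cm * np.cos(th)

    def integrand(zp):
        return 1.0 / (x * x + (z - zp) ** 2)

    val, _ = quad(integrand, -L / 2, L / 2, limit=200)
    return val / L


def kn_differential(energy_mev, cos_theta):
    """Klein-Nishina dsigma/dOmega per electron, cm^2/sr."""
    a = energy_mev / _ELECTRON_REST_MEV
    t = 1.0 / (1.0 + a * (1.0 - cos_theta))  # E'/E
    return 0.5 * _RE2 * t * t * (t + 1.0 / t - (1.0 - cos_theta * cos_theta))


def kn_quadrature_oracle(energy_mev):
    """(total cross section cm^2, mean scattered energy MeV) by quadrature.

    Integrates the Klein-Nishina differential form over angle; the total
    doubles as a check of the closed-form expression used in production.
    """
    a = energy_mev / _ELECTRON_REST_MEV

    def dsig(mu):
        return 2.0 * np.pi * kn_differential(energy_mev, mu)

    def e_weighted(mu):
        eprime = energy_mev / (1.0 + a * (1.0 - mu))
        return dsig(mu) * eprime

    total, _ = quad(dsig, -1.0, 1.0, limit=200)
    esum, _ = quad(e_weighted, -1.0, 1.0, limit=200)
    return total, esum / total


def make_synthetic_dose_table(gl_func=None, f_func=None,
                              active_length_cm=0.35,
                              r_cm=None, theta_deg=None, noise_sigma=0.0,
                              rng=None):
    """Dose-rate table built by forward-evaluating the dose-rate equation.

    D(r,theta) = [G_L(r,theta)/G_L(r0,theta0)] * g_L(r) * F(r,theta) for
    caller-supplied g_L and F (callables; defaults are identically 1), so
    the extraction routines have a known ground truth.  ``noise_sigma``
    adds relative Gaussian perturbations for robustness studies
    (noiseless by default).
    """
    r = np.asarray(r_cm if r_cm is not None
                   else np.array([0.4, 0.6, 0.8, 1.0, 1.5, 2, 3, 4, 5, 6, 8, 10]),
                   float)
    th = np.asarray(theta_deg if theta_deg is not None
                    else np.arange(0.0, 181.0, 5.0), float)
    gl_func = gl_func or (lambda rr: np.ones_like(np.asarray(rr, float)))
    f_func = f_func or (lambda rr, tt: 1.0)
    g0 = geometry_function_line(R0_CM, THETA0_DEG, active_length_cm)
    dose = np.empty((len(th), len(r)))
    for j, t in enumerate(th):
        for i, ri in enumerate(r):
            if t in (0.0, 180.0) and ri <= 0.5 * active_length_cm:
                dose[j, i] = np.nan
                continue
            g = geometry_function_line(ri, t, active_length_cm)
            dose[j, i] = (g / g0) * float(np.asarray(gl_func(ri))) \
                * float(np.asarray(f_func(ri, t)))
    if noise_sigma > 0:
        rng = rng or np.random.default_rng(0)
        dose = dose * (1.0 + noise_sigma * rng.standard_normal(dose.shape))
    avail = np.isfinite(dose)
    return DoseRateTable(r_cm=r, theta_deg=th,
                         dose=np.where(avail, dose, np.nan),
                         available=avail)


def make_vacuum_config(r_grid_cm, energy_mev=0.3165, histories=20000,
                       batches=4, seed=1):
    """Run configuration for the inverse-square verification: a bare
    monoenergetic point source in a vacuum sphere, ring tallies on the
    given radii."""
    from .transport import RunConfig  # local import to avoid a cycle

    r = np.asarray(r_grid_cm, float)
    return RunConfig(
        histories=histories, batches=batches, seed=seed,
        phantom_kind="vacuum", phantom_size=float(r[-1] * 1.5),
        spectrum=("mono", float(energy_mev)),
        source_type="point",
        r_edges_cm=r, theta_edges_deg=np.array([0.0, 60.0, 120.0, 180.0]),
    )


def mc_voxel_correction_oracle(region_cm=(0.05, 10.0, 10.0), d_cm=100.0,
                               n=2_000_000, seed=7):
    """Monte Carlo estimate of the finite-scoring-region correction,
    an independent cross-check of the quadrature version."""
    rng = np.random.default_rng(seed)
    dx, dy, dz = region_cm
    x = d_cm + dx * (rng.random(n) - 0.5)
    y = dy * (rng.random(n) - 0.5)
    z = dz * (rng.random(n) - 0.5)
    mean_inv_r2 = np.mean(1.0 / (x * x + y * y + z * z))
    return (1.0 / d_cm**2) / mean_inv_r2
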