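"""Per-material photon attenuation tables with log-log interpolation.

Tables ship as CSV fixtures under ``data/attenuation/`` (one per material,
columns ``energy_MeV, mu_photoelectric, mu_incoherent, mu_coherent,
mu_total[, mu_en]``, all cm^2/g) and can be regenerated with
``scripts/build_physics_tables.py``.

For water and dry air the total attenuation and the mass energy-absorption
coefficients follow the standard 19-energy reference compilation for those
media; the per-process split assigns the free-electron Klein-Nishina value
to incoherent scattering, the form-factor model of :mod:`tg43mc.elements`
to coherent scattering, and the remainder to photoelectric absorption, so
the columns sum to the total exactly.  The metal tables are composed from
the elemental model via the mass-fraction mixture rule.

Interpolation is log-log linear (the standard choice for photon cross
sections over this range) and exact at grid points; queries outside
[10 keV, 1.5 MeV] raise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import elements as _el
from .materials import STANDARD_MATERIALS

__all__ = ["AttenuationTable", "load_attenuation", "build_attenuation_table",
           "interpolate_mu", "interpolate_mu_en", "AttenuationError",
           "ENERGY_MIN_MEV", "ENERGY_MAX_MEV"]

ENERGY_MIN_MEV = 0.010
ENERGY_MAX_MEV = 1.5

PROCESSES = ("photoelectric", "incoherent", "coherent")

# Standard-compilation energy grid (MeV) and values for liquid water and
# dry air: total mass attenuation (coherent included) and mass
# energy-absorption coefficients, cm^2/g.
_REF_GRID = np.array([0.010, 0.015, 0.020, 0.030, 0.040, 0.050, 0.060,
                      0.080, 0.100, 0.150, 0.200, 0.300, 0.400, 0.500,
                      0.600, 0.800, 1.000, 1.250, 1.500])
_REF_WATER_MU = np.array([5.329, 1.673, 0.8096, 0.3756, 0.2683, 0.2269,
                          0.2059, 0.1837, 0.1707, 0.1505, 0.1370, 0.1186,
                          0.1061, 0.09687, 0.08956, 0.07865, 0.07072,
                          0.06323, 0.05754])
_REF_WATER_MUEN = np.array([4.944, 1.374, 0.5503, 0.1557, 0.06947, 0.04223,
                            0.03190, 0.02597, 0.02546, 0.02764, 0.02967,
                            0.03192, 0.03279, 0.03299, 0.03284, 0.03206,
                            0.03103, 0.02965, 0.02833])
_REF_AIR_MU = np.array([5.120, 1.614, 0.7779, 0.3538, 0.2485, 0.2080,
                        0.1875, 0.1662, 0.1541, 0.1356, 0.1233, 0.1067,
                        0.09549, 0.08712, 0.08055, 0.07074, 0.06358,
                        0.05687, 0.05175])
_REF_AIR_MUEN = np.array([4.742, 1.334, 0.5389, 0.1537, 0.06833, 0.04098,
                          0.03041, 0.02407, 0.02325, 0.02496, 0.02672,
                          0.02872, 0.02949, 0.02966, 0.02953, 0.02882,
                          0.02789, 0.02666, 0.02547])


class AttenuationError(ValueError):
    pass


@dataclass(frozen=True)
class AttenuationTable:
    """Tabulated per-process mass attenuation for one material."""

    material: str
    energy_mev: np.ndarray
    mu: dict  # process -> array, cm^2/g; includes "total"
    mu_en: np.ndarray = field(default=None)  # air/water only

    def __post_init__(self):
        e = self.energy_mev
        if np.any(np.diff(e) <= 0):
            raise AttenuationError(f"{self.material}: grid not ascending")
        if e[0] > ENERGY_MIN_MEV + 1e-12 or e[-1] < ENERGY_MAX_MEV - 1e-12:
            raise AttenuationError(
                f"{self.material}: grid must span [{ENERGY_MIN_MEV}, "
                f"{ENERGY_MAX_MEV}] MeV, got [{e[0]}, {e[-1]}]")
        total = self.mu["total"]
        psum = sum(self.mu[p] for p in PROCESSES)
        if np.any(np.abs(psum / total - 1.0) > 0.005):
            raise AttenuationError(
                f"{self.material}: process sum deviates from total by >0.5%")
        for key, val in self.mu.items():
            if np.any(val <= 0):
                raise AttenuationError(
                    f"{self.material}: non-positive mu ({key})")
        if self.mu_en is not None and np.any(self.mu_en > total):
            raise AttenuationError(
                f"{self.material}: mu_en exceeds mu somewhere")

    def _interp(self, values, energy_mev):
        e = np.asarray(energy_mev, dtype=float)
        if np.any(e < self.energy_mev[0] - 1e-12) or \
                np.any(e > self.energy_mev[-1] + 1e-12):
            raise AttenuationError(
                f"{self.material}: energy outside tabulated span "
                f"[{self.energy_mev[0]}, {self.energy_mev[-1]}] MeV")
        out = np.exp(np.interp(np.log(e), np.log(self.energy_mev),
                               np.log(values)))
        return float(out) if np.ndim(energy_mev) == 0 else out

    def mu_at(self, energy_mev, process="total"):
        """Log-log interpolated mu/rho (cm^2/g); exact at grid points."""
        if process not in self.mu:
            raise AttenuationError(f"unknown process {process!r}")
        return self._interp(self.mu[process], energy_mev)

    def mu_en_at(self, energy_mev):
        if self.mu_en is None:
            raise AttenuationError(
                f"{self.material}: no mu_en data (air and water only)")
        return self._interp(self.mu_en, energy_mev)


def interpolate_mu(table, energy_mev, process="total"):
    """Functional alias for :meth:`AttenuationTable.mu_at`."""
    return table.mu_at(energy_mev, process)


def interpolate_mu_en(table, energy_mev):
    """Functional alias for :meth:`AttenuationTable.mu_en_at`."""
    return table.mu_en_at(energy_mev)


def _metal_grid():
    g = np.geomspace(ENERGY_MIN_MEV, ENERGY_MAX_MEV, 45)
    extra = [0.0761100, 0.0761120]  # straddle the Ir K edge
    g = np.unique(np.concatenate([g, _REF_GRID, extra]))
    return g


def build_attenuation_table(material_name):
    """Compose the table for one of the five standard materials."""
    mat = STANDARD_MATERIALS[material_name]
    if material_name in ("water", "air"):
        grid = _REF_GRID
        total = _REF_WATER_MU if material_name == "water" else _REF_AIR_MU
        muen = _REF_WATER_MUEN if material_name == "water" else _REF_AIR_MUEN
        inc = mat.mu(grid, "incoherent")
        coh = mat.mu(grid, "coherent")
        # transcribed total stays authoritative: photoelectric is the residual
        pe = np.clip(total - inc - coh, 1e-8, None)
        mu = {"photoelectric": pe, "incoherent": inc, "coherent": coh,
              "total": pe + inc + coh}
        return AttenuationTable(material=material_name, energy_mev=grid,
                                mu=mu, mu_en=muen)
    grid = _metal_grid()
    mu = {p: mat.mu(grid, p) for p in PROCESSES}
    mu["total"] = sum(mu[p] for p in PROCESSES)
    return AttenuationTable(material=material_name, energy_mev=grid, mu=mu)


def table_to_frame(table):
    data = {"energy_MeV": table.energy_mev,
            "mu_photoelectric": table.mu["photoelectric"],
            "mu_incoherent": table.mu["incoherent"],
            "mu_coherent": table.mu["coherent"],
            "mu_total": table.mu["total"]}
    if table.mu_en is not None:
        data["mu_en"] = table.mu_en
    return pd.DataFrame(data)


def table_from_frame(material, df):
    mu = {"photoelectric": df["mu_photoelectric"].to_numpy(),
          "incoherent": df["mu_incoherent"].to_numpy(),
          "coherent": df["mu_coherent"].to_numpy(),
          "total": df["mu_total"].to_numpy()}
    mu_en = df["mu_en"].to_numpy() if "mu_en" in df.columns else None
    return AttenuationTable(material=material,
                            energy_mev=df["energy_MeV"].to_numpy(),
                            mu=mu, mu_en=mu_en)


def load_attenuation(material_name):
    """Load the shipped attenuation table for a standard material."""
    fname = f"{material_name}.csv"
    ref = resources.files("tg43mc.data.attenuation") / fname
    with resources.as_file(ref) as path:
        if not Path(path).exists():
            raise AttenuationError(f"no attenuation fixture for "
                                   f"{material_name!r}")
        df = pd.read_csv(path, comment="#")
    return table_from_frame(material_name, df)
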