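"""Material compositions and the mass-fraction mixture rule.

The five materials of the source model: the iridium core, AISI 316L capsule,
AISI 304 drive-cable steel (an effective density for the woven cable, not
bulk steel), liquid water and dry air.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import elements as _el

__all__ = ["Material", "build_material", "STANDARD_MATERIALS"]


class MaterialError(ValueError):
    pass


@dataclass(frozen=True)
class Material:
    """An elemental mixture with mass percentages summing to 100."""

    name: str
    fractions: dict = field(default_factory=dict)  # symbol -> mass percent
    density: float = 0.0  # g/cm^3

    def mu(self, energy_mev, process="total"):
        """Mixture mass attenuation coefficient, cm^2/g.

        Mass-fraction-weighted sum of the elemental coefficients.
        """
        e = np.asarray(energy_mev, dtype=float)
        out = np.zeros_like(np.atleast_1d(e), dtype=float)
        for sym, pct in self.fractions.items():
            out = out + (pct / 100.0) * np.atleast_1d(
                _el.element_mu_processes(sym, e)[process])
        return float(out[0]) if np.ndim(energy_mev) == 0 else out


def build_material(name, fractions, density):
    """Validate and construct a :class:`Material`.

    ``fractions`` maps element symbols to mass percentages; they must be
    non-negative and sum to 100 within 0.01.
    """
    for sym, pct in fractions.items():
        if sym not in _el.ELEMENTS:
            raise MaterialError(f"{name}: unknown element {sym!r}")
        if pct < 0:
            raise MaterialError(f"{name}: negative fraction for {sym}")
    total = sum(fractions.values())
    if abs(total - 100.0) > 0.01:
        raise MaterialError(
            f"{name}: mass fractions sum to {total:.4f}, expected 100 +/- 0.01")
    if density <= 0:
        raise MaterialError(f"{name}: density must be positive")
    return Material(name=name, fractions=dict(fractions), density=float(density))


STANDARD_MATERIALS = {
    "iridium": build_material("iridium", {"Ir": 100.0}, 22.42),
    "steel316l": build_material(
        "steel316l",
        {"C": 0.03, "N": 0.1, "Si": 0.75, "P": 0.045, "S": 0.03,
         "Cr": 17.0, "Mn": 2.0, "Fe": 65.545, "Ni": 12.0, "Mo": 2.5},
        7.8),
    "steel304": build_material(
        "steel304",
        {"C": 0.08, "N": 0.1, "Si": 0.75, "P": 0.045, "S": 0.03,
         "Cr": 19.0, "Mn": 2.0, "Fe": 67.995, "Ni": 10.0},
        5.6),
    "water": build_material("water", {"H": 11.1, "O": 88.9}, 0.998),
    "air": build_material(
        "air", {"C": 0.012, "N": 75.527, "O": 23.178, "Ar": 1.283},
        1.197e-3),
}
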