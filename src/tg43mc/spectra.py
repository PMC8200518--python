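"""Ir-192 photon emission spectra: loading, validation and line sampling.

Two discrete line lists ship with the package: one assembled from the NNDC
decay-data evaluation (gammas plus K and L x rays) and one following the
older Duchemin-Coursol evaluation as propagated through the EGSnrc
brachytherapy literature.  See ``data/manifest.json`` for provenance notes.

The NNDC list's total photon yield is tied to the 2.363 photons-per-decay
constant used in the air-kerma bookkeeping, and that consistency is checked
at load time.  Lines at or below the air-kerma energy cutoff delta
(10 keV by default) are retained for emission sampling but flagged, so they
count as initial photons while contributing nothing above the cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["EmissionLine", "EmissionSpectrum", "load_spectrum",
           "sample_emission_energy", "SpectrumError"]

#: Average number of photons emitted per Ir-192 decay used by the
#: air-kerma-strength bookkeeping.
PHOTONS_PER_DECAY = 2.363

#: Default air-kerma energy cutoff delta, MeV.
DEFAULT_CUTOFF_MEV = 0.010

_LABELS = {
    "NNDC": "ir192_nndc.csv",
    "DuchemCoursol": "ir192_duchemin_coursol.csv",
}


class SpectrumError(ValueError):
    pass


@dataclass(frozen=True)
class EmissionLine:
    energy_mev: float
    photons_per_decay: float
    below_cutoff: bool = False


@dataclass(frozen=True)
class EmissionSpectrum:
    """Ordered discrete photon line spectrum."""

    lines: tuple
    label: str = ""

    # derived arrays, filled in __post_init__
    energies: np.ndarray = field(default=None, repr=False, compare=False)
    intensities: np.ndarray = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        e = np.array([ln.energy_mev for ln in self.lines])
        i = np.array([ln.photons_per_decay for ln in self.lines])
        object.__setattr__(self, "energies", e)
        object.__setattr__(self, "intensities", i)

    @property
    def total_yield(self):
        """Total photons per decay (all lines, flagged ones included)."""
        return float(self.intensities.sum())

    @property
    def mean_energy(self):
        return float((self.energies * self.intensities).sum()
                     / self.intensities.sum())

    def sampling_cdf(self):
        """Cumulative line-sampling probabilities (ends at exactly 1)."""
        c = np.cumsum(self.intensities) / self.intensities.sum()
        c[-1] = 1.0
        return c


def _validate(df, label, cutoff_mev):
    if len(df) == 0:
        raise SpectrumError(f"{label}: empty spectrum file")
    lines = []
    prev_e = -np.inf
    for row_no, (e, inten) in enumerate(
            zip(df["energy_MeV"], df["photons_per_decay"]), start=1):
        if not np.isfinite(e) or not np.isfinite(inten):
            raise SpectrumError(f"{label}: non-finite value at row {row_no}")
        if inten <= 0:
            raise SpectrumError(
                f"{label}: non-positive intensity at row {row_no}")
        if e <= prev_e:
            raise SpectrumError(
                f"{label}: energies not strictly ascending at row {row_no}")
        if not (0.005 < e < 1.5):
            raise SpectrumError(
                f"{label}: energy {e} MeV out of range at row {row_no}")
        lines.append(EmissionLine(float(e), float(inten),
                                  below_cutoff=bool(e <= cutoff_mev)))
        prev_e = e
    # kerma-relevant lines must sit inside the tabulated attenuation span
    for row_no, ln in enumerate(lines, start=1):
        if not ln.below_cutoff and not (0.01 < ln.energy_mev < 1.5):
            raise SpectrumError(
                f"{label}: unflagged line outside (0.01, 1.5) MeV "
                f"at row {row_no}")
    spec = EmissionSpectrum(lines=tuple(lines), label=label)
    if label == "NNDC":
        if abs(spec.total_yield - PHOTONS_PER_DECAY) > 0.005 * PHOTONS_PER_DECAY:
            raise SpectrumError(
                f"NNDC total photon yield {spec.total_yield:.4f} deviates "
                f"from {PHOTONS_PER_DECAY} by more than 0.5%")
    return spec


def load_spectrum(source, cutoff_mev=DEFAULT_CUTOFF_MEV):
    """Load and validate an emission spectrum.

    ``source`` is either a fixture label (``"NNDC"`` or ``"DuchemCoursol"``)
    or a path to a two-column CSV ``energy_MeV,photons_per_decay`` (header
    optional, ``#`` comments allowed).
    """
    if isinstance(source, str) and source in _LABELS:
        ref = resources.files("tg43mc.data.spectra") / _LABELS[source]
        with resources.as_file(ref) as path:
            df = _read_two_column(path)
        label = source
    else:
        df = _read_two_column(Path(source))
        label = Path(source).stem
    return _validate(df, label, cutoff_mev)


def _read_two_column(path):
    df = pd.read_csv(path, comment="#")
    cols = [c.strip() for c in df.columns]
    if "energy_MeV" not in cols:
        # headerless file: first row was data
        df = pd.read_csv(path, comment="#", header=None,
                         names=["energy_MeV", "photons_per_decay"])
    else:
        df.columns = cols
    return df[["energy_MeV", "photons_per_decay"]].astype(float)


def sample_emission_energy(spectrum, u):
    """Map uniform draws ``u`` in [0, 1) to line energies by inverse CDF.

    Line ``i`` is selected with probability ``intensity_i / total``;
    ``u = 0`` maps to the lowest-energy line (CDF is right-continuous:
    line ``i`` owns the half-open interval [cdf_{i-1}, cdf_i)).
    """
    cdf = spectrum.sampling_cdf()
    idx = np.searchsorted(cdf, np.asarray(u), side="right")
    idx = np.clip(idx, 0, len(cdf) - 1)
    return spectrum.energies[idx]
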