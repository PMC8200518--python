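"""Comparison against published reference datasets and report rendering.

The package bundles, as reference fixtures, the published dosimetry
scalars for this source model (air-kerma strength per activity and
dose-rate constant for the two spectra, the consensus values, the radial
fit coefficients) and the published 2D anisotropy-function table with its
"/" markers for cells inside or within 2 mm of the source.  Full external
consensus g_L/F datasets are not bundled; comparisons against those are
optional user-supplied inputs.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .tg43 import DoseRateTable

__all__ = ["ReferenceDataset", "load_reference_scalars",
           "load_reference_anisotropy", "anisotropy_to_csv",
           "relative_difference", "compare_anisotropy", "render_report",
           "CompareError"]


class CompareError(ValueError):
    pass


@dataclass(frozen=True)
class ReferenceDataset:
    """A labelled set of published dosimetry values."""

    label: str
    sk_per_a_u_per_bq: float = None
    dose_rate_constant: float = None
    gl_fit_coefficients: np.ndarray = None
    anisotropy: DoseRateTable = None
    provenance: str = ""


def load_reference_scalars():
    """Dict of label -> ReferenceDataset for the bundled scalars."""
    ref = resources.files("tg43mc.data.reference") / "reference_scalars.json"
    with resources.as_file(ref) as path:
        raw = json.loads(open(path).read())
    out = {}
    for label, vals in raw.items():
        coeffs = vals.get("gL_fit_coefficients")
        out[label] = ReferenceDataset(
            label=label,
            sk_per_a_u_per_bq=vals.get("Sk_per_A_U_per_Bq"),
            dose_rate_constant=vals.get("Lambda_cGy_per_h_per_U"),
            gl_fit_coefficients=np.asarray(coeffs) if coeffs else None,
            provenance="bundled reference fixture")
    return out


def _read_anisotropy_text():
    ref = resources.files("tg43mc.data.reference") / \
        "anisotropy_reference.csv"
    with resources.as_file(ref) as path:
        return open(path).read()


def parse_anisotropy_csv(text):
    """Parse an F(r,theta) CSV in the fixture layout.

    Returns (table, raw_cells): the numeric DoseRateTable and the verbatim
    cell strings (used for byte-exact re-rendering)."""
    df = pd.read_csv(io.StringIO(text), dtype=str)
    r = np.array([float(c[2:]) for c in df.columns[1:]])
    theta = df["theta_deg"].astype(float).to_numpy()
    vals = df.iloc[:, 1:].to_numpy()
    f = np.where(vals == "/", np.nan, vals).astype(float)
    avail = np.isfinite(f)
    table = DoseRateTable(r_cm=r, theta_deg=theta,
                          dose=np.where(avail, f, np.nan), available=avail)
    raw = np.column_stack([df["theta_deg"].to_numpy(), vals])
    return table, raw


def load_reference_anisotropy(return_raw=False):
    """The published F(r,theta) table as a DoseRateTable (F values in the
    ``dose`` field; '/' cells unavailable)."""
    table, raw = parse_anisotropy_csv(_read_anisotropy_text())
    return (table, raw) if return_raw else table


def anisotropy_to_csv(table, raw_cells=None, fmt="%.3f"):
    """Render an anisotropy table in the fixture layout ('/' for
    unavailable cells).  With ``raw_cells`` from
    :func:`parse_anisotropy_csv`, re-rendering is byte-exact."""
    theta = np.asarray(table.theta_deg)
    cols = ["theta_deg"] + [f"r_{_fmt_r(r)}" for r in table.r_cm]
    lines = [",".join(cols)]
    f = np.asarray(table.dose, float)
    avail = np.asarray(table.available, bool)
    for j, th in enumerate(theta):
        if raw_cells is not None:
            lines.append(",".join(raw_cells[j]))
            continue
        cells = [_fmt_r(th)]
        for i in range(len(table.r_cm)):
            cells.append(fmt % f[j, i] if avail[j, i] else "/")
        lines.append(",".join(cells))
    return "\n".join(lines) + "\n"


def _fmt_r(v):
    v = float(v)
    return str(int(v)) if v == int(v) else f"{v:g}"


def relative_difference(value, reference):
    """Percent difference, 100 * (value/reference - 1)."""
    if reference == 0:
        raise CompareError("zero reference value")
    return 100.0 * (value / reference - 1.0)


def compare_anisotropy(computed, reference, interior=(15.0, 165.0)):
    """Cell-wise percent differences between two F tables.

    The tables must share (or overlap on) a common grid; cells
    unavailable in either are excluded.  Returns a dict with the
    difference matrix and summary statistics (max |diff| for interior
    polar angles, max overall, mean per radius).
    """
    r_c = np.asarray(computed.r_cm, float)
    r_r = np.asarray(reference.r_cm, float)
    th_c = np.asarray(computed.theta_deg, float)
    th_r = np.asarray(reference.theta_deg, float)
    ri = [(i, int(np.argmin(np.abs(r_r - r)))) for i, r in enumerate(r_c)
          if np.min(np.abs(r_r - r)) < 0.051]
    ti = [(j, int(np.argmin(np.abs(th_r - t)))) for j, t in enumerate(th_c)
          if np.min(np.abs(th_r - t)) < 1.01]
    if not ri or not ti:
        raise CompareError("tables have no overlapping grid cells")
    diff = np.full((len(th_r), len(r_r)), np.nan)
    for j_c, j_r in ti:
        for i_c, i_r in ri:
            if computed.available[j_c, i_c] and reference.available[j_r, i_r]:
                diff[j_r, i_r] = relative_difference(
                    computed.dose[j_c, i_c], reference.dose[j_r, i_r])
    interior_mask = (th_r > interior[0])[:, None] & \
                    (th_r < interior[1])[:, None]
    finite = np.isfinite(diff)
    out = {
        "diff_percent": diff,
        "r_cm": r_r, "theta_deg": th_r,
        "max_abs_interior": float(np.nanmax(np.abs(
            np.where(interior_mask & finite, diff, np.nan))))
        if (interior_mask & finite).any() else np.nan,
        "max_abs_overall": float(np.nanmax(np.abs(diff[finite])))
        if finite.any() else np.nan,
        "mean_per_r": np.array([np.nanmean(diff[:, i])
                                if np.isfinite(diff[:, i]).any() else np.nan
                                for i in range(len(r_r))]),
    }
    return out


def render_report(results=None, references=None):
    """Deterministic Markdown report of computed vs reference dosimetry.

    ``results``: dict label -> dict with keys like ``sk_per_a_u_per_bq``,
    ``dose_rate_constant``, ``gl_fit_coefficients``, ``anisotropy``,
    ``metadata``.  Identical inputs give byte-identical output.
    """
    lines = ["# TG-43 dosimetry report", ""]
    results = results or {}
    references = references or {}
    if not results:
        return "\n".join(lines) + "\n"
    cons = references.get("consensus")
    lines.append("## Scalars")
    lines.append("")
    lines.append("| quantity | " + " | ".join(results) + " | consensus |")
    lines.append("|---" * (len(results) + 2) + "|")
    row_sk = ["S_K/A (U/Bq)"]
    row_lam = ["Lambda (cGy/h/U)"]
    for lab, res in results.items():
        sk = res.get("sk_per_a_u_per_bq")
        lam = res.get("dose_rate_constant")
        row_sk.append("" if sk is None else f"{sk:.4e}")
        row_lam.append("" if lam is None else f"{lam:.4f}")
    row_sk.append(f"{cons.sk_per_a_u_per_bq:.4e}" if cons else "")
    row_lam.append(f"{cons.dose_rate_constant:.4f}" if cons else "")
    lines.append("| " + " | ".join(row_sk) + " |")
    lines.append("| " + " | ".join(row_lam) + " |")
    if cons:
        lines.append("")
        for lab, res in results.items():
            sk = res.get("sk_per_a_u_per_bq")
            lam = res.get("dose_rate_constant")
            if sk is not None:
                lines.append(
                    f"- {lab}: S_K/A {relative_difference(sk, cons.sk_per_a_u_per_bq):+.2f}% "
                    f"vs consensus")
            if lam is not None:
                lines.append(
                    f"- {lab}: Lambda {relative_difference(lam, cons.dose_rate_constant):+.2f}% "
                    f"vs consensus")
    for lab, res in results.items():
        coeffs = res.get("gl_fit_coefficients")
        if coeffs is not None:
            lines.append("")
            lines.append(f"## Radial fit coefficients ({lab})")
            lines.append("")
            lines.append(", ".join(f"a{i} = {c:.6g}"
                                   for i, c in enumerate(coeffs)))
        comp = res.get("anisotropy_comparison")
        if comp is not None:
            lines.append("")
            lines.append(f"## Anisotropy comparison ({lab})")
            lines.append("")
            lines.append(f"- max |diff| for 15 < theta < 165 deg: "
                         f"{comp['max_abs_interior']:.2f}%")
            lines.append(f"- max |diff| overall: "
                         f"{comp['max_abs_overall']:.2f}%")
        meta = res.get("metadata")
        if meta:
            lines.append("")
            lines.append(f"## Run metadata ({lab})")
            lines.append("")
            for k in sorted(meta):
                lines.append(f"- {k}: {meta[k]}")
    return "\n".join(lines) + "\n"
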