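"""Regenerate the CSV/JSON fixtures under src/tg43mc/data/.

Run from the repository root:

    python scripts/build_physics_tables.py

Attenuation tables are composed by tg43mc.attenuation.build_attenuation_table
(see that module's docstring for the data pedigree).  The spectrum line
lists and reference datasets are written from the literal transcriptions
below; provenance is recorded in data/manifest.json.
"""

from __future__ import annotations

import json
from datetime import date
from pathlib import Path

import numpy as np

DATA = Path(__file__).resolve().parents[1] / "src" / "tg43mc" / "data"

# ---------------------------------------------------------------------------
# Ir-192 emission spectra: (energy keV, photons per 100 decays)
# ---------------------------------------------------------------------------
# Assembled from the NNDC decay-data evaluation for Ir-192: gamma lines plus
# Pt/Os K x rays and the L x-ray groups above 10 keV.  Intensities are then
# normalised so the total photon yield equals the 2.363 photons/decay
# constant used by the air-kerma bookkeeping (raw transcription sums to
# within ~2% of that; the uniform rescaling leaves every per-photon quantity
# unchanged).
NNDC_LINES = [
    (10.51, 0.25), (11.07, 2.20), (12.42, 0.05), (12.94, 0.55),
    (61.486, 1.19), (63.000, 2.05), (65.122, 2.63), (66.831, 4.53),
    (71.079, 0.240), (71.413, 0.462), (73.363, 0.163),
    (75.368, 0.530), (75.749, 1.021), (77.850, 0.362),
    (136.343, 0.199), (176.98, 0.0043), (201.311, 0.471), (205.794, 3.34),
    (283.267, 0.266), (295.956, 28.71), (308.455, 29.70), (316.506, 82.86),
    (329.17, 0.0174), (374.485, 0.726), (416.469, 0.670), (420.52, 0.069),
    (468.069, 47.84), (484.575, 3.189), (489.06, 0.438), (588.581, 4.522),
    (593.49, 0.0421), (599.41, 0.0039), (604.411, 8.216), (612.462, 5.34),
    (703.85, 0.0053), (765.8, 0.0013), (884.537, 0.291), (920.93, 0.008),
    (1061.48, 0.053), (1089.9, 0.0012), (1378.2, 0.0012),
]

# Duchemin & Coursol (1995) photon list as propagated through the EGSnrc
# brachytherapy literature; includes the ~9.4 keV L-alpha group (below the
# 10 keV air-kerma cutoff: emitted but flagged).  Kept verbatim per source,
# no renormalisation.
DC_LINES = [
    (9.44, 4.10), (11.07, 2.60), (12.94, 0.60),
    (61.486, 1.20), (63.000, 2.05), (65.122, 2.70), (66.831, 4.60),
    (71.25, 0.70), (73.36, 0.16), (75.55, 1.55), (77.85, 0.36),
    (136.343, 0.183), (201.311, 0.473), (205.794, 3.30),
    (283.267, 0.269), (295.956, 28.72), (308.455, 29.68), (316.506, 82.75),
    (329.17, 0.0172), (374.485, 0.727), (416.469, 0.670), (420.52, 0.069),
    (468.069, 47.81), (484.575, 3.187), (489.06, 0.427), (588.581, 4.52),
    (604.411, 8.23), (612.462, 5.31), (884.537, 0.288), (1061.48, 0.0531),
]

PHOTONS_PER_DECAY = 2.363


def write_spectrum(path, lines, normalise_to=None, header=""):
    e = np.array([l[0] for l in lines]) / 1000.0  # MeV
    i = np.array([l[1] for l in lines]) / 100.0   # per decay
    if normalise_to is not None:
        i = i * (normalise_to / i.sum())
    with open(path, "w") as fh:
        fh.write(header)
        fh.write("energy_MeV,photons_per_decay\n")
        for ej, ij in zip(e, i):
            fh.write(f"{ej:.6f},{ij:.6e}\n")
    return float(i.sum())


def write_attenuation():
    from tg43mc.attenuation import build_attenuation_table, table_to_frame
    for name in ("iridium", "steel316l", "steel304", "water", "air"):
        tab = build_attenuation_table(name)
        df = table_to_frame(tab)
        out = DATA / "attenuation" / f"{name}.csv"
        with open(out, "w") as fh:
            fh.write(f"# per-process mass attenuation for {name}, cm^2/g\n")
            df.to_csv(fh, index=False, float_format="%.6e")
        print("wrote", out)


# ---------------------------------------------------------------------------
# Reference datasets: published scalars, radial fit coefficients and the 2D
# anisotropy table for the GammaMed Plus source.
# ---------------------------------------------------------------------------
REFERENCE_SCALARS = {
    "this-work-NNDC": {
        "Sk_per_A_U_per_Bq": 1.0139e-7,
        "Lambda_cGy_per_h_per_U": 1.110,
        "gL_fit_coefficients": [0.9930, 0.007834, -0.0007279, -0.0001243,
                                8.184e-6, -1.528e-7],
    },
    "this-work-DC": {
        "Sk_per_A_U_per_Bq": 9.853e-8,
        "Lambda_cGy_per_h_per_U": 1.106,
        "gL_fit_coefficients": [0.9981, 0.00768, -0.0005617, -0.0001419,
                                8.622e-6, -1.49e-7],
    },
    "consensus": {
        "Sk_per_A_U_per_Bq": 9.790e-8,
        "Lambda_cGy_per_h_per_U": 1.117,
    },
}

TABLE2_R_CM = [0.4, 0.6, 0.8, 1, 1.5, 2, 3, 4, 5, 6, 8, 10]
TABLE2_ROWS = [
    (0,   ["0.687", "0.666", "0.639", "0.627", "0.618", "0.626", "0.660", "0.674", "0.660", "0.709", "0.756", "0.762"]),
    (1,   ["0.688", "0.660", "0.635", "0.627", "0.619", "0.628", "0.659", "0.680", "0.694", "0.715", "0.749", "0.780"]),
    (2,   ["0.691", "0.651", "0.617", "0.628", "0.632", "0.637", "0.666", "0.689", "0.709", "0.725", "0.757", "0.790"]),
    (3,   ["0.692", "0.646", "0.634", "0.629", "0.645", "0.651", "0.681", "0.705", "0.728", "0.738", "0.771", "0.793"]),
    (4,   ["0.694", "0.653", "0.645", "0.646", "0.657", "0.666", "0.689", "0.706", "0.726", "0.748", "0.775", "0.796"]),
    (5,   ["0.697", "0.668", "0.660", "0.672", "0.670", "0.681", "0.702", "0.725", "0.746", "0.755", "0.782", "0.800"]),
    (6,   ["0.709", "0.683", "0.665", "0.666", "0.684", "0.693", "0.715", "0.738", "0.749", "0.760", "0.792", "0.814"]),
    (7,   ["0.719", "0.694", "0.693", "0.684", "0.698", "0.705", "0.726", "0.743", "0.760", "0.772", "0.795", "0.818"]),
    (8,   ["0.726", "0.705", "0.703", "0.695", "0.712", "0.719", "0.739", "0.756", "0.771", "0.787", "0.802", "0.823"]),
    (9,   ["0.740", "0.720", "0.712", "0.718", "0.726", "0.736", "0.751", "0.766", "0.782", "0.794", "0.815", "0.833"]),
    (10,  ["0.749", "0.732", "0.727", "0.727", "0.741", "0.748", "0.764", "0.780", "0.796", "0.803", "0.824", "0.840"]),
    (15,  ["0.811", "0.797", "0.793", "0.798", "0.800", "0.806", "0.818", "0.823", "0.834", "0.847", "0.857", "0.873"]),
    (20,  ["0.858", "0.847", "0.850", "0.844", "0.849", "0.853", "0.862", "0.868", "0.876", "0.879", "0.889", "0.899"]),
    (30,  ["0.919", "0.912", "0.906", "0.912", "0.911", "0.913", "0.916", "0.919", "0.928", "0.926", "0.932", "0.936"]),
    (40,  ["0.949", "0.952", "0.948", "0.941", "0.948", "0.949", "0.952", "0.954", "0.959", "0.955", "0.957", "0.962"]),
    (50,  ["0.970", "0.973", "0.976", "0.976", "0.971", "0.971", "0.972", "0.974", "0.976", "0.976", "0.975", "0.978"]),
    (60,  ["0.985", "0.987", "0.987", "0.983", "0.985", "0.985", "0.986", "0.986", "0.984", "0.987", "0.989", "0.988"]),
    (70,  ["0.987", "0.995", "0.995", "0.992", "0.993", "0.994", "0.997", "0.996", "0.997", "0.995", "0.994", "0.994"]),
    (80,  ["0.996", "1.001", "0.998", "0.997", "0.998", "0.998", "1.000", "1.000", "0.996", "0.998", "0.998", "0.998"]),
    (90,  ["1", "1", "1", "1", "1", "1", "1", "1", "1", "1", "1", "1"]),
    (100, ["0.996", "1.000", "0.997", "0.995", "0.999", "0.998", "0.999", "0.999", "1.000", "0.998", "0.997", "0.999"]),
    (110, ["0.989", "0.997", "0.992", "0.990", "0.995", "0.997", "0.995", "0.993", "0.996", "0.995", "0.993", "0.994"]),
    (120, ["0.984", "0.987", "0.986", "0.985", "0.987", "0.985", "0.986", "0.986", "0.986", "0.987", "0.987", "0.988"]),
    (130, ["0.969", "0.973", "0.968", "0.978", "0.970", "0.970", "0.972", "0.973", "0.971", "0.973", "0.975", "0.978"]),
    (140, ["0.952", "0.952", "0.945", "0.945", "0.946", "0.947", "0.950", "0.951", "0.952", "0.955", "0.959", "0.962"]),
    (150, ["0.917", "0.914", "0.911", "0.911", "0.909", "0.914", "0.918", "0.916", "0.923", "0.925", "0.931", "0.933"]),
    (160, ["0.857", "0.849", "0.844", "0.845", "0.846", "0.853", "0.860", "0.866", "0.872", "0.876", "0.886", "0.896"]),
    (165, ["0.812", "0.799", "0.792", "0.789", "0.797", "0.803", "0.816", "0.823", "0.836", "0.840", "0.856", "0.866"]),
    (170, ["0.756", "0.728", "0.720", "0.709", "0.723", "0.732", "0.750", "0.765", "0.780", "0.789", "0.812", "0.830"]),
    (171, ["0.747", "0.706", "0.693", "0.701", "0.704", "0.717", "0.733", "0.748", "0.765", "0.777", "0.800", "0.818"]),
    (172, ["0.743", "0.689", "0.673", "0.676", "0.684", "0.700", "0.714", "0.735", "0.752", "0.762", "0.789", "0.810"]),
    (173, ["/", "0.667", "0.652", "0.660", "0.665", "0.674", "0.695", "0.712", "0.732", "0.747", "0.780", "0.794"]),
    (174, ["/", "0.658", "0.629", "0.655", "0.640", "0.650", "0.678", "0.698", "0.707", "0.734", "0.758", "0.788"]),
    (175, ["/", "/", "0.614", "0.609", "0.613", "0.626", "0.652", "0.677", "0.691", "0.716", "0.746", "0.777"]),
    (176, ["/", "/", "0.597", "0.691", "0.581", "0.593", "0.620", "0.642", "0.665", "0.692", "0.730", "0.751"]),
    (177, ["/", "/", "/", "/", "0.548", "0.547", "0.582", "0.611", "0.643", "0.661", "0.708", "0.740"]),
    (178, ["/", "/", "/", "/", "/", "/", "0.521", "0.550", "0.597", "0.609", "0.665", "0.713"]),
    (179, ["/", "/", "/", "/", "/", "/", "/", "/", "/", "/", "0.598", "0.642"]),
    (180, ["/", "/", "/", "/", "/", "/", "/", "/", "/", "/", "0.533", "0.611"]),
]


def write_reference():
    ref_dir = DATA / "reference"
    with open(ref_dir / "reference_scalars.json", "w") as fh:
        json.dump(REFERENCE_SCALARS, fh, indent=1)
    cols = ",".join(f"r_{r}" for r in TABLE2_R_CM)
    with open(ref_dir / "anisotropy_reference.csv", "w") as fh:
        fh.write(f"theta_deg,{cols}\n")
        for theta, vals in TABLE2_ROWS:
            fh.write(f"{theta}," + ",".join(vals) + "\n")
    print("wrote reference fixtures")


def main():
    hdr_n = ("# Ir-192 photon emission spectrum, NNDC evaluation "
             "(gammas + K/L x rays > 10 keV)\n"
             "# intensities normalised to a 2.363 photons/decay total; "
             "see data/manifest.json\n")
    hdr_d = ("# Ir-192 photon emission spectrum, Duchemin & Coursol (1995) "
             "lineage\n# kept verbatim per source, including the 9.44 keV "
             "L-alpha group below the 10 keV cutoff\n")
    t1 = write_spectrum(DATA / "spectra" / "ir192_nndc.csv", NNDC_LINES,
                        normalise_to=PHOTONS_PER_DECAY, header=hdr_n)
    t2 = write_spectrum(DATA / "spectra" / "ir192_duchemin_coursol.csv",
                        DC_LINES, header=hdr_d)
    print(f"NNDC total {t1:.4f}, Duchemin-Coursol total {t2:.4f}")
    write_attenuation()
    write_reference()
    manifest = {
        "generated": str(date.today()),
        "generator": "scripts/build_physics_tables.py",
        "spectra": {
            "ir192_nndc.csv": "NNDC decay-data evaluation transcription "
                              "(gammas + K and L x rays above 10 keV); "
                              "uniformly rescaled to the 2.363 "
                              "photons/decay bookkeeping constant",
            "ir192_duchemin_coursol.csv": "Duchemin & Coursol (1995) "
                              "evaluation as propagated through the EGSnrc "
                              "brachytherapy literature; verbatim, includes "
                              "the 9.44 keV group below the kerma cutoff",
        },
        "attenuation": "water/air totals and mu_en from the standard "
                       "19-energy reference compilation; per-process split "
                       "and metal tables computed by tg43mc.elements "
                       "(Klein-Nishina incoherent, Thomas-Fermi coherent, "
                       "anchor-interpolated photoelectric); see module "
                       "docstrings for the pedigree and expected accuracy",
        "reference": "published dosimetry scalars, radial-fit coefficients "
                     "and the 2D anisotropy table for the GammaMed Plus "
                     "source ('/' marks cells inside or within 2 mm of the "
                     "source)",
    }
    with open(DATA / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    print("wrote manifest")


if __name__ == "__main__":
    main()
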