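{
 "generated": "2026-09-21",
 "generator": "scripts/build_physics_tables.py",
 "spectra": {
  "ir192_nndc.csv": "NNDC decay-data evaluation transcription (gammas + K and L x rays above 10 keV); uniformly rescaled to the 2.363 photons/decay bookkeeping constant",
  "ir192_duchemin_coursol.csv": "Duchemin & Coursol (1995) evaluation as propagated through the EGSnrc brachytherapy literature; verbatim, includes the 9.44 keV group below the kerma cutoff"
 },
 "attenuation": "water/air totals and mu_en from the standard 19-energy reference compilation; per-process split and metal tables computed by tg43mc.elements (Klein-Nishina incoherent, Thomas-Fermi coherent, anchor-interpolated photoelectric); see module docstrings for the pedigree and expected accuracy",
 "reference": "published dosimetry scalars, radial-fit coefficients and the 2D anisotropy table for the GammaMed Plus source ('/' marks cells inside or within 2 mm of the source)"
}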