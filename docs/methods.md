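# Methods

This note documents the models behind `tg43mc`: what is simulated, with
which data and approximations, how the estimators work, and what the
package's agreement with published values does and does not demonstrate.

## Source term

Two discrete ¹⁹²Ir photon line lists ship as fixtures
(`data/spectra/`):

* **NNDC** — gammas plus Pt/Os K x rays and the L x-ray groups above
  10 keV, transcribed from the NNDC decay-data evaluation.  The raw
  transcription is uniformly rescaled (×1.016) so the total yield equals
  the 2.363 photons-per-decay constant used by the air-kerma bookkeeping;
  a uniform rescale changes no per-photon quantity (sampling
  probabilities, S_K, Λ and F are all invariant), it only makes the
  fixture self-consistent with that constant.
* **Duchemin–Coursol** — the older evaluation as propagated through the
  EGSnrc brachytherapy literature, kept verbatim (total 2.373), including
  the ≈9.4 keV L-α group.  Lines at or below the 10 keV cutoff are
  emitted (they count as initial photons) but terminate at birth, which
  is how the two spectra produce different per-photon air-kerma.

The lists are best-effort transcriptions; the intensities of the weak
lines and x-ray groups carry a few-percent uncertainty, which is the
dominant systematic in the NNDC-vs-Duchemin–Coursol S_K split (we obtain
+2.5% against a published +2.9%).

Emission positions are sampled uniformly in the core volume
(inverse-CDF in ρ², φ, z); directions are isotropic; line energies by
inverse CDF, with u = 0 mapping to the lowest line.

## Interaction data

Per-material tables (`data/attenuation/*.csv`, 10 keV–1.5 MeV, log-log
interpolated, exact at grid points) are a computed compilation, not a
database transcription:

* **Water and dry air**: total μ/ρ and μ_en/ρ follow the standard
  19-energy reference compilation for those media; the per-process split
  assigns the binding-corrected Klein–Nishina value to incoherent
  scattering and the form-factor model below to coherent, with
  photoelectric as the residual, so the columns sum to the transcribed
  total exactly.
* **Iridium and the steels**: composed from a per-element model via the
  mass-fraction mixture rule — incoherent = Klein–Nishina × S(q)/Z
  (Waller–Hartree one-electron S from the Thomas–Fermi/Molière form
  factor; a <0.5% correction with this S), coherent = Thomson ×
  |F_TF(q)|² integrated over angle, photoelectric = log-log interpolation
  through per-element anchors derived from remembered standard totals for
  C/N/O/Al/Si/Fe/Cu/W/Pb (with Ir interpolated between W and Pb at fixed
  E/E_K so its 76.1 keV K edge is respected).  Composite water/air totals
  reproduce the reference compilation within ~0.5%; the metal totals are
  estimated good to ~1–2% at the energies that matter (0.3–0.6 MeV).

Densities and compositions are the conventional ones for this source
model, including the 5.6 g/cm³ *effective* density of the woven 304
cable.

## Geometry

Three coaxial right cylinders: core (radius 0.03 cm, length 0.35 cm),
capsule envelope (radius 0.045 cm, flat distal tip 0.062 cm thick,
proximal wall 0.065 cm), cable (radius 0.045 cm, length 6 cm).  Only the
core, capsule diameter and cable length are published in running text;
the tip and proximal thicknesses are drawing-derived defaults,
overridable in `SourceModel`.  +z is the distal tip (θ = 0); boundary
points belong to the inner region.  Ray tracing is exact
(quadratic/slab intersections, one interval per convex region), with a
property suite asserting segment-sum and midpoint-material consistency
on random rays.

## Transport

Analog photon transport: free flights sampled from the
piecewise-exponential law across the heterogeneous segments; interaction
type with probability μ_process/μ_total; photoelectric terminates the
history (fluorescence is neglected — the regenerated 65–78 keV K x rays
are reabsorbed within the metal for the geometries scored here);
incoherent scattering samples the free-electron Klein–Nishina
distribution by rejection with the Compton energy shift; photons below
10 keV terminate.  Coherent scattering keeps the energy and samples the
Thomson law **modulated by the squared form factor** of the material
(inverse-CDF in q² with a (1+cos²θ)/2 rejection).  Bare Thomson angles
are available (`PhysicsData(rayleigh_model="thomson")`, or disable
coherent entirely with `coherent_enabled=False`): with bare Thomson the
axial beam through the iridium core is over-diffused and F(1 cm, 0°)
drops by 3–4%, which is why the form-factor model is the default.

No electron transport: dose in water is collision kerma — track-length
fluence folded with μ_en/ρ of water — valid under charged-particle
equilibrium, i.e. beyond 2 mm from the capsule, exactly the region the
published tables report.  No Doppler broadening; no pair production
(<0.5% of μ at 1.5 MeV is absorbed into the residual column at anchor
energies).

## Estimators

* **Ring voxels.**  Tallies live on an (r, θ) grid of spherical-shell
  sectors (half-open bins, exact shell-integral volumes).  Track-length
  scoring finds every sphere/cone crossing of each flight segment
  analytically.  By azimuthal symmetry a ring is equivalent to the
  Cartesian voxel it contains at a small fraction of the variance; this
  is what makes 10⁶–10⁷-history reproductions possible.  Ring-average
  doses are converted to bin-centre values by dividing out the
  cell-averaged geometry-function variation (the assumption that dose
  varies like G_L within a cell is the TG-43 decomposition itself); the
  headline grid uses 2 mm shells at 1 and 3 cm with 3° polar caps, over
  which the published F varies by <0.5%.
* **Air region.**  The 10 × 10 × 0.05 cm³ scoring region at 1 m on the
  transverse plane is estimated three ways: an analog track-length box
  tally; a next-event (expected-value) estimate of the uncollided
  fluence, exp(−Στ)/(4πd²) traced from every emission point; and a
  point-detector next-event estimate of the collided fluence from every
  interaction (per-steradian scattering density toward the detector,
  matching the sampled angular models).  The headline S_K uses the
  next-event pair (uncollided ≈ 94% of the kerma); the analog tally
  cross-checks it within statistics after the finite-region
  inverse-square correction (computed numerically as ≈1.0017; the
  literature quotes 0.22% for this correction and the discrepancy is
  noted, not hidden — S_K via next-event needs no correction at all).
* **Air-kerma strength.**  k̇ per initial photon is the kerma fold of the
  1 m fluence spectrum (5 keV bins for reporting; an exact-energy fold is
  kept alongside and agrees within 0.1%).  S_K/A = 3.6×10⁹ · k̇d²
  [Gy·m²] · 2.363 U/Bq; the 3.6×10⁹ bundles s→h, Gy→cGy and m²→cm².
  Default transport is through dry air (attenuation and scatter buildup
  both represented); a vacuum mode (source self-absorption only) is also
  available, and both are reported.
* **Uncertainties** come from ≥2 independent batches (default 10; the
  scaled-down runs use 4); per-batch and per-chunk RNG streams are
  spawned from the root seed, so a run is bit-reproducible.  The
  point-detector term is heavy-tailed (rare air collisions near the
  detector contribute large 1/d′² spikes), so small S_K runs can show
  percent-level batch scatter; the batch standard error reports it
  honestly, and at the 10⁶-history acceptance scale it is ≲0.1%.

## Extraction

Λ = Ḋ(1 cm, 90°)/(k̇d²) with both per initial photon, so all
activity/time conversions cancel.  g_L and F are the standard
geometry-function-corrected ratios, exactly 1 at their reference
arguments by construction; the fifth-order g_L fit is unweighted least
squares without constraining g_L(1) = 1 (the published coefficients
evaluate to 0.99999 there, indicating none was imposed).  F cells inside
or within 2 mm of the capsule are masked, mirroring the "/" convention of
the published table.  Reconstruction interpolates g_L linearly in r (or
the polynomial on request) and F bilinearly.

## Verification

Every stage has an independent oracle: a numeric line integral for G_L,
adaptive quadrature of the Klein–Nishina form for the Compton sampler
(total also against the closed form), inverse-square recovery in vacuum
for the tally chain, Monte Carlo integration against quadrature for the
finite-region correction, and synthetic dose tables built by
forward-evaluating the dose-rate equation (with optional relative
Gaussian noise) that the extraction routines must invert exactly.

## Run sizes and accuracy

The packaged test suite uses 4.8×10⁶ water histories (NNDC), 10⁶ (D&C)
and 2×10⁵-scale air runs; `scripts/acceptance.py` uses 10⁷ / 6×10⁶ / 10⁶.
At those sizes, statistical precision is ~0.3% on Λ and ~1–2% in the
polar anisotropy cells.  Against the published values for this source
model we observe: S_K/A −1.6% (NNDC) and −1.2% (D&C); Λ −0.9% (NNDC) and
−0.4% (D&C); F within ~0.5% at (3 cm, 30°) and (1 cm, 170°), and −2 to
−4% at (1 cm, 0°) — the most heavily filtered point, where the remaining
physics simplifications (percent-level metal cross-section accuracy, the
approximate incoherent scattering function, tip micro-geometry) matter
most.  These offsets sit inside the few-percent budget expected when
replacing a condensed-history general-purpose code with free-electron
Compton physics and a transcribed data pedigree.

Passing these checks shows the chain — spectra, geometry, transport,
estimators, extraction — is internally consistent and reproduces the
published dosimetry of this source at the stated tolerances.  It does
not validate the package for other source models, for r < 2 mm (no
electron transport, no beta spectrum), or for media beyond water/air.
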