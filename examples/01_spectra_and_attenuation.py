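"""Load the Ir-192 emission spectra and the photon attenuation tables.

Prints the total photon yield and mean energy of each spectrum and a few
interpolated attenuation coefficients for the source materials.
"""

from tg43mc import load_attenuation, load_spectrum

for label in ("NNDC", "DuchemCoursol"):
    spec = load_spectrum(label)
    flagged = sum(ln.below_cutoff for ln in spec.lines)
    print(f"{label}: {len(spec.lines)} lines, "
          f"{spec.total_yield:.3f} photons/decay, "
          f"mean energy {spec.mean_energy * 1000:.1f} keV "
          f"({flagged} below the 10 keV kerma cutoff)")

print()
e = 0.3165  # the dominant emission line, MeV
for name in ("iridium", "steel316l", "water", "air"):
    tab = load_attenuation(name)
    print(f"mu/rho of {name:10s} at {e*1000:.1f} keV: "
          f"{tab.mu_at(e):.4f} cm^2/g "
          f"(photoelectric {tab.mu_at(e, 'photoelectric'):.4f}, "
          f"incoherent {tab.mu_at(e, 'incoherent'):.4f})")

# The mass energy-absorption coefficient enters the kerma fold; it is
# stocked for the dosimetry media only.
w = load_attenuation("water")
print(f"\nmu_en/rho of water at {e*1000:.1f} keV: {w.mu_en_at(e):.5f} cm^2/g")
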