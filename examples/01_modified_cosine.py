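"""Modified-cosine similarity between a compound and a shifted analog.

Builds a reference spectrum and an analog carrying one extra glycine
residue (+57.02146 Da) on its two largest fragments, then aligns them.
The shifted fragments still match because the kernel allows peaks to pair
at an offset equal to the precursor mass difference.
"""

from actinonet import Spectrum, align_spectra

GLYCINE = 57.02146

reference = Spectrum.from_peaks("reference", 400.0, [(100, 1.0), (150, 2.0), (390, 1.0)])
analog = Spectrum.from_peaks(
    "analog", 400.0 + GLYCINE, [(100, 1.0), (150 + GLYCINE, 2.0), (390 + GLYCINE, 1.0)]
)

alignment = align_spectra(reference, analog, fragment_tol=0.02)
print(f"score = {alignment.score:.4f}, matched peaks = {alignment.n_matched}")
for m in alignment.matches:
    kind = "shifted" if m.shifted else "direct "
    print(f"  {kind}: {m.mz_a:8.3f} <-> {m.mz_b:8.3f}  (weight {m.weight:.3f})")

# A score of 1.0 with 3 matched peaks (one direct, two glycine-shifted)
# says the analog's fragmentation is fully explained by the reference plus
# one +57.02146 Da modification.
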