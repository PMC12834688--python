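# actinonet

Molecular networking and discovery-potential statistics for microbial
untargeted LC-MS/MS studies.

Large natural-product screens culture hundreds of bacterial strains
(typically *Actinomycetes*) on several media, acquire tandem mass spectra
(MS/MS) of their extracts, and ask two questions: *which molecules did we
detect?* and *how much of the detected chemistry is still unknown?*
`actinonet` implements the standard analysis chain for such studies as a
tested, reusable Python library:

1. **Spectrum cleanup** — fragment ions within ±17 Da of the precursor are
   removed and only the 6 most intense peaks in every ±50 Da window are
   kept.
2. **Consensus clustering** — near-identical MS/MS scans across files
   (precursor within 0.02 Da, cosine ≥ 0.7) are merged into "unique MS/MS"
   consensus spectra.
3. **Molecular networking** — all consensus pairs are scored with the
   *modified cosine* and connected when the score is ≥ 0.7 with ≥ 6
   matched peaks; edges must be mutual top-10 neighbours, and connected
   components ("molecular families") are capped at 100 nodes by removing
   their lowest-scoring edges.
4. **Annotation** — exact spectral-library dereplication (precursor within
   0.02 Da) followed by analog/"suspect" annotation (precursor delta up to
   200 Da), with fragment-level localisation of the mass shift.
5. **Discovery statistics** — rarefaction/accumulation curves over
   strains, UpSet-style media-overlap counts, annotation rates and the
   pathway × media matrix normalised per pathway.

A synthetic study generator (`actinonet.synthetic`) emulates the whole
strains × media design — structural families related by biochemical mass
offsets, media-dependent production, redundant ion forms ([M+H]⁺, [M+Na]⁺,
[2M+H]⁺, in-source fragments), ppm-scale m/z error, blank injections with
media background, and a library covering only ~13% of the true molecules —
so every stage is testable against ground truth without downloading data.

## The modified cosine

For spectra *a*, *b* with precursor difference Δ = prec(*b*) − prec(*a*),
peaks *i* ∈ *a*, *j* ∈ *b* may pair when |m/z<sub>i</sub> − m/z<sub>j</sub>| ≤ ε
or |m/z<sub>i</sub> + Δ − m/z<sub>j</sub>| ≤ ε (ε = 0.02 Da). With
intensities square-root transformed and each spectrum scaled to unit
Euclidean norm, the score is

    cos_mod(a, b) = max over one-to-one assignments M of Σ_(i,j)∈M  ŵ_i · ŵ_j

solved exactly as a maximum-weight bipartite matching. The shift term is
what lets an analog that carries one extra residue still match its parent
compound: unmodified fragments pair directly, modified ones pair at Δ.

Rarefaction uses the closed-form expectation
E[S(k)] = Σ<sub>i</sub> (1 − C(N−n<sub>i</sub>, k)/C(N, k)) alongside
seeded permutation averages, where n<sub>i</sub> is the number of strains
containing item *i*.

## Worked example

`examples/01_modified_cosine.py` aligns a reference spectrum with an
analog carrying a +57.02146 Da (glycine) modification:

```text
score = 1.0000, matched peaks = 3
  direct :  100.000 <->  100.000  (weight 0.250)
  shifted:  150.000 <->  207.021  (weight 0.500)
  shifted:  390.000 <->  447.021  (weight 0.250)
```

A score of 1.0 with one direct and two Δ-shifted pairs says the analog's
fragmentation is fully explained by the reference plus a single +57.02 Da
modification — and the smallest shifted fragment bounds where that
modification sits.

The full workflow is one call (`examples/06_full_pipeline.py`), or from
the shell:

```bash
actinonet simulate --out study --n-strains 5 --n-molecules 20 --n-families 5 --seed 7
actinonet run --config demo.yaml
```

The summary reports, among others, `total_consensus` (unique MS/MS),
`total_families`, the annotation rate at both denominators (raw spectra
and consensus), and counts of annotated vs unannotated families — the
unannotated remainder is the study's discovery potential.

The remaining scripts in `examples/` each demonstrate one capability:
study simulation with ground truth, clustering + networking, library
annotation with shift localisation, and the rarefaction/overlap
statistics.

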