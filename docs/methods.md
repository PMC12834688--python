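# Methods

This note records the models, conventions and deliberate simplifications
behind `actinonet`, in the order the pipeline applies them.

## Spectrum model and cleanup

A spectrum is a precursor (m/z, charge, optional retention time) plus a
centroided peak list, normalised on construction: peaks sorted strictly
ascending in m/z, non-positive intensities dropped, peaks at exactly equal
m/z merged by intensity sum. A precursor below the largest fragment is
allowed — in-source fragments promoted to precursors legitimately look
like that.

Cleanup follows classical molecular-networking practice:

* **Precursor-region removal** (`precursor_region_window`, default 17 Da):
  every fragment with |m/z − precursor| ≤ 17 is removed. The boundary is
  inclusive — a peak at exactly precursor − 17 goes — because residual
  precursor/isotope signal carries no structural information and inflates
  self-similarity; erring toward removal is the conservative choice.
* **Windowed top-k filter** (`window_filter_k=6`, `window_filter_width=50` Da):
  a peak survives iff its intensity ranks in the top 6 among all peaks
  within ±50 Da *of its own m/z* — a per-peak sliding neighbourhood, not
  disjoint bins, matching the convention of the networking ecosystem.
  Intensity ties rank the lower-m/z peak first so the filter is
  deterministic. Both steps are idempotent.

Empty spectra after cleanup are dropped before clustering.

## Modified cosine

Candidate peak pairs are those matching directly (|δm/z| ≤ `fragment_tol`,
default 0.02 Da) or at the precursor difference Δ (|m/z_a + Δ − m/z_b| ≤
tol); a pair satisfying both counts once. Intensities are square-root
transformed and each spectrum's transformed vector scaled to unit
Euclidean norm — the upstream workflows do not document their weighting,
so this package adopts the ecosystem's usual √-intensity convention and
keeps it explicit in one place (`similarity._unit_sqrt`). The score is the
maximum total pair weight over one-to-one assignments, solved exactly with
`scipy.optimize.linear_sum_assignment` restricted to peaks that occur in
at least one candidate pair; `n_matched` counts the positive-weight pairs
of the optimal assignment. A greedy variant (descending pair weight) is
available via `method="greedy"` for speed; it lower-bounds the exact score
and is never used by the pipeline's tested path.

Charge handling: precursor m/z is used as-is (acquisition in these screens
defaults to charge 1); multi-charge Δ correction is out of scope.

## Exclusion lists and blanks

Acquisition-side suppression of culture-media ions is emulated in
software: blank-injection precursors are deduplicated (single linkage
within `exclusion_mz_tol` = 0.01 Da, half the precursor tolerance; each
group reports its mean) and any sample spectrum whose precursor falls
within tolerance of a list entry is dropped. Matching is on precursor m/z
only — the generator does not model chromatography, so no RT window.
Downstream, any consensus cluster whose blank-member fraction exceeds
`max_blank_fraction` (default 0: any blank membership) is removed.

## Consensus clustering

Industrial-scale clusterers use multi-round hashing heuristics whose
details are not reproducible from their descriptions; this package
substitutes a deterministic greedy single linkage: two spectra are
joinable iff |Δprecursor| ≤ `cluster_precursor_tol` (0.02 Da) and cosine ≥
`cluster_min_cosine` (0.7; Δ ≈ 0 inside a bucket so the modified cosine
degenerates to a plain cosine), and clusters are the transitive closure of
joinable pairs. Spectra are processed sorted by (precursor m/z,
spectrum id), making output ids deterministic; the partition itself is
provably order-independent. Consensus peaks pool the members, group within
`fragment_tol` (single linkage), emit intensity-weighted mean m/z with
summed intensity, and renormalise to a base peak of 1000; the consensus
precursor is the TIC-weighted mean of member precursors.

"Unique MS/MS" counts are reported for the whole study and per media
subset (the per-media set sizes of the overlap table), since either
denominator appears in the literature.

## Networking

All consensus pairs are scored (O(n²); an optional precursor-delta cap
exists but is off by default). Edges require cosine ≥ 0.7 and ≥ 6 matched
peaks. The mutual top-K filter (K = 10) ranks neighbours on the
threshold-filtered edge set — not on raw all-pairs scores — by descending
cosine with lexical tie-break; whether ranking precedes or follows
thresholding is not documented upstream, so the choice is configurable by
filtering order in user code. The family-size cap (100) repeatedly removes
the lowest-cosine edge (lexical tie-break) of an oversized component,
recomputing components after every single removal — exact and O(E·V)
worst case; correctness over speed at desk scale. Connected components of
the capped graph are the molecular families; isolated nodes are singleton
families, flagged as such.

The matched-peak threshold is applied inclusively (≥ 6) for both network
edges and library matches; workflow descriptions alternate between
"more than 6" and "at least 6", and the inclusive reading keeps the two
searches consistent. The value is configurable either way.

## Annotation

Library spectra are filtered with exactly the same cleanup as queries.
Exact dereplication takes the best entry with |Δprecursor| ≤ 0.02 Da at
cosine ≥ 0.7 and ≥ 6 matched peaks (ties: higher cosine, more matched
peaks, lexically first entry); one annotation per consensus. Analog
("suspect"-style propagated) annotation then considers only unannotated
consensus and entries with 0.02 < |Δ| ≤ `analog_max_delta` = 200 Da. Real
suspect libraries curate their deltas; the free ±200 Da window is a
surrogate sized to cover one-to-two residue/monomer differences, and is
flagged as such. Each analog hit carries a shifted-fragment report: the
matched pairs partitioned into direct and Δ-shifted sets and the smallest
shifted query fragment — the tightest bound on where the modification
resides along the fragment series. This is intentionally a fragment-level
simplification of modification-localisation tools, not atom-level
placement. A family is annotated iff ≥ 1 member node is.

## Discovery statistics

The incidence matrix marks item (consensus or family) presence per strain,
pooling a strain's media files — accumulation is per strain by default
(per file available) because strain count is the axis a screening campaign
controls. Rarefaction defaults to permutation averages
(`n_permutations=100`, seeded) rather than one fixed accumulation order:
the order-invariant estimate, with the fixed-order mode available. The
closed form E[S(k)] = Σᵢ (1 − C(N−nᵢ,k)/C(N,k)) is always computed
alongside (log-gamma arithmetic for range) and equals the all-orderings
mean exactly. Annotated/unannotated strata share the same seeded
permutations, so their curves add up to the total at every k.

Media-overlap (UpSet-style) counts report, per observed media
combination, the items whose media set is exactly that combination (a
partition of the items) plus per-media set sizes. Annotation rates are
reported against both denominators — raw spectra (member-weighted) and
consensus — because published studies mix them. The pathway × media
matrix counts annotated consensus per media membership and divides each
pathway row by its maximum; all-zero rows are dropped.

## Synthetic study generator

The generator's defaults define the package's study conditions: 20
strains × the five media (ISP-2, ISP-4, TSA, NSG, CZP), 60 molecules in
15 near-equal families, 13% of molecules in the reference library, 5 ppm
Gaussian m/z error, Poisson(3) noise peaks at 1–5% relative intensity,
and per-detection ion forms [M+H]⁺ (always) plus [M+Na]⁺ (p = 0.7),
[2M+H]⁺ (0.5) and an in-source fragment (0.7) — about three ion forms per
detected molecule, emulating the redundancy real screens report. Molecule
masses are U(200, 1800) Da with 8–40 fragments at log-normal(0, 1)
intensities; family members differ by cumulative sums of common
biochemical deltas (CH₂, H₂O, Gly, …) and shift 30–55% of their
fragments (the high-m/z ones) by their offset, so within-family modified
cosines are high and analog search is meaningful. Media production is
molecule-specific: each molecule produces on 1–5 media with Bernoulli
probability U(0.4, 0.9) per strain. Retention time is a U(30, 600) s
placeholder, never used in scoring.

Background (culture-media/solvent) molecules are low-mass (150–500 Da)
singletons present in every blank in all ion forms. By default they do
not appear in sample files — mirroring screens where media ions were
already suppressed at acquisition time — so the software exclusion stage
is a no-op on defaults; setting `background_in_samples > 0` puts them in
samples and exercises it. All randomness flows from one seed through
separate named streams (ground truth, background, simulation), and reruns
are byte-identical.

What passing tests on this generator do *not* show: robustness to real
fragmentation chemistry, isotope envelopes, co-elution/chimeric spectra,
ion suppression, or retention-time structure — none of which the
generator models.

## Problem sizes and numerical choices

The tested study conditions (20 × 5 files, ~7,000 spectra, ~220 consensus)
were chosen as the smallest design that still exercises every stage's
combinatorics — multi-member clusters across files, multi-family
networks, exact and analog annotation, and non-trivial rarefaction — while
a full pipeline run stays in seconds. Degenerate inputs are defined
throughout: empty spectra score 0 and are dropped after cleanup; an empty
library yields zero annotations with a warning; an empty annotated
stratum yields a zero curve. Ties are always broken lexically or toward
lower m/z, never by hash or insertion order.

## Known limitations

* Modified cosine is exact but O(n³) in matched-peak count per pair via
  the assignment solver; repository-scale inputs would need the greedy
  path or indexing, which the desk-scale scope deliberately omits.
* The clustering substitute can over-merge chained jitter (single-linkage
  transitivity) relative to centroid-based heuristics.
* Analog annotation with a free delta window can hit chance matches in
  dense libraries; no false-discovery-rate model is included.
* Pathway labels ride on library entries; no structure-based classifier
  is invoked.
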