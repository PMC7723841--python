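# Methods

## Scope and model

`molnet` reconstructs a molecular-networking workflow for seized-drug
screening: consensus MS/MS spectra are nodes, modification-tolerant
cosine similarities are edges, authentic standards form "training"
components, and unknowns inherit structural hypotheses from annotated
neighbors via precursor mass differences. The package operates on
centroided MGF spectra; everything upstream (acquisition, vendor-format
conversion, centroiding) is out of scope and is emulated by the
synthetic generator.

## Modified cosine

Peak weights are `intensity ** p` (default `p = 0.5`), normalized to unit
L2 norm per spectrum. Candidate pairs match directly or shifted by the
precursor difference, both within the fragment tolerance (0.02 Da). The
assignment is greedy over candidates sorted by descending weight product,
ties broken by smaller |m/z error| then lower peak indices; each peak is
used at most once, and a pair matchable both directly and shifted is
counted once. Shifted pairs count toward the matched-ion gate, since
shifted matches are precisely what link homologs.

Greedy assignment is standard practice but not globally optimal in
principle. The test suite compares it against an exhaustive
max-weight-assignment oracle on randomized instances whose candidate
conflicts are star-shaped (grid-spaced peaks, an off-grid precursor
delta, one-sided near-duplicate peaks); on that family the greedy choice
is provably optimal, so the equivalence check is exact rather than
statistical. Instances with crossing 2×2 conflicts can in principle make
greedy sub-optimal; they require two peaks of one spectrum within twice
the tolerance of each other, which centroided data at 0.02 Da rarely
contains.

## Consensus clustering

Single linkage over scans with three conjunctive gates: |Δprecursor| ≤
0.02 Da, |ΔRt| ≤ 30 s, modified cosine ≥ 0.7. The Rt window mirrors the
30 s dynamic-exclusion scale of the emulated acquisition; the cosine gate
keeps isobaric but chemically different species apart (the two m/z
351.243 species — α-methylfentanyl and the butyryl-type unknown — are
separated by both Rt and spectral dissimilarity). Consensus precursor is
the intensity-weighted member mean, Rt the mean, precursor intensity the
member maximum, charge the modal value (ties to the smaller charge).
Merged peaks are grouped by 1-D single linkage at the fragment tolerance;
merged intensity is the member mean with absent peaks counted as zero,
then normalized to base peak 100. Scans are sorted before clustering, so
the result is input-order invariant.

## Network construction

All-pairs modified cosine; edges kept at cosine ≥ 0.7 and ≥ 6 matched
ions (the stated workflow gates). Optional top-K pruning (default 10; an
edge survives only if each endpoint ranks the other in its top K by
cosine, then matched-ion count, then smaller |Δmass|) and a maximum
component size (default 100, enforced by iteratively deleting the
weakest in-component edge) mirror common platform defaults; both are
disabled (`None`) in the membership tests and the acceptance runs, which
probe the raw gated graph.

## Curation

Fixed order: (1) precursor-intensity floor, default 1e7 arbitrary units,
with annotated standards exempt; (2) artifact removal — an *unannotated*
node is flagged only when it co-elutes with an annotated standard (mean
Rt within 1 % of the standard's Rt) AND shows corroborating mass/charge
evidence: precursor charge 0, or precursor within 0.02 Da of the
standard's [M+H]+ − 1.0078 (the "[M−1]" reading adopted here; the
hydrogen mass is configurable). Co-elution alone never removes a node.
Both filters are idempotent.

## Annotation and propagation

The library is self-anchored: each packaged standard record is bound to
its G1 consensus node (precursor within 0.02 Da, nearest Rt), so library
matching inherits run-specific spectral detail; a theoretical-spectrum
library is available as a fallback. Matching requires precursor
agreement within 0.02 Da, cosine ≥ 0.7 and ≥ 6 matched ions. Class flags
demand *all* diagnostic fragments of a class within 0.01 Da (default
map: fentanyl core → 188.1434 and 105.0699); `require_all=False` relaxes
this to any.

Delta decomposition enumerates C 0–30, H −3–60, N 0–6, O 0–10, F 0–3,
S 0–2 (hydrogen may go negative to express substitutions such as +F −H)
and keeps candidates within 5 mDa, ranked by |mass error|, then total
atom count, then lexicographic element order — no ring-double-bond or
isotope filtering. A consequence worth knowing: near 94.005 Da the
compositions HFN3O2 (94.0053) and C5H2O2 (94.0055) differ by only
0.2 mDa, so the rank-1 candidate for that delta is measurement-noise
dependent; chemically informed reading of the candidate list remains the
analyst's task, which is why hypotheses carry the full ranked list and
mechanical labels rather than curated trivial names. Negative deltas are
decomposed as the negated composition.

## Synthetic acquisition generator

The generator emulates the study design the analysis assumes: triplicate
injections per group (G1 standards, G2/G3 seizures), three
collision-energy variants (NCE 20/30/40) per precursor, and per-class
spectral structure:

* each compound's characteristic fragments (the packaged two per
  cannabinoid; 188.1434/105.0699 for core fentanyls, 202.1590 replacing
  188.1434 for α-methylfentanyl);
* a class-shared neutral-loss offset series (six offsets per class,
  disjoint between classes) producing peaks at precursor − offset that
  shift with the precursor — the substrate for shifted matches. The
  series guarantees ≥ 6 direct-or-shifted matches for any same-class
  pair. Cannabinoid spectra put most intensity into the shared series
  (cross-subfamily edges must clear the cosine gate on shifted matches
  alone), while fentanyl spectra are dominated by the diagnostic core
  fragments (which keeps the isobaric 351.243 pair below the cosine gate
  relative to each other);
* m/z jitter: normal, sd 0.002 Th, truncated at ±3 sd so every non-noise
  peak stays within the documented envelope; multiplicative intensity
  noise (CV 0.2); five uniform noise peaks per spectrum below 5 % of the
  base peak; higher NCE tilts intensity toward low-mass fragments
  (exponential factor, gentle by design);
* precursor intensity levels: G1 standards 1e8–1e9; seizure main
  compounds 1e10–2e10; the three seizure-A unknown impurities 2–3 orders
  of magnitude below the main peaks yet above the 1e7 curation floor
  (5e7–1e8) — matching their reported roles as minor constituents that
  still appear in the final network;
* in-source artifacts for five parent standards: precursor at parent
  [M+H]+ − 1.0078, charge 0, Rt within ±0.1 % of the parent, intensity
  1e-3 of the parent, same fragment content.

Scenarios: `standards` (G1 only), `seizureA` (G1+G2), `seizureB` (the
full study, G1+G2+G3). Seizure compounds known only by precursor m/z are
simulated from their printed precursor and Rt with the core fragment
model — no full structures are assumed. Output is byte-identical for a
fixed seed (per-file RNG streams spawned from one seed sequence).

**What the generator does not emulate** — and hence what passing tests do
not show about real data: physical fragmentation chemistry (peak
positions are declared, not predicted), chromatographic peak shapes,
isotope envelopes, adducts beyond [M−1], detector saturation, and
between-run Rt drift. Membership claims verified on this generator
demonstrate that the pipeline's gates and graph logic reproduce the
intended behavior under the declared statistical structure, not that the
declared structure is chemically complete.

## Numerical choices and degenerate inputs

* Tolerances: fragment and precursor 0.02 Da; decomposition 5 mDa
  (printed deltas agree with formulas within ~1 mDa); diagnostic
  fragments 0.01 Da. All configurable.
* Empty spectra score cosine 0 with 0 matched ions; empty networks
  export as valid empty GraphML/TSV; an empty standards set yields no
  artifact flags.
* Element masses: C 12 exactly, H 1.0078250, N 14.0030740, O 15.9949146,
  F 18.9984032, S 31.9720707; proton 1.0072765; electron 0.0005486.
* Hydrogen counts in decomposition are solved in closed form per heavy-
  element combination, keeping the enumeration exhaustive at ~3·10^4
  combinations per call.
* Determinism: pipeline outputs are identical given (config, seed); the
  configuration hash (analysis parameters only, paths excluded) is
  written into every output header and the manifest.

## Problem sizes

The default study simulates 315 G1 scans (35 records × 3 NCE × 3
replicates) plus 39 G2 and 12 G3 scans; consensus, networking and
curation on this size complete in well under a second, and the 20-seed
membership and curation suites in a few seconds. These sizes were chosen
as the smallest that exercise every rule (triplicates, NCE variants,
artifacts, isobars, cross-group nodes) with full statistical structure.

## Known limitations

* The consensus step is a documented simplification of iterative
  clustering tools (no multi-round refinement or spectrum-quality
  filtering).
* Greedy assignment is exact only on conflict-light spectra (see above).
* Proposed labels are mechanical ("anchor + formula"); assigning
  trivial names requires chemistry outside the pipeline's scope.
* Library matching is restricted to the packaged standards; external
  spectral libraries and FDR estimation for matches are out of scope.
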