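# Methods

This note documents the model implemented by `phosloc`, the parameters that
matter, the synthetic data used to validate it, and the design choices made
where the design was genuinely open.

## Problem and model

An MS/MS spectrum is a peak list S = (m₁, i₁), …, (m_Q, i_Q).  Given a
search-engine first hit (sequence, non-phospho modifications, phosphate
count, precursor charge), every placement of the phosphates over the S/T/Y
residues is a candidate *configuration*.  The assignment problem is to pick
the configuration whose theoretical spectrum best explains the observed
peaks, using only the ions that can discriminate between placements.

**Theoretical spectra.**  For each configuration the b/y ladder is generated
for indices 1..L−1, crossed with six neutral-loss states (none, −H₂O, −NH₃,
−H₃PO₄, −H₃PO₄−H₂O, −H₃PO₄−NH₃) and fragment charges 1..z (z = precursor
charge by default).  b/y m/z values follow the standard recursions: the
singly-charged b neutral of index i is that of i−1 plus the residue mass
M(i); y is the complementary suffix plus water; charged m/z is
(neutral + z·proton)/z.  All masses are monoisotopic, taken from elemental
compositions (pyteomics); the water/ammonia/phosphoric-acid losses are
18.010565, 17.026549 and 97.976895 Da (their nominal 18/17/98 values are
treated as shorthand — at a 0.05 Da matching window, nominal masses would
systematically miss).  Phosphoric-acid losses are generated only from
fragments that contain a phosphate; water and ammonia losses are generated
for every fragment, with no residue-composition restriction.

**Site-determining ions.**  An ion of configuration c is site-determining
when some other configuration either lacks an ion of the same
(series, index, loss, charge) identity, or carries one differing in m/z by
more than the coincidence tolerance.  The "lacks" clause matters:
phosphoric-acid-loss satellites exist only where the fragment is
phosphorylated, so their mere presence is discriminating.  For two
placements i < j this reduces to the b ions with i ≤ index < j and the y
ions with L−j+1 ≤ index ≤ L−i (verified against a brute-force oracle in the
test suite).

**Coincident theoretical ions.**  Ions pooled over all configurations are
grouped by single-linkage chaining on sorted m/z with gap threshold equal to
the coincidence tolerance; copies of the *same* logical ion appearing in
several ladders count as one group member.  Per group: no site-determining
member → all dropped; mixed status → all dropped (the observed intensity
cannot be attributed); all site-determining and owned by one configuration →
merged into a single scoring target at the mean m/z (a matched observed peak
is counted once); all site-determining but spanning configurations → dropped,
since a shared m/z cannot discriminate between its owners.

**Scoring.**  The noise floor is ζ = f × (tallest peak of the whole
spectrum), f = 0.03 for HCD and 0.05 for CID (overridable).  For each
surviving site-determining target M the candidate match is the
maximum-intensity peak in the closed window [M − δ/2, M + δ/2], found by
binary search.  Φ is accumulated by the recursion
Φ(j) = max(I[M(j)]ₘₐₓ + Φ(j−1), Φ(j−1)) with Φ(0) = 0, admitting a candidate
only if it reaches ζ.  Because intensities are non-negative the recursion is
equivalent to thresholded summation; the equivalence is asserted exactly
against an independent brute-force implementation.  Work per configuration
is bounded by (L−1) × 12 × z target evaluations, i.e. linear in peptide
length and in spectrum count across a batch.

**Ranking and quality.**  Configurations are ranked by descending Φ, ties
broken by label for determinism; dCn = (Φ_best − Φ_second)/Φ_best.  An
assignment passes when its redundancy (number of scans whose top-ranked
configuration names the same peptide sequence and site set) reaches 7, or
when dCn strictly exceeds 0.99 and the top is not tied.  The redundancy
level comes from the chance-agreement model: under a per-scan uniform null
over n candidate sites, k agreeing scans are wrong with probability (1/n)^k,
so n = 2, k = 7 gives 99.22% confidence.

## Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| `window_delta` (δ) | 0.05 | Th | full matching-window width; set to the instrument mass accuracy |
| `min_rel_intensity_hcd` | 0.03 | fraction | ζ basis for HCD spectra |
| `min_rel_intensity_cid` | 0.05 | fraction | ζ basis for CID spectra |
| `min_rel_intensity` | unset | fraction | explicit override of the ζ basis |
| `max_fragment_charge` | precursor charge | — | fragment-charge ceiling (capped at the precursor charge) |
| `score_full_ladder` | false | — | score all surviving targets, not only site-determining ones |
| `dcn_threshold` | 0.99 | — | dCn gate (strict comparison) |
| `redundancy_threshold` | 7 | scans | redundancy gate (≥ comparison) |

Accuracy degrades when δ is far from the instrument accuracy in either
direction: too narrow loses genuine peaks, too wide admits neighbours.  ζ
trades sensitivity against noise matches; lowering the dCn gate passes more
spectra at the cost of accuracy.

## Design choices

* **y-ion formula.**  Defining y purely as a difference of b neutrals omits
  the water and proton of a physical y ion; the standard y-ion formula is
  used.  The b/y complementarity b(i) + y(L−i) = peptide neutral mass is a
  tested invariant.
* **One peak, one contribution.**  A single observed peak may lie in the
  window of several non-coincident targets.  Each observed peak contributes
  at most once per configuration — the first claimant in canonical ladder
  order (b before y, ascending index, loss order as in S, ascending charge)
  wins.  This prevents one dense spectral region from inflating Φ.
* **Site-determining-only scoring** is the default; the full-ladder variant
  exists behind `score_full_ladder` because shared ions add identical
  intensity to every configuration and only dilute dCn.
* **Coincidence tolerance = δ.**  Two theoretical ions closer than the
  matching resolution are indistinguishable when matching, so the same
  tolerance governs both.
* **dCn degenerate cases.**  A singleton candidate set returns dCn = 1 (one
  candidate site, nothing to confuse — it can pass); Φ_best = 0 with several
  candidates returns 0.  A tied top can never pass on dCn.
* **Zero-evidence scans carry no redundancy.**  A scan whose best Φ is 0
  matched nothing; with deterministic tie-breaking its "top" configuration
  is an artifact of label order, so such scans neither contribute a
  redundancy key nor draw on one (their redundancy is reported as 0).
  Without this rule a batch of evidence-free replicate spectra would pass by
  agreeing on the alphabetically first placement.
* **First hit only.**  Enumeration is seeded by the search engine's rank-1
  peptide; lower-ranked alternative sequences are not mixed in, and
  non-phospho variable modifications stay where the engine put them.

## Synthetic data

The simulator emits, per spectrum: the true configuration's full theoretical
ladder, each ion present with probability `peak_presence_prob` (default 0.9),
intensity drawn from a log-normal law (median 1000, σ = 0.6 in log), m/z
jittered by a centred Gaussian (sd 0.005 Th); plus `n_noise_peaks` (50)
uniform peaks over 100–1500 Th whose intensities stay below
median(law)/`site_determining_snr` (snr 10 by default, so the default noise
floor sits well under ζ).  Seven replicates per peptide drive the redundancy
criterion; the identification table reports the correct sequence and
phosphate count but a *random* placement, mimicking a search engine's
unreliable localization.  Three peptide families of increasing difficulty
shrink the distance between the true site and decoy S/T/Y residues, down to
a consecutive S/S/T run.

What this does **not** emulate: fragmentation chemistry (realistic relative
ion abundances, charge-state preferences, CID/HCD neutral-loss propensities),
isotope envelopes, chimeric spectra, and correlated (non-uniform) noise.
Passing the synthetic-recovery checks therefore demonstrates the scoring and
filtering machinery under a controlled signal/noise geometry, not performance
on real instrument data.

## Problem sizes and numerics

The heavier validation runs use 500 peptides × 7 replicates (3,500 spectra)
for the recovery check, 1,000 random peptide/spectrum instances for the
DP-equals-summation check, and a 200,000-draw Monte-Carlo check of the
chance-agreement model — sizes chosen to make the statistical assertions
stable while keeping the suite quick on a laptop.  Floating-point ties in
Φ are broken by configuration label; within a matching window, equal-intensity
peaks resolve to the lowest m/z.  Mass identities (recursion,
complementarity, phospho shifts) hold to 1e−9 Da in the tests.

## Known limitations

* ETD ion series (c/z), a-ions, internal fragments, immonium ions and
  isotope clusters are not modelled; the 12-type set is exhaustive for this
  scorer.
* Average-mass mode is not provided.
* Redundancy is pooled within one invocation (one batch), not across runs.
* The legacy `.out` reader extracts only the rank-1 peptide and charge;
  dialect variants beyond that are out of scope.
* No probabilistic (binomial) site-localization score and no false
  localization rate estimation; ambiguous calls are left ambiguous.
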