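# Methods

## Scope and model

`dbaffinity` implements a database-affinity identification/quantification
workflow for high-resolution LC-MS/MS of plant extracts, together with a
synthetic-data generator that emulates a complete study (runs, calibration
series, ABTS assay) for validation. The unit of analysis is a *feature*:
one detected precursor with retention time, *m/z*, peak area, an
A/A+1/A+2 isotope envelope and an optional MS/MS spectrum. Identification
is purely library-driven — no de novo or in-silico fragmentation is
attempted; the library's characteristic fragments are curated facts.

## Mass arithmetic

- Element masses and isotopic abundances come from the NIST table shipped
  with `pyteomics`; monoisotopic mass sums the most-abundant-isotope
  masses (lightest, for CHNOPS).
- Ion *m/z* adds one electron mass (0.000548579909 Da) per negative
  charge and subtracts one per positive charge, then divides by |z|.
  Only |z| = 1 occurs in the packaged library; the multi-charge contract
  is defined but untested against reference values.
- Two ppm-error conventions are exposed. `theoretical_denominator`
  (standard practice) divides by the exact theoretical *m/z* and is what
  every matching decision uses. `nominal_denominator` divides by the
  *integer part* of the theoretical *m/z* and exists solely to reproduce
  the reference tabulation this package models, whose printed errors are
  consistent with that denominator and with *truncation* (not rounding)
  at 4 decimals. The tabulated errors are also computed from the printed
  4-decimal *m/z* pair, so the report rounds both values to 4 decimals
  before taking the error. Neither convention is silently preferred: the
  report prints both.
- Isotope envelopes aggregate by nucleon offset: per-element isotope
  distributions are convolved count times (polynomial expansion),
  truncated to *n* peaks (default 3) and renormalized to unit sum. Fine
  structure within an offset is ignored, which is adequate at the
  3-peak/unit-resolution level the isotope-fit gate uses.

## The standards library

One record per authentic standard: neutral and ion formulas, polarity,
RT, characteristic MS/MS fragments (4-decimal, as curated), the subset of
fragments that are *diagnostic* within an isomer group, a reference
content (used only as simulation ground truth) and a bioactivity
annotation. Loading validates ids/names for uniqueness, diagnostic ⊆
characteristic, fragments below precursor + 0.01 Da, and (when a declared
theoretical *m/z* is present) agreement with the formula within 10 ppm.

Isomer groups are records sharing ion formula and charge. In the packaged
library there are four: {1,2,3}, {4,5,6}, {7,8}, {23,24} (10 members).
Diagnostic sets encode the published fragmentation narrative:
isoliquiritigenin's α-fragmentation pair 135.0441/119.0492 (135.0441 is
stored with its fragment list as a narrative augmentation of the
tabulated cell), pinocembrin's 213.0552/151.0029, wogonin's
163.0027/109.9998, oroxylin A's 268.0377, galangin 3-methyl ether's full
triplet. The pairs isoquercitrin/hyperoside and protocatechuic acid/
2,5-dihydroxybenzoic acid share (near-)identical fragment sets and are
resolved by RT; isoquercitrin's extra 255.0298 ion is kept as supporting
evidence only, not as a diagnostic.

## Identification decision rule

Per feature: S/N filter the spectrum (keep peaks ≥ 5× the median
intensity — the median is the noise-floor estimator, configurable),
keep the top-5 peaks; collect candidates of matching polarity within
10 ppm; gate each candidate on isotope fit (cosine ≥ 0.90), RT window
(±0.2 min) and, when a spectrum is present, at least one matched
characteristic fragment (±0.01 Da). If several candidates survive:

1. restrict to candidates whose diagnostic fragments all matched, when
   any candidate's did;
2. rank by (number of matched diagnostic fragments, number of matched
   fragments, fragment score);
3. break remaining ties by RT proximity within the tolerance; proximity
   ties within 0.01 min are *ambiguous*.

Step 2 is deliberate: with RT jitter comparable to the smallest intra-
group RT gaps (0.06 min for oroxylin A vs wogonin), RT proximity alone
would misassign a noticeable fraction of runs, whereas fragment-evidence
ranking resolves three of the four groups deterministically; only the
0.4-min-separated pair is RT-decided. Finally, assignment is one-to-one:
a standard claimed by several features keeps the best-|ppm| feature and
demotes the rest to ambiguous, which protects quantification from
double-counting.

Defaults: precursor 10 ppm, isotope fit 0.90, S/N 5, top-5 MS/MS — the
acquisition settings of the modeled workflow; RT tolerance 0.2 min (half
the smallest RT-resolved gap) and absolute fragment tolerance 0.01 Da
(4-decimal curated fragments make ppm windows sub-precision at low mass)
are this package's choices, all exposed in `MatchParams`. The cosine
isotope fit is a stand-in for the undisclosed vendor "isotopic pattern
fit" metric and is labeled as such here.

## Quantification

OLS (scipy `linregress`) per standard; r is the Pearson correlation of
the calibration points. Content conversion: (area − intercept)/slope
(µg/mL) ÷ 30 mg/mL solution concentration → mg/g lyophilized powder;
`basis="leaves"` multiplies by the 0.03 g/g extraction yield. The powder
basis is the default because the analyzed solution derives directly from
the powder; the report labels the basis. Negative back-calculated
concentrations (intercept noise near the detection limit) clamp to 0
with a warning. Replicates use the sample SD (n−1); a single replicate
is flagged. Weighted regression, LOD/LOQ and matrix-effect correction
are out of scope.

## ABTS scavenging and Q-marker

Scavenging% = (A₀ − A)/A₀ × 100. Out-of-range values (A > A₀ or
over-quench) pass through flagged, never clipped — assay drift is
information. "Relative antioxidant level" is interpreted as the
scavenging fraction (percent/100), making Eq. contribution =
level × content carry mg/g-equivalent units; the interpretation is
recorded in the report header. Replicate scavenging means feed the
contribution. The Q-marker is the maximal contribution; dominance
(contribution > sum of all others) is computed and reported. Ties break
toward the lower id with an explicit flag.

## Synthetic data

`simulate_run` emits one feature per library record plus decoy features:

- precursor and fragment *m/z* × (1 + ε), ε ~ N(0, 1 ppm);
- RT + N(0, 0.05 min), floored at 0;
- envelope = theoretical × (1 + N(0, 5%)), clipped non-negative;
- areas from per-standard true calibration lines (slopes log-uniform
  200–2000 area/(µg/mL) — about an order of magnitude of response
  spread — intercepts uniform 0–20 so trace constituents stay
  quantifiable) with 1% relative noise;
- fragment intensities log-normal (σ = 0.5) around 10⁴, with the true
  record's diagnostic fragments always the most intense;
- ~20 weak chemical-noise peaks per spectrum at ~1/50 of the fragment
  scale: they provide the noise floor that the S/N filter estimates (a
  spectrum containing only strong real fragments has no floor to
  measure);
- 20 decoy features at uniform *m/z* in the scanned 100–1500 Da range,
  kept ≥ 50 ppm away from every library ion (asserted at generation).

Replicate runs share one ground truth (contents, calibration lines,
scavenging) and differ only in derived noise seeds. Calibration series
use six levels (0.5–100 µg/mL; the modeled protocol documents only a
30 µg/mL standard solution, so the levels are a design choice) with 1%
relative area noise. ABTS readings draw A₀ ~ N(0.65, 0.01) truncated
positive and A = A₀(1 − p/100) + N(0, 0.005). The default scavenging
profile — six constituents (ids 18, 22, 24, 29, 32, 33) at 100%, ids
34–41 at 0%, all others at 50% — is a *reconstruction* consistent with
the modeled study's qualitative statements, not measured data; mid-range
values are a neutral assumption. All generators are pure functions of
(inputs, seed).

What the generator does **not** emulate: chromatographic peak shapes and
co-elution, RT drift between runs, matrix and ion-suppression effects,
in-source fragmentation, and correlated calibration errors. Passing
synthetic-recovery tests therefore demonstrates the correctness of the
decision logic and unit arithmetic under the stated noise model, not
instrument-grade performance on real extracts.

## Problem sizes and determinism

The validation suite runs one 61-feature run (41 true + 20 decoys) per
study, triplicate runs for quantification, 6-level calibrations, and
1000-query brute-force cross-checks of the candidate search — sizes at
which every check completes in seconds while still spanning the full
content range (0.003–14.418 mg/g). Identical inputs and seeds reproduce
byte-identical runs, reports and metrics.

## Known limitations

- The isotope-fit metric and the S/N noise-floor estimator are explicit
  stand-ins for undisclosed vendor definitions.
- Diagnostic-fragment sets are curated from a narrative source; absence
  evidence ("no *m/z* 135") is not modeled directly, only through the
  competing candidates' diagnostic requirements.
- Adducts beyond [M−H]⁻/[M+H]⁺, multi-charge ions in practice, and decoy
  (false-discovery) calibration of the identification are unsupported.
- Contents below ~0.01 mg/g sit near the synthetic calibration
  intercepts; their recovered values can carry large relative errors —
  the realistic near-LOD regime — which is why recovery criteria are
  stated on the median.
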