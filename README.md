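# dbaffinity

A library for **database-affinity LC-MS/MS analysis of herbal extracts**:
spectral-library identification of plant-extract constituents with isomer
discrimination, calibration-curve quantification, and ABTS-based
antioxidant-contribution scoring that selects a quality marker (Q-marker).

It is aimed at analytical chemists and method developers working with
high-resolution (Orbitrap-class) LC-MS/MS data on complex natural-product
mixtures. The packaged reference library describes the 41 authentic
standards of *Uvaria macrophylla* leaf constituents (36 negative-mode
[M−H]⁻ ions, 5 positive-mode [M+H]⁺, including four isomer groups), and a
synthetic-data module generates complete, seeded study bundles so that the
whole pipeline can be exercised and validated without instrument data.

## The method

**Identification.** A detected feature (RT, precursor *m/z*, A/A+1/A+2
isotope envelope, MS/MS spectrum) is identified by comparing four
parameters against each authentic standard:

1. *molecular ion* — |Δm/z| ≤ 10 ppm, with
   m/z<sub>theo</sub> = Σᵢ nᵢ·mᵢ ∓ z·mₑ (monoisotopic masses, electron
   mass mₑ = 0.000548579909 Da);
2. *isotope pattern* — cosine similarity of the unit-sum-scaled observed
   and theoretical envelopes ≥ 0.90;
3. *retention time* — |ΔRT| ≤ 0.2 min;
4. *MS/MS profile* — the spectrum is S/N-filtered (threshold 5 over the
   median noise floor), reduced to its top-5 peaks, and matched against
   the standard's characteristic fragments at ±0.01 Da.

Isobaric candidates (same ion formula) are separated first by **diagnostic
fragments** (e.g. the α-fragmentation pair *m/z* 135/119 of
isoliquiritigenin), then by the weight of fragment evidence, and finally
by RT proximity; each standard may be claimed by at most one feature.

**Quantification.** Per-standard calibration lines, area = a·c + b, are
fit by ordinary least squares; contents follow as
c = (area − b)/a (µg/mL), divided by the 30 mg/mL solution concentration
→ mg per g of lyophilized extract powder (optionally × 0.03 g/g yield →
per g of dried leaves), summarized as mean ± SD over triplicates.

**Q-marker selection.** ABTS⁺• scavenging% = (A₀ − A)/A₀ × 100 at 734 nm;
the antioxidant contribution of constituent *i* is

> contribution<sub>i</sub> = (scavenging%<sub>i</sub>/100) × content<sub>i</sub> (mg/g)

and the Q-marker is the constituent with the maximal contribution (its
dominance over the summed contributions of all others is also reported).

## Worked example

```sh
python examples/05_full_pipeline.py
```

```
summary:
  n_features: 61
  n_identified: 41
  n_ambiguous: 0
  isomer_groups_resolved: 4/4
  qmarker_id: 29
  qmarker_dominance: True
  content_basis: powder
  relative_level_definition: ABTS scavenging percent / 100

top antioxidant contributors:
  #1 id 29 gallic acid    content 4.794 +/- 0.022 mg/g, scavenging 100.1%, contribution 4.800
  #2 id 18 1,2,3,4,6-penta-O-galloyl-β-D-glucopyranose content 0.554 +/- 0.003 mg/g, scavenging 99.6%, contribution 0.552
  #3 id 19 sucrose        content 0.991 +/- 0.003 mg/g, scavenging 49.7%, contribution 0.493
```

All 61 features of the synthetic triplicate study (41 true constituents +
20 decoys) are processed; every constituent is identified with no false
positives, the four isomer groups are resolved, recovered contents match
the generator's ground truth (gallic acid: truth 4.800 mg/g), and gallic
acid is selected as the Q-marker with a contribution larger than the sum
of all others. The other examples (`examples/01`–`04`) walk through mass
arithmetic, identification, quantification and contribution scoring
individually.

A thin CLI wraps the same pipeline:

```sh
dbaffinity simulate --out bundle --seed 42
dbaffinity run --run bundle/run_rep1.mgf --run bundle/run_rep2.mgf \
    --run bundle/run_rep3.mgf --calibration bundle/calibration.csv \
    --assay bundle/assay.csv --out results
```

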