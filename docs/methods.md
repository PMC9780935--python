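# Methods

## Mass arithmetic

All masses derive from a fixed internal table of monoisotopic atomic
masses (C 12 exactly, H 1.00782503, N 14.00307401, O 15.99491462,
S 31.97207117 Da; electron 0.00054858 Da). The table is not user-editable:
reproducibility of printed-value comparisons outweighs configurability, and
the supported element set (C/H/N/O/S) covers the biotransformation
chemistry in scope. Ion m/z includes the electron mass —
[M−H]⁻ = M − m(H) + m(e) — because proton-only arithmetic shifts every
theoretical anion by ~1.5 ppm at m/z 350, visibly degrading agreement with
reference values at qToF accuracy.

ppm error is signed as (theoretical − observed)/theoretical × 10⁶. The
more common convention is (observed − theoretical), but the chosen sign
matches how the reference identifications report their errors; reports
round to one decimal, internal comparisons use full precision.

## Isotope patterns

Patterns are coarse: per-element isotope distributions are collapsed onto
integer nominal-mass offsets and convolved (numpy-array polynomial
products), with the exact m/z of each aggregated peak taken as the
abundance-weighted mean within the offset. Defaults: max offset 3, prune
1e-4 of the base peak. Fine structure is out of scope — the pattern check
in this pipeline is qualitative corroboration, not a fit. The agreement
score is 1 − mean |Δ relative abundance| over the union of offsets,
floored at 0; it is advisory (recorded on every hit) and only rejects a
hit below a floor of 0.5, because no quantitative acceptance criterion for
the isotope check is established for this workflow. Abundance table:
¹³C 1.07 %, ²H 0.0115 %, ¹⁵N 0.364 %, ¹⁷O/¹⁸O 0.038/0.205 %,
³³S/³⁴S/³⁶S 0.75/4.25/0.01 %.

## Candidate enumeration

Transformations are pure formula deltas; structure (regiochemistry,
stereochemistry, enzyme assignment) is explicitly out of scope. The
enumerator takes every multiset of phase I rules within per-rule bounds
(hydrogenation ≤ 2, others ≤ 1) and a global cap of 4 steps, then extends
each by at most one conjugate whose handle predicate is satisfied:
glucuronidation/sulfation require any oxygen-adding step, glycine/taurine
require carboxylation. The gate prevents chemically absurd candidates
(e.g. glucuronidation of the bare hydrocarbon) and reflects that no
conjugate of unoxidised limonene has been observed. Dehydrogenation (−H2)
is implemented but off by default: no observed metabolite requires it, and
enabling it merely enlarges the decoy space. Labels are deterministic
(parent, phase I tokens in fixed order +COOH, +OH, +OH+OH, +H2, then the
conjugate) and the library is label-sorted, so exports are diff-stable.

A known degeneracy: some distinct transformation multisets share an
elemental delta — carboxylation + hydroxylation + 2 hydrogenations equals
triple hydroxylation (diol + hydroxyl), both +O3H2. Mass-level annotation
cannot distinguish these; when such a tie occurs the ranking prefers the
candidate with fewer transformations, and distinguishing the isobaric
alternatives is left to MS/MS interpretation by the analyst. Likewise
"+OH+OH" (diol) does not resolve 1,2- vs 8,9-diol regiochemistry.

## Annotation

MS1 match: all (feature, candidate) pairs within the ppm tolerance
(default 10, the conventional qToF screening window); per-feature ranking
by |ppm| then by transformation count; ties are reported, never dropped,
since positional isomers legitimately share a formula. Retention time is
never used for identity — only to order isomer suffixes (I, II, III …)
within a shared label.

Fragment evidence uses an absolute tolerance of 0.005 Th by default:
printed product ions deviate from theory by up to ~5 mTh (e.g. the SO3
radical anion observed at 79.9568 vs theoretical 79.9574), which a ppm
tolerance sized for precursors would reject. Diagnostics above the
precursor m/z are never matched. The aglycone complement is computed from
the *theoretical* precursor m/z minus the neutral-loss mass. The taurine
rule carries two neutral losses because amide-bond cleavage can leave the
carbonyl on either side: loss of C2H5NO2S (aglycone acid anion) or of
C2H4O3S (aglycone acylium-type fragment); glycine conjugates analogously
lose CO2 or HCOOH.

Control exclusion operationalises "absent from non-supplemented groups" as
near-absence: a hit is excluded when the mean intensity in any control
group exceeds 5 % of the supplemented-group mean. Strict absence would be
brittle under integration noise; 5 % is the package's choice.

Confidence levels follow the Metabolomics Standards Initiative: level 2
when at least one diagnostic or the complement matched, level 3 for
MS1-only hits, never level 1 (no authentic standards in this workflow).

## Dose profiling

Urinary intensities are divided by per-sample creatinine; group means are
arithmetic means with zeros included (a non-detected metabolite contributes
0, so composition percents reflect true absence). Percent of total is per
group: mean/Σmeans × 100. The switching report is the per-metabolite
difference in percent participation between a low- and a high-dose group,
classed increased/decreased/stable with a ±0.5 percentage-point dead band —
the dead band is an implementation choice to keep rounding noise out of the
classification. Two-group tests: Shapiro–Wilk at α = 0.05 on *both* groups
routes to the two-sided two-sample t-test, otherwise to the Wilcoxon
rank-sum test. No multiple-testing correction is applied by default
(mirroring the single-compound screening context); a Benjamini–Hochberg
helper (`adjust_bh`) is available and off by default. The dose helpers
implement feed-content percent loss and the body-surface-area human
equivalent dose (dose × Km_animal/Km_human, mouse 3 / human 37). Note the
published human equivalents (7.2 and 46.4 mg/kg) differ slightly from
recomputation from the rounded printed intakes (90 × 3/37 = 7.3,
580 × 3/37 = 47.0); the package computes, and does not force agreement
with, such rounded chains.

## Synthetic cohorts

The generator emulates the study design: four groups (chow control NL,
high-fat control HL, and supplemented HL0.1/HL0.8), default 8 animals per
group, 16 planted urinary metabolite identities with group means
proportional to the published percent composition, log-normal
between-animal intensities at CV 0.4 (interindividual variability in
xenobiotic metabolism is high), Gaussian m/z jitter of 2 ppm, 50 decoy
features kept ≥ 0.05 Th from any library mass (far outside 10 ppm at
m/z ≤ 1000, so false-positive tests are unambiguous), creatinine per urine
sample (log-normal, mean 1.0, CV 0.3), and template MS2 spectra with 10 %
fragment dropout and 20 % abundance jitter. Control groups receive strict
zeros for planted metabolites; a leakage option exists to stress-test the
exclusion step. The log-normal uses σ_log = √log(1+CV²),
μ_log = log(mean) − σ_log²/2 so the configured mean is the distribution
mean. Everything is driven by one integer-seeded generator
(`numpy.random.default_rng`), so identical configs give bit-identical
cohorts.

What the simulator does *not* emulate: chromatographic peak shapes,
retention-time structure, in-source fragmentation, correlated matrix
backgrounds, missingness mechanisms other than hard zeros. Passing
synthetic tests therefore demonstrates the pipeline's logic under its own
statistical assumptions, not performance on raw instrument data.

## Problem sizes and numerical choices

Tests run the fixture screens at full size (23 features, 85-candidate
library) and synthetic benchmarks at 5–10 seeded cohorts of ~66 features;
the switching-direction recovery check uses 100 replicates at 8 animals
per group — sizes chosen so the whole suite completes in seconds while
estimates remain stable. Degenerate inputs fail loudly: empty formulas,
deprotonation without hydrogen, negative atom counts after a rule
application, all-zero composition groups, zero creatinine and missing
control samples all raise, rather than propagate NaNs.

## Known limitations

- Identity is elemental-formula-level; isobaric transformation multisets
  and positional isomers are indistinguishable by design.
- Only ±H adducts, singly charged, negative-mode fragment rules; no
  in-source fragments, multimers or multiply charged species.
- The packaged observed features carry printed 4-decimal m/z values, whose
  rounding limits ppm-error reproduction to ~±0.15 ppm.
- Creatinine normalisation assumes urine; liver profiles are compared on
  raw intensities.
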