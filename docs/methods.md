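# Methods

This note records the computational model the package implements, the
default parameter values, and why they were chosen. Problem sizes (library
size, replicate counts, permutation counts) are the package's own defaults
and are configurable.

## 1. Mass arithmetic and formula assignment

Spectra are negative-mode electrospray FT-ICR-MS peak lists; every ion is
treated as singly deprotonated, so the neutral mass is
`M = m/z + 1.00727646688` (proton mass). Monoisotopic atomic masses are
pinned in code: C 12 (exact), H 1.007825032, N 14.003074005, O 15.994914620,
S 31.972071174, P 30.973761998.

A candidate formula for an observed neutral mass is any CHNOSP composition
within the ppm tolerance that satisfies the plausibility rules
(`AssignmentRules`):

| Rule | Default | Rationale |
| --- | --- | --- |
| `tolerance_ppm` | 0.5 | conservative window for an instrument calibrated to < 0.07 ppm |
| element maxima | C ≤ 100, H ≤ 200, N ≤ 4, O ≤ 60, S ≤ 2, P ≤ 1 | N/S/P maxima mirror the heteroatom space the deletion ladder spans; C/H/O cover the 92.1–2000 Da window |
| `nsp_max` | 5 | combined N+S+P cap; the deletion ladder's richest patterns (N4S, S2P) carry 5 heteroatoms — compositions beyond that (e.g. N4S2P) are outside the admitted chemistry and generate irresolvable sub-0.2 mDa collisions with plain CHO formulas |
| `min_o_per_p` | 4 | P in negative-mode DOM is detected as phosphate esters; requiring O ≥ 4 per P is the standard rule in the FT-ICR assignment criteria this workflow follows, and removes chemically implausible low-O phosphorus candidates (e.g. C23H17O2P) that otherwise collide with N4-containing formulas |
| H/C | 0.3–2.5 | standard elemental-ratio filter for natural organic matter |
| O/C | ≤ 1.2 | same |
| DBE | integer, ≥ 0 | `DBE = 1 + (2C − H + N + P)/2`; valence constraint |
| `min_snr` | 4 | assignment threshold; weaker peaks are flagged sub-threshold |

Enumeration is exhaustive: the full rule grid for a mass range is built
once into a mass-sorted array database (about 10⁶ formulas for
92.1–1000 Da, under a second) and each query is a binary-search window.
The test suite proves equivalence against an independent brute-force
nested-loop oracle.

**Double assignments** (more than one candidate in the window) are
resolved by the heteroatom-priority deletion ladder, in this exact order:
NSP, N2S, N3S, N4S, N2P, N3P, N4P, NS2, S2P. Patterns match the candidate's
(n, s, p) tuple exactly — the printed list enumerates N2S, N3S, N4S
separately, which would be redundant under "at least" semantics. Deletion
stops as soon as one candidate remains; if several candidates survive the
full pass, the peak keeps no formula. This faithfully deletes, for
example, both members of an N4Ox / O≥4-phosphorus collision pair (neither
bare N4 nor bare P is a ladder pattern); the round-trip acceptance test's
residual ~4% loss below 500 Da is this behavior, not an implementation gap.

## 2. Quality control

Filters run in a fixed order, each one only ever shrinking the feature
set, idempotent, and logged:

1. **S/N ≥ 4** (applied during assignment).
2. **Alignment**: assigned peaks align by formula (the formula is the
   feature key); unassigned peaks cluster across spectra by single-linkage
   within the ppm tolerance, keyed by mean m/z. Each spectrum's minimum
   detected intensity is recorded here.
3. **Raised detection limit**: entries below 1.05 × the recorded
   per-spectrum minimum are set to not-detected. Using the *recorded*
   minimum (rather than the current one) makes the filter idempotent and
   independent of filter order.
4. **Minimum occurrence**: features detected in fewer than 3 non-blank
   spectra are dropped.
5. **Blank filter**: a feature is removed everywhere if its maximum blank
   S/N exceeds 20 × its maximum sample S/N, or if it appears in ≥ 7 of the
   10 blanks. Blank rows are dropped afterwards.
6. **Replicate outliers**: a manual exclusion list (the experimental
   workflow identified outliers by inspection), or an automatic
   Bray–Curtis-distance-to-group-mean flagger. Removing every replicate of
   a condition is an error.
7. **Normalization**: each assigned feature's intensity is divided by the
   spectrum's summed intensity over assigned features, so rows of the
   resulting `FormulaTable` sum to 1. The alternative reading of the
   protocol — normalizing by *all* remaining peaks including unassigned
   ones — is available via `normalization_total="all_peaks"` (rows then
   sum to < 1 and the table is flagged unnormalized).

## 3. Molecular indices and compound classes

`DBE = 1 + (2C − H + N + P)/2`;
`AImod = (1 + C − 0.5·O − S − 0.5·H) / (C − 0.5·O − N − S − P)`, clamped to
[0, 1] and defined as 0 when the numerator or denominator is non-positive.
Classification precedence (first match wins) makes the overlapping
threshold definitions single-valued:

1. saturated — DBE = 0
2. aromatic — AImod > 0.5
3. highly unsaturated — AImod ≤ 0.5 and H/C < 1.5
4. potential protein — H/C ≥ 1.5, DBE ≠ 0, N > 0
5. unsaturated — H/C ≥ 1.5, DBE ≠ 0
6. other

Van Krevelen exports use the replicate-presence rule: a formula counts for
a condition only if detected in all of its (non-excluded) analytical
replicates.

## 4. vDOM detection and fate

Per condition (depth, arm, day) the presence set is the set of formulas
detected in **all** replicates. For one depth,

```
vDOM = present(treatment, day 6)
       − [ present(control, day 6) ∪ present(treatment, day 0) ∪ present(control, day 0) ]
```

Persistence compares vDOM against the final time point:
`removed_fraction = 1 − |vDOM ∩ present(treatment, day 55)| / |vDOM|`.
Heteroatom fractions are the shares of vDOM formulas containing N, S or P
(overlapping categories; they need not sum to 1).

## 5. Ordination and permutation statistics

Normalized tables are Hellinger-transformed (square root of row
proportions), Bray–Curtis dissimilarities are computed with scipy, and
samples are embedded by classical PCoA (Gower double-centering of −D²/2,
symmetric eigendecomposition). Negative eigenvalues are reported
uncorrected; explained fractions are over positive eigenvalues only. The
in-package PCoA exists because these reporting details are pinned;
scikit-bio's implementation serves as an independent cross-check in the
tests.

Environmental vectors are fitted by least squares of each variable on the
first two score axes (envfit-style); significance comes from permuting the
variable (R² of permuted fits, vectorized through a QR projection).
Individual formulas are screened against environmental variables by
permutation Spearman correlation (average ranks, two-sided). All
permutation p-values use `(1 + exceedances) / (n_perm + 1)`, so p = 0 is
impossible; with the default 9,999 permutations the smallest attainable
p-value is 10⁻⁴, below the default screening threshold of 0.001. The
acceptance suite verifies both tests reject at the nominal 5% rate under
simulated nulls.

## 6. Community diversity

OTU count tables are repeatedly rarefied (subsampled without replacement
via the multivariate hypergeometric distribution) to a common depth of
11,000 reads, 30 times; richness, Shannon `H = −Σ p ln p` (natural log)
and Pielou `J = H / ln(richness)` (0 by convention for a single OTU) are
summarized as mean ± sd. Samples shallower than the rarefaction depth are
skipped, not extrapolated. Taxa below 1% relative abundance in *every*
sample aggregate into "Others". The virus-to-cell ratio is VLP/TCC.

Note the rarefaction Shannon estimator carries the classic negative bias
of roughly `(S − 1)/(2·depth)`; the acceptance test accounts for it
explicitly rather than hiding it in a loose tolerance.

## 7. Synthetic experiment generator

The simulator produces the complete experiment with an answer key
(`GroundTruth`). Defaults mirror the modeled study's design and findings,
and are *inputs*, not fitted quantities:

- **Design**: 2 depths × {treatment, control} × days (0, 6, 14, 55) ×
  3 analytical replicates = 48 samples, plus 10 procedural blanks.
- **Background library**: 5,000 formulas sampled from the assignment grid
  inside a realistic composition band (H/C 0.7–2.2, O/C 0.2–1.0,
  150–650 Da) with a 56% N / 10% S / 1.5% P heteroatom mixture allocated
  by exact counts. Library members are required to be uniquely resolvable
  by the assignment rules over the whole mass-jitter range (tolerance
  widened by six jitter standard deviations) — a compound whose exact mass
  is irrecoverably double-assigned could never be recovered by any
  downstream logic, so planting one would only test the simulator, not the
  pipeline.
- **vDOM pulse**: 1,230 additional formulas with 63% N / 28% S / 20% P,
  entering the treatment arm of one depth at day 6, attenuated ×0.5 at
  day 14; 58% of them (chosen at random) are absent by day 55 and the rest
  persist at ×0.4.
- **Measurement model**: per-sample intensities are baseline ×
  10^N(0, 0.15); m/z jitter is 0.05 ppm (instrument calibration scale);
  detection probability is logistic in log10 intensity (midpoint 10²,
  scale 0.1 decades); S/N = intensity / 50; 200 spurious noise peaks per
  spectrum, 70% of them below the S/N 4 threshold.
- **Planted contaminants**: 5 library formulas appear in 5 blanks at
  S/N 10⁶ (triggering the 20× rule) and 10 unique formulas appear in 8 of
  10 blanks and all samples (triggering the 7-of-10 rule).
- **Companion tables**: OTU tables for a "bottle-effect bloom" (read mass
  shifting onto a few copiotroph OTUs, evenness dropping) versus a
  stabilized community, and an environmental table (DOC, amino acid and
  carbohydrate pools, cell and virus counts) with linear day trends,
  arm/depth offsets and multiplicative noise.

Determinism: every generator consumes `numpy.random.default_rng([seed, k])`
with a fixed stream index `k` per stage, so outputs are bit-reproducible
under a seed and stages are independently re-runnable.

### Known limitations

- Isotopologues, adducts other than [M−H]⁻, multiply charged ions and
  isotope-pattern checks are out of scope.
- Compound classes are composition-based; structural isomers are not
  distinguishable by FT-ICR-MS and class labels are nominal.
- The simulator plants formulas on the same grid the assigner searches; it
  validates the pipeline's logic, not instrument physics (no peak shape,
  resolution, or space-charge effects).
- The N4 ↔ phosphorus mass degeneracy (Δ ≈ 0.197 mDa) is physically real;
  above ~280 Da the deletion ladder removes both partners when the
  phosphorus candidate is plausible. This loss is inherent to the printed
  resolution procedure.
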