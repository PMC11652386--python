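# Methods

## Scope and model

`snpcc` analyses one biallelic SNP at a time in an unmatched case-control
design. The data for one SNP are the two genotype count triples
(ref-hom, het, alt-hom) of cases and controls sharing one allele
orientation. Everything downstream — HWE, the six 2×2 contrasts, odds
ratios, FPRP/BFDP — is a deterministic function of those six integers and
the configuration, so a fitted study is byte-reproducible from its inputs
(the report provenance carries the input checksum and config echo).

The reference allele is a *labelling* choice, not a frequency statement:
the baseline of every contrast is the reference-homozygote category as laid
out in the input file, even where the alternate allele is the more common
one (as for CYP2E1 rs2070673 in the bundled data, where T is the declared
variant yet the majority allele in controls). Re-orienting to the rarer
allele would flip the published ORs (0.39, 0.45, 0.61 → their reciprocals)
and is deliberately not done. Genotypes are unphased; per-subject input
treats A/G and G/A as the same call. Missing calls are dropped per SNP
(never imputed), with the exclusion count logged.

## Statistical conventions

**HWE.** 1-df chi-squared goodness of fit against (p̂²n, 2p̂q̂n, q̂²n), allele
frequency estimated from the tested cohort, no Yates correction. This is the
convention that matches the bundled study's six printed χ²/p pairs. A
monomorphic cohort returns the degenerate (χ² = 0, p = 1) result with a flag
rather than raising, so simulation batches never abort.

**Association.** Crude OR = ad/bc; Woolf SE on the log scale; CI =
exp(log OR ± z·SE); two-sided Wald z-test on log OR. Wald-on-log-OR (rather
than Pearson chi-squared or Fisher's exact test) is the convention that
reproduces all 18 published p-values of the bundled study. The two additive
models drop the unused genotype class entirely (their table totals are
smaller than the cohort); they are restrictions of the genotype table, not
collapsed recodings. Zero cells trigger the Haldane–Anscombe +0.5
correction on all four cells, flagged on the result; an all-zero table is a
domain error. Reported p-values are floored at 1e-300; display rounding is
OR/CI to 2 decimals, association p to 4, HWE χ² to 2 and probabilities to
3, with the JSON report keeping full precision.

**Power at the target OR.** The FPRP power term is the two-sided rejection
probability of the Wald test at level α when the true log OR is ±ln(1.5):
Φ(ln 1.5/SE − z_α) + Φ(−ln 1.5/SE − z_α). Two conventions matter and both
are tested:

- α is the **exact** observed p-value, not the display-rounded one. For the
  rs204993 CC-vs-TT contrast the exact p (8.4e-5) gives power 0.0043
  (prints 0.004, matching the published table); the rounded p = 0.0001
  would give 0.0049 (prints 0.005).
- Protective estimates (OR < 1) use the reciprocal target, θ₁ = −ln 1.5,
  which by symmetry of the two-tailed formula equals the risk-direction
  power; an OR of exactly 1 is treated as risk. Both rejection tails are
  included; the discordant tail is < 1e-6 in all realistic rows but keeps
  the expression exact.

**FPRP.** α(1−π)/(α(1−π) + power·π) over the prior grid 0.25, 0.1, 0.01,
0.001, 0.0001. The default noteworthiness cutoff is FPRP < 0.2; the
alternative 0.5 screen used for the bundled study's published bold pattern
is available as `NoteworthinessConfig.published_screen()`. Zero power
returns FPRP = 1 with a warning (a test that cannot detect the alternative
cannot vindicate a report).

**BFDP.** Wakefield's approximate Bayes factor with the prior variance W
set so the target OR is the 97.5th percentile of the alternative:
W = (ln 1.5/1.96)². ABF = √((V+W)/V)·exp(−z²W/2(V+W)) is the null/alternative
density ratio at the estimate; BFDP = ABF·PO/(1+ABF·PO) with PO the prior
odds of the null; cutoff 0.8. The ABF is reported alongside BFDP so the
convention is auditable. **Known limitation:** published BFDP columns
produced with ad-hoc spreadsheets frequently follow unstated variants of
this formula; the bundled study's BFDP values are not reproduced by this
(or the W = (ln 1.5)²) convention, so the self-test reports BFDP cells as
informational rather than pass/fail, and BFDP correctness is established by
property tests (closed-form density-ratio oracle, the W → 0 and z → 0
limits, monotonicity in the prior) instead of by comparison to those
columns.

Both screens depend on the data only through |z| and SE, hence are invariant
to table orientation (verified by test).

## Synthetic data

The generator emulates the bundled study's design: two independent cohorts,
controls multinomial over HWE proportions (p², 2pq, q²) at a chosen
alt-allele frequency, cases multinomial over those proportions tilted by
the genotype odds ratios (1, OR_het, OR_hom) and renormalised. This
exposure-odds construction makes the sample additive-1/additive-2 ORs
converge to the generating ORs without specifying disease prevalence, which
is unidentifiable in a case-control design. Defaults are the study's
conditions: 210 subjects per arm; SNPs are independent (no linkage
disequilibrium), there is no population stratification and no genotyping
error — so passing calibration tests demonstrates correctness of the
estimators under the sampling model, not robustness to those real-data
features. A single integer seed drives `numpy.random.default_rng`; identical
seeds give bit-identical cohorts.

Calibration checks (all seeded, run in the default suite): type-I error of
the additive-2 Wald test at 210/210 over 2000 null replicates within
5% ± 1.5%; control cohorts fail HWE at the same nominal rate; mean estimated
log-OR over 1000 replicates at 5000/5000 within 3 Monte-Carlo standard
errors of ln 1.5 and ln 3.4; 95% CI coverage of the generating OR within
0.95 ± 0.02. The replicate counts (2000/1000) keep Monte-Carlo error well
below the asserted bands while the whole suite stays in the seconds range.

## Design choices on genuinely open points

- The bundled study's source tables disagree in two count cells (an allelic
  case count and an overdominant baseline); the packaged fixture follows the
  genotype tallies, which are consistent with the printed percentages and
  odds ratios. The discrepancy is documented here, not "fixed".
- No multiple-testing adjustment is applied across the 18 model tests,
  mirroring the original analysis; the report footer states this, and the
  six models of one SNP are overlapping recodings of the same data, so their
  tests are strongly dependent anyway.
- Significance is flagged at p ≤ 0.05 inclusive.
- The CI method is Woolf throughout; small-sample exact or mid-p intervals
  are out of scope.

## Degenerate inputs

Monomorphic cohorts: flagged HWE result, and the affected model tables hit
the Haldane–Anscombe path. Empty cohorts and all-zero tables are validation
errors. Priors are constrained to (0,1), the target OR to > 1, confidence
levels to (0.5, 1).
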