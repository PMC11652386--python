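# snpcc — case-control single-SNP association analysis

`snpcc` is a small, fully tested toolkit for the classical candidate-gene
case-control analysis of biallelic SNPs: Hardy–Weinberg equilibrium (HWE)
testing per cohort, the six standard genetic inheritance contrasts, crude
odds ratios with Woolf confidence intervals and Wald tests, and the
FPRP/BFDP "noteworthiness" screens that guard single-study findings against
false-positive reporting. It ships the genotype counts of a published
schizophrenia case-control study (210 cases / 210 controls at *NOTCH4*
rs2071287, *NOTCH4* rs204993 and *CYP2E1* rs2070673) as a bundled dataset
with a per-cell self-test, plus a synthetic genotype generator with known
ground truth for calibration.

## The statistics

For one cohort with genotype counts (n<sub>GG</sub>, n<sub>GA</sub>,
n<sub>AA</sub>) and estimated reference-allele frequency p̂, HWE is tested by
the 1-df chi-squared goodness of fit of the observed counts against
(p̂²n, 2p̂q̂n, q̂²n), with no continuity correction.

Each inheritance model recodes the 3×2 genotype-by-phenotype table into a
2×2 contrast (a, b; c, d) — additive 1 (het vs ref-hom), additive 2 (alt-hom
vs ref-hom), dominant, recessive, overdominant and allelic (on the 2n allele
scale). For each table,

- OR = ad / bc, with SE(log OR) = √(1/a + 1/b + 1/c + 1/d) (Woolf),
- 95% CI = exp(log OR ± z₀.₉₇₅ · SE), p from the two-sided Wald z-test on
  log OR, and the Haldane–Anscombe +0.5 correction when a cell is zero.

The noteworthiness screens, at a target OR of 1.5:

- **FPRP** = α(1−π) / (α(1−π) + power·π), where α is the *exact* observed
  p-value, π a prior probability of true association (grid 0.25 … 10⁻⁴),
  and power = Φ(ln 1.5/SE − z_α) + Φ(−ln 1.5/SE − z_α) is the probability of
  rejecting at level α under the target alternative.
- **BFDP** = ABF·PO / (1 + ABF·PO), with PO = (1−π)/π and Wakefield's
  approximate Bayes factor ABF = √((V+W)/V) · exp(−z²W / 2(V+W)),
  V = SE², W = (ln 1.5 / 1.96)².

## Worked example

```python
from snpcc import SNPAssociationStudy, ModelKind

results = SNPAssociationStudy.from_example().fit()   # bundled dataset
res = results.snps["rs204993"]

res.hwe_controls.chi2, res.hwe_controls.p_value
# (0.8584830311429714, 0.3541635529608589)   controls consistent with HWE

a = res.association(ModelKind.additive2)             # CC vs TT
round(a.or_estimate, 2), round(a.ci_low, 2), round(a.ci_high, 2), round(a.p_value, 4)
# (3.39, 1.85, 6.23, 0.0001)     CC carries a 3.4-fold odds of case status

n = res.noteworthy(ModelKind.additive2)
round(n.power, 3), round(n.fprp_by_prior[0.25], 3)
# (0.004, 0.055)                 noteworthy: FPRP 5.5% at prior 0.25
```

`results.summary()` prints the three report tables; `results.to_tsv(path)` /
`results.to_json(path)` write display-rounded and full-precision reports.
The same pipeline is available from the shell:

```bash
snpcc run --counts counts.tsv --out report.tsv --json report.json
snpcc hwe --counts counts.tsv
snpcc simulate --alt-freq 0.34 --or-hom 3.4 --seed 7 --counts-out sim.tsv
snpcc self-test        # re-analyses the bundled dataset, diffs every cell
```

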