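{
  "_comment": "Published analysis results for the bundled schizophrenia case-control dataset (210 cases / 210 controls, Bangladeshi cohort; NOTCH4 rs2071287, rs204993 and CYP2E1 rs2070673). HWE entries are [chi2, p]; association entries are [OR, CI low, CI high, p] as displayed (OR/CI to 2 decimals, p to 4). fprp_noteworthy lists the published noteworthy flags (FPRP < 0.5 screen) at priors 0.25 and 0.1. Where the source report's count cells were internally inconsistent, the values consistent with the genotype counts and printed percentages were used.",
  "tolerances": {"hwe_chi2": 0.01, "hwe_p": 0.005, "or": 0.01, "ci": 0.01, "p": 0.0005},
  "snps": {
    "rs2071287": {
      "gene": "NOTCH4",
      "hwe": {"cases": [0.26, 0.609], "controls": [0.134, 0.714]},
      "association": {
        "additive1": [0.98, 0.65, 1.49, 0.9381],
        "additive2": [1.25, 0.69, 2.27, 0.4574],
        "dominant": [1.04, 0.70, 1.54, 0.8415],
        "recessive": [1.26, 0.73, 2.19, 0.4035],
        "overdominant": [0.93, 0.63, 1.36, 0.6956],
        "allelic": [1.08, 0.82, 1.43, 0.5688]
      },
      "fprp_noteworthy": {
        "additive1": [false, false],
        "additive2": [false, false],
        "dominant": [false, false],
        "recessive": [false, false],
        "overdominant": [false, false],
        "allelic": [false, false]
      }
    },
    "rs204993": {
      "gene": "NOTCH4",
      "hwe": {"cases": [0.135, 0.713], "controls": [0.86, 0.354]},
      "association": {
        "additive1": [1.51, 0.99, 2.32, 0.0580],
        "additive2": [3.39, 1.84, 6.23, 0.0001],
        "dominant": [1.84, 1.22, 2.76, 0.0032],
        "recessive": [2.67, 1.53, 4.64, 0.0005],
        "overdominant": [1.04, 0.71, 1.52, 0.8451],
        "allelic": [1.75, 1.32, 2.30, 0.0001]
      },
      "fprp_noteworthy": {
        "additive1": [true, false],
        "additive2": [true, true],
        "dominant": [true, true],
        "recessive": [true, true],
        "overdominant": [false, false],
        "allelic": [true, true]
      }
    },
    "rs2070673": {
      "gene": "CYP2E1",
      "hwe": {"cases": [1.91, 0.166], "controls": [0.36, 0.549]},
      "association": {
        "additive1": [0.82, 0.48, 1.40, 0.4760],
        "additive2": [0.39, 0.22, 0.69, 0.0013],
        "dominant": [0.62, 0.37, 1.02, 0.0599],
        "recessive": [0.45, 0.29, 0.68, 0.0002],
        "overdominant": [1.49, 1.02, 2.19, 0.0408],
        "allelic": [0.61, 0.46, 0.80, 0.0004]
      },
      "fprp_noteworthy": {
        "additive1": [false, false],
        "additive2": [true, true],
        "dominant": [true, false],
        "recessive": [true, true],
        "overdominant": [true, true],
        "allelic": [true, true]
      }
    }
  },
  "noteworthiness_anchors": {
    "rs204993": {
      "additive2": {"power": 0.004, "fprp_prior_0.25": 0.055}
    }
  }
}
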