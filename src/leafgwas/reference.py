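"""Reference summary statistics from a published leaf-shape GWAS.

The numbers below are the printed summaries of a genome-wide association
study of leaf shape in a randomized complete block design (RCBD) of clones
from an F1 cross of *Populus deltoides* (female) x *Populus simonii* (male):
163 genotyped clones, 3 blocks, 6 cuttings per clone and plot, 2,244
measured trees.  They serve two purposes here: (i) internal-consistency
checks (a coefficient of variation recomputed from the printed mean and SD,
segregation-type counts summing to the printed total), and (ii) realistic
defaults for the synthetic-data generator.
"""

from __future__ import annotations

# Trait table: mean, SD, (min, max), CV %, heritability % per leaf trait.
# L = length (mm), W = maximum width (mm), W13/W12/W23 = widths at 1/3, 1/2,
# 2/3 of the length from the base (mm), A = area (mm^2), LW = L/W ratio.
TRAIT_SUMMARY = {
    "L":   {"mean": 114.27, "sd": 23.76, "range": (36.31, 193.12), "cv_pct": 20.79, "h2_pct": 41.56},
    "W":   {"mean": 90.79,  "sd": 21.90, "range": (23.72, 163.03), "cv_pct": 24.12, "h2_pct": 46.46},
    "W13": {"mean": 89.95,  "sd": 21.89, "range": (20.49, 157.89), "cv_pct": 24.34, "h2_pct": 45.65},
    "W12": {"mean": 83.80,  "sd": 19.83, "range": (23.72, 147.72), "cv_pct": 23.66, "h2_pct": 46.67},
    "W23": {"mean": 64.97,  "sd": 16.33, "range": (16.76, 131.03), "cv_pct": 25.14, "h2_pct": 49.53},
    "A":   {"mean": 7317.88, "sd": 3091.52, "range": (588.66, 23514.73), "cv_pct": 42.25, "h2_pct": 49.52},
    "LW":  {"mean": 1.28,   "sd": 0.13,  "range": (0.91, 1.92),    "cv_pct": 10.12, "h2_pct": 64.74},
}

# Per-segregation-type SNP counts after the Mendelian / missingness filters.
SEGREGATION_COUNTS = {
    "aaxab": 13385,
    "aaxbc": 76,
    "abxaa": 19295,
    "abxcc": 159,
    "abxab": 171,
}
TOTAL_SNPS = 33086

# Survivors of LD pruning (window 25 SNPs, step 2, r^2 > 0.7): the count of
# independent markers and LD blocks used for the Bonferroni correction.
N_INDEPENDENT = 10735

# Study geometry.
N_CLONES = 163
N_BLOCKS = 3
CUTTINGS_PER_PLOT = 6
N_TREES = 2244

# Mean relative differences (%) between two independent measurement
# pipelines (ImageJ vs. the polar-radius pipeline) on 100 leaves, for
# length, width and area; used as the accuracy bar for the synthetic
# geometry validation harness.
MEASUREMENT_REL_DIFF_PCT = {"L": 1.45, "W": 4.76, "A": 5.05}


def segregation_mix() -> dict:
    """Observed proportions of the five F1 segregation types."""
    total = sum(SEGREGATION_COUNTS.values())
    return {k: v / total for k, v in SEGREGATION_COUNTS.items()}
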