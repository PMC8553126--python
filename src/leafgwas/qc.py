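"""F1 segregation classification, Mendelian/missingness filters, LD pruning.

A SNP in an outbred F1 family is kept when (i) its offspring class counts do
not deviate from the Mendelian ratio of its segregation type by a chi-square
test at p > 0.01, (ii) fewer than 10% of clone genotypes are missing, and
(iii) its ratio is one of 1:1, 1:2:1, 1:1:1:1.  Surviving SNPs are then
pruned for linkage disequilibrium in sliding windows (default 25 SNPs,
step 2, r^2 > 0.7), and the survivor count is the number of independent
markers and LD blocks used for Bonferroni correction downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .segtypes import (
    ADMITTED_RATIOS,
    EXPECTED_RATIOS,
    OFFSPRING_CLASSES,
    SEG_TYPES,
)

DEFAULT_SEG_P = 0.01
DEFAULT_MAX_MISSING = 0.10
DEFAULT_WINDOW = 25
DEFAULT_STEP = 2
DEFAULT_R2 = 0.7


def classify_segregation(parent1, parent2):
    """Classify a SNP by its parental genotypes.

    Parents are 2-tuples of allele symbols (any hashable labels, e.g.
    nucleotides).  Returns ``(seg_type, expected_ratio, allele_map)`` where
    allele_map sends each observed allele symbol to the abstract letters
    a/b/c of the segregation type.  Unsupported or uninformative
    configurations (monomorphic, aa x bb, het x het sharing one allele,
    ab x cd, missing parents) give ``("unclassifiable", None, None)``.
    """
    unclass = ("unclassifiable", None, None)
    if parent1 is None or parent2 is None:
        return unclass
    p1, p2 = tuple(parent1), tuple(parent2)
    if any(a is None or a in (".", "") for a in p1 + p2):
        return unclass
    hom1, hom2 = p1[0] == p1[1], p2[0] == p2[1]
    if hom1 and hom2:
        return unclass  # monomorphic or aa x bb: no observable segregation
    if hom1 and not hom2:
        x = p1[0]
        if x in p2:
            other = p2[0] if p2[1] == x else p2[1]
            return "aaxab", EXPECTED_RATIOS["aaxab"], {x: "a", other: "b"}
        y, z = sorted(p2)
        return "aaxbc", EXPECTED_RATIOS["aaxbc"], {x: "a", y: "b", z: "c"}
    if not hom1 and hom2:
        y = p2[0]
        if y in p1:
            other = p1[0] if p1[1] == y else p1[1]
            return "abxaa", EXPECTED_RATIOS["abxaa"], {y: "a", other: "b"}
        x, w = sorted(p1)
        return "abxcc", EXPECTED_RATIOS["abxcc"], {x: "a", w: "b", y: "c"}
    if set(p1) == set(p2):
        x, w = sorted(p1)
        return "abxab", EXPECTED_RATIOS["abxab"], {x: "a", w: "b"}
    return unclass  # ab x ac or ab x cd: not among the supported types


def segregation_test(observed_counts: Sequence[int], expected_ratio: Sequence[int]):
    """Pearson chi-square of offspring class counts against a Mendelian
    ratio, with (classes - 1) degrees of freedom."""
    obs = np.asarray(observed_counts, dtype=float)
    ratio = np.asarray(expected_ratio, dtype=float)
    if obs.min() < 0:
        raise ValueError("counts must be non-negative")
    n = obs.sum()
    if n == 0:
        raise ValueError("all offspring classes empty")
    exp = n * ratio / ratio.sum()
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    p = float(stats.chi2.sf(chi2, df=len(obs) - 1))
    return chi2, p


@dataclass
class SegregationRecord:
    snp_id: str
    chrom: int
    pos_bp: int
    seg_type: str
    expected_ratio: tuple | None
    observed_counts: tuple
    chi2: float
    p: float
    missing_fraction: float
    passed: bool


def build_records(
    snps: pd.DataFrame,
    classes: np.ndarray,
    seg_p: float = DEFAULT_SEG_P,
    max_missing: float = DEFAULT_MAX_MISSING,
) -> list[SegregationRecord]:
    """One SegregationRecord per SNP from the clone genotype-class matrix.

    ``snps`` needs snp_id, chrom, pos_bp, seg_type columns; ``classes`` is
    the (c, m) label matrix with '' for missing.  A SNP passes iff
    p > seg_p, missing fraction < max_missing and its ratio is admitted.
    """
    c, m = classes.shape
    records = []
    for j in range(m):
        st = snps["seg_type"].iloc[j]
        col = classes[:, j]
        missing = float((col == "").mean())
        if st in SEG_TYPES:
            levels = OFFSPRING_CLASSES[st]
            counts = tuple(int((col == lab).sum()) for lab in levels)
            ratio = EXPECTED_RATIOS[st]
            if sum(counts) > 0:
                chi2, p = segregation_test(counts, ratio)
            else:
                chi2, p = np.nan, 0.0
            passed = (
                p > seg_p
                and missing < max_missing
                and tuple(ratio) in ADMITTED_RATIOS
            )
        else:
            counts, ratio, chi2, p, passed = (), None, np.nan, np.nan, False
        records.append(
            SegregationRecord(
                snp_id=snps["snp_id"].iloc[j],
                chrom=int(snps["chrom"].iloc[j]),
                pos_bp=int(snps["pos_bp"].iloc[j]),
                seg_type=st,
                expected_ratio=ratio,
                observed_counts=counts,
                chi2=chi2,
                p=p,
                missing_fraction=missing,
                passed=passed,
            )
        )
    return records


def filter_snps(records: list[SegregationRecord]):
    """Indices of passing SNPs plus the per-type summary of kept SNPs."""
    keep = [i for i, r in enumerate(records) if r.passed]
    per_type = {t: 0 for t in SEG_TYPES}
    for i in keep:
        per_type[records[i].seg_type] += 1
    return keep, per_type


def records_table(records: list[SegregationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "snp_id": [r.snp_id for r in records],
            "chrom": [r.chrom for r in records],
            "pos_bp": [r.pos_bp for r in records],
            "seg_type": [r.seg_type for r in records],
            "ratio": [
                ":".join(map(str, r.expected_ratio)) if r.expected_ratio else ""
                for r in records
            ],
            "chi2": [r.chi2 for r in records],
            "p": [r.p for r in records],
            "missing": [r.missing_fraction for r in records],
            "pass": [r.passed for r in records],
        }
    )


def pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of numeric genotype codes.

    Individuals missing (NaN) at either SNP are dropped pairwise; zero
    variance at either SNP yields 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 2:
        return 0.0
    vx, vy = x.var(), y.var()
    if vx <= 0 or vy <= 0:
        return 0.0
    cov = ((x - x.mean()) * (y - y.mean())).mean()
    return float(cov * cov / (vx * vy))


@dataclass
class PrunedSet:
    kept_snp_ids: list
    n_independent: int
    window: int
    step: int
    r2_threshold: float


def ld_prune(
    snps: pd.DataFrame,
    codes: np.ndarray,
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    r2_threshold: float = DEFAULT_R2,
    missing_fraction: np.ndarray | None = None,
) -> PrunedSet:
    """Sliding-window greedy LD pruning within chromosomes.

    ``codes`` is the (c, m) numeric genotype matrix (NaN missing), columns
    aligned with ``snps`` which must be position-sorted within chromosome.
    Within each window, while any retained pair has r^2 > threshold, the
    member with the higher missing fraction (ties: the later position) is
    removed; the window then advances by ``step`` SNPs.  Windows never span
    chromosomes.
    """
    snps = snps.reset_index(drop=True)
    m = len(snps)
    if codes.shape[1] != m:
        raise ValueError("codes and snps disagree on SNP count")
    for _, grp in snps.groupby("chrom"):
        if not grp["pos_bp"].is_monotonic_increasing:
            raise ValueError("SNPs must be position-sorted within chromosome")
    if missing_fraction is None:
        missing_fraction = np.isnan(codes).mean(axis=0)
    kept = np.ones(m, dtype=bool)
    for _, grp in snps.groupby("chrom", sort=True):
        idx = grp.index.to_numpy()
        start = 0
        while True:
            win = idx[start : start + window]
            if len(win) == 0:
                break
            _prune_window(win, codes, kept, r2_threshold, missing_fraction)
            if start + window >= len(idx):
                break
            start += step
    kept_ids = list(snps.loc[kept, "snp_id"])
    return PrunedSet(
        kept_snp_ids=kept_ids,
        n_independent=int(kept.sum()),
        window=window,
        step=step,
        r2_threshold=r2_threshold,
    )


def _prune_window(win, codes, kept, r2_threshold, missing_fraction):
    while True:
        active = [i for i in win if kept[i]]
        worst = None
        for ai in range(len(active)):
            for bi in range(ai + 1, len(active)):
                i, j = active[ai], active[bi]
                r2 = pairwise_r2(codes[:, i], codes[:, j])
                if r2 > r2_threshold:
                    # drop the worse member: higher missingness, then later position
                    drop = (
                        i
                        if (missing_fraction[i], i) > (missing_fraction[j], j)
                        else j
                    )
                    worst = drop
                    break
            if worst is not None:
                break
        if worst is None:
            return
        kept[worst] = False


def qc_summary(records, keep, pruned: PrunedSet) -> dict:
    _, per_type = filter_snps(records)
    return {
        "n_total": len(records),
        "n_pass": len(keep),
        "per_type_counts": per_type,
        "n_independent": pruned.n_independent,
    }
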