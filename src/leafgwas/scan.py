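"""Genome-scan orchestration: inflation, genomic control, thresholds, regions.

Wraps the mixed-model scanner into a whole-genome scan and applies the
standard calibration machinery: the genomic inflation factor lambda_GC
(median association chi-square over the null median of chi-square with one
degree of freedom), genomic control (dividing chi-squares by lambda_GC when
lambda_GC > 1), a Bonferroni threshold on the number of independent markers
and LD blocks from pruning, and the splitting of significant SNP runs into
regions at positions where -log10(p) switches from decreasing to increasing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .lmm import (
    MixedModelScanner,
    MultiVarComp,
    RCBDDesign,
    reml_multivariate,
    reml_univariate,
)

CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, 1))  # 0.4549364...


def inflation_factor(p_values) -> float:
    """Genomic inflation factor: median of the 1-df chi-square quantiles of
    the p-values over the null chi-square(1) median."""
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    if len(p) == 0:
        raise ValueError("no p-values")
    chi2 = stats.chi2.isf(np.clip(p, 1e-300, 1.0), 1)
    return float(np.median(chi2) / CHI2_1_MEDIAN)


def genomic_control(p_values, lambda_gc: float) -> np.ndarray:
    """Divide association chi-squares by lambda_GC and reconvert to
    p-values.  Deflation (lambda_GC <= 1) is left uncorrected."""
    if lambda_gc <= 0:
        raise ValueError("lambda_GC must be positive")
    p = np.asarray(p_values, dtype=float)
    if lambda_gc <= 1.0:
        return p.copy()
    chi2 = stats.chi2.isf(np.clip(p, 1e-300, 1.0), 1)
    return stats.chi2.sf(chi2 / lambda_gc, 1)


def bonferroni_threshold(m_independent: int, alpha: float = 0.05):
    """Per-test p cutoff alpha/m and its -log10 companion."""
    if m_independent < 1:
        raise ValueError("need at least one independent test")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    p = alpha / m_independent
    return p, float(-np.log10(p))


def split_regions(scores: np.ndarray) -> np.ndarray:
    """Assign position-sorted significant SNPs of one chromosome to regions.

    A new region starts wherever the -log10(p) sequence switches from
    strictly decreasing to strictly increasing (a strict local minimum
    boundary); ties extend the current trend.
    """
    s = np.asarray(scores, dtype=float)
    region = np.zeros(len(s), dtype=int)
    if len(s) < 2:
        return region
    current = 0
    trend = 0  # -1 decreasing, +1 increasing
    for i in range(1, len(s)):
        d = s[i] - s[i - 1]
        if d > 0 and trend < 0:
            current += 1
            trend = 1
        elif d > 0:
            trend = 1
        elif d < 0:
            trend = -1
        region[i] = current
    return region


@dataclass
class ScanResult:
    table: pd.DataFrame  # snp_id, chrom, pos_bp, g, q, df2, F, p_raw, p_gc, pve, significant, region_id
    lambda_gc: float
    threshold: float
    threshold_neglog10: float
    m_independent: int
    mode: str
    vc: MultiVarComp | None = field(default=None, repr=False)

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())

    def summary(self) -> dict:
        return {
            "mode": self.mode,
            "n_snps": int(len(self.table)),
            "lambda_gc": self.lambda_gc,
            "threshold": self.threshold,
            "threshold_neglog10": self.threshold_neglog10,
            "m_independent": self.m_independent,
            "n_significant": self.n_significant,
        }


def run_scan(
    phenotypes: pd.DataFrame,
    snps: pd.DataFrame,
    clone_classes: np.ndarray,
    m_independent: int,
    trait_columns: list[str] | None = None,
    alpha: float = 0.05,
    mode: str = "multivariate",
    vc: MultiVarComp | None = None,
    exact: bool = False,
    clone_ids: list[str] | None = None,
) -> ScanResult:
    """Genome scan of all SNPs with the (multivariate) mixed model.

    phenotypes: tree-level table with block, clone and trait columns.
    snps: SNP table (snp_id, chrom, pos_bp), columns aligned with
    ``clone_classes`` (c x m integer class codes, -1 missing; clone rows
    ordered like the sorted unique clones of the phenotype table).
    ``m_independent`` is the pruned-set size used for the Bonferroni
    threshold.  Variance components are fitted once under the no-SNP null
    unless ``vc`` is supplied; ``exact=True`` refits them per SNP.
    """
    design = RCBDDesign.from_table(phenotypes)
    if clone_ids is not None:
        # align genotype rows with the design's (sorted) clone coding
        present = np.unique(np.asarray(phenotypes["clone"]))
        lookup = {cid: i for i, cid in enumerate(clone_ids)}
        clone_classes = clone_classes[[lookup[cid] for cid in present]]
    if trait_columns is None:
        trait_columns = [c for c in phenotypes.columns if c.startswith("trait_")]
    Y = phenotypes[trait_columns].to_numpy(dtype=float)
    t = Y.shape[1]
    X0 = design.base_design_matrix()
    if vc is None:
        if t == 1:
            u = reml_univariate(Y[:, 0], X0, design.clone)
            vc = MultiVarComp(np.array([[u.sigma_g2]]), np.array([[u.sigma_e2]]),
                              u.log_restricted_likelihood, 0, u.converged)
        else:
            vc = reml_multivariate(Y, X0, design.clone)
    scanner = MixedModelScanner(Y, design, vc)

    rows = []
    for j in range(len(snps)):
        res = scanner.test_snp(clone_classes[:, j], exact=exact)
        if res is None:
            continue
        rows.append(
            {
                "snp_id": snps["snp_id"].iloc[j],
                "chrom": snps["chrom"].iloc[j],
                "pos_bp": snps["pos_bp"].iloc[j],
                "g": res.g,
                "q": res.q,
                "df2": res.df2,
                "F": res.F,
                "p_raw": res.p_value,
                "pve": res.pve,
            }
        )
    table = pd.DataFrame(rows)
    threshold, neglog = bonferroni_threshold(m_independent, alpha)
    if table.empty:
        return ScanResult(table, np.nan, threshold, neglog, m_independent, mode, vc)
    lam = inflation_factor(table["p_raw"])
    table["p_gc"] = genomic_control(table["p_raw"].to_numpy(), lam)
    p_used = table["p_gc"] if lam > 1 else table["p_raw"]
    table["significant"] = p_used < threshold
    table["region_id"] = ""
    for chrom, grp in table[table["significant"]].groupby("chrom"):
        grp = grp.sort_values("pos_bp")
        reg = split_regions(-np.log10(grp["p_raw"].to_numpy()))
        table.loc[grp.index, "region_id"] = [f"chr{chrom}_r{r+1}" for r in reg]
    return ScanResult(table, lam, threshold, neglog, m_independent, mode, vc)


def regions_table(result: ScanResult) -> pd.DataFrame:
    """Contiguous significant regions: chrom, start, end, n_snps, min p."""
    sig = result.table[result.table["significant"]]
    rows = []
    for (chrom, rid), grp in sig.groupby(["chrom", "region_id"]):
        rows.append(
            {
                "chrom": chrom,
                "region_id": rid,
                "start_bp": int(grp["pos_bp"].min()),
                "end_bp": int(grp["pos_bp"].max()),
                "n_snps": len(grp),
                "min_p": float(grp["p_raw"].min()),
            }
        )
    return pd.DataFrame(rows).sort_values(["chrom", "start_bp"]) if rows else pd.DataFrame(
        columns=["chrom", "region_id", "start_bp", "end_bp", "n_snps", "min_p"]
    )


def qq_table(p_values) -> pd.DataFrame:
    """Observed vs expected -log10(p) quantiles for a QQ plot."""
    p = np.sort(np.asarray(p_values, dtype=float))
    n = len(p)
    expected = (np.arange(1, n + 1) - 0.5) / n
    return pd.DataFrame(
        {
            "expected_neglog10": -np.log10(expected),
            "observed_neglog10": -np.log10(np.clip(p, 1e-300, 1.0)),
        }
    )


def manhattan_table(result: ScanResult) -> pd.DataFrame:
    """Per-SNP plotting table: cumulative position and -log10 p."""
    tab = result.table.sort_values(["chrom", "pos_bp"]).copy()
    offset = 0
    cum = np.empty(len(tab), dtype=float)
    for chrom, grp in tab.groupby("chrom", sort=True):
        cum[tab.index.get_indexer(grp.index)] = grp["pos_bp"].to_numpy() + offset
        offset += grp["pos_bp"].max()
    tab["cum_pos"] = cum
    tab["neglog10_p"] = -np.log10(np.clip(tab["p_raw"], 1e-300, None))
    return tab
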