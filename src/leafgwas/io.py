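"""Formats and run configuration.

VCF reading goes through cyvcf2; genotype matrices, phenotype tables and
design tables are plain CSV/TSV via pandas.  RunConfig is the single
serializable object driving the end-to-end pipeline.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .qc import classify_segregation
from .segtypes import offspring_class


@dataclass
class VcfGenotypes:
    """Parsed VCF: per-SNP parental genotypes and offspring class labels."""

    snps: pd.DataFrame          # snp_id, chrom, pos_bp, seg_type
    parent1: list               # allele tuples (or None)
    parent2: list
    classes: np.ndarray         # (c, m) abstract class labels, '' missing
    clone_ids: list


def read_vcf(path, parent_ids=("P1", "P2")) -> VcfGenotypes:
    """Read genotypes from a VCF with GT fields.

    The two declared parent samples are classified into F1 segregation
    types; offspring genotypes are translated to abstract class labels
    (aa/ab/...) through each SNP's allele map.  Missing genotypes ('./.')
    propagate as ''.  Positions stay 1-based.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    for pid in parent_ids:
        if pid not in samples:
            raise ValueError(f"parent sample {pid!r} absent from VCF")
    i1, i2 = samples.index(parent_ids[0]), samples.index(parent_ids[1])
    off_idx = [i for i, s in enumerate(samples) if s not in parent_ids]
    clone_ids = [samples[i] for i in off_idx]

    rows, p1s, p2s, class_rows = [], [], [], []
    chrom_codes = {}
    for var in vcf:
        alleles = [var.REF] + list(var.ALT)
        gts = var.genotypes  # [allele1, allele2, phased]
        def pair(i):
            a, b = gts[i][0], gts[i][1]
            if a < 0 or b < 0:
                return None
            return (alleles[a], alleles[b])
        p1, p2 = pair(i1), pair(i2)
        seg_type, ratio, amap = classify_segregation(p1, p2)
        col = []
        for i in off_idx:
            pr = pair(i)
            if pr is None or amap is None or pr[0] not in amap or pr[1] not in amap:
                col.append("")
            else:
                col.append(offspring_class(amap[pr[0]], amap[pr[1]]))
        chrom = chrom_codes.setdefault(var.CHROM, len(chrom_codes) + 1)
        rows.append(
            {
                "snp_id": var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}",
                "chrom": chrom,
                "chrom_name": var.CHROM,
                "pos_bp": var.POS,
                "seg_type": seg_type,
            }
        )
        p1s.append(p1)
        p2s.append(p2)
        class_rows.append(col)
    snps = pd.DataFrame(rows)
    classes = (
        np.array(class_rows, dtype="<U2").T
        if class_rows
        else np.empty((len(clone_ids), 0), dtype="<U2")
    )
    return VcfGenotypes(snps=snps, parent1=p1s, parent2=p2s,
                        classes=classes, clone_ids=clone_ids)


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def read_genotype_tsv(path):
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0, keep_default_na=False)
    return df.index.to_list(), df.columns.to_list(), df.to_numpy(dtype="<U2")


@dataclass
class RunConfig:
    """End-to-end pipeline configuration (JSON round-trippable)."""

    seed: int = 1
    # cross
    n_clones: int = 163
    n_chromosomes: int = 19
    snps_per_chromosome: int = 100
    chromosome_length: float = 1.5
    missing_rate: float = 0.03
    # trial
    n_blocks: int = 3
    cuttings_per_plot: int = 6
    survival_rate: float = 0.765
    n_traits: int = 11
    heritability: float = 0.45
    # qc
    seg_p: float = 0.01
    max_missing: float = 0.10
    prune_window: int = 25
    prune_step: int = 2
    prune_r2: float = 0.7
    # scan
    alpha: float = 0.05
    mode: str = "rd11"
    version: str = "0.1.0"

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls(**json.loads(text))

    def digest(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


def output_header(stage: str, config: RunConfig) -> str:
    return f"# leafgwas stage={stage} config={config.digest()} seed={config.seed}\n"
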