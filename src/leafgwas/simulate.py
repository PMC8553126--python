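"""Forward simulation of an outbred F1 cross and RCBD clonal phenotypes.

The generator stands in for the field and sequencing data of a clonally
replicated full-sib trial: it draws phased parental haplotypes for each of
the five F1 segregation types, transmits alleles through gametes with
recombination under the Haldane map function (so nearby SNPs are in LD and
distant ones are not), and realizes tree-level multivariate phenotypes under
the RCBD linear mixed model

    Y = X B + Z G + E,   Vec(G) ~ N(0, V_G (x) A),  Vec(E) ~ N(0, V_E (x) I_n)

with per-block fixed shifts, optional fixed QTL class effects, clone-level
polygenic effects correlated through the full-sib relationship matrix A, and
i.i.d. tree-level residuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import reference
from .segtypes import OFFSPRING_CLASSES, PARENT_GENOTYPES, SEG_TYPES

# Physical positions are laid out at a constant map density typical of a
# ~400 Mb / ~2500 cM tree genome.
BP_PER_MORGAN = 16_000_000


def _default_mix() -> dict:
    return reference.segregation_mix()


@dataclass(frozen=True)
class CrossConfig:
    """Parameters of the simulated F1 cross."""

    n_clones: int = reference.N_CLONES
    n_chromosomes: int = 19
    snps_per_chromosome: int = 100
    chromosome_length: float = 1.5  # Morgans
    segregation_mix: Mapping[str, float] = field(default_factory=_default_mix)
    missing_rate: float = 0.03
    seed: int = 0

    def __post_init__(self):
        if self.n_clones < 1 or self.n_chromosomes < 1 or self.snps_per_chromosome < 1:
            raise ValueError("clone, chromosome and SNP counts must be positive")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.chromosome_length <= 0:
            raise ValueError("chromosome_length must be positive")
        mix = dict(self.segregation_mix)
        if set(mix) - set(SEG_TYPES):
            raise ValueError(f"unknown segregation types: {set(mix) - set(SEG_TYPES)}")
        total = sum(mix.values())
        if not np.isclose(total, 1.0, atol=1e-8):
            raise ValueError("segregation_mix proportions must sum to 1")


@dataclass
class Cross:
    """Simulated cross: SNP table, phased parents, offspring classes."""

    snps: pd.DataFrame           # snp_id, chrom, pos_bp, pos_morgan, seg_type
    parent1: np.ndarray          # (2, m) allele letters, phased
    parent2: np.ndarray          # (2, m)
    true_classes: np.ndarray     # (c, m) offspring genotype-class labels
    classes: np.ndarray          # (c, m) observed labels, '' where missing
    clone_ids: list
    seed: int

    @property
    def n_clones(self) -> int:
        return self.true_classes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.true_classes.shape[1]


def _simulate_inheritance(rng, n_clones, rec_fracs):
    """Inheritance vectors (n_clones, m) for one parent along one chromosome."""
    m = len(rec_fracs) + 1
    h = np.empty((n_clones, m), dtype=np.int8)
    h[:, 0] = rng.integers(0, 2, size=n_clones)
    if m > 1:
        switches = rng.random((n_clones, m - 1)) < rec_fracs[None, :]
        h[:, 1:] = switches
        np.cumsum(h, axis=1, out=h)
        h &= 1
    return h


def simulate_cross(config: CrossConfig) -> Cross:
    """Simulate genotypes of two parents and their F1 clones.

    Each SNP is assigned one of the five segregation types; parental phase
    (which haplotype carries which allele in a heterozygote) is randomized
    per SNP.  Offspring receive one gamete per parent; crossovers between
    adjacent SNPs occur with the Haldane recombination fraction
    r = (1 - exp(-2 d)) / 2 at map distance d Morgans.
    """
    rng = np.random.default_rng(config.seed)
    c = config.n_clones
    types = list(SEG_TYPES)
    probs = np.array([dict(config.segregation_mix).get(t, 0.0) for t in types])

    rows = []
    p1_haps, p2_haps, class_cols = [], [], []
    for chrom in range(1, config.n_chromosomes + 1):
        m = config.snps_per_chromosome
        pos_m = np.sort(rng.uniform(0.0, config.chromosome_length, size=m))
        seg = rng.choice(len(types), size=m, p=probs)
        # phased parental haplotypes, with random phase for heterozygotes
        p1 = np.empty((2, m), dtype="<U1")
        p2 = np.empty((2, m), dtype="<U1")
        flip1 = rng.integers(0, 2, size=m).astype(bool)
        flip2 = rng.integers(0, 2, size=m).astype(bool)
        for i, s in enumerate(seg):
            (a10, a11), (a20, a21) = PARENT_GENOTYPES[types[s]]
            p1[:, i] = (a11, a10) if flip1[i] else (a10, a11)
            p2[:, i] = (a21, a20) if flip2[i] else (a20, a21)
        d = np.diff(pos_m)
        rec = 0.5 * (1.0 - np.exp(-2.0 * d))
        h1 = _simulate_inheritance(rng, c, rec)
        h2 = _simulate_inheritance(rng, c, rec)
        g1 = p1[h1, np.arange(m)[None, :]]
        g2 = p2[h2, np.arange(m)[None, :]]
        lo = np.where(g1 <= g2, g1, g2)
        hi = np.where(g1 <= g2, g2, g1)
        cls = np.char.add(lo, hi)

        pos_bp = np.round(pos_m * BP_PER_MORGAN).astype(np.int64) + 1
        pos_bp = np.maximum.accumulate(pos_bp + np.arange(m))  # strictly increasing
        for i in range(m):
            rows.append(
                {
                    "snp_id": f"chr{chrom:02d}_{pos_bp[i]}",
                    "chrom": chrom,
                    "pos_bp": int(pos_bp[i]),
                    "pos_morgan": float(pos_m[i]),
                    "seg_type": types[seg[i]],
                }
            )
        p1_haps.append(p1)
        p2_haps.append(p2)
        class_cols.append(cls)

    snps = pd.DataFrame(rows)
    true_classes = np.concatenate(class_cols, axis=1)
    observed = true_classes.copy()
    if config.missing_rate > 0:
        mask = rng.random(observed.shape) < config.missing_rate
        observed[mask] = ""
    clone_ids = [f"F1_{j+1:03d}" for j in range(c)]
    return Cross(
        snps=snps,
        parent1=np.concatenate(p1_haps, axis=1),
        parent2=np.concatenate(p2_haps, axis=1),
        true_classes=true_classes,
        classes=observed,
        clone_ids=clone_ids,
        seed=config.seed,
    )


def encode_classes(classes: np.ndarray, seg_types: Sequence[str]) -> np.ndarray:
    """Numeric codes for genotype classes, NaN where missing.

    Two-class segregation types are coded 0/1 in canonical class order;
    the three-class ab x ab type is coded by b-allele dosage 0/1/2.
    """
    c, m = classes.shape
    out = np.full((c, m), np.nan)
    for j, st in enumerate(seg_types):
        levels = OFFSPRING_CLASSES[st]
        col = classes[:, j]
        for code, label in enumerate(levels):
            out[col == label, j] = code
    return out


# ---------------------------------------------------------------------------
# RCBD phenotypes


@dataclass(frozen=True)
class QTL:
    """A fixed SNP effect: per-genotype-class trait shift vectors."""

    snp_index: int
    effects: Mapping[str, np.ndarray]  # class label -> (t,) effect vector


@dataclass(frozen=True)
class TrialConfig:
    """Parameters of the randomized complete block trial."""

    V_G: np.ndarray
    V_E: np.ndarray
    n_blocks: int = reference.N_BLOCKS
    cuttings_per_plot: int = reference.CUTTINGS_PER_PLOT
    trait_means: np.ndarray | None = None
    block_effects: np.ndarray | None = None  # (n_blocks, t)
    qtl_spec: tuple = ()
    survival_rate: float = 0.765  # observed trees / planted cuttings
    seed: int = 0

    def __post_init__(self):
        vg = np.asarray(self.V_G, dtype=float)
        ve = np.asarray(self.V_E, dtype=float)
        if vg.shape != ve.shape or vg.ndim != 2 or vg.shape[0] != vg.shape[1]:
            raise ValueError("V_G and V_E must be square matrices of equal size")
        for name, v in (("V_G", vg), ("V_E", ve)):
            if not np.allclose(v, v.T, atol=1e-10):
                raise ValueError(f"{name} must be symmetric")
            if np.linalg.eigvalsh(v).min() < -1e-8 * max(1.0, np.abs(v).max()):
                raise ValueError(f"{name} must be positive semidefinite")
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")
        if not 0 < self.survival_rate <= 1:
            raise ValueError("survival_rate must lie in (0, 1]")
        t = vg.shape[0]
        if self.block_effects is not None:
            be = np.asarray(self.block_effects, dtype=float)
            if be.shape != (self.n_blocks, t):
                raise ValueError("block_effects must be (n_blocks, t)")
        if self.trait_means is not None and np.asarray(self.trait_means).shape != (t,):
            raise ValueError("trait_means must have length t")

    @property
    def n_traits(self) -> int:
        return np.asarray(self.V_G).shape[0]


def _psd_sqrt(v: np.ndarray) -> np.ndarray:
    w, u = np.linalg.eigh(np.asarray(v, dtype=float))
    return u * np.sqrt(np.clip(w, 0.0, None))


def simulate_rcbd_phenotypes(
    trial: TrialConfig,
    classes: np.ndarray | None = None,
    kinship: np.ndarray | None = None,
    n_clones: int | None = None,
    clone_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Tree-level phenotypes under the RCBD mixed model.

    Returns a DataFrame with tree_id, block, clone and trait_1..trait_t
    columns.  ``classes`` is the (c, m) genotype-class matrix used to apply
    QTL effects (may be None when qtl_spec is empty); ``kinship`` is the
    c x c relationship matrix A (full-sib A = 0.5(I+J) by default).
    """
    if classes is not None:
        c = classes.shape[0]
    elif n_clones is not None:
        c = n_clones
    else:
        raise ValueError("need classes or n_clones")
    t = trial.n_traits
    if kinship is None:
        kinship = 0.5 * (np.eye(c) + np.ones((c, c)))
    kinship = np.asarray(kinship, dtype=float)
    if kinship.shape != (c, c):
        raise ValueError("kinship must be c x c")
    if not np.allclose(np.diag(kinship), 1.0, atol=1e-8):
        raise ValueError("kinship must have unit diagonal")
    if clone_ids is None:
        clone_ids = [f"F1_{j+1:03d}" for j in range(c)]

    rng = np.random.default_rng(trial.seed)
    # clone-level polygenic effects with cov(Vec(G)) = V_G (x) A
    la = _psd_sqrt(kinship)
    lg = _psd_sqrt(trial.V_G)
    G = la @ rng.standard_normal((c, t)) @ lg.T

    means = np.zeros(t) if trial.trait_means is None else np.asarray(trial.trait_means, float)
    blocks = (
        np.zeros((trial.n_blocks, t))
        if trial.block_effects is None
        else np.asarray(trial.block_effects, float)
    )

    qtl_shift = np.zeros((c, t))
    for q in trial.qtl_spec:
        if classes is None:
            raise ValueError("qtl_spec given but no genotype classes")
        col = classes[:, q.snp_index]
        for j in range(c):
            eff = q.effects.get(col[j])
            if eff is not None:
                qtl_shift[j] += np.asarray(eff, float)

    rows = []
    le = _psd_sqrt(trial.V_E)
    for i in range(trial.n_blocks):
        for j in range(c):
            for k in range(trial.cuttings_per_plot):
                rows.append((i, j, k))
    rows = np.array(rows)
    keep = rng.random(len(rows)) < trial.survival_rate
    rows = rows[keep]
    E = rng.standard_normal((len(rows), t)) @ le.T

    bi, cj, kk = rows.T
    Y = means[None, :] + blocks[bi] + qtl_shift[cj] + G[cj] + E
    out = pd.DataFrame(
        {
            "tree_id": [f"B{i+1}_{clone_ids[j]}_{k+1}" for i, j, k in rows],
            "block": bi + 1,
            "clone": [clone_ids[j] for j in cj],
        }
    )
    for l in range(t):
        out[f"trait_{l+1}"] = Y[:, l]
    return out


def default_radius_covariances(t: int, h2: float = 0.45, rho_g: float = 0.9,
                               rho_e: float = 0.8, sd: float = 20.0):
    """Realistic (V_G, V_E) for t polar-radius traits.

    Per-trait variance sd^2 split by heritability h2; strong positive
    genetic (rho_g) and residual (rho_e) correlations, matching the high
    phenotypic correlations among leaf dimension traits.
    """
    var = sd * sd
    vg = h2 * var * ((1 - rho_g) * np.eye(t) + rho_g * np.ones((t, t)))
    ve = (1 - h2) * var * ((1 - rho_e) * np.eye(t) + rho_e * np.ones((t, t)))
    return vg, ve


def default_radius_means(t: int, a: float = 57.0, b: float = 45.0) -> np.ndarray:
    """Mean radius profile of a typical leaf (ellipse closed form) on the
    right-side angle grid from -pi/2 to pi/2."""
    theta = np.linspace(-np.pi / 2, np.pi / 2, t)
    return a * b / np.sqrt((a * np.cos(theta)) ** 2 + (b * np.sin(theta)) ** 2)


# ---------------------------------------------------------------------------
# Writers

_ALLELE_TO_BASE = {"a": "A", "b": "C", "c": "G"}


def write_vcf(cross: Cross, path) -> None:
    """Minimal VCF 4.2 with GT fields; parents are the first two samples.

    Abstract alleles a/b/c are mapped to bases A/C/G; REF is the first
    allele in letter order at the site.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=leafgwas.simulate seed={cross.seed}\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in sorted(cross.snps["chrom"].unique()):
            fh.write(f"##contig=<ID=chr{chrom:02d}>\n")
        samples = ["P1", "P2"] + list(cross.clone_ids)
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for j, snp in cross.snps.iterrows():
            letters = sorted(
                set(cross.parent1[:, j]) | set(cross.parent2[:, j])
            )
            idx = {l: i for i, l in enumerate(letters)}
            ref = _ALLELE_TO_BASE[letters[0]]
            alts = [_ALLELE_TO_BASE[l] for l in letters[1:]] or ["."]
            def gt_phased(pair):
                return f"{idx[pair[0]]}|{idx[pair[1]]}"
            fields = [
                f"chr{snp.chrom:02d}", str(snp.pos_bp), snp.snp_id, ref,
                ",".join(alts), ".", "PASS", ".", "GT",
                gt_phased(cross.parent1[:, j]), gt_phased(cross.parent2[:, j]),
            ]
            for i in range(cross.n_clones):
                cls = cross.classes[i, j]
                if cls == "":
                    fields.append("./.")
                else:
                    a0, a1 = sorted(idx[x] for x in cls)
                    fields.append(f"{a0}/{a1}")
            fh.write("\t".join(fields) + "\n")


def write_genotype_tsv(cross: Cross, path) -> None:
    """Clone x SNP genotype-class matrix as TSV ('' = missing)."""
    df = pd.DataFrame(cross.classes, index=cross.clone_ids, columns=cross.snps["snp_id"])
    df.index.name = "clone"
    with open(path, "w") as fh:
        fh.write(f"# leafgwas.simulate genotype classes seed={cross.seed}\n")
        df.to_csv(fh, sep="\t")


def write_phenotype_csv(phenotypes: pd.DataFrame, path, seed: int | None = None) -> None:
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# leafgwas.simulate phenotypes seed={seed}\n")
        phenotypes.to_csv(fh, index=False)
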