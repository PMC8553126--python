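"""Segregation types of biallelic/multiallelic SNPs in an outbred F1 cross.

Each parent of an F1 family is either homozygous or heterozygous at a SNP;
writing parental alleles abstractly as a, b, c, the informative
configurations and their Mendelian offspring ratios are:

    aa x ab -> offspring aa : ab        1:1   (paternally informative)
    aa x bc -> offspring ab : ac        1:1
    ab x aa -> offspring aa : ab        1:1   (maternally informative)
    ab x cc -> offspring ac : bc        1:1
    ab x ab -> offspring aa : ab : bb   1:2:1 (both parents informative)

The het x het configuration sharing exactly one allele (ab x ac, ratio
1:1:1:1) is recognised in principle by the downstream filters but is not a
supported simulation/classification type here, mirroring the five-type
summary the study conditions are drawn from.
"""

from __future__ import annotations

SEG_TYPES = ("aaxab", "aaxbc", "abxaa", "abxcc", "abxab")

# Phased parental genotypes (haplotype 0, haplotype 1) per type.
PARENT_GENOTYPES = {
    "aaxab": (("a", "a"), ("a", "b")),
    "aaxbc": (("a", "a"), ("b", "c")),
    "abxaa": (("a", "b"), ("a", "a")),
    "abxcc": (("a", "b"), ("c", "c")),
    "abxab": (("a", "b"), ("a", "b")),
}

# Observable offspring genotype classes, canonical order, and Mendelian ratio.
OFFSPRING_CLASSES = {
    "aaxab": ("aa", "ab"),
    "aaxbc": ("ab", "ac"),
    "abxaa": ("aa", "ab"),
    "abxcc": ("ac", "bc"),
    "abxab": ("aa", "ab", "bb"),
}

EXPECTED_RATIOS = {
    "aaxab": (1, 1),
    "aaxbc": (1, 1),
    "abxaa": (1, 1),
    "abxcc": (1, 1),
    "abxab": (1, 2, 1),
}

# Ratios admitted by the Mendelian filter.
ADMITTED_RATIOS = {(1, 1), (1, 2, 1), (1, 1, 1, 1)}


def offspring_class(allele1: str, allele2: str) -> str:
    """Unordered genotype class label for one transmitted allele per parent."""
    return "".join(sorted((allele1, allele2)))
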