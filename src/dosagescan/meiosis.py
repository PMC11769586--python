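"""Meiotic transmission models for a triploid AAC hybrid, and SNP genotyping.

An F1 between a diploid (AA) and an allotetraploid (AACC) is triploid:
each A chromosome pair is accompanied by one homoeologous C chromosome.
Two pairing configurations matter for how that C chromosome reaches the
backcross progeny:

* **univalent** — the C chromosome stays unpaired and is included in a
  gamete with probability 1/2;
* **trivalent** — A+A+C pair as a trivalent; with strict 2:1 disjunction
  and the three pairing patterns equally likely, gametes segregate
  AA : AC : A : C = 1 : 2 : 2 : 1.

Probabilities are exact rationals.  SNP genotypes are called from allele
depths by frequency thresholds, the read-out used to phase A/C haplotype
structure in backcross individuals.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from itertools import combinations

__all__ = [
    "GametePMF",
    "SnpCall",
    "univalent_transmission",
    "trivalent_transmission",
    "joint_transmission",
    "genotype_snp",
]


@dataclass(frozen=True)
class GametePMF:
    """Probability mass over gamete genotype classes.

    Keys are sorted multiset labels of chromosome copies (e.g. ``"AC"``,
    ``"A"``, ``""`` for an empty complement); values are exact fractions
    summing to 1.
    """

    classes: dict[str, Fraction]

    def __post_init__(self) -> None:
        if any(p < 0 for p in self.classes.values()):
            raise ValueError("negative probability")
        if sum(self.classes.values(), Fraction(0)) != 1:
            raise ValueError("gamete class probabilities must sum to 1")

    def __getitem__(self, label: str) -> Fraction:
        return self.classes.get(label, Fraction(0))


def _label(chroms: tuple[str, ...]) -> str:
    return "".join(sorted(chroms))


def univalent_transmission(label: str = "C") -> GametePMF:
    """Transmission of a single unpaired (univalent) chromosome.

    The univalent enters a gamete with probability 1/2, so half of the
    backcross progeny inherit it — the null expectation against which
    depressed C-chromosome heritabilities are judged.
    """
    h = Fraction(1, 2)
    return GametePMF({label: h, "": h})


def trivalent_transmission(p_nondisjunction: Fraction | float = 0) -> GametePMF:
    """Gamete classes from a trivalent of two A homologues and one C.

    The three 2:1 disjunction patterns of (A, A, C) are enumerated as
    equally likely; each sends its two-chromosome side to one pole and the
    single chromosome to the other, and the two resulting gametes are
    equally likely.  The result is AA : AC : A : C = 1 : 2 : 2 : 1.

    ``p_nondisjunction`` adds a 3:0 segregation branch (all three
    chromosomes to one pole) with the given probability; the default 0 is
    the minimal strict-disjunction model.
    """
    p3 = Fraction(p_nondisjunction).limit_denominator(10**9)
    if not 0 <= p3 <= 1:
        raise ValueError("p_nondisjunction must be within [0, 1]")
    chroms = ("A", "A", "C")
    classes: dict[str, Fraction] = {}
    patterns = list(combinations(range(3), 2))  # the 2:1 disjunctions
    w = (1 - p3) * Fraction(1, len(patterns)) * Fraction(1, 2)
    for pair in patterns:
        duo = _label(tuple(chroms[i] for i in pair))
        solo = _label(tuple(chroms[i] for i in range(3) if i not in pair))
        classes[duo] = classes.get(duo, Fraction(0)) + w
        classes[solo] = classes.get(solo, Fraction(0)) + w
    if p3:
        half = p3 * Fraction(1, 2)
        classes[_label(chroms)] = classes.get(_label(chroms), Fraction(0)) + half
        classes[""] = classes.get("", Fraction(0)) + half
    return GametePMF(classes)


def joint_transmission(*pmfs: GametePMF) -> GametePMF:
    """Joint gamete classes of independently transmitted chromosomes.

    Class labels concatenate (as sorted multisets) across the inputs; two
    independent univalents, for instance, give four classes at 1:1:1:1.
    """
    classes = {"": Fraction(1)}
    for pmf in pmfs:
        nxt: dict[str, Fraction] = {}
        for lab1, p1 in classes.items():
            for lab2, p2 in pmf.classes.items():
                lab = _label(tuple(lab1) + tuple(lab2))
                nxt[lab] = nxt.get(lab, Fraction(0)) + p1 * p2
        classes = nxt
    return GametePMF(classes)


# ---------------------------------------------------------------------------
# SNP genotyping from allele depths


@dataclass(frozen=True)
class SnpCall:
    chrom: str
    pos: int
    ref_depth: int
    alt_depth: int
    genotype: str  # hom_ref | het | hom_alt | no_call


def genotype_snp(
    ref_depth: int,
    alt_depth: int,
    *,
    chrom: str = ".",
    pos: int = 0,
    min_depth: int = 4,
    het_band: tuple[float, float] = (0.2, 0.8),
) -> SnpCall:
    """Call a genotype from reference/alternate allele depths.

    With alternate-allele frequency f = alt / (ref + alt): f below the
    band is ``hom_ref``, above it ``hom_alt``, inside it (inclusive)
    ``het``.  Total depth below ``min_depth`` gives ``no_call``.
    """
    if ref_depth < 0 or alt_depth < 0:
        raise ValueError("allele depths must be non-negative")
    total = ref_depth + alt_depth
    if total < min_depth:
        gt = "no_call"
    else:
        f = alt_depth / total
        lo, hi = het_band
        gt = "hom_ref" if f < lo else "hom_alt" if f > hi else "het"
    return SnpCall(chrom, pos, ref_depth, alt_depth, gt)
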