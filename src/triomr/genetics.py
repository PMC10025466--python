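"""Single-locus genotype machinery for diallelic trio models.

Genotypes are stored as integer allele dosages (number of copies of the
reference allele: 0, 1 or 2); the string labels ``AA``/``Aa``/``aa`` (G locus)
and ``BB``/``Bb``/``bb`` (H locus) appear only at I/O boundaries.  The module
provides the two standard regression codings of a genotype — the additive code
``f_A`` (allele count) and the dominance code ``f_D`` (heterozygosity
indicator) — plus Hardy–Weinberg sampling, Mendelian transmission from parents
to offspring, and the six unordered parental *mating types* with their
reference-coded indicator vectors.

All sampling/coding functions are vectorised: they accept scalars or numpy
arrays of dosages and broadcast elementwise.
"""

from __future__ import annotations

import enum

import numpy as np

__all__ = [
    "MatingType",
    "additive_code",
    "dominance_code",
    "mating_type",
    "mating_type_code",
    "mating_type_indicators",
    "mating_type_indicator_matrix",
    "sample_genotype_hwe",
    "transmit",
    "genotype_label",
    "parse_genotype_label",
]


class MatingType(enum.IntEnum):
    """Unordered pair of parental genotypes at a diallelic locus.

    Six categories exist; ``aa/aa`` is the reference group in regression
    codings.  The integer values index the canonical category order.
    """

    AA_AA = 0
    AA_Aa = 1
    AA_aa = 2
    Aa_Aa = 3
    Aa_aa = 4
    aa_aa = 5

    @property
    def label(self) -> str:
        return _MATING_LABELS[self.value]


_MATING_LABELS = ("AA/AA", "AA/Aa", "AA/aa", "Aa/Aa", "Aa/aa", "aa/aa")

# canonical category for the descending-sorted dosage pair (hi, lo)
_MATING_LUT = np.full((3, 3), -1, dtype=np.int64)
_MATING_LUT[2, 2] = MatingType.AA_AA
_MATING_LUT[2, 1] = MatingType.AA_Aa
_MATING_LUT[2, 0] = MatingType.AA_aa
_MATING_LUT[1, 1] = MatingType.Aa_Aa
_MATING_LUT[1, 0] = MatingType.Aa_aa
_MATING_LUT[0, 0] = MatingType.aa_aa


def _as_dosage(g) -> np.ndarray:
    g = np.asarray(g)
    if not np.issubdtype(g.dtype, np.integer):
        gi = g.astype(np.int64)
        if not np.array_equal(gi, g):
            raise ValueError("genotype dosages must be integers")
        g = gi
    if g.size and (g.min() < 0 or g.max() > 2):
        raise ValueError("genotype dosages must lie in {0, 1, 2}")
    return g


def additive_code(g):
    """Additive coding f_A: the count of reference alleles (0, 1 or 2)."""
    return _as_dosage(g)


def dominance_code(g):
    """Dominance coding f_D: 1 for a heterozygote, 0 for either homozygote."""
    return (_as_dosage(g) == 1).astype(np.int64)


def mating_type_code(g_mother, g_father) -> np.ndarray:
    """Vectorised mating-type category codes for parental dosage arrays.

    The pair is canonicalised by sorting the two dosages, so the result is
    invariant under exchanging mother and father.
    """
    gm = _as_dosage(g_mother)
    gf = _as_dosage(g_father)
    hi = np.maximum(gm, gf)
    lo = np.minimum(gm, gf)
    return _MATING_LUT[hi, lo]


def mating_type(g_mother: int, g_father: int) -> MatingType:
    """Unordered parental mating type for a single couple."""
    return MatingType(int(mating_type_code(g_mother, g_father)))


def mating_type_indicators(p: MatingType) -> np.ndarray:
    """Reference-coded indicator vector (length 5) for one mating type.

    Components indicate AA/AA, AA/Aa, AA/aa, Aa/Aa and Aa/aa in that order;
    the vector is all-zero exactly for the reference category aa/aa.
    """
    out = np.zeros(5, dtype=np.int64)
    if p != MatingType.aa_aa:
        out[int(p)] = 1
    return out


def mating_type_indicator_matrix(codes) -> np.ndarray:
    """(n, 5) matrix of reference-coded mating-type indicators."""
    codes = np.asarray(codes, dtype=np.int64)
    n = codes.shape[0]
    out = np.zeros((n, 5), dtype=np.int64)
    rows = np.nonzero(codes != MatingType.aa_aa)[0]
    out[rows, codes[rows]] = 1
    return out


def sample_genotype_hwe(freq: float, rng: np.random.Generator, size=None):
    """Sample genotype dosages under Hardy–Weinberg equilibrium.

    Dosage probabilities are (q^2, 2q(1-q), (1-q)^2) for (2, 1, 0) where
    ``freq`` = q is the reference-allele frequency — i.e. Binomial(2, q).
    """
    if not 0.0 <= freq <= 1.0:
        raise ValueError(f"allele frequency must be in [0, 1], got {freq}")
    draw = rng.binomial(2, freq, size=size)
    return draw if size is not None else int(draw)


def transmit(g_mother, g_father, rng: np.random.Generator):
    """Mendelian transmission: one allele drawn at random from each parent.

    Each parent transmits the reference allele with probability dosage/2,
    independently of the other parent.  Accepts scalar or array dosages.
    """
    gm = _as_dosage(g_mother)
    gf = _as_dosage(g_father)
    a_m = rng.random(size=gm.shape) < gm / 2.0
    a_f = rng.random(size=gf.shape) < gf / 2.0
    child = a_m.astype(np.int64) + a_f.astype(np.int64)
    return child if child.shape else int(child)


_LABELS = {
    "G": ("aa", "Aa", "AA"),
    "H": ("bb", "Bb", "BB"),
}


def genotype_label(dosage: int, locus: str = "G") -> str:
    """Text label for a dosage at the given locus ('G' uses A/a, 'H' B/b)."""
    return _LABELS[locus][int(_as_dosage(dosage))]


def parse_genotype_label(label: str) -> int:
    """Dosage for a genotype label at either locus; raises on unknown labels."""
    for labels in _LABELS.values():
        if label in labels:
            return labels.index(label)
    raise ValueError(f"unknown genotype label: {label!r}")
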