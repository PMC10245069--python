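"""Site-saturation (NNS) variant library enumeration.

An NNS codon (N = any base, S = G or C) covers all 20 amino acids plus the
amber stop in 32 codons. Saturating every codon of an L-residue coding
sequence therefore yields 20 non-wild-type amino-acid variants per position
(19 substitutions + stop, minus nothing; the wild-type identity is excluded),
i.e. 20*L unique protein-level variants — 4220 for a 211-residue protein.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .alphabet import AA_SYMBOLS, NNS_CODONS, NNS_TRANSLATION, translate_codon

#: Default split of the 211-residue carrier into two amplicon sub-libraries,
#: chosen so each amplicon fits a 2x250 paired-end merge.
DEFAULT_SPLIT_AFTER = 107


@dataclass(frozen=True)
class VariantLibrary:
    """Complete single-mutant library over a wild-type coding sequence.

    Attributes
    ----------
    wt_cds:
        Wild-type coding sequence (length ``3*L``), no internal stop.
    wt_protein:
        Translation of ``wt_cds`` (length ``L``).
    positions:
        Ordered 1-based mutagenized positions.
    variants:
        Set of ``(position, symbol)`` pairs; symbol is an amino acid or ``*``
        and never the wild-type identity at that position.
    sublibraries:
        Inclusive 1-based position ranges partitioning ``positions``.
    """

    wt_cds: str
    wt_protein: str
    positions: tuple[int, ...]
    variants: frozenset[tuple[int, str]]
    sublibraries: tuple[tuple[int, int], ...]
    #: per-position synonymous (wild-type encoding) NNS codons, for bookkeeping
    wt_synonymous_codons: dict[int, tuple[str, ...]] = field(repr=False, default_factory=dict)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def variant_symbols(self, position: int) -> list[str]:
        """Non-WT symbols at ``position``, in alphabet order."""
        return [a for a in AA_SYMBOLS if (position, a) in self.variants]

    def sublibrary_positions(self, sub: tuple[int, int]) -> tuple[int, ...]:
        lo, hi = sub
        return tuple(p for p in self.positions if lo <= p <= hi)

    def sublibrary_cds(self, sub: tuple[int, int]) -> str:
        """Amplicon nucleotide sequence covering one sub-library range."""
        lo, hi = sub
        return self.wt_cds[3 * (lo - 1) : 3 * hi]


def default_sublibraries(n_positions: int) -> tuple[tuple[int, int], ...]:
    """Two amplicon ranges, split after position 107 (or one range if shorter)."""
    if n_positions > DEFAULT_SPLIT_AFTER:
        return ((1, DEFAULT_SPLIT_AFTER), (DEFAULT_SPLIT_AFTER + 1, n_positions))
    return ((1, n_positions),)


def generate_nns_library(
    wt_cds: str,
    positions: tuple[int, int] | None = None,
    sublibraries: tuple[tuple[int, int], ...] | None = None,
) -> VariantLibrary:
    """Enumerate the NNS site-saturation library of a coding sequence.

    At each position all 32 NNS codons are enumerated and collapsed to the
    amino-acid level; synonymous (wild-type) codons are recorded but do not
    contribute variants, so every position carries exactly 20 non-WT symbols.

    Parameters
    ----------
    wt_cds:
        Wild-type coding sequence; length divisible by 3, ACGT only, no
        internal stop codon in its translation.
    positions:
        Inclusive 1-based range of mutagenized positions; default all.
    sublibraries:
        Inclusive position ranges partitioning the mutagenized positions;
        default splits after residue 107 when the protein is longer.
    """
    wt_cds = wt_cds.upper()
    if len(wt_cds) % 3:
        raise ValueError(f"CDS length {len(wt_cds)} not divisible by 3")
    if set(wt_cds) - set("ACGT"):
        raise ValueError("CDS contains non-ACGT characters")
    n_codons = len(wt_cds) // 3
    wt_protein = "".join(
        translate_codon(wt_cds[3 * i : 3 * i + 3]) for i in range(n_codons)
    )
    if "*" in wt_protein:
        raise ValueError(
            f"wild-type translation has an internal stop at position {wt_protein.index('*') + 1}"
        )

    lo, hi = positions if positions is not None else (1, n_codons)
    if not (1 <= lo <= hi <= n_codons):
        raise ValueError(f"position range ({lo}, {hi}) outside 1..{n_codons}")
    pos_list = tuple(range(lo, hi + 1))

    if sublibraries is None:
        subs = tuple((lo + a - 1, lo + b - 1) for a, b in default_sublibraries(len(pos_list)))
    else:
        subs = tuple(tuple(s) for s in sublibraries)
        covered = [p for a, b in subs for p in range(a, b + 1)]
        if sorted(covered) != list(pos_list):
            raise ValueError("sub-library ranges must partition the position list")

    variants: set[tuple[int, str]] = set()
    synonymous: dict[int, tuple[str, ...]] = {}
    for pos in pos_list:
        wt_aa = wt_protein[pos - 1]
        syn = tuple(c for c in NNS_CODONS if NNS_TRANSLATION[c] == wt_aa)
        synonymous[pos] = syn
        for codon in NNS_CODONS:
            aa = NNS_TRANSLATION[codon]
            if aa != wt_aa:
                variants.add((pos, aa))
        assert len({a for p, a in variants if p == pos}) == 20

    return VariantLibrary(
        wt_cds=wt_cds,
        wt_protein=wt_protein,
        positions=pos_list,
        variants=frozenset(variants),
        sublibraries=subs,
        wt_synonymous_codons=synonymous,
    )


def nns_codons_for(aa: str) -> tuple[str, ...]:
    """All NNS codons encoding a given symbol (``*`` for stop)."""
    return tuple(c for c in NNS_CODONS if NNS_TRANSLATION[c] == aa)
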