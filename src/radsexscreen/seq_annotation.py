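"""Codon-level annotation of a SNP inside a gene model.

A gene model is a cDNA partitioned into 5'UTR, CDS and 3'UTR by three
stated lengths.  Given a variant at a CDS base position, the module locates
the codon, substitutes the alternate base and decides whether the change is
synonymous under the standard genetic code.  All positions are 1-based
inclusive; RNA 'U' in inputs is normalized to DNA 'T' (internal sequences
are DNA alphabet only).
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

STOP_CODONS = frozenset(standard_dna_table.stop_codons)


class PrematureStopError(ValueError):
    """Translation hit a stop codon before the end of the CDS."""

    def __init__(self, codon_index: int):
        super().__init__(f"internal stop codon at codon {codon_index}")
        self.codon_index = codon_index


def _normalize(seq: str) -> str:
    return seq.upper().replace("U", "T")


@dataclass(frozen=True)
class GeneModel:
    """A cDNA with stated 5'UTR / CDS / 3'UTR segment lengths.

    The three lengths must sum to the cDNA length, the CDS length must be a
    multiple of three, and the CDS must begin with ATG and end with a stop
    codon (checked on construction).
    """

    cdna_sequence: str
    utr5_length: int
    cds_length: int
    utr3_length: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "cdna_sequence", _normalize(self.cdna_sequence))
        total = self.utr5_length + self.cds_length + self.utr3_length
        if total != len(self.cdna_sequence):
            raise ValueError(
                f"segment lengths {self.utr5_length}+{self.cds_length}+"
                f"{self.utr3_length}={total} != cDNA length {len(self.cdna_sequence)}"
            )
        if self.cds_length % 3 != 0:
            raise ValueError(f"CDS length {self.cds_length} not divisible by 3")
        cds = self.cds
        if cds[:3] != "ATG":
            raise ValueError(f"CDS does not begin with ATG (got {cds[:3]})")
        if cds[-3:] not in STOP_CODONS:
            raise ValueError(f"CDS does not end with a stop codon (got {cds[-3:]})")

    @property
    def cds(self) -> str:
        return self.cdna_sequence[self.utr5_length:self.utr5_length + self.cds_length]


@dataclass(frozen=True)
class CodonConsequence:
    """Codon-level consequence of a single-base substitution in a CDS."""

    codon_index: int  # 1-based
    position_in_codon: int  # 1, 2 or 3
    ref_codon: str
    alt_codon: str
    ref_aa: str
    alt_aa: str
    synonymous: bool
    cdna_position: int  # 1-based offset within the whole cDNA


def translate_cds(cds: str) -> str:
    """Translate a CDS under the standard genetic code.

    The terminal stop is not included in the protein; an internal stop
    raises :class:`PrematureStopError` naming the codon.  Codons containing
    N translate to X.
    """
    cds = _normalize(cds)
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    protein = str(Seq(cds).translate(table="Standard"))
    if protein.endswith("*"):
        protein = protein[:-1]
    if "*" in protein:
        raise PrematureStopError(protein.index("*") + 1)
    return protein


def locate_transcript_region(model: GeneModel, cdna_position: int
                             ) -> tuple[str, int]:
    """Map a 1-based cDNA position to (region, 1-based offset in region)."""
    total = len(model.cdna_sequence)
    if not 1 <= cdna_position <= total:
        raise ValueError(f"cDNA position {cdna_position} outside 1..{total}")
    if cdna_position <= model.utr5_length:
        return "utr5", cdna_position
    if cdna_position <= model.utr5_length + model.cds_length:
        return "cds", cdna_position - model.utr5_length
    return "utr3", cdna_position - model.utr5_length - model.cds_length


def snp_codon_consequence(model: GeneModel, cds_position: int,
                          ref_base: str, alt_base: str) -> CodonConsequence:
    """Annotate a single-base substitution at a 1-based CDS position.

    The reference base must match the model sequence at that position; the
    codon index is ceil(cds_position / 3) and the synonymous flag compares
    standard-code translations of the reference and alternate codons.
    """
    ref_base = _normalize(ref_base)
    alt_base = _normalize(alt_base)
    if len(ref_base) != 1 or len(alt_base) != 1:
        raise ValueError("ref and alt must be single bases")
    if ref_base == alt_base:
        raise ValueError("alt base equals ref base: not a variant")
    if not 1 <= cds_position <= model.cds_length:
        raise ValueError(
            f"CDS position {cds_position} outside 1..{model.cds_length}; "
            "use locate_transcript_region for UTR positions"
        )
    cds = model.cds
    if cds[cds_position - 1] != ref_base:
        raise ValueError(
            f"reference allele mismatch: model has {cds[cds_position - 1]} "
            f"at CDS position {cds_position}, not {ref_base}"
        )
    codon_index = (cds_position + 2) // 3
    position_in_codon = (cds_position - 1) % 3 + 1
    start = (codon_index - 1) * 3
    ref_codon = cds[start:start + 3]
    alt_codon = (ref_codon[:position_in_codon - 1] + alt_base
                 + ref_codon[position_in_codon:])
    ref_aa = str(Seq(ref_codon).translate(table="Standard"))
    alt_aa = str(Seq(alt_codon).translate(table="Standard"))
    return CodonConsequence(
        codon_index=codon_index,
        position_in_codon=position_in_codon,
        ref_codon=ref_codon,
        alt_codon=alt_codon,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
        synonymous=ref_aa == alt_aa,
        cdna_position=model.utr5_length + cds_position,
    )


# ---------------------------------------------------------------------------
# Synthetic gene model
# ---------------------------------------------------------------------------

SPATA4_UTR5 = 489
SPATA4_CDS = 825
SPATA4_UTR3 = 494
SPATA4_CODON_175 = "CAC"

_SAFE_CODONS = [c for c in standard_dna_table.forward_table]  # no stops


def synthetic_spata4_model(seed: int = 0) -> GeneModel:
    """Build a synthetic stand-in for the spata4 transcript.

    The real nucleotide sequence is not reproduced here; this model only
    honours the published architecture — a 1,808-bp cDNA with a 489-bp
    5'UTR, an 825-bp ORF (274-aa protein) and a 494-bp 3'UTR, with CAC at
    codon 175 so the C>T variant at CDS position 525 is the His->His
    synonymous change.  Filler codons are drawn from the non-stop codon set
    with the given seed.
    """
    import numpy as np

    rng = np.random.default_rng(seed)
    n_codons = SPATA4_CDS // 3
    codons = ["ATG"] + [str(rng.choice(_SAFE_CODONS)) for _ in range(n_codons - 2)] \
        + ["TAA"]
    codons[174] = SPATA4_CODON_175  # codon 175, CDS positions 523-525
    cds = "".join(codons)
    bases = np.array(list("ACGT"))
    utr5 = "".join(rng.choice(bases, size=SPATA4_UTR5))
    utr3 = "".join(rng.choice(bases, size=SPATA4_UTR3))
    return GeneModel(utr5 + cds + utr3, SPATA4_UTR5, SPATA4_CDS, SPATA4_UTR3)
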