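"""Core domain types for the co-segregation mapping pipeline.

The pipeline analyses a four-library family design for a monogenic recessive
trait: one homozygous-mutant parent, one heterozygous parent, and two
phenotype-sorted offspring pools (homozygous-phenotype pool, heterozygous
pool).  Each library is genotyped as a single sample, so every biallelic
variant carries one diploid genotype call per library role.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple


class ConfigurationError(ValueError):
    """A role map or configuration does not match the input files."""


class UnsortedInputError(ValueError):
    """A variant stream is not sorted by (scaffold, position)."""


class ReferenceMismatchError(ValueError):
    """A variant's REF allele disagrees with the genome sequence at its site."""


class SimulationError(RuntimeError):
    """The cross simulator could not satisfy its constraints."""


class Genotype(enum.IntEnum):
    """Diploid genotype of one library at a biallelic site.

    Integer values equal ALT-allele dosage; MISSING is -1 so arrays of calls
    stay integer-typed.
    """

    MISSING = -1
    HOM_REF = 0
    HET = 1
    HOM_ALT = 2


class Role(str, enum.Enum):
    """The four family library roles of the breeding design."""

    HOM_PARENT = "hom_parent"
    HET_PARENT = "het_parent"
    HOM_POOL = "hom_pool"
    HET_POOL = "het_pool"


ROLES: Tuple[Role, ...] = tuple(Role)

#: Parental genotype pattern that makes a variant informative under the
#: default orientation (reference genome is wild-type, ALT is the mutant
#: lineage allele).
EXPECTED_PARENT_GENOTYPES: Dict[Role, Genotype] = {
    Role.HOM_PARENT: Genotype.HOM_ALT,
    Role.HET_PARENT: Genotype.HET,
}


class VariantClass(str, enum.Enum):
    SNP = "SNP"
    MNP = "MNP"
    INDEL = "INDEL"


def classify_alleles(ref: str, alt: str) -> VariantClass:
    """Variant class from allele lengths: SNP (1:1), MNP (n:n, n>1), else INDEL."""
    if len(ref) == len(alt):
        return VariantClass.SNP if len(ref) == 1 else VariantClass.MNP
    return VariantClass.INDEL


def normalize_role(role: "Role | str") -> Role:
    if isinstance(role, Role):
        return role
    try:
        return Role(str(role).lower())
    except ValueError:
        raise ConfigurationError(
            f"unknown library role {role!r}; expected one of "
            f"{[r.value for r in ROLES]}"
        ) from None


@dataclass
class VariantRecord:
    """One biallelic variant with a genotype call per library role.

    ``pos`` is 1-based (VCF convention).  Exactly one ALT allele is allowed;
    multi-allelic sites are skipped at read time.
    """

    scaffold: str
    pos: int
    ref: str
    alt: str
    genotypes: Dict[Role, Genotype]
    pass_filter: bool = True

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        for allele in (self.ref, self.alt):
            if not allele or "," in allele:
                raise ValueError(f"biallelic record requires one non-empty allele, got {allele!r}")
        self.genotypes = {normalize_role(r): Genotype(g) for r, g in self.genotypes.items()}
        missing = [r.value for r in ROLES if r not in self.genotypes]
        if missing:
            raise ValueError(f"genotypes missing roles: {missing}")

    @property
    def vclass(self) -> VariantClass:
        return classify_alleles(self.ref, self.alt)

    @property
    def end(self) -> int:
        """1-based inclusive end of the reference span."""
        return self.pos + len(self.ref) - 1


class ScaffoldIndex:
    """Ordered scaffold table, longest first (ties broken by name).

    Matches the per-scaffold plotting order of genome-wide scans.
    """

    def __init__(self, entries: Iterable[Tuple[str, int]]):
        cleaned = []
        for name, length in entries:
            length = int(length)
            if length <= 0:
                raise ValueError(f"scaffold {name!r} has non-positive length {length}")
            cleaned.append((str(name), length))
        names = [n for n, _ in cleaned]
        if len(set(names)) != len(names):
            raise ValueError("duplicate scaffold names in index")
        cleaned.sort(key=lambda item: (-item[1], item[0]))
        self._entries: List[Tuple[str, int]] = cleaned
        self._length = {n: l for n, l in cleaned}
        self._rank = {n: i for i, (n, _) in enumerate(cleaned)}

    def __iter__(self) -> Iterator[Tuple[str, int]]:
        return iter(self._entries)

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, name: str) -> bool:
        return name in self._length

    def __eq__(self, other: object) -> bool:
        return isinstance(other, ScaffoldIndex) and self._entries == other._entries

    def length(self, name: str) -> int:
        try:
            return self._length[name]
        except KeyError:
            raise KeyError(f"unknown scaffold {name!r}") from None

    def rank(self, name: str) -> int:
        """Position in longest-to-shortest order (0-based)."""
        return self._rank[name]

    @property
    def names(self) -> List[str]:
        return [n for n, _ in self._entries]

    def total_bp(self) -> int:
        return sum(l for _, l in self._entries)


@dataclass
class GeneModel:
    """Stranded exon/CDS structure of one canonical transcript.

    ``exons`` and ``cds`` are 1-based inclusive genomic intervals listed in
    transcription (5'->3') order: ascending coordinates on '+', descending on
    '-'.  Models whose CDS length is not a multiple of 3 are flagged via
    :attr:`complete` but kept.
    """

    gene_id: str
    gene_name: str
    scaffold: str
    strand: str
    exons: Tuple[Tuple[int, int], ...]
    cds: Tuple[Tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        self.exons = tuple((int(s), int(e)) for s, e in self.exons)
        self.cds = tuple((int(s), int(e)) for s, e in self.cds)
        for name, pieces in (("exons", self.exons), ("cds", self.cds)):
            for s, e in pieces:
                if s < 1 or e < s:
                    raise ValueError(f"{name} interval ({s}, {e}) is invalid")
            ordered = sorted(pieces, key=lambda p: p[0], reverse=self.strand == "-")
            if list(pieces) != ordered:
                raise ValueError(f"{name} must be listed in transcription order")
            flat = sorted(pieces)
            for (s1, e1), (s2, e2) in zip(flat, flat[1:]):
                if s2 <= e1:
                    raise ValueError(f"{name} intervals overlap: ({s1},{e1}) and ({s2},{e2})")

    # -- geometry -------------------------------------------------------
    @property
    def start(self) -> int:
        pieces = self.exons or self.cds
        return min(s for s, _ in pieces)

    @property
    def end(self) -> int:
        pieces = self.exons or self.cds
        return max(e for _, e in pieces)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    @property
    def complete(self) -> bool:
        """True when the CDS length is a whole number of codons."""
        return self.cds_length % 3 == 0

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def exon_ordinal(self, pos: int) -> Optional[int]:
        """1-based exon number, in transcription order, containing ``pos``."""
        for i, (s, e) in enumerate(self.exons, start=1):
            if s <= pos <= e:
                return i
        return None

    def nearest_exon_ordinal(self, pos: int) -> Optional[int]:
        best, best_d = None, None
        for i, (s, e) in enumerate(self.exons, start=1):
            d = 0 if s <= pos <= e else min(abs(pos - s), abs(pos - e))
            if best_d is None or d < best_d:
                best, best_d = i, d
        return best

    # -- spliced CDS coordinates ---------------------------------------
    def cds_index(self, pos: int) -> Optional[int]:
        """0-based offset of genomic ``pos`` in the spliced coding sequence."""
        offset = 0
        for s, e in self.cds:
            if s <= pos <= e:
                return offset + (pos - s if self.strand == "+" else e - pos)
            offset += e - s + 1
        return None

    def genomic_position(self, index: int) -> int:
        """Inverse of :meth:`cds_index`."""
        if index < 0:
            raise IndexError(f"negative CDS index {index}")
        offset = 0
        for s, e in self.cds:
            length = e - s + 1
            if index < offset + length:
                within = index - offset
                return s + within if self.strand == "+" else e - within
            offset += length
        raise IndexError(f"CDS index {index} out of range (CDS length {self.cds_length})")

    def spliced_cds(self, genome) -> str:
        """Coding-strand DNA of the spliced CDS (reverse-complemented on '-')."""
        from .io import reverse_complement  # local import avoids a cycle

        parts = []
        for s, e in self.cds:
            seq = genome.fetch(self.scaffold, s, e)
            parts.append(reverse_complement(seq) if self.strand == "-" else seq)
        return "".join(parts)
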