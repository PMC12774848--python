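"""Readers and writers for the standard formats the pipeline touches.

VCF (pysam), BED repeat masks (intervaltree), GFF3 gene annotation
(gffutils), genome FASTA (pyfaidx) and protein alignments (Biopython).
Internal interval arithmetic is 0-based half-open; everything reported to the
user is 1-based inclusive, matching the VCF/GFF3 convention.
"""
from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Sequence, Tuple

import pysam
import pyfaidx
import gffutils
from Bio import AlignIO
from Bio.Seq import Seq
from intervaltree import IntervalTree

from .records import (
    ConfigurationError,
    GeneModel,
    Genotype,
    ROLES,
    ReferenceMismatchError,
    Role,
    ScaffoldIndex,
    UnsortedInputError,
    VariantRecord,
    normalize_role,
)

logger = logging.getLogger("cosegmap")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _genotype_from_gt(gt: Optional[Tuple]) -> Genotype:
    if gt is None or len(gt) != 2 or any(a is None for a in gt):
        return Genotype.MISSING
    dosage = sum(1 for a in gt if a >= 1)
    return Genotype(dosage)


class VariantStream:
    """Iterates VariantRecords from a VCF, skipping multi-allelic sites.

    Phased and unphased genotypes are treated identically.  Records failing
    FILTER are retained with ``pass_filter=False``; the scan decides
    exclusion, which keeps quality filtering auditable in one place.
    """

    def __init__(self, path, role_map: Mapping["Role | str", str]):
        self.path = Path(path)
        roles = {normalize_role(r): str(s) for r, s in role_map.items()}
        missing_roles = [r.value for r in ROLES if r not in roles]
        if missing_roles:
            raise ConfigurationError(f"role map missing roles: {missing_roles}")
        self._vcf = pysam.VariantFile(str(self.path))
        samples = set(self._vcf.header.samples)
        for role, sample in roles.items():
            if sample not in samples:
                raise ConfigurationError(
                    f"sample {sample!r} for role {role.value!r} not found in "
                    f"{self.path.name} (samples: {sorted(samples)})"
                )
        self._roles = roles
        self.n_multiallelic = 0
        self.n_records = 0

    def scaffold_index(self) -> Optional[ScaffoldIndex]:
        entries = [
            (name, contig.length)
            for name, contig in self._vcf.header.contigs.items()
            if contig.length
        ]
        return ScaffoldIndex(entries) if entries else None

    def __iter__(self) -> Iterator[VariantRecord]:
        seen_done: set = set()
        current: Optional[str] = None
        last_pos = 0
        for rec in self._vcf:
            alts = rec.alts or ()
            if len(alts) != 1:
                self.n_multiallelic += 1
                continue
            if rec.chrom != current:
                if rec.chrom in seen_done:
                    raise UnsortedInputError(
                        f"{self.path.name}: scaffold {rec.chrom} appears in multiple "
                        "blocks; sort the VCF by (scaffold, position)"
                    )
                if current is not None:
                    seen_done.add(current)
                current, last_pos = rec.chrom, 0
            if rec.pos < last_pos:
                raise UnsortedInputError(
                    f"{self.path.name}: position {rec.pos} after {last_pos} on "
                    f"{rec.chrom}; sort the VCF by (scaffold, position)"
                )
            last_pos = rec.pos
            filters = list(rec.filter.keys())
            pass_filter = not filters or filters == ["PASS"]
            genotypes = {
                role: _genotype_from_gt(rec.samples[sample].get("GT"))
                for role, sample in self._roles.items()
            }
            self.n_records += 1
            yield VariantRecord(
                scaffold=rec.chrom,
                pos=rec.pos,
                ref=rec.ref,
                alt=alts[0],
                genotypes=genotypes,
                pass_filter=pass_filter,
            )

    def close(self) -> None:
        self._vcf.close()


def read_vcf(path, role_map: Mapping["Role | str", str]) -> VariantStream:
    """Open a multi-sample VCF as a stream of :class:`VariantRecord`."""
    return VariantStream(path, role_map)


def write_vcf(
    records: Iterable[VariantRecord],
    path,
    scaffold_index: Optional[ScaffoldIndex] = None,
    sample_names: Optional[Mapping["Role | str", str]] = None,
) -> Path:
    """Write records as an uncompressed 4-sample VCF.

    Records with ``pass_filter=False`` are written with ``FILTER=FAIL`` so
    the quality status round-trips.
    """
    path = Path(path)
    records = list(records)
    names = {normalize_role(r): s for r, s in (sample_names or {}).items()}
    samples = [names.get(role, role.value) for role in ROLES]

    header = pysam.VariantHeader()
    header.add_line('##FILTER=<ID=FAIL,Description="Failed upstream quality filter">')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    if scaffold_index is None:
        lengths: Dict[str, int] = {}
        for rec in records:
            lengths[rec.scaffold] = max(lengths.get(rec.scaffold, 0), rec.end)
        scaffold_index = ScaffoldIndex(lengths.items()) if lengths else ScaffoldIndex([])
    for name, length in scaffold_index:
        header.contigs.add(name, length=length)
    for sample in samples:
        header.add_sample(sample)

    gt_codes = {
        Genotype.MISSING: (None, None),
        Genotype.HOM_REF: (0, 0),
        Genotype.HET: (0, 1),
        Genotype.HOM_ALT: (1, 1),
    }
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for rec in records:
            vrec = out.new_record(
                contig=rec.scaffold, start=rec.pos - 1, alleles=(rec.ref, rec.alt)
            )
            vrec.filter.add("PASS" if rec.pass_filter else "FAIL")
            for role, sample in zip(ROLES, samples):
                vrec.samples[sample]["GT"] = gt_codes[rec.genotypes[role]]
            out.write(vrec)
    return path


# ---------------------------------------------------------------------------
# BED repeat mask
# ---------------------------------------------------------------------------

class RepeatMask:
    """Per-scaffold masked intervals, stored 0-based half-open and merged."""

    def __init__(self, intervals: Mapping[str, Iterable[Tuple[int, int]]]):
        self._trees: Dict[str, IntervalTree] = {}
        for scaffold, pairs in intervals.items():
            tree = IntervalTree()
            for start, end in pairs:
                if start >= end:
                    raise ValueError(f"empty mask interval ({start}, {end}) on {scaffold}")
                tree.addi(int(start), int(end))
            tree.merge_overlaps(strict=False)
            self._trees[str(scaffold)] = tree

    @classmethod
    def empty(cls) -> "RepeatMask":
        return cls({})

    def contains(self, scaffold: str, pos: int) -> bool:
        """Membership of a 1-based position."""
        tree = self._trees.get(scaffold)
        return bool(tree is not None and tree[pos - 1])

    def intervals(self, scaffold: str) -> List[Tuple[int, int]]:
        """Merged 0-based half-open intervals, sorted."""
        tree = self._trees.get(scaffold)
        if tree is None:
            return []
        return sorted((iv.begin, iv.end) for iv in tree)

    def masked_bp(self, scaffold: str) -> int:
        return sum(e - s for s, e in self.intervals(scaffold))

    @property
    def scaffolds(self) -> List[str]:
        return sorted(self._trees)


def read_bed_mask(path) -> RepeatMask:
    """Load a BED3+ file (0-based half-open) into a merged RepeatMask.

    Lines with start >= end are rejected with a warning, per-line.
    """
    path = Path(path)
    raw: Dict[str, List[Tuple[int, int]]] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                logger.warning("%s:%d: fewer than 3 BED columns, skipped", path.name, lineno)
                continue
            scaffold, start, end = fields[0], int(fields[1]), int(fields[2])
            if start >= end:
                logger.warning(
                    "%s:%d: start %d >= end %d, line rejected", path.name, lineno, start, end
                )
                continue
            raw.setdefault(scaffold, []).append((start, end))
    return RepeatMask(raw)


def write_bed(mask_or_intervals, path) -> Path:
    """Write 0-based half-open intervals as BED3."""
    path = Path(path)
    if isinstance(mask_or_intervals, RepeatMask):
        rows = [
            (scaffold, s, e)
            for scaffold in mask_or_intervals.scaffolds
            for s, e in mask_or_intervals.intervals(scaffold)
        ]
    else:
        rows = [
            (scaffold, s, e)
            for scaffold, pairs in sorted(mask_or_intervals.items())
            for s, e in sorted(pairs)
        ]
    with open(path, "w") as out:
        for scaffold, s, e in rows:
            out.write(f"{scaffold}\t{s}\t{e}\n")
    return path


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

_TRANSCRIPT_TYPES = ("mRNA", "transcript")


def read_gff3(path) -> List[GeneModel]:
    """Load gene models, selecting one canonical transcript per gene.

    Canonical transcript = longest total CDS, ties broken by the smallest
    transcript ID lexicographically (deterministic and annotation-agnostic).
    CDS features whose parent transcript is absent are excluded with an
    orphan warning.  Genes without any CDS-bearing transcript are returned
    with empty ``cds`` (usable for interval gene lists, not for consequence
    calls).
    """
    path = Path(path)
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    transcript_ids = {
        feat.id for ttype in _TRANSCRIPT_TYPES for feat in db.features_of_type(ttype)
    }
    for cds in db.features_of_type("CDS"):
        parents = cds.attributes.get("Parent", [])
        if parents and not any(p in transcript_ids for p in parents):
            logger.warning(
                "%s: CDS %s has no known parent transcript (%s); excluded",
                path.name, cds.id, ",".join(parents),
            )

    models: List[GeneModel] = []
    for gene in db.features_of_type("gene"):
        best = None
        for ttype in _TRANSCRIPT_TYPES:
            for tx in db.children(gene, featuretype=ttype, level=1):
                cds = sorted(db.children(tx, featuretype="CDS"), key=lambda f: f.start)
                exons = sorted(db.children(tx, featuretype="exon"), key=lambda f: f.start)
                cds_len = sum(f.end - f.start + 1 for f in cds)
                key = (-cds_len, tx.id)
                if best is None or key < best[0]:
                    best = (key, tx, exons, cds)
        if best is None:
            continue
        _, tx, exons, cds = best
        strand = gene.strand if gene.strand in ("+", "-") else "+"
        exon_iv = [(f.start, f.end) for f in exons] or [(f.start, f.end) for f in cds]
        cds_iv = [(f.start, f.end) for f in cds]
        if strand == "-":
            exon_iv = exon_iv[::-1]
            cds_iv = cds_iv[::-1]
        name = gene.attributes.get("Name", [gene.id])[0]
        model = GeneModel(
            gene_id=gene.id,
            gene_name=name,
            scaffold=gene.seqid,
            strand=strand,
            exons=tuple(exon_iv),
            cds=tuple(cds_iv),
        )
        if model.cds and not model.complete:
            logger.warning(
                "gene %s: CDS length %d not a multiple of 3 (incomplete model kept)",
                model.gene_id, model.cds_length,
            )
        models.append(model)
    models.sort(key=lambda m: (m.scaffold, m.start))
    return models


def write_gff3(models: Sequence[GeneModel], path) -> Path:
    """Write gene models as GFF3 (gene -> mRNA -> exon/CDS with phase)."""
    path = Path(path)
    with open(path, "w") as out:
        out.write("##gff-version 3\n")
        for m in models:
            tx_id = f"{m.gene_id}.t1"
            out.write(
                f"{m.scaffold}\tcosegmap\tgene\t{m.start}\t{m.end}\t.\t{m.strand}\t.\t"
                f"ID={m.gene_id};Name={m.gene_name}\n"
            )
            out.write(
                f"{m.scaffold}\tcosegmap\tmRNA\t{m.start}\t{m.end}\t.\t{m.strand}\t.\t"
                f"ID={tx_id};Parent={m.gene_id}\n"
            )
            for i, (s, e) in enumerate(sorted(m.exons), start=1):
                out.write(
                    f"{m.scaffold}\tcosegmap\texon\t{s}\t{e}\t.\t{m.strand}\t.\t"
                    f"ID={tx_id}.exon{i};Parent={tx_id}\n"
                )
            # phase follows transcription order
            phases = {}
            cum = 0
            for s, e in m.cds:
                phases[(s, e)] = (3 - cum % 3) % 3
                cum += e - s + 1
            for i, (s, e) in enumerate(sorted(m.cds), start=1):
                out.write(
                    f"{m.scaffold}\tcosegmap\tCDS\t{s}\t{e}\t.\t{m.strand}\t{phases[(s, e)]}\t"
                    f"ID={tx_id}.cds{i};Parent={tx_id}\n"
                )
    return path


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


class GenomeAccessor:
    """Random-access genome sequence backed by a (faidx-indexable) FASTA."""

    def __init__(self, path):
        self.path = Path(path)
        self._fasta = pyfaidx.Fasta(str(self.path), sequence_always_upper=True)

    def __contains__(self, scaffold: str) -> bool:
        return scaffold in self._fasta

    def length(self, scaffold: str) -> int:
        if scaffold not in self._fasta:
            raise KeyError(f"unknown scaffold {scaffold!r}")
        return len(self._fasta[scaffold])

    def fetch(self, scaffold: str, start: int, end: int) -> str:
        """Uppercase sequence for the 1-based inclusive range [start, end]."""
        length = self.length(scaffold)
        if start > end:
            raise ValueError(f"fetch start {start} > end {end} on {scaffold}")
        if start < 1 or end > length:
            raise ValueError(
                f"fetch [{start}, {end}] out of range for {scaffold} (length {length})"
            )
        return str(self._fasta[scaffold][start - 1 : end])

    def scaffold_index(self) -> ScaffoldIndex:
        return ScaffoldIndex((name, len(self._fasta[name])) for name in self._fasta.keys())

    def close(self) -> None:
        self._fasta.close()


class InMemoryGenome:
    """Genome accessor over a plain dict of sequences (synthetic fixtures/tests)."""

    def __init__(self, sequences: Mapping[str, str]):
        self._seqs = {str(k): str(v).upper() for k, v in sequences.items()}

    def __contains__(self, scaffold: str) -> bool:
        return scaffold in self._seqs

    def length(self, scaffold: str) -> int:
        if scaffold not in self._seqs:
            raise KeyError(f"unknown scaffold {scaffold!r}")
        return len(self._seqs[scaffold])

    def fetch(self, scaffold: str, start: int, end: int) -> str:
        length = self.length(scaffold)
        if start > end:
            raise ValueError(f"fetch start {start} > end {end} on {scaffold}")
        if start < 1 or end > length:
            raise ValueError(
                f"fetch [{start}, {end}] out of range for {scaffold} (length {length})"
            )
        return self._seqs[scaffold][start - 1 : end]

    def scaffold_index(self) -> ScaffoldIndex:
        return ScaffoldIndex((name, len(seq)) for name, seq in self._seqs.items())


def read_fasta(path) -> GenomeAccessor:
    """Open a genome FASTA for random access (a .fai index is built if absent)."""
    return GenomeAccessor(path)


def write_fasta(sequences: Mapping[str, str], path, width: int = 60) -> Path:
    path = Path(path)
    with open(path, "w") as out:
        for name, seq in sequences.items():
            out.write(f">{name}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")
    return path


def check_reference(variant: VariantRecord, genome) -> None:
    """Hard error if the variant's REF allele disagrees with the genome."""
    observed = genome.fetch(variant.scaffold, variant.pos, variant.end)
    if observed != variant.ref.upper():
        raise ReferenceMismatchError(
            f"{variant.scaffold}:{variant.pos} REF {variant.ref!r} does not match "
            f"genome sequence {observed!r}; check coordinate systems"
        )


# ---------------------------------------------------------------------------
# Protein alignments
# ---------------------------------------------------------------------------

def read_alignment(path, fmt: Optional[str] = None):
    """Read a protein multiple alignment (Clustal or aligned FASTA)."""
    path = Path(path)
    formats = [fmt] if fmt else ["clustal", "fasta"]
    last_error: Optional[Exception] = None
    for candidate in formats:
        try:
            return AlignIO.read(str(path), candidate)
        except ValueError as exc:
            last_error = exc
    raise ValueError(f"could not parse alignment {path.name}: {last_error}")
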