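"""Codon-level consequence annotation and alignment conservation calls.

A deliberately minimal annotator for SNV/MNP substitutions inside coding
sequence: it extracts the affected codon(s) from the canonical transcript,
translates reference and alternate codons under the standard genetic code,
and classifies the effect (synonymous, missense, stop_gained, stop_lost,
start_lost, splice_site_proximal, non_coding).  Codon changes are reported
in the RNA alphabet ("UGG->UAG") as is conventional for nonsense-variant
reporting; DNA alphabet is used everywhere else.

Indel consequences are out of scope at protein level: an indel overlapping
CDS is reported as ``indel_in_CDS`` with no codon detail.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd
from Bio.Seq import Seq

from .io import check_reference, reverse_complement
from .records import GeneModel, VariantClass, VariantRecord
from .scan import CandidateInterval

#: Effect classes ordered most to least severe; the MNP rule reports the
#: most severe class among the codons it touches.
SEVERITY_ORDER: Tuple[str, ...] = (
    "stop_gained",
    "stop_lost",
    "start_lost",
    "splice_site_proximal",
    "indel_in_CDS",
    "missense",
    "synonymous",
    "non_coding",
)
_SEVERITY = {name: i for i, name in enumerate(SEVERITY_ORDER)}

#: High-impact group ranks before missense in candidate triage.
HIGH_IMPACT = frozenset(
    {"stop_gained", "stop_lost", "start_lost", "splice_site_proximal", "indel_in_CDS"}
)

SPLICE_PROXIMITY_BP = 2

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def translate_codon(codon: str) -> str:
    """Single amino acid (or '*') for a DNA codon, standard genetic code."""
    if len(codon) != 3:
        raise ValueError(f"codon must have length 3, got {codon!r}")
    return str(Seq(codon).translate())


def to_rna(codon: str) -> str:
    return codon.upper().replace("T", "U")


@dataclass
class Consequence:
    """Predicted effect of one variant on one gene's canonical transcript."""

    variant: VariantRecord
    gene_id: str
    gene_name: str
    effect_class: str
    exon_ordinal: Optional[int]
    exon_total: int
    cds_codon_index: Optional[int] = None  # 1-based; equals protein position
    codon_change: Optional[str] = None  # RNA alphabet, e.g. "UGG->UAG"
    aa_change: Optional[str] = None  # e.g. "W->*"
    note: str = ""  # free text, e.g. externally attached domain annotations

    @property
    def protein_position(self) -> Optional[int]:
        return self.cds_codon_index

    def describe(self) -> str:
        bits = [self.gene_name, self.effect_class]
        if self.codon_change:
            bits.append(self.codon_change)
        if self.aa_change and self.cds_codon_index:
            ref_aa, alt_aa = self.aa_change.split("->")
            bits.append(f"{ref_aa}{self.cds_codon_index}{alt_aa}")
        if self.exon_ordinal is not None:
            bits.append(f"exon {self.exon_ordinal} of {self.exon_total}")
        return " - ".join(bits)


def _classify_codon(ref_codon: str, alt_codon: str, codon_index0: int) -> str:
    ref_aa = translate_codon(ref_codon)
    alt_aa = translate_codon(alt_codon)
    if ref_aa == alt_aa:
        return "synonymous"
    if alt_aa == "*":
        return "stop_gained"
    if ref_aa == "*":
        return "stop_lost"
    if codon_index0 == 0 and ref_codon.upper() == "ATG" and alt_codon.upper() != "ATG":
        return "start_lost"
    return "missense"


def _near_splice(gene: GeneModel, positions: Sequence[int]) -> bool:
    """Any position in the first SPLICE_PROXIMITY_BP intronic bases of a junction."""
    pieces = gene.exons or gene.cds
    lo, hi = gene.start, gene.end
    flanks = set()
    for s, e in pieces:
        for d in range(1, SPLICE_PROXIMITY_BP + 1):
            if s - d >= lo:
                flanks.add(s - d)
            if e + d <= hi:
                flanks.add(e + d)
    exonic = set()
    for s, e in pieces:
        exonic.update((s, e))
    # flank positions that fall inside another exon are not intronic
    def intronic(p: int) -> bool:
        return not any(s <= p <= e for s, e in pieces)

    return any(p in flanks and intronic(p) for p in positions)


def _annotate_against_gene(
    v: VariantRecord, gene: GeneModel, genome
) -> Consequence:
    positions = list(range(v.pos, v.end + 1))

    if v.vclass == VariantClass.INDEL:
        in_cds = any(gene.cds_index(p) is not None for p in positions)
        return Consequence(
            variant=v,
            gene_id=gene.gene_id,
            gene_name=gene.gene_name,
            effect_class="indel_in_CDS" if in_cds else "non_coding",
            exon_ordinal=gene.exon_ordinal(v.pos) or gene.nearest_exon_ordinal(v.pos),
            exon_total=gene.n_exons,
        )

    idxs = [gene.cds_index(p) for p in positions]
    if all(i is None for i in idxs):
        effect = "splice_site_proximal" if _near_splice(gene, positions) else "non_coding"
        return Consequence(
            variant=v,
            gene_id=gene.gene_id,
            gene_name=gene.gene_name,
            effect_class=effect,
            exon_ordinal=gene.nearest_exon_ordinal(v.pos),
            exon_total=gene.n_exons,
        )
    if any(i is None for i in idxs):
        # substitution spanning an exon/intron boundary: no codon call
        return Consequence(
            variant=v,
            gene_id=gene.gene_id,
            gene_name=gene.gene_name,
            effect_class="splice_site_proximal",
            exon_ordinal=gene.nearest_exon_ordinal(v.pos),
            exon_total=gene.n_exons,
        )

    cds_seq = gene.spliced_cds(genome)
    mutated = list(cds_seq)
    alt_by_index: Dict[int, str] = {}
    for p, alt_base in zip(positions, v.alt.upper()):
        i = gene.cds_index(p)
        base = alt_base if gene.strand == "+" else alt_base.translate(_COMPLEMENT)
        alt_by_index[i] = base
        mutated[i] = base
    mutated_seq = "".join(mutated)

    best: Optional[Tuple[int, int, str, str, str]] = None  # (severity, codon0, ref, alt, eff)
    for codon0 in sorted({i // 3 for i in alt_by_index}):
        ref_codon = cds_seq[codon0 * 3 : codon0 * 3 + 3]
        alt_codon = mutated_seq[codon0 * 3 : codon0 * 3 + 3]
        if len(ref_codon) < 3:
            continue  # incomplete terminal codon of a flagged model
        effect = _classify_codon(ref_codon, alt_codon, codon0)
        key = (_SEVERITY[effect], codon0)
        if best is None or key < (best[0], best[1]):
            best = (_SEVERITY[effect], codon0, ref_codon, alt_codon, effect)
    if best is None:
        return Consequence(
            variant=v,
            gene_id=gene.gene_id,
            gene_name=gene.gene_name,
            effect_class="non_coding",
            exon_ordinal=gene.nearest_exon_ordinal(v.pos),
            exon_total=gene.n_exons,
            note="variant only touches an incomplete terminal codon",
        )
    _, codon0, ref_codon, alt_codon, effect = best
    # report the exon holding the affected codon (via one of its variant bases)
    codon_positions = [p for p in positions if gene.cds_index(p) // 3 == codon0]
    exon_ordinal = gene.exon_ordinal(codon_positions[0])
    return Consequence(
        variant=v,
        gene_id=gene.gene_id,
        gene_name=gene.gene_name,
        effect_class=effect,
        exon_ordinal=exon_ordinal,
        exon_total=gene.n_exons,
        cds_codon_index=codon0 + 1,
        codon_change=f"{to_rna(ref_codon)}->{to_rna(alt_codon)}",
        aa_change=f"{translate_codon(ref_codon)}->{translate_codon(alt_codon)}",
    )


def annotate_variant(
    v: VariantRecord, genes: Iterable[GeneModel], genome
) -> List[Consequence]:
    """One Consequence per overlapping gene's canonical transcript.

    The REF allele is checked against the genome first; a mismatch is a
    coordinate-system fault and raises :class:`ReferenceMismatchError`.
    """
    check_reference(v, genome)
    hits = [
        g
        for g in genes
        if g.scaffold == v.scaffold and v.pos <= g.end and v.end >= g.start
    ]
    hits.sort(key=lambda g: g.start)
    return [_annotate_against_gene(v, g, genome) for g in hits]


def genes_in_interval(
    genes: Iterable[GeneModel], interval: CandidateInterval
) -> List[GeneModel]:
    """Genes whose span overlaps any part of the interval (1 bp suffices)."""
    out = [
        g
        for g in genes
        if g.scaffold == interval.scaffold
        and any(g.start <= e and g.end >= s for s, e in interval.parts)
    ]
    out.sort(key=lambda g: g.start)
    return out


# ---------------------------------------------------------------------------
# alignment-column conservation
# ---------------------------------------------------------------------------

#: Clustal "strong" similarity groups used for ':' calls.
CLUSTAL_STRONG_GROUPS: Tuple[frozenset, ...] = tuple(
    frozenset(group)
    for group in ("STA", "NEQK", "NHQK", "NDEQ", "QHRK", "MILV", "MILF", "HY", "FYW")
)

_GAPS = {"-", ".", " "}


@dataclass
class ConservationCall:
    """Conservation class of one alignment column.

    '*' conserved (all non-gap residues identical), ':' conservative (all
    residues within one Clustal strong similarity group), ' ' variable.
    """

    column: int
    residues: Tuple[str, ...]
    call: str


def _rows(alignment) -> List[str]:
    if hasattr(alignment, "get_alignment_length"):  # Bio.Align.MultipleSeqAlignment
        return [str(rec.seq) for rec in alignment]
    return [str(row) for row in alignment]


def classify_conservation(alignment, column: int) -> ConservationCall:
    """Classify one column of an aligned set of protein sequences."""
    rows = _rows(alignment)
    if not rows:
        raise ValueError("empty alignment")
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise ValueError(f"ragged alignment: row lengths {sorted(lengths)}")
    width = lengths.pop()
    if not 0 <= column < width:
        raise IndexError(f"column {column} outside alignment of width {width}")
    residues = tuple(r[column].upper() for r in rows)
    non_gap = [r for r in residues if r not in _GAPS]
    if not non_gap:
        call = " "
    elif len(set(non_gap)) == 1:
        call = "*"
    elif any(set(non_gap) <= group for group in CLUSTAL_STRONG_GROUPS):
        call = ":"
    else:
        call = " "
    return ConservationCall(column=column, residues=residues, call=call)


def conservation_string(alignment) -> str:
    """Clustal-style annotation line over all columns."""
    rows = _rows(alignment)
    width = len(rows[0]) if rows else 0
    return "".join(classify_conservation(rows, c).call for c in range(width))


# ---------------------------------------------------------------------------
# candidate triage report
# ---------------------------------------------------------------------------

def summarize_candidates(
    consequences: Iterable[Consequence],
    expression_table: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Deterministic triage report over an interval's consequences.

    High-impact calls (premature stops, start/stop losses, splice-proximal,
    CDS indels) rank first, then missense, then synonymous/non-coding; ties
    are ordered by position.  An externally produced differential-expression
    table (columns ``gene``, ``log2FC``, ``padj``) may be joined per gene.
    """
    rows = []
    for c in consequences:
        if c.effect_class in HIGH_IMPACT:
            group = 0
        elif c.effect_class == "missense":
            group = 1
        else:
            group = 2
        rows.append(
            {
                "gene_id": c.gene_id,
                "gene": c.gene_name,
                "scaffold": c.variant.scaffold,
                "pos": c.variant.pos,
                "ref": c.variant.ref,
                "alt": c.variant.alt,
                "effect_class": c.effect_class,
                "codon_change": c.codon_change or "",
                "aa_change": c.aa_change or "",
                "protein_position": c.cds_codon_index,
                "exon": f"{c.exon_ordinal}/{c.exon_total}" if c.exon_ordinal else "",
                "note": c.note,
                "summary": c.describe(),
                "_group": group,
                "_severity": _SEVERITY[c.effect_class],
            }
        )
    if not rows:
        columns = [
            "rank", "gene_id", "gene", "scaffold", "pos", "ref", "alt",
            "effect_class", "codon_change", "aa_change", "protein_position",
            "exon", "note", "summary",
        ]
        return pd.DataFrame(columns=columns)
    df = pd.DataFrame(rows)
    df = df.sort_values(
        ["_group", "_severity", "scaffold", "pos"], kind="mergesort"
    ).drop(columns=["_group", "_severity"])
    df.insert(0, "rank", range(1, len(df) + 1))
    if expression_table is not None and "gene" in expression_table.columns:
        df = df.merge(expression_table, on="gene", how="left")
    return df.reset_index(drop=True)
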