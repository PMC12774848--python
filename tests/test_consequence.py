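"""Codon-level consequence calls, strand symmetry and conservation classes."""
import itertools

import numpy as np
import pandas as pd
import pytest

from cosegmap import (
    CandidateInterval,
    InMemoryGenome,
    ReferenceMismatchError,
    annotate_variant,
    classify_conservation,
    conservation_string,
    genes_in_interval,
    summarize_candidates,
    translate_codon,
)
from cosegmap.consequence import CLUSTAL_STRONG_GROUPS
from cosegmap.records import GeneModel
from cosegmap.simulate import embed_gene, synthetic_gene

from conftest import make_variant
from oracles import whole_protein_effect

_BASES = "ACGT"


def genome_with_gene(model, coding, rng=None, pad=200):
    """Random scaffold sequence with the gene's coding bases embedded."""
    rng = rng or np.random.default_rng(0)
    length = model.end + pad
    arr = np.frombuffer(b"ACGT", dtype=np.uint8)[rng.integers(0, 4, size=length)].copy()
    embed_gene(arr, model, coding)
    return InMemoryGenome({model.scaffold: arr.tobytes().decode()})


def variant_at(genome, model, cds_index, alt_coding_base):
    """SNV at a spliced-CDS offset, expressed in genomic (plus-strand) alleles."""
    pos = model.genomic_position(cds_index)
    ref = genome.fetch(model.scaffold, pos, pos)
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    alt = alt_coding_base if model.strand == "+" else comp[alt_coding_base]
    return make_variant(scaffold=model.scaffold, pos=pos, ref=ref, alt=alt)


class TestPaperCodonCalls:
    def test_tryptophan_stop_gain_on_minus_strand(self):
        # UGG -> UAG through a genomic C->T: the codon sits on the minus strand
        model, coding = synthetic_gene(
            "slc_like", "s1", "-", [45] * 8,
            special_codons={80: "TGG"}, rng=np.random.default_rng(1),
        )
        genome = genome_with_gene(model, coding)
        pos = model.genomic_position(80 * 3 + 1)
        assert genome.fetch("s1", pos, pos) == "C"
        v = make_variant(scaffold="s1", pos=pos, ref="C", alt="T")
        (cons,) = annotate_variant(v, [model], genome)
        assert cons.effect_class == "stop_gained"
        assert cons.codon_change == "UGG->UAG"
        assert cons.aa_change == "W->*"
        assert (cons.exon_ordinal, cons.exon_total) == (6, 8)

    def test_arginine_stop_gain_cga_to_uga(self):
        # CGA -> UGA through a genomic G->A on the minus strand, exon 6 of 23
        model, coding = synthetic_gene(
            "oca_like", "s1", "-", [6] * 23,
            special_codons={11: "CGA"}, rng=np.random.default_rng(2),
        )
        genome = genome_with_gene(model, coding)
        pos = model.genomic_position(11 * 3)  # first codon base: the C
        assert genome.fetch("s1", pos, pos) == "G"  # complement on plus strand
        v = make_variant(scaffold="s1", pos=pos, ref="G", alt="A")
        (cons,) = annotate_variant(v, [model], genome)
        assert cons.effect_class == "stop_gained"
        assert cons.codon_change == "CGA->UGA"
        assert cons.aa_change == "R->*"
        assert (cons.exon_ordinal, cons.exon_total) == (6, 23)

    def test_missense_reports_protein_position_392(self):
        model, coding = synthetic_gene(
            "tyr_like", "s1", "+", [600, 600], special_codons={391: "GAT"},
            rng=np.random.default_rng(3),
        )
        genome = genome_with_gene(model, coding)
        v = variant_at(genome, model, 391 * 3 + 1, "T")  # GAT -> GTT, D -> V
        (cons,) = annotate_variant(v, [model], genome)
        assert cons.effect_class == "missense"
        assert cons.cds_codon_index == 392
        assert cons.protein_position == 392


@pytest.fixture(scope="module")
def plus_gene():
    model, coding = synthetic_gene(
        "plus", "s1", "+", [30, 33, 30],
        special_codons={5: "TGG", 12: "CAT"}, rng=np.random.default_rng(4),
    )
    return model, coding, genome_with_gene(model, coding)


class TestEffectClasses:
    def test_synonymous_when_translation_unchanged(self, plus_gene):
        model, coding, genome = plus_gene
        # CAT -> CAC both encode histidine
        v = variant_at(genome, model, 12 * 3 + 2, "C")
        assert coding[12 * 3 : 12 * 3 + 3] == "CAT"
        (cons,) = annotate_variant(v, [model], genome)
        assert cons.effect_class == "synonymous"

    def test_start_codon_loss(self, plus_gene):
        model, coding, genome = plus_gene
        v = variant_at(genome, model, 0, "C")  # ATG -> CTG
        (cons,) = annotate_variant(v, [model], genome)
        assert cons.effect_class == "start_lost"

    def test_stop_codon_loss(self, plus_gene):
        model, coding, genome = plus_gene
        last = len(coding) - 3
        assert coding[last:] == "TAA"
        v = variant_at(genome, model, last, "C")  # TAA -> CAA
        (cons,) = annotate_variant(v, [model], genome)
        assert cons.effect_class == "stop_lost"

    def test_intronic_near_junction_is_splice_proximal(self, plus_gene):
        model, _, genome = plus_gene
        first_exon_end = model.cds[0][1]
        for offset, expected in [(1, "splice_site_proximal"), (2, "splice_site_proximal"),
                                 (3, "non_coding")]:
            pos = first_exon_end + offset
            ref = genome.fetch("s1", pos, pos)
            alt = "A" if ref != "A" else "G"
            v = make_variant(scaffold="s1", pos=pos, ref=ref, alt=alt)
            (cons,) = annotate_variant(v, [model], genome)
            assert cons.effect_class == expected, f"offset {offset}"

    def test_mnp_spanning_junction_has_no_codon_call(self, plus_gene):
        model, _, genome = plus_gene
        end = model.cds[0][1]
        ref = genome.fetch("s1", end, end + 1)
        alt = "".join("A" if b != "A" else "G" for b in ref)
        v = make_variant(scaffold="s1", pos=end, ref=ref, alt=alt)
        (cons,) = annotate_variant(v, [model], genome)
        assert cons.effect_class == "splice_site_proximal"
        assert cons.codon_change is None

    def test_mnp_touching_two_codons_reports_most_severe(self):
        model, coding = synthetic_gene(
            "mnp", "s1", "+", [60], special_codons={5: "TGG", 6: "AAA"},
            rng=np.random.default_rng(5),
        )
        genome = genome_with_gene(model, coding)
        # change TGG|AAA -> TGA|CAA: stop_gained at codon 6 beats missense at 7
        pos = model.genomic_position(5 * 3 + 2)
        v = make_variant(scaffold="s1", pos=pos, ref="GA", alt="AC")
        (cons,) = annotate_variant(v, [model], genome)
        assert cons.effect_class == "stop_gained"
        assert cons.cds_codon_index == 6

    def test_reference_mismatch_is_hard_error(self, plus_gene):
        model, _, genome = plus_gene
        pos = model.genomic_position(10)
        wrong = "A" if genome.fetch("s1", pos, pos) != "A" else "C"
        v = make_variant(scaffold="s1", pos=pos, ref=wrong, alt="G")
        with pytest.raises(ReferenceMismatchError):
            annotate_variant(v, [model], genome)

    def test_indel_in_cds_reported_without_codon_detail(self, plus_gene):
        model, _, genome = plus_gene
        pos = model.genomic_position(9)
        ref = genome.fetch("s1", pos, pos)
        v = make_variant(scaffold="s1", pos=pos, ref=ref, alt=ref + "T")
        (cons,) = annotate_variant(v, [model], genome)
        assert cons.effect_class == "indel_in_CDS"
        assert cons.codon_change is None


class TestStrandSymmetry:
    def test_mirrored_construction_gives_identical_calls(self):
        rng = np.random.default_rng(6)
        for trial in range(20):
            lens = [int(x) for x in rng.integers(4, 30, size=rng.integers(1, 4))]
            total = sum(lens)
            lens[-1] += (3 - total % 3) % 3
            if sum(lens) < 9:
                lens[-1] += 9
            plus_model, coding = synthetic_gene(
                "fwd", "s1", "+", lens, rng=np.random.default_rng(100 + trial)
            )
            plus_genome = genome_with_gene(plus_model, coding, rng=np.random.default_rng(trial))
            length = plus_genome.length("s1")
            # mirror: reverse-complement the scaffold; gene lands on '-'
            from cosegmap import reverse_complement

            mirrored_seq = reverse_complement(plus_genome.fetch("s1", 1, length))
            minus_genome = InMemoryGenome({"s1": mirrored_seq})
            mirror = lambda iv: (length - iv[1] + 1, length - iv[0] + 1)
            minus_model = GeneModel(
                gene_id="rev", gene_name="rev", scaffold="s1", strand="-",
                exons=tuple(mirror(iv) for iv in plus_model.exons),
                cds=tuple(mirror(iv) for iv in plus_model.cds),
            )
            assert minus_model.spliced_cds(minus_genome) == coding
            idx = int(rng.integers(0, sum(lens)))
            base = coding[idx]
            alt = _BASES[(_BASES.index(base) + 1 + int(rng.integers(0, 3))) % 4]
            if alt == base:
                alt = _BASES[(_BASES.index(base) + 1) % 4]
            v_plus = variant_at(plus_genome, plus_model, idx, alt)
            v_minus = variant_at(minus_genome, minus_model, idx, alt)
            (c_plus,) = annotate_variant(v_plus, [plus_model], plus_genome)
            (c_minus,) = annotate_variant(v_minus, [minus_model], minus_genome)
            assert c_plus.effect_class == c_minus.effect_class
            assert c_plus.codon_change == c_minus.codon_change
            assert c_plus.cds_codon_index == c_minus.cds_codon_index


class TestOracleEquivalence:
    def test_effect_matches_whole_protein_rebuild_on_random_genes(self):
        """500 random single-gene models, random SNVs, vs full-CDS translation."""
        rng = np.random.default_rng(42)
        checked = {"stop_gained": 0, "missense": 0, "synonymous": 0}
        for trial in range(500):
            n_ex = int(rng.integers(1, 5))
            lens = [int(x) for x in rng.integers(4, 40, size=n_ex)]
            total = sum(lens)
            lens[-1] += (3 - total % 3) % 3
            if sum(lens) < 9:
                lens[-1] += 9  # keep at least the start/stop plus one codon
            strand = "+" if rng.random() < 0.5 else "-"
            model, coding = synthetic_gene(
                f"g{trial}", "s1", strand, lens, rng=np.random.default_rng(trial)
            )
            genome = genome_with_gene(model, coding, rng=np.random.default_rng(trial + 1))
            idx = int(rng.integers(0, len(coding)))
            base = coding[idx]
            alt = _BASES[(_BASES.index(base) + 1 + int(rng.integers(0, 3))) % 4]
            if alt == base:
                continue
            v = variant_at(genome, model, idx, alt)
            (cons,) = annotate_variant(v, [model], genome)
            expected = whole_protein_effect(model, genome, v)
            assert cons.effect_class == expected, f"trial {trial}"
            if expected in checked:
                checked[expected] += 1
        # the fuzz actually exercised every major class
        assert all(count > 0 for count in checked.values()), checked


class TestGeneticCode:
    def test_all_64_codons_translate_and_stops_are_exact(self):
        codons = ["".join(c) for c in itertools.product("ACGT", repeat=3)]
        table = {c: translate_codon(c) for c in codons}
        assert len(table) == 64
        assert all(len(aa) == 1 for aa in table.values())
        stops = {c for c, aa in table.items() if aa == "*"}
        assert stops == {"TAA", "TAG", "TGA"}


class TestGenesInInterval:
    def _gene(self, gene_id, start, end, scaffold="s1"):
        return GeneModel(
            gene_id=gene_id, gene_name=gene_id, scaffold=scaffold, strand="+",
            exons=((start, end),), cds=((start, end),),
        )

    def test_overlap_rules(self):
        interval = CandidateInterval.from_span("s1", 1_000, 2_000, n_coseg_total=0)
        inside = self._gene("inside", 1_200, 1_800)
        edge = self._gene("edge", 2_000, 2_500)  # 1 bp overlap counts
        outside = self._gene("outside", 2_001, 2_500)
        elsewhere = self._gene("elsewhere", 1_200, 1_800, scaffold="s2")
        hits = genes_in_interval([outside, edge, inside, elsewhere], interval)
        assert [g.gene_id for g in hits] == ["inside", "edge"]

    def test_multi_part_interval_excludes_gap_genes(self):
        interval = CandidateInterval(
            scaffold="s1", parts=((1_000, 2_000), (5_000, 6_000)),
            max_proportion=1.0, n_coseg_total=0,
        )
        gap = self._gene("gap", 3_000, 4_000)
        second = self._gene("second", 5_500, 5_900)
        hits = genes_in_interval([gap, second], interval)
        assert [g.gene_id for g in hits] == ["second"]


class TestConservation:
    @pytest.mark.parametrize(
        "column,expected",
        [
            (["W", "W", "W"], "*"),
            (["I", "L", "V"], ":"),  # MILV strong group
            (["W", "R", "W"], " "),
            (["W", "-", "W"], "*"),  # gaps ignored for identity
            (["-", "-", "-"], " "),  # all-gap column is variable
            (["S", "T", "A"], ":"),
            (["N", "D", "E", "Q"], ":"),
            (["F", "Y", "W"], ":"),
            (["M", "I", "L", "F", "V"], " "),  # spans two groups, no single fit
        ],
    )
    def test_column_classes(self, column, expected):
        alignment = ["".join(c) for c in column]
        assert classify_conservation(alignment, 0).call == expected

    def test_ragged_alignment_rejected(self):
        with pytest.raises(ValueError, match="ragged"):
            classify_conservation(["AB", "A"], 0)

    def test_conservation_string_over_columns(self):
        alignment = ["WIS", "WLT", "WVR"]
        assert conservation_string(alignment) == "*: "

    def test_aligned_fasta_file_classifies(self, tmp_path):
        from cosegmap import read_alignment

        path = tmp_path / "aln.fasta"
        path.write_text(">sp1\nWIS\n>sp2\nWLT\n>sp3\nWVR\n")
        alignment = read_alignment(path)
        assert conservation_string(alignment) == "*: "

    def test_clustal_file_classifies(self, tmp_path):
        from cosegmap import read_alignment

        path = tmp_path / "aln.aln"
        path.write_text(
            "CLUSTAL W (1.82) multiple sequence alignment\n\n"
            "sp1             WIS\n"
            "sp2             WLT\n"
            "sp3             WVR\n"
        )
        alignment = read_alignment(path)
        assert classify_conservation(alignment, 1).call == ":"

    def test_strong_groups_match_clustal_definition(self):
        expected = {"STA", "NEQK", "NHQK", "NDEQ", "QHRK", "MILV", "MILF", "HY", "FYW"}
        assert {"".join(sorted(g)) for g in CLUSTAL_STRONG_GROUPS} == {
            "".join(sorted(g)) for g in expected
        }


class TestSummarizeCandidates:
    def _consequences(self):
        model, coding = synthetic_gene(
            "sum", "s1", "+", [90], special_codons={5: "TGG", 10: "TGG", 20: "CAT"},
            rng=np.random.default_rng(7),
        )
        genome = genome_with_gene(model, coding)
        out = []
        for codon, alt in [(20, "C"), (5, "A"), (10, "A")]:
            # CAT->CAC synonymous is avoided: use middle base for stops
            idx = codon * 3 + 1
            v = variant_at(genome, model, idx, alt)
            out.extend(annotate_variant(v, [model], genome))
        return out

    def test_high_impact_ranks_first_then_position_order(self):
        df = summarize_candidates(self._consequences())
        assert list(df["effect_class"][:2]) == ["stop_gained", "stop_gained"]
        assert df["pos"].iloc[0] < df["pos"].iloc[1]  # two stops: position order
        assert list(df["rank"]) == [1, 2, 3]

    def test_expression_table_joined_per_gene(self):
        expr = pd.DataFrame({"gene": ["sum"], "log2FC": [-2.5], "padj": [1e-4]})
        df = summarize_candidates(self._consequences(), expr)
        assert (df["log2FC"] == -2.5).all()

    def test_empty_report(self):
        df = summarize_candidates([])
        assert df.empty
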