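"""Synthetic Mendelian cross generator for the four-library family design.

The simulator produces exactly the statistical structure the scan assumes:

* two founder lineages -- a mutant lineage haplotype carrying the causal
  recessive allele plus linked alternate alleles at informative markers, and
  wild-type haplotypes carrying reference alleles;
* gametes formed with interference-free Poisson crossovers (Haldane map),
  so linkage to the causal locus decays with genetic distance;
* offspring sorted into pools by phenotype, i.e. by genotype at the causal
  locus (recessive: homozygous-mutant <-> mutant phenotype);
* pooled libraries genotyped as one diploid-like sample: per marker, read
  depth is Poisson, alternate reads are binomial around the true pooled
  allele fraction with symmetric per-base error, and a threshold caller
  stands in for a variant caller's behaviour on pooled reads.

Everything is deterministic under the configured seed.
"""
from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .io import write_bed, write_fasta, write_gff3, write_vcf
from .records import (
    GeneModel,
    Genotype,
    ROLES,
    Role,
    ScaffoldIndex,
    SimulationError,
    VariantRecord,
)

logger = logging.getLogger("cosegmap")

HOMXHET = "HOMxHET"
HETXHET = "HETxHET"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_SENSE_CODONS = tuple(
    "".join(c)
    for c in itertools.product("ACGT", repeat=3)
    if "".join(c) not in ("TAA", "TAG", "TGA")
)
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def haldane_recombination_fraction(d_cm: float) -> float:
    """Recombinant fraction at genetic distance ``d_cm`` (centimorgans)."""
    return 0.5 * (1.0 - np.exp(-2.0 * d_cm / 100.0))


def haldane_distance_cm(r: float) -> float:
    """Inverse Haldane map: genetic distance for recombinant fraction ``r``."""
    if not 0 <= r < 0.5:
        raise ValueError("recombination fraction must be in [0, 0.5)")
    return -50.0 * np.log(1.0 - 2.0 * r)


@dataclass
class CrossConfig:
    """Full parameterization of the synthetic cross.

    Defaults are the desk-scale study conditions: 3 x 10 Mb scaffolds, 200
    markers/Mb, causal locus mid-scaffold, 10 offspring per pool sequenced
    at 30x mean pooled depth -- minutes of compute on one CPU while keeping
    hundreds of informative markers per 1 Mb window.  Each scaffold stands
    in for a chromosome, and meiosis conserves genetic length per
    chromosome (tens of cM) rather than per Mb, so the scaled-down map uses
    10 cM/Mb: a 10 Mb scaffold spans 100 cM, like a typical vertebrate
    chromosome, and linkage to the causal locus decays across it exactly as
    it would across a real chromosome.
    """

    scaffold_lengths: Tuple[int, ...] = (10_000_000, 10_000_000, 10_000_000)
    scaffold_names: Optional[Tuple[str, ...]] = None
    marker_density_per_mb: float = 200.0
    causal_scaffold: int = 0
    causal_pos: int = 5_000_000
    design: str = HOMXHET
    n_offspring: int = 10
    recomb_rate_cm_per_mb: float = 10.0
    mean_depth: float = 30.0
    error_rate: float = 0.005
    f_het: float = 0.25
    f_hom: float = 0.90
    informative_fraction: float = 0.7
    ref_is_mutant_fraction: float = 0.0
    mask_fraction: float = 0.05
    analytic_calls: bool = False
    parents_error_free: bool = True
    marker_positions: Optional[Dict[int, Sequence[int]]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.scaffold_lengths:
            raise ValueError("at least one scaffold required")
        if any(l <= 0 for l in self.scaffold_lengths):
            raise ValueError("scaffold lengths must be positive")
        if self.scaffold_names is not None and len(self.scaffold_names) != len(
            self.scaffold_lengths
        ):
            raise ValueError("scaffold_names must match scaffold_lengths")
        if self.design not in (HOMXHET, HETXHET):
            raise ValueError(f"design must be {HOMXHET!r} or {HETXHET!r}")
        if not (0 < self.f_het <= 0.5 < self.f_hom <= 1.0):
            raise ValueError("thresholds must satisfy 0 < f_het <= 0.5 < f_hom <= 1")
        for name in ("marker_density_per_mb", "recomb_rate_cm_per_mb", "mean_depth"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must be in [0, 0.5)")
        for name in ("informative_fraction", "ref_is_mutant_fraction", "mask_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0 <= self.causal_scaffold < len(self.scaffold_lengths):
            raise ValueError("causal_scaffold index out of range")
        if not 1 <= self.causal_pos <= self.scaffold_lengths[self.causal_scaffold]:
            raise ValueError("causal position outside its scaffold")
        if self.n_offspring < 1:
            raise ValueError("n_offspring must be >= 1")

    @property
    def names(self) -> Tuple[str, ...]:
        if self.scaffold_names is not None:
            return tuple(self.scaffold_names)
        return tuple(f"scaffold_{i + 1}" for i in range(len(self.scaffold_lengths)))

    @property
    def causal_scaffold_name(self) -> str:
        return self.names[self.causal_scaffold]

    def scaffold_index(self) -> ScaffoldIndex:
        return ScaffoldIndex(zip(self.names, self.scaffold_lengths))


# founder allele patterns: (hapA0, hapA1, hapB0, hapB1); hap*0 of a
# heterozygous founder is the mutant-lineage haplotype.
_INFORMATIVE_PATTERN = {
    HOMXHET: (1, 1, 1, 0),
    HETXHET: (1, 0, 1, 0),
}
_UNINFORMATIVE_PATTERNS = {
    HOMXHET: ((1, 0, 1, 0), (0, 0, 1, 0), (1, 1, 1, 1), (1, 1, 0, 0)),
    HETXHET: ((1, 1, 1, 0), (1, 0, 1, 1), (0, 0, 1, 0), (1, 0, 0, 0)),
}


@dataclass
class TruthSet:
    """Simulator ground truth for one cross."""

    causal_scaffold: str
    causal_pos: int
    design: str
    marker_positions: Dict[str, np.ndarray]
    founder_alleles: Dict[str, np.ndarray]  # (n_markers, 4) int8
    informative: Dict[str, np.ndarray]
    flipped: Dict[str, np.ndarray]
    offspring_causal_genotypes: List[int]
    hom_pool_size: int
    het_pool_size: int
    pool_alt_counts: Dict[str, Dict[str, np.ndarray]]  # scaffold -> pool -> counts

    def causal_marker_index(self) -> int:
        pos = self.marker_positions[self.causal_scaffold]
        idx = int(np.searchsorted(pos, self.causal_pos))
        if idx >= len(pos) or pos[idx] != self.causal_pos:
            raise KeyError("causal marker not present in truth set")
        return idx

    def to_json(self, path) -> Path:
        path = Path(path)
        payload = {
            "causal_scaffold": self.causal_scaffold,
            "causal_pos": self.causal_pos,
            "design": self.design,
            "hom_pool_size": self.hom_pool_size,
            "het_pool_size": self.het_pool_size,
            "offspring_causal_genotypes": list(map(int, self.offspring_causal_genotypes)),
            "marker_positions": {s: p.tolist() for s, p in self.marker_positions.items()},
            "founder_alleles": {s: a.tolist() for s, a in self.founder_alleles.items()},
            "informative": {s: a.astype(bool).tolist() for s, a in self.informative.items()},
            "flipped": {s: a.astype(bool).tolist() for s, a in self.flipped.items()},
            "pool_alt_counts": {
                s: {pool: c.tolist() for pool, c in pools.items()}
                for s, pools in self.pool_alt_counts.items()
            },
        }
        path.write_text(json.dumps(payload))
        return path

    @classmethod
    def from_json(cls, path) -> "TruthSet":
        payload = json.loads(Path(path).read_text())
        return cls(
            causal_scaffold=payload["causal_scaffold"],
            causal_pos=payload["causal_pos"],
            design=payload["design"],
            marker_positions={
                s: np.asarray(p, dtype=np.int64)
                for s, p in payload["marker_positions"].items()
            },
            founder_alleles={
                s: np.asarray(a, dtype=np.int8)
                for s, a in payload["founder_alleles"].items()
            },
            informative={
                s: np.asarray(a, dtype=bool) for s, a in payload["informative"].items()
            },
            flipped={s: np.asarray(a, dtype=bool) for s, a in payload["flipped"].items()},
            offspring_causal_genotypes=list(payload["offspring_causal_genotypes"]),
            hom_pool_size=payload["hom_pool_size"],
            het_pool_size=payload["het_pool_size"],
            pool_alt_counts={
                s: {pool: np.asarray(c, dtype=np.int64) for pool, c in pools.items()}
                for s, pools in payload["pool_alt_counts"].items()
            },
        )


@dataclass
class SimResult:
    """In-memory product of one simulated cross."""

    records: List[VariantRecord]
    truth: TruthSet
    scaffolds: ScaffoldIndex
    config: CrossConfig


# ---------------------------------------------------------------------------
# simulation internals
# ---------------------------------------------------------------------------

def _marker_positions(cfg: CrossConfig, rng: np.random.Generator) -> Dict[str, np.ndarray]:
    out: Dict[str, np.ndarray] = {}
    for i, (name, length) in enumerate(zip(cfg.names, cfg.scaffold_lengths)):
        if cfg.marker_positions is not None and i in cfg.marker_positions:
            pos = np.unique(np.asarray(cfg.marker_positions[i], dtype=np.int64))
        else:
            n = rng.poisson(cfg.marker_density_per_mb * length / 1e6)
            pos = np.unique(rng.integers(1, length + 1, size=n))
        if i == cfg.causal_scaffold and cfg.causal_pos not in pos:
            pos = np.sort(np.append(pos, cfg.causal_pos))
        out[name] = pos
    return out


def _founder_alleles(
    cfg: CrossConfig, rng: np.random.Generator, positions: Dict[str, np.ndarray]
) -> Tuple[Dict[str, np.ndarray], Dict[str, np.ndarray]]:
    informative_pattern = np.asarray(_INFORMATIVE_PATTERN[cfg.design], dtype=np.int8)
    uninf = np.asarray(_UNINFORMATIVE_PATTERNS[cfg.design], dtype=np.int8)
    founder: Dict[str, np.ndarray] = {}
    informative: Dict[str, np.ndarray] = {}
    for name, pos in positions.items():
        n = len(pos)
        is_inf = rng.random(n) < cfg.informative_fraction
        alleles = np.empty((n, 4), dtype=np.int8)
        alleles[is_inf] = informative_pattern
        n_uninf = int((~is_inf).sum())
        if n_uninf:
            alleles[~is_inf] = uninf[rng.integers(0, len(uninf), size=n_uninf)]
        if name == cfg.causal_scaffold_name:
            idx = int(np.searchsorted(pos, cfg.causal_pos))
            alleles[idx] = informative_pattern
            is_inf[idx] = True
        founder[name] = alleles
        informative[name] = is_inf
    return founder, informative


def _gamete_alleles(
    rng: np.random.Generator,
    cfg: CrossConfig,
    positions: Dict[str, np.ndarray],
    founder: Dict[str, np.ndarray],
    hap_cols: Tuple[int, int],
) -> Dict[str, np.ndarray]:
    """One gamete: per-scaffold marker alleles from a recombinant haplotype mosaic."""
    out: Dict[str, np.ndarray] = {}
    for name, length in zip(cfg.names, cfg.scaffold_lengths):
        pos = positions[name]
        morgans = cfg.recomb_rate_cm_per_mb * (length / 1e6) / 100.0
        n_x = rng.poisson(morgans)
        start = rng.integers(2)
        if n_x:
            breaks = np.sort(rng.uniform(0, length, size=n_x))
            phase = (start + np.searchsorted(breaks, pos)) % 2
        else:
            phase = np.full(len(pos), start)
        alleles = founder[name]
        out[name] = np.where(phase == 0, alleles[:, hap_cols[0]], alleles[:, hap_cols[1]])
    return out


def draw_causal_genotypes(
    design: str, n: int, rng: Optional[np.random.Generator] = None
) -> np.ndarray:
    """Offspring ALT dosages at the causal locus, before phenotype sorting.

    HOMxHET transmits one causal allele always (1:1 het:hom expected);
    HETxHET segregates 1:2:1.
    """
    rng = rng or np.random.default_rng()
    if design == HOMXHET:
        return 1 + rng.integers(0, 2, size=n)
    if design == HETXHET:
        return rng.integers(0, 2, size=n) + rng.integers(0, 2, size=n)
    raise ValueError(f"unknown design {design!r}")


def _call_fractions(
    frac: np.ndarray, valid: np.ndarray, cfg: CrossConfig
) -> np.ndarray:
    """Threshold caller: fraction -> genotype code; precedence hom > het."""
    minor = np.minimum(frac, 1.0 - frac)
    calls = np.full(frac.shape, int(Genotype.MISSING), dtype=np.int8)
    het = valid & (minor >= cfg.f_het)
    calls[het] = int(Genotype.HET)
    calls[valid & (frac <= 1.0 - cfg.f_hom)] = int(Genotype.HOM_REF)
    calls[valid & (frac >= cfg.f_hom)] = int(Genotype.HOM_ALT)
    return calls


def _call_pool(
    rng: np.random.Generator, alt_counts: np.ndarray, pool_n: int, cfg: CrossConfig
) -> np.ndarray:
    p = alt_counts / (2.0 * pool_n)
    p_err = p * (1.0 - cfg.error_rate) + (1.0 - p) * cfg.error_rate
    if cfg.analytic_calls:
        frac = p_err
        valid = np.ones(frac.shape, dtype=bool)
    else:
        depth = rng.poisson(cfg.mean_depth, size=len(alt_counts))
        alt_reads = rng.binomial(depth, p_err)
        valid = depth > 0
        frac = np.divide(alt_reads, depth, out=np.zeros(len(depth)), where=valid)
    return _call_fractions(frac, valid, cfg)


def _call_diploid(
    rng: np.random.Generator, dosage: np.ndarray, cfg: CrossConfig
) -> np.ndarray:
    """Individual (parent) library through the same read model."""
    return _call_pool(rng, dosage.astype(np.int64), 1, cfg)


def simulate_cross(
    cfg: CrossConfig, rng: Optional[np.random.Generator] = None
) -> SimResult:
    """Simulate one cross and genotype the four family libraries.

    Returns sorted VariantRecords (scaffold order longest-to-shortest) plus
    the full TruthSet.  If phenotype sorting cannot fill both pools the
    offspring draw is repeated, capped to avoid infinite loops.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    positions = _marker_positions(cfg, rng)
    founder, informative = _founder_alleles(cfg, rng, positions)
    causal_name = cfg.causal_scaffold_name
    causal_idx = int(np.searchsorted(positions[causal_name], cfg.causal_pos))

    n = cfg.n_offspring
    hom_acc = {s: np.zeros(len(p), dtype=np.int64) for s, p in positions.items()}
    het_acc = {s: np.zeros(len(p), dtype=np.int64) for s, p in positions.items()}
    hom_n = het_n = 0
    offspring_genotypes: List[int] = []
    cap = max(2_000, 200 * n)
    draws = 0
    while (hom_n < n or het_n < n) and draws < cap:
        draws += 1
        gamete_a = _gamete_alleles(rng, cfg, positions, founder, (0, 1))
        gamete_b = _gamete_alleles(rng, cfg, positions, founder, (2, 3))
        g_causal = int(gamete_a[causal_name][causal_idx] + gamete_b[causal_name][causal_idx])
        offspring_genotypes.append(g_causal)
        if g_causal == 2 and hom_n < n:
            for s in positions:
                hom_acc[s] += gamete_a[s] + gamete_b[s]
            hom_n += 1
        elif g_causal == 1 and het_n < n:
            for s in positions:
                het_acc[s] += gamete_a[s] + gamete_b[s]
            het_n += 1
        # homozygous wild-type offspring (HETxHET) and overflow are discarded
    if hom_n == 0 or het_n == 0:
        raise SimulationError(
            f"could not fill both pools after {draws} offspring draws "
            f"(hom={hom_n}, het={het_n})"
        )
    if hom_n < n or het_n < n:
        logger.warning(
            "pools under target after %d draws (hom=%d, het=%d of %d); proceeding",
            draws, hom_n, het_n, n,
        )
    if draws > 20 * n:
        logger.warning("offspring draw needed %d attempts for %d per pool", draws, n)

    calls: Dict[str, Dict[Role, np.ndarray]] = {}
    flipped: Dict[str, np.ndarray] = {}
    for s in cfg.names:
        alleles = founder[s]
        parent_a = (alleles[:, 0] + alleles[:, 1]).astype(np.int8)
        parent_b = (alleles[:, 2] + alleles[:, 3]).astype(np.int8)
        if not cfg.parents_error_free:
            parent_a = _call_diploid(rng, parent_a, cfg)
            parent_b = _call_diploid(rng, parent_b, cfg)
        calls[s] = {
            Role.HOM_PARENT: parent_a,
            Role.HET_PARENT: parent_b,
            Role.HOM_POOL: _call_pool(rng, hom_acc[s], hom_n, cfg),
            Role.HET_POOL: _call_pool(rng, het_acc[s], het_n, cfg),
        }
        flip = rng.random(len(positions[s])) < cfg.ref_is_mutant_fraction
        if s == causal_name:
            flip[causal_idx] = False  # keep the causal site ALT-oriented
        flipped[s] = flip
        for role, g in calls[s].items():
            g = g.copy()
            swap = flip & (g >= 0)
            g[swap] = 2 - g[swap]
            calls[s][role] = g

    # REF/ALT bases: random, distinct; causal site fixed to C->T so fixtures
    # can embed it in a tryptophan codon.
    records: List[VariantRecord] = []
    scaffolds = cfg.scaffold_index()
    for s, _ in scaffolds:
        pos = positions[s]
        ref_codes = rng.integers(0, 4, size=len(pos))
        alt_codes = (ref_codes + rng.integers(1, 4, size=len(pos))) % 4
        for j, p in enumerate(pos):
            if s == causal_name and j == causal_idx:
                ref, alt = "C", "T"
            else:
                ref = chr(_BASES[ref_codes[j]])
                alt = chr(_BASES[alt_codes[j]])
            records.append(
                VariantRecord(
                    scaffold=s,
                    pos=int(p),
                    ref=ref,
                    alt=alt,
                    genotypes={
                        role: Genotype(int(calls[s][role][j])) for role in ROLES
                    },
                    pass_filter=True,
                )
            )

    truth = TruthSet(
        causal_scaffold=causal_name,
        causal_pos=cfg.causal_pos,
        design=cfg.design,
        marker_positions=positions,
        founder_alleles=founder,
        informative=informative,
        flipped=flipped,
        offspring_causal_genotypes=offspring_genotypes,
        hom_pool_size=hom_n,
        het_pool_size=het_n,
        pool_alt_counts={
            s: {"hom_pool": hom_acc[s], "het_pool": het_acc[s]} for s in cfg.names
        },
    )
    return SimResult(records=records, truth=truth, scaffolds=scaffolds, config=cfg)


def expected_coseg_probability(r: float, cfg: CrossConfig) -> float:
    """Closed-form co-segregation probability for a marker at recombinant
    fraction ``r`` from the causal locus, in the infinite-depth limit
    (``analytic_calls``): pool calls are a deterministic function of the
    recombinant counts, which are binomial in ``r``.
    """
    n = cfg.n_offspring
    e = cfg.error_rate

    def fold(p: np.ndarray) -> np.ndarray:
        return p * (1.0 - e) + (1.0 - p) * e

    if cfg.design == HOMXHET:
        k = np.arange(n + 1)
        pk = stats.binom.pmf(k, n, r)
        p_hom = fold((2 * n - k) / (2.0 * n))
        p_het = fold((n + k) / (2.0 * n))
        hom_ok = p_hom >= cfg.f_hom
        het_ok = np.minimum(p_het, 1 - p_het) >= cfg.f_het
        return float((pk * hom_ok).sum() * (pk * het_ok).sum())
    if cfg.design == HETXHET:
        k2 = np.arange(2 * n + 1)
        pk2 = stats.binom.pmf(k2, 2 * n, r)
        p_hom = fold((2 * n - k2) / (2.0 * n))
        hom_ok = float((pk2 * (p_hom >= cfg.f_hom)).sum())
        # het-pool offspring carry one mutant-lineage and one wild gamete
        km = np.arange(n + 1)
        het_ok = 0.0
        pm = stats.binom.pmf(km, n, r)
        for i, p_i in enumerate(pm):  # recombinants on the mutant gamete
            kw = np.arange(n + 1)
            pw = stats.binom.pmf(kw, n, r)
            alt = (n - i) + kw
            p_het = fold(alt / (2.0 * n))
            het_ok += p_i * float((pw * (np.minimum(p_het, 1 - p_het) >= cfg.f_het)).sum())
        return float(hom_ok * het_ok)
    raise ValueError(f"unknown design {cfg.design!r}")


# ---------------------------------------------------------------------------
# synthetic gene fixtures
# ---------------------------------------------------------------------------

def synthetic_gene(
    gene_id: str,
    scaffold: str,
    strand: str,
    exon_lengths_bp: Sequence[int],
    *,
    intron_bp: int = 150,
    start_at: int = 1_000,
    anchor: Optional[Tuple[int, int]] = None,
    special_codons: Optional[Mapping[int, str]] = None,
    rng: Optional[np.random.Generator] = None,
    gene_name: Optional[str] = None,
) -> Tuple[GeneModel, str]:
    """Build a synthetic gene model plus its coding sequence.

    ``exon_lengths_bp`` is given in transcription order and must sum to a
    multiple of 3.  The coding sequence starts with ATG, ends with TAA, has
    no internal stop, and honours ``special_codons`` (0-based codon index ->
    codon).  ``anchor=(genomic_pos, cds_index)`` rigidly shifts the model so
    that spliced CDS offset ``cds_index`` lands on ``genomic_pos``.
    """
    rng = rng or np.random.default_rng(0)
    total = int(sum(exon_lengths_bp))
    if total % 3 != 0:
        raise ValueError("exon lengths must sum to a multiple of 3")
    n_codons = total // 3
    if n_codons < 3:
        raise ValueError("gene needs at least 3 codons")
    codons = [
        _SENSE_CODONS[i] for i in rng.integers(0, len(_SENSE_CODONS), size=n_codons)
    ]
    codons[0] = "ATG"
    codons[-1] = "TAA"
    for idx, codon in (special_codons or {}).items():
        if not 0 <= idx < n_codons:
            raise ValueError(f"special codon index {idx} out of range")
        codons[idx] = codon.upper()
    coding = "".join(codons)

    asc_lengths = list(exon_lengths_bp) if strand == "+" else list(exon_lengths_bp)[::-1]
    ascending = []
    g = int(start_at)
    for length in asc_lengths:
        ascending.append((g, g + int(length) - 1))
        g += int(length) + int(intron_bp)
    pieces = tuple(ascending if strand == "+" else ascending[::-1])

    model = GeneModel(
        gene_id=gene_id,
        gene_name=gene_name or gene_id,
        scaffold=scaffold,
        strand=strand,
        exons=pieces,
        cds=pieces,
    )
    if anchor is not None:
        anchor_pos, anchor_idx = anchor
        shift = int(anchor_pos) - model.genomic_position(int(anchor_idx))
        shifted = tuple((s + shift, e + shift) for s, e in pieces)
        if any(s < 1 for s, _ in shifted):
            raise ValueError("anchored gene extends before position 1")
        model = GeneModel(
            gene_id=gene_id,
            gene_name=gene_name or gene_id,
            scaffold=scaffold,
            strand=strand,
            exons=shifted,
            cds=shifted,
        )
    return model, coding


def embed_gene(sequence: np.ndarray, model: GeneModel, coding: str) -> None:
    """Write a gene's coding bases into a mutable uint8 scaffold array."""
    for i, base in enumerate(coding):
        p = model.genomic_position(i)
        if model.strand == "-":
            base = base.translate(_COMPLEMENT)
        sequence[p - 1] = ord(base)


def _fixture_genes(
    cfg: CrossConfig, rng: np.random.Generator
) -> List[Tuple[GeneModel, str]]:
    """Three genes straddling the causal locus.

    The causal gene sits on the minus strand with a tryptophan (TGG) codon
    whose middle base is the causal site: the genomic C->T substitution then
    reads G->A on the coding strand, turning UGG into the UAG stop.  A
    plus-strand and a second minus-strand gene provide strand coverage.
    """
    name = cfg.causal_scaffold_name
    length = cfg.scaffold_lengths[cfg.causal_scaffold]
    margin = 100_000
    if not margin <= cfg.causal_pos <= length - margin:
        raise SimulationError(
            f"causal position {cfg.causal_pos} too close to a scaffold edge "
            f"for gene fixtures (need {margin} bp margin)"
        )
    # 8 exons of 15 codons each; target codon 80 falls in exon 6
    exon_lengths = [45] * 8
    target_codon = 80
    causal_gene, causal_seq = synthetic_gene(
        "gene_causal",
        name,
        "-",
        exon_lengths,
        anchor=(cfg.causal_pos, target_codon * 3 + 1),
        special_codons={target_codon: "TGG"},
        rng=rng,
        gene_name="GENE_CAUSAL",
    )
    plus_gene = synthetic_gene(
        "gene_plus",
        name,
        "+",
        [60, 60, 60, 60, 60],
        start_at=cfg.causal_pos + 40_000,
        rng=rng,
        gene_name="GENE_PLUS",
    )
    far_gene = synthetic_gene(
        "gene_far",
        name,
        "-",
        [90, 90, 90],
        start_at=cfg.causal_pos - 80_000,
        rng=rng,
        gene_name="GENE_FAR",
    )
    return [(causal_gene, causal_seq), plus_gene, far_gene]


def _random_mask(
    cfg: CrossConfig,
    rng: np.random.Generator,
    exclude: Sequence[GeneModel] = (),
) -> Dict[str, List[Tuple[int, int]]]:
    """Random repeat intervals covering about ``mask_fraction`` of each scaffold.

    Intervals overlapping the fixture genes are dropped: the planted coding
    variants must stay discoverable, mirroring the fact that causal coding
    variants sit outside repeat annotations.
    """
    piece = 10_000
    spans = [(g.scaffold, g.start - 1, g.end) for g in exclude]
    out: Dict[str, List[Tuple[int, int]]] = {}
    for name, length in zip(cfg.names, cfg.scaffold_lengths):
        n = int(cfg.mask_fraction * length / piece)
        starts = rng.integers(0, max(length - piece, 1), size=n)
        kept = []
        for s in starts:
            s, e = int(s), int(s) + piece
            if any(name == sc and s < ge and e > gs for sc, gs, ge in spans):
                continue
            kept.append((s, e))
        out[name] = kept
    return out


def make_fixture_suite(cfg: CrossConfig, outdir) -> Dict[str, object]:
    """Write a complete desk-scale fixture set: FASTA + VCF + BED + GFF3 + truth.

    The genome is random sequence with each marker's REF allele equal to the
    genome base; three synthetic genes straddle the causal locus and the
    causal SNV creates a premature stop in the minus-strand causal gene.
    Byte-identical across runs for a fixed config.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = simulate_cross(cfg)
    genome_rng = np.random.default_rng([cfg.seed, 1])
    gene_rng = np.random.default_rng([cfg.seed, 2])
    mask_rng = np.random.default_rng([cfg.seed, 3])
    alt_rng = np.random.default_rng([cfg.seed, 4])

    arrays = {
        name: _BASES[genome_rng.integers(0, 4, size=length)].copy()
        for name, length in zip(cfg.names, cfg.scaffold_lengths)
    }
    genes = _fixture_genes(cfg, gene_rng)
    for model, coding in genes:
        embed_gene(arrays[model.scaffold], model, coding)

    causal_name = cfg.causal_scaffold_name
    for rec in sim.records:
        base = chr(arrays[rec.scaffold][rec.pos - 1])
        if rec.scaffold == causal_name and rec.pos == cfg.causal_pos:
            if base != "C":
                raise SimulationError("causal fixture base is not C; gene embedding failed")
            rec.ref, rec.alt = "C", "T"
            continue
        rec.ref = base
        alt = base
        while alt == base:
            alt = chr(_BASES[alt_rng.integers(0, 4)])
        rec.alt = alt

    sequences = {name: arr.tobytes().decode("ascii") for name, arr in arrays.items()}
    paths: Dict[str, object] = {}
    paths["fasta"] = write_fasta(sequences, outdir / "genome.fa")
    paths["vcf"] = write_vcf(sim.records, outdir / "variants.vcf", sim.scaffolds)
    paths["bed"] = write_bed(
        _random_mask(cfg, mask_rng, [m for m, _ in genes]), outdir / "mask.bed"
    )
    paths["gff"] = write_gff3([m for m, _ in genes], outdir / "genes.gff3")
    paths["truth"] = sim.truth.to_json(outdir / "truth.json")
    roles_path = outdir / "roles.yaml"
    roles_path.write_text("".join(f"{r.value}: {r.value}\n" for r in ROLES))
    paths["roles"] = roles_path
    paths["genes"] = [m for m, _ in genes]
    paths["sim"] = sim
    return paths
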