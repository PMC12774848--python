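"""Sliding-window co-segregation scan, peak calling and interval metrics.

The statistic: among quality-passing biallelic variants whose parental
genotypes already match the expected parental pattern (homozygous-mutant
parent HOM, heterozygous parent HET -- the *informative* variants), the
proportion whose offspring-pool genotypes also match (HOM pool homozygous,
HET pool heterozygous -- the *co-segregating* variants) is computed in
overlapping windows along each scaffold.  The window containing a recessive
causal locus is expected to attain the genome-wide maximum proportion,
because only there does phenotype sorting guarantee transmission of the
linked haplotype to the matching pool.

Two tiers mirror genome-wide and fine mapping practice:

* genome-wide: 1 Mb windows, 100 kb step, SNP/MNP only, scaffolds > 1 Mb;
* fine: 200 kb windows, 50 kb step, indels included, one scaffold/region.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .io import RepeatMask
from .records import (
    EXPECTED_PARENT_GENOTYPES,
    Genotype,
    Role,
    ScaffoldIndex,
    UnsortedInputError,
    VariantClass,
    VariantRecord,
)

GENOMEWIDE_CLASSES: FrozenSet[VariantClass] = frozenset(
    {VariantClass.SNP, VariantClass.MNP}
)
FINE_CLASSES: FrozenSet[VariantClass] = frozenset(
    {VariantClass.SNP, VariantClass.MNP, VariantClass.INDEL}
)


@dataclass
class ScanConfig:
    """Tunable parameters of the two scan tiers and peak triage.

    ``proportion_threshold=None`` selects the adaptive rule
    ``max(0.5, 99th percentile of defined window proportions)``: interval
    minima in practice track the study's noise level rather than a fixed
    cutoff.  ``min_interval_coseg`` separates well-supported peaks (thousands
    of co-segregating variants) from spurious ones (a handful) by an order of
    magnitude on each side.
    """

    window_bp: int = 1_000_000
    step_bp: int = 100_000
    min_scaffold_bp: int = 1_000_000
    fine_window_bp: int = 200_000
    fine_step_bp: int = 50_000
    genomewide_classes: FrozenSet[VariantClass] = GENOMEWIDE_CLASSES
    fine_classes: FrozenSet[VariantClass] = FINE_CLASSES
    min_interval_coseg: int = 100
    proportion_threshold: Optional[float] = None
    peak_softening: float = 0.95
    allele_orientation: str = "ALT_IS_MUTANT"

    def __post_init__(self) -> None:
        if self.step_bp > self.window_bp:
            raise ValueError("step_bp must not exceed window_bp")
        if self.fine_step_bp > self.fine_window_bp:
            raise ValueError("fine_step_bp must not exceed fine_window_bp")
        for name in ("window_bp", "step_bp", "fine_window_bp", "fine_step_bp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.min_interval_coseg < 0:
            raise ValueError("min_interval_coseg must be >= 0")
        if not 0 < self.peak_softening <= 1:
            raise ValueError("peak_softening must be in (0, 1]")
        if self.allele_orientation not in ("ALT_IS_MUTANT", "AUTO"):
            raise ValueError("allele_orientation must be 'ALT_IS_MUTANT' or 'AUTO'")
        self.genomewide_classes = frozenset(VariantClass(c) for c in self.genomewide_classes)
        self.fine_classes = frozenset(VariantClass(c) for c in self.fine_classes)


# ---------------------------------------------------------------------------
# per-variant predicates
# ---------------------------------------------------------------------------

def informative_orientation(
    v: VariantRecord,
    mask: Optional[RepeatMask],
    cfg: ScanConfig,
    classes: Optional[FrozenSet[VariantClass]] = None,
) -> Optional[str]:
    """Orientation under which ``v`` is informative, or None.

    'alt': mutant lineage carries the ALT allele (hom parent HOM_ALT, het
    parent HET) -- the default when the reference individual is wild-type.
    'ref': mirrored pattern (hom parent HOM_REF), accepted only in AUTO mode,
    for assemblies whose reference individual carries the mutant allele.
    MISSING in either parent makes the site uninformative.
    """
    if classes is None:
        classes = cfg.genomewide_classes
    if not v.pass_filter:
        return None
    if v.vclass not in classes:
        return None
    if mask is not None and mask.contains(v.scaffold, v.pos):
        return None
    if v.genotypes[Role.HET_PARENT] != Genotype.HET:
        return None
    hom_parent = v.genotypes[Role.HOM_PARENT]
    if hom_parent == Genotype.HOM_ALT:
        return "alt"
    if cfg.allele_orientation == "AUTO" and hom_parent == Genotype.HOM_REF:
        return "ref"
    return None


def is_informative(
    v: VariantRecord,
    mask: Optional[RepeatMask] = None,
    cfg: Optional[ScanConfig] = None,
    fine: bool = False,
) -> bool:
    """True iff the variant enters the denominator of the window proportion."""
    cfg = cfg or ScanConfig()
    classes = cfg.fine_classes if fine else cfg.genomewide_classes
    return informative_orientation(v, mask, cfg, classes) is not None


def is_cosegregating(v: VariantRecord, orientation: str = "alt") -> bool:
    """True iff the pools match the expected pattern (given informativeness).

    MISSING pool genotypes never count as co-segregating: missing is not
    evidence, and the variant stays in the denominator.
    """
    hom_expected = Genotype.HOM_ALT if orientation == "alt" else Genotype.HOM_REF
    return (
        v.genotypes[Role.HOM_POOL] == hom_expected
        and v.genotypes[Role.HET_POOL] == Genotype.HET
    )


# ---------------------------------------------------------------------------
# windowed scan
# ---------------------------------------------------------------------------

@dataclass
class WindowStat:
    """Co-segregation proportion over one genomic window (1-based inclusive)."""

    scaffold: str
    start: int
    end: int
    n_informative: int
    n_coseg: int
    proportion: Optional[float]
    defined: bool
    truncated: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.n_coseg <= max(self.n_informative, 0):
            raise ValueError(
                f"n_coseg {self.n_coseg} outside [0, n_informative={self.n_informative}]"
            )


@dataclass
class ScanResult:
    """Windows plus the per-scaffold position bookkeeping peak calling needs."""

    windows: List[WindowStat]
    informative_positions: Dict[str, np.ndarray]
    coseg_positions: Dict[str, np.ndarray]
    scaffolds: ScaffoldIndex
    config: ScanConfig
    tier: str = "genomewide"
    n_orientation: Dict[str, int] = field(default_factory=dict)
    threshold: Optional[float] = None

    def defined_windows(self) -> List[WindowStat]:
        return [w for w in self.windows if w.defined]


def _collect_positions(
    variants: Iterable[VariantRecord],
    mask: Optional[RepeatMask],
    cfg: ScanConfig,
    classes: FrozenSet[VariantClass],
) -> Tuple[Dict[str, np.ndarray], Dict[str, np.ndarray], Dict[str, int]]:
    """Single sorted pass: per-scaffold informative / co-segregating positions."""
    informative: Dict[str, List[int]] = {}
    coseg: Dict[str, List[int]] = {}
    n_orientation = {"alt": 0, "ref": 0}
    done: set = set()
    current: Optional[str] = None
    last_pos = 0
    for v in variants:
        if v.scaffold != current:
            if v.scaffold in done:
                raise UnsortedInputError(
                    f"scaffold {v.scaffold} appears in multiple blocks; "
                    "sort variants by (scaffold, position)"
                )
            if current is not None:
                done.add(current)
            current, last_pos = v.scaffold, 0
        if v.pos < last_pos:
            raise UnsortedInputError(
                f"position {v.pos} after {last_pos} on {v.scaffold}; "
                "sort variants by (scaffold, position)"
            )
        last_pos = v.pos
        orientation = informative_orientation(v, mask, cfg, classes)
        if orientation is None:
            continue
        n_orientation[orientation] += 1
        informative.setdefault(v.scaffold, []).append(v.pos)
        if is_cosegregating(v, orientation):
            coseg.setdefault(v.scaffold, []).append(v.pos)
    inf_arrays = {s: np.asarray(p, dtype=np.int64) for s, p in informative.items()}
    coseg_arrays = {s: np.asarray(p, dtype=np.int64) for s, p in coseg.items()}
    return inf_arrays, coseg_arrays, n_orientation


def _windows_for_span(
    scaffold: str,
    span_start0: int,
    span_end0: int,
    window_bp: int,
    step_bp: int,
    inf_pos: np.ndarray,
    coseg_pos: np.ndarray,
) -> List[WindowStat]:
    """Windows anchored at ``span_start0`` on the step grid, truncated at the end."""
    stats: List[WindowStat] = []
    for w_start in range(span_start0, span_end0, step_bp):
        w_end = min(w_start + window_bp, span_end0)
        # positions are 1-based; window is 0-based half-open [w_start, w_end)
        n_inf = int(
            np.searchsorted(inf_pos, w_end, side="right")
            - np.searchsorted(inf_pos, w_start + 1, side="left")
        )
        n_co = int(
            np.searchsorted(coseg_pos, w_end, side="right")
            - np.searchsorted(coseg_pos, w_start + 1, side="left")
        )
        defined = n_inf > 0
        stats.append(
            WindowStat(
                scaffold=scaffold,
                start=w_start + 1,
                end=w_end,
                n_informative=n_inf,
                n_coseg=n_co,
                proportion=(n_co / n_inf) if defined else None,
                defined=defined,
                truncated=(w_end - w_start) < window_bp,
            )
        )
    return stats


_EMPTY = np.asarray([], dtype=np.int64)


def window_scan(
    variants: Iterable[VariantRecord],
    scaffolds: ScaffoldIndex,
    cfg: Optional[ScanConfig] = None,
    mask: Optional[RepeatMask] = None,
) -> ScanResult:
    """Genome-wide tier: SNP/MNP co-segregation in sliding windows.

    Scans scaffolds longer than ``min_scaffold_bp``, longest first.  Windows
    are anchored at position 0 of each scaffold; the final partial window is
    retained and flagged truncated.  Windows with zero informative variants
    are undefined (0/0 is not evidence) and excluded from peak calling.
    """
    cfg = cfg or ScanConfig()
    inf_pos, coseg_pos, n_orientation = _collect_positions(
        variants, mask, cfg, cfg.genomewide_classes
    )
    windows: List[WindowStat] = []
    for scaffold, length in scaffolds:
        if length <= cfg.min_scaffold_bp:
            continue
        windows.extend(
            _windows_for_span(
                scaffold, 0, length, cfg.window_bp, cfg.step_bp,
                inf_pos.get(scaffold, _EMPTY), coseg_pos.get(scaffold, _EMPTY),
            )
        )
    return ScanResult(
        windows=windows,
        informative_positions=inf_pos,
        coseg_positions=coseg_pos,
        scaffolds=scaffolds,
        config=cfg,
        tier="genomewide",
        n_orientation=n_orientation,
    )


def fine_scan(
    variants: Iterable[VariantRecord],
    scaffold: str,
    region: Optional[Tuple[int, int]],
    cfg: Optional[ScanConfig] = None,
    mask: Optional[RepeatMask] = None,
    scaffolds: Optional[ScaffoldIndex] = None,
) -> ScanResult:
    """Fine tier: 200 kb / 50 kb windows over one region, indels included.

    ``region`` is 1-based inclusive; ``None`` covers the whole scaffold when
    a scaffold index is supplied.  An empty region yields no windows.
    """
    cfg = cfg or ScanConfig()
    if region is None:
        if scaffolds is None or scaffold not in scaffolds:
            raise ValueError("region=None requires a scaffold index covering the scaffold")
        region = (1, scaffolds.length(scaffold))
    start1, end1 = int(region[0]), int(region[1])
    inf_pos, coseg_pos, n_orientation = _collect_positions(
        variants, mask, cfg, cfg.fine_classes
    )
    windows: List[WindowStat] = []
    if start1 <= end1:
        windows = _windows_for_span(
            scaffold, start1 - 1, end1, cfg.fine_window_bp, cfg.fine_step_bp,
            inf_pos.get(scaffold, _EMPTY), coseg_pos.get(scaffold, _EMPTY),
        )
    index = scaffolds if scaffolds is not None else ScaffoldIndex([(scaffold, max(end1, 1))])
    return ScanResult(
        windows=windows,
        informative_positions=inf_pos,
        coseg_positions=coseg_pos,
        scaffolds=index,
        config=cfg,
        tier="fine",
        n_orientation=n_orientation,
    )


# ---------------------------------------------------------------------------
# peak calling and interval metrics
# ---------------------------------------------------------------------------

def _round_half_up(x: float, ndigits: int = 0) -> float:
    factor = 10 ** ndigits
    return math.floor(x * factor + 0.5) / factor


@dataclass
class CandidateInterval:
    """Merged high-co-segregation region with its support metrics.

    ``parts`` holds 1-based inclusive sub-spans; peak calling produces
    single-part intervals, but split regions (two nearby blocks flanking a
    low-co-segregation gap) can be represented and measured as a union.
    """

    scaffold: str
    parts: Tuple[Tuple[int, int], ...]
    max_proportion: float
    n_coseg_total: int
    disregarded: bool = False
    rank: Optional[int] = None

    def __post_init__(self) -> None:
        parts = tuple(sorted((int(s), int(e)) for s, e in self.parts))
        for s, e in parts:
            if s < 1 or e < s:
                raise ValueError(f"invalid interval part ({s}, {e})")
        for (_, e1), (s2, _) in zip(parts, parts[1:]):
            if s2 <= e1:
                raise ValueError("interval parts must be disjoint")
        self.parts = parts
        if self.n_coseg_total < 0:
            raise ValueError("n_coseg_total must be >= 0")

    @classmethod
    def from_span(
        cls, scaffold: str, start: int, end: int, n_coseg_total: int,
        max_proportion: float = 1.0,
    ) -> "CandidateInterval":
        return cls(scaffold, ((start, end),), max_proportion, n_coseg_total)

    @property
    def start(self) -> int:
        return self.parts[0][0]

    @property
    def end(self) -> int:
        return self.parts[-1][1]

    @property
    def span_bp(self) -> int:
        """Total covered length (union of parts), in bp."""
        return sum(e - s + 1 for s, e in self.parts)

    @property
    def width_mb(self) -> float:
        """Covered width in Mb, reported to 0.1 Mb."""
        return _round_half_up(self.span_bp / 1e6, 1)

    @property
    def density_per_mb(self) -> int:
        """Co-segregating variants per Mb of covered width, nearest integer."""
        return int(_round_half_up(self.n_coseg_total / (self.span_bp / 1e6)))

    def contains(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.parts)


def interval_metrics(interval: CandidateInterval) -> Tuple[float, int]:
    """(width in Mb to 0.1, co-segregating variants per Mb to nearest integer)."""
    if interval.span_bp <= 0:
        raise ValueError("zero-width interval")
    return interval.width_mb, interval.density_per_mb


def peak_threshold(result: ScanResult, cfg: Optional[ScanConfig] = None) -> Optional[float]:
    """Proportion cutoff for peak windows.

    Explicit config value if set, otherwise ``max(0.5, peak_softening x 99th
    percentile of the defined window proportions)``.  The percentile adapts
    the cutoff to the study's noise level; the softening factor keeps the
    peak plateau contiguous when pooled genotype-calling noise perturbs
    individual windows by a few percent (one miscalled marker among ~10^2
    informative ones).  None when no window is defined.
    """
    cfg = cfg or result.config
    if cfg.proportion_threshold is not None:
        return float(cfg.proportion_threshold)
    props = [w.proportion for w in result.windows if w.defined]
    if not props:
        return None
    return max(0.5, cfg.peak_softening * float(np.percentile(props, 99)))


def call_peaks(
    result: ScanResult, cfg: Optional[ScanConfig] = None
) -> List[CandidateInterval]:
    """Merge peak windows into candidate intervals and triage them.

    Windows at or above the threshold that overlap or are adjacent merge into
    one interval; the interval's co-segregating count is recounted over its
    span (overlapping windows are never summed).  Intervals supported by
    fewer than ``min_interval_coseg`` co-segregating variants are reported
    but flagged disregarded.  Survivors are ranked by (max proportion, total
    co-segregating count) descending, ties broken by scaffold order then
    start.
    """
    cfg = cfg or result.config
    thr = peak_threshold(result, cfg)
    result.threshold = thr
    if thr is None:
        return []
    selected = [w for w in result.windows if w.defined and w.proportion >= thr]
    if not selected:
        return []

    intervals: List[CandidateInterval] = []
    by_scaffold: Dict[str, List[WindowStat]] = {}
    scaffold_order: List[str] = []
    for w in selected:
        if w.scaffold not in by_scaffold:
            scaffold_order.append(w.scaffold)
        by_scaffold.setdefault(w.scaffold, []).append(w)
    for scaffold in scaffold_order:
        wins = sorted(by_scaffold[scaffold], key=lambda w: w.start)
        coseg_pos = result.coseg_positions.get(scaffold, _EMPTY)
        group: List[WindowStat] = [wins[0]]
        for w in wins[1:]:
            if w.start <= group[-1].end + 1:
                group.append(w)
            else:
                intervals.append(_merge_group(scaffold, group, coseg_pos, cfg))
                group = [w]
        intervals.append(_merge_group(scaffold, group, coseg_pos, cfg))

    def sort_key(iv: CandidateInterval):
        rank_in_index = (
            result.scaffolds.rank(iv.scaffold) if iv.scaffold in result.scaffolds else 1 << 30
        )
        return (-iv.max_proportion, -iv.n_coseg_total, rank_in_index, iv.start)

    survivors = sorted((iv for iv in intervals if not iv.disregarded), key=sort_key)
    for i, iv in enumerate(survivors, start=1):
        iv.rank = i
    flagged = sorted((iv for iv in intervals if iv.disregarded), key=sort_key)
    return survivors + flagged


def _merge_group(
    scaffold: str, group: List[WindowStat], coseg_pos: np.ndarray, cfg: ScanConfig
) -> CandidateInterval:
    start = min(w.start for w in group)
    end = max(w.end for w in group)
    n_total = int(
        np.searchsorted(coseg_pos, end, side="right")
        - np.searchsorted(coseg_pos, start, side="left")
    )
    return CandidateInterval(
        scaffold=scaffold,
        parts=((start, end),),
        max_proportion=max(w.proportion for w in group),
        n_coseg_total=n_total,
        disregarded=n_total < cfg.min_interval_coseg,
    )


# ---------------------------------------------------------------------------
# diagnostic markers
# ---------------------------------------------------------------------------

def diagnostic_markers(
    variants: Iterable[VariantRecord],
    interval: CandidateInterval,
    k: int,
    mask: Optional[RepeatMask] = None,
    cfg: Optional[ScanConfig] = None,
) -> List[VariantRecord]:
    """Up to ``k`` co-segregating SNPs nearest each interval edge.

    Fixed SNPs at the interval edges make good genotyping markers for
    confirming recombination boundaries in additional family members.
    """
    cfg = cfg or ScanConfig()
    snp_only = frozenset({VariantClass.SNP})
    candidates: List[VariantRecord] = []
    for v in variants:
        if v.scaffold != interval.scaffold or not interval.contains(v.pos):
            continue
        orientation = informative_orientation(v, mask, cfg, snp_only)
        if orientation is None or not is_cosegregating(v, orientation):
            continue
        candidates.append(v)
    if not candidates:
        return []
    near_start = sorted(candidates, key=lambda v: (abs(v.pos - interval.start), v.pos))[:k]
    near_end = sorted(candidates, key=lambda v: (abs(v.pos - interval.end), v.pos))[:k]
    chosen = {v.pos: v for v in near_start + near_end}
    return [chosen[p] for p in sorted(chosen)]
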