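"""Independent brute-force oracles for the window statistic and codon calls.

These deliberately avoid the package's optimized code paths: window counts
come from a direct loop over all variants per window, and consequence
classes come from rebuilding and translating the entire protein before and
after the substitution.
"""
from __future__ import annotations

import numpy as np
from Bio.Seq import Seq

from cosegmap.scan import informative_orientation, is_cosegregating

_SEVERITY = ["stop_gained", "stop_lost", "start_lost", "missense", "synonymous"]
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def brute_force_windows(records, scaffolds, cfg, mask=None, tier="genomewide"):
    """(scaffold, start, end, n_informative, n_coseg) by direct recount."""
    if tier == "genomewide":
        window, step, classes = cfg.window_bp, cfg.step_bp, cfg.genomewide_classes
    else:
        window, step, classes = cfg.fine_window_bp, cfg.fine_step_bp, cfg.fine_classes
    out = []
    for scaffold, length in scaffolds:
        if length <= cfg.min_scaffold_bp:
            continue
        for start0 in range(0, length, step):
            end0 = min(start0 + window, length)
            n_inf = n_co = 0
            for v in records:
                if v.scaffold != scaffold or not (start0 < v.pos <= end0):
                    continue
                orientation = informative_orientation(v, mask, cfg, classes)
                if orientation is None:
                    continue
                n_inf += 1
                if is_cosegregating(v, orientation):
                    n_co += 1
            out.append((scaffold, start0 + 1, end0, n_inf, n_co))
    return out


def whole_protein_effect(gene, genome, variant):
    """Effect class from full-CDS translation before/after the substitution."""
    ref_cds = gene.spliced_cds(genome)
    mutated = list(ref_cds)
    for p, alt_base in zip(range(variant.pos, variant.end + 1), variant.alt.upper()):
        i = gene.cds_index(p)
        assert i is not None, "oracle only handles fully-CDS substitutions"
        mutated[i] = alt_base if gene.strand == "+" else alt_base.translate(_COMPLEMENT)
    alt_cds = "".join(mutated)
    n_codons = len(ref_cds) // 3
    ref_prot = str(Seq(ref_cds[: n_codons * 3]).translate())
    alt_prot = str(Seq(alt_cds[: n_codons * 3]).translate())
    diffs = [i for i, (a, b) in enumerate(zip(ref_prot, alt_prot)) if a != b]
    if not diffs:
        return "synonymous"
    classes = []
    for d in diffs:
        if alt_prot[d] == "*":
            classes.append("stop_gained")
        elif ref_prot[d] == "*":
            classes.append("stop_lost")
        elif (
            d == 0
            and ref_cds[:3].upper() == "ATG"
            and alt_cds[:3].upper() != "ATG"
        ):
            classes.append("start_lost")
        else:
            classes.append("missense")
    return min(classes, key=_SEVERITY.index)


def mc_unlinked_coseg_probability(rng, n, depth, error, f_het, f_hom, reps):
    """Monte-Carlo oracle: P(co-segregation) at an unlinked marker, hom x het.

    Each pool member receives the ALT allele from the homozygous parent and
    a fair-coin allele from the heterozygous parent; reads follow the same
    Poisson-depth binomial model as the simulator but are drawn here from
    first principles.
    """

    def call(alt_count, reps_rng):
        p = alt_count / (2.0 * n)
        p_err = p * (1 - error) + (1 - p) * error
        d = reps_rng.poisson(depth, size=reps)
        x = reps_rng.binomial(d, p_err)
        frac = np.divide(x, d, out=np.zeros(reps), where=d > 0)
        hom_alt = (d > 0) & (frac >= f_hom)
        het = (d > 0) & (np.minimum(frac, 1 - frac) >= f_het)
        return hom_alt, het

    hom_alt_count = n + rng.binomial(n, 0.5, size=reps)
    het_alt_count = n + rng.binomial(n, 0.5, size=reps)
    hom_is_hom, _ = call(hom_alt_count, rng)
    _, het_is_het = call(het_alt_count, rng)
    return float(np.mean(hom_is_hom & het_is_het))
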