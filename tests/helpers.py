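"""Shared builders and independent brute-force oracles for the test suite.

The oracles here are deliberately naive re-implementations (loops,
enumeration) kept independent of the library code paths they check.
"""

from __future__ import annotations

import math
from typing import Mapping, Optional, Sequence

from dartk.types import (
    DarLocus,
    GeneModel,
    GenotypeMatrix,
    SmoothedDarRegion,
    VariantLocus,
    make_call,
)

GROUPS4 = {"s1": "g1", "s2": "g1", "s3": "g2", "s4": "g2"}


def call_from_str(text: Optional[str]):
    if text is None or text in (".", "./."):
        return None
    a, b = text.replace("|", "/").split("/")
    return make_call(a, b)


def make_locus(chrom, pos, ref, alts, genos: Mapping[str, Optional[str]],
               stats=None) -> VariantLocus:
    return VariantLocus(
        chrom=chrom, pos=pos, ref_base=ref, alt_bases=tuple(alts),
        genotypes={s: call_from_str(g) for s, g in genos.items()},
        site_stats=stats or {},
    )


def make_matrix(loci, group_of=None) -> GenotypeMatrix:
    group_of = group_of or GROUPS4
    ordered = tuple(sorted(loci, key=lambda l: (l.chrom, l.pos)))
    return GenotypeMatrix(ordered, tuple(group_of), dict(group_of))


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------

def cluster_flag_oracle(loci_positions: Mapping[str, Sequence[int]],
                        max_snps: int, window_bp: int) -> set[tuple[str, int]]:
    """Try every candidate window start; flag loci in any window holding
    more than max_snps loci."""
    flagged = set()
    for chrom, positions in loci_positions.items():
        for pos in positions:
            for start in range(pos - window_bp + 1, pos + 1):
                inside = [p for p in positions if start <= p <= start + window_bp - 1]
                if len(inside) > max_snps and pos in inside:
                    flagged.add((chrom, pos))
                    break
    return flagged


def elastic_window_oracle(track: Sequence[DarLocus], half_width: int):
    """Nearest-rank window builder: sort same-chromosome neighbours by
    rank distance (ties toward the smaller position) and keep up to
    half_width on each side."""
    out = []
    by_chrom: dict[str, list[DarLocus]] = {}
    for locus in track:
        by_chrom.setdefault(locus.chrom, []).append(locus)
    for chrom in dict.fromkeys(l.chrom for l in track):
        loci = by_chrom[chrom]
        for i, locus in enumerate(loci):
            members = [
                j for j in range(len(loci))
                if (j < i and i - j <= half_width) or (j >= i and j - i <= half_width)
            ]
            values = [loci[j].dar for j in members]
            out.append(
                (chrom, locus.pos, loci[min(members)].pos, loci[max(members)].pos,
                 sum(values) / len(values), len(members))
            )
    return out


def interval_overlap_oracle(genes: Sequence[GeneModel],
                            regions: Sequence[SmoothedDarRegion]):
    """All-pairs interval intersection; unweighted mean per gene."""
    out = []
    for gene in genes:
        values = [
            r.smoothed_dar for r in regions
            if r.chrom == gene.chrom
            and r.region_start <= gene.end and gene.start <= r.region_end
        ]
        mean = sum(values) / len(values) if values else None
        out.append((gene.gene_id, mean, len(values)))
    return out


def running_sum_oracle(abs_scores: Sequence[float], is_hit: Sequence[bool]):
    """Step the weighted KS running sum one gene at a time."""
    nr = sum(s for s, h in zip(abs_scores, is_hit) if h)
    n_hits = sum(is_hit)
    n_miss = len(is_hit) - n_hits
    cur = 0.0
    path = []
    for score, hit in zip(abs_scores, is_hit):
        if hit:
            cur += (score / nr) if nr > 0 else 1.0 / n_hits
        else:
            cur -= 1.0 / n_miss
        path.append(cur)
    peak = max(abs(v) for v in path)
    # earliest step within 1e-9 of the extremum magnitude (same tie rule
    # as the engine: exact +/- ties must not resolve on rounding noise)
    best_i = next(i for i, v in enumerate(path) if abs(v) >= peak - 1e-9)
    return path[best_i], best_i


def hypergeom_tail_oracle(n_total: int, n_de: int, n_on: int, de_on: int) -> float:
    """Exact upper-tail P[X >= de_on] by enumeration over the support."""
    denom = math.comb(n_total, n_on)
    total = 0
    for k in range(de_on, min(n_de, n_on) + 1):
        total += math.comb(n_de, k) * math.comb(n_total - n_de, n_on - k)
    return total / denom


def bh_stepup_oracle(pvalues: Sequence[float]) -> list[float]:
    """Independent Benjamini-Hochberg step-up."""
    n = len(pvalues)
    order = sorted(range(n), key=lambda i: pvalues[i])
    adjusted = [0.0] * n
    running_min = 1.0
    for rank in range(n, 0, -1):
        idx = order[rank - 1]
        running_min = min(running_min, pvalues[idx] * n / rank)
        adjusted[idx] = running_min
    return adjusted
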