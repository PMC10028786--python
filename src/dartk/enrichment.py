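"""Gene ranking, DAR-based exclusion/weighting, preranked GSEA and
chromosomal co-location testing.

The ranking statistic is sign(log2FC) x -log10(p), placing the most
significant up-regulated genes at the top of the list and the most
significant down-regulated at the bottom. DAR weighting multiplies the
statistic by (1 - DAR), pushing genes in high-DAR regions — probable
eQTL artefacts — toward the middle of the list where they contribute
little to enrichment scores. Genes without a DAR value keep their
statistic unchanged: absence of variant evidence is not evidence of
allelic divergence.

The enrichment engine is classic preranked GSEA — a weighted
Kolmogorov-Smirnov running sum (weight exponent 1 on the absolute
statistic) with significance from permuted gene sets of matched size
drawn from the ranked universe. It is deliberately transparent: every
piece is checkable against a brute-force running-sum oracle.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .types import (
    ConfigurationError,
    DataError,
    DeGene,
    GeneDarAssignment,
    GeneModel,
    GeneSetCollection,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RankedGene:
    gene_id: str
    stat: float
    weighted_stat: Optional[float] = None


@dataclass(frozen=True)
class GseaResult:
    set_name: str
    es: float
    nes: float
    pvalue: float
    fdr: float
    leading_edge: tuple[str, ...]
    n_members_used: int


@dataclass(frozen=True)
class ChromEnrichmentResult:
    """One chromosome's 2x2 Fisher test of DE-gene co-location.

    ``table`` is (DE on chrom, not-DE on chrom, DE off chrom,
    not-DE off chrom) over the expressed-gene universe.
    """

    chrom: str
    table: tuple[int, int, int, int]
    p_raw: float
    p_bonferroni: float


@dataclass(frozen=True)
class SweepPoint:
    """Exclusion outcome at one DAR threshold."""

    threshold: float
    retained: frozenset[str]
    excluded: frozenset[str]
    n_de_removed: int
    n_non_de_removed: int


def _rank_key(stat: float, gene_id: str):
    # descending stat, then gene_id ascending for bit-reproducible order
    return (-stat, gene_id)


def ranking_statistic(de: Sequence[DeGene]) -> list[RankedGene]:
    """sign(log2FC) x -log10(p) for every gene, sorted descending.

    sign(0) = 0, so a gene with zero fold-change ranks at exactly 0
    regardless of its p-value. Ties break by gene id, ascending.
    """
    ranked = []
    for gene in de:
        sign = 0.0 if gene.log2fc == 0 else math.copysign(1.0, gene.log2fc)
        ranked.append(RankedGene(gene.gene_id, sign * -math.log10(gene.pvalue)))
    ranked.sort(key=lambda r: _rank_key(r.stat, r.gene_id))
    return ranked


def dar_weight_ranks(
    ranked: Sequence[RankedGene], assignments: Sequence[GeneDarAssignment]
) -> list[RankedGene]:
    """Multiply each statistic by (1 - DAR) and re-sort.

    Genes with an absent DAR keep factor 1 (tallied in the log).
    """
    dar_of: dict[str, Optional[float]] = {a.gene_id: a.dar for a in assignments}
    out = []
    n_unassigned = 0
    for gene in ranked:
        dar = dar_of.get(gene.gene_id)
        if dar is None:
            n_unassigned += 1
            weighted = gene.stat
        else:
            if not (0.0 <= dar <= 1.0):
                raise DataError(f"gene {gene.gene_id}: DAR {dar} outside [0, 1]")
            weighted = gene.stat * (1.0 - dar)
        out.append(RankedGene(gene.gene_id, gene.stat, weighted))
    if n_unassigned:
        logger.info(
            "%d of %d genes have no DAR value; weight factor 1 applied",
            n_unassigned, len(out),
        )
    out.sort(key=lambda r: _rank_key(r.weighted_stat, r.gene_id))
    return out


def exclude_by_dar_threshold(
    genes: Sequence[str],
    assignments: Sequence[GeneDarAssignment],
    threshold: float,
) -> tuple[list[str], list[str]]:
    """Split a gene universe into (retained, excluded) at a DAR threshold.

    A gene is excluded iff its DAR is present AND strictly greater than
    the threshold; absent-DAR genes are always retained. At threshold 1
    nothing is excluded (1 is the metric's maximum).
    """
    if not (0.0 <= threshold <= 1.0):
        raise ConfigurationError(f"DAR threshold {threshold} outside [0, 1]")
    dar_of = {a.gene_id: a.dar for a in assignments}
    retained, excluded = [], []
    for gene in genes:
        dar = dar_of.get(gene)
        if dar is not None and dar > threshold:
            excluded.append(gene)
        else:
            retained.append(gene)
    return retained, excluded


DEFAULT_SWEEP_THRESHOLDS = tuple(round(0.1 * k, 1) for k in range(1, 11))


def threshold_sweep(
    genes: Sequence[str],
    assignments: Sequence[GeneDarAssignment],
    de_genes: frozenset[str] | set[str],
    thresholds: Sequence[float] = DEFAULT_SWEEP_THRESHOLDS,
) -> list[SweepPoint]:
    """Exclusion outcomes over a grid of DAR thresholds (default 0.1..1.0).

    Retained sets are nested: raising the threshold never removes a gene
    that survived a lower one. Removal counts are split by DE status.
    """
    points = []
    for threshold in thresholds:
        retained, excluded = exclude_by_dar_threshold(genes, assignments, threshold)
        points.append(
            SweepPoint(
                threshold=threshold,
                retained=frozenset(retained),
                excluded=frozenset(excluded),
                n_de_removed=sum(g in de_genes for g in excluded),
                n_non_de_removed=sum(g not in de_genes for g in excluded),
            )
        )
    return points


# ---------------------------------------------------------------------------
# Preranked GSEA
# ---------------------------------------------------------------------------

def _running_sum_extremum(
    abs_scores: np.ndarray, hit: np.ndarray
) -> tuple[float, int]:
    """Enrichment score and extremum index of the weighted KS running sum.

    The hit increment at rank j is |score_j| / sum(|score| over hits);
    the miss decrement is 1 / (N - n_hits). ES is the deviation of
    largest magnitude; at a magnitude tie the earliest rank wins.
    """
    n = len(abs_scores)
    n_hits = int(hit.sum())
    n_miss = n - n_hits
    if n_hits == 0 or n_miss == 0:
        return 0.0, 0
    nr = abs_scores[hit].sum()
    if nr == 0.0:
        # all member scores exactly zero: fall back to uniform increments
        p_hit = np.cumsum(hit) / n_hits
    else:
        p_hit = np.cumsum(np.where(hit, abs_scores, 0.0)) / nr
    p_miss = np.cumsum(~hit) / n_miss
    deviation = p_hit - p_miss
    # earliest rank within 1e-9 of the extremum magnitude: exact ties
    # between the positive and negative excursions (possible on small
    # lists) must not resolve on float rounding noise
    magnitude = np.abs(deviation)
    idx = int(np.argmax(magnitude >= magnitude.max() - 1e-9))
    return float(deviation[idx]), idx


def preranked_gsea(
    ranked: Sequence[RankedGene],
    sets: GeneSetCollection,
    n_perm: int = 10000,
    seed: int = 0,
    use_weighted: bool = False,
    min_size: int = 5,
    max_size: int = 500,
) -> list[GseaResult]:
    """Permutation preranked GSEA over a gene-set collection.

    The ranked universe is re-sorted internally on the chosen statistic
    (``weighted_stat`` when ``use_weighted``) so callers need not worry
    about list state. For each gene set restricted to the universe (and
    within [min_size, max_size]), the null is ``n_perm`` random same-size
    gene sets drawn without replacement under ``seed``;

    * p = (1 + #{same-sign permuted ES with \\|ES_perm\\| >= \\|ES\\|})
          / (#same-sign permuted ES + 1)
    * NES = ES / mean(\\|same-sign permuted ES\\|)
    * FDR = Benjamini-Hochberg across all tested sets
    * leading edge: members at or before the running-sum extremum
      (at or after it, for negative ES).

    Sets are processed in name order and nulls are cached per set size,
    so results are bit-reproducible for a given seed.
    """
    if not ranked:
        raise ConfigurationError("ranked gene list is empty")
    if use_weighted:
        if any(r.weighted_stat is None for r in ranked):
            raise ConfigurationError(
                "use_weighted requires weighted statistics (run dar_weight_ranks)"
            )
        ordered = sorted(ranked, key=lambda r: _rank_key(r.weighted_stat, r.gene_id))
        scores = np.array([r.weighted_stat for r in ordered])
    else:
        ordered = sorted(ranked, key=lambda r: _rank_key(r.stat, r.gene_id))
        scores = np.array([r.stat for r in ordered])
    gene_ids = [r.gene_id for r in ordered]
    rank_of = {g: i for i, g in enumerate(gene_ids)}
    abs_scores = np.abs(scores)
    n = len(ordered)

    rng = np.random.default_rng(seed)
    null_cache: dict[int, np.ndarray] = {}

    def null_es(k: int) -> np.ndarray:
        if k not in null_cache:
            es = np.empty(n_perm)
            hit = np.zeros(n, dtype=bool)
            for i in range(n_perm):
                idx = rng.choice(n, size=k, replace=False)
                hit[idx] = True
                es[i] = _running_sum_extremum(abs_scores, hit)[0]
                hit[idx] = False
            null_cache[k] = es
        return null_cache[k]

    results = []
    for name in sets.names():
        members = sorted(m for m in sets[name] if m in rank_of)
        k = len(members)
        if k == 0:
            logger.info("gene set %r: no members in ranked universe; skipped", name)
            continue
        if k < min_size or k > max_size:
            logger.info(
                "gene set %r: %d usable members outside [%d, %d]; skipped",
                name, k, min_size, max_size,
            )
            continue
        hit = np.zeros(n, dtype=bool)
        idx = np.fromiter((rank_of[m] for m in members), dtype=int)
        hit[idx] = True
        es, extremum = _running_sum_extremum(abs_scores, hit)
        perm = null_es(k)
        if es == 0.0:
            pvalue, nes = 1.0, 0.0
        else:
            same_sign = perm[np.sign(perm) == np.sign(es)]
            if len(same_sign) == 0:
                pvalue, nes = 1.0, 0.0
            else:
                pvalue = (1 + int((np.abs(same_sign) >= abs(es)).sum())) / (
                    len(same_sign) + 1
                )
                nes = es / float(np.abs(same_sign).mean())
        if es >= 0:
            edge = [g for g in gene_ids[: extremum + 1] if hit[rank_of[g]]]
        else:
            edge = [g for g in gene_ids[extremum:] if hit[rank_of[g]]]
        results.append(
            GseaResult(
                set_name=name, es=es, nes=nes, pvalue=pvalue, fdr=math.nan,
                leading_edge=tuple(edge), n_members_used=k,
            )
        )
    if results:
        adjusted = bh_fdr([r.pvalue for r in results])
        results = [
            GseaResult(
                r.set_name, r.es, r.nes, r.pvalue, fdr, r.leading_edge,
                r.n_members_used,
            )
            for r, fdr in zip(results, adjusted)
        ]
    return results


# ---------------------------------------------------------------------------
# Chromosomal co-location of DE genes
# ---------------------------------------------------------------------------

def chromosome_enrichment(
    de: Sequence[DeGene],
    genes: Sequence[GeneModel] = (),
    target_chrom: str = "all",
    alpha: float = 0.05,
) -> list[ChromEnrichmentResult]:
    """One-sided Fisher's exact test of DE-gene enrichment per chromosome.

    The universe is the supplied DE table (the expressed genes); a gene
    is DE when its FDR < ``alpha``. Chromosomes come from the gene
    models, falling back to the DE table's own chromosome column. The
    one-sided p is the hypergeometric upper tail (more DE genes on the
    chromosome than expected); the Bonferroni multiplier is the number
    of chromosomes holding at least one expressed gene, regardless of
    ``target_chrom`` filtering.
    """
    if not de:
        raise ConfigurationError("empty DE-gene universe")
    chrom_of = {g.gene_id: g.chrom for g in genes}
    universe = []
    for gene in de:
        chrom = chrom_of.get(gene.gene_id, gene.chrom)
        if chrom is None:
            raise DataError(f"gene {gene.gene_id}: no chromosome available")
        universe.append((gene.gene_id, chrom, gene.fdr < alpha))
    n_total = len(universe)
    n_de = sum(flag for _, _, flag in universe)
    chroms = sorted({chrom for _, chrom, _ in universe})
    multiplier = len(chroms)
    results = []
    for chrom in chroms:
        on = [flag for _, c, flag in universe if c == chrom]
        de_on = sum(on)
        n_on = len(on)
        table = (de_on, n_on - de_on, n_de - de_on, n_total - n_on - n_de + de_on)
        p_raw = float(hypergeom.sf(de_on - 1, n_total, n_de, n_on))
        p_raw = min(1.0, p_raw)
        results.append(
            ChromEnrichmentResult(
                chrom=chrom,
                table=table,
                p_raw=p_raw,
                p_bonferroni=min(1.0, p_raw * multiplier),
            )
        )
    if target_chrom != "all":
        results = [r for r in results if r.chrom == target_chrom]
    return results


def bh_fdr(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjustment, order-preserving."""
    arr = np.asarray(pvalues, dtype=float)
    if arr.size == 0:
        return []
    if np.any((arr <= 0) | (arr > 1)):
        raise DataError("p-values must lie in (0, 1]")
    return list(multipletests(arr, method="fdr_bh")[1])
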