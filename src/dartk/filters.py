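"""Site-level and group-level exclusion rules applied before DAR computation.

The hard filters mirror the GATK-recommended annotations for RNA-seq
variant calls: a site fails on strand bias (FS > 60), quality-by-depth
(QD < 2), RMS mapping quality (MQ < 40) or strand odds ratio (SOR > 4).
Absent annotations pass — many VCFs omit one or more of these, and
failing on absence would silently discard whole files; absences are
logged instead.

SNP-cluster artefacts (more than ``cluster_max_snps`` SNPs inside any
``cluster_window_bp`` window) are removed because dense local variation
usually reflects misalignment, e.g. around diverged or humanised loci,
rather than real polymorphism.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

from .types import DataError, GenotypeMatrix, VariantLocus

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterThresholds:
    """All tunable exclusion thresholds with their standard defaults."""

    fs_max: float = 60.0
    qd_min: float = 2.0
    mq_min: float = 40.0
    sor_max: float = 4.0
    cluster_max_snps: int = 3
    cluster_window_bp: int = 35
    missing_frac_max: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 <= self.missing_frac_max <= 1.0):
            raise DataError(
                f"missing_frac_max {self.missing_frac_max} outside [0, 1]"
            )


@dataclass(frozen=True)
class Rejection:
    """Why a locus was removed, for the rejection report."""

    chrom: str
    pos: int
    reasons: tuple[str, ...]


@dataclass
class FilterReport:
    """Accumulated rejections across the filter stages."""

    rejections: list[Rejection] = field(default_factory=list)

    def extend(self, items: list[Rejection]) -> None:
        self.rejections.extend(items)


def apply_hard_filters(
    matrix: GenotypeMatrix, thresholds: Optional[FilterThresholds] = None
) -> tuple[GenotypeMatrix, list[Rejection]]:
    """Remove loci failing any of the four site-annotation hard filters.

    A locus fails iff FS > fs_max, QD < qd_min, MQ < mq_min or
    SOR > sor_max; each removal carries the failing annotation name(s).
    Absent annotations pass (logged). All comparisons are strict, so a
    locus sitting exactly on every bound is retained.
    """
    t = thresholds or FilterThresholds()
    kept: list[VariantLocus] = []
    rejected: list[Rejection] = []
    n_absent = 0
    for locus in matrix.loci:
        stats = locus.site_stats
        for key, value in stats.items():
            if value < 0:
                raise DataError(
                    f"{locus.chrom}:{locus.pos}: negative {key} annotation {value}"
                )
        n_absent += sum(k not in stats for k in ("FS", "QD", "MQ", "SOR"))
        reasons = []
        if "FS" in stats and stats["FS"] > t.fs_max:
            reasons.append("FS")
        if "QD" in stats and stats["QD"] < t.qd_min:
            reasons.append("QD")
        if "MQ" in stats and stats["MQ"] < t.mq_min:
            reasons.append("MQ")
        if "SOR" in stats and stats["SOR"] > t.sor_max:
            reasons.append("SOR")
        if reasons:
            rejected.append(Rejection(locus.chrom, locus.pos, tuple(reasons)))
        else:
            kept.append(locus)
    if n_absent:
        logger.info("%d absent site annotations treated as passing", n_absent)
    return matrix.replace_loci(kept), rejected


def select_snps(matrix: GenotypeMatrix) -> GenotypeMatrix:
    """Keep only records whose REF and every ALT are single bases."""
    return matrix.replace_loci([l for l in matrix.loci if l.is_snp])


def flag_snp_clusters(
    matrix: GenotypeMatrix,
    thresholds: Optional[FilterThresholds] = None,
    remove: bool = True,
) -> tuple[GenotypeMatrix, list[Rejection]]:
    """Flag loci lying in any window of ``cluster_window_bp`` base pairs
    that contains more than ``cluster_max_snps`` loci; remove them unless
    ``remove=False`` (flag-only mode).

    Windows are evaluated over positions on the same chromosome,
    inclusive of both ends: a window of W bp covers W consecutive
    positions, so c+1 sorted loci fit in one window iff the span of their
    positions is <= W - 1.
    """
    t = thresholds or FilterThresholds()
    c = t.cluster_max_snps
    span = t.cluster_window_bp - 1
    flagged_keys: set[tuple[str, int]] = set()
    by_chrom: dict[str, list[int]] = {}
    for locus in matrix.loci:
        by_chrom.setdefault(locus.chrom, []).append(locus.pos)
    for chrom, positions in by_chrom.items():
        n = len(positions)
        for j in range(n - c):
            if positions[j + c] - positions[j] <= span:
                # every locus in the offending window is an artefact
                for m in range(j, j + c + 1):
                    flagged_keys.add((chrom, positions[m]))
    flagged = [
        Rejection(chrom, pos, ("SnpCluster",))
        for chrom, pos in sorted(flagged_keys)
    ]
    if not remove:
        return matrix, flagged
    kept = [l for l in matrix.loci if (l.chrom, l.pos) not in flagged_keys]
    return matrix.replace_loci(kept), flagged


def exclude_uninformative(matrix: GenotypeMatrix) -> GenotypeMatrix:
    """Drop loci where no sample reports a non-reference allele.

    Covers monoallelic hom-ref loci and the degenerate all-missing case:
    with no alternative allele reported anywhere, between-group
    proportion comparison is vacuous.
    """
    kept = []
    for locus in matrix.loci:
        informative = False
        for call in locus.genotypes.values():
            if call is None:
                continue
            if call[0] != locus.ref_base or call[1] != locus.ref_base:
                informative = True
                break
        if informative:
            kept.append(locus)
    return matrix.replace_loci(kept)


def missingness_filter(
    matrix: GenotypeMatrix, thresholds: Optional[FilterThresholds] = None
) -> GenotypeMatrix:
    """Drop loci whose missing-call fraction exceeds the bound in either group.

    The bound is strict: exactly ``missing_frac_max`` missing is retained.
    A locus unusable in one group cannot yield a two-group proportion
    comparison, hence the either-group rule.
    """
    t = thresholds or FilterThresholds()
    g1, g2 = matrix.group_names
    groups = [matrix.group_samples(g1), matrix.group_samples(g2)]
    kept = []
    for locus in matrix.loci:
        ok = True
        for samples in groups:
            n_missing = sum(locus.genotypes[s] is None for s in samples)
            if n_missing / len(samples) > t.missing_frac_max:
                ok = False
                break
        if ok:
            kept.append(locus)
    return matrix.replace_loci(kept)


def apply_all_filters(
    matrix: GenotypeMatrix, thresholds: Optional[FilterThresholds] = None
) -> tuple[GenotypeMatrix, FilterReport]:
    """Run the full exclusion cascade in the standard order.

    hard filters -> SNP selection -> cluster removal -> uninformative
    removal -> per-group missingness.
    """
    t = thresholds or FilterThresholds()
    report = FilterReport()
    matrix, rejected = apply_hard_filters(matrix, t)
    report.extend(rejected)
    before = {(l.chrom, l.pos) for l in matrix.loci}
    matrix = select_snps(matrix)
    after = {(l.chrom, l.pos) for l in matrix.loci}
    report.extend(
        [Rejection(c, p, ("NotSnp",)) for c, p in sorted(before - after)]
    )
    matrix, flagged = flag_snp_clusters(matrix, t)
    report.extend(flagged)
    before = {(l.chrom, l.pos) for l in matrix.loci}
    matrix = exclude_uninformative(matrix)
    after = {(l.chrom, l.pos) for l in matrix.loci}
    report.extend(
        [Rejection(c, p, ("Uninformative",)) for c, p in sorted(before - after)]
    )
    before = after
    matrix = missingness_filter(matrix, t)
    after = {(l.chrom, l.pos) for l in matrix.loci}
    report.extend(
        [Rejection(c, p, ("Missingness",)) for c, p in sorted(before - after)]
    )
    return matrix, report
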