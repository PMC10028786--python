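"""The DAR metric: normalized Euclidean distance between group allele proportions.

At each SNP locus, every called diploid genotype in a group contributes
two alleles, so n called genotypes report 2n alleles. Counts over the
four bases are normalized to proportions, and the differential allelic
representation between groups 1 and 2 is

    DAR = sqrt( sum_i (p_i1 - p_i2)^2 ) / sqrt(2),   i in {A, C, G, T}

The sqrt(2) divisor is the largest Euclidean distance attainable between
two points of the probability simplex (two distinct vertices), so DAR
ranges from 0 (identical allele proportions) to 1 (the groups fixed for
different bases).

Allele counts come from genotype calls, never from read-depth (AD)
fields: the metric quantifies between-group representation of alleles,
not within-sample expression imbalance, and the two would conflate under
an AD-based count.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from .types import (
    BASES,
    ConfigurationError,
    DarLocus,
    DataError,
    GenotypeMatrix,
    VariantLocus,
)

logger = logging.getLogger(__name__)

SQRT2 = math.sqrt(2.0)

Proportions = Union[Mapping[str, float], Sequence[float], np.ndarray]


@dataclass(frozen=True)
class AlleleProportionProfile:
    """Per-group allele tally at one locus.

    ``proportions`` is None when no sample in the group was called
    (n_called == 0): the proportion vector is undefined, not zero.
    """

    chrom: str
    pos: int
    group: str
    counts: Mapping[str, int]
    n_called: int

    def __post_init__(self) -> None:
        total = sum(self.counts.values())
        if total != 2 * self.n_called:
            raise DataError(
                f"{self.chrom}:{self.pos} [{self.group}]: allele count {total} "
                f"!= 2 x {self.n_called} called genotypes"
            )

    @property
    def proportions(self) -> Optional[dict[str, float]]:
        if self.n_called == 0:
            return None
        denom = 2.0 * self.n_called
        return {base: self.counts.get(base, 0) / denom for base in BASES}


def count_group_alleles(
    locus: VariantLocus, group_samples: Sequence[str], group: str = ""
) -> AlleleProportionProfile:
    """Tally alleles for one group at one locus.

    Each non-missing diploid call contributes exactly two alleles;
    missing calls contribute nothing and reduce ``n_called``.
    """
    if not group_samples:
        raise ConfigurationError("group_samples must be non-empty")
    counts = {base: 0 for base in BASES}
    n_called = 0
    for sample in group_samples:
        call = locus.genotypes[sample]
        if call is None:
            continue
        n_called += 1
        for base in call:
            counts[base] += 1
    return AlleleProportionProfile(
        chrom=locus.chrom, pos=locus.pos, group=group, counts=counts,
        n_called=n_called,
    )


def _as_vector(p: Proportions) -> np.ndarray:
    if isinstance(p, Mapping):
        vec = np.array([p.get(base, 0.0) for base in BASES], dtype=float)
    else:
        vec = np.asarray(p, dtype=float)
    if vec.shape != (4,):
        raise DataError(f"proportion vector must have 4 entries, got {vec.shape}")
    if abs(vec.sum() - 1.0) > 1e-9:
        raise DataError(f"proportions sum to {vec.sum()!r}, not 1")
    return vec


def dar_raw(p1: Proportions, p2: Proportions) -> float:
    """DAR between two allele-proportion vectors.

    Accepts base->proportion mappings or length-4 sequences ordered
    (A, C, G, T). Both vectors must sum to 1 (tolerance 1e-9). The result
    is clipped into [0, 1] against floating-point overshoot.
    """
    v1, v2 = _as_vector(p1), _as_vector(p2)
    distance = float(np.linalg.norm(v1 - v2))
    return min(1.0, max(0.0, distance / SQRT2))


def compute_dar_track(matrix: GenotypeMatrix) -> list[DarLocus]:
    """Per-locus DAR values for an already-filtered matrix, in genome order.

    Loci where either group has zero called samples have undefined
    proportions and are omitted (with a logged count); the upstream
    missingness filter normally prevents this.
    """
    g1, g2 = matrix.group_names
    samples1 = matrix.group_samples(g1)
    samples2 = matrix.group_samples(g2)
    track = []
    n_skipped = 0
    for locus in matrix.loci:
        prof1 = count_group_alleles(locus, samples1, g1)
        prof2 = count_group_alleles(locus, samples2, g2)
        p1, p2 = prof1.proportions, prof2.proportions
        if p1 is None or p2 is None:
            n_skipped += 1
            continue
        track.append(DarLocus(locus.chrom, locus.pos, dar_raw(p1, p2)))
    if n_skipped:
        logger.warning(
            "%d loci skipped: zero called samples in one group", n_skipped
        )
    return track
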