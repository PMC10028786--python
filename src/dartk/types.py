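"""Core domain types shared across the DAR pipeline.

All genomic coordinates are 1-based inclusive, matching both VCF and
GFF3/GTF. No half-open conversion layer exists internally; the only
0-based export is the optional BED writer, which converts at the
boundary.

Genotypes are unordered diploid base pairs: phasing carries no
information for allele counting, so ``A|G`` and ``G/A`` are the same
call, stored as the lexicographically sorted tuple ``("A", "G")``.
Missing calls are ``None``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

#: The four dimensions of every allele-proportion vector. Multiallelic
#: sites need no special casing because proportions always live on this
#: fixed 4-simplex.
BASES: tuple[str, str, str, str] = ("A", "C", "G", "T")

#: Site-level annotations consumed by the hard filters.
SITE_STAT_KEYS: tuple[str, ...] = ("FS", "QD", "MQ", "SOR")

Call = Optional[tuple[str, str]]


class DartkError(Exception):
    """Base class for all dartk errors."""


class ConfigurationError(DartkError):
    """Invalid user-supplied configuration (bad groups, thresholds, paths)."""


class DataError(DartkError):
    """A record in an input file violates the format or value contract."""


@dataclass(frozen=True)
class VariantLocus:
    """A single variant record with per-sample diploid calls.

    ``ref_base`` / ``alt_bases`` hold the literal REF/ALT strings; records
    whose alleles are not all single bases are retained at parse time and
    flagged non-SNP (``is_snp``) for later removal by the SNP selector.
    """

    chrom: str
    pos: int
    ref_base: str
    alt_bases: tuple[str, ...]
    genotypes: Mapping[str, Call]
    site_stats: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise DataError(f"{self.chrom}:{self.pos}: position must be >= 1")
        if self.ref_base in self.alt_bases:
            raise DataError(f"{self.chrom}:{self.pos}: REF allele repeated in ALT")
        if len(set(self.alt_bases)) != len(self.alt_bases):
            raise DataError(f"{self.chrom}:{self.pos}: duplicate ALT alleles")
        alleles = {self.ref_base, *self.alt_bases}
        for sample, call in self.genotypes.items():
            if call is None:
                continue
            if len(call) != 2:
                raise DataError(
                    f"{self.chrom}:{self.pos}: sample {sample} is not diploid"
                )
            for base in call:
                if base not in alleles:
                    raise DataError(
                        f"{self.chrom}:{self.pos}: sample {sample} call {call} "
                        f"uses a base outside REF/ALT"
                    )

    @property
    def is_snp(self) -> bool:
        """True when REF and every ALT are single nucleotides."""
        if len(self.ref_base) != 1 or self.ref_base not in BASES:
            return False
        return all(len(a) == 1 and a in BASES for a in self.alt_bases)

    def call(self, sample: str) -> Call:
        return self.genotypes[sample]


def make_call(a: str, b: str) -> tuple[str, str]:
    """Canonical unordered representation of a diploid call."""
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class GenotypeMatrix:
    """All loci for all samples plus the two-group partition under contrast."""

    loci: tuple[VariantLocus, ...]
    sample_ids: tuple[str, ...]
    group_of: Mapping[str, str]

    def __post_init__(self) -> None:
        groups: dict[str, list[str]] = {}
        for sample in self.sample_ids:
            if sample not in self.group_of:
                raise ConfigurationError(f"sample {sample!r} has no group assignment")
            groups.setdefault(self.group_of[sample], []).append(sample)
        if len(groups) != 2:
            raise ConfigurationError(
                f"exactly two sample groups are required, got {sorted(groups)}"
            )
        keys = [(locus.chrom, locus.pos) for locus in self.loci]
        if keys != sorted(keys):
            raise DataError("loci must be sorted by (chrom, pos)")
        if len(set(keys)) != len(keys):
            raise DataError("duplicate (chrom, pos) among loci")
        for locus in self.loci:
            if set(locus.genotypes) != set(self.sample_ids):
                raise DataError(
                    f"{locus.chrom}:{locus.pos}: sample set differs from matrix"
                )

    @property
    def group_names(self) -> tuple[str, str]:
        """The two group labels, lexicographically ordered for determinism."""
        names = sorted(set(self.group_of.values()))
        return names[0], names[1]

    def group_samples(self, group: str) -> tuple[str, ...]:
        return tuple(s for s in self.sample_ids if self.group_of[s] == group)

    def replace_loci(self, loci: Sequence[VariantLocus]) -> "GenotypeMatrix":
        return GenotypeMatrix(tuple(loci), self.sample_ids, self.group_of)

    def __len__(self) -> int:
        return len(self.loci)


@dataclass(frozen=True)
class GeneModel:
    """Gene coordinates for region overlap; strand is carried but unused."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "unknown"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise DataError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )


@dataclass(frozen=True)
class DeGene:
    """One row of a differential-expression results table."""

    gene_id: str
    log2fc: float
    pvalue: float
    fdr: float
    chrom: Optional[str] = None

    def __post_init__(self) -> None:
        for name, value in (("pvalue", self.pvalue), ("fdr", self.fdr)):
            if not (0.0 < value <= 1.0):
                raise DataError(f"gene {self.gene_id}: {name}={value} outside (0, 1]")


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets (e.g. KEGG pathways) read from a GMT file."""

    sets: Mapping[str, frozenset[str]]

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def names(self) -> list[str]:
        return sorted(self.sets)


@dataclass(frozen=True)
class DarLocus:
    """Raw DAR value at a single nucleotide locus."""

    chrom: str
    pos: int
    dar: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.dar <= 1.0):
            raise DataError(f"{self.chrom}:{self.pos}: DAR {self.dar} outside [0, 1]")


@dataclass(frozen=True)
class SmoothedDarRegion:
    """Elastic-window mean DAR anchored at an origin locus.

    ``region_start``/``region_end`` are the positions of the outermost loci
    in the window, so the region is the genomic span the averaged variants
    cover, not a fixed number of base pairs.
    """

    chrom: str
    origin_pos: int
    region_start: int
    region_end: int
    smoothed_dar: float
    window_n: int

    def __post_init__(self) -> None:
        if not (self.region_start <= self.origin_pos <= self.region_end):
            raise DataError(
                f"{self.chrom}:{self.origin_pos}: origin outside its region"
            )
        if self.window_n < 1:
            raise DataError(f"{self.chrom}:{self.origin_pos}: empty window")


@dataclass(frozen=True)
class GeneDarAssignment:
    """A gene's DAR: unweighted mean over the smoothed regions it overlaps.

    ``dar`` is None for genes overlapping no region (no variant evidence);
    such genes are never excluded and receive weight factor 1 downstream.
    """

    gene_id: str
    dar: Optional[float]
    n_regions: int

    def __post_init__(self) -> None:
        if (self.dar is None) != (self.n_regions == 0):
            raise DataError(
                f"gene {self.gene_id}: dar must be present iff n_regions >= 1"
            )
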