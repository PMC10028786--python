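"""Seeded synthetic fixtures with the genetic structure DAR analysis assumes.

The generator emulates a near-isogenic experimental cross: most of the
genome shows only residual between-group allelic divergence, while one
or more linked haplotype blocks around a nominated "mutation" locus
carry strongly diverged allele frequencies — the situation created when
comparison groups are selected by genotype at a mutation and nearby
alleles hitch-hike along. A matching DE table mixes eQTL-positioned DE
genes (inside the diverged blocks) with unlinked true-response DE genes,
so the whole exclusion/weighting machinery is exercisable offline.

Group allele frequencies are set analytically from a target divergence
``d``: at a biallelic locus the per-allele frequency difference is
``d``, so the Euclidean distance between the proportion vectors is
``d * sqrt(2)`` and the expected DAR is exactly ``d``. Allele counts per
group are the rounded expected counts (not binomial draws), so ``d = 0``
gives raw DAR exactly 0 and ``d = 1`` gives exactly 1; the residual
randomness lives in locus placement, base identities, the frequency
centre, the shuffling of alleles into genotypes, and missingness.

All randomness flows from one integer seed through per-stage child
generators; no global state is touched.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .enrichment import bh_fdr
from .io import write_gmt, write_groups, write_table, write_vcf
from .types import (
    BASES,
    ConfigurationError,
    DeGene,
    GeneModel,
    GeneSetCollection,
    GenotypeMatrix,
    VariantLocus,
    make_call,
)


@dataclass(frozen=True)
class ChromSpec:
    name: str
    length_bp: int
    n_loci: int


@dataclass(frozen=True)
class BlockSpec:
    """A linked haplotype block of elevated divergence."""

    chrom: str
    start: int
    end: int
    divergence: float  # target expected DAR inside the block, in [0, 1]


@dataclass(frozen=True)
class DeConfig:
    """How many DE genes of each kind and how their statistics are drawn.

    eQTL-positioned DE genes draw somewhat smaller p-values than the
    unlinked response genes, emulating the regime the method targets:
    strong eQTL-driven signals dominating the top of the ranked list
    until they are down-weighted.
    """

    n_eqtl_de: int = 15
    n_response_de: int = 15
    eqtl_neg_log10_p: tuple[float, float] = (5.0, 9.0)
    response_neg_log10_p: tuple[float, float] = (3.0, 6.0)
    de_log2fc_mean: float = 2.0
    de_log2fc_sd: float = 0.5
    null_log2fc_sd: float = 0.1
    #: probability a DE gene is upregulated; 1.0 models a coherently
    #: directed response (and the worst case of eQTL genes competing
    #: with it at the same end of the ranked list)
    prob_upregulated: float = 1.0


@dataclass(frozen=True)
class SimulationSpec:
    seed: int = 0
    n_per_group: tuple[int, int] = (8, 8)
    chromosomes: tuple[ChromSpec, ...] = (
        ChromSpec("chr1", 10_000_000, 500),
        ChromSpec("chr2", 10_000_000, 300),
    )
    blocks: tuple[BlockSpec, ...] = (BlockSpec("chr1", 3_000_001, 7_000_000, 0.9),)
    background_divergence: float = 0.05
    missing_rate: float = 0.05
    n_genes: int = 200
    gene_mean_length: int = 20_000
    de: DeConfig = field(default_factory=DeConfig)

    def __post_init__(self) -> None:
        chrom_len = {c.name: c.length_bp for c in self.chromosomes}
        for block in self.blocks:
            if block.chrom not in chrom_len:
                raise ConfigurationError(f"block on unknown chromosome {block.chrom}")
            if not (1 <= block.start <= block.end <= chrom_len[block.chrom]):
                raise ConfigurationError(
                    f"block {block.chrom}:{block.start}-{block.end} outside "
                    f"chromosome (length {chrom_len[block.chrom]})"
                )
            if not (0.0 <= block.divergence <= 1.0):
                raise ConfigurationError("block divergence outside [0, 1]")
        if not (0.0 <= self.background_divergence <= 1.0):
            raise ConfigurationError("background divergence outside [0, 1]")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigurationError("missing_rate outside [0, 1)")


def _stage_rng(spec: SimulationSpec, stage: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed, stage])


def _divergence_at(spec: SimulationSpec, chrom: str, pos: int) -> float:
    for block in spec.blocks:
        if block.chrom == chrom and block.start <= pos <= block.end:
            return block.divergence
    return spec.background_divergence


def _group_genotypes(
    rng: np.random.Generator,
    samples: Sequence[str],
    ref: str,
    alt: str,
    alt_freq: float,
    missing_rate: float,
) -> dict[str, tuple[str, str] | None]:
    """Allocate round(2n * alt_freq) ALT alleles across a group's genotypes."""
    n = len(samples)
    k = int(round(2 * n * alt_freq))
    alleles = [alt] * k + [ref] * (2 * n - k)
    rng.shuffle(alleles)
    calls: dict[str, tuple[str, str] | None] = {}
    for i, sample in enumerate(samples):
        if missing_rate > 0 and rng.random() < missing_rate:
            calls[sample] = None
        else:
            calls[sample] = make_call(alleles[2 * i], alleles[2 * i + 1])
    return calls


def sample_names(spec: SimulationSpec) -> tuple[tuple[str, ...], tuple[str, ...]]:
    n1, n2 = spec.n_per_group
    return (
        tuple(f"g1_s{i + 1}" for i in range(n1)),
        tuple(f"g2_s{i + 1}" for i in range(n2)),
    )


def simulate_genotypes(spec: SimulationSpec) -> GenotypeMatrix:
    """Generate the two-group genotype matrix described by the spec.

    Loci are placed uniformly at random along each chromosome. At a
    locus with target divergence d, the two groups' ALT-allele
    frequencies are centred at a shared random value and separated by
    exactly d (d = 1 fixes the groups for different bases). Missing
    calls are injected independently at ``missing_rate``.
    """
    rng = _stage_rng(spec, 0)
    group1, group2 = sample_names(spec)
    group_of = {s: "g1" for s in group1} | {s: "g2" for s in group2}
    loci = []
    for chrom in spec.chromosomes:
        positions = np.sort(
            rng.choice(chrom.length_bp, size=chrom.n_loci, replace=False) + 1
        )
        for pos in positions:
            ref, alt = rng.choice(len(BASES), size=2, replace=False)
            ref, alt = BASES[ref], BASES[alt]
            d = _divergence_at(spec, chrom.name, int(pos))
            centre = rng.uniform(d / 2, 1 - d / 2) if d < 1 else 0.5
            f1 = min(1.0, centre + d / 2)
            f2 = max(0.0, centre - d / 2)
            genotypes = _group_genotypes(
                rng, group1, ref, alt, f1, spec.missing_rate
            ) | _group_genotypes(rng, group2, ref, alt, f2, spec.missing_rate)
            loci.append(
                VariantLocus(
                    chrom=chrom.name,
                    pos=int(pos),
                    ref_base=ref,
                    alt_bases=(alt,),
                    genotypes=genotypes,
                )
            )
    loci.sort(key=lambda l: (l.chrom, l.pos))
    return GenotypeMatrix(
        tuple(loci), group1 + group2, group_of
    )


def simulate_gene_models(spec: SimulationSpec) -> list[GeneModel]:
    """Place genes along the chromosomes, count proportional to length."""
    rng = _stage_rng(spec, 1)
    total = sum(c.length_bp for c in spec.chromosomes)
    genes = []
    counter = 0
    for chrom in spec.chromosomes:
        n = int(round(spec.n_genes * chrom.length_bp / total))
        for _ in range(n):
            counter += 1
            length = max(500, int(rng.exponential(spec.gene_mean_length)))
            start = int(rng.integers(1, max(2, chrom.length_bp - length)))
            genes.append(
                GeneModel(
                    gene_id=f"gene{counter:04d}",
                    chrom=chrom.name,
                    start=start,
                    end=min(chrom.length_bp, start + length - 1),
                    strand="+" if rng.random() < 0.5 else "-",
                )
            )
    genes.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    return genes


def _in_any_block(spec: SimulationSpec, gene: GeneModel) -> bool:
    return any(
        b.chrom == gene.chrom and b.start <= gene.end and gene.start <= b.end
        for b in spec.blocks
    )


@dataclass(frozen=True)
class SimulatedDe:
    """A DE table plus the ground truth of which genes are which."""

    table: tuple[DeGene, ...]
    eqtl_gene_ids: tuple[str, ...]
    response_gene_ids: tuple[str, ...]


def simulate_de_table(spec: SimulationSpec, genes: Sequence[GeneModel]) -> SimulatedDe:
    """Mix eQTL-positioned and unlinked true-response DE genes with nulls.

    eQTL-type DE genes are sampled from genes inside the diverged
    blocks; response DE genes from genes outside every block, preferring
    chromosomes carrying no block at all (genuinely unlinked). Null
    genes get uniform p-values and near-zero log2 fold-changes; the FDR
    column is Benjamini-Hochberg over all p-values.
    """
    rng = _stage_rng(spec, 2)
    cfg = spec.de
    block_chroms = {b.chrom for b in spec.blocks}
    in_block = [g.gene_id for g in genes if _in_any_block(spec, g)]
    unlinked = [g.gene_id for g in genes if g.chrom not in block_chroms]
    if len(unlinked) < cfg.n_response_de:
        unlinked = [g.gene_id for g in genes if not _in_any_block(spec, g)]
    if len(in_block) < cfg.n_eqtl_de:
        raise ConfigurationError(
            f"requested {cfg.n_eqtl_de} eQTL DE genes but only {len(in_block)} "
            f"genes lie inside divergence blocks"
        )
    if len(unlinked) < cfg.n_response_de:
        raise ConfigurationError(
            f"requested {cfg.n_response_de} response DE genes but only "
            f"{len(unlinked)} genes lie outside the blocks"
        )
    eqtl = sorted(str(g) for g in rng.choice(in_block, size=cfg.n_eqtl_de,
                                             replace=False))
    pool = sorted(set(unlinked) - set(eqtl))
    response = sorted(
        str(g) for g in rng.choice(pool, size=cfg.n_response_de, replace=False)
    )
    chrom_of = {g.gene_id: g.chrom for g in genes}
    rows = []
    pvalues = []
    for gene in genes:
        if gene.gene_id in eqtl:
            lo, hi = cfg.eqtl_neg_log10_p
            p = 10.0 ** -rng.uniform(lo, hi)
            sign = 1.0 if rng.random() < cfg.prob_upregulated else -1.0
            fc = sign * abs(rng.normal(cfg.de_log2fc_mean, cfg.de_log2fc_sd))
        elif gene.gene_id in response:
            lo, hi = cfg.response_neg_log10_p
            p = 10.0 ** -rng.uniform(lo, hi)
            sign = 1.0 if rng.random() < cfg.prob_upregulated else -1.0
            fc = sign * abs(rng.normal(cfg.de_log2fc_mean, cfg.de_log2fc_sd))
        else:
            p = float(rng.uniform(np.nextafter(0.0, 1.0), 1.0))
            fc = float(rng.normal(0.0, cfg.null_log2fc_sd))
        rows.append((gene.gene_id, fc, p, chrom_of[gene.gene_id]))
        pvalues.append(p)
    fdrs = bh_fdr(pvalues)
    table = tuple(
        DeGene(gene_id=g, log2fc=fc, pvalue=p, fdr=max(fdr, np.nextafter(0.0, 1.0)),
               chrom=chrom)
        for (g, fc, p, chrom), fdr in zip(rows, fdrs)
    )
    return SimulatedDe(table, tuple(eqtl), tuple(response))


def simulate_gene_sets(
    spec: SimulationSpec,
    genes: Sequence[GeneModel],
    de: SimulatedDe,
    n_null_sets: int = 10,
    null_set_size: int = 15,
) -> GeneSetCollection:
    """An eQTL-block set, an unlinked-response set and random null sets."""
    rng = _stage_rng(spec, 3)
    all_ids = [g.gene_id for g in genes]
    sets = {
        "eqtl_block": frozenset(de.eqtl_gene_ids),
        "response": frozenset(de.response_gene_ids),
    }
    for i in range(n_null_sets):
        members = rng.choice(all_ids, size=min(null_set_size, len(all_ids)),
                             replace=False)
        sets[f"null_{i + 1:02d}"] = frozenset(str(m) for m in members)
    return GeneSetCollection(sets)


def write_gff3(genes: Sequence[GeneModel], chromosomes: Sequence[ChromSpec],
               path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom in chromosomes:
            fh.write(f"##sequence-region {chrom.name} 1 {chrom.length_bp}\n")
        for gene in genes:
            strand = gene.strand if gene.strand in "+-" else "."
            fh.write(
                f"{gene.chrom}\tdartk\tgene\t{gene.start}\t{gene.end}\t.\t"
                f"{strand}\t.\tID={gene.gene_id}\n"
            )


def write_fixture(spec: SimulationSpec, outdir: str | Path) -> dict[str, Path]:
    """Write a complete, mutually consistent input bundle plus manifest.

    Produces genotypes.vcf, groups.tsv, genes.gff3, de_table.tsv,
    gene_sets.gmt and manifest.json (seed, spec, per-file sha256).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrix = simulate_genotypes(spec)
    genes = simulate_gene_models(spec)
    de = simulate_de_table(spec, genes)
    sets = simulate_gene_sets(spec, genes, de)
    paths = {
        "vcf": outdir / "genotypes.vcf",
        "groups": outdir / "groups.tsv",
        "gff3": outdir / "genes.gff3",
        "de_table": outdir / "de_table.tsv",
        "gmt": outdir / "gene_sets.gmt",
    }
    write_vcf(matrix, paths["vcf"])
    write_groups(matrix.group_of, paths["groups"])
    write_gff3(genes, spec.chromosomes, paths["gff3"])
    de_df = pd.DataFrame(
        [
            {"gene_id": g.gene_id, "logFC": g.log2fc, "PValue": g.pvalue,
             "FDR": g.fdr, "chrom": g.chrom}
            for g in de.table
        ]
    )
    write_table(de_df, paths["de_table"])
    write_gmt(sets, paths["gmt"])
    manifest = {
        "seed": spec.seed,
        "spec": asdict(spec),
        "truth": {
            "eqtl_gene_ids": list(de.eqtl_gene_ids),
            "response_gene_ids": list(de.response_gene_ids),
        },
        "sha256": {
            name: hashlib.sha256(path.read_bytes()).hexdigest()
            for name, path in sorted(paths.items())
        },
    }
    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    paths["manifest"] = manifest_path
    return paths
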