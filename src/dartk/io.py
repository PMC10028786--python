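"""Readers and writers for the standard formats the pipeline touches.

VCF goes through :mod:`pysam`, gene models through :mod:`gffutils`
(in-memory database), delimited tables through :mod:`pandas`. GMT is
parsed directly — the format is three-plus tab-separated fields per line
and the error contract (line numbers) is part of this module's surface.

All dartk table outputs are tab-separated with ``#``-prefixed comment
header lines.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import pysam

from .types import (
    BASES,
    Call,
    ConfigurationError,
    DataError,
    DeGene,
    GeneModel,
    GeneSetCollection,
    GenotypeMatrix,
    SmoothedDarRegion,
    VariantLocus,
    make_call,
)

logger = logging.getLogger(__name__)

#: Replacement for p-values of exactly 0 before any -log10 transform.
P_VALUE_CLAMP = float(np.nextafter(0.0, 1.0))


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def parse_vcf(path: str | Path, group_assignment: Mapping[str, str]) -> GenotypeMatrix:
    """Read a joint-genotyped multi-sample VCF into a :class:`GenotypeMatrix`.

    Parameters
    ----------
    path
        VCF 4.x file (plain text or bgzipped).
    group_assignment
        Map from sample id to one of exactly two group labels. Every
        sample named here must appear in the VCF header; extra samples in
        the VCF are ignored.

    Notes
    -----
    Phase separators are ignored (``0|1`` == ``1/0``); ``./.`` and ``.``
    become missing calls. Records whose REF or any ALT is not a single
    base are retained but flagged non-SNP for the downstream SNP
    selector. Only diploid calls are accepted.
    """
    if len(set(group_assignment.values())) != 2:
        raise ConfigurationError(
            f"group assignment must name exactly two groups, "
            f"got {sorted(set(group_assignment.values()))}"
        )
    samples = tuple(group_assignment)
    with pysam.VariantFile(str(path)) as vf:
        header_samples = set(vf.header.samples)
        missing = [s for s in samples if s not in header_samples]
        if missing:
            raise ConfigurationError(
                f"samples not present in VCF header: {', '.join(missing)}"
            )
        loci = []
        for rec in vf:
            loci.append(_locus_from_record(rec, samples))
    loci.sort(key=lambda l: (l.chrom, l.pos))
    return GenotypeMatrix(tuple(loci), samples, dict(group_assignment))


def _locus_from_record(rec, samples: Sequence[str]) -> VariantLocus:
    alts = tuple(a for a in (rec.alts or ()) if a != ".")
    alleles = (rec.ref,) + alts
    genotypes: dict[str, Call] = {}
    for sample in samples:
        gt = rec.samples[sample].get("GT", (None,))
        if gt is None or all(idx is None for idx in gt):
            genotypes[sample] = None
            continue
        if len(gt) != 2 or any(idx is None for idx in gt):
            raise DataError(
                f"{rec.chrom}:{rec.pos}: sample {sample} genotype {gt} is not a "
                f"diploid call"
            )
        try:
            a, b = alleles[gt[0]], alleles[gt[1]]
        except IndexError:
            raise DataError(
                f"{rec.chrom}:{rec.pos}: sample {sample} genotype index outside "
                f"REF/ALT list"
            ) from None
        genotypes[sample] = make_call(a, b)
    site_stats = {}
    present = set(rec.info.keys())
    for key in ("FS", "QD", "MQ", "SOR"):
        if key not in present:
            continue
        value = rec.info[key]
        site_stats[key] = float(value[0] if isinstance(value, tuple) else value)
    return VariantLocus(
        chrom=rec.chrom,
        pos=rec.pos,
        ref_base=rec.ref,
        alt_bases=alts,
        genotypes=genotypes,
        site_stats=site_stats,
    )


def write_vcf(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write a :class:`GenotypeMatrix` as an uncompressed VCF 4.2 file.

    Round-trips exactly with :func:`parse_vcf` (loci, calls, site stats);
    the group partition travels separately (see :func:`write_groups`).
    """
    header = pysam.VariantHeader()
    for chrom in dict.fromkeys(l.chrom for l in matrix.loci):
        header.contigs.add(chrom)
    for key, desc in (
        ("FS", "Phred-scaled p-value using Fisher's exact test for strand bias"),
        ("QD", "Variant confidence normalized by depth"),
        ("MQ", "RMS mapping quality"),
        ("SOR", "Symmetric odds ratio of strand bias"),
    ):
        header.info.add(key, 1, "Float", desc)
    header.formats.add("GT", 1, "String", "Genotype")
    for sample in matrix.sample_ids:
        header.add_sample(sample)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for locus in matrix.loci:
            alleles = (locus.ref_base,) + locus.alt_bases
            index = {base: i for i, base in enumerate(alleles)}
            rec = out.new_record(
                contig=locus.chrom,
                start=locus.pos - 1,
                alleles=alleles if len(alleles) > 1 else (locus.ref_base, "."),
            )
            for key, value in locus.site_stats.items():
                rec.info[key] = value
            for sample in matrix.sample_ids:
                call = locus.genotypes[sample]
                if call is None:
                    rec.samples[sample]["GT"] = (None, None)
                else:
                    rec.samples[sample]["GT"] = (index[call[0]], index[call[1]])
            out.write(rec)


def read_groups(path: str | Path) -> dict[str, str]:
    """Read a two-column (sample, group) tab-separated file."""
    assignment: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise DataError(f"{path}:{lineno}: expected 2 tab-separated fields")
            sample, group = fields
            if sample in assignment:
                raise DataError(f"{path}:{lineno}: duplicate sample {sample!r}")
            assignment[sample] = group
    return assignment


def write_groups(group_assignment: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#sample\tgroup\n")
        for sample, group in group_assignment.items():
            fh.write(f"{sample}\t{group}\n")


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------

def parse_gene_models(
    path: str | Path,
    dialect: str = "gff3",
    id_attribute: Optional[str] = None,
) -> list[GeneModel]:
    """Read gene features from GFF3 or GTF into :class:`GeneModel` records.

    Parameters
    ----------
    dialect
        ``"gff3"`` or ``"gtf"``.
    id_attribute
        Attribute holding the stable gene identifier. Defaults to ``ID``
        for GFF3 and ``gene_id`` for GTF; exposed because annotation
        sources differ in which attribute carries the stable id.
    """
    import gffutils

    if dialect not in ("gff3", "gtf"):
        raise ConfigurationError(f"unknown gene-model dialect {dialect!r}")
    if id_attribute is None:
        id_attribute = "ID" if dialect == "gff3" else "gene_id"
    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    genes = []
    for feature in db.features_of_type("gene"):
        values = feature.attributes.get(id_attribute)
        gene_id = values[0] if values else feature.id
        strand = feature.strand if feature.strand in ("+", "-") else "unknown"
        genes.append(
            GeneModel(
                gene_id=gene_id,
                chrom=feature.seqid,
                start=feature.start,
                end=feature.end,
                strand=strand,
            )
        )
    seen: dict[str, int] = {}
    for gene in genes:
        seen[gene.gene_id] = seen.get(gene.gene_id, 0) + 1
    duplicates = sorted(g for g, n in seen.items() if n > 1)
    if duplicates:
        raise DataError(f"duplicate gene ids: {', '.join(duplicates)}")
    return genes


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def parse_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: name, description (discarded), members...

    Duplicate member ids within a set are collapsed; duplicate set names
    are an error. An empty file yields an empty collection.
    """
    sets: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataError(
                    f"{path}:{lineno}: GMT lines need >= 3 tab-separated fields "
                    f"(name, description, members...)"
                )
            name = fields[0]
            if name in sets:
                raise DataError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            sets[name] = frozenset(m for m in fields[2:] if m)
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in collection.names():
            members = "\t".join(sorted(collection[name]))
            fh.write(f"{name}\tna\t{members}\n")


# ---------------------------------------------------------------------------
# Differential-expression tables
# ---------------------------------------------------------------------------

DEFAULT_DE_COLUMNS = {
    "gene_id": "gene_id",
    "log2fc": "logFC",
    "pvalue": "PValue",
    "fdr": "FDR",
    "chrom": "chrom",
}


def read_de_table(
    path: str | Path,
    column_map: Optional[Mapping[str, str]] = None,
    sep: str = "\t",
) -> list[DeGene]:
    """Read an edgeR-style differential-expression results table.

    ``column_map`` maps the logical names ``gene_id``, ``log2fc``,
    ``pvalue``, ``fdr`` (and optionally ``chrom``) to the file's column
    headers. p-values (and FDRs) of exactly 0 are clamped to the smallest
    positive double so the downstream -log10 ranking statistic is defined;
    each clamp is logged.
    """
    column_map = dict(DEFAULT_DE_COLUMNS, **(column_map or {}))
    df = pd.read_csv(path, sep=sep, comment="#")
    required = ["gene_id", "log2fc", "pvalue", "fdr"]
    for logical in required:
        if column_map[logical] not in df.columns:
            raise ConfigurationError(
                f"DE table {path} lacks mapped column {column_map[logical]!r} "
                f"(for {logical})"
            )
    chrom_col = column_map.get("chrom")
    has_chrom = chrom_col is not None and chrom_col in df.columns
    ids = df[column_map["gene_id"]].astype(str)
    dup = sorted(ids[ids.duplicated()].unique())
    if dup:
        raise DataError(f"duplicate gene ids in DE table: {', '.join(dup)}")
    genes = []
    n_clamped = 0
    for idx, row in df.iterrows():
        numeric = {}
        for logical in ("log2fc", "pvalue", "fdr"):
            raw = row[column_map[logical]]
            try:
                numeric[logical] = float(raw)
            except (TypeError, ValueError):
                raise DataError(
                    f"DE table row {idx}: cannot parse {logical} value {raw!r}"
                ) from None
            if logical in ("pvalue", "fdr") and numeric[logical] == 0.0:
                numeric[logical] = P_VALUE_CLAMP
                n_clamped += 1
        genes.append(
            DeGene(
                gene_id=str(row[column_map["gene_id"]]),
                log2fc=numeric["log2fc"],
                pvalue=numeric["pvalue"],
                fdr=numeric["fdr"],
                chrom=str(row[chrom_col]) if has_chrom else None,
            )
        )
    if n_clamped:
        logger.warning(
            "clamped %d zero p-values/FDRs to %.3e", n_clamped, P_VALUE_CLAMP
        )
    return genes


# ---------------------------------------------------------------------------
# dartk table output
# ---------------------------------------------------------------------------

def write_table(
    df: pd.DataFrame, path: str | Path, comments: Iterable[str] = ()
) -> None:
    """Write a DataFrame as TSV with '#'-prefixed comment header lines."""
    with open(path, "w") as fh:
        for line in comments:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_regions_bed(regions: Sequence[SmoothedDarRegion], path: str | Path) -> None:
    """Export smoothed regions as BED.

    This is the single place coordinates leave the 1-based inclusive
    convention: BED is 0-based half-open, so start shifts by -1.
    """
    with open(path, "w") as fh:
        fh.write("# BED export: 0-based half-open (converted from 1-based inclusive)\n")
        for region in regions:
            fh.write(
                f"{region.chrom}\t{region.region_start - 1}\t{region.region_end}\t"
                f"dar={region.smoothed_dar:.6g};origin={region.origin_pos};"
                f"n={region.window_n}\n"
            )
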