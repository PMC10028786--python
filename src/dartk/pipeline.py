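"""Compose the pipeline stages into one reproducible run.

filter -> DAR -> smooth -> gene-assign -> {sweep, weight} -> GSEA ->
chromosome enrichment, with every intermediate written as a TSV and a
machine-readable manifest (input checksums, parameters, seed, version).
Identical config + inputs give byte-identical output bundles: nothing
time- or host-dependent is written, and every stochastic step takes the
configured seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd
import yaml

from . import __version__
from .enrichment import (
    chromosome_enrichment,
    dar_weight_ranks,
    preranked_gsea,
    ranking_statistic,
    threshold_sweep,
)
from .filters import FilterThresholds, apply_all_filters
from .io import (
    parse_gene_models,
    parse_gmt,
    parse_vcf,
    read_de_table,
    read_groups,
    write_table,
)
from .metric import compute_dar_track, count_group_alleles, dar_raw
from .profiles import assign_gene_dar, smooth_dar
from .types import ConfigurationError, GenotypeMatrix

logger = logging.getLogger(__name__)

_THRESHOLD_FIELDS = (
    "fs_max", "qd_min", "mq_min", "sor_max",
    "cluster_max_snps", "cluster_window_bp", "missing_frac_max",
)


@dataclass
class RunConfig:
    """Everything a full pipeline run needs; every CLI flag has a twin here."""

    vcf: str
    groups: str
    gene_models: str
    de_table: str
    gmt: str
    outdir: str
    gene_models_dialect: str = "gff3"
    id_attribute: Optional[str] = None
    de_columns: dict = field(default_factory=dict)
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    half_width: int = 5
    sweep_thresholds: tuple = tuple(round(0.1 * k, 1) for k in range(1, 11))
    n_perm: int = 10000
    seed: int = 0
    min_size: int = 5
    max_size: int = 500
    de_alpha: float = 0.05
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a flat-key YAML config; config values win over overrides
        (logged when they conflict)."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        threshold_kwargs = {
            k: raw.pop(k) for k in list(raw) if k in _THRESHOLD_FIELDS
        }
        for key, value in overrides.items():
            if value is None:
                continue
            if key in raw and raw[key] != value:
                logger.warning(
                    "config value %s=%r overrides flag value %r",
                    key, raw[key], value,
                )
            else:
                raw.setdefault(key, value)
        if "sweep_thresholds" in raw:
            raw["sweep_thresholds"] = tuple(raw["sweep_thresholds"])
        config = cls(**raw)
        if threshold_kwargs:
            config.thresholds = FilterThresholds(**threshold_kwargs)
        return config

    def validate(self) -> None:
        for name in ("vcf", "groups", "gene_models", "de_table", "gmt"):
            path = getattr(self, name)
            if not Path(path).exists():
                raise ConfigurationError(f"{name} path does not exist: {path}")


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def dar_track_table(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Raw-DAR table with per-group called-sample counts."""
    g1, g2 = matrix.group_names
    samples1, samples2 = matrix.group_samples(g1), matrix.group_samples(g2)
    rows = []
    for locus in matrix.loci:
        prof1 = count_group_alleles(locus, samples1, g1)
        prof2 = count_group_alleles(locus, samples2, g2)
        p1, p2 = prof1.proportions, prof2.proportions
        if p1 is None or p2 is None:
            continue
        rows.append(
            {
                "chrom": locus.chrom, "pos": locus.pos,
                "n_called_g1": prof1.n_called, "n_called_g2": prof2.n_called,
                "dar": dar_raw(p1, p2),
            }
        )
    return pd.DataFrame(rows, columns=["chrom", "pos", "n_called_g1",
                                       "n_called_g2", "dar"])


def _setup_logging(outdir: Path, level: str) -> list[logging.Handler]:
    # plain format: timestamps would break byte-identical reruns
    fmt = logging.Formatter("%(levelname)s %(name)s: %(message)s")
    handlers: list[logging.Handler] = [
        logging.FileHandler(outdir / "run.log", mode="w"),
        logging.StreamHandler(sys.stderr),
    ]
    root = logging.getLogger("dartk")
    root.setLevel(level.upper())
    for handler in handlers:
        handler.setFormatter(fmt)
        root.addHandler(handler)
    return handlers


def run_dar_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute every stage and write the output bundle.

    Returns a map from table name to output path. Any stage error halts
    the run; the exception names the stage and offending record.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handlers = _setup_logging(outdir, config.log_level)
    try:
        return _run(config, outdir)
    finally:
        for handler in handlers:
            logging.getLogger("dartk").removeHandler(handler)
            handler.close()


def _run(config: RunConfig, outdir: Path) -> dict[str, Path]:
    out: dict[str, Path] = {}

    groups = read_groups(config.groups)
    matrix = parse_vcf(config.vcf, groups)
    logger.info("parsed %d loci, %d samples", len(matrix), len(matrix.sample_ids))

    filtered, report = apply_all_filters(matrix, config.thresholds)
    logger.info("filters retained %d of %d loci", len(filtered), len(matrix))
    rej_df = pd.DataFrame(
        [{"chrom": r.chrom, "pos": r.pos, "reasons": ",".join(r.reasons)}
         for r in report.rejections],
        columns=["chrom", "pos", "reasons"],
    )
    out["filter_rejections"] = outdir / "filter_rejections.tsv"
    write_table(rej_df, out["filter_rejections"],
                [f"dartk {__version__} filter rejection report"])

    raw_df = dar_track_table(filtered)
    out["dar_raw"] = outdir / "dar_raw.tsv"
    write_table(raw_df, out["dar_raw"], [f"dartk {__version__} raw DAR track"])

    track = compute_dar_track(filtered)
    regions = smooth_dar(track, config.half_width)
    smooth_df = pd.DataFrame(
        [{"chrom": r.chrom, "region_start": r.region_start,
          "region_end": r.region_end, "origin_pos": r.origin_pos,
          "smoothed_dar": r.smoothed_dar, "window_n": r.window_n}
         for r in regions],
        columns=["chrom", "region_start", "region_end", "origin_pos",
                 "smoothed_dar", "window_n"],
    )
    out["dar_smoothed"] = outdir / "dar_smoothed.tsv"
    write_table(smooth_df, out["dar_smoothed"],
                [f"dartk {__version__} elastic-window smoothed DAR "
                 f"(half_width={config.half_width})"])

    genes = parse_gene_models(config.gene_models, config.gene_models_dialect,
                              config.id_attribute)
    assignments = assign_gene_dar(genes, regions)
    gene_df = pd.DataFrame(
        [{"gene_id": a.gene_id,
          "dar": "NA" if a.dar is None else a.dar,
          "n_regions": a.n_regions}
         for a in assignments],
        columns=["gene_id", "dar", "n_regions"],
    )
    out["gene_dar"] = outdir / "gene_dar.tsv"
    write_table(gene_df, out["gene_dar"],
                [f"dartk {__version__} gene-level DAR assignment"])

    de = read_de_table(config.de_table, config.de_columns)
    ranked = ranking_statistic(de)
    weighted = dar_weight_ranks(ranked, assignments)
    rank_df = pd.DataFrame(
        [{"gene_id": r.gene_id, "stat": r.stat, "weighted_stat": r.weighted_stat}
         for r in weighted],
        columns=["gene_id", "stat", "weighted_stat"],
    )
    out["gene_ranks"] = outdir / "gene_ranks.tsv"
    write_table(rank_df, out["gene_ranks"],
                [f"dartk {__version__} ranking statistics "
                 f"(stat = sign(log2FC) * -log10 p; weighted = stat * (1 - DAR))"])

    de_flagged = frozenset(g.gene_id for g in de if g.fdr < config.de_alpha)
    sweep = threshold_sweep([g.gene_id for g in de], assignments, de_flagged,
                            config.sweep_thresholds)
    sweep_df = pd.DataFrame(
        [{"threshold": p.threshold, "n_retained": len(p.retained),
          "n_excluded": len(p.excluded), "n_de_removed": p.n_de_removed,
          "n_non_de_removed": p.n_non_de_removed}
         for p in sweep],
        columns=["threshold", "n_retained", "n_excluded", "n_de_removed",
                 "n_non_de_removed"],
    )
    out["sweep"] = outdir / "sweep.tsv"
    write_table(sweep_df, out["sweep"],
                [f"dartk {__version__} DAR exclusion-threshold sweep"])

    sets = parse_gmt(config.gmt)
    for label, use_weighted in (("unweighted", False), ("weighted", True)):
        results = preranked_gsea(
            weighted, sets, n_perm=config.n_perm, seed=config.seed,
            use_weighted=use_weighted, min_size=config.min_size,
            max_size=config.max_size,
        )
        gsea_df = pd.DataFrame(
            [{"set_name": r.set_name, "es": r.es, "nes": r.nes,
              "pvalue": r.pvalue, "fdr": r.fdr,
              "n_members_used": r.n_members_used,
              "leading_edge": ",".join(r.leading_edge)}
             for r in results],
            columns=["set_name", "es", "nes", "pvalue", "fdr",
                     "n_members_used", "leading_edge"],
        )
        out[f"gsea_{label}"] = outdir / f"gsea_{label}.tsv"
        write_table(gsea_df, out[f"gsea_{label}"],
                    [f"dartk {__version__} preranked GSEA ({label}, "
                     f"n_perm={config.n_perm}, seed={config.seed})"])

    enrich = chromosome_enrichment(de, genes, alpha=config.de_alpha)
    enrich_df = pd.DataFrame(
        [{"chrom": r.chrom, "de_on": r.table[0], "notde_on": r.table[1],
          "de_off": r.table[2], "notde_off": r.table[3],
          "p_raw": r.p_raw, "p_bonferroni": r.p_bonferroni}
         for r in enrich],
        columns=["chrom", "de_on", "notde_on", "de_off", "notde_off",
                 "p_raw", "p_bonferroni"],
    )
    out["chrom_enrichment"] = outdir / "chrom_enrichment.tsv"
    write_table(enrich_df, out["chrom_enrichment"],
                [f"dartk {__version__} chromosomal DE-gene enrichment "
                 f"(one-sided Fisher, Bonferroni over chromosomes)"])

    manifest = {
        "dartk_version": __version__,
        "inputs": {
            name: {"path": str(getattr(config, name)),
                   "sha256": _sha256(getattr(config, name))}
            for name in ("vcf", "groups", "gene_models", "de_table", "gmt")
        },
        "parameters": {
            "thresholds": {k: getattr(config.thresholds, k)
                           for k in _THRESHOLD_FIELDS},
            "half_width": config.half_width,
            "sweep_thresholds": list(config.sweep_thresholds),
            "n_perm": config.n_perm,
            "seed": config.seed,
            "min_size": config.min_size,
            "max_size": config.max_size,
            "de_alpha": config.de_alpha,
        },
    }
    out["manifest"] = outdir / "manifest.json"
    with open(out["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out
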