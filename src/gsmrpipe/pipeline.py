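"""End-to-end driver: simulate/ingest -> split -> GRM -> MLMA -> meta -> GSMR.

The pipeline mirrors a split-cohort summary-statistics MR study: each trait
is analysed as a mixed-model GWAS in two equal cohorts, the cohorts are
combined by double genomic-control meta-analysis, exposure instruments are
LD-clumped, and each exposure-outcome pair is estimated by GSMR with HEIDI
filtering at a per-exposure threshold of 0.05 / SNP_INDEX.  Surviving IVs
are optionally annotated against a gene table.  Typed per-pair failures
(under-powered clumping, non-estimable fits) are recorded in the result
bundle and do not abort the remaining pairs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .assoc import bonferroni_threshold, mlma_scan
from .genemap import DEFAULT_WINDOW_BP, annotate_ivs
from .metastat import meta_combine
from .mrcore import (
    DEFAULT_CLUMP_R2,
    DEFAULT_HEIDI_P,
    DEFAULT_MIN_SNPS,
    LdMatrix,
    NonEstimableError,
    UnderpoweredError,
    gsmr_fit,
    ld_clump,
)
from .relatedness import build_grm, reml_univariate
from .simdata import SimConfig, simulate_genotypes, simulate_traits, split_cohorts

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Parameters of one pipeline run.

    Either ``genotype_prefix``/``phenotype_paths`` point at existing data,
    or ``sim`` describes a synthetic cohort to generate in place.
    """

    sim: SimConfig | None = None
    genotype_prefix: str | None = None
    phenotype_paths: dict[str, str] = field(default_factory=dict)
    gene_table: str | None = None
    exposures: tuple[str, ...] = ("exposure",)
    outcomes: tuple[str, ...] = ("outcome",)
    gwas_p: float | None = None       # None -> 0.05 / number of SNPs tested
    clump_r2: float = DEFAULT_CLUMP_R2
    min_snps: int = DEFAULT_MIN_SNPS
    heidi_p: float = DEFAULT_HEIDI_P
    window_bp: int = DEFAULT_WINDOW_BP
    split_seed: int = 1

    def validate(self) -> None:
        if self.sim is None and self.genotype_prefix is None:
            raise ValueError("either sim or genotype_prefix must be provided")
        for name, lo, hi in (("clump_r2", 0.0, 1.0), ("heidi_p", 0.0, 1.0)):
            v = getattr(self, name)
            if not (lo < v < hi):
                raise ValueError(f"{name} must lie in ({lo}, {hi}), got {v}")
        if self.gwas_p is not None and not (0.0 < self.gwas_p < 1.0):
            raise ValueError("gwas_p must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("sim", None)
        cfg = cls(sim=SimConfig(**sim) if sim else None, **{
            k: tuple(v) if k in ("exposures", "outcomes") else v for k, v in raw.items()
        })
        return cfg


@dataclass
class PairOutcome:
    exposure: str
    outcome: str
    status: str                   # "ok" | "not_testable" | "non_estimable"
    detail: str = ""
    result: object | None = None


@dataclass
class RunResult:
    manifest: dict
    meta_tables: dict             # trait -> meta-analysed summary stats
    gsmr_table: pd.DataFrame
    pairs: list[PairOutcome]
    gene_hits: pd.DataFrame | None
    truth: object | None = None

    @property
    def manifest_hash(self) -> str:
        return self.manifest["hash"]


def _manifest(config: PipelineConfig, counts: dict) -> dict:
    payload = {
        "package": "gsmrpipe",
        "version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "config": json.loads(json.dumps(dataclasses.asdict(config), default=str)),
        "stage_counts": counts,
    }
    digest = hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    payload["hash"] = digest
    return payload


def write_table(df: pd.DataFrame, path: str | Path, manifest_hash: str) -> None:
    """TSV with a leading ``# manifest: <hash>`` comment line."""
    with open(path, "w") as fh:
        fh.write(f"# manifest: {manifest_hash}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def run_pipeline(config: PipelineConfig) -> RunResult:
    """Execute every stage; returns the result bundle with its manifest."""
    config.validate()
    counts: dict[str, int] = {}

    # stage 1: ingest or simulate
    truth = None
    if config.sim is not None:
        panel = simulate_genotypes(config.sim)
        phenos, truth = simulate_traits(panel, config.sim)
    else:
        from .io import read_phenotype, read_plink

        panel = read_plink(config.genotype_prefix, maf_filter=0.01)
        phenos = pd.DataFrame(
            {name: read_phenotype(p, name) for name, p in config.phenotype_paths.items()}
        )
    counts["genotypes"] = panel.n_snps
    counts["samples"] = panel.n_samples
    traits = list(dict.fromkeys([*config.exposures, *config.outcomes]))

    # stage 2: split + GRM per cohort (autosomal SNPs only)
    cohorts = split_cohorts(panel, phenos, config.split_seed)
    grms = [build_grm(cp) for cp, _ in cohorts]
    counts["grm_snps"] = grms[0].n_snps_used

    # stage 3: MLMA per cohort per trait, then double-GC meta-analysis
    meta_tables = {}
    for trait in traits:
        tabs = []
        for k, ((cpanel, cphen), grm) in enumerate(zip(cohorts, grms), start=1):
            vc = reml_univariate(grm, cphen[trait])
            tabs.append(mlma_scan(cpanel, cphen[trait], grm, varcomp=vc,
                                  trait_name=trait, cohort=f"cohort{k}"))
        meta_tables[trait] = meta_combine(tabs)
    counts["meta_snps"] = len(next(iter(meta_tables.values())))
    gwas_p = config.gwas_p if config.gwas_p is not None else bonferroni_threshold(counts["meta_snps"])

    # stage 4: clump per exposure, GSMR + HEIDI per pair
    pairs: list[PairOutcome] = []
    rows = []
    iv_rows = []
    for exp in config.exposures:
        try:
            iv_set = ld_clump(meta_tables[exp], panel, p_threshold=gwas_p,
                              r2_threshold=config.clump_r2, min_snps=config.min_snps)
            ld = LdMatrix.from_panel(panel, iv_set)
        except UnderpoweredError as err:
            for outc in config.outcomes:
                pairs.append(PairOutcome(exp, outc, "not_testable", str(err)))
            continue
        for outc in config.outcomes:
            if outc == exp:
                continue
            try:
                res = gsmr_fit(meta_tables[exp], meta_tables[outc], iv_set, ld,
                               heidi_threshold=config.heidi_p,
                               exposure=exp, outcome=outc)
            except NonEstimableError as err:
                pairs.append(PairOutcome(exp, outc, "non_estimable", str(err)))
                continue
            pairs.append(PairOutcome(exp, outc, "ok", result=res))
            rows.append({
                "Exposure": exp, "Outcome": outc, "bxy": res.bxy, "se": res.se_bxy,
                "p": res.p_gsmr, "nsnp": res.snp_gsmr, "snp_index": res.snp_index,
                "p_threshold": res.p_threshold, "significant": res.significant,
            })
            for sid in res.iv_ids:
                iv_rows.append({"SNP": sid, "exposure": exp, "outcome": outc})
    gsmr_table = pd.DataFrame(
        rows, columns=["Exposure", "Outcome", "bxy", "se", "p", "nsnp",
                       "snp_index", "p_threshold", "significant"],
    )
    counts["gsmr_pairs"] = len(gsmr_table)

    # stage 5: gene-window annotation of surviving IVs
    gene_hits = None
    if iv_rows:
        ivs = pd.DataFrame(iv_rows).merge(
            panel.markers[["id", "chrom", "bp"]].rename(
                columns={"id": "SNP", "chrom": "Chr"}),
            on="SNP", how="left",
        )
        if config.gene_table is not None:
            from .io import read_genes

            gene_hits = annotate_ivs(ivs, read_genes(config.gene_table), config.window_bp)
            counts["gene_hits"] = len(gene_hits)
        else:
            gene_hits = None
    counts.setdefault("gene_hits", 0)

    manifest = _manifest(config, counts)
    logger.info("pipeline complete: %s", counts)
    return RunResult(manifest=manifest, meta_tables=meta_tables, gsmr_table=gsmr_table,
                     pairs=pairs, gene_hits=gene_hits, truth=truth)
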