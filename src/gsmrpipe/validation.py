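"""Reference validation runs: parameter recovery and calibration measurements.

These routines run the package's own machinery under the study conditions
the analysis is designed for and report the recovered quantities.  They back
both the validation test-suite and the reproduction script in ``scripts/``.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .metastat import CHI2_MEDIAN_1DF
from .mrcore import LdMatrix, NonEstimableError, gsmr_fit, gsmr_threshold
from .pipeline import PipelineConfig, run_pipeline
from .relatedness import build_grm, reml_bivariate, reml_univariate
from .simdata import (
    SimConfig,
    simulate_correlated_traits,
    simulate_genotypes,
    simulate_summary_pair,
)


def gsmr_recovery_run(seed: int) -> dict:
    """One full-pipeline run at the reference conditions (n = 10,000
    individuals, 5,000 SNPs, 50 exposure-causal SNPs, h2_x = 0.3,
    b_xy = 0.4, 5 pleiotropic SNPs)."""
    cfg = PipelineConfig(sim=replace(SimConfig(), seed=seed))
    result = run_pipeline(cfg)
    ok = [p.result for p in result.pairs if p.status == "ok"]
    if not ok:
        raise NonEstimableError(
            f"pipeline produced no estimable pair: {[p.detail for p in result.pairs]}"
        )
    res = ok[0]
    pleio = set(result.truth.pleiotropic["id"])
    candidates = set(res.per_iv["SNP"])
    return {
        "bxy": res.bxy,
        "se": res.se_bxy,
        "abs_error_in_se": abs(res.bxy - result.truth.b_xy_true) / res.se_bxy,
        "b_xy_true": result.truth.b_xy_true,
        "snp_index": res.snp_index,
        "snp_gsmr": res.snp_gsmr,
        "significant": res.significant,
        "pleio_candidates": len(pleio & candidates),
        "pleio_removed": len(pleio & set(res.removed_ids)),
        "false_removed": len(set(res.removed_ids) - pleio),
        "n": cfg.sim.n_individuals,
    }


def heidi_detection_rate(seed: int, n_replicates: int = 20, panel=None) -> dict:
    """Fraction of planted pleiotropic instruments removed by HEIDI over
    seeded summary-level replicates at the reference effect scales."""
    if panel is None:
        panel = _reference_panel(seed)
    planted = removed = 0
    rng = np.random.default_rng(seed)
    for rep in range(n_replicates):
        exp, out, pleio = simulate_summary_pair(
            panel, b_xy=0.4, n_pleiotropic=5, pleio_effect_sd=0.1,
            seed=int(rng.integers(2**31)),
        )
        ids = list(exp["SNP"])
        res = gsmr_fit(exp, out, ids, LdMatrix.identity(ids))
        planted += len(pleio)
        removed += len(set(pleio) & set(res.removed_ids))
    return {"rate": removed / planted, "planted": planted, "removed": removed,
            "n": n_replicates}


def type_one_error_rate(seed: int, n_replicates: int = 200, panel=None) -> dict:
    """Fraction of null (b_xy = 0, no pleiotropy) exposure-outcome pairs
    declared significant at 0.05 / SNP_INDEX."""
    if panel is None:
        panel = _reference_panel(seed)
    rng = np.random.default_rng(seed + 1)
    significant = tested = 0
    for rep in range(n_replicates):
        exp, out, _ = simulate_summary_pair(
            panel, b_xy=0.0, n_pleiotropic=0, seed=int(rng.integers(2**31)),
        )
        ids = list(exp["SNP"])
        try:
            res = gsmr_fit(exp, out, ids, LdMatrix.identity(ids))
        except NonEstimableError:
            continue
        tested += 1
        if res.p_gsmr < gsmr_threshold(res.snp_index):
            significant += 1
    return {"rate": significant / tested, "tested": tested, "n": n_replicates}


def greml_recovery(seed: int, n: int = 4000, m: int = 2000) -> dict:
    """Univariate h2 = 0.3 and bivariate r_G = 0.5 recovery (with and
    without the residual covariance) at n individuals, m SNPs."""
    n_chrom = 4
    cfg = SimConfig(
        n_individuals=n, n_chromosomes=n_chrom,
        snps_per_chrom=int(np.ceil(m / n_chrom)),
        h2_exposure=0.3, n_causal_exposure=100, n_pleiotropic=0, seed=seed,
    )
    panel = simulate_genotypes(cfg)
    traits = simulate_correlated_traits(panel, 0.3, 0.3, 0.5, 100, seed=seed + 1)
    grm = build_grm(panel)
    uni = reml_univariate(grm, traits["trait1"])
    biv = reml_bivariate(grm, traits["trait1"], traits["trait2"])
    biv0 = reml_bivariate(grm, traits["trait1"], traits["trait2"],
                          drop_residual_cov=True)
    return {
        "h2": uni.h2, "h2_se": uni.se_h2,
        "rg": biv.r_g, "rg_se": biv.se_rg,
        "rg_nocov": biv0.r_g, "rg_nocov_se": biv0.se_rg,
        "converged": uni.converged and biv.converged and biv0.converged,
        "n": n,
    }


def null_lambda(seed: int, n: int = 800, m: int = 5000) -> dict:
    """Genomic inflation of a mixed-model scan on a pure-noise trait."""
    import pandas as pd

    from .assoc import mlma_scan

    n_chrom = 2
    cfg = SimConfig(
        n_individuals=n, n_chromosomes=n_chrom,
        snps_per_chrom=int(np.ceil(m / n_chrom)), ld_rho=0.0,
        maf_range=(0.05, 0.5), n_causal_exposure=5, n_pleiotropic=0, seed=seed,
    )
    panel = simulate_genotypes(cfg)
    grm = build_grm(panel)
    trait = pd.Series(np.random.default_rng(seed + 1).standard_normal(panel.n_samples),
                      index=panel.samples)
    table = mlma_scan(panel, trait, grm)
    lam = float(np.median(table["z"] ** 2) / CHI2_MEDIAN_1DF)
    return {"lambda": lam, "n_snps": len(table), "n": n}


def _reference_panel(seed: int):
    """A modest LD reference for summary-level replicates."""
    cfg = SimConfig(n_individuals=2000, n_chromosomes=4, snps_per_chrom=250,
                    n_causal_exposure=10, n_pleiotropic=0, seed=seed + 17)
    return simulate_genotypes(cfg)
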