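"""Mixed-linear-model single-SNP association (MLMA).

Each SNP is tested as a fixed effect in ``y = 1 mu + x b + g + e`` with the
polygenic effect ``g ~ N(0, A sigma2_g)`` structured by a (typically
autosomal) GRM.  Variance components are estimated once on the null model
(no SNP) and held fixed; each SNP is then fit by generalised least squares
under ``V = A sigma2_g + I sigma2_e`` and tested with a Wald chi-square on
one degree of freedom.  The candidate SNP is not excluded from the GRM
(plain MLMA; no leave-one-chromosome-out), and SNPs absent from the GRM
(e.g. X-chromosome markers against an autosomal GRM) are still tested.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .relatedness import Grm, VarComp, reml_univariate
from .simdata import GenotypePanel

logger = logging.getLogger(__name__)

#: column order of the association table (GCTA .mlma layout plus n)
MLMA_COLUMNS = ["Chr", "SNP", "bp", "A1", "A2", "Freq", "b", "se", "z", "p", "n"]


def mlma_scan(
    panel: GenotypePanel,
    trait: pd.Series,
    grm: Grm,
    varcomp: VarComp | None = None,
    trait_name: str = "trait",
    cohort: str = "cohort1",
) -> pd.DataFrame:
    """Scan every SNP of ``panel`` against ``trait`` under the mixed model.

    ``varcomp`` may carry pre-estimated null-model components; otherwise
    they are fit here by REML.  Monomorphic SNPs are skipped (logged) and
    absent from the output.  Returns a DataFrame in :data:`MLMA_COLUMNS`
    order with ``attrs['trait']`` and ``attrs['cohort']`` set.
    """
    trait = trait.dropna()
    common = [s for s in panel.samples if s in trait.index]
    if len(common) < panel.n_samples:
        keep = np.array([s in set(common) for s in panel.samples])
        panel = panel.subset_samples(np.flatnonzero(keep))
    y = trait.loc[panel.samples].to_numpy(dtype=np.float64)
    if varcomp is None:
        varcomp = reml_univariate(grm, trait)
    if list(grm.sample_ids) != list(panel.samples):
        grm = grm.subset(list(panel.samples))
    d, U = grm.eig()
    v = varcomp.sigma2_g * d + varcomp.sigma2_e
    w = 1.0 / v

    freq = panel.dosages.mean(axis=0) / 2.0
    poly = (freq > 0.0) & (freq < 1.0)
    n_mono = int((~poly).sum())
    if n_mono:
        logger.info("mlma_scan: skipping %d monomorphic SNPs", n_mono)

    ys = U.T @ y
    ones = U.T @ np.ones(y.size)
    Xs = U.T @ panel.dosages[:, poly].astype(np.float64)

    sw = np.sum(w)
    swo = w * ones
    sw_oo = np.sum(ones * swo)
    sw_oy = np.sum(ys * swo)
    # weighted regression of y on [1, x] per SNP, V held fixed (known)
    sw_ox = swo @ Xs
    sw_xx = np.einsum("ij,i,ij->j", Xs, w, Xs)
    sw_xy = (w * ys) @ Xs
    sxx = sw_xx - sw_ox**2 / sw_oo
    sxy = sw_xy - sw_ox * sw_oy / sw_oo
    with np.errstate(divide="ignore", invalid="ignore"):
        b = sxy / sxx
        se = np.sqrt(1.0 / sxx)
    z = b / se
    p = chi2.sf(z**2, df=1)

    mk = panel.markers.loc[poly].reset_index(drop=True)
    out = pd.DataFrame(
        {
            "Chr": mk["chrom"], "SNP": mk["id"], "bp": mk["bp"],
            "A1": mk["a1"], "A2": mk["a2"], "Freq": freq[poly],
            "b": b, "se": se, "z": z, "p": np.clip(p, np.nextafter(0, 1), 1.0),
            "n": y.size,
        }
    )
    out.attrs["trait"] = trait_name
    out.attrs["cohort"] = cohort
    out.attrs["varcomp"] = varcomp
    return out


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    """Genome-wide significance threshold ``alpha / n_tests``."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def significant_hits(table: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Rows with ``p < threshold``; the count is logged."""
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    hits = table[table["p"] < threshold].reset_index(drop=True)
    logger.info("significant_hits: %d of %d SNPs below p = %.3g", len(hits), len(table), threshold)
    hits.attrs.update(table.attrs)
    return hits
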