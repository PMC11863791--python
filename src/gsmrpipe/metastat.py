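"""Sample-size-weighted Z-score meta-analysis with double genomic control.

Two split-cohort association tables are combined METAL-style: per-cohort Z
statistics are genomic-control corrected (inflation factor capped at one,
i.e. statistics are deflated only when lambda > 1), sign-aligned to a common
effect allele and combined as ``z_meta = sum(w_k z_k) / sqrt(sum(w_k^2))``
with ``w_k = sqrt(n_k)``.  The combined statistic is genomic-control
corrected a second time.  Meta Z-scores are then transformed back to an
allelic effect in phenotype-SD units via

    b_zx = z / sqrt(2 p (1 - p) (n + z^2)),   se = 1 / sqrt(2 p (1 - p) (n + z^2))

so that b/se reproduces z exactly.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import chi2

logger = logging.getLogger(__name__)

#: median of the chi-square distribution with 1 df (lambda denominator)
CHI2_MEDIAN_1DF = 0.4549364

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def genomic_control(z: np.ndarray) -> tuple[np.ndarray, float]:
    """Capped genomic-control correction of a Z-statistic vector.

    lambda = median(z^2) / 0.4549364.  When lambda > 1 statistics are
    divided by sqrt(lambda) so the corrected set has lambda = 1; deflated
    sets (lambda <= 1) pass through unchanged.  Returns (z, lambda).
    """
    z = np.asarray(z, dtype=np.float64)
    if z.size < 10:
        raise ValueError("genomic control needs at least 10 statistics")
    lam = float(np.median(z**2) / CHI2_MEDIAN_1DF)
    if lam > 1.0:
        z = z / np.sqrt(lam)
    return z, lam


def _orient(a1, a2, ref1, ref2) -> float:
    """Sign to align alleles (a1, a2) to reference orientation; nan = drop."""
    ambiguous = {a1, a2} in ({"A", "T"}, {"C", "G"})
    if (a1, a2) == (ref1, ref2):
        return 1.0
    if (a1, a2) == (ref2, ref1):
        return np.nan if ambiguous else -1.0
    if ambiguous:
        return np.nan
    c1, c2 = _COMPLEMENT.get(a1), _COMPLEMENT.get(a2)
    if (c1, c2) == (ref1, ref2):
        return 1.0
    if (c1, c2) == (ref2, ref1):
        return -1.0
    return np.nan


def z_to_beta(z, freq, n) -> tuple[np.ndarray, np.ndarray]:
    """Back-transform a Z-score to (b, se) in phenotype-SD units."""
    z = np.asarray(z, dtype=np.float64)
    freq = np.asarray(freq, dtype=np.float64)
    n = np.asarray(n, dtype=np.float64)
    if np.any((freq <= 0.0) | (freq >= 1.0)):
        raise ValueError("allele frequency must lie strictly in (0, 1)")
    if np.any(n <= 0):
        raise ValueError("sample size must be positive")
    denom = np.sqrt(2.0 * freq * (1.0 - freq) * (n + z**2))
    return z / denom, 1.0 / denom


def meta_combine(cohort_tables: list[pd.DataFrame], gc: bool = True) -> pd.DataFrame:
    """Two-stage sample-size-weighted meta-analysis of cohort tables.

    Stage 1 applies genomic control within each cohort and combines the
    aligned Z-scores; stage 2 re-applies genomic control to the combined
    statistic.  SNPs whose alleles cannot be reconciled with the first
    cohort's orientation (including strand-ambiguous A/T and C/G markers in
    non-matching orientation) are dropped with a log message.  The output
    carries b_zx/se_zx from :func:`z_to_beta`, an n-weighted combined allele
    frequency, and the per-stage lambda estimates in ``attrs``.
    """
    if not cohort_tables:
        raise ValueError("need at least one cohort table")
    ref = cohort_tables[0]
    lam1 = []
    aligned = []
    for k, tab in enumerate(cohort_tables):
        t = tab.set_index("SNP")
        t = t.loc[t.index.intersection(ref["SNP"])]
        z = (t["b"] / t["se"]).to_numpy()
        if gc:
            z, lam = genomic_control(z)
        else:
            lam = float(np.median(z**2) / CHI2_MEDIAN_1DF)
        lam1.append(lam)
        t = t.assign(z_gc=z)
        aligned.append(t)
    base = aligned[0]
    snps = base.index
    for t in aligned[1:]:
        snps = snps.intersection(t.index)
    base = base.loc[snps]

    num = np.zeros(len(snps))
    den = 0.0
    freq_num = np.zeros(len(snps))
    n_tot = np.zeros(len(snps))
    n_dropped = 0
    keep = np.ones(len(snps), dtype=bool)
    for t in aligned:
        t = t.loc[snps]
        signs = np.array([
            _orient(a1, a2, r1, r2)
            for a1, a2, r1, r2 in zip(t["A1"], t["A2"], base["A1"], base["A2"])
        ])
        bad = np.isnan(signs)
        n_dropped += int(bad.sum())
        keep &= ~bad
        signs = np.where(bad, 0.0, signs)
        n_k = t["n"].to_numpy(dtype=float)
        w = np.sqrt(n_k)
        num += w * signs * t["z_gc"].to_numpy()
        den += n_k  # sum of w^2; scalar if n constant, else accumulate vector
        f = t["Freq"].to_numpy(dtype=float)
        freq_num += n_k * np.where(signs < 0, 1.0 - f, f)
        n_tot += n_k
    if n_dropped:
        logger.info("meta_combine: dropped %d SNP-cohort records with irreconcilable alleles", n_dropped)
    z_meta = num / np.sqrt(den)
    lam2 = float(np.median(z_meta[keep] ** 2) / CHI2_MEDIAN_1DF)
    if gc and lam2 > 1.0:
        z_meta = z_meta / np.sqrt(lam2)
    freq = freq_num / n_tot
    b, se = z_to_beta(z_meta[keep], freq[keep], n_tot[keep])
    out = pd.DataFrame(
        {
            "SNP": snps[keep],
            "Chr": base.loc[keep, "Chr"].to_numpy(),
            "bp": base.loc[keep, "bp"].to_numpy(),
            "A1": base.loc[keep, "A1"].to_numpy(),
            "A2": base.loc[keep, "A2"].to_numpy(),
            "freq": freq[keep],
            "z": z_meta[keep],
            "p": np.clip(chi2.sf(z_meta[keep] ** 2, df=1), np.nextafter(0, 1), 1.0),
            "b": b,
            "se": se,
            "n": n_tot[keep],
        }
    )
    out.attrs["lambda_stage1"] = lam1
    out.attrs["lambda_stage2"] = lam2
    out.attrs.update({k: v for k, v in cohort_tables[0].attrs.items() if k == "trait"})
    return out.reset_index(drop=True)
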