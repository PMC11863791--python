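"""GSMR: LD clumping, generalised-least-squares causal estimation and HEIDI.

Two-sample summary-data Mendelian randomisation.  Genome-wide significant,
quasi-independent SNPs (instrumental variables, IVs) for an exposure are
selected by greedy LD clumping against a reference genotype panel.  Each
IV's ratio estimate ``b_xy(i) = b_zy(i) / b_zx(i)`` is an estimate of the
causal effect of the exposure on the outcome; the overall effect combines
the per-IV ratios by generalised least squares under
``b_xy ~ N(b_xy 1, V)`` where V is the delta-method variance-covariance of
the ratios including the LD correlation between IVs:

    var(b_xy(i))   = se_zy_i^2 / b_zx_i^2 + b_zy_i^2 se_zx_i^2 / b_zx_i^4
    cov(b_xy(i,j)) = r_ij * [ se_zy_i se_zy_j / (b_zx_i b_zx_j)
                              + b_zy_i b_zy_j se_zx_i se_zx_j / (b_zx_i^2 b_zx_j^2) ]

Horizontally pleiotropic IVs violate the constant-ratio assumption and are
removed beforehand by the HEIDI (heterogeneity in dependent instruments)
filter: the ratio distribution is ordered and a reference "top" SNP chosen
as the most strongly exposure-associated member of its third quintile (the
band around the median ratio — the globally strongest SNP is avoided in
case it is itself pleiotropic, and the tails of the ratio distribution are
where pleiotropic instruments live); every other IV is then tested on
``d_i = b_xy(i) - b_xy(top)`` with a chi-square(1) Wald statistic.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .simdata import GenotypePanel

logger = logging.getLogger(__name__)

DEFAULT_GWAS_P = 1.11e-6      # 0.05 / 44,994 tests on the reference panel size
DEFAULT_CLUMP_R2 = 0.05
DEFAULT_MIN_SNPS = 10
DEFAULT_HEIDI_P = 0.01
WEAK_Z_THRESHOLD = 2.0        # |b_zx|/se_zx below this -> ratio variance explodes


class UnderpoweredError(RuntimeError):
    """Too few index SNPs survive clumping: the pair is not testable."""


class NonEstimableError(RuntimeError):
    """Fewer than three IVs survive filtering: no GSMR estimate."""


@dataclass
class LdMatrix:
    """Pairwise dosage correlation r between a list of SNPs."""

    r: np.ndarray
    snp_ids: list[str]

    @classmethod
    def from_panel(cls, panel: GenotypePanel, snp_ids: list[str]) -> "LdMatrix":
        pos = {s: i for i, s in enumerate(panel.markers["id"])}
        idx = [pos[s] for s in snp_ids]
        X = panel.dosages[:, idx].astype(np.float64)
        r = np.corrcoef(X, rowvar=False)
        r = np.atleast_2d(r)
        np.fill_diagonal(r, 1.0)
        return cls(r=r, snp_ids=list(snp_ids))

    @classmethod
    def identity(cls, snp_ids: list[str]) -> "LdMatrix":
        return cls(r=np.eye(len(snp_ids)), snp_ids=list(snp_ids))

    def subset(self, snp_ids: list[str]) -> "LdMatrix":
        pos = {s: i for i, s in enumerate(self.snp_ids)}
        idx = [pos[s] for s in snp_ids]
        return LdMatrix(self.r[np.ix_(idx, idx)], list(snp_ids))


@dataclass
class GsmrResult:
    exposure: str
    outcome: str
    bxy: float
    se_bxy: float
    p_gsmr: float
    snp_index: int                      # clumped candidate IV count
    iv_ids: list[str]                   # surviving IVs (SNP_GSMR)
    removed_ids: list[str]              # HEIDI-flagged pleiotropic IVs
    per_iv: pd.DataFrame                # id, bxy_i, var_i, p_zx, kept
    significant: bool
    p_threshold: float

    @property
    def snp_gsmr(self) -> int:
        return len(self.iv_ids)


def ld_clump(
    exposure_stats: pd.DataFrame,
    reference_panel: GenotypePanel,
    p_threshold: float = DEFAULT_GWAS_P,
    r2_threshold: float = DEFAULT_CLUMP_R2,
    min_snps: int = DEFAULT_MIN_SNPS,
) -> list[str]:
    """Greedy LD clumping of genome-wide significant SNPs.

    The lowest-p candidate becomes an index SNP and removes all remaining
    candidates with r^2 above ``r2_threshold`` against it on the same
    chromosome; this repeats until the candidate list is exhausted.  Raises
    :class:`UnderpoweredError` when fewer than ``min_snps`` index SNPs
    remain.
    """
    cand = exposure_stats[exposure_stats["p"] < p_threshold]
    cand = cand.sort_values(["p", "SNP"], kind="mergesort")
    index_snps: list[str] = []
    by_chrom = {c: g for c, g in cand.groupby("Chr")}
    for chrom, grp in by_chrom.items():
        ids = grp["SNP"].tolist()
        if not ids:
            continue
        ld = LdMatrix.from_panel(reference_panel, ids)
        alive = np.ones(len(ids), dtype=bool)
        for i in range(len(ids)):          # rows already ordered by p
            if not alive[i]:
                continue
            index_snps.append(ids[i])
            alive &= ld.r[i] ** 2 <= r2_threshold
            alive[i] = False
    if len(index_snps) < min_snps:
        raise UnderpoweredError(
            f"only {len(index_snps)} index SNPs at p < {p_threshold:g}, "
            f"r2 <= {r2_threshold} (minimum {min_snps}); pair not testable"
        )
    order = {s: i for i, s in enumerate(exposure_stats["SNP"])}
    return sorted(index_snps, key=lambda s: order[s])


def _third_quintile_top(bxy_i: np.ndarray, p_zx: np.ndarray, ids: list[str]) -> int:
    """Index of the reference (top) SNP for HEIDI.

    The per-IV ratios are ordered and the third quintile of the b_xy
    distribution taken — positions strictly above 0.4k and at most
    ceil(0.6k) of the sorted list, i.e. the band around the median ratio.
    A pleiotropic instrument sits in the tails of the ratio distribution,
    so this band avoids anointing one as the reference.  Within the band
    the SNP with the strongest exposure association (smallest p_zx, ties
    broken by marker ID) becomes the top SNP.
    """
    k = len(ids)
    order = sorted(range(k), key=lambda i: (bxy_i[i], ids[i]))
    lo = math.floor(0.4 * k)              # positions r with r > 0.4k
    hi = math.ceil(0.6 * k)               # and r <= ceil(0.6k)
    band = order[lo:hi]
    if not band:
        band = [order[min(k - 1, max(0, round(0.5 * k) - 1))]]
    return min(band, key=lambda i: (p_zx[i], ids[i]))


def ratio_covariance(
    b_zx: np.ndarray,
    se_zx: np.ndarray,
    b_zy: np.ndarray,
    se_zy: np.ndarray,
    ld_r: np.ndarray,
) -> np.ndarray:
    """Delta-method variance-covariance matrix V of the per-IV ratios."""
    t1 = np.outer(se_zy / b_zx, se_zy / b_zx)
    t2 = np.outer(b_zy * se_zx / b_zx**2, b_zy * se_zx / b_zx**2)
    return ld_r * (t1 + t2)


def heidi_filter(
    bxy_i: np.ndarray,
    V: np.ndarray,
    p_zx: np.ndarray,
    ids: list[str],
    threshold: float = DEFAULT_HEIDI_P,
) -> tuple[list[int], list[int], int]:
    """Single-pass HEIDI outlier removal.

    Tests ``d_i = b_xy(i) - b_xy(top)`` with
    ``var(d_i) = V_ii + V_tt - 2 V_it`` against chi-square(1); IVs with
    ``p_HEIDI < threshold`` are removed.  Returns (kept, removed, top)
    positional indices; the top SNP is always kept.
    """
    k = len(ids)
    if k < 3:
        raise NonEstimableError(f"HEIDI needs >= 3 IVs, got {k}")
    top = _third_quintile_top(np.asarray(bxy_i, dtype=float), np.asarray(p_zx, dtype=float), ids)
    d = bxy_i - bxy_i[top]
    var_d = np.diag(V) + V[top, top] - 2.0 * V[:, top]
    var_d = np.maximum(var_d, 1e-300)
    with np.errstate(divide="ignore", invalid="ignore"):
        p_heidi = chi2.sf(d**2 / var_d, df=1)
    p_heidi[top] = 1.0
    removed = [i for i in range(k) if p_heidi[i] < threshold]
    kept = [i for i in range(k) if i not in removed]
    if not kept or len(kept) < 1:
        raise NonEstimableError("HEIDI removed every IV")
    return kept, removed, top


def gsmr_threshold(snp_index: int) -> float:
    """Per-exposure significance threshold 0.05 / SNP_INDEX."""
    if snp_index < 1:
        raise ValueError("snp_index must be >= 1")
    return 0.05 / snp_index


def _align_outcome(exp: pd.DataFrame, out: pd.DataFrame) -> pd.DataFrame:
    """Flip the outcome table's effects onto the exposure's effect alleles."""
    out = out.set_index("SNP").loc[exp["SNP"]].reset_index()
    swapped = (out["A1"].to_numpy() == exp["A2"].to_numpy()) & (
        out["A2"].to_numpy() == exp["A1"].to_numpy()
    )
    matched = (out["A1"].to_numpy() == exp["A1"].to_numpy()) & (
        out["A2"].to_numpy() == exp["A2"].to_numpy()
    )
    if not np.all(matched | swapped):
        bad = out.loc[~(matched | swapped), "SNP"].tolist()
        raise ValueError(f"alleles irreconcilable between tables for {bad}")
    out.loc[swapped, "b"] = -out.loc[swapped, "b"]
    if "freq" in out.columns:
        out.loc[swapped, "freq"] = 1.0 - out.loc[swapped, "freq"]
    return out


def gsmr_fit(
    exposure_stats: pd.DataFrame,
    outcome_stats: pd.DataFrame,
    iv_set: list[str],
    ld: LdMatrix,
    heidi_threshold: float = DEFAULT_HEIDI_P,
    snp_index: int | None = None,
    exposure: str = "exposure",
    outcome: str = "outcome",
    weak_z: float = WEAK_Z_THRESHOLD,
) -> GsmrResult:
    """GSMR causal-effect estimate for one exposure-outcome pair.

    Per-IV ratios are formed from allele-aligned summary statistics, HEIDI
    removes pleiotropic outliers, and the survivors are combined by GLS:
    ``b_xy = (1' V^-1 b) / (1' V^-1 1)`` with ``se^2 = 1 / (1' V^-1 1)``
    and a Wald chi-square(1) p-value.  ``significant`` compares p_GSMR with
    ``0.05 / snp_index`` (``snp_index`` defaults to ``len(iv_set)``).
    """
    snp_index = len(iv_set) if snp_index is None else snp_index
    exp = exposure_stats.set_index("SNP").loc[iv_set].reset_index()
    out = _align_outcome(exp, outcome_stats)

    strength = np.abs(exp["b"].to_numpy() / exp["se"].to_numpy())
    weak = strength < weak_z
    if weak.any():
        logger.info("gsmr_fit: refusing %d weak instruments (|z_zx| < %g)", int(weak.sum()), weak_z)
        exp, out = exp.loc[~weak].reset_index(drop=True), out.loc[~weak].reset_index(drop=True)
    ids = exp["SNP"].tolist()
    if len(ids) < 3:
        raise NonEstimableError(f"only {len(ids)} usable IVs after the weak-instrument guard")
    ldm = ld.subset(ids)

    b_zx, se_zx = exp["b"].to_numpy(float), exp["se"].to_numpy(float)
    b_zy, se_zy = out["b"].to_numpy(float), out["se"].to_numpy(float)
    bxy_i = b_zy / b_zx
    V = ratio_covariance(b_zx, se_zx, b_zy, se_zy, ldm.r)
    kept, removed, top = heidi_filter(bxy_i, V, exp["p"].to_numpy(float), ids, heidi_threshold)
    if len(kept) < 3:
        raise NonEstimableError(f"only {len(kept)} IVs survive HEIDI filtering")

    Vk = V[np.ix_(kept, kept)]
    bk = bxy_i[kept]
    ones = np.ones(len(kept))
    try:
        Vi_b = np.linalg.solve(Vk, bk)
        Vi_1 = np.linalg.solve(Vk, ones)
    except np.linalg.LinAlgError:
        ridge = 1e-8 * float(np.trace(Vk)) / len(kept)
        logger.warning("gsmr_fit: singular V, ridge-regularising with %g", ridge)
        Vk = Vk + ridge * np.eye(len(kept))
        Vi_b = np.linalg.solve(Vk, bk)
        Vi_1 = np.linalg.solve(Vk, ones)
    denom = float(ones @ Vi_1)
    bxy = float(ones @ Vi_b) / denom
    se_bxy = float(np.sqrt(1.0 / denom))
    p_gsmr = float(np.clip(chi2.sf((bxy / se_bxy) ** 2, df=1), np.nextafter(0, 1), 1.0))
    p_thr = gsmr_threshold(snp_index)

    per_iv = pd.DataFrame(
        {
            "SNP": ids,
            "bxy_i": bxy_i,
            "var_i": np.diag(V),
            "p_zx": exp["p"].to_numpy(float),
            "kept": [i in kept for i in range(len(ids))],
            "is_top": [i == top for i in range(len(ids))],
        }
    )
    return GsmrResult(
        exposure=exposure, outcome=outcome, bxy=bxy, se_bxy=se_bxy, p_gsmr=p_gsmr,
        snp_index=snp_index,
        iv_ids=[ids[i] for i in kept],
        removed_ids=[ids[i] for i in removed],
        per_iv=per_iv, significant=p_gsmr < p_thr, p_threshold=p_thr,
    )
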