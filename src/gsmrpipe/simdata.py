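"""Synthetic genotype/phenotype cohorts with known causal structure.

The generator emulates a medium-density SNP-array dataset for a single
livestock population: biallelic SNPs laid out in LD blocks along autosomes
plus one X chromosome, and continuous, pre-corrected (deregressed-proof-like)
traits with a polygenic background.  An exposure trait carries a set of
causal SNPs; an outcome trait receives the exposure's effect through a true
mediated coefficient ``b_xy`` plus a handful of horizontally pleiotropic
SNPs that act on the outcome directly.  Every planted effect is returned in
a truth record so downstream estimates can be checked against ground truth.

LD model
--------
Within a block all SNPs share one allele frequency ``p`` and haplotype
alleles follow a first-order Markov "copying" chain: allele ``j+1`` equals
allele ``j`` with probability ``ld_rho`` and is otherwise a fresh
Bernoulli(p) draw.  This keeps the marginal frequency exact and gives an
adjacent-SNP haplotype correlation of exactly ``ld_rho``; blocks are
mutually independent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: nucleotide pairs used when assigning marker alleles (both strands possible)
_BASES = np.array(list("ACGT"))


class ConfigError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic cohort.

    Defaults describe the reference study conditions used throughout the
    test-suite: 10,000 individuals, 5,000 SNPs (9 autosomes + X, 500 SNPs
    each), 50 exposure-causal SNPs, exposure heritability 0.3, a true
    mediated effect of 0.4 and 5 horizontally pleiotropic SNPs.
    """

    n_individuals: int = 10_000
    n_chromosomes: int = 9          # autosomes; one X chromosome is appended
    snps_per_chrom: int = 500
    maf_range: tuple[float, float] = (0.01, 0.5)
    ld_block_size: int = 20
    ld_rho: float = 0.7
    h2_exposure: float = 0.3
    h2_outcome: float = 0.1
    n_causal_exposure: int = 50
    b_xy_true: float = 0.4
    n_pleiotropic: int = 5
    pleio_effect_sd: float = 0.1    # per standardized-genotype direct effect SD
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo < hi < 1.0):
            raise ConfigError(f"maf_range must satisfy 0 < low < high < 1, got {self.maf_range}")
        for name in ("h2_exposure", "h2_outcome"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if not (0.0 <= self.ld_rho < 1.0):
            raise ConfigError(f"ld_rho must lie in [0, 1), got {self.ld_rho}")
        if self.n_individuals < 1 or self.n_chromosomes < 1 or self.snps_per_chrom < 1:
            raise ConfigError("counts must be positive")
        if self.ld_block_size < 1:
            raise ConfigError("ld_block_size must be positive")
        total = (self.n_chromosomes + 1) * self.snps_per_chrom
        if self.n_causal_exposure + self.n_pleiotropic > total:
            raise ConfigError(
                f"n_causal_exposure + n_pleiotropic = "
                f"{self.n_causal_exposure + self.n_pleiotropic} exceeds SNP count {total}"
            )


@dataclass
class GenotypePanel:
    """An n-individuals x m-markers dosage matrix with its marker map.

    ``dosages[i, j]`` counts copies of allele A1 of marker ``j`` in
    individual ``i`` (0, 1 or 2).  ``markers`` has columns
    ``id, chrom, bp, a1, a2, freq`` with 1-based, strictly increasing ``bp``
    within each chromosome; ``freq`` is the empirical A1 frequency.
    ``x_chrom`` is the integer chromosome code flagged as X (or None).
    """

    dosages: np.ndarray
    markers: pd.DataFrame
    samples: list[str]
    x_chrom: int | None = None

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def autosomal_mask(self) -> np.ndarray:
        if self.x_chrom is None:
            return np.ones(self.n_snps, dtype=bool)
        return (self.markers["chrom"] != self.x_chrom).to_numpy()

    def subset_samples(self, idx: np.ndarray) -> "GenotypePanel":
        return GenotypePanel(
            dosages=self.dosages[idx],
            markers=self.markers.copy(),
            samples=[self.samples[i] for i in idx],
            x_chrom=self.x_chrom,
        )

    def subset_snps(self, mask: np.ndarray) -> "GenotypePanel":
        return GenotypePanel(
            dosages=self.dosages[:, mask],
            markers=self.markers.loc[mask].reset_index(drop=True),
            samples=list(self.samples),
            x_chrom=self.x_chrom,
        )


@dataclass
class TruthRecord:
    """Planted ground truth of one simulated trait pair."""

    b_xy_true: float
    exposure_causal: pd.DataFrame   # columns: id, effect (per standardized genotype)
    outcome_causal: pd.DataFrame
    pleiotropic: pd.DataFrame       # columns: id, exposure_effect, direct_effect

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for _, r in self.exposure_causal.iterrows():
            rows.append((r["id"], "exposure_causal", r["effect"], 0.0))
        for _, r in self.outcome_causal.iterrows():
            rows.append((r["id"], "outcome_causal", r["effect"], 0.0))
        for _, r in self.pleiotropic.iterrows():
            rows.append((r["id"], "pleiotropic", r["exposure_effect"], r["direct_effect"]))
        out = pd.DataFrame(rows, columns=["id", "role", "exposure_effect", "outcome_direct_effect"])
        out.attrs["b_xy_true"] = self.b_xy_true
        return out


def _simulate_chromosome(
    rng: np.random.Generator, n: int, m: int, chrom: int, cfg: SimConfig
) -> tuple[np.ndarray, pd.DataFrame]:
    """Dosages and marker map for one chromosome of ``m`` SNPs."""
    lo, hi = cfg.maf_range
    dos = np.empty((n, m), dtype=np.int8)
    n_hap = 2 * n
    pos = np.cumsum(rng.integers(500, 5000, size=m))
    freqs = np.empty(m)
    start = 0
    while start < m:
        size = min(cfg.ld_block_size, m - start)
        p = rng.uniform(lo, hi)
        hap = np.empty((n_hap, size), dtype=np.int8)
        hap[:, 0] = rng.random(n_hap) < p
        for j in range(1, size):
            fresh = (rng.random(n_hap) < p).astype(np.int8)
            copy = rng.random(n_hap) < cfg.ld_rho
            hap[:, j] = np.where(copy, hap[:, j - 1], fresh)
        dos[:, start:start + size] = hap[:n] + hap[n:]
        freqs[start:start + size] = p
        start += size
    a_idx = rng.integers(0, 4, size=m)
    b_idx = (a_idx + rng.integers(1, 4, size=m)) % 4
    markers = pd.DataFrame(
        {
            "id": [f"snp{chrom}_{j + 1}" for j in range(m)],
            "chrom": chrom,
            "bp": pos.astype(np.int64),
            "a1": _BASES[a_idx],
            "a2": _BASES[b_idx],
            "freq": dos.mean(axis=0) / 2.0,
        }
    )
    return dos, markers


def simulate_genotypes(config: SimConfig, min_maf: float = 0.01) -> GenotypePanel:
    """Generate a block-LD genotype panel; deterministic given ``config.seed``.

    Autosomes 1..n_chromosomes each carry ``snps_per_chrom`` SNPs, as does
    one X chromosome (code ``n_chromosomes + 1``).  After generation the
    panel is re-filtered at empirical MAF >= ``min_maf``, mirroring the
    array-data QC the analysis assumes.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_individuals
    blocks, maps = [], []
    x_code = config.n_chromosomes + 1
    for chrom in range(1, x_code + 1):
        dos, markers = _simulate_chromosome(rng, n, config.snps_per_chrom, chrom, config)
        blocks.append(dos)
        maps.append(markers)
    panel = GenotypePanel(
        dosages=np.concatenate(blocks, axis=1),
        markers=pd.concat(maps, ignore_index=True),
        samples=[f"ind{i + 1}" for i in range(n)],
        x_chrom=x_code,
    )
    freq = panel.dosages.mean(axis=0) / 2.0
    panel.markers["freq"] = freq
    maf = np.minimum(freq, 1.0 - freq)
    keep = maf >= min_maf
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("MAF filter removed %d of %d SNPs (MAF < %g)", n_drop, panel.n_snps, min_maf)
        panel = panel.subset_snps(keep)
    return panel


def _standardized(dosages: np.ndarray) -> np.ndarray:
    p = dosages.mean(axis=0) / 2.0
    sd = np.sqrt(2.0 * p * (1.0 - p))
    return (dosages - 2.0 * p) / np.where(sd > 0, sd, 1.0)


def simulate_traits(
    panel: GenotypePanel, config: SimConfig, seed: int | None = None
) -> tuple[pd.DataFrame, TruthRecord]:
    """Simulate exposure/outcome traits on top of a genotype panel.

    exposure = genetic value (variance ``h2_exposure``) + residual, total
    variance ~= 1.  outcome = ``b_xy_true`` * exposure + a direct polygenic
    component of variance ``h2_outcome`` (disjoint causal set) + direct
    effects of ``n_pleiotropic`` SNPs + residual.  Pleiotropic SNPs also
    receive exposure effects, so they surface as instruments downstream.
    Causal and pleiotropic SNPs are drawn from autosomes only.

    Returns a phenotype table (index: sample ID; columns ``exposure``,
    ``outcome``) and the :class:`TruthRecord` of planted effects.
    """
    if panel.n_snps == 0 or panel.n_samples == 0:
        raise ValueError("panel must be nonempty")
    n_need = config.n_causal_exposure + config.n_pleiotropic
    auto = np.flatnonzero(panel.autosomal_mask())
    if n_need + config.n_causal_exposure > auto.size:
        raise ConfigError(
            f"requested {n_need} exposure + {config.n_causal_exposure} outcome causal SNPs "
            f"but only {auto.size} autosomal SNPs available"
        )
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    picks = rng.choice(auto, size=n_need + config.n_causal_exposure, replace=False)
    causal_x = picks[: config.n_causal_exposure]
    pleio = picks[config.n_causal_exposure: n_need]
    causal_y = picks[n_need:]
    ids = panel.markers["id"].to_numpy()
    n = panel.n_samples

    def polygenic(idx: np.ndarray, target_var: float) -> tuple[np.ndarray, np.ndarray]:
        if idx.size == 0 or target_var <= 0.0:
            return np.zeros(n), np.zeros(idx.size)
        Z = _standardized(panel.dosages[:, idx])
        u = rng.standard_normal(idx.size)
        g = Z @ u
        scale = np.sqrt(target_var / g.var()) if g.var() > 0 else 0.0
        return g * scale, u * scale

    g_x, eff_x = polygenic(np.concatenate([causal_x, pleio]), config.h2_exposure)
    exposure = g_x + rng.standard_normal(n) * np.sqrt(max(1.0 - config.h2_exposure, 0.0))

    g_y, eff_y = polygenic(causal_y, config.h2_outcome)
    if pleio.size:
        Zp = _standardized(panel.dosages[:, pleio])
        # fixed magnitude, random sign: every planted pleiotropic SNP carries
        # a controlled direct effect, so the planted-outlier detection rate
        # measures the filter rather than the luck of a Gaussian draw
        delta = rng.choice([-1.0, 1.0], size=pleio.size) * config.pleio_effect_sd
        g_p = Zp @ delta
    else:
        delta = np.zeros(0)
        g_p = np.zeros(n)
    resid_var = max(
        1.0 - config.b_xy_true ** 2 - config.h2_outcome - config.pleio_effect_sd ** 2 * pleio.size,
        0.05,
    )
    outcome = config.b_xy_true * exposure + g_y + g_p + rng.standard_normal(n) * np.sqrt(resid_var)

    phenos = pd.DataFrame({"exposure": exposure, "outcome": outcome}, index=panel.samples)
    phenos.index.name = "iid"
    k = config.n_causal_exposure
    truth = TruthRecord(
        b_xy_true=config.b_xy_true,
        exposure_causal=pd.DataFrame({"id": ids[causal_x], "effect": eff_x[:k]}),
        outcome_causal=pd.DataFrame({"id": ids[causal_y], "effect": eff_y}),
        pleiotropic=pd.DataFrame(
            {"id": ids[pleio], "exposure_effect": eff_x[k:], "direct_effect": delta}
        ),
    )
    return phenos, truth


def simulate_correlated_traits(
    panel: GenotypePanel,
    h2_1: float,
    h2_2: float,
    r_g: float,
    n_causal: int,
    seed: int,
    names: tuple[str, str] = ("trait1", "trait2"),
) -> pd.DataFrame:
    """Two traits with a controlled genetic correlation.

    A shared causal set receives per-SNP effect pairs drawn from a bivariate
    normal with correlation ``r_g``; each trait's genetic value is scaled to
    its heritability and completed with independent residuals (unit total
    variance).  Used to validate bivariate variance-component estimation.
    """
    rng = np.random.default_rng(seed)
    auto = np.flatnonzero(panel.autosomal_mask())
    if n_causal > auto.size:
        raise ConfigError(f"n_causal={n_causal} exceeds {auto.size} autosomal SNPs")
    idx = rng.choice(auto, size=n_causal, replace=False)
    Z = _standardized(panel.dosages[:, idx])
    L = np.linalg.cholesky(np.array([[1.0, r_g], [r_g, 1.0]]))
    U = rng.standard_normal((n_causal, 2)) @ L.T
    out = {}
    for k, (name, h2) in enumerate(zip(names, (h2_1, h2_2))):
        gk = Z @ U[:, k]
        gk *= np.sqrt(h2 / gk.var()) if gk.var() > 0 else 0.0
        out[name] = gk + rng.standard_normal(panel.n_samples) * np.sqrt(max(1.0 - h2, 0.0))
    df = pd.DataFrame(out, index=panel.samples)
    df.index.name = "iid"
    return df


def simulate_summary_pair(
    panel: GenotypePanel,
    n_gwas: int = 10_000,
    n_instruments: int = 40,
    var_explained_range: tuple[float, float] = (0.003, 0.01),
    b_xy: float = 0.4,
    n_pleiotropic: int = 0,
    pleio_effect_sd: float = 0.1,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Summary statistics for one exposure-outcome pair at the IV level.

    Emulates what the GWAS + meta-analysis stages hand to the MR stage:
    ``n_instruments`` quasi-independent SNPs (one per LD block of the
    reference panel) with true standardized SNP-exposure effects of
    per-SNP variance explained drawn from ``var_explained_range``, sampling
    noise at GWAS size ``n_gwas``, and SNP-outcome effects mediated through
    ``b_xy`` except for ``n_pleiotropic`` planted SNPs that receive a direct
    outcome effect of magnitude ``pleio_effect_sd`` (random sign).

    Returns (exposure_stats, outcome_stats, pleiotropic_ids) in the column
    layout the MR stage consumes (SNP, Chr, bp, A1, A2, freq, b, se, p, n).
    """
    rng = np.random.default_rng(seed)
    mk = panel.markers
    auto = np.flatnonzero(panel.autosomal_mask())
    # one SNP per spaced stratum so instruments are quasi-independent
    strata = np.array_split(auto, n_instruments)
    idx = np.array([rng.choice(s) for s in strata if s.size])
    k = idx.size
    v = rng.uniform(*var_explained_range, size=k)
    b_zx = np.sqrt(v) * rng.choice([-1.0, 1.0], size=k)
    se = np.full(k, 1.0 / np.sqrt(n_gwas))
    b_zx_hat = b_zx + rng.standard_normal(k) * se
    pleio_pos = rng.choice(k, size=n_pleiotropic, replace=False) if n_pleiotropic else np.array([], int)
    delta = np.zeros(k)
    delta[pleio_pos] = rng.choice([-1.0, 1.0], size=pleio_pos.size) * pleio_effect_sd
    b_zy_hat = b_xy * b_zx + delta + rng.standard_normal(k) * se

    from scipy.stats import chi2 as _chi2

    def table(b_hat):
        z = b_hat / se
        return pd.DataFrame({
            "SNP": mk["id"].to_numpy()[idx],
            "Chr": mk["chrom"].to_numpy()[idx],
            "bp": mk["bp"].to_numpy()[idx],
            "A1": mk["a1"].to_numpy()[idx],
            "A2": mk["a2"].to_numpy()[idx],
            "freq": mk["freq"].to_numpy()[idx],
            "b": b_hat, "se": se,
            "p": np.clip(_chi2.sf(z**2, 1), np.nextafter(0, 1), 1.0),
            "n": n_gwas,
        })

    return table(b_zx_hat), table(b_zy_hat), list(mk["id"].to_numpy()[idx[pleio_pos]])


def split_cohorts(
    panel: GenotypePanel, phenos: pd.DataFrame, seed: int
) -> tuple[tuple[GenotypePanel, pd.DataFrame], tuple[GenotypePanel, pd.DataFrame]]:
    """Random disjoint half-split of samples (sizes differ by at most one).

    Deterministic given ``seed``; the union of the halves is the input.
    """
    n = panel.n_samples
    if n < 2:
        raise ValueError("need at least 2 samples to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    half = (n + 1) // 2
    idx1, idx2 = np.sort(perm[:half]), np.sort(perm[half:])
    out = []
    for idx in (idx1, idx2):
        sub = panel.subset_samples(idx)
        out.append((sub, phenos.loc[sub.samples]))
    return out[0], out[1]
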