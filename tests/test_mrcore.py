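"""LD clumping, GSMR estimation and HEIDI pleiotropy filtering."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2

from gsmrpipe import (
    LdMatrix,
    NonEstimableError,
    UnderpoweredError,
    gsmr_fit,
    gsmr_threshold,
    heidi_filter,
    ld_clump,
)
from gsmrpipe.mrcore import _third_quintile_top, ratio_covariance
from gsmrpipe.simdata import SimConfig, simulate_genotypes, simulate_summary_pair

from conftest import make_panel


@pytest.fixture(scope="module")
def ref_panel():
    cfg = SimConfig(n_individuals=2000, n_chromosomes=4, snps_per_chrom=250,
                    n_causal_exposure=10, n_pleiotropic=0, seed=29)
    return simulate_genotypes(cfg)


def _stats(panel, p_values, snp_idx=None):
    mk = panel.markers
    idx = np.arange(len(mk)) if snp_idx is None else np.asarray(snp_idx)
    p = np.asarray(p_values, dtype=float)
    z = np.sqrt(chi2.isf(p, 1))
    return pd.DataFrame({
        "SNP": mk["id"].to_numpy()[idx], "Chr": mk["chrom"].to_numpy()[idx],
        "bp": mk["bp"].to_numpy()[idx], "A1": mk["a1"].to_numpy()[idx],
        "A2": mk["a2"].to_numpy()[idx], "freq": mk["freq"].to_numpy()[idx],
        "b": z * 0.01, "se": 0.01, "p": p, "n": 10_000,
    })


def clump_bruteforce(stats, panel, p_thr, r2_thr):
    """Exhaustive greedy reference implementation."""
    cand = stats[stats["p"] < p_thr].sort_values(["p", "SNP"]).reset_index(drop=True)
    pos = {s: i for i, s in enumerate(panel.markers["id"])}
    chrom = dict(zip(stats["SNP"], stats["Chr"]))
    taken, alive = [], list(cand["SNP"])
    while alive:
        idx = alive[0]
        taken.append(idx)
        nxt = []
        for s in alive[1:]:
            if chrom[s] != chrom[idx]:
                nxt.append(s)
                continue
            x = panel.dosages[:, pos[idx]].astype(float)
            y = panel.dosages[:, pos[s]].astype(float)
            if np.corrcoef(x, y)[0, 1] ** 2 <= r2_thr:
                nxt.append(s)
        alive = nxt
    return set(taken)


class TestClumping:
    def test_independent_significant_snps_all_retained(self, ref_panel):
        # far-apart SNPs (different blocks) are essentially uncorrelated
        idx = np.arange(0, 1000, 50)
        p = np.full(idx.size, 1e-9)
        got = ld_clump(_stats(ref_panel, p, idx), ref_panel, min_snps=1)
        assert len(got) == idx.size

    def test_perfect_ld_pair_keeps_smaller_p(self):
        rng = np.random.default_rng(0)
        col = rng.integers(0, 3, size=500)
        panel = make_panel(np.column_stack([col, col]))
        stats = _stats(panel, [1e-8, 1e-12])
        got = ld_clump(stats, panel, min_snps=1)
        assert got == ["s1"]

    def test_matches_bruteforce_on_random_instance(self, ref_panel):
        rng = np.random.default_rng(33)
        idx = rng.choice(ref_panel.n_snps, size=200, replace=False)
        p = 10.0 ** rng.uniform(-12, -3, size=200)
        stats = _stats(ref_panel, p, idx)
        got = set(ld_clump(stats, ref_panel, p_threshold=1e-5, min_snps=1))
        assert got == clump_bruteforce(stats, ref_panel, 1e-5, 0.05)

    def test_underpowered_raises_typed_signal(self, ref_panel):
        stats = _stats(ref_panel, np.full(ref_panel.n_snps, 0.5))
        with pytest.raises(UnderpoweredError):
            ld_clump(stats, ref_panel, min_snps=10)


class TestGsmrFit:
    def _pair(self, b_zx, b_zy, se_zx=1e-4, se_zy=1e-4):
        k = len(b_zx)
        mk = dict(Chr=1, A1="A", A2="G", freq=0.3, n=10_000)
        exp = pd.DataFrame({"SNP": [f"s{j}" for j in range(k)], **mk,
                            "bp": np.arange(k), "b": b_zx, "se": se_zx,
                            "p": chi2.sf((np.array(b_zx) / se_zx) ** 2, 1)})
        out = exp.copy()
        out["b"], out["se"] = b_zy, se_zy
        out["p"] = chi2.sf((np.array(b_zy) / se_zy) ** 2, 1)
        return exp, out

    def test_exact_mediation_recovers_ratio(self):
        b_zx = np.array([0.05, 0.08, -0.06, 0.07, -0.09])
        exp, out = self._pair(b_zx, 0.5 * b_zx)
        res = gsmr_fit(exp, out, list(exp["SNP"]), LdMatrix.identity(list(exp["SNP"])))
        assert res.bxy == pytest.approx(0.5, abs=1e-10)
        assert res.removed_ids == []
        assert res.snp_index == 5

    def test_gls_matches_direct_linear_algebra(self):
        rng = np.random.default_rng(3)
        k = 5
        b_zx = rng.uniform(0.05, 0.1, k) * rng.choice([-1, 1], k)
        b_zy = 0.3 * b_zx + rng.normal(0, 0.01, k)
        se_zx = rng.uniform(0.005, 0.01, k)
        se_zy = rng.uniform(0.005, 0.01, k)
        R = np.eye(k)
        R[0, 1] = R[1, 0] = 0.2
        R[2, 3] = R[3, 2] = -0.15
        exp, out = self._pair(b_zx, b_zy, se_zx, se_zy)
        ids = list(exp["SNP"])
        res = gsmr_fit(exp, out, ids, LdMatrix(R, ids), heidi_threshold=0.0)
        ratios = b_zy / b_zx
        V = ratio_covariance(b_zx, se_zx, b_zy, se_zy, R)
        Vi = np.linalg.inv(V)
        ones = np.ones(k)
        expect = (ones @ Vi @ ratios) / (ones @ Vi @ ones)
        assert res.bxy == pytest.approx(expect, abs=1e-10)
        assert res.se_bxy == pytest.approx(np.sqrt(1 / (ones @ Vi @ ones)), abs=1e-10)

    def test_zero_ld_equals_inverse_variance_weighted_mean(self):
        rng = np.random.default_rng(4)
        k = 8
        b_zx = rng.uniform(0.05, 0.12, k)
        b_zy = 0.4 * b_zx + rng.normal(0, 0.005, k)
        se_zx = rng.uniform(0.004, 0.01, k)
        se_zy = rng.uniform(0.004, 0.01, k)
        exp, out = self._pair(b_zx, b_zy, se_zx, se_zy)
        ids = list(exp["SNP"])
        res = gsmr_fit(exp, out, ids, LdMatrix.identity(ids), heidi_threshold=0.0)
        w = 1.0 / np.diag(ratio_covariance(b_zx, se_zx, b_zy, se_zy, np.eye(k)))
        ivw = np.sum(w * b_zy / b_zx) / np.sum(w)
        assert res.bxy == pytest.approx(ivw, abs=1e-10)

    def test_allele_flip_invariance(self):
        rng = np.random.default_rng(5)
        k = 6
        b_zx = rng.uniform(0.05, 0.1, k)
        b_zy = 0.4 * b_zx + rng.normal(0, 0.005, k)
        exp, out = self._pair(b_zx, b_zy, se_zx=0.005, se_zy=0.005)
        ids = list(exp["SNP"])
        base = gsmr_fit(exp, out, ids, LdMatrix.identity(ids))
        flipped = out.copy()
        flipped[["A1", "A2"]] = flipped[["A2", "A1"]].to_numpy()
        flipped["b"] = -flipped["b"]
        flipped["freq"] = 1.0 - flipped["freq"]
        res = gsmr_fit(exp, flipped, ids, LdMatrix.identity(ids))
        assert res.bxy == pytest.approx(base.bxy, abs=1e-10)

    def test_weak_instruments_refused(self):
        exp, out = self._pair([0.001, 0.07, 0.08, 0.09], [0.0, 0.028, 0.032, 0.036],
                              se_zx=0.01, se_zy=0.01)
        res = gsmr_fit(exp, out, list(exp["SNP"]), LdMatrix.identity(list(exp["SNP"])))
        assert "s0" not in set(res.per_iv["SNP"])

    def test_end_to_end_recovery_at_summary_level(self, ref_panel):
        exp, out, _ = simulate_summary_pair(ref_panel, b_xy=0.4, seed=55)
        ids = list(exp["SNP"])
        res = gsmr_fit(exp, out, ids, LdMatrix.from_panel(ref_panel, ids))
        assert abs(res.bxy - 0.4) < 3 * res.se_bxy


class TestHeidi:
    def test_identical_ratios_remove_nothing(self):
        k = 7
        V = 0.01 * np.eye(k)
        kept, removed, _ = heidi_filter(np.full(k, 0.4), V,
                                        np.linspace(1e-10, 1e-6, k),
                                        [f"s{j}" for j in range(k)])
        assert removed == []
        assert len(kept) == k

    def test_top_snp_is_strongest_in_median_ratio_band(self):
        # 10 IVs: ratio order known; band = sorted positions 5..6;
        # top = the member with the smaller p_zx
        bxy = np.array([0.1, 0.2, 0.3, 0.35, 0.4, 0.45, 0.5, 0.6, 0.7, 0.8])
        p_zx = np.array([1e-30, 1e-8, 1e-9, 1e-10, 1e-20, 1e-12,
                         1e-11, 1e-7, 1e-6, 1e-5])
        ids = [f"s{j}" for j in range(10)]
        top = _third_quintile_top(bxy, p_zx, ids)
        assert top == 4          # positions 5-6 are ratios 0.4, 0.45; 0.4 has p 1e-20
        # the globally strongest instrument (position 1) is never the reference
        assert top != 0

    def test_planted_outlier_detection_rate(self, ref_panel):
        detected = 0
        total = 0
        for seed in range(200):
            exp, out, pleio = simulate_summary_pair(
                ref_panel, n_instruments=20, b_xy=0.4,
                n_pleiotropic=1, pleio_effect_sd=0.1, seed=1000 + seed)
            ids = list(exp["SNP"])
            res = gsmr_fit(exp, out, ids, LdMatrix.identity(ids))
            total += 1
            if set(pleio) <= set(res.removed_ids):
                detected += 1
        assert detected / total >= 0.9

    def test_heidi_reduces_bias_under_pleiotropy(self, ref_panel):
        better = 0
        for seed in range(100):
            exp, out, _ = simulate_summary_pair(
                ref_panel, b_xy=0.4,
                n_pleiotropic=5, pleio_effect_sd=0.1, seed=5000 + seed)
            ids = list(exp["SNP"])
            ld = LdMatrix.identity(ids)
            on = gsmr_fit(exp, out, ids, ld)
            off = gsmr_fit(exp, out, ids, ld, heidi_threshold=0.0)
            if abs(on.bxy - 0.4) <= abs(off.bxy - 0.4):
                better += 1
        assert better >= 80

    def test_all_removed_is_flagged(self):
        with pytest.raises(NonEstimableError):
            heidi_filter(np.array([0.4, 0.5]), np.eye(2), np.array([1e-9, 1e-8]),
                         ["a", "b"])


class TestThreshold:
    def test_printed_rule(self):
        assert gsmr_threshold(56) == pytest.approx(8.93e-4, rel=1e-3)
        assert gsmr_threshold(1) == 0.05
        with pytest.raises(ValueError):
            gsmr_threshold(0)
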