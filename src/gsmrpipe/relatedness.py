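"""Genomic relationship matrix and REML variance components.

The GRM between individuals j and k is the average over SNPs of
``(x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i))`` — the covariance of
allele-frequency-standardized dosages.  On top of it, restricted maximum
likelihood fits the mixed model ``y = 1 mu + g + e`` with
``g ~ N(0, A sigma2_g)`` and ``e ~ N(0, I sigma2_e)``; the SNP heritability
is ``h2 = sigma2_g / (sigma2_g + sigma2_e)``.  The bivariate model adds a
genetic covariance ``sigma_g12`` (and optionally a residual covariance
``sigma_e12``) and reports the genetic correlation
``r_G = sigma_g12 / sqrt(sigma2_g1 sigma2_g2)``.

Univariate fits profile the restricted likelihood down to a bounded 1-D
search over the heritability after a spectral decomposition of the GRM.
Bivariate fits run average-information (AI) REML with step-halving, so the
restricted log-likelihood is non-decreasing across iterations; when the
likelihood surface is problematic the residual covariance can be dropped
(``sigma_e12`` fixed at zero) and the fit retried.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
from scipy.optimize import minimize_scalar

from .simdata import GenotypePanel

logger = logging.getLogger(__name__)

_BOUND = 1e-8          # variance floor (components are truncated here)
_TOL = 1e-6            # |delta logL| convergence criterion
_MAX_ITER = 100


@dataclass
class Grm:
    """Genetic relationship matrix with a cached spectral decomposition."""

    matrix: np.ndarray
    sample_ids: list[str]
    n_snps_used: int
    _eig: tuple[np.ndarray, np.ndarray] | None = field(default=None, repr=False)

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def eig(self) -> tuple[np.ndarray, np.ndarray]:
        """Eigenvalues (ascending) and eigenvectors of the GRM, cached."""
        if self._eig is None:
            vals, vecs = scipy.linalg.eigh(self.matrix, driver="evd")
            self._eig = (np.maximum(vals, 0.0), vecs)
        return self._eig

    def subset(self, ids: list[str]) -> "Grm":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = np.array([pos[s] for s in ids])
        return Grm(self.matrix[np.ix_(idx, idx)], list(ids), self.n_snps_used)


@dataclass
class VarComp:
    """REML variance components; bivariate fields are None for univariate fits."""

    sigma2_g: float
    sigma2_e: float
    h2: float
    se_h2: float
    converged: bool
    n: int
    loglik: float
    # bivariate extras
    sigma2_g2: float | None = None
    sigma2_e2: float | None = None
    sigma_g12: float | None = None
    sigma_e12: float | None = None
    r_g: float | None = None
    se_rg: float | None = None
    residual_cov_dropped: bool = False
    n_iter: int = 0


def build_grm(panel: GenotypePanel, chrom_subset=None) -> Grm:
    """GRM from standardized dosages; by default autosomal SNPs only.

    ``chrom_subset`` may be an iterable of chromosome codes; monomorphic
    SNPs are skipped (count logged).
    """
    mask = panel.autosomal_mask() if chrom_subset is None else (
        panel.markers["chrom"].isin(list(chrom_subset)).to_numpy()
    )
    X = panel.dosages[:, mask].astype(np.float64)
    p = X.mean(axis=0) / 2.0
    poly = X.var(axis=0) > 0.0
    n_mono = int((~poly).sum())
    if n_mono:
        logger.info("build_grm: skipping %d monomorphic SNPs", n_mono)
        X = X[:, poly]
        p = p[poly]
    m = X.shape[1]
    if m == 0:
        raise ValueError("no polymorphic SNPs available for the GRM")
    W = (X - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    A = (W @ W.T) / m
    return Grm(matrix=A, sample_ids=list(panel.samples), n_snps_used=m)


def _align(grm: Grm, y: pd.Series) -> tuple[Grm, np.ndarray]:
    """Restrict the GRM and phenotype to their common samples, GRM order."""
    y = y.dropna()
    common = [s for s in grm.sample_ids if s in y.index]
    if len(common) < len(grm.sample_ids):
        grm = grm.subset(common)
    return grm, y.loc[common].to_numpy(dtype=np.float64)


# ---------------------------------------------------------------------------
# univariate REML


def _uni_profile_nll(h2: float, d: np.ndarray, ys: np.ndarray, t: np.ndarray) -> float:
    """Negative restricted log-likelihood profiled over total variance."""
    v = h2 * d + (1.0 - h2)
    w = 1.0 / v
    xtx = np.sum(t * t * w)
    beta = np.sum(t * ys * w) / xtx
    r2 = np.sum(ys * ys * w) - beta * beta * xtx
    nfree = d.size - 1
    s2 = r2 / nfree
    return 0.5 * (np.sum(np.log(v)) + np.log(xtx) + nfree * (np.log(s2) + 1.0))


def _uni_loglik(sg: float, se: float, d: np.ndarray, ys: np.ndarray, t: np.ndarray) -> float:
    """Restricted log-likelihood at explicit component values (for the SEs)."""
    v = sg * d + se
    w = 1.0 / v
    xtx = np.sum(t * t * w)
    beta = np.sum(t * ys * w) / xtx
    r2 = np.sum(ys * ys * w) - beta * beta * xtx
    return -0.5 * (np.sum(np.log(v)) + np.log(xtx) + r2)


def reml_univariate(grm: Grm, y: pd.Series) -> VarComp:
    """Fit ``y = 1 mu + g + e`` by REML via spectral decomposition.

    The likelihood is profiled to a 1-D search over h2; standard errors come
    from the inverse observed information in ``(sigma2_g, sigma2_e)`` with
    the h2 SE by the delta method.
    """
    grm, yv = _align(grm, y)
    n = yv.size
    if n < 50:
        raise ValueError(f"REML needs at least 50 samples, got {n}")
    d, U = grm.eig()
    ys = U.T @ yv
    t = U.T @ np.ones(n)

    res = minimize_scalar(
        _uni_profile_nll, bounds=(1e-6, 1.0 - 1e-6), args=(d, ys, t), method="bounded",
        options={"xatol": 1e-10},
    )
    h2 = float(res.x)
    v = h2 * d + (1.0 - h2)
    w = 1.0 / v
    xtx = np.sum(t * t * w)
    beta = np.sum(t * ys * w) / xtx
    s2 = (np.sum(ys * ys * w) - beta * beta * xtx) / (n - 1)
    sg, se_c = max(h2 * s2, _BOUND), max((1.0 - h2) * s2, _BOUND)
    if h2 * s2 < _BOUND or (1.0 - h2) * s2 < _BOUND:
        logger.warning("reml_univariate: variance component truncated at %g", _BOUND)

    # observed information by central differences on the restricted loglik
    h = 1e-4 * max(s2, 1.0)
    def ll(a, b):
        return _uni_loglik(max(a, _BOUND), max(b, _BOUND), d, ys, t)
    f0 = ll(sg, se_c)
    hess = np.empty((2, 2))
    hess[0, 0] = (ll(sg + h, se_c) - 2 * f0 + ll(sg - h, se_c)) / h**2
    hess[1, 1] = (ll(sg, se_c + h) - 2 * f0 + ll(sg, se_c - h)) / h**2
    hess[0, 1] = hess[1, 0] = (
        ll(sg + h, se_c + h) - ll(sg + h, se_c - h) - ll(sg - h, se_c + h) + ll(sg - h, se_c - h)
    ) / (4 * h**2)
    try:
        cov = np.linalg.inv(-hess)
        tot = sg + se_c
        grad = np.array([se_c / tot**2, -sg / tot**2])  # d h2 / d (sg, se)
        se_h2 = float(np.sqrt(max(grad @ cov @ grad, 0.0)))
    except np.linalg.LinAlgError:
        se_h2 = float("nan")
    return VarComp(
        sigma2_g=float(sg), sigma2_e=float(se_c), h2=float(sg / (sg + se_c)),
        se_h2=se_h2, converged=bool(res.success), n=n, loglik=float(f0),
    )


# ---------------------------------------------------------------------------
# bivariate REML (AI algorithm on spectrally rotated data)
#
# After rotating both traits by the GRM eigenvectors the covariance of the
# i-th rotated pair is the 2x2 matrix C_i = d_i * G + E with G, E the genetic
# and residual (co)variance matrices, so every likelihood quantity reduces to
# vectorized 2x2 algebra.

_PARAM_MATS = {  # parameter -> (is_genetic, 2x2 pattern)
    "g11": (True, np.array([[1.0, 0.0], [0.0, 0.0]])),
    "g22": (True, np.array([[0.0, 0.0], [0.0, 1.0]])),
    "g12": (True, np.array([[0.0, 1.0], [1.0, 0.0]])),
    "e11": (False, np.array([[1.0, 0.0], [0.0, 0.0]])),
    "e22": (False, np.array([[0.0, 0.0], [0.0, 1.0]])),
    "e12": (False, np.array([[0.0, 1.0], [1.0, 0.0]])),
}


class _BivModel:
    def __init__(self, d: np.ndarray, Y: np.ndarray, t: np.ndarray):
        self.d, self.Y, self.t = d, Y, t       # Y: n x 2 rotated traits
        self.n = d.size

    def _cov_blocks(self, theta: dict[str, float]) -> np.ndarray:
        d = self.d[:, None, None]
        G = np.array([[theta["g11"], theta["g12"]], [theta["g12"], theta["g22"]]])
        E = np.array([[theta["e11"], theta["e12"]], [theta["e12"], theta["e22"]]])
        return d * G + E                       # n x 2 x 2

    @staticmethod
    def _inv2(C: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        det = C[:, 0, 0] * C[:, 1, 1] - C[:, 0, 1] ** 2
        inv = np.empty_like(C)
        inv[:, 0, 0] = C[:, 1, 1] / det
        inv[:, 1, 1] = C[:, 0, 0] / det
        inv[:, 0, 1] = inv[:, 1, 0] = -C[:, 0, 1] / det
        return inv, det

    def loglik(self, theta: dict[str, float]) -> float:
        C = self._cov_blocks(theta)
        Ci, det = self._inv2(C)
        if np.any(det <= 0.0):
            return -np.inf
        t2 = self.t**2
        XtVX = np.einsum("i,ijk->jk", t2, Ci)
        XtVy = np.einsum("i,ijk,ik->j", self.t, Ci, self.Y)
        sign, logdet_x = np.linalg.slogdet(XtVX)
        if sign <= 0:
            return -np.inf
        beta = np.linalg.solve(XtVX, XtVy)
        quad = np.einsum("ij,ijk,ik->", self.Y, Ci, self.Y) - beta @ XtVy
        return float(-0.5 * (np.sum(np.log(det)) + logdet_x + quad))

    def score_ai(self, theta: dict[str, float], free: list[str]):
        """Gradient and average-information matrix over the free parameters."""
        C = self._cov_blocks(theta)
        Ci, det = self._inv2(C)
        t2 = self.t**2
        XtVX = np.einsum("i,ijk->jk", t2, Ci)
        XtVX_inv = np.linalg.inv(XtVX)
        XtVy = np.einsum("i,ijk,ik->j", self.t, Ci, self.Y)
        beta = XtVX_inv @ XtVy
        # Py in rotated space: z_i = Ci (y_i - t_i beta)
        resid = self.Y - self.t[:, None] * beta[None, :]
        z = np.einsum("ijk,ik->ij", Ci, resid)

        dCs = {}
        for k in free:
            is_g, pat = _PARAM_MATS[k]
            scale = self.d if is_g else np.ones(self.n)
            dCs[k] = scale[:, None, None] * pat[None, :, :]

        grad = {}
        a_vecs = {}
        for k, dC in dCs.items():
            # tr(P dV) = sum_i tr(Ci dC_i) - tr(XtVX^-1 * sum_i t_i^2 Ci dC_i Ci)
            tr1 = np.einsum("ijk,ikj->", Ci, dC)
            M = np.einsum("i,ijk,ikl,ilm->jm", t2, Ci, dC, Ci)
            tr2 = np.trace(XtVX_inv @ M)
            a = np.einsum("ijk,ik->ij", dC, z)           # dV_k @ Py
            a_vecs[k] = a
            grad[k] = -0.5 * (tr1 - tr2 - np.einsum("ij,ij->", z, a))
        # AI_kl = 0.5 * a_k' P a_l
        ai = np.empty((len(free), len(free)))
        Ca = {k: np.einsum("ijk,ik->ij", Ci, a) for k, a in a_vecs.items()}
        tCa = {k: np.einsum("i,ij->j", self.t, v) for k, v in Ca.items()}
        for p_, kp in enumerate(free):
            for q_, kq in enumerate(free[: p_ + 1]):
                val = np.einsum("ij,ij->", a_vecs[kp], Ca[kq]) - tCa[kp] @ XtVX_inv @ tCa[kq]
                ai[p_, q_] = ai[q_, p_] = 0.5 * val
        g = np.array([grad[k] for k in free])
        return g, ai


def _clip_theta(theta: dict[str, float]) -> dict[str, float]:
    th = dict(theta)
    for k in ("g11", "g22", "e11", "e22"):
        th[k] = max(th[k], _BOUND)
    cap = np.sqrt(th["g11"] * th["g22"]) * (1.0 - 1e-8)
    th["g12"] = float(np.clip(th["g12"], -cap, cap))
    cap_e = np.sqrt(th["e11"] * th["e22"]) * (1.0 - 1e-8)
    th["e12"] = float(np.clip(th["e12"], -cap_e, cap_e))
    return th


def reml_bivariate(
    grm: Grm,
    y1: pd.Series,
    y2: pd.Series,
    drop_residual_cov: bool = False,
    return_trace: bool = False,
) -> VarComp:
    """Bivariate (AI-)REML on the samples with both traits observed.

    When ``drop_residual_cov`` is set the residual covariance is fixed at
    zero — the fallback used when the full model fails to converge.  With
    ``return_trace`` the per-iteration restricted log-likelihoods are
    attached as ``.trace`` (they are non-decreasing by construction).
    """
    y1, y2 = y1.dropna(), y2.dropna()
    common = [s for s in grm.sample_ids if s in y1.index and s in y2.index]
    if len(common) < 50:
        raise ValueError(f"bivariate REML needs >= 50 overlapping samples, got {len(common)}")
    g = grm.subset(common) if len(common) < len(grm.sample_ids) else grm
    d, U = g.eig()
    Y = U.T @ np.column_stack([y1.loc[common].to_numpy(float), y2.loc[common].to_numpy(float)])
    t = U.T @ np.ones(len(common))
    model = _BivModel(d, Y, t)

    # warm start from univariate marginals and the phenotypic correlation
    u1 = reml_univariate(g, y1.loc[common])
    u2 = reml_univariate(g, y2.loc[common])
    r_ph = float(np.corrcoef(y1.loc[common], y2.loc[common])[0, 1])
    theta = _clip_theta({
        "g11": u1.sigma2_g, "g22": u2.sigma2_g,
        "g12": 0.5 * r_ph * np.sqrt(u1.sigma2_g * u2.sigma2_g),
        "e11": u1.sigma2_e, "e22": u2.sigma2_e,
        "e12": 0.0 if drop_residual_cov else 0.5 * r_ph * np.sqrt(u1.sigma2_e * u2.sigma2_e),
    })
    free = ["g11", "g22", "g12", "e11", "e22"] + ([] if drop_residual_cov else ["e12"])

    ll = model.loglik(theta)
    trace = [ll]
    converged = False
    it = 0
    ai_last = None
    for it in range(1, _MAX_ITER + 1):
        grad, ai = model.score_ai(theta, free)
        ai_last = ai
        try:
            step = np.linalg.solve(ai + 1e-8 * np.eye(len(free)), grad)
        except np.linalg.LinAlgError:
            step = grad / max(np.abs(grad).max(), 1.0)
        # trust region: a near-singular AI (boundary cases) gives absurd steps
        cap = 2.0 * max(1.0, max(abs(v) for v in theta.values()))
        if np.abs(step).max() > cap:
            step = step * (cap / np.abs(step).max())

        def try_steps(direction):
            s = direction.copy()
            for _ in range(40):
                cand = dict(theta)
                for k, v in zip(free, s):
                    cand[k] = theta[k] + v
                cand = _clip_theta(cand)
                if drop_residual_cov:
                    cand["e12"] = 0.0
                cand_ll = model.loglik(cand)
                if cand_ll >= ll - 1e-12:
                    return cand_ll, cand
                s = s / 2.0
            return -np.inf, theta

        # step-halving keeps the restricted log-likelihood non-decreasing;
        # fall back to plain gradient ascent if the AI direction fails
        new_ll, new_theta = try_steps(step)
        if not np.isfinite(new_ll):
            gstep = grad / max(np.abs(grad).max(), 1.0) * min(cap, 1.0)
            new_ll, new_theta = try_steps(gstep)
        if not np.isfinite(new_ll):
            break
        delta = new_ll - ll
        theta, ll = new_theta, max(new_ll, ll)
        trace.append(ll)
        if abs(delta) < _TOL:
            converged = True
            break
    if not converged:
        logger.warning(
            "reml_bivariate did not converge in %d iterations%s", it,
            "" if drop_residual_cov else "; consider drop_residual_cov=True",
        )

    r_g = theta["g12"] / np.sqrt(theta["g11"] * theta["g22"])
    se_rg = se_h2 = float("nan")
    if ai_last is not None:
        try:
            cov = np.linalg.inv(ai_last)
            i = {k: free.index(k) for k in free}
            gr = np.zeros(len(free))
            gr[i["g12"]] = 1.0 / np.sqrt(theta["g11"] * theta["g22"])
            gr[i["g11"]] = -0.5 * r_g / theta["g11"]
            gr[i["g22"]] = -0.5 * r_g / theta["g22"]
            se_rg = float(np.sqrt(max(gr @ cov @ gr, 0.0)))
            tot = theta["g11"] + theta["e11"]
            gh = np.zeros(len(free))
            gh[i["g11"]] = theta["e11"] / tot**2
            gh[i["e11"]] = -theta["g11"] / tot**2
            se_h2 = float(np.sqrt(max(gh @ cov @ gh, 0.0)))
        except np.linalg.LinAlgError:
            pass
    out = VarComp(
        sigma2_g=theta["g11"], sigma2_e=theta["e11"],
        h2=theta["g11"] / (theta["g11"] + theta["e11"]), se_h2=se_h2,
        converged=converged, n=len(common), loglik=ll,
        sigma2_g2=theta["g22"], sigma2_e2=theta["e22"],
        sigma_g12=theta["g12"], sigma_e12=theta["e12"],
        r_g=float(r_g), se_rg=se_rg,
        residual_cov_dropped=drop_residual_cov, n_iter=it,
    )
    if return_trace:
        out.trace = trace  # type: ignore[attr-defined]
    return out
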