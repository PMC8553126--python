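"""Uni- and multivariate linear mixed models for clonally replicated trials.

Model (trait-major vectorization):

    Vec(Y) ~ N( (I_t (x) X) Vec(B),  V ),   V = V_G (x) Z A Z' + V_E (x) I_n

with Y the n x t tree-by-trait matrix, X the fixed design (intercept, block
effects, genotype-class effects at a tested SNP), Z the n x c tree-to-clone
incidence, A the clone relationship matrix (full-sib: unit diagonal, 0.5
elsewhere) and V_G / V_E the t x t genetic and residual covariances.

REML estimation exploits a double diagonalization.  The clone kernel
K = Z A Z' has rank <= c; its nonzero eigenpairs come from the c x c matrix
A^{1/2} diag(m) A^{1/2} (m = trees per clone), so all spectral work is at
clone scale.  Simultaneously diagonalizing V_G against V_E
(V_E = L L', L^{-1} V_G L^{-T} = Q M Q') decouples the rotated data into
t independent heteroscedastic regressions with weights lam_j * mu_k + 1,
making one restricted-likelihood evaluation O(t^3 + c t + t p^3).  The
restricted likelihood is maximized directly over Cholesky factors of
(V_G, V_E) with L-BFGS-B.

SNP tests use the F statistic

    F = (1/q) (M Vec(B))' [ M ((I_t (x) X) V^{-1} (I_t (x) X))^{-1} M' ]^{-1} (M Vec(B))

with q = (g-1) t numerator and t (n-p) denominator degrees of freedom,
where M selects all genotype-class coefficients across traits.  By default
the scan is P3D-style: variance components are fitted once under the
no-SNP null and V is reused for every SNP (an exact per-SNP refit mode is
available on the scanner).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve, solve_triangular

# ---------------------------------------------------------------------------
# Kinship


def kinship_fullsib(c: int) -> np.ndarray:
    """Additive relationship matrix of a single full-sib family.

    The kinship coefficient between two non-inbred full sibs is 1/4, so
    A = 2 x kinship has unit diagonal and 0.5 off-diagonal.  Eigenstructure
    in closed form: (1 + c)/2 on the all-ones vector, 1/2 with multiplicity
    c - 1.
    """
    if c < 1:
        raise ValueError("need at least one clone")
    return 0.5 * (np.eye(c) + np.ones((c, c)))


def _fullsib_sqrt(c: int) -> np.ndarray:
    """Closed-form symmetric square root of the full-sib A = 0.5 (I + J)."""
    alpha = np.sqrt(0.5)
    beta = (np.sqrt((1 + c) / 2) - alpha) / c
    return alpha * np.eye(c) + beta * np.ones((c, c))


# ---------------------------------------------------------------------------
# Design


@dataclass
class RCBDDesign:
    """Tree-level design: block and clone memberships."""

    block: np.ndarray  # (n,) int codes 0..b-1
    clone: np.ndarray  # (n,) int codes 0..c-1
    n_blocks: int
    n_clones: int

    @classmethod
    def from_table(cls, table) -> "RCBDDesign":
        """From a phenotype table with 'block' and 'clone' columns."""
        blocks, block_codes = np.unique(np.asarray(table["block"]), return_inverse=True)
        clones, clone_codes = np.unique(np.asarray(table["clone"]), return_inverse=True)
        return cls(
            block=block_codes.astype(np.int64),
            clone=clone_codes.astype(np.int64),
            n_blocks=len(blocks),
            n_clones=len(clones),
        )

    @property
    def n_trees(self) -> int:
        return len(self.block)

    def base_design_matrix(self) -> np.ndarray:
        """Intercept + reference-coded block columns (the no-SNP X)."""
        n = self.n_trees
        X = np.ones((n, 1 + self.n_blocks - 1))
        for b in range(1, self.n_blocks):
            X[:, b] = self.block == b
        return X


def build_fixed_design(design: RCBDDesign, clone_classes: np.ndarray):
    """Fixed-effect design for one SNP: intercept, blocks, genotype classes.

    ``clone_classes`` holds per-clone genotype-class codes (>= 0) with -1
    for missing.  Trees of clones with missing genotype are dropped; classes
    left with zero trees are omitted (g reduced).  Returns
    ``(X, keep, g, geno_cols)``; X is None when g < 2 (untestable SNP).
    """
    codes = np.asarray(clone_classes)
    tree_codes = codes[design.clone]
    keep = tree_codes >= 0
    present = np.unique(tree_codes[keep])
    g = len(present)
    block = design.block[keep]
    n = int(keep.sum())
    if g < 2:
        return None, keep, g, []
    p = 1 + (design.n_blocks - 1) + (g - 1)
    X = np.ones((n, p))
    for b in range(1, design.n_blocks):
        X[:, b] = block == b
    geno_cols = list(range(design.n_blocks, p))
    tc = tree_codes[keep]
    for i, cls in enumerate(present[1:]):
        X[:, design.n_blocks + i] = tc == cls
    return X, keep, g, geno_cols


# ---------------------------------------------------------------------------
# Clone-scale spectral decomposition


class CloneKernel:
    """Nonzero eigenpairs of K = Z A Z' computed at clone scale.

    ``rotate(M)`` maps a tree-level matrix to U' M (k rows) where U holds
    the orthonormal eigenvectors with eigenvalue lam > 0; directions
    orthogonal to U have K-eigenvalue 0.
    """

    def __init__(self, clone: np.ndarray, A="fullsib"):
        clone = np.asarray(clone)
        c = int(clone.max()) + 1 if len(clone) else 0
        m = np.bincount(clone, minlength=c).astype(float)
        active = np.flatnonzero(m > 0)
        self.clone = clone
        self.c_active = len(active)
        self._local = -np.ones(c, dtype=np.int64)
        self._local[active] = np.arange(len(active))
        if isinstance(A, str) and A == "fullsib":
            asq = _fullsib_sqrt(len(active))
        elif A is None:  # identity relationship: cov(g) = sigma_g^2 I_c
            asq = np.eye(len(active))
        else:
            Aa = np.asarray(A, dtype=float)[np.ix_(active, active)]
            w, u = np.linalg.eigh(Aa)
            asq = (u * np.sqrt(np.clip(w, 0, None))) @ u.T
        S = asq @ (asq * m[active][None, :].T)
        S = 0.5 * (S + S.T)
        lam, W = np.linalg.eigh(S)
        pos = lam > 1e-9 * max(lam.max(), 1.0)
        self.lam = lam[pos]
        self.R = asq @ (W[:, pos] / np.sqrt(self.lam))  # (c_active, k)
        self.m = m

    def clone_sums(self, M: np.ndarray) -> np.ndarray:
        """Z' M restricted to active clones."""
        out = np.zeros((self.c_active, M.shape[1]))
        np.add.at(out, self._local[self.clone], M)
        return out

    def rotate(self, M: np.ndarray) -> np.ndarray:
        return self.R.T @ self.clone_sums(M)


# ---------------------------------------------------------------------------
# REML: univariate


@dataclass
class VarianceComponents:
    sigma_g2: float
    sigma_e2: float
    log_restricted_likelihood: float
    converged: bool


def heritability(sigma_g2: float, sigma_e2: float) -> float:
    """Narrow-sense heritability h^2 = sigma_g^2 / (sigma_g^2 + sigma_e^2)."""
    if sigma_g2 < 0 or sigma_e2 < 0:
        raise ValueError("variance components must be non-negative")
    tot = sigma_g2 + sigma_e2
    if tot == 0:
        raise ValueError("heritability undefined when both components are zero")
    return sigma_g2 / tot


def reml_univariate(
    y: np.ndarray,
    X: np.ndarray,
    clone: np.ndarray,
    A: np.ndarray | None = "fullsib",
) -> VarianceComponents:
    """Restricted maximum likelihood for y = X beta + Z g + e.

    cov(g) = sigma_g^2 A with the full-sib A by default; pass ``A=None``
    for the identity-covariance variant cov(g) = sigma_g^2 I_c.  The
    restricted likelihood is profiled over the variance ratio
    delta = sigma_g^2 / sigma_e^2 (grid + Brent refinement on log delta).
    """
    y = np.asarray(y, dtype=float).reshape(-1, 1)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError("need n > p")
    kern = CloneKernel(clone, A)
    lam = kern.lam
    XtX = X.T @ X
    Xty = (X.T @ y).ravel()
    yy = float((y * y).sum())
    Xt = kern.rotate(X)
    yt = kern.rotate(y).ravel()

    def profile(log_delta):
        delta = np.exp(log_delta)
        d = lam * delta + 1.0
        omw = 1.0 - 1.0 / d
        G = XtX - (Xt * omw[:, None]).T @ Xt
        cvec = Xty - Xt.T @ (omw * yt)
        yq = yy - float(omw @ (yt * yt))
        cf = cho_factor(G)
        b = cho_solve(cf, cvec)
        rss = yq - float(cvec @ b)
        rss = max(rss, 1e-300)
        sigma_e2 = rss / (n - p)
        logdet_g = 2.0 * np.log(np.diag(cf[0])).sum()
        # the profiled-out rss/sigma_e2 term equals n - p at the optimum
        neg2 = float(np.log(d).sum() + (n - p) * np.log(sigma_e2) + logdet_g + (n - p))
        return neg2, sigma_e2, delta

    grid = np.linspace(-12.0, 12.0, 121)
    vals = [profile(g)[0] for g in grid]
    i = int(np.argmin(vals))
    lo, hi = grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        lambda g: profile(g)[0], bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-8},
    )
    neg2, sigma_e2, delta = profile(res.x)
    # boundary check: sigma_g^2 -> 0
    neg2_null, se_null, _ = profile(-30.0)
    if neg2_null <= neg2:
        return VarianceComponents(0.0, se_null, -0.5 * neg2_null, True)
    return VarianceComponents(delta * sigma_e2, sigma_e2, -0.5 * neg2, bool(res.success))


# ---------------------------------------------------------------------------
# REML: multivariate


@dataclass
class MultiVarComp:
    V_G: np.ndarray
    V_E: np.ndarray
    log_restricted_likelihood: float
    iterations: int
    converged: bool


def _chol_params(V: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    t = V.shape[0]
    w, u = np.linalg.eigh(V)
    Vp = (u * np.clip(w, floor, None)) @ u.T
    L = np.linalg.cholesky(Vp)
    out = []
    for i in range(t):
        for j in range(i):
            out.append(L[i, j])
        out.append(np.log(L[i, i]))
    return np.array(out)


def _params_chol(theta: np.ndarray, t: int) -> np.ndarray:
    L = np.zeros((t, t))
    k = 0
    for i in range(t):
        for j in range(i):
            L[i, j] = theta[k]
            k += 1
        L[i, i] = np.exp(theta[k])
        k += 1
    return L


def _mom_start(Y, clone, n_blocks_resid=None):
    """Method-of-moments start values from clone means and within-clone
    residuals."""
    c = int(clone.max()) + 1
    t = Y.shape[1]
    sums = np.zeros((c, t))
    np.add.at(sums, clone, Y)
    m = np.bincount(clone, minlength=c).astype(float)
    ok = m > 1
    means = sums[ok] / m[ok, None]
    resid = Y - sums[clone] / m[clone, None]
    ve = resid.T @ resid / max(len(Y) - ok.sum(), 1)
    vb = np.cov(means.T).reshape(t, t)
    vg = vb - ve / m[ok].mean()
    w, u = np.linalg.eigh(0.5 * (vg + vg.T))
    floor = 1e-3 * max(np.trace(ve) / t, 1e-6)
    vg = (u * np.clip(w, floor, None)) @ u.T
    return vg, ve


def reml_multivariate(
    Y: np.ndarray,
    X: np.ndarray,
    clone: np.ndarray,
    A: np.ndarray | None = "fullsib",
    tol: float = 1e-14,
    max_iter: int = 2000,
) -> MultiVarComp:
    """REML estimates of (V_G, V_E) by direct maximization of the
    restricted log-likelihood over Cholesky factors (L-BFGS-B)."""
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, t = Y.shape
    p = X.shape[1]
    if n <= p:
        raise ValueError("need n > p")
    if t > n / 2:
        raise ValueError("t > n/2 is ill-posed for this fitter")
    kern = CloneKernel(clone, A)
    lam = kern.lam
    k = len(lam)
    XtX = X.T @ X
    XtY = X.T @ Y
    YtY = Y.T @ Y
    Xt = kern.rotate(X)
    Yt = kern.rotate(Y)
    C_comp = XtX - Xt.T @ Xt  # complement-space X crossproduct
    eye = np.eye(t)
    eye_p = np.eye(p)
    nh = t * (t + 1) // 2

    def _tri_grad(grad_V, Lmat):
        """d f / d theta for V = L L' with log-diagonal parameters."""
        gl = 2.0 * grad_V @ Lmat
        out = []
        for i in range(t):
            for j in range(i):
                out.append(gl[i, j])
            out.append(gl[i, i] * Lmat[i, i])
        return np.array(out)

    def neg2ll(theta):
        """Restricted -2 log-likelihood and its analytic gradient.

        Gradient via d(-2l) = tr(P dV) - r'V^-1 dV V^-1 r with
        P = V^-1 - V^-1 X* W^-1 X*' V^-1; every term collapses onto
        T' [diag(.) - M] T patterns in the simultaneous trait basis.
        """
        LG = _params_chol(theta[:nh], t)
        LE = _params_chol(theta[nh:], t)
        VG = LG @ LG.T
        Linv = solve_triangular(LE, eye, lower=True)
        S = Linv @ VG @ Linv.T
        mu, Q = np.linalg.eigh(0.5 * (S + S.T))
        mu = np.clip(mu, 0.0, None)
        T = Q.T @ Linv
        logdet_ve = 2.0 * np.log(np.diag(LE)).sum()
        D = lam[:, None] * mu[None, :] + 1.0     # (k, t)
        omw = 1.0 - 1.0 / D
        Yto = Yt @ T.T                            # (k, t)
        XtYo = XtY @ T.T                          # (p, t)
        YtYo = T @ YtY @ T.T                      # (t, t)
        G = XtX[None, :, :] - np.einsum("jm,ja,jb->mab", omw, Xt, Xt)
        cv = XtYo.T - np.einsum("jm,jm,ja->ma", omw, Yto, Xt)
        yq = np.diag(YtYo) - np.einsum("jm,jm->m", omw, Yto * Yto)
        total = float(np.log(D).sum()) + (n - p) * logdet_ve
        B = np.empty((p, t))
        Ginv = np.empty((t, p, p))
        for m in range(t):
            cf = cho_factor(G[m])
            B[:, m] = cho_solve(cf, cv[m])
            Ginv[m] = cho_solve(cf, eye_p)
            total += 2.0 * np.log(np.diag(cf[0])).sum() + max(
                yq[m] - float(cv[m] @ B[:, m]), 1e-300
            )
        # ---- gradient
        Rt = Yto - Xt @ B                         # rotated residuals (k, t)
        RD = Rt / D
        M_G = np.einsum("j,jm,jn->mn", lam, RD, RD)
        R2_full = YtYo - B.T @ XtYo - XtYo.T @ B + B.T @ XtX @ B
        R2_comp = R2_full - Rt.T @ Rt
        M_E = RD.T @ RD + R2_comp
        sG = (lam[:, None] / D).sum(axis=0)
        sE = (1.0 / D).sum(axis=0) + (n - k)
        a = np.einsum("ja,mab,jb->jm", Xt, Ginv, Xt)  # (k, t)
        FG = (lam[:, None] * a / (D * D)).sum(axis=0)
        FE = (a / (D * D)).sum(axis=0) + np.einsum("mab,ab->m", Ginv, C_comp)
        grad_VG = T.T @ (np.diag(sG - FG) - M_G) @ T
        grad_VE = T.T @ (np.diag(sE - FE) - M_E) @ T
        grad_VG = 0.5 * (grad_VG + grad_VG.T)
        grad_VE = 0.5 * (grad_VE + grad_VE.T)
        grad = np.concatenate([_tri_grad(grad_VG, LG), _tri_grad(grad_VE, LE)])
        return total, grad

    vg0, ve0 = _mom_start(Y, clone)
    theta0 = np.concatenate([_chol_params(vg0), _chol_params(ve0)])
    bounds = []
    for _ in range(2):
        for i in range(t):
            bounds.extend([(None, None)] * i)
            bounds.append((-14.0, 14.0))
    res = optimize.minimize(
        neg2ll, theta0, method="L-BFGS-B", jac=True, bounds=bounds,
        options={"maxiter": max_iter, "maxfun": 10 * max_iter, "ftol": tol,
                 "gtol": 1e-8},
    )
    LG = _params_chol(res.x[:nh], t)
    LE = _params_chol(res.x[nh:], t)
    return MultiVarComp(
        V_G=LG @ LG.T,
        V_E=LE @ LE.T,
        log_restricted_likelihood=-0.5 * float(res.fun),
        iterations=int(res.nit),
        converged=bool(res.success),
    )


# ---------------------------------------------------------------------------
# Dense GLS + F test (small-problem reference path)


@dataclass
class GLSFit:
    B_hat: np.ndarray  # (p, t)
    RSS: float
    W: np.ndarray      # (pt, pt) = (I_t (x) X)' V^{-1} (I_t (x) X)


def gls_fit(Y: np.ndarray, X: np.ndarray, V: np.ndarray) -> GLSFit:
    """Generalized least squares of Vec(Y) on I_t (x) X under covariance V.

    Dense reference implementation (V is the full nt x nt matrix,
    trait-major vectorization); intended for small n.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] == 1:
        Y = Y.T
    n, t = Y.shape
    X = np.asarray(X, dtype=float)
    p = X.shape[1]
    vec_y = Y.reshape(-1, order="F")
    XK = np.kron(np.eye(t), X)
    cf = cho_factor(np.asarray(V, dtype=float))
    ViX = cho_solve(cf, XK)
    Viy = cho_solve(cf, vec_y)
    W = XK.T @ ViX
    try:
        wf = cho_factor(W)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(f"singular GLS normal equations: {err}") from err
    b = cho_solve(wf, XK.T @ Viy)
    resid = vec_y - XK @ b
    rss = float(resid @ cho_solve(cf, resid))
    return GLSFit(B_hat=b.reshape(p, t, order="F"), RSS=rss, W=W)


@dataclass
class FTestResult:
    F: float
    q: int
    df2: int
    p_value: float
    B_hat: np.ndarray | None = None
    RSS: float = np.nan
    RSS0: float = np.nan
    pve: float = np.nan
    g: int = 0
    n_used: int = 0


def f_test(fit: GLSFit, M: np.ndarray, t: int, n: int, p: int) -> FTestResult:
    """F test of the linear hypothesis M Vec(B) = 0 on a GLS fit."""
    M = np.atleast_2d(np.asarray(M, dtype=float))
    q = M.shape[0]
    if q == 0:
        raise ValueError("empty hypothesis (q = 0): SNP untestable")
    vec_b = fit.B_hat.reshape(-1, order="F")
    mid = M @ np.linalg.solve(fit.W, M.T)
    delta = M @ vec_b
    F = float(delta @ np.linalg.solve(mid, delta)) / q
    df2 = t * (n - p)
    return FTestResult(F=F, q=q, df2=df2, p_value=float(stats.f.sf(F, q, df2)),
                       B_hat=fit.B_hat, RSS=fit.RSS)


def pve_from_rss(rss: float, rss0: float) -> float:
    """Proportion of variance explained, R^2 = 1 - RSS/RSS0 (clipped to
    [0, 1])."""
    if rss0 <= 0:
        raise ValueError("RSS0 must be positive")
    return float(np.clip(1.0 - rss / rss0, 0.0, 1.0))


# ---------------------------------------------------------------------------
# P3D scanner


class MixedModelScanner:
    """Per-SNP multivariate F tests under fixed (P3D) variance components.

    Fits nothing itself: takes variance components (usually from the no-SNP
    null REML fit), precomputes clone/block cross-products of the trait-
    transformed data, and then tests each SNP from clone-level summaries
    only.  ``exact=True`` on :meth:`test_snp` refits the variance
    components for that SNP's complete-case subset (slow; for audits).
    """

    def __init__(self, Y: np.ndarray, design: RCBDDesign, vc: MultiVarComp,
                 A="fullsib"):
        Y = np.asarray(Y, dtype=float)
        self.n, self.t = Y.shape
        self.design = design
        self.A = A
        self.vc = vc
        t = self.t
        LE = np.linalg.cholesky(vc.V_E + 1e-10 * np.trace(vc.V_E) / t * np.eye(t))
        Linv = solve_triangular(LE, np.eye(t), lower=True)
        S = Linv @ vc.V_G @ Linv.T
        mu, Q = np.linalg.eigh(0.5 * (S + S.T))
        self.mu = np.clip(mu, 0.0, None)
        self.T = Q.T @ Linv
        self.Yo = Y @ self.T.T
        c, b = design.n_clones, design.n_blocks
        self.Nb = np.zeros((c, b))
        np.add.at(self.Nb, (design.clone, design.block), 1.0)
        self.m = self.Nb.sum(axis=1)
        self.SB = np.zeros((c, b, t))  # per clone x block trait sums
        np.add.at(self.SB, (design.clone, design.block), self.Yo)
        self.Sc = self.SB.sum(axis=1)
        self.q2 = np.zeros((c, t))
        np.add.at(self.q2, design.clone, self.Yo * self.Yo)
        self._kern_cache: dict[bytes, CloneKernel] = {}
        self._full_Y = Y

    def _kernel_for(self, kept_clones: np.ndarray) -> CloneKernel:
        key = kept_clones.tobytes()
        kern = self._kern_cache.get(key)
        if kern is None:
            tree_keep = kept_clones[self.design.clone]
            clone_sub = self.design.clone[tree_keep]
            # relabel to 0..c_s-1 happens inside CloneKernel via active clones
            kern = CloneKernel(clone_sub, self.A)
            if len(self._kern_cache) > 4096:
                self._kern_cache.clear()
            self._kern_cache[key] = kern
        return kern

    def _assemble(self, kept, classes, levels):
        """Clone-level cross products for the kept clones / class levels."""
        d = self.design
        b = d.n_blocks
        g = len(levels)
        p = 1 + (b - 1) + max(g - 1, 0)
        Nb = self.Nb[kept]
        m = self.m[kept]
        Sc = self.Sc[kept]
        SB = self.SB[kept]
        cls = classes[kept]
        n_s = m.sum()
        # X'X
        XtX = np.empty((p, p))
        XtX[0, 0] = n_s
        nb = Nb.sum(axis=0)
        for bb in range(1, b):
            XtX[0, bb] = XtX[bb, 0] = nb[bb]
            for b2 in range(1, b):
                XtX[bb, b2] = nb[bb] if bb == b2 else 0.0
        XtY = np.empty((p, self.t))
        XtY[0] = Sc.sum(axis=0)
        for bb in range(1, b):
            XtY[bb] = SB[:, bb, :].sum(axis=0)
        ZX = np.empty((len(m), p))
        ZX[:, 0] = m
        ZX[:, 1:b] = Nb[:, 1:]
        for i, lev in enumerate(levels[1:]):
            col = b + i
            ind = cls == lev
            XtX[0, col] = XtX[col, 0] = m[ind].sum()
            for bb in range(1, b):
                XtX[bb, col] = XtX[col, bb] = Nb[ind, bb].sum()
            for i2, lev2 in enumerate(levels[1:]):
                col2 = b + i2
                XtX[col, col2] = m[ind].sum() if i2 == i else 0.0
            XtY[col] = Sc[ind].sum(axis=0)
            ZX[:, col] = m * ind
        yy = self.q2[kept].sum(axis=0)
        return XtX, XtY, ZX, Sc, yy, int(n_s), p

    def _gls(self, kern, XtX, XtY, ZX, Sc, yy):
        lam = kern.lam
        Xt = kern.R.T @ ZX
        Yt = kern.R.T @ Sc
        D = lam[:, None] * self.mu[None, :] + 1.0
        omw = 1.0 - 1.0 / D
        G = XtX[None, :, :] - np.einsum("jt,ja,jb->tab", omw, Xt, Xt)
        cvec = XtY.T - np.einsum("jt,jt,ja->ta", omw, Yt, Xt)
        yq = yy - np.einsum("jt,jt->t", omw, Yt * Yt)
        p = XtX.shape[0]
        B = np.empty((self.t, p))
        Ginv = np.empty((self.t, p, p))
        rss = 0.0
        eye = np.eye(p)
        for kk in range(self.t):
            cf = cho_factor(G[kk])
            B[kk] = cho_solve(cf, cvec[kk])
            Ginv[kk] = cho_solve(cf, eye)
            rss += max(yq[kk] - float(cvec[kk] @ B[kk]), 0.0)
        return B, Ginv, rss

    def test_snp(self, clone_classes: np.ndarray, exact: bool = False) -> FTestResult | None:
        """Multivariate F test of one SNP's genotype-class effects.

        ``clone_classes``: per-clone integer class codes, -1 for missing.
        Returns None for untestable SNPs (fewer than two classes with
        trees).  With ``exact=True`` the variance components are refitted
        on this SNP's complete-case subset before testing.
        """
        codes = np.asarray(clone_classes)
        kept = (codes >= 0) & (self.m > 0)
        if not kept.any():
            return None
        levels = np.unique(codes[kept])
        g = len(levels)
        if g < 2:
            return None
        if exact:
            return self._test_exact(codes, kept, levels)
        kern = self._kernel_for(kept)
        XtX, XtY, ZX, Sc, yy, n_s, p = self._assemble(kept, codes, levels)
        B, Ginv, rss = self._gls(kern, XtX, XtY, ZX, Sc, yy)
        # null model: drop genotype columns
        p0 = p - (g - 1)
        B0, _, rss0 = self._gls(kern, XtX[:p0, :p0], XtY[:p0], ZX[:, :p0], Sc, yy)
        gi = np.arange(p0, p)
        q = (g - 1) * self.t
        num = 0.0
        for kk in range(self.t):
            sub = Ginv[kk][np.ix_(gi, gi)]
            bg = B[kk][gi]
            num += float(bg @ np.linalg.solve(sub, bg))
        F = num / q
        df2 = self.t * (n_s - p)
        return FTestResult(
            F=F, q=q, df2=df2, p_value=float(stats.f.sf(F, q, df2)),
            B_hat=(self.T, B), RSS=rss, RSS0=rss0,
            pve=pve_from_rss(rss, rss0), g=g, n_used=n_s,
        )

    def _test_exact(self, codes, kept, levels):
        d = self.design
        tree_keep = kept[d.clone]
        Y = self._full_Y[tree_keep]
        sub_design = RCBDDesign(
            block=d.block[tree_keep], clone=d.clone[tree_keep],
            n_blocks=d.n_blocks, n_clones=d.n_clones,
        )
        X0 = sub_design.base_design_matrix()
        if self.t == 1:
            vc1 = reml_univariate(Y[:, 0], X0, sub_design.clone, self.A)
            vc = MultiVarComp(
                V_G=np.array([[vc1.sigma_g2]]), V_E=np.array([[vc1.sigma_e2]]),
                log_restricted_likelihood=vc1.log_restricted_likelihood,
                iterations=0, converged=vc1.converged,
            )
        else:
            vc = reml_multivariate(Y, X0, sub_design.clone, self.A)
        sub = MixedModelScanner(Y, sub_design, vc, self.A)
        return sub.test_snp(codes, exact=False)
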