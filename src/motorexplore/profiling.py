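"""Coordination-pattern profiling: discriminative clustering of CRP cycles.

Each movement cycle is a point in R^L (its CRP curve on a fixed grid).  The
cycles of all learners, sessions and conditions are pooled and clustered
with a Fisher-EM style algorithm: an EM procedure that, at every iteration,
re-estimates an orthonormal latent subspace (dimension K - 1) chosen to
maximize the Fisher trace criterion — between-cluster scatter large,
within-cluster scatter small — and then fits a Gaussian mixture inside that
subspace with common spherical noise outside it.

The number of patterns K is chosen by scanning a range of K and taking the
first value of the plateau of the BIC curve (the "elbow"): the smallest K
whose successor scores a lower BIC.  Cluster labels are made canonical by
ordering profiles by the circular mean of their mean CRP curve, replacing
the arbitrary ordering a random initialization produces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from scipy.special import logsumexp
from sklearn.cluster import KMeans

__all__ = [
    "FisherEM",
    "FisherEMResults",
    "CoordinationProfile",
    "fit_profiles",
    "model_bic",
    "select_k",
    "assign_labels",
    "circular_mean_deg",
]


@dataclass
class CoordinationProfile:
    """One coordination pattern: canonical id, mean CRP curve, size."""

    pattern_id: int
    mean_crp: np.ndarray
    member_count: int
    circular_mean: float = 0.0


def circular_mean_deg(angles_deg) -> float:
    """Circular mean of angles in degrees, in (-180, 180]."""
    a = np.radians(np.asarray(angles_deg, dtype=float))
    mean = np.degrees(np.arctan2(np.mean(np.sin(a)), np.mean(np.cos(a))))
    return 180.0 if np.isclose(mean, -180.0) else float(mean)


class FisherEM:
    """Discriminative Gaussian mixture in a Fisher latent subspace.

    Parameters
    ----------
    X : ndarray (n, p)
        One CRP curve per row.
    n_components : int
        Number of clusters K.
    n_init : int
        Seeded k-means restarts; the best run by log-likelihood wins.
    ridge : float
        Regularization added to scatter and covariance matrices.
    random_state : int or None
        Seed; the fit is deterministic given the seed.
    """

    def __init__(self, X, n_components: int, n_init: int = 10,
                 max_iter: int = 200, tol: float = 1e-8,
                 ridge: float = 1e-6, random_state=None):
        self.X = np.ascontiguousarray(X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-d (cycles x grid points)")
        n, p = self.X.shape
        if n_components < 1:
            raise ValueError("K must be >= 1")
        if n <= n_components:
            raise ValueError("need more cycles than clusters")
        if np.any(~np.isfinite(self.X)):
            raise ValueError("X contains missing values")
        self.K = int(n_components)
        self.d = max(1, min(self.K - 1, p - 1))
        self.n_init = int(n_init)
        self.max_iter = int(max_iter)
        self.tol = float(tol)
        self.ridge = float(ridge)
        self.random_state = random_state
        self._xbar = self.X.mean(axis=0)
        Xc = self.X - self._xbar
        self._S_total = (Xc.T @ Xc) / n
        self._sqnorm = np.einsum("ij,ij->i", Xc, Xc)

    # -- steps ---------------------------------------------------------------

    def _f_step(self, resp: np.ndarray) -> np.ndarray:
        """Update the orthonormal discriminative basis U (p x d)."""
        n, p = self.X.shape
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-10)
        means = (resp.T @ self.X) / nk[:, None]
        Mc = means - self._xbar
        S_B = (Mc.T * (nk / n)) @ Mc
        S_W = self._S_total - S_B
        S_W = S_W + self.ridge * np.trace(self._S_total) / p * np.eye(p) \
            + 1e-12 * np.eye(p)
        if np.trace(S_B) <= 1e-14 * max(np.trace(self._S_total), 1.0):
            # no between-cluster structure (K=1 or collapsed): PCA fallback
            vals, vecs = linalg.eigh(self._S_total)
            U = vecs[:, ::-1][:, :self.d]
            U, _ = np.linalg.qr(U)
            return U
        # The subspace must contain the exact span of the class means:
        # any leak of between-cluster variance into the spherical
        # complement inflates the noise estimate catastrophically.  The
        # mean span (rank <= K-1) comes first; remaining dimensions are
        # filled with the top Fisher generalized eigenvectors.
        um, sm, _ = np.linalg.svd(Mc.T, full_matrices=False)
        r = int(np.sum(sm > max(sm[0], 1e-300) * 1e-8))
        Qm = um[:, :r]
        if r >= self.d:
            U = Qm[:, :self.d]
        else:
            vals, vecs = linalg.eigh(S_B, S_W)
            V = vecs[:, ::-1][:, : self.d + r]
            U, _ = np.linalg.qr(np.hstack([Qm, V]))
            U = U[:, :self.d]
        return U

    def _m_step(self, resp: np.ndarray, U: np.ndarray):
        n, p = self.X.shape
        Y = (self.X - self._xbar) @ U                     # (n, d)
        nk = np.maximum(resp.sum(axis=0), 1e-10)
        pi = nk / n
        means = (resp.T @ Y) / nk[:, None]                # (K, d)
        covs = np.empty((self.K, self.d, self.d))
        for k in range(self.K):
            Yc = Y - means[k]
            covs[k] = (Yc.T * resp[:, k]) @ Yc / nk[k]
            covs[k] += self.ridge * np.eye(self.d)
        resid = self._sqnorm - np.einsum("ij,ij->i", Y, Y)
        beta = max(float(resid.mean() / max(p - self.d, 1)), 1e-10)
        return pi, means, covs, beta

    def _log_dens(self, U, pi, means, covs, beta) -> np.ndarray:
        """(n, K) component log joint densities."""
        n, p = self.X.shape
        Y = (self.X - self._xbar) @ U
        resid = np.maximum(self._sqnorm - np.einsum("ij,ij->i", Y, Y), 0.0)
        out = np.empty((n, self.K))
        const_out = (p - self.d) * np.log(2 * np.pi * beta)
        for k in range(self.K):
            ch = linalg.cholesky(covs[k], lower=True)
            sol = linalg.solve_triangular(ch, (Y - means[k]).T, lower=True)
            maha = np.einsum("ij,ij->j", sol, sol)
            logdet = 2.0 * np.log(np.diag(ch)).sum()
            out[:, k] = np.log(pi[k]) - 0.5 * (
                self.d * np.log(2 * np.pi) + logdet + maha
                + const_out + resid / beta)
        return out

    # -- fitting -------------------------------------------------------------

    def _fit_once(self, seed: int):
        n, p = self.X.shape
        if np.trace(self._S_total) <= 1e-12:
            warnings.warn("degenerate scatter: all curves identical; "
                          "single effective component")
            resp = np.zeros((n, self.K))
            resp[:, 0] = 1.0
            U = np.eye(p)[:, :self.d]
            params = self._m_step(resp, U)
            return (U, *params), resp, -np.inf, [-np.inf]

        if self.K == 1:
            resp = np.ones((n, 1))
        else:
            km = KMeans(n_clusters=self.K, n_init=1, random_state=seed)
            hard = km.fit_predict(self.X)
            resp = np.zeros((n, self.K))
            resp[np.arange(n), hard] = 1.0

        ll_prev = -np.inf
        ll_path: list[float] = []
        best = None
        for _ in range(self.max_iter):
            U = self._f_step(resp)
            pi, means, covs, beta = self._m_step(resp, U)
            logd = self._log_dens(U, pi, means, covs, beta)
            ll = float(logsumexp(logd, axis=1).sum())
            if ll < ll_prev - 1e-10 * max(abs(ll_prev), 1.0):
                break                   # keep the previous, better iterate
            best = (U, pi, means, covs, beta)
            ll_path.append(ll)
            resp = np.exp(logd - logsumexp(logd, axis=1, keepdims=True))
            if ll_prev > -np.inf and \
                    abs(ll - ll_prev) < self.tol * max(abs(ll_prev), 1.0):
                ll_prev = ll
                break
            ll_prev = ll
        U, pi, means, covs, beta = best
        logd = self._log_dens(U, pi, means, covs, beta)
        resp = np.exp(logd - logsumexp(logd, axis=1, keepdims=True))
        return (U, pi, means, covs, beta), resp, ll_path[-1], ll_path

    def fit(self) -> "FisherEMResults":
        ss = np.random.SeedSequence(self.random_state)
        seeds = [int(s.generate_state(1)[0] % (2**31)) for s in
                 ss.spawn(max(self.n_init, 1))]
        best = None
        for sd in seeds:
            params, resp, ll, path = self._fit_once(sd)
            if best is None or ll > best[2]:
                best = (params, resp, ll, path, sd)
            if self.K == 1 or not np.isfinite(ll):
                break                    # deterministic cases need one run
        params, resp, ll, path, sd = best
        return FisherEMResults(self, params, resp, ll, path, sd)


class FisherEMResults:
    """Fitted coordination-profile clustering."""

    def __init__(self, model: FisherEM, params, resp, loglik, ll_path, seed):
        self.model = model
        self.projection, self.weights, self.means, self.covariances, \
            self.noise_variance = params
        self.responsibilities = resp
        self.loglik = loglik
        self.ll_path = list(ll_path)
        self.seed = seed
        self.preprocess_: dict = {"embed": None, "span_tol": None,
                                  "mean": None, "basis": None}
        self.curves_: np.ndarray | None = None

    def transform_curves(self, curves) -> np.ndarray:
        """Apply the fit's preprocessing (embedding, span projection) to
        new CRP curves."""
        F = np.asarray(curves, dtype=float)
        if self.preprocess_.get("embed") == "circular":
            F = _embed_circular(F)
        basis = self.preprocess_.get("basis")
        if basis is not None:
            F = (F - self.preprocess_["mean"]) @ basis
        return F

    @property
    def K(self) -> int:
        return self.model.K

    @property
    def npar(self) -> int:
        K, d = self.model.K, self.model.d
        p = self.model.X.shape[1]
        subspace = d * p - d * (d + 1) // 2
        return (K - 1) + subspace + K * d + K * d * (d + 1) // 2 + 1

    @property
    def bic(self) -> float:
        """BIC on the larger-is-better convention: 2 LL - npar log n."""
        n = self.model.X.shape[0]
        return 2.0 * self.loglik - self.npar * np.log(n)

    def predict_raw(self, curves=None, transformed: bool = False
                    ) -> np.ndarray:
        """Maximum-posterior component index (0-based, non-canonical).

        ``curves`` are CRP curves in the original space unless
        ``transformed`` is set; ``None`` scores the training data.
        """
        if curves is None:
            return np.argmax(self.responsibilities, axis=1)
        X = np.asarray(curves, float) if transformed \
            else self.transform_curves(curves)
        helper = FisherEM.__new__(FisherEM)
        helper.__dict__.update(self.model.__dict__)
        helper.X = np.ascontiguousarray(X, dtype=float)
        helper._sqnorm = np.einsum(
            "ij,ij->i", helper.X - helper._xbar, helper.X - helper._xbar)
        logd = helper._log_dens(self.projection, self.weights, self.means,
                                self.covariances, self.noise_variance)
        return np.argmax(logd, axis=1)

    def summary(self) -> str:
        return "\n".join([
            "Fisher-EM coordination profiling",
            f"  clusters K:      {self.K}",
            f"  latent dim d:    {self.model.d}",
            f"  cycles n:        {self.model.X.shape[0]}",
            f"  log-likelihood:  {self.loglik:.2f}",
            f"  parameters:      {self.npar}",
            f"  BIC (2LL-k·logn): {self.bic:.2f}",
            f"  EM iterations:   {len(self.ll_path)}",
        ])


# ---------------------------------------------------------------------------
# module-level operations


def _embed_circular(X: np.ndarray) -> np.ndarray:
    """Map angle curves (degrees) to (cos, sin) coordinates.

    CRP is circular: a curve hovering around +/-180 deg must not be torn
    apart by the Euclidean metric, so clustering operates on the unit-circle
    embedding of each grid point.
    """
    R = np.radians(X)
    return np.hstack([np.cos(R), np.sin(R)])


def fit_profiles(curves, K: int, seed=None, n_init: int = 10,
                 method: str = "fisher_em", embed: str = "circular",
                 span_tol: float = 0.01, **kwargs) -> FisherEMResults:
    """Cluster CRP cycles (degrees, n x L) into K coordination patterns.

    Preprocessing: the curves are embedded on the unit circle
    (``embed="circular"``; pass ``embed=None`` to cluster raw values) and
    restricted to their effective span — the principal directions whose
    eigenvalue exceeds ``span_tol`` times the leading one.  Band-limited
    angle curves are numerically rank-deficient, and near-null directions
    make the mixture's spherical complement noise degenerate; the span
    restriction keeps the Gaussian family well posed.

    ``method="fisher_em"`` (default) is the discriminative-subspace mixture;
    ``method="gmm_pca"`` is a plain Gaussian mixture on principal components
    behind the same interface, kept as a robustness fallback.
    """
    X0 = np.asarray(curves, dtype=float)
    F = _embed_circular(X0) if embed == "circular" else X0
    preproc = {"embed": embed, "span_tol": span_tol,
               "mean": None, "basis": None}
    if span_tol:
        mu = F.mean(axis=0)
        Fc = F - mu
        lam, vecs = linalg.eigh((Fc.T @ Fc) / max(len(F), 1))
        lam, vecs = lam[::-1], vecs[:, ::-1]
        if lam[0] > 0:
            r = max(int(np.sum(lam > span_tol * lam[0])), 2)
            preproc["mean"], preproc["basis"] = mu, vecs[:, :r]
            F = Fc @ vecs[:, :r]
    if method == "fisher_em":
        res = FisherEM(F, K, n_init=n_init, random_state=seed,
                       **kwargs).fit()
    elif method == "gmm_pca":
        res = _fit_gmm_pca(F, K, seed=seed, n_init=n_init)
    else:
        raise ValueError("method must be 'fisher_em' or 'gmm_pca'")
    res.preprocess_ = preproc
    res.curves_ = X0
    return res


def _fit_gmm_pca(curves, K: int, seed=None, n_init: int = 10
                 ) -> FisherEMResults:
    """Gaussian mixture on a PCA subspace, dressed as FisherEMResults."""
    from sklearn.decomposition import PCA
    from sklearn.mixture import GaussianMixture

    X = np.asarray(curves, dtype=float)
    model = FisherEM(X, K, n_init=n_init, random_state=seed)
    d = model.d
    pca = PCA(n_components=d, random_state=0)
    Y = pca.fit_transform(X)
    gm = GaussianMixture(n_components=K, n_init=n_init, random_state=seed,
                         covariance_type="full", reg_covar=1e-6)
    gm.fit(Y)
    resp = gm.predict_proba(Y)
    resid = model._sqnorm - np.einsum("ij,ij->i", Y, Y)
    beta = max(float(np.mean(resid) / max(X.shape[1] - d, 1)), 1e-10)
    params = (pca.components_.T, gm.weights_, gm.means_,
              gm.covariances_ + 0.0, beta)
    ll = float(gm.score(Y) * Y.shape[0])
    return FisherEMResults(model, params, resp, ll, [ll], seed)


def plot_profiles(profiles, ax=None):
    """Plot the mean CRP curve of every coordination profile."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for p in profiles:
        ax.plot(np.linspace(0, 100, p.mean_crp.size), p.mean_crp,
                label=f"pattern {p.pattern_id} (n={p.member_count})")
    ax.set_xlabel("cycle time (%)")
    ax.set_ylabel("CRP (deg)")
    ax.set_ylim(-185, 185)
    ax.legend(fontsize="small")
    return ax


def model_bic(results: FisherEMResults) -> float:
    """BIC of a fitted clustering (larger is better)."""
    return results.bic


def select_k(bic_by_k: dict[int, float]) -> tuple[int, bool]:
    """First value of the BIC plateau: smallest K whose successor has a
    lower BIC.

    Expects BIC on the larger-is-better convention over consecutive K.
    If the BIC keeps increasing to the end, the largest K is returned with
    the warning flag set.

    Returns ``(K_star, no_plateau_flag)``.
    """
    if not bic_by_k:
        raise ValueError("empty BIC map")
    ks = sorted(bic_by_k)
    if len(ks) < 2 or any(b - a != 1 for a, b in zip(ks[:-1], ks[1:])):
        raise ValueError("need BIC at >= 2 consecutive K values")
    for k in ks[:-1]:
        if bic_by_k[k + 1] < bic_by_k[k]:
            return k, False
    warnings.warn("BIC strictly increasing over the scanned range; "
                  "returning the largest K")
    return ks[-1], True


def assign_labels(results: FisherEMResults, curves=None
                  ) -> tuple[np.ndarray, list[CoordinationProfile]]:
    """Canonical per-cycle pattern labels plus the profile catalogue.

    Components are relabelled 1..K by ascending circular mean of each
    profile's mean CRP curve, so results are reproducible across seeds
    (the raw component order depends on the random initialization).
    Chronological cycle order is preserved.
    """
    if curves is None:
        X = results.curves_ if results.curves_ is not None \
            else results.model.X
        raw = results.predict_raw()
    else:
        X = np.asarray(curves, float)
        raw = results.predict_raw(X)
    rad = np.radians(X)
    order_stats = []
    for k in range(results.K):
        members = raw == k
        if not members.any():
            # empty component: sorts last
            L = X.shape[1]
            order_stats.append((np.inf, np.zeros(L), 0, np.nan))
            continue
        # pointwise circular mean, so profiles near +/-180 deg do not tear
        mean_curve = np.degrees(np.arctan2(
            np.sin(rad[members]).mean(axis=0),
            np.cos(rad[members]).mean(axis=0)))
        cm = circular_mean_deg(mean_curve)
        order_stats.append((cm, mean_curve, int(members.sum()), cm))
    order = sorted(range(results.K), key=lambda k: (order_stats[k][0], k))
    relabel = np.empty(results.K, dtype=np.int64)
    for new_id, k in enumerate(order, start=1):
        relabel[k] = new_id
    labels = relabel[raw]
    profiles = [
        CoordinationProfile(pattern_id=int(relabel[k]),
                            mean_crp=order_stats[k][1],
                            member_count=int(order_stats[k][2]),
                            circular_mean=float(order_stats[k][3]))
        for k in order
    ]
    return labels, profiles
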