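"""Response-ratio tests and PLS machinery for community-environment paths.

The partial-R2 statistic apportions the variance a PLS (projection to
latent structures) model explains among its predictors:

    partialR2_j = sum_f (W_jf^2 * SSY_f) / SSY
                = R2Y * VIP_j^2 / p

where W_jf is the (unit-norm) weight of predictor j on component f, SSY_f
the response sum of squares explained by component f, SSY the total
response sum of squares and p the number of predictors. Because the
weights are unit-norm per component, the partial R2 values of all
predictors sum exactly to R2Y.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.stats.ordination import pcoa as _skbio_pcoa

__all__ = [
    "response_ratio_test",
    "bray_curtis",
    "pcoa_axes",
    "PLSModel",
    "PLSResults",
    "pls_fit",
    "pls_permutation_test",
    "forward_select_pls",
]


# ---------------------------------------------------------------------------
# response ratio
# ---------------------------------------------------------------------------

@dataclass
class ResponseRatioResult:
    rr: float
    se: float
    ci_low: float
    ci_high: float
    significant: bool
    alternative: str


def response_ratio_test(mean_t: float, sd_t: float, n_t: int,
                        mean_c: float, sd_c: float, n_c: int,
                        level: float = 0.95,
                        alternative: str = "two-sided",
                        ) -> ResponseRatioResult:
    """Log response ratio z-test for a treatment/control contrast.

    RR = ln(mean_t / mean_c) with delta-method standard error
    SE^2 = sd_t^2/(n_t mean_t^2) + sd_c^2/(n_c mean_c^2). ``alternative``
    'greater'/'less' gives a one-sided interval (the unbounded side is
    +-inf); significance means the interval excludes zero.
    """
    if mean_t <= 0 or mean_c <= 0:
        raise ValueError("group means must be positive for a log ratio")
    if n_t < 2 or n_c < 2 or sd_t < 0 or sd_c < 0:
        raise ValueError("need n >= 2 and nonnegative sd per group")
    rr = float(np.log(mean_t / mean_c))
    se = float(np.sqrt(sd_t ** 2 / (n_t * mean_t ** 2)
                       + sd_c ** 2 / (n_c * mean_c ** 2)))
    if alternative == "two-sided":
        z = sps.norm.ppf(0.5 + level / 2.0)
        lo, hi = rr - z * se, rr + z * se
    elif alternative == "greater":
        z = sps.norm.ppf(level)
        lo, hi = rr - z * se, float("inf")
    elif alternative == "less":
        z = sps.norm.ppf(level)
        lo, hi = float("-inf"), rr + z * se
    else:
        raise ValueError("alternative must be two-sided, greater or less")
    sig = bool(lo > 0 or hi < 0)
    return ResponseRatioResult(rr, se, lo, hi, sig, alternative)


# ---------------------------------------------------------------------------
# ordination front end
# ---------------------------------------------------------------------------

def bray_curtis(counts: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Bray-Curtis dissimilarity matrix from a samples x taxa count table."""
    x = np.asarray(counts, float)
    if np.any(x < 0):
        raise ValueError("negative counts")
    return squareform(pdist(x, metric="braycurtis"))


def pcoa_axes(distance_matrix: np.ndarray, k: int = 7) -> np.ndarray:
    """Classical metric-scaling coordinates on the top positive axes.

    Returns an (n_samples, k') coordinate matrix with k' = min(k, number
    of positive eigenvalues); a warning notes any shortfall.
    """
    dm = np.asarray(distance_matrix, float)
    if dm.ndim != 2 or dm.shape[0] != dm.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(dm, dm.T) or not np.allclose(np.diag(dm), 0):
        raise ValueError("distance matrix must be symmetric, zero diagonal")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # skbio warns on negative eigenvalues
        res = _skbio_pcoa(DistanceMatrix(dm), method="eigh",
                          number_of_dimensions=0)
    pos = res.eigvals[res.eigvals > 1e-10]
    k_eff = min(k, len(pos))
    if k_eff < k:
        warnings.warn(f"only {k_eff} positive-eigenvalue axes available",
                      stacklevel=2)
    return res.samples.to_numpy()[:, :k_eff]


# ---------------------------------------------------------------------------
# PLS1 (NIPALS) with per-component explained response sums of squares
# ---------------------------------------------------------------------------

@dataclass
class PLSResults:
    """Fitted single-response PLS model.

    ``weights`` is (p, f) with unit-norm columns; ``ssy_f`` the response
    sum of squares explained by each component (in standardized units);
    ``ssy`` the total response sum of squares.
    """

    weights: np.ndarray
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    scores: np.ndarray
    ssy_f: np.ndarray
    ssy: float
    r2y: float
    q2y: float
    n_components: int
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    y_scale: float
    feature_names: list[str] | None = None

    @property
    def ssy_cum(self) -> float:
        return float(self.ssy_f.sum())

    def coefficients(self) -> np.ndarray:
        """Regression coefficients in standardized X/Y units."""
        w, pl, c = self.weights, self.x_loadings, self.y_loadings
        if w.shape[1] == 0:
            return np.zeros(w.shape[0])
        return w @ np.linalg.solve(pl.T @ w, c)

    def predict(self, x: np.ndarray) -> np.ndarray:
        xs = (np.asarray(x, float) - self.x_mean) / self.x_scale
        return self.y_mean + self.y_scale * (xs @ self.coefficients())

    def vip(self) -> np.ndarray:
        p = self.weights.shape[0]
        num = (self.weights ** 2) @ self.ssy_f
        return np.sqrt(p * num / self.ssy_cum)

    def partial_r2(self) -> np.ndarray:
        return ((self.weights ** 2) @ self.ssy_f) / self.ssy

    def summary(self) -> pd.DataFrame:
        names = self.feature_names or [f"x{j}" for j
                                       in range(self.weights.shape[0])]
        return pd.DataFrame({"predictor": names, "vip": self.vip(),
                             "partial_r2": self.partial_r2()})


class PLSModel:
    """Single-response projection to latent structures, NIPALS algorithm.

    Predictors and response are centred and scaled internally. The number
    of components defaults to the maximiser of cross-validated Q2Y.
    """

    def __init__(self, x: np.ndarray | pd.DataFrame, y: np.ndarray,
                 scale: bool = True):
        self.feature_names = (list(x.columns)
                              if isinstance(x, pd.DataFrame) else None)
        self.x = np.asarray(x, float)
        self.y = np.asarray(y, float).ravel()
        if self.x.ndim != 2 or len(self.y) != self.x.shape[0]:
            raise ValueError("X must be (n, p) matching y")
        if np.ptp(self.y) == 0:
            raise ValueError("constant response")
        self.scale = scale

    # -- internals --------------------------------------------------------
    def _standardize(self, x: np.ndarray, y: np.ndarray):
        xm, ym = x.mean(axis=0), y.mean()
        xs = x.std(axis=0, ddof=1) if self.scale else np.ones(x.shape[1])
        xs = np.where(xs > 0, xs, 1.0)
        ys = y.std(ddof=1) if self.scale else 1.0
        return (x - xm) / xs, (y - ym) / ys, xm, xs, ym, ys

    @staticmethod
    def _nipals(x0: np.ndarray, y0: np.ndarray, n_comp: int):
        n, p = x0.shape
        x, y = x0.copy(), y0.copy()
        ws, ps, cs, ts, ssy_f = [], [], [], [], []
        for _ in range(n_comp):
            xy = x.T @ y
            nrm = np.linalg.norm(xy)
            if nrm < 1e-12:
                break
            w = xy / nrm
            t = x @ w
            tt = t @ t
            if tt < 1e-12:
                break
            pl = x.T @ t / tt
            c = y @ t / tt
            before = y @ y
            x = x - np.outer(t, pl)
            y = y - c * t
            ssy_f.append(before - y @ y)
            ws.append(w)
            ps.append(pl)
            cs.append(c)
            ts.append(t)
        if not ws:  # response orthogonal to every predictor
            return (np.zeros((p, 0)), np.zeros((p, 0)), np.zeros(0),
                    np.zeros((n, 0)), np.zeros(0))
        return (np.array(ws).T, np.array(ps).T, np.array(cs),
                np.array(ts).T, np.array(ssy_f))

    def _q2(self, n_comp: int, cv_folds: int) -> float:
        n = len(self.y)
        folds = np.arange(n) % cv_folds
        press, ss = 0.0, 0.0
        for fold in range(cv_folds):
            test = folds == fold
            if test.all() or (~test).all():
                continue
            xt, yt = self.x[~test], self.y[~test]
            x0, y0, xm, xs, ym, ys = self._standardize(xt, yt)
            w, pl, c, _, _ = self._nipals(x0, y0, n_comp)
            if w.size == 0:
                return float("-inf")
            b = w @ np.linalg.solve(pl.T @ w, c)
            pred = ym + ys * (((self.x[test] - xm) / xs) @ b)
            press += float(np.sum((self.y[test] - pred) ** 2))
            ss += float(np.sum((self.y[test] - yt.mean()) ** 2))
        return 1.0 - press / ss if ss > 0 else float("-inf")

    # -- public -----------------------------------------------------------
    def fit(self, n_components: int | None = None,
            cv_folds: int = 7) -> PLSResults:
        n, p = self.x.shape
        cv_folds = min(cv_folds, n)
        max_comp = min(p, n - 1, 5)
        if n_components is None:
            q2s = [(self._q2(f, cv_folds), f)
                   for f in range(1, max_comp + 1)]
            q2y, n_components = max(q2s)
        else:
            q2y = self._q2(n_components, cv_folds)
        x0, y0, xm, xs, ym, ys = self._standardize(self.x, self.y)
        w, pl, c, t, ssy_f = self._nipals(x0, y0, n_components)
        ssy = float(y0 @ y0)
        r2y = float(ssy_f.sum() / ssy)
        return PLSResults(weights=w, x_loadings=pl, y_loadings=c, scores=t,
                          ssy_f=ssy_f, ssy=ssy, r2y=r2y, q2y=float(q2y),
                          n_components=w.shape[1], x_mean=xm, x_scale=xs,
                          y_mean=ym, y_scale=ys,
                          feature_names=self.feature_names)


def pls_fit(x: np.ndarray, y: np.ndarray, n_components: int | None = None,
            cv_folds: int = 7) -> PLSResults:
    """Convenience wrapper: fit a PLS1 model, choosing components by Q2Y."""
    return PLSModel(x, y).fit(n_components=n_components, cv_folds=cv_folds)


def pls_permutation_test(x: np.ndarray, y: np.ndarray, n_perm: int = 1000,
                         seed: int = 0, n_components: int | None = None,
                         cv_folds: int = 7) -> dict[str, float]:
    """Permutation p-values for R2Y and Q2Y.

    The response is permuted, the model refit with the same component
    count, and p = (1 + #{stat_perm >= stat_obs}) / (1 + n_perm).
    """
    if n_perm < 100:
        warnings.warn("fewer than 100 permutations gives coarse p-values",
                      stacklevel=2)
    obs = pls_fit(x, y, n_components=n_components, cv_folds=cv_folds)
    rng = np.random.default_rng(seed)
    y = np.asarray(y, float).ravel()
    ge_r2 = ge_q2 = 0
    for _ in range(n_perm):
        yp = rng.permutation(y)
        try:
            perm = pls_fit(x, yp, n_components=obs.n_components,
                           cv_folds=cv_folds)
        except ValueError:
            continue
        ge_r2 += perm.r2y >= obs.r2y
        ge_q2 += perm.q2y >= obs.q2y
    return {"r2y": obs.r2y, "q2y": obs.q2y,
            "p_r2y": (1 + ge_r2) / (1 + n_perm),
            "p_q2y": (1 + ge_q2) / (1 + n_perm),
            "n_components": obs.n_components}


def forward_select_pls(candidates: pd.DataFrame, y: np.ndarray,
                       alpha: float = 0.05, n_perm: int = 200, seed: int = 0,
                       cv_folds: int = 7,
                       ) -> tuple[list[str], PLSResults | None]:
    """Greedy forward selection of predictors by cross-validated Q2Y.

    At each step the candidate whose addition maximises Q2Y is tried; it
    is kept only if the resulting model is permutation-significant for
    both R2Y and Q2Y at ``alpha``. Returns the selected column names and
    the final fitted model (or ``(([], None)`` when nothing is
    significant).
    """
    y = np.asarray(y, float).ravel()
    remaining = list(candidates.columns)
    selected: list[str] = []
    best_model: PLSResults | None = None
    rng = np.random.default_rng(seed)
    while remaining:
        scored = []
        for name in remaining:
            cols = selected + [name]
            try:
                res = pls_fit(candidates[cols].to_numpy(), y,
                              cv_folds=cv_folds)
            except ValueError:
                continue
            scored.append((res.q2y, name, res))
        if not scored:
            break
        _, best_name, res = max(scored, key=lambda s: (s[0], s[1]))
        cols = selected + [best_name]
        pvals = pls_permutation_test(candidates[cols].to_numpy(), y,
                                     n_perm=n_perm,
                                     seed=int(rng.integers(2 ** 31)),
                                     cv_folds=cv_folds)
        if pvals["p_r2y"] < alpha and pvals["p_q2y"] < alpha:
            selected.append(best_name)
            remaining.remove(best_name)
            best_model = pls_fit(candidates[selected].to_numpy(), y,
                                 cv_folds=cv_folds)
            best_model.feature_names = list(selected)
        else:
            break
    return selected, best_model
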