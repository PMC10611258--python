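"""Multiple-comparison and multivariate test statistics.

Two procedures live here because the scoring and integration stages both
need them:

* **Dunnett's many-to-one comparison** of k treatment groups against a
  shared control. The two-sided adjusted p-value for treatment i is
  ``P(max_j |T_j| >= |t_i|)`` under the joint null, where the T_j share
  the control mean and the pooled variance estimate. Their correlation
  matrix has the one-factor form ``rho_ij = lambda_i lambda_j`` with
  ``lambda_i = sqrt(n_i / (n_i + n_0))``, so the (k+1)-dimensional
  probability reduces to a double integral over the shared standard
  normal factor and the pooled-SD scale, which we evaluate with
  Gauss-Hermite x Gauss-Legendre quadrature. The quadrature is fully
  deterministic and accurate to well below 1e-6, which the pipeline's
  reproducibility contract requires.

* **Wilks' Lambda one-way MANOVA** with Rao's F transformation, exact for
  the two-group case used in pairwise compound separation (where it is
  equivalent to Hotelling's T^2).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, special, stats as sps

__all__ = [
    "DunnettQuadrature", "dunnett_pvalues", "dunnett_critical_value",
    "dunnett_from_samples", "WilksResult", "wilks_manova",
]


class DunnettQuadrature:
    """Precomputed quadrature for one Dunnett design (n_treat, n_control).

    Reusable across many observed statistics, e.g. in simulation studies.
    """

    def __init__(self, n_treat: Sequence[int], n_control: int,
                 df: float | None = None, n_hermite: int = 128,
                 n_legendre: int = 512):
        n_treat = np.asarray(n_treat, dtype=float)
        if n_treat.ndim != 1 or n_treat.size < 1:
            raise ValueError("need at least one treatment group")
        if np.any(n_treat < 2) or n_control < 2:
            raise ValueError("all group sizes must be >= 2")
        self.n_treat = n_treat
        self.n_control = float(n_control)
        self.df = float(df) if df is not None else float(
            n_treat.sum() + n_control - (n_treat.size + 1))
        lam = np.sqrt(n_treat / (n_treat + n_control))
        self._lam = lam
        self._s = np.sqrt(1.0 - lam ** 2)
        xh, wh = special.roots_hermite(n_hermite)
        self._z = np.sqrt(2.0) * xh
        self._wz = wh / np.sqrt(np.pi)
        xg, wg = special.roots_legendre(n_legendre)
        q = 0.5 * (xg + 1.0)
        self._wq = 0.5 * wg
        self._u = np.sqrt(sps.chi2.ppf(q, self.df) / self.df)

    def cdf_max_abs(self, t: np.ndarray | float) -> np.ndarray:
        """P(max_j |T_j| <= t) under the joint null, vectorized over t."""
        t = np.atleast_1d(np.abs(np.asarray(t, dtype=float)))
        out = np.empty(t.shape)
        # (T, U, Z, K) in chunks over T to bound memory
        u = self._u[None, :, None, None]
        z = self._z[None, None, :, None]
        lam = self._lam[None, None, None, :]
        s = self._s[None, None, None, :]
        chunk = max(1, int(2e7 // (self._u.size * self._z.size * self._lam.size)))
        for i in range(0, t.size, chunk):
            tt = t[i:i + chunk][:, None, None, None]
            a = special.ndtr((tt * u - lam * z) / s)
            b = special.ndtr((-tt * u - lam * z) / s)
            prod = np.prod(a - b, axis=3)
            out[i:i + chunk] = np.einsum("j,k,tjk->t", self._wq, self._wz, prod)
        return out

    def pvalues(self, t_stats: np.ndarray | float) -> np.ndarray:
        """Two-sided adjusted p-values for observed statistics."""
        return np.clip(1.0 - self.cdf_max_abs(t_stats), 0.0, 1.0)

    def critical_value(self, alpha: float = 0.05) -> float:
        """t* with P(max |T_j| > t*) = alpha (two-sided)."""
        f = lambda t: self.cdf_max_abs(t)[0] - (1.0 - alpha)
        return float(optimize.brentq(f, 1e-6, 50.0, xtol=1e-10))


def dunnett_pvalues(t_stats, n_treat, n_control, df=None) -> np.ndarray:
    return DunnettQuadrature(n_treat, n_control, df=df).pvalues(t_stats)


def dunnett_critical_value(alpha, n_treat, n_control, df=None) -> float:
    return DunnettQuadrature(n_treat, n_control, df=df).critical_value(alpha)


def dunnett_from_samples(treatments: Sequence[np.ndarray],
                         control: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Observed Dunnett statistics and adjusted p-values from raw samples.

    The variance is pooled over all groups (control included), as in the
    classical procedure.
    """
    control = np.asarray(control, dtype=float)
    groups = [np.asarray(t, dtype=float) for t in treatments]
    n0 = control.size
    ns = np.array([g.size for g in groups])
    if n0 < 2 or np.any(ns < 2):
        raise ValueError("each group needs n >= 2")
    df = n0 + ns.sum() - (len(groups) + 1)
    ss = ((control - control.mean()) ** 2).sum() + sum(
        ((g - g.mean()) ** 2).sum() for g in groups)
    sp2 = ss / df
    if sp2 == 0.0:
        t = np.where([g.mean() != control.mean() for g in groups], np.inf, 0.0)
    else:
        t = np.array([(g.mean() - control.mean()) / np.sqrt(sp2 * (1 / g.size + 1 / n0))
                      for g in groups])
    p = dunnett_pvalues(t, ns, n0, df=df)
    return t, p


@dataclass(frozen=True)
class WilksResult:
    wilks_lambda: float
    f_statistic: float
    df_num: float
    df_den: float
    p_value: float
    n_groups: int
    n_total: int


def wilks_manova(groups: Sequence[np.ndarray]) -> WilksResult:
    """One-way MANOVA via Wilks' Lambda with Rao's F approximation.

    ``groups`` is a sequence of (n_i, p) observation matrices. The F
    transformation is exact for g = 2 (any p) and for p <= 2.
    """
    gs = [np.atleast_2d(np.asarray(g, dtype=float)) for g in groups]
    g = len(gs)
    if g < 2:
        raise ValueError("need at least two groups")
    p = gs[0].shape[1]
    if any(x.shape[1] != p for x in gs):
        raise ValueError("groups must share the same number of variables")
    ns = np.array([x.shape[0] for x in gs])
    n = int(ns.sum())
    if np.any(ns < 2):
        raise ValueError("each group needs n >= 2")
    if n - g < p:
        raise ValueError("within-group covariance is rank deficient")
    grand = np.vstack(gs).mean(axis=0)
    W = np.zeros((p, p))
    B = np.zeros((p, p))
    for x in gs:
        m = x.mean(axis=0)
        c = x - m
        W += c.T @ c
        d = (m - grand)[:, None]
        B += x.shape[0] * (d @ d.T)

    # Degenerate inputs (e.g. every sample of every group identical on an
    # axis) make the total SSCP singular; restrict the test to the subspace
    # with actual variation. If nothing varies there is no evidence: p = 1.
    T = W + B
    evals, evecs = np.linalg.eigh(T)
    keep = evals > max(evals.max(), 0.0) * 1e-12
    if not keep.any():
        return WilksResult(1.0, 0.0, float(p * (g - 1)), float(n - g), 1.0, g, n)
    if not keep.all():
        V = evecs[:, keep]
        W = V.T @ W @ V
        T = V.T @ T @ V
        p = int(keep.sum())
    detW = np.linalg.det(W)
    detT = np.linalg.det(T)
    lam = float(max(detW, 0.0) / detT)

    q = g - 1
    denom = p * p + q * q - 5
    t = np.sqrt((p * p * q * q - 4) / denom) if denom > 0 else 1.0
    w = n - 1 - (p + g) / 2.0
    df1 = p * q
    df2 = w * t - (df1 - 2) / 2.0
    lam_t = lam ** (1.0 / t)
    if lam_t == 0.0:
        f = np.inf
    else:
        f = (1.0 - lam_t) / lam_t * df2 / df1
    pval = float(sps.f.sf(f, df1, df2))
    return WilksResult(lam, float(f), float(df1), float(df2), pval, g, n)
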