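"""Univariable two-sample MR estimators and diagnostics.

Every estimator consumes a :class:`~mrmediate.gwas_io.HarmonizedSet`.  The
per-SNP building block is the Wald ratio theta_j = beta_Yj / beta_Xj with
first-order standard error se_Yj / |beta_Xj| and inverse-variance weight
w_j = 1 / se_theta_j^2.

* :func:`ivw` — inverse-variance-weighted meta-analysis of the Wald ratios,
  the primary estimator; multiplicative random-effects by default (the SE is
  inflated by sqrt(Q/df) when Cochran's Q exceeds its degrees of freedom, and
  never deflated below the fixed-effect SE).
* :func:`mr_egger` — weighted regression of beta_Y on beta_X with an
  intercept; a nonzero intercept estimates average directional pleiotropy.
* :func:`weighted_median` / :func:`weighted_mode` — estimators robust to
  invalid instruments, with parametric-bootstrap standard errors.
* :func:`leave_one_out` — IVW recomputed dropping each SNP in turn.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .gwas_io import HarmonizedSet

__all__ = [
    "Z95",
    "RatioEstimates",
    "MREstimate",
    "InterceptEstimate",
    "EggerResult",
    "QResult",
    "wald_ratios",
    "ivw",
    "mr_egger",
    "weighted_median",
    "weighted_mode",
    "leave_one_out",
]

#: two-sided 95% normal critical value
Z95 = float(stats.norm.ppf(0.975))


def _normal_p(beta: float, se: float) -> float:
    if se == 0:
        return 0.0 if beta != 0 else 1.0
    return float(2.0 * stats.norm.sf(abs(beta) / se))


@dataclass(frozen=True)
class MREstimate:
    """A causal-effect estimate on the beta (log-odds or SD) scale."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snp: int

    @classmethod
    def from_beta_se(cls, method: str, beta: float, se: float, n_snp: int,
                     pval: float | None = None) -> "MREstimate":
        return cls(
            method=method,
            beta=float(beta),
            se=float(se),
            ci_low=float(beta - Z95 * se),
            ci_high=float(beta + Z95 * se),
            pval=_normal_p(beta, se) if pval is None else float(pval),
            n_snp=int(n_snp),
        )

    @property
    def or_view(self) -> tuple[float, float, float]:
        """(OR, CI low, CI high): the exponentiated view of the estimate."""
        return (float(np.exp(self.beta)), float(np.exp(self.ci_low)), float(np.exp(self.ci_high)))


@dataclass(frozen=True)
class InterceptEstimate:
    """Egger intercept: average directional pleiotropy per SNP."""

    value: float
    se: float
    pval: float


@dataclass(frozen=True)
class EggerResult:
    slope: MREstimate
    intercept: InterceptEstimate


@dataclass(frozen=True)
class QResult:
    """Cochran's Q heterogeneity statistic for the Wald ratios."""

    q: float
    df: int
    pval: float


@dataclass
class RatioEstimates:
    """Per-SNP Wald ratios, first-order SEs and inverse-variance weights."""

    snp_ids: np.ndarray
    theta: np.ndarray
    se_theta: np.ndarray
    weight: np.ndarray
    dropped: list

    def __len__(self) -> int:
        return len(self.theta)


def wald_ratios(hs: HarmonizedSet) -> RatioEstimates:
    """Per-SNP ratio estimates; SNPs with beta_X == 0 are dropped and logged."""
    nonzero = hs.beta_exposure != 0
    dropped = [(sid, "zero exposure effect") for sid in hs.snp_ids[~nonzero]]
    bx = hs.beta_exposure[nonzero]
    by = hs.beta_outcome[nonzero]
    sy = hs.se_outcome[nonzero]
    theta = by / bx
    se_theta = sy / np.abs(bx)
    return RatioEstimates(
        snp_ids=hs.snp_ids[nonzero],
        theta=theta,
        se_theta=se_theta,
        weight=1.0 / se_theta**2,
        dropped=dropped,
    )


def ivw(hs: HarmonizedSet, model: str = "random") -> tuple[MREstimate, QResult]:
    """Inverse-variance-weighted estimate with Cochran's Q.

    ``model="fixed"`` uses SE = (sum w)^-1/2; ``model="random"``
    (multiplicative random effects, the default) multiplies that SE by
    max(1, sqrt(Q / (m - 1))).
    """
    if model not in ("fixed", "random"):
        raise ValueError(f"model must be fixed|random, got {model!r}")
    r = wald_ratios(hs)
    m = len(r)
    if m < 2:
        raise ValueError("insufficient instruments: IVW requires >= 2 SNPs")
    sw = r.weight.sum()
    beta = float((r.weight * r.theta).sum() / sw)
    q = float((r.weight * (r.theta - beta) ** 2).sum())
    df = m - 1
    se = float(sw**-0.5)
    if model == "random":
        se *= max(1.0, np.sqrt(q / df))
    est = MREstimate.from_beta_se("IVW", beta, se, m)
    return est, QResult(q=q, df=df, pval=float(stats.chi2.sf(q, df)))


def mr_egger(hs: HarmonizedSet, use_t: bool = False) -> EggerResult:
    """MR-Egger regression with intercept (directional-pleiotropy test).

    SNPs are oriented so beta_X >= 0; beta_Y is regressed on beta_X with
    weights 1/se_Y^2.  Standard errors carry a multiplicative overdispersion
    factor max(1, residual SD).  P-values are normal by default, or
    t with m - 2 df when ``use_t``.
    """
    m = len(hs)
    if m < 3:
        raise ValueError("insufficient instruments: MR-Egger requires >= 3 SNPs")
    sign = np.where(hs.beta_exposure < 0, -1.0, 1.0)
    x = hs.beta_exposure * sign
    y = hs.beta_outcome * sign
    w = 1.0 / hs.se_outcome**2
    res = sm.WLS(y, sm.add_constant(x), weights=w).fit()
    # res.scale is the weighted residual variance; never deflate the SEs
    infl = max(1.0, float(np.sqrt(res.scale)))
    se_unscaled = res.bse / np.sqrt(res.scale)
    se = se_unscaled * infl
    if use_t:
        pvals = 2.0 * stats.t.sf(np.abs(res.params / se), m - 2)
    else:
        pvals = 2.0 * stats.norm.sf(np.abs(res.params / se))
    slope = MREstimate.from_beta_se("MR-Egger", res.params[1], se[1], m, pval=pvals[1])
    intercept = InterceptEstimate(float(res.params[0]), float(se[0]), float(pvals[0]))
    return EggerResult(slope=slope, intercept=intercept)


def _weighted_median_rows(theta: np.ndarray, weight: np.ndarray) -> np.ndarray:
    """Row-wise weighted median with the standard cumulative-weight interpolation.

    ``theta`` and ``weight`` are (B, m); returns length-B estimates.  The
    standardized cumulative weight p_j = (S_j - w_j/2) / S_m is interpolated
    at 0.5.
    """
    order = np.argsort(theta, axis=1)
    th = np.take_along_axis(theta, order, axis=1)
    w = np.take_along_axis(weight, order, axis=1)
    s = np.cumsum(w, axis=1)
    p = (s - w / 2.0) / s[:, -1:]
    m = th.shape[1]
    k = (p < 0.5).sum(axis=1)  # index of first p >= 0.5
    k_hi = np.clip(k, 0, m - 1)
    k_lo = np.clip(k - 1, 0, m - 1)
    rows = np.arange(th.shape[0])
    p_lo, p_hi = p[rows, k_lo], p[rows, k_hi]
    t_lo, t_hi = th[rows, k_lo], th[rows, k_hi]
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(p_hi > p_lo, (0.5 - p_lo) / (p_hi - p_lo), 1.0)
    est = t_lo + frac * (t_hi - t_lo)
    est = np.where(k == 0, th[:, 0], est)
    est = np.where(k == m, th[:, -1], est)
    return est


def _bootstrap_draws(hs: HarmonizedSet, n_boot: int, rng: np.random.Generator):
    """Parametric bootstrap of the harmonized betas from their sampling normals."""
    bx = hs.beta_exposure + rng.standard_normal((n_boot, len(hs))) * hs.se_exposure
    by = hs.beta_outcome + rng.standard_normal((n_boot, len(hs))) * hs.se_outcome
    return bx, by


def weighted_median(hs: HarmonizedSet, n_boot: int = 5000, seed: int = 0) -> MREstimate:
    """Weighted-median estimator (valid if >=50% of weight is on valid SNPs).

    The SE is a parametric bootstrap: exposure and outcome betas are resampled
    from their normal sampling distributions ``n_boot`` times (seeded) and the
    estimator recomputed on each draw.
    """
    m = len(hs)
    if m < 3:
        raise ValueError("insufficient instruments: weighted median requires >= 3 SNPs")
    r = wald_ratios(hs)
    est = float(_weighted_median_rows(r.theta[None, :], r.weight[None, :])[0])
    rng = np.random.default_rng(seed)
    bx, by = _bootstrap_draws(hs, n_boot, rng)
    ok = bx != 0
    bx = np.where(ok, bx, np.finfo(float).tiny)
    theta = by / bx
    weight = (bx / hs.se_outcome) ** 2
    boots = _weighted_median_rows(theta, weight)
    se = float(boots.std(ddof=1))
    return MREstimate.from_beta_se("weighted median", est, se, m)


def _silverman_bandwidth(theta: np.ndarray, factor: float) -> float:
    sd = float(np.std(theta, ddof=1))
    q75, q25 = np.percentile(theta, [75, 25])
    iqr = float(q75 - q25)
    candidates = [s for s in (sd, iqr / 1.34) if s > 0]
    if not candidates:
        return 0.0
    return factor * 0.9 * min(candidates) * len(theta) ** (-1.0 / 5.0)


def _mode_rows(theta: np.ndarray, weight: np.ndarray, factor: float, grid_size: int = 512) -> np.ndarray:
    """Row-wise weighted-KDE mode on a fixed per-row grid."""
    B, m = theta.shape
    out = np.empty(B)
    h = np.array([_silverman_bandwidth(theta[b], factor) for b in range(B)])
    degenerate = h == 0
    out[degenerate] = theta[degenerate, 0]
    live = np.flatnonzero(~degenerate)
    if live.size:
        th = theta[live]
        wn = weight[live] / weight[live].sum(axis=1, keepdims=True)
        hl = h[live]
        lo = th.min(axis=1) - 3 * hl
        hi = th.max(axis=1) + 3 * hl
        grid = lo[:, None] + (hi - lo)[:, None] * np.linspace(0.0, 1.0, grid_size)[None, :]
        # (B', G, m) kernel matrix, chunked over rows to bound memory
        chunk = max(1, int(2e6 // (grid_size * m)))
        for start in range(0, len(live), chunk):
            sl = slice(start, start + chunk)
            z = (grid[sl, :, None] - th[sl, None, :]) / hl[sl, None, None]
            dens = (np.exp(-0.5 * z**2) * wn[sl, None, :]).sum(axis=2)
            out[live[sl]] = grid[sl][np.arange(dens.shape[0]), dens.argmax(axis=1)]
    return out


def weighted_mode(
    hs: HarmonizedSet,
    bandwidth_factor: float = 1.0,
    n_boot: int = 5000,
    seed: int = 0,
) -> MREstimate:
    """Mode-based estimator: the peak of a weighted normal-kernel density.

    Bandwidth follows a Silverman-type rule, bandwidth_factor * 0.9 *
    min(sd, IQR/1.34) * m^(-1/5) over the Wald ratios.  Valid when the largest
    cluster of instruments is valid.  Bootstrap SE as in
    :func:`weighted_median`.  With zero spread in the ratios the common value
    is returned with the inverse-variance SE.
    """
    m = len(hs)
    if m < 3:
        raise ValueError("insufficient instruments: weighted mode requires >= 3 SNPs")
    r = wald_ratios(hs)
    if np.ptp(r.theta) == 0 or _silverman_bandwidth(r.theta, bandwidth_factor) == 0:
        est = float(r.theta[0])
        se = float(r.weight.sum() ** -0.5)
        return MREstimate.from_beta_se("weighted mode", est, se, m)
    est = float(_mode_rows(r.theta[None, :], r.weight[None, :], bandwidth_factor)[0])
    rng = np.random.default_rng(seed)
    bx, by = _bootstrap_draws(hs, n_boot, rng)
    bx = np.where(bx != 0, bx, np.finfo(float).tiny)
    theta = by / bx
    weight = (bx / hs.se_outcome) ** 2
    boots = _mode_rows(theta, weight, bandwidth_factor)
    se = float(boots.std(ddof=1))
    return MREstimate.from_beta_se("weighted mode", est, se, m)


def leave_one_out(hs: HarmonizedSet, model: str = "random") -> list[tuple[str, MREstimate]]:
    """IVW recomputed excluding each SNP in turn."""
    m = len(hs)
    if m < 3:
        raise ValueError("leave-one-out requires >= 3 SNPs")
    out = []
    for j in range(m):
        mask = np.ones(m, dtype=bool)
        mask[j] = False
        est, _ = ivw(hs.subset(mask), model=model)
        out.append((str(hs.snp_ids[j]), est))
    return out
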