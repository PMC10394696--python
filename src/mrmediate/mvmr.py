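"""Multivariable MR: direct effects of several exposures on one outcome.

The outcome betas are regressed on the matrix of exposure betas (no
intercept for MV-IVW, with intercept for MVMR-Egger) with weights
1/se_outcome^2.  Each coefficient is the direct effect of that exposure
conditional on the others.  Instruments are the union of the per-exposure
instrument sets, jointly LD-clumped with the best p-value across exposures
deciding precedence, and every table is oriented to the outcome's effect
alleles so all columns share a per-SNP allele convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .gwas_io import SummaryStatsTable, _align_frames
from .instruments import LdInfo, ld_clump, select_significant
from .uvmr import InterceptEstimate, MREstimate

__all__ = ["MVHarmonizedSet", "build_mv_set", "mv_ivw", "mvmr_egger"]

_MAX_CONDITION = 1e8


@dataclass
class MVHarmonizedSet:
    """m SNPs x k exposures of aligned effects plus the outcome vector."""

    snp_ids: np.ndarray
    exposure_labels: list
    beta_matrix: np.ndarray  # (m, k)
    se_matrix: np.ndarray  # (m, k)
    beta_outcome: np.ndarray
    se_outcome: np.ndarray
    dropped: list

    def __post_init__(self) -> None:
        m, k = self.beta_matrix.shape
        if len(self.exposure_labels) != k or len(self.beta_outcome) != m:
            raise ValueError("inconsistent MVMR dimensions")

    @property
    def m(self) -> int:
        return self.beta_matrix.shape[0]

    @property
    def k(self) -> int:
        return self.beta_matrix.shape[1]


def build_mv_set(
    exposures: list[SummaryStatsTable],
    outcome: SummaryStatsTable,
    selections: list[list[str]] | None = None,
    ld: LdInfo | None = None,
    r2_threshold: float = 0.001,
    window_kb: int = 10_000,
    p_threshold: float = 5e-8,
    palindrome_eaf_window: float = 0.08,
    action: str = "infer",
) -> MVHarmonizedSet:
    """Assemble a jointly-harmonized multivariable instrument set.

    ``selections`` may pre-specify instruments per exposure; otherwise each
    exposure is screened at ``p_threshold``.  The union is clumped (best p
    across exposures wins) and all tables are aligned to the outcome's
    orientation with the usual palindrome handling.
    """
    if not exposures:
        raise ValueError("at least one exposure required")
    if selections is None:
        selections = [select_significant(t, p_threshold) for t in exposures]

    # union of instruments with the best p-value any exposure assigns them
    best: dict[str, float] = {}
    for table, sel in zip(exposures, selections):
        pv = table.df.set_index("snp_id")["pval"]
        for snp in sel:
            p = float(pv.get(snp, np.nan))
            if snp not in best or p < best[snp]:
                best[snp] = p
    if not best:
        raise ValueError("no instruments selected for any exposure")

    union = sorted(best)
    if ld is not None:
        pos_source = pd.concat([t.df[["snp_id", "chrom", "pos"]] for t in exposures])
        pos_source = pos_source.drop_duplicates("snp_id").set_index("snp_id")
        cand = pd.DataFrame({
            "snp_id": union,
            "pval": [best[s] for s in union],
        })
        cand["chrom"] = [pos_source["chrom"].get(s) for s in union]
        cand["pos"] = [pos_source["pos"].get(s) for s in union]
        union = ld_clump(cand, ld, r2_threshold=r2_threshold, window_kb=window_kb)

    out_df = outcome.df[outcome.df["snp_id"].isin(set(union))].reset_index(drop=True)
    if out_df.empty:
        raise ValueError("no instrument overlaps the outcome table")

    dropped: list = []
    aligned = []
    common: set[str] | None = None
    for table in exposures:
        frame, drops = _align_frames(out_df, table.df, palindrome_eaf_window, action)
        dropped.extend(drops)
        cols = frame.set_index("snp_id")[["beta_oth", "se_oth"]]
        aligned.append(cols)
        common = set(cols.index) if common is None else common & set(cols.index)

    order = [s for s in out_df["snp_id"] if s in common]
    k = len(exposures)
    if len(order) <= k:
        raise ValueError(
            f"underdetermined MVMR: {len(order)} SNPs for {k} exposures"
        )
    beta = np.column_stack([a.loc[order, "beta_oth"].to_numpy(dtype=float) for a in aligned])
    se = np.column_stack([a.loc[order, "se_oth"].to_numpy(dtype=float) for a in aligned])
    out_idx = out_df.set_index("snp_id")
    return MVHarmonizedSet(
        snp_ids=np.array(order, dtype=object),
        exposure_labels=[t.trait_label for t in exposures],
        beta_matrix=beta,
        se_matrix=se,
        beta_outcome=out_idx.loc[order, "beta"].to_numpy(dtype=float),
        se_outcome=out_idx.loc[order, "se"].to_numpy(dtype=float),
        dropped=dropped,
    )


def _wls(X: np.ndarray, y: np.ndarray, w: np.ndarray, resid_df: int):
    """Weighted least squares with multiplicative overdispersion scaling.

    Returns (coefficients, scaled SEs, Q) where Q is the weighted residual sum
    of squares and the SEs are inflated by max(1, sqrt(Q/resid_df)).
    """
    sw = np.sqrt(w)
    Xw = X * sw[:, None]
    yw = y * sw
    cond = np.linalg.cond(Xw)
    if not np.isfinite(cond) or cond > _MAX_CONDITION:
        raise ValueError(f"singular design: condition number {cond:.3e}")
    coef, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid = yw - Xw @ coef
    q = float(resid @ resid)
    cov_unscaled = np.linalg.inv(Xw.T @ Xw)
    scale = max(1.0, np.sqrt(q / resid_df)) if resid_df > 0 else 1.0
    se = np.sqrt(np.diag(cov_unscaled)) * scale
    return coef, se, q


def mv_ivw(mv: MVHarmonizedSet) -> list[MREstimate]:
    """Multivariable IVW: one direct-effect estimate per exposure.

    No-intercept WLS of the outcome betas on the exposure-beta matrix with
    weights 1/se_outcome^2; SEs carry the multiplicative overdispersion factor
    max(1, sqrt(Q_mv / (m - k))).
    """
    m, k = mv.m, mv.k
    if m <= k:
        raise ValueError("underdetermined MVMR: m must exceed k")
    coef, se, _ = _wls(mv.beta_matrix, mv.beta_outcome, 1.0 / mv.se_outcome**2, m - k)
    return [
        MREstimate.from_beta_se("MV-IVW", coef[i], se[i], m)
        for i in range(k)
    ]


def mvmr_egger(
    mv: MVHarmonizedSet, orient_to: str | None = None
) -> tuple[list[MREstimate], InterceptEstimate]:
    """Multivariable Egger regression; the intercept is the pleiotropy test.

    SNPs are oriented so the ``orient_to`` exposure's beta is non-negative
    (entire rows — all exposures and the outcome — are flipped together,
    which leaves the slopes invariant but gives the intercept its usual
    directional-pleiotropy meaning).
    """
    m, k = mv.m, mv.k
    if m <= k + 1:
        raise ValueError("MVMR-Egger requires m > k + 1")
    if orient_to is None:
        orient_to = mv.exposure_labels[0]
    try:
        col = mv.exposure_labels.index(orient_to)
    except ValueError:
        raise ValueError(f"unknown exposure label {orient_to!r}") from None
    sign = np.where(mv.beta_matrix[:, col] < 0, -1.0, 1.0)
    X = np.column_stack([np.ones(m), mv.beta_matrix * sign[:, None]])
    y = mv.beta_outcome * sign
    coef, se, _ = _wls(X, y, 1.0 / mv.se_outcome**2, m - k - 1)
    z = np.abs(coef / se)
    pvals = 2.0 * stats.norm.sf(z)
    estimates = [
        MREstimate.from_beta_se("MVMR-Egger", coef[i + 1], se[i + 1], m, pval=pvals[i + 1])
        for i in range(k)
    ]
    intercept = InterceptEstimate(float(coef[0]), float(se[0]), float(pvals[0]))
    return estimates, intercept
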