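"""Two-step MR mediation: indirect effects and proportions mediated.

Step 1 estimates beta1, the causal effect of the exposure on each candidate
mediator (univariable IVW).  Step 2 estimates beta2, the effect of the
mediator on the outcome conditional on the exposure (multivariable IVW).  The
indirect (mediated) effect is beta1 * beta2; dividing by the total effect of
the exposure on the outcome gives the proportion mediated.  Standard errors
come from the first-order delta method with the beta1/beta2 (and
indirect/total) covariances set to zero — the two-sample, non-overlapping
design assumption.

Proportions can legitimately fall outside [0, 1] when paths oppose the total
effect or sampling noise dominates; they are reported as computed, with a
warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .gwas_io import SummaryStatsTable, harmonize
from .instruments import LdInfo, ld_clump, select_significant
from .mvmr import build_mv_set, mv_ivw
from .uvmr import Z95, MREstimate, ivw

__all__ = [
    "MediationResult",
    "TwoStepResult",
    "screen_mediators",
    "indirect_effect",
    "proportion_mediated",
    "two_step_mediation",
]


@dataclass(frozen=True)
class MediationResult:
    """Per-mediator decomposition of the exposure -> outcome effect."""

    mediator_label: str
    beta1: float
    se1: float
    beta2: float
    se2: float
    total: float
    se_total: float
    indirect: float
    se_indirect: float
    proportion: float
    se_proportion: float
    ci_indirect: tuple[float, float]
    ci_proportion: tuple[float, float]


@dataclass
class TwoStepResult:
    """Full two-step output: components plus the per-mediator decompositions."""

    total: MREstimate
    step1: dict  # label -> MREstimate (exposure -> mediator)
    step2: dict  # label -> MREstimate (mediator -> outcome | exposure)
    screened: list
    results: list  # MediationResult for mediators passing the screen


def screen_mediators(
    exposure_on_mediators: Mapping[str, MREstimate],
    mediators_on_outcome_adj: Mapping[str, MREstimate],
    alpha_bonferroni: float | None = None,
) -> list[str]:
    """Mediators significant in both directions at the Bonferroni threshold.

    ``alpha_bonferroni`` defaults to 0.05 divided by the number of candidate
    mediators.  Direction of effect is not required to agree.
    """
    labels = list(exposure_on_mediators)
    if set(labels) != set(mediators_on_outcome_adj):
        raise ValueError("step-1 and step-2 results must cover the same mediators")
    if alpha_bonferroni is None:
        alpha_bonferroni = 0.05 / max(1, len(labels))
    return [
        lab
        for lab in labels
        if exposure_on_mediators[lab].pval < alpha_bonferroni
        and mediators_on_outcome_adj[lab].pval < alpha_bonferroni
    ]


def indirect_effect(beta1: float, se1: float, beta2: float, se2: float) -> tuple[float, float]:
    """Indirect effect beta1*beta2 with its first-order delta-method SE.

    se = sqrt(beta2^2 se1^2 + beta1^2 se2^2), assuming cov(beta1, beta2) = 0.
    """
    if se1 <= 0 or se2 <= 0:
        raise ValueError("standard errors must be positive")
    indirect = beta1 * beta2
    se = float(np.sqrt(beta2**2 * se1**2 + beta1**2 * se2**2))
    return float(indirect), se


def proportion_mediated(
    indirect: float, se_indirect: float, total: float, se_total: float
) -> tuple[float, float, tuple[float, float]]:
    """Proportion mediated = indirect / total with a ratio delta-method SE.

    se = |proportion| * sqrt((se_ind/ind)^2 + (se_tot/tot)^2) for a nonzero
    indirect effect (zero covariance assumed); for indirect == 0 it reduces to
    se_indirect / |total|.  Returns (proportion, se, 95% CI).
    """
    if total == 0:
        raise ValueError("total effect is zero; proportion undefined")
    prop = indirect / total
    # algebraically |prop| * sqrt((se_ind/ind)^2 + (se_tot/tot)^2), written
    # without dividing by the indirect effect so that ind -> 0 is stable
    se = float(
        np.sqrt((se_indirect / total) ** 2 + (indirect * se_total / total**2) ** 2)
    )
    ci = (prop - Z95 * se, prop + Z95 * se)
    return float(prop), float(se), (float(ci[0]), float(ci[1]))


def _compose(label: str, b1: MREstimate, b2: MREstimate, total: MREstimate) -> MediationResult:
    ind, se_ind = indirect_effect(b1.beta, b1.se, b2.beta, b2.se)
    prop, se_prop, ci_prop = proportion_mediated(ind, se_ind, total.beta, total.se)
    if not 0.0 <= prop <= 1.0:
        warnings.warn(
            f"proportion mediated for {label!r} is {prop:.3f}, outside [0, 1]",
            RuntimeWarning,
            stacklevel=3,
        )
    return MediationResult(
        mediator_label=label,
        beta1=b1.beta,
        se1=b1.se,
        beta2=b2.beta,
        se2=b2.se,
        total=total.beta,
        se_total=total.se,
        indirect=ind,
        se_indirect=se_ind,
        proportion=prop,
        se_proportion=se_prop,
        ci_indirect=(ind - Z95 * se_ind, ind + Z95 * se_ind),
        ci_proportion=ci_prop,
    )


def two_step_mediation(
    exposure: SummaryStatsTable,
    mediators: Sequence[SummaryStatsTable],
    outcome: SummaryStatsTable,
    ld: LdInfo | None = None,
    p_threshold: float = 5e-8,
    r2_threshold: float = 0.001,
    window_kb: int = 10_000,
    alpha_bonferroni: float | None = None,
    ivw_model: str = "random",
    palindrome_eaf_window: float = 0.08,
    action: str = "infer",
) -> TwoStepResult:
    """Run the full two-step mediation analysis.

    Computes the total effect (exposure -> outcome, IVW), beta1 per mediator
    (exposure -> mediator, IVW on the exposure's instruments), beta2 per
    mediator (mediator -> outcome adjusted for the exposure, multivariable
    IVW on the union of instruments), screens mediators at the Bonferroni
    threshold, and composes indirect effects and proportions mediated for the
    mediators that pass.
    """
    exp_instruments = select_significant(exposure, p_threshold)
    if ld is not None and exp_instruments:
        cand = exposure.df[exposure.df["snp_id"].isin(set(exp_instruments))]
        exp_instruments = ld_clump(
            cand[["snp_id", "pval", "chrom", "pos"]], ld, r2_threshold, window_kb
        )
    exp_sub = exposure.filter(exp_instruments)

    total, _ = ivw(
        harmonize(exp_sub, outcome, palindrome_eaf_window, action), model=ivw_model
    )

    step1: dict[str, MREstimate] = {}
    step2: dict[str, MREstimate] = {}
    for med in mediators:
        b1, _ = ivw(
            harmonize(exp_sub, med, palindrome_eaf_window, action), model=ivw_model
        )
        step1[med.trait_label] = b1
        mv = build_mv_set(
            [med, exposure],
            outcome,
            ld=ld,
            r2_threshold=r2_threshold,
            window_kb=window_kb,
            p_threshold=p_threshold,
            palindrome_eaf_window=palindrome_eaf_window,
            action=action,
        )
        step2[med.trait_label] = mv_ivw(mv)[0]

    screened = screen_mediators(step1, step2, alpha_bonferroni)
    results = [_compose(lab, step1[lab], step2[lab], total) for lab in screened]
    return TwoStepResult(
        total=total, step1=step1, step2=step2, screened=screened, results=results
    )
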