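"""Synthetic GWAS summary statistics with known causal structure.

The generator emulates the kind of consortium summary data a two-sample MR
study consumes: one binary exposure GWAS (childhood-obesity-like,
case-control on the log-odds scale), several continuous mediator GWAS
(lipid-trait-like), optional continuous covariate GWAS (adult-adiposity-like)
and one binary outcome GWAS (GDM-like).  Summary statistics are simulated
directly on the beta/SE scale — two-sample MR never touches genotypes — with
per-SNP standard errors from the standard single-SNP approximations

    continuous trait:  se = 1 / sqrt(2 p (1-p) N)
    binary trait:      se = 1 / sqrt(2 p (1-p) N phi (1-phi))

where p is the effect-allele frequency and phi the case fraction.

The causal structure is linear with no interactions.  Each exposure
instrument j has true effect b_j on the exposure; its effect on mediator k is
alpha_k * b_j, and on the outcome tau_direct * b_j + sum_k gamma_k alpha_k b_j
= tau_total * b_j.  Each mediator (and covariate) additionally has its own
instruments affecting the outcome only through it.  Optional pleiotropy adds
direct SNP -> outcome effects to exposure instruments (balanced, directional
or single-outlier contamination).  A panel of null SNPs, LD partner SNPs and
configurable allele-orientation/palindrome/incompatibility corruption
exercise instrument selection, clumping and harmonization.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from math import log
import numpy as np
import pandas as pd
from scipy import stats

from .gwas_io import CANONICAL_COLUMNS, SummaryStatsTable
from .instruments import LdInfo

__all__ = [
    "SimulationTruth",
    "SimulatedStudy",
    "simulate_triplet",
    "paper_shaped_scenario",
    "null_scenario",
]

_NONPALINDROMIC_PAIRS = [
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


@dataclass(frozen=True)
class SimulationTruth:
    """True causal parameters and sampling design of a simulated study.

    ``m`` exposure instruments carry the exposure's genetic signal; each
    mediator/covariate gets ``m_per_mediator``/``m_per_covariate`` instruments
    of its own.  ``tau_total`` is the total exposure -> outcome effect
    (log-odds); the direct effect is ``tau_total`` minus all mediated paths.
    Sample sizes drive the per-SNP standard errors.  Instrument strength is
    parameterized by the true per-SNP z score (beta over se), so the expected
    Wald F is roughly ``instrument_z_mean**2 + 1`` regardless of allele
    frequency.
    """

    m: int = 12
    tau_total: float = log(1.21)
    mediator_labels: tuple = ()
    alpha: tuple = ()
    gamma: tuple = ()
    n_mediator: tuple = ()
    m_per_mediator: int = 200
    covariate_labels: tuple = ()
    alpha_cov: tuple = ()
    gamma_cov: tuple = ()
    n_covariate: tuple = ()
    m_per_covariate: tuple = ()
    pleiotropy_mode: str = "none"  # none|balanced|directional|outlier
    pleiotropy_magnitude: float = 0.0
    pleiotropy_fraction: float = 0.0
    n_exposure: int = 13_848
    case_fraction_exposure: float = 5530 / 13_848
    n_outcome: int = 190_879
    case_fraction_outcome: float = 11_279 / 190_879
    instrument_z_mean: float = 6.7
    instrument_z_sd: float = 0.8
    n_null: int = 50
    n_ld_partners: int = 1
    ld_partner_r2: float = 0.9
    allele_flip_fraction: float = 0.5
    palindromic_fraction: float = 0.0
    incompatible_fraction: float = 0.0
    eaf_noise_sd: float = 0.003
    seed: int = 0

    def __post_init__(self) -> None:
        k = len(self.mediator_labels)
        if not (len(self.alpha) == len(self.gamma) == k):
            raise ValueError("alpha/gamma must match mediator_labels")
        if len(self.n_mediator) not in (0, k):
            raise ValueError("n_mediator must match mediator_labels")
        kc = len(self.covariate_labels)
        if not (len(self.alpha_cov) == len(self.gamma_cov) == kc):
            raise ValueError("alpha_cov/gamma_cov must match covariate_labels")
        if self.pleiotropy_mode not in ("none", "balanced", "directional", "outlier"):
            raise ValueError(f"unknown pleiotropy mode {self.pleiotropy_mode!r}")
        if not 0.0 <= self.pleiotropy_fraction <= 1.0:
            raise ValueError("pleiotropy_fraction must lie in [0, 1]")

    @property
    def k(self) -> int:
        return len(self.mediator_labels)

    @property
    def tau_direct(self) -> float:
        """Direct effect: tau_total minus every mediated path (linear identity)."""
        mediated = sum(a * g for a, g in zip(self.alpha, self.gamma))
        mediated += sum(a * g for a, g in zip(self.alpha_cov, self.gamma_cov))
        return self.tau_total - mediated

    @property
    def proportions_mediated(self) -> tuple:
        """True alpha_k * gamma_k / tau_total for each mediator."""
        if self.tau_total == 0:
            raise ValueError("tau_total is zero; proportions undefined")
        return tuple(a * g / self.tau_total for a, g in zip(self.alpha, self.gamma))

    def with_seed(self, seed: int) -> "SimulationTruth":
        return replace(self, seed=seed)


@dataclass
class SimulatedStudy:
    """Everything one simulated study produces, plus its generating truth."""

    exposure: SummaryStatsTable
    mediators: list
    covariates: list
    outcome: SummaryStatsTable
    ld: LdInfo
    truth: SimulationTruth | None
    #: snp_ids of exposure instruments carrying a pleiotropic outcome effect
    pleiotropic_snps: list = field(default_factory=list)


def _se_continuous(eaf: np.ndarray, n: float) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf) * n)


def _se_binary(eaf: np.ndarray, n: float, case_fraction: float) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf) * n * case_fraction * (1.0 - case_fraction))


def _pvalues(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    return np.maximum(2.0 * stats.norm.sf(np.abs(beta) / se), 1e-320)


def simulate_triplet(truth: SimulationTruth) -> SimulatedStudy:
    """Generate one full study (exposure, mediators, covariates, outcome, LD).

    All tables share a SNP panel.  Per SNP and trait, the observed beta is the
    true effect plus Normal(0, se) noise; p-values are two-sided Wald.  A
    single seed governs all draws through per-purpose substreams, so output is
    byte-identical for a fixed truth.
    """
    k = truth.k
    kc = len(truth.covariate_labels)
    n_med = truth.n_mediator or tuple([100_000] * k)
    m_per_cov = truth.m_per_covariate or tuple([truth.m_per_mediator] * kc)

    streams = np.random.SeedSequence(truth.seed).spawn(6 + k + kc)
    rng_panel = np.random.default_rng(streams[0])
    rng_expo = np.random.default_rng(streams[1])
    rng_out = np.random.default_rng(streams[2])
    rng_pleio = np.random.default_rng(streams[3])
    rng_orient = np.random.default_rng(streams[4])
    rng_eaf = np.random.default_rng(streams[5])
    rng_med = [np.random.default_rng(s) for s in streams[6 : 6 + k]]
    rng_cov = [np.random.default_rng(s) for s in streams[6 + k :]]

    per_locus = 1 + truth.n_ld_partners
    n_expo_snps = truth.m * per_locus
    group_sizes = [n_expo_snps, *([truth.m_per_mediator] * k), *m_per_cov, truth.n_null]
    total = sum(group_sizes)

    # --- panel: ids, positions, alleles, frequencies -------------------------
    snp_ids = np.array([f"rs{i + 1:06d}" for i in range(total)], dtype=object)
    # loci 1.5 Mb apart within a chromosome; LD partners sit 25 kb from their
    # index SNP and share its locus
    locus_of = np.empty(total, dtype=int)
    locus_of[:n_expo_snps] = np.repeat(np.arange(truth.m), per_locus)
    locus_of[n_expo_snps:] = truth.m + np.arange(total - n_expo_snps)
    pos = (1_000_000 + (locus_of // 22) * 1_500_000 + locus_of * 37) + 25_000 * (
        np.arange(total) - np.searchsorted(locus_of, locus_of)
    )
    chrom = np.array([str(1 + (l % 22)) for l in locus_of], dtype=object)

    eaf_true = rng_panel.uniform(0.05, 0.95, size=total)
    pal = rng_panel.random(total) < truth.palindromic_fraction
    np_idx = rng_panel.integers(0, len(_NONPALINDROMIC_PAIRS), size=total)
    p_idx = rng_panel.integers(0, len(_PALINDROMIC_PAIRS), size=total)
    ea = np.empty(total, dtype=object)
    oa = np.empty(total, dtype=object)
    for i in range(total):
        pair = _PALINDROMIC_PAIRS[p_idx[i]] if pal[i] else _NONPALINDROMIC_PAIRS[np_idx[i]]
        ea[i], oa[i] = pair

    # --- true effects --------------------------------------------------------
    se_exposure = _se_binary(eaf_true, truth.n_exposure, truth.case_fraction_exposure)
    b_exposure = np.zeros(total)
    idx_expo = np.arange(n_expo_snps)
    index_snps = idx_expo[idx_expo % per_locus == 0]
    z = rng_expo.normal(truth.instrument_z_mean, truth.instrument_z_sd, size=truth.m)
    sign = rng_expo.choice([-1.0, 1.0], size=truth.m)
    b_index = sign * np.abs(z) * se_exposure[index_snps]
    for j, isnp in enumerate(index_snps):
        b_exposure[isnp : isnp + per_locus] = b_index[j]
        # partners tag the same signal slightly less efficiently
        b_exposure[isnp + 1 : isnp + per_locus] *= np.sqrt(truth.ld_partner_r2)

    offset = n_expo_snps
    med_true = np.zeros((total, k))
    for ki in range(k):
        med_true[:, ki] = truth.alpha[ki] * b_exposure
        sl = slice(offset, offset + truth.m_per_mediator)
        se_med = _se_continuous(eaf_true[sl], n_med[ki])
        zm = rng_med[ki].normal(truth.instrument_z_mean, truth.instrument_z_sd,
                                size=truth.m_per_mediator)
        sm = rng_med[ki].choice([-1.0, 1.0], size=truth.m_per_mediator)
        med_true[sl, ki] += sm * np.abs(zm) * se_med
        offset += truth.m_per_mediator

    cov_true = np.zeros((total, kc))
    for ci in range(kc):
        cov_true[:, ci] = truth.alpha_cov[ci] * b_exposure
        sl = slice(offset, offset + m_per_cov[ci])
        se_cov = _se_continuous(eaf_true[sl], truth.n_covariate[ci])
        zc = rng_cov[ci].normal(truth.instrument_z_mean, truth.instrument_z_sd,
                                size=m_per_cov[ci])
        sc = rng_cov[ci].choice([-1.0, 1.0], size=m_per_cov[ci])
        cov_true[sl, ci] += sc * np.abs(zc) * se_cov
        offset += m_per_cov[ci]

    out_true = truth.tau_direct * b_exposure
    for ki in range(k):
        out_true += truth.gamma[ki] * med_true[:, ki]
    for ci in range(kc):
        out_true += truth.gamma_cov[ci] * cov_true[:, ci]

    se_outcome = _se_binary(eaf_true, truth.n_outcome, truth.case_fraction_outcome)
    pleiotropic_snps: list = []
    if truth.pleiotropy_mode != "none" and truth.pleiotropy_fraction > 0:
        n_affected = int(round(truth.pleiotropy_fraction * truth.m))
        hit_loci = rng_pleio.choice(truth.m, size=min(truth.m, max(n_affected, 0)),
                                    replace=False)
        for j in hit_loci:
            pleiotropic_snps.extend(
                snp_ids[index_snps[j] : index_snps[j] + per_locus]
            )
            sl = slice(index_snps[j], index_snps[j] + per_locus)
            if truth.pleiotropy_mode == "balanced":
                off = rng_pleio.normal(0.0, truth.pleiotropy_magnitude)
            elif truth.pleiotropy_mode == "directional":
                off = rng_pleio.normal(truth.pleiotropy_magnitude,
                                       truth.pleiotropy_magnitude / 2.0)
            else:  # outlier: a fixed offset in units of the outcome SE
                off = (rng_pleio.choice([-1.0, 1.0])
                       * truth.pleiotropy_magnitude * se_outcome[sl][0])
            out_true[sl] += off

    # --- observed tables -----------------------------------------------------
    ld_rho = np.sqrt(truth.ld_partner_r2)

    def draw_noise(rng):
        """Per-SNP sampling noise; SNPs in LD share noise with correlation r."""
        eps = rng.standard_normal(total)
        if truth.n_ld_partners:
            for isnp in index_snps:
                own = eps[isnp + 1 : isnp + per_locus]
                eps[isnp + 1 : isnp + per_locus] = (
                    ld_rho * eps[isnp] + np.sqrt(1.0 - ld_rho**2) * own
                )
        return eps

    def build_table(label, trait_type, true_beta, se, rng, n_samples):
        beta = true_beta + draw_noise(rng) * se
        eaf_obs = np.clip(eaf_true + rng_eaf.normal(0.0, truth.eaf_noise_sd, total),
                          0.001, 0.999)
        tab_ea, tab_oa = ea.copy(), oa.copy()
        df = pd.DataFrame({
            "snp_id": snp_ids,
            "chrom": chrom,
            "pos": pos,
            "effect_allele": tab_ea,
            "other_allele": tab_oa,
            "eaf": eaf_obs,
            "beta": beta,
            "se": se,
            "pval": _pvalues(beta, se),
            "n": n_samples,
        })[CANONICAL_COLUMNS]
        return df

    exposure_df = build_table("exposure", "binary", b_exposure, se_exposure,
                              rng_expo, truth.n_exposure)

    def reorient(df, rng, flip_frac):
        """Swap allele labels (with beta/EAF flips) on a random subset of rows."""
        flip = rng.random(len(df)) < flip_frac
        df = df.copy()
        # note: to_numpy on an object column can be a view; copy before swapping
        ea_c = df["effect_allele"].to_numpy(dtype=object).copy()
        oa_c = df["other_allele"].to_numpy(dtype=object).copy()
        df.loc[flip, "effect_allele"] = oa_c[flip]
        df.loc[flip, "other_allele"] = ea_c[flip]
        df.loc[flip, "beta"] = -df.loc[flip, "beta"]
        df.loc[flip, "eaf"] = 1.0 - df.loc[flip, "eaf"]
        return df

    mediators = []
    for ki in range(k):
        sl_se = _se_continuous(eaf_true, n_med[ki])
        df = build_table(truth.mediator_labels[ki], "continuous", med_true[:, ki],
                         sl_se, rng_med[ki], n_med[ki])
        df = reorient(df, rng_orient, truth.allele_flip_fraction)
        mediators.append(SummaryStatsTable(truth.mediator_labels[ki], "continuous",
                                           df, "synthetic"))

    covariates = []
    for ci in range(kc):
        sl_se = _se_continuous(eaf_true, truth.n_covariate[ci])
        df = build_table(truth.covariate_labels[ci], "continuous", cov_true[:, ci],
                         sl_se, rng_cov[ci], truth.n_covariate[ci])
        df = reorient(df, rng_orient, truth.allele_flip_fraction)
        covariates.append(SummaryStatsTable(truth.covariate_labels[ci], "continuous",
                                            df, "synthetic"))

    outcome_df = build_table("outcome", "binary", out_true, se_outcome, rng_out,
                             truth.n_outcome)
    outcome_df = reorient(outcome_df, rng_orient, truth.allele_flip_fraction)
    if truth.incompatible_fraction > 0:
        corrupt = rng_orient.random(total) < truth.incompatible_fraction
        letters = np.array(list("ACGT"), dtype=object)
        for i in np.flatnonzero(corrupt):
            bad = [a for a in letters
                   if a not in (outcome_df.at[i, "effect_allele"],
                                outcome_df.at[i, "other_allele"])]
            outcome_df.at[i, "other_allele"] = bad[int(rng_orient.integers(len(bad)))]

    # --- LD structure --------------------------------------------------------
    pairs = []
    for isnp in index_snps:
        members = list(range(isnp, isnp + per_locus))
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                pairs.append((snp_ids[members[a]], snp_ids[members[b]],
                              truth.ld_partner_r2))
    positions = {snp_ids[i]: (chrom[i], int(pos[i])) for i in range(total)}
    ld = LdInfo.from_pairs(pairs, positions)

    exposure = SummaryStatsTable("childhood adiposity", "binary", exposure_df,
                                 "synthetic")
    outcome = SummaryStatsTable("outcome", "binary", outcome_df, "synthetic")
    return SimulatedStudy(exposure=exposure, mediators=mediators,
                          covariates=covariates, outcome=outcome, ld=ld,
                          truth=truth, pleiotropic_snps=pleiotropic_snps)


# effect sizes of the emulated study: five lipid mediators with their
# exposure->mediator (alpha) and adjusted mediator->outcome (gamma) effects,
# three adult-adiposity covariates, and a total effect of ln(1.21)
_PRESET_MEDIATORS = ("LDL-C", "HDL-C", "triglyceride",
                     "apolipoprotein A-I", "apolipoprotein B")
_PRESET_ALPHA = (-0.02, -0.04, 0.02, -0.04, 0.00733)
_PRESET_GAMMA = (-0.13, -0.27, 0.26, -0.29, -0.13)
_PRESET_N_MEDIATOR = (440_546, 403_943, 441_016, 393_193, 439_214)
_PRESET_COVARIATES = ("adult BMI", "adult WC", "adult WHR")
_PRESET_N_COVARIATE = (339_224, 231_353, 212_244)
# covariate paths sized so the pairwise-adjusted direct effects are
# ln(1.17), ln(1.10) and ln(1.21)
_PRESET_ALPHA_COV = (0.15, 0.15, 0.10)
_PRESET_GAMMA_COV = (
    (log(1.21) - log(1.17)) / 0.15,
    (log(1.21) - log(1.10)) / 0.15,
    0.0,
)


def paper_shaped_scenario(seed: int = 0, **overrides) -> SimulationTruth:
    """Preset emulating the childhood-adiposity -> lipids -> GDM study.

    One binary exposure (5,530 cases / 8,318 controls), five lipid mediators
    at UK-Biobank-scale sample sizes, three adult-adiposity covariates and a
    FinnGen-scale binary outcome (11,279 cases / 190,879 total).  Effect sizes
    are the study's point estimates; instrument strength targets a mean Wald
    F of ~45.
    """
    params = dict(
        m=12,
        tau_total=log(1.21),
        mediator_labels=_PRESET_MEDIATORS,
        alpha=_PRESET_ALPHA,
        gamma=_PRESET_GAMMA,
        n_mediator=_PRESET_N_MEDIATOR,
        m_per_mediator=200,
        covariate_labels=_PRESET_COVARIATES,
        alpha_cov=_PRESET_ALPHA_COV,
        gamma_cov=_PRESET_GAMMA_COV,
        n_covariate=_PRESET_N_COVARIATE,
        m_per_covariate=(70, 40, 30),
        seed=seed,
    )
    params.update(overrides)
    return SimulationTruth(**params)


def null_scenario(seed: int = 0, m: int = 50, **overrides) -> SimulationTruth:
    """No causal effect anywhere: tau = 0, no mediators, no contamination."""
    params = dict(
        m=m,
        tau_total=0.0,
        mediator_labels=(),
        alpha=(),
        gamma=(),
        n_mediator=(),
        n_null=0,
        n_ld_partners=0,
        seed=seed,
    )
    params.update(overrides)
    return SimulationTruth(**params)
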