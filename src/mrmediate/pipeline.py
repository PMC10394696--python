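"""End-to-end two-stage MR pipeline.

Stage 1: the total effect of the exposure on the outcome (full univariable
sensitivity battery — IVW, MR-Egger, weighted median, weighted mode,
MR-PRESSO, Cochran's Q, Egger intercept, leave-one-out, mean instrument F)
plus pairwise multivariable MR adjusting the exposure for each covariate
trait in turn.

Stage 2: per-mediator univariable MR (exposure -> mediator), per-mediator
multivariable MR (mediator -> outcome adjusted for the exposure), a
Bonferroni screen requiring significance in both directions, and the
two-step mediation decomposition (indirect effects, proportions mediated).

Reports are plain dicts, serialized side by side as TSV and JSON.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import gwas_io, instruments, mediation, mr_presso, mvmr, uvmr
from .gwas_io import SummaryStatsTable, harmonize, read_summary_stats
from .instruments import LdInfo
from .synthetic_data import SimulatedStudy

__all__ = ["AnalysisConfig", "load_study", "run_stage1", "run_stage2", "run_full"]


@dataclass
class AnalysisConfig:
    """Paths, labels and thresholds for one analysis run."""

    exposure: dict = field(default_factory=dict)  # {path, label}
    covariates: list = field(default_factory=list)
    mediators: list = field(default_factory=list)
    outcome: dict = field(default_factory=dict)
    ld_path: str | None = None
    p_threshold: float = 5e-8
    clump_r2: float = 0.001
    clump_window_kb: int = 10_000
    bonferroni_alpha: float | None = None  # default 0.05 / n mediators
    ivw_model: str = "random"
    palindrome_action: str = "infer"
    palindrome_eaf_window: float = 0.08
    n_boot: int = 5000
    presso_n_sim: int = 1000
    presso_outlier_alpha: float = 0.05
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if not 0 < self.p_threshold <= 1:
            raise ValueError("p_threshold must lie in (0, 1]")
        if not 0 <= self.clump_r2 <= 1:
            raise ValueError("clump_r2 must lie in [0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def load_study(config: AnalysisConfig) -> SimulatedStudy:
    """Read the configured tables into a study record (ld optional)."""

    def read(spec, trait_type):
        return read_summary_stats(
            spec["path"], trait_type=trait_type, trait_label=spec.get("label")
        )

    ld = LdInfo.from_tsv(config.ld_path) if config.ld_path else LdInfo()
    exposure = read(config.exposure, config.exposure.get("trait_type", "binary"))
    outcome = read(config.outcome, config.outcome.get("trait_type", "binary"))
    mediators = [read(s, s.get("trait_type", "continuous")) for s in config.mediators]
    covariates = [read(s, s.get("trait_type", "continuous")) for s in config.covariates]
    if not ld.positions:
        ld.positions.update(
            {
                r.snp_id: (r.chrom, r.pos)
                for r in exposure.df.itertuples()
            }
        )
    return SimulatedStudy(
        exposure=exposure, mediators=mediators, covariates=covariates,
        outcome=outcome, ld=ld, truth=None,
    )


def _estimate_row(est: uvmr.MREstimate, **extra) -> dict:
    or_, lo, hi = est.or_view
    row = {
        "method": est.method,
        "n_snp": est.n_snp,
        "beta": est.beta,
        "se": est.se,
        "ci_low": est.ci_low,
        "ci_high": est.ci_high,
        "or": or_,
        "or_ci_low": lo,
        "or_ci_high": hi,
        "pval": est.pval,
    }
    row.update(extra)
    return row


def _select_instruments(config: AnalysisConfig, table: SummaryStatsTable, ld: LdInfo):
    ids = instruments.select_significant(table, config.p_threshold)
    if ids:
        cand = table.df[table.df["snp_id"].isin(set(ids))]
        ids = instruments.ld_clump(
            cand[["snp_id", "pval", "chrom", "pos"]],
            ld,
            r2_threshold=config.clump_r2,
            window_kb=config.clump_window_kb,
        )
    return ids


def run_stage1(config: AnalysisConfig, study: SimulatedStudy | None = None) -> dict:
    """Total effect of the exposure on the outcome, and covariate-adjusted MVMR."""
    if study is None:
        study = load_study(config)
    exp_ids = _select_instruments(config, study.exposure, study.ld)
    exp_sub = study.exposure.filter(exp_ids)
    hs = harmonize(
        exp_sub, study.outcome, config.palindrome_eaf_window, config.palindrome_action
    )

    ivw_est, q = uvmr.ivw(hs, model=config.ivw_model)
    egger = uvmr.mr_egger(hs)
    median = uvmr.weighted_median(hs, n_boot=config.n_boot, seed=config.seed)
    mode = uvmr.weighted_mode(hs, n_boot=config.n_boot, seed=config.seed)
    presso = mr_presso.presso(
        hs,
        n_sim=config.presso_n_sim,
        outlier_alpha=config.presso_outlier_alpha,
        seed=config.seed,
    )
    presso_est = presso.corrected if presso.corrected is not None else dataclasses.replace(
        ivw_est, method="MR-PRESSO"
    )
    loo = uvmr.leave_one_out(hs, model=config.ivw_model)
    strength = instruments.f_statistics(hs)

    report = {
        "uvmr": [
            _estimate_row(ivw_est),
            _estimate_row(egger.slope),
            _estimate_row(median),
            _estimate_row(mode),
            _estimate_row(presso_est, presso_global_p=presso.global_p),
        ],
        "diagnostics": {
            "cochran_q": q.q,
            "cochran_q_df": q.df,
            "cochran_q_p": q.pval,
            "egger_intercept": egger.intercept.value,
            "egger_intercept_se": egger.intercept.se,
            "egger_intercept_p": egger.intercept.pval,
            "presso_global_p": presso.global_p,
            "presso_outliers": presso.outliers,
            "presso_distortion_p": presso.distortion_p,
            "mean_f": strength.mean_f,
            "weak_instruments": strength.is_weak,
            "n_instruments": len(hs),
            "dropped": list(map(list, hs.dropped)),
            "leave_one_out": [
                {"snp_id": sid, "beta": est.beta, "se": est.se} for sid, est in loo
            ],
        },
        "mvmr": [],
    }

    for cov in study.covariates:
        mv = mvmr.build_mv_set(
            [study.exposure, cov],
            study.outcome,
            ld=study.ld,
            r2_threshold=config.clump_r2,
            window_kb=config.clump_window_kb,
            p_threshold=config.p_threshold,
            palindrome_eaf_window=config.palindrome_eaf_window,
            action=config.palindrome_action,
        )
        ests = mvmr.mv_ivw(mv)
        eg_ests, eg_int = mvmr.mvmr_egger(mv, orient_to=study.exposure.trait_label)
        report["mvmr"].append(
            _estimate_row(
                ests[0],
                adjusted_for=cov.trait_label,
                egger_beta=eg_ests[0].beta,
                egger_se=eg_ests[0].se,
                egger_intercept_p=eg_int.pval,
            )
        )

    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        gwas_io.write_report(
            [dict(r) for r in report["uvmr"]], out / "stage1_uvmr"
        )
        gwas_io.write_report([dict(r) for r in report["mvmr"]], out / "stage1_mvmr")
        with open(out / "stage1_diagnostics.json", "w") as fh:
            json.dump(report["diagnostics"], fh, indent=2, default=float)
    return report


def run_stage2(config: AnalysisConfig, study: SimulatedStudy | None = None) -> dict:
    """Mediator screen and two-step mediation decomposition."""
    if study is None:
        study = load_study(config)
    two = mediation.two_step_mediation(
        study.exposure,
        study.mediators,
        study.outcome,
        ld=study.ld,
        p_threshold=config.p_threshold,
        r2_threshold=config.clump_r2,
        window_kb=config.clump_window_kb,
        alpha_bonferroni=config.bonferroni_alpha,
        ivw_model=config.ivw_model,
        palindrome_eaf_window=config.palindrome_eaf_window,
        action=config.palindrome_action,
    )

    # per-mediator instrument strength for the step-1 rows
    exp_ids = _select_instruments(config, study.exposure, study.ld)
    exp_sub = study.exposure.filter(exp_ids)
    step1_rows = []
    for med in study.mediators:
        hs = harmonize(
            exp_sub, med, config.palindrome_eaf_window, config.palindrome_action
        )
        strength = instruments.f_statistics(hs)
        step1_rows.append(
            _estimate_row(
                two.step1[med.trait_label],
                mediator=med.trait_label,
                mean_f=strength.mean_f,
            )
        )
    step2_rows = [
        _estimate_row(two.step2[lab], mediator=lab) for lab in two.step2
    ]
    mediation_rows = [
        {
            "mediator": r.mediator_label,
            "beta1": r.beta1,
            "se1": r.se1,
            "beta2": r.beta2,
            "se2": r.se2,
            "total": r.total,
            "indirect": r.indirect,
            "se_indirect": r.se_indirect,
            "proportion_pct": 100.0 * r.proportion,
            "proportion_ci_low_pct": 100.0 * r.ci_proportion[0],
            "proportion_ci_high_pct": 100.0 * r.ci_proportion[1],
        }
        for r in two.results
    ]
    report = {
        "total": _estimate_row(two.total),
        "step1": step1_rows,
        "step2": step2_rows,
        "screened": two.screened,
        "mediation": mediation_rows,
    }
    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        gwas_io.write_report(step1_rows, out / "stage2_step1")
        gwas_io.write_report(step2_rows, out / "stage2_step2")
        gwas_io.write_report(mediation_rows, out / "stage2_mediation")
        with open(out / "stage2_summary.json", "w") as fh:
            json.dump(report, fh, indent=2, default=float)
    return report


def run_full(config: AnalysisConfig, study: SimulatedStudy | None = None) -> dict:
    """Both stages on one study; writes a combined JSON when output_dir is set."""
    if study is None:
        study = load_study(config)
    report = {
        "stage1": run_stage1(config, study),
        "stage2": run_stage2(config, study),
    }
    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=float)
    return report
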