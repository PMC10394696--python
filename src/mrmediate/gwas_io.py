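"""Reading, validation, writing and harmonization of GWAS summary statistics.

A summary-statistics table carries one row per SNP: identifiers, alleles,
effect-allele frequency (EAF), effect size (``beta``, on the log-odds scale for
binary traits and in SD units for continuous traits), its standard error,
p-value and sample size.  Two-sample MR needs the exposure and outcome effects
expressed relative to the *same* effect allele for every SNP; :func:`harmonize`
performs that alignment, flipping outcome effects where the allele labels are
swapped and resolving or removing palindromic (A/T, C/G) variants whose strand
cannot be inferred from allele labels alone.
"""

from __future__ import annotations

import dataclasses
import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CANONICAL_COLUMNS",
    "SummaryStatsTable",
    "HarmonizedSet",
    "read_summary_stats",
    "harmonize",
    "substitute_proxies",
    "write_report",
    "read_report",
    "is_palindromic",
]

#: Canonical column order of a summary-statistics frame.
CANONICAL_COLUMNS = [
    "snp_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
]

MANDATORY_COLUMNS = ["snp_id", "effect_allele", "other_allele", "beta", "se"]

_VALID_ALLELES = frozenset("ACGT")
_PALINDROME_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


def is_palindromic(effect_allele, other_allele):
    """Element-wise test for A/T or C/G (strand-ambiguous) allele pairs."""
    ea = np.asarray(effect_allele, dtype=object)
    oa = np.asarray(other_allele, dtype=object)
    out = np.zeros(ea.shape, dtype=bool)
    for a, b in _PALINDROME_PAIRS:
        out |= (ea == a) & (oa == b)
    return out


@dataclass
class SummaryStatsTable:
    """A validated GWAS summary-statistics table for a single trait.

    ``df`` holds the canonical columns of :data:`CANONICAL_COLUMNS`; rows are
    guaranteed to satisfy the per-SNP invariants (ACGT alleles, distinct
    alleles, positive SE, EAF and p in range, p consistent with beta/se).
    """

    trait_label: str
    trait_type: str  # "binary" | "continuous"
    df: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.trait_type not in ("binary", "continuous"):
            raise ValueError(f"trait_type must be binary|continuous, got {self.trait_type!r}")

    def __len__(self) -> int:
        return len(self.df)

    def filter(self, snp_ids: Iterable[str]) -> "SummaryStatsTable":
        """Restrict to the given SNPs (original row order preserved)."""
        wanted = set(snp_ids)
        sub = self.df[self.df["snp_id"].isin(wanted)].reset_index(drop=True)
        return SummaryStatsTable(self.trait_label, self.trait_type, sub, self.provenance)

    def write(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


def _validate_frame(df: pd.DataFrame) -> tuple[pd.DataFrame, Counter]:
    """Drop rows violating per-SNP invariants; return (clean frame, reasons)."""
    reasons: Counter = Counter()
    df = df.copy()
    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.upper()

    ea, oa = df["effect_allele"], df["other_allele"]
    bad_allele = ~ea.isin(_VALID_ALLELES) | ~oa.isin(_VALID_ALLELES) | (ea == oa)
    se = pd.to_numeric(df["se"], errors="coerce")
    beta = pd.to_numeric(df["beta"], errors="coerce")
    bad_se = ~np.isfinite(se) | (se <= 0)
    bad_beta = ~np.isfinite(beta)
    eaf = pd.to_numeric(df["eaf"], errors="coerce")
    bad_eaf = df["eaf"].notna() & ~((eaf > 0) & (eaf < 1))
    pval = pd.to_numeric(df["pval"], errors="coerce")
    bad_p = df["pval"].notna() & ~((pval > 0) & (pval <= 1))

    # p must agree with |beta/se| under the normal approximation (10% relative
    # error on the z scale; tiny p saturate the inverse normal and are skipped).
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.abs(beta) / se
        z_from_p = stats.norm.isf(pval / 2.0)
        rel = np.abs(z_from_p - z) / np.maximum(z, 1e-8)
    checkable = df["pval"].notna() & ~bad_p & ~bad_se & ~bad_beta & (pval >= 1e-300)
    inconsistent = checkable & (rel > 0.10)

    dup = df["snp_id"].duplicated(keep="first")

    for mask, label in [
        (bad_allele, "non-ACGT or identical alleles"),
        (bad_se, "non-positive se"),
        (bad_beta, "non-finite beta"),
        (bad_eaf, "eaf out of range"),
        (bad_p, "pval out of range"),
        (inconsistent, "pval inconsistent with beta/se"),
        (dup, "duplicate snp_id"),
    ]:
        reasons[label] += int(mask.sum())

    keep = ~(bad_allele | bad_se | bad_beta | bad_eaf | bad_p | inconsistent | dup)
    clean = df.loc[keep].reset_index(drop=True)
    # per-check counters may double-count a row failing several checks; the
    # row drop count is exact
    reasons["_dropped_rows"] = int((~keep).sum())
    return clean, reasons


def read_summary_stats(
    path,
    column_map: Mapping[str, str] | None = None,
    trait_type: str = "continuous",
    trait_label: str | None = None,
    sep: str = "\t",
) -> SummaryStatsTable:
    """Read a delimited summary-statistics file into a validated table.

    Parameters
    ----------
    path
        Delimited text file with a header row.
    column_map
        Mapping from canonical names (see :data:`CANONICAL_COLUMNS`) to the
        column names used in the file, for files with non-canonical headers.
    trait_type
        ``"binary"`` (betas are log odds ratios) or ``"continuous"``.

    Rows violating per-SNP invariants are dropped and counted in
    ``provenance``.  A missing mandatory column raises ``ValueError``.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=sep)
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"missing mandatory column '{col}' in {path}")
    for col in CANONICAL_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df = df[CANONICAL_COLUMNS]
    n_read = len(df)
    clean, reasons = _validate_frame(df)
    dropped = reasons.pop("_dropped_rows")
    detail = "; ".join(f"{k}: {v}" for k, v in sorted(reasons.items()) if v)
    provenance = f"read {n_read} rows from {path}; dropped {dropped} invalid rows"
    if detail:
        provenance += f" ({detail})"
    return SummaryStatsTable(
        trait_label=trait_label or path.stem,
        trait_type=trait_type,
        df=clean,
        provenance=provenance,
    )


@dataclass
class HarmonizedSet:
    """Exposure/outcome effects aligned to a common effect allele per SNP."""

    snp_ids: np.ndarray
    beta_exposure: np.ndarray
    se_exposure: np.ndarray
    beta_outcome: np.ndarray
    se_outcome: np.ndarray
    eaf: np.ndarray | None = None
    dropped: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.snp_ids)

    def subset(self, index) -> "HarmonizedSet":
        """Subset by boolean mask or integer indices (drop log not carried)."""
        idx = np.asarray(index)
        return HarmonizedSet(
            snp_ids=self.snp_ids[idx],
            beta_exposure=self.beta_exposure[idx],
            se_exposure=self.se_exposure[idx],
            beta_outcome=self.beta_outcome[idx],
            se_outcome=self.se_outcome[idx],
            eaf=None if self.eaf is None else self.eaf[idx],
            dropped=[],
        )


def _align_frames(
    ref: pd.DataFrame,
    oth: pd.DataFrame,
    palindrome_eaf_window: float,
    action: str,
) -> tuple[pd.DataFrame, list]:
    """Orient ``oth`` effects onto ``ref``'s effect alleles, SNP by SNP.

    Returns the merged frame (columns suffixed ``_ref``/``_oth``, with
    ``beta_oth``/``eaf_oth`` already flipped where needed) restricted to
    SNPs that survive, plus the list of ``(snp_id, reason)`` exclusions.
    """
    if action not in ("strict", "infer"):
        raise ValueError(f"action must be strict|infer, got {action!r}")
    merged = ref.merge(oth, on="snp_id", suffixes=("_ref", "_oth"))
    if merged.empty:
        raise ValueError("no overlapping SNPs between the two tables")

    ea_r = merged["effect_allele_ref"].to_numpy(dtype=object)
    oa_r = merged["other_allele_ref"].to_numpy(dtype=object)
    ea_o = merged["effect_allele_oth"].to_numpy(dtype=object)
    oa_o = merged["other_allele_oth"].to_numpy(dtype=object)

    same = (ea_o == ea_r) & (oa_o == oa_r)
    flip = (ea_o == oa_r) & (oa_o == ea_r)
    incompatible = ~(same | flip)
    pal = is_palindromic(ea_r, oa_r)

    beta = merged["beta_oth"].to_numpy(dtype=float)
    eaf_o = merged["eaf_oth"].to_numpy(dtype=float)
    eaf_r = merged["eaf_ref"].to_numpy(dtype=float)
    beta = np.where(flip, -beta, beta)
    eaf_o = np.where(flip, 1.0 - eaf_o, eaf_o)

    drop = incompatible.copy()
    reason = np.full(len(merged), "", dtype=object)
    reason[incompatible] = "incompatible alleles"

    pal_ok = pal & ~incompatible
    if action == "strict":
        drop |= pal_ok
        reason[pal_ok] = "palindromic"
    else:
        w = palindrome_eaf_window
        ambiguous = pal_ok & (
            ~np.isfinite(eaf_r)
            | ~np.isfinite(eaf_o)
            | (np.abs(eaf_r - 0.5) <= w)
            | (np.abs(eaf_o - 0.5) <= w)
        )
        drop |= ambiguous
        reason[ambiguous] = "palindromic ambiguous"
        # For an unambiguous palindrome the allele labels cannot reveal a strand
        # flip; frequencies on opposite sides of 0.5 indicate one.
        strand_flip = pal_ok & ~ambiguous & ((eaf_r < 0.5) != (eaf_o < 0.5))
        beta = np.where(strand_flip, -beta, beta)
        eaf_o = np.where(strand_flip, 1.0 - eaf_o, eaf_o)

    merged = merged.assign(beta_oth=beta, eaf_oth=eaf_o)
    dropped = [
        (sid, why)
        for sid, why in zip(merged["snp_id"].to_numpy()[drop], reason[drop])
    ]
    return merged.loc[~drop].reset_index(drop=True), dropped


def harmonize(
    exposure: SummaryStatsTable,
    outcome: SummaryStatsTable,
    palindrome_eaf_window: float = 0.08,
    action: str = "infer",
) -> HarmonizedSet:
    """Align outcome effects to the exposure's effect alleles.

    SNPs are intersected on ``snp_id``.  Where the outcome's effect allele is
    the exposure's other allele, the outcome beta sign is flipped and its EAF
    replaced by 1 - EAF.  Palindromic SNPs are dropped outright in ``strict``
    mode; in ``infer`` mode they are dropped only when either EAF is missing or
    lies within ``palindrome_eaf_window`` of 0.5, and otherwise oriented by
    frequency.  Every exclusion is recorded as ``(snp_id, reason)``.
    """
    if len(exposure) == 0 or len(outcome) == 0:
        raise ValueError("harmonize requires non-empty tables")
    merged, dropped = _align_frames(
        exposure.df, outcome.df, palindrome_eaf_window, action
    )
    return HarmonizedSet(
        snp_ids=merged["snp_id"].to_numpy(),
        beta_exposure=merged["beta_ref"].to_numpy(dtype=float),
        se_exposure=merged["se_ref"].to_numpy(dtype=float),
        beta_outcome=merged["beta_oth"].to_numpy(dtype=float),
        se_outcome=merged["se_oth"].to_numpy(dtype=float),
        eaf=merged["eaf_ref"].to_numpy(dtype=float),
        dropped=dropped,
    )


def substitute_proxies(
    needed: Sequence[str],
    available: SummaryStatsTable,
    proxy_map: pd.DataFrame,
    min_r2: float = 0.8,
) -> SummaryStatsTable:
    """Fill SNPs missing from ``available`` using a user-supplied proxy map.

    ``proxy_map`` has columns ``snp_id`` (the wanted SNP), ``proxy_id``,
    ``r2`` and ``phase`` (``"same"`` or ``"flip"``: whether the proxy's effect
    allele is in phase with the wanted SNP's effect allele).  For each needed
    SNP absent from ``available`` the highest-r2 proxy with r2 >= ``min_r2``
    that is present in ``available`` is inserted under the wanted SNP's id,
    with the phase flip applied to beta and EAF.  SNPs without a usable proxy
    simply remain absent; substitutions are logged in ``provenance``.
    """
    have = set(available.df["snp_id"])
    rows = []
    log = []
    by_proxy = available.df.set_index("snp_id")
    for snp in needed:
        if snp in have:
            continue
        cands = proxy_map[
            (proxy_map["snp_id"] == snp)
            & (proxy_map["r2"] >= min_r2)
            & proxy_map["proxy_id"].isin(have)
        ]
        if cands.empty:
            continue
        best = cands.loc[cands["r2"].idxmax()]
        rec = by_proxy.loc[best["proxy_id"]].copy()
        rec["snp_id"] = snp
        if str(best.get("phase", "same")) == "flip":
            rec["beta"] = -rec["beta"]
            if np.isfinite(rec.get("eaf", np.nan)):
                rec["eaf"] = 1.0 - rec["eaf"]
        rows.append(rec[CANONICAL_COLUMNS])
        log.append(f"{best['proxy_id']}->{snp} (r2={best['r2']:.3g})")
    if rows:
        df = pd.concat([available.df, pd.DataFrame(rows)], ignore_index=True)
    else:
        df = available.df.copy()
    provenance = available.provenance
    if log:
        provenance = (provenance + "; " if provenance else "") + "proxies: " + ", ".join(log)
    return SummaryStatsTable(available.trait_label, available.trait_type, df, provenance)


def _result_to_row(result) -> dict:
    """Flatten a result dataclass into a serializable row."""
    if dataclasses.is_dataclass(result):
        row = dataclasses.asdict(result)
    elif isinstance(result, dict):
        row = dict(result)
    else:
        raise TypeError(f"cannot serialize result of type {type(result)!r}")
    for key, value in list(row.items()):
        if isinstance(value, np.ndarray):
            row[key] = value.tolist()
        elif isinstance(value, (np.floating, np.integer)):
            row[key] = value.item()
    # expose the odds-ratio view of beta-scale estimates
    if hasattr(result, "or_view"):
        or_, lo, hi = result.or_view
        row.update({"or": or_, "or_ci_low": lo, "or_ci_high": hi})
    return row


def write_report(results, path) -> tuple[Path, Path]:
    """Serialize a list of result records to side-by-side TSV and JSON.

    ``path`` may carry any (or no) extension; the ``.tsv`` and ``.json``
    siblings are written next to it.  Each row mirrors the usual MR report
    layout (method, nSNP, beta, SE, OR, CI bounds, p).
    """
    base = Path(path)
    base.parent.mkdir(parents=True, exist_ok=True)
    tsv = base.with_suffix(".tsv")
    js = base.with_suffix(".json")
    rows = [_result_to_row(r) for r in results]
    frame = pd.DataFrame(rows)
    if frame.empty:
        frame = pd.DataFrame(
            columns=["method", "n_snp", "beta", "se", "ci_low", "ci_high", "pval"]
        )
    frame.to_csv(tsv, sep="\t", index=False)
    with open(js, "w") as fh:
        json.dump(rows, fh, indent=2, default=float)
    return tsv, js


def read_report(path) -> pd.DataFrame:
    """Read back a TSV report written by :func:`write_report`."""
    return pd.read_csv(Path(path).with_suffix(".tsv"), sep="\t")
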