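"""Instrument selection: significance screening, LD clumping, strength.

Instruments are SNPs passing genome-wide significance in the exposure GWAS
(p < 5e-8 by default) and pruned to approximate linkage equilibrium with a
greedy clump (r^2 < 0.001 within a 10,000 kb window by default).  Pairwise LD
is an explicit user input — no reference panel is consulted.  Instrument
strength is summarized by the per-SNP Wald F statistic (beta/se)^2; a mean F
below 10 conventionally signals weak-instrument bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .gwas_io import HarmonizedSet, SummaryStatsTable

__all__ = ["LdInfo", "InstrumentStrength", "select_significant", "ld_clump", "f_statistics"]

WEAK_F_THRESHOLD = 10.0


@dataclass
class LdInfo:
    """Pairwise LD (r^2) between SNPs, plus optional genomic positions.

    Pairs absent from the table are treated as unlinked (r^2 = 0); self pairs
    are r^2 = 1 by definition, and lookups are symmetric.
    """

    pairs: dict = field(default_factory=dict)
    positions: dict = field(default_factory=dict)

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    @classmethod
    def from_pairs(cls, triples: Iterable[tuple], positions: Mapping | None = None) -> "LdInfo":
        """Build from an iterable of (snp_a, snp_b, r2)."""
        pairs = {}
        for a, b, r2 in triples:
            pairs[cls._key(str(a), str(b))] = float(r2)
        return cls(pairs=pairs, positions=dict(positions or {}))

    @classmethod
    def from_tsv(cls, path, positions: Mapping | None = None) -> "LdInfo":
        """Read a 3-column TSV (snp_a, snp_b, r2) with header."""
        df = pd.read_csv(path, sep="\t")
        cols = list(df.columns[:3])
        return cls.from_pairs(df[cols].itertuples(index=False, name=None), positions)

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self.pairs.get(self._key(a, b), 0.0)

    def to_tsv(self, path) -> None:
        rows = [(a, b, r2) for (a, b), r2 in sorted(self.pairs.items())]
        pd.DataFrame(rows, columns=["snp_a", "snp_b", "r2"]).to_csv(path, sep="\t", index=False)


@dataclass
class InstrumentStrength:
    """Per-SNP Wald F statistics and their arithmetic mean."""

    per_snp_f: np.ndarray
    mean_f: float

    @property
    def is_weak(self) -> bool:
        """True when mean F < 10, the conventional weak-instrument flag."""
        return bool(self.mean_f < WEAK_F_THRESHOLD)


def select_significant(table: SummaryStatsTable, p_threshold: float = 5e-8) -> list[str]:
    """SNPs with p strictly below the threshold, original order preserved."""
    mask = table.df["pval"] < p_threshold
    return list(table.df.loc[mask, "snp_id"])


def ld_clump(
    candidates: pd.DataFrame,
    ld: LdInfo,
    r2_threshold: float = 0.001,
    window_kb: int = 10_000,
) -> list[str]:
    """Greedy LD clump of candidate SNPs.

    ``candidates`` needs columns ``snp_id`` and ``pval``; ``chrom``/``pos``
    are taken from the frame when present, else from ``ld.positions`` (required
    when window pruning is requested).  Candidates are visited in ascending p
    (ties broken by snp_id); each is accepted unless it has r^2 >=
    ``r2_threshold`` with an already-accepted SNP on the same chromosome
    within ``window_kb`` (center-to-center).  Returns accepted snp_ids in
    acceptance (p-sorted) order; deterministic given inputs.
    """
    df = candidates.copy()
    if "chrom" not in df.columns or "pos" not in df.columns:
        if window_kb is not None and not ld.positions:
            raise ValueError("window pruning requested but no positions available")
        df["chrom"] = [ld.positions.get(s, (None, None))[0] for s in df["snp_id"]]
        df["pos"] = [ld.positions.get(s, (None, None))[1] for s in df["snp_id"]]
    df = df.sort_values(["pval", "snp_id"], kind="mergesort")

    accepted: list[tuple[str, object, float]] = []
    window_bp = None if window_kb is None else window_kb * 1000.0
    for snp, chrom, pos in df[["snp_id", "chrom", "pos"]].itertuples(index=False, name=None):
        linked = False
        for a_snp, a_chrom, a_pos in accepted:
            if window_bp is not None:
                if chrom != a_chrom or pos is None or a_pos is None:
                    continue
                if abs(float(pos) - float(a_pos)) > window_bp:
                    continue
            if ld.r2(snp, a_snp) >= r2_threshold:
                linked = True
                break
        if not linked:
            accepted.append((snp, chrom, pos))
    return [s for s, _, _ in accepted]


def f_statistics(hs: HarmonizedSet) -> InstrumentStrength:
    """Per-SNP Wald F = (beta_X / se_X)^2 and the mean over instruments."""
    if len(hs) == 0:
        raise ValueError("empty harmonized set")
    per = (hs.beta_exposure / hs.se_exposure) ** 2
    return InstrumentStrength(per_snp_f=per, mean_f=float(per.mean()))
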