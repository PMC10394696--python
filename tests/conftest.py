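"""Shared fixtures and helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from mrmediate.gwas_io import CANONICAL_COLUMNS, HarmonizedSet, SummaryStatsTable

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_table(rows, trait_label="trait", trait_type="continuous"):
    """Build a SummaryStatsTable from a list of per-SNP dicts.

    Unspecified columns get sensible defaults; p-values default to the Wald
    p implied by beta/se so the validity invariants hold.
    """
    from scipy import stats

    full = []
    for i, row in enumerate(rows):
        rec = {
            "snp_id": f"rs{i + 1}",
            "chrom": "1",
            "pos": 1_000_000 + i * 100_000,
            "effect_allele": "A",
            "other_allele": "G",
            "eaf": 0.3,
            "n": 10_000,
        }
        rec.update(row)
        if "pval" not in rec:
            rec["pval"] = float(2 * stats.norm.sf(abs(rec["beta"]) / rec["se"]))
        full.append(rec)
    df = pd.DataFrame(full, columns=CANONICAL_COLUMNS)
    return SummaryStatsTable(trait_label, trait_type, df, "test fixture")


def make_hs(bx, sx, by, sy, eaf=None):
    """Build a HarmonizedSet directly from effect arrays."""
    bx = np.asarray(bx, dtype=float)
    return HarmonizedSet(
        snp_ids=np.array([f"rs{i + 1}" for i in range(len(bx))], dtype=object),
        beta_exposure=bx,
        se_exposure=np.asarray(sx, dtype=float),
        beta_outcome=np.asarray(by, dtype=float),
        se_outcome=np.asarray(sy, dtype=float),
        eaf=None if eaf is None else np.asarray(eaf, dtype=float),
    )


def random_hs(rng, m=None, true_effect=0.0):
    """A random harmonized set with exact sampling-model noise."""
    m = m or rng.integers(3, 11)
    sx = rng.uniform(0.01, 0.05, m)
    sy = rng.uniform(0.005, 0.02, m)
    bx_true = rng.choice([-1, 1], m) * rng.uniform(5, 9, m) * sx
    bx = bx_true + rng.standard_normal(m) * sx
    by = true_effect * bx_true + rng.standard_normal(m) * sy
    return make_hs(bx, sx, by, sy)


@pytest.fixture
def rng():
    return np.random.default_rng(20231)
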