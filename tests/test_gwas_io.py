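"""Reading, validation and harmonization of summary statistics."""

import numpy as np
import pandas as pd
import pytest

from mrmediate.gwas_io import (
    CANONICAL_COLUMNS,
    harmonize,
    read_summary_stats,
    read_report,
    substitute_proxies,
    write_report,
)
from mrmediate.uvmr import MREstimate

from conftest import make_table


def write_tsv(path, rows):
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


VALID_ROW = dict(
    snp_id="rs1", chrom="1", pos=1000, effect_allele="A", other_allele="G",
    eaf=0.3, beta=0.1, se=0.02, pval=5.7e-7, n=1000,
)


class TestRead:
    def test_valid_rows_pass_through(self, tmp_path):
        rows = [dict(VALID_ROW, snp_id=f"rs{i}", pval=None) for i in range(3)]
        path = tmp_path / "sumstats.tsv"
        write_tsv(path, rows)
        table = read_summary_stats(path)
        assert len(table) == 3
        assert list(table.df.columns) == CANONICAL_COLUMNS
        assert "dropped 0" in table.provenance

    def test_invalid_rows_dropped_and_counted(self, tmp_path):
        rows = [
            dict(VALID_ROW, pval=None),
            dict(VALID_ROW, snp_id="rs2", se=0.0, pval=None),  # non-positive SE
            dict(VALID_ROW, snp_id="rs3", effect_allele="I", pval=None),  # indel code
            dict(VALID_ROW, snp_id="rs4", effect_allele="G", pval=None),  # ea == oa
            dict(VALID_ROW, snp_id="rs5", eaf=1.2, pval=None),
            dict(VALID_ROW, snp_id="rs6", pval=0.9),  # inconsistent with z = 5
        ]
        path = tmp_path / "sumstats.tsv"
        write_tsv(path, rows)
        table = read_summary_stats(path)
        assert len(table) == 1
        assert "dropped 5" in table.provenance

    def test_missing_mandatory_column_is_named(self, tmp_path):
        rows = [{k: v for k, v in VALID_ROW.items() if k != "se"}]
        path = tmp_path / "sumstats.tsv"
        write_tsv(path, rows)
        with pytest.raises(ValueError, match="'se'"):
            read_summary_stats(path)

    def test_column_map_renames(self, tmp_path):
        rows = [dict(SNP="rs1", ea="A", oa="G", b=0.1, stderr=0.02)]
        path = tmp_path / "sumstats.tsv"
        write_tsv(path, rows)
        table = read_summary_stats(
            path,
            column_map={
                "snp_id": "SNP", "effect_allele": "ea", "other_allele": "oa",
                "beta": "b", "se": "stderr",
            },
        )
        assert len(table) == 1


class TestHarmonize:
    def exposure(self):
        return make_table(
            [dict(effect_allele="A", other_allele="G", beta=0.1, se=0.02, eaf=0.3)]
        )

    @pytest.mark.parametrize(
        "out_ea, out_oa, expected_beta, reason",
        [
            ("A", "G", 0.05, None),          # same orientation
            ("G", "A", -0.05, None),         # swapped: sign flips
            ("A", "C", None, "incompatible alleles"),
            ("C", "T", None, "incompatible alleles"),
        ],
    )
    def test_orientation_truth_table(self, out_ea, out_oa, expected_beta, reason):
        outcome = make_table(
            [dict(effect_allele=out_ea, other_allele=out_oa, beta=0.05, se=0.01,
                  eaf=0.3)]
        )
        hs = harmonize(self.exposure(), outcome)
        if expected_beta is None:
            assert len(hs) == 0
            assert hs.dropped == [("rs1", reason)]
        else:
            assert hs.beta_outcome[0] == pytest.approx(expected_beta)
            assert hs.dropped == []

    def test_palindrome_strict_drops(self):
        expo = make_table([dict(effect_allele="A", other_allele="T", beta=0.1,
                                se=0.02, eaf=0.8)])
        outc = make_table([dict(effect_allele="A", other_allele="T", beta=0.05,
                                se=0.01, eaf=0.8)])
        hs = harmonize(expo, outc, action="strict")
        assert len(hs) == 0 and hs.dropped[0][1] == "palindromic"

    def test_palindrome_midfrequency_ambiguous(self):
        expo = make_table([dict(effect_allele="A", other_allele="T", beta=0.1,
                                se=0.02, eaf=0.50)])
        outc = make_table([dict(effect_allele="A", other_allele="T", beta=0.05,
                                se=0.01, eaf=0.50)])
        hs = harmonize(expo, outc, palindrome_eaf_window=0.08, action="infer")
        assert hs.dropped == [("rs1", "palindromic ambiguous")]

    def test_palindrome_missing_eaf_is_ambiguous(self):
        expo = make_table([dict(effect_allele="A", other_allele="T", beta=0.1,
                                se=0.02, eaf=np.nan)])
        outc = make_table([dict(effect_allele="A", other_allele="T", beta=0.05,
                                se=0.01, eaf=0.8)])
        hs = harmonize(expo, outc, action="infer")
        assert hs.dropped == [("rs1", "palindromic ambiguous")]

    def test_palindrome_frequency_resolves_strand(self):
        # frequencies on opposite sides of 0.5 indicate a strand flip
        expo = make_table([dict(effect_allele="A", other_allele="T", beta=0.1,
                                se=0.02, eaf=0.8)])
        outc = make_table([dict(effect_allele="A", other_allele="T", beta=0.05,
                                se=0.01, eaf=0.2)])
        hs = harmonize(expo, outc, action="infer")
        assert hs.beta_outcome[0] == pytest.approx(-0.05)
        # frequencies agreeing: orientation kept
        outc2 = make_table([dict(effect_allele="A", other_allele="T", beta=0.05,
                                 se=0.01, eaf=0.75)])
        hs2 = harmonize(expo, outc2, action="infer")
        assert hs2.beta_outcome[0] == pytest.approx(0.05)

    def test_empty_intersection_errors(self):
        expo = self.exposure()
        outc = make_table([dict(snp_id="zz9", beta=0.05, se=0.01)])
        with pytest.raises(ValueError, match="overlap"):
            harmonize(expo, outc)

    def _random_pair(self, rng, m=40):
        pairs = [("A", "G"), ("C", "T"), ("A", "C"), ("A", "T"), ("C", "G")]
        rows_e, rows_o = [], []
        for i in range(m):
            ea, oa = pairs[rng.integers(len(pairs))]
            eaf = float(rng.uniform(0.05, 0.95))
            base = dict(snp_id=f"rs{i}", eaf=eaf)
            rows_e.append(dict(base, effect_allele=ea, other_allele=oa,
                               beta=float(rng.normal()), se=0.02))
            if rng.random() < 0.5:
                rows_o.append(dict(base, effect_allele=oa, other_allele=ea,
                                   beta=float(rng.normal()), se=0.01,
                                   eaf=1 - eaf))
            else:
                rows_o.append(dict(base, effect_allele=ea, other_allele=oa,
                                   beta=float(rng.normal()), se=0.01))
        return make_table(rows_e), make_table(rows_o)

    def test_sign_symmetry(self, rng):
        """Flipping every outcome allele pair and beta sign changes nothing."""
        expo, outc = self._random_pair(rng)
        flipped = outc.df.copy()
        flipped[["effect_allele", "other_allele"]] = flipped[
            ["other_allele", "effect_allele"]
        ].to_numpy()
        flipped["beta"] = -flipped["beta"]
        flipped["eaf"] = 1 - flipped["eaf"]
        outc_flipped = make_table([])
        outc_flipped.df = flipped
        h1 = harmonize(expo, outc)
        h2 = harmonize(expo, outc_flipped)
        np.testing.assert_array_equal(h1.snp_ids, h2.snp_ids)
        np.testing.assert_allclose(h1.beta_outcome, h2.beta_outcome)
        assert h1.dropped == h2.dropped

    def test_accounting(self, rng):
        """Every SNP in the intersection is either harmonized or dropped."""
        expo, outc = self._random_pair(rng)
        hs = harmonize(expo, outc)
        intersection = set(expo.df.snp_id) & set(outc.df.snp_id)
        assert len(hs) + len(hs.dropped) == len(intersection)

    def test_idempotent(self, rng):
        """Harmonizing an already-aligned pair is the identity."""
        expo, outc = self._random_pair(rng)
        h1 = harmonize(expo, outc)
        aligned = expo.df[expo.df.snp_id.isin(h1.snp_ids)].copy()
        order = {s: i for i, s in enumerate(h1.snp_ids)}
        aligned = aligned.sort_values("snp_id", key=lambda s: s.map(order))
        aligned["beta"] = h1.beta_outcome
        aligned["se"] = h1.se_outcome
        aligned["pval"] = np.nan
        outc2 = make_table([])
        outc2.df = aligned.reset_index(drop=True)
        h2 = harmonize(expo, outc2)
        np.testing.assert_array_equal(h1.snp_ids, h2.snp_ids)
        np.testing.assert_allclose(h1.beta_outcome, h2.beta_outcome)


class TestProxies:
    def available(self):
        return make_table(
            [
                dict(snp_id="rs9", beta=0.2, se=0.02),
                dict(snp_id="rs10", beta=-0.1, se=0.02),
            ]
        )

    def proxy_map(self, rows):
        return pd.DataFrame(rows, columns=["snp_id", "proxy_id", "r2", "phase"])

    def test_single_proxy_substituted(self):
        pm = self.proxy_map([("rs1", "rs9", 0.95, "same")])
        out = substitute_proxies(["rs1"], self.available(), pm, min_r2=0.8)
        assert "rs1" in set(out.df.snp_id)
        assert "rs9->rs1" in out.provenance

    def test_highest_r2_wins(self):
        pm = self.proxy_map([("rs1", "rs9", 0.8, "same"), ("rs1", "rs10", 0.9, "same")])
        out = substitute_proxies(["rs1"], self.available(), pm, min_r2=0.8)
        sub = out.df[out.df.snp_id == "rs1"]
        assert sub.beta.iloc[0] == pytest.approx(-0.1)  # rs10's record

    def test_below_threshold_not_substituted(self):
        pm = self.proxy_map([("rs1", "rs9", 0.5, "same")])
        out = substitute_proxies(["rs1"], self.available(), pm, min_r2=0.8)
        assert "rs1" not in set(out.df.snp_id)

    def test_phase_flip_applied(self):
        pm = self.proxy_map([("rs1", "rs9", 0.95, "flip")])
        out = substitute_proxies(["rs1"], self.available(), pm, min_r2=0.8)
        sub = out.df[out.df.snp_id == "rs1"]
        assert sub.beta.iloc[0] == pytest.approx(-0.2)


class TestReport:
    def test_roundtrip(self, tmp_path, rng):
        results = [
            MREstimate.from_beta_se("IVW", rng.normal(), rng.uniform(0.01, 1), 10)
            for _ in range(5)
        ]
        tsv, js = write_report(results, tmp_path / "report")
        back = read_report(tmp_path / "report")
        assert len(back) == 5
        np.testing.assert_allclose(back["beta"], [r.beta for r in results])
        # CI bounds always bracket the point estimate, on both scales
        assert (back["ci_low"] < back["beta"]).all()
        assert (back["beta"] < back["ci_high"]).all()
        assert (back["or_ci_low"] < back["or"]).all()

    def test_empty_results_header_only(self, tmp_path):
        write_report([], tmp_path / "empty")
        back = read_report(tmp_path / "empty")
        assert len(back) == 0 and "beta" in back.columns
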