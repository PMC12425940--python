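"""ENC-plot, PR2, neutrality regression and correlation matrix."""

import math

import numpy as np
import pandas as pd
import pytest

from _oracles import ols_oracle, pearson_oracle, pr2_oracle
from conftest import table_to_sequence
from cubkit.codon_stats import EncResult, enc
from cubkit.composition import CompositionProfile, composition_profile
from cubkit.diagnostics import (
    correlation_matrix,
    enc_expected,
    enc_plot_table,
    index_table,
    neutrality_fit,
    pr2_point,
)
from cubkit.genetic_code import ALL_CODONS
from cubkit.seqio import CodonCountTable


def table_from(counts, gene_id="g"):
    full = dict.fromkeys(ALL_CODONS, 0)
    full.update(counts)
    return CodonCountTable(gene_id, full, sum(counts.values()))


class TestEncExpected:
    @pytest.mark.parametrize(
        "s,expected", [(0.5, 60.5), (0.0, 31.0), (1.0, 32.0)]
    )
    def test_closed_form_values(self, s, expected):
        assert enc_expected(s) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            enc_expected(-0.01)
        with pytest.raises(ValueError):
            enc_expected(1.01)

    def test_curve_peaks_near_half(self):
        s = np.linspace(0, 1, 1001)
        vals = [enc_expected(v) for v in s]
        assert abs(s[int(np.argmax(vals))] - 0.5) < 0.01


class TestEncPlot:
    def test_gene_on_curve_has_zero_deviation(self, random_tables, code):
        prof = composition_profile(random_tables[0], code)
        on_curve = EncResult(gene_id=prof.gene_id, enc=enc_expected(prof.gc3s), f_bar={})
        df, summary = enc_plot_table([(prof, on_curve)])
        assert df["deviation"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert summary == {"n_below": 0, "n_near": 1, "n_above": 0}

    def test_mismatched_ids_rejected(self, random_tables, code):
        prof = composition_profile(random_tables[0], code)
        other = EncResult(gene_id="someone_else", enc=50.0, f_bar={})
        with pytest.raises(ValueError, match="mismatched"):
            enc_plot_table([(prof, other)])

    def test_summary_counts_partition_genes(self, random_tables, code):
        pairs = [(composition_profile(t, code), enc(t, code)) for t in random_tables]
        df, summary = enc_plot_table(pairs)
        assert summary["n_below"] + summary["n_near"] + summary["n_above"] == len(df)


class TestPr2:
    def test_balanced_fourfold_usage_is_centered(self, code):
        p = pr2_point(table_from({"GGA": 5, "GGT": 5, "GGG": 5, "GGC": 5}), code)
        assert (p.x, p.y) == (0.5, 0.5)
        assert p.n_sites == 20

    def test_zero_denominator_flags_point(self, code):
        p = pr2_point(table_from({"GGG": 3, "GGC": 1}), code)
        assert p.x == pytest.approx(0.75)
        assert math.isnan(p.y)
        assert not p.ok

    def test_twofold_codons_excluded_from_fourfold_sites(self, code):
        # Lys is 2-fold: contributes nothing under the default site set
        p = pr2_point(table_from({"AAA": 50, "GGG": 2, "GGC": 2}), code)
        assert p.n_sites == 4
        all_sites = pr2_point(table_from({"AAA": 50, "GGG": 2, "GGC": 2}), code,
                              site_set="all")
        assert all_sites.n_sites == 54

    def test_strand_symmetric_usage_is_centered(self, code):
        # every codon count equals its A<->T, G<->C swapped partner in-family
        counts = {}
        for aa in "VPTAG":
            fam = code.families[aa]
            for c in fam:
                counts[c] = {"A": 3, "T": 3, "G": 8, "C": 8}[c[2]]
        p = pr2_point(table_from(counts), code)
        assert (p.x, p.y) == (0.5, 0.5)

    def test_matches_string_walk_oracle(self, random_tables, code):
        for t in random_tables:
            p = pr2_point(t, code)
            x, y = pr2_oracle(table_to_sequence(t), code)
            assert p.x == pytest.approx(x, abs=1e-12)
            assert p.y == pytest.approx(y, abs=1e-12)


class TestNeutrality:
    def _profiles(self, xs, ys):
        return [
            CompositionProfile(
                gene_id=f"g{i}", gc=0.5, gc1=y, gc2=y, gc3=x, gc12=y,
                gc3s=x, a3s=0, t3s=0, g3s=0, c3s=0, n_codons=100,
            )
            for i, (x, y) in enumerate(zip(xs, ys))
        ]

    def test_identity_line(self):
        xs = np.linspace(0.3, 0.8, 10)
        fit = neutrality_fit(self._profiles(xs, xs))
        assert fit.slope == pytest.approx(1.0)
        assert fit.r2 == pytest.approx(1.0)

    def test_constant_response_gives_zero_slope(self):
        xs = np.linspace(0.3, 0.8, 10)
        fit = neutrality_fit(self._profiles(xs, np.full(10, 0.5)))
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        assert fit.r2 == pytest.approx(0.0, abs=1e-12)

    def test_matches_sigma_formula_ols(self):
        rng = np.random.default_rng(3)
        xs = rng.uniform(0.3, 0.9, 10)
        ys = 0.2 + 0.4 * xs + rng.normal(0, 0.03, 10)
        fit = neutrality_fit(self._profiles(xs, ys))
        slope, intercept, r2 = ols_oracle(xs, ys)
        assert fit.slope == pytest.approx(slope, abs=1e-12)
        assert fit.intercept == pytest.approx(intercept, abs=1e-12)
        assert fit.r2 == pytest.approx(r2, abs=1e-12)
        assert fit.r2 == pytest.approx(fit.pearson_r**2, abs=1e-9)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            neutrality_fit(self._profiles([0.5, 0.6], [0.5, 0.6]))
        with pytest.raises(ValueError, match="degenerate regressor"):
            neutrality_fit(self._profiles([0.5] * 5, [0.4, 0.5, 0.6, 0.5, 0.4]))


class TestCorrelations:
    def test_diagonal_and_antisymmetric_columns(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=30)
        df = pd.DataFrame({"a": x, "b": -x, "c": rng.normal(size=30)})
        m = correlation_matrix(df, labels=("a", "b", "c"))
        assert np.allclose(np.diag(m.r), 1.0)
        assert m.r.loc["a", "b"] == pytest.approx(-1.0)
        assert np.allclose(m.r, m.r.T)

    def test_matches_sigma_formula_oracle(self, random_tables, code):
        profs = [composition_profile(t, code) for t in random_tables]
        encs = [enc(t, code) for t in random_tables]
        table = index_table(profs, encs)
        m = correlation_matrix(table)
        for i, a in enumerate(m.labels):
            for b in m.labels[i + 1:]:
                r, p = pearson_oracle(table[a], table[b])
                assert m.r.loc[a, b] == pytest.approx(r, abs=1e-12)
                assert m.p.loc[a, b] == pytest.approx(p, abs=1e-9)

    def test_constant_column_flagged_nan(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0], "b": [0.5] * 4})
        m = correlation_matrix(df, labels=("a", "b"))
        assert math.isnan(m.r.loc["a", "b"])
        assert m.starred().loc["a", "b"] == "NA"

    def test_star_annotation_levels(self):
        rng = np.random.default_rng(8)
        x = np.linspace(0, 1, 50)
        df = pd.DataFrame({"a": x, "b": x + rng.normal(0, 0.01, 50),
                           "c": rng.normal(size=50)})
        m = correlation_matrix(df, labels=("a", "b", "c"))
        assert m.starred().loc["a", "b"].endswith("**")
        assert m.starred().loc["a", "a"] == "1.000"

    def test_agrees_with_neutrality_fit(self, random_tables, code):
        profs = [composition_profile(t, code) for t in random_tables]
        encs = [enc(t, code) for t in random_tables]
        fit = neutrality_fit(profs)
        table = index_table(profs, encs)
        m = correlation_matrix(table, labels=("GC12", "GC3"))
        assert m.r.loc["GC12", "GC3"] ** 2 == pytest.approx(fit.r2, abs=1e-9)
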