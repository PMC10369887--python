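"""TF-IDF, gene-peak links, openness testing and accessibility scores."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import poisson

from celldensity.chromatin import (
    accessibility_scores,
    classify_peaks,
    gene_peak_correlation,
    insilico_chip,
    lineage_relevant_peaks,
    peak_openness,
    tfidf_normalize,
)


class TestTfidf:
    def test_zero_count_stays_zero(self):
        counts = np.array([[0.0, 2.0], [1.0, 1.0]])
        out = tfidf_normalize(counts)
        assert out[0, 0] == 0.0

    def test_ubiquitous_peak_idf_approaches_log2(self):
        n = 500
        counts = np.ones((n, 1))
        out = tfidf_normalize(counts)
        # tf = 1 for a single-peak matrix; idf = log(1 + N/(1+N))
        np.testing.assert_allclose(out, np.log(1 + n / (1 + n)), rtol=1e-12)
        assert out[0, 0] == pytest.approx(np.log(2), abs=2e-3)

    def test_column_order_invariance(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(1.0, size=(30, 8)).astype(float)
        counts[:, 0] += 1  # avoid all-zero cells
        perm = rng.permutation(8)
        out = tfidf_normalize(counts)
        np.testing.assert_allclose(tfidf_normalize(counts[:, perm]), out[:, perm])

    def test_all_zero_cell_rejected(self):
        with pytest.raises(ValueError):
            tfidf_normalize(np.array([[0.0, 0.0], [1.0, 1.0]]))


class TestGenePeakCorrelation:
    def test_perfect_correlation_retained(self):
        x = np.linspace(0, 1, 50)
        expr = pd.DataFrame({"g": x})
        acc = pd.DataFrame({"p": 2 * x + 1})
        out = gene_peak_correlation(expr, acc, [("g", "p")], n_permutations=99)
        row = out.iloc[0]
        assert row["corr"] == pytest.approx(1.0)
        assert row["p"] == pytest.approx(1 / 100)
        assert bool(row["linked"])

    def test_anticorrelation_excluded_one_sided(self):
        x = np.linspace(0, 1, 50)
        out = gene_peak_correlation(
            pd.DataFrame({"g": x}), pd.DataFrame({"p": -x}), [("g", "p")],
            n_permutations=99,
        )
        assert out.iloc[0]["corr"] == pytest.approx(-1.0)
        assert not bool(out.iloc[0]["linked"])

    def test_null_calibration(self):
        # independent Gaussian pairs: the 0.1/0.1 joint gate retains few
        rng = np.random.default_rng(11)
        kept = 0
        reps = 200
        for r in range(reps):
            e = pd.DataFrame({"g": rng.standard_normal(100)})
            a = pd.DataFrame({"p": rng.standard_normal(100)})
            out = gene_peak_correlation(e, a, [("g", "p")],
                                        n_permutations=999, seed=r)
            kept += int(out.iloc[0]["linked"])
        assert kept / reps <= 0.15

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            gene_peak_correlation(
                pd.DataFrame({"g": np.ones(20)}),
                pd.DataFrame({"p": np.arange(20.0)}),
                [("g", "p")],
                n_permutations=99,
            )


class TestPeakOpenness:
    def test_printed_rate_construction(self):
        # 10 peaks, 100,000 fragments: effective length 50,000 -> lambda = 2
        counts = np.full(10, 10_000)
        lam = counts.sum() / (10 * 5000)
        assert lam == pytest.approx(2.0)

    def test_openness_calls_match_term_summation_oracle(self):
        counts = np.array([7, 5, 0, 2, 12])
        total, npk = counts.sum(), counts.size
        lam = total / (npk * 5000)
        calls = peak_openness(counts)

        import math

        def tail(n):  # P(X > n) by explicit term summation
            terms = [np.exp(-lam) * lam**k / math.factorial(k) for k in range(n + 1)]
            return 1.0 - sum(terms)

        expected = np.array([tail(int(n)) < 1e-2 for n in counts])
        np.testing.assert_array_equal(calls, expected)

    def test_lambda2_boundary_cases(self):
        # under lambda = 2: n=7 open (P ~ 0.0011), n=5 closed (P ~ 0.0166)
        counts = np.array([7, 5])
        # choose num_peaks so that lambda = 2
        total = counts.sum()
        num_peaks = total / (2 * 5000)
        calls = peak_openness(counts, num_peaks=num_peaks)
        assert poisson.sf(7, 2.0) == pytest.approx(0.0011, abs=1e-4)
        assert poisson.sf(5, 2.0) == pytest.approx(0.0166, abs=1e-4)
        assert calls[0] and not calls[1]

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            peak_openness(np.zeros(5))


class TestClassifyPeaks:
    def _links(self):
        return pd.DataFrame(
            {
                "gene": ["g1", "g1", "g1"],
                "peak": ["pA", "pB", "pC"],
                "corr": [0.5, 0.4, 0.3],
                "p": [0.01, 0.01, 0.01],
                "linked": [True, True, True],
            }
        )

    def test_open_reference_is_primed(self):
        out = classify_peaks(
            self._links(),
            lineage_relevant=[True, True, False],
            reference_open=[True, False, True],
            peak_ids=["pA", "pB", "pC"],
        )
        assert list(out["class"]) == ["primed", "lineage_specific", "excluded"]

    def test_irrelevant_peaks_excluded_regardless(self):
        out = classify_peaks(
            self._links(),
            lineage_relevant=[False, False, False],
            reference_open=[True, False, True],
            peak_ids=["pA", "pB", "pC"],
        )
        assert set(out["class"]) == {"excluded"}


class TestLineageRelevantPeaks:
    def test_screen_flags_lineage_enriched_only(self):
        acc = pd.DataFrame(
            [
                [5.0, 0.1, 5.0],  # target metacell
                [0.1, 0.1, 5.0],  # other lineage
                [0.1, 0.1, 5.0],  # reference (stem)
            ],
            columns=["specific", "silent", "ubiquitous"],
        )
        mask = lineage_relevant_peaks(
            acc,
            {"target": [0], "other": [1], "stem": [2]},
            lineage="target",
            other_lineages=["other"],
            reference="stem",
        )
        np.testing.assert_array_equal(mask, [True, False, False])


class TestAccessibilityScores:
    def _table(self):
        return pd.DataFrame(
            {
                "gene": ["g", "g"],
                "peak": ["p1", "p2"],
                "corr": [0.2, 0.6],
                "class": ["primed", "primed"],
            }
        )

    def test_single_peak_returns_accessibility(self):
        acc = pd.DataFrame({"p1": [0.4], "p2": [0.0]})
        table = self._table().iloc[:1]
        np.testing.assert_allclose(
            accessibility_scores(acc, table, "g", "primed"), [0.4]
        )

    def test_two_peak_weighted_average(self):
        acc = pd.DataFrame({"p1": [0.4], "p2": [0.8]})
        out = accessibility_scores(acc, self._table(), "g", "primed")
        assert out[0] == pytest.approx((0.4 * 0.2 + 0.8 * 0.6) / 0.8)
        assert out[0] == pytest.approx(0.7)

    def test_weight_scaling_invariance(self):
        acc = pd.DataFrame({"p1": [0.4, 0.1], "p2": [0.8, 0.9]})
        t1 = self._table()
        t2 = t1.copy()
        t2["corr"] *= 7.0
        np.testing.assert_allclose(
            accessibility_scores(acc, t1, "g", "primed"),
            accessibility_scores(acc, t2, "g", "primed"),
        )

    def test_missing_class_returns_none_with_warning(self):
        acc = pd.DataFrame({"p1": [0.4]})
        with pytest.warns(UserWarning, match="no lineage_specific"):
            out = accessibility_scores(acc, self._table(), "g", "lineage_specific")
        assert out is None


class TestInsilicoChip:
    def test_step_by_step_worked_example(self):
        # two peaks, one TF: s=(5,10), max a=(1,1), rho=(0.5,0.8)
        rho = np.array([[0.5], [0.8]])
        s = np.array([[5.0], [10.0]])
        a = np.array([1.0, 1.0])
        x = insilico_chip(rho, s, a)
        np.testing.assert_allclose(x[:, 0], [0.0, 0.8])

    def test_negative_correlation_gives_repressive_sign(self):
        rho = np.array([[0.5], [-0.8]])
        s = np.array([[5.0], [10.0]])
        x = insilico_chip(rho, s, np.array([1.0, 1.0]))
        assert x[1, 0] == pytest.approx(-0.8)

    def test_motif_scale_invariance(self):
        rng = np.random.default_rng(4)
        rho = rng.uniform(-1, 1, size=(6, 2))
        s = rng.uniform(1, 10, size=(6, 2))
        a = rng.uniform(0.1, 1, size=6)
        np.testing.assert_allclose(
            insilico_chip(rho, s, a), insilico_chip(rho, 13.0 * s, a)
        )

    def test_subthreshold_zeroed_exactly(self):
        rho = np.array([[0.1], [0.14]])
        s = np.array([[5.0], [10.0]])
        x = insilico_chip(rho, s, np.array([1.0, 1.0]))
        np.testing.assert_array_equal(x, 0.0)

    def test_degenerate_single_value_minmax_warns(self):
        rho = np.array([[0.9], [0.9]])
        s = np.array([[5.0], [5.0]])
        with pytest.warns(UserWarning, match="degenerate"):
            x = insilico_chip(rho, s, np.array([1.0, 1.0]))
        np.testing.assert_array_equal(x, 0.0)


class TestBedIO:
    def test_roundtrip(self, tmp_path):
        from celldensity.chromatin import read_peaks_bed, write_peaks_bed

        ids = ["chr1:100-600", "chr2:0-500", "chrX:1000-1500"]
        path = tmp_path / "peaks.bed"
        write_peaks_bed(ids, str(path))
        df = read_peaks_bed(str(path))
        assert list(df["peak"]) == ids
        assert df["start"].tolist() == [100, 0, 1000]

    def test_malformed_line_rejected(self, tmp_path):
        path = tmp_path / "bad.bed"
        path.write_text("chr1\t100\n")
        from celldensity.chromatin import read_peaks_bed

        with pytest.raises(ValueError, match="malformed"):
            read_peaks_bed(str(path))
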