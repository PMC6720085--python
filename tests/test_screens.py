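"""Family/locus correlation screens, binding overlap, L1HS-gene models."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tecoex.annotations import TELocus
from tecoex.screens import (
    OverlapTable, aicc, binding_overlap_family, category_mark_overlap,
    expressed_loci, fit_l1hs_gene_model, gene_filters, l1hs_gene_screen,
    locus_followup, pairwise_family_screen, peak_te_overlap,
)


def correlated_profiles(rng, n, r):
    f = rng.standard_normal(n)
    x = math.sqrt(r) * f + math.sqrt(1 - r) * rng.standard_normal(n)
    y = math.sqrt(r) * f + math.sqrt(1 - r) * rng.standard_normal(n)
    return x, y


class TestFamilyScreen:
    def _tissue_data(self, rng, n_null=200, n_planted=5, n_samples=50, r=0.8):
        samples = [f"s{i}" for i in range(n_samples)]
        kz_rows, te_rows = {}, {}
        for i in range(n_planted):
            x, y = correlated_profiles(rng, n_samples, r)
            kz_rows[f"KZ_plant{i}"] = x
            te_rows[f"TE_plant{i}"] = y
        for i in range(n_null):
            kz_rows[f"KZ_null{i % 20}"] = \
                kz_rows.get(f"KZ_null{i % 20}", rng.standard_normal(n_samples))
        for i in range(20):
            te_rows[f"TE_null{i}"] = rng.standard_normal(n_samples)
        kz = pd.DataFrame(kz_rows, index=samples).T
        te = pd.DataFrame(te_rows, index=samples).T
        return kz, te

    def test_planted_pairs_significant_nulls_controlled(self):
        rng = np.random.default_rng(0)
        kz, te = self._tissue_data(rng)
        results, rep = pairwise_family_screen({"t1": kz}, {"t1": te})
        sig = {(r.predictor, r.response) for r in results if r.q_value < 0.05}
        for i in range(5):
            assert (f"KZ_plant{i}", f"TE_plant{i}") in sig
        null_hits = [p for p in sig if "null" in p[0] and "null" in p[1]]
        assert len(null_hits) / max(len(sig), 1) <= 0.1

    def test_identical_profiles_perfect(self):
        samples = [f"s{i}" for i in range(20)]
        prof = np.random.default_rng(1).standard_normal(20)
        kz = pd.DataFrame({"KZ": prof}, index=samples).T
        te = pd.DataFrame({"TE": prof}, index=samples).T
        results, rep = pairwise_family_screen({"t1": kz}, {"t1": te})
        assert results[0].coefficient == pytest.approx(1.0)
        assert results[0].p_value == pytest.approx(0.0, abs=1e-30)
        assert rep.loc[("KZ", "TE"), "n_tissues_significant"] == 1

    def test_replication_requires_consistent_sign(self):
        rng = np.random.default_rng(2)
        samples = [f"s{i}" for i in range(40)]
        prof = rng.standard_normal(40)
        kz = {t: pd.DataFrame({"KZ": prof}, index=samples).T
              for t in ("t1", "t2")}
        te = {"t1": pd.DataFrame({"TE": prof}, index=samples).T,
              "t2": pd.DataFrame({"TE": -prof}, index=samples).T}
        _, rep = pairwise_family_screen(kz, te)
        assert rep.loc[("KZ", "TE"), "n_tissues_significant"] == 2
        assert rep.loc[("KZ", "TE"), "sign"] == 0  # inconsistent signs

    def test_too_few_samples_rejected(self):
        samples = [f"s{i}" for i in range(4)]
        m = pd.DataFrame({"a": range(4)}, index=samples).T.astype(float)
        with pytest.raises(ValueError):
            pairwise_family_screen({"t": m}, {"t": m})


class TestLocusFollowup:
    def test_driving_locus_identified(self):
        rng = np.random.default_rng(3)
        n = 60
        samples = [f"s{i}" for i in range(n)]
        kz_prof, driver = correlated_profiles(rng, n, 0.85)
        kz = {"t1": pd.DataFrame({"KZ1": kz_prof}, index=samples).T}
        loci = {"FAM_dup1": driver}
        for i in range(2, 11):
            loci[f"FAM_dup{i}"] = rng.standard_normal(n)
        locus_m = {"t1": pd.DataFrame(loci, index=samples).T}
        fam_of = {l: "FAM" for l in loci}
        hits = locus_followup([("KZ1", "FAM", "t1")], kz, locus_m, fam_of)
        assert [h.response for h in hits] == ["FAM_dup1"]

    def test_flat_loci_yield_empty(self):
        samples = [f"s{i}" for i in range(20)]
        kz = {"t1": pd.DataFrame(
            {"KZ1": np.arange(20.0)}, index=samples).T}
        locus_m = {"t1": pd.DataFrame(
            {"F_dup1": np.ones(20)}, index=samples).T}
        hits = locus_followup([("KZ1", "F", "t1")], kz, locus_m,
                              {"F_dup1": "F"})
        assert hits == []

    def test_batch_of_one_q_equals_p(self):
        rng = np.random.default_rng(4)
        n = 30
        samples = [f"s{i}" for i in range(n)]
        x, y = correlated_profiles(rng, n, 0.9)
        kz = {"t1": pd.DataFrame({"KZ1": x}, index=samples).T}
        locus_m = {"t1": pd.DataFrame({"F_dup1": y}, index=samples).T}
        [hit] = locus_followup([("KZ1", "F", "t1")], kz, locus_m,
                               {"F_dup1": "F"})
        assert hit.q_value == pytest.approx(hit.p_value)


class TestBindingOverlap:
    def test_universe_size(self):
        kzfps = {f"KZ{i}" for i in range(221)}
        fams = {f"F{i}" for i in range(909)}
        enr = pd.DataFrame({"kzfp": ["KZ0"], "family": ["F0"],
                            "score": [2.0]})
        table = binding_overlap_family({("KZ0", "F1")}, enr, kzfps, fams)
        assert table.total == 200_889

    def test_independent_binding_odds_near_one(self):
        rng = np.random.default_rng(5)
        kzfps = {f"KZ{i}" for i in range(40)}
        fams = {f"F{i}" for i in range(50)}
        pairs = [(k, f) for k in kzfps for f in fams]
        coexp = {p for p in pairs if rng.random() < 0.2}
        enr = pd.DataFrame(
            [{"kzfp": k, "family": f, "score": 2.0}
             for (k, f) in pairs if rng.random() < 0.2])
        table = binding_overlap_family(coexp, enr, kzfps, fams)
        assert table.p_value > 0.01
        assert 0.7 < table.odds_ratio < 1.4

    def test_perfect_nesting_infinite_odds(self):
        kzfps, fams = {"K1", "K2"}, {"F1", "F2"}
        enr = pd.DataFrame([
            {"kzfp": "K1", "family": "F1", "score": 3.0},
            {"kzfp": "K1", "family": "F2", "score": 3.0},
        ])
        table = binding_overlap_family({("K1", "F1"), ("K1", "F2")},
                                       enr, kzfps, fams)
        assert math.isinf(table.odds_ratio)
        # hypergeom(4,2,2): P(X=2)=P(X=0)=1/6, two-sided sums both extremes
        assert table.p_value == pytest.approx(1 / 3)

    def test_fisher_matches_hypergeometric_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            a, b, c, d = rng.integers(0, 13, size=4)
            if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
                continue
            t = OverlapTable(int(a), int(b), int(c), int(d))
            _, p = stats.fisher_exact(t.as_array())
            n, K, N = a + b + c + d, a + b, a + c
            rv = stats.hypergeom(n, K, N)
            support = np.arange(max(0, K + N - n), min(K, N) + 1)
            pmf_obs = rv.pmf(a)
            oracle = rv.pmf(support)[rv.pmf(support) <= pmf_obs * (1 + 1e-9)].sum()
            assert p == pytest.approx(oracle, rel=1e-6)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            binding_overlap_family(set(), pd.DataFrame(
                columns=["kzfp", "family", "score"]), set(), {"F"})


class TestIntervalOps:
    def _loci(self):
        return [TELocus(f"L{i}", "chr1", 10_000 * i + 5_000,
                        10_000 * i + 5_300, "+", "F", "SINE",
                        context="intergenic")
                for i in range(10)]

    def test_buffer_edges(self):
        loci = [TELocus("L", "chr1", 1000, 1300, "+", "F", "SINE")]
        at_edge = [("chr1", 700, 750)]       # widened end 750+250 = 1000: no
        assert peak_te_overlap(at_edge, loci) == set()
        touching = [("chr1", 700, 751)]      # widened end 1001 > 1000: yes
        assert peak_te_overlap(touching, loci) == {"L"}

    def test_random_peaks_match_quadratic_oracle(self):
        rng = np.random.default_rng(7)
        loci = self._loci()
        peaks = [("chr1", int(s), int(s + rng.integers(50, 400)))
                 for s in rng.integers(0, 100_000, size=60)]
        got = peak_te_overlap(peaks, loci, buffer=250)
        oracle = {
            t.locus_id for t in loci
            if any(max(s - 250, 0) < t.end and e + 250 > t.start
                   for (_, s, e) in peaks)
        }
        assert got == oracle

    def test_expressed_threshold_strict(self):
        counts = pd.DataFrame({"s1": [6.0, 5.0, 0.0], "s2": [0.0, 5.0, 0.0]},
                              index=["a", "b", "c"])
        assert expressed_loci(counts) == {"a"}
        assert expressed_loci(counts * 0) == set()

    def test_category_mark_proportions(self):
        loci = self._loci()
        expressed = {"L0", "L1", "L2"}
        bound = {"L2", "L3"}
        whole = {"all": [("chr1", 0, 200_000)]}
        df = category_mark_overlap(loci, expressed, bound, whole)
        assert (df["all"] == 1.0).all()
        none = category_mark_overlap(loci, expressed, bound,
                                     {"none": [("chr2", 0, 10)]})
        assert (none["none"] == 0.0).all()

    def test_planted_mark_enrichment_recovered(self):
        rng = np.random.default_rng(8)
        loci = [TELocus(f"L{i}", "chr1", 1_000 * i, 1_000 * i + 300, "+",
                        "F", "SINE", context="intergenic")
                for i in range(200)]
        expressed = {f"L{i}" for i in range(100)}
        marks = []
        for t in loci:
            p = 0.7 if t.locus_id in expressed else 0.1
            if rng.random() < p:
                marks.append((t.chrom, t.start + 10, t.start + 50))
        df = category_mark_overlap(loci, expressed, set(),
                                   {"enh": marks}).set_index("category")
        assert df.loc["expressed", "enh"] > df.loc["neither", "enh"]


class TestAicc:
    def test_formula_and_undefined_region(self):
        assert aicc(0.0, 3, 100) == pytest.approx(6 + 24 / 96)
        assert math.isinf(aicc(0.0, 19, 20))

    def test_true_covariate_subset_recovered(self):
        rng = np.random.default_rng(9)
        n = 100
        hits = 0
        runs = 30
        for _ in range(runs):
            gene = rng.standard_normal(n)
            lib = rng.standard_normal(n)
            cov = pd.DataFrame({
                "libsize": lib,
                "radiation": rng.integers(0, 2, n).astype(float),
                "n1": rng.standard_normal(n),
            }, index=range(n))
            signal = 0.8 * gene + 0.8 * lib
            y = signal + rng.standard_normal(n) * (signal.std() / 2)
            coef, p, pes, sel = fit_l1hs_gene_model(y, gene, cov)
            hits += sel == ("libsize",)
            assert coef == pytest.approx(0.8, abs=0.25)
        assert hits / runs >= 0.6  # spurious 1-dof terms enter with P~0.15

    def test_all_active_covariates_retained(self):
        rng = np.random.default_rng(10)
        n = 100
        exact = 0
        for _ in range(20):
            gene = rng.standard_normal(n)
            cov = pd.DataFrame({
                "libsize": rng.standard_normal(n),
                "radiation": rng.integers(0, 2, n).astype(float),
                "n1": rng.standard_normal(n),
            }, index=range(n))
            signal = (0.8 * gene + 0.9 * cov["libsize"].to_numpy()
                      + 1.0 * cov["radiation"].to_numpy()
                      + 0.7 * cov["n1"].to_numpy())
            y = signal + rng.standard_normal(n) * (signal.std() / 2)
            _, _, _, sel = fit_l1hs_gene_model(y, gene, cov)
            exact += sel == ("libsize", "n1", "radiation")
        assert exact / 20 >= 0.8

    def test_categorical_block_enters_together(self):
        rng = np.random.default_rng(11)
        n = 80
        batch = rng.integers(0, 3, n)
        cov = pd.DataFrame({
            "batch=1": (batch == 1).astype(float),
            "batch=2": (batch == 2).astype(float),
            "lib": rng.standard_normal(n),
        }, index=range(n))
        gene = rng.standard_normal(n)
        y = 0.9 * gene + 1.5 * (batch == 2) + rng.standard_normal(n) * 0.4
        _, _, _, sel = fit_l1hs_gene_model(y, gene, cov)
        assert "batch" in sel


class TestL1hsScreen:
    def test_constructed_signal_recovered(self):
        rng = np.random.default_rng(12)
        n = 60
        samples = [f"s{i}" for i in range(n)]
        out_results = {}
        gene_prof = rng.standard_normal(n)
        l1hs = {}
        genes = {}
        cov = {}
        for t in ("t1", "t2"):
            noise = rng.standard_normal(n) * 0.3
            l1hs[t] = pd.Series(0.8 * gene_prof + noise, index=samples)
            genes[t] = pd.DataFrame(
                {"TARGET": gene_prof,
                 "NULL": rng.standard_normal(n)}, index=samples).T
            cov[t] = pd.DataFrame(index=samples)
        results, replicated = l1hs_gene_screen(l1hs, genes, cov)
        assert replicated == ["TARGET"]
        target = [r for r in results if r.predictor == "TARGET"][0]
        assert target.coefficient == pytest.approx(0.8, abs=0.15)
        assert 0 <= target.effect_size <= 1

    def test_gene_filters(self):
        samples = [f"s{i}" for i in range(10)]
        raw = pd.DataFrame({
            "rare": [1] + [0] * 9,          # detected in 1 < 8 patients
            "low": [3] * 10,                # RPM below 2
            "good": [100] * 10,
            "overlap": [100] * 10,          # positionally excluded
        }, index=samples).T
        rpm = raw.div(raw.sum(axis=0), axis=1) * 1e6 / 100
        rpm.loc["low"] = 1.0
        log2 = np.log2(raw + 1)
        keep = gene_filters(log2, raw, rpm, excluded_genes={"overlap"})
        assert keep == ["good"]


class TestBhProperties:
    def test_q_monotone_in_p_and_bounded(self):
        rng = np.random.default_rng(13)
        n = 40
        samples = [f"s{i}" for i in range(n)]
        kz = pd.DataFrame(rng.standard_normal((6, n)),
                          index=[f"K{i}" for i in range(6)], columns=samples)
        te = pd.DataFrame(rng.standard_normal((6, n)),
                          index=[f"T{i}" for i in range(6)], columns=samples)
        results, _ = pairwise_family_screen({"t": kz}, {"t": te})
        df = pd.DataFrame([(r.p_value, r.q_value) for r in results],
                          columns=["p", "q"]).sort_values("p")
        assert (df["q"].to_numpy() >= df["p"].to_numpy() - 1e-12).all()
        assert df["q"].is_monotonic_increasing
        assert df["q"].between(0, 1).all()
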