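"""EM assignment, unique-only mode, family aggregation, L1HS 5', bias test."""

import itertools

import numpy as np
import pandas as pd
import pytest

from tecoex.annotations import L1HS5pRegion, TELocus
from tecoex.quantify import (
    AlignmentSet, CandidateAlignment, aggregate_family, count_l1hs_5prime,
    em_assign, ingest_alignments, mappability_bias_test, unique_only_counts,
)


def make_sets(composition: dict[tuple[str, ...], int]) -> list[AlignmentSet]:
    """Alignment sets from {candidate-locus-tuple: n_fragments}."""
    out = []
    i = 0
    for loci, n in composition.items():
        for _ in range(n):
            i += 1
            cands = tuple(CandidateAlignment(l, "chr1", 100, 148) for l in loci)
            out.append(AlignmentSet(f"f{i}", cands, len(loci)))
    return out


def grid_search_ml_counts(composition: dict[tuple[str, ...], int],
                          locus_ids: list[str],
                          step: float = 2e-5) -> np.ndarray:
    """Independent oracle: maximize the multinomial-mixture likelihood of the
    candidate-set data over locus abundances pi by brute-force grid search,
    then report expected counts sum_r w_{r,l} at the ML pi."""
    n_loci = len(locus_ids)
    idx = {l: i for i, l in enumerate(locus_ids)}
    sets = [(np.array([idx[l] for l in loci]), n)
            for loci, n in composition.items() if n > 0]

    def loglik(pis: np.ndarray) -> np.ndarray:
        ll = np.zeros(pis.shape[0])
        for members, n in sets:
            ll += n * np.log(np.maximum(pis[:, members].sum(axis=1), 1e-300))
        return ll

    def argmax_max_entropy(pis: np.ndarray) -> np.ndarray:
        # the likelihood can be flat along directions the data do not
        # identify (e.g. fully shared fragments); among ML-tied grid points
        # take the maximum-entropy one, the EM attractor from uniform init
        ll = loglik(pis)
        ties = pis[ll >= ll.max() - 1e-9]
        with np.errstate(divide="ignore", invalid="ignore"):
            ent = -np.nansum(np.where(ties > 0, ties * np.log(ties), 0.0),
                             axis=1)
        return ties[np.argmax(ent)]

    if n_loci == 2:
        p = np.arange(0.0, 1.0 + step, step)
        pis = np.column_stack([p, 1.0 - p])
        best = argmax_max_entropy(pis)
    elif n_loci == 3:
        coarse = np.arange(0.0, 1.0 + 1e-3, 1e-3)
        a, b = np.meshgrid(coarse, coarse, indexing="ij")
        mask = a + b <= 1.0
        pis = np.column_stack([a[mask], b[mask], 1.0 - a[mask] - b[mask]])
        c0 = argmax_max_entropy(pis)
        fine = np.arange(-2e-3, 2e-3 + step, step)
        a, b = np.meshgrid(np.clip(c0[0] + fine, 0, 1),
                           np.clip(c0[1] + fine, 0, 1), indexing="ij")
        mask = a + b <= 1.0
        pis = np.column_stack([a[mask], b[mask], 1.0 - a[mask] - b[mask]])
        best = argmax_max_entropy(pis)
    else:
        raise NotImplementedError
    counts = np.zeros(n_loci)
    for members, n in sets:
        tot = best[members].sum()
        if tot <= 0:
            counts[members] += n / len(members)
        else:
            counts[members] += n * best[members] / tot
    return counts


class TestEM:
    def test_symmetric_shared_mass_splits_evenly(self):
        counts = em_assign(make_sets({("A",): 5, ("B",): 5, ("A", "B"): 10}))
        assert counts["A"] == pytest.approx(10, abs=1e-4)
        assert counts["B"] == pytest.approx(10, abs=1e-4)

    def test_one_sided_evidence_drains_shared_mass(self):
        # ML fixed point: all shared mass goes to the locus with unique
        # support (oracle value frozen from grid_search_ml_counts)
        comp = {("A",): 10, ("A", "B"): 10}
        counts = em_assign(make_sets(comp))
        oracle = grid_search_ml_counts(comp, ["A", "B"])
        assert np.allclose(oracle, [20.0, 0.0], atol=1e-3)
        assert counts["A"] == pytest.approx(20.0, abs=1e-3)
        assert counts["B"] == pytest.approx(0.0, abs=1e-3)

    def test_all_unique_equals_tallies(self):
        counts = em_assign(make_sets({("A",): 3, ("B",): 7, ("C",): 2}))
        assert counts.tolist() == [3.0, 7.0, 2.0]

    def test_mass_conservation_and_monotone_likelihood(self, multimap_setup,
                                                       base_annotation):
        cfg, ann, truth, frags, out = multimap_setup
        sample = truth.sample_ids[0]
        asets, st = ingest_alignments(out / f"{sample}.sam", ann.te_loci,
                                      ann.genes)
        res = em_assign(asets, return_stats=True)
        assert res.counts.sum() == pytest.approx(st.fragments_ingested,
                                                 abs=1e-6)
        diffs = np.diff(res.loglik_trace)
        assert (diffs >= -1e-9).all()

    @pytest.mark.parametrize("n_frag", [6, 12, 20])
    def test_matches_grid_search_two_loci_exhaustive(self, n_frag):
        """EM equals brute-force ML for every 2-locus composition."""
        for n_a in range(n_frag + 1):
            for n_b in range(n_frag + 1 - n_a):
                n_ab = n_frag - n_a - n_b
                comp = {("A",): n_a, ("B",): n_b, ("A", "B"): n_ab}
                if sum(comp.values()) == 0:
                    continue
                em = em_assign(make_sets(comp), locus_ids=["A", "B"])
                oracle = grid_search_ml_counts(comp, ["A", "B"])
                assert np.allclose(em.to_numpy(), oracle, atol=1e-3), comp

    def test_matches_grid_search_three_loci_sampled(self):
        rng = np.random.default_rng(0)
        subsets = [("A",), ("B",), ("C",), ("A", "B"), ("A", "C"),
                   ("B", "C"), ("A", "B", "C")]
        for _ in range(25):
            n = int(rng.integers(3, 21))
            alloc = rng.multinomial(n, np.ones(7) / 7)
            comp = {s: int(c) for s, c in zip(subsets, alloc) if c}
            em = em_assign(make_sets(comp), locus_ids=["A", "B", "C"])
            oracle = grid_search_ml_counts(comp, ["A", "B", "C"])
            assert np.allclose(em.to_numpy(), oracle, atol=1e-3), comp

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            em_assign([])


class TestUniqueOnly:
    def test_shared_fragments_discarded(self):
        sets = make_sets({("A",): 10, ("A", "B"): 10})
        uniq = unique_only_counts(sets, ["A", "B"])
        assert uniq.tolist() == [10.0, 0.0]

    def test_all_shared_gives_zeros(self):
        assert unique_only_counts(make_sets({("A", "B"): 5})).sum() == 0

    def test_unique_below_em_everywhere(self, multimap_setup):
        cfg, ann, truth, frags, out = multimap_setup
        sample = truth.sample_ids[0]
        asets, _ = ingest_alignments(out / f"{sample}.sam", ann.te_loci,
                                     ann.genes)
        locus_ids = [t.locus_id for t in ann.te_loci]
        em = em_assign(asets, locus_ids=locus_ids)
        uniq = unique_only_counts(asets, locus_ids)
        assert (uniq <= em + 1e-9).all()
        # divergence 0: interior fragments are fully shared, EM keeps them
        assert em.sum() > 3 * uniq.sum()


class TestIngest:
    def test_exon_filter_and_truth_agreement(self, base_config,
                                             base_annotation, base_truth,
                                             base_fragments):
        frags, out = base_fragments
        sample = base_truth.sample_ids[0]
        asets, st = ingest_alignments(out / f"{sample}.sam",
                                      base_annotation.te_loci,
                                      base_annotation.genes)
        # oracle: simulator-emitted fragments with >= 1 alignment overlapping
        # a TE locus
        loci = base_annotation.te_loci
        by_chrom = {}
        for t in loci:
            by_chrom.setdefault(t.chrom, []).append(t)
        rl = base_config.read_len
        expected = 0
        for f in frags[sample]:
            hit = any(
                a_pos < t.end and a_pos + rl > t.start
                for (a_chrom, a_pos, _) in f.alignments
                for t in by_chrom.get(a_chrom, ())
            )
            expected += hit
        assert st.fragments_ingested == expected
        assert len(asets) == expected

    def test_exonic_gene_alignment_removed_from_candidates(self, tmp_path):
        # one fragment aligning both inside a TE and inside a non-TE exon
        genome = {"chr1": "A" * 5000}
        sam = tmp_path / "toy.sam"
        with open(sam, "w") as fh:
            fh.write("@HD\tVN:1.6\tSO:unsorted\n@SQ\tSN:chr1\tLN:5000\n")
            fh.write("f1\t0\tchr1\t101\t255\t48M\t*\t0\t0\t" + "A" * 48 +
                     "\t*\tNH:i:2\n")
            fh.write("f1\t256\tchr1\t2001\t255\t48M\t*\t0\t0\t" + "A" * 48 +
                     "\t*\tNH:i:2\n")
        te = [TELocus("L1", "chr1", 50, 400, "+", "L1HS", "LINE")]
        from tecoex.annotations import GeneModel
        genes = [GeneModel("G", "chr1", "+", ((1900, 2300), (3000, 3200)))]
        asets, st = ingest_alignments(sam, te, genes)
        assert len(asets) == 1
        assert asets[0].candidate_loci == {"L1"}
        assert asets[0].multiplicity == 2

    def test_multimap_cap_drops_fragment(self, tmp_path):
        sam = tmp_path / "cap.sam"
        with open(sam, "w") as fh:
            fh.write("@HD\tVN:1.6\tSO:unsorted\n@SQ\tSN:chr1\tLN:5000\n")
            fh.write("f1\t0\tchr1\t101\t255\t48M\t*\t0\t0\t*\t*\tNH:i:500\n")
        te = [TELocus("L1", "chr1", 50, 400, "+", "L1HS", "LINE")]
        asets, st = ingest_alignments(sam, te, [])
        assert asets == []
        assert st.dropped_multimap == 1


class TestFamilyAggregation:
    def _loci(self, contexts):
        return [
            TELocus(f"F_dup{i+1}", "chr1", 1000 * i + 100, 1000 * i + 400,
                    "+", "F", "SINE", context=c)
            for i, c in enumerate(contexts)
        ]

    def test_sum_excluding_exonic(self):
        loci = self._loci(["intronic", "intergenic", "intergenic"])
        counts = pd.Series([5.0, 0.0, 2.0],
                           index=[t.locus_id for t in loci])
        assert aggregate_family(counts, loci)["F"] == 7.0
        loci[0] = TELocus("F_dup1", "chr1", 100, 400, "+", "F", "SINE",
                          context="exonic")
        assert aggregate_family(counts, loci)["F"] == 2.0

    def test_total_conservation(self, base_annotation):
        rng = np.random.default_rng(1)
        loci = base_annotation.te_loci
        counts = pd.DataFrame(
            rng.poisson(20.0, size=(len(loci), 3)).astype(float),
            index=[t.locus_id for t in loci], columns=["s1", "s2", "s3"])
        fam = aggregate_family(counts, loci)
        nonexonic = [t.locus_id for t in loci if t.context != "exonic"]
        assert np.allclose(fam.sum(axis=0), counts.loc[nonexonic].sum(axis=0))


class TestL1hsCounting:
    def _sets(self):
        # two loci; region covers [0,300) of L2 only; fragments:
        # 10 unique to L2-inside-region, 5 shared with alignment in region on
        # L2 but outside on L1
        loci = [
            TELocus("L1", "chr1", 1000, 7000, "+", "L1HS", "LINE"),
            TELocus("L2", "chr1", 20_000, 26_000, "+", "L1HS", "LINE"),
        ]
        regions = [L1HS5pRegion("L2", 0, 300, 0)]
        sets = []
        for i in range(10):
            sets.append(AlignmentSet(
                f"u{i}", (CandidateAlignment("L2", "chr1", 20_050, 20_098),), 1))
        for i in range(5):
            sets.append(AlignmentSet(f"s{i}", (
                CandidateAlignment("L1", "chr1", 5000, 5048),
                CandidateAlignment("L2", "chr1", 20_100, 20_148)), 2))
        return loci, regions, sets

    def test_weighted_region_mass(self):
        loci, regions, sets = self._sets()
        em = em_assign(sets, locus_ids=["L1", "L2"])
        # oracle: recompute weight mass over region-overlapping alignments
        pi = em / em.sum()
        expected = 10.0 + 5.0 * pi["L2"] / (pi["L1"] + pi["L2"])
        got = count_l1hs_5prime(sets, regions, loci, em)
        assert got == pytest.approx(expected, abs=1e-9)

    def test_no_overlap_counts_zero(self):
        loci, regions, sets = self._sets()
        shifted = [L1HS5pRegion("L2", 5000, 5300, 0)]
        em = em_assign(sets, locus_ids=["L1", "L2"])
        assert count_l1hs_5prime(sets, shifted, loci, em) == 0.0

    def test_empty_region_warns(self):
        loci, regions, sets = self._sets()
        em = em_assign(sets, locus_ids=["L1", "L2"])
        with pytest.warns(UserWarning):
            assert count_l1hs_5prime(sets, [], loci, em) == 0.0


class TestMappabilityBias:
    def test_constructed_proportional_counts(self):
        rng = np.random.default_rng(3)
        ml = pd.Series(rng.integers(10, 300, size=60).astype(float),
                       index=[f"L{i}" for i in range(60)])
        counts = pd.Series(ml * 2 + rng.normal(0, 5, size=60), index=ml.index)
        counts = counts.clip(lower=0)
        res = mappability_bias_test(counts, ml)
        assert res.correlation > 0.9
        assert res.p_value < 1e-4

    def test_constant_counts_degenerate(self):
        ml = pd.Series(np.arange(10, 30, dtype=float),
                       index=[f"L{i}" for i in range(20)])
        counts = pd.Series(7.0, index=ml.index)
        res = mappability_bias_test(counts, ml)
        assert res.degenerate
        assert res.p_value is None

    def test_requires_ten_loci(self):
        ml = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(ValueError):
            mappability_bias_test(pd.Series([1.0, 2.0], index=["a", "b"]), ml)
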