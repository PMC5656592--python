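import itertools
from math import comb

import numpy as np
import pytest

from refreo import (
    detect_reversals,
    filter_by_controls,
    per_sample_reversal_count,
)
from refreo.reversal import FilteredPairSet, reversal_pvalues
from refreo.pairs import ReferencePairSet

from conftest import make_matrix


def refset(pair_orients, genes):
    pos = {g: i for i, g in enumerate(genes)}
    ia = np.asarray([pos[a] for a, _ in pair_orients])
    ib = np.asarray([pos[b] for _, b in pair_orients])
    return ReferencePairSet(np.asarray(genes, object), ia, ib,
                            np.asarray(list(pair_orients.values()), np.int8))


def filtered_from(refs, frac=0.95):
    return FilteredPairSet(
        genes=refs.genes, ia=refs.ia, ib=refs.ib, orientation=refs.orientation,
        control_concordance=np.ones(len(refs)), control_frac=frac,
    )


def fisher_enumeration(cc, cr, ac, ar, sided="one"):
    """Exhaustive oracle: enumerate all 2x2 tables with the observed margins."""
    r1, r2 = cc + cr, ac + ar
    c_rev = cr + ar
    total = r1 + r2
    denom = comb(total, r2)
    probs = {}
    for x in range(max(0, c_rev - r1), min(r2, c_rev) + 1):
        probs[x] = comb(c_rev, x) * comb(total - c_rev, r2 - x) / denom
    obs = probs[ar]
    if sided == "one":
        return sum(p for x, p in probs.items() if x >= ar)
    return sum(p for p in probs.values() if p <= obs * (1 + 1e-12))


class TestFilterByControls:
    def _pair_matrix(self, conc_per_pair, n_controls=20):
        """One pair per gene duo; pair p concordant in conc_per_pair[p] controls."""
        n_pairs = len(conc_per_pair)
        genes = [f"g{i}" for i in range(2 * n_pairs)]
        values = np.zeros((2 * n_pairs, n_controls))
        for p, n_conc in enumerate(conc_per_pair):
            hi, lo = 2 * p, 2 * p + 1
            values[hi, :n_conc] = 2.0   # concordant: hi > lo
            values[lo, :n_conc] = 1.0
            values[hi, n_conc:] = 1.0   # reversed elsewhere
            values[lo, n_conc:] = 2.0
        m = make_matrix(values, gene_ids=genes,
                        group=["control"] * n_controls)
        refs = refset({(f"g{2*p}", f"g{2*p+1}"): 1 for p in range(n_pairs)}, genes)
        return refs, m

    def test_fully_concordant_retained(self):
        refs, m = self._pair_matrix([20])
        assert len(filter_by_controls(refs, m, 0.95)) == 1

    def test_inclusive_95_percent_boundary(self):
        # 19/20 concordant meets "at least 95%"; 18/20 does not
        refs, m = self._pair_matrix([19, 18])
        kept = filter_by_controls(refs, m, 0.95)
        assert set(zip(kept.gene_a, kept.gene_b)) == {("g0", "g1")}

    def test_matches_direct_counting(self, rng):
        genes = ["a", "b", "c", "d", "e", "f"]
        values = rng.normal(size=(6, 10))
        m = make_matrix(values, gene_ids=genes, group=["control"] * 10)
        refs = refset({("a", "b"): 1, ("c", "d"): -1, ("e", "f"): 1}, genes)
        kept = filter_by_controls(refs, m, 0.6)
        expected = set()
        for a, b, o in [("a", "b", 1), ("c", "d", -1), ("e", "f", 1)]:
            ia, ib = genes.index(a), genes.index(b)
            conc = sum(np.sign(values[ia, j] - values[ib, j]) == o for j in range(10))
            if conc / 10 >= 0.6:
                expected.add((a, b))
        assert set(zip(kept.gene_a, kept.gene_b)) == expected

    def test_bad_fraction(self):
        refs, m = self._pair_matrix([20])
        with pytest.raises(ValueError):
            filter_by_controls(refs, m, 0.0)
        with pytest.raises(ValueError):
            filter_by_controls(refs, m, 1.5)


class TestDetectReversals:
    def _study(self, ctrl_cols, case_cols):
        """Two genes; columns give (hi_val, lo_val) per sample."""
        cols = ctrl_cols + case_cols
        values = np.array(cols, dtype=float).T
        group = ["control"] * len(ctrl_cols) + ["case"] * len(case_cols)
        return make_matrix(values, gene_ids=["A", "B"], group=group)

    def test_single_pair_exact_p(self):
        # 19 concordant / 1 reversed controls vs 8 / 12 cases
        ctrl = [(2, 1)] * 19 + [(1, 2)]
        case = [(2, 1)] * 8 + [(1, 2)] * 12
        m = self._study(ctrl, case)
        filt = filtered_from(refset({("A", "B"): 1}, ["A", "B"]))
        out = detect_reversals(filt, m.controls(), m.cases())
        assert out.loc[0, "p"] == pytest.approx(29749005 / 137846528820, rel=1e-12)
        assert bool(out.loc[0, "reversed_in_cases"])

    def test_identical_rates_not_flagged(self):
        ctrl = [(2, 1)] * 8 + [(1, 2)] * 2
        case = [(2, 1)] * 8 + [(1, 2)] * 2
        m = self._study(ctrl, case)
        filt = filtered_from(refset({("A", "B"): 1}, ["A", "B"]))
        out2 = detect_reversals(filt, m.controls(), m.cases(), sided="two")
        assert out2.loc[0, "p"] == pytest.approx(1.0)
        out1 = detect_reversals(filt, m.controls(), m.cases(), sided="one")
        assert not bool(out1.loc[0, "reversed_in_cases"])

    def test_zero_case_reversals_never_flagged(self):
        ctrl = [(2, 1)] * 5 + [(1, 2)] * 5
        case = [(2, 1)] * 10
        m = self._study(ctrl, case)
        filt = filtered_from(refset({("A", "B"): 1}, ["A", "B"]))
        out = detect_reversals(filt, m.controls(), m.cases(), alpha=1.0)
        assert not bool(out.loc[0, "reversed_in_cases"])

    def test_ties_excluded_from_table(self):
        ctrl = [(2, 1)] * 4 + [(1, 1)]
        case = [(1, 2)] * 4 + [(2, 2)]
        m = self._study(ctrl, case)
        filt = filtered_from(refset({("A", "B"): 1}, ["A", "B"]))
        out = detect_reversals(filt, m.controls(), m.cases())
        assert int(out.loc[0, "control_concordant"]) == 4
        assert int(out.loc[0, "control_reversed"]) == 0
        assert int(out.loc[0, "case_reversed"]) == 4
        assert int(out.loc[0, "case_concordant"]) == 0

    def test_missing_gene_errors(self):
        m = make_matrix([[1, 2]], gene_ids=["A"], group=["control", "case"])
        filt = filtered_from(refset({("A", "B"): 1}, ["A", "B"]))
        with pytest.raises(KeyError):
            detect_reversals(filt, m.controls(), m.cases())


class TestFisherKernel:
    @pytest.mark.parametrize("sided", ["one", "two"])
    def test_matches_enumeration_all_small_tables(self, sided):
        """Exhaustive margins-conditional enumeration, totals <= 16."""
        cells = range(0, 5)
        for cc, cr, ac, ar in itertools.product(cells, repeat=4):
            if cc + cr == 0 or ac + ar == 0:
                continue
            got = reversal_pvalues(
                np.array([cc]), np.array([cr]), np.array([ac]), np.array([ar]),
                sided=sided,
            )[0]
            want = fisher_enumeration(cc, cr, ac, ar, sided=sided)
            assert got == pytest.approx(want, rel=1e-9), (cc, cr, ac, ar)

    def test_dedup_consistent_with_scipy(self, rng):
        from scipy.stats import fisher_exact

        cc = rng.integers(0, 30, 50)
        cr = rng.integers(0, 10, 50)
        ac = rng.integers(0, 30, 50)
        ar = rng.integers(1, 15, 50)
        p = reversal_pvalues(cc, cr, ac, ar, sided="one")
        for i in range(0, 50, 7):
            want = fisher_exact([[cc[i], cr[i]], [ac[i], ar[i]]],
                                alternative="greater")[1]
            assert p[i] == pytest.approx(want, rel=1e-10)


class TestPerSampleReversalCount:
    def test_reference_matching_sample_counts_zero(self):
        genes = ["a", "b", "c", "d"]
        values = np.array([[4.0], [3.0], [2.0], [1.0]])
        m = make_matrix(values, gene_ids=genes)
        filt = filtered_from(refset({("a", "b"): 1, ("c", "d"): 1}, genes))
        assert per_sample_reversal_count(filt, m).tolist() == [0]

    def test_single_swap_counts_one(self):
        genes = ["a", "b", "c", "d"]
        values = np.array([[4.0, 3.0], [3.0, 4.0], [2.0, 2.5], [1.0, 1.0]])
        m = make_matrix(values, gene_ids=genes)
        filt = filtered_from(refset({("a", "b"): 1, ("c", "d"): 1}, genes))
        assert per_sample_reversal_count(filt, m).tolist() == [0, 1]

    def test_matches_bruteforce_tally(self, rng):
        genes = [f"g{i}" for i in range(8)]
        values = rng.normal(size=(8, 5))
        m = make_matrix(values, gene_ids=genes)
        pairs = {("g0", "g1"): 1, ("g2", "g3"): -1, ("g4", "g5"): 1,
                 ("g6", "g7"): -1}
        filt = filtered_from(refset(pairs, genes))
        got = per_sample_reversal_count(filt, m).tolist()
        for j in range(5):
            tally = 0
            for (a, b), o in pairs.items():
                d = values[genes.index(a), j] - values[genes.index(b), j]
                if np.sign(d) == -o:
                    tally += 1
            assert got[j] == tally


def test_monotone_invariance_of_reversal_stage(rng):
    """Strictly increasing per-sample transforms change nothing."""
    genes = [f"g{i}" for i in range(10)]
    values = rng.normal(size=(10, 16))
    group = ["control"] * 8 + ["case"] * 8
    m = make_matrix(values, gene_ids=genes, group=group)
    pairs = {(f"g{2*i}", f"g{2*i+1}"): int(rng.choice([-1, 1])) for i in range(5)}
    refs = refset(pairs, genes)
    base_filt = filter_by_controls(refs, m.controls(), 0.5)
    base_out = detect_reversals(base_filt, m.controls(), m.cases())
    base_counts = per_sample_reversal_count(base_filt, m).tolist()
    for _ in range(5):
        t = values.copy()
        for j in range(16):
            t[:, j] = np.arctan(t[:, j] * rng.uniform(0.5, 2)) * rng.uniform(1, 9)
        mt = make_matrix(t, gene_ids=genes, group=group)
        filt = filter_by_controls(refs, mt.controls(), 0.5)
        assert filt.pair_dict() == base_filt.pair_dict()
        out = detect_reversals(filt, mt.controls(), mt.cases())
        assert np.allclose(out["p"], base_out["p"])
        assert per_sample_reversal_count(filt, mt).tolist() == base_counts
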