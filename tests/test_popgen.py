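"""Near-fixed markers, NG86 Ka/Ks, Tajima's D, Weir-Cockerham Fst, t-test."""
import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from ricesweep.io import MISSING
from ricesweep.popgen import (fst_wc, jukes_cantor, kaks_ng86,
                              near_fixed_markers,
                              positive_selection_enrichment, tajima_constants,
                              tajimas_d, two_sample_t, yates_chi2)

from conftest import make_gm, make_sample_table


class TestNearFixed:
    def _gm(self, jap_alt, ind_alt, n=100):
        codes = np.zeros((1, 2 * n), dtype=np.int8)
        codes[0, :jap_alt] = 1          # japonica first n columns
        codes[0, n:n + ind_alt] = 2     # indica second n columns
        st = make_sample_table(n_jap=n, n_ind=n)
        return make_gm(codes, samples=st), st

    def test_eighty_percent_both_sides_is_marker(self):
        gm, st = self._gm(jap_alt=85, ind_alt=92)
        # jap major allele = 1 at 85%? no: 85 alt-1 vs 15 ref -> major=1
        m = near_fixed_markers(gm, st)
        assert len(m) == 1 and m[0].passes
        assert m[0].allele_a != m[0].allele_b

    def test_below_threshold_fails(self):
        gm, st = self._gm(jap_alt=79, ind_alt=95)
        # jap: 79% allele 1 -> fails >= 80% rule
        assert near_fixed_markers(gm, st) == []

    def test_exactly_eighty_percent_passes(self):
        gm, st = self._gm(jap_alt=80, ind_alt=80)
        assert len(near_fixed_markers(gm, st)) == 1

    def test_shared_major_allele_is_not_marker(self):
        codes = np.zeros((1, 20), dtype=np.int8)   # everyone REF
        st = make_sample_table(n_jap=10, n_ind=10)
        gm = make_gm(codes, samples=st)
        assert near_fixed_markers(gm, st) == []

    def test_frequencies_over_nonmissing(self):
        codes = np.zeros((1, 20), dtype=np.int8)
        codes[0, :10] = [1, 1, 1, 1, MISSING, MISSING, 0, 1, 1, 1]  # 8/8? no
        codes[0, 10:] = 0
        st = make_sample_table(n_jap=10, n_ind=10)
        gm = make_gm(codes, samples=st)
        m = near_fixed_markers(gm, st)
        # jap: 7 alt of 8 non-missing = 87.5% -> marker vs indica all REF
        assert len(m) == 1 and m[0].freq_a == pytest.approx(7 / 8)


# --- independent NG86 oracle -------------------------------------------------

_BASES = "TCAG"
_AA = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
_CODE = {b1 + b2 + b3: _AA[i] for i, (b1, b2, b3) in
         enumerate(itertools.product(_BASES, repeat=3))}


def oracle_ng86(sa: str, sb: str):
    """Direct enumeration of NG86 site and difference counts."""
    def syn_sites(codon):
        total = 0.0
        for p in range(3):
            syn = sum(1 for b in _BASES if b != codon[p]
                      and _CODE[codon[:p] + b + codon[p + 1:]] == _CODE[codon])
            total += syn / 3.0
        return total

    S = sum(syn_sites(sa[i:i + 3]) + syn_sites(sb[i:i + 3])
            for i in range(0, len(sa), 3)) / 2.0
    N = len(sa) - S
    nd = sd = 0.0
    for i in range(0, len(sa), 3):
        ca, cb = sa[i:i + 3], sb[i:i + 3]
        pos = [p for p in range(3) if ca[p] != cb[p]]
        if not pos:
            continue
        path_counts = []
        for order in itertools.permutations(pos):
            cur, n_, s_ = ca, 0, 0
            stop = False
            for p in order:
                nxt = cur[:p] + cb[p] + cur[p + 1:]
                if _CODE[nxt] == "*" and nxt != cb:
                    stop = True
                if _CODE[nxt] == _CODE[cur]:
                    s_ += 1
                else:
                    n_ += 1
                cur = nxt
            path_counts.append((stop, n_, s_))
        ok = [(n_, s_) for stop, n_, s_ in path_counts if not stop]
        if not ok:
            ok = [(n_, s_) for _, n_, s_ in path_counts]
        nd += sum(n_ for n_, _ in ok) / len(ok)
        sd += sum(s_ for _, s_ in ok) / len(ok)
    return N, S, nd, sd


def random_cds(rng, n_codons):
    codons = []
    while len(codons) < n_codons:
        c = "".join(_BASES[i] for i in rng.integers(0, 4, 3))
        if _CODE[c] != "*":
            codons.append(c)
    return "".join(codons)


class TestKaKs:
    def test_identical_sequences(self):
        r = kaks_ng86("ATGGCT", "ATGGCT")
        assert r.ka == 0 and r.ks == 0 and not r.positive

    def test_single_codon_worked_example(self):
        # TTT (Phe) vs TTA (Leu): S sites 0.5, Nd=1, Sd=0, Ks=0,
        # Ka = JC(1/2.5) ~ 0.572, positive via the Ks=0 branch
        r = kaks_ng86("TTT", "TTA")
        assert r.s_sites == pytest.approx(0.5)
        assert r.n_sites == pytest.approx(2.5)
        assert (r.nd, r.sd) == (1.0, 0.0)
        assert r.ks == 0.0
        assert r.ka == pytest.approx(-0.75 * math.log(1 - (4 / 3) * (1 / 2.5)))
        assert r.ka == pytest.approx(0.5717, abs=1e-4)
        assert r.positive

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            a = random_cds(rng, 12)
            b = random_cds(rng, 12)
            r1, r2 = kaks_ng86(a, b), kaks_ng86(b, a)
            for f in ("n_sites", "s_sites", "nd", "sd"):
                assert getattr(r1, f) == pytest.approx(getattr(r2, f))

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_enumeration_oracle_random_pairs(self, seed):
        rng = np.random.default_rng(seed)
        a = random_cds(rng, 30)
        b = list(a)
        # mutate ~8% of bases so p stays below saturation
        for i in rng.choice(len(a), size=7, replace=False):
            b[i] = _BASES[(int(_BASES.index(a[i])) +
                           int(rng.integers(1, 4))) % 4]
        b = "".join(b)
        r = kaks_ng86(a, b)
        N, S, nd, sd = oracle_ng86(a, b)
        assert r.n_sites == pytest.approx(N, abs=1e-9)
        assert r.s_sites == pytest.approx(S, abs=1e-9)
        assert r.nd == pytest.approx(nd, abs=1e-9)
        assert r.sd == pytest.approx(sd, abs=1e-9)

    def test_site_counts_sum_to_sequence_length(self):
        rng = np.random.default_rng(5)
        a, b = random_cds(rng, 20), random_cds(rng, 20)
        r = kaks_ng86(a, b)
        assert r.n_sites + r.s_sites == pytest.approx(60.0)

    def test_jc_correction_monotone_to_zero(self):
        ps = np.linspace(0, 0.7, 30)
        ds = [jukes_cantor(p) for p in ps]
        assert all(x < y for x, y in zip(ds, ds[1:]))
        assert jukes_cantor(1e-9) == pytest.approx(1e-9, rel=1e-3)
        assert math.isnan(jukes_cantor(0.75))

    def test_length_validation(self):
        with pytest.raises(ValueError):
            kaks_ng86("ATG", "ATGA")
        with pytest.raises(ValueError):
            kaks_ng86("ATGA", "ATGA")


class TestEnrichment:
    def test_no_association_gives_zero(self):
        chi2, p = yates_chi2(10, 10, 10, 10)
        assert chi2 == 0.0 and p == 1.0

    def test_published_counts_match_scipy_oracle(self):
        # 43/163 positively selected in-region vs 2,678/27,384 genome-wide
        chi2, p = yates_chi2(43, 120, 2678, 24706)
        obs = np.array([[43, 120], [2678, 24706]])
        c2, p2, dof, _ = sps.chi2_contingency(obs, correction=True)
        assert chi2 == pytest.approx(c2, rel=1e-12)
        assert dof == 1
        assert p < 1e-4

    def test_transpose_invariance(self):
        assert yates_chi2(5, 9, 14, 70) == pytest.approx(
            yates_chi2(5, 14, 9, 70))

    def test_monotone_in_total_at_fixed_proportions(self):
        c1, _ = yates_chi2(20, 10, 10, 20)
        c2, _ = yates_chi2(40, 20, 20, 40)
        assert c2 > c1

    def test_region_vs_genome_wrapper(self):
        chi2, p = positive_selection_enrichment(43, 163, 2678, 27384)
        assert chi2 == pytest.approx(yates_chi2(43, 120, 2635, 24586)[0])

    def test_zero_margin_is_error(self):
        with pytest.raises(ValueError):
            yates_chi2(0, 0, 5, 5)


class TestTajima:
    def test_constants_for_small_n_match_direct_formulas(self):
        for n in range(2, 21):
            c = tajima_constants(n)
            a1 = sum(1 / i for i in range(1, n))
            a2 = sum(1 / i ** 2 for i in range(1, n))
            b1 = (n + 1) / (3 * (n - 1))
            b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
            assert c.a1 == pytest.approx(a1)
            assert c.a2 == pytest.approx(a2)
            assert c.c1 == pytest.approx(b1 - 1 / a1)
            assert c.e2 == pytest.approx(
                (b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2) / (a1 ** 2 + a2))

    def test_two_singletons_in_four_samples(self):
        # n=4, two singleton mutations in different samples -> D ~ -0.710
        codes = np.array([[1, 0, 0, 0], [0, 1, 0, 0]], dtype=np.int8)
        gm = make_gm(codes)
        r = tajimas_d(gm, gm.samples, "japonica")
        assert r.s == 2 and r.n == 4
        assert r.pi_total == pytest.approx(1.0)
        assert r.d == pytest.approx(-0.710, abs=5e-3)

    def test_zero_numerator_gives_zero_d(self):
        # n=4 (a1 = 11/6): 8 singleton + 3 doubleton sites give
        # pi_total = 0.5*8 + (2/3)*3 = 6 = S/a1 exactly -> D = 0
        rows = [[1, 0, 0, 0]] * 8 + [[1, 1, 0, 0]] * 3
        gm = make_gm(np.array(rows, dtype=np.int8))
        r = tajimas_d(gm, gm.samples, "japonica")
        assert r.s == 11
        assert r.pi_total == pytest.approx(r.s / r.constants.a1)
        assert r.d == pytest.approx(0.0, abs=1e-12)

    def test_no_segregating_sites_undefined(self):
        gm = make_gm(np.zeros((3, 5), dtype=np.int8))
        r = tajimas_d(gm, gm.samples, "japonica")
        assert r.s == 0 and math.isnan(r.d)

    def test_neutral_coalescent_mean_near_zero(self):
        """msprime constant-size neutral sims as the independent oracle."""
        import msprime

        ds = []
        for rep, ts in enumerate(msprime.sim_ancestry(
                samples=10, ploidy=1, population_size=1e4,
                sequence_length=5e4, num_replicates=40,
                random_seed=97)):
            mts = msprime.sim_mutations(ts, rate=2e-8, random_seed=rep + 1)
            if mts.num_sites < 2:
                continue
            codes = mts.genotype_matrix().astype(np.int8)
            pos = np.array([int(s.position) + 1 for s in mts.sites()])
            keep = np.diff(pos, prepend=0) > 0
            gm = make_gm(codes[keep], pos=pos[keep],
                         samples=make_sample_table(n_jap=codes.shape[1]))
            r = tajimas_d(gm, gm.samples, "japonica")
            if not math.isnan(r.d):
                ds.append(r.d)
        assert len(ds) >= 30
        se = np.std(ds, ddof=1) / math.sqrt(len(ds))
        assert abs(np.mean(ds)) < 3.5 * se + 0.15


class TestFst:
    def test_fully_diverged_groups_theta_one(self):
        st = make_sample_table(n_jap=5, n_ind=5)
        codes = np.zeros((20, 10), dtype=np.int8)
        codes[:, 5:] = 1
        gm = make_gm(codes, samples=st)
        r = fst_wc(gm, st, "japonica", "indica", n_perm=99, seed=0)
        assert r.estimate == pytest.approx(1.0)
        # only a permutation recreating the exact split ties theta = 1
        assert r.p_value <= 0.05

    def test_single_site_matches_hand_formula(self):
        # group A: alleles (0,0,0,1), group B: (1,1,0,1)
        st = make_sample_table(n_jap=4, n_ind=4)
        codes = np.array([[0, 0, 0, 1, 1, 1, 0, 1]], dtype=np.int8)
        gm = make_gm(codes, samples=st)
        r = fst_wc(gm, st, "japonica", "indica", n_perm=0)
        # hand ANOVA (haploid): p1=0.25, p2=0.75, n1=n2=4
        p1, p2, n1, n2 = 0.25, 0.75, 4, 4
        ntot, nbar, r_ = n1 + n2, 4.0, 2
        nc = (ntot - (n1 ** 2 + n2 ** 2) / ntot) / (r_ - 1)
        expected = 0.0
        num = den = 0.0
        for p1a, p2a in [(p1, p2), (1 - p1, 1 - p2)]:
            pbar = (n1 * p1a + n2 * p2a) / ntot
            msp = (n1 * (p1a - pbar) ** 2 + n2 * (p2a - pbar) ** 2) / (r_ - 1)
            msg = (n1 * p1a * (1 - p1a) + n2 * p2a * (1 - p2a)) / (ntot - r_)
            num += msp - msg
            den += msp + (nc - 1) * msg
        assert r.estimate == pytest.approx(num / den)

    def test_monomorphic_region_undefined(self):
        st = make_sample_table(n_jap=3, n_ind=3)
        gm = make_gm(np.zeros((4, 6), dtype=np.int8), samples=st)
        r = fst_wc(gm, st, "japonica", "indica", n_perm=10, seed=0)
        assert math.isnan(r.estimate)

    def test_permutation_type_one_error_near_alpha(self):
        """Panmictic population split at random: p-values super-uniform."""
        rng = np.random.default_rng(42)
        st = make_sample_table(n_jap=10, n_ind=10)
        rejections = 0
        n_reps = 120
        for rep in range(n_reps):
            q = rng.uniform(0.2, 0.8, 60)
            codes = (rng.random((60, 20)) < q[:, None]).astype(np.int8)
            gm = make_gm(codes, samples=st)
            r = fst_wc(gm, st, "japonica", "indica", n_perm=59,
                       seed=int(rng.integers(2 ** 31)))
            if r.p_value is not None and r.p_value <= 0.05:
                rejections += 1
        rate = rejections / n_reps
        # binomial(120, 0.05): 3 sd ~ 0.06
        assert rate <= 0.11

    def test_determinism_same_seed(self, gm_small):
        _, res, st, _, gmf = gm_small
        reg = ("chr01", 100_001, 130_000)
        r1 = fst_wc(gmf, st, "japonica", "indica", reg, n_perm=50, seed=5)
        r2 = fst_wc(gmf, st, "japonica", "indica", reg, n_perm=50, seed=5)
        assert r1.estimate == r2.estimate and r1.p_value == r2.p_value


class TestTwoSampleT:
    def test_identical_lists(self):
        t, df, p = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_zero_variance_equal_means(self):
        t, df, p = two_sample_t([2.0, 2.0], [2.0, 2.0])
        assert (t, p) == (0.0, 1.0)

    def test_textbook_example_matches_hand_formula(self):
        a = np.array([5.1, 4.9, 6.0, 5.5, 5.3])
        b = np.array([4.2, 4.4, 4.9, 4.1])
        t, df, p = two_sample_t(a, b)
        sp2 = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) \
            / (len(a) + len(b) - 2)
        t_hand = (a.mean() - b.mean()) / math.sqrt(
            sp2 * (1 / len(a) + 1 / len(b)))
        p_hand = 2 * sps.t.sf(abs(t_hand), len(a) + len(b) - 2)
        assert t == pytest.approx(t_hand, abs=1e-9)
        assert p == pytest.approx(p_hand, abs=1e-9)
        assert df == len(a) + len(b) - 2

    def test_welch_flag(self):
        a, b = [1.0, 2, 3, 4], [10.0, 30, 50]
        t_w, df_w, _ = two_sample_t(a, b, welch=True)
        t_p, df_p, _ = two_sample_t(a, b)
        assert df_w != df_p

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            two_sample_t([1.0], [1.0, 2.0])
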