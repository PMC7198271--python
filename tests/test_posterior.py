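"""SNP- and window-level posterior inference from stored draws."""

import numpy as np
import pytest

import lbr

from conftest import make_panel


def _samples(b0, bm, bf, bp=None, chrom=None):
    b0, bm, bf = (np.asarray(a, dtype=float) for a in (b0, bm, bf))
    S, p = b0.shape
    return lbr.PosteriorSamples(
        mu_m=np.zeros(S), mu_f=np.zeros(S), b0=b0, bm=bm, bf=bf,
        sigma2_e=np.ones((S, 2)), sigma2_b=np.ones((S, 3)), pi=np.full((S, 3), 0.1),
        snp_ids=np.array([f"s{j}" for j in range(p)], dtype=object),
        chrom=np.array(chrom if chrom is not None else ["chr1"] * p, dtype=object),
        bp=np.array(bp if bp is not None else np.arange(1, p + 1) * 1000),
    )


class TestSexSpecificEffects:
    def test_elementwise_composition(self):
        s = _samples([[0.2, 0.0, 0.0]], [[0.0, 0.1, 0.0]], [[-0.05, 0.0, 0.0]])
        beta_m, beta_f = lbr.sex_specific_effects(s)
        np.testing.assert_allclose(beta_m[0], [0.2, 0.1, 0.0])
        np.testing.assert_allclose(beta_f[0], [0.15, 0.0, 0.0])

    def test_all_zero_draw(self):
        s = _samples(np.zeros((2, 3)), np.zeros((2, 3)), np.zeros((2, 3)))
        bm, bf = lbr.sex_specific_effects(s)
        assert (bm == 0).all() and (bf == 0).all()


class TestSnpProbabilities:
    def test_counting_interaction_draws(self):
        """PPDiff is the exact fraction of draws with differing interaction
        indicators: 4 of 10 here."""
        S, p = 10, 1
        bm = np.zeros((S, p)); bm[:4, 0] = 0.3
        s = _samples(np.zeros((S, p)), bm, np.zeros((S, p)))
        t = lbr.snp_probabilities(s).table
        assert t.loc[0, "PPDiff"] == pytest.approx(0.4)
        assert t.loc[0, "PPM"] == pytest.approx(0.4)
        assert t.loc[0, "PPF"] == 0.0

    def test_shared_only_gives_zero_ppdiff(self):
        """Nonzero shared effects with both interactions spiked out: PPM and
        PPF track the shared inclusion, PPDiff is exactly 0."""
        S = 10
        b0 = np.zeros((S, 1)); b0[:7, 0] = 0.5
        t = lbr.snp_probabilities(_samples(b0, np.zeros((S, 1)), np.zeros((S, 1)))).table
        assert t.loc[0, "PPDiff"] == 0.0
        assert t.loc[0, "PPM"] == pytest.approx(0.7)
        assert t.loc[0, "PPF"] == pytest.approx(0.7)
        assert t.loc[0, "PP_any"] == pytest.approx(0.7)

    def test_ppdiff_bounded_by_nonspike_fraction(self, small_fit):
        """PPDiff never exceeds 1 - fraction of draws with both interaction
        effects simultaneously zero (they are equal events up to measure
        zero)."""
        _, _, _, s = small_fit
        t = lbr.snp_probabilities(s).table
        both_zero = ((s.bm == 0) & (s.bf == 0)).mean(axis=0)
        assert (t["PPDiff"].to_numpy() <= 1 - both_zero + 1e-12).all()

    def test_half_chain_agreement(self, small_fit):
        """Probabilities from disjoint chain halves agree within 3x the
        binomial standard error."""
        _, _, _, s = small_fit
        S = s.n_draws
        import copy
        halves = []
        for sl in (slice(0, S // 2), slice(S // 2, S)):
            h = copy.copy(s)
            h.b0, h.bm, h.bf = s.b0[sl], s.bm[sl], s.bf[sl]
            halves.append(lbr.snp_probabilities(h).table)
        p1 = halves[0]["PPDiff"].to_numpy()
        p2 = halves[1]["PPDiff"].to_numpy()
        pbar = (p1 + p2) / 2
        se = np.sqrt(pbar * (1 - pbar) * 2 / (S // 2)) + 1e-9
        # autocorrelated draws: allow 3x iid SE plus a floor
        assert (np.abs(p1 - p2) <= 3 * se + 0.12).all()


class TestDefineWindow:
    def _ld_panel(self):
        """5 SNPs in perfect LD followed by independent SNPs."""
        rng = np.random.default_rng(0)
        n = 200
        base = rng.binomial(2, 0.4, n).astype(float)
        indep = rng.binomial(2, 0.4, (n, 3)).astype(float)
        X = np.column_stack([base, base, base, base, base, indep])
        sex = np.array(["male"] * 100 + ["female"] * 100, dtype=object)
        return make_panel(X, sex)

    def test_perfect_ld_spans_block(self):
        panel = self._ld_panel()
        lo, hi = lbr.define_window(panel, 2, r2_threshold=0.05)
        assert lo == 0 and hi == 5

    def test_uncorrelated_neighbors_give_singleton(self):
        panel = self._ld_panel()
        lo, hi = lbr.define_window(panel, 6, r2_threshold=0.05)
        assert (lo, hi) == (6, 7)

    def test_max_bp_truncates(self):
        panel = self._ld_panel()  # bp = 1000,2000,...
        lo, hi = lbr.define_window(panel, 2, r2_threshold=0.05, max_bp=1000)
        assert (lo, hi) == (1, 4)

    def test_window_never_crosses_chromosome(self):
        rng = np.random.default_rng(1)
        n = 100
        base = rng.binomial(2, 0.4, n).astype(float)
        X = np.column_stack([base, base, base, base])
        sex = np.array(["male"] * 50 + ["female"] * 50, dtype=object)
        panel = make_panel(X, sex, chrom=["chr1", "chr1", "chr2", "chr2"],
                           bp=[1000, 2000, 1000, 2000])
        assert lbr.define_window(panel, 1) == (0, 2)
        assert lbr.define_window(panel, 2) == (2, 4)

    def test_monomorphic_focal_warns_singleton(self):
        panel = self._ld_panel()
        panel.dosages[:, 3] = 1.0
        with pytest.warns(UserWarning, match="monomorphic"):
            assert lbr.define_window(panel, 3) == (3, 4)

    def test_width_monotone_in_threshold(self, small_fit):
        """On an LD-decay panel, raising the r2 threshold never widens any
        window."""
        panel, _, _, _ = small_fit
        focal = panel.p // 2
        widths = []
        for thr in (0.02, 0.05, 0.2, 0.5, 0.9):
            lo, hi = lbr.define_window(panel, focal, r2_threshold=thr)
            widths.append(hi - lo)
        assert all(a >= b for a, b in zip(widths, widths[1:]))
        assert widths[0] > 1  # LD panel: loose threshold spans neighbours


class TestWindowVariances:
    def test_zero_effects_zero_variance_exact(self):
        rng = np.random.default_rng(2)
        sex = np.array(["male"] * 5 + ["female"] * 5, dtype=object)
        panel = make_panel(rng.binomial(2, 0.4, (10, 3)).astype(float), sex)
        vm, vf = lbr.window_variances(
            panel, [(0, 3)], np.zeros((4, 3)), np.zeros((4, 3))
        )
        assert (vm == 0.0).all() and (vf == 0.0).all()

    def test_single_snp_closed_form(self):
        rng = np.random.default_rng(3)
        sex = np.array(["male"] * 6 + ["female"] * 6, dtype=object)
        X = rng.binomial(2, 0.5, (12, 1)).astype(float)
        panel = make_panel(X, sex)
        beta = np.array([[0.7]])
        vm, _ = lbr.window_variances(panel, [(0, 1)], beta, beta)
        expected = 0.7**2 * X[:, 0].var(ddof=1)
        assert vm[0, 0] == pytest.approx(expected, rel=1e-12)

    def test_matches_bruteforce_n_vector(self):
        """Quadratic-form computation equals the sample variance of the
        explicitly formed X_w @ beta vector, correlated dosages included."""
        rng = np.random.default_rng(4)
        n = 50
        base = rng.binomial(2, 0.4, n).astype(float)
        X = np.column_stack([base, np.clip(base + rng.binomial(1, 0.3, n), 0, 2),
                             rng.binomial(2, 0.3, n)]).astype(float)
        sex = np.array(["male"] * 25 + ["female"] * 25, dtype=object)
        panel = make_panel(X, sex)
        beta_m = rng.normal(size=(6, 3))
        beta_f = rng.normal(size=(6, 3))
        vm, vf = lbr.window_variances(panel, [(0, 3)], beta_m, beta_f)
        Xc = X - X.mean(axis=0)
        for s in range(6):
            assert vm[s, 0] == pytest.approx((Xc @ beta_m[s]).var(ddof=1), rel=1e-10)
            assert vf[s, 0] == pytest.approx((Xc @ beta_f[s]).var(ddof=1), rel=1e-10)

    def test_zero_ld_windows_are_additive(self):
        """With exactly orthogonal (centered) dosage columns, the variance of
        the union window equals the sum over subwindows, draw by draw."""
        X = np.array([[2.0, 2.0], [0.0, 2.0], [2.0, 0.0], [0.0, 0.0]])
        Xc = X - X.mean(axis=0)
        assert abs((Xc[:, 0] * Xc[:, 1]).sum()) < 1e-12
        sex = np.array(["male", "male", "female", "female"], dtype=object)
        panel = make_panel(X, sex)
        rng = np.random.default_rng(5)
        beta = rng.normal(size=(8, 2))
        vm, _ = lbr.window_variances(panel, [(0, 1), (1, 2), (0, 2)], beta, beta)
        np.testing.assert_allclose(vm[:, 2], vm[:, 0] + vm[:, 1], atol=1e-10)


class TestWindowProbabilities:
    def test_shared_only_window(self):
        """Shared effects present, interactions always spiked out:
        PPMvar = PPFvar = 1 and PPDiffVar = 0, and the male/female variances
        are bit-identical in every draw."""
        rng = np.random.default_rng(6)
        sex = np.array(["male"] * 8 + ["female"] * 8, dtype=object)
        panel = make_panel(rng.binomial(2, 0.4, (16, 2)).astype(float), sex)
        S = 5
        b0 = np.full((S, 2), 0.4)
        s = _samples(b0, np.zeros((S, 2)), np.zeros((S, 2)))
        ws = lbr.window_probabilities(s, panel, [(0, 2), (0, 2)])
        t = ws.table
        assert (t["PPMvar"] == 1.0).all()
        assert (t["PPFvar"] == 1.0).all()
        assert (t["PPDiffVar"] == 0.0).all()
        assert (t["mean_var_m"] == t["mean_var_f"]).all()

    def test_all_zero_draws(self):
        rng = np.random.default_rng(7)
        sex = np.array(["male"] * 8 + ["female"] * 8, dtype=object)
        panel = make_panel(rng.binomial(2, 0.4, (16, 2)).astype(float), sex)
        S = 5
        z = np.zeros((S, 2))
        t = lbr.window_probabilities(_samples(z, z, z), panel, [(0, 2), (1, 2)]).table
        assert (t[["PPMvar", "PPFvar", "PPDiffVar"]].to_numpy() == 0.0).all()

    def test_female_only_window(self):
        rng = np.random.default_rng(8)
        sex = np.array(["male"] * 8 + ["female"] * 8, dtype=object)
        panel = make_panel(rng.binomial(2, 0.4, (16, 2)).astype(float), sex)
        S = 10
        bf = np.zeros((S, 2)); bf[:9, 0] = 0.5
        t = lbr.window_probabilities(
            _samples(np.zeros((S, 2)), np.zeros((S, 2)), bf), panel, [(0, 2), (1, 2)]
        ).table
        assert t.loc[0, "PPFvar"] == pytest.approx(0.9)
        assert t.loc[0, "PPMvar"] == 0.0
        assert t.loc[0, "PPDiffVar"] == pytest.approx(0.9)

    def test_ppdiffvar_bounded_by_interaction_inclusion(self, small_fit):
        panel, _, _, s = small_fit
        windows = lbr.define_all_windows(panel)
        t = lbr.window_probabilities(s, panel, windows).table
        for w, (lo, hi) in enumerate(windows):
            any_int = ((s.bm[:, lo:hi] != 0) | (s.bf[:, lo:hi] != 0)).any(axis=1).mean()
            assert t.loc[w, "PPDiffVar"] <= any_int + 1e-12

    def test_equal_variances_when_no_interactions_in_draw(self, small_fit):
        """Whenever a draw has every interaction effect inside the window
        spiked out, the male and female window variances coincide exactly."""
        panel, _, _, s = small_fit
        windows = lbr.define_all_windows(panel)[:40]
        bm, bf = lbr.sex_specific_effects(s)
        vm, vf = lbr.window_variances(panel, windows, bm, bf)
        for w, (lo, hi) in enumerate(windows):
            no_int = ~((s.bm[:, lo:hi] != 0) | (s.bf[:, lo:hi] != 0)).any(axis=1)
            np.testing.assert_array_equal(vm[no_int, w], vf[no_int, w])


def test_summarize_joins_snp_and_window_tables(small_fit):
    panel, _, _, s = small_fit
    table = lbr.summarize(s, panel)
    assert len(table) == panel.p
    for col in ("PPM", "PPF", "PPDiff", "PPMvar", "PPFvar", "PPDiffVar",
                "mean_var_m", "mean_var_f", "window_start_bp", "window_end_bp"):
        assert col in table.columns
    probs = table[["PPM", "PPF", "PPDiff", "PPMvar", "PPFvar", "PPDiffVar"]].to_numpy()
    assert ((probs >= 0) & (probs <= 1)).all()
    assert (table[["mean_var_m", "mean_var_f"]].to_numpy() >= 0).all()


def test_window_variances_sex_specific_option():
    """The per-sex genotype option equals the brute-force variance of
    X_sex @ beta within each sex, and estimates the same quantity as the
    pooled default when the two sexes share the genotype distribution."""
    rng = np.random.default_rng(9)
    n = 400
    X = rng.binomial(2, 0.4, (n, 3)).astype(float)
    sex = np.array(["male"] * 200 + ["female"] * 200, dtype=object)
    panel = make_panel(X, sex)
    beta = rng.normal(size=(5, 3))
    vm, vf = lbr.window_variances(panel, [(0, 3)], beta, beta,
                                  sex_specific_genotypes=True)
    Xc = X - X.mean(axis=0)
    for s in range(5):
        gm = Xc[panel.is_male] @ beta[s]
        gf = Xc[panel.is_female] @ beta[s]
        assert vm[s, 0] == pytest.approx(gm.var(ddof=1), rel=1e-10)
        assert vf[s, 0] == pytest.approx(gf.var(ddof=1), rel=1e-10)
    pooled_m, _ = lbr.window_variances(panel, [(0, 3)], beta, beta)
    np.testing.assert_allclose(vm[:, 0], pooled_m[:, 0], rtol=0.35)
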