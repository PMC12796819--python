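"""Moderated/pooled t-tests, BH adjustment and the significance rule."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import lfqminer as L
from lfqminer.diffexpr import (
    ContrastResult,
    _contrast_stats,
    bh_adjust,
    estimate_prior,
    trigamma_inverse,
    volcano_table,
)
from lfqminer.errors import ValidationError


def bh_brute_force(p):
    """O(m^2) step-up: padj_i = min over p_(j) >= p_i of min(1, m p_(j)/j)."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    out = np.empty(m)
    for i in range(m):
        candidates = [min(1.0, m * ranked[j] / (j + 1)) for j in range(i, m)]
        out[i] = min(candidates)
    padj = np.empty(m)
    padj[order] = out
    return padj


class TestBhAdjust:
    def test_textbook_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_p_identity(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_out_of_range_fatal(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.5])

    def test_against_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            m = rng.integers(1, 51)
            p = rng.uniform(size=m)
            assert np.allclose(bh_adjust(p), bh_brute_force(p), atol=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20), st.randoms())
    @settings(deadline=None, derandomize=True, max_examples=100)
    def test_permutation_equivariance(self, pvals, rnd):
        perm = list(range(len(pvals)))
        rnd.shuffle(perm)
        base = bh_adjust(pvals)
        shuffled = bh_adjust([pvals[i] for i in perm])
        assert np.allclose([base[i] for i in perm], shuffled)


class TestModeration:
    def test_unmoderated_equals_textbook_pooled_t(self):
        x1 = np.array([[4.0, 5.0, 6.0]])
        x2 = np.array([[1.0, 2.0, 3.0]])
        lfc, p, d0, _ = _contrast_stats(x1, x2, moderated=False)
        t_ref, p_ref = stats.ttest_ind([4, 5, 6], [1, 2, 3], equal_var=True)
        assert d0 == 0.0
        assert lfc[0] == pytest.approx(3.0)
        assert p[0] == pytest.approx(p_ref, abs=1e-10)

    def test_posterior_variance_limits(self):
        rng = np.random.default_rng(0)
        s2 = rng.chisquare(4, 500) / 4
        d = 4
        # d0 -> 0: posterior variance is the per-protein variance
        assert np.allclose((0 * 1.0 + d * s2) / (0 + d), s2)
        # d0 -> infinity: posterior collapses onto the prior
        d0 = 1e8
        s02 = 0.7
        post = (d0 * s02 + d * s2) / (d0 + d)
        assert np.allclose(post, s02, atol=1e-5)

    def test_trigamma_inverse_roundtrip(self):
        from scipy.special import polygamma
        for y in (0.1, 1.0, 5.0, 42.0):
            assert trigamma_inverse(float(polygamma(1, y))) == pytest.approx(y, rel=1e-6)

    def test_prior_recovers_known_hyperparameters(self):
        # variances drawn from s0^2 * F(d, d0): moments fit should recover (d0, s0^2)
        rng = np.random.default_rng(3)
        d, d0_true, s02_true = 4, 6.0, 0.3
        s2 = s02_true * rng.f(d, d0_true, size=200_000) * 1.0
        d0, s02 = estimate_prior(s2, d)
        assert d0 == pytest.approx(d0_true, rel=0.1)
        assert s02 == pytest.approx(s02_true, rel=0.05)

    def test_agrees_with_limma_ebayes(self, tmp_path):
        """Independent oracle: limma's lmFit/eBayes on the same matrix."""
        rng = np.random.default_rng(42)
        n = 60
        sd = rng.uniform(0.5, 1.5, n)[:, None]  # heterogeneous -> finite prior df
        x = rng.normal(25, 1, size=(n, 1)) + rng.normal(0, 1, size=(n, 6)) * sd
        m = tmp_path / "m.tsv"
        pd.DataFrame(
            x, index=[f"g{i}" for i in range(n)], columns=list("abcdef")
        ).to_csv(m, sep="\t")
        out = tmp_path / "limma.tsv"
        rcode = textwrap.dedent(f"""
            suppressMessages(library(limma))
            m <- as.matrix(read.delim("{m}", row.names=1))
            design <- model.matrix(~0+factor(c(1,1,1,2,2,2)))
            colnames(design) <- c("A","B")
            fit <- eBayes(contrasts.fit(lmFit(m, design),
                          makeContrasts(B-A, levels=design)),
                          trend=FALSE, robust=FALSE)
            write.table(data.frame(lfc=fit$coefficients[,1], p=fit$p.value[,1],
                        d0=fit$df.prior, s02=fit$s2.prior),
                        "{out}", sep="\\t", quote=FALSE)
        """)
        subprocess.run(["Rscript", "-e", rcode], check=True, capture_output=True)
        ref = pd.read_csv(out, sep="\t")
        lfc, p, d0, s02 = _contrast_stats(x[:, 3:], x[:, :3], moderated=True)
        assert d0 == pytest.approx(ref["d0"].iloc[0], rel=1e-9)
        assert s02 == pytest.approx(ref["s02"].iloc[0], rel=1e-9)
        assert np.allclose(lfc, ref["lfc"], atol=1e-10)
        assert np.allclose(p, ref["p"], atol=1e-10)


class TestContrasts:
    def test_identical_groups_give_zero_lfc(self, sim_bundle):
        ds = sim_bundle["ds"]
        r = L.fit_contrast(ds, "Chow_Veh", "Chow_Veh".replace("Veh", "LDT409"))
        sym = ds.matrix.copy()
        # construct a dataset where both groups share values per protein
        cols_a = ds.design.samples_of("Chow_Veh")
        cols_b = ds.design.samples_of("Chow_LDT409")
        sym[cols_b] = sym[cols_a].to_numpy()
        from dataclasses import replace
        ds_sym = replace(ds, matrix=sym)
        r = L.fit_contrast(ds_sym, "Chow_LDT409", "Chow_Veh")
        assert np.allclose(r.table["log2fc"], 0.0)
        assert not r.table["significant"].any()

    def test_antisymmetry(self, sim_bundle):
        ds = sim_bundle["ds"]
        fwd = L.fit_contrast(ds, "Chow_LDT409", "Chow_Veh")
        rev = L.fit_contrast(ds, "Chow_Veh", "Chow_LDT409")
        assert np.array_equal(fwd.table["log2fc"].to_numpy(),
                              -rev.table["log2fc"].to_numpy())
        assert np.array_equal(fwd.table["p"].to_numpy(), rev.table["p"].to_numpy())

    def test_all_pairs_fitted(self, contrast_results):
        assert len(contrast_results) == 6  # C(4, 2)
        ids = {r.contrast_id for r in contrast_results}
        assert "Chow_LDT409_vs_Chow_Veh" in ids

    def test_changed_in_any_is_union(self, contrast_results):
        expect = set()
        for r in contrast_results:
            expect |= set(r.table.index[r.table["significant"]])
        assert L.changed_in_any(contrast_results) == expect

    def test_padj_monotone_in_p(self, contrast_results):
        t = contrast_results[0].table.sort_values("p")
        assert (t["padj"].to_numpy() >= t["p"].to_numpy() - 1e-15).all()
        assert (np.diff(t["padj"].to_numpy()) >= -1e-15).all()


class TestVolcano:
    @pytest.mark.parametrize(
        "padj,lfc,expect",
        [
            (0.04, 0.6, True),
            (0.04, 0.5, False),  # strict: |lfc| must exceed the cutoff
            (0.05, 2.0, False),  # strict: padj must be below alpha
            (0.04, -0.6, True),
        ],
    )
    def test_strict_significance_rule(self, padj, lfc, expect):
        table = pd.DataFrame(
            {"log2fc": [lfc], "p": [padj / 2], "padj": [padj],
             "significant": [(padj < 0.05) and (abs(lfc) > 0.5)]},
            index=["g"],
        )
        r = ContrastResult("B", "A", table)
        vt = volcano_table(r)
        assert bool(vt["significant"].iloc[0]) is expect


def test_type_one_error_calibration():
    """Under a global null the moderated test's raw p < .05 rate is nominal
    (500 simulated datasets, 2000 proteins, 2 conditions x 3 replicates)."""
    rng = np.random.default_rng(2024)
    frac = []
    for _ in range(500):
        x = rng.normal(0, 0.5, size=(2000, 6))
        _, p, _, _ = _contrast_stats(x[:, :3], x[:, 3:], moderated=True)
        frac.append(np.mean(p < 0.05))
    assert abs(np.mean(frac) - 0.05) < 0.01


def test_planted_effect_power_and_bias():
    """Planted log2FC of 1.5 (n = 4 per group, sigma = 0.5): estimates are
    unbiased to 0.1 and raw-alpha power exceeds 0.9 over 200 simulations."""
    rng = np.random.default_rng(99)
    lfc_means, powers = [], []
    for _ in range(200):
        x = rng.normal(25, 0.5, size=(300, 8))
        x[:30, 4:] += 1.5
        lfc, p, _, _ = _contrast_stats(x[:, 4:], x[:, :4], moderated=True)
        lfc_means.append(lfc[:30].mean())
        powers.append(np.mean(p[:30] < 0.05))
    assert abs(np.mean(lfc_means) - 1.5) <= 0.1
    assert np.mean(powers) > 0.9
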