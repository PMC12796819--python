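"""Flag removal, the detection-threshold filter, transform and imputation."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import lfqminer as L
from lfqminer.errors import ValidationError
from lfqminer.maxquant_io import ExperimentDesign
from lfqminer.preprocess import ExpressionDataset, detection_keep_mask


def make_design(reps_per_cond):
    rows, i = [], 0
    for c, n in reps_per_cond.items():
        for r in range(1, n + 1):
            i += 1
            rows.append({"label": f"S{i:02d}", "condition": c, "replicate": r, "order": i})
    return ExperimentDesign(pd.DataFrame(rows))


def dataset_from_mask(detected, design):
    """Raw-stage dataset whose missingness pattern is the given boolean matrix."""
    values = np.where(np.asarray(detected, bool), 1000.0, np.nan)
    m = pd.DataFrame(values, columns=design.labels,
                     index=[f"p{i}" for i in range(len(values))])
    ann = pd.DataFrame({"gene_name": m.index, "protein_ids": m.index}, index=m.index)
    return ExpressionDataset(matrix=m, design=design, annotations=ann)


def brute_force_keep(pattern, reps_per_cond, thr):
    """Independent evaluation of the keep rule on one detection pattern."""
    j = 0
    for n in reps_per_cond.values():
        if sum(pattern[j:j + n]) >= n - thr:
            return True
        j += n
    return False


class TestRemoveFlaggedRows:
    def test_counts(self, tiny_pg_file):
        t = L.parse_protein_groups(tiny_pg_file)
        clean = L.remove_flagged_rows(t)
        assert len(clean) == 4 and len(t) == 6

    def test_identity_when_clean(self, tiny_pg_file):
        t = L.parse_protein_groups(tiny_pg_file)
        once = L.remove_flagged_rows(t)
        twice = L.remove_flagged_rows(once)
        assert twice.unique_id == once.unique_id


class TestFilterMissing:
    def test_complete_in_one_condition_kept(self):
        d = make_design({"A": 3, "B": 3})
        ds = dataset_from_mask([[1, 1, 1, 0, 0, 0]], d)
        assert len(L.filter_missing(ds, 0).matrix) == 1

    def test_three_of_four_kept_at_thr1(self):
        d = make_design({"A": 4, "B": 4})
        ds = dataset_from_mask([[1, 1, 1, 0] + [0] * 4], d)
        assert len(L.filter_missing(ds, 1).matrix) == 1
        assert len(L.filter_missing(ds, 0).matrix) == 0

    def test_two_of_three_everywhere_removed(self):
        d = make_design({"A": 3, "B": 3, "C": 3, "D": 3})
        ds = dataset_from_mask([[1, 1, 0] * 4], d)
        assert len(L.filter_missing(ds, 0).matrix) == 0

    def test_threshold_at_replicate_count_rejected(self):
        d = make_design({"A": 2, "B": 3})
        ds = dataset_from_mask([[1] * 5], d)
        with pytest.raises(ValidationError):
            L.filter_missing(ds, 2)

    @pytest.mark.parametrize("n_cond,n_rep", [(2, 2), (2, 3), (3, 2), (4, 2), (2, 4)])
    def test_exhaustive_equivalence_with_brute_force(self, n_cond, n_rep):
        """Keep-rule matches independent evaluation on every detection pattern."""
        reps = {chr(65 + c): n_rep for c in range(n_cond)}
        d = make_design(reps)
        n = n_cond * n_rep
        patterns = list(itertools.product([0, 1], repeat=n))
        ds = dataset_from_mask(patterns, d)
        for thr in range(n_rep):
            mask = detection_keep_mask(ds.matrix.notna(), d, thr)
            expect = [brute_force_keep(p, reps, thr) for p in patterns]
            assert mask.tolist() == expect

    @given(st.integers(0, 2 ** 12 - 1), st.integers(0, 1))
    @settings(deadline=None, derandomize=True, max_examples=200)
    def test_monotone_in_threshold(self, bits, thr):
        d = make_design({"A": 3, "B": 3, "C": 3, "D": 3})
        pattern = [(bits >> i) & 1 for i in range(12)]
        ds = dataset_from_mask([pattern], d)
        kept_lo = detection_keep_mask(ds.matrix.notna(), d, thr).iloc[0]
        kept_hi = detection_keep_mask(ds.matrix.notna(), d, thr + 1).iloc[0]
        assert (not kept_lo) or kept_hi  # keep-set(thr) subset of keep-set(thr+1)


class TestTransforms:
    def test_log2_values(self):
        d = make_design({"A": 2, "B": 2})
        m = pd.DataFrame([[1024.0, 1.0, np.nan, 2.0]], columns=d.labels, index=["p0"])
        ann = pd.DataFrame({"gene_name": ["p0"], "protein_ids": ["p0"]}, index=["p0"])
        ds = ExpressionDataset(m, d, ann, stage="filtered")
        out = L.log2_transform(ds)
        assert out.matrix.iloc[0].tolist()[:2] == [10.0, 0.0]
        assert np.isnan(out.matrix.iloc[0, 2])

    def test_median_normalization_removes_shift(self):
        d = make_design({"A": 2, "B": 2})
        rng = np.random.default_rng(0)
        base = rng.normal(25, 1, size=(50, 4))
        base[:, 2] += 2.0
        m = pd.DataFrame(base, columns=d.labels)
        m.index = [f"p{i}" for i in range(50)]
        ann = pd.DataFrame({"gene_name": m.index, "protein_ids": m.index}, index=m.index)
        out = L.normalize_median(ExpressionDataset(m, d, ann, stage="filtered"))
        meds = out.matrix.median(axis=0)
        assert np.allclose(meds, meds.iloc[0], atol=1e-9)


class TestImputation:
    def _ds(self, seed=0, missing_frac=0.3, n=200):
        d = make_design({"A": 3, "B": 3})
        rng = np.random.default_rng(seed)
        vals = rng.normal(25, 2, size=(n, 6))
        # censor the lowest values (MNAR by construction)
        cutoff = np.quantile(vals, missing_frac)
        vals = np.where(vals < cutoff, np.nan, vals)
        m = pd.DataFrame(vals, columns=d.labels, index=[f"p{i}" for i in range(n)])
        ann = pd.DataFrame({"gene_name": m.index, "protein_ids": m.index}, index=m.index)
        return ExpressionDataset(m, d, ann, stage="filtered")

    def test_complete_matrix_unchanged(self):
        d = make_design({"A": 2, "B": 2})
        m = pd.DataFrame(np.full((3, 4), 25.0), columns=d.labels, index=list("xyz"))
        ann = pd.DataFrame({"gene_name": list("xyz"), "protein_ids": list("xyz")},
                           index=list("xyz"))
        ds = ExpressionDataset(m, d, ann, stage="filtered")
        out = L.impute_left_censored(ds, seed=1)
        assert out.stage == "imputed" and out.matrix.equals(m)

    def test_same_seed_bitwise_identical(self):
        ds = self._ds()
        a = L.impute_left_censored(ds, seed=42).matrix
        b = L.impute_left_censored(ds, seed=42).matrix
        assert a.equals(b)
        c = L.impute_left_censored(ds, seed=43).matrix
        assert not c.equals(a)

    def test_observed_preserved_and_complete(self):
        ds = self._ds()
        out = L.impute_left_censored(ds, seed=7)
        assert not out.matrix.isna().any().any()
        obs = ds.matrix.notna().to_numpy()
        assert np.array_equal(out.matrix.to_numpy()[obs], ds.matrix.to_numpy()[obs])

    def test_imputed_values_left_of_observed(self):
        """Left-censoring contract: imputed mean below the observed 5th percentile
        in at least 95% of 200 seeded simulations."""
        hits = 0
        for seed in range(200):
            ds = self._ds(seed=seed, n=100)
            out = L.impute_left_censored(ds, seed=seed + 1)
            mask = ds.matrix.isna()
            imputed = out.matrix.to_numpy()[mask.to_numpy()]
            p5 = np.nanpercentile(ds.matrix.to_numpy(), 5)
            hits += imputed.mean() < p5
        assert hits >= 190

    def test_starved_sample_is_fatal(self):
        d = make_design({"A": 2, "B": 2})
        m = pd.DataFrame(
            [[np.nan, 25, 25, 25], [np.nan, 24, 24, 24], [25.0, 23, 23, 23]],
            columns=d.labels, index=list("xyz"),
        )
        ann = pd.DataFrame({"gene_name": list("xyz"), "protein_ids": list("xyz")},
                           index=list("xyz"))
        ds = ExpressionDataset(m, d, ann, stage="filtered")
        with pytest.raises(ValidationError, match="observed"):
            L.impute_left_censored(ds, seed=1)


def test_full_chain_bit_reproducible(sim_bundle):
    paths = sim_bundle["paths"]
    from lfqminer.preprocess import preprocess_pipeline
    t = L.parse_protein_groups(paths["protein_groups"])
    d = L.parse_design(paths["design"], t)
    a = preprocess_pipeline(t, d, threshold=0, seed=5)
    b = preprocess_pipeline(t, d, threshold=0, seed=5)
    assert a.matrix.equals(b.matrix)
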