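"""Detection breadth, overlap, tiers, correlation, PCA, rank-abundance."""

import itertools

import numpy as np
import pandas as pd
import pytest

from csfbench.assembly import QuantMatrix
from csfbench.compare import (
    correlation_matrix,
    detection_counts,
    detection_tiers,
    membership_sets,
    membership_table,
    pca_scores,
    rank_abundance,
)


def make_matrix(values, method="A"):
    """values: dict feature -> dict sample -> value (missing = absent)."""
    samples = sorted({s for row in values.values() for s in row})
    meta = {s: {"method": method, "patient": f"pt{s}"} for s in samples}
    df = pd.DataFrame(
        [[values[f].get(s, np.nan) for s in samples] for f in sorted(values)],
        index=sorted(values),
        columns=samples,
        dtype=float,
    )
    return QuantMatrix(values=df, sample_meta=meta)


def random_matrix(rng, features, samples, method, p_detect=0.6):
    values = {
        f: {
            s: float(rng.normal(20, 2))
            for s in samples
            if rng.random() < p_detect
        }
        for f in features
    }
    values = {f: row for f, row in values.items()}
    meta = {s: {"method": method, "patient": s.split(".")[-1]} for s in samples}
    df = pd.DataFrame(
        [[values[f].get(s, np.nan) for s in samples] for f in features],
        index=list(features),
        columns=list(samples),
        dtype=float,
    )
    return QuantMatrix(values=df, sample_meta=meta)


class TestDetectionCounts:
    def test_counts_and_all_missing_sample_listed(self):
        m = make_matrix(
            {"f1": {"s1": 1.0, "s2": 2.0}, "f2": {"s1": 3.0}, "f3": {}}
        )
        out = detection_counts({"A": m})
        by_sample = dict(zip(out["sample"], out["n_detected"]))
        assert by_sample == {"s1": 2, "s2": 1}

    def test_median_matches_sort_oracle(self, rng):
        features = [f"f{i}" for i in range(30)]
        samples = [f"A.p{i}" for i in range(7)]
        m = random_matrix(rng, features, samples, "A")
        out = detection_counts({"A": m})
        counts = sorted(out["n_detected"])
        expected = float(np.sort(counts)[len(counts) // 2])
        assert out["workflow_median"].iloc[0] == pytest.approx(expected)


class TestMembership:
    def test_exclusive_and_full_regions(self):
        a = make_matrix({"x": {"s1": 1.0}, "z": {"s1": 1.0}}, "A")
        b = make_matrix({"y": {"t1": 1.0}, "z": {"t1": 1.0}}, "B")
        sets = membership_sets({"A": a, "B": b})
        assert sets.region_counts[frozenset({"A"})] == 1
        assert sets.region_counts[frozenset({"B"})] == 1
        assert sets.region_counts[frozenset({"A", "B"})] == 1
        table = membership_table(sets)
        assert table["count"].sum() == sets.union_size == 3

    @pytest.mark.parametrize("k", [3, 4, 5])
    def test_matches_per_feature_region_oracle(self, rng, k):
        features = [f"f{i}" for i in range(60)]
        matrices = {
            f"W{j}": random_matrix(
                rng, features, [f"W{j}.p{i}" for i in range(3)], f"W{j}", 0.4
            )
            for j in range(k)
        }
        sets = membership_sets(matrices)
        oracle = {}
        for f in features:
            region = frozenset(
                w
                for w, m in matrices.items()
                if m.values.loc[f].notna().any()
            )
            if region:
                oracle[region] = oracle.get(region, 0) + 1
        assert sets.region_counts == oracle
        assert sum(sets.region_counts.values()) == sets.union_size


class TestTiers:
    def test_boundaries(self):
        n = 19
        values = {
            "full": {f"s{i}": 1.0 for i in range(n)},          # 19/19 -> top
            "mid": {f"s{i}": 1.0 for i in range(9)},           # 9/19 ~ 0.47
            "rare": {"s0": 1.0},                               # 1/19 ~ 0.05
        }
        # make sure every sample column exists
        values["full"].update({f"s{i}": 1.0 for i in range(n)})
        m = make_matrix(values)
        tiers = detection_tiers(m)
        counts = dict(zip(tiers["tier"], tiers["count"]))
        assert counts["(0.9,1]"] == 1
        assert counts["(0.1,0.5]"] == 1
        assert counts["(0,0.1]"] == 1
        assert counts["(0.5,0.9]"] == 0

    def test_partition_property(self, rng):
        features = [f"f{i}" for i in range(50)]
        m = random_matrix(rng, features, [f"A.p{i}" for i in range(10)], "A", 0.5)
        tiers = detection_tiers(m)
        universe = int(m.detected().any(axis=1).sum())
        assert tiers["count"].sum() == universe


class TestCorrelation:
    def test_symmetry_unit_diagonal_and_duplicate_sample(self, rng):
        base = rng.normal(20, 3, 30)
        values = {
            f"f{i}": {"s1": base[i], "s2": base[i], "s3": float(rng.normal(20, 3))}
            for i in range(30)
        }
        m = make_matrix(values)
        corr, order = correlation_matrix(m)
        assert corr.at["s1", "s2"] == pytest.approx(1.0)
        assert np.allclose(corr.values, corr.values.T, equal_nan=True)
        assert np.allclose(np.diag(corr.values), 1.0)
        assert sorted(order) == ["s1", "s2", "s3"]

    def test_insufficient_shared_features_missing(self):
        values = {
            "f1": {"s1": 1.0},
            "f2": {"s1": 2.0},
            "f3": {"s2": 3.0},
            "f4": {"s1": 1.5, "s2": 2.5},
        }
        corr, _ = correlation_matrix(make_matrix(values))
        assert np.isnan(corr.at["s1", "s2"])


class TestPCA:
    def test_identical_samples_identical_coordinates(self, rng):
        col = rng.normal(20, 2, 10)
        values = {
            f"f{i}": {"s1": col[i], "s2": col[i], "s3": col[i] + 1.0}
            for i in range(10)
        }
        scores, fractions = pca_scores(make_matrix(values))
        pcs = [c for c in scores.columns if c.startswith("PC")]
        assert np.allclose(
            scores.loc["s1", pcs].to_numpy(dtype=float),
            scores.loc["s2", pcs].to_numpy(dtype=float),
            atol=1e-9,
        )
        assert fractions.sum() == pytest.approx(1.0, abs=1e-9)

    def test_matches_covariance_eigen_oracle(self, rng):
        X = rng.normal(size=(5, 10))  # 5 samples x 10 features
        values = {
            f"f{j}": {f"s{i}": X[i, j] for i in range(5)} for j in range(10)
        }
        scores, fractions = pca_scores(make_matrix(values))
        Xc = X - X.mean(axis=0)
        evals, evecs = np.linalg.eigh(Xc.T @ Xc)
        evals, evecs = evals[::-1], evecs[:, ::-1]
        expected = Xc @ evecs
        pcs = [c for c in scores.columns if c.startswith("PC")]
        got = scores[pcs].to_numpy(dtype=float)
        for k in range(4):  # rank is 4 after centering
            assert np.allclose(got[:, k], expected[:, k], atol=1e-8) or np.allclose(
                got[:, k], -expected[:, k], atol=1e-8
            )
        nonzero = evals[evals > 1e-12]
        assert np.allclose(
            sorted(fractions[: len(nonzero)], reverse=True),
            sorted(nonzero / evals.sum(), reverse=True),
            atol=1e-9,
        )


class TestRankAbundance:
    def test_ordering_ties_and_missing_marker(self):
        values = {
            "b": {"s1": 10.0, "s2": 10.0},
            "a": {"s1": 5.0, "s2": 5.0},
            "aa": {"s1": 5.0, "s2": 5.0},
            "c": {"s1": 1.0},
        }
        out = rank_abundance(make_matrix(values), marker_panel=["a", "ZZZ"])
        ranked = out.dropna(subset=["rank"])
        assert list(ranked["feature"]) == ["b", "a", "aa", "c"]  # lexicographic tie
        missing = out[out["feature"] == "ZZZ"]
        assert missing["detection_fraction"].iloc[0] == 0.0
        assert bool(missing["is_marker"].iloc[0])
        assert bool(out[out["feature"] == "a"]["is_marker"].iloc[0])
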