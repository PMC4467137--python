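import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from rtksubtyper import ExpressionSimConfig, generate_expression
from rtksubtyper.clanc import (
    CentroidSignature,
    clanc_classify,
    clanc_fit,
    clanc_stats,
    cv_select_size,
)


def _toy(seed=0, n_genes=30, per_class=(6, 6, 6), effect=0.0):
    rng = np.random.default_rng(seed)
    n = sum(per_class)
    X = rng.normal(0, 1, (n_genes, n))
    labels = np.repeat([f"C{i}" for i in range(len(per_class))], per_class)
    if effect:
        for i in range(len(per_class)):
            mask = labels == f"C{i}"
            X[i, mask] += effect
    m = pd.DataFrame(
        X, index=[f"g{i}" for i in range(n_genes)], columns=[f"s{j}" for j in range(n)]
    )
    return m, pd.Series(labels, index=m.columns)


def selection_oracle(absd: pd.DataFrame, genes_per_class: int) -> dict:
    """Iterated global argmax by exhaustive scan over the full |d| matrix."""
    active = {c: [] for c in absd.columns}
    remaining = absd.copy()
    while True:
        open_classes = [c for c in absd.columns if len(active[c]) < genes_per_class]
        if not open_classes or remaining.empty:
            break
        sub = remaining[open_classes]
        best = None
        for g in sub.index:
            for c in open_classes:
                if best is None or sub.loc[g, c] > best[0]:
                    best = (sub.loc[g, c], g, c)
        _, g, c = best
        active[c].append(g)
        remaining = remaining.drop(index=g)
    return active


def stats_oracle(m: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Recompute |d| with explicit loops (independent of the vectorized path)."""
    classes = sorted(labels.unique())
    n = m.shape[1]
    sds = {}
    for g in m.index:
        ss = 0.0
        for c in classes:
            vals = m.loc[g, (labels == c).to_numpy()]
            ss += float(((vals - vals.mean()) ** 2).sum())
        sds[g] = np.sqrt(ss / (n - len(classes)))
    s0 = float(np.median(list(sds.values())))
    out = pd.DataFrame(index=m.index, columns=classes, dtype=float)
    for g in m.index:
        for c in classes:
            nc = int((labels == c).sum())
            mk = np.sqrt(1.0 / nc + 1.0 / n)
            diff = m.loc[g, (labels == c).to_numpy()].mean() - m.loc[g].mean()
            out.loc[g, c] = abs(diff) / (mk * (sds[g] + s0))
    return out


class TestFit:
    def test_dominant_gene_selected(self):
        m, labels = _toy(seed=1, n_genes=51, per_class=(8, 8))
        m.iloc[0] = 0.0
        m.iloc[0, :8] = 10.0
        m.iloc[0] += np.random.default_rng(2).normal(0, 0.1, m.shape[1])
        sig = clanc_fit(m, labels, genes_per_class=1)
        assert "g0" in sig.genes

    def test_active_sets_disjoint_and_sized(self, planted):
        sig = clanc_fit(planted.matrix, planted.true_subtype, genes_per_class=10)
        sets = [set(sig.active_sets[c]) for c in sig.classes]
        assert sum(len(s) for s in sets) == len(set().union(*sets)) == 30

    def test_selection_matches_brute_force_oracle(self):
        for seed in range(20):
            m, labels = _toy(seed=seed, n_genes=6, per_class=(4, 4, 4))
            absd = stats_oracle(m, labels)
            expected = selection_oracle(absd, 1)
            sig = clanc_fit(m, labels, genes_per_class=1)
            assert sig.active_sets == expected
            # the vectorized statistics agree with the loop recomputation
            mine = clanc_stats(m, labels).abs()
            assert np.allclose(mine.to_numpy(float), absd.to_numpy(float), atol=1e-10)

    def test_permuted_labels_have_null_statistics(self):
        m, labels = _toy(seed=3, n_genes=200, per_class=(10, 10, 10), effect=4.0)
        rng = np.random.default_rng(4)
        permuted = pd.Series(rng.permutation(labels.to_numpy()), index=labels.index)
        signal_max = clanc_stats(m, labels).abs().to_numpy().max()
        null_max = clanc_stats(m, permuted).abs().to_numpy().max()
        assert null_max < signal_max / 2

    def test_errors(self):
        m, labels = _toy(n_genes=5, per_class=(4, 4))
        with pytest.raises(ValueError, match="exceeds"):
            clanc_fit(m, labels, genes_per_class=3)
        tiny_labels = labels.copy()
        tiny_labels.iloc[:] = "C0"
        tiny_labels.iloc[0] = "C1"
        with pytest.raises(ValueError, match="< 2 samples"):
            clanc_fit(m, tiny_labels, genes_per_class=1)


class TestClassify:
    def test_profile_equal_to_centroid(self):
        m, labels = _toy(seed=5, n_genes=30, per_class=(8, 8, 8), effect=3.0)
        sig = clanc_fit(m, labels, genes_per_class=2)
        profile = pd.DataFrame({"x": sig.overall_centroid.copy()})
        active = sig.active_sets["C1"]
        profile.loc[active, "x"] = sig.class_centroids.loc[active, "C1"]
        out = clanc_classify(sig, profile)
        assert out.loc["x", "label"] == "C1"

    def test_tie_flagged_and_broken_deterministically(self):
        # hand-built mirror-symmetric signature: g0 active for C0, g1 for C1
        sig = CentroidSignature(
            classes=["C0", "C1"],
            active_sets={"C0": ["g0"], "C1": ["g1"]},
            genes=["g0", "g1"],
            class_centroids=pd.DataFrame(
                {"C0": [1.0, -1.0], "C1": [-1.0, 1.0]}, index=["g0", "g1"]
            ),
            overall_centroid=pd.Series([0.0, 0.0], index=["g0", "g1"]),
            pooled_sd=pd.Series([1.0, 1.0], index=["g0", "g1"]),
            s0=0.0,
            class_counts={"C0": 6, "C1": 6},
            genes_per_class=1,
        )
        out = clanc_classify(sig, pd.DataFrame({"x": [0.5, 0.5]}, index=["g0", "g1"]))
        assert bool(out.loc["x", "tie"])
        assert out.loc["x", "label"] == "C0"  # equal priors -> first sorted label
        sig.class_counts = {"C0": 6, "C1": 10}  # larger class wins the tie
        out = clanc_classify(sig, pd.DataFrame({"x": [0.5, 0.5]}, index=["g0", "g1"]))
        assert out.loc["x", "label"] == "C1"

    def test_shift_invariance(self):
        m, labels = _toy(seed=7, n_genes=30, per_class=(8, 8), effect=2.0)
        sig = clanc_fit(m, labels, genes_per_class=3)
        rng = np.random.default_rng(8)
        profile = pd.Series(rng.normal(size=len(sig.genes)), index=sig.genes)
        base = clanc_classify(sig, profile.to_frame("x")).loc["x", "label"]
        shifted_sig = clanc_fit(m + 5.0, labels, genes_per_class=3)
        shifted = clanc_classify(shifted_sig, (profile + 5.0).to_frame("x")).loc["x", "label"]
        assert base == shifted

    def test_missing_genes_listed(self):
        m, labels = _toy(seed=9, n_genes=20, per_class=(6, 6), effect=2.0)
        sig = clanc_fit(m, labels, genes_per_class=2)
        with pytest.raises(ValueError, match=sig.genes[0]):
            clanc_classify(sig, m.drop(index=sig.genes[0]))

    def test_planted_three_class_accuracy(self):
        ds = generate_expression(
            ExpressionSimConfig(
                n_samples_per_subtype=(15, 15, 30), n_genes=300, seed=10,
                marker_effect=3.0, noise_sd=1.0,
            )
        )
        test = generate_expression(
            ExpressionSimConfig(
                n_samples_per_subtype=(15, 15, 30), n_genes=300, seed=11,
                marker_effect=3.0, noise_sd=1.0,
            )
        )
        sig = clanc_fit(ds.matrix, ds.true_subtype, genes_per_class=20)
        pred = clanc_classify(sig, test.matrix)["label"]
        assert (pred.to_numpy() == test.true_subtype.to_numpy()).mean() >= 0.95


class TestCvSelectSize:
    def test_separable_data_reaches_zero_error_with_smallest_size(self):
        ds = generate_expression(
            ExpressionSimConfig(
                n_samples_per_subtype=(10, 10, 20), n_genes=150, seed=12,
                marker_effect=5.0, noise_sd=0.3,
            )
        )
        report = cv_select_size(ds.matrix, ds.true_subtype, grid=range(1, 16), seed=0)
        assert min(report.errors) == 0.0
        zero_sizes = [g for g, e in zip(report.grid, report.errors) if e == 0.0]
        assert report.chosen == min(zero_sizes)

    def test_permuted_labels_near_chance(self):
        ds = generate_expression(
            ExpressionSimConfig(
                n_samples_per_subtype=(12, 12, 12), n_genes=150, seed=13,
                marker_effect=3.0, noise_sd=1.0,
            )
        )
        rng = np.random.default_rng(14)
        permuted = pd.Series(
            rng.permutation(ds.true_subtype.to_numpy()), index=ds.true_subtype.index
        )
        report = cv_select_size(ds.matrix, permuted, grid=[5, 20, 50], seed=0)
        # three balanced classes: chance error 2/3; allow +-10 points
        assert all(abs(e - 2 / 3) <= 0.10 for e in report.errors)

    def test_singleton_grid(self, planted):
        report = cv_select_size(planted.matrix, planted.true_subtype, grid=[1], seed=0)
        assert report.grid == [1]
        assert report.chosen == 1

    def test_class_smaller_than_folds_rejected(self):
        m, labels = _toy(per_class=(4, 12))
        with pytest.raises(ValueError, match="smaller than fold"):
            cv_select_size(m, labels, grid=[1], folds=5)

    def test_noiseless_separable_error_zero_for_all_sizes(self):
        ds = generate_expression(
            ExpressionSimConfig(
                n_samples_per_subtype=(8, 8, 16), n_genes=160, seed=15,
                marker_effect=6.0, noise_sd=1e-6,
            )
        )
        report = cv_select_size(ds.matrix, ds.true_subtype, grid=[1, 5, 10, 20], seed=1)
        assert all(e == 0.0 for e in report.errors)


def test_full_pipeline_recovery_ari(planted):
    # signature fitted on truth labels separates an independently drawn cohort
    cfg = ExpressionSimConfig(
        n_samples_per_subtype=(10, 10, 20), n_genes=200,
        n_marker_genes_per_block=20, marker_effect=4.0, noise_sd=0.5, seed=555,
    )
    other = generate_expression(cfg)
    sig = clanc_fit(planted.matrix, planted.true_subtype, genes_per_class=15)
    pred = clanc_classify(sig, other.matrix)["label"]
    assert adjusted_rand_score(other.true_subtype, pred) >= 0.9
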