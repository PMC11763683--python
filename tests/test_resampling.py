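"""Resampling techniques: balance contracts, SMOTE geometry, ADASYN
quotas, cleaning rules against hand-checkable configurations, clipping."""

import numpy as np
import pandas as pd
import pytest

import oracles
from dxaradiomics import resampling as rs
from dxaradiomics.synthetic import generate_feature_cohort


def make_table(x, y):
    df = pd.DataFrame(np.asarray(x, dtype=float),
                      columns=[f"f{j}" for j in range(np.shape(x)[1])])
    df["label"] = y
    return df


@pytest.fixture(scope="module")
def training_table():
    """Training-partition-sized cohort: 942 healthy vs 129 degraded."""
    return generate_feature_cohort(1071, 129 / 1071, 6, class_shift=2.0,
                                   seed=42)


class TestUndersampling:
    def test_training_counts_balance(self, training_table):
        r = rs.random_undersample(training_table, seed=1)
        counts = r.table.label.value_counts()
        assert counts[0] == 129 and counts[1] == 129
        assert (r.origin == "original").all()

    def test_minority_rows_untouched(self, training_table):
        r = rs.random_undersample(training_table, seed=1)
        orig_min = training_table[training_table.label == 1]
        out_min = r.table[r.table.label == 1]
        assert len(out_min) == len(orig_min)
        merged = orig_min.merge(out_min, how="inner")
        assert len(merged) == len(orig_min)

    def test_balanced_input_is_fixed_point(self):
        t = make_table(np.arange(12).reshape(6, 2), [0, 1, 0, 1, 0, 1])
        r = rs.random_undersample(t, seed=0)
        assert t.sort_values("f0").reset_index(drop=True).equals(
            r.table.sort_values("f0").reset_index(drop=True))

    def test_seed_changes_retained_subset(self, training_table):
        a = rs.random_undersample(training_table, seed=1)
        b = rs.random_undersample(training_table, seed=2)
        assert len(a.table) == len(b.table)
        assert not a.table.reset_index(drop=True).equals(
            b.table.reset_index(drop=True))

    def test_single_class_rejected(self):
        t = make_table([[0.0, 1.0]] * 4, [1, 1, 1, 1])
        with pytest.raises(rs.SingleClassInput):
            rs.random_undersample(t)


class TestSmote:
    def test_duplicated_point_synthesises_itself(self):
        p = [2.0, -1.0]
        t = make_table([p, p] + [[10, 10], [11, 11], [12, 12], [13, 13]],
                       [1, 1, 0, 0, 0, 0])
        r = rs.smote(t, k=1, seed=0)
        syn = r.synthetic_rows.drop(columns="label").to_numpy()
        assert syn.shape[0] == 2
        assert np.allclose(syn, p)

    def test_collinear_minority_stays_on_line(self):
        pts = np.array([[0.0, 0.0], [1.0, 2.0], [2.0, 4.0]])
        maj = np.array([[50, 0], [50, 1], [50, 2], [50, 3], [51, 0],
                        [51, 1], [51, 2], [51, 3], [52, 0], [52, 1]])
        t = make_table(np.vstack([pts, maj]), [1] * 3 + [0] * 10)
        r = rs.smote(t, k=2, seed=3)
        syn = r.synthetic_rows.drop(columns="label").to_numpy()
        assert syn.shape[0] == 7
        # all synthetic points on the line y = 2x
        assert np.abs(syn[:, 1] - 2 * syn[:, 0]).max() < 1e-9

    def test_balances_training_counts(self, training_table):
        r = rs.smote(training_table, seed=5)
        counts = r.table.label.value_counts()
        assert counts[0] == 942 and counts[1] == 942
        assert (r.synthetic_rows.label == 1).all()

    def test_convex_combination_property(self, training_table):
        """Every synthetic point is a convex combination of two original
        minority points (checked by exact pairwise reconstruction)."""
        t = training_table.iloc[:200]
        r = rs.smote(t, k=5, seed=7)
        x_min = t[t.label == 1].drop(columns="label").to_numpy()
        syn = r.synthetic_rows.drop(columns="label").to_numpy()
        for s in syn[:25]:
            ok = False
            for i in range(len(x_min)):
                for j in range(len(x_min)):
                    if i == j:
                        continue
                    d = x_min[j] - x_min[i]
                    denom = float(d @ d)
                    if denom == 0:
                        continue
                    u = float((s - x_min[i]) @ d) / denom
                    if -1e-9 <= u <= 1 + 1e-9 and np.allclose(
                            x_min[i] + u * d, s, atol=1e-9):
                        ok = True
                        break
                if ok:
                    break
            assert ok

    def test_too_few_minority(self):
        t = make_table(np.arange(20).reshape(10, 2), [1, 1, 1] + [0] * 7)
        with pytest.raises(rs.TooFewMinoritySamples):
            rs.smote(t, k=5)

    def test_deterministic(self, training_table):
        a = rs.smote(training_table, seed=9)
        b = rs.smote(training_table, seed=9)
        assert a.table.equals(b.table)


class TestAdasyn:
    def test_isolated_minority_falls_back_to_uniform(self):
        """All r_i = 0 (no majority neighbours): uniform quotas, SMOTE-like."""
        min_pts = np.array([[0, 0], [0.1, 0], [0, 0.1], [0.1, 0.1]])
        maj_pts = np.array([[100 + i, 100 + j] for i in range(3)
                            for j in range(4)])
        t = make_table(np.vstack([min_pts, maj_pts]), [1] * 4 + [0] * 12)
        r = rs.adasyn(t, k=3, seed=1)
        counts = r.table.label.value_counts()
        assert counts[1] == counts[0] == 12
        syn = r.synthetic_rows.drop(columns="label").to_numpy()
        assert (np.abs(syn) <= 0.1 + 1e-12).all()  # interpolants stay local

    def test_boundary_point_gets_largest_quota(self):
        """Hand configuration: the one minority point surrounded by
        majority has r=1 while the rest have r=0, so it takes the whole
        generation quota; every synthetic point therefore lies on a ray
        from it towards another minority point."""
        a = np.array([0.0, 0.0])  # boundary minority point
        others = np.array([[20.0, 0.0], [20.2, 0.0], [20.1, 0.2],
                           [20.1, -0.2]])
        maj = [[0.3, 0.0], [0.0, 0.3], [-0.3, 0.0],
               [60.0, 60.0], [61.0, 60.0], [62.0, 60.0], [63.0, 60.0],
               [64.0, 60.0], [65.0, 60.0], [66.0, 60.0]]
        t = make_table(np.vstack([[a], others, maj]), [1] * 5 + [0] * 10)
        r = rs.adasyn(t, k=3, seed=2)
        syn = r.synthetic_rows.drop(columns="label").to_numpy()
        assert len(syn) == 5
        for s in syn:
            # s = u * b for one of the other minority points b
            residual = min(abs(s[0] * b[1] - s[1] * b[0]) for b in others)
            assert residual < 1e-9
            assert np.linalg.norm(s) <= np.linalg.norm(others, axis=1).max()

    def test_balance_within_tolerance(self, training_table):
        r = rs.adasyn(training_table, seed=3)
        counts = r.table.label.value_counts()
        assert abs(counts[1] / counts[0] - 1.0) <= 0.05

    def test_quota_distribution_matches_hand_computation(self):
        """10-point configuration with quotas computable by hand."""
        # minority A at origin surrounded by 3 majority; B,C far with
        # minority-only neighbourhoods
        pts = np.array([
            [0.0, 0.0],      # A (minority)
            [30.0, 0.0],     # B (minority)
            [30.2, 0.0],     # C (minority)
            [30.1, 0.1],     # D (minority)
            [0.3, 0.0], [0.0, 0.3], [-0.3, 0.0],   # majority around A
            [60.0, 60.0], [61.0, 60.0], [62.0, 60.0],  # distant majority
        ])
        y = [1, 1, 1, 1, 0, 0, 0, 0, 0, 0]
        t = make_table(pts, y)
        # k=3: r_A = 1.0, r_B = r_C = r_D = 0 -> A takes the whole quota
        r = rs.adasyn(t, k=3, seed=0)
        syn = r.synthetic_rows.drop(columns="label").to_numpy()
        assert len(syn) == 2  # 6 majority - 4 minority
        # synthetic points emanate from A toward its minority neighbours
        for s in syn:
            assert np.linalg.norm(s) <= np.linalg.norm([30.2, 0.1]) + 1e-9


class TestCleaning:
    def test_interleaved_pair_is_single_link(self):
        pts = [[0.0, 0.0], [0.1, 0.0], [5.0, 0.0], [6.0, 0.0], [7.0, 0.0]]
        t = make_table(pts, [1, 0, 0, 0, 0])
        links = rs.tomek_links(t)
        assert links == [(0, 1)]
        cleaned = rs.remove_majority_of_links(t)
        assert len(cleaned) == 4 and 1 not in cleaned.index

    def test_separated_clusters_no_links(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 0.1, size=(10, 2))
        b = rng.normal(10, 0.1, size=(10, 2))
        t = make_table(np.vstack([a, b]), [1] * 10 + [0] * 10)
        assert rs.tomek_links(t) == []
        r = rs.smote_tomek(t, k=3, seed=1)
        s = rs.smote(t, k=3, seed=1)
        assert r.table.equals(s.table)  # no links: composition is identity

    def test_links_match_bruteforce_mutual_nn(self, rng):
        x = rng.normal(size=(40, 3))
        y = rng.integers(0, 2, size=40)
        if y.sum() in (0, 40):
            y[0] = 1 - y[0]
        t = make_table(x, y)
        got = rs.tomek_links(t)
        # O(n^2) oracle
        z = (x - x.mean(0)) / x.std(0)
        d = np.linalg.norm(z[:, None] - z[None, :], axis=2)
        np.fill_diagonal(d, np.inf)
        nn = d.argmin(axis=1)
        want = [(a, int(nn[a])) for a in range(40)
                if a < nn[a] and nn[nn[a]] == a and y[a] != y[nn[a]]]
        assert got == want

    def test_enn_homogeneous_clusters_untouched(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 0.2, size=(12, 2))
        b = rng.normal(8, 0.2, size=(15, 2))
        t = make_table(np.vstack([a, b]), [1] * 12 + [0] * 15)
        assert rs.enn_clean(t, k=3).equals(t)

    def test_enn_removes_invading_majority_point(self):
        """12-point configuration: one majority point deep inside the
        minority cluster is exactly what k=3 ENN removes."""
        minority = [[0.0, 0.0], [0.2, 0.0], [0.0, 0.2], [0.2, 0.2],
                    [0.1, 0.1], [0.0, 0.1]]
        invader = [[0.1, 0.05]]
        majority = [[10.0, 10.0], [10.2, 10.0], [10.0, 10.2],
                    [10.2, 10.2], [10.1, 10.1], [10.0, 10.1]]
        t = make_table(np.vstack([minority, invader, majority]),
                       [1] * 6 + [0] * 7)
        cleaned = rs.enn_clean(t, k=3)
        assert len(cleaned) == 12
        assert 6 not in cleaned.index  # the invader's row
        assert (cleaned.label == 1).sum() == 6  # minority retained

    def test_enn_output_never_grows(self, training_table):
        t = training_table.iloc[:300]
        assert len(rs.enn_clean(t, k=3)) <= len(t)

    def test_smote_enn_shrinks_on_overlap(self):
        t = generate_feature_cohort(200, 0.2, 4, class_shift=0.5, seed=8)
        s = rs.smote(t, seed=2)
        se = rs.smote_enn(t, seed=2)
        assert len(se.table) < len(s.table)
        # output rows are a subset of the SMOTE table
        merged = se.table.merge(s.table, how="inner")
        assert len(merged) == len(se.table)


class TestClipping:
    def test_clamps_out_of_range_and_identity(self):
        orig = make_table([[0.0, 0.0], [1.0, 1.0], [0.5, 0.2], [0.1, 0.9]],
                          [0, 0, 1, 1])
        syn = pd.DataFrame({"f0": [2.0, 0.5], "f1": [-1.0, 0.5],
                            "label": [1, 1]})
        table = pd.concat([orig, syn], ignore_index=True)
        r = rs.ResamplingResult(
            table=table, technique="SMOTE",
            origin=pd.Series(["original"] * 4 + ["synthetic"] * 2),
            seed=0)
        clipped = rs.clip_to_original_range(r, orig)
        out = clipped.table
        assert out.loc[4, "f0"] == 1.0 and out.loc[4, "f1"] == 0.0
        assert out.loc[5, "f0"] == 0.5 and out.loc[5, "f1"] == 0.5
        assert out.iloc[:4].equals(orig)

    def test_full_table_range_equals_original(self, training_table):
        r = rs.resample(training_table, "SMOTE", seed=11)
        feats = [c for c in r.table.columns if c != "label"]
        assert np.allclose(r.table[feats].min(), training_table[feats].min())
        assert np.allclose(r.table[feats].max(), training_table[feats].max())


class TestMatrix:
    def test_nine_by_five_gives_45(self):
        tables = {f"ds{i}": generate_feature_cohort(
            120, 0.15, 4, 2.0, seed=i) for i in range(9)}
        out = rs.build_resampled_matrix(tables, seed=0)
        assert len(out) == 45
        for (name, tech), res in out.items():
            if tech == "UNDERSAMPLING":
                assert len(res.table) < len(tables[name])
            else:
                assert len(res.table) > len(tables[name])

    def test_label_conservation(self, training_table):
        t = training_table.iloc[:150]
        for tech in rs.TECHNIQUES:
            res = rs.resample(t, tech, seed=4)
            orig = res.original_rows
            merged = orig.merge(t, how="inner")
            assert len(merged) == len(orig)
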