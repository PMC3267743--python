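"""Concordance correlation, CCR selection, and geNorm / NormFinder stability."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ctnorm import (
    CtMatrix,
    CtNormError,
    DegenerateInputError,
    DetectionConfig,
    NoFullyDetectedGenesError,
    SampleAnnotation,
    ccc,
    ccr_select,
    genorm_select,
    normfinder_select,
    normalize_by_genes,
    restricted_sample_means,
    simulate_titration,
    SimulationConfig,
)
from .conftest import random_ct_matrix


def ccc_oracle(x, y):
    """Brute-force Lin's coefficient straight from the defining moments."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    sxy = sum((a - x.mean()) * (b - y.mean()) for a, b in zip(x, y)) / n
    sx2 = sum((a - x.mean()) ** 2 for a in x) / n
    sy2 = sum((b - y.mean()) ** 2 for b in y) / n
    return 2 * sxy / (sx2 + sy2 + (x.mean() - y.mean()) ** 2)


class TestCCC:
    def test_hand_case(self):
        assert ccc([1, 2, 3], [2, 3, 4]).rho_c == pytest.approx(4 / 7, abs=1e-12)

    def test_perfect_concordance(self):
        r = ccc([1.0, 2.0, 5.0], [1.0, 2.0, 5.0])
        assert r.rho_c == pytest.approx(1.0)
        assert r.ci_low == pytest.approx(1.0) and r.ci_high == pytest.approx(1.0)

    def test_perfect_anticoncordance(self):
        assert ccc([1, 2, 3], [3, 2, 1]).rho_c == pytest.approx(-1.0)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = rng.integers(3, 51)
            x = rng.normal(0, rng.uniform(0.5, 3), n)
            y = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3), n)
            assert ccc(x, y).rho_c == pytest.approx(ccc_oracle(x, y), abs=1e-12)

    def test_symmetry_and_ci_ordering(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=20), rng.normal(size=20)
        a, b = ccc(x, y), ccc(y, x)
        assert a.rho_c == pytest.approx(b.rho_c, abs=1e-14)
        assert -1 <= a.ci_low <= a.rho_c <= a.ci_high <= 1

    def test_attenuated_pearson(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            x = rng.normal(size=15)
            y = 0.8 * x + rng.normal(0.5, 0.5, 15)
            r = ccc(x, y)
            assert abs(r.rho_c) <= abs(r.pearson_r) + 1e-12

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.integers(0, 10_000),
        st.floats(0.1, 5.0),
        st.floats(-10.0, 10.0),
    )
    def test_affine_invariance(self, seed, a, b):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=12), rng.normal(size=12)
        base = ccc(x, y).rho_c
        mapped = ccc(a * x + b, a * y + b).rho_c
        assert mapped == pytest.approx(base, abs=1e-9)

    def test_location_shift_strictly_decreases_ccc(self):
        x = np.random.default_rng(3).normal(size=30)
        scores = [ccc(x, x + c).rho_c for c in (0.0, 0.5, 1.0, 2.0, 4.0)]
        assert all(a > b for a, b in zip(scores, scores[1:]))

    def test_pearson_blind_to_the_same_shift(self):
        x = np.random.default_rng(4).normal(size=30)
        r = ccc(x, x + 2.0)
        assert r.pearson_r == pytest.approx(1.0)
        assert r.rho_c < 0.8

    def test_degenerate_identical_constants_error(self):
        with pytest.raises(DegenerateInputError):
            ccc([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])

    def test_length_mismatch_and_short_input(self):
        with pytest.raises(CtNormError):
            ccc([1, 2, 3], [1, 2])
        with pytest.raises(CtNormError):
            ccc([1, 2], [1, 2])


def _planted_matrix(seed: int, n_decoys: int = 30, n_samples: int = 8):
    """Decoy genes with private offsets/noise plus one gene tracking the mean."""
    rng = np.random.default_rng(seed)
    t = rng.uniform(0, 10, n_samples)  # shared per-sample technical shift
    rows = {}
    for i in range(n_decoys):
        rows[f"d{i}"] = 22 + rng.uniform(-4, 4) + t + rng.normal(0, 1.0, n_samples)
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.columns = [f"s{j}" for j in range(n_samples)]
    m = CtMatrix(frame)
    target = restricted_sample_means(m, DetectionConfig(40.0))
    frame.loc["planted"] = target.to_numpy() + rng.normal(0, 0.01, n_samples)
    return CtMatrix(frame), "planted"


class TestCCR:
    def test_planted_tracker_selected_first(self):
        for seed in range(10):
            m, planted = _planted_matrix(seed)
            sel = ccr_select(m, DetectionConfig(40.0))
            assert sel.normalizers[0] == planted
            # verify against an exhaustive single-gene CCC scan
            target = restricted_sample_means(m, DetectionConfig(40.0)).to_numpy()
            scan = {
                g: ccc(m.data.loc[g].to_numpy(), target).rho_c for g in m.gene_ids
            }
            assert max(scan, key=scan.get) == planted

    def test_small_gain_stops_after_one(self):
        # second near-ideal tracker exists but adds < epsilon concordance
        m, planted = _planted_matrix(42)
        frame = m.data.copy()
        target = restricted_sample_means(m, DetectionConfig(40.0))
        frame.loc["runnerup"] = target.to_numpy() + np.random.default_rng(1).normal(
            0, 0.05, m.shape[1]
        )
        sel = ccr_select(CtMatrix(frame), DetectionConfig(40.0), epsilon=0.01)
        assert sel.stop_reason == "converged"
        assert sel.normalizers == [planted]

    def test_fixed_count_overrides_epsilon(self):
        m, _ = _planted_matrix(7)
        sel = ccr_select(m, DetectionConfig(40.0), max_normalizers=2)
        assert len(sel.normalizers) == 2
        assert sel.stop_reason == "max_count"

    def test_trajectory_non_decreasing_in_convergence_mode(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            m = random_ct_matrix(rng, n_genes=15, n_samples=8)
            sel = ccr_select(m, DetectionConfig(40.0), epsilon=0.0)
            assert all(
                b >= a - 1e-12
                for a, b in zip(sel.score_trajectory, sel.score_trajectory[1:])
            )

    def test_selecting_all_reproduces_mean_of_candidates(self):
        rng = np.random.default_rng(9)
        m = random_ct_matrix(rng, n_genes=6, n_samples=8)
        cfg = DetectionConfig(40.0)
        sel = ccr_select(m, cfg, max_normalizers=6)
        assert sel.stop_reason in ("max_count", "exhausted")
        assert sorted(sel.normalizers) == sorted(sel.candidate_set)
        target = restricted_sample_means(m, cfg).to_numpy()
        full = ccc(m.data.loc[sel.candidate_set].mean(axis=0).to_numpy(), target)
        assert sel.score_trajectory[-1] == pytest.approx(full.rho_c, abs=1e-12)

    def test_no_candidates_at_threshold_errors_with_advice(self):
        m = CtMatrix(pd.DataFrame({"s1": [36.0], "s2": [37.0]}, index=["g1"]))
        with pytest.raises(NoFullyDetectedGenesError, match="threshold"):
            ccr_select(m, DetectionConfig(35.0))

    def test_selected_normalizers_feed_delta_ct(self):
        m, _ = _planted_matrix(11)
        sel = ccr_select(m, DetectionConfig(40.0), max_normalizers=2)
        r = normalize_by_genes(m, sel.normalizers)
        means = r.normalized.loc[sel.normalizers].mean(axis=0)
        np.testing.assert_allclose(means, means.iloc[0], atol=1e-9)


class TestGeNorm:
    def test_three_gene_hand_oracle(self):
        frame = pd.DataFrame(
            {"s0": [1.0, 2.0, 1.0], "s1": [2.0, 3.0, 3.0], "s2": [3.0, 4.0, 5.0]},
            index=["A", "B", "C"],
        )
        table = genorm_select(CtMatrix(frame))
        stab = dict(zip(table.gene_ids, table.stability))
        assert stab["A"] == pytest.approx(0.5)
        assert stab["B"] == pytest.approx(0.5)
        assert stab["C"] == pytest.approx(1.0)
        assert set(table.ranking[:2]) == {"A", "B"}
        assert table.ranking[2] == "C"

    def test_constant_offset_pair_survives(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            n_samples = 8
            base = rng.uniform(18, 28) + rng.normal(0, 0.3, n_samples)
            rows = {"p1": base, "p2": base + rng.uniform(0.5, 3)}
            for i in range(6):
                rows[f"n{i}"] = rng.uniform(18, 30) + rng.normal(0, 1.5, n_samples)
            frame = pd.DataFrame.from_dict(rows, orient="index")
            frame.columns = [f"s{j}" for j in range(n_samples)]
            frame = frame.clip(lower=1.0, upper=39.0)
            table = genorm_select(CtMatrix(frame))
            assert set(table.ranking[:2]) == {"p1", "p2"}

    def test_identical_rows_rank_in_input_order(self):
        frame = pd.DataFrame(
            np.tile([20.0, 22.0, 24.0], (4, 1)), index=list("wxyz"),
            columns=["s0", "s1", "s2"],
        )
        table = genorm_select(CtMatrix(frame))
        assert table.ranking == list("wxyz")

    def test_requires_three_fully_detected_genes(self):
        frame = pd.DataFrame({"s0": [20.0, 21.0], "s1": [22.0, 23.0]}, index=["a", "b"])
        with pytest.raises(CtNormError, match="at least 3"):
            genorm_select(CtMatrix(frame))


def normfinder_oracle(X: np.ndarray, group_of: np.ndarray) -> np.ndarray:
    """Loop-based recomputation of the implemented NormFinder formulas."""
    k, _ = X.shape
    groups = sorted(set(group_of))
    G = len(groups)
    Z = X - X.mean(axis=0, keepdims=True)
    n = {g: int(np.sum(group_of == g)) for g in groups}
    zbar = {(i, g): Z[i, group_of == g].mean() for i in range(k) for g in groups}
    s2 = {(i, g): Z[i, group_of == g].var(ddof=1) for i in range(k) for g in groups}
    sigma2 = {}
    for g in groups:
        total = sum(s2[i, g] for i in range(k)) * k / (k - 1)
        for i in range(k):
            v = (s2[i, g] - total / k**2) / (1 - 2 / k) if k >= 3 else s2[i, g]
            sigma2[i, g] = max(v, 0.0)
    d = {
        (i, g): zbar[i, g] - np.mean([zbar[i, h] for h in groups])
        for i in range(k)
        for g in groups
    }
    gamma2 = max(
        sum(d[i, g] ** 2 for i in range(k) for g in groups) / ((k - 1) * (G - 1))
        - sum(sigma2[i, g] / n[g] for i in range(k) for g in groups) / (k * G),
        0.0,
    )
    stab = []
    for i in range(k):
        acc = 0.0
        for g in groups:
            var_d = sigma2[i, g] / n[g]
            shrink = gamma2 / (gamma2 + var_d) if gamma2 + var_d > 0 else 0.0
            acc += abs(shrink * d[i, g]) + np.sqrt(shrink * var_d)
        stab.append(acc / G)
    return np.array(stab)


class TestNormFinder:
    def test_single_group_ranking_is_variance_ranking(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            m = random_ct_matrix(rng, n_genes=10, n_samples=7)
            table = normfinder_select(m)
            Z = m.data.to_numpy() - m.data.to_numpy().mean(axis=0, keepdims=True)
            variances = Z.var(axis=1, ddof=1)
            expected = [m.gene_ids[i] for i in np.argsort(variances, kind="stable")]
            assert table.ranking == expected

    def test_two_group_toy_matches_oracle(self):
        rng = np.random.default_rng(14)
        for _ in range(20):
            X = rng.uniform(18, 30, size=(6, 6)) + rng.normal(0, 1, size=(6, 6))
            frame = pd.DataFrame(
                X, index=[f"g{i}" for i in range(6)],
                columns=[f"s{j}" for j in range(6)],
            )
            ann = [
                SampleAnnotation(f"s{j}", "g1" if j < 3 else "g2") for j in range(6)
            ]
            table = normfinder_select(CtMatrix(frame), ann)
            group_of = np.array([0, 0, 0, 1, 1, 1])
            np.testing.assert_allclose(
                table.stability, normfinder_oracle(X, group_of), atol=1e-9
            )

    def test_between_group_shift_penalized(self):
        # gene A: constant within groups, 3-cycle jump between them;
        # gene B: identical group means, small within-group noise.
        rng = np.random.default_rng(15)
        n = 4
        rows = {
            "A": np.r_[np.full(n, 24.0), np.full(n, 27.0)],
            "B": 25.0 + rng.normal(0, 0.2, 2 * n),
        }
        for i in range(4):
            rows[f"f{i}"] = rng.uniform(20, 30) + rng.normal(0, 0.8, 2 * n)
        frame = pd.DataFrame.from_dict(rows, orient="index")
        frame.columns = [f"s{j}" for j in range(2 * n)]
        ann = [
            SampleAnnotation(f"s{j}", "early" if j < n else "late")
            for j in range(2 * n)
        ]
        table = normfinder_select(CtMatrix(frame), ann)
        stab = dict(zip(table.gene_ids, table.stability))
        assert stab["B"] < stab["A"]

    def test_identical_rows_equal_stability(self, two_group_annotations):
        frame = pd.DataFrame(
            np.vstack([np.tile([20, 21, 22, 23, 24, 25.0], (2, 1)),
                       [[24, 26, 22, 28, 21, 25.0]]]),
            index=["a", "b", "c"],
            columns=[x.sample_id for x in two_group_annotations],
        )
        table = normfinder_select(CtMatrix(frame), two_group_annotations)
        stab = dict(zip(table.gene_ids, table.stability))
        assert stab["a"] == pytest.approx(stab["b"], abs=1e-12)

    def test_group_of_one_errors_naming_group(self):
        frame = pd.DataFrame(
            np.random.default_rng(0).uniform(20, 30, (3, 3)),
            index=["a", "b", "c"], columns=["s0", "s1", "s2"],
        )
        ann = [
            SampleAnnotation("s0", "brain"),
            SampleAnnotation("s1", "brain"),
            SampleAnnotation("s2", "serum"),
        ]
        with pytest.raises(CtNormError, match="serum"):
            normfinder_select(CtMatrix(frame), ann)

    def test_unknown_sample_in_groups_errors(self, toy3):
        ann = [SampleAnnotation("s1", "brain")]
        with pytest.raises(CtNormError):
            normfinder_select(toy3, ann)


def test_selectors_run_on_flat_benchmark_shape():
    """Smoke test at the 500-pseudogene x 20-pseudosample benchmark shape."""
    from ctnorm import simulate_flat

    m = simulate_flat(500, 20, seed=0)
    assert m.shape == (500, 20) and not m.nd_mask.to_numpy().any()
    sel = ccr_select(m, DetectionConfig(40.0), max_normalizers=2)
    assert len(sel.normalizers) == 2
    table = normfinder_select(m)
    assert len(table.ranking) == 500
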