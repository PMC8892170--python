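"""XOR distance, normalization, exact and permutation nulls, pair scan."""

from itertools import combinations
from math import comb

import numpy as np
import pytest
from hypothesis import given, strategies as st

from cosegscan import (ComputationError, CosegConfig, InputValidationError,
                       exact_pvalue, normalized_distance, permutation_pvalue,
                       scan_pairs, xor_distance)
from cosegscan.coseg_engine import exact_pvalue_array, records_from_frame
from cosegscan.panel_io import BinaryGenotypeMatrix, VariantInfo


def _matrix(codes, ids=None):
    codes = np.asarray(codes, dtype=bool)
    ids = ids or [f"v{j}" for j in range(codes.shape[1])]
    variants = [VariantInfo(vid, "1", 100 + j, "A", "G",
                            minor_allele="G", mac=int(codes[:, j].sum()))
                for j, vid in enumerate(ids)]
    return BinaryGenotypeMatrix(
        [f"s{i}" for i in range(codes.shape[0])], ids, codes, "carrier",
        variants)


# ---------------------------------------------------------------------------
# xor_distance


@pytest.mark.parametrize("a,b,expected", [
    ((0, 1, 1, 0, 1), (0, 1, 1, 0, 1), 0),
    ((0, 1, 1, 0, 1), (1, 1, 0, 0, 1), 2),
    ((0, 0, 0, 0), (1, 1, 1, 1), 4),
])
def test_xor_distance_examples(a, b, expected):
    assert xor_distance(a, b) == expected


def test_xor_distance_length_mismatch_fatal():
    with pytest.raises(InputValidationError, match="length"):
        xor_distance([0, 1], [0, 1, 1])


@given(st.integers(0, 2**30 - 1))
def test_xor_distance_is_a_metric(state):
    """Symmetry, identity of indiscernibles, triangle inequality."""
    rng = np.random.default_rng(state)
    a, b, c = (rng.random((3, 50)) < rng.uniform(0.1, 0.9, (3, 1)))
    dab, dba = xor_distance(a, b), xor_distance(b, a)
    assert dab == dba
    assert xor_distance(a, a) == 0
    assert (dab == 0) == bool((a == b).all())
    assert dab <= xor_distance(a, c) + xor_distance(c, b)


# ---------------------------------------------------------------------------
# normalized_distance


@pytest.mark.parametrize("xor,ma,mb,ov,mode,expected", [
    (0, 3, 3, 3, "union", 0.0),          # identical non-empty carrier sets
    (2, 3, 3, 2, "union", 0.5),          # 2 / (3 + 3 - 2)
    (4, 2, 2, 0, "union", 1.0),          # disjoint -> maximal Jaccard
    (2, 3, 3, 2, "min_mac", 2 / 3),
    (2, 3, 3, 2, "max_mac", 2 / 3),
    (2, 3, 3, 2, "sum_mac", 2 / 6),
])
def test_normalized_distance_modes(xor, ma, mb, ov, mode, expected):
    assert normalized_distance(xor, ma, mb, ov, mode) == pytest.approx(expected)


def test_normalized_distance_validates_identity():
    with pytest.raises(InputValidationError, match="inconsistent"):
        normalized_distance(3, 3, 3, 2)


def test_normalized_distance_degenerate_pair():
    with pytest.raises(ComputationError, match="degenerate"):
        normalized_distance(0, 0, 0, 0, "union")


# ---------------------------------------------------------------------------
# exact p-value


def brute_force_pvalue(n, mac_a, mac_b, observed_xor):
    """Enumerate all carrier placements of B against a fixed A."""
    a = frozenset(range(mac_a))
    total = hits = 0
    for bset in combinations(range(n), mac_b):
        xor = mac_a + mac_b - 2 * len(a & frozenset(bset))
        total += 1
        hits += xor <= observed_xor
    return hits / total


def test_exact_pvalue_small_case_enumeration():
    # n=4, macs 2/2, xor 0: only the coincident placement, 1/C(4,2) = 1/6
    assert exact_pvalue(4, 2, 2, 0) == pytest.approx(1 / 6)
    assert exact_pvalue(4, 2, 2, 0) == pytest.approx(brute_force_pvalue(4, 2, 2, 0))


@pytest.mark.parametrize("n,ma,mb", [(4, 2, 2), (6, 3, 2), (8, 4, 5), (7, 1, 6)])
def test_exact_pvalue_matches_enumeration(n, ma, mb):
    lo = abs(ma - mb)
    hi = min(ma + mb, 2 * n - ma - mb)
    for xor in range(lo, hi + 1, 2):
        assert exact_pvalue(n, ma, mb, xor) == pytest.approx(
            brute_force_pvalue(n, ma, mb, xor))


def test_exact_pvalue_maximal_distance_is_one():
    # disjoint-feasible macs at maximal xor: nothing is more extreme
    assert exact_pvalue(10, 3, 4, 7) == pytest.approx(1.0)


def test_exact_pvalue_perfect_cosegregation_is_point_mass():
    p = exact_pvalue(1000, 50, 50, 0)
    assert p == pytest.approx(1 / comb(1000, 50), rel=1e-9)
    assert p < 1e-20


def test_exact_pvalue_monotone_in_xor():
    n, ma, mb = 200, 30, 40
    xs = range(abs(ma - mb), min(ma + mb, 2 * n - ma - mb) + 1, 2)
    ps = [exact_pvalue(n, ma, mb, x) for x in xs]
    assert all(p1 <= p2 + 1e-15 for p1, p2 in zip(ps, ps[1:]))
    assert all(0 < p <= 1 for p in ps)


@pytest.mark.parametrize("n,ma,mb,xor", [
    (4, 2, 2, 1),    # parity violation
    (4, 2, 2, 6),    # out of range
    (4, 0, 2, 0),    # empty carrier set
])
def test_exact_pvalue_infeasible_inputs_fatal(n, ma, mb, xor):
    with pytest.raises(InputValidationError):
        exact_pvalue(n, ma, mb, xor)


def test_exact_pvalue_array_matches_scalar():
    rng = np.random.default_rng(3)
    n = 100
    ma = rng.integers(1, n, 20)
    mb = rng.integers(1, n, 20)
    a = np.zeros((20, n), dtype=bool)
    b = np.zeros((20, n), dtype=bool)
    for i in range(20):
        a[i, rng.choice(n, ma[i], replace=False)] = True
        b[i, rng.choice(n, mb[i], replace=False)] = True
    xor = (a != b).sum(axis=1)
    vec = exact_pvalue_array(n, ma, mb, xor)
    scal = [exact_pvalue(n, int(ma[i]), int(mb[i]), int(xor[i]))
            for i in range(20)]
    assert vec == pytest.approx(scal)


# ---------------------------------------------------------------------------
# permutation p-value


def test_permutation_pvalue_is_seeded_and_bounded():
    rng = np.random.default_rng(5)
    a = rng.random(100) < 0.3
    b = rng.random(100) < 0.3
    p1 = permutation_pvalue(a, b, 500, seed=42)
    p2 = permutation_pvalue(a, b, 500, seed=42)
    assert p1 == p2
    assert 1 / 501 <= p1 <= 1.0
    # identical vectors: permutations can never beat xor = 0 strictly
    p_id = permutation_pvalue(a, a, 500, seed=1)
    assert p_id >= 1 / 501


def test_permutation_agrees_with_exact_on_enumerable_case():
    a = np.array([1, 1, 0, 0], dtype=bool)
    b = np.array([1, 1, 0, 0], dtype=bool)
    p_exact = exact_pvalue(4, 2, 2, 0)
    p_perm = permutation_pvalue(a, b, 100_000, seed=0)
    se = np.sqrt(p_exact * (1 - p_exact) / 100_000)
    assert abs(p_perm - p_exact) < 3 * se + 1 / 100_001


# ---------------------------------------------------------------------------
# scan_pairs


def test_scan_cardinality_one_rsnp_ten_markers():
    rng = np.random.default_rng(0)
    codes = rng.random((50, 11)) < 0.3
    codes[:, 0] = rng.random(50) < 0.4
    m = _matrix(codes)
    frame = scan_pairs(m, ["v0"], [f"v{j}" for j in range(1, 11)])
    assert len(frame) == 10
    recs = records_from_frame(frame)
    assert len(recs) == 10 and recs[0].rsnp_id == "v0"


def test_planted_perfect_pair_has_zero_distance_and_smallest_p():
    rng = np.random.default_rng(1)
    n = 500
    codes = rng.random((n, 52)) < rng.uniform(0.05, 0.4, 52)
    a = np.zeros(n, dtype=bool)
    a[rng.choice(n, 50, replace=False)] = True
    codes[:, 0] = a
    codes[:, 1] = a  # perfect-LD copy
    m = _matrix(codes)
    frame = scan_pairs(m, ["v0"], [f"v{j}" for j in range(1, 52)])
    top = frame.iloc[0]  # sorted by p within rSNP
    assert top.marker_id == "v1"
    assert top.normalized_distance == 0.0
    assert top.xor_distance == 0
    assert (frame.p_value[frame.marker_id != "v1"] > top.p_value).all()
    assert top.cosegregating


def test_calling_rule_is_p_below_alpha():
    rng = np.random.default_rng(2)
    codes = rng.random((200, 40)) < 0.2
    m = _matrix(codes)
    cfg = CosegConfig(alpha=0.01)
    frame = scan_pairs(m, ["v0", "v1"], [f"v{j}" for j in range(2, 40)], cfg)
    assert (frame.cosegregating == (frame.p_value < 0.01)).all()


def test_monomorphic_columns_are_excluded_with_reason():
    codes = np.zeros((20, 3), dtype=bool)
    codes[:5, 0] = True
    codes[:, 2] = True  # all-ones column
    m = _matrix(codes)
    frame = scan_pairs(m, ["v0"], ["v1", "v2"])
    assert len(frame) == 0 or set(frame.marker_id) == set()
    reasons = {mid: why for _, mid, why in frame.attrs["excluded"]}
    assert "v1" in reasons and "v2" in reasons


def test_empty_rsnp_or_marker_set_fatal():
    m = _matrix(np.ones((4, 2), dtype=bool) ^ np.eye(4, 2, dtype=bool))
    with pytest.raises(InputValidationError, match="empty"):
        scan_pairs(m, [], ["v1"])
    with pytest.raises(InputValidationError, match="empty"):
        scan_pairs(m, ["v0"], [])


def test_chunked_scan_equals_unchunked():
    rng = np.random.default_rng(4)
    codes = rng.random((100, 30)) < 0.3
    m = _matrix(codes)
    rsnps, markers = ["v0", "v1"], [f"v{j}" for j in range(2, 30)]
    f1 = scan_pairs(m, rsnps, markers, CosegConfig(chunk_size=7))
    f2 = scan_pairs(m, rsnps, markers, CosegConfig())
    assert f1.drop(columns=[]).equals(f2)


def test_benjamini_hochberg_calls_are_subset_of_raw():
    rng = np.random.default_rng(6)
    codes = rng.random((300, 101)) < 0.2
    a = np.zeros(300, dtype=bool)
    a[:40] = True
    codes[:, 0] = a
    codes[:, 1] = a
    m = _matrix(codes)
    markers = [f"v{j}" for j in range(1, 101)]
    raw = scan_pairs(m, ["v0"], markers, CosegConfig(multiple_testing="none"))
    bh = scan_pairs(m, ["v0"], markers,
                    CosegConfig(multiple_testing="benjamini_hochberg"))
    raw_called = set(raw[raw.cosegregating].marker_id)
    bh_called = set(bh[bh.cosegregating].marker_id)
    assert bh_called <= raw_called
    assert "v1" in bh_called  # the planted copy survives correction


def test_permutation_null_model_scan_agrees_with_exact():
    rng = np.random.default_rng(8)
    codes = rng.random((150, 6)) < 0.3
    m = _matrix(codes)
    markers = [f"v{j}" for j in range(1, 6)]
    exact = scan_pairs(m, ["v0"], markers)
    perm = scan_pairs(m, ["v0"], markers,
                      CosegConfig(null_model="permutation",
                                  n_permutations=2000, seed=9))
    merged = exact.merge(perm, on="marker_id", suffixes=("_e", "_p"))
    se = np.sqrt(merged.p_value_e * (1 - merged.p_value_e) / 2000)
    assert (abs(merged.p_value_p - merged.p_value_e)
            <= 3 * se + 1 / 2001).all()


# ---------------------------------------------------------------------------
# statistical properties


def test_null_calibration_is_conservative_but_nontrivial():
    """Empirical size of the exact test never exceeds the nominal level
    (upper 99% binomial bound) and is positive; the test is conservative
    because the overlap distribution is discrete."""
    from cosegscan import generate_null_pairs

    a, b = generate_null_pairs(5000, 500, (0.05, 0.5), seed=0)
    ma, mb = a.sum(1), b.sum(1)
    ok = (ma > 0) & (mb > 0)
    xor = (a != b).sum(1)
    p = exact_pvalue_array(500, ma[ok], mb[ok], xor[ok])
    for alpha in (0.01, 0.05):
        frac = (p < alpha).mean()
        upper = alpha + 2.576 * np.sqrt(alpha * (1 - alpha) / ok.sum())
        assert 0 < frac <= upper


def test_recovery_power_non_increasing_in_flip_probability():
    from cosegscan import generate_planted_pairs

    n = 500
    powers = []
    for eps in (0.0, 0.05, 0.1, 0.2, 0.4):
        a, b = generate_planted_pairs(100, n, eps, (0.05, 0.2), seed=17)
        ma, mb = a.sum(1), b.sum(1)
        ok = (mb > 0) & (mb < n)
        xor = (a != b).sum(1)
        p = exact_pvalue_array(n, ma[ok], mb[ok], xor[ok])
        powers.append((p < 0.01).mean())
    assert powers[0] == 1.0
    assert all(p1 >= p2 - 0.05 for p1, p2 in zip(powers, powers[1:]))
    assert powers[-1] < powers[0]
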