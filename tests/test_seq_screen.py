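"""TMM normalization and the two sequencing candidate screens."""

import numpy as np
import pandas as pd
import pytest

from mirnapanel import (CountMatrix, DataError, de_pvalues, normalize_counts,
                        select_method1, select_method2, tmm_factors)
from mirnapanel.containers import CandidateSet

IDS = [f"m{i:02d}" for i in range(1, 26)]


def _cm(counts: np.ndarray, groups: list[str]) -> CountMatrix:
    samples = [f"s{i}" for i in range(1, counts.shape[1] + 1)]
    return CountMatrix(
        pd.DataFrame(counts, index=IDS[: counts.shape[0]], columns=samples),
        pd.Series(groups, index=samples),
    )


# ---------------------------------------------------------------------- TMM

def test_identical_libraries_have_unit_factors():
    base = np.arange(10, 35)
    cm = _cm(np.column_stack([base, base]), ["healthy", "early"])
    nf = tmm_factors(cm, reference="s1")
    assert np.allclose(nf.factors, 1.0)


def test_doubled_library_gets_factor_two_and_equal_abundances():
    base = np.arange(10, 35)
    cm = _cm(np.column_stack([base, 2 * base]), ["healthy", "early"])
    nf = tmm_factors(cm, reference="s1")
    # pre-centering log2 factor of the doubled library is exactly 1
    # (every M value equals 1, so trimming is a no-op); after centering to
    # geometric mean 1 the pair is (1/sqrt2, sqrt2)
    assert nf.factors["s2"] / nf.factors["s1"] == pytest.approx(2.0, abs=1e-12)
    norm = normalize_counts(cm, nf)
    assert np.allclose(norm["s1"], norm["s2"])


def test_dominant_marker_is_removed_by_the_abundance_trim():
    """A single marker holding ~30% of one library's reads must be excluded
    from that library's trimmed mean; oracle = independent re-implementation
    of the doubly-trimmed weighted mean."""
    rng = np.random.default_rng(3)
    counts = rng.integers(50, 150, size=(25, 3))
    counts[4, 2] = int(counts[:, 2].sum() * 0.45)   # dominant in s3
    cm = _cm(counts, ["healthy", "early", "advanced"])
    nf = tmm_factors(cm, reference="s1")

    # oracle: sort-based trim of M (30% each tail) and A (5% each tail)
    yk, yr = counts[:, 2].astype(float), counts[:, 0].astype(float)
    nk, nr = yk.sum(), yr.sum()
    m = np.log2(yk / yr)
    a = 0.5 * np.log2(yk * yr)
    n = len(m)

    def keep_rank(v, trim):
        order = np.argsort(np.argsort(v, kind="stable"), kind="stable") + 1
        lo = np.floor(n * trim) + 1
        return (order >= lo) & (order <= n - np.floor(n * trim))

    kept = keep_rank(m, 0.30) & keep_rank(a, 0.05)
    assert not kept[4]                                  # dominant marker trimmed
    expected = 2.0 ** np.mean(m[kept])
    ratio = nf.factors["s3"] / nf.factors["s1"]   # centering cancels in the ratio
    assert ratio == pytest.approx(expected, rel=1e-10)


def test_tmm_matches_edger_oracle():
    """Frozen factors computed with edgeR::calcNormFactors (TMM,
    refColumn=1, logratioTrim=0.3, sumTrim=0.05); edgeR's library-relative
    factors were converted to this package's absolute convention via
    f * libsize, then centered to geometric mean 1."""
    counts = np.array([
        [114, 0, 135, 111], [139, 160, 100, 68], [608, 1032, 488, 944],
        [107, 60, 59, 97], [67, 32, 96, 128], [80, 0, 112, 45],
        [82, 44, 121, 73], [101, 49, 166, 145], [102, 106, 58, 125],
        [32, 163, 49, 55], [98, 0, 96, 94], [193, 160, 151, 118],
        [90, 31, 62, 107], [70, 83, 111, 48], [28, 208, 84, 53],
        [40, 0, 62, 59], [131, 66, 265, 61], [169, 143, 78, 159],
        [101, 175, 102, 161], [132, 143, 77, 133], [141, 0, 144, 91],
        [55, 113, 150, 49], [132, 68, 76, 83], [103, 34, 94, 126],
        [110, 132, 87, 52],
    ])
    expected = [1.013440825751, 0.920847754339, 1.056772025316, 1.013987177076]
    cm = _cm(counts, ["healthy", "healthy", "early", "advanced"])
    nf = tmm_factors(cm, reference="s1", weighted=True)
    assert np.allclose(nf.factors.to_numpy(), expected, atol=1e-9)


@pytest.mark.parametrize("seed", range(4))
def test_tmm_scale_equivariance_and_geometric_mean(seed):
    rng = np.random.default_rng(seed)
    counts = rng.integers(1, 500, size=(25, 4))
    cm = _cm(counts, ["healthy", "healthy", "early", "advanced"])
    nf = tmm_factors(cm, reference="s1")
    assert np.exp(np.mean(np.log(nf.factors))) == pytest.approx(1.0, abs=1e-12)

    scaled = counts.copy()
    scaled[:, 3] = scaled[:, 3] * 7
    cm2 = _cm(scaled, ["healthy", "healthy", "early", "advanced"])
    nf2 = tmm_factors(cm2, reference="s1")
    # scaling one library by c scales its factor by c relative to the rest
    ratio = (nf2.factors / nf.factors)
    assert (ratio["s4"] / ratio["s1"]) == pytest.approx(7.0, rel=1e-10)
    # and leaves normalized abundances unchanged up to the global recentering
    rescale = normalize_counts(cm2, nf2)["s4"] / normalize_counts(cm, nf)["s4"]
    assert np.allclose(rescale, 1.0 / ratio["s1"], rtol=1e-10)


def test_all_zero_sample_is_rejected_by_name():
    counts = np.column_stack([np.arange(1, 26), np.zeros(25, dtype=int)])
    cm = _cm(counts, ["healthy", "early"])
    with pytest.raises(DataError, match="s2"):
        tmm_factors(cm)


# ------------------------------------------------------------- DE p-values

def test_separated_marker_is_significant_at_6_vs_14():
    vals = pd.DataFrame(
        [np.concatenate([np.zeros(6), np.full(14, 50.0)])], index=["m01"],
        columns=[f"s{i}" for i in range(1, 21)],
    )
    groups = pd.Series(["healthy"] * 6 + ["early"] * 14, index=vals.columns)
    p = de_pvalues(vals, groups)
    assert p["m01"] < 0.01


def test_constant_marker_gets_p_one():
    vals = pd.DataFrame([np.full(10, 7.0)], index=["m01"],
                        columns=[f"s{i}" for i in range(10)])
    groups = pd.Series(["healthy"] * 5 + ["early"] * 5, index=vals.columns)
    assert de_pvalues(vals, groups)["m01"] == 1.0


def test_null_rejection_rate_is_calibrated():
    rng = np.random.default_rng(8)
    n_markers = 3000
    vals = pd.DataFrame(rng.normal(size=(n_markers, 24)) ** 2 + 1,
                        index=[f"g{i}" for i in range(n_markers)],
                        columns=[f"s{i}" for i in range(24)])
    groups = pd.Series(["healthy"] * 12 + ["advanced"] * 12, index=vals.columns)
    p = de_pvalues(vals, groups)
    rate = (p < 0.01).mean()
    # 3 sigma band around 1% over 3000 markers
    assert rate == pytest.approx(0.01, abs=3 * np.sqrt(0.01 * 0.99 / n_markers) + 0.003)


# --------------------------------------------------------------- selectors

def test_method1_union_matches_brute_force(small_counts):
    from mirnapanel.seq_screen import _top_k
    cm0 = small_counts
    cm1 = CountMatrix(cm0.counts + 1, cm0.groups, "1mm")   # perturbed re-mapping
    cs = select_method1(cm0, cm1, k=5)
    expected: set[str] = set()
    for cm in (cm0, cm1):
        norm = normalize_counts(cm, tmm_factors(cm))
        p = de_pvalues(norm, cm.groups)
        expected |= set(_top_k(p, norm, cm.groups, 5))
    assert set(cs.ids) == expected
    assert 5 <= len(cs) <= 10


def test_method1_identical_tables_give_exactly_k(small_counts):
    cs = select_method1(small_counts,
                        CountMatrix(small_counts.counts.copy(),
                                    small_counts.groups, "1mm"), k=4)
    assert len(cs) == 4


def test_method1_k_capped_with_warning(small_counts):
    with pytest.warns(UserWarning, match="capped"):
        cs = select_method1(small_counts,
                            CountMatrix(small_counts.counts.copy(),
                                        small_counts.groups, "1mm"), k=99)
    assert len(cs) <= 20


def test_method2_selects_allornone_marker(small_counts):
    cs = select_method2(small_counts, p_threshold=0.05, min_zero_healthy=6)
    assert "m07" in cs
    assert all(p < 0.05 for p in cs.table["p_value"])


def test_method2_requires_zeros_in_healthy():
    rng = np.random.default_rng(1)
    counts = rng.integers(100, 1000, size=(25, 12))   # no zeros anywhere
    counts[0, 6:] *= 50                               # hugely significant...
    cm = _cm(counts, ["healthy"] * 6 + ["early"] * 6)
    cs = select_method2(cm, p_threshold=0.05, min_zero_healthy=1)
    assert "m01" not in cs                            # ...but never selected


def test_method2_all_zero_marker_not_selected():
    counts = np.vstack([np.zeros(12, dtype=int),
                        np.random.default_rng(0).integers(10, 100, size=(5, 12))])
    cm = _cm(counts, ["healthy"] * 6 + ["advanced"] * 6)
    cs = select_method2(cm, min_zero_healthy=6)
    assert "m01" not in cs


def test_method2_monotone_in_thresholds(small_counts):
    base = set(select_method2(small_counts, 0.01, 6).ids)
    looser_p = set(select_method2(small_counts, 0.10, 6).ids)
    looser_z = set(select_method2(small_counts, 0.01, 3).ids)
    assert base <= looser_p
    assert base <= looser_z


def test_method2_min_zero_exceeding_healthy_errors(small_counts):
    with pytest.raises(DataError, match="min_zero_healthy"):
        select_method2(small_counts, min_zero_healthy=7)


def test_candidate_union_provenance():
    a = CandidateSet(pd.DataFrame({"mirna_id": ["m1", "m2"], "provenance": "method1",
                                   "p_value": [0.001, 0.002]}))
    b = CandidateSet(pd.DataFrame({"mirna_id": ["m2", "m3"], "provenance": "method2",
                                   "p_value": [0.04, 0.01]}))
    u = CandidateSet.union(a, b)
    assert set(u.ids) == {"m1", "m2", "m3"}
    row = u.table.set_index("mirna_id").loc["m2"]
    assert row["provenance"] == "both"
    assert row["p_value"] == 0.002
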