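"""TMT normalization, differential expression, Fisher meta-analysis, yields."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from myomam.quant import (
    QuantTable,
    differential_expression,
    fisher_combine,
    median_normalize,
    meta_deregulated,
    percent_reduction,
    yield_abundance,
)
from myomam.quant import _flag


def make_table(intensities: np.ndarray, tissue="heart") -> QuantTable:
    samples = [f"{tissue}_{g}{i}" for g in ("young", "old") for i in range(3)]
    design = pd.DataFrame(
        {"sample": samples, "tissue": tissue, "group": ["young"] * 3 + ["old"] * 3}
    )
    ids = [f"P{i:04d}" for i in range(intensities.shape[0])]
    return QuantTable(pd.DataFrame(intensities, index=ids, columns=samples), design)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def test_median_normalize_equalizes_medians():
    rng = np.random.default_rng(0)
    base = np.exp(rng.normal(10, 1, (200, 6)))
    bias = np.array([0.5, 0.9, 1.0, 1.3, 2.0, 0.7])
    table = make_table(base * bias)
    normed = median_normalize(table)
    medians = normed.intensities.median(axis=0)
    assert np.allclose(medians, medians.iloc[0], rtol=1e-12)
    # target is the grand median of the pre-scaling sample medians
    pre = table.intensities.median(axis=0)
    assert medians.iloc[0] == pytest.approx(float(np.median(pre)), rel=1e-12)
    assert normed.normalized


def test_median_normalize_idempotent():
    rng = np.random.default_rng(1)
    table = make_table(np.exp(rng.normal(10, 1, (100, 6))))
    once = median_normalize(table)
    twice = median_normalize(once)
    assert np.allclose(once.intensities.to_numpy(), twice.intensities.to_numpy(),
                       rtol=1e-12)


def test_median_normalize_zero_median_names_sample():
    vals = np.ones((10, 6))
    vals[:, 2] = 0.0
    table = make_table(vals)
    with pytest.raises(ValueError, match="heart_young2"):
        median_normalize(table)


def test_quant_table_validation():
    rng = np.random.default_rng(2)
    vals = np.abs(rng.normal(1, 0.1, (5, 6)))
    samples = [f"heart_{g}{i}" for g in ("young", "old") for i in range(3)]
    design = pd.DataFrame(
        {"sample": samples, "tissue": "heart", "group": ["young"] * 3 + ["old"] * 3}
    )
    dup = pd.DataFrame(vals, index=["P1"] * 5, columns=samples)
    with pytest.raises(ValueError, match="duplicate"):
        QuantTable(dup, design)
    neg = pd.DataFrame(-vals, index=[f"P{i}" for i in range(5)], columns=samples)
    with pytest.raises(ValueError, match="non-negative"):
        QuantTable(neg, design)
    small_design = design.iloc[[0, 3, 4]]  # one young sample only
    with pytest.raises(ValueError, match=">=2 samples"):
        QuantTable(
            pd.DataFrame(vals[:, :3], index=[f"P{i}" for i in range(5)],
                         columns=list(small_design["sample"])),
            small_design,
        )


# ---------------------------------------------------------------------------
# deregulation rule
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "fc,p,expected",
    [
        (1.5, 0.01, "up"),
        (0.6, 0.01, "down"),
        (1.5, 0.2, "ns"),    # significant ratio, p too large
        (1.1, 0.001, "ns"),  # significant p, ratio inside the gate
        (1.2, 0.01, "ns"),   # boundary fc is not > 1.2
        (0.83, 0.01, "ns"),  # boundary fc is not < 0.83
        (1.21, 0.049, "up"),
        (0.82, 0.049, "down"),
        (1.5, 0.05, "ns"),   # boundary p is not < 0.05
    ],
)
def test_flag_rule(fc, p, expected):
    assert _flag(fc, p) == expected


def test_differential_expression_planted_and_null():
    rng = np.random.default_rng(3)
    n = 300
    base = np.exp(rng.normal(12, 1, n))
    vals = np.empty((n, 6))
    log2fc = np.zeros(n)
    log2fc[:30] = 1.0    # planted up (FC 2)
    log2fc[30:60] = -1.0  # planted down
    for j in range(6):
        fc = np.exp2(log2fc) if j >= 3 else 1.0
        vals[:, j] = base * fc * np.exp(rng.normal(0, 0.05, n))
    table = median_normalize(make_table(vals))
    res = {r.protein_id: r for r in differential_expression(table, "heart")}
    ids = list(table.intensities.index)
    up = [res[i].flag for i in ids[:30]]
    down = [res[i].flag for i in ids[30:60]]
    null = [res[i].flag for i in ids[60:]]
    assert np.mean([f == "up" for f in up]) >= 0.9
    assert np.mean([f == "down" for f in down]) >= 0.9
    assert np.mean([f != "ns" for f in null]) <= 0.05
    # fold change is mean(old)/mean(young) of the normalized table
    pid = ids[0]
    sub = table.intensities.loc[pid]
    expected_fc = sub.iloc[3:].mean() / sub.iloc[:3].mean()
    assert res[pid].fold_change == pytest.approx(expected_fc, rel=1e-12)
    assert res[pid].log2_fc == pytest.approx(math.log2(expected_fc), rel=1e-9)


def test_differential_expression_invariant_under_global_rescale():
    rng = np.random.default_rng(4)
    table = median_normalize(make_table(np.exp(rng.normal(10, 1, (100, 6)))))
    scaled = QuantTable(table.intensities * 1e3, table.design, normalized=True)
    r1 = differential_expression(table, "heart")
    r2 = differential_expression(scaled, "heart")
    for a, b in zip(r1, r2):
        assert a.fold_change == pytest.approx(b.fold_change, rel=1e-9)
        assert a.p_value == pytest.approx(b.p_value, rel=1e-9)


def test_differential_expression_excludes_zero_intensity():
    vals = np.full((5, 6), 100.0)
    vals[2, 4] = 0.0
    table = QuantTable(
        make_table(vals).intensities, make_table(vals).design, normalized=True
    )
    res = differential_expression(table, "heart")
    assert len(res) == 4
    assert "P0002" not in {r.protein_id for r in res}


def test_differential_expression_warns_unnormalized():
    rng = np.random.default_rng(5)
    table = make_table(np.exp(rng.normal(10, 1, (20, 6))))
    with pytest.warns(UserWarning, match="not median-normalized"):
        differential_expression(table, "heart")


def test_differential_expression_matches_scipy_welch():
    rng = np.random.default_rng(6)
    table = median_normalize(make_table(np.exp(rng.normal(10, 1, (50, 6)))))
    res = differential_expression(table, "heart")
    pid = res[10].protein_id
    row = table.intensities.loc[pid]
    t = stats.ttest_ind(
        np.log2(row.iloc[3:]), np.log2(row.iloc[:3]), equal_var=False
    )
    assert res[10].p_value == pytest.approx(float(t.pvalue), rel=1e-12)


# ---------------------------------------------------------------------------
# Fisher's method
# ---------------------------------------------------------------------------

def test_fisher_known_values():
    chi2, df, p = fisher_combine([0.05, 0.05])
    assert chi2 == pytest.approx(-4 * math.log(0.05), rel=1e-12)
    assert df == 4
    # closed form for df=4: P = (1 + x/2) * exp(-x/2)
    assert p == pytest.approx((1 + chi2 / 2) * math.exp(-chi2 / 2), rel=1e-10)
    assert p == pytest.approx(0.01744, abs=5e-5)

    chi2, df, p = fisher_combine([1.0, 1.0])
    assert chi2 == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


@settings(max_examples=60, deadline=None)
@given(st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=2, max_size=2))
def test_fisher_matches_closed_form_df4(ps):
    chi2, df, p = fisher_combine(ps)
    assert df == 4
    assert p == pytest.approx((1 + chi2 / 2) * math.exp(-chi2 / 2), rel=1e-9)


def test_fisher_single_p_identity():
    _, df, p = fisher_combine([0.2])
    assert df == 2
    assert p == pytest.approx(0.2, rel=1e-12)


def test_fisher_edge_cases():
    with pytest.raises(ValueError):
        fisher_combine([])
    with pytest.raises(ValueError):
        fisher_combine([0.5, 1.5])
    with pytest.raises(ValueError):
        fisher_combine([-0.1])
    with pytest.warns(UserWarning, match="floored"):
        chi2, df, p = fisher_combine([0.0, 0.5])
    assert np.isfinite(p)


# ---------------------------------------------------------------------------
# meta-analysis
# ---------------------------------------------------------------------------

def test_meta_concordant_and_opposed():
    from myomam.quant import DEResult

    heart = [
        DEResult("A", 1.5, math.log2(1.5), 0.01, "up"),
        DEResult("B", 1.5, math.log2(1.5), 0.01, "up"),
        DEResult("C", 0.6, math.log2(0.6), 0.01, "down"),
    ]
    ga = [
        DEResult("A", 1.4, math.log2(1.4), 0.02, "up"),
        DEResult("B", 1 / 1.5, math.log2(1 / 1.5), 0.01, "down"),
        DEResult("C", 0.7, math.log2(0.7), 0.02, "down"),
    ]
    meta = {m.protein_id: m for m in meta_deregulated(heart, ga)}
    assert meta["A"].meta_flag == "up"
    assert meta["A"].combined_fc == pytest.approx(math.sqrt(1.5 * 1.4), rel=1e-12)
    chi2, df, p = fisher_combine([0.01, 0.02])
    assert meta["A"].combined_p == pytest.approx(p, rel=1e-12)
    # opposed fold changes cancel to a geometric mean of 1 -> ns
    assert meta["B"].combined_fc == pytest.approx(1.0, rel=1e-12)
    assert meta["B"].meta_flag == "ns"
    assert meta["C"].meta_flag == "down"


def test_meta_empty_intersection_warns():
    from myomam.quant import DEResult

    heart = [DEResult("A", 1.5, math.log2(1.5), 0.01, "up")]
    ga = [DEResult("B", 1.5, math.log2(1.5), 0.01, "up")]
    with pytest.warns(UserWarning, match="no proteins shared"):
        assert meta_deregulated(heart, ga) == []


# ---------------------------------------------------------------------------
# yields
# ---------------------------------------------------------------------------

def test_yield_abundance_arithmetic():
    rec = yield_abundance(0.5, 2.0, 1.0)
    assert rec.abundance_mg_per_g == pytest.approx(1.0)
    with pytest.raises(ValueError):
        yield_abundance(0.5, 2.0, 0.0)


def test_percent_reduction():
    assert percent_reduction(1.0, 0.7) == pytest.approx(30.0)
    assert percent_reduction(2.0, 2.0) == pytest.approx(0.0)
    with pytest.raises(ValueError):
        percent_reduction(0.0, 1.0)
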