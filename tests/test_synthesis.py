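"""Synthesis ratio arithmetic, group comparisons, TSS correlation, report."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from mirslam import (group_compare, report, synthesis_ratio, top_expressed,
                     tss_correlation)
from mirslam.synthesis import rate_pca, standard_group_comparisons

COLS = ["sample", "condition", "unit", "read_count", "cpm", "t_coverage",
        "tc_count", "conversion_rate"]


def _profiles(rates: dict[str, tuple[float, float, float]]) -> pd.DataFrame:
    """One replicate per condition with the given (control, dmso, plab)
    conversion rates per unit."""
    rows = []
    for unit, (c, d, p) in rates.items():
        for cond, rate in (("control_no4su", c), ("dmso_4su", d),
                           ("plab_4su", p)):
            rows.append((f"{cond}_rep1", cond, unit, 100, 1000.0, 10000,
                         int(rate * 10000), rate))
    return pd.DataFrame(rows, columns=COLS)


@pytest.mark.parametrize("rates,expected", [
    ((0.0010, 0.0035, 0.0010), 0.0),   # drug back at background
    ((0.0010, 0.0035, 0.0035), 1.0),   # no suppression
    ((0.0010, 0.0035, 0.0020), 0.4),   # partial suppression
])
def test_ratio_arithmetic(rates, expected):
    out = synthesis_ratio(_profiles({"m": rates}), ["m"])
    assert out.loc[0, "ratio"] == pytest.approx(expected)
    assert out.loc[0, "bg_sub_dmso"] == pytest.approx(rates[1] - rates[0])


def test_ratio_requires_positive_background_subtracted_dmso():
    prof = _profiles({"m": (0.0020, 0.0010, 0.0030)})
    with pytest.raises(ValueError, match="labeling filter"):
        synthesis_ratio(prof, ["m"])


def test_pooled_aggregation_weights_by_depth():
    """With equal coverage per replicate the two aggregations agree; with
    unequal coverage the pooled rate shifts toward the deeper replicate."""
    rows = []
    for cond, rates, covs in (
            ("control_no4su", (0.001, 0.001), (10000, 10000)),
            ("dmso_4su", (0.002, 0.006), (10000, 30000)),
            ("plab_4su", (0.002, 0.002), (10000, 10000))):
        for i, (r, cov) in enumerate(zip(rates, covs), start=1):
            rows.append((f"{cond}_rep{i}", cond, "m", 100, 1000.0, cov,
                         int(r * cov), r))
    prof = pd.DataFrame(rows, columns=COLS)
    by_mean = synthesis_ratio(prof, ["m"]).loc[0]
    by_pool = synthesis_ratio(prof, ["m"], aggregate="pooled").loc[0]
    assert by_mean["mean_rate_dmso"] == pytest.approx(0.004)
    assert by_pool["mean_rate_dmso"] == pytest.approx(0.005)  # 200/40000
    assert by_mean["mean_rate_control"] == by_pool["mean_rate_control"]


def test_standard_comparisons_bh_option(small_study):
    _cfg, res = small_study
    context = set(res.membership.loc[res.membership["in_context_set"], "unit"])
    sub = res.results[res.results["unit"].isin(context)]
    adj = standard_group_comparisons(sub, adjust=True)
    assert "p_adj" in adj.columns
    assert (adj["p_adj"] >= adj["p_value"] - 1e-15).all()


def test_unknown_unit_rejected():
    with pytest.raises(KeyError):
        synthesis_ratio(_profiles({"m": (0.001, 0.002, 0.002)}), ["zzz"])


@given(st.floats(min_value=-0.01, max_value=0.01),
       st.floats(min_value=0.0005, max_value=0.01),
       st.floats(min_value=0.0, max_value=0.01))
def test_ratio_invariant_under_common_shift(shift, bg_d, bg_p):
    """Adding the same constant to all three condition means (background
    included) cancels in both subtractions and leaves the ratio unchanged."""
    base = 0.02  # keep all shifted rates positive
    a = synthesis_ratio(_profiles({"m": (base, base + bg_d, base + bg_p)}),
                        ["m"]).loc[0, "ratio"]
    b = synthesis_ratio(
        _profiles({"m": (base + shift, base + shift + bg_d,
                         base + shift + bg_p)}), ["m"]).loc[0, "ratio"]
    assert a == pytest.approx(b, rel=1e-9, abs=1e-12)


def _results(ratios_by_group: dict[str, list[float]],
             grouping: str = "location_class") -> pd.DataFrame:
    rows = []
    for grp, ratios in ratios_by_group.items():
        for i, r in enumerate(ratios):
            rows.append({"unit": f"{grp}{i}", "ratio": r, grouping: grp,
                         "tss_distance_nt": 100 * (i + 1)})
    return pd.DataFrame(rows)


def test_group_compare_identical_groups():
    res = _results({"intronic": [0.1, 0.5, 0.9], "exonic": [0.1, 0.5, 0.9]})
    cmp_ = group_compare(res, "location_class")
    assert cmp_.statistic == pytest.approx(0.0)
    assert cmp_.p_value == pytest.approx(1.0)


def test_group_compare_separated_groups():
    res = _results({"intronic": [0.1] * 4, "exonic": [0.9] * 4})
    cmp_ = group_compare(res, "location_class")
    assert cmp_.p_value < 0.01
    assert cmp_.n == (4, 4)


def test_group_compare_percentile_summaries():
    res = _results({"a": list(np.linspace(0, 1, 11)), "b": [0.5] * 5})
    cmp_ = group_compare(res, "location_class", groups=("a", "b"))
    assert cmp_.medians[0] == pytest.approx(0.5)
    assert cmp_.p10[0] == pytest.approx(0.1)
    assert cmp_.p90[0] == pytest.approx(0.9)


def test_group_compare_mannwhitney_flag():
    res = _results({"intronic": [0.1, 0.2, 0.3, 0.4],
                    "exonic": [0.6, 0.7, 0.8, 0.9]})
    cmp_ = group_compare(res, "location_class", method="mannwhitney")
    assert cmp_.method == "mannwhitney" and cmp_.p_value < 0.05


def test_small_group_skipped_with_warning():
    res = _results({"intronic": [0.1, 0.2, 0.3], "exonic": [0.5]})
    with pytest.warns(UserWarning, match="fewer than 2"):
        assert group_compare(res, "location_class") is None


def test_tss_correlation_cases():
    # strictly increasing ratio with distance: perfect rank correlation
    res = pd.DataFrame({"ratio": [0.1, 0.2, 0.5, 0.9],
                        "tss_distance_nt": [100, 1000, 5000, 20000]})
    rho, _p = tss_correlation(res)
    assert rho == pytest.approx(1.0)
    # constant ratios carry no rank information
    res["ratio"] = 0.5
    assert tss_correlation(res) == (0.0, 1.0)
    with pytest.raises(ValueError):
        tss_correlation(res.iloc[:2])


def test_top_expressed_ordering():
    rng = np.random.default_rng(1)
    units = [f"m{i}" for i in range(40)]
    cpms = rng.uniform(100, 10000, size=40)
    prof = pd.DataFrame({
        "sample": "dmso_4su_rep1", "condition": "dmso_4su", "unit": units,
        "read_count": 1, "cpm": cpms, "t_coverage": 100, "tc_count": 1,
        "conversion_rate": 0.01})
    results = pd.DataFrame({
        "unit": units, "ratio": rng.uniform(0, 1, 40),
        "location_class": rng.choice(["intronic", "exonic"], 40)})
    top = top_expressed(results, prof, n=25)
    assert len(top) == 25
    assert set(top["mean_cpm"]) == set(np.sort(cpms)[-25:])
    for _loc, grp in top.groupby("location_class"):
        assert (grp["mean_cpm"].diff().dropna() <= 0).all()


def test_report_bundle(tmp_path, small_study):
    _cfg, res = small_study
    paths = report(res.results, res.comparisons, res.profiles,
                   tmp_path / "r1", plots=True)
    for p in paths.values():
        assert p.exists()
    # determinism: rerunning writes byte-identical tables
    paths2 = report(res.results, res.comparisons, res.profiles, tmp_path / "r2")
    for key in ("ratios", "comparisons", "top_expressed", "rate_matrix", "pca"):
        assert paths[key].read_bytes() == paths2[key].read_bytes()


def test_report_with_empty_final_set(tmp_path, small_study):
    _cfg, res = small_study
    empty = res.results.iloc[0:0]
    paths = report(empty, pd.DataFrame(), res.profiles, tmp_path)
    ratios = pd.read_csv(paths["ratios"], sep="\t")
    assert ratios.empty and list(ratios.columns)


def test_pca_is_centered_sample_map(small_study):
    _cfg, res = small_study
    mat = res.profiles.pivot_table(index="unit", columns="sample",
                                   values="conversion_rate")
    pcs = rate_pca(mat)
    assert pcs.shape == (mat.shape[1], 3)
    assert sum(pcs.attrs["explained_variance_ratio"]) <= 1.0 + 1e-9


def test_standard_comparisons_cover_context_groupings(small_study):
    _cfg, res = small_study
    got = set(res.comparisons["grouping"])
    assert got <= {"location_class", "gene_class", "motif_CNNC",
                   "motif_basal_UG", "motif_apical_UGU"}
    assert len(res.comparisons)  # at least one grouping had two viable groups
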