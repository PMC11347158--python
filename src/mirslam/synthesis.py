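"""Background-subtracted synthesis ratio and genomic-context analyses.

For each miRNA passing the Final filters, the no-4SU control conversion rate
is subtracted from the 4SU+vehicle and 4SU+drug rates, and the synthesis
ratio ``(drug - control) / (vehicle - control)`` is computed from
replicate-mean rates: 1 means unchanged synthesis under the drug, 0 means
fully suppressed.  Ratios are then compared between genomic-context groups
(intronic/exonic, lncRNA/protein-coding host, Microprocessor cis-motif
presence), correlated with distance from the transcription start site, and
summarized into report tables and optional figures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .config import CONTROL, DMSO, PLAB
from .filters import condition_mean_rates


def synthesis_ratio(profiles: pd.DataFrame, final_units: Iterable[str],
                    annotation: Optional[pd.DataFrame] = None,
                    control: str = CONTROL, vehicle: str = DMSO,
                    drug: str = PLAB,
                    aggregate: str = "mean_of_rates") -> pd.DataFrame:
    """Per-unit condition means, background-subtracted rates and the ratio.

    Replicates are aggregated as mean-of-rates (each replicate weighted
    equally); ``aggregate="pooled"`` switches to the pooled-count rate
    (summed conversions over summed coverage), which weights replicates by
    depth.  Upstream filters guarantee ``bg_sub_dmso > 0`` and
    ``bg_sub_plab >= 0`` for Final-dataset units; a supplied unit violating
    the former is a filter-contract violation and raises.  Ratios are not
    clamped: values above 1 (apparent synthesis increase) are reported
    as-is.
    """
    if aggregate == "mean_of_rates":
        means = condition_mean_rates(profiles)
    elif aggregate == "pooled":
        pooled = profiles.groupby(["unit", "condition"])[
            ["tc_count", "t_coverage"]].sum()
        means = (pooled["tc_count"] / pooled["t_coverage"].replace(0, np.nan)
                 ).fillna(0.0).unstack("condition")
    else:
        raise ValueError(f"unknown aggregate {aggregate!r}")
    rows = []
    for u in sorted(final_units):
        if u not in means.index:
            raise KeyError(f"unit {u!r} absent from profiles")
        m_c, m_d, m_p = (float(means.loc[u, control]),
                         float(means.loc[u, vehicle]),
                         float(means.loc[u, drug]))
        bg_d = m_d - m_c
        bg_p = m_p - m_c
        if bg_d <= 0:
            raise ValueError(
                f"unit {u!r}: background-subtracted {vehicle} rate is "
                f"{bg_d:.3g} <= 0; upstream labeling filter was not applied")
        rows.append({"unit": u, "mean_rate_control": m_c,
                     "mean_rate_dmso": m_d, "mean_rate_plab": m_p,
                     "bg_sub_dmso": bg_d, "bg_sub_plab": bg_p,
                     "ratio": bg_p / bg_d})
    out = pd.DataFrame(rows, columns=["unit", "mean_rate_control",
                                      "mean_rate_dmso", "mean_rate_plab",
                                      "bg_sub_dmso", "bg_sub_plab", "ratio"])
    if annotation is not None and len(out):
        out = annotate_units(out, annotation)
    return out


def annotate_units(results: pd.DataFrame, annotation: pd.DataFrame
                   ) -> pd.DataFrame:
    """Attach annotation columns to a unit-keyed table; collapsed units take
    the first member's annotation row."""
    ann = annotation.set_index("mirna_id") \
        if "mirna_id" in annotation.columns else annotation
    first = results["unit"].map(lambda u: u.split("|")[0])
    joined = ann.reindex(first).reset_index(drop=True)
    joined.index = results.index
    return pd.concat([results, joined], axis=1)


@dataclass
class GroupComparison:
    """Two-group comparison of synthesis ratios."""

    grouping: str
    groups: tuple[str, str]
    n: tuple[int, int]
    medians: tuple[float, float]
    p10: tuple[float, float]
    p90: tuple[float, float]
    statistic: float
    p_value: float
    method: str

    def as_row(self) -> dict:
        return {
            "grouping": self.grouping,
            "group_a": self.groups[0], "group_b": self.groups[1],
            "n_a": self.n[0], "n_b": self.n[1],
            "median_a": self.medians[0], "median_b": self.medians[1],
            "p10_a": self.p10[0], "p10_b": self.p10[1],
            "p90_a": self.p90[0], "p90_b": self.p90[1],
            "statistic": self.statistic, "p_value": self.p_value,
            "method": self.method,
        }


def group_compare(results: pd.DataFrame, grouping: str,
                  groups: Optional[tuple[str, str]] = None,
                  method: str = "welch") -> Optional[GroupComparison]:
    """Compare synthesis ratios between two groups of a context variable.

    ``grouping`` names a column of the annotated results (e.g.
    ``location_class`` or a 0/1 motif flag).  The default test is Welch's
    two-sided t; ``method="mannwhitney"`` switches to the rank test, useful
    because ratio distributions are skewed.  Groups with fewer than 2 units
    skip the comparison with a warning.
    """
    sub = results.dropna(subset=[grouping, "ratio"])
    if groups is None:
        values = sub[grouping].value_counts().index.tolist()
        if len(values) < 2:
            warnings.warn(f"{grouping}: fewer than 2 non-empty groups")
            return None
        groups = tuple(sorted(map(str, values[:2])))  # two largest groups
    a = sub.loc[sub[grouping].astype(str) == groups[0], "ratio"].to_numpy()
    b = sub.loc[sub[grouping].astype(str) == groups[1], "ratio"].to_numpy()
    if len(a) < 2 or len(b) < 2:
        warnings.warn(f"{grouping}: a group has fewer than 2 units; "
                      "comparison skipped")
        return None
    if method == "welch":
        stat, p = stats.ttest_ind(a, b, equal_var=False)
    elif method == "mannwhitney":
        stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    else:
        raise ValueError(f"unknown method {method!r}")
    return GroupComparison(
        grouping=grouping, groups=groups, n=(len(a), len(b)),
        medians=(float(np.median(a)), float(np.median(b))),
        p10=(float(np.percentile(a, 10)), float(np.percentile(b, 10))),
        p90=(float(np.percentile(a, 90)), float(np.percentile(b, 90))),
        statistic=float(stat), p_value=float(p), method=method)


#: the grouped comparisons of the standard report: (grouping column, groups)
DEFAULT_GROUPINGS: tuple[tuple[str, Optional[tuple[str, str]]], ...] = (
    ("location_class", ("exonic", "intronic")),
    ("gene_class", ("lncRNA", "protein_coding")),
    ("motif_CNNC", ("0", "1")),
    ("motif_basal_UG", ("0", "1")),
    ("motif_apical_UGU", ("0", "1")),
)


def standard_group_comparisons(results: pd.DataFrame, method: str = "welch",
                               adjust: bool = False) -> pd.DataFrame:
    """Run the standard context comparisons (location, host-gene class, and
    the three Microprocessor cis-motifs) on the context-eligible units.

    The comparisons are reported uncorrected by default (each grouping is a
    separate question); ``adjust=True`` adds a BH-adjusted column across the
    groupings.
    """
    rows = []
    for grouping, groups in DEFAULT_GROUPINGS:
        if grouping not in results.columns:
            continue
        cmp_ = group_compare(results, grouping, groups=groups, method=method)
        if cmp_ is not None:
            rows.append(cmp_.as_row())
    out = pd.DataFrame(rows)
    if adjust and len(out):
        from statsmodels.stats.multitest import multipletests
        out["p_adj"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out


def tss_correlation(results: pd.DataFrame, method: str = "spearman"
                    ) -> tuple[float, float]:
    """Correlation between the synthesis ratio and TSS distance.

    Spearman by default (Pearson by flag).  Requires >= 3 annotated points.
    """
    sub = results.dropna(subset=["ratio", "tss_distance_nt"])
    if len(sub) < 3:
        raise ValueError("tss_correlation requires at least 3 annotated units")
    if sub["ratio"].nunique() == 1 or sub["tss_distance_nt"].nunique() == 1:
        return 0.0, 1.0  # a constant variable carries no rank information
    if method == "spearman":
        rho, p = stats.spearmanr(sub["ratio"], sub["tss_distance_nt"])
    elif method == "pearson":
        rho, p = stats.pearsonr(sub["ratio"], sub["tss_distance_nt"])
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(rho), float(p)


def conversion_rate_matrix(profiles: pd.DataFrame,
                           units: Optional[Iterable[str]] = None
                           ) -> pd.DataFrame:
    """Units x samples matrix of conversion rates."""
    mat = profiles.pivot_table(index="unit", columns="sample",
                               values="conversion_rate")
    if units is not None:
        mat = mat.loc[sorted(set(units) & set(mat.index))]
    return mat


def rate_pca(matrix: pd.DataFrame) -> pd.DataFrame:
    """QC principal components of samples in conversion-rate space
    (centered, unscaled).  Returns samples x PCs with explained variance in
    ``attrs``."""
    x = matrix.T.to_numpy(dtype=float)
    x = np.nan_to_num(x) - np.nan_to_num(x).mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    k = min(3, len(s))
    pcs = pd.DataFrame(u[:, :k] * s[:k], index=matrix.columns,
                       columns=[f"PC{i + 1}" for i in range(k)])
    var = s ** 2
    pcs.attrs["explained_variance_ratio"] = (var[:k] / var.sum()).tolist() \
        if var.sum() else [0.0] * k
    return pcs


def top_expressed(results: pd.DataFrame, profiles: pd.DataFrame,
                  n: int = 25) -> pd.DataFrame:
    """The ``n`` most expressed units (mean CPM across samples), ordered by
    genomic-location class and, within each class, from highest to lowest
    expression."""
    mean_cpm = profiles.groupby("unit")["cpm"].mean()
    out = results.copy()
    out["mean_cpm"] = out["unit"].map(mean_cpm)
    out = out.nlargest(min(n, len(out)), "mean_cpm")
    sort_cols = ["location_class", "mean_cpm"] \
        if "location_class" in out.columns else ["mean_cpm"]
    return out.sort_values(sort_cols, ascending=[True, False][:len(sort_cols)]
                           ).reset_index(drop=True)


def report(results: pd.DataFrame, comparisons: pd.DataFrame,
           profiles: pd.DataFrame, outdir: str | Path,
           top_n: int = 25, plots: bool = False) -> dict[str, Path]:
    """Write the report bundle: ratio table, group comparisons, top-expressed
    table, conversion-rate matrix and sample PCA; optional figures.

    Deterministic: rerunning on the same inputs is byte-identical.  An empty
    Final set yields header-only tables.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "ratios": outdir / "synthesis_ratios.tsv",
        "comparisons": outdir / "group_comparisons.tsv",
        "top_expressed": outdir / "top_expressed.tsv",
        "rate_matrix": outdir / "conversion_rate_matrix.tsv",
        "pca": outdir / "rate_pca.tsv",
    }
    results.to_csv(paths["ratios"], sep="\t", index=False)
    comparisons.to_csv(paths["comparisons"], sep="\t", index=False)
    top_expressed(results, profiles, n=top_n).to_csv(
        paths["top_expressed"], sep="\t", index=False)
    mat = conversion_rate_matrix(profiles)
    mat.to_csv(paths["rate_matrix"], sep="\t")
    rate_pca(mat).to_csv(paths["pca"], sep="\t")
    if plots:
        paths.update(_figures(results, profiles, mat, outdir))
    return paths


def _figures(results: pd.DataFrame, profiles: pd.DataFrame,
             matrix: pd.DataFrame, outdir: Path) -> dict[str, Path]:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    paths: dict[str, Path] = {}

    fig, ax = plt.subplots(figsize=(6, 4))
    for cond, sub in profiles.groupby("condition"):
        rates = sub.loc[sub["conversion_rate"] > 0, "conversion_rate"]
        ax.hist(np.log10(rates), bins=30, alpha=0.5, label=cond)
    ax.set_xlabel("log10 T>C conversion rate")
    ax.set_ylabel("miRNA x sample observations")
    ax.legend()
    paths["fig_rates"] = outdir / "conversion_rates.png"
    fig.savefig(paths["fig_rates"], dpi=120, bbox_inches="tight")
    plt.close(fig)

    if len(results) and "location_class" in results.columns:
        fig, ax = plt.subplots(figsize=(5, 4))
        groups = [(k, g["ratio"].to_numpy())
                  for k, g in results.groupby("location_class")]
        ax.boxplot([g for _, g in groups], tick_labels=[k for k, _ in groups],
                   whis=(10, 90))
        ax.set_ylabel("synthesis ratio (drug-ctrl)/(vehicle-ctrl)")
        paths["fig_groups"] = outdir / "ratio_by_location.png"
        fig.savefig(paths["fig_groups"], dpi=120, bbox_inches="tight")
        plt.close(fig)

    pcs = rate_pca(matrix)
    if "PC2" in pcs.columns:
        fig, ax = plt.subplots(figsize=(5, 4))
        conds = profiles.drop_duplicates("sample").set_index("sample")["condition"]
        for cond in conds.unique():
            sel = [s for s in pcs.index if conds.get(s) == cond]
            ax.scatter(pcs.loc[sel, "PC1"], pcs.loc[sel, "PC2"], label=cond)
        ax.set_xlabel("PC1")
        ax.set_ylabel("PC2")
        ax.legend()
        paths["fig_pca"] = outdir / "rate_pca.png"
        fig.savefig(paths["fig_pca"], dpi=120, bbox_inches="tight")
        plt.close(fig)
    return paths
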