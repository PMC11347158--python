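"""Initial and Final dataset construction.

The Initial dataset keeps miRNAs expressed above a CPM floor in *every*
sample and present in a curated high-confidence list.  An above-background
labeling test (one-sided exact conditional test on the pooled 2x2 table of
conversions vs. non-conversions in 4SU+vehicle against no-4SU control,
Benjamini-Hochberg adjusted) then excludes units not labeled above
background, and a floor rule drops units whose mean drug-condition rate
falls below the control mean.  Units whose duplicated loci sit in differing
genomic contexts are additionally excluded from context-grouped analyses.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .config import CONTROL, DMSO, PLAB, FilterParams

#: analysis-choice notes surfaced alongside every membership table
METADATA = {
    "labeling_test": ("one-sided exact conditional (hypergeometric) test on "
                      "pooled conversion counts, DMSO vs no-4SU control"),
    "significance_rule": ("labeled = direction(DMSO > Control) and p_adj < "
                          "alpha; the source protocol's printed direction "
                          "'P_adj > 0.05' is treated as a typo for '<'"),
    "cpm_rule": "cpm > cpm_min required in every individual sample",
}


def _cpm_table(profiles: pd.DataFrame) -> pd.DataFrame:
    return profiles.pivot_table(index="unit", columns="sample", values="cpm",
                                fill_value=0.0)


def initial_filter(profiles: pd.DataFrame, params: FilterParams,
                   curated_ids: Iterable[str],
                   expected_samples: Optional[Iterable[str]] = None
                   ) -> set[str]:
    """Units with cpm > ``cpm_min`` in every sample and a curated member.

    A collapsed unit counts as curated when any member id is on the curated
    list.  ``expected_samples`` (when given) guards against a silently
    missing library.
    """
    params.validate()
    if expected_samples is not None:
        missing = sorted(set(expected_samples) - set(profiles["sample"]))
        if missing:
            raise ValueError(f"profiles missing sample(s): {missing}")
    curated = set(curated_ids)
    cpm = _cpm_table(profiles)
    expressed = cpm.index[(cpm > params.cpm_min).all(axis=1)]
    return {u for u in expressed
            if any(m in curated for m in u.split("|"))}


def pooled_counts(profiles: pd.DataFrame, condition: str
                  ) -> pd.DataFrame:
    """Sum tc_count / t_coverage over the replicates of one condition."""
    sub = profiles[profiles["condition"] == condition]
    return sub.groupby("unit")[["tc_count", "t_coverage"]].sum()


def labeling_test(profiles: pd.DataFrame, units: Iterable[str],
                  params: FilterParams,
                  control: str = CONTROL, labeled_cond: str = DMSO
                  ) -> pd.DataFrame:
    """Above-background labeling test on pooled conversion counts.

    For each unit the 2x2 table (conversions, non-conversions) x (DMSO,
    Control) is tested one-sided for a higher DMSO rate via the exact
    conditional (hypergeometric) distribution; p-values are BH-adjusted
    across tested units.  Units with zero T coverage in either condition are
    untestable and excluded.
    """
    params.validate()
    units = sorted(units)
    ctrl = pooled_counts(profiles, control)
    dmso = pooled_counts(profiles, labeled_cond)
    rows = []
    for u in units:
        tc_d, cov_d = (int(dmso.loc[u, "tc_count"]),
                       int(dmso.loc[u, "t_coverage"])) if u in dmso.index else (0, 0)
        tc_c, cov_c = (int(ctrl.loc[u, "tc_count"]),
                       int(ctrl.loc[u, "t_coverage"])) if u in ctrl.index else (0, 0)
        testable = cov_d > 0 and cov_c > 0
        if testable:
            # P(X >= tc_d) for X ~ Hypergeom(N=cov_d+cov_c, K=tc_d+tc_c, n=cov_d)
            p = float(hypergeom.sf(tc_d - 1, cov_d + cov_c, tc_d + tc_c, cov_d))
        else:
            p = np.nan
        rows.append({"unit": u, "tc_dmso": tc_d, "cov_dmso": cov_d,
                     "tc_control": tc_c, "cov_control": cov_c,
                     "testable": testable, "p": p})
    out = pd.DataFrame(rows)
    out["p_adj"] = np.nan
    tested = out["testable"].to_numpy()
    if tested.any():
        out.loc[tested, "p_adj"] = multipletests(
            out.loc[tested, "p"], method=params.adjust_method)[1]
    with np.errstate(invalid="ignore", divide="ignore"):
        rate_d = out["tc_dmso"] / out["cov_dmso"]
        rate_c = out["tc_control"] / out["cov_control"]
    out["labeled"] = (tested & (rate_d > rate_c).fillna(False).to_numpy()
                      & (out["p_adj"] < params.alpha).fillna(False).to_numpy())
    return out


def condition_mean_rates(profiles: pd.DataFrame) -> pd.DataFrame:
    """Mean of per-replicate conversion rates, units x conditions."""
    return profiles.pivot_table(index="unit", columns="condition",
                                values="conversion_rate", aggfunc="mean")


def plab_floor_filter(profiles: pd.DataFrame, labeled_units: Iterable[str],
                      control: str = CONTROL, drug: str = PLAB) -> set[str]:
    """Keep labeled units whose mean drug-condition rate is not below the
    control mean (the boundary case, exactly equal, is retained)."""
    means = condition_mean_rates(profiles)
    keep = set()
    for u in labeled_units:
        if u in means.index and means.loc[u, drug] >= means.loc[u, control]:
            keep.add(u)
    return keep


def _unit_context(unit: str, ann: pd.DataFrame) -> Optional[tuple[str, str]]:
    members = unit.split("|")
    ctxs = set()
    for m in members:
        if m not in ann.index:
            return None
        loc = ann.loc[m, "location_class"]
        if loc == "mixed":
            return None  # loci of this miRNA already span differing contexts
        ctxs.add((loc, ann.loc[m, "gene_class"]))
    return ctxs.pop() if len(ctxs) == 1 else None


def context_dedup(final_units: Iterable[str], annotation: pd.DataFrame
                  ) -> set[str]:
    """Units eligible for context-grouped analyses: annotated, and with a
    single consistent genomic context across all loci/members."""
    ann = annotation.set_index("mirna_id") \
        if "mirna_id" in annotation.columns else annotation
    keep = set()
    for u in final_units:
        members = u.split("|")
        unannotated = [m for m in members if m not in ann.index]
        if unannotated:
            warnings.warn(f"unit {u!r} lacks annotation for {unannotated}; "
                          "excluded from context grouping")
            continue
        if _unit_context(u, ann) is not None:
            keep.add(u)
    return keep


def apply_filters(profiles: pd.DataFrame, params: FilterParams,
                  curated_ids: Iterable[str],
                  annotation: Optional[pd.DataFrame] = None,
                  expected_samples: Optional[Iterable[str]] = None
                  ) -> pd.DataFrame:
    """Run the full filter cascade and return the membership table.

    Columns: unit, in_initial, pooled counts, p, p_adj, labeled, in_final,
    in_context_set, exclusion_reason.  Monotone nesting holds by
    construction: context set <= Final <= labeled <= Initial <= all units.
    """
    all_units = sorted(profiles["unit"].unique())
    initial = initial_filter(profiles, params, curated_ids, expected_samples)
    tests = labeling_test(profiles, initial, params).set_index("unit")
    labeled = set(tests.index[tests["labeled"]])
    final = plab_floor_filter(profiles, labeled)
    in_context = context_dedup(final, annotation) if annotation is not None \
        else set(final)

    curated = set(curated_ids)
    cpm = _cpm_table(profiles)
    rows = []
    for u in all_units:
        reason = ""
        if u not in initial:
            parts = []
            if not (u in cpm.index and (cpm.loc[u] > params.cpm_min).all()):
                parts.append("low_cpm")
            if not any(m in curated for m in u.split("|")):
                parts.append("not_curated")
            reason = ";".join(parts)
        elif not tests.loc[u, "testable"]:
            reason = "untestable"
        elif u not in labeled:
            reason = "not_labeled_above_background"
        elif u not in final:
            reason = "plab_below_control"
        elif u not in in_context:
            reason = "mixed_context"
        row = {"unit": u, "in_initial": u in initial,
               "labeled": u in labeled, "in_final": u in final,
               "in_context_set": u in in_context, "exclusion_reason": reason}
        if u in tests.index:
            for col in ("tc_dmso", "cov_dmso", "tc_control", "cov_control",
                        "p", "p_adj"):
                row[col] = tests.loc[u, col]
        rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs["metadata"] = dict(METADATA)
    return out
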