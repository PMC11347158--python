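"""Independent brute-force oracles used by the test suite.

These re-derive the conversion-aware assignment rules by naive per-offset,
per-base enumeration, deliberately sharing no code with the package's
vectorized implementation.
"""

from __future__ import annotations

from typing import Optional

from mirslam.config import AlignParams
from mirslam.quant import FeatureIndex


def hand_profiles():
    """Hand-computed profile fixture with one unit per filter outcome.

    Two replicates per condition; every replicate has t_coverage 10000 (0 for
    the untestable unit's control), so pooled rates are tc/20000 and
    replicate-mean rates tc_mean/10000.  Expected memberships (enumerated by
    hand from the filter rules):

    ========  ==========  =======  =====  ===========  ==================
    unit      in_initial  labeled  final  context set  reason
    ========  ==========  =======  =====  ===========  ==================
    mirA      yes         yes      yes    yes
    mirB      no (cpm=99 in one sample)                low_cpm
    mirC      no (not curated)                         not_curated
    mirD      yes         no       no     no           identical counts
    mirE      yes         yes      no     no           plab mean < control
    mirF      yes         yes      yes    no           boundary kept; mixed
    mirG      yes         no       no     no           DMSO below control
    mirH      yes         --       no     no           untestable (cov 0)
    ========  ==========  =======  =====  ===========  ==================
    """
    import pandas as pd

    tc = {
        "mirA": {"control_no4su": (2, 3), "dmso_4su": (25, 25),
                 "plab_4su": (15, 15)},
        "mirB": {"control_no4su": (2, 3), "dmso_4su": (25, 25),
                 "plab_4su": (15, 15)},
        "mirC": {"control_no4su": (2, 3), "dmso_4su": (25, 25),
                 "plab_4su": (15, 15)},
        "mirD": {"control_no4su": (5, 5), "dmso_4su": (5, 5),
                 "plab_4su": (5, 5)},
        "mirE": {"control_no4su": (10, 10), "dmso_4su": (50, 50),
                 "plab_4su": (5, 5)},
        "mirF": {"control_no4su": (5, 5), "dmso_4su": (50, 50),
                 "plab_4su": (5, 5)},
        "mirG": {"control_no4su": (50, 50), "dmso_4su": (5, 5),
                 "plab_4su": (50, 50)},
        "mirH": {"control_no4su": (0, 0), "dmso_4su": (5, 5),
                 "plab_4su": (5, 5)},
    }
    rows = []
    for unit, by_cond in tc.items():
        for cond, pair in by_cond.items():
            for rep, t in enumerate(pair, start=1):
                sample = f"{cond}_rep{rep}"
                cov = 0 if unit == "mirH" and cond == "control_no4su" else 10000
                cpm = 99.0 if unit == "mirB" and sample == "dmso_4su_rep2" \
                    else 500.0
                rows.append((sample, cond, unit, 1000, cpm, cov, t,
                             t / cov if cov else 0.0))
    profiles = pd.DataFrame(rows, columns=["sample", "condition", "unit",
                                           "read_count", "cpm", "t_coverage",
                                           "tc_count", "conversion_rate"])
    curated = [u for u in tc if u != "mirC"]
    annotation = pd.DataFrame({
        "mirna_id": list(tc),
        "location_class": ["intronic", "exonic", "exonic", "intronic",
                           "exonic", "mixed", "intronic", "exonic"],
        "gene_class": ["lncRNA", "protein_coding", "lncRNA", "lncRNA",
                       "protein_coding", "lncRNA", "other", "lncRNA"],
        "motif_CNNC": [1, 0, 1, 0, 1, 0, 1, 0],
        "motif_basal_UG": [0, 1, 0, 1, 0, 1, 0, 1],
        "motif_apical_UGU": [0, 0, 1, 1, 0, 0, 1, 1],
        "tss_distance_nt": [1000, 2000, 3000, 4000, 5000, 6000, 7000, 8000],
    })
    expected = {
        "mirA": (True, True, True, True, ""),
        "mirB": (False, False, False, False, "low_cpm"),
        "mirC": (False, False, False, False, "not_curated"),
        "mirD": (True, False, False, False, "not_labeled_above_background"),
        "mirE": (True, True, False, False, "plab_below_control"),
        "mirF": (True, True, True, False, "mixed_context"),
        "mirG": (True, False, False, False, "not_labeled_above_background"),
        "mirH": (True, False, False, False, "untestable"),
    }
    return profiles, curated, annotation, expected


def brute_force_align(insert: str, index: FeatureIndex, params: AlignParams
                      ) -> Optional[tuple[int, int, int, int]]:
    """Naive best placement of one insert.

    Returns ``(unit_index, offset, tc_count, t_coverage)`` for a kept read,
    or None when unassigned/filtered.  Scoring: matches count 1, a
    template-T read as C also counts 1 but is recorded as a conversion; best
    score wins, first (unit, offset) in scan order breaks within-unit ties,
    and a tie across different units leaves the read unassigned.
    """
    L = len(insert)
    best_score = -1
    best: Optional[tuple[int, int, int, int, int]] = None
    best_units: set[int] = set()
    for ui, unit in enumerate(index.units):
        tmpl = unit.template
        for off in range(len(tmpl) - L + 1):
            matches = conv = t_cov = tc = 0
            for j in range(L):
                t, b = tmpl[off + j], insert[j]
                if t == "T":
                    t_cov += 1
                    if b == "C":
                        tc += 1
                if t == b:
                    matches += 1
                elif t == "T" and b == "C":
                    conv += 1
            score = matches + conv
            if score > best_score:
                best_score = score
                best = (ui, off, matches, conv, t_cov)
                best_units = {ui}
            elif score == best_score:
                best_units.add(ui)
    if best is None or len(best_units) > 1:
        return None
    ui, off, matches, conv, t_cov = best
    n_mm = L - matches - conv
    if n_mm > params.nm_max:
        return None
    integrity = (matches if params.integrity_counts_conversions
                 else matches + conv) / L
    if integrity < params.integrity_min:
        return None
    # recount tc at the winning placement
    tmpl = index.units[ui].template
    tc = sum(1 for j in range(L)
             if tmpl[off + j] == "T" and insert[j] == "C")
    return ui, off, tc, t_cov


def random_alignment_instance(rng, max_units: int = 10, max_reads: int = 100):
    """A randomized alignment instance: distinct-sequence units with random
    genomic flanks, and inserts that are converted/mutated copies of the
    unit sequences plus some fully random sequences."""
    from mirslam.quant import CountingUnit, FeatureIndex

    n_units = int(rng.integers(2, max_units + 1))
    seqs: set[str] = set()
    while len(seqs) < n_units:
        L = int(rng.integers(20, 24))
        seqs.add("".join(rng.choice(list("ACGT"), size=L)))
    ordered = sorted(seqs)
    units = [
        CountingUnit(
            name=f"u{i}", members=(f"u{i}",), mature_seq=s,
            template="".join(rng.choice(list("ACGT"), size=3)) + s
            + "".join(rng.choice(list("ACGT"), size=3)),
            mature_start=3)
        for i, s in enumerate(ordered)]
    inserts = []
    for _ in range(int(rng.integers(20, max_reads + 1))):
        kind = rng.random()
        src = list(ordered[int(rng.integers(n_units))])
        if kind < 0.6:  # conversions plus occasional other mismatches
            for i, b in enumerate(src):
                r = rng.random()
                if b == "T" and r < 0.15:
                    src[i] = "C"
                elif r < 0.05:
                    src[i] = "ACGT"[int(rng.integers(4))]
        elif kind < 0.8:  # unrelated sequence
            src = list(rng.choice(list("ACGT"), size=len(src)))
        inserts.append("".join(src))
    return FeatureIndex(units=units), inserts


def brute_force_counts(inserts: list[str], index: FeatureIndex,
                       params: AlignParams) -> dict[int, tuple[int, int, int]]:
    """Aggregate naive per-unit (read_count, tc_count, t_coverage)."""
    agg: dict[int, list[int]] = {}
    for insert in inserts:
        res = brute_force_align(insert, index, params)
        if res is None:
            continue
        ui, _off, tc, t_cov = res
        a = agg.setdefault(ui, [0, 0, 0])
        a[0] += 1
        a[1] += tc
        a[2] += t_cov
    return {ui: tuple(v) for ui, v in agg.items()}
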