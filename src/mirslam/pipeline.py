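"""End-to-end orchestration: simulate -> trim -> quantify -> filter -> ratios.

`run_study` chains the whole pipeline in memory on a simulated study, which
is how the recovery and calibration analyses run; the CLI chains the same
stages through files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from .config import PipelineConfig, SimConfig
from .filters import apply_filters
from .quant import FeatureIndex, SnpMask, build_index, quantify_samples
from .simulate import (Reference, SimTruth, draw_truth, generate_reference,
                       simulate_reads)
from .synthesis import standard_group_comparisons, synthesis_ratio, tss_correlation
from .trim import trim_reads


def index_from_reference(reference: Reference, flank: int = 3) -> FeatureIndex:
    """Build the alignment index straight from an in-memory reference bundle."""
    mature = {f.mirna_id: f.seq for f in reference.features}
    rows = [(chrom, start, end, f.mirna_id, 0, strand)
            for f in reference.features
            for chrom, start, end, strand in f.loci]
    loci = pd.DataFrame(rows, columns=["chrom", "start", "end", "name",
                                       "score", "strand"])
    return build_index(mature, loci, reference.genome, flank=flank)


@dataclass
class StudyResult:
    """Everything the pipeline produced for one study."""

    reference: Reference
    truth: SimTruth
    index: FeatureIndex
    profiles: pd.DataFrame        # tidy per-(sample, unit) profile table
    mask: SnpMask
    membership: pd.DataFrame      # Initial/labeled/Final/context membership
    results: pd.DataFrame         # synthesis ratios with annotation
    comparisons: pd.DataFrame     # grouped Welch comparisons
    trim_reports: dict[str, dict[str, int]] = field(default_factory=dict)

    @property
    def final_units(self) -> list[str]:
        return self.membership.loc[self.membership["in_final"], "unit"].tolist()

    @property
    def context_units(self) -> list[str]:
        return self.membership.loc[self.membership["in_context_set"],
                                   "unit"].tolist()

    def tss_correlation(self, method: str = "spearman") -> tuple[float, float]:
        sub = self.results[self.results["unit"].isin(self.context_units)]
        return tss_correlation(sub, method=method)


def run_study(sim_config: SimConfig,
              pipe_config: Optional[PipelineConfig] = None) -> StudyResult:
    """Simulate a labeled study and run the full quantification pipeline."""
    sim_config.validate()
    pipe = (pipe_config or PipelineConfig()).validate()
    reference = generate_reference(sim_config)
    truth = draw_truth(sim_config, reference)
    index = index_from_reference(reference, flank=pipe.align.flank)

    sample_inserts: dict[str, list[str]] = {}
    trim_reports: dict[str, dict[str, int]] = {}
    for sample in sim_config.sample_names:
        reads = ((rid, seq) for rid, seq, _q in
                 simulate_reads(sim_config, reference, truth, sample))
        counts = {"none": 0, "no_adapter": 0, "too_long": 0, "too_short": 0}
        inserts = []
        for tr in trim_reads(reads, pipe.trim):
            counts[tr.discard_reason] += 1
            if tr.kept:
                inserts.append(tr.insert_seq)
        trim_reports[sample] = {"kept": counts.pop("none"), **counts}
        sample_inserts[sample] = inserts

    profiles, mask = quantify_samples(
        sample_inserts, index, pipe.align, pipe.snp,
        condition_of_sample=sim_config.condition_of_sample)

    annotation = reference.annotation_frame()
    curated = _curated_units(reference, index)
    membership = apply_filters(profiles, pipe.filters, curated,
                               annotation=annotation,
                               expected_samples=sim_config.sample_names)
    final = membership.loc[membership["in_final"], "unit"]
    results = synthesis_ratio(profiles, final, annotation=annotation)
    context_units = set(membership.loc[membership["in_context_set"], "unit"])
    comparisons = standard_group_comparisons(
        results[results["unit"].isin(context_units)])
    return StudyResult(reference=reference, truth=truth, index=index,
                       profiles=profiles, mask=mask, membership=membership,
                       results=results, comparisons=comparisons,
                       trim_reports=trim_reports)


def _curated_units(reference: Reference, index: FeatureIndex) -> list[str]:
    return reference.curated_ids()
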