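"""Parameter containers for the simulator and the quantification pipeline.

All thresholds used anywhere in the pipeline live here, so that a single
:class:`PipelineConfig` fully determines the analysis and a single
:class:`SimConfig` fully determines a simulated study (byte-identical
outputs for a fixed seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

#: 3' adapter ligated by NEXTflex-style small-RNA kits (TruSeq small-RNA adapter).
NEXTFLEX_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"

#: Condition labels of the three-arm labeling design.
CONTROL = "control_no4su"   # no 4SU, vehicle: background conversions only
DMSO = "dmso_4su"           # 4SU + vehicle: full labeling
PLAB = "plab_4su"           # 4SU + drug: labeling under splicing inhibition

CONDITIONS = (CONTROL, DMSO, PLAB)


class ConfigError(ValueError):
    """Raised when a configuration field is invalid; the message names the field."""


def _check(ok: bool, fieldname: str, msg: str) -> None:
    if not ok:
        raise ConfigError(f"{fieldname}: {msg}")


@dataclass
class SimConfig:
    """Parameters of a simulated metabolic-labeling small-RNA study.

    The defaults emulate the study design this package targets: three
    conditions (no-4SU control, 4SU+vehicle, 4SU+drug) with four replicates
    each, NEXTflex-style libraries whose inserts are flanked by 4 randomized
    nucleotides plus a 3' adapter, and T>C conversion rates in the
    sub-percent regime (per-U detection probability ``p_inc`` times a
    fraction-new of order 0.2).
    """

    n_mirnas: int = 50
    seq_length_range: tuple[int, int] = (20, 23)
    u_content_range: tuple[float, float] = (0.2, 0.45)
    #: sigma of the log-normal expression law (heavy-tailed miRNA abundance)
    expression_sigma: float = 1.5
    reads_per_sample: int = 200_000
    #: (condition label, number of replicates)
    conditions: tuple[tuple[str, int], ...] = ((CONTROL, 4), (DMSO, 4), (PLAB, 4))
    #: probability that a U in a new molecule is detected as a T>C conversion
    #: (product of 4SU incorporation and chemical-conversion efficiency)
    p_inc: float = 0.02
    #: uniform law for the per-miRNA fraction of new molecules under vehicle
    new_fraction_range: tuple[float, float] = (0.05, 0.30)
    #: uniform law for the per-miRNA multiplicative suppression under drug
    suppression_range: tuple[float, float] = (0.2, 1.0)
    #: fraction of miRNAs whose synthesis the drug leaves untouched (suppression = 1)
    frac_unaffected: float = 0.1
    #: per-base substitution error probability (uniform over the 3 alternatives)
    seq_error: float = 0.001
    #: explicit SNPs as (mirna_id, 0-based position in mature seq, alt base,
    #: allele frequency in {0.5, 1.0}); None = auto-place ``n_snp_mirnas`` T>C SNPs
    snp_spec: Optional[list[tuple[str, int, str, float]]] = None
    n_snp_mirnas: int = 2
    adapter_seq: str = NEXTFLEX_ADAPTER
    n_random_flank: int = 4
    read_length: int = 75
    #: miRNAs with a second genomic locus in the same / in a different context
    n_dup_same_context: int = 2
    n_dup_mixed_context: int = 2
    #: miRNAs left out of the curated high-confidence list
    n_uncurated: int = 3
    minus_strand_fraction: float = 0.3
    seed: int = 0

    def validate(self) -> "SimConfig":
        _check(self.n_mirnas >= 0, "n_mirnas", "must be >= 0")
        lo, hi = self.seq_length_range
        _check(0 < lo <= hi, "seq_length_range", "must be a positive interval")
        ulo, uhi = self.u_content_range
        _check(0 <= ulo <= uhi <= 1, "u_content_range", "must lie in [0, 1]")
        _check(self.expression_sigma >= 0, "expression_sigma", "must be >= 0")
        _check(self.reads_per_sample > 0, "reads_per_sample", "must be > 0")
        for label, n_rep in self.conditions:
            _check(label in CONDITIONS, "conditions",
                   f"unknown condition label {label!r}")
            _check(n_rep >= 1, "conditions", "replicates must be >= 1")
        _check(0 <= self.p_inc <= 1, "p_inc", "must be a probability")
        nlo, nhi = self.new_fraction_range
        _check(0 <= nlo <= nhi <= 1, "new_fraction_range", "must lie in [0, 1]")
        slo, shi = self.suppression_range
        _check(0 <= slo <= shi <= 1, "suppression_range", "must lie in [0, 1]")
        _check(0 <= self.frac_unaffected <= 1, "frac_unaffected",
               "must be a probability")
        _check(0 <= self.seq_error <= 1, "seq_error", "must be a probability")
        if self.snp_spec is not None:
            for spec in self.snp_spec:
                _check(len(spec) == 4, "snp_spec",
                       "entries are (mirna_id, pos, alt, freq)")
                _check(spec[2] in "ACGT", "snp_spec", "alt base must be A/C/G/T")
                _check(spec[3] in (0.5, 1.0), "snp_spec",
                       "allele frequency must be 0.5 or 1.0")
        _check(len(self.adapter_seq) >= 1, "adapter_seq", "must be non-empty")
        _check(self.n_random_flank >= 0, "n_random_flank", "must be >= 0")
        _check(self.read_length > 2 * self.n_random_flank, "read_length",
               "must exceed the randomized flanks")
        _check(0 <= self.minus_strand_fraction <= 1, "minus_strand_fraction",
               "must be a probability")
        return self

    @property
    def sample_names(self) -> list[str]:
        return [f"{label}_rep{r}"
                for label, n_rep in self.conditions for r in range(1, n_rep + 1)]

    @property
    def condition_of_sample(self) -> dict[str, str]:
        return {f"{label}_rep{r}": label
                for label, n_rep in self.conditions for r in range(1, n_rep + 1)}


@dataclass
class TrimParams:
    """Adapter removal and randomized-base clipping parameters.

    ``max_length`` is applied after the 3' clip and before the 5' clip,
    matching a workflow where the 3' randomized bases are clipped during
    adapter removal and the 5' ones at mapping time.
    """

    adapter_seq: str = NEXTFLEX_ADAPTER
    min_overlap: int = 3
    adapter_mismatch_rate: float = 0.1
    clip3: int = 4
    clip5: int = 4
    max_length: int = 30
    min_length: int = 16
    #: policy for reads in which no adapter is found: discard (default) or keep
    keep_no_adapter: bool = False

    def validate(self) -> "TrimParams":
        _check(len(self.adapter_seq) >= 1, "adapter_seq", "must be non-empty")
        _check(self.min_overlap >= 1, "min_overlap", "must be >= 1")
        _check(0 <= self.adapter_mismatch_rate < 1, "adapter_mismatch_rate",
               "must lie in [0, 1)")
        _check(self.clip3 >= 0, "clip3", "must be >= 0")
        _check(self.clip5 >= 0, "clip5", "must be >= 0")
        _check(self.max_length > 0, "max_length", "must be > 0")
        _check(self.min_length >= 1, "min_length", "must be >= 1")
        return self


@dataclass
class AlignParams:
    """Conversion-aware feature-space alignment parameters."""

    #: maximum non-T>C mismatches in a kept read
    nm_max: int = 3
    #: minimum (matches excluding conversions) / (insert length)
    integrity_min: float = 0.95
    #: template flank (nt) taken from the genomic locus on each side of the mature seq
    flank: int = 3
    #: whether T>C conversions count against the integrity filter.  Off by
    #: default: penalizing conversions discards multiply-converted reads
    #: (2 conversions on a 21-nt insert already fall below 0.95) and biases
    #: the conversion-rate estimator low; the strict variant is kept as an
    #: option for compatibility with integrity definitions that treat every
    #: non-reference base as a mismatch.
    integrity_counts_conversions: bool = False

    def validate(self) -> "AlignParams":
        _check(self.nm_max >= 0, "nm_max", "must be >= 0")
        _check(0 <= self.integrity_min <= 1, "integrity_min", "must lie in [0, 1]")
        _check(self.flank >= 0, "flank", "must be >= 0")
        return self


@dataclass
class SnpParams:
    """SNP-mask calling parameters (applied to no-4SU control alignments)."""

    min_alt_fraction: float = 0.4
    min_coverage: int = 10

    def validate(self) -> "SnpParams":
        _check(0 < self.min_alt_fraction <= 1, "min_alt_fraction",
               "must lie in (0, 1]")
        _check(self.min_coverage >= 1, "min_coverage", "must be >= 1")
        return self


@dataclass
class FilterParams:
    """Initial/Final dataset construction thresholds."""

    #: CPM must exceed this in every sample ("> 100 CPM in all datasets")
    cpm_min: float = 100.0
    #: adjusted-significance threshold of the above-background labeling test
    alpha: float = 0.05
    #: multiple-testing adjustment (Benjamini-Hochberg)
    adjust_method: str = "fdr_bh"

    def validate(self) -> "FilterParams":
        _check(self.cpm_min >= 0, "cpm_min", "must be >= 0")
        _check(0 < self.alpha < 1, "alpha", "must lie in (0, 1)")
        return self


@dataclass
class PipelineConfig:
    """All thresholds of the quantification pipeline in one place."""

    trim: TrimParams = field(default_factory=TrimParams)
    align: AlignParams = field(default_factory=AlignParams)
    snp: SnpParams = field(default_factory=SnpParams)
    filters: FilterParams = field(default_factory=FilterParams)

    def validate(self) -> "PipelineConfig":
        self.trim.validate()
        self.align.validate()
        self.snp.validate()
        self.filters.validate()
        return self

    def to_dict(self) -> dict:
        return asdict(self)
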