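"""Conversion-aware assignment of inserts to mature miRNAs and T>C counting.

Reads are compared ungapped against each mature sequence extended by a small
genomic flank, at every allowed offset.  A template-T read as C counts as a
match for scoring (so labeling never penalizes assignment) but is recorded
as a conversion.  Identical mature sequences are collapsed into one counting
unit, which realizes multi-locus miRNA retention at the counting level.

Per (unit, sample) the module reports read count, CPM, reference-T coverage,
T>C count and their ratio, the conversion rate.  SNP positions called from
no-4SU control samples (alternate-allele fraction >= 0.4) are masked from
both the numerator and the denominator.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .config import AlignParams, SnpParams

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_T, _C = _CODE["T"], _CODE["C"]


def _encode(seq: str) -> np.ndarray:
    return np.array([_CODE.get(b, 4) for b in seq], dtype=np.uint8)


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


@dataclass
class CountingUnit:
    """A collapse group of identical mature sequences."""

    name: str                 # joined member ids, stable/sorted
    members: tuple[str, ...]
    mature_seq: str
    template: str             # flank + mature + flank from the first locus
    mature_start: int         # offset of the mature seq within the template


@dataclass
class FeatureIndex:
    """Alignment index over counting units.

    ``windows[L]`` stacks, for every unit, every length-``L`` window of its
    template (one row per (unit, offset)), so a whole insert can be compared
    against all candidate placements with a single vectorized pass.
    """

    units: list[CountingUnit]
    windows: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]] = field(
        default_factory=dict, repr=False)

    @property
    def unit_names(self) -> list[str]:
        return [u.name for u in self.units]

    def unit_of_member(self) -> dict[str, str]:
        return {m: u.name for u in self.units for m in u.members}

    def _window_matrix(self, length: int
                       ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        if length not in self.windows:
            rows, unit_idx, offsets = [], [], []
            for ui, unit in enumerate(self.units):
                codes = _encode(unit.template)
                for off in range(len(unit.template) - length + 1):
                    rows.append(codes[off:off + length])
                    unit_idx.append(ui)
                    offsets.append(off)
            if rows:
                mat = np.stack(rows)
            else:
                mat = np.zeros((0, length), dtype=np.uint8)
            self.windows[length] = (mat, np.array(unit_idx, dtype=np.int32),
                                    np.array(offsets, dtype=np.int32))
        return self.windows[length]


def build_index(mature: Mapping[str, str] | str | Path,
                loci: pd.DataFrame | str | Path,
                genome: Mapping[str, str] | str | Path | None = None,
                flank: int = 3) -> FeatureIndex:
    """Build the counting-unit index from mature sequences and genomic loci.

    ``mature`` maps id -> sequence (or is a FASTA path); ``loci`` is a BED6
    table (0-based half-open, strand used) or its path; ``genome`` supplies
    the flanking template bases (without it, flank falls back to 0).
    Identical mature sequences collapse into a single unit.  Ids present in
    only one of FASTA/BED raise an error listing the orphans.
    """
    if isinstance(mature, (str, Path)):
        from Bio import SeqIO
        mature = {rec.id: str(rec.seq).upper()
                  for rec in SeqIO.parse(str(mature), "fasta")}
    if isinstance(loci, (str, Path)):
        loci = pd.read_csv(loci, sep="\t", header=None,
                           names=["chrom", "start", "end", "name", "score",
                                  "strand"])
    if isinstance(genome, (str, Path)):
        from Bio import SeqIO
        genome = {rec.id: str(rec.seq).upper()
                  for rec in SeqIO.parse(str(genome), "fasta")}

    fasta_ids = set(mature)
    bed_ids = set(loci["name"]) if len(loci) else set()
    orphans = sorted(fasta_ids ^ bed_ids)
    if orphans:
        raise ValueError(f"ids present in only one of FASTA/BED: {orphans}")

    first_locus = {row["name"]: (row["chrom"], int(row["start"]),
                                 int(row["end"]), row["strand"])
                   for _, row in loci.iloc[::-1].iterrows()}

    by_seq: dict[str, list[str]] = {}
    for mid in sorted(mature):
        by_seq.setdefault(mature[mid], []).append(mid)

    units = []
    for seq, members in sorted(by_seq.items(), key=lambda kv: kv[1][0]):
        template, mstart = seq, 0
        if genome is not None and members[0] in first_locus:
            chrom, start, end, strand = first_locus[members[0]]
            gseq = genome[chrom]
            lo, hi = max(0, start - flank), min(len(gseq), end + flank)
            tmpl = gseq[lo:hi]
            if strand == "-":
                tmpl = _revcomp(tmpl)
                mstart = hi - end
            else:
                mstart = start - lo
            # the template must embed the mature sequence; loci that disagree
            # with the FASTA fall back to the bare mature sequence
            if tmpl[mstart:mstart + len(seq)] == seq:
                template = tmpl
        units.append(CountingUnit(name="|".join(members), members=tuple(members),
                                  mature_seq=seq, template=template,
                                  mature_start=mstart))
    return FeatureIndex(units=units)


@dataclass
class Assignment:
    """Best placement of an insert: unit, offset, and per-position calls."""

    unit_index: int
    offset: int
    n_conversions: int
    n_mismatches: int            # non-T>C mismatches
    t_positions: np.ndarray      # template coords of covered reference-T positions
    c_positions: np.ndarray      # subset of t_positions read as C


def align_insert(insert: str, index: FeatureIndex, params: AlignParams
                 ) -> Optional[Assignment]:
    """Assign one insert to its best-scoring unit, or None when unassigned.

    Score = matches, counting template-T-read-C as a match.  The read is kept
    only if non-T>C mismatches <= ``nm_max`` and the mapping integrity
    (matching fraction, with conversions counted as matches unless
    ``integrity_counts_conversions`` is set) reaches ``integrity_min``.
    A score tie
    across units (which, post-collapse, always carry different mature
    sequences) leaves the read unassigned.
    """
    L = len(insert)
    mat, unit_idx, offsets = index._window_matrix(L)
    if mat.shape[0] == 0:
        return None
    codes = _encode(insert)
    eq = mat == codes
    conv = (mat == _T) & (codes == _C) & ~eq
    score = eq.sum(axis=1) + conv.sum(axis=1)
    best = int(score.max())
    top = np.flatnonzero(score == best)
    top_units = np.unique(unit_idx[top])
    if len(top_units) > 1:
        return None
    row = int(top[0])  # lowest offset among equal-scoring placements in the unit
    n_conv = int(conv[row].sum())
    n_match = int(eq[row].sum())
    n_mm = L - n_match - n_conv
    if n_mm > params.nm_max:
        return None
    integrity_matches = n_match if params.integrity_counts_conversions \
        else n_match + n_conv
    if integrity_matches / L < params.integrity_min:
        return None
    t_here = mat[row] == _T
    off = int(offsets[row])
    return Assignment(
        unit_index=int(unit_idx[row]),
        offset=off,
        n_conversions=n_conv,
        n_mismatches=n_mm,
        t_positions=np.flatnonzero(t_here) + off,
        c_positions=np.flatnonzero(t_here & (codes == _C)) + off,
    )


@dataclass
class SampleAlignment:
    """Per-sample alignment tallies: read counts and per-template-position
    T coverage / C calls for every unit."""

    index: FeatureIndex
    sample: str
    read_count: np.ndarray        # per unit
    assigned: int = 0
    unassigned: int = 0
    t_cov: list[np.ndarray] = field(default_factory=list)   # per unit, per pos
    c_count: list[np.ndarray] = field(default_factory=list)


def align_sample(inserts: Iterable[str], index: FeatureIndex,
                 params: AlignParams, sample: str = "sample") -> SampleAlignment:
    """Align a stream of inserts, caching by unique sequence (short inserts
    repeat heavily, so each distinct sequence is scored once)."""
    params.validate()
    n_units = len(index.units)
    out = SampleAlignment(
        index=index, sample=sample,
        read_count=np.zeros(n_units, dtype=np.int64),
        t_cov=[np.zeros(len(u.template), dtype=np.int64) for u in index.units],
        c_count=[np.zeros(len(u.template), dtype=np.int64) for u in index.units],
    )
    counter = Counter(inserts)
    for insert, mult in counter.items():
        a = align_insert(insert, index, params)
        if a is None:
            out.unassigned += mult
            continue
        out.assigned += mult
        out.read_count[a.unit_index] += mult
        out.t_cov[a.unit_index][a.t_positions] += mult
        out.c_count[a.unit_index][a.c_positions] += mult
    return out


@dataclass(frozen=True)
class SnpMask:
    """Masked (unit name, template position) pairs; reference-T positions only."""

    positions: frozenset[tuple[str, int]]

    def __contains__(self, item: tuple[str, int]) -> bool:
        return item in self.positions

    def for_unit(self, unit_name: str, template_len: int) -> np.ndarray:
        m = np.zeros(template_len, dtype=bool)
        for name, pos in self.positions:
            if name == unit_name and pos < template_len:
                m[pos] = True
        return m


def call_snp_mask(control_alignments: Sequence[SampleAlignment],
                  params: SnpParams) -> SnpMask:
    """Call SNP positions from pooled no-4SU control alignments.

    A reference-T template position is masked when its pooled coverage is at
    least ``min_coverage`` and the fraction of reads showing C is at least
    ``min_alt_fraction`` (0.4 catches heterozygous diploid T/C loci).
    Calling on no-4SU controls only means genuine labeling can never be
    masked as a variant.
    """
    params.validate()
    if not control_alignments:
        raise ValueError("at least one control alignment is required")
    index = control_alignments[0].index
    masked = set()
    for ui, unit in enumerate(index.units):
        cov = sum(a.t_cov[ui] for a in control_alignments)
        cc = sum(a.c_count[ui] for a in control_alignments)
        tmpl_t = np.array([b == "T" for b in unit.template])
        callable_ = tmpl_t & (cov >= params.min_coverage)
        for pos in np.flatnonzero(callable_):
            if cc[pos] / cov[pos] >= params.min_alt_fraction:
                masked.add((unit.name, int(pos)))
    return SnpMask(positions=frozenset(masked))


def count_conversions(alignment: SampleAlignment,
                      mask: Optional[SnpMask] = None) -> pd.DataFrame:
    """Per-unit profile for one sample: read_count, cpm, t_coverage,
    tc_count and conversion_rate (0 when t_coverage is 0).

    Masked positions are excluded from both the numerator and the
    denominator, so a masked variant contributes nothing to the rate.
    """
    index = alignment.index
    total = int(alignment.read_count.sum())
    rows = []
    for ui, unit in enumerate(index.units):
        cov = alignment.t_cov[ui]
        cc = alignment.c_count[ui]
        if mask is not None:
            keep = ~mask.for_unit(unit.name, len(unit.template))
            cov = cov * keep
            cc = cc * keep
        t_coverage = int(cov.sum())
        tc = int(cc.sum())
        rc = int(alignment.read_count[ui])
        rows.append({
            "unit": unit.name,
            "read_count": rc,
            "cpm": rc / total * 1e6 if total else 0.0,
            "t_coverage": t_coverage,
            "tc_count": tc,
            "conversion_rate": tc / t_coverage if t_coverage else 0.0,
        })
    return pd.DataFrame(rows)


def quantify_samples(sample_inserts: Mapping[str, Iterable[str]],
                     index: FeatureIndex, params: AlignParams,
                     snp_params: SnpParams,
                     condition_of_sample: Mapping[str, str],
                     control_condition: str = "control_no4su"
                     ) -> tuple[pd.DataFrame, SnpMask]:
    """Align every sample, call the SNP mask from the no-4SU controls, and
    return the tidy profile table (sample, condition, unit, counts, rate)."""
    alignments = {s: align_sample(ins, index, params, sample=s)
                  for s, ins in sample_inserts.items()}
    controls = [a for s, a in alignments.items()
                if condition_of_sample[s] == control_condition]
    mask = call_snp_mask(controls, snp_params) if controls \
        else SnpMask(frozenset())
    frames = []
    for s, a in alignments.items():
        df = count_conversions(a, mask)
        df.insert(0, "condition", condition_of_sample[s])
        df.insert(0, "sample", s)
        frames.append(df)
    return pd.concat(frames, ignore_index=True), mask


def write_mask_bed(mask: SnpMask, index: FeatureIndex, path: str | Path) -> None:
    """Write masked template positions as a BED-like table (unit coordinates)."""
    rows = sorted(mask.positions)
    with open(path, "w") as fh:
        for name, pos in rows:
            fh.write(f"{name}\t{pos}\t{pos + 1}\tsnp_mask\n")
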