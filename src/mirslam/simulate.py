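"""Synthetic labeled small-RNA study generator.

Emulates a three-arm 4-thiouridine (4SU) metabolic-labeling design measured
by nucleotide-conversion sequencing: a per-condition fraction of each
miRNA's molecules is "new", and every U in a new molecule is detected as a
T>C conversion with fixed probability ``p_inc``.  Reads are NEXTflex-style:
4 randomized nucleotides on each side of the insert, followed by the 3'
adapter, truncated to a fixed read length so adapter read-through always
occurs.  Sequencing errors substitute uniformly among the three alternative
bases; SNP alleles at miRNA-locus positions are applied before labeling.

Every output is a plain-text standard format (FASTA/BED6/TSV/FASTQ) and is
byte-identical for a fixed :class:`~mirslam.config.SimConfig` seed.
"""

from __future__ import annotations

import gzip
import math
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

import numpy as np
import pandas as pd

from .config import CONDITIONS, CONTROL, DMSO, PLAB, ConfigError, SimConfig

_BASES = "ACGT"
_OTHER = {b: _BASES.replace(b, "") for b in _BASES}
#: fixed sequence read after the 3' adapter (RT-primer stand-in), so that
#: fixed-length reads are always full length
_DOWNSTREAM = "GAATTCCACCACGTTCCCGTGGAATTCCACCACGTTCCCGTGG"

_LOCATION_CLASSES = ("intronic", "exonic", "other")
_LOCATION_PROBS = (0.50, 0.38, 0.12)
_GENE_CLASSES = ("lncRNA", "protein_coding", "other")
_GENE_PROBS = (0.45, 0.45, 0.10)
#: marginal frequencies of the Microprocessor-promoting cis motifs
_MOTIF_PROBS = {"motif_CNNC": 0.6, "motif_basal_UG": 0.3, "motif_apical_UGU": 0.3}


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


@dataclass
class MiRNAFeature:
    """One mature miRNA of the synthetic reference."""

    mirna_id: str
    seq: str
    loci: list[tuple[str, int, int, str]]  # (chrom, start, end, strand), BED-style
    location_class: str
    gene_class: str
    motif_CNNC: int
    motif_basal_UG: int
    motif_apical_UGU: int
    tss_distance_nt: int
    curated: bool


@dataclass
class Reference:
    """Reference bundle: features plus the synthetic genome they live on."""

    features: list[MiRNAFeature]
    genome: dict[str, str]

    @property
    def by_id(self) -> dict[str, MiRNAFeature]:
        return {f.mirna_id: f for f in self.features}

    def annotation_frame(self) -> pd.DataFrame:
        rows = [
            {
                "mirna_id": f.mirna_id,
                "location_class": f.location_class,
                "gene_class": f.gene_class,
                "motif_CNNC": f.motif_CNNC,
                "motif_basal_UG": f.motif_basal_UG,
                "motif_apical_UGU": f.motif_apical_UGU,
                "tss_distance_nt": f.tss_distance_nt,
            }
            for f in self.features
        ]
        cols = ["mirna_id", "location_class", "gene_class", "motif_CNNC",
                "motif_basal_UG", "motif_apical_UGU", "tss_distance_nt"]
        return pd.DataFrame(rows, columns=cols)

    def curated_ids(self) -> list[str]:
        return [f.mirna_id for f in self.features if f.curated]


@dataclass
class SimTruth:
    """Ground truth of a simulated study (for recovery tests)."""

    mirna_ids: list[str]
    expression_weight: np.ndarray          # sums to 1
    new_fraction: dict[str, np.ndarray]    # condition -> per-miRNA fraction new
    p_inc: float
    suppression: np.ndarray                # new_fraction[PLAB] / new_fraction[DMSO]
    snps: dict[str, list[tuple[int, str, float]]]  # id -> (pos, alt, allele freq)

    @property
    def true_ratio(self) -> np.ndarray:
        return self.suppression

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mirna_id": self.mirna_ids,
                "expression_weight": self.expression_weight,
                "new_fraction_dmso": self.new_fraction[DMSO],
                "new_fraction_plab": self.new_fraction[PLAB],
                "p_inc": self.p_inc,
                "true_ratio": self.true_ratio,
                "n_snps": [len(self.snps.get(m, [])) for m in self.mirna_ids],
            }
        )


def _random_mirna_seq(rng: np.random.Generator, length: int, u_content: float) -> str:
    p_t = u_content
    p_other = (1.0 - u_content) / 3.0
    probs = [p_other, p_other, p_other, p_t]  # A C G T
    while True:
        seq = "".join(rng.choice(list("ACGT"), size=length, p=probs))
        if "T" in seq:  # a miRNA without U cannot be labeled; redraw
            return seq


def generate_reference(config: SimConfig) -> Reference:
    """Generate mature sequences, genomic loci, annotation and curation flags.

    A configurable subset of miRNAs carries a duplicated locus with an
    identical mature sequence, either in the same genomic context or in a
    different one (annotated ``location_class="mixed"``); another subset is
    left out of the curated high-confidence list.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    if config.n_mirnas == 0:
        return Reference(features=[], genome={"chrSim": ""})

    n_dup = config.n_dup_same_context + config.n_dup_mixed_context
    if n_dup > config.n_mirnas:
        raise ConfigError("n_dup_same_context: duplicated loci exceed n_mirnas")
    if config.n_uncurated > config.n_mirnas:
        raise ConfigError("n_uncurated: exceeds n_mirnas")

    lo, hi = config.seq_length_range
    ulo, uhi = config.u_content_range
    seqs: list[str] = []
    seen: set[str] = set()
    for _ in range(config.n_mirnas):
        while True:
            length = int(rng.integers(lo, hi + 1))
            seq = _random_mirna_seq(rng, length, float(rng.uniform(ulo, uhi)))
            if seq not in seen:
                seen.add(seq)
                seqs.append(seq)
                break

    location = rng.choice(_LOCATION_CLASSES, size=config.n_mirnas, p=_LOCATION_PROBS)
    gene = rng.choice(_GENE_CLASSES, size=config.n_mirnas, p=_GENE_PROBS)
    motifs = {name: (rng.random(config.n_mirnas) < p).astype(int)
              for name, p in _MOTIF_PROBS.items()}
    # TSS distances roughly log-uniform between 200 nt and 200 kb
    tss = np.exp(rng.uniform(math.log(200), math.log(200_000),
                             size=config.n_mirnas)).astype(int)
    uncurated = set(rng.choice(config.n_mirnas, size=config.n_uncurated,
                               replace=False).tolist())

    # lay every locus down on one synthetic chromosome with random spacers
    chrom = "chrSim"
    genome_parts: list[str] = []
    cursor = 0

    def _emit_locus(seq: str, strand: str) -> tuple[str, int, int, str]:
        nonlocal cursor
        spacer = "".join(rng.choice(list("ACGT"), size=40))
        genome_parts.append(spacer)
        cursor += len(spacer)
        start = cursor
        genomic = seq if strand == "+" else _revcomp(seq)
        genome_parts.append(genomic)
        cursor += len(genomic)
        return (chrom, start, cursor, strand)

    features: list[MiRNAFeature] = []
    for i, seq in enumerate(seqs):
        mid = f"sim-mir-{i + 1}"
        strand = "-" if rng.random() < config.minus_strand_fraction else "+"
        loci = [_emit_locus(seq, strand)]
        loc_class = str(location[i])
        if i < config.n_dup_same_context:
            loci.append(_emit_locus(seq, strand))
        elif i < n_dup:
            loci.append(_emit_locus(seq, strand))
            loc_class = "mixed"  # second locus sits in a different context
        features.append(
            MiRNAFeature(
                mirna_id=mid,
                seq=seq,
                loci=loci,
                location_class=loc_class,
                gene_class=str(gene[i]),
                motif_CNNC=int(motifs["motif_CNNC"][i]),
                motif_basal_UG=int(motifs["motif_basal_UG"][i]),
                motif_apical_UGU=int(motifs["motif_apical_UGU"][i]),
                tss_distance_nt=int(tss[i]),
                curated=i not in uncurated,
            )
        )
    # closing spacer so every locus has right-hand flank sequence
    genome_parts.append("".join(rng.choice(list("ACGT"), size=40)))
    return Reference(features=features, genome={chrom: "".join(genome_parts)})


def draw_truth(config: SimConfig, reference: Reference) -> SimTruth:
    """Draw per-miRNA ground truth: abundance, fraction-new, suppression, SNPs."""
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    ids = [f.mirna_id for f in reference.features]
    n = len(ids)
    if n == 0:
        return SimTruth(ids, np.zeros(0), {c: np.zeros(0) for c in CONDITIONS},
                        config.p_inc, np.zeros(0), {})

    weights = rng.lognormal(mean=0.0, sigma=config.expression_sigma, size=n)
    weights /= weights.sum()
    new_dmso = rng.uniform(*config.new_fraction_range, size=n)
    suppression = rng.uniform(*config.suppression_range, size=n)
    unaffected = rng.random(n) < config.frac_unaffected
    suppression[unaffected] = 1.0
    new_fraction = {
        CONTROL: np.zeros(n),
        DMSO: new_dmso,
        PLAB: new_dmso * suppression,
    }

    snps: dict[str, list[tuple[int, str, float]]] = {}
    if config.snp_spec is not None:
        by_id = reference.by_id
        for mid, pos, alt, freq in config.snp_spec:
            if mid not in by_id:
                raise ConfigError(f"snp_spec: unknown miRNA {mid!r}")
            if not 0 <= pos < len(by_id[mid].seq):
                raise ConfigError(f"snp_spec: position {pos} outside {mid}")
            snps.setdefault(mid, []).append((pos, alt, freq))
    elif config.n_snp_mirnas > 0:
        # place one T>C SNP (the confounding kind) at a random T position
        candidates = [i for i, f in enumerate(reference.features) if "T" in f.seq]
        chosen = rng.choice(candidates,
                            size=min(config.n_snp_mirnas, len(candidates)),
                            replace=False)
        for i in chosen:
            feat = reference.features[i]
            t_pos = [j for j, b in enumerate(feat.seq) if b == "T"]
            pos = int(rng.choice(t_pos))
            freq = float(rng.choice([0.5, 1.0]))
            snps[feat.mirna_id] = [(pos, "C", freq)]

    return SimTruth(ids, weights, new_fraction, config.p_inc, suppression, snps)


def expected_conversion_rate(truth: SimTruth, condition: str,
                             seq_error: float = 0.0) -> np.ndarray:
    """Analytic per-miRNA expected T>C rate at reference-T positions.

    A reference-T position reads C when the molecule is new and the U was
    converted (probability ``f * p_inc``) and no sequencing error moved it
    off C, or when it was not converted but a sequencing error produced a C::

        rate = f * p_inc * (1 - e) + (1 - f * p_inc) * e / 3

    with ``f = new_fraction[condition]`` and ``e = seq_error``.  The formula
    is exact under the simulator's error model (uniform substitution among
    the 3 alternatives); SNP-carrying positions are not modeled here because
    the pipeline masks them.
    """
    if condition not in truth.new_fraction:
        raise KeyError(f"unknown condition {condition!r}")
    conv = truth.new_fraction[condition] * truth.p_inc
    return conv * (1.0 - seq_error) + (1.0 - conv) * seq_error / 3.0


def _sample_seed(config: SimConfig, sample: str) -> np.random.SeedSequence:
    idx = config.sample_names.index(sample)
    return np.random.SeedSequence([config.seed, 2, idx])


def simulate_reads(config: SimConfig, reference: Reference, truth: SimTruth,
                   sample: str) -> Iterator[tuple[str, str, str]]:
    """Yield ``(read_id, sequence, quality)`` for one library.

    Each read is 4 random nt + insert + 4 random nt + adapter (+ downstream
    filler), truncated to ``read_length``.  Molecules are drawn by expression
    weight; a molecule is "new" with probability ``new_fraction[condition]``
    (zero for the no-4SU control); each U of a new molecule converts with
    probability ``p_inc``; SNP alleles are applied before labeling and
    per-base errors last.  Qualities are constant.
    """
    config.validate()
    cond = config.condition_of_sample.get(sample)
    if cond is None:
        raise ValueError(f"unknown sample {sample!r}; known: {config.sample_names}")

    n = len(reference.features)
    seed_seq = _sample_seed(config, sample)
    rng = np.random.default_rng(seed_seq)
    pr = random.Random(int(rng.integers(0, 2**63)))

    n_reads = config.reads_per_sample
    seqs = [f.seq for f in reference.features]
    snps = [truth.snps.get(f.mirna_id, []) for f in reference.features]
    new_frac = truth.new_fraction[cond]
    p_inc = truth.p_inc
    L = config.read_length
    tail = config.adapter_seq + _DOWNSTREAM * (
        1 + L // max(1, len(_DOWNSTREAM)))
    flanks = ["".join(p) for p in _all_kmers(config.n_random_flank)]
    n_flank = len(flanks)

    mirna_idx = rng.choice(n, size=n_reads, p=truth.expression_weight)
    is_new = rng.random(n_reads) < new_frac[mirna_idx]
    err_counts = rng.binomial(L, config.seq_error, size=n_reads)

    for i in range(n_reads):
        m = int(mirna_idx[i])
        seq = seqs[m]
        for pos, alt, freq in snps[m]:
            if freq >= 1.0 or pr.random() < freq:
                seq = seq[:pos] + alt + seq[pos + 1:]
        if is_new[i]:
            conv = [j for j, b in enumerate(seq) if b == "T" and pr.random() < p_inc]
            for j in conv:
                seq = seq[:j] + "C" + seq[j + 1:]
        read = (flanks[pr.randrange(n_flank)] + seq
                + flanks[pr.randrange(n_flank)] + tail)[:L]
        k = int(err_counts[i])
        if k:
            read_l = list(read)
            for _ in range(k):
                p = pr.randrange(L)
                read_l[p] = _OTHER[read_l[p]][pr.randrange(3)] \
                    if read_l[p] in _OTHER else "N"
            read = "".join(read_l)
        yield (f"{sample}.{i} {reference.features[m].mirna_id}", read, "I" * L)


def _all_kmers(k: int) -> Iterable[tuple[str, ...]]:
    import itertools
    return itertools.product("ACGT", repeat=k)


# ---------------------------------------------------------------------------
# model-level simulation (no reads): draws the quantities the pipeline
# measures directly from the labeling model, for fast statistical studies
# ---------------------------------------------------------------------------

def simulate_profiles(config: SimConfig, reference: Reference, truth: SimTruth,
                      seed: Optional[int] = None) -> pd.DataFrame:
    """Draw per-(miRNA, sample) profiles directly from the labeling model.

    Read counts are multinomial in the expression weights; every read covers
    all reference-T positions of its miRNA, and each T observation converts
    independently with the analytic expected rate.  This bypasses read
    assembly, trimming and alignment, and is used for calibration studies
    that need hundreds of simulated datasets.
    """
    config.validate()
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed if seed is None else seed, 3]))
    ids = truth.mirna_ids
    n_t = np.array([f.seq.count("T") for f in reference.features])
    rows = []
    for sample in config.sample_names:
        cond = config.condition_of_sample[sample]
        rate = expected_conversion_rate(truth, cond, config.seq_error)
        counts = rng.multinomial(config.reads_per_sample, truth.expression_weight)
        t_cov = counts * n_t
        tc = rng.binomial(t_cov, rate)
        total = counts.sum()
        cpm = counts / total * 1e6 if total else np.zeros_like(counts, dtype=float)
        conv = np.divide(tc, t_cov, out=np.zeros(len(ids)), where=t_cov > 0)
        for j, mid in enumerate(ids):
            rows.append((sample, cond, mid, int(counts[j]), float(cpm[j]),
                         int(t_cov[j]), int(tc[j]), float(conv[j])))
    return pd.DataFrame(rows, columns=["sample", "condition", "unit", "read_count",
                                       "cpm", "t_coverage", "tc_count",
                                       "conversion_rate"])


# ---------------------------------------------------------------------------
# file output
# ---------------------------------------------------------------------------

def write_fastq(records: Iterable[tuple[str, str, str]], path: str | Path) -> int:
    """Write 4-line FASTQ records; gzip if the path ends in ``.gz``."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    n = 0
    with opener(path, "wt") as fh:
        for rid, seq, qual in records:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")
            n += 1
    return n


def write_reference(reference: Reference, outdir: str | Path) -> dict[str, Path]:
    """Write the reference bundle: mature FASTA, locus BED6, annotation TSV,
    curated-id list and the synthetic genome FASTA."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "mature_fasta": outdir / "mature.fa",
        "loci_bed": outdir / "loci.bed",
        "annotation_tsv": outdir / "annotation.tsv",
        "curated_txt": outdir / "curated.txt",
        "genome_fasta": outdir / "genome.fa",
    }
    SeqIO.write(
        [SeqRecord(Seq(f.seq), id=f.mirna_id, description="")
         for f in reference.features],
        paths["mature_fasta"], "fasta")
    with open(paths["loci_bed"], "w") as fh:
        for f in reference.features:
            for chrom, start, end, strand in f.loci:
                fh.write(f"{chrom}\t{start}\t{end}\t{f.mirna_id}\t0\t{strand}\n")
    reference.annotation_frame().to_csv(paths["annotation_tsv"], sep="\t",
                                        index=False)
    with open(paths["curated_txt"], "w") as fh:
        for mid in reference.curated_ids():
            fh.write(mid + "\n")
    SeqIO.write(
        [SeqRecord(Seq(seq), id=chrom, description="")
         for chrom, seq in reference.genome.items()],
        paths["genome_fasta"], "fasta")
    return paths


def simulate_study(config: SimConfig, outdir: str | Path,
                   gzip_fastq: bool = False) -> dict[str, Path]:
    """Generate the full study on disk: reference bundle, truth table and one
    FASTQ per sample.  Returns the path map."""
    outdir = Path(outdir)
    reference = generate_reference(config)
    truth = draw_truth(config, reference)
    paths = write_reference(reference, outdir)
    truth_path = outdir / "truth.tsv"
    truth.frame().to_csv(truth_path, sep="\t", index=False)
    paths["truth_tsv"] = truth_path
    ext = ".fastq.gz" if gzip_fastq else ".fastq"
    for sample in config.sample_names:
        p = outdir / f"{sample}{ext}"
        write_fastq(simulate_reads(config, reference, truth, sample), p)
        paths[sample] = p
    return paths
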