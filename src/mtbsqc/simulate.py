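"""Directional bisulfite library simulator for circular mtDNA.

The generator reproduces, with known ground truth, the three mechanisms
that create artifactual mitochondrial 5mC signals:

* **conversion failure** — each read draws its conversion rate from a
  two-component mixture: a majority at ``conversion_rate`` and a
  ``poor_conversion_fraction`` subpopulation at ``poor_conversion_rate``,
  whose retained cytosines mimic methylation;
* **degradation bias** — bisulfite attacks the cytosines it deaminates, so
  a fragment survives library preparation with probability
  ``exp(-degrade_c_rich x n_converted_cytosines)``.  C-rich (L-strand)
  fragments are preferentially lost, producing H/L depth ratios above 1,
  and poorly-converted fragments preferentially survive, concentrating in
  exactly the low-depth regions — the inverse depth/methylation artifact;
* **NUMT contamination** — a configurable fraction of reads is drawn from
  a methylated nuclear copy of an mtDNA interval (alleles substituted at
  its catalogued single-base differences) and mapped at the homologous
  mitochondrial coordinates, emulating forced alignment to the
  mitochondrial reference.

Fragments are drawn uniformly on the circle with wrap-around (the
pre-linearization state); linear mode forbids wrapping.  Output is
deterministic for a fixed config, including the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .calling import AlignedRead
from .numt import NumtRecord
from .reference import MtGenome, revcomp


@dataclass(frozen=True)
class NumtSpike:
    """Contaminate the library with reads from one NUMT locus."""

    locus_id: str
    fraction: float  # fraction of total reads drawn from the NUMT
    numt_methylation: float = 1.0  # per-cytosine methylation probability

    def __post_init__(self) -> None:
        if not 0 <= self.fraction <= 1 or not 0 <= self.numt_methylation <= 1:
            raise ValueError("fraction and numt_methylation must be in [0, 1]")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated library.

    ``target_depth_L`` / ``target_depth_H`` are the mean per-site depths
    aimed for *before* degradation dropout.  ``true_profile`` maps
    ``(position, strand)`` to a methylation probability; sites absent from
    the map are unmethylated.  ``degrade_c_rich`` is the decay constant k
    in the fragment-survival model ``exp(-k x converted-C count)``.
    """

    seed: int = 0
    target_depth_L: float = 50.0
    target_depth_H: float = 50.0
    fragment_len_mean: float = 250.0
    fragment_len_sd: float = 30.0
    read_len: int = 100
    conversion_rate: float = 1.0
    poor_conversion_fraction: float = 0.0
    poor_conversion_rate: float = 0.5
    true_profile: dict = field(default_factory=dict)
    numt_spike: NumtSpike | None = None
    seq_error_rate: float = 0.0
    degrade_c_rich: float = 0.0
    linear: bool = False  # forbid wrap-around (post-linearization library)

    def __post_init__(self) -> None:
        for name in (
            "conversion_rate",
            "poor_conversion_fraction",
            "poor_conversion_rate",
            "seq_error_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.fragment_len_mean < self.read_len:
            raise ValueError("fragment_len_mean must be >= read_len")
        if self.degrade_c_rich < 0:
            raise ValueError("degrade_c_rich must be >= 0")


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one emitted read."""

    read_id: str
    origin: str  # "MT" or "NUMT:<locus_id>"
    informative_strand: str
    meth_states: tuple[tuple[int, bool], ...]  # (plus position, methylated)


_BASES = np.frombuffer(b"ACGT", dtype="S1").astype("U1")


def simulate_library(
    genome: MtGenome,
    config: SimConfig,
    catalog: list[NumtRecord] | None = None,
) -> tuple[list[AlignedRead], list[TruthRecord]]:
    """Generate one directional library with per-read ground truth.

    Returns plus-strand-projected :class:`AlignedRead` records (the
    simulator plays the role of a perfect aligner, so NUMT reads appear at
    their homologous mitochondrial coordinates) and one
    :class:`TruthRecord` per read.
    """
    if config.numt_spike is not None and catalog is None:
        raise ValueError("numt_spike configured but no catalog supplied")
    rng = np.random.default_rng(config.seed)
    n = genome.length
    reads: list[AlignedRead] = []
    truth: list[TruthRecord] = []

    n_l = int(round(config.target_depth_L * n / config.read_len))
    n_h = int(round(config.target_depth_H * n / config.read_len))
    spike_rec = None
    n_spike = 0
    if config.numt_spike is not None:
        spike_rec = next(
            (r for r in catalog if r.locus_id == config.numt_spike.locus_id), None
        )
        if spike_rec is None:
            raise ValueError(f"locus {config.numt_spike.locus_id!r} not in catalog")
        f = config.numt_spike.fraction
        n_spike = int(round(f / (1.0 - f) * (n_l + n_h))) if f < 1 else n_l + n_h

    counter = 0
    for strand, count in (("L", n_l), ("H", n_h)):
        for _ in range(count):
            read = _draw_mt_read(genome, config, rng, strand, f"mt_{counter}")
            counter += 1
            if read is None:
                continue
            reads.append(read[0])
            truth.append(read[1])

    for i in range(n_spike):
        strand = "L" if rng.random() < 0.5 else "H"
        r, t = _draw_numt_read(genome, config, rng, spike_rec, strand, f"numt_{i}")
        reads.append(r)
        truth.append(t)
    return reads, truth


def emit(
    reads: list[AlignedRead],
    truth: list[TruthRecord],
    fmt: str,
    out_prefix: str,
    genome: MtGenome,
) -> list[str]:
    """Write a simulated library to disk; truth always goes to TSV.

    ``fmt`` is SAM (coordinates and class tag kept), FASTQ (sequencing
    orientation, coordinates lost — for external-aligner workflows) or TSV
    (mirrors the in-memory read model).  Returns the written paths.
    """
    from pathlib import Path

    from . import io as _io

    prefix = Path(out_prefix)
    if fmt == "SAM":
        p = prefix.with_suffix(".sam")
        _io.write_sam(reads, genome, p)
    elif fmt == "FASTQ":
        p = prefix.with_suffix(".fastq")
        _io.write_fastq(reads, genome, p)
    elif fmt == "TSV":
        p = prefix.with_suffix(".reads.tsv")
        _io.write_reads_tsv(reads, p)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    tp = prefix.with_suffix(".truth.tsv")
    _io.write_truth_tsv(truth, tp)
    return [str(p), str(tp)]


def _apply_seq_errors(bases: list[str], rng: np.random.Generator, rate: float) -> None:
    if rate <= 0:
        return
    for j in range(len(bases)):
        if rng.random() < rate:
            choices = [b for b in "ACGT" if b != bases[j]]
            bases[j] = choices[rng.integers(3)]


def _draw_mt_read(genome, config, rng, strand, read_id):
    """One genuine mitochondrial read, or None if the fragment degraded."""
    n = genome.length
    frag_len = max(config.read_len, int(round(rng.normal(config.fragment_len_mean, config.fragment_len_sd))))
    if config.linear or not genome.circular:
        if frag_len >= n:
            frag_len = n
        start = int(rng.integers(0, n - frag_len + 1))
    else:
        start = int(rng.integers(0, n))
    frag = genome.fetch(start, start + frag_len)

    plus_derived = (strand == "L") == genome.l_strand_is_plus
    target, converted_to = ("C", "T") if plus_derived else ("G", "A")

    poor = rng.random() < config.poor_conversion_fraction
    conv_rate = config.poor_conversion_rate if poor else config.conversion_rate

    frag_bases = list(frag)
    states = []
    n_converted = 0
    for j, b in enumerate(frag_bases):
        if b != target:
            continue
        pos = (start + j) % n if genome.circular else start + j
        p_meth = config.true_profile.get((pos, strand), 0.0)
        methylated = rng.random() < p_meth
        states.append((pos, methylated))
        if not methylated and rng.random() < conv_rate:
            frag_bases[j] = converted_to
            n_converted += 1
    # bisulfite-induced degradation scales with the deaminated-C load
    if config.degrade_c_rich > 0:
        if rng.random() > math.exp(-config.degrade_c_rich * n_converted):
            return None

    read_bases = frag_bases[: config.read_len] if plus_derived else frag_bases[-config.read_len:]
    read_start = start if plus_derived else start + frag_len - config.read_len
    read_states = tuple(
        (p, m) for p, m in states if _covers(read_start, config.read_len, p, n, genome.circular)
    )
    _apply_seq_errors(read_bases, rng, config.seq_error_rate)
    read = AlignedRead(
        read_id=read_id,
        mapped_start=read_start % n if genome.circular else read_start,
        aligned_bases="".join(read_bases),
        informative_strand=strand,
    )
    return read, TruthRecord(read_id, "MT", strand, read_states)


def _covers(start: int, length: int, pos: int, n: int, circular: bool) -> bool:
    if circular:
        return (pos - start) % n < length
    return start <= pos < start + length


def _draw_numt_read(genome, config, rng, rec: NumtRecord, strand, read_id):
    """One contaminating read drawn from the NUMT allele sequence."""
    n = genome.length
    spike = config.numt_spike
    numt_seq = rec.numt_sequence(genome)
    span = len(numt_seq)
    rl = min(config.read_len, span)
    off = int(rng.integers(0, span - rl + 1))
    start = rec.mt_start + off

    plus_derived = (strand == "L") == genome.l_strand_is_plus
    target, converted_to = ("C", "T") if plus_derived else ("G", "A")

    bases = list(numt_seq[off:off + rl])
    states = []
    for j, b in enumerate(bases):
        if b != target:
            continue
        pos = (start + j) % n if genome.circular else start + j
        methylated = rng.random() < spike.numt_methylation
        states.append((pos, methylated))
        if not methylated and rng.random() < config.conversion_rate:
            bases[j] = converted_to
    _apply_seq_errors(bases, rng, config.seq_error_rate)
    read = AlignedRead(
        read_id=read_id,
        mapped_start=start % n if genome.circular else start,
        aligned_bases="".join(bases),
        informative_strand=strand,
    )
    return read, TruthRecord(read_id, f"NUMT:{rec.locus_id}", strand, tuple(states))
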