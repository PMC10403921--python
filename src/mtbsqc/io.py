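"""Readers and writers for the package's file boundaries.

SAM is read and written through pysam.  Alignment records are mapped onto
the gapless plus-strand-projected read model used by the caller: positions
inside insertions are dropped, deletions yield an N (no observation).  The
informative read class is taken from the Bismark-style ``XG`` tag when
present (``CT`` = original top strand, ``GA`` = original bottom) and falls
back to the alignment strand bit.

The CX report is 1-based and tab-separated (name, position, strand symbol,
methylated count, unmethylated count, context, trinucleotide) in the
dialect popularized by Bismark; bedGraph output is 0-based half-open.
All other tables are plain TSV.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable

import pysam

from .calling import AlignedRead, Methylome
from .numt import NumtRecord, ReadOriginCall, SBD
from .reference import MtGenome, revcomp
from .simulate import TruthRecord

# -- SAM -------------------------------------------------------------------

_CLASS_TAG = "XG"  # CT -> plus/top-derived, GA -> minus/bottom-derived


def _class_from_record(rec: pysam.AlignedSegment, genome: MtGenome) -> str:
    plus_name, minus_name = ("L", "H") if genome.l_strand_is_plus else ("H", "L")
    if rec.has_tag(_CLASS_TAG):
        tag = rec.get_tag(_CLASS_TAG)
        if tag == "CT":
            return plus_name
        if tag == "GA":
            return minus_name
    return minus_name if rec.is_reverse else plus_name


def read_sam(path: str | Path, genome: MtGenome, require_mapped: bool = True) -> list[AlignedRead]:
    """Load alignments as plus-strand-projected :class:`AlignedRead` records."""
    reads: list[AlignedRead] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                if require_mapped:
                    continue
                raise ValueError(f"unmapped record {rec.query_name}")
            bases = _project_bases(rec)
            quals = _project_quals(rec)
            mate_id = None
            if rec.is_paired:
                mate_id = rec.query_name + ("/2" if rec.is_read1 else "/1")
            read_id = rec.query_name
            if rec.is_paired:
                read_id += "/1" if rec.is_read1 else "/2"
            reads.append(
                AlignedRead(
                    read_id=read_id,
                    mapped_start=rec.reference_start,
                    aligned_bases=bases,
                    informative_strand=_class_from_record(rec, genome),
                    mapq=rec.mapping_quality,
                    mate_id=mate_id,
                    base_quals=quals,
                )
            )
    return reads


def _project_bases(rec: pysam.AlignedSegment) -> str:
    """Reference-projected query bases; deletions become N, insertions drop."""
    if rec.cigartuples is None or all(op == 0 for op, _ in rec.cigartuples):
        return (rec.query_sequence or "").upper()
    span = rec.reference_end - rec.reference_start
    out = ["N"] * span
    seq = rec.query_sequence or ""
    for qpos, rpos in rec.get_aligned_pairs(matches_only=False):
        if rpos is None or not (rec.reference_start <= rpos < rec.reference_end):
            continue
        if qpos is not None:
            out[rpos - rec.reference_start] = seq[qpos].upper()
    return "".join(out)


def _project_quals(rec: pysam.AlignedSegment) -> list[int] | None:
    if rec.query_qualities is None:
        return None
    if rec.cigartuples is None or all(op == 0 for op, _ in rec.cigartuples):
        return list(rec.query_qualities)
    span = rec.reference_end - rec.reference_start
    out = [0] * span
    for qpos, rpos in rec.get_aligned_pairs(matches_only=False):
        if rpos is None or not (rec.reference_start <= rpos < rec.reference_end):
            continue
        if qpos is not None:
            out[rpos - rec.reference_start] = rec.query_qualities[qpos]
    return out


def write_sam(
    reads: Iterable[AlignedRead], genome: MtGenome, path: str | Path
) -> None:
    """Write plus-projected reads as SAM.

    Reads of the minus-derived class get the reverse FLAG bit and both
    classes carry the ``XG`` class tag.  A read wrapping the circular
    origin cannot be represented as one gapless SAM record and is split in
    two records sharing the read name (second part flagged supplementary);
    piling the split parts back up reproduces the original counts.
    """
    n = genome.length
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": genome.name, "LN": n}],
    }
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for read in reads:
            start = read.mapped_start % n
            parts = []
            if start + len(read.aligned_bases) <= n:
                parts.append((start, read.aligned_bases, False))
            else:
                split = n - start
                parts.append((start, read.aligned_bases[:split], False))
                parts.append((0, read.aligned_bases[split:], True))
            plus_derived = (read.informative_strand == "L") == genome.l_strand_is_plus
            for pstart, pbases, supplementary in parts:
                rec = pysam.AlignedSegment()
                rec.query_name = read.read_id
                rec.reference_id = 0
                rec.reference_start = pstart
                rec.mapping_quality = read.mapq
                rec.cigarstring = f"{len(pbases)}M"
                rec.query_sequence = pbases
                rec.flag = (0 if plus_derived else 16) | (2048 if supplementary else 0)
                rec.set_tag(_CLASS_TAG, "CT" if plus_derived else "GA")
                out.write(rec)


def write_fastq(reads: Iterable[AlignedRead], genome: MtGenome, path: str | Path) -> int:
    """Write reads as FASTQ in sequencing orientation (coordinates lost).

    Minus-derived reads are reverse-complemented back to the sequence the
    instrument actually produced.  Returns the number of records written.
    """
    count = 0
    with open(path, "w") as fh:
        for read in reads:
            plus_derived = (read.informative_strand == "L") == genome.l_strand_is_plus
            seq = read.aligned_bases if plus_derived else revcomp(read.aligned_bases)
            fh.write(f"@{read.read_id}\n{seq}\n+\n{'I' * len(seq)}\n")
            count += 1
    return count


# -- TSV read/truth tables -------------------------------------------------

READS_TSV_COLUMNS = ["read_id", "mapped_start", "informative_strand", "mapq", "mate_id", "aligned_bases"]


def write_reads_tsv(reads: Iterable[AlignedRead], path: str | Path) -> int:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(READS_TSV_COLUMNS)
        count = 0
        for r in reads:
            w.writerow([r.read_id, r.mapped_start, r.informative_strand, r.mapq, r.mate_id or ".", r.aligned_bases])
            count += 1
    return count


def read_reads_tsv(path: str | Path) -> list[AlignedRead]:
    reads = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            reads.append(
                AlignedRead(
                    read_id=row["read_id"],
                    mapped_start=int(row["mapped_start"]),
                    aligned_bases=row["aligned_bases"],
                    informative_strand=row["informative_strand"],
                    mapq=int(row["mapq"]),
                    mate_id=None if row["mate_id"] == "." else row["mate_id"],
                )
            )
    return reads


def write_truth_tsv(truth: Iterable[TruthRecord], path: str | Path) -> int:
    """Truth table: read_id, origin, class, and `pos:state` methylation list."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["read_id", "origin", "informative_strand", "meth_states"])
        count = 0
        for t in truth:
            states = ",".join(f"{p}:{int(m)}" for p, m in t.meth_states) or "."
            w.writerow([t.read_id, t.origin, t.informative_strand, states])
            count += 1
    return count


def read_truth_tsv(path: str | Path) -> list[TruthRecord]:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            states = ()
            if row["meth_states"] != ".":
                states = tuple(
                    (int(p), bool(int(m)))
                    for p, m in (kv.split(":") for kv in row["meth_states"].split(","))
                )
            out.append(
                TruthRecord(row["read_id"], row["origin"], row["informative_strand"], states)
            )
    return out


# -- methylome exports -----------------------------------------------------

def write_cx_report(
    methylome: Methylome, path: str | Path, collapse_cph: bool = True
) -> None:
    """Per-cytosine CX report, 1-based, zero-depth sites included.

    With ``collapse_cph`` (default) the context column reads CpG/CpH;
    otherwise CpH is split into CHG/CHH from the trinucleotide.
    """
    genome = methylome.genome
    plus_name = "L" if genome.l_strand_is_plus else "H"
    with open(path, "w") as fh:
        for i, s in enumerate(methylome.sites):
            symbol = "+" if s.strand == plus_name else "-"
            ctx = s.context
            if not collapse_cph and ctx == "CpH":
                ctx = "CHG" if s.trinucleotide[2] == "G" else "CHH"
            fh.write(
                f"{genome.name}\t{s.position + 1}\t{symbol}\t"
                f"{methylome.n_meth[i]}\t{methylome.n_unmeth[i]}\t{ctx}\t{s.trinucleotide}\n"
            )


def write_bedgraph(
    methylome: Methylome, path: str | Path, strand: str, track: str = "level"
) -> None:
    """Single-strand bedGraph of per-site level or depth (0-based half-open).

    Zero-depth sites are omitted from the level track (their level is
    undefined) but kept, as zeros, in the depth track.
    """
    if track not in ("level", "depth"):
        raise ValueError(f"track must be 'level' or 'depth', got {track!r}")
    levels = methylome.levels
    depth = methylome.depth
    name = methylome.genome.name
    with open(path, "w") as fh:
        for i, s in enumerate(methylome.sites):
            if s.strand != strand:
                continue
            if track == "level":
                if depth[i] == 0:
                    continue
                value = f"{levels[i]:.6g}"
            else:
                value = str(int(depth[i]))
            fh.write(f"{name}\t{s.position}\t{s.position + 1}\t{value}\n")


# -- NUMT catalog ----------------------------------------------------------

def write_catalog_tsv(catalog: Iterable[NumtRecord], path: str | Path) -> None:
    """Catalog TSV: locus_id, mt_start, mt_end, comma-separated pos:mt>numt."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["locus_id", "mt_start", "mt_end", "sbds"])
        for rec in catalog:
            sbds = ",".join(f"{s.mt_position}:{s.mt_base}>{s.numt_base}" for s in rec.sbds) or "."
            w.writerow([rec.locus_id, rec.mt_start, rec.mt_end, sbds])


def read_catalog_tsv(path: str | Path) -> list[NumtRecord]:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            sbds = []
            if row["sbds"] != ".":
                for item in row["sbds"].split(","):
                    pos, alleles = item.split(":")
                    mt_base, numt_base = alleles.split(">")
                    sbds.append(SBD(int(pos), mt_base, numt_base))
            out.append(NumtRecord(row["locus_id"], int(row["mt_start"]), int(row["mt_end"]), sbds))
    return out


def write_origin_calls_tsv(calls: Iterable[ReadOriginCall], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow([
            "read_id", "verdict", "informative_sbds_covered",
            "mt_allele_matches", "numt_allele_matches", "unconverted_c_count",
        ])
        for c in calls:
            w.writerow([
                c.read_id, c.verdict, c.informative_sbds_covered,
                c.mt_allele_matches, c.numt_allele_matches, c.unconverted_c_count,
            ])


# -- qPCR Ct tables --------------------------------------------------------

def read_ct_table(path: str | Path) -> list[dict]:
    """Ct TSV with columns sample, condition, target, ct (one replicate/row)."""
    rows = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            rows.append(
                {
                    "sample": row["sample"],
                    "condition": row["condition"],
                    "target": row["target"],
                    "ct": float(row["ct"]),
                }
            )
    return rows
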