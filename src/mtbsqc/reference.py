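"""Circular mitochondrial reference handling.

The mammalian mitochondrial genome is a ~16.5 kb circular duplex whose two
strands differ sharply in base composition: the light (L) strand is
cytosine-rich, the heavy (H) strand guanine-rich.  By convention the
deposited reference plus strand is treated as the L strand (this matches
both mouse chrM and the human rCRS, whose plus strands are C-rich); the
convention is overridable because strand naming varies across references.

Coordinates are 0-based, half-open everywhere in this package; 1-based
coordinates appear only in the CX-report output dialect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string over ACGTN."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MtGenome:
    """A (usually circular) mitochondrial reference sequence.

    Attributes
    ----------
    name : str
        Sequence label from the FASTA header.
    sequence : str
        Upper-case DNA over ``{A, C, G, T, N}``.
    circular : bool
        Whether coordinates wrap around the origin.
    l_strand_is_plus : bool
        If True (default) the deposited plus strand is the L strand.
    """

    name: str
    sequence: str
    circular: bool = True
    l_strand_is_plus: bool = True

    def __post_init__(self) -> None:
        bad = set(self.sequence) - VALID_BASES
        if bad:
            pos = next(i for i, b in enumerate(self.sequence) if b in bad)
            raise ValueError(
                f"invalid base {self.sequence[pos]!r} at position {pos} in {self.name!r}"
            )
        if not self.sequence:
            raise ValueError("empty sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def __len__(self) -> int:
        return len(self.sequence)

    def base(self, i: int) -> str:
        """Base at position ``i``; wraps modulo length when circular."""
        if self.circular:
            return self.sequence[i % self.length]
        if not 0 <= i < self.length:
            raise IndexError(f"position {i} outside linear genome of length {self.length}")
        return self.sequence[i]

    def fetch(self, start: int, end: int) -> str:
        """Substring ``[start, end)``; wraps across the origin when circular."""
        if end < start:
            raise ValueError("end < start")
        if self.circular:
            n = self.length
            return "".join(self.sequence[i % n] for i in range(start, end))
        if start < 0 or end > self.length:
            raise IndexError(f"[{start}, {end}) outside linear genome")
        return self.sequence[start:end]

    def rotate(self, k: int) -> "MtGenome":
        """Rotated copy: old position ``i`` moves to ``(i + k) mod length``."""
        if not self.circular:
            raise ValueError("cannot rotate a linear genome")
        n = self.length
        k %= n
        return MtGenome(
            name=self.name,
            sequence=self.sequence[n - k:] + self.sequence[: n - k],
            circular=True,
            l_strand_is_plus=self.l_strand_is_plus,
        )


@dataclass(frozen=True, order=True)
class CytosineSite:
    """One cytosine on one strand of the mitochondrial duplex.

    ``position`` is the 0-based plus-strand coordinate.  L-strand sites sit
    at plus-strand C positions, H-strand sites at plus-strand G positions
    (under the default strand convention).  ``context`` is CpG when the base
    following the cytosine *on its own strand* is G, otherwise CpH.
    ``trinucleotide`` is read 5'->3' on the site's own strand.
    """

    position: int
    strand: str  # "L" or "H"
    context: str  # "CpG" or "CpH"
    trinucleotide: str


@dataclass(frozen=True)
class IdenticalRegion:
    """An mtDNA interval whose sequence occurs verbatim in a nuclear locus."""

    mt_start: int
    mt_end: int  # half-open
    nuclear_locus: str

    @property
    def length(self) -> int:
        return self.mt_end - self.mt_start

    def contains(self, position: int) -> bool:
        return self.mt_start <= position < self.mt_end


def load_genome(
    fasta_path: str | Path,
    circular: bool = True,
    l_strand_is_plus: bool = True,
) -> MtGenome:
    """Load a single-record FASTA as an :class:`MtGenome`.

    Raises ``ValueError`` for multi-record files (naming the record count)
    and for non-ACGTN characters (naming the offending position).
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(records) != 1:
        raise ValueError(
            f"expected a single-record FASTA, got {len(records)} records in {fasta_path}"
        )
    seq = str(records[0].seq).upper().replace(" ", "")
    return MtGenome(
        name=records[0].id,
        sequence=seq,
        circular=circular,
        l_strand_is_plus=l_strand_is_plus,
    )


def _site_at(genome: MtGenome, pos: int) -> CytosineSite | None:
    """Cytosine site at plus-strand position ``pos``, or None."""
    n = genome.length
    b = genome.sequence[pos]
    # strand naming honours the convention flag
    plus_name, minus_name = ("L", "H") if genome.l_strand_is_plus else ("H", "L")
    if b == "C":
        # cytosine on the plus strand; next base downstream on the plus strand
        if genome.circular:
            tri = "".join(genome.sequence[(pos + d) % n] for d in range(3))
        else:
            tri = genome.sequence[pos:pos + 3].ljust(3, "N")
        context = "CpG" if tri[1] == "G" else "CpH"
        return CytosineSite(pos, plus_name, context, tri)
    if b == "G":
        # cytosine on the minus strand; its 5'->3' trinucleotide is the
        # reverse complement of plus [pos-2, pos+1)
        if genome.circular:
            window = "".join(genome.sequence[(pos + d) % n] for d in (-2, -1, 0))
        else:
            window = genome.sequence[max(pos - 2, 0):pos + 1].rjust(3, "N")
        tri = revcomp(window)
        context = "CpG" if tri[1] == "G" else "CpH"
        return CytosineSite(pos, minus_name, context, tri)
    return None


def index_cytosines(genome: MtGenome) -> list[CytosineSite]:
    """Enumerate all cytosine sites on both strands, sorted by position.

    One site per plus-strand C (L strand) and per plus-strand G (H strand);
    N bases form no site.  For circular genomes the trinucleotide context
    wraps across the origin.
    """
    sites = []
    for pos in range(genome.length):
        s = _site_at(genome, pos)
        if s is not None:
            sites.append(s)
    return sites


def count_strand_cytosines(genome: MtGenome) -> tuple[int, int]:
    """Total cytosines per strand as ``(l_count, h_count)``.

    Under the default convention these are the plus-strand C and G counts;
    context is not stratified.
    """
    c = genome.sequence.count("C")
    g = genome.sequence.count("G")
    return (c, g) if genome.l_strand_is_plus else (g, c)


def find_identical_regions(
    genome: MtGenome,
    nuclear_seqs: Mapping[str, str],
    min_len: int = 30,
) -> list[IdenticalRegion]:
    """Maximal exact substrings shared between mtDNA and nuclear sequences.

    Both orientations of each nuclear sequence are searched (equivalently,
    both strands of the mtDNA).  Hits are reported as plus-strand mtDNA
    intervals and merged per nuclear locus.  ``min_len`` must be >= 20:
    shorter exact matches are ubiquitous at read scale and carry no
    information about read origin.
    """
    if min_len < 20:
        raise ValueError("min_len must be >= 20")
    mt = genome.sequence
    # seed index over the mt sequence (doubled for circular wrap-around)
    doubled = mt + mt[: min_len - 1] if genome.circular else mt
    k = min_len
    seeds: dict[str, list[int]] = {}
    for i in range(len(doubled) - k + 1):
        seeds.setdefault(doubled[i:i + k], []).append(i)

    by_locus: dict[str, list[tuple[int, int]]] = {}
    n = genome.length
    for locus, raw in nuclear_seqs.items():
        nuc_fwd = raw.upper()
        intervals: set[tuple[int, int]] = set()
        for nuc in (nuc_fwd, revcomp(nuc_fwd)):
            for j in range(len(nuc) - k + 1):
                for i in seeds.get(nuc[j:j + k], ()):  # extend each seed maximally
                    # extend left
                    li, lj = i, j
                    while li > 0 and lj > 0 and doubled[li - 1] == nuc[lj - 1]:
                        li -= 1
                        lj -= 1
                    # extend right
                    ri, rj = i + k, j + k
                    while ri < len(doubled) and rj < len(nuc) and doubled[ri] == nuc[rj]:
                        ri += 1
                        rj += 1
                    if ri - li >= min_len:
                        intervals.add((li % n, li % n + (ri - li)))
        if intervals:
            by_locus.setdefault(locus, []).extend(intervals)

    # intervals from wrap-around matches may extend past the origin
    # (mt_end > genome length); callers test membership modulo length
    regions: list[IdenticalRegion] = []
    for locus, ivals in by_locus.items():
        for start, end in _merge_intervals(sorted(set(ivals))):
            regions.append(IdenticalRegion(start, end, locus))
    regions.sort(key=lambda r: (r.mt_start, r.nuclear_locus))
    return regions


def _merge_intervals(ivals: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for s, e in ivals:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def regions_to_bed(regions: Iterable[IdenticalRegion], genome_name: str) -> str:
    """Render identical regions as 4-column BED text (0-based half-open)."""
    lines = [
        f"{genome_name}\t{r.mt_start}\t{r.mt_end}\t{r.nuclear_locus}"
        for r in regions
    ]
    return "\n".join(lines) + ("\n" if lines else "")
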