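"""NUMT-aware read attribution in bisulfite space.

Nuclear mitochondrial segments (NUMTs) are nuclear-genome copies of mtDNA.
Because aligners tolerate mismatches, methylated NUMT-derived reads can be
forced onto the mitochondrial reference, where their retained cytosines
masquerade as mtDNA 5mC.  The single-base differences (SBDs) that have
accumulated between a NUMT and its mtDNA homologue let a read's origin be
attributed — but only in *bisulfite space*: after conversion every
unmethylated C reads as T, so an mt-C/numt-T difference is invisible to
reads that report the C-containing strand (and mt-G/numt-A to reads of the
other class).  Such SBDs are recorded but carry no evidence for the blind
read class.

The workflow here formalizes the manual inspection of alignments: build a
catalog of candidate NUMT loci with their SBDs, score each read's alleles
against mtDNA vs. each NUMT in the space its class can see, test whether
unconverted cytosines co-occur with NUMT alleles on the same reads, and
recompute methylation after dropping foreign reads.  Ties or zero
informative coverage never assign an origin: indistinguishable reads are
AMBIGUOUS, not evidence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _sps

from .calling import AlignedRead, Methylome, call_methylation
from .reference import MtGenome, revcomp

_BS_L = str.maketrans("C", "T")
_BS_H = str.maketrans("G", "A")


def read_bisulfite_space(seq: str, read_class: str) -> str:
    """Collapse ``seq`` into the three-letter space seen by a read class.

    L-informative comparisons replace every C with T; H-informative every G
    with A.  This is the space in which a bisulfite read must be compared
    to candidate references, since the pre-conversion sequence cannot be
    uniquely recovered.  Idempotent.
    """
    if read_class == "L":
        return seq.translate(_BS_L)
    if read_class == "H":
        return seq.translate(_BS_H)
    raise ValueError(f"read_class must be L or H, got {read_class!r}")


@dataclass(frozen=True)
class SBD:
    """A single-base difference between mtDNA and a NUMT copy.

    ``informative_for`` lists the read classes for which the two alleles
    remain distinguishable after bisulfite collapse; a C/T difference is
    blind to L-informative reads, a G/A difference to H-informative ones.
    """

    mt_position: int
    mt_base: str
    numt_base: str

    def __post_init__(self) -> None:
        if self.mt_base == self.numt_base:
            raise ValueError("SBD bases must differ")

    @property
    def informative_for(self) -> frozenset[str]:
        classes = []
        for cls in ("L", "H"):
            if read_bisulfite_space(self.mt_base, cls) != read_bisulfite_space(
                self.numt_base, cls
            ):
                classes.append(cls)
        return frozenset(classes)


@dataclass
class NumtRecord:
    """One NUMT locus: its homologous mtDNA interval and SBD catalog."""

    locus_id: str
    mt_start: int
    mt_end: int  # half-open, plus-strand mtDNA coordinates
    sbds: list[SBD] = field(default_factory=list)

    @property
    def identical(self) -> bool:
        return not self.sbds

    def overlaps(self, start: int, end: int) -> bool:
        return start < self.mt_end and end > self.mt_start

    def numt_sequence(self, genome: MtGenome) -> str:
        """NUMT allele sequence over the mt interval (SBDs substituted)."""
        seq = list(genome.fetch(self.mt_start, self.mt_end))
        for s in self.sbds:
            seq[s.mt_position - self.mt_start] = s.numt_base
        return "".join(seq)


@dataclass(frozen=True)
class ReadOriginCall:
    read_id: str
    verdict: str  # "MT", "NUMT:<locus_id>", "AMBIGUOUS"
    informative_sbds_covered: int
    mt_allele_matches: int
    numt_allele_matches: int
    unconverted_c_count: int

    @property
    def is_numt(self) -> bool:
        return self.verdict.startswith("NUMT:")


def build_numt_catalog(
    genome: MtGenome,
    nuclear_seqs: dict[str, str],
    min_len: int = 50,
    seed_k: int = 16,
) -> list[NumtRecord]:
    """Locate each nuclear sequence on the mtDNA and catalog its SBDs.

    Each nuclear sequence is placed by its best gapless match (seed vote
    over ``seed_k``-mers, both orientations, wrap-around aware); sequences
    with no seed match of at least ``min_len`` aligned length are skipped
    with a warning.  All SBDs are retained, including the C/T and G/A
    classes that are blind to one read class — each carries its own
    ``informative_for`` annotation.
    """
    n = genome.length
    doubled = genome.sequence + (genome.sequence if genome.circular else "")
    index: dict[str, list[int]] = {}
    limit = len(doubled) - seed_k + 1 if genome.circular else n - seed_k + 1
    for i in range(limit):
        index.setdefault(doubled[i:i + seed_k], []).append(i)

    records: list[NumtRecord] = []
    for locus, raw in nuclear_seqs.items():
        best = None  # (votes, offset, oriented_seq)
        for nuc in (raw.upper(), revcomp(raw.upper())):
            votes: dict[int, int] = {}
            for j in range(len(nuc) - seed_k + 1):
                for i in index.get(nuc[j:j + seed_k], ()):
                    off = (i - j) % n if genome.circular else i - j
                    votes[off] = votes.get(off, 0) + 1
            if votes:
                off, v = max(votes.items(), key=lambda kv: kv[1])
                if best is None or v > best[0]:
                    best = (v, off, nuc)
        if best is None:
            warnings.warn(f"nuclear sequence {locus!r}: no match to mtDNA; skipped")
            continue
        _, off, nuc = best
        if not genome.circular and off < 0:
            nuc = nuc[-off:]  # clip left overhang past the reference start
            off = 0
        usable = min(len(nuc), n - off) if not genome.circular else len(nuc)
        if usable < min_len:
            warnings.warn(f"nuclear sequence {locus!r}: match shorter than {min_len}; skipped")
            continue
        mt_sub = genome.fetch(off, off + usable)
        sbds = [
            SBD(mt_position=(off + j) % n if genome.circular else off + j,
                mt_base=mt_sub[j], numt_base=nuc[j])
            for j in range(usable)
            if mt_sub[j] != nuc[j] and mt_sub[j] != "N" and nuc[j] != "N"
        ]
        records.append(NumtRecord(locus_id=locus, mt_start=off, mt_end=off + usable, sbds=sbds))
    records.sort(key=lambda r: (r.mt_start, r.locus_id))
    return records


def _read_positions(read: AlignedRead, glen: int, circular: bool):
    for j, b in enumerate(read.aligned_bases):
        pos = (read.mapped_start + j) % glen if circular else read.mapped_start + j
        yield pos, b


def classify_read_origin(
    read: AlignedRead, genome: MtGenome, catalog: list[NumtRecord]
) -> ReadOriginCall:
    """Attribute one read to mtDNA or a NUMT locus via SBD alleles.

    Over the SBDs the read covers that are informative for its class, the
    read's base (in bisulfite space) is matched against the mt and NUMT
    alleles.  The locus with the highest ``numt − mt`` margin wins if that
    margin is positive and strictly beats every other locus; a read whose
    mt matches dominate every locus is MT; everything else — zero
    informative coverage or any tie — is AMBIGUOUS.  Reads overlapping no
    catalog interval are MT by convention (no evidence against).
    """
    cls = read.informative_strand
    glen = genome.length
    # base calls by mt position, collapsed to the read class's space
    obs = {
        pos: read_bisulfite_space(b, cls)
        for pos, b in _read_positions(read, glen, genome.circular)
        if b != "N"
    }
    unconverted = _unconverted_c_count(read, genome)

    per_locus: dict[str, tuple[int, int]] = {}
    covered_any = 0
    for rec in catalog:
        mt_m = numt_m = cov = 0
        for sbd in rec.sbds:
            if cls not in sbd.informative_for or sbd.mt_position not in obs:
                continue
            cov += 1
            b = obs[sbd.mt_position]
            if b == read_bisulfite_space(sbd.mt_base, cls):
                mt_m += 1
            elif b == read_bisulfite_space(sbd.numt_base, cls):
                numt_m += 1
        if cov:
            per_locus[rec.locus_id] = (mt_m, numt_m)
            covered_any += cov

    if not per_locus:
        overlapping = any(
            rec.overlaps(read.mapped_start, read.mapped_end) for rec in catalog
        )
        verdict = "AMBIGUOUS" if overlapping else "MT"
        return ReadOriginCall(read.read_id, verdict, 0, 0, 0, unconverted)

    margins = {loc: nm - mm for loc, (mm, nm) in per_locus.items()}
    best_loc = max(margins, key=margins.get)
    best = margins[best_loc]
    runner_up = max((m for loc, m in margins.items() if loc != best_loc), default=None)
    mt_m, numt_m = per_locus[best_loc]
    if best > 0 and (runner_up is None or best > runner_up):
        verdict = f"NUMT:{best_loc}"
    elif all(m < 0 for m in margins.values()):
        verdict = "MT"
    else:
        verdict = "AMBIGUOUS"
    return ReadOriginCall(read.read_id, verdict, covered_any, mt_m, numt_m, unconverted)


def _unconverted_c_count(read: AlignedRead, genome: MtGenome) -> int:
    """Retained-cytosine observations on this read (C at plus-C for
    plus-derived reads, G at plus-G for minus-derived)."""
    plus_derived = (read.informative_strand == "L") == genome.l_strand_is_plus
    ref_base, retained = ("C", "C") if plus_derived else ("G", "G")
    count = 0
    for pos, b in _read_positions(read, genome.length, genome.circular):
        if genome.sequence[pos] == ref_base and b == retained:
            count += 1
    return count


@dataclass(frozen=True)
class CooccurrenceResult:
    """2x2 association between NUMT-allele carriage and non-conversion.

    Rows: read carries >= 1 NUMT allele at an informative SBD (yes/no);
    columns: read is unconverted at the flagged cytosine (yes/no).
    ``odds_ratio`` uses the Haldane 0.5 correction when any cell is zero;
    ``p_value`` is two-sided Fisher exact, None when no covering read also
    covers an informative SBD (degenerate table).
    """

    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float | None
    p_value: float | None
    n_reads: int


def sbd_cooccurrence(
    reads: list[AlignedRead],
    site_position: int,
    site_strand: str,
    genome: MtGenome,
    catalog: list[NumtRecord],
) -> CooccurrenceResult:
    """Test whether unconverted Cs ride on the same reads as NUMT alleles.

    Considers reads of the site's informative class covering the flagged
    cytosine.  Misaligned methylated NUMT reads produce both the retained
    cytosine and the NUMT alleles, so the association is strongly positive
    when the signal is a NUMT artifact.
    """
    glen = genome.length
    plus_derived = (site_strand == "L") == genome.l_strand_is_plus
    meth_base = "C" if plus_derived else "G"
    unmeth_base = "T" if plus_derived else "A"

    table = np.zeros((2, 2), dtype=np.int64)
    n_considered = 0
    any_sbd_covered = False
    for read in reads:
        if read.informative_strand != site_strand:
            continue
        base_at = None
        for pos, b in _read_positions(read, glen, genome.circular):
            if pos == site_position:
                base_at = b
                break
        if base_at not in (meth_base, unmeth_base):
            continue
        n_considered += 1
        call = classify_read_origin(read, genome, catalog)
        if call.informative_sbds_covered > 0:
            any_sbd_covered = True
        carries = call.numt_allele_matches > 0
        unconv = base_at == meth_base
        table[0 if carries else 1][0 if unconv else 1] += 1

    if n_considered == 0:
        raise ValueError("no read covers the flagged site")
    if not any_sbd_covered:
        return CooccurrenceResult(tuple(map(tuple, table)), None, None, n_considered)

    a, b_, c, d = table[0, 0], table[0, 1], table[1, 0], table[1, 1]
    if 0 in (a, b_, c, d):
        orr = float((a + 0.5) * (d + 0.5) / ((b_ + 0.5) * (c + 0.5)))
    else:
        orr = float(a * d / (b_ * c))
    _, p = _sps.fisher_exact(table, alternative="two-sided")
    return CooccurrenceResult(tuple(map(tuple, table)), orr, float(p), n_considered)


def annotate_numt_suspects(
    flags,
    reads: list[AlignedRead],
    genome: MtGenome,
    catalog: list[NumtRecord],
    origin_calls: dict[str, ReadOriginCall] | None = None,
):
    """Attach NUMT_SUSPECT to flagged sites covered by >= 1 NUMT-verdict read."""
    from .qc import FLAG_NUMT_SUSPECT

    if origin_calls is None:
        origin_calls = {r.read_id: classify_read_origin(r, genome, catalog) for r in reads}
    glen = genome.length
    numt_read_ids = {rid for rid, c in origin_calls.items() if c.is_numt}
    for f in flags:
        for read in reads:
            if read.read_id not in numt_read_ids:
                continue
            if read.informative_strand != f.site.strand:
                continue
            covered = any(
                pos == f.site.position
                for pos, _ in _read_positions(read, glen, genome.circular)
            )
            if covered:
                f.reasons.add(FLAG_NUMT_SUSPECT)
                break
    return flags


@dataclass(frozen=True)
class SiteDelta:
    position: int
    strand: str
    old_level: float | None
    new_level: float | None
    old_depth: int
    new_depth: int


def filter_and_recompute(
    methylome: Methylome,
    reads: list[AlignedRead],
    origin_calls: dict[str, ReadOriginCall],
    policy: str = "drop_numt",
    min_mapq: int = 0,
) -> tuple[Methylome, list[SiteDelta]]:
    """Rebuild the methylome after dropping reads of foreign origin.

    ``policy`` is ``drop_numt`` (drop only NUMT verdicts) or
    ``drop_numt_and_ambiguous``.  Counts are conserved: original = corrected
    + dropped, per site.  The delta report lists every site whose depth or
    level changed.
    """
    if policy not in ("drop_numt", "drop_numt_and_ambiguous"):
        raise ValueError(f"unknown policy {policy!r}")

    def dropped(read: AlignedRead) -> bool:
        call = origin_calls.get(read.read_id)
        if call is None:
            return False
        if call.is_numt:
            return True
        return policy == "drop_numt_and_ambiguous" and call.verdict == "AMBIGUOUS"

    kept = [r for r in reads if not dropped(r)]
    corrected = call_methylation(kept, methylome.genome, min_mapq=min_mapq)

    deltas: list[SiteDelta] = []
    old_d, new_d = methylome.depth, corrected.depth
    old_lv, new_lv = methylome.levels, corrected.levels
    for i, site in enumerate(methylome.sites):
        if old_d[i] == new_d[i] and (
            (np.isnan(old_lv[i]) and np.isnan(new_lv[i])) or old_lv[i] == new_lv[i]
        ):
            continue
        deltas.append(
            SiteDelta(
                position=site.position,
                strand=site.strand,
                old_level=None if np.isnan(old_lv[i]) else float(old_lv[i]),
                new_level=None if np.isnan(new_lv[i]) else float(new_lv[i]),
                old_depth=int(old_d[i]),
                new_depth=int(new_d[i]),
            )
        )
    return corrected, deltas
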