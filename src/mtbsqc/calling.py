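"""Strand-specific methylation calling from aligned bisulfite reads.

In a directional bisulfite library every read belongs to one of two
informative classes.  L-informative reads derive from the L (plus, C-rich)
strand and report C (methylated, unconverted) or T (unmethylated,
converted) at reference-C positions; H-informative reads derive from the H
strand and, projected onto plus-strand coordinates, report G or A at
reference-G positions.  A read contributes nothing to sites of the other
strand, and bases other than the two informative states (sequencing errors,
N) contribute to neither count.

Per-cytosine calls are kept for *every* site, including zero-depth ones,
which are reported as undefined rather than 0 so that downstream summaries
cannot be silently deflated.  No depth cutoff is applied at calling time:
on mtDNA depth is a relative quantity and filtering belongs to QC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .reference import CytosineSite, MtGenome, index_cytosines, revcomp


@dataclass
class AlignedRead:
    """One aligned bisulfite read in plus-strand projection.

    ``aligned_bases`` is matched base-per-base to reference positions
    ``mapped_start, mapped_start+1, ...`` (gapless core model; deletions are
    represented as N, insertions are dropped by the SAM reader).  Positions
    may wrap past the reference end only for simulator-produced records on a
    circular genome.
    """

    read_id: str
    mapped_start: int
    aligned_bases: str
    informative_strand: str  # "L" or "H"
    mapq: int = 60
    mate_id: str | None = None
    base_quals: list[int] | None = None

    def __post_init__(self) -> None:
        if self.informative_strand not in ("L", "H"):
            raise ValueError(f"informative_strand must be L or H, got {self.informative_strand!r}")

    @property
    def mapped_end(self) -> int:
        return self.mapped_start + len(self.aligned_bases)


@dataclass(frozen=True)
class SiteCall:
    site: CytosineSite
    n_meth: int
    n_unmeth: int

    @property
    def depth(self) -> int:
        return self.n_meth + self.n_unmeth

    @property
    def level(self) -> float | None:
        """Percent methylation, or None when depth is 0."""
        if self.depth == 0:
            return None
        return 100.0 * self.n_meth / self.depth


class Methylome:
    """Per-cytosine methylation counts for a genome, both strands.

    Sites are kept in :func:`mtbsqc.reference.index_cytosines` order; counts
    are parallel integer arrays.  ``coverage_L`` / ``coverage_H`` are
    per-*position* read-coverage tracks (each read covers its whole mapped
    interval regardless of base identity), used by the binned depth
    diagnostics.
    """

    def __init__(self, genome: MtGenome, sites: list[CytosineSite] | None = None):
        self.genome = genome
        self.sites = sites if sites is not None else index_cytosines(genome)
        n = len(self.sites)
        self.n_meth = np.zeros(n, dtype=np.int64)
        self.n_unmeth = np.zeros(n, dtype=np.int64)
        self.coverage_L = np.zeros(genome.length, dtype=np.int64)
        self.coverage_H = np.zeros(genome.length, dtype=np.int64)
        self.n_reads_used = 0
        self.n_reads_skipped = 0
        self._index = {(s.position, s.strand): i for i, s in enumerate(self.sites)}

    # -- access ----------------------------------------------------------
    def site_index(self, position: int, strand: str) -> int:
        return self._index[(position, strand)]

    def call_at(self, position: int, strand: str) -> SiteCall:
        i = self.site_index(position, strand)
        return SiteCall(self.sites[i], int(self.n_meth[i]), int(self.n_unmeth[i]))

    @property
    def depth(self) -> np.ndarray:
        return self.n_meth + self.n_unmeth

    @property
    def levels(self) -> np.ndarray:
        """Per-site percent methylation; NaN where depth is 0."""
        d = self.depth.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            lv = 100.0 * self.n_meth / d
        lv[d == 0] = np.nan
        return lv

    def strand_mask(self, strand: str) -> np.ndarray:
        return np.array([s.strand == strand for s in self.sites])

    def context_mask(self, context: str) -> np.ndarray:
        return np.array([s.context == context for s in self.sites])

    def iter_calls(self):
        for i, s in enumerate(self.sites):
            yield SiteCall(s, int(self.n_meth[i]), int(self.n_unmeth[i]))

    def copy_empty(self) -> "Methylome":
        return Methylome(self.genome, self.sites)


def call_methylation(
    reads: list[AlignedRead],
    genome: MtGenome,
    min_mapq: int = 0,
    min_baseq: int = 0,
) -> Methylome:
    """Pile up reads into a strand-specific :class:`Methylome`.

    Reads below ``min_mapq`` are skipped entirely.  When mates of a pair
    (linked through ``mate_id``) overlap, the overlap is counted once: the
    first mate encountered wins.  Reads whose interval falls outside a
    linear genome are skipped with a warning and counted in
    ``n_reads_skipped``.
    """
    me = Methylome(genome)
    n = genome.length
    # plus-position -> site index, keyed by the physical plus-strand base
    # (C sites are read by plus-derived reads, G sites by minus-derived)
    c_idx = np.full(n, -1, dtype=np.int64)
    g_idx = np.full(n, -1, dtype=np.int64)
    for i, s in enumerate(me.sites):
        if genome.sequence[s.position] == "C":
            c_idx[s.position] = i
        else:
            g_idx[s.position] = i

    pair_seen: dict[tuple[str, str], set[int]] = {}

    for read in reads:
        if read.mapq < min_mapq:
            me.n_reads_skipped += 1
            continue
        if not genome.circular and (read.mapped_start < 0 or read.mapped_end > n):
            warnings.warn(
                f"read {read.read_id} maps outside linear genome; skipped", stacklevel=2
            )
            me.n_reads_skipped += 1
            continue

        claimed: set[int] | None = None
        if read.mate_id is not None:
            key = tuple(sorted((read.read_id, read.mate_id)))
            claimed = pair_seen.setdefault(key, set())

        # which physical strand the read derives from, per the naming flag
        plus_derived = (read.informative_strand == "L") == genome.l_strand_is_plus
        idx = c_idx if plus_derived else g_idx
        meth_base, unmeth_base = ("C", "T") if plus_derived else ("G", "A")
        for j, b in enumerate(read.aligned_bases):
            pos = (read.mapped_start + j) % n if genome.circular else read.mapped_start + j
            if read.informative_strand == "L":
                me.coverage_L[pos] += 1
            else:
                me.coverage_H[pos] += 1
            if claimed is not None:
                if pos in claimed:
                    continue
                claimed.add(pos)
            if read.base_quals is not None and read.base_quals[j] < min_baseq:
                continue
            si = idx[pos]
            if si < 0:
                continue
            if b == meth_base:
                me.n_meth[si] += 1
            elif b == unmeth_base:
                me.n_unmeth[si] += 1
        me.n_reads_used += 1
    return me


# -- summaries ------------------------------------------------------------

def _summary_entry(n_meth: np.ndarray, n_unmeth: np.ndarray, min_cov: int) -> dict:
    depth = n_meth + n_unmeth
    keep = depth >= max(min_cov, 1)
    if not keep.any():
        return {"n_sites": 0, "pooled_level": None, "mean_site_level": None}
    m, u = n_meth[keep], n_unmeth[keep]
    pooled = 100.0 * m.sum() / (m.sum() + u.sum())
    per_site = 100.0 * m / (m + u)
    return {
        "n_sites": int(keep.sum()),
        "pooled_level": float(pooled),
        "mean_site_level": float(per_site.mean()),
    }


def summarize_levels(
    methylome: Methylome,
    min_cov_overall: int = 3,
    min_cov_per_strand: int = 1,
) -> dict:
    """Context x strand methylation summary.

    For each of ``CpG``/``CpH`` x ``L``/``H``/``both``, reports the number
    of qualifying sites, the pooled level (100 x sum(meth)/sum(depth)) and
    the mean of per-site levels.  Both statistics are reported because
    "average methylation level" is ambiguous between the two.  The overall
    5mC entry pools both contexts and strands at ``min_cov_overall``; the
    per-strand context entries use ``min_cov_per_strand``.  Entries with no
    qualifying site are ``None`` (undefined), never 0.
    """
    out: dict = {}
    for ctx in ("CpG", "CpH"):
        cmask = methylome.context_mask(ctx)
        out[ctx] = {}
        for strand in ("L", "H", "both"):
            mask = cmask if strand == "both" else cmask & methylome.strand_mask(strand)
            out[ctx][strand] = _summary_entry(
                methylome.n_meth[mask], methylome.n_unmeth[mask], min_cov_per_strand
            )
    out["5mC"] = _summary_entry(methylome.n_meth, methylome.n_unmeth, min_cov_overall)
    return out


def conversion_rate_from_spikein(
    reads: list[AlignedRead],
    spike_genome: MtGenome,
    min_mapq: int = 0,
) -> float | None:
    """Bisulfite conversion rate from an unmethylated spike-in (e.g. λ DNA).

    rate = converted / total informative cytosine observations, pooled over
    both strands.  Returns None when there are no informative observations.
    """
    me = call_methylation(reads, spike_genome, min_mapq=min_mapq)
    total = int(me.n_meth.sum() + me.n_unmeth.sum())
    if total == 0:
        return None
    return float(me.n_unmeth.sum()) / total


# -- amplicon (Sanger clone) mode -----------------------------------------

@dataclass
class AmpliconResult:
    """Per-clone, per-site methylation matrix from Sanger bisulfite clones.

    ``matrix[clone_id][site_position]`` is ``"M"`` (methylated, retained C),
    ``"U"`` (converted) or ``"."`` (unreadable base).  ``conversion`` maps
    clone to its non-CpG conversion rate (None when the clone covers no CpH
    site).  ``rejected`` maps failed clones to the reason.
    """

    sites: list[CytosineSite]
    matrix: dict[str, dict[int, str]]
    conversion: dict[str, float | None]
    rejected: dict[str, str] = field(default_factory=dict)

    def site_summary(self) -> dict[int, dict]:
        out = {}
        for s in self.sites:
            calls = [self.matrix[c][s.position] for c in self.matrix]
            n_m = calls.count("M")
            n_u = calls.count("U")
            out[s.position] = {
                "context": s.context,
                "n_meth": n_m,
                "n_unmeth": n_u,
                "level": (100.0 * n_m / (n_m + n_u)) if n_m + n_u else None,
            }
        return out


def amplicon_clone_call(
    clones: dict[str, str],
    amplicon_ref: str,
    informative_strand: str = "L",
    min_identity: float = 0.90,
) -> AmpliconResult:
    """Call methylation on cloned bisulfite PCR products against an amplicon.

    Clones must align end-to-end (gapless, equal length) to the reference.
    A clone whose identity to the reference in three-letter bisulfite space
    falls below ``min_identity`` is rejected with a reason, as is a clone of
    mismatched length.  The per-clone conversion rate is computed over CpH
    sites only, so that genuine CpG methylation does not depress it.
    """
    from .numt import read_bisulfite_space

    ref = amplicon_ref.upper()
    ref_genome = MtGenome("amplicon", ref, circular=False)
    all_sites = index_cytosines(ref_genome)
    sites = [s for s in all_sites if s.strand == informative_strand]
    meth_base, unmeth_base = ("C", "T") if informative_strand == "L" else ("G", "A")

    res = AmpliconResult(sites=sites, matrix={}, conversion={})
    ref_bs = read_bisulfite_space(ref, informative_strand)
    for cid, raw in clones.items():
        seq = raw.upper()
        if len(seq) != len(ref):
            res.rejected[cid] = f"length {len(seq)} != reference {len(ref)}"
            continue
        clone_bs = read_bisulfite_space(seq, informative_strand)
        ident = sum(a == b for a, b in zip(clone_bs, ref_bs)) / len(ref)
        if ident < min_identity:
            res.rejected[cid] = f"identity {ident:.2f} below {min_identity:.2f} in bisulfite space"
            continue
        row: dict[int, str] = {}
        cph_m = cph_u = 0
        for s in sites:
            b = seq[s.position]
            if b == meth_base:
                row[s.position] = "M"
            elif b == unmeth_base:
                row[s.position] = "U"
            else:
                row[s.position] = "."
            if s.context == "CpH":
                if b == meth_base:
                    cph_m += 1
                elif b == unmeth_base:
                    cph_u += 1
        res.matrix[cid] = row
        res.conversion[cid] = (cph_u / (cph_m + cph_u)) if cph_m + cph_u else None
    return res


# -- primer validation -----------------------------------------------------

def primer_check(forward: str, reverse: str) -> tuple[bool, list[str]]:
    """Validate bisulfite PCR primers.

    After conversion the top strand has no C left (except methylated ones),
    so a forward primer must contain no C — degenerate Y (C/T) is allowed at
    former-C positions — and a reverse primer no G, with degenerate R (A/G)
    allowed.  Returns ``(passed, reasons)``; empty primers are an error.
    """
    if not forward or not reverse:
        raise ValueError("empty primer")
    reasons = []
    for i, b in enumerate(forward.upper()):
        if b == "C":
            reasons.append(f"forward primer has C at position {i}")
    for i, b in enumerate(reverse.upper()):
        if b == "G":
            reasons.append(f"reverse primer has G at position {i}")
    return (not reasons, reasons)
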