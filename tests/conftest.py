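"""Shared fixtures: synthetic genomes, planted NUMT fixtures, oracles.

All fixtures are generated programmatically and seeded; nothing is read
from disk.  The random genome mimics mammalian mtDNA base composition
(the plus/L strand carries roughly twice as many C as G), which is what
drives the strand-degradation asymmetry the QC module looks for.
"""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import settings

from mtbsqc.calling import AlignedRead

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")
from mtbsqc.numt import NumtRecord, SBD
from mtbsqc.reference import MtGenome

# plus-strand base frequencies close to mouse/human mtDNA (C-rich plus)
MT_BASE_PROBS = {"A": 0.35, "C": 0.24, "G": 0.12, "T": 0.29}


def random_mt_genome(length: int, seed: int, circular: bool = True) -> MtGenome:
    rng = np.random.default_rng(seed)
    bases = rng.choice(
        list(MT_BASE_PROBS), size=length, p=list(MT_BASE_PROBS.values())
    )
    return MtGenome("simMT", "".join(bases), circular=circular)


@pytest.fixture(scope="session")
def mt16k() -> MtGenome:
    """A 16,299-bp circular genome with mtDNA-like composition."""
    return random_mt_genome(16299, seed=20)


@pytest.fixture()
def small_genome() -> MtGenome:
    return MtGenome("mini", "ACGTACCGGTTACGATCGAA", circular=True)


def plant_numt(
    genome: MtGenome,
    mt_start: int,
    length: int,
    sbd_offsets: list[int],
    sbd_informative_both: bool = True,
) -> tuple[str, str]:
    """A nuclear sequence copied from an mt interval with planted SBDs.

    Substitutions avoid C/G reference bases when ``sbd_informative_both``
    so every planted difference stays visible to both read classes after
    bisulfite collapse.  Returns (locus_id, nuclear sequence).
    """
    seq = list(genome.fetch(mt_start, mt_start + length))
    # substitution choices that survive bisulfite collapse in both spaces
    both_ways = {"A": "C", "T": "G", "C": "A", "G": "T"}
    for off in sbd_offsets:
        base = seq[off]
        if sbd_informative_both:
            seq[off] = both_ways[base]
        else:
            seq[off] = {"C": "T", "G": "A"}.get(base, both_ways[base])
    return f"numt_{mt_start}_{length}", "".join(seq)


@pytest.fixture()
def numt_fixture(mt16k):
    """A 300-bp NUMT over a fixed interval, SBDs every ~50 bp.

    Gap between consecutive SBDs is below the 100-bp read length, so any
    read falling inside the interval covers at least one.
    """
    mt_start, length = 4000, 300
    offsets = [25, 75, 125, 175, 225, 275]
    locus, seq = plant_numt(mt16k, mt_start, length, offsets)
    return {
        "locus_id": locus,
        "sequence": seq,
        "mt_start": mt_start,
        "mt_end": mt_start + length,
        "sbd_positions": [mt_start + o for o in offsets],
    }


# -- independent oracles ---------------------------------------------------

def brute_force_pileup(reads, genome):
    """Per-(position, strand-name) methylation counts by direct scan.

    Deliberately naive: iterates every read against every position with no
    indexing, no mate logic (use only on single-end instances).
    """
    n = genome.length
    counts = {}
    for pos in range(n):
        ref = genome.sequence[pos]
        if ref not in ("C", "G"):
            continue
        plus_site = ref == "C"
        strand_name = (
            ("L" if genome.l_strand_is_plus else "H")
            if plus_site
            else ("H" if genome.l_strand_is_plus else "L")
        )
        meth = unmeth = 0
        for read in reads:
            plus_derived = (read.informative_strand == "L") == genome.l_strand_is_plus
            if plus_derived != plus_site:
                continue
            for j, b in enumerate(read.aligned_bases):
                p = (read.mapped_start + j) % n if genome.circular else read.mapped_start + j
                if p != pos:
                    continue
                if plus_site:
                    meth += b == "C"
                    unmeth += b == "T"
                else:
                    meth += b == "G"
                    unmeth += b == "A"
        counts[(pos, strand_name)] = (meth, unmeth)
    return counts


def brute_force_shared_substrings(mt: str, nuc: str, min_len: int):
    """All maximal shared substrings >= min_len by exhaustive scan."""
    hits = set()
    for i in range(len(mt)):
        for j in range(len(nuc)):
            if mt[i] != nuc[j]:
                continue
            if i > 0 and j > 0 and mt[i - 1] == nuc[j - 1]:
                continue  # not maximal on the left
            k = 0
            while i + k < len(mt) and j + k < len(nuc) and mt[i + k] == nuc[j + k]:
                k += 1
            if k >= min_len:
                hits.add((i, i + k))
    return hits


def rank_with_ties(values):
    """Average ranks, computed by explicit sorting (oracle helper)."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def spearman_oracle(x, y):
    """Spearman rho as the Pearson correlation of average ranks."""
    rx, ry = rank_with_ties(list(x)), rank_with_ties(list(y))
    mx, my = sum(rx) / len(rx), sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(
        sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)
    )
    return num / den


def fisher_exact_oracle(a, b, c, d):
    """Two-sided Fisher exact p by full hypergeometric enumeration."""
    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2

    def prob(x):
        return (
            math.comb(row1, x)
            * math.comb(row2, col1 - x)
            / math.comb(n, col1)
        )

    p_obs = prob(a)
    lo = max(0, col1 - row2)
    hi = min(row1, col1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9))


def make_read(read_id, start, bases, strand="L", **kw) -> AlignedRead:
    return AlignedRead(read_id, start, bases, strand, **kw)
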