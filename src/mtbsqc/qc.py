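"""Depth-bias diagnostics for mitochondrial bisulfite libraries.

Bisulfite chemistry degrades DNA at the cytosines it converts, so
unmethylated C-rich fragments drop out of the library.  On mtDNA, whose L
strand carries roughly twice the cytosines of the H strand, this produces a
strand-level depth imbalance (high H/L ratio) and, within strands, local
coverage holes whose few surviving reads are enriched for the
poorly-converted subpopulation — the classic signature being an inverse
correlation between per-site depth and apparent methylation.  Apparent 5mC
in such libraries is an artifact until these diagnostics clear it.

Flag semantics: a site is only examined once it shows a strong signal
(level above ``signal_threshold``, default 5%); it is then flagged for
low absolute depth, depth low relative to its own strand's mean (depth is a
relative concept on mtDNA, which is sequenced far deeper than the nuclear
genome), a level at or below the conversion-failure floor, and overlap with
regions identical to nuclear sequence.  NUMT suspicion is attached by the
:mod:`mtbsqc.numt` module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .calling import Methylome
from .reference import CytosineSite, IdenticalRegion

FLAG_STRONG_SIGNAL = "STRONG_SIGNAL"
FLAG_LOW_RELATIVE_DEPTH = "LOW_RELATIVE_DEPTH"
FLAG_LOW_ABSOLUTE_DEPTH = "LOW_ABSOLUTE_DEPTH"
FLAG_BELOW_CONVERSION_FLOOR = "BELOW_CONVERSION_FLOOR"
FLAG_NUMT_SUSPECT = "NUMT_SUSPECT"
FLAG_IDENTICAL_REGION = "IDENTICAL_REGION"


@dataclass(frozen=True)
class StrandDepthStats:
    """Mean per-site depth per strand and their H/L ratio.

    Zero-depth sites are included in the means (no depth cutoff);
    ``hl_ratio`` is None when the L mean is 0 or a strand has no sites.
    """

    mean_depth_L: float | None
    mean_depth_H: float | None

    @property
    def hl_ratio(self) -> float | None:
        if not self.mean_depth_L or self.mean_depth_H is None:
            return None
        return self.mean_depth_H / self.mean_depth_L


@dataclass(frozen=True)
class BinProfile:
    """Mean read coverage in consecutive fixed-width windows.

    Bins tile ``[trim, genome_length - trim)``; a final partial window is
    dropped, never padded.
    """

    bin_width: int
    trim: int
    bins: tuple[float, ...]

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    def bin_interval(self, i: int) -> tuple[int, int]:
        start = self.trim + i * self.bin_width
        return start, start + self.bin_width


@dataclass(frozen=True)
class CorrelationResult:
    rho: float | None
    p_value: float | None
    n: int
    method: str


@dataclass
class SiteFlag:
    site: CytosineSite
    reasons: set[str] = field(default_factory=set)
    low_vs_adjacent: bool = False  # same relative-depth rule vs ±1 kb window


def strand_depth_stats(methylome: Methylome) -> StrandDepthStats:
    """Per-strand mean site depth; all sites included, no cutoff."""
    depth = methylome.depth
    out = {}
    for strand in ("L", "H"):
        mask = methylome.strand_mask(strand)
        out[strand] = float(depth[mask].mean()) if mask.any() else None
    return StrandDepthStats(mean_depth_L=out["L"], mean_depth_H=out["H"])


def binned_metaplot(
    methylome: Methylome, bin_width: int = 200, trim: int = 150
) -> BinProfile:
    """Per-bin mean of per-position total read coverage (both strands).

    The first and last ``trim`` bases are ignored and the remainder tiled
    with consecutive ``bin_width`` windows; a trailing partial window is
    dropped.  Mean x width sums to the total coverage over the tiled
    interval exactly.
    """
    n = methylome.genome.length
    if n <= 2 * trim + bin_width:
        raise ValueError(
            f"genome length {n} too short for trim={trim}, bin_width={bin_width}"
        )
    cov = (methylome.coverage_L + methylome.coverage_H).astype(float)
    n_bins = (n - 2 * trim) // bin_width
    means = [
        float(cov[trim + i * bin_width: trim + (i + 1) * bin_width].mean())
        for i in range(n_bins)
    ]
    return BinProfile(bin_width=bin_width, trim=trim, bins=tuple(means))


def depth_methylation_correlation(
    methylome: Methylome, min_depth: int = 1, method: str = "spearman"
) -> CorrelationResult:
    """Rank correlation between per-site depth and methylation level.

    Restricted to sites with depth >= ``min_depth`` (level defined).  A
    strongly negative rho replicates the depth/5mC inverse relationship of
    degradation-biased libraries.  Spearman by default because the
    relationship is nonlinear; Pearson available by flag.  Returns undefined
    (None) statistics when fewer than 3 usable sites remain or either
    variable is constant.
    """
    depth = methylome.depth
    levels = methylome.levels
    keep = depth >= max(min_depth, 1)
    d, lv = depth[keep].astype(float), levels[keep]
    n = int(keep.sum())
    if n < 3:
        raise ValueError(f"need >= 3 sites with depth >= {min_depth}, got {n}")
    if np.all(lv == lv[0]) or np.all(d == d[0]):
        return CorrelationResult(None, None, n, method)
    if method == "spearman":
        rho, p = stats.spearmanr(d, lv)
    elif method == "pearson":
        rho, p = stats.pearsonr(d, lv)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    if np.isnan(rho):
        return CorrelationResult(None, None, n, method)
    return CorrelationResult(float(rho), float(p), n, method)


def flag_sites(
    methylome: Methylome,
    stats_: StrandDepthStats | None = None,
    conversion_rate: float | None = None,
    identical_regions: list[IdenticalRegion] | None = None,
    signal_threshold: float = 5.0,
    rel_depth_frac: float = 0.01,
    abs_depth: int = 10,
    adjacent_halfwidth: int = 1000,
) -> list[SiteFlag]:
    """Flag strong 5mC signals and annotate why they may be artifacts.

    A site with defined level above ``signal_threshold`` gets
    ``STRONG_SIGNAL`` and is then checked for: depth below ``abs_depth``
    (LOW_ABSOLUTE_DEPTH); depth below ``rel_depth_frac`` of the own-strand
    mean (LOW_RELATIVE_DEPTH); level at or below the apparent-methylation
    floor ``100 x (1 - conversion_rate)`` implied by incomplete conversion
    (BELOW_CONVERSION_FLOOR); and location inside a region identical to
    nuclear sequence (IDENTICAL_REGION).  The same relative rule applied
    against the mean coverage of the surrounding +-``adjacent_halfwidth``
    window is reported alongside as ``low_vs_adjacent``.
    """
    if stats_ is None:
        stats_ = strand_depth_stats(methylome)
    depth = methylome.depth
    levels = methylome.levels
    glen = methylome.genome.length
    cov_by_strand = {"L": methylome.coverage_L, "H": methylome.coverage_H}
    strand_mean = {"L": stats_.mean_depth_L, "H": stats_.mean_depth_H}

    flags: list[SiteFlag] = []
    for i, site in enumerate(methylome.sites):
        lv = levels[i]
        if np.isnan(lv) or lv <= signal_threshold:
            continue
        f = SiteFlag(site, {FLAG_STRONG_SIGNAL})
        d = int(depth[i])
        if d < abs_depth:
            f.reasons.add(FLAG_LOW_ABSOLUTE_DEPTH)
        sm = strand_mean[site.strand]
        if sm is not None and d < rel_depth_frac * sm:
            f.reasons.add(FLAG_LOW_RELATIVE_DEPTH)
        if conversion_rate is not None and lv <= 100.0 * (1.0 - conversion_rate):
            f.reasons.add(FLAG_BELOW_CONVERSION_FLOOR)
        if identical_regions:
            for r in identical_regions:
                if r.contains(site.position) or (
                    r.mt_end > glen and site.position < r.mt_end % glen
                ):
                    f.reasons.add(FLAG_IDENTICAL_REGION)
                    break
        lo = max(site.position - adjacent_halfwidth, 0)
        hi = min(site.position + adjacent_halfwidth + 1, glen)
        adj_mean = float(cov_by_strand[site.strand][lo:hi].mean())
        f.low_vs_adjacent = d < rel_depth_frac * adj_mean
        flags.append(f)
    return flags
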