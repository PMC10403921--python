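"""qPCR efficiency math and aggregate report assembly.

Relative quantification follows the 2^-ΔΔCt method:

    ΔΔCt = (Ct_target - Ct_control)_treated - (Ct_target - Ct_control)_untreated
    remaining_fraction = 2^-ΔΔCt

In *linearization* mode the target amplicon spans the restriction site, so
``remaining_fraction`` is the uncut fraction and the derived metric is the
percent linearized, ``100 x (1 - 2^-ΔΔCt)``.  In *enrichment* mode the
derived metric is the fold change itself.  Replicate Ct values are averaged
within each (condition, target) cell before the difference is taken; the
replicate spread is reported alongside.
"""

from __future__ import annotations

import json
import statistics
from dataclasses import dataclass
from typing import Any, Optional

from pydantic import BaseModel

REPORT_SCHEMA_VERSION = "1"


@dataclass(frozen=True)
class DdctResult:
    ddct: float
    remaining_fraction: float
    derived_metric: float
    mode: str
    replicate_sd: dict  # (condition, target) -> sd (None for single replicates)


def delta_delta_ct(
    rows: list[dict],
    mode: str = "linearization",
    target: str = "target",
    control: str = "control",
    treated: str = "treated",
    untreated: str = "untreated",
) -> DdctResult:
    """Compute 2^-ΔΔCt from replicate Ct rows.

    ``rows`` carry keys ``condition``, ``target`` and ``ct`` (the ``sample``
    column is free-form and ignored here).  Raises ``ValueError`` naming
    any missing (condition, target) cell.
    """
    if mode not in ("linearization", "enrichment"):
        raise ValueError(f"mode must be 'linearization' or 'enrichment', got {mode!r}")
    cells: dict[tuple[str, str], list[float]] = {}
    for row in rows:
        if row["ct"] <= 0:
            raise ValueError(f"non-positive Ct {row['ct']}")
        cells.setdefault((row["condition"], row["target"]), []).append(row["ct"])

    means = {}
    spread = {}
    for cond in (treated, untreated):
        for tgt in (target, control):
            vals = cells.get((cond, tgt))
            if not vals:
                raise ValueError(f"missing Ct values for condition={cond!r}, target={tgt!r}")
            means[(cond, tgt)] = statistics.fmean(vals)
            spread[f"{cond}/{tgt}"] = (
                statistics.stdev(vals) if len(vals) > 1 else None
            )

    ddct = (means[(treated, target)] - means[(treated, control)]) - (
        means[(untreated, target)] - means[(untreated, control)]
    )
    remaining = 2.0 ** (-ddct)
    metric = 100.0 * (1.0 - remaining) if mode == "linearization" else remaining
    return DdctResult(ddct, remaining, metric, mode, spread)


# -- report schema ---------------------------------------------------------

class SummaryEntry(BaseModel):
    n_sites: int
    pooled_level: Optional[float]
    mean_site_level: Optional[float]


class StrandStatsModel(BaseModel):
    mean_depth_L: Optional[float]
    mean_depth_H: Optional[float]
    hl_ratio: Optional[float]


class CorrelationModel(BaseModel):
    rho: Optional[float]
    p_value: Optional[float]
    n: int
    method: str


class FlagModel(BaseModel):
    position: int
    strand: str
    context: str
    level: Optional[float]
    depth: int
    reasons: list[str]
    low_vs_adjacent: bool
    cooccurrence_p: Optional[float] = None
    cooccurrence_odds_ratio: Optional[float] = None


class BinProfileModel(BaseModel):
    bin_width: int
    trim: int
    bins: list[float]


class QCReportModel(BaseModel):
    """Versioned aggregate report for one library."""

    schema_version: str
    genome: Optional[str]
    n_reads_used: Optional[int]
    n_reads_skipped: Optional[int]
    conversion_rate: Optional[float]
    summaries: Optional[dict]
    strand_stats: Optional[StrandStatsModel]
    bin_profile: Optional[BinProfileModel]
    correlation: Optional[CorrelationModel]
    flags: Optional[list[FlagModel]]
    numt: Optional[dict]


def assemble_report(
    methylome=None,
    summaries=None,
    stats=None,
    bin_profile=None,
    correlation=None,
    flags=None,
    numt_results=None,
    conversion_rate=None,
) -> dict:
    """Assemble (and validate) the aggregate JSON report.

    Any component may be absent and is reported as null.  Flag entries are
    cross-referenced with NUMT co-occurrence results by site position when
    ``numt_results`` carries a ``cooccurrence`` mapping.
    """
    flags_out = None
    if flags is not None:
        cooc = (numt_results or {}).get("cooccurrence", {})
        levels = depth = None
        if methylome is not None:
            levels = methylome.levels
            depth = methylome.depth
        flags_out = []
        for f in flags:
            i = methylome.site_index(f.site.position, f.site.strand) if methylome else None
            entry = FlagModel(
                position=f.site.position,
                strand=f.site.strand,
                context=f.site.context,
                level=(None if i is None or depth[i] == 0 else float(levels[i])),
                depth=(0 if i is None else int(depth[i])),
                reasons=sorted(f.reasons),
                low_vs_adjacent=f.low_vs_adjacent,
            )
            key = (f.site.position, f.site.strand)
            if key in cooc:
                entry.cooccurrence_p = cooc[key].p_value
                entry.cooccurrence_odds_ratio = cooc[key].odds_ratio
            flags_out.append(entry)

    numt_out = None
    if numt_results is not None:
        numt_out = {
            k: v
            for k, v in numt_results.items()
            if k in ("n_numt_reads", "n_ambiguous_reads", "n_mt_reads", "policy", "n_sites_changed")
        }

    model = QCReportModel(
        schema_version=REPORT_SCHEMA_VERSION,
        genome=methylome.genome.name if methylome is not None else None,
        n_reads_used=methylome.n_reads_used if methylome is not None else None,
        n_reads_skipped=methylome.n_reads_skipped if methylome is not None else None,
        conversion_rate=conversion_rate,
        summaries=summaries,
        strand_stats=(
            None
            if stats is None
            else StrandStatsModel(
                mean_depth_L=stats.mean_depth_L,
                mean_depth_H=stats.mean_depth_H,
                hl_ratio=stats.hl_ratio,
            )
        ),
        bin_profile=(
            None
            if bin_profile is None
            else BinProfileModel(
                bin_width=bin_profile.bin_width,
                trim=bin_profile.trim,
                bins=list(bin_profile.bins),
            )
        ),
        correlation=(
            None
            if correlation is None
            else CorrelationModel(
                rho=correlation.rho,
                p_value=correlation.p_value,
                n=correlation.n,
                method=correlation.method,
            )
        ),
        flags=flags_out,
        numt=numt_out,
    )
    return model.model_dump(mode="json")


def report_json_schema() -> dict:
    """The JSON schema the aggregate report conforms to."""
    return QCReportModel.model_json_schema()


def dump_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
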