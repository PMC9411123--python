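"""PSI quantification, control-pool profiles, specificity and RNA QC.

The percent-spliced index of an event in a sample is the fraction of reads
supporting the aberrant junction(s) over all junction reads in the region
covering the event:

    PSI = supporting / (supporting + canonical-sharing-region)

Both terms are junction reads only (exon-body coverage is not part of the
evidence class this pipeline consumes). For multi-junction cryptic-exon
events, the numerator is the rounded-half-up mean of the two flanking
junction counts; the canonical term is likewise the rounded mean over the
canonical junctions whose intron overlaps the event, so a multi-intron
exon skip is not double-counted and the binomial estimator stays unbiased.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .events import JunctionTable, SpliceEvent, canonical_junctions, _removal
from .gene_model import GeneModel

DEFAULT_MIN_PSI = 0.10
DEFAULT_FOLD = 5.0
DEFAULT_MIN_DENOMINATOR = 100
RTPCR_COVERAGE_CUTOFF = 500
ALLELE_SKEW_ALPHA = 0.01
ALLELE_SKEW_MIN_READS = 20


def round_half_up(x: float) -> int:
    return math.floor(x + 0.5)


class Specificity(Enum):
    SPECIFIC = "specific"
    NOT_SPECIFIC = "not_specific"
    INDETERMINATE = "indeterminate"


class SkewCall(Enum):
    SKEWED = "skewed"
    BALANCED = "balanced"
    INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class PsiObservation:
    """One event's quantification in one sample."""

    event_key: str
    sample_id: str
    supporting_reads: int
    region_total_reads: int
    psi: float  # NaN when the denominator is 0
    flags: Tuple[str, ...] = ()

    @property
    def defined(self) -> bool:
        return not math.isnan(self.psi)


@dataclass(frozen=True)
class ControlProfile:
    """Distribution of an event's PSI across the healthy control pool."""

    event_key: str
    n_controls: int
    per_sample_psi: Tuple[float, ...]
    n_undefined: int = 0

    @property
    def median_psi(self) -> float:
        return float(np.median(self.per_sample_psi)) if self.per_sample_psi else math.nan

    @property
    def p95_psi(self) -> float:
        return float(np.percentile(self.per_sample_psi, 95)) if self.per_sample_psi else math.nan

    @property
    def max_psi(self) -> float:
        return float(max(self.per_sample_psi)) if self.per_sample_psi else math.nan


@dataclass(frozen=True)
class RnaQcResult:
    """Sequencing QC for an RNA sample; pass requires all four thresholds."""

    pct_q30: float
    mean_base_quality: float
    pct_perfect_index: float
    pct_exons_ge_50x: float
    passed: bool
    failure_reasons: Tuple[str, ...]


# ---------------------------------------------------------------------------
# PSI
# ---------------------------------------------------------------------------


def _sharing_canonicals(event: SpliceEvent, model: GeneModel) -> List:
    """Canonical junction keys whose intron overlaps the event's removals."""
    canon = canonical_junctions(model)
    out = []
    for key in canon:
        ks, ke = _removal(key)
        for nkey in event.novel_junctions:
            a, b = _removal(nkey)
            if max(a, ks) < min(b, ke):
                out.append(key)
                break
    return out


def compute_psi(
    event: SpliceEvent, sample: JunctionTable, model: GeneModel
) -> PsiObservation:
    """Quantify an event's PSI in one sample (detected or hypothesised).

    The event need not have been detected in this sample: an absent novel
    junction contributes 0 supporting reads, giving PSI 0 when canonical
    coverage exists and an undefined (NaN, flagged) PSI otherwise.
    """
    novel_reads = [sample.get(k, 0) for k in event.novel_junctions]
    if len(novel_reads) == 1:
        numerator = novel_reads[0]
    else:
        numerator = round_half_up(sum(novel_reads) / len(novel_reads))
    sharing = _sharing_canonicals(event, model)
    if sharing:
        canonical = round_half_up(sum(sample.get(k, 0) for k in sharing) / len(sharing))
    else:
        canonical = 0
    denominator = numerator + canonical
    if denominator == 0:
        return PsiObservation(
            event.event_key, sample.sample_id, numerator, 0, math.nan, ("no_coverage",)
        )
    return PsiObservation(
        event.event_key, sample.sample_id, numerator, denominator, numerator / denominator
    )


def control_profile(
    event: SpliceEvent,
    control_tables: Iterable[JunctionTable],
    model: GeneModel,
) -> ControlProfile:
    """Profile an event's PSI across the healthy-donor control pool.

    Controls without canonical coverage of the region yield undefined PSI
    and are excluded from the statistics (counted in ``n_undefined``).
    """
    tables = list(control_tables)
    if not tables:
        raise ValueError("control pool is empty")
    values: List[float] = []
    undefined = 0
    for table in tables:
        obs = compute_psi(event, table, model)
        if obs.defined:
            values.append(obs.psi)
        else:
            undefined += 1
    return ControlProfile(event.event_key, len(tables), tuple(values), undefined)


def specificity_test(
    carrier: PsiObservation,
    controls: ControlProfile,
    min_psi: float = DEFAULT_MIN_PSI,
    fold: float = DEFAULT_FOLD,
    min_denominator: int = DEFAULT_MIN_DENOMINATOR,
) -> Specificity:
    """Is the carrier's event absent (at similar PSI) from healthy controls?

    Specific when carrier PSI clears both the absolute floor and the fold
    change over the control pool's 95th percentile; indeterminate when the
    carrier's denominator is too shallow to support either call.
    """
    if not carrier.defined or carrier.region_total_reads < min_denominator:
        return Specificity.INDETERMINATE
    p95 = controls.p95_psi if controls.per_sample_psi else 0.0
    if carrier.psi >= min_psi and carrier.psi >= fold * p95:
        return Specificity.SPECIFIC
    return Specificity.NOT_SPECIFIC


def needs_rtpcr_confirmation(
    obs: PsiObservation, cutoff: int = RTPCR_COVERAGE_CUTOFF
) -> bool:
    """RT-PCRseq confirmation is required below 500x event coverage.

    The boundary is strict: a PSI denominator of exactly 500 does not
    trigger confirmation.
    """
    if not obs.defined:
        raise ValueError("PSI undefined; confirmation rule needs a denominator")
    return obs.region_total_reads < cutoff


def allele_skew_test(
    ref_reads: int,
    alt_reads: int,
    alpha: float = ALLELE_SKEW_ALPHA,
    min_reads: int = ALLELE_SKEW_MIN_READS,
) -> Tuple[SkewCall, float]:
    """Exact binomial test of allelic imbalance at an exonic SNP.

    Indirect evidence of nonsense-mediated decay: a transcript degraded in
    cis depletes one allele's reads. Two-sided exact test against 0.5;
    fewer than ``min_reads`` total reads is indeterminate.
    """
    if ref_reads < 0 or alt_reads < 0:
        raise ValueError("read counts must be non-negative")
    total = ref_reads + alt_reads
    if total == 0:
        return SkewCall.INDETERMINATE, math.nan
    p = float(stats.binomtest(alt_reads, total, 0.5, alternative="two-sided").pvalue)
    if total < min_reads:
        return SkewCall.INDETERMINATE, p
    return (SkewCall.SKEWED if p < alpha else SkewCall.BALANCED), p


def rna_sample_qc(
    pct_q30: float,
    mean_base_quality: float,
    pct_perfect_index: float,
    pct_exons_ge_50x: float,
) -> RnaQcResult:
    """Apply the four RNA sequencing QC thresholds.

    Pass requires %Q30 > 75, mean base quality > 30, %perfect index > 85
    (all strict), and >= 85% of panel exons at >= 50x average coverage.
    """
    metrics = (pct_q30, mean_base_quality, pct_perfect_index, pct_exons_ge_50x)
    if any(m is None for m in metrics):
        raise ValueError("all four QC metrics are required")
    reasons = []
    if not pct_q30 > 75:
        reasons.append("Q30")
    if not mean_base_quality > 30:
        reasons.append("mean base quality")
    if not pct_perfect_index > 85:
        reasons.append("perfect index")
    if not pct_exons_ge_50x >= 85:
        reasons.append("exon coverage")
    return RnaQcResult(*metrics, passed=not reasons, failure_reasons=tuple(reasons))
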