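"""Cohort-level landscape summaries.

Variant-type proportions, position-bin x classification cross-tabs,
event-type counts, RNA-driven yield and VUS deltas, and "one per N
patients" frequencies. Percentages are reported to one decimal with
round-half-up, matching clinical-report formatting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .association import ClassificationOutcome, Impact
from .events import EventType, SpliceEvent
from .gene_model import PositionBin
from .variants import Classification, VariantRecord, VariantType


def pct1(x: float) -> float:
    """Percentage rounded to one decimal, half-up."""
    return float(Decimal(str(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class CohortSummary:
    n_individuals: int
    n_tests: int
    variant_type_proportions: Dict[str, float]
    position_bin_table: pd.DataFrame
    event_type_counts: Dict[str, int]
    yield_delta_pct: float
    vus_delta_pct: float
    per_patient_frequencies: Dict[str, Optional[int]]

    def to_dict(self) -> dict:
        return {
            "n_individuals": self.n_individuals,
            "n_tests": self.n_tests,
            "variant_type_proportions": self.variant_type_proportions,
            "position_bin_table": {
                str(idx): {str(c): int(v) for c, v in row.items()}
                for idx, row in self.position_bin_table.iterrows()
            },
            "event_type_counts": self.event_type_counts,
            "yield_delta_pct": self.yield_delta_pct,
            "vus_delta_pct": self.vus_delta_pct,
            "per_patient_frequencies": self.per_patient_frequencies,
        }


def variant_type_distribution(
    variants: Sequence[VariantRecord | VariantType | str],
) -> Dict[str, float]:
    """Percentage of reported variants per variant type (one decimal)."""
    if not variants:
        raise ValueError("variant_type_distribution requires at least one variant")
    types: List[str] = []
    for v in variants:
        if isinstance(v, VariantRecord):
            types.append(v.variant_type.value)
        elif isinstance(v, VariantType):
            types.append(v.value)
        else:
            types.append(str(v))
    counts = pd.Series(types).value_counts()
    total = counts.sum()
    return {t: pct1(100.0 * n / total) for t, n in counts.items()}


def reported_variant_total(n_p: int, n_lp: int, n_vus: int) -> int:
    """Total reported variants across the P/LP/VUS tiers."""
    if min(n_p, n_lp, n_vus) < 0:
        raise ValueError("counts must be non-negative")
    return n_p + n_lp + n_vus


def yield_and_vus_delta(
    individual_flags: Mapping[str, Tuple[bool, bool]],
    n_individuals: int,
) -> Tuple[float, float]:
    """Absolute positive-yield and VUS-rate changes from RNA evidence.

    ``individual_flags`` maps an individual to ``(gained_first_plp,
    vus_resolved)``; an individual with several upgraded variants still
    counts once. Returns percentages of ``n_individuals`` rounded to one
    decimal (half-up).
    """
    if n_individuals <= 0:
        raise ValueError("n_individuals must be positive")
    n_yield = sum(1 for up, _ in individual_flags.values() if up)
    n_resolved = sum(1 for _, res in individual_flags.values() if res)
    return (
        pct1(100.0 * n_yield / n_individuals),
        pct1(100.0 * n_resolved / n_individuals),
    )


def per_patient_frequency(
    n_carriers: int, n_individuals: int, rounding: str = "nearest"
) -> Optional[int]:
    """Express a carrier count as "one per N patients tested".

    ``rounding`` is ``'nearest'`` (half-up) or ``'ceiling'``; zero carriers
    yields ``None`` (undefined).
    """
    if n_carriers == 0:
        return None
    if n_carriers < 0 or n_individuals <= 0:
        raise ValueError("invalid carrier or cohort count")
    ratio = n_individuals / n_carriers
    if rounding == "nearest":
        return math.floor(ratio + 0.5)
    if rounding == "ceiling":
        return math.ceil(ratio)
    raise ValueError(f"unknown rounding mode {rounding!r}")


def position_classification_table(
    variants: Sequence[VariantRecord],
    percentages: bool = False,
) -> pd.DataFrame:
    """Cross-tab of unique variants: position bin x classification.

    Rows are position bins (all seven, in splice-relevance order), columns
    classification tiers. With ``percentages=True``, rows are normalised to
    row-wise percentages (one decimal).
    """
    bins = [b.value for b in PositionBin]
    classes = [c.value for c in Classification]
    table = pd.DataFrame(0, index=bins, columns=classes, dtype=int)
    for v in variants:
        if v.position_bin is None:
            raise ValueError(f"{v.variant_key}: position_bin not assigned")
        table.loc[v.position_bin.value, v.classification.value] += 1
    if percentages:
        totals = table.sum(axis=1)
        pct = table.astype(float)
        for b in bins:
            tot = totals[b]
            pct.loc[b] = [pct1(100.0 * x / tot) if tot else 0.0 for x in table.loc[b]]
        return pct
    return table


def event_type_counts(events: Iterable[SpliceEvent | EventType | str]) -> Dict[str, int]:
    """Count unique splicing events by taxonomy type (ESF/ESP/ES/IP/IC)."""
    counts = {t.value: 0 for t in EventType if t is not EventType.UNCLASSIFIED}
    for e in events:
        t = e.event_type.value if isinstance(e, SpliceEvent) else (
            e.value if isinstance(e, EventType) else str(e)
        )
        if t in counts:
            counts[t] += 1
    return counts


def build_cohort_summary(
    variants: Sequence[VariantRecord],
    events: Sequence[SpliceEvent],
    outcomes: Sequence[ClassificationOutcome],
    variant_carriers: Mapping[str, Sequence[str]],
    n_individuals: int,
    n_tests: Optional[int] = None,
) -> CohortSummary:
    """Assemble the full landscape summary for a analysed cohort.

    ``variant_carriers`` maps variant keys to carrier individual ids, used
    to count individuals (not variants) for the yield/VUS deltas and the
    per-patient frequencies of deep-intronic variants.
    """
    outcome_by_key = {o.variant_key: o for o in outcomes}
    flags: Dict[str, List[bool]] = {}
    for vkey, outcome in outcome_by_key.items():
        for ind in variant_carriers.get(vkey, ()):  # one flag set per individual
            up, res = flags.setdefault(ind, [False, False])
            if outcome.impact is Impact.UPGRADE:
                flags[ind][0] = True
            if outcome.impact in (Impact.UPGRADE, Impact.DOWNGRADE):
                flags[ind][1] = True
    y, r = yield_and_vus_delta({k: tuple(v) for k, v in flags.items()}, n_individuals)

    deep_bins = {PositionBin.DEEP_INTRONIC_GT20}
    gt10_bins = {PositionBin.INTRONIC_11_20, PositionBin.DEEP_INTRONIC_GT20}
    carriers_gt20 = {
        ind
        for v in variants
        if v.position_bin in deep_bins
        for ind in variant_carriers.get(v.variant_key, ())
    }
    carriers_gt10 = {
        ind
        for v in variants
        if v.position_bin in gt10_bins
        for ind in variant_carriers.get(v.variant_key, ())
    }
    freqs = {
        "intronic_gt10": per_patient_frequency(len(carriers_gt10), n_individuals)
        if carriers_gt10
        else None,
        "intronic_gt20": per_patient_frequency(len(carriers_gt20), n_individuals)
        if carriers_gt20
        else None,
    }
    return CohortSummary(
        n_individuals=n_individuals,
        n_tests=n_tests if n_tests is not None else n_individuals,
        variant_type_proportions=variant_type_distribution(variants) if variants else {},
        position_bin_table=position_classification_table(variants),
        event_type_counts=event_type_counts(events),
        yield_delta_pct=y,
        vus_delta_pct=r,
        per_patient_frequencies=freqs,
    )
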