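"""RNA-evidence integration: mechanism inference, association, reclassification.

Association of a splice event with a DNA variant weighs four lines of
evidence: the carrier's PSI, the event's specificity against the healthy
control pool, reproducibility in additional carriers of the same variant,
and a plausible mechanism (novel splice-site creation, native-site
weakening, branch-point deletion, or - flag-only - possible disruption of
an exonic splicing enhancer). The deterministic rule engine replaces
expert manual review; every decision carries a machine-readable reason
trail.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from . import pwm
from .events import EventType, FrameEffect, SpliceEvent, _removal
from .gene_model import (
    CdnaParseError,
    GeneModel,
    TranscriptPosition,
    parse_cdna_variant,
    revcomp,
    transcript_to_genomic,
)
from .psi import (
    ControlProfile,
    PsiObservation,
    Specificity,
    needs_rtpcr_confirmation,
    specificity_test,
)
from .variants import Classification, VariantRecord, VariantType

PWM_DELTA = 2.0  #: log-odds gain/loss calling creation or weakening
BRANCH_WINDOW = (18, 44)  #: nt upstream of a native acceptor holding the branch point
LINKAGE_WINDOW = 5000  #: max nt between a variant and a candidate event
#: A created site must itself be strong: alt window >= this fraction of the PWM max.
NOVEL_SITE_MIN_FRACTION = 0.5


class Mechanism(Enum):
    NOVEL_SITE_CREATION = "novel_site_creation"
    NATIVE_SITE_WEAKENING = "native_site_weakening"
    BRANCH_POINT_DELETION = "branch_point_deletion"
    POSSIBLE_ESE_DISRUPTION = "possible_ese_disruption"
    UNKNOWN = "unknown"


class Overall(Enum):
    ASSOCIATED = "associated"
    NOT_ASSOCIATED = "not_associated"
    INDETERMINATE = "indeterminate"


class Impact(Enum):
    UPGRADE = "upgrade"
    DOWNGRADE = "downgrade"
    CONFIRM = "confirm"
    NONE = "none"


@dataclass(frozen=True)
class GeneSequence:
    """Reference sequence for one gene's locus, genome-forward orientation.

    ``offset`` is the genomic coordinate of ``seq[0]``. Any object with a
    compatible ``fetch(start, end)`` (e.g. a pyfaidx-backed adapter) can
    stand in for this class.
    """

    chrom: str
    seq: str
    offset: int = 0

    def fetch(self, start: int, end: int) -> str:
        """Genome-forward subsequence for the 0-based half-open interval."""
        if start < self.offset or end > self.offset + len(self.seq):
            raise ValueError(f"requested [{start}, {end}) outside sequence bounds")
        return self.seq[start - self.offset : end - self.offset]


@dataclass(frozen=True)
class AssociationEvidence:
    """Integrated RNA evidence for one variant."""

    variant_key: str
    event_key: Optional[str]
    carrier_psi: float  # NaN when no quantifiable observation
    specificity: Specificity
    n_reproducing_carriers: int
    mechanism: Mechanism
    frame_effect: FrameEffect
    overall: Overall
    carrier_observation: Optional[PsiObservation] = None
    reasons: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.overall is Overall.ASSOCIATED:
            if self.event_key is None or self.specificity is not Specificity.SPECIFIC:
                raise ValueError("associated evidence requires a specific event")


@dataclass(frozen=True)
class ClassificationOutcome:
    """Effect of RNA evidence on a variant's classification."""

    variant_key: str
    prior_classification: Classification
    rna_informed_classification: Classification
    impact: Impact
    reasons: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.impact in (Impact.NONE, Impact.CONFIRM):
            if self.prior_classification != self.rna_informed_classification:
                raise ValueError("impact none/confirm requires unchanged classification")


# ---------------------------------------------------------------------------
# Mechanism inference
# ---------------------------------------------------------------------------


def _tx_window(ref: GeneSequence, model: GeneModel, gstart: int, length: int) -> str:
    """Window of ``length`` transcript-oriented bases whose transcript-first
    base sits at genomic ``gstart``."""
    if model.strand == "+":
        return ref.fetch(gstart, gstart + length).upper()
    return revcomp(ref.fetch(gstart - length + 1, gstart + 1)).upper()


def _native_window_starts(model: GeneModel, site_type: str) -> set:
    """Genomic coordinates of the transcript-first base of each native
    donor/acceptor PWM window."""
    out = set()
    for k in range(model.n_exons - 1):
        if site_type == "donor":
            boundary = model.donor_boundary(k)  # first intronic base
            out.add(boundary - pwm.DONOR_EXONIC if model.strand == "+" else boundary + pwm.DONOR_EXONIC)
        else:
            boundary = model.acceptor_boundary(k)  # first exonic base
            out.add(boundary - pwm.ACCEPTOR_INTRONIC if model.strand == "+" else boundary + pwm.ACCEPTOR_INTRONIC)
    return out


def _deleted_interval(v: VariantRecord, model: GeneModel) -> Optional[Tuple[int, int]]:
    """Genomic 0-based half-open interval removed by a deletion variant."""
    try:
        parsed = parse_cdna_variant(v.hgvs_c)
    except CdnaParseError:
        parsed = None
    if parsed is not None and parsed.edit.startswith("del") and parsed.end is not None:
        g1 = transcript_to_genomic(model, parsed.start)
        g2 = transcript_to_genomic(model, parsed.end)
        return min(g1, g2), max(g1, g2) + 1
    if len(v.ref) > len(v.alt):  # VCF-style deletion with anchor base
        return v.pos + len(v.alt), v.pos + len(v.ref)
    return None


def _branch_windows(model: GeneModel, window: Tuple[int, int]) -> List[Tuple[int, int]]:
    """Genomic intervals of the branch-point window upstream of each native
    acceptor (offsets -window[1]..-window[0] into the intron)."""
    near, far = window
    out = []
    for k in range(model.n_exons - 1):
        s, e = model.introns[k]
        if model.strand == "+":
            out.append((e - far, e - near + 1))
        else:
            out.append((s + near - 1, s + far))
    return out


def _native_site_windows(model: GeneModel) -> List[Tuple[int, int]]:
    """Genomic intervals covered by native donor/acceptor PWM windows."""
    out = []
    for k in range(model.n_exons - 1):
        d = model.donor_boundary(k)
        a = model.acceptor_boundary(k)
        if model.strand == "+":
            out.append((d - pwm.DONOR_EXONIC, d - pwm.DONOR_EXONIC + pwm.DONOR_WINDOW))
            out.append((a - pwm.ACCEPTOR_INTRONIC, a - pwm.ACCEPTOR_INTRONIC + pwm.ACCEPTOR_WINDOW))
        else:
            out.append((d + pwm.DONOR_EXONIC - pwm.DONOR_WINDOW + 1, d + pwm.DONOR_EXONIC + 1))
            out.append((a + pwm.ACCEPTOR_INTRONIC - pwm.ACCEPTOR_WINDOW + 1, a + pwm.ACCEPTOR_INTRONIC + 1))
    return out


def mechanism_inference(
    v: VariantRecord,
    model: GeneModel,
    ref: Optional[GeneSequence],
    associated_event: Optional[SpliceEvent] = None,
    pwm_delta: float = PWM_DELTA,
    branch_window: Tuple[int, int] = BRANCH_WINDOW,
) -> Mechanism:
    """Infer how a DNA variant perturbs splicing.

    For SNVs, every donor/acceptor PWM window overlapping the variant is
    scored for both alleles: a loss of ``pwm_delta`` log-odds at a native
    site calls weakening; a gain of ``pwm_delta`` at a non-native window
    whose alt-allele score reaches half the PWM maximum calls novel-site
    creation. Deletions overlapping a native site window call weakening;
    deletions overlapping the 18-44 nt branch-point window upstream of a
    native acceptor call branch-point deletion. An exonic variant with no
    site-score change but an associated exon-skip event is flagged as
    possible ESE disruption. Anything else - including a missing reference
    sequence - is UNKNOWN.
    """
    if ref is None:
        return Mechanism.UNKNOWN

    deleted = _deleted_interval(v, model)
    if deleted is not None and deleted[1] - deleted[0] > 0 and len(v.alt) <= 1:
        for s, e in _native_site_windows(model):
            if max(s, deleted[0]) < min(e, deleted[1]):
                return Mechanism.NATIVE_SITE_WEAKENING
        for s, e in _branch_windows(model, branch_window):
            if max(s, deleted[0]) < min(e, deleted[1]):
                return Mechanism.BRANCH_POINT_DELETION
        return Mechanism.UNKNOWN

    if not v.is_snv:
        return Mechanism.UNKNOWN

    g = v.pos
    ref_base = v.ref.upper()
    alt_base = v.alt.upper()
    step = 1 if model.strand == "+" else -1
    weakening = False
    creation = False
    for site_type in ("donor", "acceptor"):
        wlen = pwm.window_length(site_type)
        natives = _native_window_starts(model, site_type)
        max_s = pwm.max_score(site_type)
        for k in range(wlen):  # k = transcript-offset of the variant in the window
            wstart = g - step * k
            try:
                window = _tx_window(ref, model, wstart, wlen)
            except ValueError:
                continue
            expect = ref_base if model.strand == "+" else revcomp(ref_base)
            if window[k] != expect:
                continue  # reference mismatch; skip defensively
            alt_in_tx = alt_base if model.strand == "+" else revcomp(alt_base)
            alt_window = window[:k] + alt_in_tx + window[k + 1 :]
            try:
                s_ref = pwm.splice_site_strength(window, site_type)
                s_alt = pwm.splice_site_strength(alt_window, site_type)
            except ValueError:
                continue
            delta = s_alt - s_ref
            if wstart in natives and delta <= -pwm_delta:
                weakening = True
            if wstart not in natives and delta >= pwm_delta and s_alt >= NOVEL_SITE_MIN_FRACTION * max_s:
                creation = True
    if weakening:
        return Mechanism.NATIVE_SITE_WEAKENING
    if creation:
        return Mechanism.NOVEL_SITE_CREATION
    if (
        v.position is not None
        and v.position.intron_offset == 0
        and associated_event is not None
        and associated_event.event_type in (EventType.ESF, EventType.ESP, EventType.ES)
    ):
        return Mechanism.POSSIBLE_ESE_DISRUPTION
    return Mechanism.UNKNOWN


# ---------------------------------------------------------------------------
# Association
# ---------------------------------------------------------------------------


def _event_distance(event: SpliceEvent, g: int) -> int:
    a, b = event.affected_region
    if a <= g < b:
        return 0
    return a - g if g < a else g - b + 1


def associate(
    v: VariantRecord,
    carrier_events: Mapping[str, Sequence[Tuple[SpliceEvent, PsiObservation]]],
    control_profiles: Mapping[str, ControlProfile],
    model: GeneModel,
    mechanism: Mechanism = Mechanism.UNKNOWN,
    linkage_window: int = LINKAGE_WINDOW,
    min_psi: float = 0.10,
    fold: float = 5.0,
    min_denominator: int = 100,
    adequate_depth: Optional[bool] = None,
) -> AssociationEvidence:
    """Integrate RNA evidence for one variant across its carriers.

    ``carrier_events`` maps each carrier sample to its detected events
    (with PSI observations); ``control_profiles`` maps event keys to
    control-pool profiles. Candidate events lie within ``linkage_window``
    nt of the variant. The chosen event maximises carrier PSI among
    specific observations; reproducibility counts additional carriers
    showing the same event with a specific PSI. Overall association
    requires specificity plus either reproducibility or a known mechanism.
    """
    reasons: List[str] = []
    if not carrier_events:
        return AssociationEvidence(
            v.variant_key, None, math.nan, Specificity.INDETERMINATE, 0,
            mechanism, FrameEffect.NOT_APPLICABLE, Overall.INDETERMINATE,
            reasons=("no carrier RNA sample",),
        )

    candidates: List[Tuple[str, SpliceEvent, PsiObservation, Specificity]] = []
    any_observation = False
    for sample_id, pairs in carrier_events.items():
        for event, obs in pairs:
            if event.event_type is EventType.UNCLASSIFIED:
                continue
            if _event_distance(event, v.pos) > linkage_window:
                continue
            any_observation = True
            profile = control_profiles.get(event.event_key)
            if profile is None:
                profile = ControlProfile(event.event_key, 0, ())
            spec = specificity_test(obs, profile, min_psi, fold, min_denominator)
            candidates.append((sample_id, event, obs, spec))

    specific = [c for c in candidates if c[3] is Specificity.SPECIFIC]
    if specific:
        best = max(specific, key=lambda c: c[2].psi)
        sample_id, event, obs, spec = best
        reproducing = len({s for s, e, o, sp in specific if e.event_key == event.event_key} - {sample_id})
        overall = (
            Overall.ASSOCIATED
            if reproducing >= 1 or mechanism is not Mechanism.UNKNOWN
            else Overall.INDETERMINATE
        )
        if overall is Overall.INDETERMINATE:
            reasons.append("specific event without reproducibility or mechanism")
        else:
            reasons.append(
                f"specific event {event.event_key} at PSI {obs.psi:.3f}"
                + (f"; reproduced in {reproducing} additional carrier(s)" if reproducing else "")
                + (f"; mechanism {mechanism.value}" if mechanism is not Mechanism.UNKNOWN else "")
            )
        return AssociationEvidence(
            v.variant_key, event.event_key, obs.psi, spec, reproducing,
            mechanism, event.frame_effect, overall, carrier_observation=obs,
            reasons=tuple(reasons),
        )

    # No specific event: decide between not_associated and indeterminate.
    indeterminate_only = candidates and all(c[3] is Specificity.INDETERMINATE for c in candidates)
    if adequate_depth is None:
        adequate_depth = any(
            c[3] is not Specificity.INDETERMINATE for c in candidates
        ) or (not candidates)
    if indeterminate_only or not adequate_depth:
        return AssociationEvidence(
            v.variant_key, None, math.nan, Specificity.INDETERMINATE, 0,
            mechanism, FrameEffect.NOT_APPLICABLE, Overall.INDETERMINATE,
            reasons=("insufficient coverage for a call",),
        )
    best_obs = max((c[2] for c in candidates), key=lambda o: o.psi, default=None)
    reasons.append(
        "no specific event within linkage window"
        if candidates
        else "no aberrant event near variant at adequate depth"
    )
    return AssociationEvidence(
        v.variant_key,
        None,
        best_obs.psi if best_obs is not None else 0.0,
        Specificity.NOT_SPECIFIC if candidates else Specificity.NOT_SPECIFIC,
        0,
        mechanism,
        FrameEffect.NOT_APPLICABLE,
        Overall.NOT_ASSOCIATED,
        carrier_observation=best_obs,
        reasons=tuple(reasons),
    )


# ---------------------------------------------------------------------------
# Reclassification
# ---------------------------------------------------------------------------


def reclassify(
    v: VariantRecord,
    ev: AssociationEvidence,
    model: Optional[GeneModel] = None,
    rtpcr_confirmed: bool = False,
    tandem_dup: Optional[Tuple[bool, object, str]] = None,
) -> ClassificationOutcome:
    """Decide the RNA-informed classification for one variant.

    Rules (configurable in spirit, deterministic here):

    * gross duplication + tandem back-junction + frameshift: VUS -> LP;
    * prior VUS + associated event altering coding sequence, with adequate
      event coverage (or RT-PCR confirmation): VUS -> LP upgrade;
    * prior VUS splicing candidate, not associated at adequate depth,
      beyond the canonical +/-2 dinucleotide: VUS -> LB downgrade;
    * prior P/LP with a concordant associated event: confirmed, which
      counts as no impact for yield arithmetic;
    * anything else: no impact.
    """
    prior = v.classification
    reasons: List[str] = []

    if (
        v.variant_type is VariantType.GROSS_DEL_DUP
        and tandem_dup is not None
        and tandem_dup[0]
        and ev.frame_effect is not FrameEffect.IN_FRAME
        and prior is Classification.VUS
    ):
        return ClassificationOutcome(
            v.variant_key, prior, Classification.LP, Impact.UPGRADE,
            ("tandem duplication back-junction with frameshift",),
        )

    if prior is Classification.VUS and ev.overall is Overall.ASSOCIATED:
        coding_altered = ev.frame_effect in (FrameEffect.FRAMESHIFT, FrameEffect.IN_FRAME)
        confirmed = rtpcr_confirmed or (
            ev.carrier_observation is not None
            and not needs_rtpcr_confirmation(ev.carrier_observation)
        )
        if ev.frame_effect is FrameEffect.FRAMESHIFT or coding_altered:
            if confirmed:
                reasons.append("associated specific event altering coding sequence")
                return ClassificationOutcome(
                    v.variant_key, prior, Classification.LP, Impact.UPGRADE, tuple(reasons)
                )
            reasons.append("upgrade withheld pending RT-PCRseq confirmation")
            return ClassificationOutcome(
                v.variant_key, prior, prior, Impact.NONE, tuple(reasons)
            )

    if (
        prior is Classification.VUS
        and ev.overall is Overall.NOT_ASSOCIATED
        and v.position is not None
        and abs(v.intron_offset) > 2
    ):
        reasons.append("no aberrant RNA at adequate depth")
        return ClassificationOutcome(
            v.variant_key, prior, Classification.LB, Impact.DOWNGRADE, tuple(reasons)
        )

    if prior in (Classification.P, Classification.LP) and ev.overall is Overall.ASSOCIATED:
        return ClassificationOutcome(
            v.variant_key, prior, prior, Impact.CONFIRM,
            ("RNA concordant with existing interpretation",),
        )

    return ClassificationOutcome(v.variant_key, prior, prior, Impact.NONE, tuple(reasons))
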