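"""Aberrant splice-event detection and the five-type taxonomy.

Events are detected from splice-junction count tables (STAR ``SJ.out.tab``
style) relative to one canonical isoform. Five event types are recognised:

* ``ESF`` - full skipping of one or more exons, all used sites canonical;
* ``ESP`` - partial exon skipping via an alternative exonic splice site;
* ``ES``  - a combination of at least one full and one partial exon skip;
* ``IP``  - partial intron inclusion: intronic sequence retained flanking
  an exon via an alternative intronic splice site;
* ``IC``  - a cryptic exon (pseudoexon): an intronic segment bounded by a
  pair of novel junctions wholly inside one canonical intron.

Full intron retention is deliberately never emitted: junction tables carry
no signal for an unspliced intron, so an IR call cannot be supported by
this evidence class.

Geometry is evaluated in genomic coordinates (junction coordinates are
strand-independent); exon numbering in reports follows transcription
order. A junction row is the 1-based inclusive genomic interval of the
spliced-out (intronic) sequence, i.e. columns 1-4 and 7 of the STAR
dialect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from .gene_model import GeneModel

log = logging.getLogger(__name__)

#: (chrom, intron_start 1-based, intron_end 1-based inclusive, strand)
JunctionKey = Tuple[str, int, int, str]

#: Largest exonized interval accepted as a cryptic exon.
MAX_CRYPTIC_EXON = 1000
DEFAULT_MIN_READS = 3


class EventType(Enum):
    ESF = "ESF"
    ESP = "ESP"
    ES = "ES"
    IP = "IP"
    IC = "IC"
    UNCLASSIFIED = "UNCLASSIFIED"


class FrameEffect(Enum):
    IN_FRAME = "in_frame"
    FRAMESHIFT = "frameshift"
    NOT_APPLICABLE = "not_applicable"


@dataclass
class JunctionTable:
    """Per-sample splice-junction read counts keyed by genomic interval."""

    sample_id: str
    counts: Dict[JunctionKey, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, n in self.counts.items():
            if n < 0:
                raise ValueError(f"negative read count for junction {key}")

    def get(self, key: JunctionKey, default: int = 0) -> int:
        return self.counts.get(key, default)

    def add(self, key: JunctionKey, reads: int) -> None:
        self.counts[key] = self.counts.get(key, 0) + reads

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"chrom": c, "intron_start": s, "intron_end": e, "strand": st, "unique_reads": n}
            for (c, s, e, st), n in sorted(self.counts.items())
        ]
        return pd.DataFrame(rows, columns=["chrom", "intron_start", "intron_end", "strand", "unique_reads"])


@dataclass(frozen=True)
class SpliceEvent:
    """A classified aberrant transcript structure in one gene."""

    event_type: EventType
    gene_symbol: str
    novel_junctions: Tuple[JunctionKey, ...]
    affected_region: Tuple[int, int]  # genomic 0-based half-open union span
    skipped_exons: Tuple[int, ...] = ()  # transcription-order, 1-based
    partial_exons: Tuple[int, ...] = ()
    included_intronic_interval: Optional[Tuple[int, int]] = None  # 0-based half-open
    frame_effect: FrameEffect = FrameEffect.NOT_APPLICABLE
    flags: Tuple[str, ...] = ()

    @property
    def event_key(self) -> str:
        """Stable cross-sample identity: gene, type, sorted junction coords."""
        coords = ",".join(
            f"{c}:{s}-{e}" for c, s, e, _ in sorted(self.novel_junctions)
        )
        return f"{self.gene_symbol}|{self.event_type.value}|{coords}"


# ---------------------------------------------------------------------------
# Canonical junctions
# ---------------------------------------------------------------------------


def canonical_junctions(model: GeneModel) -> Dict[JunctionKey, int]:
    """Junction templates of the canonical isoform, keyed to intron index.

    Returns one junction per intron (empty for a single-exon gene); keys
    use 1-based inclusive intronic coordinates, values are the
    transcription-order intron index.
    """
    out: Dict[JunctionKey, int] = {}
    for k, (s, e) in enumerate(model.introns):
        out[(model.chrom, s + 1, e, model.strand)] = k
    return out


def _removal(key: JunctionKey) -> Tuple[int, int]:
    """0-based half-open genomic interval spliced out by a junction."""
    _, s, e, _ = key
    return s - 1, e


def _tx_exon_number(model: GeneModel, gexon_index: int) -> int:
    """1-based transcription-order number of a genomically-sorted exon."""
    if model.strand == "+":
        return gexon_index + 1
    return model.n_exons - gexon_index


# ---------------------------------------------------------------------------
# Geometry of a removal interval
# ---------------------------------------------------------------------------


def _analyse_removal(R: Tuple[int, int], model: GeneModel):
    """Decompose a spliced-out interval against the exon/intron structure.

    Returns (full_skips, partial_skips, retained_pieces) where skips are
    genomic exon indices and retained pieces are the un-removed parts of
    partially removed introns (0-based half-open intervals).
    """
    a, b = R
    gx = model.gexons
    full, partial = [], []
    for i, (s, e) in enumerate(gx):
        lo, hi = max(s, a), min(e, b)
        if lo >= hi:
            continue
        if a <= s and e <= b:
            full.append(i)
        else:
            partial.append(i)
    retained: List[Tuple[int, int]] = []
    gintrons = sorted((min(x), max(x)) for x in ((s, e) for s, e in model.introns))
    for s, e in gintrons:
        lo, hi = max(s, a), min(e, b)
        if lo >= hi or (a <= s and e <= b):
            continue  # untouched or fully removed: spliced/removed cleanly
        if s < a:
            retained.append((s, a))
        if b < e:
            retained.append((b, e))
    return full, partial, retained


def _classify_single(key: JunctionKey, model: GeneModel):
    """Classify one novel junction; returns (EventType, details, flags)."""
    R = _removal(key)
    full, partial, retained = _analyse_removal(R, model)
    flags: List[str] = []
    skipped = tuple(sorted(_tx_exon_number(model, i) for i in full))
    part = tuple(sorted(_tx_exon_number(model, i) for i in partial))
    if retained and (full or partial):
        return EventType.UNCLASSIFIED, (skipped, part, None), ["mixed_geometry"]
    if len(retained) >= 2:
        return EventType.UNCLASSIFIED, (skipped, part, None), ["unpaired_cryptic"]
    if len(retained) == 1:
        return EventType.IP, ((), (), retained[0]), flags
    if full and partial:
        return EventType.ES, (skipped, part, None), flags
    if full:
        return EventType.ESF, (skipped, (), None), flags
    if partial:
        return EventType.ESP, ((), part, None), flags
    return EventType.UNCLASSIFIED, ((), (), None), ["no_structural_change"]


def classify_event(
    novel_junctions: Sequence[JunctionKey], model: GeneModel
) -> EventType:
    """Classify a pre-grouped set of novel junctions into the taxonomy.

    A pair of junctions bounding a 1-1000 nt interval strictly inside one
    canonical intron is ``IC`` (a cryptic exon); a single junction is
    classified by its removal geometry. Unresolvable geometry returns
    ``UNCLASSIFIED`` (excluded from reports, with a logged reason).
    """
    keys = list(novel_junctions)
    if not keys:
        raise ValueError("classify_event requires at least one junction")
    if len(keys) == 2:
        ic = _ic_geometry(keys[0], keys[1], model)
        if ic is not None:
            start, end, oversized = ic
            return EventType.UNCLASSIFIED if oversized else EventType.IC
        return EventType.UNCLASSIFIED
    if len(keys) > 2:
        return EventType.UNCLASSIFIED
    etype, _, flags = _classify_single(keys[0], model)
    if etype is EventType.UNCLASSIFIED and flags:
        log.info("junction %s unclassifiable: %s", keys[0], ",".join(flags))
    return etype


def _ic_geometry(k1: JunctionKey, k2: JunctionKey, model: GeneModel):
    """Cryptic-exon geometry check for a junction pair.

    Returns (exon_start, exon_end, oversized) when the pair forms a
    donor-side and acceptor-side junction within one canonical intron
    bounding a positive-length exonized interval, else None.
    """
    gintrons = [(min(s, e), max(s, e)) for s, e in model.introns]
    for s, e in gintrons:
        for a_key, b_key in ((k1, k2), (k2, k1)):
            Ra, Rb = _removal(a_key), _removal(b_key)
            # A-type: starts at the intron start, ends strictly inside
            # B-type: ends at the intron end, starts strictly inside
            if (
                Ra[0] == s
                and s < Ra[1] < e
                and Rb[1] == e
                and s < Rb[0] < e
                and Ra[1] < Rb[0]
            ):
                length = Rb[0] - Ra[1]
                return Ra[1], Rb[0], length > MAX_CRYPTIC_EXON
    return None


# ---------------------------------------------------------------------------
# Detection
# ---------------------------------------------------------------------------


def detect_events(
    sample: JunctionTable,
    model: GeneModel,
    min_reads: int = DEFAULT_MIN_READS,
) -> List[SpliceEvent]:
    """Detect aberrant splice events in one sample against one gene model.

    Every non-canonical junction with ``unique_reads >= min_reads`` inside
    the gene span is assigned to exactly one event. Junction pairs forming
    a cryptic exon are merged into a single ``IC`` event; back-junctions
    (intron_start > intron_end, the tandem-duplication signature) are left
    to :func:`tandem_duplication_check`. Junctions outside the gene span
    are ignored with a warning.
    """
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    templates = canonical_junctions(model)
    lo, hi = model.span
    novel: List[JunctionKey] = []
    for key, reads in sample.counts.items():
        chrom, s, e, _ = key
        if chrom != model.chrom or s > e:
            continue
        if e <= lo or s - 1 >= hi:
            log.warning("junction %s outside %s span; ignored", key, model.gene_symbol)
            continue
        if key in templates or reads < min_reads:
            continue
        novel.append(key)
    novel.sort()

    events: List[SpliceEvent] = []
    used: set = set()

    # Pair cryptic-exon junctions first, greedily per intron.
    gintrons = [(min(s, e), max(s, e)) for s, e in model.introns]
    for intron_idx, (s, e) in enumerate(gintrons):
        a_type = [
            k for k in novel
            if k not in used and _removal(k)[0] == s and s < _removal(k)[1] < e
        ]
        b_type = [
            k for k in novel
            if k not in used and _removal(k)[1] == e and s < _removal(k)[0] < e
        ]
        a_type.sort(key=lambda k: _removal(k)[1])
        b_type.sort(key=lambda k: _removal(k)[0])
        for a_key in a_type:
            partner = next(
                (b for b in b_type if b not in used and _removal(b)[0] > _removal(a_key)[1]),
                None,
            )
            if partner is None:
                continue
            used.add(a_key)
            used.add(partner)
            exon_start, exon_end = _removal(a_key)[1], _removal(partner)[0]
            oversized = exon_end - exon_start > MAX_CRYPTIC_EXON
            etype = EventType.UNCLASSIFIED if oversized else EventType.IC
            flags = ("oversized_cryptic_interval",) if oversized else ()
            ev = SpliceEvent(
                event_type=etype,
                gene_symbol=model.gene_symbol,
                novel_junctions=(a_key, partner),
                affected_region=(_removal(a_key)[0], _removal(partner)[1]),
                included_intronic_interval=(exon_start, exon_end),
                flags=flags,
            )
            events.append(_with_frame(ev, model))

    # Remaining novel junctions: one event each.
    for key in novel:
        if key in used:
            continue
        etype, (skipped, part, retained), flags = _classify_single(key, model)
        ev = SpliceEvent(
            event_type=etype,
            gene_symbol=model.gene_symbol,
            novel_junctions=(key,),
            affected_region=_removal(key),
            skipped_exons=skipped,
            partial_exons=part,
            included_intronic_interval=retained,
            flags=tuple(flags),
        )
        events.append(_with_frame(ev, model))
    return events


def _with_frame(event: SpliceEvent, model: GeneModel) -> SpliceEvent:
    from dataclasses import replace

    return replace(event, frame_effect=frame_effect(event, model))


# ---------------------------------------------------------------------------
# Frame effect
# ---------------------------------------------------------------------------


def frame_effect(event: SpliceEvent, model: GeneModel) -> FrameEffect:
    """Net coding-length change of an event modulo 3.

    Deleted coding length is the exonic sequence removed intersected with
    the CDS; inserted length is the retained intronic interval when its
    host intron lies between coding exons. Events touching no coding
    sequence are ``NOT_APPLICABLE``.
    """
    cds_lo, cds_hi = model.cds_start, model.cds_end
    deleted = 0
    for key in event.novel_junctions:
        a, b = _removal(key)
        for s, e in model.gexons:
            lo = max(s, a, cds_lo)
            hi = min(e, b, cds_hi)
            if hi > lo:
                deleted += hi - lo
    inserted = 0
    if event.included_intronic_interval is not None:
        s, e = event.included_intronic_interval
        if s >= cds_lo and e <= cds_hi:  # intron between coding exons
            inserted = e - s
    if deleted == 0 and inserted == 0:
        return FrameEffect.NOT_APPLICABLE
    return FrameEffect.IN_FRAME if (inserted - deleted) % 3 == 0 else FrameEffect.FRAMESHIFT


# ---------------------------------------------------------------------------
# Tandem duplication back-junction
# ---------------------------------------------------------------------------


def tandem_duplication_check(
    sample: JunctionTable,
    model: GeneModel,
    dup_exon_range: Tuple[int, int],
    min_reads: int = DEFAULT_MIN_READS,
):
    """Test whether a gross duplication call is in tandem.

    A tandem duplication of exons ``first..last`` (transcription-order,
    1-based) produces an exon-order-inverting junction joining the donor
    of the duplicated range's last exon to the acceptor of its first exon.
    In reference coordinates that junction has its acceptor upstream of
    its donor, and is stored with ``intron_start > intron_end``.

    Returns ``(is_tandem, supporting_junction_or_None, flag)`` where flag
    is ``"insufficient_data"`` when no junctions cover the gene and
    ``"low_evidence"`` when a back-junction exists below ``min_reads``.
    """
    first, last = dup_exon_range
    if not 1 <= first <= last <= model.n_exons:
        raise ValueError(f"bad duplicated exon range {dup_exon_range}")
    lo, hi = model.span
    covering = [
        k for k in sample.counts
        if k[0] == model.chrom and min(k[1], k[2]) - 1 < hi and max(k[1], k[2]) > lo
    ]
    if not covering:
        return False, None, "insufficient_data"
    # transcription-order exon tuples
    ex_first = model.exons[first - 1]
    ex_last = model.exons[last - 1]
    if model.strand == "+":
        donor_adj = ex_last[1] + 1  # first base after the donor exon, 1-based
        acceptor_adj = ex_first[0]  # last base before the acceptor exon, 1-based
    else:
        donor_adj = ex_last[0]
        acceptor_adj = ex_first[1] + 1
    # Back-junctions are stored order-inverted (start > end) on both strands.
    expected = (model.chrom, max(donor_adj, acceptor_adj), min(donor_adj, acceptor_adj), model.strand)
    reads = sample.get(expected, 0)
    if reads >= min_reads:
        return True, expected, ""
    if reads > 0:
        return False, expected, "low_evidence"
    return False, None, ""
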