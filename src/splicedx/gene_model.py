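"""Panel gene models and HGVS-style cDNA coordinate arithmetic.

A :class:`GeneModel` holds one canonical isoform of one panel gene: its
exons as genomic 0-based half-open intervals in transcription order, the
CDS bounds, and the strand. All interval arithmetic is 0-based half-open
internally; the external notation is the field-standard ``c.`` coordinate
with signed intronic offsets (``c.423-3958C>T`` is 3958 nt upstream of the
acceptor of the exon whose first coding base is c.423).

Position bins follow the clinically meaningful partition of splice-relevant
positions: exonic (with the donor-adjacent last exonic nucleotide singled
out), the canonical +/-1,2 dinucleotides, near-intronic 3-5 and 6-10, 11-20,
and deep-intronic beyond 20 nt.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from functools import cached_property
from typing import Optional, Tuple

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


class CdnaParseError(ValueError):
    """Raised when an HGVS-like cDNA string cannot be parsed."""


class PositionBin(Enum):
    """Partition of variant positions relative to the exon structure."""

    EXONIC_INTERNAL = "exonic_internal"
    EXONIC_LAST_NT = "exonic_last_nt"
    CANONICAL_1_2 = "canonical_1_2"
    INTRONIC_3_5 = "intronic_3_5"
    INTRONIC_6_10 = "intronic_6_10"
    INTRONIC_11_20 = "intronic_11_20"
    DEEP_INTRONIC_GT20 = "deep_intronic_gt20"


@dataclass(frozen=True)
class TranscriptPosition:
    """A cDNA position: coding anchor plus a signed intronic offset.

    ``intron_offset`` 0 means exonic; ``+k`` is k nt into the intron
    downstream of the anchor exon's donor; ``-k`` is k nt into the intron
    upstream of the anchor exon's acceptor.
    """

    coding_pos: int
    intron_offset: int = 0
    anchor_exon_index: int = -1  # transcription-order exon index; -1 = unknown

    def __post_init__(self) -> None:
        if self.coding_pos < 1:
            raise ValueError("coding_pos must be a positive integer")

    def __str__(self) -> str:
        if self.intron_offset == 0:
            return str(self.coding_pos)
        return f"{self.coding_pos}{self.intron_offset:+d}"

    @property
    def is_intronic(self) -> bool:
        return self.intron_offset != 0


@dataclass(frozen=True)
class CdnaVariant:
    """A parsed HGVS-like cDNA variant name (single position or range)."""

    start: TranscriptPosition
    end: Optional[TranscriptPosition]
    edit: str  # e.g. "C>T", "del2827", "dup", "insA", or ""

    def __str__(self) -> str:
        core = str(self.start)
        if self.end is not None:
            core += f"_{self.end}"
        return f"c.{core}{self.edit}"


@dataclass(frozen=True)
class GeneModel:
    """One panel gene's canonical isoform.

    ``exons`` are genomic 0-based half-open intervals in *transcription*
    order (descending genomic coordinates on the minus strand).
    ``cds_start``/``cds_end`` are genomic and bound the CDS half-open.
    """

    gene_symbol: str
    chrom: str
    strand: str
    exons: Tuple[Tuple[int, int], ...]
    cds_start: int
    cds_end: int
    isoform_id: str = "NM_000000.0"

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if len(self.exons) < 1:
            raise ValueError("gene model needs at least one exon")
        for s, e in self.exons:
            if not (0 <= s < e):
                raise ValueError(f"invalid exon interval [{s}, {e})")
        gx = sorted(self.exons)
        expected = sorted(self.exons, reverse=(self.strand == "-"))
        if list(self.exons) != expected:
            raise ValueError("exons must be sorted in transcription order")
        for (s1, e1), (s2, e2) in zip(gx, gx[1:]):
            if e1 >= s2:
                raise ValueError("exons overlap or abut (intron length must be >= 1)")
        if not (self._span[0] <= self.cds_start < self.cds_end <= self._span[1]):
            raise ValueError("CDS bounds fall outside the gene span")
        for g in (self.cds_start, self.cds_end - 1):
            if not any(s <= g < e for s, e in self.exons):
                raise ValueError("CDS bounds must fall within exonic sequence")

    # ---- basic structure -------------------------------------------------

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @cached_property
    def gexons(self) -> Tuple[Tuple[int, int], ...]:
        """Exons sorted by ascending genomic coordinate."""
        return tuple(sorted(self.exons))

    @cached_property
    def _span(self) -> Tuple[int, int]:
        gx = sorted(self.exons)
        return gx[0][0], gx[-1][1]

    @property
    def span(self) -> Tuple[int, int]:
        """Genomic extent of the gene, 0-based half-open."""
        return self._span

    @cached_property
    def introns(self) -> Tuple[Tuple[int, int], ...]:
        """Introns in transcription order, as genomic (start, end) with start < end."""
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if self.strand == "+":
                out.append((e1, s2))
            else:
                out.append((e2, s1))
        return tuple(out)

    @cached_property
    def _cum(self) -> Tuple[int, ...]:
        """Cumulative transcript length after each exon (transcription order)."""
        tot, out = 0, []
        for s, e in self.exons:
            tot += e - s
            out.append(tot)
        return tuple(out)

    @property
    def tx_length(self) -> int:
        return self._cum[-1]

    # ---- transcript <-> genomic -----------------------------------------

    def tx_to_genomic(self, t: int) -> int:
        """Genomic coordinate (0-based) of 1-based transcript position ``t``."""
        if not 1 <= t <= self.tx_length:
            raise ValueError(f"transcript position {t} outside 1..{self.tx_length}")
        k = self._exon_of_tx(t)
        before = self._cum[k - 1] if k else 0
        within = t - before - 1
        s, e = self.exons[k]
        return s + within if self.strand == "+" else e - 1 - within

    def _exon_of_tx(self, t: int) -> int:
        for k, c in enumerate(self._cum):
            if t <= c:
                return k
        raise ValueError(f"transcript position {t} outside transcript")

    def genomic_to_tx(self, g: int) -> int:
        """1-based transcript position of exonic genomic coordinate ``g``."""
        for k, (s, e) in enumerate(self.exons):
            if s <= g < e:
                before = self._cum[k - 1] if k else 0
                within = g - s if self.strand == "+" else e - 1 - g
                return before + within + 1
        raise ValueError(f"genomic position {g} is not exonic in {self.gene_symbol}")

    @cached_property
    def cds_tx_start(self) -> int:
        g = self.cds_start if self.strand == "+" else self.cds_end - 1
        return self.genomic_to_tx(g)

    @cached_property
    def cds_tx_end(self) -> int:
        g = self.cds_end - 1 if self.strand == "+" else self.cds_start
        return self.genomic_to_tx(g)

    @property
    def cds_length(self) -> int:
        return self.cds_tx_end - self.cds_tx_start + 1

    # ---- junction boundaries --------------------------------------------

    def donor_boundary(self, intron_index: int) -> int:
        """Genomic coordinate of the first intronic base at the donor of
        intron ``intron_index`` (transcription order)."""
        s, e = self.introns[intron_index]
        return s if self.strand == "+" else e - 1

    def acceptor_boundary(self, intron_index: int) -> int:
        """Genomic coordinate of the first exonic base downstream of the
        acceptor of intron ``intron_index``."""
        s, e = self.introns[intron_index]
        return e if self.strand == "+" else s - 1


# ---------------------------------------------------------------------------
# cDNA notation parsing
# ---------------------------------------------------------------------------

_POS_RE = re.compile(r"^(\d+)([+-]\d+)?$")
_FULL_RE = re.compile(r"^(?:c\.)?(?P<p1>\d+(?:[+-]\d+)?)(?:_(?P<p2>\d+(?:[+-]\d+)?))?(?P<edit>.*)$")
_EDIT_RE = re.compile(r"^$|^[ACGTN]>[ACGTN]$|^del(?:\d+|[ACGTN]+)?$|^dup(?:\d+|[ACGTN]+)?$|^ins[ACGTN]+$")


def _parse_pos_token(token: str) -> TranscriptPosition:
    m = _POS_RE.match(token)
    if not m:
        raise CdnaParseError(f"malformed cDNA position token {token!r}")
    return TranscriptPosition(int(m.group(1)), int(m.group(2) or 0))


def parse_cdna_variant(text: str) -> CdnaVariant:
    """Parse an HGVS-like cDNA variant name into positions plus edit.

    Handles single positions (``c.423-3958C>T``) and ranges
    (``c.1565+672_1566-23del2827``). UTR anchors and protein notation are
    out of scope.
    """
    m = _FULL_RE.match(text.strip())
    if not m:
        raise CdnaParseError(f"malformed cDNA string {text!r}")
    start = _parse_pos_token(m.group("p1"))
    end = _parse_pos_token(m.group("p2")) if m.group("p2") else None
    edit = m.group("edit")
    if not _EDIT_RE.match(edit):
        raise CdnaParseError(f"malformed edit suffix {edit!r} in {text!r}")
    return CdnaVariant(start, end, edit)


def parse_cdna_position(text: str) -> TranscriptPosition:
    """Parse a single cDNA position (optionally carrying an edit suffix).

    Returns the :class:`TranscriptPosition`; any edit suffix is validated
    and discarded (use :func:`parse_cdna_variant` to keep it, or to parse
    ranges).
    """
    var = parse_cdna_variant(text)
    if var.end is not None:
        raise CdnaParseError(
            f"{text!r} is a range; use parse_cdna_variant for start/end access"
        )
    return var.start


def format_cdna(pos: TranscriptPosition, edit: str = "") -> str:
    """Format a position back into ``c.``-notation (round-trips parsing)."""
    return f"c.{pos}{edit}"


# ---------------------------------------------------------------------------
# Coordinate mapping
# ---------------------------------------------------------------------------


def transcript_to_genomic(model: GeneModel, pos: TranscriptPosition) -> int:
    """Map a cDNA position to a genomic 0-based coordinate, strand-aware.

    Intronic offsets must anchor at the adjacent exon boundary (``+k`` at
    the last coding base of an exon with a downstream intron, ``-k`` at the
    first coding base of an exon with an upstream intron) and must not
    exceed the intron length.
    """
    t = model.cds_tx_start + pos.coding_pos - 1
    if not model.cds_tx_start <= t <= model.cds_tx_end:
        raise ValueError(f"c.{pos.coding_pos} outside CDS of {model.gene_symbol}")
    k = model._exon_of_tx(t)
    g = model.tx_to_genomic(t)
    off = pos.intron_offset
    if off == 0:
        return g
    if off > 0:
        if t != model._cum[k] or k >= model.n_exons - 1:
            raise ValueError(
                f"+{off} offset must anchor at the last exonic nt of an internal exon"
            )
        intron_len = model.introns[k][1] - model.introns[k][0]
        if off > intron_len:
            raise ValueError(f"offset +{off} exceeds intron length {intron_len}")
        return g + off if model.strand == "+" else g - off
    # off < 0
    first_t = (model._cum[k - 1] if k else 0) + 1
    if t != first_t or k == 0:
        raise ValueError(
            f"{off} offset must anchor at the first exonic nt of a non-first exon"
        )
    intron_len = model.introns[k - 1][1] - model.introns[k - 1][0]
    if -off > intron_len:
        raise ValueError(f"offset {off} exceeds intron length {intron_len}")
    return g + off if model.strand == "+" else g - off


def genomic_to_transcript(model: GeneModel, g: int) -> TranscriptPosition:
    """Map a genomic coordinate within the gene span to cDNA notation.

    Intronic positions anchor at the nearer exon boundary (ties go to the
    donor side, i.e. a positive offset), matching the HGVS convention.
    """
    lo, hi = model.span
    if not lo <= g < hi:
        raise ValueError(f"genomic position {g} outside {model.gene_symbol} span")
    try:
        t = model.genomic_to_tx(g)
    except ValueError:
        t = None
    if t is not None:
        c = t - model.cds_tx_start + 1
        if not 1 <= c <= model.cds_length:
            raise ValueError(f"genomic position {g} maps outside the CDS")
        return TranscriptPosition(c, 0, model._exon_of_tx(t))
    # intronic: find the hosting intron in transcription order
    for k, (s, e) in enumerate(model.introns):
        if s <= g < e:
            if model.strand == "+":
                d_donor = g - s + 1
                d_acc = e - g
            else:
                d_donor = e - g
                d_acc = g - s + 1
            if d_donor <= d_acc:
                anchor_t = model._cum[k]
                c = anchor_t - model.cds_tx_start + 1
                return TranscriptPosition(c, d_donor, k)
            anchor_t = model._cum[k] + 1
            c = anchor_t - model.cds_tx_start + 1
            return TranscriptPosition(c, -d_acc, k + 1)
    raise ValueError(f"genomic position {g} not locatable in {model.gene_symbol}")


def position_bin(pos: TranscriptPosition, model: GeneModel) -> PositionBin:
    """Assign a position to its splice-relevance bin.

    Exonic positions at the donor-adjacent last nucleotide of an exon get
    the dedicated ``EXONIC_LAST_NT`` bin; all other exonic positions
    (including the first nucleotide of an exon) are ``EXONIC_INTERNAL``.
    Intronic offsets are binned by magnitude: 1-2 canonical, 3-5, 6-10,
    11-20, and deep-intronic beyond 20.
    """
    off = abs(pos.intron_offset)
    if off == 0:
        t = model.cds_tx_start + pos.coding_pos - 1
        if not model.cds_tx_start <= t <= model.cds_tx_end:
            raise ValueError(f"c.{pos.coding_pos} outside CDS of {model.gene_symbol}")
        k = model._exon_of_tx(t)
        if t == model._cum[k] and k < model.n_exons - 1:
            return PositionBin.EXONIC_LAST_NT
        return PositionBin.EXONIC_INTERNAL
    if off <= 2:
        return PositionBin.CANONICAL_1_2
    if off <= 5:
        return PositionBin.INTRONIC_3_5
    if off <= 10:
        return PositionBin.INTRONIC_6_10
    if off <= 20:
        return PositionBin.INTRONIC_11_20
    return PositionBin.DEEP_INTRONIC_GT20


# Re-export the splice-site scorer here: it is part of the gene-model surface.
from .pwm import splice_site_strength  # noqa: E402,F401
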