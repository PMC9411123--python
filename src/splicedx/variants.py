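"""DNA-side variant filters, confirmation rules and reporting-range masking.

These are the panel-diagnostics bookkeeping rules applied before any RNA
evidence is weighed: a quality/allele-fraction filter, the Sanger
confirmation exemption for well-supported small variants, the analytical
reporting range (coding exons plus five intronic nucleotides, beyond which
a variant is only reportable with abnormal RNA), and the definition of a
splicing candidate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional, Tuple

from .gene_model import PositionBin, TranscriptPosition

MASKING_OFFSET = 5  #: reporting range extends this many nt into each intron


class VariantType(Enum):
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    SPLICING = "splicing"
    GROSS_DEL_DUP = "gross_del_dup"
    SYNONYMOUS = "synonymous"
    OTHER = "other"


class Classification(Enum):
    P = "P"
    LP = "LP"
    VUS = "VUS"
    LB = "LB"
    B = "B"
    UNCLASSIFIED = "unclassified"


class Reportability(Enum):
    REPORTABLE = "reportable"
    MASKED = "masked"


@dataclass(frozen=True)
class VariantRecord:
    """A DNA variant with quality metrics and prior classification."""

    gene_symbol: str
    hgvs_c: str
    chrom: str
    pos: int  # genomic, 0-based
    ref: str
    alt: str
    variant_type: VariantType = VariantType.OTHER
    classification: Classification = Classification.UNCLASSIFIED
    q_score: Optional[float] = None
    allele_fraction: Optional[float] = None
    depth: Optional[int] = None
    position: Optional[TranscriptPosition] = None
    position_bin: Optional[PositionBin] = None
    insilico_deleterious: bool = False
    sample_id: Optional[str] = None
    flags: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.allele_fraction is not None and not 0 <= self.allele_fraction <= 1:
            raise ValueError("allele_fraction must lie in [0, 1]")

    @property
    def variant_key(self) -> str:
        return f"{self.gene_symbol}:{self.hgvs_c}"

    @property
    def intron_offset(self) -> int:
        return self.position.intron_offset if self.position is not None else 0

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def indel_length(self) -> int:
        return abs(len(self.ref) - len(self.alt))


def dna_variant_filter(v: VariantRecord, mode: str = "conjunction"):
    """Quality filter: drop when Q score <= 30 AND allele fraction < 10%.

    The printed rule is conjunctive; ``mode='disjunction'`` drops a variant
    failing either condition, for pipelines that read the two clauses as
    independent filters. Variants missing either metric are kept with an
    ``"unfiltered"`` flag.

    Returns ``(keep: bool, reason: str)``.
    """
    if mode not in {"conjunction", "disjunction"}:
        raise ValueError(f"unknown filter mode {mode!r}")
    if v.q_score is None or v.allele_fraction is None:
        return True, "unfiltered"
    low_q = v.q_score <= 30
    low_af = v.allele_fraction < 0.10
    drop = (low_q and low_af) if mode == "conjunction" else (low_q or low_af)
    if drop:
        bits = [b for b, hit in (("Q<=30", low_q), ("AF<10%", low_af)) if hit]
        return False, " and ".join(bits)
    return True, ""


def sanger_confirmation_required(
    v: VariantRecord,
    low_coverage_region: bool = False,
    pseudogene_flag: bool = False,
):
    """Does an NGS call need orthogonal Sanger confirmation?

    SNVs and small indels (<= 3 nt) with allele fraction > 35% and >= 100x
    depth are exempt. Calls in regions below 20x, or flagged for pseudogene
    interference, are always confirmed.

    Returns ``(required: bool, reason: str)``.
    """
    if low_coverage_region:
        return True, "region below 20x coverage"
    if pseudogene_flag:
        return True, "pseudogene interference"
    small = v.is_snv or (
        v.variant_type is not VariantType.GROSS_DEL_DUP and v.indel_length <= 3
    )
    if not small:
        return True, "indel > 3 nt"
    if v.allele_fraction is None or v.depth is None:
        return True, "missing quality metrics"
    if v.allele_fraction <= 0.35:
        return True, "allele fraction <= 35%"
    if v.depth < 100:
        return True, "depth < 100x"
    return False, ""


def reporting_range_mask(
    v: VariantRecord,
    has_abnormal_rna: bool,
    masking_offset: int = MASKING_OFFSET,
) -> Reportability:
    """Apply the analytical reporting range.

    Variants within the coding exons or up to ``masking_offset`` intronic
    nucleotides are always reportable; deeper intronic variants are
    reportable only when an abnormal RNA transcript was detected for them.
    """
    if v.position is None:
        raise ValueError(f"{v.variant_key}: position_bin not assigned")
    if abs(v.intron_offset) <= masking_offset:
        return Reportability.REPORTABLE
    return Reportability.REPORTABLE if has_abnormal_rna else Reportability.MASKED


def is_splicing_candidate(
    v: VariantRecord,
    insilico_deleterious: Optional[bool] = None,
    has_abnormal_rna: bool = False,
) -> bool:
    """Splicing-candidate definition.

    A variant is a splicing candidate when in-silico modelling predicts a
    deleterious splice impact, or it is intronic within five nucleotides of
    the exon, or an abnormal RNA transcript was detected.
    """
    if v.position is None:
        raise ValueError(f"{v.variant_key}: position not assigned")
    if insilico_deleterious is None:
        insilico_deleterious = v.insilico_deleterious
    near_intronic = v.position.is_intronic and abs(v.intron_offset) <= 5
    return bool(insilico_deleterious or near_intronic or has_abnormal_rna)
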