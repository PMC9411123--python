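"""Shared toy gene models and the independent taxonomy oracle."""

from __future__ import annotations

from typing import List, Optional, Tuple

import pytest

from splicedx import GeneModel, JunctionTable


@pytest.fixture
def toy_plus() -> GeneModel:
    """3-exon plus-strand gene; exon1=[100,200), exon2=[300,420), exon3=[500,650)."""
    return GeneModel(
        gene_symbol="TOY1",
        chrom="chrT",
        strand="+",
        exons=((100, 200), (300, 420), (500, 650)),
        cds_start=100,
        cds_end=650,
    )


@pytest.fixture
def toy_minus() -> GeneModel:
    """Same genomic exons as toy_plus, minus strand (transcription order reversed)."""
    return GeneModel(
        gene_symbol="TOY1M",
        chrom="chrT",
        strand="-",
        exons=((500, 650), (300, 420), (100, 200)),
        cds_start=100,
        cds_end=650,
    )


def make_toy(n_exons: int, exon_len: int = 8, intron_len: int = 12, offset: int = 10) -> GeneModel:
    """Tiny fully coding plus-strand gene for exhaustive enumeration."""
    exons = []
    pos = offset
    for _ in range(n_exons):
        exons.append((pos, pos + exon_len))
        pos += exon_len + intron_len
    return GeneModel(
        gene_symbol=f"TINY{n_exons}",
        chrom="chrT",
        strand="+",
        exons=tuple(exons),
        cds_start=exons[0][0],
        cds_end=exons[-1][1],
    )


# ---------------------------------------------------------------------------
# Independent taxonomy oracle: base-level transcript reconstruction
# ---------------------------------------------------------------------------


def oracle_classify(removal: Tuple[int, int], model: GeneModel) -> Optional[str]:
    """Classify a single spliced-out interval by reconstructing the product.

    Builds the set of bases present in the aberrant mature transcript
    (exonic bases surviving the removal, plus the leftover bases of any
    intron the removal cut into), then reads the taxonomy off the per-exon
    presence pattern and the number of leftover intronic segments. Returns
    one of the type labels, or None when the product equals the canonical
    transcript. Entirely base-set arithmetic - no boundary-case reasoning.
    """
    a, b = removal
    R = set(range(a, b))
    gx = sorted(model.exons)
    gintrons = [(e1, s2) for (_, e1), (s2, _) in zip(gx, gx[1:])]

    exon_status = []
    for s, e in gx:
        bases = set(range(s, e))
        left = bases - R
        if left == bases:
            exon_status.append("full")
        elif left:
            exon_status.append("partial")
        else:
            exon_status.append("absent")

    intron_pieces = 0
    retained_bases = set()
    for s, e in gintrons:
        bases = set(range(s, e))
        cut = bases & R
        if not cut:
            continue  # spliced out canonically
        left = bases - R
        if not left:
            continue  # removed entirely by the junction
        retained_bases |= left
        # count contiguous leftover segments of this intron
        run = 0
        prev = None
        for p in sorted(left):
            if prev is None or p != prev + 1:
                run += 1
            prev = p
        intron_pieces += run

    any_absent = "absent" in exon_status
    any_partial = "partial" in exon_status
    if retained_bases:
        if any_absent or any_partial:
            return "UNCLASSIFIED"
        return "IP" if intron_pieces == 1 else "UNCLASSIFIED"
    if any_absent and any_partial:
        return "ES"
    if any_absent:
        return "ESF"
    if any_partial:
        return "ESP"
    return None  # product identical to the canonical transcript
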