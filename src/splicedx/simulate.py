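"""Synthetic panels, control pools, carriers and deep-intronic fixtures.

The generator emulates the statistical structure the analysis assumes so
that every stage is testable without external data:

* gene models with canonical GT/AG junctions written from the bundled PWM
  consensus, so native sites score at the PWM maximum;
* a healthy-donor control pool (default 345 samples) whose low-baseline
  alternative splicing is drawn per sample and per event from a
  Beta(0.5, 99.5) distribution (mean PSI 0.005);
* heterozygous carrier samples whose variant-induced event is expressed at
  a specified true PSI (default 0.35, optionally attenuated by an NMD
  factor) with binomial read sampling at a fixed junction depth;
* four deep-intronic fixture cases - an APC-style strengthened cryptic
  donor (+6 C>T, cryptic exon), an ATM-style created acceptor (-1 A>G,
  cryptic exon), a BRCA2-style created donor (+2 A>T, cryptic exon) and a
  CDH1-style branch-point deletion producing two partial intron-retention
  events - with the printed cDNA offsets preserved exactly.

All outputs are bitwise deterministic for a given seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import pwm
from .association import GeneSequence
from .events import JunctionKey, JunctionTable, canonical_junctions
from .gene_model import GeneModel, TranscriptPosition, format_cdna, position_bin
from .variants import Classification, VariantRecord, VariantType

DEFAULT_N_CONTROLS = 345
DEFAULT_DEPTH = 1000
#: Beta(a, b) baseline for control-pool alternative splicing; mean 0.005.
BASELINE_NOISE_BETA = (0.5, 99.5)
DEFAULT_CARRIER_PSI = 0.35

_ALT = {"A": "C", "C": "T", "G": "A", "T": "G"}


@dataclass
class SimulationConfig:
    """Study conditions for a simulated cohort."""

    seed: int = 0
    n_controls: int = DEFAULT_N_CONTROLS
    junction_depth: int = DEFAULT_DEPTH
    baseline_noise_beta: Tuple[float, float] = BASELINE_NOISE_BETA
    carrier_true_psi: float = DEFAULT_CARRIER_PSI
    nmd_attenuation: float = 1.0
    n_deleterious: int = 20
    carriers_per_variant: int = 2
    n_benign: int = 10
    n_exons: int = 8
    exon_len_range: Tuple[int, int] = (90, 180)
    intron_len_range: Tuple[int, int] = (300, 900)
    gene_symbol: str = "BRCA1"
    chrom: str = "chr17"

    def __post_init__(self) -> None:
        if self.junction_depth <= 0:
            raise ValueError("depth must be positive")
        for p in (self.carrier_true_psi, self.nmd_attenuation):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class EventBlueprint:
    """A ground-truth aberrant splicing pattern to inject into samples."""

    kind: str  # ESF / ESP / IP / IC
    junctions: Tuple[JunctionKey, ...]
    gene_symbol: str

    @property
    def event_key(self) -> str:
        coords = ",".join(f"{c}:{s}-{e}" for c, s, e, _ in sorted(self.junctions))
        return f"{self.gene_symbol}|{self.kind}|{coords}"


# ---------------------------------------------------------------------------
# Gene model construction
# ---------------------------------------------------------------------------


def make_gene_model(
    n_exons: int,
    exon_len_range: Tuple[int, int] = (90, 180),
    intron_len_range: Tuple[int, int] = (300, 900),
    seed: int = 0,
    gene_symbol: str = "GENE1",
    chrom: str = "chr1",
    offset: int = 1000,
    isoform_id: str = "NM_900001.1",
) -> Tuple[GeneModel, GeneSequence]:
    """Generate a fully coding plus-strand gene with consensus junctions.

    Exon and intron lengths are drawn uniformly from the given ranges; the
    emitted sequence carries the PWM consensus at every canonical donor and
    acceptor, so native sites score at the PWM maximum. Deterministic for a
    given seed.
    """
    if n_exons < 2:
        raise ValueError("need at least 2 exons")
    if exon_len_range[0] < 30 or intron_len_range[0] < 60:
        raise ValueError("exons must be >= 30 nt and introns >= 60 nt for site windows")
    rng = np.random.default_rng(seed)
    exon_lens = rng.integers(exon_len_range[0], exon_len_range[1] + 1, n_exons)
    intron_lens = rng.integers(intron_len_range[0], intron_len_range[1] + 1, n_exons - 1)
    return _assemble_gene(
        [int(x) for x in exon_lens],
        [int(x) for x in intron_lens],
        rng,
        gene_symbol,
        chrom,
        offset,
        isoform_id,
    )


def _assemble_gene(
    exon_lens: Sequence[int],
    intron_lens: Sequence[int],
    rng: np.random.Generator,
    gene_symbol: str,
    chrom: str,
    offset: int,
    isoform_id: str,
) -> Tuple[GeneModel, GeneSequence]:
    exons = []
    pos = offset
    for i, el in enumerate(exon_lens):
        exons.append((pos, pos + el))
        pos += el
        if i < len(intron_lens):
            pos += intron_lens[i]
    end = pos + 50
    seq = list("".join(rng.choice(list("ACGT"), size=end)))
    model = GeneModel(
        gene_symbol=gene_symbol,
        chrom=chrom,
        strand="+",
        exons=tuple(exons),
        cds_start=exons[0][0],
        cds_end=exons[-1][1],
        isoform_id=isoform_id,
    )
    donor_cons = pwm.consensus("donor")
    acceptor_cons = pwm.consensus("acceptor")
    for s, e in model.introns:
        _write(seq, s - pwm.DONOR_EXONIC, donor_cons)
        _write(seq, e - pwm.ACCEPTOR_INTRONIC, acceptor_cons)
    return model, GeneSequence(chrom, "".join(seq), 0)


def _write(seq: List[str], start: int, text: str) -> None:
    seq[start : start + len(text)] = list(text)


# ---------------------------------------------------------------------------
# Event blueprints
# ---------------------------------------------------------------------------


def _check_plus(model: GeneModel) -> None:
    if model.strand != "+":
        raise ValueError("blueprints are generated on plus-strand panel genes")


def blueprint_esf(model: GeneModel, first_exon: int, last_exon: Optional[int] = None) -> EventBlueprint:
    """Full skip of exons ``first_exon..last_exon`` (1-based, internal)."""
    _check_plus(model)
    last_exon = first_exon if last_exon is None else last_exon
    if not 2 <= first_exon <= last_exon <= model.n_exons - 1:
        raise ValueError("skipped exons must be internal")
    s = model.exons[first_exon - 2][1]
    e = model.exons[last_exon][0]
    return EventBlueprint("ESF", ((model.chrom, s + 1, e, "+"),), model.gene_symbol)


def blueprint_esp(model: GeneModel, exon: int, trim: int, side: str = "acceptor") -> EventBlueprint:
    """Partial skip: alternative splice site ``trim`` nt inside an exon."""
    _check_plus(model)
    es, ee = model.exons[exon - 1]
    if not 0 < trim < ee - es:
        raise ValueError("trim must fall inside the exon")
    if side == "acceptor":  # 5' part of the exon excluded
        if exon == 1:
            raise ValueError("no upstream intron")
        s = model.exons[exon - 2][1]
        return EventBlueprint("ESP", ((model.chrom, s + 1, es + trim, "+"),), model.gene_symbol)
    if exon == model.n_exons:
        raise ValueError("no downstream intron")
    e = model.exons[exon][0]
    return EventBlueprint("ESP", ((model.chrom, ee - trim + 1, e, "+"),), model.gene_symbol)


def blueprint_ip(model: GeneModel, intron: int, retained: int, side: str = "acceptor") -> EventBlueprint:
    """Partial intron inclusion: ``retained`` intronic nt kept flanking an exon."""
    _check_plus(model)
    s, e = model.introns[intron - 1]
    if not 0 < retained < e - s:
        raise ValueError("retained length must fall inside the intron")
    if side == "acceptor":  # retained tail abuts the downstream exon
        return EventBlueprint("IP", ((model.chrom, s + 1, e - retained, "+"),), model.gene_symbol)
    return EventBlueprint("IP", ((model.chrom, s + retained + 1, e, "+"),), model.gene_symbol)


def blueprint_ic(model: GeneModel, intron: int, exon_offset: int, exon_len: int) -> EventBlueprint:
    """Cryptic exon of ``exon_len`` nt starting ``exon_offset`` nt into an intron."""
    _check_plus(model)
    s, e = model.introns[intron - 1]
    a = s + exon_offset
    d = a + exon_len
    if not (s < a and d < e):
        raise ValueError("cryptic exon must lie strictly inside the intron")
    return EventBlueprint(
        "IC",
        ((model.chrom, s + 1, a, "+"), (model.chrom, d + 1, e, "+")),
        model.gene_symbol,
    )


# ---------------------------------------------------------------------------
# Sample simulation
# ---------------------------------------------------------------------------


def simulate_sample(
    model: GeneModel,
    true_events: Sequence[Tuple[EventBlueprint, float]],
    depth: int,
    seed_or_rng,
    sample_id: str = "S1",
) -> JunctionTable:
    """Binomial junction sampling of a sample with known aberrant events.

    Each canonical junction starts at ``depth`` reads. For every event,
    supporting reads are drawn Binomial(depth, PSI) and placed on each of
    the event's novel junctions; the canonical junctions sharing the
    event's region lose the same number of reads (floored at zero). Events
    with zero sampled reads emit no junction row.
    """
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    canon = canonical_junctions(model)
    counts: Dict[JunctionKey, int] = {k: depth for k in canon}
    gintrons = [(min(s, e), max(s, e)) for s, e in model.introns]
    for bp, psi in true_events:
        if not 0 <= psi <= 1:
            raise ValueError("PSI must lie in [0, 1]")
        k_reads = int(rng.binomial(depth, psi))
        if k_reads == 0:
            continue
        touched = set()
        for chrom, s1, e1, strand in bp.junctions:
            key = (chrom, s1, e1, strand)
            counts[key] = counts.get(key, 0) + k_reads
            a, b = s1 - 1, e1
            for idx, (gs, ge) in enumerate(gintrons):
                if max(a, gs) < min(b, ge):
                    touched.add(idx)
        for idx in touched:
            gs, ge = gintrons[idx]
            ckey = (model.chrom, gs + 1, ge, model.strand)
            counts[ckey] = max(0, counts[ckey] - k_reads)
    counts = {k: v for k, v in counts.items() if v > 0}
    return JunctionTable(sample_id=sample_id, counts=counts)


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------


@dataclass
class Cohort:
    """A fully simulated cohort with its ground truth."""

    config: SimulationConfig
    model: GeneModel
    ref: GeneSequence
    controls: List[JunctionTable]
    carriers: Dict[str, JunctionTable]
    variants: List[VariantRecord]
    variant_carriers: Dict[str, List[str]]
    blueprints: Dict[str, Optional[EventBlueprint]]
    truth: pd.DataFrame


# Intronic offsets cycled across deleterious variants: canonical dinucleotide,
# near-intronic +3/+5, and deeper positions, exercising every position bin.
_DELETERIOUS_OFFSETS = [1, 2, -1, -2, 3, 5, -4, 8, -15, 30, -60, 120]


def _unique_offset(candidate: int, exon: int, used: set, max_abs: int) -> int:
    """First offset at or after ``candidate`` unused for this exon.

    Bumps the magnitude by 29 per collision; fails loudly rather than
    placing a variant beyond the shortest possible intron.
    """
    offset = candidate
    while (exon, offset) in used:
        offset = offset + 29 if offset > 0 else offset - 29
    if abs(offset) >= max_abs or offset == 0:
        raise ValueError(
            f"cannot place a unique variant at offset {offset}: increase the "
            f"intron length range or reduce the variant count"
        )
    used.add((exon, offset))
    return offset


def _intronic_variant(
    model: GeneModel,
    ref: GeneSequence,
    exon: int,
    offset: int,
    classification: Classification = Classification.VUS,
    rng: Optional[np.random.Generator] = None,
) -> VariantRecord:
    """A VUS at a signed offset into an intron flanking ``exon`` (1-based)."""
    cum = model._cum
    if offset > 0:  # anchored at the last coding base of the exon
        coding = cum[exon - 1]
        tp = TranscriptPosition(coding, offset)
    else:  # anchored at the first coding base of the exon
        coding = (cum[exon - 2] if exon >= 2 else 0) + 1
        tp = TranscriptPosition(coding, offset)
    from .gene_model import transcript_to_genomic

    g = transcript_to_genomic(model, tp)
    ref_base = ref.fetch(g, g + 1).upper()
    alt_base = _ALT[ref_base]
    q = 45.0 if rng is None else float(np.round(35 + 25 * rng.random(), 1))
    af = 0.48 if rng is None else float(np.round(0.35 + 0.2 * rng.random(), 3))
    dp = 200 if rng is None else int(rng.integers(120, 400))
    return VariantRecord(
        gene_symbol=model.gene_symbol,
        hgvs_c=format_cdna(tp, f"{ref_base}>{alt_base}"),
        chrom=model.chrom,
        pos=g,
        ref=ref_base,
        alt=alt_base,
        variant_type=VariantType.SPLICING,
        classification=classification,
        q_score=q,
        allele_fraction=af,
        depth=dp,
        position=tp,
        position_bin=position_bin(tp, model),
    )


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Simulate controls, carriers, variants, and the truth table.

    Deleterious variants sit at splice-relevant intronic offsets of an
    internal exon and drive a full skip of that exon at
    ``carrier_true_psi x nmd_attenuation`` in each of their carriers;
    benign variants sit deeper in introns with no event. Controls (and
    carriers, for regions other than their own event) express the
    low-baseline alternative-splicing noise of the pool.
    """
    rng = np.random.default_rng(config.seed)
    model, ref = make_gene_model(
        config.n_exons,
        config.exon_len_range,
        config.intron_len_range,
        seed=int(rng.integers(2**31 - 1)),
        gene_symbol=config.gene_symbol,
        chrom=config.chrom,
    )
    internal = list(range(2, config.n_exons))
    noise_bps = [blueprint_esf(model, k) for k in internal]
    a, b = config.baseline_noise_beta

    def noise_events(rng_):
        return [(bp, float(rng_.beta(a, b))) for bp in noise_bps]

    controls = [
        simulate_sample(
            model, noise_events(rng), config.junction_depth, rng, f"HC{i:04d}"
        )
        for i in range(config.n_controls)
    ]

    variants: List[VariantRecord] = []
    variant_carriers: Dict[str, List[str]] = {}
    blueprints: Dict[str, Optional[EventBlueprint]] = {}
    carriers: Dict[str, JunctionTable] = {}
    truth_rows = []
    pt = 0

    observed_psi = config.carrier_true_psi * config.nmd_attenuation
    used_offsets: set = set()
    max_abs = config.intron_len_range[0]
    for j in range(config.n_deleterious):
        exon = internal[j % len(internal)]
        # a +7 shift per full offset cycle spreads repeat visits to an exon
        candidate = _DELETERIOUS_OFFSETS[j % len(_DELETERIOUS_OFFSETS)] + 7 * (
            j // len(_DELETERIOUS_OFFSETS)
        )
        offset = _unique_offset(candidate, exon, used_offsets, max_abs)
        v = _intronic_variant(model, ref, exon, offset, rng=rng)
        bp = blueprint_esf(model, exon)
        samples = []
        for _ in range(config.carriers_per_variant):
            sid = f"PT{pt:04d}"
            pt += 1
            other_noise = [
                (nb, float(rng.beta(a, b))) for nb in noise_bps if nb.junctions != bp.junctions
            ]
            carriers[sid] = simulate_sample(
                model,
                [(bp, observed_psi)] + other_noise,
                config.junction_depth,
                rng,
                sid,
            )
            samples.append(sid)
        variants.append(v)
        variant_carriers[v.variant_key] = samples
        blueprints[v.variant_key] = bp
        truth_rows.append(
            {
                "variant_key": v.variant_key,
                "gene_symbol": v.gene_symbol,
                "hgvs_c": v.hgvs_c,
                "deleterious": True,
                "true_psi": observed_psi,
                "event_key": bp.event_key,
                "expected_impact": "upgrade",
                "carriers": ";".join(samples),
            }
        )

    for j in range(config.n_benign):
        exon = internal[(j + 1) % len(internal)]
        # alternating signs over growing magnitudes, all beyond +/-5
        candidate = (6 + j // 2) * (1 if j % 2 == 0 else -1)
        offset = _unique_offset(candidate, exon, used_offsets, max_abs)
        v = _intronic_variant(model, ref, exon, offset, rng=rng)
        sid = f"PT{pt:04d}"
        pt += 1
        carriers[sid] = simulate_sample(
            model, noise_events(rng), config.junction_depth, rng, sid
        )
        variants.append(v)
        variant_carriers[v.variant_key] = [sid]
        blueprints[v.variant_key] = None
        truth_rows.append(
            {
                "variant_key": v.variant_key,
                "gene_symbol": v.gene_symbol,
                "hgvs_c": v.hgvs_c,
                "deleterious": False,
                "true_psi": 0.0,
                "event_key": "",
                "expected_impact": "downgrade",
                "carriers": sid,
            }
        )

    truth = pd.DataFrame(truth_rows)
    return Cohort(
        config=config,
        model=model,
        ref=ref,
        controls=controls,
        carriers=carriers,
        variants=variants,
        variant_carriers=variant_carriers,
        blueprints=blueprints,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Deep-intronic fixture cases
# ---------------------------------------------------------------------------


@dataclass
class FixtureCase:
    """A packaged deep-intronic scenario with engineered mechanism."""

    name: str
    model: GeneModel
    ref: GeneSequence
    variant: VariantRecord
    carrier: JunctionTable
    controls: List[JunctionTable]
    expected_event_types: Tuple[str, ...]
    expected_mechanism: str
    description: str = ""


def _fixture_base(
    gene: str,
    chrom: str,
    exon_lens: Sequence[int],
    intron_lens: Sequence[int],
    seed: int,
    isoform_id: str,
) -> Tuple[GeneModel, List[str]]:
    rng = np.random.default_rng(seed)
    model, ref = _assemble_gene(
        exon_lens, intron_lens, rng, gene, chrom, offset=1000, isoform_id=isoform_id
    )
    return model, list(ref.seq)


def _canonical_table(model: GeneModel, depth: int, sample_id: str) -> JunctionTable:
    counts = {k: depth for k in canonical_junctions(model)}
    return JunctionTable(sample_id=sample_id, counts=counts)


def _carrier_table(
    model: GeneModel,
    depth: int,
    novel: Dict[JunctionKey, int],
    host_intron: int,
    lost: int,
    sample_id: str = "PROBAND",
) -> JunctionTable:
    counts = {k: depth for k in canonical_junctions(model)}
    s, e = model.introns[host_intron - 1]
    host = (model.chrom, s + 1, e, model.strand)
    counts[host] = max(0, depth - lost)
    counts.update(novel)
    return JunctionTable(sample_id=sample_id, counts=counts)


def fixture_cases(depth: int = 1000, n_controls: int = 30) -> Dict[str, FixtureCase]:
    """The four packaged deep-intronic scenarios.

    Each case bundles a scaled-down toy gene (introns of a few kb) whose
    sequence is engineered so mechanism inference reproduces the intended
    mechanism, a carrier junction table expressing the intended event
    type(s), and a canonical-only control pool. The printed cDNA offsets
    are preserved exactly, so position binning and reporting-range masking
    are exercised at the genuine deep-intronic magnitudes.
    """
    cases: Dict[str, FixtureCase] = {}
    donor_cons = pwm.consensus("donor")
    acceptor_cons = pwm.consensus("acceptor")

    # --- APC: C>T at +6 of a cryptic donor strengthens it -> cryptic exon
    model, seq = _fixture_base("APC", "chr5", [211, 211, 150, 150], [500, 4200, 400], 101, "NM_000038.6")
    i2s, i2e = model.introns[1]
    acc = i2s + 86  # cryptic acceptor boundary (first exonized base)
    don = i2s + 237  # cryptic donor boundary (first intronic base after the exon)
    _write(seq, acc - pwm.ACCEPTOR_INTRONIC, acceptor_cons)
    _write(seq, don - pwm.DONOR_EXONIC, donor_cons)
    g = don + 5  # +6 position of the cryptic donor
    seq[g] = "C"  # weak reference allele
    ref = GeneSequence(model.chrom, "".join(seq), 0)
    tp = TranscriptPosition(423, -3958)
    variant = VariantRecord(
        gene_symbol="APC", hgvs_c="c.423-3958C>T", chrom=model.chrom, pos=g,
        ref="C", alt="T", variant_type=VariantType.SPLICING,
        classification=Classification.VUS, q_score=52.0, allele_fraction=0.47,
        depth=230, position=tp, position_bin=position_bin(tp, model),
    )
    novel = {
        (model.chrom, i2s + 1, acc, "+"): 400,
        (model.chrom, don + 1, i2e, "+"): 400,
    }
    cases["APC"] = FixtureCase(
        "APC", model, ref, variant,
        _carrier_table(model, depth, novel, 2, 400),
        [_canonical_table(model, depth, f"HC{i:04d}") for i in range(n_controls)],
        ("IC",), "novel_site_creation",
        "deep-intronic C>T strengthening the +6 position of a cryptic donor",
    )

    # --- ATM: A>G creates the -1 (invariant G) of a new acceptor -> cryptic exon
    model, seq = _fixture_base("ATM", "chr11", [248, 248, 150, 150], [500, 3000, 400], 102, "NM_000051.4")
    i2s, i2e = model.introns[1]
    acc = i2s + 340
    don = acc + 131
    _write(seq, acc - pwm.ACCEPTOR_INTRONIC, acceptor_cons)
    _write(seq, don - pwm.DONOR_EXONIC, donor_cons)
    g = acc - 1  # -1 position of the created acceptor
    seq[g] = "A"
    ref = GeneSequence(model.chrom, "".join(seq), 0)
    tp = TranscriptPosition(497, -2661)
    variant = VariantRecord(
        gene_symbol="ATM", hgvs_c="c.497-2661A>G", chrom=model.chrom, pos=g,
        ref="A", alt="G", variant_type=VariantType.SPLICING,
        classification=Classification.VUS, q_score=55.0, allele_fraction=0.51,
        depth=260, position=tp, position_bin=position_bin(tp, model),
    )
    novel = {
        (model.chrom, i2s + 1, acc, "+"): 350,
        (model.chrom, don + 1, i2e, "+"): 350,
    }
    cases["ATM"] = FixtureCase(
        "ATM", model, ref, variant,
        _carrier_table(model, depth, novel, 2, 350),
        [_canonical_table(model, depth, f"HC{i:04d}") for i in range(n_controls)],
        ("IC",), "novel_site_creation",
        "deep-intronic A>G creating the invariant G of a new acceptor",
    )

    # --- BRCA2: A>T creates the +2 (invariant T) of a new donor -> cryptic exon
    model, seq = _fixture_base(
        "BRCA2", "chr13", [2777, 2777, 2777, 160], [400, 450, 3600], 103, "NM_000059.4"
    )
    i3s, i3e = model.introns[2]
    don = i3s + 215  # first intronic base after the cryptic exon
    acc = don - 155
    _write(seq, acc - pwm.ACCEPTOR_INTRONIC, acceptor_cons)
    _write(seq, don - pwm.DONOR_EXONIC, donor_cons)
    g = don + 1  # +2 position of the created donor
    seq[g] = "A"
    ref = GeneSequence(model.chrom, "".join(seq), 0)
    tp = TranscriptPosition(8332, -3384)
    variant = VariantRecord(
        gene_symbol="BRCA2", hgvs_c="c.8332-3384A>T", chrom=model.chrom, pos=g,
        ref="A", alt="T", variant_type=VariantType.SPLICING,
        classification=Classification.VUS, q_score=49.0, allele_fraction=0.46,
        depth=210, position=tp, position_bin=position_bin(tp, model),
    )
    novel = {
        (model.chrom, i3s + 1, acc, "+"): 300,
        (model.chrom, don + 1, i3e, "+"): 300,
    }
    cases["BRCA2"] = FixtureCase(
        "BRCA2", model, ref, variant,
        _carrier_table(model, depth, novel, 3, 300),
        [_canonical_table(model, depth, f"HC{i:04d}") for i in range(n_controls)],
        ("IC",), "novel_site_creation",
        "deep-intronic A>T creating the invariant T of a new donor",
    )

    # --- CDH1: intronic deletion removes the branch point -> two IP events
    model, seq = _fixture_base("CDH1", "chr16", [783, 782, 160, 150], [500, 3520, 400], 104, "NM_004360.5")
    i2s, i2e = model.introns[1]
    for idx in (300, 450):  # preexisting cryptic acceptors in the kept region
        _write(seq, i2s + idx - pwm.ACCEPTOR_INTRONIC, acceptor_cons)
    ref = GeneSequence(model.chrom, "".join(seq), 0)
    tp = TranscriptPosition(1565, 672)
    del_start = i2s + 671
    variant = VariantRecord(
        gene_symbol="CDH1", hgvs_c="c.1565+672_1566-23del2827", chrom=model.chrom,
        pos=del_start, ref="N", alt="N", variant_type=VariantType.SPLICING,
        classification=Classification.VUS, q_score=50.0, allele_fraction=0.45,
        depth=240, position=tp, position_bin=position_bin(tp, model),
    )
    novel = {
        (model.chrom, i2s + 1, i2s + 300, "+"): 250,
        (model.chrom, i2s + 1, i2s + 450, "+"): 200,
    }
    cases["CDH1"] = FixtureCase(
        "CDH1", model, ref, variant,
        _carrier_table(model, depth, novel, 2, 450),
        [_canonical_table(model, depth, f"HC{i:04d}") for i in range(n_controls)],
        ("IP", "IP"), "branch_point_deletion",
        "intronic deletion removing the native acceptor's branch point; two "
        "preexisting cryptic acceptors drive partial intron retention",
    )

    return cases


def simulate_variant_types(
    n: int,
    weights: Optional[Dict[str, float]] = None,
    seed: int = 0,
) -> List[str]:
    """Multinomial draw of variant-type labels (landscape emulation)."""
    if weights is None:
        weights = {
            "missense": 0.692,
            "splicing": 0.062,
            "gross_del_dup": 0.028,
            "other": 0.218,
        }
    rng = np.random.default_rng(seed)
    labels = list(weights)
    p = np.array([weights[k] for k in labels], dtype=float)
    p = p / p.sum()
    draws = rng.multinomial(n, p)
    out: List[str] = []
    for lab, k in zip(labels, draws):
        out.extend([lab] * int(k))
    return out
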