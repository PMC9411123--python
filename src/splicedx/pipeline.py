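"""End-to-end orchestration: QC -> detect -> PSI/controls -> associate ->
reclassify -> summarize.

The pipeline consumes the on-disk formats (BED12/GTF gene models, FASTA,
junction-table manifests, VCF, QC TSV) or the equivalent in-memory objects
produced by :mod:`splicedx.simulate`, and emits a deterministic report
bundle: per-variant evidence JSON, a PSI TSV, a masked-variant audit TSV
and a cohort summary JSON. All thresholds are echoed into report headers.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from . import io as dx_io
from .association import (
    AssociationEvidence,
    ClassificationOutcome,
    GeneSequence,
    Mechanism,
    Overall,
    associate,
    mechanism_inference,
    reclassify,
)
from .config import PipelineConfig
from .events import EventType, JunctionTable, SpliceEvent, canonical_junctions, detect_events
from .gene_model import GeneModel
from .psi import (
    ControlProfile,
    PsiObservation,
    Specificity,
    compute_psi,
    control_profile,
    needs_rtpcr_confirmation,
    rna_sample_qc,
    specificity_test,
)
from .summary import CohortSummary, build_cohort_summary
from .variants import Reportability, VariantRecord, dna_variant_filter, is_splicing_candidate, reporting_range_mask

log = logging.getLogger(__name__)


@dataclass
class ReportBundle:
    """Everything one pipeline run produced."""

    config: PipelineConfig
    qc: Dict[str, object]
    events_by_sample: Dict[str, List[SpliceEvent]]
    control_profiles: Dict[str, ControlProfile]
    psi_rows: List[dict]
    evidence: Dict[str, AssociationEvidence]
    outcomes: Dict[str, ClassificationOutcome]
    reportability: Dict[str, Reportability]
    masked_rows: List[dict]
    summary: CohortSummary
    dropped_variants: Dict[str, str]
    failed_qc_samples: List[str]


def _load_models(path: str) -> Dict[str, GeneModel]:
    if str(path).endswith((".gtf", ".gff")):
        models = dx_io.read_gtf(path)
    else:
        models = dx_io.read_bed12(path)
    return {m.gene_symbol: m for m in models}


def run_pipeline(
    config: PipelineConfig,
    *,
    models: Optional[Mapping[str, GeneModel]] = None,
    refs: Optional[Mapping[str, GeneSequence]] = None,
    controls: Optional[Sequence[JunctionTable]] = None,
    carriers: Optional[Mapping[str, JunctionTable]] = None,
    variants: Optional[Sequence[VariantRecord]] = None,
    variant_carriers: Optional[Mapping[str, Sequence[str]]] = None,
    qc_metrics: Optional[Mapping[str, Tuple[float, float, float, float]]] = None,
    write: bool = True,
) -> ReportBundle:
    """Run the full analysis and (optionally) write the report bundle.

    Inputs may be given in-memory; anything omitted is loaded from the
    paths in ``config``. Deterministic for fixed inputs and config.
    """
    # ---- load inputs ----
    if models is None:
        if not config.gene_models:
            raise FileNotFoundError("gene_models path required")
        models = _load_models(config.gene_models)
    if refs is None:
        refs = (
            dx_io.read_gene_sequences(config.reference_fasta)
            if config.reference_fasta
            else {}
        )
    if controls is None:
        if not config.control_manifest:
            raise FileNotFoundError("control_manifest path required")
        controls = dx_io.load_manifest_tables(config.control_manifest)
    if not controls:
        raise ValueError("control pool is empty")
    if carriers is None:
        if not config.sample_manifest:
            raise FileNotFoundError("sample_manifest path required")
        carriers = {
            t.sample_id: t for t in dx_io.load_manifest_tables(config.sample_manifest)
        }
    if variants is None or variant_carriers is None:
        if not config.vcf:
            raise FileNotFoundError("vcf path required")
        variants, variant_carriers = dx_io.read_vcf(config.vcf, models)
    if qc_metrics is None and config.qc_table:
        qc_metrics = dx_io.read_qc_table(config.qc_table)

    # ---- RNA sample QC ----
    qc_results: Dict[str, object] = {}
    failed: List[str] = []
    if qc_metrics:
        for sid, metrics in qc_metrics.items():
            res = rna_sample_qc(*metrics)
            qc_results[sid] = res
            if not res.passed and sid in carriers:
                failed.append(sid)
    carriers = {s: t for s, t in carriers.items() if s not in failed}

    # ---- event detection per carrier ----
    chrom_to_models: Dict[str, List[GeneModel]] = {}
    for m in models.values():
        chrom_to_models.setdefault(m.chrom, []).append(m)
    events_by_sample: Dict[str, List[SpliceEvent]] = {}
    model_of_event: Dict[str, GeneModel] = {}
    for sid, table in carriers.items():
        evs: List[SpliceEvent] = []
        for m in models.values():
            for ev in detect_events(table, m, config.min_reads):
                evs.append(ev)
                model_of_event[ev.event_key] = m
        events_by_sample[sid] = evs

    # ---- control profiles per unique event ----
    event_objects: Dict[str, SpliceEvent] = {}
    for evs in events_by_sample.values():
        for ev in evs:
            event_objects.setdefault(ev.event_key, ev)
    control_profiles: Dict[str, ControlProfile] = {
        key: control_profile(ev, controls, model_of_event[key])
        for key, ev in event_objects.items()
        if ev.event_type is not EventType.UNCLASSIFIED
    }

    # ---- PSI report rows ----
    psi_rows: List[dict] = []
    obs_cache: Dict[Tuple[str, str], PsiObservation] = {}
    for sid, evs in events_by_sample.items():
        for ev in evs:
            if ev.event_type is EventType.UNCLASSIFIED:
                continue
            m = model_of_event[ev.event_key]
            obs = compute_psi(ev, carriers[sid], m)
            obs_cache[(sid, ev.event_key)] = obs
            prof = control_profiles[ev.event_key]
            spec = specificity_test(
                obs, prof, config.min_psi, config.fold, config.min_denominator
            )
            psi_rows.append(
                {
                    "event_key": ev.event_key,
                    "sample_id": sid,
                    "supporting_reads": obs.supporting_reads,
                    "region_total_reads": obs.region_total_reads,
                    "psi": round(obs.psi, 4) if obs.defined else "NA",
                    "control_median": round(prof.median_psi, 4),
                    "control_p95": round(prof.p95_psi, 4),
                    "specificity": spec.value,
                    "needs_rtpcr": needs_rtpcr_confirmation(obs, config.rtpcr_cutoff)
                    if obs.defined
                    else True,
                }
            )

    # ---- per-variant evidence and reclassification ----
    evidence: Dict[str, AssociationEvidence] = {}
    outcomes: Dict[str, ClassificationOutcome] = {}
    reportability: Dict[str, Reportability] = {}
    masked_rows: List[dict] = []
    dropped: Dict[str, str] = {}
    for v in variants:
        keep, reason = dna_variant_filter(v, config.filter_mode)
        if not keep:
            dropped[v.variant_key] = reason
            continue
        m = models.get(v.gene_symbol)
        if m is None:
            dropped[v.variant_key] = "no gene model"
            continue
        ref = refs.get(v.chrom)
        mech = mechanism_inference(
            v, m, ref, None, config.pwm_delta, config.branch_window
        )
        carrier_events = {
            sid: [
                (ev, obs_cache[(sid, ev.event_key)])
                for ev in events_by_sample.get(sid, [])
                if ev.event_type is not EventType.UNCLASSIFIED
                and (sid, ev.event_key) in obs_cache
            ]
            for sid in variant_carriers.get(v.variant_key, ())
            if sid in carriers
        }
        adequate = _adequate_depth(
            v, m, carrier_events, carriers, config.min_denominator
        )
        ev = associate(
            v,
            carrier_events,
            control_profiles,
            m,
            mechanism=mech,
            linkage_window=config.linkage_window,
            min_psi=config.min_psi,
            fold=config.fold,
            min_denominator=config.min_denominator,
            adequate_depth=adequate,
        )
        evidence[v.variant_key] = ev
        outcomes[v.variant_key] = reclassify(v, ev, m)
        has_rna = ev.overall is Overall.ASSOCIATED
        rep = reporting_range_mask(v, has_rna, config.masking_offset)
        reportability[v.variant_key] = rep
        if rep is Reportability.MASKED:
            masked_rows.append(
                {
                    "variant_key": v.variant_key,
                    "position": str(v.position),
                    "intron_offset": v.intron_offset,
                    "reason": "outside reporting range without abnormal RNA",
                }
            )

    # ---- summary over reportable variants ----
    reportable = [
        v for v in variants
        if reportability.get(v.variant_key) is Reportability.REPORTABLE
    ]
    unique_events = [
        ev for ev in event_objects.values()
        if ev.event_type is not EventType.UNCLASSIFIED
    ]
    summary = build_cohort_summary(
        reportable,
        unique_events,
        [outcomes[v.variant_key] for v in reportable if v.variant_key in outcomes],
        variant_carriers,
        n_individuals=max(len(carriers), 1),
    )

    bundle = ReportBundle(
        config=config,
        qc=qc_results,
        events_by_sample=events_by_sample,
        control_profiles=control_profiles,
        psi_rows=psi_rows,
        evidence=evidence,
        outcomes=outcomes,
        reportability=reportability,
        masked_rows=masked_rows,
        summary=summary,
        dropped_variants=dropped,
        failed_qc_samples=failed,
    )
    if write and config.out_dir:
        write_bundle(bundle, Path(config.out_dir))
    return bundle


def _adequate_depth(
    v: VariantRecord,
    model: GeneModel,
    carrier_events: Mapping[str, Sequence],
    carriers: Mapping[str, JunctionTable],
    min_denominator: int,
) -> bool:
    """Canonical junction coverage near the variant in at least one carrier.

    Guards downgrades: a carrier without an aberrant event only argues
    against association when the region was actually sequenced deep enough
    to have seen one.
    """
    canon = list(canonical_junctions(model))
    if not canon:
        return False
    for sid in carrier_events:
        table = carriers.get(sid)
        if table is None:
            continue
        nearest = min(
            canon, key=lambda k: min(abs(v.pos - (k[1] - 1)), abs(v.pos - k[2]))
        )
        if table.get(nearest, 0) >= min_denominator:
            return True
    return False


def write_bundle(bundle: ReportBundle, out_dir: Path) -> None:
    """Write the report bundle (PSI TSV, evidence JSON, audit TSV, summary)."""
    out_dir.mkdir(parents=True, exist_ok=True)
    header = bundle.config.thresholds()
    dx_io.write_psi_report(bundle.psi_rows, out_dir / "psi_report.tsv", header)
    records = []
    for vkey, ev in bundle.evidence.items():
        outcome = bundle.outcomes[vkey]
        records.append(
            {
                "variant_key": vkey,
                "event_key": ev.event_key,
                "carrier_psi": None if math.isnan(ev.carrier_psi) else round(ev.carrier_psi, 4),
                "specificity": ev.specificity.value,
                "n_reproducing_carriers": ev.n_reproducing_carriers,
                "mechanism": ev.mechanism.value,
                "frame_effect": ev.frame_effect.value,
                "overall": ev.overall.value,
                "prior_classification": outcome.prior_classification.value,
                "rna_informed_classification": outcome.rna_informed_classification.value,
                "impact": outcome.impact.value,
                "reportability": bundle.reportability[vkey].value,
                "reasons": list(ev.reasons) + list(outcome.reasons),
            }
        )
    dx_io.write_evidence_json(records, out_dir / "evidence.json", header)
    dx_io.write_masked_audit(bundle.masked_rows, out_dir / "masked_audit.tsv")
    payload = bundle.summary.to_dict()
    payload["thresholds"] = header
    payload["failed_qc_samples"] = bundle.failed_qc_samples
    payload["dropped_variants"] = bundle.dropped_variants
    dx_io.write_summary_json(payload, out_dir / "summary.json")


# ---------------------------------------------------------------------------
# Cohort directory plumbing (simulate -> disk -> pipeline)
# ---------------------------------------------------------------------------


def write_cohort(cohort, out_dir: Path) -> PipelineConfig:
    """Write a simulated cohort to disk in the pipeline's input formats.

    Returns a :class:`PipelineConfig` pointing at the written files.
    """
    from .simulate import Cohort  # local import to avoid cycles

    out_dir = Path(out_dir)
    (out_dir / "controls").mkdir(parents=True, exist_ok=True)
    (out_dir / "carriers").mkdir(parents=True, exist_ok=True)
    dx_io.write_bed12([cohort.model], out_dir / "gene_models.bed")
    dx_io.write_fasta({cohort.model.chrom: cohort.ref.seq}, out_dir / "reference.fa")
    control_paths = {}
    for t in cohort.controls:
        p = out_dir / "controls" / f"{t.sample_id}.sj.tsv"
        dx_io.write_junction_table(t, p)
        control_paths[t.sample_id] = p.relative_to(out_dir)
    dx_io.write_manifest(control_paths, out_dir / "control_manifest.tsv")
    carrier_paths = {}
    for sid, t in cohort.carriers.items():
        p = out_dir / "carriers" / f"{sid}.sj.tsv"
        dx_io.write_junction_table(t, p)
        carrier_paths[sid] = p.relative_to(out_dir)
    dx_io.write_manifest(carrier_paths, out_dir / "sample_manifest.tsv")
    dx_io.write_vcf(
        cohort.variants,
        cohort.variant_carriers,
        out_dir / "variants.vcf",
        {cohort.model.chrom: len(cohort.ref.seq)},
    )
    qc = {sid: (92.0, 35.0, 96.0, 97.0) for sid in cohort.carriers}
    dx_io.write_qc_table(qc, out_dir / "rna_qc.tsv")
    cohort.truth.to_csv(out_dir / "truth.tsv", sep="\t", index=False)
    cfg = PipelineConfig(
        gene_models=str(out_dir / "gene_models.bed"),
        reference_fasta=str(out_dir / "reference.fa"),
        control_manifest=str(out_dir / "control_manifest.tsv"),
        sample_manifest=str(out_dir / "sample_manifest.tsv"),
        vcf=str(out_dir / "variants.vcf"),
        qc_table=str(out_dir / "rna_qc.tsv"),
        out_dir=str(out_dir / "reports"),
        seed=cohort.config.seed,
    )
    cfg.to_yaml(out_dir / "config.yaml")
    return cfg
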