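"""Readers and writers for the pipeline's file formats.

Gene models travel as BED12 (blocks = exons, thickStart/thickEnd = CDS) or
GTF; junction tables as STAR ``SJ.out.tab``-style TSV (columns 1-4 and 7 of
the STAR dialect, or the 5-column subset written here); variants as VCF 4.2
with the panel's INFO/FORMAT keys; manifests, QC metrics, truth tables and
reports as TSV/JSON.
"""

from __future__ import annotations

import json
import os
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .association import AssociationEvidence, ClassificationOutcome, GeneSequence
from .events import JunctionTable
from .gene_model import GeneModel, PositionBin, TranscriptPosition, parse_cdna_variant
from .psi import PsiObservation, RnaQcResult
from .variants import Classification, VariantRecord, VariantType

# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def write_fasta(records: Mapping[str, str], path: os.PathLike, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_gene_sequences(path: os.PathLike) -> Dict[str, GeneSequence]:
    """Load a reference FASTA into per-contig :class:`GeneSequence` objects."""
    from pyfaidx import Fasta

    fasta = Fasta(str(path), rebuild=True)
    return {name: GeneSequence(name, str(fasta[name][:]), 0) for name in fasta.keys()}


# ---------------------------------------------------------------------------
# Gene models: BED12 / GTF
# ---------------------------------------------------------------------------


def write_bed12(models: Iterable[GeneModel], path: os.PathLike) -> None:
    with open(path, "w") as fh:
        for m in models:
            gx = m.gexons
            start, end = m.span
            sizes = ",".join(str(e - s) for s, e in gx)
            starts = ",".join(str(s - start) for s, e in gx)
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        m.chrom, start, end, f"{m.gene_symbol}|{m.isoform_id}", 0,
                        m.strand, m.cds_start, m.cds_end, "0,0,0", len(gx),
                        sizes + ",", starts + ",",
                    )
                )
                + "\n"
            )


def read_bed12(path: os.PathLike) -> List[GeneModel]:
    models = []
    seen = set()
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}:{ln}: BED12 requires 12 columns")
            chrom, start = f[0], int(f[1])
            name = f[3]
            symbol, _, isoform = name.partition("|")
            if symbol in seen:
                raise ValueError(f"{path}:{ln}: duplicate isoform for gene {symbol}")
            seen.add(symbol)
            strand = f[5]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            gx = [(start + o, start + o + sz) for o, sz in zip(starts, sizes)]
            exons = tuple(gx if strand == "+" else gx[::-1])
            models.append(
                GeneModel(
                    gene_symbol=symbol, chrom=chrom, strand=strand, exons=exons,
                    cds_start=int(f[6]), cds_end=int(f[7]),
                    isoform_id=isoform or "NA",
                )
            )
    return models


def read_gtf(path: os.PathLike) -> List[GeneModel]:
    """Read one canonical isoform per gene from a GTF of exon/CDS features."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique", disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    by_tx: Dict[str, dict] = {}
    for feat in db.all_features():
        if feat.featuretype not in {"exon", "CDS"}:
            continue
        tx = feat.attributes.get("transcript_id", ["NA"])[0]
        gene = feat.attributes.get("gene_id", feat.attributes.get("gene_name", ["NA"]))[0]
        rec = by_tx.setdefault(
            tx, {"gene": gene, "chrom": feat.seqid, "strand": feat.strand, "exons": [], "cds": []}
        )
        target = rec["exons"] if feat.featuretype == "exon" else rec["cds"]
        target.append((feat.start - 1, feat.end))  # GTF is 1-based inclusive
    genes_seen = set()
    models = []
    for tx, rec in by_tx.items():
        if rec["gene"] in genes_seen:
            raise ValueError(f"multiple isoforms for gene {rec['gene']}; one canonical isoform required")
        genes_seen.add(rec["gene"])
        gx = sorted(rec["exons"])
        cds = sorted(rec["cds"]) or gx
        exons = tuple(gx if rec["strand"] == "+" else gx[::-1])
        models.append(
            GeneModel(
                gene_symbol=rec["gene"], chrom=rec["chrom"], strand=rec["strand"],
                exons=exons, cds_start=cds[0][0], cds_end=cds[-1][1], isoform_id=tx,
            )
        )
    return models


# ---------------------------------------------------------------------------
# Junction tables and manifests
# ---------------------------------------------------------------------------

_SJ_COLS = ["chrom", "intron_start", "intron_end", "strand", "unique_reads"]
_STAR_STRAND = {"0": ".", "1": "+", "2": "-"}


def write_junction_table(table: JunctionTable, path: os.PathLike) -> None:
    table.to_frame().to_csv(path, sep="\t", header=False, index=False)


def read_junction_table(path: os.PathLike, sample_id: Optional[str] = None) -> JunctionTable:
    """Read a junction TSV (5-column, or 9-column STAR ``SJ.out.tab``)."""
    sid = sample_id or Path(path).stem.split(".")[0]
    counts = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("chrom"):
                continue
            f = line.split("\t")
            try:
                if len(f) >= 9:  # STAR dialect: columns 1-4 and 7
                    chrom, s, e = f[0], int(f[1]), int(f[2])
                    strand = _STAR_STRAND.get(f[3], f[3])
                    reads = int(f[6])
                elif len(f) >= 5:
                    chrom, s, e, strand, reads = f[0], int(f[1]), int(f[2]), f[3], int(f[4])
                else:
                    raise ValueError("expected 5 or 9 columns")
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: malformed junction record ({exc})") from None
            key = (chrom, s, e, strand)
            counts[key] = counts.get(key, 0) + reads
    return JunctionTable(sample_id=sid, counts=counts)


def write_manifest(samples: Mapping[str, os.PathLike], path: os.PathLike) -> None:
    pd.DataFrame(
        [{"sample_id": k, "path": str(v)} for k, v in samples.items()]
    ).to_csv(path, sep="\t", index=False)


def read_manifest(path: os.PathLike) -> Dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty:
        raise ValueError(f"manifest {path} is empty")
    base = Path(path).parent
    out = {}
    for _, row in df.iterrows():
        p = Path(row["path"])
        out[row["sample_id"]] = str(p if p.is_absolute() else base / p)
    return out


def load_manifest_tables(path: os.PathLike) -> List[JunctionTable]:
    return [read_junction_table(p, sid) for sid, p in read_manifest(path).items()]


# ---------------------------------------------------------------------------
# RNA QC metrics
# ---------------------------------------------------------------------------

_QC_COLS = ["sample_id", "pct_q30", "mean_base_quality", "pct_perfect_index", "pct_exons_ge_50x"]


def write_qc_table(metrics: Mapping[str, Tuple[float, float, float, float]], path: os.PathLike) -> None:
    pd.DataFrame(
        [{"sample_id": k, **dict(zip(_QC_COLS[1:], v))} for k, v in metrics.items()]
    ).to_csv(path, sep="\t", index=False)


def read_qc_table(path: os.PathLike) -> Dict[str, Tuple[float, float, float, float]]:
    df = pd.read_csv(path, sep="\t")
    missing = set(_QC_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"QC table {path} missing columns: {sorted(missing)}")
    return {
        row["sample_id"]: tuple(float(row[c]) for c in _QC_COLS[1:])
        for _, row in df.iterrows()
    }


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_VCF_HEADER = """##fileformat=VCFv4.2
##source=splicedx
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=HGVSC,Number=1,Type=String,Description="cDNA variant name">
##INFO=<ID=CLASS,Number=1,Type=String,Description="Prior classification">
##INFO=<ID=TYPE,Number=1,Type=String,Description="Variant type">
##INFO=<ID=INSILICO,Number=1,Type=Integer,Description="In-silico deleterious splice prediction">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AF,Number=1,Type=Float,Description="Allele fraction">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
"""


def write_vcf(
    variants: Sequence[VariantRecord],
    variant_carriers: Mapping[str, Sequence[str]],
    path: os.PathLike,
    contig_lengths: Optional[Mapping[str, int]] = None,
) -> None:
    """Emit a multi-sample VCF 4.2; columns are all carrier samples."""
    samples = sorted({s for ss in variant_carriers.values() for s in ss})
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for chrom, length in (contig_lengths or {}).items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for v in sorted(variants, key=lambda v: (v.chrom, v.pos)):
            info = (
                f"GENE={v.gene_symbol};HGVSC={v.hgvs_c};CLASS={v.classification.value};"
                f"TYPE={v.variant_type.value};INSILICO={int(v.insilico_deleterious)}"
            )
            carriers = set(variant_carriers.get(v.variant_key, ()))
            cols = []
            for s in samples:
                if s in carriers:
                    cols.append(
                        f"0/1:{v.allele_fraction if v.allele_fraction is not None else '.'}:"
                        f"{v.depth if v.depth is not None else '.'}:"
                        f"{int(v.q_score) if v.q_score is not None else '.'}"
                    )
                else:
                    cols.append("0/0:.:.:.")
            fh.write(
                f"{v.chrom}\t{v.pos + 1}\t.\t{v.ref}\t{v.alt}\t{v.q_score if v.q_score is not None else '.'}"
                f"\tPASS\t{info}\tGT:AF:DP:GQ\t" + "\t".join(cols) + "\n"
            )


def read_vcf(
    path: os.PathLike,
    models: Optional[Mapping[str, GeneModel]] = None,
) -> Tuple[List[VariantRecord], Dict[str, List[str]]]:
    """Read variants and their carrier samples from a VCF 4.2.

    Returns one :class:`VariantRecord` per VCF record (quality metrics from
    the first carrier's FORMAT fields) plus a variant_key -> carrier-sample
    mapping. When gene models are supplied, cDNA positions and bins are
    (re)derived from the HGVSC INFO field.
    """
    from cyvcf2 import VCF

    from .gene_model import position_bin

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    variants: List[VariantRecord] = []
    carriers: Dict[str, List[str]] = {}
    for rec in vcf:
        info = dict(rec.INFO)
        gene = str(info.get("GENE", "NA"))
        hgvs = str(info.get("HGVSC", "."))
        carrier_idx = [
            i for i, gt in enumerate(rec.genotypes) if any(a == 1 for a in gt[:-1])
        ]
        af = dp = gq = None
        if carrier_idx:
            i = carrier_idx[0]
            try:
                af = float(rec.format("AF")[i][0])
            except (TypeError, ValueError):
                af = None
            try:
                dp = int(rec.format("DP")[i][0])
            except (TypeError, ValueError):
                dp = None
            try:
                gq = float(rec.format("GQ")[i][0])
            except (TypeError, ValueError):
                gq = None
        position = pbin = None
        model = (models or {}).get(gene)
        if model is not None and hgvs not in {".", ""}:
            try:
                position = parse_cdna_variant(hgvs).start
                pbin = position_bin(position, model)
            except ValueError:
                position = pbin = None
        v = VariantRecord(
            gene_symbol=gene,
            hgvs_c=hgvs,
            chrom=rec.CHROM,
            pos=rec.POS - 1,
            ref=rec.REF,
            alt=rec.ALT[0] if rec.ALT else ".",
            variant_type=VariantType(str(info.get("TYPE", "other"))),
            classification=Classification(str(info.get("CLASS", "unclassified"))),
            q_score=gq,
            allele_fraction=af,
            depth=dp,
            position=position,
            position_bin=pbin,
            insilico_deleterious=bool(int(info.get("INSILICO", 0))),
        )
        variants.append(v)
        carriers[v.variant_key] = [samples[i] for i in carrier_idx]
    return variants, carriers


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------


def write_psi_report(rows: Sequence[dict], path: os.PathLike, header: Optional[dict] = None) -> None:
    cols = [
        "event_key", "sample_id", "supporting_reads", "region_total_reads", "psi",
        "control_median", "control_p95", "specificity", "needs_rtpcr",
    ]
    with open(path, "w") as fh:
        for k, v in (header or {}).items():
            fh.write(f"# {k}={v}\n")
        pd.DataFrame(rows, columns=cols).to_csv(fh, sep="\t", index=False)


def write_evidence_json(records: Sequence[dict], path: os.PathLike, header: Optional[dict] = None) -> None:
    payload = {"thresholds": header or {}, "variants": list(records)}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=str)


def write_masked_audit(rows: Sequence[dict], path: os.PathLike) -> None:
    cols = ["variant_key", "position", "intron_offset", "reason"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def write_summary_json(summary_dict: dict, path: os.PathLike) -> None:
    with open(path, "w") as fh:
        json.dump(summary_dict, fh, indent=2, default=str)
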