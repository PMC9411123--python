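"""Pipeline configuration: paths, thresholds, rounding modes.

Every numeric constant used by the analysis lives here with its documented
default, and every report echoes the thresholds in its header for
provenance. The config round-trips through YAML.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Tuple

import yaml


@dataclass
class PipelineConfig:
    # paths (any may be None when the corresponding stage is driven in-memory)
    gene_models: Optional[str] = None  # BED12 (or GTF, by extension)
    reference_fasta: Optional[str] = None
    control_manifest: Optional[str] = None
    sample_manifest: Optional[str] = None
    vcf: Optional[str] = None
    qc_table: Optional[str] = None
    out_dir: Optional[str] = None

    # thresholds (defaults are the documented study conditions)
    min_reads: int = 3  # junction reads to emit an event
    min_psi: float = 0.10  # absolute PSI floor for specificity
    fold: float = 5.0  # fold over control p95 for specificity
    min_denominator: int = 100  # PSI denominator below which calls are indeterminate
    rtpcr_cutoff: int = 500  # PSI denominator below which RT-PCRseq confirms
    masking_offset: int = 5  # reporting range: coding exons +/- this many intronic nt
    pwm_delta: float = 2.0  # log-odds change calling site creation/weakening
    branch_window: Tuple[int, int] = (18, 44)  # nt upstream of a native acceptor
    linkage_window: int = 5000  # max nt between variant and candidate event
    allele_skew_alpha: float = 0.01
    allele_skew_min_reads: int = 20
    filter_mode: str = "conjunction"  # DNA Q/AF filter conjunction vs disjunction
    per_patient_rounding: str = "nearest"
    seed: int = 0

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["branch_window"] = list(self.branch_window)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "branch_window" in d and d["branch_window"] is not None:
            d["branch_window"] = tuple(d["branch_window"])
        return cls(**d)

    def thresholds(self) -> dict:
        """The numeric constants, for report provenance headers."""
        return {
            "min_reads": self.min_reads,
            "min_psi": self.min_psi,
            "fold": self.fold,
            "min_denominator": self.min_denominator,
            "rtpcr_cutoff": self.rtpcr_cutoff,
            "masking_offset": self.masking_offset,
            "pwm_delta": self.pwm_delta,
            "branch_window": list(self.branch_window),
            "linkage_window": self.linkage_window,
            "allele_skew_alpha": self.allele_skew_alpha,
            "allele_skew_min_reads": self.allele_skew_min_reads,
            "filter_mode": self.filter_mode,
            "per_patient_rounding": self.per_patient_rounding,
            "seed": self.seed,
        }
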