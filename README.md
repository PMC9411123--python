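# splicedx

Paired DNA–RNA splicing analysis for hereditary-cancer gene panels.

DNA panel testing reads the coding exons and a handful of intronic bases of
cancer-predisposition genes (*APC*, *ATM*, *BRCA1/2*, *CDH1*, *MLH1*, …). That
leaves two blind spots: deep-intronic variants that create or strengthen
splice sites are never sequenced, and many sequenced variants of uncertain
significance (VUS) can only be resolved by observing their effect on the
transcript. Pairing the DNA test with targeted RNA-seq closes both gaps.
`splicedx` implements the analysis layer of such a paired test as a reusable,
fully tested Python library: it consumes splice-junction count tables
(STAR `SJ.out.tab` style), gene models, and annotated VCFs, and produces
per-variant RNA evidence and classification outcomes.

## What it computes

**Aberrant splice events.** Junctions that do not match the canonical isoform
are grouped and classified into the five-type taxonomy — ESF (full exon
skip), ESP (partial skip via an alternative exonic site), ES (combined),
IP (partial intron inclusion), IC (cryptic exon / pseudoexon). Full intron
retention is deliberately out of scope for junction-level evidence.

**Percent-spliced index.** For an event *e* in a sample,

    PSI = n_alt / (n_alt + n_can)

where `n_alt` is the read count of the event's novel junction(s) and `n_can`
the count on the canonical junction(s) sharing its splice region. Each
event's PSI is profiled across a healthy-donor control pool (default n=345);
a carrier event is *specific* when `PSI ≥ 0.10` and `PSI ≥ 5 × p95(controls)`.
Events quantified at under 500× (the PSI denominator) are flagged for
RT-PCRseq confirmation.

**Mechanism.** Donor (9 nt) and acceptor (23 nt) windows are scored with
bundled log-odds PWMs. A variant that gains ≥ 2 log-odds at a non-native
window (reaching at least half the consensus score) is called novel-site
creation; a loss of ≥ 2 at a native site is native-site weakening; deletions
over the 18–44 nt window upstream of a native acceptor are branch-point
deletions; exonic variants with an associated exon-skip but no site-score
change are flagged as possible splicing-enhancer disruption.

**Association and reclassification.** A variant is *associated* with an
event when the event is specific and either reproduces in an additional
carrier or has an inferable mechanism. A deterministic rule engine then
converts evidence into outcomes: VUS with an associated coding-altering
event (confirmed at adequate coverage) upgrade to Likely Pathogenic; VUS
beyond the canonical ±2 dinucleotide with no aberrant RNA at adequate depth
downgrade to Likely Benign; prior P/LP with concordant RNA are confirmed.
Reporting-range masking is enforced throughout: intronic variants more than
5 nt from an exon are only reportable when abnormal RNA was detected.

**Cohort summaries.** Variant-type distributions, position-bin ×
classification tables, event-type counts, absolute yield / VUS-rate deltas,
and "one per N patients" frequencies.

A first-class synthetic-data module generates gene models with consensus
splice sites, binomially sampled control pools and carrier samples, and four
packaged deep-intronic fixture cases — so the entire pipeline is exercised
end to end without any external data.

## Worked example

`examples/04_deep_intronic_fixtures.py` runs the four packaged deep-intronic
scenarios through the full pipeline:

```
APC:c.423-3958C>T
  events: IC   carrier PSI: 0.400
  mechanism: novel_site_creation   overall: associated
  classification: VUS -> LP (upgrade)
...
CDH1:c.1565+672_1566-23del2827
  events: IP,IP   carrier PSI: 0.312
  mechanism: branch_point_deletion   overall: associated
  classification: VUS -> LP (upgrade)
```

The APC-style case is a C>T at the +6 position of a deep-intronic cryptic
donor: the alternate allele strengthens the site by ~2.1 log-odds, a cryptic
exon (IC) appears at PSI 0.40 with the event absent from all controls, and
the variant — 3958 nt from the nearest exon, far outside the DNA reporting
range — is upgraded from VUS to LP on RNA evidence. The CDH1-style case is
an intronic deletion that removes the native acceptor's branch point; two
pre-existing cryptic acceptors take over, producing two partial
intron-retention (IP) events at PSI 0.31 and 0.27.

The other examples cover cohort simulation (`01`), event detection and
taxonomy (`02`), PSI/control-pool specificity (`03`), and cohort summaries
plus printed-count arithmetic (`05`). A thin CLI wraps the same pipeline:

```bash
splicedx simulate --seed 1 --out-dir cohort/
splicedx run-all --config cohort/config.yaml
```

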