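# Methods

This note documents the models, rules and numerical choices behind
`splicedx`, and what the synthetic data does and does not emulate.

## Coordinates and gene models

Internally every interval is 0-based half-open; externally variants use
HGVS-style cDNA notation with 1-based coding positions and signed intronic
offsets (`c.423-3958C>T` = 3958 nt upstream of the acceptor of the exon whose
first coding base is c.423). One canonical isoform per gene is enforced at
ingest (BED12 or GTF). Minus-strand genes are mapped to transcript
orientation at the coordinate layer; all event and PSI logic then operates
on strand-independent genomic junction coordinates. UTR anchors (`c.-N`,
`c.*N`) are unsupported: the supported panel representation is fully coding,
which the synthetic generator guarantees by construction.

Position bins partition every position: exonic (with the donor-adjacent
*last* exonic nucleotide in its own bin, because of its outsized splicing
relevance), canonical ±1,2, intronic 3–5, 6–10, 11–20, and deep-intronic
beyond 20. The first exonic nucleotide is deliberately binned as exonic
internal rather than sharing the last-nucleotide bin; the alternative
grouping would only move a handful of acceptor-side variants between
adjacent rows of the position table.

## Splice-site model

Donor sites are scored over 9 nt (exonic −3..−1, intronic +1..+6), acceptors
over 23 nt (intronic −20..−1, exonic +1..+3), as log-odds sums
`Σ log2(f/0.25)` against a uniform background. `N` bases contribute exactly 0
(the column mean equals the background). The bundled frequency matrices are
fixed, versioned in-source data following the classic human U2-type
consensus (near-invariant GT/AG dinucleotides, A-rich donor +3..+5,
pyrimidine-rich acceptor tract), lightly smoothed so no column is zero.

They are deliberately *not* re-derived from the synthetic panel at build
time: the generator writes the consensus of these same matrices at every
canonical junction, so deriving the matrices from those junctions would be
circular. Bundling the generating model directly is the non-circular
equivalent — native sites in simulated panels score exactly at the PWM
maximum, and the scorer's behaviour is identical for real windows.

## Event taxonomy

Five types are recognised from junction geometry: ESF (≥1 full exon
excluded, all used sites canonical), ESP (part of an exon excluded), ES
(both), IP (one leftover intronic segment retained abutting an exon), IC (a
pseudoexon: a 1–1000 nt interval strictly inside one canonical intron,
bounded by a donor-side and an acceptor-side novel junction, merged into a
single event). Intervals above 1000 nt are flagged rather than
auto-classified. Unpaired intron-internal junctions, mixed
exonic-loss-plus-intronic-gain geometry and trans-gene junctions are
emitted as UNCLASSIFIED with a machine-readable flag and excluded from
reports. Full intron retention is never emitted: junction tables carry no
positive signal for an unspliced intron, so an IR call cannot be supported
by this evidence class.

The classifier is verified exhaustively against an independent oracle that
rebuilds the mature transcript base-by-base for every possible junction
placement on 2–4-exon toy genes and reads the label off the reconstruction.

Tandem duplications are resolved by their exon-order-inverting
back-junction (donor of the duplicated range's last exon joined to the
acceptor of its first). Back-junctions are stored with
`intron_start > intron_end` on both strands, keeping them out of the event
detector's namespace.

## PSI

PSI = supporting reads / (supporting + canonical reads sharing the event's
splice region). Both terms are junction reads only; exon-body coverage is
excluded because the pipeline's evidence class is the junction table, and a
junction-only denominator keeps the estimator a clean binomial proportion.
For IC events the numerator is the rounded-half-up mean of the two flanking
junction counts; symmetrically, when several canonical junctions share the
region (a multi-intron skip), the canonical term is the rounded mean across
them, which avoids double-counting and keeps the estimator unbiased (the
configurable alternative, taking the minimum, is more conservative at
uneven coverage). A zero denominator yields an undefined, flagged PSI —
never a zero.

Specificity against the control pool: specific ⇔ PSI ≥ `min_psi` (0.10) and
PSI ≥ `fold` (5) × the pool's 95th percentile for that event; indeterminate
below `min_denominator` (100×) coverage. The floor-plus-fold form makes the
test monotone in carrier PSI and robust to an all-zero control profile. The
RT-PCRseq confirmation trigger is strictly `denominator < 500`.

Allele skew (indirect evidence of nonsense-mediated decay at exonic SNPs)
is a two-sided exact binomial test against 0.5, indeterminate under 20
reads, α = 0.01. RNA sample QC: %Q30 > 75, mean base quality > 30, %perfect
index > 85 (strict), ≥ 85% of panel exons at ≥ 50× (inclusive).

## DNA-side rules

The quality filter drops a variant when Q ≤ 30 **and** allele fraction
< 10% — the conjunction as printed on the clinical assay; a disjunctive
mode is provided because the clinical intent of the two clauses is
arguably independent, but conjunction is the default. The Sanger exemption
(no confirmation needed) requires an SNV or ≤ 3 nt indel with AF > 35%
(strict) and depth ≥ 100 (inclusive reading of "100× coverage"); low-coverage
regions and pseudogene-flagged calls are always confirmed. The analytical
reporting range is coding exons ± 5 intronic nt; beyond it a variant is
reportable only with abnormal RNA, and masked variants go to a separate
audit file, never to the main report.

## Mechanism inference

For SNVs, every donor/acceptor window overlapping the variant is scored for
both alleles. Native-site weakening: Δ ≤ −2 log-odds at a native window.
Novel-site creation: Δ ≥ +2 at a non-native window **and** the alt window
scoring at least 50% of the PWM maximum. The absolute guard is a deliberate
refinement: the invariant GT/AG columns are worth ~9 log-odds each, so
without it any pyrimidine transition landing on such a column anywhere in
an intron would be called "creation" even when the resulting window is far
from a plausible site; real deep-intronic activating variants strengthen
already-nearly-consensus cryptic sites, which the guard captures.
Deletions overlapping a native site window are weakening; deletions
overlapping the 18–44 nt branch-point window upstream of a native acceptor
(standard branch-point biology) are branch-point deletions. ESE disruption
is flag-only: exonic variant, no site-score change, associated exon-skip
event. Everything else — including a missing reference sequence — is
UNKNOWN.

## Association and reclassification

Candidate events lie within ±5000 nt of the variant (covering the deepest
intronic offsets the fixtures preserve, −3958 included). The chosen event
maximises carrier PSI among specific observations; reproducibility counts
additional carriers of the same variant showing the same event key
specifically. `associated` requires specificity plus (reproducibility ≥ 1
or mechanism ≠ UNKNOWN). Downgrade calls additionally require demonstrated
coverage: a no-event observation only argues against association when a
canonical junction near the variant reaches `min_denominator` reads in a
carrier.

The rule engine replaces case-by-case expert review with deterministic
rules (each outcome carries its reason trail): VUS + associated
coding-altering event + coverage ≥ 500× or RT-PCR confirmation → LP;
VUS beyond ±2 + not associated at adequate depth → LB; P/LP + associated →
confirmed (counted as no impact in yield arithmetic); gross duplication +
tandem back-junction + frameshift → LP. How much reproducibility or PSI the
original assay required for an upgrade is not published; the defaults above
are the package's stated choices and all are configurable.

## Synthetic data

The generator emulates the *statistical* structure the analysis assumes:

* panel genes with uniform exon (90–180 nt) and intron (300–900 nt) lengths
  and PWM-consensus junctions, fully coding;
* a 345-sample control pool whose baseline alternative splicing is drawn
  per sample and per event from Beta(0.5, 99.5) (mean PSI 0.005) — no
  published control-noise model exists, so this is a stated assumption
  producing realistically rare 1–4% outliers;
* carriers with heterozygous true PSI 0.35 by default (a mid-range
  heterozygous value; an `nmd_attenuation` factor multiplies it to emulate
  decay of the aberrant transcript), sampled Binomial(depth=1000, PSI) per
  junction region;
* deleterious variants placed at splice-relevant offsets (±1, ±2, +3, +5,
  deeper) of the exon their event skips; benign variants deeper in introns
  with no event;
* four fixture cases preserving the printed deep-intronic cDNA offsets
  exactly (−3958, −2661, −3384, +672/−23) on scaled-down genes, with
  sequences engineered so mechanism inference succeeds from PWM scores.

What it does **not** emulate: read-level errors, mapping artifacts,
expression variability between genes, exon-body coverage, partial-intron
noise events, batch effects, or the clinical case mix. Passing tests
therefore demonstrate the correctness and calibration of the *analysis*
under its stated model, not the assay's clinical sensitivity on real
samples.

Problem sizes in the shipped tests and acceptance script — 345 controls /
50 carriers for end-to-end recovery, 500 replicates × 4 PSI levels at depth
1000 for estimator coverage, 1000 variants for masking safety, 2–4-exon
genes for exhaustive taxonomy enumeration — were chosen as the smallest
sizes at which the respective checks are statistically meaningful.

## Numerical conventions and edge cases

Percentages are reported to one decimal, round-half-up. "One per N
patients" supports nearest (default) and ceiling rounding; published
figures of this form do not consistently follow a single convention (see
the per-patient frequencies in the acceptance output, which use nearest for
the >20 nt figure and ceiling for the >10 nt figure). Read-count means are
rounded half-up before forming PSI ratios. Ties in intronic anchoring (a
position equidistant from donor and acceptor) go to the donor side.
Single-exon genes yield an empty canonical junction set and no events.
Zero-read junctions are never emitted by the simulator; zero denominators
yield flagged undefined PSI. All simulator outputs are bitwise
deterministic for a given seed.

## Known limitations

* Junction-only evidence: no full intron retention, no exon-body coverage
  models, no isoform-level quantification.
* The mechanism engine scores splice sites only; it does not model ESE/ESS
  hexamer landscapes (ESE calls are flag-only) or branch-point strength
  beyond window overlap.
* The reclassification rules are a deterministic simplification of expert
  review; they implement RNA evidence only, not segregation, population
  frequency, or functional-assay evidence.
* NMD assessment is limited to the allele-skew test; no calibration against
  historical carrier cohorts is attempted.
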