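"""The four packaged deep-intronic scenarios, end to end.

Each fixture bundles an engineered gene whose reference sequence makes
the intended mechanism inferable from PWM scores alone: a strengthened
cryptic donor (+6 C>T), two created splice sites (-1 A>G acceptor,
+2 A>T donor) - each yielding a cryptic exon - and a branch-point
deletion yielding two partial intron-retention events. All four variants
are deep intronic (far outside the DNA reporting range) and are upgraded
from VUS only because the RNA evidence associates them with a specific,
frameshifting event.
"""

from splicedx import PipelineConfig, fixture_cases, run_pipeline

for name, c in fixture_cases().items():
    bundle = run_pipeline(
        PipelineConfig(),
        models={c.model.gene_symbol: c.model},
        refs={c.model.chrom: c.ref},
        controls=c.controls,
        carriers={c.carrier.sample_id: c.carrier},
        variants=[c.variant],
        variant_carriers={c.variant.variant_key: [c.carrier.sample_id]},
        write=False,
    )
    ev = bundle.evidence[c.variant.variant_key]
    outcome = bundle.outcomes[c.variant.variant_key]
    types = ",".join(e.event_type.value for e in bundle.events_by_sample["PROBAND"])
    print(f"{c.variant.variant_key}")
    print(f"  events: {types}   carrier PSI: {ev.carrier_psi:.3f}")
    print(f"  mechanism: {ev.mechanism.value}   overall: {ev.overall.value}")
    print(f"  classification: {outcome.prior_classification.value} -> "
          f"{outcome.rna_informed_classification.value} ({outcome.impact.value})")
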