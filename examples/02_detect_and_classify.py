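"""Detect aberrant splice events in a carrier and classify them.

Every junction that does not match the canonical isoform and carries
enough reads becomes exactly one event in the five-type taxonomy:
ESF (full exon skip), ESP (partial skip), ES (combined), IP (partial
intron inclusion), IC (cryptic exon).
"""

from splicedx import detect_events, simulate_sample
from splicedx.simulate import blueprint_esf, blueprint_ic, make_gene_model

model, ref = make_gene_model(5, seed=11, gene_symbol="MLH1", chrom="chr3")

# A carrier expressing two aberrant events: a full skip of exon 3 at PSI
# 0.40 and a 150 nt cryptic exon inside intron 1 at PSI 0.25.
events = [
    (blueprint_esf(model, 3), 0.40),
    (blueprint_ic(model, 1, 60, 150), 0.25),
]
carrier = simulate_sample(model, events, depth=1000, seed_or_rng=5, sample_id="PT0001")

for ev in detect_events(carrier, model, min_reads=3):
    print(f"{ev.event_type.value:4s} {ev.event_key}")
    print(f"     skipped exons: {ev.skipped_exons or '-'}  "
          f"included intronic: {ev.included_intronic_interval or '-'}  "
          f"frame: {ev.frame_effect.value}")

# The frame effect (net coding-length change mod 3) feeds pathogenicity
# assessment: a frameshifting event is stronger evidence than an in-frame one.
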