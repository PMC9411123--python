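"""Quantify an event's PSI and test its specificity against controls.

PSI = reads supporting the aberrant junction(s) / all junction reads in
the region covering the event. An event is 'specific' when the carrier's
PSI clears an absolute floor (0.10) and a 5x fold change over the control
pool's 95th percentile; events with a PSI denominator under 500x are
flagged for RT-PCRseq confirmation.
"""

import numpy as np

from splicedx import (
    compute_psi,
    control_profile,
    detect_events,
    needs_rtpcr_confirmation,
    simulate_sample,
    specificity_test,
)
from splicedx.simulate import blueprint_esf, make_gene_model

model, _ = make_gene_model(4, seed=3, gene_symbol="PALB2", chrom="chr16")
bp = blueprint_esf(model, 2)
rng = np.random.default_rng(9)

carrier = simulate_sample(model, [(bp, 0.35)], depth=1000, seed_or_rng=rng, sample_id="PT1")
controls = [
    simulate_sample(model, [(bp, float(rng.beta(0.5, 99.5)))], 1000, rng, f"HC{i:03d}")
    for i in range(345)
]

(event,) = detect_events(carrier, model, min_reads=3)
obs = compute_psi(event, carrier, model)
profile = control_profile(event, controls, model)
spec = specificity_test(obs, profile)

print(f"event: {event.event_key}")
print(f"carrier PSI: {obs.psi:.3f} ({obs.supporting_reads}/{obs.region_total_reads})")
print(f"controls (n={profile.n_controls}): median {profile.median_psi:.4f}, "
      f"p95 {profile.p95_psi:.4f}, max {profile.max_psi:.4f}")
print(f"specificity: {spec.value}")
print(f"needs RT-PCRseq confirmation (<500x): {needs_rtpcr_confirmation(obs)}")
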