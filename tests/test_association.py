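"""Mechanism inference, association evidence, reclassification rules."""

import math

import numpy as np
import pytest

from splicedx import (
    Classification,
    ControlProfile,
    EventType,
    FrameEffect,
    GeneSequence,
    Impact,
    JunctionTable,
    Mechanism,
    Overall,
    PsiObservation,
    Specificity,
    TranscriptPosition,
    VariantRecord,
    VariantType,
    associate,
    compute_psi,
    control_profile,
    detect_events,
    mechanism_inference,
    reclassify,
)
from splicedx.association import AssociationEvidence
from splicedx.simulate import blueprint_esf, fixture_cases, make_gene_model, simulate_sample


@pytest.fixture(scope="module")
def gene():
    return make_gene_model(4, seed=21, gene_symbol="PANEL1", chrom="chrP")


def variant_at(model, ref, g, alt=None, **kw):
    from splicedx.gene_model import genomic_to_transcript, position_bin

    ref_base = ref.fetch(g, g + 1)
    alts = {"A": "C", "C": "A", "G": "A", "T": "G"}
    tp = genomic_to_transcript(model, g)
    defaults = dict(
        variant_type=VariantType.SPLICING,
        classification=Classification.VUS,
        q_score=50.0,
        allele_fraction=0.5,
        depth=200,
    )
    defaults.update(kw)
    return VariantRecord(
        gene_symbol=model.gene_symbol,
        hgvs_c=f"c.{tp}{ref_base}>{alt or alts[ref_base]}",
        chrom=model.chrom,
        pos=g,
        ref=ref_base,
        alt=alt or alts[ref_base],
        position=tp,
        **defaults,
    )


class TestMechanism:
    def test_plus_one_transversion_weakens_native_donor(self, gene):
        model, ref = gene
        g = model.introns[0][0]  # the invariant G of intron 1's donor
        v = variant_at(model, ref, g, alt="A")
        assert mechanism_inference(v, model, ref) is Mechanism.NATIVE_SITE_WEAKENING

    def test_deep_intronic_random_base_change_is_unknown(self, gene):
        model, ref = gene
        s, e = model.introns[0]
        g = (s + e) // 2
        v = variant_at(model, ref, g)
        assert mechanism_inference(v, model, ref) is Mechanism.UNKNOWN

    def test_missing_reference_sequence_is_unknown(self, gene):
        model, ref = gene
        v = variant_at(model, ref, model.introns[0][0], alt="A")
        assert mechanism_inference(v, model, None) is Mechanism.UNKNOWN

    def test_deletion_over_branch_window_is_branch_point_deletion(self, gene):
        model, ref = gene
        s, e = model.introns[1]
        # delete offsets -40..-25 of the acceptor: inside the 18-44 branch window
        tp_start = TranscriptPosition(
            model.cds_tx_start + model._cum[1] - 1 + 1 - model.cds_tx_start + 1, 0
        )
        del_len = 16
        v = VariantRecord(
            gene_symbol=model.gene_symbol,
            hgvs_c=f"c.{model._cum[1] + 1}-40_{model._cum[1] + 1}-25del",
            chrom=model.chrom,
            pos=e - 40,
            ref=ref.fetch(e - 40, e - 24),
            alt="N",
            variant_type=VariantType.SPLICING,
            classification=Classification.VUS,
            position=TranscriptPosition(model._cum[1] + 1, -40),
        )
        assert mechanism_inference(v, model, ref) is Mechanism.BRANCH_POINT_DELETION

    def test_deletion_over_native_site_is_weakening(self, gene):
        model, ref = gene
        s, e = model.introns[1]
        v = VariantRecord(
            gene_symbol=model.gene_symbol,
            hgvs_c=f"c.{model._cum[1] + 1}-10_{model._cum[1] + 1}-3del",
            chrom=model.chrom,
            pos=e - 10,
            ref=ref.fetch(e - 10, e - 2),
            alt="N",
            variant_type=VariantType.SPLICING,
            classification=Classification.VUS,
            position=TranscriptPosition(model._cum[1] + 1, -10),
        )
        assert mechanism_inference(v, model, ref) is Mechanism.NATIVE_SITE_WEAKENING

    def test_exonic_variant_with_skip_event_flags_possible_ese(self, gene):
        model, ref = gene
        s, e = model.exons[1]
        g = s + (e - s) // 2  # mid-exon, far from site windows
        v = variant_at(model, ref, g, variant_type=VariantType.SYNONYMOUS)
        bp = blueprint_esf(model, 2)
        table = simulate_sample(model, [(bp, 0.3)], 1000, 3, "S1")
        (event,) = [
            ev for ev in detect_events(table, model, 3) if ev.event_type is EventType.ESF
        ]
        got = mechanism_inference(v, model, ref, associated_event=event)
        assert got is Mechanism.POSSIBLE_ESE_DISRUPTION

    @pytest.mark.parametrize("name", ["APC", "ATM", "BRCA2", "CDH1"])
    def test_fixture_mechanisms(self, name):
        c = fixture_cases(n_controls=2)[name]
        got = mechanism_inference(c.variant, c.model, c.ref)
        assert got.value == c.expected_mechanism

    def test_apc_alt_allele_scores_higher_at_cryptic_donor(self):
        """Direct PWM evaluation of both alleles at the engineered window."""
        from splicedx import splice_site_strength

        c = fixture_cases(n_controls=2)["APC"]
        g = c.variant.pos
        wstart = g - 8  # +6 position sits at window offset 8
        ref_win = c.ref.fetch(wstart, wstart + 9)
        alt_win = ref_win[:8] + "T"
        assert splice_site_strength(alt_win, "donor") > splice_site_strength(
            ref_win, "donor"
        ) + 2.0 - 1e-9


def _assoc_inputs(model, ref, psi, control_psi=0.0, depth=1000, n_controls=20):
    bp = blueprint_esf(model, 2)
    rng = np.random.default_rng(50)
    carrier = simulate_sample(model, [(bp, psi)], depth, rng, "PT1")
    events = detect_events(carrier, model, 3)
    controls = [
        simulate_sample(model, [(bp, control_psi)], depth, rng, f"HC{i}")
        for i in range(n_controls)
    ]
    pairs = [(ev, compute_psi(ev, carrier, model)) for ev in events]
    profiles = {
        ev.event_key: control_profile(ev, controls, model) for ev in events
    }
    return {"PT1": pairs}, profiles, carrier


class TestAssociate:
    def test_specific_event_with_mechanism_is_associated(self, gene):
        model, ref = gene
        carrier_events, profiles, _ = _assoc_inputs(model, ref, 0.4)
        v = variant_at(model, ref, model.introns[1][0], alt="A")
        ev = associate(
            v, carrier_events, profiles, model, mechanism=Mechanism.NATIVE_SITE_WEAKENING
        )
        assert ev.overall is Overall.ASSOCIATED
        assert ev.specificity is Specificity.SPECIFIC
        assert ev.carrier_psi == pytest.approx(0.4, abs=0.05)

    def test_no_event_at_adequate_depth_not_associated(self, gene):
        model, ref = gene
        v = variant_at(model, ref, model.introns[1][0] + 15)
        ev = associate(v, {"PT1": []}, {}, model, adequate_depth=True)
        assert ev.overall is Overall.NOT_ASSOCIATED

    def test_event_present_in_controls_not_associated(self, gene):
        model, ref = gene
        carrier_events, profiles, _ = _assoc_inputs(model, ref, 0.35, control_psi=0.30)
        v = variant_at(model, ref, model.introns[1][0], alt="A")
        ev = associate(
            v, carrier_events, profiles, model, mechanism=Mechanism.NATIVE_SITE_WEAKENING
        )
        assert ev.overall is Overall.NOT_ASSOCIATED

    def test_no_rna_sample_indeterminate(self, gene):
        model, ref = gene
        v = variant_at(model, ref, model.introns[1][0], alt="A")
        ev = associate(v, {}, {}, model)
        assert ev.overall is Overall.INDETERMINATE

    def test_specific_event_without_mechanism_or_reproducibility(self, gene):
        model, ref = gene
        carrier_events, profiles, _ = _assoc_inputs(model, ref, 0.4)
        v = variant_at(model, ref, model.introns[1][0] + 30)
        ev = associate(v, carrier_events, profiles, model, mechanism=Mechanism.UNKNOWN)
        assert ev.overall is Overall.INDETERMINATE

    def test_reproducing_carrier_substitutes_for_mechanism(self, gene):
        model, ref = gene
        ce1, profiles, _ = _assoc_inputs(model, ref, 0.4)
        bp = blueprint_esf(model, 2)
        carrier2 = simulate_sample(model, [(bp, 0.4)], 1000, 7, "PT2")
        events2 = detect_events(carrier2, model, 3)
        ce1["PT2"] = [(ev, compute_psi(ev, carrier2, model)) for ev in events2]
        v = variant_at(model, ref, model.introns[1][0] + 30)
        ev = associate(v, ce1, profiles, model, mechanism=Mechanism.UNKNOWN)
        assert ev.overall is Overall.ASSOCIATED
        assert ev.n_reproducing_carriers == 1

    def test_event_beyond_linkage_window_ignored(self, gene):
        model, ref = gene
        carrier_events, profiles, _ = _assoc_inputs(model, ref, 0.4)
        # a variant at intron 3's donor, several hundred nt from the event
        v = variant_at(model, ref, model.introns[2][0], alt="A")
        ev = associate(
            v, carrier_events, profiles, model,
            mechanism=Mechanism.NATIVE_SITE_WEAKENING, linkage_window=1,
        )
        assert ev.overall is not Overall.ASSOCIATED


def _evidence(
    overall=Overall.ASSOCIATED,
    specificity=Specificity.SPECIFIC,
    frame=FrameEffect.FRAMESHIFT,
    psi=0.4,
    denom=1000,
    mech=Mechanism.NOVEL_SITE_CREATION,
    event_key="G|IC|chr1:1-2",
    reproducing=1,
):
    obs = PsiObservation(event_key or "E", "PT1", int(psi * denom), denom, psi)
    return AssociationEvidence(
        "G:c.1A>G", event_key, psi, specificity, reproducing, mech, frame, overall,
        carrier_observation=obs,
    )


class TestReclassify:
    def _variant(self, offset=-30, classification=Classification.VUS, vtype=VariantType.SPLICING):
        return VariantRecord(
            "G", "c.100C>T", "chr1", 500, "C", "T", vtype, classification,
            position=TranscriptPosition(100, offset),
        )

    def test_vus_with_associated_frameshift_upgrades_to_lp(self):
        out = reclassify(self._variant(), _evidence())
        assert out.impact is Impact.UPGRADE
        assert out.rna_informed_classification is Classification.LP

    def test_upgrade_withheld_below_rtpcr_coverage_without_confirmation(self):
        out = reclassify(self._variant(), _evidence(denom=300))
        assert out.impact is Impact.NONE

    def test_rtpcr_confirmation_enables_low_coverage_upgrade(self):
        out = reclassify(self._variant(), _evidence(denom=300), rtpcr_confirmed=True)
        assert out.impact is Impact.UPGRADE

    def test_vus_not_associated_beyond_dinucleotide_downgrades(self):
        ev = AssociationEvidence(
            "G:c.1A>G", None, 0.0, Specificity.NOT_SPECIFIC, 0, Mechanism.UNKNOWN,
            FrameEffect.NOT_APPLICABLE, Overall.NOT_ASSOCIATED,
        )
        out = reclassify(self._variant(offset=15), ev)
        assert out.impact is Impact.DOWNGRADE
        assert out.rna_informed_classification is Classification.LB

    def test_no_downgrade_when_coverage_indeterminate(self):
        ev = AssociationEvidence(
            "G:c.1A>G", None, math.nan, Specificity.INDETERMINATE, 0,
            Mechanism.UNKNOWN, FrameEffect.NOT_APPLICABLE, Overall.INDETERMINATE,
        )
        out = reclassify(self._variant(offset=15), ev)
        assert out.impact is Impact.NONE

    def test_no_downgrade_at_canonical_dinucleotide(self):
        ev = AssociationEvidence(
            "G:c.1A>G", None, 0.0, Specificity.NOT_SPECIFIC, 0, Mechanism.UNKNOWN,
            FrameEffect.NOT_APPLICABLE, Overall.NOT_ASSOCIATED,
        )
        out = reclassify(self._variant(offset=2), ev)
        assert out.impact is Impact.NONE

    def test_prior_pathogenic_with_concordant_rna_confirms(self):
        out = reclassify(self._variant(classification=Classification.P), _evidence())
        assert out.impact is Impact.CONFIRM
        assert out.rna_informed_classification is Classification.P

    def test_association_invariant_forbids_upgrade_without_specificity(self):
        """Constructing 'associated' evidence without specificity is impossible."""
        with pytest.raises(ValueError):
            _evidence(specificity=Specificity.NOT_SPECIFIC)

    def test_tandem_duplication_upgrade(self):
        v = self._variant(vtype=VariantType.GROSS_DEL_DUP)
        ev = AssociationEvidence(
            v.variant_key, None, math.nan, Specificity.INDETERMINATE, 0,
            Mechanism.UNKNOWN, FrameEffect.FRAMESHIFT, Overall.INDETERMINATE,
        )
        out = reclassify(v, ev, tandem_dup=(True, ("chr1", 900, 100, "+"), ""))
        assert out.impact is Impact.UPGRADE
        assert out.rna_informed_classification is Classification.LP

    def test_tandem_negative_no_upgrade(self):
        v = self._variant(vtype=VariantType.GROSS_DEL_DUP)
        ev = AssociationEvidence(
            v.variant_key, None, math.nan, Specificity.INDETERMINATE, 0,
            Mechanism.UNKNOWN, FrameEffect.FRAMESHIFT, Overall.INDETERMINATE,
        )
        out = reclassify(v, ev, tandem_dup=(False, None, "insufficient_data"))
        assert out.impact is Impact.NONE
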