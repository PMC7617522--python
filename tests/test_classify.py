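"""Damage-category evaluators, verdict rule and performance metrics."""

import math

import numpy as np
import pytest

import tmimpact as tm
from tmimpact.classify import (
    CATEGORY_REGISTRY, FeatureOutcome, OutsideMembraneError,
    verdict_from_outcomes,
)
from tmimpact.fixtures import (
    FixtureSpec, build_buried_gly_bend, build_contact_motif, build_fixture,
    build_hbond_helix_pair,
)
from tmimpact.metrics import ConfusionCounts, compute_metrics
from tmimpact.placement import CORE, HEAD
from tmimpact.structure import ResidueSelector as RS

from conftest import forced_placement


def triggered(pred):
    return [o.category for o in pred.outcomes if o.triggered]


def salt_bridge_motif(d=3.0):
    return build_contact_motif(FixtureSpec(
        kind="contact_motif", length=1, sequence="E", motif="salt_bridge",
        contact_distance=d))


class TestChargeCategories:
    def test_charge_introduced_in_core(self, helix20):
        s, _ = helix20
        pred = tm.predict(s, RS("A", 10), "L", "R",
                          placement=forced_placement(s))
        assert pred.verdict == "damaging"
        assert triggered(pred) == ["TM_Charge_Introduced"]

    def test_conservative_substitution_tolerated(self, helix20):
        s, _ = helix20
        pred = tm.predict(s, RS("A", 10), "L", "I",
                          placement=forced_placement(s))
        assert pred.verdict == "tolerated"
        assert triggered(pred) == []

    def test_charged_to_charged_not_introduction(self, helix20):
        s, _ = helix20
        # K2 in CORE under the forced placement; K->R keeps the charge
        pred = tm.predict(s, RS("A", 2), "K", "R",
                          placement=forced_placement(s))
        assert "TM_Charge_Introduced" not in triggered(pred)

    def test_charge_switched_in_core(self, helix20):
        s, _ = helix20
        pred = tm.predict(s, RS("A", 2), "K", "D",
                          placement=forced_placement(s))
        assert "TM_Charge_Switched" in triggered(pred)

    def test_core_categories_inapplicable_in_head(self, helix20):
        s, _ = helix20
        pl = forced_placement(s, region=HEAD)
        pred = tm.predict(s, RS("A", 10), "L", "R", placement=pl)
        by_cat = {o.category: o for o in pred.outcomes}
        assert not by_cat["TM_Charge_Introduced"].applicable
        assert not by_cat["TM_Charge_Switched"].applicable

    def test_head_charge_replaced_and_switched(self, helix22):
        s, _ = helix22
        pl = tm.place(s)  # terminal lysines sit in HEAD
        pred = tm.predict(s, RS("A", 1), "K", "L", placement=pl)
        out = [o for o in pred.outcomes if o.triggered][0]
        assert out.category == "Head_Charge_Lost_Or_Switched"
        assert out.subcategory == "charge_replaced"
        pred2 = tm.predict(s, RS("A", 1), "K", "E", placement=pl)
        out2 = [o for o in pred2.outcomes
                if o.category == "Head_Charge_Lost_Or_Switched"][0]
        assert out2.triggered and out2.subcategory == "charge_switched"

    def test_head_charge_conserved_tolerated(self, helix22):
        s, _ = helix22
        pred = tm.predict(s, RS("A", 1), "K", "R", placement=tm.place(s))
        assert pred.verdict == "tolerated"

    def test_head_category_needs_charged_wild_type(self, helix20):
        s, _ = helix20
        pl = forced_placement(s, region=HEAD)
        pred = tm.predict(s, RS("A", 10), "L", "A", placement=pl)
        out = [o for o in pred.outcomes
               if o.category == "Head_Charge_Lost_Or_Switched"][0]
        assert not out.applicable


class TestBondCategories:
    def test_salt_bridge_broken_by_neutral_substitution(self):
        s, _ = salt_bridge_motif(3.0)
        pred = tm.predict(s, RS("A", 1), "E", "L",
                          placement=forced_placement(s))
        assert "TM_Salt_Bridge_Broken" in triggered(pred)

    def test_salt_bridge_verdict_follows_remeasured_distance(self):
        """E->D keeps the verdict consistent with the rebuilt Asp-Lys
        distance: triggered iff no carboxylate O remains under 5 A."""
        s, _ = salt_bridge_motif(3.0)
        pred = tm.predict(s, RS("A", 1), "E", "D",
                          placement=forced_placement(s))
        mut_bridges = [c for c in
                       tm.find_salt_bridges(
                           _mutant_of(s, RS("A", 1), "E", "D"))
                       ]
        fired = "TM_Salt_Bridge_Broken" in triggered(pred)
        assert fired == (not mut_bridges)

    def test_no_bridge_means_not_applicable(self, helix20):
        s, _ = helix20
        pred = tm.predict(s, RS("A", 10), "L", "V",
                          placement=forced_placement(s))
        out = [o for o in pred.outcomes
               if o.category == "TM_Salt_Bridge_Broken"][0]
        assert not out.applicable

    def test_disulphide_broken(self):
        s, _ = build_contact_motif(FixtureSpec(
            kind="contact_motif", length=1, sequence="C", motif="disulphide",
            contact_distance=2.05))
        pred = tm.predict(s, RS("A", 1), "C", "S",
                          placement=forced_placement(s))
        assert "Disulphide_Bond_Broken" in triggered(pred)

    def test_interhelix_hbond_broken_by_ser_to_ala(self):
        s, _ = build_hbond_helix_pair("S", 2.9)
        pred = tm.predict(s, RS("A", 6), "S", "A",
                          placement=forced_placement(s))
        assert "TM_HBonds_Broken" in triggered(pred)

    def test_thr_to_ser_follows_bond_preservation(self):
        """T->S: triggered iff the rebuilt hydroxyl loses the bond to the
        Asn partner (oracle re-measures the mutant distance)."""
        s, _ = build_hbond_helix_pair("T", 2.9)
        pred = tm.predict(s, RS("A", 6), "T", "S",
                          placement=forced_placement(s))
        mut = _mutant_of(s, RS("A", 6), "T", "S")
        bonds = [c for c in tm.find_hbonds(mut)
                 if c.involves(RS("A", 6)) and c.involves(RS("B", 6))]
        fired = "TM_HBonds_Broken" in triggered(pred)
        assert fired == (not bonds)

    def test_single_helix_target_not_applicable(self, helix20):
        s, _ = helix20
        pred = tm.predict(s, RS("A", 10), "L", "A",
                          placement=forced_placement(s))
        out = [o for o in pred.outcomes if o.category == "TM_HBonds_Broken"][0]
        assert not out.applicable


class TestBuriedAndBackboneCategories:
    def test_buried_glycine_in_bend(self):
        s, _ = build_buried_gly_bend()
        pred = tm.predict(s, RS("A", 5), "G", "V",
                          placement=forced_placement(s))
        assert "Buried_Glycine_In_Bend" in triggered(pred)

    def test_cis_proline_replaced(self):
        s, _ = build_fixture(FixtureSpec(kind="cis_peptide", length=3,
                                         sequence="APA"))
        pred = tm.predict(s, RS("A", 2), "P", "A",
                          placement=forced_placement(s))
        assert "CIS_Proline_Replaced" in triggered(pred)

    def test_trans_proline_not_cis_category(self):
        from tmimpact.fixtures import build_chain
        s = build_chain("APA", phi=-75.0, psi=150.0)  # all-trans omegas
        pred = tm.predict(s, RS("A", 2), "P", "A",
                          placement=forced_placement(s))
        assert "CIS_Proline_Replaced" not in triggered(pred)

    def test_buried_charge_switch(self):
        """A charge flip at a fully buried position triggers regardless of
        core/head assignment."""
        from tmimpact.fixtures import build_buried_gly_bend
        s, _ = build_buried_gly_bend()
        # residue A/5 is buried (RSA ~ 0); force an Asp there first
        m = _mutant_of(s, RS("A", 5), "G", "D")
        pred = tm.predict(m, RS("A", 5), "D", "K",
                          placement=forced_placement(m))
        assert "Buried_Charge_Switch" in triggered(pred)


class TestPredictPipeline:
    def test_outside_membrane_soft_refusal(self, helix20):
        s, _ = helix20
        pl = forced_placement(s, region="OUTSIDE")
        with pytest.raises(OutsideMembraneError, match="globular"):
            tm.predict(s, RS("A", 10), "L", "R", placement=pl)

    def test_full_pipeline_with_real_placement(self, helix20):
        s, _ = helix20
        pred = tm.predict(s, RS("A", 10), "L", "R")
        assert pred.verdict == "damaging"
        assert pred.region == CORE
        assert pred.depth <= 15.0

    def test_report_serialises(self, helix20):
        import json
        s, _ = helix20
        pred = tm.predict(s, RS("A", 10), "L", "R",
                          placement=forced_placement(s))
        d = json.loads(pred.to_json())
        assert d["verdict"] == "damaging"
        assert len(d["outcomes"]) == len(CATEGORY_REGISTRY)
        text = pred.to_text()
        assert "TM_Charge_Introduced" in text

    def test_borderline_hbond_changes_reported(self):
        s, _ = build_hbond_helix_pair("T", 2.9)
        pred = tm.predict(s, RS("A", 6), "T", "S",
                          placement=forced_placement(s))
        changes = {c["change"] for c in pred.borderline_hbond_changes}
        assert changes <= {"lost", "gained"}


class TestVerdictProperties:
    def test_biconditional_and_monotonicity(self):
        """verdict == damaging iff >= 1 triggered outcome, and adding a
        triggered outcome never flips damaging -> tolerated (1,000
        randomised outcome sets)."""
        rng = np.random.default_rng(20240917)
        cats = list(CATEGORY_REGISTRY)
        for _ in range(1000):
            flags = rng.random(len(cats)) < 0.25
            outcomes = [FeatureOutcome(c, bool(f), True)
                        for c, f in zip(cats, flags)]
            v = verdict_from_outcomes(outcomes)
            assert (v == "damaging") == any(flags)
            extra = outcomes + [FeatureOutcome("extra", True, True)]
            assert verdict_from_outcomes(extra) == "damaging"

    def test_triggered_requires_applicable(self):
        with pytest.raises(ValueError):
            FeatureOutcome("X", triggered=True, applicable=False)


class TestMetrics:
    def test_perfect_counts(self):
        m = compute_metrics(ConfusionCounts(TP=1, FP=0, TN=1, FN=0))
        assert m["accuracy"] == 1.0
        assert m["MCC"] == pytest.approx(1.0)

    def test_no_false_positives_gives_infinite_ratio(self):
        m = compute_metrics(ConfusionCounts(TP=5, FP=0, TN=3, FN=2))
        assert math.isinf(m["TPR_FPR_ratio"])

    def test_benchmark_scale_confusion_table(self):
        """A 3,138-variant table with sens ~0.58 / spec ~0.81 lands at
        accuracy ~0.66 and MCC ~0.37."""
        m = compute_metrics(ConfusionCounts(TP=1205, FN=873, TN=859, FP=201))
        assert m["sensitivity"] == pytest.approx(0.580, abs=0.001)
        assert m["specificity"] == pytest.approx(0.810, abs=0.001)
        assert m["accuracy"] == pytest.approx(0.658, abs=0.001)
        assert m["MCC"] == pytest.approx(0.37, abs=0.01)

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(ConfusionCounts(0, 0, 0, 0))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(-1, 0, 0, 0)

    def test_matches_independent_formulas_on_random_tables(self):
        """1,000 random confusion tables against directly coded formulas."""
        rng = np.random.default_rng(7)
        for _ in range(1000):
            tp, fp, tn, fn = (int(x) for x in rng.integers(0, 500, 4))
            if tp + fp + tn + fn == 0:
                continue
            m = compute_metrics(ConfusionCounts(tp, fp, tn, fn))
            assert m["accuracy"] == pytest.approx(
                (tp + tn) / (tp + fp + tn + fn))
            if tp + fn:
                assert m["sensitivity"] == pytest.approx(tp / (tp + fn))
            if tn + fp:
                assert m["specificity"] == pytest.approx(tn / (tn + fp))
            den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
            if den:
                assert m["MCC"] == pytest.approx((tp * tn - fp * fn) / den)


def _mutant_of(s, sel, wt, mut):
    from tmimpact.variants import RepackJob, mutate_and_repack
    return mutate_and_repack(s, RepackJob(sel, wt, mut)).mutant
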