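"""Decision-tree drug response, tier-2 recommendations, pathway projection,
germline screening, trial matching and actionability accounting."""

import dataclasses

import pytest

from oncointerp.knowledgebase import DrugRule, parse_predicate
from oncointerp.synthetic import make_cna, make_germline, make_somatic
from oncointerp.therapy import (
    actionability,
    germline_risk_screen,
    match_trials,
    predict_tier1_response,
    project_onto_pathways,
    recommend_tier2,
)
from oncointerp.variant_model import ExpressionRecord, PatientProfile


def _pred(predictions, drug):
    return next(p for p in predictions if p.drug == drug)


# ---------------------------------------------------------------------------
# tier-1 decision tree
# ---------------------------------------------------------------------------


def test_ras_activating_colorectal_blocks_anti_egfr(kb, by_patient):
    preds = predict_tier1_response(by_patient["P0018"], kb)  # KRAS p.G13D
    for drug in ("cetuximab", "panitumumab"):
        p = _pred(preds, drug)
        assert (p.effect, p.evidence) == ("lack_of_benefit", "Definitive")
        assert any(a.gene == "KRAS" for a in p.supporting_alterations)


def test_quadruple_negative_with_ligand_overexpression_predicts_benefit(kb, by_patient):
    preds = predict_tier1_response(by_patient["P0009"], kb)  # EREG/AREG high, RAS/RAF wt
    p = _pred(preds, "cetuximab")
    assert (p.effect, p.evidence) == ("benefit", "Moderate")
    assert {a.gene for a in p.supporting_alterations} == {"EREG", "AREG"}


def test_no_matching_alterations_yield_no_prediction_for_all_drugs(kb):
    empty = PatientProfile("E", "colorectal")
    preds = predict_tier1_response(empty, kb)
    assert preds and all(p.effect == "no_prediction" and p.evidence is None for p in preds)


def test_definitive_match_short_circuits_conflicting_weak_rules(kb, by_patient):
    """Injected conflicting Weak rules must never alter a Definitive call."""
    conflicting = [
        DrugRule("INJ-1", "cetuximab", 1, "colorectal",
                 parse_predicate("KRAS somatic_activating"), "benefit", "Weak"),
        DrugRule("INJ-2", "panitumumab", 1, "colorectal",
                 parse_predicate("KRAS somatic_activating"), "benefit", "Weak"),
    ]
    poisoned = dataclasses.replace(kb, drug_rules=kb.drug_rules + conflicting)
    for pid in ("P0018", "P0020", "P0031", "P0033", "P0034", "P0043", "P0046"):
        before = predict_tier1_response(by_patient[pid], kb)
        after = predict_tier1_response(by_patient[pid], poisoned)
        for drug in ("cetuximab", "panitumumab"):
            b, a = _pred(before, drug), _pred(after, drug)
            assert (a.effect, a.evidence) == (b.effect, b.evidence) == (
                "lack_of_benefit", "Definitive")


def test_conflict_at_one_level_resolves_to_negative_prediction(kb):
    """Benefit and lack-of-benefit matching at the same evidence level
    resolve to the conservative negative call."""
    rules = [
        DrugRule("C-1", "drugx", 1, "colorectal",
                 parse_predicate("KRAS somatic_activating"), "benefit", "Moderate"),
        DrugRule("C-2", "drugx", 1, "colorectal",
                 parse_predicate("TP53 somatic_inactivating"), "lack_of_benefit", "Moderate"),
    ]
    custom = dataclasses.replace(kb, drug_rules=list(kb.drug_rules) + rules)
    profile = PatientProfile(
        "X", "colorectal",
        somatic=[make_somatic(kb, "KRAS", "p.G12V", "X-T1"),
                 make_somatic(kb, "TP53", "p.R213fs", "X-T1")],
    )
    p = _pred(predict_tier1_response(profile, custom), "drugx")
    assert (p.effect, p.evidence) == ("lack_of_benefit", "Moderate")


# ---------------------------------------------------------------------------
# tier-2 recommendations
# ---------------------------------------------------------------------------


def test_ret_activation_recommends_ret_kinase_inhibitors(kb, by_patient):
    drugs = {p.drug for p in recommend_tier2(by_patient["P0036"], kb)}
    assert {"vandetanib", "cabozantinib"} <= drugs


def test_ccnd1_amplification_recommends_cdk46_inhibitors(kb, by_patient):
    drugs = {p.drug for p in recommend_tier2(by_patient["P0040"], kb)}
    assert "palbociclib" in drugs


def test_pten_loss_without_erk_lesion_recommends_mtor_axis(kb, by_patient):
    preds = recommend_tier2(by_patient["P0027"], kb)
    assert {p.drug for p in preds} == {"everolimus"}
    assert all(p.effect == "sensitivity" for p in preds)


def test_two_pathway_lesions_emit_a_combination(kb):
    profile = PatientProfile(
        "X", "colorectal",
        somatic=[make_somatic(kb, "KRAS", "p.G12V", "X-T1"),
                 make_somatic(kb, "PIK3CA", "p.E545K", "X-T1")],
    )
    preds = recommend_tier2(profile, kb)
    combos = [p for p in preds if p.is_combination]
    assert combos, "expected a combination recommendation"
    # the curated KRAS/PIK3CA feedback loop fires too
    assert any(p.drug == "trametinib + buparlisib" for p in combos)


# ---------------------------------------------------------------------------
# pathway projection
# ---------------------------------------------------------------------------


def test_wnt_pathway_multi_hit_in_p0027(kb, by_patient):
    hits = {h.pathway: h for h in project_onto_pathways(by_patient["P0027"], kb.pathways, kb)}
    assert hits["WNT"].multi_hit
    assert {g for g, _ in hits["WNT"].altered_genes} >= {"DKK1", "CSNK1A1", "AXIN1"}


def test_pi3k_pathway_multi_hit_from_multiple_suppressor_lesions(kb):
    profile = PatientProfile(
        "SCC", "other",
        somatic=[make_somatic(kb, "PIK3R1", "p.E443K", "SCC-T1"),
                 make_somatic(kb, "INPP5D", "p.S19C", "SCC-T1"),
                 make_somatic(kb, "INPPL1", "p.R346W", "SCC-T1")],
    )
    hits = {h.pathway: h for h in project_onto_pathways(profile, kb.pathways, kb)}
    assert hits["PI3K-AKT"].multi_hit
    assert {g for g, _ in hits["PI3K-AKT"].altered_genes} == {"PIK3R1", "INPP5D", "INPPL1"}


def test_no_alterations_project_onto_nothing(kb):
    assert project_onto_pathways(PatientProfile("E", "breast"), kb.pathways, kb) == []


# ---------------------------------------------------------------------------
# germline risk screen
# ---------------------------------------------------------------------------


def test_brca1_frameshift_matches_with_truncating_flag(kb, by_patient):
    panel = kb.risk_panels["breast-risk"]
    matches = germline_risk_screen(by_patient["P0013"].germline, panel)
    assert len(matches) == 1
    assert matches[0].variant.gene == "BRCA1" and matches[0].truncating


def test_dclre1c_frameshift_matches_risk_panel(kb, by_patient):
    panel = kb.risk_panels["breast-risk"]
    matches = germline_risk_screen(by_patient["P0040"].germline, panel)
    assert [m.variant.gene for m in matches] == ["DCLRE1C"]
    assert matches[0].truncating


def test_off_panel_germline_variants_are_excluded(kb, by_patient):
    panel = kb.risk_panels["breast-risk"]
    # P0025 carries KDR/CXCR2/ERCC/XRCC1 variants, none on the risk panel
    assert germline_risk_screen(by_patient["P0025"].germline, panel) == []


# ---------------------------------------------------------------------------
# trial matching
# ---------------------------------------------------------------------------


def test_ccnd1_amplified_breast_matches_cdk46_trial(kb, by_patient):
    matches = match_trials(by_patient["P0040"], kb.trials, kb)
    assert any(t.trial_id == "TRL-0001" for t, _ in matches)


def test_open_trials_rank_before_closed_matches(kb):
    profile = PatientProfile(
        "X", "colorectal",
        somatic=[make_somatic(kb, "KRAS", "p.G12V", "X-T1"),
                 make_somatic(kb, "PIK3CA", "p.E545K", "X-T1")],
    )
    matches = match_trials(profile, kb.trials, kb)
    ids = [t.trial_id for t, _ in matches]
    assert "TRL-0002" in ids and "TRL-0003" in ids
    assert ids.index("TRL-0002") < ids.index("TRL-0003")  # open before closed


def test_no_biomarker_overlap_matches_nothing(kb):
    assert match_trials(PatientProfile("E", "breast"), kb.trials, kb) == []


# ---------------------------------------------------------------------------
# actionability
# ---------------------------------------------------------------------------


def test_actionability_counts_gene_by_source_units(kb):
    profile = PatientProfile(
        "X", "colorectal",
        somatic=[make_somatic(kb, "KRAS", "p.G12V", "X-T1")],
        cna=[make_cna(kb, "CCND1", "gain")],
    )
    t1 = predict_tier1_response(profile, kb)
    t2 = recommend_tier2(profile, kb)
    report = actionability(profile, t1, t2)
    assert report.counts["somatic"] == 1 and report.counts["cna"] == 1
    assert report.total == 2 and report.has_tier1 and report.has_tier2


def test_same_gene_in_two_sources_counts_once_per_source(kb):
    profile = PatientProfile(
        "X", "MTC",
        somatic=[make_somatic(kb, "RET", "p.M918T", "X-T1")],
        expression=[ExpressionRecord("RET", 50.0, 1.0, "high")],
    )
    report = actionability(
        profile, predict_tier1_response(profile, kb), recommend_tier2(profile, kb)
    )
    assert report.counts["somatic"] == 1 and report.counts["expression"] == 1
    assert report.total == 2


def test_actionability_idempotent_under_prediction_duplication(kb, by_patient):
    profile = by_patient["P0025"]
    t1 = predict_tier1_response(profile, kb)
    t2 = recommend_tier2(profile, kb)
    once = actionability(profile, t1, t2)
    twice = actionability(profile, t1 + t1, t2 + t2)
    assert once.total == twice.total and once.counts == twice.counts


def test_no_predictions_mean_zero_actionability(kb):
    empty = PatientProfile("E", "colorectal")
    report = actionability(
        empty, predict_tier1_response(empty, kb), recommend_tier2(empty, kb)
    )
    assert report.total == 0 and not report.has_tier1 and not report.has_tier2


def test_removing_kb_rules_never_increases_actionable_counts(kb, colorectal, breast, mtc):
    pruned = dataclasses.replace(
        kb,
        drug_rules=[r for r in kb.drug_rules if not r.rule_id.startswith("CRC-OXA")],
        drug_targets=[t for t in kb.drug_targets if t.drug != "everolimus"],
    )
    for profile in colorectal + breast + mtc:
        full = actionability(
            profile, predict_tier1_response(profile, kb), recommend_tier2(profile, kb)
        )
        less = actionability(
            profile,
            predict_tier1_response(profile, pruned),
            recommend_tier2(profile, pruned),
        )
        assert less.total <= full.total
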