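"""Four-class drug-toxicity prediction and prognostic biomarker matching.

Toxicity outcomes for tier-1 drugs are one of "Severe Toxicity",
"Elevated Toxicity", "Normal" and "Less Toxicity".  When several rules for
one drug match, the most severe outcome wins (Severe > Elevated > Normal >
Less) — a clinical-safety bias; with no matching rule the prediction is
"Normal".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from oncointerp.knowledgebase import (
    KnowledgeBase,
    PrognosticBiomarker,
    ToxicityRule,
    TOXICITY_OUTCOMES,
)
from oncointerp.variant_model import Alteration, PatientProfile

#: Severity order, most severe first ("Normal" outranks "Less Toxicity").
SEVERITY_ORDER: tuple[str, ...] = TOXICITY_OUTCOMES
_SEVERITY_RANK = {o: i for i, o in enumerate(SEVERITY_ORDER)}


@dataclass(frozen=True)
class ToxicityPrediction:
    drug: str
    outcome: str
    supporting: tuple[Alteration, ...] = ()
    rule_ids: tuple[str, ...] = ()

    def __post_init__(self):
        if self.outcome not in SEVERITY_ORDER:
            raise ValueError(f"unknown toxicity outcome {self.outcome!r}")
        if (self.outcome == "Normal") != (len(self.supporting) == 0):
            raise ValueError('outcome "Normal" iff no supporting variants')


@dataclass(frozen=True)
class PrognosisFinding:
    marker: str
    direction: str  # {favorable, unfavorable}
    matched: tuple[Alteration, ...]
    note: str = ""


def predict_toxicity(
    profile: PatientProfile,
    drug: str,
    rules: Sequence[ToxicityRule],
    kb: KnowledgeBase,
) -> ToxicityPrediction:
    """Predict the toxicity class of one drug from germline/somatic markers.

    Rule order in the knowledge base is irrelevant: the most severe matching
    outcome always wins.
    """
    matches: list[tuple[ToxicityRule, list[Alteration]]] = []
    for rule in rules:
        if rule.drug != drug:
            continue
        alts = kb.evaluate_predicate(rule.predicate, profile)
        if alts:
            matches.append((rule, alts))
    if not matches:
        return ToxicityPrediction(drug=drug, outcome="Normal")
    worst = min(matches, key=lambda m: _SEVERITY_RANK[m[0].outcome])[0].outcome
    supporting: list[Alteration] = []
    rule_ids = []
    seen = set()
    for rule, alts in matches:
        if rule.outcome != worst:
            continue
        rule_ids.append(rule.rule_id)
        for a in alts:
            key = (a.gene, a.source, a.description)
            if key not in seen:
                seen.add(key)
                supporting.append(a)
    return ToxicityPrediction(
        drug=drug, outcome=worst, supporting=tuple(supporting), rule_ids=tuple(rule_ids)
    )


def match_prognosis(
    profile: PatientProfile,
    markers: Sequence[PrognosticBiomarker],
    kb: KnowledgeBase,
) -> list[PrognosisFinding]:
    """Report every prognostic biomarker matching the genomic profile.

    All matches are reported without aggregation; markers of opposite
    direction may co-occur.  Cancer types without curated markers yield an
    empty list.
    """
    findings = []
    for marker in markers:
        if marker.cancer_type != profile.cancer_type:
            continue
        alts = kb.evaluate_predicate(marker.predicate, profile)
        if alts:
            findings.append(
                PrognosisFinding(
                    marker=marker.predicate.text,
                    direction=marker.direction,
                    matched=tuple(alts),
                    note=marker.note,
                )
            )
    return findings
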