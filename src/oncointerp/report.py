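"""Assembly of per-patient genomic findings documents.

A findings document collects, per patient: cancer-relevant somatic
mutations (tiers 1-4, with gene function and pathway notes), drug response
predictions (tier-1 drugs before tier-2 recommendations, evidence
descending), toxicity predictions for tier-1 drugs, prognostic biomarker
matches, pathway projection, matched clinical trials, germline findings,
and a provenance block.  The JSON rendering is the source of truth —
byte-identical across runs on identical inputs — and the human-readable
markdown regenerates from the JSON alone.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

from oncointerp.errors import AssemblyError
from oncointerp.knowledgebase import EVIDENCE_RANK, KnowledgeBase
from oncointerp.therapy import (
    ActionabilityReport,
    GermlineRiskMatch,
    PathwayHit,
    TherapyPrediction,
    actionability,
    germline_risk_screen,
    match_trials,
    predict_tier1_response,
    project_onto_pathways,
    recommend_tier2,
)
from oncointerp.tiering import TieredMutation, cancer_relevant, tier_profile
from oncointerp.toxicity import PrognosisFinding, ToxicityPrediction, match_prognosis, predict_toxicity
from oncointerp.variant_model import Alteration, PatientProfile

NO_RESULTS_BANNER = "No clinically relevant results were found to return."

_SECTION_ORDER = (
    "somatic_mutations",
    "drug_response",
    "toxicity",
    "prognosis",
    "pathways",
    "clinical_trials",
    "germline_findings",
)


@dataclass
class PatientInterpretation:
    """All engine outputs for one patient, input to document assembly."""

    profile: PatientProfile
    tiered: list[TieredMutation]
    tier1: list[TherapyPrediction]
    tier2: list[TherapyPrediction]
    toxicity: list[ToxicityPrediction]
    prognosis: list[PrognosisFinding]
    pathways: list[PathwayHit]
    trials: list
    germline_matches: list[GermlineRiskMatch]
    actionability: ActionabilityReport
    rna_confirmed: set[tuple[str, str]] = field(default_factory=set)


def interpret_patient(
    profile: PatientProfile,
    kb: KnowledgeBase,
    rna_confirmed: set[tuple[str, str]] | None = None,
) -> PatientInterpretation:
    """Run every interpretation engine on one patient profile.

    ``rna_confirmed`` optionally lists (gene, protein_change) pairs whose
    somatic calls were also observed in tumor RNA; those mutations are
    flagged "validated" in the findings.
    """
    tiered = tier_profile(profile, kb)
    tier1 = predict_tier1_response(profile, kb)
    tier2 = recommend_tier2(profile, kb)
    tox = [
        predict_toxicity(profile, drug, kb.toxicity_rules, kb)
        for drug in sorted({p.drug for p in tier1})
    ]
    prognosis = match_prognosis(profile, kb.prognostic_biomarkers, kb)
    pathways = project_onto_pathways(profile, kb.pathways, kb)
    trials = match_trials(profile, kb.trials, kb)
    germ_matches = []
    if profile.cancer_type == "breast" and "breast-risk" in kb.risk_panels:
        germ_matches = germline_risk_screen(profile.germline, kb.risk_panels["breast-risk"])
    report = actionability(profile, tier1, tier2)
    return PatientInterpretation(
        profile=profile,
        tiered=tiered,
        tier1=tier1,
        tier2=tier2,
        toxicity=tox,
        prognosis=prognosis,
        pathways=pathways,
        trials=trials,
        germline_matches=germ_matches,
        actionability=report,
        rna_confirmed=rna_confirmed or set(),
    )


# ---------------------------------------------------------------------------
# document assembly
# ---------------------------------------------------------------------------


def _alteration_dict(alt: Alteration) -> dict:
    return {
        "gene": alt.gene,
        "source": alt.source,
        "kind": alt.kind,
        "description": alt.description,
    }


def _profile_checksum(profile: PatientProfile) -> str:
    payload = {
        "patient_id": profile.patient_id,
        "cancer_type": profile.cancer_type,
        "somatic": sorted(
            (v.chrom, v.pos, v.ref, v.alt, v.tumor_id) for v in profile.somatic
        ),
        "germline": sorted((g.chrom, g.pos, g.ref, g.alt) for g in profile.germline),
        "cna": sorted((s.chrom, s.start, s.end, s.call) for s in profile.cna),
        "expression": sorted((e.gene, e.tumor_value, e.level) for e in profile.expression),
    }
    blob = json.dumps(payload, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def generate_findings(
    profile: PatientProfile,
    interp: PatientInterpretation,
    kb: KnowledgeBase,
    seed: int | None = None,
) -> dict:
    """Assemble the structured findings document (a plain JSON-able dict).

    Ordering is deterministic: mutations by tier ascending then gene
    alphabetical; drugs tier 1 before tier 2, evidence descending then drug
    name.  An all-empty document carries an explicit no-results banner.
    """
    for section in ("tiered", "tier1", "tier2", "toxicity", "prognosis", "pathways"):
        if getattr(interp, section, None) is None:
            raise AssemblyError(f"missing engine output for section {section!r}")

    pathway_note: dict[str, list[str]] = {}
    for pw in kb.pathways:
        for g in pw.genes:
            pathway_note.setdefault(g, []).append(pw.name)

    relevant, _ = cancer_relevant(interp.tiered)
    somatic_rows = sorted(
        (
            {
                "gene": m.variant.gene,
                "protein_change": m.variant.protein_change,
                "tier": m.tier,
                "rationale": m.rationale,
                "allelic_fraction": m.variant.af,
                "tumor": m.variant.tumor_id,
                "recurrent": m.variant.recurrent,
                "gene_note": "; ".join(
                    filter(
                        None,
                        [
                            kb.gene_role(m.variant.gene)
                            if kb.known_cancer_gene(m.variant.gene)
                            else "",
                            ", ".join(sorted(pathway_note.get(m.variant.gene, []))),
                        ],
                    )
                ),
                "validated": (m.variant.gene, m.variant.protein_change)
                in interp.rna_confirmed,
            }
            for m in relevant
        ),
        key=lambda r: (r["tier"], r["gene"], r["protein_change"]),
    )

    def _prediction_rows(preds: Sequence[TherapyPrediction]) -> list[dict]:
        rows = [
            {
                "drug": p.drug,
                "drug_tier": p.drug_tier,
                "effect": p.effect,
                "evidence": p.evidence,
                "is_combination": p.is_combination,
                "supporting_alterations": [
                    _alteration_dict(a) for a in p.supporting_alterations
                ],
                "rule_ids": list(p.rule_ids),
            }
            for p in preds
        ]
        rows.sort(
            key=lambda r: (
                r["drug_tier"],
                EVIDENCE_RANK.get(r["evidence"], 99) if r["evidence"] else 99,
                r["drug"],
            )
        )
        return rows

    drug_rows = _prediction_rows(list(interp.tier1)) + _prediction_rows(list(interp.tier2))

    toxicity_rows = sorted(
        (
            {
                "drug": t.drug,
                "outcome": t.outcome,
                "supporting": [_alteration_dict(a) for a in t.supporting],
                "rule_ids": list(t.rule_ids),
            }
            for t in interp.toxicity
        ),
        key=lambda r: r["drug"],
    )

    prognosis_rows = [
        {
            "marker": f.marker,
            "direction": f.direction,
            "note": f.note,
            "matched": [_alteration_dict(a) for a in f.matched],
        }
        for f in interp.prognosis
    ]

    pathway_rows = sorted(
        (
            {
                "pathway": h.pathway,
                "altered_genes": [list(g) for g in h.altered_genes],
                "multi_hit": h.multi_hit,
            }
            for h in interp.pathways
        ),
        key=lambda r: r["pathway"],
    )

    trial_rows = [
        {
            "trial_id": trial.trial_id,
            "title": trial.title,
            "open": trial.open,
            "location": trial.location,
            "matched": [_alteration_dict(a) for a in alts],
        }
        for trial, alts in interp.trials
    ]

    germline_rows = sorted(
        (
            {
                "gene": m.variant.gene,
                "protein_change": m.variant.protein_change,
                "zygosity": m.variant.zygosity,
                "classification": m.variant.classification,
                "truncating": m.truncating,
            }
            for m in interp.germline_matches
        ),
        key=lambda r: (not r["truncating"], r["gene"]),
    )

    doc = {
        "header": {
            "patient_id": profile.patient_id,
            "cancer_type": profile.cancer_type,
            "n_cancer_relevant_mutations": len(somatic_rows),
            "n_actionable_alterations": interp.actionability.total,
        },
        "somatic_mutations": somatic_rows,
        "drug_response": drug_rows,
        "toxicity": toxicity_rows,
        "prognosis": prognosis_rows,
        "pathways": pathway_rows,
        "clinical_trials": trial_rows,
        "germline_findings": germline_rows,
        "provenance": {
            "kb_version": kb.version,
            "input_checksum": _profile_checksum(profile),
            "seed": seed,
        },
        "banner": None,
    }
    informative = (
        bool(somatic_rows)
        or any(r["effect"] != "no_prediction" for r in drug_rows)
        or bool(prognosis_rows or pathway_rows or trial_rows or germline_rows)
        or any(t["outcome"] != "Normal" for t in toxicity_rows)
    )
    if not informative:
        doc["banner"] = NO_RESULTS_BANNER
    return doc


def findings_json(doc: Mapping) -> str:
    """Canonical JSON rendering (sorted keys; the document of record)."""
    return json.dumps(doc, sort_keys=True, indent=2) + "\n"


def validate_findings(doc: Mapping) -> None:
    """Validate a document against the shipped JSON schema (structure and
    primitive types of the required members)."""
    schema = json.loads(
        resources.files("oncointerp").joinpath("data/findings.schema.json").read_text()
    )
    _validate_node(doc, schema, "$")


_TYPE_MAP = {
    "object": dict,
    "array": list,
    "string": str,
    "integer": int,
    "null": type(None),
}


def _validate_node(node, schema: Mapping, path: str) -> None:
    allowed = schema.get("type")
    if allowed is not None:
        types = [allowed] if isinstance(allowed, str) else list(allowed)
        if not any(isinstance(node, _TYPE_MAP[t]) for t in types):
            raise AssemblyError(f"{path}: expected {types}, got {type(node).__name__}")
    for key in schema.get("required", []):
        if not isinstance(node, dict) or key not in node:
            raise AssemblyError(f"{path}: missing required member {key!r}")
    for key, sub in schema.get("properties", {}).items():
        if isinstance(node, dict) and key in node:
            _validate_node(node[key], sub, f"{path}.{key}")


# ---------------------------------------------------------------------------
# markdown rendering (from JSON alone)
# ---------------------------------------------------------------------------


def findings_markdown(doc: Mapping) -> str:
    """Render the human-readable document from the JSON dict alone."""
    h = doc["header"]
    lines = [
        f"# Genomic findings — {h['patient_id']}",
        "",
        f"Cancer type: **{h['cancer_type']}**  ",
        f"Cancer-relevant somatic mutations (tiers 1–4): {h['n_cancer_relevant_mutations']}  ",
        f"Actionable alterations: {h['n_actionable_alterations']}",
        "",
    ]
    if doc.get("banner"):
        lines += [f"> {doc['banner']}", ""]

    lines += ["## Somatic mutations (tiers 1–4)", ""]
    if doc["somatic_mutations"]:
        lines += ["| Gene | Protein change | Tier | Note | Validated |", "|---|---|---|---|---|"]
        for m in doc["somatic_mutations"]:
            lines.append(
                f"| {m['gene']} | {m['protein_change'] or '-'} | {m['tier']} "
                f"| {m['gene_note'] or '-'} | {'yes' if m['validated'] else ''} |"
            )
    else:
        lines.append("None.")
    lines.append("")

    lines += ["## Drug response", ""]
    if doc["drug_response"]:
        lines += ["| Drug | Tier | Effect | Evidence | Basis |", "|---|---|---|---|---|"]
        for r in doc["drug_response"]:
            basis = ", ".join(
                f"{a['gene']} {a['description']}".strip() for a in r["supporting_alterations"]
            )
            effect = r["effect"].replace("_", " ")
            if r["effect"] == "no_prediction":
                effect = "no biomarker-based prediction"
            lines.append(
                f"| {r['drug']} | {r['drug_tier']} | {effect} | {r['evidence'] or '-'} "
                f"| {basis or '-'} |"
            )
    else:
        lines.append("None.")
    lines.append("")

    lines += ["## Toxicity", ""]
    for t in doc["toxicity"]:
        basis = ", ".join(f"{a['gene']} {a['description']}".strip() for a in t["supporting"])
        lines.append(f"- {t['drug']}: **{t['outcome']}**" + (f" ({basis})" if basis else ""))
    if not doc["toxicity"]:
        lines.append("None.")
    lines.append("")

    lines += ["## Prognosis", ""]
    for p in doc["prognosis"]:
        lines.append(f"- {p['direction']}: {p['note'] or p['marker']}")
    if not doc["prognosis"]:
        lines.append("None.")
    lines.append("")

    lines += ["## Pathways", ""]
    for p in doc["pathways"]:
        genes = ", ".join(f"{g}({k})" for g, k in p["altered_genes"])
        flag = " — multiple lesions" if p["multi_hit"] else ""
        lines.append(f"- {p['pathway']}: {genes}{flag}")
    if not doc["pathways"]:
        lines.append("None.")
    lines.append("")

    lines += ["## Clinical trials", ""]
    for t in doc["clinical_trials"]:
        status = "open" if t["open"] else "closed"
        lines.append(f"- {t['trial_id']} ({status}, {t['location']}): {t['title']}")
    if not doc["clinical_trials"]:
        lines.append("None.")
    lines.append("")

    lines += ["## Germline findings", ""]
    for g in doc["germline_findings"]:
        flag = " **[truncating]**" if g["truncating"] else ""
        lines.append(
            f"- {g['gene']} {g['protein_change']} ({g['zygosity']}, "
            f"{g['classification'] or 'unclassified'}){flag}"
        )
    if not doc["germline_findings"]:
        lines.append("None.")
    lines.append("")

    prov = doc["provenance"]
    lines += [
        "---",
        f"KB version {prov['kb_version']}; input checksum {prov['input_checksum']}; "
        f"seed {prov['seed']}",
        "",
    ]
    return "\n".join(lines)
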