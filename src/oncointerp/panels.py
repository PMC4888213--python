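"""In-silico comparison of the integrative profile against targeted panels.

A panel definition restricts what a profile would have shown: hotspot panels
keep somatic SNV/indels falling inside hotspot intervals, full-gene panels
keep somatic variants on panel genes, and full-gene-plus-CNA panels
additionally keep copy-number events on panel genes.  Germline variants
survive only on panels that sequence normal DNA and expression events only
on assays that measure RNA (no DNA panel does).  Tiering and the therapy
engine are then re-run on the restricted profile with the same knowledge
base, so detection breadth is the only compared variable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from oncointerp.errors import DomainError
from oncointerp.knowledgebase import KnowledgeBase, PanelDefinition
from oncointerp.therapy import (
    ActionabilityReport,
    actionability,
    predict_tier1_response,
    recommend_tier2,
)
from oncointerp.tiering import cancer_relevant, tier_profile
from oncointerp.variant_model import PatientProfile

INTEGRATIVE = "integrative"


def panel_filter(profile: PatientProfile, panel: PanelDefinition, kb: KnowledgeBase) -> PatientProfile:
    """Restrict a patient profile to what one panel would have detected."""
    if panel.mode == "hotspot":
        somatic = [v for v in profile.somatic if panel.covers_position(v.chrom, v.pos)]
    else:
        somatic = [v for v in profile.somatic if v.gene in panel.genes]

    cna = []
    if panel.mode == "full_gene_plus_cna":
        panel_loci = [kb.gene_loci[g] for g in panel.genes if g in kb.gene_loci]
        cna = [
            seg
            for seg in profile.cna
            if any(seg.overlaps(l.chrom, l.start, l.end) for l in panel_loci)
        ]

    germline = list(profile.germline) if panel.detects_germline else []
    expression = list(profile.expression) if panel.detects_expression else []

    return PatientProfile(
        patient_id=profile.patient_id,
        cancer_type=profile.cancer_type,
        somatic=somatic,
        germline=germline,
        cna=cna,
        expression=expression,
        specimen_meta=dict(profile.specimen_meta),
    )


@dataclass(frozen=True)
class PanelResult:
    patient_id: str
    panel: str
    n_cancer_relevant: int
    actionability: ActionabilityReport

    @property
    def n_actionable(self) -> int:
        return self.actionability.total

    @property
    def has_tier1(self) -> bool:
        return self.actionability.has_tier1

    @property
    def has_tier2(self) -> bool:
        return self.actionability.has_tier2


def evaluate_profile(
    profile: PatientProfile, kb: KnowledgeBase, panel_name: str = INTEGRATIVE
) -> PanelResult:
    """Run tiering + therapy on a (possibly panel-restricted) profile."""
    tiered = tier_profile(profile, kb)
    _, n_relevant = cancer_relevant(tiered)
    t1 = predict_tier1_response(profile, kb)
    t2 = recommend_tier2(profile, kb)
    report = actionability(profile, t1, t2)
    return PanelResult(
        patient_id=profile.patient_id,
        panel=panel_name,
        n_cancer_relevant=n_relevant,
        actionability=report,
    )


@dataclass(frozen=True)
class ApproachStats:
    approach: str
    mean_cancer_relevant: float
    range_cancer_relevant: tuple[int, int]
    n_patients_tier1: int
    n_patients_tier2: int
    n_patients_actionable: int
    mean_actionable: float
    range_actionable: tuple[int, int]


@dataclass
class CohortSummary:
    n_patients: int
    approaches: dict[str, ApproachStats] = field(default_factory=dict)
    #: integrative mean / panel mean; None when the panel mean is zero.
    fold_change_cancer_relevant: dict[str, float | None] = field(default_factory=dict)
    fold_change_actionable: dict[str, float | None] = field(default_factory=dict)


def _aggregate(approach: str, results: list[PanelResult]) -> ApproachStats:
    relevant = [r.n_cancer_relevant for r in results]
    actionable = [r.n_actionable for r in results]
    return ApproachStats(
        approach=approach,
        mean_cancer_relevant=sum(relevant) / len(relevant),
        range_cancer_relevant=(min(relevant), max(relevant)),
        n_patients_tier1=sum(r.has_tier1 for r in results),
        n_patients_tier2=sum(r.has_tier2 for r in results),
        n_patients_actionable=sum(r.n_actionable > 0 for r in results),
        mean_actionable=sum(actionable) / len(actionable),
        range_actionable=(min(actionable), max(actionable)),
    )


def summarize_cohort(
    profiles: list[PatientProfile],
    panels: dict[str, PanelDefinition],
    kb: KnowledgeBase,
) -> CohortSummary:
    """Cohort comparison of the integrative approach against each panel.

    The full pipeline runs per patient on the complete profile and again on
    each panel-restricted profile; per-approach means, ranges and patient
    counts are aggregated, and fold changes (integrative mean / panel mean)
    computed, reported as undefined (None) where a panel mean is zero.
    """
    if not profiles:
        raise DomainError("cohort is empty")
    summary = CohortSummary(n_patients=len(profiles))
    per_approach: dict[str, list[PanelResult]] = {INTEGRATIVE: []}
    for name in panels:
        per_approach[name] = []
    for profile in profiles:
        per_approach[INTEGRATIVE].append(evaluate_profile(profile, kb))
        for name, panel in panels.items():
            restricted = panel_filter(profile, panel, kb)
            per_approach[name].append(evaluate_profile(restricted, kb, name))
    for name, results in per_approach.items():
        summary.approaches[name] = _aggregate(name, results)
    integ = summary.approaches[INTEGRATIVE]
    for name in panels:
        panel_stats = summary.approaches[name]
        summary.fold_change_cancer_relevant[name] = (
            integ.mean_cancer_relevant / panel_stats.mean_cancer_relevant
            if panel_stats.mean_cancer_relevant > 0
            else None
        )
        summary.fold_change_actionable[name] = (
            integ.mean_actionable / panel_stats.mean_actionable
            if panel_stats.mean_actionable > 0
            else None
        )
    return summary


def cohort_summary_table(summary: CohortSummary) -> pd.DataFrame:
    """Render the cohort summary as one row per approach."""
    rows = []
    for name, st in summary.approaches.items():
        rows.append(
            {
                "approach": name,
                "mean_cancer_relevant (range)": (
                    f"{st.mean_cancer_relevant:.1f} "
                    f"({st.range_cancer_relevant[0]}-{st.range_cancer_relevant[1]})"
                ),
                "n_patients_tier1": st.n_patients_tier1,
                "n_patients_tier2": st.n_patients_tier2,
                "n_patients_actionable": st.n_patients_actionable,
                "mean_actionable (range)": (
                    f"{st.mean_actionable:.2f} "
                    f"({st.range_actionable[0]}-{st.range_actionable[1]})"
                ),
                "fold_change_cancer_relevant": summary.fold_change_cancer_relevant.get(name),
                "fold_change_actionable": summary.fold_change_actionable.get(name),
            }
        )
    return pd.DataFrame(rows)


def alteration_frequency(
    profiles: list[PatientProfile], genes: list[str], kb: KnowledgeBase
) -> dict[str, float]:
    """Fraction of patients with any alteration (somatic, CNA or germline)
    of each listed gene — the per-gene frequency row of a cohort table."""
    if not profiles:
        raise DomainError("cohort is empty")
    genes = [g.upper() for g in genes]
    counts = {g: 0 for g in genes}
    for profile in profiles:
        altered = {v.gene for v in profile.somatic}
        altered |= {g.gene for g in profile.germline}
        altered |= set(kb.cna_gene_events(profile))
        for g in genes:
            if g in altered:
                counts[g] += 1
    return {g: counts[g] / len(profiles) for g in genes}
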