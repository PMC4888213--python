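"""Five-tier cancer-relevance classification of somatic mutations.

Tier 1: the gene is curated for the patient's specific cancer type.
Tier 2: the gene is a pan-cancer gene (involved in multiple cancer types)
        but not tier 1.
Tier 3: the gene is curated for some other cancer type, excluding tiers 1-2.
Tier 4: the exact (gene, protein change) pair was previously observed in a
        tumor catalog, but the gene is not known to be cancer-associated.
Tier 5: everything else.

Tiers 1-4 are "cancer-relevant".  The five tiers partition any input: rules
are evaluated strictly in order and the first match wins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from oncointerp.knowledgebase import KnowledgeBase, OTHER_CANCER, PAN_CANCER
from oncointerp.variant_model import PatientProfile, SomaticVariant

RATIONALES = (
    "cancer-type gene",
    "pan-cancer gene",
    "other-cancer gene",
    "catalog match",
    "none",
)


@dataclass(frozen=True)
class TieredMutation:
    variant: SomaticVariant
    tier: int
    rationale: str

    def __post_init__(self):
        if self.tier not in (1, 2, 3, 4, 5):
            raise ValueError(f"tier must be 1-5, got {self.tier}")
        if self.rationale not in RATIONALES:
            raise ValueError(f"unknown rationale {self.rationale!r}")


def assign_tier(
    variant: SomaticVariant, cancer_type: str, kb: KnowledgeBase
) -> TieredMutation:
    """Assign a somatic variant to tiers 1-5 (first matching rule wins).

    An unknown ``cancer_type`` (no curated gene list) makes tier 1
    unreachable; evaluation falls back to the pan-/other-cancer rules with
    a warning.
    """
    known_types = {
        a.cancer_type
        for a in kb.associations
        if a.cancer_type not in (PAN_CANCER, OTHER_CANCER)
    }
    if cancer_type not in known_types:
        warnings.warn(
            f"cancer type {cancer_type!r} has no curated gene list; "
            "tier 1 is unreachable for this patient",
            stacklevel=2,
        )
    gene_types = kb.gene_cancer_types(variant.gene)
    if cancer_type in gene_types:
        return TieredMutation(variant, 1, "cancer-type gene")
    if PAN_CANCER in gene_types:
        return TieredMutation(variant, 2, "pan-cancer gene")
    if gene_types:  # associated with some other cancer (or "other-cancer")
        return TieredMutation(variant, 3, "other-cancer gene")
    if variant.protein_change and (variant.gene, variant.protein_change) in kb.catalog:
        return TieredMutation(variant, 4, "catalog match")
    return TieredMutation(variant, 5, "none")


def tier_profile(profile: PatientProfile, kb: KnowledgeBase) -> list[TieredMutation]:
    """Tier every somatic mutation of a patient, preserving input order."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return [assign_tier(v, profile.cancer_type, kb) for v in profile.somatic]


def cancer_relevant(
    mutations: Sequence[TieredMutation],
) -> tuple[list[TieredMutation], int]:
    """Order-preserving filter to tiers 1-4 plus the resulting count."""
    kept = [m for m in mutations if m.tier <= 4]
    return kept, len(kept)


def write_tiered_tsv(
    path: str | Path, patient_id: str, mutations: Iterable[TieredMutation], kb: KnowledgeBase
) -> None:
    """Export tiered mutations (patient, gene, protein change, tier, note)."""
    pathways_by_gene: dict[str, list[str]] = {}
    for pw in kb.pathways:
        for g in pw.genes:
            pathways_by_gene.setdefault(g, []).append(pw.name)
    rows = [
        {
            "patient": patient_id,
            "gene": m.variant.gene,
            "protein_change": m.variant.protein_change,
            "tier": m.tier,
            "gene_note": "; ".join(
                filter(
                    None,
                    [
                        kb.gene_role(m.variant.gene) if kb.known_cancer_gene(m.variant.gene) else "",
                        ",".join(pathways_by_gene.get(m.variant.gene, [])),
                    ],
                )
            ),
        }
        for m in mutations
    ]
    pd.DataFrame(rows, columns=["patient", "gene", "protein_change", "tier", "gene_note"]).to_csv(
        path, sep="\t", index=False
    )
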