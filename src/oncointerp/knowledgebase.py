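"""Curated reference tables and the biomarker predicate grammar.

A :class:`KnowledgeBase` bundles gene-cancer tier lists, drug rules, toxicity
rules, prognostic markers, pathway gene sets, panel definitions, clinical
trial records, risk-gene panels, a catalog of previously observed
(gene, protein change) pairs, a curated activating/inactivating mutation
list, a drug-target table and synthetic gene loci.

Biomarker conditions are written in a small declarative grammar serialized
as text in the tables::

    KRAS somatic_activating
    BRAF specific_protein_change p.V600E
    EREG expression_high AND AREG expression_high
    RET somatic_activating OR RET germline_variant

Matching is conjunctive within an alternative (``AND``) and disjunctive
across alternatives (``OR``).  Evaluating a predicate against a
:class:`~oncointerp.variant_model.PatientProfile` yields the concrete
:class:`~oncointerp.variant_model.Alteration` records satisfying it.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path

from oncointerp.errors import ConfigurationError, KnowledgeBaseError, PredicateError
from oncointerp.variant_model import (
    Alteration,
    GermlineVariant,
    PatientProfile,
    SomaticVariant,
    TRUNCATING,
    codon_of,
    normalize_protein_change,
)

# ---------------------------------------------------------------------------
# vocabularies
# ---------------------------------------------------------------------------

#: Drug-response evidence hierarchy, strongest first.
EVIDENCE_LEVELS: tuple[str, ...] = ("Definitive", "Strong", "Moderate", "Weak")

EVIDENCE_RANK = {lvl: i for i, lvl in enumerate(EVIDENCE_LEVELS)}

ALTERATION_CLASSES = frozenset(
    {
        "somatic_activating",
        "somatic_inactivating",
        "specific_protein_change",
        "cna_gain",
        "cna_loss",
        "germline_variant",
        "expression_high",
        "expression_low",
    }
)

EFFECTS = frozenset({"benefit", "lack_of_benefit", "resistance", "sensitivity"})

TOXICITY_OUTCOMES: tuple[str, ...] = (
    "Severe Toxicity",
    "Elevated Toxicity",
    "Normal",
    "Less Toxicity",
)

PAN_CANCER = "pan-cancer"
OTHER_CANCER = "other-cancer"

KB_HEADER_PREFIX = "#oncointerp-kb"


# ---------------------------------------------------------------------------
# predicate grammar
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Term:
    gene: str
    aclass: str
    detail: str = ""  # exact protein change for specific_protein_change / germline


@dataclass(frozen=True)
class Predicate:
    """Disjunction of conjunctions of terms."""

    alternatives: tuple[tuple[Term, ...], ...]
    text: str = ""

    def genes(self) -> set[str]:
        return {t.gene for alt in self.alternatives for t in alt}


def parse_predicate(text: str) -> Predicate:
    """Parse a predicate string into its alternative/term structure."""
    text = text.strip()
    if not text:
        raise PredicateError("empty predicate")
    alternatives = []
    for alt_text in text.split(" OR "):
        terms = []
        for term_text in alt_text.split(" AND "):
            parts = term_text.split()
            if len(parts) < 2:
                raise PredicateError(f"cannot parse term {term_text!r} in {text!r}")
            gene, aclass = parts[0].upper(), parts[1]
            if aclass not in ALTERATION_CLASSES:
                raise PredicateError(
                    f"unsupported alteration class {aclass!r} in predicate {text!r}"
                )
            detail = normalize_protein_change(parts[2]) if len(parts) > 2 else ""
            if aclass == "specific_protein_change" and not detail:
                raise PredicateError(f"specific_protein_change needs a p. change: {text!r}")
            terms.append(Term(gene=gene, aclass=aclass, detail=detail))
        alternatives.append(tuple(terms))
    return Predicate(alternatives=tuple(alternatives), text=text)


# ---------------------------------------------------------------------------
# table record types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneCancerAssociation:
    gene: str
    cancer_type: str  # a specific type, "pan-cancer", or "other-cancer"
    role: str  # {oncogene, tumor_suppressor, other}


@dataclass(frozen=True)
class DrugRule:
    rule_id: str
    drug: str
    drug_tier: int  # 1 = FDA-approved for the tumor type, 2 = all other therapies
    cancer_type: str
    predicate: Predicate
    effect: str
    evidence: str


@dataclass(frozen=True)
class ToxicityRule:
    rule_id: str
    drug: str
    predicate: Predicate
    outcome: str


@dataclass(frozen=True)
class PrognosticBiomarker:
    cancer_type: str
    predicate: Predicate
    direction: str  # {favorable, unfavorable}
    note: str = ""


@dataclass(frozen=True)
class PanelDefinition:
    name: str
    mode: str  # {hotspot, full_gene, full_gene_plus_cna}
    genes: frozenset[str]
    hotspots: tuple[tuple[str, int, int], ...] = ()  # genomic (chrom, start, end)
    detects_germline: bool = False
    detects_expression: bool = False

    def __post_init__(self):
        if self.mode not in ("hotspot", "full_gene", "full_gene_plus_cna"):
            raise KnowledgeBaseError(f"panel {self.name}: unknown mode {self.mode!r}")
        if self.mode == "hotspot" and not self.hotspots:
            raise KnowledgeBaseError(f"hotspot panel {self.name} has no intervals")
        if self.detects_expression:
            raise KnowledgeBaseError(
                f"panel {self.name}: DNA panels cannot detect expression events"
            )

    def covers_position(self, chrom: str, pos: int) -> bool:
        return any(c == chrom and s <= pos <= e for c, s, e in self.hotspots)


@dataclass(frozen=True)
class PathwayGeneSet:
    name: str
    genes: frozenset[str]


@dataclass(frozen=True)
class TrialRecord:
    trial_id: str
    title: str
    predicate: Predicate
    cancer_types: frozenset[str]  # empty set = type-agnostic
    open: bool = True
    location: str = ""


@dataclass(frozen=True)
class RiskGenePanel:
    name: str
    genes: frozenset[str]


@dataclass(frozen=True)
class DrugTarget:
    """A drug -> target-gene link used for tier-2 recommendations.

    ``trigger`` states which alteration of the target gene recommends the
    drug: ``activation`` (activating mutation, copy gain or overexpression of
    an oncogenic node), ``loss`` (inactivating mutation or copy loss of a
    suppressor whose loss activates the drugged axis) or ``germline``
    (a germline variant in the gene).
    """

    drug: str
    gene: str
    trigger: str  # {activation, loss, germline}
    pathway: str
    evidence: str
    note: str = ""


@dataclass(frozen=True)
class FeedbackLoop:
    gene_a: str
    gene_b: str
    combo: str  # e.g. "trametinib + buparlisib"
    note: str = ""


@dataclass(frozen=True)
class GeneLocus:
    gene: str
    chrom: str
    start: int  # 1-based
    end: int  # 1-based inclusive


# ---------------------------------------------------------------------------
# the bundle
# ---------------------------------------------------------------------------


@dataclass
class KnowledgeBase:
    version: str
    associations: list[GeneCancerAssociation]
    catalog: frozenset[tuple[str, str]]  # (gene, protein_change) previously observed
    activating: dict[str, frozenset[str]]  # gene -> curated activating changes
    inactivating: dict[str, frozenset[str]]
    drug_rules: list[DrugRule]
    toxicity_rules: list[ToxicityRule]
    prognostic_biomarkers: list[PrognosticBiomarker]
    panels: dict[str, PanelDefinition]
    pathways: list[PathwayGeneSet]
    trials: list[TrialRecord]
    risk_panels: dict[str, RiskGenePanel]
    drug_targets: list[DrugTarget]
    feedback_loops: list[FeedbackLoop]
    gene_loci: dict[str, GeneLocus]
    _assoc_by_gene: dict[str, list[GeneCancerAssociation]] = field(default_factory=dict)

    def __post_init__(self):
        self._assoc_by_gene = {}
        for a in self.associations:
            self._assoc_by_gene.setdefault(a.gene, []).append(a)

    # -- association lookups ------------------------------------------------

    def gene_cancer_types(self, gene: str) -> set[str]:
        return {a.cancer_type for a in self._assoc_by_gene.get(gene.upper(), [])}

    def gene_role(self, gene: str) -> str:
        assocs = self._assoc_by_gene.get(gene.upper(), [])
        return assocs[0].role if assocs else "other"

    def known_cancer_gene(self, gene: str) -> bool:
        return bool(self._assoc_by_gene.get(gene.upper()))

    def locus(self, gene: str) -> GeneLocus | None:
        return self.gene_loci.get(gene.upper())

    # -- variant effect resolution ------------------------------------------

    def variant_effect(self, variant: SomaticVariant) -> str:
        """Resolve a somatic variant to activating / inactivating / unknown.

        The curated per-gene list wins; otherwise a fallback applies:
        a missense change at a previously catalogued hotspot of an oncogene
        is called activating, and a truncating change (nonsense, frameshift,
        splice site) in a tumor suppressor is called inactivating.
        """
        gene, p = variant.gene, variant.protein_change
        if p and p in self.activating.get(gene, frozenset()):
            return "activating"
        if p and p in self.inactivating.get(gene, frozenset()):
            return "inactivating"
        role = self.gene_role(gene)
        if (
            role == "oncogene"
            and variant.consequence == "missense"
            and (gene, p) in self.catalog
        ):
            return "activating"
        if role == "tumor_suppressor" and variant.consequence in TRUNCATING:
            return "inactivating"
        return "unknown"

    # -- CNA gene events ----------------------------------------------------

    def cna_gene_events(self, profile: PatientProfile) -> dict[str, str]:
        """Map genes to gain/loss calls from segments overlapping their loci."""
        events: dict[str, str] = {}
        for seg in profile.cna:
            if seg.call not in ("gain", "loss"):
                continue
            for locus in self.gene_loci.values():
                if seg.overlaps(locus.chrom, locus.start, locus.end):
                    events.setdefault(locus.gene, seg.call)
        return events

    # -- predicate evaluation ------------------------------------------------

    def evaluate_predicate(
        self, predicate: Predicate | str, profile: PatientProfile
    ) -> list[Alteration]:
        """Return the concrete alterations satisfying a biomarker predicate.

        Within one alternative every term must match (the alterations of all
        terms are returned); across alternatives a union is taken.  An empty
        list means no match.
        """
        if isinstance(predicate, str):
            predicate = parse_predicate(predicate)
        matched: list[Alteration] = []
        seen: set[tuple[str, str, str, str]] = set()
        for alternative in predicate.alternatives:
            per_term = [self._match_term(term, profile) for term in alternative]
            if all(per_term):
                for hits in per_term:
                    for alt in hits:
                        key = (alt.gene, alt.source, alt.kind, alt.description)
                        if key not in seen:
                            seen.add(key)
                            matched.append(alt)
        return matched

    def _match_term(self, term: Term, profile: PatientProfile) -> list[Alteration]:
        gene, aclass = term.gene, term.aclass
        hits: list[Alteration] = []
        if aclass in ("somatic_activating", "somatic_inactivating"):
            want = "inactivating" if aclass == "somatic_inactivating" else "activating"
            for v in profile.somatic:
                if v.gene == gene and self.variant_effect(v) == want:
                    hits.append(
                        Alteration(gene, "somatic", aclass, v.protein_change or f"{v.chrom}:{v.pos}", v)
                    )
        elif aclass == "specific_protein_change":
            for v in profile.somatic:
                if v.gene == gene and v.protein_change == term.detail:
                    hits.append(Alteration(gene, "somatic", aclass, v.protein_change, v))
        elif aclass in ("cna_gain", "cna_loss"):
            locus = self.locus(gene)
            if locus is None:
                return []
            want = "gain" if aclass == "cna_gain" else "loss"
            for seg in profile.cna:
                if seg.call == want and seg.overlaps(locus.chrom, locus.start, locus.end):
                    hits.append(Alteration(gene, "cna", aclass, f"{want} {seg.chrom}:{seg.start}-{seg.end}", seg))
        elif aclass == "germline_variant":
            for g in profile.germline:
                if g.gene == gene and (not term.detail or g.protein_change == term.detail):
                    hits.append(Alteration(gene, "germline", aclass, g.protein_change, g))
        elif aclass in ("expression_high", "expression_low"):
            want = "high" if aclass == "expression_high" else "low"
            for e in profile.expression:
                if e.gene == gene and e.level == want:
                    fc = e.fold_change
                    desc = f"{want}" + (f" ({fc:.1f}-fold)" if fc is not None else "")
                    hits.append(Alteration(gene, "expression", aclass, desc, e))
        else:  # pragma: no cover - parse_predicate already rejects these
            raise ConfigurationError(f"unsupported alteration class {aclass!r}")
        return hits


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

_MANDATORY_TABLES = (
    "associations.tsv",
    "catalog.tsv",
    "activating.tsv",
    "drug_rules.tsv",
    "toxicity_rules.tsv",
    "prognostic.tsv",
    "panels.tsv",
    "pathways.tsv",
    "trials.tsv",
    "risk_panels.tsv",
    "drug_targets.tsv",
    "feedback_loops.tsv",
    "gene_loci.tsv",
)


def _read_table(path: Path) -> tuple[str, list[dict[str, str]]]:
    """Read a KB TSV with a versioned ``#oncointerp-kb v<N>`` header line."""
    with open(path, newline="") as fh:
        first = fh.readline().strip()
        if not first.startswith(KB_HEADER_PREFIX):
            raise KnowledgeBaseError(f"{path.name}: missing versioned header line")
        version = first.removeprefix(KB_HEADER_PREFIX).strip()
        rows = [
            {k: (v or "").strip() for k, v in row.items()}
            for row in csv.DictReader(fh, delimiter="\t")
        ]
    return version, rows


def load_kb(directory: str | Path) -> KnowledgeBase:
    """Load and cross-validate all knowledge-base tables from a directory.

    Missing mandatory tables raise :class:`KnowledgeBaseError` naming the
    table; malformed predicates raise :class:`PredicateError` naming the
    rule.  Drug-rule genes absent from both the association table and every
    pathway emit a warning.  Ordering is deterministic (file order).
    """
    directory = Path(directory)
    for name in _MANDATORY_TABLES:
        if not (directory / name).exists():
            raise KnowledgeBaseError(f"knowledge base at {directory} lacks table {name}")

    version, assoc_rows = _read_table(directory / "associations.tsv")
    associations = [
        GeneCancerAssociation(r["gene"].upper(), r["cancer_type"], r["role"])
        for r in assoc_rows
    ]
    pairs = [(a.gene, a.cancer_type) for a in associations]
    if len(pairs) != len(set(pairs)):
        raise KnowledgeBaseError("associations.tsv: duplicate (gene, cancer_type) pairs")

    _, cat_rows = _read_table(directory / "catalog.tsv")
    catalog = frozenset(
        (r["gene"].upper(), normalize_protein_change(r["protein_change"])) for r in cat_rows
    )

    _, act_rows = _read_table(directory / "activating.tsv")
    activating: dict[str, set[str]] = {}
    inactivating: dict[str, set[str]] = {}
    for r in act_rows:
        target = activating if r["effect"] == "activating" else inactivating
        if r["effect"] not in ("activating", "inactivating"):
            raise KnowledgeBaseError(f"activating.tsv: unknown effect {r['effect']!r}")
        target.setdefault(r["gene"].upper(), set()).add(
            normalize_protein_change(r["protein_change"])
        )

    def _rule_predicate(text: str, rule_id: str) -> Predicate:
        try:
            return parse_predicate(text)
        except PredicateError as exc:
            raise PredicateError(f"rule {rule_id}: {exc}") from exc

    _, dr_rows = _read_table(directory / "drug_rules.tsv")
    drug_rules = []
    for r in dr_rows:
        if r["evidence"] not in EVIDENCE_LEVELS:
            raise KnowledgeBaseError(
                f"drug_rules.tsv rule {r['rule_id']}: unknown evidence level {r['evidence']!r}"
            )
        if r["effect"] not in EFFECTS:
            raise KnowledgeBaseError(
                f"drug_rules.tsv rule {r['rule_id']}: unknown effect {r['effect']!r}"
            )
        drug_rules.append(
            DrugRule(
                rule_id=r["rule_id"],
                drug=r["drug"],
                drug_tier=int(r["drug_tier"]),
                cancer_type=r["cancer_type"],
                predicate=_rule_predicate(r["predicate"], r["rule_id"]),
                effect=r["effect"],
                evidence=r["evidence"],
            )
        )

    _, tox_rows = _read_table(directory / "toxicity_rules.tsv")
    toxicity_rules = []
    for r in tox_rows:
        if r["outcome"] not in TOXICITY_OUTCOMES:
            raise KnowledgeBaseError(
                f"toxicity_rules.tsv rule {r['rule_id']}: unknown outcome {r['outcome']!r}"
            )
        toxicity_rules.append(
            ToxicityRule(
                rule_id=r["rule_id"],
                drug=r["drug"],
                predicate=_rule_predicate(r["predicate"], r["rule_id"]),
                outcome=r["outcome"],
            )
        )

    _, prg_rows = _read_table(directory / "prognostic.tsv")
    prognostic = [
        PrognosticBiomarker(
            cancer_type=r["cancer_type"],
            predicate=_rule_predicate(r["predicate"], r.get("marker_id", r["cancer_type"])),
            direction=r["direction"],
            note=r.get("note", ""),
        )
        for r in prg_rows
    ]

    _, loci_rows = _read_table(directory / "gene_loci.tsv")
    gene_loci: dict[str, GeneLocus] = {}
    for r in loci_rows:
        gene = r["gene"].upper()
        start = int(r["start"])
        end = start + 3 * int(r["aa_length"]) - 1
        gene_loci[gene] = GeneLocus(gene, r["chrom"], start, end)

    def _codon_interval(gene: str, c1: int, c2: int) -> tuple[str, int, int]:
        locus = gene_loci[gene]
        return (locus.chrom, locus.start + 3 * (c1 - 1), locus.start + 3 * c2 - 1)

    _, pan_rows = _read_table(directory / "panels.tsv")
    panels: dict[str, PanelDefinition] = {}
    for r in pan_rows:
        hotspots: list[tuple[str, int, int]] = []
        if r.get("hotspots"):
            for chunk in r["hotspots"].split(";"):
                gene, rng = chunk.split(":")
                c1, c2 = rng.split("-")
                hotspots.append(_codon_interval(gene.upper(), int(c1), int(c2)))
        panels[r["name"]] = PanelDefinition(
            name=r["name"],
            mode=r["mode"],
            genes=frozenset(g.strip().upper() for g in r["genes"].split(",") if g.strip()),
            hotspots=tuple(hotspots),
            detects_germline=r["detects_germline"].lower() == "true",
            detects_expression=r["detects_expression"].lower() == "true",
        )

    _, pw_rows = _read_table(directory / "pathways.tsv")
    pathways = [
        PathwayGeneSet(
            name=r["pathway"],
            genes=frozenset(g.strip().upper() for g in r["genes"].split(",") if g.strip()),
        )
        for r in pw_rows
    ]

    _, trial_rows = _read_table(directory / "trials.tsv")
    trials = []
    for r in trial_rows:
        types = frozenset(
            t.strip() for t in r["cancer_types"].split(",") if t.strip() and t.strip() != "any"
        )
        trials.append(
            TrialRecord(
                trial_id=r["trial_id"],
                title=r["title"],
                predicate=_rule_predicate(r["predicate"], r["trial_id"]),
                cancer_types=types,
                open=r["open"].lower() == "true",
                location=r.get("location", ""),
            )
        )

    _, rp_rows = _read_table(directory / "risk_panels.tsv")
    risk_panels = {
        r["name"]: RiskGenePanel(
            name=r["name"],
            genes=frozenset(g.strip().upper() for g in r["genes"].split(",") if g.strip()),
        )
        for r in rp_rows
    }

    _, dt_rows = _read_table(directory / "drug_targets.tsv")
    drug_targets = []
    for r in dt_rows:
        if r["trigger"] not in ("activation", "loss", "germline"):
            raise KnowledgeBaseError(
                f"drug_targets.tsv: unknown trigger {r['trigger']!r} for {r['drug']}"
            )
        if r["evidence"] not in EVIDENCE_LEVELS:
            raise KnowledgeBaseError(
                f"drug_targets.tsv: unknown evidence level {r['evidence']!r} for {r['drug']}"
            )
        drug_targets.append(
            DrugTarget(
                drug=r["drug"],
                gene=r["gene"].upper(),
                trigger=r["trigger"],
                pathway=r["pathway"],
                evidence=r["evidence"],
                note=r.get("note", ""),
            )
        )

    _, fl_rows = _read_table(directory / "feedback_loops.tsv")
    feedback_loops = [
        FeedbackLoop(
            gene_a=r["gene_a"].upper(),
            gene_b=r["gene_b"].upper(),
            combo=r["combo"],
            note=r.get("note", ""),
        )
        for r in fl_rows
    ]

    kb = KnowledgeBase(
        version=version,
        associations=associations,
        catalog=catalog,
        activating={g: frozenset(v) for g, v in activating.items()},
        inactivating={g: frozenset(v) for g, v in inactivating.items()},
        drug_rules=drug_rules,
        toxicity_rules=toxicity_rules,
        prognostic_biomarkers=prognostic,
        panels=panels,
        pathways=pathways,
        trials=trials,
        risk_panels=risk_panels,
        drug_targets=drug_targets,
        feedback_loops=feedback_loops,
        gene_loci=gene_loci,
    )

    pathway_genes = {g for p in pathways for g in p.genes}
    for rule in drug_rules:
        for gene in rule.predicate.genes():
            if not kb.known_cancer_gene(gene) and gene not in pathway_genes:
                warnings.warn(
                    f"drug rule {rule.rule_id}: gene {gene} appears in no "
                    "association or pathway table",
                    stacklevel=2,
                )
    return kb


@lru_cache(maxsize=1)
def packaged_kb() -> KnowledgeBase:
    """Load the mini knowledge base shipped with the package (cached;
    treat the returned bundle as read-only)."""
    root = resources.files("oncointerp").joinpath("data/kb")
    return load_kb(Path(str(root)))


def import_hotspots_bed(path: str | Path) -> tuple[tuple[str, int, int], ...]:
    """Import hotspot intervals from a BED file (0-based half-open on disk),
    converting to the package's 1-based inclusive convention."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end = line.split("\t")[:3]
            out.append((chrom, int(start) + 1, int(end)))
    return tuple(out)
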