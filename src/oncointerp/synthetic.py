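"""Seeded cohort generators and packaged in-memory cohort fixtures.

The generator emulates the statistical structure of a small prospective
sequencing cohort: per-gene driver alteration frequencies per cancer type,
a configurable six-class substitution spectrum, tumor purity driving the
somatic allelic-fraction distribution (AF ~ Binomial(depth, purity/2)/depth
under a diploid-heterozygous clonal model), and per-source rates of
knowledge-base-actionable events.  Everything is deterministic given the
mandatory seed.

:func:`table_fixtures` returns three small encoded cohorts — five medullary
thyroid carcinomas, nineteen colorectal cancers and seven breast cancers —
plus a single cancer-of-unknown-primary case carrying a rare activating
EGFR extracellular-domain mutation (p.D587H, 387 alt / 1998 total reads).
Genomic coordinates of fixture variants are synthetic but stable, derived
from the packaged gene loci.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from oncointerp.errors import ConfigurationError
from oncointerp.knowledgebase import KnowledgeBase, packaged_kb
from oncointerp.therapy import actionability, predict_tier1_response, recommend_tier2
from oncointerp.variant_model import (
    CNASegment,
    ExpressionRecord,
    GermlineVariant,
    PatientProfile,
    SomaticVariant,
    SPECTRUM_CLASSES,
    codon_of,
    consequence_of,
)

# the two ordered base substitutions collapsing onto each spectrum class
_CLASS_PAIRS: dict[str, tuple[tuple[str, str], tuple[str, str]]] = {
    "C>A": (("C", "A"), ("G", "T")),
    "C>G": (("C", "G"), ("G", "C")),
    "C>T": (("C", "T"), ("G", "A")),
    "T>A": (("T", "A"), ("A", "T")),
    "T>C": (("T", "C"), ("A", "G")),
    "T>G": (("T", "G"), ("A", "C")),
}

_AMINO = "ARNDCQEGHILKMFPSTWYV"


# ---------------------------------------------------------------------------
# coordinate helpers
# ---------------------------------------------------------------------------


def variant_position(kb: KnowledgeBase, gene: str, protein_change: str) -> tuple[str, int]:
    """Stable synthetic genomic position for a protein change: the first
    base of the affected codon under a contiguous-CDS toy gene model."""
    locus = kb.locus(gene)
    if locus is None:
        raise ConfigurationError(f"no locus for gene {gene}")
    codon = codon_of(protein_change)
    if codon is None:
        return locus.chrom, locus.start
    return locus.chrom, locus.start + 3 * (codon - 1)


def _stable_pair(gene: str, protein_change: str) -> tuple[str, str]:
    """Deterministic ref/alt pair for a fixture variant."""
    idx = zlib.crc32(f"{gene}|{protein_change}".encode()) % 12
    cls = SPECTRUM_CLASSES[idx // 2]
    return _CLASS_PAIRS[cls][idx % 2]


def make_somatic(
    kb: KnowledgeBase,
    gene: str,
    protein_change: str,
    tumor_id: str,
    depth_alt: int = 42,
    depth_total: int = 120,
    ref: str | None = None,
    alt: str | None = None,
    pos: int | None = None,
    chrom: str | None = None,
) -> SomaticVariant:
    """Construct a fixture somatic variant with stable synthetic coordinates."""
    c, p = variant_position(kb, gene, protein_change)
    if ref is None or alt is None:
        ref, alt = _stable_pair(gene, protein_change)
    return SomaticVariant(
        chrom=chrom or c,
        pos=pos or p,
        ref=ref,
        alt=alt,
        gene=gene,
        protein_change=protein_change,
        consequence=consequence_of(protein_change),
        depth_alt=depth_alt,
        depth_total=depth_total,
        tumor_id=tumor_id,
    )


def make_germline(
    kb: KnowledgeBase,
    gene: str,
    protein_change: str,
    zygosity: str = "het",
    classification: str = "",
) -> GermlineVariant:
    chrom, pos = variant_position(kb, gene, protein_change)
    ref, alt = _stable_pair(gene, protein_change)
    return GermlineVariant(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        gene=gene,
        protein_change=protein_change,
        zygosity=zygosity,
        classification=classification,
    )


def make_cna(
    kb: KnowledgeBase, gene: str, call: str, platform: str = "wes"
) -> CNASegment:
    """A segment spanning one gene's locus carrying a gain/loss call."""
    locus = kb.locus(gene)
    if locus is None:
        raise ConfigurationError(f"no locus for gene {gene}")
    log2ratio = 1.2 if call == "gain" else -1.1
    return CNASegment(
        chrom=locus.chrom,
        start=max(1, locus.start - 5000),
        end=locus.end + 5000,
        log2ratio=log2ratio,
        log2mbaf=0.4,
        call=call,
        platform=platform,
    )


# ---------------------------------------------------------------------------
# cohort configuration
# ---------------------------------------------------------------------------


@dataclass
class CohortConfig:
    """Study conditions for a simulated cohort.

    ``gene_frequencies`` maps cancer type -> gene -> per-patient Bernoulli
    alteration probability (driver events with canonical protein changes);
    ``actionable_rates`` maps alteration source -> Poisson mean count of
    knowledge-base-actionable events injected per patient (distinct genes).
    ``spectrum_weights`` orders over C>A, C>G, C>T, T>A, T>C, T>G.
    """

    n_patients: int
    seed: int
    cancer_type_mixture: dict[str, float] = field(
        default_factory=lambda: {"colorectal": 0.40, "breast": 0.15, "MTC": 0.10, "other": 0.35}
    )
    gene_frequencies: dict[str, dict[str, float]] = field(default_factory=dict)
    spectrum_weights: tuple[float, ...] = (0.07, 0.07, 0.55, 0.07, 0.17, 0.07)
    mutations_per_mb_median: float = 2.0
    mutation_rate_sigma: float = 0.2
    coding_target_mb: float = 30.0
    purity_mean: float = 0.6
    purity_sd: float = 0.15
    depth_mean: float = 110.0
    actionable_rates: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        problems = []
        if self.n_patients < 1:
            problems.append("n_patients must be >= 1")
        if self.seed is None:
            problems.append("seed is mandatory")
        if abs(sum(self.spectrum_weights) - 1.0) > 1e-9 or len(self.spectrum_weights) != 6:
            problems.append("spectrum_weights must be 6 values summing to 1")
        if not self.cancer_type_mixture or abs(sum(self.cancer_type_mixture.values()) - 1.0) > 1e-9:
            problems.append("cancer_type_mixture must sum to 1")
        for ctype, freqs in self.gene_frequencies.items():
            for gene, f in freqs.items():
                if not (0.0 <= f <= 1.0):
                    problems.append(f"gene_frequencies[{ctype}][{gene}]={f} outside [0,1]")
        if self.mutations_per_mb_median < 0 or self.coding_target_mb <= 0:
            problems.append("mutation rate/area must be non-negative/positive")
        for src, rate in self.actionable_rates.items():
            if src not in ("somatic", "cna", "germline", "expression"):
                problems.append(f"unknown actionable source {src!r}")
            elif rate < 0:
                problems.append(f"actionable_rates[{src}] must be >= 0")
        if problems:
            raise ConfigurationError("invalid cohort config: " + "; ".join(problems))


# canonical driver protein change per gene, used for frequency-driven events
_CANONICAL_CHANGE = {
    "APC": "p.R232*",
    "KRAS": "p.G12V",
    "NRAS": "p.Q61R",
    "BRAF": "p.V600E",
    "PIK3CA": "p.E545K",
    "PTEN": "p.R130*",
    "EGFR": "p.L858R",
    "TP53": "p.R273H",
    "RET": "p.M918T",
    "ALK": "p.A1200V",
    "AKT1": "p.E17K",
    "NF1": "p.R1362*",
}


def _canonical_change(kb: KnowledgeBase, gene: str) -> str:
    if gene in _CANONICAL_CHANGE:
        return _CANONICAL_CHANGE[gene]
    if gene in kb.activating:
        return sorted(kb.activating[gene])[0]
    return "p.R100*" if kb.gene_role(gene) == "tumor_suppressor" else "p.A100V"


# ---------------------------------------------------------------------------
# actionable candidate pools
# ---------------------------------------------------------------------------


def _probe_actionable(profile: PatientProfile, kb: KnowledgeBase) -> bool:
    t1 = predict_tier1_response(profile, kb)
    t2 = recommend_tier2(profile, kb)
    return actionability(profile, t1, t2).total > 0


_POOL_CACHE: dict[tuple[int, str], dict[str, list]] = {}


def actionable_pools(kb: KnowledgeBase, cancer_type: str) -> dict[str, list]:
    """Genes (with event details) whose single alteration is actionable for
    the given cancer type, per alteration source.  Computed by probing the
    knowledge base with minimal one-alteration profiles; cached per KB
    object and cancer type."""
    cache_key = (id(kb), cancer_type)
    if cache_key in _POOL_CACHE:
        return _POOL_CACHE[cache_key]
    pools: dict[str, list] = {"somatic": [], "cna": [], "germline": [], "expression": []}

    rule_genes = set()
    for rule in kb.drug_rules:
        rule_genes |= rule.predicate.genes()
    target_genes = {t.gene for t in kb.drug_targets}

    for gene in sorted(set(kb.activating) | rule_genes | target_genes):
        if gene in kb.activating:
            pchange = sorted(kb.activating[gene])[0]
            probe = PatientProfile(
                "probe", cancer_type, somatic=[make_somatic(kb, gene, pchange, "probe-T1")]
            ) if kb.locus(gene) else None
            if probe and _probe_actionable(probe, kb):
                pools["somatic"].append((gene, pchange))
        if kb.locus(gene):
            for call in ("gain", "loss"):
                probe = PatientProfile("probe", cancer_type, cna=[make_cna(kb, gene, call)])
                if _probe_actionable(probe, kb):
                    pools["cna"].append((gene, call))
        if kb.locus(gene):
            probe = PatientProfile(
                "probe", cancer_type, germline=[make_germline(kb, gene, "p.A100V")]
            )
            if _probe_actionable(probe, kb):
                pools["germline"].append(gene)
        probe = PatientProfile(
            "probe",
            cancer_type,
            expression=[ExpressionRecord(gene=gene, tumor_value=50.0, normal_value=1.0, level="high")],
        )
        if _probe_actionable(probe, kb):
            pools["expression"].append(gene)
    _POOL_CACHE[cache_key] = pools
    return pools


# ---------------------------------------------------------------------------
# the generator
# ---------------------------------------------------------------------------


def generate_cohort(
    config: CohortConfig, kb: KnowledgeBase | None = None
) -> list[PatientProfile]:
    """Generate a seeded synthetic cohort of patient profiles.

    Per patient: a cancer type is drawn from the mixture; driver genes by
    independent Bernoulli draws at the configured frequencies; background
    somatic SNVs at a lognormally dispersed per-Mb rate with substitution
    classes drawn from the spectrum weights; allelic fractions from
    Binomial(depth, purity/2) with Poisson depths; and per-source
    knowledge-base-actionable events at the configured Poisson rates
    (distinct genes per source).  Fully deterministic given the seed.
    """
    config.validate()
    if kb is None:
        kb = packaged_kb()
    rng = np.random.default_rng(config.seed)

    types = sorted(config.cancer_type_mixture)
    type_p = np.array([config.cancer_type_mixture[t] for t in types])
    pools_by_type = {
        t: actionable_pools(kb, t) for t in types if config.actionable_rates
    }

    profiles = []
    for i in range(config.n_patients):
        patient_id = f"S{i + 1:04d}"
        tumor_id = f"{patient_id}-T1"
        ctype = types[int(rng.choice(len(types), p=type_p))]
        purity = float(np.clip(rng.normal(config.purity_mean, config.purity_sd), 0.05, 1.0))

        somatic: list[SomaticVariant] = []
        germline: list[GermlineVariant] = []
        cna: list[CNASegment] = []
        expression: list[ExpressionRecord] = []
        somatic_genes: set[str] = set()

        def draw_af(n_alt_min: int = 0) -> tuple[int, int]:
            depth = int(rng.poisson(config.depth_mean))
            alt = int(rng.binomial(depth, purity / 2.0)) if depth > 0 else 0
            return max(alt, n_alt_min if depth > 0 else 0), depth

        # driver events at configured per-gene frequencies
        for gene, freq in sorted(config.gene_frequencies.get(ctype, {}).items()):
            if rng.random() < freq:
                pchange = _canonical_change(kb, gene)
                alt_reads, depth = draw_af(1)
                if kb.locus(gene):
                    somatic.append(
                        make_somatic(kb, gene, pchange, tumor_id, alt_reads, depth)
                    )
                    somatic_genes.add(gene)

        # background mutation load
        if config.mutations_per_mb_median > 0:
            rate = config.mutations_per_mb_median * float(
                np.exp(rng.normal(0.0, config.mutation_rate_sigma))
            )
            n_background = int(rng.poisson(rate * config.coding_target_mb))
            classes = rng.choice(6, size=n_background, p=np.asarray(config.spectrum_weights))
            for k in range(n_background):
                cls = SPECTRUM_CLASSES[int(classes[k])]
                ref, alt_base = _CLASS_PAIRS[cls][int(rng.integers(2))]
                gene = f"GENE{int(rng.integers(1, 4000)):04d}"
                codon = int(rng.integers(30, 600))
                aa_from, aa_to = rng.choice(list(_AMINO), size=2, replace=False)
                alt_reads, depth = draw_af()
                somatic.append(
                    SomaticVariant(
                        chrom=f"chr{int(rng.integers(1, 23))}",
                        pos=int(rng.integers(100_000, 200_000_000)),
                        ref=ref,
                        alt=alt_base,
                        gene=gene,
                        protein_change=f"p.{aa_from}{codon}{aa_to}",
                        consequence="missense",
                        depth_alt=alt_reads,
                        depth_total=depth,
                        tumor_id=tumor_id,
                    )
                )

        # knowledge-base-actionable events per source
        if config.actionable_rates:
            pools = pools_by_type[ctype]
            for source in ("somatic", "cna", "germline", "expression"):
                rate = config.actionable_rates.get(source, 0.0)
                pool = pools[source]
                if rate <= 0 or not pool:
                    continue
                k = min(int(rng.poisson(rate)), len(pool))
                picks = rng.choice(len(pool), size=k, replace=False)
                for idx in sorted(int(j) for j in picks):
                    if source == "somatic":
                        gene, pchange = pool[idx]
                        if gene in somatic_genes:
                            continue
                        alt_reads, depth = draw_af(1)
                        somatic.append(
                            make_somatic(kb, gene, pchange, tumor_id, alt_reads, depth)
                        )
                        somatic_genes.add(gene)
                    elif source == "cna":
                        gene, call = pool[idx]
                        cna.append(make_cna(kb, gene, call))
                    elif source == "germline":
                        germline.append(
                            make_germline(kb, pool[idx], "p.A100V", classification="VUS")
                        )
                    else:
                        expression.append(
                            ExpressionRecord(
                                gene=pool[idx], tumor_value=50.0, normal_value=1.0, level="high"
                            )
                        )

        profiles.append(
            PatientProfile(
                patient_id=patient_id,
                cancer_type=ctype,
                somatic=somatic,
                germline=germline,
                cna=cna,
                expression=expression,
                specimen_meta={"purity": purity, "tissue_source": "frozen"},
            )
        )
    return profiles


# ---------------------------------------------------------------------------
# encoded cohort fixtures
# ---------------------------------------------------------------------------

#: (patient, APC, KRAS, NRAS, BRAF, PIK3CA, PTEN, EGFR, TP53) somatic entries;
#: "CNA:loss"/"CNA:gain" marks copy-number events instead of mutations.
#: Column assignment for the typographically ambiguous rows follows the
#: per-gene frequency row (APC 0.89, PTEN 0.11, TP53 0.84 over 19 patients)
#: as the authoritative constraint: P0027 carries an APC copy loss plus
#: splice-donor mutations in both PTEN (its functional loss drives PI3K
#: activation in this tumor) and TP53, and P0037's splice-acceptor entry
#: belongs to PTEN.  This is the unique completion consistent with that row.
_COLORECTAL_ROWS: list[tuple[str, dict[str, list[str]]]] = [
    ("P0004", {"APC": ["p.E763*"], "KRAS": ["p.G12V"], "PIK3CA": ["p.E545K", "p.M1043I"]}),
    ("P0005", {"APC": ["p.R554*"], "KRAS": ["p.G12S"], "TP53": ["p.R273H"]}),
    ("P0008", {"BRAF": ["p.V600E"]}),
    ("P0009", {"APC": ["p.E1309fs*4"], "EGFR": ["CNA:gain"], "TP53": ["p.P151S"]}),
    ("P0016", {"KRAS": ["p.G12V"], "PIK3CA": ["p.E545K"], "TP53": ["p.R248Q"]}),
    ("P0018", {"APC": ["p.E1309*", "p.V1377fs"], "KRAS": ["p.G13D"], "TP53": ["p.G245S"]}),
    ("P0019", {"APC": ["p.R232*", "p.R1114*"], "TP53": ["p.R333fs*12"]}),
    ("P0020", {"APC": ["p.T683P", "p.R876*", "p.E1577*"], "KRAS": ["p.G13D"], "TP53": ["p.F270I"]}),
    ("P0022", {"APC": ["p.T1493fs*14"], "TP53": ["p.R248Q"]}),
    ("P0024", {"APC": ["p.E955*"], "NRAS": ["p.N116H", "p.Q61P"], "TP53": ["p.S183*"]}),
    ("P0025", {"APC": ["p.I606fs", "p.R1450*"], "NRAS": ["p.Q61R"], "TP53": ["p.R273C"]}),
    ("P0027", {"APC": ["CNA:loss"], "PTEN": ["p.splice_donor"], "TP53": ["p.splice_donor"]}),
    ("P0028", {"APC": ["p.splice_donor", "p.Q1067*"], "TP53": ["p.R282W"]}),
    ("P0031", {"APC": ["p.E1097*", "p.E1397*"], "KRAS": ["p.G12D"], "TP53": ["p.G245S"]}),
    ("P0033", {"APC": ["p.E1306*"], "KRAS": ["p.G13D"], "TP53": ["p.R273C"]}),
    ("P0034", {"APC": ["p.E1322*"], "KRAS": ["p.G12C"], "TP53": ["p.Y220C"]}),
    ("P0037", {"APC": ["p.R232*"], "BRAF": ["p.V600E"], "PTEN": ["p.splice_acceptor"]}),
    ("P0043", {"APC": ["p.F1354fs", "p.S1400*"], "KRAS": ["p.G13D"], "TP53": ["p.C176F"]}),
    ("P0046", {"APC": ["p.R876*"], "KRAS": ["p.G12D"], "TP53": ["p.S127F"]}),
]


def _colorectal_profiles(kb: KnowledgeBase) -> list[PatientProfile]:
    profiles = []
    for patient_id, entries in _COLORECTAL_ROWS:
        tumor_id = f"{patient_id}-T1"
        somatic, cna, germ, expr = [], [], [], []
        for gene, changes in entries.items():
            for change in changes:
                if change.startswith("CNA:"):
                    cna.append(make_cna(kb, gene, change.split(":")[1]))
                else:
                    somatic.append(make_somatic(kb, gene, change, tumor_id))
        if patient_id == "P0009":
            # quadruple-negative tumor with strong EGFR-ligand overexpression
            expr += [
                ExpressionRecord("EREG", tumor_value=113.0, normal_value=1.0, level="high"),
                ExpressionRecord("AREG", tumor_value=29.0, normal_value=1.0, level="high"),
            ]
        if patient_id == "P0025":
            germ += [
                make_germline(kb, "KDR", "p.Q472H"),
                make_germline(kb, "CXCR2", "p.S276T"),
                make_germline(kb, "ERCC1", "p.N118N"),
                make_germline(kb, "ERCC2", "p.K751Q"),
                make_germline(kb, "ERCC5", "p.D1104H"),
                make_germline(kb, "XRCC1", "p.R399Q"),
            ]
        if patient_id == "P0027":
            # additional non-APC WNT-component mutations
            somatic += [
                make_somatic(kb, "DKK1", "p.Q83*", tumor_id),
                make_somatic(kb, "CSNK1A1", "p.S101F", tumor_id),
                make_somatic(kb, "AXIN1", "p.R395*", tumor_id),
            ]
        if patient_id == "P0046":
            somatic.append(make_somatic(kb, "ALK", "p.A1200V", tumor_id))
            cna.append(make_cna(kb, "FLT3", "gain"))
            expr.append(ExpressionRecord("FLT3", tumor_value=40.0, normal_value=1.0, level="high"))
        profiles.append(
            PatientProfile(patient_id, "colorectal", somatic, germ, cna, expr)
        )
    return profiles


def _mtc_profiles(kb: KnowledgeBase) -> list[PatientProfile]:
    profiles = [
        PatientProfile(
            "P0010",
            "MTC",
            germline=[make_germline(kb, "RET", "p.C634R", classification="pathogenic")],
            cna=[
                make_cna(kb, "CDKN2A", "loss"),
                make_cna(kb, "RASA1", "loss"),
                make_cna(kb, "RASA3", "loss"),
                make_cna(kb, "RB1", "loss"),
            ],
        ),
        PatientProfile(
            "P0029",
            "MTC",
            germline=[make_germline(kb, "RET", "p.C634Y", classification="pathogenic")],
        ),
    ]
    for pid in ("P0036", "P0041", "P0044"):
        profiles.append(
            PatientProfile(
                pid, "MTC", somatic=[make_somatic(kb, "RET", "p.M918T", f"{pid}-T1")]
            )
        )
    return profiles


def _breast_profiles(kb: KnowledgeBase) -> list[PatientProfile]:
    def expr(gene: str, level: str, tumor: float) -> ExpressionRecord:
        return ExpressionRecord(gene, tumor_value=tumor, normal_value=1.0, level=level)

    return [
        PatientProfile(
            "P0002",
            "breast",
            somatic=[
                make_somatic(kb, "PIK3CA", "p.E545K", "P0002-T1"),
                make_somatic(kb, "MAP3K1", "p.F1462V", "P0002-T1"),
            ],
            cna=[make_cna(kb, "CCND1", "gain"), make_cna(kb, "FGFR1", "gain")],
            expression=[expr("ESR1", "high", 80.0), expr("ERBB2", "low", 0.4)],
        ),
        PatientProfile(
            "P0006",
            "breast",
            somatic=[make_somatic(kb, "PIK3CA", "p.E542K", "P0006-T1")],
            expression=[expr("ESR1", "high", 60.0), expr("ERBB2", "low", 0.5)],
        ),
        PatientProfile(
            "P0007",
            "breast",
            somatic=[make_somatic(kb, "TP53", "p.R213fs", "P0007-T1")],
            cna=[make_cna(kb, "CDK1", "gain"), make_cna(kb, "RASA1", "loss")],
        ),
        PatientProfile(
            "P0013",
            "breast",
            somatic=[make_somatic(kb, "PIK3CA", "p.R110P", "P0013-T1")],
            germline=[make_germline(kb, "BRCA1", "p.W1712fs", classification="pathogenic")],
            expression=[expr("ESR1", "low", 0.3), expr("ERBB2", "low", 0.4)],
        ),
        PatientProfile(
            "P0030",
            "breast",
            somatic=[make_somatic(kb, "TP53", "p.Y220C", "P0030-T1")],
            cna=[make_cna(kb, "NRAS", "gain")],
        ),
        PatientProfile(
            "P0040",
            "breast",
            somatic=[make_somatic(kb, "TP53", "p.W95*", "P0040-T1")],
            cna=[make_cna(kb, "CCND1", "gain")],
            germline=[
                make_germline(kb, "DCLRE1C", "p.S635_L636fs", classification="pathogenic")
            ],
            expression=[
                expr("ESR1", "high", 70.0),
                expr("ERBB2", "low", 0.5),
                expr("CCND1", "high", 60.0),
            ],
        ),
        PatientProfile(
            "P0042",
            "breast",
            somatic=[
                make_somatic(kb, "TP53", "p.L194R", "P0042-T1"),
                make_somatic(kb, "NF1", "p.R1362*", "P0042-T1"),
            ],
        ),
    ]


def _p0015_profile(kb: KnowledgeBase) -> PatientProfile:
    # rare activating EGFR extracellular-domain mutation; AF 387/1998 = 19.4 %
    return PatientProfile(
        "P0015",
        "unknown_primary",
        somatic=[
            make_somatic(
                kb,
                "EGFR",
                "p.D587H",
                "P0015-T1",
                depth_alt=387,
                depth_total=1998,
                ref="G",
                alt="C",
            )
        ],
    )


def table_fixtures(kb: KnowledgeBase | None = None) -> dict[str, list[PatientProfile]]:
    """The encoded study cohorts: 5 MTC, 19 colorectal and 7 breast
    profiles with exactly the printed alterations, plus the P0015 case."""
    if kb is None:
        kb = packaged_kb()
    return {
        "mtc": _mtc_profiles(kb),
        "colorectal": _colorectal_profiles(kb),
        "breast": _breast_profiles(kb),
        "p0015": [_p0015_profile(kb)],
    }
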