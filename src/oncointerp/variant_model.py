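"""Domain types and readers/writers for variants, CNA segments and expression.

Coordinates are 1-based inclusive everywhere (VCF convention); BED-style
inputs are converted on read.  Gene symbols are upper-cased and matched
exactly.  Somatic VCFs may be single- or multi-sample; a variant called in
two or more tumor specimens of the same patient is flagged ``recurrent``.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam

from oncointerp.errors import ConfigurationError, DomainError, VCFParseError

# ---------------------------------------------------------------------------
# substitution spectrum (pyrimidine convention)
# ---------------------------------------------------------------------------

#: The six substitution classes, named by the pyrimidine member of the pair.
SPECTRUM_CLASSES: tuple[str, ...] = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

_BASES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def classify_substitution(ref: str, alt: str) -> str:
    """Map a single-base substitution onto one of the six spectrum classes.

    The class is named by the change of the pyrimidine base of the DNA base
    pair, so e.g. ``C>T`` covers both C->T and its strand complement G->A
    (a C:G > T:A transition).  Purine-reference pairs are reverse-complemented
    onto the pyrimidine convention.
    """
    if ref not in _BASES or alt not in _BASES:
        raise DomainError(f"substitution must be single A/C/G/T bases, got {ref!r}>{alt!r}")
    if ref == alt:
        raise DomainError(f"ref and alt are identical: {ref!r}")
    if ref in ("A", "G"):  # purine reference: flip to the pyrimidine strand
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    return f"{ref}>{alt}"


# ---------------------------------------------------------------------------
# consequence handling
# ---------------------------------------------------------------------------

CONSEQUENCES = frozenset(
    {"missense", "nonsense", "frameshift", "inframe_indel", "splice_site", "synonymous", "other"}
)

#: Consequences treated as protein-truncating (loss of function) downstream.
TRUNCATING = frozenset({"nonsense", "frameshift", "splice_site"})

_PCHANGE_RE = re.compile(r"^p\.[A-Z\*]")
_CODON_RE = re.compile(r"p\.\(?([A-Z])(\d+)")


def normalize_protein_change(pchange: str) -> str:
    """Normalize an HGVS p. string: strip isoform qualifiers and whitespace.

    ``NP_004324.2:p.V600E`` -> ``p.V600E``;  ``V600E`` -> ``p.V600E``.
    Empty input stays empty.
    """
    pchange = pchange.strip()
    if not pchange:
        return ""
    if ":" in pchange:
        pchange = pchange.rsplit(":", 1)[1]
    pchange = pchange.replace(" ", "").replace("(", "").replace(")", "")
    if not pchange.startswith("p."):
        pchange = "p." + pchange
    return pchange


def consequence_of(protein_change: str) -> str:
    """Infer a coarse consequence class from a protein-change string."""
    p = normalize_protein_change(protein_change)
    if not p:
        return "other"
    if "splice" in p.lower():
        return "splice_site"
    if "fs" in p:
        return "frameshift"
    if p.endswith("*"):
        return "nonsense"
    if "del" in p or "ins" in p or "dup" in p:
        return "inframe_indel"
    if re.fullmatch(r"p\.([A-Z])(\d+)\1", p):
        return "synonymous"
    if re.fullmatch(r"p\.[A-Z]\d+[A-Z]", p):
        return "missense"
    return "other"


def codon_of(protein_change: str) -> int | None:
    """Extract the (first) affected codon number, or None for splice markers."""
    m = _CODON_RE.search(normalize_protein_change(protein_change))
    return int(m.group(2)) if m else None


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SomaticVariant:
    """A somatic (tumor-specific) small variant in one tumor specimen."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    gene: str = ""
    protein_change: str = ""
    consequence: str = "other"
    canonical_isoform: bool = True
    af: float | None = None
    depth_alt: int = 0
    depth_total: int = 0
    tumor_id: str = ""
    recurrent: bool = False

    def __post_init__(self):
        if self.pos < 1:
            raise DomainError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise DomainError(f"alt equals ref ({self.ref}) at {self.chrom}:{self.pos}")
        if self.consequence not in CONSEQUENCES:
            raise DomainError(f"unknown consequence {self.consequence!r}")
        if self.depth_alt < 0 or self.depth_total < 0:
            raise DomainError("read depths must be non-negative")
        object.__setattr__(self, "gene", self.gene.upper())
        object.__setattr__(self, "protein_change", normalize_protein_change(self.protein_change))
        if self.depth_total > 0:
            expected = self.depth_alt / self.depth_total
            if self.af is None:
                object.__setattr__(self, "af", expected)
            elif abs(self.af - expected) > 1e-6:
                raise DomainError(
                    f"af={self.af} inconsistent with {self.depth_alt}/{self.depth_total}"
                )
        if self.af is not None and not (0.0 <= self.af <= 1.0):
            raise DomainError(f"allelic fraction out of [0,1]: {self.af}")

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 == len(self.alt) and self.ref in _BASES and self.alt in _BASES


@dataclass(frozen=True)
class GermlineVariant:
    """A germline variant (shared by tumor and normal) on one gene."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str = ""
    protein_change: str = ""
    zygosity: str = "het"  # {het, hom}
    classification: str = ""  # free-text pathogenicity label

    def __post_init__(self):
        if self.pos < 1:
            raise DomainError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise DomainError(f"alt equals ref ({self.ref}) at {self.chrom}:{self.pos}")
        if self.zygosity not in ("het", "hom"):
            raise DomainError(f"zygosity must be het/hom, got {self.zygosity!r}")
        object.__setattr__(self, "gene", self.gene.upper())
        object.__setattr__(self, "protein_change", normalize_protein_change(self.protein_change))

    @property
    def truncating(self) -> bool:
        return consequence_of(self.protein_change) in TRUNCATING


CNA_CALLS = frozenset({"gain", "loss", "normal", "undecided"})


@dataclass(frozen=True)
class CNASegment:
    """A somatic copy-number segment with saasCNV-style summary statistics.

    ``log2ratio`` is the median tumor/normal log2 copy ratio of the segment;
    ``log2mBAF`` the median mirrored-B-allele-frequency statistic.  ``call``
    uses the 4-state vocabulary gain / loss / normal (no CNA) / undecided
    (unclear CNA change).
    """

    chrom: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    log2ratio: float
    log2mbaf: float
    call: str = "undecided"
    platform: str = "wes"  # {wes, array}
    tissue_source: str = "unknown"  # {ffpe, frozen, unknown}

    def __post_init__(self):
        if self.start < 1 or self.end < self.start:
            raise DomainError(f"bad segment bounds {self.chrom}:{self.start}-{self.end}")
        if self.call not in CNA_CALLS:
            raise DomainError(f"call must be one of {sorted(CNA_CALLS)}, got {self.call!r}")
        if self.platform not in ("wes", "array"):
            raise DomainError(f"platform must be wes/array, got {self.platform!r}")
        if self.tissue_source not in ("ffpe", "frozen", "unknown"):
            raise DomainError(f"bad tissue_source {self.tissue_source!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return self.chrom == chrom and self.start <= end and start <= self.end


@dataclass(frozen=True)
class ExpressionRecord:
    """Gene-level expression for one tumor, with optional matched normal.

    ``level`` summarizes the tumor value relative to a reference distribution
    as high / low / unknown; ``fold_change`` is tumor/normal when a matched
    normal value is present.
    """

    gene: str
    tumor_value: float
    normal_value: float | None = None
    level: str = "unknown"  # {high, low, unknown}

    def __post_init__(self):
        object.__setattr__(self, "gene", self.gene.upper())
        if self.level not in ("high", "low", "unknown"):
            raise DomainError(f"level must be high/low/unknown, got {self.level!r}")
        if self.normal_value is not None and self.normal_value <= 0:
            raise DomainError("normal_value must be positive when present")

    @property
    def fold_change(self) -> float | None:
        if self.normal_value is None:
            return None
        return self.tumor_value / self.normal_value


@dataclass
class PatientProfile:
    """The unit of analysis: all alterations observed in one patient."""

    patient_id: str
    cancer_type: str
    somatic: list[SomaticVariant] = field(default_factory=list)
    germline: list[GermlineVariant] = field(default_factory=list)
    cna: list[CNASegment] = field(default_factory=list)
    expression: list[ExpressionRecord] = field(default_factory=list)
    specimen_meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.cancer_type:
            raise DomainError("cancer_type must be non-empty")

    @property
    def tumor_ids(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for v in self.somatic:
            seen.setdefault(v.tumor_id or f"{self.patient_id}-T1", None)
        if not seen:
            seen[f"{self.patient_id}-T1"] = None
        return tuple(seen)


#: Alteration sources used for actionability accounting.
SOURCES = ("somatic", "cna", "germline", "expression")


@dataclass(frozen=True)
class Alteration:
    """Unifying record for one alteration of one gene in one patient.

    ``source`` is one of somatic / cna / germline / expression; ``kind`` the
    matched alteration class (e.g. ``somatic_activating``, ``cna_gain``);
    ``payload`` keeps a reference to the underlying typed record.
    """

    gene: str
    source: str
    kind: str
    description: str = ""
    payload: object = field(default=None, compare=False, hash=False)

    def __post_init__(self):
        if self.source not in SOURCES:
            raise DomainError(f"source must be one of {SOURCES}, got {self.source!r}")


# ---------------------------------------------------------------------------
# assay selection
# ---------------------------------------------------------------------------


def select_assays(
    gdna_mass_normal: float,
    gdna_mass_tumor: float,
    frozen_tumor_available: bool = False,
    frozen_adjacent_normal_available: bool = False,
) -> frozenset[str]:
    """Pick the assay set from gDNA masses (ug) and frozen-tissue flags.

    The targeted hotspot panel is always run (it needs the least DNA).  WES
    requires >= 1.5 ug of both normal and tumor gDNA; the SNP array
    additionally requires > 2.5 ug of both.  Tumor RNA-Seq requires frozen
    tumor tissue; normal RNA-Seq additionally frozen adjacent normal.
    """
    if gdna_mass_normal < 0 or gdna_mass_tumor < 0:
        raise DomainError("gDNA masses must be non-negative")
    assays = {"panel"}
    low = min(gdna_mass_normal, gdna_mass_tumor)
    if low >= 1.5:
        assays.add("wes")
    if low > 2.5:
        assays.add("array")
    if frozen_tumor_available:
        assays.add("rnaseq_tumor")
        if frozen_adjacent_normal_available:
            assays.add("rnaseq_normal")
    return frozenset(assays)


# ---------------------------------------------------------------------------
# VCF IO (pysam)
# ---------------------------------------------------------------------------

_VCF_INFO_LINES = [
    '##INFO=<ID=GENE,Number=1,Type=String,Description="HGNC gene symbol">',
    '##INFO=<ID=PCHANGE,Number=1,Type=String,Description="Protein change, HGVS p. notation">',
    '##INFO=<ID=CSQ,Number=1,Type=String,Description="Coarse consequence class">',
    '##INFO=<ID=CANON,Number=1,Type=Integer,Description="1 if impact is on the canonical isoform">',
]
_VCF_FORMAT_LINES = [
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Read depth per allele">',
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Total read depth">',
]


def write_somatic_vcf(
    path: str | Path,
    variants: Sequence[SomaticVariant],
    sample_names: Sequence[str] | None = None,
) -> None:
    """Write somatic variants to a VCF 4.2 file, one sample column per tumor.

    Variants sharing (chrom, pos, ref, alt) collapse into one VCF row with
    per-tumor genotype columns; tumors in which the variant was not called
    get a ``./.`` genotype.
    """
    if sample_names is None:
        seen: dict[str, None] = {}
        for v in variants:
            seen.setdefault(v.tumor_id or "TUMOR", None)
        sample_names = list(seen) or ["TUMOR"]

    header = pysam.VariantHeader()
    header.add_line("##fileformat=VCFv4.2")
    contigs: dict[str, int] = {}
    for v in variants:
        contigs[v.chrom] = max(contigs.get(v.chrom, 0), v.pos + len(v.ref))
    for chrom, maxpos in contigs.items():
        header.add_line(f"##contig=<ID={chrom},length={maxpos + 10_000}>")
    for line in _VCF_INFO_LINES + _VCF_FORMAT_LINES:
        header.add_line(line)
    for name in sample_names:
        header.add_sample(name)

    by_site: dict[tuple, list[SomaticVariant]] = {}
    for v in variants:
        by_site.setdefault((v.chrom, v.pos, v.ref, v.alt), []).append(v)

    with pysam.VariantFile(str(path), "w", header=header) as out:
        for (chrom, pos, ref, alt), calls in sorted(
            by_site.items(), key=lambda kv: (kv[0][0], kv[0][1], kv[0][2], kv[0][3])
        ):
            rec = out.new_record(contig=chrom, start=pos - 1, alleles=(ref, alt))
            rec.filter.add("PASS")
            first = calls[0]
            if first.gene:
                rec.info["GENE"] = first.gene
            if first.protein_change:
                rec.info["PCHANGE"] = first.protein_change
            rec.info["CSQ"] = first.consequence
            rec.info["CANON"] = 1 if first.canonical_isoform else 0
            by_tumor = {c.tumor_id or "TUMOR": c for c in calls}
            for name in sample_names:
                call = by_tumor.get(name)
                if call is None:
                    rec.samples[name]["GT"] = (None, None)
                else:
                    rec.samples[name]["GT"] = (0, 1)
                    rec.samples[name]["AD"] = (
                        call.depth_total - call.depth_alt,
                        call.depth_alt,
                    )
                    rec.samples[name]["DP"] = call.depth_total
            out.write(rec)


def read_somatic_vcf(
    path: str | Path,
    sample_map: Mapping[str, str] | None = None,
    keep_filtered: bool = False,
) -> list[SomaticVariant]:
    """Read somatic calls from a single- or multi-sample VCF.

    Returns one :class:`SomaticVariant` per variant per tumor in which it is
    called (genotype contains the alternate allele).  In multi-sample files
    a variant called in >= 2 tumor samples is flagged ``recurrent``.
    Records whose FILTER is neither PASS nor ``.`` are dropped unless
    ``keep_filtered`` (they correspond to calls rejected during manual
    review).  ``sample_map`` optionally renames VCF sample columns to tumor
    labels; unknown keys raise :class:`ConfigurationError`.
    """
    path = Path(path)
    try:
        vcf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise VCFParseError(f"cannot parse VCF {path}: {exc}") from exc

    with vcf:
        samples = list(vcf.header.samples)
        if sample_map:
            unknown = set(sample_map) - set(samples)
            if unknown:
                raise ConfigurationError(
                    f"sample_map names absent from {path.name}: {sorted(unknown)}"
                )
        out: list[SomaticVariant] = []
        for line_no, rec in enumerate(vcf, start=1):
            try:
                filters = set(rec.filter.keys())
                if filters and filters != {"PASS"} and not keep_filtered:
                    continue
                if rec.alts is None:
                    continue
                alt = rec.alts[0]

                def _info(key, default=None):
                    # tolerate annotation fields absent from the header
                    try:
                        return rec.info.get(key, default)
                    except (KeyError, ValueError):
                        return default

                gene = str(_info("GENE") or "")
                pchange = str(_info("PCHANGE") or "")
                csq = str(_info("CSQ") or "")
                if csq not in CONSEQUENCES:
                    csq = consequence_of(pchange) if pchange else "other"
                canon = bool(int(_info("CANON", 1)))
                called: list[SomaticVariant] = []
                if samples:
                    for name in samples:
                        smp = rec.samples[name]
                        gt = smp.get("GT")
                        if gt is None or not any(a not in (None, 0) for a in gt):
                            continue
                        ad = smp.get("AD")
                        dp = smp.get("DP")
                        depth_alt = int(ad[1]) if ad and ad[1] is not None else 0
                        depth_total = int(dp) if dp is not None else (
                            sum(int(a) for a in ad if a is not None) if ad else 0
                        )
                        called.append(
                            SomaticVariant(
                                chrom=rec.chrom,
                                pos=rec.pos,
                                ref=rec.ref,
                                alt=alt,
                                gene=gene,
                                protein_change=pchange,
                                consequence=csq,
                                canonical_isoform=canon,
                                depth_alt=depth_alt,
                                depth_total=depth_total,
                                tumor_id=(sample_map or {}).get(name, name),
                            )
                        )
                else:  # site-only VCF: a single anonymous tumor
                    called.append(
                        SomaticVariant(
                            chrom=rec.chrom,
                            pos=rec.pos,
                            ref=rec.ref,
                            alt=alt,
                            gene=gene,
                            protein_change=pchange,
                            consequence=csq,
                            canonical_isoform=canon,
                            tumor_id="TUMOR",
                        )
                    )
            except (KeyError, TypeError, ValueError) as exc:
                raise VCFParseError(
                    f"malformed VCF record in {path.name} (record {line_no}): {exc}"
                ) from exc
            if len(called) >= 2:
                called = [replace(v, recurrent=True) for v in called]
            out.extend(called)
        return out


# ---------------------------------------------------------------------------
# segment / expression tables
# ---------------------------------------------------------------------------

_SEG_COLUMNS = ["chrom", "start", "end", "log2ratio", "log2mbaf", "call"]


def read_cna_segments(
    path: str | Path, platform: str = "wes", tissue_source: str = "unknown"
) -> list[CNASegment]:
    """Read segments from a tab-separated table (chrom, start, end, log2ratio,
    log2mBAF, call[, platform, tissue_source]); coordinates 1-based inclusive."""
    df = pd.read_csv(path, sep="\t", comment="#")
    df.columns = [c.lower() for c in df.columns]
    missing = [c for c in _SEG_COLUMNS if c not in df.columns]
    if missing:
        raise DomainError(f"segment table {path} lacks columns {missing}")
    segs = []
    for row in df.itertuples(index=False):
        segs.append(
            CNASegment(
                chrom=str(row.chrom),
                start=int(row.start),
                end=int(row.end),
                log2ratio=float(row.log2ratio),
                log2mbaf=float(row.log2mbaf),
                call=str(row.call),
                platform=str(getattr(row, "platform", platform)),
                tissue_source=str(getattr(row, "tissue_source", tissue_source)),
            )
        )
    return segs


def write_cna_segments(path: str | Path, segments: Iterable[CNASegment]) -> None:
    rows = [
        {
            "chrom": s.chrom,
            "start": s.start,
            "end": s.end,
            "log2ratio": s.log2ratio,
            "log2mbaf": s.log2mbaf,
            "call": s.call,
            "platform": s.platform,
            "tissue_source": s.tissue_source,
        }
        for s in segments
    ]
    pd.DataFrame(rows, columns=_SEG_COLUMNS + ["platform", "tissue_source"]).to_csv(
        path, sep="\t", index=False
    )


def read_expression_table(path: str | Path) -> list[ExpressionRecord]:
    """Read gene-level expression (gene, tumor_value[, normal_value, level])."""
    df = pd.read_csv(path, sep="\t", comment="#")
    df.columns = [c.lower() for c in df.columns]
    if "gene" not in df.columns or "tumor_value" not in df.columns:
        raise DomainError(f"expression table {path} needs gene and tumor_value columns")
    out = []
    for row in df.itertuples(index=False):
        normal = getattr(row, "normal_value", None)
        if normal is not None and (isinstance(normal, float) and math.isnan(normal)):
            normal = None
        level = str(getattr(row, "level", "unknown") or "unknown")
        out.append(
            ExpressionRecord(
                gene=str(row.gene),
                tumor_value=float(row.tumor_value),
                normal_value=float(normal) if normal is not None else None,
                level=level,
            )
        )
    return out


def write_expression_table(path: str | Path, records: Iterable[ExpressionRecord]) -> None:
    rows = [
        {
            "gene": r.gene,
            "tumor_value": r.tumor_value,
            "normal_value": r.normal_value,
            "level": r.level,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=["gene", "tumor_value", "normal_value", "level"]).to_csv(
        path, sep="\t", index=False
    )
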