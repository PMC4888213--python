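"""On-disk layout for patient profiles and cohorts.

A profile directory holds::

    meta.yaml        patient_id, cancer_type, specimen metadata
    somatic.vcf      somatic calls (single- or multi-sample VCF 4.2)
    germline.tsv     chrom, pos, ref, alt, gene, protein_change, zygosity, classification
    cna.tsv          chrom, start, end, log2ratio, log2mbaf, call[, platform, tissue_source]
    expression.tsv   gene, tumor_value, normal_value, level

A cohort directory holds one such sub-directory per patient.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from oncointerp.errors import DomainError
from oncointerp.variant_model import (
    GermlineVariant,
    PatientProfile,
    read_cna_segments,
    read_expression_table,
    read_somatic_vcf,
    write_cna_segments,
    write_expression_table,
    write_somatic_vcf,
)

_GERMLINE_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "protein_change",
    "zygosity",
    "classification",
]


def write_profile_dir(directory: str | Path, profile: PatientProfile) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with open(directory / "meta.yaml", "w") as fh:
        yaml.safe_dump(
            {
                "patient_id": profile.patient_id,
                "cancer_type": profile.cancer_type,
                "specimen_meta": profile.specimen_meta,
            },
            fh,
            sort_keys=True,
        )
    write_somatic_vcf(
        directory / "somatic.vcf", profile.somatic, sample_names=list(profile.tumor_ids)
    )
    rows = [
        {
            "chrom": g.chrom,
            "pos": g.pos,
            "ref": g.ref,
            "alt": g.alt,
            "gene": g.gene,
            "protein_change": g.protein_change,
            "zygosity": g.zygosity,
            "classification": g.classification,
        }
        for g in profile.germline
    ]
    pd.DataFrame(rows, columns=_GERMLINE_COLUMNS).to_csv(
        directory / "germline.tsv", sep="\t", index=False
    )
    write_cna_segments(directory / "cna.tsv", profile.cna)
    write_expression_table(directory / "expression.tsv", profile.expression)
    return directory


def read_profile_dir(directory: str | Path) -> PatientProfile:
    directory = Path(directory)
    meta_path = directory / "meta.yaml"
    if not meta_path.exists():
        raise DomainError(f"profile directory {directory} lacks meta.yaml")
    with open(meta_path) as fh:
        meta = yaml.safe_load(fh) or {}
    somatic = []
    if (directory / "somatic.vcf").exists():
        somatic = read_somatic_vcf(directory / "somatic.vcf")
    germline = []
    if (directory / "germline.tsv").exists():
        df = pd.read_csv(directory / "germline.tsv", sep="\t", keep_default_na=False)
        for row in df.itertuples(index=False):
            germline.append(
                GermlineVariant(
                    chrom=str(row.chrom),
                    pos=int(row.pos),
                    ref=str(row.ref),
                    alt=str(row.alt),
                    gene=str(row.gene),
                    protein_change=str(row.protein_change),
                    zygosity=str(row.zygosity) or "het",
                    classification=str(row.classification),
                )
            )
    cna = []
    if (directory / "cna.tsv").exists():
        cna = read_cna_segments(directory / "cna.tsv")
    expression = []
    if (directory / "expression.tsv").exists():
        expression = read_expression_table(directory / "expression.tsv")
    return PatientProfile(
        patient_id=str(meta["patient_id"]),
        cancer_type=str(meta["cancer_type"]),
        somatic=somatic,
        germline=germline,
        cna=cna,
        expression=expression,
        specimen_meta=meta.get("specimen_meta") or {},
    )


def write_cohort_dir(directory: str | Path, profiles: list[PatientProfile]) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for profile in profiles:
        write_profile_dir(directory / profile.patient_id, profile)
    return directory


def read_cohort_dir(directory: str | Path) -> list[PatientProfile]:
    directory = Path(directory)
    profiles = []
    for sub in sorted(p for p in directory.iterdir() if p.is_dir()):
        if (sub / "meta.yaml").exists():
            profiles.append(read_profile_dir(sub))
    if not profiles:
        raise DomainError(f"no patient profiles found under {directory}")
    return profiles
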