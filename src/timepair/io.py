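"""Readers and writers for the pipeline's table and set formats.

Dialects: TSV matrices keyed by gene symbol; GMT gene sets (name,
description, genes); VCF v4.2 for somatic variants with INFO keys AF
(variant allele fraction), DP (depth), POPAF (max population database
frequency), CSQCLASS (consequence class) and GENE (gene symbol); TSV
pairing manifests; YAML run configs. All round-trips are lossless to
1e-9 for reals and exact for integers and strings.
"""

from __future__ import annotations

import os
from pathlib import Path

import pandas as pd
import yaml

from .design import PairedDesign
from .errors import ParseError, ValidationError
from .matrix import ExpressionMatrix, Unit
from .variants import Consequence, VariantRecord

# ---------------------------------------------------------------- matrices


def write_matrix_tsv(matrix: ExpressionMatrix, path: str | Path, float_format: str = "%.9g") -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene", float_format=float_format)


def read_counts_tsv(path: str | Path) -> ExpressionMatrix:
    frame = pd.read_csv(path, sep="\t", index_col="gene")
    return ExpressionMatrix(values=frame, unit=Unit.COUNTS)


def read_matrix_tsv(path: str | Path, unit: Unit | str) -> ExpressionMatrix:
    frame = pd.read_csv(path, sep="\t", index_col="gene")
    return ExpressionMatrix(values=frame, unit=Unit(unit))


def write_lengths_tsv(lengths: dict[str, float], path: str | Path) -> None:
    pd.Series(lengths, name="length_bp").rename_axis("gene").to_csv(path, sep="\t")


def read_lengths_tsv(path: str | Path) -> dict[str, float]:
    series = pd.read_csv(path, sep="\t", index_col="gene")["length_bp"]
    return {str(g): float(v) for g, v in series.items()}


# ---------------------------------------------------------------- GMT


def parse_gmt_lines(handle, filename: str = "<gmt>") -> dict[str, list[str]]:
    """Parse GMT content: one set per line, tab-separated name, description, genes."""
    sets: dict[str, list[str]] = {}
    for lineno, raw in enumerate(handle, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ParseError(
                f"{filename}:{lineno}: GMT line needs name, description and >= 1 gene"
            )
        name = fields[0]
        if name in sets:
            raise ParseError(f"{filename}:{lineno}: duplicate set name {name!r}")
        genes = [g for g in fields[2:] if g]
        if not genes:
            raise ParseError(f"{filename}:{lineno}: set {name!r} has no genes")
        sets[name] = genes
    if not sets:
        raise ParseError(f"{filename}: no gene sets found")
    return sets


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    with open(path) as handle:
        return parse_gmt_lines(handle, filename=os.fspath(path))


def write_gmt(sets: dict[str, list[str]], path: str | Path, descriptions: dict | None = None) -> None:
    descriptions = descriptions or {}
    with open(path, "w") as handle:
        for name, genes in sets.items():
            desc = descriptions.get(name, "na")
            handle.write("\t".join([name, desc, *genes]) + "\n")


# ---------------------------------------------------------------- VCF

_VCF_INFO_KEYS = ("AF", "DP", "POPAF", "CSQCLASS", "GENE")

_VCF_HEADER_LINES = [
    "##fileformat=VCFv4.2",
    '##INFO=<ID=AF,Number=A,Type=Float,Description="Variant allele fraction">',
    '##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth at the site">',
    '##INFO=<ID=POPAF,Number=1,Type=Float,Description="Max population database allele frequency">',
    '##INFO=<ID=CSQCLASS,Number=1,Type=String,Description="Consequence class">',
    '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">',
]


def write_variant_vcf(records: list[VariantRecord], path: str | Path) -> None:
    """Write somatic variants in the package's VCF v4.2 dialect (1-based positions).

    An empty record list yields a valid header-only VCF.
    """
    chroms = []
    for rec in records:
        if rec.chromosome not in chroms:
            chroms.append(rec.chromosome)
    with open(path, "w") as handle:
        for line in _VCF_HEADER_LINES:
            handle.write(line + "\n")
        for chrom in chroms:
            handle.write(f"##contig=<ID={chrom}>\n")
        handle.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for rec in records:
            info = (
                f"AF={rec.vaf:.9g};DP={rec.depth};POPAF={rec.population_frequency:.9g};"
                f"CSQCLASS={rec.consequence_class.value};GENE={rec.gene}"
            )
            handle.write(
                f"{rec.chromosome}\t{rec.position}\t.\t{rec.ref}\t{rec.alt}\t.\t.\t{info}\n"
            )


def read_variant_vcf(path: str | Path) -> list[VariantRecord]:
    """Read the dialect back via cyvcf2; missing required INFO keys raise ParseError."""
    from cyvcf2 import VCF

    records: list[VariantRecord] = []
    # htslib holds Float INFO values as float32; keep the raw data lines
    # alongside the parsed records so AF/POPAF retain written precision
    with open(path) as handle:
        data_lines = [line for line in handle if line and not line.startswith("#")]
    vcf = VCF(os.fspath(path))
    try:
        for variant, raw_line in zip(vcf, data_lines):
            info_text = raw_line.rstrip("\n").split("\t")[7]
            text_values = dict(
                item.split("=", 1) for item in info_text.split(";") if "=" in item
            )
            info = {k: variant.INFO.get(k) for k in _VCF_INFO_KEYS}
            for key, value in info.items():
                if value is None:
                    raise ParseError(
                        f"{path}: variant {variant.CHROM}:{variant.POS} missing INFO key {key!r}"
                    )
            records.append(
                VariantRecord(
                    chromosome=variant.CHROM,
                    position=int(variant.POS),
                    ref=variant.REF,
                    alt=variant.ALT[0] if variant.ALT else ".",
                    gene=str(info["GENE"]),
                    consequence_class=Consequence(str(info["CSQCLASS"])),
                    vaf=float(text_values["AF"]),
                    depth=int(info["DP"]),
                    population_frequency=float(text_values["POPAF"]),
                )
            )
    finally:
        vcf.close()
    return records


_VARIANT_COLUMNS = [
    "chromosome",
    "position",
    "ref",
    "alt",
    "gene",
    "consequence_class",
    "vaf",
    "depth",
    "population_frequency",
]


def write_variant_tsv(records: list[VariantRecord], path: str | Path) -> None:
    frame = pd.DataFrame(
        [
            {
                "chromosome": r.chromosome,
                "position": r.position,
                "ref": r.ref,
                "alt": r.alt,
                "gene": r.gene,
                "consequence_class": r.consequence_class.value,
                "vaf": r.vaf,
                "depth": r.depth,
                "population_frequency": r.population_frequency,
            }
            for r in records
        ],
        columns=_VARIANT_COLUMNS,
    )
    frame.to_csv(path, sep="\t", index=False, float_format="%.9g")


def read_variant_tsv(path: str | Path) -> list[VariantRecord]:
    frame = pd.read_csv(path, sep="\t")
    missing = set(_VARIANT_COLUMNS) - set(frame.columns)
    if missing:
        raise ParseError(f"{path}: variant table missing columns: {sorted(missing)}")
    return [
        VariantRecord(
            chromosome=str(r.chromosome),
            position=int(r.position),
            ref=str(r.ref),
            alt=str(r.alt),
            gene=str(r.gene),
            consequence_class=Consequence(str(r.consequence_class)),
            vaf=float(r.vaf),
            depth=int(r.depth),
            population_frequency=float(r.population_frequency),
        )
        for r in frame.itertuples()
    ]


# ---------------------------------------------------------------- tidy tables

_EVIDENCE_COLUMNS = ["lesion", "locus", "allele", "unique_reads", "copy_number"]
_DENSITY_COLUMNS = ["sample", "marker", "region", "density"]


def write_evidence_tsv(evidence: pd.DataFrame, path: str | Path) -> None:
    evidence[_EVIDENCE_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.9g")


def read_evidence_tsv(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    missing = set(_EVIDENCE_COLUMNS) - set(frame.columns)
    if missing:
        raise ParseError(f"{path}: evidence table missing columns: {sorted(missing)}")
    return frame


def write_densities_tsv(densities: pd.DataFrame, path: str | Path) -> None:
    densities[_DENSITY_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.9g")


def read_densities_tsv(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    missing = set(_DENSITY_COLUMNS) - set(frame.columns)
    if missing:
        raise ParseError(f"{path}: density table missing columns: {sorted(missing)}")
    return frame


def write_pairing_tsv(design: PairedDesign, path: str | Path) -> None:
    design.to_frame().to_csv(path, sep="\t", index=False)


def read_pairing_tsv(path: str | Path) -> PairedDesign:
    return PairedDesign.from_frame(pd.read_csv(path, sep="\t"))


def write_genotypes_tsv(genotypes: pd.DataFrame, path: str | Path) -> None:
    genotypes[["patient", "locus", "allele1", "allele2"]].to_csv(path, sep="\t", index=False)


def read_genotypes_tsv(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    missing = {"patient", "locus", "allele1", "allele2"} - set(frame.columns)
    if missing:
        raise ParseError(f"{path}: genotype table missing columns: {sorted(missing)}")
    return frame


# ---------------------------------------------------------------- config


def load_yaml_config(path: str | Path) -> dict:
    with open(path) as handle:
        config = yaml.safe_load(handle)
    if not isinstance(config, dict):
        raise ValidationError(f"{path}: config must be a YAML mapping")
    return config
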