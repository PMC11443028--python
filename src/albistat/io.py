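"""Readers and writers: cohort TSV dialect, annotation tables, minimal
VCF, generator configuration files and run manifests.

Cohort TSV dialect: one row per individual with columns
``individual_id``, ``label``, ``sex``, ``ancestry``, then one column per
variant id holding ``dosage[:score,depth,AB]`` (``.`` = missing), an
optional phased ``TYR_hap`` column (``hapA|hapB`` over the three TYR
sites), optional ``icd_codes`` (comma-separated) and optional trait
columns ``logmar``/``crt_um``. The record representation round-trips
losslessly through write/read.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import (
    Annotation,
    GenotypeCall,
    IndividualRecord,
    QualityRecord,
    VariantDef,
)
from .simulate import DiseaseModelConfig

__all__ = [
    "REQUIRED_COLUMNS", "format_call", "parse_call",
    "write_cohort_tsv", "read_cohort_tsv",
    "records_to_frame", "frame_to_records",
    "write_annotation_tsv", "read_annotation_tsv",
    "read_vcf_minimal", "load_config", "save_config", "write_manifest",
]

REQUIRED_COLUMNS = ("individual_id", "label", "sex", "ancestry")
_META_COLUMNS = set(REQUIRED_COLUMNS) | {"TYR_hap", "icd_codes", "logmar",
                                         "crt_um", "group", "modifier_count"}


def format_call(call: GenotypeCall | None) -> str:
    if call is None or call.dosage is None:
        return "."
    if call.quality is None:
        return str(call.dosage)
    q = call.quality
    return f"{call.dosage}:{q.genotype_score:g},{q.depth},{q.allele_balance:g}"


def parse_call(cell: str, ploidy: int = 2) -> GenotypeCall | None:
    cell = cell.strip()
    if cell in (".", ""):
        return None
    if ":" in cell:
        dos_s, qual_s = cell.split(":", 1)
        parts = qual_s.split(",")
        if len(parts) != 3:
            raise ValueError(f"malformed quality triple in cell {cell!r}")
        quality = QualityRecord(genotype_score=float(parts[0]),
                                depth=int(parts[1]),
                                allele_balance=float(parts[2]))
    else:
        dos_s, quality = cell, None
    return GenotypeCall(dosage=int(dos_s), ploidy=ploidy, quality=quality)


def write_cohort_tsv(
    records: list[IndividualRecord],
    path: str | Path,
    variant_ids: list[str] | None = None,
) -> None:
    """Serialize records in the cohort TSV dialect."""
    if variant_ids is None:
        seen: dict[str, None] = {}
        for ind in records:
            for vid in ind.genotypes:
                seen.setdefault(vid)
        variant_ids = list(seen)
    has_hap = any(
        c.phased_haplotypes for ind in records for c in ind.genotypes.values())
    has_icd = any(ind.icd_codes for ind in records)
    traits = sorted({t for ind in records for t in ind.traits})
    with open(path, "w") as fh:
        header = list(REQUIRED_COLUMNS) + variant_ids
        header += ["TYR_hap"] if has_hap else []
        header += ["icd_codes"] if has_icd else []
        header += traits
        fh.write("\t".join(header) + "\n")
        for ind in records:
            row = [ind.id, ind.label, ind.sex, ind.ancestry_label]
            row += [format_call(ind.genotypes.get(v)) for v in variant_ids]
            if has_hap:
                hap = next((c.phased_haplotypes for c in ind.genotypes.values()
                            if c.phased_haplotypes), None)
                row.append("|".join(hap) if hap else ".")
            if has_icd:
                row.append(",".join(sorted(ind.icd_codes)) or ".")
            for t in traits:
                v = ind.traits.get(t)
                row.append("." if v is None else f"{v:.10g}")
            fh.write("\t".join(row) + "\n")


def read_cohort_tsv(
    path: str | Path,
    variant_defs: dict[str, VariantDef] | None = None,
) -> list[IndividualRecord]:
    """Parse the cohort TSV dialect back into records.

    Errors name the offending row/column; duplicate individual ids and
    missing required columns are rejected. X-linked variants in males are
    read as ploidy-1 calls when variant definitions are supplied.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    dupes = df["individual_id"][df["individual_id"].duplicated()]
    if len(dupes):
        raise ValueError(f"duplicate individual ids: {sorted(set(dupes))}")
    variant_cols = [c for c in df.columns if c not in _META_COLUMNS]
    records = []
    for i, row in df.iterrows():
        genotypes: dict[str, GenotypeCall] = {}
        for col in variant_cols:
            ploidy = 2
            vdef = (variant_defs or {}).get(col)
            if vdef is not None and vdef.chrom_class == "x_linked" \
                    and row["sex"] == "male":
                ploidy = 1
            try:
                call = parse_call(str(row[col]), ploidy=ploidy)
            except (ValueError, TypeError) as exc:
                raise ValueError(
                    f"row {i + 2}, column {col!r}: {exc}") from None
            if call is not None:
                genotypes[col] = call
        if "TYR_hap" in df.columns and isinstance(row["TYR_hap"], str) \
                and "|" in row["TYR_hap"]:
            haps = tuple(row["TYR_hap"].split("|"))
            from .cohort import TYR_R402Q
            if TYR_R402Q in genotypes:
                genotypes[TYR_R402Q].phased_haplotypes = haps
        icd: set[str] = set()
        if "icd_codes" in df.columns and isinstance(row["icd_codes"], str) \
                and row["icd_codes"] != ".":
            icd = set(row["icd_codes"].split(","))
        traits = {}
        for t in ("logmar", "crt_um"):
            if t in df.columns and str(row[t]) not in (".", "nan"):
                traits[t] = float(row[t])
        records.append(IndividualRecord(
            id=row["individual_id"], label=row["label"], sex=row["sex"],
            ancestry_label=row["ancestry"], genotypes=genotypes,
            icd_codes=icd, traits=traits))
    return records


def records_to_frame(records: list[IndividualRecord]) -> pd.DataFrame:
    """Dosage-frame view of a record list (QC-unaware; NaN = missing)."""
    variant_ids: dict[str, None] = {}
    for ind in records:
        for vid in ind.genotypes:
            variant_ids.setdefault(vid)
    rows = []
    for ind in records:
        row = {"individual_id": ind.id, "label": ind.label, "sex": ind.sex,
               "ancestry": ind.ancestry_label}
        for vid in variant_ids:
            call = ind.genotypes.get(vid)
            row[vid] = math.nan if call is None or call.dosage is None \
                else float(call.dosage)
        hap = next((c.phased_haplotypes for c in ind.genotypes.values()
                    if c.phased_haplotypes), None)
        row["TYR_hap"] = "|".join(hap) if hap else None
        for t, v in ind.traits.items():
            row[t] = v
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_records(frame: pd.DataFrame) -> list[IndividualRecord]:
    """Record view of a simulator cohort frame."""
    variant_cols = [c for c in frame.columns if c not in _META_COLUMNS]
    records = []
    for _, row in frame.iterrows():
        genotypes = {}
        for vid in variant_cols:
            v = row[vid]
            if v is None or (isinstance(v, float) and math.isnan(v)):
                continue
            genotypes[vid] = GenotypeCall(dosage=int(v))
        hap = row.get("TYR_hap")
        if isinstance(hap, str) and "|" in hap:
            from .cohort import TYR_R402Q
            if TYR_R402Q in genotypes:
                genotypes[TYR_R402Q].phased_haplotypes = tuple(hap.split("|"))
        traits = {t: float(row[t]) for t in ("logmar", "crt_um")
                  if t in frame.columns and not pd.isna(row[t])}
        records.append(IndividualRecord(
            id=row["individual_id"], label=row.get("label", "control"),
            sex=row["sex"], ancestry_label=row["ancestry"],
            genotypes=genotypes, traits=traits))
    return records


# ------------------------------------------------------------- annotations

def write_annotation_tsv(
    annotations: dict[str, Annotation],
    variant_defs: dict[str, VariantDef],
    path: str | Path,
) -> None:
    with open(path, "w") as fh:
        fh.write("variant_id\tgene\tchrom_class\tacmg_class\thgmd_listed\tmaf\n")
        for vid in annotations:
            ann, vdef = annotations[vid], variant_defs[vid]
            fh.write(f"{vid}\t{vdef.gene}\t{vdef.chrom_class}\t{ann.acmg_class}"
                     f"\t{str(ann.hgmd_listed).lower()}\t{ann.maf:g}\n")


def read_annotation_tsv(
    path: str | Path,
) -> tuple[dict[str, Annotation], dict[str, VariantDef]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["variant_id", "gene", "chrom_class", "acmg_class",
                "hgmd_listed", "maf"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    annotations, variant_defs = {}, {}
    for _, row in df.iterrows():
        vid = row["variant_id"]
        annotations[vid] = Annotation(
            vid, acmg_class=row["acmg_class"],
            hgmd_listed=row["hgmd_listed"].strip().lower() in ("true", "1", "yes"),
            maf=float(row["maf"]))
        variant_defs[vid] = VariantDef(vid, gene=row["gene"],
                                       chrom_class=row["chrom_class"])
    return annotations, variant_defs


# -------------------------------------------------------------- minimal VCF

def read_vcf_minimal(
    path: str | Path,
    variant_map: dict[str, str],
    metadata: pd.DataFrame | None = None,
) -> list[IndividualRecord]:
    """Read GT/GQ/DP/AD for mapped sites from a (plain-text) VCF.

    ``variant_map`` maps ``"CHROM:POS:REF:ALT"`` (1-based position, as in
    the VCF) to internal variant ids. Haploid GTs are allowed (male X);
    allele balance is AD_alt / (AD_ref + AD_alt). Multi-allelic records
    at mapped sites must be pre-split with e.g. ``bcftools norm``.
    ``metadata`` (indexed by sample id) may supply label/sex/ancestry.
    """
    import pysam

    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    meta = metadata if metadata is not None else pd.DataFrame(index=samples)
    records = {
        s: IndividualRecord(
            id=s,
            label=meta.at[s, "label"] if "label" in meta.columns else "control",
            sex=meta.at[s, "sex"] if "sex" in meta.columns else "female",
            ancestry_label=(meta.at[s, "ancestry"]
                            if "ancestry" in meta.columns else "european"),
        )
        for s in samples
    }
    for rec in vf:
        if rec.alts is None:
            continue
        if len(rec.alts) > 1:
            key_any = f"{rec.chrom}:{rec.pos}"
            if any(k.startswith(key_any + ":") for k in variant_map):
                raise ValueError(
                    f"multi-allelic record at {rec.chrom}:{rec.pos}; "
                    "pre-split with 'bcftools norm -m -'")
            continue
        key = f"{rec.chrom}:{rec.pos}:{rec.ref}:{rec.alts[0]}"
        vid = variant_map.get(key)
        if vid is None:
            continue
        for s in samples:
            call = rec.samples[s]
            gt = call.get("GT")
            if gt is None or all(a is None for a in gt):
                continue
            alleles = [a for a in gt if a is not None]
            dosage = sum(1 for a in alleles if a == 1)
            ploidy = len(alleles)
            quality = None
            ad = call.get("AD")
            if ad is not None and call.get("GQ") is not None \
                    and call.get("DP") is not None:
                total = (ad[0] or 0) + (ad[1] or 0)
                ab = (ad[1] or 0) / total if total else 0.0
                quality = QualityRecord(genotype_score=float(call["GQ"]),
                                        depth=int(call["DP"]),
                                        allele_balance=ab)
            records[s].genotypes[vid] = GenotypeCall(
                dosage=dosage, ploidy=ploidy, quality=quality)
    return list(records.values())


# ------------------------------------------------------ config and manifest

def load_config(path: str | Path) -> DiseaseModelConfig:
    """DiseaseModelConfig from a YAML or JSON mapping (unknown keys rejected)."""
    text = Path(path).read_text()
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    known = {f.name for f in dataclasses.fields(DiseaseModelConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return DiseaseModelConfig(**data)


def save_config(config: DiseaseModelConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=False)


def config_hash(config: DiseaseModelConfig) -> str:
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def write_manifest(
    out_dir: str | Path,
    subcommand: str,
    config: DiseaseModelConfig | None,
    seed: int,
    input_paths: list[str],
    output_paths: list[str],
) -> Path:
    import albistat

    manifest = {
        "subcommand": subcommand,
        "config_hash": config_hash(config) if config else None,
        "seed": seed,
        "input_paths": [str(p) for p in input_paths],
        "output_paths": [str(p) for p in output_paths],
        "versions": {"albistat": albistat.__version__,
                     "numpy": np.__version__, "pandas": pd.__version__},
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    path = Path(out_dir) / f"manifest_{subcommand}.json"
    path.write_text(json.dumps(manifest, indent=2) + "\n")
    return path
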