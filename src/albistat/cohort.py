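"""Cohort data model, genotype QC, genotype-group classification and the
molecular-diagnosis exclusion engine.

The analysis studies the joint genotype at two common albinism-related
missense variants, TYR:c.1205G>A (p.Arg402Gln) and OCA2:c.1327G>A
(p.Val443Ile). Individuals are classified into genotype groups by their
joint allele dosage, with group A (neither variant) as reference and
group D the dual heterozygote. Two further common TYR variants,
c.-301C>T (promoter) and c.575C>A (p.Ser192Tyr), modify the effect of
R402Q and enter the regression as a summed allele-count covariate.

Individuals whose genotypes already explain albinism (a "molecular
diagnosis") are excluded so that the case-control signal isolates the
studied variant pair, as are carriers of other pathogenic TYR/OCA2
variants and individuals outside the European-like ancestry stratum.

Two APIs are provided: per-individual record functions (the reference
semantics) and vectorized DataFrame equivalents used on large simulated
cohorts; a test asserts they agree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

__all__ = [
    "TYR_PROMOTER", "TYR_S192Y", "TYR_R402Q", "OCA2_V443I",
    "AUTOSOMAL_ALBINISM_GENES", "X_LINKED_ALBINISM_GENES",
    "VariantDef", "QualityRecord", "GenotypeCall", "Annotation",
    "IndividualRecord", "GenotypeGroupAssignment", "ExclusionRecord",
    "ExclusionReason", "FilterConfig",
    "qc_genotype", "classify_genotype_group", "count_modifier_alleles",
    "risk_haplotype_count", "detect_molecular_diagnosis",
    "apply_cohort_filters", "assign_groups_frame", "filter_frame",
]

# canonical variant ids (HGVS-style, transcript-relative)
TYR_PROMOTER = "TYR:c.-301C>T"
TYR_S192Y = "TYR:c.575C>A"
TYR_R402Q = "TYR:c.1205G>A"
OCA2_V443I = "OCA2:c.1327G>A"

AUTOSOMAL_ALBINISM_GENES = frozenset(
    ["TYR", "OCA2", "TYRP1", "SLC45A2", "SLC24A5", "C10ORF11"]
    + [f"HPS{i}" for i in range(1, 11)]
    + ["LYST", "SLC38A8"]
)
X_LINKED_ALBINISM_GENES = frozenset(["GPR143", "FRMD7"])


class ExclusionReason(str, Enum):
    NON_EUROPEAN_ANCESTRY = "non_european_ancestry"
    SOLVED_BIALLELIC_AUTOSOMAL = "solved_biallelic_autosomal"
    SOLVED_HEMIZYGOUS_X = "solved_hemizygous_x"
    SOLVED_TYR_HAPLOTYPE_HOM = "solved_tyr_haplotype_hom"
    SOLVED_TYR_HAPLOTYPE_PLUS_HET = "solved_tyr_haplotype_plus_het"
    CARRIER_HET_PLP_TYR_OCA2 = "carrier_het_plp_tyr_oca2"
    FAILED_QC = "failed_qc"


@dataclass(frozen=True)
class VariantDef:
    id: str
    gene: str
    chrom_class: str = "autosomal"          # or "x_linked"
    role: str = "annotated_other"


@dataclass(frozen=True)
class QualityRecord:
    genotype_score: float
    depth: int
    allele_balance: float


@dataclass
class GenotypeCall:
    dosage: int | None                      # count of the named (alt) allele
    ploidy: int = 2
    phased_haplotypes: tuple[str, str] | None = None
    quality: QualityRecord | None = None

    def __post_init__(self) -> None:
        if self.dosage is not None and not 0 <= self.dosage <= self.ploidy:
            raise ValueError(f"dosage {self.dosage} exceeds ploidy {self.ploidy}")


@dataclass(frozen=True)
class Annotation:
    variant_id: str
    acmg_class: str = "unclassified"        # P, LP, VUS, LB, B, unclassified
    hgmd_listed: bool = False
    maf: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.maf <= 1.0:
            raise ValueError(f"maf {self.maf} outside [0,1]")


@dataclass
class IndividualRecord:
    id: str
    label: str                              # "case" / "control"
    sex: str                                # "male" / "female"
    ancestry_label: str = "european"
    genotypes: dict[str, GenotypeCall] = field(default_factory=dict)
    icd_codes: set[str] = field(default_factory=set)
    traits: dict[str, float] = field(default_factory=dict)


@dataclass
class GenotypeGroupAssignment:
    group: str                              # A-F or "unassigned"
    modifier_allele_count: int
    flags: list[str] = field(default_factory=list)


@dataclass
class ExclusionRecord:
    individual_id: str
    excluded: bool
    reasons: list[ExclusionReason] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)


@dataclass
class FilterConfig:
    european_labels: frozenset[str] = frozenset({"european"})
    autosomal_genes: frozenset[str] = AUTOSOMAL_ALBINISM_GENES
    x_linked_genes: frozenset[str] = X_LINKED_ALBINISM_GENES
    studied_ids: tuple[str, str] = (TYR_R402Q, OCA2_V443I)
    modifier_orientation: str = "risk"      # or "alt"
    apply_qc: bool = True


# ---------------------------------------------------------------- genotype QC

def qc_genotype(call: GenotypeCall) -> tuple[bool, str | None]:
    """Genotype-level quality filter.

    Fails calls with genotype score < 20, read depth < 10, heterozygote
    allele balance < 0.2 or > 0.8, homozygous-reference allele balance
    > 0.1, or homozygous-alternate allele balance < 0.9. All thresholds
    are strict inequalities, so boundary values pass. Calls without
    quality metadata pass by default. Returns (passed, reason).
    """
    q = call.quality
    if q is None:
        return True, None
    if not 0.0 <= q.allele_balance <= 1.0:
        raise ValueError(f"allele balance {q.allele_balance} outside [0,1]")
    if q.genotype_score < 20:
        return False, "low_genotype_score"
    if q.depth < 10:
        return False, "low_depth"
    d = call.dosage
    if d is None:
        return True, None
    if call.ploidy == 2 and d == 1:
        if q.allele_balance < 0.2 or q.allele_balance > 0.8:
            return False, "het_allele_balance"
    elif d == 0:
        if q.allele_balance > 0.1:
            return False, "homref_allele_balance"
    elif d == call.ploidy:
        if q.allele_balance < 0.9:
            return False, "homalt_allele_balance"
    return True, None


def _clean_dosage(ind: IndividualRecord, vid: str, apply_qc: bool = True) -> int | None:
    """Dosage after QC masking; None when absent, missing or QC-failed."""
    call = ind.genotypes.get(vid)
    if call is None or call.dosage is None:
        return None
    if apply_qc and not qc_genotype(call)[0]:
        return None
    return call.dosage


# --------------------------------------------------- genotype-group machinery

_GROUP_MAP = {(0, 0): "A", (1, 0): "B", (0, 1): "C",
              (1, 1): "D", (2, 0): "E", (2, 1): "F"}


def classify_genotype_group(
    ind: IndividualRecord,
    config: FilterConfig | None = None,
) -> GenotypeGroupAssignment:
    """Assign the genotype group from the joint dosage at the studied pair.

    (TYR R402Q, OCA2 V443I) dosage pairs map (0,0)->A, (1,0)->B, (0,1)->C,
    (1,1)->D, (2,0)->E, (2,1)->F; missing or any other combination (the
    paper defines no group for OCA2 homozygotes) -> unassigned.
    """
    cfg = config or FilterConfig()
    tyr = _clean_dosage(ind, cfg.studied_ids[0], cfg.apply_qc)
    oca2 = _clean_dosage(ind, cfg.studied_ids[1], cfg.apply_qc)
    group = _GROUP_MAP.get((tyr, oca2), "unassigned")
    count, flags = _modifier_count(ind, cfg)
    return GenotypeGroupAssignment(group=group, modifier_allele_count=count, flags=flags)


def _modifier_count(ind: IndividualRecord, cfg: FilterConfig) -> tuple[int, list[str]]:
    flags: list[str] = []
    promoter = _clean_dosage(ind, TYR_PROMOTER, cfg.apply_qc)
    s192y = _clean_dosage(ind, TYR_S192Y, cfg.apply_qc)
    count = 0
    if promoter is None:
        flags.append("modifier_missing_promoter")
    else:
        # the risk allele at c.-301 is the reference C; dosage counts the T alt
        count += (2 - promoter) if cfg.modifier_orientation == "risk" else promoter
    if s192y is None:
        flags.append("modifier_missing_s192y")
    else:
        count += s192y
    return count, flags


def count_modifier_alleles(
    ind: IndividualRecord, config: FilterConfig | None = None
) -> int:
    """Summed count (0-4) of common albinism-associated alleles.

    Counts c.-301C alleles (the reference allele at rs4547091, which the
    risk haplotypes carry) plus c.575C>A alternate alleles. Missing loci
    contribute zero and are flagged on the full assignment.
    """
    return _modifier_count(ind, config or FilterConfig())[0]


# ------------------------------------------------- molecular-diagnosis rules

def risk_haplotype_count(
    ind: IndividualRecord, config: FilterConfig | None = None
) -> tuple[int, bool]:
    """(certain count, ambiguous) of albinism-related TYR haplotypes.

    The two excluding haplotypes c.[-301C;575C>A;1205G>A] and
    c.[-301C;575C;1205G>A] differ only at c.575, so a risk haplotype is
    one carrying -301C together with 1205A. With phased data the count is
    read off directly. Unphased, only dosage-forced haplotypes are
    counted (pigeonhole: max(0, C-dosage + A-dosage - 2)); configurations
    where a risk haplotype is possible but not forced are ambiguous and
    flagged, never excluded.
    """
    cfg = config or FilterConfig()
    call = ind.genotypes.get(TYR_R402Q)
    if call is not None and call.phased_haplotypes is not None:
        # haplotype strings over (-301, 575, 1205) alleles, e.g. "CAA"
        n = sum(1 for h in call.phased_haplotypes if h[0] == "C" and h[2] == "A")
        return n, False
    c_dos = _clean_dosage(ind, TYR_PROMOTER, cfg.apply_qc)
    a_dos = _clean_dosage(ind, TYR_R402Q, cfg.apply_qc)
    if c_dos is None or a_dos is None:
        return 0, False
    c_alleles = 2 - c_dos                   # dosage counts the T alternate
    forced = max(0, c_alleles + a_dos - 2)
    possible = min(c_alleles, a_dos)
    return forced, possible > forced


def _plp_hgmd(ann: Annotation) -> bool:
    return ann.acmg_class in ("P", "LP") and ann.hgmd_listed


def _plp(ann: Annotation) -> bool:
    return ann.acmg_class in ("P", "LP")


def detect_molecular_diagnosis(
    ind: IndividualRecord,
    annotations: dict[str, Annotation],
    variant_defs: dict[str, VariantDef],
    config: FilterConfig | None = None,
) -> tuple[ExclusionReason | None, list[str]]:
    """First matching solved-genotype rule, or None.

    Rules: (i) homozygous P/LP HGMD-listed variant in an autosomal
    albinism gene; (ii) two or more distinct heterozygous such variants
    in one autosomal gene (presumed biallelic); (iii) hemizygous P/LP
    variant in GPR143 or FRMD7; (iv) the TYR risk haplotype in homozygous
    state; (v) one risk haplotype plus a heterozygous P/LP TYR variant.
    The studied pair never qualifies as the P/LP variant. Returns
    (reason, flags) with an ambiguity flag for unphased haplotypes.
    """
    cfg = config or FilterConfig()
    studied = set(cfg.studied_ids)
    het_by_gene: dict[str, int] = {}
    het_plp_tyr = False
    for vid, call in ind.genotypes.items():
        if vid in studied or call.dosage is None:
            continue
        if cfg.apply_qc and not qc_genotype(call)[0]:
            continue
        ann = annotations.get(vid)
        vdef = variant_defs.get(vid)
        if ann is None or vdef is None or not _plp_hgmd(ann):
            if ann is not None and vdef is not None and _plp(ann) \
                    and vdef.gene == "TYR" and call.ploidy == 2 and call.dosage == 1:
                het_plp_tyr = True
            continue
        if vdef.gene in cfg.autosomal_genes and vdef.chrom_class == "autosomal":
            if call.ploidy == 2 and call.dosage == 2:
                return ExclusionReason.SOLVED_BIALLELIC_AUTOSOMAL, []
            if call.ploidy == 2 and call.dosage == 1:
                het_by_gene[vdef.gene] = het_by_gene.get(vdef.gene, 0) + 1
                if vdef.gene == "TYR":
                    het_plp_tyr = True
        if vdef.gene in cfg.x_linked_genes and vdef.chrom_class == "x_linked":
            if call.ploidy == 1 and call.dosage == 1 and ind.sex == "male":
                return ExclusionReason.SOLVED_HEMIZYGOUS_X, []
    if any(n >= 2 for n in het_by_gene.values()):
        return ExclusionReason.SOLVED_BIALLELIC_AUTOSOMAL, []
    n_hap, ambiguous = risk_haplotype_count(ind, cfg)
    flags = ["haplotype_ambiguous"] if ambiguous else []
    if n_hap >= 2:
        return ExclusionReason.SOLVED_TYR_HAPLOTYPE_HOM, flags
    if n_hap >= 1 and het_plp_tyr:
        return ExclusionReason.SOLVED_TYR_HAPLOTYPE_PLUS_HET, flags
    return None, flags


def apply_cohort_filters(
    cohort: list[IndividualRecord],
    annotations: dict[str, Annotation],
    variant_defs: dict[str, VariantDef],
    config: FilterConfig | None = None,
) -> tuple[list[IndividualRecord], list[ExclusionRecord]]:
    """Case-control inclusion filter.

    Retains individuals with a European-like ancestry label, no genotype
    consistent with a molecular diagnosis of albinism, no heterozygous
    P/LP TYR/OCA2 variant other than the studied pair, and studied-variant
    genotypes that pass QC. Emits one ExclusionRecord per input
    individual; input order is preserved and the operation is idempotent.
    """
    cfg = config or FilterConfig()
    ids = [ind.id for ind in cohort]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate individual ids: {dupes}")
    kept: list[IndividualRecord] = []
    records: list[ExclusionRecord] = []
    for ind in cohort:
        reasons: list[ExclusionReason] = []
        if ind.ancestry_label not in cfg.european_labels:
            reasons.append(ExclusionReason.NON_EUROPEAN_ANCESTRY)
        # studied-variant QC: a call that exists but fails QC is a hard fail
        for vid in cfg.studied_ids:
            call = ind.genotypes.get(vid)
            if call is not None and cfg.apply_qc and not qc_genotype(call)[0]:
                reasons.append(ExclusionReason.FAILED_QC)
                break
        solved, flags = detect_molecular_diagnosis(ind, annotations, variant_defs, cfg)
        if solved is not None:
            reasons.append(solved)
        if _is_carrier_het_plp(ind, annotations, variant_defs, cfg):
            reasons.append(ExclusionReason.CARRIER_HET_PLP_TYR_OCA2)
        rec = ExclusionRecord(ind.id, excluded=bool(reasons),
                              reasons=reasons, flags=flags)
        records.append(rec)
        if not rec.excluded:
            kept.append(ind)
    return kept, records


def _is_carrier_het_plp(ind, annotations, variant_defs, cfg) -> bool:
    for vid, call in ind.genotypes.items():
        if vid in cfg.studied_ids or call.dosage is None:
            continue
        if cfg.apply_qc and not qc_genotype(call)[0]:
            continue
        ann, vdef = annotations.get(vid), variant_defs.get(vid)
        if ann is None or vdef is None:
            continue
        if vdef.gene in ("TYR", "OCA2") and _plp(ann) \
                and call.ploidy == 2 and call.dosage == 1:
            return True
    return False


# ----------------------------------------------------- vectorized frame path

def assign_groups_frame(
    df: pd.DataFrame, config: FilterConfig | None = None
) -> pd.DataFrame:
    """Vectorized group assignment and modifier count on a cohort frame.

    Expects dosage columns named by variant id (NaN = missing). Returns a
    copy with ``group`` and ``modifier_count`` columns.
    """
    cfg = config or FilterConfig()
    out = df.copy()
    tyr = df[cfg.studied_ids[0]].to_numpy(dtype=float)
    oca2 = df[cfg.studied_ids[1]].to_numpy(dtype=float)
    group = np.full(len(df), "unassigned", dtype=object)
    for (t, o), g in _GROUP_MAP.items():
        group[(tyr == t) & (oca2 == o)] = g
    out["group"] = group
    promoter = df[TYR_PROMOTER].to_numpy(dtype=float)
    s192y = df[TYR_S192Y].to_numpy(dtype=float)
    prom_alleles = (2 - promoter) if cfg.modifier_orientation == "risk" else promoter
    out["modifier_count"] = (np.nan_to_num(prom_alleles)
                             + np.nan_to_num(s192y)).astype(int)
    return out


def filter_frame(
    df: pd.DataFrame, config: FilterConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Vectorized inclusion filter for simulator-standard cohort frames.

    Covers ancestry and the TYR-haplotype homozygosity rule (the rules a
    clean simulated cohort can trigger); cohorts carrying spiked
    pathogenic annotations must go through :func:`apply_cohort_filters`.
    Returns (retained frame, per-individual exclusion frame).
    """
    cfg = config or FilterConfig()
    non_eur = ~df["ancestry"].isin(cfg.european_labels).to_numpy()
    if "TYR_hap" in df.columns and df["TYR_hap"].notna().all():
        haps = df["TYR_hap"].str.split("|", expand=True)
        n_risk = sum(
            ((haps[k].str[0] == "C") & (haps[k].str[2] == "A")).to_numpy()
            for k in (0, 1)
        )
    else:
        c_all = 2 - df[TYR_PROMOTER].to_numpy(dtype=float)
        n_risk = np.maximum(0, c_all + df[TYR_R402Q].to_numpy(dtype=float) - 2)
    hap_hom = np.asarray(n_risk) >= 2
    excluded = non_eur | hap_hom
    reasons = [
        ";".join(
            ([ExclusionReason.NON_EUROPEAN_ANCESTRY.value] if ne else [])
            + ([ExclusionReason.SOLVED_TYR_HAPLOTYPE_HOM.value] if hh else [])
        )
        for ne, hh in zip(non_eur, hap_hom)
    ]
    exclusions = pd.DataFrame({
        "individual_id": df["individual_id"],
        "excluded": excluded,
        "reasons": reasons,
    })
    return df.loc[~excluded].reset_index(drop=True), exclusions
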