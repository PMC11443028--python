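"""Synthetic case-control cohorts with the statistical structure the
digenic albinism analysis assumes.

The generator draws TYR three-site haplotypes (promoter c.-301C>T,
p.Ser192Tyr c.575C>A, p.Arg402Gln c.1205G>A) from a user-overridable
haplotype frequency table encoding the known linkage disequilibrium
between -301C and 575A, an independent OCA2 c.1327G>A allele pair under
Hardy-Weinberg, and disease status from a logistic penetrance model with
genotype-group, sex and modifier-allele effects. Case/control quotas are
then sampled without replacement, quantitative traits (LogMAR acuity and
central retinal thickness) come from group-shifted normals with optional
heavy-tail contamination, and a panel of neutral markers supports
genomic-inflation QC. Pathogenic-variant spiking exercises every
molecular-diagnosis exclusion rule at known counts.

All randomness flows from one seed; identical seeds give identical
cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import (
    OCA2_V443I,
    TYR_PROMOTER,
    TYR_R402Q,
    TYR_S192Y,
    Annotation,
    GenotypeCall,
    IndividualRecord,
    VariantDef,
    assign_groups_frame,
)

__all__ = [
    "DiseaseModelConfig", "SimulatedCohort", "default_tyr_haplotype_freqs",
    "simulate_genotypes", "assign_disease", "sample_case_control",
    "simulate_traits", "simulate_neutral_markers", "simulate_cohort",
    "spike_pathogenic_annotations",
]

# haplotype strings are alleles at (-301, 575, 1205) in order, e.g. "CAA"


def default_tyr_haplotype_freqs(
    freq_promoter_c: float = 0.60,
    maf_s192y: float = 0.36,
    maf_r402q: float = 0.27,
) -> dict[str, float]:
    """Constructed three-site haplotype table matching the single-site
    frequencies, with 575A placed exclusively on -301C backgrounds (the
    two alleles travel together) and 1205A independent of both."""
    if maf_s192y > freq_promoter_c:
        raise ValueError("575A cannot live exclusively on -301C backgrounds "
                         "when its frequency exceeds that of -301C")
    p_a_given_c = maf_s192y / freq_promoter_c
    table: dict[str, float] = {}
    for b1 in "CT":
        f1 = freq_promoter_c if b1 == "C" else 1.0 - freq_promoter_c
        for b2 in "AC":
            if b1 == "C":
                f2 = p_a_given_c if b2 == "A" else 1.0 - p_a_given_c
            else:
                f2 = 0.0 if b2 == "A" else 1.0
            for b3 in "AG":
                f3 = maf_r402q if b3 == "A" else 1.0 - maf_r402q
                f = f1 * f2 * f3
                if f > 0:
                    table[b1 + b2 + b3] = f
    return table


def _default_group_log_or() -> dict[str, float]:
    # D anchored at the dual-heterozygote point estimate; the single-het and
    # homozygote groups use plausible intermediate effects (see docs/methods.md)
    return {"B": math.log(1.5), "C": math.log(4.0), "D": math.log(12.8),
            "E": math.log(3.5), "F": math.log(15.0)}


def _default_trait_means() -> dict[str, dict[str, float]]:
    return {"A": {"logmar": 0.00, "crt_um": 270.0},
            "B": {"logmar": 0.01, "crt_um": 271.0},
            "C": {"logmar": 0.05, "crt_um": 274.0},
            "D": {"logmar": 0.12, "crt_um": 280.0}}


def _default_trait_sds() -> dict[str, dict[str, float]]:
    sd = {"logmar": 0.18, "crt_um": 22.0}
    return {g: dict(sd) for g in "ABCD"}


@dataclass
class DiseaseModelConfig:
    """Generative parameters for the synthetic cohort.

    Allele/haplotype frequencies follow the non-Finnish European values
    the analysis assumes (R402Q 27%, V443I 0.3%, -301C ~60%, S192Y ~36%).
    ``baseline_prevalence`` is the group-A disease probability at
    covariate zero; it is set to 1% (far above the population rarity of
    albinism) so that case quotas are reachable at simulation scale —
    this shifts only the intercept, not the odds ratios. Group effects
    are log odds ratios relative to group A.
    """

    maf_tyr_r402q: float = 0.27
    maf_oca2_v443i: float = 0.003
    freq_tyr_promoter_c: float = 0.60
    maf_tyr_s192y: float = 0.36
    tyr_haplotype_freqs: dict[str, float] = field(default_factory=default_tyr_haplotype_freqs)
    baseline_prevalence: float = 0.01
    group_log_or: dict[str, float] = field(default_factory=_default_group_log_or)
    sex_log_or: float = 0.0
    modifier_log_or: float = math.log(1.2)
    trait_means: dict[str, dict[str, float]] = field(default_factory=_default_trait_means)
    trait_sds: dict[str, dict[str, float]] = field(default_factory=_default_trait_sds)
    trait_contamination: float = 0.05
    n_cases: int = 204
    n_controls: int = 20350
    population_size: int = 60000
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        total = sum(self.tyr_haplotype_freqs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"haplotype frequencies sum to {total}, not 1")
        if any(f < 0 for f in self.tyr_haplotype_freqs.values()):
            raise ValueError("negative haplotype frequency")
        implied = {
            "freq_tyr_promoter_c": sum(
                f for h, f in self.tyr_haplotype_freqs.items() if h[0] == "C"),
            "maf_tyr_s192y": sum(
                f for h, f in self.tyr_haplotype_freqs.items() if h[1] == "A"),
            "maf_tyr_r402q": sum(
                f for h, f in self.tyr_haplotype_freqs.items() if h[2] == "A"),
        }
        for name, value in implied.items():
            stated = getattr(self, name)
            if abs(value - stated) > 1e-6:
                raise ValueError(
                    f"haplotype table implies {name}={value:.6f}, "
                    f"inconsistent with stated {stated:.6f}")
        if not 0 < self.baseline_prevalence < 1:
            raise ValueError("baseline_prevalence must be in (0,1)")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class SimulatedCohort:
    frame: pd.DataFrame
    truth: DiseaseModelConfig


def simulate_genotypes(
    config: DiseaseModelConfig, n: int, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw genotypes for ``n`` individuals.

    Two TYR haplotypes per individual from the haplotype table and an
    independent OCA2 allele pair (Hardy-Weinberg at the haplotype level);
    sex is Bernoulli(1/2); phased TYR haplotypes are retained.
    """
    haps = sorted(config.tyr_haplotype_freqs)
    freqs = np.array([config.tyr_haplotype_freqs[h] for h in haps])
    freqs = freqs / freqs.sum()
    idx = rng.choice(len(haps), size=(n, 2), p=freqs)
    hap_arr = np.array(haps)
    h1, h2 = hap_arr[idx[:, 0]], hap_arr[idx[:, 1]]
    h1_sites = h1.view("U1").reshape(n, 3)
    h2_sites = h2.view("U1").reshape(n, 3)

    def site_dosage(site: int, allele: str) -> np.ndarray:
        return ((h1_sites[:, site] == allele).astype(int)
                + (h2_sites[:, site] == allele).astype(int))

    df = pd.DataFrame({
        "individual_id": [f"sim{i:06d}" for i in range(n)],
        "sex": np.where(rng.random(n) < 0.5, "male", "female"),
        "ancestry": "european",
        TYR_PROMOTER: site_dosage(0, "T"),     # dosage counts the alternate
        TYR_S192Y: site_dosage(1, "A"),
        TYR_R402Q: site_dosage(2, "A"),
        OCA2_V443I: rng.binomial(2, config.maf_oca2_v443i, size=n),
        "TYR_hap": np.char.add(np.char.add(h1, "|"), h2),
    })
    return df


def assign_disease(
    genotypes: pd.DataFrame, config: DiseaseModelConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Bernoulli disease status from the logistic penetrance model.

    logit P(case) = logit(prevalence) + group effect + sex effect * male
    + modifier effect * modifier count. Genotype combinations outside
    groups A-F carry no group effect.
    """
    df = assign_groups_frame(genotypes)
    base = math.log(config.baseline_prevalence / (1 - config.baseline_prevalence))
    eff = np.array([config.group_log_or.get(g, 0.0) for g in df["group"]])
    eta = (base + eff
           + config.sex_log_or * (df["sex"] == "male").to_numpy(dtype=float)
           + config.modifier_log_or * df["modifier_count"].to_numpy(dtype=float))
    p = 1.0 / (1.0 + np.exp(-eta))
    df["label"] = np.where(rng.random(len(df)) < p, "case", "control")
    return df


def sample_case_control(
    population: pd.DataFrame,
    n_cases: int,
    n_controls: int,
    rng: np.random.Generator,
    config: DiseaseModelConfig | None = None,
) -> SimulatedCohort:
    """Sample exact case/control quotas uniformly without replacement."""
    parts = []
    for label, quota in (("case", n_cases), ("control", n_controls)):
        pool = population.index[population["label"] == label].to_numpy()
        if len(pool) < quota:
            raise ValueError(
                f"population has {len(pool)} {label}s but {quota} requested; "
                "increase population_size or baseline_prevalence")
        take = rng.choice(pool, size=quota, replace=False)
        parts.append(population.loc[np.sort(take)])
    frame = pd.concat(parts, ignore_index=True)
    return SimulatedCohort(frame=frame, truth=config)


def simulate_traits(
    cohort: pd.DataFrame, config: DiseaseModelConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Group-shifted LogMAR and central-retinal-thickness values.

    Normal within group with an optional contamination fraction drawn
    from a 3x-wider component, emulating the heavy tails seen in real
    acuity/OCT measurements. Groups without configured means fall back
    to group A.
    """
    df = cohort.copy()
    if "group" not in df.columns:
        df = assign_groups_frame(df)
    n = len(df)
    wide = rng.random(n) < config.trait_contamination
    for trait in ("logmar", "crt_um"):
        mean = np.array([
            config.trait_means.get(g, config.trait_means["A"])[trait]
            for g in df["group"]])
        sd = np.array([
            config.trait_sds.get(g, config.trait_sds["A"])[trait]
            for g in df["group"]])
        sd = np.where(wide, 3.0 * sd, sd)
        df[trait] = rng.normal(mean, sd)
    return df


def simulate_neutral_markers(
    cohort: pd.DataFrame,
    m: int = 35,
    rng: np.random.Generator | None = None,
    stratified: bool = False,
    divergence: float = 0.15,
    p_stratum_case: float = 0.9,
    p_stratum_control: float = 0.3,
) -> pd.DataFrame:
    """Panel of ``m`` neutral markers for genomic-inflation QC.

    Null mode: each marker Hardy-Weinberg at a frequency uniform in
    [0.05, 0.5], identical in cases and controls. Stratified mode splits
    the cohort into two latent strata with case-enriched membership and
    frequencies shifted by +/- ``divergence``, inducing inflation.
    Returns a frame of dosage columns ``lm001``..``lm{m}``.
    """
    if rng is None:
        raise ValueError("an explicit rng is required")
    n = len(cohort)
    freqs = rng.uniform(0.05, 0.5, size=m)
    if stratified:
        p1 = np.where(cohort["label"].to_numpy() == "case",
                      p_stratum_case, p_stratum_control)
        stratum = (rng.random(n) < p1).astype(int)
    else:
        stratum = np.zeros(n, dtype=int)
    out = {}
    for j in range(m):
        f = np.clip(freqs[j] + np.where(stratum == 1, divergence, -divergence)
                    if stratified else np.full(n, freqs[j]), 0.01, 0.99)
        out[f"lm{j + 1:03d}"] = rng.binomial(2, f)
    return pd.DataFrame(out, index=cohort.index)


def simulate_cohort(
    config: DiseaseModelConfig,
    rng: np.random.Generator | None = None,
    with_traits: bool = False,
) -> SimulatedCohort:
    """End-to-end generation: genotypes -> disease -> quota sampling."""
    rng = rng or config.rng()
    pop = simulate_genotypes(config, config.population_size, rng)
    pop = assign_disease(pop, config, rng)
    cohort = sample_case_control(pop, config.n_cases, config.n_controls, rng, config)
    if with_traits:
        cohort.frame = simulate_traits(cohort.frame, config, rng)
    return cohort


# ----------------------------------------------------------------- spiking

_SPIKE_KINDS = ("hom_plp", "biallelic_het", "hemizygous_x",
                "haplotype_hom", "haplotype_plus_het", "carrier_het")


def spike_pathogenic_annotations(
    cohort: list[IndividualRecord],
    spike_spec: dict[str, int],
    rng: np.random.Generator,
) -> tuple[list[IndividualRecord], dict[str, Annotation],
           dict[str, VariantDef], dict[str, str]]:
    """Inject rule-triggering genotypes at known counts.

    ``spike_spec`` maps spike kinds (hom_plp, biallelic_het,
    hemizygous_x, haplotype_hom, haplotype_plus_het, carrier_het) to
    counts. Distinct individuals are chosen for each spike; returns the
    modified cohort plus the spiked annotations/variant definitions and
    the ground-truth map individual id -> spike kind.
    """
    unknown = set(spike_spec) - set(_SPIKE_KINDS)
    if unknown:
        raise ValueError(f"unknown spike kinds: {sorted(unknown)}")
    total = sum(spike_spec.values())
    if total > len(cohort):
        raise ValueError(f"requested {total} spikes for {len(cohort)} individuals")

    annotations: dict[str, Annotation] = {}
    variant_defs: dict[str, VariantDef] = {}

    def _register(vid: str, gene: str, chrom: str = "autosomal",
                  acmg: str = "P", hgmd: bool = True) -> str:
        annotations[vid] = Annotation(vid, acmg_class=acmg, hgmd_listed=hgmd, maf=0.0005)
        variant_defs[vid] = VariantDef(vid, gene=gene, chrom_class=chrom)
        return vid

    chosen = rng.choice(len(cohort), size=total, replace=False)
    truth: dict[str, str] = {}
    pos = 0
    for kind in _SPIKE_KINDS:
        for k in range(spike_spec.get(kind, 0)):
            ind = cohort[chosen[pos]]
            pos += 1
            truth[ind.id] = kind
            if kind == "hom_plp":
                vid = _register(f"SLC45A2:spike_hom{k}", "SLC45A2")
                ind.genotypes[vid] = GenotypeCall(dosage=2)
            elif kind == "biallelic_het":
                v1 = _register(f"OCA2:spike_bi{k}a", "OCA2")
                v2 = _register(f"OCA2:spike_bi{k}b", "OCA2")
                ind.genotypes[v1] = GenotypeCall(dosage=1)
                ind.genotypes[v2] = GenotypeCall(dosage=1)
            elif kind == "hemizygous_x":
                vid = _register(f"GPR143:spike_x{k}", "GPR143", chrom="x_linked")
                ind.sex = "male"
                ind.genotypes[vid] = GenotypeCall(dosage=1, ploidy=1)
            elif kind == "haplotype_hom":
                _set_tyr_haplotypes(ind, ("CAA", "CCA"))
            elif kind == "haplotype_plus_het":
                _set_tyr_haplotypes(ind, ("CAA", "TCG"))
                vid = _register(f"TYR:spike_het{k}", "TYR")
                ind.genotypes[vid] = GenotypeCall(dosage=1)
            elif kind == "carrier_het":
                vid = _register(f"OCA2:spike_carrier{k}", "OCA2", acmg="LP")
                ind.genotypes[vid] = GenotypeCall(dosage=1)
    return cohort, annotations, variant_defs, truth


def _set_tyr_haplotypes(ind: IndividualRecord, haps: tuple[str, str]) -> None:
    """Overwrite the three TYR-site genotypes to match phased haplotypes."""
    dosages = {
        TYR_PROMOTER: sum(h[0] == "T" for h in haps),
        TYR_S192Y: sum(h[1] == "A" for h in haps),
        TYR_R402Q: sum(h[2] == "A" for h in haps),
    }
    for vid, d in dosages.items():
        ind.genotypes[vid] = GenotypeCall(dosage=d, phased_haplotypes=haps)
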