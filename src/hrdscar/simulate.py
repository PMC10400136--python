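"""Synthetic clinico-genomic cohort generator.

The generator encodes the statistical structure the downstream analysis
assumes: a latent per-patient HRD state drives (a) genomic scarring in the
allele-specific copy-number profile and indel spectrum, (b) the propensity
to carry biallelic alterations in homologous recombination repair (HRR)
genes, and (c) a differential survival benefit of platinum-containing
first-line chemotherapy (FOLFIRINOX) over gemcitabine + nab-paclitaxel (GP).

Defaults mirror a metastatic pancreatic-cancer setting: 9% HRD prevalence,
37% of HRD+ patients wildtype for the 14-gene HRR basket (non-genomic HRD),
GP-treated HRD− median overall survival 5.1 months, treatment hazard ratio
0.86 in HRD− and 0.37 in HRD+ patients, with delayed study entry (genomic
report lagging therapy start) that induces left truncation.

Latent truth is retained alongside the outputs for parameter-recovery
testing and is never consumed by analysis stages.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import BRCA_PALB2, GENE_LOCI, HRR_GENES, GenomeModel, default_genome
from .segments import (
    Segment,
    SegmentedCopyNumberProfile,
    read_seg,
    write_seg,
)
from .variants import ShortVariant, read_variants, write_variants

MB = 1_000_000

CLINICAL_COLUMNS = [
    "patient_id",
    "age",
    "sex",
    "treatment",
    "surgery",
    "ecog",
    "ca19_9_bin",
    "tissue",
    "entry_months",
    "os_months",
    "os_event",
    "ttnt_months",
    "ttnt_event",
    "pre_entry_event",
]

TRUTH_COLUMNS = [
    "patient_id",
    "hrd_status",
    "hrr_wildtype",
    "driver_gene",
    "driver_mechanism",
    "true_interaction_hr",
]


class ConfigurationError(ValueError):
    """A simulation parameter violates its constraints."""


def _check_prob(name: str, p: float) -> None:
    if not 0.0 <= p <= 1.0:
        raise ConfigurationError(f"{name}={p} is not a probability")


@dataclass(frozen=True)
class GeneAlterationModel:
    """Per-gene alteration rates for the 14-gene HRR basket.

    HRD+ patients either carry a single biallelic driver gene (drawn from
    ``driver_weights``) or are fully HRR-wildtype (non-genomic HRD, default
    fraction 0.37).  HRD− patients carry independent background alterations
    at ``background_rates``; a background alteration is biallelic with
    probability ``p_biallelic_background``, otherwise a heterozygous short
    variant or (with ``p_rearrangement``) a rearrangement of unknown
    zygosity.
    """

    hrr_wildtype_given_hrd: float = 0.37
    driver_weights: dict[str, float] = field(
        default_factory=lambda: {
            "BRCA2": 0.44,
            "BRCA1": 0.19,
            "PALB2": 0.16,
            "BARD1": 0.06,
            "RAD51C": 0.05,
            "RAD51D": 0.04,
            "RAD51B": 0.02,
            "ATM": 0.01,
            "BRIP1": 0.01,
            "CDK12": 0.01,
            "FANCL": 0.01,
        }
    )
    background_rates: dict[str, float] = field(
        default_factory=lambda: {
            "ATM": 0.050,
            "CHEK2": 0.030,
            "BRCA2": 0.020,
            "BRCA1": 0.010,
            "PALB2": 0.005,
            "BARD1": 0.005,
            "BRIP1": 0.005,
            "CDK12": 0.005,
            "CHEK1": 0.003,
            "FANCL": 0.003,
            "RAD51B": 0.003,
            "RAD51C": 0.003,
            "RAD51D": 0.003,
            "RAD54L": 0.003,
        }
    )
    p_biallelic_background: float = 0.15
    p_rearrangement: float = 0.10
    # biallelic mechanism mix: deep deletion / two hits / short variant under LOH
    mechanism_probs: dict[str, float] = field(
        default_factory=lambda: {
            "deep_deletion": 0.10,
            "two_hits": 0.25,
            "sv_under_loh": 0.65,
        }
    )

    def validate(self) -> None:
        _check_prob("hrr_wildtype_given_hrd", self.hrr_wildtype_given_hrd)
        _check_prob("p_biallelic_background", self.p_biallelic_background)
        _check_prob("p_rearrangement", self.p_rearrangement)
        for g, w in self.driver_weights.items():
            if g not in HRR_GENES:
                raise ConfigurationError(f"driver gene {g!r} not in HRR basket")
            if w < 0:
                raise ConfigurationError(f"driver weight for {g} is negative")
        for g, p in self.background_rates.items():
            _check_prob(f"background_rates[{g}]", p)
        if abs(sum(self.mechanism_probs.values()) - 1.0) > 1e-9:
            raise ConfigurationError("mechanism_probs must sum to 1")


@dataclass(frozen=True)
class ScarClassEffects:
    """Event rates for one latent class (HRD+ or HRD−).

    Counts are Poisson means per genome; lengths in Mb.
    """

    loh_rate: float  # interstitial LOH events (scar-sized, >15 Mb)
    lst_rate: float  # long copy-state change events (two transitions each)
    tai_rate: float  # telomeric allelic-imbalance events
    whole_arm_loh_prob: float  # per-arm whole-arm LOH probability
    mh_del_rate: float  # microhomology-flanked deletions (>=5 bp, mh >= 1 bp)
    other_del_rate: float  # deletions without flanking microhomology
    loh_len_mb: tuple[float, float] = (16.0, 45.0)
    lst_len_mb: tuple[float, float] = (10.0, 25.0)
    tai_len_mb: tuple[float, float] = (5.0, 20.0)

    def validate(self) -> None:
        for name in ("loh_rate", "lst_rate", "tai_rate", "mh_del_rate", "other_del_rate"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        _check_prob("whole_arm_loh_prob", self.whole_arm_loh_prob)


@dataclass(frozen=True)
class ScarEffectSizes:
    hrd_pos: ScarClassEffects = field(
        default_factory=lambda: ScarClassEffects(
            loh_rate=10.0,
            lst_rate=7.0,
            tai_rate=4.0,
            whole_arm_loh_prob=0.04,
            mh_del_rate=8.0,
            other_del_rate=3.0,
        )
    )
    hrd_neg: ScarClassEffects = field(
        default_factory=lambda: ScarClassEffects(
            loh_rate=1.2,
            lst_rate=1.0,
            tai_rate=0.5,
            whole_arm_loh_prob=0.01,
            mh_del_rate=0.8,
            other_del_rate=3.0,
        )
    )

    def for_status(self, hrd: bool) -> ScarClassEffects:
        return self.hrd_pos if hrd else self.hrd_neg

    def validate(self) -> None:
        self.hrd_pos.validate()
        self.hrd_neg.validate()


@dataclass(frozen=True)
class ClinicalModel:
    """Proportional-hazards outcome model with delayed entry.

    Baseline hazard is exponential, anchored by the median overall survival
    of a reference patient (GP-treated, HRD−, age 66, no surgery, ECOG 0,
    normal CA19-9, pancreas biopsy).  Time to next treatment (TTNT) is the
    minimum of a latent next-therapy time (its own PH draw) and death, so
    TTNT <= OS always.  Entry time models the genomic report lagging the
    start of first-line therapy; patients who die or are censored before
    entry are flagged (a left-truncated design never observes them).
    """

    median_os_gp_hrdneg: float = 5.1  # months
    treatment_hr_hrdneg: float = 0.86  # FOLFIRINOX vs GP in HRD−
    treatment_hr_hrdpos: float = 0.37  # FOLFIRINOX vs GP in HRD+
    hrd_hr: float = 0.87  # HRD+ vs HRD− main effect (GP arm)
    median_next_gp_hrdneg: float = 7.0  # latent next-therapy time baseline
    ttnt_treatment_hr_hrdneg: float = 0.82
    ttnt_treatment_hr_hrdpos: float = 0.48
    # log-hazard-ratio coefficients for clinical covariates
    beta_age_per_year: float = 0.015  # centered at 66
    beta_surgery: float = -0.35
    beta_ecog_1: float = 0.30
    beta_ecog_2plus: float = 0.70
    beta_ca19_lt59: float = 0.20
    beta_ca19_gt59: float = 0.50
    beta_tissue_liver: float = 0.25
    beta_tissue_other: float = 0.10
    censoring_rate: float = 0.30
    entry_mean_months: float = 1.0
    # EHR-derived dates are coarse; times are quantized to this resolution
    # (ceil for event/censor times, floor for entry, so orderings survive)
    time_resolution_months: float = 0.1
    missing_ecog: float = 0.25
    missing_ca19_9: float = 0.32
    # covariate marginals
    p_folfirinox: float = 0.52
    p_male: float = 0.55
    p_surgery: float = 0.21
    ecog_probs: tuple[float, float, float] = (0.40, 0.48, 0.12)  # 0 / 1 / >=2
    ca19_probs: tuple[float, float, float] = (0.14, 0.43, 0.43)  # normal / <59 / >59
    tissue_probs: tuple[float, float, float] = (0.29, 0.52, 0.19)  # pancreas/liver/other
    age_mean: float = 66.0
    age_sd: float = 8.0

    def validate(self) -> None:
        for name in (
            "median_os_gp_hrdneg",
            "treatment_hr_hrdneg",
            "treatment_hr_hrdpos",
            "hrd_hr",
            "median_next_gp_hrdneg",
            "ttnt_treatment_hr_hrdneg",
            "ttnt_treatment_hr_hrdpos",
        ):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        for name in ("censoring_rate", "missing_ecog", "missing_ca19_9",
                     "p_folfirinox", "p_male", "p_surgery"):
            _check_prob(name, getattr(self, name))
        if self.entry_mean_months < 0:
            raise ConfigurationError("entry_mean_months must be >= 0")
        if self.time_resolution_months < 0:
            raise ConfigurationError("time_resolution_months must be >= 0")
        for name in ("ecog_probs", "ca19_probs", "tissue_probs"):
            probs = getattr(self, name)
            if abs(sum(probs) - 1.0) > 1e-9 or min(probs) < 0:
                raise ConfigurationError(f"{name} must be a probability simplex")

    @property
    def interaction_hr(self) -> float:
        """Treatment x HRD interaction hazard ratio."""
        return self.treatment_hr_hrdpos / self.treatment_hr_hrdneg


@dataclass(frozen=True)
class SimulationConfig:
    n_patients: int = 1000
    hrd_prevalence: float = 0.09
    gene_alteration_model: GeneAlterationModel = field(default_factory=GeneAlterationModel)
    scar_effect_sizes: ScarEffectSizes = field(default_factory=ScarEffectSizes)
    clinical_model: ClinicalModel = field(default_factory=ClinicalModel)
    seed: int = 0

    def validate(self) -> "SimulationConfig":
        if self.n_patients < 0:
            raise ConfigurationError("n_patients must be >= 0")
        _check_prob("hrd_prevalence", self.hrd_prevalence)
        self.gene_alteration_model.validate()
        self.scar_effect_sizes.validate()
        self.clinical_model.validate()
        return self


@dataclass(frozen=True)
class GeneGenotype:
    altered: bool
    biallelic: bool
    mechanism: str  # deep_deletion | two_hits | sv_under_loh | het_sv | rearrangement | none


@dataclass
class LatentTruth:
    hrd_status: np.ndarray  # bool per patient
    genotypes: list[dict[str, GeneGenotype]]
    true_interaction_hr: float

    def to_frame(self, patient_ids: list[str]) -> pd.DataFrame:
        rows = []
        for pid, hrd, geno in zip(patient_ids, self.hrd_status, self.genotypes):
            driver = next(
                (g for g, gt in geno.items() if gt.biallelic), ""
            )
            mech = geno[driver].mechanism if driver else ""
            wildtype = not any(gt.altered for gt in geno.values())
            rows.append(
                (pid, int(hrd), int(wildtype), driver, mech, self.true_interaction_hr)
            )
        return pd.DataFrame(rows, columns=TRUTH_COLUMNS)


@dataclass
class Cohort:
    patient_ids: list[str]
    clinical: pd.DataFrame
    profiles: list[SegmentedCopyNumberProfile]
    variants: list[ShortVariant]
    truth: LatentTruth | None = None


def _split_rngs(seed: int, n: int) -> list[np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(n)
    return [np.random.default_rng(c) for c in children]


# ---------------------------------------------------------------------------
# genotypes


def simulate_genotypes(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> LatentTruth:
    """Draw latent HRD status and per-gene HRR genotypes for the cohort."""
    config.validate()
    rng = rng or np.random.default_rng(np.random.SeedSequence(config.seed).spawn(3)[0])
    gm = config.gene_alteration_model
    n = config.n_patients
    hrd = rng.random(n) < config.hrd_prevalence

    genes = list(HRR_GENES)
    driver_genes = list(gm.driver_weights)
    w = np.array([gm.driver_weights[g] for g in driver_genes], dtype=float)
    w = w / w.sum() if w.sum() > 0 else w
    mech_names = list(gm.mechanism_probs)
    mech_p = np.array([gm.mechanism_probs[m] for m in mech_names])

    genotypes: list[dict[str, GeneGenotype]] = []
    none_gt = GeneGenotype(False, False, "none")
    for i in range(n):
        geno = {g: none_gt for g in genes}
        if hrd[i]:
            if rng.random() >= gm.hrr_wildtype_given_hrd and len(driver_genes) > 0:
                driver = driver_genes[rng.choice(len(driver_genes), p=w)]
                mech = mech_names[rng.choice(len(mech_names), p=mech_p)]
                geno[driver] = GeneGenotype(True, True, mech)
        else:
            for g in genes:
                p_alt = gm.background_rates.get(g, 0.0)
                if p_alt > 0 and rng.random() < p_alt:
                    if rng.random() < gm.p_biallelic_background:
                        mech = mech_names[rng.choice(len(mech_names), p=mech_p)]
                        geno[g] = GeneGenotype(True, True, mech)
                    elif rng.random() < gm.p_rearrangement:
                        geno[g] = GeneGenotype(True, False, "rearrangement")
                    else:
                        geno[g] = GeneGenotype(True, False, "het_sv")
        genotypes.append(geno)
    return LatentTruth(hrd, genotypes, config.clinical_model.interaction_hr)


# ---------------------------------------------------------------------------
# copy-number profiles and variants


def _place_interval(
    rng: np.random.Generator,
    arm,
    length: int,
    taken: list[tuple[int, int]],
    anchor_telomere: bool = False,
) -> tuple[int, int] | None:
    """Find a non-overlapping interval of ``length`` bp on ``arm``."""
    length = min(length, arm.length)
    for _ in range(20):
        if anchor_telomere:
            start = arm.start if arm.name == "p" else arm.end - length
        else:
            start = arm.start + int(rng.integers(0, arm.length - length + 1))
        end = start + length
        if all(end <= s or start >= e for s, e in taken):
            return (start, end)
        if anchor_telomere:
            return None
    return None


def simulate_profile(
    hrd_status: bool,
    genome: GenomeModel,
    config: SimulationConfig,
    seed: int | np.random.Generator,
    sample_id: str = "S0",
    genotype: dict[str, GeneGenotype] | None = None,
) -> tuple[SegmentedCopyNumberProfile, list[ShortVariant]]:
    """Simulate one allele-specific profile plus its short-variant calls.

    Scarring is drawn directly at the segment level per the class effect
    sizes; genotype-driven events (deep deletions, variants under LOH) are
    placed first so the zygosity caller can recover the planted genotype.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    effects = config.scar_effect_sizes.for_status(hrd_status)
    arms = list(genome.arms())
    arm_weights = np.array([a.length for a in arms], dtype=float)
    arm_weights /= arm_weights.sum()

    # events[chrom] = list of (start, end, total, minor)
    events: dict[str, list[tuple[int, int, int, int]]] = {
        c: [] for c, _, _ in genome.chromosomes
    }
    taken: dict[str, list[tuple[int, int]]] = {c: [] for c in events}
    variants: list[ShortVariant] = []

    def add_event(chrom: str, start: int, end: int, total: int, minor: int) -> None:
        events[chrom].append((start, end, total, minor))
        taken[chrom].append((start, end))

    # --- genotype-driven events and variant records ---
    for gene, gt in (genotype or {}).items():
        if not gt.altered:
            continue
        chrom, pos = GENE_LOCI[gene]
        arm = genome.arm_at(chrom, pos)
        if gt.mechanism == "deep_deletion":
            half = int(rng.integers(250_000, 1_000_000))
            s = max(arm.start, pos - half)
            e = min(arm.end, pos + half)
            if all(e <= ts or s >= te for ts, te in taken[chrom]):
                add_event(chrom, s, e, 0, 0)
            variants.append(
                ShortVariant(sample_id, gene, "deep_deletion", True, chrom=chrom, pos=pos)
            )
        elif gt.mechanism == "two_hits":
            for _ in range(2):
                variants.append(
                    ShortVariant(
                        sample_id, gene, "SNV", True, het_flag=True, chrom=chrom, pos=pos
                    )
                )
        elif gt.mechanism == "sv_under_loh":
            half = int(rng.integers(1 * MB, 4 * MB))
            s = max(arm.start, pos - half)
            e = min(arm.end, pos + half)
            if all(e <= ts or s >= te for ts, te in taken[chrom]):
                add_event(chrom, s, e, 2, 0)
            variants.append(
                ShortVariant(
                    sample_id, gene, "SNV", True, het_flag=False, chrom=chrom, pos=pos
                )
            )
        elif gt.mechanism == "rearrangement":
            variants.append(
                ShortVariant(
                    sample_id, gene, "rearrangement", True, chrom=chrom, pos=pos
                )
            )
        else:  # het_sv
            variants.append(
                ShortVariant(
                    sample_id, gene, "SNV", True, het_flag=True, chrom=chrom, pos=pos
                )
            )

    # --- whole-arm LOH ---
    for arm in arms:
        if effects.whole_arm_loh_prob > 0 and rng.random() < effects.whole_arm_loh_prob:
            if not taken[arm.chrom]:
                add_event(arm.chrom, arm.start, arm.end, 2, 0)

    # --- scar events ---
    def draw_arm():
        return arms[rng.choice(len(arms), p=arm_weights)]

    for _ in range(rng.poisson(effects.loh_rate)):
        arm = draw_arm()
        length = int(rng.uniform(*effects.loh_len_mb) * MB)
        iv = _place_interval(rng, arm, length, taken[arm.chrom])
        if iv:
            add_event(arm.chrom, iv[0], iv[1], 2, 0)
    for _ in range(rng.poisson(effects.lst_rate)):
        arm = draw_arm()
        length = int(rng.uniform(*effects.lst_len_mb) * MB)
        iv = _place_interval(rng, arm, length, taken[arm.chrom])
        if iv:
            add_event(arm.chrom, iv[0], iv[1], 3, 1)
    for _ in range(rng.poisson(effects.tai_rate)):
        arm = draw_arm()
        max_len = min(effects.tai_len_mb[1] * MB, 0.8 * arm.length)
        length = int(rng.uniform(effects.tai_len_mb[0] * MB, max(max_len, effects.tai_len_mb[0] * MB + 1)))
        iv = _place_interval(rng, arm, length, taken[arm.chrom], anchor_telomere=True)
        if iv:
            add_event(arm.chrom, iv[0], iv[1], 3, 1)

    # --- indels (positions irrelevant to features; placed uniformly) ---
    n_mh = rng.poisson(effects.mh_del_rate)
    n_other = rng.poisson(effects.other_del_rate)
    for k in range(n_mh + n_other):
        arm = draw_arm()
        pos = arm.start + int(rng.integers(0, arm.length))
        if k < n_mh:
            del_len = 5 + int(rng.geometric(0.12))
            mh_len = 1 + int(rng.geometric(0.5))
        else:
            del_len = 1 + int(rng.geometric(0.35))
            mh_len = 0
        variants.append(
            ShortVariant(
                sample_id,
                "intergenic",
                "indel",
                False,
                del_length=del_len,
                microhomology_len=mh_len,
                het_flag=True,
                chrom=arm.chrom,
                pos=pos,
            )
        )

    # --- tile arms around events ---
    segments: list[Segment] = []
    for arm in arms:
        arm_events = sorted(
            (e for e in events[arm.chrom] if arm.start <= e[0] < arm.end),
            key=lambda e: e[0],
        )
        cursor = arm.start
        for s, e, total, minor in arm_events:
            if s > cursor:
                segments.append(Segment(arm.chrom, cursor, s, 2, 1))
            segments.append(Segment(arm.chrom, s, e, total, minor))
            cursor = e
        if cursor < arm.end:
            segments.append(Segment(arm.chrom, cursor, arm.end, 2, 1))
    return SegmentedCopyNumberProfile(sample_id, segments, genome), variants


# ---------------------------------------------------------------------------
# clinical records


def simulate_clinical(
    hrd_status: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    patient_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Draw clinical covariates and left-truncated survival outcomes.

    Overall survival follows an exponential proportional-hazards model on
    the covariates, treatment arm and latent HRD status (including the
    treatment x HRD interaction); TTNT is the minimum of a latent
    next-therapy time and death.  ``pre_entry_event`` flags patients whose
    observation ends before study entry — a left-truncated design would
    never enrol them, and the survival stage drops them with a logged count.
    """
    config.validate()
    cm = config.clinical_model
    hrd = np.asarray(hrd_status, dtype=bool)
    n = len(hrd)
    rng = rng or np.random.default_rng(np.random.SeedSequence(config.seed).spawn(3)[1])
    if patient_ids is None:
        patient_ids = [f"P{i:05d}" for i in range(n)]

    age = np.clip(np.round(rng.normal(cm.age_mean, cm.age_sd, n), 1), 30.0, 95.0)
    sex = np.where(rng.random(n) < cm.p_male, "male", "female")
    treatment = np.where(rng.random(n) < cm.p_folfirinox, "FOLFIRINOX", "GP")
    surgery = rng.random(n) < cm.p_surgery
    ecog = rng.choice(np.array(["0", "1", ">=2"]), size=n, p=cm.ecog_probs)
    ca19 = rng.choice(
        np.array(["normal", "<59xULN", ">59xULN"]), size=n, p=cm.ca19_probs
    )
    tissue = rng.choice(np.array(["pancreas", "liver", "other"]), size=n, p=cm.tissue_probs)

    folf = treatment == "FOLFIRINOX"
    # center the covariate contribution at its expectation so the anchor
    # medians describe the cohort-average patient, not the healthiest one
    expected_cov_lp = (
        cm.beta_surgery * cm.p_surgery
        + cm.beta_ecog_1 * cm.ecog_probs[1]
        + cm.beta_ecog_2plus * cm.ecog_probs[2]
        + cm.beta_ca19_lt59 * cm.ca19_probs[1]
        + cm.beta_ca19_gt59 * cm.ca19_probs[2]
        + cm.beta_tissue_liver * cm.tissue_probs[1]
        + cm.beta_tissue_other * cm.tissue_probs[2]
    )
    lp = (
        cm.beta_age_per_year * (age - 66.0)
        + cm.beta_surgery * surgery
        + cm.beta_ecog_1 * (ecog == "1")
        + cm.beta_ecog_2plus * (ecog == ">=2")
        + cm.beta_ca19_lt59 * (ca19 == "<59xULN")
        + cm.beta_ca19_gt59 * (ca19 == ">59xULN")
        + cm.beta_tissue_liver * (tissue == "liver")
        + cm.beta_tissue_other * (tissue == "other")
        - expected_cov_lp
        + np.log(cm.hrd_hr) * hrd
    )
    lp_os = lp + np.where(
        folf,
        np.log(cm.treatment_hr_hrdneg)
        + np.log(cm.interaction_hr) * hrd,
        0.0,
    )
    lam0 = np.log(2.0) / cm.median_os_gp_hrdneg
    t_death = rng.exponential(1.0, n) / (lam0 * np.exp(lp_os))

    lp_next = lp + np.where(
        folf,
        np.log(cm.ttnt_treatment_hr_hrdneg)
        + np.log(cm.ttnt_treatment_hr_hrdpos / cm.ttnt_treatment_hr_hrdneg) * hrd,
        0.0,
    )
    lam0n = np.log(2.0) / cm.median_next_gp_hrdneg
    t_next = rng.exponential(1.0, n) / (lam0n * np.exp(lp_next))
    t_ttnt = np.minimum(t_next, t_death)

    r = cm.censoring_rate
    if r >= 1.0:
        censor = rng.exponential(12.0, n)
        os_months, os_event = np.minimum(t_death, censor), np.zeros(n, dtype=bool)
        ttnt_months, ttnt_event = np.minimum(t_ttnt, censor), np.zeros(n, dtype=bool)
    else:
        if r <= 0.0:
            censor = np.full(n, np.inf)
        else:
            lam_c = lam0 * r / (1.0 - r)
            censor = rng.exponential(1.0 / lam_c, n)
        os_months = np.minimum(t_death, censor)
        os_event = t_death <= censor
        ttnt_months = np.minimum(t_ttnt, censor)
        ttnt_event = t_ttnt <= censor

    entry = (
        rng.exponential(cm.entry_mean_months, n)
        if cm.entry_mean_months > 0
        else np.zeros(n)
    )
    q = cm.time_resolution_months
    if q > 0:
        os_months = np.maximum(np.ceil(os_months / q), 1.0) * q
        ttnt_months = np.maximum(np.ceil(ttnt_months / q), 1.0) * q
        entry = np.floor(entry / q) * q
    pre_entry = os_months <= entry

    miss_ecog = rng.random(n) < cm.missing_ecog
    miss_ca19 = rng.random(n) < cm.missing_ca19_9
    ecog = np.where(miss_ecog, "missing", ecog)
    ca19 = np.where(miss_ca19, "missing", ca19)

    return pd.DataFrame(
        {
            "patient_id": patient_ids,
            "age": age,
            "sex": sex,
            "treatment": treatment,
            "surgery": surgery.astype(int),
            "ecog": ecog,
            "ca19_9_bin": ca19,
            "tissue": tissue,
            "entry_months": np.round(entry, 6),
            "os_months": np.round(os_months, 6),
            "os_event": os_event.astype(int),
            "ttnt_months": np.round(ttnt_months, 6),
            "ttnt_event": ttnt_event.astype(int),
            "pre_entry_event": pre_entry.astype(int),
        }
    )


# ---------------------------------------------------------------------------
# cohort orchestration and I/O


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Full cohort: genotypes, profiles + variants, clinical records, truth."""
    config.validate()
    genome = default_genome()
    seqs = np.random.SeedSequence(config.seed).spawn(3)
    rng_geno = np.random.default_rng(seqs[0])
    rng_clin = np.random.default_rng(seqs[1])
    profile_seqs = seqs[2].spawn(max(config.n_patients, 1))

    truth = simulate_genotypes(config, rng_geno)
    patient_ids = [f"P{i:05d}" for i in range(config.n_patients)]

    profiles: list[SegmentedCopyNumberProfile] = []
    variants: list[ShortVariant] = []
    for i, pid in enumerate(patient_ids):
        prof, vs = simulate_profile(
            bool(truth.hrd_status[i]),
            genome,
            config,
            np.random.default_rng(profile_seqs[i]),
            sample_id=pid,
            genotype=truth.genotypes[i],
        )
        profiles.append(prof)
        variants.extend(vs)

    clinical = simulate_clinical(truth.hrd_status, config, rng_clin, patient_ids)
    return Cohort(patient_ids, clinical, profiles, variants, truth)


def write_cohort(cohort: Cohort, out_dir) -> dict[str, Path]:
    """Emit the cohort as plain-text tables; round-trips through the readers."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "segments": out / "segments.seg.tsv",
        "variants": out / "variants.tsv",
        "clinical": out / "clinical.csv",
        "truth": out / "truth.csv",
    }
    write_seg(cohort.profiles, paths["segments"])
    write_variants(cohort.variants, paths["variants"])
    cohort.clinical.to_csv(paths["clinical"], index=False)
    if cohort.truth is not None:
        cohort.truth.to_frame(cohort.patient_ids).to_csv(paths["truth"], index=False)
    return paths


def read_cohort(in_dir, genome: GenomeModel | None = None) -> Cohort:
    """Read a cohort written by :func:`write_cohort` (truth not reloaded)."""
    p = Path(in_dir)
    profiles = read_seg(p / "segments.seg.tsv", genome)
    variants = read_variants(p / "variants.tsv")
    clinical = pd.read_csv(
        p / "clinical.csv",
        dtype={"patient_id": str, "ecog": str, "ca19_9_bin": str},
    )
    if clinical.empty:
        clinical = clinical.reindex(columns=CLINICAL_COLUMNS)
    patient_ids = list(clinical["patient_id"])
    return Cohort(patient_ids, clinical, profiles, variants, None)


def config_to_dict(config: SimulationConfig) -> dict:
    return dataclasses.asdict(config)


def config_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)
    if "gene_alteration_model" in d and isinstance(d["gene_alteration_model"], dict):
        d["gene_alteration_model"] = GeneAlterationModel(**d["gene_alteration_model"])
    if "scar_effect_sizes" in d and isinstance(d["scar_effect_sizes"], dict):
        se = dict(d["scar_effect_sizes"])
        for k in ("hrd_pos", "hrd_neg"):
            if isinstance(se.get(k), dict):
                sub = dict(se[k])
                for lk in ("loh_len_mb", "lst_len_mb", "tai_len_mb"):
                    if lk in sub and isinstance(sub[lk], list):
                        sub[lk] = tuple(sub[lk])
                se[k] = ScarClassEffects(**sub)
        d["scar_effect_sizes"] = ScarEffectSizes(**se)
    if "clinical_model" in d and isinstance(d["clinical_model"], dict):
        cmd = dict(d["clinical_model"])
        for k in ("ecog_probs", "ca19_probs", "tissue_probs"):
            if k in cmd and isinstance(cmd[k], list):
                cmd[k] = tuple(cmd[k])
        d["clinical_model"] = ClinicalModel(**cmd)
    return SimulationConfig(**d).validate()
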