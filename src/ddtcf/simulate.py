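"""Synthetic data with the statistical structure the analysis assumes.

Three layers, each seeded and reproducible:

1. **Cell mixtures.**  A sample with tumor cell fraction f is a mixture of
   tumor genomes (3 copies of BRAF exon 14, 2 of exon 3; 1 mutant + 1
   wild-type allele at V600E) and normal genomes (2/2; 0 + 2).  Expected
   per-channel concentrations follow exactly.

2. **Droplet partitioning.**  Template molecules load droplets as a Poisson
   process, so each of N droplets is positive with probability
   1 − exp(−c·v); positives are Binomial(N, ·) per channel.

3. **Growth competition.**  Tumor and microenvironmental cells compete in
   culture under a discrete replicator map

       f' = f·wT / (f·wT + (1 − f)·wE)

   with per-passage fitness multipliers wT (tumor) and wE (environment);
   SV40-TAg transduction multiplies wT by a boost factor from the
   transduction passage onward.  Unless wT equals wE exactly the map is
   monotone with absorbing states 0 and 1 — the two trajectory patterns seen
   in real cultures.  Tumor fitness declines linearly with patient age
   (floored), which reproduces the observed direction of the age effect.

Cohort-level defaults emulate the 18-sample study composition: ages
~ Normal(7.9, 5.4) truncated at 0, initial TCF ~ Normal(0.55, 0.23)
truncated to [0.20, 0.95], alteration frequencies 11:3:1:3
(fusion : V600E : duplication : other), transduction succeeding in 10/17 of
viable ABM cultures and never in NSM.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

from .cohort import Alteration, CohortRecord, Sex
from .errors import ValidationError
from .monitoring import (
    CultureTimepoint,
    CultureTrajectory,
    Medium,
    Stage,
    build_trajectory,
)
from .quant import Assay, Channel, DEFAULT_DROPLET_VOLUME_UL, DropletWell
from .tcf import TCFAssay, tcf_from_well

__all__ = [
    "MixtureSpec",
    "TrajectoryParams",
    "CohortParams",
    "SimConfig",
    "mixture_concentrations",
    "simulate_well",
    "simulate_trajectory",
    "simulate_cohort",
]

#: Copies per genome-equivalent, by channel, for tumor and normal cells.
_TUMOR_COPIES = {
    Channel.TARGET_EXON14: 3.0,
    Channel.REF_EXON3: 2.0,
    Channel.MUT_V600E: 1.0,
    Channel.WT_BRAF: 1.0,
}
_NORMAL_COPIES = {
    Channel.TARGET_EXON14: 2.0,
    Channel.REF_EXON3: 2.0,
    Channel.MUT_V600E: 0.0,
    Channel.WT_BRAF: 2.0,
}


@dataclass(frozen=True)
class MixtureSpec:
    """A tumor/normal cell mixture at known tumor cell fraction."""

    tcf_true: float
    assay: TCFAssay
    total_genomes_per_ul: float = 1000.0  # cell-equivalents/µl in the reaction

    def __post_init__(self) -> None:
        if not 0.0 <= self.tcf_true <= 1.0:
            raise ValidationError("tcf_true must lie in [0, 1]")
        if self.total_genomes_per_ul <= 0:
            raise ValidationError("total_genomes_per_ul must be positive")


@dataclass(frozen=True)
class SimConfig:
    """Shared simulation settings; the seed is mandatory."""

    seed: int
    n_droplets: int = 20000
    droplet_volume_ul: float = DEFAULT_DROPLET_VOLUME_UL

    def __post_init__(self) -> None:
        if self.n_droplets <= 0:
            raise ValidationError("n_droplets must be positive")
        if self.droplet_volume_ul <= 0:
            raise ValidationError("droplet_volume_ul must be positive")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class TrajectoryParams:
    """Growth-competition settings for one culture arm.

    ``fitness_tumor`` may be given directly or derived from ``age_years``
    via the linear age link wT = base − slope·age (floored) used by the
    cohort generator.
    """

    f0: float
    fitness_tumor: float = 1.0
    fitness_env: float = 1.0
    transduction_passage: Optional[int] = 2
    transduction_boost: float = 1.2
    n_passages: int = 60
    age_years: Optional[float] = None
    assay: Optional[TCFAssay] = TCFAssay.MUTATION

    def __post_init__(self) -> None:
        if not 0.0 <= self.f0 <= 1.0:
            raise ValidationError("f0 must lie in [0, 1]")
        if self.fitness_tumor <= 0 or self.fitness_env <= 0:
            raise ValidationError("fitness multipliers must be positive")
        if self.transduction_boost < 1.0:
            raise ValidationError("transduction_boost must be >= 1")
        if self.n_passages < 1:
            raise ValidationError("n_passages must be >= 1")


@dataclass(frozen=True)
class CohortParams:
    """Distribution settings for cohort-level simulation.

    Defaults reproduce the study composition: age and initial-TCF
    distributions, Table-1 alteration frequencies, per-arm transduction
    success rates, and an age-linked tumor fitness giving younger samples a
    higher chance of classifying ESTABLISHED.
    """

    age_mean: float = 7.9
    age_sd: float = 5.4
    f0_mean: float = 0.55
    f0_sd: float = 0.23
    f0_min: float = 0.20
    f0_max: float = 0.95
    alteration_probs: Mapping[Alteration, float] = field(
        default_factory=lambda: {
            Alteration.KIAA1549_BRAF_FUSION: 11 / 18,
            Alteration.BRAF_V600E: 3 / 18,
            Alteration.BRAF_DUPLICATION: 1 / 18,
            Alteration.OTHER: 3 / 18,
        }
    )
    p_viable_p1: float = 17 / 18
    p_transduced_abm: float = 10 / 17
    p_transduced_nsm: float = 0.0
    fitness_base: float = 1.15
    fitness_slope_per_year: float = 0.06
    fitness_floor: float = 0.5
    fitness_noise_sd: float = 0.05
    fitness_env: float = 1.0
    transduction_boost: float = 1.2
    transduction_passage: int = 2
    n_passages: int = 60

    def fitness_for_age(self, age_years: float, noise: float = 0.0) -> float:
        return max(
            self.fitness_floor,
            self.fitness_base - self.fitness_slope_per_year * age_years + noise,
        )


def mixture_concentrations(spec: MixtureSpec) -> dict[Channel, float]:
    """Exact expected per-channel concentrations for a mixture.

    For the duplication assay the exon14/exon3 ratio is (2+f)/2; for the
    mutation assay the mutant/wild-type ratio is f/(2−f).
    """
    f, g = spec.tcf_true, spec.total_genomes_per_ul
    channels = (
        (Channel.TARGET_EXON14, Channel.REF_EXON3)
        if spec.assay is TCFAssay.DUPLICATION
        else (Channel.MUT_V600E, Channel.WT_BRAF)
    )
    return {
        ch: g * (f * _TUMOR_COPIES[ch] + (1.0 - f) * _NORMAL_COPIES[ch]) for ch in channels
    }


def _assay_for_channels(channels) -> Assay:
    if set(channels) == {Channel.TARGET_EXON14, Channel.REF_EXON3}:
        return Assay.CNV_DUPLEX
    if set(channels) == {Channel.MUT_V600E, Channel.WT_BRAF}:
        return Assay.MUT_DUPLEX
    raise ValidationError(f"channel set {sorted(c.value for c in channels)} matches no duplex")


def simulate_well(
    concs: Mapping[Channel, float],
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
    well_id: str = "sim",
) -> DropletWell:
    """Partition a mixture into droplets and count positives per channel.

    Each droplet is positive for a channel with probability 1 − exp(−c·v);
    channels are independent given the loading (template molecules of the
    two targets partition independently after fragmentation).
    """
    if rng is None:
        rng = config.rng()
    n, v = config.n_droplets, config.droplet_volume_ul
    counts = {}
    for ch, c in concs.items():
        if c < 0:
            raise ValidationError("concentrations must be non-negative")
        p = 1.0 - np.exp(-c * v)
        counts[ch] = (int(rng.binomial(n, p)), n)
    return DropletWell(well_id=well_id, assay=_assay_for_channels(counts), channel_counts=counts)


def _replicator_step(f: float, w_tumor: float, w_env: float) -> float:
    if f in (0.0, 1.0):
        return f  # absorbing states
    num = f * w_tumor
    return num / (num + (1.0 - f) * w_env)


def simulate_trajectory(
    params: TrajectoryParams, config: SimConfig
) -> list[tuple[int, float, Optional[DropletWell]]]:
    """Iterate the growth-competition map, emitting a measured well per passage.

    Returns ``(passage, true_tcf, well)`` triples for passages
    0..n_passages.  The tumor fitness is multiplied by the transduction
    boost from ``transduction_passage`` onward; wells are ``None`` when the
    arm has no trackable assay.
    """
    rng = config.rng()
    out: list[tuple[int, float, Optional[DropletWell]]] = []
    f = params.f0
    for passage in range(params.n_passages + 1):
        well = None
        if params.assay is not None:
            spec = MixtureSpec(tcf_true=f, assay=params.assay)
            well = simulate_well(
                mixture_concentrations(spec), config, rng=rng, well_id=f"p{passage}"
            )
        out.append((passage, f, well))
        w_t = params.fitness_tumor
        if params.transduction_passage is not None and passage >= params.transduction_passage:
            w_t *= params.transduction_boost
        f = _replicator_step(f, w_t, params.fitness_env)
    return out


_LOCALIZATIONS = (
    ("Posterior fossa", 9 / 18),
    ("Brain stem", 2 / 18),
    ("Optic pathway", 2 / 18),
    ("Cerebellum", 1 / 18),
    ("Midbrain", 1 / 18),
    ("Parietooccipital", 1 / 18),
    ("Left temporal", 1 / 18),
    ("Spinal", 1 / 18),
)

_ASSAY_BY_ALTERATION = {
    Alteration.KIAA1549_BRAF_FUSION: TCFAssay.DUPLICATION,
    Alteration.BRAF_DUPLICATION: TCFAssay.DUPLICATION,
    Alteration.BRAF_V600E: TCFAssay.MUTATION,
}


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float) -> float:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return x
    return min(max(mean, lo), hi)  # pathological settings: fall back to the clipped mean


def _measure(f: float, assay: Optional[TCFAssay], config: SimConfig, rng, well_id: str):
    """True fraction -> simulated well -> estimated TCF (None if untrackable)."""
    if assay is None:
        return None
    spec = MixtureSpec(tcf_true=f, assay=assay)
    well = simulate_well(mixture_concentrations(spec), config, rng=rng, well_id=well_id)
    return tcf_from_well(well, config.droplet_volume_ul).tcf


def _simulate_arm(
    sample_id: str,
    medium: Medium,
    f0: float,
    w_tumor: float,
    params: CohortParams,
    assay: Optional[TCFAssay],
    config: SimConfig,
    rng: np.random.Generator,
) -> CultureTrajectory:
    tps = [
        CultureTimepoint(
            Stage.P0, 0, Medium.NONE, _measure(f0, assay, config, rng, f"{sample_id}-p0")
        )
    ]
    viable = rng.random() < params.p_viable_p1
    if viable:
        f1 = _replicator_step(f0, w_tumor, params.fitness_env)
        tps.append(
            CultureTimepoint(
                Stage.P1, 1, medium, _measure(f1, assay, config, rng, f"{sample_id}-p1")
            )
        )
        p_trans = params.p_transduced_abm if medium is Medium.ABM else params.p_transduced_nsm
        if rng.random() < p_trans:
            f = f1
            for passage in range(1, params.transduction_passage):
                f = _replicator_step(f, w_tumor, params.fitness_env)
            tps.append(
                CultureTimepoint(
                    Stage.TRANSDUCED,
                    params.transduction_passage,
                    medium,
                    _measure(f, assay, config, rng, f"{sample_id}-tr"),
                )
            )
            boosted = w_tumor * params.transduction_boost
            for passage in range(params.transduction_passage, params.n_passages):
                f = _replicator_step(f, boosted, params.fitness_env)
            tps.append(
                CultureTimepoint(
                    Stage.FINAL,
                    params.n_passages,
                    medium,
                    _measure(f, assay, config, rng, f"{sample_id}-final"),
                )
            )
    return build_trajectory(sample_id, medium, tps)


def simulate_cohort(
    n_samples: int,
    params: CohortParams | None = None,
    config: SimConfig | None = None,
) -> tuple[list[CohortRecord], list[CultureTrajectory]]:
    """Draw a synthetic cohort and its ABM/NSM culture trajectories.

    Every sample gets a clinical record emulating the reference-table
    composition and two culture arms.  Tumor fitness is linked negatively to
    age, so younger samples are likelier to end ESTABLISHED.  All randomness
    derives from ``config.seed`` through per-sample spawned substreams, so
    runs are bit-reproducible.
    """
    if n_samples < 1:
        raise ValidationError("n_samples must be >= 1")
    params = params or CohortParams()
    config = config or SimConfig(seed=0)
    alt_list = list(params.alteration_probs)
    probs = np.asarray([params.alteration_probs[a] for a in alt_list], dtype=float)
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValidationError("alteration probabilities must sum to 1")

    records: list[CohortRecord] = []
    trajectories: list[CultureTrajectory] = []
    streams = np.random.SeedSequence(config.seed).spawn(n_samples)
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        sid = f"SIM{i + 1:03d}"
        age = _truncated_normal(rng, params.age_mean, params.age_sd, 0.0, np.inf)
        sex = Sex.F if rng.random() < 0.5 else Sex.M
        alteration = alt_list[rng.choice(len(alt_list), p=probs)]
        assay = _ASSAY_BY_ALTERATION.get(alteration)
        f0 = _truncated_normal(rng, params.f0_mean, params.f0_sd, params.f0_min, params.f0_max)
        w_tumor = params.fitness_for_age(age, rng.normal(0.0, params.fitness_noise_sd))

        loc = _LOCALIZATIONS[
            rng.choice(len(_LOCALIZATIONS), p=[w for _, w in _LOCALIZATIONS])
        ][0]
        meth_done = rng.random() < 17 / 18
        if not meth_done:
            meth_class, score = "NOT_DONE", None
        elif rng.random() < 1 / 17:
            meth_class, score = "NOT_CLASSIFIABLE", None
        else:
            meth_class = "PA_SIM"
            score = float(rng.uniform(0.69, 1.0))
        records.append(
            CohortRecord(
                sample_id=sid,
                sex=sex,
                age_years=round(float(age), 1),
                histology="Pilocytic astrocytoma" if rng.random() < 17 / 18 else "Low grade glioma",
                localization=loc,
                methylation_class=meth_class,
                classifier_score=None if score is None else round(score, 2),
                alteration=alteration,
                detection_method="synthetic",
            )
        )
        for medium in (Medium.ABM, Medium.NSM):
            trajectories.append(
                _simulate_arm(sid, medium, f0, w_tumor, params, assay, config, rng)
            )
    return records, trajectories
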