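"""Tumor cell fraction (TCF) from duplex ddPCR concentrations.

Two estimators, one per assay:

Duplication assay (exon-14 copy gain).  Tumor cells carry 3 copies of BRAF
exon 14 against 2 copies of the exon-3 reference; microenvironmental cells
carry 2/2.  A mixture with tumor fraction f therefore has mean exon-14 copy
number CN = 2 + f, estimated as

    CN = 2 * c(exon14) / c(exon3),        TCF = CN − 2

Mutation assay (V600E).  Tumor cells are heterozygous (1 mutant + 1
wild-type allele), normal cells wild-type only, so a mixture at fraction f
has mutant:wild-type concentration ratio r = f / (2 − f) and

    TCF = 2r / (1 + r)

Both estimators are clamped to [0, 1] with an audit flag: droplet-count
noise can push the raw value slightly outside the physical range, and a
mutant excess r > 1 violates the heterozygosity assumption.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import SaturationError, ValidationError
from .quant import (
    Assay,
    Channel,
    DEFAULT_DROPLET_VOLUME_UL,
    DropletWell,
    estimate_lambda,
)

__all__ = [
    "TCFAssay",
    "TCFEstimate",
    "copy_number_from_duplex",
    "tcf_from_duplication",
    "tcf_from_mutation",
    "tcf_from_well",
    "tcf_confidence_interval",
    "tcf_percent",
]


class TCFAssay(str, enum.Enum):
    DUPLICATION = "DUPLICATION"
    MUTATION = "MUTATION"


@dataclass(frozen=True)
class TCFEstimate:
    """A tumor cell fraction with its provenance and optional interval."""

    tcf: float
    assay: TCFAssay
    copy_number: Optional[float] = None  # duplication assay: mean exon-14 CN
    ratio: Optional[float] = None  # mutation assay: c(mut)/c(wt)
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    clamped_flag: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.tcf <= 1.0:
            raise ValidationError(f"tcf must lie in [0, 1], got {self.tcf}")
        if self.ci_low is not None and self.ci_high is not None:
            if not self.ci_low <= self.tcf <= self.ci_high:
                raise ValidationError("TCF confidence interval must bracket the estimate")

    @property
    def tcf_percent(self) -> float:
        return tcf_percent(self.tcf)


def _clamp01(x: float) -> tuple[float, bool]:
    if x < 0.0:
        return 0.0, True
    if x > 1.0:
        return 1.0, True
    return x, False


def copy_number_from_duplex(conc_exon14: float, conc_exon3: float) -> float:
    """Mean BRAF exon-14 copy number from the duplex concentrations.

    The exon-3 reference is present at 2 copies per cell in every cell, so
    CN(exon14) = 2 * c(exon14)/c(exon3).
    """
    if conc_exon3 <= 0:
        raise ValidationError("no reference (exon 3) signal: copy number undefined")
    if conc_exon14 < 0:
        raise ValidationError("exon-14 concentration must be non-negative")
    return 2.0 * conc_exon14 / conc_exon3

def tcf_from_duplication(conc_exon14: float, conc_exon3: float) -> TCFEstimate:
    """TCF from the exon-14/exon-3 duplication duplex: CN − 2, clamped."""
    cn = copy_number_from_duplex(conc_exon14, conc_exon3)
    tcf, clamped = _clamp01(cn - 2.0)
    return TCFEstimate(tcf=tcf, assay=TCFAssay.DUPLICATION, copy_number=cn, clamped_flag=clamped)


def tcf_from_mutation(conc_mut: float, conc_wt: float) -> TCFEstimate:
    """TCF from the V600E duplex assuming a heterozygous mutation.

    r = c(mut)/c(wt); TCF = 2r/(1+r), clamped with a flag when r > 1
    (more mutant than wild-type signal is impossible under heterozygosity).
    """
    if conc_mut < 0:
        raise ValidationError("mutant concentration must be non-negative")
    if conc_wt <= 0:
        if conc_mut > 0:
            raise ValidationError(
                "no wild-type signal with mutant present: outside the heterozygous model"
            )
        raise ValidationError("no wild-type signal: TCF undefined")
    r = conc_mut / conc_wt
    tcf, clamped = _clamp01(2.0 * r / (1.0 + r))
    return TCFEstimate(tcf=tcf, assay=TCFAssay.MUTATION, ratio=r, clamped_flag=clamped)


def tcf_from_well(well: DropletWell, droplet_volume_ul: float = DEFAULT_DROPLET_VOLUME_UL) -> TCFEstimate:
    """Point TCF estimate from a single duplex well (no interval).

    The droplet volume cancels in both concentration ratios but is kept in
    the signature for symmetry with the quantification layer.
    """
    lam = {
        ch: estimate_lambda(k, n) / droplet_volume_ul
        for ch, (k, n) in well.channel_counts.items()
    }
    if well.assay is Assay.CNV_DUPLEX:
        return tcf_from_duplication(lam[Channel.TARGET_EXON14], lam[Channel.REF_EXON3])
    return tcf_from_mutation(lam[Channel.MUT_V600E], lam[Channel.WT_BRAF])


def tcf_confidence_interval(
    well: DropletWell,
    droplet_volume_ul: float = DEFAULT_DROPLET_VOLUME_UL,
    ci_level: float = 0.95,
    n_boot: int = 2000,
    seed: int | None = None,
) -> TCFEstimate:
    """TCF with a parametric-bootstrap confidence interval.

    Both channels' positive counts are resampled jointly from
    Binomial(N, k/N), the assay's TCF formula is re-applied to each
    resample, and the empirical quantiles at the requested level form the
    interval.  Deterministic given ``seed``.
    """
    if seed is None:
        raise ValidationError("a seed is required for the bootstrap CI")
    if not 0 < ci_level < 1:
        raise ValidationError("ci_level must lie in (0, 1)")
    for ch, (k, n) in well.channel_counts.items():
        if k == n:
            raise SaturationError(
                f"well {well.well_id}/{ch.value}: all droplets positive, TCF undefined"
            )
    point = tcf_from_well(well, droplet_volume_ul)

    rng = np.random.default_rng(seed)
    chans = list(well.channel_counts)
    lam_star = {}
    for ch in chans:
        k, n = well.channel_counts[ch]
        k_s = np.minimum(rng.binomial(n, k / n, size=n_boot), n - 1)
        lam_star[ch] = -np.log1p(-k_s / n)
    if well.assay is Assay.CNV_DUPLEX:
        ref = lam_star[Channel.REF_EXON3]
        ok = ref > 0
        cn = 2.0 * lam_star[Channel.TARGET_EXON14][ok] / ref[ok]
        tcf_s = np.clip(cn - 2.0, 0.0, 1.0)
    else:
        wt = lam_star[Channel.WT_BRAF]
        ok = wt > 0
        r = lam_star[Channel.MUT_V600E][ok] / wt[ok]
        tcf_s = np.clip(2.0 * r / (1.0 + r), 0.0, 1.0)
    if tcf_s.size == 0:
        raise ValidationError(f"well {well.well_id}: reference channel empty in every resample")
    alpha = 1.0 - ci_level
    lo, hi = np.quantile(tcf_s, [alpha / 2, 1 - alpha / 2])
    return TCFEstimate(
        tcf=point.tcf,
        assay=point.assay,
        copy_number=point.copy_number,
        ratio=point.ratio,
        ci_low=min(float(lo), point.tcf),
        ci_high=max(float(hi), point.tcf),
        clamped_flag=point.clamped_flag,
    )


def tcf_percent(tcf: float) -> float:
    """Convert a fraction in [0, 1] to percent."""
    if not 0.0 <= tcf <= 1.0:
        raise ValidationError(f"tcf must lie in [0, 1], got {tcf}")
    return 100.0 * tcf
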