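"""Poisson quantification of droplet-digital PCR wells.

A ddPCR reaction is partitioned into ~20 000 droplets of fixed volume v.
Template molecules distribute across droplets approximately as a Poisson
process, so a droplet is positive with probability 1 − exp(−λ), where λ is
the mean number of copies per droplet.  Observing k positive droplets out of
N gives the maximum-likelihood estimate

    λ̂ = −ln(1 − k/N),      concentration = λ̂ / v   [copies/µl]

Both assays used here are duplexes: two hydrolysis-probe channels read out
on the same droplets (target exon 14 vs reference exon 3 for the copy-number
assay; mutant vs wild-type BRAF for the V600E assay).

Confidence intervals are parametric bootstrap: resample k* ~ Binomial(N, k/N),
re-estimate, and take empirical quantiles.  The same machinery propagates
droplet-count noise into tumor-cell-fraction intervals downstream.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Mapping, Sequence, Tuple

import numpy as np

from .errors import SaturationError, ValidationError

__all__ = [
    "Assay",
    "Channel",
    "ASSAY_CHANNELS",
    "DEFAULT_DROPLET_VOLUME_UL",
    "DropletWell",
    "ConcentrationEstimate",
    "estimate_lambda",
    "concentration",
    "merge_wells",
    "read_droplet_csv",
    "write_concentration_csv",
]

#: Droplet volume of the instrument family behind the BRAF assays (0.85 nl);
#: the partition volume fixes the copies/µl scale and is config-overridable.
DEFAULT_DROPLET_VOLUME_UL = 0.00085


class Assay(str, enum.Enum):
    CNV_DUPLEX = "CNV_DUPLEX"  # BRAF exon 14 (target) vs exon 3 (reference)
    MUT_DUPLEX = "MUT_DUPLEX"  # BRAF V600E (mutant) vs wild-type BRAF


class Channel(str, enum.Enum):
    TARGET_EXON14 = "TARGET_EXON14"
    REF_EXON3 = "REF_EXON3"
    MUT_V600E = "MUT_V600E"
    WT_BRAF = "WT_BRAF"


ASSAY_CHANNELS: Mapping[Assay, tuple[Channel, Channel]] = {
    Assay.CNV_DUPLEX: (Channel.TARGET_EXON14, Channel.REF_EXON3),
    Assay.MUT_DUPLEX: (Channel.MUT_V600E, Channel.WT_BRAF),
}


@dataclass(frozen=True)
class DropletWell:
    """Raw per-channel positive/total droplet counts for one duplex well."""

    well_id: str
    assay: Assay
    channel_counts: Mapping[Channel, Tuple[int, int]]  # channel -> (k, N)

    def __post_init__(self) -> None:
        expected = set(ASSAY_CHANNELS[self.assay])
        got = set(self.channel_counts)
        if got != expected:
            raise ValidationError(
                f"well {self.well_id}: assay {self.assay.value} requires channels "
                f"{sorted(c.value for c in expected)}, got {sorted(c.value for c in got)}"
            )
        totals = set()
        for ch, (k, n) in self.channel_counts.items():
            if n <= 0:
                raise ValidationError(f"well {self.well_id}/{ch.value}: total droplets must be > 0")
            if not 0 <= k <= n:
                raise ValidationError(
                    f"well {self.well_id}/{ch.value}: need 0 <= positives <= total, got k={k}, N={n}"
                )
            totals.add(n)
        if len(totals) != 1:
            raise ValidationError(
                f"well {self.well_id}: duplex channels must share the same droplet count"
            )

    @property
    def n_droplets(self) -> int:
        return next(iter(self.channel_counts.values()))[1]


@dataclass(frozen=True)
class ConcentrationEstimate:
    """Target concentration in copies/µl with a bootstrap interval."""

    copies_per_ul: float
    lam: float  # mean copies per droplet
    ci_low: float
    ci_high: float
    droplet_volume_ul: float
    saturated_flag: bool = False

    def __post_init__(self) -> None:
        if not self.ci_low <= self.copies_per_ul <= self.ci_high:
            raise ValidationError("confidence interval must bracket the point estimate")


def estimate_lambda(k: int, n: int) -> float:
    """Mean copies per droplet from k positive droplets out of n.

    Raises :class:`SaturationError` when every droplet is positive and
    :class:`ValidationError` on impossible counts.
    """
    if n <= 0:
        raise ValidationError(f"total droplet count must be positive, got N={n}")
    if k < 0 or k > n:
        raise ValidationError(f"need 0 <= k <= N, got k={k}, N={n}")
    if k == n:
        raise SaturationError(
            f"all {n} droplets positive: concentration is unbounded (dilute and re-run)"
        )
    if k == 0:
        return 0.0
    return -math.log1p(-k / n)


def concentration(
    well_channel: Tuple[int, int],
    droplet_volume_ul: float = DEFAULT_DROPLET_VOLUME_UL,
    ci_level: float = 0.95,
    n_boot: int = 2000,
    seed: int | None = None,
) -> ConcentrationEstimate:
    """Estimate copies/µl for one channel with a parametric bootstrap CI.

    The bootstrap resamples the positive count k* ~ Binomial(N, k/N),
    re-applies the Poisson estimator and takes the empirical
    (1−ci_level)/2 and 1−(1−ci_level)/2 quantiles.  Deterministic given
    ``seed``.
    """
    k, n = well_channel
    if droplet_volume_ul <= 0:
        raise ValidationError("droplet_volume_ul must be positive")
    if not 0 < ci_level < 1:
        raise ValidationError("ci_level must lie in (0, 1)")
    lam = estimate_lambda(k, n)
    point = lam / droplet_volume_ul
    if k == 0:
        return ConcentrationEstimate(0.0, 0.0, 0.0, 0.0, droplet_volume_ul)
    if seed is None:
        raise ValidationError("a seed is required for the bootstrap CI")
    rng = np.random.default_rng(seed)
    k_star = rng.binomial(n, k / n, size=n_boot)
    # saturated resamples are vanishingly rare for k < N; cap them at N-1
    k_star = np.minimum(k_star, n - 1)
    lam_star = -np.log1p(-k_star / n)
    alpha = 1.0 - ci_level
    lo, hi = np.quantile(lam_star / droplet_volume_ul, [alpha / 2, 1 - alpha / 2])
    return ConcentrationEstimate(
        copies_per_ul=point,
        lam=lam,
        ci_low=min(float(lo), point),
        ci_high=max(float(hi), point),
        droplet_volume_ul=droplet_volume_ul,
    )


def merge_wells(wells: Sequence[DropletWell]) -> DropletWell:
    """Pool replicate wells of one assay by summing per-channel counts.

    Pooling droplets before estimation is the standard way to tighten the
    Poisson estimate without changing the model.
    """
    if not wells:
        raise ValidationError("cannot merge an empty list of wells")
    assay = wells[0].assay
    if any(w.assay is not assay for w in wells):
        raise ValidationError("cannot merge wells of different assay types")
    merged: dict[Channel, Tuple[int, int]] = {}
    for ch in ASSAY_CHANNELS[assay]:
        merged[ch] = (
            sum(w.channel_counts[ch][0] for w in wells),
            sum(w.channel_counts[ch][1] for w in wells),
        )
    return DropletWell(
        well_id="+".join(w.well_id for w in wells),
        assay=assay,
        channel_counts=merged,
    )


def read_droplet_csv(path) -> list[DropletWell]:
    """Read wells from the droplet CSV schema.

    Columns: ``well_id, assay, channel, positives, total`` — one row per
    channel; the two rows of a duplex share a well_id.
    """
    import csv as _csv
    from pathlib import Path

    from .errors import SchemaError

    required = {"well_id", "assay", "channel", "positives", "total"}
    grouped: dict[str, dict] = {}
    order: list[str] = []
    with Path(path).open(newline="", encoding="utf-8") as fh:
        reader = _csv.DictReader(fh)
        missing = required - set(reader.fieldnames or [])
        if missing:
            raise SchemaError(f"droplet CSV missing column(s): {', '.join(sorted(missing))}")
        for row in reader:
            wid = row["well_id"].strip()
            try:
                assay = Assay(row["assay"].strip().upper())
                chan = Channel(row["channel"].strip().upper())
                k, n = int(row["positives"]), int(row["total"])
            except (ValueError, KeyError):
                raise ValidationError(f"well {wid}: unparseable droplet row {row!r}") from None
            entry = grouped.setdefault(wid, {"assay": assay, "counts": {}})
            if wid not in order:
                order.append(wid)
            if entry["assay"] is not assay:
                raise ValidationError(f"well {wid}: conflicting assay types across rows")
            entry["counts"][chan] = (k, n)
    return [
        DropletWell(well_id=wid, assay=grouped[wid]["assay"], channel_counts=grouped[wid]["counts"])
        for wid in order
    ]


def write_concentration_csv(rows: Sequence[tuple[str, Channel, ConcentrationEstimate]], path) -> None:
    """Write per-channel concentration estimates: one row per (well, channel)."""
    import csv as _csv
    from pathlib import Path

    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = _csv.writer(fh)
        writer.writerow(
            ["well_id", "channel", "copies_per_ul", "lambda", "ci_low", "ci_high", "droplet_volume_ul"]
        )
        for well_id, chan, est in rows:
            writer.writerow(
                [
                    well_id,
                    chan.value,
                    repr(est.copies_per_ul),
                    repr(est.lam),
                    repr(est.ci_low),
                    repr(est.ci_high),
                    repr(est.droplet_volume_ul),
                ]
            )
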