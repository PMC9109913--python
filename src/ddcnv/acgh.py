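"""aCGH log2 re-normalization and CN estimation for the NEB TRI region.

Genome-wide normalization in array software can leave the nebulin locus
with a nonzero baseline, so the region is re-baselined locally: the mean
probe log2 ratio of two flanking background intervals is subtracted from
the mean log2 ratio of the triplicate (TRI) region.  Assuming a normal
copy number of 6 for the region, the normalized log2 value r converts to
an estimated copy number

    CN = 6 * 2**r.

Coordinates are 1-based inclusive on Hg19/GRCh37.  The region boundaries
are published as paired uncertainty intervals; the defaults take the
outer span of each pair (maximal background, maximal TRI), with the
inner spans available via ``AcghRegions.inner()``.  Probes are assigned
to a region by their midpoint, which is unambiguous for probes that
straddle a boundary.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence
from dataclasses import dataclass
from pathlib import Path
from typing import IO

import pandas as pd


@dataclass(frozen=True)
class GenomicInterval:
    """1-based inclusive genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")

    def contains_point(self, chrom: str, pos: float) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


@dataclass(frozen=True)
class ProbeLog2:
    """One aCGH probe's interval and log2 ratio."""

    interval: GenomicInterval
    log2_ratio: float

    def __post_init__(self) -> None:
        import math

        if not math.isfinite(self.log2_ratio):
            raise ValueError("log2_ratio must be finite")

    @property
    def midpoint(self) -> float:
        return (self.interval.start + self.interval.end) / 2.0


@dataclass(frozen=True)
class AcghRegions:
    """Background and TRI intervals used for local re-normalization."""

    background: tuple[GenomicInterval, GenomicInterval]
    tri: GenomicInterval

    def __post_init__(self) -> None:
        for bg in self.background:
            if (
                bg.chrom == self.tri.chrom
                and bg.start <= self.tri.end
                and self.tri.start <= bg.end
            ):
                raise ValueError("TRI region must not overlap background")

    @classmethod
    def default(cls) -> "AcghRegions":
        """Outer spans of the published breakpoint pairs (Hg19 chr2)."""
        return cls(
            background=(
                GenomicInterval("chr2", 152_340_824, 152_433_349),
                GenomicInterval("chr2", 152_465_657, 152_592_449),
            ),
            tri=GenomicInterval("chr2", 152_433_598, 152_465_448),
        )

    @classmethod
    def inner(cls) -> "AcghRegions":
        """Inner spans of the breakpoint pairs (alternative reading)."""
        return cls(
            background=(
                GenomicInterval("chr2", 152_341_131, 152_432_955),
                GenomicInterval("chr2", 152_465_735, 152_583_346),
            ),
            tri=GenomicInterval("chr2", 152_434_494, 152_465_223),
        )


def normalize_tri_log2(
    probes: Iterable[ProbeLog2], regions: AcghRegions | None = None
) -> float:
    """Background-subtracted mean log2 ratio of the TRI region.

    Returns mean(log2 of TRI probes) - mean(log2 of probes in the union
    of the background intervals).  Membership is by probe midpoint.

    Raises
    ------
    ValueError
        If either background interval or the TRI region contains no
        probe (named in the message).
    """
    regions = regions or AcghRegions.default()
    tri_vals: list[float] = []
    bg_vals: list[float] = []
    bg_hit = [False for _ in regions.background]
    for probe in probes:
        mid = probe.midpoint
        chrom = probe.interval.chrom
        if regions.tri.contains_point(chrom, mid):
            tri_vals.append(probe.log2_ratio)
            continue
        for i, bg in enumerate(regions.background):
            if bg.contains_point(chrom, mid):
                bg_vals.append(probe.log2_ratio)
                bg_hit[i] = True
                break
    if not tri_vals:
        raise ValueError(f"no probes in TRI region {regions.tri}")
    for i, hit in enumerate(bg_hit):
        if not hit:
            raise ValueError(f"no probes in background region {regions.background[i]}")
    return float(sum(tri_vals) / len(tri_vals) - sum(bg_vals) / len(bg_vals))


def acgh_cn(normalized_log2: float, normal_cn: float = 6.0) -> float:
    """Estimated CN from a normalized log2 ratio: normal_cn * 2**log2."""
    if normal_cn <= 0:
        raise ValueError("normal_cn must be > 0")
    return float(normal_cn * 2.0**normalized_log2)


def read_probes(
    source: str | Path | IO[str],
    *,
    coords: str = "one_based",
) -> list[ProbeLog2]:
    """Read probe log2 ratios from 4-column text (chrom, start, end, log2).

    Accepts tab-separated BED-like files or CSV (sniffed from the header
    line).  ``coords`` declares the file's convention: "one_based"
    (inclusive, the internal convention) or "bed" (0-based half-open,
    converted on read by adding 1 to starts).
    """
    if coords not in ("one_based", "bed"):
        raise ValueError("coords must be 'one_based' or 'bed'")
    df = pd.read_csv(
        source,
        sep=None,
        engine="python",
        header=None,
        comment="#",
        names=["chrom", "start", "end", "log2"],
    )
    # Tolerate a header row naming the columns.
    if df.iloc[0]["chrom"] in ("chrom", "chr", "chromosome"):
        df = df.iloc[1:]
    offset = 1 if coords == "bed" else 0
    return [
        ProbeLog2(
            interval=GenomicInterval(
                str(r["chrom"]), int(r["start"]) + offset, int(r["end"])
            ),
            log2_ratio=float(r["log2"]),
        )
        for r in df.to_dict("records")
    ]


def synthetic_probes(
    cn: float,
    *,
    baseline: float = 0.0,
    normal_cn: float = 6.0,
    probes_per_region: int = 20,
    regions: AcghRegions | None = None,
) -> list[ProbeLog2]:
    """Build a noiseless probe set for a known CN and baseline shift.

    Background probes sit at ``baseline`` and TRI probes at
    ``log2(cn/normal_cn) + baseline``; useful for round-trip checks of
    the normalization.
    """
    import math

    regions = regions or AcghRegions.default()
    tri_log2 = math.log2(cn / normal_cn) + baseline
    probes: list[ProbeLog2] = []
    for region, value in [
        (regions.background[0], baseline),
        (regions.background[1], baseline),
        (regions.tri, tri_log2),
    ]:
        span = region.end - region.start
        for i in range(probes_per_region):
            pos = region.start + int(span * (i + 0.5) / probes_per_region)
            probes.append(
                ProbeLog2(GenomicInterval(region.chrom, pos, pos + 59), value)
            )
    return probes
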