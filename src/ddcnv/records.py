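"""Core record types shared across the pipeline.

Droplet digital PCR partitions a duplexed reaction into ~20,000 droplets
read on two fluorescence channels: FAM for the custom target assay and HEX
for a diploid reference gene (EIF2C1).  These dataclasses carry a droplet's
amplitudes, a well's four-quadrant cluster counts, the Poisson
quantification of a well, and the per-run record that joins quantification
to sample metadata and QC status.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace

ASSAY_IDS = ("exon_IV", "exon_VIII", "custom")
EXCLUSION_FLAGS = ("wga", "mosaic", "other_cnv")

_WELL_RE = re.compile(r"^([A-Ha-h])0*([1-9]\d?)$")


def normalize_well_id(well_id: str) -> str:
    """Normalize a plate-well label to letter + zero-padded two digits.

    "A1", "a01" and "A01" all map to "A01".

    Raises
    ------
    ValueError
        If the label is not a letter A-H followed by a number 1-12.
    """
    well_id = str(well_id).strip()
    m = _WELL_RE.match(well_id)
    if m is None:
        raise ValueError(f"invalid well id: {well_id!r}")
    row, col = m.group(1).upper(), int(m.group(2))
    if col > 12:
        raise ValueError(f"well column out of range (1-12): {well_id!r}")
    return f"{row}{col:02d}"


@dataclass(frozen=True)
class DropletRecord:
    """One droplet's two-channel fluorescence amplitudes within a well."""

    well_id: str
    fam: float
    hex: float

    def __post_init__(self) -> None:
        if not self.well_id:
            raise ValueError("well_id must be non-empty")
        if not (math.isfinite(self.fam) and math.isfinite(self.hex)):
            raise ValueError(
                f"amplitudes must be finite, got fam={self.fam} hex={self.hex}"
            )


@dataclass(frozen=True)
class ClusterCounts:
    """The four droplet-group counts of a well.

    ``n_pp``: FAM-positive / HEX-positive, ``n_pn``: FAM-positive /
    HEX-negative, ``n_np``: FAM-negative / HEX-positive, ``n_nn``: double
    negative.  The total equals the accepted droplet count.
    """

    n_pp: int
    n_pn: int
    n_np: int
    n_nn: int

    def __post_init__(self) -> None:
        for name in ("n_pp", "n_pn", "n_np", "n_nn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer, got {v}")

    @property
    def total(self) -> int:
        return self.n_pp + self.n_pn + self.n_np + self.n_nn

    @property
    def n_target_negative(self) -> int:
        """Droplets with no target (FAM-negative)."""
        return self.n_np + self.n_nn

    @property
    def n_reference_negative(self) -> int:
        """Droplets with no reference (HEX-negative)."""
        return self.n_pn + self.n_nn

    @property
    def min_cluster(self) -> int:
        return min(self.n_pp, self.n_pn, self.n_np, self.n_nn)


@dataclass(frozen=True)
class WellQuant:
    """Poisson quantification of one well.

    ``lambda_target`` and ``lambda_ref`` are mean copies per partition,
    ``ratio`` their quotient, and ``cn_estimate`` the copy number per
    diploid genome (reference ploidy x ratio).  ``ci_low``/``ci_high``
    bound a 95% interval on ``cn_estimate``.  Concentrations are in
    copies/uL and depend on the droplet volume; the CN does not.
    """

    lambda_target: float
    lambda_ref: float
    ratio: float
    cn_estimate: float
    ci_low: float
    ci_high: float
    n_total: int
    concentration_target: float
    concentration_ref: float

    def __post_init__(self) -> None:
        if self.lambda_target < 0 or self.lambda_ref < 0:
            raise ValueError("lambda must be >= 0")
        if self.cn_estimate < 0:
            raise ValueError("cn_estimate must be >= 0")
        if not (self.ci_low <= self.cn_estimate <= self.ci_high):
            raise ValueError("require ci_low <= cn_estimate <= ci_high")


@dataclass(frozen=True)
class WellMeta:
    """Plate-config entry for one well."""

    sample_id: str | None
    assay_id: str
    experiment_id: str
    is_ntc: bool = False
    exclusion_flags: frozenset[str] = frozenset()
    acgh_cn: int | None = None

    def __post_init__(self) -> None:
        if self.assay_id not in ASSAY_IDS:
            raise ValueError(
                f"unknown assay_id {self.assay_id!r}; allowed: {list(ASSAY_IDS)}"
            )
        unknown = set(self.exclusion_flags) - set(EXCLUSION_FLAGS)
        if unknown:
            raise ValueError(
                f"unknown exclusion flags {sorted(unknown)}; "
                f"allowed: {list(EXCLUSION_FLAGS)}"
            )
        if not self.is_ntc and not self.sample_id:
            raise ValueError("non-NTC wells require a sample_id")
        if self.acgh_cn is not None and self.acgh_cn < 0:
            raise ValueError("acgh_cn must be >= 0")


@dataclass
class PlateConfig:
    """Per-well sample/assay/experiment metadata for a plate."""

    wells: dict[str, WellMeta] = field(default_factory=dict)

    def add(self, well_id: str, meta: WellMeta) -> None:
        well_id = normalize_well_id(well_id)
        if well_id in self.wells:
            raise ValueError(f"duplicate well entry: {well_id}")
        self.wells[well_id] = meta

    def __getitem__(self, well_id: str) -> WellMeta:
        return self.wells[normalize_well_id(well_id)]

    def __contains__(self, well_id: str) -> bool:
        return normalize_well_id(well_id) in self.wells

    def __len__(self) -> int:
        return len(self.wells)


@dataclass(frozen=True)
class RunRecord:
    """One well's quantification joined to its metadata and QC status.

    ``qc_status`` is "pass" or "fail:<reason>" with exactly one primary
    machine-readable reason.
    """

    sample_id: str | None
    assay_id: str
    experiment_id: str
    well_id: str
    counts: ClusterCounts
    quant: WellQuant | None
    exclusion_flags: frozenset[str] = frozenset()
    acgh_cn: int | None = None
    qc_status: str = "pass"

    def __post_init__(self) -> None:
        if self.qc_status != "pass" and not self.qc_status.startswith("fail:"):
            raise ValueError("qc_status must be 'pass' or 'fail:<reason>'")
        if self.acgh_cn is not None and self.acgh_cn < 0:
            raise ValueError("acgh_cn must be >= 0 when present")

    @property
    def passed(self) -> bool:
        return self.qc_status == "pass"

    def with_status(self, qc_status: str) -> "RunRecord":
        return replace(self, qc_status=qc_status)
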