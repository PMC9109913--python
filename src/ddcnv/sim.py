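"""Synthetic droplet-data generator with known ground truth.

The generative model mirrors the assumptions the analysis makes: target
and reference molecules partition independently into droplets with
Poisson occupancy, a droplet is channel-positive iff it holds at least
one molecule for that channel, and positive/negative droplets emit
Gaussian fluorescence around well-separated cluster means.  Two
departures from the ideal are available as knobs:

* ``rain_fraction`` — a proportion of droplets whose amplitude is drawn
  uniformly between the negative and positive cluster means, emulating
  intermediate-fluorescence "rain";
* ``linkage_fraction`` — a proportion of target molecules that stay
  physically joined in blocks of three (undigested tandem copies of the
  triplicate block).  A joined block occupies one droplet and makes it
  positive once, so full linkage collapses the six-copy diploid state to
  two allelic units and drags the apparent copy number toward 2.

For a true copy number ``c`` per diploid genome against a diploid
reference at ``lambda_ref`` copies per partition, the target rate is
``lambda_target = lambda_ref * c / 2``.  With linkage fraction ``L`` the
effective positive-making rate is ``lambda_target * (1 - L + L/3)``.
"""

from __future__ import annotations

import math
from collections.abc import Mapping
from dataclasses import dataclass, field, replace

import numpy as np

from .records import DropletRecord, PlateConfig, WellMeta, normalize_well_id


@dataclass(frozen=True)
class ChannelModel:
    """Gaussian amplitude clusters for one fluorescence channel."""

    negative_mean: float
    negative_sd: float
    positive_mean: float
    positive_sd: float

    def __post_init__(self) -> None:
        if self.positive_mean <= self.negative_mean:
            raise ValueError("positive-cluster mean must exceed negative-cluster mean")
        if self.negative_sd <= 0 or self.positive_sd <= 0:
            raise ValueError("cluster SDs must be positive")


#: Default clusters: separation > 15 SDs so threshold placement is unambiguous.
DEFAULT_FAM_MODEL = ChannelModel(1000.0, 120.0, 8000.0, 400.0)
DEFAULT_HEX_MODEL = ChannelModel(800.0, 100.0, 6000.0, 300.0)


@dataclass(frozen=True)
class SimConfig:
    """Parameters for one simulated well.

    ``true_cn`` is the target copy number per diploid genome; the normal
    state of the NEB triplicate region is 6 (three blocks per allele).
    ``lambda_ref`` is the diploid reference's mean copies per partition.
    """

    n_droplets: int = 20000
    lambda_ref: float = 0.5
    true_cn: float = 6.0
    fam_model: ChannelModel = DEFAULT_FAM_MODEL
    hex_model: ChannelModel = DEFAULT_HEX_MODEL
    rain_fraction: float = 0.0
    linkage_fraction: float = 0.0
    false_positive_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_droplets <= 0:
            raise ValueError("n_droplets must be positive")
        if self.lambda_ref <= 0:
            raise ValueError("lambda_ref must be positive")
        if self.true_cn < 0:
            raise ValueError("true_cn must be >= 0")
        if not 0 <= self.rain_fraction < 1:
            raise ValueError("rain_fraction must be in [0, 1)")
        if not 0 <= self.linkage_fraction <= 1:
            raise ValueError("linkage_fraction must be in [0, 1]")
        if not 0 <= self.false_positive_rate < 1:
            raise ValueError("false_positive_rate must be in [0, 1)")

    @property
    def lambda_target(self) -> float:
        return self.lambda_ref * self.true_cn / 2.0

    @property
    def lambda_target_effective(self) -> float:
        """Positive-making target rate after linkage.

        A fraction L of target molecules travels in indivisible 3-copy
        blocks at rate lambda_target * L / 3; the rest are singles at
        rate lambda_target * (1 - L).
        """
        L = self.linkage_fraction
        return self.lambda_target * (1.0 - L) + self.lambda_target * L / 3.0


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for a simulated well."""

    config: SimConfig
    lambda_target_effective: float
    n_target_positive: int
    n_ref_positive: int
    n_rain_fam: int
    n_rain_hex: int


def _channel_amplitudes(
    rng: np.random.Generator,
    positive: np.ndarray,
    model: ChannelModel,
    rain_fraction: float,
) -> tuple[np.ndarray, int]:
    n = positive.size
    amp = np.where(
        positive,
        rng.normal(model.positive_mean, model.positive_sd, size=n),
        rng.normal(model.negative_mean, model.negative_sd, size=n),
    )
    n_rain = 0
    if rain_fraction > 0:
        rain = rng.random(n) < rain_fraction
        n_rain = int(rain.sum())
        amp[rain] = rng.uniform(model.negative_mean, model.positive_mean, size=n_rain)
    return amp, n_rain


def simulate_well_arrays(
    config: SimConfig,
) -> tuple[np.ndarray, np.ndarray, TruthRecord]:
    """Simulate one well, returning FAM and HEX amplitude arrays.

    The array form avoids per-droplet object overhead for large
    simulation studies; :func:`simulate_well` wraps it in records.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_droplets
    lam_t = config.lambda_target
    L = config.linkage_fraction

    singles = rng.poisson(lam_t * (1.0 - L), size=n)
    blocks = rng.poisson(lam_t * L / 3.0, size=n) if L > 0 else 0
    target_pos = (singles + blocks) > 0
    ref_pos = rng.poisson(config.lambda_ref, size=n) > 0

    if config.false_positive_rate > 0:
        target_pos |= rng.random(n) < config.false_positive_rate
        ref_pos |= rng.random(n) < config.false_positive_rate

    fam, n_rain_fam = _channel_amplitudes(rng, target_pos, config.fam_model, config.rain_fraction)
    hex_, n_rain_hex = _channel_amplitudes(rng, ref_pos, config.hex_model, config.rain_fraction)

    truth = TruthRecord(
        config=config,
        lambda_target_effective=config.lambda_target_effective,
        n_target_positive=int(target_pos.sum()),
        n_ref_positive=int(ref_pos.sum()),
        n_rain_fam=n_rain_fam,
        n_rain_hex=n_rain_hex,
    )
    return fam, hex_, truth


def simulate_well(
    config: SimConfig, well_id: str = "A01"
) -> tuple[list[DropletRecord], TruthRecord]:
    """Simulate one well's droplets with ground truth."""
    well_id = normalize_well_id(well_id)
    fam, hex_, truth = simulate_well_arrays(config)
    droplets = [
        DropletRecord(well_id=well_id, fam=float(f), hex=float(h))
        for f, h in zip(fam, hex_)
    ]
    return droplets, truth


@dataclass(frozen=True)
class NtcConfig:
    """A no-template control: both rates zero, optional false positives."""

    n_droplets: int = 20000
    false_positive_rate: float = 0.0
    seed: int = 0


def _simulate_ntc(config: NtcConfig, well_id: str) -> list[DropletRecord]:
    rng = np.random.default_rng(config.seed)
    n = config.n_droplets
    fam_pos = rng.random(n) < config.false_positive_rate
    hex_pos = rng.random(n) < config.false_positive_rate
    fam, _ = _channel_amplitudes(rng, fam_pos, DEFAULT_FAM_MODEL, 0.0)
    hex_, _ = _channel_amplitudes(rng, hex_pos, DEFAULT_HEX_MODEL, 0.0)
    return [
        DropletRecord(well_id=well_id, fam=float(f), hex=float(h))
        for f, h in zip(fam, hex_)
    ]


def simulate_plate(
    configs: Mapping[str, SimConfig],
    *,
    include_ntc: bool = True,
    ntc_config: NtcConfig | None = None,
    ntc_well: str = "H12",
    metadata: Mapping[str, WellMeta] | None = None,
    assay_id: str = "exon_VIII",
    experiment_id: str = "E1",
) -> tuple[dict[str, list[DropletRecord]], PlateConfig, dict[str, TruthRecord]]:
    """Simulate a plate of wells plus an optional NTC well.

    Each well's metadata defaults to one sample per well named after the
    well; pass ``metadata`` to override (e.g. to model duplicates of the
    same sample across wells or experiments).
    """
    norm_configs: dict[str, SimConfig] = {}
    for well, cfg in configs.items():
        w = normalize_well_id(well)
        if w in norm_configs:
            raise ValueError(f"duplicate well: {w}")
        norm_configs[w] = cfg

    plate = PlateConfig()
    amplitudes: dict[str, list[DropletRecord]] = {}
    truths: dict[str, TruthRecord] = {}

    for well, cfg in norm_configs.items():
        droplets, truth = simulate_well(cfg, well)
        amplitudes[well] = droplets
        truths[well] = truth
        if metadata and well in metadata:
            plate.add(well, metadata[well])
        else:
            plate.add(
                well,
                WellMeta(
                    sample_id=f"sim-{well}",
                    assay_id=assay_id,
                    experiment_id=experiment_id,
                ),
            )

    if include_ntc:
        ntc_well = normalize_well_id(ntc_well)
        if ntc_well in norm_configs:
            raise ValueError(f"duplicate well: NTC well {ntc_well} already simulated")
        cfg = ntc_config or NtcConfig()
        amplitudes[ntc_well] = _simulate_ntc(cfg, ntc_well)
        plate.add(
            ntc_well,
            WellMeta(sample_id=None, assay_id=assay_id,
                     experiment_id=experiment_id, is_ntc=True),
        )

    return amplitudes, plate, truths


def draw_droplet_count(
    rng: np.random.Generator, mean: float = 12974.0, sd: float = 1701.2, floor: int = 1000
) -> int:
    """Draw a per-well accepted droplet count, Normal(mean, sd) truncated below.

    Defaults emulate the observed spread of accepted droplet counts in
    real plates; the generator itself uses a fixed count unless callers
    opt in to this variation.
    """
    while True:
        n = int(round(rng.normal(mean, sd)))
        if n >= floor:
            return n


def spawn_seeds(seed: int, n: int) -> list[int]:
    """Derive n child seeds (< 2**31) deterministically from one seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) for s in ss.generate_state(n) % (2**31)]
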