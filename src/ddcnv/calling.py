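"""Droplet cluster assignment and automatic threshold suggestion.

Each droplet is assigned to one of four groups by comparing its FAM and
HEX amplitudes with per-channel intensity cutoffs.  The boundary
convention is strict: an amplitude must exceed the cutoff to count as
positive; equality is negative (conservative toward non-detection).

Thresholds are kept per (plate, assay, channel).  In routine use they
are set manually; :func:`suggest_thresholds` offers a reproducible
starting point by 2-means partitioning of the 1-D amplitudes with
deterministic initialization, flagging poorly separated data.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np

from .records import ClusterCounts, DropletRecord


@dataclass(frozen=True)
class Thresholds:
    """Per-channel intensity cutoffs with provenance ("manual" or "auto")."""

    fam_cutoff: float
    hex_cutoff: float
    provenance: str = "manual"

    def __post_init__(self) -> None:
        if not (np.isfinite(self.fam_cutoff) and np.isfinite(self.hex_cutoff)):
            raise ValueError("cutoffs must be finite")
        if self.provenance not in ("manual", "auto"):
            raise ValueError("provenance must be 'manual' or 'auto'")


@dataclass(frozen=True)
class ThresholdSuggestion:
    """Auto-derived cutoff for one channel with separation diagnostics.

    ``cutoff`` is the midpoint of the two recovered cluster centers;
    ``separation`` is the center distance in units of the pooled
    within-cluster SD.  ``reliable`` is False when separation falls
    below the floor.
    """

    cutoff: float | None
    low_center: float
    high_center: float
    separation: float
    reliable: bool


class SingleClusterError(ValueError):
    """Amplitudes form one cluster; no defensible cutoff exists."""


def _amplitude_array(droplets: Sequence[DropletRecord], channel: str) -> np.ndarray:
    if channel not in ("fam", "hex"):
        raise ValueError("channel must be 'fam' or 'hex'")
    return np.array([getattr(d, channel) for d in droplets], dtype=float)


def assign_clusters(
    droplets: Sequence[DropletRecord], thresholds: Thresholds
) -> ClusterCounts:
    """Count droplets in the four fluorescence quadrants.

    A droplet is FAM-positive iff fam > fam_cutoff (strictly), and
    analogously for HEX; the four counts always sum to the input size.

    Raises
    ------
    ValueError
        On empty input, to distinguish "no droplets" from "all negative".
    """
    if len(droplets) == 0:
        raise ValueError("no droplets to assign (empty well)")
    fam = _amplitude_array(droplets, "fam") > thresholds.fam_cutoff
    hex_ = _amplitude_array(droplets, "hex") > thresholds.hex_cutoff
    return ClusterCounts(
        n_pp=int(np.sum(fam & hex_)),
        n_pn=int(np.sum(fam & ~hex_)),
        n_np=int(np.sum(~fam & hex_)),
        n_nn=int(np.sum(~fam & ~hex_)),
    )


def assign_clusters_arrays(
    fam: np.ndarray, hex_: np.ndarray, thresholds: Thresholds
) -> ClusterCounts:
    """Array-based variant of :func:`assign_clusters` for bulk simulation."""
    if fam.size == 0:
        raise ValueError("no droplets to assign (empty well)")
    fp = fam > thresholds.fam_cutoff
    hp = hex_ > thresholds.hex_cutoff
    return ClusterCounts(
        n_pp=int(np.sum(fp & hp)),
        n_pn=int(np.sum(fp & ~hp)),
        n_np=int(np.sum(~fp & hp)),
        n_nn=int(np.sum(~fp & ~hp)),
    )


def _two_means_1d(x: np.ndarray, max_iter: int = 100) -> tuple[float, float, np.ndarray]:
    """Lloyd's algorithm on 1-D data, initialized at the 5th/95th percentiles.

    The deterministic initialization makes the suggestion reproducible
    without a random seed.
    """
    lo, hi = np.percentile(x, [5.0, 95.0])
    if hi <= lo:
        hi = lo + 1.0
    centers = np.array([lo, hi], dtype=float)
    labels = np.zeros(x.size, dtype=int)
    for _ in range(max_iter):
        labels = (np.abs(x - centers[1]) < np.abs(x - centers[0])).astype(int)
        new = centers.copy()
        for k in (0, 1):
            members = x[labels == k]
            if members.size:
                new[k] = members.mean()
        if np.allclose(new, centers):
            break
        centers = new
    order = np.argsort(centers)
    centers = centers[order]
    labels = order.argsort()[labels]
    return float(centers[0]), float(centers[1]), labels


def suggest_thresholds(
    droplets: Sequence[DropletRecord],
    channel: str,
    *,
    min_droplets: int = 200,
    separation_floor: float = 4.0,
    imbalance_limit: float = 0.005,
) -> ThresholdSuggestion:
    """Suggest a cutoff for one channel by 2-group partitioning.

    The cutoff is the midpoint between the two recovered 1-D cluster
    centers.  ``separation`` is reported in pooled-within-SD units; when
    it falls below ``separation_floor`` the suggestion is flagged
    unreliable, and when the smaller group additionally holds less than
    ``imbalance_limit`` of the droplets the data are treated as a single
    cluster and no cutoff is returned.

    Raises
    ------
    ValueError
        If fewer than ``min_droplets`` droplets are provided.
    SingleClusterError
        On effectively single-cluster data.
    """
    x = _amplitude_array(droplets, channel)
    if x.size < min_droplets:
        raise ValueError(
            f"need >= {min_droplets} droplets for threshold suggestion, got {x.size}"
        )
    c_lo, c_hi, labels = _two_means_1d(x)
    n_hi = int(labels.sum())
    n_lo = x.size - n_hi
    within_var = 0.0
    for k, nk in ((0, n_lo), (1, n_hi)):
        members = x[labels == k]
        if members.size > 1:
            within_var += members.var(ddof=1) * nk
    pooled_sd = float(np.sqrt(within_var / x.size)) if within_var > 0 else 0.0
    if n_lo == 0 or n_hi == 0 or pooled_sd == 0.0:
        # a second cluster was never actually recovered
        separation = 0.0
    else:
        separation = (c_hi - c_lo) / pooled_sd

    minority = min(n_lo, n_hi) / x.size
    reliable = separation >= separation_floor
    if not reliable and minority < imbalance_limit:
        raise SingleClusterError(
            f"{channel} amplitudes form a single cluster "
            f"(separation {separation:.2f} SD, minority fraction {minority:.4f})"
        )
    cutoff = (c_lo + c_hi) / 2.0
    return ThresholdSuggestion(
        cutoff=cutoff,
        low_center=c_lo,
        high_center=c_hi,
        separation=float(separation),
        reliable=reliable,
    )


def auto_thresholds(
    droplets: Sequence[DropletRecord],
    *,
    fam_cutoff: float | None = None,
    hex_cutoff: float | None = None,
    separation_floor: float = 4.0,
) -> Thresholds:
    """Build per-well thresholds, auto-suggesting any cutoff not given manually.

    If both cutoffs are supplied the result is marked manual and no
    suggestion is computed.
    """
    if fam_cutoff is not None and hex_cutoff is not None:
        return Thresholds(fam_cutoff=fam_cutoff, hex_cutoff=hex_cutoff,
                          provenance="manual")
    if fam_cutoff is None:
        fam_cutoff = suggest_thresholds(
            droplets, "fam", separation_floor=separation_floor
        ).cutoff
    if hex_cutoff is None:
        hex_cutoff = suggest_thresholds(
            droplets, "hex", separation_floor=separation_floor
        ).cutoff
    return Thresholds(fam_cutoff=fam_cutoff, hex_cutoff=hex_cutoff, provenance="auto")
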