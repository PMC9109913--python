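"""Poisson quantification: cluster counts to copies per partition and CN.

With droplets as independent equal-volume partitions, the number of
molecules per droplet is Poisson with mean lambda, so the fraction of
negative droplets estimates exp(-lambda) and

    lambda_hat = -ln(n_negative / n_total).

The copy number per diploid genome is the target:reference rate ratio
scaled by the reference ploidy (2 for the diploid EIF2C1 reference):

    CN = ploidy * lambda_target / lambda_ref,

i.e. doubling the target-to-reference ratio.  The normal state of the
NEB triplicate region (three blocks per allele) gives CN 6, a 3:1 ratio.

Uncertainty: the delta method gives var(lambda_hat) = (e^lambda - 1)/n.
The 95% interval on CN is formed on the log-ratio scale, where the two
channel estimates are uncorrelated under duplex independence, and
exponentiated back; it is truncated below at 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .records import ClusterCounts, WellQuant

#: QX200 droplet volume convention, nanoliters.  Used only to report
#: concentrations in copies/uL; the CN estimate never depends on it.
DEFAULT_DROPLET_VOLUME_NL = 0.85

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


class SaturationError(ValueError):
    """All droplets positive; lambda is unbounded above."""


class ReferenceFailureError(ValueError):
    """No reference-positive droplets; the ratio is undefined."""


@dataclass(frozen=True)
class LambdaEstimate:
    """Copies per partition with its delta-method variance."""

    value: float
    variance: float
    n_total: int


def estimate_lambda(n_negative: int, n_total: int) -> LambdaEstimate:
    """Estimate mean copies per partition from the negative-droplet count.

    lambda_hat = -ln(n_negative/n_total); var = (e^lambda - 1)/n_total.
    lambda is exactly 0 when every droplet is negative.

    Raises
    ------
    ValueError
        If counts are inconsistent (n_total <= 0 or n_negative outside
        [0, n_total]).
    SaturationError
        If no droplet is negative: the sample is too concentrated for a
        finite estimate.
    """
    if n_total <= 0:
        raise ValueError(f"n_total must be positive, got {n_total}")
    if not 0 <= n_negative <= n_total:
        raise ValueError(f"n_negative={n_negative} outside [0, {n_total}]")
    if n_negative == 0:
        raise SaturationError(
            "all droplets positive; sample too concentrated to quantify"
        )
    lam = -math.log(n_negative / n_total)
    variance = (math.exp(lam) - 1.0) / n_total
    return LambdaEstimate(value=lam, variance=variance, n_total=n_total)


def quantify_well(
    counts: ClusterCounts,
    *,
    droplet_volume_nl: float = DEFAULT_DROPLET_VOLUME_NL,
    reference_ploidy: float = 2.0,
) -> WellQuant:
    """Quantify a well: copies per partition, ratio, CN and 95% interval.

    The target-negative count is n_np + n_nn (FAM-negative) and the
    reference-negative count is n_pn + n_nn (HEX-negative).

    Raises
    ------
    ReferenceFailureError
        If lambda_ref is 0 (no reference-positive droplet) — distinct
        from saturation of either channel.
    SaturationError
        If either channel has no negative droplets.
    """
    total = counts.total
    if total <= 0:
        raise ValueError("cluster counts sum to zero droplets")

    lam_t = estimate_lambda(counts.n_target_negative, total)
    lam_r = estimate_lambda(counts.n_reference_negative, total)
    if lam_r.value == 0.0:
        raise ReferenceFailureError(
            "no reference-positive droplets; reference assay failed"
        )

    ratio = lam_t.value / lam_r.value
    cn = reference_ploidy * ratio

    if lam_t.value > 0.0:
        # var(log lambda) = var(lambda)/lambda^2; channels independent.
        log_var = (
            lam_t.variance / lam_t.value**2 + lam_r.variance / lam_r.value**2
        )
        half = Z_95 * math.sqrt(log_var)
        ci_low = max(0.0, cn * math.exp(-half))
        ci_high = cn * math.exp(half)
    else:
        # No target-positive droplets: CN 0 with an upper bound from the
        # one-sided Poisson limit on lambda_target.
        lam_upper = 3.0 / total  # ~95% upper bound for zero counts
        ci_low = 0.0
        ci_high = reference_ploidy * lam_upper / lam_r.value

    vol_ul = droplet_volume_nl * 1e-3
    return WellQuant(
        lambda_target=lam_t.value,
        lambda_ref=lam_r.value,
        ratio=ratio,
        cn_estimate=cn,
        ci_low=ci_low,
        ci_high=ci_high,
        n_total=total,
        concentration_target=lam_t.value / vol_ul,
        concentration_ref=lam_r.value / vol_ul,
    )
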