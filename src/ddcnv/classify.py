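"""Integer CN calls and benign/pathogenic classification.

The NEB triplicate region normally carries six copies of the repeated
block per diploid genome (three per allele).  A gain or loss of a single
block (CN 5 or 7) is a benign variant; a deviation of two or more blocks
from the normal count is classified pathogenic.  The normal count and
the tolerated deviation are parameters so the rule generalizes to other
segmental duplications.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

BENIGN = "benign"
PATHOGENIC = "pathogenic"


@dataclass(frozen=True)
class CnCall:
    """An integer CN with its benign/pathogenic label."""

    cn_integer: int
    label: str
    normal_cn: int = 6
    tolerance: int = 1


def round_cn(cn_estimate: float, *, tie_rule: str = "half_away") -> int:
    """Round a CN estimate to the nearest integer.

    Exact .5 ties round away from zero by default ("half_away",
    spreadsheet ROUND behaviour: 7.5 -> 8); ``tie_rule="half_even"``
    selects banker's rounding instead.

    Raises
    ------
    ValueError
        On negative input.
    """
    if cn_estimate < 0:
        raise ValueError(f"CN estimate must be >= 0, got {cn_estimate}")
    if tie_rule == "half_away":
        return int(math.floor(cn_estimate + 0.5))
    if tie_rule == "half_even":
        return round(cn_estimate)
    raise ValueError(f"unknown tie rule: {tie_rule!r}")


def classify_cn(cn_integer: int, *, normal_cn: int = 6, tolerance: int = 1) -> str:
    """Label an integer CN benign or pathogenic.

    Benign iff |cn_integer - normal_cn| <= tolerance; a deviation of
    tolerance + 1 or more blocks is pathogenic.
    """
    if cn_integer < 0:
        raise ValueError(f"cn_integer must be >= 0, got {cn_integer}")
    if abs(cn_integer - normal_cn) <= tolerance:
        return BENIGN
    return PATHOGENIC


def call_cn(
    cn_estimate: float,
    *,
    normal_cn: int = 6,
    tolerance: int = 1,
    tie_rule: str = "half_away",
) -> CnCall:
    """Round an estimate and classify it in one step."""
    cn_int = round_cn(cn_estimate, tie_rule=tie_rule)
    return CnCall(
        cn_integer=cn_int,
        label=classify_cn(cn_int, normal_cn=normal_cn, tolerance=tolerance),
        normal_cn=normal_cn,
        tolerance=tolerance,
    )
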