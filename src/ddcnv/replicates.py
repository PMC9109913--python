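"""Replicate variability: intra-/inter-assay %CV and per-CN-group summaries.

Intra-assay pairs are duplicates run within the same experiment
(reproducibility); inter-assay pairs are the two best runs from two
separate experiments (repeatability).  Variability is summarized as the
coefficient of variation in percent, %CV = 100 * SD / mean, with the
sample SD (n-1 denominator) by default.
"""

from __future__ import annotations

import statistics
from collections.abc import Iterable, Sequence
from dataclasses import dataclass
from itertools import combinations

from .records import RunRecord


@dataclass(frozen=True)
class ReplicatePair:
    """A duplicate pair of runs for one sample and assay."""

    sample_id: str
    assay_id: str
    run_a: RunRecord
    run_b: RunRecord
    mean: float
    sd: float
    pct_cv: float


@dataclass(frozen=True)
class GroupSummary:
    """Range, mean, SD and %CV of CN estimates in one aCGH CN group."""

    acgh_cn: int
    n: int
    cn_min: float
    cn_max: float
    mean: float
    sd: float
    pct_cv: float


def percent_cv(values: Sequence[float], *, ddof: int = 1) -> float:
    """Coefficient of variation in percent: 100 * SD / mean.

    Uses the sample SD (n-1) by default; ``ddof=0`` switches to the
    population SD.

    Raises
    ------
    ValueError
        On fewer than two values or a non-positive mean.
    """
    if len(values) < 2:
        raise ValueError("%CV requires at least two values")
    mean = statistics.fmean(values)
    if mean <= 0:
        raise ValueError(f"%CV undefined for mean <= 0 (mean={mean})")
    if ddof == 1:
        sd = statistics.stdev(values)
    else:
        sd = statistics.pstdev(values)
    return 100.0 * sd / mean


def _cn(run: RunRecord) -> float:
    if run.quant is None:
        raise ValueError(f"run {run.well_id} has no quantification")
    return run.quant.cn_estimate


def _make_pair(sample_id: str, assay_id: str, a: RunRecord, b: RunRecord,
               ddof: int) -> ReplicatePair:
    values = [_cn(a), _cn(b)]
    mean = statistics.fmean(values)
    sd = statistics.stdev(values) if ddof == 1 else statistics.pstdev(values)
    return ReplicatePair(
        sample_id=sample_id, assay_id=assay_id, run_a=a, run_b=b,
        mean=mean, sd=sd, pct_cv=100.0 * sd / mean if mean > 0 else float("nan"),
    )


def intra_assay(
    runs: Iterable[RunRecord], *, ddof: int = 1
) -> tuple[list[ReplicatePair], dict[str, float]]:
    """Within-experiment duplicate pairs and the per-assay mean %CV.

    One pair per (sample, assay, experiment) group with >= 2 passing
    runs; with more than two runs the two with the highest total droplet
    counts are used.  The assay-level summary is the unweighted mean of
    pair %CVs.
    """
    groups: dict[tuple[str, str, str], list[RunRecord]] = {}
    for run in runs:
        if not run.passed or run.sample_id is None:
            continue
        key = (run.sample_id, run.assay_id, run.experiment_id)
        groups.setdefault(key, []).append(run)

    pairs: list[ReplicatePair] = []
    for (sample, assay, _exp), members in sorted(groups.items()):
        if len(members) < 2:
            continue
        best = sorted(members, key=lambda r: (-r.counts.total, r.well_id))[:2]
        pairs.append(_make_pair(sample, assay, best[0], best[1], ddof))

    assay_cv: dict[str, list[float]] = {}
    for p in pairs:
        assay_cv.setdefault(p.assay_id, []).append(p.pct_cv)
    summary = {a: statistics.fmean(v) for a, v in assay_cv.items()}
    return pairs, summary


def select_inter_assay_runs(
    runs: Sequence[RunRecord],
) -> tuple[RunRecord, RunRecord] | None:
    """Pick the two runs with the highest droplet counts from two experiments.

    Among all cross-experiment pairs for one sample and assay, the pair
    maximizing (min of the two totals, then their sum) is chosen; the
    tie-break on well ids makes the selection deterministic.  Returns
    None when all runs share one experiment.
    """
    # Candidates in well-id order; strict improvement means the earliest
    # pair wins ties, making the selection deterministic.
    passing = sorted(
        (r for r in runs if r.passed),
        key=lambda r: (r.experiment_id, r.well_id),
    )
    best_key = None
    best_pair = None
    for a, b in combinations(passing, 2):
        if a.experiment_id == b.experiment_id:
            continue
        ta, tb = a.counts.total, b.counts.total
        key = (min(ta, tb), ta + tb)
        if best_key is None or key > best_key:
            best_key = key
            best_pair = (a, b) if ta >= tb else (b, a)
    return best_pair


def inter_assay(
    runs: Iterable[RunRecord], *, ddof: int = 1
) -> tuple[list[ReplicatePair], dict[str, float]]:
    """Between-experiment duplicate pairs and the per-assay mean %CV."""
    groups: dict[tuple[str, str], list[RunRecord]] = {}
    for run in runs:
        if not run.passed or run.sample_id is None:
            continue
        groups.setdefault((run.sample_id, run.assay_id), []).append(run)

    pairs: list[ReplicatePair] = []
    for (sample, assay), members in sorted(groups.items()):
        pair = select_inter_assay_runs(members)
        if pair is not None:
            pairs.append(_make_pair(sample, assay, pair[0], pair[1], ddof))

    assay_cv: dict[str, list[float]] = {}
    for p in pairs:
        assay_cv.setdefault(p.assay_id, []).append(p.pct_cv)
    summary = {a: statistics.fmean(v) for a, v in assay_cv.items()}
    return pairs, summary


def sample_level_cn(
    runs: Iterable[RunRecord], *, rule: str = "mean_selected"
) -> dict[tuple[str, str], float]:
    """Aggregate passing runs to one CN per (sample, assay).

    ``rule`` is "mean_selected" (mean of the inter-assay selected pair,
    falling back to the mean of all passing runs when only one
    experiment exists) or "best_run" (single run with the most
    droplets).
    """
    if rule not in ("mean_selected", "best_run"):
        raise ValueError(f"unknown aggregation rule: {rule!r}")
    groups: dict[tuple[str, str], list[RunRecord]] = {}
    for run in runs:
        if not run.passed or run.sample_id is None:
            continue
        groups.setdefault((run.sample_id, run.assay_id), []).append(run)

    out: dict[tuple[str, str], float] = {}
    for key, members in groups.items():
        if rule == "best_run":
            best = sorted(members, key=lambda r: (-r.counts.total, r.well_id))[0]
            out[key] = _cn(best)
        else:
            pair = select_inter_assay_runs(members)
            if pair is not None:
                out[key] = statistics.fmean([_cn(pair[0]), _cn(pair[1])])
            else:
                out[key] = statistics.fmean([_cn(r) for r in members])
    return out


def cn_group_summary(
    samples: Iterable[tuple[int, float]], *, ddof: int = 1
) -> dict[int, GroupSummary]:
    """Summarize CN estimates grouped by the aCGH-assigned integer CN."""
    groups: dict[int, list[float]] = {}
    for acgh_cn, cn in samples:
        groups.setdefault(int(acgh_cn), []).append(float(cn))
    out: dict[int, GroupSummary] = {}
    for acgh_cn, values in sorted(groups.items()):
        mean = statistics.fmean(values)
        if len(values) > 1:
            sd = statistics.stdev(values) if ddof == 1 else statistics.pstdev(values)
        else:
            sd = 0.0
        out[acgh_cn] = GroupSummary(
            acgh_cn=acgh_cn, n=len(values),
            cn_min=min(values), cn_max=max(values),
            mean=mean, sd=sd,
            pct_cv=100.0 * sd / mean if mean > 0 else float("nan"),
        )
    return out
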