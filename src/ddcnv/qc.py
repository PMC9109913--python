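"""Run-level QC filters and NTC checks.

Runs are removed when any single droplet cluster has 100 or fewer
accepted droplets, when the total accepted droplet count is 10,000 or
less (both bounds inclusive on the removal side), or when the sample
carries an exclusion flag (whole-genome amplified DNA, known mosaicism,
or another CNV overlapping the gene).  Samples must then have at least
one passing run in each of the two assays to survive.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence
from dataclasses import dataclass

from .records import ClusterCounts, RunRecord

#: Assays a sample must succeed in to be analyzable.
REQUIRED_ASSAYS = ("exon_IV", "exon_VIII")


@dataclass(frozen=True)
class FilterCriteria:
    """Run-removal rules.

    ``min_cluster_droplets`` / ``min_total_droplets`` are the smallest
    KEPT values: defaults 101 and 10,001, i.e. runs with any cluster
    <= 100 droplets or total <= 10,000 droplets are removed.
    """

    min_cluster_droplets: int = 101
    min_total_droplets: int = 10001
    excluded_flags: frozenset[str] = frozenset({"wga", "mosaic", "other_cnv"})

    def __post_init__(self) -> None:
        if self.min_cluster_droplets <= 0 or self.min_total_droplets <= 0:
            raise ValueError("thresholds must be positive")


def _removal_reason(run: RunRecord, c: FilterCriteria) -> str | None:
    # Priority order is fixed (flags > cluster > total) so reports are
    # deterministic when several rules trip at once.
    flagged = run.exclusion_flags & c.excluded_flags
    if flagged:
        return f"excluded_flag:{sorted(flagged)[0]}"
    if run.counts.min_cluster < c.min_cluster_droplets:
        return f"min_cluster:{run.counts.min_cluster}"
    if run.counts.total < c.min_total_droplets:
        return f"total_droplets:{run.counts.total}"
    return None


def filter_runs(
    runs: Iterable[RunRecord], criteria: FilterCriteria | None = None
) -> tuple[list[RunRecord], list[RunRecord]]:
    """Split runs into (kept, removed); removed runs carry fail:<reason>.

    Kept runs are marked qc_status "pass".  The two lists partition the
    input and the operation is idempotent on its kept output.
    """
    criteria = criteria or FilterCriteria()
    kept: list[RunRecord] = []
    removed: list[RunRecord] = []
    for run in runs:
        reason = _removal_reason(run, criteria)
        if reason is None:
            kept.append(run.with_status("pass"))
        else:
            removed.append(run.with_status(f"fail:{reason}"))
    return kept, removed


def require_both_assays(
    runs: Sequence[RunRecord], assays: Sequence[str] = REQUIRED_ASSAYS
) -> tuple[list[RunRecord], list[str]]:
    """Keep only samples with >= 1 passing run in every required assay.

    Returns the surviving runs and the list of dropped sample ids
    (samples passing in only one assay, or in none).
    """
    passing_by_sample: dict[str, set[str]] = {}
    samples: set[str] = set()
    for run in runs:
        if run.sample_id is None:
            continue
        samples.add(run.sample_id)
        if run.passed:
            passing_by_sample.setdefault(run.sample_id, set()).add(run.assay_id)
    surviving = {
        s for s in samples
        if set(assays) <= passing_by_sample.get(s, set())
    }
    kept = [r for r in runs if r.sample_id in surviving]
    dropped = sorted(samples - surviving)
    return kept, dropped


def check_ntc(counts: ClusterCounts, max_positive: int = 2) -> bool:
    """Check a no-template control well.

    Fails when either channel shows more than ``max_positive`` positive
    droplets.  The default of 2 tolerated droplets is a configurable
    convention, not an instrument rule.
    """
    fam_positive = counts.n_pp + counts.n_pn
    hex_positive = counts.n_pp + counts.n_np
    return fam_positive <= max_positive and hex_positive <= max_positive
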