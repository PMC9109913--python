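"""End-to-end orchestration: amplitudes -> calls -> QC -> reports.

The stages mirror routine plate analysis: threshold and assign droplet
clusters, Poisson-quantify each well, apply run-level QC, check NTC
wells, summarize replicates, round and classify CN calls, and — when
aCGH-assigned CNs are present — compute concordance statistics.
"""

from __future__ import annotations

import logging
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

from . import classify as _classify
from . import concordance as _concordance
from . import replicates as _replicates
from .calling import Thresholds, assign_clusters, assign_clusters_arrays, auto_thresholds
from .qc import FilterCriteria, check_ntc, filter_runs, require_both_assays
from .quant import ReferenceFailureError, SaturationError, quantify_well
from .records import ClusterCounts, DropletRecord, PlateConfig, RunRecord, WellQuant
from .sim import SimConfig, simulate_well_arrays

logger = logging.getLogger(__name__)


@dataclass
class NtcReport:
    well_id: str
    counts: ClusterCounts
    passed: bool


@dataclass
class SampleCall:
    """Per-sample, per-assay aggregated CN with its classification."""

    sample_id: str
    assay_id: str
    cn_estimate: float
    cn_integer: int
    label: str
    acgh_cn: int | None
    acgh_label: str | None


@dataclass
class ConcordanceReport:
    assay_id: str
    pearson: _concordance.PearsonResult
    fit: _concordance.RegressionFit
    kappa_pathogenicity: _concordance.KappaResult
    crosstab: _concordance.CrossTab2x2
    kappa_cn_linear: _concordance.KappaResult | None = None
    kappa_cn_quadratic: _concordance.KappaResult | None = None


@dataclass
class PipelineResult:
    thresholds: dict[str, Thresholds]
    runs: list[RunRecord]
    kept: list[RunRecord]
    removed: list[RunRecord]
    dropped_samples: list[str]
    ntc: list[NtcReport]
    intra_pairs: list[_replicates.ReplicatePair] = field(default_factory=list)
    intra_cv: dict[str, float] = field(default_factory=dict)
    inter_pairs: list[_replicates.ReplicatePair] = field(default_factory=list)
    inter_cv: dict[str, float] = field(default_factory=dict)
    calls: list[SampleCall] = field(default_factory=list)
    concordance: dict[str, ConcordanceReport] = field(default_factory=dict)


def default_sim_thresholds(config: SimConfig) -> Thresholds:
    """Midpoint cutoffs of a simulation config's cluster means."""
    return Thresholds(
        fam_cutoff=(config.fam_model.negative_mean + config.fam_model.positive_mean) / 2,
        hex_cutoff=(config.hex_model.negative_mean + config.hex_model.positive_mean) / 2,
        provenance="manual",
    )


def simulate_and_quantify(
    config: SimConfig, thresholds: Thresholds | None = None
) -> WellQuant:
    """Simulate one well and run it through calling and quantification.

    The array path avoids per-droplet objects, making large simulation
    studies (hundreds of wells) cheap.  Thresholds default to the
    midpoints between the config's cluster means.
    """
    fam, hex_, _ = simulate_well_arrays(config)
    t = thresholds or default_sim_thresholds(config)
    counts = assign_clusters_arrays(fam, hex_, t)
    return quantify_well(counts)


def quantify_plate(
    amplitudes: Mapping[str, Sequence[DropletRecord]],
    plate: PlateConfig,
    *,
    thresholds: Mapping[str, Thresholds] | Thresholds | None = None,
    reference_ploidy: float = 2.0,
) -> tuple[list[RunRecord], list[NtcReport], dict[str, Thresholds]]:
    """Cluster-call and quantify every well of a plate.

    ``thresholds`` may be a single Thresholds applied everywhere, a
    per-assay mapping, or None to auto-suggest per assay from the pooled
    droplets of that assay's sample wells.  Wells that fail
    quantification (saturation, reference failure) yield a RunRecord
    with no quantification and a fail status.
    """
    for well in amplitudes:
        if well not in plate:
            raise ValueError(f"well {well} has droplets but no plate-config entry")

    per_assay: dict[str, Thresholds] = {}
    assays = {m.assay_id for m in plate.wells.values()}
    if isinstance(thresholds, Thresholds):
        per_assay = {a: thresholds for a in assays}
    elif thresholds is not None:
        per_assay = dict(thresholds)
    else:
        for assay in sorted(assays):
            pooled = [
                d
                for w, ds in amplitudes.items()
                for d in ds
                if plate[w].assay_id == assay and not plate[w].is_ntc
            ]
            if pooled:
                per_assay[assay] = auto_thresholds(pooled)

    runs: list[RunRecord] = []
    ntc_reports: list[NtcReport] = []
    for well in sorted(amplitudes):
        meta = plate[well]
        t = per_assay[meta.assay_id]
        counts = assign_clusters(amplitudes[well], t)
        logger.info(
            "well %s assay %s: droplets=%d clusters=(%d,%d,%d,%d)",
            well, meta.assay_id, counts.total,
            counts.n_pp, counts.n_pn, counts.n_np, counts.n_nn,
        )
        if meta.is_ntc:
            ntc_reports.append(
                NtcReport(well_id=well, counts=counts, passed=check_ntc(counts))
            )
            continue
        quant = None
        status = "pass"
        try:
            quant = quantify_well(counts, reference_ploidy=reference_ploidy)
        except SaturationError:
            status = "fail:saturation"
        except ReferenceFailureError:
            status = "fail:reference_failure"
        runs.append(
            RunRecord(
                sample_id=meta.sample_id,
                assay_id=meta.assay_id,
                experiment_id=meta.experiment_id,
                well_id=well,
                counts=counts,
                quant=quant,
                exclusion_flags=meta.exclusion_flags,
                acgh_cn=meta.acgh_cn,
                qc_status=status,
            )
        )
    return runs, ntc_reports, per_assay


def run_pipeline(
    amplitudes: Mapping[str, Sequence[DropletRecord]],
    plate: PlateConfig,
    *,
    thresholds: Mapping[str, Thresholds] | Thresholds | None = None,
    criteria: FilterCriteria | None = None,
    require_assay_pair: bool = False,
    normal_cn: int = 6,
    tolerance: int = 1,
    tie_rule: str = "half_away",
    aggregation: str = "mean_selected",
    reference_ploidy: float = 2.0,
) -> PipelineResult:
    """Run the full analysis on one plate (or a merged multi-plate set).

    ``require_assay_pair`` enables the sample-level rule that a sample
    must pass in both target assays; leave it off for single-assay
    plates.  Concordance statistics are computed per assay whenever at
    least three samples carry an aCGH-assigned CN.
    """
    all_runs, ntc_reports, per_assay = quantify_plate(
        amplitudes, plate, thresholds=thresholds, reference_ploidy=reference_ploidy
    )

    quantified = [r for r in all_runs if r.quant is not None]
    quant_failed = [r for r in all_runs if r.quant is None]
    kept, removed = filter_runs(quantified, criteria)
    removed = quant_failed + removed

    dropped_samples: list[str] = []
    if require_assay_pair:
        kept, dropped_samples = require_both_assays(kept)

    intra_pairs, intra_cv = _replicates.intra_assay(kept)
    inter_pairs, inter_cv = _replicates.inter_assay(kept)

    sample_cn = _replicates.sample_level_cn(kept, rule=aggregation)
    acgh_by_sample: dict[str, int | None] = {}
    for r in kept:
        if r.sample_id is not None:
            acgh_by_sample.setdefault(r.sample_id, r.acgh_cn)

    calls: list[SampleCall] = []
    for (sample, assay), cn in sorted(sample_cn.items()):
        cn_call = _classify.call_cn(
            cn, normal_cn=normal_cn, tolerance=tolerance, tie_rule=tie_rule
        )
        acgh = acgh_by_sample.get(sample)
        calls.append(
            SampleCall(
                sample_id=sample,
                assay_id=assay,
                cn_estimate=cn,
                cn_integer=cn_call.cn_integer,
                label=cn_call.label,
                acgh_cn=acgh,
                acgh_label=None
                if acgh is None
                else _classify.classify_cn(acgh, normal_cn=normal_cn, tolerance=tolerance),
            )
        )

    concord: dict[str, ConcordanceReport] = {}
    for assay in sorted({c.assay_id for c in calls}):
        with_acgh = [c for c in calls if c.assay_id == assay and c.acgh_cn is not None]
        if len(with_acgh) < 3:
            continue
        x = [c.acgh_cn for c in with_acgh]
        y = [c.cn_estimate for c in with_acgh]
        try:
            pearson = _concordance.pearson_r(x, y)
            fit = _concordance.ols_fit(x, y)
        except ValueError:
            continue
        crosstab, _ = _concordance.build_pathogenicity_crosstab(
            (c.label, c.acgh_label) for c in with_acgh
        )
        try:
            kappa = _concordance.cohen_kappa(crosstab)
        except ValueError:
            continue
        y_int = [c.cn_integer for c in with_acgh]
        kap_lin = kap_quad = None
        try:
            kap_lin = _concordance.kappa_from_codes(y_int, x, "linear")
            kap_quad = _concordance.kappa_from_codes(y_int, x, "quadratic")
        except ValueError:
            pass
        concord[assay] = ConcordanceReport(
            assay_id=assay,
            pearson=pearson,
            fit=fit,
            kappa_pathogenicity=kappa,
            crosstab=crosstab,
            kappa_cn_linear=kap_lin,
            kappa_cn_quadratic=kap_quad,
        )

    return PipelineResult(
        thresholds=per_assay,
        runs=all_runs,
        kept=kept,
        removed=removed,
        dropped_samples=dropped_samples,
        ntc=ntc_reports,
        intra_pairs=intra_pairs,
        intra_cv=intra_cv,
        inter_pairs=inter_pairs,
        inter_cv=inter_cv,
        calls=calls,
        concordance=concord,
    )
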