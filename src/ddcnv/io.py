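"""Readers and writers for the pipeline's tabular artifacts.

All artifacts are plain-text CSV (plate configs may also be YAML).  The
amplitude reader accepts a QuantaSoft-style export: columns
"Ch1 Amplitude" (FAM) and "Ch2 Amplitude" (HEX), one row per droplet,
either one file per well or a combined long format with an extra "Well"
column.  Column names are remappable because vendor exports vary, and a
locale option normalizes decimal commas on read.

Column references for every table are in ``docs/formats.md``.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping, Sequence
from io import StringIO
from pathlib import Path
from typing import IO

import pandas as pd
import yaml

from .records import (
    ClusterCounts,
    DropletRecord,
    PlateConfig,
    RunRecord,
    WellMeta,
    WellQuant,
    normalize_well_id,
)

logger = logging.getLogger(__name__)

#: Default QuantaSoft-style column names for the amplitude export.
DEFAULT_AMPLITUDE_COLUMNS = {"fam": "Ch1 Amplitude", "hex": "Ch2 Amplitude", "well": "Well"}

RESULT_COLUMNS = [
    "sample_id", "assay_id", "experiment_id", "well_id",
    "n_pp", "n_pn", "n_np", "n_nn",
    "lambda_target", "lambda_ref", "ratio", "cn_estimate", "ci_low", "ci_high",
    "n_total", "concentration_target", "concentration_ref",
    "exclusion_flags", "acgh_cn", "qc_status",
]


class FormatError(ValueError):
    """A table does not conform to the documented layout."""


def _read_csv(source, *, decimal: str = ".", sep: str = ",") -> pd.DataFrame:
    return pd.read_csv(source, decimal=decimal, sep=sep)


def read_amplitudes(
    source: str | Path | IO[str],
    *,
    columns: Mapping[str, str] | None = None,
    well_id: str | None = None,
    decimal: str = ".",
    sep: str = ",",
) -> dict[str, list[DropletRecord]]:
    """Read a droplet-amplitude export into per-well droplet lists.

    Parameters
    ----------
    source
        Path or text stream of a CSV with one row per droplet.
    columns
        Overrides for the column-name mapping; keys "fam", "hex" and
        (for the long format) "well".
    well_id
        For the one-file-per-well layout: the well all rows belong to.
        Required when the file has no well column.
    decimal, sep
        Decimal and field separators; some locales export with
        decimal "," and sep ";".

    Returns
    -------
    dict
        Mapping of normalized well id to droplets in row order.
    """
    colmap = dict(DEFAULT_AMPLITUDE_COLUMNS)
    if columns:
        colmap.update(columns)
    df = _read_csv(source, decimal=decimal, sep=sep)

    for key in ("fam", "hex"):
        if colmap[key] not in df.columns:
            raise FormatError(
                f"missing amplitude column {colmap[key]!r} for channel {key}"
            )

    if colmap["well"] in df.columns:
        wells = df[colmap["well"]].map(normalize_well_id)
    elif well_id is not None:
        wells = pd.Series([normalize_well_id(well_id)] * len(df), dtype=object)
    else:
        raise FormatError(
            f"no {colmap['well']!r} column and no well_id given for per-well file"
        )

    if df.empty:
        logger.warning("amplitude file contains a header but no droplets")
        return {}

    out: dict[str, list[DropletRecord]] = {}
    for key in ("fam", "hex"):
        col = pd.to_numeric(df[colmap[key]], errors="coerce")
        bad = col.isna() & df[colmap[key]].notna()
        if bad.any():
            # +2: header line plus 1-based indexing
            line = int(bad.idxmax()) + 2
            raise FormatError(
                f"non-numeric amplitude in column {colmap[key]!r} at line {line}"
            )
        if col.isna().any():
            line = int(col.isna().idxmax()) + 2
            raise FormatError(
                f"missing amplitude in column {colmap[key]!r} at line {line}"
            )
        df[colmap[key]] = col

    for w, fam, hx in zip(wells, df[colmap["fam"]], df[colmap["hex"]]):
        out.setdefault(w, []).append(DropletRecord(well_id=w, fam=float(fam), hex=float(hx)))
    return out


def write_amplitudes(
    amplitudes: Mapping[str, Sequence[DropletRecord]],
    sink: str | Path | IO[str],
    *,
    columns: Mapping[str, str] | None = None,
) -> None:
    """Write per-well droplets as a combined long-format CSV."""
    colmap = dict(DEFAULT_AMPLITUDE_COLUMNS)
    if columns:
        colmap.update(columns)
    rows = [
        {colmap["well"]: w, colmap["fam"]: d.fam, colmap["hex"]: d.hex}
        for w in sorted(amplitudes)
        for d in amplitudes[w]
    ]
    df = pd.DataFrame(rows, columns=[colmap["well"], colmap["fam"], colmap["hex"]])
    df.to_csv(sink, index=False)


def _parse_flags(raw) -> frozenset[str]:
    if raw is None or (isinstance(raw, float) and pd.isna(raw)) or raw == "":
        return frozenset()
    if isinstance(raw, str):
        parts = [p.strip() for p in raw.replace(";", ",").split(",")]
        return frozenset(p for p in parts if p)
    return frozenset(raw)


def _parse_bool(raw) -> bool:
    if isinstance(raw, bool):
        return raw
    if raw is None or (isinstance(raw, float) and pd.isna(raw)):
        return False
    return str(raw).strip().lower() in {"1", "true", "yes", "y"}


def _meta_from_record(rec: Mapping) -> WellMeta:
    acgh = rec.get("acgh_cn")
    if acgh is not None and (acgh == "" or (isinstance(acgh, float) and pd.isna(acgh))):
        acgh = None
    sample = rec.get("sample_id")
    if sample is not None and (sample == "" or (isinstance(sample, float) and pd.isna(sample))):
        sample = None
    return WellMeta(
        sample_id=None if sample is None else str(sample),
        assay_id=str(rec["assay_id"]),
        experiment_id=str(rec.get("experiment_id", "")),
        is_ntc=_parse_bool(rec.get("is_ntc")),
        exclusion_flags=_parse_flags(rec.get("exclusion_flags")),
        acgh_cn=None if acgh is None else int(acgh),
    )


def read_plate_config(source: str | Path | IO[str], *, fmt: str | None = None) -> PlateConfig:
    """Read a plate configuration from CSV or YAML.

    The format is inferred from the file suffix unless ``fmt`` ("csv" or
    "yaml") is given.  Duplicate wells and unknown assay ids or exclusion
    flags are rejected.
    """
    if fmt is None:
        if isinstance(source, (str, Path)) and str(source).endswith((".yaml", ".yml")):
            fmt = "yaml"
        else:
            fmt = "csv"
    config = PlateConfig()
    if fmt == "yaml":
        if isinstance(source, (str, Path)):
            with open(source, encoding="utf-8") as fh:
                data = yaml.safe_load(fh)
        else:
            data = yaml.safe_load(source)
        for well, rec in (data or {}).items():
            config.add(well, _meta_from_record(rec))
    else:
        df = _read_csv(source)
        if "well" not in df.columns:
            raise FormatError("plate config CSV requires a 'well' column")
        for rec in df.to_dict("records"):
            config.add(str(rec["well"]), _meta_from_record(rec))
    return config


def write_plate_config(config: PlateConfig, sink: str | Path | IO[str]) -> None:
    rows = []
    for well in sorted(config.wells):
        m = config.wells[well]
        rows.append(
            {
                "well": well,
                "sample_id": m.sample_id or "",
                "assay_id": m.assay_id,
                "experiment_id": m.experiment_id,
                "is_ntc": m.is_ntc,
                "exclusion_flags": ";".join(sorted(m.exclusion_flags)),
                "acgh_cn": "" if m.acgh_cn is None else m.acgh_cn,
            }
        )
    pd.DataFrame(
        rows,
        columns=["well", "sample_id", "assay_id", "experiment_id", "is_ntc",
                 "exclusion_flags", "acgh_cn"],
    ).to_csv(sink, index=False)


def read_cluster_counts(source: str | Path | IO[str]) -> dict[str, ClusterCounts]:
    """Read a per-well cluster-count table (columns well, n_pp, n_pn, n_np, n_nn)."""
    df = _read_csv(source)
    needed = {"well", "n_pp", "n_pn", "n_np", "n_nn"}
    missing = needed - set(df.columns)
    if missing:
        raise FormatError(f"cluster-count table missing columns: {sorted(missing)}")
    return {
        normalize_well_id(r["well"]): ClusterCounts(
            n_pp=int(r["n_pp"]), n_pn=int(r["n_pn"]),
            n_np=int(r["n_np"]), n_nn=int(r["n_nn"]),
        )
        for r in df.to_dict("records")
    }


def write_cluster_counts(counts: Mapping[str, ClusterCounts], sink) -> None:
    rows = [
        {"well": w, "n_pp": c.n_pp, "n_pn": c.n_pn, "n_np": c.n_np, "n_nn": c.n_nn}
        for w, c in sorted(counts.items())
    ]
    pd.DataFrame(rows, columns=["well", "n_pp", "n_pn", "n_np", "n_nn"]).to_csv(
        sink, index=False
    )


def _run_to_row(r: RunRecord) -> dict:
    q = r.quant
    return {
        "sample_id": r.sample_id or "",
        "assay_id": r.assay_id,
        "experiment_id": r.experiment_id,
        "well_id": r.well_id,
        "n_pp": r.counts.n_pp,
        "n_pn": r.counts.n_pn,
        "n_np": r.counts.n_np,
        "n_nn": r.counts.n_nn,
        "lambda_target": "" if q is None else repr(q.lambda_target),
        "lambda_ref": "" if q is None else repr(q.lambda_ref),
        "ratio": "" if q is None else repr(q.ratio),
        "cn_estimate": "" if q is None else repr(q.cn_estimate),
        "ci_low": "" if q is None else repr(q.ci_low),
        "ci_high": "" if q is None else repr(q.ci_high),
        "n_total": r.counts.total if q is None else q.n_total,
        "concentration_target": "" if q is None else repr(q.concentration_target),
        "concentration_ref": "" if q is None else repr(q.concentration_ref),
        "exclusion_flags": ";".join(sorted(r.exclusion_flags)),
        "acgh_cn": "" if r.acgh_cn is None else r.acgh_cn,
        "qc_status": r.qc_status,
    }


def write_results(records: Iterable[RunRecord], sink: str | Path | IO[str]) -> None:
    """Write run records as CSV.

    Floats are written with ``repr`` so that reading the table back
    reproduces every numeric field exactly (round-trip property).
    """
    rows = [_run_to_row(r) for r in records]
    pd.DataFrame(rows, columns=RESULT_COLUMNS).to_csv(sink, index=False)


def read_results(source: str | Path | IO[str]) -> list[RunRecord]:
    """Read back a results table written by :func:`write_results`."""
    if isinstance(source, (str, Path)):
        df = pd.read_csv(source, dtype=str, keep_default_na=False)
    else:
        df = pd.read_csv(source, dtype=str, keep_default_na=False)
    missing = set(RESULT_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"results table missing columns: {sorted(missing)}")
    out: list[RunRecord] = []
    for rec in df.to_dict("records"):
        counts = ClusterCounts(
            n_pp=int(rec["n_pp"]), n_pn=int(rec["n_pn"]),
            n_np=int(rec["n_np"]), n_nn=int(rec["n_nn"]),
        )
        quant = None
        if rec["cn_estimate"] != "":
            quant = WellQuant(
                lambda_target=float(rec["lambda_target"]),
                lambda_ref=float(rec["lambda_ref"]),
                ratio=float(rec["ratio"]),
                cn_estimate=float(rec["cn_estimate"]),
                ci_low=float(rec["ci_low"]),
                ci_high=float(rec["ci_high"]),
                n_total=int(rec["n_total"]),
                concentration_target=float(rec["concentration_target"]),
                concentration_ref=float(rec["concentration_ref"]),
            )
        out.append(
            RunRecord(
                sample_id=rec["sample_id"] or None,
                assay_id=rec["assay_id"],
                experiment_id=rec["experiment_id"],
                well_id=rec["well_id"],
                counts=counts,
                quant=quant,
                exclusion_flags=_parse_flags(rec["exclusion_flags"]),
                acgh_cn=None if rec["acgh_cn"] == "" else int(rec["acgh_cn"]),
                qc_status=rec["qc_status"],
            )
        )
    return out


def results_to_frame(records: Iterable[RunRecord]) -> pd.DataFrame:
    """Results as a DataFrame with numeric dtypes (for analysis, not round trip)."""
    buf = StringIO()
    write_results(records, buf)
    buf.seek(0)
    return pd.read_csv(buf)
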