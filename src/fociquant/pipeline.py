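"""Pipeline orchestration: fields → nuclei → foci → measurements → statistics.

A run is driven by a manifest (CSV or JSON) listing one row per field with
columns ``well_id, field_id, group, blue_path, green_path, red_path`` and a
flat set of processing parameters.  Outputs are a per-nucleus measurements
CSV, a two-group comparison CSV when exactly two group labels are present,
a QC table of excluded nuclei with reasons, and a JSON log of every
effective parameter.  The default path has no hidden randomness, so
identical inputs give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import pandas as pd

from .exceptions import ConfigError, DegenerateImageError
from .foci import FociImage, extract_foci
from .io import FieldImage, read_field, write_measurements
from .measure import NucleusMeasurement, measure_nucleus
from .nuclei import NucleusRecord, crop_nucleus, segment_nuclei
from .stats import MIN_GROUP_SIZE, GroupComparison, compare_groups

logger = logging.getLogger("fociquant")

MANIFEST_COLUMNS = ["well_id", "field_id", "group", "blue_path", "green_path", "red_path"]

#: per-nucleus metrics compared between groups (ra comes from red records)
COMPARED_METRICS = ["foci_count", "foci_area_px", "foci_intensity_sum"]


@dataclass
class PipelineParams:
    """Every tunable of the processing chain, with its default."""

    otsu_bins: int = 256
    opening_radius: int = 2
    min_area_px: int = 200
    max_area_px: int = 50000
    exclude_border: bool = True
    outline_method: str = "boundary"  # boundary | canny
    clusters: int = 3  # the one structural parameter of foci segmentation
    fuzziness: float = 2.0
    fcm_tol: float = 1e-5
    fcm_max_iter: int = 300
    fcm_init: str = "quantile"  # quantile (deterministic) | random
    connectivity: int = 8
    min_focus_px: int = 4
    alpha: float = 0.05
    seed: Optional[int] = None  # used only by fcm_init="random"


@dataclass
class ProcessedNucleus:
    """One nucleus after cropping, foci extraction and measurement."""

    record: NucleusRecord
    green_foci: FociImage
    red_foci: FociImage
    measurements: List[NucleusMeasurement]


def process_field(
    field: FieldImage,
    params: Optional[PipelineParams] = None,
    group: str = "",
) -> Tuple[List[ProcessedNucleus], List[dict]]:
    """Run segmentation, cropping, foci extraction and measurement on one field.

    Returns the processed nuclei and a QC list of exclusions with reasons.
    """
    params = params or PipelineParams()
    qc: List[dict] = []

    def qc_entry(reason, nucleus_id=""):
        return {
            "well_id": field.well_id,
            "field_id": field.field_id,
            "nucleus_id": nucleus_id,
            "reason": reason,
        }

    try:
        masks, seg_info = segment_nuclei(
            field.blue,
            min_area_px=params.min_area_px,
            max_area_px=params.max_area_px,
            exclude_border=params.exclude_border,
            opening_radius=params.opening_radius,
            n_bins=params.otsu_bins,
            return_info=True,
        )
    except DegenerateImageError:
        qc.append(qc_entry("degenerate_histogram"))
        return [], qc
    for reason, count in seg_info.items():
        for _ in range(count):
            qc.append(qc_entry(reason))

    processed: List[ProcessedNucleus] = []
    for nid, mask in enumerate(masks):
        record = crop_nucleus(field, mask, nucleus_id=nid, outline_method=params.outline_method)
        local = record.local_mask
        fcm_kw = dict(
            c=params.clusters,
            m=params.fuzziness,
            tol=params.fcm_tol,
            max_iter=params.fcm_max_iter,
            init=params.fcm_init,
            seed=params.seed,
        )
        green_foci = extract_foci(record.sub_green, local, **fcm_kw)
        red_foci = extract_foci(record.sub_red, local, **fcm_kw)
        for channel, img in (("green", green_foci), ("red", red_foci)):
            if "degenerate_fcm" in img.flags:
                qc.append(qc_entry(f"degenerate_fcm_{channel}", nid))
        measurements = measure_nucleus(
            nid,
            green_foci,
            red_foci,
            connectivity=params.connectivity,
            min_focus_px=params.min_focus_px,
            well_id=field.well_id,
            field_id=field.field_id,
            group=group,
        )
        if any("ra_undefined" in m.flags for m in measurements):
            qc.append(qc_entry("ra_undefined", nid))
        processed.append(ProcessedNucleus(record, green_foci, red_foci, measurements))
    return processed, qc


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Validated inputs of one pipeline run."""

    manifest: pd.DataFrame  # MANIFEST_COLUMNS, paths resolved
    output_dir: Path
    params: PipelineParams = dc_field(default_factory=PipelineParams)
    log_level: str = "INFO"


def _load_manifest(path: Path, errors: List[str]) -> Optional[pd.DataFrame]:
    try:
        if path.suffix.lower() == ".json":
            rows = json.loads(path.read_text())
            df = pd.DataFrame(rows)
        else:
            df = pd.read_csv(path, dtype=str)
    except Exception as exc:  # noqa: BLE001 - every parse failure is a config error
        errors.append(f"manifest {path}: cannot parse ({exc})")
        return None
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        errors.append(f"manifest {path}: missing columns {missing}")
        return None
    if df.empty:
        errors.append(f"manifest {path}: no fields listed")
        return None
    base = path.parent
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        for col in ("blue_path", "green_path", "red_path"):
            p = Path(str(row[col]))
            if not p.is_absolute():
                p = base / p
            if not p.exists():
                errors.append(f"manifest line {line}: {col} does not exist: {p}")
            df.at[i, col] = str(p)
    dupes = df.duplicated(subset=["well_id", "field_id"])
    for i in df.index[dupes]:
        errors.append(f"manifest line {i + 2}: duplicate well_id/field_id pair")
    return df


def validate_config(
    path: Union[str, Path],
    output_dir: Optional[Union[str, Path]] = None,
    **param_overrides,
) -> Tuple[Optional[RunConfig], List[str]]:
    """Validate a run configuration, collecting every error (not first-failure).

    ``path`` is either a manifest (CSV/JSON rows) or a JSON config object
    with a ``manifest`` key plus flat parameter keys.  Returns
    ``(RunConfig, [])`` on success or ``(None, errors)``.
    """
    path = Path(path)
    errors: List[str] = []
    if not path.exists():
        return None, [f"config file does not exist: {path}"]

    params_dict: Dict = {}
    manifest_path = path
    out_dir = Path(output_dir) if output_dir else Path("fociquant_out")
    if path.suffix.lower() == ".json":
        try:
            cfg = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            return None, [f"config {path}: invalid JSON ({exc})"]
        if isinstance(cfg, dict) and "manifest" in cfg:
            manifest_path = Path(cfg.pop("manifest"))
            if not manifest_path.is_absolute():
                manifest_path = path.parent / manifest_path
            if "output_dir" in cfg and output_dir is None:
                out_dir = Path(cfg.pop("output_dir"))
            cfg.pop("output_dir", None)
            valid_keys = {f.name for f in dataclasses.fields(PipelineParams)}
            for key, value in cfg.items():
                if key not in valid_keys:
                    errors.append(f"config {path}: unknown parameter {key!r}")
                else:
                    params_dict[key] = value
        # else: a JSON manifest (list of rows); fall through

    params_dict.update(param_overrides)
    try:
        params = PipelineParams(**params_dict)
    except TypeError as exc:
        errors.append(f"invalid parameters: {exc}")
        params = PipelineParams()

    manifest = _load_manifest(manifest_path, errors)
    if errors or manifest is None:
        return None, errors
    return RunConfig(manifest=manifest, output_dir=out_dir, params=params), []


def compare_measurement_frame(
    df: pd.DataFrame, mode: str = "auto", min_group_size: Optional[int] = MIN_GROUP_SIZE
) -> List[GroupComparison]:
    """Two-group comparisons of every metric in a measurements table.

    Requires exactly two distinct ``group`` labels.  The three foci metrics
    are compared per channel; Ra is compared over red-channel records.
    """
    groups = sorted(g for g in df["group"].dropna().unique() if str(g) != "")
    if len(groups) != 2:
        raise ConfigError(f"expected exactly 2 groups, found {groups}")
    g1 = df[df["group"] == groups[0]]
    g2 = df[df["group"] == groups[1]]
    comparisons: List[GroupComparison] = []
    for channel in ("green", "red"):
        a = g1[g1["channel"] == channel]
        b = g2[g2["channel"] == channel]
        if a.empty or b.empty:
            continue
        for metric in COMPARED_METRICS:
            comp = compare_groups(
                a.to_dict("records"),
                b.to_dict("records"),
                metric,
                group_labels=(groups[0], groups[1]),
                mode=mode,
                min_group_size=min_group_size,
            )
            comp.metric_name = f"{channel}_{metric}"
            comparisons.append(comp)
    red1 = g1[g1["channel"] == "red"]
    red2 = g2[g2["channel"] == "red"]
    if not red1.empty and not red2.empty:
        try:
            comparisons.append(
                compare_groups(
                    red1.to_dict("records"),
                    red2.to_dict("records"),
                    "ra",
                    group_labels=(groups[0], groups[1]),
                    mode=mode,
                    min_group_size=min_group_size,
                )
            )
        except ValueError:
            logger.warning("Ra undefined for every nucleus in one group; skipped")
    return comparisons


def run_pipeline(config: RunConfig) -> dict:
    """Execute a full run; returns a summary dict with output paths and counts."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))

    all_measurements: List[NucleusMeasurement] = []
    all_qc: List[dict] = []
    manifest = config.manifest.sort_values(["well_id", "field_id"], kind="mergesort")
    for _, row in manifest.iterrows():
        field = read_field(
            {"blue": row["blue_path"], "green": row["green_path"], "red": row["red_path"]},
            field_id=str(row["field_id"]),
            well_id=str(row["well_id"]),
        )
        processed, qc = process_field(field, config.params, group=str(row["group"]))
        logger.info(
            "well %s field %s: %d nuclei, %d QC notes",
            row["well_id"],
            row["field_id"],
            len(processed),
            len(qc),
        )
        all_qc.extend(qc)
        for proc in processed:
            all_measurements.extend(proc.measurements)

    measurements_path = out / "measurements.csv"
    write_measurements(all_measurements, measurements_path)
    qc_path = out / "qc.csv"
    pd.DataFrame(all_qc, columns=["well_id", "field_id", "nucleus_id", "reason"]).to_csv(
        qc_path, index=False
    )

    comparison_path = None
    df = pd.DataFrame([dataclasses.asdict(m) for m in all_measurements])
    groups = sorted(set(manifest["group"].astype(str)) - {""})
    if len(groups) == 2 and len(df):
        comparisons = compare_measurement_frame(df)
        comparison_path = out / "comparison.csv"
        pd.DataFrame([c.summary_row() for c in comparisons]).to_csv(comparison_path, index=False)

    log_path = out / "run_log.json"
    log_path.write_text(
        json.dumps(
            {
                "params": dataclasses.asdict(config.params),
                "n_fields": int(len(manifest)),
                "n_nuclei": int(len(all_measurements) // 2),
                "groups": groups,
            },
            indent=2,
        )
    )
    return {
        "measurements": measurements_path,
        "comparison": comparison_path,
        "qc": qc_path,
        "run_log": log_path,
        "n_nuclei": len(all_measurements) // 2,
        "n_fields": int(len(manifest)),
    }
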