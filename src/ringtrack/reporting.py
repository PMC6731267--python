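"""Population-level summaries and the end-to-end pipeline.

The scientific readout is the proportion of nuclei per field carrying
each gamma-H2AX phenotype (FOCI / RING / UNIFORM), aggregated per
experimental condition as the mean and standard deviation of the
per-field proportions.  Only descriptive statistics are produced here;
significance testing is left to downstream tools.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from . import imaging_io
from .colocalization import pixel_correlation
from .imaging_io import NUCLEUS_TABLE_COLUMNS, read_field, write_label_mask, write_table
from .model import (
    ClassifierParams,
    ConfigurationError,
    FieldOfView,
    Phenotype,
    SegmentationParams,
)
from .phenotype import classify_field
from .segmentation import global_binarize, segment_nuclei, smooth_dapi

logger = logging.getLogger(__name__)

__all__ = ["PopulationSummary", "RunConfig", "summarize", "analyse_field", "run_pipeline"]

_PER_FIELD_COLUMNS = [
    "condition",
    "field_id",
    "n_accepted",
    "n_foci",
    "n_ring",
    "n_uniform",
    "prop_foci",
    "prop_ring",
    "prop_uniform",
]


@dataclass
class PopulationSummary:
    """Per-field counts/proportions and per-condition summary statistics."""

    per_field: pd.DataFrame
    per_condition: pd.DataFrame


def summarize(per_nucleus: pd.DataFrame) -> PopulationSummary:
    """Aggregate a per-nucleus table into phenotype proportions.

    Counts use accepted nuclei only.  Fields with zero accepted nuclei
    keep their counts at 0 with proportions left undefined (NaN).  Per
    condition, the mean and standard deviation (ddof=1; NaN for a single
    field) of the per-field proportions are reported.
    """
    df = per_nucleus.copy()
    if "accepted" in df.columns:
        df["accepted"] = df["accepted"].astype(bool)
    rows = []
    for (condition, field_id), grp in df.groupby(["condition", "field_id"], sort=True):
        acc = grp[grp["accepted"]] if "accepted" in grp.columns else grp
        n = len(acc)
        counts = acc["phenotype"].value_counts()
        n_foci = int(counts.get(Phenotype.FOCI.value, 0))
        n_ring = int(counts.get(Phenotype.RING.value, 0))
        n_uniform = int(counts.get(Phenotype.UNIFORM.value, 0))
        rows.append(
            {
                "condition": condition,
                "field_id": field_id,
                "n_accepted": n,
                "n_foci": n_foci,
                "n_ring": n_ring,
                "n_uniform": n_uniform,
                "prop_foci": n_foci / n if n else float("nan"),
                "prop_ring": n_ring / n if n else float("nan"),
                "prop_uniform": n_uniform / n if n else float("nan"),
            }
        )
    per_field = pd.DataFrame(rows, columns=_PER_FIELD_COLUMNS)
    if per_field.empty or int(per_field["n_accepted"].sum()) == 0:
        logger.warning("summary over zero accepted nuclei")
    stats = []
    for condition, grp in per_field.groupby("condition", sort=True):
        entry = {"condition": condition, "n_fields": len(grp)}
        for prop in ("prop_foci", "prop_ring", "prop_uniform"):
            vals = grp[prop].dropna()
            entry[f"mean_{prop}"] = float(vals.mean()) if len(vals) else float("nan")
            entry[f"sd_{prop}"] = float(vals.std(ddof=1)) if len(vals) > 1 else float("nan")
        stats.append(entry)
    return PopulationSummary(per_field=per_field, per_condition=pd.DataFrame(stats))


def analyse_field(
    fov: FieldOfView,
    seg_params: SegmentationParams | None = None,
    cls_params: ClassifierParams | None = None,
) -> tuple[pd.DataFrame, "LabelMask", dict]:
    """Segment, classify and (when 53BP1 is present) correlate one field.

    Returns the per-nucleus table (accepted and rejected candidates),
    the accepted-nucleus label mask, and a provenance dict with the
    computed global threshold and counts.
    """
    seg_params = seg_params or SegmentationParams()
    cls_params = cls_params or ClassifierParams()
    smoothed = smooth_dapi(fov.dapi, seg_params.gaussian_sigma_px)
    _, threshold = global_binarize(smoothed, return_threshold=True)
    mask, records = segment_nuclei(fov, seg_params)
    accepted = [r for r in records if r.accepted]
    calls = {c.nucleus_id: c for c in classify_field(fov.gh2ax, mask, records, cls_params)}

    pearson: dict[int, float] = {}
    if fov.p53bp1 is not None:
        for rec in accepted:
            res = pixel_correlation(
                fov.gh2ax, fov.p53bp1, mask.labels == rec.nucleus_id, rec.nucleus_id
            )
            pearson[rec.nucleus_id] = res.pearson_r

    rows = []
    for rec in records:
        call = calls.get(rec.nucleus_id) if rec.accepted else None
        ring_score = float("nan")
        if call is not None and call.radial is not None:
            ring_score = call.radial.ring_score
        rows.append(
            {
                "field_id": fov.field_id,
                "condition": fov.condition,
                "nucleus_id": rec.nucleus_id,
                "area_px": rec.area_px,
                "perimeter_px": rec.perimeter_px,
                "centroid_row": rec.centroid[0],
                "centroid_col": rec.centroid[1],
                "eccentricity": rec.eccentricity,
                "circularity": rec.circularity,
                "mean_dapi": rec.mean_dapi,
                "accepted": rec.accepted,
                "rejection_reason": rec.rejection_reason.value,
                "foci_count": call.foci.foci_count if call else np.nan,
                "foci_density": call.foci.foci_density if call else np.nan,
                "ring_score": ring_score,
                "phenotype": call.phenotype.value if call else "",
                "pearson_gh2ax_53bp1": pearson.get(rec.nucleus_id, np.nan),
            }
        )
    table = pd.DataFrame(rows, columns=NUCLEUS_TABLE_COLUMNS)
    provenance = {
        "field_id": fov.field_id,
        "condition": fov.condition,
        "global_threshold": threshold,
        "n_candidates": len(records),
        "n_accepted": len(accepted),
    }
    return table, mask, provenance


@dataclass
class RunConfig:
    """Run description: fields, plate map and parameters.

    Condition labels are always taken from the ``plate_map`` (field_id
    -> condition); they are never inferred from file names.
    """

    fields: list[dict]
    plate_map: dict[str, str]
    segmentation: SegmentationParams = dc_field(default_factory=SegmentationParams)
    classifier: ClassifierParams = dc_field(default_factory=ClassifierParams)
    out_dir: str = "ringtrack_out"
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        seg = SegmentationParams(**raw.get("segmentation", {}))
        clf = ClassifierParams(**raw.get("classifier", {}))
        if "fields" not in raw or "plate_map" not in raw:
            raise ConfigurationError("config requires 'fields' and 'plate_map' sections")
        return cls(
            fields=list(raw["fields"]),
            plate_map=dict(raw["plate_map"]),
            segmentation=seg,
            classifier=clf,
            out_dir=str(raw.get("out_dir", "ringtrack_out")),
            seed=int(raw.get("seed", 0)),
            log_level=str(raw.get("log_level", "INFO")),
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def load_fields(self) -> list[FieldOfView]:
        fovs = []
        for entry in self.fields:
            field_id = str(entry["field_id"])
            if field_id not in self.plate_map:
                raise ConfigurationError(f"field {field_id!r} missing from plate_map")
            channel_map = {
                role: tuple(src) if isinstance(src, list) else src
                for role, src in entry["channels"].items()
            }
            fovs.append(
                read_field(
                    entry.get("stack"),
                    channel_map,
                    condition=self.plate_map[field_id],
                    field_id=field_id,
                )
            )
        return fovs


def run_pipeline(config: RunConfig) -> dict:
    """Run the whole analysis and write the output bundle.

    Writes per-nucleus CSV, per-field and per-condition summary CSVs,
    one 16-bit label-mask TIFF per field and a provenance JSON recording
    every parameter and computed global threshold.  Identical configs
    (and seeds) produce byte-identical CSVs.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables, provenances = [], []
    for fov in config.load_fields():
        table, mask, prov = analyse_field(fov, config.segmentation, config.classifier)
        write_label_mask(mask, out / f"{fov.field_id}_nuclei_mask.tif")
        tables.append(table)
        provenances.append(prov)

    per_nucleus = (
        pd.concat(tables, ignore_index=True)
        if tables
        else pd.DataFrame(columns=NUCLEUS_TABLE_COLUMNS)
    )
    write_table(per_nucleus, out / "per_nucleus.csv")
    summary = summarize(per_nucleus)
    summary.per_field.to_csv(out / "summary_per_field.csv", index=False, lineterminator="\n")
    summary.per_condition.to_csv(
        out / "summary_per_condition.csv", index=False, lineterminator="\n"
    )
    provenance = {
        "segmentation": vars(config.segmentation),
        "classifier": {
            k: v for k, v in vars(config.classifier).items()
        },
        "seed": config.seed,
        "fields": provenances,
    }
    with open(out / "provenance.json", "w", encoding="utf-8") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True, default=str)
    return {
        "per_nucleus": per_nucleus,
        "summary": summary,
        "out_dir": str(out),
        "provenance": provenance,
    }
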