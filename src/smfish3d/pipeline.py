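"""Batch orchestration: detect both channels per ROI, match, quantify.

The runner never aborts a batch on a single bad ROI: any stage error is
recorded in the summary for that ROI and processing continues. Everything
needed to audit a run — package version, a hash of the resolved config, and
the per-channel thresholds actually selected — is persisted in
``summary.json``.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import pandas as pd
import yaml

from . import __version__
from .colocalization import match_spots
from .detection import DetectionConfig, detect_spots
from .errors import FormatError, SmfishError
from .io_roi import ROI, ImageStack, RoiTable, extract_roi, read_roi_table, read_stack
from .quantification import (
    QuantRecord,
    count_nuclei,
    mrna_per_cell,
    normalized_expression,
    qc_summary,
)

log = logging.getLogger("smfish3d")


@dataclass
class ChannelSpec:
    label: str
    stack: str
    channel_index: Optional[int] = None  # for multi-channel TIFFs


@dataclass
class RunConfig:
    """Resolved configuration for one batch run."""

    channel_a: ChannelSpec
    channel_b: ChannelSpec
    output: str
    sample_id: str = "sample"
    counterstain: Optional[ChannelSpec] = None
    roi_table: Optional[str] = None
    d_max: float = 3.0
    detection: Dict = field(default_factory=dict)
    detection_a: Dict = field(default_factory=dict)
    detection_b: Dict = field(default_factory=dict)
    #: optional {"target": "a"|"b", "reference": "b"|"a"} for per-ROI
    #: normalized expression (target transcript count over reference count)
    normalization: Optional[Dict] = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        labels = [self.channel_a.label, self.channel_b.label]
        if self.counterstain is not None:
            labels.append(self.counterstain.label)
        if len(set(labels)) != len(labels):
            raise FormatError(f"channel labels must be distinct, got {labels}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw, base=Path(path).parent)

    @classmethod
    def from_dict(cls, raw: Dict, base: Optional[Path] = None) -> "RunConfig":
        base = base or Path(".")

        def _chan(key: str, required: bool) -> Optional[ChannelSpec]:
            entry = raw.get(key)
            if entry is None:
                if required:
                    raise FormatError(f"config is missing required channel {key!r}")
                return None
            spec = ChannelSpec(
                label=str(entry["label"]),
                stack=str((base / entry["stack"]).resolve()),
                channel_index=entry.get("channel_index"),
            )
            if not Path(spec.stack).exists():
                raise FormatError(f"{key}: stack file not found: {spec.stack}")
            return spec

        roi_table = raw.get("roi_table")
        if roi_table is not None:
            roi_table = str((base / roi_table).resolve())
            if not Path(roi_table).exists():
                raise FormatError(f"roi_table not found: {roi_table}")
        return cls(
            channel_a=_chan("channel_a", required=True),  # type: ignore[arg-type]
            channel_b=_chan("channel_b", required=True),  # type: ignore[arg-type]
            counterstain=_chan("counterstain", required=False),
            output=str((base / raw.get("output", "smfish3d_out")).resolve()),
            sample_id=str(raw.get("sample_id", "sample")),
            roi_table=roi_table,
            d_max=float(raw.get("d_max", 3.0)),
            detection=dict(raw.get("detection", {})),
            detection_a=dict(raw.get("detection_a", {})),
            detection_b=dict(raw.get("detection_b", {})),
            normalization=raw.get("normalization"),
            log_level=str(raw.get("log_level", "INFO")),
        )

    def config_hash(self) -> str:
        canon = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    def detection_config(self, which: str) -> DetectionConfig:
        merged = dict(self.detection)
        merged.update(self.detection_a if which == "a" else self.detection_b)
        return DetectionConfig(**merged)


def _roi_list(config: RunConfig, shape: Tuple[int, int, int]):
    """ROIs from the table, or one full-stack ROI when no table is given."""
    if config.roi_table is None:
        yield config.sample_id, "full", ROI(origin=(0, 0, 0), size=shape), None
        return
    table: RoiTable = read_roi_table(config.roi_table)
    yield from table.iter_rois()


def run_pipeline(config: RunConfig) -> Dict:
    """Run detect -> match -> quantify over every ROI; write the report bundle.

    Returns the summary dict (also written to ``summary.json``). The summary
    lists per-ROI thresholds, counts, both co-localization ratios, and any
    per-ROI failures; pairs + unmatched always equals detected per channel.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.output)
    outdir.mkdir(parents=True, exist_ok=True)

    stack_a = read_stack(
        config.channel_a.stack, config.channel_a.label, config.channel_a.channel_index
    )
    stack_b = read_stack(
        config.channel_b.stack, config.channel_b.label, config.channel_b.channel_index
    )
    hoechst = None
    if config.counterstain is not None:
        hoechst = read_stack(
            config.counterstain.stack,
            config.counterstain.label,
            config.counterstain.channel_index,
        )

    summary: Dict = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "d_max": config.d_max,
        "channels": {
            "a": config.channel_a.label,
            "b": config.channel_b.label,
        },
        "rois": [],
        "failures": [],
    }
    quant_rows: List[Dict] = []
    qc_bundle: Dict = {}

    for sample_id, roi_id, roi, manual_nuclei in _roi_list(config, stack_a.shape):
        tag = f"{sample_id}_{roi_id}"
        try:
            sub_a = extract_roi(stack_a, roi)
            sub_b = extract_roi(stack_b, roi)
            spots_a = detect_spots(sub_a, config.detection_config("a"))
            spots_b = detect_spots(sub_b, config.detection_config("b"))
            result = match_spots(spots_a, spots_b, d_max=config.d_max)

            spots_a.to_csv(outdir / f"spots_{tag}_{spots_a.channel_label}.csv", sample_id, roi_id)
            spots_b.to_csv(outdir / f"spots_{tag}_{spots_b.channel_label}.csv", sample_id, roi_id)
            for spots in (spots_a, spots_b):
                if spots.curve is not None:
                    spots.curve.to_dataframe().to_csv(
                        outdir / f"curve_{tag}_{spots.channel_label}.csv", index=False
                    )
            pd.DataFrame(
                result.pairs, columns=["label_a", "label_b", "distance"]
            ).to_csv(outdir / f"pairs_{tag}.csv", index=False)
            pd.DataFrame(
                {
                    "channel": [spots_a.channel_label] * len(result.unmatched_a)
                    + [spots_b.channel_label] * len(result.unmatched_b),
                    "label": result.unmatched_a + result.unmatched_b,
                }
            ).to_csv(outdir / f"unmatched_{tag}.csv", index=False)

            nucleus_count, nucleus_note = manual_nuclei, "manual"
            if nucleus_count is None and hoechst is not None:
                nucleus_count = count_nuclei(extract_roi(hoechst, roi))
                nucleus_note = "automatic"
            counts = {"a": len(spots_a), "b": len(spots_b)}
            for which, spots in (("a", spots_a), ("b", spots_b)):
                rec = QuantRecord(
                    sample_id=sample_id,
                    roi_id=roi_id,
                    channel_label=spots.channel_label,
                    spot_count=len(spots),
                    nucleus_count=nucleus_count,
                    notes=f"nuclei:{nucleus_note}" if nucleus_count is not None else "",
                )
                if nucleus_count:
                    rec.mrna_per_cell = mrna_per_cell(len(spots), nucleus_count)
                row = asdict(rec)
                if config.normalization and which == config.normalization.get("target"):
                    ref = config.normalization.get("reference", "b" if which == "a" else "a")
                    try:
                        row["normalized_expression"] = normalized_expression(
                            counts[which], counts[ref], roi_id=roi_id
                        )
                    except SmfishError as exc:
                        row["normalized_expression"] = None
                        row["notes"] += f"; {exc}"
                quant_rows.append(row)
                qc_bundle[f"{tag}_{spots.channel_label}"] = qc_summary(spots).to_dict()

            roi_summary = {
                "sample": sample_id,
                "roi": roi_id,
                "thresholds": {
                    spots_a.channel_label: spots_a.threshold_used,
                    spots_b.channel_label: spots_b.threshold_used,
                },
                "flat_curve_warning": {
                    spots.channel_label: bool(spots.curve.flat_warning)
                    for spots in (spots_a, spots_b)
                    if spots.curve is not None
                },
                "n_spots": {
                    spots_a.channel_label: len(spots_a),
                    spots_b.channel_label: len(spots_b),
                },
                "n_pairs": result.n_pairs,
                "n_unmatched": {
                    spots_a.channel_label: len(result.unmatched_a),
                    spots_b.channel_label: len(result.unmatched_b),
                },
                "ratio_a_in_b": result.ratio_a_in_b,
                "ratio_b_in_a": result.ratio_b_in_a,
                "nucleus_count": nucleus_count,
            }
            summary["rois"].append(roi_summary)
            log.info(
                "ROI %s: thresholds %s, %d pairs, ratios %.3f/%.3f",
                tag,
                roi_summary["thresholds"],
                result.n_pairs,
                result.ratio_a_in_b or float("nan"),
                result.ratio_b_in_a or float("nan"),
            )
        except SmfishError as exc:
            log.error("ROI %s failed: %s", tag, exc)
            summary["failures"].append({"sample": sample_id, "roi": roi_id, "error": str(exc)})

    pd.DataFrame(quant_rows).to_csv(outdir / "quant.csv", index=False)
    with open(outdir / "qc.json", "w") as fh:
        json.dump(qc_bundle, fh, indent=2, sort_keys=True)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
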