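"""Pipeline configuration and stage runner.

A single JSON config wires the stages (simulate -> score -> normalize / qc ->
screen -> fit).  Seeds are mandatory — there is no wall-clock seeding — and
per-stage sub-seeds are derived deterministically, so identical config + seed
gives identical CSV/JSON outputs.  Every output directory receives a config
snapshot for provenance.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, MyeliscreenError
from .fiber_morphometrics import FiberParams, FieldScores, score_field
from .imaging_io import (
    PlateLayout,
    load_plate_layout,
    read_field_image,
    read_score_table,
    write_field_image,
    write_plate_layout,
    write_score_table,
)
from .plate_analytics import build_score_table, plate_qc
from .screening import (
    HitCriteria,
    call_primary_hits,
    calls_to_frame,
    confirm_hits,
    hit_summary,
    refine_hits,
)
from .segmentation import SegmentationParams
from .synthdata import (
    FieldSpec,
    PlantedHit,
    ScreenSpec,
    confirmation_tables,
    simulate_screen,
)

log = logging.getLogger("myeliscreen")

STAGE_ORDER = ("simulate", "score", "normalize", "qc", "screen", "fit")


def _from_mapping(cls, data: dict, context: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise FormatError(f"unknown key(s) in {context}: {sorted(unknown)}")
    return cls(**data)


@dataclass
class PipelineConfig:
    """Validated pipeline configuration; unknown keys are rejected."""

    seed: int
    screen: ScreenSpec = dc_field(default_factory=ScreenSpec)
    field: FieldSpec = dc_field(default_factory=FieldSpec)
    segmentation: SegmentationParams = dc_field(default_factory=SegmentationParams)
    fibers: FiberParams = dc_field(default_factory=FiberParams)
    hit_criteria: HitCriteria = dc_field(default_factory=HitCriteria)
    mbp_threshold: str = "otsu"
    qc_window_center: float = 1.3
    qc_window_halfwidth: float = 0.2
    render_images: bool = False
    write_images: bool = False

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        if "seed" not in data:
            raise FormatError("config must set an integer seed (no wall-clock seeding)")
        sub = {}
        if "screen" in data:
            sdata = dict(data.pop("screen"))
            hits = [
                _from_mapping(PlantedHit, h, "screen.planted_hits")
                for h in sdata.pop("planted_hits", [])
            ]
            concs = sdata.pop("concentrations", None)
            spec = _from_mapping(ScreenSpec, sdata, "screen")
            spec.planted_hits = hits
            if concs is not None:
                spec.concentrations = tuple(concs)
            sub["screen"] = spec
        for key, typ in (
            ("field", FieldSpec),
            ("segmentation", SegmentationParams),
            ("fibers", FiberParams),
            ("hit_criteria", HitCriteria),
        ):
            if key in data:
                payload = dict(data.pop(key))
                if key == "field" and "image_shape" in payload:
                    payload["image_shape"] = tuple(payload["image_shape"])
                if key == "fibers" and "ridge_scales" in payload:
                    payload["ridge_scales"] = tuple(payload["ridge_scales"])
                sub[key] = _from_mapping(typ, payload, key)
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - names
        if unknown:
            raise FormatError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data, **sub)

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))

    def to_dict(self) -> dict:
        def encode(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: encode(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, (tuple, list)):
                return [encode(v) for v in obj]
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            return obj

        return {
            "seed": self.seed,
            "screen": encode(self.screen),
            "field": encode(self.field),
            "segmentation": encode(self.segmentation),
            "fibers": encode(self.fibers),
            "hit_criteria": encode(self.hit_criteria),
            "mbp_threshold": self.mbp_threshold,
            "qc_window_center": self.qc_window_center,
            "qc_window_halfwidth": self.qc_window_halfwidth,
            "render_images": self.render_images,
            "write_images": self.write_images,
        }


def _stage_seed(seed: int, stage: str) -> int:
    ss = np.random.SeedSequence([seed, STAGE_ORDER.index(stage)])
    return int(ss.generate_state(1)[0] % (2**31))


def _field_scores_frame(plates) -> pd.DataFrame:
    rows = []
    for plate in plates:
        for well, fields in sorted(plate.field_scores.items()):
            for i, f in enumerate(fields, start=1):
                rows.append(
                    {
                        "plate_id": plate.layout.plate_id,
                        "well": well,
                        "field_index": i,
                        "n_dapi": f.n_dapi,
                        "n_olig2": f.n_olig2,
                        "mbp_score": f.mbp_score,
                        "fiber_score": f.fiber_score,
                        "fiber_mbp": f.fiber_mbp,
                        "usable": f.usable,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "plate_id",
            "well",
            "field_index",
            "n_dapi",
            "n_olig2",
            "mbp_score",
            "fiber_score",
            "fiber_mbp",
            "usable",
        ],
    )


def _load_field_scores(path: Path) -> dict[str, dict[str, list[FieldScores]]]:
    df = pd.read_csv(path)
    out: dict[str, dict[str, list[FieldScores]]] = {}
    for _, row in df.iterrows():
        usable = bool(row["usable"])
        fs = FieldScores(
            int(row["n_dapi"]),
            int(row["n_olig2"]),
            None if pd.isna(row["mbp_score"]) else float(row["mbp_score"]),
            None if pd.isna(row["fiber_score"]) else float(row["fiber_score"]),
            None if pd.isna(row["fiber_mbp"]) else float(row["fiber_mbp"]),
            usable,
        )
        out.setdefault(str(row["plate_id"]), {}).setdefault(str(row["well"]), []).append(fs)
    return out


def _require(path: Path, stage: str, producer: str) -> Path:
    if not path.exists():
        raise MyeliscreenError(
            f"stage {stage!r}: missing input artifact {path} (produced by {producer!r})"
        )
    return path


def _load_layouts(out_dir: Path) -> list[PlateLayout]:
    paths = sorted((out_dir / "layouts").glob("*.csv"))
    if not paths:
        raise MyeliscreenError(f"no layout CSVs under {out_dir / 'layouts'}")
    return [load_plate_layout(p) for p in paths]


def run_pipeline(
    config: PipelineConfig, stages: Sequence[str], out_dir: str | Path
) -> dict:
    """Execute the requested stages in canonical order; returns a run report."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bad = [s for s in stages if s not in STAGE_ORDER]
    if bad:
        raise MyeliscreenError(f"unknown stage(s): {bad}")
    stages = [s for s in STAGE_ORDER if s in stages]
    if "simulate" in stages and "score" in stages and not config.render_images:
        # score-mode simulation already yields field scores; nothing to re-score
        stages.remove("score")
    with open(out_dir / "config_snapshot.json", "w", encoding="utf-8") as fh:
        json.dump(config.to_dict(), fh, indent=2, sort_keys=True)
    report: dict = {"stages": {}}
    handler = logging.FileHandler(out_dir / "pipeline.log")
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        for stage in stages:
            t0 = time.perf_counter()
            info = _run_stage(config, stage, out_dir)
            info["wall_s"] = round(time.perf_counter() - t0, 3)
            report["stages"][stage] = info
            log.info("stage %s done in %.2fs: %s", stage, info["wall_s"], info)
    finally:
        log.removeHandler(handler)
        handler.close()
    with open(out_dir / "run_report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


def _run_stage(config: PipelineConfig, stage: str, out_dir: Path) -> dict:
    seed = _stage_seed(config.seed, "simulate")  # one stream per simulated screen
    if stage == "simulate":
        result = simulate_screen(
            config.screen,
            seed,
            render_images=config.render_images,
            field_spec=config.field,
            score_fields=not config.render_images,
        )
        (out_dir / "layouts").mkdir(exist_ok=True)
        for plate in result.plates:
            write_plate_layout(plate.layout, out_dir / "layouts" / f"{plate.layout.plate_id}.csv")
        result.truth.to_csv(out_dir / "truth.csv", index=False)
        n_images = 0
        if config.render_images:
            manifest_rows = []
            img_dir = out_dir / "images"
            for plate in result.plates:
                for well, imgs in sorted((plate.images or {}).items()):
                    for img in imgs:
                        paths = write_field_image(img, img_dir)
                        n_images += 1
                        manifest_rows.append(
                            {
                                "plate_id": img.plate_id,
                                "well": img.well,
                                "field_index": img.field_index,
                                **{f"path_{ch}": str(p) for ch, p in paths.items()},
                            }
                        )
            pd.DataFrame(manifest_rows).to_csv(out_dir / "manifest.csv", index=False)
        else:
            _field_scores_frame(result.plates).to_csv(out_dir / "field_scores.csv", index=False)
        return {"n_plates": len(result.plates), "n_images": n_images}
    if stage == "score":
        manifest = _require(out_dir / "manifest.csv", stage, "simulate (render_images)")
        df = pd.read_csv(manifest)
        rows = []
        for _, row in df.iterrows():
            img = read_field_image(
                {ch: row[f"path_{ch}"] for ch in ("MBP", "Olig2", "DAPI")},
                str(row["plate_id"]),
                str(row["well"]),
                int(row["field_index"]),
            )
            f = score_field(img, config.segmentation, config.fibers, config.mbp_threshold)
            rows.append(
                {
                    "plate_id": img.plate_id,
                    "well": img.well,
                    "field_index": img.field_index,
                    "n_dapi": f.n_dapi,
                    "n_olig2": f.n_olig2,
                    "mbp_score": f.mbp_score,
                    "fiber_score": f.fiber_score,
                    "fiber_mbp": f.fiber_mbp,
                    "usable": f.usable,
                }
            )
        pd.DataFrame(rows).to_csv(out_dir / "field_scores.csv", index=False)
        return {"n_fields": len(rows)}
    if stage in ("normalize", "qc"):
        scores_path = _require(out_dir / "field_scores.csv", stage, "simulate or score")
        layouts = _load_layouts(out_dir)
        by_plate = _load_field_scores(scores_path)
        plates = [(lay, by_plate.get(lay.plate_id, {})) for lay in layouts]
        if stage == "normalize":
            table = build_score_table(plates)
            write_score_table(table, out_dir / "score_table.csv")
            return {"n_conditions": len(table)}
        reports = [
            plate_qc(fs, lay, config.qc_window_center, config.qc_window_halfwidth).to_dict()
            for lay, fs in plates
        ]
        with open(out_dir / "qc.json", "w", encoding="utf-8") as fh:
            json.dump(reports, fh, indent=2, sort_keys=True)
        return {"n_plates": len(reports), "n_pass": sum(r["pass"] for r in reports)}
    if stage == "screen":
        table = read_score_table(_require(out_dir / "score_table.csv", stage, "normalize"))
        calls = call_primary_hits(table, config.hit_criteria)
        calls = refine_hits(calls, table, config.hit_criteria)
        calls_to_frame(calls).to_csv(out_dir / "hits.csv", index=False)
        summary = hit_summary(calls)
        with open(out_dir / "hits_summary.json", "w", encoding="utf-8") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        return summary
    if stage == "fit":
        _require(out_dir / "hits.csv", stage, "screen")
        table = read_score_table(_require(out_dir / "score_table.csv", stage, "normalize"))
        calls = call_primary_hits(table, config.hit_criteria)
        calls = refine_hits(calls, table, config.hit_criteria)
        refined_ids = [c.compound_id for c in calls if c.rank >= 2]
        dr_dir = out_dir / "dose_response"
        tables: dict[str, list[pd.DataFrame]] = {}
        for cid in refined_ids:
            found = sorted(dr_dir.glob(f"{cid}_rep*.csv")) if dr_dir.exists() else []
            if found:
                tables[cid] = [pd.read_csv(p) for p in found]
        missing = [cid for cid in refined_ids if cid not in tables]
        if missing and (out_dir / "truth.csv").exists():
            # simulated screen: generate confirmation experiments from planted truth
            sim_tables = confirmation_tables(
                config.screen, missing, _stage_seed(config.seed, "fit")
            )
            dr_dir.mkdir(exist_ok=True)
            for cid, tabs in sim_tables.items():
                for i, tab in enumerate(tabs, start=1):
                    tab.to_csv(dr_dir / f"{cid}_rep{i}.csv", index=False)
            tables.update(sim_tables)
        calls = confirm_hits(calls, tables, config.hit_criteria)
        calls_to_frame(calls).to_csv(out_dir / "hits_confirmed.csv", index=False)
        summary = hit_summary(calls)
        with open(out_dir / "hits_summary.json", "w", encoding="utf-8") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        return summary
    raise MyeliscreenError(f"unknown stage {stage!r}")
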