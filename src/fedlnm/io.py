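"""Configuration files, cohort CSV round-tripping and image export.

The cohort CSV schema mirrors the study's medical-record field list (one row
per patient) extended with the pathology ground truth and one call column per
modality. Images are 8-bit grayscale PNGs with parallel ``*_mask.png`` files
and a JSON manifest mapping patient ids to files.
"""

from __future__ import annotations

import csv
import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import numpy as np
import yaml
from PIL import Image

from .cohort import CohortConfig, ImageConfig, PatientRecord, SyntheticImage
from .exceptions import ConfigurationError, SchemaError
from .experiments import ExperimentSpec

logger = logging.getLogger("fedlnm")

__all__ = ["RunConfig", "load_config", "save_config",
           "read_cohort_csv", "write_cohort_csv",
           "save_images", "load_images", "config_hash"]

COHORT_COLUMNS = [
    "Hospital ID", "Diagnosis result", "Age", "FIGO stage", "LVSI",
    "Stromal invasion", "Histology", "Grade", "Pathology LNM",
    "CT call", "MRI call", "PET/CT call", "Image ID",
]
_CALL_VALUES = {"positive", "negative", "not_performed"}


@dataclass(frozen=True)
class RunConfig:
    """Top-level configuration: cohort, image and experiment sections."""

    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    image: ImageConfig = field(default_factory=ImageConfig)
    experiment: ExperimentSpec = field(default_factory=ExperimentSpec)


def _build_dataclass(cls, data: dict, context: str):
    names = {f.name: f for f in dc_fields(cls)}
    unknown = sorted(set(data) - set(names))
    if unknown:
        raise ConfigurationError(f"unknown key(s) in {context}: {', '.join(unknown)}")
    def tuplify(v):
        if isinstance(v, list):
            return tuple(tuplify(x) for x in v)
        if isinstance(v, dict):
            return {k: tuplify(x) for k, x in v.items()}
        return v

    return cls(**{k: tuplify(v) for k, v in data.items()})


def load_config(path) -> RunConfig:
    """Parse a YAML run configuration; missing keys fall back to defaults,
    unknown keys raise a :class:`ConfigurationError` naming them."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ConfigurationError(f"config root must be a mapping, got {type(data).__name__}")
    unknown = sorted(set(data) - {"seed", "cohort", "image", "experiment"})
    if unknown:
        raise ConfigurationError(f"unknown top-level key(s): {', '.join(unknown)}")
    return RunConfig(
        seed=int(data.get("seed", 0)),
        cohort=_build_dataclass(CohortConfig, data.get("cohort") or {}, "cohort"),
        image=_build_dataclass(ImageConfig, data.get("image") or {}, "image"),
        experiment=_build_dataclass(ExperimentSpec, data.get("experiment") or {},
                                    "experiment"),
    )


def save_config(cfg: RunConfig, path) -> None:
    payload = {
        "seed": cfg.seed,
        "cohort": _plain(dataclasses.asdict(cfg.cohort)),
        "image": _plain(dataclasses.asdict(cfg.image)),
        "experiment": _plain(dataclasses.asdict(cfg.experiment)),
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def config_hash(cfg: RunConfig) -> str:
    """Stable short hash of a configuration, for run logs."""
    blob = json.dumps(_plain({
        "seed": cfg.seed,
        "cohort": dataclasses.asdict(cfg.cohort),
        "image": dataclasses.asdict(cfg.image),
        "experiment": dataclasses.asdict(cfg.experiment),
    }), sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# Cohort CSV
# ---------------------------------------------------------------------------

def write_cohort_csv(records: list[PatientRecord], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(COHORT_COLUMNS)
        for r in records:
            w.writerow([
                r.patient_id, r.diagnosis, r.age, r.figo_stage,
                "true" if r.lvsi else "false",
                r.stromal_invasion, r.histology, r.grade,
                "true" if r.true_lnm else "false",
                r.calls.get("CT", "not_performed"),
                r.calls.get("MRI", "not_performed"),
                r.calls.get("PET/CT", "not_performed"),
                r.image_id or "",
            ])


def read_cohort_csv(path) -> list[PatientRecord]:
    """Parse a cohort CSV; schema violations name the column, cell errors the line."""
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in COHORT_COLUMNS if c not in header]
        if missing:
            raise SchemaError(f"cohort file missing column(s): {', '.join(missing)}")
        records = []
        for lineno, row in enumerate(reader, start=2):
            try:
                calls = {}
                for mod, col in (("CT", "CT call"), ("MRI", "MRI call"),
                                 ("PET/CT", "PET/CT call")):
                    v = row[col].strip()
                    if v not in _CALL_VALUES:
                        raise ValueError(f"invalid call {v!r} in column {col!r}")
                    calls[mod] = v
                records.append(PatientRecord(
                    patient_id=row["Hospital ID"],
                    diagnosis=row["Diagnosis result"],
                    age=int(row["Age"]),
                    figo_stage=row["FIGO stage"],
                    lvsi=_parse_bool(row["LVSI"]),
                    stromal_invasion=row["Stromal invasion"],
                    histology=row["Histology"],
                    grade=row["Grade"],
                    true_lnm=_parse_bool(row["Pathology LNM"]),
                    calls=calls,
                    image_id=row["Image ID"] or None,
                ))
            except (KeyError, ValueError) as exc:
                raise SchemaError(f"line {lineno}: {exc}") from exc
    return records


def _parse_bool(s: str) -> bool:
    v = s.strip().lower()
    if v in ("true", "1", "yes"):
        return True
    if v in ("false", "0", "no"):
        return False
    raise ValueError(f"invalid boolean {s!r}")


# ---------------------------------------------------------------------------
# Images
# ---------------------------------------------------------------------------

def save_images(images: dict[str, SyntheticImage], outdir,
                records: list[PatientRecord] | None = None) -> Path:
    """Write 8-bit grayscale PNGs plus masks and a patient->file manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {}
    for img_id, img in images.items():
        px = Image.fromarray(np.round(img.pixels * 255).astype(np.uint8), mode="L")
        mk = Image.fromarray((img.mask.astype(np.uint8)) * 255, mode="L")
        px.save(outdir / f"{img_id}.png")
        mk.save(outdir / f"{img_id}_mask.png")
        manifest[img_id] = {"image": f"{img_id}.png", "mask": f"{img_id}_mask.png",
                            "label": bool(img.label)}
    if records is not None:
        by_patient = {r.patient_id: r.image_id for r in records if r.image_id}
        manifest = {"images": manifest, "patients": by_patient}
    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return mpath


def load_images(manifest_path) -> dict[str, SyntheticImage]:
    mdir = Path(manifest_path).parent
    manifest = json.loads(Path(manifest_path).read_text())
    entries = manifest.get("images", manifest)
    out = {}
    for img_id, entry in entries.items():
        px = np.asarray(Image.open(mdir / entry["image"]), dtype=float) / 255.0
        mk = np.asarray(Image.open(mdir / entry["mask"])) > 127
        out[img_id] = SyntheticImage(pixels=px, mask=mk, label=bool(entry["label"]))
    return out
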