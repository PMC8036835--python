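"""On-disk dataset bundle: radar raw data, reference vitals, participant table.

Layout (mirroring the published child vital-sign repository structure)::

    <root>/
      manifest.json            format version, participant count, config, seed
      Rawdata/P001.h5 ...      complex IF cube + serialized RadarConfig attrs
      VitalSign/P001.h5 ...    125 Hz reference waveforms + per-second rates
      VitalSign/P001_vitals.csv   (optional) radar-extracted vitals export
      Participants/participants.csv

HDF5 files are written with ``track_times=False`` so identical inputs
produce byte-identical bundles.  Opening a bundle validates the structure
but reads no cube payloads; arrays load lazily per participant.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .errors import BundleError
from .radar_model import RadarConfig, RadarCube
from .synthetic_data import ParticipantMeta, ReferenceRecord, VitalProfile
from .vitals_extraction import VitalsEstimate

FORMAT_VERSION = 1
_FOLDERS = ("Rawdata", "VitalSign", "Participants")
_MARKER = ".incomplete"

__all__ = [
    "StudyData",
    "DatasetBundle",
    "write_bundle",
    "read_bundle",
    "export_vitals_csv",
    "read_vitals_csv",
]


@dataclass
class StudyData:
    """A simulated study held in memory, keyed by participant id."""

    config: RadarConfig
    duration: float
    seed: int
    cohort: list[ParticipantMeta]
    profiles: dict[int, VitalProfile]
    cubes: dict[int, RadarCube]
    references: dict[int, ReferenceRecord]

    @property
    def participant_ids(self) -> list[int]:
        return [m.id for m in self.cohort]

    # duck-typed bundle interface (same surface as DatasetBundle)
    def load_cube(self, pid: int) -> RadarCube:
        return self.cubes[pid]

    def load_reference(self, pid: int) -> ReferenceRecord:
        return self.references[pid]

    def load_cohort(self) -> list[ParticipantMeta]:
        return list(self.cohort)


def _participant_name(pid: int) -> str:
    return f"P{pid:03d}"


def _write_h5_datasets(f: h5py.File, arrays: dict[str, np.ndarray],
                       attrs: dict) -> None:
    for name in sorted(arrays):
        f.create_dataset(name, data=arrays[name], track_times=False)
    for k in sorted(attrs):
        f.attrs[k] = attrs[k]


def write_bundle(study: StudyData, root: str | Path) -> "DatasetBundle":
    """Persist a study as a bundle; re-writing identical inputs is byte-identical.

    A ``.incomplete`` marker exists while writing; readers reject bundles
    that still carry it (partial writes).
    """
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    marker = root / _MARKER
    marker.write_text("")
    try:
        for folder in _FOLDERS:
            (root / folder).mkdir(exist_ok=True)
        config_json = study.config.to_json()
        for meta in study.cohort:
            name = _participant_name(meta.id)
            cube = study.cubes[meta.id]
            with h5py.File(root / "Rawdata" / f"{name}.h5", "w") as f:
                _write_h5_datasets(
                    f, {"if_data": cube.data},
                    {"radar_config": config_json,
                     "start_time": float(cube.start_time),
                     "participant_id": int(meta.id)},
                )
            ref = study.references[meta.id]
            prof = study.profiles[meta.id]
            with h5py.File(root / "VitalSign" / f"{name}.h5", "w") as f:
                _write_h5_datasets(
                    f,
                    {"ecg_waveform": ref.ecg_waveform,
                     "respiration_waveform": ref.respiration_waveform,
                     "hr_series": ref.hr_series,
                     "br_series": ref.br_series},
                    {"sampling_rate": 125.0,
                     "start_time": float(ref.start_time),
                     "participant_id": int(meta.id),
                     "true_heart_rate": float(prof.heart_rate),
                     "true_breathing_rate": float(prof.breathing_rate)},
                )
        rows = [dataclasses.asdict(m) for m in study.cohort]
        pd.DataFrame(rows, columns=["id", "sex", "age", "height", "weight", "bmi"]) \
            .to_csv(root / "Participants" / "participants.csv", index=False)
        manifest = {
            "format_version": FORMAT_VERSION,
            "n_participants": len(study.cohort),
            "duration_s": study.duration,
            "creation_seed": study.seed,
            "radar_config": json.loads(config_json),
        }
        (root / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    except Exception:
        raise
    else:
        marker.unlink()
    return read_bundle(root)


@dataclass
class DatasetBundle:
    """Validated handle to a bundle on disk; payloads load lazily."""

    root: Path
    manifest: dict
    participant_ids: list[int] = field(default_factory=list)

    @property
    def n_participants(self) -> int:
        return self.manifest["n_participants"]

    def load_cube(self, pid: int) -> RadarCube:
        path = self.root / "Rawdata" / f"{_participant_name(pid)}.h5"
        with h5py.File(path, "r") as f:
            config = RadarConfig.from_json(f.attrs["radar_config"])
            return RadarCube(f["if_data"][()], config,
                             start_time=float(f.attrs["start_time"]))

    def load_reference(self, pid: int) -> ReferenceRecord:
        path = self.root / "VitalSign" / f"{_participant_name(pid)}.h5"
        with h5py.File(path, "r") as f:
            return ReferenceRecord(
                ecg_waveform=f["ecg_waveform"][()],
                respiration_waveform=f["respiration_waveform"][()],
                hr_series=f["hr_series"][()],
                br_series=f["br_series"][()],
                start_time=float(f.attrs["start_time"]),
            )

    def load_cohort(self) -> list[ParticipantMeta]:
        df = pd.read_csv(self.root / "Participants" / "participants.csv")
        return [ParticipantMeta(**row) for row in df.to_dict(orient="records")]

    def vitals_csv_path(self, pid: int) -> Path:
        return self.root / "VitalSign" / f"{_participant_name(pid)}_vitals.csv"


def read_bundle(root: str | Path) -> DatasetBundle:
    """Open and validate a bundle without reading any array payloads."""
    root = Path(root)
    if not root.is_dir():
        raise BundleError(f"no bundle at {root}")
    if (root / _MARKER).exists():
        raise BundleError(f"bundle at {root} is incomplete (interrupted write)")
    manifest_path = root / "manifest.json"
    if not manifest_path.is_file():
        raise BundleError("missing manifest.json")
    manifest = json.loads(manifest_path.read_text())
    if manifest.get("format_version") != FORMAT_VERSION:
        raise BundleError(
            f"unsupported format version {manifest.get('format_version')!r} "
            f"(expected {FORMAT_VERSION})"
        )
    for folder in _FOLDERS:
        if not (root / folder).is_dir():
            raise BundleError(f"missing folder {folder!r}")
    csv_path = root / "Participants" / "participants.csv"
    if not csv_path.is_file():
        raise BundleError("missing Participants/participants.csv")
    ids = pd.read_csv(csv_path)["id"].tolist()
    n = manifest["n_participants"]
    if len(ids) != n:
        raise BundleError(
            f"manifest says {n} participants but metadata lists {len(ids)}"
        )
    for pid in ids:
        name = _participant_name(pid)
        for folder in ("Rawdata", "VitalSign"):
            if not (root / folder / f"{name}.h5").is_file():
                raise BundleError(f"participant {pid}: missing {folder}/{name}.h5")
    return DatasetBundle(root=root, manifest=manifest, participant_ids=ids)


def export_vitals_csv(estimate: VitalsEstimate, path: str | Path) -> Path:
    """Write a windowed vitals estimate as CSV.

    Columns: ``time_s,hr_bpm,br_bpm,movement_index,valid`` with fixed
    6-decimal floats for reproducible diffs; invalid windows keep NaN rates.
    """
    path = Path(path)
    df = pd.DataFrame({
        "time_s": estimate.times,
        "hr_bpm": estimate.hr,
        "br_bpm": estimate.br,
        "movement_index": estimate.movement_index,
        "valid": estimate.valid.astype(int),
    })
    df.to_csv(path, index=False, float_format="%.6f")
    return path


def read_vitals_csv(path: str | Path) -> pd.DataFrame:
    """Read back a vitals CSV written by :func:`export_vitals_csv`."""
    return pd.read_csv(path)
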