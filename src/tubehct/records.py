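"""Persistent sample records and spreadsheet export.

Mirrors the measurement app's internal database functionally: one
human-readable JSON-lines file, one record per measured sample, with
round-trip-lossless save/load and CSV/XLSX export. The stored Hct is
revalidated against the stored markers on load; a mismatch beyond the
reporting precision raises an :class:`IntegrityWarning`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import __version__ as _pkg_version
from .errors import ConflictError, EmptyStoreError, IntegrityWarning
from .geometry import CameraPose
from .measurement import REPORT_PRECISION, MarkerSet, compute_hct

__all__ = ["SampleRecord", "RecordStore", "EXPORT_COLUMNS"]

EXPORT_COLUMNS = [
    "sample_id",
    "sex",
    "hct_pct",
    "lower",
    "buffy",
    "upper",
    "pitch",
    "yaw",
    "image_path",
    "created_at",
]


@dataclass(frozen=True)
class SampleRecord:
    sample_id: str
    markers: MarkerSet
    hct_pct: float
    sex: str = ""
    pose: CameraPose | None = None
    image_path: str = ""
    created_at: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat(timespec="seconds")
    )
    app_version: str = _pkg_version

    @classmethod
    def from_markers(cls, sample_id: str, markers: MarkerSet, **kwargs) -> "SampleRecord":
        """Build a record with the Hct computed from the markers."""
        return cls(
            sample_id=sample_id,
            markers=markers,
            hct_pct=compute_hct(markers).reported_pct,
            **kwargs,
        )

    def to_json(self) -> str:
        d = {
            "sample_id": self.sample_id,
            "sex": self.sex,
            "hct_pct": self.hct_pct,
            "markers": asdict(self.markers),
            "pose": asdict(self.pose) if self.pose is not None else None,
            "image_path": self.image_path,
            "created_at": self.created_at,
            "app_version": self.app_version,
        }
        return json.dumps(d, sort_keys=True)

    @classmethod
    def from_json(cls, line: str) -> "SampleRecord":
        d = json.loads(line)
        markers = MarkerSet(**d["markers"])
        pose = CameraPose(**d["pose"]) if d.get("pose") else None
        rec = cls(
            sample_id=d["sample_id"],
            sex=d.get("sex", ""),
            hct_pct=float(d["hct_pct"]),
            markers=markers,
            pose=pose,
            image_path=d.get("image_path", ""),
            created_at=d.get("created_at", ""),
            app_version=d.get("app_version", ""),
        )
        recomputed = compute_hct(markers).reported_pct
        if abs(recomputed - rec.hct_pct) > REPORT_PRECISION:
            warnings.warn(
                f"record {rec.sample_id!r}: stored hct {rec.hct_pct} disagrees with "
                f"markers ({recomputed})",
                IntegrityWarning,
                stacklevel=2,
            )
        return rec


class RecordStore:
    """Append-only JSON-lines store of :class:`SampleRecord` objects."""

    def __init__(self, path: str | Path):
        self.path = Path(path)

    def _load_all(self) -> dict[str, SampleRecord]:
        records: dict[str, SampleRecord] = {}
        if self.path.exists():
            for line in self.path.read_text().splitlines():
                if line.strip():
                    rec = SampleRecord.from_json(line)
                    records[rec.sample_id] = rec
        return records

    def save_record(self, record: SampleRecord) -> str:
        """Append a record; duplicate sample ids are a conflict."""
        existing = self._load_all()
        if record.sample_id in existing:
            raise ConflictError(f"sample_id {record.sample_id!r} already stored")
        with self.path.open("a") as fh:
            fh.write(record.to_json() + "\n")
        return record.sample_id

    def load_record(self, sample_id: str) -> SampleRecord:
        records = self._load_all()
        if sample_id not in records:
            raise KeyError(sample_id)
        return records[sample_id]

    def __len__(self) -> int:
        return len(self._load_all())

    def export_table(self) -> pd.DataFrame:
        """All records as a flat spreadsheet-ready table (documented column order)."""
        records = self._load_all()
        if not records:
            raise EmptyStoreError(f"no records in {self.path}")
        rows = []
        for rec in records.values():
            rows.append(
                {
                    "sample_id": rec.sample_id,
                    "sex": rec.sex,
                    "hct_pct": rec.hct_pct,
                    "lower": rec.markers.lower_row,
                    "buffy": rec.markers.buffy_row,
                    "upper": rec.markers.upper_row,
                    "pitch": rec.pose.pitch_deg if rec.pose else None,
                    "yaw": rec.pose.yaw_deg if rec.pose else None,
                    "image_path": rec.image_path,
                    "created_at": rec.created_at,
                }
            )
        return pd.DataFrame(rows, columns=EXPORT_COLUMNS)

    def export_csv(self, path: str | Path) -> None:
        self.export_table().to_csv(path, index=False)

    def export_xlsx(self, path: str | Path) -> None:
        self.export_table().to_excel(path, index=False)
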