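"""Cohort registry: which patients have which ordered session images."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .errors import ValidationError


@dataclass(frozen=True)
class SessionRecord:
    """One treatment-session image of one patient."""

    session: int
    image: Path | None = None
    labels: Path | None = None
    dvf: Path | None = None

    def __post_init__(self) -> None:
        if self.session < 1:
            raise ValidationError(f"session index must be >= 1, got {self.session}")


@dataclass
class CohortRegistry:
    """Patients mapped to their ordered session records.

    Paths are optional so registries can describe a cohort before (or
    without) files existing on disk; :meth:`validate_files` checks that
    every referenced path is present.
    """

    patients: dict[str, list[SessionRecord]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pid, records in self.patients.items():
            sessions = [r.session for r in records]
            if sorted(set(sessions)) != sessions:
                raise ValidationError(
                    f"patient {pid!r}: session indices must be unique and ascending, got {sessions}")

    @classmethod
    def from_session_counts(cls, counts: dict[str, int]) -> "CohortRegistry":
        """Registry skeleton (no file paths) from per-patient session counts."""
        return cls(patients={
            pid: [SessionRecord(session=s) for s in range(1, n + 1)]
            for pid, n in counts.items()
        })

    @property
    def patient_ids(self) -> list[str]:
        return list(self.patients)

    @property
    def n_images(self) -> int:
        return sum(len(records) for records in self.patients.values())

    def sessions(self, patient_id: str) -> list[SessionRecord]:
        try:
            return self.patients[patient_id]
        except KeyError:
            raise ValidationError(f"unknown patient {patient_id!r}") from None

    def record(self, patient_id: str, session: int) -> SessionRecord:
        for rec in self.sessions(patient_id):
            if rec.session == session:
                return rec
        raise ValidationError(f"patient {patient_id!r} has no session {session}")

    def validate_files(self) -> None:
        for pid, records in self.patients.items():
            for rec in records:
                for kind in ("image", "labels", "dvf"):
                    path = getattr(rec, kind)
                    if path is not None and not Path(path).exists():
                        raise ValidationError(
                            f"patient {pid!r} session {rec.session}: missing {kind} file {path}")

    # -- JSON round trip --------------------------------------------------
    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            pid: [
                {
                    "session": rec.session,
                    **{k: str(getattr(rec, k)) for k in ("image", "labels", "dvf")
                       if getattr(rec, k) is not None},
                }
                for rec in records
            ]
            for pid, records in self.patients.items()
        }
        path.write_text(json.dumps(payload, indent=2, sort_keys=True))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "CohortRegistry":
        payload = json.loads(Path(path).read_text())
        patients = {
            pid: [
                SessionRecord(
                    session=int(entry["session"]),
                    image=Path(entry["image"]) if "image" in entry else None,
                    labels=Path(entry["labels"]) if "labels" in entry else None,
                    dvf=Path(entry["dvf"]) if "dvf" in entry else None,
                )
                for entry in entries
            ]
            for pid, entries in payload.items()
        }
        return cls(patients=patients)
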