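"""Reading transcripts and participant metadata; deriving clinical labels.

Metadata is a UTF-8 CSV with header columns ``participant_id, age, gender,
hdrs_total, h11, lifetime_affective``.  Transcripts come in two dialects:

* plain text, one turn per line, ``INT:`` / ``PAR:`` speaker prefixes;
* JSON-lines with fields ``speaker`` and ``text`` (the canonical dialect).

Labels are deterministic functions of the clinical ratings: current
depression is a 17-item Hamilton Depression Rating Scale (HDRS-17) total of
8 or above; suicidal ideation is a rating of 2 or above on the suicide-risk
item (H11), scored on five progressive levels 1-5.  A configuration switch
supports the zero-based 0-4 convention for the suicide item, with the
equivalent cut-off of 1 or above.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import List, Sequence

__all__ = [
    "Gender",
    "Speaker",
    "ParticipantRecord",
    "TranscriptTurn",
    "Labels",
    "FormatError",
    "ValidationError",
    "read_metadata",
    "write_metadata",
    "read_transcript",
    "write_transcript",
    "participant_text",
    "derive_labels",
    "AGE_RANGE",
    "HDRS_DEPRESSION_CUTOFF",
    "H11_SUICIDAL_CUTOFF",
]

AGE_RANGE = (18, 65)
HDRS_DEPRESSION_CUTOFF = 8   # HDRS-17 total >= 8 -> current depression
H11_SUICIDAL_CUTOFF = 2      # H11 (1-5 scale) >= 2 -> suicidal ideation


class FormatError(ValueError):
    """A file does not conform to the expected dialect."""


class ValidationError(ValueError):
    """A field value violates its documented range."""


class Gender(str, Enum):
    MALE = "male"
    FEMALE = "female"


class Speaker(str, Enum):
    INTERVIEWER = "interviewer"
    PARTICIPANT = "participant"


_GENDER_ALIASES = {
    "male": Gender.MALE, "m": Gender.MALE,
    "female": Gender.FEMALE, "f": Gender.FEMALE,
}
_SPEAKER_ALIASES = {
    "int": Speaker.INTERVIEWER, "interviewer": Speaker.INTERVIEWER,
    "par": Speaker.PARTICIPANT, "participant": Speaker.PARTICIPANT,
}


@dataclass(frozen=True)
class ParticipantRecord:
    """Demographics and clinical ratings for one participant."""

    participant_id: str
    age: int
    gender: Gender
    hdrs_total: int
    h11: int
    lifetime_affective: bool
    h11_zero_based: bool = False

    def __post_init__(self):
        lo, hi = AGE_RANGE
        if not lo <= self.age <= hi:
            raise ValidationError(
                f"participant {self.participant_id}: age {self.age} outside [{lo}, {hi}]"
            )
        h11_lo = 0 if self.h11_zero_based else 1
        h11_hi = h11_lo + 4
        if not h11_lo <= self.h11 <= h11_hi:
            raise ValidationError(
                f"participant {self.participant_id}: h11 {self.h11} outside "
                f"[{h11_lo}, {h11_hi}]"
            )
        if self.hdrs_total < 0:
            raise ValidationError(
                f"participant {self.participant_id}: negative hdrs_total"
            )


@dataclass(frozen=True)
class TranscriptTurn:
    """One utterance turn of an interview."""

    speaker: Speaker
    text: str

    def __post_init__(self):
        if not self.text.strip():
            raise ValidationError("turn text empty after whitespace stripping")


@dataclass(frozen=True)
class Labels:
    """Binary clinical outcomes derived from the ratings."""

    current_depression: bool
    suicidal_ideation: bool


METADATA_COLUMNS = (
    "participant_id", "age", "gender", "hdrs_total", "h11", "lifetime_affective",
)

_TRUTHY = {"1", "true", "yes", "y"}
_FALSY = {"0", "false", "no", "n"}


def _parse_bool(value: str, row: int, column: str) -> bool:
    v = value.strip().lower()
    if v in _TRUTHY:
        return True
    if v in _FALSY:
        return False
    raise FormatError(f"row {row}: cannot parse {column}={value!r} as boolean")


def read_metadata(path: str | Path, h11_zero_based: bool = False) -> List[ParticipantRecord]:
    """Read the participant metadata CSV.

    Raises :class:`FormatError` for a missing column or unparsable cell and
    :class:`ValidationError` (naming the row) for out-of-range values.
    """
    path = Path(path)
    records = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in METADATA_COLUMNS if c not in header]
        if missing:
            raise FormatError(f"{path}: missing column(s) {', '.join(missing)}")
        for i, row in enumerate(reader, start=2):  # 1-based incl. header
            gender_raw = row["gender"].strip().lower()
            if gender_raw not in _GENDER_ALIASES:
                raise FormatError(f"row {i}: unknown gender {row['gender']!r}")
            try:
                record = ParticipantRecord(
                    participant_id=row["participant_id"].strip(),
                    age=int(row["age"]),
                    gender=_GENDER_ALIASES[gender_raw],
                    hdrs_total=int(row["hdrs_total"]),
                    h11=int(row["h11"]),
                    lifetime_affective=_parse_bool(
                        row["lifetime_affective"], i, "lifetime_affective"
                    ),
                    h11_zero_based=h11_zero_based,
                )
            except ValidationError as exc:
                raise ValidationError(f"row {i}: {exc}") from exc
            except (TypeError, ValueError) as exc:
                raise FormatError(f"row {i}: {exc}") from exc
            records.append(record)
    return records


def write_metadata(records: Sequence[ParticipantRecord], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(METADATA_COLUMNS)
        for r in records:
            writer.writerow([
                r.participant_id, r.age, r.gender.value, r.hdrs_total,
                r.h11, int(r.lifetime_affective),
            ])


def read_transcript(path: str | Path) -> List[TranscriptTurn]:
    """Read a transcript in either dialect, preserving turn order.

    JSON-lines is detected by a leading ``{`` on the first non-empty line.
    """
    path = Path(path)
    raw = path.read_text(encoding="utf-8")
    lines = [(i, line) for i, line in enumerate(raw.splitlines(), start=1) if line.strip()]
    if not lines:
        return []
    is_jsonl = lines[0][1].lstrip().startswith("{")
    turns = []
    for lineno, line in lines:
        if is_jsonl:
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise FormatError(f"{path}:{lineno}: invalid JSON: {exc}") from exc
            speaker_raw = str(obj.get("speaker", "")).strip().lower()
            text = obj.get("text", "")
        else:
            if ":" not in line:
                raise FormatError(f"{path}:{lineno}: missing 'SPEAKER:' separator")
            speaker_raw, text = line.split(":", 1)
            speaker_raw = speaker_raw.strip().lower()
        if speaker_raw not in _SPEAKER_ALIASES:
            raise FormatError(f"{path}:{lineno}: unknown speaker tag {speaker_raw!r}")
        turns.append(TranscriptTurn(_SPEAKER_ALIASES[speaker_raw], text.strip()))
    return turns


def write_transcript(turns: Sequence[TranscriptTurn], path: str | Path) -> None:
    """Write a transcript in the canonical JSON-lines dialect."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for t in turns:
            fh.write(json.dumps(
                {"speaker": t.speaker.value, "text": t.text},
                ensure_ascii=False, sort_keys=True,
            ) + "\n")


def participant_text(turns: Sequence[TranscriptTurn]) -> List[str]:
    """Texts of the participant's turns only (interviewer speech filtered out),
    order preserved."""
    return [t.text for t in turns if t.speaker is Speaker.PARTICIPANT]


def derive_labels(record: ParticipantRecord) -> Labels:
    """Derive the binary clinical labels from the ratings.

    Depression: HDRS-17 total >= 8.  Suicidal ideation: suicide item >= 2 on
    the 1-5 scale (>= 1 when the record uses the zero-based 0-4 scale).
    """
    cutoff = H11_SUICIDAL_CUTOFF - (1 if record.h11_zero_based else 0)
    return Labels(
        current_depression=record.hdrs_total >= HDRS_DEPRESSION_CUTOFF,
        suicidal_ideation=record.h11 >= cutoff,
    )
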