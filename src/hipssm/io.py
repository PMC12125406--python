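"""Reading and writing landmark annotations and cohort metadata.

Two on-disk landmark dialects are supported:

* ``csv`` — one row per point with columns ``hip_id, point_index, x, y``
  (optional extra columns ``side, rater_id, session``); many hips per file.
* ``pts`` — the plain point-list format: a first line with the point
  count, then one ``x y`` pair per line; one hip per file, identified by
  the file stem.

A record holds either 13 points (contour only, protocol points 0-12) or
15 points (contour plus femoral-head center and rim, points 13 and 14).

Cohort metadata is a CSV with one row per hip carrying treatment history,
the acetabular index at age five, and the inclusion/exclusion flag used
by :func:`apply_inclusion_flow`.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Landmark",
    "AnnotatedHip",
    "PatientRecord",
    "FormatError",
    "EXCLUSION_REASONS",
    "read_landmarks",
    "write_landmarks",
    "read_cohort",
    "write_cohort",
    "apply_inclusion_flow",
    "select_bilateral_side",
]

#: Exclusion reasons in the order of the study's inclusion flowchart.
EXCLUSION_REASONS = (
    "missing_baseline_us",
    "reclassified_stable",
    "genetic_comorbidity",
    "lost_to_followup",
)


class FormatError(ValueError):
    """Malformed landmark or metadata file."""


@dataclass(frozen=True)
class Landmark:
    """One annotated point in image coordinates (pixels; y increases downward)."""

    x: float
    y: float

    def __post_init__(self):
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise FormatError(f"non-finite landmark: ({self.x}, {self.y})")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)


@dataclass(frozen=True)
class AnnotatedHip:
    """One hip's ordered landmark set.

    ``contour`` holds exactly 13 points (protocol points 0-12).
    ``head_center``/``head_rim`` (points 13 and 14) are both present or
    both absent; when present they define the femoral-head circle.
    """

    hip_id: str
    side: str = "left"
    contour: tuple = ()
    head_center: Optional[Landmark] = None
    head_rim: Optional[Landmark] = None
    rater_id: str = "r1"
    session: int = 1

    def __post_init__(self):
        if len(self.contour) != 13:
            raise FormatError(
                f"hip {self.hip_id!r}: contour has {len(self.contour)} points, expected 13"
            )
        if (self.head_center is None) != (self.head_rim is None):
            raise FormatError(
                f"hip {self.hip_id!r}: head_center and head_rim must both be present or both absent"
            )
        if self.head_center is not None:
            r = np.linalg.norm(self.head_center.as_array() - self.head_rim.as_array())
            if r <= 0:
                raise FormatError(f"hip {self.hip_id!r}: zero femoral-head radius")
        if self.side not in ("left", "right"):
            raise FormatError(f"hip {self.hip_id!r}: invalid side {self.side!r}")

    @property
    def has_head(self) -> bool:
        return self.head_center is not None

    def contour_array(self) -> np.ndarray:
        """Contour as a (13, 2) float array in protocol order."""
        return np.array([[p.x, p.y] for p in self.contour], dtype=float)

    def all_points(self) -> list:
        pts = list(self.contour)
        if self.has_head:
            pts += [self.head_center, self.head_rim]
        return pts


@dataclass(frozen=True)
class PatientRecord:
    """Clinical metadata for one included hip.

    ``acetabular_index_5y`` (degrees) is the age-five radiographic
    acetabular index; it may be absent for surgically treated hips.
    ``exclusion_flag`` is ``"none"`` for analysis-set records.
    """

    hip_id: str
    sex: str = "F"
    age_at_us: float = 3.4
    graf_type: str = "III"
    bilateral: bool = False
    closed_reduction: bool = True
    open_reduction: bool = False
    pelvic_osteotomy: bool = False
    acetabular_index_5y: Optional[float] = None
    avn: bool = False
    exclusion_flag: str = "none"

    def __post_init__(self):
        if self.exclusion_flag not in ("none",) + EXCLUSION_REASONS:
            raise FormatError(f"unknown exclusion flag {self.exclusion_flag!r}")
        if self.graf_type not in ("D", "III", "IV"):
            raise FormatError(f"unknown Graf type {self.graf_type!r}")


# ---------------------------------------------------------------------------
# Landmark files
# ---------------------------------------------------------------------------


def _hip_from_points(hip_id, side, rater_id, session, points) -> AnnotatedHip:
    n = len(points)
    if n not in (13, 15):
        raise FormatError(f"record {hip_id!r} has {n} points; expected 13 or 15")
    contour = tuple(Landmark(x, y) for x, y in points[:13])
    head_center = head_rim = None
    if n == 15:
        head_center = Landmark(*points[13])
        head_rim = Landmark(*points[14])
    return AnnotatedHip(
        hip_id=str(hip_id),
        side=side,
        contour=contour,
        head_center=head_center,
        head_rim=head_rim,
        rater_id=rater_id,
        session=session,
    )


def read_landmarks(path, dialect: str = "csv") -> list:
    """Read annotated hips from ``path``.

    Returns a list of :class:`AnnotatedHip`, point order preserved
    exactly as on disk. A record with a point count other than 13 or 15
    raises :class:`FormatError` naming the record.
    """
    path = Path(path)
    if dialect == "csv":
        df = pd.read_csv(path, float_precision="round_trip")
        required = {"hip_id", "point_index", "x", "y"}
        if not required.issubset(df.columns):
            raise FormatError(f"{path}: missing columns {required - set(df.columns)}")
        hips = []
        for hip_id, g in df.groupby("hip_id", sort=False):
            g = g.sort_values("point_index")
            if not np.array_equal(g["point_index"].to_numpy(), np.arange(len(g))):
                raise FormatError(f"record {hip_id!r}: point_index must be 0..n-1")
            side = str(g["side"].iloc[0]) if "side" in g else "left"
            rater = str(g["rater_id"].iloc[0]) if "rater_id" in g else "r1"
            session = int(g["session"].iloc[0]) if "session" in g else 1
            pts = list(zip(g["x"].astype(float), g["y"].astype(float)))
            hips.append(_hip_from_points(hip_id, side, rater, session, pts))
        return hips
    if dialect == "pts":
        lines = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
        try:
            n = int(lines[0].split()[-1])
        except (IndexError, ValueError) as exc:
            raise FormatError(f"{path}: missing point-count header") from exc
        pts = []
        for ln in lines[1 : 1 + n]:
            xs, ys = ln.split()
            pts.append((float(xs), float(ys)))
        if len(pts) != n:
            raise FormatError(f"{path}: header says {n} points, found {len(pts)}")
        return [_hip_from_points(path.stem, "left", "r1", 1, pts)]
    raise ValueError(f"unknown dialect {dialect!r}")


def write_landmarks(hips: Sequence[AnnotatedHip], path, dialect: str = "csv") -> None:
    """Write hips to ``path`` in the given dialect.

    The csv dialect round-trips coordinates bit-exactly (floats written
    with ``repr``). The pts dialect writes one hip per file and requires
    a single hip.
    """
    path = Path(path)
    if dialect == "csv":
        rows = []
        for hip in hips:
            for i, p in enumerate(hip.all_points()):
                rows.append(
                    {
                        "hip_id": hip.hip_id,
                        "point_index": i,
                        "x": repr(float(p.x)),
                        "y": repr(float(p.y)),
                        "side": hip.side,
                        "rater_id": hip.rater_id,
                        "session": hip.session,
                    }
                )
        pd.DataFrame(rows).to_csv(path, index=False)
        return
    if dialect == "pts":
        if len(hips) != 1:
            raise ValueError("pts dialect holds exactly one hip per file")
        pts = hips[0].all_points()
        lines = [str(len(pts))] + [f"{p.x!r} {p.y!r}" for p in pts]
        path.write_text("\n".join(lines) + "\n")
        return
    raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Cohort metadata
# ---------------------------------------------------------------------------

_BOOL_COLS = ("bilateral", "closed_reduction", "open_reduction", "pelvic_osteotomy", "avn")


def write_cohort(records: Sequence[PatientRecord], path) -> None:
    df = pd.DataFrame([vars(r) for r in records])
    df.to_csv(path, index=False)


def read_cohort(path) -> list:
    df = pd.read_csv(path)
    records = []
    for _, row in df.iterrows():
        ai = row["acetabular_index_5y"]
        records.append(
            PatientRecord(
                hip_id=str(row["hip_id"]),
                sex=str(row["sex"]),
                age_at_us=float(row["age_at_us"]),
                graf_type=str(row["graf_type"]),
                bilateral=bool(row["bilateral"]),
                closed_reduction=bool(row["closed_reduction"]),
                open_reduction=bool(row["open_reduction"]),
                pelvic_osteotomy=bool(row["pelvic_osteotomy"]),
                acetabular_index_5y=None if pd.isna(ai) else float(ai),
                avn=bool(row["avn"]),
                exclusion_flag=str(row["exclusion_flag"]),
            )
        )
    return records


def apply_inclusion_flow(records: Sequence[PatientRecord]):
    """Apply the study's inclusion/exclusion flow.

    Returns ``(included, tally)`` where ``included`` keeps the records
    with ``exclusion_flag == "none"`` (input order preserved) and
    ``tally`` maps each exclusion reason, in flowchart order, to its
    count. ``len(included) + sum(tally.values()) == len(records)``.
    """
    included = [r for r in records if r.exclusion_flag == "none"]
    tally = {reason: 0 for reason in EXCLUSION_REASONS}
    for r in records:
        if r.exclusion_flag != "none":
            tally[r.exclusion_flag] += 1
    return included, tally


def select_bilateral_side(
    hips_by_patient: Mapping[str, Sequence[AnnotatedHip]],
    quality: Mapping[str, float],
    seed: int,
) -> dict:
    """Pick one hip per patient.

    Unilateral patients keep their hip. Bilateral patients keep the hip
    with the higher image-quality score; on an exact tie, one side is
    chosen uniformly at random from an RNG stream derived from
    ``(seed, patient_id)``, so the choice is reproducible and does not
    depend on cohort ordering.
    """
    chosen = {}
    for patient_id, hips in hips_by_patient.items():
        if len(hips) == 1:
            chosen[patient_id] = hips[0]
            continue
        if len(hips) != 2:
            raise ValueError(f"patient {patient_id!r} has {len(hips)} hips; expected 1 or 2")
        q = [quality[h.hip_id] for h in hips]
        if q[0] != q[1]:
            chosen[patient_id] = hips[int(np.argmax(q))]
        else:
            rng = np.random.default_rng(
                [int(seed), zlib.crc32(str(patient_id).encode("utf-8"))]
            )
            chosen[patient_id] = hips[int(rng.integers(2))]
    return chosen
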