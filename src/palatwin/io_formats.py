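"""Readers and writers for every external artifact the pipeline touches.

Meshes travel as STL (binary or ASCII), landmarks as JSON documents keyed by a
fixed anatomical vocabulary, cohort trait tables and fit reports as CSV, and
run configuration as YAML.  All coordinates are interpreted as millimetres;
STL carries no unit metadata, so units are asserted, not detected.

Landmark vocabulary
-------------------
``dg_<FDI code>``
    midpoint of the palatal dento-gingival junction of one tooth (FDI two-digit
    tooth code, e.g. ``dg_53`` for the upper-right primary canine).
``raphe_anterior`` / ``raphe_middle`` / ``raphe_posterior``
    the incisive papilla and the mid-canine / mid-molar points of the
    mid-palatal raphe.
``distal_<FDI code>``
    most distal palatal point of a terminal tooth (second primary molar or
    first permanent molar), defining the posterior limit of the palate.

The dentition stage fixes which tooth codes are required: primary dentition
uses the deciduous codes 51-65, the mixed dentition mixes deciduous canines
and molars with permanent incisors and first molars, and the permanent
dentition uses 11-26.  A required landmark that is absent from a file is
*data* (recorded as missing, to be imputed downstream), not an error.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import trimesh
import yaml

logger = logging.getLogger(__name__)

STAGES = ("primary", "mixed", "permanent")

TRAIT_NAMES = (
    "anterior_width",
    "posterior_width",
    "anterior_depth",
    "posterior_depth",
    "ap_length",
    "area",
    "volume",
)

#: units of each palatal trait, in report order
TRAIT_UNITS = {
    "anterior_width": "mm",
    "posterior_width": "mm",
    "anterior_depth": "mm",
    "posterior_depth": "mm",
    "ap_length": "mm",
    "area": "mm^2",
    "volume": "mm^3",
}

RAPHE_NAMES = ("raphe_anterior", "raphe_middle", "raphe_posterior")

#: dento-gingival tooth codes required at each dentition stage
STAGE_TEETH = {
    "primary": ("51", "52", "53", "54", "55", "61", "62", "63", "64", "65"),
    "mixed": ("11", "12", "16", "21", "22", "26", "53", "54", "55", "63", "64", "65"),
    "permanent": ("11", "12", "13", "14", "15", "16",
                  "21", "22", "23", "24", "25", "26"),
}

#: terminal teeth whose most-distal palatal points define the posterior plane
TERMINAL_TEETH = {
    "primary": ("55", "65"),
    "mixed": ("16", "26"),
    "permanent": ("16", "26"),
}

#: (right, left) tooth codes used for the anterior (canine) and posterior
#: (molar) width/depth reference lines at each stage
WIDTH_TEETH = {
    "primary": {"canine": ("53", "63"), "molar": ("55", "65")},
    "mixed": {"canine": ("53", "63"), "molar": ("16", "26")},
    "permanent": {"canine": ("13", "23"), "molar": ("16", "26")},
}


class FormatError(ValueError):
    """An external file could not be parsed or failed validation."""


def required_landmarks(stage: str) -> tuple[str, ...]:
    """Full landmark vocabulary required for a dentition stage."""
    if stage not in STAGES:
        raise FormatError(f"unknown dentition stage {stage!r}")
    dg = tuple(f"dg_{t}" for t in STAGE_TEETH[stage])
    distal = tuple(f"distal_{t}" for t in TERMINAL_TEETH[stage])
    return dg + RAPHE_NAMES + distal


def antimere_map(stage: str) -> dict[str, str]:
    """Map each landmark name to its contralateral partner.

    FDI quadrant digits pair 1<->2 (permanent) and 5<->6 (deciduous); raphe
    landmarks lie on the midline and map to themselves.
    """
    swap = {"1": "2", "2": "1", "5": "6", "6": "5"}
    out: dict[str, str] = {name: name for name in RAPHE_NAMES}
    for name in required_landmarks(stage):
        if name.startswith(("dg_", "distal_")):
            prefix, code = name.rsplit("_", 1)
            out[name] = f"{prefix}_{swap[code[0]]}{code[1]}"
    return out


@dataclass(frozen=True)
class LandmarkSet:
    """Named 3D palatal landmarks for one digitized maxillary cast."""

    cast_id: str
    stage: str
    points: dict[str, np.ndarray]
    imputed: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise FormatError(f"unknown dentition stage {self.stage!r}")
        vocab = set(required_landmarks(self.stage))
        pts = {}
        for name, xyz in self.points.items():
            if name not in vocab:
                raise FormatError(
                    f"landmark {name!r} is not valid for stage {self.stage!r}"
                )
            arr = np.asarray(xyz, dtype=float)
            if arr.shape != (3,) or not np.all(np.isfinite(arr)):
                raise FormatError(f"landmark {name!r} must be a finite 3-vector")
            pts[name] = arr
        object.__setattr__(self, "points", pts)

    @property
    def missing(self) -> frozenset[str]:
        """Required landmark names absent from this set."""
        return frozenset(set(required_landmarks(self.stage)) - set(self.points))

    def __contains__(self, name: str) -> bool:
        return name in self.points

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            return self.points[name]
        except KeyError:
            raise KeyError(
                f"landmark {name!r} missing from cast {self.cast_id!r}"
            ) from None

    def coords(self, names: Iterable[str]) -> np.ndarray:
        """Stack the named landmarks into an (n, 3) array (all must exist)."""
        return np.array([self[n] for n in names], dtype=float)

    def present(self, names: Iterable[str]) -> list[str]:
        return [n for n in names if n in self.points]

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "LandmarkSet":
        """Rigidly transformed copy: p -> R p + t."""
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        return replace(
            self, points={k: R @ v + t for k, v in self.points.items()}
        )


@dataclass(frozen=True)
class CohortRecord:
    """One twin at one dentition stage with its measured palatal traits."""

    twin_id: str
    family_id: str
    zygosity: str
    sex: str
    stage: str
    age: float
    traits: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.zygosity not in ("MZ", "DZ"):
            raise FormatError(f"zygosity must be MZ or DZ, got {self.zygosity!r}")
        if self.sex not in ("M", "F"):
            raise FormatError(f"sex must be M or F, got {self.sex!r}")
        if self.stage not in STAGES:
            raise FormatError(f"unknown dentition stage {self.stage!r}")


# ---------------------------------------------------------------------------
# meshes


def read_mesh(path: str | Path) -> trimesh.Trimesh:
    """Load a triangle mesh from binary or ASCII STL.

    Degenerate (zero-area) triangles are dropped with a logged count.
    Vertices are interpreted as millimetres.
    """
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise FormatError(f"unreadable or empty mesh file: {path}")
    try:
        mesh = trimesh.load(path, file_type="stl", process=False)
    except Exception as exc:  # noqa: BLE001 - normalise loader failures
        raise FormatError(f"could not parse STL file {path}: {exc}") from exc
    if not isinstance(mesh, trimesh.Trimesh) or len(mesh.faces) == 0:
        raise FormatError(f"no triangles found in {path}")
    keep = mesh.area_faces > 0.0
    dropped = int((~keep).sum())
    if dropped:
        logger.warning("dropped %d degenerate triangle(s) from %s", dropped, path)
        mesh.update_faces(keep)
    return mesh


def write_mesh(mesh: trimesh.Trimesh, path: str | Path) -> None:
    """Write a mesh as binary STL."""
    mesh.export(Path(path), file_type="stl")


# ---------------------------------------------------------------------------
# landmarks


def read_landmarks(path: str | Path) -> LandmarkSet:
    """Read one cast's landmark JSON document.

    Schema: ``{"cast_id": str, "stage": str, "landmarks": {name: [x, y, z]}}``.
    Unknown landmark names are rejected; required names that are absent are
    recorded as missing (downstream completion imputes them).
    """
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"malformed JSON in {path}: {exc}") from exc
    for key in ("cast_id", "stage", "landmarks"):
        if key not in doc:
            raise FormatError(f"{path}: missing required key {key!r}")
    return LandmarkSet(
        cast_id=str(doc["cast_id"]),
        stage=str(doc["stage"]),
        points={str(k): v for k, v in doc["landmarks"].items()},
    )


def write_landmarks(lm: LandmarkSet, path: str | Path) -> None:
    doc = {
        "cast_id": lm.cast_id,
        "stage": lm.stage,
        "landmarks": {k: [float(x) for x in v] for k, v in sorted(lm.points.items())},
    }
    Path(path).write_text(json.dumps(doc, indent=1))


# ---------------------------------------------------------------------------
# cohort tables


_COHORT_META = ["twin_id", "family_id", "zygosity", "sex", "stage", "age"]


def cohort_to_frame(records: Sequence[CohortRecord]) -> pd.DataFrame:
    """Long-format twin-pair table: one row per twin per stage."""
    rows = []
    for r in records:
        row = {
            "twin_id": r.twin_id, "family_id": r.family_id,
            "zygosity": r.zygosity, "sex": r.sex, "stage": r.stage,
            "age": r.age,
        }
        row.update({k: r.traits.get(k, np.nan) for k in TRAIT_NAMES})
        rows.append(row)
    return pd.DataFrame(rows, columns=_COHORT_META + list(TRAIT_NAMES))


def validate_cohort(df: pd.DataFrame) -> pd.DataFrame:
    """Enforce cohort invariants; idempotent.

    Families whose zygosity differs between rows raise; family-stage cells with
    a twin count other than two are excluded with a log entry.
    """
    missing = [c for c in _COHORT_META if c not in df.columns]
    if missing:
        raise FormatError(f"cohort table lacks required column(s): {missing}")
    bad_z = df.groupby("family_id")["zygosity"].nunique()
    bad_z = bad_z[bad_z > 1]
    if len(bad_z):
        raise FormatError(
            f"zygosity differs within family/ies: {list(bad_z.index)}"
        )
    counts = df.groupby(["family_id", "stage"])["twin_id"].nunique()
    bad = counts[counts != 2]
    if len(bad):
        for (fam, stage), n in bad.items():
            logger.warning(
                "excluding family %s at stage %s: %d twin(s) instead of 2",
                fam, stage, n,
            )
        keep = df.set_index(["family_id", "stage"]).index.isin(
            counts[counts == 2].index
        )
        df = df.loc[keep]
    return df.reset_index(drop=True)


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read and validate a cohort CSV (one row per twin per stage)."""
    df = pd.read_csv(path, dtype={"twin_id": str, "family_id": str})
    return validate_cohort(df)


def write_cohort(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def cohort_records(df: pd.DataFrame) -> list[CohortRecord]:
    """Convert a validated cohort frame into typed records."""
    out = []
    for _, row in df.iterrows():
        traits = {
            k: float(row[k]) for k in TRAIT_NAMES
            if k in row and np.isfinite(row[k])
        }
        out.append(CohortRecord(
            twin_id=str(row["twin_id"]), family_id=str(row["family_id"]),
            zygosity=row["zygosity"], sex=row["sex"], stage=row["stage"],
            age=float(row["age"]), traits=traits,
        ))
    return out


# ---------------------------------------------------------------------------
# fit reports

FIT_REPORT_COLUMNS = [
    "trait", "stage", "model", "AIC",
    "A", "A_CI", "C", "C_CI", "D", "D_CI", "E", "E_CI", "h2",
]


def write_fit_report(fits: Sequence, path: str | Path) -> None:
    """Write variance-component fits as CSV (one row per trait x stage x model).

    Components absent from a model (e.g. C and D for an AE fit) are left empty.
    Confidence intervals render as ``lo-hi`` with two decimals, mirroring how
    twin-study reports print them.
    """
    if not fits:
        raise ValueError("write_fit_report requires a non-empty fit list")

    def _ci(fit, comp):
        if fit.ci95 and comp in fit.ci95:
            lo, hi = fit.ci95[comp]
            return f"{lo:.2f}-{hi:.2f}"
        return ""

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(FIT_REPORT_COLUMNS)
        for fit in fits:
            std = fit.standardized
            row = [
                getattr(fit, "trait", ""), getattr(fit, "stage", ""),
                fit.model, f"{fit.aic:.6f}",
            ]
            for comp in "ACDE":
                if comp in fit.free_components:
                    row.append(f"{std[comp]:.6f}")
                    row.append(_ci(fit, comp))
                else:
                    row.extend(["", ""])
            row.append(f"{fit.h2:.6f}")
            w.writerow(row)


def read_fit_report(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# run configuration


def read_config(path: str | Path, allowed_keys: Iterable[str] | None = None) -> dict:
    """Read a YAML run configuration; unknown top-level keys are rejected."""
    doc = yaml.safe_load(Path(path).read_text())
    if doc is None:
        doc = {}
    if not isinstance(doc, dict):
        raise FormatError(f"{path}: configuration must be a mapping")
    if allowed_keys is not None:
        unknown = set(doc) - set(allowed_keys)
        if unknown:
            raise FormatError(f"{path}: unknown configuration key(s) {sorted(unknown)}")
    return doc


def write_config(doc: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))
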