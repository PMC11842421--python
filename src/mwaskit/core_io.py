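"""Shared data model and on-disk formats.

Defines the containers used by every pipeline stage — injection-level
feature tables, sample covariate records, authentic-standard reference
libraries and pathway databases — together with exact monoisotopic mass
arithmetic.  All adduct/proton arithmetic is centralized here so that
annotation and enrichment agree to the last decimal.

On-disk formats are deliberately plain text:

* feature table: TSV with columns ``mz``, ``time`` and one column per
  injection named ``<sample>.<replicate>``; missing intensities are empty
  cells (never 0 — a zero intensity is a real measurement);
* batch map: TSV with columns ``injection_id``, ``batch``;
* covariates: TSV with one row per sample;
* reference library / pathway database: JSON.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Mode",
    "MzFeature",
    "Injection",
    "FeatureTable",
    "SampleRecord",
    "LibraryEntry",
    "ReferenceLibrary",
    "PathwayDB",
    "monoisotopic_mass",
    "parse_formula",
    "read_feature_table",
    "write_feature_table",
    "read_samples",
    "write_samples",
    "PROTON_MASS",
    "ELECTRON_MASS",
    "MONOISOTOPIC_MASS",
]

# Instrument scan range; features outside it are rejected on construction.
MZ_MIN = 85.0
MZ_MAX = 1275.0
MAX_BATCH_SIZE = 40
N_REPLICATES = 3

PROTON_MASS = 1.007276
ELECTRON_MASS = 0.000548579909

# Monoisotopic atomic masses (Da), IUPAC/CODATA values.
MONOISOTOPIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.0078250319,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "P": 30.97376151,
    "S": 31.97207069,
    "Na": 22.98976928,
    "K": 38.9637064864,
    "Cl": 34.96885268,
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class Mode(str, Enum):
    """Chromatography column + electrospray polarity."""

    HILIC_POS = "hilic_pos"
    C18_NEG = "c18_neg"


def parse_formula(formula: str) -> dict[str, int]:
    """Parse an element-count formula like ``C10H12N2O`` into counts.

    Only elements with a tabulated monoisotopic mass are accepted.  The
    empty string parses to an empty count map.
    """
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(formula):
        if m.start() != pos:
            raise ValueError(
                f"unparseable formula {formula!r}: unexpected character at position {pos}"
            )
        pos = m.end()
        sym, num = m.group(1), m.group(2)
        if sym not in MONOISOTOPIC_MASS:
            raise ValueError(f"unknown element {sym!r} in formula {formula!r}")
        counts[sym] = counts.get(sym, 0) + (int(num) if num else 1)
    if pos != len(formula):
        raise ValueError(
            f"unparseable formula {formula!r}: unexpected character at position {pos}"
        )
    return counts


def monoisotopic_mass(formula: str) -> float:
    """Neutral monoisotopic mass (Da) of an element-count formula.

    Additive by construction: ``mass(A) + mass(B) == mass(A + B)``.
    The empty formula has mass 0.
    """
    return float(sum(MONOISOTOPIC_MASS[s] * n for s, n in parse_formula(formula).items()))


# ---------------------------------------------------------------------------
# Feature table
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MzFeature:
    """A unique (m/z, retention time) ion in one chromatography mode."""

    feature_id: str
    mz: float
    rt: float
    mode: Mode

    def __post_init__(self) -> None:
        if not (MZ_MIN <= self.mz <= MZ_MAX):
            raise ValueError(
                f"feature {self.feature_id!r}: m/z {self.mz} outside scan range "
                f"[{MZ_MIN}, {MZ_MAX}]"
            )
        if self.rt < 0:
            raise ValueError(f"feature {self.feature_id!r}: negative retention time {self.rt}")


@dataclass(frozen=True)
class Injection:
    """One injection of one sample (replicate 1..3) in one analytical batch."""

    sample_id: str
    replicate: int
    batch: str

    @property
    def injection_id(self) -> str:
        return f"{self.sample_id}.{self.replicate}"


@dataclass
class FeatureTable:
    """Injection-level intensity matrix for one mode.

    ``intensities`` has shape (n_features, n_injections); missing values are
    NaN (explicit "absent" sentinel, distinct from an observed zero).
    Injections are stored sample-major with replicates in order 1..3.
    """

    features: list[MzFeature]
    injections: list[Injection]
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.validate()

    # -- invariants ---------------------------------------------------------

    def validate(self) -> None:
        n_f, n_i = len(self.features), len(self.injections)
        if self.intensities.shape != (n_f, n_i):
            raise ValueError(
                f"intensity matrix shape {self.intensities.shape} inconsistent with "
                f"{n_f} features x {n_i} injections"
            )
        ids = [f.feature_id for f in self.features]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate feature ids: {dup[:5]}")
        modes = {f.mode for f in self.features}
        if len(modes) > 1:
            raise ValueError("feature table mixes chromatography modes")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.intensities, initial=np.inf) < 0:
                raise ValueError("negative intensity encountered")

        reps: dict[str, list[int]] = {}
        batches: dict[str, set[str]] = {}
        for inj in self.injections:
            reps.setdefault(inj.sample_id, []).append(inj.replicate)
            batches.setdefault(inj.sample_id, set()).add(inj.batch)
        for sid, rr in reps.items():
            if sorted(rr) != list(range(1, N_REPLICATES + 1)):
                raise ValueError(
                    f"sample {sid!r} has replicates {sorted(rr)}; expected exactly "
                    f"{list(range(1, N_REPLICATES + 1))}"
                )
        for sid, bb in batches.items():
            if len(bb) > 1:
                raise ValueError(f"sample {sid!r} spans multiple batches {sorted(bb)}")
        batch_sizes: dict[str, int] = {}
        for sid, bb in batches.items():
            b = next(iter(bb))
            batch_sizes[b] = batch_sizes.get(b, 0) + 1
        too_big = {b: n for b, n in batch_sizes.items() if n > MAX_BATCH_SIZE}
        if too_big:
            raise ValueError(f"batches exceed {MAX_BATCH_SIZE} samples: {too_big}")

    # -- accessors ----------------------------------------------------------

    @property
    def mode(self) -> Mode:
        return self.features[0].mode if self.features else Mode.HILIC_POS

    @property
    def feature_ids(self) -> list[str]:
        return [f.feature_id for f in self.features]

    @property
    def sample_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for inj in self.injections:
            seen.setdefault(inj.sample_id, None)
        return list(seen)

    @property
    def sample_batches(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for inj in self.injections:
            out.setdefault(inj.sample_id, inj.batch)
        return out

    @property
    def mz(self) -> np.ndarray:
        return np.array([f.mz for f in self.features])

    @property
    def rt(self) -> np.ndarray:
        return np.array([f.rt for f in self.features])

    def cube(self) -> np.ndarray:
        """Intensities reshaped to (n_features, n_samples, n_replicates)."""
        n_s = len(self.sample_ids)
        return self.intensities.reshape(len(self.features), n_s, N_REPLICATES)

    def subset(self, keep_ids: Iterable[str]) -> "FeatureTable":
        keep = set(keep_ids)
        idx = [i for i, f in enumerate(self.features) if f.feature_id in keep]
        return FeatureTable(
            features=[self.features[i] for i in idx],
            injections=list(self.injections),
            intensities=self.intensities[idx],
        )


def _normalize_injections(
    columns: Sequence[str], batch_of: Mapping[str, str]
) -> tuple[list[Injection], list[str]]:
    """Parse ``sample.rep`` column names into sample-major, replicate-sorted order."""
    parsed: dict[str, dict[int, str]] = {}
    order: list[str] = []
    for col in columns:
        sid, dot, rep = col.rpartition(".")
        if not dot or not rep.isdigit():
            raise ValueError(
                f"injection column {col!r} is not of the form '<sample>.<replicate>'"
            )
        if sid not in parsed:
            parsed[sid] = {}
            order.append(sid)
        parsed[sid][int(rep)] = col
    injections: list[Injection] = []
    col_order: list[str] = []
    for sid in order:
        reps = parsed[sid]
        if sorted(reps) != list(range(1, N_REPLICATES + 1)):
            raise ValueError(
                f"sample {sid!r} has replicate columns {sorted(reps)}; expected "
                f"{list(range(1, N_REPLICATES + 1))}"
            )
        for r in range(1, N_REPLICATES + 1):
            col = reps[r]
            if col not in batch_of:
                raise ValueError(f"injection {col!r} missing from batch map")
            injections.append(Injection(sid, r, batch_of[col]))
            col_order.append(col)
    return injections, col_order  # type: ignore[return-value]


def read_feature_table(path: str | Path, batch_path: str | Path, mode: Mode) -> FeatureTable:
    """Read a TSV feature table plus its batch map.

    Missing intensities are empty cells.  Feature ids are assigned
    deterministically as ``<mode>_<row index>``.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if list(df.columns[:2]) != ["mz", "time"]:
        raise ValueError(
            f"{path}: header must start with 'mz', 'time'; got {list(df.columns[:2])}"
        )
    bmap = pd.read_csv(batch_path, sep="\t", dtype=str)
    if list(bmap.columns) != ["injection_id", "batch"]:
        raise ValueError(f"{batch_path}: expected columns ['injection_id', 'batch']")
    batch_of = dict(zip(bmap["injection_id"], bmap["batch"]))

    injections, col_order = _normalize_injections(list(df.columns[2:]), batch_of)

    def _numeric(col: str, allow_empty: bool) -> np.ndarray:
        raw = df[col].to_numpy(dtype=str)
        filled = np.where(raw == "", "nan", raw)
        try:
            # numpy string->float is correctly rounded (exact round trips)
            vals = filled.astype(np.float64)
        except ValueError:
            for row, s in enumerate(filled):
                try:
                    float(s)
                except ValueError:
                    raise ValueError(
                        f"{path}: non-numeric value {raw[row]!r} in column {col!r}, row {row}"
                    ) from None
            raise
        if not allow_empty and np.isnan(vals).any():
            row = int(np.where(np.isnan(vals))[0][0])
            raise ValueError(f"{path}: empty value in column {col!r}, row {row}")
        return vals

    mz = _numeric("mz", allow_empty=False)
    rt = _numeric("time", allow_empty=False)
    intensities = np.column_stack([_numeric(c, allow_empty=True) for c in col_order])
    features = [
        MzFeature(f"{mode.value}_{i:05d}", float(mz[i]), float(rt[i]), mode)
        for i in range(len(df))
    ]
    return FeatureTable(features=features, injections=injections, intensities=intensities)


def write_feature_table(table: FeatureTable, path: str | Path, batch_path: str | Path) -> None:
    """Write a feature table and its batch map as TSV (round-trips exactly)."""
    cols: dict[str, object] = {"mz": table.mz, "time": table.rt}
    for j, inj in enumerate(table.injections):
        cols[inj.injection_id] = table.intensities[:, j]
    # %.17g guarantees exact binary round-trip of every float
    pd.DataFrame(cols).to_csv(
        path, sep="\t", index=False, na_rep="", float_format=lambda v: format(v, ".17g")
    )
    pd.DataFrame(
        {
            "injection_id": [inj.injection_id for inj in table.injections],
            "batch": [inj.batch for inj in table.injections],
        }
    ).to_csv(batch_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Sample covariates
# ---------------------------------------------------------------------------

RACE_LEVELS = ("white_nonhispanic", "hispanic", "other")
AGE_LEVELS = ("<20", "20-24", "25-29", "30-34", "35+")
BIRTH_YEAR_LEVELS = ("1983-1990", "1991-2000", "2001-2011")
SEX_LEVELS = ("male", "female")
SES_LEVELS = (1, 2, 3, 4, 5)

SAMPLE_COLUMNS = (
    "sample_id",
    "reported_smoker",
    "race_ethnicity",
    "maternal_age",
    "birth_year_band",
    "sex",
    "ses",
)


@dataclass(frozen=True)
class SampleRecord:
    """Birth-record covariates plus the reported-smoking indicator."""

    sample_id: str
    reported_smoker: bool
    race_ethnicity: str
    maternal_age: str
    birth_year_band: str
    sex: str
    ses: int

    def __post_init__(self) -> None:
        checks = (
            ("race_ethnicity", self.race_ethnicity, RACE_LEVELS),
            ("maternal_age", self.maternal_age, AGE_LEVELS),
            ("birth_year_band", self.birth_year_band, BIRTH_YEAR_LEVELS),
            ("sex", self.sex, SEX_LEVELS),
            ("ses", self.ses, SES_LEVELS),
        )
        for name, value, levels in checks:
            if value not in levels:
                raise ValueError(
                    f"sample {self.sample_id!r}: {name}={value!r} not in {levels}"
                )


def read_samples(path: str | Path) -> list[SampleRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    records: list[SampleRecord] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        sid = row["sample_id"]
        if sid in seen:
            raise ValueError(f"{path}: duplicate sample_id {sid!r}")
        seen.add(sid)
        smoker_raw = str(row["reported_smoker"]).strip().lower()
        if smoker_raw not in {"0", "1", "true", "false"}:
            raise ValueError(f"{path}: bad reported_smoker {row['reported_smoker']!r}")
        records.append(
            SampleRecord(
                sample_id=sid,
                reported_smoker=smoker_raw in {"1", "true"},
                race_ethnicity=row["race_ethnicity"],
                maternal_age=row["maternal_age"],
                birth_year_band=row["birth_year_band"],
                sex=row["sex"],
                ses=int(row["ses"]),
            )
        )
    return records


def write_samples(samples: Sequence[SampleRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "reported_smoker": [int(s.reported_smoker) for s in samples],
            "race_ethnicity": [s.race_ethnicity for s in samples],
            "maternal_age": [s.maternal_age for s in samples],
            "birth_year_band": [s.birth_year_band for s in samples],
            "sex": [s.sex for s in samples],
            "ses": [s.ses for s in samples],
        }
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Reference library and pathway database
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LibraryEntry:
    """Authentic standard: name, formula, adduct, library m/z and RT."""

    name: str
    formula: str
    adduct: str
    mz: float
    rt: float
    mode: Mode
    neutral_mass: float = field(default=0.0)

    def __post_init__(self) -> None:
        if self.neutral_mass == 0.0 and self.formula:
            object.__setattr__(self, "neutral_mass", monoisotopic_mass(self.formula))
        if self.neutral_mass <= 0:
            raise ValueError(f"library entry {self.name!r}: non-positive neutral mass")


@dataclass
class ReferenceLibrary:
    entries: list[LibraryEntry]

    def for_mode(self, mode: Mode) -> list[LibraryEntry]:
        return [e for e in self.entries if e.mode == mode]

    @classmethod
    def from_json(cls, path: str | Path) -> "ReferenceLibrary":
        with open(path) as fh:
            raw = json.load(fh)
        entries = [
            LibraryEntry(
                name=e["name"],
                formula=e["formula"],
                adduct=e["adduct"],
                mz=float(e["mz"]),
                rt=float(e["rt"]),
                mode=Mode(e["mode"]),
            )
            for e in raw["entries"]
        ]
        return cls(entries)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "entries": [
                {
                    "name": e.name,
                    "formula": e.formula,
                    "adduct": e.adduct,
                    "mz": e.mz,
                    "rt": e.rt,
                    "mode": e.mode.value,
                }
                for e in self.entries
            ]
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


@dataclass
class PathwayDB:
    """Pathway -> metabolite-id sets plus neutral monoisotopic masses."""

    pathways: dict[str, frozenset[str]]
    metabolite_masses: dict[str, float]

    def __post_init__(self) -> None:
        self.pathways = {k: frozenset(v) for k, v in self.pathways.items()}
        for name, members in self.pathways.items():
            if not members:
                raise ValueError(f"pathway {name!r} is empty")
            orphans = [m for m in members if m not in self.metabolite_masses]
            if orphans:
                raise ValueError(f"pathway {name!r}: no mass for {sorted(orphans)[:5]}")
        bad = {m: v for m, v in self.metabolite_masses.items() if not v > 0}
        if bad:
            raise ValueError(f"non-positive metabolite masses: {bad}")

    @classmethod
    def from_json(cls, path: str | Path) -> "PathwayDB":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(
            pathways={k: frozenset(v) for k, v in raw["pathways"].items()},
            metabolite_masses={k: float(v) for k, v in raw["metabolite_masses"].items()},
        )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "pathways": {k: sorted(v) for k, v in self.pathways.items()},
            "metabolite_masses": self.metabolite_masses,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
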