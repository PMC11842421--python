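"""Feature annotation by accurate-mass (and retention-time) matching.

Two confidence tiers are produced:

* level 1 — match against an authentic-standard library run on the same
  platform, within +/-5 ppm m/z and +/-15 s retention time;
* level 4 — formula/mass-only match over the mode's full adduct list
  within 10 ppm, with a simple match-confidence equal to the number of
  distinct adducts of the same metabolite that are co-detected.

The ppm error convention is ``1e6 * (observed - theoretical) / theoretical``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .core_io import (
    ELECTRON_MASS,
    PROTON_MASS,
    Mode,
    MzFeature,
    ReferenceLibrary,
    monoisotopic_mass,
)

__all__ = [
    "ADDUCT_SHIFTS",
    "AnnotationHit",
    "adduct_mz",
    "ppm_error",
    "match_level1",
    "match_level4",
]

_H2O = monoisotopic_mass("H2O")
_NH3 = monoisotopic_mass("NH3")

# m/z = neutral mass + shift.  Electron mass is accounted for so that e.g.
# [M+Na]+ is the sodium atom minus one electron.
ADDUCT_SHIFTS: dict[Mode, dict[str, float]] = {
    Mode.HILIC_POS: {
        "[M+H]+": PROTON_MASS,
        "[M+Na]+": monoisotopic_mass("Na") - ELECTRON_MASS,
        "[M+NH4]+": _NH3 + PROTON_MASS,
        "[M+H-H2O]+": PROTON_MASS - _H2O,
    },
    Mode.C18_NEG: {
        "[M-H]-": -PROTON_MASS,
        "[M+Cl]-": monoisotopic_mass("Cl") + ELECTRON_MASS,
        "[M-H2O-H]-": -_H2O - PROTON_MASS,
    },
}

DEFAULT_PPM_LEVEL1 = 5.0
DEFAULT_RT_TOL_S = 15.0
DEFAULT_PPM_LEVEL4 = 10.0


def adduct_mz(neutral_mass: float, adduct: str, mode: Mode) -> float:
    """Theoretical m/z of ``adduct`` formed from a neutral monoisotopic mass."""
    shifts = ADDUCT_SHIFTS[mode]
    if adduct not in shifts:
        raise ValueError(f"adduct {adduct!r} not defined for mode {mode.value}")
    return neutral_mass + shifts[adduct]


def ppm_error(observed: float, theoretical: float) -> float:
    return 1e6 * (observed - theoretical) / theoretical


@dataclass(frozen=True)
class AnnotationHit:
    feature_id: str
    metabolite: str
    adduct: str
    theoretical_mz: float
    ppm: float
    level: str  # "level1" | "level4"
    rt_error: float | None = None  # level 1 only
    primary: bool = True
    support: int = 1  # level 4: number of co-detected adducts of the metabolite


def match_level1(
    features: Sequence[MzFeature],
    library: ReferenceLibrary,
    tol_ppm: float = DEFAULT_PPM_LEVEL1,
    tol_rt: float = DEFAULT_RT_TOL_S,
) -> list[AnnotationHit]:
    """All (feature, standard) pairs within both tolerances.

    When several library entries match one feature, the nearest-ppm hit is
    flagged primary and the rest are retained as secondary.
    """
    hits: list[AnnotationHit] = []
    by_feature: dict[str, list[int]] = {}
    for feat in features:
        for entry in library.for_mode(feat.mode):
            err = ppm_error(feat.mz, entry.mz)
            rt_err = feat.rt - entry.rt
            if abs(err) <= tol_ppm and abs(rt_err) <= tol_rt:
                by_feature.setdefault(feat.feature_id, []).append(len(hits))
                hits.append(
                    AnnotationHit(
                        feature_id=feat.feature_id,
                        metabolite=entry.name,
                        adduct=entry.adduct,
                        theoretical_mz=entry.mz,
                        ppm=err,
                        level="level1",
                        rt_error=rt_err,
                        primary=True,
                    )
                )
    # demote all but the nearest-ppm hit per feature
    out = list(hits)
    for fid, idxs in by_feature.items():
        if len(idxs) > 1:
            best = min(idxs, key=lambda i: abs(hits[i].ppm))
            for i in idxs:
                if i != best:
                    out[i] = AnnotationHit(
                        **{**hits[i].__dict__, "primary": False}
                    )
    return out


def match_level4(
    features: Sequence[MzFeature],
    formula_library: Iterable[tuple[str, float]],
    tol_ppm: float = DEFAULT_PPM_LEVEL4,
) -> list[AnnotationHit]:
    """Mass-only annotation over the mode's full adduct list within ``tol_ppm``.

    ``formula_library`` yields ``(metabolite name, neutral monoisotopic mass)``
    pairs.  Every hit is reported; ``support`` counts how many distinct
    adducts of the same metabolite matched some feature (a crude stand-in
    for correlation/adduct-grouping confidence scores).
    """
    lib = list(formula_library)
    mode_by_id = {f.feature_id: f.mode for f in features}
    raw: list[AnnotationHit] = []
    support: dict[tuple[str, Mode], set[str]] = {}
    for feat in features:
        for name, mass in lib:
            for adduct, shift in ADDUCT_SHIFTS[feat.mode].items():
                theo = mass + shift
                if theo <= 0:
                    continue
                err = ppm_error(feat.mz, theo)
                if abs(err) <= tol_ppm:
                    raw.append(
                        AnnotationHit(
                            feature_id=feat.feature_id,
                            metabolite=name,
                            adduct=adduct,
                            theoretical_mz=theo,
                            ppm=err,
                            level="level4",
                        )
                    )
                    support.setdefault((name, feat.mode), set()).add(adduct)
    return [
        AnnotationHit(
            **{
                **h.__dict__,
                "support": len(support[(h.metabolite, mode_by_id[h.feature_id])]),
            }
        )
        for h in raw
    ]
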