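"""Closed-form carcass, colour and lipid nutritional-quality computations.

Carcass yield is cold-carcass weight over live weight at slaughter (%).
Colour chroma and hue angle are the standard CIELab polar coordinates
C* = sqrt(a*^2 + b*^2), H* = arctan(b*/a*) in degrees.  The lipid indices
are the classical nutritional-quality scores of a fatty-acid profile
expressed in g FA / 100 g total FA:

    IA  = (C12:0 + 4*C14:0 + C16:0) / (SUM MUFA + SUM PUFA)
    IT  = (C14:0 + C16:0 + C18:0) /
          (0.5*SUM MUFA + 0.5*SUM PUFA n-6 + 3*SUM PUFA n-3 + n-3/n-6)
    h/H = (C18:1n-9 + C18:2n-6 + C20:4n-6 + C18:3n-3
           + C20:5n-3 + C22:5n-3 + C22:6n-3) / (C14:0 + C16:0)

Because each index is a nonlinear function of the profile, the index of a
mean profile differs from the mean of per-animal indices (Jensen gap);
aggregation helpers expose both.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .spectra import ParameterError

__all__ = [
    "CarcassRecord",
    "ColorRecord",
    "FattyAcidProfile",
    "FaSums",
    "LipidQualityIndices",
    "DomainError",
    "carcass_yield",
    "chroma_hue",
    "lipid_indices",
    "fa_sums_ratios",
    "SFA",
    "MUFA",
    "PUFA_N6",
    "PUFA_N3",
    "PUFA_OTHER",
]


class DomainError(ValueError):
    """Input outside the mathematical domain of a formula."""


# Fatty-acid family membership (percent of total FA).  The trans diene
# 9t,12t-C18:2 is polyunsaturated but belongs to neither omega family.
SFA = ("C10:0", "C12:0", "C14:0", "C15:0", "C16:0", "C17:0", "C18:0",
       "C20:0", "C21:0", "C22:0", "C24:0")
MUFA = ("C14:1", "C15:1", "C16:1n-7", "C17:1n-7", "9t-C18:1", "C18:1n-9",
        "C20:1n-9", "C22:1n-9", "C24:1n-9")
PUFA_N6 = ("C18:2n-6", "C18:3n-6", "C20:2n-6", "C20:3n-6", "C20:4n-6",
           "C22:2n-6")
PUFA_N3 = ("C18:3n-3", "C20:3n-3", "C20:5n-3", "C22:5n-3", "C22:6n-3")
PUFA_OTHER = ("9t, 12t-C18:2",)

H_NUMERATOR = ("C18:1n-9", "C18:2n-6", "C20:4n-6", "C18:3n-3",
               "C20:5n-3", "C22:5n-3", "C22:6n-3")


@dataclass(frozen=True)
class CarcassRecord:
    """Per-animal carcass traits: age (days), daily gain (g/day), weights (kg)."""

    lws: float
    ccw: float
    hcw: float | None = None
    age: float | None = None
    dg: float | None = None

    def __post_init__(self) -> None:
        for name in ("lws", "ccw", "hcw", "age", "dg"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise DomainError(f"{name} must be positive")
        if self.hcw is not None and not (self.ccw <= self.hcw <= self.lws):
            raise DomainError("expected ccw <= hcw <= lws")


@dataclass(frozen=True)
class ColorRecord:
    """CIELab coordinates with derived chroma and hue angle."""

    L_star: float
    a_star: float
    b_star: float

    @property
    def C_star(self) -> float:
        return chroma_hue(self.a_star, self.b_star)[0]

    @property
    def H_star(self) -> float:
        return chroma_hue(self.a_star, self.b_star)[1]


@dataclass(frozen=True)
class FaSums:
    """Family totals of a profile (percent of total FA)."""

    sfa: float
    mufa: float
    pufa: float
    pufa_n6: float
    pufa_n3: float


@dataclass(frozen=True)
class LipidQualityIndices:
    ia: float
    it: float
    h_over_H: float
    n6_n3: float
    pufa_sfa: float


class FattyAcidProfile(Mapping):
    """Named fatty-acid percentages (g FA / 100 g total FA); absent FAs are 0."""

    def __init__(self, percentages: Mapping[str, float]):
        clean = {}
        for name, value in percentages.items():
            v = float(value)
            if math.isnan(v):
                continue
            if v < 0:
                raise DomainError(f"negative percentage for {name}")
            clean[name] = v
        self._p = clean

    def __getitem__(self, name: str) -> float:
        return self._p.get(name, 0.0)

    def get(self, name: str, default: float = 0.0) -> float:
        return self._p.get(name, default)

    def __iter__(self):
        return iter(self._p)

    def __len__(self) -> int:
        return len(self._p)

    def family_sum(self, members: Iterable[str]) -> float:
        return float(sum(self[m] for m in members))

    def sums(self) -> FaSums:
        n6 = self.family_sum(PUFA_N6)
        n3 = self.family_sum(PUFA_N3)
        return FaSums(
            sfa=self.family_sum(SFA),
            mufa=self.family_sum(MUFA),
            pufa=n6 + n3 + self.family_sum(PUFA_OTHER),
            pufa_n6=n6,
            pufa_n3=n3,
        )

    def scaled(self, k: float) -> "FattyAcidProfile":
        if k <= 0:
            raise DomainError("scale factor must be positive")
        return FattyAcidProfile({n: v * k for n, v in self._p.items()})


def carcass_yield(record: CarcassRecord) -> float:
    """Carcass yield (%): 100 * cold carcass weight / live weight at slaughter."""
    if record.lws <= 0:
        raise DomainError("live weight at slaughter must be positive")
    return 100.0 * record.ccw / record.lws


def chroma_hue(a_star: float, b_star: float) -> tuple[float, float]:
    """CIELab chroma C* = sqrt(a*^2 + b*^2) and hue angle H* (degrees).

    ``a* = 0`` with ``b* != 0`` yields H* = +/-90 by the limit convention.
    """
    c = math.hypot(a_star, b_star)
    if a_star == 0 and b_star == 0:
        raise DomainError("hue undefined at (0, 0)")
    h = math.degrees(math.atan2(b_star, a_star))
    return c, h


def lipid_indices(profile: FattyAcidProfile | Mapping[str, float],
                  sums: FaSums | None = None) -> LipidQualityIndices:
    """Atherogenicity, thrombogenicity and h/H indices of a fatty-acid profile.

    Family totals are recomputed from the profile unless ``sums`` is
    supplied (useful when a summary table prints totals over FAs below the
    per-acid reporting threshold).
    """
    if not isinstance(profile, FattyAcidProfile):
        profile = FattyAcidProfile(profile)
    s = sums if sums is not None else profile.sums()

    denom_ia = s.mufa + s.pufa
    if denom_ia <= 0:
        raise DomainError("IA denominator (MUFA + PUFA) must be positive")
    ia = (profile["C12:0"] + 4.0 * profile["C14:0"] + profile["C16:0"]) / denom_ia

    if s.pufa_n6 <= 0:
        raise DomainError("IT requires a positive n-6 total")
    denom_it = 0.5 * s.mufa + 0.5 * s.pufa_n6 + 3.0 * s.pufa_n3 + s.pufa_n3 / s.pufa_n6
    if denom_it <= 0:
        raise DomainError("IT denominator must be positive")
    it = (profile["C14:0"] + profile["C16:0"] + profile["C18:0"]) / denom_it

    denom_h = profile["C14:0"] + profile["C16:0"]
    if denom_h <= 0:
        raise DomainError("h/H denominator (C14:0 + C16:0) must be positive")
    h_over_H = profile.family_sum(H_NUMERATOR) / denom_h

    if s.pufa_n3 <= 0:
        raise DomainError("n-6/n-3 requires a positive n-3 total")
    if s.sfa <= 0:
        raise DomainError("PUFA/SFA requires a positive SFA total")
    return LipidQualityIndices(
        ia=ia, it=it, h_over_H=h_over_H,
        n6_n3=s.pufa_n6 / s.pufa_n3, pufa_sfa=s.pufa / s.sfa,
    )


def fa_sums_ratios(profile: FattyAcidProfile | Mapping[str, float]) -> dict:
    """Family sums and the n-6/n-3 and PUFA/SFA ratios of one profile."""
    if not isinstance(profile, FattyAcidProfile):
        profile = FattyAcidProfile(profile)
    s = profile.sums()
    if s.pufa_n3 <= 0:
        raise DomainError("n-6/n-3 undefined: zero n-3 total")
    return {
        "SFA": s.sfa,
        "MUFA": s.mufa,
        "PUFA": s.pufa,
        "PUFA n-6": s.pufa_n6,
        "PUFA n-3": s.pufa_n3,
        "n6/n3": s.pufa_n6 / s.pufa_n3,
        "PUFA/SFA": s.pufa / s.sfa if s.sfa > 0 else float("inf"),
    }


def augment_reference_table(refs: pd.DataFrame) -> pd.DataFrame:
    """Append derived colour and lipid columns to a per-sample reference table.

    Requires ``a*``/``b*`` for chroma and hue and the fatty-acid columns for
    the lipid indices; carcass yield is appended when ``ccw`` and ``lws``
    are present.  Each index is computed per row (per animal).
    """
    out = refs.copy()
    if {"a*", "b*"}.issubset(out.columns):
        ch = out.apply(lambda r: chroma_hue(r["a*"], r["b*"]), axis=1)
        out["C*"] = [c for c, _ in ch]
        out["H*"] = [h for _, h in ch]
    fa_cols = [c for c in out.columns
               if c in set(SFA) | set(MUFA) | set(PUFA_N6) | set(PUFA_N3) | set(PUFA_OTHER)]
    if fa_cols:
        rows = []
        for _, r in out.iterrows():
            prof = FattyAcidProfile({c: r[c] for c in fa_cols})
            idx = lipid_indices(prof)
            sums = fa_sums_ratios(prof)
            rows.append({
                "SFA": sums["SFA"], "MUFA": sums["MUFA"], "PUFA": sums["PUFA"],
                "PUFA n-6": sums["PUFA n-6"], "PUFA n-3": sums["PUFA n-3"],
                "n6/n3": sums["n6/n3"], "PUFA/SFA": sums["PUFA/SFA"],
                "IA": idx.ia, "IT": idx.it, "h/H": idx.h_over_H,
            })
        out = pd.concat([out, pd.DataFrame(rows, index=out.index)], axis=1)
    if {"ccw", "lws"}.issubset(out.columns):
        out["yield"] = 100.0 * out["ccw"] / out["lws"]
    return out


def index_of_mean_vs_mean_of_index(refs: pd.DataFrame, by: str = "breed") -> pd.DataFrame:
    """Contrast per-group mean of per-animal indices with indices of the mean profile."""
    fa_cols = [c for c in refs.columns
               if c in set(SFA) | set(MUFA) | set(PUFA_N6) | set(PUFA_N3) | set(PUFA_OTHER)]
    records = []
    for group, sub in refs.groupby(by):
        per_animal = augment_reference_table(sub[fa_cols + [by]])
        mean_profile = FattyAcidProfile(sub[fa_cols].mean().to_dict())
        of_mean = lipid_indices(mean_profile)
        records.append({
            by: group,
            "IA mean_of_index": per_animal["IA"].mean(),
            "IA index_of_mean": of_mean.ia,
            "IT mean_of_index": per_animal["IT"].mean(),
            "IT index_of_mean": of_mean.it,
            "h/H mean_of_index": per_animal["h/H"].mean(),
            "h/H index_of_mean": of_mean.h_over_H,
        })
    return pd.DataFrame(records)
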