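"""Spectrum containers, CSV I/O and spectral pre-treatments.

Absorbance spectra live on a shared uniform wavenumber grid (by default
4000-10000 cm^-1 at 4 cm^-1 spacing, 1501 points).  Pre-treatments are the
scatter- and baseline-correction operators common in NIR chemometrics:

====  ==========================================================
code  operator
====  ==========================================================
SM    Savitzky-Golay smoothing
NORM  normalisation of each spectrum to unit area
ALS   asymmetric-least-squares baseline correction
MSC   multiplicative scatter correction against a reference
SNV   standard normal variate (per-spectrum standardisation)
DV1   Savitzky-Golay first derivative w.r.t. wavenumber
DV2   Savitzky-Golay second derivative w.r.t. wavenumber
====  ==========================================================

Codes compose left to right in a :class:`TreatmentSpec`, written in hyphen
syntax ("SNV-DV1" = SNV then first derivative).  Operators that estimate
set-level statistics (only MSC's reference spectrum here) are fitted on a
designated subset of rows and then applied to all rows, so that a
calibration/prediction split never leaks prediction-set information.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.signal import savgol_filter
from scipy.sparse.linalg import spsolve

__all__ = [
    "WavenumberGrid",
    "Spectrum",
    "SpectraSet",
    "TreatmentSpec",
    "FormatError",
    "ParameterError",
    "DegenerateInputError",
    "read_spectra_csv",
    "write_spectra_csv",
    "smooth",
    "norm_unit_area",
    "snv",
    "msc",
    "als_baseline",
    "derivative",
    "decimate",
    "apply_treatment",
    "TREATMENT_CODES",
]

METADATA_COLUMNS = ("sample_id", "replicate", "breed", "sex")

TREATMENT_CODES = ("SM", "NORM", "ALS", "MSC", "SNV", "DV1", "DV2")


class FormatError(ValueError):
    """Malformed input table (bad header, non-uniform grid, missing columns)."""


class ParameterError(ValueError):
    """Invalid operator parameter."""


class DegenerateInputError(ValueError):
    """Input on which the operator is mathematically undefined."""


@dataclass(frozen=True)
class WavenumberGrid:
    """Uniform ascending wavenumber axis in cm^-1."""

    start: float = 4000.0
    stop: float = 10000.0
    spacing: float = 4.0

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ParameterError("grid spacing must be positive")
        if self.stop <= self.start:
            raise ParameterError("grid stop must exceed start")
        n = (self.stop - self.start) / self.spacing + 1.0
        if abs(n - round(n)) > 1e-9:
            raise ParameterError(
                f"(stop - start)/spacing must be integral, got {n!r}"
            )

    @property
    def n_points(self) -> int:
        return int(round((self.stop - self.start) / self.spacing)) + 1

    @property
    def values(self) -> np.ndarray:
        return self.start + self.spacing * np.arange(self.n_points)

    @classmethod
    def from_values(cls, wavenumbers: np.ndarray, rtol: float = 1e-6) -> "WavenumberGrid":
        """Build a grid from an explicit axis, validating uniform spacing."""
        w = np.asarray(wavenumbers, dtype=float)
        if w.ndim != 1 or w.size < 2:
            raise FormatError("need at least two wavenumber columns")
        d = np.diff(w)
        if np.any(d <= 0):
            raise FormatError("wavenumbers must be strictly ascending")
        spacing = d[0]
        if not np.allclose(d, spacing, rtol=rtol, atol=spacing * rtol):
            raise FormatError("non-uniform wavenumber spacing")
        return cls(start=float(w[0]), stop=float(w[-1]), spacing=float(spacing))


@dataclass(frozen=True)
class Spectrum:
    """A single absorbance spectrum on a uniform grid."""

    grid: WavenumberGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1 or v.size != self.grid.n_points:
            raise FormatError(
                f"values length {v.size} != grid n_points {self.grid.n_points}"
            )
        if not np.all(np.isfinite(v)):
            raise FormatError("spectrum contains non-finite values")


@dataclass
class SpectraSet:
    """A stack of spectra sharing one grid, with per-row sample metadata."""

    grid: WavenumberGrid
    matrix: np.ndarray
    sample_id: np.ndarray
    replicate: np.ndarray
    breed: np.ndarray
    sex: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != self.grid.n_points:
            raise FormatError("matrix shape does not match grid")
        n = self.matrix.shape[0]
        self.sample_id = np.asarray(self.sample_id)
        self.replicate = np.asarray(self.replicate, dtype=int)
        self.breed = np.asarray(self.breed)
        self.sex = np.asarray(self.sex)
        for name in ("sample_id", "replicate", "breed", "sex"):
            if getattr(self, name).shape != (n,):
                raise FormatError(f"metadata column {name} has wrong length")
        # breed/sex must be constant within a sample, and replicate counts equal
        meta = pd.DataFrame({
            "sample_id": self.sample_id, "breed": self.breed, "sex": self.sex,
        })
        per_sample = meta.groupby("sample_id", sort=False).nunique()
        if (per_sample[["breed", "sex"]] > 1).any().any():
            raise FormatError("breed/sex not constant within a sample_id")
        counts = meta.groupby("sample_id", sort=False).size()
        if counts.nunique() > 1:
            raise FormatError("unequal replicate counts across samples")

    @property
    def n_spectra(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_points(self) -> int:
        return self.grid.n_points

    def spectrum(self, row: int) -> Spectrum:
        return Spectrum(self.grid, self.matrix[row])

    def subset(self, rows: np.ndarray) -> "SpectraSet":
        rows = np.asarray(rows)
        return SpectraSet(
            grid=self.grid,
            matrix=self.matrix[rows],
            sample_id=self.sample_id[rows],
            replicate=self.replicate[rows],
            breed=self.breed[rows],
            sex=self.sex[rows],
        )

    def rows_for_samples(self, sample_ids: Sequence) -> np.ndarray:
        wanted = set(sample_ids)
        return np.array([i for i, s in enumerate(self.sample_id) if s in wanted])

    def with_matrix(self, matrix: np.ndarray, grid: WavenumberGrid | None = None) -> "SpectraSet":
        return SpectraSet(
            grid=grid if grid is not None else self.grid,
            matrix=matrix,
            sample_id=self.sample_id,
            replicate=self.replicate,
            breed=self.breed,
            sex=self.sex,
        )

    def sample_mean_matrix(self) -> tuple[np.ndarray, np.ndarray]:
        """Replicate-averaged matrix, one row per sample (order of first occurrence)."""
        ids = pd.unique(self.sample_id)
        rows = np.vstack([
            self.matrix[self.sample_id == s].mean(axis=0) for s in ids
        ])
        return ids, rows

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.matrix, columns=[f"{w:g}" for w in self.grid.values])
        for i, name in enumerate(METADATA_COLUMNS):
            df.insert(i, name, getattr(self, name if name != "replicate" else "replicate"))
        return df


@dataclass(frozen=True)
class TreatmentSpec:
    """Ordered list of pre-treatment codes, applied left to right."""

    codes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.codes:
            raise ParameterError("treatment spec must contain at least one code")
        for c in self.codes:
            if c not in TREATMENT_CODES:
                raise ParameterError(f"unknown treatment code {c!r}")

    @classmethod
    def parse(cls, text: str) -> "TreatmentSpec":
        """Parse hyphen syntax, e.g. ``"MSC-DV1"`` -> (MSC, DV1)."""
        return cls(tuple(code.strip() for code in text.split("-")))

    def __str__(self) -> str:
        return "-".join(self.codes)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def read_spectra_csv(path: str | Path) -> SpectraSet:
    """Read a spectra table: metadata columns then one numeric column per wavenumber."""
    df = pd.read_csv(path)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing metadata column(s): {', '.join(missing)}")
    wn_cols = [c for c in df.columns if c not in METADATA_COLUMNS]
    try:
        wavenumbers = np.array([float(c) for c in wn_cols])
    except ValueError as exc:
        raise FormatError(f"non-numeric wavenumber column header: {exc}") from exc
    grid = WavenumberGrid.from_values(wavenumbers)
    matrix = df[wn_cols].to_numpy(dtype=float)
    return SpectraSet(
        grid=grid,
        matrix=matrix,
        sample_id=df["sample_id"].to_numpy(),
        replicate=df["replicate"].to_numpy(),
        breed=df["breed"].to_numpy(),
        sex=df["sex"].to_numpy(),
    )


def write_spectra_csv(spectra: SpectraSet, path: str | Path) -> None:
    spectra.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Pre-treatment operators
# ---------------------------------------------------------------------------

def _check_savgol(window: int, polyorder: int, n_points: int) -> None:
    if window % 2 == 0:
        raise ParameterError("window must be odd")
    if window < polyorder + 2:
        raise ParameterError("window must be >= polyorder + 2")
    if window > n_points:
        raise ParameterError("window exceeds spectrum length")


def smooth(s: Spectrum, window: int = 11, polyorder: int = 2) -> Spectrum:
    """Savitzky-Golay smoothing; exact on polynomials of degree <= polyorder."""
    _check_savgol(window, polyorder, s.grid.n_points)
    out = savgol_filter(s.values, window_length=window, polyorder=polyorder,
                        mode="interp")
    return Spectrum(s.grid, out)


def norm_unit_area(s: Spectrum) -> Spectrum:
    """Scale so the trapezoidal integral over the wavenumber axis equals 1."""
    area = float(np.trapezoid(s.values, dx=s.grid.spacing))
    if abs(area) < 1e-12:
        raise DegenerateInputError("spectrum has zero integral")
    return Spectrum(s.grid, s.values / area)


def snv(s: Spectrum) -> Spectrum:
    """Standard normal variate: per-spectrum (x - mean)/sd with n-1 denominator."""
    sd = float(np.std(s.values, ddof=1))
    if sd <= 0 or not np.isfinite(sd):
        raise DegenerateInputError("zero variance spectrum")
    return Spectrum(s.grid, (s.values - s.values.mean()) / sd)


def _msc_row(x: np.ndarray, ref: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    # OLS of x on ref: x ~ a + b*ref ; corrected = (x - a)/b
    b, a = np.polyfit(ref, x, 1)
    if abs(b) < tol:
        raise DegenerateInputError("MSC slope below tolerance")
    return (x - a) / b


def msc(spectra: SpectraSet, reference: Spectrum | str = "mean") -> tuple[SpectraSet, Spectrum]:
    """Multiplicative scatter correction of every row against a reference.

    Each spectrum x is regressed on the reference (x = a + b*ref) and returned
    as (x - a)/b.  ``reference="mean"`` uses the column mean of ``spectra`` —
    at prediction time pass the stored calibration-set reference instead.
    Returns the corrected set and the reference actually used.
    """
    if isinstance(reference, str):
        if reference != "mean":
            raise ParameterError(f"unknown reference {reference!r}")
        ref = Spectrum(spectra.grid, spectra.matrix.mean(axis=0))
    else:
        if reference.grid != spectra.grid:
            raise FormatError("reference grid differs from set grid")
        ref = reference
    out = np.vstack([_msc_row(row, ref.values) for row in spectra.matrix])
    return spectra.with_matrix(out), ref


def als_baseline(s: Spectrum, lam: float = 1e5, p: float = 0.01,
                 n_iter: int = 10) -> tuple[Spectrum, Spectrum]:
    """Asymmetric-least-squares baseline estimate and baseline-corrected spectrum.

    Minimises ``sum_i w_i (x_i - z_i)^2 + lam * sum (d2 z)^2`` with weights
    re-set each iteration to ``p`` above the baseline and ``1 - p`` below, so
    the fit tracks the lower envelope for small ``p``.
    """
    if lam <= 0:
        raise ParameterError("lam must be positive")
    if not 0 < p < 1:
        raise ParameterError("p must be in (0, 1)")
    if n_iter < 1:
        raise ParameterError("n_iter must be >= 1")
    x = s.values
    n = x.size
    d = sparse.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(n - 2, n), format="csc")
    penalty = lam * (d.T @ d)
    w = np.ones(n)
    z = x
    for _ in range(n_iter):
        wmat = sparse.diags(w, format="csc")
        z = spsolve(wmat + penalty, w * x)
        w = np.where(x > z, p, 1.0 - p)
    baseline = Spectrum(s.grid, z)
    return baseline, Spectrum(s.grid, x - z)


def derivative(s: Spectrum, order: int = 1, window: int = 11,
               polyorder: int = 2) -> Spectrum:
    """Savitzky-Golay derivative with respect to wavenumber (absorbance * cm)."""
    if order not in (1, 2):
        raise ParameterError("order must be 1 or 2")
    if polyorder < order:
        raise ParameterError("polyorder must be >= derivative order")
    _check_savgol(window, polyorder, s.grid.n_points)
    out = savgol_filter(s.values, window_length=window, polyorder=polyorder,
                        deriv=order, delta=s.grid.spacing, mode="interp")
    return Spectrum(s.grid, out)


def decimate(s: Spectrum, keep_every: int = 10) -> Spectrum:
    """Keep every ``keep_every``-th point starting at index 0 (1501 -> 151 at 10)."""
    if keep_every < 1:
        raise ParameterError("keep_every must be >= 1")
    if keep_every == 1:
        return s
    idx = np.arange(0, s.grid.n_points, keep_every)
    new_grid = WavenumberGrid(
        start=s.grid.start,
        stop=float(s.grid.values[idx[-1]]),
        spacing=s.grid.spacing * keep_every,
    )
    return Spectrum(new_grid, s.values[idx])


def decimate_set(spectra: SpectraSet, keep_every: int = 10) -> SpectraSet:
    """Apply :func:`decimate` to every row of a set."""
    if keep_every == 1:
        return spectra
    first = decimate(spectra.spectrum(0), keep_every)
    idx = np.arange(0, spectra.grid.n_points, keep_every)
    return spectra.with_matrix(spectra.matrix[:, idx], grid=first.grid)


# ---------------------------------------------------------------------------
# Composition
# ---------------------------------------------------------------------------

@dataclass
class FittedTreatment:
    """A treatment chain with its set-level statistics frozen on the fit rows.

    Currently only MSC carries fitted state (its reference spectrum); all
    other operators are purely per-row.  Keeping the fitted references makes
    the chain re-applicable to new spectra without touching them during fit.
    """

    spec: TreatmentSpec
    savgol_window: int = 11
    savgol_polyorder: int = 2
    als_lam: float = 1e5
    als_p: float = 0.01
    als_n_iter: int = 10
    msc_references: dict[int, Spectrum] = field(default_factory=dict)

    def _apply_code(self, position: int, code: str, current: SpectraSet,
                    fit_rows: np.ndarray | None) -> SpectraSet:
        if code == "SM":
            mat = np.vstack([
                smooth(current.spectrum(i), self.savgol_window,
                       self.savgol_polyorder).values
                for i in range(current.n_spectra)
            ])
            return current.with_matrix(mat)
        if code == "NORM":
            mat = np.vstack([
                norm_unit_area(current.spectrum(i)).values
                for i in range(current.n_spectra)
            ])
            return current.with_matrix(mat)
        if code == "SNV":
            mat = np.vstack([
                snv(current.spectrum(i)).values for i in range(current.n_spectra)
            ])
            return current.with_matrix(mat)
        if code == "ALS":
            mat = np.vstack([
                als_baseline(current.spectrum(i), self.als_lam, self.als_p,
                             self.als_n_iter)[1].values
                for i in range(current.n_spectra)
            ])
            return current.with_matrix(mat)
        if code == "MSC":
            if position in self.msc_references:
                ref = self.msc_references[position]
            else:
                fit_set = current if fit_rows is None else current.subset(fit_rows)
                ref = Spectrum(current.grid, fit_set.matrix.mean(axis=0))
                self.msc_references[position] = ref
            corrected, _ = msc(current, ref)
            return corrected
        if code in ("DV1", "DV2"):
            order = 1 if code == "DV1" else 2
            mat = np.vstack([
                derivative(current.spectrum(i), order, self.savgol_window,
                           max(self.savgol_polyorder, order)).values
                for i in range(current.n_spectra)
            ])
            return current.with_matrix(mat)
        raise ParameterError(f"unknown treatment code {code!r}")

    def apply(self, spectra: SpectraSet, fit_rows: np.ndarray | None = None) -> SpectraSet:
        current = spectra
        for position, code in enumerate(self.spec.codes):
            current = self._apply_code(position, code, current, fit_rows)
        return current


def apply_treatment(spectra: SpectraSet, spec: TreatmentSpec | str,
                    fit_rows: np.ndarray | None = None,
                    **operator_kwargs) -> SpectraSet:
    """Apply a treatment chain; set-level statistics are fitted on ``fit_rows`` only.

    ``fit_rows=None`` fits on all rows (appropriate only before any
    calibration/prediction split exists).
    """
    if isinstance(spec, str):
        spec = TreatmentSpec.parse(spec)
    fitted = FittedTreatment(spec=spec, **operator_kwargs)
    return fitted.apply(spectra, fit_rows=fit_rows)


def fit_treatment(spectra: SpectraSet, spec: TreatmentSpec | str,
                  fit_rows: np.ndarray | None = None,
                  **operator_kwargs) -> tuple[SpectraSet, FittedTreatment]:
    """Like :func:`apply_treatment` but also return the fitted chain for reuse."""
    if isinstance(spec, str):
        spec = TreatmentSpec.parse(spec)
    fitted = FittedTreatment(spec=spec, **operator_kwargs)
    treated = fitted.apply(spectra, fit_rows=fit_rows)
    return treated, fitted
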