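"""Synthetic two-breed goat-meat NIR cohort generator.

Real spectra for this population are not publicly deposited, so the
pipeline is exercised on a simulated cohort that reproduces the study's
statistical structure: two breeds ("Serrana", "Preta de Montesinho"), 16
samples per breed balanced across sexes, three replicate spectra per
sample, absorbance on the 4000-10000 cm^-1 / 4 cm^-1 grid.

Per-sample chemistry is drawn from truncated normal distributions whose
means are the published breed-level means and whose standard deviations
are SEM * sqrt(n) (n = 16 per breed for meat and fatty-acid attributes,
n = 8 per breed-sex cell for carcass traits).  Clean spectra follow a
Beer-Lambert-style linear mixing model: each constituent contributes a
Gaussian absorption band (plus small cross-loadings on its spectral
neighbours), scaled by the constituent's value relative to the pooled
mean.  Breed identity adds a smooth band-shaped offset scaled by
``class_separation``.  Each replicate is then corrupted by multiplicative
gain, additive offset and iid noise:

    replicate = gain * clean + offset + eps,
    gain ~ N(1, scatter_gain_sd), offset ~ N(0, scatter_offset_sd),
    eps ~ N(0, noise_sd) per point.

The generator returns the ground truth (clean spectra, per-replicate gain
and offset, generating means) so tests can verify that scatter correction
and calibration actually invert the corruption they were designed for.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from . import reference_data as ref
from .spectra import ParameterError, SpectraSet, WavenumberGrid

__all__ = ["SyntheticConfig", "generate_references", "generate_spectra",
           "generate_dataset"]

# Constituents that carry spectral signal, with a home absorption band each
# (center cm^-1, width cm^-1).  Only actual chromophores are encoded: water
# (O-H), protein (N-H/C-H) and fat with its major fatty acids (C-H).
# Attributes without an absorbing moiety (pH, colour, texture) stay in the
# reference table but leave no spectral trace.
SPECTRAL_CONSTITUENTS: dict[str, tuple[float, float]] = {
    "moisture": (5160.0, 220.0),   # O-H combination
    "protein": (4600.0, 160.0),    # N-H/C-H combination
    "IMF": (5790.0, 150.0),        # C-H first overtone
    "C14:0": (4260.0, 120.0),      # C-H combination
    "C16:0": (5680.0, 140.0),
    "C18:0": (8250.0, 220.0),      # C-H second overtone
    "C18:1n-9": (4770.0, 150.0),
    "C18:2n-6": (7180.0, 200.0),
}

# Common absorbance background shared by every sample: the broad water
# first-overtone/combination envelope plus a gentle C-H shoulder.  Its
# presence anchors the per-spectrum scale so SNV and MSC do not erase
# concentration information.
BACKGROUND_BANDS: tuple[tuple[float, float, float], ...] = (
    (5150.0, 420.0, 1.0),   # O-H combination envelope
    (6900.0, 520.0, 0.8),   # O-H first overtone
    (8400.0, 900.0, 0.3),   # C-H second-overtone shoulder
    (4400.0, 600.0, 0.5),
)

# Bands carrying the breed-specific offset (distinct from the home bands).
BREED_OFFSET_BANDS: tuple[tuple[float, float], ...] = (
    (4450.0, 130.0), (5350.0, 170.0), (6550.0, 210.0),
    (7650.0, 190.0), (8050.0, 160.0), (8900.0, 250.0),
)

# Physical bounds for the truncated normal draws.
_BOUNDS: dict[str, tuple[float, float]] = {
    "pH": (5.0, 7.0),
    "WHC": (0.0, 100.0), "moisture": (0.0, 100.0), "ash": (0.0, 100.0),
    "protein": (0.0, 100.0), "IMF": (0.0, 100.0),
    "SF": (0.0, np.inf), "L*": (0.0, 100.0),
    "a*": (0.0, np.inf), "b*": (0.0, np.inf),
}


@dataclass
class SyntheticConfig:
    """Study-design parameters of the simulated cohort."""

    n_samples_per_breed: int = 16
    replicates: int = 3
    sd_scale: float = 1.0               # multiplies every constituent sd (0 = exact means)
    grid: WavenumberGrid = field(default_factory=WavenumberGrid)
    band_amplitude: float = 0.08        # absorbance of a home band at pooled-mean value
    background_amplitude: float = 0.30  # absorbance scale of the shared background
    cross_loading: float = 0.25         # relative loading on the two neighbouring bands
    active_constituents: tuple[str, ...] | None = None  # None = all encoded
    scatter_gain_sd: float = 0.05
    scatter_offset_sd: float = 0.02
    noise_sd: float = 0.001             # iid absorbance noise per point
    class_separation: float = 1.0       # scales the 0.05-absorbance breed offset
    breed_offset_amplitude: float = 0.05
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_samples_per_breed < 1 or self.replicates < 1:
            raise ParameterError("counts must be >= 1")
        for name in ("scatter_gain_sd", "scatter_offset_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        for center, _ in list(SPECTRAL_CONSTITUENTS.values()) + list(BREED_OFFSET_BANDS):
            if not self.grid.start <= center <= self.grid.stop:
                raise ParameterError(f"band center {center} outside grid")


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float, size: int) -> np.ndarray:
    if sd == 0:
        return np.full(size, mean)
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_references(cfg: SyntheticConfig, seed: int | None = None,
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw per-sample physicochemical, fatty-acid and carcass tables.

    Returns ``(refs, carcass)``; both carry ``sample_id``, ``breed`` and
    ``sex`` columns and are deterministic for a given seed.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n = cfg.n_samples_per_breed
    sd_factor_meat = np.sqrt(ref.N_PER_BREED)
    sd_factor_carcass = np.sqrt(ref.N_PER_BREED_SEX)

    rows, carcass_rows = [], []
    for breed, tag in zip(ref.BREEDS, ("SER", "PRE")):
        sexes = np.array([ref.SEXES[i % 2] for i in range(n)])
        sample_ids = [f"{tag}{i + 1:02d}" for i in range(n)]
        attrs = {}
        for name, mean in ref.MEAT_MEANS[breed].items():
            lo, hi = _BOUNDS.get(name, (0.0, np.inf))
            attrs[name] = _truncated_normal(
                rng, mean, ref.MEAT_SEM[name] * sd_factor_meat * cfg.sd_scale, lo, hi, n)
        for name, mean in ref.FA_MEANS[breed].items():
            attrs[name] = _truncated_normal(
                rng, mean, ref.FA_SEM[name] * sd_factor_meat * cfg.sd_scale, 0.0, 100.0, n)
        for i in range(n):
            row = {"sample_id": sample_ids[i], "breed": breed, "sex": sexes[i]}
            row.update({k: v[i] for k, v in attrs.items()})
            rows.append(row)

        for sex in ref.SEXES:
            idx = np.where(sexes == sex)[0]
            means = ref.CARCASS_MEANS[(breed, sex)]
            draws = {
                name: _truncated_normal(
                    rng, means[name], ref.CARCASS_SEM[name] * sd_factor_carcass * cfg.sd_scale,
                    0.0, np.inf, idx.size)
                for name in ("age", "dg", "lws", "ccw")
            }
            # keep the carcass lighter than the animal
            draws["ccw"] = np.minimum(draws["ccw"], 0.95 * draws["lws"])
            for j, i in enumerate(idx):
                carcass_rows.append({
                    "sample_id": sample_ids[i], "breed": breed, "sex": sex,
                    **{k: draws[k][j] for k in draws},
                })

    refs = pd.DataFrame(rows)
    carcass = pd.DataFrame(carcass_rows).sort_values("sample_id", ignore_index=True)
    return refs, carcass


def _gaussian_band(grid: WavenumberGrid, center: float, width: float) -> np.ndarray:
    nu = grid.values
    return np.exp(-0.5 * ((nu - center) / width) ** 2)


def _pooled_means() -> dict[str, float]:
    names = list(SPECTRAL_CONSTITUENTS)
    out = {}
    for name in names:
        vals = []
        for breed in ref.BREEDS:
            table = ref.MEAT_MEANS[breed] if name in ref.MEAT_MEANS[breed] else ref.FA_MEANS[breed]
            vals.append(table[name])
        out[name] = float(np.mean(vals))
    return out


def clean_spectrum_matrix(refs: pd.DataFrame, cfg: SyntheticConfig) -> np.ndarray:
    """Noise- and scatter-free per-sample spectra from the linear mixing model."""
    if cfg.active_constituents is None:
        names = list(SPECTRAL_CONSTITUENTS)
    else:
        unknown = set(cfg.active_constituents) - set(SPECTRAL_CONSTITUENTS)
        if unknown:
            raise ParameterError(f"no absorption band defined for {sorted(unknown)}")
        names = list(cfg.active_constituents)
    pooled = _pooled_means()
    bands = np.vstack([
        _gaussian_band(cfg.grid, *SPECTRAL_CONSTITUENTS[name]) for name in names
    ])
    # loading matrix: identity plus small cross-loadings on neighbouring bands
    k = len(names)
    loadings = np.eye(k)
    if k > 1:
        for i in range(k):
            loadings[i, (i + 1) % k] += cfg.cross_loading
            loadings[i, (i - 1) % k] += 0.5 * cfg.cross_loading
    conc = refs[names].to_numpy(float) / np.array([pooled[n] for n in names])
    clean = cfg.band_amplitude * conc @ loadings @ bands

    background = cfg.background_amplitude * np.sum([
        a * _gaussian_band(cfg.grid, c, w) for c, w, a in BACKGROUND_BANDS
    ], axis=0)
    clean += background[None, :]

    offset_shape = np.sum([
        _gaussian_band(cfg.grid, c, w) for c, w in BREED_OFFSET_BANDS
    ], axis=0)
    sign = np.where(refs["breed"].to_numpy() == ref.BREEDS[0], 1.0, -1.0)
    clean += (cfg.class_separation * cfg.breed_offset_amplitude / 2.0) * np.outer(
        sign, offset_shape)
    return clean


def generate_spectra(refs: pd.DataFrame, cfg: SyntheticConfig,
                     seed: int | None = None) -> tuple[SpectraSet, dict]:
    """Replicate spectra with multiplicative/additive scatter and noise.

    Returns the spectra set and a ground-truth dict with keys ``clean``
    (per-sample clean matrix), ``gain``/``offset`` (per replicate row) and
    ``constituents`` (the column names that carry signal).
    """
    rng = np.random.default_rng((cfg.seed if seed is None else seed) + 1)
    clean = clean_spectrum_matrix(refs, cfg)
    n_samples = clean.shape[0]
    r = cfg.replicates
    gain = rng.normal(1.0, cfg.scatter_gain_sd, size=n_samples * r)
    offset = rng.normal(0.0, cfg.scatter_offset_sd, size=n_samples * r)
    noise = rng.normal(0.0, cfg.noise_sd, size=(n_samples * r, cfg.grid.n_points))

    matrix = np.repeat(clean, r, axis=0) * gain[:, None] + offset[:, None] + noise
    spectra = SpectraSet(
        grid=cfg.grid,
        matrix=matrix,
        sample_id=np.repeat(refs["sample_id"].to_numpy(), r),
        replicate=np.tile(np.arange(1, r + 1), n_samples),
        breed=np.repeat(refs["breed"].to_numpy(), r),
        sex=np.repeat(refs["sex"].to_numpy(), r),
    )
    truth = {
        "clean": clean,
        "gain": gain,
        "offset": offset,
        "constituents": list(SPECTRAL_CONSTITUENTS),
        "sample_id": refs["sample_id"].to_numpy(),
    }
    return spectra, truth


def generate_dataset(cfg: SyntheticConfig | None = None, seed: int | None = None,
                     ) -> tuple[SpectraSet, pd.DataFrame, pd.DataFrame, dict]:
    """Convenience wrapper: references, carcass table, spectra and ground truth."""
    cfg = cfg or SyntheticConfig()
    refs, carcass = generate_references(cfg, seed=seed)
    spectra, truth = generate_spectra(refs, cfg, seed=seed)
    return spectra, refs, carcass, truth
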