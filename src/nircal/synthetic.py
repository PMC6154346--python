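"""Synthetic reference tables and Vis/NIR leaf spectra.

The generator states a small, transparent world with the statistical and
spectroscopic structure a ground-leaf calibration study assumes:

* concentrations of glucoraphanin (GRA), glucosativin (GLSAT), glucoerucin
  (GER) and total phenolics (TPC) drawn from a multivariate Gaussian with
  configured means/SDs and pairwise correlations, then clipped to the
  configured ranges;
* total glucosinolates (TGLs) = GRA + GLSAT + GER + an independent "other
  glucosinolates" remainder whose variance is set so the configured
  TGLs-GRA correlation holds in the latent model;
* spectra as additive Beer-Lambert mixtures of per-constituent Gaussian
  absorption bands plus fixed matrix components (water, cellulose,
  chlorophyll, carotenoid), corrupted by multiplicative lognormal scatter,
  a random linear baseline and white noise -- the minimal particle-size
  artefact model that SNV + detrend is designed to remove.

All randomness flows from one seed through per-stage spawned streams, so
each stage can be regenerated independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigurationError, ParameterError
from .io import ReferenceTable, SpectraSet, STANDARD_GRID, WavelengthGrid

__all__ = [
    "AnalyteSpec", "BandSpec", "SyntheticConfig", "default_config",
    "draw_concentrations", "simulate_spectra", "make_validation_fixture",
    "GSL_UNIT", "TPC_UNIT",
]

GSL_UNIT = "umol/g dw"
TPC_UNIT = "mg GAE/g dw"

#: baseline slope pivot (nm): the random linear baseline is slope*(lambda-1450)
SLOPE_PIVOT_NM = 1450.0


@dataclass(frozen=True)
class AnalyteSpec:
    """Concentration distribution of one analyte: mean/SD and hard range."""

    name: str
    unit: str
    mean: float
    sd: float
    low: float
    high: float

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ConfigurationError(f"{self.name}: low must be < high")
        if not self.low <= self.mean <= self.high:
            raise ConfigurationError(f"{self.name}: mean outside [low, high]")
        if self.sd <= 0:
            raise ConfigurationError(f"{self.name}: sd must be positive")


@dataclass(frozen=True)
class BandSpec:
    """One Gaussian absorption band: centre (nm), sigma (nm), amplitude
    (absorbance per concentration unit)."""

    center_nm: float
    width_nm: float
    amplitude: float

    def __post_init__(self) -> None:
        if not 400 <= self.center_nm <= 2500:
            raise ConfigurationError("band centre must lie in 400-2500 nm")
        if self.width_nm <= 0:
            raise ConfigurationError("band width must be positive")


@dataclass
class SyntheticConfig:
    """Full description of the synthetic world.

    ``analytes`` are the sampled (non-derived) constituents; ``correlation``
    is their matrix in the same order.  ``sum_analyte`` optionally names a
    derived total = ``sum_components`` + an independent remainder constituent
    (``remainder``) that also carries absorption bands.
    """

    analytes: list[AnalyteSpec]
    correlation: np.ndarray
    bands_per_analyte: dict[str, list[BandSpec]]
    matrix_components: dict[str, list[BandSpec]] = field(default_factory=dict)
    sum_analyte: AnalyteSpec | None = None
    sum_components: tuple[str, ...] = ()
    remainder: AnalyteSpec | None = None
    baseline_offset_sd: float = 0.0
    baseline_slope_sd: float = 0.0
    scatter_sd: float = 0.0
    noise_sd: float = 0.0
    n_samples: int = 156
    seed: int = 0
    grid: WavelengthGrid = STANDARD_GRID

    def __post_init__(self) -> None:
        self.correlation = np.asarray(self.correlation, dtype=float)
        k = len(self.analytes)
        if self.correlation.shape != (k, k):
            raise ConfigurationError("correlation shape must match analyte count")
        if not np.allclose(self.correlation, self.correlation.T):
            raise ConfigurationError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(self.correlation), 1.0):
            raise ConfigurationError("correlation diagonal must be 1")
        if np.any(np.abs(self.correlation) > 1 + 1e-12):
            raise ConfigurationError("correlation entries must lie in [-1, 1]")
        for v in (self.baseline_offset_sd, self.baseline_slope_sd,
                  self.scatter_sd, self.noise_sd):
            if v < 0:
                raise ConfigurationError("noise/scatter parameters must be >= 0")
        if self.n_samples < 1:
            raise ConfigurationError("n_samples must be >= 1")
        if self.sum_analyte is not None:
            names = {a.name for a in self.analytes}
            missing = set(self.sum_components) - names
            if missing:
                raise ConfigurationError(f"sum components not sampled: {missing}")
            if self.remainder is None:
                raise ConfigurationError("sum_analyte requires a remainder spec")

    @property
    def analyte_names(self) -> list[str]:
        names = [a.name for a in self.analytes]
        if self.sum_analyte is not None:
            names = [self.sum_analyte.name] + names
        return names

    def stream(self, stage: int) -> np.random.Generator:
        """Per-stage random stream spawned from the single global seed."""
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(stage,))
        )


def _nearest_psd_correlation(c: np.ndarray, max_shift: float = 0.05) -> np.ndarray:
    """Repair a near-PSD correlation matrix by eigenvalue clipping.

    Raises if the repair would move any entry by more than ``max_shift``
    (such a matrix is treated as a configuration error, not noise).
    """
    vals, vecs = np.linalg.eigh(c)
    if vals.min() >= 0:
        return c
    repaired = (vecs * np.clip(vals, 0.0, None)) @ vecs.T
    d = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(d, d)
    if np.max(np.abs(repaired - c)) > max_shift:
        raise ConfigurationError(
            "correlation matrix is too far from positive semidefinite to repair"
        )
    return repaired


# ---------------------------------------------------------------------------
# default world: rocket-leaf glucosinolates + total phenolics

def default_config(seed: int = 0, n_samples: int = 156, **overrides) -> SyntheticConfig:
    """The rocket-leaf world: published concentration moments, ranges and
    pairwise correlations; band centres from the standard NIR assignments.

    Band amplitudes and widths are free parameters of this package, fixed
    here once at values giving constituent signals of a few hundredths of
    an absorbance unit (realistic for ground-leaf constituents at these
    concentrations).
    """
    gra = AnalyteSpec("GRA", GSL_UNIT, 9.11, 6.41, 0.13, 27.85)
    glsat = AnalyteSpec("GLSAT", GSL_UNIT, 9.66, 3.92, 0.25, 18.61)
    ger = AnalyteSpec("GER", GSL_UNIT, 1.45, 1.60, 0.14, 8.01)
    tpc = AnalyteSpec("TPC", TPC_UNIT, 8.73, 1.99, 2.30, 12.30)
    tgls = AnalyteSpec("TGLs", GSL_UNIT, 23.56, 7.32, 4.86, 44.65)

    # pairwise correlations among the sampled analytes; entries reported as
    # non-significant are set to 0
    names = ["GRA", "GLSAT", "GER", "TPC"]
    corr = np.eye(4)

    def put(a: str, b: str, r: float) -> None:
        i, j = names.index(a), names.index(b)
        corr[i, j] = corr[j, i] = r

    put("GRA", "GLSAT", 0.48)
    put("GRA", "GER", -0.53)
    put("GER", "TPC", 0.33)

    # remainder ("other glucosinolates") variance chosen so that in the
    # latent Gaussian model corr(TGLs, GRA) equals the configured 0.83
    sds = np.array([gra.sd, glsat.sd, ger.sd])
    cov3 = corr[:3, :3] * np.outer(sds, sds)
    var_sum = float(cov3.sum())
    cov_sum_gra = float(cov3[0].sum())
    sd_tgls_needed = cov_sum_gra / (0.83 * gra.sd)
    rem_var = sd_tgls_needed ** 2 - var_sum
    if rem_var <= 0:
        raise ConfigurationError("remainder variance is not attainable")
    rem_mean = tgls.mean - (gra.mean + glsat.mean + ger.mean)
    remainder = AnalyteSpec(
        "other_gsl", GSL_UNIT, rem_mean, float(np.sqrt(rem_var)),
        0.0, tgls.high,
    )

    bands = {
        # glucosinolates: S-H first overtone (1696), amide N-H (2054/2084),
        # methylene C-H combinations (2310/2324); signatures differ so the
        # individual compounds are spectrally identifiable
        "GRA": [BandSpec(2054, 16, 0.010), BandSpec(1696, 12, 0.004),
                BandSpec(2310, 14, 0.003)],
        "GLSAT": [BandSpec(2084, 16, 0.012), BandSpec(1696, 12, 0.005),
                  BandSpec(2324, 14, 0.004)],
        "GER": [BandSpec(1696, 12, 0.020), BandSpec(2310, 14, 0.008),
                BandSpec(2054, 16, 0.004)],
        # phenolics: O-H combination / aromatic C-H overtone regions
        "TPC": [BandSpec(1450, 24, 0.012), BandSpec(1495, 22, 0.008),
                BandSpec(1660, 30, 0.006), BandSpec(2010, 28, 0.008)],
        "other_gsl": [BandSpec(2054, 16, 0.005), BandSpec(2084, 16, 0.005),
                      BandSpec(1696, 12, 0.006), BandSpec(2324, 14, 0.004)],
    }
    matrix = {
        "water": [BandSpec(1432, 30, 0.25), BandSpec(1920, 40, 0.45)],
        "cellulose": [BandSpec(2270, 25, 0.30)],
        "chlorophyll": [BandSpec(670, 18, 0.35)],
        "carotenoid": [BandSpec(470, 22, 0.25)],
    }
    cfg = SyntheticConfig(
        analytes=[gra, glsat, ger, tpc],
        correlation=corr,
        bands_per_analyte=bands,
        matrix_components=matrix,
        sum_analyte=tgls,
        sum_components=("GRA", "GLSAT", "GER"),
        remainder=remainder,
        baseline_offset_sd=0.02,
        baseline_slope_sd=2e-5,
        scatter_sd=0.05,
        noise_sd=0.002,
        n_samples=n_samples,
        seed=seed,
    )
    return replace(cfg, **overrides) if overrides else cfg


# ---------------------------------------------------------------------------
# concentrations

def draw_concentrations(config: SyntheticConfig) -> ReferenceTable:
    """Sample the reference table (derived total first when configured).

    Values are clipped to each analyte's [low, high] range; clipping is a
    small, documented bias on means, SDs and correlations.
    """
    n = config.n_samples
    corr = _nearest_psd_correlation(config.correlation)
    vals, vecs = np.linalg.eigh(corr)
    root = vecs * np.sqrt(np.clip(vals, 0.0, None))
    rng = config.stream(0)
    z = rng.standard_normal((n, len(config.analytes))) @ root.T
    cols = {}
    for j, a in enumerate(config.analytes):
        cols[a.name] = np.clip(a.mean + a.sd * z[:, j], a.low, a.high)

    analytes = [(a.name, a.unit) for a in config.analytes]
    if config.sum_analyte is not None:
        rem = config.remainder
        r = config.stream(1).standard_normal(n)
        rem_vals = np.clip(rem.mean + rem.sd * r, rem.low, rem.high)
        total = sum(cols[c] for c in config.sum_components) + rem_vals
        ta = config.sum_analyte
        cols[ta.name] = np.clip(total, ta.low, ta.high)
        analytes = [(ta.name, ta.unit)] + analytes

    ids = [f"S{i + 1:04d}" for i in range(n)]
    values = np.column_stack([cols[name] for name, _ in analytes])
    return ReferenceTable(ids, analytes, values)


# ---------------------------------------------------------------------------
# spectra

def _profile(bands: list[BandSpec], wavelengths: np.ndarray) -> np.ndarray:
    out = np.zeros_like(wavelengths)
    for b in bands:
        out += b.amplitude * np.exp(-((wavelengths - b.center_nm) ** 2)
                                    / (2.0 * b.width_nm ** 2))
    return out


def _component_concentrations(
    refs: ReferenceTable, config: SyntheticConfig
) -> dict[str, np.ndarray]:
    """Spectrally active constituents and their per-sample concentrations."""
    comps = {a.name: refs.column(a.name) for a in config.analytes}
    if config.sum_analyte is not None:
        total = refs.column(config.sum_analyte.name)
        partial = sum(refs.column(c) for c in config.sum_components)
        comps[config.remainder.name] = np.clip(total - partial, 0.0, None)
    return comps


def simulate_spectra(refs: ReferenceTable, config: SyntheticConfig) -> SpectraSet:
    """Additive Beer-Lambert mixing plus scatter/baseline/noise artefacts.

    clean(lam) = sum_constituents c * profile(lam) + matrix terms;
    observed   = exp(scatter_sd * z) * clean + offset
                 + slope * (lam - 1450 nm) + white noise.
    """
    ref_names = set(refs.names)
    cfg_names = set(config.analyte_names)
    if not cfg_names <= ref_names:
        raise ConfigurationError(
            f"reference table lacks configured analytes: {cfg_names - ref_names}"
        )
    comps = _component_concentrations(refs, config)
    for name in comps:
        if not config.bands_per_analyte.get(name):
            raise ConfigurationError(f"analyte {name!r} has no absorption bands")

    wl = config.grid.wavelengths
    n = len(refs.sample_ids)
    clean = np.zeros((n, config.grid.n_points))
    for name, conc in comps.items():
        clean += np.outer(conc, _profile(config.bands_per_analyte[name], wl))
    for bands in config.matrix_components.values():
        clean += _profile(bands, wl)[None, :]

    scatter = np.exp(config.scatter_sd * config.stream(2).standard_normal(n))
    rng_base = config.stream(3)
    offset = config.baseline_offset_sd * rng_base.standard_normal(n)
    slope = config.baseline_slope_sd * rng_base.standard_normal(n)
    noise = config.noise_sd * config.stream(4).standard_normal(clean.shape)
    observed = (scatter[:, None] * clean
                + offset[:, None]
                + np.outer(slope, wl - SLOPE_PIVOT_NM)
                + noise)
    return SpectraSet(list(refs.sample_ids), config.grid, observed)


# ---------------------------------------------------------------------------
# validation fixtures

_FIXTURE_SEED = 851851  # fixed: the fixture is a deterministic base sequence

def make_validation_fixture(
    n: int,
    target_sd: float | None = None,
    target_sep: float = 0.0,
    target_bias: float = 0.0,
    mean: float = 0.0,
    target_range: tuple[float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Reference/predicted pairs with exactly prescribed summary statistics.

    The reference values are an affine rescaling of a fixed base sequence so
    their sample SD equals ``target_sd`` (or their min/max equal
    ``target_range``) to floating precision; residuals have mean
    ``target_bias`` and bias-corrected SEP exactly ``target_sep``.
    """
    if n < 3:
        raise ParameterError("fixture needs n >= 3 (SD/SEP undefined below)")
    if target_sd is None and target_range is None:
        raise ParameterError("give target_sd or target_range")
    if target_sd is not None and target_sd <= 0:
        raise ParameterError("target_sd must be positive")
    if target_sep < 0:
        raise ParameterError("target_sep must be >= 0")
    rng = np.random.default_rng(_FIXTURE_SEED)
    base_y = rng.standard_normal(n)
    base_r = rng.standard_normal(n)
    base_y = (base_y - base_y.mean()) / np.std(base_y, ddof=1)
    base_r = base_r - base_r.mean()
    base_r /= np.std(base_r, ddof=1)

    if target_range is not None:
        low, high = target_range
        if not low < high:
            raise ParameterError("target_range must satisfy low < high")
        y = low + (base_y - base_y.min()) * (high - low) / np.ptp(base_y)
    else:
        y = mean + target_sd * base_y
    e = target_bias + target_sep * base_r
    return y, y + e
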