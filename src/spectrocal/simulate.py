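"""Synthetic diffuse-reflectance spectra with the structure the analysis assumes.

No raw spectra were ever deposited for the published study, so this module
generates reflectance curves that reproduce the *statistical* features the
pipeline has to cope with, driven by the packaged reference concentrations:

* a smooth composition-independent background with broad bands near 1920,
  1720 and 1450 nm (NIR overtone/combination region) and visible bands near
  650 nm (orange petals) and 500 nm (green involucral bracts);
* per-component signal: each of the 14 components contributes a few narrow
  Gaussian bands scaled linearly by its concentration (mg/g);
* replicate-level nuisance structure: a multiplicative scatter factor, a
  random quadratic baseline drift, white additive noise, a sharp
  detector-switch spike near 900 nm, and signal saturation below 270 nm.

With the noise model switched off (:meth:`NoiseModel.noiseless`) the spectrum
matrix is an exact linear function of the concentration matrix, which the
recovery tests exploit.

All randomness derives from one integer seed through
:class:`numpy.random.SeedSequence` spawn keys, so every sample/replicate draws
an independent but fully reproducible stream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .concentrations import ConcentrationTable
from .spectra import SpectraSet, Spectrum

__all__ = [
    "BandSpec",
    "NoiseModel",
    "ComponentLibrary",
    "default_library",
    "generate_sample_spectrum",
    "generate_study",
    "DEFAULT_GRID",
]

#: Full instrument grid: 250-2000 nm at 1 nm steps (1751 points).
DEFAULT_GRID = np.arange(250.0, 2001.0)

#: Background band centers stated for the raw reflectance morphology.
BACKGROUND_CENTERS_NM = (500.0, 650.0, 1450.0, 1720.0, 1920.0)


@dataclass(frozen=True)
class BandSpec:
    """One Gaussian band.

    ``amplitude`` is the signed reflectance contribution at the band center;
    for component bands it is per unit concentration, i.e. (mg/g)^-1 in
    reflectance units (negative amplitudes model absorption dips).
    """

    center_nm: float
    width_nm: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.width_nm <= 0:
            raise ValueError("width_nm must be > 0")

    def profile(self, grid: np.ndarray) -> np.ndarray:
        return self.amplitude * np.exp(
            -((grid - self.center_nm) ** 2) / (2.0 * self.width_nm**2)
        )


@dataclass(frozen=True)
class NoiseModel:
    """Replicate-level nuisance parameters (all amplitudes in reflectance units).

    ``saturation_level`` emulates detector saturation below 270 nm: signal is
    ceiled there and extra noise added. ``inf`` disables it.
    """

    additive_sd: float = 0.2
    baseline_drift_amplitude: float = 2.0
    scatter_slope_sd: float = 0.03
    detector_spike_center_nm: float = 900.0
    detector_spike_amplitude: float = 10.0
    detector_spike_width_nm: float = 3.0
    saturation_level: float = 95.0
    saturation_edge_nm: float = 270.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "additive_sd",
            "baseline_drift_amplitude",
            "scatter_slope_sd",
            "detector_spike_amplitude",
            "detector_spike_width_nm",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def noiseless(cls, seed: int = 0) -> "NoiseModel":
        """All stochastic and artifact terms off (saturation disabled too)."""
        return cls(
            additive_sd=0.0,
            baseline_drift_amplitude=0.0,
            scatter_slope_sd=0.0,
            detector_spike_amplitude=0.0,
            saturation_level=math.inf,
            seed=seed,
        )

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class ComponentLibrary:
    """Background bands plus per-component band lists (keyed by component index)."""

    background: tuple[BandSpec, ...]
    components: dict[int, tuple[BandSpec, ...]]
    baseline_offset: float = 20.0

    def background_curve(self, grid: np.ndarray = DEFAULT_GRID) -> np.ndarray:
        out = np.full(grid.shape, float(self.baseline_offset))
        for band in self.background:
            out += band.profile(grid)
        return out

    def component_curve(self, component: int, grid: np.ndarray = DEFAULT_GRID) -> np.ndarray:
        """Unit-concentration signature of one component."""
        out = np.zeros(grid.shape)
        for band in self.components[component]:
            out += band.profile(grid)
        return out

    def validate_against(self, table: ConcentrationTable) -> None:
        missing = [c for c in table.components if c not in self.components]
        if missing:
            raise ValueError(f"library lacks bands for components {missing}")


# Background amplitudes/widths chosen so each listed center is a clear local
# maximum of the noiseless background despite band overlap.
_BACKGROUND_BANDS = (
    BandSpec(500.0, 40.0, 18.0),
    BandSpec(650.0, 45.0, 25.0),
    BandSpec(1450.0, 70.0, 30.0),
    BandSpec(1720.0, 60.0, 26.0),
    BandSpec(1920.0, 55.0, 34.0),
)


def default_library(
    seed: int = 0, components: tuple[int, ...] = tuple(range(1, 15))
) -> ComponentLibrary:
    """Reproducible default band library.

    Each component receives 2-4 pseudo-random narrow absorption bands
    (centers in 300-1980 nm, sigma 10-30 nm, amplitude -4..-1 per mg/g);
    the draw is a pure function of ``seed``.
    """
    comp_bands: dict[int, tuple[BandSpec, ...]] = {}
    for j in components:
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(j,)))
        n_bands = int(rng.integers(2, 5))
        bands = []
        for _ in range(n_bands):
            center = float(rng.uniform(300.0, 1980.0))
            width = float(rng.uniform(10.0, 30.0))
            amplitude = -float(rng.uniform(1.0, 4.0))
            bands.append(BandSpec(center, width, amplitude))
        comp_bands[int(j)] = tuple(bands)
    return ComponentLibrary(background=_BACKGROUND_BANDS, components=comp_bands)


def _replicate_rng(noise: NoiseModel, sample_index: int, replicate_id: int):
    return np.random.default_rng(
        np.random.SeedSequence(noise.seed, spawn_key=(1000 + sample_index, replicate_id))
    )


def generate_sample_spectrum(
    lib: ComponentLibrary,
    table: ConcentrationTable,
    sample_id: str,
    noise: NoiseModel,
    replicate_id: int = 1,
    grid: np.ndarray = DEFAULT_GRID,
) -> Spectrum:
    """One replicate's simulated reflectance curve for one sample.

    The deterministic part is ``background + sum_j c_j * signature_j`` with
    missing concentrations contributing zero; the stochastic part multiplies
    by ``(1 + scatter)`` and adds baseline drift, white noise and the
    detector-switch spike, then applies saturation below the UV edge.
    """
    if sample_id not in table.samples:
        raise KeyError(f"unknown sample_id {sample_id!r}")
    lib.validate_against(table)
    sample_index = table.samples.index(sample_id)
    rng = _replicate_rng(noise, sample_index, replicate_id)

    signal = lib.background_curve(grid).copy()
    for j in table.components:
        c = table.concentration(j, sample_id)
        if np.isnan(c) or c == 0.0:
            continue
        signal += c * lib.component_curve(j, grid)

    scatter = rng.normal(0.0, noise.scatter_slope_sd) if noise.scatter_slope_sd else 0.0
    values = signal * (1.0 + scatter)

    if noise.baseline_drift_amplitude:
        u = (grid - grid.mean()) / (grid[-1] - grid[0])
        a0, a1, a2 = rng.normal(0.0, noise.baseline_drift_amplitude, size=3)
        values = values + a0 + a1 * u + a2 * u**2

    if noise.detector_spike_amplitude:
        values = values + noise.detector_spike_amplitude * np.exp(
            -((grid - noise.detector_spike_center_nm) ** 2)
            / (2.0 * noise.detector_spike_width_nm**2)
        )

    if noise.additive_sd:
        values = values + rng.normal(0.0, noise.additive_sd, size=grid.size)

    if np.isfinite(noise.saturation_level):
        uv = grid < noise.saturation_edge_nm
        values = values.copy()
        values[uv] = np.minimum(values[uv], noise.saturation_level)
        if noise.additive_sd:
            values[uv] += rng.normal(0.0, 5.0 * noise.additive_sd, size=int(uv.sum()))

    return Spectrum(grid, values, sample_id=sample_id, replicate_id=replicate_id)


def generate_study(
    lib: ComponentLibrary,
    table: ConcentrationTable,
    noise: NoiseModel,
    n_replicates: int = 3,
    grid: np.ndarray = DEFAULT_GRID,
) -> SpectraSet:
    """Full simulated measurement campaign: ``n_replicates`` spectra per sample.

    Replicate-level noise is independent across replicates and samples; the
    whole set is a pure function of ``noise.seed``.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    spectra = []
    for sid in table.samples:
        for rep in range(1, n_replicates + 1):
            spectra.append(
                generate_sample_spectrum(lib, table, sid, noise, replicate_id=rep, grid=grid)
            )
    return SpectraSet(tuple(spectra))
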