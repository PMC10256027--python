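"""Synthetic season-long grape-must NIR datasets.

The study's field data (four *Vitis vinifera* varieties sampled weekly
through ripening, three spectra per sample at 10/14/18 degC, water-blank
referenced at 20 degC) are available only on request, so this module
generates datasets with the same statistical structure:

* per-variety concentration ranges for fructose, glucose, malic acid and
  tartaric acid matching the published per-variety value ranges;
* ripening trajectories — sugars rise (logistic), malic acid falls
  (exponential-style decay, it is metabolized), tartaric acid falls more
  gently (it is diluted by berry growth);
* Beer--Lambert mixture absorbance from Gaussian absorption bands, acids
  concentrated in the 1100--1160 nm window and sugars in 1300--1350 nm;
* a water background whose temperature dependence (band shift plus
  amplitude change relative to the 20 degC reference) is what the
  replicate temperatures probe;
* a must-matrix background (residual water mismatch and a solute-
  proportional turbidity slope) standing for the imperfect water-blank
  referencing the instrument exhibits in the field;
* per-spectrum multiplicative gain / additive offset jitter (what SNV
  exists to remove) and additive detector noise anchored to the sensor's
  15,000:1 signal-to-noise ratio.

Everything is driven by a :class:`SimulationConfig`; generation is
bit-for-bit reproducible from (config, seed).
"""
from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .io import ANALYTES
from .spectra import SpectraCollection, SpectraError, Spectrum

__all__ = [
    "Band",
    "AnalyteBandSet",
    "VarietyProfile",
    "SimulationConfig",
    "SimulatedDataset",
    "SUGARS",
    "ACID_WINDOW",
    "SUGAR_WINDOW",
    "TABLE1_RANGES",
    "TABLE1_N_SAMPLES",
    "default_band_sets",
    "default_varieties",
    "default_config",
    "ripening_trajectory",
    "pure_component_absorbance",
    "simulate_transmission",
    "generate_dataset",
    "calibration_series",
]

logger = logging.getLogger(__name__)

SUGARS = ("fructose", "glucose")
ACIDS = ("malic_acid", "tartaric_acid")

#: Published wavelength windows attributable to acids and sugars (nm).
ACID_WINDOW = (1100.0, 1160.0)
SUGAR_WINDOW = (1300.0, 1350.0)

#: Per-variety concentration ranges (g/L) of the four analytes in the
#: modeling dataset, and sample counts, as published for the 2021 season.
TABLE1_RANGES: dict[str, dict[str, tuple[float, float]]] = {
    "Chardonnay": {
        "fructose": (27.63, 112.19),
        "glucose": (37.12, 111.70),
        "malic_acid": (4.89, 24.38),
        "tartaric_acid": (5.32, 9.30),
    },
    "Riesling": {
        "fructose": (28.49, 103.68),
        "glucose": (32.37, 101.87),
        "malic_acid": (6.34, 21.44),
        "tartaric_acid": (6.76, 12.49),
    },
    "Dornfelder": {
        "fructose": (59.02, 104.79),
        "glucose": (66.93, 104.82),
        "malic_acid": (4.54, 9.90),
        "tartaric_acid": (5.22, 6.65),
    },
    "Pinot Noir": {
        "fructose": (39.59, 105.64),
        "glucose": (47.09, 109.32),
        "malic_acid": (6.73, 23.00),
        "tartaric_acid": (5.06, 8.55),
    },
}
TABLE1_N_SAMPLES = {"Chardonnay": 26, "Riesling": 22, "Dornfelder": 23, "Pinot Noir": 18}


@dataclass(frozen=True)
class Band:
    """One Gaussian absorption band: center (nm), sd width (nm),
    absorptivity in absorbance units per (g/L) per mm path at the peak."""

    center_nm: float
    width_nm: float
    absorptivity: float


@dataclass(frozen=True)
class AnalyteBandSet:
    """Absorption bands of one analyte on the 1100--1350 nm axis."""

    analyte: str
    bands: tuple[Band, ...]

    def __post_init__(self) -> None:
        if len(self.bands) < 1:
            raise SpectraError(f"{self.analyte}: needs at least one band")
        for b in self.bands:
            if not 1100.0 <= b.center_nm <= 1350.0:
                raise SpectraError(
                    f"{self.analyte}: band center {b.center_nm} nm outside [1100, 1350]"
                )
            if b.absorptivity <= 0 or b.width_nm <= 0:
                raise SpectraError(
                    f"{self.analyte}: band width and absorptivity must be positive"
                )

    def window_mass_fraction(self, window: tuple[float, float]) -> float:
        """Fraction of total band mass (absorptivity x width) inside a window."""
        total = sum(b.absorptivity * b.width_nm for b in self.bands)
        inside = sum(
            b.absorptivity * b.width_nm
            for b in self.bands
            if window[0] <= b.center_nm <= window[1]
        )
        return inside / total


@dataclass(frozen=True)
class VarietyProfile:
    """Concentration ranges and sampling layout for one variety.

    ``n_samples`` is the total number of must samples for the variety
    across the season; samples are spread over ``n_time_points`` weekly
    time points (the published counts, 18--26 per variety over the last 6
    sampling weeks, are not multiples of the time-point count).
    """

    variety: str
    ranges: Mapping[str, tuple[float, float]]
    n_samples: int
    n_time_points: int = 6

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise SpectraError(f"{self.variety}: n_samples must be >= 1")
        if self.n_time_points < 2:
            raise SpectraError(f"{self.variety}: need >= 2 time points")
        for analyte, (lo, hi) in self.ranges.items():
            if not lo < hi:
                raise SpectraError(
                    f"{self.variety}/{analyte}: invalid range [{lo}, {hi}] (min >= max)"
                )


def default_band_sets() -> dict[str, AnalyteBandSet]:
    """Default absorption bands: acids in 1100--1160 nm, sugars in
    1300--1350 nm (the attribution supported by the field results; the
    assignment is one config edit to swap).

    Absorptivities put full-range analyte contributions at 0.01--0.05 AU
    over the 5 mm path — small against the must-matrix background, as in
    dilute aqueous NIR practice.
    """
    return {
        "fructose": AnalyteBandSet("fructose", (
            Band(1308.0, 10.0, 1.0e-4), Band(1338.0, 16.0, 0.6e-4))),
        "glucose": AnalyteBandSet("glucose", (
            Band(1322.0, 12.0, 0.9e-4), Band(1348.0, 10.0, 0.8e-4))),
        "malic_acid": AnalyteBandSet("malic_acid", (
            Band(1112.0, 10.0, 3.5e-4), Band(1148.0, 16.0, 2.0e-4))),
        "tartaric_acid": AnalyteBandSet("tartaric_acid", (
            Band(1130.0, 9.0, 4.0e-4), Band(1104.0, 12.0, 2.5e-4))),
    }


def default_varieties() -> tuple[VarietyProfile, ...]:
    return tuple(
        VarietyProfile(v, TABLE1_RANGES[v], TABLE1_N_SAMPLES[v])
        for v in ("Chardonnay", "Riesling", "Dornfelder", "Pinot Noir")
    )


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults are the study conditions."""

    seed: int = 0
    wavelength_start_nm: float = 1100.0
    wavelength_stop_nm: float = 1350.0
    wavelength_step_nm: float = 2.0
    path_length_mm: float = 5.0
    temperatures_c: tuple[float, ...] = (10.0, 14.0, 18.0)
    reference_temperature_c: float = 20.0
    snr: float = 15000.0
    noise_scale: float | None = None       # absorbance sd; None -> water peak / snr
    temperature_shift_nm_per_c: float = 0.15
    temperature_amplitude_per_c: float = 0.0015
    water_amplitude: float = 0.9
    background_residual_mean: float = 0.35  # must-matrix vs water-blank mismatch
    background_residual_sd: float = 0.001   # per-spectrum referencing drift
    turbidity_per_g_l: float = 2.0e-4      # broad scatter slope per g/L total solutes
    scatter_gain_sd: float = 0.01
    scatter_offset_sd: float = 0.003
    concentration_jitter_frac: float = 0.07
    sugar_logistic_steepness: float = 6.0
    malic_decay_rate: float = 2.0
    secondary_disagreement_sd: Mapping[str, float] = field(
        default_factory=lambda: {
            "fructose": 3.4, "glucose": 4.8, "malic_acid": 1.25, "tartaric_acid": 0.9,
        }
    )
    varieties: tuple[VarietyProfile, ...] = field(default_factory=default_varieties)
    band_sets: Mapping[str, AnalyteBandSet] = field(default_factory=default_band_sets)

    def __post_init__(self) -> None:
        if self.wavelength_step_nm <= 0:
            raise SpectraError("wavelength step must be positive")
        if (self.wavelength_start_nm < 1100.0 - 1e-9
                or self.wavelength_stop_nm > 1350.0 + 1e-9):
            raise SpectraError("wavelength grid must lie within [1100, 1350] nm")
        if self.grid.size < 25:
            raise SpectraError(
                f"grid has {self.grid.size} points; need >= 25 so the "
                "Savitzky-Golay window leaves usable spectra"
            )
        if self.path_length_mm <= 0:
            raise SpectraError("path length must be positive")

    @property
    def grid(self) -> np.ndarray:
        """Wavelength grid in nm, endpoints inclusive."""
        return np.arange(
            self.wavelength_start_nm,
            self.wavelength_stop_nm + self.wavelength_step_nm / 2,
            self.wavelength_step_nm,
        )

    @property
    def noise_sd(self) -> float:
        """Additive absorbance noise sd: explicit, or water peak / SNR."""
        if self.noise_scale is not None:
            return float(self.noise_scale)
        peak = float(np.max(self.water_background(self.reference_temperature_c)))
        return peak / self.snr

    def water_background(self, temperature_c: float) -> np.ndarray:
        """Water absorbance background at a sample temperature.

        Two Gaussian lobes: the 1190 nm combination band and the shoulder
        of the 1450 nm first overtone.  Temperature relative to the 20 degC
        reference shifts the band centers (nm/degC) and scales the
        amplitude — the hydrogen-bonding effect the protocol controls for.
        """
        dt = temperature_c - self.reference_temperature_c
        shift = self.temperature_shift_nm_per_c * dt
        amp = self.water_amplitude * (1.0 + self.temperature_amplitude_per_c * dt)
        lam = self.grid - shift
        return amp * (
            np.exp(-0.5 * ((lam - 1190.0) / 45.0) ** 2)
            + 1.6 * np.exp(-0.5 * ((lam - 1412.0) / 85.0) ** 2)
        )

    def noise_free(self) -> "SimulationConfig":
        """Copy with every stochastic / background term switched off.

        In this configuration a zero-concentration sample at the reference
        temperature is exactly the water blank: flat zero absorbance.
        """
        return replace(
            self,
            noise_scale=0.0,
            scatter_gain_sd=0.0,
            scatter_offset_sd=0.0,
            background_residual_mean=0.0,
            background_residual_sd=0.0,
            concentration_jitter_frac=0.0,
        )

    # -- (de)serialization --------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["varieties"] = [
            {"variety": v.variety, "ranges": {k: list(r) for k, r in v.ranges.items()},
             "n_samples": v.n_samples, "n_time_points": v.n_time_points}
            for v in self.varieties
        ]
        d["band_sets"] = {
            name: [[b.center_nm, b.width_nm, b.absorptivity] for b in bs.bands]
            for name, bs in self.band_sets.items()
        }
        d["secondary_disagreement_sd"] = dict(self.secondary_disagreement_sd)
        d["temperatures_c"] = list(self.temperatures_c)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        if "varieties" in d:
            d["varieties"] = tuple(
                VarietyProfile(
                    v["variety"],
                    {k: tuple(r) for k, r in v["ranges"].items()},
                    v["n_samples"],
                    v.get("n_time_points", 6),
                )
                for v in d["varieties"]
            )
        if "band_sets" in d:
            d["band_sets"] = {
                name: AnalyteBandSet(name, tuple(Band(*b) for b in bands))
                for name, bands in d["band_sets"].items()
            }
        if "temperatures_c" in d:
            d["temperatures_c"] = tuple(d["temperatures_c"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_config(seed: int = 0) -> SimulationConfig:
    """The study-condition dataset configuration under a given seed."""
    return SimulationConfig(seed=seed)


@dataclass
class SimulatedDataset:
    """Spectra plus matching reference tables from one generator run."""

    spectra: SpectraCollection
    primary_reference: pd.DataFrame    # true concentrations, method_role "primary"
    secondary_reference: pd.DataFrame  # perturbed twin, method_role "secondary"
    config: SimulationConfig

    def validate(self) -> None:
        n_temps = len(self.config.temperatures_c)
        counts = pd.Series([s.sample_id for s in self.spectra]).value_counts()
        if not (counts == n_temps).all():
            raise SpectraError("every sample must have exactly one spectrum per temperature")
        ref_ids = set(self.primary_reference["sample_id"])
        spec_ids = set(counts.index)
        if ref_ids != spec_ids:
            raise SpectraError("sample ids of spectra and primary reference differ")
        if self.primary_reference["sample_id"].duplicated().any():
            raise SpectraError("primary reference has duplicated sample ids")


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def ripening_trajectory(
    profile: VarietyProfile,
    seed=None,
    *,
    jitter_frac: float = 0.07,
    sugar_steepness: float = 6.0,
    malic_decay_rate: float = 2.0,
) -> pd.DataFrame:
    """Per-sample concentrations across the ripening season.

    Samples are spread over the profile's time points; at time fraction
    tau in [0, 1] the trajectory means are

    * sugars: min + (max-min) * logistic(tau) rescaled so the endpoints
      hit the range exactly (rapid post-veraison accumulation),
    * malic acid: max - (max-min) * (1-exp(-r tau))/(1-exp(-r))
      (metabolic decay, fastest early),
    * tartaric acid: max - (max-min) * tau (slow dilution by berry
      growth; its relative span is smaller than malic acid's).

    Per-sample Gaussian jitter (sd = ``jitter_frac`` x range, independent
    per analyte) is added and clipped to the range, so all values stay
    inside the profile's [min, max] and the analytes are not perfectly
    collinear.  With ``jitter_frac=0`` the first/last time points sit
    exactly on the range endpoints.
    """
    rng = _rng(seed)
    n, T = profile.n_samples, profile.n_time_points
    time_points = np.array([(i * T) // n for i in range(n)])
    tau = time_points / (T - 1)

    k = sugar_steepness
    sig = lambda z: 1.0 / (1.0 + np.exp(-z))
    g = (sig(k * (tau - 0.5)) - sig(-k / 2)) / (sig(k / 2) - sig(-k / 2))
    r = malic_decay_rate
    h = (1.0 - np.exp(-r * tau)) / (1.0 - np.exp(-r))

    out = {"sample_index": np.arange(n), "time_point": time_points}
    for analyte, (lo, hi) in profile.ranges.items():
        span = hi - lo
        if analyte in SUGARS:
            mean = lo + span * g
        elif analyte == "malic_acid":
            mean = hi - span * h
        elif analyte == "tartaric_acid":
            mean = hi - span * tau
        else:
            raise SpectraError(f"unknown analyte {analyte!r} in profile {profile.variety!r}")
        vals = mean + rng.normal(0.0, jitter_frac * span, size=n)
        out[analyte] = np.clip(vals, lo, hi)
    return pd.DataFrame(out)


def pure_component_absorbance(bands: AnalyteBandSet, grid: np.ndarray) -> np.ndarray:
    """Absorbance per (g/L) per mm path of one analyte on a grid."""
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise SpectraError("empty wavelength grid")
    lo, hi = grid[0], grid[-1]
    eps = np.zeros_like(grid)
    for b in bands.bands:
        if not lo - 3 * b.width_nm <= b.center_nm <= hi + 3 * b.width_nm:
            logger.info(
                "%s band at %.1f nm lies outside grid support [%.1f, %.1f]",
                bands.analyte, b.center_nm, lo, hi,
            )
        eps += b.absorptivity * np.exp(-0.5 * ((grid - b.center_nm) / b.width_nm) ** 2)
    return eps


def simulate_transmission(
    concentrations: Mapping[str, float],
    temperature_c: float,
    config: SimulationConfig,
    seed=None,
    *,
    sample_id: str = "synthetic",
    variety: str = "synthetic",
    date: str | None = None,
) -> Spectrum:
    """Simulate one referenced (absorbance-state) must spectrum.

    A(lambda) = sum_a c_a eps_a(lambda) L                    Beer--Lambert mixture
              + turbidity * C_total * slope(lambda)          scatter baseline
              + eta * water(lambda, T_ref)                   referencing residual
              + water(lambda, T) - water(lambda, T_ref)      temperature effect
    then per-spectrum gain/offset jitter and additive detector noise.
    Deterministic given (config, seed).
    """
    rng = _rng(seed)
    grid = config.grid
    for analyte, c in concentrations.items():
        if c < 0:
            raise SpectraError(f"negative concentration for {analyte}: {c}")
        if analyte not in config.band_sets:
            raise SpectraError(f"no absorption bands configured for {analyte!r}")

    absorbance = np.zeros_like(grid)
    for analyte, c in concentrations.items():
        absorbance += c * config.path_length_mm * pure_component_absorbance(
            config.band_sets[analyte], grid
        )

    c_total = float(sum(concentrations.values()))
    slope = (config.wavelength_stop_nm - grid) / (
        config.wavelength_stop_nm - config.wavelength_start_nm
    )
    absorbance = absorbance + config.turbidity_per_g_l * c_total * slope

    eta = config.background_residual_mean
    if config.background_residual_sd > 0:
        eta = rng.normal(eta, config.background_residual_sd)
    ref_bg = config.water_background(config.reference_temperature_c)
    absorbance = absorbance + eta * ref_bg
    absorbance = absorbance + config.water_background(temperature_c) - ref_bg

    gain = 1.0
    offset = 0.0
    if config.scatter_gain_sd > 0:
        gain = rng.normal(1.0, config.scatter_gain_sd)
    if config.scatter_offset_sd > 0:
        offset = rng.normal(0.0, config.scatter_offset_sd)
    absorbance = gain * absorbance + offset
    if config.noise_sd > 0:
        absorbance = absorbance + rng.normal(0.0, config.noise_sd, size=grid.size)

    return Spectrum(
        sample_id=sample_id,
        variety=variety,
        temperature_c=float(temperature_c),
        wavelengths_nm=grid,
        values=absorbance,
        state="absorbance",
        date=date,
    )


def _timepoint_date(time_point: int) -> str:
    """Weekly sampling dates over the late 2021 season."""
    base = np.datetime64("2021-08-27") + np.timedelta64(7 * int(time_point), "D")
    return str(base)


def generate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate the full multi-variety dataset the pipeline consumes.

    For every variety profile: draw the ripening concentration table, then
    simulate one spectrum per sample per configured temperature.  The
    primary reference table carries the true concentrations; the secondary
    table adds independent Gaussian disagreement per analyte (defaults
    sized to the published HPLC-vs-FTIR residuals: a few g/L for sugars,
    about 1 g/L for acids).
    """
    rng = np.random.default_rng(config.seed)
    spectra: list[Spectrum] = []
    primary_rows = []
    secondary_rows = []

    for profile in config.varieties:
        traj = ripening_trajectory(
            profile,
            rng,
            jitter_frac=config.concentration_jitter_frac,
            sugar_steepness=config.sugar_logistic_steepness,
            malic_decay_rate=config.malic_decay_rate,
        )
        tag = profile.variety.replace(" ", "")
        for row in traj.itertuples(index=False):
            sid = f"{tag}-{row.sample_index:03d}"
            date = _timepoint_date(row.time_point)
            conc = {a: float(getattr(row, a)) for a in profile.ranges}
            primary_rows.append({"sample_id": sid, "method_role": "primary", **{
                f"{a}_g_l": conc[a] for a in ANALYTES}})
            secondary_rows.append({"sample_id": sid, "method_role": "secondary", **{
                f"{a}_g_l": conc[a] + rng.normal(
                    0.0, config.secondary_disagreement_sd.get(a, 0.0))
                for a in ANALYTES}})
            for temp in config.temperatures_c:
                spectra.append(
                    simulate_transmission(
                        conc, temp, config, rng,
                        sample_id=sid, variety=profile.variety, date=date,
                    )
                )

    dataset = SimulatedDataset(
        spectra=SpectraCollection(spectra),
        primary_reference=pd.DataFrame(primary_rows),
        secondary_reference=pd.DataFrame(secondary_rows),
        config=config,
    )
    dataset.validate()
    return dataset


def calibration_series(
    analyte: str,
    seed=None,
    *,
    n_levels: int = 4,
    replicates: int = 3,
    response_per_g_l: float = 100.0,
    residual_sd_g_l: float | None = None,
) -> pd.DataFrame:
    """Synthetic instrument calibration series for LOQ estimation.

    Mirrors the reference method's four-stage dilution standards: 1.5--90
    g/L for the sugars and 0.15--9 g/L for the acids, geometrically
    spaced, with a linear detector response plus Gaussian residuals.  The
    default residual sd (0.35 g/L sugars, 0.07 g/L acids, in concentration
    units) represents routine chromatographic repeatability.
    """
    rng = _rng(seed)
    if analyte in SUGARS:
        lo, hi = 1.5, 90.0
        resid = 0.35 if residual_sd_g_l is None else residual_sd_g_l
    elif analyte in ACIDS:
        lo, hi = 0.15, 9.0
        resid = 0.07 if residual_sd_g_l is None else residual_sd_g_l
    else:
        raise SpectraError(f"unknown analyte {analyte!r}")
    levels = np.geomspace(lo, hi, n_levels)
    conc = np.repeat(levels, replicates)
    response = response_per_g_l * (conc + rng.normal(0.0, resid, size=conc.size))
    return pd.DataFrame({"analyte": analyte, "concentration_g_l": conc,
                         "response": response})
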