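"""Synthetic inputs with known ground truth.

Every input the pipeline consumes can be generated here so the whole
chain — bioclim derivation, palaeo overlay, habitat model, fossil
validation, stability mapping and variance-component estimation — is
testable end to end without external downloads:

* spatially autocorrelated monthly climate-normal grids (a smooth
  latitudinal temperature gradient plus an elevation-like correlated
  noise field),
* coarse palaeo anomaly grids per period,
* presence/absence occurrences drawn from a known niche-response
  function,
* fossil-type records with false-positive/false-negative taphonomic
  noise on top of thresholded true occupancy,
* common-garden phenotypes generated exactly under the trial's
  random-effects decomposition with region-specific variance components.

Every generator is a pure function of its configuration and seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import gaussian_filter

from .bioclim import BioclimGrid
from .climate import ClimateNormalGrid
from .paleo import AnomalyGrid
from .raster import RasterGrid
from .trials import TrialDesign, expand_design

__all__ = [
    "SyntheticConfig", "NicheFunction", "ThresholdNiche",
    "make_climate_grid", "make_anomaly_grid", "niche_surface",
    "sample_occurrences", "make_fossil_records", "simulate_trial",
    "load_config", "PERIOD_ANOMALIES",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic baseline climate.

    The grid spans ``grid_rows × grid_cols`` cells of ``cell_size``
    degrees, row 0 at the northern edge.  Monthly mean temperature is
    ``mean_temp + lapse·row`` plus a seasonal cosine of amplitude
    ``cycle_amplitude`` (July warmest) plus one static elevation-like
    noise field (white noise smoothed over ``noise_correlation`` cells,
    rescaled to ``noise_amplitude`` °C).  tmin/tmax sit ``diurnal_range``
    apart around the mean.  Precipitation follows the monthly profile
    with a multiplicative log-normal spatial field of coefficient of
    variation ``precip_noise_cv``.
    """

    grid_rows: int = 40
    grid_cols: int = 50
    cell_size: float = 0.5
    origin_lon: float = -120.0
    origin_lat: float = 60.0
    mean_temp: float = -4.0
    lapse: float = 0.35
    noise_amplitude: float = 1.5
    cycle_amplitude: float = 16.0
    diurnal_range: float = 8.0
    precip_profile: tuple = (30, 25, 30, 35, 50, 70, 80, 70, 50, 40, 35, 30)
    precip_noise_cv: float = 0.2
    noise_correlation: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_rows < 1 or self.grid_cols < 1:
            raise ValueError("grid dimensions must be >= 1")
        profile = np.asarray(self.precip_profile, dtype=float)
        if profile.shape != (12,) or np.any(profile < 0):
            raise ValueError("precip_profile must be 12 non-negative values")
        if self.noise_amplitude < 0 or self.precip_noise_cv < 0:
            raise ValueError("noise amplitudes must be non-negative")
        object.__setattr__(self, "precip_profile", tuple(profile))


def load_config(path) -> SyntheticConfig:
    """Read a :class:`SyntheticConfig` from a YAML mapping (seed required)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "seed" not in raw:
        raise ValueError("config must set an explicit seed")
    return SyntheticConfig(**raw)


def _noise_field(rng, shape, correlation: float, std: float) -> np.ndarray:
    """Seeded correlated noise: smoothed white noise rescaled to std."""
    white = rng.standard_normal(shape)
    if correlation > 0:
        smooth = gaussian_filter(white, sigma=correlation, mode="reflect")
    else:
        smooth = white
    s = smooth.std()
    if s == 0 or std == 0:
        return np.zeros(shape)
    return smooth * (std / s)


def make_climate_grid(config: SyntheticConfig) -> ClimateNormalGrid:
    """Generate the 36 monthly baseline normals (12 tmin, 12 tmax, 12 precip)."""
    rng = np.random.default_rng(config.seed)
    nrow, ncol = config.grid_rows, config.grid_cols
    rows = np.arange(nrow)[:, None] * np.ones((1, ncol))
    elev_noise = _noise_field(
        rng, (nrow, ncol), config.noise_correlation, config.noise_amplitude
    )
    months = np.arange(12)
    season = config.cycle_amplitude * np.cos(2 * np.pi * (months - 6) / 12.0)
    tmean = (
        config.mean_temp
        + config.lapse * rows[None, :, :]
        + season[:, None, None]
        + elev_noise[None, :, :]
    )
    half = config.diurnal_range / 2.0
    tmin = tmean - half
    tmax = tmean + half

    pnoise = _noise_field(
        rng, (nrow, ncol), config.noise_correlation, 1.0
    )
    pfield = np.exp(config.precip_noise_cv * pnoise)
    profile = np.asarray(config.precip_profile, dtype=float)
    precip = profile[:, None, None] * pfield[None, :, :]

    return ClimateNormalGrid(
        tmin, tmax, precip,
        x0=config.origin_lon, y0=config.origin_lat,
        cell_size=config.cell_size,
    )


#: Default period anomalies: mean temperature shift (°C, additive) and
#: mean precipitation factor (multiplicative).
PERIOD_ANOMALIES = {
    "6k": (-1.0, 0.95),
    "11k": (-3.0, 0.90),
    "14k": (-5.0, 0.80),
    "21k": (-8.0, 0.70),
    "baseline": (0.0, 1.0),
}


def make_anomaly_grid(config: SyntheticConfig, period: str,
                      coarsening_factor: int = 4,
                      mean_dt: float | None = None,
                      mean_pfactor: float | None = None,
                      dt_sd: float = 1.0,
                      pfactor_log_sd: float = 0.05) -> AnomalyGrid:
    """Generate a coarse anomaly grid covering the baseline extent.

    Known period tags carry default mean anomalies
    (:data:`PERIOD_ANOMALIES`); user-defined periods must supply
    ``mean_dt`` and ``mean_pfactor``.  Per cell and month, ΔT is
    ``mean_dt`` plus independent N(0, dt_sd²) noise and the
    precipitation factor is ``mean_pfactor · exp(N(0, pfactor_log_sd²))``.
    """
    if coarsening_factor < 1:
        raise ValueError("coarsening_factor must be >= 1")
    if mean_dt is None or mean_pfactor is None:
        if period not in PERIOD_ANOMALIES:
            raise KeyError(
                f"unknown period {period!r}; supply mean_dt and mean_pfactor "
                f"or use one of {sorted(PERIOD_ANOMALIES)}"
            )
        default_dt, default_pf = PERIOD_ANOMALIES[period]
        mean_dt = default_dt if mean_dt is None else mean_dt
        mean_pfactor = default_pf if mean_pfactor is None else mean_pfactor
    rng = np.random.default_rng([config.seed, zlib.crc32(period.encode())])
    nrow = -(-config.grid_rows // coarsening_factor)
    ncol = -(-config.grid_cols // coarsening_factor)
    dt = mean_dt + dt_sd * rng.standard_normal((12, nrow, ncol))
    pf = mean_pfactor * np.exp(
        pfactor_log_sd * rng.standard_normal((12, nrow, ncol))
    )
    return AnomalyGrid(
        period, dt, pf,
        x0=config.origin_lon, y0=config.origin_lat,
        cell_size=config.cell_size * coarsening_factor,
    )


# ----------------------------------------------------------------------
# Niche-response functions


@dataclass(frozen=True)
class NicheFunction:
    """Gaussian niche: the product over variables of bell-shaped
    responses exp(−½((x − optimum)/breadth)²), giving a probability of
    presence in [0, 1] with value 1 at the joint optimum."""

    responses: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.responses:
            raise ValueError("niche needs at least one variable response")
        for var, (_, breadth) in self.responses.items():
            if breadth <= 0:
                raise ValueError(f"breadth for {var!r} must be positive")

    @property
    def variables(self) -> tuple[str, ...]:
        return tuple(self.responses)

    def __call__(self, values: pd.DataFrame) -> np.ndarray:
        prob = np.ones(len(values))
        for var, (opt, breadth) in self.responses.items():
            z = (values[var].to_numpy(dtype=float) - opt) / breadth
            prob *= np.exp(-0.5 * z**2)
        return prob


@dataclass(frozen=True)
class ThresholdNiche:
    """Step niche: presence probability 1 where the variable is at or
    above (or below, if ``above=False``) the threshold, else 0.
    Generates perfectly separable occurrence data."""

    variable: str
    threshold: float
    above: bool = True

    @property
    def variables(self) -> tuple[str, ...]:
        return (self.variable,)

    def __call__(self, values: pd.DataFrame) -> np.ndarray:
        x = values[self.variable].to_numpy(dtype=float)
        hit = x >= self.threshold if self.above else x <= self.threshold
        return hit.astype(float)


def niche_surface(bioclim: BioclimGrid, niche) -> RasterGrid:
    """Evaluate a niche function on a bioclim grid → true probability
    surface (nodata propagates)."""
    variables = niche.variables
    stack = bioclim.stack(variables)
    valid = ~np.isnan(stack).any(axis=0)
    out = np.full(bioclim.template.shape, np.nan)
    if valid.any():
        frame = pd.DataFrame(stack[:, valid].T, columns=list(variables))
        out[valid] = niche(frame)
    return bioclim.template.with_data(out, name="true_prob")


def sample_occurrences(bioclim: BioclimGrid, niche, n: int, seed: int,
                       replace: bool = True) -> pd.DataFrame:
    """Draw presence/absence records from the niche on a bioclim grid.

    Cells are sampled uniformly among non-nodata cells (with replacement
    by default); each record's label is Bernoulli in the niche
    probability of its cell, and the true probability is retained for
    testing.  Returns columns (lon, lat, label, true_prob).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    surface = niche_surface(bioclim, niche)
    valid_rows, valid_cols = np.nonzero(~np.isnan(surface.data))
    n_valid = valid_rows.size
    if n_valid == 0:
        raise ValueError("bioclim grid has no usable (non-nodata) cells")
    if not replace and n > n_valid:
        raise ValueError(
            f"cannot sample {n} cells without replacement from {n_valid}"
        )
    rng = np.random.default_rng(seed)
    pick = rng.choice(n_valid, size=n, replace=replace)
    rows, cols = valid_rows[pick], valid_cols[pick]
    lons, lats = surface.cell_centers()
    prob = surface.data[rows, cols]
    labels = (rng.random(n) < prob).astype(int)
    return pd.DataFrame({
        "lon": lons[cols], "lat": lats[rows],
        "label": labels, "true_prob": prob,
    })


def make_fossil_records(true_prob: RasterGrid, period: str, n: int,
                        occupancy_threshold: float = 0.5,
                        fp_rate: float = 0.0, fn_rate: float = 0.0,
                        seed: int = 0) -> pd.DataFrame:
    """Generate fossil-type records with taphonomic label noise.

    True occupancy of a cell is ``true_prob ≥ occupancy_threshold``.
    The recorded label flips occupancy with probability ``fp_rate``
    (unoccupied recorded as present — e.g. long-distance pollen
    transport) or ``fn_rate`` (occupied recorded as absent — e.g.
    fragile pollen disintegrating).  Columns: lon, lat, period, label,
    record_class, true_occupied.
    """
    if not (0.0 < occupancy_threshold < 1.0):
        raise ValueError("occupancy_threshold must lie in (0, 1)")
    for name, rate in (("fp_rate", fp_rate), ("fn_rate", fn_rate)):
        if not (0.0 <= rate <= 1.0):
            raise ValueError(f"{name} must lie in [0, 1]")
    valid_rows, valid_cols = np.nonzero(~np.isnan(true_prob.data))
    if valid_rows.size == 0:
        raise ValueError("probability surface has no usable cells")
    rng = np.random.default_rng(seed)
    pick = rng.choice(valid_rows.size, size=n, replace=True)
    rows, cols = valid_rows[pick], valid_cols[pick]
    lons, lats = true_prob.cell_centers()
    occupied = true_prob.data[rows, cols] >= occupancy_threshold
    u = rng.random(n)
    flip = np.where(occupied, u < fn_rate, u < fp_rate)
    label = np.where(flip, ~occupied, occupied).astype(int)
    return pd.DataFrame({
        "lon": lons[cols], "lat": lats[rows], "period": period,
        "label": label, "record_class": "synthetic",
        "true_occupied": occupied.astype(int),
    })


# ----------------------------------------------------------------------
# Common-garden phenotypes


def simulate_trial(design: TrialDesign, seed: int) -> pd.DataFrame:
    """Simulate phenotypes under the trial's random-effects model.

    For every trait and region, each observation is the trait mean plus
    independent mean-zero Gaussian effects for provenance, site,
    provenance × site, block within site, provenance × block within
    site, and a residual, at the region's generating variances.
    Single-site traits use only the first site and the reduced model
    (block instead of block-within-site, no site terms).  Returns a
    long-format table (region, provenance, site, block, tree, trait,
    value).
    """
    if not design.traits:
        raise ValueError("design declares no traits")
    rng = np.random.default_rng(seed)
    frames = []
    for trait, spec in design.traits.items():
        skeleton, _ = expand_design(design, single_site=spec.single_site)
        multi = not spec.single_site
        for region in design.regions:
            params = spec.params_by_region[region]
            sub = skeleton[skeleton["region"] == region].copy()
            provs = np.sort(sub["provenance"].unique())
            sites = np.sort(sub["site"].unique())
            blocks = np.sort(sub["block"].unique())
            p_codes = sub["provenance"].map(
                {v: i for i, v in enumerate(provs)}).to_numpy()
            s_codes = sub["site"].map(
                {v: i for i, v in enumerate(sites)}).to_numpy()
            b_codes = sub["block"].map(
                {v: i for i, v in enumerate(blocks)}).to_numpy()
            np_, ns, nb = provs.size, sites.size, blocks.size

            def draw(var: float, size) -> np.ndarray:
                return np.sqrt(var) * rng.standard_normal(size)

            value = params.mean + draw(params.var_resid, len(sub))
            value += draw(params.var_prov, np_)[p_codes]
            if multi:
                value += draw(params.var_site, ns)[s_codes]
                value += draw(params.var_prov_site, (np_, ns))[p_codes, s_codes]
                value += draw(params.var_block, (ns, nb))[s_codes, b_codes]
                value += draw(
                    params.var_prov_block, (np_, ns, nb)
                )[p_codes, s_codes, b_codes]
            else:
                value += draw(params.var_block, nb)[b_codes]
                value += draw(
                    params.var_prov_block, (np_, nb)
                )[p_codes, b_codes]
            sub["trait"] = trait
            sub["value"] = value
            frames.append(sub)
    return pd.concat(frames, ignore_index=True)
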