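"""Synthetic studies with the statistical structure the pipeline assumes.

Communities are assembled by Gaussian-kernel filtering on the impervious
axis: species i has an environmental optimum mu_i in [0, 1] and expected
abundance exp(a_i - beta_f * (mu_i - e_s)^2) at a site with impervious
proportion e_s, thinned to a target mean richness. beta_f = 0 is the
neutral world (no trait-environment coupling), the ground truth for null
calibration; large beta_f produces trait clustering and detectable
trait-environment association.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ecofilter.data_model import (
    UGS_TYPES,
    CommunityMatrix,
    SiteTable,
    TraitTable,
)
from ecofilter.landscape import ClassAggregation, LandCoverRaster

#: study green-space sample sizes (community garden, home garden,
#: public park, green roof) used as default sampling frequencies
DEFAULT_UGS_COUNTS = (13, 67, 42, 14)

TRAIT_SPEC = {
    "body_size": {"kind": "continuous", "weight": 1.0},
    "native_status": {"kind": "nominal", "weight": 1.0},
    "diet_type": {"kind": "nominal", "weight": 1.0},
    "diet_specialization": {"kind": "nominal", "weight": 1.0},
    "trophic_rank": {"kind": "continuous", "weight": 1.0},
    "nesting_material": {"kind": "nominal", "weight": 1.0},
    "n_nesting_materials": {"kind": "continuous", "weight": 1.0},
}

_LEVELS = {
    "native_status": ["native", "non_native"],
    "diet_type": ["pollen", "aphids", "spiders", "caterpillars"],
    "diet_specialization": ["generalist", "intermediate", "specialist"],
    "nesting_material": ["leaf", "mud", "resin", "secretion", "debris"],
}


@dataclass
class SimulationSpec:
    n_sites: int = 192
    n_species: int = 46
    ugs_frequencies: tuple[float, ...] = DEFAULT_UGS_COUNTS
    gradient_correlation: float = -0.9
    filtering_strength: float = 0.0
    trait_optimum_coupling: float = 0.0
    baseline_log_abundance: float = 1.5
    target_mean_richness: float = 6.0
    n_years: int = 3
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_sites < 2 or self.n_species < 2:
            raise ValueError("need at least 2 sites and 2 species")
        if self.filtering_strength < 0:
            raise ValueError("filtering_strength must be >= 0")
        if not -1 < self.gradient_correlation < 1:
            raise ValueError("|gradient correlation| must be < 1")


@dataclass
class SimulatedStudy:
    community: CommunityMatrix
    traits: TraitTable
    sites: SiteTable
    ground_truth: dict = field(default_factory=dict)


def _impervious_from_latent(z: np.ndarray) -> np.ndarray:
    # support [0, 0.97], right-skewed like an urban gradient
    return 0.97 * stats.beta.ppf(stats.norm.cdf(z), 1.3, 1.4)


def _closed_from_latents(z_imp: np.ndarray, z2: np.ndarray,
                         rho: float) -> np.ndarray:
    z = rho * z_imp + np.sqrt(1 - rho**2) * z2
    frac = stats.beta.ppf(stats.norm.cdf(z), 2.0, 2.0)
    imp = _impervious_from_latent(z_imp)
    return frac * (1.0 - imp) * 0.999


def _calibrate_rho(target_r: float, rng: np.random.Generator) -> float:
    """Bisect the copula correlation so corr(impervious, closed) hits target.

    The multiplication by (1 - impervious) adds negative correlation on
    top of the copula's, so the copula rho is solved numerically against
    a fixed latent sample.
    """
    z1 = rng.standard_normal(4000)
    z2 = rng.standard_normal(4000)
    imp = _impervious_from_latent(z1)

    def achieved(rho: float) -> float:
        closed = _closed_from_latents(z1, z2, rho)
        return float(np.corrcoef(imp, closed)[0, 1])

    lo, hi = -0.999, 0.999
    if achieved(hi) < target_r:
        return hi
    if achieved(lo) > target_r:
        return lo
    for _ in range(40):
        mid = (lo + hi) / 2
        if achieved(mid) < target_r:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def simulate_sites(spec: SimulationSpec,
                   rng: np.random.Generator | None = None) -> SiteTable:
    """Collinear land-cover gradients at both buffer scales plus
    green-space types sampled at the study frequencies."""
    rng = np.random.default_rng(spec.seed if rng is None else rng)
    rho = _calibrate_rho(spec.gradient_correlation, rng)
    n = spec.n_sites

    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    data: dict[str, np.ndarray] = {}
    for scale, mix in ((250, 1.0), (500, 0.9)):
        # the 500 m gradient is a noisy version of the 250 m one
        z1s = mix * z1 + np.sqrt(1 - mix**2) * rng.standard_normal(n)
        z2s = mix * z2 + np.sqrt(1 - mix**2) * rng.standard_normal(n)
        imp = _impervious_from_latent(z1s)
        closed = _closed_from_latents(z1s, z2s, rho)
        data[f"impervious_{scale}"] = imp
        data[f"closed_green_{scale}"] = closed
        data[f"open_green_{scale}"] = 1.0 - imp - closed

    freqs = np.asarray(spec.ugs_frequencies, dtype=float)
    freqs = freqs / freqs.sum()
    ugs = rng.choice(UGS_TYPES, size=n, p=freqs)
    df = pd.DataFrame(data, index=[f"site_{i:03d}" for i in range(n)])
    df.insert(0, "ugs_type", ugs)
    df["x"] = rng.uniform(0, 40_000, n)
    df["y"] = rng.uniform(0, 40_000, n)
    return SiteTable(df, (250, 500))


def simulate_traits(spec: SimulationSpec,
                    rng: np.random.Generator | None = None,
                    max_resample: int = 100) -> tuple[TraitTable, np.ndarray]:
    """Mixed trait table plus per-species environmental optima.

    Optima are uniform on [0, 1] when ``trait_optimum_coupling`` is zero
    and correlate with body size otherwise (copula coupling), so size is
    a filterable trait. Nominal traits are resampled until every level is
    represented.
    """
    rng = np.random.default_rng(spec.seed if rng is None else rng)
    m = spec.n_species
    z_size = rng.standard_normal(m)
    body_size = np.exp(np.log(2.0) + 0.4 * z_size)

    cols: dict[str, np.ndarray] = {"body_size": np.round(body_size, 3)}
    for name, levels in _LEVELS.items():
        for _ in range(max_resample):
            draw = rng.choice(levels, size=m)
            if len(set(draw)) == len(levels) or m < len(levels):
                break
        cols[name] = draw
    cols["trophic_rank"] = rng.integers(1, 4, size=m)
    cols["n_nesting_materials"] = rng.integers(1, 5, size=m)

    kappa = spec.trait_optimum_coupling
    eps = rng.standard_normal(m)
    optima = stats.norm.cdf(kappa * z_size + np.sqrt(1 - kappa**2) * eps)

    order = list(TRAIT_SPEC)
    df = pd.DataFrame({k: cols[k] for k in order},
                      index=[f"sp_{i:02d}" for i in range(m)])
    return TraitTable(df, {k: dict(v) for k, v in TRAIT_SPEC.items()}), optima


def simulate_community(
    traits: TraitTable,
    sites: SiteTable,
    beta_f: float,
    rng: np.random.Generator | int | None = None,
    optima: np.ndarray | None = None,
    baseline_log_abundance: float = 1.5,
    target_mean_richness: float = 6.0,
    n_years: int = 3,
) -> CommunityMatrix:
    """Poisson abundances filtered on the impervious axis, then thinned.

    Expected abundance of species i at site s is
    exp(a_i - beta_f * (mu_i - e_s)^2) with e_s the site's impervious
    proportion at 250 m. Independent Bernoulli retention per cell brings
    the mean per-site richness to the target (expected richness is linear
    in the retention rate, so the rate is the simple ratio, capped at 1).
    """
    if beta_f < 0:
        raise ValueError("beta_f must be >= 0")
    rng = np.random.default_rng(rng)
    m = len(traits.species_ids)
    n = len(sites.site_ids)
    if optima is None:
        optima = rng.uniform(0, 1, m)
    e_s = sites.covariates(250)["impervious"].to_numpy()
    a_i = baseline_log_abundance + 0.5 * rng.standard_normal(m)
    lam = np.exp(a_i[None, :] - beta_f * (optima[None, :] - e_s[:, None]) ** 2)
    counts = rng.poisson(lam)

    richness = (counts > 0).sum(axis=1).mean()
    if richness > 0:
        rate = min(1.0, target_mean_richness / richness)
        keep = rng.random(counts.shape) < rate
        counts = counts * keep

    years = frozenset(range(2011, 2011 + n_years))
    return CommunityMatrix(
        list(sites.site_ids), list(traits.species_ids), counts,
        {s: years for s in sites.site_ids},
    )


def simulate_study(spec: SimulationSpec,
                   rng: np.random.Generator | int | None = None) -> SimulatedStudy:
    """One complete synthetic study with recorded ground truth."""
    rng = np.random.default_rng(spec.seed if rng is None else rng)
    sites = simulate_sites(spec, rng)
    traits, optima = simulate_traits(spec, rng)
    community = simulate_community(
        traits, sites, spec.filtering_strength, rng, optima,
        spec.baseline_log_abundance, spec.target_mean_richness, spec.n_years,
    )
    return SimulatedStudy(
        community=community,
        traits=traits,
        sites=sites,
        ground_truth={
            "filtering_strength": spec.filtering_strength,
            "optima": optima,
            "impervious": sites.covariates(250)["impervious"].to_numpy(),
        },
    )


STRIPE_LEGEND = {0: "paved", 1: "grass", 2: "trees", 3: "lake"}
STRIPE_AGGREGATION = ClassAggregation(
    {0: "impervious", 1: "open_green", 2: "closed_green", 3: "water"})


def simulate_raster(
    n_cells: int = 400,
    pixel_size: float = 5.0,
    stripe_classes: tuple[int, ...] = (0, 1, 2, 0),
    rng: np.random.Generator | int | None = None,
    n_sites: int = 5,
    margin_m: float = 600.0,
) -> tuple[LandCoverRaster, pd.DataFrame]:
    """Vertical-striped class raster plus interior site coordinates.

    Equal-width vertical stripes cycle through ``stripe_classes``; site
    coordinates are drawn at least ``margin_m`` from every edge so a
    500 m buffer stays contained.
    """
    rng = np.random.default_rng(rng)
    stripe_w = n_cells // len(stripe_classes)
    grid = np.zeros((n_cells, n_cells), dtype=int)
    for k, cls in enumerate(stripe_classes):
        lo = k * stripe_w
        hi = (k + 1) * stripe_w if k < len(stripe_classes) - 1 else n_cells
        grid[:, lo:hi] = cls
    raster = LandCoverRaster(grid, pixel_size, (0.0, 0.0), STRIPE_LEGEND)
    side = n_cells * pixel_size
    coords = pd.DataFrame(
        {"x": rng.uniform(margin_m, side - margin_m, n_sites),
         "y": rng.uniform(margin_m, side - margin_m, n_sites)},
        index=[f"site_{i:03d}" for i in range(n_sites)],
    )
    return raster, coords
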