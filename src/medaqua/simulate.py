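"""Synthetic production panels with the regularities of long-run aquaculture.

The generator reproduces the statistical structure that seventy years of
FAO-style production tables show in regions such as the Mediterranean:

* a heavy-tailed species-share distribution — the Pareto "vital few", where
  a handful of species carry ~80% of annual volume;
* per-species logistic growth with staggered introduction years (early
  quasi-exponential growth saturating toward a carrying level);
* a country-adoption (diffusion-of-innovation) process, so each species'
  country count rises over time;
* multiplicative log-normal noise, since production data are positive and
  right-skewed.

Every random draw descends from a single seed through per-(species, country)
sub-streams, so adding one species never perturbs the others' series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import ProductionPanel


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic production process.

    Defaults describe a Mediterranean-like basin: 25 species and 25
    countries over 1950–2020, a geometric rank-abundance with decay 0.72
    (about 5 species carrying 80% of volume and ~14 carrying 99%), logistic
    growth at 0.15/yr toward a 1 Mt basin total, adoption of half a country
    per species-year, and 5% multiplicative noise.
    """

    n_species: int = 25
    n_countries: int = 25
    years: tuple[int, int] = (1950, 2020)
    share_model: str = "geometric"       # or "lognormal"
    share_param: float = 0.72            # decay ratio k, or log-sd sigma
    total_capacity: float = 1_000_000.0  # tonnes, K summed over species
    growth_rate: float = 0.15            # logistic r, per year
    midpoint_offset: int = 40            # t0 = intro_year + offset
    intro_span: int = 50                 # intro years staggered over this span
    adoption_rate: float = 0.5           # expected new countries per year
    country_decay: float = 0.6           # geometric weight ratio across adopters
    noise_cv: float = 0.05               # log-normal coefficient of variation
    seed: int = 0

    def validate(self) -> None:
        if self.n_species < 1 or self.n_countries < 1:
            raise ValueError("n_species and n_countries must be >= 1")
        if self.years[0] > self.years[1]:
            raise ValueError("years start must be <= end")
        if self.share_model == "geometric" and not (0 < self.share_param < 1):
            raise ValueError("geometric decay ratio must lie in (0, 1)")
        if self.share_model == "lognormal" and self.share_param <= 0:
            raise ValueError("lognormal sigma must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.growth_rate <= 0 or self.adoption_rate <= 0:
            raise ValueError("rates must be positive")
        if not (0 < self.country_decay < 1):
            raise ValueError("country_decay must lie in (0, 1)")


def rank_abundance_shares(n_species: int, model: str = "geometric",
                          param: float = 0.72, seed: int = 0) -> np.ndarray:
    """Species shares of total volume, sorted descending, summing to one.

    ``geometric``: share_i ∝ k^i (deterministic); ``lognormal``: shares drawn
    log-normally with log-sd ``param`` then sorted (seeded).
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    if model == "geometric":
        if not (0 < param < 1):
            raise ValueError("geometric decay ratio must lie in (0, 1)")
        raw = param ** np.arange(n_species, dtype=float)
    elif model == "lognormal":
        if param <= 0:
            raise ValueError("lognormal sigma must be positive")
        rng = np.random.default_rng([seed, 7])
        raw = np.sort(rng.lognormal(0.0, param, n_species))[::-1]
    else:
        raise ValueError(f"unknown share model {model!r}")
    shares = raw / raw.sum()
    return np.sort(shares)[::-1]


def logistic_trajectory(K: float, r: float, t0: float,
                        years: np.ndarray | range) -> np.ndarray:
    """Logistic curve K / (1 + exp(−r (t − t0))) over the given years."""
    if K <= 0 or r <= 0:
        raise ValueError("K and r must be positive")
    t = np.asarray(list(years), dtype=float)
    if t.size == 0:
        raise ValueError("empty year range")
    return K / (1.0 + np.exp(-r * (t - t0)))


def adoption_years(n_countries: int, intro_year: int, rate: float,
                   seed: int = 0) -> np.ndarray:
    """First-farming year per country under exponential waiting times.

    The first adopter farms at ``intro_year``; each subsequent country joins
    after an exponential gap with mean ``1/rate`` years (gaps accumulate, so
    adoption order is the country order).  Returned as float years; callers
    compare against the horizon to decide who never adopts.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    rng = np.random.default_rng([seed, 11])
    gaps = rng.exponential(1.0 / rate, size=max(n_countries - 1, 0))
    return intro_year + np.concatenate([[0.0], np.cumsum(gaps)])


def _country_weights(n_adopters: int, decay: float) -> np.ndarray:
    w = decay ** np.arange(n_adopters, dtype=float)
    return w / w.sum()


_ENV_CYCLE = ("marine", "freshwater", "brackish")
_GROUP_CYCLE = ("fish", "fish", "bivalve", "fish", "crustacean", "fish", "alga")


def generate_panel(config: SyntheticConfig) -> ProductionPanel:
    """Draw one synthetic production panel.

    Each national quantity is ``share_s × logistic_s(t) × weight_c ×
    lognormal noise``, where the country weights are a geometric
    rank-abundance over the countries that have adopted species *s* by year
    *t* (renormalised each year, so national volumes sum exactly to the
    species total when noise is zero).  Noise is mean-one log-normal, so
    expected totals equal the deterministic skeleton.
    """
    config.validate()
    start, end = config.years
    years = np.arange(start, end + 1)
    shares = rank_abundance_shares(config.n_species, config.share_model,
                                   config.share_param, seed=config.seed)
    # staggered introductions: dominant species first, spread over intro_span
    span = min(config.intro_span, end - start)
    if config.n_species == 1:
        intro_years = np.array([start])
    else:
        intro_years = start + np.round(
            np.linspace(0, span, config.n_species)).astype(int)

    countries = [f"country_{c:02d}" for c in range(config.n_countries)]
    records = []
    for s in range(config.n_species):
        intro = int(intro_years[s])
        t0 = intro + config.midpoint_offset
        traj = logistic_trajectory(config.total_capacity, config.growth_rate,
                                   t0, years)
        adopt = adoption_years(config.n_countries, intro, config.adoption_rate,
                               seed=int(np.random.default_rng(
                                   [config.seed, s]).integers(2**31)))
        env = _ENV_CYCLE[s % len(_ENV_CYCLE)]
        grp = _GROUP_CYCLE[s % len(_GROUP_CYCLE)]
        noise_rngs = {
            c: np.random.default_rng([config.seed, s, c])
            for c in range(config.n_countries)
        }
        if config.noise_cv > 0:
            sigma = float(np.sqrt(np.log1p(config.noise_cv ** 2)))
        else:
            sigma = 0.0
        for ti, year in enumerate(years):
            if year < intro:
                continue
            adopters = np.flatnonzero(adopt <= year)
            if adopters.size == 0:
                continue
            weights = _country_weights(adopters.size, config.country_decay)
            species_total = shares[s] * traj[ti]
            for c, w in zip(adopters, weights):
                q = species_total * w
                if sigma > 0:
                    q *= float(np.exp(noise_rngs[int(c)].normal(
                        -0.5 * sigma ** 2, sigma)))
                records.append((int(year), countries[int(c)],
                                f"species_{s:02d}", env, grp, q, np.nan))

    df = pd.DataFrame(records, columns=[
        "year", "country", "species", "environment", "group",
        "quantity_t", "value_kusd"])
    return ProductionPanel(df, provenance=f"synthetic(seed={config.seed})")


def species_intro_years(config: SyntheticConfig) -> dict[str, int]:
    """Ground-truth introduction year per species label (for validation)."""
    start, end = config.years
    span = min(config.intro_span, end - start)
    if config.n_species == 1:
        intros = np.array([start])
    else:
        intros = start + np.round(
            np.linspace(0, span, config.n_species)).astype(int)
    return {f"species_{s:02d}": int(intros[s]) for s in range(config.n_species)}
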