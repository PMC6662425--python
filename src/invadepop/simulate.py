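"""Synthetic invasion datasets with known ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes: a few hundred predominantly selfing individuals sampled from ~50
sites, a thousand-odd biallelic SNPs, several genetic clusters founded by
independent introductions at different times, rare variation that thins out
with dispersal distance from each origin (serial founder effect), heavy and
uneven missingness, and dated occurrence records that accumulate
exponentially with an optional lag phase.

Genetics are forward-time with discrete non-overlapping generations and no
mutation: each offspring is produced by selfing a random parent with
probability S, or by random outcrossing otherwise, which drives genotype
frequencies to the partial-selfing equilibrium Fis* = S / (2 - S). Range
growth across sites is modelled as serial founder hops: every new site is
seeded by a bounded subsample of an existing site's plants, so rare alleles
are progressively lost along the expansion path.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .matrix import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------- selfing core
def _gametes(pop: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One gamete per individual per locus from diploid dosages."""
    return (pop == 2).astype(np.int8) + (
        (pop == 1) & (rng.random(pop.shape) < 0.5)
    ).astype(np.int8)


def _next_generation(
    pop: np.ndarray, n_offspring: int, selfing: float, rng: np.random.Generator
) -> np.ndarray:
    n_parents = pop.shape[0]
    p1 = rng.integers(n_parents, size=n_offspring)
    selfed = rng.random(n_offspring) < selfing
    p2 = np.where(selfed, p1, rng.integers(n_parents, size=n_offspring))
    return _gametes(pop[p1], rng) + _gametes(pop[p2], rng)


def simulate_selfing_population(
    founder_freqs,
    selfing: float,
    n_generations: int,
    n_individuals: int,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Forward simulation of a partially selfing diploid population.

    Founders are drawn at Hardy-Weinberg proportions from ``founder_freqs``;
    each subsequent generation applies mixed selfing/outcrossing mating. At
    equilibrium the inbreeding coefficient approaches ``S / (2 - S)``
    (approach is geometric, halving the distance each generation).
    """
    if not 0 <= selfing <= 1:
        raise ValueError("selfing rate must be in [0, 1]")
    if n_individuals < 2 and selfing < 1:
        raise ValueError("outcrossing requires at least 2 individuals")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    p = np.asarray(founder_freqs, float)
    pop = rng.binomial(2, p, size=(n_individuals, len(p))).astype(np.int8)
    for _ in range(n_generations):
        pop = _next_generation(pop, n_individuals, selfing, rng)
    return pop


# -------------------------------------------------------------- configuration
@dataclass
class IntroductionSpec:
    """One introduction: its origin, recency, footprint and founder novelty."""

    name: str
    lat: float
    lon: float
    founding_year: int
    n_sites: int
    n_private_rare: int
    spread_deg: float = 0.6


@dataclass
class SimulationConfig:
    """Study-scale defaults: ~744 individuals, 52 sites, 1,525 SNPs, three
    introductions with staggered founder novelty (newest carries the most
    private low-frequency alleles), selfing rate 0.9."""

    n_loci: int = 1525
    n_samples: int = 744
    selfing: float = 0.9
    founder_beta: tuple[float, float] = (0.5, 0.5)
    introductions: list[IntroductionSpec] = field(default_factory=lambda: [
        IntroductionSpec("Malibu", 34.03, -118.69, 1927, 36, 60),
        IntroductionSpec("PalmSprings", 33.82, -116.55, 1965, 10, 150),
        IntroductionSpec("Nipomo", 35.04, -120.48, 2000, 6, 300),
    ])
    private_freq_range: tuple[float, float] = (0.02, 0.08)
    founder_pop: int = 150
    founder_generations: int = 12
    site_pop: int = 40
    site_generations: int = 4
    hop_founders: int = 10
    dropout: float = 0.15
    high_missing_fraction: float = 0.02
    high_missing_dropout: float = 0.85


@dataclass
class SimulatedDataset:
    genotypes: GenotypeMatrix
    metadata: pd.DataFrame
    cluster_labels: np.ndarray
    origins_newest_first: list[dict]
    site_hops: dict[str, int]
    planted_private: dict[str, int]
    config: SimulationConfig

    def truth_json(self) -> str:
        payload = {
            "cluster_labels": {s: str(c) for s, c in
                               zip(self.genotypes.samples, self.cluster_labels)},
            "origins_newest_first": self.origins_newest_first,
            "site_hops": self.site_hops,
            "planted_private": self.planted_private,
            "config": asdict(self.config),
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    def write(self, directory) -> None:
        from pathlib import Path

        from .io import write_genotypes

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        write_genotypes(self.genotypes, directory / "genotypes.tsv")
        self.metadata.to_csv(directory / "metadata.csv", index=False)
        (directory / "truth.json").write_text(self.truth_json())


def _ecoregion(lat: float, lon: float) -> str:
    # deterministic coarse binning by longitude (coastal vs desert vs interior)
    if lon < -118.0:
        return "coastal"
    if lon < -114.5:
        return "west_desert"
    return "east_desert"


# ------------------------------------------------------------------ invasion
def simulate_invasion(
    config: SimulationConfig | None = None, seed: int = 0
) -> SimulatedDataset:
    """Simulate a multi-introduction invasion with serial founder expansion.

    Per introduction: founder allele frequencies are drawn from the
    configured Beta law, a disjoint block of loci is reserved for its
    private rare alleles (absent from every other introduction), the founder
    population evolves under partial selfing, and sites are scattered
    outward by serial founder hops. Introductions are merged, missingness is
    injected, and the full ground truth is returned alongside the data.
    """
    cfg = config or SimulationConfig()
    if not cfg.introductions:
        raise ValueError("at least one introduction required")
    if sum(i.n_sites for i in cfg.introductions) < 1:
        raise ValueError("infeasible geometry: zero sites")
    n_private_total = sum(i.n_private_rare for i in cfg.introductions)
    if n_private_total > cfg.n_loci:
        raise ValueError("private rare alleles exceed the locus count")
    rng = np.random.default_rng(seed)
    L = cfg.n_loci

    # reserve disjoint private blocks, newest first at the end (arbitrary)
    blocks: dict[str, np.ndarray] = {}
    cursor = L - n_private_total
    for intro in cfg.introductions:
        blocks[intro.name] = np.arange(cursor, cursor + intro.n_private_rare)
        cursor += intro.n_private_rare

    # allocate samples to sites (evenly, remainder spread over first sites)
    n_sites_total = sum(i.n_sites for i in cfg.introductions)
    base, extra = divmod(cfg.n_samples, n_sites_total)
    site_sizes = [base + (1 if s < extra else 0) for s in range(n_sites_total)]

    all_calls, all_samples, meta_rows = [], [], []
    labels: list[str] = []
    site_hops: dict[str, int] = {}
    site_counter = 0
    for intro in cfg.introductions:
        p = rng.beta(*cfg.founder_beta, size=L)
        for other in cfg.introductions:
            p[blocks[other.name]] = 0.0
        founders = simulate_selfing_population(
            p, cfg.selfing, cfg.founder_generations, cfg.founder_pop, rng
        )
        # plant the introduction's private rare alleles into the evolved
        # founder pool at equilibrium genotype proportions (they are standing
        # variation the introduction arrived with, not de novo mutations)
        fis_eq = cfg.selfing / (2.0 - cfg.selfing)
        freqs = rng.uniform(*cfg.private_freq_range,
                            size=intro.n_private_rare)
        for j, f in zip(blocks[intro.name], freqs):
            copies = max(1, round(2 * cfg.founder_pop * f))
            carriers = rng.permutation(cfg.founder_pop)
            ci = 0
            while copies > 0 and ci < cfg.founder_pop:
                if copies >= 2 and rng.random() < fis_eq:
                    founders[carriers[ci], j] = 2
                    copies -= 2
                else:
                    founders[carriers[ci], j] = 1
                    copies -= 1
                ci += 1
        # site populations by serial founder hops from the origin
        site_pops = [founders]
        coords = [(intro.lat, intro.lon)]
        hops = [0]
        for s in range(1, intro.n_sites):
            src = int(rng.integers(s))  # any established site can seed a new one
            pool = site_pops[src]
            pick = rng.choice(pool.shape[0], size=min(cfg.hop_founders,
                                                      pool.shape[0]),
                              replace=False)
            pop = pool[pick]
            for _ in range(cfg.site_generations):
                pop = _next_generation(pop, cfg.site_pop, cfg.selfing, rng)
            site_pops.append(pop)
            lat = coords[src][0] + rng.normal(0, intro.spread_deg)
            lon = coords[src][1] + rng.normal(0, intro.spread_deg)
            coords.append((float(lat), float(lon)))
            hops.append(hops[src] + 1)
        for s in range(intro.n_sites):
            n_here = site_sizes[site_counter]
            site_name = intro.name if s == 0 else f"{intro.name}_{s:02d}"
            pool = site_pops[s]
            pick = rng.choice(pool.shape[0], size=min(n_here, pool.shape[0]),
                              replace=False)
            for k, row in enumerate(pick):
                sid = f"{site_name}_i{k:03d}"
                all_samples.append(sid)
                all_calls.append(pool[row])
                labels.append(intro.name)
                meta_rows.append({
                    "sample": sid, "site": site_name,
                    "lat": coords[s][0], "lon": coords[s][1],
                    "ecoregion": _ecoregion(*coords[s]),
                })
            site_hops[site_name] = hops[s]
            site_counter += 1

    calls = np.vstack(all_calls).astype(np.int8)
    # missingness: base per-call dropout plus a high-missingness stratum
    n = calls.shape[0]
    drop = rng.random(calls.shape) < cfg.dropout
    high = rng.random(n) < cfg.high_missing_fraction
    drop[high] = rng.random((int(high.sum()), L)) < cfg.high_missing_dropout
    calls[drop] = MISSING

    loci = [f"snp{j:05d}" for j in range(L)]
    g = GenotypeMatrix(all_samples, loci, calls)
    metadata = pd.DataFrame(meta_rows)
    origins = sorted(cfg.introductions, key=lambda i: -i.founding_year)
    origins_newest_first = [
        {"cluster": i.name, "site": i.name, "lat": i.lat, "lon": i.lon,
         "founding_year": i.founding_year}
        for i in origins
    ]
    return SimulatedDataset(
        genotypes=g,
        metadata=metadata,
        cluster_labels=np.array(labels, dtype=object),
        origins_newest_first=origins_newest_first,
        site_hops=site_hops,
        planted_private={i.name: i.n_private_rare for i in cfg.introductions},
        config=cfg,
    )


# ---------------------------------------------------------------- occurrences
def simulate_occurrences(
    rate_b: float = 0.0823,
    lag_years: int = 0,
    start_year: int = 1927,
    end_year: int = 2016,
    n_records: int = 2900,
    origin: tuple[float, float] = (33.82, -116.55),
    dispersal_scale: float = 0.08,
    seed: int = 0,
) -> pd.DataFrame:
    """Dated occurrence records from exponential range growth.

    The cumulative number of occupied ~1 km^2 cells follows
    ``10 ** (rate_b * t)`` (log-linear in time with slope ``rate_b``),
    anchored so that it reaches ``n_records`` at ``end_year``; each newly
    occupied cell contributes one record in its first year. Because the
    anchor fixes the endpoint, the first occupied year falls
    ``log10(n_records) / rate_b`` years before ``end_year`` — an exponential
    cannot span an arbitrary period and record count simultaneously. With
    ``lag_years > 0`` the origin cell is additionally planted at
    ``start_year`` and the clock only starts after the lag, producing the
    flat-then-exponential signature of a lagged invasion.
    """
    if rate_b <= 0:
        raise ValueError("rate_b must be positive")
    if end_year <= start_year:
        raise ValueError("years must be ordered")
    if n_records < 1:
        raise ValueError("n_records must be >= 1")
    rng = np.random.default_rng(seed)
    years = np.arange(start_year, end_year + 1)
    t_eff = np.maximum(0, (years - start_year) - lag_years).astype(float)
    growth_span = max((end_year - start_year) - lag_years, 1)
    c0 = np.log10(n_records) - rate_b * growth_span
    cum = np.rint(10 ** (c0 + rate_b * t_eff)).astype(int)
    cum = np.minimum(cum, n_records)
    if lag_years > 0:
        cum = np.maximum(cum, 1)  # origin cell present throughout the lag
    cum = np.maximum.accumulate(cum)
    cum[-1] = n_records
    new = np.diff(np.concatenate([[0], cum]))

    occupied: set[tuple[float, float]] = set()
    rows = []

    def place(year, n_new, radius):
        placed = 0
        r = radius
        while placed < n_new:
            lat = origin[0] + rng.normal(0, r)
            lon = origin[1] + rng.normal(0, r)
            cell = (round(lat, 2), round(lon, 2))
            if cell in occupied:
                r *= 1.02  # expand the search on collision
                continue
            occupied.add(cell)
            rows.append({"year": int(year), "lat": float(lat),
                         "lon": float(lon)})
            placed += 1

    for year, n_new, t in zip(years, new, t_eff):
        if n_new <= 0:
            continue
        if not occupied and lag_years > 0:
            # the very first cell is the origin itself
            occupied.add((round(origin[0], 2), round(origin[1], 2)))
            rows.append({"year": int(year), "lat": origin[0],
                         "lon": origin[1]})
            n_new -= 1
        radius = dispersal_scale * (t + 1.0)
        place(year, int(n_new), radius)
    return pd.DataFrame(rows, columns=["year", "lat", "lon"])
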