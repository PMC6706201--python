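"""Synthetic study systems with known ground truth.

This module emulates the two tamarin-dispersed plant systems the package
targets: a sparse canopy tree (*Parkia*-like, ~1 adult/ha, large fruit
crops, gut passage 30–240 min) and a dense understory tree
(*Leonia*-like, 5–11 adults/ha, small crops, trap-lining visits, gut
passage 120–240 min), both inside a 25–50 ha tamarin home range sampled
by 30-min positional scans.  Every generator is deterministic under an
explicit seed and returns ground truth (a :class:`TruthTable`) so each
estimator can be validated by parameter recovery rather than against
field data.

The true dispersal kernel is a synthetic choice (exponential by
default): it exists only to create known distances, not to assert what
the real kernel looks like.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from shapely.geometry import Point, Polygon

from .core import Genotype, Location, MISSING_CALL, PlantRecord, euclidean_distance
from .cmg import MovementTrack

__all__ = [
    "KernelSpec",
    "ScenarioConfig",
    "TruthRow",
    "TruthTable",
    "generate_landscape",
    "generate_genotypes",
    "generate_offspring_and_seedcoats",
    "generate_tracks",
    "generate_dispersal_events",
    "parkia_like",
    "leonia_like",
]


@dataclass(frozen=True)
class KernelSpec:
    """Parametric family for the synthetic true dispersal kernel."""

    family: Literal["exponential", "rayleigh"] = "exponential"
    mean_m: float = 200.0

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.family == "exponential":
            return rng.exponential(self.mean_m, size=n)
        if self.family == "rayleigh":
            # mean of Rayleigh(sigma) is sigma*sqrt(pi/2)
            return rng.rayleigh(self.mean_m / math.sqrt(math.pi / 2), size=n)
        raise ValueError(f"unknown kernel family {self.family!r}")


@dataclass
class ScenarioConfig:
    """All species and disperser parameters for one synthetic scenario.

    Defaults describe the *Parkia*-like system; :func:`leonia_like`
    builds the understory contrast.  Durations are minutes, lengths
    metres, areas hectares.
    """

    species_name: str = "parkia_like"
    home_range_area_ha: float = 38.9
    adult_density_per_ha: float = 1.0
    n_loci: int = 9
    alleles_per_locus: int = 8
    dirichlet_concentration: float = 1.0
    genotyping_error: float = 0.0
    missing_rate: float = 0.0
    scan_interval_min: float = 30.0
    daily_path_mean_m: float = 1700.0
    daily_path_min_m: float = 600.0
    daily_path_max_m: float = 3000.0
    daily_path_sd_m: float = 400.0          # (max - min) / 6 of the reported range
    turning_sd_rad: float = 0.7
    activity_hours: float = 9.0
    gut_window_min: tuple[float, float] = (30.0, 240.0)
    feeding_visit_min: float = 11.8
    trees_visited_per_day: float = 4.0
    revisit_max_per_day: int = 4
    fruit_sugar_mg_per_g: float = 811.0
    true_kernel: KernelSpec = field(default_factory=KernelSpec)
    n_days: int = 31
    seed: int = 0

    def validate(self) -> "ScenarioConfig":
        if self.home_range_area_ha <= 0:
            raise ValueError("home_range_area_ha must be positive")
        if self.adult_density_per_ha <= 0:
            raise ValueError("adult_density_per_ha must be positive")
        if self.adult_density_per_ha * self.home_range_area_ha < 2:
            raise ValueError("density × area must allow at least 2 adults")
        if self.n_loci < 1 or self.alleles_per_locus < 2:
            raise ValueError("need ≥1 locus with ≥2 alleles each")
        lo, up = self.gut_window_min
        if not 0 < lo < up:
            raise ValueError(f"gut window must satisfy 0 < lower < upper, got {self.gut_window_min}")
        for name in (
            "scan_interval_min", "daily_path_mean_m", "daily_path_sd_m",
            "activity_hours", "feeding_visit_min", "trees_visited_per_day",
            "fruit_sugar_mg_per_g",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.genotyping_error < 1 or not 0 <= self.missing_rate < 1:
            raise ValueError("rates must lie in [0, 1)")
        if self.n_days < 1:
            raise ValueError("n_days must be ≥ 1")
        return self


def parkia_like(**overrides) -> ScenarioConfig:
    """Sparse canopy tree: large crops, repeat visits, fast gut passage."""
    return replace(ScenarioConfig(), **overrides).validate()


def leonia_like(**overrides) -> ScenarioConfig:
    """Dense understory tree: small crops, trap-lining, slow gut passage."""
    cfg = ScenarioConfig(
        species_name="leonia_like",
        adult_density_per_ha=8.0,
        n_loci=11,
        gut_window_min=(120.0, 240.0),
        feeding_visit_min=1.9,
        trees_visited_per_day=7.5,
        revisit_max_per_day=1,
        fruit_sugar_mg_per_g=528.5,  # midpoint of the 415–642 mg/g range
    )
    return replace(cfg, **overrides).validate()


@dataclass(frozen=True)
class TruthRow:
    """Ground truth for one synthetic offspring or dispersal event."""

    offspring_id: str
    mother_id: str
    father_id: str | None
    deposition: Location
    true_distance_m: float
    flagged: bool = False


@dataclass
class TruthTable:
    rows: list[TruthRow]

    def __len__(self) -> int:
        return len(self.rows)

    def mother_of(self, offspring_id: str) -> str:
        for r in self.rows:
            if r.offspring_id == offspring_id:
                return r.mother_id
        raise KeyError(offspring_id)

    def distances(self) -> np.ndarray:
        return np.array([r.true_distance_m for r in self.rows])


def _home_range_polygon(area_ha: float) -> Polygon:
    """Square home range of the configured area, origin at (0, 0)."""
    side = math.sqrt(area_ha * 10_000.0)
    return Polygon([(0, 0), (side, 0), (side, side), (0, side)])


def generate_landscape(
    cfg: ScenarioConfig, rng: np.random.Generator | int | None = None
) -> tuple[list[PlantRecord], Polygon]:
    """Place adult trees by a homogeneous Poisson process in the home range.

    The adult count is Poisson(density × area); coordinates are uniform
    inside a square polygon of the configured area.  Draws are retried
    (preserving determinism) until at least two adults exist, since every
    downstream analysis needs ≥2 candidate parents.
    """
    cfg.validate()
    rng = np.random.default_rng(rng if rng is not None else cfg.seed)
    poly = _home_range_polygon(cfg.home_range_area_ha)
    minx, miny, maxx, maxy = poly.bounds
    lam = cfg.adult_density_per_ha * cfg.home_range_area_ha
    n = int(rng.poisson(lam))
    while n < 2:  # vanishing probability at realistic densities
        n = int(rng.poisson(lam))
    xs = rng.uniform(minx, maxx, size=n)
    ys = rng.uniform(miny, maxy, size=n)
    adults = [
        PlantRecord(
            id=f"A{i:03d}",
            role="adult",
            species=cfg.species_name,
            location=Location(float(x), float(y)),
        )
        for i, (x, y) in enumerate(zip(xs, ys))
    ]
    assert all(poly.covers(Point(a.location.x, a.location.y)) for a in adults)
    return adults, poly


def _locus_names(n_loci: int) -> tuple[str, ...]:
    return tuple(f"L{i + 1:02d}" for i in range(n_loci))


def draw_allele_frequencies(
    cfg: ScenarioConfig, rng: np.random.Generator
) -> dict[str, dict[int, float]]:
    """One Dirichlet draw of allele frequencies per locus."""
    freqs: dict[str, dict[int, float]] = {}
    for locus in _locus_names(cfg.n_loci):
        p = rng.dirichlet(np.full(cfg.alleles_per_locus, cfg.dirichlet_concentration))
        freqs[locus] = {a + 1: float(p[a]) for a in range(cfg.alleles_per_locus)}
    return freqs


def _draw_hw_genotype(
    sample_id: str,
    loci: tuple[str, ...],
    freqs: dict[str, dict[int, float]],
    rng: np.random.Generator,
) -> Genotype:
    calls = []
    for locus in loci:
        alleles = np.array(list(freqs[locus].keys()))
        p = np.array(list(freqs[locus].values()))
        a, b = rng.choice(alleles, size=2, p=p)
        calls.append((int(a), int(b)))
    return Genotype(sample_id=sample_id, loci=loci, calls=tuple(calls))


def _corrupt(
    g: Genotype,
    freqs: dict[str, dict[int, float]],
    error_rate: float,
    missing_rate: float,
    rng: np.random.Generator,
) -> Genotype:
    """Apply per-locus genotyping error and missing data to a copy.

    Errors replace the whole call with a fresh Hardy–Weinberg draw — the
    same error model the parentage likelihood assumes.
    """
    if error_rate == 0 and missing_rate == 0:
        return g
    calls = list(g.calls)
    for i, locus in enumerate(g.loci):
        if calls[i] == MISSING_CALL:
            continue
        if missing_rate > 0 and rng.random() < missing_rate:
            calls[i] = MISSING_CALL
            continue
        if error_rate > 0 and rng.random() < error_rate:
            alleles = np.array(list(freqs[locus].keys()))
            p = np.array(list(freqs[locus].values()))
            a, b = rng.choice(alleles, size=2, p=p)
            calls[i] = (int(a), int(b))
    return Genotype(sample_id=g.sample_id, loci=g.loci, calls=tuple(calls))


def generate_genotypes(
    adults: Sequence[PlantRecord],
    cfg: ScenarioConfig,
    rng: np.random.Generator | int | None = None,
) -> tuple[list[Genotype], list[Genotype], dict[str, dict[int, float]]]:
    """Adult genotypes in Hardy–Weinberg proportions.

    Returns ``(true_genotypes, observed_genotypes, allele_freqs)``.  The
    observed copies carry the configured genotyping-error and missing
    rates; with both at zero, observed == true.
    """
    cfg.validate()
    rng = np.random.default_rng(rng if rng is not None else cfg.seed)
    freqs = draw_allele_frequencies(cfg, rng)
    loci = _locus_names(cfg.n_loci)
    true = [_draw_hw_genotype(a.id, loci, freqs, rng) for a in adults]
    observed = [
        _corrupt(g, freqs, cfg.genotyping_error, cfg.missing_rate, rng) for g in true
    ]
    return true, observed, freqs


def mendelian_offspring(
    sample_id: str,
    mother: Genotype,
    father: Genotype,
    rng: np.random.Generator,
) -> Genotype:
    """One allele from each parent, independently per locus."""
    calls = []
    for cm, cf in zip(mother.calls, father.calls):
        calls.append((cm[rng.integers(2)], cf[rng.integers(2)]))
    return Genotype(sample_id=sample_id, loci=mother.loci, calls=tuple(calls))


def generate_offspring_and_seedcoats(
    adults: Sequence[PlantRecord],
    adult_genotypes: Sequence[Genotype],
    cfg: ScenarioConfig,
    n_offspring: int,
    rng: np.random.Generator | int | None = None,
    external_father_rate: float = 0.0,
) -> tuple[list[Genotype], list[Genotype], list[PlantRecord], TruthTable]:
    """Offspring genotypes, maternal seed-coat genotypes and ground truth.

    For each offspring a mother is drawn uniformly among adults and a
    father uniformly among the remaining adults; inheritance is Mendelian.
    The seed coat is an exact copy of the mother's genotype (maternal
    tissue).  The deposition point is the mother's location displaced by
    a draw from the configured true kernel in a uniform direction.

    ``external_father_rate`` is the probability that the father is an
    unsampled individual outside the candidate set (pollen immigration);
    such fathers get fresh Hardy–Weinberg genotypes and ids ``EXTnnn``.

    Returns ``(offspring_genotypes, seedcoat_genotypes, offspring_records,
    truth)``.
    """
    cfg.validate()
    if n_offspring < 1:
        raise ValueError("n_offspring must be ≥ 1")
    if len(adults) < 2:
        raise ValueError("need at least 2 adults")
    rng = np.random.default_rng(rng if rng is not None else cfg.seed)
    freqs = None
    by_id = {a.id: (a, g) for a, g in zip(adults, adult_genotypes)}
    loci = adult_genotypes[0].loci

    offspring_g: list[Genotype] = []
    seedcoat_g: list[Genotype] = []
    records: list[PlantRecord] = []
    rows: list[TruthRow] = []
    distances = cfg.true_kernel.sample(rng, n_offspring)
    angles = rng.uniform(0, 2 * math.pi, size=n_offspring)
    for k in range(n_offspring):
        mi = int(rng.integers(len(adults)))
        mother_rec, mother_g = adults[mi], adult_genotypes[mi]
        if external_father_rate > 0 and rng.random() < external_father_rate:
            if freqs is None:
                from .core import allele_frequencies

                freqs = allele_frequencies(adult_genotypes)
            father_id = f"EXT{k:03d}"
            father_g = _draw_hw_genotype(father_id, loci, freqs, rng)
        else:
            fi = int(rng.integers(len(adults) - 1))
            if fi >= mi:
                fi += 1
            father_rec, father_g = adults[fi], adult_genotypes[fi]
            father_id = father_rec.id
        oid = f"O{k:03d}"
        child = mendelian_offspring(oid, mother_g, father_g, rng)
        coat = Genotype(sample_id=f"SC{k:03d}", loci=loci, calls=mother_g.calls)
        dep = Location(
            mother_rec.location.x + distances[k] * math.cos(angles[k]),
            mother_rec.location.y + distances[k] * math.sin(angles[k]),
        )
        offspring_g.append(child)
        seedcoat_g.append(coat)
        records.append(
            PlantRecord(id=oid, role="seedling", species=cfg.species_name, location=dep)
        )
        rows.append(
            TruthRow(
                offspring_id=oid,
                mother_id=mother_rec.id,
                father_id=father_id,
                deposition=dep,
                true_distance_m=float(distances[k]),
            )
        )
    return offspring_g, seedcoat_g, records, TruthTable(rows)


def generate_tracks(
    cfg: ScenarioConfig,
    n_days: int | None = None,
    rng: np.random.Generator | int | None = None,
    polygon: Polygon | None = None,
) -> list[MovementTrack]:
    """Correlated random walk sampled at the scan interval.

    Step lengths between successive scans are gamma distributed with
    moments matched so the summed daily path length has the configured
    mean and spread: with ``k`` steps per day, the per-step mean is
    ``daily_path_mean_m / k`` and the per-step standard deviation
    ``daily_path_sd_m / sqrt(k)`` (variance of an independent sum).
    Headings follow a wrapped-normal turning-angle process and steps are
    reflected at the home-range boundary.
    """
    cfg.validate()
    n_days = n_days if n_days is not None else cfg.n_days
    rng = np.random.default_rng(rng if rng is not None else cfg.seed)
    poly = polygon if polygon is not None else _home_range_polygon(cfg.home_range_area_ha)
    minx, miny, maxx, maxy = poly.bounds

    n_steps = int(round(cfg.activity_hours * 60.0 / cfg.scan_interval_min))
    step_mean = cfg.daily_path_mean_m / n_steps
    step_sd = cfg.daily_path_sd_m / math.sqrt(n_steps)
    shape = (step_mean / step_sd) ** 2
    scale = step_sd**2 / step_mean

    tracks = []
    for day in range(n_days):
        x = rng.uniform(minx, maxx)
        y = rng.uniform(miny, maxy)
        heading = rng.uniform(0, 2 * math.pi)
        scans = [(0.0, Location(x, y))]
        for s in range(1, n_steps + 1):
            heading += rng.normal(0.0, cfg.turning_sd_rad)
            r = rng.gamma(shape, scale)
            x += r * math.cos(heading)
            y += r * math.sin(heading)
            x, y, heading = _reflect(x, y, heading, minx, miny, maxx, maxy)
            scans.append((s * cfg.scan_interval_min, Location(x, y)))
        tracks.append(MovementTrack(day_id=f"day{day:03d}", scans=scans))
    return tracks


def _reflect(
    x: float, y: float, heading: float, minx: float, miny: float, maxx: float, maxy: float
) -> tuple[float, float, float]:
    """Mirror a point back into the bounding box, flipping the heading."""
    for _ in range(100):
        if minx <= x <= maxx and miny <= y <= maxy:
            break
        if x < minx:
            x = 2 * minx - x
            heading = math.pi - heading
        elif x > maxx:
            x = 2 * maxx - x
            heading = math.pi - heading
        if y < miny:
            y = 2 * miny - y
            heading = -heading
        elif y > maxy:
            y = 2 * maxy - y
            heading = -heading
    return x, y, heading


def _track_position(track: MovementTrack, t_min: float) -> tuple[Location, bool]:
    """Linear interpolation along the scan sequence; clamps at day end.

    Returns ``(location, clamped)`` where ``clamped`` is True when
    ``t_min`` falls past the last scan (seed still in the gut at the
    sleeping site).
    """
    times = [t for t, _ in track.scans]
    if t_min >= times[-1]:
        return track.scans[-1][1], t_min > times[-1]
    if t_min <= times[0]:
        return track.scans[0][1], False
    j = next(i for i, t in enumerate(times) if t >= t_min)
    t0, p0 = track.scans[j - 1]
    t1, p1 = track.scans[j]
    w = (t_min - t0) / (t1 - t0)
    return Location(p0.x + w * (p1.x - p0.x), p0.y + w * (p1.y - p0.y)), False


def generate_dispersal_events(
    tracks: Sequence[MovementTrack],
    adults: Sequence[PlantRecord],
    cfg: ScenarioConfig,
    rng: np.random.Generator | int | None = None,
    events_per_day: int = 3,
) -> tuple[list["DispersalRecord"], TruthTable]:
    """Observable feeding→defecation events along synthetic tracks.

    Feeding scans are chosen uniformly per day; the feeding location is
    the scan position and the source tree is the nearest adult to it.
    Each seed receives a gut passage time uniform on the configured
    window and is deposited at the interpolated track position that much
    later — or at the final scan (the sleeping site, flagged) when the
    activity period ends first, mirroring seed accumulation under
    sleeping sites.
    """
    from .core import DispersalRecord

    cfg.validate()
    rng = np.random.default_rng(rng if rng is not None else cfg.seed)
    lo, up = cfg.gut_window_min
    adult_xy = np.array([[a.location.x, a.location.y] for a in adults])

    records: list[DispersalRecord] = []
    rows: list[TruthRow] = []
    k = 0
    for track in tracks:
        n_scans = len(track.scans)
        feed_idx = rng.choice(n_scans - 1, size=min(events_per_day, n_scans - 1), replace=False)
        for i in sorted(int(i) for i in feed_idx):
            t_feed, feed_loc = track.scans[i]
            d2 = (adult_xy[:, 0] - feed_loc.x) ** 2 + (adult_xy[:, 1] - feed_loc.y) ** 2
            source = adults[int(np.argmin(d2))]
            gut = rng.uniform(lo, up)
            dep_loc, clamped = _track_position(track, t_feed + gut)
            rec = DispersalRecord(
                source_id=source.id,
                source_loc=feed_loc,
                deposition_loc=dep_loc,
                method="OSD",
                flagged=clamped,
            )
            records.append(rec)
            rows.append(
                TruthRow(
                    offspring_id=f"E{k:04d}",
                    mother_id=source.id,
                    father_id=None,
                    deposition=dep_loc,
                    true_distance_m=rec.distance,
                    flagged=clamped,
                )
            )
            k += 1
    return records, TruthTable(rows)
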