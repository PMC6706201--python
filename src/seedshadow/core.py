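"""Shared domain types, planar geometry and genotype arithmetic.

Everything downstream — the direct estimators, parentage analysis, the
movement×gut-passage model and the foraging simulation — works with the
small set of records defined here: planar locations in metres (a single
UTM-like frame, so distances are Euclidean), plant records, diploid
multilocus microsatellite genotypes with a 0/0 missing sentinel, and
dispersal records whose length is one seed-dispersal-distance (SDD)
observation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

__all__ = [
    "MISSING_CALL",
    "Location",
    "PlantRecord",
    "Genotype",
    "DispersalRecord",
    "DistanceSample",
    "euclidean_distance",
    "allele_frequencies",
    "mismatch_count",
    "mendelian_compatible",
    "filter_max_distance",
]

#: GenAlex-style sentinel for a missing genotype call.
MISSING_CALL: tuple[int, int] = (0, 0)

PLANT_ROLES = frozenset({"adult", "seedling", "sapling", "seed", "seed_coat"})

METHOD_TAGS = ("OSD", "GSC", "PAS", "CMG", "IBM")


@dataclass(frozen=True, slots=True)
class Location:
    """A planar point in metres (easting-like x, northing-like y)."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"non-finite coordinates: ({self.x}, {self.y})")


@dataclass(frozen=True, slots=True)
class PlantRecord:
    """A mapped plant individual or seed sample."""

    id: str
    role: str
    species: str
    location: Location

    def __post_init__(self) -> None:
        if self.role not in PLANT_ROLES:
            raise ValueError(f"unknown plant role {self.role!r}; expected one of {sorted(PLANT_ROLES)}")


def _normalise_call(call: tuple[int, int]) -> tuple[int, int]:
    a, b = int(call[0]), int(call[1])
    if (a == 0) != (b == 0):
        raise ValueError(f"half-missing call {call!r}: both alleles must be 0 for a missing locus")
    if a < 0 or b < 0:
        raise ValueError(f"negative allele code in call {call!r}")
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class Genotype:
    """Diploid multilocus genotype.

    ``calls[i]`` is the unordered allele pair at ``loci[i]`` stored in
    sorted order; ``(0, 0)`` marks a missing locus.  Allele codes are
    positive integers (microsatellite fragment sizes or arbitrary labels).
    """

    sample_id: str
    loci: tuple[str, ...]
    calls: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if len(self.loci) != len(self.calls):
            raise ValueError(
                f"{self.sample_id}: {len(self.loci)} loci but {len(self.calls)} calls"
            )
        object.__setattr__(self, "loci", tuple(self.loci))
        object.__setattr__(self, "calls", tuple(_normalise_call(c) for c in self.calls))

    def is_missing(self, i: int) -> bool:
        return self.calls[i] == MISSING_CALL

    @property
    def n_typed(self) -> int:
        """Number of loci with a non-missing call."""
        return sum(1 for c in self.calls if c != MISSING_CALL)


@dataclass(frozen=True)
class DispersalRecord:
    """One seed movement from a source plant to a deposition point.

    ``distance`` caches the Euclidean length and is validated against the
    coordinates on construction.  ``source_id`` may be None when the
    source plant is unknown (e.g. an unassigned seed).
    """

    source_id: str | None
    source_loc: Location
    deposition_loc: Location
    method: str
    distance: float = field(default=None)  # type: ignore[assignment]
    flagged: bool = False

    def __post_init__(self) -> None:
        if self.method not in METHOD_TAGS:
            raise ValueError(f"unknown method tag {self.method!r}")
        d = euclidean_distance(self.source_loc, self.deposition_loc)
        if self.distance is None:
            object.__setattr__(self, "distance", d)
        elif abs(self.distance - d) > 1e-9:
            raise ValueError(
                f"cached distance {self.distance} disagrees with coordinates ({d})"
            )


@dataclass
class DistanceSample:
    """A per-method sample of seed dispersal distances in metres."""

    method: str
    species: str
    values: list[float]

    def __post_init__(self) -> None:
        if self.method not in METHOD_TAGS:
            raise ValueError(f"unknown method tag {self.method!r}")
        if any(v < 0 for v in self.values):
            raise ValueError("negative dispersal distance")

    def __len__(self) -> int:
        return len(self.values)

    def require_nonempty(self) -> "DistanceSample":
        if not self.values:
            raise ValueError(f"empty distance sample for {self.method}/{self.species}")
        return self


def euclidean_distance(a: Location, b: Location) -> float:
    """Straight-line distance in metres between two planar points."""
    return math.hypot(a.x - b.x, a.y - b.y)


def allele_frequencies(
    genotypes: Iterable[Genotype],
) -> dict[str, dict[int, float]]:
    """Per-locus allele frequencies over all non-missing allele copies.

    Loci at which every genotype is missing are excluded from the result
    with a warning — downstream likelihoods cannot use them anyway.
    """
    genotypes = list(genotypes)
    if not genotypes:
        raise ValueError("no genotypes supplied")
    loci = genotypes[0].loci
    for g in genotypes[1:]:
        if g.loci != loci:
            raise ValueError(f"genotype {g.sample_id} has a different locus list")

    freqs: dict[str, dict[int, float]] = {}
    for i, locus in enumerate(loci):
        counts: dict[int, int] = {}
        for g in genotypes:
            if g.is_missing(i):
                continue
            a, b = g.calls[i]
            counts[a] = counts.get(a, 0) + 1
            counts[b] = counts.get(b, 0) + 1
        total = sum(counts.values())
        if total == 0:
            warnings.warn(
                f"locus {locus!r} has no non-missing calls; excluded from frequencies",
                stacklevel=2,
            )
            continue
        freqs[locus] = {allele: n / total for allele, n in sorted(counts.items())}
    return freqs


def _check_shared_loci(g1: Genotype, g2: Genotype) -> None:
    if g1.loci != g2.loci:
        shared = set(g1.loci) & set(g2.loci)
        if not shared:
            raise ValueError(
                f"{g1.sample_id} and {g2.sample_id} share no loci"
            )
        raise ValueError(
            f"{g1.sample_id} and {g2.sample_id} have different locus lists; "
            "align panels before comparing"
        )


def mismatch_count(g1: Genotype, g2: Genotype) -> tuple[int, int]:
    """Compare two genotypes locus by locus.

    Returns ``(n_compared, n_mismatching)``.  Loci missing in either
    genotype are excluded from ``n_compared``; a locus mismatches iff the
    unordered allele pairs differ.
    """
    _check_shared_loci(g1, g2)
    n_compared = n_mismatch = 0
    for c1, c2 in zip(g1.calls, g2.calls):
        if c1 == MISSING_CALL or c2 == MISSING_CALL:
            continue
        n_compared += 1
        if c1 != c2:
            n_mismatch += 1
    return n_compared, n_mismatch


def mendelian_compatible(offspring: Genotype, candidate: Genotype) -> int:
    """Number of loci at which the candidate cannot be a parent.

    A locus is incompatible iff both genotypes are typed there and the
    candidate shares no allele with the offspring (a parent must have
    transmitted one of the offspring's two alleles).
    """
    _check_shared_loci(offspring, candidate)
    n_incompatible = 0
    for co, cc in zip(offspring.calls, candidate.calls):
        if co == MISSING_CALL or cc == MISSING_CALL:
            continue
        if co[0] not in cc and co[1] not in cc:
            n_incompatible += 1
    return n_incompatible


def filter_max_distance(
    records: Sequence[DispersalRecord], max_m: float = 700.0
) -> tuple[list[DispersalRecord], int]:
    """Drop records farther than ``max_m`` from their source.

    Parent–offspring pairs separated by more than the diameter of a
    disperser home range are more plausibly explained by pollen flow than
    by seed transport, so they are excluded from SDD samples.  The
    boundary is kept: "beyond" is read as strictly greater than ``max_m``.
    Returns ``(kept, n_removed)``.
    """
    kept = [r for r in records if r.distance <= max_m]
    return kept, len(records) - len(kept)
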