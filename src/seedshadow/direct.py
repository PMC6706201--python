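"""Direct SDD estimators: observed events and seed-coat maternity matching.

OSD (observed seed dispersal) turns feeding→defecation event pairs into
distances.  GSC (genotyped seed coats) exploits the fact that the seed
coat is maternal tissue: an exact multilocus match between a seed-coat
genotype and an adult identifies the mother, and the distance from that
adult to the seed's deposition point is one realized SDD.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

from .core import (
    DispersalRecord,
    DistanceSample,
    Genotype,
    Location,
    euclidean_distance,
    mismatch_count,
)

__all__ = [
    "MaternityAssignment",
    "estimate_osd",
    "match_seed_coats",
    "expected_random_matches",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MaternityAssignment:
    """Outcome of matching one seed coat against the adult population."""

    seed_id: str
    matched_mother_id: str | None
    n_candidate_matches: int
    n_compared_loci: int
    reason: str = ""


def estimate_osd(
    events: Sequence[DispersalRecord], species: str = ""
) -> DistanceSample:
    """Distances of observed dispersal events, in input order.

    Zero-distance events (defecation at the feeding tree) are kept: a
    dispersal event is defined by seeds in the defecation, not by a
    minimum distance.  Events flagged upstream as violating the
    single-source rule should already have been excluded by the caller.
    """
    values = [e.distance for e in events]
    n_zero = sum(1 for v in values if v == 0)
    if n_zero:
        logger.info("OSD: %d zero-distance event(s) kept (non-dispersal distances)", n_zero)
    return DistanceSample(method="OSD", species=species, values=values)


def match_seed_coats(
    seed_coats: Sequence[Genotype],
    adults: Sequence[Genotype],
    adult_locs: Mapping[str, Location],
    seed_locs: Mapping[str, Location],
    species: str = "",
    min_compared_loci: int = 5,
) -> tuple[list[MaternityAssignment], DistanceSample, list[DispersalRecord]]:
    """Exact-match maternity assignment of seed coats (no mismatches allowed).

    An adult is a match iff ``mismatch_count == 0`` over at least
    ``min_compared_loci`` compared loci (loci missing in either genotype
    are ignored; the floor guards against trivial matches on a handful of
    loci).  A seed is assigned only when exactly one adult matches —
    ties yield no assignment rather than a nearest-adult guess.  The
    distance sample is built from unique matches with known coordinates.
    """
    if not adults:
        raise ValueError("no adult genotypes supplied")
    assignments: list[MaternityAssignment] = []
    records: list[DispersalRecord] = []
    for coat in seed_coats:
        matches: list[str] = []
        best_compared = 0
        for adult in adults:
            n_comp, n_mis = mismatch_count(coat, adult)
            if n_mis == 0 and n_comp >= min_compared_loci:
                matches.append(adult.sample_id)
                best_compared = max(best_compared, n_comp)
        if len(matches) == 1:
            assignments.append(
                MaternityAssignment(
                    seed_id=coat.sample_id,
                    matched_mother_id=matches[0],
                    n_candidate_matches=1,
                    n_compared_loci=best_compared,
                )
            )
            mother_loc = adult_locs.get(matches[0])
            seed_loc = seed_locs.get(coat.sample_id)
            if mother_loc is not None and seed_loc is not None:
                records.append(
                    DispersalRecord(
                        source_id=matches[0],
                        source_loc=mother_loc,
                        deposition_loc=seed_loc,
                        method="GSC",
                    )
                )
        else:
            reason = (
                "no zero-mismatch adult"
                if not matches
                else f"ambiguous ({len(matches)} matches)"
            )
            assignments.append(
                MaternityAssignment(
                    seed_id=coat.sample_id,
                    matched_mother_id=None,
                    n_candidate_matches=len(matches),
                    n_compared_loci=best_compared,
                    reason=reason,
                )
            )
    sample = DistanceSample(
        method="GSC", species=species, values=[r.distance for r in records]
    )
    return assignments, sample, records


def expected_random_matches(
    coat: Genotype,
    freqs: Mapping[str, Mapping[int, float]],
    n_unrelated: int,
) -> float:
    """Expected number of unrelated adults matching a seed coat by chance.

    For each typed locus, the probability that a random Hardy–Weinberg
    genotype is identical to the coat's is ``2·p_a·p_b`` (heterozygote)
    or ``p_a²`` (homozygote); the full-genotype match probability is the
    product over typed loci, and the expectation scales with the number
    of unrelated candidates.  When this expectation is much below one,
    an exact match is convincing evidence of maternity.
    """
    p_match = 1.0
    for locus, call in zip(coat.loci, coat.calls):
        if call == (0, 0) or locus not in freqs:
            continue
        a, b = call
        pa = freqs[locus].get(a, 0.0)
        pb = freqs[locus].get(b, 0.0)
        p_match *= (pa * pa) if a == b else (2 * pa * pb)
    return n_unrelated * p_match
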