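"""Likelihood-based parentage analysis of seedlings and saplings.

Assignment follows the classic maximum-likelihood recipe for codominant
markers: for every offspring×candidate pair a LOD score sums, over
shared typed loci, the log ratio of the probability of the offspring
genotype given the candidate as one parent (Mendelian transmission, the
other allele drawn from the population) to its unconditional
Hardy–Weinberg probability.  Confidence is calibrated by simulation: the
delta statistic (LOD of the best candidate minus the second best) is
compared against a threshold chosen so that a stated fraction (strict
95%) of above-threshold assignments on self-simulated data are correct.

Because the maternal parent of a seedling cannot be told apart from the
paternal one with nuclear markers alone, either assigned parent is
treated as a potential mother and all assigned parent–offspring pairs
enter the distance sample, after removing pairs separated by more than
the disperser home-range diameter (default 700 m) as likely pollen
rather than seed movement.

Error model: with per-locus probability ``e`` the observed genotype is
an independent Hardy–Weinberg draw instead of the true genotype.  This
is the simplest error model consistent with a single error rate and it
is the same model the synthetic generator uses to corrupt genotypes.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .core import (
    DispersalRecord,
    DistanceSample,
    Genotype,
    Location,
    filter_max_distance,
)

__all__ = [
    "ParentageConfig",
    "AssignedParent",
    "ParentageAssignment",
    "single_parent_lod",
    "lod_matrix",
    "critical_delta",
    "assign_parentage",
    "estimate_pas",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ParentageConfig:
    """Settings of the parentage run (candidate pool, error, confidence)."""

    n_candidates: int = 33
    proportion_sampled: float = 0.99
    genotyping_error: float = 0.01
    min_typed_loci: int = 5
    confidence_level: float = 0.95
    n_confidence_sims: int = 10_000
    max_distance_m: float = 700.0
    allow_second_parent: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.proportion_sampled <= 1:
            raise ValueError("proportion_sampled must be in (0, 1]")
        if not 0 <= self.genotyping_error < 1:
            raise ValueError("genotyping_error must be in [0, 1)")
        if self.min_typed_loci < 1:
            raise ValueError("min_typed_loci must be ≥ 1")
        if not 0 < self.confidence_level < 1:
            raise ValueError("confidence_level must be in (0, 1)")
        if self.n_candidates < 2:
            raise ValueError("need ≥2 candidate parents")


@dataclass(frozen=True)
class AssignedParent:
    parent_id: str
    lod: float
    delta: float
    confident: bool = True


@dataclass(frozen=True)
class ParentageAssignment:
    offspring_id: str
    parents: tuple[AssignedParent, ...]


# ---------------------------------------------------------------------------
# frequency tables and genotype arrays
# ---------------------------------------------------------------------------

def _freq_table(
    freqs: Mapping[str, Mapping[int, float]], loci: Sequence[str]
) -> np.ndarray:
    """(L, max_code + 1) table of allele frequencies, zero elsewhere."""
    max_code = max(
        (a for locus in loci for a in freqs.get(locus, {})), default=0
    )
    tab = np.zeros((len(loci), max_code + 1))
    for li, locus in enumerate(loci):
        for allele, p in freqs.get(locus, {}).items():
            tab[li, allele] = p
    return tab


def genotypes_to_array(genotypes: Sequence[Genotype]) -> np.ndarray:
    """(N, L, 2) integer allele array; 0 encodes missing."""
    return np.array([[list(c) for c in g.calls] for g in genotypes], dtype=np.int64)


def _lod_kernel(
    a: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    d: np.ndarray,
    ftab: np.ndarray,
    e: float,
) -> np.ndarray:
    """Sum of per-locus log likelihood ratios over the last axis.

    ``a, b`` are the offspring's alleles and ``c, d`` the candidate's,
    broadcast to a common shape ``(..., L)``.  Loci missing in either
    genotype, or whose offspring genotype has zero population frequency,
    contribute nothing.
    """
    L = a.shape[-1]
    lidx = np.arange(L)
    pa = ftab[lidx, a]
    pb = ftab[lidx, b]
    hom = a == b
    p_geno = np.where(hom, pa * pa, 2.0 * pa * pb)
    t_a = 0.5 * ((c == a).astype(float) + (d == a).astype(float))
    t_b = 0.5 * ((c == b).astype(float) + (d == b).astype(float))
    trans = np.where(hom, t_a * pa, t_a * pb + t_b * pa)
    valid = (a > 0) & (c > 0) & (p_geno > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = ((1.0 - e) * trans + e * p_geno) / p_geno
        locus_lod = np.where(valid, np.log(ratio), 0.0)
    return locus_lod.sum(axis=-1)


def lod_matrix(
    offspring: np.ndarray,
    candidates: np.ndarray,
    ftab: np.ndarray,
    e: float,
) -> np.ndarray:
    """LOD of every offspring (N, L, 2) against every candidate (M, L, 2)."""
    a = offspring[:, None, :, 0]
    b = offspring[:, None, :, 1]
    c = candidates[None, :, :, 0]
    d = candidates[None, :, :, 1]
    return _lod_kernel(a, b, c, d, ftab, e)


def single_parent_lod(
    offspring: Genotype,
    candidate: Genotype,
    freqs: Mapping[str, Mapping[int, float]],
    e: float = 0.0,
) -> float:
    """Natural-log LOD that ``candidate`` is a parent of ``offspring``.

    Returns NaN (with a warning) when the pair shares no typed loci —
    the score is undefined there, not zero evidence.
    """
    if offspring.loci != candidate.loci:
        raise ValueError("offspring and candidate must share the locus panel")
    off = genotypes_to_array([offspring])
    cand = genotypes_to_array([candidate])
    shared = int(np.sum((off[0, :, 0] > 0) & (cand[0, :, 0] > 0)))
    if shared == 0:
        warnings.warn(
            f"{offspring.sample_id} × {candidate.sample_id}: no shared typed loci; "
            "LOD undefined",
            stacklevel=2,
        )
        return float("nan")
    ftab = _freq_table(freqs, offspring.loci)
    return float(lod_matrix(off, cand, ftab, e)[0, 0])


# ---------------------------------------------------------------------------
# simulation-derived confidence threshold
# ---------------------------------------------------------------------------

def _draw_hw_array(
    ftab: np.ndarray, shape: tuple[int, ...], rng: np.random.Generator
) -> np.ndarray:
    """Hardy–Weinberg genotype draws as an integer array ``shape + (L, 2)``."""
    L = ftab.shape[0]
    out = np.empty(shape + (L, 2), dtype=np.int64)
    for li in range(L):
        p = ftab[li]
        codes = np.flatnonzero(p)
        out[..., li, :] = rng.choice(codes, size=shape + (2,), p=p[codes] / p[codes].sum())
    return out


def _apply_error(
    arr: np.ndarray, ftab: np.ndarray, e: float, rng: np.random.Generator
) -> np.ndarray:
    """Replace each call with probability ``e`` by a fresh HW draw."""
    if e == 0:
        return arr
    mask = rng.random(arr.shape[:-1]) < e  # per (…, locus)
    fresh = _draw_hw_array(ftab, arr.shape[:-2], rng)
    out = arr.copy()
    out[mask] = fresh[mask]
    return out


def critical_delta(
    freqs: Mapping[str, Mapping[int, float]],
    cfg: ParentageConfig,
    seed: int | np.random.Generator = 0,
    loci: Sequence[str] | None = None,
    chunk: int = 500,
) -> float:
    """Delta threshold at the configured (strict) confidence level.

    Simulates offspring from random Hardy–Weinberg parents; each
    simulated candidate set holds ``n_candidates`` genotypes and contains
    the true parent with probability ``proportion_sampled``; observed
    genotypes carry the configured error rate.  The threshold is the
    smallest delta such that at least ``confidence_level`` of the
    simulated assignments exceeding it identify the true parent.
    Deterministic under the seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    loci = list(loci) if loci is not None else list(freqs.keys())
    ftab = _freq_table(freqs, loci)
    e = cfg.genotyping_error

    deltas: list[np.ndarray] = []
    corrects: list[np.ndarray] = []
    remaining = cfg.n_confidence_sims
    while remaining > 0:
        S = min(chunk, remaining)
        remaining -= S
        d, ok = _simulate_deltas(ftab, cfg, S, rng)
        deltas.append(d)
        corrects.append(ok)
    delta = np.concatenate(deltas)
    correct = np.concatenate(corrects)

    order = np.argsort(-delta, kind="stable")
    delta_sorted = delta[order]
    frac = np.cumsum(correct[order]) / np.arange(1, delta.size + 1)
    ok_prefix = np.flatnonzero(frac >= cfg.confidence_level)
    if ok_prefix.size == 0:
        warnings.warn(
            "no delta threshold reaches the requested confidence; "
            f"best achieved {frac.max():.3f} — returning +inf",
            stacklevel=2,
        )
        return float("inf")
    idx = int(ok_prefix.max())
    if idx == delta.size - 1:
        return 0.0  # even unconditional assignment meets the confidence level
    threshold = float(delta_sorted[idx])
    n_above = idx + 1
    if n_above < 50:
        warnings.warn(
            f"threshold rests on only {n_above} above-threshold simulations; "
            "increase n_confidence_sims for a stabler estimate",
            stacklevel=2,
        )
    return max(threshold, 0.0)


def _simulate_deltas(
    ftab: np.ndarray,
    cfg: ParentageConfig,
    S: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """One chunk of confidence simulations → (delta, correct) arrays."""
    L = ftab.shape[0]
    C = cfg.n_candidates
    e = cfg.genotyping_error

    p1 = _draw_hw_array(ftab, (S,), rng)
    p2 = _draw_hw_array(ftab, (S,), rng)
    pick1 = rng.integers(2, size=(S, L))
    pick2 = rng.integers(2, size=(S, L))
    off = np.stack(
        [
            np.take_along_axis(p1[..., :], pick1[..., None], axis=-1)[..., 0],
            np.take_along_axis(p2[..., :], pick2[..., None], axis=-1)[..., 0],
        ],
        axis=-1,
    )  # (S, L, 2)

    cands = _draw_hw_array(ftab, (S, C), rng)
    included = rng.random(S) < cfg.proportion_sampled
    cands[included, 0] = p1[included]

    off_obs = _apply_error(off, ftab, e, rng)
    cands_obs = _apply_error(cands, ftab, e, rng)

    a = off_obs[:, None, :, 0]
    b = off_obs[:, None, :, 1]
    c = cands_obs[..., 0]
    d = cands_obs[..., 1]
    lods = _lod_kernel(a, b, c, d, ftab, e)  # (S, C)

    top2 = np.partition(lods, -2, axis=1)[:, -2:]
    best_idx = np.argmax(lods, axis=1)
    best = top2[:, 1]
    second = top2[:, 0]
    with np.errstate(invalid="ignore"):
        delta = best - second
    delta[np.isinf(best) & (best < 0)] = np.nan  # no assignable candidate
    correct = included & (best_idx == 0)

    keep = ~np.isnan(delta)
    # +inf delta (single compatible candidate at e = 0) sorts as the surest
    return delta[keep], correct[keep]


# ---------------------------------------------------------------------------
# assignment and distances
# ---------------------------------------------------------------------------

def assign_parentage(
    offspring: Sequence[Genotype],
    candidates: Sequence[Genotype],
    freqs: Mapping[str, Mapping[int, float]],
    cfg: ParentageConfig,
    seed: int | np.random.Generator = 0,
    threshold: float | None = None,
) -> tuple[list[ParentageAssignment], int]:
    """Assign up to two confident parents per offspring.

    Offspring with fewer than ``min_typed_loci`` typed loci are excluded
    up front (their count is returned).  Per offspring, candidates are
    ranked by LOD; the top candidate is assigned when its delta against
    the runner-up meets the simulated threshold, and the runner-up is
    additionally assigned when it independently clears the threshold
    against the field excluding the best (both assigned parents are
    potential mothers).  Candidates with LOD −inf (Mendelian exclusion
    at e = 0) are never assigned.
    """
    if threshold is None:
        threshold = critical_delta(freqs, cfg, seed, loci=list(offspring[0].loci) if offspring else None)
    kept = [g for g in offspring if g.n_typed >= cfg.min_typed_loci]
    n_excluded = len(offspring) - len(kept)
    if n_excluded:
        logger.info(
            "parentage: excluded %d offspring with < %d typed loci",
            n_excluded,
            cfg.min_typed_loci,
        )
    if not kept:
        return [], n_excluded

    loci = kept[0].loci
    ftab = _freq_table(freqs, loci)
    off_arr = genotypes_to_array(kept)
    cand_arr = genotypes_to_array(candidates)
    lods = lod_matrix(off_arr, cand_arr, ftab, cfg.genotyping_error)

    assignments: list[ParentageAssignment] = []
    for i, g in enumerate(kept):
        row = lods[i]
        order = np.argsort(-row, kind="stable")
        parents: list[AssignedParent] = []
        lod1 = row[order[0]]
        lod2 = row[order[1]] if len(order) > 1 else -math.inf
        delta1 = lod1 - lod2 if math.isfinite(lod1) else -math.inf
        if math.isfinite(lod1) and delta1 >= threshold:
            parents.append(
                AssignedParent(
                    parent_id=candidates[order[0]].sample_id,
                    lod=float(lod1),
                    delta=float(delta1),
                )
            )
            if cfg.allow_second_parent and len(order) > 2:
                lod3 = row[order[2]]
                delta2 = lod2 - lod3 if math.isfinite(lod2) else -math.inf
                if math.isfinite(lod2) and delta2 >= threshold:
                    parents.append(
                        AssignedParent(
                            parent_id=candidates[order[1]].sample_id,
                            lod=float(lod2),
                            delta=float(delta2),
                        )
                    )
        assignments.append(ParentageAssignment(offspring_id=g.sample_id, parents=tuple(parents)))
    return assignments, n_excluded


def estimate_pas(
    assignments: Sequence[ParentageAssignment],
    locations: Mapping[str, Location],
    cfg: ParentageConfig,
    species: str = "",
) -> tuple[DistanceSample, int]:
    """Distance sample from all assigned parent–offspring pairs.

    Every assigned parent contributes one distance (an offspring with two
    confident parents contributes two — the distances are not
    deduplicated, since either parent may be the mother).  Pairs farther
    apart than ``max_distance_m`` are excluded as presumed pollen flow;
    the exclusion count is returned.
    """
    records: list[DispersalRecord] = []
    for asn in assignments:
        dep = locations.get(asn.offspring_id)
        if dep is None:
            continue
        for parent in asn.parents:
            src = locations.get(parent.parent_id)
            if src is None:
                continue
            records.append(
                DispersalRecord(
                    source_id=parent.parent_id,
                    source_loc=src,
                    deposition_loc=dep,
                    method="PAS",
                )
            )
    if not records:
        raise ValueError("no assigned parent–offspring pairs; cannot build a PAS sample")
    kept, n_removed = filter_max_distance(records, cfg.max_distance_m)
    sample = DistanceSample(method="PAS", species=species, values=[r.distance for r in kept])
    return sample, n_removed
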