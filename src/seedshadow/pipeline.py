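"""End-to-end scenario driver: synthetic data → five estimators → comparison.

One call runs the whole chain for a configured scenario: generate the
landscape, genotypes, tracks and true dispersal events; estimate SDD by
direct observation (OSD), seed-coat matching (GSC), parentage analysis
(PAS), the movement×gut-passage model (CMG) and the foraging simulation
(IBM); then run the comparison battery.  Everything is seeded from one
master seed through ``numpy.random.SeedSequence.spawn``, so a run is
reproducible bit for bit, and a manifest records the config, the child
seeds, per-stage record counts and SHA-256 hashes of every output file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import tomllib
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np

from . import __version__
from .cmg import estimate_cmg, gut_passage_window
from .core import DistanceSample, Location, allele_frequencies
from .direct import estimate_osd, match_seed_coats
from .ibm import IbmConfig, leonia_ibm_config, parkia_ibm_config, simulate_ibm
from .io import write_distances_csv, write_genotypes_csv, write_locations_csv
from .parentage import ParentageConfig, assign_parentage, critical_delta, estimate_pas
from .stats import compare_methods
from .synthetic import (
    KernelSpec,
    ScenarioConfig,
    generate_dispersal_events,
    generate_genotypes,
    generate_landscape,
    generate_offspring_and_seedcoats,
    generate_tracks,
    leonia_like,
    parkia_like,
)

__all__ = ["RunManifest", "load_config", "run_scenario", "make_fixtures"]

logger = logging.getLogger(__name__)


@dataclass
class RunManifest:
    config: dict[str, Any]
    master_seed: int
    child_seeds: dict[str, int]
    record_counts: dict[str, int]
    file_hashes: dict[str, str]
    package_version: str

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def load_config(path: str | Path) -> dict[str, Any]:
    """Read a TOML scenario config and validate the parts we understand."""
    with open(path, "rb") as fh:
        cfg = tomllib.load(fh)
    if "scenario" not in cfg:
        raise ValueError(f"{path}: missing [scenario] table")
    build_scenario(cfg)  # validation happens inside the dataclasses
    return cfg


def build_scenario(cfg: dict[str, Any]) -> tuple[ScenarioConfig, IbmConfig, ParentageConfig, dict[str, Any]]:
    """Turn the raw TOML dict into validated config objects."""
    sc = dict(cfg.get("scenario", {}))
    base = sc.pop("base", "parkia")
    if "true_kernel" in sc:
        sc["true_kernel"] = KernelSpec(**sc["true_kernel"])
    if "gut_window_min" in sc:
        sc["gut_window_min"] = tuple(sc["gut_window_min"])
    factory = {"parkia": parkia_like, "leonia": leonia_like}.get(base)
    if factory is None:
        raise ValueError(f"unknown scenario base {base!r}")
    scenario = factory(**sc)

    ib = dict(cfg.get("ibm", {}))
    if "gut_window_min" in ib:
        ib["gut_window_min"] = tuple(ib["gut_window_min"])
    ibm_factory = {"parkia": parkia_ibm_config, "leonia": leonia_ibm_config}[base]
    ibm_cfg = ibm_factory(**ib)

    pc = dict(cfg.get("parentage", {}))
    parentage_cfg = ParentageConfig(**pc)

    run = dict(cfg.get("run", {}))
    run.setdefault("n_offspring", 150)
    run.setdefault("n_seed_coats", 120)
    run.setdefault("osd_events_per_day", 3)
    run.setdefault("n_gut_sample", 60)
    run.setdefault("n_boot_mean", 10_000)
    run.setdefault("n_boot_kernel", 100)
    run.setdefault("external_father_rate", 0.0)
    run.setdefault("candidate_fraction", 1.0)
    run.setdefault("lag_tolerance_min", 0.0)
    run.setdefault("n_other_trees", 40)
    return scenario, ibm_cfg, parentage_cfg, run


def run_scenario(
    config_path: str | Path,
    out_dir: str | Path,
    seed: int,
    skip: set[str] | None = None,
) -> RunManifest:
    """Execute the full scenario and write all outputs plus a manifest.

    ``skip`` may name stages ("osd", "gsc", "pas", "cmg", "ibm") to omit;
    the comparison then covers the remaining samples.
    """
    skip = skip or set()
    cfg = load_config(config_path)
    scenario, ibm_cfg, parentage_cfg, run = build_scenario(cfg)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    ss = np.random.SeedSequence(seed)
    stage_names = [
        "landscape", "genotypes", "offspring", "tracks", "events",
        "gut_sample", "parentage", "ibm", "stats", "other_trees",
    ]
    children = ss.spawn(len(stage_names))
    child_seeds = {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(stage_names, children)
    }
    rngs = {name: np.random.default_rng(child) for name, child in zip(stage_names, children)}

    counts: dict[str, int] = {}
    files: list[Path] = []

    # --- synthetic study system -------------------------------------------
    adults, polygon = generate_landscape(scenario, rngs["landscape"])
    counts["adults"] = len(adults)
    write_locations_csv(adults, out / "adults.csv")
    files.append(out / "adults.csv")

    true_g, obs_g, freqs = generate_genotypes(adults, scenario, rngs["genotypes"])
    write_genotypes_csv(obs_g, out / "adult_genotypes.csv")
    files.append(out / "adult_genotypes.csv")

    offspring_g, seedcoat_g, offspring_rec, truth = generate_offspring_and_seedcoats(
        adults,
        true_g,
        scenario,
        n_offspring=run["n_offspring"],
        rng=rngs["offspring"],
        external_father_rate=run["external_father_rate"],
    )
    counts["offspring"] = len(offspring_g)
    write_locations_csv(offspring_rec, out / "offspring.csv")
    files.append(out / "offspring.csv")

    tracks = generate_tracks(scenario, rng=rngs["tracks"], polygon=polygon)
    counts["track_days"] = len(tracks)

    events, event_truth = generate_dispersal_events(
        tracks, adults, scenario, rng=rngs["events"], events_per_day=run["osd_events_per_day"]
    )
    counts["events"] = len(events)

    samples: list[DistanceSample] = []
    sp = scenario.species_name

    # --- OSD ---------------------------------------------------------------
    if "osd" not in skip:
        osd = estimate_osd([e for e in events if not e.flagged], species=sp).require_nonempty()
        samples.append(osd)
        counts["osd_distances"] = len(osd)
        write_distances_csv([e for e in events if not e.flagged], sp, out / "osd_distances.csv")
        files.append(out / "osd_distances.csv")

    # --- GSC ---------------------------------------------------------------
    if "gsc" not in skip:
        n_coats = min(run["n_seed_coats"], len(seedcoat_g))
        adult_locs = {a.id: a.location for a in adults}
        seed_locs = {
            sc.sample_id: truth.rows[i].deposition for i, sc in enumerate(seedcoat_g)
        }
        assignments, gsc, gsc_records = match_seed_coats(
            seedcoat_g[:n_coats], obs_g, adult_locs, seed_locs, species=sp
        )
        gsc.require_nonempty()
        samples.append(gsc)
        counts["gsc_assigned"] = len(gsc)
        write_distances_csv(gsc_records, sp, out / "gsc_distances.csv")
        files.append(out / "gsc_distances.csv")

    # --- PAS ---------------------------------------------------------------
    if "pas" not in skip:
        # genotyped candidate pool: possibly a subset of the adults, as when
        # sampling quadrats cover only part of the home range
        frac = run["candidate_fraction"]
        if frac < 1.0:
            idx = rngs["parentage"].choice(
                len(obs_g), size=max(2, int(round(frac * len(obs_g)))), replace=False
            )
            candidates = [obs_g[i] for i in sorted(idx)]
        else:
            candidates = obs_g
        freqs_all = allele_frequencies(list(candidates) + offspring_g)
        threshold = critical_delta(freqs_all, parentage_cfg, rngs["parentage"])
        asn, n_excl = assign_parentage(
            offspring_g, candidates, freqs_all, parentage_cfg, rngs["parentage"], threshold=threshold
        )
        locations = {a.id: a.location for a in adults}
        locations.update({r.id: r.location for r in offspring_rec})
        pas, n_removed = estimate_pas(asn, locations, parentage_cfg, species=sp)
        samples.append(pas)
        counts["pas_pairs"] = len(pas)
        counts["pas_removed_beyond_700m"] = n_removed
        counts["pas_offspring_excluded"] = n_excl

    # --- CMG ---------------------------------------------------------------
    if "cmg" not in skip:
        lo, up = scenario.gut_window_min
        gut_sample = rngs["gut_sample"].uniform(lo, up, size=run["n_gut_sample"])
        window = gut_passage_window(gut_sample)
        cmg = estimate_cmg(
            tracks, window, species=sp, lag_tolerance_min=run["lag_tolerance_min"]
        )
        samples.append(cmg)
        counts["cmg_pairs"] = len(cmg)

    # --- IBM ---------------------------------------------------------------
    if "ibm" not in skip:
        other = []
        if ibm_cfg.include_other_species:
            from .core import PlantRecord

            n_other = run["n_other_trees"]
            minx, miny, maxx, maxy = polygon.bounds
            r = rngs["other_trees"]
            other = [
                PlantRecord(
                    id=f"X{i:03d}",
                    role="adult",
                    species="other",
                    location=Location(float(r.uniform(minx, maxx)), float(r.uniform(miny, maxy))),
                )
                for i in range(n_other)
            ]
            focal = adults[: min(8, len(adults))]
        else:
            focal = adults
        result = simulate_ibm(ibm_cfg, focal, other, rngs["ibm"])
        ibm_sample = result.distance_sample(species=sp).require_nonempty()
        samples.append(ibm_sample)
        counts["ibm_seeds"] = result.n_deposited
        write_distances_csv([d.record for d in result.depositions], sp, out / "ibm_distances.csv")
        files.append(out / "ibm_distances.csv")

    # --- comparison --------------------------------------------------------
    report = compare_methods(
        samples,
        n_boot_mean=run["n_boot_mean"],
        n_boot_kernel=run["n_boot_kernel"],
        seed=rngs["stats"],
    )
    files.extend(report.write_csvs(out))
    (out / "summary.txt").write_text(report.summary() + "\n")
    files.append(out / "summary.txt")

    manifest = RunManifest(
        config=cfg,
        master_seed=seed,
        child_seeds=child_seeds,
        record_counts=counts,
        file_hashes={f.name: _sha256(f) for f in sorted(set(files))},
        package_version=__version__,
    )
    manifest.write(out / "manifest.json")
    logger.info("run complete: %s", counts)
    return manifest


def make_fixtures(out_dir: str | Path, seed: int = 0) -> list[Path]:
    """Write the small deterministic datasets used by the test suite."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = parkia_like(home_range_area_ha=25.0, adult_density_per_ha=1.0, seed=seed)
    ss = np.random.SeedSequence(seed)
    r_land, r_geno, r_track = [np.random.default_rng(s) for s in ss.spawn(3)]
    adults, polygon = generate_landscape(cfg, r_land)
    true_g, obs_g, _ = generate_genotypes(adults, cfg, r_geno)
    tracks = generate_tracks(cfg, n_days=2, rng=r_track, polygon=polygon)

    paths = []
    write_locations_csv(adults, out / "toy_landscape.csv")
    paths.append(out / "toy_landscape.csv")
    write_genotypes_csv(obs_g, out / "toy_genotypes.csv")
    paths.append(out / "toy_genotypes.csv")
    rows = []
    for track in tracks:
        for i, (t, loc) in enumerate(track.scans):
            rows.append(f"{track.day_id},{i},{t:.1f},{loc.x:.3f},{loc.y:.3f}")
    (out / "toy_tracks.csv").write_text(
        "day,scan_index,minutes_since_start,x,y\n" + "\n".join(rows) + "\n"
    )
    paths.append(out / "toy_tracks.csv")
    return paths
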