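"""CSV readers and writers for the package's table formats.

Formats:

* locations: ``id,role,species,x,y`` (UTF-8, dot decimal, metres)
* genotypes: GenAlex dialect — ``sample_id`` then two columns per locus
  named ``<locus>_1,<locus>_2``; allele code 0 marks missing data
* distances: ``method,species,source_id,source_x,source_y,dep_x,dep_y,distance_m``
* tracks: ``day,scan_index,minutes_since_start,x,y``
* truth: ``offspring_id,mother_id,father_id,true_distance_m``
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from .core import DispersalRecord, Genotype, Location, PlantRecord

__all__ = [
    "read_locations_csv",
    "write_locations_csv",
    "read_genotypes_csv",
    "write_genotypes_csv",
    "read_distances_csv",
    "write_distances_csv",
]


def write_locations_csv(records: Sequence[PlantRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "id": [r.id for r in records],
            "role": [r.role for r in records],
            "species": [r.species for r in records],
            "x": [r.location.x for r in records],
            "y": [r.location.y for r in records],
        }
    )
    # %.17g guarantees float round-tripping through the text format
    df.to_csv(path, index=False, float_format="%.17g")


def read_locations_csv(path: str | Path) -> list[PlantRecord]:
    df = pd.read_csv(path, dtype={"id": str}, float_precision="round_trip")
    records = [
        PlantRecord(
            id=row.id,
            role=row.role,
            species=row.species,
            location=Location(float(row.x), float(row.y)),
        )
        for row in df.itertuples()
    ]
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate plant ids in {path}")
    return records


def write_genotypes_csv(genotypes: Sequence[Genotype], path: str | Path) -> None:
    if not genotypes:
        raise ValueError("no genotypes to write")
    loci = genotypes[0].loci
    data: dict[str, list] = {"sample_id": [g.sample_id for g in genotypes]}
    for i, locus in enumerate(loci):
        data[f"{locus}_1"] = [g.calls[i][0] for g in genotypes]
        data[f"{locus}_2"] = [g.calls[i][1] for g in genotypes]
    pd.DataFrame(data).to_csv(path, index=False)


def read_genotypes_csv(path: str | Path) -> list[Genotype]:
    df = pd.read_csv(path, dtype={"sample_id": str})
    cols = [c for c in df.columns if c != "sample_id"]
    if len(cols) % 2 != 0:
        raise ValueError(f"{path}: expected two allele columns per locus")
    loci = []
    for c1, c2 in zip(cols[::2], cols[1::2]):
        if not (c1.endswith("_1") and c2.endswith("_2") and c1[:-2] == c2[:-2]):
            raise ValueError(f"{path}: allele columns {c1!r},{c2!r} do not pair up")
        loci.append(c1[:-2])
    genotypes = []
    for row in df.itertuples(index=False):
        sample_id = row[0]
        alleles = [int(v) for v in row[1:]]
        calls = tuple(zip(alleles[::2], alleles[1::2]))
        genotypes.append(Genotype(sample_id=sample_id, loci=tuple(loci), calls=calls))
    return genotypes


def write_distances_csv(
    records: Sequence[DispersalRecord], species: str, path: str | Path
) -> None:
    df = pd.DataFrame(
        {
            "method": [r.method for r in records],
            "species": [species] * len(records),
            "source_id": [r.source_id if r.source_id is not None else "" for r in records],
            "source_x": [r.source_loc.x for r in records],
            "source_y": [r.source_loc.y for r in records],
            "dep_x": [r.deposition_loc.x for r in records],
            "dep_y": [r.deposition_loc.y for r in records],
            "distance_m": [r.distance for r in records],
        }
    )
    df.to_csv(path, index=False, float_format="%.6f")


def read_distances_csv(path: str | Path) -> list[DispersalRecord]:
    df = pd.read_csv(path, dtype={"source_id": str}, keep_default_na=False)
    records = []
    for row in df.itertuples():
        records.append(
            DispersalRecord(
                source_id=row.source_id or None,
                source_loc=Location(float(row.source_x), float(row.source_y)),
                deposition_loc=Location(float(row.dep_x), float(row.dep_y)),
                method=row.method,
            )
        )
    return records
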