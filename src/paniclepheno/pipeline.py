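"""End-to-end orchestration over synthetic or reconstructed sessions.

Ties the stages together: generate (or load) one scene per plant x week,
run the 3D trait pipeline on each, assemble the long trait table, and
join the end-point measurements, producing the input for the correlation
and clustering analyses.
"""

from __future__ import annotations

import pandas as pd

from .cloud3d import (DEFAULT_CHAMBER, BoundingCube, ChamberModel,
                      session_traits)
from .io import validate_trait_table
from .stats import ClusterResult, cluster_genotypes
from .synthetic import Cohort, make_scene


def cohort_trait_table(
    cohort: Cohort,
    model: ChamberModel = DEFAULT_CHAMBER,
    cube: BoundingCube | None = None,
    *,
    resolution: int = 200,
) -> pd.DataFrame:
    """Run the full 3D pipeline on every plant x week of a cohort.

    Returns a long trait table keyed by (genotype, replicate, treatment,
    week) carrying voxel count, color sums, R:G ratio, the scene's true
    volume, and the plant's end-point measurements repeated on each of
    its weekly rows (the form used for week-wise correlation analysis).
    """
    if cube is None:
        cube = BoundingCube(resolution=resolution)
    truth_vol = cohort.truth.true_volumes.set_index(
        ["genotype", "replicate", "treatment", "week"])["true_volume"]
    manual = cohort.manual_table.drop(columns=["week"]).set_index(
        ["genotype", "replicate", "treatment"])
    rows = []
    for plant in cohort.plants:
        for week, spec in sorted(plant.specs.items()):
            cloud, _ = make_scene(spec, model)
            traits = session_traits(cloud, model, cube)
            key = (plant.genotype, plant.replicate, plant.treatment, week)
            row = {
                "genotype": plant.genotype, "replicate": plant.replicate,
                "treatment": plant.treatment, "week": week,
                "voxel_count": traits.voxel_count,
                "color_sum_r": traits.color_sum_r,
                "color_sum_g": traits.color_sum_g,
                "color_sum_b": traits.color_sum_b,
                "rg_ratio": traits.rg_ratio,
                "true_volume": float(truth_vol.loc[key]),
            }
            row.update(manual.loc[key[:3]].to_dict())
            rows.append(row)
    table = pd.DataFrame(rows)
    return validate_trait_table(table)


def genotype_trajectories(
    table: pd.DataFrame, *, treatment: str = "control",
    value: str = "voxel_count",
) -> pd.DataFrame:
    """Genotype x week matrix of replicate-mean values under one
    treatment — the clustering input."""
    sub = table[table["treatment"] == treatment]
    return sub.pivot_table(index="genotype", columns="week", values=value,
                           aggfunc="mean")


def cluster_cohort(
    table: pd.DataFrame, k: int, *, treatment: str = "control"
) -> ClusterResult:
    """Hierarchical clustering of genotype voxel-count trajectories."""
    return cluster_genotypes(genotype_trajectories(table,
                                                   treatment=treatment), k)
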