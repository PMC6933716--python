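"""Cohort-level statistics: correlation, clustering, letter display.

Generates a small designed cohort (two growth groups), runs the full 3D
pipeline on every plant x week, correlates week-3 voxel count with
end-point seed weight, clusters genotype trajectories, and letter-codes
the weekly voxel-count distributions.
"""

from paniclepheno.pipeline import cluster_cohort, cohort_trait_table
from paniclepheno.stats import group_compare, pearson_matrix
from paniclepheno.synthetic import make_cohort

cohort = make_cohort(n_genotypes=6, reps=(2,), treatments=("control",),
                     rng_seed=42)
table = cohort_trait_table(cohort, resolution=150)

week3 = table[table["week"] == 3]
corr = pearson_matrix(week3, ["voxel_count", "total_seed_weight"])
r = corr.r.loc["voxel_count", "total_seed_weight"]
p = corr.p.loc["voxel_count", "total_seed_weight"]
print(f"week-3 r(voxel count, seed weight) = {r:.3f} (p = {p:.2g}, "
      f"n = {corr.n.loc['voxel_count', 'total_seed_weight']})")

clusters = cluster_cohort(table, k=2)
print("genotype clusters:", clusters.labels.to_dict())
print("designed groups  :", cohort.truth.genotype_groups)

weeks = {f"week {w}": table[table["week"] == w]["voxel_count"].to_numpy()
         for w in (1, 2, 3)}
letters = group_compare(weeks, alpha=0.1)
print("letter display over weeks:", letters.letters)
print("A strong positive correlation, clean group recovery, and distinct")
print("letters across weeks mirror a growing, volume-tracked panicle.")
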