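"""(Partial) canonical correspondence analysis with variance partitioning.

Constrains community variation to biotic/environmental variables, then
conditions on the spatial design (area, subsite) to remove spatial
autocorrelation, and finally attributes inertia to each variable
marginally (each constrained with all others as conditions), with
permutation p-values.
"""

from mossbiome import filter_rare
from mossbiome.ordination import cca, prepare_constraints, variance_partition, vif
from mossbiome.synthetic import StudyConfig, generate_study

table, metadata, _ = generate_study(StudyConfig(seed=1))
table, _ = filter_rare(table)
md = metadata.loc[list(table.sample_ids)]

variables = ["plant_label", "hydrology", "fraction", "pH", "ch4", "temperature"]
cm = prepare_constraints(md, variables + ["area", "subsite"])

full = cca(table, cm, drop_aliased=True)
print(f"full model: {100 * full.constrained_inertia / full.total_inertia:.1f}% of "
      f"total inertia ({full.total_inertia:.2f}) constrained")

partial = cca(table, cm.subset(variables), cm.subset(["area", "subsite"]), drop_aliased=True)
print(f"conditioning on area+subsite: {100 * partial.conditioned_inertia / partial.total_inertia:.1f}% "
      f"conditioned, {100 * partial.constrained_inertia / partial.total_inertia:.1f}% constrained")

print("\nVIF of the non-spatial constraints (no redundancy if all modest):")
print(vif(cm.subset(variables)).round(2).to_string())

vp = variance_partition(table, cm, variables=variables, n_perm=199, seed=7, drop_aliased=True)
print("\nmarginal inertia shares (% of total) with permutation p-values:")
print(vp.table.round(3).to_string(index=False))
# Plant species carries the planted system/species structure and should
# dominate; the continuous covariates contribute smaller significant
# shares, mirroring the ordering seen in natural peatlands.
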