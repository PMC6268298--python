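"""Generate a synthetic repositioning study with known planted structure.

The generator plants three disease-perturbed sub-pathways (their genes are
differentially expressed in a 16 vs 16 cohort) and three active molecules
whose treatment profiles shift those same sub-pathways' genes.
"""

from subpathrx import SyntheticSpec, simulate_study

spec = SyntheticSpec(seed=1)
study = simulate_study(spec, n_disease_subpathways=3, n_active_molecules=3)

print(f"cohort: {study.expression.values.shape[0]} genes x "
      f"{study.expression.values.shape[1]} samples")
print(f"pathways: {len(study.pathways)}, mined sub-pathways: {len(study.catalogue)}, "
      f"pathway gene universe: {len(study.catalogue.gene_universe)}")
print(f"planted DE genes: {len(study.truth.de_genes)}")
print(f"planted disease sub-pathways: {sorted(study.truth.disease_subpathways)}")
active = {m: sorted(v) for m, v in study.truth.perturbed_map.items() if v}
print(f"active molecules: {active}")
# Everything above is ground truth: downstream stages must recover the
# disease sub-pathways from expression alone and rank the active molecules
# above the 17 inert ones.
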