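"""Hypergeometric sub-pathway enrichment of a disease signature.

The DEG set of the cohort is tested against every mined sub-pathway; the
disease arm keeps sub-pathways with raw p < 0.01.
"""

from subpathrx import (SyntheticSpec, enrich_signature, select_degs,
                       simulate_study, t_test_genes)

study = simulate_study(SyntheticSpec(seed=3), n_disease_subpathways=3)
degs = select_degs(t_test_genes(study.expression), cutoff=0.1)

result = enrich_signature(degs, study.catalogue, threshold_mode="p", cutoff=0.01)
print(result[["subpathway_id", "N", "K", "n", "x", "p"]].round(6).to_string())
planted = study.truth.disease_subpathways
recovered = set(result["subpathway_id"]) & planted
print(f"\nplanted disease sub-pathways recovered: {len(recovered)}/{len(planted)}")
# N is the pathway gene universe, K the sub-pathway's gene count, n the DEG
# signature inside the universe, x their overlap; p is the exact
# hypergeometric upper tail P(X >= x).
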