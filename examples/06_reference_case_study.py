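"""Inspect the packaged reference results of the AS case study.

The published analysis of GSE25101 (ankylosing spondylitis, 16 patients vs
16 controls) against 130 KEGG pathways and 6,100 connectivity-map instances
reported 35 disease-enriched sub-pathways in 18 entire pathways and 15
candidate molecules. The tables ship with the package and anchor the
candidate-table output format.
"""

from subpathrx import load_reference_candidates, load_reference_subpathways
from subpathrx.reference import reference_summary

sub = load_reference_subpathways()
print("disease-enriched sub-pathways per entire pathway:")
print(sub.groupby("pathway_name").size().sort_values(ascending=False).head(5).to_string())

cand = load_reference_candidates()
print("\ntop candidate molecules:")
print(cand.head(5).to_string(index=False))

print("\nsummary:", reference_summary())
# anisomycin (8 overlapping sub-pathways) and the HDAC inhibitors vorinostat
# and trichostatin A (5 each) head the published ranking.
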