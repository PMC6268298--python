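# Methods

## The model

The analysis treats a pathway as an undirected simple graph whose nodes are
enzymes/genes (a node may carry several gene IDs, as KGML entries do, or
none for compounds). Two definitions of "sub-pathway" circulate for this
kind of analysis: linear receptor-to-transcription-factor paths, and
k-cliques in the social-network sense. The published parameterization
("k = 3") belongs to the k-clique definition, so that is what the miner
implements; relation-based signaling graphs are still parsed and built so
that both metabolic and signaling pathways can be mined with the same
machinery.

A **k-clique sub-pathway** is a maximal node set in which every pair lies
within shortest-path distance k *in the parent graph* (the ambient-distance
"n-clique" of social network analysis, not the "n-clan" whose diameter is
measured inside the sub-graph). This choice makes the construction exact:
build the distance-k closure by breadth-first search, then enumerate the
maximal cliques of the closure with Bron–Kerbosch with pivoting
(`networkx.find_cliques`). Tests verify the combination against exhaustive
subset enumeration on hundreds of random graphs of up to 12 nodes.
Sub-pathway IDs are `"<pathway>_<n>"` with n assigned by (size descending,
lexicographically smallest member node): deterministic for a given graph,
but deliberately *not* the numbering of any other tool, so IDs like
`path:04110_16` in the packaged reference tables are opaque labels here.
Identical gene sets arising from different node sets are kept as distinct
sub-pathways. Singleton components are reported (no size filter by
default; `min_size` is available).

**Metabolic graphs** connect two enzymes when their reactions share a
compound, with substrates and products pooled — direction is ignored
because the graph is undirected. **Signaling graphs** symmetrize KGML
relation edges; a compound node mediating a relation chain is collapsed
into direct edges between all pairs of its gene neighbours, then dropped.
Nodes without gene annotation never contribute to sub-pathway gene sets but
may mediate edges.

## Statistics

- **Disease DEGs**: per-gene two-sample t-tests, pooled variance by default
  ("classical" t-test; Welch via `equal_var=False`), two-sided (candidate
  molecules act in both directions, so sidedness is not assumed).
  Benjamini–Hochberg step-up across all tested genes; the 0.1 cutoff is
  applied to the *adjusted* p by default — computing BH and then
  thresholding raw p would make the correction decorative — with a flag to
  switch to raw p, since published gene counts of this design are ambiguous
  about which was used. Degenerate genes: zero variance in both groups with
  equal means gives t = 0, p = 1; with unequal means the p-value is floored
  at the smallest positive double and logged.
- **Enrichment**: exact hypergeometric upper tail (scipy's log-space
  survival function; brute-force rational-arithmetic tail summation as the
  test oracle). The universe is the set of genes annotated to the pathway
  collection, not the whole array (the convention of pathway-structure
  enrichment tools; an explicit `universe=` override is available), and
  signatures are intersected with it before testing. Sub-pathways with zero
  overlap are not reported (their p is 1) and by default do not count
  toward the BH family; `adjust_over_all=True` widens the family to every
  sub-pathway. The disease arm filters on raw p < 0.01 and the drug arm on
  FDR < 0.005 — the asymmetry mirrors the published procedure and both
  cutoffs are plain config fields.
- **Molecule DEGs**: the published procedure says only that a DEG analysis
  was run per molecule; here it is a paired one-sample t-test on
  treatment-minus-control differences across a molecule's instances
  (pairing matches the instance structure of connectivity-map data), BH per
  molecule (each molecule is its own testing family), adjusted p < 0.1.
  Molecules with a single instance fall back to an absolute log-difference
  threshold (default 1.0) because a t-test is undefined there. Test,
  cutoff, and threshold are all config-exposed.
- **Overlap significance**: no formula is published for the candidate
  p-values; the minimal model consistent with "significant overlapping
  sub-pathways" is adopted — hypergeometric over the mined sub-pathway
  universe with K = |disease set|, n = |molecule set|, x = their overlap.
  Fisher's two-sided exact test and a universe restricted to
  disease-or-drug-enriched sub-pathways are available via config; neither
  variant is claimed to reproduce published candidate p-values, which
  depended on external database snapshots. Sub-pathways are treated as
  exchangeable units in this test although their gene content is
  correlated (overlapping cliques); this is a known statistical caveat of
  the set-overlap framing. Candidates are not p-filtered (published
  candidate lists include p ≈ 0.05); every molecule with x ≥ 1 is ranked.

## The synthetic generator

`SyntheticSpec` defaults define the standard desk-scale scenario: 1,000
genes, 16 vs 16 cohort, 5% of genes differentially expressed with a
standardized shift of 2 (in units of the per-gene noise SD, default 1.0 on
a log2-intensity scale with baselines ~N(7, 1)), 20 pathways of 5–12 nodes,
20 molecules × 10 instances, 2 perturbed sub-pathways per active molecule.
The cohort size mirrors the AS study; gene, pathway and molecule counts are
scaled down from the real databases (≈48k probes, 130 pathways, 1,309
molecules) to keep replicate experiments cheap while leaving dozens of
sub-pathways competing in each enrichment.

Noise is Gaussian, equal variance in both groups — deliberately matching
the downstream t-test's assumptions so calibration tests are interpretable.
Pathway graphs are random connected graphs (uniform random recursive tree
plus `size // 2` extra edges), chosen to exercise the miner on varied
clique structure rather than to mimic scale-free pathway topology. Nodes
carry one gene by default; `genes_per_node` exercises the multi-gene-node
case the enrichment must tolerate.

Instance pairs share a within-pair noise component: a fraction
`pair_correlation` (default 0.5) of each column's noise variance is common
to a treatment profile and its vehicle control, so paired differences have
SD `sqrt(2·(1−ρ))·noise_sd`. This models what makes paired instances
informative in real perturbation screens — treatment and control come from
the same culture and batch — and is the reason a paired test outperforms an
unpaired one here. Cross-instance batch structure is *not* modelled, and
the default of 0.5 (an even split between shared and independent
variation) is a modelling choice, not an estimate from real data.

`simulate_study` couples the pieces: it picks disease sub-pathways (at
least 3 genes each), plants their genes as DE (topping up with random genes
to reach `round(frac_de·n_genes)`; if the planted genes already exceed that
count, they all stay DE), and assigns a subset of molecules to perturb
sub-pathways drawn from the disease set, the rest perturbing nothing. All
randomness flows from one seed through `numpy.random.SeedSequence` spawns,
so identical specs give bit-identical studies.

What passing on this generator does **not** show: robustness to
heavy-tailed or heteroscedastic noise, probe-level artefacts and
normalization residue, correlated genes outside planted sub-pathways,
realistic pathway topology, dose/cell-line heterogeneity across instances,
or molecules that perturb disease-adjacent (rather than identical)
sub-pathways.

## Numerical and design notes

- Hypergeometric p-values are clamped to (0, 1] after the log-space tail
  computation to absorb round-off.
- BH is `statsmodels.multipletests(method="fdr_bh")` behind the package's
  `adjust_bh`; the step-up formula is evaluated directly in the tests as an
  independent oracle. A worked consequence of the formula worth noting:
  with all m p-values equal, the minimum of m·p/j over j ≥ i is attained at
  j = m, so every adjusted value equals p itself.
- Candidate ranking breaks p ties by descending overlap count, then
  molecule ID, so output order is total and stable; all CSV writers sort on
  stated keys, making rerun outputs byte-identical (checked in tests).
- `run_full` writes a manifest (package version, config, config hash, seed,
  per-stage counts). A run with zero disease-enriched sub-pathways is a
  valid outcome, flagged with a notice and a distinct CLI exit code (3)
  rather than an error.
- The reference tables transcribe the published AS results verbatim,
  including one oddity: niclosamide and parthenolide are both listed under
  DrugBank ID DB06803. The transcription preserves the source; the
  annotation joiner rejects duplicate *names*, not duplicate IDs.

## Known limitations

- Published headline counts (3,280 disease DEGs; 233 drug sub-pathways in
  107 molecules; the exact Table p-values) are not reproducible without the
  June-2011 KEGG snapshot, the original CMap build, and the exact
  preprocessing stack, and are therefore not asserted anywhere; the
  reference tables are fixtures, not recomputation targets.
- KGML parsing covers entry/relation/reaction elements and a compact
  synthetic dialect; organism-specific ID mapping, live KEGG downloads, and
  array preprocessing (RMA et al.) are out of scope — inputs are assumed
  normalized and log-scaled.
- The enrichment model ignores gene–gene correlation and sub-pathway
  overlap; p-values are exact under independent sampling, optimistic
  otherwise.
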