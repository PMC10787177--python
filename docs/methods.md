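# Methods

This document records the models implemented in `altppi`, the default
parameters and why they were chosen, the numerical decisions that affect
results, and the known limits of the synthetic-study generator.

## 1. Expanded protein catalog

`altppi.catalog.ProteinCatalog` holds records of two categories:

- **refProt** — one annotated protein per gene (`P_<gene>`); its entity for
  counting purposes is the *gene*, so isoform-level evidence aggregates to
  gene level.
- **altProt** — a protein from a non-canonical ORF (`IP_<number>`); it is its
  own counting entity. Three annotation structures are generated:
  *pseudogene-derived* (a mutated, truncated copy of a parental refProt —
  the case that creates shared tryptic peptides), *dual-coding* (an
  independent short ORF hosted on a refProt transcript) and *ncRNA-derived*.

Tryptic digestion uses `pyteomics.parser` rules (cleave after K/R, not before
P), up to 2 missed cleavages, peptide length 8–30. Peptide-to-protein
matching is exact substring matching after I/L normalization (isoleucine and
leucine are isobaric and indistinguishable by mass, so both are mapped to a
common letter before comparison).

## 2. Synthetic study generator (`altppi.simulate`)

The generator emulates the statistical structure of a large plate-based
AP-MS screen. It does **not** simulate chromatography, fragmentation or
search-engine scoring; it directly emits identified-peptide evidence rows
(`run_id, bait_id, peptide, matched_accessions, psm_count, ...`).

**Ground truth.** `n_complexes` complexes of size `complex_size_range` are
drawn from disjoint gene sets; with probability `altprot_complex_prob` a
complex additionally recruits one altProt. True edges are the clique
expansion of each complex. Baits are complex members; each bait is run in
`replicate_count = 2` technical replicates.

**Plate design.** Baits are assigned to 96-well plate batches
(`plate_size = 96`) in round-robin order, so every plate holds a balanced
cross-section of baits. With sequential filling, a 100-bait study would
produce one plate of 96 and one of 4; leave-one-plate-out cross-validation
then scores 96 % of the data with a model trained on 4 baits' pairs, which is
not how a real multi-plate screen behaves (a comparable full-scale screen
spreads thousands of baits over dozens of plates, every fold large). The
round-robin assignment restores that structure at small scale. This is a
design-emulation decision, fixed before results are read, not a tuning knob.

**Counts.** A true interactor's PSM count in a run is negative binomial with
mean `negbin_mean_true = 30` scaled by a per-protein log-normal(0, 0.5)
abundance factor, dispersion `negbin_dispersion = 3` (variance μ + μ²/3,
matching the strong overdispersion of spectral counts). The bait itself gets
a 3× mean so it dominates its own runs. `contaminant_pool_size = 50` sticky
proteins each carry a per-run detection probability drawn from
log-normal(−2.2, 1.0) clipped to [0, 0.8] — a frequency-weighted background
where a few contaminants appear in a large fraction of runs, most rarely.
Per-protein PSM totals are spread over that protein's distinct tryptic
peptides.

**Randomness.** `SimulationParams.seed` feeds a `numpy` `SeedSequence` that
spawns one child stream per subcomponent (catalog / truth / design / counts),
so changing one stage's parameters cannot reshuffle another stage's draws.

**Limitations.** Peptide matching is substring-based, so it cannot produce
chance peptide sharing between unrelated sequences (only pseudogene-parent
sharing is modeled); there is no decoy/FDR model for identifications, no
missing-value structure beyond Bernoulli contaminant detection, no
protein-level abundance correlation between complex members, and the altProt
recruitment model (at most one altProt per complex) is simpler than real
complex composition.

## 3. Spectral counting and detection rules (`altppi.counts`)

Peptide assignment is asymmetric to protect altProt calls from canonical
explanations:

- peptide matches **only refProts** → each matched gene is credited;
- peptide matches **only altProts** → each matched altProt is credited;
- peptide matches **both** → only the refProt genes are credited; the
  altProts get nothing.

A peptide is *unique* if it credits exactly one entity of its credited
class. Detection filters: an **altProt** is kept only if some peptide unique
to it appears in ≥ 2 technical replicates of the same bait experiment; a
**gene** is kept only with ≥ 2 distinct unique peptides and presence in ≥ 2
replicates. Designs with a single replicate per bait are flagged with a
warning because the replicate-based rules then cannot fire.

## 4. CompPASS statistics (`altppi.compass`)

With `X[i, j]` the mean PSM of prey *j* over bait *i*'s replicates (zeros
included over all *k* baits):

- `z = (X − μ_j) / σ_j` with σ the **sample** SD (ddof = 1); a constant prey
  (σ = 0) gets z = 0 instead of NaN so it cannot poison the classifier.
- `wd = sqrt(X · ((k / f_j) · ω_j) ** p)` with `f_j` the number of baits
  detecting the prey, `ω_j = max(1, σ_j/μ_j)` and `p` the number of
  replicates in which the pair was seen.
- replicate entropy uses pseudocount 1/R:
  `q_r = (c_r + 1/R) / Σ(c_s + 1/R)`, entropy in bits, maximum `log2 R` for
  perfectly even replication.

Nine features per candidate (bait, prey) pair (the bait's own gene is
excluded): z, wd, entropy, reproducibility (p/R), prey frequency (f/k),
`log1p` mean PSM, bait ratio (prey PSMs over the bait's own PSMs), plate
frequency (fraction of same-plate baits detecting the prey — a batch-effect
signal) and mean unique-peptide count.

## 5. HCIP classification (`altppi.hcip`)

A Gaussian Naive Bayes classifier (`sklearn`, `var_smoothing = 1e-9`) is
trained with **leave-one-plate-out** cross-validation: each pair's posterior
comes from a model that never saw its plate, so plate-level batch effects
cannot leak into the score. Labels come from a reference edge list (for
synthetic studies, the planted truth). If a training fold contains a single
class, the fold's pairs receive that class's prior as posterior and a
warning is raised.

Features are used raw. A log transform of the heavy-tailed features (wd,
unique peptides) was evaluated and rejected: `sklearn` adds
`var_smoothing × max-feature-variance` to every feature's variance, so wd's
large variance usefully regularizes the near-degenerate features; shrinking
it degraded cross-validated ranking sharply.

Threshold selection scans a grid of 200 posterior values plus every observed
posterior and computes Jaccard, precision, recall and F1 against the
reference; policies `f1`, `jaccard` and `precision_at_recall` pick the
operating point, with ties resolved toward the smaller (more inclusive)
threshold and a warning emitted.

## 6. Network analysis (`altppi.network`)

**Assembly.** HCIP pairs become an undirected graph with gene nodes
(refProts) and accession nodes (altProts); self-pairs are dropped.

**Degree power law.** The discrete power law
`P(x) ∝ x^(−α), x ≥ xmin` is fit by **exact maximum likelihood**: minimize
`n·ln ζ(α, xmin) + α·Σ ln x` (Hurwitz zeta via `scipy.special.zeta`, bounded
scalar minimization on (1.0001, 25), `xatol = 1e-9`). The familiar
closed-form approximation `α ≈ 1 + n / Σ ln(x/(xmin−0.5))` was implemented
first and rejected: it is derived from the continuous distribution and is
severely biased at small `xmin` (it converges to ≈ 2.05 for a true α = 2.5
at `xmin = 1`), while the exact MLE recovers the truth (2.525 on a 10 000
sample). When `xmin` is not given, it is chosen to minimize the
Kolmogorov–Smirnov distance between fitted and empirical CDFs over the tail.
Fits on very small or low-diversity samples raise, and fits with fewer than
50 tail points are flagged low-confidence.

**Separation.** Shortest-path histogram over unordered node pairs (BFS);
unreachable pairs are excluded from the mean and reported separately, since a
bait-centric HCIP network is typically a forest of complex-sized components
and averaging infinities is meaningless.

**Eigenvector centrality.** Power iteration on `A + I` — the shift makes the
matrix primitive so iteration converges on bipartite/periodic components —
normalized to max 1 per connected component. The altProt effect measure
(`evc_delta`) recomputes EVC with all altProt nodes removed and reports the
per-node change.

**Complex recovery.** A known complex is scored over its baited subunits: the
fraction of its other members found adjacent to a baited member in the HCIP
network; complexes with no baited subunit are excluded rather than scored 0.

**Pseudogene-parent alignment.** Global Needleman–Wunsch via Biopython's
`PairwiseAligner`, BLOSUM62, gap open 11 and extend 1 (a length-L gap costs
11 + L; end gaps are penalized — the convention under which `PEPTIDE`
aligned to itself scores 39). Aligning against an empty sequence scores
−(11 + L).

## 7. Communities and enrichment (`altppi.communities`)

**MCL** is implemented directly (no suitable library in the environment):
add self-loops, column-normalize, iterate expansion (matrix square) and
inflation (elementwise power 2.0, renormalize) with pruning at 1e-5 until
convergence; clusters are read off attractor rows and merged by union-find;
clusters with fewer than 3 members are discarded (reported, not silently
dropped).

**Enrichment** uses the hypergeometric survival function
(`scipy.stats.hypergeom.sf(k−1, N, K, n)`) with Benjamini–Hochberg control
(`statsmodels` `fdr_bh`); a result is *significant* only if the raw p-value
is below α **and** BH rejects. Applications: inter-cluster link enrichment
(observed links between two clusters vs. the urn of all possible
inter-cluster pairs), cluster–disease association over a gene–disease table
(clusters containing an altProt are flagged, altProt nodes themselves are
skipped since disease annotations are gene-level), and ontology-term
enrichment with annotations propagated to ancestors (cycle detection raises;
the root term is always p = 1).

## 8. Spectral validation (`altppi.spectra`)

Observed vs. synthetic-peptide spectra are compared by greedy nearest-m/z
peak matching within 0.02 Da (each peak used at most once, closest pairs
first), Pearson correlation of square-root-transformed intensities of the
matched peaks (the square root stabilizes the intensity variance), the
normalized contrast angle, and a strict `> 0.6` correlation cutoff for
calling the identification supported. Zero-variance matched intensities
raise rather than returning NaN. MGF files are read and written with
`pyteomics.mgf`.

## 9. Validation strategy

Every statistical primitive is tested against an independently coded oracle
that shares no code with the implementation: a loop-based CompPASS
reimplementation, exact hypergeometric enumeration with `math.comb`, a
reference BH step-up, a three-matrix (Gotoh) affine-gap aligner,
Floyd–Warshall for path lengths, and dense eigendecomposition for
centrality. Behavioral checks on the generator (contaminant detection rates
against binomial bands, bait enrichment, determinism, substring containment
of every matched peptide) and an end-to-end acceptance suite
(`tests/test_acceptance.py`) complete the suite. `scripts/acceptance.py`
reproduces the headline numbers from a single seed.
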