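# Methods

This note documents the models and procedures implemented in `redunet`, the
parameter choices that matter, what the synthetic generator does and does not
emulate, and the numerical decisions taken where the design was open.

## 1. Abundance model

Gene abundance is RPKM: `count / (length_bp / 1e3) / (total_mapped / 1e6)`.
Samples with zero mapped reads and genes without a length are excluded with a
logged diagnostic rather than propagating NaNs. Relative abundance is
row-normalized within an explicitly chosen feature universe (all genes, or the
genes of one functional class), because the normalizing denominator changes
the meaning of "share" and should never be implicit.

The functional catalog maps each KEGG-style level-2 category to `broad`
(present in essentially all cells) or `specialized` (restricted to a subset of
taxa; here the nitrogen-cycle categories). The shipped default — 15 broad +
4 specialized — is a documented stand-in with exactly that class balance; the
mapping is fully configurable through `FunctionalCatalogConfig`, and
`classify_functions` refuses silently-unmapped categories.

Top-k selection ranks features by mean relative abundance across all samples
(ties broken by feature id) so every downstream stage sees one shared feature
set; a per-sample top-k union mode exists for the gene-level network
convention of selecting the most abundant genes per sample.

## 2. Synthetic community

The generator emulates a 2×2 grazing × phosphorus factorial with 4 replicate
blocks (16 samples) over 190 species:

* **Dominants.** Species A (grazing/P-sensitive) and R (complementary) hold
  `dominant_share` = 0.50 of relative abundance together and carry genes in
  *all* categories. Per treatment t, A's share is `0.25 − δ(t)` and R's is
  `0.25 + δ(t)`, with δ = 0 (control), 0.04 (single treatments, "relatively
  weak"), 0.10 (G+P+, the strongest response).
* **Conservation.** A and R share one category-allocation profile, so any
  abundance that A loses in a category R gains — per-category functional
  totals are constant across treatments in expectation. Setting
  `conservation=False` draws separate profiles, breaking the invariance so
  ANOVA can detect large shifts (used as a power control).
* **Noise species.** 188 species with Dirichlet shares around a geometric
  decay (ratio 0.75) that flattens past rank 30; the flattening keeps the
  rare tail present at small but detectable abundance (a pure geometric decay
  underflows to exact zeros, which would delete the tail from every
  prevalence-filtered analysis). The head decay puts >95% of abundance in the
  top-12 species, matching the study community. Each noise species carries
  all broad categories and each specialized category independently with
  probability 0.2, sizing the specialized gene pool near 300 genes.
* **Gene structure.** Two genes per species per carried category, assigned to
  one of 6 pathways per category with geometrically skewed sizes (ratio 0.6),
  mirroring the heavy tail of KEGG pathway gene counts. Gene lengths are
  uniform on 100–3000 bp; per-sample totals are scaled to 1e5 RPKM.
* **Noise model** (all layers treatment-independent, applied multiplicatively
  on the log scale, iid across samples):
  * per-pathway, per-sample guild factor, sd 0.15, entering each gene with
    sensitivity 1 ± 0.1 — genes of one pathway co-fluctuate across replicate
    soils, which is what gives real co-occurrence networks their modules;
  * residual per-sample factor, sd 0.05, with per-species sensitivities
    1 ± 0.1 — small because RPKM units are depth-normalized, so no strong
    global sample factor survives in real tables;
  * per-species, per-sample fluctuation, sd 0.02, shared by a species' genes;
  * iid per-gene noise, sd `sigma` = 0.1.

  Together these move species' relative shares by well under 1% — the study
  reports the same stability for non-dominant species — while producing
  gene–gene correlation structure with within-pathway r ≈ 0.7 and
  between-pathway r ≈ 0.1.

What the generator does **not** emulate: sequencing-count discreteness and
zero-inflation (abundances are continuous lognormal), phylogenetic
relatedness among species, any mechanistic inhibition/bistability dynamics
between the dominants, block (plot) effects, and gene-length bias beyond the
RPKM definition. A green end-to-end test therefore establishes that the
pipeline recovers the planted dominance/conservation structure from
realistically noisy tables — not that it would survive every pathology of
raw sequencing data.

All randomness flows from one seed through named substreams (one per stage),
so any stage can be regenerated in isolation with identical values.

## 3. RMT threshold selection

The co-occurrence cutoff is chosen by the random-matrix-theory transition.
For each scanned cutoff (from 1.0 downward in steps of 0.01) the correlation
matrix is thresholded (|r| below the cutoff zeroed; Pearson on
log10(RPKM + 1) by default), rows with no surviving off-diagonal entry are
dropped, and the nearest-neighbour spacing distribution of the eigenvalues is
computed:

* **Unfolding** fits a cubic least-squares spline (15 interior knots at
  spectrum quantiles) to the empirical cumulative spectral density;
  spacings are consecutive differences of the unfolded levels, normalized to
  mean 1. Numerically degenerate eigenvalues (within 1e−8) are collapsed
  first: thresholded sparse matrices otherwise flood the NNSD with exact-zero
  spacings that reflect structural degeneracy, not level statistics.
* **Goodness of fit** is a chi-square against Poisson `exp(−s)` and the
  Wigner surmise `(πs/2)exp(−πs²/4)` on 30 equal bins over [0, 3] plus an
  overflow bin, adjacent bins pooled to expected counts ≥ 5, dof = bins − 2.
* **Transition rule.** The scan stops at the first cutoff whose NNSD rejects
  Poisson (p ≤ 0.05) *and* fits Wigner better than Poisson; the previous
  scanned cutoff is returned. The directional condition matters: at high
  cutoffs, half-assembled correlation blocks produce *clustered* spectra (an
  excess of small spacings — the opposite of GOE repulsion) that also reject
  Poisson but lie on the fragmented side of the transition. Cutoffs with
  fewer than 30 distinct eigenvalues cannot be assessed and count as
  non-rejecting; if no cutoff is ever assessable the scan errors, and if the
  transition never arrives (featureless input) the lowest scanned cutoff is
  returned with a warning.

Edges use |r| ≥ threshold with the sign kept as an attribute; isolated nodes
are dropped and logged. A prevalence filter (genes present in ≥ 50% of the
treatment's samples) runs before correlation. Because four replicates give
fragile correlations, network construction warns below six samples; synthetic
designs for network analyses use eight replicates per treatment.

Index panel definitions: avgK = 2L/N; avgCC = mean over nodes of the local
clustering coefficient (0 for degree < 2); GD = mean geodesic over connected
ordered pairs; E = mean of 1/d over all ordered pairs with 1/∞ = 0;
HD = 1/E; Q from an in-package CNM agglomeration (merge the connected pair
with the largest ΔQ, lexicographic tie-break, return the best partition seen
along the merge sequence — verified against exhaustive search on all
≤ 8-node fixtures and against the networkx modularity function).

## 4. Natural connectivity and the removal experiment

λ̄ = ln((1/N) Σ exp(λᵢ)) is computed with a log-sum-exp, so dense graphs
with λ_max in the hundreds do not overflow. λ̄ strictly increases with any
edge addition (property-tested), is 0 for an edgeless graph, and is evaluated
on the full possibly-disconnected surviving graph at each removal step.

The removal experiment draws, per replicate, one uniformly random removal
order without replacement and recomputes λ̄ after every removal (0 … m_max,
default min(200, N−2)); the default 100 replicates are aggregated as
mean ± sd, and `replicates=1` reproduces the single-trajectory style of the
original figures.

**Scale caveat.** The study prints intact natural-connectivity values of
~134–150, far above what ln-scale λ̄ yields at plausible network sizes
(tens). The normalization its pipeline used is not recoverable; this package
implements the standard spectral definition and treats the printed values as
incomparable.

**Trend classification** fits (a) a straight line and (b) a continuous
two-segment piecewise line (breakpoint searched over every integer removal
count in the middle 80%) to the mean trajectory, and prefers the line when
AIC(a) ≤ AIC(b) + 4, or when the fitted segments are practically equivalent
(slope magnitudes within a factor 1.5). Three numerical choices deserve
explanation:

* the AIC uses an effective sample size n_eff = n / (1 + 2 Σ ρ_k) from the
  piecewise residuals' autocorrelation (initial-positive-sequence
  truncation), because trajectory points share almost all of their surviving
  subgraph and an iid AIC at n = 201 treats a <2%-of-range systematic wiggle
  as decisive evidence; with independent noise n_eff ≈ n and planted-trend
  recovery is unaffected;
* the margin 4 (not the conventional 2) compensates the piecewise model's
  grid-searched breakpoint, which makes it more flexible than its two extra
  parameters suggest — at margin 2 a true straight line is misclassified
  ~6% of the time, at margin 4 ~2%;
* the 1.5× practical-equivalence ratio encodes that a redundancy verdict
  ("gentle first, then steep") means a *material* bend — the canonical
  planted example bends 16-fold — not a statistically resolvable few-percent
  slope change whose direction is seed noise.

With these choices, planted linear, gentle-then-steep, and steep-then-gentle
trajectories are classified correctly in ≥ 98% of runs each, and the
synthetic specialized network is classified linear (no redundancy) across
seeds, reproducing the study's verdict.

## 5. Ordination and Procrustes

Bray–Curtis dissimilarity d(i,j) = Σ|xᵢ−xⱼ| / Σ(xᵢ+xⱼ) on relative
abundance. NMDS is scikit-learn's SMACOF with monotone (weak-tie) regression,
k = 2, best of 20 random restarts, stress reported as Kruskal stress-1;
coordinates are column-centered.

Symmetric Procrustes: both configurations centered and scaled to unit sum of
squares, optimal rotation from the SVD of XᵀY, M² = 1 − (Σ singular values)².
The protest permutation test row-permutes one configuration;
p = (1 + #{M²_perm ≤ M²_obs}) / (permutations + 1), default 999.

`concordance_pipeline` compares, per functional class, the top-20-species
composition within that class against the class's functional *gene*
composition (both as relative abundance). The functional side is gene-level
by default: when per-category totals are conserved — the very phenomenon
under study — category totals carry no treatment signal at all, and only the
gene-level functional profile retains the dominant-species axis that makes
the taxonomy–function comparison meaningful. Category-level profiles remain
available via `functional_level="category"`.

## 6. Treatment statistics

Per-category one-way fixed-effects ANOVA across the four treatments (scipy),
Tukey HSD via the studentized range (scipy), and an insert-and-absorb compact
letter display whose consistency with the pairwise p-matrix is asserted on
every call. A category with no variance anywhere is reported with the
degenerate convention F = 0, p = 1, all letters "a"; a treatment with fewer
than two replicates skips the category with a warning. Blocks are ignored in
the default model; no multiplicity correction is applied across categories
(each category is reported with its own letters), matching the reporting
convention the pipeline mirrors.

The reciprocal-shift report computes Δ_s(t) = mean share under t − mean share
under control per species, identifies the extreme decreasing/increasing
species per treatment, and scores complementarity
c = 1 − |Δ_dec + Δ_inc| / (|Δ_dec| + |Δ_inc|) ∈ [0, 1] (1 = exact
cancellation). Σ_s Δ_s(t) = 0 holds identically because shares sum to one.

## 7. Pipeline

`run_pipeline` executes simulate/load → profiles → stats → networks →
robustness → concordance, writing TSV/JSON outputs, the resolved config, and
a manifest (seed, input hashes, stage timings). Networks are built per
treatment on the 300 most abundant genes; the removal experiment runs on one
pooled specialized-function network across all samples (per-treatment runs
are available through the API, but four replicates per treatment make
correlation networks fragile). Identical config + seed reproduce every
numeric output byte for byte; only manifest timings differ.

## 8. Known limitations

* The RMT transition detector needs many weakly-coupled modules to see a
  Poisson regime; data dominated by one or two giant correlated blocks stop
  the scan at a high cutoff and yield small networks (this is a property of
  the method, observable on planted worlds).
* Greedy CNM modularity is a heuristic; it is exact on the shipped ≤ 8-node
  oracle fixtures but provably suboptimal on some graphs (e.g. the 8-cycle).
* NMDS stress depends on the tie convention in the monotone regression
  (weak/primary ties here, via scikit-learn); stress values from other
  software may differ slightly even at identical configurations.
* The natural-connectivity scale of the original figures is not reproducible
  (see §4); all robustness conclusions here are about trends, not levels.
* p-values from 199–999 permutations are granular; the +1-corrected floor is
  1/(permutations + 1).
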