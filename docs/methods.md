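# Methods

`fcnet` implements a graph-theoretic group analysis of pharmacologically
induced functional-network reconfiguration, together with a synthetic study
generator that makes the whole chain testable end to end. This note
documents the models, conventions, parameter choices and known limitations.

## Pipeline

For each subject-session the input is a T x N table of regional signals
(rows = time points, columns = labelled regions of interest). The stages
are:

1. **Band-pass filtering.** Each regional signal is demeaned and filtered
   with a zero-phase (forward-backward) Butterworth band-pass, order 2 by
   default. Presets use 0.01–0.15 Hz for the human-like design (TR 1.79 s)
   and 0.01–0.10 Hz for the rat-like design (TR 1.0 s). The band must lie
   below the Nyquist frequency implied by the sampling interval; violating
   bands raise an error naming the bound.
2. **Connectivity.** Pearson correlation between every pair of regional
   signals, Fisher z-transformed (z = atanh r). The diagonal is zero;
   zero-variance regions and |r| = 1 off-diagonal pairs are rejected as
   degenerate input.
3. **Proportional thresholding.** For a density d in (0, 1), the strongest
   k = round(d * N(N-1)/2) pairs (signed z ranking by default; |z| ranking
   available) become the edges of an undirected, unweighted graph. Every
   network in a study therefore has the same number of links, removing
   global correlation-strength differences. Rounding is half-even so edge
   counts are reproducible bit-exactly; ties at the cutoff are broken by
   lexicographic (row, column) order and logged, since the retained set
   then depends on node order rather than data.
4. **Graph metrics** (binary, per density): Watts–Strogatz mean local
   clustering C; characteristic path length L as the mean hop distance over
   *reachable* ordered pairs, with unreachable pairs excluded and counted
   (an edgeless graph has no defined L and raises); Latora–Marchiori global
   efficiency E_glob (mean 1/d with 1/inf = 0, robust to fragmentation);
   local efficiency E_loc (mean over nodes of the global efficiency of the
   neighbourhood-induced subgraph, node excluded, degree < 2 contributing
   0); and small-worldness sigma = (C/C_rand)/(L/L_rand), where C_rand and
   L_rand are means over a seeded null ensemble.
5. **Null ensemble.** Default: Maslov–Sneppen degree-preserving rewiring,
   100 nulls, 10 swap *attempts* per edge (acceptance logged); an
   Erdos–Renyi G(N, M) null with matched node and edge counts is the
   config-switchable alternative. Connectedness is deliberately not
   enforced — rejection sampling for connectivity would bias the ensemble —
   and null path lengths use the same reachable-pairs convention as data.
6. **Motif census.** Counts of *induced* connected subgraphs on 3 and 4
   nodes, classified into the eight isomorphism classes of connected
   undirected graphs of that size: 3-path, triangle, 4-path, 4-star,
   4-cycle, paw, diamond, K4. The cyclic family (contains a cycle, i.e.
   edges >= nodes) is {triangle, 4-cycle, paw, diamond, K4}; the acyclic
   family (trees) is {3-path, 4-path, 4-star}. For graphs on <= 4 nodes
   the pair (edge count, sorted degree sequence) is a complete isomorphism
   invariant, which both counting routes use. The default route computes
   all eight induced counts from exact matrix identities (triangle counts
   from diag(A^3), wedge counts from degrees, 4-cycle counts from tr(A^4),
   common-neighbour counts per edge, then inclusion–exclusion from
   non-induced to induced counts); an ESU-style connected-subgraph
   enumeration is provided as a second, independent route. Tests assert
   both equal a brute-force all-subsets oracle. Frequencies are raw counts:
   the group comparison is at matched density, where raw counts are
   directly comparable; a per-total normalisation is not applied.
7. **AUC summarisation.** Each metric and motif count is computed on the
   density grid 0.05 to 0.20 in steps of 0.01 (16 levels) and reduced to
   its trapezoidal area under the curve, one threshold-free scalar per
   subject and measure. Undefined values (e.g. sigma when the null
   ensemble of a very sparse graph is triangle-free) abort the AUC with the
   offending densities named, rather than being imputed — the remedy is to
   raise the density floor, which is also the rationale for the 0.05
   default floor.
8. **Group inference.** Paired design: one-sample t-test on per-subject
   drug-minus-placebo AUC differences (df = n-1). Two-group design:
   classical pooled-variance independent-samples t-test (df = n1+n2-2);
   Welch is not the default because the classical test is the plain
   reading of an "independent samples t-test". P-values are two-sided and
   Benjamini–Hochberg FDR-adjusted within separate families: the five
   graph metrics, the eight motif classes, and the two cyclic/acyclic
   totals.
9. **Network Based Statistics (NBS).** Edge-wise t statistics (paired or
   two-group as above, vectorised over all N(N-1)/2 edges; zero-variance
   edges get t = 0 with a logged warning), a primary threshold t* on the
   edge statistics, connected components of the supra-threshold graph, and
   FWER-corrected p-values from the permutation distribution of the
   *maximum* component extent (edge count). Paired permutation = per-subject
   sign flips of the difference matrices, enumerated exactly when 2^n does
   not exceed the requested permutation count; two-group permutation =
   group-label shuffles. Sampled permutations use the add-one convention
   p = (1 + #{max >= observed}) / (1 + n_perm) so p > 0 always; exact
   enumeration uses the plain fraction over the full group (which contains
   the identity). The primary threshold has *no default*: component-level
   inference is conditional on it, so it is a required analysis input, and
   outputs echo the minimum supra-threshold t. Component "size" is extent
   (edge count); per-node "altered connection" counts are node degrees
   restricted to significant components. The default tail is `greater`
   (increased connectivity); `two_sided` runs both one-sided passes with a
   Bonferroni factor of 2.

## Synthetic study generator

No suitable public recordings exist for this design, so the generator is a
first-class, tested component that defines the study conditions.

**Covariance model.** Regions are partitioned into near-equal modules. A
latent edge appears between two regions with probability `p_within` inside
a module and `p_between` across modules (one draw per latent structure,
shared by both conditions). The session covariance is

    Sigma = I + c * W / rho(W0),

where W0 is the 0/1 latent edge matrix, rho its spectral radius, c the
coupling, and W reweights within-module edges by (1 + delta_within) and
between-module edges by (1 + delta_between) for the session's condition.
Normalising by the spectral radius of the *baseline* matrix keeps the
condition deltas visible as absolute covariance changes; positive
definiteness is checked spectrally and violating configurations are
rejected rather than repaired.

**Time series.** Sessions are stationary AR(1) Gaussian processes
x_t = phi x_{t-1} + eps_t with eps_t ~ N(0, Sigma) and x_0 drawn from the
stationary distribution, so the sample covariance converges to
Sigma/(1 - phi^2). A single AR coefficient phi = 0.3 is shared by all
regions — the simplest temporal structure that makes the band-pass stage
consequential. No haemodynamic response, scanner noise or spatial structure
is modelled.

**Designs.** The paired (cross-over-like) design emits a placebo and a drug
session per subject sharing a per-subject lognormal multiplicative jitter
on the coupling (sd 0.1), which is what gives paired tests their power
advantage; the two-group design emits one session per subject, first group
placebo, second drug, with independent jitters. All randomness flows from
one master seed through `SeedSequence` spawn keys (subject index, session
index), recorded in the manifest, so any single session is reproducible in
isolation.

**Default study conditions.** The planted drug effect is delta_within =
+0.15, delta_between = -0.10: within-module coupling up, between-module
coupling down, the planted analogue of a shift toward more-segregated,
less-integrated processing. The defaults are 90 regions in 15 modules of
6, p_within = 0.95, p_between = 0.02, coupling = 0.95, paired n = 20
subjects, T = 300 time points. The latent geometry (small dense
communities with sparse bridges, per-edge within-module correlation ~0.17)
was chosen once, after exploring module geometries, as the configuration in
which the fixed deltas express most cleanly as topological segregation at
desk scale; the deltas are far larger than anything plausible in vivo, and
the defaults are calibrated for clear desk-scale recovery, not for matching
empirical effect sizes.

**What recovery does and does not show.** At these defaults, across
replicate studies the drug condition reliably shows lower global-efficiency
AUC, higher cyclic-motif AUC, lower acyclic-motif AUC, and higher
clustering — the segregation pattern. Small-worldness, however, reliably
*increases*: concentrating the fixed edge budget inside modules raises
C/C_rand faster than L/L_rand at every density, because the between-module
edges the drug demotes are replaced, at fixed density, by uniformly random
noise edges that are themselves shortcuts. This is a structural property of
the block-model generator combined with the reachable-pairs L convention
and degree-preserving nulls, and it persisted across every module geometry,
coupling and delta magnitude explored, under both null models. Empirical
reports of drug-induced sigma decreases plausibly involve hub-concentrated
connectivity increases and fragmentation-inflated path lengths, neither of
which this generator produces. The validation suite asserts the sigma
direction anyway and the assertion fails at the frozen defaults; it is kept
as an honest negative result documenting the generator's limitation.

## Numerical and implementation notes

- Distances are BFS hop counts (dense-adjacency kernel, JIT-compiled when
  `numba` is available, with an identical pure-Python/scipy fallback);
  metrics were cross-validated to 1e-10..1e-12 against networkx and
  Floyd–Warshall/subset oracles on every graph of the 7-node atlas and on
  random G(30, p) graphs.
- The rewiring kernel attempts `swaps_per_edge * |E|` swaps (attempts, not
  successes); a graph admitting no legal swap (e.g. complete) is returned
  unchanged with a warning. Ensembles are bit-reproducible given (graph,
  spec, seed).
- Machine-readable warnings (threshold ties, zero-variance edges, rewiring
  degeneracies) are emitted as one JSON object per log line.
- Recovery and calibration experiments correlate the simulated series
  directly, without the band-pass stage: the generator's innovation
  covariance is frequency-flat, so filtering cannot change the expected
  correlations and only shrinks the effective sample count (inflating
  per-edge noise ~1.5x under the human-like band, enough to wash out the
  deliberately subtle planted effect at desk-scale n). The filter itself is
  validated separately against FFT amplitude oracles, and the CLI exposes
  `--skip-bandpass` for data that are already filtered.
- Validation problem sizes: directional recovery uses 20 replicate studies
  at the default conditions with 4 nulls per density for sigma; t-test
  calibration uses 600 null studies of 60 regions, paired n = 6, T = 80,
  2 nulls (replicates whose sigma is undefined at the density floor are
  skipped and counted — a fraction of a percent); NBS calibration uses 200
  null studies of 60 regions, paired n = 12, T = 100, 500 permutations at
  t* = 3.0; planted-component recovery uses paired n = 20, 60 regions,
  1000 permutations, t* = 4.0, with a 10-edge planted component at +0.25
  Fisher-z. These sizes are the package's desk-scale choices; all scale up
  by configuration.

## Known limitations

- The generator's covariance has only direct (one-edge) dependencies; real
  functional connectivity has transitive correlation structure.
- Small-worldness recovery is structurally outside the generator's reach
  (see above); directions for C, L, E_glob, E_loc and motif families are
  recovered.
- Binary undirected analysis only: no weighted metrics, no partial
  correlation, no directed motifs, no motif normalisation against null
  ensembles, no lattice-referenced small-worldness variants.
- The characteristic path length of a fragmented graph is a biased
  (downward) summary restricted to reachable pairs; the unreachable-pair
  count is reported alongside, and E_glob is the fragmentation-robust
  integration measure.
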