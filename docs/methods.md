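# Methods

This note records the model assumptions, parameter choices and numerical
conventions behind `taxograsp`, and what the synthetic validation
experiments do and do not establish.

## Signal model of the synthetic generator

The generator (`taxograsp.synthetic`) emulates the structure of a
Ninapro-style acquisition: S subjects × G grasps × R repetitions, each
repetition `movement_s` seconds of movement alternated with `rest_s`
seconds of rest (defaults 6 repetitions, 5 s / 3 s), sEMG on 12 channels
at 2 kHz, a 22-sensor glove at 25 Hz.

**Planted structure.** Each grasp has an EMG activation-amplitude vector
(one value per channel, mV) and a glove posture vector (dimensionless),
generated by Brownian motion along the edges of a known binary
similarity tree: child = parent + N(0, σ²_tree·I) per edge, with
σ_tree = `profile_scale`. Roots are positive baselines (`emg_base_amp`,
default 0.3 mV — a typical forearm sEMG magnitude; `glove_base_amp` 1.0)
so that amplitudes and sensor deflections, which are magnitudes, stay
positive for moderate σ_tree. Grasps close in the tree therefore have
similar profiles *in expectation*; a single draw can invert individual
pairs (see "well-separated profiles" below).

**EMG.** A channel is zero-mean Gaussian noise amplitude-modulated by the
grasp's channel amplitude, plus an additive noise floor (`noise_sd`) and
an optional 50 Hz sinusoid (`powerline_amp`). Under this minimal model
RMS, MAV, IAV and WL all scale with the activation amplitude, which is
the only property the downstream statistics use. No motor-unit-level
detail or 20–450 Hz spectral shaping is modelled.

**Glove.** A sensor rises smoothly from the zero rest posture to the
grasp's posture value, holds, and returns. Small multiplicative
fluctuation of the held posture (`glove_tremor_sd`, default 0.02)
represents physiological tremor and grip adjustment; without it the hold
phase would be perfectly flat and waveform-length features would carry no
grasp information, which no real recording exhibits.

**Label convention.** The labelled movement block covers only the steady
(plateau) phase; the 100 ms raised-cosine on/off ramps (300 ms for the
glove) fall in the surrounding rest. This mirrors re-labelled movement
boundaries, which mark the actual movement rather than the cue, and
keeps transition transients out of the analysis windows.

**Variability hierarchy.** Three independent levels: `subject_sd`
(per-subject perturbation of the grasp profiles), `rep_sd`
(repetition-to-repetition motor variability around the subject's
profile) and the per-sample noise floors. All randomness flows from one
seed through per-subject spawned streams, so the generator is
deterministic given the configuration.

## Statistical pipeline

**Windowing.** 200 ms windows, 100 ms overlap, cut strictly inside
contiguous (grasp, repetition) label runs after synchronization to the
2 kHz grid; trailing partial windows are dropped so every window has the
same length T. Constant T is what makes IAV = T·MAV an exact identity,
and with the scale invariance of the Mahalanobis distance it forces the
IAV- and MAV-based trees (and supertrees) to coincide — a structural
invariant the acceptance run checks.

**Feature conventions.** ZC counts strictly opposite signs of
consecutive samples with |xₜ − xₜ₊₁| at or above a threshold; SSC counts
strict local extrema with at least one adjacent difference at or above a
threshold. Both thresholds default to 0 (pure sign counts) and are
configurable. For the TD family the last window of each repetition is
dropped so that the MAVS slope is defined on every retained row; MAVS is
never computed across a rest gap or repetition boundary.

**Grasp distances.** All windows of all repetitions are pooled per grasp
(the one-way MANOVA layout; no per-repetition averaging), giving group
means m_g and the pooled within-group covariance W with N − G degrees of
freedom. The distance clustered is the Mahalanobis distance itself, not
its square. If W is numerically singular (Cholesky failure or condition
number above 1e12 — e.g. the TD family on 22 glove sensors gives p = 110
columns, several of them constant on clean data), a ridge
W + λ·tr(W)/p·I with λ = 1e−6 (configurable) is applied and the event is
recorded on the result object.

**Clustering.** Plain O(G³) agglomeration with average (UPGMA), single
or complete linkage; UPGMA is the default because its ultrametric output
matches the tree model (all leaves equidistant from the root). Ties are
broken deterministically: among equal-distance pairs, the pair whose
(smallest member label, then the other cluster's smallest label) is
lexicographically smallest merges first. scipy's implementation is used
as a cross-check oracle on tie-free inputs, not in the pipeline, because
it does not guarantee this tie-break.

**SPR distance.** Exact rooted SPR distance via maximum agreement
forests of the ρ-augmented trees (a handle leaf attached above each
root). The search is iterative deepening over the number of cut edges k:
every k-subset of edges of the second tree is cut and the resulting
forest checked for agreement (each component equals the first tree's
restriction to its leaves, and the components' spanning subtrees are
pairwise vertex-disjoint there). Exponential in k but exact; at the
20-leaf scale of this problem and the small distances of coherent data
it is fast. Beyond `k_max` (default 12) a greedy forest yields an upper
bound flagged `exact=False`. Since all trees here share one leaf set,
the cluster-decomposition step of the general partial-overlap supertree
problem degenerates to a no-op and is not implemented.

**Supertree search.** Phase 1 seeds with the input tree of minimal total
SPR distance to the others (ties → lowest index). Phase 2 enumerates all
SPR rearrangements of the current supertree in canonical order (prune
positions in preorder, regraft positions in preorder, duplicates removed
keeping first occurrence) and accepts the move that most reduces the
total distance, first-best among equals, until no move improves. The
whole search is deterministic. Hill-climbing carries no global
optimality guarantee in general; on all exhaustive small-instance checks
(≤ 5 leaves, all 105 topologies enumerated) it attains the global
minimum.

**Tree edit distance.** The Zhang–Shasha dynamic program computes exact
*ordered* TED; the taxonomy trees are unordered, so both trees are first
canonicalized (children sorted by smallest descendant leaf label). This
canonicalization is the single most consequential convention for
reproducing printed distances and is applied uniformly. Internal nodes
share one null label, so renames effectively act on leaves; costs
default to 1/1/1. Exact unordered TED is NP-hard and out of scope.

**Robinson–Foulds.** Symmetric difference of the internal-node leaf-set
collections; used as the planted-tree recovery metric.

**Pair statistics.** `pairwise_stats` reports mean and *population* SD
(ddof = 0) over all unordered pairs, so the two-tree case is defined.

## Validation experiments and their scope

**Planted-tree recovery.** The principal end-to-end check: with
`subject_sd = 0`, small noise and *well-separated profiles*, every tree
the pipeline produces (subject trees, feature supertrees, modality
taxonomies, general taxonomy) must equal the planted tree (RF = 0).
Because Brownian evolution guarantees tree-structured similarity only in
expectation, "well-separated" is made operational:
`profile_tree_margin` runs UPGMA on the Euclidean distances of the drawn
effective profiles and returns the smallest ratio between the best
tree-*violating* merge candidate and the chosen merge, over both
modalities (0 if the draw itself contradicts the tree);
`find_separated_seed` scans seeds for a margin ≥ 1.15. The margin
absorbs the bounded geometric distortion between profile space and
measured Mahalanobis feature space (per-channel whitening weights,
clipping, estimation error). The recovery experiment uses 3 subjects and
6 grasps with `profile_scale 0.3`, baselines 3.0, `rep_sd 0.01`,
`noise_sd 0.03`, glove noise 0.05 and tremor 0.05 — a regime where the
within-group covariance is dominated by iid window-level noise and hence
estimated with thousands of degrees of freedom. (With repetition-level
variability dominating, W would carry only ~(R−1)·G degrees of freedom
in up to 110 dimensions, and whitening noise would scramble the
geometry — a real phenomenon, not an implementation artifact.)

**Noise ladder.** The seed-averaged RF distance of the general taxonomy
to the planted tree is checked to be non-decreasing over noise floors
{0.03, 20, 100} (mV). The large values are deliberate: with 288 windows
per grasp the pooled-covariance test has enormous power, and amplitude
structure survives noise several times the signal; degradation only sets
in once per-window estimation error swamps the profile separation.

**Oracle equivalence.** TED is checked against exhaustive enumeration of
valid ordered mappings on small trees; SPR distance against BFS over an
independently generated SPR adjacency of all 945 six-leaf topologies;
the supertree's total distance against the exhaustive minimum over all
rooted binary topologies on ≤ 5 leaves; Mahalanobis distances against an
explicit double-loop implementation; UPGMA against scipy cophenetic
distances.

**What passing does not show.** The generator's plateau-hold signal
model, iid noise and profile-proportional features are idealizations;
real sEMG has nonstationary spectra, crosstalk and electrode artifacts,
and real glove data has sensor nonlinearity. Synthetic recovery
therefore validates the *machinery* (formulas, estimators, tree
algorithms, merge logistics), not the biological claim that 20 human
grasps organize into any particular hierarchy. Reproducing the published
full-scale edit distances requires the real 40-subject corpus and
depends on conventions the original analysis leaves open (linkage,
tie-breaks, TED ordering, rearrangement schedule); the report's
`reference` column exists to audit such runs, and the problem sizes used
by the shipped experiments (5 × 8 for the IAV/MAV identity, 3 × 6 for
recovery) are the package's own desk-scale choices.

## Known limitations

* Exact SPR search is exponential in the distance; radically incongruent
  large trees fall back to a flagged greedy upper bound.
* The supertree hill-climb can in principle stop in a local optimum.
* Unordered TED is approximated by canonical-order TED (exact for the
  identity and well-behaved in practice, but a different convention than
  an NP-hard exact unordered solver would give).
* Weighted (branch-length-aware) tree comparison is not implemented;
  heights are discarded when dendrograms become trees.
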