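# Methods

`curvnet` compares the robustness of weighted brain structural networks
between a cognitively impaired (MSCI) and a non-impaired (MSNI) cohort
of multiple-sclerosis patients, and ships a synthetic cohort generator
so the full pipeline is testable without patient data.  This note
records the models, the defaults and why, the numerical choices, and
what the synthetic experiments do and do not demonstrate.

## Data model

A study consists of a parcellation (an ordered node table: ID, label,
functional community, hemisphere, centroid in mm — the 333-area Gordon
layout is the reference case), one symmetric non-negative count matrix
per subject (streamline counts; zero diagonal), and a cohort manifest
assigning each subject a group label or a cognitive-impairment index.
Node order is defined by the node table, not by the numeric IDs;
matrices must follow it.  Asymmetries up to 1e-9 are averaged away;
anything larger is treated as a wrong file rather than silently fixed,
because tractography count matrices are exactly symmetric by
construction.  Weights are kept as raw counts; no normalisation is
applied on input.

## Ollivier-Ricci curvature

Curvature is the direct robustness measure.  Node i carries the lazy
random-walk measure

    m_i(i) = idleness,   m_i(j) = (1 - idleness) * w_ij / s_i,

with strength s_i = sum_j w_ij, and each edge gets

    kappa_ij = 1 - W1(m_i, m_j) / d(i, j),

where W1 is the exact Wasserstein-1 distance and d the ground metric.
Defaults: idleness 0.5, hop ground metric (d = unweighted shortest-path
length), with a 1/w-geodesic alternative behind a flag.  All four
construction choices (idleness, mass rule, ground metric, aggregation)
are configuration-exposed, because the analysis target is a group
*difference*, which should be robust to them; with the hop metric,
curvature depends only on weight ratios and is invariant to a uniform
rescaling of all weights.

W1 is solved exactly.  Two solvers are provided and tested to agree to
1e-9: a network-simplex transportation solver (numba-compiled; supply
perturbation `a_i += (i+1)*eps` against degeneracy, objective evaluated
from the optimal duals against the unperturbed masses, which is exact
by strong duality) and a linear program (HiGHS), where all edge
subproblems of one graph are stacked into a single block-diagonal LP.
Before either solver runs, the shared mass min(m_i, m_j) is subtracted;
for a metric ground cost some optimal plan leaves common mass in place,
so this is exact and it shrinks most subproblems to a handful of atoms.
One-point residuals are solved in closed form.

Node curvature is the strength-weighted mean of incident edge
curvatures (this keeps it on the edge-curvature scale); global
curvature is the unweighted mean of node curvatures over non-isolated
nodes, with a strength-weighted variant behind a flag.  Isolated nodes
have no curvature and are reported missing.  A two-node graph is
computed normally: at idleness 0 the two measures are point masses at
the opposite endpoints, so W1 = d and kappa = 0.

## Graph measures

Strength, betweenness centrality and weighted clustering are the other
local measures.  Path-based quantities use the standard
streamline-count length map d = 1/w.  Betweenness is Brandes
accumulation on those lengths, reported unnormalized by default (group
comparisons are invariant to the constant); clustering is the Onnela
geometric-mean form with weights scaled by the graph maximum, which
reduces to the binary coefficient on uniform weights and stays in
[0, 1].  Shortest-path multiplicities treat lengths within a relative
1e-12 as tied.

Global measures: density, diameter, global efficiency, characteristic
path length, mean clustering, small-worldness.  Path-based global
measures are computed after dividing weights by the subject maximum, so
lengths are >= 1 and efficiency lies in [0, 1]; this also removes a
per-subject global count scale, which is a nuisance for count data.  A
consequence worth knowing: raising one weight above the previous
maximum rescales all lengths, so efficiency is monotone in a single
weight only while the maximum is unchanged.  Characteristic path length
averages over reachable pairs and sets a `disconnected` flag instead of
returning infinity.  Small-worldness sigma = (C/C_rand)/(L/L_rand) uses
degree-preserving double-edge-swap surrogates in which weights travel
with their edges (default 100 surrogates, 10x n_edges swap attempts,
seeded); scaled-down studies in the test suite use 5–20 surrogates,
which widens only sigma's own sampling error.

## Cognitive-impairment index

Twenty MACFIMS-derived parameters with user-supplied normative mean, sd
and direction ("higher is better") per parameter.  A parameter is
failed when performance is strictly more than 1 normative sd below the
mean after direction correction; the CI index is the failed fraction
(n_failed/20 — the definition consistent with the published >0.35
impairment threshold).  Classification: index < 0.2 MSNI, > 0.35 MSCI,
the closed interval [0.2, 0.35] borderline — borderline subjects are
excluded before any statistics.  Thresholds and the index definition
are configuration keys.  Normative values are never guessed; the
synthetic generator fabricates them for tests.

## Statistics

Nodewise: two-tailed pooled-variance (Student) t-tests — the
homoscedastic variant is deliberate, not Welch — one per node, with
Holm-Sidak step-down control at alpha = 0.05 over the node family
(333 for the Gordon layout).  Each local measure forms its own family
by default; a flag merges all measures into one family.  Nodes with
zero variance in both cohorts are dropped and the family size reduced,
with a log message.  Global: one-tailed pooled t-tests under the
a-priori hypothesis that robustness measures are higher in MSNI,
Holm-Sidak across the seven global measures.  The expected direction of
characteristic path length and diameter is genuinely ambiguous (shorter
paths could equally signal robustness), so those two directions are a
required configuration entry with no default.  Correlations of node
measures with the CI index are Pearson r over all included subjects
(both cohorts pooled), two-tailed, uncorrected by default to mirror
per-node scatter plots, with an optional Holm-Sidak flag.  No stepwise
regression is implemented anywhere, by design.

## Synthetic cohorts

The generator emulates the statistical shape of tractography count
matrices, not their anatomy:

- centroids on a cortical-like spherical shell (radius 70 mm, 20%
  radial jitter); hemispheres split by the x sign; community labels
  assigned round-robin from the standard functional-network names;
- one study-level template: edge existence Bernoulli with probability
  exp(-distance / 45 mm), template counts log-normal (log-mean 2.5,
  log-sd 1.0).  At 333 nodes this gives density ~0.19 and ~2x10^5
  total streamlines, in the range of whole-brain random-seeded
  tractography;
- subjects share the template (real cohorts share one anatomy) and
  vary by independent per-edge log-normal noise (log-sd 0.45) and
  integer rounding, so weak edges flicker across subjects.  A fully
  independent redraw per subject was rejected: it yields between-
  subject strength CVs around 0.6, far above what shared anatomy
  produces, and no group analysis at n = 10 vs 31 could work under it;
- impairment: each impaired subject draws a latent severity in
  [0.6, 1.0]; every edge incident to a planted node (defaults: nodes 5
  and 17) is multiplied by (1 - delta * severity), delta = 0.5 —
  graded loss rather than deletion, though rounding does delete
  attenuated low-count edges;
- the CI index is logistic(logit(0.1) + 5.0 * severity + N(0, 0.2))
  and the recorded group label comes from thresholding that index —
  the same path real subjects take — so controls land below 0.2 and
  impaired above 0.35 at the defaults (10 + 31 included subjects),
  and widening the CI noise produces borderline subjects for
  exclusion-path testing.

What passing synthetic tests shows: the pipeline recovers localized
connectivity deficits nodewise, controls the family-wise error rate
under a complete null, and recovers the planted sign of
measure-vs-impairment correlations.  What it does not show: anything
about registration, tractography biases, lesion geometry, or the
anatomical identity of affected areas in real data.

A known negative result, reproduced honestly by the acceptance suite:
with the deficit confined to two planted nodes, *global* (whole-brain
mean) curvature does not separate the cohorts reliably.  Multiplying
all edges of a node by one factor leaves that node's own random-walk
measure unchanged (masses are ratios w/s), so curvature responds only
through second-order shifts in the neighbours' measures, and a 2-in-60
node deficit moves the global mean by ~0.2 pooled sd.  Nodewise
curvature at the planted nodes does separate — the neighbour-measure
shifts concentrate on their incident edges.  A diffuse deficit, not a
localized one, is what a global curvature drop detects.

## Problem sizes in the shipped experiments

Unit tests run on toy graphs (3–12 nodes) and oracle sweeps on up to
7-node graphs where exhaustive path enumeration is feasible.  The
family-wise-error experiment uses 1,000 replicate null studies at the
full 333-node, 10-vs-31 design.  The recovery experiment uses 100
replicate studies scaled to 60 nodes with 5 rewired surrogates per
subject; scaling affects runtime only and the planted-node positions,
sizes and effect are the generator defaults.
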