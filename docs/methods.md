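# Methods

storknet turns raw GPS telemetry of site-faithful commuting birds (the
motivating system is white storks wintering between Iberia and Morocco) into
a spatially explicit habitat-connectivity network, and models that network's
link values with a valued exponential random graph model (ERGM). This note
records the models, the parameter choices and their rationale, the numerical
decisions, and what the synthetic-data tests do and do not establish.

## Track filtering (`trackio`)

Fixes are kept in a pandas frame keyed by (bird, UTC timestamp). Kinematics
(time difference `dt_min`, great-circle distance `dist_km`, speed `speed_kmh`)
are attributes of the *incoming* step: the values stored on fix k describe the
move from fix k-1 to k. Great-circle distance is the haversine formula on a
sphere of radius 6371.0088 km (IUGG mean radius); at the study's spatial
scales the spheroid error (< 0.5%) is far below GPS and behavioural noise.

The quality cascade has five stages, applied in order, with kinematics
recomputed after every fix-removing stage:

1. **Winter-range box** (lat 30.0–42.5 N, lon 10.0 W–3.5 E): a bird is kept if
   the median of its December–February positions falls inside the box. Birds
   with no mid-winter fixes are judged on their full-track median — dropping
   them outright would make any record shorter than a winter unusable.
2. **Season window**: September through March. Fixes are then split into
   *bird-years*: a bird's fixes from one September (year y) through the
   following March all carry the label `<bird>-<y>`.
3. **Minimum spacing** (> 4 min): greedy forward thinning — a fix survives only
   if it is more than 4 min after the previously kept fix. Fixes arriving
   after a gap of ≥ 61 min are *kept* but flagged as segment starts; deleting
   them would discard all data after every transmission outage. Long gaps are
   instead handled at the flight level (no flight may span a step > 60 min).
4. **Speed cap** (100 km/h): greedy forward scan per bird — a fix is deleted
   when its speed from the last *retained* fix exceeds the cap, so a single
   displaced fix does not also condemn its (correct) successor, whose inbound
   speed is inflated only by the outlier's displacement. The pass repeats to a
   fixed point (≤ 10 iterations; in practice the second pass is a no-op).
5. **Sparse bird-years** (< 1000 fixes) are removed.

The cascade is idempotent on its own output and reports per-stage, per-bird
drop counts so that drops + survivors always reconcile with the input.

## Site nodes (`sites`)

Land-cover polygons carry one of 14 habitat classes (3 urban, 3 agricultural,
5 artificial wetland, 3 natural wetland); CLC codes map deterministically onto
these classes, with the three ambiguous codes (131, 422, 512) taking a
documented default unless an override is supplied. Wetland polygons are
dilated outward by a shoreline buffer (default 200 m — shorelines are favoured
foraging/roosting strips; the width is a configurable choice, not an
estimated quantity). Same-habitat polygons within 10 km are merged into one
node by single-linkage clustering on minimum boundary-to-boundary great-circle
distance, approximated by densifying boundaries to ≤ 100 m vertex spacing.
Node ids are assigned by sorted centroid (lat, lon), so node identity is
independent of input order.

Metric geometry (buffers, centroids) is computed in local spherical azimuthal
projections about each geometry: equidistant for buffering (preserves
distances from the centre), Lambert equal-area for centroids (preserves area
weighting). For sub-100-km geometries the projection error is O((size/R)²).

Fix-to-node assignment is point-in-polygon with boundaries counting as inside;
a fix covered by overlapping nodes goes to the smallest node id (deterministic
tie-break, warned when habitats differ). A node is retained when enough
bird-years use it: the threshold is the median bird-year count over candidate
nodes with centroid latitude ≤ 38 N (the wintering belt), even-length medians
taking the lower middle value (the conservative reading that keeps more
nodes), and it applies network-wide. An explicit override reproduces a fixed
cutoff such as "six or more bird-years".

## Direct flights (`flights`)

A fix is *stationary* when its incoming speed is below 10 km/h (exactly
10 km/h counts as flying); segment starts, which have no incoming step, are
stationary by definition. A candidate flight is a maximal run of flying fixes
bounded by stationary fixes; it becomes a direct flight iff the bounding
stationary fixes lie in two different nodes (both assigned) and every step of
the bounded run — including the two bounding steps — is at most 60 min.
Node crossings at flying speed do not split a flight; a mid-run stationary fix
outside any node kills the candidate. Flight start/end times are the
timestamps of the bounding stationary fixes. Flights pool across bird-years
into a directed edge list weighted by flight counts.

## Network metrics (`netmetrics`)

The spatial network is a directed graph with integer flight-count weights and
a symmetric matrix of centroid great-circle distances in metres. Betweenness
uses *geographic distance* as the path cost (flight counts do not modulate
cost) and is reported unnormalised; equal-cost paths are detected with a
relative tolerance of 1e-9 on accumulated distance, a necessity with floating
point distance sums that exact-equality implementations silently ignore.
Strength is the in/out weighted degree. Habitat aggregation sums directed
flights over all node pairs of each (unordered) habitat pair; same-habitat
totals are kept as self-links, so the habitat network's total weight always
equals the spatial network's.

## Map-equation modules (`mapeq`)

Visit rates come from the weighted random walk with uniform teleportation
(τ = 0.15, the standard PageRank default; configurable), dangling nodes
teleporting uniformly; power iteration stops when the L1 change is below
1e-12. The two-level map equation

    L(M) = q H(Q) + Σ_m (q_m + p_m) H(P_m)

is evaluated with teleportation recorded in module exit flows, which gives the
exact limit L = H(visit rates) for the one-module partition. Rather than
simulating random walks, the objective is minimised deterministically: greedy
single-node moves to neighbouring modules, then pairwise module merges,
iterated to convergence from several seeded restart orders; the one-module
partition is always evaluated as a baseline, so the returned codelength can
never exceed it. On all ≤ 8-node instances tested the optimiser attains the
exhaustive minimum over every set partition. Module counts on a given network
remain optimiser-dependent in general, as they are for any heuristic
(including walk-based implementations).

## Valued ERGM (`vergm`)

The model for a directed count network y is the Poisson-reference exponential
family

    P(y; θ) ∝ [Π_{i≠j} 1/y_ij!] · exp(θᵀ g(y)),

with statistics: `sum` Σy_ij (the intercept); `nodeofactor(L)` /
`nodeifactor(L)` summing counts leaving/entering nodes of habitat L;
`edgecov` Σ y_ij·d_ij with d in km; and mutuality in negative-absolute-
difference form −Σ_{i<j}|y_ij − y_ji| (≤ 0 always, 0 iff perfectly
reciprocal). At θ = 0 the reference measure makes all counts iid Poisson(1);
without mutuality the model is exactly a Poisson log-linear GLM on ordered
pairs. A coefficient c multiplies the expected count by exp(c) per unit of
its statistic, all else equal.

Every supported statistic depends on at most (y_ij, y_ji), so the likelihood
factorises over unordered dyads with per-dyad normaliser

    Z = Σ_{a,b≥0} exp(a·η_ij + b·η_ji − θ_m|a−b|) / (a! b!),

an absolutely convergent series (factorials dominate any exponential). The
implementation evaluates Z *exactly up to certified truncation*: splitting
the kernel at b = a turns every b-marginal quantity into prefix/suffix
cumulative log-sums, giving logZ and the per-dyad first and second moments of
(a, b, |a−b|) in O(cap) per dyad, all in log space (no overflow by
construction). The truncation cap is max(30, λ′ + 10√λ′ + 30) with
λ′ = max(e^η)·e^{|θ_m|}; the boundary row/column mass is checked against a
1e-10 tolerance and the cap doubled until certified (hard ceiling 2¹⁷, beyond
which the linear predictor is reported as unnormalisable). Dyads are batched
by power-of-two cap class and chunked to bound memory.

Estimation is direct maximum likelihood — no MCMC. The gradient is
g(y) − E_θ[g] and the Hessian is −Cov_θ[g] (canonical exponential family),
both assembled exactly from the per-dyad moments, so Newton's method with
step halving converges globally on this concave likelihood (typically 4–6
iterations from the Poisson-GLM initialiser, which fixes θ_mut = 0 and uses
the closed-form normaliser). Standard errors are the exact observed
information inverse — no finite differences anywhere; z = θ̂/SE with two-sided
normal p-values, no multiplicity correction. Identifiability (column rank of
the dyadic design) is checked before fitting. Simulation is exact: each dyad
draws y_ij from its truncated marginal by inverse CDF, then y_ji from the
conditional; with θ_mut = 0 this reduces to independent Poisson draws.

## Synthetic data (`synthdata`)

The generator emulates the statistical structure the pipeline assumes, not
stork behaviour: a landscape of 24-gon habitat sites (radii 300–800 m,
centres ≥ 15 km apart so one polygon is one node under the 10-km merge), and
a two-state movement model per bird — dwell at a site (log-normal duration,
median 3 h, σ = 0.5, floor 2.5 fix intervals; within-site random walk stepping
≤ 150 m per fix, i.e. ≲ 2 km/h) alternating with straight great-circle
transits at uniform 25–60 km/h to a site chosen with probability ∝
preference(h)·exp(−d/20 km), landfills weighted 3:1. Fixes arrive every
5 min ± 30 s with isotropic 10 m GPS noise; transmission gaps (probability
0.05/day, duration 2–24 h) occur only inside dwell phases, away from their
edges. Departures are anchored to fix times so a boundary-straddling fix can
never be classified stationary outside its node. Every transit is logged as a
ground-truth trip, which makes flight extraction exactly checkable: at zero
noise the extracted edge list equals the trip matrix; at 10 m noise ≥ 99% of
trips are recovered with no false links.

What this does *not* establish: the movement model has no soaring, thermal
drift, diel rhythm, partial migration or tag failure correlated with
behaviour, so passing tests certify the pipeline's algebra and segmentation
logic, not its robustness to every pathology of field telemetry.

ERGM study configurations are shipped as documented defaults: a 34-node
southern-Spain inventory (5 landfills, 3 of each of the 8 wetland classes,
10 default-habitat nodes) with its full 12-term model, and a 31-node
northern-Morocco inventory (no fish aquaculture, irrigation ponds, dams or
salines) with the corresponding 8-term model, plus the regional generating
coefficient vectors. Pairwise distances are drawn uniformly on 2–200 km
(symmetric, not metric-embedded — the ERGM only reads the matrix).

## Recovery experiments and problem sizes

`storknet.recovery` simulates 20 replicate networks per configuration
(redrawing distances each replicate), refits each by exact MLE, and reports
replicate means with Monte-Carlo standard errors. With the southern-Spain
coefficients the mean absolute recovery error per coefficient is ~0.01 (at
most ~1–2 MC SEs); both experiments together run in well under a minute on
one CPU, which is why the shipped problem sizes (20 × 34 and 20 × 31 nodes)
were chosen — they already estimate every coefficient to two decimals.

## Known limitations

- The ERGM supports only dyad-pair-decomposable statistics; triangles,
  k-stars and other genuinely dependent terms would require MCMC and raise a
  "not supported" error by design (they are not in scope).
- Stage-1 winter residency and the merge distance are operationalisations of
  verbally specified rules; alternatives (any-position membership, centroid
  distance) are easy to add but change node identity.
- Betweenness tie detection at 1e-9 relative tolerance can, in adversarial
  constructions, either merge nearly-equal paths or split exactly-equal ones
  computed in different float orders; on random instances it matches
  exhaustive enumeration to 1e-9.
- The map-equation optimiser is exact on small instances but heuristic in
  general; restarts trade runtime for optimality.
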