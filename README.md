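# storknet

Movement ecology pipeline: from raw GPS telemetry of commuting birds to a
spatially explicit habitat-connectivity network, and from that network to a
statistical model of *why* its links are strong or weak.

White storks (and other opportunists such as large gulls) forage in landfills
and then visit wetlands and farmland, physically connecting habitats — and
potentially moving plastics, antibiotic-resistant bacteria and propagules
between them. Quantifying that connectivity takes four steps, each a module
here:

1. **`trackio`** — clean multi-month GPS fix streams: winter-range box, season
   window (Sep–Mar "bird-years"), > 4-min fix spacing, 100 km/h speed cap
   applied to a fixed point, and a minimum-fixes rule.
2. **`sites`** — build network nodes from land-cover polygons: a 14-class
   habitat vocabulary, 10-km single-linkage merge of same-habitat polygons,
   metric shoreline buffers for wetlands, point-in-polygon fix assignment,
   and a median bird-year occupancy cutoff.
3. **`flights`** — extract *direct flights*: maximal runs of fixes at
   ≥ 10 km/h bounded by sub-threshold fixes sitting in two different nodes,
   with no step over 60 min; pooled counts become directed link weights.
4. **`netmetrics` / `mapeq` / `vergm`** — analyse the network:
   distance-weighted betweenness and in/out strength, two-level map-equation
   modules, habitat-level aggregation, and a **valued Poisson-reference ERGM**

       P(y; θ) ∝ [Π 1/y_ij!] · exp(θᵀ g(y)),

   with statistics sum, nodeofactor/nodeifactor (habitat as source/sink),
   edgecov (centroid distance, km) and mutuality −Σ|y_ij − y_ji|. Because all
   of these are dyad-pair-decomposable, the likelihood factorises over dyads
   and is maximised **exactly** (Newton with analytic gradient and Hessian,
   certified truncated partition sums) — no MCMC; simulation is exact too.

A ground-truthed synthetic generator (**`synthdata`**) stands in for telemetry
downloads: habitat landscapes, two-state commuting trajectories whose every
transit is logged, and ERGM count networks with known coefficients.

## Worked example

`examples/04_fit_ergm.py` simulates one 34-node count network from the
southern-Spain regional configuration and refits it by exact MLE:

```
simulated network: 34 nodes, total 4268 flights, max link 247

exact MLE (5 Newton iterations, loglik -364.5):

                          term estimate   se      z       p
                           Sum     4.77 0.05 100.88 < 0.001
       Nodeofactor (landfills)     1.45 0.07  21.99 < 0.001
     Nodeifactor (rice fields)     2.51 0.07  37.94 < 0.001
...
         Edgecov (distance_km)    -0.15 0.00 -62.49 < 0.001
           Edgecov (mutuality)     0.86 0.04  22.37 < 0.001
```

Reading the table: the intercept-level expectation is exp(4.77) ≈ 118 flights
between two default-habitat nodes at zero distance; a landfill origin
multiplies that by exp(1.45) ≈ 4.3; each kilometre of separation multiplies
it by exp(−0.15) ≈ 0.86. The generating coefficients (4.75, 1.49, …, −0.15,
0.85) sit within ~2 standard errors of every estimate.

The other examples show the track filter report (`01`), the full
tracks-to-network build with node rankings and habitat totals (`02`), and
map-equation module detection with its codelength accounting (`03`). The
command-line interface runs the same stages from a shell
(`storknet --seed 7 --out-dir out full-pipeline`).

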