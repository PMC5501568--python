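# Methods

This note documents the models and numerical choices behind `terrazone`:
what each stage computes, which parameters matter, what the synthetic
generator does and does not emulate, and where genuinely open design
choices were settled.

## Terrain attributes

All grids are cell-center registered on a regular spacing (default 10 m),
row 0 southernmost. First and second derivatives of elevation come from
the 3×3 quadratic-surface (Zevenbergen–Thorne) finite differences:
central differences in the interior, one-sided on edges, and any cell with
a nodata neighbor masked.

* **Slope** `= 100·√(f_x² + f_y²)` in percent.
* **Aspect** is the azimuth of the downslope vector `(−f_x, −f_y)`,
  degrees clockwise from north in [0, 360). Cells with slope below
  10⁻⁸ % have no defined downslope direction and are nodata.
* **Plan curvature** `κ_p = (q²r − 2pqs + p²t)/(p² + q²)` (m⁻¹), with
  p, q the first and r, s, t the second partials. Sign convention:
  **positive = convergent** (concave in plan); a bowl `z = a(x²+y²)`,
  a > 0, gives the constant `2a`. Flat cells return 0.

EMI transect points are interpolated by inverse distance weighting,
`Σ d⁻ᵖ v / Σ d⁻ᵖ` over the nearest neighbors. The weighting power (2) and
neighborhood size (12) are conventional defaults, configurable; a cell
within 10⁻⁹ m of an observation takes its value exactly. The pipeline
starts from a gridded DEM; gridding raw GPS tracks is out of scope.

The feature matrix stacks elevation, slope, aspect, plan curvature, H-H
EMI and V-V EMI for every cell valid in all six layers, then z-scores each
column (constant columns are an error, reported by name). Aspect enters
**linearly**, not circularly encoded — the field convention for this kind
of summary table — which is adequate when the relevant slope faces sit
away from the 0°/360° wrap (here ~180° and ~45°) but is a known
limitation for north-facing terrain.

## Self-organizing map

Sequential Kohonen training on the normalized matrix. The winner for an
input x is the node with minimal Euclidean distance (ties broken toward
the lowest node index, for determinism); every node then moves by
`h_ci(t)·(x − m_i)` with the Gaussian neighborhood
`h_ci = α(t)·exp(−d_lat²/2σ(t)²)` on the lattice metric (hexagonal
lattices use odd-row offset coordinates with unit neighbor spacing).

Defaults, all configurable:

* lattice size ≈ `5√n` nodes, side ratio from the square root of the
  ratio of the two leading feature-covariance eigenvalues (clipped to
  [1, 4]); hexagonal topology;
* linear initialization on the first two principal components, spanning
  ±2 SD (deterministic); seeded random-row initialization as an option
  (and the fallback when k < 2);
* two phases of linear decay: rough ordering (σ: max(rows, cols)/4 → 1,
  α: 0.5 → 0.05, 10·n steps) and fine tuning (σ: 1 → 0.1,
  α: 0.05 → 0.01, 40·n steps);
* one seeded generator drives all input draws, so training is
  bit-reproducible given (codebook, data, schedule).

Numerical choices: neighborhood weights below 10⁻¹²·α are skipped (the
corresponding updates are below double-precision relevance; this keeps
training on ~400-node maps fast); node finiteness is checked periodically
and at the end, failing with the step index. Quantization error (mean
winner distance) is the fit metric. The U-matrix records the prototype
distance across every lattice edge plus per-node means of incident edges.

## Zones and sampling sites

K-means is a from-scratch Lloyd iteration: seeded starts (best of 10
restarts by SSE), convergence when membership stops changing, empty
clusters re-seeded from the farthest point. `cluster_field` runs it on the
**codebook nodes weighted by their hit counts** (the number of locations
each node wins). This weighting is deliberate: the SOM spreads prototypes
into high-variance corners of feature space (pothole rims), and an
unweighted node partition can spend clusters subdividing such a region
rather than separating the zones the data density supports. The unweighted
variant remains available (`node_weighting="none"`). Locations inherit
their winner node's cluster; cluster ids are renumbered by descending
membership; centroids are recomputed as means of the member *locations*
in normalized feature space (a node-space centroid option exists but the
location-space definition is what the BMU-site rule needs).

The number of zones k is a user decision, guided by the U-matrix (and an
optional Davies–Bouldin scan could be layered on); the package does not
pick k automatically.

Per cluster, the **BMU site** is the member location with minimal
Euclidean distance to the centroid (ties → lowest row index). Additional
sites use greedy farthest-point selection in geographic (x, y) space,
anchored at the BMU: repeatedly add the member maximizing its minimum
distance to the already-selected sites. Greedy max–min dispersion is not
subset-optimal, but is provably within a factor 2 of the best achievable
minimum pairwise distance; the tests verify both the exact greedy
behavior against an independent re-implementation and the ½ bound against
exhaustive enumeration on small clusters. Clusters smaller than the
requested 1 + n sites contribute all members and the shortfall is
recorded.

## Microbial indicators

* Biomass pools: `(fumigated − nonfumigated)/calibration`, 0.45 for MBC
  and 0.54 for MBN (µg g⁻¹ soil). Negative fumigation differences are
  physically impossible pools; they are floored at 0 and flagged rather
  than propagated.
* C mineralization: ordinary least-squares slope of **cumulative** CO₂
  (post-venting increments summed) against day over the sampling days
  (1, 3, 7, 10), i.e. a rate that uses all four incubation points rather
  than an endpoint difference. Units are whatever concentration unit the
  analyser reports, per day; the module treats them as opaque but
  consistent.
* N mineralization: inorganic-N difference over the 28-day incubation;
  negative values (net immobilization) pass through.
* Specific rates: rate / MBC, undefined (NaN, excluded downstream) when
  MBC ≤ 0.
* EOC is identified with the non-fumigated extract DOC value.

## Statistics

Pearson correlations for every landscape attribute × indicator pair
(reported to 2 decimals; undefined for constant columns). One-way ANOVA
per indicator across clusters with Tukey HSD pairwise comparisons at
α = 0.05 and a compact-letter display built from the maximal cliques of
the non-significance graph. BMU representativeness is a **one-sample**
two-sided t-test of each cluster's non-BMU members against the BMU's
value — the BMU contributes a single observation, so a two-sample test is
not possible; this choice matters when comparing against any published
yes/no table of BMU agreement. Cluster-mean ratio matrices round to 2
decimals in reports. No multiple-testing correction is applied across
indicators, and no variance-stabilizing transforms; both are noted in the
report output.

## Synthetic fields

The generator encodes the relationships the analysis assumes, not a
calibrated model of any real field:

* **DEM**: upper envelope of a south-dipping (0.20 %) and a
  northeast-dipping (0.17 %) plane forms a rounded ridge; 8 flat-bottomed
  potholes (depth ~3 m, rim radius 30–55 m, tanh shoulder 10 m) are
  carved out; smoothed micro-relief noise (1.5 cm SD) is added; the
  result is rescaled so max − min equals the configured 6 m exactly.
  Zone truth: cells with > 0.2 m of pit influence are zone 1
  (pothole + toe slope); the rest split into the south-facing (zone 2)
  and northeast-facing (zone 3) faces. Most of the relief sits in the
  depressions — the regime in which zone-based sampling is the natural
  design — and the two faces carry crisp, distinct aspects.
* **EMI**: `base + coef·(z − z̄) + offset·1[zone 1] + noise` sampled along
  north–south sled passes 20 m apart, 5 m along track, floored at
  0.5 mS/m. Defaults (H-H: base 47, coef −8.5 mS m⁻¹ per m, offset +8,
  noise SD 5; V-V: 32.6, −7.0, +6.5, 4) put the point summaries inside
  Table-1-style envelopes (H-H mean ≈ 47–48, SD ≈ 9–12) and make
  conductivity highest in the wet, clay-rich depressions.
* **Indicators**: per-site draws `Normal(zone mean, SD)` with the zone-1
  mean multiplied by the configured contrast (MBC ×1.6 at 250 ± 50,
  MBN ×1.75 at 30 ± 6, %TC ×1.6 at 2.0 ± 0.35, %TN ×1.8 at 0.17 ± 0.03,
  EOC ×1.3 at 60 ± 12; specific C/N mineralization ×0.625 / ×0.7 —
  inverted, lowest in the pothole zone; nitrate, ammonium, bulk C/N
  mineralization and pH have no zone contrast). The ~20 % coefficients of
  variation are typical of field-scale biomass assays and give the
  three-group ANOVA essentially full power at 12 sites per zone while
  keeping single-seed ratio estimates honest (SE ≈ 0.1 on a 1.6 ratio).

What the generator does **not** emulate, hence what passing tests do not
show about real data: spatial autocorrelation of the indicator noise
(draws are independent given the zone); EMI response to texture and depth
profiles (a linear elevation proxy plus a zone offset); seasonal moisture
dynamics; and the gentle-walled depressions of real pothole terrain —
synthetic pit rims are steeper than a cultivated field's, so slope and
curvature correlate *positively* with the pothole-zone indicators here,
whereas published field tables report negative slope–indicator
correlations. Zone recovery scores on these fields therefore measure the
pipeline's behavior under clean planted structure, not expected accuracy
on any particular field.

## Problem sizes

The whole-system checks run the full pipeline on the default 70 × 100-cell
field (7000 locations, ≈ 400-node SOM, the 50·n two-phase schedule) over
20 seeds, score effect-size recovery on 50 generated 36-site tables, and
calibrate the ANOVA type-I rate on 1000 null tables; brute-force oracle
batteries use 100 randomized small instances per operation. These sizes
were chosen so the complete suite and the acceptance script each finish in
minutes on a single CPU while keeping the study-scale conditions (n ≈ 7000,
k = 6, 36 sites) intact.

## Known limitations

* Linear aspect (see above); no circular statistics anywhere.
* No spatial-autocorrelation-aware inference; ANOVA and t-tests treat
  sites as independent.
* Sequential SOM training only (the printed update rule); no batch mode.
* IDW only; no kriging, no geodetic reprojection (coordinates are planar
  meters throughout).
* K-means restarts make the partition seed-dependent in near-tie cases;
  all outputs record their seed.
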