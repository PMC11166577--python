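# Methods

This note documents the models, algorithms and design choices behind
`mpxtools`: what the synthetic-data generator emulates, how the graph
pipeline and the spatial statistics are defined, which parameters
matter, and where the approach has known limits.

## The data model

One sequenced MPX molecule carries four motifs: a UMI (default 10 nt)
identifying the AOC molecule, a protein-identity barcode, and two 25-nt
unique pixel identifiers (UPI-A, UPI-B) acquired from two sequential
DNA-pixel hybridisation rounds. A unique molecule is an edge of a
bipartite graph whose nodes are UPI-A and UPI-B pixels; a cell appears
as one connected component. Spatial statistics operate on the one-mode
projection: UPI-A nodes, linked when they share a UPI-B neighbour, each
annotated with the marker counts of its incident molecules.

The amplicon layout is configurable; the default synthetic read is
5'→3' `UMI(10) · barcode(8) · BS1(20) · UPI-A(25) · BS2(20) · UPI-B(25)`.
The 20-nt binding-site motifs make the 10% mismatch tolerance exactly
two bases. Real MPX read structure differs in detail (cycle splits are
instrument-specific); the layout here is a stand-in that preserves the
four-motif content.

## Synthetic experiment generator

**Geometry.** A cell is a unit sphere. DNA pixels are spherical caps of
angular radius `pixel_radius` whose centres are uniform on the sphere,
in two sets A and B. Defaults calibrate to a lymphocyte-scale
experiment: 1,737 zones per set and ~10,900 placed molecules per cell
across an 80-plex panel. The cap radius default (0.083 rad) is chosen
so ~1,700 random caps cover ≥95% of the surface; on a 7-µm cell this
corresponds to ~290 nm, the assay's spatial resolution scale. The ~12%
of molecules falling outside either zone set are dropped (unhybridised
AOCs), leaving ~9,600 retained molecules — matching the reported
per-cell average of ~9,580 UMIs over 1,737 A-pixels (5.6 UMIs/pixel).

**Placement.** Each marker's molecules are placed uniformly or drawn
from a von Mises–Fisher distribution with concentration κ about a pole
(drawn per cell unless fixed). `colocalized(partner, κ)` reuses the
partner's pole, so two markers share one cap. κ = 0 reduces to uniform;
κ = 2/5/20 span weak to near-complete polarisation.

**Zone assignment.** A molecule hybridises to a *uniformly chosen* zone
among those within `pixel_radius`, independently for sets A and B
(`zone_assignment="proximity"`). The alternative `"nearest"` (strictly
nearest centre) is available but not the default: nearest-centre
assignment quantises all molecules of a region onto a single (A, B)
pair, which collapses the simple bipartite graph to mean degree ~2.4 —
nearly a tree — whereas proximity assignment yields mean degree ~3.6
and robustly connected cells. Random hybridisation within reach is also
the physically sensible model. Equidistant candidates are a measure-zero
event and resolved by sampling order.

**Doublets.** `doublet_fraction` f merges `round(f · n_cells)` pairs
(each doublet consumes two cells). The fused cells keep their own zone
sets; 5 bridge molecules at the contact interface are rewired to take
UPI-B from the partner cell, joining the graphs by a handful of edges —
the structure the refinement stage is designed to sever.

**Sequencing artifacts.** Per molecule, a geometric number of PCR
duplicates (mean `pcr_duplication`, default 3; heavy right tail matches
PCR amplification), optional dropout, and per-base substitutions at
`substitution_rate` (default 0.005) applied independently per read.
Quality strings are a constant placeholder.

**Reproducibility.** Each cell draws from an RNG stream keyed by
`SeedSequence(seed, spawn_key=(cell_index,))`, so results do not depend
on simulation order. UPIs are globally unique by construction (13
random nt + 12 nt encoding a global zone index); random prefixes keep
pairwise Hamming distances large so the error corrector is unaffected.

**What the generator does not model.** Rolling-circle amplification
chemistry, antibody binding kinetics, steric hindrance, membrane
deformation (a uropod is emulated only as a polarised cap), ambient
molecules and debris components of real libraries. Passing tests on
simulated data therefore validate the computational pipeline, not assay
chemistry; real-data peculiarities (aggregates, free antibody, uneven
pixel sizes) are only partially represented.

## Read processing

Reads shorter than the layout are rejected (`length`), then mean Phred
< 20 (`quality`), then BS1/BS2 Hamming mismatch fraction > 0.10 checked
independently per motif (`motif`), then the protein barcode is matched
allowing ≤1 mismatch — safe because panels are generated with pairwise
barcode distance ≥3 (`barcode`). QC counters always sum to the read
total.

Accepted reads are collapsed on the exact (UMI, UPI-A) key; the
representative marker and UPI-B of a group are the most frequent values
(ties lexicographic). Error correction clusters the concatenated
UMI·UPI-A keys with the directional rule: key *b* merges into key *a*
when Hamming(a, b) ≤ `max_dist` (default 2) and reads(a) ≥ 2·reads(b)−1,
representative = most frequent key. Neighbour search uses pigeonhole
n-gram partitioning (max_dist+1 chunks; any key within distance
max_dist shares one exact chunk). Greedy merging is iterated to a fixed
point, which makes the correction idempotent by construction. UPI-B
variants within a merged cluster are corrected by the same rule before
a weighted majority vote.

A fundamental limit: a molecule observed by a *single* read that
carries an error cannot be restored exactly (the true key was never
sequenced). At 0.5% substitution and geometric duplication (mean 3),
≥99% of molecules survive as records with the correct marker and ≤2 nt
residual identifier error; exact round-trip identity holds for
error-free input. At very high per-zone molecule density, true
same-zone molecules whose UMIs happen to lie within Hamming 2 can
merge — an intrinsic cost of UMI-style deduplication.

## Graph assembly

**Refinement.** Spurious inter-cell edges (doublet bridges, chimeras)
are removed per connected component: Leiden (RB-configuration) with a
*scale-free* resolution — for a component with m simple edges the
effective resolution is `resolution · 2 · crossing_max / m`. Under the
RB null model this makes Leiden keep two halves of a component apart
exactly when the edges joining them number ≲ `resolution·crossing_max`,
so the community scale automatically tracks the component scale: whole
cells remain one or two communities with thick interfaces, while
doublet bridges (≤ `crossing_max` = 10 edges) separate. Every community
pair joined by 1..`crossing_max` distinct node pairs has those edges
removed; up to `max_iter` = 3 rounds. A fixed resolution cannot achieve
this — it either fragments large cells into patch communities (all of
whose mutual interfaces fall below `crossing_max`, shredding the cell)
or swallows small doublets whole; both failure modes were observed
empirically before adopting the scaling.

**Component calling and size filtering.** Components are labelled in
descending edge count (ties by smallest UPI-A), making labels invariant
to input order. The size threshold fits a GCV-smoothed cubic spline to
(rank, log₁₀ size) with sizes sorted descending and takes the rank
minimising the second derivative — the elbow where component size
collapses; the returned cutoff is placed inside the gap below the elbow
component (geometric mean of the two adjacent sizes) so it separates
the modes without changing which components pass. With < 20 components
or all-equal sizes a fallback signal instructs use of the manual
cutoff. `filter_components` drops the `drop_top_k` largest components
and everything below max(threshold, manual minimum); the defaults used
on real libraries (drop ten largest, manual minima of 4,000–20,000
UMIs) exist to remove debris and aggregates, which the noise-free
simulator does not emit — simulations therefore filter with
`drop_top_k=0` and a small manual minimum.

**Counts and Tau.** The count matrix sums *unique molecules* (not
reads) per component per marker, with explicit zeros; its CLR view is
ln(1+x) − mean(ln(1+x)) per component. The Tau skewness of a component,
Σᵢ(1 − xᵢ/x_max)/(n−1), is 0 for even profiles and 1 for single-marker
profiles. Components are flagged HighTau when tau > 0.995 or more than
2 IQRs above the population median (single-antibody aggregates), LowTau
when more than 5 IQRs below (high-complexity aggregates); the two rules
are directional — a two-sided reading would make LowTau unreachable
under HighTau precedence.

## Spatial statistics

**CLR.** clrᵢ = ln(1+xᵢ) − mean ln(1+x). The unit pseudocount keeps
zeros finite (zeros dominate sparse panels); the vector sums to zero.

**Polarity.** For each marker, node values are that marker's entries of
the per-node CLR vectors (CLR across markers within each node); the
score is Moran's *I* with W the row-normalised adjacency of the
projection (S₀ = N, so *I* reduces to the quadratic form
zᵀWz / zᵀz). z-scores and two-sided *P* values use the closed-form
randomisation moments (E[*I*] = −1/(N−1); the standard randomisation
variance involving S₁, S₂ and the sample kurtosis b₂). The variance is
undefined for N < 4 or constant values; such markers are flagged, not
silently zeroed. Calibration on uniformly placed markers: mean *I*
within ±0.02 of the −1/(N−1) expectation, z approximately standard
normal.

A compositional caveat: CLR couples markers within a node. When some
markers are strongly polarised, the remaining markers' CLR values are
depressed wherever the polarised markers pile up, giving uniform
markers a small positive polarity (*I* ≈ 0.1 at κ = 20 on two of eight
markers). This is a property of CLR-based polarity itself, not a
simulator artifact.

**Colocalization.** Six steps per component: (1) drop markers with
fewer than 10 total counts; (2) aggregate each marker over every node
and its immediate neighbours, dropping neighbourhoods totalling < 5;
(3) build `n_perm` (default 50) permuted components by shuffling each
marker's node counts independently across nodes — equal abundance,
random localisation; (4) log1p; (5) Pearson's r per unordered pair;
(6) fit the permuted r values as a Gaussian and report
z = (r − μ̂)/σ̂ with a two-sided normal *P*. Both r and z are reported;
"the colocalization score" refers to z. Because neighbourhood
aggregation shares each node's local pixel-density factor across all
markers while the permutation destroys it, *geometrically* simulated
cells show a small positive baseline z even for independent markers
(the score partly reflects abundance and pixel-size structure);
statistic-level calibration with counts placed iid over nodes is
centred at zero. Both facts are covered by tests.

**Differential comparisons.** Long-format scores or CLR counts are
compared per feature against a reference condition with the two-sided
Wilcoxon rank-sum test, optional per-condition downsampling of
components without replacement at a fixed seed (50 per condition is the
reference choice for abundance/polarity, 100 for colocalization), and
BH or Bonferroni adjustment across features within each condition. The
effect is the mean difference (scores) or mean CLR difference / ln 2,
a log2 fold change (abundance). Gating applies conjunctions of CLR
cutoff rules with optional disjunction groups (e.g. CD3 > 0.9 and
(CD4 > 1.8 or CD8 > 1.5)).

## Layouts and density maps

Kamada–Kawai in 3D (igraph) from a deterministic initial placement —
the `seed` argument is accepted for interface stability but does not
change the result; a random initial placement was found to settle into
visibly worse stress optima (e.g. collinear triangles). Coordinates are
centred on their centroid before radial projection to the unit sphere;
centring prevents hemisphere collapse for asymmetric layouts.
Density maps evaluate, per marker, Σ count · (1 − d/cutoff) over nodes
within a Euclidean (chord) cutoff of each grid point on a Fibonacci
mesh (default 2,000 points, cutoff 0.3), reporting the natural log and
masking empty grid points. Values are rotation-equivariant, and layouts
exist for visualisation only — all statistics run on the raw graphs.
Note that a force-directed layout is defined only up to rotation and
reflection; localisation accuracy against simulated truth is assessed
with true zone positions.

## Pipeline and problem sizes

`run_pipeline` chains simulate → (amplicon) → graph → analyze →
(layout); each stage's seed is `sha256(seed:stage)` reduced below 2³¹
and recorded in `manifest.json`, so single stages re-run identically in
any order and chained CLI calls match the monolith byte for byte.
Tabular outputs carry a header comment with the package version and a
hash of the scientific parameters.

Tests run at two scales chosen as this package's desk-scale study
conditions: full calibration cells (1,737 + 1,737 zones, ~10,900
molecules) for recovery, polarity calibration and monotonicity; and
density-preserving small cells (150 + 150 zones, cap radius 0.283 rad,
1,000 molecules — the same ~6.7 molecules per zone) for read-processing
and pipeline tests. Preserving per-zone molecule density matters: it is
the quantity that controls graph connectivity and refinement behaviour,
so conclusions at the small scale transfer to the calibration scale.

## Known limitations

- The geometric colocalization baseline (positive mean z for
  independent markers on simulated cells) means absolute z values
  should be compared across conditions rather than against zero.
- CLR compositional coupling leaks strong polarisation into other
  markers' polarity scores at the ~0.1 level.
- Exact FASTQ round-trip identity requires error-free reads;
  single-read molecules with errors are recoverable only up to small
  residual identifier mismatch.
- The refinement rule assumes doublet bridges are few (≤ crossing_max
  distinct node pairs); heavily fused cells joined by broad interfaces
  are retained as one component by design.
- Differential analysis treats components as exchangeable replicates;
  no hierarchical (donor/batch) structure is modelled.
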