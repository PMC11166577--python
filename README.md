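# mpxtools

Analysis toolkit for **Molecular Pixelation (MPX)** data — an optics-free,
sequencing-based assay for spatial proteomics of single cells. Antibody–
oligonucleotide conjugates (AOCs) bound to surface proteins are associated
into overlapping spatial neighbourhoods by two sequential sets of DNA
pixels; every sequenced molecule carries a UMI, a protein-identity barcode
and two unique pixel identifiers (UPI-A, UPI-B). `mpxtools` turns such
reads into per-cell spatial graphs and computes graph-spatial statistics
that detect protein clustering and co-occurrence.

The package is aimed at computational biologists who want to process MPX
amplicon reads (or simulated experiments) end to end:

1. **simulate** — generate ground-truth experiments: cells as unit
   spheres, DNA-pixel zones as spherical caps, molecules placed uniformly
   or with von Mises–Fisher concentration κ around a pole, PCR
   duplication and sequencing errors, FASTQ rendering;
2. **reads** — FASTQ → edge list: binding-site motif matching (reads with
   >10% mismatches in BS1 or BS2 are discarded), barcode demultiplexing,
   PCR-duplicate collapse on the (UMI, UPI-A) key, directional
   error-correction of near-identical keys;
3. **graph** — bipartite UPI multigraph, Leiden-based removal of spurious
   inter-cell edges, connected-component calling, edge-rank size
   filtering (smoothing-spline elbow + manual minimum), counts matrix
   with CLR view, Tau aggregate flagging, one-mode UPI-A projection;
4. **spatial** — per-cell statistics on the projection:
   - **MPX polarity score** — Moran's *I* of a marker's CLR node counts,
     with spatial weights from the row-normalised adjacency matrix:
     *I* = (N/S₀) Σᵢⱼ wᵢⱼ(xᵢ−x̄)(xⱼ−x̄) / Σᵢ(xᵢ−x̄)², plus the analytic
     randomisation z-score and two-sided *P* (E[*I*] = −1/(N−1));
   - **MPX colocalization score** — per marker pair, Pearson's *r*
     between neighbourhood-aggregated log1p counts, compared against a
     Gaussian fit to the same statistic on components with each marker's
     counts shuffled independently across nodes; the score is the
     z-score (negative = segregation);
   - differential abundance/polarity/colocalization between conditions
     (two-sided Wilcoxon rank-sum, BH or Bonferroni adjustment) and
     CLR-threshold gating (e.g. T cells: CLR CD3 > 0.9 and CD4 > 1.8 or
     CD8 > 1.5);
5. **layout** — 3D Kamada–Kawai layouts, unit-sphere projection and
   surface density heat-map exports.

## Worked example

Simulate three cells on an 8-plex panel where marker `M001` is polarized
(κ = 20) and `M002` is colocalized with it, then run the graph and
spatial stages:

```python
import mpxtools as mpx

panel = mpx.generate_panel(8, seed=7, n_controls=1)
patterns = {"M001": mpx.polarized(kappa=20),
            "M002": mpx.colocalized("M001", kappa=20)}
spec = mpx.default_cell_spec(panel, spatial_pattern=patterns)
truth, edges = mpx.simulate_sample([(spec, 3)], seed=1)

g = mpx.refine_components(mpx.build_graph(edges))
labels = mpx.call_components(g)
retained, rank = mpx.filter_components(labels, manual_min=1000, drop_top_k=0)

pg = mpx.project_a_graph(g.edges[g.edges.component == 0],
                         markers=panel.marker_names, component=0)
print(mpx.polarity_scores(pg)[["marker", "morans_i", "z", "p"]].head(4))
```

prints (three cells of ~9,700 retained molecules each; all three
components recovered):

```
marker  morans_i         z            p
  M001  0.794825 57.421759 0.000000e+00
  M002  0.791905 57.211192 0.000000e+00
  M003  0.098128  7.100686 1.241387e-12
  M004  0.116026  8.387950 4.946920e-17
```

The two polarized markers score high polarity (*I* ≈ 0.79); the uniform
markers sit an order of magnitude lower, with a small positive offset
caused by CLR compositional coupling (where polarized markers pile up,
every other marker's CLR value is depressed — see `docs/methods.md`).
Colocalization confirms the design:

```python
coloc = mpx.colocalization_scores(pg, n_perm=50, seed=2)
# M001–M002 (shared pole): r = 0.989, z = 16.5
# M003–M004 (independent): r = 0.597, z = 3.2
```

The same pipeline is available from the shell:

```bash
mpx simulate --cells 10 --markers 80 --seed 1 --out run/
mpx amplicon --out run/            # FASTQ rendering + read processing
mpx graph    --out run/ --min-size 4000
mpx analyze  --out run/ --n-perm 50
mpx layout   --out run/ --cells 2
mpx report   --out run/
```

Chained stages and `mpx run --config cfg.yaml` produce byte-identical
tables for the same configuration; every stage derives its own seed from
the top-level one, recorded in `manifest.json`.

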