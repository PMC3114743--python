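# voromesh

Digitize 2D microscopy images onto a Voronoi polygonal mesh, quantify
per-compartment fluorescence, and simulate reaction–diffusion kinetics on
the same mesh — so that simulated concentration fields can be compared
subcompartment-by-subcompartment with the images they are meant to explain.

The package targets the analysis of intracellular signal gradients, using
as its running example the pheromone response of mating *Saccharomyces
cerevisiae*: the active MAP kinase Fus3 (double-phosphorylated, Fus3PP) is
released at the shmoo tip, diffuses through the cytoplasm, is
dephosphorylated on the way, and cannot cross the cell or nuclear
membranes, producing a spatial gradient that can be measured in microscopy
images and reproduced in simulation.

## How it works

1. **Meshing** (`voromesh.mesh`). Seed points — by default a triangular
   lattice whose Voronoi cells are equilateral hexagons, optionally with
   different densities inside user-supplied mask regions — are tessellated
   and clipped to the image rectangle. Each Voronoi cell becomes a
   *subcompartment* with explicit corner coordinates, area `V_i`, centroid,
   a compartment-type label, and named scalar properties. Shared edges give
   the adjacency graph with contact lengths `S_in`.
2. **Digitization** (`voromesh.digitize`). Every pixel center is assigned
   to exactly one subcompartment. Ordered binary masks (cytoplasm, nucleus,
   membranes, shmoo tip) type the subcompartments by majority vote — later
   masks override earlier ones, and marker masks too small to win any vote
   (a single tip pixel) are applied by point assignment. Intensity images
   deposit per-subcompartment mean signal (raw values, a.u.).
3. **Analysis** (`voromesh.analyze`). Area-weighted compartment means and
   ratios, signal profiles along the x-axis within a band, and angular
   profiles around a point (e.g. the nucleus, measured from the
   nucleus-to-tip direction).
4. **Simulation** (`voromesh.simulate`). A cell-centered finite-volume
   model: for subcompartment *i* in the cytoplasm (role A) or shmoo tip
   (role B),

   ```
   dC_i/dt = γ Σ_{n∈N_i} (w_in / V_i) (C_n − C_i) [n ∈ A∪B]
             + α [i ∈ B] − β C_i [i ∈ A]
   ```

   with `w_in = S_in` (`paper_literal` mode) or `S_in/d_in`, the contact
   length over the centroid distance (`distance_normalized`, the standard
   consistent finite-volume Laplacian). Membranes (`blocked`) and the
   image exterior (`outside`) carry no equation and exchange no flux. The
   linear system is integrated with a stiff BDF solver using its exact
   sparse Jacobian; steady states are detected by a normalized residual.
   Simulated fields are compared with digitized ones as per-subcompartment
   error maps `E` and `E/max(E)`, and rates can be fitted directly to a
   digitized image (`fit_to_image`).
5. **Synthetic scenes** (`voromesh.synth`). A deterministic generator of
   mating-cell geometries (ellipse plus shmoo protrusion, nuclear disk,
   2 px membrane rings, a single tip pixel) and signal images
   (`I = I_max·exp(−dist(p, tip)/λ)` in the cytoplasm, uniform nucleus,
   zero outside) so the whole workflow is testable without image data.

## Worked example

```python
from voromesh import analyze as an, digitize as dg, mesh as mm, synth

scene = synth.make_scene("paper_like", 42)        # 400x400 px mating cell
masks = synth.make_masks(scene)                   # five compartment masks
image = synth.make_signal_image(scene)            # Fus3PP-like gradient

mesh = mm.build_voronoi_mesh(mm.generate_hex_seeds((0, 0, 400, 400), 4.0))
labels = dg.label_grid(mesh)
dg.assign_types(mesh, [masks[k] for k in synth.MASK_ORDER], "outside", labels=labels)
dg.apply_point_masks(mesh, [masks["shmoo_tip"]], labels)
dg.acquire_signal(mesh, image, labels=labels)

cyt = an.compartment_mean(mesh, "cytoplasm", "Fus3PP")
nuc = an.compartment_mean(mesh, "nucleus", "Fus3PP")
print(f"cytoplasm {cyt:.2f} a.u.  nucleus {nuc:.2f} a.u.  ratio {cyt/nuc:.4f}")
```

prints

```
cytoplasm 43.77 a.u.  nucleus 54.32 a.u.  ratio 0.8059
```

i.e. the mesh sees a mean Fus3PP signal of 43.77 a.u. over the ~3300
cytoplasm subcompartments and 54.32 a.u. over the nucleus, a
cytoplasm-to-nucleus ratio of 0.81. The same ratio computed directly from
the pixels under the masks is 0.7956, so digitizing onto 4 px hexagons
costs about 1.3% relative accuracy — the price of representing compartment
boundaries by whole polygons.

The same workflow is available from the shell:

```
voromesh synth --preset paper_like --seed 42 --out-dir fixtures/
voromesh mesh --bbox 400 400 --spacing 4 --out mesh.json
voromesh digitize --mesh mesh.json --mask fixtures/cytoplasm.png:cytoplasm \
    ... --signal fixtures/fus3pp.png:Fus3PP --out digitized.json
voromesh analyze --mesh digitized.json --species Fus3PP --ratio cytoplasm:nucleus
voromesh simulate --mesh digitized.json --model model.toml --steady-state --out sim.json
voromesh run config.yaml        # the whole chain from one YAML config
```

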