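# ddsd — diffusion distance shape descriptors for flexible molecules

Many molecules function by changing shape: domains hinge, arms swing,
and at extreme conformations previously separate surface regions touch.
Shape-retrieval methods that treat molecules as rigid bodies (or that
rank them by shortest-path metrics) mis-score such conformers: a
straight and a folded conformation of the same protein look entirely
different to a Euclidean distance histogram, and a single self-contact
event abruptly re-routes every shortest path through the new "shortcut",
breaking inner-distance descriptors exactly when flexibility matters
most.

`ddsd` implements the **Diffusion Distance Shape Descriptor**: a compact,
orientation-free signature of a molecular shape that is insensitive to
bending *and* to topological (self-contact) changes, for people building
molecular shape search / virtual-screening pipelines over conformer
databases.

## The method

Given a volumetric model of the molecule (binary occupancy on a uniform
lattice; an object voxel is *boundary* if one of its 26 neighbours is
background):

1. **Sample** n = 500 landmark points S = {q₁, …, q_n} uniformly on the
   boundary surface with Lloyd's k-means.
2. **Inner distances.** d_I(qᵢ, qⱼ) = length of the shortest path
   between landmarks constrained to the molecular volume, computed
   exactly by Dijkstra's algorithm on the 26-connected object-voxel
   graph (edge weights spacing·{1, √2, √3}).
3. **Diffusion distances.** Build the Gaussian kernel
   k(x, y) = exp(−d_I²(x, y)/σ²) with σ the mean pairwise inner
   distance, normalise it into a Markov chain p(x, y) = k(x, y)/v(x)
   with symmetric conjugate p̃(x, y) = k(x, y)/√(v(x)v(y)), and
   eigendecompose p̃ = Σᵢ λᵢ φᵢφᵢᵀ. The diffusion map
   Φ_m(x) = (λ₁^m φ₁(x), λ₂^m φ₂(x), …) at diffusion time m = 50
   embeds the landmarks so that ‖Φ_m(x) − Φ_m(y)‖ equals the diffusion
   distance d_m(x, y) — the distance between the m-step random-walk
   profiles of x and y. Because d_m averages over *all* paths rather
   than following one shortest path, a new contact shortcut perturbs it
   only mildly.
4. **Descriptor.** Min–max normalise the n(n−1)/2 pairwise diffusion
   distances and histogram them into 128 equal bins; frequencies sum
   to 1. Shapes are compared by L1/L2/χ²/Bhattacharyya distance between
   histograms — no superposition or alignment.

Histograms built identically from inner distances (ID) or straight-line
distances (ED) serve as baselines, and a retrieval harness computes
precision–recall curves, nearest-neighbour accuracy, E- and F-measures
over a labelled shape database.

Because no external conformer database is bundled, the `synth` module
generates articulated voxel families (a folding tube, a two-lobe clamp
closing into a ring, a trefoil with a sweeping arm) whose conformer
series cross controlled self-contact events — the same phenomenology as
morphs between crystallographic conformations.

## Worked example

Generate a three-conformer folding-tube series (straight → bent →
self-contacting) and compare the first and last conformer under the
diffusion (DD) and inner-distance (ID) descriptors:

```sh
$ ddsd synth --family bent_tube --params 0,120,166 --dims 48 --out demo
3 conformers -> demo (contact_index=2)

$ ddsd describe --vox demo/bent_tube_0.vox --n 300 --seed 17 --out demo/a.json
$ ddsd describe --vox demo/bent_tube_2.vox --n 300 --seed 17 --out demo/b.json
$ ddsd compare demo/a.json demo/b.json --metric L1
0.203523

$ ddsd describe --vox demo/bent_tube_0.vox --n 300 --seed 17 --kind inner --out demo/a_id.json
$ ddsd describe --vox demo/bent_tube_2.vox --n 300 --seed 17 --kind inner --out demo/b_id.json
$ ddsd compare demo/a_id.json demo/b_id.json --metric L1
0.410613
```

The third conformer is folded past self-contact (`contact_index=2`:
the arm-tip inner distance collapsed by more than 25% there). The ID
histogram moves twice as far (L1 = 0.41) as the DD histogram
(L1 = 0.20) across the same deformation: the shortest-path metric
re-routes through the contact shortcut, while the all-paths average
absorbs it. L1 between normalized histograms ranges over [0, 2].

`ddsd benchmark --manifest demo/manifest.tsv --out results/` ranks every
shape against the rest and writes nearest-neighbour accuracy, mean E/F
measures and the averaged precision–recall curve (CSV + plot).

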