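# stainfit

Rigid-body fitting of atomic structures into low-resolution negative-stain
EM maps — with the two decisions such maps force on you: **which mirror
image is the real one**, and **which pairwise combination of fits is the
assembly**.

A negative-stain reconstruction at ~30 Å approximates the *surface* of a
particle, its intensity scale is arbitrary, and its handedness is
undetermined: a map and its mirror explain the projection data equally
well. `stainfit` implements the complete analysis pipeline for this regime:

- **Multi-start global fitting.** A body is placed at *N* random poses
  (rotations uniform on SO(3), centroids uniform in the envelope's bounding
  box), each placement is locally optimized against the *overlap* score
  `O(T) = Σ_v ρ_exp(v) · ρ_model,T(v)`, placements whose simulated envelope
  is < 30% covered by the experimental envelope (threshold 0.06 on a
  max-normalized map) are discarded, and survivors are clustered greedily,
  keeping each cluster's best-scoring member.
- **Four-metric scoring.** Each representative fit is scored with the
  overlap, the about-zero normalized cross-correlation inside the
  experimental envelope, the symmetrized Chamfer distance between envelope
  surfaces, and an envelope (Dice) score `2|A∩B| / (|A|+|B|)`.
- **Handedness determination.** Both mirror maps are fitted; a mirror is
  chosen only when it is superior under all four metrics, the same top fit
  wins regardless of metric, and the margin exceeds the pipeline's own
  replicate sampling jitter — otherwise the call is *ambiguous*.
- **Two-body assembly.** Loosely-clustered fits of two bodies are combined
  as a Cartesian product, sterically impossible pairs are removed, each
  surviving pair is scored as a union model, and pairs are ranked by mean
  rank across the four metrics with crosslink satisfaction as a soft
  tiebreak.
- **Crosslinking-MS validation.** xQuest-style tables are filtered at
  ld ≥ 40, mapped onto assemblies (Cα–Cα), and links above 35 Å are flagged
  as violations — reported, never used to hard-reject a fit.
- **Fit significance.** `z = (s_top − mean(rest)) / sd(rest)` against the
  remaining cluster representatives, with an upper-tail normal p-value.
- **Synthetic benchmarks.** A generator builds ground-truth two-body
  complexes (Cα-only chains with controllable chirality), their ~30 Å maps
  (true + mirrored, optionally noisy) and crosslink tables with planted
  satisfied/violated links — so every stage is testable without downloads.

Intended users: structural biologists and integrative modelers validating
low-resolution map interpretations, and method developers who need a small,
fully-tested reference implementation of this workflow.

## Worked example

```python
import stainfit as sf

# a ground-truth two-body benchmark: two chains docked with a 5-8 A
# interface, a 30 A map, its mirror, and a crosslink table
case = sf.make_two_body_case()          # seed 7 defaults
body_a, body_b = case.bodies

# fit body A into the map simulated from its true placement
self_map = sf.simulate_map(body_a.transformed(case.truth[0]), case.params.sim_params)
config = sf.FitConfig(n_placements=2000, opt_steps=100, rng_seed=7,
                      sim_params=case.params.sim_params)
ensemble = sf.global_fit(self_map, body_a, config)
print(len(ensemble), "representative fits")
print("top-fit RMSD to truth:",
      round(sf.ca_rmsd(body_a, ensemble.top.transform, case.truth[0]), 2), "A")
print("top-fit scores:", {k: round(v, 3) for k, v in ensemble.top.scores.as_dict().items()})

# crosslink validation of the true assembly
result = sf.map_crosslinks(case.assembled(), case.xlinks,
                           sf.XlinkConfig(chain_map=case.chain_map))
print(result.totals(), "satisfaction:", result.satisfaction)
```

prints

```
276 representative fits
top-fit RMSD to truth: 0.36 A
top-fit scores: {'overlap': 2228.791, 'ccc': 1.0, 'chamfer': 0.2, 'envelope': 0.99}
{'n_input': 34, 'n_pass_filter': 28, 'n_mapped': 25, 'n_violated': 4} satisfaction: 0.84
```

The top fit lands 0.36 Å from the true pose, with a cross-correlation of
1.0 and near-perfect surface agreement (a noiseless self-fit); of the 34
links in the table, 28 pass the ld ≥ 40 confidence filter, 25 map onto Cα
pairs, and 4 exceed 35 Å, giving a satisfaction fraction of 0.84.

The same pipeline is available from a shell:

```bash
stainfit benchmark make --seed 7 --outdir case/
stainfit fit case/map.mrc case/bodyA.pdb --n 2000 --steps 100 --seed 7 --out fits.json
stainfit handedness case/map.mrc case/bodyA.pdb --report handedness.json
stainfit xlink-validate assembly.pdb case/links.tsv --chain-map chains.yaml
```

Deposited data (a structure in mmCIF, an exported crosslink table, a
protein-to-chain map) go through the identical functions —
`read_structure`, `read_xlink_table`, `map_crosslinks`, `buried_area`.

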