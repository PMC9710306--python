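# iacta

Guided discovery of chemical reaction pathways by **imposed activation**:
constrain one user-chosen internal coordinate — the *activating coordinate*
q‡ — at out-of-equilibrium values, explore the orthogonal conformational
space with RMSD-biased metadynamics, drive relaxed scans along q‡ to
products, and post-process the trajectories into a ranked table of
reactions with transition-structure guesses and estimated barriers.

The package is for computational chemists who want to screen what a
reactive system *can* do — products, by-products, decomposition channels —
without supplying product structures, transition-state guesses, or training
data. The only chemistry input is the reactant structure and the choice of
one coordinate to activate (e.g. the C–I bond of an alkyl halide).

## The method

Given a backend that evaluates energies and gradients of 3-D structures,
the workflow is:

1. **Initialize.** Optimize the reactants; measure the equilibrium value
   q‡₀ of the activating coordinate; run a constrained conformer search at
   q‡₀ to build the reactant ensemble (the barrier reference).
2. **Activate.** For each value q‡ᵢ between reactant and product regimes,
   drive a relaxed scan q‡₀ → q‡ᵢ and run a shorter metadynamics search
   with q‡ restrained at q‡ᵢ. The bias is a sum of repulsive Gaussian
   kernels in RMSD space,

       V_bias = Σᵢ k · exp(−α · Δᵢ²),

   where Δᵢ is the minimum rigid-body-superposed RMSD to the i-th stored
   snapshot — the surface "fills in" behind the trajectory, forcing new
   conformations. Snapshots are optimized and pruned by joint RMSD /
   energy / rotational-constant thresholds into distinct *activated
   conformers*.
3. **React.** From every activated conformer, a forward relaxed scan
   q‡ᵢ → q‡_N and a backward scan q‡ᵢ → q‡₀ are stitched into one
   reactant → product trajectory.
4. **Post-process.** Trajectory energy minima are re-optimized without
   constraints and converted to canonical SMILES (bonds perceived from
   covalent radii; metal centres optionally dropped first). A SMILES change
   between consecutive minima is a reaction event; its transition-structure
   guess is the highest-energy frame strictly between the minima. Per
   reaction, the lowest-energy transition structure over all trajectories
   is kept and the estimated activation energy is

       ΔE‡ = E(best TS guess) − E(most stable reactant conformer),

   reported in kcal/mol together with the reaction energy and the
   occurrence count.

Steps 2–4 repeat over the q‡ᵢ ladder, so trajectories sample multiple
transition regions. Any engine that returns energies and gradients can sit
behind the backend contract; the package bundles a pairwise-Morse toy
backend (reactive, desk-scale, oracle-verifiable) and a subprocess adapter
for external semi-empirical engines.

## Worked example

`examples/04_reaction_search.py` runs the full search on a three-atom
exchange system Cl–H + Br → Cl + H–Br modelled by pairwise Morse
potentials, activating the Cl–H bond:

```
equilibrium q0 = 1.449 A, scanned out to qN = 3.621 A
activated values: ['1.59', '1.74', '1.88', '2.17']
ensemble sizes: {'reactant': 1, '1.5934': 1, '1.7383': 1, '1.8832': 1, '2.1729': 1}
trajectory ledger: {'launched': 4, 'completed': 4, 'flagged': 0, 'failed': 0}

reactions with estimated barriers below 35 kcal/mol:
reactant_smiles product_smiles  count  dE_act_kcal  dE_rxn_kcal
        Cl.[Br]        Br.[Cl]      4    11.499596    -0.000061

grid-oracle barrier: 11.54 kcal/mol (pipeline estimate deviates by 0.04 kcal/mol)
```

The table says: four independent trajectories all found the hydrogen
exchange (`Cl.[Br] → Br.[Cl]`), the best transition-structure guess lies
11.50 kcal/mol above the most stable reactant conformer, and the reaction
is thermoneutral (symmetric Morse parameters). An independent exhaustive
grid search of the collinear 2-D surface puts the true saddle at
11.54 kcal/mol — the workflow's estimate agrees to 0.04 kcal/mol. The other
examples demonstrate the surface oracle (`01`), the closed-form relaxed
scan check (`02`), and how the bias discovers conformers that unbiased
dynamics misses (`03`).

A thin CLI wraps the same pipeline (1-based atom indices, per chemistry
convention):

```bash
iacta run --input geom.xyz --charge -1 --mult 1 --coord dist:2,7 \
          --stretch 1.1,1.2,1.3,1.5 --qmax-factor 2.5 --seed 42 --out runs/r1
```

with `--backend toy` (generic Morse demo) or `--backend external
--engine-cmd "..."` for a real engine; outputs land in `runs/r1/`
(`reactions.csv`, `reactions.json`, `report.json`, per-reaction TS
structures, ensembles and trajectories as multi-frame XYZ).

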