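# assocmem

Rate-based simulation of **associative memory retrieval under
local–global inhibition balance**, for computational neuroscientists
studying how inhibitory diversity shapes which memories a cortical
network retrieves.

Memory items are sparse assemblies of excitatory neurons (40 of
N_E = 4000 by default) embedded in an arbitrary *memory structure*: a
graph M = (P, A) whose vertices are patterns and whose edges are
associations. The excitatory weights follow the extended association
rule

```
T = ξᵀ (I + A) ξ        (ξ: p × N_E binary pattern membership)
```

so neurons in the same or graph-adjacent assemblies are coupled.
Inhibition comes from one **global** pool (Bernoulli connectivity to the
whole excitatory population) and from per-pattern **local** pools wired
all-to-all with their assembly. The excitatory current mixes the two
pathways through the balance parameter c:

```
τ_E dI_i/dt = −I_i + (N_E⟨f⟩)⁻¹ Σ_{j≠i} T_ij V_j
              − (1−c)·(global inhibition) − c·(local inhibition) + H_ext
```

with rates read out through saturating transfer functions and integrated
by explicit Euler at dt = 0.1 ms. A trial stimulates one assembly for
80 ms and lets the network settle to 500 ms.

The analysis layer measures how far retrieval spreads and how it mirrors
the graph: the **range of retrieval D** (plateau detection on the
correlation-versus-distance profile of a ring, ε = 0.05, Y = 5), the
**clustering index Q** (agreement of pattern correlations with
label-propagation communities), and the **geometric index R(d)**
(agreement with closed d-neighborhoods). Raising c from global- toward
local-dominant inhibition widens retrieval — with the default
reconstructed transfer functions, D roughly doubles between c = 0 and
c = 0.6 — and shifts the network from fine to coarse segmentation of
the memory structure.

## Worked example

```python
import assocmem as am

ring = am.build_ring_chain(100)
config = am.SimulationConfig(c=0.0)          # purely global inhibition
D, profile, corr = am.chain_battery(ring, config, seed=7)
print("D =", D)
print("C_d for d=0..6:", profile.c_d[:7].round(2))
```

```
D = 6
C_d for d=0..6: [1.   0.72 0.5  0.26 0.14 0.03 0.  ]
```

The battery stimulates a distance-covering subset of patterns (one
trial each, same network, integrated batched), time-averages each
trial's steady state over t = 480–500 ms, and correlates the resulting
population vectors across neurons. The profile starts at 1 (a pattern
with itself), stays high for immediate neighbors — their retrieval
states overlap — and decays to noise level a few steps out: with purely
global inhibition the network retrieves only a compact neighborhood of
the stimulated memory (D ≈ 5–7). Re-running with `c=0.6` widens the
profile and roughly doubles D.

On an arbitrary graph:

```python
karate = am.build_karate()
row = am.graph_battery(karate, am.SimulationConfig(c=0.525), seed=11)
print(round(row["Q_all"], 3), round(row["R_all_d5"], 3))
```

```
0.281 0.218
```

Positive Q says the pattern correlations agree with the
label-propagation community split; R(d) scans how far that agreement
reaches geometrically. With the default reconstructed transfer
functions, retrieval on the karate club at c = 0.525 stays partial
(a cluster around the stimulated vertex) rather than engaging the whole
structure — see `docs/methods.md` for what depends on the
reconstruction.

## Command line

```
assocmem simulate --graph tutte --seed 7 --out trial.h5
assocmem chain-sweep --seed 0 --out sweep_out      # c = 0 .. 1
assocmem graph-run --graph karate --seed 0 --out karate_out
assocmem scaling --multipliers 1,8 --out scaling_out
assocmem analyze trial.h5 --graph tutte
assocmem fixtures --graph k5-3-chain --fmt edgelist
```

Experiment specs can be given as YAML/JSON (`--config`); outputs are
tidy CSV tables plus a JSON run manifest, and every result is
reproducible byte-for-byte from the experiment spec and base seed.

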