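# Methods

## Model

`assocmem` simulates a rate-based cortical network in which memory items
are sparse assemblies of excitatory neurons linked through an arbitrary
*memory structure* — an undirected graph M = (P, A) whose p vertices are
memory patterns and whose edges mark associated pattern pairs.

**Patterns and excitatory recurrence.** Each of the p patterns is a
binary membership vector over the N_E excitatory neurons, with each entry
set independently with sparseness probability f (defaults N_E = 4000,
f = 0.01, so 40 neurons per assembly; neurons may belong to several
patterns). The excitatory weight between neurons i and j counts their
co-memberships in the same pattern and in graph-adjacent patterns:

    T = ξᵀ (I + A) ξ,

with ξ the p × N_E membership matrix and A the adjacency matrix of M.
Functionally, neurons in the same or neighboring assemblies are connected
with probability 1 and all other excitatory pairs are unconnected.

**Inhibition.** Two inhibitory populations close the loop:

* a single **global** pool of N_G = 500 neurons with Bernoulli
  connectivity to and from the whole excitatory population
  (excitatory→global density 0.1, global→excitatory density 0.5 — the
  densities that the printed current normalizers cancel);
* **local** pools drawn from N_L = 500 neurons, n_LI = 10 per pattern,
  each wired all-to-all with its pattern's excitatory assembly (a *joint
  assembly*). A neuron belonging to several patterns receives local
  inhibition from each pattern's pool.

**Balancing.** Excitatory-to-excitatory weights are used as constructed.
Every inhibitory→excitatory weight onto excitatory neuron i is set to
that neuron's *balancing factor*: its presynaptic input sum in T divided
by the population mean of those sums. The factors average exactly 1, so
the inhibition a neuron receives is proportional to the recurrent
excitation it receives — a homeostatic normalization. Applying the
factor additionally to the excitatory→inhibitory weights
(`balance_mode="both"`) compounds it quadratically; because only a
fraction ≈ 1 − (1 − f)^p of neurons belong to any pattern, member
factors grow as that fraction shrinks (≈ 3.5 for a 34-pattern
structure), and the compounded inhibition then silences small dense
structures outright. The default therefore scales the incoming weights
only.

**Dynamics.** Currents follow three linear filters (τ_E = 10 ms for
excitatory, τ_I = 2 ms for both inhibitory populations) driven by the
normalized synaptic sums; rates are instantaneous readouts through the
transfer functions, V^E = φ(I^E) + noise (clipped at zero), V^G = ψ(I^G),
V^L = ψ(I^L). The excitatory current mixes the two inhibitory pathways
through the balance parameter c ∈ [0, 1]: the global term carries weight
(1 − c), the local term weight c. Integration is explicit Euler at
dt = 0.1 ms. Per-neuron Gaussian rate noise (sd 0.0015) is redrawn every
step; inhibitory readouts are noise-free.

The excitatory recurrence is normalized by N_E·⟨f⟩, where ⟨f⟩ is the
expected-rate constant. We generalize the chain value (⟨f⟩ = 1.5·f) to
arbitrary structures by ⟨f⟩ = f·(1 + mean_degree/4); this is an
extrapolation from the single known value and can be overridden in the
config.

The local inhibitory population's input current is normalized by N_E·f
(the expected assembly size) by default, which keeps the local pathway
invariant under network scaling; the printed alternative 1/(N_L·f)
(`local_input_norm="printed"`) makes that input grow linearly with
assembly size, which suppresses the stimulated assembly outright at the
enlarged network sizes — the opposite of the reported behavior there —
and is kept as an option.

**Trial protocol.** From the all-zero state, every excitatory member of
one chosen pattern receives a constant drive H_ext = 0.2 for
t ∈ [0, 80) ms; the network then evolves freely and is stopped at
t = 500 ms. The final 20 ms (t = 480–500 ms) is the analysis window.

### Transfer functions: a reconstruction

The source model specifies φ and ψ only by their anchors: φ maps every
input above 0.15 to the saturation rate 0.08 (and negative input to 0);
ψ continues linearly with constant slope above 0.6. The sub-threshold
shapes are not published numerically, so the defaults here are a
reconstruction pinned to those anchors:

* φ(I) = 0.08 · s(((I − θ)/(0.15 − θ))^γ), with s the cubic smoothstep,
  activation threshold θ = 0.01 and shape γ = 0.5. Neither feature is
  cosmetic: a neighbor assembly driven by one saturated assembly
  receives input ≈ 0.05, and with a convex ramp φ(0.05) is too small
  for the neighbor to ignite, so the retrieved bump collapses after the
  stimulus ends instead of persisting and spreading; conversely,
  without the threshold any positive residual input produces rate, an
  unselective low-rate state survives everywhere, and retrieval loses
  its spatial confinement.
* ψ(I) = g·I² for 0 < I ≤ 0.6, continuing linearly with slope 1.2·g
  above. The gain g = 0.25 sets the total-activity level at which
  global inhibition halts the spread of retrieval; it was calibrated,
  on a coarse grid, so that purely global inhibition (c = 0) on a
  100-pattern ring retrieves a compact neighborhood of roughly five
  patterns — the regime-defining behavior reported for the original
  curves. Concave alternatives (ψ ∝ √I), attractive on steady-state
  grounds for the strongly local-dominant regime, proved dynamically
  unstable (the fast inhibitory loop's gain diverges at low activity)
  and were rejected.

Both curves can be replaced by user-supplied monotone tables
(`make_transfer_functions`), and every statistic in the package is
defined independently of the curve shapes.

## Analysis

**Correlation between memories.** Each pattern of interest is stimulated
in its own trial on the *same* network realization (a *battery*). Each
trial's excitatory steady state is averaged over the analysis window into
a population vector, and C_{μν} is the Pearson correlation *across
neurons* between the vectors of the trials stimulating μ and ν. Retrieval
states of nearby patterns overlap, so C decays with graph distance;
trials converging to one global state give C ≈ 1 everywhere, and
complementary states give negative values. A within-trial alternative
(temporal Pearson correlation between summed assembly-rate traces over
the window) is also implemented; under the i.i.d. per-step noise model
its fluctuations are dominated by independent noise, so it is kept for
time-course inspection rather than for the distance statistics.

**Distance profile and range of retrieval (ring).** C_d is the mean
correlation over pattern pairs at ring distance d. D is found by plateau
detection with ε = 0.05 and Y = 5: successive differences
|C_{d−1} − C_d| are scanned outward from the onset of decay, and D is the
first d from which Y consecutive differences stay below ε. A profile
that never moves by ε gives the minimal D = 2; if no plateau of length Y
exists, D = p/2. (Starting the scan at the decay onset rather than at
d = 2 makes the rule robust to profiles that begin with a flat plateau
at full correlation, where the literal first-window rule would fire
immediately.)

**Graph indices.** For arbitrary structures the correlation matrix is
compared against two references: label-propagation communities
(clustering index Q, the mean of C signed by community co-membership
over ordered pattern pairs) and closed d-neighborhoods (geometric index
R(d), the mean of C signed by whether the pair lies within hop distance
d). R is scanned over d = 1..diameter; at d = diameter, R equals the
mean off-diagonal correlation exactly. Both indices are also computed on
the *selective* neuron subset — neurons whose rate reached 0.02
(proportion of maximum, a quarter of saturation) at any point in any of
the battery's trials.

**Label propagation.** Asynchronous, seeded: vertices adopt their
neighborhood's majority label in a random order with random tie-breaks,
one run per battery (no consensus clustering).

## Problem sizes and numerical choices

* A full chain battery stimulates all p = 100 patterns. The default
  desk-scale battery stimulates an 18-mark "ruler" subset (0–9 and every
  fifth vertex from 15 to 50) whose pairwise ring distances cover every
  d ≤ p/2 with several pairs per distance, estimating the same profile
  from ~5× fewer trials. Graph batteries stimulate every vertex.
* The chain experiments report one D per battery; sweeps run several
  batteries per c with seeds derived as SeedSequence([base, c-index,
  battery-index]) — fully reproducible, no global RNG state.
* The integrator state is float32 (the mask matvecs are memory-bound;
  the global→excitatory mask is stored uint8 with a compiled kernel).
  Balancing factors and all analysis statistics are computed in float64.
  The association operator is applied in factorized form
  ξᵀ((I+A)(ξv)) − diag(T)∘v, algebraically identical to the matrix form
  and never materializing the N_E × N_E matrix.
* Degenerate inputs: an all-zero association matrix raises a
  degenerate-network error; silent (zero-variance) assemblies get
  correlation 0 off-diagonal, flagged, so Q and R stay defined in quiet
  regimes; non-finite currents raise a divergence error naming the step.
* The enlarged condition for strongly local-dominant dynamics uses
  N_E = 32,000 with N_G = N_L = 1,000 (the published 8× excitatory / 2×
  inhibitory ladder, reached in the scaling driver at multiplier 8).

## What the generator does and does not emulate

All inputs are generated internally: patterns are i.i.d. Bernoulli(f),
connectivity masks i.i.d. Bernoulli, and the five builtin structures are
deterministic graphs. Real cortical assemblies are not statistically
independent, joint excitatory–inhibitory assemblies are not all-to-all,
neurons are not points, and weights here never change during retrieval
(no plasticity). Passing tests therefore demonstrate properties of this
idealized model — the effect of local–global inhibitory balance on
retrieval range and graph segmentation — not claims about biological
tissue.

## Known limitations

* The sub-threshold transfer-function shapes are reconstructed, not
  digitized from the source; quantities that depend on fine details of
  the curves (exact steady-state rates, exact correlation values at a
  single c, how far the extension continues beyond c = 0.6) carry that
  uncertainty, which is why the calibration anchors are regime-level
  behaviors. In this reconstruction the retrieval range roughly doubles
  between c = 0 and c = 0.6 and widens only moderately further at
  c = 0.7 in the enlarged network, and karate-club retrieval at
  c = 0.525 engages a partial cluster rather than the whole structure;
  both are measured by the acceptance script and the test suite.
* The multiroom structure is a parameterized reconstruction from a
  verbal description; its printed diameter (18) is not reachable by any
  parameter of the 4-room grid construction (which always has diameter
  4·room_side), so comparisons on it are qualitative.
* ⟨f⟩ for non-chain graphs is an extrapolation (see above).
* The local-inhibitory input normalizer is implemented as printed,
  1/(N_L·f), although 1/(N_E·f) would be scale-consistent; a config
  switch (`local_input_norm="scaled"`) selects the latter.
* At strongly local-dominant balance (c > 0.7) small networks are
  noise-unstable (the finite-size effect); only the enlarged ladder
  gives stable retrieval there.
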