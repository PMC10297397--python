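# Methods

## Model

`padicwc` integrates the two-population Wilson–Cowan system on the compact
abelian group (Z_p, +) of p-adic integers,

    τ ∂E/∂t = −E + (1 − r_E E) · S_E( w_EE∗E − w_EI∗I + h_E )
    τ ∂I/∂t = −I + (1 − r_I I) · S_I( w_IE∗E − w_II∗I + h_I ),

where ∗ is convolution against the normalized Haar measure. The state
variables are coarse-grained firing fractions (dimensionless); t and τ share
one arbitrary time unit. The group is ultrametric: |x − y|_p = p^{−v} when x
and y share exactly v leading base-p digits, so "space" is the leaf set of a
rooted p-ary tree and balls are subtrees. Modeling assumptions inherited from
the formulation:

- couplings are radial in the p-adic norm, w_AB(x) = b_AB(e^{σ_AB} −
  e^{σ_AB|x|_p}), nonnegative, maximal at 0 and exactly zero at |x|_p = 1;
- gains are bounded Lipschitz sigmoids with S_A(0) = 0, so the resting state
  E = I = 0 is an exact fixed point in the absence of input;
- for r_E = r_I = 0 ("two coupled perceptrons") solutions are global and obey
  |E(·, t)| ≤ |E₀| + τ sup|S_E| (monitored, never enforced by clipping).

## Discretization

Fields are locally constant at level l: vectors over G_l = Z_p/p^l Z_p,
indexed by the canonical representatives 0..p^l−1. The Haar weight per site
is p^{−l}, and the discrete convolution keeps that factor,

    (w∗φ)_k = p^{−l} Σ_i w_{(k−i) mod p^l} φ_i,

so that discrete sums approximate the continuum integral and the coupling
strength is independent of grid refinement; without the factor the operator
norm grows like p^l and level-to-level convergence fails. Since G_l is a
cyclic group, the sum is a circular convolution and is evaluated with
length-p^l real FFTs (kernel transforms precomputed once per model); the test
suite pins the fast path to the brute-force double sum at 10⁻¹⁰ relative.

Level changes use two operators: embedding a level-l field into level l′ > l
repeats its values (the step function on Z_p is unchanged), and projecting a
fine field to level l samples it at the coarse representatives. Projection
after embedding is the identity, and projection never increases the sup norm.
The convergence check integrates the same model at l = 2..5 (p = 3, smooth
moving-bump stimulus, t ≤ 20) and verifies that the sup-over-time gap between
consecutive levels is nonincreasing.

## Time integration

Fixed-step classical RK4 (forward Euler available for comparison), default
dt = 0.05 in model time units — the step at which the published heat maps
were drawn; the generating scheme was not stated, so a robust explicit
fourth-order method was chosen. The decay test (all couplings zero) matches
e^{−t/τ} to 10⁻⁸ at t = 10 and shows the expected ~dt⁴ error scaling. Every
step is recorded; integration is fully deterministic, and a non-finite state
aborts with the failure time. Initial conditions default to rest (E = I = 0),
matching responses that develop from quiescence at stimulus onset.

## Parameters

The preset experiments use the published set: τ = 10, r_E = r_I = 1, p = 3,
l = 6 (729 sites); kernels (b, σ) = EE (1.5, 4), EI = IE (1.35, 6),
II (1.8, 3); sigmoids (v, θ) = E (2.75, 9), I (0.3, 17). Stimuli: excitatory
pulse 3.7 on the ball 4 + 9Z₃ gated to [0, δ] with δ = 5 (brief) or 100
(maintained); inhibitory pulse level Q (0 or −30) with spatial ball exponent
0 — taken literally, a spatially uniform input (the exponent is configurable);
hysteresis stimulus h(x, t) = e^{−(30(0.5−m(x))−0.5t)²} +
e^{−(30(0.5−m(x))+0.5t)²} with m the Monna map, played forward (open) or
reflected at t = 18 and switched off at t = 36 (return); connectome runs use
p = 2, l = 6, constant inputs h_E = 3.5 on 1 + 4Z₂ and h_I = −30.

The Monna map is the standard digit reversal m(Σ i_j p^j) = Σ i_j p^{−(j+1)},
a bijection of G_l onto {k p^{−l}} ⊂ [0, 1) under which every ball is a
contiguous interval; it orders heat-map rows (integer order is available) and
places the hysteresis bumps on the real segment. Ties cannot occur (m is
injective), so the display permutation is unique.

## Connectome kernels

`pad_matrix` embeds an n×n matrix in the smallest p^k × p^k frame (zeros
elsewhere; node order taken as given). At resolution r, entries are
partitioned into p^{2r} blocks by (row mod p^r, column mod p^r) — the
ball-based reading of the block decomposition; each block of size
p^{k−r} × p^{k−r} is replaced by its wrapped-diagonal means (each difference
class (i−j) mod p^k averaged separately). This is the unique mean-square
orthogonal projection onto locally translation-invariant kernels: it is
idempotent, preserves the total entry sum and every block sum, reproduces the
matrix bit-exactly at r = k, and its mean-square error is nonincreasing in r
(the projections are nested). The resulting K_r drives the EE coupling as the
Haar-weighted matrix–vector product p^{−l} K_r φ, with no additional
rescaling of the matrix entries.

## Synthetic connection matrices

External cortical matrices are not bundled; the generator produces a
synthetic stand-in a_ij = exp(−decay·|i−j|_p) + N(0, noise_sd²), truncated at
zero, with zero diagonal, seeded. Defaults decay = 2.0, noise_sd = 0.15 give
entries spanning ≈ [0.14, 1] across ultrametric distance scales with moderate
pairwise heterogeneity — a plausible emulation of a normalized
cortical-region weight matrix with hierarchical block structure. What it does
*not* emulate: asymmetric in/out-degree statistics, sparse zero blocks,
integer weight classes, and any non-ultrametric community structure of real
parcellations; at noise 0 it is exactly circulant, hence a fixed point of the
kernel projection at every r. Tests passing on these matrices therefore
exercise the algebra of the approximation, not the fidelity of any particular
cortex.

## Readouts

Spatial pattern complexity is the number of local maxima of a field in the
chosen ordering above 10% of its maximum; temporal oscillation counts apply
the same rule along time at one site (interior maxima only, so monotone
relaxation counts zero, while spatial endpoints may count). Because fields on
G_l are locally constant on balls, exact plateaus are generic: runs of equal
consecutive values are compressed to a single candidate before the strict
comparison, so a ball-wide bump counts once and a strict-inequality counter
cannot return zero on a locally constant pattern. The 10% threshold is a
reporting choice, not a model parameter.

## Regime of the published parameter set, and limitations

With θ_E = 9 and v_E = 2.75, every preset stimulus (amplitude ≤ 3.7) is far
below the sigmoid threshold: S_E(3.7 − 9) ≈ 5·10⁻⁷. Starting from rest, the
simulated responses are correspondingly small (10⁻⁷–10⁻⁵) and the dynamics
remain effectively linear — heat-map *patterns* (which are normalized) are
meaningful, but nonlinear phenomena are not reachable from quiescence under
these inputs. Concretely, as computed by the test suite: the brief pulse
yields a transient localized response; the separating twin stimulus yields
the single-peak → twin-peak transition (with a slowly decaying central
remnant, a signature of linear memory with time constant τ); the maintained
stimulus produces a single saturating transient rather than a pulse train;
and the return-mode run ends with a single peak — no hysteretic retention,
which would require bistability the subthreshold regime cannot provide. The
corresponding two checks in `tests/test_acceptance.py` fail by design rather
than being weakened; slope values of order 0.25 (as in classical
Wilson–Cowan parameter tables) would place the same stimuli in the sensitive
region of the gain, but no such alteration is made to the presets.

Other limitations: no adaptive step-size or stiff solvers; no graph-theoretic
small-world statistics; kernel couplings must live on the simulation grid
(a matrix padded to p^k with k < l is zero-extended, k > l is an error);
problem sizes used by the default suite are l ≤ 6 (≤ 729 sites) and
t_end ≤ 200, the published grid and horizons.
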