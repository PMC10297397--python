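# padicwc — hierarchical (p-adic) Wilson–Cowan neural fields

`padicwc` simulates excitatory/inhibitory neural-population dynamics on an
ultrametric space: the ring of p-adic integers **Z_p**, whose elements are the
leaves of an infinite rooted p-ary tree. It is aimed at computational
neuroscientists interested in neural-field models whose connectivity respects
the hierarchical, small-world-like organization seen in cortical connection
matrices — a property the classical Wilson–Cowan model on the real line cannot
express, because integrable kernels on a non-compact group force purely
short-range coupling.

## The model

On the compact group (Z_p, +) with normalized Haar measure dx, the activity
E(x, t), I(x, t) of the excitatory and inhibitory populations evolves as

    τ ∂E/∂t = −E + (1 − r_E E) · S_E( w_EE∗E − w_EI∗I + h_E(x, t) )
    τ ∂I/∂t = −I + (1 − r_I I) · S_I( w_IE∗E − w_II∗I + h_I(x, t) )

with convolutional couplings w_AB(x) = b_AB e^{σ_AB} − b_AB e^{σ_AB |x|_p}
(decreasing in the p-adic norm: nearby leaves interact strongly, maximally
distant leaves not at all), two-term logistic gains
S_A(z) = 1/(1+e^{−v_A(z−θ_A)}) − 1/(1+e^{v_A θ_A}) with S_A(0) = 0, refractory
coefficients r_E, r_I, and external inputs h_E, h_I. For r_E = r_I = 0 the
solution obeys the a priori bound |E| ≤ |E₀| + τ·sup|S_E| for all time.

Numerically the model lives on the finite quotient G_l = Z_p/p^l Z_p (p^l
leaves of the depth-l tree). Convolution becomes a Haar-weighted cyclic
convolution, (w∗φ)_k = p^{−l} Σ_i w_{(k−i) mod p^l} φ_i, evaluated by FFT, and
time stepping is fixed-step classical RK4 at dt = 0.05. Refining l converges
to the continuum dynamics; the test suite checks this level-to-level.

Connection matrices (weighted directed adjacency of cortical regions, e.g. a
cat-cortex parcellation) enter through a kernel approximation: the matrix is
zero-padded to p^k × p^k, its entries are partitioned into p^{2r} blocks by
row/column residue mod p^r, and each block is averaged over its wrapped
diagonals — the mean-square projection onto kernels K_r(x, y) that depend only
on x − y within each pair of p-adic balls of radius p^{−r}. K_k reproduces the
matrix exactly; K_r then replaces the w_EE convolution as a general integral
operator ∫ K_r(x, y) E(y) dy. A seeded synthetic generator produces
hierarchical matrices (entries decaying with ultrametric distance plus noise)
for experiments without external data.

## Worked example

```python
import numpy as np
from padicwc import PadicGrid, BallSpec, ExperimentConfig, run_experiment

# a locally constant test function on Z_2 at level 4:
# phi = Ω(2⁴|x|) − Ω(2⁴|x−2|) + Ω(2⁴|x−1|) + Ω(2⁴|x−7|)
grid = PadicGrid(2, 4)
phi = np.zeros(16)
for c, s in [(0, +1), (2, -1), (1, +1), (7, +1)]:
    phi += s * grid.ball_mask(BallSpec(c, 4))
print(phi[2], phi[7])

# brief localized pulse (amplitude 3.7 on the ball 4 + 9Z_3 for 5 time units)
# on the depth-6 ternary tree, published parameter set
result = run_experiment(ExperimentConfig.preset("sim1_pulse"))
print(result.metrics)
```

prints

```
-1.0 1.0
{'max_abs_E': 1.8409956554768234e-07, 'max_abs_I': 9.199827189551183e-09,
 'final_spatial_peaks_E': 1, 'temporal_oscillations_at_center': 1}
```

The test function takes the signed values its four ball indicators dictate
(−1 at site 2, +1 at site 7). The pulse run shows a transient response that
peaks at the stimulated ball and decays after stimulus offset: one temporal
maximum at the stimulated site, one spatial peak, and a small overall
amplitude — at the published sigmoid threshold (θ_E = 9) a 3.7-amplitude
stimulus stays subthreshold, so the network responds in its linear regime
(see `docs/methods.md`).

## Command line

```
padicwc simulate --preset hysteresis_open --out runs/hyst --image
padicwc synthesize-matrix --p 2 --k 6 --decay 2.0 --noise-sd 0.15 --seed 1 --out cat_synth.csv
padicwc kernelize cat_synth.csv --p 2 -r 0 -r 3 -r 5 --out kernels/
```

`simulate` writes space×time heat maps (TSV plus optional PNG, rows ordered by
the Monna digit-reversal map so every p-adic ball is a contiguous band), a
JSON metadata sidecar, and summary metrics. `kernelize` emits the K_r family
for a matrix together with an approximation-error table. Presets:
`sim1_pulse`, `sim1_maintained`, `sim1_inhib`, `hysteresis_open`,
`hysteresis_return`, `connectome_run`; custom experiments are YAML configs
(see `ExperimentConfig`).

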