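# Methods

## The problem and the approach

`excitedvmc` computes the lowest n eigenstates of a small electronic (or
model) Hamiltonian by variational Monte Carlo. n parametrized real-space
trial wavefunctions ψ_θ,i are optimized jointly by stochastic gradient
descent on the penalized loss

    L(θ) = Σ_i E_i[E_loc[ψ_θ,i](r)]  +  α Σ_{i>j} ( 1/(1 − |S_ij|) − 1 ),

where E_i denotes expectation over r ~ |ψ_θ,i|², E_loc = Hψ/ψ is the
local energy, and S_ij is the pairwise overlap of the (unnormalized)
states.  The penalty is linear in |S| near orthogonality — so any α > 0
makes an orthogonal configuration locally stable — and diverges as two
states collapse onto each other, so collapse is excluded for every α.
For α above the relevant energy gap the global optimum of L is the sum of
the n lowest eigenvalues with exactly orthogonal states (verified by a
brute-force sweep over the two-state mixture family in the tests).

Gradients are detached onto lower states: state 0 performs plain energy
minimization, and state i > 0 feels only the penalty terms with j < i,
through its own parameters.  This makes the ground state's trajectory
bit-identical to a single-state run on the same seed.

## Estimators

**Energy.**  Batch mean of E_loc over the state's own walker ensemble;
the batch variance σ² is recorded per iteration (it is the convergence
metric used by variance matching).  Non-finite local energies are
excluded and counted.

**Overlap / mixed observables.**  Norms are never computed.  The overlap
is the sign-resolved geometric mean of the two directional ratio
expectations,

    S_ij = sgn(E_i[ψ_j/ψ_i]) √( E_i[ψ_j/ψ_i] · E_j[ψ_i/ψ_j] ),

with all ratios evaluated in sign/log form.  If the two directional
estimates disagree in sign, the states are reported orthogonal (S = 0).
Replacing the plain ratio with (Ôψ_j)/ψ_i for a pointwise-computable
operator Ô gives general mixed matrix elements; the transition dipole
moment uses Ô = Σ_k q r̂_k componentwise (q = −1), and the oscillator
strength is f = (2/3)·ΔE·d².  The TDM's global sign is a phase
convention and is never asserted; only |d| and d² are compared to
references.

**Gradients.**  Both the energy and the overlap gradients follow the
score-function convention: they are the exact parameter derivatives of
the self-normalized *reweighted* estimators with the per-sample local
values held fixed,

    ∂E    = 2 E[(E_loc − E[E_loc]) ∂ln|ψ|],
    ∂S_ij = (1/S_ij) { E_i[(R_ij − E_i[R_ij]) ∂ln|ψ_i|] E_j[R_ji] + (i↔j) }.

The omitted integrand-derivative terms vanish in expectation (Hermiticity
for the energy; norm cancellation for the overlap), so the estimators are
unbiased, and being reweighting-exact they match finite differences of
the frozen-batch reweighted estimators to ~1e−8 relative (tested).

**Robustification.**  The ratio ψ_j/ψ_i has heavy tails near nodes of
ψ_i; per-batch ratios are capped at the 99.9th percentile of |ratio| and
the capping rate is reported for audit.  Local energies entering the
*gradient* (never the reported estimate) are winsorized at
median ± 5·MAD.  Penalty gradient terms are norm-clipped (default 10).
Overlap error bars are block-jackknife estimates over 20 paired blocks;
this choice of error bar is a package-level convention, not a law.

## The ansatz

Molecular trial states are multi-determinant Slater–Jastrow(–backflow)
wavefunctions

    ψ(r) = e^{γ(r) + J(r)} Σ_p c_p det[φ̃↑_p] det[φ̃↓_p],
    φ̃_{μi}(r) = φ_μ(r_i) f^m_{μi}(r) + f^a_{μi}(r),

with orbitals φ_μ = Σ_k c_{μk} ϕ_k over Slater- or Gaussian-type
primitives (c_{μk}, c_p trainable; a fixed-spin mode freezes c_p so a
state stays in its baseline's spin sector).

*Cusp envelope.*  γ(r) = −Σ_{iI} Z_I q(r_iI) + Σ_{i<j} c_ij q(r_ij) with
q(r) = r/(1 + a r), giving exactly the Kato nuclear slope −Z_I and the
pair slopes ½ (opposite spin) / ¼ (same spin; switchable, since the
same-spin slope could also be left to the determinant zeros).  The range
parameter a = 2 (default) makes the envelope saturate within ~0.5 bohr:
beyond that it is a constant factor and therefore does not disturb the
orthogonality of the baseline orbitals it multiplies (with a = 1 an
imported orthonormal 1s/2s pair acquired overlap 0.14; with a = 2,
0.05).  Slater-type bases carry their own nuclear cusp and are used
without the nuclear envelope term.

*Jastrow and backflow.*  Both are built from small tanh networks over the
scalar distance feature s(r) = r²/(1+r), whose derivative vanishes at
coalescence so the trainable parts cannot disturb the cusps.  The Jastrow
is a sum of per-pair-type networks (same-spin, opposite-spin,
electron–nucleus) — exchange-symmetric, hence node-preserving.  The
backflow computes one invariant feature per electron,
g_i = Σ_{j≠i} χ(s(r_ij)) + Σ_I ξ(s(r_iI)), and per-orbital linear heads
produce f^m_{μi} = 1 + a^m_μ g_i and f^a_{μi} = a^a_μ g_i — equivariant
under like-spin permutations, so antisymmetry is preserved while nodes
can move.  Heads start at zero: the untrained ansatz is exactly its
Slater–Jastrow baseline.  Network defaults are two hidden layers of
width 32 (16 in the CPU-scale tests); these are deliberately small —
large enough to bend nodes on few-electron toys, cheap enough for a
laptop.

*Derivatives.*  Everything is differentiated in closed form: scalar
networks propagate (value, f′, f″) through their layers (second-order
forward mode) and ordinary backpropagation supplies ∂θ; determinants use
d ln|det A| = tr(A⁻¹∂A) and d²ln|det A| = tr(A⁻¹∂²A) − tr((A⁻¹∂A)²) with
per-axis second derivatives of the orbital primitives.  The kinetic
energy uses the log-domain identity
−½ Σ_i [∇_i² ln|ψ| + |∇_i ln|ψ||²], which never exponentiates ψ.  A
finite-difference fallback exists only in the test suite.

For 1D studies the flexible ansatz is a polynomial-times-Gaussian,
P(x)·exp(−e^t x²/2), with trainable coefficients over *normalized*
Hermite functions and trainable log-width t.  The normalized basis is a
pure reparametrization chosen for conditioning: with raw Hermite
polynomials the coefficient directions differ in scale by orders of
magnitude and plain SGD diverges at any useful learning rate.

## Sampling

Each state owns an independent walker ensemble (default B = 2000
walkers) driven by a Metropolis-adjusted Langevin algorithm: proposals
r′ = r + (δ²/2)∇ln|ψ|² + δξ accepted with the Metropolis–Hastings ratio
for the drifted Gaussian kernel, so |ψ|² is the exact stationary law.
The drift displacement is norm-capped at δ·√(Nd) per walker; the raw
drift diverges at nodes and uncapped walkers freeze there (the
reverse-proposal density underflows), which measurably biased estimates.
The cap is a deterministic function of position applied identically in
the forward and reverse kernels, so detailed balance is exact (verified
pointwise in the tests).  Proposals landing on nodes are rejected;
walkers whose current drift is non-finite are reinitialized and counted.

δ adapts multiplicatively toward acceptance 0.57 (Langevin
optimal-scaling practice), with the measured acceptance clipped into
[0.3, 0.9] per update; adaptation is frozen during estimator evaluation
windows so chains are time-homogeneous when statistics are collected.
Between parameter updates each chain takes 10 decorrelation steps
(config-exposed).  Burn-in: 200 steps for training chains (which keep
equilibrating across iterations), but 1000+ for *frozen-parameter*
estimation of nodal states — the relative probability mass of lobes
separated by a node mixes slowly, and short burn-in produced multi-SE
biases in overlap estimates (measured, see the tests).

Reproducibility: per-state RNG streams are spawned from one master seed;
single-threaded reruns are bit-identical (asserted in the tests).

## Training schedule

Plain SGD with per-group learning rates (groups: determinants, orbitals,
jastrow, backflow).  Two optional schedule devices, both off by default:

- α ramp: the penalty weight can increase linearly over training,
  tightening orthogonality as states settle;
- learning-rate decay lr_t = lr/(1 + t/τ) (Robbins–Monro).  With a
  constant rate the excited state of the hydrogen pair stalls on a noise
  floor ~7 mHa above the exact excitation — penalty-gradient noise keeps
  kicking it off the eigenstate; with decay plus the α ramp the gap
  converges to within ~0.5 mHa.

Per-iteration batch energy means and variances are smoothed with a
bias-corrected exponential moving average (decay 0.99).  Checkpoints are
taken every 100 iterations.  A divergence guard aborts (with the trace
attached) if any state's smoothed energy rises by more than 1 Ha over
100 iterations.

**Variance matching.**  The smoothed variance is treated as the quality
metric of each state.  For a pair, the state with the *higher* final
smoothed variance keeps its final checkpoint; the other is rewound to
the checkpoint whose smoothed variance is closest to that target (ties →
latest).  If the rewound state was never as noisy as the target, the
final checkpoints are used and the pair is flagged unmatched.  Matched
excitation energies are differences of energies re-evaluated by fresh
long sampling at the selected checkpoints.

**Final evaluation.**  After training, each state is sampled exhaustively
with frozen parameters (default 1e5 decorrelated samples; 4e4 in the
desk-scale runs) for energies (block-jackknife errors), all pairwise
overlaps, TDMs and oscillator strengths.

## Baselines

Solvable systems use analytic baselines: the hydrogenic 1s/2s/2p_z
Slater-orbital ladder, or Hermite functions for the harmonic trap (the
1D spectrum-recovery runs start them at a deliberately wrong envelope
width, 1.25× the exact one, so the optimization is not a no-op).
Molecular systems import the products of an external multi-configuration
engine from a documented JSON payload (Gaussian basis, MO coefficients,
CI determinant lists); orbitals are checked for orthonormality with
analytic Gaussian overlap integrals, the expansion is truncated to the
largest-|c_p| determinants (budget 10 by default, stable ties), and the
fixed envelope supplies the missing nuclear cusps multiplicatively,
leaving the baseline nodal structure intact.

## Oracles and what the tests do (and do not) show

Ground truth comes from closed forms (harmonic ladder, hydrogenic
levels, particle-in-a-box) and a second-order finite-difference grid
eigensolver (1D/2D one particle; 1D two particles on a tensor grid with
exchange-sector projection; hard walls imposed by deleting
infinite-potential grid points, which is an exact Dirichlet condition).
The two-state mixture fixture ψ_ε = √(1−ε)ψ_1 + √ε ψ_0 has exact overlap
√ε and energy (1−ε)E_1 + εE_0 and calibrates the overlap and energy
estimators end to end.

These systems exercise every estimator and the full training loop, but
they are few-body and mostly effectively low-dimensional: passing them
shows the estimators are unbiased, the gradients exact, the sampler's
stationary law correct, and the joint optimization able to find and hold
orthogonal low-lying states.  It does not demonstrate chemical accuracy
for many-electron molecules, which requires expressive network
components and far more compute than these desk-scale runs use.

## Numerical conventions and edge cases

- Atomic (Hartree) units throughout; XYZ input defaults to angstrom
  (1 Å = 1.8897259886 bohr), with a "bohr" tag honored.
- Nuclear–nuclear repulsion is included in V, so reported energies are
  total energies.
- ψ = 0 is reported as sign 0 with ln|ψ| = −∞; samplers reject such
  proposals, nothing is clamped.
- Exact particle coincidences raise a distinguishable singular-
  configuration error.
- Determinant sums are signed log-sum-exp; ratios of wavefunctions are
  exponentials of log differences times sign products.
- Overlap gradients are zeroed when |S| < 1e−8 or when the directional
  estimates disagree in sign (the estimator has declared orthogonality).

## Known limitations

- The grid oracle stops at two discretized dimensions.
- Mixed observables cover multiplicative and Hamiltonian-type local
  operators only; non-local operators and nuclear forces are out of
  scope.
- The backflow heads are linear in a single scalar invariant per
  electron; this bends nodes on toys but is far below the expressiveness
  of deep equivariant architectures.
- MALA mixing across nodal barriers is slow; the long-burn-in defaults
  mitigate but do not remove this for frozen-state estimation.
- Spin is controlled only through (N↑, N↓) and optionally frozen
  determinant coefficients; S² is not sampled.
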