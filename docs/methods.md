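# Methods

`photopot` implements a multi-state, multi-fidelity atomic neural-network
potential for ground- and excited-state energies and oscillator strengths of
neutral singlet molecules built from H, C, N, O, F, S, and Cl, together with
the machinery that turns such a potential into science: UV/Vis spectra,
ensemble uncertainty quantification, Landau–Zener–Belyaev–Lebedev (LZBL)
surface-hopping dynamics, and uncertainty-driven active learning. Everything
is exercised end-to-end against bundled analytic model systems, so no
quantum-chemistry engine or external dataset is required.

Units throughout: energies in eV, lengths in Å, time in fs, masses in amu;
ħ = 0.6582119569 eV·fs. All conversion factors derive from CODATA values via
`scipy.constants` (`photopot.constants`).

## Model

### Descriptor

Each atom is described by an ANI-style atomic environment vector (AEV):
radial Gaussian-shell sums per neighbor element, and angular terms over
unordered neighbor pairs keyed by the unordered element pair, both damped by
the cosine cutoff f_c(R) = ½cos(πR/R_c) + ½. The angle is evaluated as
θ = arccos(0.95·cosθ); the 0.95 factor keeps the gradient finite for
collinear triples and is part of the descriptor definition. Default
hyperparameters follow the ANI-1x convention (radial cutoff 5.2 Å with 16
shifts, angular cutoff 3.5 Å with 4 radial shifts × 8 angle sections,
η_r = 16, η_a = 8, ζ = 32); these are conventional choices, fully
configurable, and `AEVConfig.desk()` provides a reduced set (8 radial
shifts, 2 × 4 angular terms) used for fast desk-scale training in the tests.

Two scalar features are appended per atom: the electronic state ordinal
(a raw non-negative float — ordinal rather than one-hot, so one network
serves an arbitrary number of states and the natural energy ordering is
built into the input), and a one-hot encoding of the fidelity level
(the "all-in-one" multi-fidelity mechanism: data from several levels of
theory train one model, distinguished only by this feature).

### Networks and training

One feed-forward subnetwork per chemical element maps the augmented feature
vector to an atomic energy; molecular state energies are atom-wise sums.
There is no autodiff framework in the target environment, so the networks
are plain numpy MLPs (tanh hidden layers, linear scalar output) with
hand-derived backpropagation; forces are exact analytic derivatives obtained
by chaining the network input gradient with the analytic AEV Jacobian, and
are verified against central finite differences to < 1e-4 eV/Å.

Training minimizes the energies-only MSE loss over all (record, state)
pairs with Adam (default initial rate 1e-3, cosine decay, early stopping
with patience 50; desk-scale tests use 1e-2). Per-element self-energies are
removed by least squares on the ground-state energies before fitting and
restored at prediction time; input features are standardized and targets
scaled by their standard deviation, with all scalers frozen at the first
fit so fine-tuning and checkpoints stay consistent. Default hidden layers
(160, 128, 96); the test suite uses (32–64)-unit layers, which suffice for
the bundled diatomic model systems.

A separate network of the same architecture predicts oscillator strengths
of the S0→Sn transitions, keyed by the state ordinal n, without the
fidelity one-hot (it is trained on single-level data); the atom-wise sum is
clamped at zero so f ≥ 0 always holds. Excitation energies paired with
these strengths come from the energy ensemble.

### Ensemble and uncertainty

The production prediction is the mean of an ensemble of three models
trained with member-specific seeds and splits; the per-state sample
standard deviation (n−1 denominator) across members is the uncertainty
(UQ). Warning thresholds are calibrated per electronic state as
median + 3·MAD of the UQs over a test set; the flag is monotone in the UQ.

### Fragment correction

Atom-wise summation makes raw energies extensive, so a dimer of two
non-interacting monomers doubles every state energy and corrupts the
(intensive) excitation energies. When the covalent-bond graph
(bond when d ≤ 1.2·(r_cov,i + r_cov,j), Cordero radii) splits into
fragments separated by more than the descriptor radial cutoff, the
composite ground state is the sum of fragment ground states and the excited
manifold is the sorted union of fragment excitations, each carrying its
fragment's oscillator strength. The trigger is a hard switch at the cutoff
distance; the resulting discontinuity is documented and intentional (the
underlying model cannot see inter-fragment correlation beyond the cutoff
anyway). How the original excimer-vs-localized decision rule worked is not
recoverable; this distance trigger is our stand-in.

### Interpretability

Per-atom excitation contributions ΔE_i are the ensemble-averaged
differences between excited- and ground-state atomic energies; they sum to
the excitation energy exactly, and the fractional contribution is
|ΔE_i|/ΔE. Signed contributions are averaged over the ensemble *before*
taking the absolute value (the alternative order is not distinguishable
from the available description; this choice is the stabler one).

## Spectra

Single-point-convolution (SPC) spectra use the Gaussian broadening
L(x) = 0.619 Σ_i (f_i/Γ)·exp(−(x−x_i)²/Γ²) with Γ = 0.3 eV by default.
Nuclear-ensemble (NEA) spectra average the same sum over a geometry
ensemble with a narrower default Γ = 0.05 eV (the ensemble supplies the
physical width; the value is our choice, not a published one). Spectra are
compared by Spearman rank correlation on a shared grid (default 200 points
spanning the transitions ± 3Γ). The `standard` variant carries the
classical factor 6; the `as_printed` variant omits it, which bounds r below
by 2/3 — since observed spectrum correlations extend well below that bound,
the standard variant is the default and the other is retained behind a flag
for auditability. A broadening-free quality score is the geometric mean
√(MAE_E · MAE_f). Wavelength output uses λ[nm] = 1239.841984/x[eV] without
Jacobian re-weighting of intensities.

## Dynamics

Initial conditions are sampled from the harmonic Wigner distribution:
independent zero-mean Gaussians per normal mode with mass-weighted
variances σ_Q² = (ħ/2ω)·coth(ħω/2k_BT) and σ_P² = (ħω/2)·coth(ħω/2k_BT),
transformed to Cartesian coordinates; net linear and angular momentum are
projected out. Rotational sampling is not performed.

Trajectories propagate with velocity Verlet (defaults dt = 0.1 fs,
t_max = 60 fs) on the active adiabatic surface. LZBL hopping needs no
nonadiabatic couplings: at each local minimum of the gap to an adjacent
state (rule Z(t−dt) > Z(t) ≤ Z(t+dt); plateaus count once), the second
time derivative is estimated by the 3-point central difference and one hop
is attempted with probability P = exp(−(π/2ħ)√(Z³/Z̈)), lower-gap partner
first. Accepted hops rescale all velocities by κ = √((KE+E_j−E_k)/KE)
(uniform scaling equals rescaling along the momentum direction), conserving
total energy; insufficient kinetic energy frustrates an upward hop. Upward
hops are allowed whenever energetically possible. The exact
"reduced kinetic-energy reservoir" variant used elsewhere is not
reproducible from the available description; rescaling is behind this
single strategy with the full kinetic energy as reservoir.

Analysis: per-state populations on a time grid and the photoisomerization
quantum yield Φ = N_reactive/N_traj both carry normal-approximation 95%
binomial confidence intervals (1.96·√(p(1−p)/N)); stability is the
fraction of trajectories finishing without dissociation (a bond is broken
when an initially bonded pair exceeds 2.5 × the covalent-radius sum), and a
dihedral-based cis/trans classifier (threshold 90°) is provided for
photoswitch yields.

The flagship validation: on the 1-D linear two-state crossing model the
LZBL machinery must reproduce the classical Landau–Zener single-passage
probability exp(−2πV²/(ħα)). The algebraic equivalence (√(Z³/Z̈) = 4V²/α at
the gap minimum of Z(t) = 2√((αt/2)²+V²)) is verified numerically in the
tests, the closed form is cross-checked against brute-force integration of
the two-state time-dependent Schrödinger equation to < 1%, and simulated
hop fractions over 2000 trajectories match within binomial 3σ across a
velocity grid spanning P ≈ 0.2–0.8. The reference particle is heavy
(200 amu) so that kinetic energy dominates the upper-surface potential drop
and the crossing velocity can be dialed precisely.

## Active learning

The NAMD loop: label an initial pool of Wigner samples (default 250) with
the oracle; each iteration fine-tune the 3-member ensemble from the
pretrained potential (or train from scratch in the comparison arm), run 50
ML surface-hopping and 50 gap-biased (gapMD) trajectories, flag frames
whose UQ exceeds the calibrated threshold (up to 300 per iteration), add
the 15 frames with the largest ensemble spread in hopping probability,
label, repeat. gapMD propagates on the effective surface E_active + λ·Z
(λ = 0.5) whose bias force drives trajectories toward small gaps; the
effective energy is conserved where the gap is smooth. Convergence — the
stand-in for external "standard settings" — is fewer than 1% flagged frames
with no error-terminated trajectories.

The screening loop fine-tunes two copies of one energy model with
different train/validation splits, measures candidate uncertainty as the
absolute deviation between the copies' predicted first excitations, labels
the most uncertain batch (default 1000) per iteration, and stops when a
random audit sample (default 100) reaches correlation ≥ 0.78 and
MAE ≤ 0.25 eV; candidates are returned most-red-shifted first.

A practical finding encoded in the tests: fine-tuning a small pretrained
model at the full training rate on a handful of clustered points destroys
its behavior away from the cluster (catastrophic forgetting). The
active-learning comparison therefore runs both arms at a gentler rate
(3e-3), which is standard fine-tuning practice and an identical budget for
both arms.

## Synthetic model systems and what green tests establish

Two analytic families stand in for quantum-chemistry reference data:

* **Linear Landau–Zener model** — a free particle crossing an avoided
  intersection E±(x) = ±√((ax)²+V²); the closed-form transition probability
  is the oracle for the hopping machinery.
* **Displaced multi-state harmonic oscillators** mapped onto the bond
  length of a diatomic (q = r − r₀), with configurable force constants,
  displacements, and offsets. Offsets well separated give smooth
  non-crossing manifolds (training, spectra, screening fixtures); nearby
  offsets give genuinely crossing diabats whose ascending sort produces a
  conical-intersection-like cusp (dynamics and active-learning fixtures).
  Oscillator strengths are generated as scaled softplus(a_n + b_n·q):
  smooth and strictly positive. Two fidelity levels are emulated by a
  constant (or smooth) energy offset, default 0.5 eV.

These fixtures reproduce the statistical *structure* the method assumes —
ascending adiabatic energies, smooth surfaces away from crossings,
non-negative strengths, fidelity levels related by a smooth offset — but
not the dimensionality, conformational diversity, or electronic-structure
noise of real molecules. A green suite therefore establishes that the
machinery is implemented correctly and behaves as the method intends at
desk scale; it does not certify chemical accuracy on real systems.

Desk-scale choices (documented, never silently changed): tests train on a
reduced descriptor and small hidden layers; the active-learning comparison
uses 16 initial points, 4+4 trajectories of 10 fs, caps of 20+3 points, and
up to 6 iterations per arm. Protocol constants that the method itself fixes
(ensemble size 3, Γ = 0.3 eV, MAD multiplier 3, dt = 0.1 fs, t_max = 60 fs,
250/50/50/15/300 active-learning counts, 0.78/0.25 eV stopping rule) are
the package defaults and are asserted verbatim in the acceptance tests.

## Numerical notes and limitations

* Gap minima are detected one step after they occur; the hop is applied at
  the current frame using current energies for rescaling. The O(dt²) bias
  this introduces is invisible at dt = 0.1 fs in the oracle test.
* Sorted-diabat crossings have a non-smooth gap; strict (biased-)energy
  conservation and the LZBL curvature estimate apply where the gap is
  smooth. At an exact crossing Z → 0 gives P → 1, the correct limit.
* The MLPs are smooth (tanh), so forces are exact derivatives of the
  learned surface — but the learned surface near a cusp is a smooth
  approximation of a non-smooth target.
* Checkpoints are single-file `.npz` archives holding descriptor config,
  level registry, scalers, self-energies, and all weight tensors;
  save → load reproduces predictions bit-exactly.
* Oscillator-strength predictions are atom-wise sums and hence extensive;
  for the fixed-size model systems this is immaterial, and the fragment
  path assigns each transition its own fragment's strength.
* The CLI covers conversion/validation, training, fine-tuning, prediction,
  spectra, fixture generation, and NAMD; the active-learning and screening
  loops are library functions because their oracles are Python callables.
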