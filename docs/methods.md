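# Methods

## Cell construction

Fragments are treated as rigid bodies in Cartesian coordinates. The
reorientation step permutes the coordinate axes so the extents come out
first-longest / second-shortest (the second axis carries the P2₁ screw by
convention); when the sorting permutation is improper, one axis is negated
so the transform stays a rotation — proteins are chiral and a reflection
would silently invert them.

The P1 cell starts from the raw max–min extents and grows iteratively:
at each step the minimum intermolecular contact over all 26 neighbour-cell
translations is measured, and every axis with a non-zero component in the
violating lattice translation grows by 0.5 Å. The 3.5 Å floor is the
binding constraint; the step size is this package's choice (smaller steps
yield slightly tighter cells at more iterations; 0.5 Å keeps the loop
short without overshooting by more than the step). The centre of mass is
mass-weighted over heavy atoms (C 12, N 14, O 16, S 32) and sits at the
cell centre, which pins the Patterson origin — Patterson maps are
translation-invariant, so without a centring convention the learning
target would be ambiguous.

P2₁ conversion adds 1 Å to each axis, stretches the second axis by a
multiplier drawn once per example from U(1.7, 1.95), re-centres the
fragment (after all length changes), and generates the second copy with
(x, y, z) → (−x, y+½, −z) through the conventional origin. No contact
re-check is performed after conversion; examples whose screw mate lands
closer than 3.5 Å are kept, which is what produces the spread of solvent
contents across the dataset. Cell angles are fixed at 90°: a monoclinic
cell with β = 90° is a valid P2₁ setting and the simplest geometry
consistent with extent-derived boxes.

Solvent fraction is the fraction of grid voxels farther than 2.2 Å
(periodic distance) from every atom. The radius is a configuration
parameter; 2.2 Å sits near typical van-der-Waals mask radii.

## Reciprocal space

Structure factors are computed by direct summation over all atoms of all
symmetry copies (the cell is always expanded to P1 content — no
space-group-specific phase arithmetic to get subtly wrong), with
4-Gaussian Cromer–Mann scattering factors for C/N/O/S and isotropic
Debye–Waller damping exp(−B s²/4). A "constant-Z" mode (f ≡ atomic
number) is kept as a testing oracle because point atoms make phases exact.
The test suite cross-validates the summation against gemmi's independent
calculator on the same model.

Synthesis conventions: reflections are enumerated over the resolution
sphere and stored Friedel-reduced; density and Patterson maps are obtained
by scattering coefficients (F, or |F|², with the conjugate at −h) into an
FFT array. F(000) is omitted from both syntheses, so all maps are
mean-zero (the CCP4 FFT convention). The Patterson is also available as
the autocorrelation Re(IFFT(FFT(e) ⊙ FFT(ě))) · V/N; the two routes are
the same mathematical object and the suite holds them to < 1e-6 relative
error, which is the central numerical cross-check of the package. Map
grids are rounded up to {2,3,5}-smooth sizes; the axis order is fixed
X,Y,Z.

## Dataset generation

Twenty resolution bins span d_min 1.75–2.3 Å, paired monotonically with
grid-sampling factors 2.29–2.7 (lowest with lowest); the pairing is a
package choice — any bijection satisfies the stated ranges, and the
monotone one keeps voxel counts balanced. Examples are assigned to bins by
index mod 20. Grid size per axis is cell_length × factor / d_min, rounded
up to the next 5-smooth integer; because every factor exceeds 2, Shannon
sampling for the bin's resolution is automatic.

Partial templates omit 3–7 of 15 residues from the start, end, or both
ends (floor/ceil split, fair coin for the odd residue). Up to J = 3
templates are drawn per example; a duplicate omission pattern (compared by
the omitted-index set, not the raw draws) is discarded rather than
redrawn, so some examples carry fewer templates. Template atoms get a
constant B of 20 Å² while ground-truth fragments keep their original
B-factors. All maps of one example share the bin's d_min, sampling factor
and grid shape. Normalisation to [−1, 1] uses global per-flavor extremes;
template maps reuse the *density* extremes so templates and truths live on
one scale. Batches group identical shapes, drop groups under 6, chunk at
≤ 11, and rebalance the final two chunks so no batch falls below 6.

## The synthetic fixtures

The fixture generator emulates the two inputs of the real pipeline —
an experimentally solved fragment and an independently predicted model of
the same sequence, pre-aligned to its frame:

- backbones are built by torsion chaining from ideal bond geometry
  (N–CA 1.46, CA–C 1.52, C–N 1.33 Å; trans peptide), with φ/ψ drawn from
  broad coil-like windows (φ ∈ [−150°, −60°], ψ ∈ [−50°, 160°]);
- side chains stop at Cβ, so the default composition is ALA/GLY
  (0.75/0.25) — the two residue types whose full heavy-atom complement
  survives that truncation, which keeps fixtures consistent with the
  missing-atom screen;
- the "prediction" adds a Gaussian displacement field rescaled so the
  realised Cα r.m.s.d. equals the requested target exactly (default
  0.5 Å, the low end of realistic prediction error), optionally inflated
  on the terminal residues, with B reset to 20 Å².

What the fixtures do **not** model: real side-chain mass (≈ 40 % of the
scattering matter), sequence-dependent conformational preferences,
Ramachandran statistics, crystal-packing contacts, bulk solvent, or
experimental noise. Tests passing on fixtures therefore demonstrate the
correctness of the *computational machinery* — symmetry, synthesis,
metrics, training dynamics — not performance on real crystals.

## Metrics

Phase errors are wrapped to [0°, 180°]; no origin-shift search is
performed because generator and predictions share one origin by
construction (a real comparison program must search allowed origins).
E-values use equal-population resolution shells (default 10) with
⟨E²⟩ = 1 per shell. σ_A is estimated per shell by the moment identity
corr(E_o², E_c²) = σ_A⁴ of the acentric Rice model, soft-thresholded at
2/√n_shell before the fourth root — without that noise floor the fourth
root turns the O(1/√n) sampling noise of an uninformative shell into a
spurious σ_A around 0.4. This deterministic estimator replaces the
likelihood maximisation a full σ_A treatment performs; it preserves the
two limits that matter for weighting (→1 for a perfect model, →0 for an
uninformative one) and is documented as a fidelity gap. Figures of merit
are I₁(X)/I₀(X) for acentric and tanh(X/2) for centric reflections
(X = 2σ_A E_o E_c/(1−σ_A²)); in P2₁ the centric zone is k = 0. The
weighted synthesis uses (2m|F_o| − D|F_c|)·exp(iφ_c) acentric and
m|F_o|·exp(iφ_c) centric coefficients.

## Model

The completion network stacks the Patterson and one partial template as
two input channels (the simplest fusion consistent with equal-shaped
inputs; exposed as configuration). Stages: a 3×3×3 convolution stem
(10 channels at full scale; optionally a scale-equivariant variant that
applies the same kernel at dilations 1 and 2 and max-pools over scale,
off by default), patchification (4³ at full scale) with a linear embedding
and fixed 3D sinusoidal positional encodings (learned tables would pin the
input shape; the dataset's shapes vary), then 12 pre-norm transformer
blocks with Nyström-approximated self-attention (12 heads × dim 64, inner
dimension 768 projected back to embed 512 — the standard resolution of the
head-count/embed mismatch; MLP 2048). The token grid is downsampled by the
patch factor with a strided projection after blocks 2 and 4 and upsampled
after blocks 8 and 10; a final linear head de-patchifies to one channel
and the volume is cropped back to the input shape (inputs are
reflection-padded to the required divisibility first). Nyström attention
uses 64 segment-mean landmarks and 6 Newton–Schulz pseudo-inverse
iterations, and falls back to exact attention for short sequences. The
approximation is accurate for token fields with sequence-local
correlation — which volumetric patch grids are — and is *not* expected to
approximate attention over i.i.d. tokens, whose softmax matrix is
effectively full-rank; the oracle test generates smooth token fields for
this reason.

Loss: MSE plus a negative-Pearson term (weight 1 by default; weight 0
reduces exactly to MSE). Training uses Adam with decoupled weight decay
3e-2 under a one-cycle schedule (initial 4.5e-4, peak 2.85e-3, final
8.57e-4, cosine ramps, 30 % warmup) and gradient accumulation every two
batches. The whole model runs on a small reverse-mode autodiff engine over
float32 numpy arrays written for this package; it is adequate for the toy
preset (patch 2, embed 64, 4 layers, 4 heads) and deliberately not a
general training framework.

### Problem sizes used by the test suite

The capacity check trains the toy preset on eight 6-residue examples
(grids ≈ 18–25 voxels per axis, one-residue omissions) and requires an
in-model-region correlation of 0.95 on every training example, reached in
roughly 600 optimiser steps. The degradation checks use 15-residue
fixtures at the coarsest bin (d_min 2.3 Å): 50 seeds for the
omission-depth monotonicity and 100 seeds for the weighted-vs-unweighted
cosine comparison. The acceptance script measures contacts on 100 fixtures
and expansion ratios over 1000 conversions. These sizes were chosen as the
smallest that make the Monte-Carlo averages stable.

## Numerical notes and edge cases

- Reflections at exactly h = n/2 on an even grid alias onto their own
  Friedel mate; coefficients are accumulated (+=), which keeps the FFT
  identical to the direct sum. Dataset grids avoid the situation entirely
  because sampling factors exceed 2.
- `normalize_dataset` rejects a flavor whose global max equals its min
  (a degenerate all-constant dataset) rather than dividing by zero.
- Zero-variance inputs to the Pearson correlation are a signalled error;
  the loss skips the Pearson term with a warning when the truth is
  constant.
- Degenerate fragments (coincident or axis-collinear atoms) are rejected
  by reorientation since no extent ordering exists.
- σ_A is clamped strictly below 1 so the FOM argument X stays finite.

## Known limitations

- Only P1 and P2₁ in orthogonal-axis settings; no non-90° cells, no other
  space groups, occupancies fixed at 1, isotropic B only.
- No bulk-solvent model, anomalous scattering, or experimental noise.
- The σ_A/FOM baseline is a moment estimator, not a likelihood fit, and
  phase comparisons assume a shared origin.
- The training harness is CPU-scale by design: no GPU, no mixed precision,
  no distributed training, and the full-scale configuration is provided as
  configuration only, not exercised by the tests.
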