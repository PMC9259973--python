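# Methods

## The algebra and why it is there

A three-channel image is modeled over G2, the geometric algebra generated
by two orthonormal vectors γ1, γ2 with γi² = 1. Its basis is
{1, γ1, γ2, γ12} with γ12 = γ1γ2, γ1γ2 = −γ2γ1 and γ12² = −1; a general
element ("multivector") is stored as the component quadruple
(e0, e1, e2, e12), in that order everywhere. A pixel is encoded as
0 + R·γ1 + G·γ2 + B·γ12: the scalar slot is structurally zero, the channels
ride on the non-scalar blades, and every product mixes the channels
coherently instead of processing them independently.

Two 4×4 real matrix representations are used. `to_real_matrix(a)` is the
operator of **right** multiplication (M(a)·vec(b) = vec(b·a)); it satisfies
the anti-homomorphism M(a)M(b) = M(b·a), which the test suite asserts
rather than assumes. The linear-algebra layer, however, needs
**left**-multiplication blocks, because a dictionary–coefficient product
q = D a multiplies each dictionary entry on the right by a coefficient:
`real_embedding` therefore tiles L(d) blocks (L(d)·vec(a) = vec(d·a)), a
true homomorphism, giving `real_embedding(D) @ vec(a) == vec(D a)` exactly.

Magnitude is the Euclidean norm of the component quadruple. G2 is
isomorphic to the algebra of real 2×2 matrices and has zero divisors
(e.g. (1+γ1)(1−γ1) = 0), so this magnitude is **not** multiplicative; the
sharp bound is |ab| ≤ √2·|a|·|b|, tight at a = b = 1+γ1. The test suite
checks the bound, not the (false) product rule.

## GAOMP

Greedy pursuit of min ‖α‖₀ s.t. q ≈ D α. Per iteration: (i) correlate the
residual with every atom through c_m = Σ_i reverse(d_im)·r_i — the scalar
part of c_m is the real-embedding inner product and its magnitude is the
norm of the residual's projection coefficients onto the four real
dimensions spanned by the GA multiples of atom m; (ii) select the largest
magnitude (ties → lowest index); (iii) re-solve all active coefficients by
least squares on the real embedding; (iv) update the residual. Stops at J
atoms (default 8) or when the residual drops below `tol·‖q‖`
(tol = 1e-6). On scalar-only inputs this is exactly classical OMP.

The batch coder runs all patch columns in lockstep and solves each
column's least squares through the normal equations on a precomputed
embedded Gram matrix, re-solved from scratch every iteration (no
progressive factor updates); ill-conditioned columns fall back to an SVD
solve. A test pins the batch solutions to the explicit `ga_lstsq` route.

## K-GASVD

Alternates coding and per-atom updates. For atom k, the error matrix
restricted to the columns using it, E_k = Y_Ω − Σ_{m≠k} d_m α_mΩ, is laid
out as a real 4N×|Ω| matrix (each multivector column flattened). Its
leading left singular vector (deterministic power iteration, initialized
from the largest column) is folded back into a length-N multivector atom by
de-interleaving consecutive 4-blocks; the k-th code row is then re-solved
exactly by multivector least squares given the new atom — the step that, in
the scalar case, reproduces K-SVD's σ·vᵀ row. Updates are accepted only if
they do not increase the residual on Ω. Atoms used by no column are
re-seeded from the worst-represented training column.

Two design points deserve emphasis:

* **Why the thin (4N×|Ω|) embedding.** Embedding each entry as a 4×4 block
  instead makes the error matrix of scalar-only data a Kronecker product
  E ⊗ I₄ whose leading singular subspace is four-fold degenerate; any
  vector in it is a valid answer, and the folded atom then carries an
  arbitrary GA-unit factor. The thin embedding has no such degeneracy and
  reduces exactly to classical K-SVD on scalar data.
* **Gauge freedom.** For any invertible unit w, d ↦ d·w together with
  α ↦ w⁻¹·α leaves every product d·α unchanged, so a planted dictionary is
  identifiable only up to a per-atom unit right factor when the planted
  coefficients are full multivectors. Recovery experiments therefore plant
  **real scalar gains**, which pin the gauge; coding against a *known*
  dictionary (the pursuit recovery tests) has no such ambiguity and uses
  full multivector coefficients.

Housekeeping between iterations follows standard K-SVD practice: an atom
that has converged onto another atom (|cos| > 0.97 between their 4N-real
flattenings) or is used by fewer than 8 columns is re-seeded from the
worst-represented column. Without this, training stalls in duplicate-atom
local minima. The recorded error history (RMS over all 4N·K real residual
components, once per completed iteration) is kept strictly non-increasing
by one more guard: since a fresh greedy pursuit is not guaranteed to beat
the previous iteration's codes (which are still valid J-sparse codes under
the current dictionary), the coder keeps, per column, whichever of the two
has the smaller residual.

## Fusion pipeline

Both sources are encoded, cut into n×n patches (n = 8, step 1; patch
vectors are column-major flattenings), and one dictionary (M = 256 atoms,
J = 8, 20 iterations) is trained on the pooled patches of both sources —
a single D feeds both coding branches, so the L1 comparison of the two code
columns is meaningful. Training pools are capped at 10 000 randomly chosen
patches (seeded) to keep desk-scale runtimes; a 64×64 input stays below the
cap. The fused coefficient column is the source column with the larger L1
norm (Σ of entry magnitudes), ties to source 1; reconstruction
overlap-averages D·αF patches. Because D and αF are full multivectors,
their product can acquire a small scalar (e0) component even though the
encoding has none; it is discarded at decode time and logged when its
maximum exceeds `e0_tolerance` (default 0.01 — at reconstruction scale this
residue is typically ~1e-2 near strong edges and is an audit, not an
error).

Coordinates are 0-based (row, col); pixel intensities are unit-range floats
(8-/16-bit files are divided by their type maximum on read). Channel order
R→γ1, G→γ2, B→γ12 is a fixed convention. Steps > 1 are supported for
speed, with an explicit error if any pixel ends up uncovered.

## Metrics

CC, RMSE, PSNR (peak 1.0) and joint entropy are each computed fused-vs-
source for both sources and averaged; per-source sub-scores are always
reported so other conventions can be recomputed. Joint entropy bins
channel-mean luminance on a 256×256 histogram over [0,1] (configurable),
consistent with 8-bit-style marginals. An infinite PSNR term (identical
images) is reported as a 300 dB sentinel plus a flag. Zero-variance images
make Pearson correlation undefined and raise an error rather than returning
a number.

## Synthetic data

Phantom pairs emulate functional nuclear-medicine pseudo-color: a ground-
truth scene of smooth radial color blobs plus sharp ring structures,
convolved with a small Gaussian PSF (σ = 0.6 px — every real acquisition is
band-limited, this modality emphatically so), then split into two sources
by a binary spatial mask (`halves`, `bands` or `checker`), optionally with
Gaussian noise, everything clipped to [0,1]. By construction
img1 + img2 = truth before noise, so the truth is recoverable only from
both. What the phantoms do **not** model: acquisition physics, tracer
kinetics, registration error, Poisson counting noise, or inter-modality
intensity relationships — passing tests demonstrate the algebra, the
pursuit and the fusion rule, not clinical performance.

Planted sparse problems draw a random unit-norm multivector dictionary,
exactly-k-sparse coefficients with magnitudes in [0.5, 2] (multivector or
scalar gains, see above) and assemble observations through the geometric
product; the mutual coherence of the planted dictionary (max |inner
product| of flattened atom pairs) is reported alongside.

## Numerical choices and limitations

* Algebra identity tolerance 1e-12 (double precision); unit-norm atoms
  enforced to 1e-10.
* Atom sign is canonicalized (largest-|component| entry positive) so runs
  are comparable; atom matching in experiments uses |cosine| and greedy
  one-to-one assignment.
* Degenerate inputs: zero patches code to empty supports; an all-zero
  training residual leaves atoms unchanged; rank-deficient least squares
  returns the minimum-norm solution with a log flag.
* Problem sizes in the tests (64×64 phantoms, N = 16 sparse problems,
  ≤ 2000 training columns) were chosen as the smallest scales at which the
  studied effects are clearly expressed.
* Known limitations: only the two-source, three-channel (G2) case is
  implemented; the dictionary is trained per image pair rather than on an
  external corpus; greedy pursuit and alternating minimization find local
  optima — dictionary recovery is typically 94–100% of atoms, not always
  100%.
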