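# Methods

## The problem

A nucleosome wraps 147 bp of DNA, and its binding affinity depends on the
sequence it wraps. With 4^147 ≈ 10^88.5 possible sequences, affinities cannot
be tabulated; a model must assign them. `nucleomark` implements the
probability-based (Markov-chain) family of affinity models, the machinery to
train them on sequence ensembles, and a benchmarking framework that measures
how well they approximate an exact, physics-based reference.

## Position-dependent Markov models

A sequence S = (S_1, …, S_147) is modelled as an inhomogeneous Markov chain of
order m. All probabilities are position-specific: P_n(w) is the probability
that the k-mer starting at window position n equals w, estimated as a relative
frequency over a training ensemble of aligned 147-bp sequences. The model
probability is a telescoping ratio of joint tables,

    order 0:  P(S) = Π_{n=1..147} P_n(S_n)
    order 1:  P(S) = Π_{n=2..147} P_n(S_{n-1} S_n) / Π_{n=2..146} P_n(S_n)
    order 2:  P(S) = Π_{n=3..147} P_n(S_{n-2} S_{n-1} S_n) / Π_{n=3..146} P_n(S_{n-1} S_n)

and so on for higher orders (numerator: (m+1)-mers at every start; denominator:
m-mers at the interior starts). The free energy is F(S) = −kT log P(S), defined
up to the unknown log-partition-function offset; only differences matter, and
every landscape comparison first applies the same Boltzmann normalization to
both sides.

Two implementation guarantees are worth stating because correctness proofs in
the tests rely on them:

* **Internal consistency.** The m-mer denominator table is derived from the
  (m+1)-mer numerator table by exact marginalization over the last base, never
  recounted. Together with the fact that empirical counts from one ensemble
  are automatically consistent across positions, this makes the model an
  exactly normalized distribution: Σ_S P(S) = 1, verified by complete
  enumeration at window length 8 for orders 0–2.
* **Exactness on nearest-neighbour fields.** If the true sequence distribution
  is a nearest-neighbour Markov field (as the toy model's is for λ = 0), the
  order-1 model built from its exact marginals reproduces every log P(S)
  up to one additive constant. This is the structural reason dinucleotide
  models approximate physics-based nucleosome models well.

### Zero-probability policies

K-mers never observed in a finite ensemble get probability 0, which would void
the whole product. Three policies are implemented:

* `flat_quarter` — treat the event as an ensemble failure carrying no
  information and substitute a flat conditional probability of 0.25 at the
  affected position (the affected factor contributes log 0.25 regardless of
  context; a 0/0 conditional is handled the same way). The unseen leading
  m-mer factor degenerates to m flat factors, i.e. 4^−m.
* `smoothed` — train on tables smoothed with a 3-bp positional running
  average (mean over positions n−1, n, n+1; truncated to the available
  neighbours at the two boundary positions, then renormalized per position).
  Residual zeros still fall back to the flat 0.25 conditional. Smoothing is
  applied eagerly to the whole table — it emulates the preprocessing used with
  low-resolution experimental ensembles — so the smoothed policy changes
  scores even where no zero occurs.
* `strict` — raise an error naming the position and k-mer.

Renormalizing smoothed rows is this package's choice (the 3-bp mean of
normalized rows is normalized anyway up to boundary truncation); the flag is
recorded in the table metadata.

## The toy biophysical nucleosome model

Full-scale biophysical nucleosome models are too expensive to serve as test
oracles, so the package ships a deliberately minimal stand-in with one angular
degree of freedom per base-pair step:

    E(S, θ) = Σ_n ½ K(d_n) (θ_n − θ0(d_n))² + ½ κ (θ_n − c_n)²
            + Σ_n ½ λ (θ_{n+1} − θ_n)²

with d_n the dinucleotide at step n, K and θ0 dinucleotide-dependent stiffness
and intrinsic angle (the rigid-base-pair caricature), c_n = A·cos(2πn/p + φ)
a periodic constraint profile imposed by the histone surface (p = 10 bp, the
helical repeat — this is what makes landscapes ~10-bp periodic), and λ a
nearest-step elastic coupling. The Boltzmann weight e^{−βE} defines
P(S, θ); integrating out θ gives P(S) and F(S) = −kT log P(S).

Because E is quadratic in θ, everything is exact:

* **Free energy.** Writing E = ½θᵀMθ − bᵀθ + c₀ (M tridiagonal),
  F(S) = c₀ − ½bᵀM⁻¹b − (kT/2)[(L−1)·log(2πkT) − log det M], evaluated with
  banded Cholesky factorizations. For λ = 0, M is diagonal and F decomposes
  into per-step terms f_n(d) = ½·Kκ/(K+κ)·(θ0−c_n)² + (kT/2)·log((K+κ)/2πkT);
  the two routes agree to ~1e−10 and cross-check each other.
* **Mean energy.** ⟨E⟩_S = E(S, θ*) + (L−1)·kT/2 with θ* = M⁻¹b
  (equipartition for quadratic forms), independently validated against 1-D
  quadrature in the tests.
* **Sequence marginals (λ = 0).** P(S) ∝ Π_n e^{−β f_n(d_n)} is an
  inhomogeneous nearest-neighbour Markov field; position-specific k-mer
  marginals follow from forward/backward products of 4×4 transfer matrices,
  validated against complete enumeration at window length 6.

Default parameters (frozen in `data/toy_default.json`): 16 stiffnesses
log-uniform in [5, 50] kT_room/angle², intrinsic angles uniform in
[−0.3, 0.3], κ = 20, A = 0.2, p = 10 bp, φ = 0, λ = 0, drawn once from a
fixed RNG and shipped as data so every installation sees the same model.
Energies are in units of kT at room temperature; the default working
temperature is 1/6 of room temperature (β = 6) — cold enough that sequence
preferences are pronounced, warm enough that sampling mixes.

## Mutation Monte Carlo

`mmc_sample` runs Metropolis over the joint state (S, θ). Each elementary
proposal is, with probability `mutation_fraction` (default 0.5), a single-site
mutation to one of the three other bases (symmetric), otherwise a single-angle
perturbation uniform in ±`spatial_step` (default 0.15). A sweep counts
L + (L−1) proposals; sequences are recorded every `thinning_sweeps` (default
4; the benchmark experiments use 2) after `burn_in_sweeps` (default 200).
Both proposals are symmetric, so detailed balance holds and the recorded
sequences sample the exact marginal P(S) — verified against the
transfer-matrix marginals (λ = 0, L = 20, 10⁵ samples: ≥ 95% of
position-dinucleotide cells within 4 nominal binomial σ; thinning keeps the
residual autocorrelation small enough for that bound). Defaults were
convergence-tested against the oracle, not tuned per experiment. The chain is
initialized at a random sequence with θ at the energy minimum θ*; the kernel
is compiled with numba and generates ~10⁷ proposals/s, so a 10⁶-sequence
147-bp ensemble takes about a minute.

`mc_mean_energy` is the same chain with mutations disabled; it reports the
time-average of E with a batch-means standard error (~32 contiguous batches),
which absorbs residual autocorrelation.

## Landscapes and benchmarking

A landscape assigns an energy to every 147-bp window (step 1, 0-based start
index; windows overlapping an N are excluded and their starts recorded).
Boltzmann normalization shifts a landscape so Σ_windows e^{−E/kT} = 1 — a pure
offset, applied identically to model and reference landscapes before
comparison, which removes the unknown partition-function constants on both
sides. The decomposition splits a landscape into its 11-bp centered running
average (≈ one helical period; 5 positions trimmed at each end, this
package's edge choice) and the periodic component (signal − local average).
By construction full = average + periodic exactly on the common positions.

RMSDs of the three signals are expressed relative to bad-model scales: the
Boltzmann-normalized uniform landscape for the full and averaged signals, and
the reference's own periodic component shifted by half a period (5 bp) for
the periodic signal. Landscape pairs are always compared on the intersection
of their positions, so edge-trimming and N-exclusion cannot misalign them.

## Benchmark experiments and their conditions

`experiments.order_benchmark` fixes the study conditions: toy model at β = 6
with λ = 20, a 10⁶-sequence MMC ensemble (burn-in 200 sweeps, thinning 2),
and a 5 kb uniform random genome. λ = 20 is comparable to the on-site
stiffness scale K + κ (≈ 25–70), giving an effective inter-step correlation
parameter λ/(K+κ+2λ) ≈ 0.3: the elastic coupling then transmits sequence
information over a few steps, so the sequence distribution genuinely carries
beyond-nearest-neighbour correlations. In that regime the landscape RMSD
decreases strictly from mono- to di- to trinucleotide models once the
ensemble is large enough; with the toy model the trinucleotide model
overtakes the dinucleotide model between 10⁵ and 10⁶ training sequences, so
the 10⁶ default sits safely past the crossover. The 5 kb genome and the
other problem sizes (window length 8 for enumeration checks, L = 20 for
sampler validation) were chosen so the exhaustive oracles stay exact and the
full pipeline runs in minutes on one core.

`experiments.size_sweep` re-trains on nested random subsets of the same
ensemble (subsets depend only on the seed and the size index, so orders and
policies are compared on identical data) and tracks full-signal RMSD. It
reproduces the qualitative picture that accuracy is non-increasing in
ensemble size, that small ensembles hurt higher orders most (unseen k-mers),
and that eager 3-bp smoothing costs accuracy at large ensemble sizes.

## What the synthetic data does and does not emulate

Training ensembles here are MMC samples from the toy model and scoring
targets are uniform random genomes. This isolates exactly what the benchmark
needs: a known ground-truth energy function and an unbiased sequence sample
from its Boltzmann distribution. It does **not** emulate real nucleosomal
data: genomic base composition and repeat structure, experimental biases of
in-vitro/in-vivo maps, duplicate and overlapping reads from a finite genome,
or the 6-degrees-of-freedom mechanics of real DNA. Passing benchmarks
therefore demonstrate correctness of the modelling machinery and the
qualitative dependence on order/ensemble-size/policy, not quantitative
accuracy on any particular organism.

## Numerical choices and degenerate inputs

* All sequence probabilities are evaluated in natural-log space; 147-factor
  products cannot underflow. kT multiplies only at the energy boundary.
* Probability-table rows must sum to 1 within 1e−9; counts are recoverable
  from probabilities to 1e−6 when the table came from counting.
* Transfer-matrix forward/backward vectors are renormalized at every site;
  scale factors cancel in the per-position normalization.
* Banded Cholesky requires M positive definite, guaranteed by K > 0, κ ≥ 0,
  λ ≥ 0.
* Landscape normalization uses log-sum-exp. `local_average` requires at least
  11 windows and drops centers whose neighbourhood is interrupted by excluded
  windows. A landscape with a single window normalizes to E = 0.
* Reverse-complement symmetrization of training ensembles is available but
  off by default; strands are scored as given.
* Coordinates are 0-based half-open; the landscape position of a window is
  its start (the dyad is start + 73).

## Known limitations

* The toy model is a caricature: one degree of freedom per step, harmonic
  everywhere, no unwrapping, no histone-tail effects. It is an oracle for the
  machinery, not a model of real nucleosomes.
* `transfer_matrix_marginals` requires λ = 0; for λ > 0 only brute-force
  enumeration at small window lengths is exact, which is how the λ > 0
  pipeline is validated (indirectly, through the λ = 0 identities plus
  Monte Carlo agreement).
* Occupancy/positioning maps (dynamic-programming thermodynamics) are out of
  scope; the package benchmarks energies, not occupancies.
* The MMC kernel's random stream is numba's legacy per-thread RNG, seeded
  from the user seed; runs are bit-reproducible for a fixed seed and numba
  version.
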