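# Methods

This note documents the models implemented in `lgl`, the defaults and why
they were chosen, the numerical decisions that affect results, and what the
synthetic test families do and do not demonstrate about real data.

## Input representation

Alignments are read as aligned FASTA or Stockholm and normalized to a
frozen 23-letter alphabet `ACDEFGHIKLMNPQRSTVWYUO-` (20 canonical amino
acids, selenocysteine U, pyrrolysine O, gap last at index 22).  Dots become
gaps, lowercase becomes uppercase, and ambiguity codes (B, Z, X, J, \*) are
mapped to the gap with a logged count rather than raised as errors, because
family alignments derived from large databases routinely contain them.
Sequences whose longest run of consecutive gaps covers 20% or more of the
alignment length are removed before model fitting (boundary inclusive);
mutant libraries additionally drop variants whose terminal truncation
relative to the reference exceeds 20% of the length (strictly greater).
Truncation is measured as the tail run of columns where the mutant is
gapped but the reference is not: a premature stop manifests in an alignment
as exactly such a tail, and alignment-gap columns shared with the reference
carry no evidence of truncation.  One-hot encoding produces an
(n, L, 23) tensor with exactly one 1 per (sequence, position); decoding is
the per-position argmax, so encode/decode is a bijection on valid
alignments.

## Mean-field DCA Potts model

The family distribution is modelled as

P(S) = Z⁻¹ exp( Σ_{i<j} e_ij(a_i, a_j) + Σ_i h_i(a_i) ),

and sequences are scored with the Hamiltonian H(S) = −Σ e − Σ h (lower is
more family-compatible).  Z is never computed; every use is either H or a
difference of H values.

Estimation follows the standard mean-field inversion.  Single-site and
pair frequencies are computed with optional sequence reweighting — each
sequence weighted by the inverse size of its ≥ 80% identity neighbourhood —
and a uniform pseudocount λ: f_i ← (1−λ)f + λ/q, f_ij ← (1−λ)f + λ/q²
(diagonal blocks are pinned to δ_ab f_i(a) so pair marginals match exactly).
The connected-correlation matrix C_ij(a,b) = f_ij − f_i f_j is built over
q−1 states per site (gap state as gauge reference), inverted, and
e = −C⁻¹ mapped back to the q-state tensor; fields solve the mean-field
self-consistency h_i(a) = log f_i(a)/f_i(gap) − Σ_j Σ_b e_ij(a,b) f_j(b),
which makes the model's independent-site marginals reproduce f_i (verified
by a unit test to 1e-8).

Defaults: λ = 0.5 (relative weight) and reweighting ON at 80% identity —
the standard operating point of mean-field DCA on natural families, where
phylogenetic redundancy and limited sampling demand heavy regularization.
Whether the original landscape construction reweighted its alignments is
not documented; both knobs are exposed in the config and CLI.  The
couplings use the same q = 23 alphabet as the VAE so every decoded sequence
is scorable without remapping.

Two diagnostic helpers exist outside the landscape path: `zero_sum_fields`
(parameters transformed to the zero-sum gauge, the canonical gauge for
comparing field estimates between models) and `coupling_norms` (Frobenius
norms of zero-sum couplings, with optional average-product correction) for
contact-style ranking.  On ground-truthed Gibbs-sampled families (L = 20,
q = 5, n = 5000) the implementation recovers fields at Pearson r ≈ 0.95 in
the zero-sum gauge and ranks all 10 true coupled pairs in the top 10 norms;
these checks use a small pseudocount (0.01) and no reweighting because the
synthetic samples are i.i.d. and unregularized truth is being compared.

## Variational autoencoder

Architecture: one hidden layer per side with 3·L rectified-linear units,
a 2-dimensional Gaussian latent code, and a per-position softmax output
over the 23 symbols.  The encoder emits μ and log σ² (variance through an
exponential for positivity); sampling uses the reparameterization
z = μ + σ ⊙ ε.  The loss is the negative ELBO: reconstruction
cross-entropy −Σ_i log p(a_i | z) summed over positions plus the
closed-form KL divergence of N(μ, σ²) from N(0, I) summed over latent
dimensions, averaged over the batch.  Both terms are non-negative and have
analytic zeros (perfect reconstruction; posterior equal to the prior),
which the tests assert exactly.

Training: Adam at learning rate 1e-4, an L2 penalty of 1e-4 applied to the
hidden-layer weight matrices (the conventional reading of a penalty "on
the hidden units"), batch size 64, early stopping when the epoch mean
training loss has not improved for 10 epochs, best-epoch weights restored,
and a hard cap of 500 epochs.  Early stopping monitors the training loss —
the landscape is a descriptive model of its own training alignment, not a
predictor needing a holdout.  The whole network is explicit numpy with
hand-written backpropagation, which keeps training single-threaded,
dependency-free and bit-for-bit reproducible from the config seed.  Test
fixtures raise the learning rate to 1e-3–1e-2 so that toy families train in
seconds; the defaults above are the recommended operating point for real
families.

Depth is configurable but defaults to one hidden layer per side; with only
two latent dimensions, added capacity mostly sharpens memorization rather
than improving the landscape.  Whether reconstruction/KL are summed or
averaged per position is a convention choice that rescales the loss but not
the optimum; only relative loss behavior is asserted in tests.

## The landscape and its companions

The grid defaults to 500 × 500 pixels (250,000 decoded and scored
sequences) over the training embeddings' bounding box expanded by a 10%
margin per side — unstated in the original construction; the box guarantees
every training point falls inside the map, and explicit bounds can be
supplied and are stored in the output metadata for reproducibility.  The
pixel value is the Hamiltonian of the argmax sequence decoded at the pixel
center; argmax ties break to the lowest alphabet index, deterministically.
ΔH rasters subtract the Hamiltonian of the reference's *decoded
representation* S\* (encode to μ, decode, argmax), so the reference's own
pixel scores ΔH = 0.

The entropy map is the average per-residue Shannon entropy of the decoder
distribution, in nats (0 · log 0 := 0), bounded by [0, ln 23]; the base is
a convention choice and natural log is used throughout.  The re-encoding
vector field decodes each pixel's argmax sequence, re-encodes it, and draws
the displacement from the pixel to the resulting μ; on memorized models the
training embeddings behave as attractors of this field.

Filtered sampling draws latent coordinates from a spherical normal with
variance scale·I (default scale 2), gates acceptance on the *argmax*
sequence's Hamiltonian beating a cutoff, and emits the
*distribution-evaluated* sequence (independent categorical draw per
position) — the argmax filters, the sampler diversifies.  Accepted
coordinates are recorded alongside the sequences so acceptances can be
re-audited.  The cutoff is family-specific and has no default; an attempt
budget (default 1000 × n_samples) turns an unsatisfiable cutoff into an
informative error rather than a hang.

The radial-exclusion analysis quantifies how well the landscape's decoded
sequences track their inputs: for each training sequence, the Hamiltonian
of the input is paired with the Hamiltonian of the argmax sequence at its
encoded μ, and the Pearson correlation is recomputed as a disk of growing
radius around the latent origin (where decoder entropy is highest) is
excluded.  Radii with fewer than 3 survivors report NaN rather than raise.

## Evaluation protocols

**r20.**  For each K in 2..7, 3000 unique K-column sets are drawn (all
C(L, K) sets, with a warning, when fewer exist); per set, the reference
alignment's 20 most frequent motifs (ties broken lexicographically) have
their normalized frequencies looked up in the generated alignment (absent
motifs count 0) and the two 20-vectors are Pearson-correlated.  The
reported statistic is the per-K mean over column sets.  The source text
for this procedure is ambiguous about what is averaged; since each column
set yields exactly one correlation over 20 motif frequencies, the per-set
correlations are averaged.  Column sets with zero-variance frequency
vectors are counted and skipped, except when both vectors are identical
(self-comparison), which scores 1 by definition.  Self-comparison yields
exactly 1.0 for every K.

**Tree protocol.**  A 70-component Gaussian mixture is fit to the training
embeddings; components are discarded if their mean's decoded sequence fails
the Hamiltonian cutoff (automatic barrier detection), by explicit index, or
as the k lowest-membership components (`auto_exclude_smallest`, the
deterministic analogue of curating away degenerate clusters).  Each
retained cluster contributes 10 generated sequences (component draws,
rejection-gated by the argmax Hamiltonian, emitted as distribution draws)
and 10 randomly chosen natural members, with matching "cluster_index" ids —
64 retained clusters give paired 640-sequence MSAs ready for external tree
builders.  A retained cluster with fewer members than requested raises an
error naming it.

**Annotation transfer.**  Queries are encoded to μ and take the label of
the Euclidean-nearest training embedding (ties by training order,
deterministically).  With truth labels, predictions score
correct / coverage_error (truth label absent from the training label set) /
incorrect; with an ontology (child→parent edge list, cycle-checked),
exact / synonymous (direct or transitive ancestor–descendant) / missed.

**Mutant libraries.**  Combinatorial k-of-n mutants substitute target
residues at k of the positions where reference and target differ, chosen
uniformly without replacement, positions recorded per mutant.  The mutant
report embeds each variant (encoder μ), scores H and ΔH against the
reference, and computes fractional identity.

## Synthetic families

Two generators provide ground truth.  `make_truth_potts` +
`sample_potts_family` draw sequences from a known Potts model by
single-site Gibbs sampling (sequential sweep order; burn-in sweeps
discarded, every thin-th sweep kept; optionally several identical chains
vectorized together, each a seeded substream).  Empirical state frequencies
match exhaustive enumeration of the Boltzmann distribution on small models
within sampling error.  `make_clustered_family` draws per-cluster Dirichlet
position profiles (concentration 0.5 by default — peaked enough that
clusters separate in latent space, as real subfamilies do) and samples
sequences i.i.d. from them.  Families with q < 23 use the first q canonical
symbols so all downstream modules run unchanged.

Synthetic defaults mirror the scales at which the statistical properties
are testable on one CPU in seconds-to-minutes: n = 400–3000 training
sequences, L = 20, n = 5000 for inference-recovery checks.  What these
families lack, by construction, is phylogenetic correlation between
sequences, indel structure beyond profile gaps, and the long-tailed
subfamily sizes of real alignments.  Passing tests therefore demonstrate
the correctness of the algorithms and the recoverability of planted signal
— not that a 2-D VAE trained for a few seconds captures a real family's
statistics; on natural data, training runs to early-stopping convergence
at the default learning rate.

## Numerical details and degenerate inputs

- Softmax rows are computed max-shifted; decoder rows renormalize to 1
  within 1e-9 regardless of parameter scale.
- Batched and per-item evaluation are numerically identical paths for
  encoding, decoding, and Hamiltonian scoring (asserted at 1e-9 or
  tighter).
- A singular correlation matrix (e.g., duplicate-only alignments at zero
  pseudocount) raises an error that names the pseudocount as the remedy.
- Pseudocount may be anywhere in [0, 1]: 1 gives uniform frequencies
  (useful as a limit check) though inversion then fails as singular.
- Empty alignments are legal outputs of filters; empty query sets produce
  empty reports, not errors.
- All stochastic entry points accept a `numpy.random.Generator`; module
  seeds derive from user seeds and stay below 2³¹.

## Known limitations

- Landscape rendering requires exactly two latent dimensions; training
  with more is possible but unmapped.
- Mean-field DCA is the fastest, least accurate member of the DCA family;
  pseudolikelihood or Boltzmann-machine inference is out of scope.
- The Gibbs sampler is adequate for the weakly coupled synthetic families
  used here but will mix slowly on glassy, strongly coupled models.
- Tree building and tree-distance scoring are external by design; the
  package emits the paired MSAs only.
- The numpy VAE is single-threaded; training cost scales with n·L·hidden
  and becomes the bottleneck for alignments beyond ~10⁴ sequences.
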