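# Methods

## Model

pairgeom predicts binned inter-residue geometries from an MSA through a
frozen protein-language-model embedding and a trainable convolutional head.
The four predicted quantities follow the trRosetta scheme: Cβ–Cβ distance
`d`, the inter-residue dihedral `ω` (Cα_i–Cβ_i–Cβ_j–Cα_j, symmetric in
i↔j), the directional dihedral `θ` (N_i–Cα_i–Cβ_i–Cβ_j) and the directional
planar angle `φ` (Cα_i–Cβ_i–Cβ_j). Each is a per-pair classification: 37
distance classes (bin 0 = no contact at d ≥ 20 Å, bins 1–36 = [2, 20) Å in
0.5 Å steps), 25 classes for each dihedral (24 × 15° over (−180°, 180°] plus
the no-contact class) and 13 for φ (12 × 15° over (0°, 180°] plus
no-contact). Whenever d ≥ 20 Å, all four labels are the no-contact class, so
the angular heads are only asked to be right where a pair is geometrically
coupled.

The head architecture is: per-position MLP 768 → 384 → 192 → 128 over the
query row of the embedder features (ReLU between layers, none after the
last, no internal normalization); outer concatenation to 256 channels;
row attentions symmetrized as `M + Mᵀ` (addition, not averaging) and stacked
layer-major to 144 channels; three 1×1 convolutions 400 → 256 → 128 → 64,
each followed by instance normalization (learned affine) and ReLU; 28
pre-activation residual blocks (IN → ReLU → Conv3×3 → ReLU → Conv3×3 →
skip), 64 channels, both convolutions of block k dilated by `(1, 2, 4)[k mod
3]`; four independent 1×1 heads. Where a printed inventory left the order of
operations open (one instance norm, two ReLUs, two convolutions per block),
the pre-activation arrangement was chosen; both convolutions share the
block's dilation. Initialization is seeded He-normal for all weight
matrices, zeros for biases, gamma 1 / beta 0 for instance norms.

Posteriors are per-pair softmaxes; the symmetric objectives `d` and `ω` are
averaged with their position transpose by default, the directional `θ`, `φ`
are left asymmetric. This is an output-side convention choice; it can be
switched off.

## The embedding contract

The language model enters only through a contract: features `r × c × 768`
(last attention block output) and row attentions `12 × 12 × c × c`, each
slice row-stochastic. No gradients flow into the embedder anywhere. The
shipped stub embedder honors the contract deterministically: features are a
fixed seeded projection of one-hot tokens plus a positional term, attentions
are softmaxed bilinear scores over per-column residue-frequency profiles.
It is content-sensitive (different sequences give different features and
attentions) but carries no evolutionary signal — it exists so shapes,
gradients, serialization and metrics can be exercised end to end offline.
The optional adapter to a pretrained MSA transformer remaps the vocabulary
and strips the model's prepended begin-of-sequence column so attentions are
exactly `c × c`; symmetrization uses plain `M + Mᵀ` with no average-product
correction.

## Numerical implementation

The trainable head is implemented directly on numpy arrays with explicit
backward passes per layer (im2col convolutions with 'same' zero padding and
arbitrary dilation; the standard instance-norm backward over the spatial
axes). Gradient correctness is established by central-difference checks
through the entire stack (MLP → outer concatenation → reduction → trunk →
heads → cross-entropy) in float64; checks use short sequences so a weight
perturbation cannot flip ReLU activation states across the spatial map.
RAdam follows the rectified-variance formulation: moment estimates as in
Adam, the adaptive step applied only once the variance-rectification term
ρ_t exceeds 5, plain momentum updates before that. Default dtype for
training and inference is float32; optimizer statistics are kept in
float64.

## Training procedure

Loss is the equal-weight sum of four categorical cross-entropies averaged
over off-diagonal pairs; the diagonal is excluded and no-contact pairs are
trained with label 0 rather than masked. Optimization uses learning rate
1e-3, no schedule, no weight decay, no clipping (all config-exposed).
The effective batch of 16 is assembled by accumulating 16 micro-batches of
one example, since variable sequence lengths make padded batching wasteful;
with micro-batches of one, instance normalization sees exactly the same
statistics either way, so accumulation is equivalent to true batching up to
floating-point order. Each example is re-subsampled at every visit
(`min(r, max(16, ⌊2¹⁴/c⌋))` random rows, query kept), which acts as data
augmentation. Proteins longer than 1023 residues are skipped. An epoch is
one seeded shuffled pass over the dataset; runs are deterministic given the
config seed and resumable from checkpoints.

## Ground-truth featurization

Backbones are read from single-chain PDB files (first model, altlocs by
occupancy, residues missing N/CA/C dropped with a warning). Virtual Cβ
positions (glycine, or any residue without a deposited Cβ) use the
fixed-coefficient tetrahedral construction from the unnormalized frame
vectors u₁ = (Cα−N)×(C−Cα), u₂ = Cα−N, u₃ = C−Cα with coefficients
(−0.58273431, 0.56802827, −0.54067466). Dihedrals follow the right-handed
convention with trans = 180°, range (−180°, 180°]; +180° wraps into the top
bin. Binning is half-open [lo, hi); distances below 2 Å (steric clashes in
deposited coordinates) are clamped into bin 1 with a warning rather than
rejected. The featurizer is validated against an independent
double-precision brute-force implementation (projection-formula dihedrals)
and cross-checked against biotite's geometry routines, which compute in
float32 and therefore agree to ~10⁻³ degrees rather than machine precision.

## Subsampling

Hamming fraction counts mismatching columns over all c positions, gaps
counted as an ordinary symbol. "Lowest average Hamming distance" is read as
greedy accretion: the average is taken over the already-selected set,
starting from the query, ties broken by lowest original row index. The
alternative reading (distance to the query only) differs only in degenerate
cases; the greedy form matches the incremental phrasing of the selection
rule and is deterministic. The training-time row count is a deterministic
clamp — randomness applies only to which rows are drawn, not to how many.
Duplicate rows are preserved by the parser; deduplication is left to
callers.

## Synthetic data

The MSA generator mutates a uniform-random query per column with probability
`mutation_rate` (uniform over the 19 alternative residues, so a substitution
always changes the symbol) and inserts gaps with probability `gap_rate`;
the expected Hamming fraction to the query is `m(1−g) + g`. Defaults
(`mutation_rate` 0.2, `gap_rate` 0.05) give the moderate divergence typical
of a usable homology search; there is no phylogenetic correlation, no
coevolution and no column-wise conservation structure, so passing tests
demonstrate pipeline correctness, not predictive skill on real proteins.

Backbones are grown by natural-extension (NeRF) placement from ideal
peptide internal coordinates (N–Cα 1.458 Å, Cα–C 1.525 Å, C–N 1.329 Å,
standard angles, trans ω). `ideal_helix` uses φ = −57°, ψ = −47°,
reproducing the ~1.5 Å rise and ~100°/residue turn of a standard α-helix;
`helix_turn_helix` joins two helices by a two-residue turn whose dihedrals
((120°, −90°), (0°, 120°)) were fixed once by a grid search for packing
that yields separation ≥ 24 Cβ contacts under 8 Å at every tested length;
`random_chain` draws φ/ψ uniformly and is the workhorse of the geometry
oracles. Written PDBs carry minimal ATOM records (N, CA, C, CB except
glycine).

## Problem sizes and fixtures

The test suite and the acceptance script run everything at desk scale as
the package's own study conditions: contract checks on an 8 × 32 alignment;
geometry oracles on 100 random 8-residue chains; binning oracles on a
120-residue map (> 10⁴ in-contact pairs per objective); ranking oracles on
30-residue instances; and an overfit run of 200 accumulated micro-steps on
two 32-residue synthetic proteins with the full-size network (28 blocks).
For that fixture the accumulation window is the dataset size (2), i.e. 100
optimizer updates at the standard learning rate — with the production
window of 16 an overfit this short would make only 12 updates, which is a
statement about the fixture, not about the training loop, whose default
remains 16. The run cuts the loss to well under a quarter of its initial
value and reaches top-L/5 = 1.0 long-range precision on its own training
fixture, which demonstrates that gradients, optimizer and featurization are
wired correctly — nothing more.

## Known limitations

* The stub embedder carries no coevolutionary information; predictive
  performance on real proteins requires the pretrained adapter and real
  training data, neither of which is bundled.
* The numpy network is single-threaded-friendly but unbatched; very long
  sequences (c near the 1023 training cutoff) are slow and memory-hungry
  compared to a GPU implementation.
* Only single-chain, single-model PDB inputs are supported; mmCIF is not.
* The restraint archive stores float32 posteriors; consumers needing exact
  re-normalization should re-softmax from logits, which are not stored.
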