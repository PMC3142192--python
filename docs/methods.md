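# Methods

## The two-step hybridization model

starpick predicts targets of *trans*-acting bacterial small RNAs (sRNAs,
40–500 nt) among mRNA translation-initiation regions.  Hybridization is
modeled in two steps: (i) nucleation at a **seed**, a short helix of
perfectly consecutive inter-molecular base pairs (Watson–Crick plus G-U
wobble), which must be both thermodynamically stable and *accessible* in
the pre-existing secondary structures of both molecules; (ii) elongation
of that initial duplex into the full **binding site**.  Candidates
surviving both steps are described by 22 structural and energetic
features and scored by a voting ensemble of 1000 classifiers; the voting
fraction is reported as an interaction probability with a (strict) 0.5
decision threshold.

Three energies drive the screening, all in kcal/mol at 37 °C:

* `ΔG_hybrid` — minimum free energy of the purely inter-molecular duplex
  between two regions;
* `ΔG_open = ΔG_unpaired − ΔG_paired` — cost of freeing a region from
  intra-molecular structure, where `ΔG_paired` is the unconstrained
  ensemble free energy (−RT ln Z) and `ΔG_unpaired` the ensemble free
  energy with the region forced single-stranded.  Non-negative by
  construction (the constrained ensemble is a subset); engine rounding
  below −0.05 kcal/mol raises, smaller negatives clamp to 0;
* `ΔΔG = ΔG_hybrid + ΔG_open(sRNA region) + ΔG_open(target region)` —
  the accessibility-corrected interaction energy.

For sRNAs the opening energy folds the full molecule; for mRNA targets
it folds the region plus up to 100 nt of flanking sequence each side
(base pairs spanning more than ~100 nt are rare, and the truncation
bounds the cubic folding cost).  Flanks shorter than 100 nt at molecule
ends are used as-is.

## Seed selection

All maximal antiparallel runs of consecutive complementary pairs between
the sRNA and the 250-nt target window are enumerated (sub-runs are not
emitted separately), terminal G-U pairs are trimmed from both ends, and
runs of ≥ 5 pairs are kept.  Composition rules then apply by length:
5 nt — no G-U and ≥ 4 G-C or 3 consecutive G-C; 6–7 nt — ≤ 1 G-U and
≥ 3 G-C; 8–9 nt — ≤ 1 G-U and ≥ 2 G-C; ≥ 10 nt — ≤ 4 G-U and ≥ 2 G-C.
The "3 consecutive G-C" alternative applies to the length-5 rule only,
measured within the seed.  Rule-passing seeds are scored and kept when
`ΔΔG_seed` is strictly below −2 kcal/mol (`--seed-ddg-threshold`).
Composition rules run before the energy screen: energies are only
computed for helices that already satisfy the cheap combinatorial
conditions, which is also the order in which the screens are defined.

## Extension

Each selected seed is extended independently (overlapping survivors are
not merged).  The sRNA is co-folded with the target seed region plus up
to 100 nt of window context per side, with every seed pair enforced,
lonely (isolated) pairs disallowed and G-U forbidden at helix ends.  The
production engine enforces the latter two natively; for engines without
native support an engine-agnostic post-pass prunes violating pairs
(seed pairs exempt) to a fixed point.  From each seed boundary the joint
structure is scanned outward over inter-molecularly paired or unpaired
positions; the first position in an intra-molecular pair halts that
side.  Unpaired positions *between* inter-molecular pairs belong to the
site (interior loops and bulges are features of the hybrid), and the
site is then clipped to the outermost inter-molecular pair on each side.
When the window edge truncates the context, extension stops at the edge.
Identical extended sites reached from different seeds are deduplicated
keeping the smallest `ΔΔG_seed`.

## Features

The hybrid is the concatenation of the sRNA-site and target-site
nucleotides with its inter-molecular pairs.  Features: f1–f7 nucleotide
composition percentages (A, C, G, U, G+C, A+U, A+C); f8/f17 paired and
unpaired percentages (f8 + f17 = 100 exactly); f9, f10 pairing within
duplexes of ≥ 3 bp (percentage of nucleotides, fraction of pairs); f11
maximum consecutive pairs; f12–f16 interior-loop and bulge counts and
nucleotide percentages (interior loop: unpaired stretch on both strands
between consecutive pairs; bulge: on exactly one strand); f18/f19 ΔG
and ΔΔG of the binding region; f20/f21 of the seed; f22 seed length.
Percentage denominators use the nucleotides of both strands.  Features
stay on natural scales; the tree-based learner is scale-free.

## Folding engines

All energies go through one deterministic engine contract with two
implementations:

* **ViennaEngine** (production): RNAduplex-style duplex folding for
  `ΔG_hybrid`; the constrained partition function for `ΔG_paired` /
  `ΔG_unpaired`; two-strand MFE folding with enforced seed pairs, noLP
  and no-closing-G-U for extension.  Dangling-end and terminal-AU
  options stay at library defaults; the engine id and version are stored
  in the model file.  (The two-strand MFE entry point is used directly;
  the dimer-specific call in the installed library build crashes under
  enforced-pair constraints.)
* **ToyEngine** (reference): a stacking-free model — pair energies
  G-C −3, A-U −2, G-U −1 kcal/mol, no loop terms, minimum hairpin loop
  3 nt — with exact MFE (interval dynamic programming) and exact
  partition function (per-nucleotide rescaling keeps Z in double range;
  the scale derives from the unconstrained MFE).  Every test and the
  acceptance script run fully offline on this engine, and its results
  are verified against explicit structure enumeration.  Absolute
  energies are larger in magnitude than nearest-neighbor values, so
  toy-engine scores are comparable only to toy-engine scores.

Seed-retention statistics computed with nearest-neighbor engines depend
on the exact parameter-set version of the folding programs; the engine
contract isolates that dependency.

## Ensemble training

Positive/negative samples come from extended binding sites: per
sRNA–target pair, among candidates overlapping a validated site the one
with the smallest `ΔΔG_seed` is the positive; candidates overlapping the
chosen positive are discarded; mutually overlapping negatives are
greedily deduplicated keeping the smallest `ΔΔG_seed`.

Feature selection is a forward wrapper: a beam of width ten records, for
each subset size 1–10, the ten subsets with the best leave-one-out
cross-validation accuracy (ties lexicographic).  The best subset of each
size then undergoes **stability analysis**: 1000 uniform random 75/25
train/test partitions (degenerate splits with a one-class training
portion are resampled and logged), each training one base classifier and
scoring it on the held-out 25 %.  The mean test accuracy is the
stability index; the subset with the highest index wins (ties: smaller
subset, then lexicographic), and its 1000 stability-round classifiers
*are* the final ensemble.  Evaluating one subset per size reproduces the
one-stability-value-per-feature-count selection curve; ranking every
recorded subset instead is available through the lower-level API, but
with ~40 near-tied noisy candidates the argmax degrades into a
max-of-noise draw on ~130-row tables.

The base learner is a depth-3 decision tree with information-gain
splits, a minimum of 5 samples per leaf, and fully deterministic
tie-breaking (smaller feature index, then smaller threshold midpoint;
leaf ties predict non-interacting).  The depth limit and leaf floor are
variance controls sized for ~130-row training tables — without the leaf
floor such trees memorize handfuls of rows and single-feature LOOCV can
fall below the majority-class rate.  Any scale-free, cheap-to-fit
classifier could stand in the tree's place behind the same voting
interface.

Prediction is unweighted voting: probability = positive votes / 1000,
exactly on the 0.001 grid; "interacting" means probability strictly
greater than the threshold.  Per-round RNG seeds derive from the master
seed by hashing, so the whole training path is reproducible end to end.

## Target windows and ranking

The putative binding region is the sub-sequence from −150 to +100 nt
around the start codon: 150 bases upstream plus 100 bases beginning at
(and including) the start-codon first base; there is no position 0.
Minus-strand genes use the reverse complement (the start-codon first
base is the CDS end coordinate on the forward strand); up to 100 nt of
genomic flank per side is kept as accessibility context; contig edges
truncate silently, and truncated genes are processed, not skipped.
Results sort by probability (descending), then ΔΔG of the binding
region, then ΔΔG of the seed (both ascending), with residual ties broken
by gene id for determinism; genome-wide reports keep all candidate sites
of a pair, and the per-pair ranking view keeps the smallest-rank site.

## Synthetic data

The generators provide label-known inputs for every stage:

* `generate_pair` plants an exact complementary helix of chosen length
  and G-C/G-U composition (terminal pairs never G-U) in random
  backgrounds (default A/U-rich — 40/40/10/10 — which keeps accidental
  rule-passing seeds rare); bases stacking onto the helix ends are
  pinned unpairable so the planted run is exactly maximal.  The
  `occluded` variant wraps the target stretch in a perfect hairpin stem,
  making its opening energy large.  Generators audit their own output
  for unplanned rule-passing seeds.
* `generate_training_table` draws a 22-feature table (default 31
  positives : 102 negatives, the imbalance the predictor is designed
  for) with signal only on f19 (binding-region ΔΔG, lower in positives)
  and f22 (seed length, longer in positives) at a stated effect size
  (default 2.0 SD).  Positives clear *both* screens of the two-step
  model — ΔΔG below a bound and a long seed — while 20 % of negatives
  are stable-but-short and 20 % long-but-inaccessible decoys, mirroring
  the two failure modes of pseudo-interactions.  Each feature alone
  therefore misclassifies one decoy population (single-feature LOOCV
  ≈ 0.80) and only the pair excludes both (≈ 0.97), which is what makes
  the planted subset recoverable by wrapper selection.  All other
  features are label-independent noise on natural scales; effect 0
  degenerates to a pure null.
* `generate_genome` builds a contig of non-overlapping CDSs alternating
  strands (strand-balanced planting), with each planted target carrying
  the sRNA-complement cassette inside its window, ending at position
  −20: `fence | C-buffer | complement | C-buffer | fence`.  The
  C-buffers are nearly unpairable against the A/U-rich sRNA and the
  fences are self-pairing hairpins that always fold in the MFE and halt
  the outward scan — without them, the loop-penalty-free toy model
  extends sites into arbitrarily long gappy A-U tails whose opening cost
  buries the planted interaction.  The planted helix is purine-only on
  the sRNA side so its C/U-only complement cannot pair the buffers.

What the synthetic data does *not* emulate: real genome composition and
codon structure, Hfq binding, transcript boundaries, nearest-neighbor
energetics (toy energies are a different scale), and biological feature
correlations.  Passing tests therefore demonstrate correctness of the
algorithmic pipeline under controlled conditions, not field performance
on real genomes.

## Problem sizes used in verification

The shipped verification suite runs the toy engine throughout: 500
random duplex instances (combined ≤ 24 nt) and 200 folding instances
(≤ 20 nt) against enumeration oracles; 500 random 60 × 260 seed
enumeration instances against a brute-force diagonal scan; 1000 random
hybrids for the feature identities; 20 independent training repetitions
(selection up to 4 features — the planted signal spans two, and larger
subsets only add noise candidates — with the full 1000 stability
rounds); and a 20-gene genome with 2 planted targets.  The training
operating point is also reported on a held-out table drawn from the same
synthetic conditions, where specificity exceeds sensitivity at
threshold 0.5, the direction expected from the 1:3.3 class imbalance.

## Known limitations

* The toy engine's absolute energies (and hence the −2 kcal/mol seed
  threshold's stringency) are not calibrated to nearest-neighbor
  values; genome-scale conclusions require the Vienna engine.
* No pre-trained model ships with the package: the experimentally
  validated sRNA-target pairs needed to train one live in external
  databases.  The training *procedure* is implemented in full and
  exercised on synthetic data; users with curated interaction sets can
  train their own model with `starpick train`.
* Seeds shorter than 5 pairs are invisible by design; interactions
  nucleating on such seeds are missed.
* Pseudoknots, suboptimal joint structures and operon-aware windows are
  not modeled; annotation start codons are trusted as given.
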