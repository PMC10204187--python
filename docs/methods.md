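# Methods

## Model and assumptions

The package treats an ortholog family as independent draws from position-wise
residue preferences. Each ortholog is compared to the reference by an
*optimal global pairwise alignment* rather than a multiple sequence
alignment: with tens of thousands of orthologs, pairwise reference anchoring
is linear in family size, keeps every statistic in reference numbering, and
matches how large pangenomic PSSMs are built in practice. The price is that
columns are defined per pair, so a residue's "position" is only as good as
each pairwise alignment; at the identity levels targeted here (≥ 25%) global
alignment of full-length orthologs is reliable.

The profile is a pure frequency PSSM: per reference position, counts of the
20 standard residues over the orthologs aligning a residue there. Gaps are
excluded from the per-site denominator and reported separately as
`gap_count`; this choice prevents indel-rich regions from depressing residue
frequencies, at the cost of making per-site coverage vary. `X` (unknown)
residues count toward coverage but never enter the 20-residue table or the
background.

"Expected frequency" — the yardstick for favored/avoided calls — is the
pooled background: the frequency of each residue over all aligned non-gap
cells of the whole family. This background reflects both the family's
composition and the alignment, and is the natural null for "does this site
prefer residue *a* more than the protein as a whole does". A uniform 1/20
background is available (`background="uniform"`) for compositionally skewed
families.

## Alignment

Needleman-Wunsch with affine gap penalties (a run of length L costs
`gap_open + (L−1)·gap_extend`), BLOSUM62, open 11, extend 1 — the standard
protein-search defaults; all three are configurable. Terminal gaps are
penalized (true global mode). The aligner backend is Biopython's
`PairwiseAligner`; among co-optimal alignments the backend's first-reported
traceback is used, which is deterministic for fixed inputs, and the test
suite verifies score optimality against an independent exhaustive
enumeration of all global alignments on random short pairs. `X` scores 0
against every residue and never counts as an identity. Percent identity uses
all alignment columns (including gap columns) as the denominator by default;
`denominator="aligned"` switches to gap-free columns, which is what the
structure-chain mapping uses so that a subunit chain covering only a segment
of the precursor is not rejected for its terminal gaps.

Only global alignment is implemented; local alignment and nucleotide support
are non-goals.

## Classification thresholds

* `pseudocount` (default 1.0, Laplace) smooths only the observed frequency
  inside favored/avoided comparisons and log-odds; the emitted table stays
  unsmoothed so it is a pure frequency PSSM. With a zero pooled background
  for some residue the log-odds is ±∞ by convention (never hit on realistic
  families).
* `min_count` (default 5) keeps singletons in large families from being
  called favored.
* "Highly conserved": modal frequency ≥ 0.9 with coverage ≥ 50% of the
  family (`min_modal_freq`, `min_coverage_frac`, both configurable and
  echoed in outputs).
* Site variability is Shannon entropy (bits) of the 20-residue frequency
  vector, gaps excluded; ties in `most_variable_site` break to the lowest
  position.

## Active-site neighborhood

"Close vicinity" is a distance query: all residues with an in-scope atom
(all-atom, side-chain, or Cα scope) within `radius_A` (default 8 Å) of any
in-scope atom of an anchor residue, anchors defaulting to the catalytic
triad. Every protein chain in the file is aligned to the reference and the
hits are reported in reference numbering, deduplicated across chains — this
is how a heterodimer whose α and β chains are both fragments of one
precursor contributes a single position set. Chains under 20% aligned-pair
identity to the reference are skipped (wrong chain / different entity). The
resulting set is a *default suggestion* for the binding-site position list;
users with a curated list (e.g. 17 positions from prior structural work)
should pass it explicitly, and the bundled default binding-site list is
exactly such a curated set of 17 active-site-shell positions. Alternate
locations collapse to a single conformer; waters and non-peptide
heteroatoms are dropped; nonstandard amino acids map to `X` (mapped, never
profiled).

## Candidate ranking and ortholog selection

Candidates at the focal site are the favored non-reference residues ranked
by **raw frequency** (the residues most often found in nature), with
log-odds then alphabetical order as tie-breaks; log-odds ranking is a
documented alternative key but not the default, because enrichment and
abundance diverge exactly for rare residues, and a mutagenesis shortlist
should start from abundance.

Selection for modeling filters, per target focal residue, to orthologs
carrying that residue with overall identity inside the window
(default 25–65%, **bounds inclusive**), then greedily picks in descending
identity (ties by lexicographic id), skipping any ortholog whose
binding-site signature — its ordered residue tuple at the binding-site
positions, gap markers included — duplicates an already-chosen one, until
five are taken. Greedy-by-identity was chosen over a
maximal-signature-diversity objective for determinism and auditability; the
diversity objective is a possible extension. Shortfalls are warnings, not
errors.

## Synthetic families

The generator draws each sequence independently: per position a residue from
that position's categorical distribution, then a Poisson(`indel_rate`)
number of single-residue deletions at uniform positions. Unlisted positions
keep the reference residue with probability `p_conserved`, spreading
`substitution_spread` of the remainder uniformly over the other 19 residues.
All sampling uses one integer-seeded NumPy `Generator`; runs are
deterministic across platforms, and the recorded ground truth (per-sequence
substitutions and deletions) replays to the exact emitted sequences.

The "benchmark" preset emulates the conservation structure reported for
bacterial Class 2 L-asparaginase families: 57 positions in contiguous blocks
around the catalytic triad and substrate-binding shell near-fixed at 0.99,
the focal gate position carrying the mixture M 0.35 / W 0.15 / L 0.15 /
T 0.13 / K 0.12 / I 0.10 (so the five non-reference residues jointly exceed
half the family), all other positions at `p_conserved` 0.7, 2,000 sequences,
deletion rate 0.3 per sequence. Because the reference itself is a synthetic
stand-in (a fixed random 321-mer with the canonical active-site residues
pinned at positions 117–122, 179, 197, 199–204, 207, 210–211, 230, 232, 234
and 238), tests against this preset demonstrate *pipeline correctness and
statistical recovery*, not properties of any natural protein. What the
preset does not model: phylogenetic correlation between sequences (every
ortholog is independent, so real families conserve less information per
sequence than these), insertions relative to the reference, alignment
ambiguity in low-identity regions, and compositional bias.

Frequency-recovery checks compare, per site, the observed frequency of the
site's true modal residue with its generating probability, using the
3-standard-error binomial band √(p(1−p)/n) at that site's coverage; with
independent draws ≈ 99.7% of sites should fall inside, and the acceptance
threshold is 99%.

## Problem sizes

Default test and reproduction scales: 1,000 random pairs for the alignment
oracle; 20 families of 500–2,000 sequences for frequency recovery; 20 seeds
of the 2,000-sequence preset for candidate recovery; 1,000 random pools for
selection invariants; an 800-sequence divergent family
(`p_conserved` 0.55, mean identity ≈ 63%) for the selection demonstration,
chosen so the identity distribution straddles the upper window bound.

## Known limitations

* No phylogenetic down-weighting: over-represented clades bias both the
  profile and the background.
* Pairwise anchoring cannot represent ortholog insertions in the profile
  (they are counted per flanking position but not profiled).
* The distance-based neighborhood depends on the supplied structure's
  conformational state; a ligand-gated residue may move several Å between
  apo and complexed forms.
* Identity figures depend on the alignment parameters; with other
  matrices/penalties the 25–65% window selects a somewhat different pool.
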