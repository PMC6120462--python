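# Methods

## The analysis in brief

The package reconstructs a sequence-based enzyme-discovery procedure for
imine reductases (IREDs): starting from candidate protein sequences and a
small set of confirmed template enzymes, it selects candidates by homology
and active-site criteria, aligns the survivors, builds a neighbour-joining
phylogeny, types each enzyme by its proton-donor residue (D-type vs
Y-type), and predicts stereoselectivity from a second residue pair. A
separate module implements the photometric arithmetic used to characterise
hits. All coordinates are 1-based residue positions; "reference numbering"
means positions in the reference enzyme (IRED-B, UniProt Q1EQE0 in the
bundled panel) transferred to candidates through alignment columns.

## Homology gate

The original procedure used a protein BLAST search of UniProtKB. At desk
scale the package scores each candidate against each template with
full (non-heuristic) Smith–Waterman local alignment under BLOSUM62 with
affine gaps, and converts raw scores to E-values with the Karlin–Altschul
form `bit = (λ·S − ln K)/ln 2`, `E = m·n·2^(−bit)`. This is a deliberate
surrogate, not a BLAST re-implementation: there is no k-mer seeding, no
X-drop, no composition-based statistics, and the effective database length
`n` is supplied by the caller (default: the summed length of the candidate
pool). Defaults are the standard gapped-BLOSUM62 constants λ = 0.267,
K = 0.041 and the protein-search gap costs open −11 / extend −1; all are
configurable because the original search parameters are not recoverable.
The gate takes the best E-value over the templates (union semantics over
the pooled searches) and admits candidates at E ≤ 10⁻⁵⁰.

Gap convention: a gap run of length L costs `open + (L−1)·extend`, so a
single-residue gap costs exactly `open`. Traceback ties are broken
diagonal → gap-in-subject → gap-in-query, which makes alignments (not just
scores) deterministic. Unknown residues (`X`) score 0 against everything in
the matrix, but any record containing `X` fails the motif/residue criteria
rather than being silently classified.

The dynamic programme is verified against two independent oracles: an
explicit enumeration of every alignment path for all sequence pairs of
length ≤ 4 over a four-letter alphabet (115 940 score comparisons), and
Biopython's `PairwiseAligner` on longer random pairs.

## Rossmann / full-length criterion

"Full-length Rossmann-fold protein" is operationalised as: length ≥ 250
residues and a `GxGxxG` match starting within the first 60 residues. The
two numbers are declared conventions chosen from typical IRED domain
geometry (~290-residue subunits with the dinucleotide-binding motif in the
N-terminal domain); the source procedure states no cutoffs, and both are
configurable. Overlapping motif hits are all reported; the earliest one
within the window is the one quoted in verdicts.

## Residue criteria and position transfer

Candidates are globally aligned to the reference; each required reference
position maps to the candidate residue in the same alignment column, or to
"unaligned" when the candidate has a gap there. An unaligned key position
fails its criterion (with reason `*:unaligned`) instead of raising, so
batch runs always complete. The criteria are exactly the quoted residue
lists: Ser/Thr at 111; Asp/Glu at 187 with apolar (Ala/Ile/Leu/Met/Phe/Val)
residues at *both* 137 and 191; or Tyr at 187 with no flank requirement.
Both published readings of the criteria list are supported: the
four-criterion reading (including polar-111) is the default, and the
polar-111 rule can be toggled off to reproduce the three-criterion reading.
Every verdict records the observed residues alongside each boolean so a
filter run is auditable line by line.

## Deduplication

Duplicates (same accession) and redundant entries (different accession,
identical residue string) are removed keeping the first occurrence in
input order. Keep-first is a declared convention — the source procedure
does not say which member of a redundant pair was retained. Near-identical
sequences are *not* collapsed; redundancy means exact equality only.

## Multiple alignment and phylogeny

The survivors are aligned progressively: pairwise global alignments give
p-distances, a neighbour-joining guide tree fixes the merge order, and
profiles are merged with the same affine DP on expected column scores
(profile frequency vectors through the substitution matrix). Degapping any
output row reproduces the input sequence exactly; this invariant is tested
on every input.

Distances from the alignment use pairwise deletion (only columns where both
sequences carry residues) and, by default, the Poisson multiple-hit
correction `d = −ln(1 − p)` so branch lengths read as substitutions per
site; the uncorrected p-distance is available. The exact distance
correction used by the original Clustal-based analysis is not recoverable,
so the tree is a qualitative, not numeric, reproduction target.

Neighbour joining follows Saitou–Nei (Q-matrix minimisation with the
standard branch-length formulas). Ties in Q are resolved to the lowest
index pair; negative branch-length estimates are clamped to zero with a
warning. On additive matrices the implementation is exact: 100 random
4–12-taxon trees are recovered with Robinson–Foulds distance 0 and induced
path lengths within 1e-9. Trees are left unrooted (trifurcating root);
newick serialisation orders children by smallest leaf label, making output
byte-deterministic. Donor-type monophyly is defined edge-wise on the
unrooted tree: a type is monophyletic when some edge separates exactly its
leaves (equivalently the set or its complement is a clade of the rooted
representation).

## Stereoselectivity classification

The bundled reference panel mirrors the printed partial-alignment segments
of 14 characterised enzymes. Segment columns are treated as alignment
columns anchored to the printed IRED-B coordinates: segment 1 ends at the
139-equivalent column (columns 4 and 6 ↔ 137/139) and segment 2 starts at
the 185-equivalent column (columns 3, 7, 10 ↔ 187/191/194). This is the
only reading under which the anomalous enzyme IRED-G shows Pro and Phe at
139/194, as described for it.

The S-rule (Pro139 + Phe194) takes precedence over the R-rule
(Val/Thr/Ile 139 + Met/Leu 194) because the S-markers are reported as
invariant among (S)-selective enzymes while the R-markers are typical;
`matched_rule` is always reported so the precedence is transparent.
Enzymes matching neither rule are *indeterminate* — notably IRED-L, which
is experimentally (S)-selective but carries Ala at 139; the classifier
reports the discrepancy rather than resolving it. Donor typing and marker
prediction disagree for exactly one panel member (IRED-G), reproducing the
published anomaly.

## Assay arithmetic

Specific activity is `A = (ΔOD − ΔOD_blank)/(ε·l·c_P)` in U/mg
(µmol·min⁻¹·mg⁻¹), with ε the NADPH extinction coefficient at 370 nm
(2.216 L·mmol⁻¹·cm⁻¹), `l` the path length in cm and `c_P` the protein
concentration in mg/mL. Negative corrected slopes clamp to zero activity
with a flag — the photometric assay cannot report negative consumption.
Replicates aggregate as mean ± sample standard deviation (ddof = 1). Path
length is always a required input; per-well instrument corrections are
outside scope. Slope extraction from raw time series is the instrument's
job; a plain OLS helper over a user-specified window is provided for
convenience. pH optima are argmax conditions of mean activity (ties
returned as a set, profile normalised to max = 100 %); thermal retention
is activity(T)/activity(reference). Conversion and ee use
`ee = (major − minor)/(major + minor)·100` and a response-factor-scaled
product/(product + substrate) ratio, with the response factor defaulting
to 1.

## Synthetic data: what it emulates and what it does not

`simulate.generate_family` draws a random binary tree whose two root
subtrees are the D-type and Y-type clades (branch lengths exponential,
mean 0.15, floor 0.02, clade stems 0.25), builds a 290-residue ancestor
with the `GxGxxG` motif planted at position 15 and the key residues planted
at 111/137/139/187/191/194 (D-clade: Asp donor with R-markers; Y-clade:
Tyr donor with S-markers), and evolves sequences site-independently: the
number of substitution events per site on a branch of length t is
Poisson(rate·t) (default rate 0.3 events per site per unit branch length),
each event replacing the residue uniformly among the other 19. Planted
sites are hard-protected in positives, and accidental `GxGxxG` matches in
the N-terminal window are scrubbed, so the selection criteria are
deterministic features of every positive. The ancestor itself carries the
D-regime residues, making the reference/template a valid family member.
Each family is self-audited at generation time: the truth table is
recomputed from the emitted sequences.

Planted negatives violate one criterion each: motif ablation, truncation
to 230 residues (below the 250-residue length floor but long enough to
retain all key residues, so only the length criterion fails), a Lys donor,
a polar 191-flank on an Asp-donor background, an apolar residue at 111,
and an unrelated random sequence as a distant outgroup. The outgroup is
guaranteed only to fail the homology gate; it may incidentally fail later
criteria too, and tests require the E-gate failure to be named rather than
to be unique.

The generator deliberately omits several features of real sequence data:
no indels by default (reference numbering is then the identity map, which
keeps neighbour-joining exactness tests sharp), no empirical amino-acid
exchangeability (uniform replacement), no rate variation across sites, no
compositional bias outside the planted features. Passing the planted-truth
tests therefore demonstrates correctness of the pipeline's logic under its
own model assumptions — not performance on real, indel-rich, biased
databases, where alignment quality and the E-value surrogate would
dominate.

## Problem sizes and numerical choices

Default study sizes: 20-taxon families (10 per clade) with 4 negatives per
violation mode for filter-recovery checks; 16 taxa for the end-to-end
monophyly check; 100 random 4–12-taxon trees for neighbour-joining
exactness; all sequence pairs of length ≤ 4 over a four-letter alphabet
for the alignment oracle. Alignment inner loops are numba-compiled;
exhaustive enumeration oracles are compiled too but share no recurrence
with the DP. Floating-point tolerances: NJ exactness at 1e-9 on induced
path lengths; newick round trip at 1e-10; everything else exact or at
pytest's default relative tolerance.

## Known limitations

* The E-value surrogate is calibrated with published gapped-BLOSUM62
  constants, not fitted to the scoring system at hand; absolute E-values
  are indicative, and the 10⁻⁵⁰ gate should be interpreted relative to
  this convention.
* Progressive MSA has no iterative refinement; alignment errors cannot be
  repaired after a bad early merge (mitigated here by moderate divergence).
* The original discovery counts (1065 hits → 215 → 182 → 116 D-type)
  depend on a historical database snapshot and are not reproduction
  targets; the pipeline reproduces the *procedure* and its arithmetic, and
  the dedup arithmetic is exercised on synthetic pools of the same shape.
* Bootstrap support, likelihood-based phylogenetics and tree graphics are
  out of scope.
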