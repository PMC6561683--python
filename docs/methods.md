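# Methods

## The motif model

A KFERQ-like motif is modeled as a 5-residue window with a flank residue at
the first or last position and a 4-residue variable region.  The variable
region must contain 1–2 basic residues (K, R), 1–2 hydrophobic residues
(I, L, V, F) and exactly one "acidic-slot" residue, the three categories
filling all four positions.  The acidic slot is D/E for the canonical and
acetylation-generated classes and exactly one of S/T/Y (with no D/E
anywhere in the region) for the phosphorylation-generated class; the flank
is Q for the Q-flanked classes and K — acidic once acetylated — for the
acetylation-generated class.  Key interpretation choices:

- **The flank is part of the window.**  "A glutamine on either side" is
  read as first-or-last position of the pentapeptide (KFERQ itself is five
  residues); every window is therefore tested in both orientations.
- **One PTM per motif.**  A window that would need two simultaneous
  modifications (K flank *and* a phospho-acceptor acidic slot) is not a
  motif.  Likewise a region mixing D/E with S/T/Y satisfies neither class:
  under canonical rules S/T/Y is an illegal residue, under phospho rules
  D/E is, and two phospho-acceptors (e.g. pS+pT) are rejected because the
  acidic count must be exactly one.
- **Matches are counted per (window, class, orientation).**  A window such
  as `KKFEK` legitimately reads as an acetylation-generated motif in both
  orientations and contributes two matches.  At most one class can hold
  per oriented reading (the canonical and phospho region rules are
  mutually exclusive).
- **N-for-Q substitution** (advanced mode) applies only to the Q-flanked
  classes, yielding `n_canonical`/`n_phospho`; these are tallied separately
  and excluded from grouping, signatures and fractional content by default
  because they are necessary but not sufficient for HSC70 recognition.
  The `n_acetyl` label exists in the class enumeration for symmetry but is
  unreachable: the acetyl class has a K flank, so nothing can substitute
  for a Q there.
- Ambiguity codes (X, B, Z, J, U, O) belong to no category; windows
  containing them simply never match, and the scan continues.
- Coordinates are 1-based inclusive everywhere a user sees them; the
  motif's *center* (third residue) is the position used in positional and
  exposure analyses.

Exhaustive enumeration over all 20⁴ variable regions yields 2,304 oriented
canonical, 3,456 phosphorylation-generated and 2,304 acetylation-generated
windows; the acceptance suite recomputes these by brute force and against
the closed-form multinomial count.

## Proteome statistics

**Grouping.**  Proteins are assigned to their highest-ranking class
(canonical > phosphorylation- > acetylation-generated > none).  Group
percentages partition the proteome; the combination breakdown partitions
it into the 8 subsets of classes present.  Fractional motif content is
computed over the three main-class counts and sums to 100% whenever a
protein has any main-class motif.

**Length model.**  OLS of log₂(canonical motif count) on protein length,
restricted to proteins with ≥1 canonical motif (log₂ 0 is undefined —
zero-count proteins are excluded, which should be kept in mind when
interpreting the slope).  Outlier handling is a single pass: fit, drop all
points with Cook's distance > 1, refit once.  A numerically exact initial
fit (residual sum of squares ≤ 1e−10) skips removal, because Cook's
distances there are ratios of rounding noise; a constant response is
reported as R² = 0 by convention.

**Positional distribution.**  A motif's relative position is center /
length on a 0 (N-terminus) to 1 (C-terminus) scale, histogrammed at a
configurable bin size (0.02 default, 0.001 for terminal close-ups); an
option discounts the initiator methionine from both coordinate and length.
The N-terminal depletion statistic compares motif *densities* (motifs per
unit relative length) in the first 2.5% against the remaining 97.5% and
reports 100·(1 − head/tail); densities rather than raw counts make the
asymmetric split scale-fair.  The alternative (count ratio) would conflate
the 2.5/97.5 imbalance with the biological signal.

**Position preferences.**  Motifs of one class are aligned on a downstream
flank (flank-first motifs mirrored), positions numbered −1 (adjacent to
the flank) to −4.  Each amino-acid row is normalized as the percentage of
that residue's occurrences across the four positions; a property-grouped
table aggregates basic/hydrophobic/acidic rows, counting S/T/Y as acidic
for the phospho class.

**Permutation baseline.**  Each protein sequence is independently shuffled
(composition exactly preserved; one permuted proteome per analysis, with
the seed exposed).  For each of 40 replicates, 10% of the proteins are
sampled without replacement from the observed and from the scrambled
proteome; per-cell (residue × position) frequency tables are computed and
the observed/scrambled ratio recorded.  Per cell, a two-sided Welch t-test
compares the 40 observed against the 40 scrambled frequencies, Bonferroni-
corrected by the number of cells (32 for the 8-residue canonical
alphabet).  The subsampling unit is the protein, since the subsampled
"data set" is the proteome.  **Calibration caveat:** the 40 replicates are
drawn from the *same* two scanned datasets, so the between-replicate
standard error reflects subsampling noise only, not the sampling variation
of the realized observed-vs-scrambled difference; at 40 × 10% this
understates the null variance by roughly a factor of two, and a handful of
spuriously "significant" cells per run are expected under a global null.
Conclusions should therefore rest on effect sizes (ratios well away
from 1) with the t-test as a secondary screen; the planted-bias tests show
genuine composition effects stand far above this floor.

## Solvent exposure

Per-residue relative solvent accessibility (RSA) arrives as a TSV
(`protein_id, position, rsa` or binary `exposed`); computing RSA is the
job of an external predictor or of structure-derived tracks, and proteins
longer than 800 residues are dropped by default to mirror the input limit
of common sequence-based predictors.  A residue is buried iff RSA < 0.25
(strict: RSA = 0.25 is exposed).  The profile aligns a ±30-residue window
on each motif center and reports the percent of exposed residues per
offset; offsets beyond a protein's termini shrink the denominator rather
than being padded, and each motif of a multi-motif protein contributes an
independent window.  The baseline is the percent of exposed residues over
*all* residues of all proteins in scope (not just motif-bearing ones),
chosen as the least biased background rate.

## Conservation

Species are called CMA-able when any proteome sequence ends with the
LAMP-2A tail signature: 3–4 consecutive K/R/H, a 1–3 residue spacer, then
GYEQF at the absolute C-terminus, examined within the last 100 residues.
For each human protein with a single canonical motif, the five alignment
columns holding the motif are located by walking the gapped human row
(columns may be non-contiguous around human gaps).  Each species'
residues at those columns are classified: *conserved* if they form a motif
of the same main class as the human one (orientation is not required to
match), *partial* if only a different class, *absent* if no motif or a gap
inside the window, *no-ortholog* if the species has no row.  N-bearing
motifs do not count toward *partial* by default (flag available).  The
group score is (n_conserved + 0.5·n_partial − n_noOrtholog)/n_species,
with absent species contributing zero to the numerator; a motif is
*selectively conserved* when its CMA-able score is > 0 and its CMA-unable
score ≤ 0.  Ortholog retrieval and alignment are upstream concerns:
families arrive as aligned FASTA plus a species table.

## Enrichment

For a protein group against a background, the per-term p-value is the
one-sided Fisher exact (upper hypergeometric tail) probability — one-sided
because the question is over-representation; a two-sided option exists.
The z-score re-assigns the term's annotation set to a uniformly random
same-size subset of the background 40 times and standardizes the observed
in-group count against the replicate counts; zero replicate spread flags z
as undefined and excludes the term from ranking.  Terms are ranked by the
combined score −ln(p)·z (ties: smaller p, then term id).  No
multiple-testing correction is applied across terms — the ranking
statistic, not a corrected p, is the output, and this is stated
prominently.  Compartment analysis is a chi-squared goodness-of-fit of a
compartment's four-group composition against whole-proteome proportions.
Ternary binning maps each motif-bearing protein's (canonical%, phospho%,
acetyl%) fractions to a 5%-resolution simplex bin (the 100% edge folds
into the top bin so the bins partition the simplex) and scores each bin as
a group.  Term–term Jaccard similarities are exported for enrichment-map
style network tools.

## Synthetic data

The generators produce exactly the statistical structure the analyses
measure, with recorded ground truth and full determinism under a seed:

- **Proteomes** draw background residues i.i.d. — uniform over the 20
  standard residues by default, or from an empirical composition table to
  emulate proteome-like chance-motif rates — and overwrite planted,
  validated motif windows at starts spaced ≥5 residues apart.  Planted
  motifs are re-detected by the scanner before the proteome is returned;
  chance motifs arising from the background are not suppressed but
  recorded separately, so tests assert supersets.
- **Ortholog families** copy a human sequence carrying one canonical motif
  into each species and disrupt the motif with probability 1 − retention:
  flank Q→K (partial), row dropped (no-ortholog) or acidic→G (absent),
  with configurable branch probabilities; alignments are gapless by
  construction.  The mean group score has the closed form
  r + (1 − r)(0.5·p_partial − p_noOrth), which the tests check.
- **Annotation tables** draw term members uniformly, or with sampling
  weight equal to the relative risk for a target group's proteins.
- **RSA tracks** are Bernoulli exposure calls at a baseline rate, with a
  boosted rate at configured offsets from motif centers.

What these fixtures do *not* emulate: domain structure, repeat content,
real amino-acid autocorrelation, phylogenetic correlation between species,
or the GO DAG.  Passing tests therefore demonstrate that the machinery
measures what it claims on data with known structure, not that any
particular biological proteome shows a given effect.

## Numerical and design notes

- Default study sizes (250-protein null proteomes, 250 ortholog families
  over 15+15 species, 500-protein enrichment backgrounds with 20 terms,
  400-replicate null calibrations, 150-protein exposure fixtures) were
  chosen to give Monte-Carlo standard errors comfortably below the effect
  sizes being asserted.
- The 40-replicate resampling z has t-like tails (null |z| > 1.96 rate
  ≈ 0.055, not 0.050); where a significance call on z is needed, the exact
  finite-replicate threshold t₃₉,₀.₉₇₅·√(1 + 1/40) ≈ 2.05 is used, which
  restores nominal 5% calibration.
- Reports are written with deterministic row order (accession, start,
  class) so repeated runs are byte-identical; all stochastic steps take an
  explicit seed.
- Reference-proteome figures (human/mouse/fly/yeast group percentages,
  length-model R², terminal depletion on real data) require the
  corresponding UniProt release FASTAs as input; the pipelines here accept
  any such FASTA but the package ships no proteome data.

## Known limitations

- The scanner treats sequence only; it says nothing about whether a motif
  is exposed, modified or bound in vivo (the exposure module helps when an
  RSA track is supplied).
- PTM evidence is not consulted: phosphorylation- and acetylation-
  generated motifs are *potential* motifs.
- The baseline-comparison t-test is anti-conservative under a global null
  (see above); the conservation pipeline assumes the human motif position
  is meaningful in orthologs and that alignment quality is adequate.
- The enrichment module performs no GO DAG traversal; annotations must
  arrive pre-mapped (two-column TSV or GAF 2.x).
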