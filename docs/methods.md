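# Methods

## Model and statistic

A trained gapped k-mer SVM summarizes a transcription factor's sequence
preference as a weight per k-mer (k = 10 throughout; the weight file is the
`gkmpredict` output over all 4^10 10-mers). The affinity score of a sequence
is the sum of weights over all overlapping k-windows, and the test statistic
for a binding site is

    deltaSVM = S(focal) − S(ancestor),

the predicted affinity change of the substitutions accumulated on the focal
branch since the ancestor shared with the sister species. Positive values
mean the substitutions strengthened predicted binding.

deltaSVM is computed incrementally: only windows covering a differing
position are rescored. Because an unaffected window contributes an exactly
zero difference, summing per-window differences with `math.fsum` (correctly
rounded) makes the incremental result *bitwise identical* to enumerating
every window — this is asserted, not approximated, in the tests. Summation
by fsum also makes scores independent of window order.

## Ancestral reconstruction

Per aligned column of (focal f, sister s, outgroup o), parsimony on the
rooted topology ((f,s),o): s==o pins the ancestor to s; otherwise f==o or
f==s pins it to f. When all three differ the most-parsimonious internal
state is not unique; the column is flagged ambiguous, the ancestor carries
the focal base, and no substitution is recorded — conservative, since a
fabricated substitution direction would feed the statistic. Columns with a
gap in any taxon are removed from both ancestor and focal before scoring
(the model covers substitutions only). Sites whose gap-free length falls
below k are excluded, as are sites with more than 20% ambiguous columns
(configurable). An exhaustive check against a small-parsimony oracle over
all 64 base configurations is part of the test suite.

CpG context of a substitution is judged on the *ancestral* sequence (the
hypermutable methyl-CpG acts on the pre-substitution state); a substitution
is a dinucleotide-cluster member if another substitution sits at an adjacent
position. Both annotations feed the robustness stratification.

## The empirical null and p-value

For a site with n observed substitutions, a null replicate places n
substitutions at distinct uniformly chosen positions of the ancestor
(sampling without replacement — a position hit twice would not preserve the
substitution count) and draws each derived base either uniformly from the
three alternatives or with weights (r, 1, 1) on (transition, transversion,
transversion); r defaults to 4, the genome-wide transition:transversion
ratio, giving transitions probability r/(r+2) = 2/3. N = 10,000 replicates
by default.

p = (1 + #{null ≥ observed}) / (1 + N) for the higher tail (mirrored for the
lower tail). The pseudo-count keeps p in (0, 1]; ties count toward the
extreme tail (conservative). A `paper-compat` flag yields the plain
proportion instead. Conserved and gained peaks are tested with the higher
tail — with ChIP-seq from a single species the observed peaks are a mix of
conserved and gained sites, so the expected signal is increased binding;
lost peaks use the lower tail. No multiple-testing correction is applied by
default (calls are made at raw p < 0.01); a Benjamini–Hochberg q column is
emitted for convenience.

The null is evaluated vectorized: windows are encoded in base 4, each
replicate's code changes are accumulated sparsely, and only affected windows
are rescored (a window's code delta is a sum of distinct-power base-4 digit
changes, which cannot cancel, so nonzero deltas identify affected windows
exactly). This makes 2,000 sites × 10,000 permutations a ~2.5-minute
computation on one CPU.

Per-site RNG streams are derived from (global seed, CRC32 of the site id),
so results are reproducible regardless of processing order or subsetting.

## Peak classification and tissue activity

With all peaks on focal coordinates (liftover is upstream), ≥1 bp overlap
(half-open intervals) defines: conserved = focal peak overlapping both
sister and outgroup peaks; gain = overlapping neither; loss = sister peak
overlapping an outgroup peak but no focal peak. Focal peaks overlapping
exactly one of the two other sets are "unclassified" and excluded — the
three categories are not exhaustive and mixing partial patterns into them
would blur the category contrasts. Multi-tissue sites are single-linkage
unions of ≥1 bp-overlapping peaks across tissue sets; a site's activity
count is the number of tissues with an overlapping peak.

## McDonald–Kreitman contrast

D = focal-branch substitution count, P = number of SNP positions falling in
a site (each genomic position counted once; no allele-frequency filter by
default, since the sensible filter depends on the SNP panel). Aggregated
over PBS and non-PBS sites into a 2×2 table tested by two-sided Fisher exact
test; effect size α = 1 − (D_np·P_p)/(D_p·P_np), defined when D_p > 0 and
P_np > 0 (α = 1 when P_p = 0). Untested sites belong to neither class.
Substitution rates are estimated as count(X→Y)/count(X in ancestors),
optionally stratified by ancestral CpG context.

## Adjusted expression variance

The expression matrix is log-transformed upstream (log2). Because the
per-gene mean is then already a log-scale quantity, the mean–variance trend
is fit as log(var) = polynomial(mean): starting at degree 1, the degree
grows while the nested-model F-test for one more degree has p < 0.05; the
first non-significant extension stops the search (degrees capped at 8; a
numerically exact fit also stops it). The adjusted variance is observed
variance / exp(predicted log variance). Fitting the polynomial on the
log-scale mean directly — rather than on its logarithm — keeps the procedure
exactly invariant to rescaling expression by a constant in linear space
(polynomials are closed under a shift of the predictor), and avoids
undefined values for genes whose mean log-expression is non-positive. Note
the stop rule retains its nominal ~5% chance of overshooting the true degree
by one; that is a property of sequential F-testing, not of the data.

Target genes are assigned by nearest TSS (distance 0 inside the site;
equidistant ties break to the lexicographically smallest gene id). PBS vs
non-PBS target adjusted variances are compared by a two-sided Wilcoxon
rank-sum test, each gene counted once per group with PBS membership taking
precedence.

## The synthetic-data generator

`simulate` produces complete studies with known truth, emulating the shape
of the real inputs:

* **Weight table** — weight of a k-mer is the best-alignment summed log-odds
  of a planted 8-bp motif (consensus TTGCGCAA) against a uniform background.
  Column probabilities are deliberately heterogeneous (consensus probability
  0.86–0.95, residual mass split unevenly): homogeneous columns would place
  all k-mer weights on a one-dimensional lattice, creating massive deltaSVM
  ties that continuous-valued trained SVM weights do not show and that make
  the test artifactually conservative.
* **Site triples** — 200-bp sites with one PWM-sampled motif instance at the
  center, evolved on ((focal,sister),outgroup) with per-bp neutral
  divergences 0.5% (internal), 1% (sister), 2% (outgroup), echoing the
  human–chimpanzee range. Focal branches carry 2–6 substitutions (4–6 for
  selected regimes): `neutral` draws them exactly by the null process (the
  calibration standard); `directional_up/down` accepts random proposals only
  when they move the score by at least 2.0 log-odds units in the selected
  direction (~ one strong motif-position change — selection fixes
  consequential changes, and near-zero-effect "selected" substitutions would
  make the regime indistinguishable from neutral drift); `stabilizing`
  accepts only proposals keeping the score within 1.0 unit of the ancestral
  score. Default study: 500 neutral, 150 up, 150 down, 100 stabilizing.
* **SNPs** — planted at 0.02/bp in neutral and stabilizing sites but
  0.005/bp in directional ones (selective sweeps deplete polymorphism), so
  the MK contrast has a known direction.
* **Expression** — 175 samples per gene (the size of a typical liver donor
  panel); per-gene variance follows exp(−3 + 0.8·m − 0.06·m²) in the
  log-scale mean m ~ U(1, 10), times a lognormal(0, 0.1) residual; target
  genes of directionally selected sites get a 0.4× variance multiplier.

Identical config + seed reproduces every bundle file byte-for-byte.

What the generator does *not* emulate: context-dependent mutation beyond the
ts/tv ratio (no CpG hypermutability in the null or the branches), indels,
alignment error, ChIP-seq intensity noise, linked selection, or realistic
gene–site distance structure. Passing tests therefore demonstrate the
statistical machinery (calibration, power, exactness, determinism) under the
stated model, not robustness to every bias of real comparative data — the
CpG/dinucleotide stratification and the strict ts/tv re-test exist precisely
because real data violate the uniform-mutation assumption.

## Numerical and design choices

* Absent k-mers score 0 with a counted warning (complete LS-GKM tables make
  this a toy-data-only event); windows containing non-ACGT characters score
  0 and are counted; input is uppercased (soft-masked genomes).
* Sequences are scored as given on the peak strand; no reverse-complement
  folding (RC-aware gkm-SVM training already encodes strand symmetry, and
  folding would double-count). A both-strands mode is deliberately absent
  for the same reason.
* Coordinates are BED-convention 0-based half-open everywhere; substitution
  positions are 0-based within the ungapped site.
* Whole-site exclusion (not subsequence masking) implements the strict
  CpG/dinucleotide robustness mode, paired with the ts/tv-weighted null.
* Degenerate MK tables: any zero margin returns Fisher p = 1 with the odds
  ratio flagged undefined (or +inf when only the denominator vanishes).
* Problem sizes used by the validation script — 1,000 oracle pairs, 2,000
  calibration sites × 10,000 permutations, the 900-site default study, 20
  expression seeds × 5,000 genes — were chosen to estimate each quantity to
  well within its acceptance margin while keeping a full run to a few
  minutes on a single CPU.

## Known limitations

* Three-taxon parsimony cannot polarize sites where sister and outgroup
  converged; such columns silently pin the ancestor to the shared base
  (≈ divergence² per bp, negligible at the default divergences but not for
  distant outgroups).
* The per-site null conditions on the substitution *count*, not on
  mutational opportunity: highly mutable contexts make the test
  conservative, which is the motivation for the stratified and strict modes
  rather than a fully context-aware null.
* k-mer weight tables larger than k = 12 are rejected (dense 4^k storage).
* The expression module assumes genes × samples matrices small enough for
  in-memory dense fitting.
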