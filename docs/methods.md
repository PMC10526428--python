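# Methods

This note documents the models, rules, and numerical choices behind
`deorphan`, and what the validation battery does and does not show.

## Scope and design stance

The pipeline automates clade-based ligand annotation for a
paralog-rich transporter family surveyed across a small panel of
model-organism proteomes. Tree inference is distance-based (neighbor
joining with a nonparametric bootstrap): it reproduces the decision
surface the annotation stage needs — a topology plus a 0–100 support
per clade — at desk scale and fully deterministically. Where a
maximum-likelihood tree is preferred, the pipeline ingests it as
Newick (supports as internal node labels or bracketed comments) and
runs the identical annotation stage on it. Multiple-alignment
construction is deliberately out of scope: the pipeline consumes
pre-aligned FASTA, and the simulator is indel-free so its identity
alignment is exact.

## Curation

Four record-level rules, applied in this order:

1. **Overrides** — targeted replacement of individual records known to
   be mis-curated upstream (e.g. a frameshift-truncated strain variant
   replaced by the full-length protein from another strain), each with
   a logged reason.
2. **Length filter** — records shorter than `min_len` (default 200 aa)
   are removed. A carrier core is ~300 aa; 200 is a loose cutoff that
   tolerates shortened loops while catching fragments. The filter sees
   the full-length, pre-trim sequence.
3. **Duplicate collapse** — records at p-distance < `dup_threshold`
   (default 0.005, i.e. >99.5% identity) are treated as duplicate
   entries of one protein. Distances come from affine-gap global
   alignment (BLOSUM62, open 11 / extend 1) with pairwise deletion of
   gap columns. Clustering is single-linkage over the
   "distance < threshold" relation; each cluster keeps one
   representative chosen by reviewed status, then sequence length,
   then smallest id — a deterministic rule where the underlying data
   give no guidance.
4. **Domain trim** — each record is cut to the span from the start of
   its first Solcar interval to the end of its last (removing, e.g.,
   N-terminal EF-hand extensions). Intervals are 1-based inclusive,
   following the UNIPROT feature convention; a record without interval
   annotations passes through unchanged with a warning.

The length filter runs before duplicate collapse on purpose: an
unmutated truncated fragment has p-distance 0 to its source under
pairwise deletion, so the opposite order would silently absorb
truncations into the duplicate rule. Each rule is idempotent, and the
kept/removed sets always partition the input.

The residue `X` (unknown) is accepted everywhere and scored as a
mismatch in every identity and p-distance computation, including
`X` vs `X`.

## Distances

For rows *i*, *j* of the alignment, *p* is the mismatch fraction over
columns where both rows carry a residue (pairwise deletion — robust to
the family's variable loop regions, and switchable in principle by
pre-filtering columns). Corrections:

* `none`: *d* = *p*
* `poisson`: *d* = −ln(1 − *p*)
* `kimura`: *d* = −ln(1 − *p* − 0.2 *p*²)

A pair whose correction diverges (poisson at *p* ≥ 1; kimura at
*p* ≳ 0.854) is clamped to a ceiling of 10 substitutions/site with a
warning. Pairs sharing no residue columns get *p* = 1 with a warning
rather than an error.

## Tree inference and support

**Neighbor joining** follows the classic algorithm: join the pair
minimizing Q<sub>ij</sub> = (n−2)d<sub>ij</sub> − Σ<sub>k</sub>d<sub>ik</sub> −
Σ<sub>k</sub>d<sub>jk</sub>, with branch lengths from the standard
formulas. Ties are broken toward the smallest (i, j) pair in the
current node order (new nodes appended last), making the output
deterministic. A negative branch length is clamped to zero with the
deficit transferred to its sister branch, preserving their sum — the
common practice. The unrooted result carries a trifurcating virtual
root. On additive matrices the generating topology is recovered
exactly (this is tested by simulation and against exhaustive
least-squares fits at 4–5 taxa).

**Bootstrap** is Felsenstein column resampling: replicate *r* draws
*L* columns with replacement from a generator seeded with
`(seed, r)`, so replicates are order-independent and reproducible
bit-for-bit. Each internal edge of the point tree gets
100 × (replicates containing its bipartition) / n_reps, rounded to the
nearest integer with ties up — so the strict thresholds "> 70" and
"> 90" are well defined on integers. Default 100 replicates; larger
counts (e.g. 10 000) are a parameter.

**Rooting** places the root at the midpoint of the outgroup's terminal
branch. The implementation rebuilds the tree from an undirected
adjacency in which each edge carries its length and support, so every
support stays attached to the same bipartition and all leaf-to-leaf
path lengths are preserved (tested to 1e−9).

**Long branches**: leaves whose terminal branch exceeds *k* × the
median terminal branch (default *k* = 3) are flagged as candidate
long-branch-attraction artifacts — a screen, not a verdict.

## Label propagation

Experimental ligand labels are the only trusted inputs; they are never
altered. For a labeled source tip, a clade is **accepted** when it
contains the tip, its support is strictly above `s_prop` (default 90),
and it contains no experimental label with a different ligand. The
source's ligand expands to every unlabeled tip of its maximal accepted
clade, with evidence `propagated` and `min_support` = the minimum
support over the accepted clades (hence always above the threshold).
Ancestors below the threshold are skipped rather than treated as
barriers: the justification for expansion is the supported clade
itself, not the (possibly poorly resolved) structure inside it. The
first threshold-clearing ancestor that does contain a conflicting
label blocks the ascent permanently, since every higher clade inherits
the conflict.

Two different ligands can never reach the same unlabeled tip: their
justifying clades would have to be nested, and the inner source would
be a conflicting label inside the outer clade. This impossibility is
kept as a runtime assertion.

**Class-level fallback** (switchable off): when the blocking conflict
involves a different ligand of the same chemical class — e.g. two
amino-acid substrates — the blocking clade (the smallest sufficiently
supported clade containing both sources) assigns its still-unlabeled
tips a class-level label (`class_level`, ligand empty, class set).
This formalizes the practice of calling a mixed clade "amino-acid
transporters" when its members' ligands share chemistry.

Remaining tips are `orphan`. Confidence tiers: `high` when
`min_support` > `s_conf` (default 70), else `low`. The outgroup is
excluded from propagation and species-restriction analysis, and no
justification can pass through the root (which carries no support).
Sources are processed in lexicographic order; same-ligand sources that
do not share an accepted clade are reported in the conflict log as
non-monophyletic rather than failing the run. Increasing `s_prop`
never increases the number of propagated tips (tested over thresholds
50/70/90/99 on random trees).

**Species restriction**: every maximal clade with support > `s_conf`
whose species set is a strict subset of the panel is reported —
`single-species`, `<group>-restricted` when the set lies within a
configured group (default groups: vertebrate = {HUMAN, DANRE},
animal = all but YEAST), else `species-restricted`. Nested clades with
the same verdict report only the outermost.

## Reciprocal best hits

Cross-species ortholog claims are probed with global-alignment
reciprocal best hits: a pair qualifies only if each member is the
other's *unique* top-scoring match in the opposite proteome; score
ties void reciprocity (conservative) and are logged. Local alignment
and E-values are out of scope — at family scale, global scores over
trimmed cores are the appropriate comparison.

## The simulator

`simulate_family` generates the structure the analysis assumes:

* a random ancestral sequence of `seq_length` (default 300) over the
  20 amino acids;
* `n_subfamilies` (default 8) subfamily ancestors, each with a
  disjoint signature set of `signature_fraction` × length positions
  (default 10%, i.e. 30 sites) fixed to subfamily-specific residues and
  frozen thereafter — the sequence correlate of ligand specificity —
  plus Poisson(`sub_rate_subfamily` × non-signature sites)
  substitutions (default 0.5/site: deep, pre-species-split
  divergence);
* within each subfamily, one ortholog per species evolved along the
  fixed topology (((HUMAN, DANRE), (DROME, CAEEL)), YEAST) with
  Poisson(`sub_rate_species` × sites) substitutions per branch
  (default 0.05/site: shallow species divergence);
* substitutions land uniformly (with replacement) on non-signature
  sites and replace the residue uniformly among the 19 alternatives —
  no rate matrix, no rate heterogeneity, no indels;
* decoys: near-duplicates mutated at 0.3% of sites (inside the 0.005
  collapse radius; default 3) and sub-200-aa truncated fragments
  (default 2);
* an unrelated random outgroup sequence (id `MCU_HUMAN`), mirroring
  rooting on a non-homologous channel;
* experimental labels for exactly one designated representative
  species per subfamily (default HUMAN), mimicking annotation anchored
  on well-characterized human/yeast proteins; ligand `LIG_k` with
  chemical classes cycling through the six ligand classes.

Everything is deterministic given the config seed. For sister species
the expected p-distance at non-signature sites is ≈ 1 − exp(−2·rate)
to first order; the suite verifies this against a 200-replicate Monte
Carlo estimate within three standard errors.

**What passing on simulated data does not show**: real alignments have
indels, rate heterogeneity across sites and lineages, gene duplication
and loss within subfamilies, and signature residues that are neither
perfectly conserved nor perfectly disjoint. The simulator makes the
clustered-by-function premise *testable*, not *proven* for real data;
on real families the support thresholds do the corresponding work.

## Validation scales

The acceptance battery (and `scripts/acceptance.py`) runs at sizes
chosen to give tight checks in well under a minute each on one CPU:
100 random additive matrices (4–8 taxa) for NJ recovery with
least-squares cross-checks at 4–5 taxa; 1000 random labeled trees
(≤ 12 tips) for propagation-oracle equivalence and monotonicity;
10 simulated families (8 subfamilies × 5 species, 300 aa, 100
bootstrap replicates) for end-to-end recovery; and small fixtures for
curation, closed forms, and BBH.

## Known limitations

* NJ on near-saturated between-subfamily distances resolves
  within-subfamily structure with only moderate support; the
  annotation stage is designed to be insensitive to that (expansion
  rides on the subfamily clade, not its interior).
* The duplicate threshold is a single global value; families with
  recent, genuine paralogs above 99.5% identity would need it lowered
  (it is a parameter everywhere it appears).
* Class-level fallback assigns the *blocking* clade only; it does not
  search for larger same-class consensus clades.
* The long-branch flag is a median-ratio screen and carries no
  statistical guarantee.
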