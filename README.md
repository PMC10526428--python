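# deorphan

Phylogeny-guided ligand annotation ("deorphanization") for transporter
protein families, modeled on the mitochondrial carrier (SLC25) family.

## The problem

Eukaryotic genomes encode dozens of SLC25 carriers — ~300-aa inner
mitochondrial membrane transporters built from three tandem
Solcar/mito_carr repeats — that move chemically diverse metabolites
(nucleotides, amino acids, carboxylates, cofactors, inorganic ions,
protons). A third of the human members have no established ligand.
Because the family diversified into ligand-defined subfamilies before
the major eukaryotic lineages split, orthologs that transport the same
ligand cluster together in a phylogeny, and a well-characterized
representative can lend its ligand to the rest of its clade — provided
the clade is statistically solid. `deorphan` turns that reasoning into
a reproducible pipeline for anyone annotating a transporter (or other
paralog-rich) family across model organisms:

1. **Curation** — drop truncated records (length < 200 aa by default),
   collapse near-duplicate database entries (p-distance < 0.005, i.e.
   \>99.5% identical), trim each protein to its Solcar-repeat core, and
   patch individual mis-curated records.
2. **Distances** — pairwise p-distances from the alignment with
   pairwise deletion of gaps and a Poisson multiple-hit correction
   *d* = −ln(1 − *p*).
3. **Tree** — neighbor joining (Saitou–Nei, Studier–Keppler Q-matrix)
   with nonparametric bootstrap supports from column resampling
   (Felsenstein); externally built trees can be supplied as Newick
   instead.
4. **Rooting** — on a designated outgroup (for SLC25, the unrelated
   calcium uniporter MCU).
5. **Annotation** — each experimentally labeled tip expands its ligand
   to the largest clade that (a) has bootstrap support strictly above
   `s_prop` (default 90) and (b) contains no conflicting experimental
   label. A conflict between two ligands of the same chemical class
   downgrades the shared clade to a class-level label. Support above
   `s_conf` (default 70) marks high confidence; everything unreachable
   is an orphan. Species-restricted clades (e.g. vertebrate-only) and
   suspiciously long terminal branches (candidate long-branch
   attraction artifacts) are reported, and cross-species ortholog
   claims can be probed by reciprocal best hits (BBH).

A ground-truth simulator (`deorphan.synthetic`) generates families with
this exact structure — ligand-defined subfamilies older than the
species split, subfamily-specific signature residues, per-species
orthologs, plus curation decoys — so the whole pipeline can be
validated against known answers.

## Worked example

Simulate a 4-subfamily family across the five model proteomes (human,
zebrafish, fly, worm, yeast) with planted decoys, then run the full
pipeline:

```bash
deorphan simulate --subfamilies 4 --seed 11 --out-prefix fam
# 26 records (5 decoys) -> fam.*
deorphan run-all --fasta fam.fasta --annotations fam_annotations.tsv \
    --bootstrap 100 --seed 11 --out out
# artifacts written to out/
```

`out/curation_report.tsv` shows both truncated decoys caught by the
length filter:

```
id               action         detail
SF1_CAEEL_TRUNC  removed_short  length 150 < 200
SF1_YEAST_TRUNC  removed_short  length 150 < 200
```

`out/propagation.tsv` assigns every unlabeled ortholog the ligand of
its subfamily's experimentally characterized human representative, with
the minimum bootstrap support of the justifying clades:

```
id         species  ligand  chem_class  evidence     min_support  tier  sources    clade
SF1_CAEEL  CAEEL    LIG_1   nucleotide  propagated   97           high  SF1_HUMAN  C1
SF1_DANRE  DANRE    LIG_1   nucleotide  propagated   97           high  SF1_HUMAN  C1
SF1_DROME  DROME    LIG_1   nucleotide  propagated   97           high  SF1_HUMAN  C1
SF1_HUMAN  HUMAN    LIG_1   nucleotide  experimental                    SF1_HUMAN
...
```

with tier counts in `out/propagation.counts.json`:

```json
{"class_level": 0, "experimental": 4, "orphan": 0, "propagated": 16}
```

i.e. all 16 unlabeled orthologs received the correct subfamily ligand
at support > 90. `out/species_restriction.tsv` flags well-supported
clades missing from part of the species panel (the analogue of
"vertebrate-specific, only in human and zebrafish"):

```
verdict                support  n_tips  species      tips
vertebrate-restricted  97       2       DANRE;HUMAN  SF1_DANRE;SF1_HUMAN
```

The run also writes the supported and rooted trees
(`tree_support.nwk`, `tree_rooted.nwk`, supports as internal node
labels), the PHYLIP distance matrix, an iTOL color-strip dataset
keyed by ligand class, and a machine-readable `run_manifest.json`
(parameters, input checksums, long-branch flags, conflict log).

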