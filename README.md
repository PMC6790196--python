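# splicekin

Analysis toolkit for clone-based studies of small multigene families — the
setting of the macaque *BTN3A* butyrophilin cluster: a handful of tightly
linked, recently duplicated genes typed by Sanger sequencing of cDNA clones
in multi-generation breeding families. The package covers the full analytic
chain of such a study:

* **Allele calling** from cDNA clone sequences under the clone-study
  evidence rule: an allele is validated by at least two identical clones
  from different animals or from independent PCRs of one animal; everything
  else stays a singleton and is never genotyped.
* **Haplotype phasing** of the linked genes by Mendelian co-segregation in
  pedigrees — an exact branch-and-bound search minimizing recombination and
  de-novo mutation events, plus co-segregation tables against an external
  (e.g. MHC) haplotype labelling.
* **Alternative-splicing classification**: anchor-based spliced alignment of
  each clone to its gene model, classification of every deviant junction
  (exon skipping, alternative 3′/5′ splice sites, intron retention, cryptic
  exons, and the paired exon-internal alt-3′SS/alt-5′SS deletion class), and
  predicted protein consequences (frame, premature stop, retained domains,
  soluble isoforms lacking the transmembrane exon).
* **Splice-site scoring** with a position-weight matrix and a
  maximum-entropy model (donor 9-mers, acceptor 23-mers). Scores are log₂
  likelihood ratios with no absolute threshold; they only compare related
  sites. With order-1 constraints the max-ent model provably reduces to the
  PWM; order-2 adds adjacent-pair dependencies, fitted by iterative scaling
  with exact chain marginals.
* **Distance phylogenetics**: p and Kimura two-parameter distances with
  pairwise deletion, canonical neighbour joining with deterministic
  tie-breaks, and site-resampling bootstrap support — used to test that
  alleles cluster by gene across species (orthology).
* **A synthetic cohort generator** that emulates the study's data: a
  nine-exon BTN3A-like gene scaffold (long IgV exon 2, in-frame-skippable
  transmembrane exon 4, four short heptad exons, large B30.2 exon), a
  pseudogene with an engineered stop at exon-2 triplet 65 (protein codon
  94), two four-generation families of 13 animals, 32 clones per animal and
  gene in two PCR batches, substitution errors, and a configurable planted
  AS spectrum. Every pipeline stage is testable against the generator's
  ground truth; nothing is downloaded.

## Worked example

Run the whole synthetic study in one command:

```sh
splicekin run-all --seed 7 --outdir demo/
```

This simulates the cohort, writes the gene models (GFF3 + FASTA), pedigree
TSV, clone FASTA, validated alleles, genotypes, haplotypes, event tally,
site-score comparisons and a Newick tree into `demo/`, and prints the
report. With seed 7 it prints (abridged):

```json
{
  "alleles":  {"validated": 13, "true_carried": 13, "recovery_pct": 100.0,
               "false_validated": 0, "singletons": 0, "as_excluded": 182},
  "phase":    {"animals": 26, "haplotypes_correct": 26, "recovery_pct": 100.0,
               "events": 0},
  "classify": {"clones": 3328, "as_clones": 182, "distinct_events": 7,
               "categorized": 6, "matches_truth": true},
  "sites":    {"comparisons": 16, "actual_dominant": 16},
  "tree":     {"gene_clades": {"g1": {"monophyletic": true, "support": 100.0},
                               "g2": {"monophyletic": true, "support": 100.0},
                               "g3": {"monophyletic": true, "support": 100.0}}}
}
```

Reading: all 13 distinct allele sequences carried by the 26 animals were
validated by the evidence rule with no false calls; phasing reconstructed
every animal's two multi-gene haplotypes with zero recombination events;
3328 clones were classified, 182 of them alternatively spliced, and the
tally of every event combination equals the generator's bookkeeping; the
actual splice sites outscore the alternative sites in all 16 comparisons;
and in the simulated three-gene ortholog family each gene's sequences form
a clade with 100% bootstrap support.

The first lines of `demo/event_tally.tsv` show the dominant planted event —
the exon-2-internal 112-nt deletion bounded by an alternative 3′SS and 5′SS
(frameshifting, hence no product expected), present in all genes including
the pseudogene:

```
gene    events                              mechanism        count  categorized
pseudo  (('alt3ss_alt5ss', 517, 629),)      alt3ss_alt5ss    42     True
gene2   (('alt3ss_alt5ss', 630, 742),)      alt3ss_alt5ss    37     True
gene1   (('alt3ss_alt5ss', 611, 723),)      alt3ss_alt5ss    34     True
```

Individual stages are available as `splicekin simulate | call-alleles |
phase | classify | score-sites | tree`, and `splicekin model validate`
checks a GFF3/FASTA gene-model pair. The same functionality is importable
(`splicekin.alleles`, `splicekin.phasing`, `splicekin.splicing`,
`splicekin.sites`, `splicekin.phylo`, `splicekin.cohort`).

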