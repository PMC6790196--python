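# Methods

This note documents the models and procedures implemented in `splicekin`,
the assumptions behind them, the parameters that matter, and what the
synthetic cohort does and does not emulate.

## The synthetic cohort

The generator (`splicekin.cohort`) defines the study conditions every other
module is tested against.

**Gene scaffold.** Each gene has nine exons with default lengths
(150, 351, 330, 105, 21, 24, 27, 36, 520) nt and random introns of 150–400
nt carrying consensus-sampled donor (GT…) and acceptor (…AG) motifs. Exon 1
holds 63 nt of 5′ UTR and 87 nt of CDS — exactly 29 codons, so that a stop
at exon-2-local triplet 65 is protein codon 94; this single construction
reproduces both printed conventions for the pseudogene stop. Exon 2 encodes
the IgV domain, exon 3 IgC, exon 4 (105 nt, a multiple of 3, hence
in-frame-skippable) the transmembrane segment, exons 5–8 are heptads, and
exon 9 carries the B30.2 domain and the terminal stop. The cohort has three
functional genes and one pseudogene: the pseudogene carries an engineered
TAA at protein codon 94; the second functional gene ends at the first codon
of its seventh exon (a heptad), so its product lacks B30.2 — the
BTN3A2-like configuration. A latent 112-nt deletion window inside exon 2,
bounded by planted GT/AG dinucleotides, models the paired
alternative-3′SS/5′SS event; 112 ≡ 1 (mod 3), so using it shifts frame.
After motif planting, unintended in-frame stops are scrubbed
deterministically.

**Alleles.** Allele \*01 is the reference; further alleles carry
Binomial(eligible sites, 0.002) substitutions at exonic CDS positions at
least 10 nt from any splice junction (including the latent deletion
boundaries, which are splice sites too), rejected if they create an
in-frame stop. Allotype-controlled panels build a requested number of
protein-distinct groups and pad with synonymous third-position variants —
the allele-versus-allotype distinction under which 8 nucleotide alleles can
collapse to 7 proteins and 12 to 6.

**Families and clones.** Two families with a fixed 13-animal,
four-generation topology (6 founders each). Founder chromosomes draw from a
pool of 8 distinct multi-gene haplotypes; transmission is intact (zero
recombination) unless a crossover is explicitly planted. Each animal yields
32 clones per gene, split into two PCR batches so the independent-PCR
evidence rule is exercisable; each clone is one of the animal's two alleles
with planted AS events and substitution errors at 5 × 10⁻⁴ per site
(substitutions only — every length change is a splice event by
construction). The default AS spectrum plants transmembrane-exon skipping
at exact per-gene counts 18/17/0 across the three functional genes and the
112-nt deletion at frequency 0.05 in all four genes. Planted event
coordinates are canonicalized identically to the classifier's rule, so
truth bookkeeping and observed tallies are comparable as exact keys.

**What the generator does not emulate:** PCR recombination chimeras,
indels, coverage bias between alleles, paralog cross-amplification, and
inter-gene sequence similarity (the four genes are independent random
sequences, so 31-mer gene assignment is easier than for real paralogs with
~95% identity). Passing recovery tests therefore shows the algorithms are
correct under the stated error model, not that they are robust to every
real-data artefact.

## Allele calling

Clones are assigned to genes by unique 31-mer vote, aligned and classified;
clones with any splice event are excluded, and the remaining constitutive
clones are grouped by exact sequence. A cluster is validated when supported
by two identical clones from different animals or from different PCR
batches of one animal; singletons are retained for reporting but never
genotyped. No consensus polishing is performed — the evidence rule alone is
the error filter. More than two validated alleles for one animal and gene
raises a contamination error rather than truncating.

A quantitative caveat, measured on the generator: at 5 × 10⁻⁴ errors/site
over ~1.8-kb clones, a cohort of ~3300 clones contains on the order of 10⁴
same-allele clone pairs, and the probability that two independent clones
carry the *same* single error is ≈ 1/(3 × 1764), so a few coincidentally
identical error pairs per cohort are expected — and observed. These satisfy
the evidence rule and surface as a third validated allele for some animal
(the contamination error above). Exact recovery of the truth set holds at
error rate 0; at 5 × 10⁻⁴ the evidence rule provably cannot guarantee it.

## Haplotype phasing

Tight linkage means each parental chromosome transmits its whole allele
tuple. Phasing is exact: each animal's genotypes are split into two
per-gene tuples (founder splits are free; 2^(h−1) options for h
heterozygous genes), and every non-founder haplotype must derive from one
parent either intact or at a cost — 1 per crossover between adjacent genes,
1 per de-novo allele mutation — computed by a two-state dynamic program
over genes. Depth-first search with branch-and-bound minimizes total
events, then the number of distinct haplotypes, then a lexicographic
canonical form; equally parsimonious solutions are counted and the
canonical one kept. Families of 13–19 animals phase in well under a second,
so exactness costs nothing. Untyped animals and genes participate as
wildcards. Co-segregation with an external labelling counts, per
parent→child transmission, which haplotype travelled with which external
label; concordance is measured against each haplotype's modal partner, and
transmissions whose external origin cannot be resolved are excluded with a
warning.

## Spliced alignment and event classification

Alignment anchors unique 15-mers of the clone to the gene's genomic
sequence, merges co-diagonal runs across substitution mismatches, chains
runs (tolerating the few-base overlaps that junction ambiguity creates),
rescues unanchored internal segments (e.g. a heptad exon whose anchors were
all killed by one error) by sliding-window placement, and finally resolves
every junction: the split point is chosen to minimize mismatches over a
padded window, with two deliberate priors — (1) a placement using both
annotated splice sites may absorb one extra mismatch, so a sequencing error
at a junction-adjacent base cannot fake a 1-nt-shifted novel junction
(consequence: genuine ±1-nt alternative sites are below the aligner's
resolution); (2) among ties, gaps shift maximally 5′-ward, the standard
canonical form. Fewer than 80% anchored bases is a wrong-gene error; an
unplaceable segment raises rather than guessing.

Classification compares each genomic gap with the annotated exon chain:
annotated-donor-to-annotated-acceptor gaps spanning whole exons are
(multi-)exon skips; a boundary offset into an exon is an alternative 3′/5′
site (signed `shift_nt`); an offset into an intron is partial intron
retention; a block spanning an annotated intron is intron retention; a
block wholly inside an intron is a cryptic exon; and a gap with both
boundaries inside one exon is the paired alt-3′SS/alt-5′SS class (the
112-nt deletion). Events co-occurring in one clone are tallied as one
compound key; a combination is "categorized" at ≥ 4 observations (the
more-than-three rule).

Consequences rebuild the isoform CDS from the gene sequence (clone errors
play no role), translate it, and scan for stops. An isoform is in-frame iff
its summed length change is 0 mod 3; the expected terminal codon shifts
with in-frame length changes, so a shorter intact product is not counted as
premature. Domains are retained when their exon is fully present and fully
translated before any premature stop; an isoform is soluble when intact and
lacking the transmembrane exon. `product_expected` is the negation of
`premature_stop`.

## Splice-site models

Windows follow the MaxEntScan convention: donor 9-mers (3 exonic + 6
intronic), acceptor 23-mers (20 intronic + 3 exonic); the convention is a
choice (widths are configurable). The PWM scores Σᵢ log₂ fᵢ(wᵢ)/bg(wᵢ) with
pseudocount 0.5 by default and a −20 bits/position floor guarding zero
frequencies. The maximum-entropy model is the least-committed distribution
matching positional marginals (order 1) or additionally adjacent-pair
marginals (order 2). Because the constraints form a chain, the solution is
a chain-structured exponential family: expectations and the partition
function come from exact forward–backward recursions (never 4^W
enumeration), generalized iterative scaling starts at the closed-form
first-order Markov solution and polishes to a marginal discrepancy below
`tol` (1e-8 default), and non-convergence raises with the final
discrepancy. With order-1 constraints the model factorizes and reproduces
PWM scores to numerical precision — a property test, and the package's
internal consistency check. Scores are log₂ likelihood ratios against a
background composition; they carry no threshold and are only meaningful
between related sites of the same type. For alternative-site events, the
actual and alternative donor/acceptor windows are extracted from the gene
sequence and compared per model; pure exon skips use only annotated sites
and yield no comparison.

## Phylogenetics

Distances use pairwise deletion (sites with non-ACGT in either member of a
pair are dropped for that pair). p is the mismatch fraction; K2P is
−½ ln(1−2P−Q) − ¼ ln(1−2Q) with P transitions and Q transversions, raising
a saturation error when a log argument is non-positive. Neighbour joining
is the canonical Saitou–Nei agglomeration; Q-criterion ties break on the
smallest taxon-label pair, negative branch lengths clamp to zero with the
deficit logged. Bootstrap resamples alignment columns, rebuilds the tree,
and reports the percentage of replicates containing each original internal
bipartition; Newick output places supports as internal-node labels. The
maximum-composite-likelihood distance of the original analysis is not
implemented — the clustering claims under test are robust to the distance
model, and p/K2P keep the module dependency-free and exactly testable
(NJ is verified against brute-force minimum evolution on ≤5-taxon additive
matrices and against an independent NJ implementation).

The ortholog-family simulation (3 genes × 6 species, 500 nt, 0.30
substitutions/site between genes, 0.02 within) represents the regime where
gene identity dominates species divergence, in which each gene's sequences
must form a clade with high support.

## Problem sizes and numerical choices

The default cohort is 2 families × 13 animals × 4 genes × 32 clones = 3328
clones of ~1.8 kb; a full pipeline run takes ~20 s on one core. Bootstrap
uses 500 replicates in the reproduction script (1000 is the conventional
figure; support estimates at these divergences are saturated well below
500). All randomness flows from explicit seeds through
`numpy.random.Generator`; a run's configuration plus seed determines every
output byte. Tolerances: max-ent convergence 1e-8 on marginals; PWM/max-ent
order-1 agreement asserted at 1e-6; NJ tie detection at 1e-12 absolute on
the Q criterion.

## Known limitations

* Alternative splice sites shifted by exactly ±1 nt from an annotated site
  are attributed to the annotated site when a single mismatch explains the
  difference (see the junction prior above).
* Gene assignment by unique 31-mers assumes the gene models are distinct
  enough to have unique anchors; real paralogs at ~95% identity would leave
  fewer informative k-mers and more unassigned clones.
* The evidence rule cannot exclude coincidentally identical error pairs
  (quantified above); genotyping surfaces them as contamination errors
  rather than guessing.
* Phasing assumes the pedigree is correct; pedigree errors masquerade as
  recombination or mutation events.
* The chain max-ent model captures adjacent-pair dependencies only; longer-
  range dependencies in real splice sites are not modelled.
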