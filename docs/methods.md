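# Methods

This note records the models, statistics and numerical choices behind
`ejcsplice`, the assumptions they rest on, and what the synthetic-data
generator does and does not emulate.

## Biological setting

The exon junction complex (EJC — eIF4A3, RBM8A and MAGOH or MAGOHB) is
deposited ~20 nt upstream of exon–exon junctions during splicing and, among
other roles, represses cryptic splice sites that would otherwise mediate
recursive splicing of the already-spliced junction.  When MAGOH/MAGOHB are
depleted, junctions normally protected by high EJC occupancy can re-splice,
producing junction reads that jump one or several exons.  The package
quantifies this chain of evidence: junction classification against a
reference exon chain, per-skip-class read ratios between knockdown and
control, a bootstrap test for elevated EJC occupancy on exons immediately
upstream of skipped exons, protein-level consequences of multi-exon skips,
and the sequence divergence of the two paralogs themselves.

## Reference exon chains

Each gene is represented by exactly one reference transcript: the
MANE-tagged transcript when one exists, else the longest-CDS isoform (ties:
lexicographically smallest transcript id), else the longest exonic span.
Exons are re-indexed in transcript orientation (exon 1 = 5′-most; on the
minus strand this is the genomically last interval).  Only genes with ≥ 3
exons are eligible — a skipped exon needs neighbours on both sides.
Coordinates are 0-based half-open internally; GTF's 1-based inclusive
convention is converted at the parser boundary.  Overlapping exons within a
transcript are merged with a warning rather than rejected.

## Junction classification and skip quantification

A junction (donor_end, acceptor_start) is matched exactly against exon
boundaries (a slop window exists as a config knob, default 0, because
modern spliced aligners are base-precise).  Canonical = adjacent exons;
skip of k = exons i and j with k = j − i − 1 ≥ 1; anything else
unannotated.  On the minus strand the junction's genomically-right boundary
is the donor side.

The per-k knockdown/control profile normalizes each sample's counts to
counts-per-million of its total junction reads, then forms, per event,
(mean normalized kd + c) / (mean normalized control + c) with pseudocount
c = 0.5, and reports the median across events of each class k plus the
pooled k ≥ 2 class.  Whether the ratio is formed per event (default) or
per class before the median is config-exposed; at low expected counts the
pseudocount shrinks ratios toward 1, so recovered medians slightly
underestimate large multipliers for rare high-k events.

## Skipped-exon event calling

PSI is estimated from junction counts only:
PSI = ((inc_up + inc_down)/2) / ((inc_up + inc_down)/2 + exc), where the
two inclusion junctions are the exon's flanks and the exclusion junction
directly joins the flanking exons.  No effective-length normalization is
applied and no multi-isoform projection is attempted.  Counts are pooled
across replicates per condition; the test is Fisher's exact test on the
pooled 2×2 (rounded mean inclusion, exclusion), with Benjamini–Hochberg
FDR across all tested exons.  The rounded mean (rather than the sum of the
two inclusion junctions) keeps the test's inclusion weight consistent with
the PSI definition and avoids double-counting each included molecule.
Significance requires both |ΔPSI| > 0.2 and FDR < 0.01; these gates are
fixed defaults of the analysis, not fitted quantities.  The exact test is
deliberately simple plumbing — the replicate-aware likelihood models of
dedicated splicing callers are out of scope — so p-values here understate
between-replicate variability; the gates, not the test, carry the
scientific content.

## EJC occupancy bootstrap test

Per gene, crosslink counts are aggregated across crosslink experiments;
genes with zero RNA-seq support across all exons, or fewer than three
exons, are dropped.  The *internal-exon mean* is the mean crosslink count
over exons 2..n−1 (first and last exons excluded: their apparent skipping
is usually driven by other transcriptional events).  For a skip event with
upstream exon u, the offset-o ratio is crosslink[u − o + 1] / internal
mean; it is NA when the referenced exon would be exon 1 or off the chain,
or the internal mean is 0.  Events are deduplicated on (gene, upstream
exon) so one junction neighbourhood cannot contribute twice when event
lists from several analyses are pooled.

The null is built by drawing m exons (m = number of contributing events,
so observed and null means are exchangeable under H0) uniformly with
replacement from the pool of internal exons of all filtered genes,
computing each exon's within-gene ratio, and recording the replicate mean;
B = 100,000 by default (10,000 in the CLI's smoke default).  The p-value
is the +1-corrected two-tailed empirical probability
p = min(1, 2·min((1+#{null ≥ obs}), (1+#{null ≤ obs}))/(B+1)), bounded
below by 2/(B+1) and above by 1.  The pool composition is config-exposed
(`internal`, `all-but-last`, `all`); `internal` is the default because it
matches the domain over which the statistic itself is defined.  A single
integer seed drives one generator instance per run.

A structural property of this statistic worth knowing: within one gene the
ratios of all internal exons average exactly 1, so if the exon upstream of
a skipped exon is genuinely enriched by a factor γ, the remaining internal
exons of that gene — including the offset-2 exon — are depressed by
≈ (γ−1)/(n_int−1+γ).  The offset-1 excess and the offset-2 deficit are two
faces of the same within-gene conservation; the deficit shrinks with the
number of internal exons.  This is why the offset-2 ("further upstream")
curve can only look null when affected genes have many internal exons
and/or the enrichment is modest relative to the between-exon noise.

## Protein-level consequences

The coding nucleotides removed by a skip event are the intersection of the
skipped exons with the CDS interval.  Frame: none (0 nt), in-frame
(multiple of 3), frameshift.  PTC detection deletes the skipped coding
span from the spliced CDS, translates from the original start, and calls a
premature stop when the first in-frame stop lies strictly before the codon
homologous to the annotated stop (for a frameshift: before the last
complete codon of the mutant).  No NMD heuristics (e.g. the 50-nt rule)
are applied — the claim is purely positional.  Domain impact is interval
arithmetic on the ORIGINAL protein's coordinates: a domain is `total` when
fully inside the union of lost residue intervals (for frameshifts,
everything at/after the first diverged codon is lost), `partial` on proper
overlap, `none` otherwise.  Codons only partially encoded by a skipped
exon change identity and count as lost.

## Paralog divergence

Global affine-gap alignment (Needleman–Wunsch; BLOSUM62, gap −10/−0.5 for
protein; +5/−4, −10/−0.5 for nucleotide) via Biopython's PairwiseAligner,
taking its canonical first alignment for determinism.  Percent identity is
reported both over aligned non-gap columns (default) and over the full
alignment length.  dN/dS uses Nei–Gojobori (1986) counting on the codon
alignment obtained by back-translating the protein alignment: synonymous
site fractions per codon (changes to stop codons count as nonsynonymous),
multi-step codon differences averaged over all orderings of the differing
positions excluding pathways through stop codons, Jukes–Cantor correction
d = −(3/4)·ln(1 − 4p/3) (undefined at p ≥ 0.75, reported as an error).
ω = dN/dS, NA when dS = 0.  A counting estimator was chosen over
codeml-style maximum likelihood because it is self-contained and exactly
testable against enumeration; the purifying-selection conclusion (ω ≪ 1)
is robust to the estimator even though the third decimal of ω is not.

The bundled sequence pair (`data/synthetic_magoh_paralogs.fasta`) is a
synthetic stand-in for the human MAGOH/MAGOHB pair, constructed to carry
that pair's documented divergence structure: 146-residue proteins
differing at two N-terminal positions (144/146 = 98.63% identity) and CDSs
with ~60 synonymous third-position differences (62/441 nt differ, ≈ 86%
identity).  Its amino-acid composition is biased toward high-degeneracy
residues so that synonymous sites are plentiful and the Jukes–Cantor
correction stays below saturation, as in real conserved protein pairs.
On this pair the package reports ω ≈ 0.006 — strong purifying selection.

## Synthetic-data generator

Everything the pipeline consumes can be generated from one seeded
configuration; every artifact is a pure function of the configuration.

* **Gene models** — one transcript per gene; exon count uniform in
  (15, 30) by default, exon lengths 80–300 nt, introns 200–2000 nt, both
  strands; the CDS starts inside the first and ends inside the last exon,
  so every internal exon is fully coding, and its length is a multiple
  of 3.  The exon-count default is deliberately at the long end of human
  genes: the analysis targets genes capable of multi-exon skips with
  intact flanks, and (see the conservation property above) the offset-2
  null behaviour of the occupancy statistic only emerges for genes with
  many internal exons.
* **Events** — exactly round(n_genes × fraction_affected) genes are
  affected (an exact count, drawn without replacement, so study sizes are
  reproducible); each affected gene gets one designated skip event per
  configured class k where geometry allows, with the first skipped exon at
  index ≥ 3 so the upstream ratio is defined.
* **Junction reads** — Poisson; canonical junctions share the gene's
  expected depth (default 10,000 reads/gene) equally; each designated
  event draws Poisson(depth × rate) with rate = base_skip_rate[k] in
  control and × kd_multiplier[k] under knockdown.  Default multipliers
  rise from 1.5× (k = 1) to 3× (k = 5), emulating the observed pattern
  that higher skip classes respond more strongly to knockdown (≈2× for
  2-exon and ≈3× for 5-exon skips).
* **Occupancy** — negative-binomial crosslink counts (mean 50, size 0.3;
  CLIP-like strong overdispersion), with the mean multiplied by
  enrichment_gamma (default 3) on the exon immediately upstream of each
  designated skipped exon; two crosslink and two RNA-seq columns per exon
  exercise the loader's aggregation; a configurable fraction of genes is
  silent (all-zero RNA-seq) and is dropped by the loader's filter.
* **CDS/domains** — random internal-stop-free CDS per gene; for each
  gene's first designated event three domains are placed relative to the
  deleted residue interval (inside / straddling / before), giving known
  total / partial / none outcomes; in-frame events are guaranteed PTC-free
  by regenerating the CDS if a junction-spanning codon happens to become a
  stop; expected consequence calls are emitted alongside the data.

What the generator does **not** emulate: read-level artifacts (mapping
bias, positional coverage, overhang filters), sequence-dependent splice
site strength, isoform mixtures beyond a single reference transcript per
gene, correlated replicate effects, or any causal coupling between
occupancy and skip rates (enrichment is injected at designated exons, not
mechanistically derived).  Tests passing on these data therefore validate
the statistical machinery and its calibration, not the biological claims
on real RNA-seq/CLIP data.

## Problem sizes and numerics

Simulation-based checks use 200 genes (150–250 where noted) at depth 10⁴
junction reads per gene with triplicate conditions; calibration and power
studies of the occupancy test use 250 genes with 200 affected events,
B = 2,000 resamplings and 100–200 repetitions, sizes at which the
empirical p floor (2/(B+1) ≈ 0.001) and the binomial precision of
rejection rates are adequate.  The bootstrap vectorizes replicate draws in
chunks of 4,096 to bound memory at large B.  Ties in reference selection
and alignment traceback are broken deterministically; all randomness flows
from explicit integer seeds through one numpy Generator per run.

## Known limitations

* The SE-event test ignores replicate structure (pooled counts).
* PSI is junction-only; no exon-body or effective-length evidence.
* The occupancy test treats events as independent; shared genes are
  handled only through (gene, upstream exon) deduplication.
* NG86 with Jukes–Cantor saturates at p ≥ 0.75 and refuses to extrapolate.
* The bundled paralog pair is a labelled synthetic stand-in, not the
  deposited human sequences.
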