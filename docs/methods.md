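# Methods

## Coordinate conventions

All profiles, bins and target sites live on the spliced transcript in
0-based, half-open coordinates with the construct start (start codon for
the reporters) at position 0, read 5′→3′ along the mRNA.  The 5′/3′ half
boundary is ⌊L/2⌋: positions strictly below it are 5′, the midpoint of an
odd-length transcript falls 3′.  This tie rule is arbitrary but
deterministic and biases the partition by at most one nucleotide.  piRNA
sequences are stored in the DNA alphabet (U→T) so matching is plain string
comparison.

## Read model and placement

A 22G read is defined by length and 5′ nucleotide; the defaults (21–23 nt,
5′ G) tolerate ±1 nt around the characteristic 22, and both are
configurable rather than hard-coded.  Reads are assumed adapter-trimmed
and error-free relative to their source, so placement is exact string
matching of the read and of its reverse complement against the supplied
reference set; `n_loci` counts all placements of the read's sequence over
that set, and the default filters keep unique antisense 22G hits.
Uniqueness is therefore *reference-set* uniqueness, not genome-wide
uniqueness — with a transgene-plus-transcripts reference this matches the
"unique matches" convention of transgene profiling, but a read unique here
could still be multi-mapping against a full genome.  External aligners can
be used instead via a 6-column TSV (read_id, transcript_id, start, end,
strand, n_loci).

The sensor reference set pairs the construct with a separate "endogenous
his-58" sequence.  The normalizer segment is an endogenous histone gene
that also exists outside the transgene, so reads fully matching it place
at two loci and drop out of the construct's unique-match profile, while
still being counted (containment in the segment, both orientations, any
length, one count per read) for his-58 normalization.  Normalization
modes: `per_his58` divides by that count, `per_million` by library size in
millions, `raw` leaves counts untouched.

## Profiles, regions, bins

The default counting rule attributes each read once, at its 5′ end on the
antisense strand (the right-hand end of the covered interval in transcript
coordinates); the figures this emulates are read-count histograms, and
full-coverage counting is kept only for visualization.  Raw-mode totals
therefore equal the filtered hit count exactly, and both the 10-bin
summary (bin b covers [⌊bL/10⌋, ⌊(b+1)L/10⌋), every position in exactly
one bin) and the proximal/distal split conserve the total exactly.
Proximal means within 200 nt of the target-site segment (the segment
itself is the site ± 50 bp flanks of the construct design; the 200-nt
window is the biological definition of "site-proximal" and is a separate
parameter).  Fold enrichments and log-ratios use a pseudocount of 1 read
per million by default.

## Spreading clusters

Genes with ≥ 1 raw antisense 22G read in the clustering condition (the
nuclear-RNAi mutant) enter the analysis; each bin vector is scaled to
proportions so clusters capture shape rather than abundance (raw-count
clustering is available behind a flag).  k-means is Lloyd's algorithm with
k-means++ seeding, 20 restarts keeping the lowest within-cluster sum of
squares, tol 1e-6 on the maximum centroid shift, max 300 iterations;
"failed to converge" means the shift still exceeded tol at the iteration
cap.  `select_k` runs k = 2..8 and keeps the largest k whose best run
converged.  On clean synthetic data every k converges, so k = 8 is chosen;
with real libraries larger k can legitimately fail, which is the intended
behavior of the rule.  Per cluster, the ratio curve is
log₂[(mean mutant bin, library-scaled) + ε] − log₂[(mean WT bin,
library-scaled) + ε] with ε = 1 read per million, and the spreading index
is the mean of bins 1–5 minus the mean of bins 6–10; |index| > 0.5 log₂
units calls `loss_5prime` / `loss_3prime`.  The threshold is symmetric, so
the call is antisymmetric under reversing bin order.

`SpreadingKMeans` wraps the same clustering as a scikit-learn estimator
(get_params/set_params, fit/predict, trailing-underscore attributes) so it
composes with sklearn model selection; scikit-learn's own KMeans is used
in the tests as an independent check on the objective, never as the
implementation.

## Target-site prediction and tests

A site is an ungapped, end-to-end antisense match: position p is reported
when Hamming(transcript[p:p+21], revcomp(piRNA)) ≤ max_mm (default 3),
with N counting as a mismatch and overlapping hits all kept.  Site-position
bias of a cluster is a 2×2 table — (cluster 3′ sites, cluster 5′ sites;
background 3′ sites, background 5′ sites) — tested one-sided with Fisher's
exact test on the raw counts; the displayed log₂ enrichment adds 0.5 per
cell.  Because the historical analysis does not fix whether the comparison
was within-cluster or cluster-versus-background, both are computed: the
cluster-vs-background Fisher test is primary and a within-cluster binomial
against 0.5 is reported alongside.  Per-gene level changes between
conditions are log₂ ratios of library-scaled totals (ε = 1 rpm) with a
paired Wilcoxon signed-rank test per cluster, plus quartile/1.5-IQR
whisker summaries for box plots.

Fisher's exact test enumerates the hypergeometric distribution in
log-space (log-gamma), which is stable for margins up to ~10⁶; the
two-sided p sums all tables with probability ≤ the observed one (with
1e-7 relative slack for ties), the dominant convention.  The signed-rank
test drops zeros by default (the original treatment; Pratt's method is an
option), uses midranks for ties, enumerates the exact sign-flip null via
dynamic programming when n ≤ 12 and tie-free, and otherwise applies the
normal approximation with tie and continuity corrections.  Both are
verified against full enumeration oracles and against scipy in the tests.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes, not
sequencing chemistry: no sequencing errors, adapters, quality variation or
multigenerational dynamics.  Its genotype logic is two flags —
`secondary_active` (false for *prg-1*, *mut-16*, *rrf-1;ego-1*, *drh-3*)
and `tertiary_active` (false for *hrde-1*, *nrde-1*, *nrde-4*, and forced
false whenever the secondary tier is off) — encoding the epistasis that
tertiary small RNAs require the secondary tier.

Reads are exact reverse complements of transcript windows.  Antisense
emission anchors each read's 5′ end at a template-C position (so every
antisense read starts with G) drawn uniformly (or shape-weighted) within
its region; anchors closer than 22 nt to the transcript start are excluded
so every read fits full-length.  Region counts are Poisson with mean
rate × region length × depth.  Defaults, chosen once for a plausible
desk-scale library of 10⁵ reads:

* `lambda_proximal` 1.5e-5 and `lambda_distal` 8e-6 reads/nt per unit
  depth — on the 1561-nt sensor this gives ≈ 780 proximal and ≈ 830
  distal antisense reads, comparable populations of a clearly silenced
  reporter;
* `lambda_background` 1e-9 — ≈ 1 stray antisense read per million reads
  per kb of transcript, the near-zero nonspecific background expected on
  a non-target;
* read lengths {21: 0.15, 22: 0.70, 23: 0.15} — the class is defined by
  its characteristic 22 nt; exact proportions are unreported in the kind
  of data emulated, so they are configuration, not constants;
* `his58_rate` 2000 expected normalizer reads, sense-agnostic, contained
  in the his-58 segment;
* random filler sequences pad each library to the configured depth, so
  per-million normalization behaves like a real library in which the
  reporter is a small fraction of reads.

The sensor construct is GFP (870 nt) :: his-58 (370 nt) :: 21U site ± 50 bp
(121 nt) :: tbb-2 3′UTR (200 nt); the operon reporter is mCherry (711) ::
linker (100) :: GFP (870) :: par-5 3′UTR (200).  Construct sequences and
the 21U query are generated from a fixed internal seed: they are
reference, not sample, and stay identical across simulation seeds.

The genome panel (default 300 genes, depth 3×10⁵ per library) contains
50% `cluster6_like` genes (a piRNA site at ~0.76 of the gene length ± 5 nt;
wild type shows proximal + distal reads, nuclear-RNAi mutants only
proximal — hence 5′-bin loss; *prg-1* loses both), 20% mirrored
`cluster1_like` genes (site at ~0.24, 3′-bin loss), and 30%
genotype-insensitive genes split across six shape archetypes (uniform,
cubic 5′ and 3′ ramps, both-ends, middle block, double peak), each a 15%
uniform baseline plus 85% shape so no bin is ever empty.  Untargeted genes
are emitted at twice the per-gene read budget of targeted genes,
reflecting abundant piRNA-independent 22G targets and keeping library
composition stable across genotypes.  Gene lengths are drawn from a narrow
band (1180–1220 nt): the shape classes are defined in relative
coordinates, and a wide length spread would smear the fixed 200-nt
proximal window across bins and turn each class into a continuum rather
than a cluster.  Each targeted gene gets its own 21U piRNA whose reverse
complement is embedded at the site with 0–2 substitutions, exercising the
mismatch-tolerant scan.  IP simulation resamples a base library with
weight `ip_fold` (default 10) on construct-antisense reads and 1
elsewhere; the control IP resamples uniformly.  Because the enriched class
is a finite fraction f of the library, the measurable fold is
ip_fold / (1 + (ip_fold − 1)·f) ≈ 9 at the default composition — the same
compression a real IP over a fixed sequencing depth shows.

What passing on this data does **not** show: robustness to sequencing
error, to multi-mapping beyond the supplied reference set, to isoform
mixtures, to uneven RdRP processivity along templates, or to the much
larger gene-to-gene variability of real libraries.  The defaults are
detectability choices, not biological estimates — in particular the
secondary:tertiary abundance ratio is unreported in the emulated setting
and the 1:1 default should not be read as biology.

## Scale of the shipped analyses

Simulated library sizes default to 10⁵ reads (sensor) and 3×10⁵ (panel)
with 300 genes — enough for every per-region expectation to sit well
above shot noise while a full pipeline run stays in tens of seconds.
Deeper libraries sharpen the same estimates; all depths are configuration.

## Known limitations

* Exact matching cannot ingest reads with errors; supply external
  alignments via TSV for real data.
* One isoform per gene; the caller chooses which isoform to supply.
* The k-selection rule inherits k-means' locality: with few restarts a
  non-optimal partition can masquerade as converged.  The default 20
  restarts make this rare at panel scale.
* Fisher p-values below ~1e-300 underflow to 0; they are reported as
  computed.
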