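# Methods

`plasmidkit` implements the inference chain used to discover and
characterize large extrachromosomal elements (ECEs) — in particular the
megabase-scale-adjacent (150–250 kb) circular plasmids of anaerobic
methane-oxidizing *Methanoperedens* archaea — from assembled metagenomes,
read alignments and metatranscriptomes. This note records the models,
parameter choices and numerical decisions, and what the synthetic tests do
and do not demonstrate.

## Candidate discovery (`discover`)

Contigs are screened on three axes:

* **Taxonomy.** Each gene carries an ordered lineage (domain → species); a
  contig's profile at a chosen rank (default genus) is dominated by the most
  frequent classified lineage. "Dominant" is quantified as ≥ 50% of
  classified genes (configurable) — plasmid genes inherit their host's
  taxonomic signal because plasmid proteomes are closest to their host's.
  Ties are broken lexicographically and flagged rather than hidden.
* **GC/coverage binning.** Single-linkage grouping joins contigs whose GC
  differs by ≤ 0.02 (absolute), whose coverages differ by ≤ 15% (relative
  to the larger), and whose dominant lineage agrees. The windows are wide
  enough to keep a chromosome sequenced at ~4,350× in one bin while cleanly
  separating a 27× replicon, and to separate replicons at 39.2% vs 41.5% GC.
  The largest lineage-matching bin (by summed length) is the chromosome.
* **Replication markers.** Case-insensitive substring matching of product
  strings against {Orc1, Cdc6, ParA, RepA}. Annotation itself is out of
  scope; keyword matching on an existing annotation is deliberately simple
  and auditable. Candidates are lineage-matching non-chromosome bins with at
  least one marker.

Relative abundance is coverage·length weighted: fraction_i =
cov_i·bp_i / Σ_j cov_j·bp_j.

## Host assignment and copy number (`hostlink`)

Coverage is Σ aligned bases / contig length. An ECE is assigned to the
lineage-matching chromosome; with several candidates the one whose depth
ratio is closest to 1 (smallest |log ratio|, ties by id) is chosen and the
ambiguity reported, never silently resolved. The **abundant** band for the
ECE/host depth ratio is [0.67, 1.5]: wide enough to cover observed ~0.73 and
~1.06 plasmid:chromosome ratios, far from the ~0.006 ratio of a rare
replicon against a dominant chromosome. Copy number is the ratio reported to
two decimals. On simulations the estimate is within 10% of truth at ≥ 50×
host depth (relative error scales as ~1/√pairs).

## Circularity (`circ`)

Two independent signatures of an assembled circle are required jointly:

1. **Terminal direct repeat** — the longest k ∈ [20, 5000] with Hamming
   distance(prefix_k, suffix_k) ≤ 0 (mismatch allowance configurable for
   base-call errors). Hamming rather than edit distance: assembler terminal
   duplications are exact copies. A ≥ 20 bp spurious repeat on random
   sequence has probability ≈ L·4⁻²⁰ per contig — negligible.
2. **Junction-spanning pairs** — mate pairs with the forward mate ending
   within one insert length (default 1,000 bp) before the junction and the
   reverse mate starting within one insert length after it. At least 3 pairs
   are required (expected spanning pairs ≈ depth·(insert − 2·read)/(2·read)
   at any point, so ≥ 10× depth gives a comfortable margin).

Either signature alone yields a "suggestive" flag, not a circular call.
Trimming removes the duplicated terminus; rotation to a chosen start (for
instance the predicted origin) remaps gene coordinates mod length, snapping
to the nearest intergenic position so no ORF is split.

## GC skew and replication (`skew`)

Windowed skew is (G−C)/(G+C) per window (0 when a window has no G/C;
non-ACGT ignored), computed at offsets 0, step, 2·step… (defaults 1,000 bp /
10 bp, the defaults of the widely used gc_skew tooling). For circular
replicons windows wrap. The cumulative skew is de-trended by subtracting the
linear ramp (total skew)·(i/n): without de-trending the extrema of a
sequence with nonzero total skew depend on the arbitrary assembly rotation.
The origin is placed at the global minimum of the de-trended cumulative and
the terminus at the maximum (G-rich leading strand convention; flip
`origin_at_minimum` for the opposite). On synthetic replicons with amplitude
a ≥ 0.05 and L ≥ 100 kb the origin is recovered within 2 windows, and the
prediction is rotation-equivariant.

Classification uses the non-overlapping (stride = window/step) subseries so
its permutation null is exchangeable — overlapping windows are heavily
autocorrelated and would invalidate a naive permutation. Signal strength is
the de-trended cumulative range; the threshold defaults to the 95th
percentile of 100 seeded permutations. A profile above threshold is
**supported** when the windowed skew's signs agree with the best two-arm
(origin→terminus) split for ≥ 75% of informative windows, **weak**
otherwise, and **none** below threshold. The expected agreement is
Φ(a/σ_w) with σ_w ≈ 1/√(gc·window), i.e. ≈ 0.98 at a = 0.1 and ≈ 0.58 at
a = 0.01 with 1-kb windows, which is what makes the 0.75 cut discriminating.

## Expression (`express`)

Alignment filtering keeps placements with identity ≥ 0.99 (inclusive);
reads with several equal-best placements are resolved by a seeded uniform
choice (or dropped). A read counts for a gene when its overlap covers
≥ 10% of the **feature** length — the denominator is the gene, not the
read; this matters and is easy to get backwards. A read qualifying for
several genes counts once, for the gene with the largest overlap (seeded
tie-break; a count-for-all mode is available). Counts are normalized to
reads per 1,000 bp of gene; ≥ 0.5 is expressed. Tier presets: {0.5, 10,
100} and, for very deeply sampled replicons, {0.5, 50, 500} — all bounds
inclusive-lower. Replicate counts are summed before normalization
(per-replicate mode available). The "rate ≥ 2 ⇒ expressed with P ≥ 0.99"
guarantee is a Poisson-tail statement: the no-call probability is
P(Poisson(rate·len/1000) < 0.5·len/1000), ≈ 3·10⁻³ at rate 2 for a 5-kb
gene but ~0.2 for an 800-bp gene; the property test uses 5-kb genes
accordingly.

## Protein subfamilies and enrichment (`protfam`)

All-vs-all local alignment (BLOSUM62, gap open −11 / extend −1 via
Biopython's PairwiseAligner) yields a similarity edge when the e-value is
≤ 10⁻³ and the aligned span covers ≥ 50% of the **shorter** sequence.
E-values use the Karlin–Altschul form E = m·n·2^(−bits), bits =
(λS − ln K)/ln 2 with the standard gapped-regime constants for BLOSUM62
11/1 (λ = 0.267, K = 0.041), recorded here so the thresholds are
reproducible: gapped scores under ungapped constants would overstate
significance and admit spurious edges between unrelated ~200-mers (random
local scores sit near ln(Kmn)/λ ≈ 30–40, well below the ≈ 58 needed to
reach E ≤ 10⁻³ at this search space). An optional exact 6-mer prefilter
(off by default) skips alignment only for pairs sharing no exact 6-mer;
family members at ≤ 10% per-site divergence share dozens of exact 6-mers,
so the filter is lossless there in practice and plays the role of a
sensitivity knob.

Subfamilies come from greedy set cover on the similarity network: the
uncovered protein with the largest uncovered neighborhood (itself plus
uncovered neighbors) becomes a representative and claims that neighborhood;
ties break lexicographically; singletons are legitimate leftovers. The
result is a partition.

Enrichment tests each subfamily of size ≥ 2 (singletons carry no
information for a 2×2 test) against the plasmid/non-plasmid dichotomy:
a = plasmid members, b = other members, c/d = the complements outside the
subfamily. The two-sided Fisher p is computed by exact big-integer
hypergeometric enumeration — summing all tables with the observed margins
whose probability is ≤ the observed one, with a 1+10⁻⁷ relative tie
tolerance matching floating-point implementations — and verified in the
tests against an independent factorial-formula oracle on every table with
total ≤ 30 and against `scipy.stats.fisher_exact`. BH FDR is the explicit
step-up q_(i) = min_{j≥i} m·p_(j)/j, verified against
`statsmodels.stats.multitest`. A subfamily is **enriched** when its odds
ratio (a·d)/(b·c), with ∞ when b·c = 0 and a·d > 0, is ≥ 1 and q ≤ 0.05.
"Ratio ≥ 1" is read as the odds ratio; the fraction-ratio reading is
sign-equivalent and available as a flag. Percent enrichment is
100·a/(a+b) rounded half-up to an integer — half-up, not banker's
rounding, so the output is deterministic at .5 boundaries.

## Synthetic communities (`synth`)

The generator encodes the study conditions, not a dial to tune:

* **Skew model.** Bases are drawn i.i.d. with P(G) = gc/2·(1+a),
  P(C) = gc/2·(1−a) on the leading replichore (swapped on the lagging) and
  P(A) = P(T) = (1−gc)/2, so the expected windowed skew is exactly ±a and
  every downstream check has a closed-form expectation. Defaults: plasmid
  150 kb (the published complete plasmids are 155,605 and 191,912 bp),
  GC 0.392, amplitude 0.1, a 1,743-bp AT-rich (GC halved) origin segment.
* **Host.** A 300-kb linear chromosome at GC 0.45 — scaled down ~13× from a
  real ~3.9-Mb chromosome to keep simulations fast; its GC is set far enough
  from the plasmid's for composition binning to be informative on its own,
  standing in for the taxonomy/curation context a real analysis also has.
* **Reads.** Fragment starts are uniform (no GC bias — sufficient for
  ratio-based copy-number logic), insert ~ N(350, 50) clipped, 150-bp mates,
  identity 1.0; circular replicons wrap, which is what produces
  junction-spanning pairs. Pair count = depth·L/(2·read_length).
* **Genes and transcripts.** Genes tile at ~1 per kb (matching ~159 ORFs on
  a 155-kb plasmid) with ~800-bp bodies — at least read_length/0.1, so a
  fully contained 100-bp transcript read passes the 10% feature-overlap
  rule. 60% of genes are planted expressed at per-kb rates log-uniform in
  [10, 100]; transcript reads are Poisson per gene and fall entirely inside
  the gene body.
* **Proteins.** Family seeds are uniform 200-mers; members carry i.i.d.
  substitutions (expected pairwise identity (1−p)² + p²/19 ≈ 0.81 at
  p = 0.1). Family sizes default to a geometric distribution truncated to
  [2, 10]. For enrichment-power experiments plasmid-only families are
  planted with 3–5 members: the published 100%-enriched subfamilies have
  2–4 members against a ~1.1% plasmid background (1,079 of 96,548
  proteins), and at the desk-scale background used here (~190 proteins,
  ~15% plasmid) a 2-member family carries no power after FDR, so the
  planted effect is sized to be detectable under the scaled-down null.

What the synthetic data does **not** model: sequencing error, chimeras and
misassembly, strain heterogeneity, GC-coverage bias, rRNA carryover in
transcriptomes, domain-level (as opposed to full-length) protein homology.
Passing tests therefore demonstrate the correctness of the inference rules
under their stated assumptions, not robustness to real-data artifacts.

## Determinism

Every stochastic step consumes an explicit seed (one global seed in the
pipeline); repeated runs are byte-identical, which is tested. Tie-breaks are
deterministic everywhere (lexicographic ids; seeded draws for the two
policies that are random by definition).

## Known limitations

* Marker detection is keyword-based; a plasmid annotated without the marker
  vocabulary is invisible to `discover`.
* The GC-skew origin convention (minimum = origin) must be flipped for
  C-rich-leading genomes.
* The e-value calibration is a closed-form approximation, not an empirical
  fit per scoring system; it is calibrated for ~200-residue proteins at the
  default thresholds.
* Host assignment uses a single sample's coverages; time-series
  co-abundance and Hi-C linkage are out of scope.
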