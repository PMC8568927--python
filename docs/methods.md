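# Methods

`clonetrace` analyses the somatic evolution of multifocal tumors from
multi-sample, tumor-normal short-read sequencing summaries. Its design
target is the multifocal small-intestine neuroendocrine tumor (SI-NET)
setting: many synchronous intestinal primaries plus regional/distant
metastases per patient, very low mutational burden (hundreds to a few
thousand genome-wide SNVs), clock-like SBS5/SBS40-dominated spectra,
recurrent hemizygous chromosome 18 loss, and occasional chromothripsis.
Because patient-level WGS of this kind is controlled-access, the
package pairs every analysis stage with a ground-truth synthetic cohort
generator, and all validation rests on closed-form worked examples plus
truth-recovery on simulated cohorts.

## Clonality model

Two tumor samples are judged clonally related through the set of
somatic SNVs they share. The underlying model is a clone tree per
patient: each primary arises from an independent founder cell and
accumulates private variants; a metastasis inherits its seeding
primary's full variant complement at the time of seeding (the *trunk*)
and then continues to diverge. Under this model:

* a metastatic primary and its metastases share hundreds to thousands
  of trunk SNVs at clonal VAF;
* clonally independent primaries share essentially nothing — the only
  systematic exceptions are (i) *embryonic* variants, somatic mutations
  fixed early in development and therefore shared by tissue lineages
  rather than tumor clones (small counts, clonal VAF in every carrier),
  and (ii) *contamination traces* from sample handling (low VAF in
  exactly one sample, clonal VAF in the donor).

`classify_overlap` encodes this trichotomy with four thresholds:
`min_trunk = 50` shared variants and `clonal_floor = 0.10` median VAF
define a trunk; `trace_ceiling = 0.10` in exactly one sample defines a
contamination trace; `embryonic_max = 20` with clonal VAF in all
carriers defines an embryonic overlap; everything else is
`unexplained`. The defaults separate the three regimes the model
produces by wide margins (trunks of ~400–2,000 vs. overlaps of ≤ 20;
clonal VAF ~0.2–0.5 at usable purity vs. traces at ≤ 0.05) and are all
configurable.

## Strict filtering and whitelist recall

The strict somatic-call contract retains a call only if it has ≥ 2 alt
reads, VAF ≥ 0.01, alt support on both strands, ≥ 20 reads in the
matched normal, absence from the normal, presence in both callers'
output, and absence from a population-variant blacklist; SNVs within
3 bp of an indel call in the same sample are dropped (a stand-in for
caller-internal proximity filters; the SNP-cluster rule is off by
default because it is not reconstructible outside the caller). Each
rejected record is annotated with the first rule it fails, in a fixed
documented rule order, which makes rejection accounting testable.

Strict filtering deliberately sacrifices sensitivity for specificity —
appropriate for phylogenetics, fatal for detecting *shared subclonal*
variants. The whitelist-recall path restores sensitivity pairwise:
variants strictly called in either member of a sample pair are
re-queried in both samples' unfiltered ("relaxed") call tables,
requiring only ≥ 2 supporting reads (no VAF floor by default; the floor
is configurable because published pipelines leave it unstated). Strict
calls are by construction a subset of their own sample's recall.

Blacklists load from 4-column TSV or VCF. Two stringency tiers are
supported because aggressive population-variant removal is right for
tree building but skews signature refitting; the tier is chosen per
analysis, not baked in.

## Maximum parsimony phylogeny

The character matrix is binary presence/absence over the union of
filtered SNV keys (indels are excluded: their call quality is
systematically worse), with an all-absent germline outgroup row. Trees
are rooted at the germline — the ancestral state is biologically known,
so midpoint or unrooted display would discard information.

Scoring is Fitch small parsimony over weighted site patterns: identical
columns are collapsed, which reduces a low-burden patient (tens of
thousands of columns, but essentially one pattern per sample plus one
per trunk) to a handful of weighted patterns and makes 500-replicate
bootstraps cheap. Search is exhaustive over all rooted ingroup shapes
up to 9 leaves (global optimum guaranteed); beyond that, greedy
stepwise addition followed by nearest-neighbor-interchange hill
climbing, restarted from 5 deterministic leaf orders (fixed-seed
shuffles) with lexicographic tie-breaking, so results are reproducible
and ties resolve to a canonical topology. The restarts matter: NNI
alone stalls in local optima on ~1 in 10 random 6-leaf matrices.

Per-branch SNV counts come from a deterministic Fitch backtrace: the
root is fixed to the germline state whenever the down-pass set allows
it, and each child takes its parent's state when compatible, otherwise
preferring absent. For homoplasy-free columns this is the unique
most-parsimonious placement; for homoplastic columns it is one
documented minimal placement (stem gain plus terminal reversal in the
canonical example). Bootstrap support is the percentage of 500
column-resampling replicates whose maximum-parsimony tree contains each
internal split of the original tree, with splits compared unrooted.
"Major" branches are defined as internal branches with assigned count
≥ 10, since the distinction published alongside support values is
otherwise unstated.

## Mutational signatures

Autosomal SNVs are folded into the 96 trinucleotide channels
(pyrimidine-centred; purine-reference records reverse-complemented).
Refitting is greedy forward selection: starting from no signatures,
repeatedly add the signature whose inclusion most reduces the sum of
squared errors between the normalised profile and its non-negative
least-squares reconstruction, stopping at 4 signatures or when the
improvement falls below 1e-4; final weights under 0.06 are zeroed and
the survivors refit. The cap of 4, the 0.06 floor and the SSE objective
mirror the conventions of standard refitting tools. No genome
trinucleotide-frequency correction is applied by default (the flag
exists); profiles are compared in raw channel space.

Because genuine COSMIC v3 definitions are a controlled download, the
package ships a deterministic **synthetic** signature bank
(`signature_bank.synthetic_signature_bank`) with the structural
features the analysis depends on: a broad clock-like "SBS5", a
near-collinear "SBS40" (cosine ≈ 0.99, reproducing the real pair's
practical confusability — tests therefore assert on SBS5+SBS40
combined loading, never SBS5 alone), and sharply peaked, well-separated
"SBS1/2/13/18" analogues. Real COSMIC TSVs load through the same
reader and are drop-in replacements.

## Copy number, phasing and concordance

Window read counts (2,000 bp grid) become tumor/normal log2 ratios,
centred on the copy-neutral mode (a trimmed re-estimate of the median;
a plain median is biased when a sizeable genome fraction is altered).
Each chromosome is segmented by recursive binary splitting on the mean
difference (split accepted while |Δmean| ≥ 0.15 with ≥ 5 windows per
side), adjacent same-state segments are merged, and segments tile the
chromosome exactly. States use loss < −0.25 < neutral < 0.2 < gain,
symmetric detection down to ~30% purity; segments under 25 kb are
dropped from *reports only*. This simple segmenter replaces an
HSLM-based caller deliberately: downstream logic needs states and
breakpoints, not the specific shifting-level machinery.

A whole-chromosome event is emitted when ≥ 90% of a chromosome's
length shares one non-neutral state. Homolog phasing uses germline
heterozygous SNPs (blood-normal VAF 0.25–0.75): at purity *p*, a
monoallelic loss moves het-SNP VAFs to 1/(2−p) on the retained homolog
and (1−p)/(2−p) on the lost one. Each SNP is oriented by which allele
is elevated (deviation > 0.05) in a reference sample; test-sample VAFs
are folded onto that orientation, and the concordance fraction is the
share deviating to the same side. Concordance ≥ 0.9 calls
`same_as_reference`, ≤ 0.1 `different_from_reference`; an oriented
median within 0.05 of 0.5 despite the copy loss calls `biallelic`
(the fold-first construction is what makes this robust to binomial
read noise); anything else, or fewer than 20 informative SNPs, is
`indeterminate`.

The concordance test counts sample pairs related by the SNV phylogeny
(overlap classified as clonal trunk) in which both members carry a
monoallelic whole-chromosome event of the same kind on the same
chromosome; biallelic and indeterminate calls are excluded, reference
monoallelicity is checked via the median absolute VAF deviation
(> 0.1, which sits between read-noise level and the monoallelic signal
at purity ≥ 0.4). The one-sided exact binomial tail
P(X ≥ k | n, 0.5) is computed with `scipy.stats.binomtest`; 13
concordant pairs out of 13 gives 1.22 × 10⁻⁴.

Chromothripsis is flagged on a chromosome with ≥ 10 segments whose
states oscillate between exactly two levels: ≥ 80% of adjacent
transitions must alternate within the top two states and those states
must cover ≥ 90% of segments.

Purity is estimated as 2 × median VAF of clonal candidate SNVs on
copy-neutral regions (clipped to (0, 1]; ≥ 20 SNVs required), flagged
below the 30% usability floor. Fusion breakpoint pairs are classified
in_frame / out_of_frame / non_coding by requiring the retained pieces
to transcribe in one direction (5' piece keeps its transcription
start, 3' piece its CDS end) and the cumulative CDS lengths upstream
of the two breakpoints to agree modulo 3.

## The synthetic cohort generator

`simulate_cohort` draws a full patient from a `SimConfig`: lineage plan
(trunks, per-sample privates, embryonic sets, contamination), mutation
positions on a genome model, homolog-labelled CNAs, and read-level
observation noise. Key choices:

* **Genome**: default is the 22 hg19 autosomes scaled 1/100 (~28.8 Mb),
  so a patient simulates in ~1 s; full-length hg19 is selectable. The
  analyses depend on counts and ratios, not absolute coordinates.
* **Spectra**: contexts are drawn from the signature mixture directly
  (default 75% SBS5 / 15% SBS40 / 10% SBS1), with a random strand flip
  so that purine-reference records exercise the collapsing logic.
  Context frequencies are uniform by default; the per-year mutation
  rate is deliberately a free parameter (burden is set by
  `private_range`, default 300–1,700, keeping per-sample burdens within
  the 411–3,390 range reported for this tumor type).
* **VAFs**: a clonal variant on homolog *h* at a site with homolog
  copies (c_A, c_B) in a sample of purity *p* has expected VAF
  p·c_h / (p·(c_A+c_B) + 2(1−p)). Somatic variants are placed on a
  homolog retained in every carrier when one exists (loss-first
  chronology — clonal losses precede most point mutations in this
  low-burden setting), so configured trunks survive configured losses.
* **Reads**: site depth ~ Poisson(mean depth, default 40×), alt reads
  ~ Binomial(depth, VAF), strand split symmetric-binomial; a variant
  with < 2 alt reads is dropped (the caller support floor). The
  noise-off mode replaces draws by expectations, giving byte-identical
  arithmetic recovery of configured counts.
* **Caller provenance**: the emitted table is the relaxed
  (VarScan-like) output; records additionally carry a Mutect-like
  flag requiring ≥ 4 alt reads on both strands. This is a two-caller
  *emulation* sufficient to reproduce the observed interplay between
  strict intersection filtering and whitelist recall; it is not a model
  of either caller's internals.
* **Contamination**: a configured count of *donor-clonal* variants
  appears at trace VAF (default U(0.02, 0.05)) in the recipient only.
  Both ends are conditioned on detectability — recipient draws are
  zero-truncated at 2 alt reads, donor draws at strict-detection level —
  because the quantity being modelled is the *whitelist-detectable*
  trace count: contamination leaving < 2 reads, or stemming from a
  donor variant no caller detected, cannot appear in such a count by
  definition.
* **Het SNPs and windows**: germline het SNPs sit on a regular grid
  (default 5 kb — denser than needed, ~150 informative SNPs on scaled
  chr18) with the ALT allele assigned to homolog A or B at random;
  window counts use λ = depth × window / 300 (paired 150 bp reads)
  scaled by the purity-mixed copy factor. Window depth is not reduced
  for biallelic losses' missing tumor DNA mass; this second-order
  effect is irrelevant to state calling.

What the generator does **not** emulate — and what passing tests
therefore do not demonstrate about real data: alignment and
base-quality artifacts, mapping bias near SVs and repeats, FFPE or
oxidative damage chemistry, subclonal architecture within a sample
(all lineages are clonal in their carriers), germline leakage into
somatic calls, sequence-realistic indels (indels appear only as a
labelled minority class and are excluded from trees), and focal
amplification beyond single-copy gains.

## Reproducibility and scale

Every stochastic step takes a seed or `numpy.random.Generator`;
identical configuration yields byte-identical tables, and the
per-patient report writer is idempotent (an existing report manifest
short-circuits a rerun unless forced). Desk-scale problem sizes used
throughout the tests and the acceptance script: 1/100-scale genome,
6–12 samples per patient, 500 bootstrap replicates, 100-patient
phasing-recovery sweeps, 1,000-matrix brute-force parsimony
comparisons; a full synthetic patient analyses end-to-end in a few
seconds.

## Known limitations

* The MP search above 9 leaves is heuristic; with 5 restarts it
  matched exhaustive optima on all tested 6-leaf instances, but no
  global guarantee exists for larger trees (the published trees'
  signal — one massive trunk against private leaves — is an easy
  regime).
* `estimate_purity` assumes clonal, copy-neutral, heterozygous input
  VAFs; subclonality biases it downward.
* The chromothripsis rule is a two-state oscillation screen, not a
  full rearrangement-graph test; it will miss oscillations split by
  the 25 kb report filter if segments are smaller.
* Overlap classification assumes VAFs comparable across samples;
  strong purity differences between carriers can push an embryonic
  overlap below the clonal floor in one sample and yield
  `contamination_trace` instead.
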