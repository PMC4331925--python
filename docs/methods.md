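# Methods

This note documents the models, the numerical choices, and what the
synthetic-data experiments do and do not establish.

## Coordinates and conventions

Internally every interval is 0-based half-open on the plus strand; GFF3
(1-based closed) is converted on load. TSS-relative region bounds use the
biology-style closed convention without a position 0: −1 is the base
immediately 5' of the TSS, +1 is the TSS base, so [-300;+1] spans 301
bases. A minus-strand hit is recorded at the plus-strand offset of its
leftmost base, keeping all distance arithmetic in one frame. `N` matches
only an `N` pattern position, so masked or gap-filled sequence never
produces hits. Regions whose 3' end is "5'UTR" run to the last base of
the annotated 5'UTR; genes without one use the TSS base. Promoter regions
are not truncated at neighbouring genes (regions are fixed-length by
design); the representative transcript of a gene is the one with the
5'-most TSS.

## oPWM

Training sites are aligned on their TGTCNN core with 50-nt flanks
(25 records × 106 nt by default). Column frequency tables carry a Laplace
pseudocount of 0.25 per letter (one pseudo-observation per column;
dinucleotide columns analogously 0.25 per cell). Weights are
log2(frequency/background). The window optimisation evaluates every
(offset, length) pair on a grid (lengths 12–40, all offsets keeping the
6-nt core inside the window) by the AUC separating the training windows
from 3× dinucleotide-shuffled decoys (Altschul–Erickson shuffle, exact
doublet preservation); ties prefer shorter windows, then windows centred
closer to the core. The original oPWM optimisation criterion is not
restated in the source literature available to us, so the AUC objective
is this package's own stand-in: it is threshold-free and reproducible.
The chosen window length is data-dependent — on flat synthetic flanks the
AUC favours tight windows near the grid minimum, while flanks carrying
planted context attract longer windows.

Scores are the equal-weight mean of the two min-max-normalised raw sums,
where the normalisation endpoints are the analytic per-column extreme
sums; the combination rule is likewise a design choice (the two matrices
are presented as joint evidence, without a stated rule). Windows
containing `N` score 0.

## SiteGA

An LPD feature is the frequency of one dinucleotide among the start
positions inside a character window [a,b) (spans 2–6 nt by default) of
the 25-nt [-12;+13] frame around the core. A genetic algorithm
(population 100, 200 generations, tournament size 3, one-point crossover
on the sorted index set, per-gene mutation 0.02, mandatory seed) selects
K = 30 features maximising the Fisher criterion
(μ₁−μ₂)ᵀ S_w⁻¹ (μ₁−μ₂), with the pooled covariance ridge-regularised by
1e−6 on the diagonal for small-n stability. The discriminant direction on
the winning subset gives the score, min-max normalised over the training
scores and clamped to [0,1]. Negatives default to 3× dinucleotide-
shuffled positives (preserving local composition). K, the GA schedule and
the discriminant form are this package's choices; the original method's
hyperparameters are not restated in the available description.

Genome scanning is anchor-based: only 25-nt frames whose core positions
match TGTCNN (either strand) are scored. This matches the core-centred
training alignment, keys the conservation rule to the same TGTC core, and
bounds runtime; scoring every genomic offset would also dilute the
score's meaning, since the discriminant was trained on core-centred
frames only.

The AuxRE_P&S call is the conjunction: oPWM score ≥ 0.78 AND SiteGA
score ≥ 0.936 at the same anchor and strand (hit score = min of the two).
When thresholds are re-calibrated on a positive promoter set, the two
thresholds are chosen **jointly** — matched per-region-maximum quantiles
of the two score distributions, lowered together until the fraction of
regions containing at least one anchor passing *both* reaches the target
(~32% by default). Calibrating each model independently at the target
fraction would make the conjunction far rarer than the target, since the
two marginal pass events at a given anchor are nearly independent.

## MotiGA

The 6-nt core is masked before flank motif search. The GA chromosome
holds one (offset, strand) instance per record (OOPS); fitness is the
KDIC of the induced frequency matrix,
KDIC = (1/W)·Σ_cols Σ_letters f·log2(f/b) with 0·log 0 = 0, against the
mononucleotide background of the unmasked flanks. After the GA, a
deterministic greedy polish alternates (i) re-placing every instance at
its best-scoring position under the current matrix and (ii) register
shifts of ±1–2 columns applied to all instances, each accepted only while
KDIC increases — this removes the local-optimum and phase-ambiguity
failure modes of a pure placement GA. Successive motifs are found by
deflation (found instances are masked); records left without a legal
placement drop out of later rounds, and discovery stops below 5 records.

Word-score p-values are exact under the i.i.d. background: per-column
score distributions are discretised at 1e−4 of the total score range and
convolved; the tail of the resulting distribution gives
P(score ≥ s), monotone by construction. A motif's hit threshold is the
smallest achievable score with p ≤ critical_p (default 0.005, exposed in
config). KDIC is reported per position in log2 (bits/position); the
normalisation of the original measure is not restated in the available
text, so per-position log2 is this package's convention.

## Composite elements

Center-to-center distances use real-valued motif centers
(start + (width−1)/2, half-integral for even widths) rounded half-up to
integer nt before classing: overlapped ≤ 5, short 6–25, long 26–50;
pairs beyond 50 nt are not composites. Side is 5' when the coupling
center lies upstream of the anchor center in transcript orientation,
ties to 5'. One coupling hit may pair with several anchors; anchor and
coupling sequence overlap is allowed (the overlapped class requires it
for 6+8-mers). Per-gene classes: single/multiple by hit count in the
named region, orientation class +/−/mixed ("multiple +" means all hits
direct — the strictest reading of an all-of-one-orientation subclass).

## Densities, profiles, conservation

The genome partition assigns every position exactly one class with
priority 5'UTR > 3'UTR > CDS exon > intron > intergenic. Density is hits
per tested position (one position universe; hits from both strands),
abundance is density relative to the whole-genome density, so the
length-weighted mean of class densities equals the genome density
exactly. TSS profiles bin the hit core centers in [-2000;+250]
strand-aware and divide by the genome-wide density; a hit may count for
every gene whose window covers it.

Alignment blocks shorter than 101 reference nt (i.e. not "more than
100 nt") or missing a required species are discarded. A site is conserved
iff its 4-nt TGTC core (strand-aware: the last four plus-strand bases of
a minus-strand hexamer) lies entirely inside one filtered block and every
non-reference species' aligned characters at those columns equal the
reference — any gap or substitution breaks the call. The baseline set is
genes whose regulatory region overlaps any filtered block by ≥ 1 nt.
Where the required-species list is ambiguous, all four non-reference
species must agree (the strictest reading).

## Expression association

Fold change is 2^(mean_treat − mean_ctrl) on the log2 scale; the gate is
strict (> 1.5-fold). The per-gene test is a two-sided pooled-variance
Student t (Welch available as an option); single-replicate experiments
are called on fold change alone. An experiment is valid with ≥ 100
regulated genes. No multiple-testing correction is applied across genes
or variants: the cross-experiment binomial-trial argument carries the
error control instead. The enrichment test keeps the element subset
inside the "all probed genes" group (no disjointing), and is one-sided
for enrichment — the published direction of interest; notably the
headline subset proportions (191/1779 vs 1965/21098) are significant
one-sided (p ≈ 0.027) but not two-sided. The influence threshold is
resolved as the smallest k with an exact binomial tail
P(X ≥ k | N, α) < 0.01 (k = 4 for N = 16, α = 0.05).

## Synthetic data: what it emulates and what it does not

The generator produces i.i.d. background sequence (GC 0.36 by default,
order-1 Markov exposed as an option), non-overlapping genes with
5'UTR/CDS/intron/3'UTR structure and clear promoter margins, planted
motif instances drawn uniformly from their IUPAC patterns at uniform
legal offsets, expression panels with homoscedastic Normal log2 noise
(sd 0.2) where element-carrying genes gain +log2(3) in the treatment arm
with probability 0.8 versus 0.05 background (sixteen experiments, one
single-replicate), and gap-free alignment blocks over a configurable
fraction of regulatory regions with i.i.d. per-column substitutions at
rate μ in four non-reference species (planted TGTC cores optionally
protected). Composite plantings draw the spacer from the configured
class and write overlapping anchor/coupling instances from the
intersection of their IUPAC constraints (re-drawing when incompatible —
e.g. the overlapped class is letter-compatible for TGTCTC/Y-patch only
on the 3' side, which is also the configuration observed in vivo).

Passing tests on these data establish that the algorithms recover what
was planted under their own model assumptions. They do not establish
performance on real genomes: real promoters have compositional
heterogeneity (CpG/TA skews, repeats), correlated expression noise and
probe effects, alignment blocks with indels and lineage structure, and
TSS annotations with errors — none of which the generator mimics.

## Problem sizes

Default analysis runs use 120 genes on a 700-kb chromosome, 16
experiments × 3+3 replicates, and GA schedules of 60×60
(population × generations); the test suite uses smaller grids and 40–50
GA schedules. These sizes were chosen so a complete run stays in the
minutes range on one core while keeping every statistical check
well-powered (planted-recovery rates are estimated from 10–25 seeded
replicates).

## Known limitations

* The oPWM objective/normalisation and the SiteGA/MotiGA hyperparameters
  stand in for originals that the available description does not restate.
* Anchor-based scanning cannot call AuxREs whose core diverges from
  TGTCNN.
* The dependency profile reports marginal pairwise correlations; heavily
  overlapping LPD windows make neighbouring pair tests strongly
  dependent, so per-position counts are descriptive, not inferential.
* The conservation model has no indel handling beyond "gap breaks the
  call" and no substitution-model weighting.
* Motif classes (Y-patch / ABRE-like / AuxRE-like) are not assigned
  automatically; discovered matrices are reported in discovery order.
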