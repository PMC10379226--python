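# Methods

## Coordinates and formats

All in-memory coordinates are 0-based half-open on "chr"-prefixed
chromosome names. Sources are converted on read according to their own
documented conventions: UCSC rmsk `genoStart`/`genoEnd` are already
half-open and taken verbatim; RepeatMasker `.out` and GFF3 are 1-based
inclusive (start decremented); the packaged HERV-miRNA coordinate table
follows the miRBase 1-based convention and is normalized the same way.
That table records no strand, so its records carry strand "." and all
overlap logic is strand-agnostic by default. Converting its rows yields
mature lengths of 17–24 bp, inside the 15–30 bp bounds the
`MirnaFeature` type enforces. Malformed annotation rows are skipped
individually with a logged line number; only structural problems
(missing file, unknown dialect, corrupted packaged fixture by sha256)
are fatal.

## MDTE calling

A mature miRNA overlapping a repeat by at least `min_overlap_bp`
(default 1 bp, the bedtools-intersect default; no overlap fraction is
imposed) is called an MDTE. A stricter full-containment mode is a flag.
A miRNA overlapping several repeats produces one call per repeat, all
flagged ambiguous; the call with the largest overlap (leftmost repeat on
ties) is marked primary, and family/subfamily tallies count primary
calls only, so each miRNA contributes once. The HERV filter keeps
families ERV1/ERVK/ERVL by case-insensitive exact match — ERVL-MaLR and
Gypsy are distinct labels and are dropped, as are unknown labels (with a
log notice). Subfamily selection accepts literal names and `NAME*`
patterns where the `*` matches at most one letter: `LTR7*` captures
LTR7/LTR7B/LTR7C/LTR7Y without capturing numerically unrelated names
like LTR70.

## HERV-H architecture

RepeatMasker splits one element into several rows, so `HERV-H-int`
fragments on one chromosome and strand are first merged into runs while
consecutive gaps are ≤ `int_merge_gap` (default 1000 bp). A run's length
is its summed member length rather than its genomic span, which is
robust to nested insertions inflating the span. The classification
thresholds, all configurable and echoed into output headers:

| parameter        | default | meaning                                      |
|------------------|---------|----------------------------------------------|
| `int_min_len`    | 7000 bp | internal run length required, strict >       |
| `ltr_len_min/max`| 435/465 | solitary length window, strict bounds        |
| `solitary_window`| 200 bp  | no `HERV-H-int` within this distance         |
| `flank_max_gap`  | 200 bp  | max gap between an internal run and a flank  |
| `int_merge_gap`  | 1000 bp | fragment-chaining gap                        |

A full-length call needs a qualifying run plus an LTR7-group feature
ending within `flank_max_gap` upstream and one starting within it
downstream, all on the run's strand; each LTR is assigned to at most one
run (smallest gap wins, leftmost run on ties). A solitary call needs an
LTR7-group feature strictly inside the length window — a window sized to
tolerate ~15 bp internal deletions around the ~450 bp consensus — with
no internal fragment within `solitary_window` on either side, on any
strand (conservative: any nearby internal sequence disqualifies).
Strictness of the bounds is switchable (`strict_bounds=False` makes them
inclusive). With the defaults, a provirus flank can never double as a
solitary call (its flank gap ≤ 200 bp fails the > 200 bp isolation
test); flanks are additionally excluded explicitly in case the two
windows are configured apart. `int_merge_gap` and `flank_max_gap` have
no canonical literature value; the defaults tolerate typical rmsk
fragmentation while staying local, and genome-wide counts are sensitive
to them — which is why the comparison against published genome-wide
reference counts (17 full-length, 931 solitary: 680 LTR7 / 155 LTR7B /
69 LTR7C / 27 LTR7Y for GRCh38) is produced as an observed-vs-reference
table by `architecture.comparison_table`, a report rather than an
assertion.

Each HERV-H MDTE is labelled by its source repeat: inside a provirus
footprint → `full_length`; a solitary call's LTR → `solitary_ltr`;
anything else → `truncated_element` (e.g. a mature miRNA inside a 63 bp
LTR7C scrap far below consensus length).

## Dot plots and conservation extent

`kmer_dotplot` reports maximal runs of shared exact k-mers (default
k=11; N never matches) on both strands, reverse-complement matches in
forward-subject coordinates. `conservation_extent` tiles the subject
with fixed windows (default 200 bp), scans left to right, and returns
the last window end whose match coverage is ≥ `min_coverage` (default
0.5) before the first failure. The defaults are the package's own; the
upstream analyses used interactive web tools without published
parameters. The extent is a coordinate, not a gene-region label;
interpreting it (e.g. "up to mid-pol") requires the consensus's gene
map, which is out of scope.

## Seed sites and duplex scoring

Seed matching is Watson–Crick only (no G·U), per target-prediction
convention: the 6mer core is the reverse complement of miRNA nt 2–7;
a match to nt 8 upgrades to 7mer-m8, an A opposite nt 1 to 7mer-A1, and
both to 8mer. Every core occurrence is reported, including overlapping
ones.

The duplex score is a pure intermolecular dynamic program: antiparallel,
non-crossing pairs with no intra-strand structure. Adjacent pairs score
by a nearest-neighbor stack table; the Watson–Crick entries are the ten
published ΔG°37 stack parameters (kcal/mol) completed by helix-reversal
symmetry. Stacks involving G·U wobbles use a single default value of
−1.0 rather than per-stack wobble parameters — a deliberate
simplification; wobbles can also be disabled entirely. Bulges and
internal loops pay affine penalties (open 3.8/4.0, extend 0.5 per extra
base) and are bounded at `max_bulge` = 4 nt per strand between
consecutive pairs. Unpaired ends are free; the empty pairing scores 0,
so reported optima are ≤ 0. Ties resolve deterministically: lower
score, then more pairs, then stack > miRNA-bulge > target-bulge > loop,
then 5′-most predecessor. `report_mfe` scores a window of miRNA length
+ 10 nt centered on each seed core and returns sites sorted by score.
Scores are "model scores (kcal/mol-scaled)": they order duplexes
correctly under the model's assumptions but are not calibrated to any
external folding server, whose parameter sets and site sequences are
unavailable — absolute published MFE values are therefore not
reproduction targets anywhere in the package.

## Differential expression and triage

Expression values are taken as already log₂-scale (the convention of the
emulated array series), so the per-gene log₂ fold change is the plain
difference of group means, case − control; no variance moderation or
p-value enters the filter, which is fold-change-only with a strict
threshold (default < −1.1). Genes missing an entire group are dropped
with a warning. Gene identifiers match exactly after whitespace
stripping; aliasing/ID mapping is out of scope. The triage report gives
all seven Venn regions of (predicted targets, down-regulated,
tumor-suppressors) plus the sorted three-way intersection; the region
counts sum to the union size by construction.

## Relative quantification

ΔCt is formed per replicate (target and reference from the same well
set); a per-sample mode averaging replicates first is available
(`per_replicate=False`). ΔΔCt subtracts the control group's mean ΔCt,
making the control mean map to fold change 1 exactly, and fold changes
are 2^−ΔΔCt. Group summaries are mean ± SD of replicate fold changes.
Two groups are compared by the pooled-variance Student *t*-test on ΔCt,
three or more by one-way ANOVA, with the conventional α = 0.05; the
degenerate all-equal zero-variance case returns statistic 0, p = 1.
Amplification-efficiency correction and melt-curve analysis are out of
scope.

## Synthetic data: what it emulates, and what it does not

Generators are pure functions of parameters + seed (numpy Generator; no
clock seeding) and place features by rejection sampling with a 10,000-try
cap, failing loudly on crowded genomes. Independently placed blocks keep
≥ 1200 bp clearance — more than both `int_merge_gap` and
`solitary_window` — so planted elements never interact by accident.
Proviruses are laid as LTR7 (440–460 bp) – internal region (7.2–9 kb,
1–3 fragments with 100–800 bp gaps) – LTR7 with flank gaps ≤ 150 bp;
solitary LTRs draw lengths uniformly inside (436, 464); decoys each fail
exactly one rule (in-window LTR with an internal fragment 50–150 bp
away; off-window lengths; ERVL-MaLR and Gypsy elements), and truncated
elements include 63 bp LTR7C scraps. The expression generator uses the
study's 16-case/9-control design with uniform(4, 12) baselines,
effect −2.0 log₂ units on planted genes and Gaussian noise
(SD 0.25) — at which point the −1.1 filter's planted-gene recovery is
effectively complete (the fold-change estimator SE is ≈ 0.10, nine SEs
from the threshold). Ct tables realize a chosen fold change exactly at
zero noise.

Passing on these benchmarks demonstrates the correctness of the rules
and arithmetic, not performance on real annotation: synthetic elements
have no sequence divergence, no overlapping or nested repeats, no
chromosome-scale inhomogeneity, and decoys are constructed rather than
learned from the rmsk error profile. Genome-wide counts on real rmsk
additionally depend on the two non-canonical gap parameters noted above.

## Problem sizes in the shipped benchmarks

The test suite and `scripts/acceptance.py` use 5-provirus/20-solitary
synthetic genomes of 5 Mb over 20 seeds, 100 random interval instances
against the all-pairs oracle, 1000 random duplexes ≤ 8 nt against
exhaustive pairing enumeration, 50 random Ct tables against the direct
formula (agreement to < 1e−12), and 50 expression seeds at the design
point — sizes chosen so the whole suite runs in seconds while every
code path and boundary case (6.9 kb runs, 435/465 bp lengths, ±200 bp
windows, the −1.1 threshold) is exercised exactly.
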