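# Methods

## The model

A single-copy "graft" chromosome (human chr21) rides on a diploid host
(mouse) genome. γ-irradiation fragmented the graft before transfer;
non-homologous end joining religated the pieces, producing a derivative
chromosome describable as an ordered, oriented list of reference
segments. Three measurable consequences drive the reconstruction:

1. read pairs spanning a novel adjacency map discordantly to the
   reference (wrong separation, wrong orientation, or different
   sequences);
2. segments present 0 or 2 times shift read depth and aCGH log₂ ratio to
   −∞/+1 relative to the single-copy baseline (depth of the graft itself
   runs at half the host's, because the host is diploid);
3. each junction carries NHEJ scars: 0–4 bp micro-homology shared by both
   flanks, occasional untemplated or distally templated insertions, and
   small flanking deletions.

Coordinates are 1-based inclusive throughout; 0-based half-open appears
only at BED import/export. A junction side is `(sequence, position,
direction)` where *ascending* means the flank reads along the forward
strand toward higher coordinates and *descending* means the reverse
complement read toward lower coordinates (the printed arrows `→P`/`←P`).
With micro-homology of length *h* the derivative reads left flank through
`left.pos`, then any inserted bases, then the right flank resuming *h*
bases past `right.pos`: both printed positions include the homology,
which appears once in the derivative and is attributable to either side.
A junction read in the opposite direction swaps sides, flips directions
and reverse-complements the scar bases; `junction_key` compares junctions
up to that symmetry.

## Pipeline parameters (defaults = the analysis contract)

| parameter | default | meaning |
|---|---|---|
| seed k-mer | 31 nt | exact-match seeding; unique seed + ≤1 mismatch → MAPQ 60, unique + 2–4 → 37, else 0 |
| pair quality floor | > 35 (strict) | discordant screen admits unique-seed pairs only |
| insert histogram bin | 10 bp | threshold scan granularity |
| threshold ratio | < 1.1 | histogram flattening criterion, scanned up from the mode |
| safety margin | 50 bp | added to the scan's stopping bin edge |
| profile sample | first 5000 eligible pairs | stream-order dependence is deliberate (first lane) |
| cluster confirmation | ≥2 pairs AND ≥3 libraries | a config override admits large-insert-only events |
| assembly window | 4 kb | reads collected around cluster breakpoints |
| depth bin | 1 kb | correct-category pairs by leftmost coordinate |
| probe quality filter | retain ≥ 0.6 | low scores flag repetitive, unreliable probes |
| call criteria | ≥10 probes and \|log₂\| ≥ 0.5 | applied after segmentation |
| wave cutoff | 5 Mb | wavelength above which log₂ trend is removed |
| boundary merge radius | 3 kb | region segmentation, see below |

## Numerical and design choices

**Insert-size threshold scan.** Scanning up from the modal bin, the
threshold is the upper edge of the first bin whose count ratio to the
next bin falls below 1.1, plus 50 bp. An *empty* next bin ends the scan
at that point: junction-spanning pairs place isolated counts far beyond
the library distribution, and scanning across the gap into them would
inflate the threshold by orders of magnitude. The method presupposes a
histogram that falls steeply from its mode — i.e. tightly size-selected
libraries; with very broad insert distributions the ratio test triggers
at the mode itself and the threshold carries no tail information. The
generator's library defaults (sd 1–5% of the mean, draws truncated at
±3.5 sd as a size-selection step would) put every library in the regime
where the threshold clears the truncated tail, so the discordant screen
is essentially stray-free — the regime in which the
zero-false-confirmed-clusters guarantee holds.

**Change-point engine.** The aCGH caller's contract is the two calling
criteria, not any particular segmentation machinery; here a plain
squared-error binary segmentation is grown to exhaustion and then pruned
by merging adjacent segments whose mean difference is under 5 noise
standard errors (noise estimated by the MAD of first differences). The
overfit-then-prune design is deliberate: a single penalized split cannot
detect a 10-probe event inside tens of thousands of probes (its one-split
gain scales as 1/n), while exhaustive splitting isolates it and pruning
removes the spurious cuts. Ties and degenerate inputs: a flat signal
yields no split; with zero noise any nonzero mean step is significant.

**Wavelet detrend.** The trend ("genomic waves") is estimated on a
uniform genomic grid (step = cutoff/64) after cell-averaging and a
9-cell running median (which keeps genuine copy-number segments, narrow
relative to the cutoff, out of the trend); a db2 decomposition keeps the
approximation plus detail bands reaching wavelengths above half the
cutoff as trend, which is interpolated back to probe positions and
subtracted. Dyadic bands have octave-wide transitions, hence the factor-2
margin; structure wider than roughly half the cutoff is treated as trend.
At realistic probe spacing (80–500 bp) the planted segments of interest
(tens to hundreds of probes) are orders of magnitude below that scale.

**Spline normalization.** Both channels move toward the per-probe
geometric mean: per rank-window medians of each channel's displacement
are smoothed with a cubic spline and subtracted, with linear
extrapolation beyond the outermost windows so monotone biases at the
intensity extremes are still corrected. Probes in a true copy-number
segment have their geometric mean shifted by half the signal, so a steep
bias curve shaves segment amplitude slightly; the injected synthetic bias
(±0.35 log₂ across the intensity range) matches two-color array practice.

**Region segmentation.** Boundary evidence arrives at three resolutions:
junction sides sequenced to the base pair, junction flanking-deletion
edges, and array change points localized only to a few kb (in this
corpus the array edges sit 1.5–2.9 kb from the junctions that refine
them). Cuts are single-linkage merged at a 3 kb radius — any radius
between the largest array-vs-sequence discrepancy (2.9 kb) and the
smallest true inter-boundary distance (4.7 kb) gives the same partition —
and each cluster is represented by its most precise member (verified
junction > flanking-deletion edge > unverified junction > array). A
copy-number interval edge coinciding with the end of the probed span is a
span edge, not a change point, and contributes no boundary. Under these
rules the packaged corpus partitions into 41 regions whose deleted
members (14, 16, 34, 39) and the one region with printed coordinates
(region 27, 24,725,876–24,880,958) come out exactly as reported. Zero
merge radius is available as a parameter but fragments the corpus into
~88 boundary artifacts of the mixed resolutions.

**Structure assembly.** Junctions are edges between oriented region
ports; the walk uses each edge at most once and visits each region at
most copy-number times, preferring the self-loop edge at a tandem
duplication. Any other branch ends the section: duplicate copies without
linking evidence are reported unplaced, never placed arbitrarily.
External ordering observations merge sections with "suggested"
confidence; contradictory observations (two different successors for a
single-copy region) raise an error.

**Gene status and fusions.** A junction side strictly inside the gene
body disrupts it, introns included (transcript continuity breaks either
way). Two genes disrupted by the two sides of one junction form a fusion
candidate; the fusion is in frame when the retained upstream coding
length plus inserted bases matches the downstream gene's reading-frame
phase modulo 3. Gene models are read from BED12 with all block bases
treated as coding — adequate for the synthetic models used here; real
UTR-annotated models would need thick-region handling.

**Mutation burden.** The expected radiation-induced point-mutation count
is `(chromosome length / target size) × rate × dose`; at 48.1 Mb, a 1 kb
gene target, 10⁻⁶ per Gy and 200 Gy this is ≈ 9.6 — "on the order of
ten".

## The synthetic generator, and what passing tests show

`genome_forge`-style simulation emulates: a random graft chromosome
(GC 42%) at copy 1 on a diploid host; optional host↔graft shared 200 bp
blocks (conserved-sequence confounding — reads from them get quality 0);
derivative construction from an explicit plan with NHEJ-style junction
scars (micro-homology planted into the reference so it pre-exists on
both flanks, and the reference base adjacent to each flank forced to
mismatch so the planned scar is the *maximal* decomposition); five
mixed-insert libraries with coordinate-exact duplicates and independent
substitution errors.

It does **not** emulate: indel sequencing errors, quality-score decay,
chimeric library artifacts, GC-dependent coverage, satellite/centromeric
repeat structure, or assembly gaps. Insert distributions are truncated
normals far tighter (especially for the jumping libraries) than typical
real large-insert preparations — the regime the printed thresholding
method requires. Recovery results on these simulations therefore
demonstrate the correctness of the evidence chain's logic, not its
robustness to real-platform noise; on real data the quality screen,
duplicate removal and multi-library confirmation carry that burden.

Problem sizes used in the shipped tests and drivers: a 200 kb graft +
50–160 kb host at ~25× pair coverage for the shared simulation, a 1 Mb
graft + 2×0.5 Mb diploid host at ~10× pair density for the end-to-end
recovery check, and 30,000-probe arrays for the aCGH chain — small
enough to run in seconds to a couple of minutes, large enough that every
library contributes multiple pairs to every junction.

## Known limitations

* The mapper is single-seed exact-k-mer with ungapped extension; there is
  no gapped alignment or Smith–Waterman rescue, so the externally-rescued
  pair category is populated only when ingesting SAM from other tools.
* Cross-sequence junction assembly needs side hints from both sequences;
  within-sequence events assemble automatically.
* Boundary-merge segmentation assumes true region boundaries are farther
  apart than array localization error; chromosomes with genuine sub-3 kb
  regions would need the radius lowered and base-pair-resolved evidence
  throughout.
* The fusion frame arithmetic treats exon blocks as coding and assumes
  the upstream gene keeps its promoter-proximal portion.
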