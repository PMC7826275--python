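# Methods

## Problem

A macrosatellite array — a unit sequence of roughly 2 kb iterated head-to-tail
tens of times between unique flanking sequences, such as the *CUP1* array of
budding yeast — changes its copy number under replication stress. A single
long read that contains both unique 1-kb flanks ("spanning read") carries the
complete internal structure of the array in one molecule, so per-read unit
counts give the copy-number distribution of a cell population directly,
without assembly. This package implements the desk side of that analysis:
simulation of array molecules and nanopore-like reads with known truth,
spanning-read selection, two independent unit counters (spectral and
dot-plot), and the downstream instability statistics.

## Match-run profile

For a read `s_0 … s_{n-1}` and unit `r_0 … r_{m-1}`, conceptually form the
n × n matrix with entries `a_{i,j} = r_{(i-j) mod m}` — each column is the
unit shifted down one row relative to its left neighbour and wrapped, so the
columns enumerate every phase of the periodic extension of the unit. Binarize
against the read (1 where `s_i` equals `a_{i,j}`), relabel each vertical run
of 1s with its length, zero all values below a threshold X, and sum rows to
get the profile `c_i`. Positions inside a tandem array accumulate long runs
at the matching phase in every column of that phase (there are about n/m such
columns), so `c` is large over the array and zero elsewhere; X suppresses the
short chance matches that random sequence produces at every phase.

`literal_matrix_profile` performs this construction verbatim (capped at
n ≤ 2000) and serves as the oracle. `match_run_profile` is the production
path and is exactly equal to it on every input, by two reductions:

1. Columns j and j′ with j ≡ j′ (mod m) are identical, so each distinct
   phase is computed once and weighted by its column multiplicity.
2. A surviving run (length ≥ X) is precisely a maximal extension of an exact
   X-mer match between the read and the cyclic unit, so runs are found by
   X-mer seeding in O(n + matches) rather than scanning all n·m cells.

Ambiguous bases (N and any other non-ACGT character) never match; the unit
itself must be plain A/C/G/T.

## Smoothing, region, spectral count

The profile is smoothed with a (2L+1)-point moving average; the first and
last L entries are copied through unchanged. The repeat region R is the
longest stretch of positions with smoothed value above `alpha · max`,
merging marked runs separated by gaps of at most `gap_tolerance`. The
density search deliberately runs on the smoothed profile rather than the raw
one: the raw profile drops to zero wherever an error cluster breaks the
matching runs, and thresholding it directly would fragment the region.

Counting within R:

* R narrower than m/2 is reported as "no repeat": a lone chance X-run on a
  repeat-free read otherwise masquerades as a single-copy array.
* R narrower than 1.5 m holds a single unit — one period has no usable
  fundamental frequency.
* Otherwise R is split at internal sub-threshold gaps of at least
  `split_gap` (default m/4). Such gaps arise where non-repeat sequence sits
  inside the array — typically an inserted marker cassette — and folding
  them into one window would bias the period estimate: a 16-unit array with
  a 1.2-kb central cassette spans 16 m + 1.2 kb, whose spectral index and
  length ratio both land between 16 and 17. Splitting yields two 8-unit
  blocks whose counts sum to 16. Error dropouts never produce gaps of this
  size at the error rates the simulator covers, and a partial-unit deletion
  produces no gap at all (the remaining partial unit still matches the unit
  at a shifted phase).
* Per block, the DFT of the mean-subtracted smoothed profile is searched
  over the index band `[band_low · |B|/m, band_high · |B|/m]` (DC excluded).
  The peak index is the count when it is an interior local maximum of the
  band with magnitude at least `min_prominence` times the band median;
  otherwise the block count falls back to `round(|B|/m)`. All gates compare
  ratios of magnitudes, so the count is invariant under positive rescaling
  of the profile.

The prominence and local-maximum gates matter because a block's spectrum is
never exactly flat: the ramps at the block edges contribute smoothly decaying
(sinc-lobe) energy whose largest band values sit at the low band edge, and
profile noise adds random peaks. A genuine periodic profile produces a line
that exceeds the band median by orders of magnitude, so the gates cost
nothing there.

With the uniform error model used by the simulator the smoothed profile of a
clean array is close to constant — uniform errors break runs at random
positions without creating per-unit structure — so the operative path on
simulated reads is the length-ratio fallback, and its accuracy rests on the
region edges being located consistently (the moving-average ramp crosses
`alpha · max` a fixed distance outside the true array edge on both sides).
On real nanopore reads the error process is sequence-context dependent, which
repeats every m bases along an array and gives the profile a genuine
m-periodicity for the spectral path. Passing the simulation tests therefore
demonstrates correctness of the machinery and of the fallback, not the
spectral behaviour on context-dependent errors.

End-to-end (`count_read`), both orientations of the unit are considered; an
exact k-mer vote pre-selects the orientation and both orientations are fully
computed only when the vote is close (within 25% plus five k-mers). The
orientation with the larger in-region profile mass is reported. The vote is
exactly symmetric under reverse complement, so counts are strand-invariant.

## Dot-plot counter

Exact k-mer matches (k = 13, both strands) between read and unit are chained
into diagonal segments while the diagonal offset drifts at most 0.1 m between
consecutive seeds (absorbing indels) and read-position gaps stay below 0.2 m;
chains with fewer than 5 seeds are dropped. Adjacent tandem copies lie on
diagonals a full m apart and therefore form separate segments, so the number
of segments is the unit count. Segments covering at least 80% of the unit
count as full units, shorter ones as partial units (interstitial deletions).
A cassette insertion is located by the same machinery run against the
cassette sequence; the boundary index is the number of full unit segments on
the upstream side of the cassette segment in array orientation. Only the
dominant strand's segments are counted, which makes the count
strand-invariant.

This counter automates what is traditionally done by eye on a dot plot, and
is deliberately independent of the spectral counter: the two agree exactly on
error-free full-unit arrays, and may differ by one unit when a partial unit
is present (the spectral counter rounds the partial length either way, the
dot plot reports it separately).

## Spanning-read selection

Each 1-kb flank is located in the read by exact 15-mer seeds clustered on
near-constant diagonals; each cluster is rescored by edit-distance alignment
(edlib, semi-global) of the chained flank stretch against the padded read
window. Hits need identity ≥ 0.75 and flank coverage ≥ 0.5. A read is called
spanning when the best upstream and downstream hits share a strand, occur in
array order, and each hit's chain reaches both ends of its flank within a
tolerance of `3 · (1 − identity) · flank_length`. The tolerance is zero on
error-free reads, so the call then reduces exactly to containment of both
full flanks; on noisy reads it absorbs seed dropout near the flank ends. The
array interval is the span between the inner flank edges.

## Synthetic data

The generator emulates the study system, not nanopore physics:

* Default unit length 2,000 bases, default flanks 1,000 bases, both i.i.d.
  uniform over ACGT under a seed (real sequences can be supplied as FASTA).
* Copy numbers 0–30, optional cassette (sequence, unit-boundary index),
  optional partial-unit deletions per copy.
* Per-base substitution/insertion/deletion errors at default rates
  0.03/0.02/0.03 (8% total), a caricature of R9.4.1-era reads. Insertions add
  one uniform base; there is no homopolymer or context dependence. Expected
  read length is (1 + ins − del) × template length.
* Read lengths are log-normal (median ≈ 12 kb, σ = 0.8 in log space), the
  usual shape of nanopore length distributions; a window at least as long as
  the molecule becomes a full-molecule (spanning) read, shorter windows are
  placed uniformly. This reproduces the key sampling bias: longer arrays are
  spanned by a smaller fraction of reads.
* Strands are drawn uniformly; minus-strand reads are reverse-complemented
  after the error process.

Not emulated: signal-level behaviour, context-dependent error hotspots
(see above for the consequence), chimeric reads, extrachromosomal circular
copies of the unit, coverage non-uniformity.

## Instability statistics

* Divisions per day from absorbance: `log2(OD_end / OD_start_after_dilution)`,
  summed over days.
* Variation index: `VI = 100 · (c_start − c_end) / c_start / divisions`,
  percent copy-number change per cell division. Positive VI means
  contraction; this sign convention makes destabilized strains score higher.
* qPCR copy number: target quantity normalized to a single-copy reference
  gene (ACT1), multiplied by a calibration factor anchored so that a
  reference sample returns its sequencing-determined copy number.
* Marker-loss frequency: `(resistant CFU × dilution) / (total CFU × dilution)`
  and its fold change over a control assay. Zero control frequency leaves the
  fold undefined (NaN, flagged).
* Bootstrap confidence intervals (seeded percentile, B = 1,000) are provided
  as a convenience; no hypothesis testing is included.

## Numerical and degenerate-input choices

* X defaults to 12: a 12-base exact run between unrelated sequences occurs
  with probability ≈ 4⁻¹² per position and phase, while nanopore-like errors
  (one per ~12 bases) still leave runs of that order at the matching phase.
* L defaults to m/20 (100 for a 2-kb unit): wide enough to bridge error
  dropouts, narrow relative to the unit period.
* alpha = 0.1, gap_tolerance = m, split_gap = m/4, band 0.5–1.5 of |B|/m,
  min_prominence = 8. All exposed as parameters.
* Ties in region selection go to the leftmost candidate; equal-scoring flank
  hits likewise. Orientation ties in `count_read` are broken by the larger
  (mass, count) pair, which is symmetric under reverse complement.
* Empty or all-zero profiles, reads shorter than the smoothing window, zero
  copy numbers, empty regions and missing cassettes all return flagged
  results rather than raising, except where an input violates a documented
  precondition (these raise `ValueError` with the offending value named).

## Problem sizes used in the test suite

The acceptance-style tests sweep copy numbers 1–30 with 20 noisy spanning
reads each (plus one error-free read per k), classify 200 mixed-length noisy
reads for spanning, and verify the profile oracle on 200 random instances.
These sizes give per-condition binomial resolution of one read in twenty at
the 95% thresholds while keeping the full suite around half a minute.

## Known limitations

* The uniform error model exercises the fallback count path, not the
  spectral path, on clean arrays (see above); the spectral path is exercised
  by synthetic periodic profiles.
* The dot-plot chainer assumes the read contains a single repeat family;
  two interleaved families would chain independently but the counts are
  reported per reference only.
* Copy numbers beyond ~30 work in principle but the length-ratio fallback
  accumulates edge bias of order 100 bases per region end; at 0.05 units per
  end this is negligible up to the tested range and grows slowly beyond it.
* `locate_insertion` reports the boundary in full-unit indices; a cassette
  inserted mid-unit (not at a unit boundary) is located but its boundary
  index refers to the nearest completed unit count.
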