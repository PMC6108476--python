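# Methods

This note documents the models, parameter choices and numerical conventions
behind `spongescan`, and what the synthetic benchmarks do and do not show.

## Coordinates and masking

All intervals are 0-based half-open on the forward strand; strand is a
separate attribute. GTF (1-based inclusive), wig fixedStep (1-based) and
VCF-style SNP positions are converted at file boundaries only. A genome
position counts as masked when the base is lowercase **or** N, so both
soft- and hard-masked genomes work; seeds may not overlap masked bases and
extension windows truncate at the first masked base, which reproduces the
behaviour of scanning a hard-masked genome.

## Duplex energy model

The scanner scores RNA–RNA duplexes with a simplified nearest-neighbour
model: a 36-entry stack table over the six admissible pairs
{A·U, U·A, C·G, G·C, G·U, U·G}, an affine penalty for interior
loops/bulges (`loop_open` + `loop_extend` per unpaired nucleotide, charged
once per gap regardless of which side the unpaired bases sit on), and an
optional duplex initiation penalty. Defaults ship in
`src/spongescan/data/stack_energies.tsv` (editable plain text):

- Watson–Crick steps carry the standard published Turner ΔG°₃₇ values
  (−0.93 … −3.42 kcal/mol).
- Wobble-containing steps carry Turner-style values in the published range,
  including the destabilizing 5'GU/3'UG (+1.29) and 5'UG/3'GU (+0.30)
  motifs. Reversal symmetry ΔG(P₁P₂) = ΔG(flip P₂, flip P₁) holds for the
  whole table.
- `loop_open` = 4.0 kcal/mol, `loop_extend` = 0.3 kcal/mol/nt,
  `init_penalty` = 0 (configurable; whether the original screen charged
  initiation is unknown, so the default is the neutral choice).

Dangling/terminal unpaired bases are free; the duplex is intermolecular
only (no multiloops). Predicted energies are therefore approximate
hybridization energies, adequate for ranking and for the −10 kcal/mol
site cutoff, not for thermodynamic precision.

## Seed matching and DP extension

Seed windows are the six-mers at query offsets 0–2 within the first eight
bases; matching is implemented by enumerating the admissible
target-complement 6-mers per offset (at most 2^6, since A and C admit one
target letter and G and U two) and intersecting with a rolling 2-bit k-mer
index of the sense strand. This is exhaustive, so it is equivalent to a
suffix-array search but trivial to verify.

Each match is extended on both sides by dynamic programming with the seed
pairs held fixed. The target window on each side spans the remaining query
length plus 5 nt (`window_pad`), truncated at masked bases and sequence
ends. The DP carries a match state and a gap state (the affine loop), so a
minimum-energy extension and its traceback cost O(n·m) per side; trailing
unpaired bases cost nothing, hence the returned duplex is never worse than
the seed alone. The reported seed site is the 7-mer opposite query
positions 2–8 laid out without gaps from the seed window (the seed window
pins its geometry; this is exact whenever positions 2–8 pair contiguously,
which holds for every planted and virtually every natural site).

Overlapping sites (same chromosome and strand, ≥ 1 shared bp) merge
transitively; the merged site keeps the span union and the energy, seed
site and paired fraction of its minimum-energy constituent (ties resolved
toward the leftmost seed).

## Dinucleotide-preserving shuffle

Each maximal unmasked segment is cut into non-overlapping 120-nt windows
anchored at the segment start; a shorter final remainder is shuffled as its
own window (length-1 remainders stay put). Dropping remainders instead
would shrink the searchable background and bias the real/shuffled volume
comparison. Windows are shuffled by the Euler-path construction on the
dinucleotide transition multigraph (random last-exit edges forming an
arborescence to the final base, remaining out-edges randomly ordered), so
the 16 dinucleotide counts — hence mononucleotide counts, GC and the first
and last base — are preserved exactly per window.

## Site graph and MCL

Edge weight sim(x) = C − x with C = 1000 nt, where x is the end-to-start
gap between two sites (0 when adjacent); gap distance rather than
midpoint distance keeps the weight independent of site length. Because
merged sites on one strand never overlap, connected components are exactly
the maximal chains with consecutive gaps < C, and each component is
clustered independently (block-diagonal exactness, and the genome-scale
memory win).

MCL runs with expansion 2, inflation 3.5 (default), pruning threshold
1e-5, convergence tolerance 1e-6 on the max entry change, and self-loops
set to each node's maximum incident edge weight (1 for isolated nodes) —
the standard stabilization for weighted graphs. Clusters are read from the
converged matrix as attractor systems; a node attracted by several systems
goes to the one with the largest flow (ties: lowest attractor index);
isolated nodes are singletons. The test suite checks exact agreement with
an independently coded dense reference implementation.

## Significance

Shuffled-genome clusters of size ≥ 2 enter the statistic (a lone site is
not a cluster; `min_cluster_size` is configurable). The ⌈0.10·N⌉ largest
clusters are selected with boundary ties included, their size histogram is
fitted by unweighted least squares of log₁₀ count on size, and the cutoff
is ⌈(log₁₀ p − b)/a⌉ with p = 0.001 — the size expected less than once in
1000 randomizations, extrapolated from a single shuffled genome because
thousands of full randomizations are impractical. The ceiling carries a
1e-9 guard so float noise in the fitted coefficients cannot bump an
exact-integer extrapolation to the next size. Fewer than two distinct
sizes among the selected clusters, or a non-negative slope, yields a
no-cutoff outcome: the miRNA is reported but makes no significance calls.
Per-miRNA p-values over all cluster sizes (cross-miRNA FDR) are out of
scope.

## Filters and characterization

- Conservation: a site is conserved when its 7-nt seed site contains ≥ 5
  consecutive positions with score strictly > 0.3; positions without data
  count as non-conserved. A cluster passes when its conserved fraction is
  ≥ 2× the miRNA's genome-wide fraction (inclusive comparison); a
  genome-wide fraction of 0 keeps everything rather than dividing by zero.
- Entropy: binding energies are binned at 2 decimals (kcal/mol) before
  counting distinct values; normalized Shannon entropy −Σ pᵢ log₂ pᵢ /
  log₂ n, defined 0 for n = 1; clusters pass at ≥ 0.6 (inclusive).
- Annotation: same-strand genes overlapping ≥ 50% of the smaller region
  qualify; ties break by source priority (primary gene set before circRNA
  records), then overlap length, then gene id. circRNA-database records
  are treated as single-exon spans.
- FBSE counts a site as exonic only when fully contained in one
  same-strand exon.
- SDR uses the union of member seed sites as the seed region and the gaps
  between consecutive seed sites within the cluster span as flanking;
  zero flanking length or zero flanking SNPs makes SDR undefined
  (serialized "NA").
- Shortlist: annotated candidates with ≥ 10 sites above their cutoff and
  FBSE strictly > 0.09, sorted by excess size.

## Synthetic benchmarks

The generator emulates the pipeline's study conditions without any
downloads: an i.i.d. background genome (GC 0.41, human-like) with
soft-masked geometric stretches (30% masked), planted arrays of
near-reverse-complements of a 22-nt query whose seed 7-mer is always
perfect (so recovery failures isolate clustering/statistics, not scanner
sensitivity), with 2 random substitutions elsewhere per site and
inter-site gaps of 2–40 nt — the site density of validated natural
sponges, e.g. ~76 sites in ~1.7 kb. Conservation, SNP (rate 1e-3 per
unmasked nt) and gene-model fixtures are constructed to exercise the
filters; exons cover a configurable fraction of planted sites so FBSE has
a known truth.

Presets: `recovery` (one 30-site sponge), `null` (background only),
`repeat_decoy` (30 identical copies — the entropy filter's target) on
600-kb genomes, and `parity` (5-Mb background for the real/shuffled
site-volume comparison). 600 kb is the smallest background that yields a
stable shuffled tail fit for the default query; the bundled quantities in
`scripts/acceptance.py` use 20 seeded runs per scenario.

What passing these benchmarks does **not** show: performance on real
genomes with repeat families, segmental duplications, Markovian base
composition or annotation errors; sensitivity of the scanner to imperfect
seeds; or the biological validity of any candidate. The i.i.d. background
is deliberately the simplest null — dinucleotide structure is exercised
separately by the shuffle tests.

## Known limitations

- The default stack table's wobble entries are Turner-style estimates;
  absolute site counts at the −10 kcal/mol cutoff shift with the energy
  parameters (the table is a plain-text file precisely so it can be
  replaced).
- MCL granularity is heuristic: on path-like site chains the largest
  cluster size is only approximately monotone in the inflation factor.
- Significance extrapolates from one shuffled genome; the empirical p is
  a calibration device, not an exact p-value.
- The scanner is pure Python/NumPy, comfortable at tens of Mb per miRNA;
  a whole-genome, all-miRNA screen would want the per-miRNA runs
  parallelized (results are independent per miRNA and canonically sorted,
  so any scheduling yields identical outputs).
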