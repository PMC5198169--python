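# Methods

## Degenerate k-mer signatures

A window of DNA is summarised by the frequencies of its *degenerate sets* of
k-mers: every k-mer is pooled with its reverse complement, because a genome
signature should not depend on which strand was assembled.  For k = 4 this
gives (4^4 + 4^2)/2 = 136 dimensions (16 tetranucleotides are their own
reverse complement and form singleton sets); dimensions are ordered by the
lexicographically smaller member of each pair, so vectors are comparable
across runs and exports are self-describing.  Counting is exact and
vectorised: bases are encoded A=0, C=1, G=2, T=3, N=4, every k-mer position
containing an N is discarded, and the remaining counts are divided by the
number of valid positions.  Normalising by valid k-mer positions (rather
than by the raw window length net of Ns) is the one reading of
"length without Ns" under which every non-omitted vector sums to exactly 1,
which the rest of the pipeline assumes.

N policy: a window whose N count exceeds `n_fraction_max` (default 0.10) of
its length is omitted; a window that passes this test but has no N-free
k-mer position at all is also omitted, with a distinct reason code, rather
than producing a zero vector.  Lower-case (soft-masked) input is upper-cased;
IUPAC ambiguity codes other than N are converted to N with a logged warning,
since public assemblies contain both.  All coordinates are 0-based half-open
internally; user-facing tables print 1-based inclusive coordinates.

Two windowing modes are used deliberately:

* **training** — non-overlapping fragments of exactly `window` bp (trailing
  residue dropped), so no part of a genome is double-weighted in the map;
  reference records contributing less than `min_reference_total` (default
  10 kb) are excluded, host contigs shorter than `min_contig` (default
  5,001 bp, i.e. strictly longer than 5 kb) likewise;
* **querying** — sliding windows of `window` bp every `step` bp (defaults
  5 kb / 1 kb), giving floor((L − window)/step) + 1 segments per contig.

## The batch-learning self-organising map

Weight vectors w_ij live on an I x J lattice.  Initialisation is not random:
the data mean and the first two principal axes b1, b2 (numpy SVD; each
axis's sign is fixed so its largest-magnitude loading is positive) define a
plane, and node (i, j) starts at

    mean + s·sigma1·(2i/(I−1) − 1)·b1 + s·sigma2·(2j/(J−1) − 1)·b2

with span s = 2.5 standard deviations per axis.  The lattice aspect follows
the data: J = max(1, round(I·sigma2/sigma1)).  When I is not given it is
chosen so that I·J ≈ `nodes_per_vector` x n_data with the same aspect
ratio; the default 0.35 nodes per training vector keeps roughly three
training fragments per node — enough occupancy to label territories while
still resolving sub-clusters.  Training runs T epochs (default 100); in
epoch r every data vector is assigned its best-matching unit (BMU, minimum
squared Euclidean distance, ties to the smallest i then j), and every node
moves toward the mean of the data whose BMUs lie within Chebyshev distance
beta(r):

    w_ij += alpha(r) · (mean − w_ij)
    alpha(r) = max(0.01, 0.6·(1 − r/T))
    beta(r)  = max(1, round(beta0·(1 − r/T))),   beta0 = max(I, J)/2

Nodes whose neighbourhood receives no data in an epoch are left unchanged.
These schedules are standard batch-SOM practice; they are configurable, and
nothing downstream depends on their exact values beyond cluster
separability.

Determinism is treated as a contract: there is no random state anywhere, and
before training the data rows are put into a canonical (lexicographic)
order, so floating-point accumulation order — and therefore the trained map,
bitwise — is identical for any permutation of the input.  Distances for the
BMU search use the expanded form ||x||² − 2x·w + ||w||² (constant dropped),
which is fast and reproducible run-to-run; quantization error (mean distance
of data to BMU weights) is reported as the convergence diagnostic.  Lattices
serialise to a self-describing text format that round-trips weights at full
precision (`%.17g`), so save → load → save is byte-identical.

## Territories and the hierarchical calls

After joint training on pooled host + reference fragments, each node is
tallied: how many host training fragments and how many reference fragments
of each phylum chose it as BMU.  The territory classes are exclusive —
*host* (host only), *prokaryote* (references only), *mixed* (both), *empty*
(neither) — and only pure prokaryote nodes ever produce candidates; this is
deliberately conservative.  A prokaryote node's phylum is its most abundant
reference phylum; ties leave the node unlabelled rather than picking
arbitrarily, and segments landing there count as candidates without a
phylum (they contribute to a contig's candidate total but to no taxon, the
"Unassigned" behaviour).

A contig with at least `min_candidates` (default 1) candidate segments is
reported; it is *assigned* to its top phylum only when that phylum's count
strictly exceeds `contig_threshold` (default 0.40) of the contig's candidate
segments.  The candidate-segment denominator (rather than all segments of
the contig) is the default because contigs carrying transfers from several
phyla then naturally fall into the Unassigned row; the denominator is
configurable to `total`.  Genus refinement re-maps each phylum-labelled
candidate on a per-phylum map trained only on that phylum's reference
fragments; node genus labels are majority-based with the same tie rule, and
reference fragments lacking a genus keep their coarser supplied rank label
as their class, so references resolved only to class or phylum level can
still dominate a node and be reported at that rank.  A contig's genus uses
the >threshold rule over its genus-labelled candidate segments of the
assigned phylum.

## The synthetic study

The generator draws genomes from order-0 or order-1 Markov chains.  The
default study emulates the structure of a real scan:

* **host** — 30 contigs x 50 kb from a symmetric (hence doubly stochastic:
  G+C exactly 0.50) order-1 chain with mild CpG-like depletion;
* **references** — 3 pseudo-phyla x 4 pseudo-genera, 1.96 Mb per genus
  (~23.5 Mb, ~4,700 training fragments — a collection that outweighs the
  host roughly 16:1, as a genome database outweighs one genome).  One
  phylum is AT-rich (genus G+C 0.29–0.41), one GC-rich (0.59–0.71), and one
  sits at G+C 0.50 exactly, differing from the host only in a strong AA/TT
  persistence (0.39–0.51) — separable by tetranucleotides but invisible to
  G+C content;
* **transfers** — 40 inserts of 5–10 kb, drawn from the genus models,
  *replacing* host sequence at uniform non-overlapping positions so contig
  coordinates stay stable and the truth table aligns with windows.

Everything derives from a single seed and regenerates bitwise-identically.
Order-1 chains are sampled by precomputing, for each position, the candidate
next state under every current state (vectorised searchsorted over the
cumulative transition rows), then following the chain through that table.

Scoring: a mapped segment is truth-covered when at least half its length
(configurable) overlaps planted intervals, summed across intervals; a
candidate is a true positive iff it is truth-covered.  Recall is TP over
truth-covered segments, precision TP over candidates (undefined with zero
candidates), and contig accuracy the fraction of insert-bearing contigs
whose assigned phylum equals the base-weighted majority donor.  An
insert-level detection rate (inserts touched by at least one candidate) is
reported alongside, because contigs — not windows — are the unit at which
composition-based scans are usually validated.

What the synthetic study does *not* emulate: compositional drift of ancient
transfers toward the host, repeats, assembly artifacts, sequencing error,
and contamination.  Passing here demonstrates the machinery — counting,
training, territory logic, the threshold rules — under idealised
composition contrast, not performance on real genomes.

## Known limitations

* **Self-shadowing bounds segment-level recall.**  The joint map must be
  trained on the host assembly as it is — including its transferred
  regions.  Host training fragments cut from those regions sit at donor
  compositions but carry the host label, so the nodes they reach are host
  or mixed and, under the conservative territory rule, excluded from
  candidacy.  Query windows over the same regions share sequence with those
  fragments (one in five full-coverage windows is byte-identical to one)
  and are drawn to exactly those nodes.  Boundary windows that are 50–99%
  donor behave similarly: their mixture compositions coincide with the
  host-labelled partial fragments and with empty interpolation bands
  between clusters.  On the default study this caps segment-level recall
  near 0.46 at perfect precision, while probes of *fresh* donor sequence
  (never in training) reach prokaryote territory at 85–90% and insert-level
  detection is 38/40.  Detection at the contig level is therefore the
  robust read-out; per-window recall understates the method by
  construction.
* Node-level ties (phylum or genus) discard the label rather than guessing;
  with few references per node this inflates the Unassigned rows.
* Candidacy has no statistical calibration — no null model or FDR; the
  territory rule is purely combinatorial.
* One k per run; amino-acid and RNA alphabets are out of scope.
* Batch-SOM quantization error is not guaranteed monotone; the test suite
  checks the observed decrease on seeded runs, not a theorem.
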