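# Methods

`coevomap` detects coevolving residue pairs in a protein family from a
multiple sequence alignment (MSA), summarizes each residue's participation in
the coevolution network, and — when a structure is available — relates that
signal to spatial proximity. This note records the model, the defaults and
the numerical choices, and what the synthetic benchmarks do and do not show.

## Input processing

Alignments are read in FASTA, ClustalW, Phylip, Nexus or PIR format.
Residues are uppercased, `.` is normalized to the gap character `-`, and any
non-standard code (B, Z, J, U, O, `*`, ...) is mapped to `X`; `X` is treated
like a gap wherever frequencies are counted. One row is the *reference
sequence* (the first row unless an identifier is given); all reported
positions are 1-based indices into the ungapped reference, or the PDB author
numbering once a structure is mapped.

Columns are masked before analysis: a column is kept iff its gap fraction is
at most `max_gap_fraction` (default **0.5**) *and* the reference row carries
a residue there. Reference-gap columns are always dropped because every
downstream report (tables, circos, networks) is indexed by reference
positions. The 0.5 default is this package's documented choice; it is a
plain dial (`--gap-threshold`) with no claimed optimality.

## Sequence weights

Redundancy is corrected by single-linkage clustering at fractional identity
≥ `identity_threshold` (default **0.62**, `--identity`). Identity between two
rows is the fraction of identical residues over positions where neither row
is gapped (0 if there is no such position). Each sequence gets weight
1/(cluster size), so each cluster — not each sequence — contributes one
effective observation. Single linkage (the transitive closure of the
similarity relation, computed as connected components of the thresholded
identity graph) was chosen over greedy Hobohm-style reduction because it is
invariant to the order of sequences in the input file, which makes the
weights a pure function of the set of sequences.

## Mutual information

For a kept column pair (i, j), the joint amino-acid frequency table counts
each sequence's weight into its (a, b) cell, skipping sequences gapped or
unknown at either column; a pseudocount λ (default **0.05**, `--pseudocount`)
is added to every one of the 400 cells before normalization (the low-count
correction). Pairs to which fewer than two sequences contribute are treated
as missing, not zero. The raw score is

    MI(i,j) = Σ_{a,b} p_ij(a,b) ln[ p_ij(a,b) / (p_i(a) p_j(b)) ]

in **nats** (natural log; z-scores are invariant to the base, so only the
raw/APC magnitudes depend on this choice). The average product correction
(APC) subtracts `mean_i · mean_j / mean_all` from each entry, where `mean_i`
is the mean of row i over defined off-diagonal entries and `mean_all` the
mean over all defined off-diagonal entries; this removes the shared
background produced by phylogeny and column entropy. Missing entries are
excluded from every mean and stay missing.

Because λ is an absolute count, MI is exactly invariant to rescaling all
sequence weights only at λ = 0; at λ > 0 a fully conserved pair has a small
positive MI that decays as the alignment deepens. The permutation null (next
section) absorbs this bias — the same pseudocount distortion appears in the
null replicates — which is why significance is assessed on z-scores rather
than raw MI.

## Permutation z-scores

The null ensemble shuffles the residues (gaps included) *within every kept
column independently*, destroying inter-column correlation while preserving
each column's composition and the per-sequence weights, and recomputes the
full APC-corrected MI matrix per replicate (default **100** replicates,
`--permutations`; the benchmarks below use 25). Each pair is standardized by
its own null mean and standard deviation (ddof = 1):

    z(i,j) = (APC_obs(i,j) − mean_null(i,j)) / sd_null(i,j)

The per-pair null is the default because conserved, low-entropy columns have
intrinsically smaller null scales than diverse columns; a pooled null (one
mean/SD across all pairs and replicates) is available via `--null pooled`.
Pairs whose null SD is zero (e.g. an invariant column, which is unchanged by
any permutation) get z = 0 and are flagged degenerate rather than dropped.
The generator is `numpy.random.default_rng(seed)`; the whole pipeline is
bitwise reproducible for a fixed seed (default **42**).

## Conservation and logo data

Per-column conservation is the Kullback–Leibler divergence of the weighted,
pseudocounted column distribution from a background distribution, in nats.
The default background is the BLOSUM62 marginal amino-acid frequency set
(`--background uniform` switches to 1/20 each); the background choice shifts
absolute KL values but not their ranking. A fully conserved column scores
ln 20 ≈ 3.0 under the uniform background (λ = 0). Logo data decompose each
selected column's KL into signed per-amino-acid terms p_c(a)·ln(p_c(a)/q(a))
— positive for enrichment, negative for depletion — and carry the raw
frequencies alongside for single-position inspection.

## Structure mapping and distances

PDB files are parsed with gemmi; the first model and one chain are used.
Altloc conformers collapse to the highest-occupancy atom per atom name;
insertion codes are preserved in the reported author numbering. Inter-residue
distance is the minimum over all non-hydrogen atom pairs (hydrogens are kept
in storage but never contribute; detection uses the element field). The
distance network connects residues strictly closer than `--distance-cutoff`
(default **5 Å**). Secondary-structure labels come from HELIX/SHEET header
records when present, else every residue is coil; no DSSP-style assignment
is attempted.

The ungapped reference sequence is aligned to the chain sequence with
Smith–Waterman local alignment (BLOSUM62, gap open 10, extend 0.5 —
conventional protein local-alignment defaults, all configurable). Matched
positions define a one-to-one, order-preserving map; coverage below 30% of
the reference logs a warning, zero aligned pairs is an error.

## The coevolution network

Edges are exactly the pairs with z **strictly greater than 6.5** (the
method's operating point, `--z-threshold`); all kept positions remain as
nodes so isolated residues still carry conservation. Per node,

* **cMI** = sum of z over incident retained edges (0 when isolated) — how
  much the residue participates in the coevolution network;
* **pMI** = mean cMI over *mapped* residues at distance ≤ 5 Å (the residue
  itself excluded; `include_self` flips that) — how concentrated the signal
  is around the residue in space. Unmapped positions, or positions with no
  neighbor inside the radius, have pMI missing. Note the deliberate
  asymmetry: `<` for distance-network edges, `≤` for the pMI neighborhood.

Edges are banded by linear-interpolation percentiles of the retained-edge z
values: ≥ 95th percentile → `top5`, ≥ 70th → `mid70_95`, else `low`; ties
promote upward, so an all-equal edge set is entirely `top5`. Filters accept
closed ranges on node attributes (kl, cMI, pMI) and edge attributes (z,
spatial distance, sequence separation on reference numbering), plus a top-N
selection that keeps the N highest-z edges and their endpoints. Contradictory
ranges yield an empty sub-network, not an error.

## Figures and bundle

The circular summary draws, outside in: residue labels (amino acid +
reference or PDB number), conservation boxes on a red→cyan scale (red =
most conserved), the cMI histogram facing outward, the pMI histogram facing
inward, and center chords for retained edges colored red/black/gray by band.
Histograms are scaled per track to their own maximum. SVG elements carry
stable `id` attributes (one per label, box, bar and chord), so figure
content is machine-checkable; `svg.hashsalt` is pinned so the SVG is
deterministic. Network images use a seeded force-directed layout.

A run writes the processed MSA, the weights table, the z-score edge table,
node/conservation/logo tables, SIF + attribute files loadable in Cytoscape,
the circos SVG/PNG, network images, and a JSON manifest (parameters, seed,
versions, stage timings, present/absent artifacts), all zipped into a bundle.
Tables are written with a fixed float format, so fixed-seed reruns are
byte-identical.

## Synthetic benchmark

The generator draws independent columns from the background and plants
covarying pairs under a two-state coupled model: with probability equal to
the coupling, a sequence carries state (A,D) or (C,E) chosen uniformly;
otherwise the two columns are drawn independently with the same marginals.
At coupling 1 the pair's MI is exactly ln 2, giving an analytic target.
Optional conserved columns fix a dominant residue at a chosen frequency;
gaps are injected uniformly at random.

The benchmark conditions are 200 sequences × 30 columns, one coupling-1
pair, 25 permutation replicates; over 100 seeds the planted pair is the
top-z pair with z > 6.5 in ≥ 95% of runs, and with no planted pair fewer
than 1% of pairs exceed the threshold. The end-to-end check uses 200 × 50
with two planted pairs and a 50-residue ideal α-helix (CA-only) toy
structure. These sizes keep the full suite under a minute of compute while
still exercising every stage at realistic depth.

What the generator does **not** model: phylogenetic relatedness (sequences
are i.i.d., so the APC and weighting machinery is exercised but not stressed
by tree-structured redundancy), structured gap blocks, multi-state or
chained couplings, and real side-chain geometry (toy structures are CA-only).
Passing these benchmarks therefore demonstrates correctness of the
computation and calibration of the null on exchangeable data, not detection
power on strongly phylogenetically structured families.

## Numerical notes

* All pair counting is vectorized: a one-hot expansion of the encoded
  alignment gives all 20×20 joint tables for all column pairs in one matrix
  product, with row-blocking to bound memory; a brute-force double-loop
  implementation is kept in the test suite as the oracle.
* Degenerate/missing values propagate as NaN through APC and z and are
  excluded from means; they surface as `NA` in tables.
* Percentiles use numpy's linear interpolation; band assignment uses `>=`
  against both cut points.
* Weighted MI ≥ 0 holds analytically; tests allow 1e-12 slack for floating
  point.
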