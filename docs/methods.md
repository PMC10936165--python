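# Methods

This note documents the models, algorithms, defaults, and numerical
choices behind the package, and what the synthetic study does and does
not establish about real genomes.

## Problem setting

Top-down genome streamlining removes dispensable DNA from an existing
chromosome to cut replication/expression burden.  The design question is
*which* contiguous stretches can go.  Three constraint sources are
combined: (i) essentiality labels transferred from a well-characterized
relative, (ii) a constraint-based metabolic model that predicts growth
after gene loss, and (iii) the biology of the deletion tool —
CRISPR-Cas3 erodes the chromosome bidirectionally from a single cut and
stops only at genes whose loss kills the cell, so flanking essential
genes define the reachable deletion window.

## Essentiality transfer

Orthology is inferred by reciprocal best hit (RBH).  Alignment is
Smith–Waterman local with affine gaps: a gap of length k costs
`gap_open + k·gap_extend` (defaults 11/1), scored with BLOSUM62.
Biopython's `PairwiseAligner` supplies the dynamic program; the test
suite validates it against an independently written Gotoh DP on short
random pairs.  Significance uses the ungapped-form Karlin–Altschul
expectation E = K·m·n·e^(−λS) with the standard gapped-BLOSUM62
constants λ = 0.267, K = 0.041; no finite-size length correction is
applied, since the pipeline's decision variable is a very stringent
cutoff (E ≤ 1e−10 by default) rather than a calibrated p-value.  Ties in
best-hit selection break by higher score, then lexicographic subject id,
making the map deterministic.

Transferred labels: RBH partner essential → *essential*; partner present
but non-essential → *dispensable*; no partner → *unknown*.  Unknown loci
are deletable by default — transfers of this kind only protect mapped
essentials, and the transfer itself is fallible — with a
`protect_unknown` flag and an `always_protect` locus list (e.g. for
rRNA/tRNA genes outside a protein-level transfer's reach) to tighten the
policy explicitly.  An adapter accepts an external tabular hit file
(outfmt-6-like TSV) so real-genome runs can use a production search
engine instead of the built-in aligner.

## FBA and gene knockouts

Flux balance analysis maximizes the biomass objective v_bio subject to
S·v = 0 and bounds, solved with HiGHS via `scipy.optimize.linprog`
(single-threaded, deterministic).  Tolerances: LP feasibility 1e−9;
mass-balance and reporting comparisons 1e−6.  Gene deletions act through
GPR booleans (AND = complex subunits, OR = isozymes; empty rule =
constitutively active): inactive reactions get bounds [0, 0].  The
uptake basis (default 10 mmol/gDW·h on the carbon exchange) is applied
to whichever bound limits import.  cobrapy/GLPK is used in tests as an
independent oracle, never as the implementation.

"Growth fixed at the maximum" is implemented as μ ≥ (1−ε)·μ_max with
ε = 1e−6 by default: strict LP equality is numerically brittle, and the
criterion is qualitative.

## Region search

A window of consecutive genes is deletable iff it contains no protected
locus (checked first, without FBA) and the knockout model retains
μ ≥ (1−ε)·μ_max.  The longest deletable window is found, excluded, and
the search repeated; ranks follow discovery order.  Window length for
optimization is the genomic span (end of last gene − start of first
gene), so enclosed intergenic DNA counts, matching deletion of regions
rather than gene sets.  Reports also carry the start-site-to-start-site
convention used by published dispensable-region tables, in both variants:
strand-aware (the translational start of a minus-strand gene is its
high coordinate) and naive leftmost, because the published convention's
strand handling is not stated.

Two engines, one contract:

* **scan** — exact two-pointer sweep over each run of unprotected genes.
  Correct because knockout feasibility is monotone: deleting more genes
  never increases μ, so any superwindow of an infeasible window is
  infeasible, and per-start maximal windows can be grown incrementally
  with O(run length) FBA solves (cached by deleted-gene set).
* **milp** — per-gene binary deletion variables; contiguity via start
  indicators (at most one 0→1 transition); the GPR network linearized
  node-wise with upper-bound constraints (sufficient because leaves are
  binary and the objective pushes activity up); the flux polytope and
  the growth floor embedded as constraints; objective = gene lengths
  plus pairwise-linearized intergenic gaps, i.e. the exact span.  A
  second lexicographic solve (minimize window start, then gene count)
  reproduces the scan engine's tie rule, so both engines return
  identical regions; this equivalence is a release-blocking test.

Ties go to the leftmost window, then fewest genes — determinism over
biology, since equal-span alternatives are equally good designs.
Iteration is non-cumulative by default (each region is evaluated against
the intact model; found regions are mutually excluded); `cumulative=True`
re-applies prior deletions and re-fixes μ_max before each further search.
A brute-force oracle enumerates every window (guarded to ≤ 300 genes)
with the same feasibility test and tie rule.

Circularity is ignored: coordinates live on a linear line and windows
never wrap the origin, which is adequate for internal chromosome regions
and avoids untested wrap-around arithmetic.

## Cas3 planning and tiling PCR

The permitted deletion window around a protospacer runs from the end of
the nearest protected gene on the left to the start of the nearest on
the right (genome edges otherwise); targeting inside a protected gene is
an error.  Simulated libraries draw left/right extents independently,
truncated to the window: **uniform** by default, **geometric(p)**
(processivity decay, mean extent ≈ 1/p) as an option.  No mechanistic
endpoint distribution is claimed — this is a design tool, and empirical
deletion-length spectra are strain- and locus-specific; the endpoint
model is a hook, not a calibrated fit.  Escaper colonies (no deletion)
occur with configurable probability and are represented as zero-length
events at the protospacer.

Tiling PCR is modeled positionally: a band appears iff both primer
binding intervals are disjoint from the deletion and the post-deletion
product (expected amplicon minus deleted overlap) is ≤ `max_amplicon`
(default 20 kb — long-range PCR across a large wild-type span fails, but
succeeds once a deletion shortens the template).  Inference inverts a
band pattern: present bands certify their primers intact; absent bands
with an amplifiable wild-type product implicate their uncertified
primers.  The *outer* interval is the gap between the nearest certified
primers flanking the evidence; the *inner* interval is what every
consistent single deletion must cover — the span between the leftmost
implicated band's rightmost candidate primer and the rightmost
implicated band's leftmost candidate.  With a single implicated band the
inner interval is empty: one absent band proves only that *some* part of
one primer site is gone, and a sound lower bound cannot name any
specific deleted base pair.  Patterns no single deletion explains (an
absent band whose primers are both certified, or a certified primer
inside the inner interval) are flagged contradictory rather than
silently reconciled.

## Synthetic study fixtures

The generators produce: an ordered annotation whose CDSs are random
proteins back-translated (NCBI table 11) into the genome sequence, so
GFF3+FASTA extraction is exact; a reference proteome obtained by i.i.d.
residue substitution at `mutation_rate` with a known ortholog bijection;
and a toy metabolic model wired so the truth's essential genes are
growth-essential (AND-grouped module reactions feeding mandatory biomass
components) while non-essential genes sit only in reactions redundant
with a constitutive backbone or in dead-end side reactions.  Biomass
consumes 10 carbon equivalents per unit growth, so μ_max = uptake/10 and
scales linearly with the bound — convenient closed forms for testing.

Defaults (chosen once as desk-scale-realistic, not fitted): 120 genes,
mean CDS 300 bp (~100-residue proteins), 50 bp intergenic spacing,
essential fraction 0.3, mutation rate 0.05, background non-essential
runs capped at 3 genes.  The cap plus forced essential flanks makes
planted regions the unambiguous maximal dispensable stretches, mirroring
the empirical observation that Cas3 deletions stop at flanking essential
genes.  One RNG stream per generator, derived from the spec seed by a
fixed offset, so adding a generator never perturbs the others.

What passing tests show — and don't.  The synthetic genome has no
realistic codon usage, GC content, operon structure, or metabolic
network topology; essential-gene spacing is a modeling choice, not a
calibrated distribution; and the toy models make non-essential deletions
exactly growth-neutral, which real models only approximate.  The tests
therefore establish the *correctness of the machinery* (transfer logic,
optimization, inference) with planted ground truth, not the biological
accuracy of any particular prediction.  Real-genome runs must supply the
organism's published annotation, essentiality list, and genome-scale
model.

## Problem sizes used in validation

Oracle-equivalence checks run 20 random instances of 50–300 genes with
toy models of 10–40 reactions; end-to-end recovery uses 10 seeds of
60-gene genomes at 5% proteome divergence; monotonicity is sampled on
100 nested knockout pairs; Cas3 round trips screen 200 simulated
colonies with a 2 kb panel.  These sizes give fully exhaustive oracles
and tight closed forms while keeping the whole validation suite fast
enough to run on every change.

## Known limitations

* Multi-contig genomes are handled only one replicon at a time.
* SBML support is read-only (Level 3 + FBC bounds/GPR); the canonical
  on-disk model format is the package's JSON dialect.
* The built-in aligner is exact but unindexed; for full proteome pairs
  beyond a few hundred sequences, import an external hit table instead.
* PAM/gRNA sequence design is out of scope; a protospacer is a
  coordinate.
* No FVA, parsimonious FBA, thermodynamic constraints, or explicit
  light/photon modeling beyond a generic exchange bound.
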