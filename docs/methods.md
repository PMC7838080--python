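# Methods

## Family gate

BAHD acyltransferases carry two conserved motifs: the catalytic **HXXXD**
(the histidine deprotonates the acceptor nucleophile; it sits near the middle
of the chain at the N/C-domain interface) and the structural **DFGWG** near
the C terminus. The gate accepts a sequence iff

- an HXXXD hit (exact H and D anchors, any three middle residues) starts
  within the central window, by default between 25% and 60% of the sequence
  length — the catalytic histidines of the two bundled references sit at
  34% (His155/451) and 37% (His169/451) of their chains — and
- a DFGWG hit starts in the C-terminal portion (default: at or beyond 2/3 of
  the length). One mismatch is tolerated by default because the motif degrades
  in distant family members; `X` never satisfies a motif position.

Both windows and the mismatch budget are configurable. Redundancy collapse
defaults to exact-duplicate removal (threshold 1.0, string equality); below
1.0 a greedy rule in input order is used (a record joins the first earlier
representative at or above the identity threshold). Greedy collapse is
order-dependent; that is inherent to the rule and documented rather than
hidden behind a canonical sort.

## Pairwise alignment and E-values

Optimal affine-gap alignment (global and local) is computed with BLOSUM62 and
BLAST-convention gap costs `gap_open + g·gap_extend` (defaults 11/1); the
dynamic programming is delegated to Biopython's `PairwiseAligner`, and the
optimal scores are verified against independent brute-force dynamic programs
in the test suite. Local raw scores S are converted with the standard gapped
BLOSUM62 Karlin–Altschul parameters λ = 0.267, K = 0.041:

    bit = (λ·S − ln K) / ln 2,   E = m·n·2^(−bit)

with m, n the sequence lengths. This replaces a heuristic search tool: scores
are exact (no word-hit heuristics, no composition-based adjustment, no
low-complexity masking), so E-values are comparable to, but not identical
with, BLAST's. The usual cutoffs (1e-25 for family gathering, 10^-51.5 for
cluster visualization) are used unchanged.

**Identity convention.** Percent identity = identical aligned pairs divided
by global-alignment columns after trimming terminal-overhang columns (columns
inside an end-gap run). This one definition feeds redundancy collapse,
distance matrices, chain pairing and template selection. Traceback
tie-breaking among co-optimal alignments is the library's; it is
deterministic, and both argument orders are canonicalized to the same
internal orientation so identity is exactly symmetric, but a different
optimal-path convention could shift identity slightly on ties (scores are
unaffected).

## Sequence similarity network

Nodes are sequences (optionally representatives carrying collapsed members);
an undirected edge connects pairs with local E-value ≤ the cutoff; a cluster
is a connected component, numbered by descending size then smallest member
id so downstream outputs are stable. Queries are assigned by their passing
edges; the report carries the characterized labels present in the joined
cluster and the best-E-value characterized neighbor. Singletons are retained
everywhere — "unclustered" is itself evidence. `threshold_sweep` tabulates
edge/cluster counts across cutoffs; because loosening a cutoff only adds
edges, clusters at a stricter cutoff always nest inside clusters at a looser
one (property-tested).

## Phylogeny

Distances are p-distances (1 − identity) by default — the common protein
default — with an optional Poisson correction −ln(identity), capped at 10
substitutions/site when identity approaches 0. Tree inference is Saitou–Nei
neighbor joining with the standard Q-criterion; ties in Q break on the
smallest (i, j) index pair; branch lengths use the two-point formulas, and a
negative length is clamped to zero (with a warning and the pre-clamp value
kept on the node), mirroring common NJ tool behaviour. On additive matrices
NJ recovers topology and branch lengths exactly; the suite verifies this on
randomized additive matrices and against an independent NJ implementation.
Newick output prints branch lengths to six decimals and single-quotes labels
containing metacharacters.

## Structures and pockets

PDB files are parsed with gemmi; alternate locations resolve to the
highest-occupancy copy (ties: altloc `A`, then blank); non-water HETATM
residues are kept aside keyed by residue name, waters tagged separately.
Superposition is the closed-form Kabsch SVD solution with the reflection
branch excluded; inputs whose covariance is rank-deficient (collinear point
sets) are rejected rather than silently resolved. `ca_rmsd_by_alignment`
pairs chains greedily by best global sequence identity, pairs CA atoms at
non-gap aligned columns, and computes one superposition over all pairs — all
aligned CAs, no outlier trimming, so values are comparable across inputs but
may differ from tools that trim.

Pocket extraction around a bound ligand uses a heavy-atom contact radius of
4.5 Å (a conventional contact definition); explicit residue lists — such as
the bundled published pocket tables — are taken verbatim and are never
overridden by geometry. The charge model is formal charge at neutral pH:
D, E → −1; K, R → +1; H → +0.1 (fractional protonation); others 0; waters
never contribute. A pocket is **acidic** at net ≤ −1 and **basic** at net ≥
+1. This threshold is a declared operationalization of the qualitative
surface-electrostatics contrast between amine- and shikimate-accepting
enzymes; Poisson–Boltzmann electrostatics is out of scope. Template pockets
map onto queries through the global alignment (positions falling in query
gaps are reported unresolved, not guessed); mapping is refused below 20%
identity, where alignment-transferred positions are unreliable.

## Predictor

The verdict vocabulary is binary plus "indeterminate", matching the
amine-vs-shikimate pocket contrast. Decision rule:

- a class verdict always requires pocket support: acidic → polyamine/amine,
  basic → shikimate-type; a neutral or unmappable pocket cannot support a
  class;
- in the default two-evidence mode the cluster evidence must agree; a
  conflict (cluster labels vs pocket class, or mixed labels) forces
  "indeterminate" with both lines in the notes;
- pocket-only mode yields the pocket class with an explicit
  reduced-confidence note; cluster-only mode never yields a class verdict
  (the cluster lean goes in the notes), so removing pocket evidence can only
  move verdicts toward indeterminate, never flip them;
- sequences failing the motif gate are reported as such and not scored
  (an override flag exists and is recorded in the notes);
- no passing network edge and no usable template → "insufficient homology".

Donor preference (caffeoyl vs feruloyl vs sinapoyl CoA) and acylation degree
are deliberately not predicted: there is no computable rule for them in this
framework.

## Synthetic data

The generator emulates a protein superfamily as star-shaped families:
independent uniform-random seed sequences of length 450 (the real enzymes
are ~450 aa) with HXXXD planted at 35% and DFGWG at 85% of the length, each
family evolved by i.i.d. per-site substitution (default rate 0.1, giving
~90% identity to the seed and ~81% within-family — comfortably inside one
family's divergence range) with motif anchors protected, optional
geometric-length indels outside motif spans, and optional pocket scaffolds
whose charged sites are protected and can be charge-shifted by an exact
integer delta (acidic↔basic swaps move 2 units, charged↔neutral 1; His sites
are excluded from the arithmetic). Toy structures are ideal α-helix CA
traces (rise 1.5 Å, radius 2.3 Å, 100°/residue) with optional Gaussian noise
and random rigid transforms.

What the generator does **not** emulate: matrix-weighted substitution
processes, among-site rate variation, tree-like within-family structure,
domain architecture, or realistic 3D folds. Passing tests therefore
demonstrate algorithmic correctness and the pipeline's behaviour under
controlled divergence — not performance on real proteomes, where family
boundaries are fuzzier and pocket conservation weaker.

## Problem sizes and numerical choices

The test and acceptance runs use: 500/300 random short pairs for the
alignment oracles (lengths ≤ 8, 4-letter alphabet, where exhaustive dynamic
programs are exact); 100/50 random graphs of ≤ 50 nodes for the component
oracle; 100 additive matrices of 4–8 taxa for NJ recovery (equality at
1e-9); 50 rigid-copy and 10 noisy-pair superpositions (rigid RMSD < 1e-6 Å,
optimizer agreement < 1e-4 Å); and 10 two-class replicates of 6+6 members at
substitution rate 0.15 for the end-to-end prediction check (ARI and accuracy
both expected perfect — the planted classes are unambiguous by design).
These sizes make the full suite run in seconds while exercising every code
path; all randomness is seeded.

## Known limitations

- E-values use fixed Karlin–Altschul constants for BLOSUM62 11/1; other
  matrices/penalties would need their own λ, K.
- Database-scale quantities (non-redundant family counts, cluster node
  counts from public-database sweeps) depend on database versions and are
  not reproduced.
- The pocket classifier is a formal-charge count, not an electrostatic
  potential; borderline pockets (net charge in (−1, +1)) are deliberately
  indeterminate.
- Greedy sub-1.0 redundancy collapse depends on input order.
- Comparisons against the published identity/RMSD values of the real enzymes
  require user-supplied accession data (sequences and PDB files are not
  redistributed).
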