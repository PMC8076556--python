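# Methods

This note documents the models, conventions, parameters and design choices
behind `tcrmotif`, in the order the pipeline runs.

## CDR3 convention

All `cdr3_aa` / `cdr3_nt` fields hold IMGT positions 105–117: the junction
*minus* the conserved C104 and F/W118 anchors.  Inputs carrying full
junctions are converted on read with `Dialect(junction_is_full=True)`, which
strips one residue / three nucleotides from each end.  V and J calls are
reduced to gene level everywhere: amplicon reads of this design are too short
for allele assignment, so allele suffixes (`*01`) are dropped, and the IMGT
subgroup is the gene name before the `-` (TRBV7-2 → TRBV7).  Ambiguous V
calls (several comma-separated genes) are flagged and represented by the
top-ranked call for motif/coherence checks; they are excluded from V-usage
counting altogether.

## Ingestion filters

* **Read support** (`min_reads = 50`): chains below the threshold are
  discarded.  The value mirrors the quality floor of plate-based single-cell
  TCR amplicon sequencing, where sub-50-read chains are dominated by index
  hopping and PCR chimeras.
* **Dual chains** (`dual_min_fraction = 0.10`): within a cell and locus,
  chains are ranked by read support; a second chain survives only with
  ≥ 50 reads *and* ≥ 10% of the top chain's reads.  The source protocol
  accepted duals "based on read support proportions" without publishing the
  proportion; 10% is our default and is configurable.
* **Valid cells**: 1–2 α and 1–2 β chains, ≤ 3 chains total, counted over
  productive accepted chains (the cap is configurable via
  `call_valid_cells(max_total_chains=...)`).  Unproductive chains are read
  and flagged but excluded from everything downstream.
* **Clonotypes** are patient-scoped, keyed on the defining β chain's
  (V gene, J gene, CDR3 nt).  The defining β of a dual-β cell is its
  highest-read β — the mapping is not specified by the source protocol and
  dual β is rare (~0.2%), so the choice is inert in practice.  The
  representative α is the α identity present in the most member cells, ties
  broken by total read support, then lexicographically smallest CDR3 nt; a
  second α is retained when it co-occurs with the first in at least one cell.

## Trimming and the clustering set

`trim_cdr3` removes the first two and last CDR3 residues (IMGT 105, 106,
117), which structural surveys of TCR–peptide–MHC complexes show rarely
contact antigen.  Clonotypes whose trimmed CDR3 is shorter than
`min_trimmed_len = 8` are excluded; in paired mode a clonotype is excluded
when *either* chain fails (configurable design choice — the alternative,
β-only filtering, keeps a handful of extra clonotypes with very short α).
Dual-α clonotypes contribute one α, drawn uniformly under the run seed; the
draw is recorded so V-coherence in motif discovery is judged on the chain
that was actually clustered.

## Distances and UPGMA

Distances are unit-cost Levenshtein edit distances (computed with edlib, a
C implementation of bit-parallel edit distance; an independent DP oracle
checks it in the tests).  Paired receptors use the sum of the α and β
distances, which preserves the metric property.

UPGMA is implemented in-package rather than delegated to
`scipy.cluster.hierarchy` because we require a *documented deterministic
tie-break*: leaves are numbered 0..n−1 in input order, internal nodes n,
n+1, … in merge order, and among equally distant cluster pairs the
lexicographically smallest (min id, max id) pair merges first.  Inter-cluster
distances are maintained as exact sums divided by the pair count on access;
for integer Levenshtein inputs equal averages then compare exactly equal
(IEEE division of exact integers is correctly rounded), so tie detection is
well-defined and runs are bit-reproducible.  scipy's average linkage serves
as an independent cross-check on tie-free random matrices in the tests, and
a from-definition rational-arithmetic agglomerator is the acceptance oracle.
Memory is O(n²); n ≈ 3000 uses a few hundred MB and ~10 s per tree.

`cut_tree(h)` returns the maximal subtrees with node height ≤ h (so the
partitions at increasing h are nested).  A node "below" the cutoff means
height ≤ cutoff (the strict-vs-weak reading is not specified upstream; we
use ≤ and document it).

## Motif discovery

The dendrogram is walked root-to-leaves.  A node qualifies when height ≤
cutoff, it has ≥ `min_leaves = 5` leaf clonotypes, and all leaves use one V
gene (`v_mode="gene"`) or one IMGT V subgroup (`"subgroup"`); for paired
trees both chains must each be coherent.  Qualifying nodes are emitted and
not descended into, so candidates are leaf-disjoint.

Members' **full** (untrimmed) CDR3s are aligned progressively in subtree leaf
order: each sequence is aligned to the running profile by Needleman–Wunsch
with score = fraction of profile rows matching the residue, mismatch 0, gap
−1, with a deterministic move preference (match/mismatch, then gap-in-new-row,
then new gap column).  Candidate members are near-identical by construction
(they merged below a small edit-distance cutoff), so this simple aligner
recovers the alignment a general protein aligner would; it is pluggable.

The regex builder maps each alignment column to a token: a literal when all
residues agree; the full character class of an amino-acid group when the
residues fall inside one group — charged `[KRED]`, polar `[QNHSTYC]`,
amphipathic `[WYM]`, hydrophobic `[AILMFVPG]` (Y, M and W belong to more
than one group; when a column fits several groups we pick by the fixed
priority charged > polar > amphipathic > hydrophobic); the wildcard `.` when
several groups are represented; and the token is suffixed `?` when the
column contains a gap.  Patterns are matched **anchored** (`re.fullmatch`)
against full CDR3s.  A match additionally requires the identical V gene (or
subgroup, matching the discovery mode); paired motifs must match both
chains; either chain of a dual-chain clonotype may satisfy its side.
Recorded J genes are *not* enforced by default (`enforce_j` switches this
on), because motif matching is defined by regex + V gene.

Candidates re-discovering established celiac motifs (the R-motif family and
the NDYKLS α motif, shipped as packaged data) are removed when ≥ 50% of
their members match an established motif; the threshold is configurable and
removals are logged with the overlap fraction.

## Repertoire statistics

* **V-gene usage**: dual chains contribute 0.5 per alternative gene or gene
  pair; ambiguous-V chains are excluded; frequencies are normalized over the
  included mass.  Report tables collapse genes seen in < 2 clonotypes into
  "other" (display only; mass is preserved).
* **Public sequences**: chain (or chain-pair) identities observed in ≥ 2
  patients.  The default identity key is (V gene, J gene, CDR3 aa) per chain
  — consistent with the clonotype definition and with motif-matching
  semantics; `key_fields="aa"` gives the CDR3-only alternative and
  `"vj_nt"` the nucleotide-level key.  Every accepted chain is keyed (both
  α of a dual-α clonotype); within-patient repeats count once toward the
  patient set.  Patients with very few clonotypes stay in the analysis —
  they simply tend to produce no public hits.
* **Shared fraction**: per patient, the fraction of clonotypes whose α or β
  identity is public; the cross-patient median is the headline number.
* **Epitope annotation**: a motif inherits the epitopes of reference clones
  (in-vitro T-cell clones of known specificity) that match it; a public
  paired record is annotated `clone_exact` on identity with a reference
  clone and `clone_similar` when V genes agree and the total CDR3
  Levenshtein distance summed over both chains is ≤ 1 (the "one amino-acid
  difference" rule; the budget is configurable).  Cross-reactive clones
  contribute all their epitopes.
* **External database search**: rows whose epitope/disease labels contain
  celiac-related keywords are removed first; a hit requires the anchored
  regex plus the identical V gene, and paired motifs require both chains in
  one row.
* **Generation probabilities** (the probability that V(D)J recombination
  produces a given sequence) are consumed as precomputed per-sequence inputs
  — inferring recombination models is out of scope for this package.  Paired
  probabilities are the exact product of the chain probabilities.  Public vs
  private values are compared with a one-sided Mann-Whitney U test: exact by
  enumeration of label assignments for combined n ≤ 20 (valid under ties),
  tie-corrected normal approximation otherwise.

## The synthetic cohort generator

The generator emulates the structure of a tetramer-sorted, antigen-specific
single-cell TCR study; its defaults are the study conditions the tests and
acceptance script run under.

* **Cohort**: 30 patients, 20–160 clonotypes each (uniform), ≈ 2700
  clonotypes in total; cells per clonotype 1 + Poisson(1.3) (≈ 2.3 on
  average, ≈ 6300 cells).
* **Gene usage**: categorical V/J tables with TRAV26-1 (15%) and TRBV7-2
  (10%) dominating, so that together with the dominant planted motif the
  TRAV26-1:TRBV7-2 pair mass lands near 12% of clonotypes.
* **CDR3s**: lengths 9–18 (mean ≈ 12.9, mode 12); the first two residues are
  fixed per V gene (always `AS` for β, as in real TRB junctions) and the
  last per J gene, so trimming behaves as in real data; interiors are drawn
  i.i.d. from a CDR3-like composition (G/S rich, C/W rare).  Real CDR3s have
  positional and germline structure this background lacks; passing tests
  show the *method* recovers planted structure against a realistic null, not
  that it performs identically on real repertoires.
* **Planted motifs** (defaults): a dominant paired R-motif analogue — β
  template `ASS.R.TDTQY` on TRBV7-2/TRBJ2-3 with the arginine at a
  convergent codon position, α template `IVS.NDYKLSF` on TRAV26-1/TRAJ20 —
  at 10.5% prevalence, plus five minor motifs (two α, two β, one paired) at
  0.5–1%.  Wildcard slots draw uniformly from the 20 residues.  All
  templates are ≥ 11 residues so trimmed lengths pass the clustering filter.
* **Public sequences**: per patient, 37% of background clonotypes are marked
  and linked into cross-patient groups of 2–4 patients (60% α, 40% β).
  Group members share the amino-acid chain identity while their nucleotide
  sequences are re-drawn at two convergent codon positions — the convergent
  recombination mechanism that makes real public TCRs possible.  With motifs
  planted, *observed* sharing exceeds the 37% target because identical motif
  instantiations across patients are public too; cohorts generated with
  `planted_motifs=[]` realize the target exactly, which is what the
  public-recovery checks use.
* **Noise**: dual productive α at 6.9% and β at 0.2% (background clonotypes
  only, so planted truth is never hidden behind the random dual-chain pick),
  unproductive α/β at 16.1%/3.5%, one sub-threshold (< 50 reads) decoy chain
  in 8% of cells, and 3% structurally invalid decoy cells (β-only, or 2α+2β).
  Read supports are log-normal (ln-scale mean 6.2, σ 1.4; ~5% of raw draws
  fall below 50); defining chains of true cells draw from the distribution
  truncated at 50 so the planted truth survives ingestion exactly and
  attrition bookkeeping is exact per seed.
* **Surrogate generation probabilities** are log-normal (ln-mean −17.3 at
  amino-acid level, −19.8 at nucleotide level, σ 1.5) with a +1.5 ln-scale
  shift for public clonotypes — the direction real repertoires show.  They
  are surrogates for external recombination-model output, good for testing
  the comparison machinery, not a recombination model.
* Ground truth is keyed by (patient, β V, β J, β CDR3 nt), which is exactly
  the pipeline's clonotype key, so truth joins are lossless.

## Numerical and degenerate-input policy

Levenshtein distances are integers; UPGMA heights are exact sums divided
once, so cluster-membership comparisons use plain ≤ with no tolerance.
Empty sequences are legal for the distance (d("", s) = |s|); empty sample
sets, empty MSAs, single-item distance matrices and CDR3s shorter than three
residues raise `DegenerateInputError`.  Filters never raise; they only drop.
Probabilities outside [0, 1] raise.  All randomness (dual-α selection,
synthetic generation) flows from explicit seeds; reruns are byte-identical,
which the test suite asserts on whole report bundles.

## Problem sizes used by tests and the acceptance script

Module tests run on an 8-patient cohort (~700 clonotypes); the planted-motif
recovery check runs one full-scale 30-patient cohort (~2700 clonotypes,
three clusterings, ≈ 1 minute); determinism reruns use a 10-patient cohort.
These sizes reproduce the study-scale census where it matters (the 2764 →
2750 trimming attrition is checked at exactly that census) while keeping the
whole suite around two minutes.

## Known limitations

* The background CDR3 model is i.i.d. within a chain; it has no germline
  D-segment signal, no N-insertion length correlation, and no positional
  amino-acid profile beyond the fixed V/J flanks.
* The progressive aligner assumes near-identical members (true for motif
  candidates by construction); it is not a general MSA tool.
* Established-motif exclusion uses a member-overlap threshold (default 50%)
  because "matching" an established motif is not otherwise quantified.
* Generation probabilities must be computed externally; the package only
  combines and compares them.
* Alpha-chain publicity is keyed on the representative α (plus the dual
  partner when present); cells whose duals were filtered by read support are
  represented by the surviving chain only.
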