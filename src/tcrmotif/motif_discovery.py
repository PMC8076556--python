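"""Recursive V-gene-constrained CDR3 motif discovery on UPGMA dendrograms.

A motif candidate is a dendrogram node (i) whose average-linkage height is at
or below a Levenshtein cutoff, (ii) whose leaf clonotypes all use the same V
gene (or, in subgroup mode, the same IMGT V subgroup), and (iii) that covers
at least ``min_leaves`` clonotypes.  The search walks the tree from the root;
when a node qualifies it is emitted and the walk does not descend further, so
emitted candidates are leaf-disjoint.

Each candidate's full (untrimmed) CDR3s are multiply aligned and rendered as
an anchored regular expression, one column at a time:

* identical residues -> the literal residue,
* distinct residues within a single amino-acid group -> the full character
  class of that group (charged ``[KRED]``, polar ``[QNHSTYC]``, amphipathic
  ``[WYM]``, hydrophobic ``[AILMFVPG]``),
* residues spanning several groups -> the wildcard ``.``,
* any gap in the column -> the column's token is made optional (``?``).

Matching a motif always requires both the anchored regex match on the full
CDR3 and the V-gene (or V-subgroup) constraint; paired motifs require both
chains to match.  Candidates reproducing motifs already established for
celiac disease (the R-motif family) can be removed with
:func:`exclude_established`; that library ships as packaged data.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Literal, Mapping, Sequence

import pandas as pd

from .distance_clustering import DendrogramNode
from .io_repertoire import ChainRecord, Clonotype, DegenerateInputError

DEFAULT_MIN_LEAVES = 5
DEFAULT_OVERLAP_THRESHOLD = 0.5

#: amino-acid groups used for regex character classes; Y, M, W deliberately
#: belong to more than one group
AA_GROUPS: dict[str, str] = {
    "charged": "KRED",
    "polar": "QNHSTYC",
    "amphipathic": "WYM",
    "hydrophobic": "AILMFVPG",
}

#: tie-break when a column's residues fit several (overlapping) groups
GROUP_PRIORITY = ("charged", "polar", "amphipathic", "hydrophobic")

VMode = Literal["gene", "subgroup"]


@dataclass
class MotifCandidate:
    """A discovered CDR3 pattern with its V constraint and members."""

    motif_id: str
    chain_mode: str  # alpha | beta | paired
    pattern_alpha: str | None
    pattern_beta: str | None
    v_constraint: dict[str, str]  # chain -> required V gene or subgroup
    v_mode: VMode
    member_ids: tuple[str, ...]
    node_height: float
    msa: dict[str, list[str]] = field(default_factory=dict)  # chain -> rows

    @property
    def size(self) -> int:
        return len(self.member_ids)


@dataclass(frozen=True)
class EstablishedMotif:
    """A previously described celiac-relevant CDR3 motif.

    ``pattern`` applies to the motif's own chain; for paired motifs the
    pattern constrains the beta chain and ``partner_v_genes`` constrains the
    alpha V gene.  J genes are recorded but not enforced by default, since
    motif matching is defined by regex plus identical V gene.
    """

    name: str
    chain: str  # alpha | beta | paired
    pattern: str
    v_genes: frozenset[str]
    j_gene: str = ""
    partner_v_genes: frozenset[str] = frozenset()

    def __post_init__(self):
        re.compile(self.pattern)  # patterns must parse


def load_established_motifs() -> list[EstablishedMotif]:
    """Load the packaged library of established celiac-disease CDR3 motifs."""
    with resources.files("tcrmotif.data").joinpath("established_motifs.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", dtype=str, keep_default_na=False).fillna("")
    motifs = []
    for row in df.to_dict("records"):
        motifs.append(EstablishedMotif(
            name=row["name"],
            chain=row["chain"],
            pattern=row["pattern"],
            v_genes=frozenset(v for v in row["v_genes"].split("|") if v),
            j_gene=row["j_gene"],
            partner_v_genes=frozenset(v for v in row["partner_v_genes"].split("|") if v),
        ))
    return motifs


# ---------------------------------------------------------------------------
# node search
# ---------------------------------------------------------------------------

def _chain_v(ct: Clonotype, chain: str, alpha_index: int = 0) -> tuple[str, str]:
    rec = ct.beta if chain == "beta" else ct.alpha_chains[min(alpha_index, len(ct.alpha_chains) - 1)]
    return rec.v_gene, rec.v_subgroup


def _coherent_v(values: set[str]) -> str | None:
    return next(iter(values)) if len(values) == 1 else None


def discover_motif_nodes(
    root: DendrogramNode,
    clonotypes: Mapping[str, Clonotype],
    cutoff: float,
    chain_mode: str,
    v_mode: VMode = "gene",
    min_leaves: int = DEFAULT_MIN_LEAVES,
    alpha_choice: Mapping[str, int] | None = None,
    id_prefix: str = "m",
) -> list[MotifCandidate]:
    """Recursive root-to-leaves motif-node search.

    ``alpha_choice`` optionally records which alpha (0 or 1) of a dual-alpha
    clonotype entered the clustering, so V coherence is judged on the same
    chain that was clustered.  Emitted candidates carry patterns built from
    their members' full CDR3s (see :func:`align_members` /
    :func:`build_regex`) and are leaf-disjoint.
    """
    alpha_choice = alpha_choice or {}
    chains = ("alpha", "beta") if chain_mode == "paired" else (chain_mode,)
    out: list[MotifCandidate] = []

    def qualifies(node: DendrogramNode) -> dict[str, str] | None:
        if node.height > cutoff or len(node.leaf_ids) < min_leaves:
            return None
        constraint = {}
        for chain in chains:
            vals = set()
            for cid in node.leaf_ids:
                gene, subgroup = _chain_v(clonotypes[cid], chain,
                                          alpha_choice.get(cid, 0))
                vals.add(gene if v_mode == "gene" else subgroup)
            v = _coherent_v(vals)
            if v is None:
                return None
            constraint[chain] = v
        return constraint

    def descend(node: DendrogramNode) -> None:
        constraint = qualifies(node)
        if constraint is not None:
            out.append(_make_candidate(node, clonotypes, chain_mode, v_mode,
                                       constraint, alpha_choice,
                                       f"{id_prefix}{len(out):03d}"))
            return  # search stops below an emitted node
        for child in node.children:
            descend(child)

    descend(root)
    return out


def _make_candidate(node, clonotypes, chain_mode, v_mode, constraint,
                    alpha_choice, motif_id) -> MotifCandidate:
    patterns: dict[str, str | None] = {"alpha": None, "beta": None}
    msa: dict[str, list[str]] = {}
    chains = ("alpha", "beta") if chain_mode == "paired" else (chain_mode,)
    for chain in chains:
        seqs = []
        for cid in node.leaf_ids:
            ct = clonotypes[cid]
            if chain == "beta":
                seqs.append(ct.beta_cdr3_aa)
            else:
                idx = min(alpha_choice.get(cid, 0), len(ct.alpha_chains) - 1)
                seqs.append(ct.alpha_chains[idx].cdr3_aa)
        rows = align_members(seqs)
        msa[chain] = rows
        patterns[chain] = build_regex(rows)
    return MotifCandidate(
        motif_id=motif_id,
        chain_mode=chain_mode,
        pattern_alpha=patterns["alpha"],
        pattern_beta=patterns["beta"],
        v_constraint=constraint,
        v_mode=v_mode,
        member_ids=tuple(node.leaf_ids),
        node_height=node.height,
        msa=msa,
    )


# ---------------------------------------------------------------------------
# alignment and regex construction
# ---------------------------------------------------------------------------

def align_members(cdr3s: Sequence[str]) -> list[str]:
    """Progressive multiple alignment with identity scoring.

    Sequences are added in the given order (callers pass UPGMA subtree leaf
    order); each new sequence is aligned to the current profile by
    Needleman-Wunsch with score = fraction of rows matching the residue,
    mismatch 0, gap -1.  Removing gaps from row i recovers input i.  Member
    sets are near-identical by construction, so this simple scheme recovers
    the obvious alignment.
    """
    if not cdr3s:
        raise DegenerateInputError("cannot align an empty sequence set")
    msa = [cdr3s[0]]
    for seq in cdr3s[1:]:
        msa = _align_to_profile(msa, seq)
    return msa


def _align_to_profile(msa: list[str], seq: str) -> list[str]:
    ncol, m = len(msa[0]), len(seq)
    nrow = len(msa)
    counts = [Counter(row[c] for row in msa if row[c] != "-") for c in range(ncol)]
    gap = -1.0
    # dp[i][j]: best score aligning first i profile columns with first j chars
    dp = [[0.0] * (m + 1) for _ in range(ncol + 1)]
    back = [[0] * (m + 1) for _ in range(ncol + 1)]  # 1=diag, 2=up(col/gap), 3=left(char/gapcol)
    for i in range(1, ncol + 1):
        dp[i][0] = dp[i - 1][0] + gap
        back[i][0] = 2
    for j in range(1, m + 1):
        dp[0][j] = dp[0][j - 1] + gap
        back[0][j] = 3
    for i in range(1, ncol + 1):
        ci = counts[i - 1]
        for j in range(1, m + 1):
            diag = dp[i - 1][j - 1] + ci.get(seq[j - 1], 0) / nrow
            up = dp[i - 1][j] + gap
            left = dp[i][j - 1] + gap
            # deterministic preference: diag, then consume-column, then insert-column
            best, move = diag, 1
            if up > best:
                best, move = up, 2
            if left > best:
                best, move = left, 3
            dp[i][j] = best
            back[i][j] = move
    # traceback
    new_cols: list[tuple[int | None, str | None]] = []  # (profile col, seq char)
    i, j = ncol, m
    while i > 0 or j > 0:
        move = back[i][j]
        if move == 1:
            new_cols.append((i - 1, seq[j - 1]))
            i, j = i - 1, j - 1
        elif move == 2:
            new_cols.append((i - 1, None))
            i -= 1
        else:
            new_cols.append((None, seq[j - 1]))
            j -= 1
    new_cols.reverse()
    out_rows = []
    for row in msa:
        out_rows.append("".join(row[c] if c is not None else "-" for c, _ in new_cols))
    out_rows.append("".join(ch if ch is not None else "-" for _, ch in new_cols))
    return out_rows


def _column_token(residues: set[str]) -> str:
    if len(residues) == 1:
        return next(iter(residues))
    for name in GROUP_PRIORITY:
        letters = AA_GROUPS[name]
        if residues <= set(letters):
            return f"[{letters}]"
    return "."


def build_regex(msa: Sequence[str]) -> str:
    """Render an MSA as an anchored regular expression, column by column.

    The returned pattern is intended for anchored matching
    (:func:`re.fullmatch`) against full CDR3 amino-acid sequences.
    """
    if not msa:
        raise DegenerateInputError("empty MSA")
    ncol = len(msa[0])
    tokens = []
    for c in range(ncol):
        column = [row[c] for row in msa]
        residues = {ch for ch in column if ch != "-"}
        gapped = "-" in column
        if not residues:
            continue  # all-gap column carries no constraint
        token = _column_token(residues)
        if gapped:
            token += "?"
        tokens.append(token)
    return "".join(tokens)


def text_logo(msa: Sequence[str]) -> str:
    """Plain-text sequence logo: per-column residue counts, most common first."""
    lines = []
    for c in range(len(msa[0])):
        counts = Counter(row[c] for row in msa)
        parts = " ".join(f"{ch}:{n}" for ch, n in counts.most_common())
        lines.append(f"{c + 1:>3}  {parts}")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# matching
# ---------------------------------------------------------------------------

def _side_matches(pattern: str | None, v_required: str | Iterable[str] | None,
                  v_mode: VMode, chains: Sequence[ChainRecord]) -> bool:
    """True if any of the candidate chains satisfies pattern + V constraint."""
    if isinstance(v_required, str):
        v_set = {v_required}
    else:
        v_set = set(v_required) if v_required else set()
    for rec in chains:
        if v_set:
            v_val = rec.v_gene if v_mode == "gene" else rec.v_subgroup
            if v_val not in v_set:
                continue
        if pattern is not None and not re.fullmatch(pattern, rec.cdr3_aa):
            continue
        return True
    return False


def match_motif(
    motif: MotifCandidate | EstablishedMotif,
    subject: ChainRecord | Clonotype,
    enforce_j: bool = False,
) -> bool:
    """Anchored regex + identical-V matching of a motif against a subject.

    For dual-chain clonotypes either chain of the relevant locus may satisfy
    its side; paired motifs require both the alpha and the beta side to match.
    ``enforce_j`` additionally requires the recorded J gene (established
    motifs only).
    """
    if isinstance(motif, EstablishedMotif):
        pattern, chain = motif.pattern, motif.chain
        if isinstance(subject, ChainRecord):
            if chain == "paired" or subject.chain != chain:
                return False
            if enforce_j and motif.j_gene and subject.j_gene != motif.j_gene:
                return False
            return _side_matches(pattern, motif.v_genes, "gene", [subject])
        alphas, betas = subject.alpha_chains, [subject.beta]
        if enforce_j and motif.j_gene:
            if chain in ("beta", "paired"):
                betas = [b for b in betas if b.j_gene == motif.j_gene]
            if chain == "alpha":
                alphas = [a for a in alphas if a.j_gene == motif.j_gene]
        if chain == "alpha":
            return _side_matches(pattern, motif.v_genes, "gene", alphas)
        if chain == "beta":
            return _side_matches(pattern, motif.v_genes, "gene", betas)
        return (_side_matches(pattern, motif.v_genes, "gene", betas)
                and _side_matches(None, motif.partner_v_genes, "gene", alphas))

    # discovered candidate
    if isinstance(subject, ChainRecord):
        if motif.chain_mode == "paired" or subject.chain != motif.chain_mode:
            return False
        pattern = motif.pattern_alpha if motif.chain_mode == "alpha" else motif.pattern_beta
        return _side_matches(pattern, motif.v_constraint.get(motif.chain_mode),
                             motif.v_mode, [subject])
    ok = True
    if motif.chain_mode in ("alpha", "paired"):
        ok = _side_matches(motif.pattern_alpha, motif.v_constraint.get("alpha"),
                           motif.v_mode, subject.alpha_chains)
    if ok and motif.chain_mode in ("beta", "paired"):
        ok = _side_matches(motif.pattern_beta, motif.v_constraint.get("beta"),
                           motif.v_mode, [subject.beta])
    return ok


def exclude_established(
    candidates: Iterable[MotifCandidate],
    clonotypes: Mapping[str, Clonotype],
    established: Sequence[EstablishedMotif] | None = None,
    overlap_threshold: float = DEFAULT_OVERLAP_THRESHOLD,
) -> tuple[list[MotifCandidate], list[tuple[str, str, float]]]:
    """Drop candidates that re-discover established motifs.

    A candidate is removed when at least ``overlap_threshold`` of its members
    match any single established motif (same chain repertoire, full matching
    semantics).  Returns ``(kept, removed)`` where removed rows are
    ``(motif_id, established name, member overlap fraction)``.
    """
    established = load_established_motifs() if established is None else established
    kept, removed = [], []
    for cand in candidates:
        hit = None
        for est in established:
            frac = sum(
                match_motif(est, clonotypes[cid]) for cid in cand.member_ids
            ) / cand.size
            if frac >= overlap_threshold:
                hit = (cand.motif_id, est.name, frac)
                break
        if hit:
            removed.append(hit)
        else:
            kept.append(cand)
    return kept, removed


def motif_frequency(
    motif: MotifCandidate | EstablishedMotif,
    clonotypes: Iterable[Clonotype],
) -> tuple[int, float]:
    """(count, fraction) of clonotypes with at least one matching chain/pair."""
    cts = list(clonotypes)
    if not cts:
        raise DegenerateInputError("empty clonotype set")
    count = sum(match_motif(motif, ct) for ct in cts)
    return count, count / len(cts)
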