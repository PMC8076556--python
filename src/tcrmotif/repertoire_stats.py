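"""Repertoire-level statistics: V-gene usage, public/private sharing, epitope
annotation, external-database motif search and generation-probability tests.

Public sequences are chain (or chain-pair) amino-acid identities observed in
at least two patients.  The default identity key is (V gene, J gene, CDR3 aa)
per chain, consistent with the clonotype definition and with motif-matching
semantics; a CDR3-only key is available via ``key_fields="aa"``.

Generation probabilities (the probability that V(D)J recombination produces a
given receptor) are consumed as precomputed per-sequence inputs; paired
probabilities are the product of the per-chain values, and public-vs-private
comparisons use a one-sided Mann-Whitney U test (exact permutation for small
samples, tie-corrected normal approximation otherwise).
"""

from __future__ import annotations

import itertools
import math
import re
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .distance_clustering import levenshtein
from .io_repertoire import (Clonotype, DegenerateInputError, FormatError,
                            strip_allele)
from .motif_discovery import EstablishedMotif, MotifCandidate, match_motif

EPITOPES = ("DQ2.5-glia-a1a", "DQ2.5-glia-a2", "DQ2.5-glia-o1", "DQ2.5-glia-o2")


# ---------------------------------------------------------------------------
# V-gene usage
# ---------------------------------------------------------------------------

def vgene_usage(
    clonotypes: Iterable[Clonotype],
    mode: Literal["TRAV", "TRBV", "paired"],
) -> pd.DataFrame:
    """Weighted V-gene (or V-gene-pair) usage frequencies.

    Chains with ambiguous V calls are excluded; dual-chain clonotypes
    contribute 0.5 to each alternative gene or gene pair, so each clonotype
    carries total weight 1 (when not excluded) and frequencies sum to 1 over
    the included mass.  Returns a frame with columns
    ``gene, weight, n_clonotypes, frequency`` sorted by descending weight.
    """
    cts = list(clonotypes)
    if not cts:
        raise DegenerateInputError("empty clonotype set")
    weight: dict[str, float] = defaultdict(float)
    support: dict[str, set[str]] = defaultdict(set)
    for ct in cts:
        alphas = [a for a in ct.alpha_chains if not a.v_ambiguous]
        beta_ok = not ct.beta.v_ambiguous
        if mode == "TRAV":
            keys = [a.v_gene for a in alphas]
        elif mode == "TRBV":
            keys = [ct.beta.v_gene] if beta_ok else []
        else:
            keys = ([f"{a.v_gene}:{ct.beta.v_gene}" for a in alphas]
                    if beta_ok else [])
        if not keys:
            continue
        w = 1.0 / len(keys)
        for key in keys:
            weight[key] += w
            support[key].add(ct.clonotype_id)
    total = sum(weight.values())
    rows = [{"gene": g, "weight": w, "n_clonotypes": len(support[g]),
             "frequency": w / total}
            for g, w in weight.items()]
    return (pd.DataFrame(rows)
            .sort_values(["weight", "gene"], ascending=[False, True])
            .reset_index(drop=True))


def collapse_rare(usage: pd.DataFrame, min_clonotypes: int = 2) -> pd.DataFrame:
    """Collapse genes observed in fewer than ``min_clonotypes`` clonotypes
    into an ``other`` row (report-level convenience; totals preserved)."""
    keep = usage[usage.n_clonotypes >= min_clonotypes]
    rare = usage[usage.n_clonotypes < min_clonotypes]
    if rare.empty:
        return usage.copy()
    other = pd.DataFrame([{
        "gene": "other",
        "weight": rare.weight.sum(),
        "n_clonotypes": int(rare.n_clonotypes.sum()),
        "frequency": rare.frequency.sum(),
    }])
    return pd.concat([keep, other], ignore_index=True)


# ---------------------------------------------------------------------------
# public / private sequences
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PublicRecord:
    """A chain (or chain-pair) identity observed in at least two patients."""

    mode: str  # alpha | beta | paired
    identity_key: tuple
    patients: frozenset[str]
    n_clonotypes: int
    clonotype_ids: tuple[str, ...] = ()

    @property
    def public(self) -> bool:
        return len(self.patients) >= 2


def _chain_key(rec, key_fields: str) -> tuple:
    if key_fields == "vj_aa":
        return (rec.v_gene, rec.j_gene, rec.cdr3_aa)
    if key_fields == "aa":
        return (rec.cdr3_aa,)
    if key_fields == "vj_nt":
        return (rec.v_gene, rec.j_gene, rec.cdr3_nt)
    raise ValueError(f"unknown key_fields {key_fields!r}")


def find_public_sequences(
    clonotypes: Iterable[Clonotype],
    mode: Literal["alpha", "beta", "paired"],
    key_fields: str = "vj_aa",
) -> list[PublicRecord]:
    """Group chain identities across patients and return the public ones.

    Every accepted chain is keyed (both alphas of a dual-alpha clonotype);
    within-patient repeats count once toward the patient set.  A record is
    public when its identity occurs in >= 2 distinct patients.
    """
    groups: dict[tuple, set[str]] = defaultdict(set)
    members: dict[tuple, list[str]] = defaultdict(list)
    for ct in clonotypes:
        if mode == "alpha":
            keys = [_chain_key(a, key_fields) for a in ct.alpha_chains]
        elif mode == "beta":
            keys = [_chain_key(ct.beta, key_fields)]
        else:
            bk = _chain_key(ct.beta, key_fields)
            keys = [(_chain_key(a, key_fields), bk) for a in ct.alpha_chains]
        for key in set(keys):
            groups[key].add(ct.patient_id)
            members[key].append(ct.clonotype_id)
    records = [
        PublicRecord(mode=mode, identity_key=key,
                     patients=frozenset(pats),
                     n_clonotypes=len(members[key]),
                     clonotype_ids=tuple(sorted(members[key])))
        for key, pats in groups.items() if len(pats) >= 2
    ]
    records.sort(key=lambda r: (-len(r.patients), -r.n_clonotypes, str(r.identity_key)))
    return records


def shared_fraction_per_patient(
    clonotypes: Iterable[Clonotype],
    public_alpha: Sequence[PublicRecord],
    public_beta: Sequence[PublicRecord],
    key_fields: str = "vj_aa",
) -> tuple[dict[str, float], float]:
    """Per-patient fraction of clonotypes whose alpha or beta identity is
    public, plus the median fraction across patients."""
    pub_a = {r.identity_key for r in public_alpha}
    pub_b = {r.identity_key for r in public_beta}
    total: dict[str, int] = defaultdict(int)
    shared: dict[str, int] = defaultdict(int)
    for ct in clonotypes:
        total[ct.patient_id] += 1
        hit = (_chain_key(ct.beta, key_fields) in pub_b
               or any(_chain_key(a, key_fields) in pub_a for a in ct.alpha_chains))
        if hit:
            shared[ct.patient_id] += 1
    fractions = {p: shared[p] / total[p] for p in total}
    return fractions, float(np.median(list(fractions.values())))


def bin_patients_by_size(
    clonotypes: Iterable[Clonotype],
    edges: Sequence[int] = (100,),
) -> dict[str, list[str]]:
    """Group patients by clonotype count (default bins: 1-100, 101+)."""
    counts: dict[str, int] = defaultdict(int)
    for ct in clonotypes:
        counts[ct.patient_id] += 1
    bins: dict[str, list[str]] = defaultdict(list)
    for patient, n in counts.items():
        lo = 1
        label = None
        for edge in edges:
            if n <= edge:
                label = f"{lo}-{edge}"
                break
            lo = edge + 1
        bins[label or f"{lo}+"].append(patient)
    return dict(bins)


# ---------------------------------------------------------------------------
# epitope annotation
# ---------------------------------------------------------------------------

REFERENCE_COLUMNS = ("clone_id", "epitope", "alpha_v", "alpha_j",
                     "alpha_cdr3_aa", "beta_v", "beta_j", "beta_cdr3_aa")


@dataclass
class EpitopeAnnotation:
    """Epitope assignments for a motif or a public paired record."""

    target_id: str
    assignments: dict[str, str] = field(default_factory=dict)  # epitope -> evidence

    @property
    def epitopes(self) -> tuple[str, ...]:
        return tuple(sorted(self.assignments))


def _check_reference(reference: pd.DataFrame) -> None:
    missing = [c for c in REFERENCE_COLUMNS if c not in reference.columns]
    if missing:
        raise FormatError(f"reference clone table missing column(s): "
                          f"{', '.join(missing)}")


_EVIDENCE_RANK = {"clone_exact": 0, "clone_similar": 1, "single_tetramer": 2}


def _record_evidence(ann: EpitopeAnnotation, epitope: str, evidence: str) -> None:
    prev = ann.assignments.get(epitope)
    if prev is None or _EVIDENCE_RANK[evidence] < _EVIDENCE_RANK[prev]:
        ann.assignments[epitope] = evidence


def annotate_motifs(
    motifs: Sequence[MotifCandidate | EstablishedMotif],
    reference: pd.DataFrame,
) -> list[EpitopeAnnotation]:
    """Assign epitopes to motifs from reference clones with known specificity.

    A reference clone supports an assignment when its paired TCR matches the
    motif (regex + V constraint); cross-reactive clones (multiple epitopes,
    ``/``-separated) contribute all of their epitopes.
    """
    _check_reference(reference)
    from .io_repertoire import ChainRecord  # local to avoid cycle at import

    out = []
    for motif in motifs:
        mid = motif.motif_id if isinstance(motif, MotifCandidate) else motif.name
        ann = EpitopeAnnotation(target_id=mid)
        for row in reference.to_dict("records"):
            subject = _reference_clonotype(row, ChainRecord)
            if match_motif(motif, subject):
                for epi in str(row["epitope"]).split("/"):
                    _record_evidence(ann, epi.strip(), "clone_exact")
        out.append(ann)
    return out


def _reference_clonotype(row: Mapping, ChainRecord) -> Clonotype:
    alpha = ChainRecord(
        cell_id="", patient_id=str(row.get("patient_id", "")), chain="alpha",
        v_gene=strip_allele(row["alpha_v"]),
        v_subgroup=strip_allele(row["alpha_v"]).split("-")[0],
        v_ambiguous=False, j_gene=strip_allele(row["alpha_j"]),
        cdr3_aa=row["alpha_cdr3_aa"], cdr3_nt="", read_count=0, productive=True)
    beta = ChainRecord(
        cell_id="", patient_id=str(row.get("patient_id", "")), chain="beta",
        v_gene=strip_allele(row["beta_v"]),
        v_subgroup=strip_allele(row["beta_v"]).split("-")[0],
        v_ambiguous=False, j_gene=strip_allele(row["beta_j"]),
        cdr3_aa=row["beta_cdr3_aa"], cdr3_nt="", read_count=0, productive=True)
    return Clonotype(clonotype_id=str(row["clone_id"]),
                     patient_id=str(row.get("patient_id", "")),
                     beta_key=beta.identity, beta=beta,
                     alpha_chains=[alpha], n_cells=1)


def annotate_public_pairs(
    public_pairs: Sequence[PublicRecord],
    reference: pd.DataFrame,
    max_mismatch: int = 1,
) -> list[EpitopeAnnotation]:
    """Assign epitopes to public paired records from reference clones.

    Exact identity of the paired (V, J, CDR3 aa) key gives evidence
    ``clone_exact``; equal V genes with total CDR3 Levenshtein distance
    (alpha + beta) <= ``max_mismatch`` gives ``clone_similar``.
    """
    _check_reference(reference)
    out = []
    for rec in public_pairs:
        if rec.mode != "paired":
            raise ValueError("annotate_public_pairs expects paired records")
        (a_key, b_key) = rec.identity_key
        ann = EpitopeAnnotation(target_id="|".join(map(str, (a_key, b_key))))
        for row in reference.to_dict("records"):
            ra = (strip_allele(row["alpha_v"]), strip_allele(row["alpha_j"]),
                  row["alpha_cdr3_aa"])
            rb = (strip_allele(row["beta_v"]), strip_allele(row["beta_j"]),
                  row["beta_cdr3_aa"])
            epis = [e.strip() for e in str(row["epitope"]).split("/")]
            if len(a_key) == 3:  # vj_aa key
                exact = (ra == a_key and rb == b_key)
                v_equal = ra[0] == a_key[0] and rb[0] == b_key[0]
                a_aa, b_aa = a_key[2], b_key[2]
            else:  # aa-only key
                exact = (ra[2],) == a_key and (rb[2],) == b_key
                v_equal = True
                a_aa, b_aa = a_key[0], b_key[0]
            if exact:
                for epi in epis:
                    _record_evidence(ann, epi, "clone_exact")
            elif v_equal:
                dist = levenshtein(a_aa, ra[2]) + levenshtein(b_aa, rb[2])
                if dist <= max_mismatch:
                    for epi in epis:
                        _record_evidence(ann, epi, "clone_similar")
        out.append(ann)
    return out


# ---------------------------------------------------------------------------
# external database search
# ---------------------------------------------------------------------------

DB_COLUMNS = ("chain", "cdr3_aa", "v_call", "epitope", "disease")


def search_external_db(
    motifs: Sequence[MotifCandidate | EstablishedMotif],
    db: pd.DataFrame,
    exclusion_keywords: Sequence[str] = ("celiac", "coeliac", "gliadin", "gluten"),
    aliases: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Count database rows matching each motif (regex + identical V gene).

    Rows whose epitope/disease annotation contains any exclusion keyword are
    removed before counting, so hits reflect non-celiac specificities.
    Single-chain rows carry ``chain`` in {TRA, TRB}; paired rows carry
    ``chain == "paired"`` with ``alpha_cdr3_aa/alpha_v_call`` plus
    ``cdr3_aa/v_call`` for the beta side.  Returns a frame
    ``motif_id, n_matches``.
    """
    df = db.rename(columns=dict(aliases or {})).fillna("")
    missing = [c for c in ("chain", "cdr3_aa", "v_call") if c not in df.columns]
    if missing:
        raise FormatError(f"database table missing column(s): {', '.join(missing)}")
    label_cols = [c for c in ("epitope", "disease", "pathology") if c in df.columns]
    if exclusion_keywords and label_cols:
        pat = "|".join(re.escape(k) for k in exclusion_keywords)
        mask = pd.Series(False, index=df.index)
        for col in label_cols:
            mask |= df[col].astype(str).str.contains(pat, case=False, regex=True)
        df = df[~mask]

    rows = df.to_dict("records")
    out = []
    for motif in motifs:
        if isinstance(motif, EstablishedMotif):
            mid, mode = motif.name, motif.chain
            pattern_a = motif.pattern if motif.chain == "alpha" else None
            pattern_b = motif.pattern if motif.chain in ("beta", "paired") else None
            v_a = motif.v_genes if motif.chain == "alpha" else motif.partner_v_genes
            v_b = motif.v_genes if motif.chain in ("beta", "paired") else frozenset()
        else:
            mid, mode = motif.motif_id, motif.chain_mode
            pattern_a, pattern_b = motif.pattern_alpha, motif.pattern_beta
            v_a = {motif.v_constraint["alpha"]} if "alpha" in motif.v_constraint else set()
            v_b = {motif.v_constraint["beta"]} if "beta" in motif.v_constraint else set()
        n = 0
        for row in rows:
            chain = str(row["chain"]).strip()
            if mode in ("alpha", "beta"):
                want = "TRA" if mode == "alpha" else "TRB"
                if chain.upper() != want:
                    continue
                pattern = pattern_a if mode == "alpha" else pattern_b
                v_req = v_a if mode == "alpha" else v_b
                gene = strip_allele(row["v_call"])
                if v_req and gene not in v_req:
                    continue
                if re.fullmatch(pattern, str(row["cdr3_aa"])):
                    n += 1
            else:  # paired: both chains must be present in one row
                if chain.lower() != "paired":
                    continue
                a_cdr3 = str(row.get("alpha_cdr3_aa", ""))
                a_gene = strip_allele(row.get("alpha_v_call", ""))
                b_cdr3 = str(row["cdr3_aa"])
                b_gene = strip_allele(row["v_call"])
                if not a_cdr3 or not b_cdr3:
                    continue
                if v_a and a_gene not in v_a:
                    continue
                if v_b and b_gene not in v_b:
                    continue
                if pattern_a and not re.fullmatch(pattern_a, a_cdr3):
                    continue
                if pattern_b and not re.fullmatch(pattern_b, b_cdr3):
                    continue
                n += 1
        out.append({"motif_id": mid, "n_matches": n})
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# generation probabilities
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenProbRecord:
    """Per-clonotype generation probabilities at one level (aa or nt)."""

    clonotype_id: str
    level: str  # "aa" | "nt"
    p_alpha: float
    p_beta: float

    @property
    def p_paired(self) -> float:
        return paired_generation_probability(self.p_alpha, self.p_beta)


def paired_generation_probability(p_alpha: float, p_beta: float) -> float:
    """Paired-receptor generation probability: the product of chain values."""
    for name, p in (("p_alpha", p_alpha), ("p_beta", p_beta)):
        if not (0.0 <= p <= 1.0) or math.isnan(p):
            raise ValueError(f"{name}={p!r} outside [0, 1]")
    return p_alpha * p_beta


def read_genprob_table(path) -> list[GenProbRecord]:
    """Read a generation-probability TSV (clonotype_id, level, p_alpha, p_beta)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("clonotype_id", "level", "p_alpha", "p_beta")
               if c not in df.columns]
    if missing:
        raise FormatError(f"generation-probability table missing column(s): "
                          f"{', '.join(missing)}")
    return [GenProbRecord(str(r.clonotype_id), str(r.level),
                          float(r.p_alpha), float(r.p_beta))
            for r in df.itertuples(index=False)]


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney U for sample x (ties counted half)."""
    u = 0.0
    for xi in x:
        u += np.sum(y < xi) + 0.5 * np.sum(y == xi)
    return float(u)


def compare_public_private(
    public_values: Sequence[float],
    private_values: Sequence[float],
    alternative: str = "greater",
    exact_max_n: int = 20,
) -> tuple[float, float]:
    """One-sided Mann-Whitney U test of public vs private values.

    Returns ``(U, p)`` where U counts (public, private) pairs with the public
    value larger (ties half).  For combined sample sizes up to
    ``exact_max_n`` the p-value is exact by enumerating all label
    assignments (valid under ties); larger samples use the tie-corrected
    normal approximation.
    """
    x = np.asarray(public_values, dtype=float)
    y = np.asarray(private_values, dtype=float)
    if x.size == 0 or y.size == 0:
        raise DegenerateInputError("both samples must be non-empty")
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    u_obs = _u_statistic(x, y)
    n, m = x.size, y.size
    if n + m <= exact_max_n:
        pooled = np.concatenate([x, y])
        total = math.comb(n + m, n)
        count = 0
        idx_all = frozenset(range(n + m))
        for combo in itertools.combinations(range(n + m), n):
            xs = pooled[list(combo)]
            ys = pooled[sorted(idx_all - set(combo))]
            u = _u_statistic(xs, ys)
            if alternative == "greater":
                count += u >= u_obs
            else:
                count += u <= u_obs
        return u_obs, count / total
    res = stats.mannwhitneyu(x, y, alternative=alternative, method="asymptotic")
    return float(res.statistic), float(res.pvalue)
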