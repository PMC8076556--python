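"""Ingest annotated single-cell TCR rearrangement tables and call clonotypes.

Input is the AIRR-C rearrangement TSV dialect: one row per sequenced chain
with cell barcode, locus, V/J calls, junction (nt + aa), read support and a
productivity flag, plus a patient identifier (embedded column or sidecar
table).  The operations in this module apply the standard single-cell QC
cascade for plate-based paired TCR sequencing:

1. read-support filter (chains with < ``min_reads`` supporting reads dropped),
2. dual-chain acceptance (a second alpha or beta is kept only when its read
   support is a sufficient fraction of the top chain's),
3. valid-cell calling (one or two productive chains per locus, at most three
   chains in total), and
4. clonotype definition on the beta chain: clonotypes are patient-scoped and
   keyed on identical V gene, J gene and CDR3 *nucleotide* sequence, so that
   convergent-recombination variants of one amino-acid sequence remain
   distinct clones.

CDR3 convention: throughout the package ``cdr3_aa``/``cdr3_nt`` hold IMGT
positions 105-117, i.e. the junction minus the conserved C104 and F/W118
anchors.  Inputs that provide full junctions are converted by setting
``Dialect.junction_is_full``.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

ALPHA = "alpha"
BETA = "beta"

#: locus spellings accepted in the ``locus``/``chain`` column
_LOCUS_MAP = {
    "TRA": ALPHA,
    "TRB": BETA,
    "ALPHA": ALPHA,
    "BETA": BETA,
    "A": ALPHA,
    "B": BETA,
}

DEFAULT_MIN_READS = 50
DEFAULT_DUAL_MIN_FRACTION = 0.10


class FormatError(ValueError):
    """A mandatory column is missing or a table is structurally malformed."""


class DegenerateInputError(ValueError):
    """An operation received an input too small/empty to be meaningful."""


def parse_v_call(v_call: str) -> tuple[str, str, bool]:
    """Split a V call into (gene, IMGT subgroup, ambiguous-flag).

    Allele suffixes (``*01``) are stripped: read lengths in this assay do not
    support allele calling, so genes are compared at gene level throughout.
    Multiple comma-separated calls mark the record ambiguous; the top-ranked
    (first) call represents the sequence.

    >>> parse_v_call("TRAV26-1*01")
    ('TRAV26-1', 'TRAV26', False)
    """
    calls = [c.strip() for c in str(v_call).split(",") if c.strip()]
    ambiguous = len(calls) > 1
    gene = calls[0].split("*")[0]
    subgroup = gene.split("-")[0]
    return gene, subgroup, ambiguous


def strip_allele(call: str) -> str:
    """Reduce a single V/J call to gene level (drop ``*NN`` allele suffix)."""
    return str(call).split(",")[0].strip().split("*")[0]


@dataclass(frozen=True)
class ChainRecord:
    """One sequenced TCR chain of one cell."""

    cell_id: str
    patient_id: str
    chain: str  # "alpha" | "beta"
    v_gene: str
    v_subgroup: str
    v_ambiguous: bool
    j_gene: str
    cdr3_aa: str
    cdr3_nt: str
    read_count: int
    productive: bool

    @property
    def identity(self) -> tuple[str, str, str]:
        """(v_gene, j_gene, cdr3_nt) — the nucleotide-level chain identity."""
        return (self.v_gene, self.j_gene, self.cdr3_nt)

    @property
    def aa_identity(self) -> tuple[str, str, str]:
        """(v_gene, j_gene, cdr3_aa) — the amino-acid-level chain identity."""
        return (self.v_gene, self.j_gene, self.cdr3_aa)


@dataclass
class Cell:
    """A single sorted T cell with its accepted chains."""

    cell_id: str
    patient_id: str
    alpha_chains: list[ChainRecord] = field(default_factory=list)
    beta_chains: list[ChainRecord] = field(default_factory=list)
    valid: bool = False


@dataclass
class Clonotype:
    """A patient-level T-cell clone keyed on its TCRbeta.

    ``beta_key`` is (v_gene, j_gene, cdr3_nt) of the defining beta chain;
    ``alpha_chains`` holds the representative one or two alpha chain records.
    """

    clonotype_id: str
    patient_id: str
    beta_key: tuple[str, str, str]
    beta: ChainRecord
    alpha_chains: list[ChainRecord]
    n_cells: int

    @property
    def beta_cdr3_aa(self) -> str:
        return self.beta.cdr3_aa

    @property
    def alpha_cdr3_aa(self) -> list[str]:
        return [a.cdr3_aa for a in self.alpha_chains]


@dataclass
class Dialect:
    """Column aliases and junction convention for rearrangement TSVs.

    ``aliases`` maps canonical names to the candidate column names tried in
    order.  ``junction_is_full`` declares that the junction columns include
    the conserved C104 / F-W118 anchors, which are then stripped on read.
    """

    aliases: Mapping[str, Sequence[str]] = field(
        default_factory=lambda: {
            "cell_id": ("cell_id",),
            "patient_id": ("patient_id", "subject_id"),
            "locus": ("locus", "chain"),
            "v_call": ("v_call",),
            "j_call": ("j_call",),
            "junction_aa": ("junction_aa", "cdr3_aa"),
            "junction": ("junction", "cdr3_nt", "cdr3"),
            "read_count": ("duplicate_count", "consensus_count", "read_count"),
            "productive": ("productive",),
        }
    )
    junction_is_full: bool = False

    def resolve(self, columns: Iterable[str]) -> dict[str, str]:
        cols = set(columns)
        resolved = {}
        for canon, cands in self.aliases.items():
            for cand in cands:
                if cand in cols:
                    resolved[canon] = cand
                    break
            else:
                if canon == "patient_id":
                    continue  # may come from a sidecar table
                raise FormatError(f"missing mandatory column: {canon} "
                                  f"(accepted aliases: {', '.join(cands)})")
        return resolved


_TRUE = {"t", "true", "1", "yes", "y"}


def _as_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    return str(value).strip().lower() in _TRUE


def translate_nt(nt: str) -> str:
    """Translate an in-frame nucleotide string (no ambiguity codes)."""
    return str(Seq(nt).translate())


def read_rearrangements(
    path: str | Path,
    dialect: Dialect | None = None,
    patient_map: Mapping[str, str] | None = None,
) -> tuple[list[ChainRecord], list[tuple[int, str]]]:
    """Read a rearrangement TSV into ChainRecords.

    Returns ``(records, rejects)`` where rejects is a list of
    ``(row_index, reason)`` for rows with unparseable CDR3s, missing V/J
    calls, or productive rows whose junction translation does not match the
    reported amino-acid sequence.

    Raises :class:`FormatError` if a mandatory column is absent.  An empty
    file yields ``([], [])``.
    """
    dialect = dialect or Dialect()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        return [], []
    if df.empty and len(df.columns) == 0:
        return [], []
    cols = dialect.resolve(df.columns)
    if "patient_id" not in cols and patient_map is None:
        raise FormatError("missing mandatory column: patient_id "
                          "(provide an embedded column or a patient_map sidecar)")

    records: list[ChainRecord] = []
    rejects: list[tuple[int, str]] = []
    for idx, row in enumerate(df.itertuples(index=False)):
        row = dict(zip(df.columns, row))
        cell_id = row[cols["cell_id"]]
        if "patient_id" in cols:
            patient_id = row[cols["patient_id"]]
        else:
            patient_id = patient_map.get(cell_id) if patient_map else None
            if patient_id is None:
                rejects.append((idx, "no patient mapping for cell"))
                continue
        locus = str(row[cols["locus"]]).strip().upper()
        chain = _LOCUS_MAP.get(locus)
        if chain is None:
            rejects.append((idx, f"unrecognized locus {locus!r}"))
            continue
        v_call = row[cols["v_call"]].strip()
        j_call = row[cols["j_call"]].strip()
        if not v_call or not j_call:
            rejects.append((idx, "missing V/J call"))
            continue
        aa = row[cols["junction_aa"]].strip().upper()
        nt = row[cols["junction"]].strip().upper()
        if dialect.junction_is_full:
            aa, nt = aa[1:-1], nt[3:-3]
        if not aa or not nt:
            rejects.append((idx, "empty CDR3"))
            continue
        if len(nt) != 3 * len(aa):
            rejects.append((idx, "CDR3 nt/aa length mismatch"))
            continue
        productive = _as_bool(row[cols["productive"]])
        if productive:
            try:
                if translate_nt(nt) != aa:
                    rejects.append((idx, "translation mismatch"))
                    continue
            except Exception:
                rejects.append((idx, "unparseable CDR3 nucleotide sequence"))
                continue
        try:
            read_count = int(float(row[cols["read_count"]]))
        except ValueError:
            rejects.append((idx, "unparseable read count"))
            continue
        if read_count < 0:
            rejects.append((idx, "negative read count"))
            continue
        v_gene, v_subgroup, v_amb = parse_v_call(v_call)
        records.append(ChainRecord(
            cell_id=cell_id,
            patient_id=patient_id,
            chain=chain,
            v_gene=v_gene,
            v_subgroup=v_subgroup,
            v_ambiguous=v_amb,
            j_gene=strip_allele(j_call),
            cdr3_aa=aa,
            cdr3_nt=nt,
            read_count=read_count,
            productive=productive,
        ))
    if rejects:
        logger.info("read_rearrangements: %d records, %d rejects", len(records), len(rejects))
    return records, rejects


def write_rearrangements(records: Iterable[ChainRecord], path: str | Path) -> None:
    """Write ChainRecords back to a rearrangement TSV (canonical columns)."""
    rows = [{
        "cell_id": r.cell_id,
        "patient_id": r.patient_id,
        "locus": "TRA" if r.chain == ALPHA else "TRB",
        "v_call": r.v_gene,
        "j_call": r.j_gene,
        "junction_aa": r.cdr3_aa,
        "junction": r.cdr3_nt,
        "duplicate_count": r.read_count,
        "productive": "T" if r.productive else "F",
    } for r in records]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _chain_sort_key(rec: ChainRecord):
    # highest read support first; nt sequence breaks ties deterministically
    return (-rec.read_count, rec.cdr3_nt, rec.v_gene, rec.j_gene)


def filter_chains(
    records: Iterable[ChainRecord],
    min_reads: int = DEFAULT_MIN_READS,
    dual_min_fraction: float = DEFAULT_DUAL_MIN_FRACTION,
    productive_only: bool = True,
) -> dict[str, list[ChainRecord]]:
    """Apply the read-support and dual-chain filters.

    Within each (cell, locus) group, chains are ranked by read support; the
    top chain survives if it has at least ``min_reads`` reads, and a second
    chain survives only if it additionally reaches ``dual_min_fraction`` of
    the top chain's reads.  At most two chains per locus survive.
    Unproductive chains are excluded up front by default (they carry no
    receptor and never enter clonotype calling).

    Never raises; returns ``{cell_id: [accepted chains]}``.  Idempotent.
    """
    groups: dict[tuple[str, str], list[ChainRecord]] = defaultdict(list)
    for rec in records:
        if productive_only and not rec.productive:
            continue
        groups[(rec.cell_id, rec.chain)].append(rec)

    accepted: dict[str, list[ChainRecord]] = defaultdict(list)
    for (cell_id, _chain), chains in groups.items():
        chains.sort(key=_chain_sort_key)
        top = chains[0]
        if top.read_count < min_reads:
            continue
        kept = [top]
        if len(chains) > 1:
            second = chains[1]
            if (second.read_count >= min_reads
                    and second.read_count >= dual_min_fraction * top.read_count):
                kept.append(second)
        accepted[cell_id].extend(kept)
    return dict(accepted)


def call_valid_cells(
    accepted: Mapping[str, list[ChainRecord]],
    max_total_chains: int = 3,
) -> list[Cell]:
    """Assemble Cells and set the validity flag.

    A valid cell has one or two chains at each locus and at most
    ``max_total_chains`` chains overall; cells missing a locus are invalid.
    """
    cells = []
    for cell_id in sorted(accepted):
        chains = accepted[cell_id]
        alphas = sorted((c for c in chains if c.chain == ALPHA), key=_chain_sort_key)
        betas = sorted((c for c in chains if c.chain == BETA), key=_chain_sort_key)
        patient_id = chains[0].patient_id
        valid = (1 <= len(alphas) <= 2 and 1 <= len(betas) <= 2
                 and len(alphas) + len(betas) <= max_total_chains)
        cells.append(Cell(cell_id=cell_id, patient_id=patient_id,
                          alpha_chains=alphas, beta_chains=betas, valid=valid))
    return cells


def define_clonotypes(cells: Iterable[Cell]) -> list[Clonotype]:
    """Call clonotypes from valid cells.

    Clonotypes are patient-scoped and keyed on the defining beta chain's
    (V gene, J gene, CDR3 nucleotide sequence); the defining beta of a cell
    is its highest-read beta.  The representative alpha is the alpha chain
    identity seen in the most member cells (ties: higher total read support,
    then lexicographically smallest CDR3 nt); a second alpha is retained when
    it co-occurs with the representative in at least one member cell (dual
    alpha).
    """
    members: dict[tuple[str, tuple[str, str, str]], list[Cell]] = defaultdict(list)
    for cell in cells:
        if not cell.valid:
            continue
        defining_beta = cell.beta_chains[0]
        members[(cell.patient_id, defining_beta.identity)].append(cell)

    clonotypes = []
    for i, (patient_id, beta_key) in enumerate(sorted(members)):
        cells_i = members[(patient_id, beta_key)]
        beta = next(b for c in cells_i for b in c.beta_chains[:1]
                    if b.identity == beta_key)
        # tally alpha identities across member cells
        n_cells_by_alpha: dict[tuple, int] = defaultdict(int)
        reads_by_alpha: dict[tuple, int] = defaultdict(int)
        rec_by_alpha: dict[tuple, ChainRecord] = {}
        partners: dict[tuple, set] = defaultdict(set)
        for c in cells_i:
            ids = [a.identity for a in c.alpha_chains]
            for a in c.alpha_chains:
                n_cells_by_alpha[a.identity] += 1
                reads_by_alpha[a.identity] += a.read_count
                rec_by_alpha.setdefault(a.identity, a)
                for other in ids:
                    if other != a.identity:
                        partners[a.identity].add(other)
        ranked = sorted(
            n_cells_by_alpha,
            key=lambda k: (-n_cells_by_alpha[k], -reads_by_alpha[k], k[2]),
        )
        alpha_ids = [ranked[0]]
        dual = [k for k in ranked[1:] if k in partners[ranked[0]]]
        if dual:
            alpha_ids.append(dual[0])
        clonotypes.append(Clonotype(
            clonotype_id=f"{patient_id}.ct{i:05d}",
            patient_id=patient_id,
            beta_key=beta_key,
            beta=replace(beta, cell_id="", read_count=beta.read_count),
            alpha_chains=[rec_by_alpha[k] for k in alpha_ids],
            n_cells=len(cells_i),
        ))
    return clonotypes


def clonotypes_from_frame(df: pd.DataFrame) -> list[Clonotype]:
    """Rebuild Clonotype objects from a clonotype table (see
    :func:`clonotypes_to_frame`); read counts and cell ids are not retained
    in the table and come back empty."""
    out = []
    for row in df.to_dict("records"):
        def chain(prefix: str, locus: str) -> ChainRecord:
            v = str(row[f"{prefix}_v"])
            return ChainRecord(
                cell_id="", patient_id=str(row["patient_id"]), chain=locus,
                v_gene=v, v_subgroup=v.split("-")[0], v_ambiguous=False,
                j_gene=str(row[f"{prefix}_j"]),
                cdr3_aa=str(row[f"{prefix}_cdr3_aa"]),
                cdr3_nt=str(row[f"{prefix}_cdr3_nt"]),
                read_count=0, productive=True)
        beta = chain("beta", BETA)
        alphas = [chain("alpha1", ALPHA)]
        if str(row.get("alpha2_v", "")):
            alphas.append(chain("alpha2", ALPHA))
        out.append(Clonotype(
            clonotype_id=str(row["clonotype_id"]),
            patient_id=str(row["patient_id"]),
            beta_key=beta.identity, beta=beta, alpha_chains=alphas,
            n_cells=int(row["n_cells"])))
    return out


def clonotypes_to_frame(clonotypes: Iterable[Clonotype]) -> pd.DataFrame:
    """Flatten clonotypes into the output clonotype table."""
    rows = []
    for ct in clonotypes:
        a1 = ct.alpha_chains[0]
        a2 = ct.alpha_chains[1] if len(ct.alpha_chains) > 1 else None
        rows.append({
            "clonotype_id": ct.clonotype_id,
            "patient_id": ct.patient_id,
            "beta_v": ct.beta.v_gene,
            "beta_j": ct.beta.j_gene,
            "beta_cdr3_nt": ct.beta.cdr3_nt,
            "beta_cdr3_aa": ct.beta.cdr3_aa,
            "alpha1_v": a1.v_gene,
            "alpha1_j": a1.j_gene,
            "alpha1_cdr3_nt": a1.cdr3_nt,
            "alpha1_cdr3_aa": a1.cdr3_aa,
            "alpha2_v": a2.v_gene if a2 else "",
            "alpha2_j": a2.j_gene if a2 else "",
            "alpha2_cdr3_nt": a2.cdr3_nt if a2 else "",
            "alpha2_cdr3_aa": a2.cdr3_aa if a2 else "",
            "n_cells": ct.n_cells,
        })
    return pd.DataFrame(rows)
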