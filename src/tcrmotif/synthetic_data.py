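"""Synthetic multi-patient paired-chain TCR repertoires with known truth.

The generator emulates the structure of single-cell paired TCR data from
tetramer-sorted, antigen-specific CD4+ T cells:

* a cohort of patients with heterogeneous repertoire sizes,
* biased V/J usage with one dominant alpha:beta V-gene pairing,
* planted CDR3 motifs (templates with wildcard slots, fixed V/J context),
* public sequences realized by convergent recombination — identical
  amino-acid chains across patients whose nucleotide sequences may differ at
  designated codon positions,
* dual productive alpha (and rarely beta) chains, unproductive chains,
  low-read decoy chains and structurally invalid decoy cells, so the
  ingestion filters have real work to do,
* per-chain read supports drawn log-normally, and
* surrogate per-clonotype generation probabilities with a configurable
  public-vs-private shift.

Ground-truth labels (planted motif, public group, intended epitope, codon
choices) are emitted for every clonotype, keyed by the defining beta chain
(patient, V, J, CDR3 nt) so they can be joined against pipeline output.

Defining chains of true cells are given read supports at or above the read
filter so the planted truth survives ingestion exactly; sub-threshold reads
appear on separate decoy chains and decoy cells, whose attrition is counted
in the bundle.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

from .motif_discovery import EstablishedMotif

AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: standard-genetic-code codon sets per residue, sorted for determinism
CODONS_BY_AA: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(standard_dna_table.forward_table.items()):
    CODONS_BY_AA.setdefault(_aa, ())
    CODONS_BY_AA[_aa] += (_codon,)

#: fixed codon used at non-convergent positions
CANONICAL_CODON = {aa: codons[0] for aa, codons in CODONS_BY_AA.items()}


class ConfigError(ValueError):
    """The synthetic configuration is infeasible."""


# ---------------------------------------------------------------------------
# default study conditions
# ---------------------------------------------------------------------------

TRAV_FREQS = {
    "TRAV26-1": 0.15, "TRAV4": 0.08, "TRAV35": 0.07, "TRAV12-2": 0.06,
    "TRAV8-6": 0.05, "TRAV13-1": 0.05, "TRAV23/DV6": 0.04, "TRAV29/DV5": 0.04,
    "TRAV19": 0.04, "TRAV38-1": 0.04, "TRAV5": 0.04, "TRAV9-2": 0.04,
    "TRAV12-1": 0.04, "TRAV17": 0.04, "TRAV21": 0.04, "TRAV6": 0.03,
    "TRAV16": 0.03, "TRAV25": 0.03, "TRAV36/DV7": 0.03, "TRAV39": 0.03,
    "TRAV10": 0.03,
}
TRBV_FREQS = {
    "TRBV7-2": 0.10, "TRBV29-1": 0.08, "TRBV20-1": 0.07, "TRBV5-1": 0.06,
    "TRBV19": 0.06, "TRBV9": 0.05, "TRBV6-1": 0.05, "TRBV28": 0.05,
    "TRBV2": 0.05, "TRBV4-1": 0.04, "TRBV12-3": 0.04, "TRBV18": 0.04,
    "TRBV7-3": 0.03, "TRBV11-2": 0.03, "TRBV6-5": 0.03, "TRBV10-3": 0.03,
    "TRBV27": 0.03, "TRBV30": 0.03, "TRBV14": 0.03, "TRBV15": 0.03,
    "TRBV25-1": 0.03, "TRBV3-1": 0.02, "TRBV13": 0.02,
}
TRAJ_FREQS = {
    "TRAJ20": 0.10, "TRAJ42": 0.09, "TRAJ49": 0.08, "TRAJ33": 0.08,
    "TRAJ7": 0.08, "TRAJ29": 0.08, "TRAJ12": 0.08, "TRAJ43": 0.08,
    "TRAJ22": 0.08, "TRAJ37": 0.08, "TRAJ54": 0.09, "TRAJ27": 0.08,
}
TRBJ_FREQS = {
    "TRBJ2-3": 0.15, "TRBJ2-1": 0.13, "TRBJ2-7": 0.13, "TRBJ1-1": 0.12,
    "TRBJ1-2": 0.12, "TRBJ2-2": 0.10, "TRBJ1-5": 0.09, "TRBJ2-5": 0.08,
    "TRBJ1-3": 0.08,
}

#: CDR3 length distributions (IMGT 105-117); most mass at 11-14 residues so
#: trimming to the inner CDR3 leaves >= 8 residues for almost all chains
CDR3_LEN_ALPHA = {9: 0.01, 10: 0.03, 11: 0.18, 12: 0.27, 13: 0.21,
                  14: 0.12, 15: 0.08, 16: 0.05, 17: 0.03, 18: 0.02}
CDR3_LEN_BETA = {9: 0.01, 10: 0.03, 11: 0.18, 12: 0.27, 13: 0.21,
                 14: 0.12, 15: 0.08, 16: 0.05, 17: 0.03, 18: 0.02}

#: residue composition of background CDR3 interiors (CDR3-like: glycine/serine
#: rich, tryptophan/cysteine rare)
CDR3_COMPOSITION = {
    "G": 0.11, "S": 0.11, "A": 0.08, "L": 0.08, "R": 0.07, "D": 0.06,
    "N": 0.06, "E": 0.06, "T": 0.06, "Q": 0.05, "P": 0.05, "V": 0.05,
    "Y": 0.04, "F": 0.03, "I": 0.03, "K": 0.03, "H": 0.01, "M": 0.01,
    "W": 0.005, "C": 0.005,
}

_ALPHA_STARTS = ("IV", "AV", "AL", "AT", "IL", "VV")
_J_ENDS = "YFTNS"


def _v_prefix(v_gene: str) -> str:
    """Fixed first two CDR3 residues per V gene (germline-encoded end of V)."""
    if v_gene.startswith("TRBV"):
        return "AS"
    return _ALPHA_STARTS[sum(map(ord, v_gene)) % len(_ALPHA_STARTS)]


def _j_suffix(j_gene: str) -> str:
    """Fixed last CDR3 residue per J gene (germline-encoded start of J)."""
    return _J_ENDS[sum(map(ord, j_gene)) % len(_J_ENDS)]


@dataclass(frozen=True)
class MotifSpec:
    """A CDR3 motif to plant: template(s) with '.' wildcard slots, V/J
    context, prevalence among all clonotypes and convergent codon positions."""

    name: str
    chain_mode: str  # alpha | beta | paired
    prevalence: float
    epitope: str = "unknown"
    template_alpha: str | None = None
    template_beta: str | None = None
    v_alpha: str | None = None
    j_alpha: str | None = None
    v_beta: str | None = None
    j_beta: str | None = None
    convergent_alpha: tuple[int, ...] = ()
    convergent_beta: tuple[int, ...] = ()
    slot_pools: Mapping[int, str] = field(default_factory=dict)

    def as_established(self) -> EstablishedMotif:
        """Render the spec as an established motif for match checks."""
        if self.chain_mode == "alpha":
            return EstablishedMotif(name=self.name, chain="alpha",
                                    pattern=self.template_alpha,
                                    v_genes=frozenset({self.v_alpha}),
                                    j_gene=self.j_alpha or "")
        if self.chain_mode == "beta":
            return EstablishedMotif(name=self.name, chain="beta",
                                    pattern=self.template_beta,
                                    v_genes=frozenset({self.v_beta}),
                                    j_gene=self.j_beta or "")
        return EstablishedMotif(name=self.name, chain="paired",
                                pattern=self.template_beta,
                                v_genes=frozenset({self.v_beta}),
                                j_gene=self.j_beta or "",
                                partner_v_genes=frozenset({self.v_alpha}))


def default_motifs() -> list[MotifSpec]:
    """The planted motif set emulating the study's motif landscape: one
    dominant paired R-motif analogue (~10.5% of clonotypes, conserved
    non-germline arginine at a convergent codon position) and five minor
    motifs at 0.5-1%."""
    return [
        MotifSpec(name="R-motif-like", chain_mode="paired", prevalence=0.105,
                  epitope="DQ2.5-glia-a2",
                  template_beta="ASS.R.TDTQY", v_beta="TRBV7-2", j_beta="TRBJ2-3",
                  convergent_beta=(4,),
                  template_alpha="IVS.NDYKLSF", v_alpha="TRAV26-1", j_alpha="TRAJ20"),
        MotifSpec(name="minor-a1", chain_mode="alpha", prevalence=0.008,
                  epitope="DQ2.5-glia-a1a",
                  template_alpha="AVN.GGSQGNLI", v_alpha="TRAV35", j_alpha="TRAJ42"),
        MotifSpec(name="minor-a2", chain_mode="alpha", prevalence=0.006,
                  epitope="DQ2.5-glia-o1",
                  template_alpha="ALSE.SARQLT", v_alpha="TRAV12-2", j_alpha="TRAJ22"),
        MotifSpec(name="minor-b1", chain_mode="beta", prevalence=0.010,
                  epitope="DQ2.5-glia-o2",
                  template_beta="ASSP.GQGYEQ", v_beta="TRBV20-1", j_beta="TRBJ2-7"),
        MotifSpec(name="minor-b2", chain_mode="beta", prevalence=0.005,
                  epitope="DQ2.5-glia-a1a",
                  template_beta="ASGDR.NTGEL", v_beta="TRBV19", j_beta="TRBJ1-3"),
        MotifSpec(name="minor-p1", chain_mode="paired", prevalence=0.007,
                  epitope="DQ2.5-glia-o2",
                  template_alpha="ILRG.NNRLAF", v_alpha="TRAV4", j_alpha="TRAJ7",
                  template_beta="ASSE.TGELFF", v_beta="TRBV9", j_beta="TRBJ2-2"),
    ]


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic cohort.

    Defaults reproduce the scale and rates of the emulated study: 30 patients
    with 20-160 clonotypes each (~2700 in total), dual productive alpha/beta
    at 6.9%/0.2%, unproductive alpha/beta at 16.1%/3.5%, ~37% of clonotypes
    involved in cross-patient sharing, and a dominant planted motif at 10.5%
    prevalence.
    """

    n_patients: int = 30
    #: int (fixed), (lo, hi) uniform inclusive, or explicit per-patient list
    clonotypes_per_patient: int | tuple[int, int] | Sequence[int] = (20, 160)
    v_freqs_alpha: Mapping[str, float] = field(default_factory=lambda: dict(TRAV_FREQS))
    v_freqs_beta: Mapping[str, float] = field(default_factory=lambda: dict(TRBV_FREQS))
    j_freqs_alpha: Mapping[str, float] = field(default_factory=lambda: dict(TRAJ_FREQS))
    j_freqs_beta: Mapping[str, float] = field(default_factory=lambda: dict(TRBJ_FREQS))
    cdr3_len_alpha: Mapping[int, float] = field(default_factory=lambda: dict(CDR3_LEN_ALPHA))
    cdr3_len_beta: Mapping[int, float] = field(default_factory=lambda: dict(CDR3_LEN_BETA))
    planted_motifs: Sequence[MotifSpec] = field(default_factory=default_motifs)
    public_fraction: float = 0.37
    public_group_sizes: Sequence[int] = (2, 3, 4)
    public_group_size_probs: Sequence[float] = (0.6, 0.3, 0.1)
    public_alpha_share: float = 0.6
    dual_alpha_rate: float = 0.069
    dual_beta_rate: float = 0.002
    unproductive_alpha_rate: float = 0.161
    unproductive_beta_rate: float = 0.035
    read_log_mean: float = 6.2
    read_log_sigma: float = 1.4  # ~5% of raw draws fall below 50 reads
    min_reads: int = 50
    cells_per_clonotype_poisson: float = 1.3  # n_cells = 1 + Poisson
    noise_chain_rate: float = 0.08
    decoy_cell_rate: float = 0.03
    short_cdr3_count: int = 0  # clonotypes planted with trimmed CDR3 < 8
    genprob_log_shift: float = 1.5  # public-vs-private ln-scale mean shift
    seed: int = 0

    def validate(self) -> None:
        rates = {
            "public_fraction": self.public_fraction,
            "dual_alpha_rate": self.dual_alpha_rate,
            "dual_beta_rate": self.dual_beta_rate,
            "unproductive_alpha_rate": self.unproductive_alpha_rate,
            "unproductive_beta_rate": self.unproductive_beta_rate,
            "noise_chain_rate": self.noise_chain_rate,
            "decoy_cell_rate": self.decoy_cell_rate,
        }
        for name, value in rates.items():
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name}={value} outside [0, 1]")
        prev = sum(m.prevalence for m in self.planted_motifs)
        if prev > 1.0:
            raise ConfigError(f"motif prevalences sum to {prev} > 1")
        if prev + self.public_fraction > 1.0:
            raise ConfigError("motif prevalences plus public_fraction exceed 1: "
                              "no room for background clonotypes")


@dataclass
class SyntheticBundle:
    """Everything one cohort run produces."""

    rearrangements: pd.DataFrame
    reference_clones: pd.DataFrame
    truth: pd.DataFrame
    genprob: pd.DataFrame
    config: SyntheticConfig
    counts: dict[str, int]

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.rearrangements.to_csv(outdir / "rearrangements.tsv", sep="\t", index=False)
        self.reference_clones.to_csv(outdir / "reference_clones.tsv", sep="\t", index=False)
        self.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
        self.genprob.to_csv(outdir / "genprob.tsv", sep="\t", index=False)
        cfg = dataclasses.asdict(self.config)
        cfg["planted_motifs"] = [dataclasses.asdict(m) for m in self.config.planted_motifs]
        cfg["counts"] = self.counts
        for key in ("slot_pools",):
            for m in cfg["planted_motifs"]:
                m[key] = dict(m[key])
        (outdir / "config.json").write_text(json.dumps(cfg, indent=2, default=str))


# ---------------------------------------------------------------------------
# sequence-level helpers
# ---------------------------------------------------------------------------

def generate_cdr3_nt(
    aa: str,
    convergent_positions: Sequence[int],
    rng: np.random.Generator,
) -> str:
    """Encode an amino-acid CDR3 as nucleotides.

    Codons at ``convergent_positions`` are drawn uniformly from the residue's
    standard-genetic-code codon set (arginine has six), emulating convergent
    recombination; all other positions use a fixed canonical codon, so two
    chains with identical amino acids differ in nucleotides only at the
    convergent positions.
    """
    conv = set(convergent_positions)
    codons = []
    for i, residue in enumerate(aa):
        if residue not in CODONS_BY_AA:
            raise ValueError(f"invalid residue {residue!r} at position {i}")
        if i in conv:
            options = CODONS_BY_AA[residue]
            codons.append(options[int(rng.integers(len(options)))])
        else:
            codons.append(CANONICAL_CODON[residue])
    return "".join(codons)


def _draw(rng, table: Mapping) -> object:
    keys = list(table.keys())
    probs = np.asarray([table[k] for k in keys], dtype=float)
    probs /= probs.sum()
    return keys[int(rng.choice(len(keys), p=probs))]


def _background_cdr3(rng, v_gene: str, j_gene: str, length: int) -> str:
    middle = length - 3
    comp_keys = list(CDR3_COMPOSITION)
    comp_p = np.asarray([CDR3_COMPOSITION[k] for k in comp_keys])
    comp_p /= comp_p.sum()
    inner = "".join(comp_keys[i] for i in rng.choice(len(comp_keys), size=middle, p=comp_p))
    return _v_prefix(v_gene) + inner + _j_suffix(j_gene)


def _instantiate_template(rng, template: str, slot_pools: Mapping[int, str]) -> str:
    out = []
    for i, ch in enumerate(template):
        if ch == ".":
            pool = slot_pools.get(i, AA20)
            out.append(pool[int(rng.integers(len(pool)))])
        else:
            out.append(ch)
    return "".join(out)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

@dataclass
class _Chain:
    v: str
    j: str
    aa: str
    nt: str


def _patient_counts(rng, config: SyntheticConfig) -> list[int]:
    spec = config.clonotypes_per_patient
    if isinstance(spec, int):
        return [spec] * config.n_patients
    if (isinstance(spec, tuple) and len(spec) == 2
            and all(isinstance(x, int) for x in spec)):
        lo, hi = spec
        return [int(rng.integers(lo, hi + 1)) for _ in range(config.n_patients)]
    counts = list(spec)
    if len(counts) != config.n_patients:
        raise ConfigError("explicit clonotype counts must match n_patients")
    return counts


def generate_repertoire(config: SyntheticConfig | None = None) -> SyntheticBundle:
    """Generate one synthetic cohort (deterministic under ``config.seed``)."""
    config = config or SyntheticConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    counts = _patient_counts(rng, config)
    patients = [f"P{i + 1:02d}" for i in range(config.n_patients)]

    # --- assign motif labels -------------------------------------------------
    motifs = list(config.planted_motifs)
    probs = [m.prevalence for m in motifs]
    background_p = 1.0 - sum(probs)
    clonotypes: list[dict] = []
    for patient, n in zip(patients, counts):
        for _ in range(n):
            r = rng.random()
            acc, label = 0.0, None
            for m, p in zip(motifs, probs):
                acc += p
                if r < acc:
                    label = m
                    break
            clonotypes.append({"patient": patient, "motif": label})

    # --- plant short-CDR3 clonotypes (background only) ----------------------
    bg_idx = [i for i, c in enumerate(clonotypes) if c["motif"] is None]
    if config.short_cdr3_count > len(bg_idx):
        raise ConfigError("short_cdr3_count exceeds background clonotypes")
    short_idx = {bg_idx[k] for k in
                 rng.permutation(len(bg_idx))[: config.short_cdr3_count]}

    # --- designate public slots per patient (background, non-short only) ----
    slots_by_patient: dict[str, list[int]] = {p: [] for p in patients}
    for i, c in enumerate(clonotypes):
        if c["motif"] is None and i not in short_idx:
            slots_by_patient[c["patient"]].append(i)
    remaining: dict[str, list[int]] = {}
    for patient, n in zip(patients, counts):
        want = int(round(config.public_fraction * n))
        pool = slots_by_patient[patient]
        take = rng.permutation(len(pool))[:want]
        remaining[patient] = [pool[t] for t in sorted(take)]

    group_sizes = list(config.public_group_sizes)
    group_probs = np.asarray(config.public_group_size_probs, dtype=float)
    group_probs /= group_probs.sum()
    public_groups: list[dict] = []
    while True:
        avail = [p for p in patients if remaining[p]]
        if len(avail) < 2:
            break
        m = group_sizes[int(rng.choice(len(group_sizes), p=group_probs))]
        m = min(m, len(avail))
        # balance: draw from the patients with the most remaining slots
        order = sorted(avail, key=lambda p: (-len(remaining[p]), p))
        chosen = order[:m]
        chain = "alpha" if rng.random() < config.public_alpha_share else "beta"
        if chain == "alpha":
            v = _draw(rng, config.v_freqs_alpha)
            j = _draw(rng, config.j_freqs_alpha)
            length = _draw(rng, config.cdr3_len_alpha)
        else:
            v = _draw(rng, config.v_freqs_beta)
            j = _draw(rng, config.j_freqs_beta)
            length = _draw(rng, config.cdr3_len_beta)
        aa = _background_cdr3(rng, v, j, int(length))
        conv = tuple(sorted(int(x) for x in
                            rng.choice(np.arange(2, len(aa) - 1), size=2, replace=False)))
        gid = f"pub{len(public_groups):04d}"
        public_groups.append({"group_id": gid, "chain": chain, "v": v, "j": j,
                              "aa": aa, "convergent": conv, "members": []})
        for patient in chosen:
            idx = remaining[patient].pop(int(rng.integers(len(remaining[patient]))))
            clonotypes[idx]["public_group"] = gid
            clonotypes[idx]["public_chain"] = chain
            public_groups[-1]["members"].append(idx)

    # --- realize chain identities -------------------------------------------
    group_by_id = {g["group_id"]: g for g in public_groups}
    used_beta_keys: set[tuple] = set()
    for i, c in enumerate(clonotypes):
        spec: MotifSpec | None = c["motif"]
        gid = c.get("public_group")
        group = group_by_id[gid] if gid else None
        for attempt in range(200):
            # alpha side
            if spec is not None and spec.template_alpha is not None:
                v_a, j_a = spec.v_alpha, spec.j_alpha
                aa_a = _instantiate_template(rng, spec.template_alpha, spec.slot_pools)
                conv_a = spec.convergent_alpha
            elif group is not None and group["chain"] == "alpha":
                v_a, j_a, aa_a = group["v"], group["j"], group["aa"]
                conv_a = group["convergent"]
            else:
                v_a = _draw(rng, config.v_freqs_alpha)
                j_a = _draw(rng, config.j_freqs_alpha)
                aa_a = _background_cdr3(rng, v_a, j_a, int(_draw(rng, config.cdr3_len_alpha)))
                conv_a = ()
            # beta side
            if spec is not None and spec.template_beta is not None:
                v_b, j_b = spec.v_beta, spec.j_beta
                aa_b = _instantiate_template(rng, spec.template_beta, spec.slot_pools)
                conv_b = spec.convergent_beta
            elif group is not None and group["chain"] == "beta":
                v_b, j_b, aa_b = group["v"], group["j"], group["aa"]
                conv_b = group["convergent"]
            else:
                v_b = _draw(rng, config.v_freqs_beta)
                j_b = _draw(rng, config.j_freqs_beta)
                length_b = 10 if i in short_idx else int(_draw(rng, config.cdr3_len_beta))
                aa_b = _background_cdr3(rng, v_b, j_b, length_b)
                conv_b = ()
            nt_a = generate_cdr3_nt(aa_a, conv_a, rng)
            nt_b = generate_cdr3_nt(aa_b, conv_b, rng)
            key = (c["patient"], v_b, j_b, nt_b)
            if key not in used_beta_keys:
                used_beta_keys.add(key)
                break
        else:
            raise ConfigError("could not generate a unique beta key after 200 tries")
        c["alpha"] = _Chain(v_a, j_a, aa_a, nt_a)
        c["beta"] = _Chain(v_b, j_b, aa_b, nt_b)
        # dual chains only for unlabelled background clonotypes, so planted
        # truth is never hidden behind the random dual-chain pick
        is_bg = spec is None and group is None
        c["dual_alpha"] = bool(is_bg and rng.random() < config.dual_alpha_rate)
        c["dual_beta"] = bool(is_bg and not c["dual_alpha"]
                              and rng.random() < config.dual_beta_rate)
        if c["dual_alpha"]:
            v2 = _draw(rng, config.v_freqs_alpha)
            j2 = _draw(rng, config.j_freqs_alpha)
            aa2 = _background_cdr3(rng, v2, j2, int(_draw(rng, config.cdr3_len_alpha)))
            c["alpha2"] = _Chain(v2, j2, aa2, generate_cdr3_nt(aa2, (), rng))
        if c["dual_beta"]:
            v2 = _draw(rng, config.v_freqs_beta)
            j2 = _draw(rng, config.j_freqs_beta)
            aa2 = _background_cdr3(rng, v2, j2, int(_draw(rng, config.cdr3_len_beta)))
            c["beta2"] = _Chain(v2, j2, aa2, generate_cdr3_nt(aa2, (), rng))

    # --- emit cells and chain rows ------------------------------------------
    rows: list[dict] = []
    counts_out = {"true_cells": 0, "decoy_cells": 0, "noise_chains": 0,
                  "unproductive_chains": 0, "emitted_chains": 0}
    cell_counter = 0

    def read_count(minimum: int | None) -> int:
        while True:
            r = int(np.exp(rng.normal(config.read_log_mean, config.read_log_sigma)))
            r = max(r, 1)
            if minimum is None or r >= minimum:
                return r

    def add_row(cell_id, patient, locus, chain: _Chain, reads, productive=True):
        rows.append({
            "cell_id": cell_id, "patient_id": patient, "locus": locus,
            "v_call": chain.v, "j_call": chain.j, "junction_aa": chain.aa,
            "junction": chain.nt, "duplicate_count": reads,
            "productive": "T" if productive else "F",
        })
        counts_out["emitted_chains"] += 1

    def random_chain(locus: str) -> _Chain:
        if locus == "TRA":
            v = _draw(rng, config.v_freqs_alpha)
            j = _draw(rng, config.j_freqs_alpha)
            aa = _background_cdr3(rng, v, j, int(_draw(rng, config.cdr3_len_alpha)))
        else:
            v = _draw(rng, config.v_freqs_beta)
            j = _draw(rng, config.j_freqs_beta)
            aa = _background_cdr3(rng, v, j, int(_draw(rng, config.cdr3_len_beta)))
        return _Chain(v, j, aa, generate_cdr3_nt(aa, (), rng))

    for c in clonotypes:
        n_cells = 1 + int(rng.poisson(config.cells_per_clonotype_poisson))
        c["n_cells"] = n_cells
        for _ in range(n_cells):
            cell_id = f"cell{cell_counter:06d}"
            cell_counter += 1
            counts_out["true_cells"] += 1
            beta_reads = read_count(config.min_reads)
            add_row(cell_id, c["patient"], "TRB", c["beta"], beta_reads)
            alpha_reads = read_count(config.min_reads)
            add_row(cell_id, c["patient"], "TRA", c["alpha"], alpha_reads)
            if c["dual_alpha"]:
                second = max(config.min_reads,
                             int(alpha_reads * rng.uniform(0.15, 0.9)))
                add_row(cell_id, c["patient"], "TRA", c["alpha2"], second)
            if c["dual_beta"]:
                second = max(config.min_reads,
                             int(beta_reads * rng.uniform(0.15, 0.8)))
                add_row(cell_id, c["patient"], "TRB", c["beta2"], second)
            if rng.random() < config.unproductive_alpha_rate:
                add_row(cell_id, c["patient"], "TRA", random_chain("TRA"),
                        read_count(None), productive=False)
                counts_out["unproductive_chains"] += 1
            if rng.random() < config.unproductive_beta_rate:
                add_row(cell_id, c["patient"], "TRB", random_chain("TRB"),
                        read_count(None), productive=False)
                counts_out["unproductive_chains"] += 1
            if rng.random() < config.noise_chain_rate:
                locus = "TRA" if rng.random() < 0.5 else "TRB"
                add_row(cell_id, c["patient"], locus, random_chain(locus),
                        int(rng.integers(1, config.min_reads)))
                counts_out["noise_chains"] += 1

    # structurally invalid decoy cells: read filters pass, cell calling fails
    n_decoys = int(rng.binomial(counts_out["true_cells"], config.decoy_cell_rate))
    for _ in range(n_decoys):
        patient = patients[int(rng.integers(len(patients)))]
        cell_id = f"cell{cell_counter:06d}"
        cell_counter += 1
        counts_out["decoy_cells"] += 1
        if rng.random() < 0.5:  # beta-only cell
            add_row(cell_id, patient, "TRB", random_chain("TRB"),
                    read_count(config.min_reads))
        else:  # four productive chains: 2 alpha + 2 beta
            for locus in ("TRA", "TRB"):
                reads = read_count(config.min_reads)  # equal support: both
                add_row(cell_id, patient, locus, random_chain(locus), reads)
                add_row(cell_id, patient, locus, random_chain(locus), reads)

    rearr = pd.DataFrame(rows)

    # --- truth table ----------------------------------------------------------
    truth_rows = []
    for i, c in enumerate(clonotypes):
        spec = c["motif"]
        truth_rows.append({
            "synthetic_id": f"syn{i:05d}",
            "patient_id": c["patient"],
            "beta_v": c["beta"].v, "beta_j": c["beta"].j,
            "beta_cdr3_nt": c["beta"].nt, "beta_cdr3_aa": c["beta"].aa,
            "alpha_v": c["alpha"].v, "alpha_j": c["alpha"].j,
            "alpha_cdr3_nt": c["alpha"].nt, "alpha_cdr3_aa": c["alpha"].aa,
            "motif": spec.name if spec else "",
            "epitope": spec.epitope if spec else "unknown",
            "public_group": c.get("public_group", ""),
            "public_chain": c.get("public_chain", ""),
            "short_cdr3": i in short_idx,
            "dual_alpha": c["dual_alpha"],
            "dual_beta": c["dual_beta"],
            "n_cells": c["n_cells"],
        })
    truth = pd.DataFrame(truth_rows)

    # --- reference clone table ------------------------------------------------
    ref_rows = []
    clone_counter = 0
    for spec in motifs:
        for _ in range(4):
            if spec.template_alpha is not None:
                v_a, j_a = spec.v_alpha, spec.j_alpha
                aa_a = _instantiate_template(rng, spec.template_alpha, spec.slot_pools)
            else:
                ch = random_chain("TRA")
                v_a, j_a, aa_a = ch.v, ch.j, ch.aa
            if spec.template_beta is not None:
                v_b, j_b = spec.v_beta, spec.j_beta
                aa_b = _instantiate_template(rng, spec.template_beta, spec.slot_pools)
            else:
                ch = random_chain("TRB")
                v_b, j_b, aa_b = ch.v, ch.j, ch.aa
            ref_rows.append({
                "clone_id": f"TCC{clone_counter:03d}", "patient_id": "ref",
                "epitope": spec.epitope,
                "alpha_v": v_a, "alpha_j": j_a, "alpha_cdr3_aa": aa_a,
                "beta_v": v_b, "beta_j": j_b, "beta_cdr3_aa": aa_b,
            })
            clone_counter += 1
    epilist = ("DQ2.5-glia-a1a", "DQ2.5-glia-a2", "DQ2.5-glia-o1", "DQ2.5-glia-o2")
    for _ in range(6):  # unrelated clones with known specificity
        cha, chb = random_chain("TRA"), random_chain("TRB")
        ref_rows.append({
            "clone_id": f"TCC{clone_counter:03d}", "patient_id": "ref",
            "epitope": epilist[int(rng.integers(len(epilist)))],
            "alpha_v": cha.v, "alpha_j": cha.j, "alpha_cdr3_aa": cha.aa,
            "beta_v": chb.v, "beta_j": chb.j, "beta_cdr3_aa": chb.aa,
        })
        clone_counter += 1
    reference = pd.DataFrame(ref_rows)

    # --- surrogate generation probabilities -----------------------------------
    gp_rows = []
    base = {"aa": -17.3, "nt": -19.8}
    for i, c in enumerate(clonotypes):
        shift = config.genprob_log_shift if c.get("public_group") else 0.0
        for level in ("aa", "nt"):
            p_a = float(min(np.exp(rng.normal(base[level] + shift, 1.5)), 1.0))
            p_b = float(min(np.exp(rng.normal(base[level] + shift, 1.5)), 1.0))
            gp_rows.append({"synthetic_id": f"syn{i:05d}",
                            "patient_id": c["patient"],
                            "beta_cdr3_nt": c["beta"].nt,
                            "level": level, "p_alpha": p_a, "p_beta": p_b})
    genprob = pd.DataFrame(gp_rows)

    counts_out["clonotypes"] = len(clonotypes)
    counts_out["public_groups"] = len(public_groups)
    counts_out["public_involved"] = sum(1 for c in clonotypes if c.get("public_group"))
    return SyntheticBundle(rearrangements=rearr, reference_clones=reference,
                           truth=truth, genprob=genprob, config=config,
                           counts=counts_out)
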