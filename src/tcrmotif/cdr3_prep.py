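"""Trim CDR3 sequences and assemble the clonotype sets used for clustering.

Crystal-structure surveys of TCR-peptide-MHC complexes show that the first
two CDR3 residues (IMGT 105, 106) and the last one (IMGT 117) rarely contact
peptide antigen, so clustering for shared specificity is performed on the
inner CDR3.  Trimmed sequences shorter than ``min_trimmed_len`` residues are
excluded; for dual-alpha clonotypes in paired mode one alpha is selected by a
seeded uniform draw so runs are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np

from .io_repertoire import Clonotype, DegenerateInputError

DEFAULT_MIN_TRIMMED_LEN = 8

ChainMode = Literal["alpha", "beta", "paired"]


@dataclass(frozen=True)
class ClusterItem:
    """One clonotype's trimmed sequence (or pair) entering clustering."""

    clonotype_id: str
    alpha: str | None  # trimmed alpha CDR3 (None in beta mode)
    beta: str | None   # trimmed beta CDR3 (None in alpha mode)
    alpha_index: int = 0  # which alpha of a dual-alpha clonotype was used


def trim_cdr3(full_aa: str) -> str:
    """Remove the first two and the last residue of a CDR3 (IMGT 105-117).

    >>> trim_cdr3("ASSIRATDTQY")
    'SIRATDTQ'
    """
    if len(full_aa) < 3:
        raise DegenerateInputError(
            f"CDR3 {full_aa!r} too short to trim (need >= 3 residues)")
    return full_aa[2:-1]


def prepare_clustering_set(
    clonotypes: Iterable[Clonotype],
    chain_mode: ChainMode,
    min_trimmed_len: int = DEFAULT_MIN_TRIMMED_LEN,
    seed: int = 0,
) -> list[ClusterItem]:
    """Build the trimmed clustering set for one chain mode.

    Clonotypes whose relevant trimmed CDR3 is shorter than
    ``min_trimmed_len`` are excluded; in paired mode a clonotype is excluded
    if *either* chain fails the filter.  Dual-alpha clonotypes contribute one
    alpha: in paired/alpha mode it is chosen uniformly at random under
    ``seed``.  Output order is stable (sorted by clonotype id), and is
    seed-independent for clonotypes without dual alphas.
    """
    if chain_mode not in ("alpha", "beta", "paired"):
        raise ValueError(f"unknown chain_mode {chain_mode!r}")
    rng = np.random.default_rng(seed)
    items: list[ClusterItem] = []
    for ct in sorted(clonotypes, key=lambda c: c.clonotype_id):
        alpha = beta = None
        alpha_index = 0
        if chain_mode in ("alpha", "paired"):
            cands = [a.cdr3_aa for a in ct.alpha_chains]
            alpha_index = 0 if len(cands) == 1 else int(rng.integers(len(cands)))
            chosen = cands[alpha_index]
            if len(chosen) < 3:
                continue
            alpha = trim_cdr3(chosen)
            if len(alpha) < min_trimmed_len:
                continue
        if chain_mode in ("beta", "paired"):
            if len(ct.beta_cdr3_aa) < 3:
                continue
            beta = trim_cdr3(ct.beta_cdr3_aa)
            if len(beta) < min_trimmed_len:
                continue
        items.append(ClusterItem(ct.clonotype_id, alpha, beta, alpha_index))
    return items
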