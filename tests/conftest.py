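"""Shared fixtures: synthetic cohorts processed through the ingestion stack."""

from __future__ import annotations

import pytest

from tcrmotif.io_repertoire import (ChainRecord, call_valid_cells,
                                    define_clonotypes, filter_chains,
                                    read_rearrangements)
from tcrmotif.synthetic_data import SyntheticConfig, generate_repertoire


def make_chain(cell_id="c0", patient_id="P1", chain="beta", v_gene="TRBV7-2",
               j_gene="TRBJ2-3", cdr3_aa="ASSIRATDTQY", cdr3_nt=None,
               read_count=500, productive=True, v_ambiguous=False):
    """ChainRecord factory with sensible defaults for tests."""
    from tcrmotif.synthetic_data import generate_cdr3_nt
    import numpy as np
    if cdr3_nt is None:
        cdr3_nt = generate_cdr3_nt(cdr3_aa, (), np.random.default_rng(0))
    return ChainRecord(
        cell_id=cell_id, patient_id=patient_id, chain=chain, v_gene=v_gene,
        v_subgroup=v_gene.split("-")[0], v_ambiguous=v_ambiguous,
        j_gene=j_gene, cdr3_aa=cdr3_aa, cdr3_nt=cdr3_nt,
        read_count=read_count, productive=productive)


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """An 8-patient cohort with default planted motifs, written to disk."""
    bundle = generate_repertoire(SyntheticConfig(seed=42, n_patients=8))
    outdir = tmp_path_factory.mktemp("small_bundle")
    bundle.write(outdir)
    return bundle, outdir


@pytest.fixture(scope="session")
def small_clonotypes(small_bundle):
    """Clonotypes called from the small cohort, plus the truth join."""
    bundle, outdir = small_bundle
    records, _ = read_rearrangements(outdir / "rearrangements.tsv")
    accepted = filter_chains(records)
    cells = call_valid_cells(accepted)
    clonotypes = define_clonotypes([c for c in cells if c.valid])
    truth_by_key = {
        (r.patient_id, r.beta_v, r.beta_j, r.beta_cdr3_nt): r
        for r in bundle.truth.itertuples()
    }
    return clonotypes, truth_by_key, cells
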