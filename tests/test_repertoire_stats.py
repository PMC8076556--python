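"""V-gene usage, public-sequence analysis, epitope annotation, database
search and the public-vs-private rank test."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from tcrmotif.io_repertoire import (Clonotype, DegenerateInputError,
                                    FormatError)
from tcrmotif.motif_discovery import load_established_motifs
from tcrmotif.repertoire_stats import (annotate_motifs, annotate_public_pairs,
                                       bin_patients_by_size, collapse_rare,
                                       compare_public_private,
                                       find_public_sequences,
                                       paired_generation_probability,
                                       search_external_db,
                                       shared_fraction_per_patient,
                                       vgene_usage)
from tcrmotif.synthetic_data import SyntheticConfig, generate_repertoire

from conftest import make_chain


def make_ct(cid, patient="P1", beta_v="TRBV7-2", beta_aa="ASSIRATDTQY",
            alpha_v="TRAV26-1", alpha_aa="IVSNDYKLSF", alpha2=None,
            beta_j="TRBJ2-3", alpha_j="TRAJ20", v_ambiguous=False):
    beta = make_chain(chain="beta", v_gene=beta_v, j_gene=beta_j,
                      cdr3_aa=beta_aa, v_ambiguous=v_ambiguous)
    alphas = [make_chain(chain="alpha", v_gene=alpha_v, j_gene=alpha_j,
                         cdr3_aa=alpha_aa)]
    if alpha2:
        alphas.append(make_chain(chain="alpha", v_gene=alpha2,
                                 j_gene="TRAJ42", cdr3_aa="AVRDTGGYKVV"))
    return Clonotype(clonotype_id=cid, patient_id=patient,
                     beta_key=beta.identity, beta=beta,
                     alpha_chains=alphas, n_cells=1)


class TestVgeneUsage:
    def test_dual_alpha_counted_half_each(self):
        ct = make_ct("c0", alpha_v="TRAV26-1", alpha2="TRAV4")
        usage = vgene_usage([ct], "TRAV").set_index("gene")
        assert usage.loc["TRAV26-1", "weight"] == pytest.approx(0.5)
        assert usage.loc["TRAV4", "weight"] == pytest.approx(0.5)

    def test_single_chain_counts_are_integers_normalized(self):
        cts = [make_ct(f"c{i}", alpha_v="TRAV26-1" if i < 3 else "TRAV4")
               for i in range(5)]
        usage = vgene_usage(cts, "TRAV").set_index("gene")
        assert usage.loc["TRAV26-1", "frequency"] == pytest.approx(0.6)
        assert usage.loc["TRAV4", "frequency"] == pytest.approx(0.4)

    def test_frequencies_sum_to_one_with_duals_and_ambiguous(self, small_clonotypes):
        clonotypes, _, _ = small_clonotypes
        for mode in ("TRAV", "TRBV", "paired"):
            usage = vgene_usage(clonotypes, mode)
            assert usage.frequency.sum() == pytest.approx(1.0, abs=1e-12)

    def test_ambiguous_v_excluded(self):
        cts = [make_ct("c0", v_ambiguous=True), make_ct("c1", beta_v="TRBV5-1")]
        usage = vgene_usage(cts, "TRBV")
        assert list(usage.gene) == ["TRBV5-1"]

    def test_collapse_rare_preserves_mass(self, small_clonotypes):
        clonotypes, _, _ = small_clonotypes
        usage = vgene_usage(clonotypes, "TRBV")
        collapsed = collapse_rare(usage, min_clonotypes=2)
        assert collapsed.frequency.sum() == pytest.approx(1.0, abs=1e-12)
        rare = usage[usage.n_clonotypes < 2]
        if not rare.empty:
            assert "other" in set(collapsed.gene)


class TestFindPublicSequences:
    def test_identical_beta_in_two_patients_is_public(self):
        cts = [make_ct("c0", patient="P1"), make_ct("c1", patient="P2")]
        recs = find_public_sequences(cts, "beta")
        assert len(recs) == 1
        assert recs[0].patients == {"P1", "P2"}

    def test_within_patient_repeats_count_once(self):
        cts = [make_ct("c0", patient="P1"), make_ct("c1", patient="P1")]
        assert find_public_sequences(cts, "beta") == []

    def test_default_key_separates_v_genes(self):
        cts = [make_ct("c0", patient="P1", beta_v="TRBV7-2"),
               make_ct("c1", patient="P2", beta_v="TRBV7-3")]
        assert find_public_sequences(cts, "beta", key_fields="vj_aa") == []
        loose = find_public_sequences(cts, "beta", key_fields="aa")
        assert len(loose) == 1

    def test_planted_groups_recovered_exactly(self):
        cfg = SyntheticConfig(seed=9, n_patients=10, planted_motifs=[],
                              clonotypes_per_patient=(20, 80))
        bundle = generate_repertoire(cfg)
        import tempfile
        from pathlib import Path
        from tcrmotif.io_repertoire import (call_valid_cells, define_clonotypes,
                                            filter_chains, read_rearrangements)
        with tempfile.TemporaryDirectory() as td:
            bundle.write(td)
            records, _ = read_rearrangements(Path(td) / "rearrangements.tsv")
        cells = call_valid_cells(filter_chains(records))
        cts = define_clonotypes([c for c in cells if c.valid])
        pub_a = find_public_sequences(cts, "alpha")
        pub_b = find_public_sequences(cts, "beta")
        assert len(pub_a) + len(pub_b) == bundle.counts["public_groups"]
        # paired sharing was not planted, so none should appear
        assert find_public_sequences(cts, "paired") == []

    def test_removing_a_patient_never_raises_counts(self, small_clonotypes):
        clonotypes, _, _ = small_clonotypes
        full = {r.identity_key: len(r.patients)
                for r in find_public_sequences(clonotypes, "beta")}
        one_patient = {ct.patient_id for ct in clonotypes}.pop()
        reduced = find_public_sequences(
            [ct for ct in clonotypes if ct.patient_id != one_patient], "beta")
        for rec in reduced:
            assert len(rec.patients) <= full.get(rec.identity_key, math.inf)


class TestSharedFraction:
    def test_fraction_counts_public_involved_clonotypes(self):
        cts = ([make_ct(f"s{i}", patient="P1", beta_aa="ASSIRATDTQY")
                for i in range(4)]
               + [make_ct(f"p{i}", patient="P1", beta_v="TRBV5-1",
                          beta_aa=f"ASGELSNQPQ{'HKR'[i]}", alpha_v="TRAV4",
                          alpha_aa=f"AVRDTGGYK{'VAD'[i]}")
                  for i in range(3)]
               + [make_ct(f"q{i}", patient="P2", beta_aa="ASSIRATDTQY")
                  for i in range(3)])
        pub_a = find_public_sequences(cts, "alpha")
        pub_b = find_public_sequences(cts, "beta")
        fractions, median = shared_fraction_per_patient(cts, pub_a, pub_b)
        # P1: 4 of 7 clonotypes carry the shared beta; P2: all 3 do
        assert fractions["P1"] == pytest.approx(4 / 7)
        assert fractions["P2"] == pytest.approx(1.0)

    def test_patient_sharing_nothing_scores_zero(self):
        cts = [make_ct("c0", patient="P1"),
               make_ct("c1", patient="P2", beta_v="TRBV5-1",
                       beta_aa="ASGELSNQPQH", alpha_v="TRAV4",
                       alpha_aa="AVRDTGGYKVV")]
        fractions, _ = shared_fraction_per_patient(cts, [], [])
        assert fractions == {"P1": 0.0, "P2": 0.0}

    def test_patient_bins(self):
        cts = ([make_ct(f"a{i}", patient="P1") for i in range(5)]
               + [make_ct(f"b{i}", patient="P2") for i in range(150)])
        bins = bin_patients_by_size(cts, edges=(100,))
        assert bins == {"1-100": ["P1"], "101+": ["P2"]}


class TestAnnotateEpitopes:
    @pytest.fixture()
    def reference(self):
        return pd.DataFrame([
            {"clone_id": "TCC1", "patient_id": "r", "epitope": "DQ2.5-glia-a2",
             "alpha_v": "TRAV26-1", "alpha_j": "TRAJ20",
             "alpha_cdr3_aa": "IVSNDYKLSF",
             "beta_v": "TRBV7-2", "beta_j": "TRBJ2-3",
             "beta_cdr3_aa": "ASSIRATDTQY"},
            {"clone_id": "TCC2", "patient_id": "r", "epitope": "DQ2.5-glia-o2",
             "alpha_v": "TRAV26-1", "alpha_j": "TRAJ20",
             "alpha_cdr3_aa": "IVSNDYKLSF",
             "beta_v": "TRBV7-2", "beta_j": "TRBJ2-3",
             "beta_cdr3_aa": "ASSIRATDTQF"},  # one residue off TCC1
        ])

    def test_motif_annotation_collects_matching_clone_epitopes(self, reference):
        r_motif = next(m for m in load_established_motifs() if m.name == "R-motif")
        anns = annotate_motifs([r_motif], reference)
        assert anns[0].assignments == {"DQ2.5-glia-a2": "clone_exact"}

    def test_public_pair_exact_and_similar_evidence(self, reference):
        cts = [make_ct("c0", patient="P1"), make_ct("c1", patient="P2")]
        pairs = find_public_sequences(cts, "paired")
        anns = annotate_public_pairs(pairs, reference, max_mismatch=1)
        # TCC1 is an exact match, TCC2 differs by one beta residue
        assert anns[0].assignments["DQ2.5-glia-a2"] == "clone_exact"
        assert anns[0].assignments["DQ2.5-glia-o2"] == "clone_similar"

    def test_cross_reactive_epitopes_accumulate(self, reference):
        reference.loc[0, "epitope"] = "DQ2.5-glia-a1a/DQ2.5-glia-o1"
        r_motif = next(m for m in load_established_motifs() if m.name == "R-motif")
        anns = annotate_motifs([r_motif], reference)
        assert set(anns[0].epitopes) == {"DQ2.5-glia-a1a", "DQ2.5-glia-o1"}

    def test_missing_epitope_column_is_format_error(self, reference):
        broken = reference.drop(columns=["epitope"])
        with pytest.raises(FormatError, match="epitope"):
            annotate_motifs(load_established_motifs()[:1], broken)


class TestSearchExternalDb:
    @pytest.fixture()
    def db(self):
        return pd.DataFrame([
            # genuine R-motif rows, but CeD-labelled: excluded before search
            {"chain": "TRB", "cdr3_aa": "ASSIRATDTQY", "v_call": "TRBV7-2*01",
             "epitope": "gliadin peptide", "disease": "celiac disease"},
            # non-CeD beta row that matches nothing
            {"chain": "TRB", "cdr3_aa": "ASGELSNQPQH", "v_call": "TRBV5-1",
             "epitope": "M1 influenza", "disease": "influenza"},
            # alpha row matching the NDYKLS pattern and V gene
            {"chain": "TRA", "cdr3_aa": "IVNDYKLS", "v_call": "TRAV26-1",
             "epitope": "CMV pp65", "disease": "CMV"},
        ])

    def test_r_motif_absent_after_ced_exclusion(self, db):
        r_motif = next(m for m in load_established_motifs() if m.name == "R-motif")
        out = search_external_db([r_motif], db)
        assert out.set_index("motif_id").loc["R-motif", "n_matches"] == 0

    def test_planted_rows_counted(self, db):
        ndy = next(m for m in load_established_motifs() if m.name == "NDYKLS")
        extra = pd.concat([db] + [db.iloc[[2]]] * 3, ignore_index=True)
        out = search_external_db([ndy], extra)
        assert out.set_index("motif_id").loc["NDYKLS", "n_matches"] == 4

    def test_exclusion_can_be_disabled(self, db):
        r_motif = next(m for m in load_established_motifs() if m.name == "R-motif")
        out = search_external_db([r_motif], db, exclusion_keywords=())
        assert out.set_index("motif_id").loc["R-motif", "n_matches"] == 1


class TestGenerationProbability:
    @pytest.mark.parametrize("pa,pb,expected", [
        (1e-8, 1e-9, 1e-17),
        (0.5, 0.0, 0.0),
        (1.0, 0.37, 0.37),
    ])
    def test_product_rule(self, pa, pb, expected):
        assert paired_generation_probability(pa, pb) == pytest.approx(expected)

    @pytest.mark.parametrize("pa,pb", [(-0.1, 0.5), (0.5, 1.5), (float("nan"), 0.5)])
    def test_out_of_range_rejected(self, pa, pb):
        with pytest.raises(ValueError):
            paired_generation_probability(pa, pb)


def oracle_rank_test(x, y, alternative="greater"):
    """Exhaustive labeling oracle computing U from the pairwise definition."""
    def u_of(xs, ys):
        return sum((xi > yj) + 0.5 * (xi == yj) for xi in xs for yj in ys)
    pooled = list(x) + list(y)
    u_obs = u_of(x, y)
    n = len(x)
    hits = total = 0
    for combo in itertools.combinations(range(len(pooled)), n):
        xs = [pooled[i] for i in combo]
        ys = [pooled[i] for i in range(len(pooled)) if i not in combo]
        u = u_of(xs, ys)
        total += 1
        if alternative == "greater":
            hits += u >= u_obs
        else:
            hits += u <= u_obs
    return u_obs, hits / total


class TestComparePublicPrivate:
    def test_exact_small_sample_matches_enumeration_oracle(self):
        u, p = compare_public_private([3, 4, 5], [1, 2])
        u_ref, p_ref = oracle_rank_test([3, 4, 5], [1, 2])
        assert u == u_ref and p == pytest.approx(p_ref)

    def test_exact_path_handles_ties(self):
        rng = np.random.default_rng(17)
        for _ in range(5):
            x = list(rng.integers(0, 4, size=6))
            y = list(rng.integers(0, 4, size=5))
            u, p = compare_public_private(x, y)
            u_ref, p_ref = oracle_rank_test(x, y)
            assert u == u_ref and p == pytest.approx(p_ref)

    def test_shifted_sample_detected_with_high_power(self):
        rng = np.random.default_rng(23)
        rejected = 0
        for _ in range(50):
            pub = rng.normal(2.0, 1.0, size=100)
            priv = rng.normal(0.0, 1.0, size=100)
            _, p = compare_public_private(pub, priv)
            rejected += p < 0.05
        assert rejected >= 48  # >= 95% power at a +2 sigma shift

    def test_empty_sample_rejected(self):
        with pytest.raises(DegenerateInputError):
            compare_public_private([], [1.0])
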