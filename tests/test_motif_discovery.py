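"""Motif-node search, alignment, regex construction and motif matching."""

import re

import numpy as np
import pytest

from tcrmotif.cdr3_prep import prepare_clustering_set
from tcrmotif.distance_clustering import pairwise_distances, upgma
from tcrmotif.io_repertoire import Clonotype
from tcrmotif.motif_discovery import (AA_GROUPS, EstablishedMotif,
                                      align_members, build_regex,
                                      discover_motif_nodes,
                                      exclude_established,
                                      load_established_motifs, match_motif,
                                      motif_frequency, text_logo)

from conftest import make_chain


def make_clonotype(cid, patient="P1", beta_v="TRBV7-2", beta_aa="ASSIRATDTQY",
                   alpha_v="TRAV26-1", alpha_aa="IVSNDYKLSF", beta_j="TRBJ2-3",
                   alpha_j="TRAJ20"):
    beta = make_chain(chain="beta", v_gene=beta_v, j_gene=beta_j, cdr3_aa=beta_aa)
    alpha = make_chain(chain="alpha", v_gene=alpha_v, j_gene=alpha_j, cdr3_aa=alpha_aa)
    return Clonotype(clonotype_id=cid, patient_id=patient,
                     beta_key=beta.identity, beta=beta,
                     alpha_chains=[alpha], n_cells=1)


def cluster_fixture(clonotypes, chain_mode="beta", seed=0):
    items = prepare_clustering_set(clonotypes, chain_mode, seed=seed)
    seqs = ([(it.alpha, it.beta) for it in items] if chain_mode == "paired"
            else [it.alpha if chain_mode == "alpha" else it.beta for it in items])
    matrix = pairwise_distances(seqs, ids=[it.clonotype_id for it in items])
    return upgma(matrix), {it.clonotype_id: it.alpha_index for it in items}


class TestAminoAcidGroups:
    def test_groups_cover_alphabet_with_stated_overlaps(self):
        union = set().union(*(set(v) for v in AA_GROUPS.values()))
        assert union == set("ACDEFGHIKLMNPQRSTVWY")
        assert "Y" in AA_GROUPS["polar"] and "Y" in AA_GROUPS["amphipathic"]
        assert "M" in AA_GROUPS["amphipathic"] and "M" in AA_GROUPS["hydrophobic"]
        assert "W" in AA_GROUPS["amphipathic"] and "W" not in AA_GROUPS["polar"]


class TestAlignMembers:
    def test_identical_sequences_align_without_gaps(self):
        rows = align_members(["SIRATDTQ"] * 4)
        assert rows == ["SIRATDTQ"] * 4

    def test_single_deletion_gets_one_gap_column(self):
        rows = align_members(["SIRATDTQ", "SIRTDTQ"])
        assert rows[0] == "SIRATDTQ"
        assert rows[1].replace("-", "") == "SIRTDTQ"
        assert rows[1].count("-") == 1
        assert len(rows[0]) == len(rows[1]) == 8

    def test_rows_recover_inputs_and_width_bound(self):
        seqs = ["ASSIRATDTQY", "ASSLRQTDTQY", "ASSIRTDTQY", "ASSIRATDTQYV"]
        rows = align_members(seqs)
        assert len({len(r) for r in rows}) == 1
        assert len(rows[0]) >= max(map(len, seqs))
        for row, seq in zip(rows, seqs):
            assert row.replace("-", "") == seq

    def test_empty_input_rejected(self):
        from tcrmotif.io_repertoire import DegenerateInputError
        with pytest.raises(DegenerateInputError):
            align_members([])


class TestBuildRegex:
    @pytest.mark.parametrize("msa,expected", [
        (["ARDT", "AKDT"], "A[KRED]DT"),   # K,R both charged
        (["AYT", "AVT"], "A.T"),           # Y vs V share no group
        (["AST", "A-T"], "AS?T"),          # gapped column becomes optional
    ])
    def test_column_rules(self, msa, expected):
        assert build_regex(msa) == expected

    def test_group_priority_on_overlapping_residues(self):
        # Y and M: polar/amphipathic and amphipathic/hydrophobic; jointly
        # only amphipathic contains both
        assert build_regex(["Y", "M"]) == "[WYM]"
        # Y alone with another polar residue stays in the polar class
        assert build_regex(["YA", "SA"]) == "[QNHSTYC]A"

    def test_variable_gapped_column_renders_class_then_optional(self):
        assert build_regex(["AK", "AR", "A-"]) == "A[KRED]?"

    def test_members_match_their_own_pattern(self):
        seqs = ["ASSIRATDTQY", "ASSLRQTDTQY", "ASSIRTDTQY"]
        rows = align_members(seqs)
        pattern = build_regex(rows)
        for seq in seqs:
            assert re.fullmatch(pattern, seq)


class TestDiscoverMotifNodes:
    def test_coherent_node_emitted_and_search_stops(self):
        members = [make_clonotype(f"m{i}", beta_aa=f"ASSIR{c}TDTQY")
                   for i, c in enumerate("ADEFGH")]
        background = [make_clonotype("b0", beta_v="TRBV5-1", beta_aa="ASGELSNQPQH"),
                      make_clonotype("b1", beta_v="TRBV28", beta_aa="ASTPGGYSNQP")]
        cts = {c.clonotype_id: c for c in members + background}
        root, _ = cluster_fixture(list(cts.values()))
        cands = discover_motif_nodes(root, cts, cutoff=2.0, chain_mode="beta")
        assert len(cands) == 1
        assert sorted(cands[0].member_ids) == sorted(c.clonotype_id for c in members)
        # leaf-disjointness is trivial with one candidate; emitted node height
        # is at or below the cutoff
        assert cands[0].node_height <= 2.0

    def test_fewer_than_min_leaves_yields_nothing(self):
        members = [make_clonotype(f"m{i}", beta_aa=f"ASSIR{c}TDTQY")
                   for i, c in enumerate("ADEF")]  # only 4 leaves
        background = [make_clonotype("b0", beta_v="TRBV5-1", beta_aa="ASGELSNQPQH"),
                      make_clonotype("b1", beta_v="TRBV28", beta_aa="ASTPGGYSNQP")]
        cts = {c.clonotype_id: c for c in members + background}
        root, _ = cluster_fixture(list(cts.values()))
        assert discover_motif_nodes(root, cts, cutoff=2.0, chain_mode="beta") == []

    def test_v_gene_vs_v_subgroup_modes(self):
        # TRBV7-2 and TRBV7-3 share the TRBV7 subgroup but differ at gene level
        members = [make_clonotype(f"m{i}", beta_v="TRBV7-2" if i % 2 else "TRBV7-3",
                                  beta_aa=f"ASSIR{c}TDTQY")
                   for i, c in enumerate("ADEFGH")]
        background = [make_clonotype("b0", beta_v="TRBV5-1", beta_aa="ASGELSNQPQH"),
                      make_clonotype("b1", beta_v="TRBV28", beta_aa="ASTPGGYSNQP")]
        cts = {c.clonotype_id: c for c in members + background}
        root, _ = cluster_fixture(list(cts.values()))
        at_gene = discover_motif_nodes(root, cts, cutoff=2.0, chain_mode="beta",
                                       v_mode="gene")
        at_subgroup = discover_motif_nodes(root, cts, cutoff=2.0, chain_mode="beta",
                                           v_mode="subgroup")
        assert at_gene == []
        assert len(at_subgroup) == 1
        assert at_subgroup[0].v_constraint == {"beta": "TRBV7"}
        assert at_subgroup[0].size == 6

    def test_candidates_are_leaf_disjoint(self, small_clonotypes):
        clonotypes, _, _ = small_clonotypes
        cts = {c.clonotype_id: c for c in clonotypes}
        subset = list(cts.values())[:300]
        root, _ = cluster_fixture(subset)
        cands = discover_motif_nodes(root, cts, cutoff=2.0, chain_mode="beta")
        seen = set()
        for cand in cands:
            assert not (set(cand.member_ids) & seen)
            seen |= set(cand.member_ids)
            # self-consistency: every member matches its own pattern + V
            for cid in cand.member_ids:
                assert match_motif(cand, cts[cid])


class TestMatchMotif:
    @pytest.fixture()
    def r_motif(self):
        return next(m for m in load_established_motifs() if m.name == "R-motif")

    def test_r_motif_matches_canonical_sequence(self, r_motif):
        subject = make_chain(cdr3_aa="ASSIRATDTQY", v_gene="TRBV7-2")
        assert match_motif(r_motif, subject)

    def test_v_constraint_blocks_match(self, r_motif):
        subject = make_chain(cdr3_aa="ASSIRATDTQY", v_gene="TRBV5-1")
        assert not match_motif(r_motif, subject)

    def test_extended_r_motif_open_suffix(self):
        extended = next(m for m in load_established_motifs()
                        if m.name == "Extended R-motif")
        subject = make_chain(cdr3_aa="ASSLRWGEQF", v_gene="TRBV7-2")
        assert match_motif(extended, subject)

    def test_paired_motif_requires_both_chains(self):
        paired = next(m for m in load_established_motifs()
                      if m.name == "Paired R-motif")
        good = make_clonotype("x", beta_v="TRBV7-2", beta_aa="ASSIRATDTQY",
                              alpha_v="TRAV26-1")
        wrong_alpha = make_clonotype("y", beta_v="TRBV7-2", beta_aa="ASSIRATDTQY",
                                     alpha_v="TRAV4")
        assert match_motif(paired, good)
        assert not match_motif(paired, wrong_alpha)

    def test_established_library_reproduces_known_patterns(self):
        by_name = {m.name: m for m in load_established_motifs()}
        assert by_name["R-motif"].pattern == "ASS.R.TDTQY"
        assert by_name["R-motif"].v_genes == {"TRBV7-2", "TRBV7-3"}
        assert by_name["Extended R-motif"].pattern == "ASS.R.*"
        assert by_name["NDYKLS"].pattern == "I.NDYKLS"
        assert by_name["NDYKLS"].v_genes == {"TRAV26-1"}
        assert by_name["Paired R-motif"].partner_v_genes == {"TRAV26-1"}


class TestExcludeEstablished:
    def _candidate_with_members(self, n_matching, n_total):
        members = []
        for i in range(n_total):
            if i < n_matching:
                ct = make_clonotype(f"c{i}", beta_aa=f"ASS{'ADEFGH'[i]}RATDTQY")
            else:
                ct = make_clonotype(f"c{i}", beta_v="TRBV5-1",
                                    beta_aa="ASGELSNQPQH")
            members.append(ct)
        cts = {c.clonotype_id: c for c in members}
        from tcrmotif.motif_discovery import MotifCandidate
        cand = MotifCandidate(
            motif_id="test", chain_mode="beta", pattern_alpha=None,
            pattern_beta=".*", v_constraint={}, v_mode="gene",
            member_ids=tuple(cts), node_height=1.0)
        return cand, cts

    def test_fully_matching_candidate_removed(self):
        cand, cts = self._candidate_with_members(6, 6)
        kept, removed = exclude_established([cand], cts)
        assert kept == [] and removed[0][1] in ("R-motif", "Extended R-motif")

    def test_non_matching_candidate_kept(self):
        cand, cts = self._candidate_with_members(0, 6)
        kept, removed = exclude_established([cand], cts)
        assert len(kept) == 1 and removed == []

    def test_threshold_semantics_at_half_overlap(self):
        cand, cts = self._candidate_with_members(3, 6)
        kept, _ = exclude_established([cand], cts, overlap_threshold=0.5)
        assert kept == []
        kept, _ = exclude_established([cand], cts, overlap_threshold=0.6)
        assert len(kept) == 1


class TestMotifFrequency:
    def test_zero_when_nothing_matches(self):
        motif = EstablishedMotif(name="never", chain="beta", pattern="ZZZZ",
                                 v_genes=frozenset({"TRBV7-2"}))
        cts = [make_clonotype(f"c{i}") for i in range(5)]
        assert motif_frequency(motif, cts) == (0, 0.0)

    def test_count_matches_planted_truth(self, small_clonotypes, small_bundle):
        bundle, _ = small_bundle
        clonotypes, truth_by_key, _ = small_clonotypes
        r_spec = next(m for m in bundle.config.planted_motifs
                      if m.name == "R-motif-like")
        motif = r_spec.as_established()
        count, frac = motif_frequency(motif, clonotypes)
        planted = sum(1 for ct in clonotypes
                      if truth_by_key[(ct.patient_id,) + ct.beta_key].motif
                      == "R-motif-like")
        assert count >= planted  # every planted member matches ...
        # ... and near-misses are rare: background hits need the exact
        # template plus the same V gene
        assert count - planted <= 0.01 * len(clonotypes)

    def test_count_invariant_to_ordering(self):
        motif = next(m for m in load_established_motifs() if m.name == "R-motif")
        cts = [make_clonotype(f"c{i}", beta_aa=f"ASS{'ADEFGH'[i]}RATDTQY")
               for i in range(6)]
        fwd = motif_frequency(motif, cts)
        rev = motif_frequency(motif, list(reversed(cts)))
        assert fwd == rev

    def test_empty_set_rejected(self):
        from tcrmotif.io_repertoire import DegenerateInputError
        motif = load_established_motifs()[0]
        with pytest.raises(DegenerateInputError):
            motif_frequency(motif, [])


class TestTextLogo:
    def test_per_column_counts_most_common_first(self):
        logo = text_logo(["ARD", "AKD", "ARD"])
        lines = logo.splitlines()
        assert lines[0].split()[1] == "A:3"
        assert lines[1].split()[1] == "R:2"
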