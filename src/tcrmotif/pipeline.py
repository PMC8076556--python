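"""End-to-end analysis pipeline and command-line interface.

``run_pipeline`` wires the stages together: ingestion and clonotype calling,
CDR3 trimming, Levenshtein/UPGMA clustering per chain mode, recursive motif
discovery per (cutoff, V-mode) run, established-motif frequencies, public
sequence analysis, V-gene usage tables, epitope annotation, external-database
search and the public-vs-private generation-probability comparison.  All
randomness flows from one seed, so a rerun reproduces the report bundle
byte for byte.

Patients below ``min_clonotypes_for_clustering`` clonotypes are excluded from
clustering and motif discovery but retained in the public-sharing analysis.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import click
import pandas as pd
import yaml

from . import __version__
from .cdr3_prep import ClusterItem, prepare_clustering_set
from .distance_clustering import cut_tree, pairwise_distances, to_newick, upgma
from .io_repertoire import (Clonotype, Dialect, call_valid_cells,
                            clonotypes_from_frame, clonotypes_to_frame,
                            define_clonotypes, filter_chains,
                            read_rearrangements)
from .motif_discovery import (MotifCandidate, discover_motif_nodes,
                              exclude_established, load_established_motifs,
                              match_motif, motif_frequency, text_logo)
from .repertoire_stats import (annotate_motifs, annotate_public_pairs,
                               collapse_rare, compare_public_private,
                               find_public_sequences, read_genprob_table,
                               search_external_db, shared_fraction_per_patient,
                               vgene_usage)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunSpec:
    """One motif-discovery run: chain mode, cut-off distance, V-gene mode."""

    chain_mode: str  # alpha | beta | paired
    cutoff: float
    v_mode: str = "gene"  # gene | subgroup

    @property
    def tag(self) -> str:
        return f"{self.chain_mode}_cut{self.cutoff:g}_{self.v_mode}"


#: the default analysis runs: single-chain cutoffs 1.0 and 2.0, paired
#: cutoffs 2.0 and 4.0 (distances add over two chains), plus a V-subgroup
#: paired run at 8.0
DEFAULT_RUNS = (
    RunSpec("alpha", 1.0), RunSpec("alpha", 2.0),
    RunSpec("beta", 1.0), RunSpec("beta", 2.0),
    RunSpec("paired", 2.0), RunSpec("paired", 4.0),
    RunSpec("paired", 8.0, "subgroup"),
)


@dataclass
class PipelineConfig:
    rearrangements: str | Path = ""
    reference_clones: str | Path | None = None
    external_db: str | Path | None = None
    genprob: str | Path | None = None
    outdir: str | Path = "out"
    min_reads: int = 50
    dual_min_fraction: float = 0.10
    min_trimmed_len: int = 8
    min_clonotypes_for_clustering: int = 20
    min_leaves: int = 5
    established_overlap: float = 0.5
    runs: Sequence[RunSpec] = DEFAULT_RUNS
    junction_is_full: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        runs = raw.pop("runs", None)
        cfg = cls(**raw)
        if runs is not None:
            cfg.runs = tuple(RunSpec(**r) for r in runs)
        return cfg


@dataclass
class PipelineResult:
    """In-memory handles on everything the pipeline wrote."""

    clonotypes: list[Clonotype]
    clustering_clonotypes: list[Clonotype]
    candidates: dict[str, list[MotifCandidate]]  # run tag -> kept candidates
    removed: dict[str, list[tuple[str, str, float]]]
    public: dict[str, list]
    shared_fractions: dict[str, float]
    median_shared: float
    manifest: dict
    outdir: Path


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed,
                      "config": _config_dict(config), "stages": {}}

    # --- ingest ---------------------------------------------------------------
    records, rejects = read_rearrangements(
        config.rearrangements, Dialect(junction_is_full=config.junction_is_full))
    accepted = filter_chains(records, min_reads=config.min_reads,
                             dual_min_fraction=config.dual_min_fraction)
    cells = call_valid_cells(accepted)
    valid_cells = [c for c in cells if c.valid]
    clonotypes = define_clonotypes(valid_cells)
    if not clonotypes:
        raise StageError("ingest", "no clonotypes called from input")
    n_accepted = sum(len(v) for v in accepted.values())
    manifest["stages"]["ingest"] = {
        "rows": len(records) + len(rejects), "records": len(records),
        "rejects": len(rejects), "accepted_chains": n_accepted,
        "cells": len(cells), "valid_cells": len(valid_cells),
        "clonotypes": len(clonotypes),
    }
    clonotypes_to_frame(clonotypes).to_csv(outdir / "clonotypes.tsv",
                                           sep="\t", index=False)
    if rejects:
        pd.DataFrame(rejects, columns=["row", "reason"]).to_csv(
            outdir / "rejects.tsv", sep="\t", index=False)

    # --- clustering subset ----------------------------------------------------
    per_patient = pd.Series([ct.patient_id for ct in clonotypes]).value_counts()
    included = set(per_patient[per_patient >= config.min_clonotypes_for_clustering].index)
    clustering_cts = [ct for ct in clonotypes if ct.patient_id in included]
    by_id = {ct.clonotype_id: ct for ct in clonotypes}
    manifest["stages"]["clustering_subset"] = {
        "patients_total": int(per_patient.size),
        "patients_included": len(included),
        "clonotypes_included": len(clustering_cts),
    }

    established = load_established_motifs()
    candidates: dict[str, list[MotifCandidate]] = {}
    removed: dict[str, list] = {}
    trees = {}
    items_by_mode: dict[str, list[ClusterItem]] = {}

    for mode in sorted({r.chain_mode for r in config.runs}):
        items = prepare_clustering_set(clustering_cts, mode,
                                       min_trimmed_len=config.min_trimmed_len,
                                       seed=config.seed)
        if len(items) < 2:
            raise StageError("cluster", f"fewer than 2 sequences in mode {mode}")
        items_by_mode[mode] = items
        seqs = ([(it.alpha, it.beta) for it in items] if mode == "paired"
                else [it.alpha if mode == "alpha" else it.beta for it in items])
        matrix = pairwise_distances(seqs, ids=[it.clonotype_id for it in items])
        trees[mode] = upgma(matrix)
        (outdir / f"dendrogram_{mode}.nwk").write_text(to_newick(trees[mode]))
        manifest["stages"][f"cluster_{mode}"] = {"sequences": len(items)}

    for run in config.runs:
        items = items_by_mode[run.chain_mode]
        alpha_choice = {it.clonotype_id: it.alpha_index for it in items}
        clusters = cut_tree(trees[run.chain_mode], run.cutoff)
        pd.DataFrame(
            [{"cluster": k, "clonotype_id": cid}
             for k, cl in enumerate(clusters) for cid in cl]
        ).to_csv(outdir / f"clusters_{run.tag}.tsv", sep="\t", index=False)
        cands = discover_motif_nodes(
            trees[run.chain_mode], by_id, cutoff=run.cutoff,
            chain_mode=run.chain_mode, v_mode=run.v_mode,
            min_leaves=config.min_leaves, alpha_choice=alpha_choice,
            id_prefix=f"{run.tag}.m")
        kept, dropped = exclude_established(
            cands, by_id, established, overlap_threshold=config.established_overlap)
        candidates[run.tag] = kept
        removed[run.tag] = dropped
        _write_candidates(kept, outdir / f"motifs_{run.tag}.tsv")
        if dropped:
            pd.DataFrame(dropped, columns=["motif_id", "established_motif",
                                           "member_overlap"]).to_csv(
                outdir / f"motifs_removed_{run.tag}.tsv", sep="\t", index=False)
        with open(outdir / f"logos_{run.tag}.txt", "w") as fh:
            for cand in kept:
                for chain, rows in sorted(cand.msa.items()):
                    fh.write(f"# {cand.motif_id} {chain}\n{text_logo(rows)}\n\n")
        manifest["stages"][f"discover_{run.tag}"] = {
            "candidates": len(cands), "kept": len(kept), "removed": len(dropped)}

    # --- established-motif frequencies (among clustering clonotypes) ----------
    est_rows = []
    for motif in established:
        count, frac = motif_frequency(motif, clustering_cts)
        est_rows.append({"motif": motif.name, "count": count,
                         "total": len(clustering_cts), "fraction": frac})
    pd.DataFrame(est_rows).to_csv(outdir / "established_frequencies.tsv",
                                  sep="\t", index=False)

    # --- public sequences (all patients) ---------------------------------------
    public = {}
    for mode in ("alpha", "beta", "paired"):
        recs = find_public_sequences(clonotypes, mode)
        public[mode] = recs
        pd.DataFrame([{
            "identity": "|".join(map(str, r.identity_key)),
            "n_patients": len(r.patients), "n_clonotypes": r.n_clonotypes,
            "patients": ",".join(sorted(r.patients)),
        } for r in recs]).to_csv(outdir / f"public_{mode}.tsv", sep="\t", index=False)
    fractions, median_shared = shared_fraction_per_patient(
        clonotypes, public["alpha"], public["beta"])
    pd.DataFrame(sorted(fractions.items()),
                 columns=["patient_id", "shared_fraction"]).to_csv(
        outdir / "shared_fraction.tsv", sep="\t", index=False)
    manifest["stages"]["public"] = {
        "public_alpha": len(public["alpha"]), "public_beta": len(public["beta"]),
        "public_paired": len(public["paired"]),
        "median_shared_fraction": median_shared,
    }

    # --- V-gene usage -----------------------------------------------------------
    for mode in ("TRAV", "TRBV", "paired"):
        usage = vgene_usage(clonotypes, mode)
        collapse_rare(usage).to_csv(outdir / f"vusage_{mode}.tsv", sep="\t", index=False)
    public_paired_ids = {cid for r in public["paired"] for cid in r.clonotype_ids}
    if public_paired_ids:
        usage = vgene_usage([by_id[c] for c in sorted(public_paired_ids)], "paired")
        collapse_rare(usage).to_csv(outdir / "vusage_public_paired.tsv",
                                    sep="\t", index=False)

    # --- epitope annotation ------------------------------------------------------
    if config.reference_clones:
        reference = pd.read_csv(config.reference_clones, sep="\t", dtype=str)
        motif_pool = [c for tag in sorted(candidates) for c in candidates[tag]]
        ann = annotate_motifs(motif_pool + list(established), reference)
        ann += annotate_public_pairs(public["paired"], reference)
        pd.DataFrame([
            {"target": a.target_id, "epitope": epi, "evidence": ev}
            for a in ann for epi, ev in sorted(a.assignments.items())
        ]).to_csv(outdir / "epitope_annotations.tsv", sep="\t", index=False)

    # --- external database search -------------------------------------------------
    if config.external_db:
        db = pd.read_csv(config.external_db, sep="\t", dtype=str)
        motif_pool = [c for tag in sorted(candidates) for c in candidates[tag]]
        search_external_db(motif_pool + list(established), db).to_csv(
            outdir / "external_db_matches.tsv", sep="\t", index=False)

    # --- generation probabilities ---------------------------------------------------
    if config.genprob:
        _genprob_report(config, clonotypes, public, outdir)

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return PipelineResult(
        clonotypes=clonotypes, clustering_clonotypes=clustering_cts,
        candidates=candidates, removed=removed, public=public,
        shared_fractions=fractions, median_shared=median_shared,
        manifest=manifest, outdir=outdir)


def _write_candidates(cands: Sequence[MotifCandidate], path: Path) -> None:
    pd.DataFrame([{
        "motif_id": c.motif_id, "chain_mode": c.chain_mode,
        "pattern_alpha": c.pattern_alpha or "", "pattern_beta": c.pattern_beta or "",
        "v_constraint": "|".join(f"{k}={v}" for k, v in sorted(c.v_constraint.items())),
        "v_mode": c.v_mode, "size": c.size, "node_height": c.node_height,
        "members": ",".join(c.member_ids),
    } for c in cands]).to_csv(path, sep="\t", index=False)


def _genprob_report(config, clonotypes, public, outdir: Path) -> None:
    """Public-vs-private generation-probability comparison per sample/level."""
    from .repertoire_stats import GenProbRecord, _chain_key  # shared key definition

    gp_df = pd.read_csv(config.genprob, sep="\t", dtype={"p_alpha": float,
                                                         "p_beta": float})
    # probabilities may be keyed by pipeline clonotype id or by the defining
    # beta chain (patient_id + beta_cdr3_nt), which external tools know
    if "clonotype_id" in gp_df.columns:
        gp_by = {(str(r.clonotype_id), str(r.level)):
                 GenProbRecord(str(r.clonotype_id), str(r.level),
                               float(r.p_alpha), float(r.p_beta))
                 for r in gp_df.itertuples(index=False)}
    elif {"patient_id", "beta_cdr3_nt"} <= set(gp_df.columns):
        nt_to_id = {(ct.patient_id, ct.beta.cdr3_nt): ct.clonotype_id
                    for ct in clonotypes}
        gp_by = {}
        for r in gp_df.itertuples(index=False):
            cid = nt_to_id.get((str(r.patient_id), str(r.beta_cdr3_nt)))
            if cid is not None:
                gp_by[(cid, str(r.level))] = GenProbRecord(
                    cid, str(r.level), float(r.p_alpha), float(r.p_beta))
    else:
        read_genprob_table(config.genprob)  # raises the format error
    rows = []
    for level in ("aa", "nt"):
        key_fields = "vj_aa" if level == "aa" else "vj_nt"
        pub = {m: {r.identity_key for r in find_public_sequences(clonotypes, m, key_fields)}
               for m in ("alpha", "beta", "paired")}
        for sample in ("alpha", "beta", "paired"):
            pub_vals, priv_vals = [], []
            for ct in clonotypes:
                rec = gp_by.get((ct.clonotype_id, level))
                if rec is None:
                    continue
                if sample == "alpha":
                    is_pub = any(_chain_key(a, key_fields) in pub["alpha"]
                                 for a in ct.alpha_chains)
                    val = rec.p_alpha
                elif sample == "beta":
                    is_pub = _chain_key(ct.beta, key_fields) in pub["beta"]
                    val = rec.p_beta
                else:
                    bk = _chain_key(ct.beta, key_fields)
                    is_pub = any((_chain_key(a, key_fields), bk) in pub["paired"]
                                 for a in ct.alpha_chains)
                    val = rec.p_paired
                (pub_vals if is_pub else priv_vals).append(val)
            if pub_vals and priv_vals:
                u, p = compare_public_private(pub_vals, priv_vals)
                rows.append({
                    "sample": sample, "level": level,
                    "private_mean": float(pd.Series(priv_vals).mean()),
                    "private_n": len(priv_vals),
                    "public_mean": float(pd.Series(pub_vals).mean()),
                    "public_n": len(pub_vals), "U": u, "p_value": p,
                })
    pd.DataFrame(rows).to_csv(outdir / "genprob_comparison.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------

def _config_dict(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    d["runs"] = [dataclasses.asdict(r) for r in config.runs]
    # where outputs land is not an analysis parameter; keep the echo stable
    # across output locations so reruns are byte-identical
    d.pop("outdir")
    for key in ("rearrangements", "reference_clones", "external_db", "genprob"):
        if d[key] is not None:
            d[key] = str(d[key])
    return d


@click.group()
@click.option("-v", "--verbose", is_flag=True, help="Stage-level progress logging.")
def cli(verbose: bool) -> None:
    """CDR3 motif discovery and public-clonotype analysis for paired
    single-cell TCR repertoires."""
    logging.basicConfig(
        level=logging.INFO if verbose else logging.WARNING,
        format="%(levelname)s %(name)s: %(message)s")


@cli.command()
@click.option("--seed", type=int, default=0, show_default=True)
@click.option("--patients", type=int, default=30, show_default=True)
@click.option("--out", "outdir", type=click.Path(), required=True)
def simulate(seed: int, patients: int, outdir: str) -> None:
    """Generate a synthetic cohort with ground-truth labels."""
    from .synthetic_data import SyntheticConfig, generate_repertoire
    bundle = generate_repertoire(SyntheticConfig(seed=seed, n_patients=patients))
    bundle.write(outdir)
    click.echo(f"wrote {bundle.counts['clonotypes']} clonotypes "
               f"({bundle.counts['true_cells']} cells) to {outdir}")


@cli.command()
@click.argument("rearrangements", type=click.Path(exists=True))
@click.option("--out", "outdir", type=click.Path(), required=True)
@click.option("--min-reads", type=int, default=50, show_default=True)
@click.option("--dual-min-fraction", type=float, default=0.10, show_default=True)
def ingest(rearrangements, outdir, min_reads, dual_min_fraction):
    """Read a rearrangement TSV, apply filters and write the clonotype table."""
    records, rejects = read_rearrangements(rearrangements)
    accepted = filter_chains(records, min_reads=min_reads,
                             dual_min_fraction=dual_min_fraction)
    cells = call_valid_cells(accepted)
    clonotypes = define_clonotypes([c for c in cells if c.valid])
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    clonotypes_to_frame(clonotypes).to_csv(out / "clonotypes.tsv", sep="\t", index=False)
    click.echo(f"{len(records)} records, {len(rejects)} rejects, "
               f"{len(clonotypes)} clonotypes")


@cli.command("run-all")
@click.option("--config", "config_path", type=click.Path(exists=True),
              help="Pipeline config YAML.")
@click.option("--rearrangements", type=click.Path(exists=True))
@click.option("--reference-clones", type=click.Path(exists=True))
@click.option("--external-db", type=click.Path(exists=True))
@click.option("--genprob", type=click.Path(exists=True))
@click.option("--out", "outdir", type=click.Path())
@click.option("--seed", type=int, default=None)
def run_all(config_path, rearrangements, reference_clones, external_db,
            genprob, outdir, seed):
    """Run the full analysis and write the report bundle."""
    cfg = PipelineConfig.from_yaml(config_path) if config_path else PipelineConfig()
    if rearrangements:
        cfg.rearrangements = rearrangements
    if reference_clones:
        cfg.reference_clones = reference_clones
    if external_db:
        cfg.external_db = external_db
    if genprob:
        cfg.genprob = genprob
    if outdir:
        cfg.outdir = outdir
    if seed is not None:
        cfg.seed = seed
    if not cfg.rearrangements:
        raise click.UsageError("no rearrangement table given")
    try:
        result = run_pipeline(cfg)
    except (ValueError, FileNotFoundError) as exc:
        click.echo(f"validation error: {exc}", err=True)
        sys.exit(2)
    except StageError as exc:
        click.echo(str(exc), err=True)
        sys.exit(1)
    stages = result.manifest["stages"]
    click.echo(f"{stages['ingest']['clonotypes']} clonotypes; "
               f"median shared fraction {result.median_shared:.3f}; "
               f"reports in {result.outdir}")


@cli.command()
@click.argument("clonotype_table", type=click.Path(exists=True))
@click.option("--mode", type=click.Choice(["alpha", "beta", "paired"]),
              default="beta", show_default=True)
@click.option("--out", "outdir", type=click.Path(), required=True)
@click.option("--cutoff", type=float, multiple=True, default=(2.0,), show_default=True)
@click.option("--v-mode", type=click.Choice(["gene", "subgroup"]), default="gene")
@click.option("--seed", type=int, default=0)
def discover(clonotype_table, mode, outdir, cutoff, v_mode, seed):
    """Cluster a clonotype table and discover motif candidates."""
    df = pd.read_csv(clonotype_table, sep="\t", dtype=str)
    clonotypes = clonotypes_from_frame(df)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    items = prepare_clustering_set(clonotypes, mode, seed=seed)
    seqs = ([(it.alpha, it.beta) for it in items] if mode == "paired"
            else [it.alpha if mode == "alpha" else it.beta for it in items])
    matrix = pairwise_distances(seqs, ids=[it.clonotype_id for it in items])
    tree = upgma(matrix)
    (out / f"dendrogram_{mode}.nwk").write_text(to_newick(tree))
    by_id = {ct.clonotype_id: ct for ct in clonotypes}
    alpha_choice = {it.clonotype_id: it.alpha_index for it in items}
    for c in cutoff:
        cands = discover_motif_nodes(tree, by_id, cutoff=c, chain_mode=mode,
                                     v_mode=v_mode, alpha_choice=alpha_choice,
                                     id_prefix=f"{mode}_cut{c:g}_{v_mode}.m")
        kept, _ = exclude_established(cands, by_id)
        _write_candidates(kept, out / f"motifs_{mode}_cut{c:g}_{v_mode}.tsv")
        click.echo(f"cutoff {c:g}: {len(cands)} candidates, {len(kept)} kept")


@cli.command()
@click.argument("clonotype_table", type=click.Path(exists=True))
@click.option("--out", "outdir", type=click.Path(), required=True)
def stats(clonotype_table, outdir):
    """Public-sequence and V-usage statistics for a clonotype table."""
    df = pd.read_csv(clonotype_table, sep="\t", dtype=str)
    clonotypes = clonotypes_from_frame(df)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    public = {m: find_public_sequences(clonotypes, m)
              for m in ("alpha", "beta", "paired")}
    fractions, median_shared = shared_fraction_per_patient(
        clonotypes, public["alpha"], public["beta"])
    pd.DataFrame(sorted(fractions.items()),
                 columns=["patient_id", "shared_fraction"]).to_csv(
        out / "shared_fraction.tsv", sep="\t", index=False)
    for mode in ("TRAV", "TRBV", "paired"):
        collapse_rare(vgene_usage(clonotypes, mode)).to_csv(
            out / f"vusage_{mode}.tsv", sep="\t", index=False)
    click.echo(f"public alpha/beta/paired: {len(public['alpha'])}/"
               f"{len(public['beta'])}/{len(public['paired'])}; "
               f"median shared fraction {median_shared:.3f}")


if __name__ == "__main__":
    cli()
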