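"""End-to-end synthetic replay: families → profile search → alignment → SSN
→ genome neighbourhoods → cohort report.

``run_pipeline`` executes the stages in the order the analyses build on each
other, writing each stage's outputs as plain files into a run directory and
recording seeds, parameters and SHA-256 checksums in a JSON manifest.
Identical configs produce identical checksums.  A plain directory-of-files
design is deliberate: the value is the computation, not orchestration.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

import sqgsuite
from sqgsuite import pairalign, profsearch, ssn as ssn_mod, syndata
from sqgsuite.neighborhood import (
    cohort_report, features_to_frame, load_rules, write_gff3,
)
from sqgsuite.records import write_fasta
from sqgsuite.syndata import (
    FamilySpec, GenomeSpec, make_decoys, make_family, make_genome,
    seed_locus_of,
)

log = logging.getLogger("sqgsuite.pipeline")

STAGES = ("syndata", "profsearch", "pairalign", "ssn", "neighborhood",
          "report")


@dataclass
class RunConfig:
    """Seeds, sizes and thresholds for one reproducible pipeline run."""

    seed: int = 0
    stages: tuple[str, ...] = STAGES
    # synthetic world
    n_families: int = 2
    family_size: int = 12
    family_identity: float = 80.0
    family_inter_identity: float = 30.0
    seq_length: int = 200
    n_decoys: int = 40
    genomes_per_pathway: int = 4
    n_background_genes: int = 25
    # analysis knobs
    evalue_cutoff: float = 1e-3
    calibration_decoys: int = 150
    max_iters: int = 6
    as_grid: tuple[float, ...] = tuple(float(t) for t in range(0, 310, 15))
    betweenness_collapse_fraction: float = 0.1
    rules_path: str | None = None

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stage name(s): {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**raw)
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Run the configured stages; returns the manifest (also written as
    ``manifest.json`` in the run directory)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": sqgsuite.__version__,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "stages": {},
        "checksums": {},
    }
    (outdir / "config.json").write_text(
        json.dumps(manifest["config"], indent=2, sort_keys=True)
    )

    state: dict = {}
    for stage in STAGES:
        if stage not in config.stages:
            continue
        t0 = time.perf_counter()
        log.info("stage %s started", stage)
        _STAGE_FUNCS[stage](config, outdir, state)
        manifest["stages"][stage] = {
            "wall_time_s": round(time.perf_counter() - t0, 3),
        }
        log.info("stage %s finished", stage)

    for path in sorted(outdir.glob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest["checksums"][path.name] = _sha256(path)
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True)
    )
    return manifest


def _stage_syndata(cfg: RunConfig, outdir: Path, state: dict) -> None:
    families = []
    for f in range(cfg.n_families):
        spec = FamilySpec(
            n_members=cfg.family_size,
            target_intra_identity=cfg.family_identity,
            length=cfg.seq_length,
            seed=cfg.seed * 1000 + f,
            prefix=f"fam{f}",
            taxonomy=f"taxon_{f}",
        )
        families.append(make_family(spec))
    all_family = [r for fam in families for r in fam]
    decoys = make_decoys(all_family, cfg.n_decoys, seed=cfg.seed * 1000 + 99)
    write_fasta(all_family + decoys, outdir / "sequences.fasta")
    state["families"] = families
    state["decoys"] = decoys

    genomes, seeds, labels = [], [], []
    pathways = ("sulfo-EMP", "sulfo-ED", "sulfo-SFT", "sulfo-SMO",
                "sulfo-SDO", "none")
    for p_i, pathway in enumerate(pathways):
        for g_i in range(cfg.genomes_per_pathway):
            spec = GenomeSpec(
                pathway_label=pathway,
                n_background_genes=cfg.n_background_genes,
                include_gh188=pathway != "none",
                include_gh31=False,
                seed=cfg.seed * 10000 + p_i * 100 + g_i,
            )
            feats = make_genome(spec)
            genomes.append(feats)
            seeds.append(seed_locus_of(feats))
            labels.append(pathway)
    all_feats = [f for g in genomes for f in g]
    write_gff3(all_feats, outdir / "genomes.gff3")
    state["genomes"], state["genome_seeds"] = genomes, seeds
    state["genome_labels"] = labels


def _stage_profsearch(cfg: RunConfig, outdir: Path, state: dict) -> None:
    family0 = state["families"][0]
    database = [r for fam in state["families"] for r in fam] + state["decoys"]
    seed_msa = [(r.id, r.seq) for r in family0[:4]]  # unaligned=trivially aligned
    result = profsearch.iterate_to_convergence(
        seed_msa, database,
        evalue_cutoff=cfg.evalue_cutoff,
        max_iters=cfg.max_iters,
        n_decoys=cfg.calibration_decoys,
        seed=cfg.seed,
    )
    pd.DataFrame({
        "iteration": range(1, len(result.set_sizes) + 1),
        "set_size": result.set_sizes,
    }).to_csv(outdir / "profsearch_iterations.csv", index=False)
    (outdir / "profsearch_family.txt").write_text(
        "\n".join(result.final_ids) + "\n"
    )
    state["profsearch"] = result


def _stage_pairalign(cfg: RunConfig, outdir: Path, state: dict) -> None:
    records = [r for fam in state["families"] for r in fam]
    pairs = pairalign.all_vs_all(records, mode="local")
    pairalign.write_edges_tsv(pairs, outdir / "edges.tsv")
    state["edges"] = pairs
    state["records"] = records


def _stage_ssn(cfg: RunConfig, outdir: Path, state: dict) -> None:
    sweep = ssn_mod.select_threshold(
        cfg.as_grid, state["edges"],
        collapse_fraction=cfg.betweenness_collapse_fraction,
    )
    sweep.table.to_csv(outdir / "ssn_sweep.csv", index=False)
    threshold = (sweep.selected if sweep.selected is not None
                 else max(cfg.as_grid))
    graph = ssn_mod.build_graph(state["edges"], threshold)
    metadata = pd.DataFrame(
        {"taxonomy": {r.id: r.taxonomy or "unannotated"
                      for r in state["records"]}}
    )
    ssn_mod.annotate_and_export(
        graph, metadata, "taxonomy",
        xgmml_path=outdir / "ssn.xgmml",
        graphml_path=outdir / "ssn.graphml",
    )
    state["ssn"] = graph
    state["ssn_sweep"] = sweep


def _stage_neighborhood(cfg: RunConfig, outdir: Path, state: dict) -> None:
    rules = load_rules(cfg.rules_path)
    per_genome, summary = cohort_report(
        state["genomes"], state["genome_seeds"], rules
    )
    per_genome.to_csv(outdir / "pathway_calls.csv", index=False)
    summary.to_csv(outdir / "pathway_summary.csv", index=False)
    state["pathway_calls"] = per_genome
    state["pathway_summary"] = summary


def _stage_report(cfg: RunConfig, outdir: Path, state: dict) -> None:
    report = {
        "n_sequences": len(state.get("records", [])),
        "profsearch": {
            "status": state["profsearch"].status,
            "n_iterations": state["profsearch"].n_iterations,
            "family_size": len(state["profsearch"].final_ids),
        } if "profsearch" in state else None,
        "ssn": {
            "selected_threshold": state["ssn_sweep"].selected,
            "n_clusters": len(state["ssn"].clusters()),
        } if "ssn" in state else None,
        "pathways": (state["pathway_summary"]
                     .to_dict(orient="records")
                     if "pathway_summary" in state else None),
    }
    (outdir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True)
    )


_STAGE_FUNCS = {
    "syndata": _stage_syndata,
    "profsearch": _stage_profsearch,
    "pairalign": _stage_pairalign,
    "ssn": _stage_ssn,
    "neighborhood": _stage_neighborhood,
    "report": _stage_report,
}
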