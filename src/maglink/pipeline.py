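"""End-to-end pipeline: simulate -> recruit -> ani -> cluster ->
pathways -> complement -> cooccur -> pangenome.

One YAML config drives a full run; every stochastic stage gets its own
seed derived from the master seed, and all seeds, input digests and the
config snapshot are recorded in a JSON run manifest.  Re-running with
the same config and seed reproduces every stage output byte for byte
(the manifest's timestamps are the only thing that differs).
"""

from __future__ import annotations

import hashlib
import logging
import time
from pathlib import Path

import numpy as np
import yaml

from . import io
from .ani import ani_matrix, cluster_populations
from .complementarity import build_complementarity, community_sufficiency
from .cooccurrence import (order_by_hclust, promiscuity_summary,
                           significant_partners, spearman_matrix)
from .errors import ConfigError
from .pangenome import GeneFamilyMatrix, pangenome_summary
from .pathways import auxotrophy_profile, default_markers, default_panel
from .recruitment import major_members, pseudo_map, recruitment_fractions
from .synthetic import simulate_community, simulate_reads, simulate_time_series

log = logging.getLogger(__name__)

__version__ = "0.1.0"

STAGES = ("simulate", "recruit", "ani", "cluster", "pathways",
          "complement", "cooccur", "pangenome")

_DEFAULTS = {
    "culture_id": "culture",
    "recruit": {"kmer": 21, "major_threshold": 0.01, "min_contig_len": 1000},
    "ani": {"threshold": 97.0, "distinct_below": 90.0, "fragment_len": 1020},
    "cooccur": {"n_permutations": 199, "rho_min": 0.5, "q_max": 0.05},
    "pangenome": {"core_fraction": 1.0},
}


def validate_config(config: dict) -> dict:
    """Validate and fill defaults; raises ConfigError naming the
    offending key.  Validation runs before any stage."""
    if not isinstance(config, dict):
        raise ConfigError("config must be a mapping")
    cfg = {**config}
    if "seed" not in cfg:
        raise ConfigError("missing required key 'seed'")
    if not isinstance(cfg["seed"], int):
        raise ConfigError("'seed' must be an integer")
    for section, defaults in _DEFAULTS.items():
        if isinstance(defaults, dict):
            merged = {**defaults, **(cfg.get(section) or {})}
            unknown = set(merged) - set(defaults)
            if unknown:
                raise ConfigError(f"unknown key '{section}.{sorted(unknown)[0]}'")
            cfg[section] = merged
        else:
            cfg.setdefault(section, defaults)
    if "simulate" not in cfg:
        raise ConfigError("missing required section 'simulate'")
    sim = cfg["simulate"]
    com = sim.get("community")
    if not com:
        raise ConfigError("missing required section 'simulate.community'")
    for key in ("n_populations", "members_per_population",
                "within_divergence", "between_divergence"):
        if key not in com:
            raise ConfigError(f"missing required key 'simulate.community.{key}'")
    if not com["between_divergence"] > com["within_divergence"]:
        raise ConfigError(
            "'simulate.community.between_divergence' must exceed "
            "'simulate.community.within_divergence'")
    if "reads" not in sim:
        raise ConfigError("missing required section 'simulate.reads'")
    if "time_series" not in sim:
        raise ConfigError("missing required section 'simulate.time_series'")
    ts = sim["time_series"]
    if ts.get("n_samples", 45) < 3:
        raise ConfigError("'simulate.time_series.n_samples' must be >= 3")
    return cfg


def load_config(path) -> dict:
    with open(path) as fh:
        return validate_config(yaml.safe_load(fh))


def _pathway_truth_from_config(com: dict, panel) -> dict[tuple[str, str], bool]:
    """Nested config mapping {population: {metabolite: bool}} ->
    flat (population, metabolite) -> bool; unlisted pairs are present."""
    truth: dict[tuple[str, str], bool] = {}
    n_pops = com["n_populations"]
    metabolites = [p.metabolite for p in panel]
    nested = com.get("pathway_truth") or {}
    for p in range(1, n_pops + 1):
        pop = f"pop{p}"
        for m in metabolites:
            truth[(pop, m)] = bool(nested.get(pop, {}).get(m, True))
    return truth


def _stage_seeds(master_seed: int) -> dict[str, int]:
    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(len(STAGES))
    return {stage: int(c.generate_state(1, dtype=np.uint32)[0] % (2**31))
            for stage, c in zip(STAGES, children)}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config, outdir) -> Path:
    """Run every stage; returns the output directory.

    ``config`` is a path to a YAML file or an already-validated dict.
    """
    if not isinstance(config, dict):
        cfg = load_config(config)
    else:
        cfg = validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(cfg["seed"])
    started = time.strftime("%Y-%m-%dT%H:%M:%S")
    panel = default_panel()
    markers = default_markers()
    culture = cfg["culture_id"]

    # ---- simulate -------------------------------------------------
    log.info("[simulate] building synthetic community")
    com_cfg = cfg["simulate"]["community"]
    truth = _pathway_truth_from_config(com_cfg, panel)
    community = simulate_community(
        n_populations=com_cfg["n_populations"],
        members_per_population=com_cfg["members_per_population"],
        within_divergence=com_cfg["within_divergence"],
        between_divergence=com_cfg["between_divergence"],
        pathway_truth=truth, seed=seeds["simulate"],
        genome_length=com_cfg.get("genome_length", 20_000),
        gc=com_cfg.get("gc", 0.5), panel=panel,
        proportions=com_cfg.get("proportions"))
    reads_cfg = cfg["simulate"]["reads"]
    reads = simulate_reads(community, n_reads=reads_cfg["n_reads"],
                           read_length=reads_cfg["read_length"],
                           error_rate=reads_cfg.get("error_rate", 0.005),
                           seed=seeds["simulate"] + 1)
    ts_cfg = cfg["simulate"]["time_series"]
    n_focal = ts_cfg.get("n_focal", len(community.genomes))
    n_env = ts_cfg["n_environment"]
    n_blocks = ts_cfg.get("n_blocks", 3)
    blocks = {f"culture_{i:02d}": f"block{i % n_blocks}" for i in range(1, n_focal + 1)}
    blocks.update({f"ts_{j:02d}": f"block{j % n_blocks}" for j in range(1, n_env + 1)})
    series = simulate_time_series(
        n_focal=n_focal, n_environment=n_env, n_samples=ts_cfg["n_samples"],
        block_assignments=blocks, block_rho=ts_cfg.get("block_rho", 0.8),
        seed=seeds["simulate"] + 2)
    # partner taxonomy groups deliberately cut across correlation blocks
    taxonomy = {t: f"taxgroup_{hash_group(t)}" for t in series.taxon_ids}

    io.write_genomes_fasta(community.genomes, outdir / "genomes.fasta")
    io.write_annotations_tsv({g.id: g.gene_families for g in community.genomes},
                             outdir / "annotations.tsv")
    io.write_reads_fasta(reads, outdir / "reads.fasta")
    io.write_abundance_tsv(series, outdir / "time_series.tsv")
    io.write_taxonomy_tsv(taxonomy, outdir / "taxonomy.tsv")
    io.write_taxonomy_tsv(community.true_population, outdir / "true_populations.tsv")
    io.write_fractions_tsv(community.true_proportions, outdir / "true_proportions.tsv")

    # ---- recruit --------------------------------------------------
    log.info("[recruit] pseudo-mapping %d reads", len(reads.reads))
    counts, unassigned = pseudo_map(reads, community.genomes,
                                    k=cfg["recruit"]["kmer"])
    fractions = recruitment_fractions(counts)
    majors = major_members(fractions, cfg["recruit"]["major_threshold"])
    io.write_counts_tsv(counts, outdir / "recruit_counts.tsv", unassigned=unassigned)
    io.write_fractions_tsv(fractions, outdir / "recruit_fractions.tsv")
    (outdir / "major_members.tsv").write_text(
        "genome_id\n" + "".join(f"{g}\n" for g in sorted(majors)))

    # ---- ani + cluster -------------------------------------------
    log.info("[ani] pairwise fragment ANI over %d genomes", len(community.genomes))
    matrix = ani_matrix(community.genomes)
    io.write_ani_tsv(matrix, outdir / "ani_matrix.tsv")
    clustering = cluster_populations(matrix, cfg["ani"]["threshold"])
    io.write_clustering_tsv(clustering, outdir / "populations.tsv")

    # ---- pathways -------------------------------------------------
    log.info("[pathways] auxotrophy profiles")
    profiles = [auxotrophy_profile(g.id, g.gene_families, panel, markers)
                for g in community.genomes]
    io.write_profiles_tsv(profiles, outdir / "auxotrophy_profiles.tsv")

    # ---- complement ----------------------------------------------
    log.info("[complement] complementarity graphs")
    major_profiles = [p for p in profiles if p.genome_id in majors] or profiles
    graphs = [build_complementarity(major_profiles, pw.metabolite, culture_id=culture)
              for pw in panel]
    io.write_edges_tsv(graphs, outdir / "complementarity_edges.tsv")
    graphml_dir = outdir / "graphml"
    graphml_dir.mkdir(exist_ok=True)
    for g in graphs:
        io.write_graphml(g, graphml_dir / f"{culture}_{g.metabolite}.graphml")
    report = community_sufficiency(major_profiles,
                                   [p.metabolite for p in panel], culture_id=culture)
    io.write_sufficiency_tsv([report], outdir / "sufficiency.tsv")

    # ---- cooccur --------------------------------------------------
    log.info("[cooccur] Spearman matrix, %d permutations",
             cfg["cooccur"]["n_permutations"])
    focal_taxa = [t for t in series.taxon_ids if t.startswith("culture_")]
    env_taxa = [t for t in series.taxon_ids if t.startswith("ts_")]
    result = spearman_matrix(series.subset_taxa(focal_taxa),
                             series.subset_taxa(env_taxa),
                             n_permutations=cfg["cooccur"]["n_permutations"],
                             seed=seeds["cooccur"])
    result = order_by_hclust(result)
    io.write_correlation_tsvs(result, outdir)
    partners = significant_partners(result, rho_min=cfg["cooccur"]["rho_min"],
                                    q_max=cfg["cooccur"]["q_max"])
    io.write_partners_tsv(partners, outdir / "partners.tsv")
    summary = promiscuity_summary(partners, taxonomy)
    summary.to_frame().to_csv(outdir / "promiscuity.tsv", sep="\t", index=False)

    # ---- pangenome ------------------------------------------------
    log.info("[pangenome] core/flexible partition")
    gfm = GeneFamilyMatrix.from_annotations(
        {g.id: g.gene_families for g in community.genomes})
    io.write_presence_tsv(gfm, outdir / "gene_presence.tsv")
    core = sorted(pangenome_summary(gfm, cfg["pangenome"]["core_fraction"]).items())
    (outdir / "pangenome_summary.tsv").write_text(
        "metric\tvalue\n" + "".join(f"{k}\t{v:.10g}\n" for k, v in core))

    manifest = {
        "tool": "maglink",
        "version": __version__,
        "config": cfg,
        "stage_seeds": seeds,
        "input_digests": {p.name: _sha256(p) for p in sorted(outdir.glob("*.tsv"))},
        "started": started,
        "finished": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    io.write_manifest(manifest, outdir / "manifest.json")
    return outdir


def hash_group(taxon_id: str, n_groups: int = 4) -> int:
    """Stable small group index for a taxon id (used to assign
    taxonomy labels that cut across correlation blocks)."""
    digest = hashlib.sha256(taxon_id.encode()).digest()
    return digest[0] % n_groups
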