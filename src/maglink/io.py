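"""Readers and writers for every on-disk form the pipeline uses.

All tables are tab-separated with one header row; "NA" is the only
missing-value token.  FASTA goes through Biopython; graphs are written
as GraphML via networkx.  Every writer has a matching reader and the
pair round-trips (read(write(x)) == x).
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .ani import ANIMatrix, PopulationClustering
from .complementarity import ComplementarityGraph, SufficiencyReport
from .cooccurrence import CorrelationResult
from .errors import ParseError
from .pangenome import GeneFamilyMatrix
from .pathways import AuxotrophyProfile
from .synthetic import Genome, ReadSet
from .tables import AbundanceTable

NA = "NA"
ORIGIN_TOKEN = "origin="


# ---------------------------------------------------------------- FASTA

def write_genomes_fasta(genomes: list[Genome], path) -> None:
    records = [SeqRecord(Seq(g.sequence), id=g.id, description="") for g in genomes]
    SeqIO.write(records, str(path), "fasta")


def read_genomes_fasta(path) -> list[Genome]:
    """Read genomes from FASTA; lowercase bases are accepted and
    uppercased."""
    genomes = []
    for rec in SeqIO.parse(str(path), "fasta"):
        genomes.append(Genome(id=rec.id, sequence=str(rec.seq).upper()))
    if not genomes:
        raise ParseError(f"no FASTA records in {path}")
    return genomes


def write_reads_fasta(reads: ReadSet, path) -> None:
    """Reads as FASTA with the true origin recorded after a reserved
    header token."""
    records = [SeqRecord(Seq(seq), id=rid, description=f"{ORIGIN_TOKEN}{origin}")
               for rid, seq, origin in reads.reads]
    SeqIO.write(records, str(path), "fasta")


def read_reads_fasta(path) -> ReadSet:
    reads = []
    length = None
    for rec in SeqIO.parse(str(path), "fasta"):
        origin = ""
        for token in rec.description.split():
            if token.startswith(ORIGIN_TOKEN):
                origin = token[len(ORIGIN_TOKEN):]
        reads.append((rec.id, str(rec.seq).upper(), origin))
        length = len(rec.seq) if length is None else length
    if not reads:
        raise ParseError(f"no FASTA records in {path}")
    return ReadSet(reads=reads, read_length=length)


# ---------------------------------------------------------------- TSV

def _read_tsv(path, required: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", na_values=[NA], keep_default_na=False)
    except pd.errors.ParserError as e:
        raise ParseError(f"{path}: {e}") from e
    for col in required:
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    return df


def write_annotations_tsv(annotations: dict[str, set[str]], path) -> None:
    rows = [(g, f) for g in sorted(annotations) for f in sorted(annotations[g])]
    pd.DataFrame(rows, columns=["genome_id", "gene_family_id"]).to_csv(
        path, sep="\t", index=False)


def read_annotations_tsv(path) -> dict[str, set[str]]:
    df = _read_tsv(path, ["genome_id", "gene_family_id"])
    out: dict[str, set[str]] = {}
    for g, f in zip(df["genome_id"], df["gene_family_id"]):
        out.setdefault(str(g), set()).add(str(f))
    return out


def write_counts_tsv(counts: dict[str, int], path, unassigned: int | None = None) -> None:
    rows = sorted(counts.items())
    if unassigned is not None:
        rows.append(("__unassigned__", unassigned))
    pd.DataFrame(rows, columns=["taxon_id", "count"]).to_csv(path, sep="\t", index=False)


def read_counts_tsv(path) -> tuple[dict[str, int], int]:
    df = _read_tsv(path, ["taxon_id", "count"])
    counts = {str(t): int(c) for t, c in zip(df["taxon_id"], df["count"])}
    unassigned = counts.pop("__unassigned__", 0)
    return counts, unassigned


def write_fractions_tsv(fractions: dict[str, float], path) -> None:
    pd.DataFrame(sorted(fractions.items()), columns=["taxon_id", "fraction"]).to_csv(
        path, sep="\t", index=False, float_format="%.10g")


def read_fractions_tsv(path) -> dict[str, float]:
    df = _read_tsv(path, ["taxon_id", "fraction"])
    return {str(t): float(f) for t, f in zip(df["taxon_id"], df["fraction"])}


def write_abundance_tsv(table: AbundanceTable, path) -> None:
    df = table.to_frame()
    df.index.name = "sample"
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_abundance_tsv(path, kind: str) -> AbundanceTable:
    df = _read_tsv(path, ["sample"]).set_index("sample")
    return AbundanceTable(sample_ids=[str(i) for i in df.index],
                          taxon_ids=[str(c) for c in df.columns],
                          values=df.to_numpy(dtype=float), kind=kind)


def write_taxonomy_tsv(taxonomy: dict[str, str], path) -> None:
    pd.DataFrame(sorted(taxonomy.items()), columns=["taxon_id", "group"]).to_csv(
        path, sep="\t", index=False)


def read_taxonomy_tsv(path) -> dict[str, str]:
    df = _read_tsv(path, ["taxon_id", "group"])
    return {str(t): str(g) for t, g in zip(df["taxon_id"], df["group"])}


# ---------------------------------------------------------------- ANI

def write_ani_tsv(matrix: ANIMatrix, path) -> None:
    df = pd.DataFrame(matrix.values, index=matrix.ids, columns=matrix.ids)
    df.index.name = "genome_id"
    df.to_csv(path, sep="\t", na_rep=NA, float_format="%.6g")


def read_ani_tsv(path) -> ANIMatrix:
    df = _read_tsv(path, ["genome_id"]).set_index("genome_id")
    ids = [str(i) for i in df.index]
    if list(df.columns) != ids:
        raise ParseError(f"{path}: row and column labels differ; not a symmetric ANI matrix")
    values = df.to_numpy(dtype=float)
    frac = np.where(np.isfinite(values), 1.0, 0.0)
    return ANIMatrix(ids=ids, values=values, aligned_fraction=frac)


def write_clustering_tsv(clustering: PopulationClustering, path) -> None:
    rows = sorted(clustering.assignment.items())
    pd.DataFrame(rows, columns=["genome_id", "population_id"]).to_csv(
        path, sep="\t", index=False)


def read_clustering_tsv(path, threshold: float = float("nan")) -> PopulationClustering:
    df = _read_tsv(path, ["genome_id", "population_id"])
    return PopulationClustering(
        threshold=threshold,
        assignment={str(g): str(p) for g, p in zip(df["genome_id"], df["population_id"])})


def write_cross_match_tsv(matches: dict[str, tuple[str | None, float | None, str]],
                          path) -> None:
    rows = [(cid, best or NA, NA if ani is None else f"{ani:.4f}", status)
            for cid, (best, ani, status) in sorted(matches.items())]
    pd.DataFrame(rows, columns=["culture_genome", "best_environment_genome",
                                "ani", "status"]).to_csv(path, sep="\t", index=False)


# ------------------------------------------------------- complementarity

def write_edges_tsv(graphs: list[ComplementarityGraph], path) -> None:
    rows = [(g.culture_id, g.metabolite, d, r)
            for g in graphs for d, r in sorted(g.edges)]
    pd.DataFrame(rows, columns=["culture", "metabolite", "donor", "recipient"]).to_csv(
        path, sep="\t", index=False)


def write_graphml(graph: ComplementarityGraph, path) -> None:
    nx.write_graphml(graph.to_networkx(), str(path))


def write_sufficiency_tsv(reports: list[SufficiencyReport], path) -> None:
    rows = [{"culture": r.culture_id, **r.status} for r in reports]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_profiles_tsv(profiles: list[AuxotrophyProfile], path) -> None:
    """Genome x metabolite/function 0/1 matrix: 1 = prototroph or
    function present."""
    rows = []
    for p in profiles:
        row = {"genome_id": p.genome_id}
        for m, s in p.metabolite_status.items():
            row[m] = int(s == "prototroph")
        for f, s in p.function_status.items():
            row[f] = int(s == "present")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ----------------------------------------------------------- cooccurrence

def write_correlation_tsvs(result: CorrelationResult, outdir) -> None:
    outdir = Path(outdir)
    ordered = result.reordered()
    for name, df in (("rho", ordered.rho), ("p", ordered.p), ("q", ordered.q)):
        if df is None:
            continue
        out = df.copy()
        out.index.name = "focal_id"
        out.to_csv(outdir / f"correlation_{name}.tsv", sep="\t", na_rep=NA,
                   float_format="%.6g")


def write_partners_tsv(partners: dict[str, set[str]], path) -> None:
    rows = [(f, p) for f in sorted(partners) for p in sorted(partners[f])]
    pd.DataFrame(rows, columns=["focal_id", "partner_id"]).to_csv(
        path, sep="\t", index=False)


# -------------------------------------------------------------- pangenome

def write_presence_tsv(matrix: GeneFamilyMatrix, path) -> None:
    df = matrix.presence.astype(int)
    df.index.name = "genome_id"
    df.to_csv(path, sep="\t")


def read_presence_tsv(path) -> GeneFamilyMatrix:
    df = _read_tsv(path, ["genome_id"]).set_index("genome_id")
    return GeneFamilyMatrix(df.astype(bool))


def write_core_tsv(core: set[str], path) -> None:
    pd.DataFrame(sorted(core), columns=["gene_family_id"]).to_csv(
        path, sep="\t", index=False)


# --------------------------------------------------------------- manifest

def write_manifest(manifest: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_manifest(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
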