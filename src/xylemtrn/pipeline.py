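"""Staged pipeline runner: simulate -> deg -> cluster -> scan -> trn -> integrate.

Each stage reads the previous stage's files from the run directory, writes
its own outputs there, and records itself in ``manifest.json`` (inputs,
parameters, seed, package version), so any run is reproducible from its
manifest.  The :func:`report` function renders a human-readable summary of
whatever stages have completed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .catalog import GeneCatalog
from .errors import ValidationError
from .expression import (
    classify_trajectories,
    cluster_groups,
    differential_genes,
    select_upregulated_tfs,
    soft_cluster,
    standardize_profiles,
    write_matrix,
)
from .integration import concordance, differential_proteins, ptm_candidates
from .motifs import (
    default_motifs,
    element_profiles,
    load_motif_config,
    scan_promoters,
    write_bed,
)
from .simulate import generate_reference_dataset, read_fasta, write_fasta
from .trn import (
    assign_layers,
    build_edges,
    export_network,
    read_curated_edges,
    read_layer_overrides,
    read_network,
    summarize,
)

STAGES = ("simulate", "deg", "cluster", "scan", "trn", "integrate")


@dataclass
class RunConfig:
    """Paths, thresholds and seed for a pipeline run."""

    outdir: Path = Path("run")
    motif_config: Path | None = None
    layer_overrides: Path | None = None
    curated_edges: Path | None = None
    alpha_rna: float = 0.01
    lfc: float = 1.0
    alpha_prot: float = 0.05
    fc_prot: float = 2.0
    window: int = 2000
    c: int = 12
    m: float = 2.0
    epsilon: float = 0.25
    strands: str = "both"
    n_background: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        for name in ("alpha_rna", "lfc", "alpha_prot", "fc_prot", "window", "c", "m", "epsilon"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"config threshold {name} must be positive")

    def motifs(self):
        if self.motif_config is not None:
            return load_motif_config(self.motif_config)
        return default_motifs()

    def validate_window(self) -> None:
        longest = max(len(m) for m in self.motifs().values())
        if self.window < longest:
            raise ValidationError(
                f"window {self.window} is shorter than the longest motif ({longest} bp)"
            )


def _update_manifest(config: RunConfig, stage: str, outputs: list[str], inputs: list[str]) -> None:
    path = config.outdir / "manifest.json"
    manifest = json.loads(path.read_text()) if path.exists() else {
        "version": __version__,
        "seed": config.seed,
        "config": {},
        "stages": {},
    }
    cfg = dataclasses.asdict(config)
    manifest["config"] = {k: (str(v) if isinstance(v, Path) else v) for k, v in cfg.items()}
    manifest["stages"][stage] = {"inputs": inputs, "outputs": outputs}
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")


def _require(config: RunConfig, *names: str) -> list[Path]:
    paths = [config.outdir / n for n in names]
    for p in paths:
        if not p.exists():
            raise FileNotFoundError(f"required input {p} not found; run the earlier stage first")
    return paths


def run_stage(stage: str, config: RunConfig) -> list[str]:
    """Run one pipeline stage; returns the names of the files written."""
    if stage == "all":
        written: list[str] = []
        for s in STAGES:
            written += run_stage(s, config)
        return written
    if stage not in STAGES:
        raise ValidationError(f"unknown stage {stage!r}")
    config.outdir.mkdir(parents=True, exist_ok=True)
    out = config.outdir

    if stage == "simulate":
        config.validate_window()
        ds = generate_reference_dataset(
            seed=config.seed, n_background=config.n_background, window=config.window
        )
        ds.catalog.to_tsv(out / "catalog.tsv")
        write_fasta(ds.promoters, out / "promoters.fasta")
        write_matrix(ds.expression, out / "expression.tsv")
        write_matrix(ds.proteome, out / "proteome.tsv")
        pd.Series(ds.protein_gene_map, name="gene_id").rename_axis("protein_id").to_csv(
            out / "protein_gene_map.tsv", sep="\t"
        )
        ds.truth.to_json(out / "truth.json")
        outputs = [
            "catalog.tsv", "promoters.fasta", "expression.tsv", "proteome.tsv",
            "protein_gene_map.tsv", "truth.json",
        ]
        _update_manifest(config, stage, outputs, inputs=[])
        return outputs

    if stage == "deg":
        (expr_path, cat_path) = _require(config, "expression.tsv", "catalog.tsv")
        matrix = pd.read_csv(expr_path, sep="\t", index_col=0)
        catalog = GeneCatalog.from_tsv(cat_path)
        de = differential_genes(matrix, alpha=config.alpha_rna, lfc_threshold=config.lfc)
        de.rename_axis("gene_id").to_csv(out / "de_genes.tsv", sep="\t")
        upregulated = sorted(select_upregulated_tfs(de, catalog))
        (out / "upregulated_tfs.txt").write_text("\n".join(upregulated) + "\n")
        groups = classify_trajectories(matrix.loc[de.index[de["deg"]]], epsilon=config.epsilon)
        groups.rename_axis("gene_id").to_csv(out / "trajectory_groups.tsv", sep="\t")
        outputs = ["de_genes.tsv", "upregulated_tfs.txt", "trajectory_groups.tsv"]
        _update_manifest(config, stage, outputs, inputs=["expression.tsv", "catalog.tsv"])
        return outputs

    if stage == "cluster":
        (expr_path, de_path) = _require(config, "expression.tsv", "de_genes.tsv")
        matrix = pd.read_csv(expr_path, sep="\t", index_col=0)
        de = pd.read_csv(de_path, sep="\t", index_col=0)
        degs = matrix.loc[de.index[de["deg"]]]
        profiles, dropped = standardize_profiles(degs)
        table, fit = soft_cluster(
            profiles, c=config.c, m=config.m, seed=config.seed
        )
        table.rename_axis("gene_id").to_csv(out / "clusters.tsv", sep="\t")
        centers = cluster_groups(fit, epsilon=config.epsilon)
        (out / "cluster_groups.json").write_text(
            json.dumps({str(k): v for k, v in centers.items()}, indent=1) + "\n"
        )
        outputs = ["clusters.tsv", "cluster_groups.json"]
        _update_manifest(config, stage, outputs, inputs=["expression.tsv", "de_genes.tsv"])
        return outputs

    if stage == "scan":
        config.validate_window()
        (fasta_path, cat_path, up_path) = _require(
            config, "promoters.fasta", "catalog.tsv", "upregulated_tfs.txt"
        )
        promoters = read_fasta(fasta_path)
        catalog = GeneCatalog.from_tsv(cat_path)
        upregulated = set((up_path).read_text().split())
        motifs = config.motifs()
        hits = scan_promoters(promoters, motifs, strands=config.strands)
        write_bed(hits, out / "hits.bed")
        # profile everything that can enter the network: scanned TFs + effectors
        scanned_tfs = sorted(upregulated - {e.gene_id for e in catalog.with_role("WND")})
        effectors = [e.gene_id for e in catalog.with_role("CW_secondary", "CW_primary", "PCD")]
        subset = scanned_tfs + effectors
        subset_hits = [h for h in hits if h.gene_id in set(subset)]
        profiles, _ = element_profiles(subset_hits, list(motifs), subset)
        _, tf_partition = element_profiles(
            [h for h in subset_hits if h.gene_id in set(scanned_tfs)],
            list(motifs), scanned_tfs,
        )
        rows = [
            {
                "gene_id": g,
                **{f"n_{m.lower()}": profiles[g].count(m) for m in motifs},
            }
            for g in subset
        ]
        pd.DataFrame(rows).set_index("gene_id").to_csv(out / "element_profiles.tsv", sep="\t")
        (out / "element_partition.json").write_text(json.dumps(tf_partition, indent=1) + "\n")
        outputs = ["hits.bed", "element_profiles.tsv", "element_partition.json"]
        _update_manifest(
            config, stage, outputs,
            inputs=["promoters.fasta", "catalog.tsv", "upregulated_tfs.txt"],
        )
        return outputs

    if stage == "trn":
        (prof_path, cat_path, up_path) = _require(
            config, "element_profiles.tsv", "catalog.tsv", "upregulated_tfs.txt"
        )
        profiles = _read_profiles(prof_path)
        catalog = GeneCatalog.from_tsv(cat_path)
        upregulated = set((up_path).read_text().split())
        overrides = (
            read_layer_overrides(config.layer_overrides) if config.layer_overrides else None
        )
        curated = read_curated_edges(config.curated_edges) if config.curated_edges else ()
        nodes, unplaced = assign_layers(profiles, catalog, upregulated, overrides=overrides)
        edges = build_edges(nodes, profiles, curated=curated)
        export_network(nodes, edges, out / "trn.edges.tsv", fmt="edgelist")
        export_network(nodes, edges, out / "trn.graphml", fmt="graphml")
        export_network(nodes, edges, out / "trn.dot", fmt="dot")
        partition_path = out / "element_partition.json"
        partition = (
            json.loads(partition_path.read_text()) if partition_path.exists() else None
        )
        report_data = summarize(nodes, edges, unplaced, element_partition=partition)
        (out / "trn_summary.json").write_text(json.dumps(report_data, indent=1) + "\n")
        outputs = [
            "trn.edges.tsv", "trn.edges.nodes.tsv", "trn.graphml", "trn.dot",
            "trn_summary.json",
        ]
        _update_manifest(
            config, stage, outputs,
            inputs=["element_profiles.tsv", "catalog.tsv", "upregulated_tfs.txt"],
        )
        return outputs

    # integrate
    (prot_path, de_path, map_path) = _require(
        config, "proteome.tsv", "de_genes.tsv", "protein_gene_map.tsv"
    )
    proteome = pd.read_csv(prot_path, sep="\t", index_col=0)
    de = pd.read_csv(de_path, sep="\t", index_col=0)
    mapping = pd.read_csv(map_path, sep="\t", index_col=0)["gene_id"].to_dict()
    prot_de = differential_proteins(
        proteome, fc_threshold=config.fc_prot, alpha=config.alpha_prot
    )
    prot_de.rename_axis("protein_id").to_csv(out / "protein_de.tsv", sep="\t")
    table, summary = concordance(de, prot_de, mapping)
    table.to_csv(out / "concordance.tsv", sep="\t")
    (out / "concordance_summary.json").write_text(json.dumps(summary, indent=1) + "\n")
    (out / "ptm_candidates.txt").write_text("\n".join(ptm_candidates(table)) + "\n")
    outputs = [
        "protein_de.tsv", "concordance.tsv", "concordance_summary.json",
        "ptm_candidates.txt",
    ]
    _update_manifest(
        config, stage, outputs,
        inputs=["proteome.tsv", "de_genes.tsv", "protein_gene_map.tsv"],
    )
    return outputs


def _read_profiles(path: Path):
    from .motifs import ElementProfile

    df = pd.read_csv(path, sep="\t", index_col=0)
    profiles = {}
    for gene_id, row in df.iterrows():
        counts = {col[2:].upper(): int(v) for col, v in row.items() if col.startswith("n_")}
        profiles[gene_id] = ElementProfile(gene_id, counts)
    return profiles


def report(run_dir: str | Path) -> str:
    """Human-readable summary of a (possibly partial) run directory."""
    run_dir = Path(run_dir)
    if not run_dir.exists() or not any(run_dir.iterdir()):
        raise ValidationError(f"{run_dir} is not a populated run directory")
    lines = [f"Run report: {run_dir}"]

    manifest_path = run_dir / "manifest.json"
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
        lines.append(
            f"  version {manifest['version']}, seed {manifest['seed']}, "
            f"stages: {', '.join(manifest['stages'])}"
        )
    else:
        lines.append("  warning: no manifest.json")

    de_path = run_dir / "de_genes.tsv"
    if de_path.exists():
        de = pd.read_csv(de_path, sep="\t", index_col=0)
        lines.append(f"  DEGs: {int(de['deg'].sum())} of {len(de)} genes")
        for tag in ("2v1", "3v1"):
            up = int((de[f"direction_{tag}"] == "up").sum())
            down = int((de[f"direction_{tag}"] == "down").sum())
            lines.append(f"    {tag}: {up} up, {down} down")
    up_path = run_dir / "upregulated_tfs.txt"
    if up_path.exists():
        lines.append(f"  upregulated TFs: {len(up_path.read_text().split())}")

    cl_path = run_dir / "clusters.tsv"
    if cl_path.exists():
        clusters = pd.read_csv(cl_path, sep="\t", index_col=0)
        sizes = clusters["cluster_id"].value_counts().sort_index()
        lines.append(
            "  cluster sizes: "
            + ", ".join(f"{k}:{v}" for k, v in sizes.items())
        )

    part_path = run_dir / "element_partition.json"
    if part_path.exists():
        part = json.loads(part_path.read_text())
        lines.append(
            f"  scanned-TF element partition: {part['snbe_only']} SNBE-only, "
            f"{part['smre_only']} SMRE-only, {part['both']} both, "
            f"{part['neither']} neither"
        )

    trn_path = run_dir / "trn_summary.json"
    if trn_path.exists():
        s = json.loads(trn_path.read_text())
        per_layer = ", ".join(f"L{k}:{v}" for k, v in sorted(s["per_layer"].items()))
        lines.append(
            f"  TRN: {s['n_nodes']} nodes ({per_layer}), {s['n_edges']} edges, "
            f"{s['n_unplaced']} unplaced TFs"
        )

    conc_path = run_dir / "concordance_summary.json"
    if conc_path.exists():
        c = json.loads(conc_path.read_text())
        lines.append(
            f"  transcript-protein concordance: {c['consistent']} consistent, "
            f"{c['discordant']} discordant, {c['untestable']} untestable"
        )

    missing = [s for s in STAGES if s not in (manifest_path.exists() and json.loads(manifest_path.read_text())["stages"] or {})]
    if missing:
        lines.append(f"  warning: stages not (yet) run: {', '.join(missing)}")
    return "\n".join(lines)
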