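"""End-to-end orchestration of the atlas and knockdown analyses.

``run_atlas`` chains simulate -> filter -> classify -> quantify -> trend ->
motif over a developmental fusion-call series; ``run_knockdown`` chains
differential expression -> ORA -> GSEA -> marker panels over a two-group
count matrix. Both write tidy TSV/JSON outputs plus a machine-readable run
manifest (parameters, seeds, and record counts in/out at every filter), and
both are byte-for-byte reproducible at a fixed seed: no timestamps enter
any output file.

Inputs may be supplied as paths (in the formats of :mod:`.io_formats`) or
generated by :mod:`.synthetic_data` when a path is absent.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import pandas as pd

from . import __version__
from .fusion_classify import (
    classified_to_frame,
    classify_all,
    filter_candidates,
    resolve_models,
    summarize_biotypes,
    summarize_classes,
)
from .fusion_quantify import (
    expression_heatmap_table,
    expression_records,
    parent_chimera_correlation,
    stage_trend,
)
from .io_formats import (
    FormatError,
    read_annotation,
    read_counts,
    read_fusion_table,
    read_genome,
    read_gmt,
    read_libraries,
    write_counts,
    write_fusion_table,
    write_gmt,
    write_libraries,
)
from .junction_motif import build_pwm, consensus_report, extract_junction_windows
from .knockdown_enrichment import differential_expression, gsea, marker_panel_table, ora
from .synthetic_data import (
    SimulationConfig,
    simulate_expression,
    simulate_fusions,
    simulate_genome_annotation,
    simulate_knockdown,
)

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_atlas", "run_knockdown", "load_config"]


@dataclass
class RunConfig:
    """Paths, thresholds and the seed of one pipeline run.

    Any input path left as None is produced by the synthetic-data generator
    (seeded from ``seed``) inside ``outdir``.
    """

    outdir: Path = Path("fusionatlas_out")
    seed: int = 0
    genome: Path | None = None
    annotation: Path | None = None
    fusions: Path | None = None          # minimal-dialect fusion TSV
    fusion_dialect: str = "minimal"
    libraries: Path | None = None
    parent_counts: Path | None = None
    counts: Path | None = None           # knockdown count matrix
    groups: Path | None = None           # sample<TAB>group
    gene_sets: Path | None = None
    min_spanning_reads: int = 1
    lfc_cut: float = 1.0
    p_cut: float = 0.05
    gsea_permutations: int = 1000
    gsea_weight: float = 1.0
    sim: SimulationConfig = field(default_factory=SimulationConfig)

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        for name in ("genome", "annotation", "fusions", "libraries",
                     "parent_counts", "counts", "groups", "gene_sets"):
            value = getattr(self, name)
            if value is not None:
                p = Path(value)
                if not p.exists():
                    raise FileNotFoundError(f"config path {name!r} does not exist: {p}")
                setattr(self, name, p)
        if self.min_spanning_reads < 0 or self.gsea_permutations < 1:
            raise ValueError("thresholds must be positive")


def load_config(path: str | Path, **overrides) -> RunConfig:
    """Parse a flat ``key = value`` config file; keyword overrides win."""
    values: dict[str, object] = {}
    sim_values: dict[str, object] = {}
    run_fields = {f.name: f for f in fields(RunConfig)}
    sim_fields = {f.name: f for f in fields(SimulationConfig)}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise FormatError(f"{path}: line {lineno}: expected key = value")
            key, raw = (s.strip() for s in line.split("=", 1))
            if key.startswith("sim."):
                target, key2 = sim_values, key[4:]
                if key2 not in sim_fields:
                    raise FormatError(f"{path}: line {lineno}: unknown key {key!r}")
                target[key2] = _coerce(raw)
            elif key in run_fields:
                values[key] = _coerce(raw)
            else:
                raise FormatError(f"{path}: line {lineno}: unknown key {key!r}")
    values.update(overrides)
    seed = values.get("seed", 0)
    sim_values.setdefault("seed", seed)
    values["sim"] = SimulationConfig(**sim_values)
    return RunConfig(**values)


def _coerce(raw: str):
    for cast in (int, float):
        try:
            return cast(raw)
        except ValueError:
            pass
    return raw


def _manifest(outdir: Path, stage: str, payload: dict) -> None:
    path = outdir / f"{stage}_manifest.json"
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Atlas: simulate -> classify -> quantify -> motif -> trend
# ---------------------------------------------------------------------------

def run_atlas(config: RunConfig) -> dict[str, Path]:
    """Full chimeric-RNA characterization run; returns the output paths."""
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    sim_cfg = config.sim
    counts_audit: dict[str, int] = {}

    if config.genome is None or config.annotation is None:
        log.info("atlas: simulating genome and annotation (seed=%d)", sim_cfg.seed)
        simdir = out / "sim"
        sim = simulate_genome_annotation(sim_cfg, simdir)
        genome_path, annotation_path = sim.fasta_path, sim.gtf_path
    else:
        genome_path, annotation_path = config.genome, config.annotation
        sim = None

    genome = read_genome(genome_path)
    models = read_annotation(annotation_path)

    if config.fusions is None:
        if sim is None:
            raise ValueError("cannot simulate fusions against a user-supplied genome")
        calls, truth = simulate_fusions(sim_cfg, sim, genome)
        libs, parent_counts, _ = simulate_expression(sim_cfg, calls)
        write_fusion_table(calls, out / "sim" / "fusions.tsv")
        write_libraries(libs, out / "sim" / "libraries.tsv")
        write_counts(parent_counts, out / "sim" / "parent_counts.tsv")
        truth_df = pd.DataFrame({
            "call_index": range(len(calls)),
            "true_class": truth.call_classes,
            "true_relation": truth.call_relations,
        })
        truth_df.to_csv(out / "sim" / "ground_truth.tsv", sep="\t", index=False)
        # round-trip through our own readers so the pipeline exercises them
        calls = read_fusion_table(out / "sim" / "fusions.tsv")
        libs = read_libraries(out / "sim" / "libraries.tsv")
        parent_counts = read_counts(out / "sim" / "parent_counts.tsv")
    else:
        calls = read_fusion_table(config.fusions, dialect=config.fusion_dialect)
        if config.libraries is None:
            raise ValueError("a fusion table requires a libraries table")
        libs = read_libraries(config.libraries)
        parent_counts = read_counts(config.parent_counts) if config.parent_counts else None

    counts_audit["calls_in"] = len(calls)
    survivors = [c for c in filter_candidates(calls)
                 if c.spanning_unique_reads >= config.min_spanning_reads]
    counts_audit["calls_after_spanning_read_filter"] = len(survivors)
    log.info("atlas: filter kept %d/%d calls", len(survivors), len(calls))

    resolved = resolve_models(models)
    classified = classify_all(survivors, resolved, genome)
    paths: dict[str, Path] = {}

    frame = classified_to_frame(classified)
    paths["classified"] = out / "classified.tsv"
    frame.to_csv(paths["classified"], sep="\t", index=False)
    paths["class_summary"] = out / "class_summary.tsv"
    summarize_classes(classified).to_csv(paths["class_summary"], sep="\t", index=False)
    paths["biotype_summary"] = out / "biotype_summary.tsv"
    summarize_biotypes(classified).to_csv(paths["biotype_summary"], sep="\t", index=False)

    expr = expression_records(survivors, libs)
    paths["expression"] = out / "expression.tsv"
    expr.to_csv(paths["expression"], sep="\t", index=False)
    paths["heatmap"] = out / "expression_heatmap.tsv"
    expression_heatmap_table(expr).to_csv(paths["heatmap"], sep="\t")

    trend_report = {}
    for relation in ("intra", "inter"):
        t = stage_trend(classified, libs, relation)
        trend_report[relation] = {
            "r": t.r, "r_squared": t.r_squared, "p_value": t.p_value,
            "slope": t.slope, "intercept": t.intercept, "n_points": t.n_points,
            "flagged": t.flagged,
        }
    paths["trend"] = out / "trend.json"
    with open(paths["trend"], "w") as fh:
        json.dump(trend_report, fh, indent=2, sort_keys=True)
        fh.write("\n")

    if parent_counts is not None:
        per_fusion, pooled = parent_chimera_correlation(expr, parent_counts, libs)
        paths["parent_correlation"] = out / "parent_correlation.tsv"
        per_fusion.to_csv(paths["parent_correlation"], sep="\t", index=False)
        paths["parent_correlation_pooled"] = out / "parent_correlation_pooled.json"
        with open(paths["parent_correlation_pooled"], "w") as fh:
            json.dump({"rho": pooled.rho, "p_value": pooled.p_value,
                       "n_pairs": pooled.n_pairs, "flagged": pooled.flagged},
                      fh, indent=2, sort_keys=True)
            fh.write("\n")

    windows, dropped = extract_junction_windows(classified, genome)
    counts_audit["junction_windows"] = len(windows)
    counts_audit["junction_windows_dropped"] = dropped
    consensus = {}
    for side in ("donor", "acceptor"):
        side_windows = [w for w in windows if w.side == side]
        if side_windows:
            pwm = build_pwm(side_windows)
            paths[f"pwm_{side}"] = out / f"pwm_{side}.tsv"
            pwm.to_frame().to_csv(paths[f"pwm_{side}"], sep="\t")
            rep = consensus_report(pwm)
            consensus[side] = {
                "consensus": rep.consensus,
                "donor_canonical": rep.donor_canonical,
                "acceptor_canonical": rep.acceptor_canonical,
                "n_sequences": pwm.n_sequences,
            }
    paths["consensus"] = out / "consensus.json"
    with open(paths["consensus"], "w") as fh:
        json.dump(consensus, fh, indent=2, sort_keys=True)
        fh.write("\n")

    _manifest(out, "atlas", {
        "pipeline": "atlas",
        "version": __version__,
        "seed": config.seed,
        "record_counts": counts_audit,
        "parameters": {
            "min_spanning_reads": config.min_spanning_reads,
            "simulation": asdict(sim_cfg) if sim is not None else None,
        },
        "outputs": {k: str(Path(v).name) for k, v in sorted(paths.items())},
    })
    paths["manifest"] = out / "atlas_manifest.json"
    return paths


# ---------------------------------------------------------------------------
# Knockdown: de -> ora -> gsea -> marker panels
# ---------------------------------------------------------------------------

def _read_groups(path: Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns or "group" not in df.columns:
        raise FormatError(f"{path}: needs columns sample_id, group")
    return dict(zip(df["sample_id"].astype(str), df["group"].astype(str)))


def run_knockdown(config: RunConfig) -> dict[str, Path]:
    """Knockdown-arm statistics run; returns the output paths."""
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    sim_cfg = config.sim

    if config.counts is None:
        log.info("knockdown: simulating counts (seed=%d)", sim_cfg.seed)
        simdir = out / "sim"
        simdir.mkdir(parents=True, exist_ok=True)
        kd = simulate_knockdown(sim_cfg)
        write_counts(kd.counts, simdir / "kd_counts.tsv")
        pd.DataFrame(
            {"sample_id": list(kd.groups), "group": list(kd.groups.values())}
        ).to_csv(simdir / "kd_groups.tsv", sep="\t", index=False)
        write_gmt(kd.gene_sets, simdir / "gene_sets.gmt")
        pd.DataFrame(
            {"gene": list(kd.truth.de_genes), "true_lfc": list(kd.truth.de_genes.values())}
        ).to_csv(simdir / "kd_ground_truth.tsv", sep="\t", index=False)
        counts = read_counts(simdir / "kd_counts.tsv")
        groups = _read_groups(simdir / "kd_groups.tsv")
        gene_sets = read_gmt(simdir / "gene_sets.gmt")
        treatment, control = "knockdown", "control"
    else:
        counts = read_counts(config.counts)
        if config.groups is None or config.gene_sets is None:
            raise ValueError("a counts matrix requires groups and gene_sets paths")
        groups = _read_groups(config.groups)
        gene_sets = read_gmt(config.gene_sets)
        labels = sorted(set(groups.values()))
        if len(labels) != 2:
            raise ValueError(f"need exactly two groups, got {labels}")
        treatment, control = (
            ("knockdown", "control") if set(labels) == {"knockdown", "control"}
            else (labels[0], labels[1])
        )

    paths: dict[str, Path] = {}
    de, excluded = differential_expression(
        counts, groups, treatment=treatment, control=control,
        lfc_cut=config.lfc_cut, p_cut=config.p_cut,
    )
    paths["de"] = out / "de.tsv"
    de.to_csv(paths["de"], sep="\t", index=False)

    universe = de["gene"].tolist()
    up = de.loc[de["status"] == "up", "gene"].tolist()
    down = de.loc[de["status"] == "down", "gene"].tolist()
    for direction, genes in (("up", up), ("down", down)):
        table = ora(genes, universe, gene_sets) if genes else pd.DataFrame(
            columns=["set", "set_size", "overlap", "p_value", "skipped", "fdr"]
        )
        paths[f"ora_{direction}"] = out / f"ora_{direction}.tsv"
        table.to_csv(paths[f"ora_{direction}"], sep="\t", index=False)

    ranking = de.set_index("gene")["log2_fold_change"]
    gsea_table = gsea(
        ranking, gene_sets,
        n_permutations=config.gsea_permutations,
        weight=config.gsea_weight,
        seed=config.seed,
    )
    paths["gsea"] = out / "gsea.tsv"
    gsea_table.to_csv(paths["gsea"], sep="\t", index=False)

    paths["marker_panels"] = out / "marker_panels.tsv"
    marker_panel_table(de, gene_sets).to_csv(paths["marker_panels"], sep="\t", index=False)

    _manifest(out, "knockdown", {
        "pipeline": "knockdown",
        "version": __version__,
        "seed": config.seed,
        "record_counts": {
            "genes_in": int(counts.shape[0]),
            "genes_tested": int(len(de)),
            "genes_excluded_all_zero": len(excluded),
            "de_up": len(up),
            "de_down": len(down),
        },
        "parameters": {
            "lfc_cut": config.lfc_cut,
            "p_cut": config.p_cut,
            "gsea_permutations": config.gsea_permutations,
            "gsea_weight": config.gsea_weight,
            "gsea_seed": config.seed,
            "simulation": asdict(sim_cfg) if config.counts is None else None,
        },
        "outputs": {k: str(Path(v).name) for k, v in sorted(paths.items())},
    })
    paths["manifest"] = out / "knockdown_manifest.json"
    return paths
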