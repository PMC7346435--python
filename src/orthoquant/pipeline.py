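"""End-to-end orchestration: calls -> orthology -> quantile maps ->
region enrichment -> concordant genes -> sample similarity -> gene-set ORA.

Driven by a single YAML config, writing every stage artifact plus a JSON
summary report and a manifest with SHA-256 checksums, so a rerun with the
same inputs and seed is verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
import math
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calls import make_call_set, tpm_distribution
from .concordance import intersect_and_rank, top_region_genes
from .enrichment import enrich
from .errors import ValidationError
from .io import (
    ExpressionDataset,
    read_expression_matrix,
    read_gene_list,
    read_gmt,
    write_quantile_map,
)
from .orthology import filter_high_confidence, read_orthology
from .quantile_map import (
    assign_quantiles,
    build_quantile_mapping,
    project_reference_list,
    region_enrichment,
    summarize_projection,
)
from .similarity import adonis, anosim, pc_distances, pca_scores, upgma_cluster

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "summarize_overlaps",
           "round_percent"]


def round_percent(x: float) -> int:
    """Round a percentage half-away-from-zero to an integer (x >= 0)."""
    return int(math.floor(x + 0.5))


def summarize_overlaps(sets: dict[str, frozenset[str] | set[str]]) -> pd.DataFrame:
    """Pairwise overlap table: common count and percent of the smaller set."""
    if len(sets) < 2:
        raise ValidationError("need >=2 named sets")
    for name, s in sets.items():
        if not s:
            raise ValidationError(f"set {name!r} is empty")
    names = list(sets)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            sa, sb = set(sets[a]), set(sets[b])
            common = len(sa & sb)
            rows.append({
                "set1": a, "set2": b,
                "size1": len(sa), "size2": len(sb),
                "common": common,
                "overlap_pct": round_percent(100.0 * common / min(len(sa), len(sb))),
            })
    return pd.DataFrame(rows)


@dataclass
class DatasetEntry:
    dataset_id: str
    species: str
    path: str


@dataclass
class PipelineConfig:
    """Validated run configuration (see ``from_yaml`` for the file schema)."""

    datasets: list[DatasetEntry]
    orthology_path: str
    out_dir: str
    query_datasets: list[str] | None = None  # default: all species-A datasets
    species_a: str | None = None             # default: species of first dataset
    tpm_threshold: float = 1.0
    z_threshold: float = 1.5
    n_quantiles: int = 10
    k: int = 3
    n_permutations: int = 999
    seed: int = 0
    gene_sets_path: str | None = None
    reference_list_path: str | None = None
    strip_id_version: bool = False

    def __post_init__(self) -> None:
        if len(self.datasets) < 2:
            raise ValidationError("pipeline needs >=2 datasets")
        ids = [d.dataset_id for d in self.datasets]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate dataset_id in config")
        if self.orthology_path is None:
            raise ValidationError("orthology_path is required")
        for entry in self.datasets:
            if not Path(entry.path).is_file():
                raise ValidationError(f"dataset file not found: {entry.path}")
        for path in (self.orthology_path, self.gene_sets_path,
                     self.reference_list_path):
            if path is not None and not Path(path).is_file():
                raise ValidationError(f"input file not found: {path}")
        if self.species_a is None:
            self.species_a = self.datasets[0].species
        if self.query_datasets is None:
            self.query_datasets = [
                d.dataset_id for d in self.datasets if d.species == self.species_a
            ]
        known = set(ids)
        if not set(self.query_datasets) <= known:
            raise ValidationError("query_datasets must name configured datasets")
        if self.n_quantiles < 2 or not 1 <= self.k <= self.n_quantiles:
            raise ValidationError("invalid n_quantiles/k")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as handle:
            data = yaml.safe_load(handle) or {}
        if "datasets" not in data:
            raise ValidationError(f"{path}: missing 'datasets' section")
        data = dict(data)
        data["datasets"] = [
            DatasetEntry(
                dataset_id=d["dataset_id"], species=d["species"], path=d["path"]
            )
            for d in data["datasets"]
        ]
        return cls(**data)


@dataclass
class RunManifest:
    """Reproducibility record for one pipeline run."""

    version: str
    seed: int
    config: dict
    started: str
    finished: str
    checksums: dict[str, str] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig) -> RunManifest:
    """Execute all stages and write outputs under ``cfg.out_dir``.

    Any stage failure aborts with the stage name prefixed to the cause.
    Returns the manifest (also written as ``MANIFEST.json``).
    """
    started = time.strftime("%Y-%m-%dT%H:%M:%S")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "seed": cfg.seed}
    stage = "load"
    try:
        datasets = {
            e.dataset_id: read_expression_matrix(
                e.path, e.dataset_id, e.species,
                strip_id_version=cfg.strip_id_version,
            )
            for e in cfg.datasets
        }
        om = read_orthology(
            cfg.orthology_path,
            species_a=cfg.species_a,
            species_b=next(
                (e.species for e in cfg.datasets if e.species != cfg.species_a),
                "B",
            ),
        )
        report["orthology"] = om.counts()

        stage = "calls"
        (out / "calls").mkdir(exist_ok=True)
        call_sets = {}
        for ds_id, ds in datasets.items():
            cs = make_call_set(ds, tpm_threshold=cfg.tpm_threshold,
                               z_threshold=cfg.z_threshold)
            call_sets[ds_id] = cs
            frame = pd.DataFrame({
                "gene_id": ds.genes,
                "mean_tpm": ds.mean_tpm().to_numpy(),
                "expressed": [g in cs.expressed for g in ds.genes],
                "highly_expressed": [g in cs.highly_expressed for g in ds.genes],
            })
            frame.to_csv(out / "calls" / f"{ds_id}.calls.tsv", sep="\t",
                         index=False, lineterminator="\n")
            dist = tpm_distribution(ds)
            dist.counts.to_csv(out / "calls" / f"{ds_id}.tpm_bins.tsv", sep="\t",
                               lineterminator="\n")
        report["n_expressed"] = {k: len(v.expressed) for k, v in call_sets.items()}
        report["n_highly_expressed"] = {
            k: len(v.highly_expressed) for k, v in call_sets.items()
        }
        expressed_sets = {k: v.expressed for k, v in call_sets.items()}
        report["expressed_overlaps"] = summarize_overlaps(expressed_sets).to_dict(
            orient="records"
        )

        stage = "quantile-maps"
        (out / "maps").mkdir(exist_ok=True)
        assignments = {
            ds_id: assign_quantiles(cs, cfg.n_quantiles)
            for ds_id, cs in call_sets.items()
        }
        other = [d.dataset_id for d in cfg.datasets
                 if d.species != cfg.species_a]
        maps = {}
        enrich_rows = []
        for q in cfg.query_datasets:
            for t in other:
                qm = build_quantile_mapping(
                    assignments[q], assignments[t], om=om, row_side="a"
                )
                maps[(q, t)] = qm
                write_quantile_map(qm, out / "maps" / f"{q}_vs_{t}",
                                   row_ds=datasets[q], col_ds=datasets[t])
                for label, rows_, cols_ in (
                    ("top_cell", [1], [1]),
                    ("top_corner", range(1, cfg.k + 1), range(1, cfg.k + 1)),
                ):
                    re_ = region_enrichment(qm, rows_, cols_)
                    enrich_rows.append({
                        "map": f"{q}_vs_{t}", "region": label,
                        "observed": re_.observed, "expected": re_.expected,
                        "odds_ratio": re_.odds_ratio, "p_value": re_.p_value,
                    })
        q_ids = list(cfg.query_datasets)
        for i, q1 in enumerate(q_ids):
            for q2 in q_ids[i + 1:]:
                qm = build_quantile_mapping(assignments[q1], assignments[q2], om=None)
                maps[(q1, q2)] = qm
                write_quantile_map(qm, out / "maps" / f"{q1}_vs_{q2}",
                                   row_ds=datasets[q1], col_ds=datasets[q2])
        pd.DataFrame(enrich_rows).to_csv(out / "maps" / "region_enrichment.tsv",
                                         sep="\t", index=False, lineterminator="\n")
        report["region_enrichment"] = enrich_rows

        stage = "concordance"
        (out / "concordance").mkdir(exist_ok=True)
        top_sets = {
            q: top_region_genes(maps[(q, t)], cfg.k)
            for q in cfg.query_datasets for t in other
        }
        result = None
        if top_sets and all(top_sets.values()):
            result = intersect_and_rank(
                top_sets, list(datasets.values()), orthology=om, query_side="a",
                tpm_threshold=cfg.tpm_threshold,
            )
            ranked = pd.DataFrame(result.ranking, columns=["gene_id", "average_tpm"])
            ranked.insert(0, "rank", np.arange(1, len(ranked) + 1))
            ranked["pooled_orthologs"] = ranked["gene_id"].isin(
                result.multi_ortholog_genes
            )
            ranked.to_csv(out / "concordance" / "concordant.tsv", sep="\t",
                          index=False, lineterminator="\n")
            report["concordance"] = {
                "per_dataset": {k: len(v) for k, v in result.per_dataset.items()},
                "n_intersection": len(result.intersection),
                "overlap_pct": round_percent(result.overlap_pct),
            }
        else:
            report["concordance"] = None

        stage = "reference-projection"
        if cfg.reference_list_path and maps:
            ref = read_gene_list(cfg.reference_list_path)
            proj_report = {}
            for q in cfg.query_datasets:
                for t in other:
                    pqm = project_reference_list(maps[(q, t)], ref)
                    write_quantile_map(pqm, out / "maps" / f"{q}_vs_{t}.reference")
                    proj_report[f"{q}_vs_{t}"] = summarize_projection(pqm)
            report["reference_projection"] = proj_report

        stage = "similarity"
        sim_report = None
        if result is not None and len(result.intersection) >= 3:
            genes = sorted(result.intersection)
            hc_map = filter_high_confidence(om).a_to_b
            cols = {}
            groups = {}
            for ds in datasets.values():
                for rep in ds.replicates:
                    col_name = f"{ds.dataset_id}:{rep}"
                    groups[col_name] = ds.dataset_id
                    values = []
                    for g in genes:
                        if g in ds.tpm.index:
                            values.append(ds.tpm.at[g, rep])
                        else:
                            partners = sorted(
                                p for p in hc_map.get(g, frozenset())
                                if p in ds.tpm.index
                            )
                            values.append(
                                float(ds.tpm.loc[partners, rep].mean())
                                if partners else 0.0
                            )
                    cols[col_name] = values
            matrix = pd.DataFrame(cols, index=genes)
            matrix = np.log2(matrix + 1.0)
            matrix = matrix.loc[matrix.std(axis=1, ddof=1) > 0]
            (out / "similarity").mkdir(exist_ok=True)
            tree = upgma_cluster(matrix)
            (out / "similarity" / "dendrogram.nwk").write_text(
                tree.to_newick() + "\n", encoding="utf-8"
            )
            pca = pca_scores(matrix, n_components=2)
            pca.scores.to_csv(out / "similarity" / "pca_scores.tsv", sep="\t",
                              lineterminator="\n")
            dist = pc_distances(matrix)
            tests = []
            tests.append(("three-way", anosim(dist, groups, cfg.n_permutations,
                                              seed=cfg.seed)))
            tests.append(("three-way", adonis(dist, groups, cfg.n_permutations,
                                              seed=cfg.seed)))
            ds_ids = list(datasets)
            for i, a in enumerate(ds_ids):
                for b in ds_ids[i + 1:]:
                    keep = [c for c, g in groups.items() if g in (a, b)]
                    sub = dist.loc[keep, keep]
                    sub_groups = {c: groups[c] for c in keep}
                    tests.append((f"{a}-vs-{b}",
                                  anosim(sub, sub_groups, cfg.n_permutations,
                                         seed=cfg.seed)))
                    tests.append((f"{a}-vs-{b}",
                                  adonis(sub, sub_groups, cfg.n_permutations,
                                         seed=cfg.seed)))
            sim_rows = [{
                "comparison": name,
                "statistic_name": r.statistic_name,
                "statistic": r.statistic,
                "p_value": r.p_value,
                "n_permutations": r.n_permutations,
                "method": r.method,
            } for name, r in tests]
            pd.DataFrame(sim_rows).to_csv(out / "similarity" / "tests.tsv",
                                          sep="\t", index=False,
                                          lineterminator="\n")
            sim_report = {
                "pc_variance_pct": [round(100 * f, 1)
                                    for f in pca.explained_variance_ratio],
                "tests": sim_rows,
            }
        report["similarity"] = sim_report

        stage = "gene-set-enrichment"
        if cfg.gene_sets_path and result is not None and result.intersection:
            collection = read_gmt(cfg.gene_sets_path)
            universe = collection.all_genes() | result.intersection
            results = enrich(result.intersection, collection, universe=universe)
            (out / "ora").mkdir(exist_ok=True)
            pd.DataFrame([r.__dict__ for r in results]).to_csv(
                out / "ora" / "enrichment.tsv", sep="\t", index=False,
                lineterminator="\n",
            )
            report["n_significant_sets"] = sum(r.significant for r in results)
    except Exception as exc:
        from .errors import OrthoquantError
        raise OrthoquantError(f"stage {stage!r} failed: {exc}") from exc

    stage = "report"
    (out / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True, default=str) + "\n",
        encoding="utf-8",
    )
    finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    checksums = {
        str(p.relative_to(out)): _sha256(p)
        for p in sorted(out.rglob("*"))
        if p.is_file() and p.name != "MANIFEST.json"
    }
    manifest = RunManifest(
        version=__version__,
        seed=cfg.seed,
        config={
            "datasets": [e.__dict__ for e in cfg.datasets],
            "orthology_path": cfg.orthology_path,
            "out_dir": cfg.out_dir,
            "query_datasets": cfg.query_datasets,
            "tpm_threshold": cfg.tpm_threshold,
            "z_threshold": cfg.z_threshold,
            "n_quantiles": cfg.n_quantiles,
            "k": cfg.k,
            "n_permutations": cfg.n_permutations,
            "seed": cfg.seed,
        },
        started=started,
        finished=finished,
        checksums=checksums,
    )
    (out / "MANIFEST.json").write_text(manifest.to_json() + "\n", encoding="utf-8")
    return manifest
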