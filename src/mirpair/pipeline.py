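"""End-to-end orchestration: normalize -> DE (both modes) -> targets ->
anticorrelated pairs -> enrichment -> survival, from a single flat config.

``--demo`` mode generates every input with the synthetic-data module first
(planting coordinated truth: DE miRNAs whose listed targets are DE genes of
the opposite direction), then runs the identical stages on those files, so
the whole pipeline is exercisable with no external data.  A machine-readable
run manifest records, per stage, the input hashes, row counts and
parameters; identical config and inputs reproduce an identical manifest.
"""

from __future__ import annotations

import hashlib
import json
import sys
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
import yaml

from . import simulate as sim
from .containers import (
    PairedCountMatrix,
    TargetMap,
    TargetRelation,
    read_counts_tsv,
    read_fasta,
    write_fasta,
)
from .de import DEConfig, DEFeatureSet, select_de_features
from .integrate import (
    anticorrelated_pairs,
    hypergeometric_enrich,
    pair_summary,
    pairs_to_frame,
    read_gmt,
    write_gmt,
)
from .survival import assign_percentile_groups, compare_groups
from .targets import MLRModel, merge_target_maps, predict_targets

__all__ = ["PipelineConfig", "run_pipeline", "generate_demo_inputs"]


@dataclass
class PipelineConfig:
    """Flat configuration; every pipeline threshold has a key here.

    Paths may be None when a stage should be skipped (e.g. no survival
    table).  Defaults equal the published analysis thresholds.
    """

    # inputs
    mirna_counts: Optional[str] = None
    mirna_manifest: Optional[str] = None
    mrna_counts: Optional[str] = None
    mrna_manifest: Optional[str] = None
    mirna_fasta: Optional[str] = None
    utr_fasta: Optional[str] = None
    gmt: Optional[str] = None
    validated_targets: list[str] = field(default_factory=list)
    predicted_targets: list[str] = field(default_factory=list)
    targetscan_targets: Optional[str] = None
    survival_table: Optional[str] = None

    # DE thresholds (miRNA / mRNA modes)
    fdr_threshold: float = 1e-5
    min_avg_logcpm: float = 3.0
    min_abs_avg_logfc: float = 0.5
    mirna_direction_frac: float = 0.80
    mirna_fold_frac: float = 0.70
    mrna_direction_frac: float = 0.70
    mrna_fold_frac: float = 0.60
    fold_threshold: float = 2.0

    # target scoring / merge
    mlr_intercept: float = 0.0
    mlr_coefficients: tuple[float, float, float, float] = (-0.40, 0.05, 0.10, 0.02)
    mlr_score_threshold: float = -0.3
    flank: int = 30
    min_support: int = 3
    ts_threshold: float = 0.2

    # survival
    low_pct: float = 0.10
    high_pct: float = 0.10

    seed: int = 0
    outdir: str = "mirpair_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "mlr_coefficients" in data:
            data["mlr_coefficients"] = tuple(data["mlr_coefficients"])
        return cls(**data)

    def de_config(self, mode: str) -> DEConfig:
        if mode == "mirna":
            return DEConfig.mirna(
                fdr_threshold=self.fdr_threshold,
                min_avg_logcpm=self.min_avg_logcpm,
                direction_frac=self.mirna_direction_frac,
                fold_frac=self.mirna_fold_frac,
                fold_threshold=self.fold_threshold,
            )
        return DEConfig.mrna(
            fdr_threshold=self.fdr_threshold,
            min_abs_avg_logfc=self.min_abs_avg_logfc,
            direction_frac=self.mrna_direction_frac,
            fold_frac=self.mrna_fold_frac,
            fold_threshold=self.fold_threshold,
        )

    def mlr_model(self) -> MLRModel:
        return MLRModel(
            intercept=self.mlr_intercept,
            coefficients=tuple(self.mlr_coefficients),
            score_threshold=self.mlr_score_threshold,
        )


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _log(msg: str) -> None:
    print(msg, file=sys.stderr)


def generate_demo_inputs(
    outdir: str | Path,
    seed: int = 0,
    n_mirnas: int = 300,
    n_genes: int = 400,
    n_pairs: int = 48,
    frac_de: float = 0.10,
    logfc_range: tuple[float, float] = (2.0, 3.0),
    survival_n: int = 200,
    survival_hazard_ratio: float = 3.0,
) -> dict[str, Any]:
    """Write a complete synthetic input bundle and return paths + truth.

    The planted regulatory truth is built by construction: after both count
    matrices are drawn, every (planted DE miRNA, planted DE gene) with
    opposite directions and a planted or listed relation becomes part of a
    "validated" target list, so the downstream pair stage has a known answer.
    Demo fold changes are planted well clear of the calling thresholds; the
    demo demonstrates plumbing and recovery, not borderline power.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    mirnas, utrs, seq_truth = sim.simulate_sequence_universe(
        n_mirnas, n_genes, utr_len_range=(200, 1500), sites_per_utr={0: 0.4, 1: 0.4, 2: 0.2},
        seed=int(rng.integers(2**31)),
    )
    mirna_ids, gene_ids = list(mirnas), list(utrs)

    mirna_counts, mirna_truth = sim.simulate_paired_counts(
        sim.SimCountParams(
            n_features=n_mirnas, n_pairs=n_pairs, frac_de=frac_de,
            logfc_range=logfc_range, mean_log_range=(0.0, 6.0),
            seed=int(rng.integers(2**31)),
        )
    )
    mirna_counts.counts.index = pd.Index(mirna_ids, name="feature_id")
    mirna_truth.de_features = [
        (mid, lfc) for mid, (_, lfc) in zip(mirna_ids, mirna_truth.de_features)
    ]

    mrna_counts, mrna_truth = sim.simulate_paired_counts(
        sim.SimCountParams(
            n_features=n_genes, n_pairs=n_pairs, frac_de=frac_de,
            logfc_range=logfc_range, mean_log_range=(0.0, 8.0),
            seed=int(rng.integers(2**31)),
        )
    )
    mrna_counts.counts.index = pd.Index(gene_ids, name="feature_id")
    mrna_truth.de_features = [
        (gid, lfc) for gid, (_, lfc) in zip(gene_ids, mrna_truth.de_features)
    ]

    # planted regulatory pairs: DE miRNA -> opposite-direction DE gene,
    # recorded in a validated target list
    mdir = mirna_truth.de_directions()
    gdir = mrna_truth.de_directions()
    planted_pairs: list[tuple[str, str]] = []
    validated = TargetMap()
    for mid, md in sorted(mdir.items()):
        opposite = [g for g, gd in sorted(gdir.items()) if gd != md]
        if not opposite:
            continue
        chosen = rng.choice(opposite, size=min(4, len(opposite)), replace=False)
        for gid in chosen:
            validated.add(TargetRelation(mid, str(gid), "validated"))
            planted_pairs.append((mid, str(gid)))
    # noise relations between arbitrary entities
    for _ in range(200):
        validated.add(
            TargetRelation(
                str(rng.choice(mirna_ids)), str(rng.choice(gene_ids)), "validated"
            )
        )

    # prediction-program lists: some relations shared by >= 3 programs
    prediction_paths = []
    shared = {
        (str(rng.choice(mirna_ids)), str(rng.choice(gene_ids))) for _ in range(60)
    }
    for prog in range(4):
        tm = TargetMap()
        for mid, gid in shared:
            if rng.uniform() < 0.8:
                tm.add(TargetRelation(mid, gid, f"predicted:prog{prog}"))
        for _ in range(80):
            tm.add(
                TargetRelation(
                    str(rng.choice(mirna_ids)), str(rng.choice(gene_ids)),
                    f"predicted:prog{prog}",
                )
            )
        p = outdir / f"predicted_prog{prog}.tsv"
        tm.to_tsv(p)
        prediction_paths.append(str(p))

    ts = TargetMap()
    for _ in range(150):
        ts.add(
            TargetRelation(
                str(rng.choice(mirna_ids)), str(rng.choice(gene_ids)),
                "predicted:targetscan", float(rng.uniform(-0.5, 0.6)),
            )
        )

    gene_sets = sim.simulate_gene_sets(
        gene_ids, n_sets=50, set_size_range=(15, 60),
        enriched_in=sorted(gdir), seed=int(rng.integers(2**31)),
    )

    survival, surv_truth = sim.simulate_survival_cohort(
        survival_n, survival_hazard_ratio, censor_rate=0.2,
        seed=int(rng.integers(2**31)),
    )

    paths = {
        "mirna_counts": outdir / "mirna_counts.tsv",
        "mirna_manifest": outdir / "mirna_manifest.tsv",
        "mrna_counts": outdir / "mrna_counts.tsv",
        "mrna_manifest": outdir / "mrna_manifest.tsv",
        "mirna_fasta": outdir / "mirnas.fasta",
        "utr_fasta": outdir / "utrs.fasta",
        "gmt": outdir / "gene_sets.gmt",
        "validated_targets": outdir / "validated_targets.tsv",
        "targetscan_targets": outdir / "targetscan.tsv",
        "survival_table": outdir / "survival.tsv",
    }
    mirna_counts.to_tsv(paths["mirna_counts"])
    mirna_counts.manifest_to_tsv(paths["mirna_manifest"])
    mrna_counts.to_tsv(paths["mrna_counts"])
    mrna_counts.manifest_to_tsv(paths["mrna_manifest"])
    write_fasta(mirnas, paths["mirna_fasta"])
    write_fasta(utrs, paths["utr_fasta"])
    write_gmt(gene_sets, paths["gmt"])
    validated.to_tsv(paths["validated_targets"])
    ts.to_tsv(paths["targetscan_targets"])
    survival.to_csv(paths["survival_table"], sep="\t", index=False)

    truth_df = pd.DataFrame(planted_pairs, columns=["mirna_id", "gene_id"])
    truth_df.to_csv(outdir / "truth_planted_pairs.tsv", sep="\t", index=False)
    pd.DataFrame(mirna_truth.de_features, columns=["feature_id", "log2fc"]).to_csv(
        outdir / "truth_mirna_de.tsv", sep="\t", index=False
    )
    pd.DataFrame(mrna_truth.de_features, columns=["feature_id", "log2fc"]).to_csv(
        outdir / "truth_mrna_de.tsv", sep="\t", index=False
    )

    return {
        "paths": {k: str(v) for k, v in paths.items()},
        "prediction_paths": prediction_paths,
        "planted_pairs": planted_pairs,
        "mirna_truth": mirna_truth,
        "mrna_truth": mrna_truth,
        "seq_truth": seq_truth,
        "survival_truth": surv_truth,
    }


def run_pipeline(config: PipelineConfig, demo: bool = False) -> dict[str, Any]:
    """Execute every configured stage; returns the run manifest (also written).

    Stage results land in ``config.outdir`` as self-describing TSVs; the
    manifest JSON records input hashes, row counts and parameters per stage.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "config": {k: list(v) if isinstance(v, tuple) else v for k, v in asdict(config).items()},
        "stages": {},
    }

    if demo:
        _log("[demo] generating synthetic inputs")
        demo_dir = outdir / "demo_inputs"
        bundle = generate_demo_inputs(demo_dir, seed=config.seed)
        for key, val in bundle["paths"].items():
            setattr(config, key, val)
        config.validated_targets = [bundle["paths"]["validated_targets"]]
        config.predicted_targets = bundle["prediction_paths"]
        manifest["config"]["demo"] = True

    def record(stage: str, t0: float, inputs: list[str], **info: Any) -> None:
        manifest["stages"][stage] = {
            "inputs": {Path(p).name: _sha256(p) for p in inputs if p},
            "seconds": round(time.time() - t0, 2),
            **info,
        }
        _log(f"[{stage}] " + ", ".join(f"{k}={v}" for k, v in info.items()))

    de_sets: dict[str, DEFeatureSet] = {}
    for mode, cpath, mpath in (
        ("mirna", config.mirna_counts, config.mirna_manifest),
        ("mrna", config.mrna_counts, config.mrna_manifest),
    ):
        if not cpath:
            continue
        t0 = time.time()
        counts = read_counts_tsv(cpath, mpath)
        if mode == "mirna":
            # quantile-normalized abundance, the reported quantification
            from .normalize import log_cpm, quantile_normalize

            quantile_normalize(log_cpm(counts)).to_tsv(
                outdir / "mirna_abundance_qnorm.tsv"
            )
        feats = select_de_features(counts, config.de_config(mode))
        feats.to_tsv(outdir / f"de_{mode}.tsv")
        de_sets[mode] = feats
        record(f"de_{mode}", t0, [cpath, mpath],
               n_called=len(feats.called_ids()), **feats.step_counts)

    targets = TargetMap()
    if config.mirna_fasta and config.utr_fasta:
        t0 = time.time()
        mirnas = read_fasta(config.mirna_fasta)
        utrs = read_fasta(config.utr_fasta)
        mlr_map = predict_targets(mirnas, utrs, config.mlr_model(), flank=config.flank)
        mlr_map.to_tsv(outdir / "targets_mlr.tsv")
        record("targets_mlr", t0, [config.mirna_fasta, config.utr_fasta],
               n_relations=len(mlr_map))
    else:
        mlr_map = TargetMap()

    t0 = time.time()
    validated = [TargetMap.from_tsv(p) for p in config.validated_targets]
    predicted = [TargetMap.from_tsv(p) for p in config.predicted_targets]
    ts_map = (
        TargetMap.from_tsv(config.targetscan_targets)
        if config.targetscan_targets
        else None
    )
    targets = merge_target_maps(
        validated, predicted, ts_map,
        min_support=config.min_support, ts_threshold=config.ts_threshold,
    )
    for rel in mlr_map.relations:
        targets.add(rel)
    targets.to_tsv(outdir / "targets_merged.tsv")
    record("targets_merge", t0,
           config.validated_targets + config.predicted_targets
           + ([config.targetscan_targets] if config.targetscan_targets else []),
           n_relations=len(targets))

    pairs = []
    if "mirna" in de_sets and "mrna" in de_sets:
        t0 = time.time()
        pairs = anticorrelated_pairs(
            de_sets["mirna"].directions(), de_sets["mrna"].directions(), targets
        )
        pairs_to_frame(pairs).to_csv(outdir / "pairs.tsv", sep="\t", index=False)
        record("pairs", t0, [], **pair_summary(pairs))

    if config.gmt and "mrna" in de_sets:
        t0 = time.time()
        gene_sets = read_gmt(config.gmt)
        universe = list(de_sets["mrna"].records["feature_id"])
        deg_dirs = de_sets["mrna"].directions()
        pair_genes = {(p.gene_id, p.gene_direction) for p in pairs}
        queries = {
            "deg_up": [g for g, d in deg_dirs.items() if d == "up"],
            "deg_down": [g for g, d in deg_dirs.items() if d == "down"],
            "target_deg_up": sorted(g for g, d in pair_genes if d == "up"),
            "target_deg_down": sorted(g for g, d in pair_genes if d == "down"),
        }
        frames = []
        for name, query in queries.items():
            if not query:
                continue
            df = hypergeometric_enrich(
                query, gene_sets, universe,
                query_direction="up" if name.endswith("up") else "down",
            )
            df.insert(0, "query", name)
            frames.append(df)
        enrich = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
        enrich.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
        record("enrichment", t0, [config.gmt], n_rows=len(enrich),
               n_sets=len(gene_sets))

    if config.survival_table:
        t0 = time.time()
        cohort = pd.read_csv(config.survival_table, sep="\t")
        cohort = assign_percentile_groups(cohort, config.low_pct, config.high_pct)
        km_low, km_high, res = compare_groups(cohort)
        km_low.assign(group="low").pipe(
            lambda a: pd.concat([a, km_high.assign(group="high")])
        ).to_csv(outdir / "km_curves.tsv", sep="\t", index=False)
        pd.DataFrame(
            [
                (res.chi_square, res.p_value, res.n_low, res.n_high,
                 res.events_low, res.events_high)
            ],
            columns=["chi_square", "p_value", "n_low", "n_high",
                     "events_low", "events_high"],
        ).to_csv(outdir / "logrank.tsv", sep="\t", index=False)
        record("survival", t0, [config.survival_table],
               chi_square=round(res.chi_square, 4), p_value=float(res.p_value))

    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest
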