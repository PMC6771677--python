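"""End-to-end pipeline driver.

``run_pipeline`` chains the stages — simulate, quantify, featurize, rank,
train, transfer, tf-overlap, variant — over a synthetic study whose
every input is produced by :mod:`mprameta.synthetic`. Each stage is
toggleable; a stage whose inputs were not produced fails fast naming the
missing dependency. All randomness flows from the seeds in the configuration
and a run manifest records the configuration hash, seeds, and output paths.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import assessment, featurize, io, models, quantify, synthetic, tf_overlap, transfer, variants

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All knobs of a pipeline run; defaults are the analysis' standard values.

    FDR 0.05, 10 fold sections, 1,000 estimators, elastic-net mixing 0.5,
    100 subsamples at 80%, 90th score percentile, 20-bp motif-density window,
    k = 5.
    """

    out_dir: str = "pipeline_out"
    seed: int = 0
    # stage toggles
    stages: tuple[str, ...] = (
        "simulate",
        "quantify",
        "featurize",
        "rank",
        "train",
        "transfer",
        "tf_overlap",
        "variant",
    )
    # analysis constants
    fdr_threshold: float = 0.05
    n_sections: int = 10
    n_estimators: int = 1000
    elastic_net_mixing: float = 0.5
    n_subsamples: int = 100
    subsample_frac: float = 0.8
    score_percentile: float = 90.0
    motif_window: int = 20
    k: int = 5
    # synthetic-study sizes
    sim: synthetic.SimConfig = field(default_factory=synthetic.SimConfig)
    paired: synthetic.PairedSimConfig = field(
        default_factory=synthetic.PairedSimConfig
    )
    satmut: synthetic.SatMutSimConfig = field(
        default_factory=synthetic.SatMutSimConfig
    )
    n_sequences: int = 50
    sequence_length: int = 150
    variant_min_train: int = 50

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["stages"] = tuple(raw.get("stages", cls().stages))
        raw["sim"] = synthetic.SimConfig(**raw.get("sim", {}))
        raw["paired"] = synthetic.PairedSimConfig(
            base=synthetic.SimConfig(**raw["paired"].pop("base", {})),
            **raw.get("paired", {}),
        )
        raw["satmut"] = synthetic.SatMutSimConfig(**raw.get("satmut", {}))
        return cls(**raw)


def _require(produced: dict, stage: str, *deps: str) -> None:
    for dep in deps:
        if dep not in produced:
            raise RuntimeError(
                f"stage {stage!r} requires output {dep!r}, which was not produced "
                "(is its stage toggled off?)"
            )


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    produced: dict[str, object] = {}
    manifest: dict = {
        "config_hash": io.config_hash(config.to_dict()),
        "seed": config.seed,
        "stages": list(config.stages),
        "outputs": {},
        "timings_s": {},
        "counts": {},
    }

    def record(name: str, path: Path | None, obj=None, n: int | None = None):
        produced[name] = obj if obj is not None else path
        if path is not None:
            manifest["outputs"][name] = str(path)
        if n is not None:
            manifest["counts"][name] = n

    for stage in config.stages:
        t0 = time.perf_counter()
        if stage == "simulate":
            counts, truth = synthetic.simulate_counts(config.sim)
            io.write_count_table(counts, out / "counts.tsv")
            truth.to_csv(out / "truth.tsv", sep="\t", index=False)
            record("counts", out / "counts.tsv", counts, len(counts))
            record("truth", out / "truth.tsv", truth, len(truth))

            (xa, act_a, lab_a), (xb, act_b, lab_b) = synthetic.simulate_paired_datasets(
                config.paired
            )
            io.write_feature_matrix(xa, out / "paired_features.tsv")
            pd.DataFrame({"activity_A": act_a, "activity_B": act_b,
                          "label_A": lab_a, "label_B": lab_b}).to_csv(
                out / "paired_activity.tsv", sep="\t")
            record("paired", None, ((xa, act_a, lab_a), (xb, act_b, lab_b)), len(xa))

            sat_table, element_seq = synthetic.simulate_saturation(config.satmut)
            sat_table.to_csv(out / "variants.tsv", sep="\t", index=False)
            io.write_fasta({"element_0": element_seq}, out / "elements.fa")
            record("variants", out / "variants.tsv", (sat_table, element_seq), len(sat_table))

            rng_motif = np.random.default_rng(config.seed + 11)
            motif = rng_motif.dirichlet(np.full(4, 0.2), size=8)
            pwm = {"M1": motif}
            records, seq_truth = synthetic.simulate_sequences(
                config.n_sequences, config.sequence_length, motifs=pwm,
                plant_prob=0.5, seed=config.seed + 12,
            )
            io.write_fasta(records, out / "sequences.fa")
            io.write_meme([featurize.PWM("M1", motif)], out / "motifs.meme")
            record("sequences", out / "sequences.fa", (records, seq_truth), len(records))

        elif stage == "quantify":
            _require(produced, stage, "counts")
            activity = quantify.estimate_alpha(produced["counts"])
            activity = quantify.call_active(activity, fdr_threshold=config.fdr_threshold)
            io.write_activity_table(activity, out / "activity.tsv")
            record("activity", out / "activity.tsv", activity, len(activity))

        elif stage == "featurize":
            _require(produced, stage, "sequences")
            records, _ = produced["sequences"]
            pwms = io.read_meme(out / "motifs.meme")
            block = featurize.sequence_feature_block(dict(records), pwms=pwms, k=config.k)
            io.write_feature_matrix(block, out / "sequence_features.tsv")
            record("sequence_features", out / "sequence_features.tsv", block, block.shape[1])

        elif stage == "rank":
            _require(produced, stage, "paired")
            (xa, act_a, lab_a), (xb, act_b, lab_b) = produced["paired"]
            ranks = {}
            for name, (x, act, lab) in (("A", (xa, act_a, lab_a)), ("B", (xb, act_b, lab_b))):
                suite = assessment.feature_test_suite(x, act, lab)
                suite.to_csv(out / f"tests_{name}.tsv", sep="\t", index=False)
                ranks[name] = assessment.within_dataset_rank(suite)
            comp = assessment.comprehensive_rank(ranks)
            comp.to_csv(out / "comprehensive_ranks.tsv", sep="\t")
            record("ranks", out / "comprehensive_ranks.tsv", comp, len(comp))

        elif stage == "train":
            _require(produced, stage, "paired")
            (xa, act_a, lab_a), _ = produced["paired"]
            spec = models.ModelSpec(
                task="regression", n_estimators=config.n_estimators,
                elastic_net_mixing=config.elastic_net_mixing, seed=config.seed,
            )
            cv = models.cross_validate(xa, act_a, spec)
            cv["folds"].to_csv(out / "cv_folds.tsv", sep="\t", index=False)
            cv["aggregate"].to_csv(out / "cv_aggregate.tsv", sep="\t")
            record("cv", out / "cv_aggregate.tsv", cv, len(cv["folds"]))

        elif stage == "transfer":
            _require(produced, stage, "paired")
            (xa, act_a, lab_a), (xb, act_b, lab_b) = produced["paired"]
            spec = models.ModelSpec(task="classification",
                                    n_estimators=config.n_estimators, seed=config.seed)
            res = models.cross_dataset_evaluate(xa, lab_a, xb, lab_b, spec)
            cats = transfer.categorize_regions(lab_a, lab_b)
            hard = transfer.hardness(res["predictions"].dropna(),
                                     lab_b.loc[res["predictions"].dropna().index])
            hard["category"] = cats.loc[hard.index]
            hard.to_csv(out / "hardness.tsv", sep="\t")
            cmp_res = transfer.compare_hardness(hard, cats)
            cmp_res["ks"].to_csv(out / "hardness_ks.tsv", sep="\t", index=False)
            record("hardness", out / "hardness.tsv", (hard, cmp_res), len(hard))

        elif stage == "tf_overlap":
            _require(produced, stage, "paired")
            (xa, act_a, _), (xb, act_b, _) = produced["paired"]
            pa = tf_overlap.predictive_tfs(xa, act_a)
            pb = tf_overlap.predictive_tfs(xb, act_b)
            pa.to_csv(out / "predictive_tfs_A.tsv", sep="\t")
            pb.to_csv(out / "predictive_tfs_B.tsv", sep="\t")
            sets = {"A": set(pa.index[pa["predictive"]]), "B": set(pb.index[pb["predictive"]])}
            universe = {("A", "B"): len(pa.index.intersection(pb.index))}
            pair = tf_overlap.pairwise_overlap(sets, universe)
            pair.to_csv(out / "tf_overlap.tsv", sep="\t", index=False)
            record("tf_overlap", out / "tf_overlap.tsv", pair, len(pair))

        elif stage == "variant":
            _require(produced, stage, "variants")
            sat_table, element_seq = produced["variants"]
            cfg = variants.VariantFeatureConfig(k=config.k)
            feats = variants.variant_feature_table(
                sat_table, {"element_0": element_seq}, cfg
            )
            train_mask = sat_table["split"] == "train"
            fitted = variants.train_continuous(
                sat_table[train_mask], feats[train_mask],
                scope="per_element", n_estimators=min(config.n_estimators, 200),
                seed=config.seed, min_train=config.variant_min_train,
            )
            test = sat_table[~train_mask]
            pred = fitted["element_0"].predict(feats[~train_mask])
            ev = variants.evaluate_variants(None, pred, test)
            pd.Series(ev).to_csv(out / "variant_eval.tsv", sep="\t", header=False)
            record("variant_eval", out / "variant_eval.tsv", ev, len(test))

        else:
            raise ValueError(f"unknown stage {stage!r}")
        manifest["timings_s"][stage] = round(time.perf_counter() - t0, 3)
        logger.info("stage %s finished in %.2fs", stage, manifest["timings_s"][stage])

    manifest_path = out / "manifest.json"
    stable = {k: v for k, v in manifest.items() if k != "timings_s"}
    manifest["manifest_hash"] = io.config_hash(stable)
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    manifest["outputs"]["manifest"] = str(manifest_path)
    return manifest
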