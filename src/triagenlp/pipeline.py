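"""End-to-end experiment orchestration.

``run_experiment`` wires the full analysis: simulate (or load) triage
records, preprocess the two free-text fields, build the four nested feature
models, split 64/20/16 into fixed train/validate/test sets, train the
AUC-optimizing linear scorer over a regularization grid, pick the grid
point with the best validation AUC, Platt-scale its decision values,
choose the Youden operating threshold on the validation split, and evaluate
on the held-out test split.  Every artifact lands in the working directory
with a manifest (config hash, derived per-stage seeds, artifact list), so a
rerun with the same config reproduces the run exactly and any stage can be
replayed in isolation.

Text-model artifacts (bigram list, vocabulary, topic model) are fitted on
the training split only by default; ``paper_faithful=True`` fits them on
the whole dataset and re-optimizes the operating threshold per split, which
reproduces the original protocol at the cost of a leakage-prone vocabulary.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__ as _pkg_version
from .evaluation import evaluate_scores
from .features import BowEncoder, assemble_features
from .lda import GibbsLDA
from .models import AucSvm, PlattCalibrator, make_split, select_model
from .synthetic import SyntheticConfig, generate_dataset, read_dataset, write_dataset
from .text import NotePreprocessor
from .vitals import VitalSpec, VitalsVectorizer
from .evaluation import youden_threshold

__all__ = ["RunConfig", "run_experiment", "check_no_leakage", "load_vitals_specs"]

# fixed offsets deriving independent per-stage seeds from the global seed
_SEED_OFFSETS = {"simulate": 0, "split": 1, "topics": 2, "svm": 3}


@dataclass
class RunConfig:
    """Configuration of one experiment run."""

    workdir: str = "runs/default"
    input_path: str | None = None  # None -> simulate
    synthetic: dict = field(default_factory=dict)  # SyntheticConfig overrides
    vitals_spec_path: str | None = None
    fractions: tuple[float, float, float] = (0.64, 0.20, 0.16)
    models: tuple[str, ...] = ("vitals", "cc", "bow", "topics")
    c_grid: tuple[float, ...] = (0.001, 0.01, 0.1, 1.0, 10.0, 100.0, 1000.0)
    vocab_min_count: int = 5
    bigram_min_count: int = 5
    bigram_min_score: float = 3.0
    n_topics: int = 24
    topic_alpha: float | None = 0.5  # sharper than 50/K: short notes
    topic_fit_iter: int = 150
    topic_infer_iter: int = 200
    topic_burn_in: int = 100
    topic_threshold: float = 0.001
    svm_epochs: int = 150
    svm_pairs_per_epoch: int = 200_000
    svm_learning_rate: float = 0.2
    paper_faithful: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        cfg.fractions = tuple(cfg.fractions)
        cfg.models = tuple(cfg.models)
        cfg.c_grid = tuple(cfg.c_grid)
        return cfg

    def stage_seed(self, stage: str) -> int:
        return (self.seed + _SEED_OFFSETS[stage]) % (2**31)


def load_vitals_specs(path) -> dict[str, VitalSpec]:
    """Read a vitals-spec table (YAML: field -> {min, max, normal})."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return {
        name: VitalSpec(name, float(v["min"]), float(v["max"]), float(v["normal"]))
        for name, v in raw.items()
    }


def _config_hash(config: RunConfig) -> str:
    fields = {k: v for k, v in asdict(config).items() if k != "workdir"}
    blob = json.dumps(fields, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_experiment(config: RunConfig) -> dict:
    """Execute the full pipeline; returns {model_id: {split: report dict}}."""
    workdir = Path(config.workdir)
    stage = "validate-config"
    try:
        # fail fast on missing referenced files, before any compute
        if config.input_path is not None and not Path(config.input_path).exists():
            raise FileNotFoundError(f"input dataset not found: {config.input_path}")
        if config.vitals_spec_path is not None and not Path(config.vitals_spec_path).exists():
            raise FileNotFoundError(f"vitals spec not found: {config.vitals_spec_path}")
        if abs(sum(config.fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        workdir.mkdir(parents=True, exist_ok=True)
        specs = (
            load_vitals_specs(config.vitals_spec_path)
            if config.vitals_spec_path
            else None
        )

        stage = "simulate"
        if config.input_path is None:
            synth = SyntheticConfig(
                **{"seed": config.stage_seed("simulate"), **config.synthetic}
            )
            records = generate_dataset(synth)
            write_dataset(records, workdir / "dataset.csv")
        else:
            records = read_dataset(config.input_path)
        y = records["label"].to_numpy(dtype=int)
        visit_ids = records["visit_id"].tolist()

        stage = "split"
        split = make_split(visit_ids, config.fractions, seed=config.stage_seed("split"))
        masks = {part: split.mask(visit_ids, part) for part in ("train", "validate", "test")}
        (workdir / "split.json").write_text(
            json.dumps({"seed": split.seed, "fractions": split.fractions,
                        "assignment": split.assignment})
        )

        stage = "preprocess"
        fit_mask = (
            np.ones(len(records), dtype=bool) if config.paper_faithful else masks["train"]
        )
        cc_raw = records["chief_complaint"].tolist()
        na_raw = records["nursing_assessment"].tolist()
        fit_corpus = [t for t, m in zip(cc_raw, fit_mask) if m] + [
            t for t, m in zip(na_raw, fit_mask) if m
        ]
        prep = NotePreprocessor(
            min_pair_count=config.bigram_min_count, min_score=config.bigram_min_score
        ).fit(fit_corpus)
        cc_tokens = prep.transform(cc_raw)
        na_tokens = prep.transform(na_raw)
        both_tokens = [c + n for c, n in zip(cc_tokens, na_tokens)]
        fit_ids = [v for v, m in zip(visit_ids, fit_mask) if m]
        (workdir / "text_fit_ids.json").write_text(json.dumps(fit_ids))
        (workdir / "bigrams.json").write_text(
            json.dumps(sorted(list(p) for p in prep.config_.bigram_list))
        )

        stage = "featurize"
        vitals = VitalsVectorizer(specs=specs).fit(records)
        X_vitals = vitals.transform(records)
        need_cc = "cc" in config.models
        need_both = bool({"bow", "topics"} & set(config.models))
        cc_counts = both_counts = None
        vocab_cc = vocab_both = None
        if need_cc:
            enc_cc = BowEncoder(min_count=config.vocab_min_count).fit(
                [t for t, m in zip(cc_tokens, fit_mask) if m]
            )
            vocab_cc = enc_cc.vocabulary_
            cc_counts = enc_cc.transform(cc_tokens)
            (workdir / "vocab_cc.json").write_text(vocab_cc.to_json())
        if need_both:
            enc_both = BowEncoder(min_count=config.vocab_min_count).fit(
                [t for t, m in zip(both_tokens, fit_mask) if m]
            )
            vocab_both = enc_both.vocabulary_
            both_counts = enc_both.transform(both_tokens)
            (workdir / "vocab_both.json").write_text(vocab_both.to_json())

        topic_props = None
        if "topics" in config.models:
            stage = "topics"
            lda = GibbsLDA(
                n_topics=config.n_topics,
                alpha=config.topic_alpha,
                n_iter=config.topic_fit_iter,
                infer_iter=config.topic_infer_iter,
                infer_burn_in=config.topic_burn_in,
                threshold=config.topic_threshold,
                random_state=config.stage_seed("topics"),
            ).fit(both_counts[fit_mask])
            topic_props = lda.transform(both_counts)
            (workdir / "topic_model.json").write_text(lda.to_json())

        results: dict[str, dict] = {}
        for model_id in config.models:
            stage = f"train:{model_id}"
            X = assemble_features(
                X_vitals, model_id, cc_counts=cc_counts, both_counts=both_counts,
                topic_props=topic_props,
            )
            feature_names = list(vitals.get_feature_names_out())
            if model_id == "cc":
                feature_names += [f"word:{t}" for t in vocab_cc.tokens]
            elif model_id == "bow":
                feature_names += [f"word:{t}" for t in vocab_both.tokens]
            elif model_id == "topics":
                feature_names += [f"topic:{k}" for k in range(config.n_topics)]

            X_tr, y_tr = X[masks["train"]], y[masks["train"]]
            X_va, y_va = X[masks["validate"]], y[masks["validate"]]
            X_te, y_te = X[masks["test"]], y[masks["test"]]
            candidates = []
            for C in config.c_grid:
                svm = AucSvm(
                    C=C,
                    n_epochs=config.svm_epochs,
                    pairs_per_epoch=config.svm_pairs_per_epoch,
                    learning_rate=config.svm_learning_rate,
                    random_state=config.stage_seed("svm"),
                ).fit(X_tr, y_tr)
                candidates.append((svm, C))
            best, val_auc = select_model(candidates, X_va, y_va)

            stage = f"calibrate:{model_id}"
            platt = PlattCalibrator().fit(best.decision_function(X_va), y_va)

            stage = f"evaluate:{model_id}"
            thr_val, _, _, _ = youden_threshold(best.decision_function(X_va), y_va)
            model_reports = {}
            for part, Xp, yp in [
                ("train", X_tr, y_tr),
                ("validate", X_va, y_va),
                ("test", X_te, y_te),
            ]:
                s = best.decision_function(Xp)
                p = platt.transform(s)
                part_mask = masks[part]
                subgroups = {
                    "all": np.ones(int(part_mask.sum()), dtype=bool),
                    "admitted": records.loc[part_mask, "admitted"].to_numpy(dtype=int) == 1,
                    "not_admitted": records.loc[part_mask, "admitted"].to_numpy(dtype=int) == 0,
                    "icu": records.loc[part_mask, "icu"].to_numpy(dtype=int) == 1,
                }
                report = evaluate_scores(
                    s,
                    yp,
                    probabilities=p,
                    threshold=None if config.paper_faithful else thr_val,
                    subgroup_masks=subgroups,
                )
                model_reports[part] = report.to_dict()
            model_reports["validation_auc"] = val_auc
            model_reports["C"] = best.C
            artifact = {
                "model_id": model_id,
                "C": best.C,
                "weights": dict(zip(feature_names, best.coef_.tolist())),
                "bias": 0.0,
                "platt": {"slope": platt.slope_, "intercept": platt.intercept_},
                "threshold": float(thr_val),
                "seed": config.stage_seed("svm"),
            }
            (workdir / f"model_{model_id}.json").write_text(json.dumps(artifact))
            (workdir / f"report_{model_id}.json").write_text(json.dumps(model_reports))
            results[model_id] = model_reports
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "config": asdict(config),
        "config_hash": _config_hash(config),
        "stage_seeds": {s: config.stage_seed(s) for s in _SEED_OFFSETS},
        "version": _pkg_version,
        "fit_scope": "whole_dataset" if config.paper_faithful else "train_only",
        "artifacts": sorted(p.name for p in workdir.iterdir()),
    }
    (workdir / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, default=str))
    return results


def check_no_leakage(workdir) -> bool:
    """Verify text-artifact fitting used no validate/test record.

    Compares the recorded fitting ids against the split assignment; raises
    ``AssertionError`` on a violation (trivially true in paper-faithful
    mode, which declares whole-dataset scope in the manifest).
    """
    workdir = Path(workdir)
    manifest = json.loads((workdir / "manifest.json").read_text())
    if manifest["fit_scope"] == "whole_dataset":
        return True
    split = json.loads((workdir / "split.json").read_text())["assignment"]
    fit_ids = json.loads((workdir / "text_fit_ids.json").read_text())
    bad = [v for v in fit_ids if split[v] != "train"]
    if bad:
        raise AssertionError(
            f"{len(bad)} non-train records leaked into text-artifact fitting"
        )
    return True
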