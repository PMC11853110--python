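"""End-to-end experiment runner.

Ties the stages together — cohort simulation, preprocessing into average
pressure maps, CNN training, autoencoder compression, enrolment,
threshold sweeps and metric reports — under a single serialisable
configuration with one master seed fanned out deterministically per
stage.  Outputs are tagged with the configuration hash so intermediates
from different runs cannot be mixed silently.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from . import evaluate, openset, preprocess, simulate
from .models import (AeConfig, CnnConfig, encode, extract_embeddings,
                     maps_to_array, train_autoencoder, train_cnn)
from .openset import UNKNOWN, FeatureDatabase, FeatureRecord, enroll

logger = logging.getLogger("gaitpress")

#: Held-out (unauthorized) subject ids for the 60-subject protocol.
DEFAULT_UNKNOWN_SUBJECTS = (2, 4, 10, 11, 20, 24, 46, 50, 51, 55, 56, 57)


@dataclass(frozen=True)
class ExperimentConfig:
    """Complete, hashable description of one experiment."""

    n_subjects: int = 60
    shoe_size_distribution: dict | None = None
    rounds_type1: int = 3
    rounds_type2: int = 1
    unit_steps_per_round: int = 40
    noise_sd: float = 2.0
    anomaly_rate: float = 0.02
    z_threshold: float = 4.0
    min_mass: float = 50.0
    identical_templates: bool = False
    unknown_subjects: tuple[int, ...] | None = None
    epochs: int = 50
    ae_epochs: int = 50
    learning_rate: float = 1e-3
    batch_size: int = 16
    validation_split: float = 0.1
    decision_threshold: float = 0.85
    standardize: bool = True
    seed: int = 0

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the master seed."""
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31 - 1)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if raw.get("unknown_subjects") is not None:
            raw["unknown_subjects"] = tuple(raw["unknown_subjects"])
        return cls(**raw)


def simulate_and_preprocess(config: ExperimentConfig
                            ) -> list[preprocess.AveragePressureMap]:
    """Cohort -> trials -> average maps (trials streamed, not retained)."""
    t0 = time.perf_counter()
    profiles = simulate.generate_cohort(
        config.n_subjects,
        config.shoe_size_distribution,
        seed=config.stage_seed("cohort"),
        identical_templates=config.identical_templates,
    )
    z = config.z_threshold if config.anomaly_rate > 0 or config.noise_sd > 0 \
        else None
    maps: list[preprocess.AveragePressureMap] = []
    sim_seed = config.stage_seed("walks")
    for profile in profiles:
        seqs = simulate.schedule_cohort_trials(
            [profile], config.rounds_type1, config.rounds_type2,
            config.unit_steps_per_round, seed=sim_seed,
            noise_sd=config.noise_sd, anomaly_rate=config.anomaly_rate,
        )
        for seq in seqs:
            maps.extend(preprocess.maps_from_sequence(
                seq, z_threshold=z, min_mass=config.min_mass))
    logger.info("simulate+preprocess: %d maps in %.1fs [cfg %s]",
                len(maps), time.perf_counter() - t0, config.config_hash())
    return maps


def _subject_meta(config: ExperimentConfig) -> dict[int, dict]:
    profiles = simulate.generate_cohort(
        config.n_subjects, config.shoe_size_distribution,
        seed=config.stage_seed("cohort"),
        identical_templates=config.identical_templates,
    )
    return {p.subject_id: {"weight_kg": p.weight_kg,
                           "shoe_size_us": p.shoe_size_us} for p in profiles}


def run_closed_set(config: ExperimentConfig,
                   maps: Sequence[preprocess.AveragePressureMap] | None = None,
                   ) -> dict:
    """Closed-set protocol: train on Type I rounds 1-2, test per condition."""
    if maps is None:
        maps = simulate_and_preprocess(config)
    parts = preprocess.build_datasets(maps, preprocess.PartitionSpec.closed_set())
    cnn_cfg = CnnConfig(
        n_classes=config.n_subjects,
        learning_rate=config.learning_rate,
        epochs=config.epochs,
        batch_size=config.batch_size,
        validation_split=config.validation_split,
        seed=config.stage_seed("cnn"),
    )
    model, trace = train_cnn(parts["train"], config=cnn_cfg)
    report: dict = {
        "config_hash": config.config_hash(),
        "task": "closed_set",
        "n_train": len(parts["train"]),
        "trace": dataclasses.asdict(trace),
        "decisions": {},
    }
    meta = _subject_meta(config)
    for split in ("test_type_i", "test_type_ii"):
        x, y = maps_to_array(parts[split])
        pred = model.predict(x)
        metrics = evaluate.multiclass_metrics(y, pred)
        metrics["n_test"] = len(y)
        report[split] = metrics
        report["decisions"][split] = list(zip(y.tolist(), pred.tolist()))
        report.setdefault("misclassification", {})[split] = [
            dataclasses.asdict(r) for r in evaluate.misclassification_report(
                report["decisions"][split], meta)
        ]
    return report


def run_open_set(config: ExperimentConfig,
                 maps: Sequence[preprocess.AveragePressureMap] | None = None,
                 ) -> dict:
    """Open-set protocol: CNN on knowns -> AE codes -> enrolment -> sweep.

    Returns per-condition genuine/impostor score sets, EER, AUC, and
    accuracies at both the configured threshold and the EER threshold.
    """
    if maps is None:
        maps = simulate_and_preprocess(config)
    if config.unknown_subjects is not None:
        unknown_ids = set(config.unknown_subjects)
    elif config.n_subjects == 60:
        unknown_ids = set(DEFAULT_UNKNOWN_SUBJECTS)
    else:
        # hold out every fifth subject, mimicking the 12-of-60 pattern
        unknown_ids = {i for i in range(config.n_subjects) if i % 5 == 2}
    known_ids = sorted(set(range(config.n_subjects)) - unknown_ids)

    parts = preprocess.build_datasets(
        maps, preprocess.PartitionSpec.open_set(known_ids))
    cnn_cfg = CnnConfig(
        n_classes=len(known_ids),
        learning_rate=config.learning_rate,
        epochs=config.epochs,
        batch_size=config.batch_size,
        validation_split=config.validation_split,
        seed=config.stage_seed("cnn_open"),
    )
    model, trace = train_cnn(parts["train"], config=cnn_cfg)

    train_x, train_y = maps_to_array(parts["train"])
    emb_train = extract_embeddings(model, train_x)
    ae_cfg = AeConfig(epochs=config.ae_epochs,
                      learning_rate=config.learning_rate,
                      batch_size=config.batch_size,
                      seed=config.stage_seed("ae"))
    ae, ae_trace = train_autoencoder(emb_train, ae_cfg)

    # enrol the knowns' unaugmented training maps
    enroll_mask = np.array([not m.augmented for m in parts["train"]])
    codes_train = encode(ae, emb_train[enroll_mask])
    db = enroll(
        FeatureDatabase(standardize=config.standardize),
        [FeatureRecord(subject_id=int(sid), vector=vec)
         for sid, vec in zip(train_y[enroll_mask], codes_train)],
    )

    report: dict = {
        "config_hash": config.config_hash(),
        "task": "open_set",
        "known_subjects": known_ids,
        "unknown_subjects": sorted(unknown_ids),
        "n_train": len(parts["train"]),
        "trace": dataclasses.asdict(trace),
        "ae_trace": dataclasses.asdict(ae_trace),
    }
    for split in ("test_type_i", "test_type_ii"):
        test_maps = parts[split]
        x, y = maps_to_array(test_maps)
        codes = encode(ae, extract_embeddings(model, x))
        scores = openset.score_queries(db, codes)
        genuine = scores[np.isin(y, known_ids)]
        impostor = scores[~np.isin(y, known_ids)]
        sweep = evaluate.sweep_thresholds(genuine, impostor)
        decisions = []
        for yi, code in zip(y, codes):
            res = openset.identify(db, code, config.decision_threshold)
            true = int(yi) if yi in known_ids else UNKNOWN
            decisions.append((true, res.subject_id))
        counts = evaluate.confusion(decisions, known=set(known_ids))
        metrics = evaluate.classification_metrics(counts)
        report[split] = {
            "eer": sweep.eer,
            "eer_threshold": sweep.eer_threshold,
            "auc": evaluate.roc_auc(genuine, impostor),
            "threshold": config.decision_threshold,
            "far": evaluate.far(counts),
            "frr": evaluate.frr(counts),
            "n_genuine": int(genuine.size),
            "n_impostor": int(impostor.size),
            "identity_accuracy": (counts.tp_correct_id / (counts.tp + counts.fn)
                                  if counts.tp + counts.fn else float("nan")),
            **metrics,
        }
        report[split]["genuine_scores"] = genuine.tolist()
        report[split]["impostor_scores"] = impostor.tolist()
    return report
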