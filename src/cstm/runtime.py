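"""Experiment orchestration: config, seeding, persistence, full pipeline.

``run_experiment`` wires the stages together: synthesize a word corpus,
run the auditory front-end, train the encoder layer on the clean stream,
re-run both representations in inference mode on the clean and degraded
corpora, train linear SVMs on the clean word vectors, and score the
trained classifiers on every degraded condition.

``small_scale_robustness_run`` is the scaled-down study condition used for
fast, repeatable robustness checks (small layer, 100-word monosyllabic
corpus); its choices are fixed and documented in the methods note.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import corpus as corpus_mod
from . import encoder as encoder_mod
from . import evaluation as eval_mod
from . import frontend as frontend_mod

__all__ = [
    "ExperimentConfig",
    "StageError",
    "run_experiment",
    "small_scale_robustness_run",
    "SMALL_ENCODER_CONFIG",
    "load_experiment_config",
    "save_experiment_config",
]


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


# The standard degraded-listening conditions, on the corpus's native scale.
STANDARD_VARIANTS: dict[str, corpus_mod.AcousticVariant] = {
    "white_noise_19.8dB": corpus_mod.AcousticVariant("white_noise", 19.8),
    "white_noise_13.8dB": corpus_mod.AcousticVariant("white_noise", 13.8),
    "reverberation_0.61s": corpus_mod.AcousticVariant("reverberation", 0.61),
    "reverberation_1.78s": corpus_mod.AcousticVariant("reverberation", 1.78),
    "pitch_up_20pct": corpus_mod.AcousticVariant("pitch_shift", 1.2),
    "pitch_down_20pct": corpus_mod.AcousticVariant("pitch_shift", 0.8),
    "changed_voices": corpus_mod.AcousticVariant("changed_voices", "set2"),
}

# Reduced architecture for fast runs: 3x3 columns of 6x6 units keeps the
# sparse (1 unit) vs massive (3 units) activation structure of the full
# model at a size where staged training completes in seconds.
SMALL_ENCODER_CONFIG = encoder_mod.EncoderConfig(
    grid_shape=(3, 3),
    unit_shape=(6, 6),
    afferent_inputs=31,
    lateral_rf=(3, 3),
    linked_fraction=0.9,
    potential_per_dendrite=6,
    sparsity=0.97,
    proximal_activation_pct=0.10,
    schedule=encoder_mod.TrainingSchedule(n_stages=2, passes_per_stage=2, final_passes=1),
)


@dataclass
class ExperimentConfig:
    n_words: int = 5
    syllables: int = 1
    total_words: int = 100
    n_voices: int = 10
    sample_rate: int = 8000
    variants: tuple[str, ...] = ("white_noise_13.8dB",)
    c_grid: tuple[float, ...] = eval_mod.DEFAULT_C_GRID
    folds: int = 5
    encoder: encoder_mod.EncoderConfig = field(default_factory=lambda: SMALL_ENCODER_CONFIG)
    seed: int = 0

    def frontend_config(self) -> frontend_mod.FrontEndConfig:
        return frontend_mod.FrontEndConfig(sample_rate=self.sample_rate)


def _word_features(stream, activations, marks):
    mr = eval_mod.aggregate_frame_vectors(stream, marks)
    el = eval_mod.aggregate_activation_vectors(activations, marks)
    return {"mrstsa": mr, "encoder": el}


def run_experiment(config: ExperimentConfig, out_dir: str | Path | None = None) -> dict:
    """Full pipeline for one seed; returns the results bundle as a dict."""
    seed = config.seed
    try:
        vocab = corpus_mod.make_vocabulary(config.n_words, config.syllables, seed=seed)
        voices = corpus_mod.make_voice_set(config.n_voices, seed=seed, set_id="set1")
        spec = corpus_mod.CorpusSpec(
            vocabulary=vocab,
            voices=voices,
            total_words=config.total_words,
            sample_rate=config.sample_rate,
            seed=seed,
        )
        audio, track = corpus_mod.render_corpus(spec)
    except Exception as exc:  # noqa: BLE001
        raise StageError("corpus", str(exc)) from exc

    fe_config = config.frontend_config()
    try:
        clean_stream = frontend_mod.process_audio(audio, fe_config)
    except Exception as exc:  # noqa: BLE001
        raise StageError("frontend", str(exc)) from exc

    try:
        layer = encoder_mod.EncoderLayer(config.encoder, seed=seed)
        train_log = layer.train(clean_stream)
    except Exception as exc:  # noqa: BLE001
        raise StageError("train", str(exc)) from exc

    try:
        marks, labels = eval_mod.marks_from_track(
            track, config.sample_rate, fe_config.frame_period
        )
        detected = eval_mod.detect_word_boundaries(clean_stream)
        clean_acts = layer.infer(clean_stream, seed=seed)
        clean_features = _word_features(clean_stream, clean_acts, marks)
    except Exception as exc:  # noqa: BLE001
        raise StageError("infer", str(exc)) from exc

    try:
        results = {
            source: eval_mod.svm_crossval(X, labels, config.c_grid, folds=config.folds, seed=seed)
            for source, X in clean_features.items()
        }
        variant_features: dict[str, dict[str, tuple]] = {}
        for name in config.variants:
            variant = STANDARD_VARIANTS[name]
            if variant.kind == "changed_voices":
                voices2 = corpus_mod.make_voice_set(
                    config.n_voices, seed=seed + 1, set_id="set2"
                )
                spec2 = dataclasses.replace(spec, voices=voices2)
                v_audio, v_track = corpus_mod.render_corpus(spec2)
                v_marks, v_labels = eval_mod.marks_from_track(
                    v_track, config.sample_rate, fe_config.frame_period
                )
            else:
                v_audio = corpus_mod.apply_variant(
                    audio, variant, config.sample_rate, seed=seed
                )
                v_marks, v_labels = marks, labels
            v_stream = frontend_mod.process_audio(v_audio, fe_config)
            v_acts = layer.infer(v_stream, seed=seed)
            feats = _word_features(v_stream, v_acts, v_marks)
            variant_features[name] = {s: (X, v_labels) for s, X in feats.items()}
        table = eval_mod.evaluate_variants(results, variant_features)
    except Exception as exc:  # noqa: BLE001
        raise StageError("evaluate", str(exc)) from exc

    bundle = {
        "seed": seed,
        "n_frames": len(clean_stream),
        "detected_segments": len(detected),
        "true_segments": len(track),
        "train_log": train_log,
        "cv_accuracy": {s: r.accuracy for s, r in results.items()},
        "best_c": {s: r.best_c for s, r in results.items()},
        "variant_accuracy": table,
        "established_distal_fraction": layer.established_synapse_fraction(),
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        encoder_mod.save_model(out / "model.h5", layer)
        frontend_mod.save_frames(out / "frames.h5", clean_stream)
        with open(out / "results.json", "w") as fh:
            json.dump(bundle, fh, indent=1)
        with open(out / "results.tsv", "w") as fh:
            fh.write("variant\tsource\taccuracy\n")
            for variant, row in table.items():
                for source, acc in row.items():
                    fh.write(f"{variant}\t{source}\t{acc:.2f}\n")
    return bundle


def small_scale_robustness_run(seed: int = 0) -> dict:
    """One scaled-down robustness comparison under 13.8 dB white noise.

    Returns CV accuracies on the clean corpus and test accuracies under
    noise for both feature sources.
    """
    bundle = run_experiment(ExperimentConfig(seed=seed))
    noise = bundle["variant_accuracy"]["white_noise_13.8dB"]
    return {
        "seed": seed,
        "mrstsa_cv": bundle["cv_accuracy"]["mrstsa"],
        "encoder_cv": bundle["cv_accuracy"]["encoder"],
        "mrstsa_noise": noise["mrstsa"],
        "encoder_noise": noise["encoder"],
    }


def save_experiment_config(path: str | Path, config: ExperimentConfig) -> None:
    d = dataclasses.asdict(config)
    d["encoder"]["schedule"] = dataclasses.asdict(config.encoder.schedule)
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh)


def load_experiment_config(path: str | Path) -> ExperimentConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    enc = d.pop("encoder")
    sched = encoder_mod.TrainingSchedule(**enc.pop("schedule"))
    for key in ("grid_shape", "unit_shape", "afferent_shape", "lateral_rf"):
        if key in enc:
            enc[key] = tuple(enc[key])
    d["encoder"] = encoder_mod.EncoderConfig(schedule=sched, **enc)
    for key in ("variants", "c_grid"):
        if key in d:
            d[key] = tuple(d[key])
    return ExperimentConfig(**d)
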