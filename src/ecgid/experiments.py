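"""The desk-scale reference identification experiment, end to end.

One call generates a synthetic cohort, cleans and windows every recording,
encodes GAF images, splits 80/10/10 stratified, trains the desk-profile
classifier and evaluates closed-set identification on the held-out test
windows.  Both the test suite and the reproduction script drive this module,
so the protocol lives in exactly one place.
"""

from __future__ import annotations

from dataclasses import dataclass

from .evaluate import DatasetSplit, EvalReport, evaluate_pipeline, split_dataset
from .gaf import encode_segment
from .io import GAFDataset
from .model import TrainingHistory, build_model, desk_config, train
from .preprocess import PreprocessConfig, preprocess_pipeline
from .simulate import PopulationConfig, generate_cohort

__all__ = ["ExperimentResult", "encode_cohort", "run_identification_experiment"]


@dataclass
class ExperimentResult:
    report: EvalReport
    history: TrainingHistory
    n_images: int
    n_train: int
    n_test: int


def encode_cohort(
    seed: int,
    activities: list[str],
    n_subjects: int = 10,
    duration: float = 120.0,
    paa_size: int = 64,
    sampling_rate: float = 128.0,
) -> GAFDataset:
    """Synthesise, clean, window and GAF-encode a labelled cohort."""
    population = PopulationConfig(
        n_subjects=n_subjects, sampling_rate=sampling_rate, seed=seed
    )
    recordings = generate_cohort(population, activities, duration)
    config = PreprocessConfig()
    segments = [s for rec in recordings for s in preprocess_pipeline(rec, config)]
    images = [encode_segment(s, paa_size=paa_size) for s in segments]
    return GAFDataset.from_images(
        images,
        meta={
            "window_seconds": config.window_seconds,
            "paa_size": paa_size,
            "rescale_mode": "symmetric",
            "source": f"synthetic cohort (seed={seed}, activities={activities})",
        },
    )


def run_identification_experiment(
    seed: int,
    activities: list[str] | None = None,
    n_subjects: int = 10,
    duration: float = 120.0,
    paa_size: int = 64,
    max_epochs: int = 60,
) -> ExperimentResult:
    """Run the full pipeline once and return the closed-set evaluation report.

    ``seed`` drives every stochastic element: the cohort, the split and the
    training run.
    """
    if activities is None:
        activities = ["resting"]
    dataset = encode_cohort(
        seed, activities, n_subjects=n_subjects, duration=duration, paa_size=paa_size
    )
    train_set, val_set, test_set = split_dataset(dataset, DatasetSplit(seed=seed))
    config = desk_config(
        num_classes=n_subjects,
        input_size=paa_size,
        max_epochs=max_epochs,
        early_stop_patience=max_epochs,
        seed=seed,
    )
    trained, history = train(build_model(config), train_set, val_set, config)
    report = evaluate_pipeline(trained, test_set)
    return ExperimentResult(
        report=report,
        history=history,
        n_images=len(dataset),
        n_train=len(train_set),
        n_test=len(test_set),
    )
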