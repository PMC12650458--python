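"""Desk-scale end-to-end benchmark configurations.

The separable benchmark uses the default class couplings (distinct
directed VAR patterns and band emphases per emotion class) at a reduced
problem size — 2 subjects, 15 clips per class, 7.5 s clips, 8 EEG / 4
fNIRS channels — chosen so the full generate -> preprocess -> GC ->
train cycle completes in minutes on one CPU while retaining the study's
clip-wise structure and 12/3 per-class split. The null benchmark keeps
every class's coupling identical, so labels carry no signal and any
classifier must stay at the 25% chance level.
"""

from __future__ import annotations

from .features import dataset_to_bundles
from .synthetic import SimConfig, default_class_coupling, generate_dataset
from .train import EvalReport, TrainConfig, cross_validate

__all__ = ["benchmark_sim_config", "benchmark_train_config", "run_benchmark"]


def benchmark_sim_config(separable: bool = True, seed: int = 0) -> SimConfig:
    return SimConfig(
        n_subjects=2,
        n_clips_per_class=15,
        clip_duration=7.5,
        n_eeg_channels=8,
        n_fnirs_channels=4,
        class_coupling=default_class_coupling(8, 4, separable=separable),
        seed=seed,
    )


def benchmark_train_config(
    variant: str = "mfa_cnn", seed: int = 0, epochs: int = 5
) -> TrainConfig:
    return TrainConfig(variant=variant, epochs=epochs, seed=seed)


def run_benchmark(
    separable: bool = True,
    seed: int = 0,
    variant: str = "mfa_cnn",
    epochs: int = 5,
    protocol: str = "fivefold_subject_dependent",
) -> EvalReport:
    """Generate, featurise and cross-validate one benchmark condition."""
    ds = generate_dataset(benchmark_sim_config(separable=separable, seed=seed))
    bundles = dataset_to_bundles(ds, order_policy="bic", seed=seed)
    cfg = benchmark_train_config(variant=variant, seed=seed, epochs=epochs)
    return cross_validate(bundles, protocol, cfg)
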