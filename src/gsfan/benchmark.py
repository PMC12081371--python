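"""The default synthetic gesture benchmark.

One canonical configuration of the synthetic generator, used by the
ablation sweeps and the acceptance script, so every consumer measures
the same conditions: 32 gesture classes x 4 subjects x 10 clouds each,
64 points per cloud, 1 mm measurement noise, +/-15 deg / +/-5 cm pose
jitter (the generator defaults).

The cloud size and epoch budget are desk-scale choices: training runs
on a single CPU, so the sweeps use small clouds and a reduced epoch
count that leaves the reference configuration (3 edge-convolution
layers, embedding dimension 128) on the rising part of its learning
curve; see docs/methods.md for the sizing rationale and what that
implies for interpreting sweep accuracies.
"""

from __future__ import annotations

from .evaluate import SweepResult, sweep_dims, sweep_layers
from .hand import generate_dataset
from .model import TrainConfig

__all__ = [
    "BENCHMARK_N_PER_CLASS",
    "BENCHMARK_N_SUBJECTS",
    "BENCHMARK_N_POINTS",
    "BENCHMARK_NOISE_SD",
    "SWEEP_EPOCHS",
    "SWEEP_SEEDS",
    "benchmark_dataset",
    "benchmark_train_config",
    "run_layer_sweep",
    "run_dim_sweep",
]

BENCHMARK_N_PER_CLASS = 10
BENCHMARK_N_SUBJECTS = 4
BENCHMARK_N_POINTS = 64
BENCHMARK_NOISE_SD = 1e-3
SWEEP_EPOCHS = 30
SWEEP_SEEDS = 3


def benchmark_dataset(seed: int = 0):
    """Generate the default synthetic benchmark dataset."""
    return generate_dataset(
        n_per_class=BENCHMARK_N_PER_CLASS,
        n_subjects=BENCHMARK_N_SUBJECTS,
        n_points=BENCHMARK_N_POINTS,
        noise_sd=BENCHMARK_NOISE_SD,
        seed=seed,
    )


def benchmark_train_config(seed: int = 0, epochs: int = SWEEP_EPOCHS) -> TrainConfig:
    return TrainConfig(epochs=epochs, seed=seed)


def run_layer_sweep(seed: int = 0, dataset=None, n_seeds: int = SWEEP_SEEDS,
                    epochs: int = SWEEP_EPOCHS) -> SweepResult:
    """The edge-convolution depth ablation on the default benchmark."""
    dataset = dataset if dataset is not None else benchmark_dataset(seed)
    return sweep_layers(
        dataset,
        n_seeds=n_seeds,
        train_config=benchmark_train_config(seed=seed, epochs=epochs),
    )


def run_dim_sweep(seed: int = 0, dataset=None, n_seeds: int = SWEEP_SEEDS,
                  epochs: int = SWEEP_EPOCHS) -> SweepResult:
    """The embedding-dimension ablation on the default benchmark."""
    dataset = dataset if dataset is not None else benchmark_dataset(seed)
    return sweep_dims(
        dataset,
        n_seeds=n_seeds,
        train_config=benchmark_train_config(seed=seed, epochs=epochs),
    )
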