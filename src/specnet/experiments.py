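"""Robustness and tracking experiments.

Three computational experiments probe the network representation:

* a noise-robustness sweep — an ensemble of copies of the cohort is polluted
  with additive zero-mean Gaussian noise of increasing standard deviation,
  and the network method's leave-one-out score is compared against standard
  classifiers (naive Bayes, decision tree, multilayer perceptron) trained on
  the raw bin intensities;
* a bin-size sweep — classification scores after aggregating raw
  measurements into increasingly coarse bins;
* longitudinal tracking — link density of per-timepoint networks of a
  single subject measured repeatedly, e.g. across chemotherapy sessions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import loo_classify
from .dataset import SpectralDataset, add_noise, bin_spectrum
from .metrics import link_density
from .network import binarize, reconstruct
from .pairmodel import DualClassModel

#: the network pipeline plus the three baseline classifiers
DEFAULT_METHODS = ("network", "naive_bayes", "decision_tree", "mlp")

#: ensemble size for the noise experiment
DEFAULT_REPLICATES = 100


@dataclass
class SweepResult:
    """Scores of a parameter sweep, per (axis value, method), averaged over replicates."""

    axis: list
    axis_name: str
    methods: list[str]
    scores: pd.DataFrame  # index: axis values, columns: methods, mean scores
    records: pd.DataFrame  # tidy rows: axis value, replicate, method, score
    replicates: int
    seed: int


@dataclass
class TrajectoryResult:
    """Link density of one subject's network at each timepoint."""

    timepoints: list
    densities: list[float]
    threshold_used: float


def _score_method(data: SpectralDataset, method: str, *, threshold, features, seed):
    if method == "network":
        res = loo_classify(
            data,
            features=features,
            classifier="svm_linear",
            threshold=threshold,
            refit_models=True,
            seed=seed,
        )
    else:
        res = loo_classify(data, representation="raw", classifier=method, seed=seed)
    return res.score


def noise_sweep(
    data: SpectralDataset,
    sigmas: list[float],
    n_replicates: int = DEFAULT_REPLICATES,
    methods: tuple[str, ...] = DEFAULT_METHODS,
    seed: int = 0,
    *,
    threshold: float = 0.65,
    features: tuple[str, ...] = ("density", "efficiency"),
    sigma_as_fraction: bool = False,
) -> SweepResult:
    """Noise-robustness sweep over an ensemble of polluted cohorts.

    ``sigma_as_fraction=True`` reads each sigma as a fraction of the per-bin
    standard deviation instead of absolute intensity units.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    streams = np.random.SeedSequence(seed).spawn(len(sigmas) * n_replicates)
    rows = []
    for si, sigma in enumerate(sigmas):
        if sigma < 0:
            raise ValueError("noise sigma must be non-negative")
        for rep in range(n_replicates):
            stream = streams[si * n_replicates + rep]
            if sigma_as_fraction:
                rng = np.random.default_rng(stream)
                scales = sigma * data.intensities.std(axis=0, ddof=1)
                noisy_values = data.intensities + rng.standard_normal(
                    data.intensities.shape
                ) * scales[None, :]
                noisy = SpectralDataset(
                    noisy_values,
                    data.subject_ids,
                    data.labels,
                    data.bin_axis,
                    data.axis_unit,
                    [*data.provenance, f"added per-bin fractional noise {sigma}"],
                )
            else:
                noisy = add_noise(data, sigma, np.random.default_rng(stream))
            for method in methods:
                score = _score_method(
                    noisy, method, threshold=threshold, features=features, seed=seed
                )
                rows.append(
                    {"sigma": sigma, "replicate": rep, "method": method, "score": score}
                )
    records = pd.DataFrame(rows)
    scores = records.pivot_table(
        index="sigma", columns="method", values="score", aggfunc="mean"
    )[list(methods)]
    return SweepResult(
        axis=list(sigmas),
        axis_name="sigma",
        methods=list(methods),
        scores=scores,
        records=records,
        replicates=n_replicates,
        seed=seed,
    )


def binning_sweep(
    data: SpectralDataset,
    bin_sizes: list[int],
    seed: int = 0,
    *,
    threshold: float = 0.65,
    features: tuple[str, ...] = ("density", "efficiency"),
    classifier: str = "svm_linear",
) -> SweepResult:
    """Classification score as a function of the bin size.

    A bin size that collapses the spectrum to fewer than two bins leaves no
    pairs to model; its score is recorded as NaN and flagged.
    """
    rows = []
    for size in bin_sizes:
        binned = bin_spectrum(data, bin_size=size)
        if binned.n_bins < 2:
            rows.append(
                {"bin_size": size, "replicate": 0, "method": "network",
                 "score": np.nan, "flag": "degenerate: fewer than 2 bins"}
            )
            continue
        res = loo_classify(
            binned,
            features=features,
            classifier=classifier,
            threshold=threshold,
            refit_models=True,
            seed=seed,
        )
        rows.append(
            {"bin_size": size, "replicate": 0, "method": "network",
             "score": res.score, "flag": ""}
        )
    records = pd.DataFrame(rows)
    scores = records.pivot_table(
        index="bin_size", columns="method", values="score", aggfunc="mean",
        dropna=False,
    )
    return SweepResult(
        axis=list(bin_sizes),
        axis_name="bin_size",
        methods=["network"],
        scores=scores,
        records=records,
        replicates=1,
        seed=seed,
    )


def track_evolution(
    model: DualClassModel,
    series: list[tuple[object, np.ndarray]],
    threshold: float = 0.65,
    *,
    symmetrization: str = "mean",
) -> TrajectoryResult:
    """Link density of per-timepoint networks, in input order.

    ``series`` holds (timepoint, intensity-vector) pairs of one subject
    measured repeatedly; the dual-class model stays fixed (trained on the
    reference cohorts), so density changes reflect the subject, not the model.
    """
    if not series:
        raise ValueError("series must be non-empty")
    timepoints = []
    densities = []
    for t, values in series:
        net = reconstruct(
            np.asarray(values, dtype=float), model,
            symmetrization=symmetrization, subject_id=str(t),
        )
        densities.append(link_density(binarize(net, threshold)))
        timepoints.append(t)
    return TrajectoryResult(
        timepoints=timepoints, densities=densities, threshold_used=float(threshold)
    )


def plot_sweep(result: SweepResult, path) -> None:
    """Line plot of mean score vs the swept parameter, one line per method."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    for method in result.methods:
        ax.plot(result.scores.index, result.scores[method], marker="o", label=method)
    ax.set_xlabel(result.axis_name)
    ax.set_ylabel("mean classification score (%)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_trajectory(result: TrajectoryResult, path) -> None:
    """Link density through time for a tracked subject."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(range(len(result.densities)), result.densities, marker="s", color="k")
    ax.set_xticks(range(len(result.timepoints)))
    ax.set_xticklabels([str(t) for t in result.timepoints], rotation=45, fontsize=8)
    ax.set_ylabel("link density")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
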