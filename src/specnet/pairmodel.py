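"""Class-conditional pairwise linear models and the probabilistic link weight.

For every ordered pair of bins (i, j) two ordinary least-squares lines are
fitted, one within the control group and one within the disease group:

    c[.,j] = alpha  * c[.,i] + beta  + eps
    d[.,j] = alpha' * d[.,i] + beta' + eps'

The spread of each residual vector defines a Gaussian error model around the
fitted line.  For a new subject with values (x_i, x_j), the link weight is the
normalized probability that the point is generated by the disease model:

    w = N(x_j; yhat_d, sigma_d) / (N(x_j; yhat_c, sigma_c) + N(x_j; yhat_d, sigma_d))

with yhat the class-specific prediction of bin j from bin i.  The ratio is
evaluated in log-density space, so distant points never overflow and the
weight is always a well-defined number in [0, 1].
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

MODEL_FORMAT_VERSION = 1

#: minimum number of subjects per class: two points pin a line, one more
#: leaves a degree of freedom for the residual spread
MIN_CLASS_SIZE = 3

#: residual-spread floor, as a fraction of the response-bin intensity range
#: per class; a perfect fit would otherwise collapse the Gaussian to a delta
RESID_FLOOR_SCALE = 1e-9


@dataclass
class PairwiseLinearModel:
    """Fitted dual model for one ordered bin pair (predictor -> response)."""

    predictor_bin: int
    response_bin: int
    control_slope: float
    control_intercept: float
    control_resid_std: float
    disease_slope: float
    disease_intercept: float
    disease_resid_std: float
    n_control: int
    n_disease: int
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.predictor_bin == self.response_bin:
            raise ValueError("predictor and response bin must differ")
        if self.control_resid_std < 0 or self.disease_resid_std < 0:
            raise ValueError("residual spreads must be non-negative")


@dataclass
class DualClassModel:
    """All n(n-1) ordered-pair models, stored as dense n x n coefficient grids.

    Entry ``[i, j]`` of each grid describes the regression of bin j on bin i.
    The diagonal is unused and flagged degenerate.
    """

    control_slope: np.ndarray
    control_intercept: np.ndarray
    control_resid_std: np.ndarray
    disease_slope: np.ndarray
    disease_intercept: np.ndarray
    disease_resid_std: np.ndarray
    degenerate: np.ndarray
    n_control: int
    n_disease: int
    bin_axis: np.ndarray | None = None
    training_ids: dict[str, list[str]] = field(default_factory=dict)
    config_digest: str = ""

    @property
    def n_bins(self) -> int:
        return self.control_slope.shape[0]

    @property
    def n_pairs(self) -> int:
        """Number of ordered pair models, n(n-1)."""
        n = self.n_bins
        return n * (n - 1)

    def pair(self, i: int, j: int) -> PairwiseLinearModel:
        """View of the ordered pair (i -> j) as a :class:`PairwiseLinearModel`."""
        if i == j:
            raise ValueError("predictor and response bin must differ")
        return PairwiseLinearModel(
            predictor_bin=i,
            response_bin=j,
            control_slope=float(self.control_slope[i, j]),
            control_intercept=float(self.control_intercept[i, j]),
            control_resid_std=float(self.control_resid_std[i, j]),
            disease_slope=float(self.disease_slope[i, j]),
            disease_intercept=float(self.disease_intercept[i, j]),
            disease_resid_std=float(self.disease_resid_std[i, j]),
            n_control=self.n_control,
            n_disease=self.n_disease,
            degenerate=bool(self.degenerate[i, j]),
        )

    # -- serialization ---------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        payload = {
            "format_version": MODEL_FORMAT_VERSION,
            "n_control": self.n_control,
            "n_disease": self.n_disease,
            "bin_axis": None if self.bin_axis is None else self.bin_axis.tolist(),
            "training_ids": self.training_ids,
            "config_digest": self.config_digest,
            "arrays": {
                name: getattr(self, name).tolist()
                for name in (
                    "control_slope",
                    "control_intercept",
                    "control_resid_std",
                    "disease_slope",
                    "disease_intercept",
                    "disease_resid_std",
                    "degenerate",
                )
            },
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "DualClassModel":
        payload = json.loads(Path(path).read_text())
        version = payload.get("format_version")
        if version != MODEL_FORMAT_VERSION:
            raise ValueError(f"unsupported model format version {version!r}")
        arrays = {k: np.asarray(v) for k, v in payload["arrays"].items()}
        arrays["degenerate"] = arrays["degenerate"].astype(bool)
        axis = payload["bin_axis"]
        return cls(
            n_control=payload["n_control"],
            n_disease=payload["n_disease"],
            bin_axis=None if axis is None else np.asarray(axis, dtype=float),
            training_ids=payload.get("training_ids", {}),
            config_digest=payload.get("config_digest", ""),
            **arrays,
        )


def _class_fit(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """OLS of every column on every other, vectorized through the Gram matrix.

    Returns (slope, intercept, resid_std, zero_variance_bins); entry [i, j]
    regresses column j on column i.  Residual variance uses the unbiased
    denominator (m - 2).
    """
    m, n = X.shape
    mu = X.mean(axis=0)
    Xc = X - mu
    S = Xc.T @ Xc  # centered cross-product matrix
    var = np.diag(S).copy()
    zero_var = var <= 0
    safe_var = np.where(zero_var, 1.0, var)
    slope = S / safe_var[:, None]
    slope[zero_var, :] = 0.0
    intercept = mu[None, :] - slope * mu[:, None]
    # RSS[i, j] = S[j,j] - slope[i,j] * S[i,j]; clip tiny negatives from rounding
    rss = np.clip(var[None, :] - slope * S, 0.0, None)
    resid_std = np.sqrt(rss / (m - 2))
    # floor per response column: fraction of that bin's intensity range
    col_range = X.max(axis=0) - X.min(axis=0)
    floor = RESID_FLOOR_SCALE * np.where(col_range > 0, col_range, 1.0)
    resid_std = np.maximum(resid_std, floor[None, :])
    return slope, intercept, resid_std, zero_var


def fit_pair_models(
    controls: np.ndarray,
    patients: np.ndarray,
    *,
    bin_axis: np.ndarray | None = None,
    control_ids: list[str] | None = None,
    disease_ids: list[str] | None = None,
) -> DualClassModel:
    """Fit both class-conditional lines for all ordered bin pairs.

    ``controls`` and ``patients`` are the per-class intensity matrices
    (subjects x bins).  Pairs in which either bin has zero variance in either
    class are flagged degenerate (their weight is later pinned at the neutral
    0.5) rather than dropped, so the node set stays constant across subjects.
    """
    controls = np.asarray(controls, dtype=float)
    patients = np.asarray(patients, dtype=float)
    if controls.ndim != 2 or patients.ndim != 2:
        raise ValueError("class matrices must be 2-D (subjects x bins)")
    if controls.shape[1] != patients.shape[1]:
        raise ValueError(
            f"bin count mismatch: {controls.shape[1]} control vs "
            f"{patients.shape[1]} disease bins"
        )
    for name, X in (("control", controls), ("disease", patients)):
        if X.shape[0] < MIN_CLASS_SIZE:
            raise ValueError(
                f"{name} class has {X.shape[0]} subjects; at least "
                f"{MIN_CLASS_SIZE} are required to fit a line and a spread"
            )
    if control_ids and disease_ids and set(control_ids) & set(disease_ids):
        raise ValueError("training sets must be disjoint between classes")

    sc, ic, rc, zc = _class_fit(controls)
    sd, idc, rd, zd = _class_fit(patients)
    zero_bins = zc | zd
    degenerate = zero_bins[:, None] | zero_bins[None, :]
    np.fill_diagonal(degenerate, True)

    digest = hashlib.sha256(
        json.dumps(
            {
                "min_class_size": MIN_CLASS_SIZE,
                "resid_floor_scale": RESID_FLOOR_SCALE,
                "resid_denominator": "m-2",
            }
        ).encode()
    ).hexdigest()[:16]

    return DualClassModel(
        control_slope=sc,
        control_intercept=ic,
        control_resid_std=rc,
        disease_slope=sd,
        disease_intercept=idc,
        disease_resid_std=rd,
        degenerate=degenerate,
        n_control=controls.shape[0],
        n_disease=patients.shape[0],
        bin_axis=None if bin_axis is None else np.asarray(bin_axis, dtype=float),
        training_ids={
            "control": list(control_ids or []),
            "disease": list(disease_ids or []),
        },
        config_digest=digest,
    )


def fit_dataset(data) -> DualClassModel:
    """Fit a :class:`DualClassModel` from a labeled :class:`~specnet.dataset.SpectralDataset`."""
    from .dataset import CONTROL, DISEASE

    c_mask = data.labels == CONTROL
    d_mask = data.labels == DISEASE
    ids = np.asarray(data.subject_ids, dtype=object)
    return fit_pair_models(
        data.intensities[c_mask],
        data.intensities[d_mask],
        bin_axis=data.bin_axis,
        control_ids=list(ids[c_mask]),
        disease_ids=list(ids[d_mask]),
    )


# ---------------------------------------------------------------------------
# Link weight
# ---------------------------------------------------------------------------


def _weight_from_logs(log_c, log_d):
    """w = p_d / (p_c + p_d) from log-densities, via a shifted softmax.

    Subtracting the elementwise maximum keeps both exponentials in range;
    equal log-densities give exactly 0.5.
    """
    shift = np.maximum(log_c, log_d)
    ec = np.exp(log_c - shift)
    ed = np.exp(log_d - shift)
    return ed / (ec + ed)


def disease_probability(x_i: float, x_j: float, pair: PairwiseLinearModel) -> float:
    """Probability that the pair of values follows the disease model.

    Returns the neutral 0.5 for degenerate pairs.  The complementary control
    probability is ``1 - w``.
    """
    if not (math.isfinite(x_i) and math.isfinite(x_j)):
        raise ValueError("bin values must be finite")
    if pair.degenerate:
        return 0.5
    if pair.control_resid_std <= 0 or pair.disease_resid_std <= 0:
        raise ValueError("pair has non-positive residual spread; refit with flooring")
    yc = pair.control_slope * x_i + pair.control_intercept
    yd = pair.disease_slope * x_i + pair.disease_intercept
    zc = (x_j - yc) / pair.control_resid_std
    zd = (x_j - yd) / pair.disease_resid_std
    log_c = -math.log(pair.control_resid_std) - 0.5 * zc * zc
    log_d = -math.log(pair.disease_resid_std) - 0.5 * zd * zd
    return float(_weight_from_logs(log_c, log_d))


def weight_matrix(model: DualClassModel, x: np.ndarray) -> np.ndarray:
    """All n(n-1) ordered link weights of one subject, as an n x n matrix.

    Entry ``[i, j]`` is the weight of the ordered pair predicting bin j from
    bin i.  Degenerate pairs (including the diagonal) get the neutral 0.5.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (model.n_bins,):
        raise ValueError(
            f"subject has {x.shape} values, model expects ({model.n_bins},)"
        )
    if not np.all(np.isfinite(x)):
        raise ValueError("subject values must be finite")
    yc = model.control_slope * x[:, None] + model.control_intercept
    yd = model.disease_slope * x[:, None] + model.disease_intercept
    zc = (x[None, :] - yc) / model.control_resid_std
    zd = (x[None, :] - yd) / model.disease_resid_std
    log_c = -np.log(model.control_resid_std) - 0.5 * zc * zc
    log_d = -np.log(model.disease_resid_std) - 0.5 * zd * zd
    W = _weight_from_logs(log_c, log_d)
    W[model.degenerate] = 0.5
    return W
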