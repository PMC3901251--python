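"""Spectral matrix container and preprocessing.

A cohort of subjects is held as an ``m x n`` intensity matrix (one row per
subject, one column per spectral bin), together with subject labels
(control / disease / unlabeled) and the spectral axis (ppm for NMR,
cm^-1 for Raman; the unit is metadata only and never converted).

Preprocessing covers the steps applied to raw spectra before network
reconstruction: aggregating raw measurements into bins, masking excluded
axis regions (e.g. water or drug peaks), and injecting additive Gaussian
noise for robustness experiments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

#: the only label values a dataset may carry
LABELS = ("control", "disease", "unlabeled")

CONTROL = "control"
DISEASE = "disease"
UNLABELED = "unlabeled"


@dataclass
class SpectralDataset:
    """Subjects x bins intensity matrix with labels and an axis.

    Parameters
    ----------
    intensities
        ``(m, n)`` float matrix, one row per subject, one column per bin.
        Must be fully finite: the loader rejects missing values rather than
        imputing silently.
    subject_ids
        Unique opaque identifiers, one per row.
    labels
        Per-subject category, each in :data:`LABELS`.
    bin_axis
        Per-column axis position (ppm or cm^-1), strictly monotone.
    axis_unit
        Free-text unit tag; carried along, never interpreted.
    provenance
        Append-only log of the processing steps applied.
    """

    intensities: np.ndarray
    subject_ids: list[str]
    labels: np.ndarray
    bin_axis: np.ndarray
    axis_unit: str = "ppm"
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        self.bin_axis = np.asarray(self.bin_axis, dtype=float)
        self.subject_ids = list(self.subject_ids)
        if self.intensities.ndim != 2:
            raise ValueError("intensities must be a 2-D matrix")
        m, n = self.intensities.shape
        if len(self.subject_ids) != m:
            raise ValueError(
                f"{len(self.subject_ids)} subject ids for {m} intensity rows"
            )
        if len(set(self.subject_ids)) != m:
            raise ValueError("subject ids must be unique")
        if self.labels.shape != (m,):
            raise ValueError(f"{self.labels.shape[0]} labels for {m} rows")
        bad = sorted(set(self.labels) - set(LABELS))
        if bad:
            raise ValueError(
                f"invalid labels {bad}; allowed labels are {list(LABELS)}"
            )
        if self.bin_axis.shape != (n,):
            raise ValueError(f"{self.bin_axis.shape[0]} axis values for {n} columns")
        if not np.all(np.isfinite(self.intensities)):
            r, c = np.argwhere(~np.isfinite(self.intensities))[0]
            raise ValueError(
                f"non-finite intensity for subject {self.subject_ids[r]!r}, "
                f"bin {self.bin_axis[c]!r}"
            )
        if n >= 2:
            d = np.diff(self.bin_axis)
            if not (np.all(d > 0) or np.all(d < 0)):
                raise ValueError("bin_axis must be strictly monotone")

    # -- basic shape accessors -------------------------------------------

    @property
    def m(self) -> int:
        """Number of subjects."""
        return self.intensities.shape[0]

    @property
    def n_bins(self) -> int:
        """Number of spectral bins (columns)."""
        return self.intensities.shape[1]

    @property
    def m_control(self) -> int:
        return int(np.sum(self.labels == CONTROL))

    @property
    def m_disease(self) -> int:
        return int(np.sum(self.labels == DISEASE))

    def class_matrix(self, label: str) -> np.ndarray:
        """Return the submatrix of subjects carrying ``label``."""
        if label not in LABELS:
            raise ValueError(f"unknown label {label!r}; allowed: {list(LABELS)}")
        return self.intensities[self.labels == label]

    def subject_row(self, subject_id: str) -> np.ndarray:
        """Return the intensity vector of one subject by id."""
        try:
            idx = self.subject_ids.index(subject_id)
        except ValueError:
            raise KeyError(f"unknown subject id {subject_id!r}") from None
        return self.intensities[idx]

    def with_provenance(self, entry: str) -> "SpectralDataset":
        return replace(self, provenance=[*self.provenance, entry])


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_ID_COL = "subject_id"
_LABEL_COL = "label"


def load_spectra(
    path: str | Path,
    *,
    delimiter: str = ",",
    decimal: str = ".",
    label_aliases: dict[str, str] | None = None,
    axis_unit: str = "ppm",
) -> SpectralDataset:
    """Read a delimited spectral matrix.

    The file must carry one row per subject with a ``subject_id`` column,
    a ``label`` column and one column per bin named by its axis position.
    ``label_aliases`` maps study-specific label names (e.g. ``"patient"``)
    onto the fixed vocabulary ``{control, disease, unlabeled}``.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=delimiter, decimal=decimal, dtype=str)
    if _LABEL_COL not in df.columns:
        raise ValueError(f"{path}: missing required {_LABEL_COL!r} column")
    if _ID_COL not in df.columns:
        raise ValueError(f"{path}: missing required {_ID_COL!r} column")
    bin_cols = [c for c in df.columns if c not in (_ID_COL, _LABEL_COL)]
    if not bin_cols:
        raise ValueError(f"{path}: no bin columns found")
    try:
        axis = np.array([float(c) for c in bin_cols])
    except ValueError as exc:
        raise ValueError(f"{path}: bin column names must be numeric axis positions ({exc})")

    labels = df[_LABEL_COL].astype(str)
    if label_aliases:
        labels = labels.map(lambda v: label_aliases.get(v, v))
    bad = sorted(set(labels) - set(LABELS))
    if bad:
        raise ValueError(
            f"{path}: label value(s) {bad} not allowed; "
            f"allowed labels are {list(LABELS)} (use label_aliases to map)"
        )

    values = np.empty((len(df), len(bin_cols)))
    for j, col in enumerate(bin_cols):
        raw = df[col].tolist()
        for r, cell in enumerate(raw):
            try:
                # python's float() is correctly rounding, so repr-written
                # values round-trip bit for bit
                values[r, j] = float(cell.replace(decimal, ".") if decimal != "." else cell)
            except (ValueError, AttributeError):
                raise ValueError(
                    f"{path}: non-numeric intensity {cell!r} for subject "
                    f"{df[_ID_COL].iloc[r]!r}, bin column {col!r}"
                ) from None

    data = SpectralDataset(
        intensities=values,
        subject_ids=df[_ID_COL].tolist(),
        labels=labels.to_numpy(dtype=object),
        bin_axis=axis,
        axis_unit=axis_unit,
        provenance=[f"loaded {data_shape(values)} from {path.name}"],
    )
    return data


def data_shape(values: np.ndarray) -> str:
    return f"{values.shape[0]} subjects x {values.shape[1]} bins"


def write_spectra(data: SpectralDataset, path: str | Path, *, delimiter: str = ",") -> None:
    """Write a dataset in the same delimited layout :func:`load_spectra` reads.

    Floats are written with ``repr`` (shortest round-trip form), so a
    write -> load cycle reproduces intensities and axis bit for bit.
    """
    path = Path(path)
    cols = [repr(float(v)) for v in data.bin_axis]
    with path.open("w") as fh:
        fh.write(delimiter.join([_ID_COL, _LABEL_COL, *cols]) + "\n")
        for sid, lab, row in zip(data.subject_ids, data.labels, data.intensities):
            cells = [sid, str(lab), *(repr(float(v)) for v in row)]
            fh.write(delimiter.join(cells) + "\n")


def write_provenance(data: SpectralDataset, path: str | Path) -> None:
    Path(path).write_text(json.dumps({"provenance": data.provenance}, indent=2))


# ---------------------------------------------------------------------------
# Binning
# ---------------------------------------------------------------------------


def bin_spectrum(
    data: SpectralDataset,
    bin_size: int | None = None,
    *,
    bin_width: float | None = None,
    aggregate: str = "mean",
) -> SpectralDataset:
    """Aggregate consecutive columns into bins.

    Exactly one of ``bin_size`` (number of consecutive raw columns per bin)
    or ``bin_width`` (axis span per bin) must be given.  Each output column
    is the mean of its member columns by default (``aggregate="sum"`` is
    available); the output axis holds bin centers (mean member position).
    A trailing partial bin is kept and recorded in the provenance log.
    """
    if (bin_size is None) == (bin_width is None):
        raise ValueError("give exactly one of bin_size or bin_width")
    if aggregate not in ("mean", "sum"):
        raise ValueError("aggregate must be 'mean' or 'sum'")
    n = data.n_bins
    if bin_size is not None:
        bin_size = int(bin_size)
        if bin_size < 1:
            raise ValueError("bin_size must be a positive integer")
        if bin_size > n:
            raise ValueError(f"bin_size {bin_size} exceeds the {n} available columns")
        starts = np.arange(0, n, bin_size)
        how = f"bin_size={bin_size}"
    else:
        if bin_width <= 0:
            raise ValueError("bin_width must be positive")
        axis = data.bin_axis
        if n >= 2 and axis[1] < axis[0]:
            raise ValueError("bin_width binning requires an increasing axis")
        idx = np.floor((axis - axis[0]) / bin_width).astype(int)
        starts = np.flatnonzero(np.r_[True, np.diff(idx) != 0])
        how = f"bin_width={bin_width}"

    counts = np.diff(np.r_[starts, n]).astype(float)
    sums = np.add.reduceat(data.intensities, starts, axis=1)
    values = sums if aggregate == "sum" else sums / counts
    centers = np.add.reduceat(data.bin_axis, starts) / counts

    partial = ""
    if bin_size is not None and n % bin_size:
        partial = f"; trailing partial bin of {n % bin_size} columns kept"
    return replace(
        data,
        intensities=values,
        bin_axis=centers,
        provenance=[
            *data.provenance,
            f"binned {n} -> {len(starts)} columns ({how}, aggregate={aggregate}{partial})",
        ],
    )


# ---------------------------------------------------------------------------
# Masking
# ---------------------------------------------------------------------------


def mask_bins(
    data: SpectralDataset, regions: list[tuple[float, float]]
) -> SpectralDataset:
    """Remove every column whose axis position falls inside any interval.

    ``regions`` is a list of closed ``(low, high)`` axis intervals (order
    inside each pair is irrelevant); overlapping intervals behave as their
    union.  Used to drop water regions and drug peaks before modeling.
    """
    keep = np.ones(data.n_bins, dtype=bool)
    for lo, hi in regions:
        lo, hi = min(lo, hi), max(lo, hi)
        keep &= ~((data.bin_axis >= lo) & (data.bin_axis <= hi))
    if not keep.any():
        raise ValueError("mask removes every bin; at least one must remain")
    removed = int((~keep).sum())
    if removed == 0:
        return data
    return replace(
        data,
        intensities=data.intensities[:, keep],
        bin_axis=data.bin_axis[keep],
        provenance=[*data.provenance, f"masked {removed} bins in {len(regions)} region(s)"],
    )


# ---------------------------------------------------------------------------
# Noise injection
# ---------------------------------------------------------------------------


def add_noise(
    data: SpectralDataset,
    sigma: float,
    seed: int | np.random.Generator,
) -> SpectralDataset:
    """Add i.i.d. zero-mean Gaussian noise of standard deviation ``sigma``.

    Deterministic given ``seed``; ``sigma=0`` returns the data unchanged.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    rng = np.random.default_rng(seed)
    noisy = data.intensities + rng.normal(0.0, sigma, size=data.intensities.shape)
    return replace(
        data,
        intensities=noisy,
        provenance=[*data.provenance, f"added N(0, {sigma}^2) noise"],
    )
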