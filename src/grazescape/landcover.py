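"""Dual-date composite construction, random-forest classification, and
confusion-matrix accuracy assessment.

Savanna woody and herbaceous vegetation are spectrally similar on any single
date but phenologically distinct: grasses senesce soon after the rains while
most woody plants stay photosynthetically active. Stacking the six
reflective bands (blue, green, red, NIR, SWIR1, SWIR2) of a senescent-season
scene with the same bands of a flushed-season scene yields a 12-band
composite on which the woody-cover gradient classes separate well.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .raster import LandCoverRaster, DEFAULT_CRS, DEFAULT_NODATA
from .scheme import ClassScheme, DEFAULT_SCHEME

__all__ = [
    "BandStack",
    "build_composite",
    "allocate_roles",
    "train_classifier",
    "classify_raster",
    "ConfusionMatrix",
    "confusion_matrix",
    "AccuracySummary",
    "accuracy_summary",
    "round_half_up",
]

#: Landsat ETM+ reflective bands used on each date.
BAND_NAMES = ("b1", "b2", "b3", "b4", "b5", "b7")


@dataclass
class BandStack:
    """Multi-band reflectance stack on one grid, with a per-pixel validity mask."""

    bands: np.ndarray  # (nbands, rows, cols)
    cell_size: float
    origin: Tuple[float, float] = (0.0, 0.0)
    crs: str = DEFAULT_CRS
    crs_unit: str = "m"
    mask: Optional[np.ndarray] = None  # True where valid
    band_names: Tuple[str, ...] = ()

    def __post_init__(self):
        self.bands = np.asarray(self.bands, dtype=float)
        if self.bands.ndim != 3:
            raise ValueError("band stack must be (nbands, rows, cols)")
        if self.mask is None:
            self.mask = np.ones(self.bands.shape[1:], dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.bands.shape[1:]:
            raise ValueError("mask shape must match the band grid")
        if not self.band_names:
            self.band_names = tuple(f"b{i + 1}" for i in range(self.bands.shape[0]))
        if len(self.band_names) != self.bands.shape[0]:
            raise ValueError("band_names length must equal the band count")

    @property
    def n_bands(self) -> int:
        return self.bands.shape[0]

    @property
    def shape(self) -> Tuple[int, int]:
        return self.bands.shape[1:]

    def index_of(self, x: float, y: float) -> Tuple[int, int]:
        x0, y0 = self.origin
        c = self.cell_size
        return (int(np.floor((y0 - y) / c)), int(np.floor((x - x0) / c)))

    def features_at(self, x: float, y: float) -> np.ndarray:
        i, j = self.index_of(x, y)
        rows, cols = self.shape
        if not (0 <= i < rows and 0 <= j < cols):
            raise ValueError(f"point ({x}, {y}) is off-grid")
        if not self.mask[i, j]:
            raise ValueError(f"point ({x}, {y}) falls on a masked pixel")
        return self.bands[:, i, j]


def _same_geometry(a: BandStack, b: BandStack) -> bool:
    return (
        a.shape == b.shape
        and a.cell_size == b.cell_size
        and a.origin == b.origin
        and a.crs == b.crs
    )


def build_composite(senescent: BandStack, flushed: BandStack) -> BandStack:
    """Stack the senescent-date bands over the flushed-date bands.

    Output band order: the six senescent bands, then the six flushed bands;
    the validity mask is the intersection of the two dates' masks.
    """
    if not _same_geometry(senescent, flushed):
        raise ValueError("senescent and flushed stacks must share grid geometry")
    if senescent.band_names != flushed.band_names:
        raise ValueError(
            "band lists differ between dates: "
            f"{senescent.band_names} vs {flushed.band_names}"
        )
    bands = np.concatenate([senescent.bands, flushed.bands], axis=0)
    names = tuple(f"sen_{n}" for n in senescent.band_names) + tuple(
        f"flu_{n}" for n in flushed.band_names
    )
    return BandStack(
        bands=bands,
        cell_size=senescent.cell_size,
        origin=senescent.origin,
        crs=senescent.crs,
        crs_unit=senescent.crs_unit,
        mask=senescent.mask & flushed.mask,
        band_names=names,
    )


def allocate_roles(points: pd.DataFrame) -> pd.DataFrame:
    """Alternate reference points into training/validation roles per class.

    Within each class (input order preserved) even positions become training
    and odd positions validation, producing two equal-sized disjoint sets.
    """
    if "class_code" not in points.columns:
        raise ValueError("points table lacks required column 'class_code'")
    out = points.copy()
    out["role"] = ""
    for _, idx in out.groupby("class_code", sort=False).indices.items():
        roles = np.where(np.arange(len(idx)) % 2 == 0, "training", "validation")
        out.iloc[idx, out.columns.get_loc("role")] = roles
    return out


def _point_features(stack: BandStack, points: pd.DataFrame):
    X = np.empty((len(points), stack.n_bands))
    y = np.empty(len(points), dtype=int)
    for k, row in enumerate(points.itertuples(index=False)):
        X[k] = stack.features_at(float(row.x), float(row.y))
        y[k] = int(row.class_code)
    return X, y


def train_classifier(
    stack: BandStack,
    points: pd.DataFrame,
    n_estimators: int = 500,
    seed: int = 0,
) -> RandomForestClassifier:
    """Fit a random forest on composite features at the training points.

    ``points`` columns: x, y, class_code and optionally role (rows with
    role != 'training' are ignored). At least two classes are required, and
    every training point must fall on a valid pixel.
    """
    df = points
    if "role" in df.columns:
        df = df[df["role"] == "training"]
    if df.empty:
        raise ValueError("no training points supplied")
    X, y = _point_features(stack, df)
    if np.unique(y).size < 2:
        raise ValueError("training data must contain at least 2 classes")
    clf = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
    clf.fit(X, y)
    return clf


def classify_raster(
    stack: BandStack,
    classifier: RandomForestClassifier,
    nodata: int = DEFAULT_NODATA,
) -> LandCoverRaster:
    """Predict a class code for every valid pixel; masked pixels get nodata."""
    if classifier.n_features_in_ != stack.n_bands:
        raise ValueError(
            f"classifier expects {classifier.n_features_in_} bands, "
            f"stack has {stack.n_bands}"
        )
    rows, cols = stack.shape
    out = np.full((rows, cols), nodata, dtype=np.int32)
    valid = stack.mask
    if valid.any():
        X = stack.bands[:, valid].T
        out[valid] = classifier.predict(X)
    return LandCoverRaster(
        data=out,
        cell_size=stack.cell_size,
        origin=stack.origin,
        crs=stack.crs,
        crs_unit=stack.crs_unit,
        nodata=nodata,
        meta={"n_estimators": str(classifier.n_estimators),
              "random_state": str(classifier.random_state)},
    )


@dataclass
class ConfusionMatrix:
    """Square count matrix: rows = classified label, columns = reference label."""

    counts: np.ndarray
    classes: Tuple[int, ...]

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise ValueError("confusion matrix must be square over the class list")
        if (self.counts < 0).any():
            raise ValueError("confusion-matrix counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self, scheme: Optional[ClassScheme] = None) -> pd.DataFrame:
        names = (
            [scheme.by_code(c).abbrev for c in self.classes]
            if scheme is not None
            else list(self.classes)
        )
        return pd.DataFrame(self.counts, index=names, columns=names)


def confusion_matrix(
    classified: LandCoverRaster,
    validation: pd.DataFrame,
    classes: Optional[Sequence[int]] = None,
) -> ConfusionMatrix:
    """Cross-tabulate classified map values against validation points.

    ``validation`` columns: x, y, class_code (the reference label). Points on
    nodata pixels or off-grid raise; an empty validation set is rejected.
    """
    df = validation
    if "role" in df.columns:
        df = df[df["role"] == "validation"]
    if df.empty:
        raise ValueError("validation set is empty")
    pred = []
    ref = []
    for row in df.itertuples(index=False):
        v = classified.value_at(float(row.x), float(row.y))
        if v == classified.nodata:
            raise ValueError(
                f"validation point ({row.x}, {row.y}) falls on a nodata pixel"
            )
        pred.append(v)
        ref.append(int(row.class_code))
    if classes is None:
        classes = sorted(set(pred) | set(ref))
    classes = tuple(int(c) for c in classes)
    pos = {c: k for k, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for p, r in zip(pred, ref):
        counts[pos[p], pos[r]] += 1
    return ConfusionMatrix(counts, classes)


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding as used for printed accuracy percentages."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class AccuracySummary:
    """Overall, per-class user's (row-wise) and producer's (column-wise) accuracy, %.

    Classes with a zero row or column sum have no defined accuracy and are
    reported as NaN, not zero.
    """

    overall: float
    users: Dict[int, float]
    producers: Dict[int, float]

    def rounded(self, ndigits: int = 2) -> "AccuracySummary":
        rnd = lambda v: v if np.isnan(v) else round_half_up(v, ndigits)
        return AccuracySummary(
            overall=rnd(self.overall),
            users={c: rnd(v) for c, v in self.users.items()},
            producers={c: rnd(v) for c, v in self.producers.items()},
        )

    def to_frame(self, scheme: Optional[ClassScheme] = None) -> pd.DataFrame:
        codes = list(self.users)
        names = [scheme.by_code(c).abbrev for c in codes] if scheme else codes
        return pd.DataFrame(
            {
                "class": names,
                "users_accuracy_pct": [self.users[c] for c in codes],
                "producers_accuracy_pct": [self.producers[c] for c in codes],
            }
        )


def accuracy_summary(cm: ConfusionMatrix) -> AccuracySummary:
    """Overall = 100·trace/total; user's(i) = 100·cm[i,i]/row-sum(i);
    producer's(j) = 100·cm[j,j]/column-sum(j)."""
    if cm.total <= 0:
        raise ValueError("confusion matrix has zero total count")
    counts = cm.counts.astype(float)
    overall = 100.0 * np.trace(counts) / counts.sum()
    row = counts.sum(axis=1)
    col = counts.sum(axis=0)
    diag = np.diag(counts)
    users = {
        c: (100.0 * diag[k] / row[k] if row[k] > 0 else float("nan"))
        for k, c in enumerate(cm.classes)
    }
    producers = {
        c: (100.0 * diag[k] / col[k] if col[k] > 0 else float("nan"))
        for k, c in enumerate(cm.classes)
    }
    return AccuracySummary(overall=overall, users=users, producers=producers)


# ---------------------------------------------------------------------------
# Stack I/O: multiband TIFF (via tifffile) or .npy, grid geometry in a JSON
# sidecar named <path>.json with keys cell_size, origin, crs, band_names and
# optional nodata (pixels equal to nodata in any band are masked).

def read_band_stack(path, cell_size=None, origin=(0.0, 0.0), crs=DEFAULT_CRS):
    import json
    from pathlib import Path as _Path

    path = _Path(path)
    sidecar = path.with_name(path.name + ".json")
    meta = {}
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        arr = np.asarray(tifffile.imread(path), dtype=float)
    elif path.suffix.lower() == ".npy":
        arr = np.asarray(np.load(path), dtype=float)
    else:
        raise ValueError(f"unsupported stack format {path.suffix!r}")
    if arr.ndim == 2:
        arr = arr[None]
    elif arr.ndim == 3 and arr.shape[0] not in (1, 6, 12) and arr.shape[-1] in (1, 6, 12):
        arr = np.moveaxis(arr, -1, 0)  # bands-last TIFF
    mask = np.isfinite(arr).all(axis=0)
    nodata = meta.get("nodata")
    if nodata is not None:
        mask &= (arr != nodata).all(axis=0)
    return BandStack(
        bands=arr,
        cell_size=float(meta.get("cell_size", cell_size if cell_size else 1.0)),
        origin=tuple(meta.get("origin", origin)),
        crs=meta.get("crs", crs),
        mask=mask,
        band_names=tuple(meta.get("band_names", ())),
    )


def write_band_stack(stack: BandStack, path) -> None:
    import json
    from pathlib import Path as _Path

    path = _Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, stack.bands.astype(np.float32))
    elif path.suffix.lower() == ".npy":
        np.save(path, stack.bands)
    else:
        raise ValueError(f"unsupported stack format {path.suffix!r}")
    sidecar = path.with_name(path.name + ".json")
    sidecar.write_text(
        json.dumps(
            {
                "cell_size": stack.cell_size,
                "origin": list(stack.origin),
                "crs": stack.crs,
                "band_names": list(stack.band_names),
            },
            indent=2,
        )
    )
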