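"""Feature fusion and leakage-safe standardization.

The hybrid representation of an image is the concatenation
``x_hybrid = [x_TDA, x_BoVW]`` — 800 topological values followed by the
150-bin visual-word histogram, 950 features in all.  Construction yields
exactly 950 by design; the length is asserted rather than truncated so a
wrong-sized block surfaces as an error instead of silent data loss.

Standardization is per-feature z-scoring fitted on training rows only.
Features that are constant on the training fold (the red-channel Betti
bins of red-empty images, typically) get a standard-deviation floor and
standardize to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .betti import TDA_DIM, TdaFeatureBlock
from .betti import feature_names as _tda_names
from .bovw import BovwHistogram
from .bovw import feature_names as _bovw_names

BOVW_DIM = 150
FUSED_DIM = TDA_DIM + BOVW_DIM  # 950

#: contiguous feature blocks of the fused vector, by half-open index range
BLOCKS = {
    "tda": (0, TDA_DIM),
    "bovw": (TDA_DIM, FUSED_DIM),
}

SD_FLOOR = 1e-8


@dataclass(frozen=True)
class FeatureVector:
    """One fused 950-dim sample with named block boundaries."""

    values: np.ndarray
    image_id: str = ""
    label: int | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (FUSED_DIM,):
            raise ValueError(
                f"fused vector must have length {FUSED_DIM}, got {v.shape}"
            )
        object.__setattr__(self, "values", v)

    @property
    def tda(self) -> np.ndarray:
        return self.values[slice(*BLOCKS["tda"])]

    @property
    def bovw(self) -> np.ndarray:
        return self.values[slice(*BLOCKS["bovw"])]


def fuse(tda: TdaFeatureBlock, bovw: BovwHistogram, image_id: str = "",
         label: int | None = None) -> FeatureVector:
    """Concatenate the TDA block and BoVW histogram (TDA first)."""
    if tda.values.shape != (TDA_DIM,):
        raise ValueError(f"tda block has length {tda.values.shape}, need {TDA_DIM}")
    if bovw.values.shape != (BOVW_DIM,):
        raise ValueError(f"bovw block has length {bovw.values.shape}, need {BOVW_DIM}")
    return FeatureVector(values=np.concatenate([tda.values, bovw.values]),
                         image_id=image_id, label=label)


def feature_names() -> list[str]:
    return _tda_names() + _bovw_names(BOVW_DIM)


def to_matrix(vectors) -> tuple[np.ndarray, np.ndarray]:
    """Stack FeatureVectors into (X, y); missing labels become -1."""
    X = np.vstack([v.values for v in vectors])
    y = np.array([-1 if v.label is None else v.label for v in vectors])
    return X, y


@dataclass
class Standardizer:
    """Per-feature z-scoring with training-fold bookkeeping.

    ``fit`` learns mean and sd from training rows and refuses rows marked
    as belonging to the validation fold unless explicitly overridden —
    the guard that keeps held-out information out of the scaling.
    ``transform`` applies the training statistics to any rows.
    """

    val_fold: int | None = None
    mean_: np.ndarray | None = field(default=None, repr=False)
    scale_: np.ndarray | None = field(default=None, repr=False)

    def fit(self, X: np.ndarray, row_folds=None,
            allow_validation_rows: bool = False) -> "Standardizer":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("standardizer needs >= 2 training rows")
        if (row_folds is not None and self.val_fold is not None
                and not allow_validation_rows):
            row_folds = np.asarray(row_folds)
            leaked = np.flatnonzero(row_folds == self.val_fold)
            if leaked.size:
                raise ValueError(
                    f"refusing to fit on rows {leaked.tolist()} of held-out "
                    f"fold {self.val_fold} (pass allow_validation_rows=True "
                    f"to override)"
                )
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        self.scale_ = np.where(sd > SD_FLOOR, sd, np.inf)  # constants -> 0
        return self

    def _check_fitted(self) -> None:
        if self.mean_ is None:
            raise ValueError("standardizer has not been fitted")

    def transform(self, X: np.ndarray) -> np.ndarray:
        self._check_fitted()
        return (np.asarray(X, dtype=float) - self.mean_) / self.scale_

    def inverse_transform(self, Z: np.ndarray) -> np.ndarray:
        self._check_fitted()
        scale = np.where(np.isinf(self.scale_), 0.0, self.scale_)
        return np.asarray(Z, dtype=float) * scale + self.mean_
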