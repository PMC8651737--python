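"""Threshold calibration and symmetric/asymmetric classification.

The decision threshold is calibrated as mean + 2σ of the asymmetry scores of
a reference population of cells asserted to be normal (ellipsoidal cells
from low-shear control frames, or a labelled subset). Cells scoring strictly
above the threshold are classified asymmetric. For an approximately Gaussian
reference score population this targets a one-sided false-positive rate of
about 2.3% on normal cells.

`AsymmetryThresholdClassifier` exposes this as a scikit-learn estimator
(``fit`` on reference scores, ``predict`` labels) so it composes with
sklearn tooling; `calibrate_threshold` / `classify_cell` are the functional
surface used by the pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator

from .morphometry import AsymmetryResult

__all__ = [
    "CalibrationModel",
    "AsymmetryThresholdClassifier",
    "REFERENCE_THRESHOLD",
    "calibrate_threshold",
    "save_calibration",
    "load_calibration",
    "classify_cell",
    "FrameSummary",
    "summarize_frame",
    "detect_onset",
]

#: Threshold preset (percent) from a prior published calibration of this
#: scoring method on healthy ellipsoidal cells in 60 Pa shear flow. It is
#: specific to that optical setup and cell population: prefer calibrating on
#: your own reference cells and use this only as a documented preset.
REFERENCE_THRESHOLD = 2.77

LABEL_SYMMETRIC = "symmetric"
LABEL_ASYMMETRIC = "asymmetric"


@dataclass
class CalibrationModel:
    """Mean + n·σ threshold model for asymmetry scores (all in percent)."""

    mean_score: float
    sd_score: float  # sample standard deviation (n − 1)
    threshold: float
    n_reference: int
    n_sigma: float = 2.0
    source: str = ""

    def __post_init__(self) -> None:
        if self.sd_score < 0:
            raise ValueError("sd_score must be non-negative")
        if self.threshold < self.mean_score:
            raise ValueError("threshold must be >= mean_score")


def calibrate_threshold(
    reference_scores, n_sigma: float = 2.0, source: str = ""
) -> CalibrationModel:
    """Calibrate the decision threshold as mean + ``n_sigma``·sd.

    ``reference_scores`` are asymmetry scores (percent) of cells asserted
    normal; at least two finite scores are required. The standard deviation
    uses the n − 1 (sample) denominator.
    """
    scores = np.asarray(reference_scores, dtype=np.float64).ravel()
    if scores.size < 2:
        raise ValueError("calibration needs at least 2 reference scores")
    if not np.all(np.isfinite(scores)):
        raise ValueError("reference scores must be finite")
    mean = float(np.mean(scores))
    sd = float(np.std(scores, ddof=1))
    return CalibrationModel(
        mean_score=mean,
        sd_score=sd,
        threshold=mean + n_sigma * sd,
        n_reference=int(scores.size),
        n_sigma=n_sigma,
        source=source,
    )


class AsymmetryThresholdClassifier(BaseEstimator):
    """Mean + n·σ threshold classifier over asymmetry scores.

    Parameters
    ----------
    n_sigma : float, default 2.0
        Number of reference-population standard deviations above the mean at
        which the threshold is placed.
    threshold : float or None
        Fixed decision threshold in percent. When set, ``fit`` keeps it
        instead of calibrating (use ``REFERENCE_THRESHOLD`` for the published
        preset).

    Attributes
    ----------
    mean_ : float
        Reference-population mean score (nan when a fixed threshold is used).
    sd_ : float
        Reference-population sample standard deviation.
    threshold_ : float
        Decision threshold in percent; scores strictly above it are
        classified asymmetric.
    """

    def __init__(self, n_sigma: float = 2.0, threshold: float | None = None):
        self.n_sigma = n_sigma
        self.threshold = threshold

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=np.float64).reshape(-1)
        self.classes_ = np.array([LABEL_ASYMMETRIC, LABEL_SYMMETRIC])
        if self.threshold is not None:
            self.mean_ = math.nan
            self.sd_ = math.nan
            self.threshold_ = float(self.threshold)
            self.n_reference_ = int(X.size)
            return self
        model = calibrate_threshold(X, n_sigma=self.n_sigma)
        self.mean_ = model.mean_score
        self.sd_ = model.sd_score
        self.threshold_ = model.threshold
        self.n_reference_ = model.n_reference
        return self

    def decision_function(self, X):
        self._check_fitted()
        return np.asarray(X, dtype=np.float64).reshape(-1) - self.threshold_

    def predict(self, X):
        """Label each score: asymmetric iff score > threshold (strict)."""
        self._check_fitted()
        scores = np.asarray(X, dtype=np.float64).reshape(-1)
        return np.where(scores > self.threshold_, LABEL_ASYMMETRIC, LABEL_SYMMETRIC)

    def to_model(self, source: str = "") -> CalibrationModel:
        """Export the fitted threshold as a serializable CalibrationModel."""
        self._check_fitted()
        fixed = math.isnan(self.mean_)
        return CalibrationModel(
            mean_score=self.threshold_ if fixed else self.mean_,
            sd_score=0.0 if fixed else self.sd_,
            threshold=self.threshold_,
            n_reference=getattr(self, "n_reference_", 0),
            n_sigma=self.n_sigma,
            source=source or ("fixed threshold" if fixed else ""),
        )

    def _check_fitted(self) -> None:
        if not hasattr(self, "threshold_"):
            raise AttributeError("classifier is not fitted; call fit() first")


def classify_cell(result: AsymmetryResult, model: CalibrationModel) -> str:
    """Classify one cell: asymmetric iff score > threshold (strict).

    A boundary score equal to the threshold is symmetric. Invalid results
    must be filtered by the caller (they are tallied as skipped upstream).
    """
    if not result.valid or not math.isfinite(result.score):
        raise ValueError("cannot classify an invalid asymmetry result")
    return LABEL_ASYMMETRIC if result.score > model.threshold else LABEL_SYMMETRIC


def _calibration_dict(model: CalibrationModel) -> dict:
    return {
        "mean_score": model.mean_score,
        "sd_score": model.sd_score,
        "threshold": model.threshold,
        "n_reference": model.n_reference,
        "n_sigma": model.n_sigma,
        "source": model.source,
    }


def save_calibration(model: CalibrationModel, path) -> None:
    """Write a calibration model as human-readable key = value text."""
    lines = [f"{key} = {value}" for key, value in _calibration_dict(model).items()]
    Path(path).write_text("\n".join(lines) + "\n")


def load_calibration(path) -> CalibrationModel:
    values: dict = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#") or "=" not in line:
            continue
        key, _, raw = line.partition("=")
        values[key.strip()] = raw.strip()
    return CalibrationModel(
        mean_score=float(values["mean_score"]),
        sd_score=float(values["sd_score"]),
        threshold=float(values["threshold"]),
        n_reference=int(values["n_reference"]),
        n_sigma=float(values.get("n_sigma", 2.0)),
        source=values.get("source", ""),
    )


@dataclass
class FrameSummary:
    """Per-frame counts, asymmetric fraction, and ensemble EI statistics."""

    frame_index: int
    time_s: float
    n_cells: int
    n_fragments: int
    n_asymmetric: int
    fraction_asymmetric: float  # percent of n_cells
    ei_mean: float
    ei_median: float
    n_skipped: int = 0
    flags: tuple[str, ...] = field(default_factory=tuple)


def summarize_frame(
    classified: list[tuple[AsymmetryResult, str, float]],
    n_fragments: int,
    frame_index: int,
    fps: float = 10.0,
    n_skipped: int = 0,
) -> FrameSummary:
    """Aggregate one frame's classified cells into a summary record.

    ``classified`` holds (asymmetry result, label, EI) triples for the
    frame's valid intact cells; the asymmetric fraction is reported as a
    percentage of the frame's cell count (0 with a flag for empty frames).
    """
    n_cells = len(classified)
    n_asym = sum(1 for _, label, _ in classified if label == LABEL_ASYMMETRIC)
    flags: tuple[str, ...] = ()
    if n_cells == 0:
        fraction = 0.0
        flags = ("no_cells",)
        ei_mean = ei_median = math.nan
    else:
        fraction = 100.0 * n_asym / n_cells
        eis = np.array([ei for _, _, ei in classified])
        ei_mean = float(np.mean(eis))
        ei_median = float(np.median(eis))
    return FrameSummary(
        frame_index=frame_index,
        time_s=frame_index / fps,
        n_cells=n_cells,
        n_fragments=n_fragments,
        n_asymmetric=n_asym,
        fraction_asymmetric=fraction,
        ei_mean=ei_mean,
        ei_median=ei_median,
        n_skipped=n_skipped,
        flags=flags,
    )


def detect_onset(values, n_trials=None) -> int:
    """Change-point estimate: index of the first frame of the elevated regime.

    Fits a single step change by maximum likelihood over all split points.
    With ``n_trials`` given, ``values`` are per-frame asymmetric counts and
    the likelihood is binomial (per-frame cell counts as trials; scalar or
    array) — the appropriate model for counts of independently classified
    cells. Otherwise ``values`` are fractions and the split minimizes the
    two-segment squared error (equivalent Gaussian fit). Splits are searched
    over [2, n − 2]; returns 0 for an empty or constant series.
    """
    v = np.asarray(values, dtype=np.float64)
    n = v.size
    if n < 4 or np.ptp(v) == 0:
        return 0
    if n_trials is not None:
        m = np.broadcast_to(np.asarray(n_trials, dtype=np.float64), v.shape)
        cs = np.concatenate([[0.0], np.cumsum(v)])
        ms = np.concatenate([[0.0], np.cumsum(m)])

        def loglik(successes: float, trials: float) -> float:
            if successes <= 0 or successes >= trials:
                return 0.0
            p = successes / trials
            return successes * math.log(p) + (trials - successes) * math.log(1 - p)

        best_k, best_ll = 2, -math.inf
        for k in range(2, n - 1):
            ll = loglik(cs[k], ms[k]) + loglik(cs[n] - cs[k], ms[n] - ms[k])
            if ll > best_ll:
                best_ll, best_k = ll, k
        return best_k
    c1 = np.concatenate([[0.0], np.cumsum(v)])
    c2 = np.concatenate([[0.0], np.cumsum(v * v)])
    best_k, best_sse = 2, math.inf
    for k in range(2, n - 1):
        s1, q1 = c1[k], c2[k]
        s2, q2 = c1[n] - c1[k], c2[n] - c2[k]
        sse = (q1 - s1 * s1 / k) + (q2 - s2 * s2 / (n - k))
        if sse < best_sse:
            best_sse, best_k = sse, k
    return best_k
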