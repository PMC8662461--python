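"""Window-level movement descriptors and GMM behavioural classes.

The trajectory is cut into contiguous 1-s windows; each window yields mean
speed, sinuosity (path length over net displacement), path length, and the
mean lateral / longitudinal speed-component magnitudes. A Gaussian mixture
is fitted over these descriptors for each candidate class count k = 1..15
and the count with the lowest AIC is retained; mixture components are then
given semantic labels (slow / fast x plain / tortuous) from their means,
since component order is arbitrary.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.mixture import GaussianMixture

from .trajectory import Trajectory

FEATURE_COLUMNS = ["mean_speed", "sinuosity", "path_length",
                   "lateral_speed", "longitudinal_speed"]

#: floor for the net displacement in the sinuosity ratio [m]; one range bin
#: of the indoor radar, below which start/end separation is not measurable
SINUOSITY_NET_FLOOR = 0.05


def segment_windows(traj: Trajectory, window_s: float = 1.0) -> list[Trajectory]:
    """Cut a constant-rate trajectory into contiguous non-overlapping windows.

    A trailing partial window shorter than half ``window_s`` is dropped; a
    longer partial window is kept.
    """
    if window_s <= 0:
        raise ValueError("window length must be positive")
    n = len(traj)
    rate = traj.rate
    per = int(round(window_s * rate))
    if n < per:
        raise ValueError("trajectory shorter than one window")
    starts = list(range(0, n - per + 1, per))
    windows = [slice(s, s + per) for s in starts]
    tail = n - (starts[-1] + per)
    if tail / rate >= window_s / 2:
        windows.append(slice(starts[-1] + per, n))
    out = []
    for sl in windows:
        out.append(Trajectory(traj.times[sl], traj.x[sl], traj.y[sl],
                              traj.phase[sl], source=traj.source))
    return out


def window_features(window: Trajectory) -> dict:
    """Movement descriptors for one window (>= 2 samples).

    sinuosity = path_length / max(net displacement, floor), clipped to
    >= 1; a stationary window has sinuosity 1 by convention.
    """
    if len(window) < 2:
        raise ValueError("window needs at least 2 samples")
    dt = np.diff(window.times)
    if np.any(dt <= 0):
        raise ValueError("timestamps must be strictly increasing")
    dx = np.diff(window.x)
    dy = np.diff(window.y)
    steps = np.hypot(dx, dy)
    path = float(steps.sum())
    net = float(np.hypot(window.x[-1] - window.x[0],
                         window.y[-1] - window.y[0]))
    duration = float(window.times[-1] - window.times[0])
    if path <= SINUOSITY_NET_FLOOR:
        sinuosity = 1.0
    else:
        sinuosity = max(1.0, path / max(net, SINUOSITY_NET_FLOOR))
    return {
        "window_start": float(window.times[0]),
        "phase": int(window.phase[0]),
        "mean_speed": path / duration,
        "sinuosity": sinuosity,
        "path_length": path,
        "lateral_speed": float(np.mean(np.abs(dx) / dt)),
        "longitudinal_speed": float(np.mean(np.abs(dy) / dt)),
    }


def feature_table(traj: Trajectory, window_s: float = 1.0) -> pd.DataFrame:
    """Per-window feature table for one trajectory."""
    rows = [window_features(w) for w in segment_windows(traj, window_s)]
    return pd.DataFrame(rows)


def _quadrant_label(speed_fast: bool, tortuous: bool) -> str:
    if speed_fast:
        return "fast_tortuous" if tortuous else "fast"
    return "slow_tortuous" if tortuous else "slow"


class MovementClassifier(BaseEstimator):
    """Gaussian-mixture behavioural classifier with AIC model selection.

    Fits full-covariance mixtures for each candidate class count in
    ``k_range`` (with ``n_restarts`` random initialisations each) on the
    standardized window features, and keeps the count minimising the AIC
    (2 p - 2 log L). Components are named slow/fast x plain/tortuous from
    their mean speed and sinuosity (see ``_name_components``).

    Attributes (after fit)
    ----------------------
    n_classes_ : selected class count
    aic_curve_ : AIC per candidate k (same order as ``k_range``)
    labels_ : component index per training window
    class_names_ : semantic label per component
    gmm_ : the selected fitted ``sklearn.mixture.GaussianMixture``
    """

    def __init__(self, k_range=range(1, 16), n_restarts: int = 10,
                 standardize: bool = True, random_state: int | None = 0,
                 reg_covar: float = 1e-2):
        self.k_range = k_range
        self.n_restarts = n_restarts
        self.standardize = standardize
        self.random_state = random_state
        # ridge on the (standardized) component covariances; the default
        # keeps many-restart AIC selection from rewarding near-singular
        # high-k solutions
        self.reg_covar = reg_covar

    def _matrix(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X[FEATURE_COLUMNS].to_numpy(float)
        X = np.asarray(X, float)
        if X.ndim != 2:
            raise ValueError("feature matrix must be 2D")
        return X

    def fit(self, X, y=None):
        X = self._matrix(X)
        ks = list(self.k_range)
        if len(X) < 2 * max(ks):
            raise ValueError("need at least 2 * k_max windows")
        if np.allclose(X.std(axis=0), 0):
            raise ValueError("degenerate (constant) feature matrix")
        self.feature_mean_ = X.mean(axis=0)
        sd = X.std(axis=0)
        self.feature_std_ = np.where(sd > 0, sd, 1.0)
        Z = (X - self.feature_mean_) / self.feature_std_ if self.standardize \
            else X
        aics, models = [], []
        for k in ks:
            gmm = GaussianMixture(n_components=k, covariance_type="full",
                                  n_init=self.n_restarts,
                                  reg_covar=self.reg_covar,
                                  random_state=self.random_state)
            gmm.fit(Z)
            aics.append(gmm.aic(Z))
            models.append(gmm)
        self.aic_curve_ = np.asarray(aics)
        best = int(np.argmin(self.aic_curve_))
        self.n_classes_ = ks[best]
        self.gmm_ = models[best]
        self.labels_ = self.gmm_.predict(Z)
        self._name_components(X)
        return self

    def _name_components(self, X: np.ndarray) -> None:
        """Semantic labels from the component means.

        Speed is split midway between the slowest and fastest component
        means (0.3 m/s — a slow walk — when a single component leaves no
        spread); sinuosity is split at the absolute value 1.5, since the
        ratio is scale-free with 1 meaning perfectly straight. Medians of
        the pooled windows are deliberately not used: with one dominant
        class the median falls inside a cluster and misnames it.
        """
        i_speed = FEATURE_COLUMNS.index("mean_speed")
        i_sin = FEATURE_COLUMNS.index("sinuosity")
        means = self.gmm_.means_ * (self.feature_std_ if self.standardize
                                    else 1.0)
        if self.standardize:
            means = means + self.feature_mean_
        speeds = means[:, i_speed]
        if speeds.max() - speeds.min() > 1e-9:
            speed_cut = 0.5 * (speeds.min() + speeds.max())
        else:
            speed_cut = 0.3
        self.class_names_ = [
            _quadrant_label(mu[i_speed] > speed_cut, mu[i_sin] > 1.5)
            for mu in means
        ]

    def predict(self, X) -> np.ndarray:
        X = self._matrix(X)
        Z = (X - self.feature_mean_) / self.feature_std_ if self.standardize \
            else X
        return self.gmm_.predict(Z)

    def predict_names(self, X) -> np.ndarray:
        return np.asarray(self.class_names_)[self.predict(X)]


def fit_movement_classes(features, k_range=range(1, 16), n_restarts: int = 10,
                         seed: int | None = 0) -> MovementClassifier:
    """Functional wrapper over :class:`MovementClassifier`."""
    return MovementClassifier(k_range=k_range, n_restarts=n_restarts,
                              random_state=seed).fit(features)


def quadrant_occupancy(model: MovementClassifier, features) -> dict:
    """Fraction of windows in each semantic quadrant label.

    Mixture components sharing a quadrant (e.g. two "fast" components) are
    merged, so the result is comparable across fits with different selected
    component counts.
    """
    names = np.asarray(model.class_names_)[model.predict(features)]
    out = {}
    for label in ("slow", "fast", "fast_tortuous", "slow_tortuous"):
        out[label] = float((names == label).mean())
    return out


def class_time_rates(model: MovementClassifier, features: pd.DataFrame,
                     phases=(2, 3)) -> pd.DataFrame:
    """Per-phase occupancy proportion of each mixture component.

    Rows: phase; columns: component index; each row sums to 1.
    """
    labels = model.predict(features)
    out = {}
    for p in phases:
        m = features["phase"].to_numpy() == p
        if not m.any():
            raise ValueError(f"no windows in phase {p}")
        counts = np.bincount(labels[m], minlength=model.n_classes_)
        out[p] = counts / counts.sum()
    df = pd.DataFrame(out).T
    df.index.name = "phase"
    return df


def fast_movement_proportion(model: MovementClassifier,
                             features: pd.DataFrame,
                             phase: int | None = None) -> float:
    """Time in the fast plain class out of the plain (non-tortuous) classes.

    The tortuous components are ignored, mirroring the restriction of the
    class analysis to the two dominant modes.
    """
    names = np.asarray(model.class_names_)
    labels = model.predict(features)
    if phase is not None:
        m = features["phase"].to_numpy() == phase
        labels = labels[m]
    window_names = names[labels]
    n_fast = int((window_names == "fast").sum())
    n_slow = int((window_names == "slow").sum())
    if n_fast + n_slow == 0:
        raise ValueError("no windows in the slow or fast classes")
    return n_fast / (n_fast + n_slow)
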