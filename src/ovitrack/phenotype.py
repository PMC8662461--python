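"""Per-sheep behavioural phenotypes: eight features, PCA, agreement stats.

The phenotype of each animal is the vector of four behavioural estimators
(fast-movement proportion, wavelet transition counts on X and Y, heatmap
score) in each of the two analysis phases — eight values. A PCA of the
cohort's feature correlation matrix summarizes them; components with
eigenvalue > 1 are retained (Kaiser-Guttman). Simple regressions of the
component scores on the docility and sociability covariates, and Pearson
correlations between estimators derived from different sensors, round out
the statistical surface; mixed-model fitting is deliberately left to
downstream tools, which consume the tidy tables written here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .movement import (MovementClassifier, fast_movement_proportion,
                       feature_table)
from .occupancy import build_grid, dwell_times, heatmap_score
from .wavelets import transition_features

PHENOTYPE_FEATURES = [
    "fast_proportion_p2", "fast_proportion_p3",
    "wavelet_x_p2", "wavelet_x_p3",
    "wavelet_y_p2", "wavelet_y_p3",
    "heatmap_p2", "heatmap_p3",
]


@dataclass
class PhenotypeRecord:
    """One sheep's covariates, eight features, and retained PC scores."""

    sheep_id: str
    covariates: dict
    features: dict
    pc_scores: np.ndarray | None = None

    def __post_init__(self) -> None:
        missing = [f for f in PHENOTYPE_FEATURES if f not in self.features]
        if missing:
            raise ValueError(f"missing features: {missing}")


@dataclass
class PcaSummary:
    """Eigenstructure of the cohort feature correlation matrix."""

    eigenvalues: np.ndarray
    variance_fractions: np.ndarray
    loadings: np.ndarray  # (feature, component)
    n_retained: int
    feature_names: list[str]

    def to_dict(self) -> dict:
        return {
            "eigenvalues": self.eigenvalues.tolist(),
            "variance_fractions": self.variance_fractions.tolist(),
            "loadings": self.loadings.tolist(),
            "n_retained": int(self.n_retained),
            "feature_names": list(self.feature_names),
        }


def kaiser_guttman(eigenvalues) -> int:
    """Number of components with eigenvalue strictly greater than 1.

    For correlation-matrix PCA an eigenvalue of 1 is the share of a single
    standardized variable, so only components explaining more than one
    variable's worth are kept; an eigenvalue of exactly 1.0 is not retained.
    """
    ev = np.asarray(eigenvalues, float)
    if ev.size == 0:
        raise ValueError("empty eigenvalue list")
    if np.any(np.diff(ev) > 1e-9):
        raise ValueError("eigenvalues must be sorted in descending order")
    return int((ev > 1.0).sum())


class PhenotypePCA(BaseEstimator, TransformerMixin):
    """PCA of the feature correlation matrix with Kaiser-Guttman retention.

    Features are z-scored across the cohort (they have incommensurate
    units), so the decomposition acts on the correlation matrix and the
    eigenvalues sum to the number of features. Loadings are sign-fixed so
    each component's largest-magnitude loading is positive.

    Attributes (after fit): ``eigenvalues_`` (descending),
    ``variance_fractions_``, ``loadings_`` (feature x component),
    ``n_retained_``, ``mean_``, ``std_``.
    """

    def __init__(self, min_cohort: int = 3):
        self.min_cohort = min_cohort

    def _matrix(self, X):
        if isinstance(X, pd.DataFrame):
            cols = [c for c in PHENOTYPE_FEATURES if c in X.columns] or \
                list(X.columns)
            self.feature_names_ = list(cols)
            return X[cols].to_numpy(float)
        X = np.asarray(X, float)
        self.feature_names_ = [f"f{i}" for i in range(X.shape[1])]
        return X

    def fit(self, X, y=None):
        M = self._matrix(X)
        if M.shape[0] < self.min_cohort:
            raise ValueError(f"need a cohort of at least {self.min_cohort}")
        if np.any(~np.isfinite(M)):
            raise ValueError("missing entries in the feature matrix")
        sd = M.std(axis=0, ddof=1)
        keep = sd > 0
        if not keep.all():
            dropped = [n for n, k in zip(self.feature_names_, keep) if not k]
            warnings.warn(f"dropping zero-variance features: {dropped}")
            M = M[:, keep]
            self.feature_names_ = [n for n, k in
                                   zip(self.feature_names_, keep) if k]
            sd = sd[keep]
        self.mean_ = M.mean(axis=0)
        self.std_ = sd
        Z = (M - self.mean_) / self.std_
        corr = (Z.T @ Z) / (M.shape[0] - 1)
        vals, vecs = np.linalg.eigh(corr)
        order = np.argsort(vals)[::-1]
        vals = np.clip(vals[order], 0.0, None)  # rank deficiency -> zeros
        vecs = vecs[:, order]
        # sign fix: largest-|loading| entry positive per component
        for c in range(vecs.shape[1]):
            i = int(np.argmax(np.abs(vecs[:, c])))
            if vecs[i, c] < 0:
                vecs[:, c] = -vecs[:, c]
        self.eigenvalues_ = vals
        self.variance_fractions_ = vals / vals.sum()
        self.loadings_ = vecs
        self.n_retained_ = kaiser_guttman(vals)
        return self

    def transform(self, X) -> np.ndarray:
        """Scores on the retained components, cohort-standardized inputs."""
        if isinstance(X, pd.DataFrame):
            M = X[self.feature_names_].to_numpy(float)
        else:
            M = np.asarray(X, float)
        Z = (M - self.mean_) / self.std_
        k = max(self.n_retained_, 1)
        return Z @ self.loadings_[:, :k]

    def summary(self) -> PcaSummary:
        return PcaSummary(self.eigenvalues_, self.variance_fractions_,
                          self.loadings_, self.n_retained_,
                          self.feature_names_)


def pca(records) -> PcaSummary:
    """Correlation-matrix PCA of an assembled phenotype table."""
    df = records if isinstance(records, pd.DataFrame) else \
        phenotype_frame(records)
    return PhenotypePCA().fit(df).summary()


def pearson_agreement(series_a, series_b) -> tuple[float, float]:
    """Product-moment correlation and two-sided p between two estimator
    series (e.g. radar-derived vs infrared-derived proximity scores)."""
    a = np.asarray(series_a, float)
    b = np.asarray(series_b, float)
    if len(a) != len(b) or len(a) < 3:
        raise ValueError("need equal-length series of at least 3")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance in an input series")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)


def covariate_association(pc_scores, covariates) -> pd.DataFrame:
    """OLS simple regression of each PC score on each covariate.

    Returns a tidy table with columns component, covariate, slope, se, p.
    """
    scores = np.atleast_2d(np.asarray(pc_scores, float))
    cov = covariates if isinstance(covariates, pd.DataFrame) else \
        pd.DataFrame(covariates)
    if len(cov) < 10:
        raise ValueError("need at least 10 animals for the regressions")
    rows = []
    for k in range(scores.shape[1]):
        for name in cov.columns:
            x = cov[name].to_numpy(float)
            if x.std() == 0:
                raise ValueError(f"constant covariate: {name}")
            res = stats.linregress(x, scores[:, k])
            rows.append({"component": f"PC{k + 1}", "covariate": name,
                         "slope": res.slope, "se": res.stderr,
                         "p": res.pvalue})
    return pd.DataFrame(rows)


def phenotype_frame(records: list[PhenotypeRecord]) -> pd.DataFrame:
    """Tidy table: one row per sheep with covariates and the 8 features."""
    rows = []
    for r in records:
        row = {"sheep_id": r.sheep_id}
        row.update(r.covariates)
        row.update({f: r.features[f] for f in PHENOTYPE_FEATURES})
        rows.append(row)
    return pd.DataFrame(rows)


def session_features(session, classifier: MovementClassifier,
                     features_df: pd.DataFrame, phases=(2, 3),
                     heatmap_threshold: float = 0.2) -> PhenotypeRecord:
    """Assemble the eight-feature record for one session.

    ``features_df`` is the per-window feature table of this sheep (already
    standardized consistently with how ``classifier`` was fitted).
    """
    traj = session.ground_truth
    wav = transition_features(traj, phases=phases)
    grid = build_grid(session.arena)
    dwell = dwell_times(traj, grid)
    feats = {}
    for p in phases:
        feats[f"fast_proportion_p{p}"] = fast_movement_proportion(
            classifier, features_df, phase=p)
        feats[f"wavelet_x_p{p}"] = wav[("X", p)]
        feats[f"wavelet_y_p{p}"] = wav[("Y", p)]
        feats[f"heatmap_p{p}"] = heatmap_score(dwell, phase=p,
                                               threshold=heatmap_threshold)
    return PhenotypeRecord(session.sheep_id, session.covariates, feats)


def assemble_features(sessions, k_range=range(1, 7), n_restarts: int = 3,
                      seed: int | None = 0, phases=(2, 3),
                      window_s: float = 1.0) -> list[PhenotypeRecord]:
    """Cohort pipeline: windows -> pooled GMM -> the 8 features per sheep.

    Window features are pooled across the cohort and classified by a single
    mixture (standardized over the pool) so class labels are comparable
    across animals. Requires a cohort of >= 3 with every estimator
    computable for every sheep.
    """
    if len(sessions) < 3:
        raise ValueError("need a cohort of at least 3 sheep")
    tables = []
    for s in sessions:
        ft = feature_table(s.ground_truth, window_s)
        ft = ft[ft["phase"].isin(phases)].reset_index(drop=True)
        ft["sheep_id"] = s.sheep_id
        tables.append(ft)
    pooled = pd.concat(tables, ignore_index=True)
    clf = MovementClassifier(k_range=k_range, n_restarts=n_restarts,
                             standardize=True, random_state=seed)
    clf.fit(pooled)
    records = []
    for s, tab in zip(sessions, tables):
        records.append(session_features(s, clf, tab, phases=phases))
    return records


def fit_phenotypes(records: list[PhenotypeRecord]) -> tuple[pd.DataFrame,
                                                            PcaSummary]:
    """PCA the assembled cohort and attach retained PC scores.

    Returns the tidy phenotype table (with ``PC1..PCk`` columns appended)
    and the PCA summary.
    """
    df = phenotype_frame(records)
    model = PhenotypePCA().fit(df)
    scores = model.transform(df)
    for k in range(scores.shape[1]):
        df[f"PC{k + 1}"] = scores[:, k]
    for r, row in zip(records, scores):
        r.pc_scores = row
    return df, model.summary()
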