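"""NIPALS partial least squares (PLS2) and the community-structure analyses.

A from-scratch NIPALS implementation of two-block PLS regression with
multivariate response, reporting per-component explained variance of
both blocks and biplot coordinates, plus the two analyses built on it:

* :func:`pls_enrichment_analysis` — treatment/time indicators as
  predictors of empirical-logit-transformed proportional PLFA
  enrichment profiles;
* :func:`compare_to_isolates` — mean relative PLFA profiles of
  bacterial genera (predictors) against the incubation's enriched
  treatment profiles (responses), with per-genus axis correlations.

Sign convention: each X-weight vector's largest-magnitude element is
made positive, so output is deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .plfa import empirical_logit, filter_low_enrichment

logger = logging.getLogger(__name__)

__all__ = [
    "PLSModel",
    "PLSConvergenceError",
    "nipals_pls2",
    "PLSEnrichmentResult",
    "pls_enrichment_analysis",
    "IsolateDB",
    "compare_to_isolates",
]


class PLSConvergenceError(RuntimeError):
    """NIPALS failed to converge for some component."""


@dataclass
class PLSModel:
    """A fitted PLS2 model.

    Matrices follow the usual two-block conventions: X-weights W (p×a),
    X-scores T (n×a), X-loadings P (p×a), Y-loadings C (q×a),
    Y-scores U (n×a).  ``explained_y`` / ``explained_x`` hold the
    percentage of each block's (centred, optionally scaled) variance
    captured per component.
    """

    n_components: int
    x_weights: np.ndarray
    x_scores: np.ndarray
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    y_scores: np.ndarray
    explained_y: np.ndarray
    explained_x: np.ndarray
    x_mean: np.ndarray
    y_mean: np.ndarray
    x_scale: np.ndarray
    y_scale: np.ndarray
    x_names: list[str] = field(default_factory=list)
    y_names: list[str] = field(default_factory=list)
    obs_names: list[str] = field(default_factory=list)

    @property
    def cumulative_explained_y(self) -> np.ndarray:
        return np.cumsum(self.explained_y)

    def coefficients(self) -> np.ndarray:
        """Regression coefficients B (p×q) on the centred/scaled blocks."""
        W, P, C = self.x_weights, self.x_loadings, self.y_loadings
        return W @ np.linalg.solve(P.T @ W, C.T)

    def variable_correlations(self, block: str = "y") -> np.ndarray:
        """Correlation of each variable of a block with the X-scores.

        These are the standard biplot coordinates on the circle of
        correlations (one row per variable, one column per component).
        """
        Y0 = self._y_centred if block == "y" else self._x_centred
        T = self.x_scores
        out = np.empty((Y0.shape[1], self.n_components))
        for j in range(Y0.shape[1]):
            col = Y0[:, j]
            for a in range(self.n_components):
                t = T[:, a]
                denom = np.linalg.norm(col) * np.linalg.norm(t)
                out[j, a] = (col @ t) / denom if denom > 0 else 0.0
        return out

    # centred working copies stashed by nipals_pls2 for correlations
    _x_centred: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    _y_centred: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]


def _prepare_block(M: np.ndarray, scale: bool, names: Sequence[str], label: str):
    mean = M.mean(axis=0)
    centred = M - mean
    if scale:
        sd = centred.std(axis=0, ddof=1)
        zero = np.flatnonzero(sd == 0)
        if zero.size:
            bad = names[zero[0]] if len(names) else str(zero[0])
            raise ValueError(
                f"zero-variance {label} column {bad!r} cannot be unit-scaled"
            )
        centred = centred / sd
    else:
        sd = np.ones(M.shape[1])
    return centred, mean, sd


def nipals_pls2(
    X,
    Y,
    n_components: int,
    scale: bool = False,
    max_iter: int = 500,
    tol: float = 1e-10,
) -> PLSModel:
    """Two-block PLS regression by the NIPALS algorithm.

    Columns of both blocks are centred (and unit-variance scaled when
    ``scale`` is on).  Each component iterates

        w ∝ Xᵀu,  t = Xw,  c = Yᵀt / tᵀt,  u = Yc / cᵀc

    until the weight vector changes by less than ``tol`` (Euclidean
    norm), then deflates X by its loading p = Xᵀt/tᵀt and Y by c.
    X-scores are mutually orthogonal by construction.  Explained
    variance per component is the drop in residual sum of squares of a
    block relative to its total.
    """
    x_names = list(X.columns) if isinstance(X, pd.DataFrame) else [
        f"x{j}" for j in range(np.asarray(X).shape[1])
    ]
    y_names = list(Y.columns) if isinstance(Y, pd.DataFrame) else [
        f"y{j}" for j in range(np.asarray(Y).shape[1])
    ]
    obs_names = list(X.index) if isinstance(X, pd.DataFrame) else []
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must have the same number of rows")
    if np.isnan(X).any() or np.isnan(Y).any():
        raise ValueError("missing values are not allowed after preprocessing")
    n, p = X.shape
    q = Y.shape[1]
    max_rank = min(n - 1, p)
    if not (1 <= n_components <= max_rank):
        raise ValueError(
            f"n_components must be in [1, {max_rank}] for a {n}x{p} predictor block"
        )

    Xc, x_mean, x_sd = _prepare_block(X, scale, x_names, "predictor")
    Yc, y_mean, y_sd = _prepare_block(Y, scale, y_names, "response")
    X0, Y0 = Xc.copy(), Yc.copy()
    ss_x_total = float((Xc**2).sum())
    ss_y_total = float((Yc**2).sum())

    W = np.zeros((p, n_components))
    T = np.zeros((n, n_components))
    P = np.zeros((p, n_components))
    C = np.zeros((q, n_components))
    U = np.zeros((n, n_components))
    expl_y = np.zeros(n_components)
    expl_x = np.zeros(n_components)

    Xw, Yw = Xc.copy(), Yc.copy()
    for a in range(n_components):
        # start from the response column with the largest remaining SS
        u = Yw[:, int(np.argmax((Yw**2).sum(axis=0)))].copy()
        if not np.any(u):
            u = np.ones(n)
        w_old = np.zeros(p)
        for _ in range(max_iter):
            w = Xw.T @ u
            norm = np.linalg.norm(w)
            if norm == 0:
                raise PLSConvergenceError(
                    f"component {a + 1}: predictor block exhausted (zero weight vector)"
                )
            w /= norm
            t = Xw @ w
            tt = t @ t
            c = Yw.T @ t / tt
            cc = c @ c
            u = Yw @ c / cc if cc > 0 else t.copy()
            if np.linalg.norm(w - w_old) < tol:
                break
            w_old = w
        else:
            raise PLSConvergenceError(
                f"component {a + 1}: NIPALS did not converge in {max_iter} iterations"
            )
        # deterministic sign: largest-|.| weight element positive
        flip = np.sign(w[int(np.argmax(np.abs(w)))]) or 1.0
        w, t, c, u = w * flip, t * flip, c * flip, u * flip
        tt = t @ t
        p_vec = Xw.T @ t / tt

        ss_x_before = float((Xw**2).sum())
        ss_y_before = float((Yw**2).sum())
        Xw = Xw - np.outer(t, p_vec)
        Yw = Yw - np.outer(t, c)
        expl_x[a] = 100.0 * (ss_x_before - float((Xw**2).sum())) / ss_x_total
        expl_y[a] = (
            100.0 * (ss_y_before - float((Yw**2).sum())) / ss_y_total
            if ss_y_total > 0
            else 0.0
        )
        W[:, a], T[:, a], P[:, a], C[:, a], U[:, a] = w, t, p_vec, c, u

    model = PLSModel(
        n_components=n_components,
        x_weights=W,
        x_scores=T,
        x_loadings=P,
        y_loadings=C,
        y_scores=U,
        explained_y=expl_y,
        explained_x=expl_x,
        x_mean=x_mean,
        y_mean=y_mean,
        x_scale=x_sd,
        y_scale=y_sd,
        x_names=x_names,
        y_names=y_names,
        obs_names=obs_names,
    )
    model._x_centred = X0
    model._y_centred = Y0
    return model


@dataclass
class PLSEnrichmentResult:
    """PLS of enrichment profiles plus tidy biplot coordinate tables."""

    model: PLSModel
    observation_scores: pd.DataFrame  # condition × axis
    variable_coordinates: pd.DataFrame  # PLFA × axis (correlations with scores)
    predictor_coordinates: pd.DataFrame  # indicator × axis
    retained_plfas: list[str]
    dropped_plfas: list[str]


def _indicator_matrix(conditions: Sequence[str]) -> pd.DataFrame:
    """Treatment (and day) indicator columns from 'TREAT' / 'TREAT:day' labels."""
    treatments = []
    days = []
    for c in conditions:
        if ":" in str(c):
            t, d = str(c).split(":", 1)
            treatments.append(t)
            days.append(d)
        else:
            treatments.append(str(c))
            days.append(None)
    X = pd.get_dummies(pd.Series(treatments, name="treatment"), prefix="treatment")
    if any(d is not None for d in days):
        X = pd.concat(
            [X, pd.get_dummies(pd.Series(days, name="day"), prefix="day")], axis=1
        )
    X.index = pd.Index(conditions, name="condition")
    return X.astype(float)


def pls_enrichment_analysis(
    matrix: pd.DataFrame,
    n_components: int = 2,
    logit_tol: float = 0.1,
    enrichment_threshold: float = 0.001,
    scale: bool = False,
) -> PLSEnrichmentResult:
    """PLS of proportional PLFA enrichment on treatment/time indicators.

    ``matrix`` is the PLFA × condition proportion matrix from
    :func:`sipriming.plfa.enrichment_matrix` (columns ``TREAT`` or
    ``TREAT:day``).  Low-enrichment PLFAs (grand mean < threshold) are
    dropped, the empirical logit transform applied, and a NIPALS PLS2
    fitted with the condition indicators as predictors.  Observations
    are the conditions; responses are the transformed PLFA profiles.
    """
    filtered, retained, dropped = filter_low_enrichment(matrix, enrichment_threshold)
    if filtered.empty:
        raise ValueError("no PLFAs retained after low-enrichment filtering")
    transformed = filtered.apply(
        lambda col: empirical_logit(np.clip(col.to_numpy(), 0.0, 1.0), logit_tol)
    )
    Y = transformed.T  # conditions × PLFAs
    X = _indicator_matrix(list(Y.index))
    model = nipals_pls2(X, Y, n_components=n_components, scale=scale)

    axes = [f"axis{a + 1}" for a in range(n_components)]
    obs = pd.DataFrame(model.x_scores, index=Y.index, columns=axes)
    var = pd.DataFrame(
        model.variable_correlations("y"), index=Y.columns, columns=axes
    )
    var.index.name = "plfa"
    pred = pd.DataFrame(
        model.variable_correlations("x"), index=X.columns, columns=axes
    )
    pred.index.name = "indicator"
    return PLSEnrichmentResult(
        model=model,
        observation_scores=obs,
        variable_coordinates=var,
        predictor_coordinates=pred,
        retained_plfas=retained,
        dropped_plfas=dropped,
    )


@dataclass(frozen=True)
class IsolateDB:
    """Mean relative PLFA profiles of bacterial genera.

    ``profiles``: rows = PLFA names, columns = genus names, cells = mean
    relative abundance over the genus's isolates (columns sum to 1).
    """

    profiles: pd.DataFrame
    phylum: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.profiles.to_numpy() < 0).any():
            raise ValueError("isolate profiles must be non-negative")
        if self.profiles.columns.duplicated().any():
            raise ValueError("genus names must be unique")

    @classmethod
    def read(cls, path) -> "IsolateDB":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(profiles=df)

    def write(self, path) -> None:
        self.profiles.to_csv(path, sep="\t", float_format="%.10g")


def compare_to_isolates(
    profiles: pd.DataFrame,
    db: IsolateDB,
    n_components: int = 3,
    scale: bool = True,
) -> tuple[PLSModel, pd.DataFrame]:
    """PLS of enriched treatment profiles against genus PLFA profiles.

    Observations are the PLFAs common to both matrices (≥3 required);
    predictors are the genus profiles, responses the treatment
    enrichment profiles.  Returns the model and a genus × axis table of
    correlations between each genus's profile and the X-scores — high
    axis-1 correlation marks genera whose PLFA fingerprint resembles
    the ¹³C-labelled community.
    """
    common = [p for p in profiles.index if p in db.profiles.index]
    if len(common) < 3:
        raise ValueError(
            f"only {len(common)} PLFA(s) common to profiles and isolate database; need >= 3"
        )
    X = db.profiles.loc[common]
    Y = profiles.loc[common]
    model = nipals_pls2(X, Y, n_components=n_components, scale=scale)
    axes = [f"axis{a + 1}" for a in range(n_components)]
    cors = pd.DataFrame(
        model.variable_correlations("x"), index=X.columns, columns=axes
    )
    cors.index.name = "genus"
    if db.phylum:
        cors["phylum"] = [db.phylum.get(g, "") for g in cors.index]
    return model, cors
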