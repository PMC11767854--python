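"""NIPALS PLS-1 discrimination between control and treated groups.

Spectra (rows of X) are regressed on a two-level class code y (default
control -> 0, abeta -> 1) by the NIPALS partial-least-squares algorithm for a
single response.  Factor-1 scores separate the groups when treatment effects
dominate the within-group variation, and the regression (beta) coefficients on
the original wavenumber variables localize which bands drive the
discrimination: with the default coding, positive beta extrema characterize
the treated class.

Model quality is summarized the chemometrics way: Pearson correlation and
root-mean-squared error of calibration (full-data fit: r_cal, RMSEC) and of
cross-validation (held-out prediction: r_val, RMSECV).  RMSE uses 1/n
denominators.  The default cross-validation scheme leaves out one spectrum at
a time; ``loo_bio_rep`` leaves out all technical replicates of one biological
replicate together, which avoids leaking class information through technical
pseudoreplicates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spectra import SampleMeta, SpectraSet, WavenumberAxis

CV_SCHEMES = ("loo_spectrum", "loo_bio_rep")


@dataclass(frozen=True)
class ClassCoding:
    """Mapping from condition labels to the real-valued PLS response."""

    codes: dict[str, float] = field(
        default_factory=lambda: {"control": 0.0, "abeta": 1.0}
    )

    def __post_init__(self) -> None:
        if len(set(self.codes.values())) != 2:
            raise ValueError("class coding must assign exactly two distinct codes")

    def positive_class(self) -> str:
        """Label of the higher-coded class (the one positive beta points to)."""
        return max(self.codes, key=self.codes.get)

    def negative_class(self) -> str:
        return min(self.codes, key=self.codes.get)


def encode_classes(meta: tuple[SampleMeta, ...], coding: ClassCoding | None = None) -> np.ndarray:
    """Response vector ``y_i = coding(condition_i)``."""
    coding = coding or ClassCoding()
    try:
        return np.array([coding.codes[m.condition] for m in meta], dtype=float)
    except KeyError as exc:
        raise ValueError(f"condition {exc.args[0]!r} not present in the class coding")


@dataclass
class PLSModel:
    """Fitted NIPALS PLS-1 state.

    ``W`` (weights), ``P`` (x-loadings) and ``q`` (y-loadings) hold one column
    (entry) per extracted factor; ``T`` are the scores.  ``beta`` gives the
    regression coefficients on the centered original variables for
    ``n_factors`` factors, so that ``yhat = y_mean + (X - x_mean) @ beta``.
    """

    n_factors: int
    x_mean: np.ndarray
    y_mean: float
    W: np.ndarray
    P: np.ndarray
    q: np.ndarray
    T: np.ndarray
    axis: WavenumberAxis | None = None

    def beta_for(self, n_factors: int | None = None) -> np.ndarray:
        """beta = W (P^T W)^-1 q restricted to the first ``n_factors`` factors."""
        k = self.n_factors if n_factors is None else n_factors
        if not 1 <= k <= self.n_factors:
            raise ValueError(f"n_factors must be in [1, {self.n_factors}], got {k}")
        Wk, Pk, qk = self.W[:, :k], self.P[:, :k], self.q[:k]
        return Wk @ np.linalg.solve(Pk.T @ Wk, qk)

    @property
    def beta(self) -> np.ndarray:
        return self.beta_for()


@dataclass(frozen=True)
class PLSMetrics:
    """Calibration and validation figures of merit."""

    r_cal: float
    r_val: float
    rmsec: float
    rmsecv: float


def _as_matrix(X: SpectraSet | np.ndarray) -> tuple[np.ndarray, WavenumberAxis | None]:
    if isinstance(X, SpectraSet):
        return X.absorbance, X.axis
    return np.asarray(X, dtype=float), None


def fit_pls(
    X: SpectraSet | np.ndarray, y: np.ndarray, n_factors: int = 1
) -> PLSModel:
    """Fit a NIPALS PLS-1 model on mean-centered data.

    Per factor: ``w`` proportional to ``X^T y`` (unit norm), ``t = X w``,
    ``p = X^T t / (t^T t)``, ``q = y^T t / (t^T t)``, then ``X`` and ``y`` are
    deflated by the rank-one fit.  The sign indeterminacy of each factor is
    resolved by forcing the largest-magnitude element of ``w`` positive.
    Extraction stops early (with a warning) if deflation degenerates.
    """
    Xm, axis = _as_matrix(X)
    y = np.asarray(y, dtype=float).ravel()
    n, p = Xm.shape
    if y.size != n:
        raise ValueError(f"y has {y.size} entries but X has {n} rows")
    if n < 3:
        raise ValueError("PLS requires at least 3 samples")
    if np.ptp(y) == 0:
        raise ValueError("response y is constant; nothing to discriminate")
    if not 1 <= n_factors <= min(n - 1, p):
        raise ValueError(
            f"n_factors must be in [1, min(n_samples - 1, n_variables)] = "
            f"[1, {min(n - 1, p)}], got {n_factors}"
        )

    x_mean = Xm.mean(axis=0)
    y_mean = float(y.mean())
    Xc = Xm - x_mean
    yc = y - y_mean

    W = np.empty((p, n_factors))
    P = np.empty((p, n_factors))
    q = np.empty(n_factors)
    T = np.empty((n, n_factors))
    extracted = 0
    for a in range(n_factors):
        w = Xc.T @ yc
        nw = np.linalg.norm(w)
        if nw < 1e-14:
            warnings.warn(
                f"deflation degenerated after {extracted} factors; "
                f"returning a smaller model",
                stacklevel=2,
            )
            break
        w /= nw
        if w[int(np.argmax(np.abs(w)))] < 0:
            w = -w
        t = Xc @ w
        tt = float(t @ t)
        if tt < 1e-14:
            warnings.warn(
                f"score norm vanished after {extracted} factors; "
                f"returning a smaller model",
                stacklevel=2,
            )
            break
        pvec = Xc.T @ t / tt
        qa = float(yc @ t) / tt
        Xc = Xc - np.outer(t, pvec)
        yc = yc - t * qa
        W[:, a], P[:, a], q[a], T[:, a] = w, pvec, qa, t
        extracted += 1

    if extracted == 0:
        raise ValueError("no PLS factor could be extracted (X^T y is zero)")
    return PLSModel(
        n_factors=extracted,
        x_mean=x_mean,
        y_mean=y_mean,
        W=W[:, :extracted],
        P=P[:, :extracted],
        q=q[:extracted],
        T=T[:, :extracted],
        axis=axis,
    )


def predict(
    m: PLSModel, X_new: SpectraSet | np.ndarray, n_factors: int | None = None
) -> np.ndarray:
    """``yhat = y_mean + (X_new - x_mean) @ beta``."""
    Xm, axis = _as_matrix(X_new)
    if axis is not None and m.axis is not None and axis != m.axis:
        raise ValueError("wavenumber axis of X_new does not match the model axis")
    if Xm.shape[1] != m.x_mean.size:
        raise ValueError(
            f"X_new has {Xm.shape[1]} variables but the model was fit on "
            f"{m.x_mean.size}"
        )
    return m.y_mean + (Xm - m.x_mean) @ m.beta_for(n_factors)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def _rmse(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean((a - b) ** 2)))


def cross_validate(
    X: SpectraSet | np.ndarray,
    y: np.ndarray,
    n_factors: int = 1,
    scheme: str = "loo_spectrum",
    meta: tuple[SampleMeta, ...] | None = None,
) -> tuple[np.ndarray, PLSMetrics]:
    """Leave-one-out cross-validation with full-data calibration metrics.

    ``loo_bio_rep`` segments by ``(condition, bio_rep)`` so all technical
    replicates of a biological replicate are held out together; it requires
    ``meta`` (taken from ``X`` when it is a :class:`SpectraSet`).
    """
    if scheme not in CV_SCHEMES:
        raise ValueError(f"scheme must be one of {CV_SCHEMES}, got {scheme!r}")
    Xm, _ = _as_matrix(X)
    y = np.asarray(y, dtype=float).ravel()
    if meta is None and isinstance(X, SpectraSet):
        meta = X.meta

    if scheme == "loo_spectrum":
        segments = [[i] for i in range(Xm.shape[0])]
    else:
        if meta is None:
            raise ValueError("loo_bio_rep needs sample metadata")
        groups: dict[tuple[str, int], list[int]] = {}
        for i, m in enumerate(meta):
            groups.setdefault((m.condition, m.bio_rep), []).append(i)
        segments = [groups[k] for k in sorted(groups)]
    if len(segments) < 3:
        raise ValueError(f"need at least 3 cross-validation segments, got {len(segments)}")

    y_cv = np.empty_like(y)
    for seg in segments:
        train = np.setdiff1d(np.arange(Xm.shape[0]), seg)
        if np.ptp(y[train]) == 0:
            raise ValueError(
                f"training fold excluding spectra {seg} has a constant response"
            )
        model = fit_pls(Xm[train], y[train], n_factors=min(n_factors, len(train) - 1))
        y_cv[seg] = predict(model, Xm[seg])

    full = fit_pls(Xm, y, n_factors=n_factors)
    y_fit = predict(full, Xm)
    metrics = PLSMetrics(
        r_cal=_pearson(y, y_fit),
        r_val=_pearson(y, y_cv),
        rmsec=_rmse(y, y_fit),
        rmsecv=_rmse(y, y_cv),
    )
    return y_cv, metrics


def beta_peak_attribution(
    m: PLSModel,
    targets: tuple[float, ...] | list[float],
    tolerance: float = 6.0,
    coding: ClassCoding | None = None,
    n_factors: int = 1,
) -> pd.DataFrame:
    """Match target wavenumbers to local extrema of the beta-coefficient trace.

    Every strict local extremum of beta (interior maxima and minima; plateau
    runs contribute their highest-wavenumber point) is a candidate; each
    target is matched to the nearest extremum within ``tolerance`` cm^-1.  The
    sign of beta at the extremum assigns the peak to the positively or
    negatively coded class.  Unmatched targets are reported, not errors.
    """
    if m.axis is None:
        raise ValueError("the model carries no wavenumber axis")
    coding = coding or ClassCoding()
    beta = m.beta_for(n_factors)
    v = m.axis.values

    idx: list[int] = []
    i = 1
    n = beta.size
    while i < n - 1:
        j = i
        while j < n - 1 and beta[j + 1] == beta[j]:
            j += 1
        if j < n - 1:
            left, right = beta[i - 1], beta[j + 1]
            if (beta[i] > left and beta[i] > right) or (
                beta[i] < left and beta[i] < right
            ):
                idx.append(i)  # leftmost point of a plateau
        i = j + 1

    rows = []
    for target in targets:
        best = None
        if idx:
            dists = np.abs(v[idx] - target)
            k = int(np.argmin(dists))
            if dists[k] <= tolerance:
                best = idx[k]
        if best is None:
            rows.append(
                {
                    "target_cm1": target,
                    "found_cm1": np.nan,
                    "beta": np.nan,
                    "sign": 0,
                    "associated_class": None,
                    "matched": False,
                }
            )
        else:
            sign = int(np.sign(beta[best]))
            rows.append(
                {
                    "target_cm1": target,
                    "found_cm1": float(v[best]),
                    "beta": float(beta[best]),
                    "sign": sign,
                    "associated_class": (
                        coding.positive_class() if sign > 0 else coding.negative_class()
                    ),
                    "matched": True,
                }
            )
    return pd.DataFrame(rows)
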