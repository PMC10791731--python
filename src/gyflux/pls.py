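"""Batch-level PLS of final titer on time-resolved culture variables.

The qualified (outlier-screened) dataset is unfolded into a batch-level
matrix: one row per batch, one column per (variable, timepoint) pair over the
post-feeding sampling days {4, 5, 6, 7, 8, 10, 12, 14}.  The response is the
final-day IgG titer normalized to the maximum across the dataset.  A PLS1
regression (NIPALS) links the autoscaled matrix to the response; variable
influence on projection (VIP) scores identify the influential columns, and
per-variable sums of regression coefficients over the VIP-passing timepoints
rank nutrients by the consistency and direction of their association with
final titer.

The modelling surface follows the statsmodels convention: a
:class:`BatchLevelPLS` model object whose :meth:`~BatchLevelPLS.fit` returns
a :class:`PLSResults` carrying estimates, diagnostics and ``summary()``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from gyflux.synth import CultureBatch

logger = logging.getLogger(__name__)

#: post-feeding timepoints entering the batch-level model
BLM_TIMEPOINTS = [4.0, 5.0, 6.0, 7.0, 8.0, 10.0, 12.0, 14.0]

#: process variables that are not nutrients (excluded from nutrient rankings)
NON_NUTRIENT_VARIABLES = ("VCD", "viability", "titer")


@dataclass
class BatchLevelMatrix:
    """Unfolded batch-level data: X (batches x variable*timepoint), y titer."""

    X: pd.DataFrame                  # columns: MultiIndex (variable, day)
    y: pd.Series                     # final titer / max final titer, unitless
    dropped_columns: list[tuple[str, float]] = field(default_factory=list)

    @property
    def variables(self) -> list[str]:
        return sorted({v for v, _ in self.X.columns})


def unfold_batch_level(
    batches: list[CultureBatch],
    timepoints: list[float] | None = None,
    variables: list[str] | None = None,
) -> BatchLevelMatrix:
    """Decompose batch trajectories into one row per batch.

    All variables (VCD, viability, titer and metabolite concentrations, or an
    explicit ``variables`` list) at each requested timepoint become columns.
    The response is the final-timepoint titer normalized to the dataset
    maximum, so the best batch scores exactly 1.  Columns with zero variance
    are removed and logged.
    """
    timepoints = timepoints if timepoints is not None else list(BLM_TIMEPOINTS)
    if not batches:
        raise ValueError("no batches to unfold")
    if variables is None:
        mets = sorted(batches[0].conc)
        variables = list(NON_NUTRIENT_VARIABLES) + mets

    missing = []
    for b in batches:
        for t in timepoints:
            if t not in b.days:
                missing.append((b.batch_id, t))
    if missing:
        raise ValueError(f"missing (batch, day) samples: {missing}")

    data = {}
    for var in variables:
        for t in timepoints:
            data[(var, t)] = [b.value_at(var, t) for b in batches]
    X = pd.DataFrame(
        data,
        index=pd.Index([b.batch_id for b in batches], name="batch_id"),
    )
    X.columns = pd.MultiIndex.from_tuples(X.columns, names=["variable", "day"])

    final_day = max(timepoints)
    titer = np.array([b.value_at("titer", final_day) for b in batches], dtype=float)
    max_titer = titer.max()
    if max_titer <= 0:
        raise ValueError("final titers are all non-positive; cannot normalize")
    y = pd.Series(titer / max_titer, index=X.index, name="final_titer_norm")

    sd = X.std(axis=0, ddof=1)
    dropped = [(f"{v}@{d:g}", float(X[(v, d)].iloc[0])) for (v, d) in X.columns[sd == 0]]
    if dropped:
        logger.info("dropping %d zero-variance columns: %s", len(dropped), dropped)
        X = X.loc[:, sd > 0]
    return BatchLevelMatrix(X=X, y=y, dropped_columns=dropped)


def _nipals_pls1(
    X: np.ndarray, y: np.ndarray, n_components: int, tol: float = 1e-10, max_iter: int = 500
) -> dict[str, np.ndarray]:
    """NIPALS PLS1 on pre-scaled data; returns weights/loadings/scores/coefs."""
    n, p = X.shape
    Xa = X.copy()
    ya = y.astype(float).copy()
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    T = np.zeros((n, n_components))
    q = np.zeros(n_components)
    for a in range(n_components):
        w = Xa.T @ ya
        norm = np.linalg.norm(w)
        if norm == 0:
            raise ValueError(f"residual X'y vanished at component {a + 1}")
        w /= norm
        for _ in range(max_iter):  # converges in one pass for a single response
            t = Xa @ w
            w_new = Xa.T @ ya
            w_new /= np.linalg.norm(w_new)
            if np.linalg.norm(w_new - w) < tol:
                w = w_new
                break
            w = w_new
        t = Xa @ w
        tt = float(t @ t)
        p_a = Xa.T @ t / tt
        q_a = float(ya @ t / tt)
        Xa = Xa - np.outer(t, p_a)
        ya = ya - q_a * t
        W[:, a], P[:, a], T[:, a], q[a] = w, p_a, t, q_a
    # regression vector in the scaled space
    PW = P.T @ W
    coef = W @ np.linalg.solve(PW, q)
    return {"W": W, "P": P, "T": T, "q": q, "coef": coef}


def vip_scores(results: "PLSResults") -> pd.Series:
    """Wold VIP per column: sqrt(p * sum_a SSY_a (w_ja/||w_a||)^2 / sum_a SSY_a)."""
    W, T, q = results.weights, results.scores, results.y_loadings
    p = W.shape[0]
    ssy = q**2 * np.einsum("ia,ia->a", T, T)  # explained y-variance per component
    wnorm2 = np.einsum("ja,ja->a", W, W)
    vip = np.sqrt(p * (W**2 / wnorm2) @ ssy / ssy.sum())
    return pd.Series(vip, index=results.columns, name="VIP")


@dataclass
class PLSResults:
    """Fitted batch-level PLS model: estimates, importances, diagnostics."""

    model: "BatchLevelPLS"
    n_components: int
    weights: np.ndarray              # W, columns unit-norm
    x_loadings: np.ndarray           # P
    scores: np.ndarray               # T
    y_loadings: np.ndarray           # q
    coef: pd.Series                  # regression coefficients, autoscaled space
    r2y: np.ndarray                  # cumulative explained y-variance per component
    q2: float | None = None          # leave-one-out Q2 at the chosen rank

    @property
    def columns(self) -> pd.MultiIndex:
        return self.model.X.columns

    @property
    def vip(self) -> pd.Series:
        return vip_scores(self)

    def predict(self, X: pd.DataFrame | None = None) -> pd.Series:
        Xs = self.model._scale(self.model.X if X is None else X)
        yhat = Xs @ self.coef.to_numpy()
        yhat = self.model.y_mean + self.model.y_std * yhat
        index = (self.model.X if X is None else X).index
        return pd.Series(np.asarray(yhat), index=index, name="predicted")

    def rank_nutrients(
        self,
        vip_threshold: float = 1.00,
        by: str = "signed",
        variables: list[str] | None = None,
    ) -> pd.DataFrame:
        return coefficient_sum_ranking(
            self, vip_threshold=vip_threshold, by=by, variables=variables
        )

    def coefficient_table(self) -> pd.DataFrame:
        """Variable x timepoint matrix of scaled-space coefficients."""
        return self.coef.unstack(level="day")

    def scores_table(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.scores,
            index=self.model.X.index,
            columns=[f"t{a + 1}" for a in range(self.n_components)],
        )
        df["final_titer_norm"] = self.model.y.to_numpy()
        return df

    def summary(self) -> str:
        lines = [
            "Batch-level PLS regression (final titer ~ unfolded trajectories)",
            "=" * 64,
            f"batches:            {self.model.X.shape[0]}",
            f"columns:            {self.model.X.shape[1]} (variable x timepoint)",
            f"components:         {self.n_components}",
            f"R2Y (cumulative):   "
            + ", ".join(f"{v:.3f}" for v in self.r2y),
        ]
        if self.q2 is not None:
            lines.append(f"Q2 (leave-one-out): {self.q2:.3f}")
        vip = self.vip
        lines.append(f"columns with VIP >= 1.00: {int((vip >= 1.0).sum())} / {len(vip)}")
        ranking = self.rank_nutrients().head(10)
        if len(ranking):
            lines.append("")
            lines.append("top nutrients by signed coefficient-sum (most negative first):")
            for _, row in ranking.iterrows():
                lines.append(
                    f"  {row['rank']:>3d}. {row['variable']:<14s} "
                    f"sum={row['coefficient_sum']:+.4f}  timepoints={int(row['n_timepoints'])}"
                )
        return "\n".join(lines)


class BatchLevelPLS:
    """PLS1 model of normalized final titer on the unfolded batch matrix.

    Parameters
    ----------
    X, y :
        Batch-level matrix (rows = batches, columns = (variable, day)) and
        the normalized final titer; typically from :func:`unfold_batch_level`.
    scale :
        Autoscale columns to zero mean / unit variance (default, the SIMCA
        convention); the response is likewise centred and scaled.
    """

    def __init__(self, X: pd.DataFrame, y: pd.Series, scale: bool = True):
        if list(X.index) != list(y.index):
            raise ValueError("X and y must share the same batch index")
        self.X = X
        self.y = y
        self.scale = scale
        Xv = X.to_numpy(dtype=float)
        self.x_mean = Xv.mean(axis=0)
        sd = Xv.std(axis=0, ddof=1)
        if np.any(sd == 0):
            zero = [f"{v}@{d:g}" for (v, d) in X.columns[sd == 0]]
            raise ValueError(f"zero-variance columns in X (drop first): {zero}")
        self.x_std = sd if scale else np.ones_like(sd)
        self.y_mean = float(y.mean())
        ysd = float(y.std(ddof=1))
        self.y_std = ysd if (scale and ysd > 0) else 1.0

    @classmethod
    def from_batches(cls, batches: list[CultureBatch], **kwargs) -> "BatchLevelPLS":
        m = unfold_batch_level(batches, **kwargs)
        return cls(m.X, m.y)

    @classmethod
    def from_matrix(cls, matrix: BatchLevelMatrix, scale: bool = True) -> "BatchLevelPLS":
        return cls(matrix.X, matrix.y, scale=scale)

    def _scale(self, X: pd.DataFrame) -> np.ndarray:
        return (X.to_numpy(dtype=float) - self.x_mean) / self.x_std

    def _scaled_xy(self) -> tuple[np.ndarray, np.ndarray]:
        ys = (self.y.to_numpy(dtype=float) - self.y_mean) / self.y_std
        return self._scale(self.X), ys

    def max_components(self) -> int:
        return max(1, min(self.X.shape[0] - 1, self.X.shape[1]))

    def fit(
        self,
        n_components: int | None = None,
        max_components: int = 5,
        min_q2_gain: float = 0.05,
    ) -> PLSResults:
        """Fit with a fixed rank, or pick it by leave-one-out Q2 (capped)."""
        q2 = None
        if n_components is None:
            n_components, q2 = self.select_components(
                max_components=max_components, min_q2_gain=min_q2_gain
            )
        if not 1 <= n_components <= self.max_components():
            raise ValueError(
                f"n_components must be in [1, {self.max_components()}], got {n_components}"
            )
        Xs, ys = self._scaled_xy()
        fit = _nipals_pls1(Xs, ys, n_components)
        ss_tot = float(ys @ ys)
        resid = ys.copy()
        r2 = []
        for a in range(n_components):
            resid = resid - fit["q"][a] * fit["T"][:, a]
            r2.append(1.0 - float(resid @ resid) / ss_tot)
        return PLSResults(
            model=self,
            n_components=n_components,
            weights=fit["W"],
            x_loadings=fit["P"],
            scores=fit["T"],
            y_loadings=fit["q"],
            coef=pd.Series(fit["coef"], index=self.X.columns, name="coef"),
            r2y=np.array(r2),
            q2=q2,
        )

    def select_components(
        self, max_components: int = 5, min_q2_gain: float = 0.05
    ) -> tuple[int, float]:
        """Smallest adequate rank by leave-one-out Q2.

        Components are accepted sequentially while each adds at least
        ``min_q2_gain`` to the cross-validated Q2 (the stopping rule used by
        batch-level PLS practice: once prediction stops improving materially,
        further components only redistribute coefficient mass among
        collinear columns).
        """
        Xs, ys = self._scaled_xy()
        n = Xs.shape[0]
        amax = min(max_components, self.max_components(), n - 2)
        amax = max(amax, 1)
        press = np.zeros(amax)
        for i in range(n):
            mask = np.arange(n) != i
            Xtr, ytr = Xs[mask], ys[mask]
            mu, sd = Xtr.mean(axis=0), Xtr.std(axis=0, ddof=1)
            sd[sd == 0] = 1.0
            ymu = ytr.mean()
            a_i = min(amax, Xtr.shape[0] - 1)
            fit = _nipals_pls1((Xtr - mu) / sd, ytr - ymu, a_i)
            W, P, q = fit["W"], fit["P"], fit["q"]
            xi = (Xs[i] - mu) / sd
            for a in range(amax):
                aa = min(a + 1, a_i)
                coef_a = W[:, :aa] @ np.linalg.solve(P[:, :aa].T @ W[:, :aa], q[:aa])
                press[a] += (ys[i] - (ymu + xi @ coef_a)) ** 2
        ss_tot = float(ys @ ys)
        q2 = 1.0 - press / ss_tot
        best = 0
        for a in range(1, amax):
            if q2[a] - q2[best] < min_q2_gain:
                break
            best = a
        return best + 1, float(q2[best])


def fit_pls(matrix: BatchLevelMatrix, n_components: int | None = None) -> PLSResults:
    """Functional wrapper: fit the batch-level PLS on an unfolded matrix."""
    return BatchLevelPLS.from_matrix(matrix).fit(n_components=n_components)


def coefficient_sum_ranking(
    results: PLSResults,
    vip_threshold: float = 1.00,
    by: str = "signed",
    variables: list[str] | None = None,
) -> pd.DataFrame:
    """Rank variables by their coefficient-sum over VIP-passing timepoints.

    For each variable, regression coefficients (autoscaled space) are summed
    over the timepoints whose column VIP >= ``vip_threshold``.  ``by='signed'``
    sorts most-negative first (the detrimental-nutrient view); ``by='abs'``
    sorts by magnitude.  Ties break lexicographically by variable name.
    By default only nutrient variables are ranked (VCD, viability and titer
    columns are excluded).
    """
    if by not in ("signed", "abs"):
        raise ValueError("by must be 'signed' or 'abs'")
    vip = results.vip
    coef = results.coef
    passing = vip >= vip_threshold
    if not passing.any():
        logger.warning("no column passes VIP >= %.2f; ranking is empty", vip_threshold)
        return pd.DataFrame(
            columns=["variable", "coefficient_sum", "n_timepoints", "rank"]
        )
    if variables is None:
        variables = [
            v
            for v in {var for var, _ in results.columns}
            if v not in NON_NUTRIENT_VARIABLES
        ]
    rows = []
    for var in sorted(variables):
        cols = [c for c in results.columns if c[0] == var and passing[c]]
        if not cols:
            continue
        rows.append((var, float(coef[cols].sum()), len(cols)))
    df = pd.DataFrame(rows, columns=["variable", "coefficient_sum", "n_timepoints"])
    if by == "signed":
        df = df.sort_values(["coefficient_sum", "variable"], ascending=[True, True])
    else:
        df = df.assign(_mag=df["coefficient_sum"].abs()).sort_values(
            ["_mag", "variable"], ascending=[False, True]
        ).drop(columns="_mag")
    df["rank"] = np.arange(1, len(df) + 1)
    return df.reset_index(drop=True)
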