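"""QSPR machinery: Grubbs outlier screening, stepwise multiple linear
regression with partial-F entry/removal, and noise-replicate robustness
selection of descriptors.

The stepwise regressor is scikit-learn shaped (fit/predict, get_params,
fitted attributes with trailing underscores); ``RobustDescriptorSelector``
wraps it, refitting on multiplicatively noised responses and counting how
often each descriptor is retained across the base + replicate models.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin


# ---------------------------------------------------------------------------
# Grubbs outlier test

def grubbs_critical_value(n: int, alpha: float) -> float:
    """Two-sided critical value G_crit(n, alpha) from Student's t:

        G_crit = (n-1)/sqrt(n) * sqrt(t^2 / (n - 2 + t^2))

    with t the upper alpha/(2n) quantile of t with n-2 degrees of freedom.
    """
    if n < 3:
        raise ValueError("Grubbs test needs n >= 3")
    t = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(t * t / (n - 2 + t * t))


def grubbs_outliers(values, alpha: float = 0.05
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Iterative two-sided Grubbs screening.

    Repeatedly removes the single most extreme point while its statistic
    G = max|x - mean|/sd exceeds the critical value; stops when nothing is
    flagged or fewer than 3 points remain.  Returns (kept, removed) index
    arrays into the input.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("Grubbs test needs n >= 3")
    idx = np.arange(x.size)
    removed: list[int] = []
    while idx.size >= 3:
        sub = x[idx]
        sd = sub.std(ddof=1)
        if sd == 0.0:
            break
        dev = np.abs(sub - sub.mean())
        imax = int(np.argmax(dev))
        G = dev[imax] / sd
        if G > grubbs_critical_value(idx.size, alpha):
            removed.append(int(idx[imax]))
            idx = np.delete(idx, imax)
        else:
            break
    return idx, np.asarray(removed, dtype=int)


# ---------------------------------------------------------------------------
# stepwise MLR

def _ols(Xm: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """Least squares with intercept; returns (coef_with_intercept, rss)."""
    A = np.column_stack([np.ones(len(y)), Xm])
    coef, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    return coef, float(resid @ resid)


def _partial_f_p(rss_small: float, rss_big: float, n: int, p_big: int) -> float:
    """p-value of the partial F test for one added term.

    p_big counts predictors (excluding intercept) in the bigger model.
    """
    df2 = n - p_big - 1
    if df2 <= 0:
        return 1.0
    num = max(rss_small - rss_big, 0.0)
    if rss_big <= 0.0:
        return 0.0 if num > 0 else 1.0
    F = num / (rss_big / df2)
    return float(stats.f.sf(F, 1, df2))


class StepwiseMLR(BaseEstimator, RegressorMixin):
    """Stepwise multiple linear regression with F-based entry and removal.

    At each iteration the excluded column with the smallest partial-F
    p-value is added if it passes the entry criterion; then included columns
    with p >= p_remove are removed (largest p first); iterate to a fixed
    point.  Because the entry step picks the minimum p over all candidates,
    the default entry criterion Bonferroni-corrects p_enter by the number of
    candidates examined, which keeps the admission rate of a pure-noise
    response at the nominal p_enter level (``entry_correction="none"``
    restores the uncorrected per-candidate threshold).  Candidates nearly
    collinear with the included set (tolerance 1 - R²(candidate | included)
    < 1e-4) are refused.  With z-scaled inputs the coefficients are
    standardized.

    Attributes
    ----------
    selected_ : retained column names, in entry order
    coef_ : standardized coefficients of the retained columns
    intercept_, r2_, adj_r2_, pvalues_, n_obs_, cycled_
    """

    def __init__(self, p_enter: float = 0.05, p_remove: float = 0.10,
                 max_steps: int = 200, tol: float = 1e-4,
                 entry_correction: str = "bonferroni"):
        self.p_enter = p_enter
        self.p_remove = p_remove
        self.max_steps = max_steps
        self.tol = tol
        self.entry_correction = entry_correction

    def fit(self, X, y):
        X = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X))
        if X.isna().any().any():
            raise ValueError("descriptor matrix contains undefined cells")
        y = np.asarray(y, dtype=float)
        n = len(y)
        if len(X) != n:
            raise ValueError("X and y length mismatch")
        cols = list(X.columns)
        Xa = X.to_numpy(float)
        included: list[int] = []
        seen_states: set[frozenset] = set()
        self.cycled_ = False
        tss_scale = max(float(np.sum((y - y.mean()) ** 2)), 1e-300)

        for _ in range(self.max_steps):
            changed = False
            # forward: best candidate by partial-F p-value
            _, rss_cur = _ols(Xa[:, included], y)
            best_p, best_j, n_candidates = None, None, 0
            if rss_cur > 1e-12 * tss_scale:  # nothing left to explain
                for j in range(len(cols)):
                    if j in included:
                        continue
                    if included:
                        # collinearity guard: candidate tolerance vs included
                        _, rssj = _ols(Xa[:, included], Xa[:, j])
                        ss = np.sum((Xa[:, j] - Xa[:, j].mean()) ** 2)
                        if ss <= 0 or (rssj / ss) < self.tol:
                            continue
                    n_candidates += 1
                    _, rss_new = _ols(Xa[:, included + [j]], y)
                    p = _partial_f_p(rss_cur, rss_new, n, len(included) + 1)
                    if best_p is None or p < best_p:
                        best_p, best_j = p, j
            threshold = self.p_enter
            if self.entry_correction == "bonferroni" and n_candidates > 0:
                threshold = self.p_enter / n_candidates
            if best_p is not None and best_p <= threshold:
                included.append(best_j)
                changed = True
            # backward: drop terms with p >= p_remove, worst first
            while len(included) > 0:
                _, rss_full = _ols(Xa[:, included], y)
                worst_p, worst_j = None, None
                for j in included:
                    rest = [i for i in included if i != j]
                    _, rss_red = _ols(Xa[:, rest], y)
                    p = _partial_f_p(rss_red, rss_full, n, len(included))
                    if worst_p is None or p > worst_p:
                        worst_p, worst_j = p, j
                if worst_p is not None and worst_p >= self.p_remove:
                    included.remove(worst_j)
                    changed = True
                else:
                    break
            state = frozenset(included)
            if state in seen_states and changed:
                self.cycled_ = True
                break
            seen_states.add(state)
            if not changed:
                break

        coef, rss = _ols(Xa[:, included], y)
        tss = float(np.sum((y - y.mean()) ** 2))
        self.selected_ = [cols[j] for j in included]
        self.intercept_ = float(coef[0])
        self.coef_ = coef[1:]
        self.r2_ = 1.0 - rss / tss if tss > 0 else 0.0
        k = len(included)
        self.adj_r2_ = (1.0 - (1.0 - self.r2_) * (n - 1) / (n - k - 1)
                        if n - k - 1 > 0 else np.nan)
        pvals = {}
        _, rss_full = _ols(Xa[:, included], y)
        for j in included:
            rest = [i for i in included if i != j]
            _, rss_red = _ols(Xa[:, rest], y)
            pvals[cols[j]] = _partial_f_p(rss_red, rss_full, n, len(included))
        self.pvalues_ = pvals
        self.n_obs_ = n
        self._columns = cols
        return self

    def predict(self, X) -> np.ndarray:
        X = X if isinstance(X, pd.DataFrame) else pd.DataFrame(
            np.asarray(X), columns=self._columns)
        return (self.intercept_
                + X[self.selected_].to_numpy(float) @ self.coef_)


def stepwise_mlr(X: pd.DataFrame, y, p_enter: float = 0.05,
                 p_remove: float = 0.10, max_steps: int = 200) -> StepwiseMLR:
    return StepwiseMLR(p_enter, p_remove, max_steps).fit(X, y)


# ---------------------------------------------------------------------------
# noise-replicate robustness

class RobustDescriptorSelector(BaseEstimator):
    """Select descriptors stable under multiplicative response noise.

    Fits the stepwise model on y, then on ``n_replicates`` noised responses
    y' = y * u, u ~ Uniform(noise_low, noise_high) i.i.d. per observation,
    and counts per-descriptor retention over the base + replicate models.
    The robust set holds descriptors retained in more than half of the
    models (count > (n_replicates + 1) / 2).

    Attributes
    ----------
    models_, counts_, robust_set_, coefficients_, sign_consistent_
    """

    def __init__(self, n_replicates: int = 10, noise_low: float = 0.90,
                 noise_high: float = 1.10, random_state: int = 0,
                 p_enter: float = 0.05, p_remove: float = 0.10,
                 majority_threshold: float | None = None):
        self.n_replicates = n_replicates
        self.noise_low = noise_low
        self.noise_high = noise_high
        self.random_state = random_state
        self.p_enter = p_enter
        self.p_remove = p_remove
        self.majority_threshold = majority_threshold

    def fit(self, X, y):
        y = np.asarray(y, dtype=float)
        models = []
        failures = []
        base = StepwiseMLR(self.p_enter, self.p_remove).fit(X, y)
        models.append(("base", base))
        for r in range(self.n_replicates):
            # replicate seeds derived from the master seed by fixed offsets
            rng = np.random.default_rng(self.random_state + 1000 * (r + 1))
            u = rng.uniform(self.noise_low, self.noise_high, size=len(y))
            try:
                m = StepwiseMLR(self.p_enter, self.p_remove).fit(X, y * u)
                models.append((f"replicate_{r+1}", m))
            except Exception as exc:  # noqa: BLE001 - recorded, not raised
                failures.append((r + 1, str(exc)))
        self.models_ = models
        self.failures_ = failures
        n_models = len(models)
        counts: dict[str, int] = {}
        coefs: dict[str, dict[str, float]] = {}
        for name, m in models:
            for col, c in zip(m.selected_, m.coef_):
                counts[col] = counts.get(col, 0) + 1
                coefs.setdefault(col, {})[name] = float(c)
        self.counts_ = counts
        self.coefficients_ = coefs
        threshold = (self.majority_threshold
                     if self.majority_threshold is not None
                     else n_models / 2.0)
        self.threshold_ = threshold
        self.robust_set_ = sorted(
            [c for c, k in counts.items() if k > threshold])
        self.sign_consistent_ = {
            c: (len({np.sign(v) for v in d.values()}) == 1)
            for c, d in coefs.items()}
        return self

    def report(self) -> pd.DataFrame:
        """Per-model coefficient table (rows: descriptors sorted by retention
        count; header rows carry each model's R² / adjusted R²)."""
        model_names = [name for name, _ in self.models_]
        rows = {}
        rows["R2"] = {name: m.r2_ for name, m in self.models_}
        rows["Adjusted_R2"] = {name: m.adj_r2_ for name, m in self.models_}
        order = sorted(self.counts_, key=lambda c: (-self.counts_[c], c))
        for col in order:
            rows[col] = {name: self.coefficients_[col].get(name, np.nan)
                         for name in model_names}
        out = pd.DataFrame.from_dict(rows, orient="index")[model_names]
        out["count"] = [np.nan, np.nan] + [self.counts_[c] for c in order]
        out["robust"] = [None, None] + [c in self.robust_set_ for c in order]
        return out


def robust_selection(X: pd.DataFrame, y, n_replicates: int = 10,
                     noise_low: float = 0.90, noise_high: float = 1.10,
                     seed: int = 0,
                     majority_threshold: float | None = None
                     ) -> RobustDescriptorSelector:
    return RobustDescriptorSelector(
        n_replicates=n_replicates, noise_low=noise_low,
        noise_high=noise_high, random_state=seed,
        majority_threshold=majority_threshold).fit(X, y)
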