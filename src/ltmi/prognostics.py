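"""Survival analysis: Kaplan-Meier, log-rank, cutpoint search, Cox fits.

Also carries the ordinal mast-cell infiltration categories used when a
pathologist scores tryptase-stained tissue cores: none (0 cells),
low (1-9), medium (10-30), high (>= 31).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

MAST_CELL_CATEGORIES = ("none", "low", "medium", "high")


def bin_mast_cell_counts(count: int) -> str:
    """Map a per-core mast-cell count to none/low/medium/high.

    Boundaries: 0 -> none, 1-9 -> low, 10-30 -> medium, >= 31 -> high
    (31 is assigned to "high" so the bins partition the nonnegative
    integers exactly).
    """
    if isinstance(count, bool) or not float(count).is_integer():
        raise ValueError(f"count must be a nonnegative integer, got {count!r}")
    count = int(count)
    if count < 0:
        raise ValueError(f"count must be nonnegative, got {count}")
    if count == 0:
        return "none"
    if count <= 9:
        return "low"
    if count <= 30:
        return "medium"
    return "high"


@dataclass
class SurvivalTable:
    """Per-subject time-to-event records with covariates.

    ``data`` needs columns ``time`` (> 0) and ``event`` (1 = event,
    0 = censored); any further columns are covariates or strata.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if not {"time", "event"}.issubset(self.data.columns):
            raise ValueError("survival table needs 'time' and 'event' columns")
        if (self.data["time"].to_numpy() <= 0).any():
            raise ValueError("survival times must be positive")
        if not self.data["event"].isin([0, 1]).all():
            raise ValueError("event flags must be 0 or 1")

    def __len__(self) -> int:
        return len(self.data)

    def write_tsv(self, path: str) -> None:
        self.data.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str) -> "SurvivalTable":
        return cls(pd.read_csv(path, sep="\t"))


def kaplan_meier(table: SurvivalTable, groups: pd.Series | None = None) -> dict[str, pd.DataFrame]:
    """Product-limit survival curve per group (right-censoring handled).

    Returns, per group label, a step-function frame with columns ``time``
    and ``survival`` (S(0) = 1 included as the first row).
    """
    df = table.data
    if groups is None:
        groups = pd.Series("all", index=df.index)
    groups = pd.Series(groups, index=df.index)
    out = {}
    for label, idx in groups.groupby(groups).groups.items():
        sub = df.loc[idx]
        if len(sub) == 0:
            raise ValueError(f"empty group {label!r}")
        km = KaplanMeierFitter()
        km.fit(sub["time"], sub["event"])
        sf = km.survival_function_
        out[label] = pd.DataFrame(
            {"time": sf.index.to_numpy(float), "survival": sf.iloc[:, 0].to_numpy(float)}
        ).reset_index(drop=True)
    return out


def _logrank_observed_expected(
    time: np.ndarray, event: np.ndarray, group_codes: np.ndarray, n_groups: int
):
    """Aggregated O, E and covariance of the log-rank statistic."""
    order = np.argsort(time, kind="stable")
    time, event, group_codes = time[order], event[order], group_codes[order]
    event_times = np.unique(time[event == 1])
    O = np.zeros(n_groups)
    E = np.zeros(n_groups)
    V = np.zeros((n_groups, n_groups))
    for t in event_times:
        at_risk = time >= t
        n_t = at_risk.sum()
        d_t = int(((time == t) & (event == 1)).sum())
        n_gt = np.bincount(group_codes[at_risk], minlength=n_groups).astype(float)
        d_gt = np.bincount(group_codes[(time == t) & (event == 1)], minlength=n_groups).astype(float)
        O += d_gt
        frac = n_gt / n_t
        E += d_t * frac
        if n_t > 1:
            mult = d_t * (n_t - d_t) / (n_t - 1.0)
            V += mult * (np.diag(frac) - np.outer(frac, frac))
    return O, E, V


def logrank_test(table: SurvivalTable, groups: pd.Series) -> tuple[float, int, float]:
    """Multi-group log-rank test; returns (chi2, df, p).

    Standard observed-minus-expected statistic with the aggregated-risk-set
    handling of tied event times; df = number of groups - 1.
    """
    df_ = table.data
    groups = pd.Series(groups, index=df_.index).astype(str)
    labels = sorted(groups.unique())
    if len(labels) < 2:
        raise ValueError("log-rank test needs at least two groups")
    if int(df_["event"].sum()) == 0:
        raise ValueError("log-rank test needs at least one event")
    codes = groups.map({lb: i for i, lb in enumerate(labels)}).to_numpy()
    O, E, V = _logrank_observed_expected(
        df_["time"].to_numpy(float), df_["event"].to_numpy(int), codes, len(labels)
    )
    k = len(labels)
    diff = (O - E)[: k - 1]
    Vsub = V[: k - 1, : k - 1]
    chi2 = float(diff @ np.linalg.pinv(Vsub) @ diff)
    dof = k - 1
    return chi2, dof, float(stats.chi2.sf(chi2, dof))


def optimal_cutpoint(
    table: SurvivalTable,
    covariate: str,
    quantile_range: tuple[float, float] = (0.10, 0.90),
) -> dict:
    """Scan candidate cutpoints of a continuous covariate for log-rank separation.

    Candidates are the unique covariate values within the inner quantile
    range; the returned cutpoint minimizes the (naive) log-rank p of the
    induced dichotomization.  The output always carries
    ``multiple_testing_caution=True`` and the number of cutpoints scanned:
    the minimal p over a scan is optimistically biased and must not be read
    as a calibrated significance level.
    """
    x = table.data[covariate].to_numpy(float)
    if len(np.unique(x)) < 2:
        raise ValueError(f"covariate {covariate!r} is constant")
    lo, hi = np.quantile(x, quantile_range)
    candidates = np.unique(x[(x >= lo) & (x <= hi)])
    # a cutpoint must leave both sides nonempty
    candidates = candidates[(candidates > x.min()) & (candidates <= x.max())]
    if len(candidates) == 0:
        candidates = np.unique(x)[1:]
    best = None
    for c in candidates:
        groups = pd.Series(np.where(x >= c, "high", "low"), index=table.data.index)
        try:
            chi2, _, p = logrank_test(table, groups)
        except ValueError:
            continue
        if best is None or p < best[1]:
            best = (float(c), float(p))
    if best is None:
        raise ValueError("no admissible cutpoint")
    return {
        "cutpoint": best[0],
        "logrank_p": best[1],
        "n_cutpoints_scanned": int(len(candidates)),
        "multiple_testing_caution": True,
    }


def cox_likelihood_ratio(
    table: SurvivalTable,
    covariate: str,
    max_iter: int = 50,
    tol: float = 1e-9,
) -> dict:
    """Single-covariate proportional-hazards fit with a likelihood-ratio test.

    Newton iteration on the Breslow partial likelihood.  Returns
    ``log_hr``, ``lr_statistic`` and ``p``.  Non-convergence (e.g. complete
    separation of events by the covariate) raises with diagnostics.
    """
    df_ = table.data
    if len(df_) < 10:
        raise ValueError("Cox fit needs at least 10 subjects")
    if int(df_["event"].sum()) < 2:
        raise ValueError("Cox fit needs at least 2 events")
    x = df_[covariate].to_numpy(float)
    time = df_["time"].to_numpy(float)
    event = df_["event"].to_numpy(int)
    if np.ptp(x) == 0:
        return {"log_hr": 0.0, "lr_statistic": 0.0, "p": 1.0, "n_iter": 0}
    xs = (x - x.mean()) / x.std()

    order = np.argsort(-time, kind="stable")  # descending: risk set = prefix
    t_sorted, x_sorted, e_sorted = time[order], xs[order], event[order]
    # risk set of an event at time t includes all subjects with time >= t
    risk_end = np.searchsorted(-t_sorted, -t_sorted, side="right")
    ev_idx = np.where(e_sorted == 1)[0]
    ev_end = risk_end[ev_idx]

    def loglik_parts(beta: float):
        eta = beta * x_sorted
        w = np.exp(eta)
        s0 = np.cumsum(w)
        s1 = np.cumsum(w * x_sorted)
        s2 = np.cumsum(w * x_sorted ** 2)
        S0, S1, S2 = s0[ev_end - 1], s1[ev_end - 1], s2[ev_end - 1]
        ll = float(np.sum(eta[ev_idx] - np.log(S0)))
        score = float(np.sum(x_sorted[ev_idx] - S1 / S0))
        info = float(np.sum(S2 / S0 - (S1 / S0) ** 2))
        return ll, score, info

    beta = 0.0
    ll0, _, _ = loglik_parts(0.0)
    converged = False
    for it in range(1, max_iter + 1):
        ll, score, info = loglik_parts(beta)
        if info <= 1e-12 or not np.isfinite(info):
            break
        step = score / info
        beta += step
        if abs(beta) > 50:
            break
        if abs(step) < tol:
            converged = True
            break
    if not converged:
        raise RuntimeError(
            f"Cox fit did not converge after {it} iterations "
            f"(beta={beta:.3g} on standardized covariate); the covariate may "
            "completely separate events from censored subjects"
        )
    ll_hat, _, info = loglik_parts(beta)
    lr = 2.0 * (ll_hat - ll0)
    return {
        "log_hr": float(beta / x.std()),  # back to the covariate's own units
        "lr_statistic": float(lr),
        "p": float(stats.chi2.sf(max(lr, 0.0), 1)),
        "n_iter": it,
    }
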