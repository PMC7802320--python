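"""Prognostic stratification from deletion carriers and recurrence-free survival.

Feature selection uses a linear ranking survival SVM: for every comparable
pair (i, j) — sample j recurred strictly before sample i's observed time —
the model is pushed to score i above j by a margin, via the convex
objective  ½‖w‖² + γ Σ max(0, 1 − w·(x_i − x_j)).  A large |coefficient|
marks a deletion informative for recurrence timing; the sign of the
deletion's univariate Cox log hazard ratio then splits the selected set
into recurrence-associated (log HR > 0) and non-recurrence-associated
groups.  Patients carrying more recurrence-associated than
non-recurrence-associated deletions form the poor-prognosis stratum G1;
everyone else is G2.  Separation is assessed with Kaplan–Meier curves and
the log-rank test.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize

logger = logging.getLogger(__name__)

RECURRENCE = "recurrence-associated"
NON_RECURRENCE = "non-recurrence-associated"


@dataclass
class SurvivalData:
    """Observed times (months), event indicators, binary carrier features."""

    time: np.ndarray
    event: np.ndarray
    X: pd.DataFrame  # samples x DSVs

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if (self.time < 0).any():
            raise ValueError("times must be non-negative")
        if not np.isin(self.event, [0, 1]).all():
            raise ValueError("event indicators must be 0/1")
        if len(self.X) != len(self.time):
            raise ValueError("feature matrix row count must match times")

    @classmethod
    def from_cohort(cls, carriers, cohort: pd.DataFrame) -> "SurvivalData":
        """Restrict to recurrence-evaluable samples of the cohort table."""
        meta = cohort.set_index("sample_id").loc[carriers.data.index]
        ok = meta["rfs_time"].notna() & meta["rfs_event"].notna()
        return cls(
            time=meta.loc[ok, "rfs_time"].to_numpy(),
            event=meta.loc[ok, "rfs_event"].to_numpy(dtype=int),
            X=carriers.data.loc[ok.to_numpy()],
        )


def _comparable_pairs(time: np.ndarray, event: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices (i, j) with t_j < t_i and sample j an observed event."""
    order_i, order_j = np.meshgrid(np.arange(len(time)), np.arange(len(time)), indexing="ij")
    mask = (time[order_j] < time[order_i]) & (event[order_j] == 1)
    return order_i[mask], order_j[mask]


@dataclass
class SurvivalSvmFit:
    coef: np.ndarray
    objective_path: list[float] = field(default_factory=list)
    n_pairs: int = 0

    @property
    def objective(self) -> float:
        return self.objective_path[-1]


def fit_survival_svm(data: SurvivalData, gamma: float = 1.0) -> SurvivalSvmFit:
    """Fit the linear ranking survival SVM by L-BFGS on the convex primal.

    ``w @ x`` is a survival-time score (higher = later predicted
    recurrence), so a deletion that accelerates recurrence gets a negative
    coefficient.  The recorded objective path is non-increasing (the line
    search only accepts decreasing iterates).
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    if data.event.sum() == 0:
        raise ValueError("no observed events")
    ii, jj = _comparable_pairs(data.time, data.event)
    if len(ii) < 2:
        raise ValueError("need at least 2 comparable pairs")
    X = data.X.to_numpy(dtype=float)
    D = X[ii] - X[jj]  # pairs x features

    def fun(w):
        margins = 1.0 - D @ w
        active = margins > 0
        f = 0.5 * w @ w + gamma * margins[active].sum()
        g = w - gamma * D[active].sum(axis=0)
        return f, g

    path: list[float] = []

    def cb(w):
        path.append(fun(w)[0])

    w0 = np.zeros(X.shape[1])
    path.append(fun(w0)[0])
    res = minimize(fun, w0, jac=True, method="L-BFGS-B", callback=cb,
                   options={"maxiter": 500})
    # keep the path monotone view honest: record the final accepted point
    if not path or res.fun <= path[-1]:
        path.append(float(res.fun))
    return SurvivalSvmFit(coef=res.x, objective_path=path, n_pairs=len(ii))


def rank_prognostic_dsvs(coef: np.ndarray, dsv_ids, k: int) -> list[str]:
    """Top-k DSVs by |coefficient|, ties broken by original column order."""
    dsv_ids = list(dsv_ids)
    if k > len(dsv_ids):
        raise ValueError(f"k = {k} exceeds number of DSVs ({len(dsv_ids)})")
    order = np.argsort(-np.abs(np.asarray(coef, dtype=float)), kind="stable")
    return [dsv_ids[i] for i in order[:k]]


def cox_univariate(x, data: SurvivalData) -> tuple[float, float, float]:
    """Univariate Cox proportional-hazards fit (Efron ties): (log HR, se, p).

    Monotone-likelihood / separation problems surface as lifelines
    convergence warnings; callers treating a DSV-level failure as soft
    should catch ``ConvergenceError``.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    x = np.asarray(x, dtype=float)
    if np.unique(x).size < 2:
        raise ValueError("constant covariate: Cox fit undefined")
    df = pd.DataFrame({"time": data.time, "event": data.event, "x": x})
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df, duration_col="time", event_col="event")
    beta = float(cph.params_["x"])
    se = float(cph.standard_errors_["x"])
    p = float(cph.summary.loc["x", "p"])
    return beta, se, p


def partition_by_hazard(ranked_ids, data: SurvivalData) -> pd.DataFrame:
    """Assign each selected DSV to a prognostic group by Cox log-HR sign.

    log HR > 0 -> recurrence-associated; <= 0 -> non-recurrence-associated
    (an exact zero ties to the better-prognosis side).  DSVs whose Cox fit
    fails are dropped with a warning.  Columns feed a volcano plot
    (log2 HR vs -log10 p) downstream.
    """
    from lifelines.exceptions import ConvergenceError

    if len(ranked_ids) == 0:
        raise ValueError("empty ranked DSV set")
    rows = []
    for rank, dsv in enumerate(ranked_ids):
        x = data.X[dsv].to_numpy(dtype=float)
        try:
            beta, se, p = cox_univariate(x, data)
        except (ValueError, ConvergenceError) as exc:
            warnings.warn(f"{dsv}: Cox fit failed ({exc}); dropped from partition")
            continue
        rows.append(
            {
                "dsv_id": dsv,
                "rank": rank,
                "log_hr": beta,
                "se": se,
                "p": p,
                "group": RECURRENCE if beta > 0 else NON_RECURRENCE,
                "carrier_freq": float(x.mean()),
            }
        )
    return pd.DataFrame(rows)


def stratify_patients(carriers, partition: pd.DataFrame) -> pd.DataFrame:
    """Count carried DSVs per prognostic group; G1 iff R > P (ties -> G2)."""
    if len(partition) == 0:
        raise ValueError("empty partition")
    rec = partition.loc[partition["group"] == RECURRENCE, "dsv_id"]
    non = partition.loc[partition["group"] == NON_RECURRENCE, "dsv_id"]
    R = carriers.data[list(rec)].sum(axis=1) if len(rec) else pd.Series(0, index=carriers.data.index)
    P = carriers.data[list(non)].sum(axis=1) if len(non) else pd.Series(0, index=carriers.data.index)
    return pd.DataFrame(
        {
            "sample_id": carriers.data.index,
            "n_recurrence_assoc": R.to_numpy(),
            "n_non_recurrence_assoc": P.to_numpy(),
            "group": np.where(R.to_numpy() > P.to_numpy(), "G1", "G2"),
        }
    )


def kaplan_meier(data: SurvivalData, groups) -> dict[str, pd.DataFrame]:
    """Product-limit survival curve per group: (time, survival, at-risk)."""
    from lifelines import KaplanMeierFitter

    groups = np.asarray(groups)
    if groups.shape[0] != len(data.time):
        raise ValueError("group labels must match sample count")
    out: dict[str, pd.DataFrame] = {}
    for g in pd.unique(groups):
        sel = groups == g
        kmf = KaplanMeierFitter()
        kmf.fit(data.time[sel], data.event[sel])
        sf = kmf.survival_function_
        out[str(g)] = pd.DataFrame(
            {"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()}
        )
    return out


def logrank_test(data: SurvivalData, groups) -> tuple[float, float]:
    """Two-group log-rank test: ((O-E)^2/V statistic, chi-square(1) p)."""
    from lifelines.statistics import logrank_test as ll_logrank

    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) != 2:
        raise ValueError(f"log-rank test needs exactly 2 groups, got {len(labels)}")
    if data.event.sum() == 0:
        return 0.0, 1.0
    a = groups == labels[0]
    res = ll_logrank(
        data.time[a], data.time[~a], data.event[a], data.event[~a]
    )
    return float(res.test_statistic), float(res.p_value)
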