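"""Case/control association statistics for deletion carriers.

All tests operate on 2x2 tables laid out rows = exposure (yes/no),
columns = group (e.g. cancer / non-cancer, or recurrence / non-recurrence):

             group A   group B
  exposed       a         b
  unexposed     c         d

The gene-level frequency spectrum collapses all deletions overlapping a gene
by logical OR before testing, odds-ratio confidence intervals are Woolf
(log-normal) with a Haldane–Anscombe 0.5 correction when a cell is empty,
and multiplicity is controlled by Benjamini–Hochberg within each analysis
family.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


def _as_table(t) -> np.ndarray:
    t = np.asarray(t, dtype=np.int64)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    if t.sum() == 0:
        raise ValueError("table total must be positive")
    return t


def fisher_exact_two_sided(table) -> float:
    """Two-sided Fisher exact p by the minimum-likelihood rule.

    Sums hypergeometric probabilities (margins fixed) of every table no more
    probable than the observed one.  An empty margin carries no information:
    p = 1 with a warning.
    """
    t = _as_table(table)
    if 0 in t.sum(axis=0) or 0 in t.sum(axis=1):
        warnings.warn("empty margin: Fisher test uninformative, p = 1")
        return 1.0
    return float(min(1.0, stats.fisher_exact(t, alternative="two-sided")[1]))


def yates_chi_square(table) -> tuple[float, float]:
    """Continuity-corrected chi-square for a 2x2 table.

    statistic = N * (max(|ad - bc| - N/2, 0))^2 / (r1 r2 c1 c2), with the
    correction clamped at zero, referred to the chi-square(1) upper tail.
    """
    t = _as_table(table).astype(float)
    (a, b), (c, d) = t
    n = t.sum()
    r1, r2 = t.sum(axis=1)
    c1, c2 = t.sum(axis=0)
    if 0 in (r1, r2, c1, c2):
        raise ValueError("chi-square undefined for a zero margin")
    stat = n * max(abs(a * d - b * c) - n / 2, 0.0) ** 2 / (r1 * r2 * c1 * c2)
    return float(stat), float(stats.chi2.sf(stat, df=1))


@dataclass
class OddsRatio:
    odds_ratio: float
    ci_low: float
    ci_high: float
    corrected: bool = False  # Haldane–Anscombe +0.5 applied


def odds_ratio_ci(table, level: float = 0.95) -> OddsRatio:
    """Cross-product odds ratio with a Woolf (log-normal) interval.

    Any zero cell triggers the Haldane–Anscombe +0.5 correction to all four
    cells (flagged in the result).  A zero diagonal in both directions
    (a = d = 0 or b = c = 0) leaves the odds ratio undefined.
    """
    t = _as_table(table).astype(float)
    (a, b), (c, d) = t
    if (a == 0 and d == 0) or (b == 0 and c == 0):
        raise ValueError("odds ratio undefined: zero cells in a cross pattern")
    corrected = 0 in (a, b, c, d)
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    orr = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(0.5 + level / 2)
    return OddsRatio(
        odds_ratio=float(orr),
        ci_low=float(np.exp(np.log(orr) - z * se)),
        ci_high=float(np.exp(np.log(orr) + z * se)),
        corrected=corrected,
    )


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _gene_exposure(carriers, gene_map: Mapping[str, Sequence[str]]) -> pd.DataFrame:
    """Sample x gene exposure: carries >= 1 DSV overlapping the gene."""
    gene_to_dsvs: dict[str, list[str]] = {}
    for dsv, genes in gene_map.items():
        if dsv not in carriers.data.columns:
            continue
        for g in genes:
            gene_to_dsvs.setdefault(g, []).append(dsv)
    cols = {
        g: carriers.data[dsvs].any(axis=1).astype(np.int8)
        for g, dsvs in sorted(gene_to_dsvs.items())
    }
    return pd.DataFrame(cols, index=carriers.data.index)


def _exposure_tests(
    exposure: pd.DataFrame, group: np.ndarray
) -> pd.DataFrame:
    """Per-column 2x2 tests of exposure vs a binary group indicator."""
    rows = []
    for name in exposure.columns:
        x = exposure[name].to_numpy(dtype=bool)
        a = int((x & group).sum())
        b = int((x & ~group).sum())
        c = int((~x & group).sum())
        d = int((~x & ~group).sum())
        if a + b == 0 or c + d == 0:
            logger.info("skipping %s: exposure constant across samples", name)
            continue
        orr = odds_ratio_ci([[a, b], [c, d]])
        p = fisher_exact_two_sided([[a, b], [c, d]])
        rows.append(
            {
                "unit": name,
                "a": a,
                "b": b,
                "c": c,
                "d": d,
                "odds_ratio": orr.odds_ratio,
                "ci_low": orr.ci_low,
                "ci_high": orr.ci_high,
                "p": p,
                "direction": "risk" if orr.odds_ratio > 1 else "protective",
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        df["p_adj"] = bh_adjust(df["p"].to_numpy())
    return df


def dsv_gene_spectrum(
    carriers, cohort: pd.DataFrame, gene_map: Mapping[str, Sequence[str]]
) -> pd.DataFrame:
    """Gene-level carrier-frequency spectrum vs cancer status.

    A sample is exposed to a gene iff it carries at least one DSV
    overlapping it.  Returns one row per testable gene with counts, odds
    ratio + Woolf CI, Fisher p and BH-adjusted p across genes.
    """
    exposure = _gene_exposure(carriers, gene_map)
    meta = cohort.set_index("sample_id").loc[exposure.index]
    group = (meta["cohort_label"] == "cancer").to_numpy()
    return _exposure_tests(exposure, group)


def top_k_by_direction(spectrum: pd.DataFrame, k: int = 10) -> dict[str, pd.DataFrame]:
    """Top-k risk (OR > 1) and protective (OR < 1) units by odds ratio."""
    risk = spectrum[spectrum["odds_ratio"] > 1].nlargest(k, "odds_ratio")
    protective = spectrum[spectrum["odds_ratio"] < 1].nsmallest(k, "odds_ratio")
    return {"risk": risk, "protective": protective}


@dataclass
class FchResult:
    table: np.ndarray
    odds_ratio: float
    ci_low: float
    ci_high: float
    p: float
    n_unknown: int


def fch_analysis(cohort: pd.DataFrame) -> FchResult:
    """Family-cancer-history x cancer-status 2x2 with OR, Woolf CI, Fisher p.

    Samples with unknown FCH are excluded (count reported).
    """
    known = cohort[cohort["fch"].isin(["yes", "no"])]
    n_unknown = len(cohort) - len(known)
    if len(known) == 0:
        raise ValueError("FCH unknown for every sample")
    fch = known["fch"] == "yes"
    cancer = known["cohort_label"] == "cancer"
    for grp in (True, False):
        if (cancer == grp).sum() < 2:
            raise ValueError("need FCH-known samples in both cohorts")
    t = np.array(
        [
            [int((fch & cancer).sum()), int((fch & ~cancer).sum())],
            [int((~fch & cancer).sum()), int((~fch & ~cancer).sum())],
        ]
    )
    orr = odds_ratio_ci(t)
    return FchResult(
        table=t,
        odds_ratio=orr.odds_ratio,
        ci_low=orr.ci_low,
        ci_high=orr.ci_high,
        p=fisher_exact_two_sided(t),
        n_unknown=n_unknown,
    )


def fch_stratified_dsv_tests(
    carriers,
    cohort: pd.DataFrame,
    gene_map: Mapping[str, Sequence[str]] | None = None,
    min_stratum: int = 5,
) -> dict[str, pd.DataFrame]:
    """Per-gene (or per-DSV) carrier x FCH tests within each cohort stratum.

    Returns ``{"cancer": ..., "non-cancer": ...}``; a stratum with fewer
    than ``min_stratum`` FCH-known samples on either side is skipped with a
    warning.  BH adjustment is applied within each stratum separately.
    """
    if gene_map is not None:
        exposure = _gene_exposure(carriers, gene_map)
    else:
        exposure = carriers.data
    meta = cohort.set_index("sample_id").loc[exposure.index]
    out: dict[str, pd.DataFrame] = {}
    for label in ("cancer", "non-cancer"):
        sel = (meta["cohort_label"] == label) & meta["fch"].isin(["yes", "no"])
        sub = exposure[sel.to_numpy()]
        fch = (meta.loc[sel.to_numpy(), "fch"] == "yes").to_numpy()
        if fch.sum() < min_stratum or (~fch).sum() < min_stratum:
            warnings.warn(f"stratum {label}: below minimum size, skipped")
            continue
        out[label] = _exposure_tests(sub, fch)
    return out


def characteristics_table(
    cohort: pd.DataFrame,
    covariates: Sequence[str],
    group_col: str = "recurrence",
    expected_min: float = 1.0,
) -> pd.DataFrame:
    """Cohort-characteristics table: per-covariate cross-tab vs a binary group.

    For a 2-level covariate the test is the continuity-corrected chi-square
    when every expected count is >= ``expected_min`` (default 1: the
    continuity correction keeps the chi-square usable well below the
    classical >= 5 rule of thumb) and Fisher's exact test otherwise; for
    more levels a plain chi-square is used.  The rule applied is recorded
    per row.  One-level covariates get no p-value.
    """
    sub = cohort[cohort[group_col].isin(["yes", "no"])]
    group = (sub[group_col] == "yes").to_numpy()
    rows = []
    for cov in covariates:
        ct = pd.crosstab(sub[cov], group)
        if ct.shape[1] < 2 or ct.shape[0] < 2:
            rows.append({"covariate": cov, "test": "none", "p": np.nan})
            continue
        obs = ct.to_numpy()
        expected = stats.contingency.expected_freq(obs)
        if obs.shape == (2, 2):
            if (expected >= expected_min).all():
                _, p = yates_chi_square(obs)
                test = "yates-chi-square"
            else:
                p = fisher_exact_two_sided(obs)
                test = "fisher-exact"
        else:
            _, p, _, _ = stats.chi2_contingency(obs, correction=False)
            test = "chi-square"
        logger.info("characteristic %s tested with %s", cov, test)
        counts = {
            f"{level}|{grp}": int(ct.loc[level, g])
            for level in ct.index
            for grp, g in (("group", True), ("rest", False))
        }
        rows.append({"covariate": cov, "test": test, "p": float(p), **counts})
    return pd.DataFrame(rows)
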