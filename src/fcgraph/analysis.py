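"""Group-level analysis: standardization, threshold averaging, the
interaction regression screen, age stratification, and DMN system
segregation.

The screening model, fitted separately per (scheme, region, metric) and
per cognitive test, is

    Score ~ Age + Sex + CHD + GraphMeasure + CHD x GraphMeasure

with ordinary least squares and a fixed two-sided significance threshold
of p < 0.001 on the interaction term (no multiplicity correction by
default, matching the screening design; an optional Benjamini-Hochberg
mode is provided as a clearly-labelled extension).

Graph measures are standardized across participants within each
(scheme, threshold, region, metric) cell before model fitting, then
averaged across the threshold sweep so each participant contributes one
summary value per region and metric.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .connectivity import ConnectivityMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "DMN_LABELS",
    "ParticipantRecord",
    "SegregationResult",
    "standardize_across_participants",
    "average_over_thresholds",
    "fit_interaction_model",
    "screen_significant",
    "stratify_by_age",
    "system_segregation",
    "fit_segregation_model",
]

#: AALv3 labels defining the Default Mode Network (14 regions): medial
#: prefrontal, posterior cingulate, angular gyri, precuneus, and the three
#: anterior-cingulate subdivisions, bilaterally.
DMN_LABELS = (
    "Frontal_Sup_Medial_L",
    "Frontal_Sup_Medial_R",
    "Cingulate_Post_L",
    "Cingulate_Post_R",
    "Angular_L",
    "Angular_R",
    "Precuneus_L",
    "Precuneus_R",
    "ACC_sub_L",
    "ACC_sub_R",
    "ACC_pre_L",
    "ACC_pre_R",
    "ACC_sup_L",
    "ACC_sup_R",
)

#: Columns identifying one standardization cell.
CELL_KEYS = ["scheme", "threshold", "region", "metric"]
#: Model terms in design-matrix order.
MODEL_TERMS = ["intercept", "age", "sex", "chd", "metric_value", "chd_x_metric"]


@dataclass
class ParticipantRecord:
    """Covariates and test scores for one participant.

    ``group`` is coded CHD=1, control=0; ``sex`` is a {0, 1} code
    (female=0 by default convention). Missing scores are allowed and
    handled complete-case per test.
    """

    participant_id: str
    group: int
    age_years: float
    sex: int
    scores: dict[str, float]


@dataclass
class SegregationResult:
    """Within/between-system mean connectivity and the segregation index."""

    participant_id: str
    z_within: float
    z_between: float
    segregation: float


def participants_frame(participants: list[ParticipantRecord]) -> pd.DataFrame:
    """Covariate table with one score column per test."""
    rows = []
    for p in participants:
        row = {
            "participant_id": p.participant_id,
            "chd": int(p.group),
            "age": float(p.age_years),
            "sex": int(p.sex),
        }
        row.update(p.scores)
        rows.append(row)
    return pd.DataFrame(rows)


def standardize_across_participants(table: pd.DataFrame) -> pd.DataFrame:
    """Z-score metric values across participants within each cell.

    A cell is one (scheme, threshold, region, metric) combination; the
    sample-SD (n-1) convention is used. Cells with zero variance are set
    entirely to missing with a warning so they drop out downstream rather
    than entering the regression as constants.
    """
    def _z(x: pd.Series) -> pd.Series:
        sd = x.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            return pd.Series(np.nan, index=x.index)
        return (x - x.mean()) / sd

    out = table.copy()
    grouped = out.groupby(CELL_KEYS, dropna=False)["value"]
    out["value"] = grouped.transform(_z)
    n_dropped = int(out["value"].isna().sum() - table["value"].isna().sum())
    if n_dropped > 0:
        logger.warning(
            "standardization set %d values to missing (zero-variance cells)",
            n_dropped,
        )
    return out


def average_over_thresholds(
    table: pd.DataFrame, min_coverage: float = 0.5
) -> pd.DataFrame:
    """Average standardized values per region/metric across the sweep.

    Missing thresholds are skipped; a participant's summary is kept only
    when more than ``min_coverage`` of that scheme's thresholds are
    present. The weighted scheme has a single (null) threshold and passes
    through unchanged.
    """
    n_thresh = (
        table.groupby("scheme")["threshold"].nunique(dropna=False).to_dict()
    )
    keys = ["participant_id", "scheme", "region", "metric"]
    grouped = table.groupby(keys, dropna=False)["value"]
    out = grouped.mean().rename("value").reset_index()  # skips missing
    n_present = grouped.count().to_numpy()
    total = out["scheme"].map(n_thresh).to_numpy()
    insufficient = (total > 1) & (n_present <= min_coverage * total)
    out.loc[insufficient, "value"] = np.nan
    return out


def _ols(y: np.ndarray, x: np.ndarray):
    model = sm.OLS(y, x)
    return model.fit()


def fit_interaction_model(
    summary: pd.DataFrame,
    participants: list[ParticipantRecord] | pd.DataFrame,
    test: str,
    min_cases: int = 10,
) -> pd.DataFrame:
    """Fit Score ~ Age + Sex + CHD + GraphMeasure + CHD x GraphMeasure.

    One OLS fit per (scheme, region, metric) cell of the summary table,
    complete-case on the given test's score and the metric value. Returns
    a tidy result table with a coefficient and two-sided p-value per term,
    ``n_used``, a ``significant`` flag (interaction p < 0.001), and an
    ``unestimable`` flag for rank-deficient designs.
    """
    pf = (
        participants
        if isinstance(participants, pd.DataFrame)
        else participants_frame(participants)
    )
    if test not in pf.columns:
        raise KeyError(f"test {test!r} not present in participant table")
    merged = summary.merge(
        pf[["participant_id", "age", "sex", "chd", test]], on="participant_id"
    )
    rows = []
    for (scheme, region, metric), cell in merged.groupby(
        ["scheme", "region", "metric"], dropna=False
    ):
        cc = cell.dropna(subset=["value", test])
        n_used = len(cc)
        rec: dict[str, object] = {
            "test": test,
            "scheme": scheme,
            "region": region,
            "metric": metric,
            "n_used": n_used,
            "unestimable": False,
        }
        if n_used < min_cases:
            rec["unestimable"] = True
            rec["significant"] = False
            rows.append(rec)
            continue
        x = np.column_stack(
            [
                np.ones(n_used),
                cc["age"].to_numpy(float),
                cc["sex"].to_numpy(float),
                cc["chd"].to_numpy(float),
                cc["value"].to_numpy(float),
                cc["chd"].to_numpy(float) * cc["value"].to_numpy(float),
            ]
        )
        if np.linalg.matrix_rank(x) < x.shape[1]:
            rec["unestimable"] = True
            rec["significant"] = False
            rows.append(rec)
            continue
        fit = _ols(cc[test].to_numpy(float), x)
        for term, coef, se, p in zip(MODEL_TERMS, fit.params, fit.bse, fit.pvalues):
            rec[f"coef_{term}"] = coef
            rec[f"se_{term}"] = se
            rec[f"p_{term}"] = p
        rec["significant"] = bool(rec["p_chd_x_metric"] < 0.001)
        rows.append(rec)
    return pd.DataFrame(rows)


def screen_significant(
    results: pd.DataFrame, alpha: float = 0.001, fdr: bool = False
) -> pd.DataFrame:
    """Rows whose interaction term passes the screen, sorted by p-value.

    The default is the fixed uncorrected threshold (strict ``p < alpha``).
    ``fdr=True`` switches to a Benjamini-Hochberg screen at level alpha —
    an optional extension, off by default.
    """
    if results.empty or "p_chd_x_metric" not in results.columns:
        return results.iloc[0:0]
    estimable = results[~results["unestimable"].astype(bool)].copy()
    estimable = estimable.dropna(subset=["p_chd_x_metric"])
    if fdr:
        keep, *_ = multipletests(
            estimable["p_chd_x_metric"], alpha=alpha, method="fdr_bh"
        )
        hits = estimable[keep]
    else:
        hits = estimable[estimable["p_chd_x_metric"] < alpha]
    return hits.sort_values("p_chd_x_metric").reset_index(drop=True)


def stratify_by_age(
    participants: list[ParticipantRecord],
    bins: list[tuple[float, float]] = ((8, 11), (12, math.inf)),
) -> dict[str, list[ParticipantRecord]]:
    """Split the cohort into age strata by floor of age in years.

    A participant belongs to bin (lo, hi) iff lo <= floor(age) <= hi.
    Participants outside all bins are excluded with a log entry; bins may
    not overlap.
    """
    bins = [tuple(b) for b in bins]
    for i, (lo1, hi1) in enumerate(bins):
        for lo2, hi2 in bins[i + 1 :]:
            if max(lo1, lo2) <= min(hi1, hi2):
                raise ValueError(f"overlapping age bins {bins}")
    out: dict[str, list[ParticipantRecord]] = {
        _bin_name(lo, hi): [] for lo, hi in bins
    }
    n_excluded = 0
    for p in participants:
        fl = math.floor(p.age_years)
        for lo, hi in bins:
            if lo <= fl <= hi:
                out[_bin_name(lo, hi)].append(p)
                break
        else:
            n_excluded += 1
    if n_excluded:
        logger.info("age stratification excluded %d participant(s)", n_excluded)
    return out


def _bin_name(lo: float, hi: float) -> str:
    return f"{lo:g}-{hi:g}" if math.isfinite(hi) else f"{lo:g}+"


def system_segregation(
    cm: ConnectivityMatrix,
    system_labels: tuple[str, ...] = DMN_LABELS,
    participant_id: str = "",
) -> SegregationResult:
    """System segregation of one subnetwork within a connectivity matrix.

    segregation = (Zw - Zb) / Zw where Zw is the mean connectivity over
    unordered within-system pairs and Zb the mean over system-external
    pairs. Undefined (NaN, with warning) when Zw = 0.
    """
    labels = list(cm.region_labels)
    missing = [s for s in system_labels if s not in labels]
    if missing:
        raise ValueError(f"system labels not in parcellation: {missing}")
    idx = np.array([labels.index(s) for s in system_labels])
    if idx.size < 2:
        raise ValueError("need at least 2 system regions")
    ext = np.array([i for i in range(cm.n_regions) if i not in set(idx.tolist())])
    if ext.size < 1:
        raise ValueError("need at least 1 external region")
    sub = cm.values[np.ix_(idx, idx)]
    iu = np.triu_indices(idx.size, 1)
    z_within = float(sub[iu].mean())
    z_between = float(cm.values[np.ix_(idx, ext)].mean())
    if z_within == 0:
        logger.warning("system segregation undefined: zero within-system mean")
        seg = float("nan")
    else:
        seg = (z_within - z_between) / z_within
    return SegregationResult(
        participant_id=participant_id,
        z_within=z_within,
        z_between=z_between,
        segregation=seg,
    )


def fit_segregation_model(
    segregation: pd.DataFrame | list[SegregationResult],
    participants: list[ParticipantRecord] | pd.DataFrame,
    min_cases: int = 10,
) -> pd.DataFrame:
    """Fit SystemSegregation ~ Age + Sex + CHD by OLS.

    Returns a one-row table with coefficients and two-sided p-values for
    the intercept, age, sex, and CHD terms, plus ``n_used``.
    """
    if not isinstance(segregation, pd.DataFrame):
        segregation = pd.DataFrame(
            {
                "participant_id": [s.participant_id for s in segregation],
                "segregation": [s.segregation for s in segregation],
            }
        )
    pf = (
        participants
        if isinstance(participants, pd.DataFrame)
        else participants_frame(participants)
    )
    merged = segregation.merge(
        pf[["participant_id", "age", "sex", "chd"]], on="participant_id"
    ).dropna(subset=["segregation"])
    n_used = len(merged)
    if n_used < min_cases:
        raise ValueError(f"only {n_used} complete cases (< {min_cases})")
    x = np.column_stack(
        [
            np.ones(n_used),
            merged["age"].to_numpy(float),
            merged["sex"].to_numpy(float),
            merged["chd"].to_numpy(float),
        ]
    )
    if np.linalg.matrix_rank(x) < x.shape[1]:
        return pd.DataFrame(
            [{"n_used": n_used, "unestimable": True}]
        )
    fit = _ols(merged["segregation"].to_numpy(float), x)
    rec: dict[str, object] = {"n_used": n_used, "unestimable": False}
    terms = ["intercept", "age", "sex", "chd"]
    for term, coef, se, p in zip(terms, fit.params, fit.bse, fit.pvalues):
        rec[f"coef_{term}"] = coef
        rec[f"se_{term}"] = se
        rec[f"p_{term}"] = p
    return pd.DataFrame([rec])
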