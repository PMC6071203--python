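"""Component-wise group inference on ICA subject weights.

Nine analysis families mirror the study design: a paired task effect on
centrality (one-sample t on task-minus-rest weight differences), age
effects on task and rest weights, a task-by-age interaction (age effect on
the difference score), behavioral associations (hit rate, false alarms,
d-prime as predictors of the difference score, adjusting for age and sex),
the task effect on activation contrasts, and the age effect on activation.
Benjamini-Hochberg FDR is applied per family by default (one family per
statistic across components) or globally across all tests.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .decomposition import Decomposition
from .ecm import REST, TASK
from .errors import CollinearityError, DataError, DimensionError, ZeroVarianceError

logger = logging.getLogger(__name__)

FAMILIES = (
    "task_effect",
    "age_task",
    "age_rest",
    "interaction",
    "perf_hit",
    "perf_fp",
    "perf_dprime",
    "activation_task",
    "activation_age",
)


def compute_difference_scores(dec: Decomposition) -> pd.DataFrame:
    """Task-minus-rest subject weight per subject per retained component.

    Subjects lacking either run are listed in a warning and dropped.
    Returns a DataFrame indexed by subject_id with one column per retained
    component index.
    """
    meta = dec.meta
    idx = dec.retained_indices
    task_rows = {
        sid: r for r, (sid, cond) in enumerate(zip(meta.subject_id, meta.condition))
        if cond == TASK
    }
    rest_rows = {
        sid: r for r, (sid, cond) in enumerate(zip(meta.subject_id, meta.condition))
        if cond == REST
    }
    paired = [sid for sid in meta.subject_id.unique() if sid in task_rows and sid in rest_rows]
    unpaired = [sid for sid in meta.subject_id.unique() if sid not in paired]
    if unpaired:
        logger.warning("dropping unpaired subject(s): %s", ", ".join(unpaired))
    if not paired:
        raise DataError("no subject has both a task and a rest run")
    rows = np.array(
        [dec.weights[task_rows[s], idx] - dec.weights[rest_rows[s], idx] for s in paired]
    )
    return pd.DataFrame(rows, index=pd.Index(paired, name="subject_id"), columns=idx)


def task_effect_test(diff: pd.DataFrame) -> pd.DataFrame:
    """One-sample t test of the difference scores against zero, per component."""
    n = len(diff)
    if n < 3:
        raise DataError(f"need at least 3 paired subjects, got {n}")
    records = []
    for comp in diff.columns:
        x = diff[comp].to_numpy(dtype=float)
        sd = x.std(ddof=1)
        if sd == 0:
            raise ZeroVarianceError(f"component {comp} has zero difference variance")
        t = x.mean() / (sd / np.sqrt(n))
        p = 2 * scipy.stats.t.sf(abs(t), df=n - 1)
        records.append(
            {"component": comp, "estimate": x.mean(), "t": t, "p": p, "n": n}
        )
    return pd.DataFrame(records)


def weight_regression(
    response: pd.Series,
    covariates: pd.DataFrame,
    predictor_of_interest: str,
) -> dict:
    """OLS of a per-subject response on covariates, with intercept.

    Returns the estimate, t, two-tailed p, and n for the predictor of
    interest.  Covariates must be complete and non-collinear.
    """
    if predictor_of_interest not in covariates.columns:
        raise DataError(f"predictor {predictor_of_interest!r} not among covariates")
    merged = pd.concat([response.rename("__y__"), covariates], axis=1, join="inner")
    if merged.isna().any().any():
        raise DataError("missing values in response or covariates")
    y = merged["__y__"].to_numpy(dtype=float)
    X = sm.add_constant(merged[covariates.columns].to_numpy(dtype=float))
    if len(y) <= X.shape[1]:
        raise DataError("fewer observations than parameters")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise CollinearityError("collinear covariates in regression")
    fit = sm.OLS(y, X).fit()
    j = 1 + list(covariates.columns).index(predictor_of_interest)
    return {
        "estimate": float(fit.params[j]),
        "t": float(fit.tvalues[j]),
        "p": float(fit.pvalues[j]),
        "n": int(len(y)),
    }


def bh_fdr(pvals: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: monotone q-values and significance flags."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        raise DataError("empty p-value vector")
    if np.any(~np.isfinite(pvals)) or np.any((pvals < 0) | (pvals > 1)):
        raise DataError("p-values must be finite and in [0, 1]")
    _, qvals, _, _ = multipletests(pvals, alpha=q, method="fdr_bh")
    return qvals, qvals <= q


def build_stat_table(
    dec: Decomposition,
    diff: pd.DataFrame,
    subject_table: pd.DataFrame,
    activation: pd.DataFrame | None = None,
    behavior: pd.DataFrame | None = None,
    q: float = 0.05,
    fdr_scope: str = "per_family",
) -> pd.DataFrame:
    """Assemble the full per-component statistics table across families.

    ``subject_table`` must carry ``subject_id``, ``age``, ``sex``;
    ``activation`` (optional) is a subject-by-component table of task
    contrasts; ``behavior`` (optional) carries ``hit_rate``, ``fp_rate``,
    ``dprime`` per subject.  FDR correction is applied per family
    (default) or globally (``fdr_scope='global'``).
    """
    if fdr_scope not in ("per_family", "global"):
        raise DataError(f"unknown fdr_scope {fdr_scope!r}")
    covars = subject_table.set_index("subject_id")[["age", "sex"]]
    idx = dec.retained_indices
    meta = dec.meta

    def weights_frame(condition: str) -> pd.DataFrame:
        rows = meta.index[meta.condition == condition]
        return pd.DataFrame(
            dec.weights[np.ix_(rows, idx)],
            index=pd.Index(meta.subject_id[rows], name="subject_id"),
            columns=idx,
        )

    records = []

    for row in task_effect_test(diff).itertuples():
        records.append(
            {"component": row.component, "family": "task_effect",
             "estimate": row.estimate, "t": row.t, "p": row.p, "n": row.n}
        )

    for family, frame in (("age_task", weights_frame(TASK)),
                          ("age_rest", weights_frame(REST)),
                          ("interaction", diff)):
        for comp in frame.columns:
            res = weight_regression(frame[comp], covars.loc[frame.index], "age")
            records.append({"component": comp, "family": family, **res})

    if behavior is not None:
        perf = behavior.set_index("subject_id") if "subject_id" in behavior else behavior
        for family, col in (("perf_hit", "hit_rate"),
                            ("perf_fp", "fp_rate"),
                            ("perf_dprime", "dprime")):
            cov = pd.concat([perf[[col]], covars], axis=1, join="inner")
            for comp in diff.columns:
                res = weight_regression(diff[comp], cov.loc[diff.index], col)
                records.append({"component": comp, "family": family, **res})

    if activation is not None:
        n_act = len(activation)
        for comp in activation.columns:
            x = activation[comp].to_numpy(dtype=float)
            sd = x.std(ddof=1)
            if sd == 0:
                raise ZeroVarianceError(f"component {comp} has zero activation variance")
            t = x.mean() / (sd / np.sqrt(n_act))
            p = 2 * scipy.stats.t.sf(abs(t), df=n_act - 1)
            records.append(
                {"component": comp, "family": "activation_task",
                 "estimate": x.mean(), "t": t, "p": p, "n": n_act}
            )
        for comp in activation.columns:
            res = weight_regression(
                activation[comp], covars.loc[activation.index], "age"
            )
            records.append({"component": comp, "family": "activation_age", **res})

    table = pd.DataFrame(records)
    table["q"] = np.nan
    if fdr_scope == "global":
        table["q"], flags = bh_fdr(table["p"].to_numpy(), q=q)
        table["significant"] = flags
    else:
        table["significant"] = False
        for family in table["family"].unique():
            rows = table.index[table["family"] == family]
            qvals, flags = bh_fdr(table.loc[rows, "p"].to_numpy(), q=q)
            table.loc[rows, "q"] = qvals
            table.loc[rows, "significant"] = flags
    return table


def ec_activation_correlation(
    stat_table: pd.DataFrame, statistic: str = "t"
) -> tuple[float, float, int]:
    """Correlation across components of EC task effects and activation effects.

    By default uses the group t statistics of both families, which are
    invariant to ICA scale ambiguity; ``statistic='estimate'`` selects the
    group means instead.  Returns (Pearson r, two-tailed p, n components).
    """
    ec = stat_table[stat_table.family == "task_effect"].set_index("component")[statistic]
    act = stat_table[stat_table.family == "activation_task"].set_index("component")[statistic]
    common = ec.index.intersection(act.index)
    if len(common) < 3:
        raise DimensionError("need at least 3 components for the correlation")
    r, p = scipy.stats.pearsonr(ec.loc[common], act.loc[common])
    return float(r), float(p), int(len(common))
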