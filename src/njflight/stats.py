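"""Season-by-region group comparisons and paired seasonal tests.

Flight-level responses (level fraction, mean vertical speed, tortuosity,
ascent maxima ...) are compared across season x region strata with a
linear mixed model — season and region as categorical fixed effects and a
per-bird random intercept, since episodes of the same individual are not
independent — followed by Tukey-HSD-adjusted pairwise contrasts displayed
as compact letters (groups sharing a letter do not differ). Degenerate
designs (one bird, or zero residual variance) fall back gracefully rather
than crash.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)


@dataclass
class GroupEstimate:
    group: str
    estimate: float
    ci_low: float
    ci_high: float
    letter: str
    n: int


@dataclass
class GroupComparison:
    response: str
    groups: list[GroupEstimate]
    model: str  # "lmm" | "ols" | "degenerate"
    pairwise: pd.DataFrame  # columns: group1, group2, diff, p
    alpha: float = 0.05

    def letters(self) -> dict[str, str]:
        return {g.group: g.letter for g in self.groups}


@dataclass
class PairedTestResult:
    statistic: float
    df: int
    p_value: float
    n_pairs: int
    degenerate: bool = False


def significance_letters(
    names: list[str], different: np.ndarray
) -> dict[str, str]:
    """Compact letter display from a boolean 'significantly different' matrix.

    Insert-and-absorb: start from one all-inclusive letter and sever each
    significantly different pair, so two groups share a letter iff they
    are not significantly different. ``different`` must be symmetric with
    a False diagonal.
    """
    k = len(names)
    letter_sets: list[set[int]] = [set(range(k))]
    for i in range(k):
        for j in range(i + 1, k):
            if not different[i, j]:
                continue
            for s in [s for s in letter_sets if i in s and j in s]:
                letter_sets.remove(s)
                letter_sets.append(s - {i})
                letter_sets.append(s - {j})
    letter_sets = [s for s in letter_sets if s]
    # absorb duplicates and subsets
    unique: list[set[int]] = []
    for s in sorted(letter_sets, key=len, reverse=True):
        if not any(s <= t for t in unique):
            unique.append(s)
    unique.sort(key=lambda s: (min(s), sorted(s)))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {name: "" for name in names}
    for pos, s in enumerate(unique):
        for i in sorted(s):
            out[names[i]] += alphabet[pos % len(alphabet)]
    return out


def compare_groups(
    metrics: pd.DataFrame,
    response: str,
    group_cols: tuple[str, str] = ("season", "region"),
    bird_col: str = "bird_id",
    alpha: float = 0.05,
) -> GroupComparison:
    """Fit the mixed model and report Tukey-lettered group means.

    ``metrics`` needs one row per flight with the response, the grouping
    columns and the bird identifier. Groups are the observed season x
    region cells. With a single bird the random intercept is dropped (OLS)
    with a logged warning; a response with no variance yields the
    degenerate "no differences" comparison.
    """
    import statsmodels.formula.api as smf

    data = metrics.dropna(subset=[response]).copy()
    data["_group"] = (
        data[group_cols[0]].astype(str) + ":" + data[group_cols[1]].astype(str)
    )
    counts = data.groupby("_group").size()
    if (counts == 0).any() or len(counts) < 2:
        raise ValueError(
            f"need at least two non-empty groups, got {counts.to_dict()}"
        )
    names = list(counts.index)
    k = len(names)
    n_birds = data[bird_col].nunique()
    y = data[response].to_numpy(dtype=float)

    if np.ptp(y) == 0.0:
        est = [
            GroupEstimate(g, float(y[0]), float(y[0]), float(y[0]), "a", int(counts[g]))
            for g in names
        ]
        pairs = _pairs_frame(names, np.zeros((k, k)), np.ones((k, k)))
        return GroupComparison(response, est, "degenerate", pairs, alpha)

    formula = f"{response} ~ 0 + C(_group)"
    fit = None
    model_kind = ""
    if n_birds >= 2:
        spread = float(np.ptp(y))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(formula, data, groups=data[bird_col])
            for method in ("powell", None):
                try:
                    cand = (
                        model.fit(reml=True, method=method)
                        if method
                        else model.fit(reml=True)
                    )
                except Exception:
                    continue
                se_cand = np.sqrt(np.diag(cand.cov_params()))[: k]
                if np.all(np.isfinite(se_cand)) and np.max(se_cand) < 10 * (
                    spread + 1e-9
                ):
                    fit = cand
                    break
    if fit is not None:
        model_kind = "lmm"
        params = fit.fe_params
        cov = fit.cov_params().iloc[: len(params), : len(params)]
        resid_df = max(len(data) - k - 1, 1)
    else:
        if n_birds >= 2:
            logger.warning(
                "compare_groups(%s): mixed model unstable, using fixed effects",
                response,
            )
        if n_birds < 2:
            logger.warning(
                "compare_groups(%s): single bird, falling back to fixed effects",
                response,
            )
        fit = smf.ols(formula, data).fit()
        model_kind = "ols"
        params = fit.params
        cov = fit.cov_params()
        resid_df = int(fit.df_resid) if fit.df_resid > 0 else 1
    order = [f"C(_group)[{g}]" for g in names]
    mu = np.array([params[o] for o in order])
    vcov = np.array([[cov.loc[a, b] for b in order] for a in order])
    se = np.sqrt(np.diag(vcov))
    tcrit = sps.t.ppf(1 - alpha / 2, resid_df)

    diffs = np.zeros((k, k))
    pvals = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            d = mu[i] - mu[j]
            sed = np.sqrt(vcov[i, i] + vcov[j, j] - 2 * vcov[i, j])
            if sed == 0:
                p = 1.0 if d == 0 else 0.0
            else:
                q = abs(d) * np.sqrt(2.0) / sed
                p = float(sps.studentized_range.sf(q, k, resid_df))
            diffs[i, j] = diffs[j, i] = d
            pvals[i, j] = pvals[j, i] = p
    different = pvals < alpha
    np.fill_diagonal(different, False)
    letters = significance_letters(names, different)
    estimates = [
        GroupEstimate(
            group=g,
            estimate=float(mu[i]),
            ci_low=float(mu[i] - tcrit * se[i]),
            ci_high=float(mu[i] + tcrit * se[i]),
            letter=letters[g],
            n=int(counts[g]),
        )
        for i, g in enumerate(names)
    ]
    return GroupComparison(
        response, estimates, model_kind, _pairs_frame(names, diffs, pvals), alpha
    )


def _pairs_frame(names: list[str], diffs: np.ndarray, pvals: np.ndarray) -> pd.DataFrame:
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            rows.append(
                {
                    "group1": names[i],
                    "group2": names[j],
                    "diff": diffs[i, j],
                    "p": pvals[i, j],
                }
            )
    return pd.DataFrame(rows)


def paired_seasonal_test(per_bird: pd.DataFrame) -> PairedTestResult:
    """Two-sided paired t-test on per-bird seasonal values.

    ``per_bird`` needs columns bird_id, season ("spring"/"autumn") and
    value; birds lacking either season are dropped. The statistic is on
    spring minus autumn with n_birds - 1 degrees of freedom. A non-zero
    constant difference (zero variance) is reported as an infinite
    statistic with p = 0 and flagged degenerate rather than NaN.
    """
    wide = per_bird.pivot_table(
        index="bird_id", columns="season", values="value", aggfunc="mean"
    )
    if "spring" not in wide or "autumn" not in wide:
        raise ValueError("need both seasons")
    wide = wide.dropna(subset=["spring", "autumn"])
    n = len(wide)
    if n < 2:
        raise ValueError("need at least two birds with both seasons")
    d = (wide["spring"] - wide["autumn"]).to_numpy()
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d.mean(), 0.0):
            return PairedTestResult(0.0, n - 1, 1.0, n)
        return PairedTestResult(
            float(np.inf) * np.sign(d.mean()), n - 1, 0.0, n, degenerate=True
        )
    t, p = sps.ttest_rel(wide["spring"], wide["autumn"])
    return PairedTestResult(float(t), n - 1, float(p), n)
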