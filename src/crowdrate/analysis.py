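"""Analytical pipeline for sequential-rating experiments.

The stages mirror how such an experiment is analysed:

1. estimate per-message difficulties from the independent condition
   (decisions there are iid, so simple pooled fractions suffice);
2. select the messages in scope for each hypothesis by thresholding the
   estimated difficulties at 0.5;
3. compare conditions via group-level fraction-correct and two-sided
   randomization (permutation) tests;
4. summarise cascade dynamics with trailing moving averages of accuracy by
   sequence position and logistic position-trend regressions with
   group-clustered standard errors;
5. propagate the statistical uncertainty of the difficulty estimates with a
   nonparametric bootstrap and report how stable each message's
   hypothesis-scope classification is.

Difficulty here is the probability of an *incorrect* independent decision,
so ``d_hat`` is the fraction of incorrect decisions. Estimates use pooled
fractions rather than sequence-level aggregation because independent
decisions are exchangeable.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import InvalidParameterError, MissingDataError

HYPOTHESES = ("H1", "H2", "H3", "H4", "H5")

#: Relative tolerance for |ATE*| >= |ATE| comparisons; keeps the count
#: invariant under affine rescaling of the group fractions.
_REL_TOL = 1e-12


@dataclass(frozen=True)
class TestResult:
    """A group-level randomization test of an average treatment effect.

    ``ate`` is the difference in group-mean fraction correct between the
    two arms, in percentage points (arm A minus arm B).
    """

    label: str
    ate: float
    p_value: float
    n_groups: int
    n_permutations: int
    method: str  # "exhaustive" or "monte_carlo"
    seed: int | None = None


@dataclass(frozen=True)
class TrendResult:
    """Logistic slope of correctness on sequence position for one stratum."""

    stratum: str
    beta: float | None
    se: float | None
    p_value: float | None
    n_decisions: int
    flag: str | None = None  # "degenerate" or "separation" when suppressed


def _with_alignment(decisions: pd.DataFrame) -> pd.DataFrame:
    out = decisions.copy()
    out["aligned"] = out["ideology"] == out["lean"]
    return out


def estimate_difficulty(decisions: pd.DataFrame) -> pd.DataFrame:
    """Per-message difficulty estimates from independent-condition records.

    Returns one row per message with ``d_bar_hat`` (fraction of incorrect
    decisions over all independent decisions) and ``d_align_hat`` (the same
    fraction among raters aligned with the message lean), plus the decision
    counts behind each estimate.

    Raises :class:`MissingDataError` if any message in the table has no
    independent decisions, or no aligned independent decisions.
    """
    ind = _with_alignment(decisions[decisions["condition"] == "independent"])
    all_messages = decisions["message_id"].unique()
    missing = set(all_messages) - set(ind["message_id"].unique())
    if missing:
        raise MissingDataError(
            f"no independent-condition decisions for messages: {sorted(missing)}"
        )
    rows = []
    for mid, sub in ind.groupby("message_id", sort=False):
        aligned = sub[sub["aligned"]]
        if len(aligned) == 0:
            raise MissingDataError(
                f"no aligned independent-condition decisions for message {mid!r}"
            )
        rows.append(
            {
                "message_id": mid,
                "veracity": int(sub["veracity"].iloc[0]),
                "lean": sub["lean"].iloc[0],
                "d_bar_hat": 1.0 - sub["correct"].mean(),
                "d_align_hat": 1.0 - aligned["correct"].mean(),
                "n_decisions": len(sub),
                "n_aligned_decisions": len(aligned),
            }
        )
    return pd.DataFrame(rows).set_index("message_id")


def select_messages(estimates: pd.DataFrame, hypothesis: str) -> list[str]:
    """Messages in scope for a hypothesis, by estimated-difficulty filters.

    All hypotheses require ``d_bar_hat < 0.5`` (the average decision maker
    must beat chance). H2/H4 additionally restrict to true messages with
    ``d_align_hat < 0.5``; H3/H5 to false messages with
    ``d_align_hat > 0.5``. Ties at 0.5 are excluded (strict inequalities).
    An empty selection triggers a warning, not an error.
    """
    if hypothesis not in HYPOTHESES:
        raise InvalidParameterError(
            f"unknown hypothesis {hypothesis!r}; expected one of {HYPOTHESES}"
        )
    mask = estimates["d_bar_hat"] < 0.5
    if hypothesis in ("H2", "H4"):
        mask &= (estimates["veracity"] == 1) & (estimates["d_align_hat"] < 0.5)
    elif hypothesis in ("H3", "H5"):
        mask &= (estimates["veracity"] == -1) & (estimates["d_align_hat"] > 0.5)
    selected = list(estimates.index[mask])
    if not selected:
        warnings.warn(
            f"no messages fall in the scope of {hypothesis}", stacklevel=2
        )
    return selected


def group_fraction_correct(
    decisions: pd.DataFrame, message_ids: list[str] | None = None
) -> pd.Series:
    """Per-group fraction of correct decisions on a message subset."""
    sub = (
        decisions
        if message_ids is None
        else decisions[decisions["message_id"].isin(message_ids)]
    )
    if len(sub) == 0:
        raise MissingDataError("no decisions left after message selection")
    return sub.groupby("group_id")["correct"].mean()


def randomization_test(
    fractions_a: pd.Series | np.ndarray,
    fractions_b: pd.Series | np.ndarray,
    n_permutations: int = 100_000,
    seed: int | None = None,
    label: str = "A_vs_B",
    method: str = "auto",
) -> TestResult:
    """Two-sided randomization test of the group-level ATE.

    The observed ATE is ``mean(A) - mean(B)`` (reported in percentage
    points); the null distribution re-randomizes arm labels over the pooled
    group fractions, preserving arm sizes, and the p-value counts
    relabelings with ``|ATE*| >= |ATE|``.

    ``method="exhaustive"`` enumerates all C(n_A+n_B, n_A) assignments and
    returns the exact p (count / total). ``"monte_carlo"`` samples
    ``n_permutations`` random relabelings and applies the add-one
    convention ``p = (1 + count) / (1 + n_permutations)``, which keeps p
    strictly positive. ``"auto"`` enumerates whenever the assignment count
    does not exceed ``n_permutations``.
    """
    a = np.asarray(fractions_a, dtype=float)
    b = np.asarray(fractions_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InvalidParameterError("both arms must be nonempty")
    if n_permutations < 1:
        raise InvalidParameterError("n_permutations must be >= 1")
    if method not in ("auto", "exhaustive", "monte_carlo"):
        raise InvalidParameterError(f"unknown method {method!r}")
    pooled = np.concatenate([a, b])
    n_a, n_total = a.size, pooled.size
    observed = a.mean() - b.mean()
    threshold = abs(observed) * (1.0 - _REL_TOL)

    n_exhaustive = comb(n_total, n_a)
    if method == "auto":
        method = "exhaustive" if n_exhaustive <= n_permutations else "monte_carlo"

    if method == "exhaustive":
        total = pooled.sum()
        count = 0
        for idx in itertools.combinations(range(n_total), n_a):
            sum_a = pooled[list(idx)].sum()
            ate = sum_a / n_a - (total - sum_a) / (n_total - n_a)
            if abs(ate) >= threshold:
                count += 1
        p = count / n_exhaustive
        n_used = n_exhaustive
    else:
        rng = np.random.default_rng(seed)
        # All permutations in one vectorised pass; chunk to bound memory.
        count = 0
        chunk = 20_000
        done = 0
        while done < n_permutations:
            size = min(chunk, n_permutations - done)
            perms = rng.permuted(
                np.broadcast_to(pooled, (size, n_total)).copy(), axis=1
            )
            ates = perms[:, :n_a].mean(axis=1) - perms[:, n_a:].mean(axis=1)
            count += int(np.sum(np.abs(ates) >= threshold))
            done += size
        p = (1 + count) / (1 + n_permutations)
        n_used = n_permutations

    return TestResult(
        label=label,
        ate=100.0 * observed,
        p_value=float(p),
        n_groups=n_total,
        n_permutations=n_used,
        method=method,
        seed=seed,
    )


def moving_average_by_position(
    decisions: pd.DataFrame,
    window: int = 3,
    message_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Trailing moving average of accuracy by sequence position, per condition.

    Accuracy at position i is averaged over groups and messages within a
    condition; the profile is the trailing mean of the last ``window``
    positions and is only defined from position ``window`` onwards (early
    positions are omitted, not imputed).
    """
    n_positions = int(decisions["subject_position"].max())
    if window < 1 or window > n_positions:
        raise InvalidParameterError(
            f"window must be in [1, {n_positions}], got {window}"
        )
    sub = (
        decisions
        if message_ids is None
        else decisions[decisions["message_id"].isin(message_ids)]
    )
    if len(sub) == 0:
        raise MissingDataError("no decisions left after message selection")
    rows = []
    for condition, cond_sub in sub.groupby("condition", sort=False):
        acc = cond_sub.groupby("subject_position")["correct"].mean().sort_index()
        ma = acc.rolling(window).mean()
        for pos, value in acc.items():
            rows.append(
                {
                    "condition": condition,
                    "position": int(pos),
                    "accuracy": float(value),
                    "moving_average": float(ma.loc[pos])
                    if pos >= window
                    else np.nan,
                }
            )
    out = pd.DataFrame(rows)
    return out[out["position"] >= window].reset_index(drop=True)


def position_trend(
    decisions: pd.DataFrame,
    stratum: str = "all",
    ideology: str | None = None,
    aligned: bool | None = None,
    veracity: int | None = None,
    message_ids: list[str] | None = None,
    conditions: list[str] | None = None,
) -> TrendResult:
    """Logistic regression of correctness on sequence position.

    The stratum is carved out by ideology, alignment (ideology equals the
    message lean), veracity, message subset, and conditions. Uncertainty is
    group-clustered (robust sandwich over groups), approximating a
    multilevel model with group random effects. Strata in which every
    decision has the same outcome, or in which the fit separates, are
    flagged and the estimate suppressed.
    """
    sub = _with_alignment(decisions)
    if conditions is not None:
        sub = sub[sub["condition"].isin(conditions)]
    if ideology is not None:
        sub = sub[sub["ideology"] == ideology]
    if aligned is not None:
        sub = sub[sub["aligned"] == aligned]
    if veracity is not None:
        sub = sub[sub["veracity"] == veracity]
    if message_ids is not None:
        sub = sub[sub["message_id"].isin(message_ids)]
    if len(sub) == 0:
        raise MissingDataError(f"stratum {stratum!r} contains no decisions")
    y = sub["correct"].to_numpy(dtype=float)
    if y.min() == y.max():
        return TrendResult(
            stratum=stratum, beta=None, se=None, p_value=None,
            n_decisions=len(sub), flag="degenerate",
        )
    x = sm.add_constant(sub["subject_position"].to_numpy(dtype=float))
    groups = sub["group_id"].to_numpy()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.GLM(y, x, family=sm.families.Binomial()).fit(
                cov_type="cluster", cov_kwds={"groups": groups}
            )
    except Exception:
        return TrendResult(
            stratum=stratum, beta=None, se=None, p_value=None,
            n_decisions=len(sub), flag="separation",
        )
    beta, se, p = fit.params[1], fit.bse[1], fit.pvalues[1]
    if not np.isfinite(beta) or not np.isfinite(se) or abs(beta) > 50:
        return TrendResult(
            stratum=stratum, beta=None, se=None, p_value=None,
            n_decisions=len(sub), flag="separation",
        )
    return TrendResult(
        stratum=stratum,
        beta=float(beta),
        se=float(se),
        p_value=float(p),
        n_decisions=len(sub),
    )


def run_hypothesis_analysis(
    decisions: pd.DataFrame,
    hypothesis: str,
    n_permutations: int = 100_000,
    seed: int | None = None,
    estimates: pd.DataFrame | None = None,
) -> dict:
    """Run the full pipeline for one hypothesis: estimate, select, test.

    H1–H3 yield group-level randomization tests; the condition arms are
    compared lean-by-lean so each test uses a homogeneous message sample
    (H1 additionally reports the pooled comparison). H4/H5 yield logistic
    position-trend results for the aligned-first segregated sequences,
    stratified by subject ideology and alignment.

    Difficulty estimates are computed from the independent condition unless
    supplied (e.g. oracle estimates in tests).
    """
    if estimates is None:
        estimates = estimate_difficulty(decisions)
    scope = select_messages(estimates, hypothesis)
    result: dict = {"hypothesis": hypothesis, "messages": scope}
    if not scope:
        result["tests" if hypothesis in ("H1", "H2", "H3") else "trends"] = []
        return result

    leans = ("liberal", "conservative")
    if hypothesis == "H1":
        tests = []
        subsets = [(f"H1_{lean}", [m for m in scope if estimates.loc[m, "lean"] == lean])
                   for lean in leans]
        subsets.append(("H1_all", scope))
        for label, msgs in subsets:
            if not msgs:
                continue
            frac = group_fraction_correct(
                decisions[decisions["condition"].isin(["integrated", "independent"])],
                msgs,
            )
            cond = decisions.drop_duplicates("group_id").set_index("group_id")[
                "condition"
            ]
            a = frac[cond.loc[frac.index] == "integrated"]
            b = frac[cond.loc[frac.index] == "independent"]
            tests.append(
                randomization_test(a, b, n_permutations, seed, label=label)
            )
        result["tests"] = tests
        return result

    if hypothesis in ("H2", "H3"):
        # Segregated arm: groups whose first-rating ideology matches the lean.
        first_cond = {
            "liberal": "segregated_liberal_first",
            "conservative": "segregated_conservative_first",
        }
        tests = []
        cond = decisions.drop_duplicates("group_id").set_index("group_id")[
            "condition"
        ]
        pooled_a: list[pd.Series] = []
        pooled_b: pd.Series | None = None
        for lean in leans:
            msgs = [m for m in scope if estimates.loc[m, "lean"] == lean]
            if not msgs:
                continue
            frac = group_fraction_correct(
                decisions[
                    decisions["condition"].isin([first_cond[lean], "independent"])
                ],
                msgs,
            )
            a = frac[cond.loc[frac.index] == first_cond[lean]]
            b = frac[cond.loc[frac.index] == "independent"]
            pooled_a.append(a)
            tests.append(
                randomization_test(
                    a, b, n_permutations, seed, label=f"{hypothesis}_{lean}"
                )
            )
        if len(pooled_a) == 2:
            # Pooled comparison: each segregated group summarised on the
            # messages its first-rating ideology aligns with, independent
            # groups on the full scope. Per-group summaries are fixed
            # unit-level outcomes, so label permutation remains a valid
            # randomization test of the sharp null.
            pooled_b = group_fraction_correct(
                decisions[decisions["condition"] == "independent"], scope
            )
            tests.append(
                randomization_test(
                    pd.concat(pooled_a),
                    pooled_b,
                    n_permutations,
                    seed,
                    label=f"{hypothesis}_all",
                )
            )
        result["tests"] = tests
        return result

    # H4/H5: position trends in aligned-first segregated sequences.
    sub_letter = {True: "a", False: "b"}
    first_cond = {
        "liberal": "segregated_liberal_first",
        "conservative": "segregated_conservative_first",
    }
    veracity = 1 if hypothesis == "H4" else -1
    trends = []
    for lean in leans:
        msgs = [m for m in scope if estimates.loc[m, "lean"] == lean]
        if not msgs:
            continue
        for aligned_flag in (True, False):
            ideology = lean if aligned_flag else (
                "conservative" if lean == "liberal" else "liberal"
            )
            label = f"{hypothesis}{sub_letter[aligned_flag]}_{ideology}"
            trends.append(
                position_trend(
                    decisions,
                    stratum=label,
                    ideology=ideology,
                    aligned=aligned_flag,
                    veracity=veracity,
                    message_ids=msgs,
                    conditions=[first_cond[lean]],
                )
            )
    result["trends"] = trends
    return result


def bootstrap_difficulty_uncertainty(
    decisions: pd.DataFrame,
    n_boot: int = 1000,
    seed: int | None = None,
    ci_level: float = 0.95,
) -> pd.DataFrame:
    """Nonparametric bootstrap of the per-message difficulty estimates.

    Independent-condition decisions are resampled with replacement within
    each message; percentile intervals are reported for ``d_bar_hat`` and
    ``d_align_hat`` together with a selection-stability report: the share
    of resamples on which the message's hypothesis-scope classifications
    (``d_bar_hat < 0.5`` and ``d_align_hat > 0.5``) flip relative to the
    point estimate.
    """
    if n_boot < 1:
        raise InvalidParameterError("n_boot must be >= 1")
    ind = _with_alignment(decisions[decisions["condition"] == "independent"])
    if len(ind) == 0:
        raise MissingDataError("no independent-condition decisions")
    rng = np.random.default_rng(seed)
    alpha = (1.0 - ci_level) / 2.0
    rows = []
    for mid, sub in ind.groupby("message_id", sort=False):
        incorrect = 1.0 - sub["correct"].to_numpy(dtype=float)
        aligned = sub["aligned"].to_numpy()
        n = len(sub)
        idx = rng.integers(0, n, size=(n_boot, n))
        boot_inc = incorrect[idx]
        boot_aligned = aligned[idx]
        d_bar_star = boot_inc.mean(axis=1)
        n_aligned = boot_aligned.sum(axis=1)
        with np.errstate(invalid="ignore"):
            d_align_star = np.where(
                n_aligned > 0,
                (boot_inc * boot_aligned).sum(axis=1) / n_aligned,
                np.nan,
            )
        d_bar_hat = incorrect.mean()
        d_align_hat = incorrect[aligned].mean() if aligned.any() else np.nan
        in_scope = d_bar_hat < 0.5
        align_above = d_align_hat > 0.5
        valid = ~np.isnan(d_align_star)
        rows.append(
            {
                "message_id": mid,
                "d_bar_hat": d_bar_hat,
                "d_bar_lo": float(np.quantile(d_bar_star, alpha)),
                "d_bar_hi": float(np.quantile(d_bar_star, 1 - alpha)),
                "d_align_hat": d_align_hat,
                "d_align_lo": float(np.nanquantile(d_align_star, alpha)),
                "d_align_hi": float(np.nanquantile(d_align_star, 1 - alpha)),
                "flip_rate_d_bar": float(np.mean((d_bar_star < 0.5) != in_scope)),
                "flip_rate_d_align": float(
                    np.mean((d_align_star[valid] > 0.5) != align_above)
                ),
                "n_boot": n_boot,
            }
        )
    return pd.DataFrame(rows).set_index("message_id")
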