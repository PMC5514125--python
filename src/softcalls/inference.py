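"""Mixed-model inference with posterior simulation of fixed effects.

The analysis follows the design-based "simulate from the joint
posterior" workflow common in behavioural ecology: a linear mixed model
is fitted by maximum likelihood, the fixed-effect coefficients are then
treated as approximately multivariate normal around their estimates
(a flat-prior asymptotic posterior, as implemented by ``arm::sim`` in
R), and cell means, 95% credible intervals and pairwise exceedance
probabilities are computed from 10 000 joint draws.  Two cells differ
"significantly" when their credible intervals do not overlap, or when
the exceedance probability is below 5% (or above 95%).

Responses (first-answer latency per emission, or answer count per
series) are square-root transformed before fitting to approximate
normality; the transform is configurable.  Random intercepts for
subject, audience and playback order reflect the study design and are
kept even when a variance component estimates to zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import patsy
import statsmodels.formula.api as smf
from scipy import stats

from ._rng import split_rng

__all__ = [
    "ModelSpec",
    "FittedMixedModel",
    "PosteriorDraws",
    "ExceedanceResult",
    "fit_mixed_model",
    "simulate_posterior",
    "compare_cells",
    "familiarity_comparisons",
    "habituation_test",
    "answer_type_composition_test",
    "baseline_playback_correlation",
    "subset_robustness",
]

_TRANSFORMS = {
    "sqrt": (np.sqrt, lambda y: y**2),
    "identity": (lambda y: y, lambda y: y),
}


@dataclass(frozen=True)
class ModelSpec:
    """What to model and how.

    ``response``: column holding the raw response (e.g. ``latency_s``
    or ``n_answers``); ``transform``: ``"sqrt"`` (default, both counts
    and latencies) or ``"identity"``; ``fixed``: factor columns whose
    full interaction forms the fixed part; ``random``: columns given
    random intercepts (subject identity, audience identity, playback
    order).  Factors with a single observed level drop out of the
    formula automatically, so the same spec serves full and reduced
    designs.
    """

    response: str
    transform: str = "sqrt"
    fixed: tuple[str, ...] = ("familiarity", "call_type", "trial")
    random: tuple[str, ...] = ("subject_id", "audience_id", "playback_order")

    def fixed_terms(self, table: pd.DataFrame) -> list[str]:
        return [c for c in self.fixed if table[c].nunique() > 1]


@dataclass
class FittedMixedModel:
    result: object  # statsmodels MixedLMResults
    spec: ModelSpec
    table: pd.DataFrame
    formula: str
    diagnostics: dict = field(default_factory=dict)

    @property
    def fe_params(self) -> pd.Series:
        return getattr(self.result, "fe_params", self.result.params)

    def fe_cov(self) -> np.ndarray:
        k = len(self.fe_params)
        cov = np.asarray(self.result.cov_params())[:k, :k]
        # degenerate fits (zero residual variance) yield NaN entries;
        # treat those directions as known exactly
        cov = np.nan_to_num(cov, nan=0.0, posinf=0.0, neginf=0.0)
        return (cov + cov.T) / 2


def _fit_mixedlm(model) -> object:
    """ML fit with an optimizer cascade.

    Powell handles the near-boundary variance components these designs
    produce (a subject variance close to zero) far more reliably than
    the gradient optimizers, which either stall or collapse the
    component entirely; fall back if it ever fails.
    """
    last = None
    for method in ("powell", "nm", "bfgs"):
        try:
            result = model.fit(reml=False, method=method)
        except Exception:
            continue
        last = result
        bse = np.asarray(result.bse_fe, dtype=float)
        if result.converged and np.all(np.isfinite(bse)):
            return result
    if last is None:
        raise RuntimeError("mixed-model optimization failed with every optimizer")
    return last


def fit_mixed_model(table: pd.DataFrame, spec: ModelSpec) -> FittedMixedModel:
    """Fit the linear mixed model described by ``spec`` by ML.

    Crossed random intercepts are handled as variance components on a
    single grouping; with one random factor the ordinary grouped fit is
    used.  Convergence/singularity warnings are captured into
    ``diagnostics`` rather than silenced, along with simple residual
    summaries (skewness, kurtosis) for a normality check.
    """
    df = table.copy()
    y_raw = df[spec.response].to_numpy(dtype=np.float64)
    if spec.transform not in _TRANSFORMS:
        raise ValueError(f"unknown transform {spec.transform!r}")
    fwd, _ = _TRANSFORMS[spec.transform]
    df["_y"] = fwd(y_raw)
    terms = spec.fixed_terms(df)
    rhs = "*".join(f"C({t})" for t in terms) if terms else "1"
    formula = f"_y ~ {rhs}"
    randoms = [r for r in spec.random if r in df.columns and df[r].nunique() > 1]
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        if len(randoms) == 1:
            model = smf.mixedlm(formula, df, groups=df[randoms[0]])
            result = _fit_mixedlm(model)
        elif len(randoms) > 1:
            vc = {r: f"0 + C({r})" for r in randoms}
            model = smf.mixedlm(formula, df, groups=np.ones(len(df)), vc_formula=vc)
            result = _fit_mixedlm(model)
        else:
            # every random factor constant in this table (e.g. one
            # subject): the model degenerates to ordinary least squares
            warnings.warn("no random factor with >1 level; fitting by OLS")
            result = smf.ols(formula, df).fit()
    try:
        resid = np.asarray(result.resid)
        resid_skew = float(stats.skew(resid))
        resid_kurt = float(stats.kurtosis(resid))
    except ValueError:  # singular RE covariance: BLUPs unavailable
        resid_skew = resid_kurt = float("nan")
    diagnostics = {
        "warnings": sorted({str(w.message) for w in caught}),
        "resid_skew": resid_skew,
        "resid_kurtosis": resid_kurt,
        "converged": bool(getattr(result, "converged", True)),
        "random_factors": randoms,
    }
    return FittedMixedModel(result=result, spec=spec, table=df, formula=formula, diagnostics=diagnostics)


@dataclass
class PosteriorDraws:
    """Joint draws of fixed-effect cell means.

    ``cells`` has one row per fixed-effect cell; ``draws`` is
    (n_draws, n_cells) on the transformed scale; ``summary`` adds the
    fitted value and the 2.5/50/97.5 percentiles per cell, both on the
    transformed and the response scale.
    """

    cells: pd.DataFrame
    draws: np.ndarray
    fitted: np.ndarray
    transform: str

    def cell_index(self, **levels) -> int:
        mask = np.ones(len(self.cells), dtype=bool)
        for col, val in levels.items():
            mask &= self.cells[col].astype(str).to_numpy() == str(val)
        idx = np.flatnonzero(mask)
        if len(idx) != 1:
            raise KeyError(f"{levels} matches {len(idx)} cells")
        return int(idx[0])

    def cell_draws(self, **levels) -> np.ndarray:
        return self.draws[:, self.cell_index(**levels)]

    def summary(self) -> pd.DataFrame:
        lo, med, hi = np.percentile(self.draws, [2.5, 50, 97.5], axis=0)
        out = self.cells.copy()
        out["fitted"] = self.fitted
        out["cri_lo"] = lo
        out["median"] = med
        out["cri_hi"] = hi
        _, back = _TRANSFORMS[self.transform]
        for col in ("fitted", "cri_lo", "median", "cri_hi"):
            out[col + "_resp"] = back(out[col].to_numpy())
        return out


def simulate_posterior(fitted: FittedMixedModel, n_draws: int = 10000, seed: int = 0) -> PosteriorDraws:
    """Draw cell means from the asymptotic joint posterior of the fixed
    effects (multivariate normal at the ML estimate)."""
    rng = split_rng(seed, "inference", "posterior")
    beta = np.asarray(fitted.fe_params, dtype=np.float64)
    cov = fitted.fe_cov()
    terms = fitted.spec.fixed_terms(fitted.table)
    if terms:
        levels = [list(pd.unique(fitted.table[t])) for t in terms]
        grid = pd.DataFrame(
            [dict(zip(terms, combo)) for combo in _product(levels)]
        )
    else:
        grid = pd.DataFrame({"_intercept": [1]})
    di = fitted.result.model.data.design_info
    (X,) = patsy.build_design_matrices([di], grid if terms else fitted.table.iloc[:1])
    X = np.asarray(X)
    draws_beta = rng.multivariate_normal(beta, cov, size=n_draws, method="svd", check_valid="ignore")
    draws = draws_beta @ X.T
    fitted_vals = X @ beta
    cells = grid if terms else pd.DataFrame({"cell": ["(intercept)"]})
    return PosteriorDraws(cells=cells.reset_index(drop=True), draws=draws, fitted=fitted_vals, transform=fitted.spec.transform)


def _product(level_lists):
    if not level_lists:
        yield ()
        return
    for head in level_lists[0]:
        for rest in _product(level_lists[1:]):
            yield (head, *((rest,) if not isinstance(rest, tuple) else rest))


@dataclass(frozen=True)
class ExceedanceResult:
    p_greater: float  # fraction of joint draws where A > B (ties count 0.5)
    significant: bool
    alpha: float
    cri_a: tuple[float, float]
    cri_b: tuple[float, float]

    @property
    def cri_overlap(self) -> bool:
        return self.cri_a[0] <= self.cri_b[1] and self.cri_b[0] <= self.cri_a[1]


def compare_cells(draws_a: np.ndarray, draws_b: np.ndarray, alpha: float = 0.05) -> ExceedanceResult:
    """Exceedance probability P(A > B) over paired joint draws.

    Significant when ``p < alpha`` (A smaller) or ``p > 1 - alpha``
    (A larger); ties (equal draws up to floating-point noise)
    contribute 0.5.
    """
    a = np.asarray(draws_a, dtype=np.float64)
    b = np.asarray(draws_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("draw vectors must be paired (equal length)")
    tie = np.isclose(a, b, rtol=1e-9, atol=1e-12)
    p = float(np.mean((a > b) & ~tie) + 0.5 * np.mean(tie))
    return ExceedanceResult(
        p_greater=p,
        significant=bool(p < alpha or p > 1 - alpha),
        alpha=alpha,
        cri_a=tuple(np.percentile(a, [2.5, 97.5])),
        cri_b=tuple(np.percentile(b, [2.5, 97.5])),
    )


def familiarity_comparisons(post: PosteriorDraws, alpha: float = 0.05) -> pd.DataFrame:
    """Mate-vs-familiar and mate-vs-unfamiliar contrasts per cell group.

    For every combination of the non-familiarity factors present,
    compares the mate cell against the familiar and unfamiliar cells:
    exceedance probability, CrI overlap, and the fitted difference on
    the response scale (other cell minus mate; positive = slower/more).
    """
    others = [c for c in post.cells.columns if c != "familiarity"]
    _, back = _TRANSFORMS[post.transform]
    rows = []
    groups = post.cells.groupby(others, sort=False) if others else [((), post.cells)]
    for key, grp in groups:
        fam_levels = set(grp["familiarity"])
        if "m" not in fam_levels:
            continue
        key = key if isinstance(key, tuple) else (key,)
        i_m = grp.index[grp["familiarity"] == "m"][0]
        for other in ("f", "uf"):
            if other not in fam_levels:
                continue
            i_o = grp.index[grp["familiarity"] == other][0]
            res = compare_cells(post.draws[:, i_m], post.draws[:, i_o], alpha=alpha)
            rows.append(
                dict(zip(others, key))
                | {
                    "contrast": f"m-vs-{other}",
                    "p_mate_greater": res.p_greater,
                    "significant": res.significant,
                    "cri_overlap": res.cri_overlap,
                    "effect_resp": float(back(post.fitted[i_o]) - back(post.fitted[i_m])),
                }
            )
    return pd.DataFrame(rows)


def habituation_test(
    counts: pd.DataFrame,
    n_draws: int = 10000,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """First-vs-last-bin comparison of calling rate across a trial.

    ``counts`` needs columns ``subject_id, bin, n_calls`` (one row per
    subject per 500-s bin).  Fits ``n_calls ~ C(bin)`` with a subject
    random intercept and compares the first and last bins by posterior
    simulation.  Returns the exceedance result plus the cell summary.
    """
    if counts["bin"].nunique() < 2:
        raise ValueError("need at least 2 bins")
    spec = ModelSpec(response="n_calls", transform="sqrt", fixed=("bin",), random=("subject_id",))
    fitted = fit_mixed_model(counts, spec)
    post = simulate_posterior(fitted, n_draws=n_draws, seed=seed)
    bins = sorted(counts["bin"].unique())
    res = compare_cells(post.cell_draws(bin=bins[0]), post.cell_draws(bin=bins[-1]), alpha=alpha)
    return {"comparison": res, "posterior": post, "model": fitted, "first_bin": bins[0], "last_bin": bins[-1]}


@dataclass(frozen=True)
class CompositionTestResult:
    statistic: float | None
    p_value: float | None
    n_nonnull: int
    skipped: bool
    reason: str | None = None


def answer_type_composition_test(
    proportions_by_group: Mapping[str, Sequence[float]],
    min_nonnull: int = 8,
) -> CompositionTestResult:
    """Kruskal–Wallis comparison of answer-type proportions across
    familiarity groups, run only with at least ``min_nonnull`` non-null
    values pooled across groups."""
    groups = {k: [v for v in vals if v is not None and np.isfinite(v)] for k, vals in proportions_by_group.items()}
    n_nonnull = sum(len(v) for v in groups.values())
    if n_nonnull < min_nonnull:
        return CompositionTestResult(None, None, n_nonnull, True, f"only {n_nonnull} non-null values (< {min_nonnull})")
    arrays = [np.asarray(v) for v in groups.values() if len(v)]
    if len(arrays) < 2:
        return CompositionTestResult(None, None, n_nonnull, True, "fewer than 2 non-empty groups")
    if np.ptp(np.concatenate(arrays)) == 0:
        return CompositionTestResult(0.0, 1.0, n_nonnull, False)
    stat, p = stats.kruskal(*arrays)
    return CompositionTestResult(float(stat), float(p), n_nonnull, False)


def baseline_playback_correlation(
    baseline: Sequence[float],
    playback: Sequence[float],
    n_draws: int = 10000,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Relation between playback answer proportion and baseline answer
    proportion across subjects (one trial at a time).

    Ordinary least squares of playback on baseline; the slope's
    credible interval and exceedance probability P(slope > 0) come from
    draws of the coefficient's asymptotic posterior.  Also reports the
    Pearson correlation.
    """
    x = np.asarray(baseline, dtype=np.float64)
    y = np.asarray(playback, dtype=np.float64)
    if len(x) != len(y):
        raise ValueError("baseline and playback must align")
    if len(x) < 3:
        raise ValueError("need at least 3 subjects")
    import statsmodels.api as sm

    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    rng = split_rng(seed, "inference", "baseline_corr")
    cov = np.asarray(fit.cov_params())
    draws = rng.multivariate_normal(np.asarray(fit.params), (cov + cov.T) / 2, size=n_draws, method="svd", check_valid="ignore")
    slope_draws = draws[:, 1]
    p_pos = float(np.mean(slope_draws > 0) + 0.5 * np.mean(slope_draws == 0))
    lo, hi = np.percentile(slope_draws, [2.5, 97.5])
    r = float(np.corrcoef(x, y)[0, 1]) if np.std(x) > 0 and np.std(y) > 0 else np.nan
    return {
        "slope": float(fit.params[1]),
        "cri": (float(lo), float(hi)),
        "p_slope_positive": p_pos,
        "significant": bool(p_pos < alpha or p_pos > 1 - alpha),
        "pearson_r": r,
        "n": len(x),
    }


def subset_robustness(
    tables: Mapping[str, pd.DataFrame],
    spec: ModelSpec,
    n_draws: int = 2000,
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Compare familiarity contrasts between full-series data and
    first/last-emission subsets.

    ``tables`` maps dataset name (``"full"`` plus e.g. ``"first"``,
    ``"last"``) to a response table; the same model and comparisons are
    run on each, and the signed contrasts are tabulated with agreement
    flags against the full dataset.  Use
    :func:`softcalls.pipeline.subset_emissions` to restrict a schedule
    to the first/last emissions of each series before scoring.
    """
    if "full" not in tables:
        raise ValueError("tables must include the 'full' dataset")
    results = {}
    for name, table in tables.items():
        fitted = fit_mixed_model(table, spec)
        post = simulate_posterior(fitted, n_draws=n_draws, seed=seed)
        comp = familiarity_comparisons(post, alpha=alpha)
        results[name] = comp.set_index([c for c in comp.columns if c not in ("p_mate_greater", "significant", "cri_overlap", "effect_resp")])
    full = results["full"]
    rows = []
    for key, row in full.iterrows():
        entry = {"key": key, "effect_full": row["effect_resp"], "sig_full": row["significant"]}
        for name in results:
            if name == "full":
                continue
            sub = results[name]
            if key in sub.index:
                entry[f"effect_{name}"] = sub.loc[key, "effect_resp"]
                entry[f"sig_{name}"] = sub.loc[key, "significant"]
                entry[f"agree_{name}"] = bool(np.sign(sub.loc[key, "effect_resp"]) == np.sign(row["effect_resp"]))
        rows.append(entry)
    return pd.DataFrame(rows)
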