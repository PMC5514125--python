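"""Individual distinctiveness of call types and its link to response.

For each focal bird and call type, the playback stimuli (3 exemplars
from each of the 3 opposite-sex callers, i.e. the three familiarity
identities) are described by the 14 spectral features, reduced to the
first two principal components of the standardized features, and a
linear discriminant analysis is trained to assign each stimulus to its
caller.  The proportion of *incorrectly* re-assigned stimuli is the
(inverse) distinctiveness index: low misassignment = highly individual
call type.  Prediction is by resubstitution on the training calls;
leave-one-out is available behind a flag.

Chance-level misassignment for k balanced indistinguishable callers is
(k-1)/k.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from ._rng import split_rng

__all__ = ["DistinctivenessResult", "distinctiveness_index", "summarize_distinctiveness", "relate_distinctiveness_to_response"]


@dataclass(frozen=True)
class DistinctivenessResult:
    focal_bird: str | None
    call_type: str | None
    proportion_incorrect: float
    n_stimuli: int
    n_identities: int
    predicted: tuple  # per-stimulus predicted identity labels


def distinctiveness_index(
    features: np.ndarray | pd.DataFrame,
    identities,
    n_components: int = 2,
    method: str = "resubstitution",
    focal_bird: str | None = None,
    call_type: str | None = None,
) -> DistinctivenessResult:
    """PCA -> LDA misassignment proportion for one (bird, call type).

    ``features``: one row per stimulus (the 14 spectral features);
    ``identities``: caller label per stimulus.  Features are
    standardized (PCA on the correlation structure, since units mix Hz,
    seconds and unitless measures).  ``method`` is ``"resubstitution"``
    (default) or ``"loo"`` (leave-one-out).
    """
    X = np.asarray(features, dtype=np.float64)
    if isinstance(features, pd.DataFrame):
        X = features.to_numpy(dtype=np.float64)
    ids = np.asarray(identities)
    if len(X) != len(ids):
        raise ValueError("features and identities must align")
    uniq = pd.unique(ids)
    if len(uniq) < 3:
        raise ValueError("need at least 3 identities")
    counts = pd.Series(ids).value_counts()
    if counts.min() < 2:
        raise ValueError("need at least 2 stimuli per identity")
    sd = X.std(axis=0)
    live = sd > 0
    if live.sum() < 2:
        raise ValueError("degenerate features: fewer than 2 columns with non-zero variance")
    # constant columns (e.g. the spectral resolution, fixed by the
    # analysis settings) carry no identity information; drop them
    X = X[:, live]
    sd = sd[live]
    Z = (X - X.mean(axis=0)) / sd
    n_comp = min(n_components, Z.shape[1], len(Z) - 1)

    def fit_predict(train_idx, test_idx):
        pca = PCA(n_components=n_comp).fit(Z[train_idx])
        lda = LinearDiscriminantAnalysis().fit(pca.transform(Z[train_idx]), ids[train_idx])
        return lda.predict(pca.transform(Z[test_idx]))

    all_idx = np.arange(len(Z))
    if method == "resubstitution":
        pred = fit_predict(all_idx, all_idx)
    elif method == "loo":
        pred = np.empty(len(Z), dtype=ids.dtype)
        for i in all_idx:
            train = np.delete(all_idx, i)
            pred[i] = fit_predict(train, [i])[0]
    else:
        raise ValueError(f"unknown method {method!r}")
    wrong = float(np.mean(pred != ids))
    return DistinctivenessResult(
        focal_bird=focal_bird,
        call_type=call_type,
        proportion_incorrect=wrong,
        n_stimuli=len(Z),
        n_identities=len(uniq),
        predicted=tuple(pred),
    )


def summarize_distinctiveness(results: list[DistinctivenessResult]) -> pd.DataFrame:
    """Across-bird mean and SD of the misassignment proportion per call type."""
    df = pd.DataFrame(
        [
            {"focal_bird": r.focal_bird, "call_type": r.call_type, "proportion_incorrect": r.proportion_incorrect}
            for r in results
        ]
    )
    return (
        df.groupby("call_type")["proportion_incorrect"]
        .agg(["mean", "std", "count"])
        .reset_index()
        .rename(columns={"mean": "mean_incorrect", "std": "sd_incorrect", "count": "n_birds"})
    )


def relate_distinctiveness_to_response(
    table: pd.DataFrame,
    magnitude_col: str = "magnitude",
    distinctiveness_col: str = "proportion_incorrect",
    subject_col: str = "focal_bird",
    n_draws: int = 10000,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Slope of response magnitude on distinctiveness, with CrI.

    ``table`` has one row per (bird, call type): a response-magnitude
    column (e.g. mate-minus-familiar count or mean-latency difference)
    and the misassignment proportion.  A linear mixed model with a
    subject random intercept is fitted and the slope's credible
    interval obtained by posterior simulation.
    """
    if table["call_type"].nunique() < 3 if "call_type" in table.columns else len(table) < 3:
        raise ValueError("need at least 3 call types")
    df = table.rename(columns={magnitude_col: "_mag", distinctiveness_col: "_dist"}).copy()
    import statsmodels.formula.api as smf

    model = smf.mixedlm("_mag ~ _dist", df, groups=df[subject_col])
    import warnings as _w

    with _w.catch_warnings():
        _w.simplefilter("ignore")
        result = model.fit(reml=False)
    k = len(result.fe_params)
    cov = np.asarray(result.cov_params())[:k, :k]
    cov = np.nan_to_num(cov, nan=0.0, posinf=0.0, neginf=0.0)
    rng = split_rng(seed, "distinctiveness", "slope")
    draws = rng.multivariate_normal(np.asarray(result.fe_params), (cov + cov.T) / 2, size=n_draws, method="svd", check_valid="ignore")
    slope_draws = draws[:, 1]
    lo, hi = np.percentile(slope_draws, [2.5, 97.5])
    p_pos = float(np.mean(slope_draws > 0) + 0.5 * np.mean(slope_draws == 0))
    return {
        "slope": float(result.fe_params.iloc[1]),
        "cri": (float(lo), float(hi)),
        "p_slope_positive": p_pos,
        "significant": bool(p_pos < alpha or p_pos > 1 - alpha),
        "n": len(df),
    }
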