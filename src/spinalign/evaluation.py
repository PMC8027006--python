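"""Downstream statistics: letter-value error quantiles, parameter-error
summaries, interobserver agreement (ICC) with grading and clustering, and
the heatmap-SD learning-speed fit.

Conventions follow common practice for skewed error distributions: medians
and letter values rather than means where distributions are long-tailed,
type-7 (linear-interpolation) quantiles, two-way random-effects
single-measure absolute-agreement ICC, and Wilcoxon signed-rank tests with
zero differences dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .geometry import SpinopelvicParameters

ICC_GRADES = (
    (0.9, "excellent"),
    (0.7, "high"),
    (0.5, "moderate"),
    (0.25, "low"),
)


# ---------------------------------------------------------------------------
# letter values


def letter_value_quantiles(errors, depth: int = 3) -> pd.DataFrame:
    """Nested letter-value quantile boxes plus the median.

    Level ``k`` >= 1 covers the quantile pair (2^-(k+1), 1 - 2^-(k+1)):
    level 1 is the quartile box (0.25..0.75, the IQR), level 2 the eighths
    box (0.125..0.875), level 3 the sixteenths box (0.0625..0.9375), and so
    on; level 0 is the median.  Intervals are nested by construction of the
    quantile function (type-7, linear interpolation).
    """
    x = np.asarray(errors, dtype=float)
    if x.size == 0:
        raise ValueError("empty error list")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite error values")
    rows = [{"level": 0, "lower": float(np.quantile(x, 0.5)), "upper": float(np.quantile(x, 0.5))}]
    for k in range(1, depth + 1):
        p = 2.0 ** -(k + 1)
        rows.append(
            {"level": k, "lower": float(np.quantile(x, p)), "upper": float(np.quantile(x, 1 - p))}
        )
    return pd.DataFrame(rows).set_index("level")


# ---------------------------------------------------------------------------
# parameter errors


def _to_frame(items) -> pd.DataFrame:
    if isinstance(items, pd.DataFrame):
        return items.reset_index(drop=True)
    return pd.DataFrame([p.as_dict() if isinstance(p, SpinopelvicParameters) else dict(p) for p in items])


def parameter_error_summary(pred, truth) -> pd.DataFrame:
    """Per-parameter error statistics for paired prediction/truth tables.

    Columns: ground-truth mean/SD, absolute-error mean/SD and median/IQR,
    Pearson r with its p-value (NaN + ``r_defined`` False when an input is
    constant), and the two-sided Wilcoxon signed-rank p-value (1.0 by
    convention when all differences vanish).
    """
    pf, tf = _to_frame(pred), _to_frame(truth)
    if len(pf) != len(tf):
        raise ValueError(f"length mismatch: {len(pf)} predictions vs {len(tf)} truths")
    if list(pf.columns) != list(tf.columns):
        raise ValueError("prediction/truth parameter names differ")
    rows = []
    for name in pf.columns:
        p, t = pf[name].to_numpy(float), tf[name].to_numpy(float)
        err = np.abs(p - t)
        q75, q25 = np.percentile(err, [75, 25])
        r_defined = np.std(p) > 0 and np.std(t) > 0
        if r_defined:
            r, rp = stats.pearsonr(p, t)
        else:
            r, rp = np.nan, np.nan
        diffs = p - t
        if np.all(diffs == 0):
            wp = 1.0
        else:
            wp = float(stats.wilcoxon(p, t, zero_method="wilcox", alternative="two-sided").pvalue)
        rows.append(
            {
                "parameter": name,
                "unit": SpinopelvicParameters.unit(name) if name in SpinopelvicParameters.names() else "",
                "truth_mean": float(np.mean(t)),
                "truth_sd": float(np.std(t, ddof=1)) if len(t) > 1 else 0.0,
                "error_mean": float(np.mean(err)),
                "error_sd": float(np.std(err, ddof=1)) if len(err) > 1 else 0.0,
                "error_median": float(np.median(err)),
                "error_iqr": float(q75 - q25),
                "pearson_r": float(r) if r_defined else np.nan,
                "pearson_p": float(rp) if r_defined else np.nan,
                "r_defined": bool(r_defined),
                "wilcoxon_p": wp,
            }
        )
    return pd.DataFrame(rows).set_index("parameter")


# ---------------------------------------------------------------------------
# ICC


def icc_grade(value: float) -> str:
    for lo, label in ICC_GRADES:
        if value >= lo:
            return label
    return "poor"


def icc_pair(x: np.ndarray, y: np.ndarray) -> float:
    """ICC(2,1) between two raters: two-way random effects, absolute
    agreement, single measurement (via pingouin)."""
    import pingouin as pg

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("need two equal-length rating vectors of >= 2 subjects")
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        raise ValueError("constant ratings: ICC undefined (no subject variance)")
    long = pd.DataFrame(
        {
            "subject": np.tile(np.arange(x.size), 2),
            "rater": np.repeat(["a", "b"], x.size),
            "score": np.concatenate([x, y]),
        }
    )
    table = pg.intraclass_corr(long, targets="subject", raters="rater", ratings="score")
    table = table.set_index("Type")
    key = "ICC2" if "ICC2" in table.index else "ICC(A,1)"
    return float(table.loc[key, "ICC"])


@dataclass(frozen=True)
class ICCReport:
    """Pairwise agreement per parameter with grades and clustered orders."""

    icc: pd.DataFrame  # parameters x observer-pairs
    grades: pd.DataFrame
    row_order: list[str]
    col_order: list[str]
    method: str = "ICC(2,1): two-way random effects, absolute agreement, single measurement"


def icc_analysis(ratings: dict[str, pd.DataFrame]) -> ICCReport:
    """Pairwise ICC matrix over all observer pairs for every parameter.

    ``ratings`` maps a parameter name to a subjects x observers table
    (observers may include the model and the ground truth as columns).
    Rows and columns are ordered by average-linkage hierarchical clustering
    on Euclidean distances, oriented so higher agreement sorts last.
    """
    if not ratings:
        raise ValueError("no rating tables given")
    rows = {}
    for param, table in ratings.items():
        obs = list(table.columns)
        if len(obs) < 2 or len(table) < 2:
            raise ValueError(f"{param}: need >= 2 observers and >= 2 subjects")
        vals = {}
        for i, a in enumerate(obs):
            for b in obs[i + 1 :]:
                vals[f"{a}-{b}"] = icc_pair(table[a].to_numpy(), table[b].to_numpy())
        rows[param] = vals
    icc = pd.DataFrame(rows).T
    grades = icc.map(icc_grade)
    row_order = _cluster_order(icc.to_numpy(), list(icc.index))
    col_order = _cluster_order(icc.to_numpy().T, list(icc.columns))
    return ICCReport(icc=icc, grades=grades, row_order=row_order, col_order=col_order)


def _cluster_order(mat: np.ndarray, names: list[str]) -> list[str]:
    if len(names) < 3:
        order = list(np.argsort(mat.mean(axis=1)))
    else:
        link = hierarchy.linkage(mat, method="average", metric="euclidean")
        order = list(hierarchy.leaves_list(link))
        if mat[order].mean(axis=1)[0] > mat[order].mean(axis=1)[-1]:
            order = order[::-1]
    return [names[i] for i in order]


# ---------------------------------------------------------------------------
# heatmap SD and its decay


def heatmap_sd(probs: np.ndarray, atol: float = 1e-6) -> float:
    """Isotropic spread of a normalised heatmap: sqrt of the mean of the x
    and y marginal variances, in grid pixels."""
    p = np.asarray(probs, dtype=float)
    if p.ndim != 2:
        raise ValueError("expected a 2-D grid")
    if abs(p.sum() - 1.0) > atol or (p < 0).any():
        raise ValueError("grid is not a normalised distribution")
    h, w = p.shape
    px, py = p.sum(axis=0), p.sum(axis=1)
    xs, ys = np.arange(w, dtype=float), np.arange(h, dtype=float)
    var_x = float(px @ xs**2 - (px @ xs) ** 2)
    var_y = float(py @ ys**2 - (py @ ys) ** 2)
    return float(np.sqrt(max(0.0, (var_x + var_y) / 2.0)))


@dataclass(frozen=True)
class DecayFit:
    """Power-law fit SD(t) ~ t^-gamma over an epoch window."""

    area: str
    gamma: float
    adj_r2: float
    p_value: float
    n_epochs: int


def heatmap_sd_decay(
    sds: pd.DataFrame,
    area_of: dict[str, str] | None = None,
    window: tuple[int, int] = (10, 100),
) -> dict[str, DecayFit]:
    """Fit log SD vs log epoch per anatomic area.

    ``sds`` is indexed by epoch with one column per landmark (averaged into
    areas via ``area_of``) or directly one column per area.  The decay rate
    is the negative log-log slope; adjusted R^2 and the slope's p-value come
    from the least-squares fit.
    """
    import statsmodels.api as sm

    lo, hi = window
    sel = sds.loc[(sds.index >= lo) & (sds.index <= hi)]
    if len(sel) < 3:
        raise ValueError(f"need >= 3 epochs inside window {window}")
    if area_of is not None:
        grouped = {}
        for col, area in area_of.items():
            grouped.setdefault(area, []).append(sel[col])
        series = {a: pd.concat(cols, axis=1).mean(axis=1) for a, cols in grouped.items()}
    else:
        series = {a: sel[a] for a in sel.columns}
    out = {}
    for area, s in series.items():
        y = s.to_numpy(dtype=float)
        if np.any(y <= 0):
            raise ValueError(f"{area}: non-positive SDs, log-log fit undefined")
        x = sm.add_constant(np.log(s.index.to_numpy(dtype=float)))
        fit = sm.OLS(np.log(y), x).fit()
        out[area] = DecayFit(
            area=area,
            gamma=float(-fit.params[1]),
            adj_r2=float(fit.rsquared_adj),
            p_value=float(fit.pvalues[1]),
            n_epochs=len(y),
        )
    return out
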