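"""Statistical pipeline for simulated (or tabulated) response data.

Covers the analyses of the two experiments: drawn shape ratios and their
2x2 within-participant ANOVA (spectacles x object, parametric and
permutation), per-participant magnification/response correlations,
slant-to-shape prediction fits (cubic in signed magnification, r^2 and
RMSE per participant), Cochran Q and McNemar tests with odds ratios for
the binary slant reports, and Benjamini-Hochberg FDR correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .predictors import ObjectSpec, predicted_shape_curve


@dataclass(frozen=True)
class GroupStats:
    """One-sample group summary of a per-participant statistic."""

    mean: float
    sd: float
    t: float
    df: int
    p: float
    cohen_d: float

    @classmethod
    def from_values(cls, values: np.ndarray, popmean: float = 0.0) -> "GroupStats":
        v = np.asarray(values, dtype=float)
        n = v.size
        mean = float(v.mean())
        sd = float(v.std(ddof=1))
        t, p = stats.ttest_1samp(v, popmean)
        d = (mean - popmean) / sd if sd > 0 else np.inf * np.sign(mean - popmean)
        return cls(mean=mean, sd=sd, t=float(t), df=n - 1, p=float(p),
                   cohen_d=float(d))


def drawing_shape_ratio(left_cm: float, right_cm: float) -> float:
    """Right/left side-length ratio of one drawing."""
    if left_cm <= 0 or right_cm <= 0:
        raise ValueError(
            f"drawing side lengths must be > 0, got left={left_cm}, "
            f"right={right_cm}"
        )
    return right_cm / left_cm


def average_repetitions(table: pd.DataFrame) -> pd.DataFrame:
    """Mean response per participant x axis x eye x magnification."""
    keys = ["participant_id", "axis", "eye", "magnification_pct"]
    return table.groupby(keys, as_index=False)["response"].mean()


def per_participant_correlation(
    table: pd.DataFrame, task: str, axis: str, average_reps: bool = True
) -> Tuple[pd.DataFrame, GroupStats]:
    """Pearson r of response vs signed magnification, per participant.

    Repetitions are averaged within condition first (matching the use of
    per-condition means), then each participant's r is computed and the
    cohort is summarised by a one-sample t test of the r values against
    zero with Cohen's d = mean / SD.
    """
    sub = table[(table["task"] == task) & (table["axis"] == axis)]
    if sub.empty:
        raise ValueError(f"no rows for task={task!r}, axis={axis!r}")
    data = average_repetitions(sub) if average_reps else sub
    rows = []
    for pid, grp in data.groupby("participant_id"):
        x = grp["magnification_pct"].to_numpy(dtype=float)
        y = grp["response"].to_numpy(dtype=float)
        if np.unique(x).size < 3:
            raise ValueError(
                f"participant {pid}: need >= 3 distinct magnification levels"
            )
        if np.std(x) == 0 or np.std(y) == 0:
            raise ValueError(
                f"participant {pid}: zero variance, correlation undefined"
            )
        r, _ = stats.pearsonr(x, y)
        rows.append((pid, float(r)))
    per = pd.DataFrame(rows, columns=["participant_id", "r"])
    return per, GroupStats.from_values(per["r"].to_numpy())


def prediction_fit_metrics(
    shape_table: pd.DataFrame,
    slant_table: pd.DataFrame,
    obj: ObjectSpec,
    average_reps: bool = True,
) -> Tuple[pd.DataFrame, Dict[str, Dict[str, GroupStats]]]:
    """Per-participant agreement between predicted and observed shape settings.

    For each participant and axis, the slant-task settings are converted
    to predicted shape-task settings and fit with a third-order
    polynomial in signed magnification (see
    :func:`stereoshape.predictors.predicted_shape_curve`), evaluated at
    the shape-task grid, and compared with the observed settings:
    r^2 as the squared Pearson correlation (primary) and as 1 - SSE/SST,
    plus RMSE in ratio units.  Group-level one-sample t tests against 0
    summarise each metric per axis.
    """
    shape = average_repetitions(shape_table) if average_reps else shape_table
    slant = average_repetitions(slant_table) if average_reps else slant_table
    axes = sorted(shape["axis"].unique())
    rows = []
    for axis in axes:
        sh_ax = shape[shape["axis"] == axis]
        sl_ax = slant[slant["axis"] == axis]
        for pid in sorted(sh_ax["participant_id"].unique()):
            sh = sh_ax[sh_ax["participant_id"] == pid]
            sl = sl_ax[sl_ax["participant_id"] == pid]
            if sl.empty:
                raise ValueError(
                    f"participant {pid}, axis {axis}: slant-task data missing"
                )
            pred = predicted_shape_curve(
                sl["magnification_pct"].to_numpy(dtype=float),
                sl["response"].to_numpy(dtype=float),
                obj,
                sh["magnification_pct"].to_numpy(dtype=float),
            )
            obs = sh["response"].to_numpy(dtype=float)
            r = stats.pearsonr(pred, obs)[0] if np.std(pred) > 0 else np.nan
            sse = float(np.sum((obs - pred) ** 2))
            sst = float(np.sum((obs - obs.mean()) ** 2))
            rows.append(
                (pid, axis, float(r) ** 2,
                 1.0 - sse / sst if sst > 0 else np.nan,
                 float(np.sqrt(np.mean((obs - pred) ** 2))))
            )
    per = pd.DataFrame(
        rows, columns=["participant_id", "axis", "r2", "r2_sse", "rmse"]
    )
    group: Dict[str, Dict[str, GroupStats]] = {}
    for axis in axes:
        sub = per[per["axis"] == axis]
        group[axis] = {
            "r2": GroupStats.from_values(sub["r2"].to_numpy()),
            "rmse": GroupStats.from_values(sub["rmse"].to_numpy()),
        }
    return per, group


# ---------------------------------------------------------------------------
# 2 x 2 within-participant ANOVA (spectacles x object) on drawn shape ratios
# ---------------------------------------------------------------------------

_CELL_ORDER = [
    ("control", "phone"), ("control", "square"),
    ("experimental", "phone"), ("experimental", "square"),
]

# Effect contrasts on the cell order above; each effect's F(1, n-1) equals
# the one-sample t^2 of the per-participant contrast values.
_CONTRASTS = {
    "spectacles": np.array([-0.5, -0.5, 0.5, 0.5]),
    "object": np.array([-0.5, 0.5, -0.5, 0.5]),
    "interaction": np.array([1.0, -1.0, -1.0, 1.0]),
}


def _drawings_to_cells(drawings: pd.DataFrame) -> np.ndarray:
    """Pivot a drawing table to an (n_participants, 4) ratio array."""
    d = drawings.copy()
    d["ratio"] = d.apply(
        lambda r: drawing_shape_ratio(r["left_cm"], r["right_cm"]), axis=1
    )
    pivot = d.pivot_table(
        index="participant_id", columns=["spectacles", "object"],
        values="ratio", aggfunc="mean",
    )
    missing = [c for c in _CELL_ORDER if c not in pivot.columns]
    if missing or pivot.isna().any().any():
        raise ValueError(
            f"incomplete 2x2 design: missing cells {missing or 'some rows'}"
        )
    return pivot[_CELL_ORDER].to_numpy(dtype=float)


def _anova_f(cells: np.ndarray) -> Dict[str, float]:
    """F(1, n-1) per effect from an (..., n, 4) within-participant array."""
    out = {}
    n = cells.shape[-2]
    for name, c in _CONTRASTS.items():
        e = cells @ c  # per-participant contrast, shape (..., n)
        mean = e.mean(axis=-1)
        var = e.var(axis=-1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            f = np.where(var > 0, n * mean**2 / var,
                         np.where(mean == 0, 0.0, np.inf))
        out[name] = f
    return out


def rm_anova_2x2(
    drawings: pd.DataFrame,
    n_permutations: int = 5000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Two-way repeated-measures ANOVA on drawn shape ratios.

    Standard within-subject decomposition for a complete 2 (spectacles)
    x 2 (object) design with one observation per cell: each effect is
    tested against its effect-by-participant interaction, F(1, n-1).
    A permutation variant relabels the four cells within each
    participant (seeded) and reports p = (1 + #{F* >= F}) /
    (1 + n_permutations) per effect.  An infinite F (zero error
    variance) is reported as-is.
    """
    cells = _drawings_to_cells(drawings)
    n = cells.shape[0]
    observed = {k: float(v) for k, v in _anova_f(cells).items()}

    rng = np.random.default_rng(seed)
    perm_idx = np.stack(
        [rng.permuted(np.tile(np.arange(4), (n, 1)), axis=1)
         for _ in range(n_permutations)]
    )  # (B, n, 4)
    permuted = np.take_along_axis(cells[None, :, :], perm_idx, axis=2)
    perm_f = _anova_f(permuted)

    rows = []
    for name in _CONTRASTS:
        f_obs = observed[name]
        p_param = float(stats.f.sf(f_obs, 1, n - 1))
        exceed = int(np.sum(perm_f[name] >= f_obs))
        p_perm = (1 + exceed) / (1 + n_permutations)
        rows.append((name, f_obs, 1, n - 1, p_param, p_perm))
    return pd.DataFrame(
        rows, columns=["effect", "F", "df_num", "df_den", "p_param", "p_perm"]
    )


def paired_cohen_d(x: np.ndarray, y: np.ndarray) -> float:
    """Cohen's d for paired data: mean difference / SD of differences."""
    diff = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    sd = diff.std(ddof=1)
    return float(diff.mean() / sd) if sd > 0 else float("inf") * np.sign(diff.mean())


# ---------------------------------------------------------------------------
# Binary slant reports
# ---------------------------------------------------------------------------

def cochran_q(reports: np.ndarray) -> Tuple[float, int, float]:
    """Cochran Q omnibus test on a participants x conditions binary matrix.

    Q = k(k-1) * sum_j (G_j - Gbar)^2 / (k * sum_i L_i - sum_i L_i^2)
    with G_j the condition totals and L_i the participant totals; df =
    k - 1, p from the chi-squared distribution.  Participants with
    all-equal rows contribute through the formula and are not dropped.
    """
    x = np.asarray(reports)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("reports must be a 2D matrix with >= 2 conditions")
    if not np.isin(x, (0, 1)).all():
        raise ValueError("reports must be binary (0/1)")
    k = x.shape[1]
    col = x.sum(axis=0)
    row = x.sum(axis=1)
    denom = k * row.sum() - np.sum(row**2)
    if denom == 0:
        raise ValueError(
            "degenerate data: every participant gave the same answer in all "
            "conditions; Q is undefined"
        )
    q = k * (k - 1) * np.sum((col - col.mean()) ** 2) / denom
    df = k - 1
    return float(q), df, float(stats.chi2.sf(q, df))


def mcnemar_pair(
    x: np.ndarray,
    y: np.ndarray,
    continuity: bool = True,
    exact: bool = False,
) -> Tuple[float, float, float]:
    """McNemar test and odds ratio for two paired binary conditions.

    Returns ``(chi2, p, odds_ratio)``.  The statistic uses the
    continuity-corrected form ``(max(0, |b - c| - 1))^2 / (b + c)`` on
    the discordant counts (``exact=True`` replaces the chi-squared p
    with the exact binomial one).  With no discordant pairs the result
    is (0, 1, OR).  The odds ratio is odds(x) / odds(y) — pass the
    control condition first to follow the convention of control over
    experimental — with a Haldane-Anscombe 0.5 correction whenever a
    cell is empty.
    """
    x = np.asarray(x).astype(int)
    y = np.asarray(y).astype(int)
    if x.shape != y.shape:
        raise ValueError("paired conditions must have equal length")
    b = int(np.sum((x == 1) & (y == 0)))
    c = int(np.sum((x == 0) & (y == 1)))
    if b + c == 0:
        chi2, p = 0.0, 1.0
    elif exact:
        chi2 = float("nan")
        p = float(stats.binomtest(min(b, c), b + c, 0.5).pvalue)
    else:
        num = max(0.0, abs(b - c) - 1 if continuity else abs(b - c)) ** 2
        chi2 = num / (b + c)
        p = float(stats.chi2.sf(chi2, 1))

    def _odds(v: np.ndarray) -> float:
        yes, no = float(np.sum(v == 1)), float(np.sum(v == 0))
        if yes == 0 or no == 0:
            yes, no = yes + 0.5, no + 0.5
        return yes / no

    return float(chi2), p, _odds(x) / _odds(y)


def bh_fdr(p_values: Sequence[float], alpha: float = 0.05) -> Tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (adjusted p-values, rejections at alpha)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return p_adj, reject
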