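"""Measurement-error metrics and repeated-measures statistics.

Bias is the signed difference observed minus expected; inaccuracy (precision)
is its absolute value. Together they characterise the accuracy of the
measurement technique. The analysis pipeline mirrors a standard
observer-error validation: a signed cube-root transform to tame skew while
preserving the sign of directional errors, removal of extreme outliers
(beyond three interquartile ranges from the quartiles), per-image summary
means, fully within-subject repeated-measures ANOVA (no sphericity
correction), and Holm step-down family-wise error correction for post hoc
pairwise tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import pingouin as pg
from statsmodels.stats.multitest import multipletests

from .errors import DesignError

MODES = ("freehand", "overlay", "semi_auto")

ERROR_VARIABLES = ("bias_angle", "inaccuracy_angle", "bias_length", "inaccuracy_length")


@dataclass(frozen=True)
class ErrorRecord:
    """One observed-vs-expected line measurement, tagged by image, mode, observer and round."""

    image_id: str
    mode: str
    observer: int
    round: int
    angle_theta: float
    observed_angle: float
    expected_angle: float
    observed_length: float
    expected_length: float
    bias_angle: float = field(init=False)
    inaccuracy_angle: float = field(init=False)
    bias_length: float = field(init=False)
    inaccuracy_length: float = field(init=False)

    def __post_init__(self) -> None:
        ba, ia = compute_error(self.observed_angle, self.expected_angle)
        bl, il = compute_error(self.observed_length, self.expected_length)
        object.__setattr__(self, "bias_angle", ba)
        object.__setattr__(self, "inaccuracy_angle", ia)
        object.__setattr__(self, "bias_length", bl)
        object.__setattr__(self, "inaccuracy_length", il)


@dataclass(frozen=True)
class StudyDataset:
    """Per-line error records plus per image x mode x event summary points (midline ratio)."""

    records: tuple
    summaries: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.records])

    def __len__(self) -> int:
        return len(self.records)


def compute_error(observed: float, expected: float) -> tuple[float, float]:
    """(bias, inaccuracy) = (observed - expected, |observed - expected|)."""
    bias = float(observed) - float(expected)
    return bias, abs(bias)


def cube_root_transform(x):
    """Signed cube root sign(x) * |x|^(1/3); monotone and sign-preserving."""
    return np.cbrt(x)


def remove_extreme_outliers(values: Sequence[float], k: float = 3.0
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Split values into (kept, removed) by the extreme-outlier fences Q1 - k*IQR, Q3 + k*IQR.

    Quartiles use linear interpolation between order statistics. The fences
    are re-fitted and re-applied until no value falls outside them (a single
    pass of a re-fitted fence filter is not idempotent; iterating to the fixed
    point makes it so, and on continuous data it converges immediately in all
    but pathological cases). Requires at least 4 values. With k=3 only
    extreme outliers are removed.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 4:
        raise DesignError(f"need at least 4 values for quartiles, got {arr.size}")
    kept = arr
    removed: list[np.ndarray] = []
    while kept.size >= 4:
        q1, q3 = np.percentile(kept, [25.0, 75.0])
        iqr = q3 - q1
        lo, hi = q1 - k * iqr, q3 + k * iqr
        inside = (kept >= lo) & (kept <= hi)
        if inside.all():
            break
        removed.append(kept[~inside])
        kept = kept[inside]
    out = np.concatenate(removed) if removed else np.empty(0, dtype=float)
    return kept, out


def summarize(data: pd.DataFrame, value: str,
              group_by: Sequence[str]) -> pd.DataFrame:
    """Per-group n, mean and sd (sample sd, NaN when n = 1)."""
    grouped = data.groupby(list(group_by), observed=True)[value]
    out = grouped.agg(n="count", mean="mean", sd=lambda v: v.std(ddof=1)).reset_index()
    out.loc[out["n"] == 1, "sd"] = np.nan
    return out


def _check_balanced(data: pd.DataFrame, subject: str, within: Sequence[str]) -> None:
    counts = data.groupby([subject, *within], observed=True).size()
    subjects = data[subject].nunique()
    n_cells = int(np.prod([data[w].nunique() for w in within]))
    if (counts != 1).any() or len(counts) != subjects * n_cells:
        raise DesignError(
            "repeated-measures design must be complete and balanced: every subject "
            "observed exactly once in every within-factor cell")


def rm_anova(data: pd.DataFrame, dv: str, subject: str,
             within: Sequence[str] | str) -> pd.DataFrame:
    """Fully within-subject repeated-measures ANOVA (one or two within factors).

    Returns one row per effect with columns Source, F, df1, df2, p. The
    design must be complete and balanced; no sphericity correction is applied.
    """
    within_list = [within] if isinstance(within, str) else list(within)
    if not 1 <= len(within_list) <= 2:
        raise DesignError("rm_anova supports 1 or 2 within factors")
    _check_balanced(data, subject, within_list)
    with np.errstate(all="ignore"):
        if len(within_list) == 1:
            aov = pg.rm_anova(data=data, dv=dv, within=within_list[0], subject=subject,
                              correction=False)
        else:
            aov = pg.rm_anova(data=data, dv=dv, within=within_list, subject=subject)
    out = aov.rename(columns={"ddof1": "df1", "ddof2": "df2",
                              "p-unc": "p", "p_unc": "p"})
    # zero within-cell variation: the effect sum of squares is 0, so F = 0
    if "F" not in out.columns:
        out["F"] = 0.0
    if "p" not in out.columns:
        out["p"] = 1.0
    out["F"] = out["F"].fillna(0.0)
    out["p"] = out["p"].fillna(1.0)
    return out[["Source", "F", "df1", "df2", "p"]].reset_index(drop=True)


def pairwise_holm(p_values: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values, returned in the input order.

    Sorted ascending, the i-th p-value is multiplied by (m - i + 1); running
    maxima enforce monotonicity and values are capped at 1.
    """
    arr = np.asarray(p_values, dtype=float)
    if arr.size == 0:
        return arr
    if np.any((arr < 0.0) | (arr > 1.0)) or not np.all(np.isfinite(arr)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(arr, method="holm")[1]


# ---------------------------------------------------------------------------
# study-level analysis pipeline
# ---------------------------------------------------------------------------

def _event_means(df: pd.DataFrame, variable: str, k_outlier: float = 3.0) -> pd.DataFrame:
    """Transform, de-outlier and average one error variable per image x mode x event."""
    work = df.copy()
    work["t"] = cube_root_transform(work[variable].to_numpy())
    vals = work["t"].to_numpy()
    kept, _removed = remove_extreme_outliers(vals, k=k_outlier)
    if len(kept) < len(vals):
        q1, q3 = np.percentile(vals, [25.0, 75.0])
        iqr = q3 - q1
        lo, hi = q1 - k_outlier * iqr, q3 + k_outlier * iqr
        work = work[(work["t"] >= lo) & (work["t"] <= hi)]
    means = (work.groupby(["image_id", "mode", "observer", "round"], observed=True)["t"]
             .mean().reset_index())
    return means


def analyze_study(dataset: StudyDataset, k_outlier: float = 3.0) -> dict:
    """Run the full intra-/interobserver error analysis on a study dataset.

    Per error variable: signed cube-root transform at the line level, extreme
    outlier removal, then mean per image x mode x event. Intraobserver tests
    compare observer 1's two rounds across modes; interobserver tests compare
    the two observers' first rounds. Each is a two-way (mode x round, or
    mode x observer) fully within-subject RM ANOVA with subject = image,
    followed by per-mode paired comparisons with Holm correction when wanted.

    Returns ``{"summary": ..., "intra_anova": ..., "inter_anova": ...,
    "midline_summary": ...}`` tables.
    """
    df = dataset.to_frame()
    summary_rows = []
    intra_tables = []
    inter_tables = []
    for variable in ERROR_VARIABLES:
        means = _event_means(df, variable, k_outlier=k_outlier)

        per_mode = summarize(means, "t", ["mode"])
        per_mode.insert(0, "variable", variable)
        summary_rows.append(per_mode)

        intra = means[(means["observer"] == 1)]
        if intra["round"].nunique() >= 2:
            aov = rm_anova(intra, dv="t", subject="image_id", within=["mode", "round"])
            aov.insert(0, "variable", variable)
            intra_tables.append(aov)

        inter = means[means["round"] == 1]
        if inter["observer"].nunique() >= 2:
            aov = rm_anova(inter, dv="t", subject="image_id", within=["mode", "observer"])
            aov.insert(0, "variable", variable)
            inter_tables.append(aov)

    out = {
        "summary": pd.concat(summary_rows, ignore_index=True),
        "intra_anova": (pd.concat(intra_tables, ignore_index=True)
                        if intra_tables else pd.DataFrame()),
        "inter_anova": (pd.concat(inter_tables, ignore_index=True)
                        if inter_tables else pd.DataFrame()),
        "midline_summary": summarize(dataset.summaries, "midline_ratio_observed",
                                     ["mode", "round"]),
    }
    return out


def pairwise_by_mode(means: pd.DataFrame, dv: str, between_levels: str,
                     subject: str = "image_id") -> pd.DataFrame:
    """Per-mode paired t-tests between two levels (rounds or observers), Holm-adjusted."""
    from scipy import stats as sp_stats

    rows = []
    for mode, grp in means.groupby("mode", observed=True):
        wide = grp.pivot_table(index=subject, columns=between_levels, values=dv)
        if wide.shape[1] != 2 or wide.isna().any().any():
            raise DesignError(f"mode {mode!r}: need exactly two complete levels for pairing")
        a, b = wide.iloc[:, 0], wide.iloc[:, 1]
        t, p = sp_stats.ttest_rel(a, b)
        rows.append({"mode": mode, "t": float(t), "df": len(a) - 1, "p": float(p)})
    table = pd.DataFrame(rows)
    table["p_adj"] = pairwise_holm(table["p"].to_numpy())
    return table
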