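"""ROI grayscale-trend analysis and run-level report rendering.

The trend analysis asks, per facial region, whether the mean gray level
(a proxy for skin temperature) shifts between emotional states.  Each
participant contributes one mean gray value per ROI per state (baseline,
positive, negative); paired two-sided Student's t-tests across participants
compare the three contrasts (P vs Base, N vs Base, P vs N) for each of the
five ROIs, and the 15 p-values are Bonferroni-corrected.  Significance
categories: ``***`` (p <= 0.001), ``**`` (p <= 0.01), ``*`` (p <= 0.05) on
the corrected p-value, ``N`` otherwise.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ThermaffectError
from .types import BASELINE, ROI_NAMES

#: The three state contrasts, as (minuend state, subtrahend state, label).
CONTRASTS: tuple[tuple[str, str, str], ...] = (
    ("positive", BASELINE, "P vs Base"),
    ("negative", BASELINE, "N vs Base"),
    ("positive", "negative", "P vs N"),
)


def significance_category(p_corrected: float) -> str:
    if p_corrected <= 0.001:
        return "***"
    if p_corrected <= 0.01:
        return "**"
    if p_corrected <= 0.05:
        return "*"
    return "N"


def roi_trends(
    state_means: pd.DataFrame,
    contrasts: tuple[tuple[str, str, str], ...] = CONTRASTS,
) -> pd.DataFrame:
    """Paired t-tests of per-participant ROI means across state contrasts.

    ``state_means`` needs columns ``participant``, ``roi``, ``state`` and
    ``mean_gray`` with one row per participant x ROI x state.  Returns one
    row per ROI x contrast with the mean paired difference (gray levels),
    the t statistic, raw and Bonferroni-corrected p-values (corrected over
    all ROI x contrast tests) and the significance category.
    """
    required = {"participant", "roi", "state", "mean_gray"}
    missing = required - set(state_means.columns)
    if missing:
        raise ValueError(f"state_means missing columns: {sorted(missing)}")
    n_participants = state_means["participant"].nunique()
    if n_participants < 3:
        raise ThermaffectError(
            f"trend analysis needs >= 3 participants, got {n_participants}"
        )
    wide = state_means.pivot_table(
        index="participant", columns=["roi", "state"], values="mean_gray"
    )
    n_tests = len(ROI_NAMES) * len(contrasts)
    rows = []
    for roi in ROI_NAMES:
        for state_a, state_b, label in contrasts:
            a = wide[(roi, state_a)]
            b = wide[(roi, state_b)]
            paired = pd.concat([a, b], axis=1).dropna()
            if len(paired) < 3:
                raise ThermaffectError(
                    f"contrast {label!r} for {roi} has fewer than 3 paired participants"
                )
            diff = paired.iloc[:, 0] - paired.iloc[:, 1]
            t_stat, p_raw = stats.ttest_rel(paired.iloc[:, 0], paired.iloc[:, 1])
            p_corr = min(1.0, float(p_raw) * n_tests)
            rows.append(
                {
                    "roi": roi,
                    "contrast": label,
                    "mean_diff": float(diff.mean()),
                    "t": float(t_stat),
                    "p_raw": float(p_raw),
                    "p_corrected": p_corr,
                    "significance": significance_category(p_corr),
                }
            )
    return pd.DataFrame(rows)


def state_mean_table(roi_mean_rows: pd.DataFrame) -> pd.DataFrame:
    """Collapse per-frame ROI means into the participant x ROI x state table.

    Input columns: ``participant``, ``state``, ``roi``, ``mean_gray`` with
    one row per frame x ROI; frames of the same participant and state are
    averaged (pooling the two sessions of equal valence sign).
    """
    return (
        roi_mean_rows.groupby(["participant", "roi", "state"], as_index=False)["mean_gray"]
        .mean()
    )


def render_report(
    eval_tables: dict[str, pd.DataFrame],
    trends: pd.DataFrame | None,
    outdir: str | Path,
) -> str:
    """Write CSV tables (metrics per group x task, trends) and a summary.

    ``eval_tables`` maps a metric name (e.g. ``accuracy``, ``f1``) to a
    DataFrame with one row per test group plus a ``Mean`` row and one
    column per task.  Values are formatted to 4 decimals.  Pure
    formatting — no numbers are computed here.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    lines = []
    for metric, table in eval_tables.items():
        formatted = table.map(lambda v: f"{v:.4f}" if pd.notna(v) else "")
        path = outdir / f"{metric}.csv"
        formatted.to_csv(path)
        lines.append(f"== {metric} ==")
        lines.append(formatted.to_string())
        lines.append("")
    if trends is not None:
        trend_out = trends.copy()
        for col in ("mean_diff", "t", "p_raw", "p_corrected"):
            if col in trend_out.columns:
                trend_out[col] = trend_out[col].map(lambda v: f"{v:.4f}")
        trend_out.to_csv(outdir / "trends.csv", index=False)
        lines.append("== ROI grayscale trends ==")
        lines.append(trend_out.to_string(index=False) if len(trend_out) else "(empty)")
        lines.append("")
    summary = "\n".join(lines)
    (outdir / "summary.txt").write_text(summary)
    return summary
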