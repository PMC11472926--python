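"""Figure-legend statistics, the ERK-activity / cluster correlation, and
report assembly.

The statistical tests mirror the conventions of the source experiments:
two-sample Kolmogorov-Smirnov on pooled death-time distributions for
elimination-curve comparisons, two-sided Mann-Whitney for value
comparisons, and Pearson correlation between the mean nuclear/cytoplasmic
reporter ratio (high = low ERK) and the clustered-death count across
condition-phase points.  No multiple-testing correction is applied (none
is applied in the source analyses); the report footer flags this.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class ConditionSummary:
    """Per-condition (or condition x phase) summary point."""

    name: str
    mean_ratio: float            # mean nuclear/cytoplasmic reporter ratio
    clustered_count: float       # cells dying in clusters
    replicate_ratios: tuple[float, ...] = ()
    replicate_counts: tuple[float, ...] = ()


def ks_compare(death_times_a, death_times_b) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test on pooled death-time samples
    (the elimination-curve comparison).  Returns (D, p)."""
    a = np.asarray(death_times_a, float)
    b = np.asarray(death_times_b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 deaths")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def mw_compare(values_a, values_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.  Returns (U of the first sample, p)."""
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("samples must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def correlate_activity_clusters(
    summaries: list[ConditionSummary],
) -> tuple[float, float]:
    """Pearson r (and p) between mean nuclear/cytoplasmic ratio and
    clustered-death count across condition points.

    A positive r means: the higher the nuclear reporter (the lower ERK
    activity), the more clustered deaths.  Zero variance in either
    coordinate yields (NaN, NaN) with a warning.
    """
    if len(summaries) < 3:
        raise ValueError("need at least 3 condition points")
    x = np.asarray([s.mean_ratio for s in summaries], float)
    y = np.asarray([s.clustered_count for s in summaries], float)
    if np.std(x) == 0 or np.std(y) == 0:
        logger.warning("zero variance in a coordinate; correlation undefined")
        return float("nan"), float("nan")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# Report assembly

def build_report(sections: dict) -> tuple[str, dict]:
    """Assemble a human-readable report and its machine-readable twin.

    ``sections`` maps section name to a dict of scalars / small tables
    (``pandas`` objects are serialized to records).  Missing sections are
    marked absent; the run continues.  Returns ``(text, data)`` where every
    number in ``text`` also appears in ``data``.
    """
    known = [
        "elimination", "clusters", "null_comparison",
        "phase_proportions", "pulses", "correlation",
    ]
    data: dict = {}
    lines = ["apoclust analysis report", "=" * 24, ""]
    for name in known + [k for k in sections if k not in known]:
        lines.append(f"[{name}]")
        if name not in sections or sections[name] is None:
            lines.append("  (absent)")
            lines.append("")
            continue
        content = sections[name]
        serial: dict = {}
        for key, val in content.items():
            if isinstance(val, (pd.DataFrame, pd.Series)):
                serial[key] = json.loads(val.to_json(orient="split"))
                lines.append(f"  {key}: table ({len(val)} rows)")
            elif isinstance(val, (int, float, np.floating, np.integer)):
                serial[key] = float(val)
                lines.append(f"  {key}: {float(val):.6g}")
            else:
                serial[key] = val
                lines.append(f"  {key}: {val}")
        data[name] = serial
        lines.append("")
    lines.append("note: no multiple-testing correction applied")
    data["_footer"] = {"multiple_testing_correction": "none"}
    return "\n".join(lines), data
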