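"""Time-to-onset: days from suspect-drug therapy start to event onset.

Per cohort report the latency is ``event_dt - earliest full-precision
therapy start date`` of the matched suspect drug.  Reports are excluded (and
tallied by reason) when either date is missing, only partially dated, or the
difference is negative; a same-day start and event counts as onset 0.

The summary gives n, median, quartiles and a binned distribution.  Default
quantile rule: even-n medians are the midpoint of the central order
statistics and quartiles are Tukey hinges (median of each half, including
the middle value when n is odd); ``method="linear"`` switches to linear
interpolation.  Default bins are [0, 37], [38, 74], ... — width-37 spans
mirroring the conventional first-five-weeks window of onset analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .faers import parse_faers_date

EXCLUSION_REASONS = ("missing_date", "partial_date", "negative")


@dataclass
class OnsetSummary:
    n: int
    median_days: float | None
    q1: float | None
    q3: float | None
    bins: list[tuple[int, int, int, float]] = field(default_factory=list)
    max_days: int | None = None

    def bins_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.bins, columns=["lo", "hi", "count", "percent"])


def compute_onset(event_reports: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-report onset days and an exclusion tally.

    Input: the cohort's event reports (``event_dt``, ``ther_start_dt``,
    ``ther_start_status`` columns).  One onset per (report, drug) even when
    several event terms matched — the event date is report-level.

    Returns ``(records, exclusions)``: records with columns primaryid, drug,
    onset_days; exclusions long-format (drug, reason, count).
    """
    base = event_reports.drop_duplicates(["primaryid", "drug"]) if len(event_reports) else event_reports
    rows = []
    tally: dict[tuple[str, str], int] = {}

    def exclude(drug: str, reason: str) -> None:
        tally[(drug, reason)] = tally.get((drug, reason), 0) + 1

    for row in base.itertuples(index=False):
        event = parse_faers_date(row.event_dt)
        if event.precision == "missing":
            exclude(row.drug, "missing_date")
            continue
        if not event.is_full:
            exclude(row.drug, "partial_date")
            continue
        status = getattr(row, "ther_start_status", "full")
        start_raw = getattr(row, "ther_start_dt", "")
        if status == "missing" or (status == "full" and not start_raw):
            exclude(row.drug, "missing_date")
            continue
        if status == "partial":
            exclude(row.drug, "partial_date")
            continue
        start = parse_faers_date(start_raw)
        if not start.is_full:
            exclude(row.drug, "partial_date" if start.precision != "missing" else "missing_date")
            continue
        days = (event.to_date() - start.to_date()).days
        if days < 0:
            exclude(row.drug, "negative")
            continue
        rows.append({"primaryid": row.primaryid, "drug": row.drug, "onset_days": days})

    records = pd.DataFrame(rows, columns=["primaryid", "drug", "onset_days"])
    exclusions = pd.DataFrame(
        [{"drug": d, "reason": r, "count": c} for (d, r), c in sorted(tally.items())],
        columns=["drug", "reason", "count"],
    )
    return records, exclusions


def _median(sorted_values: np.ndarray) -> float:
    n = len(sorted_values)
    mid = n // 2
    if n % 2:
        return float(sorted_values[mid])
    return float(sorted_values[mid - 1] + sorted_values[mid]) / 2.0


def tukey_hinges(values) -> tuple[float, float, float]:
    """(q1, median, q3) by Tukey's hinge rule (halves include the median
    value when n is odd)."""
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    if n == 0:
        raise ValueError("no values")
    if n == 1:
        return float(x[0]), float(x[0]), float(x[0])
    med = _median(x)
    half = (n + 1) // 2  # lower half includes the middle value for odd n
    return _median(x[:half]), med, _median(x[n - half:])


def summarize_onset(
    records: pd.DataFrame,
    bin_width: int = 37,
    method: str = "tukey",
) -> OnsetSummary:
    """Median, quartiles and the binned onset distribution.

    Bin k covers [k*w+1, (k+1)*w] days except bin 0 which covers [0, w];
    percents are to one decimal; an empty record set yields an empty summary.
    """
    values = records["onset_days"].to_numpy(dtype=float) if len(records) else np.array([])
    if len(values) == 0:
        return OnsetSummary(n=0, median_days=None, q1=None, q3=None, bins=[])
    if method == "tukey":
        q1, med, q3 = tukey_hinges(values)
    elif method == "linear":
        q1, med, q3 = (float(np.quantile(values, q)) for q in (0.25, 0.5, 0.75))
    else:
        raise ValueError(f"unknown quantile method {method!r}")
    n = len(values)
    w = int(bin_width)
    idx = np.where(values <= w, 0, (values.astype(int) - 1) // w)
    bins = []
    for k in range(int(idx.max()) + 1):
        lo = 0 if k == 0 else k * w + 1
        hi = (k + 1) * w
        count = int(np.sum(idx == k))
        bins.append((lo, hi, count, round(100.0 * count / n, 1)))
    return OnsetSummary(
        n=n, median_days=med, q1=q1, q3=q3, bins=bins, max_days=int(values.max()),
    )


def summarize_onset_by_drug(records: pd.DataFrame, bin_width: int = 37, method: str = "tukey") -> dict[str, OnsetSummary]:
    out = {}
    for drug in sorted(records["drug"].unique()) if len(records) else []:
        out[drug] = summarize_onset(records[records["drug"] == drug], bin_width=bin_width, method=method)
    return out


def plot_onset(summaries: dict[str, OnsetSummary], path=None):
    """Bar chart of the binned onset distribution per drug (optional)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    drugs = list(summaries)
    width = 0.8 / max(len(drugs), 1)
    max_bins = max((len(s.bins) for s in summaries.values()), default=0)
    for i, drug in enumerate(drugs):
        s = summaries[drug]
        heights = [b[3] for b in s.bins] + [0.0] * (max_bins - len(s.bins))
        ax.bar(np.arange(max_bins) + i * width, heights, width=width, label=drug)
    if max_bins:
        ref = max(summaries.values(), key=lambda s: len(s.bins))
        labels = [f"{lo}-{hi}" for lo, hi, _, _ in ref.bins]
        ax.set_xticks(np.arange(max_bins) + 0.4 - width / 2)
        ax.set_xticklabels(labels, rotation=45, ha="right")
    ax.set_xlabel("days from therapy start to onset")
    ax.set_ylabel("% of reports")
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
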