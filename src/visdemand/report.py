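"""Aggregate summaries: dual task rankings, scene-code distributions,
metric distribution summaries, and narrative word frequencies."""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from visdemand.coding import SceneCode, TaskRecord
from visdemand.metrics import SceneMetrics


@dataclass
class RankingTable:
    """Dual task ranking.

    ``table`` has one row per task label with snapshot counts (every
    occurrence counts) and participant counts (each participant counts at
    most once per task), the derived percentages, and both rank orders.
    ``snapshot_pct`` is relative to all records; ``participant_pct`` is
    relative to all distinct participants and does not sum to 100.
    """

    table: pd.DataFrame
    n_records: int
    n_participants: int


def _ranked(counts: pd.Series) -> pd.Series:
    # ties broken alphabetically for deterministic output
    order = counts.reset_index()
    order.columns = ["task_label", "count"]
    order = order.sort_values(["count", "task_label"], ascending=[False, True])
    return pd.Series(
        np.arange(1, len(order) + 1), index=order["task_label"], name="rank"
    )


def rank_tasks(records: Sequence[TaskRecord]) -> RankingTable:
    """Rank tasks by snapshot frequency and by participant prevalence."""
    if not records:
        return RankingTable(
            table=pd.DataFrame(
                columns=[
                    "snapshot_count",
                    "snapshot_pct",
                    "participant_count",
                    "participant_pct",
                    "rank_by_snapshot",
                    "rank_by_participant",
                ]
            ),
            n_records=0,
            n_participants=0,
        )
    df = pd.DataFrame(
        {
            "task_label": [r.task_label for r in records],
            "participant_id": [r.participant_id for r in records],
        }
    )
    n_records = len(df)
    n_participants = df["participant_id"].nunique()
    snap = df.groupby("task_label").size()
    part = df.groupby("task_label")["participant_id"].nunique()
    table = pd.DataFrame(
        {
            "snapshot_count": snap,
            "snapshot_pct": 100.0 * snap / n_records,
            "participant_count": part,
            "participant_pct": 100.0 * part / n_participants,
            "rank_by_snapshot": _ranked(snap),
            "rank_by_participant": _ranked(part),
        }
    ).sort_values(["rank_by_snapshot"])
    table.index.name = "task_label"
    return RankingTable(table=table, n_records=n_records, n_participants=n_participants)


def distribution_by_classifier(codes: Sequence[SceneCode]) -> pd.DataFrame:
    """Category share per classifier, as percentage of all snapshots.

    Returns a long-form frame (classifier, category, pct); percentages sum
    to 100 within each classifier.
    """
    if not codes:
        return pd.DataFrame(columns=["classifier", "category", "pct"])
    n = len(codes)
    rows = []
    for name in codes[0].values:
        counts: dict[str, int] = {}
        for code in codes:
            counts[code.values[name]] = counts.get(code.values[name], 0) + 1
        for category in sorted(counts):
            rows.append(
                {
                    "classifier": name,
                    "category": category,
                    "pct": 100.0 * counts[category] / n,
                }
            )
    return pd.DataFrame(rows)


def summarize_metric_distributions(
    metrics: Sequence[SceneMetrics], hist_bins: int = 20
) -> tuple[pd.DataFrame, dict[str, tuple[np.ndarray, np.ndarray]]]:
    """Mean/SD/min/max per metric plus proportion-normalized histograms.

    SD uses the n−1 denominator; a single-image input reports SD 0 with a
    degenerate-sample warning. Histogram counts are expressed as
    proportions of images (sum to 1).
    """
    if not metrics:
        raise ValueError("empty metric list")
    if len(metrics) == 1:
        warnings.warn(
            "metric summary over a single image: SD reported as 0", stacklevel=2
        )
    rows = []
    hists: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for name in SceneMetrics.FIELDS:
        vals = np.array([getattr(m, name) for m in metrics], dtype=float)
        sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
        rows.append(
            {
                "metric": name,
                "mean": float(np.mean(vals)),
                "sd": sd,
                "min": float(np.min(vals)),
                "max": float(np.max(vals)),
                "n": vals.size,
            }
        )
        counts, edges = np.histogram(vals, bins=hist_bins)
        hists[name] = (counts / vals.size, edges)
    return pd.DataFrame(rows), hists


_TOKEN_RE = re.compile(r"[^0-9a-z]+")


def default_stopwords() -> frozenset[str]:
    text = resources.files("visdemand.data").joinpath("stopwords.txt").read_text()
    return frozenset(
        line.strip()
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    )


def word_frequency(
    narratives: Iterable[str],
    lexicon: Mapping[str, str] | None = None,
    stopwords: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Ranked word counts over narrative texts.

    Tokenization is case-folded on non-alphanumeric boundaries; an
    optional ``lexicon`` maps inflected forms to stems ("reading" →
    "read") before counting; stop-words are dropped. Percentages are
    relative to the retained tokens; the total is recorded in
    ``df.attrs["total_tokens"]``.
    """
    stop = frozenset(stopwords) if stopwords is not None else default_stopwords()
    lexicon = dict(lexicon or {})
    counts: dict[str, int] = {}
    total = 0
    for text in narratives:
        for token in _TOKEN_RE.split(str(text).casefold()):
            if not token:
                continue
            token = lexicon.get(token, token)
            if token in stop:
                continue
            counts[token] = counts.get(token, 0) + 1
            total += 1
    df = pd.DataFrame(
        sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["word", "count"],
    )
    df["pct"] = 100.0 * df["count"] / total if total else []
    df.attrs["total_tokens"] = total
    return df


def format_pct(value: float) -> str:
    """Rendered-table rounding: whole percent, but one decimal below 1%."""
    if 0 < value < 1:
        return f"{value:.1f}%"
    return f"{value:.0f}%"


def render_ranking(ranking: RankingTable, round_pct: bool = True) -> pd.DataFrame:
    """Human-readable ranking table (percentages rounded for display)."""
    table = ranking.table.copy()
    if round_pct:
        table["snapshot_pct"] = table["snapshot_pct"].map(format_pct)
        table["participant_pct"] = table["participant_pct"].map(format_pct)
    return table
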