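"""Diagnostic evaluation statistics for program-vs-reference grade records.

Given paired ordinal grades — the program's call and an automated urine
analyzer's call for the same specimen — this module computes the agreement
measures used to validate strip readers: exact concordance, ±k-rank
concordance (a reader one ordinal step off is still clinically useful for
screening), per-analyte summaries with an unweighted cross-analyte mean,
2×2 sensitivity/specificity at a binary disease threshold (e.g. urinary
albumin ≥ 30 mg/L for microalbuminuria), and the ROC curve with
tie-corrected AUC.

Percentages are reported rounded half-up to one decimal, the convention of
clinical concordance tables.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve

from .errors import EvaluationError

__all__ = [
    "ConcordanceRecord",
    "CrossTable2x2",
    "round_half_up",
    "concordance_rate",
    "within_rank_rate",
    "summarize_by_analyte",
    "mean_over_analytes",
    "sensitivity_specificity",
    "crosstable_from_ranks",
    "roc_curve_auc",
    "read_records_csv",
    "write_summary_csv",
    "write_metrics_json",
    "plot_roc",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConcordanceRecord:
    """One specimen×analyte pair of ordinal grades."""

    analyte: str
    program_rank: int
    reference_rank: int


@dataclass(frozen=True)
class CrossTable2x2:
    """TP/FP/FN/TN counts for a binary diagnostic threshold."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round with ties away from zero at the given decimal, as tables print."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def _ranks(records) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(records, pd.DataFrame):
        prog = records["program_rank"].to_numpy()
        ref = records["reference_rank"].to_numpy()
    else:
        recs = list(records)
        prog = np.array([r.program_rank for r in recs])
        ref = np.array([r.reference_rank for r in recs])
    if len(prog) == 0:
        raise EvaluationError("no records to evaluate")
    if (prog < 0).any() or (ref < 0).any():
        raise EvaluationError("ranks must be non-negative")
    return prog, ref


def concordance_rate(records) -> float:
    """Percent of records whose program and reference ranks agree exactly."""
    prog, ref = _ranks(records)
    return round_half_up(100.0 * np.count_nonzero(prog == ref) / len(prog))


def within_rank_rate(records, k: int = 1) -> float:
    """Percent of records with |program − reference| ≤ k ranks."""
    if k < 0:
        raise EvaluationError(f"k must be >= 0, got {k}")
    prog, ref = _ranks(records)
    return round_half_up(100.0 * np.count_nonzero(np.abs(prog - ref) <= k) / len(prog))


def summarize_by_analyte(records, k: int = 1) -> pd.DataFrame:
    """Per-analyte exact and ±k concordance with sample counts.

    Returns a DataFrame indexed by analyte with columns
    ``exact_pct``, ``within{k}_pct``, ``n`` (layout order not preserved;
    rows are sorted by first appearance).
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        df = pd.DataFrame([vars(r) for r in records])
    if df.empty:
        raise EvaluationError("no records to evaluate")
    rows = []
    for name in df["analyte"].drop_duplicates():
        sub = df[df["analyte"] == name]
        rows.append(
            {
                "analyte": name,
                "exact_pct": concordance_rate(sub),
                f"within{k}_pct": within_rank_rate(sub, k),
                "n": len(sub),
            }
        )
    return pd.DataFrame(rows).set_index("analyte")


def mean_over_analytes(exact_rates, within_rates) -> tuple[float, float]:
    """Unweighted cross-analyte means of the two concordance columns.

    The mean is over analytes, not pooled over specimens, matching the
    "average of 12 items" convention of clinical concordance tables.
    """
    exact = np.asarray(list(exact_rates), dtype=float)
    within = np.asarray(list(within_rates), dtype=float)
    if exact.size == 0 or within.size == 0:
        raise EvaluationError("need at least one analyte")
    return round_half_up(float(exact.mean())), round_half_up(float(within.mean()))


def sensitivity_specificity(ct: CrossTable2x2) -> tuple[float, float]:
    """(sensitivity %, specificity %) from a 2×2 table, half-up 1 decimal."""
    if ct.tp + ct.fn == 0:
        raise EvaluationError("no diseased specimens: sensitivity undefined")
    if ct.tn + ct.fp == 0:
        raise EvaluationError("no disease-free specimens: specificity undefined")
    sens = 100.0 * ct.tp / (ct.tp + ct.fn)
    spec = 100.0 * ct.tn / (ct.tn + ct.fp)
    return round_half_up(sens), round_half_up(spec)


def crosstable_from_ranks(program_ranks, disease, threshold_rank: int) -> CrossTable2x2:
    """Build the 2×2 table: program positive iff rank ≥ threshold_rank."""
    prog = np.asarray(program_ranks)
    dis = np.asarray(disease, dtype=bool)
    if prog.shape != dis.shape:
        raise EvaluationError("program_ranks and disease labels differ in length")
    pos = prog >= threshold_rank
    return CrossTable2x2(
        tp=int(np.count_nonzero(pos & dis)),
        fp=int(np.count_nonzero(pos & ~dis)),
        fn=int(np.count_nonzero(~pos & dis)),
        tn=int(np.count_nonzero(~pos & ~dis)),
    )


def roc_curve_auc(scores, labels) -> tuple[np.ndarray, float]:
    """ROC points and tie-corrected AUC.

    ``scores`` are the program's outputs (ordinal grade indices or any
    continuous score, higher = more diseased); ``labels`` are binary
    disease status.  The AUC equals the Mann–Whitney probability that a
    diseased specimen outscores a disease-free one, with tied pairs
    counting 0.5.  ROC points (fpr, tpr) are emitted at every distinct
    score threshold.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if s.size != y.size or s.size == 0:
        raise EvaluationError("scores and labels must be equal-length and non-empty")
    classes = np.unique(y)
    if len(classes) != 2:
        raise EvaluationError(f"need both classes present, got {classes}")
    fpr, tpr, _ = roc_curve(y, s, drop_intermediate=False)
    auc = float(roc_auc_score(y, s))
    return np.column_stack([fpr, tpr]), auc


def read_records_csv(path, label_maps: dict[str, dict[str, int]] | None = None,
                     layout=None) -> pd.DataFrame:
    """Read paired grade records.

    Expected columns: ``specimen_id, analyte, program_label, reference_label``
    (rank columns ``program_rank``/``reference_rank`` are accepted directly
    if present).  Labels are mapped to ordinal ranks through ``label_maps``
    (analyte → {label: rank}) or through a :class:`~uristrip.layout.ChartLayout`;
    records whose label cannot be mapped are dropped with a logged count.
    """
    try:
        df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise EvaluationError(f"cannot read records CSV {path}: {exc}") from exc
    if df.empty:
        raise EvaluationError(f"records CSV {path} contains no rows")
    have_ranks = {"program_rank", "reference_rank"} <= set(df.columns)
    need = {"analyte"} | (
        set() if have_ranks else {"program_label", "reference_label"}
    )
    missing = need - set(df.columns)
    if missing:
        raise EvaluationError(
            f"records CSV {path}: missing column(s) {sorted(missing)}; "
            f"found {list(df.columns)}"
        )
    if have_ranks:
        out = df.copy()
        out["program_rank"] = out["program_rank"].astype(int)
        out["reference_rank"] = out["reference_rank"].astype(int)
        return out

    maps: dict[str, dict[str, int]] = dict(label_maps or {})
    if layout is not None:
        for a in layout.analytes:
            maps.setdefault(a.name, {g.label: g.rank for g in a.grades})
    if not maps:
        raise EvaluationError(
            "label columns present but no label→rank mapping supplied "
            "(pass label_maps or a layout)"
        )

    def _map(row, col):
        m = maps.get(row["analyte"])
        if m is None:
            return None
        return m.get(str(row[col]).strip())

    df = df.copy()
    df["program_rank"] = df.apply(_map, axis=1, col="program_label")
    df["reference_rank"] = df.apply(_map, axis=1, col="reference_label")
    bad = df["program_rank"].isna() | df["reference_rank"].isna()
    if bad.any():
        logger.warning("dropping %d record(s) with unmappable labels", int(bad.sum()))
    df = df[~bad]
    if df.empty:
        raise EvaluationError("no records remain after label mapping")
    df["program_rank"] = df["program_rank"].astype(int)
    df["reference_rank"] = df["reference_rank"].astype(int)
    return df


def write_summary_csv(summary: pd.DataFrame, path) -> None:
    """Write the per-analyte summary plus a cross-analyte mean row."""
    cols = list(summary.columns)
    within_col = next(c for c in cols if c.startswith("within"))
    mean_exact, mean_within = mean_over_analytes(
        summary["exact_pct"], summary[within_col]
    )
    with open(path, "w", newline="") as f:
        w = csv.writer(f, quoting=csv.QUOTE_NONNUMERIC)
        w.writerow(["analyte", "exact_pct", within_col, "n"])
        for name, row in summary.iterrows():
            w.writerow([name, row["exact_pct"], row[within_col], int(row["n"])])
        w.writerow(["mean", mean_exact, mean_within, ""])


def write_metrics_json(ct: CrossTable2x2, path, roc: tuple[np.ndarray, float] | None = None) -> None:
    sens, spec = sensitivity_specificity(ct)
    doc = {
        "crosstable": {"tp": ct.tp, "fp": ct.fp, "fn": ct.fn, "tn": ct.tn},
        "sensitivity_pct": sens,
        "specificity_pct": spec,
    }
    if roc is not None:
        points, auc = roc
        doc["auc"] = auc
        doc["roc_points"] = [[float(a), float(b)] for a, b in points]
    Path(path).write_text(json.dumps(doc, indent=2))


def plot_roc(points: np.ndarray, auc: float, path) -> None:
    """Save a ROC plot (optional output; requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(points[:, 0], points[:, 1], drawstyle="steps-post", label=f"AUC = {auc:.3f}")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
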