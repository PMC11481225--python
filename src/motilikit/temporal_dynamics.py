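"""Linking short-duration behavior classes across time within single cells.

Each 8-h trajectory (5-min interval) is cut into three non-overlapping
2.5-h segments T1, T2, T3; every segment is profiled and classified into the
short-duration clusters/classes, and the full 8-h trajectory into the
long-duration ones.  Transition tables between consecutive stages (T1->T2,
T2->T3, T3->C), per-class stability fractions and Sankey-ready flow listings
summarize the temporal dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from motilikit.classification import ClassifierBundle, predict_cluster
from motilikit.clustering import ClusterModel
from motilikit.aprw import PARAMETER_NAMES, profile_cell
from motilikit.trajectory_io import (
    TrajectorySet,
    segment_trajectory,
    truncate_trajectory,
)

SHORT_WINDOW = 150.0  # minutes per segment
LONG_DURATION = 480.0  # minutes of the long-duration trajectory
STAGES = ("T1", "T2", "T3", "C")


@dataclass
class TransitionTable:
    """Joint distribution over ordered class pairs for one stage step."""

    step: str  # e.g. "T1->T2"
    counts: pd.DataFrame  # rows: from-class, cols: to-class

    @property
    def probabilities(self) -> pd.DataFrame:
        total = self.counts.to_numpy().sum()
        return self.counts / total if total else self.counts * np.nan

    @property
    def n(self) -> int:
        return int(self.counts.to_numpy().sum())


def _fit_params_row(traj) -> dict | None:
    try:
        params, fit, _ = profile_cell(traj)
    except (ValueError, FloatingPointError):
        return None
    row = {k: getattr(params, k) for k in PARAMETER_NAMES}
    if any(not np.isfinite(v) or v <= 0 for v in row.values()):
        return None
    return row


def build_transition_records(
    ts: TrajectorySet,
    short_model: ClusterModel,
    long_model: ClusterModel,
    short_bundle: ClassifierBundle,
    long_bundle: ClassifierBundle,
) -> tuple[pd.DataFrame, int]:
    """Per-cell behavior-class labels for segments T1-T3 and the 8-h class.

    Trajectories shorter than 8 h, non-uniform, or with any failed segment
    fit are excluded and counted.  Returns ``(records, n_excluded)`` with
    one row per retained cell: cluster and class per segment and for the
    full duration.
    """
    records, excluded = [], 0
    for traj in ts.trajectories:
        if not traj.is_uniform or traj.duration < LONG_DURATION - 1e-9:
            excluded += 1
            continue
        long_traj = truncate_trajectory(traj, LONG_DURATION)
        segments = segment_trajectory(long_traj, SHORT_WINDOW)[:3]
        if len(segments) < 3:
            excluded += 1
            continue
        rows = [_fit_params_row(seg) for seg in segments]
        long_row = _fit_params_row(long_traj)
        if long_row is None or any(r is None for r in rows):
            excluded += 1
            continue
        rec = {"condition_id": traj.condition_id, "cell_id": traj.cell_id}
        for stage, row in zip(("T1", "T2", "T3"), rows):
            pred = predict_cluster(
                short_bundle,
                pd.DataFrame([row]),
                model=short_model,
            )
            rec[f"cluster_{stage}"] = short_model.cluster_label(
                pred["cluster"].iloc[0]
            )
            rec[f"class_{stage}"] = pred["behavior_class"].iloc[0]
        pred = predict_cluster(
            long_bundle, pd.DataFrame([long_row]), model=long_model
        )
        rec["cluster_C"] = long_model.cluster_label(pred["cluster"].iloc[0])
        rec["class_C"] = pred["behavior_class"].iloc[0]
        records.append(rec)
    return pd.DataFrame(records), excluded


def _pair_counts(
    from_labels: pd.Series,
    to_labels: pd.Series,
    from_alphabet: list[str],
    to_alphabet: list[str],
) -> pd.DataFrame:
    counts = pd.crosstab(from_labels, to_labels)
    return counts.reindex(
        index=from_alphabet, columns=to_alphabet, fill_value=0
    )


def transition_tables(
    records: pd.DataFrame,
    short_classes: list[str] | None = None,
    long_classes: list[str] | None = None,
) -> dict[str, TransitionTable]:
    """Joint class-pair tables for the steps T1->T2, T2->T3 and T3->C."""
    if records.empty:
        raise ValueError("no transition records")
    if short_classes is None:
        short_classes = sorted(
            set(records["class_T1"])
            | set(records["class_T2"])
            | set(records["class_T3"])
        )
    if long_classes is None:
        long_classes = sorted(set(records["class_C"]))
    steps = {
        "T1->T2": ("class_T1", "class_T2", short_classes, short_classes),
        "T2->T3": ("class_T2", "class_T3", short_classes, short_classes),
        "T3->C": ("class_T3", "class_C", short_classes, long_classes),
    }
    return {
        step: TransitionTable(
            step,
            _pair_counts(records[a], records[b], alpha_a, alpha_b),
        )
        for step, (a, b, alpha_a, alpha_b) in steps.items()
    }


def stability_fraction(
    records: pd.DataFrame, on: str = "class"
) -> pd.DataFrame:
    """Fraction of cells that keep their label across consecutive segments.

    For every short-duration label and each step (T1->T2, T2->T3), the
    fraction of cells carrying that label at the step's start which still
    carry it at the step's end; plus the aggregate over both steps.  Empty
    classes at a step give NaN (reported as missing).  ``on`` selects
    ``'class'`` (behavior classes) or ``'cluster'`` (fine-grained clusters).
    """
    col = {"class": "class", "cluster": "cluster"}[on]
    labels = sorted(
        set(records[f"{col}_T1"])
        | set(records[f"{col}_T2"])
        | set(records[f"{col}_T3"])
    )
    rows = []
    for label in labels:
        fracs = {}
        pooled_stay = pooled_n = 0
        for step, (a, b) in {
            "T1->T2": (f"{col}_T1", f"{col}_T2"),
            "T2->T3": (f"{col}_T2", f"{col}_T3"),
        }.items():
            start = records[records[a] == label]
            if len(start) == 0:
                fracs[step] = np.nan
                continue
            stay = int((start[b] == label).sum())
            fracs[step] = stay / len(start)
            pooled_stay += stay
            pooled_n += len(start)
        fracs["overall"] = pooled_stay / pooled_n if pooled_n else np.nan
        rows.append({"label": label, **fracs})
    return pd.DataFrame(rows).set_index("label")


def sankey_table(
    tables: dict[str, TransitionTable]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Plot-ready node and flow listings for a Sankey rendering.

    Nodes are (stage, class) with their cell counts; flows are the pairwise
    counts between consecutive stages.  Flow conservation holds at every
    node: flows out of a node sum to its count.
    """
    flows = []
    for step, table in tables.items():
        src_stage, dst_stage = step.split("->")
        for src in table.counts.index:
            for dst in table.counts.columns:
                count = int(table.counts.loc[src, dst])
                if count:
                    flows.append(
                        {
                            "source": f"{src_stage}:{src}",
                            "target": f"{dst_stage}:{dst}",
                            "count": count,
                        }
                    )
    flows = pd.DataFrame(flows, columns=["source", "target", "count"])

    nodes = []
    order = ["T1->T2", "T2->T3", "T3->C"]
    for step in order:
        table = tables[step]
        src_stage = step.split("->")[0]
        for src in table.counts.index:
            nodes.append(
                {
                    "stage": src_stage,
                    "class": src,
                    "count": int(table.counts.loc[src].sum()),
                }
            )
    last = tables[order[-1]]
    dst_stage = order[-1].split("->")[1]
    for dst in last.counts.columns:
        nodes.append(
            {
                "stage": dst_stage,
                "class": dst,
                "count": int(last.counts[dst].sum()),
            }
        )
    return pd.DataFrame(nodes), flows
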