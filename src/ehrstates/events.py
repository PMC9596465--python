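"""Present- and future-event labels and per-state event risk.

Each snapshot gets, per clinical event type, a *present* flag (the event's
timestamp falls inside the snapshot's 30-day window) and a *pre-event* flag
(the snapshot strictly precedes the patient's first event-containing
snapshot).  Pre-event snapshots are the basis of "future risk": states whose
snapshots are disproportionately pre-event identify patients on a path
toward the event.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st

from .snapshots import _timestamps_to_days

logger = logging.getLogger(__name__)


@dataclass
class EventLabels:
    """Boolean snapshot x event-type flag tables, row-aligned to the
    snapshot matrix.  A snapshot is never both present and pre-event for the
    same event type, and pre-event flags exist only for patients who ever
    have the event in a snapshot."""

    present: pd.DataFrame
    pre_event: pd.DataFrame

    @property
    def event_types(self) -> list[str]:
        return list(self.present.columns)


def label_events(
    rows: pd.DataFrame,
    anchors: pd.Series,
    events: pd.DataFrame,
    bin_width: int = 30,
    first_occurrence_only: bool = True,
) -> EventLabels:
    """Label each snapshot with present and pre-event flags per event type.

    Event timestamps are mapped to bins with the same per-patient anchoring
    as the snapshots.  Events for unknown patients, or falling in windows
    with no snapshot, are skipped with a warning.  With
    ``first_occurrence_only`` (default) the pre-event flag marks snapshots
    strictly before the *first* event-containing snapshot; the alternative
    marks snapshots before *any* event-containing snapshot (identical for
    the first occurrence, looser afterwards).
    """
    event_types = sorted(events["event_type"].unique()) if len(events) else []
    n = len(rows)
    present = pd.DataFrame(
        np.zeros((n, len(event_types)), dtype=bool), columns=event_types
    )
    pre_event = present.copy()
    if not event_types:
        return EventLabels(present, pre_event)

    ev = events.copy()
    ev["day"] = _timestamps_to_days(ev["timestamp"])
    ev["anchor"] = ev["patient_id"].map(anchors)
    unknown = ev["anchor"].isna()
    if unknown.any():
        logger.warning(
            "%d events refer to patients absent from the cohort; skipped",
            int(unknown.sum()),
        )
        ev = ev[~unknown]
    ev["bin_index"] = ((ev["day"] - ev["anchor"]) // bin_width).astype(int)

    row_index = pd.MultiIndex.from_frame(rows[["patient_id", "bin_index"]])
    row_pos = pd.Series(np.arange(n), index=row_index)
    patient_bins = rows.groupby("patient_id")["bin_index"]

    for et in event_types:
        sub = ev[ev["event_type"] == et]
        keys = pd.MultiIndex.from_frame(sub[["patient_id", "bin_index"]])
        hit = row_pos.reindex(keys)
        matched = hit.dropna().astype(int).to_numpy()
        present.iloc[matched, present.columns.get_loc(et)] = True
        # first (or any) present bin per patient
        hits = rows.iloc[matched]
        if first_occurrence_only:
            boundary = hits.groupby("patient_id")["bin_index"].min()
        else:
            boundary = hits.groupby("patient_id")["bin_index"].max()
        for pid, first_bin in boundary.items():
            bins = patient_bins.get_group(pid)
            pre_idx = bins.index[bins < first_bin]
            pre_event.iloc[
                rows.index.get_indexer(pre_idx), pre_event.columns.get_loc(et)
            ] = True
    if first_occurrence_only:
        overlap = (present.to_numpy() & pre_event.to_numpy()).any()
        assert not overlap, "a snapshot cannot be both present and pre-event"
    return EventLabels(present, pre_event)


def state_risk_table(labels, event_labels: EventLabels) -> pd.DataFrame:
    """Per-(cluster, event) present prevalence and future-risk prevalence.

    Denominators are snapshot counts per cluster (patient-level denominators
    can be derived from the counts also returned).
    """
    labels = np.asarray(labels)
    out = []
    for c in np.unique(labels):
        mask = labels == c
        n = int(mask.sum())
        for et in event_labels.event_types:
            n_present = int(event_labels.present[et].to_numpy()[mask].sum())
            n_pre = int(event_labels.pre_event[et].to_numpy()[mask].sum())
            out.append(
                {
                    "cluster": int(c),
                    "event_type": et,
                    "n_snapshots": n,
                    "n_present": n_present,
                    "present_pct": 100.0 * n_present / n,
                    "n_pre_event": n_pre,
                    "future_risk_pct": 100.0 * n_pre / n,
                }
            )
    return pd.DataFrame(out)


def density_overlay(
    coords: np.ndarray,
    event_labels: EventLabels,
    event_type: str,
    grid_size: int = 100,
    bandwidth: str | float = "scott",
) -> dict:
    """Gaussian-kernel density grids of present and pre-event snapshots over
    a 2D embedding, each normalized to integrate to 1 on the grid.

    Returns a dict with ``x``, ``y`` grid axes and ``present`` /
    ``pre_event`` density arrays (None when fewer than 2 points carry the
    flag).
    """
    coords = np.asarray(coords, dtype=float)
    pad = 0.05 * (coords.max(axis=0) - coords.min(axis=0) + 1e-9)
    lo, hi = coords.min(axis=0) - pad, coords.max(axis=0) + pad
    x = np.linspace(lo[0], hi[0], grid_size)
    y = np.linspace(lo[1], hi[1], grid_size)
    xx, yy = np.meshgrid(x, y)
    grid = np.vstack([xx.ravel(), yy.ravel()])
    cell = (x[1] - x[0]) * (y[1] - y[0])
    out = {"x": x, "y": y}
    for name, flags in (
        ("present", event_labels.present[event_type]),
        ("pre_event", event_labels.pre_event[event_type]),
    ):
        pts = coords[flags.to_numpy()]
        if len(pts) < 2 or np.allclose(pts.std(axis=0), 0):
            if len(pts) < 2:
                logger.warning(
                    "fewer than 2 %s-flagged points for %r; empty grid",
                    name, event_type,
                )
                out[name] = None
                continue
            # all points coincide: put the mass in the nearest cell
            dens = np.zeros(grid.shape[1])
            d2 = ((grid.T - pts[0]) ** 2).sum(axis=1)
            dens[np.argmin(d2)] = 1.0 / cell
            out[name] = dens.reshape(grid_size, grid_size)
            continue
        kde = st.gaussian_kde(pts.T, bw_method=bandwidth)
        dens = kde(grid).reshape(grid_size, grid_size)
        dens /= dens.sum() * cell
        out[name] = dens
    return out
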