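"""Salient-ROI interpretation from the first pooling layer.

A trained model keeps ``k`` of the original ROIs after the first TopK
layer, and which ROIs survive varies by subject.  Running the holdout
set through the model and counting, per ROI, the fraction of subjects
for which it survives gives a selection-frequency profile; ROIs at or
above a frequency threshold (0.90 by convention, 0.95 for high pooling
ratios) are reported as the salient set.  An optional ROI-to-domain
lookup groups the retained ROIs into functional domains (e.g. the seven
canonical resting-state networks).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model_pipeline import BrainRGIN, GraphBatch

__all__ = [
    "ROISelectionRecord",
    "TopROIReport",
    "collect_selections",
    "frequency_report",
]


@dataclass
class ROISelectionRecord:
    """Original ROI ids surviving block-1 pooling for one subject."""

    subject_id: str
    selected_roi_ids: np.ndarray

    def __post_init__(self):
        self.selected_roi_ids = np.asarray(self.selected_roi_ids, dtype=np.int64)


@dataclass
class TopROIReport:
    """Per-ROI selection frequencies over a holdout set.

    ``frequencies[i]`` is the fraction of records containing ROI ``i``;
    ``retained`` lists ROIs with frequency >= threshold (inclusive),
    sorted by descending frequency then ROI id.
    """

    frequencies: np.ndarray
    threshold: float
    retained: list[int]
    n_records: int
    k: int
    domains: pd.DataFrame | None = field(default=None)

    def as_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "roi": np.arange(len(self.frequencies)),
                "frequency": self.frequencies,
                "retained": [
                    int(i in set(self.retained)) for i in range(len(self.frequencies))
                ],
            }
        )
        if self.domains is not None:
            df = df.merge(self.domains, on="roi", how="left")
        return df


def collect_selections(
    model: BrainRGIN, holdout: GraphBatch, chunk: int = 256
) -> list[ROISelectionRecord]:
    """One selection record per holdout subject (block-1 survivors)."""
    if len(holdout) == 0:
        raise ValueError("holdout set is empty")
    records: list[ROISelectionRecord] = []
    for start in range(0, len(holdout), chunk):
        idx = np.arange(start, min(start + chunk, len(holdout)))
        sub = holdout.subset(idx)
        res = model.forward(sub)
        block1 = res.selected_roi[0]  # (b, k) original ROI ids
        for row, sid in zip(block1, sub.subject_ids or [""] * len(sub)):
            records.append(ROISelectionRecord(sid, np.sort(row)))
    return records


def frequency_report(
    records: list[ROISelectionRecord],
    threshold: float = 0.9,
    n_rois: int | None = None,
    domains: pd.DataFrame | None = None,
) -> TopROIReport:
    """Selection frequencies and the thresholded salient-ROI set.

    ``domains``, if given, must have columns ``roi`` and ``domain``; it
    is joined onto the report for network-level grouping.
    """
    if not records:
        raise ValueError("no selection records")
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must lie in (0, 1]")
    k = len(records[0].selected_roi_ids)
    if n_rois is None:
        n_rois = int(max(r.selected_roi_ids.max() for r in records)) + 1
    counts = np.zeros(n_rois, dtype=np.int64)
    for rec in records:
        if len(rec.selected_roi_ids) != k:
            raise ValueError("records disagree on the number of survivors")
        counts[rec.selected_roi_ids] += 1
    freq = counts / len(records)
    retained = [int(i) for i in np.flatnonzero(freq >= threshold)]
    retained.sort(key=lambda i: (-freq[i], i))
    if domains is not None and not {"roi", "domain"} <= set(domains.columns):
        raise ValueError("domain table needs 'roi' and 'domain' columns")
    return TopROIReport(
        frequencies=freq,
        threshold=threshold,
        retained=retained,
        n_records=len(records),
        k=k,
        domains=domains,
    )
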