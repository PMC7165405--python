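"""Scoring of analysis results against synthetic-section ground truth.

Companion to :mod:`fibrequant.synthetic_section`: matches detected fibres to
drawn fibres and computes recovery metrics (coverage error, overlap quality).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .synthetic_section import GroundTruth


def match_records_to_truth(records: Sequence, truth: GroundTruth) -> pd.DataFrame:
    """Match each per-fibre record to its nearest ground-truth fibre by centroid.

    Returns one row per record with the truth fields joined and the signed
    coverage error ``coverage_error_pts`` (estimated minus true, percentage
    points).
    """
    t = truth.fibres
    rows = []
    for r in records:
        d2 = (t["centroid_r"] - r.centroid_r) ** 2 + (t["centroid_c"] - r.centroid_c) ** 2
        tr = t.loc[d2.idxmin()]
        rows.append({
            "label": r.label,
            "true_label": int(tr["label"]),
            "true_coverage_pct": 100.0 * float(tr["true_coverage_fraction"]),
            "estimated_coverage_pct": r.circumference_positivity,
            "coverage_error_pts": r.circumference_positivity - 100.0 * float(tr["true_coverage_fraction"]),
            "coverage_class": r.coverage_class,
            "is_positive": r.is_positive,
            "true_myosin_positive": bool(tr["true_myosin_positive"]),
            "myosin_positive": getattr(r, "myosin_positive", None),
            "quantifiable": r.quantifiable,
        })
    return pd.DataFrame(rows)


def jaccard_per_truth_fibre(true_labels: np.ndarray, detected_labels: np.ndarray) -> np.ndarray:
    """Best-overlap Jaccard index for every drawn fibre (0 when undetected)."""
    out = []
    for lab in range(1, int(true_labels.max()) + 1):
        tm = true_labels == lab
        if not tm.any():
            out.append(0.0)
            continue
        overlap = detected_labels[tm]
        overlap = overlap[overlap > 0]
        if overlap.size == 0:
            out.append(0.0)
            continue
        det = np.bincount(overlap).argmax()
        dm = detected_labels == det
        out.append(float((tm & dm).sum() / (tm | dm).sum()))
    return np.array(out)


def expected_class(true_pct: float) -> str:
    """Ground-truth coverage class for a true coverage percentage."""
    if true_pct <= 25.0:
        return "0-25"
    if true_pct <= 50.0:
        return "25-50"
    if true_pct <= 75.0:
        return "50-75"
    return "75-100"
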