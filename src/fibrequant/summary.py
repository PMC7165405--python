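"""Section-level aggregation of per-fibre results and replicate comparison.

Section endpoints follow the per-fibre framing of the method: the section mean
intensity is the unweighted mean of per-fibre sarcolemmal raw means (large
fibres do not dominate), percentages use the quantifiable analysed fibres as
denominator (rejected and unquantifiable counts are reported alongside), and
cumulative-frequency tables are emitted at 1-percentile resolution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .image_io import COVERAGE_CLASSES


@dataclass
class SectionSummary:
    n_fibres_analysed: int
    n_rejected: int
    n_unquantifiable: int
    pct_positive: float
    mean_sarcolemma_intensity: float        # AU, primary channel
    mean_tertiary_sarcolemma_intensity: float
    class_counts: dict[str, int]
    cumulative_frequency_intensity: dict[str, list[float]]
    cumulative_frequency_coverage: dict[str, list[float]]
    coloc_tertiary_in_primary_pos: float    # AU, NaN when undefined
    coloc_tertiary_in_primary_neg: float
    pct_myosin_positive: float              # NaN when no myosin channel

    def to_dict(self) -> dict:
        def clean(v):
            if isinstance(v, float) and math.isnan(v):
                return None
            return v
        return {
            "n_fibres_analysed": self.n_fibres_analysed,
            "n_rejected": self.n_rejected,
            "n_unquantifiable": self.n_unquantifiable,
            "pct_positive": clean(self.pct_positive),
            "mean_sarcolemma_intensity": clean(self.mean_sarcolemma_intensity),
            "mean_tertiary_sarcolemma_intensity": clean(self.mean_tertiary_sarcolemma_intensity),
            "class_counts": self.class_counts,
            "cumulative_frequency_intensity": self.cumulative_frequency_intensity,
            "cumulative_frequency_coverage": self.cumulative_frequency_coverage,
            "coloc_tertiary_in_primary_pos": clean(self.coloc_tertiary_in_primary_pos),
            "coloc_tertiary_in_primary_neg": clean(self.coloc_tertiary_in_primary_neg),
            "pct_myosin_positive": clean(self.pct_myosin_positive),
        }


def _cumfreq_table(values: np.ndarray) -> dict[str, list[float]]:
    pct = np.arange(0, 101, dtype=float)
    if values.size == 0:
        return {"pct_fibres_le": pct.tolist(), "value": [float("nan")] * len(pct)}
    quant = np.percentile(values, pct)
    return {"pct_fibres_le": pct.tolist(), "value": [float(v) for v in quant]}


def summarise_section(records: Sequence, n_rejected: int = 0,
                      positivity_cutoff: float = 25.0) -> SectionSummary:
    """Aggregate per-fibre records into section endpoints.

    Percentages are over the quantifiable fibres; missing colocalisation values
    are excluded from their means.  Records are sorted by label first so the
    output is bit-identical under any input permutation.
    """
    records = sorted(records, key=lambda r: r.label)
    quant = [r for r in records if r.quantifiable]
    if not quant:
        raise ValueError("no quantifiable fibres to summarise")
    n_unq = len(records) - len(quant)
    cov = np.array([r.circumference_positivity for r in quant], dtype=np.float64)
    intens = np.array([r.primary_sarcolemma_mean for r in quant], dtype=np.float64)
    tert = np.array([r.tertiary_sarcolemma_mean for r in quant], dtype=np.float64)
    counts = {c: 0 for c in COVERAGE_CLASSES}
    for r in quant:
        counts[r.coverage_class] += 1
    pct_positive = float(100.0 * (cov > positivity_cutoff).sum() / len(quant))

    def nan_mean(vals: list[float]) -> float:
        arr = np.array([v for v in vals if v is not None and not math.isnan(v)], dtype=np.float64)
        return float(arr.mean()) if arr.size else float("nan")

    coloc_pos = nan_mean([r.tertiary_mean_in_primary_pos for r in quant])
    coloc_neg = nan_mean([r.tertiary_mean_in_primary_neg for r in quant])
    myosin_flags = [r.myosin_positive for r in quant if r.myosin_positive is not None]
    pct_myosin = (float(100.0 * sum(bool(f) for f in myosin_flags) / len(myosin_flags))
                  if myosin_flags else float("nan"))
    return SectionSummary(
        n_fibres_analysed=len(quant),
        n_rejected=int(n_rejected),
        n_unquantifiable=n_unq,
        pct_positive=pct_positive,
        mean_sarcolemma_intensity=float(intens.mean()),
        mean_tertiary_sarcolemma_intensity=float(tert.mean()),
        class_counts=counts,
        cumulative_frequency_intensity=_cumfreq_table(intens),
        cumulative_frequency_coverage=_cumfreq_table(cov),
        coloc_tertiary_in_primary_pos=coloc_pos,
        coloc_tertiary_in_primary_neg=coloc_neg,
        pct_myosin_positive=pct_myosin,
    )


REPLICATE_ENDPOINTS = (
    "pct_positive",
    "mean_sarcolemma_intensity",
    "mean_tertiary_sarcolemma_intensity",
    "coloc_tertiary_in_primary_pos",
    "coloc_tertiary_in_primary_neg",
    "pct_myosin_positive",
)


def compare_replicates(summaries: Sequence[SectionSummary],
                       endpoints: Sequence[str] = REPLICATE_ENDPOINTS) -> dict[str, dict[str, float]]:
    """Replicate-variability report across same-condition sections.

    Per endpoint: min, max, mean and percent variability = (max - min) / mean x 100,
    the natural-variability measure used for repeat-staining experiments.
    Endpoints that are undefined (NaN) in any replicate are skipped.
    """
    if len(summaries) < 2:
        raise ValueError("need >= 2 summaries to compare replicates")
    report: dict[str, dict[str, float]] = {}
    for ep in endpoints:
        vals = np.array([getattr(s, ep) for s in summaries], dtype=np.float64)
        if np.isnan(vals).any():
            continue
        mean = float(vals.mean())
        spread = float(vals.max() - vals.min())
        report[ep] = {
            "min": float(vals.min()),
            "max": float(vals.max()),
            "mean": mean,
            "percent_variability": float(spread / mean * 100.0) if mean != 0 else 0.0,
        }
    return report
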