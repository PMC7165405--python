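"""Regenerating-fibre classification by sarcoplasmic f/d-myosin intensity.

Fetal/developmental myosin is absent from healthy mature muscle, so negative
control sections provide the baseline: the positivity threshold is a statistic
of the per-fibre sarcoplasmic means measured on controls (a high percentile by
default, robust to the occasional outlier control fibre; mean + k*sd is also
available).  A test fibre is positive iff its average sarcoplasmic intensity is
strictly greater than the threshold.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .sarcolemmal import FibreStainProfile

MIN_CONTROL_FIBRES = 50


@dataclass
class MyosinThreshold:
    value: float
    method: str                      # 'percentile' or 'mean_plus_ksd'
    param: float                     # percentile, or k
    n_control_fibres: int
    provenance: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "value": self.value,
            "method": self.method,
            "param": self.param,
            "n_control_fibres": self.n_control_fibres,
            "provenance": self.provenance,
        }, sort_keys=True, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "MyosinThreshold":
        d = json.loads(Path(path).read_text())
        return cls(value=float(d["value"]), method=d["method"], param=float(d["param"]),
                   n_control_fibres=int(d["n_control_fibres"]),
                   provenance=list(d.get("provenance", [])))


def _control_means(controls: Iterable) -> np.ndarray:
    means = []
    for item in controls:
        if isinstance(item, FibreStainProfile):
            means.append(item.tertiary_sarcoplasm_mean)
        else:
            means.append(float(item))
    arr = np.asarray(means, dtype=np.float64)
    return arr[np.isfinite(arr)]


def derive_myosin_threshold(controls: Sequence, method: str = "percentile",
                            param: float | None = None,
                            provenance: Sequence[str] = ()) -> MyosinThreshold:
    """Derive the sarcoplasmic positivity threshold from negative-control fibres.

    ``controls`` is a sequence of control-fibre stain profiles or plain
    sarcoplasm means.  ``percentile`` (default 99.5) takes the stated empirical
    percentile of the per-fibre means; ``mean_plus_ksd`` (default k = 5) their
    mean + k*sd.  Fewer than 50 control fibres is an error: the threshold would
    be unreliable.
    """
    means = _control_means(controls)
    if means.size < MIN_CONTROL_FIBRES:
        raise ValueError(
            f"only {means.size} control fibres; >= {MIN_CONTROL_FIBRES} required "
            "for a reliable myosin threshold"
        )
    if method == "percentile":
        p = 99.5 if param is None else float(param)
        if not 0 < p <= 100:
            raise ValueError("percentile must lie in (0, 100]")
        value = float(np.percentile(means, p))
    elif method == "mean_plus_ksd":
        k = 5.0 if param is None else float(param)
        value = float(means.mean() + k * means.std())
    else:
        raise ValueError(f"unknown method {method!r}")
    return MyosinThreshold(
        value=value, method=method,
        param=(99.5 if param is None and method == "percentile" else
               5.0 if param is None else float(param)),
        n_control_fibres=int(means.size),
        provenance=list(provenance),
    )


def classify_myosin(profile: FibreStainProfile | float, threshold: MyosinThreshold) -> bool | None:
    """Positive iff the fibre's average sarcoplasmic intensity strictly exceeds the threshold.

    Returns None (unquantifiable) when the sarcoplasm mean is missing.
    """
    mean = profile.tertiary_sarcoplasm_mean if isinstance(profile, FibreStainProfile) else float(profile)
    if mean is None or math.isnan(mean):
        return None
    return bool(mean > threshold.value)
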