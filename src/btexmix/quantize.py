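"""Quartile coding of cumulative exposures.

The analysis represents each chemical's cumulative exposure two ways, both
derived from quartile cutpoints estimated on the *full* analysis sample:

* disjoint quartile indicators (Q2/Q3/Q4 vs a Q1 reference) for
  single-pollutant censored regressions, and
* integer quartile scores 0..3 for quantile g-computation.

Cutpoints use the linear-interpolation empirical quantile (the "type 7"
convention). Bins are half-open ``(lo, hi]``: a value exactly equal to a
cutpoint falls in the lower bin, so scoring is deterministic and monotone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np


@dataclass(frozen=True)
class QuantizationSpec:
    """Per-chemical quantile cutpoints and the sample they came from."""

    chemical: str
    q: int
    cutpoints: tuple[float, ...]
    source_n: int

    def __post_init__(self):
        if self.q < 2:
            raise ValueError("q must be >= 2")
        if len(self.cutpoints) != self.q - 1:
            raise ValueError(f"need {self.q - 1} cutpoints, got {len(self.cutpoints)}")
        if not np.all(np.diff(self.cutpoints) > 0):
            raise ValueError(f"{self.chemical}: cutpoints must be strictly increasing")

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "QuantizationSpec":
        d = json.loads(s)
        d["cutpoints"] = tuple(d["cutpoints"])
        return cls(**d)


def fit_cutpoints(values: Sequence[float], q: int = 4,
                  chemical: str = "") -> QuantizationSpec:
    """Estimate ``q``-quantile cutpoints on the full analysis sample.

    Raises if the sample has fewer distinct values than bins (a constant
    exposure cannot be quantized).
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < q:
        raise ValueError("values must be a 1-D sample with n >= q")
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{chemical or 'exposure'}: non-finite values present")
    if np.any(x < 0):
        raise ValueError(f"{chemical or 'exposure'}: negative exposures present")
    if np.unique(x).size < q:
        raise ValueError(
            f"{chemical or 'exposure'}: fewer than {q} distinct values; "
            "quantile coding is degenerate")
    probs = np.arange(1, q) / q
    cut = np.quantile(x, probs, method="linear")
    if not np.all(np.diff(cut) > 0):
        raise ValueError(
            f"{chemical or 'exposure'}: tied quantiles {cut.tolist()}; "
            "cannot form strictly increasing cutpoints")
    return QuantizationSpec(chemical=chemical, q=q,
                            cutpoints=tuple(float(c) for c in cut),
                            source_n=int(x.size))


def score(values: Sequence[float], spec: QuantizationSpec) -> np.ndarray:
    """Integer quartile scores 0..q-1 with half-open ``(lo, hi]`` bins."""
    x = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite exposure value")
    if np.any(x < 0):
        raise ValueError("negative exposure value")
    return np.searchsorted(np.asarray(spec.cutpoints), x, side="left").astype(np.int64)


def indicators(scores: Sequence[int], q: int = 4) -> np.ndarray:
    """Expand integer scores into q-1 indicator columns (reference bin 0 omitted)."""
    s = np.asarray(scores)
    if s.size and (s.min() < 0 or s.max() > q - 1):
        raise ValueError(f"scores outside 0..{q - 1}")
    out = np.zeros((s.size, q - 1), dtype=np.int64)
    for j in range(1, q):
        out[:, j - 1] = s == j
    return out
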