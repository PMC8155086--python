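"""Cohort-level ordinal recoding of raw ALM values to a 1-4 impairment scale.

Each measure is recoded against the observed distribution of the whole
sample so that heterogeneously distributed measures share a common scale:
roughly the bottom half of the impairment-ordered distribution scores 1,
the next quarter 2, the next 15% 3, and the most impaired decile 4.

For measures where *low* raw values indicate impairment (MLUM, NDWR, um
proportion, CPM) the scale is reversed: bins are fitted at the 10th, 25th
and 50th empirical centiles and the score runs 4 (bottom decile) down to 1
(top half).  For the remaining measures bins sit at the 50th, 75th and
90th centiles and the score runs 1 up to 4.

Quantiles use linear interpolation of the empirical distribution (the
ubiquitous "type 7" estimator) and intervals are closed on the right: a
value exactly equal to a threshold falls in the lower bin.  Both choices
are deterministic conventions, documented here because the scale is only
reproducible bit-for-bit once they are fixed.

um proportion receives one adjustment: its distribution typically has a
point mass at exactly zero (children who said *uh* but never *um*).  When
more than 10% of fitted values are exact zeros, the bottom threshold is
clamped so that *every* zero receives the maximal impairment score 4; the
effective size of the top impairment bin then grows from 10% to the zero
mass (e.g. ~14% of the sample, i.e. a cut at the 86th centile of the
reversed scale).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

__all__ = [
    "REVERSED_ALMS",
    "ZERO_ADJUSTED_ALMS",
    "CentileBins",
    "fit_bins",
    "apply_bins",
]

#: measures where lower raw values mean higher impairment
REVERSED_ALMS = frozenset({"mlum", "ndwr", "um_prop", "cpm"})
#: measures whose zero point-mass is forced into the top impairment bin
ZERO_ADJUSTED_ALMS = frozenset({"um_prop"})


@dataclass(frozen=True)
class CentileBins:
    """Fitted cohort thresholds for one ALM.

    ``thresholds`` are non-decreasing cutpoints: the (50, 75, 90)th
    centiles for a non-reversed measure, the (10, 25, 50)th for a reversed
    one.
    """

    alm_name: str
    thresholds: tuple[float, float, float]
    reversed: bool
    zero_adjusted: bool
    fitted_n: int

    def __post_init__(self) -> None:
        t1, t2, t3 = self.thresholds
        if not (t1 <= t2 <= t3):
            raise ValueError("thresholds must be non-decreasing")
        if self.fitted_n < 10:
            raise ValueError("bins must be fitted on >= 10 values")

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "CentileBins":
        d = json.loads(text)
        d["thresholds"] = tuple(d["thresholds"])
        return cls(**d)


def fit_bins(values, alm_name: str) -> CentileBins:
    """Fit centile thresholds for one measure on a cohort sample.

    ``values`` may contain NaN (undefined measures); those are excluded
    before fitting.  Requires at least 10 defined values and a
    non-constant sample.
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size < 10:
        raise ValueError(
            f"{alm_name}: need >= 10 defined values to fit bins, "
            f"got {arr.size}")
    if np.min(arr) == np.max(arr):
        raise ValueError(f"{alm_name}: constant sample, bins degenerate")
    is_reversed = alm_name in REVERSED_ALMS
    qs = (0.10, 0.25, 0.50) if is_reversed else (0.50, 0.75, 0.90)
    t1, t2, t3 = (float(q) for q in np.quantile(arr, qs, method="linear"))
    zero_adjusted = False
    if alm_name in ZERO_ADJUSTED_ALMS:
        zero_frac = float(np.mean(arr == 0.0))
        if zero_frac > 0.10:
            # make sure the bottom (score-4) threshold covers every zero
            t1 = max(t1, 0.0)
            t2 = max(t2, t1)
            t3 = max(t3, t2)
            zero_adjusted = True
    return CentileBins(
        alm_name=alm_name,
        thresholds=(t1, t2, t3),
        reversed=is_reversed,
        zero_adjusted=zero_adjusted,
        fitted_n=int(arr.size),
    )


def apply_bins(value: float, bins: CentileBins) -> int:
    """Map one raw value to its ordinal impairment score in {1, 2, 3, 4}.

    Undefined values must be excluded upstream; passing NaN raises.
    """
    v = float(value)
    if np.isnan(v):
        raise ValueError(f"{bins.alm_name}: cannot score an undefined value")
    t1, t2, t3 = bins.thresholds
    if v <= t1:
        base = 1
    elif v <= t2:
        base = 2
    elif v <= t3:
        base = 3
    else:
        base = 4
    return 5 - base if bins.reversed else base
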