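"""Human-mtDNA qPCR: standard curve fitting, human-fraction estimation, and
embryo chimera-positivity calls."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import round_half_up


@dataclass
class StandardCurve:
    slope: float
    intercept: float
    efficiency: float  # 1.0 == 100%
    r_squared: float

    def fraction_from_ct(self, ct: float) -> float:
        return float(10.0 ** ((ct - self.intercept) / self.slope))


@dataclass
class QpcrPlate:
    """standards: (log10_fraction, ct); unknowns: (embryo_id, ct or NaN)."""

    standards: pd.DataFrame   # columns: log10_fraction, ct
    unknowns: pd.DataFrame    # columns: id, ct, condition (ct NaN == non-detect)
    ct_ceiling: float = 40.0

    def __post_init__(self) -> None:
        std = self.standards
        if len(std) < 4 or std["log10_fraction"].max() - std["log10_fraction"].min() < 3:
            raise ValueError("need >= 4 standards spanning >= 3 decades")
        if (std["ct"] >= self.ct_ceiling).any():
            raise ValueError("standard ct at or above the non-detect ceiling")


def fit_standard_curve(standards: pd.DataFrame) -> StandardCurve:
    """Least-squares ct = slope * log10(fraction) + intercept.

    Amplification efficiency is 10^(-1/slope) - 1 (2.0 per cycle == 100%).
    """
    if len(standards) < 3:
        raise ValueError("need >= 3 standards")
    x = standards["log10_fraction"].to_numpy(dtype=float)
    y = standards["ct"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("singular fit: standards at one concentration")
    res = stats.linregress(x, y)
    if res.slope == 0:
        raise ValueError("singular fit: flat ct values")
    return StandardCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        efficiency=float(10.0 ** (-1.0 / res.slope) - 1.0),
        r_squared=float(res.rvalue**2),
    )


@dataclass
class ChimeraSummary:
    condition: str
    n_injected: int
    n_tested: int
    n_positive: int
    pct_positive: float


def call_embryos(
    plate: QpcrPlate,
    threshold: float = 1e-4,
    curve: Optional[StandardCurve] = None,
    n_injected: Optional[dict[str, int]] = None,
) -> tuple[pd.DataFrame, list[ChimeraSummary]]:
    """Estimate the human-cell fraction of each unknown and call positivity.

    Positive iff the well amplified (not a non-detect) and the estimated
    fraction is at least ``threshold``. Non-detects are never positive. Wells
    brighter than the top standard are flagged as above the calibration range
    but still estimated.
    """
    if curve is None:
        curve = fit_standard_curve(plate.standards)
    min_std_ct = float(plate.standards["ct"].min())
    rows = []
    for u in plate.unknowns.itertuples(index=False):
        nondetect = pd.isna(u.ct) or u.ct >= plate.ct_ceiling
        fraction = np.nan if nondetect else curve.fraction_from_ct(float(u.ct))
        rows.append({
            "id": u.id,
            "condition": getattr(u, "condition", ""),
            "ct": u.ct,
            "estimated_fraction": fraction,
            "above_calibration": bool(not nondetect and u.ct < min_std_ct),
            "positive": bool(not nondetect and fraction >= threshold),
        })
    per_embryo = pd.DataFrame(rows)

    summaries = []
    for condition, g in per_embryo.groupby("condition", sort=True):
        tested = len(g)
        positive = int(g["positive"].sum())
        summaries.append(ChimeraSummary(
            condition=str(condition),
            n_injected=(n_injected or {}).get(str(condition), tested),
            n_tested=tested,
            n_positive=positive,
            pct_positive=round_half_up(100.0 * positive / tested, 1) if tested else float("nan"),
        ))
    return per_embryo, summaries


def summaries_to_frame(summaries: Sequence[ChimeraSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in summaries])
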