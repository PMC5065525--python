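"""Shared domain types: thresholds, sample sheets, count matrices, RNG streams."""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, fields, replace
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

STATES = (
    "primed",
    "naive_5iLA",
    "naive_4iLA",
    "naive_t2iL_DOX",
    "reprimed",
    "embryo",
)

STAGES = (
    "oocyte",
    "zygote",
    "two_cell",
    "four_cell",
    "eight_cell",
    "morula",
    "late_blastocyst_TE",
    "late_blastocyst_PE",
    "late_blastocyst_EPI",
)

SEXES = ("female", "male", "unknown")


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (half-up), as printed percentages are."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, reproducible RNG substream derived from one global seed."""
    return np.random.default_rng([int(seed), zlib.crc32(name.encode("utf8"))])


@dataclass(frozen=True)
class Thresholds:
    """All analysis cutoffs in one auditable place.

    Defaults mirror the study's stated rules: 2-fold change, p/p-adj 0.05,
    1% FDR for the overexpressed-TE methylation contrast, erasure below 0.30
    with an intermediate primed band of [0.30, 0.70], ten allelic reads,
    +/-20 kb metaprofile windows, top-10,000-SD feature selection, and a
    1:10,000 chimera detection limit.
    """

    fold_cutoff: float = 2.0
    p_cutoff: float = 0.05
    padj_cutoff: float = 0.05
    overexpr_fdr: float = 0.01
    erase_level: float = 0.30
    intermediate_band: tuple[float, float] = (0.30, 0.70)
    min_allelic_reads: int = 10
    metaprofile_halfwidth: int = 20_000
    top_sd_n: int = 10_000
    detection_limit: float = 1e-4

    def __post_init__(self) -> None:
        for name in ("p_cutoff", "padj_cutoff", "overexpr_fdr"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        lo, hi = self.intermediate_band
        if not lo < hi:
            raise ValueError("intermediate_band lower bound must be < upper")
        if self.fold_cutoff <= 1.0:
            raise ValueError("fold_cutoff must be > 1")
        if self.min_allelic_reads < 0:
            raise ValueError("min_allelic_reads must be >= 0")

    def with_overrides(self, overrides: Mapping[str, object]) -> "Thresholds":
        known = {f.name for f in fields(self)}
        bad = set(overrides) - known
        if bad:
            raise ValueError(f"unknown threshold keys: {sorted(bad)}")
        clean = dict(overrides)
        if "intermediate_band" in clean:
            clean["intermediate_band"] = tuple(clean["intermediate_band"])  # type: ignore[arg-type]
        return replace(self, **clean)  # type: ignore[arg-type]

    def as_dict(self) -> dict:
        return {
            f.name: (list(v) if isinstance(v := getattr(self, f.name), tuple) else v)
            for f in fields(self)
        }


@dataclass
class SampleSheet:
    """Sample metadata: id, culture state, embryo stage, sex, replicate."""

    frame: pd.DataFrame

    COLUMNS = ("sample_id", "state", "stage", "sex", "replicate")

    def __post_init__(self) -> None:
        df = self.frame.copy()
        missing = [c for c in self.COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"sample sheet missing columns: {missing}")
        df = df[list(self.COLUMNS)]
        if df["sample_id"].duplicated().any():
            dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValueError(f"duplicate sample_ids: {dups}")
        bad_state = set(df["state"]) - set(STATES)
        if bad_state:
            raise ValueError(f"unknown states: {sorted(bad_state)}")
        bad_sex = set(df["sex"]) - set(SEXES)
        if bad_sex:
            raise ValueError(f"unknown sex values: {sorted(bad_sex)}")
        stage = df["stage"]
        is_embryo = df["state"] == "embryo"
        has_stage = stage.notna() & (stage != "")
        if (is_embryo & ~has_stage).any():
            offenders = df.loc[is_embryo & ~has_stage, "sample_id"].tolist()
            raise ValueError(f"embryo samples without a stage: {offenders}")
        if (~is_embryo & has_stage).any():
            offenders = df.loc[~is_embryo & has_stage, "sample_id"].tolist()
            raise ValueError(f"non-embryo samples with a stage: {offenders}")
        bad_stage = set(stage[has_stage]) - set(STAGES)
        if bad_stage:
            raise ValueError(f"unknown stages: {sorted(bad_stage)}")
        if (df["replicate"].astype(int) < 1).any():
            raise ValueError("replicate must be >= 1")
        df["replicate"] = df["replicate"].astype(int)
        df["stage"] = stage.where(has_stage, None)
        self.frame = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return self.frame["sample_id"].tolist()

    def samples_in_state(self, *states: str) -> list[str]:
        return self.frame.loc[self.frame["state"].isin(states), "sample_id"].tolist()

    def samples_in_stage(self, stage: str) -> list[str]:
        return self.frame.loc[self.frame["stage"] == stage, "sample_id"].tolist()

    def state_of(self, sample_id: str) -> str:
        row = self.frame.loc[self.frame["sample_id"] == sample_id]
        if row.empty:
            raise KeyError(sample_id)
        return row["state"].iloc[0]

    @classmethod
    def from_records(cls, records: Iterable[Mapping]) -> "SampleSheet":
        df = pd.DataFrame(records)
        for col in ("stage",):
            if col not in df.columns:
                df[col] = None
        return cls(df)


@dataclass
class CountMatrix:
    """Feature x sample matrix of non-negative integer counts."""

    feature_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        arr = np.asarray(self.counts)
        if arr.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError(
                f"counts shape {arr.shape} inconsistent with "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("counts must be integers")
            arr = np.round(arr).astype(np.int64)
        if (arr < 0).any():
            raise ValueError("counts must be non-negative")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("duplicate feature_ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample_ids")
        self.counts = arr.astype(np.int64)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.feature_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CountMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy())

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return CountMatrix(list(self.feature_ids), list(sample_ids), self.counts[:, idx])

    def subset_features(self, feature_ids: Sequence[str]) -> "CountMatrix":
        pos = {f: i for i, f in enumerate(self.feature_ids)}
        idx = [pos[f] for f in feature_ids]
        return CountMatrix(list(feature_ids), list(self.sample_ids), self.counts[idx, :])

    def hstack(self, other: "CountMatrix") -> "CountMatrix":
        """Join sample-wise on the shared feature set (order of self)."""
        other_aligned = other.subset_features(self.feature_ids)
        return CountMatrix(
            list(self.feature_ids),
            self.sample_ids + other_aligned.sample_ids,
            np.hstack([self.counts, other_aligned.counts]),
        )
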