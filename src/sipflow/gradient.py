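"""CsCl buoyant-density gradients: fraction records, percent-of-gradient
normalization, and pooled fractions.

A gradient is collected drop-wise from the bottom of the ultracentrifuge
tube, so fraction 1 is the densest and density is non-increasing with
fraction index.  Per-fraction DNA mass and 16S rRNA gene copy number are
normalized as a percentage of the gradient total, which makes labeled and
control gradients comparable even when absolute DNA recovery differs.
Adjacent fractions are grouped into named pooled fractions (density
windows such as ``upper`` / ``medium`` / ``lower``); the dense windows are
the ones interrogated for isotope-labeled taxa downstream.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DENSITY_MIN_VALID",
    "DENSITY_MAX_VALID",
    "FractionRecord",
    "GradientProfile",
    "DensityWindow",
    "PoolingScheme",
    "PooledFraction",
    "normalize_profile",
    "pool_fractions",
    "density_shift",
    "fraction_count",
    "default_scheme",
]

logger = logging.getLogger(__name__)

#: Physically plausible CsCl buoyant densities for DNA (g/ml).
DENSITY_MIN_VALID = 1.60
DENSITY_MAX_VALID = 1.80


@dataclass(frozen=True)
class FractionRecord:
    """One collected gradient fraction.

    ``index`` is 1-based with 1 = first collected, i.e. the densest
    fraction (bottom-first collection).
    """

    index: int
    density_g_ml: float
    dna_ng: float
    copies_16s: float

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ValueError(f"fraction index must be >= 1, got {self.index}")
        if not (DENSITY_MIN_VALID <= self.density_g_ml <= DENSITY_MAX_VALID):
            raise ValueError(
                f"fraction {self.index}: density {self.density_g_ml} g/ml outside "
                f"[{DENSITY_MIN_VALID}, {DENSITY_MAX_VALID}]"
            )
        if self.dna_ng < 0 or self.copies_16s < 0:
            raise ValueError(f"fraction {self.index}: negative DNA or copy number")


@dataclass
class GradientProfile:
    """Ordered fractions of one gradient (substrate x treatment x life stage)."""

    fractions: list[FractionRecord]
    substrate: str = "cellulose"
    treatment: str = "control"
    life_stage: str = "larva"

    def __post_init__(self) -> None:
        if len(self.fractions) < 2:
            raise ValueError("a gradient needs at least 2 fractions")
        idx = [f.index for f in self.fractions]
        if idx != list(range(1, len(idx) + 1)):
            raise ValueError("fraction indices must be consecutive starting at 1")
        dens = [f.density_g_ml for f in self.fractions]
        if any(b > a + 1e-12 for a, b in zip(dens, dens[1:])):
            raise ValueError(
                "densities must be non-increasing with fraction index "
                "(fraction 1 = densest, bottom-first collection)"
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "fraction_index": [f.index for f in self.fractions],
                "density_g_ml": [f.density_g_ml for f in self.fractions],
                "dna_ng": [f.dna_ng for f in self.fractions],
                "copies_16s": [f.copies_16s for f in self.fractions],
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, **meta: str) -> "GradientProfile":
        """Build a profile from a fraction table.

        Tables supplied in top-first order (density increasing with index)
        are detected and re-indexed bottom-first with a logged warning.
        """
        required = {"fraction_index", "density_g_ml", "dna_ng", "copies_16s"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"fraction table missing columns: {sorted(missing)}")
        frame = frame.sort_values("fraction_index").reset_index(drop=True)
        if frame["fraction_index"].duplicated().any():
            dupes = frame.loc[frame["fraction_index"].duplicated(), "fraction_index"]
            raise ValueError(f"duplicate fraction indices: {sorted(set(dupes))}")
        dens = frame["density_g_ml"].to_numpy(float)
        if len(dens) >= 2 and dens[-1] > dens[0]:
            logger.warning(
                "fraction table is top-first (density increases with index); "
                "re-indexing bottom-first so fraction 1 is densest"
            )
            frame = frame.iloc[::-1].reset_index(drop=True)
        records = [
            FractionRecord(
                index=i + 1,
                density_g_ml=float(row.density_g_ml),
                dna_ng=float(row.dna_ng),
                copies_16s=float(row.copies_16s),
            )
            for i, row in enumerate(frame.itertuples(index=False))
        ]
        return cls(fractions=records, **meta)


@dataclass(frozen=True)
class DensityWindow:
    """Named half-open density interval [low, high); ties go to the denser window."""

    name: str
    low: float
    high: float
    dense: bool = False

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError(f"window {self.name!r}: low must be < high")


@dataclass
class PoolingScheme:
    """Disjoint density windows, stored densest-first; >=1 marked ``dense``."""

    windows: list[DensityWindow]

    def __post_init__(self) -> None:
        if not self.windows:
            raise ValueError("pooling scheme needs at least one window")
        self.windows = sorted(self.windows, key=lambda w: -w.high)
        for a, b in zip(self.windows, self.windows[1:]):
            if b.high > a.low + 1e-12:
                raise ValueError(
                    f"windows {a.name!r} and {b.name!r} overlap "
                    f"([{b.low},{b.high}) vs [{a.low},{a.high}))"
                )
        if not any(w.dense for w in self.windows):
            raise ValueError("pooling scheme needs at least one dense window")

    @property
    def names(self) -> list[str]:
        return [w.name for w in self.windows]

    @property
    def dense_names(self) -> list[str]:
        return [w.name for w in self.windows if w.dense]

    def assign(self, density: float) -> str | None:
        """Window name for a density, or None if outside all windows.

        Membership is [low, high); a density equal to a shared boundary
        therefore lands in the adjacent denser window.  The densest
        window also accepts its own upper bound so the gradient maximum
        is never orphaned.
        """
        for i, w in enumerate(self.windows):
            if w.low <= density < w.high:
                return w.name
            if i == 0 and density == w.high:
                return w.name
        return None


@dataclass(frozen=True)
class PooledFraction:
    name: str
    member_indices: tuple[int, ...]
    dna_percent: float
    copies_percent: float
    dense: bool = False


def normalize_profile(profile: GradientProfile) -> pd.DataFrame:
    """Percent-of-gradient normalization of DNA mass and 16S copies.

    Each series is expressed as a percentage of the total over all
    recovered fractions of the gradient, so both columns sum to 100.
    """
    frame = profile.to_frame()
    for col, out in (("dna_ng", "dna_percent"), ("copies_16s", "copies_percent")):
        total = frame[col].sum()
        if total <= 0:
            raise ValueError(f"cannot normalize: {col} is zero across the gradient")
        frame[out] = frame[col] / total * 100.0
    return frame


def pool_fractions(
    profile: GradientProfile, scheme: PoolingScheme
) -> tuple[list[PooledFraction], pd.DataFrame]:
    """Group fractions into named pooled fractions by measured density.

    Returns the pooled fractions (densest-first, one per window that
    captured at least one fraction is required in total) and a table of
    unpooled fractions; fractions outside every window are reported, not
    silently dropped.
    """
    norm = normalize_profile(profile)
    norm["pool"] = [scheme.assign(d) for d in norm["density_g_ml"]]
    if norm["pool"].notna().sum() == 0:
        raise ValueError("pooling scheme captures no fractions of this gradient")
    pooled: list[PooledFraction] = []
    for w in scheme.windows:
        members = norm[norm["pool"] == w.name]
        pooled.append(
            PooledFraction(
                name=w.name,
                member_indices=tuple(int(i) for i in members["fraction_index"]),
                dna_percent=float(members["dna_percent"].sum()),
                copies_percent=float(members["copies_percent"].sum()),
                dense=w.dense,
            )
        )
    unpooled = norm[norm["pool"].isna()].drop(columns="pool")
    if len(unpooled):
        logger.info(
            "%d fraction(s) fall outside all pooling windows (%.3f%% of DNA)",
            len(unpooled),
            unpooled["dna_percent"].sum(),
        )
    return pooled, unpooled.reset_index(drop=True)


def density_shift(labeled: GradientProfile, control: GradientProfile) -> float:
    """DNA-weighted mean density of the labeled gradient minus the control's.

    A positive value means labeled DNA bands denser on average — the
    gradient-level signature of heavy-isotope incorporation.
    """
    if labeled.substrate != control.substrate:
        raise ValueError(
            f"substrate mismatch: {labeled.substrate!r} vs {control.substrate!r}"
        )

    def weighted_mean(profile: GradientProfile) -> float:
        frame = normalize_profile(profile)
        return float(np.average(frame["density_g_ml"], weights=frame["dna_percent"]))

    return weighted_mean(labeled) - weighted_mean(control)


def fraction_count(gradient_volume_ml: float, fraction_volume_ul: float) -> int:
    """Number of fractions obtained by drop-wise collection.

    A 4.8 ml gradient split into 400 ul fractions yields 12; into 200 ul
    fractions, 24.
    """
    if gradient_volume_ml <= 0 or fraction_volume_ul <= 0:
        raise ValueError("volumes must be positive")
    n = gradient_volume_ml * 1000.0 / fraction_volume_ul
    return int(round(n))


def default_scheme(
    substrate: str, density_min: float = 1.66, density_max: float = 1.78
) -> PoolingScheme:
    """Shipped pooling schemes.

    Cellulose gradients use three windows (upper / medium / lower) with
    medium and lower dense; urea gradients use four (upper / upper_medium
    / lower_medium / lower) with the three densest dense.  Bounds are
    configuration values; the defaults follow the selection rule that
    pooled ranges are chosen where labeled and control gradients show a
    visible DNA difference: the dense windows sit above the buoyant
    densities of a typical unlabeled community (GC up to ~65%, i.e.
    about 1.724 g/ml), so control DNA reaches them only as band tails.
    """
    span = density_max - density_min
    if substrate == "cellulose":
        b1 = density_min + 7 / 12 * span
        b2 = density_min + 9 / 12 * span
        return PoolingScheme(
            [
                DensityWindow("upper", density_min, b1, dense=False),
                DensityWindow("medium", b1, b2, dense=True),
                DensityWindow("lower", b2, density_max, dense=True),
            ]
        )
    if substrate == "urea":
        b1 = density_min + 13 / 24 * span
        b2 = density_min + 16 / 24 * span
        b3 = density_min + 19 / 24 * span
        return PoolingScheme(
            [
                DensityWindow("upper", density_min, b1, dense=False),
                DensityWindow("upper_medium", b1, b2, dense=True),
                DensityWindow("lower_medium", b2, b3, dense=True),
                DensityWindow("lower", b3, density_max, dense=True),
            ]
        )
    raise ValueError(f"unknown substrate {substrate!r}; expected 'cellulose' or 'urea'")
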