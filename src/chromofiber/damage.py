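"""Strand-break induction from energy deposits in backbone volumes.

Energy deposited inside a sugar-phosphate backbone volume is accumulated
per (primary history, strand, bp) and converted into a strand break by an
energy-threshold (ET) model:

* **constant(T)** — the backbone breaks iff its accumulated energy reaches
  the threshold (boundary inclusive; the canonical values 8.22, 12.6, 17.5
  and 21.25 eV are the minimum excitation energy of water, its first
  ionization energy, the KURBUC threshold and the midpoint of the linear
  ramp, respectively);
* **linear** — break probability 0 below 5 eV, 1 at or above 37.5 eV,
  linear in between, so P(21.25 eV) = 0.5.

Deposits in base, histone or water volumes contribute nothing (base damage
is out of scope).  A backbone volume breaks at most once per history.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Union

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError
from .geometry import KIND_BACKBONE, FiberGeometry

__all__ = [
    "ConstantET",
    "LinearET",
    "BreakModel",
    "parse_model",
    "BackboneEnergyMap",
    "StrandBreak",
    "accumulate",
    "break_probability",
    "induce_breaks",
]

CANONICAL_THRESHOLDS_EV = (8.22, 12.6, 17.5, 21.25)


@dataclass(frozen=True)
class ConstantET:
    """Step-function ET model: break iff accumulated energy >= threshold."""

    threshold_eV: float

    def __post_init__(self) -> None:
        if self.threshold_eV <= 0:
            raise InvalidArgumentError("threshold must be positive")

    def probability(self, edep_eV: np.ndarray) -> np.ndarray:
        return (np.asarray(edep_eV, dtype=float) >= self.threshold_eV).astype(float)

    @property
    def deterministic(self) -> bool:
        return True

    def __str__(self) -> str:
        return f"constant:{self.threshold_eV:g}"


@dataclass(frozen=True)
class LinearET:
    """Linear proportional ET model between ``e_min`` and ``e_max``."""

    e_min_eV: float = 5.0
    e_max_eV: float = 37.5

    def __post_init__(self) -> None:
        if not self.e_min_eV < self.e_max_eV:
            raise InvalidArgumentError("e_min must be < e_max")

    def probability(self, edep_eV: np.ndarray) -> np.ndarray:
        e = np.asarray(edep_eV, dtype=float)
        return np.clip((e - self.e_min_eV) / (self.e_max_eV - self.e_min_eV), 0.0, 1.0)

    @property
    def deterministic(self) -> bool:
        return False

    def __str__(self) -> str:
        return "linear"


BreakModel = Union[ConstantET, LinearET]


def parse_model(text: str) -> BreakModel:
    """Parse ``"linear"`` or ``"constant:<eV>"`` (CLI syntax)."""
    text = text.strip().lower()
    if text == "linear":
        return LinearET()
    if text.startswith("constant:"):
        return ConstantET(threshold_eV=float(text.split(":", 1)[1]))
    raise InvalidArgumentError(f"unrecognized ET model {text!r}; use 'linear' or 'constant:<eV>'")


def break_probability(edep_eV: float, model: BreakModel) -> float:
    """Probability that an accumulated backbone energy causes a break."""
    if np.any(np.asarray(edep_eV) < 0):
        raise InvalidArgumentError("edep must be >= 0")
    return float(model.probability(edep_eV)) if np.isscalar(edep_eV) else model.probability(edep_eV)


@dataclass(frozen=True)
class BackboneEnergyMap:
    """Accumulated backbone energies keyed by (history_id, strand, bp_index)."""

    energies: dict[tuple[int, int, int], float]

    def __len__(self) -> int:
        return len(self.energies)

    def total_eV(self) -> float:
        return float(sum(self.energies.values()))

    def to_frame(self) -> pd.DataFrame:
        if not self.energies:
            return pd.DataFrame(columns=["history_id", "strand", "bp_index", "edep_eV"])
        keys = np.array(list(self.energies.keys()), dtype=np.int64)
        return pd.DataFrame(
            {
                "history_id": keys[:, 0],
                "strand": keys[:, 1],
                "bp_index": keys[:, 2],
                "edep_eV": np.fromiter(self.energies.values(), dtype=float, count=len(self.energies)),
            }
        )


class StrandBreak(NamedTuple):
    history_id: int
    strand: int
    bp_index: int
    edep_eV: float


def accumulate(events: pd.DataFrame, geometry: FiberGeometry) -> BackboneEnergyMap:
    """Bin deposited energy into backbone volumes per primary history."""
    if len(events) == 0:
        return BackboneEnergyMap({})
    pts = events[["x_nm", "y_nm", "z_nm"]].to_numpy(dtype=float)
    kind, strand, bp_index, _ = geometry.locate_many(pts, skip_histone=True)
    mask = kind == KIND_BACKBONE
    if not mask.any():
        return BackboneEnergyMap({})
    df = pd.DataFrame(
        {
            "history_id": events["history_id"].to_numpy()[mask],
            "strand": strand[mask],
            "bp_index": bp_index[mask],
            "edep_eV": events["edep_eV"].to_numpy(dtype=float)[mask],
        }
    )
    grouped = df.groupby(["history_id", "strand", "bp_index"], sort=True)["edep_eV"].sum()
    return BackboneEnergyMap({(int(h), int(s), int(b)): float(e) for (h, s, b), e in grouped.items()})


def induce_breaks(energy_map: BackboneEnergyMap, model: BreakModel,
                  rng: np.random.Generator | None = None) -> list[StrandBreak]:
    """Convert accumulated backbone energies into strand breaks.

    Constant-threshold models are deterministic; the linear model needs a
    seeded ``rng``.  Output is sorted by (history, strand, bp).
    """
    if not energy_map.energies:
        return []
    keys = list(energy_map.energies.keys())
    edep = np.fromiter(energy_map.energies.values(), dtype=float, count=len(keys))
    p = model.probability(edep)
    if model.deterministic:
        hit = p >= 1.0
    else:
        if rng is None:
            raise InvalidArgumentError("the linear ET model requires a seeded rng")
        hit = rng.random(len(p)) < p
    breaks = [
        StrandBreak(history_id=k[0], strand=k[1], bp_index=k[2], edep_eV=float(e))
        for k, e, h in zip(keys, edep, hit)
        if h
    ]
    breaks.sort(key=lambda b: (b.history_id, b.strand, b.bp_index))
    return breaks
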