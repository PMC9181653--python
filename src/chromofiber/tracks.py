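"""Synthetic track-structure generator.

Emulates the energy-deposition pattern of MeV protons traversing the
scoring region: each primary history is a straight chord through the
envelope (heavy charged particles barely scatter at these energies), with
interaction sites distributed as a Poisson process along the chord.  Each
site spawns a Poisson-distributed cluster of deposits displaced
isotropically around it — the nanometre-scale signature of the secondary
electrons that carry most of the damaging energy.  Per-deposit energies are
drawn from a two-component spectrum (excitation-like peak plus an
ionization tail) in which most single deposits fall below 17.5 eV.

The canonical event container is a :class:`pandas.DataFrame` with columns
``history_id x_nm y_nm z_nm edep_eV tag``; the same table round-trips
through the TSV format written by :func:`write_events`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EventParseError, InvalidArgumentError

__all__ = [
    "DepositionEvent",
    "SpectrumParams",
    "TrackParams",
    "Cylinder",
    "generate_tracks",
    "absorbed_dose",
    "write_events",
    "read_events",
    "EVENT_COLUMNS",
]

EVENT_COLUMNS = ["history_id", "x_nm", "y_nm", "z_nm", "edep_eV", "tag"]
EV_TO_J = 1.602176634e-19


class DepositionEvent(NamedTuple):
    """One energy deposit of one primary history."""

    history_id: int
    x_nm: float
    y_nm: float
    z_nm: float
    edep_eV: float
    tag: str = "secondary"


@dataclass(frozen=True)
class Cylinder:
    """Finite cylinder centered at the origin, axis along z."""

    radius_nm: float
    length_nm: float

    @property
    def half_length_nm(self) -> float:
        return self.length_nm / 2.0

    @property
    def volume_nm3(self) -> float:
        return math.pi * self.radius_nm**2 * self.length_nm

    @property
    def mass_kg(self) -> float:
        """Mass of the enclosed liquid water (density 1 g/cm^3)."""
        return self.volume_nm3 * 1e-24

    @property
    def bounding_radius_nm(self) -> float:
        return math.hypot(self.radius_nm, self.half_length_nm)


@dataclass(frozen=True)
class SpectrumParams:
    """Per-deposit energy spectrum: a truncated-normal excitation component
    plus an exponential ionization tail starting at the first ionization
    energy of water (12.6 eV).  Defaults keep ~80% of single deposits below
    17.5 eV and leave little mass between 17.5 and 21.25 eV relative to the
    tail beyond, the qualitative regime the damage model operates in."""

    excitation_weight: float = 0.75
    excitation_mean_eV: float = 11.0
    excitation_sigma_eV: float = 3.0
    excitation_lo_eV: float = 1.0
    excitation_hi_eV: float = 17.5
    ionization_offset_eV: float = 12.6
    ionization_scale_eV: float = 15.0

    def _truncnorm(self):
        a = (self.excitation_lo_eV - self.excitation_mean_eV) / self.excitation_sigma_eV
        b = (self.excitation_hi_eV - self.excitation_mean_eV) / self.excitation_sigma_eV
        return stats.truncnorm(a, b, loc=self.excitation_mean_eV, scale=self.excitation_sigma_eV)

    def prob_below(self, edep_eV: float) -> float:
        """Analytic P(single deposit < edep_eV)."""
        w = self.excitation_weight
        p_exc = float(self._truncnorm().cdf(edep_eV))
        p_ion = float(stats.expon(loc=self.ionization_offset_eV, scale=self.ionization_scale_eV).cdf(edep_eV))
        return w * p_exc + (1.0 - w) * p_ion

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if n == 0:
            return np.empty(0)
        is_exc = rng.random(n) < self.excitation_weight
        out = np.empty(n)
        n_exc = int(is_exc.sum())
        if n_exc:
            out[is_exc] = self._truncnorm().rvs(size=n_exc, random_state=rng)
        n_ion = n - n_exc
        if n_ion:
            out[~is_exc] = self.ionization_offset_eV + rng.exponential(self.ionization_scale_eV, n_ion)
        return out


@dataclass(frozen=True)
class TrackParams:
    """Ensemble parameters.

    ``deposits_per_nm`` is the mean linear density of deposits along the
    primary chord and acts as the LET proxy (monotone in 1/proton-energy);
    ``cluster_size_mean`` and ``radial_sigma_nm`` shape the secondary-electron
    clusters around each interaction site.
    """

    n_tracks: int = 1000
    deposits_per_nm: float = 3.0
    cluster_size_mean: float = 5.0
    radial_sigma_nm: float = 1.0
    spectrum: SpectrumParams = field(default_factory=SpectrumParams)
    seed: int = 0

    def validate(self) -> None:
        if self.n_tracks < 0:
            raise InvalidArgumentError("n_tracks must be >= 0")
        if self.deposits_per_nm < 0 or self.cluster_size_mean <= 0 or self.radial_sigma_nm < 0:
            raise InvalidArgumentError("rates and spreads must be non-negative (cluster size positive)")
        if self.spectrum.prob_below(17.5) <= 0.5:
            raise InvalidArgumentError(
                "spectrum must put most single-deposit energies below 17.5 eV"
            )


def _chord_through_cylinder(rng: np.random.Generator, cyl: Cylinder) -> tuple[np.ndarray, np.ndarray, float] | None:
    """One isotropic uniform random chord (mu-randomness): an isotropic
    direction plus a uniform offset on the perpendicular disc of the
    bounding sphere.  Returns (entry point, unit direction, chord length) or
    None if the line misses the cylinder."""
    # isotropic direction
    u = rng.normal(size=3)
    u /= np.linalg.norm(u)
    # orthonormal basis perpendicular to u
    a = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    v = np.cross(u, a)
    v /= np.linalg.norm(v)
    w = np.cross(u, v)
    rr = cyl.bounding_radius_nm * math.sqrt(rng.random())
    phi = rng.random() * 2.0 * math.pi
    q = rr * (math.cos(phi) * v + math.sin(phi) * w)

    # intersect line q + t*u with the finite cylinder
    t_lo, t_hi = -math.inf, math.inf
    # side surface: (qx + t ux)^2 + (qy + t uy)^2 <= r^2
    aa = u[0] ** 2 + u[1] ** 2
    bb = 2.0 * (q[0] * u[0] + q[1] * u[1])
    cc = q[0] ** 2 + q[1] ** 2 - cyl.radius_nm**2
    if aa > 1e-12:
        disc = bb * bb - 4.0 * aa * cc
        if disc <= 0.0:
            return None
        sq = math.sqrt(disc)
        t_lo = (-bb - sq) / (2.0 * aa)
        t_hi = (-bb + sq) / (2.0 * aa)
    elif cc > 0.0:
        return None
    # caps: |qz + t uz| <= h
    if abs(u[2]) > 1e-12:
        t1 = (-cyl.half_length_nm - q[2]) / u[2]
        t2 = (cyl.half_length_nm - q[2]) / u[2]
        t_lo = max(t_lo, min(t1, t2))
        t_hi = min(t_hi, max(t1, t2))
    elif abs(q[2]) > cyl.half_length_nm:
        return None
    if t_hi <= t_lo:
        return None
    entry = q + t_lo * u
    return entry, u, t_hi - t_lo


def generate_tracks(params: TrackParams, envelope: Cylinder) -> pd.DataFrame:
    """Generate the deposition-event table for ``params.n_tracks`` histories.

    Each history owns an independent RNG stream seeded from
    ``(params.seed, history_id)``, so results are reproducible regardless of
    execution order.  Histories whose chord misses the envelope contribute
    no events.
    """
    params.validate()
    frames: list[pd.DataFrame] = []
    site_rate = params.deposits_per_nm / params.cluster_size_mean
    for hist in range(params.n_tracks):
        rng = np.random.default_rng(np.random.SeedSequence([abs(int(params.seed)), hist]))
        chord = _chord_through_cylinder(rng, envelope)
        if chord is None or params.deposits_per_nm == 0:
            continue
        entry, direction, length = chord
        n_sites = rng.poisson(site_rate * length)
        if n_sites == 0:
            continue
        t_sites = np.sort(rng.random(n_sites)) * length
        n_dep = rng.poisson(params.cluster_size_mean, n_sites)
        total = int(n_dep.sum())
        if total == 0:
            continue
        site_pos = entry[None, :] + t_sites[:, None] * direction[None, :]
        centers = np.repeat(site_pos, n_dep, axis=0)
        offsets = rng.normal(scale=params.radial_sigma_nm, size=(total, 3)) if params.radial_sigma_nm > 0 else 0.0
        pos = centers + offsets
        edep = params.spectrum.sample(rng, total)
        first_of_site = np.zeros(total, dtype=bool)
        first_of_site[np.concatenate([[0], np.cumsum(n_dep)[:-1]])[n_dep > 0]] = True
        frames.append(
            pd.DataFrame(
                {
                    "history_id": np.full(total, hist, dtype=np.int64),
                    "x_nm": pos[:, 0],
                    "y_nm": pos[:, 1],
                    "z_nm": pos[:, 2],
                    "edep_eV": edep,
                    "tag": np.where(first_of_site, "primary", "secondary"),
                }
            )
        )
    if not frames:
        return pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(EVENT_COLUMNS, [np.int64, float, float, float, float, object])})
    return pd.concat(frames, ignore_index=True)


def absorbed_dose(events: pd.DataFrame, mass_kg: float) -> float:
    """Absorbed dose in Gy: total deposited energy (J) over the mass of the
    scoring region (liquid water, 1 g/cm^3)."""
    if mass_kg <= 0:
        raise InvalidArgumentError(f"mass_kg must be > 0, got {mass_kg}")
    return float(events["edep_eV"].sum()) * EV_TO_J / mass_kg


def write_events(events: pd.DataFrame, path: str) -> None:
    """Write the event table as TSV (header ``history_id x_nm y_nm z_nm
    edep_eV tag``), lossless at 9 significant digits."""
    events.to_csv(path, sep="\t", index=False, columns=EVENT_COLUMNS, float_format="%.9g")


def read_events(path: str) -> pd.DataFrame:
    """Read and validate an event TSV (possibly produced elsewhere)."""
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:  # malformed structure
        raise EventParseError(f"{path}: {exc}") from exc
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise EventParseError(f"{path}: missing columns {missing}")
    df = df[EVENT_COLUMNS]
    if len(df) == 0:
        return df.astype({"history_id": np.int64, "x_nm": float, "y_nm": float, "z_nm": float, "edep_eV": float})
    numeric = df[["x_nm", "y_nm", "z_nm", "edep_eV"]].apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().any(axis=1) | ~np.isfinite(numeric).all(axis=1) | (numeric["edep_eV"] <= 0)
    if bad.any():
        line = int(bad.idxmax()) + 2  # header is line 1
        raise EventParseError(f"{path}: invalid event on line {line} (non-numeric, non-finite or edep_eV <= 0)")
    out = df.copy()
    out[["x_nm", "y_nm", "z_nm", "edep_eV"]] = numeric
    out["history_id"] = out["history_id"].astype(np.int64)
    return out


def fiber_envelope_from_config(config) -> Cylinder:
    """Scoring cylinder matching a :class:`~chromofiber.geometry.FiberConfig`."""
    return Cylinder(radius_nm=config.fiber_diameter_nm / 2.0, length_nm=config.fiber_length_nm)
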