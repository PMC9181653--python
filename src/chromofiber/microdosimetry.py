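"""Single-event microdosimetry: lineal-energy spectra in nanometre spheres.

The lineal energy of a single event is y = ε / l̄, where ε is the energy a
single primary history deposits inside a spherical scoring volume and l̄ is
the mean chord length of that sphere — 2d/3 for diameter d under Cauchy's
theorem for convex bodies.  The frequency-mean y_F and dose-mean y_D are the
first moment of f(y) and the ratio of its second to first moment; both are
estimated here by the corresponding sample moments.

Spheres are anchored on the track: each scoring sphere is centered at a
randomly chosen deposition displaced by an isotropic offset shorter than
the sphere radius, so every sphere contains at least one deposit.  Internal
units are eV/nm; 1 eV/nm = 1 keV/µm, so values are numerically identical in
either unit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import InvalidArgumentError, UndefinedResultError

__all__ = [
    "ScoringSphere",
    "mean_chord_length",
    "place_spheres",
    "single_event_energies",
    "spectrum_stats",
    "lineal_energy_table",
    "log_histogram",
]

CANONICAL_DIAMETERS_NM = (2.3, 10.0, 30.0)


@dataclass(frozen=True)
class ScoringSphere:
    center: np.ndarray
    diameter_nm: float

    def __post_init__(self) -> None:
        if self.diameter_nm <= 0:
            raise InvalidArgumentError("sphere diameter must be > 0")


def mean_chord_length(d: float) -> float:
    """Cauchy mean chord length of a sphere of diameter ``d``: 2d/3."""
    if d <= 0:
        raise InvalidArgumentError(f"diameter must be > 0, got {d}")
    return 2.0 * d / 3.0


def place_spheres(events: pd.DataFrame, d: float, n_spheres: int,
                  rng: np.random.Generator) -> list[ScoringSphere]:
    """Place ``n_spheres`` scoring spheres of diameter ``d``, each centered
    at a uniformly chosen deposition plus an isotropic offset of length
    uniform in [0, d/2) — so the anchoring deposit is always inside."""
    if len(events) == 0:
        raise InvalidArgumentError("cannot place spheres on an empty event list")
    if d <= 0:
        raise InvalidArgumentError("sphere diameter must be > 0")
    pos = events[["x_nm", "y_nm", "z_nm"]].to_numpy(dtype=float)
    anchors = rng.integers(0, len(pos), size=n_spheres)
    direction = rng.normal(size=(n_spheres, 3))
    direction /= np.linalg.norm(direction, axis=1, keepdims=True)
    length = rng.random(n_spheres) * (d / 2.0)
    centers = pos[anchors] + direction * length[:, None]
    return [ScoringSphere(center=c, diameter_nm=d) for c in centers]


def single_event_energies(events: pd.DataFrame, spheres: list[ScoringSphere]) -> pd.DataFrame:
    """Per-(sphere, history) energy transfers ε.

    Each sample is the summed edep of one primary history inside one sphere;
    only positive samples are kept (a history absent from a sphere is not an
    event there).
    """
    if not spheres:
        return pd.DataFrame(columns=["sphere_id", "history_id", "eps_eV"])
    pos = events[["x_nm", "y_nm", "z_nm"]].to_numpy(dtype=float)
    hist = events["history_id"].to_numpy()
    edep = events["edep_eV"].to_numpy(dtype=float)
    tree = cKDTree(pos)
    rows = []
    for sid, sph in enumerate(spheres):
        idx = tree.query_ball_point(sph.center, sph.diameter_nm / 2.0)
        if not idx:
            continue
        idx = np.asarray(idx)
        df = pd.DataFrame({"history_id": hist[idx], "eps_eV": edep[idx]})
        eps = df.groupby("history_id")["eps_eV"].sum()
        for h, e in eps.items():
            if e > 0:
                rows.append((sid, int(h), float(e)))
    return pd.DataFrame(rows, columns=["sphere_id", "history_id", "eps_eV"])


def spectrum_stats(samples_eV: np.ndarray, d: float) -> tuple[float, float]:
    """Frequency- and dose-mean lineal energies (eV/nm == keV/µm).

    y_F is the sample mean of y = ε/l̄; y_D = E[y²]/E[y], the sample-moment
    estimator of the dose-weighted mean.
    """
    eps = np.asarray(samples_eV, dtype=float)
    if eps.size == 0:
        raise UndefinedResultError("no single-event energy samples")
    y = eps / mean_chord_length(d)
    y_f = float(np.mean(y))
    y_d = float(np.mean(y**2) / np.mean(y))
    return y_f, y_d


def lineal_energy_table(samples: pd.DataFrame, d: float) -> pd.DataFrame:
    """Spectrum table with columns ``sphere_d_nm history_id eps_eV
    y_keV_per_um`` (1 eV/nm = 1 keV/µm)."""
    out = samples.copy()
    out["sphere_d_nm"] = d
    out["y_keV_per_um"] = out["eps_eV"] / mean_chord_length(d)
    return out[["sphere_d_nm", "history_id", "eps_eV", "y_keV_per_um"]]


def log_histogram(y: np.ndarray, bins_per_decade: int = 40) -> pd.DataFrame:
    """Log-binned frequency histogram of lineal energies (plotting aid)."""
    y = np.asarray(y, dtype=float)
    y = y[y > 0]
    if y.size == 0:
        raise UndefinedResultError("no positive lineal energies")
    lo = np.floor(np.log10(y.min()))
    hi = np.ceil(np.log10(y.max())) + 1e-9
    edges = 10 ** np.arange(lo, hi + 1.0 / bins_per_decade, 1.0 / bins_per_decade)
    counts, edges = np.histogram(y, bins=edges)
    widths = np.diff(edges)
    f = counts / counts.sum() / widths
    return pd.DataFrame({"y_lo": edges[:-1], "y_hi": edges[1:], "f_y": f, "count": counts})
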