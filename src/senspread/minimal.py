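"""Analytic minimal model of senescence spread from a single cell.

A single senescent cell emits ``NE`` SASP ligands per hour onto a plane of
non-senescent cells.  Each emitted ligand finally binds (is internalised) at
distance ``r`` from the emitter with cumulative probability

    Pin(r) = r / (r + a),

where ``a`` is the capture length of the monolayer; with probability ``Pau``
the ligand is recaptured by its own emitter and never contributes to spread.
Partitioning the plane into concentric annuli of width ``2 * rcell`` converts
this into, per annulus:

* probability that a given ligand lands in the annulus (difference of Pin at
  the annulus edges, scaled by ``1 - Pau``);
* probability that it lands on one particular cell (cell area over annulus
  area, a factor ``rcell / (4 r)``);
* hourly induction rate per cell (binomial tail: at least ``ND`` of the
  ``NE`` emitted ligands land on that cell);
* hourly spread rate of the annulus (per-cell rate times the expected
  ``4 * sigma * r / rcell`` cells the annulus holds).

The probability of at least one induction anywhere within a time window then
follows from a Poisson-binomial combination over annuli, and scanning the
(``Rtot``, ``ND``) plane for the largest ``ND`` that still spreads traces the
phase boundary between contained and uncontrolled senescence spread.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .params import DerivedParams, KineticParams, derive_compound_params

__all__ = [
    "AnnulusGrid",
    "SpreadResult",
    "cumulative_binding_probability",
    "autocrine_probability",
    "annulus_binding_probability",
    "per_cell_binding_probability",
    "expected_ligands_bound",
    "induction_rate_per_cell",
    "expected_cells_in_annulus",
    "annulus_spread_rate",
    "prob_spread_by_time",
    "prob_any_annulus_spread",
    "build_annulus_grid",
    "nearest_neighbour_distance",
    "classify_spread",
    "spread_probability",
    "phase_boundary_scan",
    "UNCONTROLLABLE_WINDOW_H",
    "DEFAULT_SPREAD_THRESHOLD",
]

#: window within which a single senescent cell must convert a neighbour for
#: the spread to count as uncontrollable (2 days).
UNCONTROLLABLE_WINDOW_H = 48.0

#: "probability ~ 1" cut-off for classifying a parameter set as spreading.
DEFAULT_SPREAD_THRESHOLD = 0.99

#: default number of annuli in the grid; contributions decay as 1/r^3 so the
#: tail beyond 50 annuli is negligible (checked by doubling in the tests).
DEFAULT_N_ANNULI = 50


@dataclass(frozen=True)
class AnnulusGrid:
    """Concentric annuli of width ``2 * rcell`` around the emitting cell.

    ``centers[k] = r_start + (k + 1/2) * width``; every annulus lies fully
    outside the emitter.
    """

    r_start: float
    width: float
    n_annuli: int
    centers: np.ndarray

    def __post_init__(self) -> None:
        if self.n_annuli < 1:
            raise ValueError("annulus grid must contain at least one annulus")
        if np.any(np.diff(self.centers) <= 0):
            raise ValueError("annulus centers must be strictly increasing")


@dataclass(frozen=True)
class SpreadResult:
    """Spread probability over a time window and its classification."""

    p_spread: float
    per_annulus_p: np.ndarray
    classification: str  # "spreads" | "contained"
    window: float  # h

    @property
    def spreads(self) -> bool:
        return self.classification == "spreads"


def cumulative_binding_probability(r, d: DerivedParams):
    """Cumulative probability that a ligand finally binds within distance ``r``.

    ``Pin(r) = r / (r + a)`` with the capture length ``a``; autocrine
    trajectories are excluded from this distribution by construction.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("distance r must be >= 0")
    out = r / (r + d.a)
    return float(out) if out.ndim == 0 else out


def autocrine_probability(d: DerivedParams, internalized: bool = True) -> float:
    """Probability that a ligand is recaptured by its own emitter.

    The first-binding variant is ``Da / (Da + 4/pi)``; the internalisation
    (final-binding) variant scales the reaction side by ``nu``:
    ``nu * Da / (nu * Da + 4/pi)``.  They coincide when ``nu = 1``.
    """
    eff_da = d.nu * d.Da if internalized else d.Da
    return eff_da / (eff_da + 4.0 / math.pi)


def annulus_binding_probability(r, d: DerivedParams, rcell: float):
    """Probability that a ligand finally binds inside the annulus centred at ``r``.

    Telescoping-exact closed form

        (1 - Pau) * 2 * a * rcell / ((r + a)^2 - rcell^2),

    identically equal to ``(1 - Pau) * (Pin(r + rcell) - Pin(r - rcell))``.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= rcell):
        raise ValueError("annulus overlaps emitter: require r > rcell")
    out = (1.0 - d.Pau) * 2.0 * d.a * rcell / ((r + d.a) ** 2 - rcell**2)
    return float(out) if out.ndim == 0 else out


def per_cell_binding_probability(r, d: DerivedParams, rcell: float):
    """Probability that a ligand finally binds to one particular cell at ``r``.

    The annulus of width ``2 * rcell`` has area ``4 * pi * r * rcell``; one
    cell covers ``pi * rcell^2`` of it, a fraction ``rcell / (4 r)``.
    """
    r = np.asarray(r, dtype=float)
    out = annulus_binding_probability(r, d, rcell) * rcell / (4.0 * r)
    return float(out) if out.ndim == 0 else out


def expected_ligands_bound(r, p: KineticParams, d: DerivedParams):
    """Expected ligands bound per hour, lambda(r), by a cell at distance ``r``."""
    out = p.NE * np.asarray(per_cell_binding_probability(r, d, p.rcell))
    return float(out) if out.ndim == 0 else out


def induction_rate_per_cell(r, p: KineticParams, d: DerivedParams):
    """Hourly senescence-induction rate for one cell at distance ``r``.

    Of the ``NE`` ligands emitted in an hour, each lands on the target cell
    with the per-cell binding probability; induction requires at least ``ND``
    of them to do so, so the rate is the binomial survival function
    ``P[Binomial(NE, p_cell) >= ND]`` per hour.
    """
    ne = int(round(p.NE))
    nd = int(round(p.ND))
    if ne < 1:
        raise ValueError("binomial induction requires NE >= 1")
    pc = np.asarray(per_cell_binding_probability(r, d, p.rcell))
    if np.any(pc < 0) or np.any(pc > 1):
        raise ValueError("per-cell binding probability outside [0, 1]")
    # sf(nd - 1) = P[X >= nd]; handles nd = 0 (-> 1) and nd > ne (-> 0)
    out = stats.binom.sf(nd - 1, ne, pc)
    return float(out) if out.ndim == 0 else out


def expected_cells_in_annulus(r, sigma: float, rcell: float):
    """Expected cell count ``m(r) = 4 * sigma * r / rcell`` of an annulus."""
    out = 4.0 * sigma * np.asarray(r, dtype=float) / rcell
    return float(out) if out.ndim == 0 else out


def annulus_spread_rate(r, p: KineticParams, d: DerivedParams):
    """Hourly rate of creating a senescent cell anywhere in the annulus at ``r``."""
    m = expected_cells_in_annulus(r, p.sigma, p.rcell)
    out = m * np.asarray(induction_rate_per_cell(r, p, d))
    return float(out) if out.ndim == 0 else out


def prob_spread_by_time(r, t: float, p: KineticParams, d: DerivedParams):
    """Probability of at least one induction in the annulus at ``r`` within ``t`` hours."""
    if t < 0:
        raise ValueError("time window t must be >= 0")
    out = -np.expm1(-np.asarray(annulus_spread_rate(r, p, d)) * t)
    return float(out) if out.ndim == 0 else out


def prob_any_annulus_spread(
    grid: AnnulusGrid, t: float, p: KineticParams, d: DerivedParams,
    threshold: float = DEFAULT_SPREAD_THRESHOLD,
) -> SpreadResult:
    """Probability that at least one annulus produces a senescent cell by ``t``.

    The annuli are independent Bernoulli trials with unequal success
    probabilities (a Poisson-binomial family); the probability of one or more
    successes is ``1 - prod_k (1 - p_k)``.
    """
    if grid.n_annuli == 0 or len(grid.centers) == 0:
        raise ValueError("empty annulus grid")
    per_p = np.clip(np.asarray(prob_spread_by_time(grid.centers, t, p, d)), 0.0, 1.0)
    if np.any(per_p >= 1.0):
        p_spread = 1.0
    else:
        # log-space product for numerical robustness with many near-zero terms
        p_spread = float(-np.expm1(np.sum(np.log1p(-per_p))))
    classification = "spreads" if p_spread >= threshold else "contained"
    return SpreadResult(
        p_spread=p_spread, per_annulus_p=per_p,
        classification=classification, window=t,
    )


def nearest_neighbour_distance(p: KineticParams, juxtacrine_ring: bool = False) -> float:
    """Distance to the nearest candidate cells around the emitter.

    ``r1 = sqrt(pi * rcell^2 / sigma)`` is the average distance between cells
    at area fraction ``sigma``; with a ring of (non-emitting) juxtacrine
    senescent cells in contact with the emitter the nearest inducible cells
    sit one ring further out, ``r2 = 2 * r1``.
    """
    r1 = math.sqrt(math.pi * p.rcell**2 / p.sigma)
    return 2.0 * r1 if juxtacrine_ring else r1


def build_annulus_grid(
    p: KineticParams,
    juxtacrine_ring: bool = False,
    n_annuli: int = DEFAULT_N_ANNULI,
) -> AnnulusGrid:
    """Annulus grid of width ``2 * rcell`` with the first annulus at ``r1``.

    The first annulus is *centred* on the average nearest-cell distance
    ``r1`` (or ``r2`` with a juxtacrine ring) — the candidate cells sit at
    that distance — so it spans ``[r1 - rcell, r1 + rcell]``.
    """
    width = 2.0 * p.rcell
    r_start = nearest_neighbour_distance(p, juxtacrine_ring) - p.rcell
    centers = r_start + (np.arange(n_annuli) + 0.5) * width
    return AnnulusGrid(r_start=r_start, width=width, n_annuli=n_annuli, centers=centers)


def spread_probability(
    p: KineticParams,
    juxtacrine_ring: bool = False,
    window: float = UNCONTROLLABLE_WINDOW_H,
    n_annuli: int = DEFAULT_N_ANNULI,
    threshold: float = DEFAULT_SPREAD_THRESHOLD,
    derived: DerivedParams | None = None,
) -> SpreadResult:
    """Spread probability from a single senescent cell over ``window`` hours."""
    d = derived if derived is not None else derive_compound_params(p)
    grid = build_annulus_grid(p, juxtacrine_ring, n_annuli)
    return prob_any_annulus_spread(grid, window, p, d, threshold=threshold)


def classify_spread(
    p: KineticParams,
    juxtacrine_ring: bool = False,
    window: float = UNCONTROLLABLE_WINDOW_H,
    n_annuli: int = DEFAULT_N_ANNULI,
    threshold: float = DEFAULT_SPREAD_THRESHOLD,
) -> str:
    """Classify a parameter set as ``"spreads"`` or ``"contained"``.

    A single senescent cell that converts at least one neighbour within the
    window (2 days by default — roughly the time the body would take to clear
    it) with probability above the threshold marks uncontrollable spread.
    """
    return spread_probability(
        p, juxtacrine_ring=juxtacrine_ring, window=window,
        n_annuli=n_annuli, threshold=threshold,
    ).classification


def _largest_spreading_nd(
    p: KineticParams,
    nd_max: int,
    juxtacrine_ring: bool,
    window: float,
    threshold: float,
    n_annuli: int,
) -> int:
    """Largest integer ND (<= nd_max) that still spreads; 0 if none does.

    The binomial tail is non-increasing in ND, so the classification is
    monotone and bisection is exact.
    """

    def spreads(nd: int) -> bool:
        return (
            classify_spread(
                p.replace(ND=float(nd)), juxtacrine_ring=juxtacrine_ring,
                window=window, threshold=threshold, n_annuli=n_annuli,
            )
            == "spreads"
        )

    if not spreads(1):
        return 0
    lo, hi = 1, nd_max  # spreads(lo) True; hi may or may not spread
    if spreads(hi):
        return hi
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if spreads(mid):
            lo = mid
        else:
            hi = mid
    return lo


def phase_boundary_scan(
    p: KineticParams,
    rtot_values: Sequence[float],
    variants: Iterable[dict] | None = None,
    nd_max: int = 5000,
    window: float = UNCONTROLLABLE_WINDOW_H,
    threshold: float = DEFAULT_SPREAD_THRESHOLD,
    n_annuli: int = DEFAULT_N_ANNULI,
) -> pd.DataFrame:
    """Trace the spread / no-spread boundary in the (Rtot, ND) plane.

    For every ``Rtot`` and every variant (a dict of :class:`KineticParams`
    field overrides plus an optional ``juxtacrine_ring`` flag and ``name``),
    finds the largest ``ND`` for which senescence still spreads.  Returns a
    tidy frame with columns ``Rtot``, ``ND_boundary``, ``variant``.
    """
    if variants is None:
        variants = [{"name": "default"}]
    rows = []
    for variant in variants:
        overrides = dict(variant)
        name = overrides.pop("name", "variant")
        ring = bool(overrides.pop("juxtacrine_ring", False))
        base = p.replace(**overrides) if overrides else p
        for rtot in rtot_values:
            nd_star = _largest_spreading_nd(
                base.replace(Rtot=float(rtot)), nd_max=nd_max,
                juxtacrine_ring=ring, window=window,
                threshold=threshold, n_annuli=n_annuli,
            )
            rows.append({"Rtot": float(rtot), "ND_boundary": nd_star, "variant": name})
    return pd.DataFrame(rows)
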