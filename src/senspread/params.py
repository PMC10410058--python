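"""Kinetic parameters of SASP ligand capture and their compound quantities.

The monolayer is described by a small set of physical constants: the rate at
which a senescent cell emits SASP ligands (``NE``), the number of bound
ligands per hour needed to push a cell into senescence (``ND``), the ligand
diffusion coefficient ``DL``, the area fraction ``sigma`` covered by cells of
radius ``rcell``, and the receptor kinetics (``Rtot`` receptors per cell,
forward binding constant ``kon``, endocytosis rate ``ke``, dissociation rate
``koff``).

From these, boundary-homogenisation theory for a plane partially covered by
absorbing discs gives a handful of compound quantities that fully determine
where emitted ligands end up:

* ``nu = ke / (ke + koff)`` — probability that a bound ligand is internalised
  rather than released;
* ``kappa = kon * Rtot / (pi * rcell**2 * NA)`` — trapping rate constant of a
  single cell (velocity units);
* ``Da = rcell * kappa / DL`` — Damköhler number, reaction vs. diffusion;
* ``keff = kappa * sigma / (1 + pi * Da / 4)`` — effective trapping rate of
  the homogenised cell-covered surface;
* ``a = 1.1 * DL / (nu * keff)`` — capture length: the distance at which the
  cumulative probability of (final) ligand binding reaches one half;
* ``Pau = nu * Da / (nu * Da + 4 / pi)`` — probability of an autocrine
  trajectory (the ligand is internalised by its own emitter).

Internal unit convention: lengths in cm, times in hours for all rate
bookkeeping (``NE``, ``ND``, induction rates), with the exceptions dictated
by the inputs themselves — ``DL``, ``kappa`` and ``keff`` are carried in
cm²/s and cm/s because only the dimensionless combinations ``Da``, ``Pau``
and the length ``a`` enter the hourly rate calculations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

__all__ = [
    "AVOGADRO",
    "KineticParams",
    "DerivedParams",
    "derive_compound_params",
]

AVOGADRO = 6.02214076e23  # mol^-1

#: litres per cm^3 — kon arrives in M^-1 min^-1 = L mol^-1 min^-1
_L_PER_CM3 = 1e-3
_SECONDS_PER_MINUTE = 60.0


@dataclass(frozen=True)
class KineticParams:
    """Raw physical and kinetic constants of the monolayer signalling system.

    Parameters
    ----------
    NE : float
        Ligands emitted per senescent cell per hour (count/h).
    ND : float
        Bound-ligand threshold for senescence induction (count/h).
    DL : float
        Ligand diffusion coefficient (cm^2/s).
    sigma : float
        Cell area fraction of the plane (dimensionless, 0 < sigma < 1).
    rcell : float
        Cell radius (cm).
    Rtot : float
        Receptors per cell (count).
    ke : float
        Endocytosis rate of bound complexes (1/min).
    koff : float
        Dissociation rate of bound complexes (1/min).
    kon : float
        Forward binding rate constant (M^-1 min^-1).
    NA : float
        Avogadro constant (1/mol); fixed physical constant.
    irreversible_binding : bool
        Marks the regime where both ``ke`` and ``koff`` are negligible and a
        ligand that binds stays bound.  In that regime the internalisation
        probability is taken as 1 (the first binding event is final), which
        otherwise would be the undefined ratio 0/0.
    """

    NE: float = 2887.0
    ND: float = 62.0
    DL: float = 1e-6
    sigma: float = 0.35
    rcell: float = 10e-4
    Rtot: float = 1e5
    ke: float = 0.2
    koff: float = 0.2
    kon: float = 1e8
    NA: float = field(default=AVOGADRO, repr=False)
    irreversible_binding: bool = False

    def __post_init__(self) -> None:
        for name in ("NE", "ND", "Rtot", "ke", "koff", "kon"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)!r}")
        if not 0.0 < self.sigma < 1.0:
            raise ValueError(f"sigma must lie in (0, 1), got {self.sigma!r}")
        if self.rcell <= 0:
            raise ValueError(f"rcell must be > 0, got {self.rcell!r}")
        if self.DL <= 0:
            raise ValueError(f"DL must be > 0, got {self.DL!r}")
        if self.ke + self.koff == 0 and not self.irreversible_binding:
            raise ValueError(
                "undefined internalisation probability: ke = koff = 0; "
                "set irreversible_binding=True to mark the no-unbinding/"
                "no-endocytosis regime explicitly"
            )

    def replace(self, **changes) -> "KineticParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)


@dataclass(frozen=True)
class DerivedParams:
    """Compound capture quantities derived from :class:`KineticParams`.

    ``Pau`` is the internalisation (final-binding) variant of the autocrine
    probability, which is the one entering all downstream spread rates; the
    first-binding variant is available via :func:`senspread.minimal.autocrine_probability`.
    """

    nu: float  # internalisation probability, dimensionless
    kappa: float  # single-cell trapping rate constant, cm/s
    Da: float  # Damköhler number, dimensionless
    keff: float  # effective surface trapping rate, cm/s
    a: float  # capture length, cm
    Pau: float  # autocrine (internalisation) probability, dimensionless

    def __post_init__(self) -> None:
        if not 0.0 <= self.nu <= 1.0:
            raise ValueError(f"nu must lie in [0, 1], got {self.nu!r}")
        if not 0.0 <= self.Pau < 1.0:
            raise ValueError(f"Pau must lie in [0, 1), got {self.Pau!r}")
        if self.a <= 0:
            raise ValueError(f"capture length a must be > 0, got {self.a!r}")
        if self.Da < 0 or self.keff < 0:
            raise ValueError("Da and keff must be >= 0")


def derive_compound_params(p: KineticParams) -> DerivedParams:
    """Compute the compound capture quantities for a parameter set.

    ``kon`` is converted from M^-1 min^-1 (i.e. L mol^-1 min^-1) to
    cm^3 mol^-1 s^-1 before forming the trapping rate constant
    ``kappa = kon * Rtot / (pi * rcell^2 * NA)``, so that ``kappa`` carries
    velocity units (cm/s) and ``Da = rcell * kappa / DL`` is dimensionless.
    """
    if p.irreversible_binding:
        nu = 1.0
    else:
        nu = p.ke / (p.ke + p.koff)

    kon_cm3_per_mol_s = p.kon / _L_PER_CM3 / _SECONDS_PER_MINUTE
    kappa = kon_cm3_per_mol_s * p.Rtot / (math.pi * p.rcell**2 * p.NA)
    Da = p.rcell * kappa / p.DL
    keff = kappa * p.sigma / (1.0 + math.pi * Da / 4.0)
    if nu * keff == 0.0:
        raise ValueError(
            "capture length undefined: nu * keff = 0 (no internalisation or "
            "no trapping)"
        )
    a = 1.1 * p.DL / (nu * keff)
    pau = nu * Da / (nu * Da + 4.0 / math.pi)
    return DerivedParams(nu=nu, kappa=kappa, Da=Da, keff=keff, a=a, Pau=pau)
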