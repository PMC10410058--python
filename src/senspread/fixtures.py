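"""Small deterministic fixtures for tests and examples."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import lesion, minimal
from .params import KineticParams, derive_compound_params

__all__ = ["make_fixtures", "tiny_population_frame", "toy_annulus_grid"]


def tiny_population_frame() -> pd.DataFrame:
    """Five cells on fixed coordinates, one primary senescent at the origin.

    Distances are in cm for a 10 um cell radius; the four normal cells sit
    at 3-6 cell radii from the emitter.
    """
    rc = 10e-4
    rows = [
        (0, 0.0, 0.0, "senescent", "primary", 1.0),
        (1, 3 * rc, 0.0, "normal", "none", 0.0),
        (2, 0.0, 4 * rc, "normal", "none", 0.0),
        (3, -5 * rc, 0.0, "normal", "none", 0.0),
        (4, 0.0, -6 * rc, "normal", "none", 0.0),
    ]
    return pd.DataFrame(
        rows, columns=["id", "x", "y", "state", "mechanism", "sasp_scale"]
    )


def toy_annulus_grid(p: KineticParams | None = None) -> minimal.AnnulusGrid:
    """Three annuli with hand-checkable probabilities."""
    if p is None:
        p = KineticParams()
    return minimal.build_annulus_grid(p, n_annuli=3)


def make_fixtures(kind: str, seed: int, out_dir: str | Path) -> list[Path]:
    """Write one fixture kind to ``out_dir``; returns the files written."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if kind == "tiny-population":
        path = out_dir / "tiny_population.csv"
        tiny_population_frame().to_csv(path, index=False)
        written.append(path)
    elif kind == "toy-annuli":
        p = KineticParams()
        d = derive_compound_params(p)
        grid = toy_annulus_grid(p)
        df = pd.DataFrame(
            {
                "center": grid.centers,
                "p_annulus": minimal.annulus_binding_probability(
                    grid.centers, d, p.rcell
                ),
                "p_per_cell": minimal.per_cell_binding_probability(
                    grid.centers, d, p.rcell
                ),
            }
        )
        path = out_dir / "toy_annuli.csv"
        df.to_csv(path, index=False)
        written.append(path)
    elif kind == "synthetic-observation":
        design = lesion.ExperimentDesign()
        obs = lesion.generate_synthetic_observation(
            design, KineticParams(), seed=seed
        )
        df = pd.DataFrame(
            {
                "distance": obs.eval_distances,
                "fraction": obs.F,
                "n_cells": design.cells_per_distance,
            }
        )
        path = out_dir / "synthetic_observation.csv"
        df.to_csv(path, index=False)
        written.append(path)
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    return written
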