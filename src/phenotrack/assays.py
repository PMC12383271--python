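"""Closed-form assay calculations: MATH surface hydrophobicity, PAM
chlorophyll-fluorescence photophysiology and population count metrics."""

from __future__ import annotations

import logging
import numpy as np
import pandas as pd

from .presets import ValidationError

__all__ = [
    "hydrophobicity_percent",
    "max_quantum_yield",
    "effective_quantum_yield",
    "rel_electron_transport",
    "rapid_light_curve",
    "population_metrics",
]

log = logging.getLogger(__name__)


def hydrophobicity_percent(a0: float, a1: float) -> float:
    """MATH-assay hydrophobicity: (A0 - A1) / A0 * 100, where A0 and A1 are
    aqueous-layer cell counts without and with hexadecane.  Negative results
    (A1 > A0) are possible and flagged with a warning."""
    if a0 <= 0:
        raise ValidationError("A0 must be > 0")
    if a1 < 0:
        raise ValidationError("A1 must be >= 0")
    value = (a0 - a1) / a0 * 100.0
    if value < 0:
        log.warning("negative hydrophobicity (%0.1f%%): A1 exceeds A0", value)
    return value


def max_quantum_yield(f0: float, fm: float) -> float:
    """Maximum PSII quantum yield of dark-adapted cells: Fv/Fm = (Fm - F0)/Fm."""
    if fm <= 0:
        raise ValidationError("Fm must be > 0")
    if not fm >= f0 >= 0:
        raise ValidationError("require Fm >= F0 >= 0")
    return (fm - f0) / fm


def effective_quantum_yield(f: float, fm_prime: float) -> float:
    """Effective PSII quantum yield in the light: phi = (Fm' - F)/Fm'."""
    if fm_prime <= 0:
        raise ValidationError("Fm' must be > 0")
    if not fm_prime >= f >= 0:
        raise ValidationError("require Fm' >= F >= 0")
    return (fm_prime - f) / fm_prime


def rel_electron_transport(par: float, phi: float) -> float:
    """Relative electron transport rate through PSII: rETR = PAR * phi."""
    if par < 0:
        raise ValidationError("PAR must be >= 0")
    if not 0 <= phi <= 1:
        raise ValidationError("phi must lie in [0, 1]")
    return par * phi


def rapid_light_curve(readings: pd.DataFrame) -> pd.DataFrame:
    """Build an rETR-vs-PAR rapid light curve from saturation-pulse readings.

    ``readings`` needs columns ``F, Fm_prime, PAR``; rows are sorted by PAR,
    which must be strictly increasing after sorting (duplicate PAR levels
    are rejected).  Returns columns ``PAR, phi, rETR``.
    """
    required = {"F", "Fm_prime", "PAR"}
    if not required.issubset(readings.columns):
        raise ValidationError(f"readings must carry columns {sorted(required)}")
    df = readings.sort_values("PAR").reset_index(drop=True)
    par = df["PAR"].to_numpy(float)
    if np.any(np.diff(par) <= 0):
        raise ValidationError("PAR levels must be unique (strictly increasing)")
    phi = np.array(
        [effective_quantum_yield(f, fmp) for f, fmp in zip(df["F"], df["Fm_prime"])]
    )
    return pd.DataFrame({"PAR": par, "phi": phi, "rETR": par * phi})


def population_metrics(
    table: pd.DataFrame,
    population: str,
    t_start: float,
    t_end: float,
    algal_populations: tuple[str, ...] = ("haploid", "amoeboid"),
) -> dict:
    """Decline/growth metrics for one population between two time points.

    Uses a tidy count table with columns ``day, population, cells_per_ml``
    (densities averaged over samples at each day).  Returns raw values plus
    display-rounded companions; rounding never alters the raw fields.

    - ``percent_change``: (N_start - N_end)/N_start * 100, positive = decline.
    - ``fold_change``: N_end / N_start (inf, flagged, when N_start = 0).
    - ``fraction_of_total``: N_population / sum over ``algal_populations`` at
      t_end (bacteria excluded by default; denominator configurable).
    """
    required = {"day", "population", "cells_per_ml"}
    if not required.issubset(table.columns):
        raise ValidationError(f"count table must carry columns {sorted(required)}")

    def density(pop: str, day: float) -> float:
        sel = table[(table["population"] == pop) & (table["day"] == day)]
        if sel.empty:
            raise ValidationError(f"no rows for population={pop!r} at day={day}")
        return float(sel["cells_per_ml"].mean())

    n_start = density(population, t_start)
    n_end = density(population, t_end)
    percent = (n_start - n_end) / n_start * 100.0 if n_start > 0 else np.nan
    if n_start > 0:
        fold = n_end / n_start
        fold_flag = False
    else:
        fold = np.inf
        fold_flag = True
        log.warning("N_start = 0: fold change flagged infinite")
    total = sum(density(p, t_end) for p in algal_populations)
    fraction = n_end / total if total > 0 else np.nan
    return {
        "percent_change": percent,
        "percent_change_display": round(percent) if np.isfinite(percent) else percent,
        "fold_change": fold,
        "fold_change_infinite": fold_flag,
        "fraction_of_total": fraction,
        "n_start": n_start,
        "n_end": n_end,
    }
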