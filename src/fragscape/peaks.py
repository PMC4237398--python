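"""Quadratic extrema of fitted responses and peak-shift rates.

A fitted index with first- and second-order terms in a predictor
(distance to urban centers D, slope s, or slope SD) is a parabola with
vertex at -b1 / (2 b2): a maximum when b2 < 0, a minimum when b2 > 0.
The outward migration of the urban edge-to-area peak along D is the
quantitative signature of urban sprawl; its annual rate between two
dates is (later - earlier) / years, and the relative rate divides that
by the earlier peak location so differently sized regions compare.

Reported locations are rounded to one decimal (0.1 km or 0.1 degree)
and rates to two decimals. By default the shift rates are computed from
the rounded locations — the convention used when quoting locations and
rates together, so the printed numbers are mutually consistent — with
an unrounded mode available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sem import SEMFit

__all__ = [
    "QuadraticExtremum",
    "PeakShift",
    "quadratic_extremum",
    "peak_shift",
    "predicted_curve",
    "slope_extrema_report",
]


@dataclass
class QuadraticExtremum:
    """Vertex of a fitted quadratic response."""

    location: float          # units of the predictor (km for D, degrees for s)
    kind: str                # "maximum" | "minimum"
    value: float             # response at the vertex (relative to omitted terms)
    predictor: str = "D"
    source: str = ""

    @property
    def location_rounded(self) -> float:
        return round(self.location, 1)


@dataclass
class PeakShift:
    """Displacement of an extremum between two dates."""

    earlier: float
    later: float
    years: float
    absolute_rate: float     # predictor units per year
    relative_rate: float     # percent of the earlier location per year


def quadratic_extremum(
    b1: float,
    b2: float,
    b0: float = 0.0,
    predictor: str = "D",
    source: str = "",
) -> QuadraticExtremum:
    """Vertex of b0 + b1 x + b2 x^2; requires b2 != 0."""
    if b2 == 0:
        raise ValueError("no extremum: second-order coefficient is zero")
    loc = -b1 / (2.0 * b2)
    return QuadraticExtremum(
        location=loc,
        kind="maximum" if b2 < 0 else "minimum",
        value=b0 + b1 * loc + b2 * loc**2,
        predictor=predictor,
        source=source,
    )


def peak_shift(
    earlier: QuadraticExtremum,
    later: QuadraticExtremum,
    years: float,
    rounded: bool = True,
) -> PeakShift:
    """Absolute (units/yr) and relative (%/yr) displacement rates.

    With ``rounded`` (default) the locations enter at reporting
    precision (one decimal). The relative rate divides the *unrounded*
    annual rate by the earlier location, then reports to two decimals:
    e.g. locations 8.7 -> 10.4 over 9 years give 0.19 units/yr absolute
    and 2.17 %/yr relative.
    """
    if earlier.predictor != later.predictor:
        raise ValueError(
            f"extrema on different predictors: {earlier.predictor} vs {later.predictor}"
        )
    if earlier.kind != later.kind:
        raise ValueError("cannot compare a maximum with a minimum")
    if years <= 0:
        raise ValueError("years must be positive")
    loc1 = earlier.location_rounded if rounded else earlier.location
    loc2 = later.location_rounded if rounded else later.location
    if loc1 == 0:
        raise ZeroDivisionError("relative rate undefined for a zero earlier location")
    rate = (loc2 - loc1) / years
    return PeakShift(
        earlier=loc1,
        later=loc2,
        years=years,
        absolute_rate=rate,
        relative_rate=100.0 * rate / loc1,
    )


#: term spelling convention: the squared term of predictor "D" is "D2"
def _sq(name: str) -> str:
    return f"{name}2"


def predicted_curve(
    fit: SEMFit,
    predictor: str,
    grid: np.ndarray,
    others_at: dict[str, float] | None = None,
) -> np.ndarray:
    """Evaluate X b-hat along a predictor grid, other terms at their means.

    ``others_at`` maps every non-focal, non-intercept term of the fit to
    the value it is held at (typically the sample mean). The predictor's
    linear and squared terms (``name`` and ``name2``) vary with the grid.
    """
    terms = fit.term_names
    if predictor not in terms and _sq(predictor) not in terms:
        raise ValueError(f"fit has no terms in predictor {predictor!r}")
    others_at = others_at or {}
    grid = np.asarray(grid, dtype=float)
    out = np.zeros_like(grid)
    for term in terms:
        coef = float(fit.params[term])
        if term == "intercept":
            out += coef
        elif term == predictor:
            out += coef * grid
        elif term == _sq(predictor):
            out += coef * grid**2
        else:
            if term not in others_at:
                raise KeyError(f"no held value supplied for term {term!r}")
            out += coef * others_at[term]
    return out


def slope_extrema_report(
    fits: dict[str, SEMFit] | pd.DataFrame,
    predictors: tuple[str, ...] = ("s", "sigma_s"),
) -> pd.DataFrame:
    """Extrema of the terrain terms across a set of fitted models.

    Accepts either fitted models keyed by response label or a frame of
    printed coefficients (rows = response labels, columns = terms). A
    fit lacking the squared term of a predictor is skipped with a note
    row rather than an error.
    """
    if isinstance(fits, pd.DataFrame):
        coef_rows = {
            label: {c: row[c] for c in fits.columns if pd.notna(row[c])}
            for label, row in fits.iterrows()
        }
    else:
        coef_rows = {
            label: dict(zip(fit.term_names, fit.params.values))
            for label, fit in fits.items()
        }
    records = []
    for label, coefs in coef_rows.items():
        for pred in predictors:
            has = pred in coefs and _sq(pred) in coefs and coefs[_sq(pred)] != 0
            if not has:
                records.append(
                    {"source": label, "predictor": pred, "location": np.nan,
                     "kind": "absent", "note": "missing first/second-order term"}
                )
                continue
            ext = quadratic_extremum(
                coefs[pred], coefs[_sq(pred)], coefs.get("intercept", 0.0),
                predictor=pred, source=label,
            )
            records.append(
                {"source": label, "predictor": pred,
                 "location": ext.location_rounded, "kind": ext.kind, "note": ""}
            )
    return pd.DataFrame(records)
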