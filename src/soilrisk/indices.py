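"""Single- and multi-metal soil contamination indices.

Implements the classical battery of pollution indicators:

* contamination factor ``Cf = C / B`` against the geochemical background,
* geoaccumulation index ``Igeo = log2(C / (1.5 B))``,
* pollution load index ``PLI`` (geometric mean of Cf across metals),
* single pollution index ``Pi = C / S`` against a permissible limit and the
  Nemerow composite ``PIN = sqrt((mean(Pi)^2 + max(Pi)^2) / 2)``,
* enrichment factor ``EF = (Cn/Cref)_sample / (Bn/Bref)_background`` with Fe
  as the conservative reference element,

plus the standard class gradings for each index.  Summary statistics of
per-site indices are always computed site-wise and then aggregated — the
index of a mean concentration is not the mean index (Jensen gap).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (REFERENCE_METAL, BackgroundProfile, ConcentrationTable,
                   StandardProfile, ValidationError)

__all__ = [
    "contamination_factor", "igeo", "pli", "single_pollution_index",
    "nemerow", "enrichment_factor", "classify", "IndexReport",
    "index_report", "CLASS_TABLES",
]


def _frame(table) -> pd.DataFrame:
    return table.df if isinstance(table, ConcentrationTable) else pd.DataFrame(table)


# ---------------------------------------------------------------------------
# Elementary indices
# ---------------------------------------------------------------------------

def contamination_factor(table, background: BackgroundProfile) -> pd.DataFrame:
    """Per-site, per-metal contamination factor C/B (dimensionless)."""
    df = _frame(table)
    b = background.as_series(df.columns)
    return df / b


def igeo(table, background: BackgroundProfile) -> pd.DataFrame:
    """Geoaccumulation index log2(C / (1.5 B)).

    The 1.5 factor corrects for natural lithogenic variability.  Requires
    strictly positive concentrations and background.
    """
    df = _frame(table)
    if (df.to_numpy() <= 0).any():
        raise ValidationError("Igeo requires strictly positive concentrations")
    b = background.as_series(df.columns)
    return np.log2(df / (1.5 * b))


def pli(cf: pd.DataFrame | np.ndarray) -> pd.Series | float:
    """Pollution load index: geometric mean of contamination factors.

    Accepts a per-site Cf frame (returns a per-site Series) or a plain Cf
    vector (returns a float).
    """
    if isinstance(cf, pd.DataFrame):
        arr = cf.to_numpy()
        if (arr <= 0).any():
            raise ValidationError("PLI requires strictly positive Cf")
        return pd.Series(np.exp(np.log(arr).mean(axis=1)), index=cf.index,
                         name="PLI")
    arr = np.asarray(cf, dtype=float)
    if (arr <= 0).any():
        raise ValidationError("PLI requires strictly positive Cf")
    return float(np.exp(np.log(arr).mean()))


def single_pollution_index(table, standards: StandardProfile) -> pd.DataFrame:
    """Single pollution index Pi = C/S against the permissible limit S."""
    df = _frame(table)
    metals = [m for m in df.columns if m in standards]
    s = standards.as_series(metals)
    return df[metals] / s


def nemerow(pis) -> float | pd.Series:
    """Nemerow composite index sqrt((mean(Pi)^2 + max(Pi)^2) / 2).

    Accepts a Pi vector (float out) or a per-site frame (Series out).
    """
    if isinstance(pis, pd.DataFrame):
        if pis.shape[1] == 0:
            raise ValidationError("empty Pi input")
        m = pis.mean(axis=1)
        mx = pis.max(axis=1)
        return np.sqrt((m**2 + mx**2) / 2.0).rename("PIN")
    arr = np.asarray(pis, dtype=float)
    if arr.size == 0:
        raise ValidationError("empty Pi input")
    return float(np.sqrt((arr.mean() ** 2 + arr.max() ** 2) / 2.0))


def enrichment_factor(table, background: BackgroundProfile,
                      reference: str = REFERENCE_METAL) -> pd.DataFrame:
    """Enrichment factor, double ratio against the reference element.

    EF_n = (C_n / C_ref)_sample / (B_n / B_ref)_background.  The reference
    column is dropped from the output (its EF is identically 1).
    """
    df = _frame(table)
    if reference not in df.columns:
        raise ValidationError("reference metal absent")
    if reference not in background:
        raise ValidationError(f"reference metal {reference} missing from background")
    b = background.as_series(df.columns)
    sample_ratio = df.div(df[reference], axis=0)
    back_ratio = b / b[reference]
    ef = sample_ratio / back_ratio
    return ef.drop(columns=[reference])


# ---------------------------------------------------------------------------
# Class gradings
# ---------------------------------------------------------------------------

# Breakpoint convention: each bin is (lower, upper, label] with the lower
# bound exclusive and the upper bound inclusive, so an exact boundary value
# falls in the lower class; printed inclusive extremes (e.g. Igeo >= 5)
# override this at the ends.
CLASS_TABLES: dict[str, list[tuple[float, float, str]]] = {
    "Igeo": [
        (-np.inf, 0.0, "unpolluted"),
        (0.0, 1.0, "unpolluted to moderately polluted"),
        (1.0, 2.0, "moderately polluted"),
        (2.0, 3.0, "moderately to heavily polluted"),
        (3.0, 4.0, "heavily polluted"),
        (4.0, 5.0, "heavily to extremely polluted"),
        (5.0, np.inf, "extremely polluted"),
    ],
    "PLI": [
        (-np.inf, 1.0, "low level"),
        (1.0, 2.0, "moderate level"),
        (2.0, 3.0, "high level"),
        (3.0, np.inf, "extremely high level"),
    ],
    "PERI": [
        (-np.inf, 150.0, "low risk"),
        (150.0, 300.0, "moderate risk"),
        (300.0, 600.0, "considerable risk"),
        (600.0, np.inf, "high risk"),
    ],
    "EF": [
        (-np.inf, 1.0, "no enrichment"),
        (1.0, 3.0, "minor enrichment"),
        (3.0, 5.0, "moderate enrichment"),
        (5.0, 10.0, "moderate to severe enrichment"),
        (10.0, 25.0, "severe enrichment"),
        (25.0, 50.0, "very severe enrichment"),
        (50.0, np.inf, "extremely severe enrichment"),
    ],
    "PIN": [
        (-np.inf, 0.7, "secure"),
        (0.7, 1.0, "alert"),
        (1.0, 2.0, "slight"),
        (2.0, 3.0, "moderate"),
        (3.0, np.inf, "heavy"),
    ],
}

# The printed grading tables make the extreme Igeo class inclusive
# ("Igeo >= 5 extremely polluted"); same for the top EF/PLI/PERI bins via
# the open upper bound.  Exact value 5 therefore classifies as extreme.
_INCLUSIVE_TOP = {"Igeo": 5.0, "PERI": 600.0}


def classify(index_name: str, value: float) -> str:
    """Class label for an index value under the standard grading table."""
    if index_name not in CLASS_TABLES:
        raise ValidationError(f"unknown index {index_name!r}")
    top = _INCLUSIVE_TOP.get(index_name)
    if top is not None and value >= top:
        return CLASS_TABLES[index_name][-1][2]
    for lo, hi, label in CLASS_TABLES[index_name]:
        if lo < value <= hi or (lo == -np.inf and value <= hi):
            return label
    return CLASS_TABLES[index_name][-1][2]


def classify_frame(index_name: str, values) -> pd.DataFrame | pd.Series:
    """Vectorized :func:`classify` over a Series or DataFrame."""
    if isinstance(values, pd.DataFrame):
        return values.map(lambda v: classify(index_name, v))
    return values.map(lambda v: classify(index_name, v))


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

@dataclass
class IndexReport:
    """Values, class labels and a min/max/mean summary for one index."""

    index_name: str
    values: pd.DataFrame | pd.Series
    classes: pd.DataFrame | pd.Series
    summary: pd.DataFrame

    def to_long(self) -> pd.DataFrame:
        """Tidy (site, metal, index, value, class) frame."""
        v = self.values
        if isinstance(v, pd.Series):
            out = v.rename("value").to_frame()
            out["class"] = self.classes
            out = out.reset_index(names="site")
            out.insert(1, "metal", "")
        else:
            out = v.stack().rename("value").reset_index()
            out.columns = ["site", "metal", "value"]
            out["class"] = self.classes.stack().reset_index(drop=True)
        out.insert(0, "index", self.index_name)
        return out


def _summary(values) -> pd.DataFrame:
    if isinstance(values, pd.Series):
        values = values.to_frame(name="")
    return values.agg(["min", "max", "mean"])


def index_report(table: ConcentrationTable,
                 background: BackgroundProfile,
                 standards: StandardProfile) -> dict[str, IndexReport]:
    """Compute every index for a table; per-site first, summaries after."""
    reports: dict[str, IndexReport] = {}

    cf = contamination_factor(table, background)
    ig = igeo(table, background)
    reports["Igeo"] = IndexReport("Igeo", ig, classify_frame("Igeo", ig),
                                  _summary(ig))
    p = pli(cf)
    reports["PLI"] = IndexReport("PLI", p, classify_frame("PLI", p), _summary(p))
    ef = enrichment_factor(table, background)
    reports["EF"] = IndexReport("EF", ef, classify_frame("EF", ef), _summary(ef))
    pis = single_pollution_index(table, standards)
    pin = nemerow(pis)
    reports["PIN"] = IndexReport("PIN", pin, classify_frame("PIN", pin),
                                 _summary(pin))
    return reports
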