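"""Domain types and study registries shared by every pipeline stage.

The package models a sites x metals survey of topsoil trace metal(oid)
concentrations (mg/kg dry weight).  Eight elements are tracked in a fixed
reporting order: Cd, Pb, As, Cr, Ni, Cu, Zn, Fe.  Concentrations come in a
*total* (aqua-regia) fraction and an *available* fraction (DTPA extraction,
CaCl2 for Pb).

This module holds the concentration-table container and its validation, the
geochemical background and permissible-limit profiles, the toxicology
registry (Hakanson toxic-response factors, route-specific reference doses
and cancer slope factors) and the receptor exposure profiles used by the
deterministic and probabilistic risk stages.  All registry defaults are the
study's own values; every one can be overridden from a YAML config.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

#: Canonical metal(oid) reporting order.
METALS: tuple[str, ...] = ("Cd", "Pb", "As", "Cr", "Ni", "Cu", "Zn", "Fe")

#: Exposure routes in reporting order.
ROUTES: tuple[str, ...] = ("ingestion", "dermal", "inhalation")

#: Metals with published cancer slope factors.
CARCINOGENS: tuple[str, ...] = ("Pb", "Cd", "Cr", "Ni", "As")

#: Conservative lithogenic reference element for enrichment factors.
REFERENCE_METAL = "Fe"

FRACTIONS = ("total", "dtpa", "cacl2")


class ValidationError(ValueError):
    """Raised when an input table or registry violates its contract."""


def canonical_metals(columns) -> list[str]:
    """Return ``columns`` restricted to known metals, in canonical order."""
    known = [m for m in METALS if m in set(columns)]
    unknown = [c for c in columns if c not in METALS]
    if unknown:
        raise ValidationError(f"unknown metal column(s): {unknown}")
    return known


# ---------------------------------------------------------------------------
# Concentration tables
# ---------------------------------------------------------------------------

@dataclass
class ConcentrationTable:
    """Sites x metals concentration matrix (mg/kg dry weight).

    Wraps a :class:`pandas.DataFrame` whose index holds site identifiers and
    whose columns are metal symbols in canonical order.  ``fraction`` labels
    which extraction the values refer to.
    """

    df: pd.DataFrame
    fraction: str = "total"

    def __post_init__(self) -> None:
        if self.fraction not in FRACTIONS:
            raise ValidationError(
                f"fraction must be one of {FRACTIONS}, got {self.fraction!r}")
        self.df = self.df[canonical_metals(self.df.columns)].astype(float)
        self.df.index.name = "site"

    # -- accessors ----------------------------------------------------------
    @property
    def metals(self) -> list[str]:
        return list(self.df.columns)

    @property
    def site_ids(self) -> list:
        return list(self.df.index)

    @property
    def values(self) -> np.ndarray:
        return self.df.to_numpy()

    def __len__(self) -> int:
        return len(self.df)

    # -- i/o ----------------------------------------------------------------
    @classmethod
    def read_csv(cls, path, fraction: str | None = None) -> "ConcentrationTable":
        """Read a table from CSV.

        Layout: optional ``# fraction: <label>`` comment line, then a header
        row of metal symbols with the first column holding site ids.
        """
        path = Path(path)
        label = None
        with open(path) as fh:
            first = fh.readline()
        if first.startswith("#"):
            if "fraction:" in first:
                label = first.split("fraction:", 1)[1].strip()
            df = pd.read_csv(path, index_col=0, comment="#",
                             skiprows=1, header=0)
        else:
            df = pd.read_csv(path, index_col=0)
        return cls(df=df, fraction=fraction or label or "total")

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# fraction: {self.fraction}\n")
            self.df.to_csv(fh, index_label="site")


def validate_table(table: ConcentrationTable,
                   background: "BackgroundProfile | None" = None,
                   require_reference: bool = False) -> ConcentrationTable:
    """Validate a concentration table and return it with canonical ordering.

    Rejects negative or missing cells (naming the offending site and metal)
    and duplicated site ids.  When ``require_reference`` is set, the table
    must contain the enrichment reference metal (Fe).
    """
    df = table.df
    dup = df.index[df.index.duplicated()].tolist()
    if dup:
        raise ValidationError(f"duplicated site id(s): {dup}")
    bad = df.isna() | (df < 0)
    if bad.to_numpy().any():
        site = df.index[bad.any(axis=1)][0]
        metal = df.columns[bad.loc[site]][0]
        raise ValidationError(
            f"negative or missing concentration at site {site!r}, metal {metal}")
    if require_reference and REFERENCE_METAL not in df.columns:
        raise ValidationError("reference metal absent")
    if background is not None:
        missing = [m for m in df.columns if m not in background.values]
        if missing:
            raise ValidationError(f"background profile missing metal(s): {missing}")
    return table


def availability_ratio(available: ConcentrationTable,
                       total: ConcentrationTable) -> pd.DataFrame:
    """Per-site, per-metal available/total concentration ratio.

    Cells whose total concentration is zero are flagged as NaN (undefined)
    rather than raising; everything else is the plain ratio.  Use
    :func:`availability_ranking` for the metal ordering by mean ratio.
    """
    if total.fraction != "total":
        raise ValidationError("second table must hold the total fraction")
    if available.fraction == "total":
        raise ValidationError("first table must hold an available fraction")
    if set(available.site_ids) != set(total.site_ids):
        raise ValidationError("site sets differ between available and total tables")
    common = [m for m in total.metals if m in available.metals]
    av = available.df.loc[total.df.index, common]
    tot = total.df[common]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = av.to_numpy() / tot.to_numpy()
    ratio = np.where(tot.to_numpy() == 0, np.nan, ratio)
    return pd.DataFrame(ratio, index=tot.index, columns=common)


def availability_ranking(ratio: pd.DataFrame) -> pd.Series:
    """Metals ranked by mean availability ratio, descending."""
    return ratio.mean(axis=0, skipna=True).sort_values(ascending=False)


# ---------------------------------------------------------------------------
# Reference profiles
# ---------------------------------------------------------------------------

@dataclass
class _MetalProfile:
    """Base class: strictly positive per-metal scalar map."""

    values: dict[str, float]

    def __post_init__(self) -> None:
        for m, v in self.values.items():
            if m not in METALS:
                raise ValidationError(f"unknown metal {m!r}")
            if not v > 0:
                raise ValidationError(f"nonpositive value for {m}: {v}")
        self.values = {m: float(self.values[m]) for m in METALS
                       if m in self.values}

    def __getitem__(self, metal: str) -> float:
        return self.values[metal]

    def __contains__(self, metal: str) -> bool:
        return metal in self.values

    def as_series(self, metals=None) -> pd.Series:
        metals = list(metals) if metals is not None else list(self.values)
        missing = [m for m in metals if m not in self.values]
        if missing:
            raise ValidationError(f"profile missing metal(s): {missing}")
        return pd.Series({m: self.values[m] for m in metals}, dtype=float)


@dataclass
class BackgroundProfile(_MetalProfile):
    """Geochemical background concentrations Bn (mg/kg dw)."""


@dataclass
class StandardProfile(_MetalProfile):
    """Permissible-limit concentrations Si (mg/kg dw)."""


#: Local uncontaminated reference soil, total fraction (mg/kg dw).
DEFAULT_BACKGROUND = BackgroundProfile({
    "Cd": 0.3, "Pb": 9.5, "As": 0.625, "Cr": 12.0,
    "Ni": 14.3, "Cu": 3.5, "Zn": 26.5, "Fe": 6054.5,
})

#: Background of the extractable (bioavailable) fraction (mg/kg dw).
DEFAULT_BACKGROUND_AVAILABLE = BackgroundProfile({
    "Cd": 0.1, "Pb": 0.035, "As": 0.042, "Cr": 0.10,
    "Ni": 0.23, "Cu": 0.07, "Zn": 0.45, "Fe": 9.68,
})

#: WHO soil-quality guideline values used as the Nemerow standard (mg/kg dw).
#: No guideline value is used for Fe.
DEFAULT_STANDARDS = StandardProfile({
    "Pb": 100.0, "Cd": 2.0, "As": 25.0, "Cr": 150.0,
    "Ni": 50.0, "Cu": 100.0, "Zn": 300.0,
})


# ---------------------------------------------------------------------------
# Toxicology registry
# ---------------------------------------------------------------------------

@dataclass
class ToxicologyRegistry:
    """Per-metal toxicology constants.

    ``tr`` holds Hakanson toxic-response factors (dimensionless, Fe has
    none), ``rfd`` route-specific chronic reference doses
    (mg kg^-1 day^-1) and ``csf`` route-specific cancer slope factors
    ((mg kg^-1 day^-1)^-1, defined only for Pb, Cd, Cr, Ni and As).
    Route keys are ``ingestion``, ``dermal``, ``inhalation``.
    """

    tr: dict[str, float]
    rfd: dict[str, dict[str, float]]
    csf: dict[str, dict[str, float]]

    def __post_init__(self) -> None:
        for m in self.tr:
            if m == "Fe":
                raise ValidationError("Fe has no toxic-response factor")
        for table, name in ((self.rfd, "RfD"), (self.csf, "CSF")):
            for m, routes in table.items():
                for r, v in routes.items():
                    if r not in ROUTES:
                        raise ValidationError(f"unknown route {r!r} for {m}")
                    if not v > 0:
                        raise ValidationError(f"nonpositive {name} for {m}/{r}")
        extra = set(self.csf) - set(CARCINOGENS)
        if extra:
            raise ValidationError(
                f"CSF defined for non-carcinogenic metal(s): {sorted(extra)}")

    def toxic_response(self, metal: str) -> float:
        if metal not in self.tr:
            raise ValidationError(f"no toxic-response factor for {metal}")
        return self.tr[metal]

    def reference_dose(self, metal: str, route: str) -> float:
        try:
            return self.rfd[metal][route]
        except KeyError:
            raise ValidationError(f"no RfD for {metal}/{route}") from None

    def slope_factor(self, metal: str, route: str) -> float:
        if metal not in CARCINOGENS:
            raise ValidationError(f"no cancer slope factor for {metal}")
        return self.csf[metal][route]

    # -- yaml round trip ----------------------------------------------------
    def to_dict(self) -> dict:
        return {"tr": dict(self.tr),
                "rfd": {m: dict(r) for m, r in self.rfd.items()},
                "csf": {m: dict(r) for m, r in self.csf.items()}}

    @classmethod
    def from_dict(cls, d: Mapping) -> "ToxicologyRegistry":
        return cls(tr=dict(d["tr"]),
                   rfd={m: dict(r) for m, r in d["rfd"].items()},
                   csf={m: dict(r) for m, r in d["csf"].items()})

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "ToxicologyRegistry":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _routes(oral: float, dermal: float, inhal: float) -> dict[str, float]:
    return {"ingestion": oral, "dermal": dermal, "inhalation": inhal}


#: Hakanson toxic-response factors (Fe excluded).
DEFAULT_TR = {"Cd": 30.0, "As": 10.0, "Cu": 5.0, "Pb": 5.0,
              "Ni": 5.0, "Cr": 2.0, "Zn": 1.0}

DEFAULT_TOXICOLOGY = ToxicologyRegistry(
    tr=dict(DEFAULT_TR),
    rfd={
        "Pb": _routes(3.5e-3, 5.25e-4, 3.52e-3),
        "Cd": _routes(1.0e-3, 1.0e-5, 1.0e-5),
        "As": _routes(3.0e-4, 1.23e-4, 3.0e-4),
        "Cr": _routes(3.0e-3, 6.0e-5, 2.86e-5),
        "Ni": _routes(2.0e-2, 5.4e-3, 9.0e-5),
        "Cu": _routes(4.0e-2, 1.2e-2, 4.0e-2),
        "Zn": _routes(3.0e-1, 6.0e-2, 3.0e-1),
        "Fe": _routes(7.0e-1, 4.5e-2, 2.2e-4),
    },
    csf={
        "Pb": _routes(8.5e-3, 8.5e-3, 4.2e-2),
        "Cd": _routes(0.38, 0.38, 6.3),
        "As": _routes(1.5, 3.66, 15.1),
        "Cr": _routes(0.5, 2.0, 42.0),
        "Ni": _routes(1.7, 42.5, 0.84),
    },
)


# ---------------------------------------------------------------------------
# Exposure profiles
# ---------------------------------------------------------------------------

@dataclass
class ExposureProfile:
    """Receptor-group exposure parameters for the USEPA intake equations.

    Units: IngR mg/day; InhR m3/day; SA cm2; AF mg/cm2; ABS dimensionless;
    EF days/year; ED years; BW kg; AT days; PEF m3/kg.  The averaging time
    convention is AT = ED x 365 for both the non-carcinogenic and the
    carcinogenic pathway.
    """

    receptor: str
    IngR: float
    InhR: float
    SA: float
    AF: float
    ABS: float
    EF: float
    ED: float
    BW: float
    AT: float
    PEF: float = 1.36e9

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if f.name == "receptor":
                if v not in ("child", "adult"):
                    raise ValidationError(f"receptor must be child/adult, got {v!r}")
                continue
            if not float(v) > 0:
                raise ValidationError(f"exposure parameter {f.name} must be > 0")
        if self.AT < self.EF * self.ED:
            raise ValidationError("averaging time shorter than exposure period")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "ExposureProfile":
        return cls(**d)


DEFAULT_EXPOSURE = {
    "child": ExposureProfile(receptor="child", IngR=200, InhR=7.3, SA=2800,
                             AF=0.2, ABS=0.001, EF=350, ED=6, BW=15,
                             AT=2190, PEF=1.36e9),
    "adult": ExposureProfile(receptor="adult", IngR=100, InhR=20, SA=5800,
                             AF=0.07, ABS=0.001, EF=350, ED=24, BW=70,
                             AT=8760, PEF=1.36e9),
}


# ---------------------------------------------------------------------------
# Study descriptive statistics (survey inputs for worked examples)
# ---------------------------------------------------------------------------

#: Descriptive statistics of the 30-sample survey, total fraction (mg/kg dw).
STUDY_STATS = pd.DataFrame(
    {
        "Cd": [0.210, 2.930, 0.889, 0.7697],
        "Pb": [12.235, 78.968, 24.861, 0.5993],
        "As": [0.520, 2.988, 1.816, 0.3513],
        "Cr": [9.714, 51.900, 19.096, 0.5144],
        "Ni": [9.642, 53.728, 25.438, 0.4552],
        "Cu": [2.758, 16.481, 7.984, 0.5134],
        "Zn": [29.200, 85.406, 49.126, 0.3110],
        "Fe": [5671.5, 6583.0, 6183.317, 0.0309],
    },
    index=["min", "max", "mean", "cv"],
)

#: Concentration column of the deterministic risk tables.  Identical to
#: STUDY_STATS at 2 decimals except Cu, whose mean is listed there as 4.10.
RISK_TABLE_CONCENTRATIONS = pd.DataFrame(
    {
        "Cd": [0.21, 2.93, 0.89],
        "Pb": [12.24, 78.97, 24.86],
        "As": [0.52, 2.99, 1.81],
        "Cr": [9.71, 51.90, 19.10],
        "Ni": [9.64, 53.73, 25.44],
        "Cu": [2.76, 16.48, 4.10],
        "Zn": [29.20, 85.41, 49.13],
        "Fe": [5671.50, 6583.00, 6183.32],
    },
    index=["min", "max", "mean"],
)


def show_defaults() -> str:
    """YAML dump of every shipped registry/profile default, for audit."""
    blob = {
        "metals": list(METALS),
        "background_total": DEFAULT_BACKGROUND.values,
        "background_available": DEFAULT_BACKGROUND_AVAILABLE.values,
        "standards_who": DEFAULT_STANDARDS.values,
        "toxicology": DEFAULT_TOXICOLOGY.to_dict(),
        "exposure": {k: v.to_dict() for k, v in DEFAULT_EXPOSURE.items()},
    }
    return yaml.safe_dump(blob, sort_keys=False)
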