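"""Deterministic USEPA multi-route human-health risk.

Chronic daily intake (CDI, mg kg^-1 day^-1) per exposure route:

    CDI_ing  = C . IngR . EF . ED . 1e-6 / (BW . AT)
    CDI_inh  = C . InhR . EF . ED / (BW . AT . PEF)
    CDI_derm = C . AF . SA . ABS . EF . ED . 1e-6 / (BW . AT)

Non-carcinogenic risk: HQ = CDI / RfD per route, HI = sum of a metal's HQs
over routes, THI = sum of HIs over metals; THI > 1 flags likely adverse
effects.  Carcinogenic risk (Pb, Cd, Cr, Ni, As only): CR = CDI x CSF per
route, TCR = sum over metals and routes, screened against the 1e-6
(negligible) and 1e-4 (actionable) thresholds.

All computations are vectorised over a per-metal concentration Series or a
sites x metals DataFrame and are linear in concentration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (CARCINOGENS, ROUTES, ExposureProfile, ToxicologyRegistry,
                   ValidationError)

__all__ = [
    "cdi_ingestion", "cdi_inhalation", "cdi_dermal", "chronic_daily_intake",
    "hazard_quotient", "cancer_risk", "RiskReport", "risk_report",
    "classify_cancer_risk",
]


def cdi_ingestion(conc, p: ExposureProfile):
    """Soil-ingestion chronic daily intake."""
    return conc * p.IngR * p.EF * p.ED * 1e-6 / (p.BW * p.AT)


def cdi_inhalation(conc, p: ExposureProfile):
    """Inhalation chronic daily intake via the particle emission factor."""
    return conc * p.InhR * p.EF * p.ED / (p.BW * p.AT * p.PEF)


def cdi_dermal(conc, p: ExposureProfile):
    """Dermal-contact chronic daily intake."""
    return conc * p.AF * p.SA * p.ABS * p.EF * p.ED * 1e-6 / (p.BW * p.AT)


_CDI = {"ingestion": cdi_ingestion, "inhalation": cdi_inhalation,
        "dermal": cdi_dermal}


def chronic_daily_intake(conc, p: ExposureProfile, route: str):
    try:
        return _CDI[route](conc, p)
    except KeyError:
        raise ValidationError(f"unknown route {route!r}") from None


def hazard_quotient(cdi, rfd: float):
    """HQ = CDI / RfD."""
    if not rfd > 0:
        raise ValidationError("RfD must be > 0")
    return cdi / rfd


def cancer_risk(cdi, csf: float):
    """Incremental lifetime cancer risk CR = CDI x CSF."""
    return cdi * csf


def classify_cancer_risk(cr: float) -> str:
    """Screen a CR/TCR value against the 1e-6 / 1e-4 decision thresholds."""
    if cr < 1e-6:
        return "negligible"
    if cr > 1e-4:
        return "actionable"
    return "tolerable"


@dataclass
class RiskReport:
    """Deterministic risk bundle for one receptor.

    ``cdi``/``hq``/``cr`` map route -> per-metal values (Series for a single
    concentration vector, DataFrame sites x metals otherwise).  ``hi`` sums
    HQ over routes per metal, ``thi`` over metals; ``tcr`` sums CR over the
    carcinogenic metals and routes.
    """

    receptor: str
    cdi: dict[str, pd.Series | pd.DataFrame]
    hq: dict[str, pd.Series | pd.DataFrame]
    hi: pd.Series | pd.DataFrame
    thi: float | pd.Series
    cr: dict[str, pd.Series | pd.DataFrame]
    tcr: float | pd.Series

    @property
    def thi_exceeds(self) -> bool | pd.Series:
        return self.thi > 1.0

    def route_hq_totals(self) -> pd.Series | pd.DataFrame:
        """Cumulative HQ per route (the risk tables' totals rows)."""
        out = {r: (v.sum() if isinstance(v, pd.Series) else v.sum(axis=1))
               for r, v in self.hq.items()}
        return pd.Series(out) if np.isscalar(self.thi) else pd.DataFrame(out)

    def route_cr_totals(self) -> pd.Series | pd.DataFrame:
        out = {r: (v.sum() if isinstance(v, pd.Series) else v.sum(axis=1))
               for r, v in self.cr.items()}
        return pd.Series(out) if np.isscalar(self.thi) else pd.DataFrame(out)

    def to_long(self) -> pd.DataFrame:
        """Tidy (metal, route, quantity, value) frame; single-vector only."""
        rows = []
        for route in ROUTES:
            for metal, v in self.cdi[route].items():
                rows.append((metal, route, "CDI", v))
            for metal, v in self.hq[route].items():
                rows.append((metal, route, "HQ", v))
            for metal, v in self.cr[route].items():
                rows.append((metal, route, "CR", v))
        out = pd.DataFrame(rows, columns=["metal", "route", "quantity", "value"])
        out["receptor"] = self.receptor
        return out


def risk_report(conc, profile: ExposureProfile,
                registry: ToxicologyRegistry) -> RiskReport:
    """Full deterministic risk report for one receptor.

    ``conc`` is a per-metal concentration Series (mg/kg) or a sites x metals
    DataFrame; output containers mirror the input shape.
    """
    if isinstance(conc, dict):
        conc = pd.Series(conc, dtype=float)
    metals = list(conc.index if isinstance(conc, pd.Series) else conc.columns)

    cdi = {r: chronic_daily_intake(conc, profile, r) for r in ROUTES}
    hq = {r: cdi[r] / pd.Series({m: registry.reference_dose(m, r)
                                 for m in metals})
          for r in ROUTES}
    hi = sum(hq.values())
    thi = hi.sum() if isinstance(hi, pd.Series) else hi.sum(axis=1)

    carcs = [m for m in metals if m in CARCINOGENS]
    cr = {}
    for r in ROUTES:
        c = cdi[r][carcs] if isinstance(conc, pd.Series) else cdi[r][carcs]
        csf = pd.Series({m: registry.slope_factor(m, r) for m in carcs})
        cr[r] = c * csf
    tcr = sum(v.sum() if isinstance(v, pd.Series) else v.sum(axis=1)
              for v in cr.values())

    if isinstance(conc, pd.Series):
        thi = float(thi)
        tcr = float(tcr)
    return RiskReport(receptor=profile.receptor, cdi=cdi, hq=hq, hi=hi,
                      thi=thi, cr=cr, tcr=tcr)
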