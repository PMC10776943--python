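"""Hakanson potential ecological risk.

Single-metal risk ``Eri = Tr_i x Cf_i`` weights the contamination factor by
a toxic-response factor Tr (Cd 30, As 10, Cu 5, Pb 5, Ni 5, Cr 2, Zn 1; Fe
has none and is excluded), and the site-level potential ecological risk
index is the sum ``PERI = sum_i Eri``.  PERI grades: <=150 low, (150, 300]
moderate, (300, 600) considerable, >=600 high risk.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .core import BackgroundProfile, ToxicologyRegistry, ValidationError
from .indices import CLASS_TABLES, classify, classify_frame, contamination_factor


@dataclass
class EcoRiskReport:
    """Per-site Eri and PERI with classes and class shares."""

    eri: pd.DataFrame
    peri: pd.Series
    classes: pd.Series
    class_shares: pd.Series

    def fraction_above(self, threshold: float) -> float:
        return float((self.peri > threshold).mean())


def eri(table, background: BackgroundProfile,
        registry: ToxicologyRegistry) -> pd.DataFrame:
    """Per-site, per-metal single ecological risk Tr x Cf.

    Only metals with a toxic-response factor contribute; asking for Fe
    explicitly is an error.
    """
    cf = contamination_factor(table, background)
    metals = [m for m in cf.columns if m in registry.tr]
    if not metals:
        raise ValidationError("no metal with a toxic-response factor in table")
    tr = pd.Series({m: registry.toxic_response(m) for m in metals})
    return cf[metals] * tr


def peri(eri_values: pd.DataFrame) -> pd.Series:
    """Potential ecological risk index: row sum of Eri."""
    return eri_values.sum(axis=1).rename("PERI")


def eco_risk_report(table, background: BackgroundProfile,
                    registry: ToxicologyRegistry) -> EcoRiskReport:
    e = eri(table, background, registry)
    p = peri(e)
    classes = classify_frame("PERI", p)
    shares = classes.value_counts(normalize=True)
    order = [label for _, _, label in CLASS_TABLES["PERI"]]
    shares = shares.reindex(order, fill_value=0.0)
    return EcoRiskReport(eri=e, peri=p, classes=classes, class_shares=shares)


def classify_peri(value: float) -> str:
    return classify("PERI", value)
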