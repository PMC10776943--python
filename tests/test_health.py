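"""Deterministic multi-route risk against the study's printed worked examples.

The survey's deterministic risk tables give, for each metal at its min, max
and mean concentration, the per-route intake (ADD/CDI), hazard quotient and
cancer risk for child and adult receptors.  Every internally consistent
cell is regenerated here within 1.5 % relative (the printed inputs carry
two decimals).  A handful of printed cells are internally inconsistent and
excluded: the child Pb-inhalation CR column (its printed min exceeds its
max and the mean exceeds the oral CR), the child Pb and adult Pb-min TCR
cells and cumulative rows inheriting it, and the adult non-carcinogenic
totals rows (whose printed sums demonstrably drop As).
"""

import numpy as np
import pandas as pd
import pytest

from soilrisk.core import (CARCINOGENS, DEFAULT_EXPOSURE, DEFAULT_TOXICOLOGY,
                           METALS, RISK_TABLE_CONCENTRATIONS,
                           ValidationError)
from soilrisk import health

REL = 0.015

# level -> metal -> (conc, child (ADDo, HQo, ADDd, HQd, ADDi, HQi, HI),
#                          adult (ADDo, HQo, ADDd, HQd, ADDi, HQi, HI))
NONCARC = {
    "min": {
        "Pb": (12.24, (1.56e-4, 4.47e-2, 4.38e-7, 8.34e-4, 4.20e-9, 1.19e-6, 4.55e-2),
               (1.68e-5, 4.79e-3, 6.80e-8, 1.30e-4, 2.46e-9, 7.00e-7, 4.92e-3)),
        "Cu": (2.76, (3.53e-5, 8.82e-4, 9.87e-8, 8.23e-6, 9.46e-10, 2.37e-8, 8.90e-4),
               (3.78e-6, 9.45e-5, 1.53e-8, 1.28e-6, 5.56e-10, 1.39e-8, 9.57e-5)),
        "Cr": (9.71, (1.24e-4, 4.14e-2, 3.48e-7, 5.80e-3, 3.33e-9, 1.17e-4, 4.73e-2),
               (1.33e-5, 4.44e-3, 5.40e-8, 9.00e-4, 1.96e-9, 6.84e-5, 5.40e-3)),
        "Zn": (29.20, (3.73e-4, 1.24e-3, 1.05e-6, 1.74e-5, 1.00e-8, 3.34e-8, 1.26e-3),
               (4.00e-5, 1.33e-4, 1.62e-7, 2.71e-6, 5.88e-9, 1.96e-8, 1.36e-4)),
        "Ni": (9.64, (1.23e-4, 6.16e-3, 3.45e-7, 6.39e-5, 3.31e-9, 3.68e-5, 6.26e-3),
               (1.32e-5, 6.60e-4, 5.36e-8, 9.93e-6, 1.94e-9, 2.16e-5, 6.92e-4)),
        "Cd": (0.21, (2.68e-6, 2.68e-3, 7.52e-9, 7.52e-4, 7.21e-11, 7.21e-6, 3.44e-3),
               (2.88e-7, 2.88e-4, 1.17e-9, 1.17e-4, 4.23e-11, 4.23e-6, 4.09e-4)),
        "As": (0.52, (6.65e-6, 2.22e-2, 1.86e-8, 1.51e-4, 1.78e-10, 5.95e-7, 2.23e-2),
               (7.12e-7, 2.37e-3, 2.89e-9, 2.35e-5, 1.05e-10, 3.49e-7, 2.40e-3)),
        "Fe": (5671.50, (7.25e-2, 1.04e-1, 2.03e-4, 4.51e-3, 1.95e-6, 8.85e-3, 1.17e-1),
               (7.77e-3, 1.11e-2, 3.15e-5, 7.01e-4, 1.14e-6, 5.19e-3, 1.70e-2)),
    },
    "max": {
        "Pb": (78.97, (1.01e-3, 2.88e-1, 2.83e-6, 5.38e-3, 2.71e-8, 7.70e-6, 2.94e-1),
               (1.08e-4, 3.09e-2, 4.39e-7, 8.37e-4, 1.59e-8, 4.52e-6, 3.17e-2)),
        "Cu": (16.48, (2.11e-4, 5.27e-3, 5.90e-7, 4.92e-5, 5.66e-9, 1.41e-7, 5.32e-3),
               (2.26e-5, 5.64e-4, 9.17e-8, 7.64e-6, 3.32e-9, 8.30e-8, 5.72e-4)),
        "Cr": (51.90, (6.64e-4, 2.21e-1, 1.86e-6, 3.10e-2, 1.78e-8, 6.23e-4, 2.53e-1),
               (7.11e-5, 2.37e-2, 2.89e-7, 4.81e-3, 1.05e-8, 3.66e-4, 2.89e-2)),
        "Zn": (85.41, (1.09e-3, 3.64e-3, 3.06e-6, 5.10e-5, 2.93e-8, 9.77e-8, 3.69e-3),
               (1.17e-4, 3.90e-4, 4.75e-7, 7.92e-6, 1.72e-8, 5.74e-8, 3.98e-4)),
        "Ni": (53.73, (6.87e-4, 3.43e-2, 1.92e-6, 3.56e-4, 1.84e-8, 2.05e-4, 3.49e-2),
               (7.36e-5, 3.68e-3, 2.99e-7, 5.53e-5, 1.08e-8, 1.20e-4, 3.86e-3)),
        "Cd": (2.93, (3.75e-5, 3.75e-2, 1.05e-7, 1.05e-2, 1.01e-9, 1.01e-4, 4.81e-2),
               (4.01e-6, 4.01e-3, 1.63e-8, 1.63e-3, 5.90e-10, 5.90e-5, 5.70e-3)),
        "As": (2.99, (3.82e-5, 1.27e-1, 1.07e-7, 8.70e-4, 1.03e-9, 3.42e-6, 1.28e-1),
               (4.09e-6, 1.36e-2, 1.66e-8, 1.35e-4, 6.02e-10, 2.01e-6, 1.38e-2)),
        "Fe": (6583.00, (8.42e-2, 1.20e-1, 2.36e-4, 5.24e-3, 2.26e-6, 1.03e-2, 1.36e-1),
               (9.02e-3, 1.29e-2, 3.66e-5, 8.14e-4, 1.33e-6, 6.03e-3, 1.97e-2)),
    },
    "mean": {
        "Pb": (24.86, (3.18e-4, 9.08e-2, 8.90e-7, 1.70e-3, 8.53e-9, 2.42e-6, 9.25e-2),
               (3.41e-5, 9.73e-3, 1.38e-7, 2.63e-4, 5.01e-9, 1.42e-6, 1.00e-2)),
        "Cu": (4.10, (5.24e-5, 1.31e-3, 1.47e-7, 1.22e-5, 1.41e-9, 3.52e-8, 1.32e-3),
               (5.62e-6, 1.40e-4, 2.28e-8, 1.90e-6, 8.26e-10, 2.06e-8, 1.42e-4)),
        "Cr": (19.10, (2.44e-4, 8.14e-2, 6.84e-7, 1.14e-2, 6.55e-9, 2.29e-4, 9.30e-2),
               (2.62e-5, 8.72e-3, 1.06e-7, 1.77e-3, 3.85e-9, 1.35e-4, 1.06e-2)),
        "Zn": (49.13, (6.28e-4, 2.09e-3, 1.76e-6, 2.93e-5, 1.69e-8, 5.62e-8, 2.12e-3),
               (6.73e-5, 2.24e-4, 2.73e-7, 4.55e-6, 9.90e-9, 3.30e-8, 2.29e-4)),
        "Ni": (25.44, (3.25e-4, 1.63e-2, 9.11e-7, 1.69e-4, 8.73e-9, 9.70e-5, 1.65e-2),
               (3.48e-5, 1.74e-3, 1.41e-7, 2.62e-5, 5.12e-9, 5.69e-5, 1.83e-3)),
        "Cd": (0.89, (1.14e-5, 1.14e-2, 3.18e-8, 3.18e-3, 3.05e-10, 3.05e-5, 1.46e-2),
               (1.22e-6, 1.22e-3, 4.94e-9, 4.94e-4, 1.79e-10, 1.79e-5, 1.73e-3)),
        "As": (1.81, (2.31e-5, 7.71e-2, 6.48e-8, 5.27e-4, 6.21e-10, 2.07e-6, 7.77e-2),
               (2.48e-6, 8.26e-3, 1.01e-8, 8.18e-5, 3.65e-10, 1.22e-6, 8.35e-3)),
        "Fe": (6183.32, (7.91e-2, 1.13e-1, 2.21e-4, 4.92e-3, 2.12e-6, 9.64e-3, 1.28e-1),
               (8.47e-3, 1.21e-2, 3.44e-5, 7.64e-4, 1.25e-6, 5.66e-3, 1.85e-2)),
    },
}

# level -> metal -> (conc, child (CRo, CRd, CRi, TCR), adult (CRo, CRd, CRi, TCR))
# None marks an internally inconsistent printed cell, skipped.
CARC = {
    "min": {
        "Pb": (12.24, (1.33e-6, 3.72e-9, None, None), (1.42e-7, 5.78e-10, 1.04e-10, None)),
        "Cr": (9.71, (6.21e-5, 6.96e-7, 1.40e-7, 6.29e-5), (6.65e-6, 1.08e-7, 8.22e-8, 6.84e-6)),
        "Ni": (9.64, (2.10e-4, 1.47e-5, 2.78e-9, 2.24e-4), (2.25e-5, 2.28e-6, 1.63e-9, 2.47e-5)),
        "Cd": (0.21, (1.02e-6, 2.86e-9, 4.54e-10, 1.02e-6), (1.09e-7, 4.44e-10, 2.67e-10, 1.10e-7)),
        "As": (0.52, (9.97e-6, 6.81e-8, 2.69e-9, 1.00e-5), (1.07e-6, 1.06e-8, 1.58e-9, 1.08e-6)),
    },
    "max": {
        "Pb": (78.97, (8.58e-6, 2.40e-8, None, None), (9.19e-7, 3.73e-9, 6.68e-10, 9.24e-7)),
        "Cr": (51.90, (3.32e-4, 3.72e-6, 7.48e-7, 3.36e-4), (3.55e-5, 5.77e-7, 4.39e-7, 3.66e-5)),
        "Ni": (53.73, (1.17e-3, 8.17e-5, 1.55e-8, 1.25e-3), (1.25e-4, 1.27e-5, 9.09e-9, 1.38e-4)),
        "Cd": (2.93, (1.42e-5, 3.99e-8, 6.33e-9, 1.43e-5), (1.53e-6, 6.19e-9, 3.72e-9, 1.54e-6)),
        "As": (2.99, (5.73e-5, 3.92e-7, 1.55e-8, 5.77e-5), (6.14e-6, 6.08e-8, 9.09e-9, 6.21e-6)),
    },
    "mean": {
        "Pb": (24.86, (2.70e-6, 7.57e-9, None, None), (2.89e-7, 1.18e-9, 2.10e-10, 2.91e-7)),
        "Cr": (19.10, (1.22e-4, 1.37e-6, 2.75e-7, 1.24e-4), (1.31e-5, 2.12e-7, 1.62e-7, 1.35e-5)),
        "Ni": (25.44, (5.53e-4, 3.87e-5, 7.33e-9, 5.92e-4), (5.92e-5, 6.01e-6, 4.30e-9, 6.53e-5)),
        "Cd": (0.89, (4.32e-6, 1.21e-8, 1.92e-9, 4.33e-6), (4.63e-7, 1.88e-9, 1.13e-9, 4.66e-7)),
        "As": (1.81, (3.47e-5, 2.37e-7, 9.38e-9, 3.50e-5), (3.72e-6, 3.68e-8, 5.51e-9, 3.76e-6)),
    },
}


def reports_for(level):
    conc = RISK_TABLE_CONCENTRATIONS.loc[level]
    return {r: health.risk_report(conc, DEFAULT_EXPOSURE[r],
                                  DEFAULT_TOXICOLOGY) for r in ("child", "adult")}


@pytest.mark.parametrize("level", ["min", "max", "mean"])
@pytest.mark.parametrize("receptor", ["child", "adult"])
def test_noncarcinogenic_cells(level, receptor):
    """Every printed ADD/HQ/HI cell regenerates within 1.5 % relative."""
    rep = reports_for(level)[receptor]
    idx = 1 if receptor == "child" else 2
    for metal, row in NONCARC[level].items():
        cells = row[idx]
        for k, route in enumerate(("ingestion", "dermal", "inhalation")):
            assert rep.cdi[route][metal] == pytest.approx(cells[2 * k], rel=REL), \
                f"{metal} {route} CDI at {level}"
            assert rep.hq[route][metal] == pytest.approx(cells[2 * k + 1], rel=REL), \
                f"{metal} {route} HQ at {level}"
        assert rep.hi[metal] == pytest.approx(cells[6], rel=REL), \
            f"{metal} HI at {level}"


@pytest.mark.parametrize("level", ["min", "max", "mean"])
@pytest.mark.parametrize("receptor", ["child", "adult"])
def test_carcinogenic_cells(level, receptor):
    """Every internally consistent CR/TCR cell regenerates within 1.5 %."""
    rep = reports_for(level)[receptor]
    idx = 1 if receptor == "child" else 2
    for metal, row in CARC[level].items():
        cells = row[idx]
        per_metal_tcr = 0.0
        for k, route in enumerate(("ingestion", "dermal", "inhalation")):
            per_metal_tcr += rep.cr[route][metal]
            if cells[k] is None:
                continue
            assert rep.cr[route][metal] == pytest.approx(cells[k], rel=REL), \
                f"{metal} {route} CR at {level}"
        if cells[3] is not None:
            assert per_metal_tcr == pytest.approx(cells[3], rel=REL), \
                f"{metal} TCR at {level}"


@pytest.mark.parametrize("level,child_thi,child_routes,adult_inh", [
    # (THI, (oral, dermal, inhal) cumulative HQ, adult inhal cumulative)
    ("min", 2.44e-1, (2.23e-1, 1.21e-2, 9.01e-3), 5.29e-3),
    ("max", 9.03e-1, (8.38e-1, 5.34e-2, 1.12e-2), 6.58e-3),
    ("mean", 4.25e-1, (3.93e-1, 2.19e-2, 1.00e-2), 5.87e-3),
])
def test_hazard_totals_rows(level, child_thi, child_routes, adult_inh):
    """Cumulative HQ rows; the adult oral/dermal/THI totals are excluded
    because the printed sums drop As (printed 3.39e-2 = full sum minus the
    As HQ at every level)."""
    reps = reports_for(level)
    child = reps["child"]
    assert child.thi == pytest.approx(child_thi, rel=REL)
    totals = child.route_hq_totals()
    for route, expected in zip(("ingestion", "dermal", "inhalation"),
                               child_routes):
        assert totals[route] == pytest.approx(expected, rel=REL)
    assert reps["adult"].route_hq_totals()["inhalation"] == pytest.approx(
        adult_inh, rel=REL)


@pytest.mark.parametrize("level,child_tcr,adult_tcr", [
    ("min", 3.00e-4, None),       # adult min total inherits the bad Pb cell
    ("max", 1.67e-3, 1.83e-4),
    ("mean", 7.60e-4, 8.32e-5),
])
def test_total_cancer_risk(level, child_tcr, adult_tcr):
    """Headline TCR aggregates; children within 0.5 % (one inconsistent
    printed Pb-inhalation cell biases the printed total upward slightly)."""
    reps = reports_for(level)
    assert reps["child"].tcr == pytest.approx(child_tcr, rel=0.005)
    if adult_tcr is not None:
        assert reps["adult"].tcr == pytest.approx(adult_tcr, rel=REL)


def test_children_oral_cancer_risk_sum():
    rep = reports_for("mean")["child"]
    assert rep.route_cr_totals()["ingestion"] == pytest.approx(7.17e-4, rel=0.005)


class TestProperties:
    def test_linearity_in_concentration(self):
        conc = RISK_TABLE_CONCENTRATIONS.loc["mean"]
        r1 = health.risk_report(conc, DEFAULT_EXPOSURE["child"],
                                DEFAULT_TOXICOLOGY)
        r2 = health.risk_report(3.0 * conc, DEFAULT_EXPOSURE["child"],
                                DEFAULT_TOXICOLOGY)
        assert r2.thi == pytest.approx(3.0 * r1.thi, rel=1e-12)
        assert r2.tcr == pytest.approx(3.0 * r1.tcr, rel=1e-12)

    def test_child_adult_oral_intake_ratio(self):
        c, a = DEFAULT_EXPOSURE["child"], DEFAULT_EXPOSURE["adult"]
        ratio = (health.cdi_ingestion(1.0, c) / health.cdi_ingestion(1.0, a))
        # with AT = ED x 365, ED/AT cancels: ratio = (IngR/BW)c / (IngR/BW)a
        assert ratio == pytest.approx((200 / 15) / (100 / 70), rel=1e-12)
        assert ratio == pytest.approx(9.33, abs=0.01)

    def test_hi_is_route_sum_and_thi_is_metal_sum(self):
        conc = RISK_TABLE_CONCENTRATIONS.loc["mean"]
        rep = health.risk_report(conc, DEFAULT_EXPOSURE["child"],
                                 DEFAULT_TOXICOLOGY)
        manual_hi = sum(rep.hq[r] for r in ("ingestion", "dermal", "inhalation"))
        pd.testing.assert_series_equal(rep.hi, manual_hi)
        assert rep.thi == pytest.approx(rep.hi.sum(), rel=1e-14)
        assert not rep.thi_exceeds

    def test_zero_concentration_zero_risk(self):
        conc = pd.Series(0.0, index=list(METALS))
        rep = health.risk_report(conc, DEFAULT_EXPOSURE["adult"],
                                 DEFAULT_TOXICOLOGY)
        assert rep.thi == 0.0 and rep.tcr == 0.0

    def test_csf_only_for_carcinogens(self):
        with pytest.raises(ValidationError):
            DEFAULT_TOXICOLOGY.slope_factor("Zn", "ingestion")
        assert set(DEFAULT_TOXICOLOGY.csf) == set(CARCINOGENS)

    def test_cancer_risk_classification(self):
        assert health.classify_cancer_risk(1e-7) == "negligible"
        assert health.classify_cancer_risk(5e-5) == "tolerable"
        assert health.classify_cancer_risk(7.6e-4) == "actionable"

    def test_per_site_table_input(self, default_dataset):
        rep = health.risk_report(default_dataset.table.df,
                                 DEFAULT_EXPOSURE["child"], DEFAULT_TOXICOLOGY)
        assert len(rep.thi) == len(default_dataset.table)
        assert (rep.thi > 0).all() and (rep.tcr > 0).all()
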