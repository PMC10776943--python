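"""Monte-Carlo probabilistic risk and contribution-to-variance sensitivity.

Re-implements the Crystal-Ball-style workflow: each uncertain input (metal
concentrations, exposure parameters) gets an independent marginal
distribution, the deterministic multi-route risk model is evaluated on
every joint draw, and the THI / TCR output distributions are summarised by
mean, 5th/50th/95th percentiles and threshold exceedance probabilities.

Sensitivity follows the rank-correlation contribution-to-variance
convention: for each varying input, the signed share sign(rho) * rho^2 /
sum(rho^2) * 100 where rho is the Spearman correlation between the input's
draws and the output.  Signs therefore agree with analytic monotonicity
(concentrations and exposure frequency positive, body weight negative).

Default input distributions: concentrations lognormal, moment-matched to
the survey per-metal mean and CV; exposure frequency triangular(180, 350,
365) days/yr; body weight normal (15 +/- 2 kg child, 70 +/- 10 kg adult,
truncated at 0); remaining parameters point values.  Averaging time is
derived as ED x 365 within each draw.  All defaults are overridable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import (CARCINOGENS, ROUTES, ExposureProfile, STUDY_STATS,
                   ToxicologyRegistry, ValidationError, DEFAULT_EXPOSURE,
                   DEFAULT_TOXICOLOGY)

__all__ = ["DistributionSpec", "McResult", "default_input_specs",
           "sample_inputs", "simulate", "sensitivity"]


@dataclass
class DistributionSpec:
    """Marginal distribution of one model input.

    families: point(value), normal(mu, sd), lognormal(mean, cv | mu, sigma),
    uniform(lo, hi), triangular(left, mode, right); optional truncation
    bounds (applied by rejection for normal/lognormal).
    """

    name: str
    family: str
    params: dict = field(default_factory=dict)
    lower: float | None = None
    upper: float | None = None

    def __post_init__(self) -> None:
        if self.family not in ("point", "normal", "lognormal", "uniform",
                               "triangular"):
            raise ValidationError(f"unknown family {self.family!r}")
        if (self.lower is not None and self.upper is not None
                and self.lower >= self.upper):
            raise ValidationError("truncation bounds out of order")

    @classmethod
    def lognormal_from_mean_cv(cls, name: str, mean: float,
                               cv: float) -> "DistributionSpec":
        """Moment-matched lognormal: E = mean, sd/E = cv."""
        if mean <= 0 or cv <= 0:
            raise ValidationError("lognormal moment matching needs mean, cv > 0")
        sigma2 = np.log1p(cv**2)
        return cls(name=name, family="lognormal",
                   params={"mu": np.log(mean) - sigma2 / 2.0,
                           "sigma": float(np.sqrt(sigma2))})

    @property
    def is_point(self) -> bool:
        return self.family == "point"

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        p = self.params
        if self.family == "point":
            return np.full(n, float(p["value"]))
        if self.family == "uniform":
            x = rng.uniform(p["lo"], p["hi"], n)
        elif self.family == "triangular":
            x = rng.triangular(p["left"], p["mode"], p["right"], n)
        elif self.family == "normal":
            x = rng.normal(p["mu"], p["sd"], n)
        elif self.family == "lognormal":
            if "mu" in p:
                x = rng.lognormal(p["mu"], p["sigma"], n)
            else:
                spec = self.lognormal_from_mean_cv(self.name, p["mean"], p["cv"])
                x = rng.lognormal(spec.params["mu"], spec.params["sigma"], n)
        if self.lower is not None or self.upper is not None:
            lo = -np.inf if self.lower is None else self.lower
            hi = np.inf if self.upper is None else self.upper
            bad = (x < lo) | (x > hi)
            while bad.any():  # rejection resampling within bounds
                x[bad] = self.draw(int(bad.sum()), rng)
                bad = (x < lo) | (x > hi)
        return x


def default_input_specs(receptor: str,
                        conc_stats: pd.DataFrame | None = None,
                        ) -> list[DistributionSpec]:
    """Study-default marginals for one receptor group.

    Concentration inputs are named ``C_<metal>``; exposure inputs use the
    profile field names.
    """
    if conc_stats is None:
        conc_stats = STUDY_STATS
    prof = DEFAULT_EXPOSURE[receptor]
    specs = [DistributionSpec.lognormal_from_mean_cv(
                f"C_{m}", conc_stats.loc["mean", m], conc_stats.loc["cv", m])
             for m in conc_stats.columns]
    specs.append(DistributionSpec("EF", "triangular",
                                  {"left": 180.0, "mode": 350.0, "right": 365.0}))
    specs.append(DistributionSpec("ED", "point", {"value": prof.ED}))
    bw_sd = 2.0 if receptor == "child" else 10.0
    specs.append(DistributionSpec("BW", "normal",
                                  {"mu": prof.BW, "sd": bw_sd}, lower=1e-6))
    for name in ("IngR", "InhR", "SA", "AF", "ABS", "PEF"):
        specs.append(DistributionSpec(name, "point",
                                      {"value": getattr(prof, name)}))
    return specs


def sample_inputs(specs: list[DistributionSpec], n: int,
                  seed: int) -> pd.DataFrame:
    """n independent joint draws, one column per input, reproducible by seed."""
    if n < 1:
        raise ValidationError("n must be >= 1")
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValidationError("duplicate input names")
    rng = np.random.default_rng(seed)
    return pd.DataFrame({s.name: s.draw(n, rng) for s in specs})


@dataclass
class McResult:
    """Simulation summary for one receptor."""

    receptor: str
    n_iterations: int
    seed: int
    summary: pd.DataFrame            # rows THI/TCR: mean, p5, p50, p95, exceedance
    sensitivity: dict[str, pd.Series]  # output -> signed contribution (%)
    draws: pd.DataFrame | None = None
    outputs: pd.DataFrame | None = None


def _risk_outputs(draws: pd.DataFrame, registry: ToxicologyRegistry,
                  metals: list[str]) -> pd.DataFrame:
    """Vectorised THI and TCR over joint draws (AT derived as ED x 365)."""
    ef, ed, bw = (draws[k].to_numpy() for k in ("EF", "ED", "BW"))
    at = ed * 365.0
    ing = draws["IngR"].to_numpy() * ef * ed * 1e-6 / (bw * at)
    derm = (draws["AF"].to_numpy() * draws["SA"].to_numpy()
            * draws["ABS"].to_numpy() * ef * ed * 1e-6 / (bw * at))
    inh = (draws["InhR"].to_numpy() * ef * ed
           / (bw * at * draws["PEF"].to_numpy()))
    per_conc = {"ingestion": ing, "dermal": derm, "inhalation": inh}

    thi = np.zeros(len(draws))
    tcr = np.zeros(len(draws))
    for m in metals:
        c = draws[f"C_{m}"].to_numpy()
        for route, factor in per_conc.items():
            cdi = c * factor
            thi += cdi / registry.reference_dose(m, route)
            if m in CARCINOGENS:
                tcr += cdi * registry.slope_factor(m, route)
    return pd.DataFrame({"THI": thi, "TCR": tcr})


def simulate(specs: list[DistributionSpec] | None = None,
             receptor: str = "child",
             registry: ToxicologyRegistry | None = None,
             n: int = 10_000,
             seed: int = 0,
             keep_draws: bool = False,
             thresholds: dict[str, float] | None = None) -> McResult:
    """Monte-Carlo THI/TCR distributions for one receptor.

    The risk model applied per draw is exactly the deterministic multi-route
    pipeline, so point-mass inputs reproduce the deterministic THI/TCR.
    """
    registry = registry or DEFAULT_TOXICOLOGY
    if specs is None:
        specs = default_input_specs(receptor)
    thresholds = thresholds or {"THI": 1.0, "TCR": 1e-4}

    draws = sample_inputs(specs, n, seed)
    metals = [c[2:] for c in draws.columns if c.startswith("C_")]
    missing = [k for k in ("EF", "ED", "BW", "IngR", "InhR", "SA", "AF",
                           "ABS", "PEF") if k not in draws.columns]
    if missing:
        raise ValidationError(f"missing exposure input spec(s): {missing}")
    out = _risk_outputs(draws, registry, metals)

    bad = ~np.isfinite(out.to_numpy()).all(axis=1)
    n_bad = int(bad.sum())
    if n_bad:
        out = out[~bad]
        draws = draws[~bad]

    rows = {}
    for col in out.columns:
        x = out[col].to_numpy()
        rows[col] = {
            "mean": x.mean(),
            "p5": np.percentile(x, 5),
            "p50": np.percentile(x, 50),
            "p95": np.percentile(x, 95),
            "exceedance": float((x > thresholds[col]).mean()),
            "n_invalid": n_bad,
        }
    summary = pd.DataFrame(rows).T

    sens = {}
    for col in out.columns:
        try:
            sens[col] = sensitivity(draws, out[col])
        except ValidationError:  # degenerate run: nothing varies
            sens[col] = pd.Series(dtype=float)
    return McResult(receptor=receptor, n_iterations=n, seed=seed,
                    summary=summary, sensitivity=sens,
                    draws=draws if keep_draws else None,
                    outputs=out if keep_draws else None)


def sensitivity(draws: pd.DataFrame, output: pd.Series | np.ndarray) -> pd.Series:
    """Signed contribution-to-variance (%) per varying input.

    sign(rho) * rho^2 / sum(rho^2) * 100, rho the Spearman rank correlation
    between an input's draws and the output.  Absolute contributions sum to
    100; constant inputs are skipped and a constant output is an error.
    """
    y = np.asarray(output, dtype=float)
    if np.ptp(y) == 0:
        raise ValidationError("constant output: sensitivity undefined")
    rhos = {}
    for name in draws.columns:
        x = draws[name].to_numpy()
        if np.ptp(x) == 0:
            continue
        rho = stats.spearmanr(x, y).statistic
        rhos[name] = 0.0 if np.isnan(rho) else float(rho)
    if not rhos:
        raise ValidationError("no varying inputs")
    rho = pd.Series(rhos)
    total = (rho**2).sum()
    if total == 0:
        return rho * 0.0
    contrib = np.sign(rho) * rho**2 / total * 100.0
    return contrib.sort_values(key=lambda s: s.abs(), ascending=False)
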