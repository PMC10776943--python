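"""Pipeline orchestration: run stages in order, write outputs + manifest.

The canonical stage order is indices -> ecorisk -> hhra -> mc -> pmf ->
pca.  Any subset can be requested, but a stage whose inputs come from an
earlier stage (mc needs the hhra setup) must follow it.  Every run writes a
manifest recording the package version, the master seed and the derived
per-stage seeds, a config echo and a sha256 checksum per output file, so
identical configs reproduce byte-identical numeric outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import (BackgroundProfile, ConcentrationTable, DEFAULT_BACKGROUND,
                   DEFAULT_EXPOSURE, DEFAULT_STANDARDS, DEFAULT_TOXICOLOGY,
                   StandardProfile, ToxicologyRegistry, ValidationError,
                   validate_table)
from . import ecorisk as _ecorisk
from . import health as _health
from . import indices as _indices
from . import montecarlo as _mc
from . import mvstats as _mvstats
from . import pmf as _pmf

log = logging.getLogger("soilrisk")

STAGE_ORDER = ("indices", "ecorisk", "hhra", "mc", "pmf", "pca")


@dataclass
class RunConfig:
    """Declarative description of one pipeline run."""

    table_path: str
    out_dir: str
    stages: list[str] = field(default_factory=lambda: list(STAGE_ORDER))
    available_path: str | None = None
    seed: int = 0
    background: dict | None = None
    standards: dict | None = None
    toxicology: dict | None = None
    mc_n: int = 10_000
    pmf_factors: int = 3
    pmf_runs: int = 20
    pmf_error_fraction: float = 0.1
    pmf_mdl: float = 0.001

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGE_ORDER)
        if unknown:
            raise ValidationError(f"unknown stage(s): {sorted(unknown)}")
        if "mc" in self.stages and "hhra" not in self.stages:
            raise ValidationError("stage dependency unmet: mc requires hhra")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        cfg = cls(**d)
        if not Path(cfg.table_path).exists():
            raise ValidationError(f"input table not found: {cfg.table_path}")
        return cfg


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed: first word of SeedSequence([master, i])."""
    i = STAGE_ORDER.index(stage)
    return int(np.random.SeedSequence([master, i]).generate_state(1)[0] % (2**31))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages; return the manifest dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    background = (BackgroundProfile(config.background) if config.background
                  else DEFAULT_BACKGROUND)
    standards = (StandardProfile(config.standards) if config.standards
                 else DEFAULT_STANDARDS)
    registry = (ToxicologyRegistry.from_dict(config.toxicology)
                if config.toxicology else DEFAULT_TOXICOLOGY)

    table = validate_table(ConcentrationTable.read_csv(config.table_path),
                           background)
    log.info("loaded table: %d sites x %d metals", len(table), len(table.metals))

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": {s: stage_seed(config.seed, s) for s in config.stages},
        "config": dataclasses.asdict(config),
        "outputs": {},
        "stages": {},
    }
    written: list[Path] = []

    def save(df: pd.DataFrame, name: str, **kw) -> None:
        p = out / name
        df.to_csv(p, **kw)
        written.append(p)

    for stage in [s for s in STAGE_ORDER if s in config.stages]:
        t0 = time.perf_counter()
        log.info("stage %s: start (input %d x %d)", stage, len(table),
                 len(table.metals))
        if stage == "indices":
            reports = _indices.index_report(table, background, standards)
            long = pd.concat([r.to_long() for r in reports.values()],
                             ignore_index=True)
            save(long, "indices.csv", index=False)
        elif stage == "ecorisk":
            rep = _ecorisk.eco_risk_report(table, background, registry)
            save(rep.eri, "eri.csv")
            peri = rep.peri.to_frame()
            peri["class"] = rep.classes
            save(peri, "peri.csv")
        elif stage == "hhra":
            aggregates = {}
            frames = []
            for receptor, profile in DEFAULT_EXPOSURE.items():
                for level in ("min", "max", "mean"):
                    conc = getattr(table.df, level)()
                    rep = _health.risk_report(conc, profile, registry)
                    longf = rep.to_long()
                    longf["level"] = level
                    frames.append(longf)
                    aggregates[f"{receptor}_{level}"] = {
                        "THI": rep.thi, "TCR": rep.tcr}
            save(pd.concat(frames, ignore_index=True), "hhra.csv", index=False)
            p = out / "hhra_aggregates.json"
            p.write_text(json.dumps(aggregates, indent=1))
            written.append(p)
        elif stage == "mc":
            stats_df = pd.DataFrame({
                m: [table.df[m].mean(),
                    table.df[m].std(ddof=1) / table.df[m].mean()]
                for m in table.metals}, index=["mean", "cv"])
            for receptor in ("child", "adult"):
                res = _mc.simulate(
                    specs=_mc.default_input_specs(receptor, stats_df),
                    receptor=receptor, registry=registry, n=config.mc_n,
                    seed=stage_seed(config.seed, "mc"))
                save(res.summary, f"mc_{receptor}_summary.csv")
                sens = pd.DataFrame(res.sensitivity)
                save(sens, f"mc_{receptor}_sensitivity.csv")
        elif stage == "pmf":
            U = _pmf.build_uncertainty(table, mdl=config.pmf_mdl,
                                       error_fraction=config.pmf_error_fraction)
            sol = _pmf.fit(table, U, n_factors=config.pmf_factors,
                           n_runs=config.pmf_runs,
                           seed=stage_seed(config.seed, "pmf"))
            diag = _pmf.diagnostics(sol, table)
            save(sol.G, "pmf_G.csv")
            save(sol.F, "pmf_F.csv")
            save(diag["percent_contribution"], "pmf_percent_contribution.csv")
            p = out / "pmf_diagnostics.json"
            p.write_text(json.dumps({
                "Q": sol.Q, "converged": sol.converged,
                "best_run": sol.best_run,
                "r2": diag["r2"].to_dict(),
                "frac_abs_resid_le_3": diag["frac_abs_resid_le_3"]}, indent=1))
            written.append(p)
        elif stage == "pca":
            rho, pval = _mvstats.spearman_matrix(table)
            save(rho, "spearman.csv")
            res = _mvstats.pca(table)
            save(res.loadings, "pca_loadings.csv")
            scree = pd.DataFrame({"eigenvalue": res.eigenvalues,
                                  "percent": res.percent_variance,
                                  "cumulative": res.cumulative_percent})
            save(scree, "pca_scree.csv")
        manifest["stages"][stage] = {"elapsed_s": time.perf_counter() - t0}
        log.info("stage %s: done in %.2fs", stage,
                 manifest["stages"][stage]["elapsed_s"])

    manifest["outputs"] = {p.name: _sha256(p) for p in written}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


# ---------------------------------------------------------------------------
# Human-readable report
# ---------------------------------------------------------------------------

def summarize(out_dir) -> str:
    """One markdown report over an output directory's stage files.

    Sections for missing stages are marked absent rather than failing.
    """
    out = Path(out_dir)
    lines = ["# soilrisk run summary", ""]
    if not out.exists() or not any(out.iterdir()):
        return "nothing to summarize\n"

    def have(name: str) -> bool:
        return (out / name).exists()

    if have("manifest.json"):
        man = json.loads((out / "manifest.json").read_text())
        lines += [f"version {man['version']}, master seed {man['seed']}", ""]

    lines.append("## Descriptive statistics")
    if have("manifest.json"):
        table = ConcentrationTable.read_csv(
            json.loads((out / "manifest.json").read_text())
            ["config"]["table_path"])
        desc = table.df.agg(["min", "max", "mean"])
        cv = table.df.std(ddof=1) / table.df.mean()
        desc.loc["cv_percent"] = 100 * cv
        lines.append(desc.round(3).to_markdown())
        order = " > ".join(cv.sort_values(ascending=False).index)
        lines.append(f"\nCV ordering: {order}")
    else:
        lines.append("(absent)")
    lines.append("")

    lines.append("## Pollution indices")
    if have("indices.csv"):
        idx = pd.read_csv(out / "indices.csv")
        summ = (idx.groupby(["index", "metal"], dropna=False)["value"]
                .agg(["min", "max", "mean"]).round(3))
        lines.append(summ.to_markdown())
    else:
        lines.append("(absent)")
    lines.append("")

    lines.append("## Ecological risk")
    if have("peri.csv"):
        peri = pd.read_csv(out / "peri.csv", index_col=0)
        tally = peri["class"].value_counts()
        lines.append(f"PERI range {peri['PERI'].min():.1f}-"
                     f"{peri['PERI'].max():.1f}; classes: "
                     + ", ".join(f"{k}: {v}" for k, v in tally.items()))
    else:
        lines.append("(absent)")
    lines.append("")

    lines.append("## Human health risk (deterministic)")
    if have("hhra_aggregates.json"):
        agg = json.loads((out / "hhra_aggregates.json").read_text())
        for k, v in agg.items():
            lines.append(f"- {k}: THI = {v['THI']:.3g}, TCR = {v['TCR']:.3g}")
    else:
        lines.append("(absent)")
    lines.append("")

    lines.append("## Monte-Carlo risk")
    if have("mc_child_summary.csv"):
        for receptor in ("child", "adult"):
            s = pd.read_csv(out / f"mc_{receptor}_summary.csv", index_col=0)
            lines.append(f"### {receptor}")
            lines.append(s.round(6).to_markdown())
    else:
        lines.append("(absent)")
    lines.append("")

    lines.append("## PMF source apportionment")
    if have("pmf_diagnostics.json"):
        d = json.loads((out / "pmf_diagnostics.json").read_text())
        r2 = pd.Series(d["r2"])
        lines.append(f"Q = {d['Q']:.4g}; r2 range "
                     f"{r2.min():.3f}-{r2.max():.3f}; "
                     f"|scaled residual| <= 3: {d['frac_abs_resid_le_3']:.0%}")
    else:
        lines.append("(absent)")
    lines.append("")

    lines.append("## PCA")
    if have("pca_scree.csv"):
        scree = pd.read_csv(out / "pca_scree.csv", index_col=0)
        lines.append(scree.round(3).to_markdown())
    else:
        lines.append("(absent)")
    lines.append("")
    return "\n".join(lines)
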