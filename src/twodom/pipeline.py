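"""End-to-end pipeline: simulate -> fit -> classify -> epistasis -> landscape.

Driven by a flat ``key = value`` config file, writes one JSON per fit, a
phenotype table, a machine-readable landscape matrix, and a log naming
every seed, so a whole panel analysis reruns from a single command.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np

from . import __version__
from .epistasis import (
    AdditiveModelSpec,
    additive_params,
    delta_params,
    epistasis_deviation,
    predict_combined_curve,
)
from .inference import PriorSpec, SamplerConfig, degenerate_summary, fit_dataset
from .landscape import fc1000_landscape, panel_correlation, phenotype_table
from .model import ModelParams, SystemConstants
from .synth import NoiseModel, panel_fixture, simulate_dataset, write_dataset

log = logging.getLogger("twodom")

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

_STAGES = ("simulate", "fit", "classify", "epistasis", "landscape")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Flat configuration of one pipeline run.

    ``mutants`` is a comma list of panel variant names or ``all``;
    ``stages`` a comma list drawn from simulate/fit/classify/epistasis/
    landscape; ``pairs`` lists combined mutants for the additive model
    as ``mut1+mut2`` entries.
    """

    mutants: str = "WT"
    stages: str = "simulate,fit"
    pairs: str = ""
    seed: int = 0
    out_dir: str = "twodom_out"
    r_star: float = 100.0
    k: float = 3.0
    cv: float = 0.05
    floor: float = 0.002
    n_rep: int = 4
    eps_d: float = 0.0
    prior_gamma_mean: float = 5.0
    prior_gamma_sd: float = 2.5
    n_walkers: int = 32
    n_steps: int = 1800
    n_burn: int = 800
    thin: int = 8

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Parse a flat ``key = value`` text file (# starts a comment)."""
        known = {f.name: f.type for f in fields(cls)}
        values: dict[str, object] = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise PipelineError(f"{path}:{lineno}: expected 'key = value'")
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key not in known:
                raise PipelineError(f"{path}:{lineno}: unknown config key {key!r}")
            values[key] = value
        return cls(**cls._coerce(values))

    @staticmethod
    def _coerce(values: dict[str, object]) -> dict[str, object]:
        out: dict[str, object] = {}
        defaults = PipelineConfig()
        for key, value in values.items():
            target = getattr(defaults, key)
            try:
                out[key] = type(target)(value)
            except (TypeError, ValueError) as exc:
                raise PipelineError(f"config key {key!r}: {exc}") from exc
        return out

    def validate(self) -> None:
        for stage in self.stage_list():
            if stage not in _STAGES:
                raise PipelineError(f"unknown stage {stage!r}; choose from {_STAGES}")
        if self.n_rep < 1:
            raise PipelineError("n_rep must be >= 1")

    def stage_list(self) -> list[str]:
        return [s.strip() for s in self.stages.split(",") if s.strip()]

    def constants(self) -> SystemConstants:
        return SystemConstants(r_star=self.r_star, k=self.k)

    def sampler(self) -> SamplerConfig:
        return SamplerConfig(
            n_walkers=self.n_walkers,
            n_steps=self.n_steps,
            n_burn=self.n_burn,
            thin=self.thin,
        )

    def prior(self) -> PriorSpec:
        return PriorSpec(
            gamma_mean=self.prior_gamma_mean, gamma_sd=self.prior_gamma_sd
        )


@dataclass
class ReportBundle:
    """Paths and in-memory results produced by one pipeline run."""

    out_dir: Path
    datasets: dict = field(default_factory=dict)
    fits: dict = field(default_factory=dict)
    phenotypes: object = None
    epistasis: dict = field(default_factory=dict)
    landscape: object = None
    log_path: Path | None = None


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute the configured stages, writing all outputs under
    ``config.out_dir``.  Raises :class:`PipelineError` naming the stage
    on failure."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = out_dir / "pipeline.log"
    handler = logging.FileHandler(log_path)
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)

    bundle = ReportBundle(out_dir=out_dir, log_path=log_path)
    panel = panel_fixture()
    constants = config.constants()
    noise = NoiseModel(cv=config.cv, floor=config.floor)
    mutants = (
        panel.mutants
        if config.mutants.strip() == "all"
        else [m.strip() for m in config.mutants.split(",") if m.strip()]
    )
    log.info(
        "twodom %s | seed=%d mutants=%s stages=%s",
        __version__,
        config.seed,
        mutants,
        config.stage_list(),
    )

    try:
        stages = config.stage_list()
        if "simulate" in stages:
            for i, mutant in enumerate(mutants):
                params = panel.params_for(mutant, eps_d=config.eps_d)
                ds = simulate_dataset(
                    params,
                    constants,
                    n_rep=config.n_rep,
                    noise=noise,
                    seed=config.seed + i,
                    mutant_id=mutant,
                )
                write_dataset(ds, out_dir / f"{mutant}.csv")
                bundle.datasets[mutant] = ds
                log.info("simulate %s seed=%d", mutant, config.seed + i)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage simulate failed: {exc}") from exc

    try:
        if "fit" in stages:
            for i, mutant in enumerate(mutants):
                ds = bundle.datasets[mutant]
                summary = fit_dataset(
                    ds,
                    constants,
                    prior=config.prior(),
                    config=config.sampler(),
                    seed=config.seed + 1000 + i,
                )
                summary.save(out_dir / f"{mutant}.fit.json")
                bundle.fits[mutant] = summary
                log.info(
                    "fit %s eps_L=%.2f gamma=%.2f flags=%s",
                    mutant,
                    summary.medians["eps_L"],
                    summary.medians["gamma"],
                    summary.flags,
                )
    except Exception as exc:
        raise PipelineError(f"stage fit failed: {exc}") from exc

    try:
        if "classify" in stages:
            table = phenotype_table(panel, constants, eps_d=config.eps_d)
            table.to_csv(out_dir / "phenotypes.csv", index=False)
            bundle.phenotypes = table
            log.info("classify: %d variants", len(table))
    except Exception as exc:
        raise PipelineError(f"stage classify failed: {exc}") from exc

    try:
        if "epistasis" in stages:
            wt_post = degenerate_summary(
                panel.params_for("WT"), constants, mutant_id="WT"
            )
            for pair in [p.strip() for p in config.pairs.split(",") if p.strip()]:
                m1, _, m2 = pair.partition("+")
                if not m2:
                    raise PipelineError(f"epistasis pair {pair!r} must be 'mut1+mut2'")
                p1 = degenerate_summary(panel.params_for(m1), constants, mutant_id=m1)
                p2 = degenerate_summary(panel.params_for(m2), constants, mutant_id=m2)
                band = predict_combined_curve(
                    p1, p2, wt_post, AdditiveModelSpec(), constants,
                    grid=np.array(
                        [10.0, 20.0, 40.0, 60.0, 80.0, 100.0, 150.0, 250.0,
                         500.0, 750.0, 1000.0]
                    ),
                    n_draws=200,
                    seed=config.seed,
                )
                band.to_csv(out_dir / f"{m1}+{m2}.additive.csv")
                bundle.epistasis[pair] = band
                log.info("epistasis %s", pair)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage epistasis failed: {exc}") from exc

    try:
        if "landscape" in stages:
            grid = fc1000_landscape((0.0, 14.0), (-4.0, 8.0), 80, config.eps_d, constants)
            grid.to_frame().to_csv(out_dir / "landscape.csv", index=False)
            corr = panel_correlation(panel)
            (out_dir / "panel_correlation.json").write_text(
                json.dumps(
                    {"r": corr.r, "slope": corr.slope, "intercept": corr.intercept,
                     "n": corr.n}
                )
            )
            bundle.landscape = grid
            log.info("landscape: r=%.3f over %d variants", corr.r, corr.n)
    except Exception as exc:
        raise PipelineError(f"stage landscape failed: {exc}") from exc
    finally:
        log.removeHandler(handler)
        handler.close()

    return bundle
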