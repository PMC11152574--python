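"""Panel-level analyses: the FC1000 landscape over (eps_L, gamma), the
eps_L-gamma correlation across characterised variants, counterfactual
coupling resets, and phenotype tables.

The landscape view is the natural summary of the model: at fixed eps_D,
the fold change at 1000 nM ligand is a function of the two remaining
parameters, and the measured variants scatter across it.  Inducible
variants occupy low eps_L / high gamma; additional mutations push them
along the anti-diagonal toward weak response, which is what the
negative eps_L-gamma correlation across the panel quantifies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model import (
    ModelParams,
    SystemConstants,
    classify_phenotype,
    fc1000,
    fold_change,
)
from .synth import MutantPanel

__all__ = [
    "LandscapeGrid",
    "CorrelationResult",
    "fc1000_landscape",
    "panel_correlation",
    "counterfactual_gamma",
    "phenotype_table",
]


@dataclass(frozen=True)
class LandscapeGrid:
    """FC1000 evaluated on a rectangular (eps_L, gamma) grid.

    ``fc1000[i, j]`` corresponds to ``eps_L_axis[i]``, ``gamma_axis[j]``.
    """

    eps_L_axis: np.ndarray
    gamma_axis: np.ndarray
    fc1000: np.ndarray
    eps_D: float
    constants: SystemConstants

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (eps_L, gamma, fc1000), for machine-readable
        output alongside any plot."""
        el, ga = np.meshgrid(self.eps_L_axis, self.gamma_axis, indexing="ij")
        return pd.DataFrame(
            {"eps_L": el.ravel(), "gamma": ga.ravel(), "fc1000": self.fc1000.ravel()}
        )


def fc1000_landscape(
    eps_L_range: tuple[float, float],
    gamma_range: tuple[float, float],
    resolution: int = 100,
    eps_D: float = 0.0,
    constants: SystemConstants = SystemConstants(),
) -> LandscapeGrid:
    """Evaluate FC1000 over a rectangular (eps_L, gamma) grid."""
    if resolution < 2:
        raise ValueError("resolution must be >= 2")
    for name, (lo, hi) in (("eps_L_range", eps_L_range), ("gamma_range", gamma_range)):
        if not lo < hi:
            raise ValueError(f"{name} must satisfy lower < upper")
    eps_l_axis = np.linspace(*eps_L_range, resolution)
    gamma_axis = np.linspace(*gamma_range, resolution)
    mat = np.empty((resolution, resolution))
    for i, el in enumerate(eps_l_axis):
        for j, ga in enumerate(gamma_axis):
            mat[i, j] = fold_change(1000.0, ModelParams(eps_D, el, ga), constants)
    return LandscapeGrid(eps_l_axis, gamma_axis, mat, eps_D, constants)


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation and OLS regression of gamma on eps_L."""

    r: float
    slope: float
    intercept: float
    n: int


def panel_correlation(panel: MutantPanel, prior: int = 1) -> CorrelationResult:
    """Correlation between eps_L and gamma medians across the panel.

    Ordinary least squares of gamma on eps_L over the posterior medians;
    requires at least 3 variants and non-degenerate eps_L spread.
    """
    eps_l = panel.posteriors[f"eps_L{prior}_med"].to_numpy(float)
    gamma = panel.posteriors[f"gamma{prior}_med"].to_numpy(float)
    if len(eps_l) < 3:
        raise ValueError("need at least 3 variants for a correlation")
    if np.ptp(eps_l) == 0:
        raise ValueError("eps_L has zero variance; correlation undefined")
    fit = stats.linregress(eps_l, gamma)
    return CorrelationResult(
        r=float(fit.rvalue),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        n=len(eps_l),
    )


def counterfactual_gamma(
    params: ModelParams,
    gamma_ref: float,
    constants: SystemConstants = SystemConstants(),
) -> tuple[float, float]:
    """FC1000 before and after resetting the coupling to ``gamma_ref``.

    Isolates how much of a variant's phenotype is carried by its
    inter-domain coupling: a dead variant whose FC1000 recovers once
    gamma is reset to the wild-type value lost induction through the
    coupling, not through its intra-domain energetics.
    """
    return (
        fc1000(params, constants),
        fc1000(params.with_gamma(gamma_ref), constants),
    )


def phenotype_table(
    panel: MutantPanel,
    constants: SystemConstants = SystemConstants(),
    eps_d: float = 0.0,
    prior: int = 1,
) -> pd.DataFrame:
    """FC1000 and phenotype class for every panel variant.

    Evaluates the model at each variant's posterior medians (with the
    shared ``eps_d``) and classifies against the wild-type FC1000:
    ``dead`` below 0.1, ``enhanced`` above wild type, else ``neutral``.
    """
    wt = fc1000(panel.params_for("WT", eps_d, prior), constants)
    rows = []
    for mutant in panel.mutants:
        v = fc1000(panel.params_for(mutant, eps_d, prior), constants)
        rows.append(
            {
                "mutant": mutant,
                "fc1000": v,
                "phenotype": classify_phenotype(v, wt).value,
            }
        )
    return pd.DataFrame(rows)
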