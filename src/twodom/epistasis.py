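"""Additive and weighted-additive prediction of combined mutants.

Under the additive null model, a combined mutant's parameters are the
wild type's plus the sum of each constituent mutation's perturbation:

    p(mut1+mut2) = p_WT + a1_p * dp(mut1) + a2_p * dp(mut2),
    dp(mut) = p(mut) - p_WT,     p in {eps_D, eps_L, gamma}

with all six weights a = 1.  Epistasis is whatever the data refuse of
this: deviations are quantified by comparing predicted induction-curve
bands against observations, and mechanistic hypotheses are expressed by
quenching individual weights toward 0 (e.g. a residue far from the DBD
contributing nothing to eps_D once a DBD-proximal mutation is present).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import ModelParams, SystemConstants, induction_curve
from .inference import PosteriorSummary
from .synth import InductionDataset

__all__ = [
    "AdditiveModelSpec",
    "MutantDelta",
    "DeviationScore",
    "WEIGHT_PRESETS",
    "delta_params",
    "additive_params",
    "predict_combined_curve",
    "epistasis_deviation",
]

_PARAMS = ("eps_D", "eps_L", "gamma")


@dataclass(frozen=True)
class AdditiveModelSpec:
    """The six weights of the weighted additive model, each in [0, 1].

    The all-ones instance is the plain additive model.  Weight order
    follows (mutant 1, mutant 2) per parameter.
    """

    a1_eps_D: float = 1.0
    a2_eps_D: float = 1.0
    a1_eps_L: float = 1.0
    a2_eps_L: float = 1.0
    a1_gamma: float = 1.0
    a2_gamma: float = 1.0

    def __post_init__(self) -> None:
        for name, v in self.as_dict().items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"weight {name} must lie in [0, 1], got {v}")

    def as_dict(self) -> dict[str, float]:
        return {
            f"a{i}_{p}": getattr(self, f"a{i}_{p}") for p in _PARAMS for i in (1, 2)
        }

    def swapped(self) -> "AdditiveModelSpec":
        """The same weights with the mutant-1/mutant-2 roles exchanged.

        Published weight sets are printed per combined mutant without an
        unambiguous statement of which constituent is 'mutant 1'; use
        this to test the other assignment.
        """
        return AdditiveModelSpec(
            self.a2_eps_D,
            self.a1_eps_D,
            self.a2_eps_L,
            self.a1_eps_L,
            self.a2_gamma,
            self.a1_gamma,
        )


def _preset(weights: tuple[float, ...]) -> AdditiveModelSpec:
    # caption order: {a1_epsD, a2_epsD, a1_epsL, a2_epsL, a1_gamma, a2_gamma}
    return AdditiveModelSpec(*weights)


#: Published weight sets for the eight characterised combined mutants,
#: keyed by panel letter, in the caption's weight order
#: {a1_epsD, a2_epsD, a1_epsL, a2_epsL, a1_gamma, a2_gamma}.
WEIGHT_PRESETS: dict[str, AdditiveModelSpec] = {
    "A": _preset((1, 1, 1, 1, 1, 1)),
    "B": _preset((1, 1, 0.5, 1, 1, 1)),
    "C": _preset((1, 1, 0.5, 1, 1, 1)),
    "D": _preset((1, 1, 0, 1, 1, 1)),
    "E": _preset((0, 1, 1, 1, 0, 1)),
    "F": _preset((0, 1, 1, 1, 0, 1)),
    "G": _preset((0, 1, 1, 1, 1, 1)),
    "H": _preset((0, 1, 1, 1, 1, 1)),
}


@dataclass(frozen=True)
class MutantDelta:
    """Per-parameter perturbation of one mutant relative to the wild type."""

    d_eps_D: float
    d_eps_L: float
    d_gamma: float


def delta_params(mut: ModelParams, wt: ModelParams) -> MutantDelta:
    """Elementwise perturbation dp = p_mut - p_WT."""
    return MutantDelta(
        mut.eps_D - wt.eps_D, mut.eps_L - wt.eps_L, mut.gamma - wt.gamma
    )


def additive_params(
    delta1: MutantDelta,
    delta2: MutantDelta,
    wt: ModelParams,
    spec: AdditiveModelSpec = AdditiveModelSpec(),
) -> ModelParams:
    """Weighted-additive parameters of the combined mutant."""
    return ModelParams(
        eps_D=wt.eps_D + spec.a1_eps_D * delta1.d_eps_D + spec.a2_eps_D * delta2.d_eps_D,
        eps_L=wt.eps_L + spec.a1_eps_L * delta1.d_eps_L + spec.a2_eps_L * delta2.d_eps_L,
        gamma=wt.gamma + spec.a1_gamma * delta1.d_gamma + spec.a2_gamma * delta2.d_gamma,
    )


def predict_combined_curve(
    post1: PosteriorSummary,
    post2: PosteriorSummary,
    wt_post: PosteriorSummary,
    spec: AdditiveModelSpec,
    constants: SystemConstants,
    grid,
    n_draws: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Credible band of the combined mutant's induction curve.

    Draws (eps_L, gamma) triples independently from the three posteriors
    (eps_D is each summary's fixed value), applies the weighted additive
    model per draw, evaluates the curve on ``grid``, and returns the
    {2.5, 50, 97.5}th percentiles per concentration (columns ``p2.5``,
    ``p50``, ``p97.5``).  No cross-mutant posterior correlation exists,
    so independent pairing is the only defensible choice.
    """
    for other in (post1, post2):
        if other.constants != wt_post.constants:
            raise ValueError("posteriors were fitted under different constants")
    grid = np.asarray(grid, dtype=float)
    rng = np.random.default_rng(seed)
    curves = np.empty((n_draws, len(grid)))
    wt_eps_d = wt_post.eps_d
    for j in range(n_draws):
        rows = [
            p.samples.iloc[rng.integers(0, len(p.samples))]
            for p in (post1, post2, wt_post)
        ]
        p1 = ModelParams(post1.eps_d, rows[0]["eps_L"], rows[0]["gamma"])
        p2 = ModelParams(post2.eps_d, rows[1]["eps_L"], rows[1]["gamma"])
        wt = ModelParams(wt_eps_d, rows[2]["eps_L"], rows[2]["gamma"])
        combined = additive_params(delta_params(p1, wt), delta_params(p2, wt), wt, spec)
        curves[j] = induction_curve(grid, combined, constants)
    qs = np.percentile(curves, [2.5, 50, 97.5], axis=0)
    return pd.DataFrame(
        {"p2.5": qs[0], "p50": qs[1], "p97.5": qs[2]},
        index=pd.Index(grid, name="conc_nM"),
    )


@dataclass(frozen=True)
class DeviationScore:
    """How far observations sit from an additive-model prediction band."""

    rms: float
    frac_outside_band: float


def epistasis_deviation(
    predicted_band: pd.DataFrame, observed: InductionDataset
) -> DeviationScore:
    """Quantify epistasis as misfit of the additive prediction.

    RMS difference between the predicted median curve and the observed
    per-concentration replicate means, plus the fraction of those means
    falling outside the 95% band.  The grids must match.
    """
    grid = np.asarray(predicted_band.index, dtype=float)
    if len(grid) != len(observed.concentrations) or not np.allclose(
        grid, observed.concentrations
    ):
        raise ValueError("prediction and observation grids differ")
    means = observed.replicate_means()
    rms = float(np.sqrt(np.mean((predicted_band["p50"].to_numpy() - means) ** 2)))
    outside = (means < predicted_band["p2.5"].to_numpy()) | (
        means > predicted_band["p97.5"].to_numpy()
    )
    return DeviationScore(rms=rms, frac_outside_band=float(outside.mean()))
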