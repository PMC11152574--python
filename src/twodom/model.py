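"""Forward model of two-domain allosteric induction.

A two-domain repressor (TetR-like) is modelled with a ligand-binding
domain (LBD) and a DNA-binding domain (DBD), each switching between an
inactive and an active conformation.  Three free energies, all in units
of kBT, characterise a variant:

* ``eps_D`` — cost for the DBD to adopt its DNA-binding-competent
  (active) conformation;
* ``eps_L`` — cost for the LBD to adopt its ligand-binding-competent
  (active) conformation;
* ``gamma`` — inter-domain coupling penalty paid when both domains are
  active simultaneously.  Its sign sets whether the ligand behaves as an
  inducer (``gamma > 0``) or a corepressor (``gamma < 0``).

The observable is the fold change (FC) of the regulated gene: the ratio
of its expression with the repressor present to the unregulated level,
bounded in (0, 1):

    FC(c) = [1 + R* exp(-eps_D) * (1 + exp(-eps_L - gamma) x)
                                 / (1 + exp(-eps_L) x)]^-1,
    x = (c / K)^2

where ``c`` is ligand concentration, ``K`` the ligand dissociation
constant of the active LBD, and ``R*`` a rescaled repressor copy number
folding in TF abundance and operator affinity.  ``R*`` and ``K`` are
mutation-invariant system constants.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

__all__ = [
    "ModelParams",
    "SystemConstants",
    "CurveSummary",
    "PhenotypeLabel",
    "FlatResponseError",
    "DEAD_FC1000_THRESHOLD",
    "fold_change",
    "leakiness",
    "saturation",
    "epsilon_d_from_leakiness",
    "ec50",
    "fc1000",
    "classify_phenotype",
    "state_free_energies",
    "induction_curve",
    "summarize_curve",
]

#: FC at 1000 nM below which a variant is classified non-inducible ("dead").
DEAD_FC1000_THRESHOLD = 0.1


class FlatResponseError(ValueError):
    """Raised when a curve property is undefined because gamma = 0.

    With zero inter-domain coupling, ligand and operator binding are
    independent and the fold change does not depend on concentration, so
    quantities such as the EC50 have no meaning.
    """


@dataclass(frozen=True)
class ModelParams:
    """Biophysical parameters of one repressor variant (kBT).

    The wild type is the reference point of the energy scale: its
    ``eps_D`` is defined to be 0.
    """

    eps_D: float
    eps_L: float
    gamma: float

    def __post_init__(self) -> None:
        for name in ("eps_D", "eps_L", "gamma"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be a finite real, got {v!r}")

    def with_gamma(self, gamma: float) -> "ModelParams":
        """Copy with the coupling replaced (used for counterfactuals)."""
        return ModelParams(self.eps_D, self.eps_L, gamma)


@dataclass(frozen=True)
class SystemConstants:
    """Mutation-invariant constants of the induction model.

    ``r_star`` is the rescaled repressor number (dimensionless), ``k``
    the ligand dissociation constant in nM, and ``n_lig`` the exponent
    on ``c / K`` — fixed at 2 by the functional form; override only if
    you know what you are doing.
    """

    r_star: float = 100.0
    k: float = 3.0
    n_lig: int = 2

    def __post_init__(self) -> None:
        if not (self.r_star > 0 and math.isfinite(self.r_star)):
            raise ValueError(f"r_star must be positive and finite, got {self.r_star}")
        if not (self.k > 0 and math.isfinite(self.k)):
            raise ValueError(f"k must be positive and finite, got {self.k}")
        if self.n_lig < 1:
            raise ValueError(f"n_lig must be a positive integer, got {self.n_lig}")


class PhenotypeLabel(str, enum.Enum):
    """Induction phenotype relative to the wild type at 1000 nM ligand."""

    DEAD = "dead"
    ENHANCED = "enhanced"
    NEUTRAL = "neutral"


def _log_occupancy_ratio(c, params: ModelParams, constants: SystemConstants):
    """log of R* e^(-eps_D) (1 + e^(-eps_L-gamma) x) / (1 + e^(-eps_L) x).

    Evaluated in log space so that eps_L, gamma far outside [-20, 30] and
    c/K up to 1e6 neither overflow nor lose the small terms.  At c = 0
    the log concentration term is -inf and logaddexp collapses each
    factor to 0 exactly.
    """
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("ligand concentration must be non-negative")
    with np.errstate(divide="ignore"):  # log(0) -> -inf is the c = 0 case
        log_x = constants.n_lig * (np.log(c) - math.log(constants.k))
    log_num = np.logaddexp(0.0, -params.eps_L - params.gamma + log_x)
    log_den = np.logaddexp(0.0, -params.eps_L + log_x)
    return math.log(constants.r_star) - params.eps_D + log_num - log_den


def fold_change(
    c, params: ModelParams, constants: SystemConstants = SystemConstants()
):
    """Fold change of the regulated gene at ligand concentration ``c`` (nM).

    Accepts a scalar or array of concentrations; returns the same shape.
    Values lie strictly in (0, 1) for finite parameters.
    """
    out = expit(-_log_occupancy_ratio(c, params, constants))
    return out if np.ndim(c) else float(out)


def leakiness(params: ModelParams, constants: SystemConstants = SystemConstants()) -> float:
    """Fold change at zero ligand: (1 + R* e^(-eps_D))^-1.

    Depends on eps_D only — eps_L and gamma cancel exactly at c = 0.
    """
    return float(expit(params.eps_D - math.log(constants.r_star)))


def saturation(params: ModelParams, constants: SystemConstants = SystemConstants()) -> float:
    """Fold change in the saturating-ligand limit: (1 + R* e^(-eps_D-gamma))^-1."""
    return float(expit(params.eps_D + params.gamma - math.log(constants.r_star)))


def epsilon_d_from_leakiness(leak: float, r_star: float) -> float:
    """Invert the leakiness relation for the DBD activation cost.

    eps_D = -ln((1/leak - 1) / R*); exact inverse of ``leakiness``.
    """
    if not (0.0 < leak < 1.0):
        raise ValueError(f"leakiness must lie in (0, 1), got {leak}")
    if r_star <= 0:
        raise ValueError(f"r_star must be positive, got {r_star}")
    return math.log(r_star) + math.log(leak) - math.log1p(-leak)


def fc1000(params: ModelParams, constants: SystemConstants = SystemConstants()) -> float:
    """Fold change at 1000 nM ligand, the phenotype-defining readout."""
    return float(fold_change(1000.0, params, constants))


def ec50(
    params: ModelParams,
    constants: SystemConstants = SystemConstants(),
    rtol: float = 1e-10,
) -> float:
    """Ligand concentration (nM) of half-maximal response.

    Defined as the concentration where the fold change crosses the
    midpoint (leakiness + saturation) / 2; unique because FC is strictly
    monotone in ``c`` whenever gamma != 0.  Solved by bracketing and
    Brent's method.
    """
    if params.gamma == 0:
        raise FlatResponseError("gamma = 0 gives a flat curve with no EC50")
    target = 0.5 * (leakiness(params, constants) + saturation(params, constants))

    def f(c: float) -> float:
        return fold_change(c, params, constants) - target

    # FC moves from leakiness toward saturation, so f(0) and the large-c
    # limit straddle 0; grow the upper bracket geometrically from K.
    hi = constants.k
    for _ in range(200):
        if f(0.0) * f(hi) < 0:
            break
        hi *= 2.0
    else:  # pragma: no cover - unreachable for finite parameters
        raise RuntimeError("failed to bracket the EC50")
    return float(brentq(f, 0.0, hi, rtol=rtol, xtol=1e-300))


def classify_phenotype(fc1000_value: float, fc1000_wt: float) -> PhenotypeLabel:
    """Classify a variant by its FC at 1000 nM.

    ``dead`` if below the 0.1 threshold (takes precedence), ``enhanced``
    if strictly above the wild-type value, ``neutral`` otherwise.
    """
    for name, v in (("fc1000", fc1000_value), ("fc1000_wt", fc1000_wt)):
        if not (0.0 < v < 1.0):
            raise ValueError(f"{name} must lie in (0, 1), got {v}")
    if fc1000_value < DEAD_FC1000_THRESHOLD:
        return PhenotypeLabel.DEAD
    if fc1000_value > fc1000_wt:
        return PhenotypeLabel.ENHANCED
    return PhenotypeLabel.NEUTRAL


def state_free_energies(params: ModelParams) -> dict[str, float]:
    """Free energies (kBT) of the four conformational states.

    States are labelled L{I,A}D{I,A} for inactive/active LBD and DBD;
    the doubly inactive state LIDI is the zero of the scale, and the
    doubly active state pays the coupling penalty on top of both
    activation costs.
    """
    return {
        "LIDI": 0.0,
        "LADI": params.eps_L,
        "LIDA": params.eps_D,
        "LADA": params.eps_L + params.eps_D + params.gamma,
    }


def induction_curve(
    grid, params: ModelParams, constants: SystemConstants = SystemConstants()
) -> np.ndarray:
    """Evaluate the fold change on a concentration grid (elementwise)."""
    grid = np.asarray(grid, dtype=float)
    return np.asarray(fold_change(grid, params, constants))


@dataclass(frozen=True)
class CurveSummary:
    """The scalar descriptors of one induction curve.

    ``ec50`` is ``None`` for a flat (gamma = 0) curve.
    """

    leakiness: float
    saturation: float
    ec50: float | None
    fc1000: float


def summarize_curve(
    params: ModelParams, constants: SystemConstants = SystemConstants()
) -> CurveSummary:
    """Compute leakiness, saturation, EC50 and FC1000 for one variant."""
    try:
        half = ec50(params, constants)
    except FlatResponseError:
        half = None
    return CurveSummary(
        leakiness=leakiness(params, constants),
        saturation=saturation(params, constants),
        ec50=half,
        fc1000=fc1000(params, constants),
    )
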