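"""Synthetic induction datasets and packaged reference tables.

The experimental readout the model is fitted to is a plate-reader /
flow-cytometry dose-response assay: normalised reporter fluorescence
(fold change) of one repressor variant measured in replicate at each
point of a 12-concentration anhydrotetracycline (aTC) gradient.  The
raw curves are not redistributable, so this module generates datasets
with the same statistical structure — the noiseless model curve plus
heteroscedastic replicate noise — and packages the published posterior
summaries for 23 variants together with residue-distance metadata, so
every downstream stage runs without any download.

Replicate noise is Gaussian with standard deviation
``max(cv * FC_true, floor)``: a relative component (``cv``) matching
the roughly constant relative error of normalised fluorescence, and an
absolute floor so that near-zero fold changes keep a finite error.
Observations are clipped at zero (fluorescence ratios cannot be
negative).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .model import ModelParams, SystemConstants, induction_curve

__all__ = [
    "DEFAULT_GRID",
    "NoiseModel",
    "InductionDataset",
    "MutantPanel",
    "DatasetParseError",
    "default_grid",
    "simulate_dataset",
    "read_dataset",
    "write_dataset",
    "panel_fixture",
]

#: The 12-point aTC gradient of the dose-response assay, in nM.
_GRID = (0.0, 10.0, 20.0, 40.0, 60.0, 80.0, 100.0, 150.0, 250.0, 500.0, 750.0, 1000.0)

DEFAULT_GRID = np.array(_GRID)


def default_grid() -> np.ndarray:
    """The standard 12-concentration measurement grid (nM), ascending."""
    return np.array(_GRID)


class DatasetParseError(ValueError):
    """Raised when a dataset file violates the tabular contract."""


@dataclass(frozen=True)
class NoiseModel:
    """Heteroscedastic replicate-noise model: sd = max(cv * FC, floor)."""

    cv: float = 0.05
    floor: float = 0.002

    def __post_init__(self) -> None:
        if self.cv < 0 or self.floor < 0:
            raise ValueError("cv and floor must be non-negative")
        if self.cv == 0 and self.floor == 0:
            raise ValueError("noise model must have cv > 0 or floor > 0")

    def sd(self, fc_true: np.ndarray) -> np.ndarray:
        return np.maximum(self.cv * np.asarray(fc_true, float), self.floor)


@dataclass
class InductionDataset:
    """Replicate fold-change observations on a concentration grid.

    ``replicates`` has shape (n_concentrations, n_replicates); missing
    observations are NaN (some variants were measured in triplicate).
    ``provenance`` records either the full generator inputs and seed, or
    ``{"source": "experimental"}`` for measured data.
    """

    mutant_id: str
    concentrations: np.ndarray
    replicates: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.replicates = np.atleast_2d(np.asarray(self.replicates, dtype=float))
        c = self.concentrations
        if c.ndim != 1 or len(c) == 0:
            raise ValueError("concentrations must be a non-empty 1-D array")
        if np.any(c < 0):
            raise ValueError("concentrations must be non-negative")
        if np.any(np.diff(c) <= 0):
            raise ValueError("concentration grid must be sorted ascending and unique")
        if self.replicates.shape[0] != len(c):
            raise ValueError(
                f"replicate matrix has {self.replicates.shape[0]} rows "
                f"for {len(c)} concentrations"
            )
        if np.all(np.isnan(self.replicates), axis=1).any():
            raise ValueError("every concentration needs at least one replicate")
        if np.nanmin(self.replicates) < 0:
            raise ValueError("fold-change observations must be non-negative")

    @property
    def n_replicates(self) -> int:
        return self.replicates.shape[1]

    def replicate_means(self) -> np.ndarray:
        """Per-concentration mean over the available replicates."""
        return np.nanmean(self.replicates, axis=1)

    def leakiness_replicates(self) -> np.ndarray:
        """Observations at c = 0 (the leakiness measurements)."""
        idx = np.flatnonzero(self.concentrations == 0.0)
        if len(idx) == 0:
            raise ValueError("dataset has no zero-concentration measurements")
        row = self.replicates[idx[0]]
        return row[~np.isnan(row)]

    def nonzero_subset(self) -> tuple[np.ndarray, np.ndarray]:
        """(concentrations, replicate matrix) for c > 0 — the induction data
        that remains once the leakiness has fixed eps_D."""
        mask = self.concentrations > 0
        return self.concentrations[mask], self.replicates[mask]


def simulate_dataset(
    params: ModelParams,
    constants: SystemConstants = SystemConstants(),
    grid=None,
    n_rep: int = 4,
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
    mutant_id: str = "synthetic",
) -> InductionDataset:
    """Simulate a replicate dose-response dataset for one variant.

    Each observation is the noiseless model fold change plus zero-mean
    Gaussian noise with sd ``max(cv * FC, floor)``, clipped at zero.
    Identical inputs and seed give bit-identical datasets.  A warning is
    emitted if more than 1% of points clip (the Gaussian noise model is
    then visibly truncated).
    """
    if grid is None:
        grid = default_grid()
    grid = np.asarray(grid, dtype=float)
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    rng = np.random.default_rng(seed)
    fc_true = induction_curve(grid, params, constants)
    sd = noise.sd(fc_true)
    obs = fc_true[:, None] + rng.normal(size=(len(grid), n_rep)) * sd[:, None]
    n_clipped = int(np.sum(obs < 0))
    if n_clipped > 0.01 * obs.size:
        warnings.warn(
            f"{n_clipped}/{obs.size} simulated observations clipped at 0; "
            "the noise model is strongly truncated at these parameters",
            stacklevel=2,
        )
    obs = np.clip(obs, 0.0, None)
    provenance = {
        "source": "simulated",
        "eps_D": params.eps_D,
        "eps_L": params.eps_L,
        "gamma": params.gamma,
        "r_star": constants.r_star,
        "k": constants.k,
        "n_lig": constants.n_lig,
        "cv": noise.cv,
        "floor": noise.floor,
        "n_rep": n_rep,
        "seed": seed,
    }
    return InductionDataset(mutant_id, grid, obs, provenance)


# ---------------------------------------------------------------------------
# Tabular text I/O (long format: one observation per row)

_COLUMNS = ["mutant", "conc_nM", "replicate", "fold_change"]


def write_dataset(dataset: InductionDataset, path) -> None:
    """Write a dataset as long-format CSV (columns mutant, conc_nM,
    replicate, fold_change; one row per observation, NaNs omitted)."""
    rows = []
    for i, c in enumerate(dataset.concentrations):
        for r in range(dataset.n_replicates):
            v = dataset.replicates[i, r]
            if not np.isnan(v):
                rows.append((dataset.mutant_id, c, r, v))
    # %.17g round-trips IEEE doubles exactly
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, index=False, float_format="%.17g")


def read_dataset(path) -> InductionDataset:
    """Read a long-format dataset written by :func:`write_dataset`.

    Malformed rows raise :class:`DatasetParseError` naming the offending
    line (1-based, counting the header as line 1).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # noqa: BLE001 - rewrap with file context
        raise DatasetParseError(f"{path}: cannot parse as CSV ({exc})") from exc
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise DatasetParseError(f"{path}: missing columns {missing}")
    for col in ("conc_nM", "fold_change"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header is line 1
            raise DatasetParseError(f"{path}: non-numeric {col} at line {line}")
        df[col] = pd.to_numeric(df[col])
    if df["fold_change"].isna().any():
        line = int(df["fold_change"].isna().idxmax()) + 2
        raise DatasetParseError(f"{path}: missing fold_change at line {line}")
    neg = df["fold_change"] < 0
    if neg.any():
        line = int(neg.idxmax()) + 2
        raise DatasetParseError(f"{path}: negative fold_change at line {line}")
    mutants = df["mutant"].unique()
    if len(mutants) != 1:
        raise DatasetParseError(f"{path}: expected one mutant per file, got {list(mutants)}")
    concs = np.sort(df["conc_nM"].unique())
    n_rep = int(df.groupby("conc_nM").size().max())
    mat = np.full((len(concs), n_rep), np.nan)
    for i, c in enumerate(concs):
        vals = df.loc[df["conc_nM"] == c, "fold_change"].to_numpy()
        mat[i, : len(vals)] = vals
    return InductionDataset(str(mutants[0]), concs, mat, {"source": str(path)})


# ---------------------------------------------------------------------------
# Packaged reference tables

@dataclass(frozen=True)
class MutantPanel:
    """The published panel of 23 characterised variants.

    ``posteriors`` holds, per variant, the posterior medians and 95%
    credible bounds of eps_L and gamma under two priors on gamma
    (columns ``eps_L1_*`` / ``gamma1_*`` for the sd-2.5 prior,
    ``eps_L2_*`` / ``gamma2_*`` for the sd-5 prior).  ``distances``
    carries each mutated residue's distance to the DNA operator and to
    the ligand (Å), structural metadata only.
    """

    posteriors: pd.DataFrame
    distances: pd.DataFrame

    @property
    def mutants(self) -> list[str]:
        return list(self.posteriors["mutant"])

    def params_for(
        self, mutant: str, eps_d: float = 0.0, prior: int = 1
    ) -> ModelParams:
        """Point parameters for one variant from the posterior medians.

        Published per-variant eps_D values are graphical only, so the
        default treats eps_D as the wild-type reference 0; pass
        ``eps_d`` to override.
        """
        if prior not in (1, 2):
            raise ValueError("prior must be 1 (sd 2.5) or 2 (sd 5)")
        row = self.posteriors.loc[self.posteriors["mutant"] == mutant]
        if row.empty:
            raise KeyError(f"unknown mutant {mutant!r}")
        row = row.iloc[0]
        return ModelParams(
            eps_D=eps_d,
            eps_L=float(row[f"eps_L{prior}_med"]),
            gamma=float(row[f"gamma{prior}_med"]),
        )


def _load_csv(name: str) -> pd.DataFrame:
    ref = resources.files("twodom").joinpath("data", name)
    with resources.as_file(ref) as p:
        return pd.read_csv(p)


def panel_fixture() -> MutantPanel:
    """Load the packaged 23-variant panel with residue distances."""
    post = _load_csv("mutant_posteriors.csv")
    dist = _load_csv("residue_distances.csv")
    for p in ("eps_L1", "eps_L2", "gamma1", "gamma2"):
        lo, med, hi = post[f"{p}_lo"], post[f"{p}_med"], post[f"{p}_hi"]
        if not ((lo <= med).all() and (med <= hi).all()):
            raise ValueError(f"packaged panel violates CI ordering for {p}")
    return MutantPanel(posteriors=post, distances=dist)
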