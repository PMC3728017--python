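"""Two-stage stochastic cytokine expression.

Stage one (deterministic/analogue) sets continuous transcription-factor
levels; stage two throws one independent biased coin per cytokine, with the
coin's probability a monotone function of the corresponding TF level in that
cell.  Sorting cells on their cytokine pattern and re-throwing the coins
("sort and re-culture") repopulates all four on/off quadrants whenever the
coin probabilities are interior to (0, 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import EmptySortGateError

__all__ = [
    "BiasFunction",
    "bias_probability",
    "draw_cytokine_states",
    "reculture_simulation",
    "CYTOKINE_TF",
    "DEFAULT_BIASES",
    "QUADRANTS",
]

log = logging.getLogger(__name__)

#: Which TF channel biases which cytokine coin.
CYTOKINE_TF = {"ifng": "tbet", "il4": "gata3", "il13": "gata3", "il5": "gata3"}

QUADRANTS = ("-/-", "+/-", "-/+", "+/+")


@dataclass(frozen=True)
class BiasFunction:
    """Logistic-in-log-TF map from a TF level to an expression probability.

    p(t) = p_min + (p_max - p_min) / (1 + exp(-slope * (ln t - midpoint)))

    Monotone non-decreasing in t, with floor ``p_min`` and ceiling ``p_max``
    absorbing TF-independent influences on the coin.
    """

    p_min: float
    p_max: float
    midpoint: float  # ln(TF level) at half-rise
    slope: float

    def __post_init__(self):
        if not (0.0 <= self.p_min <= self.p_max <= 1.0):
            raise ValueError("need 0 <= p_min <= p_max <= 1")
        if self.slope <= 0:
            raise ValueError("slope must be > 0")

    def __call__(self, tf_level):
        t = np.asarray(tf_level, dtype=float)
        if np.any(t <= 0):
            raise ValueError("tf_level must be > 0")
        z = -self.slope * (np.log(t) - self.midpoint)
        return self.p_min + (self.p_max - self.p_min) / (1.0 + np.exp(z))


def bias_probability(tf_level, bias: BiasFunction):
    """Probability of cytokine expression at the given TF level."""
    return bias(tf_level)


# Default calibrations.  Fit (simulation-in-the-loop, against thresholded
# readout at the default generator noise) so that synthetic populations
# reproduce the reference summary fractions: Th1 IFN-g+ ~60% overall / ~85%
# in the top T-bet bin; Th2 IL-4+ ~20% overall / ~40% in the top GATA3 bin;
# IL-5 ~10% (Th2) vs ~1% (Th1).  IL-13 mirrors IL-4 with its own ceiling.
DEFAULT_BIASES: Mapping[str, BiasFunction] = {
    "ifng": BiasFunction(p_min=0.02, p_max=0.8072, midpoint=5.2415, slope=9.0),
    "il4": BiasFunction(p_min=0.01, p_max=0.2673, midpoint=6.9695, slope=1.5634),
    "il13": BiasFunction(p_min=0.01, p_max=0.30, midpoint=6.90, slope=1.6),
    "il5": BiasFunction(p_min=0.005, p_max=0.12, midpoint=7.25, slope=2.0),
}


def draw_cytokine_states(tf_levels: pd.DataFrame,
                         biases: Mapping[str, BiasFunction],
                         seed: int | None = None) -> pd.DataFrame:
    """Draw one independent Bernoulli state per cytokine per cell.

    ``tf_levels`` holds one column per TF channel; ``biases`` maps cytokine
    names to their :class:`BiasFunction`, each applied to the TF channel
    given by :data:`CYTOKINE_TF`.
    """
    if seed is None:
        seed = int(np.random.SeedSequence().entropy % (2 ** 32))
        log.warning("draw_cytokine_states: no seed given, drew seed=%d", seed)
    rng = np.random.default_rng(seed)
    out = {}
    for cyt, bias in biases.items():
        tf_chan = CYTOKINE_TF[cyt]
        if tf_chan not in tf_levels.columns:
            raise KeyError(f"TF channel {tf_chan!r} (for {cyt}) missing from table")
        p = bias(tf_levels[tf_chan].to_numpy())
        out[f"{cyt}_on"] = (rng.random(len(tf_levels)) < p).astype(np.int8)
    return pd.DataFrame(out, index=tf_levels.index)


def quadrant_of(states: pd.DataFrame, a: str = "ifng", b: str = "il4") -> pd.Series:
    """Label each cell -/-, +/-, -/+ or +/+ from two binary state columns."""
    pa = states[f"{a}_on"].astype(bool)
    pb = states[f"{b}_on"].astype(bool)
    lab = np.where(pa, np.where(pb, "+/+", "+/-"), np.where(pb, "-/+", "-/-"))
    return pd.Series(lab, index=states.index)


def reculture_simulation(population: pd.DataFrame,
                         sort_quadrant: str,
                         biases: Mapping[str, BiasFunction],
                         seed: int,
                         n_out: int | None = None,
                         persistence_rho: float = 0.2,
                         condition_log_medians: Mapping[str, float] | None = None,
                         sigma_log: float | None = None):
    """Sort one cytokine quadrant, re-culture, restimulate, re-throw coins.

    ``population`` is a cell table with TF columns (``tbet``, ``gata3``) and
    binary ``ifng_on`` / ``il4_on`` columns.  Cells in ``sort_quadrant`` are
    selected and expanded (sampling with replacement) to ``n_out`` cells.
    During re-culture each TF level partially regresses to the condition's
    stationary distribution: with persistence correlation ``rho``,

        ln t' = rho * ln t + (1 - rho) * mu + sqrt(1 - rho^2) * sigma * Z.

    ``mu`` (per-channel stationary log-median) and ``sigma`` default to the
    sorted population's own log statistics.  With ``rho = 1`` TF levels are
    retained exactly.  Cytokine coins are then re-thrown for the new
    restimulation.

    Returns ``(cells, fractions)``: the repopulated table (TF columns plus
    fresh ``*_on`` columns) and the quadrant fraction dict.
    """
    if sort_quadrant not in QUADRANTS:
        raise ValueError(f"sort_quadrant must be one of {QUADRANTS}")
    if not (0.0 <= persistence_rho <= 1.0):
        raise ValueError("persistence_rho must be in [0, 1]")
    rng = np.random.default_rng(seed)
    mask = quadrant_of(population).to_numpy() == sort_quadrant
    if not mask.any():
        raise EmptySortGateError(f"no cells in sort gate {sort_quadrant!r}")
    gated = population.loc[mask]
    n_out = int(n_out if n_out is not None else len(population))
    idx = rng.integers(0, len(gated), size=n_out)
    tf_cols = [c for c in population.columns if not c.endswith("_on")]
    cells = gated.iloc[idx][tf_cols].reset_index(drop=True)

    rho = persistence_rho
    if rho < 1.0:
        for col in ("tbet", "gata3"):
            logs = np.log(cells[col].to_numpy())
            parent_logs = np.log(population[col].to_numpy())
            mu = (condition_log_medians[col] if condition_log_medians
                  else float(np.median(parent_logs)))
            sig = sigma_log if sigma_log is not None else float(np.std(parent_logs))
            z = rng.standard_normal(n_out)
            cells[col] = np.exp(rho * logs + (1 - rho) * mu
                                + np.sqrt(1 - rho ** 2) * sig * z)

    states = draw_cytokine_states(cells[["tbet", "gata3"]], biases,
                                  seed=int(rng.integers(2 ** 31)))
    cells = pd.concat([cells, states], axis=1)
    quad = quadrant_of(cells)
    fractions = {q: float((quad == q).mean()) for q in QUADRANTS}
    return cells, fractions
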