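"""Dynamical-systems engine for the two-TF cross-inhibition/autoactivation motif.

The motif couples two lineage-specifying transcription factors x and y.  Each
is produced at a basal input-driven rate, amplified by its own saturating
autoactivation, repressed by the other factor, and degraded linearly (time is
rescaled so the degradation rate is 1):

    dx/dt = beta1 + b * A(x; k_auto_x, n) * R(y; k_cross_x, n) - x
    dy/dt = beta2 + b * A(y; k_auto_y, n) * R(x; k_cross_y, n) - y

with A(u; k, n) = u^n / (u^n + k^n) and R(v; k, n) = k^n / (v^n + k^n).

The qualitative behaviour is organised by the ratios
k1_tilde = k_cross_x / k_auto_x and k2_tilde = k_cross_y / k_auto_y: weak
cross-inhibition (large ratios) yields a single steady state that tunes
continuously with the inputs, while strong cross-inhibition (small ratios)
yields winner-take-all or bistable behaviour.  Region labels:

    I   one stable state, high x / low y
    II  one stable state, low x / high y
    III one stable state co-expressing both factors
    IV  two stable states (bistable switch)

All region boundaries are computed numerically from the fixed-point structure;
no closed-form boundary is assumed anywhere.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import root

from .errors import AmbiguousSteadyStateError, NoFixedPointError

__all__ = [
    "GRNParameters",
    "FixedPoint",
    "RegionMap",
    "CoexpressionMap",
    "InputTrajectory",
    "drift",
    "jacobian",
    "find_fixed_points",
    "classify_region",
    "phase_diagram",
    "input_response_map",
    "input_trajectory",
    "hysteresis_scan",
    "beta_from_concentration",
    "REGION_III_PARAMS",
    "REGION_IV_PARAMS",
    "PHASE_BASE_PARAMS",
]

STABILITY_MARGIN = 1e-8
DEDUP_RTOL = 1e-6


@dataclass(frozen=True)
class GRNParameters:
    """Parameters of the two-TF motif ODEs (degradation rate rescaled to 1)."""

    beta1: float
    beta2: float
    b: float
    k_auto_x: float
    k_auto_y: float
    k_cross_x: float
    k_cross_y: float
    n: float = 1.0

    def __post_init__(self):
        if min(self.k_auto_x, self.k_auto_y, self.k_cross_x, self.k_cross_y) <= 0:
            raise ValueError("all half-activation thresholds must be > 0")
        if self.b < 0:
            raise ValueError("feedback rate b must be >= 0")
        if self.beta1 < 0 or self.beta2 < 0:
            raise ValueError("basal rates beta1, beta2 must be >= 0")
        if self.n < 1:
            raise ValueError("Hill exponent n must be >= 1")

    @property
    def k1_tilde(self) -> float:
        """Cross-inhibition / autoactivation threshold ratio felt by x."""
        return self.k_cross_x / self.k_auto_x

    @property
    def k2_tilde(self) -> float:
        """Cross-inhibition / autoactivation threshold ratio felt by y."""
        return self.k_cross_y / self.k_auto_y

    def swapped(self) -> "GRNParameters":
        """Parameters with the roles of x and y exchanged."""
        return GRNParameters(
            beta1=self.beta2, beta2=self.beta1, b=self.b,
            k_auto_x=self.k_auto_y, k_auto_y=self.k_auto_x,
            k_cross_x=self.k_cross_y, k_cross_y=self.k_cross_x, n=self.n,
        )

    def with_inputs(self, beta1: float, beta2: float) -> "GRNParameters":
        return replace(self, beta1=beta1, beta2=beta2)


@dataclass(frozen=True)
class FixedPoint:
    x: float
    y: float
    stable: bool
    eigenvalues: tuple  # real parts of the Jacobian spectrum

    @property
    def state(self) -> np.ndarray:
        return np.array([self.x, self.y])


# Defaults used throughout tests/CLI.  REGION_III_PARAMS has weak
# cross-inhibition (k~=5) and b < k_auto so the zero-input state is quiescent;
# REGION_IV_PARAMS has strong cross-inhibition (k~=0.1) and is bistable at
# small balanced inputs.  PHASE_BASE_PARAMS fixes inputs/feedback for the
# (k1~, k2~) phase diagram, which exhibits all four regions.
REGION_III_PARAMS = GRNParameters(
    beta1=0.5, beta2=0.5, b=0.8,
    k_auto_x=1.0, k_auto_y=1.0, k_cross_x=5.0, k_cross_y=5.0, n=1.0)
REGION_IV_PARAMS = GRNParameters(
    beta1=0.05, beta2=0.05, b=2.0,
    k_auto_x=0.5, k_auto_y=0.5, k_cross_x=0.05, k_cross_y=0.05, n=1.0)
PHASE_BASE_PARAMS = GRNParameters(
    beta1=0.02, beta2=0.02, b=2.0,
    k_auto_x=0.5, k_auto_y=0.5, k_cross_x=0.5, k_cross_y=0.5, n=1.0)


def _hill_act(u, k, n):
    u = np.asarray(u, dtype=float)
    return u ** n / (u ** n + k ** n)


def _hill_rep(v, k, n):
    v = np.asarray(v, dtype=float)
    return k ** n / (v ** n + k ** n)


def drift(state, params: GRNParameters) -> np.ndarray:
    """Time derivatives (dx/dt, dy/dt) of the motif at ``state``.

    ``state`` may be a pair or an array of shape (..., 2); derivatives are
    returned with the same leading shape.
    """
    s = np.asarray(state, dtype=float)
    x, y = s[..., 0], s[..., 1]
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("state components must be >= 0")
    p = params
    dx = p.beta1 + p.b * _hill_act(x, p.k_auto_x, p.n) * _hill_rep(y, p.k_cross_x, p.n) - x
    dy = p.beta2 + p.b * _hill_act(y, p.k_auto_y, p.n) * _hill_rep(x, p.k_cross_y, p.n) - y
    return np.stack([dx, dy], axis=-1)


def jacobian(state, params: GRNParameters) -> np.ndarray:
    """Analytic 2x2 Jacobian of :func:`drift` at ``state``."""
    x, y = float(state[0]), float(state[1])
    p = params
    n = p.n

    def d_act(u, k):
        # d/du of u^n/(u^n+k^n); at u=0 only finite for n=1
        if u == 0.0:
            return 1.0 / k if n == 1.0 else 0.0
        return n * k ** n * u ** (n - 1) / (u ** n + k ** n) ** 2

    def d_rep(v, k):
        if v == 0.0:
            return -1.0 / k if n == 1.0 else 0.0
        return -n * k ** n * v ** (n - 1) / (v ** n + k ** n) ** 2

    j11 = p.b * d_act(x, p.k_auto_x) * _hill_rep(y, p.k_cross_x, n) - 1.0
    j12 = p.b * _hill_act(x, p.k_auto_x, n) * d_rep(y, p.k_cross_x)
    j21 = p.b * _hill_act(y, p.k_auto_y, n) * d_rep(x, p.k_cross_y)
    j22 = p.b * d_act(y, p.k_auto_y) * _hill_rep(x, p.k_cross_y, n) - 1.0
    return np.array([[j11, j12], [j21, j22]])


def _classify_stability(state, params) -> FixedPoint:
    ev = np.linalg.eigvals(jacobian(state, params))
    re = tuple(sorted(float(v.real) for v in ev))
    stable = all(r < -STABILITY_MARGIN for r in re)
    return FixedPoint(float(state[0]), float(state[1]), stable, re)


def _seed_grid(hi: float, n_lin: int) -> np.ndarray:
    lin = np.linspace(0.0, hi, n_lin)
    logp = np.geomspace(max(hi * 1e-6, 1e-9), hi, 24)
    return np.unique(np.concatenate([lin, logp]))


def find_fixed_points(
    params: GRNParameters,
    search_box: tuple | None = None,
    tol: float = DEDUP_RTOL,
    seed_grid: int = 64,
) -> list[FixedPoint]:
    """All fixed points of the motif inside ``search_box``, sorted by x.

    Roots are located by multi-start Newton iteration (scipy ``hybr``) seeded
    from sign-change cells of the drift field on a linear+log grid, then
    deduplicated at relative tolerance ``tol``.  Stability is classified from
    the real parts of the analytic Jacobian spectrum with a margin of
    ``1e-8``.

    Raises
    ------
    NoFixedPointError
        If no root is found; the system always has at least one fixed point
        in [0, beta_max + b]^2, so this indicates a bad search box.
    """
    p = params
    if p.b == 0.0:
        # Linear decay system: unique fixed point at (beta1, beta2).
        return [_classify_stability((p.beta1, p.beta2), p)]
    if search_box is None:
        hi = max(p.beta1, p.beta2) + p.b
        search_box = (0.0, hi * (1.0 + 1e-9) + 1e-12)
    lo, hi = search_box
    g = _seed_grid(hi, seed_grid)
    g = g[(g >= lo) & (g <= hi)]
    X, Y = np.meshgrid(g, g, indexing="ij")
    F = drift(np.stack([X, Y], axis=-1), p)
    fx, fy = F[..., 0], F[..., 1]

    def cell_has_sign_change(a):
        return (a.min() <= 0.0) & (a.max() >= 0.0)

    roots: list[np.ndarray] = []
    for i in range(len(g) - 1):
        for j in range(len(g) - 1):
            cx = fx[i : i + 2, j : j + 2]
            cy = fy[i : i + 2, j : j + 2]
            if not (cell_has_sign_change(cx) and cell_has_sign_change(cy)):
                continue
            s0 = np.array([(g[i] + g[i + 1]) / 2, (g[j] + g[j + 1]) / 2])
            sol = root(lambda s: drift(np.clip(s, 0, None), p), s0, method="hybr")
            if not sol.success or np.max(np.abs(sol.fun)) > 1e-10:
                continue
            r = np.clip(sol.x, 0.0, None)
            if r[0] > hi + 1e-6 or r[1] > hi + 1e-6:
                continue
            if np.max(np.abs(drift(r, p))) > 1e-8:
                continue
            if any(np.linalg.norm(r - q) <= tol * (1.0 + np.linalg.norm(q)) for q in roots):
                continue
            roots.append(r)
    if not roots:
        raise NoFixedPointError(
            f"no fixed point found in box {search_box} for {params}")
    fps = sorted((_classify_stability(r, p) for r in roots), key=lambda f: f.x)
    return fps


def classify_region(params: GRNParameters, expression_threshold: float = 0.5) -> str:
    """Region label in {I, II, III, IV} from the computed fixed-point set.

    IV iff at least two stable fixed points exist.  Otherwise the unique
    stable fixed point is classified against ``expression_threshold`` times
    the largest stable coordinate: high-x/low-y -> I, low-x/high-y -> II,
    otherwise (co-expression) -> III.
    """
    fps = find_fixed_points(params)
    stable = [f for f in fps if f.stable]
    if not stable:
        raise NoFixedPointError(f"no stable fixed point for {params}")
    if len(stable) > 2:
        warnings.warn(
            f"{len(stable)} stable fixed points found (unexpected for n=1); "
            "labelling region IV", stacklevel=2)
        return "IV"
    if len(stable) == 2:
        return "IV"
    fp = stable[0]
    ref = expression_threshold * max(max(f.x for f in stable), max(f.y for f in stable))
    hx, hy = fp.x >= ref, fp.y >= ref
    if hx and not hy:
        return "I"
    if hy and not hx:
        return "II"
    return "III"


@dataclass
class RegionMap:
    """Region label per (k1_tilde, k2_tilde) grid point."""

    k1_axis: np.ndarray
    k2_axis: np.ndarray
    labels: np.ndarray  # shape (len(k1_axis), len(k2_axis)), dtype <U3
    inputs: tuple  # (beta1, beta2)
    base_params: GRNParameters = None

    @property
    def distinct_labels(self) -> set:
        return set(self.labels.ravel().tolist())

    def to_tsv(self, path, seed=None) -> None:
        _write_grid_tsv(path, self.k1_axis, self.k2_axis, self.labels,
                        "k1_tilde", "k2_tilde",
                        meta={"beta1": self.inputs[0], "beta2": self.inputs[1],
                              "params": _params_dict(self.base_params),
                              "seed": seed})


@dataclass
class CoexpressionMap:
    """Steady-state co-expression pattern per input pair."""

    il12_axis: np.ndarray
    il4_axis: np.ndarray
    pattern: np.ndarray  # strings in {neither, X-only, Y-only, both}
    x_ss: np.ndarray
    y_ss: np.ndarray
    threshold_frac: float
    params: GRNParameters = None

    def to_tsv(self, path, seed=None) -> None:
        _write_grid_tsv(path, self.il12_axis, self.il4_axis, self.pattern,
                        "beta1_axis", "beta2_axis",
                        meta={"threshold_frac": self.threshold_frac,
                              "params": _params_dict(self.params),
                              "seed": seed})


def phase_diagram(k1_grid, k2_grid, base_params: GRNParameters,
                  expression_threshold: float = 0.5) -> RegionMap:
    """Classify every (k1_tilde, k2_tilde) grid point at fixed inputs.

    The cross-inhibition thresholds are set to ``k_tilde * k_auto`` with the
    autoactivation thresholds taken from ``base_params``.
    """
    k1_grid = np.asarray(k1_grid, dtype=float)
    k2_grid = np.asarray(k2_grid, dtype=float)
    if np.any(k1_grid <= 0) or np.any(k2_grid <= 0):
        raise ValueError("k_tilde grids must be strictly positive")
    labels = np.empty((k1_grid.size, k2_grid.size), dtype="U3")
    for i, k1 in enumerate(k1_grid):
        for j, k2 in enumerate(k2_grid):
            p = replace(base_params,
                        k_cross_x=k1 * base_params.k_auto_x,
                        k_cross_y=k2 * base_params.k_auto_y)
            labels[i, j] = classify_region(p, expression_threshold)
    return RegionMap(k1_grid, k2_grid, labels,
                     (base_params.beta1, base_params.beta2), base_params)


def _unique_stable_state(params: GRNParameters, inputs_tag=None) -> FixedPoint:
    fps = find_fixed_points(params)
    stable = [f for f in fps if f.stable]
    if len(stable) != 1:
        raise AmbiguousSteadyStateError(
            f"{len(stable)} stable states at inputs "
            f"(beta1={params.beta1:.6g}, beta2={params.beta2:.6g})",
            inputs=inputs_tag or (params.beta1, params.beta2))
    return stable[0]


def input_response_map(params: GRNParameters, beta1_grid, beta2_grid,
                       T_frac: float = 0.5) -> CoexpressionMap:
    """Steady-state co-expression pattern over the input plane.

    Every grid point must be monostable (else
    :class:`AmbiguousSteadyStateError` names the offending inputs).  Patterns
    compare each steady-state coordinate to ``T_frac`` times its maximum over
    the whole map.
    """
    b1 = np.asarray(beta1_grid, dtype=float)
    b2 = np.asarray(beta2_grid, dtype=float)
    xs = np.zeros((b1.size, b2.size))
    ys = np.zeros_like(xs)
    for i, v1 in enumerate(b1):
        for j, v2 in enumerate(b2):
            fp = _unique_stable_state(params.with_inputs(v1, v2), (v1, v2))
            xs[i, j], ys[i, j] = fp.x, fp.y
    tx, ty = T_frac * xs.max(), T_frac * ys.max()
    pattern = np.full(xs.shape, "neither", dtype="U7")
    pattern[(xs >= tx) & (ys < ty)] = "X-only"
    pattern[(xs < tx) & (ys >= ty)] = "Y-only"
    pattern[(xs >= tx) & (ys >= ty)] = "both"
    return CoexpressionMap(b1, b2, pattern, xs, ys, T_frac, params)


@dataclass
class InputTrajectory:
    """Steady states along a straight path in the input plane."""

    betas: np.ndarray        # (n_steps, 2)
    states: np.ndarray       # (n_steps, 2)
    max_jump: float          # largest step-to-step Euclidean jump
    dynamic_range: float     # overall state excursion along the path
    sharp_transition: bool

    @property
    def max_relative_jump(self) -> float:
        if self.dynamic_range == 0.0:
            return 0.0
        return self.max_jump / self.dynamic_range


def input_trajectory(params: GRNParameters, start_inputs, end_inputs,
                     n_steps: int, jump_tol: float = 0.2,
                     strict: bool = False) -> InputTrajectory:
    """Steady-state trajectory for inputs interpolated start -> end.

    The steady state at each step is obtained by continuation: among the
    stable fixed points at the current inputs, the one nearest the previous
    state is followed.  A jump larger than ``jump_tol`` times the trajectory's
    dynamic range marks a sharp transition; with ``strict=True`` this raises
    :class:`SharpTransitionError` (the expected outcome for bistable
    parameterizations), otherwise it is reported on the result.
    """
    from .errors import SharpTransitionError

    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    start = np.asarray(start_inputs, dtype=float)
    end = np.asarray(end_inputs, dtype=float)
    ts = np.linspace(0.0, 1.0, n_steps)
    betas = np.outer(1 - ts, start) + np.outer(ts, end)
    states = np.zeros((n_steps, 2))
    prev = None
    for i, (b1v, b2v) in enumerate(betas):
        fps = find_fixed_points(params.with_inputs(b1v, b2v))
        stable = [f for f in fps if f.stable]
        if not stable:
            raise NoFixedPointError(f"no stable state at step {i}")
        if prev is None:
            # start from the pure-condition steady state nearest the corner
            fp = min(stable, key=lambda f: -(f.x - f.y) * np.sign(b1v - b2v + 1e-300))
            if len(stable) == 1:
                fp = stable[0]
        else:
            fp = min(stable, key=lambda f: np.linalg.norm(f.state - prev))
        states[i] = fp.state
        prev = fp.state
    jumps = np.linalg.norm(np.diff(states, axis=0), axis=1)
    span = states.max(axis=0) - states.min(axis=0)
    dyn = float(np.linalg.norm(span))
    max_jump = float(jumps.max()) if len(jumps) else 0.0
    sharp = dyn > 0 and max_jump > jump_tol * dyn
    if sharp and strict:
        raise SharpTransitionError(
            f"max jump {max_jump:.4g} exceeds {jump_tol:.2g} x dynamic range {dyn:.4g}")
    return InputTrajectory(betas, states, max_jump, dyn, sharp)


def hysteresis_scan(params: GRNParameters, start_inputs, end_inputs,
                    n_steps: int) -> tuple[InputTrajectory, InputTrajectory, bool]:
    """Branch-following continuation along the path in both directions.

    Returns (forward, backward, hysteretic) where ``hysteretic`` is True when
    the two branch trajectories disagree beyond numerical tolerance anywhere
    along the path -- the signature of bistability.
    """
    fwd = input_trajectory(params, start_inputs, end_inputs, n_steps)
    bwd = input_trajectory(params, end_inputs, start_inputs, n_steps)
    gap = np.linalg.norm(fwd.states - bwd.states[::-1], axis=1)
    scale = max(fwd.dynamic_range, bwd.dynamic_range, 1e-12)
    return fwd, bwd, bool(gap.max() > 1e-3 * scale)


def beta_from_concentration(conc_ng_ml, beta_max: float = 1.0,
                            K_ng_ml: float = 30.0):
    """Saturating map from cytokine concentration (ng/ml) to a basal rate."""
    c = np.asarray(conc_ng_ml, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentrations must be >= 0")
    return beta_max * c / (c + K_ng_ml)


# ---------------------------------------------------------------------------
# export helpers

def _params_dict(p: GRNParameters | None):
    if p is None:
        return None
    return {k: getattr(p, k) for k in
            ("beta1", "beta2", "b", "k_auto_x", "k_auto_y",
             "k_cross_x", "k_cross_y", "n")}


def _write_grid_tsv(path, row_axis, col_axis, values, row_name, col_name, meta):
    path = str(path)
    with open(path, "w") as fh:
        fh.write("\t" + "\t".join(f"{v:.10g}" for v in col_axis) + "\n")
        for rv, row in zip(row_axis, values):
            fh.write(f"{rv:.10g}\t" + "\t".join(str(c) for c in row) + "\n")
    sidecar = {"row_axis": row_name, "col_axis": col_name, **meta}
    with open(path + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=2, default=float)
        fh.write("\n")
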