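"""Single-cell statistics: transforms, isotype-anchored normalization, the
alpha angle, MFI matrices, log-space rank-1 separability, noise profiles,
fixed-size-bin bias curves, binary mutual information, BIC modality, quadrant
tables and the GATA3/T-bet ratio statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from sklearn.mixture import GaussianMixture

from .generate import FlowSample, InputMatrixDataset

__all__ = [
    "transform_channel",
    "NormalizedChannel",
    "normalize_to_isotype",
    "AlphaResult",
    "alpha_angle",
    "alpha_mode",
    "mfi_matrix",
    "decompose_separable",
    "noise_profile",
    "BiasCurve",
    "bin_bias_curve",
    "fit_bias_curve",
    "mutual_information_binary",
    "bic_modality",
    "QuadrantTable",
    "quadrant_fractions",
    "isotype_threshold",
    "ratio_statistic",
]

DEFAULT_COFACTOR = 20.0


# ---------------------------------------------------------------------------
# transforms

def _logicle_forward(y, T, W, M, A):
    # Inverse of the biexponential B(x) (Parks/Roederer/Moore); solved per
    # value by bracketed root finding.  x is in "display" units on [0, 1].
    b = (M + A) * np.log(10.0)
    w = W / (M + A)
    x2 = A / (M + A)
    x1 = x2 + w
    x0 = x1 + w
    # d solves 2 ln(d) + w b = 2 ln(b) ... standard parameter equation:
    # w = 2 ln(d/b) / (b + d)  -> solve for d in (0, b)
    if w == 0:
        d = b
    else:
        func = lambda dd: 2.0 * np.log(dd / b) / (b + dd) + w
        d = brentq(func, 1e-12, b - 1e-12)
    c_a = np.exp(x0 * (b + d))
    mf_a = np.exp(b * x1) - c_a / np.exp(d * x1)
    a2 = T / (np.exp(b) - c_a / np.exp(d) - mf_a)

    def B(x):
        return a2 * (np.exp(b * x) - c_a * np.exp(-d * x) - mf_a)

    flat = np.asarray(y, dtype=float).ravel()
    res = np.empty_like(flat)
    for i, v in enumerate(flat):
        # B is monotone on the real line; data value 0 maps to display x1
        res[i] = brentq(lambda x: B(x) - v, -2.0, 3.0)
    return res.reshape(np.shape(y))


def transform_channel(values, method: str = "asinh", cofactor: float = DEFAULT_COFACTOR,
                      T: float = 262144.0, W: float = 0.5, M: float = 4.5,
                      A: float = 0.0):
    """Monotone display transform: linear near 0, logarithmic for large values.

    ``asinh`` (default) uses asinh(v / cofactor); ``logicle`` evaluates the
    standard biexponential display scale with parameters (T, W, M, A).
    """
    v = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("values must be finite")
    if method == "asinh":
        if cofactor <= 0:
            raise ValueError("cofactor must be > 0")
        return np.arcsinh(v / cofactor)
    if method == "logicle":
        return _logicle_forward(v, T, W, M, A)
    raise ValueError(f"unknown transform method {method!r}")


# ---------------------------------------------------------------------------
# normalization and angles

@dataclass
class NormalizedChannel:
    """Channel rescaled so the isotype median sits at 1 and the sample's 95th
    percentile at 10 (affine map; order preserving; invariant to a global
    rescaling applied to sample and isotype alike)."""

    values: np.ndarray
    anchor: float  # isotype median
    scale: float   # 95th percentile of the raw experiment values


def normalize_to_isotype(values, isotype_values) -> NormalizedChannel:
    v = np.asarray(values, dtype=float)
    iso = np.asarray(isotype_values, dtype=float)
    if iso.size == 0:
        raise ValueError("isotype sample is empty")
    m = float(np.median(iso))
    q = float(np.quantile(v, 0.95))
    if q == m:
        if m == 0.0:
            raise ValueError("degenerate isotype: zero spread and zero median")
        q = m * (1.0 + 1e-12)
    out = 1.0 + 9.0 * (v - m) / (q - m)
    return NormalizedChannel(values=out, anchor=m, scale=q)


@dataclass
class AlphaResult:
    values: np.ndarray     # alpha in degrees, excluded cells dropped
    n_excluded: int
    mask: np.ndarray = None  # boolean keep-mask aligned with the input cells


def alpha_angle(x_norm, y_norm, variant: str = "log") -> AlphaResult:
    """Per-cell angle alpha = atan(x/y) in degrees, on normalized channels.

    ``variant="log"`` (default, matching the log-space convention in which
    the isotype anchor sits at the origin): alpha = atan2(log10 x, log10 y)
    with normalized values floored at 1, so a channel at/below its isotype
    median contributes 0.  Pure Th1-like cells give 90 deg, pure Th2-like
    cells 0 deg.  Cells with both channels at the floor are excluded.

    ``variant="linear"``: alpha = atan2(x, y) on the normalized values; cells
    with a non-positive normalized value are excluded.  This variant is
    exactly invariant to any per-cell factor multiplying both raw channels.
    """
    x = np.asarray(getattr(x_norm, "values", x_norm), dtype=float)
    y = np.asarray(getattr(y_norm, "values", y_norm), dtype=float)
    if x.shape != y.shape:
        raise ValueError("channel shapes differ")
    if variant == "log":
        lx = np.log10(np.clip(x, 1.0, None))
        ly = np.log10(np.clip(y, 1.0, None))
        keep = (lx > 0) | (ly > 0)
        a = np.degrees(np.arctan2(lx[keep], ly[keep]))
    elif variant == "linear":
        keep = (x > 0) & (y > 0)
        a = np.degrees(np.arctan2(x[keep], y[keep]))
    else:
        raise ValueError(f"unknown alpha variant {variant!r}")
    return AlphaResult(values=a, n_excluded=int((~keep).sum()), mask=keep)


def alpha_mode(alpha_values, bin_deg: float = 1.0) -> float:
    """Mode of an alpha distribution: most frequent value after rounding to
    ``bin_deg``-degree resolution."""
    a = np.asarray(alpha_values, dtype=float)
    if a.size == 0:
        raise ValueError("empty alpha sample")
    r = np.round(a / bin_deg) * bin_deg
    vals, counts = np.unique(r, return_counts=True)
    return float(vals[np.argmax(counts)])


# ---------------------------------------------------------------------------
# matrix statistics

def mfi_matrix(dataset: InputMatrixDataset, channel: str) -> pd.DataFrame:
    """Median fluorescence intensity per grid condition (rows IL-12, cols IL-4).

    Empty samples yield NaN entries and a warning.
    """
    mat = pd.DataFrame(index=pd.Index(dataset.il12_grid, name="il12_ng_ml"),
                       columns=pd.Index(dataset.il4_grid, name="il4_ng_ml"),
                       dtype=float)
    for c12 in dataset.il12_grid:
        for c4 in dataset.il4_grid:
            s = dataset.sample_at(c12, c4)
            if len(s) == 0:
                warnings.warn(f"empty sample at ({c12}, {c4}); MFI set to NaN",
                              stacklevel=2)
                continue
            mat.loc[c12, c4] = float(np.median(s.cells[channel]))
    return mat


def decompose_separable(mfi: pd.DataFrame, background: float,
                        reference_col: int = 0, floor: float = 0.0):
    """Best separable factorization M - bg ~ F1 (outer) F2, fit in log space.

    A separable matrix is multiplicatively rank 1, i.e. additive in log
    space; the least-squares additive fit has the closed form
    ``log F1_i + log F2_j = rowmean_i + colmean_j - grandmean``.  Returns
    ``(f1, f2, residual)`` with ``f2[reference_col] == 1`` and
    ``residual = 1 - |fit|^2 / |log M|^2`` (0 for exactly separable input).

    With ``floor > 0`` entries below the floor are raised to it; with the
    default ``floor = 0`` any non-positive entry after background subtraction
    raises ``ValueError`` naming the first offending cell.
    """
    M = np.asarray(mfi, dtype=float) - background
    if floor > 0:
        M = np.maximum(M, floor)
    bad = np.argwhere(M <= 0)
    if len(bad):
        i, j = bad[0]
        raise ValueError(
            f"non-positive entry after background subtraction at row {i}, "
            f"column {j} (value {M[i, j]:.6g})")
    L = np.log(M)
    rm = L.mean(axis=1)
    cm = L.mean(axis=0)
    g = L.mean()
    fit = rm[:, None] + cm[None, :] - g
    lf2 = cm - cm[reference_col]
    lf1 = rm + cm[reference_col] - g
    total = float(np.sum((L - g) ** 2))  # centred: fraction of log-variance
    residual = 0.0 if total == 0 else float(max(np.sum((L - fit) ** 2) / total, 0.0))
    return np.exp(lf1), np.exp(lf2), residual


def noise_profile(dataset: InputMatrixDataset, channel: str) -> pd.DataFrame:
    """Coefficient of variation (SD/mean) of the channel per grid condition.

    The result carries ``max_min_ratio`` in ``DataFrame.attrs`` as the
    constancy summary.
    """
    rows = []
    for c12 in dataset.il12_grid:
        for c4 in dataset.il4_grid:
            s = dataset.sample_at(c12, c4)
            v = s.cells[channel].to_numpy()
            mean = v.mean()
            if mean == 0:
                warnings.warn(f"zero mean at ({c12}, {c4})", stacklevel=2)
                cv = np.nan
            else:
                cv = v.std() / mean
            rows.append({"il12_ng_ml": c12, "il4_ng_ml": c4, "cv": cv})
    out = pd.DataFrame(rows)
    cvs = out["cv"].dropna()
    if len(cvs) == 0:
        out.attrs["max_min_ratio"] = np.nan
    elif cvs.min() == 0:
        out.attrs["max_min_ratio"] = np.inf if cvs.max() > 0 else np.nan
    else:
        out.attrs["max_min_ratio"] = float(cvs.max() / cvs.min())
    return out


# ---------------------------------------------------------------------------
# bias curves

@dataclass
class BiasCurve:
    """Positive fraction per fixed-size TF bin."""

    bin_mean_tf: np.ndarray
    positive_fraction: np.ndarray
    bin_size: int
    population_fraction: float  # the "green line"
    tf_median: float            # the "red line"
    short_bin_dropped: bool


def bin_bias_curve(sample: FlowSample, tf_channel: str, cytokine_channel: str,
                   bin_size: int = 500, threshold: float | None = None,
                   positive: np.ndarray | None = None,
                   drop_short_bin: bool = True) -> BiasCurve:
    """Sort cells by TF level, cut into consecutive ``bin_size``-cell bins and
    compute the cytokine-positive fraction per bin.

    Positivity comes from ``positive`` (explicit boolean vector, e.g. true
    simulated states) or from thresholding ``cytokine_channel`` at
    ``threshold``.  The trailing short bin is dropped by default (flagged).
    """
    cells = sample.cells if isinstance(sample, FlowSample) else sample
    n = len(cells)
    if bin_size > n:
        raise ValueError(f"bin_size {bin_size} exceeds sample size {n}")
    tf = cells[tf_channel].to_numpy()
    if positive is not None:
        pos = np.asarray(positive, dtype=bool)
        if pos.shape != tf.shape:
            raise ValueError("positive vector length mismatch")
    elif threshold is not None:
        pos = cells[cytokine_channel].to_numpy() > threshold
    else:
        raise ValueError("provide either threshold or positive")
    order = np.argsort(tf, kind="stable")
    tf_sorted, pos_sorted = tf[order], pos[order]
    n_full = n // bin_size
    short = n % bin_size != 0
    means, fracs = [], []
    for i in range(n_full):
        sl = slice(i * bin_size, (i + 1) * bin_size)
        means.append(tf_sorted[sl].mean())
        fracs.append(pos_sorted[sl].mean())
    if short and not drop_short_bin:
        sl = slice(n_full * bin_size, n)
        means.append(tf_sorted[sl].mean())
        fracs.append(pos_sorted[sl].mean())
    return BiasCurve(np.array(means), np.array(fracs), bin_size,
                     float(pos.mean()), float(np.median(tf)),
                     short_bin_dropped=short and drop_short_bin)


def fit_bias_curve(curve: BiasCurve):
    """Fit the package's logistic bias shape to a binned curve.

    Returns (p_min, p_max, midpoint, slope) by least squares on the binned
    fractions, weighted equally.
    """
    from scipy.optimize import least_squares

    lt = np.log(curve.bin_mean_tf)
    f = curve.positive_fraction

    def model(q):
        pmin, pmax, mid, slope = q
        return pmin + (pmax - pmin) / (1 + np.exp(-slope * (lt - mid)))

    lo = f.min()
    hi = f.max()
    res = least_squares(lambda q: model(q) - f,
                        x0=[max(lo, 1e-4), min(max(hi, 2e-4), 1.0),
                            float(np.median(lt)), 2.0],
                        bounds=([0, 0, lt.min() - 5, 0.05],
                                [1, 1, lt.max() + 5, 50]))
    return tuple(res.x)


# ---------------------------------------------------------------------------
# independence, modality, quadrants, ratio

def mutual_information_binary(a, b) -> float:
    """Plug-in mutual information (bits) of two binary vectors."""
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError("length mismatch")
    if a.size == 0:
        raise ValueError("empty vectors")
    n = a.size
    tab = np.array([[np.sum(~a & ~b), np.sum(~a & b)],
                    [np.sum(a & ~b), np.sum(a & b)]], dtype=float) / n
    pa = tab.sum(axis=1)
    pb = tab.sum(axis=0)
    mi = 0.0
    for i in range(2):
        for j in range(2):
            if tab[i, j] > 0:
                mi += tab[i, j] * np.log2(tab[i, j] / (pa[i] * pb[j]))
    return float(max(mi, 0.0))


def bic_modality(values, max_components: int = 2, n_restarts: int = 5,
                 seed: int = 0, transform: bool = True,
                 cofactor: float = DEFAULT_COFACTOR) -> int:
    """Number of Gaussian mixture components (1..max) minimizing BIC.

    Fits operate on asinh-transformed values by default; ties prefer fewer
    components.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 50:
        raise ValueError("need at least 50 values")
    if transform:
        v = np.arcsinh(v / cofactor)
    v = v.reshape(-1, 1)
    best_k, best_bic = None, np.inf
    rng = np.random.default_rng(seed)
    for k in range(1, max_components + 1):
        bic_k = np.inf
        converged = False
        for _ in range(n_restarts):
            gm = GaussianMixture(n_components=k, n_init=1,
                                 random_state=int(rng.integers(2 ** 31)))
            try:
                gm.fit(v)
            except ValueError:  # pragma: no cover - degenerate input
                continue
            if gm.converged_:
                converged = True
                bic_k = min(bic_k, gm.bic(v))
        if not converged:
            raise RuntimeError(f"no GMM restart converged for k={k}")
        if bic_k < best_bic - 1e-9:  # strict improvement; ties keep fewer
            best_k, best_bic = k, bic_k
    return int(best_k)


@dataclass
class QuadrantTable:
    """Cell counts of the four cytokine on/off quadrants."""

    counts: Mapping[str, int]  # keys -/-, +/-, -/+, +/+
    thresholds: Mapping[str, float]
    n: int

    @property
    def fractions(self) -> dict:
        return {k: v / self.n for k, v in self.counts.items()}


def isotype_threshold(isotype_values, q: float = 0.99) -> float:
    """Positivity threshold: the ``q`` quantile of the isotype distribution."""
    return float(np.quantile(np.asarray(isotype_values, dtype=float), q))


def quadrant_fractions(sample: FlowSample, thresholds: Mapping[str, float],
                       a: str = "ifng", b: str = "il4") -> QuadrantTable:
    """Classify cells into -/-, +/-, -/+, +/+ by thresholding two channels."""
    cells = sample.cells if isinstance(sample, FlowSample) else sample
    va = cells[a].to_numpy()
    vb = cells[b].to_numpy()
    for ch, thr in ((a, thresholds[a]), (b, thresholds[b])):
        vals = cells[ch].to_numpy()
        if thr < vals.min() or thr > vals.max():
            warnings.warn(f"threshold for {ch} outside data range", stacklevel=2)
    pa, pb = va > thresholds[a], vb > thresholds[b]
    counts = {
        "-/-": int(np.sum(~pa & ~pb)),
        "+/-": int(np.sum(pa & ~pb)),
        "-/+": int(np.sum(~pa & pb)),
        "+/+": int(np.sum(pa & pb)),
    }
    return QuadrantTable(counts=counts, thresholds=dict(thresholds), n=len(cells))


def ratio_statistic(sample: FlowSample, isotype: FlowSample,
                    num: str = "gata3", den: str = "tbet") -> float:
    """Normalized GATA3/T-bet ratio: population median of per-cell ratios of
    isotype-median-normalized channels.

    Ratiometric, hence invariant to per-cell shared factors and to global
    channel rescalings applied to sample and isotype alike.
    """
    cells = sample.cells if isinstance(sample, FlowSample) else sample
    iso = isotype.cells if isinstance(isotype, FlowSample) else isotype
    m_num = float(np.median(iso[num]))
    m_den = float(np.median(iso[den]))
    if m_num <= 0 or m_den <= 0:
        raise ValueError("isotype medians must be > 0")
    r = (cells[num].to_numpy() / m_num) / (cells[den].to_numpy() / m_den)
    return float(np.median(r))
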