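"""Connectivity indices: bivariate Granger causality and mutual information.

Granger causality (GC) is estimated pairwise from bivariate autoregressive
(BVAR) models of order p (default 15).  With

    x(n) = sum_k a_xx[k] x(n-k) + sum_k a_xy[k] y(n-k) + u_xy(n)
    y(n) = sum_k a_yx[k] x(n-k) + sum_k a_yy[k] y(n-k) + u_yx(n)

fitted by ordinary least squares over the samples n = p+1..N, the influence
of y on x is

    GC_{y->x} = ln( V_{x|x} / V_{x|x,y} )

where V_{x|x} is the residual variance of the *restricted* model (x
regressed on its own p lags only, same sample window) and V_{x|x,y} that of
the full model.  Because the restricted regressors are a subset of the full
ones, the ratio is >= 1 and GC >= 0 up to round-off.  Residual "variance" is
the mean squared residual over the fitted window (population 1/M
normaliser, no mean re-centering; epochs are detrended upstream by the
1-40 Hz band-pass).

Mutual information (MI) is the plug-in histogram estimate of

    MI_xy = sum p(x,y) log2[ p(x,y) / (p(x) p(y)) ]

with equal-width binning (default 16 bins) over each series' observed
range, in bits.  MI is symmetric; GC is directed.

The per-epoch feature vectors follow the 32-channel conventions: GC is the
row-major flattening of the full 32 x 32 matrix (diagonal fixed at 0),
length 1024; MI is the strict upper triangle in row-major order, length
32*31/2 = 496.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import Epoch

__all__ = [
    "BVARFit",
    "ARFit",
    "MIEstimate",
    "ConnectivityFeatures",
    "SingularFitError",
    "GCMatrixError",
    "fit_bvar",
    "fit_univariate_ar",
    "granger_causality",
    "gc_matrix",
    "mutual_information",
    "mi_vector",
    "connectivity_dataset",
    "features_to_matrix",
    "features_to_frame",
    "save_features_tsv",
    "load_features_tsv",
]

log = logging.getLogger(__name__)

#: Floor applied to residual variances before the log ratio.
VARIANCE_FLOOR = 1e-12
#: Numerical tolerance on GC nonnegativity before clipping at zero.
GC_NEG_TOL = -1e-9

DEFAULT_ORDER = 15
DEFAULT_BINS = 16


class SingularFitError(np.linalg.LinAlgError):
    """Least-squares design matrix is rank deficient (constant or collinear
    input)."""


class GCMatrixError(RuntimeError):
    """A pairwise fit failed while assembling a GC matrix."""


@dataclass(frozen=True)
class BVARFit:
    """OLS fit of the bivariate AR model (both equations)."""

    order: int
    a_xx: np.ndarray
    a_xy: np.ndarray
    a_yx: np.ndarray
    a_yy: np.ndarray
    resid_var_x_full: float  # V_{x|x,y}
    resid_var_y_full: float  # V_{y|x,y}


@dataclass(frozen=True)
class ARFit:
    """OLS fit of the restricted (univariate) AR model."""

    order: int
    coefficients: np.ndarray
    resid_var: float  # V_{x|x}


@dataclass(frozen=True)
class MIEstimate:
    """Histogram mutual-information estimate with its joint distribution."""

    n_bins: int
    joint_hist: np.ndarray  # (B, B) counts, rows = x bins
    marginal_x: np.ndarray
    marginal_y: np.ndarray
    mi: float  # bits


@dataclass
class ConnectivityFeatures:
    """Per-epoch connectivity feature vector with provenance labels."""

    kind: str  # "GC" or "MI"
    values: np.ndarray
    subject_id: str
    session_id: str
    epoch_index: int


# ---------------------------------------------------------------------------
# lag-matrix helpers


def _lagged_design(series: np.ndarray, p: int) -> np.ndarray:
    """Columns are lags 1..p of ``series``; rows are samples p..N-1."""
    n = series.shape[-1]
    return np.column_stack([series[p - k : n - k] for k in range(1, p + 1)])


def _ols(design: np.ndarray, target: np.ndarray):
    coef, _, rank, _ = np.linalg.lstsq(design, target, rcond=None)
    if rank < design.shape[1]:
        raise SingularFitError(
            f"rank-deficient design matrix (rank {rank} < {design.shape[1]}); "
            "constant or collinear input?"
        )
    resid = target - design @ coef
    return coef, float(np.mean(resid**2))


def fit_bvar(x, y, p: int = DEFAULT_ORDER) -> BVARFit:
    """Fit the order-p bivariate AR model of two series by per-equation OLS."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    if x.size < 5 * p:
        raise ValueError(f"need at least 5p = {5 * p} samples, got {x.size}")
    design = np.hstack([_lagged_design(x, p), _lagged_design(y, p)])
    coef_x, var_x = _ols(design, x[p:])
    coef_y, var_y = _ols(design, y[p:])
    return BVARFit(
        order=p,
        a_xx=coef_x[:p],
        a_xy=coef_x[p:],
        a_yx=coef_y[:p],
        a_yy=coef_y[p:],
        resid_var_x_full=var_x,
        resid_var_y_full=var_y,
    )


def fit_univariate_ar(x, p: int = DEFAULT_ORDER) -> ARFit:
    """Fit the restricted model: x on its own p lags, same sample window."""
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 3 * p:
        raise ValueError(f"need at least 3p = {3 * p} samples, got {x.size}")
    coef, var = _ols(_lagged_design(x, p), x[p:])
    return ARFit(order=p, coefficients=coef, resid_var=var)


def granger_causality(x, y, p: int = DEFAULT_ORDER) -> float:
    """GC_{y->x}: the influence OF y ON x, ln(V_{x|x} / V_{x|x,y}) >= 0."""
    restricted = fit_univariate_ar(x, p).resid_var
    full = fit_bvar(x, y, p).resid_var_x_full
    gc = float(np.log(max(restricted, VARIANCE_FLOOR) / max(full, VARIANCE_FLOOR)))
    if gc < GC_NEG_TOL:
        raise GCMatrixError(f"GC estimate {gc} below the nonnegativity tolerance")
    return max(gc, 0.0)


# ---------------------------------------------------------------------------
# full-matrix fast path
#
# All pairwise order-p OLS problems on one epoch share the same lag matrix,
# so the Gram matrix L'L is computed once and every restricted (p x p) and
# full (2p x 2p) normal system is solved from its sub-blocks, batched over
# pairs.  This matches the per-pair lstsq route to numerical precision (see
# the consistency test) at a small fraction of the cost.


def _epoch_gram(data: np.ndarray, p: int):
    c, n = data.shape
    m = n - p
    lagmat = np.empty((m, c * p))
    for ch in range(c):
        for k in range(1, p + 1):
            lagmat[:, ch * p + (k - 1)] = data[ch, p - k : n - k]
    targets = data[:, p:].T  # (m, c)
    gram = lagmat.T @ lagmat
    cross = lagmat.T @ targets  # (c*p, c)
    tss = np.einsum("mc,mc->c", targets, targets)  # per-channel sum x(n)^2
    return gram, cross, tss, m


def gc_matrix(epoch: Epoch, p: int = DEFAULT_ORDER) -> np.ndarray:
    """Directed GC matrix of one epoch: entry (i, j) = GC_{channel j -> i}.

    Diagonal is fixed at 0; all off-diagonal entries are nonnegative.
    Raises :class:`GCMatrixError` naming the offending pair if any pairwise
    fit is degenerate.
    """
    data = np.asarray(epoch.data, dtype=float)
    c, n = data.shape
    if n < 3 * p:
        raise ValueError(f"epoch has {n} samples; need at least 3p = {3 * p}")
    gram, cross, tss, m = _epoch_gram(data, p)

    blocks = [np.arange(ch * p, (ch + 1) * p) for ch in range(c)]
    # restricted models, batched: G_ii beta = cross[block_i, i]
    g_rest = np.stack([gram[np.ix_(blocks[i], blocks[i])] for i in range(c)])
    r_rest = np.stack([cross[blocks[i], i] for i in range(c)])
    try:
        beta_rest = np.linalg.solve(g_rest, r_rest[:, :, None])[:, :, 0]
    except np.linalg.LinAlgError as exc:
        bad = [i for i in range(c) if np.linalg.matrix_rank(g_rest[i]) < p]
        raise GCMatrixError(
            f"restricted AR fit singular for channel(s) {bad}"
        ) from exc
    ssr_rest = tss - np.einsum("ck,ck->c", r_rest, beta_rest)
    v_rest = np.maximum(ssr_rest / m, VARIANCE_FLOOR)

    pairs = [(i, j) for i in range(c) for j in range(i + 1, c)]
    idx = np.stack([np.concatenate([blocks[i], blocks[j]]) for i, j in pairs])
    g_full = gram[idx[:, :, None], idx[:, None, :]]  # (P, 2p, 2p)
    tgt = np.array(pairs)  # (P, 2)
    r_full = np.take_along_axis(
        cross[idx], np.broadcast_to(tgt[:, None, :], (len(pairs), 2 * p, 2)), axis=2
    )  # (P, 2p, 2)
    try:
        beta_full = np.linalg.solve(g_full, r_full)
    except np.linalg.LinAlgError as exc:
        raise GCMatrixError(_find_bad_pair(g_full, pairs)) from exc
    ssr_full = tss[tgt] - np.einsum("pkt,pkt->pt", r_full, beta_full)
    v_full = np.maximum(ssr_full / m, VARIANCE_FLOOR)

    out = np.zeros((c, c))
    gc_i = np.log(v_rest[tgt[:, 0]] / v_full[:, 0])  # GC_{j -> i}
    gc_j = np.log(v_rest[tgt[:, 1]] / v_full[:, 1])  # GC_{i -> j}
    worst = min(gc_i.min(initial=0.0), gc_j.min(initial=0.0))
    if worst < GC_NEG_TOL:
        k = int(np.argmin(np.minimum(gc_i, gc_j)))
        raise GCMatrixError(
            f"negative GC {worst:.3e} beyond tolerance for channel pair {pairs[k]}"
        )
    out[tgt[:, 0], tgt[:, 1]] = np.maximum(gc_i, 0.0)
    out[tgt[:, 1], tgt[:, 0]] = np.maximum(gc_j, 0.0)
    return out


def _find_bad_pair(g_full, pairs) -> str:
    for k, (i, j) in enumerate(pairs):
        if np.linalg.matrix_rank(g_full[k]) < g_full.shape[1]:
            return f"BVAR fit singular for channel pair ({i}, {j})"
    return "BVAR fit singular (pair not localised)"


# ---------------------------------------------------------------------------
# mutual information


def _bin_codes(x: np.ndarray, n_bins: int) -> np.ndarray:
    lo, hi = x.min(), x.max()
    if hi <= lo:
        return None  # degenerate (constant) series
    codes = np.floor((x - lo) * (n_bins / (hi - lo))).astype(np.intp)
    return np.minimum(codes, n_bins - 1)


def _mi_from_joint(joint: np.ndarray, base: float = 2.0) -> float:
    n = joint.sum()
    p_xy = joint / n
    # marginals from integer counts: exact, so mi is symmetric to the bit
    p_x = (joint.sum(axis=1) / n)[:, None]
    p_y = (joint.sum(axis=0) / n)[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p_xy * np.log(p_xy / (p_x * p_y))
    terms = terms[joint > 0]
    # summing in sorted order makes mi(x, y) and mi(y, x) bit-identical
    terms.sort()
    return float(terms.sum() / np.log(base))


def mutual_information(
    x, y, n_bins: int = DEFAULT_BINS, *, base: float = 2.0, warn: bool = True
) -> MIEstimate:
    """Plug-in histogram MI of two series, in bits by default.

    Equal-width bins over each series' observed range; zero-count cells
    contribute nothing.  A constant input makes MI trivially 0 (degenerate
    marginal) and emits a warning.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    if warn and x.size < 5 * n_bins**2:
        warnings.warn(
            f"{x.size} samples is few for {n_bins}^2 histogram cells; "
            "the plug-in MI will be biased upward",
            stacklevel=2,
        )
    bx = _bin_codes(x, n_bins)
    by = _bin_codes(y, n_bins)
    if bx is None or by is None:
        warnings.warn("constant input series; MI defined as 0", stacklevel=2)
        joint = np.zeros((n_bins, n_bins), dtype=np.intp)
        joint[0, 0] = x.size
        return MIEstimate(
            n_bins=n_bins,
            joint_hist=joint,
            marginal_x=joint.sum(axis=1),
            marginal_y=joint.sum(axis=0),
            mi=0.0,
        )
    joint = np.bincount(bx * n_bins + by, minlength=n_bins**2).reshape(n_bins, n_bins)
    return MIEstimate(
        n_bins=n_bins,
        joint_hist=joint,
        marginal_x=joint.sum(axis=1),
        marginal_y=joint.sum(axis=0),
        mi=_mi_from_joint(joint, base=base),
    )


def mi_vector(epoch: Epoch, n_bins: int = DEFAULT_BINS, *, base: float = 2.0) -> np.ndarray:
    """Strict-upper-triangle MI vector of one epoch (row-major pair order).

    For 32 channels the length is 32*31/2 = 496.
    """
    data = np.asarray(epoch.data, dtype=float)
    c, n = data.shape
    if n < 5 * n_bins**2:
        warnings.warn(
            f"{n} samples per epoch is few for {n_bins}^2 histogram cells",
            stacklevel=2,
        )
    codes = [_bin_codes(data[ch], n_bins) for ch in range(c)]
    out = np.empty(c * (c - 1) // 2)
    k = 0
    for i in range(c):
        for j in range(i + 1, c):
            if codes[i] is None or codes[j] is None:
                out[k] = 0.0
            else:
                joint = np.bincount(
                    codes[i] * n_bins + codes[j], minlength=n_bins**2
                ).reshape(n_bins, n_bins)
                out[k] = _mi_from_joint(joint, base=base)
            k += 1
    return out


# ---------------------------------------------------------------------------
# datasets


def connectivity_dataset(
    epochs,
    kind: str = "GC",
    *,
    order: int = DEFAULT_ORDER,
    n_bins: int = DEFAULT_BINS,
    max_skip_frac: float = 0.10,
) -> list:
    """Compute one feature record per epoch (GC 1024-vector or MI 496-vector).

    Epochs whose matrix computation fails are skipped with a log message;
    the call fails outright if more than ``max_skip_frac`` are skipped.
    """
    epochs = list(epochs)
    if not epochs:
        raise ValueError("empty epoch list")
    if kind not in ("GC", "MI"):
        raise ValueError(f"kind must be 'GC' or 'MI', got {kind!r}")
    records, skipped = [], 0
    for ep in epochs:
        try:
            if kind == "GC":
                values = gc_matrix(ep, order).ravel()  # row-major, diag 0
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    values = mi_vector(ep, n_bins)
        except (SingularFitError, GCMatrixError, ValueError) as exc:
            skipped += 1
            log.warning(
                "skipping epoch %s/%s #%d: %s",
                ep.subject_id, ep.session_id, ep.index, exc,
            )
            continue
        records.append(
            ConnectivityFeatures(
                kind=kind,
                values=values,
                subject_id=ep.subject_id,
                session_id=ep.session_id,
                epoch_index=ep.index,
            )
        )
    if skipped > max_skip_frac * len(epochs):
        raise GCMatrixError(
            f"{skipped}/{len(epochs)} epochs failed connectivity estimation"
        )
    return records


def features_to_matrix(features):
    """Stack feature records into (X, subject labels, session labels)."""
    features = list(features)
    if not features:
        raise ValueError("empty feature list")
    x = np.vstack([f.values for f in features])
    subjects = np.array([f.subject_id for f in features])
    sessions = np.array([f.session_id for f in features])
    return x, subjects, sessions


def features_to_frame(features) -> pd.DataFrame:
    """Feature records as a DataFrame: labels first, then feature columns."""
    x, subjects, sessions = features_to_matrix(features)
    df = pd.DataFrame(x, columns=[f"f{i}" for i in range(x.shape[1])])
    df.insert(0, "epoch_index", [f.epoch_index for f in features])
    df.insert(0, "session_id", sessions)
    df.insert(0, "subject_id", subjects)
    return df


def save_features_tsv(features, path) -> None:
    features_to_frame(features).to_csv(path, sep="\t", index=False)


def load_features_tsv(path, kind: str) -> list:
    df = pd.read_csv(path, sep="\t")
    feat_cols = [c for c in df.columns if c.startswith("f") and c[1:].isdigit()]
    return [
        ConnectivityFeatures(
            kind=kind,
            values=row[feat_cols].to_numpy(dtype=float),
            subject_id=str(row["subject_id"]),
            session_id=str(row["session_id"]),
            epoch_index=int(row["epoch_index"]),
        )
        for _, row in df.iterrows()
    ]
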