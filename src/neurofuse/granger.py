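"""Directed Granger causality between physiological time series.

A source series Y Granger-causes a target series X when adding Y's past
to an autoregression of X on its own past lowers the residual variance.
The strength is the log variance ratio

    F_{Y->X} = ln( Var(residual of restricted model) /
                   Var(residual of full model) )

with the restricted model X(t) = sum_i a_i X(t-i) + e(t) and the full
model adding sum_i b_i Y(t-i). Both models are ordinary least squares on
the identical effective sample (the first `order` samples are lost to
lagging), after per-series mean removal and with no intercept, so the
nesting guarantees F >= 0. Under the null of no coupling the statistic
n_effective * F is asymptotically chi-square with `order` degrees of
freedom (standard likelihood-ratio asymptotics for nested OLS).

Within-modality features are square channel-by-channel matrices per EEG
rhythm band; cross-modal features pair every fNIRS hemoglobin channel
with every EEG channel in both directions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import Recording

__all__ = [
    "ARFit",
    "GCValue",
    "GCMatrix",
    "DegenerateFitError",
    "fit_ar",
    "select_order",
    "gc_pair",
    "eeg_gc_matrix",
    "cross_modal_gc",
]


class DegenerateFitError(ValueError):
    """Raised when an AR fit has (numerically) zero residual variance."""


@dataclass
class ARFit:
    order: int
    coefficients: np.ndarray  # [n_predictors x order]
    residual_variance: float
    n_effective: int


@dataclass
class GCValue:
    f: float
    source: str
    target: str
    band: str | None
    order: int


@dataclass
class GCMatrix:
    """Directed channel-pair GC values; values[i, j] = F_{source i -> target j}."""

    values: np.ndarray
    direction: str  # "eeg->eeg", "fnirs->eeg", "eeg->fnirs"
    band: str | None = None
    chromophore: str | None = None
    source_labels: list[str] | None = None
    target_labels: list[str] | None = None
    order: int = 0


def _lag_matrix(x: np.ndarray, order: int) -> np.ndarray:
    """Columns are lags 1..order of x, aligned to targets x[order:]."""
    n = x.shape[0]
    return np.column_stack([x[order - i : n - i] for i in range(1, order + 1)])


def _as_series(x) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64).ravel()
    if not np.isfinite(x).all():
        raise ValueError("series contains non-finite values")
    return x


def fit_ar(target, predictors, order: int) -> ARFit:
    """OLS autoregression of `target` on lags 1..order of each predictor.

    Series are mean-removed first and no intercept is included. The
    residual variance uses the plain denominator n_effective = n - order.
    """
    target = _as_series(target)
    predictors = [_as_series(p) for p in predictors]
    n = target.shape[0]
    if any(p.shape[0] != n for p in predictors):
        raise ValueError("all series must have equal length")
    if order < 1:
        raise ValueError("order must be >= 1")
    k = len(predictors) * order
    if n - order <= k + 5:
        raise ValueError(
            f"insufficient samples: n={n}, order={order}, predictors={len(predictors)}"
        )
    target = target - target.mean()
    predictors = [p - p.mean() for p in predictors]
    y = target[order:]
    design = np.hstack([_lag_matrix(p, order) for p in predictors])
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < design.shape[1]:
        raise ValueError("rank-deficient lag design (collinear predictors)")
    resid = y - design @ coef
    n_eff = n - order
    rss = float(resid @ resid)
    tvar = max(float(target @ target) / n, 1e-30)
    degenerate = rss <= 1e-12 * tvar * n_eff
    if not degenerate and rss <= 1e-3 * tvar * n_eff:
        # a suspiciously good intercept-free fit may hide an exactly
        # deterministic recursion whose nonzero mean leaks into the
        # residual; re-check with an intercept column
        aug = np.column_stack([design, np.ones(y.shape[0])])
        coef_aug, _, _, _ = np.linalg.lstsq(aug, y, rcond=None)
        resid_aug = y - aug @ coef_aug
        degenerate = float(resid_aug @ resid_aug) <= 1e-12 * tvar * n_eff
    if degenerate:
        raise DegenerateFitError(
            "residual variance is numerically zero (deterministic input)"
        )
    return ARFit(
        order=order,
        coefficients=coef.reshape(len(predictors), order),
        residual_variance=rss / n_eff,
        n_effective=n_eff,
    )


def select_order(
    x, y, max_order: int = 20, criterion: str = "bic"
) -> int:
    """Pick the bivariate AR order by an information criterion.

    Fits the full model (x on lags of x and y) for orders 1..max_order on
    the common effective sample aligned to max_order, and returns the
    order minimising BIC (default) or AIC.
    """
    if max_order < 1:
        raise ValueError("max_order must be >= 1")
    criterion = criterion.lower()
    if criterion not in {"aic", "bic"}:
        raise ValueError("criterion must be 'aic' or 'bic'")
    x = _as_series(x)
    y = _as_series(y)
    n = x.shape[0]
    if n - max_order <= 2 * max_order + 5:
        raise ValueError("insufficient samples for max_order")
    x = x - x.mean()
    y = y - y.mean()
    t = x[max_order:]
    n_eff = t.shape[0]
    lx = _lag_matrix(x, max_order)  # aligned to t, columns lag 1..max
    ly = _lag_matrix(y, max_order)
    best_order, best_score = 1, np.inf
    for p in range(1, max_order + 1):
        design = np.hstack([lx[:, :p], ly[:, :p]])
        coef, _, _, _ = np.linalg.lstsq(design, t, rcond=None)
        resid = t - design @ coef
        sigma2 = max(float(resid @ resid) / n_eff, 1e-300)
        k = 2 * p
        if criterion == "bic":
            score = n_eff * np.log(sigma2) + k * np.log(n_eff)
        else:
            score = n_eff * np.log(sigma2) + 2 * k
        if score < best_score - 1e-12:
            best_score, best_order = score, p
    return best_order


def gc_pair(
    x,
    y,
    order: int,
    source: str = "y",
    target: str = "x",
    band: str | None = None,
) -> GCValue:
    """Granger causality F_{y -> x}: does y's past help predict x?

    The first argument is the target, the second the candidate source.
    Both nested fits use the identical effective sample, so F >= 0.
    """
    restricted = fit_ar(x, [x], order)
    full = fit_ar(x, [x, y], order)
    f = float(np.log(restricted.residual_variance / full.residual_variance))
    return GCValue(f=max(f, 0.0), source=source, target=target, band=band, order=order)


# ---------------------------------------------------------------------------
# batched matrix computation
#
# For matrices over many channel pairs the per-pair lstsq calls are
# replaced by shared Gram blocks: with L_c the [n_eff x order] lag block
# of channel c, every restricted/full fit only needs L_i^T L_j and
# L_i^T x_j, each computed once.
# ---------------------------------------------------------------------------


class _GramCache:
    """Shared lag blocks, Gram blocks and restricted-fit residuals.

    data is [channels x n], already mean-removed per channel. Residual
    sums of squares are always evaluated from explicit residual series
    (never as tss - b'coef), which stays accurate even for strongly
    autocorrelated band-limited signals where the Gram matrix is
    ill-conditioned.
    """

    def __init__(self, data: np.ndarray, order: int):
        c, n = data.shape
        self.order = order
        self.n_eff = n - order
        self.lags = np.stack(
            [_lag_matrix(data[i], order) for i in range(c)]
        )  # [c, n_eff, p]
        self.targets = data[:, order:]  # [c, n_eff]
        self.gram = np.einsum("iak,jal->ijkl", self.lags, self.lags, optimize=True)
        self.cross = np.einsum("iak,ja->ijk", self.lags, self.targets, optimize=True)
        self.tvar_floor = np.maximum((data**2).mean(axis=1), 1e-30)
        # restricted fits (each channel on its own past) are cached on
        # first use, so a degenerate channel only errors when targeted
        self._rss_restricted: dict[int, float] = {}

    def rss_restricted(self, j: int) -> float:
        if j not in self._rss_restricted:
            coef = self._solve(self.gram[j, j], self.cross[j, j], j, j)
            resid = self.targets[j] - self.lags[j] @ coef
            rss = float(resid @ resid)
            self._check(rss, j)
            self._rss_restricted[j] = rss
        return self._rss_restricted[j]

    def _solve(self, a: np.ndarray, b: np.ndarray, i: int, j: int) -> np.ndarray:
        try:
            return np.linalg.solve(a, b)
        except np.linalg.LinAlgError:
            coef, _, _, _ = np.linalg.lstsq(a, b, rcond=None)
            return coef

    def _check(self, rss: float, j: int) -> None:
        # floor catches constant/deterministic channels; band-limited
        # oversampled series legitimately reach ~1e-12 relative residual
        if rss <= 1e-15 * self.tvar_floor[j] * self.n_eff:
            raise DegenerateFitError(
                "residual variance numerically zero while building GC matrix"
            )

    def pair_f(self, i: int, j: int) -> float:
        """F_{channel i -> channel j} on the shared effective sample."""
        p = self.order
        a = np.empty((2 * p, 2 * p))
        a[:p, :p] = self.gram[j, j]
        a[:p, p:] = self.gram[j, i]
        a[p:, :p] = self.gram[i, j]
        a[p:, p:] = self.gram[i, i]
        b = np.concatenate([self.cross[j, j], self.cross[i, j]])
        coef = self._solve(a, b, i, j)
        resid = self.targets[j] - self.lags[j] @ coef[:p] - self.lags[i] @ coef[p:]
        rss_f = float(resid @ resid)
        self._check(rss_f, j)
        return max(float(np.log(self.rss_restricted(j) / rss_f)), 0.0)


def _resolve_order(data_pairs, order_policy, max_order: int, seed: int) -> int:
    """A single shared order for a matrix, per the order policy.

    An integer policy is used directly; "bic"/"aic" select per-pair orders
    on up to 20 randomly sampled pairs and share the rounded mean, keeping
    matrix entries comparable across pairs.
    """
    if isinstance(order_policy, (int, np.integer)):
        if order_policy < 1:
            raise ValueError("fixed order must be >= 1")
        return int(order_policy)
    if order_policy not in {"bic", "aic"}:
        raise ValueError("order_policy must be an int, 'bic' or 'aic'")
    rng = np.random.default_rng(seed)
    n_pairs = len(data_pairs)
    idx = rng.choice(n_pairs, size=min(20, n_pairs), replace=False)
    orders = [
        select_order(data_pairs[i][0], data_pairs[i][1], max_order, order_policy)
        for i in idx
    ]
    return max(1, int(round(float(np.mean(orders)))))


def eeg_gc_matrix(
    band_signals: dict[str, Recording],
    order_policy="bic",
    max_order: int = 8,
    seed: int = 0,
) -> dict[str, GCMatrix]:
    """Within-EEG GC matrix per rhythm band.

    Entry (i, j) holds F_{channel i -> channel j}; the diagonal is zero.
    The AR order is shared across all pairs of a band (fixed integer, or
    criterion-selected on a subsample of pairs).
    """
    out: dict[str, GCMatrix] = {}
    for band, rec in band_signals.items():
        data = rec.data - rec.data.mean(axis=1, keepdims=True)
        c = data.shape[0]
        pairs = [
            (data[j], data[i]) for i in range(c) for j in range(c) if i != j
        ]
        order = _resolve_order(pairs, order_policy, max_order, seed)
        cache = _GramCache(data, order)
        values = np.zeros((c, c))
        for i in range(c):
            for j in range(c):
                if i != j:
                    values[i, j] = cache.pair_f(i, j)
        out[band] = GCMatrix(
            values=values,
            direction="eeg->eeg",
            band=band,
            source_labels=list(rec.channel_labels),
            target_labels=list(rec.channel_labels),
            order=order,
        )
    return out


def cross_modal_gc(
    eeg_band: Recording,
    fnirs: Recording,
    order_policy="bic",
    max_order: int = 8,
    seed: int = 0,
    band: str | None = None,
    chromophore: str | None = None,
    directions: tuple[str, ...] = ("fnirs->eeg", "eeg->fnirs"),
) -> tuple[GCMatrix | None, GCMatrix | None]:
    """Directed GC between every fNIRS channel and every EEG channel.

    Returns (G_fnirs->eeg, G_eeg->fnirs). The first matrix is
    [n_fnirs x n_eeg] with entry (f, z) = F_{fnirs f -> eeg z}; the
    second is its reverse-direction analogue, [n_eeg x n_fnirs]. Both
    modalities must already share the 200 Hz rate and duration.

    `directions` restricts computation to one direction (the other slot
    returns None); useful when the hemodynamic series is so heavily
    oversampled after upsampling that using it as a prediction target
    is numerically degenerate.
    """
    if eeg_band.fs != fnirs.fs:
        raise ValueError(
            f"rate mismatch: EEG at {eeg_band.fs} Hz, fNIRS at {fnirs.fs} Hz "
            "(upsample fNIRS first)"
        )
    if eeg_band.n_samples != fnirs.n_samples:
        raise ValueError("EEG and fNIRS must share duration")
    e = eeg_band.data - eeg_band.data.mean(axis=1, keepdims=True)
    f = fnirs.data - fnirs.data.mean(axis=1, keepdims=True)
    ne, nf = e.shape[0], f.shape[0]
    stacked = np.vstack([e, f])  # channels 0..ne-1 EEG, ne..ne+nf-1 fNIRS
    pairs = [(e[z], f[k]) for z in range(ne) for k in range(nf)]
    known = {"fnirs->eeg", "eeg->fnirs"}
    if not set(directions) <= known or not directions:
        raise ValueError(f"directions must be a non-empty subset of {known}")
    order = _resolve_order(pairs, order_policy, max_order, seed)
    cache = _GramCache(stacked, order)
    meta = dict(band=band, chromophore=chromophore, order=order)
    mat_f2e = mat_e2f = None
    if "fnirs->eeg" in directions:
        f_to_e = np.zeros((nf, ne))
        for k in range(nf):
            for z in range(ne):
                f_to_e[k, z] = cache.pair_f(ne + k, z)
        mat_f2e = GCMatrix(
            values=f_to_e,
            direction="fnirs->eeg",
            source_labels=list(fnirs.channel_labels),
            target_labels=list(eeg_band.channel_labels),
            **meta,
        )
    if "eeg->fnirs" in directions:
        e_to_f = np.zeros((ne, nf))
        for k in range(nf):
            for z in range(ne):
                e_to_f[z, k] = cache.pair_f(z, ne + k)
        mat_e2f = GCMatrix(
            values=e_to_f,
            direction="eeg->fnirs",
            source_labels=list(eeg_band.channel_labels),
            target_labels=list(fnirs.channel_labels),
            **meta,
        )
    return mat_f2e, mat_e2f
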