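"""Entropy estimators for short EEG windows and feature-table assembly.

Four regularity/complexity statistics are computed per single-channel
window of length ``L``:

* spectral entropy (``PE``) — Shannon entropy of the normalized
  periodogram power distribution;
* approximate entropy (``AE``) — difference of log template-match
  frequencies at embedding dimensions ``m`` and ``m+1``, self-matches
  included;
* sample entropy (``SE``) — negative log of the ratio of match
  frequencies at ``m+1`` vs ``m``, self-matches excluded;
* fuzzy entropy (``FE``) — sample-entropy variant replacing the hard
  match indicator with the fuzzy membership ``exp(-d^n / s)`` evaluated
  on baseline-centered templates.

Template similarity uses the Chebyshev (max-coordinate) distance with
tolerance ``s = s_coef * SD(x)`` computed per window, which makes the
hard-threshold estimators (AE, SE) invariant to amplitude rescaling of
the window.  Fuzzy entropy is invariant to additive offsets through
the per-template baseline subtraction, but its membership
``exp(-d^n / s)`` couples ``d^n`` to a tolerance linear in the SD, so
for ``n != 1`` it is *not* exactly scale-invariant — a property of the
canonical formulation, not an implementation artifact.  Natural
logarithms throughout.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import periodogram
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .recording import Epoch

__all__ = [
    "EntropyParams",
    "FEATURE_ORDER",
    "embed",
    "chebyshev_distance",
    "spectral_entropy",
    "approximate_entropy",
    "sample_entropy",
    "fuzzy_entropy",
    "extract_features",
    "scale_features",
    "EntropyFeaturizer",
]

logger = logging.getLogger(__name__)

#: Column order of the combined feature set.
FEATURE_ORDER = ("FE", "SE", "AE", "PE")

METADATA_COLUMNS = ("subject", "channel", "epoch_index", "state")


@dataclass(frozen=True)
class EntropyParams:
    """Shared estimator parameters.

    m : embedding dimension (template length), default 2.
    s_coef : tolerance as a fraction of the window SD, default 0.2.
    n : gradient (exponent) of the fuzzy membership function, default 4.
    """

    m: int = 2
    s_coef: float = 0.2
    n: float = 4.0

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("embedding dimension m must be >= 1")
        if self.s_coef <= 0:
            raise ValueError("tolerance coefficient s_coef must be positive")
        if self.n <= 0:
            raise ValueError("fuzzy gradient n must be positive")


def embed(x: np.ndarray, m: int, center: bool = False) -> np.ndarray:
    """Phase-space embedding: the ``L - m + 1`` overlapping ``m``-length templates.

    With ``center=True`` each template has its own mean subtracted
    (the fuzzy-entropy baseline removal).
    """
    x = np.asarray(x, dtype=float)
    L = x.shape[0]
    if L < m:
        raise ValueError(f"sequence of length {L} too short for embedding m={m}")
    idx = np.arange(L - m + 1)[:, None] + np.arange(m)[None, :]
    T = x[idx]
    if center:
        T = T - T.mean(axis=1, keepdims=True)
    return T


def chebyshev_distance(a: Sequence[float], b: Sequence[float]) -> float:
    """Maximum absolute coordinate difference between two equal-length vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"dimension mismatch: {a.shape} vs {b.shape}")
    return float(np.max(np.abs(a - b)))


def spectral_entropy(
    x: np.ndarray, params: EntropyParams | None = None, normalize: bool = False
) -> float:
    """Shannon entropy of the normalized periodogram of a window.

    The window mean is removed, the power spectrum is estimated by a
    plain (rectangular-window) periodogram, powers are normalized to a
    probability distribution ``y_i``, and ``PE = sum y_i ln(1/y_i)``
    with zero-power bins contributing nothing.  A constant window (zero
    AC power) returns 0.  With ``normalize=True`` the value is divided
    by ``ln(n_bins)`` to land in [0, 1].
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples for a spectrum")
    if np.ptp(x) == 0:
        return 0.0  # zero AC power
    _, power = periodogram(x, detrend="constant", window="boxcar")
    total = power.sum()
    if total <= 0 or not np.isfinite(total):
        return 0.0
    y = power / total
    y = y[y > 0]
    pe = float(-(y * np.log(y)).sum())
    if normalize:
        pe /= np.log(power.size)
    return pe


def _tolerance(x: np.ndarray, params: EntropyParams) -> float:
    return params.s_coef * float(np.std(x))


def approximate_entropy(
    x: np.ndarray, params: EntropyParams | None = None, exclude_self: bool = False
) -> float:
    """Approximate entropy (ApEn) of a window.

    For each order ``k`` in ``{m, m+1}`` the fraction ``C_i`` of
    templates within Chebyshev tolerance ``s`` of template ``i`` is
    computed over all ``L - k + 1`` templates, self-match included (so
    ``C_i >= 1/(L-k+1)`` and the log is always defined); ``phi_k`` is
    the mean of ``ln C_i`` and ``ApEn = phi_m - phi_{m+1}``.

    ``exclude_self=True`` drops the self-match from the counts (a
    stricter reading under which ``ln 0`` can occur; the result is then
    ``inf``/``nan`` and the window should be discarded).
    """
    params = params or EntropyParams()
    x = np.asarray(x, dtype=float)
    L = x.shape[0]
    if L < params.m + 2:
        raise ValueError(f"window of length {L} too short for m={params.m}")
    s = _tolerance(x, params)
    if s == 0:
        return 0.0

    def phi(k: int) -> float:
        T = embed(x, k)
        d = cdist(T, T, metric="chebyshev")
        counts = (d <= s).sum(axis=1).astype(float)
        if exclude_self:
            counts -= 1.0
        n_templates = T.shape[0]
        with np.errstate(divide="ignore"):
            return float(np.mean(np.log(counts / n_templates)))

    return phi(params.m) - phi(params.m + 1)


def sample_entropy(x: np.ndarray, params: EntropyParams | None = None) -> float:
    """Sample entropy (SampEn) of a window.

    Match frequencies exclude the self-match: over the ``L - m``
    templates common to both orders, ``B`` is the mean fraction of
    other templates within tolerance at length ``m`` and ``A`` the same
    at length ``m + 1`` (each fraction normalized by the ``L - m - 1``
    candidate matches).  ``SampEn = ln(B / A)``, non-negative whenever
    defined.  Returns ``nan`` (an undefined-entropy sentinel, for
    exclusion upstream) when no matches survive at length ``m + 1``.
    """
    params = params or EntropyParams()
    x = np.asarray(x, dtype=float)
    L = x.shape[0]
    m = params.m
    if L < m + 2:
        raise ValueError(f"window of length {L} too short for m={m}")
    s = _tolerance(x, params)
    if s == 0:
        return 0.0

    def match_rate(k: int) -> float:
        # templates restricted to the L - m common to both orders
        T = embed(x, k)[: L - m]
        d = cdist(T, T, metric="chebyshev")
        counts = (d <= s).sum(axis=1).astype(float) - 1.0  # drop self
        return float(np.mean(counts / (L - m - 1)))

    B = match_rate(m)
    A = match_rate(m + 1)
    if A == 0 or B == 0:
        return float("nan")
    return float(np.log(B / A))


def fuzzy_entropy(x: np.ndarray, params: EntropyParams | None = None) -> float:
    """Fuzzy entropy (FuzzyEn) of a window.

    Templates are baseline-centered; pairwise Chebyshev distances are
    mapped through the fuzzy membership ``D_ij = exp(-d_ij^n / s)``;
    ``gamma_k`` is the double average of ``D_ij`` over the ``L - m``
    templates and their ``L - m - 1`` partners (``j != i``), and
    ``FuzzyEn = ln gamma_m - ln gamma_{m+1}``.  Always finite since
    ``D_ij > 0`` everywhere.
    """
    params = params or EntropyParams()
    x = np.asarray(x, dtype=float)
    L = x.shape[0]
    m = params.m
    if L < m + 2:
        raise ValueError(f"window of length {L} too short for m={m}")
    s = _tolerance(x, params)
    if s == 0:
        return 0.0

    def gamma(k: int) -> float:
        T = embed(x, k, center=True)[: L - m]
        d = cdist(T, T, metric="chebyshev")
        D = np.exp(-(d**params.n) / s)
        np.fill_diagonal(D, 0.0)
        return float(D.sum() / (T.shape[0] * (T.shape[0] - 1)))

    return float(np.log(gamma(m)) - np.log(gamma(m + 1)))


_ESTIMATORS = {
    "FE": fuzzy_entropy,
    "SE": sample_entropy,
    "AE": approximate_entropy,
    "PE": spectral_entropy,
}


def _resolve_feature_set(feature_set: str) -> tuple[str, ...]:
    if feature_set == "combined":
        return FEATURE_ORDER
    if feature_set in _ESTIMATORS:
        return (feature_set,)
    raise ValueError(
        f"unknown feature_set {feature_set!r}; expected one of "
        f"{sorted(_ESTIMATORS)} or 'combined'"
    )


def extract_features(
    epochs: Sequence[Epoch],
    feature_set: str = "FE",
    params: EntropyParams | None = None,
) -> pd.DataFrame:
    """Compute the requested entropy features for every unit.

    Returns a table with metadata columns ``subject, channel,
    epoch_index, state`` followed by the feature columns (ordered
    ``FE, SE, AE, PE`` for the combined set).  Units with an undefined
    sample entropy (no template matches) are excluded; their count is
    logged and stored in ``table.attrs["n_excluded"]``.
    """
    if len(epochs) == 0:
        raise ValueError("empty epoch list")
    params = params or EntropyParams()
    columns = _resolve_feature_set(feature_set)
    lengths = {len(ep.values) for ep in epochs}
    if len(lengths) != 1:
        raise ValueError(f"epochs have inconsistent lengths {sorted(lengths)}")

    records = []
    for ep in epochs:
        row: dict[str, object] = {
            "subject": ep.subject_id,
            "channel": ep.channel,
            "epoch_index": ep.epoch_index,
            "state": ep.state,
        }
        for name in columns:
            row[name] = _ESTIMATORS[name](ep.values, params)
        records.append(row)
    table = pd.DataFrame.from_records(records)

    feature_cols = list(columns)
    defined = table[feature_cols].notna().all(axis=1)
    n_excluded = int((~defined).sum())
    if n_excluded:
        logger.info("excluding %d units with undefined entropy", n_excluded)
        table = table.loc[defined].reset_index(drop=True)
    table.attrs["n_excluded"] = n_excluded
    table.attrs["feature_columns"] = feature_cols
    table.attrs["normalization_state"] = "raw"
    return table


def feature_columns(table: pd.DataFrame) -> list[str]:
    """Feature columns of a table (everything that is not metadata)."""
    return [c for c in table.columns if c not in METADATA_COLUMNS]


def scale_features(
    table: pd.DataFrame,
    mode: str = "per_subject_channel_global",
    train_mask: np.ndarray | None = None,
    clip: bool = True,
) -> pd.DataFrame:
    """Min-max scale every feature column to [-1, 1] within each
    ``(subject, channel)`` group.

    ``mode="per_subject_channel_global"`` fits the group minima/maxima
    on all units (the conventional whole-dataset normalization);
    ``mode="train_only"`` fits them on the units flagged by
    ``train_mask`` and applies the map to everything, optionally
    clipping test values that fall outside [-1, 1].  A constant group
    maps to 0 with a warning.
    """
    if mode not in ("per_subject_channel_global", "train_only"):
        raise ValueError(f"unknown scaling mode {mode!r}")
    if mode == "train_only":
        if train_mask is None:
            raise ValueError("train_only mode requires train_mask")
        train_mask = np.asarray(train_mask, dtype=bool)
        if train_mask.shape[0] != len(table):
            raise ValueError("train_mask length must match table")
    out = table.copy()
    cols = feature_columns(table)
    degenerate = 0
    for _, idx in table.groupby(["subject", "channel"], sort=False).groups.items():
        idx = np.asarray(idx)
        fit_idx = idx
        if mode == "train_only":
            fit_idx = idx[train_mask[idx]]
            if fit_idx.size == 0:
                raise ValueError("a (subject, channel) group has no training units")
        for col in cols:
            vals = table[col].to_numpy()
            lo, hi = vals[fit_idx].min(), vals[fit_idx].max()
            if hi == lo:
                out.loc[idx, col] = 0.0
                degenerate += 1
                continue
            scaled = 2.0 * (vals[idx] - lo) / (hi - lo) - 1.0
            if clip:
                scaled = np.clip(scaled, -1.0, 1.0)
            out.loc[idx, col] = scaled
    if degenerate:
        warnings.warn(
            f"{degenerate} constant (subject, channel, feature) groups mapped to 0",
            stacklevel=2,
        )
    out.attrs = dict(table.attrs)
    out.attrs["normalization_state"] = "scaled"
    return out


class EntropyFeaturizer(TransformerMixin, BaseEstimator):
    """Transformer mapping a matrix of windows to entropy features.

    Rows of ``X`` are fixed-length single-channel windows; the
    transform emits one column per estimator in the chosen feature set
    (``FE``, ``SE``, ``AE``, ``PE`` or ``combined``).  Stateless apart
    from input-shape validation, so it composes with scikit-learn
    pipelines and cross-validation without leakage.

    Parameters
    ----------
    feature_set : str, default "combined"
    m : int, default 2
        Embedding dimension.
    s_coef : float, default 0.2
        Tolerance as a fraction of each window's SD.
    n : float, default 4.0
        Fuzzy membership exponent.
    """

    def __init__(
        self,
        feature_set: str = "combined",
        m: int = 2,
        s_coef: float = 0.2,
        n: float = 4.0,
    ) -> None:
        self.feature_set = feature_set
        self.m = m
        self.s_coef = s_coef
        self.n = n

    def fit(self, X, y=None):
        X = check_array(X, ensure_min_features=self.m + 2)
        self.n_features_in_ = X.shape[1]
        self.feature_names_out_ = list(_resolve_feature_set(self.feature_set))
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "n_features_in_")
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} samples per window, expected {self.n_features_in_}"
            )
        params = EntropyParams(m=self.m, s_coef=self.s_coef, n=self.n)
        names = self.feature_names_out_
        out = np.empty((X.shape[0], len(names)), dtype=float)
        for i, row in enumerate(X):
            for j, name in enumerate(names):
                out[i, j] = _ESTIMATORS[name](row, params)
        return out

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "feature_names_out_")
        return np.asarray(self.feature_names_out_, dtype=object)
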