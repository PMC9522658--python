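"""Model-free SVD decomposition of line-scan waveforms.

The space x time waveform ``A`` (m position bins x n time points) is
factorized as ``A = U S V^T``.  Columns of ``U`` are spatial base vectors,
columns of ``V`` the matching kinetic time courses, and the singular values
order components by their contribution to the total signal.  Structured
(signal-carrying) components have smooth singular vectors, so the number of
relevant base vectors is selected by scanning components in order of
decreasing singular value and retaining those whose amplitude share is above
a noise floor *and* whose spatial and temporal vectors are both smooth by
lag-1 autocorrelation; scanning stops at the first rejection, so the retained
components are always the leading ones.  Zeroing the remaining singular
values yields a denoised reconstruction.

Because an SVD determines each (u_i, v_i) pair only up to a joint sign, each
pair is flipped so the largest-magnitude element of u_i is positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import WaveformMatrix

__all__ = [
    "SVDResult", "ComponentReadout", "decompose", "lag1_autocorrelation",
    "select_rank", "reconstruct", "component_readouts", "match_components",
    "compartment_energies",
    "DEFAULT_AC_MIN", "DEFAULT_SV_FRAC_MIN", "RECONSTRUCTION_RTOL",
]

DEFAULT_AC_MIN = 0.5        # minimum lag-1 autocorrelation of U and V columns
DEFAULT_SV_FRAC_MIN = 0.01  # minimum share of the total singular-value sum
RECONSTRUCTION_RTOL = 1e-8  # relative Frobenius tolerance for SVD identities


@dataclass
class SVDResult:
    """Factorization of a waveform plus rank-selection diagnostics.

    ``U`` is m x m, ``V`` is n x n (columns are right singular vectors),
    ``S`` holds the min(m, n) singular values in non-increasing order.
    ``diagnostics`` has one row per component: singular value, amplitude
    share, lag-1 autocorrelations of the U and V columns, retained flag.
    """

    U: np.ndarray
    S: np.ndarray
    V: np.ndarray
    matrix: np.ndarray
    times: np.ndarray
    position_bins: np.ndarray
    selected_rank: int = 0
    diagnostics: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape


def decompose(waveform: WaveformMatrix | np.ndarray) -> SVDResult:
    """Full SVD of a waveform with the sign convention applied.

    Deterministic for fixed input; raises on non-finite entries.
    """
    if isinstance(waveform, WaveformMatrix):
        A = waveform.values
        times, bins = waveform.times, waveform.position_bins
    else:
        A = np.asarray(waveform, dtype=float)
        times = np.arange(A.shape[1], dtype=float)
        bins = np.arange(A.shape[0], dtype=float)
    if A.size == 0:
        raise ValueError("empty matrix")
    if not np.all(np.isfinite(A)):
        raise ValueError("matrix contains non-finite entries")
    U, S, Vt = np.linalg.svd(A, full_matrices=True)
    V = Vt.T
    for i in range(S.size):  # sign convention: dominant element of u_i positive
        j = int(np.argmax(np.abs(U[:, i])))
        if U[j, i] < 0:
            U[:, i] = -U[:, i]
            V[:, i] = -V[:, i]
    return SVDResult(U=U, S=S, V=V, matrix=A, times=times, position_bins=bins)


def lag1_autocorrelation(vector: np.ndarray) -> float:
    """Centered, biased lag-1 autocorrelation.

    ``sum_t (x_t - xbar)(x_{t+1} - xbar) / sum_t (x_t - xbar)^2``; in [-1, 1].
    Smooth structured vectors score near 1, white noise near 0.
    """
    x = np.asarray(vector, dtype=float)
    if x.size < 3:
        raise ValueError("autocorrelation needs at least 3 samples")
    d = x - x.mean()
    denom = float(np.dot(d, d))
    if denom == 0:
        raise ValueError("zero-variance vector (degenerate component)")
    return float(np.dot(d[:-1], d[1:]) / denom)


def _component_diagnostics(result: SVDResult, ac_min: float,
                           sv_frac_min: float) -> pd.DataFrame:
    total = float(result.S.sum())
    rows = []
    for i in range(result.S.size):
        share = result.S[i] / total if total > 0 else 0.0
        try:
            ac_u = lag1_autocorrelation(result.U[:, i])
            ac_v = lag1_autocorrelation(result.V[:, i])
        except ValueError:
            ac_u = ac_v = np.nan
        passes = (share >= sv_frac_min
                  and np.isfinite(ac_u) and ac_u >= ac_min
                  and np.isfinite(ac_v) and ac_v >= ac_min)
        rows.append((i, float(result.S[i]), float(share), float(ac_u),
                     float(ac_v), bool(passes)))
    return pd.DataFrame(rows, columns=["component", "singular_value",
                                       "amplitude_share", "autocorr_U",
                                       "autocorr_V", "passes"])


def select_rank(result: SVDResult, sv_frac_min: float = DEFAULT_SV_FRAC_MIN,
                ac_min: float = DEFAULT_AC_MIN) -> int:
    """Select the number of relevant base vectors.

    Components are scanned in order of decreasing singular value; component i
    is retained iff its singular-value amplitude share is >= ``sv_frac_min``
    and the lag-1 autocorrelations of both its U and V columns are >=
    ``ac_min``.  Scanning stops at the first rejected component, so retained
    components are contiguous and leading.  Updates ``result.selected_rank``
    and ``result.diagnostics`` in place; returns the rank.
    """
    diag = _component_diagnostics(result, ac_min, sv_frac_min)
    k = 0
    for passes in diag["passes"]:
        if not passes:
            break
        k += 1
    diag["retained"] = diag["component"] < k
    result.diagnostics = diag.drop(columns="passes")
    result.selected_rank = k
    return k


def reconstruct(result: SVDResult, k: int | None = None) -> np.ndarray:
    """Rank-``k`` reconstruction: singular values beyond ``k`` zeroed.

    With ``k = min(m, n)`` this reproduces the input to machine precision;
    by Eckart-Young the Frobenius error equals ``sqrt(sum_{i>k} S_i^2)``.
    """
    if k is None:
        k = result.selected_rank
    r = result.S.size
    if not 0 <= k <= r:
        raise ValueError(f"rank {k} out of range [0, {r}]")
    if k == 0:
        return np.zeros_like(result.matrix)
    return (result.U[:, :k] * result.S[:k]) @ result.V[:, :k].T


@dataclass
class ComponentReadout:
    """One retained base vector: spatial shape and singular-value-weighted kinetics."""

    component: int
    singular_value: float
    spatial_shape: np.ndarray     # U column (sign-fixed), unit norm
    kinetic_amplitude: np.ndarray  # S_i * V column: contribution over time


def component_readouts(result: SVDResult) -> list[ComponentReadout]:
    """Per-retained-component spatial shape and kinetic amplitude.

    The sum over retained components of the outer product
    ``spatial_shape x kinetic_amplitude`` equals the rank-k reconstruction.
    An empty list is returned when no components are retained.
    """
    return [
        ComponentReadout(i, float(result.S[i]), result.U[:, i].copy(),
                         result.S[i] * result.V[:, i])
        for i in range(result.selected_rank)
    ]


def _abs_corr(a: np.ndarray, b: np.ndarray) -> float:
    da, db = a - a.mean(), b - b.mean()
    na, nb = np.sqrt((da ** 2).sum()), np.sqrt((db ** 2).sum())
    if na == 0 or nb == 0:
        return 0.0
    return float(abs(np.dot(da, db)) / (na * nb))


def match_components(result: SVDResult,
                     reference_profiles: dict[str, np.ndarray]
                     ) -> dict[str, tuple[int, float]]:
    """Greedily match retained components to reference spatial profiles.

    Pairs are assigned in order of decreasing absolute Pearson correlation
    between the (mean-removed) U column and reference profile; each component
    and each reference is used at most once.  References left unmatched when
    fewer components are retained than references are absent from the result.

    Returns ``{reference_name: (component_index, |correlation|)}``.
    """
    pairs = []
    for i in range(result.selected_rank):
        for name, prof in reference_profiles.items():
            pairs.append((_abs_corr(result.U[:, i], np.asarray(prof, float)),
                          i, name))
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_i: set[int] = set()
    used_n: set[str] = set()
    out: dict[str, tuple[int, float]] = {}
    for corr, i, name in pairs:
        if i in used_i or name in used_n:
            continue
        out[name] = (i, corr)
        used_i.add(i)
        used_n.add(name)
    return out


def compartment_energies(result: SVDResult,
                         reference_profiles: dict[str, np.ndarray]
                         ) -> dict[str, float]:
    """Squared-singular-value energy of the component matched to each reference.

    References with no matched retained component get energy 0 — e.g. a
    perturbation that abolishes a compartment's contribution.
    """
    matches = match_components(result, reference_profiles)
    return {name: float(result.S[matches[name][0]] ** 2) if name in matches
            else 0.0 for name in reference_profiles}
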