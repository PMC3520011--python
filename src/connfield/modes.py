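"""Eigenmode extraction and characterisation.

Because the linearised drift is J = h·Δ·κ − τ·I, the eigenvectors of the
anatomical connectivity κ are exactly the modes of the resting dynamics
and each dynamical eigenvalue λ_l carries a decay time constant
τ_l = −1/Re λ_l.  This module extracts the modes (slowest-decaying first),
verifies the Rayleigh-quotient identity for symmetric operators, and
quantifies how periodic (dominant DFT wavenumber, spectral concentration)
or localised (inverse participation ratio) each mode is — the diagnostics
that distinguish translationally invariant connectivity, which supports a
full spectrum of damped spatially periodic modes, from heterogeneous
connectivity, whose dominant modes localise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .fixtures import ConnectivityMatrix, InvalidParameterError
from .dynamics import DegenerateInputError

__all__ = [
    "ModeSet",
    "anatomical_modes",
    "time_constants",
    "rayleigh_check",
    "mode_similarity",
    "localization_index",
    "dominant_wavenumber",
    "phase_lags",
]


class NotOscillatoryError(ValueError):
    """Requested phase structure of a purely real (non-oscillatory) mode."""


@dataclass(frozen=True)
class ModeSet:
    """Eigen-decomposition of κ or of the Jacobian.

    eigenvalues are sorted by descending real part (slowest-decaying
    first) with conjugate pairs adjacent; mode columns are unit 2-norm and
    phase-fixed so the largest-magnitude entry of each is positive real.
    ``defective`` flags inputs that are not diagonalisable to tolerance.
    """

    eigenvalues: np.ndarray
    modes: np.ndarray  # (N, N) complex; column l pairs with eigenvalues[l]
    source: Literal["connectivity", "jacobian"] = "connectivity"
    defective: bool = False

    @property
    def n_modes(self) -> int:
        return self.eigenvalues.shape[0]


def _phase_fix(vecs: np.ndarray) -> np.ndarray:
    """Rotate each column so its largest-|·| entry is positive real; ties
    break to the lowest index."""
    out = vecs.copy()
    for l in range(out.shape[1]):
        v = out[:, l]
        nrm = np.linalg.norm(v)
        if nrm == 0:
            continue
        v = v / nrm
        mags = np.abs(v)
        pivot = int(np.argmax(mags > mags.max() - 1e-12))
        piv = v[pivot]
        if abs(piv) > 0:
            v = v * (np.conj(piv) / abs(piv))
        v[pivot] = abs(v[pivot])  # kill residual imaginary round-off at pivot
        out[:, l] = v
    return out


def anatomical_modes(
    matrix: ConnectivityMatrix | np.ndarray,
    source: Literal["connectivity", "jacobian"] = "connectivity",
) -> ModeSet:
    """Full eigendecomposition of a connectivity matrix or Jacobian.

    Symmetric inputs go through the Hermitian solver so their modes are
    orthonormal and exactly real; general inputs keep complex conjugate
    pairs adjacent in the descending-real-part ordering.
    """
    w = matrix.weights if isinstance(matrix, ConnectivityMatrix) else np.asarray(matrix)
    if w.ndim != 2 or w.shape[0] != w.shape[1] or not np.all(np.isfinite(w)):
        raise InvalidParameterError("need a square finite matrix")
    symmetric = np.allclose(w, w.T, atol=1e-12 * max(1.0, np.abs(w).max()))
    if symmetric:
        vals, vecs = np.linalg.eigh((w + w.T) / 2.0)
        vals = vals[::-1].astype(complex)
        vecs = vecs[:, ::-1].astype(complex)
        defective = False
    else:
        vals, vecs = np.linalg.eig(w)
        # descending real part; conjugate pairs adjacent (larger |Im| first
        # within equal real parts, +Im before −Im within a pair)
        order = np.lexsort((-vals.imag, -np.abs(vals.imag), -vals.real))
        vals, vecs = vals[order], vecs[:, order]
        try:
            cond = np.linalg.cond(vecs)
        except np.linalg.LinAlgError:  # pragma: no cover
            cond = np.inf
        defective = not np.isfinite(cond) or cond > 1e12
    return ModeSet(
        eigenvalues=vals, modes=_phase_fix(vecs), source=source, defective=defective
    )


def time_constants(modeset: ModeSet) -> np.ndarray:
    """Decay time constants τ_l = −1/Re λ_l of dynamical eigenvalues; modes
    with Re λ ≥ 0 do not decay and are flagged with τ_l = +inf."""
    re = modeset.eigenvalues.real
    out = np.full(re.shape, np.inf)
    decaying = re < 0
    out[decaying] = -1.0 / re[decaying]
    return out


def oscillation_frequencies(modeset: ModeSet) -> np.ndarray:
    """|Im λ_l| in rad/s — the oscillation frequency of complex modes."""
    return np.abs(modeset.eigenvalues.imag)


def rayleigh_check(modeset: ModeSet, jacobian: np.ndarray) -> np.ndarray:
    """Per-mode residual |V_lᵀ J V_l − λ_l| of the Rayleigh identity.

    The identity is claimed only for symmetric operators; non-symmetric
    input returns NaNs with a notice (no failure).
    """
    j = np.asarray(jacobian, dtype=float)
    if not np.allclose(j, j.T, atol=1e-12 * max(1.0, np.abs(j).max())):
        import warnings

        warnings.warn(
            "Rayleigh identity only holds for symmetric operators; skipped",
            stacklevel=2,
        )
        return np.full(modeset.n_modes, np.nan)
    res = np.empty(modeset.n_modes)
    for l in range(modeset.n_modes):
        v = modeset.modes[:, l]
        quad = np.real(np.conj(v) @ j @ v) / np.real(np.conj(v) @ v)
        res[l] = abs(quad - modeset.eigenvalues[l].real)
    return res


def mode_similarity(v1: np.ndarray, v2: np.ndarray) -> float:
    """|⟨v1, v2⟩| / (‖v1‖·‖v2‖) ∈ [0, 1]: cosine similarity invariant to
    sign and global phase (the ±π equivalence of eigenvector sign flips)."""
    a = np.asarray(v1).ravel()
    b = np.asarray(v2).ravel()
    if a.shape != b.shape:
        raise InvalidParameterError("vectors must have equal length")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise DegenerateInputError("zero vector has no direction")
    return float(np.abs(np.vdot(a, b)) / (na * nb))


def localization_index(v: np.ndarray) -> float:
    """Inverse participation ratio Σ|v_i|⁴/(Σ|v_i|²)² ∈ [1/N, 1]: 1/N for a
    fully extended mode, 1 for a single-node mode."""
    v = np.asarray(v).ravel()
    p2 = np.sum(np.abs(v) ** 2)
    if p2 == 0:
        raise DegenerateInputError("zero vector")
    return float(np.sum(np.abs(v) ** 4) / p2**2)


def dominant_wavenumber(
    v: np.ndarray, spacing: float = 1.0
) -> tuple[float, float]:
    """Dominant spatial wavenumber of a mode and its spectral concentration.

    After mean removal, k = 2π·m*/(N·spacing) where m* maximises the DFT
    magnitude over m = 1..⌊N/2⌋; concentration is the energy fraction in
    m* and its conjugate bin.  A nearly constant vector has no spatial
    frequency content and raises a degenerate-input error.
    """
    v = np.asarray(v).ravel()
    n = v.size
    if n < 4:
        raise InvalidParameterError("need at least 4 samples")
    x = v - v.mean()
    power = np.abs(np.fft.fft(x)) ** 2
    total = power[1:].sum()  # DC removed by mean subtraction
    if total <= 1e-24 * max(1.0, float(np.sum(np.abs(v) ** 2))):
        raise DegenerateInputError("constant vector has no dominant wavenumber")
    half = n // 2
    m_star = 1 + int(np.argmax(power[1 : half + 1]))
    k = 2.0 * np.pi * m_star / (n * spacing)
    bins = {m_star, n - m_star}
    conc = float(sum(power[m] for m in bins) / total)
    return k, conc


def phase_lags(modeset: ModeSet, mode_index: int) -> np.ndarray:
    """Per-node phase of a complex mode relative to its largest-|·| node.

    arg(v_i) − arg(v_ref) wrapped to (−π, π].  A node pair with entries
    proportional to 1 and i lags by π/2 — the quadrature relationship of
    oscillatory modes.  Purely real modes have no phase structure.
    """
    lam = modeset.eigenvalues[mode_index]
    if abs(lam.imag) <= 1e-12 * max(1.0, abs(lam)):
        raise NotOscillatoryError(f"mode {mode_index} has a real eigenvalue")
    v = modeset.modes[:, mode_index]
    ref = int(np.argmax(np.abs(v)))
    raw = np.angle(v) - np.angle(v[ref])
    wrapped = np.mod(raw + np.pi, 2.0 * np.pi) - np.pi
    wrapped[wrapped == -np.pi] = np.pi  # range (−π, π]
    return wrapped
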