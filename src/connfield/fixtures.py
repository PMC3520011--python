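"""Connectivity matrices: exemplar generators and delimited-text I/O.

The package studies resting-state dynamics on weighted anatomical
connectivity.  This module builds every connectivity configuration the
analyses use — translationally invariant exponential-footprint (Toeplitz)
matrices, heterogeneous two-point perturbations of them, signed/asymmetric
excitatory–inhibitory variants, and planted modular block matrices — and
reads/writes matrices as CSV/TSV so a user-supplied tractography matrix
(e.g. a 66-node DSI matrix with weights on an arbitrary 0–1 scale) can be
dropped into the same pipeline.

All generators are deterministic given their parameters.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConnectivityMatrix",
    "KernelSpec",
    "TwoPointConnection",
    "make_exponential_footprint",
    "add_two_point_connections",
    "make_planted_modular",
    "make_ei_clique_fixture",
    "read_connectivity",
    "write_connectivity",
]


class InvalidParameterError(ValueError):
    """A generator or operation received an out-of-domain parameter."""


class FormatError(ValueError):
    """A connectivity file violates the dense delimited-matrix format."""


_SYM_ATOL = 0.0  # undirected means *exact* transpose equality


@dataclass(frozen=True)
class ConnectivityMatrix:
    """A weighted graph over N nodes: the structural substrate κ.

    Parameters
    ----------
    weights
        N×N real matrix of connection weights (tract-density-like,
        arbitrary units).  Entry (i, j) couples source j into target i.
    labels
        N node identifiers.
    directed
        False iff ``weights`` equals its transpose exactly.
    signed
        True iff any entry is negative.
    spacing
        Grid step Δ for kernel-derived matrices (node i sits at x = i·Δ
        on a one-dimensional manifold); 1.0 for abstract graphs.
    """

    weights: np.ndarray
    labels: tuple[str, ...] = ()
    directed: bool = False
    signed: bool = False
    spacing: float = 1.0

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise InvalidParameterError(f"weights must be square, got shape {w.shape}")
        if not np.all(np.isfinite(w)):
            raise InvalidParameterError("weights must be finite")
        if not self.labels:
            object.__setattr__(
                self, "labels", tuple(f"n{i}" for i in range(w.shape[0]))
            )
        elif len(self.labels) != w.shape[0]:
            raise InvalidParameterError(
                f"{len(self.labels)} labels for {w.shape[0]} nodes"
            )
        else:
            object.__setattr__(self, "labels", tuple(str(l) for l in self.labels))
        if not self.directed and not np.array_equal(w, w.T):
            raise InvalidParameterError("directed=False requires exact symmetry")
        if not self.signed and np.any(w < 0):
            raise InvalidParameterError("signed=False requires nonnegative weights")
        if self.spacing <= 0:
            raise InvalidParameterError("spacing must be positive")

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    def fingerprint(self) -> str:
        """SHA-256 of the weight bytes — provenance for reports."""
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.weights).tobytes())
        h.update(str(self.spacing).encode())
        return h.hexdigest()[:16]

    def with_weights(self, weights: np.ndarray) -> "ConnectivityMatrix":
        """New matrix with the same metadata, flags re-inferred."""
        w = np.asarray(weights, dtype=float)
        return ConnectivityMatrix(
            weights=w,
            labels=self.labels if len(self.labels) == w.shape[0] else (),
            directed=not np.array_equal(w, w.T),
            signed=bool(np.any(w < 0)),
            spacing=self.spacing,
        )


@dataclass(frozen=True)
class KernelSpec:
    """Translationally invariant coupling kernel on a 1-D grid.

    The exponential synaptic footprint e^(−d/σ)/(2σ) is the classic
    choice: σ sets the lateral spread of connections and the default
    normalization 1/(2σ) makes the continuum kernel integrate to 1.
    """

    form: str = "exponential"
    sigma: float = 1.0
    normalization: float | None = None  # None -> 1/(2·sigma)
    boundary: str = "truncated"  # or "circulant"

    def __post_init__(self) -> None:
        if self.form != "exponential":
            raise InvalidParameterError(f"unknown kernel form {self.form!r}")
        if self.sigma <= 0:
            raise InvalidParameterError("sigma must be positive")
        if self.normalization is None:
            object.__setattr__(self, "normalization", 1.0 / (2.0 * self.sigma))
        elif self.normalization <= 0:
            raise InvalidParameterError("normalization must be positive")
        if self.boundary not in ("truncated", "circulant"):
            raise InvalidParameterError(f"unknown boundary {self.boundary!r}")


@dataclass(frozen=True)
class TwoPointConnection:
    """A single heterogeneous connection added on top of a base matrix.

    Signed weights model excitatory (+) and inhibitory (−) connections;
    ``reciprocal`` adds the same weight in both directions.
    """

    source: int
    target: int
    weight: float
    reciprocal: bool = False

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise InvalidParameterError("two-point connection needs distinct nodes")


def make_exponential_footprint(
    n_nodes: int,
    spec: KernelSpec | None = None,
    spacing: float = 1.0,
    *,
    keep_diagonal: bool = False,
) -> ConnectivityMatrix:
    """Sample the exponential footprint on a 1-D grid of ``n_nodes`` nodes.

    Entry (i, j) is ``normalization · exp(−d_ij/σ)`` with
    d_ij = |i−j|·spacing (boundary="truncated") or the wrap-around
    distance min(|i−j|, n−|i−j|)·spacing (boundary="circulant").  The
    diagonal (self-connection) is zeroed unless ``keep_diagonal``; the
    circulant variant with the diagonal kept is the exact discretisation
    whose eigenvalues Riemann-sum the continuum Fourier transform.
    """
    spec = spec or KernelSpec()
    if n_nodes < 3:
        raise InvalidParameterError("need at least 3 nodes")
    if spacing <= 0:
        raise InvalidParameterError("spacing must be positive")
    idx = np.arange(n_nodes)
    d = np.abs(idx[:, None] - idx[None, :]).astype(float)
    if spec.boundary == "circulant":
        d = np.minimum(d, n_nodes - d)
    d *= spacing
    w = spec.normalization * np.exp(-d / spec.sigma)
    if not keep_diagonal:
        np.fill_diagonal(w, 0.0)
    w = np.minimum(w, w.T)  # enforce exact symmetry against fp asymmetry
    return ConnectivityMatrix(weights=w, directed=False, signed=False, spacing=spacing)


def add_two_point_connections(
    matrix: ConnectivityMatrix,
    connections: Iterable[TwoPointConnection],
) -> ConnectivityMatrix:
    """Return a new matrix with heterogeneous two-point connections added.

    Each connection adds ``weight`` at (target, source); reciprocal
    connections add it at (source, target) too.  Directed/signed flags of
    the result are re-inferred from the summed weights, so a symmetric
    set of additions keeps the matrix undirected.  Additive: applying two
    lists in sequence equals applying their concatenation.
    """
    w = matrix.weights.copy()
    n = matrix.n_nodes
    for c in connections:
        if not (0 <= c.source < n and 0 <= c.target < n):
            raise InvalidParameterError(
                f"connection ({c.source},{c.target}) outside 0..{n - 1}"
            )
        w[c.target, c.source] += c.weight
        if c.reciprocal:
            w[c.source, c.target] += c.weight
    return matrix.with_weights(w)


def make_planted_modular(
    block_sizes: Sequence[int],
    w_in: float,
    w_out: float,
) -> ConnectivityMatrix:
    """Planted modular block matrix: within-block off-diagonal entries
    ``w_in``, between-block entries ``w_out`` (requires w_in > w_out ≥ 0)."""
    if any(s <= 0 for s in block_sizes):
        raise InvalidParameterError("block sizes must be positive")
    if not (w_in > w_out >= 0):
        raise InvalidParameterError("need w_in > w_out >= 0")
    n = int(sum(block_sizes))
    membership = np.repeat(np.arange(len(block_sizes)), block_sizes)
    same = membership[:, None] == membership[None, :]
    w = np.where(same, w_in, w_out).astype(float)
    np.fill_diagonal(w, 0.0)
    return ConnectivityMatrix(weights=w, directed=False, signed=False)


def make_ei_clique_fixture(
    n_nodes: int = 66,
    sigma: float = 5.0,
    clique_a: Sequence[int] = (20, 21, 22),
    clique_b: Sequence[int] = (40, 41, 42),
    w_within: float = 0.6,
    w_between: float = 1.0,
    spacing: float = 1.0,
) -> ConnectivityMatrix:
    """Asymmetric excitatory/inhibitory exemplar on a footprint base.

    Two local cliques are planted on top of the exponential footprint:
    extra reciprocal excitation within each clique, plus reciprocal
    between-clique connections that are excitatory one way (+w, A→B) and
    inhibitory the other (−w, B→A).  The clique-uniform pattern then
    carries a complex leading eigenvalue pair (≈ (|A|−1)·w_within ±
    i·√(|A||B|)·w_between for equal cliques), i.e. oscillatory dynamics
    with the second clique in phase quadrature — the behaviour that a
    symmetric matrix cannot produce.
    """
    base = make_exponential_footprint(
        n_nodes, KernelSpec(sigma=sigma), spacing=spacing
    )
    conns: list[TwoPointConnection] = []
    for group in (clique_a, clique_b):
        for a in group:
            for b in group:
                if a < b:
                    conns.append(TwoPointConnection(a, b, w_within, reciprocal=True))
    for a in clique_a:
        for b in clique_b:
            conns.append(TwoPointConnection(a, b, +w_between, reciprocal=False))
            conns.append(TwoPointConnection(b, a, -w_between, reciprocal=False))
    return add_two_point_connections(base, conns)


# ---------------------------------------------------------------------------
# delimited-text I/O


def write_connectivity(matrix: ConnectivityMatrix, path: str | Path) -> None:
    """Write a matrix as delimited text (CSV, or TSV for .tsv/.txt paths),
    with node labels as header row and index column."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.DataFrame(
        matrix.weights, index=list(matrix.labels), columns=list(matrix.labels)
    )
    df.to_csv(path, sep=sep, float_format="%.17g")


def _sniff_sep(text: str) -> str:
    first = text.splitlines()[0] if text else ""
    return "\t" if first.count("\t") >= first.count(",") and "\t" in first else ","


def read_connectivity(path: str | Path, spacing: float = 1.0) -> ConnectivityMatrix:
    """Read a dense connectivity matrix from delimited numeric text.

    Accepts comma- or tab-separated values, with an optional single
    header row and/or label column.  Directed/signed flags are inferred
    from the content.  Non-square shapes, non-numeric cells and NaNs are
    format errors naming the offending row.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise FormatError(f"{path}: empty file")
    sep = _sniff_sep(text)

    rows = [line.split(sep) for line in text.splitlines() if line.strip()]

    def is_num(tok: str) -> bool:
        try:
            float(tok)
            return True
        except ValueError:
            return False

    has_header = not all(is_num(t) for t in rows[0][0:] if t != "")
    body = rows[1:] if has_header else rows
    has_index = bool(body) and not is_num(body[0][0])

    labels: list[str] = []
    data: list[list[float]] = []
    width = None
    for r, row in enumerate(body):
        toks = row[1:] if has_index else row
        if has_index:
            labels.append(row[0])
        if width is None:
            width = len(toks)
        elif len(toks) != width:
            raise FormatError(f"{path}: row {r + 1} has {len(toks)} columns, expected {width}")
        vals = []
        for tok in toks:
            if not is_num(tok):
                raise FormatError(f"{path}: non-numeric cell {tok!r} in row {r + 1}")
            vals.append(float(tok))
        data.append(vals)

    w = np.asarray(data, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise FormatError(f"{path}: matrix is {w.shape[0]}×{w.shape[1]}, not square")
    bad = np.where(~np.isfinite(w).all(axis=1))[0]
    if bad.size:
        raise FormatError(f"{path}: non-finite entry in row {bad[0] + 1}")

    if not labels and has_header:
        hdr = rows[0]
        labels = hdr[-w.shape[1]:]
    return ConnectivityMatrix(
        weights=w,
        labels=tuple(labels) if labels else (),
        directed=not np.array_equal(w, w.T),
        signed=bool(np.any(w < 0)),
        spacing=spacing,
    )
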