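"""Spatial Semantic Pointer algebra.

A continuous value x in R^m is encoded as a unit-norm d-vector by fractional
power encoding: phases A @ x are placed on the unit circle in the frequency
domain and brought back with an inverse DFT,

    phi(x) = IDFT[ exp(i A x) ].

Conjugate symmetry of the rows of A (plus one zero-frequency row) makes
phi(x) real.  Binding is circular convolution, so phases add:
phi(x) (*) phi(y) = phi(x + y), which is what lets sums of bound pairs act
as queryable maps of an environment, and dot products of encodings act as a
shift-invariant similarity kernel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize

__all__ = [
    "SSPSpace",
    "make_encoding_matrix",
    "bind",
    "unbind",
    "make_unitary",
    "ConceptVocabulary",
    "EnvironmentMap",
    "build_map",
    "query_map",
]


def _phase_matrix_to_full(phase_rows: np.ndarray, d: int) -> np.ndarray:
    """Assemble the full d x m frequency matrix from free phase-slope rows.

    Row 0 is the zero-frequency row; rows 1..n_free carry the free slopes and
    rows d-1..d-n_free their negations, matching numpy's rfft/irfft layout of
    conjugate-symmetric spectra for odd d.
    """
    n_free = phase_rows.shape[0]
    m = phase_rows.shape[1]
    A = np.zeros((d, m))
    A[1 : n_free + 1] = phase_rows
    A[d - n_free :] = -phase_rows[::-1]
    return A


@dataclass
class SSPSpace:
    """Fractional-power-encoding space with conjugate-symmetric phase matrix.

    A : (d, m) phase-slope matrix (row 0 all zeros, rows paired A[k] = -A[d-k]).
    length_scale : spatial units per radian of phase, folded into A at
        construction.
    """

    A: np.ndarray
    length_scale: float = 1.0
    kind: str = "random"
    module_waves: Optional[np.ndarray] = None  # hex spaces: (n_modules, 3, m)

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        d = self.A.shape[0]
        if not np.allclose(self.A[0], 0.0):
            raise ValueError("row 0 of the phase matrix must be the zero frequency")
        if not np.allclose(self.A[1:], -self.A[1:][::-1]):
            raise ValueError("phase matrix must be conjugate-symmetric")
        if d % 2 == 0:
            raise ValueError("dimension d must be odd (zero row + conjugate pairs)")

    @property
    def d(self) -> int:
        return self.A.shape[0]

    @property
    def m(self) -> int:
        return self.A.shape[1]

    @property
    def n_pairs(self) -> int:
        return (self.d - 1) // 2

    @property
    def free_rows(self) -> np.ndarray:
        """Phase slopes of the independent (positive-frequency) components."""
        return self.A[1 : self.n_pairs + 1]

    def encode(self, x) -> np.ndarray:
        """phi(x); batch-aware over leading axes of ``x`` (last axis = m)."""
        x = np.asarray(x, dtype=float)
        scalar = x.ndim <= 1
        x2 = np.atleast_2d(x)
        if x2.shape[-1] != self.m:
            raise ValueError(f"x must have {self.m} components")
        phases = x2 @ self.A.T  # (..., d)
        # unnormalized-ifft of a unit-modulus spectrum has unit L2 norm
        v = np.fft.ifft(np.exp(1j * phases), axis=-1).real
        return v[0] if scalar else v.reshape(x.shape[:-1] + (self.d,))

    def encode_fourier(self, x) -> np.ndarray:
        """Unit-modulus frequency-domain encoding exp(i A x)."""
        x = np.asarray(x, dtype=float)
        return np.exp(1j * np.atleast_2d(x) @ self.A.T).squeeze()

    def similarity(self, v: np.ndarray, x) -> np.ndarray:
        """Dot products of ``v`` with phi at one or many query points."""
        return self.encode(x) @ np.asarray(v, dtype=float)

    def similarity_grid(
        self, v: np.ndarray, bounds: Sequence[tuple[float, float]], resolution: int = 64
    ) -> tuple[np.ndarray, list[np.ndarray]]:
        """Similarity heat-map of ``v`` over a rectangular grid.

        Returns (values with shape (resolution,)*m, per-axis coordinates).
        """
        axes = [np.linspace(lo, hi, resolution) for lo, hi in bounds]
        mesh = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
        return self.similarity(v, mesh), axes

    def decode(
        self,
        v: np.ndarray,
        bounds: Sequence[tuple[float, float]],
        resolution: int = 25,
        reliability_threshold: float = 0.5,
    ) -> tuple[np.ndarray, float, bool]:
        """Estimate the x whose encoding best matches ``v``.

        Coarse grid argmax over ``bounds`` followed by Nelder-Mead
        refinement.  Returns (x_hat, peak similarity, reliable flag); the
        flag drops when the peak similarity (normalized by |v|) is below the
        threshold, e.g. for vectors far off the encoding manifold.
        """
        sims, axes = self.similarity_grid(v, bounds, resolution)
        idx = np.unravel_index(np.argmax(sims), sims.shape)
        x0 = np.array([ax[i] for ax, i in zip(axes, idx)])
        span = max(hi - lo for lo, hi in bounds)
        res = minimize(
            lambda x: -self.similarity(v, x),
            x0,
            method="Nelder-Mead",
            options={"xatol": 1e-6 * span, "fatol": 1e-12, "maxiter": 400},
        )
        x_hat = res.x
        peak = float(self.similarity(v, x_hat))
        nv = np.linalg.norm(v)
        reliable = nv > 0 and peak / nv >= reliability_threshold
        return x_hat, peak, bool(reliable)

    def encode_region(
        self,
        region,
        spacing: Optional[float] = None,
        normalize_by_area: bool = False,
    ) -> np.ndarray:
        """Quadrature of phi over a region (Eq-style area integral).

        ``region`` is either an (N, m) array of sample points (summed with
        unit weights times the implied cell area) or, for m = 2, a shapely-
        style polygon exposing ``bounds`` and ``contains``-like predicate via
        ``covers``.  Grid spacing defaults to length_scale / 4.
        """
        if spacing is None:
            spacing = self.length_scale / 4.0
        pts, w = self._region_points(region, spacing)
        if pts.shape[0] == 0:
            raise ValueError("region contains no quadrature points")
        v = self.encode(pts).sum(axis=0) * w
        if normalize_by_area:
            v = v / (pts.shape[0] * w)
        return v

    def _region_points(self, region, spacing: float) -> tuple[np.ndarray, float]:
        """Quadrature points and the per-point weight (cell area)."""
        if isinstance(region, np.ndarray):
            return np.atleast_2d(region), spacing**self.m
        pts = getattr(region, "points", None)
        if pts is not None:
            return np.atleast_2d(np.asarray(pts, dtype=float)), spacing**self.m
        # shapely geometry path: cell-centred grid with an integer cell
        # count per axis, so the covered area converges as O(spacing^2)
        from shapely.geometry import Point

        minx, miny, maxx, maxy = region.bounds
        nx = max(1, int(np.ceil((maxx - minx) / spacing)))
        ny = max(1, int(np.ceil((maxy - miny) / spacing)))
        dx, dy = (maxx - minx) / nx, (maxy - miny) / ny
        xs = minx + (np.arange(nx) + 0.5) * dx
        ys = miny + (np.arange(ny) + 0.5) * dy
        out = [(x, y) for x in xs for y in ys if region.covers(Point(x, y))]
        return np.asarray(out, dtype=float).reshape(-1, 2), dx * dy

    def to_json(self) -> str:
        return json.dumps(
            {
                "A": self.A.tolist(),
                "length_scale": self.length_scale,
                "kind": self.kind,
                "module_waves": None if self.module_waves is None else self.module_waves.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "SSPSpace":
        dct = json.loads(text)
        mw = dct["module_waves"]
        return cls(
            np.array(dct["A"]),
            dct["length_scale"],
            dct["kind"],
            None if mw is None else np.array(mw),
        )


def make_encoding_matrix(
    d: int,
    m: int,
    kind: str = "random",
    length_scale: float = 0.5,
    seed: int | np.random.Generator | None = None,
    n_scales: int = 5,
    n_orientations: int = 5,
    scale_range: tuple[float, float] = (1.0, 3.0),
) -> SSPSpace:
    """Construct an SSP space.

    random: phase slopes uniform in [-pi, pi]^m / length_scale.
    hex (m = 2 only): slopes are triplets of wave vectors 120 degrees apart,
    one triplet per (scale, orientation) module, scales geometrically spaced
    over ``scale_range`` / length_scale.  ``d`` is then determined by the
    module structure (6 * n_scales * n_orientations + 1) and the passed value
    is ignored if it disagrees.
    """
    if m not in (1, 2, 3):
        raise ValueError("m must be 1, 2 or 3")
    rng = np.random.default_rng(seed)
    if kind == "random":
        if d % 2 == 0:
            raise ValueError("d must be odd so conjugate pairs balance")
        n_free = (d - 1) // 2
        # stratified (Latin-hypercube) uniform draw over [-pi, pi]^m: same
        # marginal law as iid uniform but with far lower Monte-Carlo error in
        # the induced kernel (the standard variance reduction for random
        # Fourier features)
        u = (np.stack([rng.permutation(n_free) for _ in range(m)], axis=1) + rng.random((n_free, m))) / n_free
        rows = (2 * np.pi * u - np.pi) / length_scale
        A = _phase_matrix_to_full(rows, d)
        return SSPSpace(A, length_scale, "random")
    if kind == "hex":
        if m != 2:
            raise ValueError("hex structure is defined for m = 2")
        base = np.array(
            [[np.cos(a), np.sin(a)] for a in (np.pi / 2, np.pi / 2 + 2 * np.pi / 3, np.pi / 2 + 4 * np.pi / 3)]
        )
        scales = np.geomspace(*scale_range, n_scales) / length_scale
        orientations = np.linspace(0, np.pi / 3, n_orientations, endpoint=False)
        waves = []
        for s in scales:
            for o in orientations:
                R = np.array([[np.cos(o), -np.sin(o)], [np.sin(o), np.cos(o)]])
                waves.append(s * base @ R.T)
        waves = np.asarray(waves)  # (n_modules, 3, 2)
        rows = waves.reshape(-1, 2)
        A = _phase_matrix_to_full(rows, 2 * rows.shape[0] + 1)
        return SSPSpace(A, length_scale, "hex", module_waves=waves)
    raise ValueError("kind must be 'random' or 'hex'")


def bind(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Circular convolution via the frequency domain."""
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("bound vectors must share a dimension")
    return np.fft.ifft(np.fft.fft(a) * np.fft.fft(b)).real


def unbind(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Bind with the involution of b (frequency conjugate); exact inverse of
    ``bind(., b)`` when b is unitary."""
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("unbound vectors must share a dimension")
    return np.fft.ifft(np.fft.fft(a) * np.conj(np.fft.fft(b))).real


def make_unitary(d: int, rng: np.random.Generator) -> np.ndarray:
    """Random unitary vector: all Fourier magnitudes 1 (exactly invertible)."""
    if d % 2 == 0:
        raise ValueError("d must be odd")
    n_free = (d - 1) // 2
    phases = rng.uniform(-np.pi, np.pi, n_free)
    spec = np.concatenate([[1.0], np.exp(1j * phases), np.exp(-1j * phases[::-1])])
    return np.fft.ifft(spec).real


@dataclass
class ConceptVocabulary:
    """Named random unitary vectors for slot-filler binding."""

    d: int
    seed: int = 0
    vectors: dict = field(default_factory=dict)

    def add(self, *names: str) -> "ConceptVocabulary":
        for name in names:
            if name in self.vectors:
                continue
            # per-name stream: a concept's vector never depends on what else
            # is in the vocabulary or on insertion order
            digest = int.from_bytes(name.encode(), "big") % (2**31)
            rng = np.random.default_rng([self.seed, digest])
            self.vectors[name] = make_unitary(self.d, rng)
        return self

    def __getitem__(self, name: str) -> np.ndarray:
        return self.vectors[name]

    def __contains__(self, name: str) -> bool:
        return name in self.vectors


@dataclass
class EnvironmentMap:
    """Sum vector E over concept-bound location encodings, with provenance."""

    vector: np.ndarray
    items: list
    space: SSPSpace
    vocab: ConceptVocabulary

    def rebuild_check(self, atol: float = 1e-10) -> bool:
        fresh = build_map(self.space, self.vocab, self.items)
        return bool(np.allclose(fresh.vector, self.vector, atol=atol))


def build_map(space: SSPSpace, vocab: ConceptVocabulary, items: Sequence) -> EnvironmentMap:
    """E = sum over items of concept (*) encoding(location-or-set-or-region).

    Each item is (concept_name, payload) where payload is a single m-vector,
    an iterable of m-vectors (a location set), or a region accepted by
    ``encode_region``.
    """
    E = np.zeros(space.d)
    for concept, payload in items:
        if concept not in vocab:
            raise KeyError(f"concept {concept!r} not in vocabulary")
        payload_arr = np.asarray(payload, dtype=float) if not hasattr(payload, "bounds") else None
        if payload_arr is not None and payload_arr.ndim == 1:
            enc = space.encode(payload_arr)
        elif payload_arr is not None and payload_arr.ndim == 2:
            enc = space.encode(payload_arr).sum(axis=0)
        else:
            enc = space.encode_region(payload)
        E += bind(vocab[concept], enc)
    return EnvironmentMap(E, list(items), space, vocab)


def query_map(
    env: EnvironmentMap,
    concept: str,
    bounds: Sequence[tuple[float, float]],
    resolution: int = 64,
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Unbind the map with a concept and scan similarity over a grid."""
    probe = unbind(env.vector, env.vocab[concept])
    return env.space.similarity_grid(probe, bounds, resolution)
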