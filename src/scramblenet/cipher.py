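"""Position-permutation image ciphers: the generalized discretized Baker map
and the Arnold cat map.

Both ciphers act on square ``N x N`` 8-bit grayscale images and only move
pixels around -- the multiset of intensities (hence histogram and Shannon
entropy) is exactly invariant, and every encryption is exactly invertible.

Coordinate convention
---------------------
The Baker map is written in terms of an index pair ``(r, s)`` where ``r`` is
the **column** index and ``s`` the **row** index, both 0-based.  The key is an
ordered partition ``(n_1, ..., n_k)`` of ``N`` into parts that each divide
``N``; part ``i`` owns the vertical strip of columns ``N_i <= r < N_i + n_i``
with offsets ``N_i = n_1 + ... + n_{i-1}`` (``N_1 = 0``).  One application of
the map sends ``(r, s)`` with ``q = N / n_i`` to::

    r' = q * (r - N_i) + (s mod q)
    s' = (s - s mod q) / q + N_i

Every quantity above is an exact integer for a valid key, and the
implementation uses integer arithmetic only, so round trips are bit-exact.

The Arnold (cat map) transform is the linear torus map
``(r, s) -> ((a*r + b*s) mod N, (c*r + d*s) mod N)`` with an integer matrix
``[[a, b], [c, d]]`` whose determinant is a unit mod ``N``; iterating it is
periodic with period equal to the multiplicative order of the matrix mod
``N``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, NamedTuple, Sequence, Union

import numpy as np
from scipy import stats

__all__ = [
    "CipherError",
    "CipherKeyError",
    "BakerKey",
    "ArnoldParams",
    "PermutationTable",
    "as_pixel_grid",
    "validate_baker_key",
    "baker_index_map",
    "arnold_index_map",
    "arnold_period",
    "build_permutation",
    "apply_permutation",
    "encrypt",
    "decrypt",
    "CorrelationResult",
    "adjacent_correlation",
    "random_baker_key",
    "load_key",
    "save_key",
]


class CipherError(ValueError):
    """Base class for cipher-domain errors."""


class CipherKeyError(CipherError):
    """An invalid cipher key (bad partition, non-invertible matrix, ...)."""


# ---------------------------------------------------------------------------
# Pixel grids
# ---------------------------------------------------------------------------

def as_pixel_grid(image: np.ndarray) -> np.ndarray:
    """Validate *image* as a square 8-bit grid and return it as ``uint8``.

    Raises
    ------
    CipherError
        If the array is not 2-D square, not integer-valued, or outside
        ``[0, 255]``.
    """
    arr = np.asarray(image)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1] or arr.shape[0] < 1:
        raise CipherError(
            f"pixel grid must be square 2-D, got shape {arr.shape!r}"
        )
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.round(arr)):
            raise CipherError("pixel intensities must be integers")
        arr = np.round(arr).astype(np.int64)
    if arr.min() < 0 or arr.max() > 255:
        raise CipherError("pixel intensities must lie in [0, 255]")
    return arr.astype(np.uint8)


# ---------------------------------------------------------------------------
# Keys
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BakerKey:
    """A validated Baker-map key: an ordered partition of ``N`` plus a round
    count.

    Attributes
    ----------
    parts : tuple of int
        The ordered parts ``n_1 .. n_k``; each divides ``N`` and they sum
        to ``N``.
    n : int
        Grid side length the key is valid for.
    rounds : int
        How many times the permutation is composed with itself during
        encryption (default 1).
    """

    parts: tuple
    n: int
    rounds: int = 1

    @property
    def offsets(self) -> tuple:
        """Strip offsets ``N_i = n_1 + ... + n_{i-1}`` with ``N_1 = 0``."""
        return tuple(int(x) for x in np.concatenate([[0], np.cumsum(self.parts)[:-1]]))


def validate_baker_key(
    parts: Sequence[int], n: int, rounds: int = 1
) -> BakerKey:
    """Validate an ordered partition as a Baker key for an ``n x n`` grid.

    Every part must be a positive integer dividing ``n`` and the parts must
    sum to ``n`` (so ``n / n_i`` and ``s mod (n / n_i)`` are well defined on
    integer indices and the strips tile the grid exactly).
    """
    if n < 1:
        raise CipherKeyError(f"grid side must be >= 1, got {n}")
    parts = tuple(int(p) for p in parts)
    if len(parts) == 0:
        raise CipherKeyError("key must have at least one part")
    if any(p <= 0 for p in parts):
        raise CipherKeyError(f"all parts must be positive, got {parts}")
    if sum(parts) != n:
        raise CipherKeyError(
            f"parts {parts} sum to {sum(parts)}, expected grid side {n}"
        )
    bad = [p for p in parts if n % p != 0]
    if bad:
        raise CipherKeyError(
            f"parts {bad} do not divide the grid side {n}"
        )
    if rounds < 1:
        raise CipherKeyError(f"rounds must be >= 1, got {rounds}")
    return BakerKey(parts=parts, n=n, rounds=rounds)


@dataclass(frozen=True)
class ArnoldParams:
    """Arnold transform parameters: a 2x2 integer matrix and iteration count.

    The default matrix is the classical cat map ``[[1, 1], [1, 2]]``.  The
    matrix must be invertible mod every grid side it is applied to, i.e.
    ``gcd(a*d - b*c, N) = 1``.
    """

    a: int = 1
    b: int = 1
    c: int = 1
    d: int = 2
    iterations: int = 1

    def __post_init__(self):
        if self.iterations < 0:
            raise CipherKeyError(
                f"iterations must be >= 0, got {self.iterations}"
            )

    @property
    def matrix(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)

    def check_invertible(self, n: int) -> None:
        det = self.a * self.d - self.b * self.c
        if np.gcd(det, n) != 1:
            raise CipherKeyError(
                f"matrix determinant {det} is not a unit mod {n}; "
                "the Arnold map would not be invertible"
            )


KeyLike = Union[BakerKey, ArnoldParams]


# ---------------------------------------------------------------------------
# Index maps
# ---------------------------------------------------------------------------

def baker_index_map(r: int, s: int, key: BakerKey, n: int | None = None):
    """One application of the discretized Baker map to index ``(r, s)``.

    ``r`` is the column, ``s`` the row, both 0-based.  Integer arithmetic
    only; the division in the row formula is exact because ``q`` divides
    ``s - s mod q``.
    """
    if n is None:
        n = key.n
    if n != key.n:
        raise CipherKeyError(f"key is for side {key.n}, grid has side {n}")
    if not (0 <= r < n and 0 <= s < n):
        raise IndexError(f"index ({r}, {s}) outside [0, {n})^2")
    offsets = key.offsets
    # locate the strip containing column r
    i = int(np.searchsorted(offsets, r, side="right")) - 1
    n_i, off = key.parts[i], offsets[i]
    q = n // n_i
    r2 = q * (r - off) + s % q
    s2 = (s - s % q) // q + off
    return r2, s2


def arnold_index_map(r: int, s: int, params: ArnoldParams, n: int):
    """One application of the Arnold matrix map to index ``(r, s)``."""
    params.check_invertible(n)
    if not (0 <= r < n and 0 <= s < n):
        raise IndexError(f"index ({r}, {s}) outside [0, {n})^2")
    r2 = (params.a * r + params.b * s) % n
    s2 = (params.c * r + params.d * s) % n
    return r2, s2


def _matrix_power_mod(m: np.ndarray, t: int, n: int) -> np.ndarray:
    """``m ** t mod n`` by repeated squaring (Python ints, no overflow)."""
    result = np.eye(2, dtype=object)
    base = m.astype(object) % n
    t = int(t)
    while t > 0:
        if t & 1:
            result = (result @ base) % n
        base = (base @ base) % n
        t >>= 1
    return result


def arnold_period(params: ArnoldParams, n: int, max_steps: int = 10_000_000) -> int:
    """Smallest ``P >= 1`` with ``P`` applications equal to the identity.

    Equals the multiplicative order of the cipher matrix mod ``n``; for
    ``n = 1`` every map is the identity, so the period is 1.
    """
    if n < 1:
        raise CipherError(f"grid side must be >= 1, got {n}")
    if n == 1:
        return 1
    params.check_invertible(n)
    ident = np.eye(2, dtype=object)
    m = params.matrix.astype(object) % n
    power = m.copy()
    for p in range(1, max_steps + 1):
        if np.array_equal(power % n, ident):
            return p
        power = (power @ m) % n
    raise CipherError(f"period exceeds {max_steps} for side {n}")


# ---------------------------------------------------------------------------
# Permutation tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PermutationTable:
    """A materialized bijection on the ``N x N`` index grid.

    ``forward[src]`` is the flat destination index of flat source index
    ``src``, with flat index ``s * N + r`` (row-major).  ``inverse`` is the
    inverse lookup.  Bijectivity is verified at construction.
    """

    n: int
    forward: np.ndarray
    inverse: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        fwd = np.asarray(self.forward, dtype=np.int64)
        if fwd.shape != (self.n * self.n,):
            raise CipherError(
                f"forward table has shape {fwd.shape}, expected ({self.n**2},)"
            )
        counts = np.bincount(fwd, minlength=self.n * self.n)
        if not np.all(counts == 1):
            raise CipherError(
                "index map is not a bijection: some destination is hit "
                f"{counts.max()} times"
            )
        inv = np.empty_like(fwd)
        inv[fwd] = np.arange(fwd.size)
        object.__setattr__(self, "forward", fwd)
        object.__setattr__(self, "inverse", inv)

    def compose(self, other: "PermutationTable") -> "PermutationTable":
        """Table applying ``self`` then ``other``."""
        if other.n != self.n:
            raise CipherError("cannot compose tables of different sizes")
        return PermutationTable(self.n, other.forward[self.forward])


def _baker_table_single(key: BakerKey) -> PermutationTable:
    n = key.n
    fwd = np.empty(n * n, dtype=np.int64)
    s = np.arange(n)
    for n_i, off in zip(key.parts, key.offsets):
        q = n // n_i
        s_mod = s % q
        s2 = (s - s_mod) // q + off  # one row value per s, shared by the strip
        for r in range(off, off + n_i):
            r2 = q * (r - off) + s_mod
            fwd[s * n + r] = s2 * n + r2
    return PermutationTable(n, fwd)


def _arnold_table(params: ArnoldParams, n: int, iterations: int) -> PermutationTable:
    params.check_invertible(n)
    m = _matrix_power_mod(params.matrix, iterations, n)
    rr, ss = np.meshgrid(np.arange(n), np.arange(n), indexing="xy")
    r2 = (int(m[0, 0]) * rr + int(m[0, 1]) * ss) % n
    s2 = (int(m[1, 0]) * rr + int(m[1, 1]) * ss) % n
    fwd = np.empty(n * n, dtype=np.int64)
    fwd[ss.ravel() * n + rr.ravel()] = s2.ravel() * n + r2.ravel()
    return PermutationTable(n, fwd)


def build_permutation(spec: KeyLike, n: int) -> PermutationTable:
    """Materialize one full encryption as a permutation table.

    For a :class:`BakerKey` this composes ``rounds`` applications of the map;
    for :class:`ArnoldParams` it raises the matrix to the ``iterations``-th
    power mod ``n`` (0 iterations gives the identity).
    """
    if isinstance(spec, BakerKey):
        if spec.n != n:
            raise CipherKeyError(f"key is for side {spec.n}, grid has side {n}")
        single = _baker_table_single(spec)
        table = single
        for _ in range(spec.rounds - 1):
            table = table.compose(single)
        return table
    if isinstance(spec, ArnoldParams):
        return _arnold_table(spec, n, spec.iterations)
    raise TypeError(f"unsupported key type {type(spec).__name__}")


def apply_permutation(
    image: np.ndarray, table: PermutationTable, inverse: bool = False
) -> np.ndarray:
    """Move pixels according to *table* (or its inverse).

    The output is an exact rearrangement of the input pixels; applying the
    table and then its inverse restores the input bit-exactly.
    """
    img = as_pixel_grid(image)
    if img.shape[0] != table.n:
        raise CipherError(
            f"image side {img.shape[0]} does not match table size {table.n}"
        )
    mapping = table.inverse if inverse else table.forward
    out = np.empty_like(img)
    out.ravel()[mapping] = img.ravel()
    return out


# ---------------------------------------------------------------------------
# Encrypt / decrypt
# ---------------------------------------------------------------------------

def _resolve_key(scheme: str, key: KeyLike, n: int) -> PermutationTable:
    scheme = scheme.lower()
    if scheme == "baker":
        if not isinstance(key, BakerKey):
            raise CipherKeyError("baker scheme requires a BakerKey")
    elif scheme == "arnold":
        if not isinstance(key, ArnoldParams):
            raise CipherKeyError("arnold scheme requires ArnoldParams")
    else:
        raise CipherKeyError(f"unknown scheme {scheme!r}")
    return build_permutation(key, n)


def encrypt(
    image: np.ndarray, scheme: Literal["baker", "arnold"], key: KeyLike
) -> np.ndarray:
    """Encrypt a square 8-bit image by permuting pixel positions."""
    img = as_pixel_grid(image)
    table = _resolve_key(scheme, key, img.shape[0])
    return apply_permutation(img, table)


def decrypt(
    image: np.ndarray, scheme: Literal["baker", "arnold"], key: KeyLike
) -> np.ndarray:
    """Exact inverse of :func:`encrypt` with the same scheme and key."""
    img = as_pixel_grid(image)
    table = _resolve_key(scheme, key, img.shape[0])
    return apply_permutation(img, table, inverse=True)


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------

class CorrelationResult(NamedTuple):
    """Adjacent-pixel correlation with a degeneracy flag.

    ``r`` is the Pearson correlation of sampled adjacent pairs; when either
    member of the pair set is constant the correlation is undefined and
    ``degenerate`` is True (``r`` is then NaN, never silently 0).
    """

    r: float
    n_pairs: int
    degenerate: bool


def adjacent_correlation(
    image: np.ndarray,
    direction: Literal["horizontal", "vertical"] = "horizontal",
    sample_size: int = 2000,
    seed: int = 0,
) -> CorrelationResult:
    """Pearson correlation of randomly sampled adjacent pixel pairs.

    A smooth natural image has correlation near 1; a well-scrambled one
    near 0.  Sampling is deterministic given *seed*; if *sample_size*
    meets or exceeds the number of available pairs, all pairs are used.
    """
    img = as_pixel_grid(image).astype(np.float64)
    n = img.shape[0]
    if n < 2:
        raise CipherError("correlation needs side >= 2")
    if sample_size < 2:
        raise CipherError("sample_size must be >= 2")
    if direction == "horizontal":
        first, second = img[:, :-1], img[:, 1:]
    elif direction == "vertical":
        first, second = img[:-1, :], img[1:, :]
    else:
        raise ValueError(f"unknown direction {direction!r}")
    a, b = first.ravel(), second.ravel()
    if sample_size < a.size:
        rng = np.random.default_rng(seed)
        idx = rng.choice(a.size, size=sample_size, replace=False)
        a, b = a[idx], b[idx]
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return CorrelationResult(float("nan"), a.size, True)
    r = float(stats.pearsonr(a, b).statistic)
    return CorrelationResult(r, a.size, False)


# ---------------------------------------------------------------------------
# Key generation and JSON files
# ---------------------------------------------------------------------------

def random_baker_key(n: int, seed: int, rounds: int = 1) -> BakerKey:
    """Draw a random valid Baker key for an ``n x n`` grid.

    Parts are drawn uniformly from the divisors of ``n`` not exceeding the
    remaining width, so the partition always completes (1 divides ``n``).
    The single-part key ``(n,)`` is excluded for ``n > 1`` because it is the
    identity map, not an encryption.
    """
    rng = np.random.default_rng(seed)
    divisors = [d for d in range(1, n + 1) if n % d == 0 and (d < n or n == 1)]
    parts = []
    remaining = n
    while remaining > 0:
        choices = [d for d in divisors if d <= remaining]
        d = int(rng.choice(choices))
        parts.append(d)
        remaining -= d
    return validate_baker_key(parts, n, rounds=rounds)


def save_key(key: KeyLike, path: str | Path) -> None:
    """Write a cipher key as a JSON file."""
    if isinstance(key, BakerKey):
        obj = {"scheme": "baker", "parts": list(key.parts), "rounds": key.rounds}
    elif isinstance(key, ArnoldParams):
        obj = {
            "scheme": "arnold",
            "matrix": [key.a, key.b, key.c, key.d],
            "iterations": key.iterations,
        }
    else:
        raise TypeError(f"unsupported key type {type(key).__name__}")
    Path(path).write_text(json.dumps(obj, indent=2) + "\n")


def load_key(path: str | Path, n: int | None = None) -> KeyLike:
    """Read a cipher key from JSON; Baker keys require *n* for validation."""
    obj = json.loads(Path(path).read_text())
    scheme = obj.get("scheme")
    if scheme == "baker":
        if n is None:
            n = sum(obj["parts"])
        return validate_baker_key(obj["parts"], n, rounds=obj.get("rounds", 1))
    if scheme == "arnold":
        a, b, c, d = obj["matrix"]
        return ArnoldParams(a, b, c, d, iterations=obj.get("iterations", 1))
    raise CipherKeyError(f"unknown scheme {scheme!r} in key file {path}")
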