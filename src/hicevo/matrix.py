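"""Contact-matrix data model and normalization.

Intra-chromosomal binned Hi-C matrices with the normalizations shared by all
downstream stages: matrix balancing to equal row sums (Knight-Ruiz-style,
implemented as a damped symmetric Sinkhorn iteration), distance-decay expected
curves, observed/expected transformation, binomial depth down-sampling, and
quantile normalization across samples.

Coordinates are 0-based half-open everywhere; bin ``i`` covers
``[i*resolution, (i+1)*resolution)``.  Bins with zero marginal in the raw
matrix are masked and stay masked through every normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "BinGrid",
    "ContactMatrix",
    "DecayCurve",
    "MalformedInputError",
    "ContractError",
    "ConvergenceError",
    "EmptyInputError",
    "load_contacts",
    "kr_balance",
    "expected_by_distance",
    "observed_over_expected",
    "downsample",
    "quantile_normalize",
]


class MalformedInputError(ValueError):
    """Input file violates the format contract (bad index, negative count...)."""


class ContractError(ValueError):
    """Caller violated an operation precondition."""


class ConvergenceError(RuntimeError):
    """Iterative balancing failed to reach tolerance."""

    def __init__(self, msg: str, residual: float):
        super().__init__(msg)
        self.residual = residual


class EmptyInputError(ValueError):
    """Operation received no usable (unmasked) data."""


@dataclass(frozen=True)
class BinGrid:
    """Uniform binning of one chromosome."""

    chrom: str
    resolution: int
    n_bins: int

    def __post_init__(self):
        if self.resolution <= 0:
            raise ContractError("resolution must be positive")
        if self.n_bins <= 0:
            raise ContractError("n_bins must be positive")

    @property
    def length(self) -> int:
        return self.resolution * self.n_bins

    def bin_of(self, pos: int) -> int:
        b = int(pos) // self.resolution
        if not 0 <= b < self.n_bins:
            raise ContractError(f"position {pos} outside grid {self.chrom}")
        return b

    def start_of(self, i: int) -> int:
        return i * self.resolution

    def interval_of(self, i: int) -> tuple[int, int]:
        return i * self.resolution, (i + 1) * self.resolution


@dataclass
class ContactMatrix:
    """Symmetric intra-chromosomal contact matrix.

    ``norm_tag`` is one of ``raw``, ``KR``, ``OE``, ``quantile``.  ``weights``
    holds per-bin balancing factors (NaN on masked bins) iff the matrix is
    balanced.  ``masked`` marks bins with zero marginal in the raw matrix;
    the flag propagates through all normalizations.
    """

    grid: BinGrid
    values: np.ndarray
    norm_tag: str = "raw"
    weights: np.ndarray | None = None
    masked: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (self.grid.n_bins, self.grid.n_bins):
            raise ContractError("matrix shape does not match grid")
        if not np.allclose(v, v.T, equal_nan=True):
            raise MalformedInputError("contact matrix must be symmetric")
        if np.nanmin(v) < 0:
            raise MalformedInputError("contact values must be non-negative")
        self.values = v
        if self.masked is None:
            self.masked = v.sum(axis=0) == 0
        else:
            self.masked = np.asarray(self.masked, dtype=bool)

    @property
    def n_bins(self) -> int:
        return self.grid.n_bins

    @property
    def total_contacts(self) -> float:
        iu = np.triu_indices(self.n_bins)
        return float(self.values[iu].sum())

    @property
    def unmasked(self) -> np.ndarray:
        return ~self.masked

    def copy_with(self, values: np.ndarray, norm_tag: str, weights=None) -> "ContactMatrix":
        return ContactMatrix(self.grid, values, norm_tag, weights, self.masked.copy())


@dataclass
class DecayCurve:
    """Expected contact value per bin separation ``d = |i - j|``."""

    grid: BinGrid
    values: np.ndarray  # length n_bins, E(d) for d = 0 .. n_bins-1
    estimator: str = "median"

    @property
    def zero_strata(self) -> np.ndarray:
        return self.values == 0


def load_contacts(path, grid: BinGrid) -> ContactMatrix:
    """Read a raw matrix from sparse-triplet or dense whitespace-separated text.

    Sparse triplets are ``bin_i  bin_j  count`` rows; entries on either
    triangle are mirrored and duplicates summed.  A dense file must be an
    ``n_bins`` x ``n_bins`` table.
    """
    import warnings

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)  # empty file is valid
            data = np.loadtxt(path, ndmin=2)
    except ValueError as exc:
        raise MalformedInputError(f"cannot parse {path}: {exc}") from exc
    n = grid.n_bins
    if data.size == 0:
        return ContactMatrix(grid, np.zeros((n, n)))
    if data.shape[1] == 3 and data.shape[0] != n:
        return _from_triplets(data, grid)
    if data.shape == (n, n):
        if np.nanmin(data) < 0:
            raise MalformedInputError("negative count in dense matrix")
        m = np.maximum(data, data.T) if not np.allclose(data, data.T) else data
        return ContactMatrix(grid, m)
    if data.shape[1] == 3:
        return _from_triplets(data, grid)
    raise MalformedInputError(
        f"{path}: expected triplets or a {n}x{n} dense matrix, got shape {data.shape}"
    )


def _from_triplets(data: np.ndarray, grid: BinGrid) -> ContactMatrix:
    n = grid.n_bins
    i = data[:, 0].astype(int)
    j = data[:, 1].astype(int)
    c = data[:, 2]
    if (i < 0).any() or (i >= n).any() or (j < 0).any() or (j >= n).any():
        raise MalformedInputError("bin index outside grid")
    if (c < 0).any():
        raise MalformedInputError("negative contact count")
    m = np.zeros((n, n))
    # sum duplicates; mirror lower-triangle entries onto the upper triangle
    np.add.at(m, (np.minimum(i, j), np.maximum(i, j)), c)
    m = m + np.triu(m, 1).T
    return ContactMatrix(grid, m)


def kr_balance(m: ContactMatrix, tol: float = 1e-10, max_iter: int = 3000) -> ContactMatrix:
    """Balance a raw matrix to equal row sums over unmasked bins.

    Returns a matrix with per-bin weights ``w`` such that
    ``w[i] * values[i, j] * w[j]`` has uniform row sums on the unmasked
    submatrix, rescaled so the total contact sum matches the input.  Uses a
    damped symmetric Sinkhorn iteration ``w <- w * rowsum**-theta``; the
    equal-row-sum property, not the specific iteration, is the contract.
    """
    if m.norm_tag != "raw":
        raise ContractError("kr_balance expects a raw matrix")
    keep = m.unmasked
    if not keep.any():
        raise EmptyInputError("all bins masked")
    a = m.values[np.ix_(keep, keep)]
    k = a.shape[0]
    w = np.ones(k)
    theta = 0.5
    residual = np.inf
    for _ in range(max_iter):
        rs = w * (a @ w)
        residual = float(np.max(np.abs(rs - 1.0)))
        if residual < tol:
            break
        w = w * np.where(rs > 0, rs, 1.0) ** (-theta)
    else:
        raise ConvergenceError(
            f"balancing did not converge in {max_iter} iterations "
            f"(residual {residual:.3e})",
            residual,
        )
    balanced = (w[:, None] * a) * w[None, :]
    # restore the raw total so downstream count-scale statistics keep magnitude
    scale = m.values[np.ix_(keep, keep)].sum() / balanced.sum()
    balanced *= scale
    full = np.zeros_like(m.values)
    full[np.ix_(keep, keep)] = balanced
    weights = np.full(m.n_bins, np.nan)
    weights[keep] = w * np.sqrt(scale)
    return ContactMatrix(m.grid, full, "KR", weights, m.masked.copy())


def expected_by_distance(
    m: ContactMatrix,
    estimator: str = "median",
    domains: np.ndarray | None = None,
) -> DecayCurve:
    """Per-distance expected value over unmasked bin pairs.

    ``estimator`` is ``median`` (the field's usual choice for O/E maps) or
    ``mean``.  Masked bins are excluded from every distance stratum.  When
    ``domains`` gives a per-bin domain id (e.g. the containing TAD; negative
    means none), pairs inside one domain are excluded, yielding a background
    free of within-domain enrichment; strata left empty fall back to the
    all-pair estimate.
    """
    if estimator not in ("median", "mean"):
        raise ContractError(f"unknown estimator {estimator!r}")
    keep = m.unmasked
    if not keep.any():
        raise EmptyInputError("all bins masked")
    n = m.n_bins
    stat = np.median if estimator == "median" else np.mean
    out = np.zeros(n)
    for d in range(n):
        vals = np.diagonal(m.values, offset=d)
        ok = keep[: n - d] & keep[d:]
        if domains is not None and d > 0:
            cross = ~(
                (domains[: n - d] == domains[d:]) & (domains[: n - d] >= 0)
            )
            if (ok & cross).any():
                ok = ok & cross
        if ok.any():
            out[d] = stat(vals[ok])
    return DecayCurve(m.grid, out, estimator)


def observed_over_expected(m: ContactMatrix, decay: DecayCurve) -> ContactMatrix:
    """Divide each entry by the expected value at its distance.

    Strata with E(d)=0 are set to 0 (flagged on the decay curve via
    ``zero_strata``).
    """
    if decay.grid != m.grid:
        raise ContractError("decay curve computed on a different grid")
    n = m.n_bins
    d = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
    e = decay.values[d]
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = np.where(e > 0, m.values / np.where(e > 0, e, 1.0), 0.0)
    return m.copy_with(oe, "OE")


def downsample(m: ContactMatrix, target_total: int, seed: int) -> ContactMatrix:
    """Binomially thin a raw integer matrix to ~``target_total`` contacts."""
    if m.norm_tag != "raw":
        raise ContractError("downsample expects a raw matrix")
    vals = m.values
    if not np.allclose(vals, np.round(vals)):
        raise ContractError("downsample expects integer counts")
    total = m.total_contacts
    if target_total > total:
        raise ContractError(f"target {target_total} exceeds total {total:.0f}")
    if target_total == total:
        return m.copy_with(vals.copy(), "raw")
    rng = np.random.default_rng(seed)
    p = target_total / total
    iu = np.triu_indices(m.n_bins)
    thinned = rng.binomial(vals[iu].astype(np.int64), p)
    out = np.zeros_like(vals)
    out[iu] = thinned
    out = out + np.triu(out, 1).T
    return ContactMatrix(m.grid, out, "raw", None, None)


def quantile_normalize(ms: list[ContactMatrix]) -> list[ContactMatrix]:
    """Standard quantile normalization across matrices on one grid.

    Operates on upper-triangle entries of bins unmasked in *all* matrices, so
    the sorted value multisets of the outputs are identical.  Ties are broken
    by stable sort order, which preserves that invariant exactly.
    """
    if len(ms) < 2:
        raise ContractError("quantile normalization needs at least two matrices")
    grid = ms[0].grid
    if any(m.grid != grid for m in ms):
        raise ContractError("matrices on different grids")
    keep = np.logical_and.reduce([m.unmasked for m in ms])
    idx = np.where(keep)[0]
    iu = np.triu_indices(len(idx))
    rows, cols = idx[iu[0]], idx[iu[1]]
    vecs = [m.values[rows, cols] for m in ms]
    orders = [np.argsort(v, kind="stable") for v in vecs]
    mean_sorted = np.mean([v[o] for v, o in zip(vecs, orders)], axis=0)
    out = []
    for m, v, o in zip(ms, vecs, orders):
        nv = np.empty_like(v)
        nv[o] = mean_sorted
        vals = np.zeros_like(m.values)
        vals[rows, cols] = nv
        vals[cols, rows] = nv
        out.append(m.copy_with(vals, "quantile"))
    return out
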