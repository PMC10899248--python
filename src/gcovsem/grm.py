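"""Genetic relationship matrices: construction, GCTA-format I/O, pruning.

The GRM is the n × n matrix of average genome-wide genotypic similarity
between individuals, estimated from standardized SNP dosages,

    A_jk = (1/M) Σ_i (x_ij − 2 p_i)(x_ik − 2 p_i) / (2 p_i (1 − p_i)),

with allele frequencies p_i estimated in-sample and M the number of SNPs
non-missing for both members of the pair.  Files use the GCTA binary
dialect: ``.grm.bin`` / ``.grm.N.bin`` hold the lower triangle (diagonal
included, row-major) as little-endian float32, and ``.grm.id`` holds one
``FID IID`` pair per line.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "GenotypeMatrix",
    "GRMatrix",
    "compute_grm",
    "read_grm",
    "write_grm",
    "prune_related",
    "eigendecompose",
]

_EIG_CLAMP = 1e-10


@dataclass
class GenotypeMatrix:
    """Biallelic dosages (individuals × SNPs) with 0/1/2 coding.

    Missing entries are NaN in ``dosages``; ``allele_freqs`` are the
    alternate-allele frequencies implied by the non-missing column means.
    """

    dosages: np.ndarray
    sample_ids: np.ndarray
    allele_freqs: np.ndarray = field(default=None)

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (individuals × SNPs)")
        obs = ~np.isnan(self.dosages)
        vals = self.dosages[obs]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise ValueError("dosages must be 0, 1 or 2 (or NaN for missing)")
        self.sample_ids = np.asarray(self.sample_ids, dtype=str)
        if self.sample_ids.shape[0] != self.dosages.shape[0]:
            raise ValueError("sample_ids length does not match dosage rows")
        if self.allele_freqs is None:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                self.allele_freqs = np.nanmean(self.dosages, axis=0) / 2.0
        else:
            self.allele_freqs = np.asarray(self.allele_freqs, dtype=float)

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]


@dataclass
class GRMatrix:
    """Symmetric relationship matrix with per-pair SNP counts and IDs."""

    values: np.ndarray
    sample_ids: np.ndarray
    pair_counts: np.ndarray = field(default=None)
    family_ids: np.ndarray = field(default=None)
    _eigen: tuple = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("GRM must be square")
        if not np.allclose(self.values, self.values.T, atol=1e-12, rtol=0.0, equal_nan=True):
            raise ValueError("GRM must be symmetric within 1e-12")
        self.sample_ids = np.asarray(self.sample_ids, dtype=str)
        if self.sample_ids.shape[0] != n:
            raise ValueError("sample_ids length does not match GRM order")
        if self.family_ids is None:
            self.family_ids = self.sample_ids.copy()
        else:
            self.family_ids = np.asarray(self.family_ids, dtype=str)
        if self.pair_counts is None:
            self.pair_counts = np.zeros((n, n))
        else:
            self.pair_counts = np.asarray(self.pair_counts, dtype=float)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def eigen(self):
        """Cached ``(eigenvalues, eigenvectors)`` in non-increasing order."""
        if self._eigen is None:
            eigendecompose(self)
        return self._eigen

    def subset(self, ids) -> "GRMatrix":
        """Restrict to the given sample IDs, in the GRM's own order."""
        keep = np.isin(self.sample_ids, np.asarray(ids, dtype=str))
        idx = np.where(keep)[0]
        return GRMatrix(
            values=self.values[np.ix_(idx, idx)],
            sample_ids=self.sample_ids[idx],
            pair_counts=self.pair_counts[np.ix_(idx, idx)],
            family_ids=self.family_ids[idx],
        )


def compute_grm(genotypes: GenotypeMatrix) -> GRMatrix:
    """Estimate the GRM from 0/1/2 dosages with in-sample allele frequencies.

    Monomorphic SNPs carry no relationship information and are dropped (a
    count is reported via a warning).  Missingness is handled pairwise: each
    pair's relationship averages over the SNPs observed for both, and the
    per-pair SNP count is returned alongside.
    """
    X = genotypes.dosages
    obs = ~np.isnan(X)
    if not obs.any(axis=1).all():
        bad = genotypes.sample_ids[~obs.any(axis=1)][0]
        raise ValueError(f"individual {bad!r} has no non-missing genotypes")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p = np.nanmean(X, axis=0) / 2.0
    poly = (p > 0.0) & (p < 1.0)
    n_mono = int((~poly).sum())
    if poly.sum() == 0:
        raise ValueError("all SNPs are monomorphic; GRM undefined")
    if n_mono:
        warnings.warn(f"excluded {n_mono} monomorphic SNP(s) from the GRM")
    X = X[:, poly]
    p = p[poly]
    obs = obs[:, poly]

    denom = 2.0 * p * (1.0 - p)
    Z = (X - 2.0 * p) / np.sqrt(denom)
    Z = np.where(obs, Z, 0.0)
    counts = obs.astype(float) @ obs.T.astype(float)
    if (counts == 0).any():
        i, j = np.argwhere(counts == 0)[0]
        raise ValueError(
            f"no mutually observed SNPs for pair "
            f"({genotypes.sample_ids[i]!r}, {genotypes.sample_ids[j]!r})"
        )
    A = (Z @ Z.T) / counts
    A = (A + A.T) / 2.0
    return GRMatrix(values=A, sample_ids=genotypes.sample_ids, pair_counts=counts)


def _tri_pack(M: np.ndarray) -> np.ndarray:
    """Lower triangle (diagonal included) in row-major order."""
    i, j = np.tril_indices(M.shape[0])
    return M[i, j]


def _tri_unpack(v: np.ndarray, n: int) -> np.ndarray:
    M = np.zeros((n, n))
    i, j = np.tril_indices(n)
    M[i, j] = v
    M[j, i] = v
    return M


def write_grm(grm: GRMatrix, prefix) -> None:
    """Write ``prefix{.grm.bin,.grm.N.bin,.grm.id}`` in the GCTA dialect."""
    if not np.isfinite(grm.values).all():
        raise ValueError("GRM contains non-finite values; refusing to write")
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    _tri_pack(grm.values).astype("<f4").tofile(f"{prefix}.grm.bin")
    _tri_pack(grm.pair_counts).astype("<f4").tofile(f"{prefix}.grm.N.bin")
    with open(f"{prefix}.grm.id", "w") as fh:
        for fid, iid in zip(grm.family_ids, grm.sample_ids):
            fh.write(f"{fid}\t{iid}\n")


def read_grm(prefix) -> GRMatrix:
    """Read a GCTA-dialect GRM written by :func:`write_grm` or GCTA/PLINK."""
    prefix = Path(prefix)
    ids = []
    with open(f"{prefix}.grm.id") as fh:
        for line in fh:
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"malformed .grm.id line: {line!r}")
            ids.append((parts[0], parts[1]))
    n = len(ids)
    n_tri = n * (n + 1) // 2
    vals = np.fromfile(f"{prefix}.grm.bin", dtype="<f4")
    if vals.size != n_tri:
        raise ValueError(
            f".grm.bin holds {vals.size} floats; expected n(n+1)/2 = {n_tri} "
            f"for the {n} IDs in .grm.id"
        )
    npath = Path(f"{prefix}.grm.N.bin")
    if npath.exists():
        counts = np.fromfile(npath, dtype="<f4")
        if counts.size not in (n_tri, 1):
            raise ValueError(
                f".grm.N.bin holds {counts.size} floats; expected {n_tri} or 1"
            )
        if counts.size == 1:  # GCTA allows a single overall count
            counts = np.full(n_tri, counts[0])
    else:
        counts = np.zeros(n_tri)
    fids, iids = zip(*ids)
    return GRMatrix(
        values=_tri_unpack(vals.astype(float), n),
        pair_counts=_tri_unpack(counts.astype(float), n),
        sample_ids=np.array(iids, dtype=str),
        family_ids=np.array(fids, dtype=str),
    )


def prune_related(grm: GRMatrix, cutoff: float = 0.05) -> np.ndarray:
    """Drop individuals until no pair relates above ``cutoff``.

    Greedy: repeatedly remove the individual with the most above-cutoff
    partners (ties broken by input order), so the retained set is free of
    pairs with off-diagonal relationship > cutoff.  Returns retained IDs in
    input order.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    A = grm.values.copy()
    np.fill_diagonal(A, -np.inf)
    over = A > cutoff
    active = np.ones(grm.n, dtype=bool)
    deg = over.sum(axis=1)
    while True:
        deg_active = np.where(active, deg, -1)
        worst = int(np.argmax(deg_active))
        if deg_active[worst] <= 0:
            break
        active[worst] = False
        deg = deg - over[:, worst].astype(int)
        over[worst, :] = False
        over[:, worst] = False
        deg[worst] = 0
    return grm.sample_ids[active]


def eigendecompose(grm: GRMatrix):
    """Eigendecompose G = U diag(d) Uᵀ; caches and returns ``(d, U)``.

    Eigenvalues come back in non-increasing order; values below 1e-10 are
    clamped to zero (with a warning) so near-singular GRMs stay usable in
    downstream likelihood work.
    """
    if not np.isfinite(grm.values).all():
        raise ValueError("GRM contains non-finite entries")
    d, U = np.linalg.eigh(grm.values)
    d, U = d[::-1].copy(), U[:, ::-1].copy()
    tiny = d < _EIG_CLAMP
    if tiny.any() and (d[tiny] != 0).any():
        warnings.warn(
            f"clamped {int(tiny.sum())} eigenvalue(s) below {_EIG_CLAMP:g} to 0"
        )
        d[tiny] = 0.0
    grm._eigen = (d, U)
    return d, U
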