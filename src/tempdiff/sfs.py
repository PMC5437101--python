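"""Site-frequency-spectrum containers, projection, folding and file I/O.

A :class:`JointSFS` is a dense grid over derived-allele configurations:
entry ``(i, j)`` holds the count (or model expectation) of sites with
``i`` derived copies in the population-1 sample and ``j`` in the
population-2 sample.  Single-population spectra are the 1-D special
case.  The absorbing corners -- all-ancestral and all-derived -- carry
no information about segregating variation and are always masked, as is
standard for composite-likelihood fitting of SNP data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

__all__ = ["JointSFS", "project_sfs", "fold_sfs", "projection_weights"]


@dataclass
class JointSFS:
    """A (joint) site frequency spectrum with a validity mask.

    ``data`` has shape ``(n1+1,)`` or ``(n1+1, n2+1)``; ``mask`` is True
    where a cell is *excluded*.  ``folded`` records whether entries are
    indexed by minor-allele configuration.  ``se`` optionally carries
    per-cell Monte Carlo standard errors for model expectations.
    """

    data: np.ndarray
    mask: np.ndarray | None = None
    folded: bool = False
    se: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim not in (1, 2):
            raise ValueError("SFS must be 1-D or 2-D")
        if self.mask is None:
            self.mask = self.corner_mask(self.data.shape)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.data.shape:
                raise ValueError("mask shape must match data shape")
            self.mask = self.mask | self.corner_mask(self.data.shape)
        if np.any(self.data[~self.mask] < 0):
            raise ValueError("unmasked SFS entries must be >= 0")

    @staticmethod
    def corner_mask(shape: tuple[int, ...]) -> np.ndarray:
        mask = np.zeros(shape, dtype=bool)
        mask[(0,) * len(shape)] = True
        mask[tuple(s - 1 for s in shape)] = True
        return mask

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def sample_sizes(self) -> tuple[int, ...]:
        return tuple(s - 1 for s in self.data.shape)

    def unmasked_sum(self) -> float:
        return float(self.data[~self.mask].sum())

    def copy(self) -> "JointSFS":
        return JointSFS(self.data.copy(), self.mask.copy(), self.folded,
                        None if self.se is None else self.se.copy())

    # -- persistence --------------------------------------------------------

    def save(self, path) -> None:
        """Plain-text format: header `n1 [n2] folded`, row-major entries, NA masked."""
        header = " ".join(str(n) for n in self.sample_sizes)
        header += f" {int(self.folded)}"
        flat = self.data.ravel()
        cells = [
            "NA" if m else repr(float(v))
            for v, m in zip(flat, self.mask.ravel())
        ]
        with open(path, "w") as fh:
            fh.write(header + "\n")
            fh.write(" ".join(cells) + "\n")

    @classmethod
    def load(cls, path) -> "JointSFS":
        with open(path) as fh:
            header = fh.readline().split()
            body = fh.read().split()
        *ns, folded = (int(x) for x in header)
        shape = tuple(n + 1 for n in ns)
        data = np.zeros(shape)
        mask = np.zeros(shape, dtype=bool)
        if len(body) != data.size:
            raise ValueError(
                f"expected {data.size} cells for sample sizes {ns}, got {len(body)}"
            )
        flat_d, flat_m = data.ravel(), mask.ravel()
        for idx, tok in enumerate(body):
            if tok == "NA":
                flat_m[idx] = True
            else:
                flat_d[idx] = float(tok)
        return cls(data, mask, bool(folded))


def projection_weights(n: int, m: int) -> np.ndarray:
    """Hypergeometric down-sampling matrix W of shape (m+1, n+1).

    ``W[a, i]`` is the probability that a uniform draw of ``m`` of ``n``
    haplotypes contains ``a`` of the ``i`` derived copies:
    ``C(i, a) * C(n - i, m - a) / C(n, m)``.
    """
    if m > n:
        raise ValueError(f"cannot project {n} haplotypes up to {m}")
    i = np.arange(n + 1)[None, :]
    a = np.arange(m + 1)[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        logw = (
            _log_comb(i, a)
            + _log_comb(n - i, m - a)
            - _log_comb(n, m)
        )
    w = np.where(np.isfinite(logw), np.exp(logw), 0.0)
    return w


def _log_comb(n, k):
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    bad = (k < 0) | (k > n)
    with np.errstate(invalid="ignore"):
        out = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    return np.where(bad, -np.inf, out)


def project_sfs(sfs: JointSFS, *m: int) -> JointSFS:
    """Hypergeometrically project an SFS down to sample sizes ``m``.

    Masked cells contribute nothing; corners are re-masked afterwards.
    """
    ns = sfs.sample_sizes
    if len(m) != len(ns):
        raise ValueError("one target size per population required")
    data = np.where(sfs.mask, 0.0, sfs.data)
    for axis, (n, mm) in enumerate(zip(ns, m)):
        w = projection_weights(n, mm)
        data = np.tensordot(w, data, axes=(1, axis))
        data = np.moveaxis(data, 0, axis)
    return JointSFS(data, None, sfs.folded)


def fold_sfs(sfs: JointSFS) -> JointSFS:
    """Fold an unfolded spectrum onto minor-allele configurations.

    Cell ``(i, j)`` is combined with its mirror ``(n1-i, n2-j)``; cells
    whose total derived count exceeds half the total sample size are
    masked, and self-conjugate cells (total exactly half) are averaged
    so the unmasked mass is conserved.
    """
    if sfs.folded:
        raise ValueError("spectrum is already folded")
    data = np.where(sfs.mask, 0.0, sfs.data)
    rev = data[tuple(slice(None, None, -1) for _ in range(data.ndim))]
    total = sum(
        np.arange(s).reshape([-1 if a == ax else 1 for a in range(data.ndim)])
        for ax, s in enumerate(data.shape)
    )
    ntot = sum(sfs.sample_sizes)
    folded = data + rev
    folded = np.where(total * 2 == ntot, folded / 2.0, folded)
    rev_mask = sfs.mask[tuple(slice(None, None, -1) for _ in range(data.ndim))]
    mask = (total * 2 > ntot) | (sfs.mask & rev_mask)
    folded = np.where(mask, 0.0, folded)
    return JointSFS(folded, mask, True)
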