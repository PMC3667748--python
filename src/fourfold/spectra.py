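"""Observed folded site-frequency spectra with a monomorphic class.

The observed spectrum is the atom the likelihood consumes: counts k_x of
sites whose folded minor-allele count is x, for x = 0..floor(n/2), at a
uniform sample depth n.  k_0 counts monomorphic sites, so L = sum(k) is
the total number of sites and m = L - k_0 the number of segregating ones.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np

__all__ = ["ObservedSpectrum"]


@dataclass
class ObservedSpectrum:
    """Folded SFS including the zero-frequency (monomorphic) class."""

    n: int
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1 or len(self.counts) != self.n // 2 + 1:
            raise ValueError(
                f"folded spectrum at n={self.n} needs {self.n // 2 + 1} classes, "
                f"got {len(self.counts)}"
            )
        if np.any(self.counts < 0):
            raise ValueError("negative class count")

    @property
    def L(self) -> int:
        """Total number of sites."""
        return int(self.counts.sum())

    @property
    def m(self) -> int:
        """Number of segregating sites."""
        return int(self.counts[1:].sum())

    @property
    def density(self) -> float:
        """Fraction of sites segregating, m/L."""
        return self.m / self.L

    # -- plain-text round trip -------------------------------------------

    def to_text(self, **metadata) -> str:
        buf = io.StringIO()
        buf.write(f"# n={self.n}\n")
        for key, val in metadata.items():
            buf.write(f"# {key}={val}\n")
        for j, k in enumerate(self.counts):
            buf.write(f"{j}\t{k}\n")
        return buf.getvalue()

    def save(self, path, **metadata) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_text(**metadata))

    @classmethod
    def from_text(cls, text: str) -> "ObservedSpectrum":
        n = None
        counts: list[int] = []
        for line in text.splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if line[1:].strip().startswith("n="):
                    n = int(line.split("=", 1)[1])
                continue
            idx, val = line.split("\t")
            if int(idx) != len(counts):
                raise ValueError("spectrum classes out of order")
            counts.append(int(round(float(val))))
        if n is None:
            raise ValueError("spectrum file lacks '# n=' header")
        return cls(n=n, counts=np.array(counts, dtype=np.int64))

    @classmethod
    def load(cls, path) -> "ObservedSpectrum":
        with open(path) as fh:
            return cls.from_text(fh.read())
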