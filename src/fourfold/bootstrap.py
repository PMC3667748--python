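"""Matched-pair bootstrap for the missing-polymorphism fraction.

4D sites carry a higher GC content than short introns (about 64% vs 31%
in *D. melanogaster*), and mutation is AT-biased, so a naive comparison
of SNP densities confounds selection with mutation rate.  The matched
bootstrap removes this: every test (4D) site is paired with nearby
(within 1 kb on the same chromosome arm) reference sites sharing its
major allele, pairs are drawn with replacement — a fresh partner drawn
per occurrence of a test site — until as many pairs are drawn as there
are pairable test sites, and the deficit

    1 - (segregating fraction of drawn test sites)
      / (segregating fraction of drawn reference sites)

is averaged over replicates, with the replicate SD as its standard
error.  Matching on the major allele equalises GC composition exactly;
drawing partners locally cancels regional mutation/diversity structure.

Variants: matching the ordered major-allele triplet (site plus 5'/3'
neighbours) controls context-dependent mutation; dropping the distance
predicate keeps only the GC control; and slow-evolving 4D sites can be
paired against fast-evolving 4D sites as an internal neutral reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .sites import build_spectrum
from .spectra import ObservedSpectrum

__all__ = [
    "PairIndex",
    "BootstrapEstimate",
    "build_pair_index",
    "bootstrap_deficit",
    "paired_spectra",
    "fast_vs_slow_pairing",
    "naive_deficit",
]


@dataclass
class PairIndex:
    """Eligible test sites with their candidate reference partners.

    Reference sites are stored grouped (by chromosome arm and matching
    key) and position-sorted; each pairable test site holds a half-open
    [lo, hi) range into that ordering.  Memory stays linear in the
    number of sites.
    """

    test_minor: np.ndarray  # folded minor counts of pairable test sites
    ref_minor: np.ndarray  # folded minor counts of grouped/sorted ref sites
    lo: np.ndarray
    hi: np.ndarray
    n: int  # uniform sample depth
    n_test_total: int
    n_ref_total: int
    mode: str
    max_dist: Optional[int]

    @property
    def n_pairable(self) -> int:
        return len(self.test_minor)

    @property
    def coverage(self) -> float:
        """Fraction of test sites with at least one eligible partner."""
        return self.n_pairable / self.n_test_total

    def __len__(self) -> int:
        return self.n_pairable


@dataclass
class BootstrapEstimate:
    """Missing-polymorphism fraction with replicate values and SE."""

    replicate_deficits: np.ndarray
    n_pairs_drawn: int
    coverage: float
    n_excluded_replicates: int = 0

    @property
    def mean_deficit(self) -> float:
        return float(np.mean(self.replicate_deficits))

    @property
    def se(self) -> float:
        if len(self.replicate_deficits) < 2:
            return np.nan
        return float(np.std(self.replicate_deficits, ddof=1))

    def __repr__(self) -> str:
        return (
            f"BootstrapEstimate(mean_deficit={self.mean_deficit:.4f}, "
            f"se={self.se:.4f}, n_boot={len(self.replicate_deficits)}, "
            f"n_pairs_drawn={self.n_pairs_drawn}, coverage={self.coverage:.3f})"
        )


def _matching_key(df: pd.DataFrame, mode: str) -> pd.Series:
    if mode in ("major_allele", "none"):
        return df["chrom"].astype(str) + ":" + df["major_allele"].astype(str)
    if mode == "triplet":
        col = "attr:triplet"
        if col not in df.columns:
            raise ValueError("triplet mode needs an 'attr:triplet' column")
        return df["chrom"].astype(str) + ":" + df[col].astype(str)
    raise ValueError(f"unknown pairing mode {mode!r}")


def build_pair_index(
    test_sites: pd.DataFrame,
    ref_sites: pd.DataFrame,
    mode: str = "major_allele",
    max_dist: int = 1000,
) -> PairIndex:
    """Pair each test site with the eligible reference sites.

    A pair must lie on the same chromosome arm and share its major
    allele ('major_allele' mode) or its ordered major-allele triplet
    ('triplet' mode), and lie within ``max_dist`` bp (inclusive).  Mode
    'none' keeps the allele predicate but drops the distance predicate.
    Test sites without a partner are excluded and counted via
    ``coverage``.
    """
    depths = set(test_sites["called_depth"].unique()) | set(
        ref_sites["called_depth"].unique()
    )
    if len(depths) != 1:
        raise ValueError(f"pairing requires one uniform depth, got {sorted(depths)}")
    n = int(depths.pop())

    tkey = _matching_key(test_sites, mode)
    rkey = _matching_key(ref_sites, mode)

    ref = pd.DataFrame(
        {
            "key": rkey.to_numpy(),
            "pos": ref_sites["pos"].to_numpy(),
            "minor": ref_sites["minor_count"].to_numpy(),
        }
    ).sort_values(["key", "pos"], kind="mergesort", ignore_index=True)
    # contiguous slice of the sorted ref array per key
    starts = ref.groupby("key", sort=False).indices
    key_bounds = {k: (idx[0], idx[-1] + 1) for k, idx in starts.items()}

    ref_pos = ref["pos"].to_numpy()
    test_pos = test_sites["pos"].to_numpy()
    test_minor_all = test_sites["minor_count"].to_numpy()

    lo = np.zeros(len(test_sites), dtype=np.int64)
    hi = np.zeros(len(test_sites), dtype=np.int64)
    # vectorised per matching key: all test sites sharing a key hit the
    # same contiguous slice of the sorted reference array
    tkeys = pd.Series(tkey.to_numpy())
    for key, tidx in tkeys.groupby(tkeys, sort=False).indices.items():
        bounds = key_bounds.get(key)
        if bounds is None:
            continue
        a, b = bounds
        if mode == "none" or max_dist is None:
            lo[tidx], hi[tidx] = a, b
        else:
            p = test_pos[tidx]
            lo[tidx] = a + np.searchsorted(ref_pos[a:b], p - max_dist, side="left")
            hi[tidx] = a + np.searchsorted(ref_pos[a:b], p + max_dist, side="right")

    pairable = hi > lo
    if not pairable.any():
        raise ValueError(
            f"no pairable test sites (mode={mode}, max_dist={max_dist}; "
            f"{len(test_sites)} test, {len(ref_sites)} ref sites)"
        )
    return PairIndex(
        test_minor=test_minor_all[pairable].astype(np.int64),
        ref_minor=ref["minor"].to_numpy().astype(np.int64),
        lo=lo[pairable],
        hi=hi[pairable],
        n=n,
        n_test_total=len(test_sites),
        n_ref_total=len(ref_sites),
        mode=mode,
        max_dist=None if mode == "none" else max_dist,
    )


def _draw_replicate(index: PairIndex, rng) -> tuple[np.ndarray, np.ndarray]:
    """One bootstrap replicate: N pairs drawn with replacement.

    Each draw picks a pairable test site uniformly, then independently
    one of its partners; a test site drawn twice redraws its partner.
    """
    N = index.n_pairable
    t = rng.integers(0, N, size=N)
    span = index.hi[t] - index.lo[t]
    r = index.lo[t] + rng.integers(0, span)
    return index.test_minor[t], index.ref_minor[r]


def bootstrap_deficit(
    index: PairIndex, n_boot: int = 10, seed=None
) -> BootstrapEstimate:
    """Replicate deficits 1 - density(test)/density(ref) over paired draws."""
    rng = np.random.default_rng(seed)
    deficits = []
    excluded = 0
    for _ in range(n_boot):
        tm, rm = _draw_replicate(index, rng)
        ref_density = np.count_nonzero(rm) / len(rm)
        if ref_density == 0.0:
            excluded += 1
            warnings.warn("replicate with zero reference density excluded")
            continue
        test_density = np.count_nonzero(tm) / len(tm)
        deficits.append(1.0 - test_density / ref_density)
    return BootstrapEstimate(
        replicate_deficits=np.array(deficits),
        n_pairs_drawn=index.n_pairable,
        coverage=index.coverage,
        n_excluded_replicates=excluded,
    )


def paired_spectra(
    index: PairIndex, n_boot: int = 10, seed=None
) -> list[tuple[ObservedSpectrum, ObservedSpectrum]]:
    """Folded (test, reference) spectra per bootstrap replicate.

    Both spectra count exactly N = n_pairable sites by construction, so
    they can be fed straight into the mixture-model fit; identical seeds
    reproduce the draws of :func:`bootstrap_deficit`.
    """
    rng = np.random.default_rng(seed)
    half = index.n // 2
    out = []
    for _ in range(n_boot):
        tm, rm = _draw_replicate(index, rng)
        ts = ObservedSpectrum(
            n=index.n, counts=np.bincount(tm, minlength=half + 1).astype(np.int64)
        )
        rs = ObservedSpectrum(
            n=index.n, counts=np.bincount(rm, minlength=half + 1).astype(np.int64)
        )
        out.append((ts, rs))
    return out


def fast_vs_slow_pairing(
    sites_4d: pd.DataFrame,
    slow_bins: list[str],
    fast_bins: list[str],
    bin_column: str = "attr:rate_bin",
    max_dist: int = 1000,
    n_boot: int = 10,
    seed=None,
) -> BootstrapEstimate:
    """Deficit of slow-evolving 4D sites against fast-evolving 4D sites.

    Uses the fastest-evolving 4D sites themselves as the neutral
    reference, removing any mutational difference between 4D sites and
    introns from the comparison.  ``bin_column`` carries substitution-
    rate bin labels (see the stratification module).
    """
    if bin_column not in sites_4d.columns:
        raise ValueError(f"sites lack rate-bin column {bin_column!r}")
    slow = sites_4d[sites_4d[bin_column].isin(slow_bins)]
    fast = sites_4d[sites_4d[bin_column].isin(fast_bins)]
    if len(slow) == 0 or len(fast) == 0:
        raise ValueError(
            f"empty pairing input: {len(slow)} slow sites ({slow_bins}), "
            f"{len(fast)} fast sites ({fast_bins})"
        )
    index = build_pair_index(slow, fast, mode="major_allele", max_dist=max_dist)
    return bootstrap_deficit(index, n_boot=n_boot, seed=seed)


def naive_deficit(test_sites: pd.DataFrame, ref_sites: pd.DataFrame) -> float:
    """Unmatched density comparison 1 - density(test)/density(ref).

    The quantity the matched bootstrap exists to correct: it confounds
    selection with GC-dependent mutation rate and regional structure.
    """
    td = np.count_nonzero(test_sites["minor_count"]) / len(test_sites)
    rd = np.count_nonzero(ref_sites["minor_count"]) / len(ref_sites)
    return 1.0 - td / rd
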