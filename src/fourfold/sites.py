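"""Per-site polymorphism records: loading, filtering, depth resampling.

The site table is a TSV with one row per candidate site — a 4-fold
degenerate (4D) third codon position or an interior short-intron (SI)
position — carrying its alleles, folded minor-allele count, the number
of chromosomes with a call, and optional codon/conservation annotations.
Columns use '.' for absent values; extra ``attr:<name>`` columns are
carried through as open annotations.

All analyses run at a uniform sample depth: sites called in fewer than
``min_called`` chromosomes are dropped and deeper sites are resampled to
``depth_target`` chromosomes by hypergeometric subsampling, re-labelling
SNPs that lose their minor allele as monomorphic.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from enum import Enum
from typing import Optional, Union

import numpy as np
import pandas as pd

from .spectra import ObservedSpectrum

__all__ = [
    "SiteClass",
    "SiteRecord",
    "MANDATORY_COLUMNS",
    "OPTIONAL_COLUMNS",
    "load_site_table",
    "site_records",
    "write_site_table",
    "filter_and_resample",
    "trim_short_intron_positions",
    "build_spectrum",
]


class SiteClass(str, Enum):
    FOURFOLD = "4D"
    SHORT_INTRON = "SI"


#: amino acids with four-fold degenerate codon families
FOURFOLD_AMINO_ACIDS = frozenset("PATGV")

MANDATORY_COLUMNS = (
    "chrom",
    "pos",
    "site_class",
    "major_allele",
    "minor_allele",
    "minor_count",
    "called_depth",
    "n_alleles",
)
OPTIONAL_COLUMNS = (
    "gene_id",
    "codon_anc",
    "amino_acid",
    "preference",
    "subst_count",
)

_NUCLEOTIDES = ("A", "C", "G", "T")


@dataclass
class SiteRecord:
    """One candidate genomic site — the atom of all analyses."""

    chrom: str
    pos: int
    site_class: SiteClass
    major_allele: str
    minor_allele: Optional[str]
    minor_count: int
    called_depth: int
    n_alleles: int
    gene_id: Optional[str] = None
    codon_anc: Optional[str] = None
    amino_acid: Optional[str] = None
    preference: Optional[str] = None
    subst_count: Optional[float] = None
    attrs: dict = dc_field(default_factory=dict)

    def validate(self) -> None:
        if self.major_allele not in _NUCLEOTIDES:
            raise ValueError(f"bad major allele {self.major_allele!r}")
        if self.minor_allele is not None and self.minor_allele not in _NUCLEOTIDES:
            raise ValueError(f"bad minor allele {self.minor_allele!r}")
        if not 0 <= self.minor_count <= self.called_depth:
            raise ValueError(
                f"minor_count {self.minor_count} outside 0..{self.called_depth}"
            )
        if (self.minor_count == 0) != (self.minor_allele is None):
            raise ValueError("minor_count=0 must coincide with an absent minor allele")
        if self.n_alleles < 1:
            raise ValueError("n_alleles must be >= 1")
        if (
            self.site_class is SiteClass.FOURFOLD
            and self.amino_acid is not None
            and self.amino_acid not in FOURFOLD_AMINO_ACIDS
        ):
            raise ValueError(
                f"4D site annotated with non-4D amino acid {self.amino_acid!r}"
            )


def _read_frame(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        na_values=["."],
        keep_default_na=False,
        dtype={"chrom": str},
        low_memory=False,
    )
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"site table lacks mandatory column(s): {', '.join(missing)}")
    return df


def _validate_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a site DataFrame in place; raise with 1-based data line numbers."""
    classes = set(SiteClass)
    bad_class = ~df["site_class"].isin([c.value for c in SiteClass])
    if bad_class.any():
        lines = (df.index[bad_class] + 2).tolist()[:10]
        vals = df.loc[bad_class, "site_class"].unique()[:5]
        raise ValueError(
            f"unknown site_class value(s) {list(vals)} at line(s) {lines}"
        )
    problems = []
    minor = df["minor_allele"]
    mono_mismatch = (df["minor_count"] == 0) != minor.isna()
    for cond, msg in [
        (~df["major_allele"].isin(_NUCLEOTIDES), "bad major_allele"),
        (~(minor.isna() | minor.isin(_NUCLEOTIDES)), "bad minor_allele"),
        (df["minor_count"] < 0, "negative minor_count"),
        (df["minor_count"] > df["called_depth"], "minor_count exceeds called_depth"),
        (mono_mismatch, "minor_count=0 must coincide with absent minor_allele"),
        (df["n_alleles"] < 1, "n_alleles < 1"),
    ]:
        if cond.any():
            problems.append(f"{msg} at line(s) {(df.index[cond] + 2).tolist()[:10]}")
    if problems:
        raise ValueError("malformed site table: " + "; ".join(problems))
    return df


def load_site_table(
    path, as_records: bool = False
) -> Union[pd.DataFrame, list[SiteRecord]]:
    """Load and validate a site-table TSV.

    Returns a validated DataFrame by default (the container every bulk
    operation consumes); ``as_records=True`` materialises a list of
    ``SiteRecord`` instead.  Rows with more than two alleles are loaded
    as-is (a downstream filter removes them); malformed rows raise with
    their line numbers.
    """
    df = _validate_frame(_read_frame(path))
    return site_records(df) if as_records else df


def site_records(df: pd.DataFrame) -> list[SiteRecord]:
    """Convert a validated site DataFrame to SiteRecord objects."""
    attr_cols = [c for c in df.columns if c.startswith("attr:")]
    out = []
    for d in df.to_dict("records"):
        rec = SiteRecord(
            chrom=str(d["chrom"]),
            pos=int(d["pos"]),
            site_class=SiteClass(d["site_class"]),
            major_allele=d["major_allele"],
            minor_allele=None if pd.isna(d["minor_allele"]) else d["minor_allele"],
            minor_count=int(d["minor_count"]),
            called_depth=int(d["called_depth"]),
            n_alleles=int(d["n_alleles"]),
            gene_id=None if pd.isna(d.get("gene_id")) else str(d["gene_id"]),
            codon_anc=None if pd.isna(d.get("codon_anc")) else d["codon_anc"],
            amino_acid=None if pd.isna(d.get("amino_acid")) else d["amino_acid"],
            preference=None if pd.isna(d.get("preference")) else d["preference"],
            subst_count=None if pd.isna(d.get("subst_count")) else float(d["subst_count"]),
            attrs={c[5:]: d[c] for c in attr_cols if not pd.isna(d.get(c))},
        )
        out.append(rec)
    return out


def write_site_table(df: pd.DataFrame, path, **provenance) -> None:
    """Write a site DataFrame as TSV with '.' for absent values.

    Provenance key-value pairs (seed, config hash, ...) are written as
    '#'-prefixed header lines.
    """
    with open(path, "w") as fh:
        for key, val in provenance.items():
            fh.write(f"# {key}={val}\n")
        df.to_csv(fh, sep="\t", index=False, na_rep=".")


def filter_and_resample(
    sites: pd.DataFrame,
    depth_target: int = 130,
    min_called: int = 130,
    rng=None,
) -> pd.DataFrame:
    """Normalise every site to exactly ``depth_target`` chromosomes.

    Sites called in fewer than ``min_called`` chromosomes and sites with
    more than two alleles are removed.  Deeper sites are subsampled
    without replacement (the minor-allele count after subsampling is
    hypergeometric); SNPs whose minor allele is lost are re-labelled
    monomorphic, and counts are re-folded if the former minor allele
    becomes the majority of the subsample.  Deterministic under a fixed
    ``rng`` seed; chrom/pos are never altered.
    """
    rng = np.random.default_rng(rng)
    keep = (sites["called_depth"] >= min_called) & (sites["n_alleles"] <= 2)
    df = sites.loc[keep].copy()
    if len(df) == 0:
        import warnings

        warnings.warn("no sites meet the depth/allele filters; empty result")
        return df

    depth = df["called_depth"].to_numpy()
    minor = df["minor_count"].to_numpy().copy()
    deep = depth > depth_target
    if deep.any():
        minor[deep] = rng.hypergeometric(
            minor[deep], depth[deep] - minor[deep], depth_target
        )
    # re-fold: if the old minor allele now exceeds half the subsample it
    # has become the major allele
    flip = minor > depth_target - minor
    folded = np.where(flip, depth_target - minor, minor)

    major = df["major_allele"].to_numpy(dtype=object)
    minor_al = df["minor_allele"].to_numpy(dtype=object)
    if flip.any():
        major[flip], minor_al[flip] = minor_al[flip].copy(), major[flip].copy()
    lost = folded == 0
    minor_al[lost] = np.nan

    df["minor_count"] = folded
    df["major_allele"] = major
    df["minor_allele"] = minor_al
    df["called_depth"] = depth_target
    df["n_alleles"] = np.where(folded > 0, 2, 1)
    return df


def trim_short_intron_positions(
    intron_start: int, intron_end: int, strand: str = "+"
) -> np.ndarray:
    """Interior positions of a short intron used as neutral reference.

    Introns must be shorter than 86 bp; positions within 16 bp of the 5'
    (transcriptional start) boundary and within 6 bp of the 3' boundary
    are trimmed.  Returns retained genomic coordinates (1-based,
    ascending); empty for introns of length >= 86 or too short to retain
    anything.
    """
    if intron_end < intron_start:
        raise ValueError("intron_end before intron_start")
    if strand not in ("+", "-"):
        raise ValueError(f"bad strand {strand!r}")
    length = intron_end - intron_start + 1
    if length >= 86 or length <= 22:
        return np.array([], dtype=np.int64)
    # offsets within the intron, 1-based from the 5' end in transcription
    # orientation: keep strictly more than 16 bp from the 5' boundary and
    # more than 6 bp from the 3' boundary
    offsets = np.arange(17, length - 6 + 1)
    if strand == "+":
        return intron_start + offsets - 1
    return np.sort(intron_end - offsets + 1)


def build_spectrum(sites: pd.DataFrame, n: int = 130) -> ObservedSpectrum:
    """Fold site minor-allele counts into an ObservedSpectrum at depth n."""
    depths = sites["called_depth"].unique()
    if len(depths) > 1 or (len(depths) == 1 and depths[0] != n):
        raise ValueError(
            f"sites must be at uniform depth {n}; found depths {sorted(depths)[:5]}"
        )
    counts = np.bincount(sites["minor_count"].to_numpy(), minlength=n // 2 + 1)
    if len(counts) > n // 2 + 1:
        raise ValueError("minor_count above floor(n/2); fold the table first")
    return ObservedSpectrum(n=n, counts=counts.astype(np.int64))
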