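"""Site and gene stratifications for the constraint analyses.

Groups 4D sites by substitution-rate class, codon identity and
preference, genic features (distance to translation start/stop, splice
junctions, exon count, length tertiles, X vs autosome) and gene-level
attributes (expression tertiles, codon-bias metrics), then estimates the
missing-polymorphism fraction within each group with the matched
bootstrap.  Also ranks genes by a surrogate for extensive strong
constraint: among SNP-free 4D sites in conserved amino acids, the
fraction that are unpreferred and fully conserved (zero substitutions).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .bootstrap import BootstrapEstimate, bootstrap_deficit, build_pair_index

__all__ = [
    "RateBins",
    "PreferenceTable",
    "GeneRanking",
    "bin_by_substitutions",
    "classify_preference",
    "polarize",
    "annotate_positional_features",
    "group_and_estimate",
    "rank_genes_surrogate",
    "tertiles",
]

#: default substitution-count bin boundaries: b1 is exactly 0 and the
#: open/closed pattern is (0,1.4], (1.4,1.92], (1.92,3.10], (3.10,4.40],
#: (4.40,6.20], (6.20,9.30), [9.30,inf)
DEFAULT_RATE_BOUNDARIES = (1.4, 1.92, 3.10, 4.40, 6.20, 9.30)

#: optimal codon per four-fold amino acid (D. melanogaster, G/C-ending)
DEFAULT_OPTIMAL_CODONS = {"A": "GCC", "G": "GGC", "P": "CCC", "T": "ACC", "V": "GTG"}

_FOURFOLD_FAMILY = {"GC": "A", "GG": "G", "CC": "P", "AC": "T", "GT": "V"}


@dataclass(frozen=True)
class RateBins:
    """Ordered substitution-count bins partitioning [0, inf)."""

    boundaries: tuple = DEFAULT_RATE_BOUNDARIES

    def __post_init__(self) -> None:
        b = self.boundaries
        if any(b[i] >= b[i + 1] for i in range(len(b) - 1)) or b[0] <= 0:
            raise ValueError("boundaries must be positive and strictly increasing")

    @property
    def labels(self) -> list[str]:
        return [f"b{i + 1}" for i in range(len(self.boundaries) + 2)]

    def assign(self, subst_count: np.ndarray) -> np.ndarray:
        """Bin label per site; b1 requires exactly zero substitutions."""
        x = np.asarray(subst_count, float)
        if np.any(x < 0) or np.any(np.isnan(x)):
            raise ValueError("substitution counts must be non-negative and present")
        # searchsorted over (0, b_1, ..., b_k) with right-closed interior
        # bins; the top bin is closed on the left (>= last boundary)
        edges = np.array((0.0,) + self.boundaries)
        idx = np.searchsorted(edges, x, side="left")
        idx[x == edges[-1]] = len(edges)  # 9.30 belongs to the top bin
        labels = np.array(self.labels, dtype=object)
        return labels[idx]


@dataclass(frozen=True)
class PreferenceTable:
    """Amino acid -> optimal (translationally preferred) codon."""

    optimal: dict = field(default_factory=lambda: dict(DEFAULT_OPTIMAL_CODONS))

    def __post_init__(self) -> None:
        for aa, codon in self.optimal.items():
            if _FOURFOLD_FAMILY.get(codon[:2]) != aa:
                raise ValueError(f"{codon} does not encode 4D amino acid {aa}")


def classify_preference(codon: str, table: Optional[PreferenceTable] = None) -> str:
    """'P' if the codon is its amino acid's optimal codon, else 'U'."""
    table = table or PreferenceTable()
    codon = codon.upper()
    aa = _FOURFOLD_FAMILY.get(codon[:2])
    if aa is None or len(codon) != 3:
        raise ValueError(f"{codon!r} is not a four-fold degenerate codon")
    return "P" if codon == table.optimal[aa] else "U"


def polarize(
    major_allele: str,
    minor_allele: Optional[str],
    outgroup_allele: Optional[str],
    context: str = "single_outgroup",
) -> tuple[str, str]:
    """Infer the ancestral allele by parsimony against an outgroup.

    single_outgroup: the outgroup allele is ancestral when it matches
    either *melanogaster* allele; otherwise the major allele is used
    (method 'MAJOR_FALLBACK') so that no sites are dropped and SNP
    densities are unchanged by polarization.  ten_species: the deep
    outgroup consensus must match an allele, else 'UNPOLARIZED'.

    Returns (ancestral allele or 'UNPOLARIZED', method).
    """
    if context not in ("single_outgroup", "ten_species", "none"):
        raise ValueError(f"unknown polarization context {context!r}")
    if context == "none":
        return major_allele, "MAJOR"
    if outgroup_allele is None:
        if context == "single_outgroup":
            raise ValueError("single_outgroup polarization needs an outgroup allele")
        return "UNPOLARIZED", "NO_OUTGROUP"
    alleles = {major_allele} | ({minor_allele} if minor_allele else set())
    if outgroup_allele in alleles:
        return outgroup_allele, "PARSIMONY"
    if context == "single_outgroup":
        return major_allele, "MAJOR_FALLBACK"
    return "UNPOLARIZED", "MISMATCH"


def tertiles(values: pd.Series) -> pd.Series:
    """Split into 'low'/'medium'/'high' thirds of equal size (±1).

    Ties are broken by the stable order of the index (gene identifier),
    so the grouping is deterministic.
    """
    order = values.sort_values(kind="mergesort").index
    k = len(order)
    labels = pd.Series(index=values.index, dtype=object)
    labels.loc[order[: k // 3]] = "low"
    labels.loc[order[k // 3 : k - (k // 3) - (k % 3 == 2)]] = "medium"
    labels.loc[order[k - (k // 3) - (k % 3 == 2) :]] = "high"
    return labels


def bin_by_substitutions(
    sites: pd.DataFrame, bins: Optional[RateBins] = None
) -> dict[str, pd.DataFrame]:
    """Partition sites into substitution-rate classes (b1..b8 by default)."""
    bins = bins or RateBins()
    labels = bins.assign(sites["subst_count"].to_numpy())
    out = {}
    for lab in bins.labels:
        sub = sites.loc[labels == lab]
        if len(sub):
            out[lab] = sub
    return out


def annotate_positional_features(
    sites: pd.DataFrame, gene_models: pd.DataFrame
) -> pd.DataFrame:
    """Attach genic-feature attributes to 4D sites.

    Gene models carry gene_id, chrom, strand, exon_starts/exon_ends
    (';'-separated CDS exon coordinates of the longest transcript),
    cds_length and gene_length.  Adds boolean columns near_start_75,
    near_stop_75 (within 75 bp of the translation start/stop along the
    spliced CDS), near_splice_48 (within 48 bp of an internal exon
    boundary), single_exon, x_linked, and tertile columns for gene and
    CDS length.  Sites in genes absent from the models keep NA attrs and
    are counted in the returned frame's ``attrs['n_unmatched']``.
    """
    gm = gene_models.set_index("gene_id")
    out = sites.copy()
    for col in ("attr:near_start_75", "attr:near_stop_75", "attr:near_splice_48",
                "attr:single_exon", "attr:x_linked"):
        out[col] = pd.NA

    len_tert = tertiles(gm["gene_length"])
    cds_tert = tertiles(gm["cds_length"])
    out["attr:gene_length_class"] = out["gene_id"].map(len_tert)
    out["attr:cds_length_class"] = out["gene_id"].map(cds_tert)

    n_unmatched = 0
    for gene_id, grp in out.groupby("gene_id", sort=False):
        if gene_id not in gm.index:
            n_unmatched += len(grp)
            continue
        g = gm.loc[gene_id]
        starts = np.array([int(x) for x in str(g["exon_starts"]).split(";")])
        ends = np.array([int(x) for x in str(g["exon_ends"]).split(";")])
        exon_lens = ends - starts + 1
        offsets = np.concatenate([[0], np.cumsum(exon_lens)[:-1]])
        pos = grp["pos"].to_numpy()
        # CDS coordinate of each site (1-based along the spliced CDS)
        cds_pos = np.full(len(pos), -1)
        for s, e, off in zip(starts, ends, offsets):
            inside = (pos >= s) & (pos <= e)
            cds_pos[inside] = off + pos[inside] - s + 1
        if str(g.get("strand", "+")) == "-":
            cds_pos = np.where(cds_pos > 0, g["cds_length"] - cds_pos + 1, -1)
        # distance to nearest internal splice boundary in genomic space
        internal = np.concatenate([ends[:-1], starts[1:]]) if len(starts) > 1 else None
        if internal is None:
            near_splice = np.zeros(len(pos), dtype=bool)
        else:
            d = np.min(np.abs(pos[:, None] - internal[None, :]), axis=1)
            near_splice = d <= 48
        idx = grp.index
        out.loc[idx, "attr:near_start_75"] = cds_pos <= 75
        out.loc[idx, "attr:near_stop_75"] = cds_pos > int(g["cds_length"]) - 75
        out.loc[idx, "attr:near_splice_48"] = near_splice
        out.loc[idx, "attr:single_exon"] = len(starts) == 1
        out.loc[idx, "attr:x_linked"] = str(g["chrom"]) == "X"
    out.attrs["n_unmatched"] = n_unmatched
    if n_unmatched:
        import warnings

        warnings.warn(f"{n_unmatched} sites not in any supplied gene model")
    return out


def group_and_estimate(
    sites_by_group: dict[str, pd.DataFrame],
    ref_sites: pd.DataFrame,
    mode: str = "major_allele",
    max_dist: int = 1000,
    n_boot: int = 10,
    seed=None,
) -> dict[str, BootstrapEstimate]:
    """Matched-bootstrap deficit within each site group.

    The machinery behind every per-category figure: groups partition the
    test sites, the reference pool is shared, and each group gets its
    own paired resampling (deficits may legitimately be negative —
    an excess of polymorphism — and are never clamped).  Groups whose
    sites cannot be paired are skipped with a diagnostic.
    """
    rng = np.random.default_rng(seed)
    out = {}
    for label, grp in sites_by_group.items():
        sub_seed = int(rng.integers(0, 2**31 - 1))
        try:
            index = build_pair_index(grp, ref_sites, mode=mode, max_dist=max_dist)
        except ValueError as exc:
            import warnings

            warnings.warn(f"group {label!r} skipped: {exc}")
            continue
        out[label] = bootstrap_deficit(index, n_boot=n_boot, seed=sub_seed)
    return out


@dataclass
class GeneRanking:
    """Per-gene surrogate scores for extensive strong constraint."""

    scores: pd.Series  # gene_id -> score in [0,1], eligible genes only
    n_total: int
    n_eligible: int
    top_genes: pd.Index

    def rank(self) -> pd.Series:
        return self.scores.rank(ascending=False, method="first").astype(int)


def rank_genes_surrogate(
    sites: pd.DataFrame,
    min_conserved_frac: float = 0.2,
    top_frac: float = 1.0 / 6.0,
    conserved_aa_col: str = "attr:conserved_aa",
) -> GeneRanking:
    """Rank genes by conserved-unpreferred SNP-free 4D site fraction.

    For each gene, among SNP-free 4D sites in conserved amino acids, the
    score is the fraction that are unpreferred and themselves fully
    conserved (zero substitutions).  Genes whose conserved-amino-acid 4D
    fraction is below ``min_conserved_frac`` are ineligible.  Returns
    scores, and the top floor(top_frac * eligible) genes.
    """
    df = sites[sites["site_class"] == "4D"]
    if conserved_aa_col not in df.columns:
        raise ValueError(f"sites lack conservation column {conserved_aa_col!r}")
    cons = df[conserved_aa_col].astype(bool)
    per_gene = pd.DataFrame(
        {
            "n_sites": df.groupby("gene_id").size(),
            "n_cons": df[cons].groupby(df.loc[cons, "gene_id"]).size(),
        }
    ).fillna(0)
    eligible = per_gene[
        per_gene["n_cons"] / per_gene["n_sites"] >= min_conserved_frac
    ].index

    snp_free = df[cons & (df["minor_count"] == 0)]
    denom = snp_free.groupby("gene_id").size()
    hits = snp_free[
        (snp_free["preference"] == "U") & (snp_free["subst_count"] == 0)
    ]
    num = hits.groupby("gene_id").size()
    scores = (num.reindex(denom.index, fill_value=0) / denom).reindex(eligible)
    scores = scores.dropna().sort_values(ascending=False, kind="mergesort")
    if len(scores) == 0:
        raise ValueError("no eligible genes for the constraint surrogate")
    n_top = int(np.floor(top_frac * len(scores)))
    return GeneRanking(
        scores=scores,
        n_total=per_gene.shape[0],
        n_eligible=len(scores),
        top_genes=scores.index[:n_top],
    )
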