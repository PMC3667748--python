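"""Synthetic DGRP-like site tables with the structure the analysis assumes.

The generator emulates the statistical features the pipeline relies on,
without forward simulation: two site classes (4D, short intron) with
different GC composition (defaults 64% vs 31%); spatially covarying
mutation/diversity through a piecewise-constant lognormal multiplier
shared by all sites in the same 1-kb window; per-site called depths
spanning 100..168 chromosomes so the depth filter is exercised; and 4D
sites split between neutral and strongly selected classes whose folded
minor-allele counts are drawn from the model's own sample SFS at each
site's depth.

Layout: genes tile five chromosome arms, each with two CDS exons
separated by two 85-bp introns whose interior (trimmed) positions are
the short-intron reference, so nearly every 4D site has reference
partners within 1 kb — the geometry the matched bootstrap needs.

Confound knobs: ``at_theta_ratio`` scales theta at A/T-major sites
(GC-dependent mutation rate); ``mutation_deficit`` replaces the strong
category with a zero-mutation class; ``alpha`` applies a shared
frequency-class distortion to both site classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .sfs import GAMMA_LIMIT, unfolded_shape
from .sites import trim_short_intron_positions

__all__ = ["GeneratorConfig", "generate_layout", "generate_sites", "generate_codon_annotations", "generate_gene_attributes"]

_ARMS = ("2L", "2R", "3L", "3R", "X")
_NUC = np.array(["A", "C", "G", "T"])
_GC = np.array(["G", "C"])
_AT = np.array(["A", "T"])

#: four-fold codon families: amino acid -> first two codon bases
_FOURFOLD_PREFIX = {"A": "GC", "G": "GG", "P": "CC", "T": "AC", "V": "GT"}
_OPTIMAL_CODON = {"A": "GCC", "G": "GGC", "P": "CCC", "T": "ACC", "V": "GTG"}


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic site tables.

    Defaults mirror the deep *D. melanogaster* population sample the
    analysis targets: ~8.6e5 sites per class at theta = 0.0132, with
    22.6% of 4D sites under strong purifying selection at gamma = -283
    and GC contents of 64% (4D) vs 31% (short introns).
    """

    n_4d_sites: int = 864_000
    n_si_sites: int = 870_000
    theta: float = 0.0132
    f_strong: float = 0.226
    gamma_strong: float = -283.0
    f_weak: float = 0.0
    gamma_weak: float = -1.0
    gc_4d: float = 0.64
    gc_si: float = 0.31
    regional_sd: float = 0.3
    window_bp: int = 1000
    depth_min: int = 100
    depth_max: int = 168
    depth_target: int = 130
    at_theta_ratio: float = 1.0
    mutation_deficit: bool = False
    alpha: Optional[np.ndarray] = None
    # codon-annotation model
    conserved_aa_frac: float = 0.7
    subst_correlated: bool = True
    subst_p0_strong: float = 0.35
    subst_p0_neutral: float = 0.10
    subst_mean_strong: float = 2.0
    subst_mean_neutral: float = 4.5
    # layout geometry
    codons_per_exon: int = 63
    intron_length: int = 85
    gene_gap: int = 400

    def __post_init__(self) -> None:
        if not (0 <= self.f_strong <= 1 and 0 <= self.f_weak <= 1):
            raise ValueError("fractions must lie in [0,1]")
        if self.f_strong + self.f_weak > 1:
            raise ValueError("f_strong + f_weak exceeds 1")
        for gc in (self.gc_4d, self.gc_si):
            if not 0 < gc < 1:
                raise ValueError("gc fractions must lie in (0,1)")
        if self.n_4d_sites <= 0 or self.n_si_sites <= 0:
            raise ValueError("site counts must be positive")
        if abs(self.gamma_strong) > GAMMA_LIMIT or abs(self.gamma_weak) > GAMMA_LIMIT:
            raise ValueError(f"|gamma| exceeds {GAMMA_LIMIT}")

    @property
    def fractions(self) -> np.ndarray:
        return np.array([1.0 - self.f_weak - self.f_strong, self.f_weak, self.f_strong])


@dataclass
class Layout:
    """Genomic scaffold: gene models plus 4D / short-intron positions."""

    genes: pd.DataFrame
    sites_4d: pd.DataFrame
    sites_si: pd.DataFrame

    def summary(self) -> str:
        return (
            f"{len(self.genes)} genes over {self.genes['chrom'].nunique()} arms; "
            f"{len(self.sites_4d)} 4D sites, {len(self.sites_si)} short-intron sites"
        )


def generate_layout(config: GeneratorConfig, rng=None) -> Layout:
    """Tile genes along chromosome arms.

    Each gene carries two CDS exons of ``codons_per_exon`` codons whose
    third positions are the 4D sites, separated by two short introns of
    ``intron_length`` bp whose interior positions (after the 16/6 bp
    trims) are the reference sites.  Gene spans are ~550 bp with
    ``gene_gap`` between genes, so 4D sites always have short-intron
    partners within 1 kb.
    """
    n_per_gene_4d = 2 * config.codons_per_exon
    trimmed = len(trim_short_intron_positions(1, config.intron_length))
    n_per_gene_si = 2 * trimmed
    if n_per_gene_si == 0:
        import warnings

        warnings.warn("intron length leaves no reference positions; pairing coverage 0")
    n_genes = int(
        max(
            np.ceil(config.n_4d_sites / n_per_gene_4d),
            np.ceil(config.n_si_sites / max(n_per_gene_si, 1)),
        )
    )

    exon_len = 3 * config.codons_per_exon
    gene_records = []
    p4, psi = [], []
    cursors = {arm: 1 for arm in _ARMS}
    for g in range(n_genes):
        arm = _ARMS[g % len(_ARMS)]
        start = cursors[arm]
        # exon1 | intron1 | exon2(first half) | intron2 | exon2(second half)
        e1 = (start, start + exon_len - 1)
        i1 = (e1[1] + 1, e1[1] + config.intron_length)
        e2 = (i1[1] + 1, i1[1] + exon_len - 1 + 1)
        i2 = (e2[1] + 1, e2[1] + config.intron_length)
        e3 = (i2[1] + 1, i2[1] + exon_len)
        gene_id = f"FFg{g:05d}"
        gene_records.append(
            {
                "gene_id": gene_id,
                "chrom": arm,
                "strand": "+",
                "start": e1[0],
                "end": e3[1],
                "exon_starts": f"{e1[0]};{e2[0]};{e3[0]}",
                "exon_ends": f"{e1[1]};{e2[1]};{e3[1]}",
                "cds_length": 2 * exon_len,
                "gene_length": e3[1] - e1[0] + 1,
            }
        )
        # third codon positions across the spliced CDS
        cds_pos = np.concatenate(
            [
                np.arange(e1[0], e1[1] + 1),
                np.arange(e2[0], e2[1] + 1),
                np.arange(e3[0], e3[1] + 1),
            ]
        )
        p4.append((gene_id, arm, cds_pos[2::3]))
        si_pos = np.concatenate(
            [
                trim_short_intron_positions(i1[0], i1[1]),
                trim_short_intron_positions(i2[0], i2[1]),
            ]
        )
        psi.append((gene_id, arm, si_pos))
        cursors[arm] = e3[1] + 1 + config.gene_gap

    def _frame(parts, n_max):
        gene_ids = np.concatenate(
            [np.repeat(g, len(pos)) for g, _, pos in parts]
        )
        chroms = np.concatenate([np.repeat(a, len(pos)) for _, a, pos in parts])
        pos = np.concatenate([pos for _, _, pos in parts])
        df = pd.DataFrame({"chrom": chroms, "pos": pos, "gene_id": gene_ids})
        return df.iloc[:n_max].reset_index(drop=True)

    layout = Layout(
        genes=pd.DataFrame(gene_records),
        sites_4d=_frame(p4, config.n_4d_sites),
        sites_si=_frame(psi, config.n_si_sites),
    )
    return layout


def _draw_minor_counts(
    theta_site: np.ndarray,
    depth: np.ndarray,
    gamma: np.ndarray,
    deficit_mask: np.ndarray,
    alpha: Optional[np.ndarray],
    rng,
) -> np.ndarray:
    """Folded minor-allele counts from the class-conditional sample SFS.

    For each site the chance of segregating is theta_site * S(gamma, n)
    (the model's expected segregating mass per unit theta) and the
    conditional derived-allele count follows the normalised unfolded
    spectrum, drawn at the site's own called depth then folded.  An
    optional shared alpha distortion reweights the folded classes of
    every site, the zero class included (alpha_0 = 1).
    """
    minor = np.zeros(len(depth), dtype=np.int64)
    for (n, g) in set(zip(depth.tolist(), gamma.tolist())):
        sel = (depth == n) & (gamma == g) & ~deficit_mask
        if not sel.any():
            continue
        h = unfolded_shape(int(n), float(g))
        half = int(n) // 2
        if alpha is not None:
            # fold, distort, then draw folded counts directly
            hf = np.zeros(half)
            for i in range(1, int(n)):
                j = min(i, int(n) - i)
                hf[j - 1] += h[i - 1]
            a = np.ones(half + 1)
            a[: len(alpha)] = alpha[: half + 1]
            w = a[1:] * hf
            th = theta_site[sel]
            p_seg = th * w.sum() / (1.0 - th * hf.sum() + th * w.sum())
            seg = rng.random(sel.sum()) < p_seg
            idx = np.flatnonzero(sel)[seg]
            if len(idx):
                minor[idx] = rng.choice(
                    np.arange(1, half + 1), size=len(idx), p=w / w.sum()
                )
        else:
            p_seg = np.minimum(theta_site[sel] * h.sum(), 1.0)
            seg = rng.random(sel.sum()) < p_seg
            idx = np.flatnonzero(sel)[seg]
            if len(idx):
                derived = rng.choice(
                    np.arange(1, int(n)), size=len(idx), p=h / h.sum()
                )
                minor[idx] = np.minimum(derived, int(n) - derived)
    return minor


def generate_sites(
    config: GeneratorConfig, seed=None, layout: Optional[Layout] = None
) -> pd.DataFrame:
    """Generate the full site table (4D + short-intron rows).

    Major alleles hit the per-class GC targets; a lognormal multiplier
    (sd ``regional_sd``, unit mean) shared within each 1-kb window
    scales theta for 4D and reference sites alike; 4D sites are assigned
    to mixture categories and their folded minor-allele counts drawn
    from the class-conditional sample SFS at their called depth.
    Deterministic for a fixed config and seed.
    """
    rng = np.random.default_rng(seed)
    if layout is None:
        layout = generate_layout(config, rng)

    frames = []
    for cls, sites, gc in (
        ("4D", layout.sites_4d, config.gc_4d),
        ("SI", layout.sites_si, config.gc_si),
    ):
        k = len(sites)
        is_gc = rng.random(k) < gc
        major = np.where(is_gc, _GC[rng.integers(0, 2, k)], _AT[rng.integers(0, 2, k)])
        df = sites.copy()
        df["site_class"] = cls
        df["major_allele"] = major
        frames.append(df)
    table = pd.concat(frames, ignore_index=True)

    # regional diversity: lognormal multiplier per (arm, 1-kb window),
    # unit mean, shared across site classes
    window = table["chrom"].astype(str) + "@" + (
        table["pos"] // config.window_bp
    ).astype(str)
    codes, uniques = pd.factorize(window)
    mult = rng.lognormal(
        mean=-0.5 * config.regional_sd**2, sigma=config.regional_sd, size=len(uniques)
    )
    theta_site = config.theta * mult[codes]
    is_at = np.isin(table["major_allele"].to_numpy(), _AT)
    theta_site = theta_site * np.where(is_at, config.at_theta_ratio, 1.0)

    depth = rng.integers(config.depth_min, config.depth_max + 1, size=len(table))

    # selection category per 4D site; reference sites are neutral
    is_4d = (table["site_class"] == "4D").to_numpy()
    gammas = np.zeros(len(table))
    deficit = np.zeros(len(table), dtype=bool)
    cat = rng.choice(3, size=int(is_4d.sum()), p=config.fractions)
    g4 = np.where(cat == 1, config.gamma_weak, 0.0)
    g4 = np.where(cat == 2, config.gamma_strong, g4)
    if config.mutation_deficit:
        deficit[is_4d] = cat == 2
        g4 = np.where(cat == 2, 0.0, g4)
    gammas[is_4d] = g4

    minor = _draw_minor_counts(theta_site, depth, gammas, deficit, config.alpha, rng)

    seg = minor > 0
    # minor allele: any different nucleotide (uniform over the other 3)
    other = np.array(
        [[n for n in _NUC if n != m] for m in _NUC], dtype=object
    )  # 4 x 3
    maj_idx = np.searchsorted(_NUC, table["major_allele"].to_numpy())
    pick = rng.integers(0, 3, size=len(table))
    minor_allele = np.where(seg, other[maj_idx, pick], None)

    # ordered major-allele triplet (5' neighbour, site, 3' neighbour) for
    # the context-matched bootstrap variant; neighbours are independent
    # draws with the class GC composition
    def _nbr(k, gc):
        isgc = rng.random(k) < gc
        return np.where(isgc, _GC[rng.integers(0, 2, k)], _AT[rng.integers(0, 2, k)])

    nb5 = np.empty(len(table), dtype=object)
    nb3 = np.empty(len(table), dtype=object)
    nb5[is_4d] = _nbr(int(is_4d.sum()), config.gc_4d)
    nb3[is_4d] = _nbr(int(is_4d.sum()), config.gc_4d)
    nb5[~is_4d] = _nbr(int((~is_4d).sum()), config.gc_si)
    nb3[~is_4d] = _nbr(int((~is_4d).sum()), config.gc_si)
    triplet = nb5 + table["major_allele"].to_numpy() + nb3

    out = pd.DataFrame(
        {
            "chrom": table["chrom"],
            "pos": table["pos"],
            "site_class": table["site_class"],
            "major_allele": table["major_allele"],
            "minor_allele": minor_allele,
            "minor_count": minor,
            "called_depth": depth,
            "n_alleles": np.where(seg, 2, 1),
            "gene_id": table["gene_id"],
            "codon_anc": None,
            "amino_acid": None,
            "preference": None,
            "subst_count": np.nan,
            "attr:triplet": triplet,
            "attr:sel_class": _sel_class_labels(is_4d, cat),
        }
    )
    return out


def _sel_class_labels(is_4d: np.ndarray, cat: np.ndarray) -> np.ndarray:
    labels = np.full(len(is_4d), "neutral", dtype=object)
    labels[is_4d] = np.array(["neutral", "weak", "strong"], dtype=object)[cat]
    return labels


def generate_codon_annotations(
    config: GeneratorConfig, sites: pd.DataFrame, seed=None
) -> pd.DataFrame:
    """Fill codon, preference, conservation and substitution annotations.

    4D rows get an amino acid from the five four-fold families, an
    ancestral codon whose third base is the major allele, a preference
    call against the optimal-codon table, a conserved-amino-acid flag,
    and a substitution count whose distribution may be coupled to the
    selection class (strong-class sites slower) via ``subst_correlated``.
    """
    rng = np.random.default_rng(seed)
    out = sites.copy()
    is4d = (out["site_class"] == "4D").to_numpy()
    k = int(is4d.sum())

    aas = rng.choice(list(_FOURFOLD_PREFIX), size=k)
    prefix = np.array([_FOURFOLD_PREFIX[a] for a in aas])
    codon = np.char.add(prefix, out.loc[is4d, "major_allele"].to_numpy(dtype=str))
    optimal = np.array([_OPTIMAL_CODON[a] for a in aas])

    out.loc[is4d, "amino_acid"] = aas
    out.loc[is4d, "codon_anc"] = codon
    out.loc[is4d, "preference"] = np.where(codon == optimal, "P", "U")
    out.loc[is4d, "attr:conserved_aa"] = rng.random(k) < config.conserved_aa_frac

    strong = (out.loc[is4d, "attr:sel_class"] == "strong").to_numpy()
    if not config.subst_correlated:
        strong = np.zeros(k, dtype=bool)
    p0 = np.where(strong, config.subst_p0_strong, config.subst_p0_neutral)
    mean = np.where(strong, config.subst_mean_strong, config.subst_mean_neutral)
    counts = rng.gamma(2.0, mean / 2.0, size=k)
    counts[rng.random(k) < p0] = 0.0
    out.loc[is4d, "subst_count"] = counts
    return out


def generate_gene_attributes(
    config: GeneratorConfig, layout: Layout, seed=None
) -> pd.DataFrame:
    """Gene-level attribute table: lengths, codon-bias metrics, expression.

    FOP/ENC and the per-stage expression levels are independent draws by
    default — stratifying on them should find no deficit differences
    unless the caller couples them to the site table explicitly.
    """
    rng = np.random.default_rng(seed)
    genes = layout.genes
    k = len(genes)
    fop = rng.beta(5, 5, size=k)
    df = pd.DataFrame(
        {
            "gene_id": genes["gene_id"],
            "length": genes["gene_length"],
            "cds_length": genes["cds_length"],
            "chrom": genes["chrom"],
            "fop": np.round(fop, 4),
            "enc": np.round(61.0 - 30.0 * fop + rng.normal(0, 3, k), 2),
        }
    )
    for stage in ("embryo", "larva", "pupa", "adult"):
        df[f"expr:{stage}"] = np.round(rng.lognormal(3.0, 1.0, size=k), 3)
    return df
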