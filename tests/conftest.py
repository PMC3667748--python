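import numpy as np
import pandas as pd
import pytest


def make_sites(rows):
    """Build a site DataFrame from per-row dicts with sensible defaults."""
    defaults = {
        "chrom": "2L",
        "pos": 0,
        "site_class": "4D",
        "major_allele": "G",
        "minor_allele": None,
        "minor_count": 0,
        "called_depth": 130,
        "n_alleles": 1,
        "gene_id": None,
        "codon_anc": None,
        "amino_acid": None,
        "preference": None,
        "subst_count": np.nan,
    }
    records = []
    for i, row in enumerate(rows):
        rec = dict(defaults)
        rec["pos"] = 100 + i
        rec.update(row)
        records.append(rec)
    return pd.DataFrame(records)


@pytest.fixture
def small_table(tmp_path):
    """A 3-row well-formed site-table TSV on disk."""
    df = make_sites(
        [
            {"pos": 100, "site_class": "4D", "major_allele": "G"},
            {
                "pos": 200,
                "site_class": "4D",
                "major_allele": "C",
                "minor_allele": "T",
                "minor_count": 5,
                "n_alleles": 2,
            },
            {"pos": 300, "site_class": "SI", "major_allele": "A"},
        ]
    )
    path = tmp_path / "sites.tsv"
    df.to_csv(path, sep="\t", index=False, na_rep=".")
    return path, df


def trapezoid_sfs_oracle(n, gamma, npts=10**6):
    """Dense-grid trapezoid evaluation of the expected unfolded spectrum.

    Integrates stationary_density(q) * Binomial(n, q) pmf written in the
    form C(n,i) q^(i-1) (1-q)^(n-i-1) * shape(q), which is continuous on
    the closed interval, with shape(q) = (e^{gq} - e^g)/(1 - e^g).
    Independent of the package's Gauss-Legendre path.
    """
    from scipy.special import gammaln

    q = np.linspace(0.0, 1.0, npts)
    if gamma == 0.0:
        shape = 1.0 - q
    else:
        with np.errstate(under="ignore"):
            shape = (np.exp(gamma * q[1:-1]) - np.exp(gamma)) / -np.expm1(gamma)
        shape = np.concatenate([[1.0], shape, [0.0]])
    out = np.empty(n - 1)
    with np.errstate(divide="ignore"):
        lq, l1q = np.log(q), np.log1p(-q)
    for i in range(1, n):
        logC = gammaln(n + 1.0) - gammaln(i + 1.0) - gammaln(n - i + 1.0)
        with np.errstate(under="ignore", invalid="ignore"):
            poly = np.exp(logC + (i - 1) * lq + (n - i - 1) * l1q)
        poly[0] = np.exp(logC) if i == 1 else 0.0
        poly[-1] = np.exp(logC) if i == n - 1 else 0.0
        out[i - 1] = np.trapezoid(poly * shape, q)
    return out
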