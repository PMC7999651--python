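"""Hardy–Weinberg equilibrium testing from genotype counts.

Provides the Pearson goodness-of-fit chi-square (1 df, expected counts from
the estimated allele frequency) and the exact test obtained by enumerating
all heterozygote counts compatible with the observed allele counts
(conditional distribution of the number of heterozygotes given the minor
allele count).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import lgamma, log, exp

import pandas as pd
from scipy import stats as sps


@dataclass
class HweResult:
    rsid: str
    n_ref_hom: int
    n_het: int
    n_alt_hom: int
    chi2: float | None
    p_chi2: float | None
    p_exact: float | None
    monomorphic: bool

    @property
    def deviates(self) -> bool | None:
        if self.monomorphic or self.p_chi2 is None:
            return None
        return self.p_chi2 < 0.05


def _log_het_prob(n_het: int, n_rare: int, n: int) -> float:
    """Log probability of ``n_het`` heterozygotes given rare-allele count."""
    n_common = 2 * n - n_rare
    n_rare_hom = (n_rare - n_het) // 2
    n_common_hom = n - n_het - n_rare_hom
    return (n_het * log(2.0)
            + lgamma(n + 1)
            - lgamma(n_het + 1) - lgamma(n_rare_hom + 1) - lgamma(n_common_hom + 1)
            + lgamma(n_rare + 1) + lgamma(n_common + 1) - lgamma(2 * n + 1))


def hwe_exact_p(n_ref_hom: int, n_het: int, n_alt_hom: int) -> float:
    """Exact HWE p value by heterozygote enumeration at fixed allele counts."""
    n = n_ref_hom + n_het + n_alt_hom
    n_rare = min(2 * n_alt_hom + n_het, 2 * n_ref_hom + n_het)
    obs = _log_het_prob(n_het, n_rare, n)
    total = 0.0
    p_obs_sum = 0.0
    for h in range(n_rare % 2, n_rare + 1, 2):
        lp = _log_het_prob(h, n_rare, n)
        p = exp(lp)
        total += p
        if lp <= obs + 1e-12:
            p_obs_sum += p
    return min(1.0, p_obs_sum / total)


def hwe_test(counts: tuple[int, int, int], rsid: str = "") -> HweResult:
    """Chi-square and exact HWE tests from (hom-ref, het, hom-alt) counts."""
    n_ref, n_het, n_alt = (int(c) for c in counts)
    if min(n_ref, n_het, n_alt) < 0:
        raise ValueError("negative genotype count")
    n = n_ref + n_het + n_alt
    if n == 0:
        raise ValueError("empty genotype table")
    q = (2 * n_alt + n_het) / (2 * n)
    if q in (0.0, 1.0):
        return HweResult(rsid, n_ref, n_het, n_alt, chi2=None, p_chi2=None,
                         p_exact=None, monomorphic=True)
    p = 1.0 - q
    expected = (n * p * p, 2 * n * p * q, n * q * q)
    chi2 = sum((o - e) ** 2 / e
               for o, e in zip((n_ref, n_het, n_alt), expected))
    p_chi2 = float(sps.chi2.sf(chi2, df=1))
    return HweResult(rsid, n_ref, n_het, n_alt, chi2=float(chi2),
                     p_chi2=p_chi2, p_exact=hwe_exact_p(n_ref, n_het, n_alt),
                     monomorphic=False)


def genotype_counts(genotypes: pd.DataFrame, panel: pd.DataFrame) -> pd.DataFrame:
    """Per-variant (hom-ref, het, hom-alt) counts from a long genotype table."""
    panel = panel.set_index("rsid")
    rows = []
    for rsid, sub in genotypes.groupby("rsid"):
        alt = panel.loc[rsid, "alt"]
        copies = (sub["allele1"] == alt).astype(int) + (sub["allele2"] == alt).astype(int)
        rows.append({"rsid": rsid,
                     "n_ref_hom": int((copies == 0).sum()),
                     "n_het": int((copies == 1).sum()),
                     "n_alt_hom": int((copies == 2).sum())})
    return pd.DataFrame(rows).set_index("rsid")


def hwe_table(genotypes: pd.DataFrame, panel: pd.DataFrame) -> pd.DataFrame:
    """HWE results for every variant in a long genotype table."""
    counts = genotype_counts(genotypes, panel)
    rows = []
    for rsid, row in counts.iterrows():
        res = hwe_test((row["n_ref_hom"], row["n_het"], row["n_alt_hom"]), rsid)
        rows.append({"rsid": rsid, "n_ref_hom": res.n_ref_hom,
                     "n_het": res.n_het, "n_alt_hom": res.n_alt_hom,
                     "chi2": res.chi2, "p_chi2": res.p_chi2,
                     "p_exact": res.p_exact, "monomorphic": res.monomorphic,
                     "deviates": res.deviates})
    return pd.DataFrame(rows)
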