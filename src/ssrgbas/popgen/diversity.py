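"""Codominant diversity statistics, HWE tests and null-allele estimation.

Conventions follow the classic GenAlEx-style per-locus, per-population
summaries: expected heterozygosity is the biased estimator He = 1 - sum(p^2)
(the unbiased 2n/(2n-1) variant is reported alongside as uHe), the fixation
index is FIS = (He - Ho) / He, and the effective allele number Ne = 1 /
sum(p^2).  PIC is the polymorphic information content
1 - sum(p_i^2) - sum_{i<j} 2 p_i^2 p_j^2.

Null-allele frequencies are estimated by an expectation-maximization fit of
the model in which each observed homozygote class is a mixture of true
homozygotes and heterozygotes carrying one amplifying and one null allele
(the estimator popularized by FreeNA / Dempster-type EM), without an observed
blank (null/null) class.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "allele_frequencies",
    "genotype_counts",
    "diversity_stats",
    "pic",
    "hwe_chi2",
    "HweResult",
    "em_null_allele_freq",
]


def allele_frequencies(matrix):
    """Per (population, locus) allele frequencies over non-missing genotypes.

    Returns ``{(pop, locus): (freqs_dict, n_typed)}``; each fully typed
    individual contributes two allele observations.
    """
    table = {}
    pops = sorted(set(matrix.pop_map.values()))
    for pop in pops:
        samples = [s for s in matrix.samples if matrix.pop_map[s] == pop]
        for locus in matrix.loci:
            counts = Counter()
            n = 0
            for s in samples:
                e = matrix.entries.get((s, locus))
                if e is None:
                    continue
                n += 1
                counts.update(e)
            total = sum(counts.values())
            freqs = ({a: c / total for a, c in counts.items()} if total else {})
            table[(pop, locus)] = (freqs, n)
    return table


def genotype_counts(matrix, locus, pop=None):
    """Counts of unordered genotypes at one locus (optionally one population)."""
    counts = Counter()
    for s in matrix.samples:
        if pop is not None and matrix.pop_map[s] != pop:
            continue
        e = matrix.entries.get((s, locus))
        if e is not None:
            counts[tuple(sorted(e))] += 1
    return dict(counts)


def _he(p: np.ndarray) -> float:
    return 1.0 - float(np.sum(p ** 2))


def diversity_stats(matrix, freq_table=None) -> pd.DataFrame:
    """Na, Na_freq5, Ne, Npa, Ho, He, uHe and FIS per population and locus."""
    if freq_table is None:
        freq_table = allele_frequencies(matrix)
    pops = sorted(set(matrix.pop_map.values()))
    # private alleles: present in exactly one population
    seen_in = defaultdict(set)
    for (pop, locus), (freqs, _) in freq_table.items():
        for a in freqs:
            seen_in[(locus, a)].add(pop)
    rows = []
    for pop in pops:
        samples = [s for s in matrix.samples if matrix.pop_map[s] == pop]
        for locus in matrix.loci:
            freqs, n = freq_table[(pop, locus)]
            if n == 0:
                continue
            p = np.array(list(freqs.values()))
            typed = [matrix.entries[(s, locus)] for s in samples
                     if matrix.entries.get((s, locus)) is not None]
            ho = sum(1 for e in typed if e[0] != e[1]) / len(typed)
            he = _he(p)
            uhe = he * (2 * n) / (2 * n - 1) if n > 1 else np.nan
            fis = (he - ho) / he if he > 0 else np.nan
            rows.append({
                "population": pop,
                "locus": locus,
                "n": n,
                "Na": len(p),
                "Na_freq5": int(np.sum(p >= 0.05)),
                "Ne": 1.0 / float(np.sum(p ** 2)),
                "Npa": sum(1 for a in freqs if seen_in[(locus, a)] == {pop}),
                "Ho": ho,
                "He": he,
                "uHe": uhe,
                "Fis": fis,
            })
    return pd.DataFrame(rows)


def pic(freqs) -> float:
    """Polymorphic information content of one locus from pooled frequencies."""
    p = np.asarray(list(freqs.values()) if isinstance(freqs, Mapping) else freqs,
                   dtype=float)
    s2 = np.sum(p ** 2)
    cross = 0.0
    for i in range(len(p)):
        for j in range(i + 1, len(p)):
            cross += 2.0 * p[i] ** 2 * p[j] ** 2
    return float(1.0 - s2 - cross)


@dataclass
class HweResult:
    chi2: float
    df: int
    p: float
    fis: Optional[float] = None
    f_null: Optional[float] = None
    applicable: bool = True
    warning: Optional[str] = None


def hwe_chi2(counts: Mapping[tuple, int]) -> HweResult:
    """Chi-square goodness-of-fit to Hardy-Weinberg genotype proportions.

    All k(k+1)/2 genotype classes enter the statistic (no pooling of rare
    classes; expected counts below 1 only raise a warning).  Degrees of
    freedom are k(k-1)/2 for k observed alleles.
    """
    n = sum(counts.values())
    if n == 0:
        return HweResult(np.nan, 0, np.nan, applicable=False,
                         warning="no typed individuals")
    allele_counts = Counter()
    for (a, b), c in counts.items():
        allele_counts[a] += c
        allele_counts[b] += c
    alleles = sorted(allele_counts)
    k = len(alleles)
    if k < 2:
        return HweResult(np.nan, 0, np.nan, applicable=False,
                         warning="monomorphic")
    p = {a: allele_counts[a] / (2 * n) for a in alleles}
    chi2 = 0.0
    warning = None
    ho = sum(c for (a, b), c in counts.items() if a != b) / n
    he = 1.0 - sum(v ** 2 for v in p.values())
    for i, a in enumerate(alleles):
        for b in alleles[i:]:
            exp = n * (p[a] ** 2 if a == b else 2 * p[a] * p[b])
            obs = counts.get((a, b) if a <= b else (b, a), 0)
            if exp < 1:
                warning = "expected count below 1 in at least one class"
            if exp > 0:
                chi2 += (obs - exp) ** 2 / exp
    df = k * (k - 1) // 2
    pval = float(stats.chi2.sf(chi2, df))
    fis = (he - ho) / he if he > 0 else np.nan
    return HweResult(float(chi2), df, pval, fis=fis, warning=warning)


def em_null_allele_freq(counts: Mapping[tuple, int], tol: float = 1e-6,
                        max_iter: int = 1000):
    """EM estimate of the null-allele frequency at one locus/population.

    Model: allele frequencies (p_1..p_k, beta) with beta the null allele;
    genotypes are in Hardy-Weinberg proportions; null homozygotes are not
    observed (no blank class); an observed homozygote i/i arises from true
    i/i (p_i^2) or i/null (2 p_i beta).  Returns ``(f_null, converged)``;
    ``(None, False)`` when fewer than two visible alleles are present.
    """
    n = sum(counts.values())
    visible = sorted({a for g in counts for a in g})
    if n == 0 or len(visible) < 2:
        return None, False
    het = {g: c for g, c in counts.items() if g[0] != g[1]}
    hom = {g[0]: c for g, c in counts.items() if g[0] == g[1]}
    k = len(visible)
    p = {a: 1.0 / (k + 1) for a in visible}
    beta = 1.0 / (k + 1)
    converged = False
    for _ in range(max_iter):
        # E-step: split observed homozygotes into true hom vs null het
        exp_null = {}
        for a, c in hom.items():
            denom = p[a] ** 2 + 2 * p[a] * beta
            exp_null[a] = c * (2 * p[a] * beta / denom) if denom > 0 else 0.0
        # M-step: allele counts over 2n observed gene copies
        gene = {a: 0.0 for a in visible}
        null_gene = 0.0
        for (a, b), c in het.items():
            gene[a] += c
            gene[b] += c
        for a, c in hom.items():
            null_part = exp_null[a]
            gene[a] += 2 * (c - null_part) + null_part
            null_gene += null_part
        total = 2.0 * n
        new_p = {a: g / total for a, g in gene.items()}
        new_beta = null_gene / total
        delta = abs(new_beta - beta) + sum(abs(new_p[a] - p[a]) for a in visible)
        p, beta = new_p, new_beta
        if delta < tol:
            converged = True
            break
    return float(beta), converged
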