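"""Distance-based structure analyses: AMOVA, Phi/FST statistics, PCoA.

The analysis of molecular variance partitions the total genetic variance of a
codominant multilocus dataset over a sampling hierarchy (regions >
populations > individuals > allele copies within individuals).  Sums of
squares are computed at the allele-copy (gamete) level, where the distance
between two allele copies at a locus is 0 when they carry the same allele and
1 otherwise; summed over loci this is equivalent to partitioning the classic
squared genotypic distances between individuals
(d^2 = 1/2 * sum_alleles (count_1 - count_2)^2 per locus).

Variance components follow the standard moment (expected-mean-square)
equations with unbalanced-design coefficients computed from gene-copy counts.
Phi statistics are intraclass correlations of those components; the overall
FST reported for a hierarchical design is
(sigma_regions + sigma_pops) / sigma_total.  Permutation tests shuffle units
at the stratum under test (individuals among populations, populations among
regions) and use the raw, untruncated statistic so the null distribution is
continuous.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "squared_genotypic_distance",
    "AmovaResult",
    "amova",
    "pairwise_fst",
    "weir_cockerham_theta",
    "PcoaResult",
    "pcoa",
]


# ---------------------------------------------------------------------------
# count encoding


def _locus_arrays(matrix):
    """Per locus: allele-count matrix (N x A), typed mask, het indicator."""
    out = []
    samples = matrix.samples
    n = len(samples)
    for locus in matrix.loci:
        alleles = sorted({a for s in samples
                          for a in (matrix.entries.get((s, locus)) or ())})
        index = {a: i for i, a in enumerate(alleles)}
        C = np.zeros((n, max(len(alleles), 1)))
        typed = np.zeros(n, dtype=bool)
        het = np.zeros(n, dtype=bool)
        for i, s in enumerate(samples):
            e = matrix.entries.get((s, locus))
            if e is None:
                continue
            typed[i] = True
            C[i, index[e[0]]] += 1
            C[i, index[e[1]]] += 1
            het[i] = e[0] != e[1]
        out.append((C, typed, het))
    return out


def squared_genotypic_distance(matrix) -> np.ndarray:
    """Individual x individual squared genotypic distances.

    Per locus the contribution is 1/2 * sum over alleles of the squared
    difference in allele counts (0 for identical genotypes, up to 4 for
    homozygotes sharing no allele), summed over loci typed in both
    individuals.  Pairs with no commonly typed locus are NaN.
    """
    arrays = _locus_arrays(matrix)
    n = len(matrix.samples)
    D = np.zeros((n, n))
    shared = np.zeros((n, n))
    for C, typed, _ in arrays:
        sq = (C ** 2).sum(axis=1)
        d = 0.5 * (sq[:, None] + sq[None, :] - 2.0 * C @ C.T)
        mask = np.outer(typed, typed)
        D += np.where(mask, d, 0.0)
        shared += mask
    D[shared == 0] = np.nan
    np.fill_diagonal(D, 0.0)
    return D


# ---------------------------------------------------------------------------
# gamete-level sums of squares


def _ss_group(arrays, members: np.ndarray) -> float:
    """SS among allele copies of the individuals in ``members`` (bool mask)."""
    ss = 0.0
    for C, typed, _ in arrays:
        m = members & typed
        n = int(m.sum())
        if n == 0:
            continue
        g = C[m].sum(axis=0)
        ng = 2.0 * n
        ss += ((ng * ng - float((g ** 2).sum())) / 2.0) / ng
    return ss


def _ss_within_individuals(arrays, members: np.ndarray) -> float:
    ss = 0.0
    for _, typed, het in arrays:
        ss += float((members & typed & het).sum()) / 2.0
    return ss


def _components(arrays, pop_labels, region_labels, pop_sizes):
    """Sums of squares and variance components for one labelling.

    ``pop_labels``/``region_labels`` are integer arrays per individual;
    ``pop_sizes`` maps pop index -> gene-copy count (2 * n individuals).
    Returns a dict of SS, df, MS and raw variance components.
    """
    n_ind = len(pop_labels)
    pops = np.unique(pop_labels)
    regions = np.unique(region_labels)
    P, R = len(pops), len(regions)
    all_mask = np.ones(n_ind, dtype=bool)

    ss_total = _ss_group(arrays, all_mask)
    ss_wi = _ss_within_individuals(arrays, all_mask)
    ss_wp = sum(_ss_group(arrays, pop_labels == p) for p in pops)
    ss_ai = ss_wp - ss_wi
    if R > 1:
        ss_wr = sum(_ss_group(arrays, region_labels == r) for r in regions)
        ss_ap = ss_wr - ss_wp
        ss_ar = ss_total - ss_wr
    else:
        ss_ap = ss_total - ss_wp
        ss_ar = 0.0

    df_ar = R - 1
    df_ap = P - R
    df_ai = n_ind - P
    df_wi = n_ind

    ms_wi = ss_wi / df_wi
    ms_ai = ss_ai / df_ai if df_ai > 0 else np.nan
    ms_ap = ss_ap / df_ap if df_ap > 0 else np.nan
    ms_ar = ss_ar / df_ar if df_ar > 0 else np.nan

    c = np.array([pop_sizes[p] for p in pops], dtype=float)  # gene copies
    C = c.sum()
    region_of_pop = {}
    for p in pops:
        region_of_pop[p] = region_labels[pop_labels == p][0]
    Cr = {r: sum(pop_sizes[p] for p in pops if region_of_pop[p] == r)
          for r in regions}
    sum_cp2_over_Cr = sum(pop_sizes[p] ** 2 / Cr[region_of_pop[p]] for p in pops)
    sum_cp2_over_C = float((c ** 2).sum()) / C

    sigma_wi = ms_wi
    sigma_ai = (ms_ai - ms_wi) / 2.0 if df_ai > 0 else np.nan
    if df_ap > 0:
        n1 = (C - sum_cp2_over_Cr) / df_ap
        sigma_ap = (ms_ap - ms_wi - 2.0 * _z(sigma_ai)) / n1
    else:
        sigma_ap = np.nan
    if R > 1:
        n2 = (sum_cp2_over_Cr - sum_cp2_over_C) / (R - 1)
        n3 = (C - sum(v ** 2 for v in Cr.values()) / C) / (R - 1)
        sigma_ar = (ms_ar - ms_wi - 2.0 * _z(sigma_ai)
                    - n2 * _z(sigma_ap)) / n3
    else:
        sigma_ar = np.nan

    return {
        "ss": {"among_regions": ss_ar, "among_pops": ss_ap,
               "among_individuals": ss_ai, "within_individuals": ss_wi,
               "total": ss_total},
        "df": {"among_regions": df_ar, "among_pops": df_ap,
               "among_individuals": df_ai, "within_individuals": df_wi,
               "total": 2 * n_ind - 1},
        "ms": {"among_regions": ms_ar, "among_pops": ms_ap,
               "among_individuals": ms_ai, "within_individuals": ms_wi},
        "sigma": {"among_regions": sigma_ar, "among_pops": sigma_ap,
                  "among_individuals": sigma_ai, "within_individuals": sigma_wi},
    }


def _z(x):
    """NaN-safe non-negative value for use inside higher-stratum equations."""
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return 0.0
    return x


@dataclass
class AmovaResult:
    table: pd.DataFrame
    phi: dict
    p_values: dict
    fst: float

    def __repr__(self):
        return (f"AmovaResult(fst={self.fst:.4f}, "
                f"phi={ {k: round(v, 4) for k, v in self.phi.items()} })")


_ROW_NAMES = {
    "among_regions": "Among regions",
    "among_pops": "Among populations",
    "among_individuals": "Among individuals",
    "within_individuals": "Within individuals",
}


def amova(matrix, regions: Optional[Mapping[str, str]] = None,
          n_perm: int = 999, seed: int = 0) -> AmovaResult:
    """Hierarchical AMOVA of a codominant matrix.

    ``regions`` maps population name -> region; omit it for a two-level
    design (populations > individuals > within individuals).  Negative
    variance components are truncated to zero for the percentage column and
    the Phi statistics (raw values stay in the ``Est.Var.raw`` column).
    Permutation p-values: individuals among populations (within regions) for
    Phi-PR, whole populations among regions for Phi-RT, individuals among all
    populations for Phi-PT.
    """
    arrays = _locus_arrays(matrix)
    samples = matrix.samples
    pop_names = sorted(set(matrix.pop_map.values()))
    pop_index = {p: i for i, p in enumerate(pop_names)}
    pop_labels = np.array([pop_index[matrix.pop_map[s]] for s in samples])
    if regions is None:
        region_names = ["all"]
        region_of_pop = {p: "all" for p in pop_names}
    else:
        region_of_pop = dict(regions)
        region_names = sorted(set(region_of_pop.values()))
    region_index = {r: i for i, r in enumerate(region_names)}
    region_labels = np.array(
        [region_index[region_of_pop[matrix.pop_map[s]]] for s in samples])
    pop_sizes = {pop_index[p]: 2 * sum(1 for s in samples
                                       if matrix.pop_map[s] == p)
                 for p in pop_names}

    res = _components(arrays, pop_labels, region_labels, pop_sizes)
    have_regions = len(region_names) > 1
    strata = (["among_regions"] if have_regions else []) + \
        ["among_pops", "among_individuals", "within_individuals"]
    sigma_trunc = {k: max(_z(res["sigma"][k]), 0.0) for k in strata}
    total_var = sum(sigma_trunc.values())

    rows = []
    for k in strata:
        rows.append({
            "Source": _ROW_NAMES[k],
            "df": res["df"][k],
            "SS": res["ss"][k],
            "MS": res["ms"][k],
            "Est.Var.raw": res["sigma"][k],
            "Est.Var": sigma_trunc[k],
            "%": 100.0 * sigma_trunc[k] / total_var if total_var > 0 else np.nan,
        })
    rows.append({"Source": "Total", "df": res["df"]["total"],
                 "SS": res["ss"]["total"], "MS": np.nan,
                 "Est.Var.raw": np.nan, "Est.Var": total_var, "%": 100.0})
    table = pd.DataFrame(rows)

    lower = (sigma_trunc["among_pops"] + sigma_trunc["among_individuals"]
             + sigma_trunc["within_individuals"])
    phi = {}
    if have_regions:
        phi["PhiRT"] = (sigma_trunc["among_regions"] / total_var
                        if total_var > 0 else np.nan)
        phi["PhiPR"] = (sigma_trunc["among_pops"] / lower
                        if lower > 0 else np.nan)
        fst = ((sigma_trunc["among_regions"] + sigma_trunc["among_pops"])
               / total_var if total_var > 0 else np.nan)
    else:
        fst = (sigma_trunc["among_pops"] / total_var
               if total_var > 0 else np.nan)
    phi["PhiPT"] = fst

    p_values = {}
    if n_perm and n_perm > 0:
        rng = np.random.default_rng(seed)

        def raw_stats(plabels, rlabels):
            r = _components(arrays, plabels, rlabels, pop_sizes)
            s = r["sigma"]
            tot = sum(_z(s[k]) for k in strata)
            out = {}
            if have_regions:
                out["PhiRT"] = _z(s["among_regions"]) / tot if tot else 0.0
                low = (_z(s["among_pops"]) + _z(s["among_individuals"])
                       + _z(s["within_individuals"]))
                out["PhiPR"] = _z(s["among_pops"]) / low if low else 0.0
                out["PhiPT"] = ((_z(s["among_regions"]) + _z(s["among_pops"]))
                                / tot if tot else 0.0)
            else:
                out["PhiPT"] = _z(s["among_pops"]) / tot if tot else 0.0
            return out

        obs = raw_stats(pop_labels, region_labels)
        hits = {k: 0 for k in obs}
        for _ in range(n_perm):
            # Phi-PT: individuals shuffled among all populations
            perm = rng.permutation(pop_labels)
            perm_regions = np.array([
                region_index[region_of_pop[pop_names[p]]] for p in perm])
            stat = raw_stats(perm, perm_regions)
            if stat["PhiPT"] >= obs["PhiPT"] - 1e-12:
                hits["PhiPT"] += 1
            if have_regions:
                # Phi-PR: individuals shuffled among pops within their region
                perm2 = pop_labels.copy()
                for r in np.unique(region_labels):
                    idx = np.where(region_labels == r)[0]
                    perm2[idx] = pop_labels[idx][rng.permutation(len(idx))]
                stat2 = raw_stats(perm2, region_labels)
                if stat2["PhiPR"] >= obs["PhiPR"] - 1e-12:
                    hits["PhiPR"] += 1
                # Phi-RT: whole populations shuffled among regions
                pr = [region_of_pop[p] for p in pop_names]
                shuffled = list(rng.permutation(pr))
                rmap = {pop_index[p]: region_index[shuffled[i]]
                        for i, p in enumerate(pop_names)}
                rlab = np.array([rmap[p] for p in pop_labels])
                stat3 = raw_stats(pop_labels, rlab)
                if stat3["PhiRT"] >= obs["PhiRT"] - 1e-12:
                    hits["PhiRT"] += 1
        p_values = {k: (hits[k] + 1) / (n_perm + 1) for k in hits}

    return AmovaResult(table=table, phi=phi, p_values=p_values, fst=fst)


# ---------------------------------------------------------------------------
# pairwise FST


def _pair_fst_from_counts(arrays, labels, n1, n2):
    """Allele-level AMOVA FST for a 2-population labelling (0/1 labels).

    Returns ``(truncated, raw)``: the reported value truncates a negative
    among-population component to zero; the raw value keeps its sign for
    permutation comparisons.
    """
    pop_sizes = {0: 2 * n1, 1: 2 * n2}
    res = _components(arrays, labels, np.zeros_like(labels), pop_sizes)
    s = res["sigma"]
    sap = max(_z(s["among_pops"]), 0.0)
    sai = max(_z(s["among_individuals"]), 0.0)
    swi = max(_z(s["within_individuals"]), 0.0)
    total = sap + sai + swi
    raw_sap = _z(s["among_pops"])
    raw_total = raw_sap + _z(s["among_individuals"]) + _z(s["within_individuals"])
    raw = raw_sap / raw_total if raw_total > 0 else 0.0
    return (sap / total if total > 0 else np.nan), raw


def pairwise_fst(matrix, n_perm: int = 999, seed: int = 0,
                 method: str = "amova"):
    """Population x population FST matrix with permutation p-values.

    ``method="amova"`` (default) runs, per pair, the allele-level AMOVA with
    populations, individuals and within-individual strata; its Phi statistic
    is an unbiased estimator of Wright's FST under random mating.
    ``method="phipt"`` is the individual-level variant without the
    within-individual stratum (GenAlEx's PhiPT for binary/distance data);
    ``method="wc"`` is Weir & Cockerham's theta.  Permutations shuffle
    individuals between the two populations; p-values use the raw statistic.
    Populations with fewer than two individuals give NaN entries.
    """
    pops = sorted(set(matrix.pop_map.values()))
    k = len(pops)
    fst = pd.DataFrame(np.zeros((k, k)), index=pops, columns=pops)
    pvals = pd.DataFrame(np.ones((k, k)), index=pops, columns=pops)
    rng = np.random.default_rng(seed)
    for i in range(k):
        for j in range(i + 1, k):
            sub = _submatrix(matrix, [pops[i], pops[j]])
            n1 = sum(1 for s in sub.samples if sub.pop_map[s] == pops[i])
            n2 = len(sub.samples) - n1
            if n1 < 2 or n2 < 2:
                fst.iloc[i, j] = fst.iloc[j, i] = np.nan
                pvals.iloc[i, j] = pvals.iloc[j, i] = np.nan
                continue
            value, raw_obs, perm_raw = _pair_fst(
                sub, pops[i], pops[j], n_perm, rng, method)
            fst.iloc[i, j] = fst.iloc[j, i] = value
            if n_perm:
                p = (np.sum(perm_raw >= raw_obs - 1e-12) + 1) / (n_perm + 1)
                pvals.iloc[i, j] = pvals.iloc[j, i] = p
    return fst, pvals


def _submatrix(matrix, keep_pops):
    from ..genotyping import GenotypeMatrix

    samples = [s for s in matrix.samples if matrix.pop_map[s] in keep_pops]
    entries = {(s, l): matrix.entries.get((s, l))
               for s in samples for l in matrix.loci}
    return GenotypeMatrix(samples, matrix.loci, entries,
                          {s: matrix.pop_map[s] for s in samples},
                          matrix.registry)


def _pair_fst(sub, pop_a, pop_b, n_perm, rng, method):
    arrays = _locus_arrays(sub)
    labels = np.array([0 if sub.pop_map[s] == pop_a else 1
                       for s in sub.samples])
    n1 = int((labels == 0).sum())
    n2 = int((labels == 1).sum())
    if method == "amova":
        value, raw_obs = _pair_fst_from_counts(arrays, labels, n1, n2)
        stat = lambda lab: _pair_fst_from_counts(arrays, lab, n1, n2)[1]
    elif method == "phipt":
        value, raw_obs = _phipt_individual(arrays, labels, n1, n2)
        stat = lambda lab: _phipt_individual(arrays, lab, n1, n2)[1]
    elif method == "wc":
        raw_obs = _wc_theta(arrays, labels)
        value = max(raw_obs, 0.0)
        stat = lambda lab: _wc_theta(arrays, lab)
    else:
        raise ValueError(f"unknown method {method!r}")
    perm_raw = np.empty(n_perm) if n_perm else np.empty(0)
    for t in range(n_perm or 0):
        perm_raw[t] = stat(rng.permutation(labels))
    return value, raw_obs, perm_raw


def _phipt_individual(arrays, labels, n1, n2):
    """Two-stratum AMOVA on individual-level squared genotypic distances."""
    # individual-level SS from counts: observation = allele-count vector / sqrt2
    ss_total = 0.0
    ss_within = 0.0
    for C, typed, _ in arrays:
        def ss_of(members):
            m = members & typed
            n = int(m.sum())
            if n < 1:
                return 0.0
            X = C[m]
            mu = X.mean(axis=0)
            return 0.5 * float(((X - mu) ** 2).sum())
        ss_total += ss_of(np.ones_like(typed, dtype=bool))
        ss_within += ss_of(labels == 0) + ss_of(labels == 1)
    n = n1 + n2
    df_among, df_within = 1, n - 2
    ms_among = (ss_total - ss_within) / df_among
    ms_within = ss_within / df_within if df_within > 0 else np.nan
    n0 = (n - (n1 ** 2 + n2 ** 2) / n)  # / (P - 1) with P = 2
    sigma_a = (ms_among - ms_within) / n0
    raw = sigma_a / (sigma_a + ms_within) if (sigma_a + ms_within) > 0 else 0.0
    value = max(raw, 0.0)
    return value, raw


def _wc_theta(arrays, labels):
    """Weir & Cockerham (1984) theta over loci and alleles, two or more pops."""
    num = 0.0
    den = 0.0
    groups = np.unique(labels)
    for C, typed, het in arrays:
        ns = np.array([int(((labels == g) & typed).sum()) for g in groups],
                      dtype=float)
        if (ns < 1).any() or ns.sum() < 2:
            continue
        r = len(groups)
        nbar = ns.mean()
        nc = (r * nbar - (ns ** 2).sum() / (r * nbar)) / (r - 1)
        A = C.shape[1]
        for a in range(A):
            p_i = np.array([
                C[(labels == g) & typed, a].sum() / (2 * ns[gi])
                for gi, g in enumerate(groups)])
            pbar = (ns * p_i).sum() / (r * nbar)
            if pbar <= 0 or pbar >= 1:
                continue
            s2 = (ns * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
            h_i = np.array([
                ((labels == g) & typed & het
                 & (C[:, a] == 1)).sum() / ns[gi]
                for gi, g in enumerate(groups)])
            hbar = (ns * h_i).sum() / (r * nbar)
            a_comp = (nbar / nc) * (
                s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
                / (nbar - 1))
            b_comp = (nbar / (nbar - 1)) * (
                pbar * (1 - pbar) - (r - 1) / r * s2
                - (2 * nbar - 1) / (4 * nbar) * hbar)
            c_comp = hbar / 2
            num += a_comp
            den += a_comp + b_comp + c_comp
    return num / den if den != 0 else 0.0


def weir_cockerham_theta(matrix) -> float:
    """Multi-population, multilocus Weir & Cockerham (1984) theta."""
    arrays = _locus_arrays(matrix)
    pops = sorted(set(matrix.pop_map.values()))
    index = {p: i for i, p in enumerate(pops)}
    labels = np.array([index[matrix.pop_map[s]] for s in matrix.samples])
    return _wc_theta(arrays, labels)


# ---------------------------------------------------------------------------
# principal coordinates


@dataclass
class PcoaResult:
    coordinates: np.ndarray      # individuals x axes
    percent_variance: np.ndarray  # per retained axis
    eigenvalues: np.ndarray       # all eigenvalues, descending


def pcoa(D: np.ndarray, n_axes: int = 3, squared: bool = False) -> PcoaResult:
    """Metric multidimensional scaling of a distance matrix.

    Gower double-centering of -1/2 * D^2 (pass ``squared=True`` when ``D``
    already holds squared distances, as :func:`squared_genotypic_distance`
    does), eigendecomposition, coordinates scaled by the square root of the
    eigenvalues.  Percent variance is taken over positive eigenvalues only.
    """
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if np.isnan(D).any():
        raise ValueError("distance matrix contains undefined entries")
    if not np.allclose(D, D.T, atol=1e-9):
        raise ValueError("distance matrix must be symmetric")
    A = -0.5 * (D if squared else D ** 2)
    n = D.shape[0]
    row = A.mean(axis=1, keepdims=True)
    col = A.mean(axis=0, keepdims=True)
    B = A - row - col + A.mean()
    vals, vecs = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > 1e-10
    total_pos = vals[pos].sum()
    n_axes = min(n_axes, n)
    coords = np.zeros((n, n_axes))
    pct = np.zeros(n_axes)
    for ax in range(n_axes):
        if ax < len(vals) and vals[ax] > 1e-10:
            coords[:, ax] = vecs[:, ax] * np.sqrt(vals[ax])
            pct[ax] = 100.0 * vals[ax] / total_pos if total_pos > 0 else 0.0
    return PcoaResult(coordinates=coords, percent_variance=pct,
                      eigenvalues=vals)
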