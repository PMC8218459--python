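"""Synthetic amplicon and mitochondrial data with known truth.

This module generates the inputs of an SSR-GBAS study — diploid genotypes at
tetra/pentanucleotide microsatellite loci under an island model, merged
amplicon reads carrying realistic PCR/sequencing artifacts, and aligned
mitochondrial sequences with planted group divergence — so that every
downstream stage (locus discovery, genotyping, population statistics,
haplotype analyses) can be validated against a ground truth.

Population differentiation follows the Balding–Nichols island model:
population allele frequencies are Dirichlet draws with parameters
``p_i * (1 - F) / F`` around the ancestral vector ``p``, so that the expected
Wright FST across loci equals ``F`` and each per-allele frequency has variance
``F * p_i * (1 - p_i)``.

Reads are emitted already merged (one sequence per amplicon fragment):
``forward_primer + left_flank + motif*repeats + right_flank +
revcomp(reverse_primer)``.  Artifacts are per-base substitution errors and
single-repeat-unit stutter (PCR slippage producing reads one unit shorter than
the template allele).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "LocusSpec",
    "PopModel",
    "ReadSimConfig",
    "TrueGenotypeTable",
    "Allele",
    "draw_population_allele_freqs",
    "simulate_genotypes",
    "build_allele_sequence",
    "simulate_reads",
    "simulate_coi_dataset",
    "make_tetranucleotide_loci",
    "make_pop_model",
    "write_fastq_dir",
    "write_locus_csv",
    "truth_wai_pair",
]

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# An allele of a microsatellite locus: repeat count of the tandem tract plus a
# flanking-SNP state (0 = reference flanks, 1 = all declared SNP substitutions
# applied).
Allele = tuple  # (repeat_count: int, snp_state: int)


@dataclass(frozen=True)
class LocusSpec:
    """Definition of one SSR locus and its amplicon layout.

    ``snp_positions`` lists flanking single-nucleotide variants as
    ``(flank, offset, alt_base)`` with ``flank`` in {"left", "right"} and a
    0-based offset into that flank.  Alleles with ``snp_state == 1`` carry all
    of them; ``snp_state == 0`` is the reference flank sequence.
    """

    name: str
    motif: str
    min_repeats: int
    max_repeats: int
    left_flank: str
    right_flank: str
    forward_primer: str
    reverse_primer: str
    snp_positions: tuple = ()

    def __post_init__(self):
        if len(self.motif) not in (2, 3, 4, 5):
            raise ValueError(f"motif length must be 2-5, got {self.motif!r}")
        if len(self.left_flank) < 30 or len(self.right_flank) < 30:
            raise ValueError("flanks must be at least 30 bases")
        if self.min_repeats < 1 or self.max_repeats < self.min_repeats:
            raise ValueError("invalid repeat-count bounds")
        for r in (self.min_repeats, self.max_repeats):
            n = self.amplicon_length(r)
            if not 250 <= n <= 450:
                raise ValueError(
                    f"amplicon length {n} for {r} repeats outside [250, 450]"
                )

    def amplicon_length(self, repeat_count: int) -> int:
        return (
            len(self.forward_primer)
            + len(self.left_flank)
            + len(self.motif) * repeat_count
            + len(self.right_flank)
            + len(self.reverse_primer)
        )

    def insert_length(self, repeat_count: int) -> int:
        """Primer-trimmed amplicon length for a given repeat count."""
        return (
            len(self.left_flank)
            + len(self.motif) * repeat_count
            + len(self.right_flank)
        )


@dataclass(frozen=True)
class PopModel:
    """Island-model study design.

    ``ancestral_freqs`` maps locus name -> (alleles, probability vector); the
    alleles are ``(repeat_count, snp_state)`` pairs resolvable through the
    matching :class:`LocusSpec`.
    """

    n_pops: int
    n_ind_per_pop: int
    fst_target: float
    inbreeding_f: float
    ancestral_freqs: Mapping[str, tuple]

    def __post_init__(self):
        if not 0 <= self.fst_target < 1:
            raise ValueError("fst_target must be in [0, 1)")
        if not 0 <= self.inbreeding_f <= 1:
            raise ValueError("inbreeding_f must be in [0, 1]")
        for locus, (alleles, p) in self.ancestral_freqs.items():
            p = np.asarray(p, dtype=float)
            if len(alleles) != len(p):
                raise ValueError(f"{locus}: alleles and freqs differ in length")
            if abs(p.sum() - 1.0) > 1e-9:
                raise ValueError(f"{locus}: frequencies sum to {p.sum()}, not 1")


@dataclass(frozen=True)
class ReadSimConfig:
    """Depth and artifact rates for merged-read simulation."""

    mean_depth: float = 100.0
    base_error_rate: float = 0.001
    stutter_prob: float = 0.15
    seed: int = 0

    def __post_init__(self):
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        for r in (self.base_error_rate, self.stutter_prob):
            if not 0 <= r <= 1:
                raise ValueError("rates must be in [0, 1]")


class TrueGenotypeTable:
    """Mapping (sample, locus) -> unordered diploid allele pair."""

    def __init__(self, entries: Mapping[tuple, tuple], pop_map: Mapping[str, str]):
        self.entries = {k: tuple(sorted(v)) for k, v in entries.items()}
        for k, pair in self.entries.items():
            if len(pair) != 2:
                raise ValueError(f"{k}: diploid entry must hold two alleles")
        self.pop_map = dict(pop_map)
        self.samples = sorted({s for s, _ in self.entries})
        self.loci = sorted({l for _, l in self.entries})

    def __getitem__(self, key):
        return self.entries[key]

    def to_csv(self, path) -> None:
        import csv

        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["sample", "population", "locus",
                        "repeats_1", "snp_1", "repeats_2", "snp_2"])
            for (s, l), ((r1, v1), (r2, v2)) in sorted(self.entries.items()):
                w.writerow([s, self.pop_map[s], l, r1, v1, r2, v2])


def draw_population_allele_freqs(model: PopModel, seed: int):
    """Per-population, per-locus allele frequencies under Balding–Nichols.

    Returns ``{pop_index: {locus: freq_vector}}``.  With ``fst_target == 0``
    every population inherits the ancestral vector unchanged.
    """
    if not 0 <= model.fst_target < 1:
        raise ValueError("fst_target must be in [0, 1)")
    rng = np.random.default_rng(seed)
    F = model.fst_target
    out = {}
    for pop in range(model.n_pops):
        per_locus = {}
        for locus, (alleles, p) in model.ancestral_freqs.items():
            p = np.asarray(p, dtype=float)
            if F == 0:
                per_locus[locus] = p.copy()
                continue
            fixed = p >= 1 - 1e-12
            if fixed.any():
                # degenerate ancestral vector: population stays fixed
                per_locus[locus] = p.copy()
                continue
            alpha = p * (1 - F) / F
            # guard against zero-frequency ancestral alleles
            draw = np.zeros_like(p)
            pos = alpha > 0
            draw[pos] = rng.dirichlet(alpha[pos])
            per_locus[locus] = draw
        out[pop] = per_locus
    return out


def simulate_genotypes(freqs, model: PopModel, seed: int,
                       sample_prefix: str = "P") -> TrueGenotypeTable:
    """Draw diploid genotypes from per-population allele frequencies.

    With inbreeding coefficient ``f`` an individual is autozygous (one allele
    drawn, duplicated) with probability ``f`` and a random-union-of-gametes
    draw otherwise, giving heterozygosity ``(1 - f) * 2 p q`` in expectation.
    """
    rng = np.random.default_rng(seed)
    f = model.inbreeding_f
    entries, pop_map = {}, {}
    for pop in range(model.n_pops):
        pname = f"{sample_prefix}{pop + 1}"
        for ind in range(model.n_ind_per_pop):
            sample = f"{pname}_I{ind + 1:03d}"
            pop_map[sample] = pname
            for locus, (alleles, _) in model.ancestral_freqs.items():
                p = freqs[pop][locus]
                if len(p) == 0:
                    raise ValueError(f"{locus}: empty frequency vector")
                if f > 0 and rng.random() < f:
                    i = rng.choice(len(p), p=p)
                    pair = (alleles[i], alleles[i])
                else:
                    i, j = rng.choice(len(p), size=2, p=p)
                    pair = (alleles[i], alleles[j])
                entries[(sample, locus)] = pair
    return TrueGenotypeTable(entries, pop_map)


def build_allele_sequence(locus: LocusSpec, repeat_count: int,
                          snp_state: int = 0, with_primers: bool = False) -> str:
    """Amplicon insert sequence of one allele (flanks + perfect repeat tract)."""
    if not locus.min_repeats <= repeat_count <= locus.max_repeats:
        raise ValueError(
            f"repeat_count {repeat_count} outside "
            f"[{locus.min_repeats}, {locus.max_repeats}] for {locus.name}"
        )
    left, right = locus.left_flank, locus.right_flank
    if snp_state:
        left, right = list(left), list(right)
        for flank, offset, alt in locus.snp_positions:
            target = left if flank == "left" else right
            target[offset] = alt
        left, right = "".join(left), "".join(right)
    seq = left + locus.motif * repeat_count + right
    if with_primers:
        seq = locus.forward_primer + seq + revcomp(locus.reverse_primer)
    return seq


def _apply_substitutions(seq: str, rate: float, rng) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(arr.size) < rate)[0]
    if hits.size == 0:
        return seq
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    for i in hits:
        choices = bases[bases != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


def simulate_reads(truth: TrueGenotypeTable, loci: Sequence[LocusSpec],
                   config: ReadSimConfig):
    """Merged amplicon reads per sample, with depth, stutter and error models.

    Returns ``{sample: [(read_id, sequence), ...]}``.  Depth per
    (sample, locus) is Poisson(``mean_depth``); each read copies one of the two
    true alleles uniformly; with probability ``stutter_prob`` the read loses
    one repeat unit; substitution errors are applied per base.
    """
    rng = np.random.default_rng(config.seed)
    by_name = {l.name: l for l in loci}
    reads = {s: [] for s in truth.samples}
    for sample in truth.samples:
        counter = 0
        for locus_name in truth.loci:
            if (sample, locus_name) not in truth.entries:
                continue
            locus = by_name[locus_name]
            pair = truth.entries[(sample, locus_name)]
            depth = rng.poisson(config.mean_depth)
            if depth == 0:
                continue
            which = rng.integers(0, 2, size=depth)
            stutter = rng.random(depth) < config.stutter_prob
            for k in range(depth):
                rep, snp = pair[which[k]]
                if stutter[k] and rep - 1 >= locus.min_repeats:
                    rep = rep - 1
                seq = build_allele_sequence(locus, rep, snp, with_primers=True)
                seq = _apply_substitutions(seq, config.base_error_rate, rng)
                counter += 1
                reads[sample].append((f"{sample}_r{counter:06d}", seq))
    return reads


def write_fastq_dir(reads, out_dir, quality_char: str = "G") -> list:
    """One 4-line-record FASTQ per sample; constant Phred-38 qualities."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for sample, recs in reads.items():
        path = out_dir / f"{sample}.fastq"
        with open(path, "w") as fh:
            for rid, seq in recs:
                fh.write(f"@{rid}\n{seq}\n+\n{quality_char * len(seq)}\n")
        paths.append(path)
    return paths


def write_locus_csv(loci: Sequence[LocusSpec], path) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["name", "motif", "forward_primer", "reverse_primer",
                    "left_flank", "right_flank"])
        for l in loci:
            w.writerow([l.name, l.motif, l.forward_primer, l.reverse_primer,
                        l.left_flank, l.right_flank])


def truth_wai_pair(truth: TrueGenotypeTable, locus: LocusSpec, sample: str):
    """Expected (length, insert sequence) allele pair for one truth entry."""
    pair = truth.entries[(sample, locus.name)]
    out = []
    for rep, snp in pair:
        seq = build_allele_sequence(locus, rep, snp)
        out.append((len(seq), seq))
    return tuple(sorted(out))


# ---------------------------------------------------------------------------
# study-condition builders


def _random_dna(rng, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def make_tetranucleotide_loci(n_loci: int, seed: int, *, motif_len: int = 4,
                              flank_len: int = 115, primer_len: int = 20,
                              min_repeats: int = 8, max_repeats: int = 15,
                              snp_fraction: float = 0.5):
    """Random loci matching the study's amplicon design.

    Defaults give primer-trimmed inserts of 262-290 bp (above the 250 bp
    read-length threshold even for single-unit stutter) and full amplicons of
    302-330 bp (inside the 300-450 bp product window).  A fraction of loci
    carry one flanking SNP so that same-length sequence alleles exist.
    """
    rng = np.random.default_rng(seed)
    loci = []
    seen_primers = set()
    for i in range(n_loci):
        while True:
            motif = _random_dna(rng, motif_len)
            # avoid homopolymer or periodic motifs (degenerate tracts)
            if len(set(motif)) > 1 and not _is_periodic(motif):
                break
        while True:
            fwd = _random_dna(rng, primer_len)
            rev = _random_dna(rng, primer_len)
            if fwd not in seen_primers and rev not in seen_primers and fwd != rev:
                seen_primers.update((fwd, rev))
                break
        left = _clean_flank(rng, flank_len, motif)
        right = _clean_flank(rng, flank_len, motif)
        snps = ()
        if rng.random() < snp_fraction:
            off = int(rng.integers(5, flank_len - 5))
            ref = left[off]
            alt = rng.choice([b for b in "ACGT" if b != ref])
            snps = (("left", off, str(alt)),)
        loci.append(LocusSpec(
            name=f"SIM{i + 1:02d}_{motif}",
            motif=motif,
            min_repeats=min_repeats,
            max_repeats=max_repeats,
            left_flank=left,
            right_flank=right,
            forward_primer=fwd,
            reverse_primer=rev,
            snp_positions=snps,
        ))
    return loci


def _is_periodic(motif: str) -> bool:
    for k in range(1, len(motif)):
        if len(motif) % k == 0 and motif == motif[:k] * (len(motif) // k):
            return True
    return False


def _clean_flank(rng, n: int, motif: str) -> str:
    """Flank free of the locus motif, long homopolymers and other SSR tracts."""
    from itertools import groupby

    while True:
        s = _random_dna(rng, n)
        if motif in s:
            continue
        if max(len(list(g)) for _, g in groupby(s)) > 4:
            continue
        if _has_tandem(s):
            continue
        return s


def _has_tandem(s: str, min_units: int = 4) -> bool:
    # any unit of length 2-5 repeated >= min_units times would confound
    # discovery tests on planted reads
    for k in range(2, 6):
        for i in range(len(s) - k * min_units + 1):
            unit = s[i:i + k]
            if s[i:i + k * min_units] == unit * min_units:
                return True
    return False


def make_pop_model(loci: Sequence[LocusSpec], n_pops: int, n_ind_per_pop: int,
                   fst_target: float, inbreeding_f: float, seed: int,
                   n_length_alleles: int = 5) -> PopModel:
    """Ancestral allele frequencies drawn from a flat Dirichlet per locus.

    Alleles are distinct repeat counts; loci carrying a declared flanking SNP
    additionally segregate an alternate-flank copy of one repeat count, giving
    same-length WAI alleles.
    """
    rng = np.random.default_rng(seed)
    anc = {}
    for locus in loci:
        counts = rng.choice(
            np.arange(locus.min_repeats, locus.max_repeats + 1),
            size=min(n_length_alleles,
                     locus.max_repeats - locus.min_repeats + 1),
            replace=False,
        )
        alleles = [(int(c), 0) for c in sorted(counts)]
        if locus.snp_positions:
            alleles.append((int(sorted(counts)[0]), 1))
        p = rng.dirichlet(np.full(len(alleles), 5.0))
        anc[locus.name] = (alleles, p)
    return PopModel(
        n_pops=n_pops,
        n_ind_per_pop=n_ind_per_pop,
        fst_target=fst_target,
        inbreeding_f=inbreeding_f,
        ancestral_freqs=anc,
    )


# ---------------------------------------------------------------------------
# mitochondrial alignments


def simulate_coi_dataset(n_pops: int, seqs_per_pop: int, seq_length: int,
                         divergence_spec: Sequence[int], seed: int,
                         within_variation: int = 0):
    """Aligned sequences with planted between-group divergence.

    ``divergence_spec[g]`` is the number of fixed differences between group
    ``g``'s founder haplotype and the shared ancestral sequence; mutation sites
    are distinct across groups, so two groups differ at exactly
    ``divergence_spec[a] + divergence_spec[b]`` sites.  ``within_variation``
    adds that many private singleton mutations to each non-founder sequence
    (at sites untouched by the group mutations).

    Returns ``(ids, sequences, pop_map)`` with equal-length sequences.
    """
    if seq_length < 1:
        raise ValueError("seq_length must be >= 1")
    if len(divergence_spec) != n_pops:
        raise ValueError("divergence_spec must list one count per group")
    total = sum(divergence_spec) + n_pops * seqs_per_pop * within_variation
    if total > seq_length:
        raise ValueError("divergence_spec requires more mutations than sites")
    rng = np.random.default_rng(seed)
    ancestor = _random_dna(rng, seq_length)
    site_pool = list(rng.permutation(seq_length))
    ids, seqs, pop_map = [], [], {}
    for g in range(n_pops):
        founder = list(ancestor)
        for _ in range(divergence_spec[g]):
            site = site_pool.pop()
            founder[site] = rng.choice([b for b in "ACGT" if b != founder[site]])
        founder = "".join(founder)
        for i in range(seqs_per_pop):
            seq = founder
            if within_variation and i > 0:
                s = list(seq)
                for _ in range(within_variation):
                    site = site_pool.pop()
                    s[site] = rng.choice([b for b in "ACGT" if b != s[site]])
                seq = "".join(s)
            sid = f"G{g + 1}_S{i + 1:02d}"
            ids.append(sid)
            seqs.append(seq)
            pop_map[sid] = f"G{g + 1}"
    return ids, seqs, pop_map


def write_fasta(ids, seqs, path) -> None:
    with open(path, "w") as fh:
        for i, s in zip(ids, seqs):
            fh.write(f">{i}\n{s}\n")


def write_pop_map(pop_map, path) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["sequence_id", "population"])
        for k in sorted(pop_map):
            w.writerow([k, pop_map[k]])
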