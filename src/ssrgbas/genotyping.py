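"""SSR-GBAS genotyping core: merged reads to a codominant WAI matrix.

The pipeline mirrors the four classic steps of microsatellite genotyping by
amplicon sequencing:

1. demultiplex merged reads by matching both locus primers (Hamming distance
   at the fixed read ends) and trim them;
2. per (sample, locus), count reads by length, discarding reads below the
   250 bp threshold;
3. call a length genotype: peaks with >= 10 supporting reads are candidate
   alleles, peaks exactly one repeat unit shorter than a stronger peak and
   below half its count are absorbed as PCR stutter, and the surviving peaks
   are classified as homozygote / heterozygote / missing;
4. call whole-amplicon-information (WAI) alleles: a consensus sequence per
   length, with positions where a second base is well supported splitting a
   length class into two same-length sequence alleles (flanking SNPs).

Missing genotypes are coded ``None`` in memory, an empty field in the native
CSV, and ``0`` in the GenAlEx-dialect export.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

from .simdata import LocusSpec, revcomp

__all__ = [
    "LocusBin",
    "LengthGenotype",
    "SequenceAllele",
    "GenotypeMatrix",
    "PipelineParams",
    "merge_pairs",
    "demultiplex_reads",
    "build_length_histogram",
    "call_length_genotype",
    "consensus_sequence",
    "call_wai_alleles",
    "assemble_genotype_matrix",
    "filter_missing",
    "run_pipeline",
    "read_fastq_dir",
]

MISSING = None


@dataclass
class LocusBin:
    locus: str
    sample: str
    reads: list = field(default_factory=list)  # primer-trimmed sequences


@dataclass
class LengthGenotype:
    """Allele lengths with supporting read counts and diagnostic flags."""

    allele_lengths: Optional[tuple]  # (a, b) sorted, or None = missing
    supporting_counts: dict = field(default_factory=dict)
    flags: frozenset = frozenset()

    @property
    def is_missing(self) -> bool:
        return self.allele_lengths is None


@dataclass(frozen=True)
class SequenceAllele:
    locus: str
    length: int
    consensus: str
    allele_id: str
    snp_signature: tuple = ()  # (1-based position, base) vs locus reference


@dataclass(frozen=True)
class PipelineParams:
    min_length: int = 250
    min_reads: int = 10
    min_minor_ratio: float = 0.25
    stutter_ratio: float = 0.5
    min_snp_fraction: float = 0.25
    max_primer_mismatches: int = 2


# ---------------------------------------------------------------------------
# plumbing: pair merging and primer demultiplexing


def merge_pairs(forward_read: str, reverse_read: str, min_overlap: int = 20,
                max_mismatch_frac: float = 0.1):
    """Merge a read pair by its best ungapped 3' overlap.

    The reverse read is reverse-complemented and slid over the forward read;
    the overlap with the fewest mismatches (longest on ties) wins if it spans
    at least ``min_overlap`` bases with a mismatch fraction at or below the
    threshold.  Disagreeing overlap positions become N.  Returns the merged
    sequence or ``None`` when no overlap qualifies.
    """
    rev = revcomp(reverse_read)
    best = None  # (mismatch_frac, -overlap, merged)
    max_ov = min(len(forward_read), len(rev))
    for ov in range(min_overlap, max_ov + 1):
        a = forward_read[len(forward_read) - ov:]
        b = rev[:ov]
        mism = sum(1 for x, y in zip(a, b) if x != y and x != "N" and y != "N")
        frac = mism / ov
        if frac > max_mismatch_frac:
            continue
        overlap = "".join(x if x == y or y == "N" else (y if x == "N" else "N")
                          for x, y in zip(a, b))
        merged = forward_read[:len(forward_read) - ov] + overlap + rev[ov:]
        key = (frac, -ov)
        if best is None or key < best[0]:
            best = (key, merged)
    return None if best is None else best[1]


def _hamming_le(a: str, b: str, limit: int) -> bool:
    if len(a) != len(b):
        return False
    d = 0
    for x, y in zip(a, b):
        if x != y:
            d += 1
            if d > limit:
                return False
    return True


def demultiplex_reads(reads: Sequence[tuple], loci: Sequence[LocusSpec],
                      sample: str = "sample",
                      max_mismatches_per_primer: int = 2):
    """Assign merged reads to loci by both primers; trim primers.

    A read matches a locus when its 5' prefix equals the forward primer and
    its 3' suffix equals the reverse-complemented reverse primer, each within
    the mismatch tolerance.  Reads matching primers of two different loci
    ("chimera" or ambiguous) and reads matching no locus are left unassigned.
    Returns ``(bins, unassigned)`` where ``bins`` maps locus name ->
    :class:`LocusBin` and ``unassigned`` is a list of (read_id, tag).
    """
    bins = {l.name: LocusBin(locus=l.name, sample=sample) for l in loci}
    rc_rev = {l.name: revcomp(l.reverse_primer) for l in loci}
    unassigned = []
    for rid, seq in reads:
        fwd_hits = [l.name for l in loci
                    if _hamming_le(seq[:len(l.forward_primer)],
                                   l.forward_primer, max_mismatches_per_primer)]
        rev_hits = [l.name for l in loci
                    if _hamming_le(seq[len(seq) - len(l.reverse_primer):],
                                   rc_rev[l.name], max_mismatches_per_primer)]
        both = [n for n in fwd_hits if n in rev_hits]
        if len(both) == 1:
            locus = next(l for l in loci if l.name == both[0])
            trimmed = seq[len(locus.forward_primer):
                          len(seq) - len(locus.reverse_primer)]
            bins[locus.name].reads.append(trimmed)
        elif len(both) > 1:
            unassigned.append((rid, "ambiguous"))
        elif fwd_hits and rev_hits:
            unassigned.append((rid, "chimera"))
        else:
            unassigned.append((rid, "no_primer"))
    return bins, unassigned


# ---------------------------------------------------------------------------
# length genotypes


def build_length_histogram(bin_or_reads, min_length: int = 250) -> dict:
    """Read counts per length, excluding reads below ``min_length``."""
    reads = bin_or_reads.reads if isinstance(bin_or_reads, LocusBin) else bin_or_reads
    hist = Counter(len(r) for r in reads if len(r) >= min_length)
    return dict(hist)


def call_length_genotype(hist: Mapping[int, int], motif_len: int,
                         min_reads: int = 10, min_minor_ratio: float = 0.25,
                         stutter_ratio: float = 0.5) -> LengthGenotype:
    """Stutter-aware diploid genotype call from a length histogram.

    Peaks with at least ``min_reads`` reads are candidate alleles.  A
    candidate exactly one motif length shorter than a higher-count candidate,
    with fewer than ``stutter_ratio`` times its reads, is reclassified as PCR
    stutter and its reads are added to the parent allele.  After stutter
    absorption: two candidates whose minor/major ratio reaches
    ``min_minor_ratio`` -> heterozygote; one candidate -> homozygote; none ->
    missing (low_depth); more than two -> missing (ambiguous).
    """
    if motif_len <= 0:
        raise ValueError("motif_len must be positive")
    counts = dict(hist)
    candidates = {L: c for L, c in counts.items() if c >= min_reads}
    flags = set()
    # absorb stutter peaks, largest parents first so chained stutter collapses
    for L in sorted(candidates, key=lambda x: -candidates[x]):
        if L not in candidates:
            continue
        s = L - motif_len
        if s in candidates and candidates[s] < stutter_ratio * candidates[L]:
            candidates[L] += candidates.pop(s)
            flags.add("stutter_corrected")
    if not candidates:
        return LengthGenotype(None, dict(counts), frozenset(flags | {"low_depth"}))
    if len(candidates) > 2:
        return LengthGenotype(None, dict(candidates),
                              frozenset(flags | {"ambiguous"}))
    if len(candidates) == 1:
        (L, c), = candidates.items()
        return LengthGenotype((L, L), {L: c}, frozenset(flags))
    (l1, c1), (l2, c2) = sorted(candidates.items(), key=lambda kv: -kv[1])
    if c2 / c1 < min_minor_ratio:
        # weak minor peak: call the major allele homozygous
        flags.add("minor_below_ratio")
        return LengthGenotype((l1, l1), {l1: c1}, frozenset(flags))
    pair = tuple(sorted((l1, l2)))
    return LengthGenotype(pair, {l1: c1, l2: c2}, frozenset(flags))


# ---------------------------------------------------------------------------
# sequence (WAI) alleles


def consensus_sequence(reads: Sequence[str]):
    """Per-position majority base (ties -> N) and base-frequency table."""
    if not reads:
        raise ValueError("consensus of empty read set")
    n = len(reads[0])
    if any(len(r) != n for r in reads):
        raise ValueError("reads must share one length")
    cons = []
    freqs = []
    for i in range(n):
        col = Counter(r[i] for r in reads)
        total = sum(col.values())
        best = max(col.values())
        winners = [b for b, c in col.items() if c == best]
        cons.append(winners[0] if len(winners) == 1 else "N")
        freqs.append({b: c / total for b, c in col.items()})
    return "".join(cons), freqs


def _qualifying_splits(reads: Sequence[str], min_snp_fraction: float,
                       min_reads: int):
    """Positions where a second base is frequent and well supported."""
    cons, freqs = consensus_sequence(reads)
    total = len(reads)
    positions = []
    for i, f in enumerate(freqs):
        ranked = sorted(f.items(), key=lambda kv: -kv[1])
        if len(ranked) < 2:
            continue
        frac = ranked[1][1]
        if frac >= min_snp_fraction and frac * total >= min_reads:
            positions.append(i)
    return cons, positions


def call_wai_alleles(length_genotype: LengthGenotype,
                     reads_by_length: Mapping[int, Sequence[str]],
                     min_reads: int = 10, min_snp_fraction: float = 0.25):
    """Resolve a length genotype into sequence alleles.

    Returns ``(pair, flags)`` where ``pair`` is a tuple of two
    ``(length, consensus)`` alleles (sorted) or ``None`` with an explanatory
    flag.  A length-homozygote whose read pile splits at a well-supported SNP
    position becomes a heterozygote of two same-length alleles; a qualifying
    split inside one length class of a length-heterozygote would imply three
    alleles in a diploid and yields a missing/ambiguous call.
    """
    if length_genotype.is_missing:
        raise ValueError("length genotype is missing")
    lengths = sorted(set(length_genotype.allele_lengths))
    flags = set(length_genotype.flags)
    if len(lengths) == 1:
        L = lengths[0]
        reads = list(reads_by_length.get(L, ()))
        if not reads:
            return None, frozenset(flags | {"no_reads"})
        cons, positions = _qualifying_splits(reads, min_snp_fraction, min_reads)
        if not positions:
            return ((L, cons), (L, cons)), frozenset(flags)
        groups = defaultdict(list)
        for r in reads:
            groups[tuple(r[i] for i in positions)].append(r)
        total = len(reads)
        strong = [g for g in groups.values()
                  if len(g) >= min_reads and len(g) / total >= min_snp_fraction]
        if len(strong) == 1:
            cons1, _ = consensus_sequence(strong[0])
            return ((L, cons1), (L, cons1)), frozenset(flags)
        if len(strong) == 2:
            a, _ = consensus_sequence(strong[0])
            b, _ = consensus_sequence(strong[1])
            flags.add("snp_split")
            return tuple(sorted(((L, a), (L, b)))), frozenset(flags)
        return None, frozenset(flags | {"ambiguous"})
    # length heterozygote: one consensus allele per length class
    pair = []
    for L in lengths:
        reads = list(reads_by_length.get(L, ()))
        if not reads:
            return None, frozenset(flags | {"no_reads"})
        cons, positions = _qualifying_splits(reads, min_snp_fraction, min_reads)
        if positions:
            return None, frozenset(flags | {"ambiguous"})
        pair.append((L, cons))
    return tuple(sorted(pair)), frozenset(flags)


# ---------------------------------------------------------------------------
# matrix assembly and filtering


class GenotypeMatrix:
    """Codominant sample x locus matrix of registered WAI allele ids."""

    def __init__(self, samples, loci, entries, pop_map, registry):
        self.samples = list(samples)
        self.loci = list(loci)
        self.entries = dict(entries)   # (sample, locus) -> (id, id) or None
        self.pop_map = dict(pop_map)
        self.registry = dict(registry)  # allele_id -> SequenceAllele

    def get(self, sample, locus):
        return self.entries.get((sample, locus))

    def missing_fraction_by_sample(self):
        return {s: sum(self.entries.get((s, l)) is None for l in self.loci)
                / len(self.loci) for s in self.samples}

    def missing_fraction_by_locus(self):
        return {l: sum(self.entries.get((s, l)) is None for s in self.samples)
                / len(self.samples) for l in self.loci}

    # -- serialization ------------------------------------------------------

    def to_csv(self, path) -> None:
        import csv

        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            header = ["sample", "population"]
            for l in self.loci:
                header += [f"{l}.1", f"{l}.2"]
            w.writerow(header)
            for s in self.samples:
                row = [s, self.pop_map.get(s, "")]
                for l in self.loci:
                    e = self.entries.get((s, l))
                    row += ["", ""] if e is None else list(e)
                w.writerow(row)

    @classmethod
    def from_csv(cls, path, registry=None):
        import csv

        with open(path, newline="") as fh:
            rows = list(csv.reader(fh))
        header = rows[0]
        loci = [h[:-2] for h in header[2::2]]
        samples, pop_map, entries = [], {}, {}
        for row in rows[1:]:
            s = row[0]
            samples.append(s)
            pop_map[s] = row[1]
            for i, l in enumerate(loci):
                a, b = row[2 + 2 * i], row[3 + 2 * i]
                entries[(s, l)] = None if a == "" else (a, b)
        return cls(samples, loci, entries, pop_map, registry or {})

    def to_genalex_csv(self, path) -> None:
        """Two-columns-per-locus dialect with numeric ids, 0 = missing."""
        import csv

        code = {aid: i + 1 for i, aid in enumerate(sorted(self.registry))}
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            header = ["sample", "population"]
            for l in self.loci:
                header += [l, ""]
            w.writerow(header)
            for s in self.samples:
                row = [s, self.pop_map.get(s, "")]
                for l in self.loci:
                    e = self.entries.get((s, l))
                    row += [0, 0] if e is None else [code[e[0]], code[e[1]]]
                w.writerow(row)

    def write_allele_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for aid in sorted(self.registry):
                a = self.registry[aid]
                fh.write(f">{aid}\n{a.consensus}\n")


def assemble_genotype_matrix(calls, pop_map, loci_order=None) -> GenotypeMatrix:
    """Register alleles and build the matrix from per-sample raw calls.

    ``calls`` maps (sample, locus) -> pair of (length, consensus) or None.
    Allele ids are assigned deterministically after all samples are seen:
    within a locus, alleles sort by (length, consensus) and receive ids
    ``{locus}:{length}`` with a letter suffix when several sequences share a
    length, so the final matrix is independent of sample processing order.
    """
    samples = sorted({s for s, _ in calls})
    loci = list(loci_order) if loci_order else sorted({l for _, l in calls})
    for s in samples:
        if s not in pop_map:
            raise KeyError(f"sample {s} missing from population map")
    per_locus = defaultdict(set)
    for (s, l), pair in calls.items():
        if pair is not None:
            per_locus[l].update(pair)
    registry = {}
    id_of = {}
    for l in loci:
        alleles = sorted(per_locus.get(l, ()))
        by_len = defaultdict(list)
        for length, cons in alleles:
            by_len[length].append(cons)
        ref = {length: seqs[0] for length, seqs in by_len.items()}
        for length, seqs in by_len.items():
            for j, consensus in enumerate(seqs):
                suffix = "" if len(seqs) == 1 else chr(ord("a") + j)
                aid = f"{l}:{length}{suffix}"
                sig = tuple((i + 1, b) for i, (a, b)
                            in enumerate(zip(ref[length], consensus)) if a != b)
                registry[aid] = SequenceAllele(
                    locus=l, length=length, consensus=consensus,
                    allele_id=aid, snp_signature=sig)
                id_of[(l, length, consensus)] = aid
    entries = {}
    for s in samples:
        for l in loci:
            pair = calls.get((s, l))
            if pair is None:
                entries[(s, l)] = None
            else:
                ids = tuple(sorted(id_of[(l, L, c)] for L, c in pair))
                entries[(s, l)] = ids
    return GenotypeMatrix(samples, loci, entries,
                          {s: pop_map[s] for s in samples}, registry)


def filter_missing(matrix: GenotypeMatrix, max_missing_per_sample: float = 0.60,
                   max_missing_per_locus: float = 0.60):
    """Drop loci then samples exceeding the missing-data thresholds.

    Loci are filtered first (failed markers removed before judging samples),
    then samples are re-evaluated on the retained loci.  Returns
    ``(filtered_matrix, report)`` with one report row per exclusion.
    """
    report = []
    loci = []
    for l in matrix.loci:
        frac = (sum(matrix.entries.get((s, l)) is None for s in matrix.samples)
                / max(len(matrix.samples), 1))
        if frac > max_missing_per_locus:
            report.append({"kind": "locus", "name": l, "missing_fraction": frac})
        else:
            loci.append(l)
    samples = []
    for s in matrix.samples:
        frac = (sum(matrix.entries.get((s, l)) is None for l in loci)
                / max(len(loci), 1)) if loci else 1.0
        if frac > max_missing_per_sample:
            report.append({"kind": "sample", "name": s, "missing_fraction": frac})
        else:
            samples.append(s)
    entries = {(s, l): matrix.entries.get((s, l)) for s in samples for l in loci}
    used = {a for e in entries.values() if e for a in e}
    registry = {k: v for k, v in matrix.registry.items() if k in used}
    pop_map = {s: matrix.pop_map[s] for s in samples}
    return GenotypeMatrix(samples, loci, entries, pop_map, registry), report


# ---------------------------------------------------------------------------
# end-to-end driver


def genotype_sample(reads, loci: Sequence[LocusSpec],
                    params: PipelineParams = PipelineParams(),
                    sample: str = "sample"):
    """Full per-sample calling: demultiplex -> length call -> WAI call."""
    bins, unassigned = demultiplex_reads(
        reads, loci, sample=sample,
        max_mismatches_per_primer=params.max_primer_mismatches)
    calls = {}
    for locus in loci:
        b = bins[locus.name]
        hist = build_length_histogram(b, min_length=params.min_length)
        lg = call_length_genotype(
            hist, motif_len=len(locus.motif), min_reads=params.min_reads,
            min_minor_ratio=params.min_minor_ratio,
            stutter_ratio=params.stutter_ratio)
        if lg.is_missing:
            calls[locus.name] = None
            continue
        reads_by_length = defaultdict(list)
        for r in b.reads:
            if len(r) >= params.min_length:
                reads_by_length[len(r)].append(r)
        pair, flags = call_wai_alleles(
            lg, reads_by_length, min_reads=params.min_reads,
            min_snp_fraction=params.min_snp_fraction)
        calls[locus.name] = pair
    return calls, unassigned


def run_pipeline(reads_by_sample, loci: Sequence[LocusSpec], pop_map,
                 params: PipelineParams = PipelineParams()) -> GenotypeMatrix:
    """Genotype every sample and assemble the codominant WAI matrix."""
    all_calls = {}
    for sample, reads in reads_by_sample.items():
        calls, _ = genotype_sample(reads, loci, params, sample=sample)
        for locus_name, pair in calls.items():
            all_calls[(sample, locus_name)] = pair
    return assemble_genotype_matrix(
        all_calls, pop_map, loci_order=[l.name for l in loci])


def matrix_from_truth(truth) -> GenotypeMatrix:
    """Codominant matrix directly from simulated true genotypes.

    Bypasses read simulation and calling: allele ids are
    ``{locus}:{repeats}.{snp_state}``.  Useful for statistics that only need
    genotypes, not reads.
    """
    entries = {}
    for (s, l), pair in truth.entries.items():
        entries[(s, l)] = tuple(sorted(f"{l}:{r}.{v}" for r, v in pair))
    return GenotypeMatrix(truth.samples, truth.loci, entries,
                          truth.pop_map, {})


def read_fastq_dir(directory):
    """Load per-sample FASTQ files (sample name = file stem)."""
    from Bio import SeqIO

    reads_by_sample = {}
    for path in sorted(Path(directory).glob("*.fastq")):
        recs = [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fastq")]
        reads_by_sample[path.stem] = recs
    return reads_by_sample
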