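"""Microsatellite marker discovery from merged reads.

Scans sequences for maximal perfect tandem repeats, reports motifs in
canonical form (lexicographically smallest rotation of the observed strand),
and applies the candidate-locus quality filters used when designing SSR
primers from shotgun reads: minimum flank length, per-motif-length repeat
minima, rejection of reads with interrupted motifs, multiple repeat tracts, or
long mononucleotide runs, plus an amplicon-placement rule that keeps the
complete repeat tract within the leading or trailing window covered by one of
a paired-end read set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import groupby
from typing import Iterable, Mapping, Sequence

__all__ = [
    "SsrCandidate",
    "DiscoveryCriteria",
    "canonical_motif",
    "scan_read_for_ssr",
    "apply_discovery_filters",
    "assess_amplicon_placement",
    "scan_reads",
]


@dataclass(frozen=True)
class SsrCandidate:
    """One maximal perfect repeat tract found in a read (0-based half-open)."""

    read_id: str
    motif: str
    repeat_count: int
    motif_start: int
    motif_end: int
    read_length: int

    @property
    def left_flank_len(self) -> int:
        return self.motif_start

    @property
    def right_flank_len(self) -> int:
        return self.read_length - self.motif_end


@dataclass(frozen=True)
class DiscoveryCriteria:
    min_flank: int = 30
    min_repeats_by_motif_len: Mapping[int, int] = field(
        default_factory=lambda: {2: 9, 3: 7, 4: 5, 5: 5})
    max_mononucleotide_run: int = 6
    # primers for the study system were designed from tetra/penta tracts only;
    # di/tri scanning stays available by widening this set
    allowed_motif_lens: frozenset = frozenset({4, 5})

    def __post_init__(self):
        if self.min_flank <= 0 or self.max_mononucleotide_run <= 0:
            raise ValueError("thresholds must be positive")


def canonical_motif(motif: str) -> str:
    """Lexicographically smallest rotation (no reverse-complement folding)."""
    return min(motif[i:] + motif[:i] for i in range(len(motif)))


def _is_primitive(motif: str) -> bool:
    for k in range(1, len(motif)):
        if len(motif) % k == 0 and motif == motif[:k] * (len(motif) // k):
            return False
    return True


def scan_read_for_ssr(sequence: str, criteria: DiscoveryCriteria = DiscoveryCriteria(),
                      read_id: str = "read") -> list:
    """Every maximal perfect tandem repeat meeting the per-length minimum.

    N bases terminate tracts.  The same tract is reported once even though its
    rotations (e.g. AAAT/AATA) start at successive offsets; tracts whose unit
    is a power of a shorter unit are reported at the shorter period only when
    that period is allowed.
    """
    sequence = sequence.upper()
    n = len(sequence)
    found = []
    claimed = set()  # (start, end) intervals already reported
    for k in sorted(criteria.allowed_motif_lens):
        min_rep = criteria.min_repeats_by_motif_len.get(k)
        if min_rep is None:
            continue
        i = 0
        while i + k <= n:
            unit = sequence[i:i + k]
            if "N" in unit or not _is_primitive(unit):
                i += 1
                continue
            # extend maximal run of `unit` starting at i
            j = i + k
            while j + k <= n and sequence[j:j + k] == unit:
                j += k
            reps = (j - i) // k
            # also allow a partial trailing unit to be ignored (tract is the
            # full-unit portion only; maximality is over whole units)
            if reps >= min_rep:
                # maximality on the left: previous k bases must not equal unit
                if i >= k and sequence[i - k:i] == unit:
                    i += 1
                    continue
                span = (i, i + reps * k)
                if span not in claimed:
                    claimed.add(span)
                    found.append(SsrCandidate(
                        read_id=read_id,
                        motif=canonical_motif(unit),
                        repeat_count=reps,
                        motif_start=i,
                        motif_end=i + reps * k,
                        read_length=n,
                    ))
                i = i + reps * k
            else:
                i += 1
    found.sort(key=lambda c: (c.motif_start, c.motif_end))
    # deduplicate nested reports of the same tract at different periods
    out = []
    for c in found:
        if any(o.motif_start <= c.motif_start and c.motif_end <= o.motif_end
               and o is not c for o in found):
            continue
        out.append(c)
    return out


def _max_mono_run(sequence: str) -> int:
    runs = [len(list(g)) for b, g in groupby(sequence) if b in "ACGT"]
    return max(runs, default=0)


def _is_interrupted(sequence: str, cand: SsrCandidate, window_units: int = 2) -> bool:
    """A nearby second copy of the motif marks an imperfect/interrupted tract."""
    k = len(cand.motif)
    rotations = {cand.motif[i:] + cand.motif[:i] for i in range(k)}
    w = window_units * k
    left = sequence[max(0, cand.motif_start - w):cand.motif_start]
    right = sequence[cand.motif_end:cand.motif_end + w]
    return any(rot in left or rot in right for rot in rotations)


def apply_discovery_filters(candidates_by_read: Mapping[str, Sequence[SsrCandidate]],
                            sequences: Mapping[str, str],
                            criteria: DiscoveryCriteria = DiscoveryCriteria()):
    """Apply the candidate-locus filters read by read.

    A read is rejected when its tract flanks are shorter than ``min_flank``,
    when it holds more than one qualifying tract, when the tract is
    interrupted, or when any A/C/G/T mononucleotide run longer than
    ``max_mononucleotide_run`` occurs anywhere in the read.  Returns
    ``(retained, tally)`` where ``tally`` counts one rule per rejected read
    (first failing rule in the order above).
    """
    retained = {}
    tally = {"flank_too_short": 0, "multiple_motifs": 0,
             "interrupted_motif": 0, "mononucleotide_run": 0, "no_candidate": 0}
    for read_id, cands in candidates_by_read.items():
        seq = sequences[read_id].upper()
        if len(cands) == 0:
            tally["no_candidate"] += 1
            continue
        if any(c.left_flank_len < criteria.min_flank
               or c.right_flank_len < criteria.min_flank for c in cands):
            tally["flank_too_short"] += 1
            continue
        if len(cands) > 1:
            tally["multiple_motifs"] += 1
            continue
        cand = cands[0]
        if _is_interrupted(seq, cand):
            tally["interrupted_motif"] += 1
            continue
        if _max_mono_run(seq) > criteria.max_mononucleotide_run:
            tally["mononucleotide_run"] += 1
            continue
        retained[read_id] = cand
    return retained, tally


def assess_amplicon_placement(candidate: SsrCandidate,
                              product_range=(300, 450),
                              read_window: int = 300) -> bool:
    """True when the complete tract sits in the leading or trailing window.

    Amplicons are sequenced as paired reads of ``read_window`` bases, so the
    repeat tract must be fully covered by one mate: within the first
    ``read_window`` bases or the last ``read_window`` bases of the product.
    Templates longer than the largest designable product cannot be placed.
    """
    lo, hi = product_range
    if candidate.read_length > hi and (
            candidate.motif_end > read_window
            and candidate.motif_start < candidate.read_length - read_window):
        return False
    return (candidate.motif_end <= read_window
            or candidate.motif_start >= candidate.read_length - read_window)


def scan_reads(reads: Iterable[tuple],
               criteria: DiscoveryCriteria = DiscoveryCriteria()):
    """Convenience: scan (read_id, sequence) pairs and filter.

    Returns ``(retained, tally, sequences)``.
    """
    sequences = {rid: seq for rid, seq in reads}
    cands = {rid: scan_read_for_ssr(seq, criteria, read_id=rid)
             for rid, seq in sequences.items()}
    retained, tally = apply_discovery_filters(cands, sequences, criteria)
    return retained, tally, sequences
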