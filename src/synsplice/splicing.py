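"""Splice-junction strength and exonic splicing enhancer/silencer scoring.

Junction strength is the PSSM matching score of the donor or acceptor
window (defaults: donor = last 3 exonic + first 6 intronic nt, acceptor =
last 20 intronic + first 3 exonic nt) against a splice-site PWM.

ESE/ESS burden is scored by exact-matching a library of 6-mer motifs
against the exon sequence. Overlapping hits are union-merged into *motif
sets* (set score 2^(N_m - 1) for N_m merged hits); sets no more than 6 bp
apart chain into *motif clusters*. Within a cluster a gap of <= 3 bp is a
short interval (I_s) and a gap of 4-6 bp a long interval (I_l), and

    S_cluster = (2*I_s + I_l + #sets) + sum over sets of S_set

The exon's cluster score is log2 of the summed cluster scores, normalised
by the exon length in units of 100 bp; an exon without any motif hit scores
0 by convention. A variant's effect is the alt-minus-ref difference of this
score, computed separately for the ESE and the ESS library.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

from .errors import MultipleDifferences, WindowOutOfSequence
from .pwm import BindingScoreModel, PWMModel, build_pssm, matching_score

MOTIF_LEN = 6
CLUSTER_MAX_GAP = 6
SHORT_INTERVAL_MAX_GAP = 3

DONOR_EXONIC_NT = 3
DONOR_INTRONIC_NT = 6
ACCEPTOR_INTRONIC_NT = 20
ACCEPTOR_EXONIC_NT = 3


@dataclass(frozen=True)
class SpliceSitePWM:
    """A donor or acceptor site PWM with its window definition."""

    site_type: str  # "donor" | "acceptor"
    exonic_nt: int
    intronic_nt: int
    model: BindingScoreModel

    def __post_init__(self):
        if self.site_type not in ("donor", "acceptor"):
            raise ValueError(f"site_type must be donor/acceptor, got {self.site_type!r}")
        if self.exonic_nt <= 0 or self.intronic_nt <= 0:
            raise ValueError("window lengths must be positive")
        if self.exonic_nt + self.intronic_nt != self.model.width:
            raise ValueError(
                f"window ({self.exonic_nt}+{self.intronic_nt}) != PWM width "
                f"{self.model.width}"
            )

    @classmethod
    def from_pwm(cls, site_type: str, exonic_nt: int, intronic_nt: int, pwm: PWMModel):
        return cls(site_type, exonic_nt, intronic_nt, build_pssm(pwm))


def junction_strength(seq_slice: str, site_pwm: SpliceSitePWM) -> float:
    """Matching score (bits) of a junction window against the site PWM."""
    if len(seq_slice) != site_pwm.model.width:
        raise WindowOutOfSequence(
            f"junction slice length {len(seq_slice)} != window "
            f"{site_pwm.model.width} for {site_pwm.site_type}"
        )
    return matching_score(site_pwm.model, seq_slice)


def junction_strength_delta(
    ref_slice: str, alt_slice: str, site_pwm: SpliceSitePWM
) -> float:
    """Ref-vs-alt matching-score difference; 0 when the slices are equal."""
    if ref_slice == alt_slice:
        return 0.0
    return junction_strength(alt_slice, site_pwm) - junction_strength(ref_slice, site_pwm)


@dataclass(frozen=True)
class MotifSet:
    """A union-merged run of overlapping motif hits on an exon (1-based)."""

    start: int
    end: int
    n_motifs: int

    @property
    def score(self) -> float:
        return 2.0 ** (self.n_motifs - 1)


@dataclass(frozen=True)
class MotifCluster:
    """A chain of motif sets with inter-set gaps <= 6 bp."""

    sets: tuple
    short_intervals: int
    long_intervals: int

    @property
    def score(self) -> float:
        return (
            2.0 * self.short_intervals
            + self.long_intervals
            + len(self.sets)
            + sum(s.score for s in self.sets)
        )


def find_motif_sets(exon_seq: str, motif_library) -> list:
    """Exact-scan 6-mer motifs and union-merge overlapping hits into sets."""
    motifs = {m.upper().replace("U", "T") for m in motif_library}
    seq = exon_seq.upper().replace("U", "T")
    hits = [
        i + 1  # 1-based start
        for i in range(len(seq) - MOTIF_LEN + 1)
        if seq[i : i + MOTIF_LEN] in motifs
    ]
    sets = []
    for start in hits:
        end = start + MOTIF_LEN - 1
        if sets and start <= sets[-1][1]:  # overlaps previous set (shares >= 1 bp)
            sets[-1][1] = max(sets[-1][1], end)
            sets[-1][2] += 1
        else:
            sets.append([start, end, 1])
    return [MotifSet(s, e, n) for s, e, n in sets]


def chain_clusters(sets: Sequence[MotifSet]) -> list:
    """Chain motif sets into clusters (consecutive gaps <= 6 bp).

    The gap is the number of nucleotides strictly between adjacent set
    intervals; adjacency (gap 0) counts as a short interval. A lone set is a
    cluster of one.
    """
    clusters = []
    cur, n_short, n_long = [], 0, 0
    for s in sets:
        if not cur:
            cur = [s]
            continue
        gap = s.start - cur[-1].end - 1
        if gap <= CLUSTER_MAX_GAP:
            if gap <= SHORT_INTERVAL_MAX_GAP:
                n_short += 1
            else:
                n_long += 1
            cur.append(s)
        else:
            clusters.append(MotifCluster(tuple(cur), n_short, n_long))
            cur, n_short, n_long = [s], 0, 0
    if cur:
        clusters.append(MotifCluster(tuple(cur), n_short, n_long))
    return clusters


def cluster_score(
    exon_seq: str,
    motif_library,
    exon_len: Optional[int] = None,
    log_base: float = 2.0,
) -> float:
    """Exon-level motif-cluster enrichment score.

    log (base 2 by default) of the summed cluster scores, divided by the
    exon length in units of 100 bp. 0.0 when the exon has no motif hit.
    """
    if exon_len is None:
        exon_len = len(exon_seq)
    if exon_len < 1:
        raise ValueError("exon_len must be >= 1")
    sets = find_motif_sets(exon_seq, motif_library)
    if not sets:
        return 0.0
    total = sum(c.score for c in chain_clusters(sets))
    return math.log(total, log_base) / (exon_len / 100.0)


def cluster_score_delta(
    ref_exon_seq: str,
    alt_exon_seq: str,
    motif_library,
    exon_len: Optional[int] = None,
    log_base: float = 2.0,
) -> float:
    """Alt-minus-ref cluster-score difference for one motif library."""
    if len(ref_exon_seq) != len(alt_exon_seq):
        raise MultipleDifferences("ref and alt exon sequences differ in length")
    diffs = [i for i, (a, b) in enumerate(zip(ref_exon_seq, alt_exon_seq)) if a != b]
    if len(diffs) > 1:
        raise MultipleDifferences(f"sequences differ at {len(diffs)} positions")
    return cluster_score(alt_exon_seq, motif_library, exon_len, log_base) - cluster_score(
        ref_exon_seq, motif_library, exon_len, log_base
    )
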