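"""Deterministic synthetic data: reference resources and labelled cohorts.

The generator emulates every input the pipeline consumes — a toy genome
with multi-exon genes (canonical GT/AG splice dinucleotides), an RBP PWM
panel including the four SR-protein factors, ESE/ESS 6-mer libraries,
splice-site PWMs estimated from the generated junctions themselves,
per-residue protein tracks, domain/PTM annotations, a conservation track —
and a labelled variant cohort with *planted* class signal:

* disease variants disrupt a planted ESE motif or SR-protein binding site
  overlapping the variant, and fall in exons whose residues get lower
  solvent accessibility and disorder, more domain coverage, more PTM sites
  and higher conservation;
* neutral variants are placed uniformly with high allele frequencies.

Effect directions follow the empirical disease-vs-neutral contrasts the
method was built on. Setting every effect field to zero (``cfg.null()``)
makes the two classes exchangeable, which is the negative control used in
the recovery tests. All randomness flows through numpy Generators derived
from ``cfg.seed``; identical configs produce byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .errors import ConfigInvalid, Saturation
from .features import AnnotationBundle
from .genomic import TranscriptModel, complement, reverse_complement
from .protein import DomainAnnotation, ResidueTrack
from .pwm import ALPHABET, PWMModel, SRSF_IDS, build_pssm
from .splicing import (
    ACCEPTOR_EXONIC_NT,
    ACCEPTOR_INTRONIC_NT,
    DONOR_EXONIC_NT,
    DONOR_INTRONIC_NT,
    MOTIF_LEN,
    SpliceSitePWM,
)

SPACER_LEN = 300
CATEGORIES = ("DM", "DM?", "FP", "DP/DFP")
CATEGORY_PROBS = (0.85, 0.09, 0.04, 0.02)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic benchmark.

    Geometry, cohort size and the planted effect sizes are frozen here;
    ``null()`` returns the matched zero-effect configuration.
    """

    seed: int = 0
    # genome geometry
    n_genes: int = 50
    exons_per_gene: int = 10
    exon_len_range: Tuple[int, int] = (75, 150)
    intron_len_range: Tuple[int, int] = (80, 200)
    # cohort
    n_pos: int = 200
    n_neg: int = 200
    site_class: str = "VIE"
    # motif/PWM resources
    n_rbp_pwms: int = 16  # panel beyond the four SR factors
    pwm_width_range: Tuple[int, int] = (6, 7)
    pwm_n_sites: int = 20
    pwm_consensus_count: int = 14
    n_ese_motifs: int = 60
    n_ess_motifs: int = 40
    # track noise
    asa_mean: float = 60.0
    asa_sd: float = 20.0
    disorder_mean: float = 0.45
    disorder_sd: float = 0.20
    conservation_sd: float = 0.8
    pfam_base_prob: float = 0.25
    ptm_base_density: float = 1.5  # sites per 100 aa
    # planted effects (disease vs neutral contrasts)
    splice_disrupt_prob: float = 0.9
    asa_offset: float = -18.0
    disorder_offset: float = -0.18
    pfam_boost: float = 0.45
    ptm_boost: float = 1.5
    conservation_offset: float = 1.5
    # allele-frequency models
    maf_pos_beta: Tuple[float, float] = (0.5, 30.0)
    maf_neg_max: float = 0.5

    def __post_init__(self):
        if min(self.n_genes, self.exons_per_gene, self.n_pos, self.n_neg) < 1:
            raise ConfigInvalid("all counts must be >= 1")
        if self.exons_per_gene < 3:
            raise ConfigInvalid("need >= 3 exons per gene for internal exons")
        if self.exon_len_range[0] < 30:
            raise ConfigInvalid("exons must be >= 30 nt for junction windows")
        if self.site_class not in ("VSS", "VIE"):
            raise ConfigInvalid(f"site_class must be VSS or VIE, got {self.site_class}")
        for name in ("splice_disrupt_prob", "pfam_boost", "pfam_base_prob"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ConfigInvalid(f"{name} must lie in [0, 1]")

    def null(self) -> "SimConfig":
        """Matched configuration with every planted effect zeroed."""
        return replace(
            self,
            splice_disrupt_prob=0.0,
            asa_offset=0.0,
            disorder_offset=0.0,
            pfam_boost=0.0,
            ptm_boost=0.0,
            conservation_offset=0.0,
        )


@dataclass
class Reference:
    """In-memory bundle of every generated reference resource."""

    genome: Dict[str, str]
    transcripts: Dict[str, TranscriptModel]
    pwms: list  # PWMModel, SR factors first
    ese_motifs: frozenset
    ess_motifs: frozenset
    donor_pwm: PWMModel
    acceptor_pwm: PWMModel
    tracks: Dict[str, ResidueTrack]
    domains: Dict[str, DomainAnnotation]
    conservation: Dict[str, np.ndarray]

    def to_bundle(self, structure_provider=None) -> AnnotationBundle:
        return AnnotationBundle(
            genome=self.genome,
            transcripts=self.transcripts,
            rbp_models=[build_pssm(p) for p in self.pwms],
            donor_pwm=SpliceSitePWM.from_pwm(
                "donor", DONOR_EXONIC_NT, DONOR_INTRONIC_NT, self.donor_pwm
            ),
            acceptor_pwm=SpliceSitePWM.from_pwm(
                "acceptor", ACCEPTOR_EXONIC_NT, ACCEPTOR_INTRONIC_NT, self.acceptor_pwm
            ),
            ese_motifs=self.ese_motifs,
            ess_motifs=self.ess_motifs,
            tracks=self.tracks,
            domains=self.domains,
            conservation=self.conservation,
            structure_provider=structure_provider,
        )


def _random_seq(rng, n: int) -> str:
    return "".join(np.array(list(ALPHABET))[rng.integers(0, 4, n)])


def _rngs(cfg: SimConfig):
    ss = np.random.SeedSequence(cfg.seed)
    return [np.random.default_rng(s) for s in ss.spawn(3)]


def _consensus_pwm(rng, rbp_id: str, width: int, n_sites: int, peak: int) -> PWMModel:
    """A PWM with one dominant base per column and uniform remainder."""
    counts = np.full((width, 4), (n_sites - peak) / 3.0)
    consensus = rng.integers(0, 4, width)
    for i, b in enumerate(consensus):
        counts[i, b] = peak
    return PWMModel(rbp_id=rbp_id, counts=counts, n_sites=n_sites)


def pwm_consensus(pwm: PWMModel) -> str:
    return "".join(ALPHABET[i] for i in pwm.counts.argmax(axis=1))


def _motif_library(rng, n: int, exclude=frozenset()) -> frozenset:
    """Distinct random 6-mers, disjoint from ``exclude``."""
    out = set()
    while len(out) < n:
        m = _random_seq(rng, MOTIF_LEN)
        if m not in exclude:
            out.add(m)
    return frozenset(out)


def generate_reference(cfg: SimConfig) -> Reference:
    """Generate all mutually consistent reference resources for ``cfg``."""
    rng, _, _ = _rngs(cfg)

    # --- motif resources ---------------------------------------------------
    pwms = []
    for sid in SRSF_IDS:
        w = int(rng.integers(cfg.pwm_width_range[0], cfg.pwm_width_range[1] + 1))
        pwms.append(_consensus_pwm(rng, sid, w, cfg.pwm_n_sites, cfg.pwm_consensus_count))
    for i in range(cfg.n_rbp_pwms):
        w = int(rng.integers(cfg.pwm_width_range[0], cfg.pwm_width_range[1] + 1))
        pwms.append(
            _consensus_pwm(rng, f"RBP{i:03d}", w, cfg.pwm_n_sites, cfg.pwm_consensus_count)
        )
    ese = _motif_library(rng, cfg.n_ese_motifs)
    ess = _motif_library(rng, cfg.n_ess_motifs, exclude=ese)

    # --- genes -------------------------------------------------------------
    chrom_name = "chr1"
    parts = []
    cursor = 0  # 0-based length so far
    transcripts = {}
    donor_windows, acceptor_windows = [], []

    for g in range(cfg.n_genes):
        strand = "+" if g % 2 == 0 else "-"
        tid = f"GENE{g:03d}"
        exon_lens = [
            int(rng.integers(cfg.exon_len_range[0], cfg.exon_len_range[1] + 1))
            for _ in range(cfg.exons_per_gene)
        ]
        rem = sum(exon_lens) % 3
        if rem:
            exon_lens[-1] += 3 - rem
        intron_lens = [
            int(rng.integers(cfg.intron_len_range[0], cfg.intron_len_range[1] + 1))
            for _ in range(cfg.exons_per_gene - 1)
        ]

        # transcript-orientation gene sequence with canonical dinucleotides
        segs = []
        for i, el in enumerate(exon_lens):
            segs.append(_random_seq(rng, el))
            if i < len(intron_lens):
                il = intron_lens[i]
                intron = "GT" + _random_seq(rng, il - 4) + "AG"
                segs.append(intron)
        gene_seq = "".join(segs)
        gene_len = len(gene_seq)

        # exon offsets in transcript orientation (0-based inclusive)
        offsets = []
        off = 0
        for i, el in enumerate(exon_lens):
            offsets.append((off, off + el - 1))
            off += el
            if i < len(intron_lens):
                off += intron_lens[i]

        # collect junction windows for the site PWMs
        for i in range(len(exon_lens)):
            a, b = offsets[i]
            if i < len(exon_lens) - 1:
                donor_windows.append(
                    gene_seq[b - DONOR_EXONIC_NT + 1 : b + DONOR_INTRONIC_NT + 1]
                )
            if i > 0:
                acceptor_windows.append(
                    gene_seq[a - ACCEPTOR_INTRONIC_NT : a + ACCEPTOR_EXONIC_NT]
                )

        spacer = _random_seq(rng, SPACER_LEN)
        gene_start = cursor + SPACER_LEN + 1  # 1-based genomic start
        if strand == "+":
            parts.append(spacer + gene_seq)
            exons = [(gene_start + a, gene_start + b) for a, b in offsets]
        else:
            parts.append(spacer + reverse_complement(gene_seq))
            exons = [
                (gene_start + gene_len - 1 - b, gene_start + gene_len - 1 - a)
                for a, b in offsets
            ]
            exons = exons[::-1]
        cursor += SPACER_LEN + gene_len
        transcripts[tid] = TranscriptModel(
            transcript_id=tid,
            chrom=chrom_name,
            strand=strand,
            exons=tuple(exons),
            gene_id=tid,
        )
    parts.append(_random_seq(rng, SPACER_LEN))
    genome = {chrom_name: "".join(parts)}

    # --- splice-site PWMs from the generated junctions ---------------------
    def count_matrix(windows):
        width = len(windows[0])
        counts = np.zeros((width, 4))
        for wseq in windows:
            for i, c in enumerate(wseq):
                counts[i, ALPHABET.index(c)] += 1
        return counts

    donor_pwm = PWMModel("donor_site", count_matrix(donor_windows))
    acceptor_pwm = PWMModel("acceptor_site", count_matrix(acceptor_windows))

    # --- protein tracks, domains, PTMs ------------------------------------
    tracks, domains = {}, {}
    for tid, t in transcripts.items():
        n_aa = t.protein_length()
        asa = np.clip(rng.normal(cfg.asa_mean, cfg.asa_sd, n_aa), 1.0, None)
        disorder = np.clip(rng.normal(cfg.disorder_mean, cfg.disorder_sd, n_aa), 0.0, 1.0)
        ss = rng.dirichlet((2.0, 2.0, 2.0), n_aa)
        tracks[tid] = ResidueTrack(tid, asa, disorder, ss)

        pfam = []
        for ei in range(t.n_exons):
            if rng.random() < cfg.pfam_base_prob:
                r0, r1 = t.residue_range(ei)
                span = r1 - r0 + 1
                frac = rng.uniform(0.6, 1.0)
                length = max(1, int(span * frac))
                start = r0 + int(rng.integers(0, span - length + 1))
                pfam.append((start, start + length - 1))
        n_ptm = rng.poisson(cfg.ptm_base_density * n_aa / 100.0)
        ptm = tuple(
            (int(p), "phospho")
            for p in sorted(rng.integers(1, n_aa + 1, n_ptm).tolist())
        )
        domains[tid] = DomainAnnotation(tid, tuple(pfam), ptm)

    conservation = {
        chrom_name: rng.normal(0.0, cfg.conservation_sd, len(genome[chrom_name]))
    }

    return Reference(
        genome=genome,
        transcripts=transcripts,
        pwms=pwms,
        ese_motifs=ese,
        ess_motifs=ess,
        donor_pwm=donor_pwm,
        acceptor_pwm=acceptor_pwm,
        tracks=tracks,
        domains=domains,
        conservation=conservation,
    )


def _exon_genomic_interval(t: TranscriptModel, exon_index: int):
    gi = exon_index if t.strand == "+" else t.n_exons - 1 - exon_index
    return t.exons[gi]


def _pick_offset(rng, cfg: SimConfig, exon_len: int) -> int:
    """0-based transcript-orientation offset matching cfg.site_class."""
    if cfg.site_class == "VIE":
        # dist_to_acceptor = off+1 > 1 and dist_to_donor = len-off > 3
        return int(rng.integers(1, exon_len - 3))
    choices = [0, exon_len - 1, exon_len - 2, exon_len - 3]
    return int(choices[rng.integers(0, len(choices))])


def generate_cohort(cfg: SimConfig, ref: Reference):
    """Place labelled variants and plant the configured class effects.

    Mutates ``ref`` in place (sequence rewrites around disease variants,
    track offsets, extra domains/PTM sites, conservation bumps) and returns
    ``(cohort, truth)`` DataFrames. Raises :class:`Saturation` when more
    variants are requested than internal exons exist.
    """
    _, rng, _ = _rngs(cfg)
    slots = [
        (tid, ei)
        for tid in sorted(ref.transcripts)
        for ei in range(1, ref.transcripts[tid].n_exons - 1)
    ]
    n_total = cfg.n_pos + cfg.n_neg
    if n_total > len(slots):
        raise Saturation(
            f"{n_total} variants requested but only {len(slots)} internal exons"
        )
    order = rng.permutation(len(slots))
    ese_sorted = sorted(ref.ese_motifs)
    srsf_pwms = [p for p in ref.pwms if p.rbp_id in SRSF_IDS]
    genome = dict(ref.genome)  # chrom -> str, edited below

    rows, truth_rows = [], []
    for vi in range(n_total):
        is_pos = vi < cfg.n_pos
        tid, ei = slots[order[vi]]
        t = ref.transcripts[tid]
        gstart, gend = _exon_genomic_interval(t, ei)
        exon_len = gend - gstart + 1
        off = _pick_offset(rng, cfg, exon_len)

        # transcript-oriented exon sequence
        seq = genome[t.chrom][gstart - 1 : gend]
        if t.strand == "-":
            seq = reverse_complement(seq)

        mechanism = "none"
        alt_t: Optional[str] = None
        if is_pos and rng.random() < cfg.splice_disrupt_prob:
            mechanism = "ese" if rng.random() < 0.5 else "rbp"
            if mechanism == "ese":
                motif = ese_sorted[rng.integers(0, len(ese_sorted))]
            else:
                motif = pwm_consensus(srsf_pwms[rng.integers(0, len(srsf_pwms))])
            mlen = len(motif)
            lo = max(0, off - mlen + 1)
            hi = min(off, exon_len - mlen)
            if hi < lo:  # exon edge; fall back to no planting
                mechanism = "none"
            else:
                o = int(rng.integers(lo, hi + 1))
                seq = seq[:o] + motif + seq[o + mlen :]
                ref_t = motif[off - o]
                alts = [b for b in ALPHABET if b != ref_t]
                if mechanism == "ese":
                    safe = [
                        b
                        for b in alts
                        if not _creates_hit(seq, off, b, ref.ese_motifs)
                    ]
                    alts = safe or alts
                alt_t = alts[rng.integers(0, len(alts))]
        ref_t = seq[off]
        if alt_t is None:
            alts = [b for b in ALPHABET if b != ref_t]
            alt_t = alts[rng.integers(0, len(alts))]

        # write the (possibly rewritten) exon back to the genome
        gseq = seq if t.strand == "+" else reverse_complement(seq)
        chrom_seq = genome[t.chrom]
        genome[t.chrom] = chrom_seq[: gstart - 1] + gseq + chrom_seq[gend:]

        pos = gstart + off if t.strand == "+" else gend - off
        ref_fwd = ref_t if t.strand == "+" else complement(ref_t)
        alt_fwd = alt_t if t.strand == "+" else complement(alt_t)

        # protein/conservation effects for positives
        r0, r1 = t.residue_range(ei)
        if is_pos:
            track = ref.tracks[tid]
            track.asa[r0 - 1 : r1] = np.clip(
                track.asa[r0 - 1 : r1] + cfg.asa_offset, 1.0, None
            )
            track.disorder[r0 - 1 : r1] = np.clip(
                track.disorder[r0 - 1 : r1] + cfg.disorder_offset, 0.0, 1.0
            )
            dom = ref.domains[tid]
            covered = any(s <= r0 and r1 <= e for s, e in dom.pfam_intervals)
            new_pfam = dom.pfam_intervals
            if not covered and rng.random() < cfg.pfam_boost:
                new_pfam = new_pfam + ((r0, r1),)
            n_extra = rng.poisson(cfg.ptm_boost * (r1 - r0 + 1) / 100.0)
            new_ptm = dom.ptm_sites + tuple(
                (int(p), "phospho")
                for p in rng.integers(r0, r1 + 1, n_extra).tolist()
            )
            ref.domains[tid] = DomainAnnotation(tid, new_pfam, new_ptm)
            cons = ref.conservation[t.chrom]
            cons[max(0, pos - 8) : pos + 7] += cfg.conservation_offset

        if is_pos:
            maf = float(np.clip(rng.beta(*cfg.maf_pos_beta), 0.0, 0.999))
            label = "disease"
            category = CATEGORIES[
                rng.choice(len(CATEGORIES), p=np.array(CATEGORY_PROBS))
            ]
        else:
            floor = 0.03 if cfg.site_class == "VSS" else 0.10
            maf = float(rng.uniform(floor + 0.005, cfg.maf_neg_max))
            label = "neutral"
            category = ""

        dist_acc = off + 1
        dist_don = exon_len - off
        site_class = "VSS" if (dist_don <= 3 or dist_acc <= 1) else "VIE"
        vid = f"var{vi:04d}"
        rows.append(
            {
                "variant_id": vid,
                "chrom": t.chrom,
                "pos": pos,
                "ref": ref_fwd,
                "alt": alt_fwd,
                "maf": maf,
                "label": label,
                "category": category,
                "site_class": site_class,
                "transcript_id": tid,
                "exon_id": f"{tid}:exon{ei}",
                "exon_index": ei,
                "n_exons": t.n_exons,
            }
        )
        truth_rows.append(
            {
                "variant_id": vid,
                "label": label,
                "mechanism": mechanism,
                "asa_offset": cfg.asa_offset if is_pos else 0.0,
                "disorder_offset": cfg.disorder_offset if is_pos else 0.0,
                "conservation_offset": cfg.conservation_offset if is_pos else 0.0,
                "exon_offset": off,
            }
        )

    ref.genome = genome
    cohort = pd.DataFrame(rows)
    truth = pd.DataFrame(truth_rows)
    return cohort, truth


def _creates_hit(seq: str, off: int, alt: str, library: frozenset) -> bool:
    """Would substituting ``alt`` at ``off`` leave/create a library hit there?"""
    mutated = seq[:off] + alt + seq[off + 1 :]
    lo = max(0, off - MOTIF_LEN + 1)
    hi = min(off, len(mutated) - MOTIF_LEN)
    return any(mutated[o : o + MOTIF_LEN] in library for o in range(lo, hi + 1))


def simulate(cfg: SimConfig):
    """Generate the reference and cohort in one call: (ref, cohort, truth)."""
    ref = generate_reference(cfg)
    cohort, truth = generate_cohort(cfg, ref)
    return ref, cohort, truth
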