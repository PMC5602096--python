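"""Per-variant feature assembly against an annotation bundle.

The bundle holds every reference resource the featurizer needs in memory:
genome sequences, transcript models, the RBP PWM panel, splice-site PWMs,
ESE/ESS motif libraries, per-residue protein tracks, domain/PTM
annotations, a per-base conservation track, and an RNA-structure provider.

The output is a rectangular matrix with a fixed, named column order per
site class. The internal-exon (VIE) schema is the splice-site (VSS) schema
plus the junction-proximity feature, which is deliberately withheld from
the VSS model (it would trivially encode the class definition). Missing
protein tracks are median-imputed with a companion indicator column.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import AnnotationMissing
from .genomic import (
    ExonContext,
    TranscriptModel,
    Variant,
    complement,
    map_variant_to_exon,
    reverse_complement,
)
from .protein import (
    DomainAnnotation,
    ResidueTrack,
    asa_features,
    disorder_features,
    pfam_overlap_pct,
    ptm_density,
    ss_features,
)
from .pwm import BindingScoreModel, SRSF_IDS, rbp_feature_summary
from .splicing import (
    SpliceSitePWM,
    cluster_score,
    cluster_score_delta,
    junction_strength,
    junction_strength_delta,
)
from .structure import get_provider, rna_structure_features

CONSERVATION_FLANK = 7
STRUCTURE_CONTEXT = 50

_PROTEIN_FEATURES = (
    "asa_avg",
    "asa_min",
    "asa_max",
    "disorder_min",
    "disorder_max",
    "disorder_avg",
    "disorder_avg_disordered",
    "disorder_avg_structured",
    "disorder_n_switches",
    "disorder_region_len_avg",
    "disorder_region_len_max",
    "disorder_region_len_min",
    "structured_region_len_avg",
    "structured_region_len_max",
    "structured_region_len_min",
    "has_disordered_region",
    "has_structured_region",
    "ss_argmax_prob_max",
    "ss_argmax_prob_min",
    "ss_argmax_prob_avg",
    "ss_helix_avg",
    "ss_helix_min",
    "ss_helix_max",
    "ss_sheet_avg",
    "ss_sheet_min",
    "ss_sheet_max",
    "ss_coil_avg",
    "ss_coil_min",
    "ss_coil_max",
    "pfam_overlap_pct",
    "ptm_density",
)

_SPLICING_FEATURES = (
    "avg_single_strandedness",
    "structure_distance",
    "donor_score",
    "acceptor_score",
    "junction_score_delta",
    "ese_cluster_wild",
    "ese_cluster_delta",
    "ess_cluster_wild",
    "ess_cluster_delta",
    "exon_len",
    "upstream_intron_len",
    "downstream_intron_len",
)

_SRSF_FEATURES = tuple(
    f"{sid.lower()}_max_score_{kind}" for sid in SRSF_IDS for kind in ("wild", "mut")
)

_PANEL_FEATURES = ("rbp_max_abs_magnitude", "rbp_n_binding_flips")

_CONSERVATION_FEATURES = ("phylop_mean_7bp",)

VSS_SCHEMA = (
    _SPLICING_FEATURES
    + _SRSF_FEATURES
    + _PANEL_FEATURES
    + _CONSERVATION_FEATURES
    + _PROTEIN_FEATURES
    + ("protein_track_missing",)
)
VIE_SCHEMA = (
    _SPLICING_FEATURES
    + ("proximity",)
    + _SRSF_FEATURES
    + _PANEL_FEATURES
    + _CONSERVATION_FEATURES
    + _PROTEIN_FEATURES
    + ("protein_track_missing",)
)


def feature_schema(site_class: str) -> tuple:
    if site_class == "VSS":
        return VSS_SCHEMA
    if site_class == "VIE":
        return VIE_SCHEMA
    raise ValueError(f"unknown site class {site_class!r}")


@dataclass
class AnnotationBundle:
    """All reference resources needed to featurize variants."""

    genome: Dict[str, str]
    transcripts: Dict[str, TranscriptModel]
    rbp_models: Sequence[BindingScoreModel]
    donor_pwm: SpliceSitePWM
    acceptor_pwm: SpliceSitePWM
    ese_motifs: frozenset
    ess_motifs: frozenset
    tracks: Dict[str, ResidueTrack] = field(default_factory=dict)
    domains: Dict[str, DomainAnnotation] = field(default_factory=dict)
    conservation: Dict[str, np.ndarray] = field(default_factory=dict)
    structure_provider: object = None
    srsf_ids: Sequence[str] = SRSF_IDS

    def __post_init__(self):
        if self.structure_provider is None:
            self.structure_provider = get_provider("auto")


def _oriented_exon(bundle: AnnotationBundle, ctx: ExonContext):
    """Exon sequence in transcript orientation, plus the variant offset."""
    t = ctx.transcript
    gi = ctx.exon_index if t.strand == "+" else t.n_exons - 1 - ctx.exon_index
    start, end = t.exons[gi]
    seq = bundle.genome[t.chrom][start - 1 : end].upper()
    if t.strand == "-":
        seq = reverse_complement(seq)
    offset = ctx.dist_to_acceptor - 1  # 0-based within oriented exon
    return seq, offset


def _oriented_allele(v: Variant, strand: str):
    if strand == "+":
        return v.ref, v.alt
    return complement(v.ref), complement(v.alt)


def _junction_windows(bundle: AnnotationBundle, ctx: ExonContext):
    """(donor_slice, acceptor_slice) wild windows in transcript orientation.

    Returns None for a side whose window would run past the chromosome or
    which does not exist (first/last exon).
    """
    t = ctx.transcript
    chrom_seq = bundle.genome[t.chrom]
    gi = ctx.exon_index if t.strand == "+" else t.n_exons - 1 - ctx.exon_index
    start, end = t.exons[gi]
    d = bundle.donor_pwm
    a = bundle.acceptor_pwm

    def slice1(lo, hi):  # 1-based inclusive, oriented later
        if lo < 1 or hi > len(chrom_seq):
            return None
        return chrom_seq[lo - 1 : hi].upper()

    if t.strand == "+":
        donor = None if ctx.is_last_exon else slice1(
            end - d.exonic_nt + 1, end + d.intronic_nt
        )
        acceptor = None if ctx.is_first_exon else slice1(
            start - a.intronic_nt, start + a.exonic_nt - 1
        )
    else:
        donor = None if ctx.is_last_exon else slice1(
            start - d.intronic_nt, start + d.exonic_nt - 1
        )
        acceptor = None if ctx.is_first_exon else slice1(
            end - a.exonic_nt + 1, end + a.intronic_nt
        )
        donor = reverse_complement(donor) if donor else None
        acceptor = reverse_complement(acceptor) if acceptor else None
    return donor, acceptor


def _mutate(seq: str, index: int, ref: str, alt: str, what: str) -> str:
    if seq[index] != ref:
        raise AnnotationMissing(
            f"{what}: reference base mismatch (sequence has {seq[index]!r}, "
            f"variant says {ref!r})"
        )
    return seq[:index] + alt + seq[index + 1 :]


def _structure_context(bundle: AnnotationBundle, ctx: ExonContext):
    """Pre-mRNA folding context (variant +/- STRUCTURE_CONTEXT nt), oriented."""
    v = ctx.variant
    chrom_seq = bundle.genome[v.chrom]
    lo = max(1, v.pos - STRUCTURE_CONTEXT)
    hi = min(len(chrom_seq), v.pos + STRUCTURE_CONTEXT)
    seq = chrom_seq[lo - 1 : hi].upper()
    center = v.pos - lo
    if ctx.transcript.strand == "-":
        seq = reverse_complement(seq)
        center = len(seq) - 1 - center
    return seq, center


def variant_features(
    v: Variant,
    bundle: AnnotationBundle,
    transcript_id: Optional[str] = None,
    ctx: Optional[ExonContext] = None,
) -> dict:
    """Compute the full named feature dict for one variant."""
    if ctx is None:
        ctx = map_variant_to_exon(v, bundle.transcripts.values(), transcript_id)
    t = ctx.transcript
    ref_o, alt_o = _oriented_allele(v, t.strand)
    exon_seq, offset = _oriented_exon(bundle, ctx)
    alt_exon_seq = _mutate(exon_seq, offset, ref_o, alt_o, f"variant {v.key}")

    feats: dict = {}

    # RNA secondary structure around the variant
    ctx_seq, center = _structure_context(bundle, ctx)
    alt_ctx_seq = _mutate(ctx_seq, center, ref_o, alt_o, f"variant {v.key}")
    ss_prob, struct_dist = rna_structure_features(
        ctx_seq, alt_ctx_seq, center, bundle.structure_provider
    )
    feats["avg_single_strandedness"] = ss_prob
    feats["structure_distance"] = struct_dist

    # Junction strength and variant-induced delta
    donor_slice, acceptor_slice = _junction_windows(bundle, ctx)
    feats["donor_score"] = (
        junction_strength(donor_slice, bundle.donor_pwm) if donor_slice else 0.0
    )
    feats["acceptor_score"] = (
        junction_strength(acceptor_slice, bundle.acceptor_pwm) if acceptor_slice else 0.0
    )
    delta = 0.0
    if donor_slice and ctx.dist_to_donor <= bundle.donor_pwm.exonic_nt:
        idx = bundle.donor_pwm.exonic_nt - ctx.dist_to_donor
        alt_slice = _mutate(donor_slice, idx, ref_o, alt_o, f"variant {v.key} donor")
        delta += junction_strength_delta(donor_slice, alt_slice, bundle.donor_pwm)
    if acceptor_slice and ctx.dist_to_acceptor <= bundle.acceptor_pwm.exonic_nt:
        idx = bundle.acceptor_pwm.intronic_nt + ctx.dist_to_acceptor - 1
        alt_slice = _mutate(
            acceptor_slice, idx, ref_o, alt_o, f"variant {v.key} acceptor"
        )
        delta += junction_strength_delta(acceptor_slice, alt_slice, bundle.acceptor_pwm)
    feats["junction_score_delta"] = delta

    # ESE/ESS cluster burden and variant delta
    feats["ese_cluster_wild"] = cluster_score(exon_seq, bundle.ese_motifs)
    feats["ess_cluster_wild"] = cluster_score(exon_seq, bundle.ess_motifs)
    feats["ese_cluster_delta"] = cluster_score_delta(
        exon_seq, alt_exon_seq, bundle.ese_motifs
    )
    feats["ess_cluster_delta"] = cluster_score_delta(
        exon_seq, alt_exon_seq, bundle.ess_motifs
    )

    # Exon/intron geometry
    feats["exon_len"] = float(ctx.exon_len_nt)
    feats["upstream_intron_len"] = float(ctx.upstream_intron_len or 0)
    feats["downstream_intron_len"] = float(ctx.downstream_intron_len or 0)
    if ctx.site_class == "VIE":
        feats["proximity"] = float(min(ctx.dist_to_donor, ctx.dist_to_acceptor))

    # RBP panel
    feats.update(
        rbp_feature_summary(
            exon_seq,
            alt_exon_seq,
            offset,
            bundle.rbp_models,
            srsf_ids=bundle.srsf_ids,
        )
    )

    # Conservation
    track = bundle.conservation.get(v.chrom)
    if track is not None:
        lo = max(0, v.pos - 1 - CONSERVATION_FLANK)
        hi = min(len(track), v.pos + CONSERVATION_FLANK)
        window = track[lo:hi]
        window = window[~np.isnan(window)]
        feats["phylop_mean_7bp"] = float(window.mean()) if window.size else np.nan
    else:
        feats["phylop_mean_7bp"] = np.nan

    # Protein structure/function features on the exon's residues
    ptrack = bundle.tracks.get(t.transcript_id)
    pdom = bundle.domains.get(t.transcript_id)
    if ptrack is not None:
        feats.update(asa_features(ptrack, ctx.residue_range))
        feats.update(disorder_features(ptrack, ctx.residue_range))
        feats.update(ss_features(ptrack, ctx.residue_range))
        feats["protein_track_missing"] = 0.0
    else:
        for name in _PROTEIN_FEATURES:
            if name not in ("pfam_overlap_pct", "ptm_density"):
                feats[name] = np.nan
        feats["protein_track_missing"] = 1.0
    dom = pdom if pdom is not None else DomainAnnotation(t.transcript_id)
    feats["pfam_overlap_pct"] = pfam_overlap_pct(dom, ctx.residue_range)
    feats["ptm_density"] = ptm_density(dom, ctx.residue_range)
    return feats


def assemble_features(
    cohort: pd.DataFrame,
    bundle: AnnotationBundle,
    site_class: str,
    impute: bool = True,
) -> pd.DataFrame:
    """Build the feature matrix for all cohort variants of one site class.

    Rows are indexed by ``variant_id`` in cohort order; columns follow the
    fixed schema for ``site_class``. Remaining NaNs (absent protein tracks,
    uncovered conservation) are median-imputed per column when ``impute``
    (the indicator columns record which rows were affected). Raises
    :class:`AnnotationMissing` naming every variant that cannot be
    resolved.
    """
    schema = feature_schema(site_class)
    sub = cohort[cohort["site_class"] == site_class]
    rows, failed = {}, []
    for rec in sub.itertuples():
        v = Variant(
            chrom=rec.chrom,
            pos=int(rec.pos),
            ref=rec.ref,
            alt=rec.alt,
            maf=None if pd.isna(rec.maf) else float(rec.maf),
            label=rec.label,
            variant_id=rec.variant_id,
        )
        tid = getattr(rec, "transcript_id", None)
        try:
            feats = variant_features(v, bundle, transcript_id=tid)
        except AnnotationMissing as exc:
            failed.append((v.key, str(exc)))
            continue
        rows[v.key] = [feats.get(name, np.nan) for name in schema]
    if failed:
        raise AnnotationMissing(
            "could not featurize: "
            + "; ".join(f"{k} ({msg})" for k, msg in failed[:10]),
            variant_ids=[k for k, _ in failed],
        )
    matrix = pd.DataFrame.from_dict(rows, orient="index", columns=list(schema))
    matrix.index.name = "variant_id"
    if impute and matrix.isna().any().any():
        med = matrix.median()
        matrix = matrix.fillna(med.fillna(0.0))
    return matrix
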