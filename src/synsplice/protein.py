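"""Exon-level aggregation of per-residue protein annotation tracks.

Tracks are consumed, never computed here: solvent accessible surface area
(ASA), intrinsic-disorder scores and 3-class secondary-structure
probabilities come from upstream predictors as TSV tracks; Pfam domain
intervals and post-translational-modification (PTM) sites come as interval/
position files in protein coordinates. Features summarise the residues
coded by one exon (1-based inclusive residue range; junction-spanning
codons belong to both flanking exons).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import EmptyRange

SS_CLASSES = ("helix", "sheet", "coil")
DEFAULT_DISORDER_THRESHOLD = 0.5


@dataclass(frozen=True)
class ResidueTrack:
    """Per-residue annotation arrays for one protein."""

    protein_id: str
    asa: np.ndarray
    disorder: np.ndarray
    ss_probs: np.ndarray  # (n_residues, 3) in helix/sheet/coil order

    def __post_init__(self):
        asa = np.asarray(self.asa, dtype=float)
        dis = np.asarray(self.disorder, dtype=float)
        ss = np.asarray(self.ss_probs, dtype=float)
        if not (len(asa) == len(dis) == ss.shape[0]):
            raise ValueError("track arrays must have equal length")
        if ss.ndim != 2 or ss.shape[1] != 3:
            raise ValueError("ss_probs must have shape (n, 3)")
        if np.any(np.abs(ss.sum(axis=1) - 1.0) > 1e-6):
            raise ValueError("secondary-structure probabilities must sum to 1")
        if np.any((dis < 0) | (dis > 1)):
            raise ValueError("disorder scores must lie in [0, 1]")
        object.__setattr__(self, "asa", asa)
        object.__setattr__(self, "disorder", dis)
        object.__setattr__(self, "ss_probs", ss)

    def __len__(self) -> int:
        return len(self.asa)


@dataclass(frozen=True)
class DomainAnnotation:
    """Pfam domain intervals and PTM site positions (1-based, inclusive)."""

    protein_id: str
    pfam_intervals: tuple = ()
    ptm_sites: tuple = ()  # (position, modification_type) pairs

    def __post_init__(self):
        object.__setattr__(
            self, "pfam_intervals", tuple(tuple(iv) for iv in self.pfam_intervals)
        )
        object.__setattr__(
            self, "ptm_sites", tuple(tuple(p) for p in self.ptm_sites)
        )


def _slice(values: np.ndarray, residue_range) -> np.ndarray:
    first, last = residue_range
    if first < 1 or last > len(values) or first > last:
        raise EmptyRange(
            f"residue range [{first}, {last}] invalid for track of length {len(values)}"
        )
    return values[first - 1 : last]


def asa_features(track: ResidueTrack, residue_range) -> dict:
    """Average, minimum and maximum ASA over the exon's residues."""
    vals = _slice(track.asa, residue_range)
    return {
        "asa_avg": float(vals.mean()),
        "asa_min": float(vals.min()),
        "asa_max": float(vals.max()),
    }


def _runs(mask: np.ndarray) -> list:
    """Run-length encode a boolean array as (value, length) pairs."""
    out = []
    for v in mask:
        if out and out[-1][0] == bool(v):
            out[-1][1] += 1
        else:
            out.append([bool(v), 1])
    return [(v, n) for v, n in out]


def disorder_features(
    track: ResidueTrack,
    residue_range,
    threshold: float = DEFAULT_DISORDER_THRESHOLD,
) -> dict:
    """Twelve disorder features plus two category-presence indicators.

    A residue with score >= ``threshold`` is disordered. Run features
    (average/max/min region length for disordered and structured runs, and
    average score within each category) are 0 with the matching indicator
    unset when the exon contains no residue of that category.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    vals = _slice(track.disorder, residue_range)
    dis_mask = vals >= threshold
    runs = _runs(dis_mask)
    d_lens = np.array([n for v, n in runs if v], dtype=float)
    s_lens = np.array([n for v, n in runs if not v], dtype=float)

    feats = {
        "disorder_min": float(vals.min()),
        "disorder_max": float(vals.max()),
        "disorder_avg": float(vals.mean()),
        "disorder_n_switches": float(len(runs) - 1),
        "disorder_avg_disordered": float(vals[dis_mask].mean()) if dis_mask.any() else 0.0,
        "disorder_avg_structured": float(vals[~dis_mask].mean()) if (~dis_mask).any() else 0.0,
        "disorder_region_len_avg": float(d_lens.mean()) if d_lens.size else 0.0,
        "disorder_region_len_max": float(d_lens.max()) if d_lens.size else 0.0,
        "disorder_region_len_min": float(d_lens.min()) if d_lens.size else 0.0,
        "structured_region_len_avg": float(s_lens.mean()) if s_lens.size else 0.0,
        "structured_region_len_max": float(s_lens.max()) if s_lens.size else 0.0,
        "structured_region_len_min": float(s_lens.min()) if s_lens.size else 0.0,
        "has_disordered_region": float(d_lens.size > 0),
        "has_structured_region": float(s_lens.size > 0),
    }
    return feats


def ss_features(track: ResidueTrack, residue_range) -> dict:
    """Twelve secondary-structure features over the exon's residues.

    Each residue's predicted class is the argmax of its (helix, sheet, coil)
    probabilities; ties break by that fixed class order. Features: stats of
    the winning-class probability, plus per-class probability stats.
    """
    probs = _slice(track.ss_probs, residue_range)
    # np.argmax takes the first maximum -> helix > sheet > coil tie order
    argmax_prob = probs[np.arange(len(probs)), np.argmax(probs, axis=1)]
    feats = {
        "ss_argmax_prob_max": float(argmax_prob.max()),
        "ss_argmax_prob_min": float(argmax_prob.min()),
        "ss_argmax_prob_avg": float(argmax_prob.mean()),
    }
    for ci, cname in enumerate(SS_CLASSES):
        col = probs[:, ci]
        feats[f"ss_{cname}_avg"] = float(col.mean())
        feats[f"ss_{cname}_min"] = float(col.min())
        feats[f"ss_{cname}_max"] = float(col.max())
    return feats


def pfam_overlap_pct(domains: DomainAnnotation, residue_range) -> float:
    """Fraction of the exon's residues covered by >= 1 Pfam domain."""
    first, last = residue_range
    if first > last:
        raise EmptyRange(f"residue range [{first}, {last}] is empty")
    covered = np.zeros(last - first + 1, dtype=bool)
    for d_start, d_end in domains.pfam_intervals:
        lo = max(first, d_start)
        hi = min(last, d_end)
        if lo <= hi:
            covered[lo - first : hi - first + 1] = True
    return float(covered.sum() / covered.size)


def ptm_density(domains: DomainAnnotation, residue_range) -> float:
    """PTM sites per 100 amino acids within the exon's residue range."""
    first, last = residue_range
    if first > last:
        raise EmptyRange(f"residue range [{first}, {last}] is empty")
    n = sum(1 for pos, _kind in domains.ptm_sites if first <= pos <= last)
    return 100.0 * n / (last - first + 1)
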