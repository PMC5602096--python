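"""Position-weight-matrix binding models for RNA-binding proteins.

A PWM of nucleotide counts is turned into a position-specific scoring matrix
(PSSM) of log2 odds against a uniform background (d_j = 0.25). A candidate
k-mer is scored by the matching score

    S = sum_i s[i, seq[i]]        (bits)

The matching-score distribution is modelled as Gaussian both for binding
events (moments taken under the PWM-implied base frequencies
f_ij = 2^{s_ij}/4) and for non-binding events (f_ij = 0.25):

    M_s = sum_ij f_ij * s_ij
    V_s = sum_ij [ f_ij * s_ij^2 - (f_ij * s_ij)^2 ]

The variance expression is implemented literally, term by term, as the
method defines it; note the f_ij need not normalise to 1 per column —
:func:`column_frequency_sums` exposes the deviation as a diagnostic.

A variant's effect on one RBP is the magnitude

    M = log2{ [Phi_B(S_A) / (1 - Phi_NB(S_A))] / [Phi_B(S_R) / (1 - Phi_NB(S_R))] }

(Phi_B / Phi_NB = Gaussian CDFs of the binding / non-binding score models;
positive M = site gain), and the Bayesian posterior P that the variant flips
binding status, obtained by integrating the prior binding probability B over
a Beta distribution with mode 0.05 (default Beta(2, 20)).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import stats

from .errors import (
    DegenerateMatrix,
    DegenerateVariance,
    IntegrationFailure,
    InvalidAlphabet,
    LengthMismatch,
    WindowTooShort,
)

logger = logging.getLogger(__name__)

ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}
_BASE_INDEX["U"] = _BASE_INDEX["T"]

# CDF clamp bounds: keep log-ratios finite for extreme scores.
_CDF_LO = 1e-300
_CDF_HI = 1.0 - 1e-16

DEFAULT_PSEUDOCOUNT = 0.25
DEFAULT_BETA_PRIOR = (2.0, 20.0)  # mode (a-1)/(a+b-2) = 0.05


def encode(seq: str) -> np.ndarray:
    """Encode an RNA/DNA string as int indices into ACGT (U -> T)."""
    try:
        return np.array([_BASE_INDEX[c] for c in seq.upper()], dtype=np.int64)
    except KeyError as exc:
        raise InvalidAlphabet(f"invalid nucleotide {exc.args[0]!r} in {seq!r}") from exc


@dataclass(frozen=True)
class PWMModel:
    """Nucleotide count matrix for one RBP.

    ``counts`` has shape (k, 4) in ACGT column order (U collapsed onto T at
    the reader). ``n_sites`` is the number of experimentally validated
    binding sites behind the counts; when absent it defaults to the largest
    per-position count total. ``pseudocounts`` defaults to add-1/4 smoothing.
    """

    rbp_id: str
    counts: np.ndarray
    pseudocounts: Optional[np.ndarray] = None
    n_sites: Optional[float] = None

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=float)
        if counts.ndim != 2 or counts.shape[1] != 4 or counts.shape[0] < 1:
            raise ValueError("counts must have shape (k, 4) with k >= 1")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", counts)
        pseudo = self.pseudocounts
        if pseudo is None:
            pseudo = np.full_like(counts, DEFAULT_PSEUDOCOUNT)
        else:
            pseudo = np.broadcast_to(np.asarray(pseudo, dtype=float), counts.shape).copy()
        object.__setattr__(self, "pseudocounts", pseudo)
        n = self.n_sites
        if n is None:
            n = float(counts.sum(axis=1).max())
        object.__setattr__(self, "n_sites", float(n))
        if (pseudo <= 0).any() and np.any(
            (counts.sum(axis=1) + pseudo.sum(axis=1)) == 0
        ):
            raise DegenerateMatrix(
                f"PWM {self.rbp_id}: a column sums to 0 with zero pseudocount"
            )

    @property
    def width(self) -> int:
        return self.counts.shape[0]


@dataclass(frozen=True)
class BindingScoreModel:
    """PSSM plus Gaussian score models for binding and non-binding events."""

    rbp_id: str
    pssm: np.ndarray  # (k, 4) log2-odds
    binding_freq: np.ndarray  # f_ij = 2^{s_ij}/4
    binding_mean: float
    binding_var: float
    nonbinding_mean: float
    nonbinding_var: float

    @property
    def width(self) -> int:
        return self.pssm.shape[0]

    @property
    def degenerate(self) -> bool:
        return self.binding_var <= 0.0 or self.nonbinding_var <= 0.0


@dataclass(frozen=True)
class BindingDelta:
    """Per-RBP effect of one variant: paired scores, magnitude, posterior."""

    rbp_id: str
    score_ref: float
    score_alt: float
    magnitude: float
    posterior: float
    offset: int  # window offset (0-based in the supplied window) used


def build_pssm(pwm: PWMModel, background: float = 0.25) -> BindingScoreModel:
    """Construct the PSSM and the binding/non-binding Gaussian score models."""
    denom = pwm.n_sites + pwm.pseudocounts.sum(axis=1, keepdims=True)
    if np.any(denom <= 0):
        raise DegenerateMatrix(f"PWM {pwm.rbp_id}: zero column total")
    probs = (pwm.counts + pwm.pseudocounts) / denom
    pssm = np.log2(probs / background)

    f_bind = np.power(2.0, pssm) / 4.0
    binding_mean = float(np.sum(f_bind * pssm))
    binding_var = float(np.sum(f_bind * pssm**2 - (f_bind * pssm) ** 2))

    f_nb = 0.25
    nonbinding_mean = float(np.sum(f_nb * pssm))
    nonbinding_var = float(np.sum(f_nb * pssm**2 - (f_nb * pssm) ** 2))

    col_sums = f_bind.sum(axis=1)
    if np.any(np.abs(col_sums - 1.0) > 1e-6):
        logger.debug(
            "PWM %s: binding frequencies deviate from per-column normalisation "
            "(max |sum-1| = %.3g)",
            pwm.rbp_id,
            float(np.max(np.abs(col_sums - 1.0))),
        )

    return BindingScoreModel(
        rbp_id=pwm.rbp_id,
        pssm=pssm,
        binding_freq=f_bind,
        binding_mean=binding_mean,
        binding_var=max(binding_var, 0.0),
        nonbinding_mean=nonbinding_mean,
        nonbinding_var=max(nonbinding_var, 0.0),
    )


def column_frequency_sums(model: BindingScoreModel) -> np.ndarray:
    """Per-column sums of the PWM-implied frequencies f_ij (diagnostic).

    The f_ij = 2^{s_ij}/4 approximation only sums to exactly 1 per column
    when the count totals equal n_sites; deviations are surfaced here rather
    than silently renormalised.
    """
    return model.binding_freq.sum(axis=1)


def matching_score(model: BindingScoreModel, seq: str) -> float:
    """Matching score S (bits) of a k-length sequence against the PSSM."""
    idx = encode(seq)
    if idx.size != model.width:
        raise LengthMismatch(
            f"sequence length {idx.size} != PWM width {model.width}"
        )
    return float(model.pssm[np.arange(model.width), idx].sum())


def window_scores(model: BindingScoreModel, seq: str) -> np.ndarray:
    """Matching scores of every k-length window of ``seq`` (vectorised)."""
    idx = encode(seq)
    k = model.width
    if idx.size < k:
        return np.empty(0, dtype=float)
    windows = sliding_window_view(idx, k)  # (n_windows, k)
    return model.pssm[np.arange(k), windows].sum(axis=1)


def max_window_score(model: BindingScoreModel, seq: str) -> float:
    """Maximum matching score over all k-windows; 0.0 if seq shorter than k."""
    scores = window_scores(model, seq)
    return float(scores.max()) if scores.size else 0.0


def _check_variance(model: BindingScoreModel):
    if model.degenerate:
        raise DegenerateVariance(
            f"{model.rbp_id}: zero binding/non-binding variance"
        )


def _clamped_cdfs(model: BindingScoreModel, s: float):
    sd_b = np.sqrt(model.binding_var)
    sd_nb = np.sqrt(model.nonbinding_var)
    cdf_b = np.clip(stats.norm.cdf(s, model.binding_mean, sd_b), _CDF_LO, _CDF_HI)
    sf_nb = np.clip(stats.norm.sf(s, model.nonbinding_mean, sd_nb), _CDF_LO, _CDF_HI)
    return cdf_b, sf_nb


def magnitude(score_ref: float, score_alt: float, model: BindingScoreModel) -> float:
    """Magnitude M of the binding change: log2 likelihood-ratio difference.

    Positive M indicates a gain of an RBP-binding site under the alternative
    allele; M is antisymmetric under allele swap and exactly 0 when the two
    scores coincide. CDF values are clamped away from {0, 1} so the ratio
    stays finite for extreme scores.
    """
    _check_variance(model)
    if score_ref == score_alt:
        return 0.0
    cdf_b_a, sf_nb_a = _clamped_cdfs(model, score_alt)
    cdf_b_r, sf_nb_r = _clamped_cdfs(model, score_ref)
    return float(
        np.log2(cdf_b_a) - np.log2(sf_nb_a) - np.log2(cdf_b_r) + np.log2(sf_nb_r)
    )


def posterior_gain_loss(
    score_ref: float,
    score_alt: float,
    model: BindingScoreModel,
    prior: Sequence[float] = DEFAULT_BETA_PRIOR,
    n_grid: int = 2001,
) -> float:
    """Posterior probability that the variant flips binding status.

    Integrates over the prior binding probability B ~ Beta(alpha, beta)
    (default mode 0.05):

        P = E_B[ B(1-B) (g_B(S_R) g_NB(S_A) + g_NB(S_R) g_B(S_A))
                 / (P(S_R) P(S_A)) ]

    with g_B / g_NB the Gaussian binding / non-binding score densities and
    P(S) = B g_B(S) + (1-B) g_NB(S) the prior-weighted mixture. The
    expectation is a deterministic composite-Simpson quadrature on a fixed
    ``n_grid``-point grid over [0, 1].
    """
    _check_variance(model)
    alpha, beta_p = prior
    if alpha <= 0 or beta_p <= 0:
        raise ValueError("Beta prior parameters must be positive")
    if n_grid < 3 or n_grid % 2 == 0:
        raise ValueError("n_grid must be an odd integer >= 3")

    sd_b = np.sqrt(model.binding_var)
    sd_nb = np.sqrt(model.nonbinding_var)
    # densities are constants w.r.t. B
    g_b_r = stats.norm.pdf(score_ref, model.binding_mean, sd_b)
    g_nb_r = stats.norm.pdf(score_ref, model.nonbinding_mean, sd_nb)
    g_b_a = stats.norm.pdf(score_alt, model.binding_mean, sd_b)
    g_nb_a = stats.norm.pdf(score_alt, model.nonbinding_mean, sd_nb)

    b = np.linspace(0.0, 1.0, n_grid)
    w = stats.beta.pdf(b, alpha, beta_p)
    # Beta pdf may be infinite at the endpoints for shape < 1; the B(1-B)
    # factor kills the integrand there, so zero the endpoints explicitly.
    w[~np.isfinite(w)] = 0.0

    mix_r = b * g_b_r + (1.0 - b) * g_nb_r
    mix_a = b * g_b_a + (1.0 - b) * g_nb_a
    num = b * (1.0 - b) * (g_b_r * g_nb_a + g_nb_r * g_b_a)
    denom = np.clip(mix_r * mix_a, 1e-300, None)
    integrand = w * num / denom
    integrand[[0, -1]] = 0.0

    from scipy.integrate import simpson

    p = float(simpson(integrand, x=b))
    if not np.isfinite(p):
        raise IntegrationFailure(
            f"{model.rbp_id}: posterior integration returned {p}"
        )
    return float(np.clip(p, 0.0, 1.0))


def scan_variant(
    model: BindingScoreModel,
    ref_window: str,
    alt_window: str,
    var_index: int,
    mode: str = "best_ref",
    prior: Sequence[float] = DEFAULT_BETA_PRIOR,
) -> BindingDelta:
    """Score a variant against one RBP over all k-windows covering it.

    ``ref_window`` and ``alt_window`` are equal-length sequences differing
    only at ``var_index`` (0-based). All k-length sub-windows overlapping the
    variant are scored at identical offsets for both alleles; the reported
    pair is the offset maximising the reference score (``mode='best_ref'``,
    the default) or the larger of the two alleles' scores
    (``mode='best_either'``, symmetric under allele swap).
    """
    if len(ref_window) != len(alt_window):
        raise LengthMismatch("ref and alt windows differ in length")
    diffs = [i for i, (a, b) in enumerate(zip(ref_window, alt_window)) if a != b]
    if diffs and diffs != [var_index]:
        raise ValueError(
            f"windows differ at {diffs}, expected only at var_index={var_index}"
        )
    k = model.width
    if len(ref_window) < k:
        raise WindowTooShort(
            f"window length {len(ref_window)} < PWM width {k}"
        )
    lo = max(0, var_index - k + 1)
    hi = min(var_index, len(ref_window) - k)
    if hi < lo:
        raise WindowTooShort("no k-window overlaps the variant position")

    ref_scores = window_scores(model, ref_window)[lo : hi + 1]
    alt_scores = window_scores(model, alt_window)[lo : hi + 1]
    if mode == "best_ref":
        off = int(np.argmax(ref_scores))
    elif mode == "best_either":
        off = int(np.argmax(np.maximum(ref_scores, alt_scores)))
    else:
        raise ValueError(f"unknown scan mode {mode!r}")
    s_r = float(ref_scores[off])
    s_a = float(alt_scores[off])

    if model.degenerate:
        m, p = 0.0, 0.0
    else:
        m = magnitude(s_r, s_a, model)
        p = posterior_gain_loss(s_r, s_a, model, prior=prior)
    return BindingDelta(
        rbp_id=model.rbp_id,
        score_ref=s_r,
        score_alt=s_a,
        magnitude=m,
        posterior=p,
        offset=lo + off,
    )


SRSF_IDS = ("SFRS1", "SFRS2", "SFRS5", "SFRS6")


def rbp_feature_summary(
    ref_exon_seq: str,
    alt_exon_seq: str,
    var_index: int,
    models: Sequence[BindingScoreModel],
    srsf_ids: Sequence[str] = SRSF_IDS,
    posterior_cutoff: float = 0.5,
    mode: str = "best_ref",
) -> dict:
    """Per-variant RBP feature block.

    Emits, for each serine/arginine-rich splicing factor in ``srsf_ids``, the
    maximum matching score over the wild and the mutated exon sequence, plus
    panel-wide summaries: the largest |M| across all RBPs and the number of
    RBPs whose flip posterior exceeds ``posterior_cutoff``.
    """
    by_id = {m.rbp_id: m for m in models}
    features = {}
    for sid in srsf_ids:
        model = by_id.get(sid)
        wild = max_window_score(model, ref_exon_seq) if model else 0.0
        mut = max_window_score(model, alt_exon_seq) if model else 0.0
        features[f"{sid.lower()}_max_score_wild"] = wild
        features[f"{sid.lower()}_max_score_mut"] = mut

    max_abs_m = 0.0
    n_flips = 0
    for model in models:
        if model.width > len(ref_exon_seq):
            continue
        try:
            delta = scan_variant(model, ref_exon_seq, alt_exon_seq, var_index, mode=mode)
        except WindowTooShort:
            continue
        if abs(delta.magnitude) > abs(max_abs_m):
            max_abs_m = delta.magnitude
        if delta.posterior > posterior_cutoff:
            n_flips += 1
    features["rbp_max_abs_magnitude"] = abs(max_abs_m)
    features["rbp_n_binding_flips"] = float(n_flips)
    return features
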