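"""Shared fixtures: toy transcripts, a hand-checkable PWM, small cohorts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings as _h_settings

from synsplice import PWMModel, SimConfig, TranscriptModel, build_pssm, simulate

_h_settings.register_profile("deterministic", derandomize=True)
_h_settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def hand_pwm():
    """Width-2 PWM with N=4 sites and add-1/4 pseudocounts.

    Column 1: A=3, C=1, G=0, T=0; column 2: G=4. Small enough that every
    downstream quantity can be recomputed by hand.
    """
    counts = np.array([[3, 1, 0, 0], [0, 0, 4, 0]], dtype=float)
    return PWMModel(rbp_id="toy", counts=counts, n_sites=4)


@pytest.fixture(scope="session")
def hand_model(hand_pwm):
    return build_pssm(hand_pwm)


@pytest.fixture(scope="session")
def uniform_model():
    """Uniform PWM: all-zero PSSM, degenerate (zero-variance) score models."""
    counts = np.full((3, 4), 5.0)
    return build_pssm(PWMModel(rbp_id="uniform", counts=counts, n_sites=20))


@pytest.fixture(scope="session")
def plus_transcript():
    """Three-exon plus-strand transcript; middle exon is 120 nt."""
    return TranscriptModel(
        transcript_id="TX+",
        chrom="chrT",
        strand="+",
        exons=((101, 200), (301, 420), (521, 620)),
    )


@pytest.fixture(scope="session")
def minus_transcript():
    """Two-exon minus-strand toy; genomic order reversed in transcript."""
    return TranscriptModel(
        transcript_id="TX-",
        chrom="chrT",
        strand="-",
        exons=((101, 160), (261, 320)),
    )


@pytest.fixture(scope="session")
def toy_cohort():
    """Ten-variant cohort exercising every training-set filter.

    Composition: 2 variants in first exons, 3 sharing one internal exon,
    1 neutral VIE with MAF 0.05 (below the 10% floor), and 4 unremarkable
    survivors -> exactly 5 variants remain after filtering.
    """
    rows = [
        # two first-exon variants (dropped)
        dict(variant_id="v0", label="disease", site_class="VIE", exon_id="g1:e0",
             exon_index=0, n_exons=5, maf=np.nan, category="DM", pos=100),
        dict(variant_id="v1", label="neutral", site_class="VIE", exon_id="g2:e0",
             exon_index=0, n_exons=5, maf=0.30, category="", pos=200),
        # three sharing one internal exon (two dropped)
        dict(variant_id="v2", label="disease", site_class="VIE", exon_id="g3:e2",
             exon_index=2, n_exons=5, maf=np.nan, category="DM", pos=300),
        dict(variant_id="v3", label="disease", site_class="VIE", exon_id="g3:e2",
             exon_index=2, n_exons=5, maf=np.nan, category="DM?", pos=310),
        dict(variant_id="v4", label="disease", site_class="VIE", exon_id="g3:e2",
             exon_index=2, n_exons=5, maf=np.nan, category="DM", pos=320),
        # neutral VIE below the 10% MAF floor (dropped)
        dict(variant_id="v5", label="neutral", site_class="VIE", exon_id="g4:e1",
             exon_index=1, n_exons=5, maf=0.05, category="", pos=400),
        # four clean survivors
        dict(variant_id="v6", label="neutral", site_class="VIE", exon_id="g5:e1",
             exon_index=1, n_exons=5, maf=0.25, category="", pos=500),
        dict(variant_id="v7", label="neutral", site_class="VSS", exon_id="g6:e2",
             exon_index=2, n_exons=5, maf=0.08, category="", pos=600),
        dict(variant_id="v8", label="disease", site_class="VSS", exon_id="g7:e3",
             exon_index=3, n_exons=5, maf=np.nan, category="DM", pos=700),
        dict(variant_id="v9", label="disease", site_class="VIE", exon_id="g8:e1",
             exon_index=1, n_exons=5, maf=np.nan, category="FP", pos=800),
    ]
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def small_sim():
    """A small but complete synthetic dataset (reference + cohort + truth)."""
    cfg = SimConfig(seed=11, n_genes=8, exons_per_gene=5, n_pos=10, n_neg=10)
    return simulate(cfg)
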