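"""Synthetic generator: determinism, internal consistency, planted signal."""

import hashlib

import numpy as np
import pandas as pd
import pytest

from synsplice import (
    SimConfig,
    cluster_score_delta,
    find_motif_sets,
    generate_cohort,
    generate_reference,
    map_variant_to_exon,
    simulate,
)
from synsplice.errors import ConfigInvalid, Saturation
from synsplice.genomic import Variant, reverse_complement
from synsplice.pwm import SRSF_IDS


def _checksum(ref):
    h = hashlib.sha256()
    for chrom in sorted(ref.genome):
        h.update(ref.genome[chrom].encode())
    for tid in sorted(ref.transcripts):
        h.update(repr(ref.transcripts[tid].exons).encode())
    for p in ref.pwms:
        h.update(p.counts.tobytes())
    h.update(",".join(sorted(ref.ese_motifs)).encode())
    for tid in sorted(ref.tracks):
        h.update(ref.tracks[tid].asa.tobytes())
    return h.hexdigest()


class TestDeterminism:
    def test_same_seed_identical_reference(self):
        cfg = SimConfig(seed=5, n_genes=4, exons_per_gene=4, n_pos=3, n_neg=3)
        assert _checksum(generate_reference(cfg)) == _checksum(generate_reference(cfg))

    def test_different_seed_differs(self):
        a = generate_reference(SimConfig(seed=5, n_genes=4, exons_per_gene=4))
        b = generate_reference(SimConfig(seed=6, n_genes=4, exons_per_gene=4))
        assert _checksum(a) != _checksum(b)

    def test_same_seed_identical_cohort(self):
        cfg = SimConfig(seed=7, n_genes=6, exons_per_gene=5, n_pos=6, n_neg=6)
        _, c1, t1 = simulate(cfg)
        _, c2, t2 = simulate(cfg)
        pd.testing.assert_frame_equal(c1, c2)
        pd.testing.assert_frame_equal(t1, t2)


class TestReferenceConsistency:
    def test_cds_lengths_divisible_by_three(self, small_sim):
        ref, _, _ = small_sim
        for t in ref.transcripts.values():
            assert t.cds_length() % 3 == 0

    def test_tracks_cover_every_protein(self, small_sim):
        ref, _, _ = small_sim
        for tid, t in ref.transcripts.items():
            assert len(ref.tracks[tid]) == t.protein_length()

    def test_exon_and_intron_lengths_within_config(self):
        cfg = SimConfig(seed=3, n_genes=5, exons_per_gene=4)
        ref = generate_reference(cfg)
        lo, hi = cfg.exon_len_range
        for t in ref.transcripts.values():
            lens = t.exon_lengths_transcript_order()
            # last exon may be padded by up to 2 nt for codon alignment
            assert all(lo <= L <= hi + 2 for L in lens)
            for il in t.intron_lengths_transcript_order():
                assert cfg.intron_len_range[0] <= il <= cfg.intron_len_range[1]

    def test_canonical_splice_dinucleotides(self, small_sim):
        ref, _, _ = small_sim
        for t in ref.transcripts.values():
            chrom = ref.genome[t.chrom]
            exons_t = t.exons_transcript_order()
            for (s1, e1), (s2, e2) in zip(exons_t, exons_t[1:]):
                if t.strand == "+":
                    intron = chrom[e1 : s2 - 1]
                else:
                    intron = reverse_complement(chrom[e2 : s1 - 1])
                assert intron[:2] == "GT" and intron[-2:] == "AG"

    def test_site_pwms_prefer_canonical_bases(self, small_sim):
        ref, _, _ = small_sim
        donor = ref.donor_pwm.counts
        # intronic positions 4-5 of the 3+6 window are the invariant GT
        assert donor[3].argmax() == 2  # G
        assert donor[4].argmax() == 3  # T
        acceptor = ref.acceptor_pwm.counts
        assert acceptor[18].argmax() == 0  # A
        assert acceptor[19].argmax() == 2  # G

    def test_srsf_factors_present_in_panel(self, small_sim):
        ref, _, _ = small_sim
        ids = {p.rbp_id for p in ref.pwms}
        assert set(SRSF_IDS) <= ids


class TestCohort:
    def test_requested_variant_counts(self, small_sim):
        _, cohort, _ = small_sim
        assert len(cohort) == 20
        assert (cohort["label"] == "disease").sum() == 10
        assert (cohort["label"] == "neutral").sum() == 10

    def test_default_cohort_is_vie_with_valid_geometry(self, small_sim):
        ref, cohort, _ = small_sim
        assert (cohort["site_class"] == "VIE").all()
        for rec in cohort.itertuples():
            v = Variant(rec.chrom, rec.pos, rec.ref, rec.alt)
            ctx = map_variant_to_exon(v, ref.transcripts[rec.transcript_id])
            assert ctx.site_class == "VIE"
            assert ctx.exon_index == rec.exon_index
            # ref allele matches the (possibly rewritten) genome
            assert ref.genome[rec.chrom][rec.pos - 1] == rec.ref

    def test_neutral_vie_mafs_exceed_floor(self, small_sim):
        _, cohort, _ = small_sim
        neutral = cohort[cohort["label"] == "neutral"]
        assert (neutral["maf"] > 0.10).all()

    def test_vss_config_places_on_splice_sites(self):
        cfg = SimConfig(seed=2, n_genes=6, exons_per_gene=5, n_pos=5, n_neg=5,
                        site_class="VSS")
        ref, cohort, _ = simulate(cfg)
        assert (cohort["site_class"] == "VSS").all()
        neutral = cohort[cohort["label"] == "neutral"]
        assert (neutral["maf"] > 0.03).all()

    def test_one_variant_per_exon(self, small_sim):
        _, cohort, _ = small_sim
        assert cohort["exon_id"].is_unique

    def test_planted_ese_is_findable_and_disruptive(self, small_sim):
        ref, cohort, truth = small_sim
        merged = cohort.merge(truth[["variant_id", "mechanism", "exon_offset"]],
                              on="variant_id")
        planted = merged[merged["mechanism"] == "ese"]
        assert len(planted) > 0
        for rec in planted.itertuples():
            t = ref.transcripts[rec.transcript_id]
            gi = rec.exon_index if t.strand == "+" else t.n_exons - 1 - rec.exon_index
            s, e = t.exons[gi]
            seq = ref.genome[t.chrom][s - 1 : e]
            if t.strand == "-":
                seq = reverse_complement(seq)
            sets = find_motif_sets(seq, ref.ese_motifs)
            off1 = rec.exon_offset + 1  # 1-based
            assert any(m.start <= off1 <= m.end for m in sets)
            # the alternative allele removes ESE burden at the locus
            comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
            alt_t = rec.alt if t.strand == "+" else comp[rec.alt]
            alt_seq = seq[: rec.exon_offset] + alt_t + seq[rec.exon_offset + 1 :]
            assert cluster_score_delta(seq, alt_seq, ref.ese_motifs) < 0

    def test_planted_asa_contrast_has_configured_sign(self, small_sim):
        ref, cohort, _ = small_sim
        means = {}
        for label in ("disease", "neutral"):
            sub = cohort[cohort["label"] == label]
            vals = []
            for rec in sub.itertuples():
                t = ref.transcripts[rec.transcript_id]
                r0, r1 = t.residue_range(rec.exon_index)
                vals.append(ref.tracks[rec.transcript_id].asa[r0 - 1 : r1].mean())
            means[label] = np.mean(vals)
        assert means["disease"] < means["neutral"]

    def test_saturation_error(self):
        cfg = SimConfig(seed=0, n_genes=2, exons_per_gene=3, n_pos=5, n_neg=5)
        ref = generate_reference(cfg)
        with pytest.raises(Saturation):
            generate_cohort(cfg, ref)

    def test_null_config_plants_nothing(self):
        cfg = SimConfig(seed=4, n_genes=6, exons_per_gene=5, n_pos=6, n_neg=6).null()
        _, _, truth = simulate(cfg)
        assert (truth["mechanism"] == "none").all()
        assert (truth["asa_offset"] == 0).all()

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigInvalid):
            SimConfig(exons_per_gene=2)
        with pytest.raises(ConfigInvalid):
            SimConfig(site_class="BOTH")
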