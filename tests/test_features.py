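"""Feature assembly: schema, composition of module-level oracles, imputation."""

import numpy as np
import pandas as pd
import pytest

from synsplice import (
    AnnotationBundle,
    DomainAnnotation,
    PWMModel,
    ResidueTrack,
    SpliceSitePWM,
    TranscriptModel,
    assemble_features,
    build_pssm,
    cluster_score,
    feature_schema,
)
from synsplice.errors import AnnotationMissing
from synsplice.genomic import reverse_complement
from synsplice.protein import pfam_overlap_pct, ptm_density
from synsplice.structure import NussinovProvider

EXON1 = "ACG" * 33  # 99 nt
EXON2 = "A" * 47 + "CCCCCC" + "A" * 47  # 100 nt, single planted ESE
EXON3 = "GTC" * 34  # 102 nt


def _uniform_site_pwm(site_type, exonic, intronic):
    counts = np.full((exonic + intronic, 4), 5.0)
    return SpliceSitePWM.from_pwm(
        site_type, exonic, intronic, PWMModel(site_type, counts, n_sites=20)
    )


@pytest.fixture(scope="module")
def hand_bundle():
    """One plus-strand 3-exon gene with fully hand-checkable annotations."""
    flank = "T" * 60
    intron1 = "GT" + "A" * 26 + "AG"  # 30 nt
    intron2 = "GT" + "C" * 36 + "AG"  # 40 nt
    chrom = flank + EXON1 + intron1 + EXON2 + intron2 + EXON3 + flank
    e1s = len(flank) + 1
    e2s = e1s + len(EXON1) + len(intron1)
    e3s = e2s + len(EXON2) + len(intron2)
    t = TranscriptModel(
        "TX1", "chrH", "+",
        ((e1s, e1s + 98), (e2s, e2s + 99), (e3s, e3s + 101)),
    )
    n_aa = t.protein_length()
    track = ResidueTrack(
        "TX1",
        asa=np.full(n_aa, 50.0),
        disorder=np.full(n_aa, 0.9),
        ss_probs=np.tile([1.0, 0.0, 0.0], (n_aa, 1)),
    )
    # exon 2 codes residues 34..67 (34 residues); domain covers 10 of them
    domains = DomainAnnotation(
        "TX1",
        pfam_intervals=((40, 49),),
        ptm_sites=((35, "phospho"), (60, "acetyl"), (5, "phospho")),
    )
    cons = {"chrH": np.full(len(chrom), 0.5)}
    bundle = AnnotationBundle(
        genome={"chrH": chrom},
        transcripts={"TX1": t},
        rbp_models=[build_pssm(PWMModel("SFRS1", np.full((2, 4), 5.0), n_sites=20))],
        donor_pwm=_uniform_site_pwm("donor", 3, 6),
        acceptor_pwm=_uniform_site_pwm("acceptor", 3, 20),
        ese_motifs=frozenset({"CCCCCC"}),
        ess_motifs=frozenset({"GGGGGG"}),
        tracks={"TX1": track},
        domains={"TX1": domains},
        conservation=cons,
        structure_provider=NussinovProvider(),
    )
    return bundle, t


def _cohort_row(pos, ref, alt, vid="x1", site_class="VIE"):
    return pd.DataFrame(
        [
            dict(
                variant_id=vid, chrom="chrH", pos=pos, ref=ref, alt=alt,
                maf=0.2, label="neutral", category="", site_class=site_class,
                transcript_id="TX1", exon_id="TX1:exon1", exon_index=1, n_exons=3,
            )
        ]
    )


class TestComposition:
    def test_row_matches_module_level_oracles(self, hand_bundle):
        bundle, t = hand_bundle
        e2s = t.exons[1][0]
        pos = e2s + 50  # 0-based offset 50: fourth C of the planted motif
        cohort = _cohort_row(pos, "C", "A")
        m = assemble_features(cohort, bundle, "VIE")
        row = m.loc["x1"]
        # ESE oracle: single isolated set on a 100-bp exon scores exactly 1
        assert row["ese_cluster_wild"] == pytest.approx(
            cluster_score(EXON2, {"CCCCCC"})
        )
        assert row["ese_cluster_wild"] == pytest.approx(1.0)
        assert row["ese_cluster_delta"] == pytest.approx(-1.0)
        assert row["ess_cluster_wild"] == 0.0
        # protein oracles on residues 34..67
        assert t.residue_range(1) == (34, 67)
        dom = bundle.domains["TX1"]
        assert row["pfam_overlap_pct"] == pytest.approx(
            pfam_overlap_pct(dom, (34, 67))
        )
        assert row["pfam_overlap_pct"] == pytest.approx(10 / 34)
        assert row["ptm_density"] == pytest.approx(ptm_density(dom, (34, 67)))
        assert row["ptm_density"] == pytest.approx(100 * 2 / 34)
        # geometry and conservation
        assert row["exon_len"] == 100.0
        assert row["upstream_intron_len"] == 30.0
        assert row["downstream_intron_len"] == 40.0
        assert row["proximity"] == min(51, 50)
        assert row["phylop_mean_7bp"] == pytest.approx(0.5)
        # uniform site PWMs: zero junction scores and delta
        assert row["donor_score"] == 0.0
        assert row["acceptor_score"] == 0.0
        assert row["junction_score_delta"] == 0.0
        assert row["asa_avg"] == 50.0
        assert row["protein_track_missing"] == 0.0

    def test_identical_variants_identical_rows(self, hand_bundle):
        bundle, t = hand_bundle
        pos = t.exons[1][0] + 50
        cohort = pd.concat(
            [_cohort_row(pos, "C", "A", "a"), _cohort_row(pos, "C", "A", "b")]
        )
        m = assemble_features(cohort, bundle, "VIE")
        np.testing.assert_array_equal(m.loc["a"].to_numpy(), m.loc["b"].to_numpy())

    def test_vss_schema_has_no_proximity(self, hand_bundle):
        bundle, t = hand_bundle
        pos = t.exons[1][1]  # last exonic base -> dist_to_donor = 1 -> VSS
        base = bundle.genome["chrH"][pos - 1]
        alt = "A" if base != "A" else "G"
        cohort = _cohort_row(pos, base, alt, site_class="VSS")
        m = assemble_features(cohort, bundle, "VSS")
        assert "proximity" not in m.columns
        assert set(m.columns) == set(feature_schema("VSS"))
        assert tuple(feature_schema("VIE")) == tuple(
            c for c in feature_schema("VIE")
        )
        assert set(feature_schema("VSS")) | {"proximity"} == set(feature_schema("VIE"))

    def test_reference_mismatch_reported_with_variant_id(self, hand_bundle):
        bundle, t = hand_bundle
        pos = t.exons[1][0] + 50  # genome has C here
        cohort = _cohort_row(pos, "G", "A", vid="bad1")
        with pytest.raises(AnnotationMissing) as err:
            assemble_features(cohort, bundle, "VIE")
        assert "bad1" in err.value.variant_ids

    def test_missing_protein_track_imputed_with_indicator(self, hand_bundle):
        bundle, t = hand_bundle
        pos = t.exons[1][0] + 50
        cohort = pd.concat(
            [_cohort_row(pos, "C", "A", "a"), _cohort_row(pos - 5, "A", "G", "b")]
        )
        stripped = AnnotationBundle(
            genome=bundle.genome,
            transcripts=bundle.transcripts,
            rbp_models=bundle.rbp_models,
            donor_pwm=bundle.donor_pwm,
            acceptor_pwm=bundle.acceptor_pwm,
            ese_motifs=bundle.ese_motifs,
            ess_motifs=bundle.ess_motifs,
            tracks={},  # no residue tracks at all
            domains=bundle.domains,
            conservation=bundle.conservation,
            structure_provider=bundle.structure_provider,
        )
        m = assemble_features(cohort, stripped, "VIE")
        assert (m["protein_track_missing"] == 1.0).all()
        assert not m.isna().any().any()


class TestStrandSymmetry:
    def test_minus_strand_gene_gives_mirror_features(self, hand_bundle):
        """The same transcript content on the minus strand must featurize
        identically for strand-symmetric features (motifs, exon geometry)."""
        bundle, t = hand_bundle
        chrom = bundle.genome["chrH"]
        rc = reverse_complement(chrom)
        L = len(chrom)
        exons_rc = tuple(
            sorted((L - e + 1, L - s + 1) for s, e in t.exons)
        )
        t_rc = TranscriptModel("TXR", "chrR", "-", exons_rc)
        bundle_rc = AnnotationBundle(
            genome={"chrR": rc},
            transcripts={"TXR": t_rc},
            rbp_models=bundle.rbp_models,
            donor_pwm=bundle.donor_pwm,
            acceptor_pwm=bundle.acceptor_pwm,
            ese_motifs=bundle.ese_motifs,
            ess_motifs=bundle.ess_motifs,
            tracks={"TXR": bundle.tracks["TX1"]},
            domains={"TXR": DomainAnnotation("TXR",
                                             bundle.domains["TX1"].pfam_intervals,
                                             bundle.domains["TX1"].ptm_sites)},
            conservation={"chrR": bundle.conservation["chrH"]},
            structure_provider=bundle.structure_provider,
        )
        pos = t.exons[1][0] + 50
        pos_rc = L - pos + 1
        m_plus = assemble_features(_cohort_row(pos, "C", "A"), bundle, "VIE")
        cohort_rc = _cohort_row(pos_rc, "G", "T")  # complemented alleles
        cohort_rc["chrom"] = "chrR"
        cohort_rc["transcript_id"] = "TXR"
        m_minus = assemble_features(cohort_rc, bundle_rc, "VIE")
        for col in (
            "ese_cluster_wild", "ese_cluster_delta", "exon_len", "proximity",
            "upstream_intron_len", "downstream_intron_len",
            "pfam_overlap_pct", "ptm_density", "asa_avg",
            "avg_single_strandedness", "structure_distance",
        ):
            assert m_plus[col].iloc[0] == pytest.approx(
                m_minus[col].iloc[0]
            ), col
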