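"""Readers and writers for every on-disk format the pipeline touches.

All outputs are plain text. Tabular files are TSV with ``#``-prefixed
header comments carrying the tool version, seed and config hash; floats are
printed at 6 significant digits for diffability. Coordinates follow the
conventions of each format (VCF/GFF3 1-based inclusive; BED conversion
happens here at the boundary).
"""

from __future__ import annotations

import json
import os
from pathlib import Path
from typing import Dict, Iterable, Optional

import numpy as np
import pandas as pd

from . import __version__
from .errors import FormatError
from .genomic import TranscriptModel, Variant
from .protein import DomainAnnotation, ResidueTrack
from .pwm import ALPHABET, PWMModel
from .simulate import Reference

FLOAT_FMT = "%.6g"


def _header_lines(seed=None, config_hash=None) -> list:
    line = f"# synsplice v{__version__}"
    if seed is not None:
        line += f" seed={seed}"
    if config_hash is not None:
        line += f" config={config_hash}"
    return [line]


def _write_tsv(df: pd.DataFrame, path, seed=None, config_hash=None, index=False):
    path = Path(path)
    with open(path, "w") as fh:
        for line in _header_lines(seed, config_hash):
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=index, float_format=FLOAT_FMT, lineterminator="\n")


def _read_tsv(path, **kw) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", comment="#", **kw)
    except Exception as exc:
        raise FormatError(f"{path}: {exc}") from exc


# --- FASTA ----------------------------------------------------------------

def write_fasta(genome: Dict[str, str], path):
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> Dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# --- transcript models (GFF3 / BED12) -------------------------------------

def write_gff3(transcripts: Dict[str, TranscriptModel], path):
    lines = ["##gff-version 3"]
    for tid in sorted(transcripts):
        t = transcripts[tid]
        start = min(s for s, _ in t.exons)
        end = max(e for _, e in t.exons)
        lines.append(
            f"{t.chrom}\tsynsplice\tmRNA\t{start}\t{end}\t.\t{t.strand}\t.\t"
            f"ID={tid};gene_id={t.gene_id or tid}"
        )
        for i, (s, e) in enumerate(t.exons):
            lines.append(
                f"{t.chrom}\tsynsplice\texon\t{s}\t{e}\t.\t{t.strand}\t.\t"
                f"ID={tid}.exon{i};Parent={tid}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path) -> Dict[str, TranscriptModel]:
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    out = {}
    for mrna in db.features_of_type("mRNA"):
        exons = sorted(
            (f.start, f.end) for f in db.children(mrna, featuretype="exon")
        )
        out[mrna.id] = TranscriptModel(
            transcript_id=mrna.id,
            chrom=mrna.seqid,
            strand=mrna.strand,
            exons=tuple(exons),
            gene_id=mrna.attributes.get("gene_id", [mrna.id])[0],
        )
    return out


def read_bed12(path) -> Dict[str, TranscriptModel]:
    """BED12 transcript models; 0-based half-open converted here."""
    out = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                raise FormatError(f"{path}:{ln}: BED12 needs 12 fields, got {len(f)}")
            chrom, chrom_start, name, strand = f[0], int(f[1]), f[3], f[5]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = tuple(
                (chrom_start + st + 1, chrom_start + st + sz)
                for st, sz in zip(starts, sizes)
            )
            out[name] = TranscriptModel(name, chrom, strand, exons, gene_id=name)
    return out


# --- VCF ------------------------------------------------------------------

def write_vcf(variants: pd.DataFrame, path, contigs: Optional[Dict[str, int]] = None,
              seed=None):
    """Write a minimal VCF 4.2 with AF in INFO (``maf`` column, if present)."""
    lines = [
        "##fileformat=VCFv4.2",
        f"##source=synsplice_v{__version__}" + (f"_seed{seed}" if seed is not None else ""),
        '##INFO=<ID=AF,Number=A,Type=Float,Description="Allele Frequency">',
    ]
    if contigs:
        for name, length in contigs.items():
            lines.append(f"##contig=<ID={name},length={length}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    df = variants.sort_values(["chrom", "pos"], kind="stable")
    for rec in df.itertuples():
        maf = getattr(rec, "maf", None)
        info = "." if maf is None or pd.isna(maf) else f"AF={FLOAT_FMT % maf}"
        lines.append(
            f"{rec.chrom}\t{rec.pos}\t{rec.variant_id}\t{rec.ref}\t{rec.alt}\t.\t.\t{info}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path, af_key: str = "AF") -> list:
    """Parse SNVs from a VCF into :class:`Variant` records (via cyvcf2)."""
    from cyvcf2 import VCF

    out = []
    for rec in VCF(str(path)):
        if len(rec.REF) != 1:
            raise FormatError(f"{path}: record {rec.CHROM}:{rec.POS} is not a SNV")
        if len(rec.ALT) != 1:
            raise FormatError(
                f"{path}: record {rec.CHROM}:{rec.POS} is multi-allelic; split upstream"
            )
        maf = rec.INFO.get(af_key)
        if isinstance(maf, tuple):
            maf = maf[0]
        out.append(
            Variant(
                chrom=rec.CHROM,
                pos=rec.POS,
                ref=rec.REF,
                alt=rec.ALT[0],
                maf=float(maf) if maf is not None else None,
                variant_id=rec.ID or None,
            )
        )
    return out


# --- PWMs and motif libraries ---------------------------------------------

def write_pwms(pwms: Iterable[PWMModel], path, seed=None):
    rows = []
    for p in pwms:
        for i in range(p.width):
            rows.append(
                {
                    "rbp_id": p.rbp_id,
                    "position": i + 1,
                    **{b: p.counts[i, j] for j, b in enumerate(ALPHABET)},
                    "n_sites": p.n_sites,
                }
            )
    _write_tsv(pd.DataFrame(rows), path, seed=seed)


def read_pwms(path) -> list:
    df = _read_tsv(path)
    needed = {"rbp_id", "position", *ALPHABET}
    if not needed.issubset(df.columns):
        raise FormatError(f"{path}: PWM table needs columns {sorted(needed)}")
    out = []
    for rbp_id, grp in df.groupby("rbp_id", sort=False):
        grp = grp.sort_values("position")
        if list(grp["position"]) != list(range(1, len(grp) + 1)):
            raise FormatError(f"{path}: PWM {rbp_id} has non-contiguous positions")
        counts = grp[list(ALPHABET)].to_numpy(dtype=float)
        n_sites = float(grp["n_sites"].iloc[0]) if "n_sites" in grp else None
        out.append(PWMModel(rbp_id=str(rbp_id), counts=counts, n_sites=n_sites))
    return out


def read_meme_pwms(path) -> list:
    """Minimal MEME-format motif reader (letter-probability matrices)."""
    out = []
    name, rows, nsites = None, [], 20
    with open(path) as fh:
        for ln, raw in enumerate(fh, 1):
            line = raw.strip()
            if line.startswith("MOTIF"):
                if name and rows:
                    out.append(_meme_to_pwm(name, rows, nsites))
                parts = line.split()
                name, rows = parts[1], []
            elif line.startswith("letter-probability"):
                if "nsites=" in line:
                    try:
                        nsites = int(line.split("nsites=")[1].split()[0])
                    except (ValueError, IndexError) as exc:
                        raise FormatError(f"{path}:{ln}: bad nsites") from exc
            elif name is not None and line and line[0].isdigit() or (
                name is not None and line.startswith("0.")
            ):
                vals = line.split()
                if len(vals) != 4:
                    raise FormatError(f"{path}:{ln}: expected 4 probabilities")
                rows.append([float(v) for v in vals])
    if name and rows:
        out.append(_meme_to_pwm(name, rows, nsites))
    return out


def _meme_to_pwm(name, rows, nsites) -> PWMModel:
    probs = np.asarray(rows, dtype=float)
    return PWMModel(rbp_id=name, counts=probs * nsites, n_sites=nsites)


def write_motifs(motifs: Iterable[str], path):
    Path(path).write_text("\n".join(sorted(motifs)) + "\n")


def read_motifs(path) -> frozenset:
    out = set()
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        m = line.strip().upper().replace("U", "T")
        if not m or m.startswith("#"):
            continue
        if any(c not in ALPHABET for c in m):
            raise FormatError(f"{path}:{ln}: invalid motif {m!r}")
        out.add(m)
    return frozenset(out)


# --- protein tracks / domains / PTMs --------------------------------------

def write_tracks(tracks: Dict[str, ResidueTrack], path, seed=None):
    rows = []
    for pid in sorted(tracks):
        tr = tracks[pid]
        for i in range(len(tr)):
            rows.append(
                {
                    "protein_id": pid,
                    "residue_index": i + 1,
                    "asa": tr.asa[i],
                    "disorder": tr.disorder[i],
                    "p_helix": tr.ss_probs[i, 0],
                    "p_sheet": tr.ss_probs[i, 1],
                    "p_coil": tr.ss_probs[i, 2],
                }
            )
    _write_tsv(pd.DataFrame(rows), path, seed=seed)


def read_tracks(path) -> Dict[str, ResidueTrack]:
    df = _read_tsv(path)
    out = {}
    for pid, grp in df.groupby("protein_id", sort=False):
        grp = grp.sort_values("residue_index")
        ss = grp[["p_helix", "p_sheet", "p_coil"]].to_numpy(dtype=float)
        # renormalise against 6-sig-digit rounding in the TSV
        ss = ss / ss.sum(axis=1, keepdims=True)
        out[str(pid)] = ResidueTrack(
            str(pid),
            grp["asa"].to_numpy(dtype=float),
            grp["disorder"].to_numpy(dtype=float),
            ss,
        )
    return out


def write_domains(domains: Dict[str, DomainAnnotation], pfam_path, ptm_path, seed=None):
    pfam_rows, ptm_rows = [], []
    for pid in sorted(domains):
        d = domains[pid]
        for s, e in d.pfam_intervals:
            pfam_rows.append({"protein_id": pid, "start_aa": s, "end_aa": e})
        for pos, kind in d.ptm_sites:
            ptm_rows.append({"protein_id": pid, "position": pos, "modification": kind})
    _write_tsv(
        pd.DataFrame(pfam_rows, columns=["protein_id", "start_aa", "end_aa"]),
        pfam_path, seed=seed,
    )
    _write_tsv(
        pd.DataFrame(ptm_rows, columns=["protein_id", "position", "modification"]),
        ptm_path, seed=seed,
    )


def read_domains(pfam_path, ptm_path) -> Dict[str, DomainAnnotation]:
    pfam = _read_tsv(pfam_path)
    ptm = _read_tsv(ptm_path)
    pids = set(pfam.get("protein_id", [])) | set(ptm.get("protein_id", []))
    out = {}
    for pid in sorted(pids):
        ivals = tuple(
            (int(r.start_aa), int(r.end_aa))
            for r in pfam[pfam["protein_id"] == pid].itertuples()
        )
        sites = tuple(
            (int(r.position), str(r.modification))
            for r in ptm[ptm["protein_id"] == pid].itertuples()
        )
        out[str(pid)] = DomainAnnotation(str(pid), ivals, sites)
    return out


# --- conservation ---------------------------------------------------------

def write_conservation(
    conservation: Dict[str, np.ndarray],
    transcripts: Dict[str, TranscriptModel],
    path,
    pad: int = 10,
    seed=None,
):
    """Write per-base scores restricted to exons +/- ``pad`` (sparse TSV)."""
    rows = []
    for chrom in sorted(conservation):
        track = conservation[chrom]
        mask = np.zeros(len(track), dtype=bool)
        for t in transcripts.values():
            if t.chrom != chrom:
                continue
            for s, e in t.exons:
                mask[max(0, s - 1 - pad) : min(len(track), e + pad)] = True
        pos = np.nonzero(mask)[0]
        rows.append(
            pd.DataFrame({"chrom": chrom, "pos": pos + 1, "score": track[pos]})
        )
    _write_tsv(pd.concat(rows, ignore_index=True), path, seed=seed)


def read_conservation(path, chrom_lengths: Dict[str, int]) -> Dict[str, np.ndarray]:
    df = _read_tsv(path)
    out = {
        chrom: np.full(length, np.nan) for chrom, length in chrom_lengths.items()
    }
    for chrom, grp in df.groupby("chrom", sort=False):
        out[str(chrom)][grp["pos"].to_numpy(dtype=int) - 1] = grp["score"].to_numpy(
            dtype=float
        )
    return out


# --- cohort / matrix / metrics --------------------------------------------

def write_cohort(cohort: pd.DataFrame, path, seed=None):
    _write_tsv(cohort, path, seed=seed)


def read_cohort(path) -> pd.DataFrame:
    df = _read_tsv(path)
    if "category" in df.columns:
        df["category"] = df["category"].fillna("")
    return df


def write_matrix(matrix: pd.DataFrame, path, seed=None):
    _write_tsv(matrix, path, seed=seed, index=True)


def read_matrix(path) -> pd.DataFrame:
    return _read_tsv(path, index_col="variant_id")


def write_json(payload: dict, path, seed=None):
    payload = dict(payload)
    payload.setdefault("_meta", {})
    payload["_meta"].update({"tool": "synsplice", "version": __version__})
    if seed is not None:
        payload["_meta"]["seed"] = seed
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


# --- reference directory ---------------------------------------------------

def write_reference(ref: Reference, outdir, seed=None):
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(ref.genome, outdir / "genome.fa")
    write_gff3(ref.transcripts, outdir / "transcripts.gff3")
    write_pwms(ref.pwms, outdir / "rbp_pwms.tsv", seed=seed)
    write_pwms([ref.donor_pwm], outdir / "donor_pwm.tsv", seed=seed)
    write_pwms([ref.acceptor_pwm], outdir / "acceptor_pwm.tsv", seed=seed)
    write_motifs(ref.ese_motifs, outdir / "ese_motifs.txt")
    write_motifs(ref.ess_motifs, outdir / "ess_motifs.txt")
    write_tracks(ref.tracks, outdir / "residue_tracks.tsv", seed=seed)
    write_domains(
        ref.domains, outdir / "pfam_domains.tsv", outdir / "ptm_sites.tsv", seed=seed
    )
    write_conservation(
        ref.conservation, ref.transcripts, outdir / "conservation.tsv", seed=seed
    )


def load_reference(refdir) -> Reference:
    refdir = Path(refdir)
    genome = read_fasta(refdir / "genome.fa")
    transcripts = read_gff3(refdir / "transcripts.gff3")
    return Reference(
        genome=genome,
        transcripts=transcripts,
        pwms=read_pwms(refdir / "rbp_pwms.tsv"),
        ese_motifs=read_motifs(refdir / "ese_motifs.txt"),
        ess_motifs=read_motifs(refdir / "ess_motifs.txt"),
        donor_pwm=read_pwms(refdir / "donor_pwm.tsv")[0],
        acceptor_pwm=read_pwms(refdir / "acceptor_pwm.tsv")[0],
        tracks=read_tracks(refdir / "residue_tracks.tsv"),
        domains=read_domains(refdir / "pfam_domains.tsv", refdir / "ptm_sites.tsv"),
        conservation=read_conservation(
            refdir / "conservation.tsv",
            {c: len(s) for c, s in genome.items()},
        ),
    )
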