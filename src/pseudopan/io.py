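"""Readers and writers for the formats shared by all pipeline stages.

Pseudogene calls travel as a BED6+ dialect (comment-headed, tab-separated),
genes as GFF3 (1-based inclusive on disk, converted at this boundary),
liftover block maps and tabular data as TSV, trees as Newick, and the
simulation ground truth as JSON.  ``write_dataset``/``read_dataset``
round-trip a :class:`~pseudopan.simulate.SyntheticDataset` exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import seqevo
from .records import HaplotypeSegment, LiftoverMap, PseudogeneRecord
from .simulate import SimConfig, SyntheticDataset
from .trees import StrainTree

BED_COLUMNS = ["chrom", "start", "end", "uid", "score", "strand", "strain_id",
               "biotype", "parent_id", "pct_identity", "query_coverage", "level",
               "source", "ens_id", "n_stop", "n_deletion", "n_insertion",
               "haplotype", "exons"]
LIFTOVER_COLUMNS = ["srcChrom", "srcStart", "srcEnd", "dstChrom", "dstStart", "dstEnd", "strand"]


def _none_to_dot(v):
    return "." if v is None else str(v)


def _dot_to_none(v):
    return None if v == "." else v


# ---------------------------------------------------------------------------
# BED6+ pseudogene records


def write_bed_plus(records: list, path) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(BED_COLUMNS) + "\n")
        for r in records:
            exons = ",".join(f"{a}-{b}" for a, b in r.exon_intervals)
            fields = [r.chrom, r.start, r.end, r.uid, 0, r.strand, r.strain_id,
                      r.biotype, _none_to_dot(r.parent_id), repr(float(r.pct_identity)),
                      repr(float(r.query_coverage)), _none_to_dot(r.level), r.source,
                      _none_to_dot(r.ens_id), r.disablements.get("stop", 0),
                      r.disablements.get("deletion", 0), r.disablements.get("insertion", 0),
                      _none_to_dot(r.haplotype), exons or "."]
            fh.write("\t".join(str(f) for f in fields) + "\n")


def parse_bed_plus(path) -> list:
    """Parse the BED6+ pseudogene dialect; tolerant of track/comment lines."""
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}:{lineno}: expected >= 6 tab-separated fields, "
                                 f"got {len(parts)}")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start {start} must be < end {end}")
            extra = parts + ["."] * (len(BED_COLUMNS) - len(parts))
            exons = []
            if extra[18] != ".":
                for piece in extra[18].split(","):
                    a, b = piece.split("-")
                    exons.append((int(a), int(b)))
            level = _dot_to_none(extra[11])
            try:
                rec = PseudogeneRecord(
                    uid=parts[3], strain_id=extra[6] if extra[6] != "." else "",
                    chrom=parts[0], start=start, end=end, strand=parts[5],
                    biotype=extra[7] if extra[7] != "." else "processed",
                    parent_id=_dot_to_none(extra[8]),
                    pct_identity=float(extra[9]) if extra[9] != "." else 100.0,
                    query_coverage=float(extra[10]) if extra[10] != "." else 1.0,
                    level=int(level) if level is not None else None,
                    source=extra[12] if extra[12] != "." else "auto",
                    ens_id=_dot_to_none(extra[13]),
                    disablements={"stop": int(extra[14]) if extra[14] != "." else 0,
                                  "deletion": int(extra[15]) if extra[15] != "." else 0,
                                  "insertion": int(extra[16]) if extra[16] != "." else 0},
                    haplotype=_dot_to_none(extra[17]),
                    exon_intervals=exons)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            records.append(rec)
    return records


# ---------------------------------------------------------------------------
# GFF3 genes


def write_genes_gff3(genes: pd.DataFrame, path) -> None:
    """genes: DataFrame with gene_id, chrom, start, end (0-based half-open)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in genes.itertuples():
            fh.write("\t".join([
                row.chrom, "pseudopan", "gene", str(row.start + 1), str(row.end),
                ".", "+", ".", f"ID={row.gene_id}"]) + "\n")


def read_genes_gff3(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
            rows.append((attrs.get("ID", ""), f[0], int(f[3]) - 1, int(f[4])))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])


# ---------------------------------------------------------------------------
# simple tracks


def write_segments_bed(segments: list, path) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tlabel\n")
        for s in segments:
            fh.write(f"{s.chrom}\t{s.start}\t{s.end}\t{s.label}\n")


def read_segments_bed(path) -> list:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            chrom, start, end, label = line.rstrip("\n").split("\t")[:4]
            out.append(HaplotypeSegment(chrom, int(start), int(end), label))
    return out


def write_intervals_bed(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=["chrom", "start", "end"])


def read_intervals_bed(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str, "start": np.int64, "end": np.int64})


# ---------------------------------------------------------------------------
# liftover maps


def write_liftover_tsv(lift: LiftoverMap, path) -> None:
    df = lift.blocks.rename(columns=dict(zip(LiftoverMap.COLUMNS, LIFTOVER_COLUMNS)))
    df.to_csv(path, sep="\t", index=False)


def read_liftover_tsv(path, src: str = "", dst: str = "") -> LiftoverMap:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in LIFTOVER_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: liftover TSV missing columns {missing}")
    df = df.rename(columns=dict(zip(LIFTOVER_COLUMNS, LiftoverMap.COLUMNS)))
    return LiftoverMap(df, src=src, dst=dst)


# ---------------------------------------------------------------------------
# FASTA sequences


def write_fasta(seqs: dict, path) -> None:
    recs = [SeqRecord(Seq(seqevo.decode(codes)), id=name, description="")
            for name, codes in sorted(seqs.items())]
    SeqIO.write(recs, path, "fasta")


def read_fasta(path) -> dict:
    return {rec.id: seqevo.encode(str(rec.seq)) for rec in SeqIO.parse(path, "fasta")}


# ---------------------------------------------------------------------------
# dataset round trip


def write_dataset(ds: SyntheticDataset, directory) -> list:
    """Write the dataset to ``directory``; returns the file manifest."""
    root = Path(directory)
    root.mkdir(parents=True, exist_ok=True)
    manifest = []

    def emit(relpath, writer):
        p = root / relpath
        p.parent.mkdir(parents=True, exist_ok=True)
        writer(p)
        manifest.append(str(relpath))

    for s in ds.strains:
        emit(f"{s}/genes.gff3", lambda p, s=s: write_genes_gff3(ds.gene_coords[s], p))
        emit(f"{s}/pseudogenes_auto.bed", lambda p, s=s: write_bed_plus(ds.auto[s], p))
        emit(f"{s}/pseudogenes_manual.bed", lambda p, s=s: write_bed_plus(ds.manual[s], p))
        emit(f"{s}/pseudogenes_truth.bed", lambda p, s=s: write_bed_plus(ds.truth_records[s], p))
        emit(f"{s}/sequences.fa", lambda p, s=s: write_fasta(ds.sequences[s], p))
        emit(f"{s}/haplotypes.bed", lambda p, s=s: write_segments_bed(ds.haplotypes[s], p))
        emit(f"{s}/mappability.bed", lambda p, s=s: write_intervals_bed(ds.mappability[s], p))
        for t in ds.pseudogene_fpkm[s].columns:
            emit(f"{s}/fpkm_{t}.tsv",
                 lambda p, s=s, t=t: ds.pseudogene_fpkm[s][[t]].to_csv(p, sep="\t"))
    for (a, b), lift in sorted(ds.liftovers.items()):
        emit(f"liftover_{a}_{b}.tsv", lambda p, lift=lift: write_liftover_tsv(lift, p))
    for t in ds.gene_fpkm.columns:
        emit(f"fpkm_{t}.tsv", lambda p, t=t: ds.gene_fpkm[[t]].to_csv(p, sep="\t"))
    emit("genes.tsv", lambda p: ds.genes.to_csv(p, sep="\t", index=False))
    emit("essentiality.tsv", lambda p: ds.essentiality.to_csv(p, sep="\t", index=False))
    emit("counts.tsv", lambda p: ds.counts.to_csv(p, sep="\t", index=False))
    emit("parents.fa", lambda p: write_fasta(ds.parent_seqs, p))
    emit("tree.nwk", lambda p: p.write_text(ds.tree.to_newick() + "\n"))

    cfg = dataclasses.asdict(ds.config)
    cfg.pop("tree", None)
    classes = ds.classes.copy()
    classes["strains"] = classes["strains"].map(list)
    truth = {
        "config": cfg,
        "strains": ds.strains,
        "calibration_strain": ds.calibration_strain,
        "processed_fraction": ds.processed_fraction,
        "classes": classes.to_dict(orient="list"),
        "transcribed_truth": {s: sorted(ds.transcribed_truth[s]) for s in ds.strains},
        "tissues": list(ds.gene_fpkm.columns),
    }
    emit("truth.json", lambda p: p.write_text(json.dumps(truth, sort_keys=True, indent=1)))
    emit("manifest.json", lambda p: p.write_text(json.dumps(sorted(manifest + ["manifest.json"]),
                                                            indent=1)))
    return sorted(manifest + ["manifest.json"])


def read_dataset(directory) -> SyntheticDataset:
    root = Path(directory)
    truth = json.loads((root / "truth.json").read_text())
    cfg = SimConfig(**{k: (tuple(v) if isinstance(v, list) and k in
                           ("gene_length_range", "pg_length_bounds", "burst_identities")
                           else v)
                       for k, v in truth["config"].items()})
    if cfg.burst_times is not None:
        cfg.burst_times = [tuple(x) for x in cfg.burst_times]
    strains = truth["strains"]
    tree = StrainTree.from_newick((root / "tree.nwk").read_text(), outgroup=cfg.outgroup)

    class_cols = ["class_id", "parent_id", "biotype", "birth_age", "length",
                  "gene_offset", "n_exons", "strains", "chrom", "anc_start", "anc_end"]
    classes = pd.DataFrame(truth["classes"])
    if set(class_cols) <= set(classes.columns):
        classes = classes[class_cols]
    if len(classes):
        classes["strains"] = classes["strains"].map(tuple)
    genes = pd.read_csv(root / "genes.tsv", sep="\t")
    essentiality = pd.read_csv(root / "essentiality.tsv", sep="\t")
    counts = pd.read_csv(root / "counts.tsv", sep="\t")
    tissues = truth["tissues"]

    gene_fpkm = pd.concat(
        [pd.read_csv(root / f"fpkm_{t}.tsv", sep="\t", index_col="uid") for t in tissues],
        axis=1)
    truth_records, auto, manual, sequences = {}, {}, {}, {}
    haplotypes, mappability, pseudogene_fpkm, gene_coords = {}, {}, {}, {}
    for s in strains:
        d = root / s
        truth_records[s] = parse_bed_plus(d / "pseudogenes_truth.bed")
        auto[s] = parse_bed_plus(d / "pseudogenes_auto.bed")
        manual[s] = parse_bed_plus(d / "pseudogenes_manual.bed")
        sequences[s] = read_fasta(d / "sequences.fa")
        haplotypes[s] = read_segments_bed(d / "haplotypes.bed")
        mappability[s] = read_intervals_bed(d / "mappability.bed")
        pseudogene_fpkm[s] = pd.concat(
            [pd.read_csv(d / f"fpkm_{t}.tsv", sep="\t", index_col="uid") for t in tissues],
            axis=1)
        gene_coords[s] = read_genes_gff3(d / "genes.gff3")
    liftovers = {}
    for a in strains:
        for b in strains:
            if a != b:
                liftovers[(a, b)] = read_liftover_tsv(root / f"liftover_{a}_{b}.tsv",
                                                      src=a, dst=b)
    return SyntheticDataset(
        config=cfg, tree=tree, strains=strains, genes=genes, classes=classes,
        truth_records=truth_records, auto=auto, manual=manual,
        sequences=sequences, parent_seqs=read_fasta(root / "parents.fa"),
        liftovers=liftovers, gene_fpkm=gene_fpkm, pseudogene_fpkm=pseudogene_fpkm,
        transcribed_truth={s: set(v) for s, v in truth["transcribed_truth"].items()},
        essentiality=essentiality, haplotypes=haplotypes, mappability=mappability,
        counts=counts, gene_coords=gene_coords,
        calibration_strain=truth["calibration_strain"],
        processed_fraction=truth["processed_fraction"])


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
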