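"""Readers and writers for the formats the pipeline touches.

FASTA parsing is delegated to Bio.SeqIO, VCF parsing to pysam and GFF3
to gffutils; the wrappers here normalise case, enforce the small
subset of each format the pipeline needs (DP/AD/MQ for VCF), and
convert between the user-facing 1-based inclusive coordinates and the
0-based half-open coordinates used internally.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO

from .genome import COMPARTMENTS, GeneModel, Genome, experiment_table

VALID_BASES = frozenset("ACGTN")


class FormatError(ValueError):
    """A file violates the subset of its format this pipeline accepts."""


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str) -> dict[str, str]:
    """Read a FASTA file into {contig id: uppercase sequence}.

    The contig id is the first whitespace-delimited token of the
    header.  Duplicate ids and non-IUPAC characters are format errors;
    the error message names the offending line.
    """
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(path, "fasta"):
        seq = str(record.seq).upper()
        if record.id in sequences:
            raise FormatError(
                f"{path}: duplicate sequence id {record.id!r} "
                f"(line {_find_line(path, '>' + record.id)})"
            )
        bad = set(seq) - VALID_BASES
        if bad:
            raise FormatError(
                f"{path}: non-IUPAC character(s) {sorted(bad)} in record "
                f"{record.id!r} (line {_find_bad_char_line(path, bad)})"
            )
        sequences[record.id] = seq
    if not sequences:
        raise FormatError(f"{path}: no FASTA records found")
    return sequences


def _find_line(path: str, prefix: str) -> int:
    n = 0
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            if line.startswith(prefix):
                n += 1
                if n == 2:  # second occurrence is the duplicate
                    return i
    return -1


def _find_bad_char_line(path: str, bad: set[str]) -> int:
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            if line.startswith(">"):
                continue
            if set(line.strip().upper()) & bad:
                return i
    return -1


def write_fasta(sequences: dict[str, str], path: str, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3

_GFF_COLUMNS = ["seqid", "source", "type", "start", "end", "score", "strand",
                "phase", "attributes"]


def write_gff3(genome: Genome, path: str) -> None:
    """Write gene models as GFF3 (gene/mRNA/exon/CDS/UTR features, 1-based)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for contig, seq in genome.sequences.items():
            fh.write(f"##sequence-region {contig} 1 {len(seq)}\n")
        for g in genome.genes:
            s0, e0 = g.span
            row = [g.contig, "mutacc", "gene", s0 + 1, e0, ".", g.strand, ".",
                   f"ID={g.gene_id}"]
            fh.write("\t".join(map(str, row)) + "\n")
            mrna = f"{g.gene_id}.t1"
            fh.write("\t".join(map(str, [g.contig, "mutacc", "mRNA", s0 + 1, e0,
                                         ".", g.strand, ".",
                                         f"ID={mrna};Parent={g.gene_id}"])) + "\n")
            for ftype, ivals in (("five_prime_UTR", g.utr5), ("CDS", g.cds),
                                 ("three_prime_UTR", g.utr3), ("exon", g.exons)):
                for s, e in ivals:
                    fid = f"{mrna}.{ftype}.{s + 1}"
                    fh.write("\t".join(map(str, [g.contig, "mutacc", ftype,
                                                 s + 1, e, ".", g.strand, ".",
                                                 f"ID={fid};Parent={mrna}"])) + "\n")


def read_gff3(path: str) -> list[GeneModel]:
    """Read gene models from GFF3.

    Honours gene, mRNA, CDS, exon and UTR feature types; introns are
    derived from gaps between exons.  One mRNA per gene is assumed
    (the first, if several).
    """
    import gffutils

    db = gffutils.create_db(path, dbfn=":memory:", force=True,
                            merge_strategy="create_unique", keep_order=True)
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        mrnas = list(db.children(gene, featuretype="mRNA"))
        parent = mrnas[0] if mrnas else gene
        cds = [(f.start - 1, f.end) for f in db.children(parent, featuretype="CDS")]
        utr5 = [(f.start - 1, f.end)
                for f in db.children(parent, featuretype="five_prime_UTR")]
        utr3 = [(f.start - 1, f.end)
                for f in db.children(parent, featuretype="three_prime_UTR")]
        gm = GeneModel(gene_id=gene.id, contig=gene.seqid, strand=gene.strand,
                       cds=sorted(cds), utr5=sorted(utr5), utr3=sorted(utr3))
        gm.validate()
        genes.append(gm)
    return genes


def read_genome(fasta_path: str, gff_path: str | None = None,
                compartments: dict[str, str] | None = None) -> Genome:
    seqs = read_fasta(fasta_path)
    comp = dict(compartments or {})
    for c in comp.values():
        if c not in COMPARTMENTS:
            raise ValueError(f"unknown compartment label {c!r}")
    genome = Genome(sequences=seqs, compartments=comp)
    if gff_path:
        genome.genes = read_gff3(gff_path)
    genome.validate()
    return genome


# ---------------------------------------------------------------------------
# VCF candidate tables

#: Core columns of a candidate table; per-sample depths are added as
#: ``DP:<sample>`` and alt-supporting depths as ``AD:<sample>``.
CANDIDATE_CORE = ["contig", "pos", "ref", "alt", "mq", "dist_indel"]


@dataclass
class CandidateTable:
    """SNV candidates plus the sample layout of the source VCF."""

    table: pd.DataFrame
    samples: list[str]
    ancestor: str

    @property
    def lines(self) -> list[str]:
        return [s for s in self.samples if s != self.ancestor]

    def depth(self, sample: str) -> pd.Series:
        return self.table[f"DP:{sample}"]

    def alt_depth(self, sample: str) -> pd.Series:
        return self.table[f"AD:{sample}"]


def read_vcf_candidates(path: str, ancestor: str) -> CandidateTable:
    """Read SNV candidates from a VCF with per-sample DP/AD and INFO MQ.

    Indel records (REF or ALT longer than one base) are not returned as
    candidates; instead each SNV's distance to the nearest indel record
    on its contig is recorded (``inf`` when the contig has none).
    Multiallelic records are split into one candidate per alt allele.
    """
    vf = pysam.VariantFile(path)
    samples = list(vf.header.samples)
    if ancestor not in samples:
        raise FormatError(f"{path}: ancestor sample {ancestor!r} not in VCF")
    if len(samples) < 2:
        raise FormatError(f"{path}: need one ancestor plus at least one MA line")

    rows: list[dict] = []
    indel_pos: dict[str, list[int]] = {}
    for rec in vf:
        alts = rec.alts or ()
        is_indel = any(len(rec.ref) != 1 or len(a) != 1 for a in alts)
        if is_indel:
            indel_pos.setdefault(rec.contig, []).append(rec.pos)
            continue
        if "MQ" not in rec.info:
            raise FormatError(f"{path}: unusable record {rec.contig}:{rec.pos} "
                              f"({rec.ref}>{','.join(alts)}): missing INFO/MQ")
        mq = float(rec.info["MQ"])
        per_sample: dict[str, tuple[int, tuple[int, ...]]] = {}
        for s in samples:
            fmt = rec.samples[s]
            dp = fmt.get("DP")
            ad = fmt.get("AD")
            if dp is None or ad is None:
                raise FormatError(
                    f"{path}: unusable record {rec.contig}:{rec.pos} "
                    f"({rec.ref}>{','.join(alts)}): missing DP/AD for {s}")
            per_sample[s] = (int(dp), tuple(int(x) for x in ad))
        for ai, alt in enumerate(alts, start=1):
            row = {"contig": rec.contig, "pos": rec.pos, "ref": rec.ref,
                   "alt": alt, "mq": mq, "dist_indel": np.inf}
            for s in samples:
                dp, ad = per_sample[s]
                row[f"DP:{s}"] = dp
                row[f"AD:{s}"] = ad[ai] if ai < len(ad) else 0
            rows.append(row)

    df = pd.DataFrame(rows, columns=CANDIDATE_CORE
                      + [f"{k}:{s}" for s in samples for k in ("DP", "AD")])
    _annotate_indel_distance(df, indel_pos)
    return CandidateTable(table=df, samples=samples, ancestor=ancestor)


def _annotate_indel_distance(df: pd.DataFrame,
                             indel_pos: dict[str, list[int]]) -> None:
    for contig, positions in indel_pos.items():
        arr = np.sort(np.asarray(positions))
        mask = df["contig"] == contig
        if not mask.any():
            continue
        pos = df.loc[mask, "pos"].to_numpy()
        idx = np.searchsorted(arr, pos)
        left = np.abs(pos - arr[np.clip(idx - 1, 0, len(arr) - 1)])
        right = np.abs(arr[np.clip(idx, 0, len(arr) - 1)] - pos)
        df.loc[mask, "dist_indel"] = np.minimum(left, right).astype(float)


def write_vcf(candidates: CandidateTable, path: str,
              indels: pd.DataFrame | None = None) -> None:
    """Write a candidate table back to a minimal VCF 4.2.

    ``indels`` may carry extra indel records (columns contig, pos, ref,
    alt) so the SnpGap-style distance annotation survives a round trip.
    """
    df = candidates.table
    samples = candidates.samples
    recs: list[tuple[str, int, str, str, float, dict | None]] = [
        (r.contig, int(r.pos), r.ref, r.alt, float(r.mq),
         {s: (int(df.at[r.Index, f"DP:{s}"]), int(df.at[r.Index, f"AD:{s}"]))
          for s in samples})
        for r in df.itertuples()
    ]
    if indels is not None:
        for r in indels.itertuples():
            recs.append((r.contig, int(r.pos), r.ref, r.alt, 60.0, None))
    recs.sort(key=lambda t: (t[0], t[1]))

    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        contigs = sorted({c for c, *_ in recs})
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for contig, pos, ref, alt, mq, per_sample in recs:
            cols = [contig, str(pos), ".", ref, alt, ".", "PASS",
                    f"MQ={mq:g}", "GT:DP:AD"]
            for s in samples:
                if per_sample is None:
                    cols.append("./.:30:30,0")
                else:
                    dp, ad = per_sample[s]
                    gt = "0/1" if ad > 0 else "0/0"
                    cols.append(f"{gt}:{dp}:{max(dp - ad, 0)},{ad}")
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# Pileup statistics tables

def write_pileup_tsv(mq: dict[str, np.ndarray],
                     depth: dict[str, dict[str, np.ndarray]],
                     path: str) -> None:
    """Per-site MQ and per-sample depths as TSV (1-based positions)."""
    samples = list(depth)
    frames = []
    for contig in mq:
        df = pd.DataFrame({"contig": contig,
                           "pos": np.arange(1, len(mq[contig]) + 1),
                           "mq": mq[contig]})
        for s in samples:
            df[f"DP:{s}"] = depth[s][contig]
        frames.append(df)
    pd.concat(frames).to_csv(path, sep="\t", index=False)


def read_pileup_tsv(path: str) -> tuple[dict[str, np.ndarray],
                                        dict[str, dict[str, np.ndarray]]]:
    df = pd.read_csv(path, sep="\t")
    samples = [c[3:] for c in df.columns if c.startswith("DP:")]
    mq: dict[str, np.ndarray] = {}
    depth: dict[str, dict[str, np.ndarray]] = {s: {} for s in samples}
    for contig, sub in df.groupby("contig", sort=False):
        sub = sub.sort_values("pos")
        if not (sub["pos"].to_numpy() == np.arange(1, len(sub) + 1)).all():
            raise FormatError(f"{path}: pileup rows for {contig} not dense")
        mq[contig] = sub["mq"].to_numpy(dtype=np.float32)
        for s in samples:
            depth[s][contig] = sub[f"DP:{s}"].to_numpy(dtype=np.int32)
    return mq, depth


# ---------------------------------------------------------------------------
# TSV tables

def read_experiment_table(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return experiment_table(df)


def read_expression_table(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"gene", "fpkm"} <= set(df.columns):
        raise FormatError(f"{path}: expression table needs columns gene, fpkm")
    return df


def read_species_table(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"species", "ne", "mu"} <= set(df.columns):
        raise FormatError(f"{path}: species table needs columns species, ne, mu")
    return df


def write_tsv(df: pd.DataFrame, path: str) -> None:
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
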