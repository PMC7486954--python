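"""Genome, gene-model and experiment-table containers.

Coordinates are stored internally as 0-based half-open intervals and
converted to 1-based inclusive (VCF/GFF convention) only at I/O
boundaries.  The conversion is loss-free and round-trip tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

NUCLEAR = "nuclear"
MITOCHONDRIAL = "mitochondrial"
CHLOROPLAST = "chloroplast"
COMPARTMENTS = (NUCLEAR, MITOCHONDRIAL, CHLOROPLAST)

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass
class GeneModel:
    """One protein-coding gene: strand, CDS/UTR intervals, derived introns.

    Intervals are 0-based half-open tuples in genomic order on the
    contig, regardless of strand.  The CDS total length must be a
    multiple of 3 (enforced by :meth:`validate`).
    """

    gene_id: str
    contig: str
    strand: str  # '+' or '-'
    cds: list[tuple[int, int]]
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)

    @property
    def exons(self) -> list[tuple[int, int]]:
        """Exon intervals: union of UTRs and CDS, merged when adjacent."""
        parts = sorted(self.utr5 + self.cds + self.utr3)
        merged: list[tuple[int, int]] = []
        for s, e in parts:
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(e, merged[-1][1]))
            else:
                merged.append((s, e))
        return merged

    @property
    def introns(self) -> list[tuple[int, int]]:
        ex = self.exons
        return [(ex[i][1], ex[i + 1][0]) for i in range(len(ex) - 1)]

    @property
    def span(self) -> tuple[int, int]:
        ex = self.exons
        return ex[0][0], ex[-1][1]

    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    def validate(self, contig_length: int | None = None) -> None:
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        if self.cds_length() % 3 != 0:
            raise ValueError(
                f"gene {self.gene_id}: CDS length {self.cds_length()} not divisible by 3"
            )
        parts = sorted(self.utr5 + self.cds + self.utr3)
        for (s1, e1), (s2, e2) in zip(parts, parts[1:]):
            if s2 < e1:
                raise ValueError(f"gene {self.gene_id}: overlapping intervals")
        for s, e in parts:
            if s < 0 or (contig_length is not None and e > contig_length):
                raise ValueError(f"gene {self.gene_id}: interval ({s},{e}) out of bounds")

    def cds_sequence(self, contig_seq: str) -> str:
        """Spliced CDS on the coding strand, start codon first."""
        s = "".join(contig_seq[a:b] for a, b in sorted(self.cds))
        return revcomp(s) if self.strand == "-" else s


@dataclass
class Genome:
    """Contig sequences with compartment labels and gene annotation."""

    sequences: dict[str, str]
    compartments: dict[str, str] = field(default_factory=dict)
    genes: list[GeneModel] = field(default_factory=list)

    def __post_init__(self) -> None:
        for contig in self.sequences:
            self.compartments.setdefault(contig, NUCLEAR)

    @property
    def size(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def cds_size(self) -> int:
        return sum(g.cds_length() for g in self.genes)

    def gc_fraction(self, compartment: str | None = None) -> float:
        gc = at = 0
        for contig, seq in self.sequences.items():
            if compartment and self.compartments[contig] != compartment:
                continue
            gc += seq.count("G") + seq.count("C")
            at += seq.count("A") + seq.count("T")
        if gc + at == 0:
            raise ValueError("no unambiguous bases")
        return gc / (gc + at)

    def base_at(self, contig: str, pos0: int) -> str:
        return self.sequences[contig][pos0]

    def context(self, contig: str, pos0: int) -> str:
        """Trinucleotide context centred on pos0; N-padded at contig ends."""
        seq = self.sequences[contig]
        left = seq[pos0 - 1] if pos0 > 0 else "N"
        right = seq[pos0 + 1] if pos0 + 1 < len(seq) else "N"
        return left + seq[pos0] + right

    def is_cpg(self, contig: str, pos0: int) -> bool:
        """True if pos0 is the C of a CG dinucleotide on either strand.

        On the forward strand that is C followed by G; on the reverse
        strand the C of a CG corresponds to a forward-strand G preceded
        by C - i.e. either strand, the site sits inside a CG dinucleotide.
        """
        seq = self.sequences[contig]
        b = seq[pos0]
        if b == "C":
            return pos0 + 1 < len(seq) and seq[pos0 + 1] == "G"
        if b == "G":
            return pos0 > 0 and seq[pos0 - 1] == "C"
        return False

    def validate(self) -> None:
        for g in self.genes:
            if g.contig not in self.sequences:
                raise ValueError(f"gene {g.gene_id}: unknown contig {g.contig}")
            g.validate(len(self.sequences[g.contig]))


EXPERIMENT_COLUMNS = ["line", "generations", "callable_sites", "mutations"]


def experiment_table(rows: list[tuple[str, int, int, int]] | pd.DataFrame,
                     genome_size: int | None = None) -> pd.DataFrame:
    """Build and validate the per-line experiment table.

    Columns: line id, generations (>0), callable sites (>0), observed
    de novo substitution count (>=0).
    """
    if isinstance(rows, pd.DataFrame):
        df = rows.copy()
    else:
        df = pd.DataFrame(rows, columns=EXPERIMENT_COLUMNS)
    missing = set(EXPERIMENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"experiment table missing columns: {sorted(missing)}")
    if df["line"].duplicated().any():
        raise ValueError("duplicate line ids in experiment table")
    if (df["generations"] <= 0).any():
        raise ValueError("generations must be positive")
    if (df["callable_sites"] <= 0).any():
        raise ValueError("callable sites must be positive")
    if (df["mutations"] < 0).any():
        raise ValueError("mutation counts must be non-negative")
    if genome_size is not None and (df["callable_sites"] > genome_size).any():
        raise ValueError("callable sites exceed genome size")
    return df.reset_index(drop=True)
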