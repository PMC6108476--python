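"""Readers/writers for the standard formats the pipeline touches, plus shared types.

All coordinates inside the package are 0-based half-open on the forward
strand; strand is carried separately.  Conversions from 1-based conventions
(GTF, wig fixedStep, VCF-style SNP positions) happen only at file boundaries.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

__all__ = [
    "GenomeSequence",
    "MatureMirna",
    "GeneModel",
    "ConservationTrack",
    "SnpTable",
    "BedInterval",
    "FormatError",
    "read_fasta",
    "read_intervals",
    "read_conservation",
    "read_snps",
    "write_candidates",
    "write_fasta",
    "BIOTYPES",
]

BIOTYPES = (
    "protein_coding",
    "lincRNA",
    "circRNA",
    "antisense",
    "pseudogene",
    "processed_transcript",
    "other",
)

_RNA_ALPHABET = set("ACGU")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class GenomeSequence:
    """One chromosome/contig.  Masked positions are lowercase or N."""

    chrom_id: str
    sequence: str
    _mask: np.ndarray | None = field(default=None, repr=False, compare=False)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where the base is masked (lowercase or N/n)."""
        if self._mask is None:
            arr = np.frombuffer(self.sequence.encode("ascii"), dtype=np.uint8)
            lower = (arr >= ord("a")) & (arr <= ord("z"))
            self._mask = lower | (arr == ord("N"))
        return self._mask

    def masked_positions(self) -> set[int]:
        return set(np.flatnonzero(self.mask).tolist())

    def subseq(self, start: int, end: int) -> str:
        if not (0 <= start < end <= self.length):
            raise IndexError(f"interval [{start},{end}) out of range for {self.chrom_id}")
        return self.sequence[start:end]


@dataclass
class MatureMirna:
    """A mature miRNA query, RNA alphabet, 5'->3'."""

    mirna_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"{self.mirna_id}: empty miRNA sequence")
        bad = set(self.sequence) - _RNA_ALPHABET
        if bad:
            raise FormatError(f"{self.mirna_id}: non-RNA characters {sorted(bad)}")
        if len(self.sequence) < 8:
            raise FormatError(f"{self.mirna_id}: shorter than the 8-nt seed region")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GeneModel:
    gene_id: str
    biotype: str
    source: str  # "gencode" or "circbase"
    chrom: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise FormatError(f"{self.gene_id}: strand must be + or -, got {self.strand!r}")
        if self.start >= self.end:
            raise FormatError(f"{self.gene_id}: start >= end")
        self.exons = sorted(self.exons)
        for s, e in self.exons:
            if s < self.start or e > self.end or s >= e:
                raise FormatError(f"{self.gene_id}: exon [{s},{e}) outside span or empty")
        if self.biotype not in BIOTYPES:
            self.biotype = "other"

    @property
    def span_length(self) -> int:
        return self.end - self.start


@dataclass
class BedInterval:
    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    strand: str = "."


class ConservationTrack:
    """Sparse per-base conservation scores; missing positions are no-data (None)."""

    def __init__(self) -> None:
        self._scores: dict[str, dict[int, float]] = {}

    def set_score(self, chrom: str, pos: int, score: float) -> None:
        d = self._scores.setdefault(chrom, {})
        if pos in d and d[pos] != score:
            raise FormatError(
                f"conflicting conservation scores at {chrom}:{pos} ({d[pos]} vs {score})"
            )
        d[pos] = score

    def score(self, chrom: str, pos: int) -> float | None:
        return self._scores.get(chrom, {}).get(pos)

    def scores(self, chrom: str, start: int, end: int) -> list[float | None]:
        d = self._scores.get(chrom, {})
        return [d.get(p) for p in range(start, end)]

    def __len__(self) -> int:
        return sum(len(d) for d in self._scores.values())


class SnpTable:
    """Set of (chrom, 0-based position) SNP records."""

    def __init__(self) -> None:
        self._pos: dict[str, set[int]] = {}

    def add(self, chrom: str, pos: int) -> None:
        self._pos.setdefault(chrom, set()).add(int(pos))

    def count(self, chrom: str, start: int, end: int) -> int:
        s = self._pos.get(chrom)
        if not s:
            return 0
        return sum(1 for p in s if start <= p < end)

    def __len__(self) -> int:
        return sum(len(s) for s in self._pos.values())

    def __contains__(self, item: tuple[str, int]) -> bool:
        chrom, pos = item
        return pos in self._pos.get(chrom, set())


# ---------------------------------------------------------------------------
# readers


def read_fasta(path, rna: bool = False):
    """Parse FASTA into ``{id: GenomeSequence}`` (or ``{id: MatureMirna}`` if rna).

    Sequence case is preserved for genomes (it encodes masking).  With
    ``rna=True``, T is transcribed to U and records are uppercased.
    """
    # pre-scan for empty records so errors can name a line number
    with open(path) as fh:
        header_line = None
        has_seq = False
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if line.startswith(">"):
                if header_line is not None and not has_seq:
                    raise FormatError(f"{path}: empty sequence for header at line {header_line}")
                if line == ">":
                    raise FormatError(f"{path}: malformed (empty) header at line {lineno}")
                header_line = lineno
                has_seq = False
            elif line:
                if header_line is None:
                    raise FormatError(f"{path}: sequence before any header at line {lineno}")
                has_seq = True
        if header_line is not None and not has_seq:
            raise FormatError(f"{path}: empty sequence for header at line {header_line}")

    out: dict = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if rna:
            out[rec.id] = MatureMirna(rec.id, seq.upper().replace("T", "U"))
        else:
            out[rec.id] = GenomeSequence(rec.id, seq)
    return out


def write_fasta(records, path, width: int = 70) -> None:
    """Write GenomeSequence/MatureMirna records as FASTA, preserving case."""
    with open(path, "w") as fh:
        for rec in records:
            name = getattr(rec, "chrom_id", None) or getattr(rec, "mirna_id")
            fh.write(f">{name}\n")
            seq = rec.sequence
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _parse_gtf_attributes(attr: str) -> dict[str, str]:
    out = {}
    for chunk in attr.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if " " in chunk:
            key, _, val = chunk.partition(" ")
            out[key] = val.strip().strip('"')
    return out


def read_intervals(path, dialect: str):
    """Read gene models (``dialect="gtf"``) or raw intervals (``dialect="bed"``)."""
    if dialect == "bed":
        out = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                f = line.split("\t")
                if len(f) < 3:
                    raise FormatError(f"{path}:{lineno}: BED line with < 3 fields")
                start, end = int(f[1]), int(f[2])
                if start >= end:
                    raise FormatError(f"{path}:{lineno}: start >= end")
                strand = f[5] if len(f) > 5 else "."
                if strand not in "+-.":
                    raise FormatError(f"{path}:{lineno}: unknown strand {strand!r}")
                out.append(
                    BedInterval(
                        f[0],
                        start,
                        end,
                        f[3] if len(f) > 3 else ".",
                        float(f[4]) if len(f) > 4 else 0.0,
                        strand,
                    )
                )
        return out

    if dialect != "gtf":
        raise ValueError(f"unknown dialect {dialect!r}")

    genes: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 9:
                raise FormatError(f"{path}:{lineno}: GTF line with < 9 fields")
            chrom, source, feature, start1, end1, _score, strand, _frame, attrs = f[:9]
            start, end = int(start1) - 1, int(end1)  # GTF 1-based inclusive -> half-open
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start >= end after conversion")
            if strand not in "+-":
                raise FormatError(f"{path}:{lineno}: unknown strand {strand!r}")
            a = _parse_gtf_attributes(attrs)
            gid = a.get("gene_id", f"gene_{lineno}")
            g = genes.setdefault(
                gid,
                {
                    "chrom": chrom,
                    "strand": strand,
                    "start": start,
                    "end": end,
                    "biotype": a.get("gene_biotype", a.get("gene_type", "other")),
                    "source": "circbase" if "circbase" in source.lower() else "gencode",
                    "exons": [],
                    "utr5": [],
                    "utr3": [],
                },
            )
            g["start"] = min(g["start"], start)
            g["end"] = max(g["end"], end)
            if feature == "exon":
                g["exons"].append((start, end))
            elif feature.lower() in ("five_prime_utr", "5utr", "utr5"):
                g["utr5"].append((start, end))
            elif feature.lower() in ("three_prime_utr", "3utr", "utr3"):
                g["utr3"].append((start, end))

    out = []
    for gid, g in genes.items():
        biotype = g["biotype"]
        if g["source"] == "circbase":
            biotype = "circRNA"
        out.append(
            GeneModel(
                gene_id=gid,
                biotype=biotype,
                source=g["source"],
                chrom=g["chrom"],
                strand=g["strand"],
                start=g["start"],
                end=g["end"],
                exons=g["exons"],
                utr5=g["utr5"],
                utr3=g["utr3"],
            )
        )
    return out


def read_conservation(path, dialect: str) -> ConservationTrack:
    """Read a phyloP-like per-base track from fixedStep wig or bedGraph."""
    track = ConservationTrack()
    if dialect == "fixedStep_wig":
        chrom, pos, step = None, None, 1
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith(("#", "track")):
                    continue
                if line.startswith("fixedStep"):
                    kv = dict(tok.split("=") for tok in line.split()[1:])
                    chrom = kv["chrom"]
                    pos = int(kv["start"]) - 1  # wig is 1-based
                    step = int(kv.get("step", 1))
                else:
                    if chrom is None:
                        raise FormatError(f"{path}:{lineno}: value before fixedStep header")
                    track.set_score(chrom, pos, float(line))
                    pos += step
    elif dialect == "bedGraph":
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith(("#", "track")):
                    continue
                f = line.split("\t")
                if len(f) < 4:
                    raise FormatError(f"{path}:{lineno}: bedGraph line with < 4 fields")
                chrom, start, end, score = f[0], int(f[1]), int(f[2]), float(f[3])
                for p in range(start, end):
                    track.set_score(chrom, p, score)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return track


def read_snps(path, one_based: bool = False) -> SnpTable:
    """Read a chrom<TAB>position SNP table; duplicates collapse."""
    table = SnpTable()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 2:
                raise FormatError(f"{path}:{lineno}: expected chrom<TAB>position")
            try:
                pos = int(f[1])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer position {f[1]!r}") from exc
            table.add(f[0], pos - 1 if one_based else pos)
    return table


# ---------------------------------------------------------------------------
# candidate output

CANDIDATE_COLUMNS = [
    "mirna_id",
    "cluster_size",
    "cutoff",
    "chrom",
    "start",
    "end",
    "strand",
    "annotation",
    "biotype",
    "fbse",
    "sdr",
    "entropy",
    "conserved_fraction",
]


def write_candidates(candidates, path, format: str = "tsv") -> None:
    """Write sponge candidates as TSV (full columns) or BED6 (cluster spans)."""
    if format == "tsv":
        with open(path, "w") as fh:
            fh.write("\t".join(CANDIDATE_COLUMNS) + "\n")
            for c in candidates:
                fh.write("\t".join(str(v) for v in c.as_row()) + "\n")
    elif format == "bed":
        with open(path, "w") as fh:
            for c in candidates:
                cl = c.cluster
                fh.write(
                    f"{cl.chrom}\t{cl.start}\t{cl.end}\t{c.mirna_id}\t{cl.size}\t{cl.strand}\n"
                )
    else:
        raise ValueError(f"unknown format {format!r}")


def read_candidates_tsv(path):
    """Re-parse a candidate TSV into a list of plain dict rows (round-trip aid)."""
    import csv

    with open(path) as fh:
        return list(csv.DictReader(fh, delimiter="\t"))
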