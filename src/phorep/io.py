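"""Readers and writers for the external formats and the shared data model.

Sequences travel as :class:`SequenceRecord`, gene coordinates as
:class:`GeneModel` (1-based inclusive, reverse-strand rows may list
start > end), and count/weight matrices as :class:`MatrixFile` in one of
three dialects (TRANSFAC-like, MEME minimal, or a plain symbol-per-line
table).
"""

from __future__ import annotations

import io as _io
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

from .constants import DNA_ALPHABET, DNA_ALPHABET_N, PROTEIN_ALPHABET, PROTEIN_ALPHABET_X


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class SequenceRecord:
    """A named protein or DNA sequence.

    Residues are upper-case; ``X`` (protein) and ``N`` (DNA) mark unknown
    positions and are accepted everywhere.
    """

    id: str
    description: str
    residues: str
    moltype: str  # "protein" | "dna"

    def __post_init__(self) -> None:
        if self.moltype not in ("protein", "dna"):
            raise ValueError(f"unknown moltype {self.moltype!r}")
        if not self.residues:
            raise ValueError(f"record {self.id!r}: empty sequence")
        alphabet = PROTEIN_ALPHABET_X if self.moltype == "protein" else DNA_ALPHABET_N
        allowed = set(alphabet)
        for pos, ch in enumerate(self.residues, start=1):
            if ch not in allowed:
                raise FormatError(
                    f"record {self.id!r}: illegal {self.moltype} residue "
                    f"{ch!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.residues)

    def reverse_complement(self) -> "SequenceRecord":
        if self.moltype != "dna":
            raise ValueError("reverse_complement requires a DNA record")
        rc = str(Seq(self.residues).reverse_complement())
        return SequenceRecord(self.id, self.description, rc, "dna")


@dataclass
class GeneModel:
    """One CDS row of a gene coordinate table.

    Coordinates are 1-based inclusive. Strand is ``D`` (direct) or ``R``
    (reverse); reverse-strand rows may be listed with start > end and are
    normalized on access via :attr:`left`/:attr:`right`.
    """

    locus_tag: str
    strand: str  # "D" | "R"
    start: int
    end: int
    product_id: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("D", "R"):
            raise ValueError(f"{self.locus_tag}: strand must be D or R, got {self.strand!r}")
        if min(self.start, self.end) < 1:
            raise ValueError(f"{self.locus_tag}: coordinates must be >= 1")

    @property
    def left(self) -> int:
        return min(self.start, self.end)

    @property
    def right(self) -> int:
        return max(self.start, self.end)

    @property
    def span(self) -> int:
        """Genomic footprint in bp (inclusive)."""
        return self.right - self.left + 1

    @property
    def protein_length(self) -> int:
        """Encoded protein length in aa, excluding the stop codon."""
        if self.span % 3 != 0:
            raise ValueError(f"{self.locus_tag}: span {self.span} not divisible by 3")
        return self.span // 3 - 1


@dataclass
class MatrixFile:
    """A count or weight matrix over an ordered alphabet.

    ``counts`` has shape (positions, len(alphabet)); the alphabet is
    normalized to ACGT for DNA and the fixed 20-aa order for protein.
    """

    accession: str
    alphabet: str
    counts: np.ndarray
    dialect: str  # "transfac" | "meme" | "plain"
    nsites: int | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[1] != len(self.alphabet):
            raise FormatError(
                f"matrix {self.accession!r}: shape {self.counts.shape} does not "
                f"match alphabet of length {len(self.alphabet)}"
            )
        if (self.counts < 0).any():
            raise FormatError(f"matrix {self.accession!r}: negative counts")

    @property
    def length(self) -> int:
        return self.counts.shape[0]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def parse_sequences(text: str, moltype: str) -> list[SequenceRecord]:
    """Parse FASTA text into records, preserving order.

    Whitespace inside sequence lines is stripped; residues are upper-cased.
    Empty input yields an empty list; an illegal residue raises
    :class:`FormatError` naming the record and position.
    """
    if not text.strip():
        return []
    records = []
    for rec in SeqIO.parse(_io.StringIO(text), "fasta"):
        residues = re.sub(r"\s", "", str(rec.seq)).upper()
        description = rec.description[len(rec.id):].strip()
        records.append(SequenceRecord(rec.id, description, residues, moltype))
    return records


def write_sequences(records: list[SequenceRecord], width: int = 60) -> str:
    """Serialize records as FASTA text (inverse of :func:`parse_sequences`)."""
    handle = _io.StringIO()
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
    writer.write_file(bio)
    return handle.getvalue()


# ---------------------------------------------------------------------------
# Gene coordinate tables
# ---------------------------------------------------------------------------

_GENE_COLUMNS = ("locus_tag", "strand", "start", "end")


def parse_gene_table(text: str) -> list[GeneModel]:
    """Parse a tab-separated gene coordinate table.

    The header must name ``locus_tag``, ``strand``, ``start`` and ``end``
    (an optional ``product_id`` column is carried through). Non-integer
    coordinates raise :class:`FormatError` with the offending row number.
    """
    df = pd.read_csv(_io.StringIO(text), sep="\t", dtype=str)
    missing = [c for c in _GENE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"gene table missing columns: {', '.join(missing)}")
    genes = []
    for i, row in df.iterrows():
        try:
            start, end = int(row["start"]), int(row["end"])
        except (TypeError, ValueError):
            raise FormatError(
                f"gene table row {i + 1}: non-integer coordinate "
                f"({row['start']!r}, {row['end']!r})"
            ) from None
        product = row.get("product_id")
        if product is not None and pd.isna(product):
            product = None
        genes.append(GeneModel(str(row["locus_tag"]), str(row["strand"]), start, end, product))
    return genes


def write_gene_table(genes: list[GeneModel]) -> str:
    rows = [
        {
            "locus_tag": g.locus_tag, "strand": g.strand,
            "start": g.start, "end": g.end,
            "product_id": g.product_id if g.product_id is not None else "",
        }
        for g in genes
    ]
    df = pd.DataFrame(rows, columns=list(_GENE_COLUMNS) + ["product_id"])
    return df.to_csv(sep="\t", index=False)


# ---------------------------------------------------------------------------
# Matrices
# ---------------------------------------------------------------------------

def _normalize_alphabet(symbols: list[str], counts: np.ndarray) -> tuple[str, np.ndarray]:
    symbols = [s.upper() for s in symbols]
    key = "".join(sorted(symbols))
    if key == "".join(sorted(DNA_ALPHABET)):
        target = DNA_ALPHABET
    elif key == "".join(sorted(PROTEIN_ALPHABET)):
        target = PROTEIN_ALPHABET
    else:
        return "".join(symbols), counts
    order = [symbols.index(s) for s in target]
    return target, counts[:, order]


def _parse_plain(text: str, accession: str) -> MatrixFile:
    symbols, rows = [], []
    for line in text.strip().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        m = re.match(r"^(\w)\s*[:|]?\s*(.*)$", line)
        if not m:
            raise FormatError(f"plain matrix: cannot parse line {line!r}")
        symbols.append(m.group(1))
        rows.append([float(v) for v in m.group(2).split()])
    if not rows:
        raise FormatError("plain matrix: no rows")
    if len({len(r) for r in rows}) != 1:
        raise FormatError("plain matrix: ragged rows")
    counts = np.array(rows, dtype=float).T  # rows are symbols -> transpose
    alphabet, counts = _normalize_alphabet(symbols, counts)
    return MatrixFile(accession, alphabet, counts, "plain")


def _parse_transfac(text: str, accession: str) -> MatrixFile:
    name = accession
    symbols: list[str] = []
    rows: list[list[float]] = []
    for line in text.splitlines():
        line = line.rstrip()
        if not line:
            continue
        tag = line[:2].upper()
        if tag in ("AC", "ID", "NA") and len(line) > 2:
            name = line[2:].strip() or name
        elif tag in ("P0", "PO"):
            symbols = line.split()[1:]
        elif re.match(r"^\d+\s", line):
            fields = line.split()
            vals = fields[1:1 + len(symbols)] if symbols else fields[1:]
            try:
                rows.append([float(v) for v in vals])
            except ValueError:
                raise FormatError(f"TRANSFAC matrix: bad count line {line!r}") from None
    if not symbols or not rows:
        raise FormatError("TRANSFAC matrix: missing P0 header or count rows")
    if any(len(r) != len(symbols) for r in rows):
        raise FormatError("TRANSFAC matrix: ragged rows")
    alphabet, counts = _normalize_alphabet(symbols, np.array(rows))
    return MatrixFile(name, alphabet, counts, "transfac")


def _parse_meme(text: str, accession: str) -> MatrixFile:
    name = accession
    alphabet = DNA_ALPHABET
    m = re.search(r"^ALPHABET\s*=\s*(\S+)", text, re.M)
    if m:
        alphabet = m.group(1).upper()
    m = re.search(r"^MOTIF\s+(\S+)", text, re.M)
    if m:
        name = m.group(1)
    m = re.search(
        r"letter-probability matrix:[^\n]*?w=\s*(\d+)[^\n]*?nsites=\s*(\d+)[^\n]*\n"
        r"((?:\s*[\d.eE+-]+[^\n]*\n?)+)",
        text,
    )
    if not m:
        raise FormatError("MEME matrix: no letter-probability block")
    width, nsites = int(m.group(1)), int(m.group(2))
    rows = [[float(v) for v in line.split()] for line in m.group(3).strip().splitlines()]
    if len(rows) != width:
        raise FormatError(f"MEME matrix: expected {width} rows, got {len(rows)}")
    if any(len(r) != len(alphabet) for r in rows):
        raise FormatError("MEME matrix: ragged rows")
    probs = np.array(rows)
    counts = np.rint(probs * nsites)
    alphabet, counts = _normalize_alphabet(list(alphabet), counts)
    return MatrixFile(name, alphabet, counts, "meme", nsites=nsites)


_DIALECTS = {"plain": _parse_plain, "transfac": _parse_transfac, "meme": _parse_meme}


def parse_matrix(text: str, dialect: str, accession: str = "matrix") -> MatrixFile:
    """Parse one count matrix in the given dialect.

    MEME probability matrices are converted back to counts via the stated
    ``nsites``; counts in the other dialects are preserved exactly.
    """
    try:
        parser = _DIALECTS[dialect]
    except KeyError:
        raise ValueError(f"unknown matrix dialect {dialect!r}") from None
    return parser(text, accession)


def parse_matrices(text: str, dialect: str) -> list[MatrixFile]:
    """Parse a multi-matrix TRANSFAC file (records separated by ``//``)."""
    if dialect != "transfac":
        return [parse_matrix(text, dialect)]
    return [
        _parse_transfac(block, "matrix")
        for block in re.split(r"^//\s*$", text, flags=re.M)
        if block.strip()
    ]
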