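"""Sequence and locus-table input/output.

Nucleotide sequences are held as plain uppercase strings over ``{A,C,G,T,N}``
(``U`` is mapped to ``T`` on input); gapped alignment rows additionally allow
``-``.  Proviral loci follow the cytoband-table convention
``name | chrom:start-end (strand)`` with 1-based, fully inclusive coordinates,
so ``length = end - start + 1``.

FASTA reading/writing is delegated to Biopython; this module adds the strict
alphabet validation and the locus-table conventions used by the rest of the
package.
"""
from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import CoordinateError, FastaFormatError, InputError

NUC_ALPHABET = frozenset("ACGTN")
GAP = "-"
GAPPED_ALPHABET = NUC_ALPHABET | {GAP}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# En dash, em dash and true minus all appear in printed coordinate tables.
_DASHES = "–—−"
_COORD_RE = re.compile(
    r"^\s*(?P<chrom>[^:\s]+)\s*:\s*(?P<start>[\d,]+)\s*[-" + _DASHES + r"]\s*"
    r"(?P<end>[\d,]+)\s*(?:\(\s*(?P<strand>[+\-" + _DASHES + r"])\s*\))?\s*$"
)


def normalize_residues(raw: str, *, allow_gaps: bool = False) -> str:
    """Uppercase, map U->T and validate against the nucleotide alphabet."""
    residues = raw.upper().replace("U", "T")
    allowed = GAPPED_ALPHABET if allow_gaps else NUC_ALPHABET
    bad = set(residues) - allowed
    if bad:
        raise FastaFormatError(
            f"illegal residue(s) {sorted(bad)!r} (allowed: {sorted(allowed)})"
        )
    if not residues:
        raise FastaFormatError("empty sequence")
    return residues


@dataclass(frozen=True)
class NucSequence:
    """An ungapped nucleotide sequence over {A,C,G,T,N}."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self):
        object.__setattr__(self, "residues", normalize_residues(self.residues))

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class GappedSequence:
    """One row of a multiple alignment; gap character is ``-``."""

    id: str
    residues: str

    def __post_init__(self):
        object.__setattr__(
            self, "residues", normalize_residues(self.residues, allow_gaps=True)
        )

    def __len__(self) -> int:
        return len(self.residues)

    def ungapped(self) -> str:
        return self.residues.replace(GAP, "")


@dataclass
class MultipleAlignment:
    """An ordered set of equal-length gapped rows (>= 2 members)."""

    members: list[GappedSequence]

    def __post_init__(self):
        if len(self.members) < 2:
            raise InputError("an alignment needs at least 2 members")
        lengths = {len(m) for m in self.members}
        if len(lengths) != 1:
            raise InputError(f"unequal alignment row lengths: {sorted(lengths)}")

    @property
    def length(self) -> int:
        return len(self.members[0])

    @property
    def ids(self) -> list[str]:
        return [m.id for m in self.members]

    def member(self, seq_id: str) -> GappedSequence:
        for m in self.members:
            if m.id == seq_id:
                return m
        raise KeyError(seq_id)

    def to_matrix(self) -> np.ndarray:
        """Encode as an int8 matrix: A,C,G,T -> 0..3, N -> 4, gap -> 5."""
        lut = np.full(128, -1, dtype=np.int8)
        for i, c in enumerate("ACGTN-"):
            lut[ord(c)] = i
        rows = [
            lut[np.frombuffer(m.residues.encode(), dtype=np.uint8)]
            for m in self.members
        ]
        return np.vstack(rows)


def _first_line_number_failing(path: Path) -> tuple[int, str]:
    """Locate the first offending line for a FASTA format error report."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith(">"):
                continue
            bad = set(stripped.upper().replace("U", "T")) - GAPPED_ALPHABET
            if bad:
                return lineno, f"illegal residue(s) {sorted(bad)!r}"
    return 1, "no FASTA records found"


def read_fasta(path, *, allow_gaps: bool = False) -> list[NucSequence]:
    """Read a FASTA file into :class:`NucSequence` records.

    Raises :class:`FastaFormatError` (naming a line number) on empty files,
    files whose first record is malformed, or illegal residues.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        lineno, why = _first_line_number_failing(path)
        raise FastaFormatError(f"{path}:{lineno}: {why}")
    out = []
    for rec in records:
        try:
            if allow_gaps:
                out.append(GappedSequence(rec.id, str(rec.seq)))
            else:
                out.append(NucSequence(rec.id, str(rec.seq), rec.description))
        except FastaFormatError as exc:
            lineno, _ = _first_line_number_failing(path)
            raise FastaFormatError(f"{path}:{lineno}: record {rec.id!r}: {exc}")
    return out


def read_alignment(path) -> MultipleAlignment:
    """Read an aligned (gapped) FASTA file."""
    return MultipleAlignment(read_fasta(path, allow_gaps=True))


def write_fasta(seqs: Iterable[NucSequence | GappedSequence], path, wrap: int = 60):
    """Write sequences as FASTA, wrapping residues at ``wrap`` columns."""
    records = []
    for s in seqs:
        desc = getattr(s, "description", "") or ""
        records.append(SeqRecord(Seq(s.residues), id=s.id, description=desc))
    path = Path(path)
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
        writer.write_file(records)
    return path


def write_alignment(msa: MultipleAlignment, path, wrap: int = 60):
    return write_fasta(msa.members, path, wrap=wrap)


def reverse_complement(seq: str | NucSequence) -> str:
    residues = seq.residues if isinstance(seq, NucSequence) else seq
    return residues.translate(_COMPLEMENT)[::-1]


def locus_length(start: int, end: int) -> int:
    """Length of a 1-based, fully inclusive interval."""
    if end < start:
        raise CoordinateError(f"end ({end}) < start ({start})")
    return end - start + 1


@dataclass(frozen=True)
class ProviralLocus:
    """A named proviral genomic interval (1-based inclusive, strand metadata)."""

    name: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    context: str = "intergenic"

    def __post_init__(self):
        if self.end < self.start:
            raise CoordinateError(
                f"{self.name}: end ({self.end}) < start ({self.start})"
            )
        if self.strand not in "+-":
            raise CoordinateError(f"{self.name}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return locus_length(self.start, self.end)


def parse_locus_row(text_row: str) -> ProviralLocus:
    """Parse ``name | chrom:start-end (strand) [| context]`` into a locus.

    Thousands separators are stripped, en dash and hyphen are both accepted,
    and the strand defaults to ``+`` when absent.
    """
    parts = [p.strip() for p in text_row.split("|")]
    if len(parts) < 2:
        raise FastaFormatError(f"locus row needs 'name | coordinates': {text_row!r}")
    name, coords = parts[0], parts[1]
    context = parts[2] if len(parts) > 2 and parts[2] else "intergenic"
    m = _COORD_RE.match(coords)
    if m is None:
        raise FastaFormatError(f"unparseable coordinates {coords!r}")
    start = int(m.group("start").replace(",", ""))
    end = int(m.group("end").replace(",", ""))
    strand = m.group("strand") or "+"
    if strand in _DASHES:
        strand = "-"
    return ProviralLocus(name, m.group("chrom"), start, end, strand, context)


LOCUS_TABLE_COLUMNS = ["name", "chrom", "start", "end", "strand", "context"]


def read_locus_table(path) -> list[ProviralLocus]:
    """Read a TSV locus table with header ``name chrom start end strand context``."""
    import pandas as pd

    frame = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(LOCUS_TABLE_COLUMNS[:4]) - set(frame.columns)
    if missing:
        raise InputError(f"locus table missing columns: {sorted(missing)}")
    loci = []
    for row in frame.itertuples(index=False):
        loci.append(
            ProviralLocus(
                name=str(row.name),
                chrom=str(row.chrom),
                start=int(row.start),
                end=int(row.end),
                strand=str(getattr(row, "strand", "+") or "+"),
                context=str(getattr(row, "context", "intergenic") or "intergenic"),
            )
        )
    return loci


def write_locus_table(loci: Sequence[ProviralLocus], path):
    import pandas as pd

    frame = pd.DataFrame(
        [
            {
                "name": l.name,
                "chrom": l.chrom,
                "start": l.start,
                "end": l.end,
                "strand": l.strand,
                "context": l.context,
            }
            for l in loci
        ],
        columns=LOCUS_TABLE_COLUMNS,
    )
    frame.to_csv(path, sep="\t", index=False)
    return path
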