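"""Sequence-feature detection for proviral loci.

Covers the structural features that characterise Betaretrovirus-like
proviruses: the primer binding site (PBS) with tRNA assignment against a
pluggable library, the Pro G-patch / Pro dUTPase / Gag NC zinc-finger protein
motifs, LTR regulatory motifs (TATA box, SV40 enhancer, polyadenylation
signal), A/T-rich inter-genic stretches, nucleotide-composition bias, ORF
integrity (premature stops and frameshifts against a reference coding
sequence) and the type I / type II subtype call based on the pol-3'/env-5'
window.

All provirus coordinates are 1-based and inclusive, on the group reference
frame: 5'LTR 1-548, PBS 552-569, gag 698-1314, pol 1316-3786, env 3801-5780,
PPT 5786-5798, 3'LTR 5811-6358.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .errors import InputError
from .seqio import GAP, NucSequence

# Reference feature frame (1-based inclusive).
REFERENCE_LENGTH = 6358
REFERENCE_FEATURES: dict[str, tuple[int, int]] = {
    "5LTR": (1, 548),
    "PBS": (552, 569),
    "gag": (698, 1314),
    "pol": (1316, 3786),
    "env": (3801, 5780),
    "PPT": (5786, 5798),
    "3LTR": (5811, 6358),
    "TATA_5": (30, 35),
    "SV40_5": (65, 72),
    "PolyA_5": (384, 389),
    "TATA_3": (5840, 5845),
    "SV40_3": (5875, 5882),
    "PolyA_3": (6194, 6199),
}

# pol-3'/env-5' window discriminating subtype I (A/T-rich) from subtype II
# (Rec-coding) proviruses, on the reference frame.
SUBTYPE_WINDOW = (3159, 4130)

REGULATORY_MOTIFS = {"TATA": "TATAAA", "SV40": "GTGGAAAG", "PolyA": "AATAAA"}

STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass
class AnnotatedProvirus:
    """A provirus sequence plus feature intervals on its own coordinates."""

    sequence: NucSequence
    features: dict[str, tuple[int, int]] = field(default_factory=dict)
    subtype: str = "unassigned"

    def __post_init__(self):
        n = len(self.sequence)
        for label, (start, end) in self.features.items():
            if not (1 <= start <= end <= n):
                raise InputError(
                    f"feature {label} interval ({start},{end}) outside 1..{n}"
                )

    def feature_seq(self, label: str) -> str:
        start, end = self.features[label]
        return self.sequence.residues[start - 1 : end]


@dataclass(frozen=True)
class PBSRecord:
    sequence: str
    offset_from_ltr_end: int
    length: int
    assigned_trna: str
    identity_percent: float
    indel: bool = False


@dataclass(frozen=True)
class MotifHit:
    motif_name: str
    pattern: str
    frame: int | str
    start: int
    end: int
    matched_text: str


@dataclass(frozen=True)
class OrfIntegrityReport:
    putein_length_aa: int
    internal_stops: tuple[int, ...]
    frameshifts: tuple[int, ...]

    @property
    def intact(self) -> bool:
        return not self.internal_stops and not self.frameshifts


@dataclass(frozen=True)
class ATRichInterval:
    start: int
    end: int
    at_fraction: float

    @property
    def length(self) -> int:
        return self.end - self.start + 1


# ---------------------------------------------------------------------------
# protein motif patterns
# ---------------------------------------------------------------------------

# x = any residue except a stop; fixed counts as written; the G-patch GxnG run
# is bounded (an unbounded run would make the pattern degenerate).
_X = None  # sentinel token: any non-stop residue


def _fixed_tokens(pattern: str) -> list:
    """Expand a pattern such as ``DSDYxGEIQ`` into match tokens."""
    return [_X if c == "x" else c for c in pattern]


_DUTPASE = _fixed_tokens("DSDYxGEIQ")
_ZINC = _fixed_tokens("CxxCxxxxHxxxxC")
_GPATCH_HEAD = _fixed_tokens("GYxxGxGLGxxxxG")  # then x{n} then G

PATTERN_STRINGS = {
    "dutpase": "DSDYxGEIQ",
    "gag_zinc_finger": "CX2CX4HX4C",
    "g_patch": "GYx2GxGLGx4GxnG",
}


def _match_fixed(seq: str, pos: int, tokens: list) -> bool:
    if pos + len(tokens) > len(seq):
        return False
    for off, tok in enumerate(tokens):
        c = seq[pos + off]
        if c == "*":
            return False
        if tok is not _X and c != tok:
            return False
    return True


def _scan_one(seq: str, name: str, g_patch_run: tuple[int, int]) -> list[tuple[int, int]]:
    """All (start, end) 0-based half-open hits of one motif, overlaps included."""
    hits = []
    if name == "dutpase":
        tokens = _DUTPASE
        for i in range(len(seq)):
            if _match_fixed(seq, i, tokens):
                hits.append((i, i + len(tokens)))
    elif name == "gag_zinc_finger":
        tokens = _ZINC
        for i in range(len(seq)):
            if _match_fixed(seq, i, tokens):
                hits.append((i, i + len(tokens)))
    elif name == "g_patch":
        lo, hi = g_patch_run
        head = _GPATCH_HEAD
        for i in range(len(seq)):
            if not _match_fixed(seq, i, head):
                continue
            run_start = i + len(head)
            for n in range(lo, hi + 1):
                j = run_start + n  # position of the closing G
                if j >= len(seq):
                    break
                run = seq[run_start:j]
                if "*" in run:
                    break
                if seq[j] == "G":
                    hits.append((i, j + 1))
    else:
        raise InputError(f"unknown motif {name!r}")
    return hits


def _looks_nucleotide(seq: str) -> bool:
    return bool(seq) and set(seq) <= set("ACGTUN")


def translate_frames(nt: str, both_strands: bool = False) -> dict[int | str, str]:
    """Translate the three forward frames (and optionally the reverse ones)."""
    from .seqio import reverse_complement

    nt = nt.upper().replace("U", "T")
    frames: dict[int | str, str] = {}
    for f in range(3):
        sub = nt[f:]
        sub = sub[: len(sub) - len(sub) % 3]
        frames[f] = str(Seq(sub).translate()) if sub else ""
    if both_strands:
        rc = reverse_complement(nt)
        for f in range(3):
            sub = rc[f:]
            sub = sub[: len(sub) - len(sub) % 3]
            frames[f"-{f}"] = str(Seq(sub).translate()) if sub else ""
    return frames


def scan_protein_motifs(
    sequence: str,
    motifs: tuple[str, ...] = ("g_patch", "dutpase", "gag_zinc_finger"),
    *,
    is_nucleotide: bool | None = None,
    both_strands: bool = False,
    g_patch_run: tuple[int, int] = (1, 15),
) -> list[MotifHit]:
    """Scan an amino-acid sequence, or all three forward frames of a
    nucleotide sequence, for the Betaretroviral protein motifs.

    ``x`` matches any residue except a stop; overlapping hits are all
    reported. Positions are 1-based within the scanned protein frame.
    """
    seq = sequence.residues if isinstance(sequence, NucSequence) else str(sequence)
    seq = seq.upper()
    if is_nucleotide is None:
        is_nucleotide = _looks_nucleotide(seq)
    if is_nucleotide:
        frames = translate_frames(seq, both_strands=both_strands)
    else:
        frames = {"n/a": seq}
    out: list[MotifHit] = []
    for frame, aa in frames.items():
        for name in motifs:
            for s, e in _scan_one(aa, name, g_patch_run):
                out.append(
                    MotifHit(
                        motif_name=name,
                        pattern=PATTERN_STRINGS[name],
                        frame=frame,
                        start=s + 1,
                        end=e,
                        matched_text=aa[s:e],
                    )
                )
    return out


# ---------------------------------------------------------------------------
# PBS detection and tRNA assignment
# ---------------------------------------------------------------------------

PBS_OFFSET_FROM_LTR = 3  # spacer between the 5'LTR end and the PBS start
PBS_CANONICAL_LENGTH = 18


def _identity_ungapped(a: str, b: str) -> int:
    return sum(x == y for x, y in zip(a, b))


def _best_single_indel(candidate: str, lib: str) -> int:
    """Best match count between a 17/19-nt candidate and an 18-nt library
    entry allowing exactly one indel in the candidate."""
    n = len(candidate)
    best = 0
    if n == len(lib) + 1:  # candidate carries an insertion: drop one base
        for d in range(n):
            best = max(best, _identity_ungapped(candidate[:d] + candidate[d + 1 :], lib))
    elif n == len(lib) - 1:  # candidate carries a deletion: drop one lib base
        for d in range(len(lib)):
            best = max(best, _identity_ungapped(candidate, lib[:d] + lib[d + 1 :]))
    else:
        raise InputError("single-indel comparison needs length 17 or 19")
    return best


def find_pbs(
    provirus,
    ltr5_end: int | None = None,
    pbs_library: list[tuple[str, str]] | None = None,
) -> PBSRecord | None:
    """Extract the PBS just downstream of the 5'LTR and assign its tRNA.

    The window starting ``PBS_OFFSET_FROM_LTR`` nt after the LTR end is
    compared at lengths 17-19 (ungapped, or with a single indel) against each
    library entry; the maximal-identity entry wins, ties going to the earlier
    (higher-ranked) library entry and to the canonical indel-free length.
    Returns ``None`` when the provirus has no 5'LTR coordinate (mirrors loci
    lacking the 5' proviral portion).
    """
    if isinstance(provirus, AnnotatedProvirus):
        if ltr5_end is None:
            ltr = provirus.features.get("5LTR")
            ltr5_end = ltr[1] if ltr else None
        seq = provirus.sequence.residues
    else:
        seq = provirus.residues if isinstance(provirus, NucSequence) else str(provirus)
    if ltr5_end is None:
        return None
    if pbs_library is None:
        from .datasets import load_pbs_library

        pbs_library = load_pbs_library()

    win0 = ltr5_end + PBS_OFFSET_FROM_LTR  # 0-based start of the PBS
    if win0 + PBS_CANONICAL_LENGTH - 1 > len(seq):
        return None

    best = None  # (identity, no_indel, -rank, record)
    for rank, (code, lib) in enumerate(pbs_library):
        for length in (18, 19, 17):
            cand = seq[win0 : win0 + length]
            if len(cand) < length:
                continue
            if length == PBS_CANONICAL_LENGTH:
                matches, indel = _identity_ungapped(cand, lib), False
            else:
                matches, indel = _best_single_indel(cand, lib), True
            identity = 100.0 * matches / len(lib)
            key = (identity, not indel, -rank)
            if best is None or key > best[0]:
                best = (
                    key,
                    PBSRecord(
                        sequence=cand,
                        offset_from_ltr_end=PBS_OFFSET_FROM_LTR,
                        length=length,
                        assigned_trna=code,
                        identity_percent=identity,
                        indel=indel,
                    ),
                )
    return best[1] if best else None


def pbs_alignment_profile(records: list[PBSRecord]) -> pd.DataFrame:
    """Logo-ready per-position symbol counts across PBS records.

    Columns are positions (1-based); each column's counts sum to the number
    of records long enough to contribute to it.
    """
    if not records:
        raise InputError("no PBS records")
    maxlen = max(r.length for r in records)
    counts = pd.DataFrame(
        0, index=list("ACGTN"), columns=range(1, maxlen + 1), dtype=int
    )
    for r in records:
        for pos, c in enumerate(r.sequence, start=1):
            counts.loc[c, pos] += 1
    return counts


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------


def find_at_rich_stretches(
    sequence,
    min_len: int = 800,
    min_at: float = 0.67,
    max_at: float = 1.0,
) -> list[ATRichInterval]:
    """Maximal runs of length >= ``min_len`` whose A+T fraction is within
    ``[min_at, max_at]``; overlapping qualifying windows are merged.

    Qualification is evaluated on sliding windows of exactly ``min_len``;
    merged runs are the unions of overlapping qualifying windows.  If a merged
    union happens to fall below ``min_at`` overall, the single best window of
    the run is reported instead, so every reported interval satisfies the
    threshold.
    """
    if min_len < 1 or not (0 < min_at <= 1):
        raise InputError("min_len >= 1 and 0 < min_at <= 1 required")
    seq = sequence.residues if isinstance(sequence, NucSequence) else str(sequence)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    is_at = ((arr == ord("A")) | (arr == ord("T"))).astype(np.int64)
    n = len(seq)
    if n < min_len:
        return []
    csum = np.concatenate([[0], np.cumsum(is_at)])
    win = (csum[min_len:] - csum[:-min_len]) / min_len  # window starting at i
    ok = np.flatnonzero((win >= min_at) & (win <= max_at))
    if ok.size == 0:
        return []

    def frac(a: int, b: int) -> float:  # 0-based half-open
        return (csum[b] - csum[a]) / (b - a)

    out: list[ATRichInterval] = []
    run_start = ok[0]
    prev = ok[0]
    starts = list(ok) + [None]
    for s in starts[1:]:
        if s is not None and s <= prev + min_len:  # windows overlap or touch
            prev = s
            continue
        a, b = run_start, prev + min_len  # merged union, 0-based half-open
        f = frac(a, b)
        if f < min_at:  # rare: union dips below threshold -> best window only
            cand = [i for i in ok if run_start <= i <= prev]
            i_best = max(cand, key=lambda i: frac(i, i + min_len))
            a, b, f = i_best, i_best + min_len, frac(i_best, i_best + min_len)
        out.append(ATRichInterval(start=a + 1, end=b, at_fraction=float(f)))
        if s is not None:
            run_start = prev = s
    return out


def nucleotide_frequencies(sequences) -> pd.DataFrame:
    """Per-base percentage composition summarised across sequences.

    ``N`` and gaps are excluded from the denominator; rows are A/C/G/T and
    columns are the across-sequence mean, min, max and (sample) SD of the
    per-sequence percentages.
    """
    rows = []
    for s in sequences:
        seq = s.residues if hasattr(s, "residues") else str(s)
        seq = seq.upper()
        counts = {b: seq.count(b) for b in "ACGT"}
        total = sum(counts.values())
        if total == 0:
            warnings.warn(f"sequence with no unambiguous bases skipped")
            continue
        rows.append({b: 100.0 * counts[b] / total for b in "ACGT"})
    if not rows:
        raise InputError("no usable sequences")
    per_seq = pd.DataFrame(rows)
    return pd.DataFrame(
        {
            "mean": per_seq.mean(),
            "min": per_seq.min(),
            "max": per_seq.max(),
            "sd": per_seq.std(ddof=1) if len(per_seq) > 1 else 0.0,
        }
    ).loc[list("ACGT")]


# ---------------------------------------------------------------------------
# ORF integrity
# ---------------------------------------------------------------------------


def assess_orf_integrity(region_nt: str, reference_cds: str) -> OrfIntegrityReport:
    """Premature-stop and frameshift assessment of a putein-coding region.

    ``region_nt`` and ``reference_cds`` are two rows of a codon-aware pairwise
    alignment (equal length; ungapped inputs of equal length are treated as an
    identity alignment).  Internal stops are reported by residue index in the
    reference frame; any gap run whose length is not a multiple of 3 is a
    frameshift at its codon position.
    """
    region = (region_nt.residues if isinstance(region_nt, NucSequence) else str(region_nt)).upper()
    ref = (reference_cds.residues if isinstance(reference_cds, NucSequence) else str(reference_cds)).upper()
    if len(region) != len(ref):
        raise InputError("region and reference rows must be aligned (equal length)")
    n_ref = len(ref.replace(GAP, ""))
    if n_ref < 3 or len(region.replace(GAP, "")) < 3:
        raise InputError("region shorter than one codon")
    n_codons = n_ref // 3

    # frameshifts: gap runs of non-multiple-of-3 length in either row
    frameshifts: list[int] = []
    i = 0
    ref_pos = 0  # reference residues consumed so far
    while i < len(ref):
        if region[i] == GAP or ref[i] == GAP:
            in_region = region[i] == GAP
            j = i
            while j < len(ref) and (region[j] == GAP if in_region else ref[j] == GAP):
                j += 1
            run = j - i
            if run % 3 != 0:
                # report the residue preceding the disrupted codon boundary
                codon = ref_pos // 3 if ref_pos % 3 == 0 else ref_pos // 3 + 1
                frameshifts.append(max(1, codon))
            if in_region:
                ref_pos += sum(1 for k in range(i, j) if ref[k] != GAP)
            i = j
        else:
            ref_pos += 1
            i += 1

    # internal stops: translate region characters at reference codon positions
    region_at_ref = [region[k] for k in range(len(ref)) if ref[k] != GAP]
    internal_stops: list[int] = []
    for c in range(n_codons):
        codon = "".join(region_at_ref[3 * c : 3 * c + 3])
        if GAP in codon or len(codon) < 3:
            continue
        if codon in STOP_CODONS and (c + 1) < n_codons:
            internal_stops.append(c + 1)

    length = (internal_stops[0] - 1) if internal_stops else n_codons
    return OrfIntegrityReport(
        putein_length_aa=length,
        internal_stops=tuple(internal_stops),
        frameshifts=tuple(sorted(set(frameshifts))),
    )


# ---------------------------------------------------------------------------
# subtype classification and LTR regulatory motifs
# ---------------------------------------------------------------------------


def classify_subtype(
    provirus,
    reference: str | None = None,
    window: tuple[int, int] = SUBTYPE_WINDOW,
    min_at: float = 0.67,
    min_len: int = 600,
) -> str:
    """Type I/II call from the pol-3'/env-5' reference window.

    Type I proviruses carry an A/T-rich stretch in the window; type II carry
    coding sequence there.  With ``reference`` (a gapped row the provirus is
    aligned to), the window is mapped through the alignment; otherwise the
    provirus is assumed to be on reference coordinates.  Returns
    ``"unassigned"`` when fewer than ``min_len`` unambiguous window bases
    remain.
    """
    if isinstance(provirus, AnnotatedProvirus):
        seq = provirus.sequence.residues
    else:
        seq = provirus.residues if isinstance(provirus, NucSequence) else str(provirus)
    seq = seq.upper()
    lo, hi = window
    if reference is not None:
        if len(reference) != len(seq):
            raise InputError("provirus row and reference row must be aligned")
        ref_pos = 0
        cols = []
        for i, c in enumerate(reference.upper()):
            if c != GAP:
                ref_pos += 1
                if lo <= ref_pos <= hi:
                    cols.append(i)
        win = "".join(seq[i] for i in cols)
    else:
        win = seq[lo - 1 : hi]
    bases = [c for c in win if c in "ACGT"]
    if len(bases) < min_len:
        return "unassigned"
    at = sum(1 for c in bases if c in "AT") / len(bases)
    return "I" if at >= min_at else "II"


def ltr_motif_conservation(provirus: AnnotatedProvirus) -> pd.DataFrame:
    """Mismatch counts of the LTR regulatory motifs at their mapped reference
    coordinates, one row per (motif, LTR copy)."""
    rows = []
    for label, (start, end) in provirus.features.items():
        for motif, expected in REGULATORY_MOTIFS.items():
            if not label.startswith(motif):
                continue
            observed = provirus.sequence.residues[start - 1 : end]
            mism = sum(a != b for a, b in zip(observed, expected))
            rows.append(
                {
                    "motif": motif,
                    "copy": "5LTR" if label.endswith("_5") else "3LTR",
                    "expected": expected,
                    "observed": observed,
                    "mismatches": mism,
                    "conserved": mism == 0,
                }
            )
    return pd.DataFrame(rows, columns=["motif", "copy", "expected", "observed", "mismatches", "conserved"])
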