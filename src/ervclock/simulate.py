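"""Synthetic provirus generation with known ground truth.

The simulator emulates the life history that divergence dating assumes: a
provirus (5'LTR-gag-pol-env-3'LTR on the group reference frame) integrates
with its two LTR copies identical, then evolves neutrally under a Poisson
molecular clock at a configurable substitution rate (default 0.2%/nt/My, the
human neutral rate).  Optional processes layer realistic lesions on top:
CpG hypermutation (excess C->T / G->A at CpG dinucleotides), indels with
geometric lengths, premature stops/frameshifts, secondary insertions and
solo-LTR recombination products.  Every run records a ``SimulatedTruth`` with
the true age, per-region substitution counts, the true template/mutant
alignment and the lesions introduced, so downstream estimators can be tested
for parameter recovery without any external data.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError
from .motifs import REFERENCE_FEATURES, REFERENCE_LENGTH, AnnotatedProvirus
from .seqio import GAP, LOCUS_TABLE_COLUMNS, NucSequence

_BASES = "ACGT"
_CODE = {c: i for i, c in enumerate(_BASES)}

# background composition matching the A-biased group consensus
_BACKGROUND = {"A": 0.33, "C": 0.21, "G": 0.18, "T": 0.28}

_TEMPLATE_SEED = 6358  # fixed: the default template is a deterministic constant


@dataclass(frozen=True)
class ClockConfig:
    """Neutral-clock parameters: age in My, rate in %/nt/My, CpG excess
    multiplier (>=1), per-site indel probability and the RNG seed."""

    age_my: float
    rate: float = 0.2
    cpg_multiplier: float = 1.0
    indel_rate: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        if self.age_my < 0:
            raise ConfigError("age_my must be >= 0")
        if self.rate < 0:
            raise ConfigError("rate must be >= 0")
        if self.cpg_multiplier < 1:
            raise ConfigError("cpg_multiplier must be >= 1")
        if not (0 <= self.indel_rate < 1):
            raise ConfigError("indel_rate must be in [0, 1)")

    @property
    def substitution_probability(self) -> float:
        """Per-site probability of a realized substitution: 1 - exp(-r*t)."""
        return 1.0 - math.exp(-(self.rate / 100.0) * self.age_my)


@dataclass
class SimulatedTruth:
    """Ground truth of one simulated provirus."""

    true_age_my: float
    rate: float
    region_substitutions: dict[str, int]
    n_substitutions: int
    alignment: tuple[str, str]  # gapped (template row, mutant row)
    insertions: list[tuple[int, int]] = field(default_factory=list)  # (after tpl pos, len)
    deletions: list[tuple[int, int]] = field(default_factory=list)  # (tpl start, len)
    stop_codons: list[tuple[str, int]] = field(default_factory=list)
    frameshifts: list[tuple[str, int]] = field(default_factory=list)
    secondary_insertions: list[tuple[int, int]] = field(default_factory=list)
    solo_ltr: bool = False

    def _maps(self):
        tpl_row, mut_row = self.alignment
        t2m, m2t = {}, {}
        t = m = 0
        for a, b in zip(tpl_row, mut_row):
            if a != GAP and b != GAP:
                t2m[t + 1] = m + 1
                m2t[m + 1] = t + 1
            if a != GAP:
                t += 1
            if b != GAP:
                m += 1
        return t2m, m2t

    def map_to_mutant(self, template_pos: int) -> int | None:
        return self._maps()[0].get(template_pos)

    def map_to_template(self, mutant_pos: int) -> int | None:
        return self._maps()[1].get(mutant_pos)


@dataclass
class ProvirusTemplate:
    """An ancestral provirus: sequence plus reference feature map.

    The two LTR copies are identical by construction (the state at
    integration time).
    """

    sequence: str
    features: dict[str, tuple[int, int]]
    subtype: str = "I"

    def __post_init__(self):
        l5 = self.features.get("5LTR")
        l3 = self.features.get("3LTR")
        if l5 and l3:
            a = self.sequence[l5[0] - 1 : l5[1]]
            b = self.sequence[l3[0] - 1 : l3[1]]
            if a != b:
                raise ConfigError("template LTR copies must be identical")

    def as_annotated(self, name: str = "template") -> AnnotatedProvirus:
        return AnnotatedProvirus(
            NucSequence(name, self.sequence), dict(self.features), self.subtype
        )


def _random_bases(rng: np.random.Generator, n: int, at_fraction: float | None = None) -> str:
    if at_fraction is None:
        probs = [_BACKGROUND[b] for b in _BASES]
    else:
        gc = 1.0 - at_fraction
        probs = [at_fraction * 0.55, gc / 2, gc / 2, at_fraction * 0.45]
    return "".join(rng.choice(list(_BASES), size=n, p=np.array(probs) / sum(probs)))


def default_template(
    subtype: str = "I", cpg_rich: bool = False, seed: int = _TEMPLATE_SEED
) -> ProvirusTemplate:
    """The packaged synthetic provirus template on the reference frame.

    Regulatory motifs (TATA/SV40/PolyA), the lysine PBS and the PPT are
    planted at their reference coordinates; subtype I templates carry a
    ~70%-AT stretch in the pol-3'/env-5' window, subtype II templates carry
    ordinary background composition there.  ``cpg_rich`` plants a lattice of
    CpG dinucleotides inside both LTR copies (for hypermutation studies).
    """
    from .datasets import load_pbs_library
    from .motifs import REGULATORY_MOTIFS, SUBTYPE_WINDOW

    rng = np.random.default_rng(seed)
    seq = list(_random_bases(rng, REFERENCE_LENGTH))

    def plant(start: int, text: str):
        seq[start - 1 : start - 1 + len(text)] = list(text)

    # one LTR, reused verbatim for the 3' copy
    ltr = list(_random_bases(rng, 548))

    def plant_ltr(start: int, text: str):
        ltr[start - 1 : start - 1 + len(text)] = list(text)

    plant_ltr(30, REGULATORY_MOTIFS["TATA"])
    plant_ltr(65, REGULATORY_MOTIFS["SV40"])
    plant_ltr(384, REGULATORY_MOTIFS["PolyA"])
    if cpg_rich:
        for i in range(100, 380, 4):
            plant_ltr(i, "CG")
    plant(1, "".join(ltr))
    plant(5811, "".join(ltr))
    plant(552, load_pbs_library()[0][1])  # lysine PBS, 552-569
    plant(5786, "AAAAGGGGGAGGA")  # polypurine tract, 5786-5798
    lo, hi = SUBTYPE_WINDOW
    if subtype == "I":
        plant(lo, _random_bases(rng, hi - lo + 1, at_fraction=0.70))
    features = {
        k: v
        for k, v in REFERENCE_FEATURES.items()
    }
    return ProvirusTemplate("".join(seq), features, subtype=subtype)


# ---------------------------------------------------------------------------
# the clock
# ---------------------------------------------------------------------------


def _substitute_uniform(codes: np.ndarray, p: float, rng: np.random.Generator) -> np.ndarray:
    """Vectorised draw: each site substituted with probability p, uniformly
    among the three alternative bases."""
    hit = rng.random(codes.size) < p
    shift = rng.integers(1, 4, size=codes.size)
    out = codes.copy()
    out[hit] = (codes[hit] + shift[hit]) % 4
    return out


def _substitute_cpg(
    codes: np.ndarray, p: float, cpg_multiplier: float, rng: np.random.Generator
) -> np.ndarray:
    """Sequential 5'->3' scan with CpG context evaluated on the current
    (partially mutated) sequence.  At a CpG, the deamination target (C->T on
    the C, G->A on the G) has its per-target probability multiplied by
    ``cpg_multiplier``; other targets keep probability p/3."""
    out = codes.copy()
    n = out.size
    u = rng.random(n)
    base_p = p / 3.0
    C, G, A, T = _CODE["C"], _CODE["G"], _CODE["A"], _CODE["T"]
    for i in range(n):
        b = out[i]
        hot = None
        if b == C and i + 1 < n and out[i + 1] == G:
            hot = T
        elif b == G and i > 0 and out[i - 1] == C:
            hot = A
        alts = [x for x in range(4) if x != b]
        probs = []
        for x in alts:
            q = base_p * cpg_multiplier if x == hot else base_p
            probs.append(q)
        total = sum(probs)
        if total > 1.0:  # cap: scale down proportionally
            probs = [q / total for q in probs]
        acc = 0.0
        for x, q in zip(alts, probs):
            acc += q
            if u[i] < acc:
                out[i] = x
                break
    return out


def _geometric_lengths(rng: np.random.Generator, n: int, mean: float = 3.0) -> np.ndarray:
    return rng.geometric(1.0 / mean, size=n)


def simulate_provirus(
    template: ProvirusTemplate, config: ClockConfig, rng: np.random.Generator | None = None
) -> tuple[AnnotatedProvirus, SimulatedTruth]:
    """Evolve a template under the neutral clock; return the mutant provirus
    (feature map remapped through any indels) and its ground truth."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    codes = np.array([_CODE[c] for c in template.sequence], dtype=np.int8)
    p = config.substitution_probability
    if p > 0:
        if config.cpg_multiplier == 1.0:
            mut = _substitute_uniform(codes, p, rng)
        else:
            mut = _substitute_cpg(codes, p, config.cpg_multiplier, rng)
    else:
        mut = codes.copy()

    changed = np.flatnonzero(mut != codes)
    region_counts = {}
    for label in ("5LTR", "gag", "pol", "env", "3LTR"):
        if label in template.features:
            lo, hi = template.features[label]
            region_counts[label] = int(
                np.count_nonzero((changed >= lo - 1) & (changed <= hi - 1))
            )

    tpl_chars = list(template.sequence)
    mut_chars = [_BASES[c] for c in mut]

    # alignment as parallel rows; indels applied on top
    tpl_row = tpl_chars[:]
    mut_row = mut_chars[:]
    insertions: list[tuple[int, int]] = []
    deletions: list[tuple[int, int]] = []
    if config.indel_rate > 0:
        n_events = rng.binomial(len(tpl_chars), config.indel_rate)
        if n_events:
            positions = np.sort(rng.integers(0, len(tpl_chars), size=n_events))[::-1]
            lengths = _geometric_lengths(rng, n_events)
            is_del = rng.random(n_events) < 0.5
            for pos, length, d in zip(positions, lengths, is_del):
                pos, length = int(pos), int(length)
                if d:
                    end = min(pos + length, len(tpl_chars))
                    for k in range(pos, end):
                        mut_row[k] = GAP
                    deletions.append((pos + 1, end - pos))
                else:
                    ins = _random_bases(rng, length)
                    tpl_row[pos:pos] = [GAP] * length
                    mut_row[pos:pos] = list(ins)
                    insertions.append((pos, length))

    mutant_seq = "".join(c for c in mut_row if c != GAP)
    truth = SimulatedTruth(
        true_age_my=config.age_my,
        rate=config.rate,
        region_substitutions=region_counts,
        n_substitutions=int(changed.size),
        alignment=("".join(tpl_row), "".join(mut_row)),
        insertions=sorted(insertions),
        deletions=sorted(deletions),
    )

    features = _remap_features(template.features, truth) if (insertions or deletions) else dict(template.features)
    mutant = AnnotatedProvirus(
        NucSequence("mutant", mutant_seq), features, subtype=template.subtype
    )
    return mutant, truth


def _remap_features(
    features: dict[str, tuple[int, int]], truth: SimulatedTruth
) -> dict[str, tuple[int, int]]:
    t2m, _ = truth._maps()
    out = {}
    for label, (lo, hi) in features.items():
        mapped = [t2m[p] for p in range(lo, hi + 1) if p in t2m]
        if mapped:
            out[label] = (min(mapped), max(mapped))
    return out


# ---------------------------------------------------------------------------
# locus sets and consensus-divergence alignments
# ---------------------------------------------------------------------------


def simulate_locus_set(
    n_proviruses: int,
    n_solo_ltrs: int,
    chrom_length_table,
    seed: int | None = None,
    *,
    clock: ClockConfig | None = None,
    enrichment: dict[str, float] | None = None,
    template: ProvirusTemplate | None = None,
    emit_sequences: bool = True,
):
    """Place proviruses and solo LTRs on chromosomes proportionally to length.

    ``enrichment`` multiplies individual chromosomes' sampling weight (e.g. a
    9-fold multiplier emulates a strongly enriched chromosome).  Solo LTRs are
    recombination products: the internal region between the two LTR copies of
    a simulated provirus is deleted, leaving a single LTR-length record.

    Returns ``(locus_table, sequences, truths)`` where the locus table is a
    DataFrame with the standard columns; ``sequences`` is empty when
    ``emit_sequences`` is False (counts-only studies).
    """
    lengths = pd.Series(dict(chrom_length_table), dtype=float)
    if lengths.empty:
        raise ConfigError("chromosome length table is empty")
    if (lengths <= 0).any():
        raise ConfigError("chromosome lengths must be positive")
    rng = np.random.default_rng(seed)
    weights = lengths.copy()
    for chrom, mult in (enrichment or {}).items():
        weights[str(chrom)] = weights[str(chrom)] * mult
    probs = (weights / weights.sum()).to_numpy()
    chrom_names = list(lengths.index.astype(str))

    if template is None and emit_sequences:
        template = default_template()
    clock = clock or ClockConfig(age_my=20.0)

    records, sequences, truths = [], {}, []
    total = n_proviruses + n_solo_ltrs
    picks = rng.choice(len(chrom_names), size=total, p=probs)
    for i in range(total):
        solo = i >= n_proviruses
        chrom = chrom_names[picks[i]]
        if emit_sequences:
            mutant, truth = simulate_provirus(template, clock, rng=rng)
            if solo:
                ltr = mutant.features.get("5LTR")
                res = (
                    mutant.sequence.residues[ltr[0] - 1 : ltr[1]]
                    if ltr
                    else mutant.sequence.residues
                )
                truth.solo_ltr = True
                seq_len = len(res)
            else:
                res = mutant.sequence.residues
                seq_len = len(res)
        else:
            res, truth = None, None
            seq_len = REFERENCE_LENGTH if not solo else 548
        start = int(rng.integers(1, max(2, int(lengths[chrom]) - seq_len + 1)))
        name = f"{'solo' if solo else 'prov'}{i:04d}_{chrom}"
        records.append(
            {
                "name": name,
                "chrom": chrom,
                "start": start,
                "end": start + seq_len - 1,
                "strand": "+" if rng.random() < 0.5 else "-",
                "context": "intergenic",
            }
        )
        if emit_sequences:
            sequences[name] = NucSequence(name, res)
            truths.append(truth)
    table = pd.DataFrame(records, columns=LOCUS_TABLE_COLUMNS)
    return table, sequences, truths


def simulate_msa_from_consensus(
    consensus, per_member_divergence, seed: int | None = None
):
    """Mutate a consensus to the requested expected p-distances.

    Each member substitutes every site independently with probability equal
    to its target divergence (uniform among the three alternatives), so the
    expected p-distance to the consensus equals the target.  Returns the
    alignment (ungapped, equal-length rows) and the realized per-member
    p-distances as truth.
    """
    from .seqio import GappedSequence, MultipleAlignment

    res = consensus.residues if isinstance(consensus, NucSequence) else str(consensus)
    rng = np.random.default_rng(seed)
    codes = np.array([_CODE[c] for c in res], dtype=np.int8)
    members, realized = [], []
    for k, d in enumerate(per_member_divergence):
        if not (0 <= d < 0.75):
            raise ConfigError("divergence must be in [0, 0.75) (p-distance saturation)")
        mut = _substitute_uniform(codes, float(d), rng)
        realized.append(float(np.mean(mut != codes)))
        members.append(GappedSequence(f"m{k + 1}", "".join(_BASES[c] for c in mut)))
    if len(members) < 2:
        members.append(GappedSequence("consensus", res))
    return MultipleAlignment(members), realized


# ---------------------------------------------------------------------------
# optional lesions
# ---------------------------------------------------------------------------


def plant_premature_stop(
    provirus: AnnotatedProvirus, region: str, codon_index: int
) -> AnnotatedProvirus:
    """Overwrite one codon of a gene region with TAA (1-based codon index,
    region reading frame starting at the region's first base)."""
    lo, hi = provirus.features[region]
    start = lo - 1 + 3 * (codon_index - 1)
    if start + 3 > hi:
        raise ConfigError(f"codon {codon_index} outside region {region}")
    res = provirus.sequence.residues
    res = res[:start] + "TAA" + res[start + 3 :]
    return AnnotatedProvirus(
        NucSequence(provirus.sequence.id, res), dict(provirus.features), provirus.subtype
    )


def plant_frameshift(
    provirus: AnnotatedProvirus, region: str, codon_index: int
) -> AnnotatedProvirus:
    """Delete one base at a codon boundary inside a gene region."""
    lo, hi = provirus.features[region]
    pos = lo - 1 + 3 * codon_index  # 0-based, boundary after codon_index
    if pos >= hi:
        raise ConfigError(f"codon {codon_index} outside region {region}")
    res = provirus.sequence.residues
    res = res[:pos] + res[pos + 1 :]
    feats = {}
    for label, (a, b) in provirus.features.items():
        feats[label] = (a if a <= pos else a - 1, b if b <= pos else b - 1)
    return AnnotatedProvirus(
        NucSequence(provirus.sequence.id, res), feats, provirus.subtype
    )


def insert_secondary(
    provirus: AnnotatedProvirus, position: int, length: int, seed: int | None = None
) -> tuple[AnnotatedProvirus, tuple[int, int]]:
    """Insert a random secondary-integration segment after ``position``."""
    rng = np.random.default_rng(seed)
    segment = _random_bases(rng, length)
    res = provirus.sequence.residues
    res = res[:position] + segment + res[position:]
    feats = {}
    for label, (a, b) in provirus.features.items():
        feats[label] = (a if a <= position else a + length, b if b <= position else b + length)
    interval = (position + 1, position + length)
    return (
        AnnotatedProvirus(NucSequence(provirus.sequence.id, res), feats, provirus.subtype),
        interval,
    )
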