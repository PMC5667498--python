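import re

import numpy as np
import pytest

from ervclock import motifs
from ervclock.datasets import load_pbs_library
from ervclock.errors import InputError
from ervclock.motifs import (
    AnnotatedProvirus,
    assess_orf_integrity,
    classify_subtype,
    find_at_rich_stretches,
    find_pbs,
    ltr_motif_conservation,
    nucleotide_frequencies,
    pbs_alignment_profile,
    scan_protein_motifs,
)
from ervclock.seqio import NucSequence
from ervclock.simulate import ClockConfig, simulate_provirus

AA = "ACDEFGHIKLMNPQRSTVWY"


def regex_oracle_hits(seq: str) -> set:
    """Independent regex oracle for the three Betaretroviral patterns
    (x = any non-stop residue; overlapping hits enumerated exhaustively)."""
    x = "[A-Z]"
    out = set()
    fixed = {
        "dutpase": f"DSDY{x}GEIQ",
        "gag_zinc_finger": f"C{x}{{2}}C{x}{{4}}H{x}{{4}}C",
    }
    for name, pat in fixed.items():
        rx = re.compile(pat)
        for i in range(len(seq)):
            if rx.fullmatch(seq, i, i + (9 if name == "dutpase" else 14)):
                out.add((name, i + 1))
    head = f"GY{x}{{2}}G{x}GLG{x}{{4}}G"
    for n in range(1, 16):
        rx = re.compile(head + x + "{%d}G" % n)
        for i in range(len(seq)):
            if rx.fullmatch(seq, i, i + 14 + n + 1):
                out.add(("g_patch", i + 1, i + 14 + n + 1))
    return out


def package_hits(seq: str) -> set:
    out = set()
    for h in scan_protein_motifs(seq, is_nucleotide=False):
        if h.motif_name == "g_patch":
            out.add((h.motif_name, h.start, h.end))
        else:
            out.add((h.motif_name, h.start))
    return out


def test_pattern_instances():
    hits = scan_protein_motifs("DSDYAGEIQ", is_nucleotide=False)
    assert any(h.motif_name == "dutpase" for h in hits)
    hits = scan_protein_motifs("CAACAAAAHAAAAC", is_nucleotide=False)
    assert any(h.motif_name == "gag_zinc_finger" for h in hits)
    hits = scan_protein_motifs("GYAAGAGLGAAAAGAG", is_nucleotide=False)
    assert any(h.motif_name == "g_patch" for h in hits)


def test_stop_breaks_pattern():
    assert not scan_protein_motifs("DSDY*GEIQ", is_nucleotide=False)


def test_scan_agrees_with_regex_oracle(rng):
    for _ in range(200):
        n = int(rng.integers(20, 120))
        seq = "".join(rng.choice(list(AA), size=n))
        # salt with partial motifs to exercise near-misses
        if rng.random() < 0.5:
            pos = int(rng.integers(0, max(1, n - 14)))
            seq = seq[:pos] + "GYAAGAGLGAAAAG" + seq[pos + 14 :]
        assert package_hits(seq) == regex_oracle_hits(seq)


def test_nucleotide_input_scans_three_frames():
    nt = "T" + "GATTCTGATTATGCTGGGGAAATTCAG"  # DSDYAGEIQ in frame 1
    hits = scan_protein_motifs(nt, is_nucleotide=True)
    assert any(h.motif_name == "dutpase" and h.frame == 1 for h in hits)


# --- A/T-rich stretches -------------------------------------------------------


def test_planted_at_stretch_recovered(rng):
    def draw(n, at):
        return "".join(
            rng.choice(["A", "T", "G", "C"], size=n, p=[at / 2, at / 2, (1 - at) / 2, (1 - at) / 2])
        )

    background = draw(2000, 0.50)
    planted = draw(830, 0.72)
    seq = background[:1000] + planted + background[1000:]
    found = find_at_rich_stretches(seq, min_len=800, min_at=0.67)
    assert len(found) == 1
    iv = found[0]
    assert abs(iv.start - 1001) < 120 and abs(iv.end - 1830) < 120
    assert iv.at_fraction >= 0.67


def test_all_gc_has_no_stretch():
    assert find_at_rich_stretches("GC" * 600, min_len=800) == []


def test_all_at_single_full_interval():
    (iv,) = find_at_rich_stretches("AT" * 500, min_len=800)
    assert (iv.start, iv.end, iv.at_fraction) == (1, 1000, 1.0)


def test_stretches_never_overlap_and_satisfy_threshold(rng):
    for _ in range(20):
        seq = "".join(rng.choice(list("ACGT"), size=600, p=[0.33, 0.17, 0.17, 0.33]))
        found = find_at_rich_stretches(seq, min_len=50, min_at=0.7)
        for iv in found:
            assert iv.at_fraction >= 0.7
        for a, b in zip(found, found[1:]):
            assert a.end < b.start


# --- composition --------------------------------------------------------------


def test_nucleotide_frequencies_trivial():
    freq = nucleotide_frequencies(["AAAA"])
    assert freq.loc["A", "mean"] == 100.0 and freq.loc["G", "mean"] == 0.0
    freq = nucleotide_frequencies(["AATT", "GGCC"])
    assert list(freq["mean"]) == [25.0, 25.0, 25.0, 25.0]


def test_frequencies_preserved_by_uniform_clock(template, rng):
    base = nucleotide_frequencies([template.sequence])
    mutants = [
        simulate_provirus(template, ClockConfig(age_my=20), rng=rng)[0].sequence
        for _ in range(30)
    ]
    mutated = nucleotide_frequencies(mutants)
    # uniform substitution drifts composition toward 25% but only by ~4% of
    # the deviation at these divergences; means stay within ~1 point
    assert np.allclose(base["mean"], mutated["mean"], atol=1.0)


# --- PBS ----------------------------------------------------------------------


def test_planted_pbs_exact_match(template):
    rec = find_pbs(template.sequence, ltr5_end=548)
    assert rec.assigned_trna == "K"
    assert rec.identity_percent == 100.0
    assert rec.length == 18 and not rec.indel


def test_pbs_single_insertion_between_10_and_11(template):
    seq = template.sequence
    pbs_start = 551  # 0-based: PBS occupies 551..568
    mutated = seq[: pbs_start + 10] + "A" + seq[pbs_start + 10 :]
    rec = find_pbs(mutated, ltr5_end=548)
    assert rec.length == 19 and rec.indel
    assert rec.assigned_trna == "K"
    assert rec.identity_percent == 100.0


def test_pbs_not_applicable_without_5ltr(template):
    truncated = AnnotatedProvirus(NucSequence("x", template.sequence[600:]), {})
    assert find_pbs(truncated) is None


def test_pbs_invariant_to_flanking_sequence(template):
    rec1 = find_pbs(template.sequence, ltr5_end=548)
    altered = "T" * 100 + template.sequence[100:570] + "G" * 50
    rec2 = find_pbs(altered, ltr5_end=548)
    assert (rec1.assigned_trna, rec1.sequence) == (rec2.assigned_trna, rec2.sequence)


def test_pbs_profile_counts():
    lib = load_pbs_library()
    rec = motifs.PBSRecord(lib[0][1], 3, 18, "K", 100.0)
    prof = pbs_alignment_profile([rec, rec])
    assert prof.sum(axis=0).tolist() == [2] * 18
    assert prof.loc[lib[0][1][0], 1] == 2


# --- ORF integrity -------------------------------------------------------------


def test_planted_internal_stop():
    ref = "ATG" + "GCT" * 8  # 9 codons
    region = ref[:12] + "TAA" + ref[15:]
    rep = assess_orf_integrity(region, ref)
    assert rep.internal_stops == (5,) and not rep.intact
    assert rep.putein_length_aa == 4


def test_reference_identical_region_is_intact():
    ref = "ATG" + "GCT" * 8
    rep = assess_orf_integrity(ref, ref)
    assert rep.intact and rep.putein_length_aa == 9 and rep.frameshifts == ()


def test_frameshift_between_residues_17_and_18():
    ref = "ATG" + "GCT" * 29  # 30 codons
    region = ref[:51] + "-" + ref[52:]  # 1-nt deletion at the 17/18 boundary
    rep = assess_orf_integrity(region, ref)
    assert rep.frameshifts == (17,) and not rep.intact


def test_orf_region_shorter_than_codon_rejected():
    with pytest.raises(InputError):
        assess_orf_integrity("AT", "AT")


# --- subtype and LTR motifs ----------------------------------------------------


def test_subtype_classification(template, template_type2):
    assert classify_subtype(template.sequence) == "I"
    assert classify_subtype(template_type2.sequence) == "II"


def test_subtype_unassigned_when_window_deleted(template):
    lo, hi = motifs.SUBTYPE_WINDOW
    ref = template.sequence
    row = ref[: lo - 1] + "-" * (hi - lo + 1) + ref[hi:]
    assert classify_subtype(row, reference=ref) == "unassigned"


def test_ltr_regulatory_motifs_conserved_on_template(template):
    annotated = template.as_annotated()
    table = ltr_motif_conservation(annotated)
    assert len(table) == 6  # three motifs x two LTR copies
    assert table["conserved"].all()
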