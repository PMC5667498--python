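import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ervclock import dating
from ervclock.errors import ConfigError
from ervclock.simulate import (
    ClockConfig,
    default_template,
    plant_frameshift,
    plant_premature_stop,
    simulate_locus_set,
    simulate_msa_from_consensus,
    simulate_provirus,
)


def expected_interltr_p(age_my, rate=0.2):
    """Closed-form expected inter-LTR p-distance under the clock: each copy
    substitutes a site with p = 1-exp(-r t) uniformly among 3 alternatives,
    so the per-site mismatch probability is 2p(1-p) + (2/3)p^2."""
    p = 1.0 - np.exp(-(rate / 100.0) * age_my)
    return 2 * p * (1 - p) + (2.0 / 3.0) * p * p


def test_zero_age_is_identity(template):
    mutant, truth = simulate_provirus(template, ClockConfig(age_my=0, seed=1))
    assert mutant.sequence.residues == template.sequence
    assert truth.n_substitutions == 0
    assert all(v == 0 for v in truth.region_substitutions.values())


def test_config_validation():
    with pytest.raises(ConfigError):
        ClockConfig(age_my=-1)
    with pytest.raises(ConfigError):
        ClockConfig(age_my=1, rate=-0.1)
    with pytest.raises(ConfigError):
        ClockConfig(age_my=1, cpg_multiplier=0.5)
    with pytest.raises(ConfigError):
        ClockConfig(age_my=1, indel_rate=1.0)


def test_interltr_divergence_matches_poisson_expectation(template, rng):
    """Observed inter-LTR p-distance converges to the clock's closed form
    (and stays close to the linear 2(1-exp(-rt)) approximation)."""
    age = 20.0
    cfg = ClockConfig(age_my=age)
    ds = []
    for _ in range(300):
        mutant, _ = simulate_provirus(template, cfg, rng=rng)
        d, _ = dating.p_distance(mutant.feature_seq("5LTR"), mutant.feature_seq("3LTR"))
        ds.append(d / 100.0)
    mean_d = np.mean(ds)
    exact = expected_interltr_p(age)
    mc_se = np.std(ds) / np.sqrt(len(ds))
    assert abs(mean_d - exact) < 4 * mc_se
    approx = 2 * (1 - np.exp(-0.002 * age))
    assert abs(mean_d - approx) < 0.004  # linear-regime approximation


def test_cpg_multiplier_increases_deamination(cpg_rich_template, rng):
    """cpg_multiplier > 1 yields strictly more C->T + G->A changes on a
    CpG-rich template in expectation."""

    def deamination_count(cfg, n=60):
        total = 0
        for _ in range(n):
            mutant, truth = simulate_provirus(cpg_rich_template, cfg, rng=rng)
            tpl_row, mut_row = truth.alignment
            total += sum(
                1
                for a, b in zip(tpl_row, mut_row)
                if (a, b) in (("C", "T"), ("G", "A"))
            )
        return total

    base = deamination_count(ClockConfig(age_my=20, cpg_multiplier=1.0))
    hot = deamination_count(ClockConfig(age_my=20, cpg_multiplier=4.0))
    assert hot > base


def test_truth_alignment_maps_are_consistent(template, rng):
    cfg = ClockConfig(age_my=15, indel_rate=0.002)
    mutant, truth = simulate_provirus(template, cfg, rng=rng)
    assert truth.insertions or truth.deletions  # indels realised at this rate
    hits = 0
    for pos in range(1, len(template.sequence) + 1, 97):
        m = truth.map_to_mutant(pos)
        if m is not None:
            assert truth.map_to_template(m) == pos
            hits += 1
    assert hits > 0
    # mutant length bookkeeping
    ins = sum(l for _, l in truth.insertions)
    dels = sum(l for _, l in truth.deletions)
    assert len(mutant.sequence) == len(template.sequence) + ins - dels


def test_locus_set_no_solo_requested(template):
    table, seqs, truths = simulate_locus_set(
        3, 0, {"1": 10_000_000, "2": 10_000_000}, seed=5, template=template
    )
    assert len(table) == 3
    assert not any(t.solo_ltr for t in truths)


def test_solo_ltr_records_are_single_ltr_length(template):
    table, seqs, truths = simulate_locus_set(
        2, 3, {"1": 10_000_000}, seed=5, template=template
    )
    ltr_len = template.features["5LTR"][1] - template.features["5LTR"][0] + 1
    solo_names = table.loc[table["name"].str.startswith("solo"), "name"]
    assert len(solo_names) == 3
    for name in solo_names:
        assert len(seqs[name]) == ltr_len


def test_locus_set_length_proportional_sampling():
    lengths = {"1": 4_000_000, "2": 3_000_000, "3": 2_000_000, "4": 1_000_000}
    table, _, _ = simulate_locus_set(
        1200, 0, lengths, seed=11, emit_sequences=False
    )
    observed = table["chrom"].value_counts().reindex(list(lengths), fill_value=0)
    total = sum(lengths.values())
    expected = [1200 * v / total for v in lengths.values()]
    stat, p = stats.chisquare(observed.to_numpy(), expected)
    assert p > 0.01


def test_enrichment_multiplier_scales_fold():
    lengths = {str(c): 10_000_000 for c in range(1, 11)}
    table, _, _ = simulate_locus_set(
        5000, 0, lengths, seed=13, enrichment={"7": 9.0}, emit_sequences=False
    )
    counts = table["chrom"].value_counts()
    # expected under plain length-proportionality
    expected_7 = 5000 / 10
    fold = counts["7"] / expected_7
    # weight 9 among 10 chromosomes -> sampling share 9/18 -> fold 5
    assert 4.0 < fold < 6.0


def test_empty_chromosome_table_rejected():
    with pytest.raises(ConfigError):
        simulate_locus_set(1, 0, {}, seed=1, emit_sequences=False)


def test_msa_zero_divergence_is_identity(template):
    cons = template.sequence[:200]
    msa, realized = simulate_msa_from_consensus(cons, [0.0, 0.0], seed=2)
    assert all(m.residues == cons for m in msa.members)
    assert realized == [0.0, 0.0]


def test_msa_realized_divergence_within_mc_error(template):
    cons = template.sequence[:1000]
    targets = [0.02, 0.04]
    msa, realized = simulate_msa_from_consensus(cons, targets, seed=3)
    for target, real in zip(targets, realized):
        sd = np.sqrt(target * (1 - target) / 1000)
        assert abs(real - target) < 3 * sd


def test_msa_rejects_saturating_divergence(template):
    with pytest.raises(ConfigError):
        simulate_msa_from_consensus(template.sequence[:100], [0.8], seed=1)


def test_consensus_rebuild_recovers_generator(template):
    cons = template.sequence[:548]
    msa, _ = simulate_msa_from_consensus(cons, [0.05] * 10, seed=7)
    rebuilt = dating.majority_consensus(msa)
    agree = sum(a == b for a, b in zip(rebuilt.residues, cons)) / len(cons)
    assert agree >= 0.99


def test_planted_lesions(template):
    annotated = simulate_provirus(template, ClockConfig(age_my=0, seed=1))[0]
    stopped = plant_premature_stop(annotated, "env", 5)
    lo = stopped.features["env"][0]
    assert stopped.sequence.residues[lo - 1 + 12 : lo - 1 + 15] == "TAA"
    shifted = plant_frameshift(annotated, "env", 17)
    assert len(shifted.sequence) == len(annotated.sequence) - 1
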