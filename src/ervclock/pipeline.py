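"""End-to-end orchestration: simulate -> annotate -> date -> distribution ->
phylogeny, with deterministic per-stage seeds and a JSON run summary.

Every stochastic stage receives a seed derived from the single run seed via
``numpy.random.SeedSequence`` spawn keys, so a rerun with the same
configuration reproduces every output.
"""
from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import dating, distribution, phylo
from .datasets import load_grch37_chromosome_lengths
from .errors import InputError
from .seqio import (
    GappedSequence,
    MultipleAlignment,
    read_alignment,
    write_alignment,
    write_fasta,
)
from .simulate import ClockConfig, default_template, simulate_locus_set

log = logging.getLogger("ervclock")


@dataclass
class RunConfig:
    """Flat run configuration; every field is mirrored by a CLI flag."""

    outdir: str = "ervclock_run"
    seed: int = 0
    rate: float = dating.DEFAULT_RATE
    cv_threshold: float = 0.20
    bootstrap: int = 1000
    halve_ltr: bool = True
    cpg_mask: bool = True
    age_my: float = 20.0
    n_proviruses: int = 12
    n_solo_ltrs: int = 6
    cpg_multiplier: float = 1.0
    indel_rate: float = 0.0
    template_subtype: str = "I"
    # optional external inputs; when unset the simulate stage provides them
    ltr_alignment: str | None = None
    locus_table: str | None = None
    chrom_lengths: str | None = None

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Read a flat ``key = value`` config file (flags win over the file)."""
        values = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise InputError(f"{path}:{lineno}: expected key = value")
            key, raw = (s.strip() for s in line.split("=", 1))
            values[key] = raw
        cfg = cls()
        for key, raw in values.items():
            if not hasattr(cfg, key):
                raise InputError(f"unknown config key {key!r}")
            current = getattr(cfg, key)
            if isinstance(current, bool):
                setattr(cfg, key, raw.lower() in ("1", "true", "yes", "on"))
            elif isinstance(current, int):
                setattr(cfg, key, int(raw))
            elif isinstance(current, float):
                setattr(cfg, key, float(raw))
            else:
                setattr(cfg, key, raw)
        return cfg


def stage_seed(run_seed: int, stage: int) -> int:
    """Deterministic per-stage seed below 2**31."""
    ss = np.random.SeedSequence(entropy=run_seed, spawn_key=(stage,))
    return int(ss.generate_state(1)[0] % (2**31))


def ltr_alignment_from_simulation(sequences, truths, template) -> MultipleAlignment:
    """Per-locus 5'/3' LTR rows (reference coordinates; substitution-only
    simulations keep the template frame so rows align without gaps)."""
    members = []
    l5 = template.features["5LTR"]
    l3 = template.features["3LTR"]
    for (name, seq), truth in zip(sequences.items(), truths):
        if truth.solo_ltr:
            continue
        members.append(GappedSequence(f"{name}/5LTR", seq.residues[l5[0] - 1 : l5[1]]))
        members.append(GappedSequence(f"{name}/3LTR", seq.residues[l3[0] - 1 : l3[1]]))
    if len(members) < 2:
        raise InputError("need at least one provirus with both LTRs")
    return MultipleAlignment(members)


def gene_alignment_from_simulation(sequences, truths, template, gene: str) -> MultipleAlignment:
    lo, hi = template.features[gene]
    members = []
    for (name, seq), truth in zip(sequences.items(), truths):
        if truth.solo_ltr:
            continue
        members.append(GappedSequence(f"{name}/{gene}", seq.residues[lo - 1 : hi]))
    if len(members) < 2:
        raise InputError("need at least 2 proviruses")
    return MultipleAlignment(members)


def column_consensus(msa: MultipleAlignment) -> str:
    """Majority consensus kept on alignment columns (gap where gaps win),
    for positional comparison against alignment rows."""
    mat = msa.to_matrix()
    order = "ACGT-"
    out = []
    for col in mat.T:
        counts = {c: int(np.count_nonzero(col == i)) for i, c in enumerate("ACGTN")}
        counts["-"] = int(np.count_nonzero(col == 5))
        best = max(order, key=lambda c: (counts[c], -order.index(c)))
        out.append(best)
    return "".join(out)


def date_from_alignments(
    ltr_msa: MultipleAlignment | None,
    gene_msas: dict[str, MultipleAlignment] | None = None,
    *,
    rate: float = dating.DEFAULT_RATE,
    cv_threshold: float = 0.20,
    halve_ltr: bool = True,
    mask_cpg: bool = True,
    n_boot: int = 1000,
    seed: int | None = None,
) -> tuple[list[dating.AgeEstimate], list[dating.DivergenceEstimate]]:
    """Per-locus integration ages from region alignments.

    LTR alignment rows are named ``<locus>/5LTR`` and ``<locus>/3LTR``; gene
    alignment rows ``<locus>/<gene>``.  Produces the LTR-pair, LTR-vs-consensus
    and gene-vs-consensus components, then aggregates per locus with the
    bootstrap-CV exclusion rule.
    """
    rng = np.random.default_rng(seed)
    per_locus: dict[str, list[dating.DivergenceEstimate]] = {}
    all_estimates: list[dating.DivergenceEstimate] = []

    def boot_seed() -> int:
        return int(rng.integers(0, 2**31))

    if ltr_msa is not None:
        cons = column_consensus(ltr_msa)
        by_locus: dict[str, dict[str, GappedSequence]] = {}
        for m in ltr_msa.members:
            locus, _, which = m.id.rpartition("/")
            by_locus.setdefault(locus, {})[which] = m
        for locus, parts in sorted(by_locus.items()):
            ests = per_locus.setdefault(locus, [])
            if "5LTR" in parts and "3LTR" in parts:
                ests.append(
                    dating.estimate_divergence(
                        parts["5LTR"], parts["3LTR"], "ltr_vs_ltr", "LTR",
                        mask_cpg=mask_cpg, n_boot=n_boot, seed=boot_seed(),
                    )
                )
            cons_ds = []
            for which in ("5LTR", "3LTR"):
                if which in parts:
                    cons_ds.append(
                        dating.estimate_divergence(
                            parts[which], cons, "ltr_vs_consensus", which,
                            mask_cpg=mask_cpg, n_boot=n_boot, seed=boot_seed(),
                        )
                    )
            if cons_ds:
                # one component per locus: average D over the LTR copies
                d = float(np.mean([e.d_percent for e in cons_ds]))
                sd = float(np.mean([e.bootstrap_sd for e in cons_ds]))
                ests.append(
                    dating.DivergenceEstimate(
                        "ltr_vs_consensus", "LTR", d,
                        min(e.sites_used for e in cons_ds), sd, n_boot,
                    )
                )
            all_estimates.extend(ests)

    for gene, msa in (gene_msas or {}).items():
        cons = column_consensus(msa)
        for m in msa.members:
            locus, _, _ = m.id.rpartition("/")
            est = dating.estimate_divergence(
                m, cons, f"{gene}_vs_consensus", gene,
                mask_cpg=mask_cpg, n_boot=n_boot, seed=boot_seed(),
            )
            per_locus.setdefault(locus, []).append(est)
            all_estimates.append(est)

    ages = [
        dating.aggregate_locus_age(
            ests, locus=locus, rate=rate, cv_threshold=cv_threshold, halve_ltr=halve_ltr
        )
        for locus, ests in sorted(per_locus.items())
        if ests
    ]
    return ages, all_estimates


def run_pipeline(config: RunConfig) -> dict:
    """Execute simulate -> date -> distribution -> phylogeny and write all
    stage outputs plus a JSON summary under ``config.outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    log.addHandler(handler)
    summary: dict = {"config": asdict(config), "stages": {}, "warnings": []}
    try:
        chrom_lengths = (
            pd.read_csv(config.chrom_lengths, sep="\t", dtype={"chrom": str}).set_index("chrom")["length_bp"]
            if config.chrom_lengths
            else load_grch37_chromosome_lengths()
        )

        template = default_template(subtype=config.template_subtype)
        clock = ClockConfig(
            age_my=config.age_my,
            rate=config.rate,
            cpg_multiplier=config.cpg_multiplier,
            indel_rate=config.indel_rate,
        )

        # --- simulate -----------------------------------------------------
        sim_seed = stage_seed(config.seed, 0)
        log.info("simulate: seed=%d age=%.1f", sim_seed, config.age_my)
        loci, sequences, truths = simulate_locus_set(
            config.n_proviruses,
            config.n_solo_ltrs,
            chrom_lengths,
            seed=sim_seed,
            clock=clock,
            template=template,
        )
        loci.to_csv(outdir / "loci.tsv", sep="\t", index=False)
        write_fasta(sequences.values(), outdir / "sequences.fasta")
        truth_json = [
            {
                "name": name,
                "true_age_my": t.true_age_my,
                "n_substitutions": t.n_substitutions,
                "region_substitutions": t.region_substitutions,
                "solo_ltr": t.solo_ltr,
            }
            for name, t in zip(sequences, truths)
        ]
        (outdir / "truth.json").write_text(json.dumps(truth_json, indent=1))
        summary["stages"]["simulate"] = {
            "seed": sim_seed,
            "n_proviruses": config.n_proviruses,
            "n_solo_ltrs": config.n_solo_ltrs,
        }

        # --- date ----------------------------------------------------------
        date_seed = stage_seed(config.seed, 1)
        ltr_msa = (
            read_alignment(config.ltr_alignment)
            if config.ltr_alignment
            else ltr_alignment_from_simulation(sequences, truths, template)
        )
        write_alignment(ltr_msa, outdir / "ltr_alignment.fasta")
        gene_msas = {
            g: gene_alignment_from_simulation(sequences, truths, template, g)
            for g in ("gag", "pol", "env")
        }
        ages, estimates = date_from_alignments(
            ltr_msa,
            gene_msas,
            rate=config.rate,
            cv_threshold=config.cv_threshold,
            halve_ltr=config.halve_ltr,
            mask_cpg=config.cpg_mask,
            n_boot=config.bootstrap,
            seed=date_seed,
        )
        table = dating.summarize_age_table(ages, rate=config.rate)
        table.summary().to_csv(outdir / "ages.tsv", sep="\t")
        excluded = {a.locus: a.excluded for a in ages if a.excluded}
        if excluded:
            summary["warnings"].append({"excluded_dating_components": excluded})
        summary["stages"]["date"] = {
            "seed": date_seed,
            "column_means": table.column_means,
            "implied_divergence": table.implied_divergence,
        }

        # --- distribution ---------------------------------------------------
        report = distribution.distribution_report(loci, chrom_lengths)
        report.table.to_csv(outdir / "distribution.tsv", sep="\t", index=False)
        summary["stages"]["distribution"] = {
            "chi_square": report.overall.statistic,
            "df": report.overall.df,
            "p_value": report.overall.p_value,
            "mean_per_chrom_p": report.mean_per_chrom_p,
        }

        # --- phylogeny -------------------------------------------------------
        phylo_seed = stage_seed(config.seed, 2)
        tree = phylo.bootstrap_support(
            ltr_msa, "p", n=min(config.bootstrap, 200), seed=phylo_seed
        )
        newick = phylo.write_newick(tree, outdir / "ltr_tree.nwk")
        summary["stages"]["phylo"] = {
            "seed": phylo_seed,
            "n_boot": tree.n_boot,
            "skipped_replicates": tree.skipped_replicates,
            "newick_chars": len(newick),
        }

        (outdir / "summary.json").write_text(json.dumps(summary, indent=1))
        return summary
    finally:
        log.removeHandler(handler)
        handler.close()
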