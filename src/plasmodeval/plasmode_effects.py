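"""Effect-injection plasmodes.

Starting from samples of a single biological group, each plasmode replicate
randomly assigns samples to two artificial treatments (A or B) within each
block, then transplants a randomly chosen subset of previously estimated
differential-expression effects into the B arm.  Samples therefore differ
between arms only by the injected effects, and within arms only by the block
effect — a known ground truth on real-data noise.

Three gene-subset scenarios tune the signal-to-noise ratio: only the injected
(DE) genes; all genes; or the DE genes plus a random half of the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import math

import numpy as np
import pandas as pd

from .io_counts import CountMatrix, SampleMeta

__all__ = [
    "EffectPlasmodeDesign",
    "PlasmodeReplicate",
    "SCENARIOS",
    "relabel_by_role",
    "call_de_genes",
    "effects_from_de_table",
    "generate_effect_plasmode",
    "assemble_scenario",
]

SCENARIOS = ("DE100", "DE10_NONDE90", "DE20_NONDE80")


@dataclass
class EffectPlasmodeDesign:
    """Replicate count, DE fraction and group layout for effect plasmodes.

    ``de_fraction`` is the fraction of *all* genes that receive an effect
    (|S1| = round(de_fraction * n_genes), round-half-up); it cannot exceed the
    fraction of genes available in the detected DE set.  Within each block
    ``group_b_per_block`` samples go to arm B, then up to ``group_a_per_block``
    of the remaining to arm A; any further samples are left out of the
    replicate.
    """

    n_plasmodes: int = 50
    de_fraction: float = 0.10
    q_threshold: float = 0.05
    group_b_per_block: int = 2
    group_a_per_block: int = 2
    stochastic_effects: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must lie in [0, 1]")
        if self.n_plasmodes < 1:
            raise ValueError("n_plasmodes must be >= 1")
        if min(self.group_b_per_block, self.group_a_per_block) < 1:
            raise ValueError("per-block group sizes must be >= 1")


@dataclass
class PlasmodeReplicate:
    """A plasmode count matrix plus its ground truth."""

    counts: CountMatrix
    labels: SampleMeta
    injected: dict[str, float] = field(default_factory=dict)  # gene_id -> effect
    scenario_tag: str = ""
    composition: dict[str, dict[str, float]] = field(default_factory=dict)


def relabel_by_role(rep: PlasmodeReplicate) -> PlasmodeReplicate:
    """Rename samples to their (treatment, block) role, e.g. ``A.b1.1``.

    Replicates re-randomize which source sample plays which role, so
    dendrograms from different replicates are comparable only after aligning
    leaves by role, not by source sample ID.  Samples sharing a role are
    exchangeable by construction; within a role the suffix follows the source
    ID sort order.
    """
    seen: dict[tuple[str, str], int] = {}
    mapping: dict[str, str] = {}
    for s in sorted(rep.counts.sample_ids):
        role = (rep.labels.group_of(s), rep.labels.block_of(s))
        seen[role] = seen.get(role, 0) + 1
        mapping[s] = f"{role[0]}.{role[1]}.{seen[role]}"
    new_ids = [mapping[s] for s in rep.counts.sample_ids]
    counts = CountMatrix(list(rep.counts.gene_ids), new_ids, rep.counts.counts)
    labels = SampleMeta.from_records(
        [(mapping[s], rep.labels.group_of(s), rep.labels.block_of(s))
         for s in rep.counts.sample_ids])
    return PlasmodeReplicate(counts, labels, dict(rep.injected),
                             rep.scenario_tag, dict(rep.composition))


def call_de_genes(de_table: pd.DataFrame, q_threshold: float = 0.05) -> set[str]:
    """Genes with q-value strictly below the threshold."""
    if de_table.empty:
        return set()
    return set(de_table.loc[de_table["q_value"] < q_threshold, "gene_id"].astype(str))


def effects_from_de_table(de_table: pd.DataFrame) -> dict[str, float]:
    """Multiplicative effects 2**lfc per gene from a DE table."""
    return {str(g): float(2.0**lfc)
            for g, lfc in zip(de_table["gene_id"], de_table["log2_fold_change"])}


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _assign_groups(meta: SampleMeta, sample_ids: list[str],
                   design: EffectPlasmodeDesign,
                   rng: np.random.Generator) -> list[tuple[str, str, str]]:
    """Random A/B assignment within blocks; extra samples are dropped."""
    by_block: dict[str, list[str]] = {}
    for s in sample_ids:
        by_block.setdefault(meta.block_of(s), []).append(s)
    records: list[tuple[str, str, str]] = []
    for block in sorted(by_block):
        samples = by_block[block]
        need = design.group_b_per_block + 1  # at least one A sample
        if len(samples) < need:
            raise ValueError(
                f"block {block!r} has {len(samples)} samples; "
                f"needs >= {need} for {design.group_b_per_block} B + 1 A")
        order = list(rng.permutation(samples))
        b_samples = order[: design.group_b_per_block]
        rest = order[design.group_b_per_block:]
        a_samples = rest[: design.group_a_per_block]
        records += [(s, "B", block) for s in b_samples]
        records += [(s, "A", block) for s in a_samples]
    return records


def _apply_effect(counts: np.ndarray, effect: float, rng: np.random.Generator,
                  stochastic: bool) -> np.ndarray:
    """Scale integer counts by a positive factor, staying integer.

    Deterministic default rounds to the nearest integer.  The stochastic
    alternative thins binomially for effect < 1 and adds a Poisson top-up for
    effect > 1, preserving the same expectation.
    """
    if not stochastic:
        return np.rint(counts * effect).astype(np.int64)
    if effect <= 1.0:
        return rng.binomial(counts, effect)
    return counts + rng.poisson(counts * (effect - 1.0))


def generate_effect_plasmode(cm_one_group: CountMatrix, meta: SampleMeta,
                             de_genes: set[str], de_table: pd.DataFrame,
                             design: EffectPlasmodeDesign,
                             replicate_index: int) -> PlasmodeReplicate:
    """One effect-injection replicate, seeded by (design.seed, replicate_index).

    Samples are partitioned A/B within blocks; a subset S1 of the detected DE
    genes of size round(de_fraction * n_genes) is drawn without replacement
    and each B-arm count of a gene in S1 is scaled by that gene's estimated
    effect.  Every other entry is an untouched copy of the source counts.
    """
    meta.validate_against(cm_one_group)
    rng = np.random.default_rng(
        np.random.SeedSequence([design.seed, int(replicate_index)]))

    n_s1 = _round_half_up(design.de_fraction * cm_one_group.n_genes)
    available = sorted(de_genes & set(cm_one_group.gene_ids))
    if n_s1 > len(available):
        raise ValueError(
            f"requested {n_s1} effect genes but only {len(available)} detected "
            "DE genes are available")

    records = _assign_groups(meta, cm_one_group.sample_ids, design, rng)
    kept = [s for s, _, _ in records]
    labels = SampleMeta.from_records(records)
    cm = cm_one_group.subset_samples(kept)

    s1 = [available[i] for i in rng.choice(len(available), size=n_s1, replace=False)] \
        if n_s1 else []
    effects = effects_from_de_table(de_table)
    injected = {g: effects[g] for g in s1}

    counts = cm.counts.copy()
    row_of = {g: i for i, g in enumerate(cm.gene_ids)}
    b_cols = [j for j, s in enumerate(cm.sample_ids) if labels.group_of(s) == "B"]
    for g in s1:
        i = row_of[g]
        counts[i, b_cols] = _apply_effect(counts[i, b_cols], injected[g], rng,
                                          design.stochastic_effects)
    return PlasmodeReplicate(CountMatrix(cm.gene_ids, cm.sample_ids, counts),
                             labels, injected, scenario_tag="")


def assemble_scenario(rep: PlasmodeReplicate, scenario: str,
                      seed: int = 0) -> PlasmodeReplicate:
    """Restrict a replicate to one of the DE/nonDE gene-subset scenarios.

    DE100 keeps exactly the injected genes; DE10_NONDE90 keeps every gene;
    DE20_NONDE80 keeps the injected genes plus a seeded simple random sample
    of half (floor) of the remaining genes.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")
    s1 = [g for g in rep.counts.gene_ids if g in rep.injected]
    if scenario == "DE10_NONDE90":
        keep = list(rep.counts.gene_ids)
    elif scenario == "DE100":
        keep = s1
    else:
        non_de = [g for g in rep.counts.gene_ids if g not in rep.injected]
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xDE20]))
        take = len(non_de) // 2
        sampled = [non_de[i] for i in sorted(rng.choice(len(non_de), size=take,
                                                        replace=False))]
        keep = sorted(s1 + sampled, key=rep.counts.gene_ids.index)
    return PlasmodeReplicate(rep.counts.subset_genes(keep), rep.labels,
                             dict(rep.injected), scenario_tag=scenario)
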