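"""Read-mixture plasmodes and their reference dissimilarity.

Synthetic samples are built by combining a known proportion of randomly
subsampled reads of each gene from two base samples: per gene g the mixed
count is Binomial(x_g, prop) + Binomial(y_g, 1 - prop).  The default plasmode
holds 12 samples derived from five base samples A..E — the five pure samples
(AAA..EEE), five 2/3:1/3 combinations (AAC, BBC, CCB, DDE, EED) and two
1/2:1/2 combinations (CxB, ExD) — so every pair of samples shares a known
expected fraction of reads.

That expected shared-reads fraction defines the reference similarity s_ij,
and d_ref = 1 - s_ij the reference dissimilarity a good measure should
recover.  The default rule is s_ij = sum over sources of min(p_i, p_j)
(expected fraction of reads with a common origin); a max-min variant is
available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_counts import CountMatrix, SampleMeta
from .plasmode_effects import PlasmodeReplicate

__all__ = [
    "MixtureDesign",
    "ReferenceSimilarity",
    "default_recipes",
    "mix_samples",
    "build_mixture_plasmode",
    "reference_similarity",
]


def default_recipes(base_ids: list[str]) -> list[tuple[str, dict[str, float]]]:
    """The 12-sample recipe set over base samples in roles A..E."""
    if len(base_ids) != 5:
        raise ValueError("default recipes need exactly 5 base samples")
    a, b, c, d, e = base_ids
    return [
        ("AAA", {a: 1.0}), ("BBB", {b: 1.0}), ("CCC", {c: 1.0}),
        ("DDD", {d: 1.0}), ("EEE", {e: 1.0}),
        ("AAC", {a: 2 / 3, c: 1 / 3}), ("BBC", {b: 2 / 3, c: 1 / 3}),
        ("CCB", {c: 2 / 3, b: 1 / 3}), ("DDE", {d: 2 / 3, e: 1 / 3}),
        ("EED", {e: 2 / 3, d: 1 / 3}),
        ("CxB", {c: 0.5, b: 0.5}), ("ExD", {e: 0.5, d: 0.5}),
    ]


@dataclass
class MixtureDesign:
    """Base sample roles, mixing recipes and replicate count."""

    base_ids: list[str]
    recipes: list[tuple[str, dict[str, float]]] | None = None
    n_plasmodes: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.recipes is None:
            self.recipes = default_recipes(self.base_ids)
        names = [name for name, _ in self.recipes]
        if len(set(names)) != len(names):
            raise ValueError("recipe names must be unique")
        for name, comp in self.recipes:
            props = np.array(list(comp.values()), dtype=float)
            if (props <= 0).any():
                raise ValueError(f"recipe {name!r} has non-positive proportions")
            if abs(props.sum() - 1.0) > 1e-9:
                raise ValueError(f"recipe {name!r} proportions must sum to 1")
            unknown = set(comp) - set(self.base_ids)
            if unknown:
                raise ValueError(f"recipe {name!r} uses unknown sources {sorted(unknown)}")


@dataclass
class ReferenceSimilarity:
    """Expected shared-reads similarity s and reference dissimilarity 1 - s."""

    sample_ids: list[str]
    s: np.ndarray

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        if not np.allclose(self.s, self.s.T):
            raise ValueError("similarity must be symmetric")
        if not np.allclose(np.diag(self.s), 1.0):
            raise ValueError("self-similarity must be 1")

    @property
    def d_ref(self) -> np.ndarray:
        return 1.0 - self.s


def mix_samples(x: np.ndarray, y: np.ndarray, prop: float,
                rng: np.random.Generator | int) -> np.ndarray:
    """Per-gene binomial mixture Binomial(x_g, prop) + Binomial(y_g, 1 - prop)."""
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValueError("source count vectors are misaligned (different gene lists)")
    if not 0.0 <= prop <= 1.0:
        raise ValueError("prop must lie in [0, 1]")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return rng.binomial(x.astype(np.int64), prop) + \
        rng.binomial(y.astype(np.int64), 1.0 - prop)


def _mix_composition(base: CountMatrix, comp: dict[str, float],
                     rng: np.random.Generator) -> np.ndarray:
    cols = {s: base.counts[:, base.sample_ids.index(s)] for s in comp}
    items = sorted(comp.items())
    if len(items) == 1:
        # pure samples are exact copies, not resampled
        return cols[items[0][0]].copy()
    if len(items) == 2:
        (s1, p1), (s2, _p2) = items
        return mix_samples(cols[s1], cols[s2], p1, rng)
    # >2 sources: sequential binomial splitting keeps each gene's draws independent
    out = np.zeros(base.n_genes, dtype=np.int64)
    remaining = 1.0
    for s, p in items:
        out += rng.binomial(cols[s], min(1.0, p / remaining)) if remaining > 0 else 0
        remaining -= p
    return out


def build_mixture_plasmode(base: CountMatrix, design: MixtureDesign,
                           replicate_index: int) -> PlasmodeReplicate:
    """One mixture replicate, seeded by (design.seed, replicate_index).

    Pure samples are copied unmixed (and are therefore identical across
    replicates); mixed samples are re-randomized per replicate.  Labels carry
    each synthetic sample's composition.
    """
    missing = set(design.base_ids) - set(base.sample_ids)
    if missing:
        raise ValueError(f"base matrix lacks design samples {sorted(missing)}")
    if set(base.sample_ids) != set(design.base_ids):
        base = base.subset_samples(design.base_ids)
    rng = np.random.default_rng(
        np.random.SeedSequence([design.seed, int(replicate_index), 0x311C]))

    names, columns = [], []
    for name, comp in design.recipes:
        names.append(name)
        columns.append(_mix_composition(base, comp, rng))
    counts = np.column_stack(columns)
    meta = SampleMeta.from_records(
        [(name, "+".join(sorted(comp)), "mixture") for name, comp in design.recipes])
    return PlasmodeReplicate(
        CountMatrix(list(base.gene_ids), names, counts), meta,
        injected={}, scenario_tag="mixture",
        composition={name: dict(comp) for name, comp in design.recipes})


def reference_similarity(design: MixtureDesign, rule: str = "sum_min") -> ReferenceSimilarity:
    """Expected shared-reads similarity between every pair of recipe samples.

    ``sum_min``: s_ij = sum over sources of min(p_i, p_j) — the expected
    fraction of reads with a common origin.  ``max_min``: s_ij = max over
    sources of min(p_i, p_j).  Both agree on the pure-vs-2/3 pairs; sum_min
    is the default because it ranks a pure sample closer to its 2/3 partner
    than the 2/3 mixture is to its minor source.
    """
    if rule not in ("sum_min", "max_min"):
        raise ValueError(f"unknown rule {rule!r}")
    names = [name for name, _ in design.recipes]
    comps = [comp for _, comp in design.recipes]
    n = len(names)
    s = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            shared = [min(comps[i].get(src, 0.0), comps[j].get(src, 0.0))
                      for src in set(comps[i]) | set(comps[j])]
            s[i, j] = s[j, i] = sum(shared) if rule == "sum_min" else max(shared)
    return ReferenceSimilarity(names, s)
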