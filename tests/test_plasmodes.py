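from collections import Counter

import numpy as np
import pandas as pd
import pytest

from plasmodeval import (BaseSimDesign, CountMatrix, EffectPlasmodeDesign,
                         MixtureDesign, SampleMeta, assemble_scenario,
                         build_mixture_plasmode, call_de_genes,
                         complete_linkage, cophenetic_matrix,
                         generate_effect_plasmode, mix_samples,
                         reference_similarity, relabel_by_role,
                         simulate_base_counts)


def de_table_for(gene_ids, lfc=1.0, q=0.01):
    return pd.DataFrame({"gene_id": gene_ids,
                         "log2_fold_change": np.full(len(gene_ids), lfc),
                         "p_value": np.full(len(gene_ids), q / 2),
                         "q_value": np.full(len(gene_ids), q)})


@pytest.fixture
def one_group_base():
    """10 samples in blocks of 4/3/3, single group, seeded."""
    design = BaseSimDesign(
        n_genes=200,
        samples=[("g1", "f1")] * 4 + [("g1", "f2")] * 3 + [("g1", "f3")] * 3,
        frac_de=0.0, seed=21)
    cm, meta, _ = simulate_base_counts(design)
    return cm.drop_all_zero(), meta


class TestCallDEGenes:
    def test_strict_threshold(self):
        tab = pd.DataFrame({"gene_id": ["gene1", "gene2", "gene3"],
                            "log2_fold_change": [1, 2, 3],
                            "p_value": [0.001, 0.01, 0.1],
                            "q_value": [0.01, 0.05, 0.2]})
        assert call_de_genes(tab, 0.05) == {"gene1"}  # 0.05 is excluded

    def test_empty_and_full(self):
        assert call_de_genes(pd.DataFrame(columns=["gene_id", "q_value"])) == set()
        tab = de_table_for(["a", "b"], q=0.001)
        assert call_de_genes(tab) == {"a", "b"}


class TestEffectPlasmodes:
    def test_two_strain_layout_label_multiset(self, one_group_base):
        cm, meta = one_group_base
        design = EffectPlasmodeDesign(de_fraction=0.0, seed=1)
        rep = generate_effect_plasmode(cm, meta, set(), de_table_for([]), design, 0)
        roles = Counter((rep.labels.group_of(s), rep.labels.block_of(s))
                        for s in rep.counts.sample_ids)
        assert roles == {("A", "f1"): 2, ("B", "f1"): 2,
                         ("A", "f2"): 1, ("B", "f2"): 2,
                         ("A", "f3"): 1, ("B", "f3"): 2}

    def test_zero_de_fraction_copies_counts(self, one_group_base):
        cm, meta = one_group_base
        design = EffectPlasmodeDesign(de_fraction=0.0, seed=3)
        rep = generate_effect_plasmode(cm, meta, set(), de_table_for([]), design, 0)
        src = cm.subset_samples(rep.counts.sample_ids)
        assert np.array_equal(rep.counts.counts, src.counts)

    def test_unit_effects_leave_counts_unchanged(self, one_group_base):
        cm, meta = one_group_base
        g1 = set(cm.gene_ids[:60])
        design = EffectPlasmodeDesign(de_fraction=0.10, seed=3)
        rep = generate_effect_plasmode(cm, meta, g1,
                                       de_table_for(cm.gene_ids, lfc=0.0),
                                       design, 0)
        src = cm.subset_samples(rep.counts.sample_ids)
        assert np.array_equal(rep.counts.counts, src.counts)
        assert len(rep.injected) == round(0.10 * cm.n_genes)

    def test_effect_transplantation_is_surgical(self, one_group_base):
        """Genes outside S1 are bit-identical to the source; S1 genes change
        only in B-arm columns, by the rounded multiplicative effect."""
        cm, meta = one_group_base
        g1 = set(cm.gene_ids[:80])
        design = EffectPlasmodeDesign(de_fraction=0.10, seed=5)
        rep = generate_effect_plasmode(cm, meta, g1,
                                       de_table_for(cm.gene_ids, lfc=1.0),
                                       design, 0)
        src = cm.subset_samples(rep.counts.sample_ids)
        b_cols = [j for j, s in enumerate(rep.counts.sample_ids)
                  if rep.labels.group_of(s) == "B"]
        a_cols = [j for j in range(rep.counts.n_samples) if j not in b_cols]
        for i, g in enumerate(rep.counts.gene_ids):
            if g in rep.injected:
                assert np.array_equal(rep.counts.counts[i, b_cols],
                                      np.rint(src.counts[i, b_cols] * 2.0))
                assert np.array_equal(rep.counts.counts[i, a_cols],
                                      src.counts[i, a_cols])
            else:
                assert np.array_equal(rep.counts.counts[i], src.counts[i])

    def test_seeded_determinism(self, one_group_base):
        cm, meta = one_group_base
        g1 = set(cm.gene_ids[:60])
        design = EffectPlasmodeDesign(de_fraction=0.10, seed=9)
        tab = de_table_for(cm.gene_ids)
        rep1 = generate_effect_plasmode(cm, meta, g1, tab, design, 4)
        rep2 = generate_effect_plasmode(cm, meta, g1, tab, design, 4)
        assert rep1.counts == rep2.counts and rep1.injected == rep2.injected
        rep3 = generate_effect_plasmode(cm, meta, g1, tab, design, 5)
        assert rep1.counts != rep3.counts or rep1.injected != rep3.injected

    def test_requesting_more_effects_than_detected_fails(self, one_group_base):
        cm, meta = one_group_base
        design = EffectPlasmodeDesign(de_fraction=0.5, seed=1)
        with pytest.raises(ValueError, match="effect genes"):
            generate_effect_plasmode(cm, meta, set(cm.gene_ids[:3]),
                                     de_table_for(cm.gene_ids), design, 0)

    def test_small_block_fails_with_block_name(self):
        cm = CountMatrix(["g1"], ["s1", "s2"], np.array([[1, 2]]))
        meta = SampleMeta.from_records([("s1", "g1", "tiny"), ("s2", "g1", "tiny")])
        design = EffectPlasmodeDesign(de_fraction=0.0)
        with pytest.raises(ValueError, match="tiny"):
            generate_effect_plasmode(cm, meta, set(), de_table_for([]), design, 0)

    def test_effect_recovery_across_replicates(self, one_group_base):
        """The realized B/A mean count ratio of an injected gene recovers the
        applied effect within 10% when averaged over replicates."""
        cm, meta = one_group_base
        keep = [g for g in cm.gene_ids if cm.counts[cm.gene_ids.index(g)].min() >= 20]
        g1 = set(keep)
        design = EffectPlasmodeDesign(de_fraction=0.10, seed=13)
        tab = de_table_for(cm.gene_ids, lfc=1.5)
        ratios = []
        for k in range(30):
            rep = generate_effect_plasmode(cm, meta, g1, tab, design, k)
            src = cm.subset_samples(rep.counts.sample_ids)
            b = [j for j, s in enumerate(rep.counts.sample_ids)
                 if rep.labels.group_of(s) == "B"]
            for g in rep.injected:
                i = rep.counts.gene_ids.index(g)
                ratios.append(rep.counts.counts[i, b].mean()
                              / src.counts[i, b].mean())
        assert abs(np.mean(ratios) - 2.0**1.5) / 2.0**1.5 < 0.10


class TestScenarios:
    @pytest.fixture
    def replicate(self, one_group_base):
        cm, meta = one_group_base
        g1 = set(cm.gene_ids[:80])
        design = EffectPlasmodeDesign(de_fraction=0.10, seed=2)
        return generate_effect_plasmode(cm, meta, g1,
                                        de_table_for(cm.gene_ids), design, 0)

    def test_row_counts_per_scenario(self, replicate):
        n = replicate.counts.n_genes
        n_s1 = len(replicate.injected)
        de100 = assemble_scenario(replicate, "DE100")
        assert de100.counts.n_genes == n_s1
        assert set(de100.counts.gene_ids) == set(replicate.injected)
        full = assemble_scenario(replicate, "DE10_NONDE90")
        assert full.counts.n_genes == n
        half = assemble_scenario(replicate, "DE20_NONDE80", seed=1)
        assert half.counts.n_genes == n_s1 + (n - n_s1) // 2
        assert set(replicate.injected) <= set(half.counts.gene_ids)

    def test_scenario_sampling_is_seeded(self, replicate):
        a = assemble_scenario(replicate, "DE20_NONDE80", seed=7)
        b = assemble_scenario(replicate, "DE20_NONDE80", seed=7)
        c = assemble_scenario(replicate, "DE20_NONDE80", seed=8)
        assert a.counts == b.counts
        assert a.counts != c.counts

    def test_unknown_scenario_rejected(self, replicate):
        with pytest.raises(ValueError, match="unknown scenario"):
            assemble_scenario(replicate, "DE50")

    def test_relabel_by_role_is_alignable(self, replicate):
        rel = relabel_by_role(assemble_scenario(replicate, "DE100"))
        assert sorted(rel.counts.sample_ids) == sorted(
            f"{g}.{b}.{i}" for (g, b), n in
            Counter((rel.labels.group_of(s), rel.labels.block_of(s))
                    for s in rel.counts.sample_ids).items()
            for i in range(1, n + 1))


class TestMixSamples:
    def test_boundary_proportions(self, rng):
        x = rng.poisson(50, size=30)
        y = rng.poisson(10, size=30)
        assert np.array_equal(mix_samples(x, y, 1.0, rng), x)
        assert np.array_equal(mix_samples(x, y, 0.0, rng), y)

    def test_binomial_expectation(self):
        """x=300, y=30 at prop 2/3: mean of many draws near 210."""
        rng = np.random.default_rng(99)
        draws = [mix_samples(np.array([300]), np.array([30]), 2 / 3, rng)[0]
                 for _ in range(10_000)]
        assert abs(np.mean(draws) - 210.0) < 3.0

    def test_equal_sources_keep_expectation(self):
        rng = np.random.default_rng(7)
        x = np.full(2000, 40)
        mixed = mix_samples(x, x, 0.3, rng)
        assert abs(mixed.mean() - 40.0) < 0.5

    def test_misaligned_gene_lists_rejected(self, rng):
        with pytest.raises(ValueError, match="misaligned"):
            mix_samples(np.zeros(3, dtype=int), np.zeros(4, dtype=int), 0.5, rng)


class TestMixturePlasmodes:
    @pytest.fixture
    def base5(self):
        design = BaseSimDesign(n_genes=300,
                               samples=[("g1", f"i{k}") for k in range(5)],
                               frac_de=0.0, block_lfc_sd=0.5, seed=31)
        cm, _, _ = simulate_base_counts(design)
        return cm.drop_all_zero()

    def test_default_design_yields_twelve_samples(self, base5):
        design = MixtureDesign(base_ids=base5.sample_ids, seed=1)
        rep = build_mixture_plasmode(base5, design, 0)
        assert rep.counts.n_samples == 12
        assert set(rep.counts.sample_ids) == {
            "AAA", "BBB", "CCC", "DDD", "EEE", "AAC", "BBC", "CCB", "DDE",
            "EED", "CxB", "ExD"}

    def test_pure_samples_are_exact_copies(self, base5):
        design = MixtureDesign(base_ids=base5.sample_ids, seed=1)
        rep = build_mixture_plasmode(base5, design, 0)
        for role, src in zip(["AAA", "BBB", "CCC", "DDD", "EEE"], base5.sample_ids):
            j = rep.counts.sample_ids.index(role)
            assert np.array_equal(rep.counts.counts[:, j],
                                  base5.counts[:, base5.sample_ids.index(src)])

    def test_pure_samples_identical_across_replicates(self, base5):
        design = MixtureDesign(base_ids=base5.sample_ids, seed=1)
        r0 = build_mixture_plasmode(base5, design, 0)
        r1 = build_mixture_plasmode(base5, design, 1)
        j = r0.counts.sample_ids.index("AAA")
        assert np.array_equal(r0.counts.counts[:, j], r1.counts.counts[:, j])
        jm = r0.counts.sample_ids.index("AAC")
        assert not np.array_equal(r0.counts.counts[:, jm], r1.counts.counts[:, jm])

    def test_seeded_determinism(self, base5):
        design = MixtureDesign(base_ids=base5.sample_ids, seed=4)
        assert build_mixture_plasmode(base5, design, 2).counts == \
            build_mixture_plasmode(base5, design, 2).counts

    def test_column_total_expectation(self, base5):
        """E[total of a mixed sample] = sum of prop * source totals, within 1%."""
        design = MixtureDesign(base_ids=base5.sample_ids, seed=6)
        totals = {s: base5.counts[:, j].sum()
                  for j, s in enumerate(base5.sample_ids)}
        a, c = base5.sample_ids[0], base5.sample_ids[2]
        expected = 2 / 3 * totals[a] + 1 / 3 * totals[c]
        observed = np.mean([
            build_mixture_plasmode(base5, design, k).counts.counts[
                :, build_mixture_plasmode(base5, design, k).counts
                .sample_ids.index("AAC")].sum()
            for k in range(20)])
        assert abs(observed - expected) / expected < 0.01

    def test_missing_base_sample_rejected(self, base5):
        design = MixtureDesign(base_ids=base5.sample_ids, seed=1)
        with pytest.raises(ValueError, match="lacks"):
            build_mixture_plasmode(base5.subset_samples(base5.sample_ids[:4]),
                                   design, 0)

    def test_invalid_recipes_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            MixtureDesign(base_ids=list("abcde"),
                          recipes=[("bad", {"a": 0.5, "b": 0.4})])
        with pytest.raises(ValueError, match="unknown sources"):
            MixtureDesign(base_ids=list("abcde"), recipes=[("bad", {"z": 1.0})])


class TestReferenceSimilarity:
    @pytest.fixture
    def ref(self):
        return reference_similarity(MixtureDesign(base_ids=list("abcde")))

    def entry(self, ref, x, y):
        return ref.s[ref.sample_ids.index(x), ref.sample_ids.index(y)]

    def test_pure_vs_two_thirds_partner(self, ref):
        assert np.isclose(self.entry(ref, "AAA", "AAC"), 2 / 3)

    def test_self_and_disjoint(self, ref):
        assert np.isclose(self.entry(ref, "AAA", "AAA"), 1.0)
        assert np.isclose(self.entry(ref, "AAA", "DDD"), 0.0)
        assert np.isclose(ref.d_ref[ref.sample_ids.index("AAA"),
                                    ref.sample_ids.index("DDD")], 1.0)

    def test_sum_min_orders_partners_ahead_of_minor_sources(self, ref):
        # AAA is closer to AAC (1/3 apart) than AAC is to CCC (2/3 apart)
        d = ref.d_ref
        i = ref.sample_ids.index
        assert d[i("AAA"), i("AAC")] < d[i("AAC"), i("CCC")]

    def test_max_min_rule_differs(self):
        design = MixtureDesign(base_ids=list("abcde"))
        s_sum = reference_similarity(design, rule="sum_min")
        s_max = reference_similarity(design, rule="max_min")
        assert not np.allclose(s_sum.s, s_max.s)

    def test_reference_dendrogram_joins_pure_samples_to_partners_first(self, ref):
        """In the reference tree every pure sample's nearest cophenetic
        neighbour set is its 2/3 partner, and samples built from disjoint
        sources only meet at the maximal height 1."""
        t = complete_linkage(ref.d_ref, ref.sample_ids)
        c = cophenetic_matrix(t)
        i = {s: j for j, s in enumerate(t.leaf_ids)}
        for pure, partner in [("AAA", "AAC"), ("BBB", "BBC"),
                              ("DDD", "DDE"), ("EEE", "EED")]:
            others = [s for s in t.leaf_ids if s not in (pure, partner)]
            assert c[i[pure], i[partner]] <= min(c[i[pure], i[o]] for o in others)
        for x in ("AAA", "AAC", "BBB", "BBC", "CCB", "CCC", "CxB"):
            for y in ("DDD", "DDE", "EED", "EEE", "ExD"):
                assert np.isclose(c[i[x], i[y]], 1.0)
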