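"""Haplotype phasing by co-segregation: exactness, completeness, events."""

import itertools

import numpy as np
import pytest

from splicekin.cohort import CohortConfig, simulate_family
from splicekin.pedigree import PedRecord, Pedigree
from splicekin.phasing import (
    MendelianInconsistencyError,
    cosegregation_table,
    phase_family,
)

GENES = ["g1", "g2", "g3"]


def make_ped(records):
    return Pedigree([PedRecord(*r) for r in records])


def genotypes_from_haps(haps: dict) -> dict:
    gt = {}
    for animal, (h1, h2) in haps.items():
        for i, g in enumerate(GENES):
            gt[(animal, g)] = {h1[i], h2[i]}
    return gt


TRIO = make_ped(
    [
        ("S", None, None, "M", "fam"),
        ("D", None, None, "F", "fam"),
        ("K", "S", "D", "M", "fam"),
    ]
)


class TestPhaseFamily:
    def test_homozygous_trio_unique_phase(self):
        haps = {
            "S": (("a1", "b1", "c1"),) * 2,
            "D": (("a2", "b2", "c2"),) * 2,
            "K": (("a1", "b1", "c1"), ("a2", "b2", "c2")),
        }
        res = phase_family(TRIO, genotypes_from_haps(haps), gene_order=GENES)
        assert res.total_events == 0
        assert len(res.labels) == 2
        assert set(res.by_animal["K"]) == {("a1", "b1", "c1"), ("a2", "b2", "c2")}

    def test_four_generation_family_recovers_truth(self):
        cfg = CohortConfig(seed=4)
        _, ped, truth = simulate_family(cfg)
        gt = truth.genotypes()
        for fam, members in ped.families.items():
            res = phase_family(
                ped.family(fam),
                {k: v for k, v in gt.items() if k[0] in members},
                gene_order=truth.gene_order,
            )
            assert res.total_events == 0
            for a in members:
                got = {tuple(h) for h in res.by_animal[a]}
                want = {tuple(h) for h in truth.haplotypes[a]}
                assert got == want

    def test_planted_crossover_reported_at_correct_interval(self):
        cfg = CohortConfig(seed=3, planted_crossovers=(("F1", "B1", "F1-A1", 2),))
        _, ped, truth = simulate_family(cfg)
        gt = truth.genotypes()
        members = ped.families["F1"]
        res = phase_family(
            ped.family("F1"),
            {k: v for k, v in gt.items() if k[0] in members},
            gene_order=truth.gene_order,
        )
        recombs = [e for e in res.events if e["kind"] == "recombination"]
        assert res.total_events == 1
        assert len(recombs) == 1
        assert recombs[0]["child"] == "F1-B1"
        assert recombs[0]["parent"] == "F1-A1"
        assert recombs[0]["detail"] == "between gene2 and gene3"

    def test_relabeling_invariance(self):
        """Phase depends only on the identity structure of allele names."""
        cfg = CohortConfig(seed=5)
        _, ped, truth = simulate_family(cfg)
        gt = truth.genotypes()
        members = ped.families["F1"]
        sub = {k: v for k, v in gt.items() if k[0] in members}
        res1 = phase_family(ped.family("F1"), sub, gene_order=truth.gene_order)
        rename = lambda a: "X" + a[::-1]
        sub2 = {k: {rename(a) for a in v} for k, v in sub.items()}
        res2 = phase_family(ped.family("F1"), sub2, gene_order=truth.gene_order)
        for a in members:
            h1 = {tuple(rename(x) for x in h) for h in res1.by_animal[a]}
            assert h1 == {tuple(h) for h in res2.by_animal[a]}

    def test_event_budget_raises(self):
        haps = {
            "S": (("a1", "b1", "c1"),) * 2,
            "D": (("a2", "b2", "c2"),) * 2,
            # child carries an allele neither parent has: needs a mutation
            "K": (("a1", "b1", "c9"), ("a2", "b2", "c2")),
        }
        with pytest.raises(MendelianInconsistencyError):
            phase_family(TRIO, genotypes_from_haps(haps), gene_order=GENES, max_events=0)

    def test_untyped_animals_transmit_unconstrained(self):
        haps = {
            "S": (("a1", "b1", "c1"),) * 2,
            "D": (("a2", "b2", "c2"),) * 2,
            "K": (("a1", "b1", "c1"), ("a2", "b2", "c2")),
        }
        gt = genotypes_from_haps(haps)
        gt = {k: v for k, v in gt.items() if k[0] != "D"}  # D untyped
        res = phase_family(TRIO, gt, gene_order=GENES)
        assert res.total_events == 0


class TestSearchCompleteness:
    @staticmethod
    def _oracle_cost(hap, parent_pair, n):
        """Independent minimal-event computation: enumerate every copy path."""
        best = 10 ** 9
        for sigma in itertools.product((0, 1), repeat=n):
            switches = sum(1 for i in range(n - 1) if sigma[i] != sigma[i + 1])
            mm = sum(
                1
                for i in range(n)
                if hap[i] is not None
                and parent_pair[sigma[i]][i] is not None
                and hap[i] != parent_pair[sigma[i]][i]
            )
            best = min(best, switches + mm)
        return best

    def test_matches_brute_force_on_small_families(self):
        """Exhaustive oracle over all phase assignments for ≤6 animals."""
        rng = np.random.default_rng(11)
        ped = make_ped(
            [
                ("S", None, None, "M", "f"),
                ("D", None, None, "F", "f"),
                ("K1", "S", "D", "M", "f"),
                ("K2", "S", "D", "F", "f"),
                ("M", None, None, "M", "f"),
                ("G", "M", "K2", "F", "f"),
            ]
        )
        n = len(GENES)
        for trial in range(15):
            alleles = [[f"{g}{i}" for i in range(3)] for g in range(n)]
            haps = {}
            pool = [
                tuple(alleles[g][rng.integers(3)] for g in range(n)) for _ in range(4)
            ]
            for f in ("S", "D", "M"):
                haps[f] = (pool[rng.integers(4)], pool[rng.integers(4)])
            for child, (p1, p2) in (("K1", ("S", "D")), ("K2", ("S", "D")), ("G", ("M", "K2"))):
                hs = haps[p1][rng.integers(2)]
                hd = haps[p2][rng.integers(2)]
                if rng.random() < 0.3:  # random corruption introduces events
                    i = int(rng.integers(n))
                    hs = hs[:i] + (alleles[i][int(rng.integers(3))],) + hs[i + 1 :]
                haps[child] = (hs, hd)
            gt = genotypes_from_haps(haps)
            res = phase_family(ped, gt, gene_order=GENES)

            # brute force over all phase splits of every animal
            def options(animal):
                per_gene = [sorted(gt[(animal, g)]) for g in GENES]
                outs = set()
                for combo in itertools.product(*[
                    [(a[0], a[-1]), (a[-1], a[0])] for a in per_gene
                ]):
                    outs.add((tuple(c[0] for c in combo), tuple(c[1] for c in combo)))
                return sorted(outs)

            order = ped.animals
            best = 10 ** 9
            for assign in itertools.product(*[options(a) for a in order]):
                ph = dict(zip(order, assign))
                cost = 0
                for rec in ped:
                    if rec.is_founder:
                        continue
                    h1, h2 = ph[rec.animal]
                    cost += min(
                        self._oracle_cost(h1, ph[rec.sire], n)
                        + self._oracle_cost(h2, ph[rec.dam], n),
                        self._oracle_cost(h2, ph[rec.sire], n)
                        + self._oracle_cost(h1, ph[rec.dam], n),
                    )
                best = min(best, cost)
            assert res.total_events == best

    def test_haplotype_count_bound_without_events(self):
        cfg = CohortConfig(seed=6)
        _, ped, truth = simulate_family(cfg)
        gt = truth.genotypes()
        for fam, members in ped.families.items():
            fped = ped.family(fam)
            res = phase_family(
                fped,
                {k: v for k, v in gt.items() if k[0] in members},
                gene_order=truth.gene_order,
            )
            if res.total_events == 0:
                assert len(res.labels) <= 2 * len(fped.founders)


class TestCosegregation:
    def _family(self):
        ped = make_ped(
            [
                ("S", None, None, "M", "f"),
                ("D", None, None, "F", "f"),
                ("K1", "S", "D", "M", "f"),
                ("K2", "S", "D", "F", "f"),
                ("K3", "S", "D", "M", "f"),
                ("K4", "S", "D", "F", "f"),
            ]
        )
        A, B = ("a1", "b1", "c1"), ("a2", "b2", "c2")
        C, Dh = ("a3", "b3", "c3"), ("a4", "b4", "c4")
        haps = {
            "S": (A, B),
            "D": (C, Dh),
            "K1": (A, C),
            "K2": (A, Dh),
            "K3": (B, C),
            "K4": (A, C),
        }
        res = phase_family(ped, genotypes_from_haps(haps), gene_order=GENES)
        return ped, res, haps

    def test_identical_labels_full_concordance(self):
        ped, res, haps = self._family()
        ext = {a: res.label_pair(a) for a in ped.animals}
        _, summary = cosegregation_table(res, ped, ext)
        assert summary["transmissions"] == 8
        assert summary["discordant"] == 0
        assert summary["excluded"] == 0

    def test_planted_crossover_single_discordance(self):
        ped, res, haps = self._family()
        # external labels mirror the haplotypes except in K4, where the
        # sire-derived chromosome recombined between the two loci
        hap_ext = {
            ("a1", "b1", "c1"): "mS1",
            ("a2", "b2", "c2"): "mS2",
            ("a3", "b3", "c3"): "mD1",
            ("a4", "b4", "c4"): "mD2",
        }
        ext = {
            a: tuple(hap_ext[h] for h in haps[a]) for a in ped.animals
        }
        ext["K4"] = ("mS2", "mD1")  # BTN hap A arrived with the mS2 MHC
        _, summary = cosegregation_table(res, ped, ext)
        assert summary["transmissions"] == 8
        assert summary["discordant"] == 1

    def test_shuffled_labels_lose_concordance(self):
        ped, res, haps = self._family()
        hap_ext = {
            ("a1", "b1", "c1"): "mS1",
            ("a2", "b2", "c2"): "mS2",
            ("a3", "b3", "c3"): "mD1",
            ("a4", "b4", "c4"): "mD2",
        }
        ext = {a: tuple(hap_ext[h] for h in haps[a]) for a in ped.animals}
        rng = np.random.default_rng(2)
        shuffled = {}
        for a in ped.animals:
            pair = list(ext[a])
            if a in ("K1", "K2", "K3", "K4"):
                pair = list(rng.permutation(["mS1", "mS2", "mD1", "mD2"])[:2])
            shuffled[a] = tuple(pair)
        _, summary = cosegregation_table(res, ped, shuffled)
        assert summary["discordant"] > 0 or summary["excluded"] > 0

    def test_missing_animal_excluded_with_warning(self):
        ped, res, haps = self._family()
        ext = {a: res.label_pair(a) for a in ped.animals if a != "K1"}
        _, summary = cosegregation_table(res, ped, ext)
        assert summary["excluded"] >= 1
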