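"""Pedigree-based haplotype phasing of tightly linked genes.

Alleles of genes duplicated in close proximity co-segregate: each parental
chromosome transmits its whole multi-gene allele combination as one
haplotype. Phasing is an exact search: every animal's genotypes are split
into two per-chromosome allele tuples, founders' splits are free variables,
and each non-founder's two haplotypes must each derive from one parent —
either copied intact (cost 0) or explained by events: a crossover between
adjacent genes (cost 1 per switch) or a de-novo point mutation at one gene
(cost 1). The search minimizes total event count, then the number of
distinct haplotypes, then a lexicographic canonical form; families in this
domain are small (13–19 animals), so exhaustive branch-and-bound is exact.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import pandas as pd

from .pedigree import Pedigree

__all__ = [
    "MendelianInconsistencyError",
    "PhasingResult",
    "phase_family",
    "cosegregation_table",
]

log = logging.getLogger(__name__)

WILD = None  # untyped-gene wildcard inside haplotype tuples


class MendelianInconsistencyError(ValueError):
    pass


@dataclass
class PhasingResult:
    gene_order: list[str]
    by_animal: dict  # animal -> (hap_from_sire, hap_from_dam) as allele tuples
    labels: dict  # haplotype tuple -> single-letter label (a, b, c, ...)
    events: list  # dicts: child, parent, kind ('recombination'|'mutation'), detail
    total_events: int
    n_solutions: int  # optimal solutions found (ties reported, first kept)

    def label_pair(self, animal) -> tuple[str, str]:
        h1, h2 = self.by_animal[animal]
        return self.labels[h1], self.labels[h2]

    def haplotype_set(self) -> set:
        return set(self.labels)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for animal, (h1, h2) in sorted(self.by_animal.items()):
            rows.append(
                {
                    "animal": animal,
                    "hap_paternal": self.labels[h1],
                    "hap_maternal": self.labels[h2],
                    **{
                        f"{g}_pat": h1[i] or "?"
                        for i, g in enumerate(self.gene_order)
                    },
                    **{
                        f"{g}_mat": h2[i] or "?"
                        for i, g in enumerate(self.gene_order)
                    },
                }
            )
        return pd.DataFrame(rows)


def _phase_options(genotype_row):
    """All distinct unordered splits of per-gene allele sets into two tuples."""
    per_gene = []
    for alleles in genotype_row:
        if alleles is None:
            per_gene.append([(WILD, WILD)])
        elif len(alleles) == 1:
            (a,) = alleles
            per_gene.append([(a, a)])
        else:
            a, b = sorted(alleles)
            per_gene.append([(a, b), (b, a)])
    seen = set()
    out = []
    for combo in itertools.product(*per_gene):
        h1 = tuple(c[0] for c in combo)
        h2 = tuple(c[1] for c in combo)
        key = frozenset((h1, h2))
        if key in seen:
            continue
        seen.add(key)
        out.append((h1, h2))
    return out


def _trans_cost(child_hap, parent_pair):
    """Minimal event cost of deriving ``child_hap`` from one parent.

    Dynamic program over genes: state = which parental haplotype is being
    copied; a switch costs 1 (crossover between adjacent informative genes),
    an allele mismatch costs 1 (de-novo mutation). Wildcards match anything.
    """
    p1, p2 = parent_pair
    c0 = c1 = 0
    for g, a in enumerate(child_hap):
        m0 = 0 if a is WILD or p1[g] is WILD or a == p1[g] else 1
        m1 = 0 if a is WILD or p2[g] is WILD or a == p2[g] else 1
        c0, c1 = min(c0, c1 + 1) + m0, min(c1, c0 + 1) + m1
    return min(c0, c1)


def _trans_events(child, parent, child_hap, parent_pair, gene_order):
    """Traceback of one optimal derivation, as reportable event records."""
    p1, p2 = parent_pair
    n = len(child_hap)
    INF = 10 ** 9
    cost = [[0, 0] for _ in range(n + 1)]
    back = [[None, None] for _ in range(n + 1)]
    for g in range(1, n + 1):
        a = child_hap[g - 1]
        for s, p in ((0, p1), (1, p2)):
            m = 0 if a is WILD or p[g - 1] is WILD or a == p[g - 1] else 1
            stay = cost[g - 1][s]
            switch = cost[g - 1][1 - s] + 1
            if stay <= switch:
                cost[g][s] = stay + m
                back[g][s] = s
            else:
                cost[g][s] = switch + m
                back[g][s] = 1 - s
    s = 0 if cost[n][0] <= cost[n][1] else 1
    events = []
    for g in range(n, 0, -1):
        p = (p1, p2)[s]
        a = child_hap[g - 1]
        if not (a is WILD or p[g - 1] is WILD or a == p[g - 1]):
            events.append(
                {
                    "child": child,
                    "parent": parent,
                    "kind": "mutation",
                    "detail": f"{gene_order[g - 1]}: {p[g - 1]} -> {a}",
                }
            )
        ps = back[g][s]
        if ps != s:
            events.append(
                {
                    "child": child,
                    "parent": parent,
                    "kind": "recombination",
                    "detail": f"between {gene_order[g - 2]} and {gene_order[g - 1]}",
                }
            )
        s = ps
    return events[::-1]


def phase_family(
    pedigree: Pedigree,
    genotypes: dict,
    gene_order: list[str] | None = None,
    max_events: int | None = None,
) -> PhasingResult:
    """Phase one family by exhaustive branch-and-bound.

    ``genotypes`` maps ``(animal, gene)`` to a set of one or two allele
    names; missing entries are untyped. Raises
    :class:`MendelianInconsistencyError` when no assignment within
    ``max_events`` exists (with unlimited events every input is explainable,
    so the error fires only under an event budget).
    """
    if gene_order is None:
        gene_order = sorted({g for (_, g) in genotypes})
    animals = pedigree.animals
    rows = {
        a: [genotypes.get((a, g)) for g in gene_order]
        for a in animals
    }
    options = {a: _phase_options(rows[a]) for a in animals}

    best: dict = {"key": None, "phases": None, "count": 0}

    order = animals  # already topological
    phases: dict[str, tuple] = {}

    def leaf_key():
        # secondary criteria: distinct haplotype count, then canonical label seq
        haps = []
        for a in order:
            haps.extend(phases[a])
        distinct = len(set(haps))
        flat = tuple(tuple("" if x is WILD else x for x in h) for h in haps)
        return distinct, flat

    bound = max_events if max_events is not None else 10 ** 9

    def dfs(i, cost):
        if best["key"] is not None and cost > best["key"][0]:
            return
        if cost > bound:
            return
        if i == len(order):
            key = (cost, *leaf_key())
            if best["key"] is None or key < best["key"]:
                best["key"] = key
                best["phases"] = dict(phases)
                best["count"] = 1
            elif key == best["key"]:
                best["count"] += 1
            return
        animal = order[i]
        rec = pedigree[animal]
        for h1, h2 in options[animal]:
            if rec.is_founder:
                phases[animal] = (h1, h2)
                dfs(i + 1, cost)
            else:
                sp = phases[rec.sire]
                dp = phases[rec.dam]
                arrangements = [(h1, h2)] if h1 == h2 else [(h1, h2), (h2, h1)]
                for hs, hd in arrangements:
                    c = _trans_cost(hs, sp) + _trans_cost(hd, dp)
                    phases[animal] = (hs, hd)
                    dfs(i + 1, cost + c)
            phases.pop(animal, None)

    dfs(0, 0)
    if best["phases"] is None:
        raise MendelianInconsistencyError(
            f"no phase assignment within {max_events} events"
        )
    total = best["key"][0]
    if max_events is not None and total > max_events:
        raise MendelianInconsistencyError(f"needs {total} events (> {max_events})")

    by_animal = best["phases"]
    events = []
    for a in order:
        rec = pedigree[a]
        if rec.is_founder:
            continue
        hs, hd = by_animal[a]
        events.extend(_trans_events(a, rec.sire, hs, by_animal[rec.sire], gene_order))
        events.extend(_trans_events(a, rec.dam, hd, by_animal[rec.dam], gene_order))

    labels: dict[tuple, str] = {}
    for a in order:
        for h in by_animal[a]:
            if h not in labels:
                labels[h] = _letter(len(labels))
    if best["count"] > 1:
        log.info("phasing: %d equally parsimonious solutions; canonical one kept", best["count"])
    return PhasingResult(
        gene_order=list(gene_order),
        by_animal=by_animal,
        labels=labels,
        events=events,
        total_events=total,
        n_solutions=best["count"],
    )


def _letter(i: int) -> str:
    out = ""
    while True:
        out = chr(ord("a") + i % 26) + out
        i = i // 26 - 1
        if i < 0:
            return out


def cosegregation_table(
    result: PhasingResult, pedigree: Pedigree, external_labels: dict
) -> tuple[pd.DataFrame, dict]:
    """Co-transmission of phased haplotypes with an external (e.g. MHC)
    haplotype labelling.

    ``external_labels`` maps animal -> (label, label). For every parent→child
    transmission where both labellings are resolvable, the transmitted
    haplotype pair is counted; concordant transmissions are those matching
    the modal external partner of each haplotype. Animals missing from either
    labelling are excluded with a warning.
    """
    counts: dict[tuple, int] = {}
    skipped = 0
    for rec in pedigree:
        if rec.is_founder:
            continue
        trio = (rec.animal, rec.sire, rec.dam)
        if any(a not in result.by_animal or a not in external_labels for a in trio):
            log.warning("cosegregation: %s excluded (missing labelling)", rec.animal)
            skipped += 1
            continue
        e1, e2 = external_labels[rec.animal]
        hs, hd = result.by_animal[rec.animal]
        sire_ext = set(external_labels[rec.sire])
        dam_ext = set(external_labels[rec.dam])
        # resolve which external label came from which parent
        resolution = None
        for ext_s, ext_d in ((e1, e2), (e2, e1)):
            if ext_s in sire_ext and ext_d in dam_ext:
                if resolution is not None and resolution != (ext_s, ext_d):
                    resolution = "ambiguous"
                    break
                resolution = (ext_s, ext_d)
        if resolution is None or resolution == "ambiguous":
            log.warning("cosegregation: %s external origin unresolved", rec.animal)
            skipped += 1
            continue
        ext_s, ext_d = resolution
        for hap, ext in ((hs, ext_s), (hd, ext_d)):
            key = (rec.family, result.labels[hap], ext)
            counts[key] = counts.get(key, 0) + 1
    df = pd.DataFrame(
        [
            {"family": f, "haplotype": h, "external": e, "count": c}
            for (f, h, e), c in sorted(counts.items())
        ],
        columns=["family", "haplotype", "external", "count"],
    )
    concordant = 0
    total = int(df["count"].sum()) if len(df) else 0
    if len(df):
        modal = df.groupby(["family", "haplotype"])["count"].max()
        concordant = int(modal.sum())
    summary = {
        "transmissions": total,
        "concordant": concordant,
        "discordant": total - concordant,
        "excluded": skipped,
    }
    return df, summary
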